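"""Orchestration: simulate -> fitmaps -> anatomy -> stats, with a manifest.

Each stage reads only the previous stage's on-disk artifacts, so stages can
be re-run individually from the CLI.  Every written artifact is recorded in
``manifest.json`` with its SHA-256; identical configuration and seed give
identical manifest hashes.  A stage failure marks the stage failed in the
manifest and skips the later stages, leaving earlier artifacts intact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import synthesize_acquisition
from .anatomy import build_ribbon_model, segment_ribbon, synthesize_mprage
from .config import PipelineConfig
from .io import (
    config_hash,
    file_sha256,
    load_nifti,
    read_covariates,
    save_nifti,
    write_covariates,
    write_sidecar,
)
from .model import CorticalAgingModel
from .phantom import build_phantom, plan_cohort
from .relaxometry import QMaps, fit_qmaps
from .stats import cortical_summary, extract_lobe_values, global_summary

__all__ = ["run_pipeline", "stage_simulate", "stage_fitmaps", "stage_anatomy", "stage_stats"]

log = logging.getLogger("cortexage")

TRUTH_PARAMS = ("T1", "PD", "T2", "T2star", "T2prime")
STACKS = ("vfa", "fse", "ge", "b1", "te_pair")


def _subject_ids(n: int) -> list[str]:
    return [f"sub-{i + 1:03d}" for i in range(n)]


def stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    """Generate the phantom cohort and synthesize all acquisitions."""
    out.mkdir(parents=True, exist_ok=True)
    aging = config.aging_model.build()
    geo = config.geometry
    affine = geo.affine()
    c = config.cohort
    ages, sexes, seeds = plan_cohort(c.n, c.age_range, c.sex_counts, config.seed)
    written = []
    cov_rows = []
    chash = config_hash(config.to_dict())
    for sid, age, sex, sseq in zip(_subject_ids(c.n), ages, sexes, seeds):
        phantom_seed, acq_seed = sseq.spawn(2)
        ph = build_phantom(age, sex, aging, geo, phantom_seed)
        bundle = synthesize_acquisition(ph, config.protocol, acq_seed)
        sdir = out / sid
        written.append(save_nifti(ph.labels, affine, sdir / "labels.nii.gz", dtype=np.uint8))
        for p in TRUTH_PARAMS:
            written.append(save_nifti(ph.maps[p], affine, sdir / f"truth_{p}.nii.gz"))
        for name in STACKS:
            written.append(save_nifti(getattr(bundle, name), affine, sdir / f"{name}.nii.gz"))
        written.append(save_nifti(bundle.kappa_field, affine, sdir / "kappa.nii.gz"))
        written.append(save_nifti(bundle.receive_field, affine, sdir / "receive.nii.gz"))
        written.append(
            write_sidecar(
                {
                    "subject_id": sid,
                    "protocol": dataclasses.asdict(config.protocol),
                    "noise_sd": bundle.noise_sd,
                    "seed": config.seed,
                    "config_hash": chash,
                    "center_mm": ph.center_mm,
                    "rotation_rad": ph.rotation_rad,
                    "true_thickness_mm": ph.true_thickness_mm,
                },
                sdir / "acquisition.json",
            )
        )
        cov_rows.append(
            {"subject_id": sid, "age_years": age, "sex": sex, "tiv_ml": ph.tiv_ml}
        )
    written.append(write_covariates(pd.DataFrame(cov_rows), out / "covariates.csv"))
    return written


def stage_fitmaps(config: PipelineConfig, sim_dir: Path, out: Path) -> list[Path]:
    """Fit B1/T1/PD/T2/T2* and derive T2' for every simulated subject."""
    out.mkdir(parents=True, exist_ok=True)
    written = []
    chash = config_hash(config.to_dict())
    for sid in _subject_ids(config.cohort.n):
        sdir = sim_dir / sid
        labels, affine = load_nifti(sdir / "labels.nii.gz")
        meta = json.loads((sdir / "acquisition.json").read_text())
        bundle_arrays = {name: load_nifti(sdir / f"{name}.nii.gz")[0] for name in STACKS}
        receive, _ = load_nifti(sdir / "receive.nii.gz")
        from .acquisition import AcquisitionBundle

        bundle = AcquisitionBundle(
            **bundle_arrays,
            protocol=config.protocol,
            voxel_size_mm=config.geometry.voxel_size_mm,
            noise_sd=float(meta["noise_sd"]),
            receive_field=receive,
        )
        floor = 3.0 * bundle.noise_sd if bundle.noise_sd > 0 else None
        qmaps = fit_qmaps(bundle, csf_mask=labels == 4, floor=floor)
        odir = out / sid
        for p in qmaps.parameters:
            written.append(save_nifti(qmaps[p], affine, odir / f"{p}.nii.gz"))
            written.append(
                save_nifti(qmaps.mask(p), affine, odir / f"mask_{p}.nii.gz", dtype=np.uint8)
            )
        for p, r2 in qmaps.r2.items():
            written.append(save_nifti(r2, affine, odir / f"r2_{p}.nii.gz"))
        written.append(
            write_sidecar(
                {"subject_id": sid, "config_hash": chash, "floor": floor or 0.0},
                odir / "fit.json",
            )
        )
    return written


def stage_anatomy(config: PipelineConfig, sim_dir: Path, fit_dir: Path, out: Path) -> list[Path]:
    """Synthetic anatomy, ribbon masks, thickness, lobes and TIV per subject."""
    out.mkdir(parents=True, exist_ok=True)
    written = []
    rows = []
    from .anatomy import LOBE_NAMES

    for sid in _subject_ids(config.cohort.n):
        labels, affine = load_nifti(sim_dir / sid / "labels.nii.gz")
        labels = labels.astype(np.uint8)
        meta = json.loads((sim_dir / sid / "acquisition.json").read_text())
        t1, _ = load_nifti(fit_dir / sid / "T1.nii.gz")
        pd_map, _ = load_nifti(fit_dir / sid / "PD.nii.gz")
        brain = labels > 0
        mprage = synthesize_mprage(t1, pd_map, mask=brain)
        ribbon, wm, csf, dice = segment_ribbon(
            mprage, brain, truth_labels=labels, oracle=config.oracle_ribbon
        )
        rm = build_ribbon_model(
            ribbon,
            wm,
            csf,
            config.geometry.voxel_size_mm,
            center_mm=np.asarray(meta["center_mm"]),
            rotation_rad=float(meta["rotation_rad"]),
        )
        odir = out / sid
        written.append(save_nifti(mprage, affine, odir / "mprage.nii.gz"))
        for name, m in (("ribbon", rm.ribbon), ("wm", rm.wm_mask), ("csf", rm.csf_mask)):
            written.append(save_nifti(m, affine, odir / f"{name}.nii.gz", dtype=np.uint8))
        written.append(
            save_nifti(np.nan_to_num(rm.thickness_map), affine, odir / "thickness.nii.gz")
        )
        written.append(save_nifti(rm.lobe_labels, affine, odir / "lobes.nii.gz", dtype=np.uint8))
        rows.append(
            {
                "subject_id": sid,
                "tiv_ml": rm.tiv_ml,
                "mean_thickness_mm": rm.mean_thickness_mm,
                **{f"dice_{k}": v for k, v in rm.dice.items()},
            }
        )
    tbl = pd.DataFrame(rows)
    p = out / "anatomy.csv"
    tbl.to_csv(p, index=False)
    written.append(p)
    codes = {str(code): f"left {name}" for code, name in LOBE_NAMES.items()}
    codes.update({str(code + 4): f"right {name}" for code, name in LOBE_NAMES.items()})
    written.append(write_sidecar({"lobe_codes": codes}, out / "lobes.json"))
    return written


def _template_ribbon(config: PipelineConfig):
    """Template ribbon: the reference-age phantom without subject variation."""
    geo = dataclasses.replace(
        config.geometry,
        center_jitter_vox=0.0,
        rotation_max_deg=0.0,
        scale_sd=0.0,
        sex_scale_effect=0.0,
    )
    aging = config.aging_model.build().noise_free()
    ph = build_phantom(config.aging_model.reference_age, 0, aging, geo, seed=0)
    return ph.gm_mask


def _sample_on_template(volume, valid, template_ribbon):
    """Subject map resampled on the template ribbon, nearest-valid fill."""
    from scipy.ndimage import distance_transform_edt

    out = np.where(valid, volume, 0.0)
    missing = template_ribbon & ~valid
    if missing.any():
        _, idx = distance_transform_edt(~valid, return_indices=True)
        out[missing] = volume[tuple(i[missing] for i in idx)]
    return np.where(template_ribbon, out, 0.0)


def stage_stats(config: PipelineConfig, sim_dir: Path, fit_dir: Path, anat_dir: Path, out: Path) -> list[Path]:
    """Global, lobar and voxelwise statistics from the fitted artifacts."""
    out.mkdir(parents=True, exist_ok=True)
    written = []
    cov = read_covariates(sim_dir / "covariates.csv")
    anat = pd.read_csv(anat_dir / "anatomy.csv")
    sids = _subject_ids(config.cohort.n)

    per_subject = []
    lobe_tables = []
    maps_stack: dict[str, list[np.ndarray]] = {}
    template = _template_ribbon(config)
    affine = config.geometry.affine()
    for sid in sids:
        arrays = {p: load_nifti(fit_dir / sid / f"{p}.nii.gz")[0] for p in TRUTH_PARAMS}
        masks = {
            p: load_nifti(fit_dir / sid / f"mask_{p}.nii.gz")[0].astype(bool)
            for p in TRUTH_PARAMS
        }
        qmaps = QMaps(
            t1=arrays["T1"],
            pd=arrays["PD"],
            t2=arrays["T2"],
            t2star=arrays["T2star"],
            t2prime=arrays["T2prime"],
            masks=masks,
        )
        ribbon = load_nifti(anat_dir / sid / "ribbon.nii.gz")[0].astype(bool)
        wm = load_nifti(anat_dir / sid / "wm.nii.gz")[0].astype(bool)
        csf = load_nifti(anat_dir / sid / "csf.nii.gz")[0].astype(bool)
        thickness = load_nifti(anat_dir / sid / "thickness.nii.gz")[0]
        lobes = load_nifti(anat_dir / sid / "lobes.nii.gz")[0].astype(np.uint8)
        try:
            per_subject.append(cortical_summary(qmaps, ribbon))
        except Exception as exc:
            warnings.warn(f"{sid}: {exc}")
            per_subject.append(None)
            continue
        from .anatomy import RibbonModel

        rm = RibbonModel(
            ribbon=ribbon,
            wm_mask=wm,
            csf_mask=csf,
            thickness_map=np.where(ribbon, thickness, np.nan),
            lobe_labels=lobes,
            tiv_ml=float(anat.loc[anat.subject_id == sid, "tiv_ml"].iloc[0]),
            mean_thickness_mm=float(
                anat.loc[anat.subject_id == sid, "mean_thickness_mm"].iloc[0]
            ),
        )
        lobe_tables.append(extract_lobe_values(qmaps, rm, sid))
        for p in TRUTH_PARAMS:
            maps_stack.setdefault(p, []).append(
                _sample_on_template(arrays[p], masks[p] & ribbon, template)
            )

    subject_table, cohort_table = global_summary(per_subject, sids)
    written.append(out / "global_subjects.csv")
    subject_table.to_csv(written[-1])
    written.append(out / "global_cohort.csv")
    cohort_table.to_csv(written[-1])

    data = cov.merge(
        subject_table[[f"{p}_mean" for p in TRUTH_PARAMS]].rename(
            columns={f"{p}_mean": p for p in TRUTH_PARAMS}
        ),
        left_on="subject_id",
        right_index=True,
    ).merge(anat[["subject_id", "mean_thickness_mm"]], on="subject_id")
    data = data.rename(columns={"mean_thickness_mm": "thickness"})

    model = CorticalAgingModel(
        data,
        maps={p: np.stack(v) for p, v in maps_stack.items()},
        template_ribbon=template,
        voxel_size_mm=config.geometry.voxel_size_mm,
        lobe_values=pd.concat(lobe_tables, ignore_index=True),
    )
    results = model.fit(
        n_perm=config.stats.n_perm,
        seed=config.seed,
        threshold_p=config.stats.threshold_p,
        smooth_fwhm_mm=config.stats.smooth_fwhm_mm,
    )
    written.append(out / "correlations.csv")
    results.global_table.to_csv(written[-1])
    if results.lobar_table is not None:
        written.append(out / "lobar.csv")
        results.lobar_table.to_csv(written[-1], index=False)
    cluster_payload = {}
    for p, rep in results.voxel_reports.items():
        written.append(save_nifti(rep.r_map, affine, out / f"voxelwise_{p}_r.nii.gz"))
        written.append(save_nifti(rep.p_map, affine, out / f"voxelwise_{p}_p.nii.gz"))
        cluster_payload[p] = rep.clusters.to_dict(orient="records")
    written.append(write_sidecar(cluster_payload, out / "clusters.json"))
    written.append(out / "summary.txt")
    written[-1].write_text(results.summary())
    return written


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all four stages and write ``manifest.json``.

    On a stage failure the manifest marks that stage ``failed`` (with the
    error message) and the remaining stages ``skipped``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    stages = [
        ("simulate", lambda: stage_simulate(config, out_dir / "simulate")),
        (
            "fitmaps",
            lambda: stage_fitmaps(config, out_dir / "simulate", out_dir / "fitmaps"),
        ),
        (
            "anatomy",
            lambda: stage_anatomy(
                config, out_dir / "simulate", out_dir / "fitmaps", out_dir / "anatomy"
            ),
        ),
        (
            "stats",
            lambda: stage_stats(
                config,
                out_dir / "simulate",
                out_dir / "fitmaps",
                out_dir / "anatomy",
                out_dir / "stats",
            ),
        ),
    ]
    manifest: dict = {
        "config_hash": config_hash(config.to_dict()),
        "seed": config.seed,
        "stages": {},
    }
    failed = False
    for name, fn in stages:
        if failed:
            manifest["stages"][name] = {"status": "skipped"}
            continue
        t0 = time.perf_counter()
        try:
            artifacts = fn()
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
                "artifacts": {
                    str(Path(a).relative_to(out_dir)): file_sha256(a) for a in artifacts
                },
            }
            log.info("stage %s ok (%.1fs)", name, time.perf_counter() - t0)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            log.error("stage %s failed: %s", name, exc)
            failed = True
    write_sidecar(manifest, out_dir / "manifest.json")
    return manifest
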
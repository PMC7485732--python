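"""Three-level cortical statistics: global, lobar and voxelwise.

Global level: per-subject means and SDs of each quantitative parameter over
the cortical ribbon, and (partial) Pearson correlations of the cohort's
per-subject means with age, optionally controlling for nuisance covariates
(total intracranial volume and sex).  Partial correlations are computed by
correlating the least-squares residuals of both variables on the covariates;
the t-test p-value uses n - 2 - k degrees of freedom for k covariates.

Voxel level: a per-voxel Pearson correlation map with age on a template
ribbon, Gaussian-smoothed within the ribbon (mask-normalised weights, so no
values bleed in from outside), thresholded at an uncorrected p, grouped into
6-connected clusters separately by sign, and corrected for multiple
comparisons with a max-cluster-size permutation null: ages are randomly
permuted, the largest suprathreshold cluster per sign recorded, and the
cluster-wise p-value is ``(1 + #{perm max >= observed}) / (1 + n_perm)``.
For tiny cohorts the full permutation group can be enumerated instead.

Lobar level: parameters averaged across hemispheres per lobe, correlated
with age, and with regional thickness partialling out TIV.

Sample SDs (n-1 denominator) are used throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .anatomy import HEMISPHERES, LOBE_NAMES, RibbonModel
from .relaxometry import QMaps

__all__ = [
    "CorrelationReport",
    "correlate",
    "partial_correlation",
    "cortical_summary",
    "global_summary",
    "smooth_map",
    "mapwise_correlation",
    "lobar_analysis",
    "extract_lobe_values",
]


class UndefinedCorrelationError(ValueError):
    """Raised when x, y (or their covariate residuals) have zero variance."""


class EmptyRibbonError(ValueError):
    """Raised when a subject has no valid ribbon voxel."""


@dataclass
class CorrelationReport:
    """One correlation result at global, lobe or voxel level."""

    parameter: str
    level: str  # "global" | "lobe" | "voxel"
    r: float
    p: float
    n: int
    covariates: list[str] = field(default_factory=list)
    # voxel-level payload
    r_map: np.ndarray | None = None
    p_map: np.ndarray | None = None
    clusters: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isnan(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    parameter: str = "",
    level: str = "global",
    covariate_names: list[str] | None = None,
) -> CorrelationReport:
    """(Partial) Pearson correlation with a two-sided t-test.

    Without covariates this is the plain Pearson r with df = n - 2.  With a
    covariate matrix (n x k), x and y are both projected off [1, covariates]
    and the residuals correlated, with df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    k = 0
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        k = covariates.shape[1]
    if n < 3 + k:
        raise ValueError(f"need at least {3 + k} observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if covariates is not None:
        design = np.column_stack([np.ones(n), covariates])
        x = _residualize(x, design)
        y = _residualize(y, design)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError(
            "zero variance in x or y (or their covariate residuals)"
        )
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    names = covariate_names if covariate_names is not None else (
        [f"cov{i}" for i in range(k)] if k else []
    )
    return CorrelationReport(parameter=parameter, level=level, r=r, p=max(p, np.finfo(float).tiny), n=n, covariates=list(names))


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray, **kw
) -> CorrelationReport:
    """Convenience wrapper: Pearson correlation controlling for covariates."""
    return correlate(x, y, covariates=covariates, **kw)


def cortical_summary(
    qmaps: QMaps, ribbon: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Per-subject mean and sample SD of each parameter over the ribbon."""
    out = {}
    for p in qmaps.parameters:
        sel = ribbon & qmaps.mask(p)
        if not sel.any():
            raise EmptyRibbonError(f"no valid ribbon voxel for {p}")
        vals = qmaps[p][sel]
        out[p] = (float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
    return out


def global_summary(
    per_subject: list[dict[str, tuple[float, float]]],
    subject_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort table of cortical means and SDs.

    Returns ``(subject_table, cohort_table)``: the former one row per
    subject with ``<param>_mean`` / ``<param>_sd`` columns; the latter one
    row per parameter with the across-subject mean and SD of both. Subjects
    flagged as ``None`` (e.g. empty ribbon) are excluded with a warning.
    """
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(len(per_subject))]
    rows, ids = [], []
    for sid, stats_ in zip(subject_ids, per_subject):
        if stats_ is None:
            warnings.warn(f"excluding {sid}: no valid ribbon voxels")
            continue
        row = {}
        for p, (m, sd) in stats_.items():
            row[f"{p}_mean"] = m
            row[f"{p}_sd"] = sd
        rows.append(row)
        ids.append(sid)
    subject_table = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    params = sorted({c.rsplit("_", 1)[0] for c in subject_table.columns})
    cohort = {}
    for p in params:
        cohort[p] = {
            "mean_of_means": subject_table[f"{p}_mean"].mean(),
            "sd_of_means": subject_table[f"{p}_mean"].std(ddof=1),
            "mean_of_sds": subject_table[f"{p}_sd"].mean(),
            "sd_of_sds": subject_table[f"{p}_sd"].std(ddof=1),
        }
    cohort_table = pd.DataFrame(cohort).T.rename_axis("parameter")
    return subject_table, cohort_table


def smooth_map(
    volume: np.ndarray,
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float,
) -> np.ndarray:
    """Gaussian smoothing restricted to a mask (no bleed-in from outside).

    Weights are renormalised over the mask, so a constant map is unchanged
    everywhere; ``fwhm_mm = 0`` returns the input on the mask unchanged.
    Values outside the mask are zero.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    out = np.zeros_like(np.asarray(volume, dtype=float))
    if fwhm_mm == 0:
        out[mask] = volume[mask]
        return out
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    num = ndimage.gaussian_filter(np.where(mask, volume, 0.0), sigma_vox)
    den = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
    out[mask] = num[mask] / den[mask]
    return out


_CONN6 = ndimage.generate_binary_structure(3, 1)


def _max_cluster_sizes(sig_pos: np.ndarray, sig_neg: np.ndarray) -> tuple[int, int]:
    sizes = []
    for sig in (sig_pos, sig_neg):
        lab, nlab = ndimage.label(sig, structure=_CONN6)
        sizes.append(int(np.bincount(lab.ravel())[1:].max()) if nlab else 0)
    return sizes[0], sizes[1]


def _threshold(r: np.ndarray, n: int, threshold_p: float) -> np.ndarray:
    """Boolean suprathreshold map from |r| at an uncorrected p threshold."""
    # invert the t-test once: |r| > r_crit <=> p < threshold_p
    df = n - 2
    t_crit = sps.t.isf(threshold_p / 2.0, df)
    r_crit = t_crit / np.sqrt(df + t_crit**2)
    return np.abs(r) > r_crit


def mapwise_correlation(
    maps: np.ndarray,
    mask: np.ndarray,
    ages: np.ndarray,
    threshold_p: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    exact: bool = False,
    cluster_alpha: float = 0.05,
    parameter: str = "",
) -> CorrelationReport:
    """Voxelwise age correlation with permutation cluster correction.

    ``maps`` is (n_subjects, X, Y, Z) on a shared template grid; ``mask`` is
    the template ribbon.  Suprathreshold voxels are clustered with
    6-connectivity separately for positive and negative correlations; the
    null distribution of the maximum cluster size per sign is built from
    ``n_perm`` random permutations of the ages (or, with ``exact=True``, the
    full permutation group, feasible for n <= 8), and each observed cluster
    receives ``p = (1 + #{perm max >= size}) / (1 + n_perm)`` (exhaustive
    mode: the unconditional fraction over all permutations).

    Returns a voxel-level :class:`CorrelationReport`; ``r``/``p`` are those
    of the single strongest voxel, the full maps and the cluster table ride
    along.
    """
    maps = np.asarray(maps, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    if maps.shape[0] != n:
        raise ValueError("subject axis of maps must match ages")
    if maps.shape[1:] != mask.shape:
        raise ValueError("maps and template ribbon are on mismatched grids")
    if not exact and n_perm < 100:
        raise ValueError("n_perm must be at least 100")

    v = maps[:, mask]  # (n, nvox)
    vc = v - v.mean(axis=0)
    vnorm = np.sqrt((vc**2).sum(axis=0))
    vnorm[vnorm == 0] = np.inf

    def rvec(age_vec: np.ndarray) -> np.ndarray:
        a = age_vec - age_vec.mean()
        anorm = np.sqrt(a @ a)
        return (a @ vc) / (vnorm * anorm)

    r = rvec(ages)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / np.clip(1.0 - r**2, 1e-300, None))
    pvox = 2.0 * sps.t.sf(np.abs(tstat), df)

    r_map = np.zeros(mask.shape)
    p_map = np.ones(mask.shape)
    r_map[mask] = r
    p_map[mask] = pvox

    supra = np.zeros(mask.shape, bool)
    supra[mask] = _threshold(r, n, threshold_p)
    obs_pos = supra & (r_map > 0)
    obs_neg = supra & (r_map < 0)

    # observed clusters
    rows = []
    for sign, sig in (("+", obs_pos), ("-", obs_neg)):
        lab, nlab = ndimage.label(sig, structure=_CONN6)
        for cid in range(1, nlab + 1):
            rows.append(
                {"sign": sign, "label_volume_id": cid, "size_vox": int((lab == cid).sum())}
            )

    # permutation null of the max cluster size, per sign
    if exact:
        perms = list(itertools.permutations(range(n)))
        if len(perms) > 50000:
            raise ValueError("exhaustive enumeration infeasible for this n")
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]
    max_pos = np.empty(len(perms))
    max_neg = np.empty(len(perms))
    for i, perm in enumerate(perms):
        rp = rvec(ages[list(perm)])
        sp = _threshold(rp, n, threshold_p)
        svol = np.zeros(mask.shape, bool)
        svol[mask] = sp
        rvol = np.zeros(mask.shape)
        rvol[mask] = rp
        max_pos[i], max_neg[i] = _max_cluster_sizes(svol & (rvol > 0), svol & (rvol < 0))

    denom = len(perms) if exact else len(perms) + 1
    for row in rows:
        null = max_pos if row["sign"] == "+" else max_neg
        exceed = int((null >= row["size_vox"]).sum())
        row["p_cluster"] = (exceed if exact else exceed + 1) / denom
        row["significant"] = row["p_cluster"] < cluster_alpha
    clusters = pd.DataFrame(
        rows, columns=["sign", "label_volume_id", "size_vox", "p_cluster", "significant"]
    )

    best = int(np.argmax(np.abs(r))) if r.size else 0
    return CorrelationReport(
        parameter=parameter,
        level="voxel",
        r=float(r[best]) if r.size else np.nan,
        p=float(max(pvox[best], np.finfo(float).tiny)) if r.size else np.nan,
        n=n,
        r_map=r_map,
        p_map=p_map,
        clusters=clusters,
    )


def extract_lobe_values(
    qmaps: QMaps,
    ribbon_model: RibbonModel,
    subject_id: str,
) -> pd.DataFrame:
    """Tidy per-lobe, per-hemisphere parameter means for one subject.

    Rows: (subject, lobe, hemisphere, parameter, value); cortical thickness
    is included as a parameter.
    """
    rows = []
    for lobe, lobe_name in LOBE_NAMES.items():
        for hemi in HEMISPHERES:
            sel = ribbon_model.lobe_mask(lobe, hemi)
            if not sel.any():
                warnings.warn(f"{subject_id}: empty {hemi} {lobe_name}; skipped")
                continue
            for p in qmaps.parameters:
                good = sel & qmaps.mask(p)
                if good.any():
                    rows.append(
                        {
                            "subject": subject_id,
                            "lobe": lobe_name,
                            "hemisphere": hemi,
                            "parameter": p,
                            "value": float(qmaps[p][good].mean()),
                        }
                    )
            th = ribbon_model.thickness_map[sel]
            th = th[np.isfinite(th)]
            rows.append(
                {
                    "subject": subject_id,
                    "lobe": lobe_name,
                    "hemisphere": hemi,
                    "parameter": "thickness",
                    "value": float(th.mean()),
                }
            )
    return pd.DataFrame(rows)


def lobar_analysis(
    lobe_values: pd.DataFrame,
    ages: pd.Series,
    tiv: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Region-of-interest correlations per lobe.

    ``lobe_values`` is the tidy table from :func:`extract_lobe_values`
    concatenated over subjects.  Values are first averaged across the two
    hemispheres.  For each lobe and parameter the table reports the Pearson
    correlation with age, and (for qMRI parameters) the correlation with the
    lobe's thickness partialling out TIV.
    """
    hemi_avg = (
        lobe_values.groupby(["subject", "lobe", "parameter"])["value"]
        .mean()
        .unstack("parameter")
    )
    rows = []
    for lobe, tbl in hemi_avg.groupby(level="lobe"):
        tbl = tbl.droplevel("lobe")
        if len(tbl) < 1:
            warnings.warn(f"lobe {lobe} has no data; excluded")
            continue
        age_v = ages.loc[tbl.index].to_numpy()
        tiv_v = tiv.loc[tbl.index].to_numpy()
        th = tbl["thickness"].to_numpy() if "thickness" in tbl else None
        for param in tbl.columns:
            vals = tbl[param].to_numpy()
            rep_age = correlate(vals, age_v, parameter=param, level="lobe")
            row = {
                "lobe": lobe,
                "parameter": param,
                "n": rep_age.n,
                "r_age": rep_age.r,
                "p_age": rep_age.p,
                "significant_age": rep_age.p < alpha,
            }
            if th is not None and param != "thickness":
                rep_th = correlate(
                    vals,
                    th,
                    covariates=tiv_v[:, None],
                    covariate_names=["tiv"],
                    parameter=param,
                    level="lobe",
                )
                row.update(
                    r_thickness=rep_th.r,
                    p_thickness=rep_th.p,
                    significant_thickness=rep_th.p < alpha,
                )
            rows.append(row)
    return pd.DataFrame(rows)
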
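"""Statsmodels-style front end: a cohort model and its fitted results.

:class:`CorticalAgingModel` is built from a per-subject data table (age,
sex, TIV and the cortical means of the quantitative parameters), optionally
with per-subject ribbon maps for the voxelwise analysis and a tidy lobar
table.  ``fit()`` runs the three-level statistical analysis and returns a
:class:`CorticalAgingResults` carrying the estimates, their p-values and a
``summary()`` table; simulation (``from_simulation``) and plotting hang off
these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import (
    CorrelationReport,
    correlate,
    lobar_analysis,
    mapwise_correlation,
    smooth_map,
)

__all__ = ["CorticalAgingModel", "CorticalAgingResults"]

DEFAULT_PARAMETERS = ("T1", "PD", "T2", "T2star", "T2prime", "thickness")


class CorticalAgingModel:
    """Cohort-level model of cortical aging.

    Parameters
    ----------
    data : DataFrame
        One row per subject; must contain ``age_years``, ``sex``, ``tiv_ml``
        and one column per analyzed parameter (cortical means).
    parameters : sequence of str, optional
        Parameter columns to analyze; defaults to the intersection of
        ``data.columns`` with T1/PD/T2/T2star/T2prime/thickness.
    maps : dict, optional
        ``parameter -> (n_subjects, X, Y, Z)`` arrays on a shared template
        ribbon for the voxelwise analysis.
    template_ribbon : ndarray, optional
        Boolean template ribbon mask matching ``maps``.
    lobe_values : DataFrame, optional
        Tidy per-lobe table (see :func:`cortexage.stats.extract_lobe_values`).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        parameters: list[str] | None = None,
        maps: dict[str, np.ndarray] | None = None,
        template_ribbon: np.ndarray | None = None,
        voxel_size_mm: float | None = None,
        lobe_values: pd.DataFrame | None = None,
    ) -> None:
        for col in ("age_years", "sex", "tiv_ml"):
            if col not in data.columns:
                raise ValueError(f"data must contain a {col!r} column")
        if parameters is None:
            parameters = [p for p in DEFAULT_PARAMETERS if p in data.columns]
        if not parameters:
            raise ValueError("no parameter columns to analyze")
        self.data = data.reset_index(drop=True)
        self.parameters = list(parameters)
        self.maps = maps or {}
        self.template_ribbon = template_ribbon
        self.voxel_size_mm = voxel_size_mm
        self.lobe_values = lobe_values
        if self.maps and template_ribbon is None:
            raise ValueError("voxelwise maps need a template ribbon mask")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "CorticalAgingModel":
        return cls(data, **kw)

    @classmethod
    def from_simulation(
        cls,
        seed: int,
        n_subjects: int = 40,
        aging_model=None,
        geometry=None,
        protocol=None,
    ) -> "CorticalAgingModel":
        """Simulate a cohort end-to-end and wrap the fitted cortical means."""
        from .closedloop import run_cohort_measurement

        df = run_cohort_measurement(
            seed,
            n_subjects=n_subjects,
            aging_model=aging_model,
            geometry=geometry,
            protocol=protocol,
        )
        return cls(df)

    @property
    def n(self) -> int:
        return len(self.data)

    def fit(
        self,
        n_perm: int = 1000,
        seed: int | None = None,
        threshold_p: float = 0.05,
        smooth_fwhm_mm: float = 10.0,
    ) -> "CorticalAgingResults":
        """Run the global, lobar and (if maps given) voxelwise analyses."""
        ages = self.data["age_years"].to_numpy()
        covs = self.data[["tiv_ml", "sex"]].to_numpy()
        rows = []
        reports: dict[str, dict[str, CorrelationReport]] = {}
        thick = (
            self.data["thickness"].to_numpy() if "thickness" in self.data else None
        )
        tiv = self.data[["tiv_ml"]].to_numpy()
        for p in self.parameters:
            vals = self.data[p].to_numpy()
            ok = np.isfinite(vals)
            plain = correlate(vals[ok], ages[ok], parameter=p)
            partial = correlate(
                vals[ok],
                ages[ok],
                covariates=covs[ok],
                covariate_names=["tiv_ml", "sex"],
                parameter=p,
            )
            reports[p] = {"age": plain, "age_partial": partial}
            row = {
                "parameter": p,
                "n": plain.n,
                "r_age": plain.r,
                "p_age": plain.p,
                "r_age_partial": partial.r,
                "p_age_partial": partial.p,
            }
            if thick is not None and p != "thickness":
                vs_th = correlate(
                    vals[ok],
                    thick[ok],
                    covariates=tiv[ok],
                    covariate_names=["tiv_ml"],
                    parameter=p,
                )
                reports[p]["thickness_partial_tiv"] = vs_th
                row["r_thickness"] = vs_th.r
                row["p_thickness"] = vs_th.p
            rows.append(row)
        global_table = pd.DataFrame(rows).set_index("parameter")

        voxel_reports: dict[str, CorrelationReport] = {}
        if self.maps:
            rng = np.random.default_rng(seed)
            for p, stack in self.maps.items():
                if smooth_fwhm_mm and self.voxel_size_mm:
                    stack = np.stack(
                        [
                            smooth_map(
                                vol, self.template_ribbon, smooth_fwhm_mm, self.voxel_size_mm
                            )
                            for vol in stack
                        ]
                    )
                voxel_reports[p] = mapwise_correlation(
                    stack,
                    self.template_ribbon,
                    ages,
                    threshold_p=threshold_p,
                    n_perm=n_perm,
                    seed=int(rng.integers(2**31)),
                    parameter=p,
                )

        lobar_table = None
        if self.lobe_values is not None:
            idx = self.data.get("subject_id", pd.Series(range(self.n)))
            ages_s = pd.Series(ages, index=idx.to_numpy())
            tiv_s = pd.Series(self.data["tiv_ml"].to_numpy(), index=idx.to_numpy())
            lobar_table = lobar_analysis(self.lobe_values, ages_s, tiv_s)

        return CorticalAgingResults(
            model=self,
            global_table=global_table,
            reports=reports,
            voxel_reports=voxel_reports,
            lobar_table=lobar_table,
        )


@dataclass
class CorticalAgingResults:
    """Fitted cohort statistics with a text summary and plotting helpers."""

    model: CorticalAgingModel
    global_table: pd.DataFrame
    reports: dict[str, dict[str, CorrelationReport]]
    voxel_reports: dict[str, CorrelationReport] = field(default_factory=dict)
    lobar_table: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            "Cortical aging analysis",
            "=" * 70,
            f"subjects: {self.model.n}   parameters: {', '.join(self.model.parameters)}",
            "partial correlations control for: tiv_ml, sex",
            "-" * 70,
        ]
        tbl = self.global_table.copy()
        fmt = {c: "{:8.3f}".format for c in tbl.columns if c != "n"}
        lines.append(tbl.to_string(float_format="%.4f"))
        if self.lobar_table is not None:
            lines += ["-" * 70, "lobar analysis (hemisphere-averaged):",
                      self.lobar_table.to_string(float_format="%.4f", index=False)]
        for p, rep in self.voxel_reports.items():
            nsig = int(rep.clusters["significant"].sum()) if rep.clusters is not None else 0
            lines.append(
                f"voxelwise {p}: peak r = {rep.r:+.3f}, {nsig} significant cluster(s)"
            )
        lines.append("=" * 70)
        return "\n".join(lines)

    def plot_global(self, parameter: str, ax=None):
        """Scatter of a parameter's cortical mean against age, with the LS line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.data["age_years"].to_numpy()
        y = self.model.data[parameter].to_numpy()
        ax.scatter(x, y, s=18, alpha=0.8)
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 10)
        ax.plot(xs, a + b * xs, color="crimson")
        rep = self.reports[parameter]["age"]
        ax.set_xlabel("age [years]")
        ax.set_ylabel(parameter)
        ax.set_title(f"{parameter}: r = {rep.r:+.3f}, p = {rep.p:.3g}")
        return ax
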
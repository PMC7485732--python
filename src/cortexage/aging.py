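"""Linear cortical-aging model and its calibration.

Cortical gray-matter qMRI parameters (T1, PD, T2, the reversible transverse
relaxation time T2') and cortical thickness are modelled, per subject, as

    value = baseline + b * (age - reference_age) + eta,   eta ~ N(0, sigma_res)

i.e. a linear population trend with Gaussian between-subject scatter.  The
slope ``b`` and residual SD ``sigma_res`` are calibrated from a target
population Pearson correlation ``r`` with age and a target between-subject
SD of the parameter:

    b         = r * sd_param / sd_age
    sigma_res = sd_param * sqrt(1 - r**2)

so that, for an age distribution of SD ``sd_age``, the marginal parameter SD
equals ``sd_param`` and corr(value, age) equals ``r`` in the infinite-cohort
limit.

The effective transverse relaxation time T2* is *not* calibrated directly:
its ground truth is always derived from T2 and T2' through
1/T2* = 1/T2 + 1/T2', so that the T2' trend (the headline iron-sensitive
parameter) is injected exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ParameterTrend",
    "AgingModel",
    "calibrate_aging_model",
    "CORTICAL_REFERENCE",
    "AGE_SD_REFERENCE",
]

#: Reference cortical statistics used for default calibration: for each
#: parameter, (baseline at the reference age, between-subject SD of the
#: per-subject cortical mean, population correlation with age, within-cortex
#: spatial SD).  Units: T1/T2/T2' in ms, PD in percent units, thickness in mm.
CORTICAL_REFERENCE: dict[str, dict[str, float]] = {
    "T1": {"baseline": 1528.75, "sd_between": 40.58, "r_age": -0.421, "sd_cortex": 146.73},
    "PD": {"baseline": 79.48, "sd_between": 1.85, "r_age": 0.287, "sd_cortex": 5.45},
    "T2": {"baseline": 86.99, "sd_between": 4.17, "r_age": 0.445, "sd_cortex": 27.69},
    "T2prime": {"baseline": 201.50, "sd_between": 22.47, "r_age": -0.724, "sd_cortex": 90.83},
    "thickness": {"baseline": 2.45, "sd_between": 0.08, "r_age": -0.444, "sd_cortex": 0.0},
}

#: Age SD of the reference adult cohort (years), used for default calibration.
AGE_SD_REFERENCE: float = 14.97

#: Physical floors applied when spatial texture is added to a parameter map,
#: to keep every voxel in a physically meaningful range (ms / p.u.).
PARAMETER_FLOORS: dict[str, float] = {
    "T1": 300.0,
    "PD": 30.0,
    "T2": 25.0,
    "T2prime": 20.0,
    "thickness": 0.5,
}


class CalibrationError(ValueError):
    """Raised when a requested correlation cannot be realised (|r| >= 1)."""


@dataclass(frozen=True)
class ParameterTrend:
    """Linear age trend of one cortical parameter.

    Attributes
    ----------
    baseline : float
        Population value at the reference age (ms, p.u. or mm).
    slope : float
        Change per year of age, same units per year.
    sigma_res : float
        Between-subject residual SD around the trend line (same units).
    sd_cortex : float
        Within-subject spatial SD across the cortex (same units); 0 disables
        spatial texture for this parameter.
    """

    baseline: float
    slope: float = 0.0
    sigma_res: float = 0.0
    sd_cortex: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_res < 0:
            raise ValueError("sigma_res must be non-negative")
        if self.sd_cortex < 0:
            raise ValueError("sd_cortex must be non-negative")

    def population_value(self, age: float, reference_age: float) -> float:
        """Trend-line value at ``age`` (no residual)."""
        return self.baseline + self.slope * (age - reference_age)


@dataclass(frozen=True)
class AgingModel:
    """Per-parameter linear aging trends for the cortical ribbon.

    ``trends`` maps parameter names (``"T1"``, ``"PD"``, ``"T2"``,
    ``"T2prime"``, ``"thickness"``) to :class:`ParameterTrend`.  ``T2*`` is
    intentionally absent: it is derived from T2 and T2'.
    """

    trends: Mapping[str, ParameterTrend]
    reference_age: float = 45.0
    lobe_slope_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "trends", dict(self.trends))
        object.__setattr__(
            self, "lobe_slope_multipliers", dict(self.lobe_slope_multipliers)
        )

    def __getitem__(self, param: str) -> ParameterTrend:
        return self.trends[param]

    def __contains__(self, param: str) -> bool:
        return param in self.trends

    @property
    def parameters(self) -> list[str]:
        return list(self.trends)

    def draw_subject_means(
        self, age: float, rng: np.random.Generator
    ) -> dict[str, float]:
        """Sample one subject's cortical mean for every parameter."""
        out = {}
        for name, tr in self.trends.items():
            val = tr.population_value(age, self.reference_age)
            if tr.sigma_res > 0:
                val += rng.normal(0.0, tr.sigma_res)
            out[name] = val
        return out

    def zero_slope(self) -> "AgingModel":
        """Copy of the model with every slope set to zero (null cohort)."""
        return replace(
            self,
            trends={k: replace(v, slope=0.0) for k, v in self.trends.items()},
        )

    def noise_free(self) -> "AgingModel":
        """Copy with all between-subject residual SDs set to zero."""
        return replace(
            self,
            trends={k: replace(v, sigma_res=0.0) for k, v in self.trends.items()},
        )


def calibrate_trend(
    r_target: float,
    sd_param: float,
    sd_age: float,
    baseline: float,
    sd_cortex: float = 0.0,
) -> ParameterTrend:
    """Calibrate one linear trend from a target age correlation.

    Solves for the slope and residual SD such that a population with age SD
    ``sd_age`` has parameter SD ``sd_param`` and Pearson correlation
    ``r_target`` between parameter and age.

    Raises
    ------
    CalibrationError
        If ``|r_target| >= 1`` (a deterministic relation cannot carry a
        residual SD) or ``sd_param``/``sd_age`` are not positive.
    """
    if abs(r_target) >= 1.0:
        raise CalibrationError(f"|r| must be < 1, got {r_target}")
    if sd_param <= 0 or sd_age <= 0:
        raise CalibrationError("sd_param and sd_age must be positive")
    slope = r_target * sd_param / sd_age
    sigma_res = sd_param * float(np.sqrt(1.0 - r_target**2))
    return ParameterTrend(
        baseline=baseline, slope=slope, sigma_res=sigma_res, sd_cortex=sd_cortex
    )


def calibrate_aging_model(
    targets: Mapping[str, Mapping[str, float]] | None = None,
    sd_age: float = AGE_SD_REFERENCE,
    reference_age: float = 45.0,
) -> AgingModel:
    """Build an :class:`AgingModel` from correlation/SD targets.

    Parameters
    ----------
    targets : mapping, optional
        Per-parameter dicts with keys ``baseline``, ``sd_between``, ``r_age``
        and optionally ``sd_cortex``.  Defaults to the reference adult-cohort
        statistics in :data:`CORTICAL_REFERENCE`.
    sd_age : float
        Age SD (years) the correlations refer to.
    reference_age : float
        Age (years) at which the baselines apply.  The default cohort draws
        ages uniformly on [19, 71], whose mean is 45, so baselines equal the
        expected cohort means.
    """
    if targets is None:
        targets = CORTICAL_REFERENCE
    trends = {}
    for name, tgt in targets.items():
        trends[name] = calibrate_trend(
            r_target=float(tgt.get("r_age", 0.0)),
            sd_param=float(tgt["sd_between"]),
            sd_age=sd_age,
            baseline=float(tgt["baseline"]),
            sd_cortex=float(tgt.get("sd_cortex", 0.0)),
        )
    return AgingModel(trends=trends, reference_age=reference_age)
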
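"""Digital brain phantoms carrying calibrated cortical-aging effects.

Each subject is a nested-ellipsoid head: a white-matter (WM) core containing
one ventricle, a cortical gray-matter (GM) shell whose thickness depends on
age, and an outer cerebrospinal-fluid (CSF) layer.  Ground-truth quantitative
maps (T1, PD, T2, T2*, T2') are piecewise constant per tissue, with a smooth
zero-mean spatial texture added inside the cortical ribbon so that the
within-cortex SD matches the configured cortical distribution.  The cortical
means and the shell thickness follow the linear :class:`~cortexage.aging.AgingModel`.

Subject-to-subject geometric variation (overall scale, sub-voxel centre
jitter, a small axial rotation) decorrelates voxel-grid quantisation across
the cohort, which matters for recovering small thickness effects on coarse
grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .aging import PARAMETER_FLOORS, AgingModel

__all__ = [
    "GeometryConfig",
    "SubjectPhantom",
    "Cohort",
    "build_phantom",
    "generate_cohort",
    "LABEL_BACKGROUND",
    "LABEL_WM",
    "LABEL_GM",
    "LABEL_CSF",
    "LABEL_VENTRICLE",
]

LABEL_BACKGROUND = 0
LABEL_WM = 1
LABEL_GM = 2
LABEL_CSF = 3  # sulcal / outer CSF
LABEL_VENTRICLE = 4

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_WM: "white matter",
    LABEL_GM: "cortical gray matter",
    LABEL_CSF: "outer CSF",
    LABEL_VENTRICLE: "ventricle CSF",
}


class GeometryError(ValueError):
    """Raised when the requested geometry cannot be voxelised sensibly."""


class ConfigurationError(ValueError):
    """Raised for inconsistent cohort configuration."""


#: Fixed (non-aging) tissue parameters for WM and CSF, 3 T literature-style
#: values.  T2* follows from T2 and T2' via 1/T2* = 1/T2 + 1/T2'.
TISSUE_DEFAULTS: dict[str, dict[str, float]] = {
    "WM": {"T1": 850.0, "PD": 69.0, "T2": 75.0, "T2prime": 150.0},
    "CSF": {"T1": 4000.0, "PD": 100.0, "T2": 500.0, "T2prime": 2000.0},
}


@dataclass(frozen=True)
class GeometryConfig:
    """Phantom geometry on an isotropic voxel grid.

    The default 64^3 grid at 2 mm is the desk-scale configuration; a 1 mm
    grid is obtained by doubling ``shape`` and halving ``voxel_size_mm``.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    pial_semiaxes_mm: tuple[float, float, float] = (48.0, 44.0, 40.0)
    csf_shell_mm: float = 3.0
    ventricle_semiaxes_mm: tuple[float, float, float] = (14.0, 9.0, 9.0)
    #: sub-voxel centre jitter, in voxels, uniform per axis
    center_jitter_vox: float = 0.5
    #: maximal axial (about z) rotation, degrees, uniform
    rotation_max_deg: float = 8.0
    #: SD of the per-subject global size scale
    scale_sd: float = 0.025
    #: fractional head-size difference between sexes (males larger)
    sex_scale_effect: float = 0.025

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise GeometryError("grid must be at least 32^3")
        if self.voxel_size_mm <= 0:
            raise GeometryError("voxel size must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm**3)

    def affine(self) -> np.ndarray:
        """RAS+ affine with the grid centre at the world origin (mm)."""
        h = self.voxel_size_mm
        aff = np.diag([h, h, h, 1.0])
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * h
        return aff


@dataclass
class SubjectPhantom:
    """Ground truth for one simulated participant."""

    labels: np.ndarray  # uint8 label volume
    maps: dict[str, np.ndarray]  # T1, PD, T2, T2star, T2prime (ms / p.u.)
    age: float  # years
    sex: int  # 0 = female, 1 = male
    tiv_ml: float
    true_thickness_mm: float
    cortical_means: dict[str, float]  # subject-level true cortical means
    geometry: GeometryConfig
    seed: int | None = None
    #: world position of the head centre and axial rotation (radians), needed
    #: to parcellate in the subject-native frame
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_rad: float = 0.0

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND

    @property
    def gm_mask(self) -> np.ndarray:
        return self.labels == LABEL_GM

    @property
    def wm_mask(self) -> np.ndarray:
        return self.labels == LABEL_WM

    @property
    def csf_mask(self) -> np.ndarray:
        return (self.labels == LABEL_CSF) | (self.labels == LABEL_VENTRICLE)

    @property
    def ventricle_mask(self) -> np.ndarray:
        return self.labels == LABEL_VENTRICLE

    @property
    def affine(self) -> np.ndarray:
        return self.geometry.affine()


@dataclass
class Cohort:
    """A simulated study population."""

    subjects: list[SubjectPhantom]
    ages: np.ndarray
    sexes: np.ndarray
    seed: int | None
    aging_model: AgingModel
    geometry: GeometryConfig

    @property
    def n(self) -> int:
        return len(self.subjects)

    def covariates(self):
        """Per-subject covariate table (subject_id, age_years, sex, tiv_ml)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": [f"sub-{i + 1:03d}" for i in range(self.n)],
                "age_years": self.ages,
                "sex": self.sexes,
                "tiv_ml": [s.tiv_ml for s in self.subjects],
            }
        )


def _world_coords(geometry: GeometryConfig) -> tuple[np.ndarray, ...]:
    """Voxel-centre world coordinates (mm), one array per axis."""
    h = geometry.voxel_size_mm
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * h for n in geometry.shape
    ]
    return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


def _ellipsoid(
    coords: Sequence[np.ndarray],
    center: np.ndarray,
    semiaxes: Sequence[float],
    rotation_rad: float,
) -> np.ndarray:
    """Boolean mask of an axially rotated ellipsoid."""
    x = coords[0] - center[0]
    y = coords[1] - center[1]
    z = coords[2] - center[2]
    if rotation_rad != 0.0:
        c, s = np.cos(rotation_rad), np.sin(rotation_rad)
        x, y = c * x + s * y, -s * x + c * y
    a, b, cax = semiaxes
    if min(semiaxes) <= 0:
        raise GeometryError(f"non-positive ellipsoid semi-axis in {semiaxes}")
    return (x / a) ** 2 + (y / b) ** 2 + (z / cax) ** 2 <= 1.0


def _cortical_texture(
    shape: tuple[int, int, int],
    mask: np.ndarray,
    rng: np.random.Generator,
    smooth_vox: float = 1.5,
) -> np.ndarray:
    """Smooth random field, zero mean and unit SD over ``mask``."""
    f = gaussian_filter(rng.standard_normal(shape), smooth_vox, mode="nearest")
    sel = f[mask]
    sd = sel.std()
    if sd == 0:  # pragma: no cover - degenerate mask
        return np.zeros(shape)
    return (f - sel.mean()) / sd


def _textured_values(
    target_mean: float,
    sd_cortex: float,
    floor: float,
    texture: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Cortical voxel values with exact mean ``target_mean`` and floor clip."""
    if target_mean <= floor:
        raise GeometryError(
            f"cortical mean {target_mean:.3g} at or below physical floor {floor}"
        )
    vals = target_mean + sd_cortex * texture[mask]
    if sd_cortex > 0:
        for _ in range(4):
            np.clip(vals, floor, None, out=vals)
            vals += target_mean - vals.mean()
        # final exact re-centring; the residual shift is tiny so values stay
        # strictly above zero
        vals += target_mean - vals.mean()
    return vals


def build_phantom(
    age: float,
    sex: int,
    aging_model: AgingModel,
    geometry: GeometryConfig | None = None,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> SubjectPhantom:
    """Voxelise one subject and fill in ground-truth parameter maps.

    The cortical shell thickness and the cortical means of T1/PD/T2/T2' are
    drawn from ``aging_model`` at this ``age``; T2* is derived voxelwise via
    1/T2* = 1/T2 + 1/T2'.

    Raises
    ------
    GeometryError
        If the GM shell would be thinner than one voxel.
    """
    geometry = geometry or GeometryConfig()
    rng = np.random.default_rng(seed)
    means = aging_model.draw_subject_means(age, rng)
    thickness = float(means.get("thickness", 2.45))
    if thickness < geometry.voxel_size_mm:
        raise GeometryError(
            f"GM shell thickness {thickness:.2f} mm is below one voxel "
            f"({geometry.voxel_size_mm} mm)"
        )

    # subject-specific geometric variation
    scale = 1.0 + geometry.sex_scale_effect * (0.5 if sex else -0.5)
    if geometry.scale_sd > 0:
        scale *= 1.0 + rng.normal(0.0, geometry.scale_sd)
    center = rng.uniform(-1.0, 1.0, 3) * geometry.center_jitter_vox * geometry.voxel_size_mm
    rotation = float(np.deg2rad(rng.uniform(-1.0, 1.0) * geometry.rotation_max_deg))

    pial = scale * np.asarray(geometry.pial_semiaxes_mm)
    outer = pial + geometry.csf_shell_mm
    wm_outer = pial - thickness
    if np.any(wm_outer <= 0):
        raise GeometryError("GM shell thicker than the pial semi-axes")
    ventricle = scale * np.asarray(geometry.ventricle_semiaxes_mm)

    coords = _world_coords(geometry)
    in_outer = _ellipsoid(coords, center, outer, rotation)
    in_pial = _ellipsoid(coords, center, pial, rotation)
    in_wm = _ellipsoid(coords, center, wm_outer, rotation)
    in_vent = _ellipsoid(coords, center, ventricle, rotation)

    labels = np.zeros(geometry.shape, dtype=np.uint8)
    labels[in_outer] = LABEL_CSF
    labels[in_pial] = LABEL_GM
    labels[in_wm] = LABEL_WM
    labels[in_vent] = LABEL_VENTRICLE

    gm = labels == LABEL_GM
    if not gm.any():
        raise GeometryError("empty cortical ribbon after voxelisation")

    maps: dict[str, np.ndarray] = {
        p: np.zeros(geometry.shape) for p in ("T1", "PD", "T2", "T2prime")
    }
    for tissue, label in (("WM", labels == LABEL_WM), ("CSF", (labels == LABEL_CSF) | in_vent)):
        for p, v in TISSUE_DEFAULTS[tissue].items():
            maps[p][label] = v
    # ventricle voxels share CSF values (set above via the combined mask)

    texture_cache: dict[str, np.ndarray] = {}
    for p in ("T1", "PD", "T2", "T2prime"):
        trend = aging_model[p] if p in aging_model else None
        sd_cortex = trend.sd_cortex if trend is not None else 0.0
        mean = float(means.get(p, TISSUE_DEFAULTS["WM"][p]))
        tex = _cortical_texture(geometry.shape, gm, rng) if sd_cortex > 0 else np.zeros(geometry.shape)
        texture_cache[p] = tex
        maps[p][gm] = _textured_values(
            mean, sd_cortex, PARAMETER_FLOORS.get(p, 0.0), tex, gm
        )

    brain = labels != LABEL_BACKGROUND
    t2star = np.zeros(geometry.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2star[brain] = 1.0 / (1.0 / maps["T2"][brain] + 1.0 / maps["T2prime"][brain])
    maps["T2star"] = t2star

    tiv_ml = float(brain.sum()) * geometry.voxel_volume_mm3 / 1000.0

    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return SubjectPhantom(
        labels=labels,
        maps=maps,
        age=float(age),
        sex=int(sex),
        tiv_ml=tiv_ml,
        true_thickness_mm=thickness,
        cortical_means={k: float(v) for k, v in means.items()},
        geometry=geometry,
        seed=seed_int,
        center_mm=np.asarray(center, dtype=float),
        rotation_rad=rotation,
    )


def crop_phantom(phantom: SubjectPhantom, margin_vox: int = 2) -> SubjectPhantom:
    """Crop a phantom to the bounding box of the head plus a margin.

    Used to keep synthesis and fitting cost proportional to the head, not
    the field of view.  The stored head centre is shifted into the cropped
    frame so that parcellation stays consistent.
    """
    from dataclasses import replace as _dc_replace

    brain = phantom.brain_mask
    h = phantom.geometry.voxel_size_mm
    slices = []
    offsets = []
    for ax in range(3):
        proj = np.any(brain, axis=tuple(a for a in range(3) if a != ax))
        idx = np.where(proj)[0]
        a = max(0, idx[0] - margin_vox)
        b = min(brain.shape[ax], idx[-1] + 1 + margin_vox)
        n_old, n_new = brain.shape[ax], b - a
        slices.append(slice(a, b))
        offsets.append((a + (n_new - 1) / 2.0 - (n_old - 1) / 2.0) * h)
    sl = tuple(slices)
    new_shape = tuple(s.stop - s.start for s in slices)
    geometry = _dc_replace(phantom.geometry, shape=new_shape)
    return SubjectPhantom(
        labels=phantom.labels[sl],
        maps={k: v[sl] for k, v in phantom.maps.items()},
        age=phantom.age,
        sex=phantom.sex,
        tiv_ml=phantom.tiv_ml,
        true_thickness_mm=phantom.true_thickness_mm,
        cortical_means=phantom.cortical_means,
        geometry=geometry,
        seed=phantom.seed,
        center_mm=phantom.center_mm - np.asarray(offsets),
        rotation_rad=phantom.rotation_rad,
    )


def plan_cohort(
    n: int,
    age_range: tuple[float, float],
    sex_counts: tuple[int, int],
    seed: int | None,
) -> tuple[np.ndarray, np.ndarray, list[np.random.SeedSequence]]:
    """Draw ages, assign sexes and spawn per-subject random streams.

    Ages are uniform on ``age_range``; sexes are assigned deterministically
    to the configured (male, female) counts and then shuffled.
    """
    if n < 3:
        raise ConfigurationError("a cohort needs at least 3 subjects")
    lo, hi = age_range
    if not hi > lo:
        raise ConfigurationError("age range must be non-degenerate")
    n_male, n_female = sex_counts
    if n_male + n_female != n:
        raise ConfigurationError(
            f"sex counts {sex_counts} do not sum to the cohort size {n}"
        )
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n + 1)
    rng = np.random.default_rng(subject_seeds[0])
    ages = rng.uniform(lo, hi, n)
    sexes = np.array([1] * n_male + [0] * n_female)
    rng.shuffle(sexes)
    return ages, sexes, subject_seeds[1:]


def generate_cohort(
    n: int,
    age_range: tuple[float, float] = (19.0, 71.0),
    sex_counts: tuple[int, int] | None = None,
    aging_model: AgingModel | None = None,
    geometry: GeometryConfig | None = None,
    seed: int | None = None,
) -> Cohort:
    """Generate ``n`` subject phantoms with calibrated aging effects.

    ``sex_counts`` is (males, females); the default splits the cohort as
    evenly as a 19/21-style split allows.  The same ``seed`` reproduces the
    cohort bit-exactly.
    """
    from .aging import calibrate_aging_model

    aging_model = aging_model or calibrate_aging_model()
    geometry = geometry or GeometryConfig()
    if sex_counts is None:
        sex_counts = (n // 2, n - n // 2)
    ages, sexes, subject_seeds = plan_cohort(n, age_range, sex_counts, seed)
    subjects = []
    for age, sex, sseq in zip(ages, sexes, subject_seeds):
        try:
            subjects.append(build_phantom(age, sex, aging_model, geometry, sseq))
        except GeometryError as exc:  # pragma: no cover - defensive
            warnings.warn(f"subject at age {age:.1f} failed: {exc}")
            raise
    return Cohort(
        subjects=subjects,
        ages=ages,
        sexes=sexes,
        seed=seed,
        aging_model=aging_model,
        geometry=geometry,
    )
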
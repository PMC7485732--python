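"""Voxelwise estimation of B1, T1, PD, T2, T2* and derivation of T2'.

All fitters are closed-form and fully vectorised:

* B1 (transmit scale ``k``): ratio of a saturation-prepared to a reference
  volume, ``k = arccos(clip(prepared/reference, -1, 1)) / beta``;
* T1: two-point variable-flip-angle linearisation — plotting ``S_i/sin(a_i)``
  against ``S_i/tan(a_i)`` yields a line of slope ``exp(-TR/T1)`` (angles are
  B1-corrected, ``a_i = k * alpha_i``); the line's intercept feeds PD;
* T2 and T2*: weighted log-linear mono-exponential fits over the echo train,
  with squared-signal weights (variance stabilising for log-transformed
  Gaussian noise); a nonlinear least-squares alternative is provided and
  used as a test oracle;
* PD: the VFA intercept corrected for residual T1 and T2* weighting (the
  latter via a two-echo TE-difference pair), divided by the receive-field
  estimate, then scaled so that ventricle CSF has a median of 100 p.u.;
* T2': ``1/T2' = 1/T2* - 1/T2``; voxels where noise pushes ``T2* >= T2`` are
  masked invalid rather than clipped, which keeps region means unbiased.

Every fitter returns validity masks; no NaN/Inf is reported inside a mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionBundle

__all__ = [
    "B1Map",
    "QMaps",
    "fit_b1",
    "fit_t1_vfa",
    "fit_monoexp",
    "fit_monoexp_nonlinear",
    "fit_pd",
    "derive_t2prime",
    "fit_qmaps",
    "estimate_noise_sd",
    "estimate_receive_field",
]


class FitError(RuntimeError):
    """Raised when a fit fails globally (e.g. every voxel invalid)."""


class AcquisitionOrderError(ValueError):
    """Raised when the B1 pair looks swapped (prepared > reference)."""


class CalibrationError(RuntimeError):
    """Raised when PD calibration is impossible (e.g. empty CSF mask)."""


@dataclass
class B1Map:
    """Relative transmit flip-angle scale per voxel."""

    kappa: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        bad = self.mask & ~((self.kappa > 0) & (self.kappa <= 2))
        if bad.any():
            self.mask = self.mask & ~bad


@dataclass
class QMaps:
    """Fitted quantitative maps with per-parameter validity masks."""

    t1: np.ndarray
    pd: np.ndarray
    t2: np.ndarray
    t2star: np.ndarray
    t2prime: np.ndarray
    masks: dict[str, np.ndarray]
    r2: dict[str, np.ndarray] = field(default_factory=dict)
    b1: B1Map | None = None

    _KEYS = {"T1": "t1", "PD": "pd", "T2": "t2", "T2star": "t2star", "T2prime": "t2prime"}

    def __getitem__(self, param: str) -> np.ndarray:
        return getattr(self, self._KEYS[param])

    def mask(self, param: str) -> np.ndarray:
        return self.masks[param]

    @property
    def parameters(self) -> list[str]:
        return list(self._KEYS)


def estimate_noise_sd(volume: np.ndarray, patch: int = 5) -> float:
    """Estimate the noise SD from the eight background corner patches.

    Assumes the corners contain magnitude background (half-normal) signal;
    the SD is recovered from the patch median via ``sigma = med / 0.6745``.
    """
    n = patch
    corners = []
    for sx in (slice(0, n), slice(-n, None)):
        for sy in (slice(0, n), slice(-n, None)):
            for sz in (slice(0, n), slice(-n, None)):
                corners.append(volume[sx, sy, sz].ravel())
    med = float(np.median(np.concatenate(corners)))
    return med / 0.6745


def _signal_floor(volume: np.ndarray, floor: float | None) -> float:
    if floor is not None:
        return floor
    sd = estimate_noise_sd(volume)
    return max(3.0 * sd, 1e-9 * float(np.abs(volume).max() or 1.0))


def fit_b1(
    reference: np.ndarray,
    prepared: np.ndarray,
    nominal_beta_deg: float,
    floor: float | None = None,
    order_tolerance: float = 0.05,
) -> B1Map:
    """Map the transmit field from a saturation-prepared / reference pair.

    Raises
    ------
    AcquisitionOrderError
        If the prepared signal exceeds the reference in more than half of
        the above-floor voxels — the two inputs are most likely swapped.
    """
    if reference.shape != prepared.shape:
        raise ValueError("B1 pair volumes must share a grid")
    if not 0 < nominal_beta_deg <= 90:
        raise ValueError("nominal saturation angle must be in (0, 90] degrees")
    flo = _signal_floor(reference, floor)
    valid = reference > flo
    if valid.any():
        frac_super = float((prepared[valid] > reference[valid] * (1 + order_tolerance)).mean())
        if frac_super > 0.5:
            raise AcquisitionOrderError(
                "prepared volume brighter than reference in "
                f"{frac_super:.0%} of voxels; acquisition order looks swapped"
            )
    ratio = np.ones_like(reference, dtype=float)
    np.divide(prepared, reference, out=ratio, where=valid)
    kappa = np.arccos(np.clip(ratio, -1.0, 1.0)) / np.deg2rad(nominal_beta_deg)
    mask = valid & (kappa > 0) & (kappa <= 2)
    return B1Map(kappa=kappa, mask=mask)


def fit_t1_vfa(
    s1: np.ndarray,
    s2: np.ndarray,
    alpha1_deg: float,
    alpha2_deg: float,
    tr_ms: float,
    b1: B1Map | None = None,
    floor: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-point VFA T1 fit with B1-corrected flip angles.

    Returns ``(t1_ms, intercept, mask)``.  The intercept of the
    ``S/sin`` vs ``S/tan`` line equals ``M0 * (1 - exp(-TR/T1))`` with
    ``M0 = R * PD * exp(-TE/T2*)`` and is consumed by :func:`fit_pd`.
    """
    if alpha1_deg == alpha2_deg:
        raise ValueError("VFA flip angles must differ")
    kappa = b1.kappa if b1 is not None else 1.0
    kmask = b1.mask if b1 is not None else True
    a1 = np.deg2rad(alpha1_deg) * kappa
    a2 = np.deg2rad(alpha2_deg) * kappa
    flo = max(_signal_floor(s1, floor), _signal_floor(s2, floor))
    ok = (s1 > flo) & (s2 > flo) & kmask & (a1 < np.pi / 2) & (a2 < np.pi / 2)
    ok &= np.abs(np.asarray(a1) - np.asarray(a2)) > 1e-12

    with np.errstate(divide="ignore", invalid="ignore"):
        x1, y1 = s1 / np.tan(a1), s1 / np.sin(a1)
        x2, y2 = s2 / np.tan(a2), s2 / np.sin(a2)
        dx = x2 - x1
        ok &= np.abs(dx) > 0
        slope = np.where(ok, (y2 - y1) / np.where(ok, dx, 1.0), np.nan)
    ok &= (slope > 0) & (slope < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(ok, -tr_ms / np.log(np.where(ok, slope, 0.5)), 0.0)
        intercept = np.where(ok, y1 - slope * x1, 0.0)
    ok &= intercept > 0
    t1 = np.where(ok, t1, 0.0)
    if not ok.any():
        raise FitError("VFA T1 fit produced no valid voxel")
    return t1, intercept, ok


def fit_monoexp(
    stack: np.ndarray,
    te_ms: np.ndarray | list[float],
    floor: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted log-linear mono-exponential fit over an echo train.

    Weighted least squares on ``log S`` with weights ``S^2`` (the first-order
    variance of ``log S`` under additive noise is ``sigma^2 / S^2``, so these
    weights are variance stabilising).  Echoes below the signal floor are
    dropped per voxel; voxels with fewer than two usable echoes or a
    non-negative decay slope are masked.

    Returns ``(s0, t_decay_ms, r_squared, mask)``.
    """
    te = np.asarray(te_ms, dtype=float)
    if stack.shape[0] != te.size:
        raise ValueError("echo axis of the stack must match the TE list")
    if te.size < 2:
        raise ValueError("need at least two echoes")
    flo = _signal_floor(stack[0], floor)
    valid = stack > flo
    s = np.where(valid, stack, 1.0)
    logs = np.log(s)
    w = np.where(valid, stack, 0.0) ** 2

    te_b = te.reshape((-1,) + (1,) * (stack.ndim - 1))
    sw = w.sum(axis=0)
    swx = (w * te_b).sum(axis=0)
    swy = (w * logs).sum(axis=0)
    swxx = (w * te_b**2).sum(axis=0)
    swxy = (w * te_b * logs).sum(axis=0)
    nvalid = valid.sum(axis=0)

    denom = sw * swxx - swx**2
    ok = (nvalid >= 2) & (denom > 0)
    denom_safe = np.where(ok, denom, 1.0)
    slope = (sw * swxy - swx * swy) / denom_safe
    inter = (swy * swxx - swx * swxy) / denom_safe
    ok &= slope < 0
    with np.errstate(over="ignore"):
        s0 = np.where(ok, np.exp(np.clip(inter, None, 700.0)), 0.0)
    t_decay = np.where(ok, -1.0 / np.where(slope < 0, slope, -1.0), 0.0)

    # weighted R^2 in the log domain
    ybar = np.where(sw > 0, swy / np.where(sw > 0, sw, 1.0), 0.0)
    fit_log = inter + slope * te_b
    ss_res = (w * (logs - fit_log) ** 2).sum(axis=0)
    ss_tot = (w * (logs - ybar) ** 2).sum(axis=0)
    r2 = np.where(ok & (ss_tot > 0), 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), 0.0)
    return s0, t_decay, r2, ok


def fit_monoexp_nonlinear(
    stack: np.ndarray,
    te_ms: np.ndarray | list[float],
    floor: float | None = None,
    max_voxels: int = 20000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel nonlinear least-squares mono-exponential fit (oracle path).

    Slow (one ``curve_fit`` call per voxel); intended for small volumes and
    as an independent cross-check of :func:`fit_monoexp`.
    """
    from scipy.optimize import curve_fit

    te = np.asarray(te_ms, dtype=float)
    s0_lin, t_lin, _, ok = fit_monoexp(stack, te, floor=floor)
    idx = np.argwhere(ok)
    if len(idx) > max_voxels:
        raise ValueError(f"too many voxels for the nonlinear path ({len(idx)})")
    s0 = np.zeros_like(s0_lin)
    t = np.zeros_like(t_lin)

    def model(x, a, tdec):
        return a * np.exp(-x / tdec)

    for vox in idx:
        key = tuple(vox)
        y = stack[(slice(None),) + key]
        p0 = (float(s0_lin[key]), float(t_lin[key]))
        try:
            popt, _ = curve_fit(model, te, y, p0=p0, maxfev=2000)
        except RuntimeError:  # pragma: no cover - rare non-convergence
            continue
        s0[key], t[key] = popt
    return s0, t, ok


def fit_pd(
    intercept: np.ndarray,
    t1: np.ndarray,
    tr_ms: float,
    te_pair: np.ndarray,
    vfa_te_ms: float,
    dte_ms: float,
    receive_field: np.ndarray,
    csf_mask: np.ndarray,
    mask: np.ndarray | None = None,
    floor: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Proton-density map from the VFA intercept.

    Removes, in order: residual T1 weighting (``M0 = intercept /
    (1 - exp(-TR/T1))``), residual T2* weighting at the VFA echo time using
    the decay rate measured from the TE-difference pair, and the receive
    sensitivity profile; finally scales the map so that the ventricle-CSF
    median equals 100 percent units.

    Returns ``(pd, mask)``.
    """
    if not np.any(csf_mask):
        raise CalibrationError("empty CSF mask: cannot calibrate PD to 100 p.u.")
    ok = (t1 > 0) & (intercept > 0)
    if mask is not None:
        ok = ok & mask
    flo = _signal_floor(te_pair[0], floor)
    s1, s2 = te_pair[0], te_pair[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((s1 > flo) & (s2 > 0), s2 / np.where(s1 > 0, s1, 1.0), np.nan)
    ok &= np.isfinite(ratio) & (ratio > 0) & (ratio < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2star_pair = np.where(ok, -dte_ms / np.log(np.where(ok, ratio, 0.5)), np.inf)
        e1 = np.exp(-tr_ms / np.where(ok, t1, 1.0))
        m0 = np.where(ok, intercept / (1.0 - e1), 0.0)
        pd = np.where(ok, m0 * np.exp(vfa_te_ms / t2star_pair) / receive_field, 0.0)
    csf = csf_mask & ok
    if not csf.any():
        raise CalibrationError("no valid CSF voxel for PD calibration")
    median_csf = float(np.median(pd[csf]))
    if median_csf <= 0:
        raise CalibrationError("non-positive CSF median; cannot scale PD")
    pd = pd * (100.0 / median_csf)
    return pd, ok


def derive_t2prime(
    t2: np.ndarray,
    t2star: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reversible transverse relaxation time, ``1/T2' = 1/T2* - 1/T2``.

    Voxels with ``T2* >= T2`` (non-physical under noise) are masked invalid
    rather than clipped.  Returns ``(t2prime, mask)``.
    """
    ok = (t2 > 0) & (t2star > 0) & (t2star < t2)
    if mask is not None:
        ok = ok & mask
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(ok, 1.0 / np.where(t2star > 0, t2star, 1.0) - 1.0 / np.where(t2 > 0, t2, 1.0), 1.0)
    ok &= rate > 0
    t2p = np.where(ok, 1.0 / np.where(rate > 0, rate, 1.0), 0.0)
    return t2p, ok


def estimate_receive_field(
    biased: np.ndarray,
    brain_mask: np.ndarray,
    order: int = 2,
) -> np.ndarray:
    """Polynomial receive-field estimate for field-free inputs.

    Fits a log-domain polynomial of total degree ``order`` to a
    receive-biased, approximately tissue-flat map over the brain mask and
    returns the normalised multiplicative field (mean 1 over the mask).
    This is a coarse estimator; in simulation mode the known synthetic field
    should be consumed instead.
    """
    shape = biased.shape
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    u, v, w = np.meshgrid(*axes, indexing="ij")
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((u**i) * (v**j) * (w**k))
    a = np.stack([c[brain_mask] for c in cols], axis=1)
    sel = brain_mask & (biased > 0)
    a = np.stack([c[sel] for c in cols], axis=1)
    y = np.log(biased[sel])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    logf = sum(c * cc for c, cc in zip(coef, cols))
    fld = np.exp(logf)
    fld /= fld[brain_mask].mean()
    return fld


def fit_qmaps(
    bundle: AcquisitionBundle,
    csf_mask: np.ndarray,
    receive_field: np.ndarray | None = None,
    drop_first_fse_echo: bool = False,
    floor: float | None = None,
) -> QMaps:
    """Run the full fitting chain on one acquisition bundle.

    ``receive_field`` defaults to the bundle's synthetic ground-truth field
    (simulation mode); pass an :func:`estimate_receive_field` output for
    field-free inputs.  ``drop_first_fse_echo`` excludes the first spin-echo
    from the T2 fit (a pragmatic alternative to an explicit stimulated-echo
    correction).
    """
    proto = bundle.protocol
    b1 = fit_b1(bundle.b1[0], bundle.b1[1], proto.b1_beta_deg, floor=floor)
    t1, intercept, m_t1 = fit_t1_vfa(
        bundle.vfa[0],
        bundle.vfa[1],
        proto.vfa_angles_deg[0],
        proto.vfa_angles_deg[1],
        proto.vfa_tr_ms,
        b1=b1,
        floor=floor,
    )
    fse = bundle.fse
    fse_te = np.asarray(proto.fse_te_ms)
    if drop_first_fse_echo:
        fse, fse_te = fse[1:], fse_te[1:]
    _, t2, r2_t2, m_t2 = fit_monoexp(fse, fse_te, floor=floor)
    _, t2star, r2_t2s, m_t2s = fit_monoexp(bundle.ge, np.asarray(proto.ge_te_ms), floor=floor)
    if receive_field is None:
        receive_field = bundle.receive_field
    if receive_field is None:
        raise ValueError("no receive field available; pass an estimate")
    pd, m_pd = fit_pd(
        intercept,
        t1,
        proto.vfa_tr_ms,
        bundle.te_pair,
        proto.vfa_te_ms,
        proto.te_pair_dte_ms,
        receive_field,
        csf_mask,
        mask=m_t1,
        floor=floor,
    )
    t2prime, m_t2p = derive_t2prime(t2, t2star, mask=m_t2 & m_t2s)
    return QMaps(
        t1=t1,
        pd=pd,
        t2=t2,
        t2star=t2star,
        t2prime=t2prime,
        masks={"T1": m_t1, "PD": m_pd, "T2": m_t2, "T2star": m_t2s, "T2prime": m_t2p},
        r2={"T2": r2_t2, "T2star": r2_t2s},
        b1=b1,
    )
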
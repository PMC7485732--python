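"""Forward synthesis of the multiparametric qMRI acquisition stacks.

Five stacks are synthesized from a phantom's ground-truth maps:

* a variable-flip-angle (VFA) pair of spoiled gradient-echo (FLASH) volumes
  for T1/PD mapping, using the ideal spoiled steady state
  ``S = R * PD * sin(k*a) * (1 - E1) / (1 - cos(k*a) * E1) * exp(-TE/T2*)``
  with ``E1 = exp(-TR/T1)`` and transmit scale ``k``;
* a 4-echo fast-spin-echo (FSE) stack for T2 (``S ∝ PD * exp(-TE/T2)``,
  ideal refocusing, saturation factor ``1 - exp(-TR/T1)``);
* an 8-echo gradient-echo (GE) stack for T2* (spoiled steady state times
  ``exp(-TE/T2*)``);
* a B1-calibration pair: a reference volume and a saturation-prepared volume
  whose longitudinal magnetization is scaled by ``cos(k*beta)``;
* a two-echo GE pair with a small TE difference, used to remove residual
  T2* weighting from the PD calculation.

Smooth multiplicative transmit (``k``) and receive (``R``) bias fields are
low-order 3D polynomials.  Noise is additive Gaussian on the magnitude (a
Rician option exists); its SD is anchored to the mean cortical-GM signal of
the T1-weighted VFA volume divided by the configured SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .phantom import SubjectPhantom

__all__ = [
    "AcquisitionProtocol",
    "AcquisitionBundle",
    "synthesize_acquisition",
    "spgr_signal",
    "polynomial_field",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing, flip angles and noise/bias configuration of all stacks.

    Defaults reproduce the 3 T protocol the analysis is designed around:
    VFA FLASH with TR 16.4 ms, TE 6.7 ms and nominal angles 4/24 deg; FSE
    echoes at 17/86/103/120 ms; GE echoes 10..52 ms in steps of 6 ms at
    30 deg/TR 2.4 s; and a TE-difference pair with dTE 6.7 ms.
    """

    vfa_tr_ms: float = 16.4
    vfa_te_ms: float = 6.7
    vfa_angles_deg: tuple[float, float] = (4.0, 24.0)

    fse_te_ms: tuple[float, ...] = (17.0, 86.0, 103.0, 120.0)
    fse_tr_ms: float = 8000.0

    ge_te_ms: tuple[float, ...] = (10.0, 16.0, 22.0, 28.0, 34.0, 40.0, 46.0, 52.0)
    ge_tr_ms: float = 2400.0
    ge_angle_deg: float = 30.0

    b1_beta_deg: float = 60.0  # nominal saturation angle of the prepared scan
    b1_angle_deg: float = 11.0
    b1_tr_ms: float = 2400.0
    b1_te_ms: float = 5.0

    te_pair_te1_ms: float = 6.7
    te_pair_dte_ms: float = 6.7
    te_pair_angle_deg: float = 30.0
    te_pair_tr_ms: float = 2400.0

    #: SNR of the T1-weighted VFA volume in cortical GM; ``None`` disables noise
    snr: float | None = 50.0
    noise_kind: str = "gaussian"  # "gaussian" | "rician"
    transmit_bias_amplitude: float = 0.10
    receive_bias_amplitude: float = 0.10

    def __post_init__(self) -> None:
        for name in ("vfa_tr_ms", "vfa_te_ms", "fse_tr_ms", "ge_tr_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for te_list in (self.fse_te_ms, self.ge_te_ms):
            if np.any(np.diff(te_list) <= 0):
                raise ValueError("echo-time lists must be strictly increasing")
        if self.vfa_angles_deg[0] == self.vfa_angles_deg[1]:
            raise ValueError("the two VFA flip angles must differ")
        if self.noise_kind not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")

    def noiseless(self) -> "AcquisitionProtocol":
        return replace(self, snr=None)

    def unbiased(self) -> "AcquisitionProtocol":
        return replace(self, transmit_bias_amplitude=0.0, receive_bias_amplitude=0.0)


@dataclass
class AcquisitionBundle:
    """The synthesized signal stacks for one subject (echo/volume first)."""

    vfa: np.ndarray  # (2, X, Y, Z)
    fse: np.ndarray  # (n_fse, X, Y, Z)
    ge: np.ndarray  # (n_ge, X, Y, Z)
    b1: np.ndarray  # (2, X, Y, Z): reference, prepared
    te_pair: np.ndarray  # (2, X, Y, Z)
    protocol: AcquisitionProtocol
    voxel_size_mm: float
    seed: int | None = None
    noise_sd: float = 0.0
    #: simulation ground truth, consumed by the fitters in oracle mode
    kappa_field: np.ndarray | None = None
    receive_field: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = self.vfa.shape[1:]
        for name in ("fse", "ge", "b1", "te_pair"):
            if getattr(self, name).shape[1:] != grid:
                raise ValueError(f"stack {name!r} is not on the phantom grid")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(self.vfa.shape[1:])


def spgr_signal(
    pd: np.ndarray,
    t1: np.ndarray,
    flip_rad: np.ndarray | float,
    tr_ms: float,
) -> np.ndarray:
    """Ideal spoiled gradient-echo steady-state signal (no T2* decay)."""
    pd, t1, flip = np.broadcast_arrays(
        np.asarray(pd, dtype=float), np.asarray(t1, dtype=float), np.asarray(flip_rad, dtype=float)
    )
    ok = t1 > 0
    e1 = np.exp(-tr_ms / np.where(ok, t1, 1.0))
    sig = pd * np.sin(flip) * (1.0 - e1) / (1.0 - np.cos(flip) * e1)
    return np.where(ok, sig, 0.0)


def polynomial_field(
    shape: tuple[int, int, int],
    amplitude: float,
    rng: np.random.Generator,
    order: int = 2,
) -> np.ndarray:
    """Smooth multiplicative bias field ``1 + amplitude * q`` with |q| <= 1.

    ``q`` is a random polynomial of total degree ``order`` in grid
    coordinates normalised to [-1, 1], rescaled to peak magnitude 1.
    """
    if amplitude == 0:
        return np.ones(shape)
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    u, v, w = np.meshgrid(*axes, indexing="ij", sparse=True)
    q = np.zeros(shape)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i + j + k == 0:
                    continue
                q = q + rng.normal() * (u**i) * (v**j) * (w**k)
    q -= q.mean()
    peak = np.abs(q).max()
    if peak > 0:
        q /= peak
    return 1.0 + amplitude * q


def _add_noise(
    stacks: dict[str, np.ndarray],
    sd: float,
    kind: str,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    out = {}
    for name, s in stacks.items():
        if sd <= 0:
            out[name] = s
        elif kind == "rician":
            re = s + sd * rng.standard_normal(s.shape)
            im = sd * rng.standard_normal(s.shape)
            out[name] = np.hypot(re, im)
        else:
            noisy = rng.standard_normal(s.shape)
            noisy *= sd
            noisy += s
            np.abs(noisy, out=noisy)
            out[name] = noisy
    return out


def synthesize_acquisition(
    phantom: SubjectPhantom,
    protocol: AcquisitionProtocol | None = None,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> AcquisitionBundle:
    """Forward-synthesize every acquisition stack for one phantom.

    Noiseless synthesis followed by the fitters in
    :mod:`cortexage.relaxometry` recovers the ground-truth maps to numerical
    precision (round-trip property).
    """
    protocol = protocol or AcquisitionProtocol()
    rng = np.random.default_rng(seed)
    shape = phantom.labels.shape
    brain = phantom.brain_mask

    kappa = polynomial_field(shape, protocol.transmit_bias_amplitude, rng)
    receive = polynomial_field(shape, protocol.receive_bias_amplitude, rng)

    # signals are zero outside the head, so everything is computed on the
    # flattened brain voxels only and scattered back into full volumes
    t1 = phantom.maps["T1"][brain]
    pd = phantom.maps["PD"][brain]
    inv_t2 = 1.0 / phantom.maps["T2"][brain]
    inv_t2s = 1.0 / phantom.maps["T2star"][brain]
    kv = kappa[brain]
    rv = receive[brain]

    def vols(voxel_stacks: list[np.ndarray]) -> np.ndarray:
        out = np.zeros((len(voxel_stacks),) + shape)
        for i, vals in enumerate(voxel_stacks):
            out[i][brain] = vals
        return out

    def t2s_decay(te: float) -> np.ndarray:
        return np.exp(-te * inv_t2s)

    # --- VFA pair -----------------------------------------------------------
    vfa_decay = t2s_decay(protocol.vfa_te_ms)
    vfa = vols(
        [
            rv
            * spgr_signal(pd, t1, kv * np.deg2rad(a), protocol.vfa_tr_ms)
            * vfa_decay
            for a in protocol.vfa_angles_deg
        ]
    )

    # --- FSE stack (T2) -----------------------------------------------------
    sat = 1.0 - np.exp(-protocol.fse_tr_ms / t1)
    fse_base = rv * pd * sat
    fse = vols([fse_base * np.exp(-te * inv_t2) for te in protocol.fse_te_ms])

    # --- GE stack (T2*) -----------------------------------------------------
    ge_base = rv * spgr_signal(
        pd, t1, kv * np.deg2rad(protocol.ge_angle_deg), protocol.ge_tr_ms
    )
    ge = vols([ge_base * t2s_decay(te) for te in protocol.ge_te_ms])

    # --- B1 pair ------------------------------------------------------------
    b1_ref = rv * spgr_signal(
        pd, t1, kv * np.deg2rad(protocol.b1_angle_deg), protocol.b1_tr_ms
    ) * t2s_decay(protocol.b1_te_ms)
    b1_prep = np.abs(b1_ref * np.cos(kv * np.deg2rad(protocol.b1_beta_deg)))
    b1 = vols([b1_ref, b1_prep])

    # --- TE-difference pair -------------------------------------------------
    tp_base = rv * spgr_signal(
        pd, t1, kv * np.deg2rad(protocol.te_pair_angle_deg), protocol.te_pair_tr_ms
    )
    tp = vols(
        [
            tp_base * t2s_decay(protocol.te_pair_te1_ms),
            tp_base * t2s_decay(protocol.te_pair_te1_ms + protocol.te_pair_dte_ms),
        ]
    )

    stacks = {"vfa": vfa, "fse": fse, "ge": ge, "b1": b1, "te_pair": tp}

    gm = phantom.gm_mask
    noise_sd = 0.0
    if protocol.snr is not None and protocol.snr > 0:
        noise_sd = float(vfa[1][gm].mean() / protocol.snr)
        stacks = _add_noise(stacks, noise_sd, protocol.noise_kind, rng)

    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return AcquisitionBundle(
        **stacks,
        protocol=protocol,
        voxel_size_mm=phantom.geometry.voxel_size_mm,
        seed=seed_int,
        noise_sd=noise_sd,
        kappa_field=kappa,
        receive_field=receive,
    )
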
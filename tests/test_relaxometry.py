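"""Voxelwise fitters: round trips, oracles, masks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cortexage.acquisition import spgr_signal
from cortexage.relaxometry import (
    AcquisitionOrderError,
    derive_t2prime,
    fit_b1,
    fit_monoexp,
    fit_monoexp_nonlinear,
    fit_pd,
    fit_t1_vfa,
)

VFA_TR = 16.4
VFA_ANGLES = (4.0, 24.0)


def _vfa_pair(t1, pd=80.0, kappa=1.0):
    t1 = np.atleast_1d(np.asarray(t1, dtype=float))
    pd = np.broadcast_to(np.asarray(pd, dtype=float), t1.shape)
    return [
        spgr_signal(pd, t1, kappa * np.deg2rad(a), VFA_TR) for a in VFA_ANGLES
    ]


class TestRoundTrip:
    """Noiseless synthesis -> fitting recovers ground truth to 1e-6."""

    @pytest.mark.parametrize("param", ["T1", "PD", "T2", "T2star", "T2prime"])
    def test_all_fitters(self, ref_phantom, noiseless_qmaps, param):
        truth = ref_phantom.maps[param]
        sel = noiseless_qmaps.mask(param) & ref_phantom.brain_mask
        # every tissue voxel must be recovered, not just a lucky subset
        assert sel.sum() == ref_phantom.brain_mask.sum()
        rel = np.abs(noiseless_qmaps[param][sel] - truth[sel]) / truth[sel]
        assert rel.max() < 1e-6

    def test_b1_field_recovered(self, ref_phantom, noiseless_bundle, noiseless_qmaps):
        kappa_true = noiseless_bundle.kappa_field
        b1 = noiseless_qmaps.b1
        sel = b1.mask & ref_phantom.brain_mask
        assert np.abs(b1.kappa[sel] - kappa_true[sel]).max() < 1e-9


class TestB1:
    def test_identity_and_example(self):
        ref = np.full((4, 4, 4), 100.0)
        prep = ref * 0.5
        m = fit_b1(ref, prep, 60.0, floor=1.0)
        assert np.allclose(m.kappa[m.mask], 1.0)
        m2 = fit_b1(ref, ref * 0.400, 60.0, floor=1.0)
        assert np.allclose(m2.kappa[m2.mask], np.degrees(np.arccos(0.400)) / 60.0)
        assert m2.kappa[m2.mask][0] == pytest.approx(1.107, abs=2e-3)

    def test_unsaturated_voxel_masked(self):
        ref = np.full((2, 2, 2), 100.0)
        m = fit_b1(ref, ref.copy(), 60.0, floor=1.0)  # ratio 1 -> kappa 0
        assert not m.mask.any()

    def test_swapped_pair_detected(self):
        ref = np.full((4, 4, 4), 50.0)
        with pytest.raises(AcquisitionOrderError):
            fit_b1(ref, ref * 2.0, 60.0, floor=1.0)


class TestVfaT1:
    def test_exact_recovery(self):
        s1, s2 = _vfa_pair(1300.0)
        t1, _, ok = fit_t1_vfa(s1, s2, *VFA_ANGLES, VFA_TR, floor=1e-12)
        assert ok.all()
        assert t1[0] == pytest.approx(1300.0, rel=1e-9)

    def test_b1_correction_identity(self):
        """Ignoring a 20% transmit error biases T1; correcting it is exact."""
        from cortexage.relaxometry import B1Map

        s1, s2 = _vfa_pair(1300.0, kappa=1.2)
        t1_raw, _, _ = fit_t1_vfa(s1, s2, *VFA_ANGLES, VFA_TR, floor=1e-12)
        assert abs(t1_raw[0] - 1300.0) / 1300.0 > 0.10
        b1 = B1Map(kappa=np.full(1, 1.2), mask=np.ones(1, bool))
        t1_cor, _, _ = fit_t1_vfa(s1, s2, *VFA_ANGLES, VFA_TR, b1=b1, floor=1e-12)
        assert t1_cor[0] == pytest.approx(1300.0, rel=1e-9)

    def test_noisy_median_within_two_percent(self):
        """Monte Carlo at SNR 50: the closed-form estimator's median is
        within 2% of truth and agrees with a nonlinear LS oracle."""
        from scipy.optimize import curve_fit

        rng = np.random.default_rng(77)
        n = 1000
        s1, s2 = _vfa_pair(np.full(n, 1300.0))
        sd = s2[0] / 50.0
        s1n = s1 + rng.normal(0, sd, n)
        s2n = s2 + rng.normal(0, sd, n)
        t1, _, ok = fit_t1_vfa(s1n, s2n, *VFA_ANGLES, VFA_TR, floor=1e-12)
        med = np.median(t1[ok])
        assert med == pytest.approx(1300.0, rel=0.02)

        def model(a_deg, pd, t1_):
            return spgr_signal(pd, np.asarray(t1_), np.deg2rad(a_deg), VFA_TR)

        # nonlinear oracle on a subsample
        angles = np.asarray(VFA_ANGLES)
        oracle = []
        for i in range(0, 200):
            popt, _ = curve_fit(
                model, angles, [s1n[i], s2n[i]], p0=(80.0, 1200.0), maxfev=5000
            )
            oracle.append(popt[1])
        assert np.median(oracle) == pytest.approx(med, rel=0.02)

    def test_all_invalid_raises(self):
        from cortexage.relaxometry import FitError

        with pytest.raises(FitError):
            fit_t1_vfa(
                np.zeros(4), np.zeros(4), *VFA_ANGLES, VFA_TR, floor=1.0
            )


class TestMonoexp:
    @pytest.mark.parametrize(
        "tdecay, te",
        [
            (80.0, [17.0, 86.0, 103.0, 120.0]),
            (55.0, list(range(10, 53, 6))),
        ],
    )
    def test_exact_on_noiseless(self, tdecay, te):
        te = np.asarray(te, dtype=float)
        stack = 100.0 * np.exp(-te / tdecay)[:, None]
        s0, t, r2, ok = fit_monoexp(stack, te, floor=1e-12)
        assert ok.all()
        assert t[0] == pytest.approx(tdecay, rel=1e-12)
        assert s0[0] == pytest.approx(100.0, rel=1e-12)
        assert r2[0] == pytest.approx(1.0, abs=1e-12)

    @given(
        tdecay=st.floats(20.0, 300.0),
        s0=st.floats(1.0, 500.0),
    )
    def test_exact_recovery_property(self, tdecay, s0):
        te = np.asarray([10.0, 22.0, 34.0, 52.0])
        stack = s0 * np.exp(-te / tdecay)[:, None]
        _, t, _, ok = fit_monoexp(stack, te, floor=0.0)
        assert ok[0]
        assert t[0] == pytest.approx(tdecay, rel=1e-9)

    def test_weighted_fit_bias_vs_nonlinear_oracle(self):
        """At SNR 40 the weighted log-linear T2 agrees with the nonlinear LS
        oracle to better than 1% on average."""
        rng = np.random.default_rng(11)
        te = np.asarray([17.0, 86.0, 103.0, 120.0])
        n = 1000
        clean = 100.0 * np.exp(-te / 90.0)
        stack = clean[:, None] + rng.normal(0, 100.0 / 40.0, (te.size, n))
        stack = np.abs(stack).reshape(te.size, n, 1, 1)
        _, t_lin, _, ok = fit_monoexp(stack, te, floor=0.5)
        _, t_nl, ok_nl = fit_monoexp_nonlinear(stack, te, floor=0.5)
        both = ok & ok_nl & (t_nl > 0)
        assert both.mean() > 0.95
        bias = abs(t_lin[both].mean() - t_nl[both].mean()) / t_nl[both].mean()
        assert bias < 0.01

    def test_insufficient_echoes_masked(self):
        te = np.asarray([10.0, 20.0, 30.0])
        stack = np.array([5.0, 0.0, 0.0])[:, None]  # one echo above floor
        _, _, _, ok = fit_monoexp(stack, te, floor=0.5)
        assert not ok[0]


class TestPd:
    def test_te_pair_t2star_example(self):
        """dTE = 6.7 ms and T2* = 50 ms give a pair ratio exp(-6.7/50)."""
        ratio = np.exp(-6.7 / 50.0)
        assert ratio == pytest.approx(0.8745, abs=2e-4)
        assert -6.7 / np.log(ratio) == pytest.approx(50.0, rel=1e-12)

    def test_cortical_pd_recovery(self, ref_phantom, noiseless_qmaps):
        gm = ref_phantom.gm_mask
        target = ref_phantom.maps["PD"][gm].mean()
        fitted = noiseless_qmaps["PD"][gm & noiseless_qmaps.mask("PD")].mean()
        assert fitted == pytest.approx(target, abs=0.5)

    def test_empty_csf_raises(self, ref_phantom, noiseless_bundle):
        from cortexage.relaxometry import CalibrationError, fit_qmaps

        with pytest.raises(CalibrationError):
            fit_qmaps(noiseless_bundle, csf_mask=np.zeros(ref_phantom.labels.shape, bool))


class TestT2Prime:
    def test_algebraic_identity(self):
        t2 = np.linspace(40.0, 160.0, 13)
        t2p, ok = derive_t2prime(t2, t2 / 2.0)
        assert ok.all()
        assert np.allclose(t2p, t2, rtol=1e-12)

    def test_printed_value_combination(self):
        t2p, ok = derive_t2prime(np.array([86.99]), np.array([61.60]))
        assert ok[0]
        assert t2p[0] == pytest.approx(211.05, abs=0.05)

    def test_nonphysical_masked_not_clipped(self):
        t2 = np.array([80.0, 80.0, 80.0])
        t2s = np.array([80.0, 90.0, 40.0])
        t2p, ok = derive_t2prime(t2, t2s)
        assert list(ok) == [False, False, True]
        assert t2p[2] == pytest.approx(80.0)

    def test_monotone_in_true_t2prime(self):
        """Noiseless: larger ground-truth T2' never yields smaller fitted T2'."""
        te_fse = np.asarray([17.0, 86.0, 103.0, 120.0])
        te_ge = np.asarray(range(10, 53, 6), dtype=float)
        t2 = 87.0
        t2p_grid = np.linspace(60.0, 400.0, 25)
        t2s_grid = 1.0 / (1.0 / t2 + 1.0 / t2p_grid)
        fse = 80.0 * np.exp(-te_fse[:, None] / t2)
        ge = 70.0 * np.exp(-te_ge[:, None] / t2s_grid[None, :])
        _, t2_fit, _, ok1 = fit_monoexp(np.broadcast_to(fse, (4, 25)).copy(), te_fse, floor=0.0)
        _, t2s_fit, _, ok2 = fit_monoexp(ge, te_ge, floor=0.0)
        t2p_fit, ok = derive_t2prime(t2_fit, t2s_fit, ok1 & ok2)
        assert ok.all()
        assert np.all(np.diff(t2p_fit) > 0)


def test_mask_soundness_under_noise(noisy_subject):
    """No NaN/Inf inside validity masks; physicality holds where valid."""
    ph, _, qmaps = noisy_subject
    for p in qmaps.parameters:
        vals = qmaps[p][qmaps.mask(p)]
        assert np.isfinite(vals).all()
        assert (vals > 0).all()
    joint = qmaps.mask("T2") & qmaps.mask("T2star") & qmaps.mask("T2prime")
    assert np.all(qmaps["T2star"][joint] <= qmaps["T2"][joint])
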
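"""Correlation statistics: global, partial, smoothing, cluster inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cortexage.stats import (
    EmptyRibbonError,
    UndefinedCorrelationError,
    correlate,
    global_summary,
    lobar_analysis,
    mapwise_correlation,
    smooth_map,
)


class TestCorrelate:
    def test_identity_and_hand_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert correlate(x, x).r == pytest.approx(1.0)
        rep = correlate(x, np.array([2.0, 1.0, 4.0, 3.0, 5.0]))
        assert rep.r == pytest.approx(0.8, abs=1e-12)  # 8 / sqrt(10*10)
        assert rep.n == 5

    def test_p_value_matches_scipy(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rep = correlate(x, y)
        r_sp, p_sp = pearsonr(x, y)
        assert rep.r == pytest.approx(r_sp, abs=1e-12)
        assert rep.p == pytest.approx(p_sp, rel=1e-9)

    def test_partial_matches_matrix_inverse_oracle(self):
        """Partial correlation equals the inverse-correlation-matrix formula
        to 1e-10 on random small datasets."""
        rng = np.random.default_rng(3)
        for trial in range(20):
            n, k = 25, rng.integers(1, 4)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            z = rng.normal(size=(n, k))
            rep = correlate(x, y, covariates=z)
            corr = np.corrcoef(np.column_stack([x, y, z]).T)
            om = np.linalg.inv(corr)
            oracle = -om[0, 1] / np.sqrt(om[0, 0] * om[1, 1])
            assert rep.r == pytest.approx(oracle, abs=1e-10)

    def test_partial_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n = 40
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "z1": rng.normal(size=n),
                "z2": rng.normal(size=n),
            }
        )
        rep = correlate(
            df["x"].to_numpy(), df["y"].to_numpy(), covariates=df[["z1", "z2"]].to_numpy()
        )
        out = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        assert rep.r == pytest.approx(float(out["r"].iloc[0]), abs=1e-9)
        assert rep.p == pytest.approx(float(out["p_val"].iloc[0]), rel=1e-6)

    def test_independent_covariate_leaves_r_untouched(self):
        rng = np.random.default_rng(8)
        n = 4000
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # independent of both
        plain = correlate(x, y).r
        partial = correlate(x, y, covariates=z[:, None]).r
        assert partial == pytest.approx(plain, abs=0.02)

    def test_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            correlate(np.arange(4.0), np.arange(4.0), covariates=np.ones((4, 2)))
        with pytest.raises(ValueError):
            correlate(np.array([1.0, np.nan, 2.0]), np.arange(3.0))


class TestGlobalSummary:
    def test_constant_and_two_voxel_sd(self):
        per_subject = [
            {"T1": (100.0, 0.0)},
            {"T1": (100.0, 28.284)},
        ]
        subj, cohort = global_summary(per_subject)
        assert subj["T1_mean"].tolist() == [100.0, 100.0]
        assert cohort.loc["T1", "mean_of_means"] == 100.0
        assert cohort.loc["T1", "sd_of_means"] == 0.0

    def test_cortical_summary_conventions(self, ref_phantom, noiseless_qmaps):
        from cortexage.stats import cortical_summary

        gm = ref_phantom.gm_mask
        stats_ = cortical_summary(noiseless_qmaps, gm)
        vals = noiseless_qmaps["T1"][gm]
        assert stats_["T1"][0] == pytest.approx(vals.mean())
        assert stats_["T1"][1] == pytest.approx(vals.std(ddof=1))  # sample SD

    def test_two_voxel_sample_sd(self, noiseless_qmaps, ref_phantom):
        vals = np.array([80.0, 120.0])
        assert vals.std(ddof=1) == pytest.approx(28.284, abs=1e-3)

    def test_empty_ribbon_flagged(self, noiseless_qmaps):
        from cortexage.stats import cortical_summary

        with pytest.raises(EmptyRibbonError):
            cortical_summary(noiseless_qmaps, np.zeros(noiseless_qmaps.t1.shape, bool))
        with pytest.warns(UserWarning, match="excluding"):
            subj, _ = global_summary([{"T1": (1.0, 0.0)}, None])
        assert len(subj) == 1


class TestSmoothing:
    def _blob(self):
        mask = np.zeros((24, 24, 24), bool)
        mask[4:20, 4:20, 4:20] = True
        return mask

    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        mask = self._blob()
        vol = rng.normal(size=mask.shape)
        out = smooth_map(vol, mask, 0.0, 2.0)
        assert np.array_equal(out[mask], vol[mask])
        assert np.all(out[~mask] == 0)

    def test_constant_preserved_exactly(self):
        mask = self._blob()
        vol = np.where(mask, 7.25, 0.0)
        out = smooth_map(vol, mask, 10.0, 2.0)
        assert np.allclose(out[mask], 7.25, rtol=1e-10)

    def test_delta_mass_preserved_in_interior(self):
        mask = self._blob()
        vol = np.zeros(mask.shape)
        vol[12, 12, 12] = 5.0
        out = smooth_map(vol, mask, 6.0, 2.0)
        assert out.sum() == pytest.approx(5.0, rel=1e-3)

    def test_no_bleed_from_outside(self):
        mask = self._blob()
        vol = np.full(mask.shape, 1000.0)  # huge values outside the mask
        vol[mask] = 1.0
        out = smooth_map(vol, mask, 8.0, 2.0)
        assert np.allclose(out[mask], 1.0, rtol=1e-10)


def _brute_force_cluster_p(maps, mask, ages, threshold_p):
    """Independent enumeration oracle: voxel r via np.corrcoef, clusters via
    breadth-first search, exhaustive permutations of the ages."""
    from scipy.stats import pearsonr

    coords = np.argwhere(mask)

    def cluster_sizes(age_vec):
        rs, ps = [], []
        for c in coords:
            r, p = pearsonr(maps[(slice(None), *c)], age_vec)
            rs.append(r)
            ps.append(p)
        supra = {
            tuple(c)
            for c, r, p in zip(coords, rs, ps)
            if p < threshold_p
        }
        sign = {tuple(c): np.sign(r) for c, r in zip(coords, rs)}
        seen, out = set(), {1.0: [], -1.0: []}
        for start in supra:
            if start in seen:
                continue
            group, queue = [], [start]
            seen.add(start)
            while queue:
                v = queue.pop()
                group.append(v)
                for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                    if w in supra and w not in seen and sign[w] == sign[start]:
                        seen.add(w)
                        queue.append(w)
            out[sign[start]].append(len(group))
        return out

    obs = cluster_sizes(ages)
    n = len(ages)
    null = {1.0: [], -1.0: []}
    for perm in itertools.permutations(range(n)):
        sizes = cluster_sizes(ages[list(perm)])
        for sgn in (1.0, -1.0):
            null[sgn].append(max(sizes[sgn], default=0))
    results = {}
    total = len(null[1.0])
    for sgn in (1.0, -1.0):
        for size in obs[sgn]:
            p = sum(m >= size for m in null[sgn]) / total
            results.setdefault(sgn, []).append((size, p))
    return results


class TestMapwise:
    def test_exhaustive_toy_matches_enumeration_oracle(self):
        """3x3 single-slice ribbon, n=6: exhaustive cluster p equals an
        independent brute-force enumeration exactly."""
        rng = np.random.default_rng(42)
        mask = np.zeros((3, 3, 1), bool)
        mask[:, :, 0] = True
        ages = np.array([20.0, 30.0, 40.0, 50.0, 60.0, 70.0])
        maps = rng.normal(size=(6, 3, 3, 1))
        maps[:, 0, :, 0] += 0.05 * ages[:, None]  # plant an effect in one row
        rep = mapwise_correlation(maps, mask, ages, threshold_p=0.3, exact=True)
        oracle = _brute_force_cluster_p(maps, mask, ages, threshold_p=0.3)
        assert rep.clusters is not None and len(rep.clusters)
        for _, row in rep.clusters.iterrows():
            sgn = 1.0 if row["sign"] == "+" else -1.0
            matches = [p for s, p in oracle.get(sgn, []) if s == row["size_vox"]]
            assert row["p_cluster"] in matches

    def test_type_one_error_calibration(self):
        """Null data: the family-wise rate of >=1 significant cluster stays
        at the nominal 5% (within the binomial CI over 200 repeats)."""
        rng = np.random.default_rng(2024)
        mask = np.zeros((6, 6, 4), bool)
        mask[1:5, 1:5, 1:3] = True
        n_sub, n_rep = 10, 200
        ages = np.linspace(20, 70, n_sub)
        hits = 0
        for rep_i in range(n_rep):
            maps = rng.normal(size=(n_sub,) + mask.shape)
            rep = mapwise_correlation(
                maps, mask, ages, threshold_p=0.05, n_perm=199, seed=rep_i
            )
            if rep.clusters is not None and len(rep.clusters):
                hits += rep.clusters["significant"].any()
        rate = hits / n_rep
        assert 0.005 <= rate <= 0.095  # 0.05 +- ~3 binomial SDs (and conservative)

    def test_localised_effect_recovered(self, template_phantom):
        """An age effect painted into the frontal sectors produces
        significant clusters that lie in the frontal sectors."""
        from cortexage.anatomy import parcellate_lobes

        ph = template_phantom
        ribbon = ph.gm_mask
        lobes = parcellate_lobes(ribbon, ph.geometry.voxel_size_mm)
        frontal = (lobes == 1) | (lobes == 5)
        rng = np.random.default_rng(9)
        n = 24
        ages = np.linspace(19, 71, n)
        maps = rng.normal(0, 1.0, size=(n,) + ribbon.shape)
        effect = -0.05 * (ages - ages.mean())
        maps[:, frontal] += effect[:, None]
        rep = mapwise_correlation(maps, ribbon, ages, n_perm=200, seed=3)
        sig = rep.clusters[rep.clusters["significant"] & (rep.clusters["sign"] == "-")]
        assert len(sig) >= 1
        # reconstruct significant negative voxels and check their location
        from scipy import ndimage

        neg = (rep.p_map < 0.05) & (rep.r_map < 0)
        lab, _ = ndimage.label(neg, structure=ndimage.generate_binary_structure(3, 1))
        good = np.zeros_like(neg)
        for _, row in sig.iterrows():
            for cid in range(1, lab.max() + 1):
                if (lab == cid).sum() == row["size_vox"]:
                    good |= lab == cid
        assert good.any()
        assert (good & frontal).sum() / good.sum() >= 0.90

    def test_input_validation(self):
        mask = np.ones((2, 2, 2), bool)
        maps = np.zeros((4, 2, 2, 2))
        with pytest.raises(ValueError, match="mismatch"):
            mapwise_correlation(np.zeros((4, 3, 2, 2)), mask, np.arange(4.0))
        with pytest.raises(ValueError, match="n_perm"):
            mapwise_correlation(maps, mask, np.arange(4.0), n_perm=10)


class TestLobar:
    @staticmethod
    def _tidy(values_by_lobe, ages, extra_param=None):
        rows = []
        lobe_names = ("frontal", "parietal", "temporal", "occipital")
        th_rng = np.random.default_rng(5)
        thickness = 2.45 + th_rng.normal(0, 0.08, len(ages))
        for i in range(len(ages)):
            for lobe in lobe_names:
                for hemi in ("left", "right"):
                    rows.append(
                        {
                            "subject": f"s{i}",
                            "lobe": lobe,
                            "hemisphere": hemi,
                            "parameter": "T2prime",
                            "value": values_by_lobe[lobe][i],
                        }
                    )
                    rows.append(
                        {
                            "subject": f"s{i}",
                            "lobe": lobe,
                            "hemisphere": hemi,
                            "parameter": "thickness",
                            "value": thickness[i],
                        }
                    )
        return pd.DataFrame(rows)

    def test_hemisphere_average_identity(self):
        df = pd.DataFrame(
            [
                {"subject": "s", "lobe": "frontal", "hemisphere": "left", "parameter": "T1", "value": 10.0},
                {"subject": "s", "lobe": "frontal", "hemisphere": "right", "parameter": "T1", "value": 20.0},
            ]
        )
        avg = df.groupby(["subject", "lobe", "parameter"])["value"].mean()
        assert avg.iloc[0] == 15.0

    def test_global_effect_reaches_every_lobe(self):
        rng = np.random.default_rng(12)
        n = 30
        ages = np.linspace(19, 71, n)
        vals = {
            lobe: 201.5 - 1.087 * (ages - 45) + rng.normal(0, 10, n)
            for lobe in ("frontal", "parietal", "temporal", "occipital")
        }
        tidy = self._tidy(vals, ages)
        idx = [f"s{i}" for i in range(n)]
        out = lobar_analysis(
            tidy,
            ages=pd.Series(ages, index=idx),
            tiv=pd.Series(rng.normal(1400, 100, n), index=idx),
        )
        t2p = out[out.parameter == "T2prime"]
        assert len(t2p) == 4
        assert (t2p["r_age"] < 0).all()
        assert t2p["significant_age"].all()

    def test_null_cohort_rarely_significant(self):
        rng = np.random.default_rng(77)
        n = 30
        ages = np.linspace(19, 71, n)
        flags = []
        for rep in range(40):
            vals = {
                lobe: rng.normal(200, 20, n)
                for lobe in ("frontal", "parietal", "temporal", "occipital")
            }
            tidy = self._tidy(vals, ages)
            idx = [f"s{i}" for i in range(n)]
            out = lobar_analysis(
                tidy,
                ages=pd.Series(ages, index=idx),
                tiv=pd.Series(rng.normal(1400, 100, n), index=idx),
            )
            flags.extend(out[out.parameter == "T2prime"]["significant_age"].tolist())
        rate = np.mean(flags)
        assert rate <= 0.12  # nominal 5%, generous binomial margin
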
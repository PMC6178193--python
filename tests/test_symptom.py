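"""Cohort statistics, correlation mapping, peaks, and sphere contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cerebsig as cs
from cerebsig.errors import CerebsigError

from conftest import small_config


def _patient_table(n, groups=("A", "B", "C"), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append({"subject_id": f"p{i:03d}", "group": groups[i % len(groups)],
                     "sara": float(rng.uniform(2, 30)),
                     "cerebrum_volume": 1e6})
    return pd.DataFrame(rows)


class TestCohortStats:
    def test_equal_group_means_give_zero_F(self):
        tab = _patient_table(12)
        # severities identical across groups -> between-group variance 0
        sev = {}
        for g, sub in tab.groupby("group"):
            for k, sid in enumerate(sub.subject_id):
                sev[sid] = 0.05 + 0.01 * k
        st = cs.severity_group_stats(sev, tab)
        assert st.anova_F < 1e-20
        assert st.anova_p > 0.999

    def test_anova_matches_statsmodels_oracle(self, rng):
        import statsmodels.formula.api as smf
        import statsmodels.api as sm
        tab = _patient_table(21, seed=3)
        sev = {s: float(v) for s, v in zip(
            tab.subject_id, rng.normal(0.1, 0.03, len(tab)))}
        st = cs.severity_group_stats(sev, tab)
        df = tab.assign(severity=tab.subject_id.map(sev))
        an = sm.stats.anova_lm(smf.ols("severity ~ C(group)", df).fit(), typ=1)
        assert abs(st.anova_F - float(an.loc["C(group)", "F"])) < 1e-10
        # Pearson r against scipy directly
        r, _ = stats.pearsonr(df.severity, df.sara)
        assert abs(st.severity_sara_r - r) < 1e-12

    def test_sara_covariate_absorbs_group_effect(self):
        # severity exactly linear in sara; groups differ only through sara.
        # The covariate absorbs the whole group effect: the group term's
        # sum of squares vanishes relative to the covariate's.
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        tab = _patient_table(30)
        tab["sara"] = [5.0 + 0.8 * i + 10 * ("ABC".index(g))
                       for i, g in enumerate(tab.group)]
        sev = {s: 0.01 + 0.004 * sara for s, sara in zip(tab.subject_id, tab.sara)}
        st = cs.severity_group_stats(sev, tab)
        assert st.anova_p < 1e-4         # without the covariate, groups differ
        df = tab.assign(severity=tab.subject_id.map(sev))
        an = sm.stats.anova_lm(smf.ols("severity ~ C(group) + sara", df).fit(),
                               typ=2)
        assert an.loc["C(group)", "sum_sq"] < 1e-12 * an.loc["sara", "sum_sq"]

    def test_df_bookkeeping(self):
        tab = _patient_table(55)
        rngl = np.random.default_rng(1)
        sev = {s: float(v) for s, v in zip(tab.subject_id,
                                           rngl.normal(0.1, 0.02, 55))}
        st = cs.severity_group_stats(sev, tab)
        assert st.anova_df == (2, 52)
        assert st.ancova_df == (2, 51)


class TestNucleusROIs:
    def test_control_equals_template_zero_degeneration(self):
        cfg = small_config(noise_sd=0.0, brain_coupling=0.0,
                           group_sizes={"HC": 3, "SCA2like": 3, "SCA3like": 3})
        cohort = cs.simulate(cfg)
        df = cs.nucleus_roi_volumes(cohort.maps, cohort.table, cohort.atlas)
        hc = df[df.group == "HC"]
        assert np.allclose(hc.degeneration, 0.0, atol=1e-12)

    def test_low_nucleus_subtype_least_degenerated(self):
        # the SCA3 analog is configured with half nucleus involvement: its
        # group-mean nucleus degeneration should be lowest in all three ROIs
        cfg = small_config(seed=6, group_sizes={"HC": 8, "SCA2like": 10,
                                                "SCA3like": 10, "SCA7like": 10},
                           severity_mean={"SCA2like": 0.12, "SCA3like": 0.12,
                                          "SCA7like": 0.12})
        cohort = cs.simulate(cfg)
        df = cs.nucleus_roi_volumes(cohort.maps, cohort.table, cohort.atlas)
        pat = df[df.group != "HC"]
        for roi, sub in pat.groupby("roi"):
            means = sub.groupby("group")["degeneration"].mean()
            assert means.idxmin() == "SCA3like"
        assert set(df.attrs["group_contrasts"]) == {
            "dentate", "pontine", "inferior_olive"}

    def test_single_voxel_roi_mean(self):
        atlas = cs.make_atlas(small_config())
        vol = np.zeros_like(atlas.label_volume)
        nid = int(atlas.nucleus_ids[0])
        vox = np.argwhere(atlas.label_volume == nid)
        one = np.zeros_like(vol)
        one[tuple(vox[0])] = nid
        # shrink the first nucleus ROI to one voxel, keep the rest
        lv = atlas.label_volume.copy()
        lv[lv == nid] = 0
        lv[tuple(vox[0])] = nid
        small_atlas = cs.SyntheticAtlas(lv, atlas.region_table, atlas.affine)
        rngl = np.random.default_rng(0)
        data = rngl.uniform(0.2, 0.9, vol.shape)
        m = cs.GrayMatterMap("s1", data, atlas.affine)
        m2 = cs.GrayMatterMap("s2", data * 0.9, atlas.affine)
        tab = pd.DataFrame({"subject_id": ["s1", "s2"], "group": ["HC", "A"],
                            "sara": [0, 5], "cerebrum_volume": [1e6, 1e6]})
        df = cs.nucleus_roi_volumes([m, m2], tab, small_atlas)
        got = df[(df.subject_id == "s1") & (df.roi == df.roi.iloc[0])]
        roi_name = atlas.region_table.set_index("region_id").loc[nid, "name"]
        row = df[(df.subject_id == "s1") & (df.roi == roi_name)]
        assert abs(float(row.scaled_mean.iloc[0]) - data[tuple(vox[0])]) < 1e-12


class TestCorrelationMap:
    def _maps(self, X, mask_shape, mask):
        maps = []
        for i, row in enumerate(X):
            vol = np.zeros(mask_shape)
            vol[mask] = row
            maps.append(cs.GrayMatterMap(f"p{i:02d}", vol, np.eye(4)))
        return maps

    def test_perfectly_anticorrelated_voxel(self, rng):
        shape = (5, 5, 5)
        mask = np.zeros(shape, bool)
        mask[1:4, 1:4, 1:4] = True
        n = 8
        sara = np.linspace(2, 30, n)
        X = rng.uniform(0.2, 0.8, (n, mask.sum()))
        X[:, 0] = 1.0 - sara / 40.0               # intensity = -sara (affine)
        maps = self._maps(X, shape, mask)
        cmap = cs.correlation_map(maps, {m.subject_id: s for m, s in zip(maps, sara)},
                                  cs.MaskDefinition("atlas-cortical", mask))
        r0 = cmap.r[tuple(np.argwhere(mask)[0])]
        assert abs(r0 - (-1.0)) < 1e-12

    def test_vectorized_equals_loop_oracle(self, rng):
        shape = (10, 10, 10)
        mask = rng.random(shape) < 0.5
        n = 12
        X = rng.uniform(0.1, 0.9, (n, mask.sum()))
        sara = rng.uniform(0, 40, n)
        maps = self._maps(X, shape, mask)
        cmap = cs.correlation_map(maps, {m.subject_id: s for m, s in zip(maps, sara)},
                                  cs.MaskDefinition("atlas-cortical", mask))
        r_flat = cmap.r[mask]
        p_flat = cmap.p[mask]
        for j in range(0, mask.sum(), 37):        # spot-check every 37th voxel
            r, p = stats.pearsonr(X[:, j], sara)
            assert abs(r_flat[j] - r) < 1e-12
            assert abs(p_flat[j] - p) < 1e-12

    def test_permutation_calibration(self, rng):
        """With scores shuffled independently of the data, the fraction of
        significant voxels matches alpha (99% binomial interval)."""
        shape = (16, 16, 16)
        mask = np.ones(shape, bool)
        n = 20
        X = rng.standard_normal((n, mask.sum())) * 0.05 + 0.5
        sara = rng.uniform(0, 40, n)
        maps = self._maps(X, shape, mask)
        cmap = cs.correlation_map(maps, {m.subject_id: s for m, s in zip(maps, sara)},
                                  cs.MaskDefinition("atlas-cortical", mask),
                                  alpha=0.05)
        frac = cmap.significant.sum() / mask.sum()
        half = 2.58 * np.sqrt(0.05 * 0.95 / mask.sum())
        assert abs(frac - 0.05) < half

    def test_constant_voxels_dropped_and_counted(self, rng):
        shape = (4, 4, 4)
        mask = np.ones(shape, bool)
        n = 6
        X = rng.uniform(0.2, 0.8, (n, 64))
        X[:, 5] = 0.4                              # constant across subjects
        maps = self._maps(X, shape, mask)
        cmap = cs.correlation_map(maps, {m.subject_id: s for m, s in
                                         zip(maps, np.linspace(1, 30, n))},
                                  cs.MaskDefinition("atlas-cortical", mask))
        assert cmap.n_dropped_constant == 1
        assert np.isnan(cmap.r.ravel()[5])
        assert not cmap.significant.ravel()[5]

    def test_voxel_order_invariance(self, rng):
        """Permuting voxels (consistently across subjects) permutes the map."""
        shape = (6, 6, 6)
        mask = np.ones(shape, bool)
        n = 9
        X = rng.uniform(0.1, 0.9, (n, 216))
        sara = rng.uniform(0, 40, n)
        perm = rng.permutation(216)
        m1 = self._maps(X, shape, mask)
        m2 = self._maps(X[:, perm], shape, mask)
        md = cs.MaskDefinition("atlas-cortical", mask)
        c1 = cs.correlation_map(m1, {m.subject_id: s for m, s in zip(m1, sara)}, md)
        c2 = cs.correlation_map(m2, {m.subject_id: s for m, s in zip(m2, sara)}, md)
        assert np.allclose(c1.r[mask][perm], c2.r[mask], equal_nan=True)


def _bump(shape, center, width, height):
    ii = np.indices(shape).astype(float)
    d2 = sum((ii[k] - center[k]) ** 2 for k in range(3))
    return height * np.exp(-d2 / (2 * width ** 2))


class TestLocalMaxima:
    def _cmap_from_r(self, r_vol, affine=None):
        sig = np.abs(r_vol) > 0.05
        return cs.CorrelationMap(r_vol, np.where(sig, 0.01, 0.5), sig, 0.05,
                                 20, 0, affine if affine is not None else np.eye(4))

    def test_single_bump_single_peak(self):
        r = _bump((15, 15, 15), (7, 7, 7), 2.0, 0.8)
        peaks = cs.find_local_maxima(self._cmap_from_r(r), k=10)
        assert len(peaks) == 1
        assert tuple(peaks.peaks.iloc[0][["i", "j", "k"]]) == (7, 7, 7)

    def test_two_bumps_ordered_by_r(self):
        r = (_bump((20, 20, 20), (5, 5, 5), 1.5, 0.6)
             + _bump((20, 20, 20), (14, 14, 14), 1.5, 0.9))
        peaks = cs.find_local_maxima(self._cmap_from_r(r), k=10,
                                     min_separation_mm=4.0)
        assert len(peaks) == 2
        assert tuple(peaks.peaks.iloc[0][["i", "j", "k"]]) == (14, 14, 14)
        assert tuple(peaks.peaks.iloc[1][["i", "j", "k"]]) == (5, 5, 5)

    def test_min_separation_suppresses_nearby_peaks(self):
        r = (_bump((20, 20, 20), (8, 8, 8), 1.5, 0.9)
             + _bump((20, 20, 20), (11, 8, 8), 1.5, 0.6))
        peaks = cs.find_local_maxima(self._cmap_from_r(r), k=10,
                                     min_separation_mm=8.0)
        assert len(peaks) == 1

    def test_k_zero_and_empty_mask(self):
        r = _bump((10, 10, 10), (5, 5, 5), 2.0, 0.8)
        assert len(cs.find_local_maxima(self._cmap_from_r(r), k=0)) == 0
        empty = cs.CorrelationMap(r, np.full_like(r, 0.9),
                                  np.zeros_like(r, bool), 0.05, 20, 0, np.eye(4))
        assert len(cs.find_local_maxima(empty, k=10)) == 0


class TestSphereContrast:
    def _setup(self, n_focus=17, n_other=38, delta=0.05, seed=0):
        rng = np.random.default_rng(seed)
        shape = (12, 12, 12)
        mask = np.ones(shape, bool)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        peak_vox = (6, 6, 6)
        r_vol = _bump(shape, peak_vox, 2.0, 0.8)
        cmap = cs.CorrelationMap(r_vol, np.where(r_vol > 0.05, 0.01, 0.5),
                                 r_vol > 0.05, 0.05, 20, 0, affine)
        peaks = cs.find_local_maxima(cmap, k=1)
        md = cs.MaskDefinition("atlas-cortical", mask)
        world = (affine[:3, :3] @ np.argwhere(mask).T).T + affine[:3, 3]
        center = peaks.peaks.iloc[0][["x", "y", "z"]].to_numpy(float)
        inside = np.linalg.norm(world - center, axis=1) <= 6.0

        rows, deg = [], {}
        for i in range(n_focus + n_other):
            grp = "SCA3like" if i < n_focus else ("SCA2like" if i % 2 else "SCA7like")
            sid = f"p{i:03d}"
            v = rng.normal(0.1, 0.01, int(mask.sum()))
            if grp == "SCA3like":
                v[inside] += delta
            deg[sid] = v
            rows.append({"subject_id": sid, "group": grp, "sara": 10.0,
                         "cerebrum_volume": 1e6})
        return peaks, deg, md, affine, pd.DataFrame(rows), inside

    def test_df_bookkeeping_55_patients(self):
        peaks, deg, md, affine, tab, _ = self._setup()
        con = cs.sphere_contrast(peaks, deg, md, affine, tab, "SCA3like",
                                 radius_mm=6.0)
        assert len(tab) == 55
        assert con.df == 53

    def test_focus_shift_detected_with_positive_t(self):
        peaks, deg, md, affine, tab, _ = self._setup(delta=0.05)
        con = cs.sphere_contrast(peaks, deg, md, affine, tab, "SCA3like")
        assert float(con.table.t.iloc[0]) > 3.0

    def test_t_matches_pooled_variance_oracle(self):
        peaks, deg, md, affine, tab, inside = self._setup()
        con = cs.sphere_contrast(peaks, deg, md, affine, tab, "SCA3like")
        focus = [deg[s][inside].mean() for s in tab[tab.group == "SCA3like"].subject_id]
        other = [deg[s][inside].mean() for s in tab[tab.group != "SCA3like"].subject_id]
        n1, n2 = len(focus), len(other)
        sp2 = (((n1 - 1) * np.var(focus, ddof=1) + (n2 - 1) * np.var(other, ddof=1))
               / (n1 + n2 - 2))
        t_oracle = (np.mean(focus) - np.mean(other)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert abs(float(con.table.t.iloc[0]) - t_oracle) < 1e-10

    def test_per_pair_option(self):
        peaks, deg, md, affine, tab, _ = self._setup()
        con = cs.sphere_contrast(peaks, deg, md, affine, tab, "SCA3like",
                                 per_pair=True)
        assert {"t_vs_SCA2like", "t_vs_SCA7like"} <= set(con.table.columns)

    def test_unknown_focus_group(self):
        peaks, deg, md, affine, tab, _ = self._setup()
        with pytest.raises(CerebsigError):
            cs.sphere_contrast(peaks, deg, md, affine, tab, "nope")
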
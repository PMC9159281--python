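"""Merging, quality statistics, resolution cutoff, damage curves, absences."""

import math

import numpy as np
import pytest

from multimerge.merging import (
    apply_resolution_cutoff,
    damage_curves,
    detect_absences,
    estimate_resolution,
    merge,
    statistics,
    tanh_fit,
)
from multimerge.refl_model import (
    DatasetCollection,
    ExperimentMeta,
    ReflectionSet,
    SpaceGroupSetting,
    UnitCell,
)
from multimerge.synthetic import SimulationConfig, simulate

P1 = SpaceGroupSetting(symbol="P 1")


def _collection_from_obs(H, I, sig, img=None, n_split=2, cell=UnitCell(20, 20, 20)):
    """Split flat observation arrays into datasets round-robin."""
    H, I, sig = np.asarray(H), np.asarray(I, float), np.asarray(sig, float)
    img = np.ones(len(I), dtype=int) if img is None else np.asarray(img, int)
    refls, metas = [], []
    for i in range(n_split):
        sel = np.arange(len(I)) % n_split == i
        refls.append(ReflectionSet(i, H[sel], I[sel], sig[sel], img[sel]))
        metas.append(ExperimentMeta(dataset_id=i, cell=cell, orientation=np.eye(3)))
    return DatasetCollection(refls, metas)


class TestMerge:
    def test_equal_observations_weighted_mean(self):
        coll = _collection_from_obs([[1, 2, 3]] * 2, [10.0, 10.0], [1.0, 1.0])
        m = merge(coll, P1)
        assert m.intensity[0] == pytest.approx(10.0)
        assert m.sigma[0] == pytest.approx(1.0 / math.sqrt(2))
        assert m.multiplicity[0] == 2

    def test_unequal_weights_oracle(self):
        # (8, sigma 1) and (12, sigma 2): weighted mean = (8*1 + 12*0.25)/1.25
        coll = _collection_from_obs([[1, 2, 3]] * 2, [8.0, 12.0], [1.0, 2.0])
        m = merge(coll, P1)
        assert m.intensity[0] == pytest.approx(8.8)

    def test_singleton_passes_through(self):
        coll = _collection_from_obs([[1, 2, 3], [2, 3, 4]], [5.0, 7.0], [0.5, 0.7])
        m = merge(coll, P1)
        order = np.argsort(m.intensity)
        assert np.allclose(m.intensity[order], [5.0, 7.0])
        assert np.allclose(m.sigma[order], [0.5, 0.7])
        assert np.all(m.multiplicity == 1)


class TestStatistics:
    def test_duplicate_noise_free_data_perfect_scores(self):
        rng = np.random.default_rng(0)
        H = np.column_stack([rng.integers(1, 9, 60), rng.integers(1, 9, 60), rng.integers(1, 9, 60)])
        H = np.unique(H, axis=0)
        I = rng.exponential(10.0, len(H))
        H2 = np.vstack([H, H])
        I2 = np.concatenate([I, I])
        coll = _collection_from_obs(H2, I2, np.full(len(I2), 0.1))
        st = statistics(coll, P1, n_bins=5)
        assert st.overall.r_merge == pytest.approx(0.0, abs=1e-12)
        assert st.overall.cc_half == pytest.approx(1.0)
        assert st.overall.multiplicity == pytest.approx(2.0)

    def test_hand_worked_r_factor_sums(self):
        # two groups of three observations
        H = [[1, 2, 3]] * 3 + [[2, 3, 4]] * 3
        I = [9.0, 10.0, 11.0, 18.0, 20.0, 22.0]
        coll = _collection_from_obs(H, I, np.ones(6), n_split=3)
        st = statistics(coll, P1, n_bins=1)
        # group means 10 and 20; |dev| sums 2 and 4; denominator 90
        r_merge = (2 + 4) / 90
        r_meas = math.sqrt(3 / 2) * (2 + 4) / 90
        r_pim = math.sqrt(1 / 2) * (2 + 4) / 90
        assert st.overall.r_merge == pytest.approx(r_merge)
        assert st.overall.r_meas == pytest.approx(r_meas)
        assert st.overall.r_pim == pytest.approx(r_pim)

    def test_r_factor_multiplicity_identities(self):
        # single group of n: R_meas/R_merge = sqrt(n/(n-1)), exactly
        for n in (2, 3, 5, 8):
            H = [[1, 2, 3]] * n
            I = list(10.0 + np.arange(n))
            coll = _collection_from_obs(H, I, np.ones(n), n_split=min(n, 3))
            st = statistics(coll, P1, n_bins=1)
            assert st.overall.r_meas / st.overall.r_merge == pytest.approx(
                math.sqrt(n / (n - 1)), abs=1e-12
            )
            assert st.overall.r_pim / st.overall.r_merge == pytest.approx(
                math.sqrt(1 / (n - 1)), abs=1e-12
            )

    def test_complete_synthetic_set_full_completeness(self):
        cfg = SimulationConfig(
            space_group="P 41 21 2", d_min=3.5, n_datasets=8, noise=None,
            scale_range=(1, 1), b_range=(0, 0), sampling="random", multiplicity=10.0,
            seed=1,
        )
        coll, _ = simulate(cfg)
        group = SpaceGroupSetting.from_symbol("P 41 21 2")
        st = statistics(coll, group)
        assert st.overall.completeness == pytest.approx(100.0, abs=0.5)

    def test_all_singletons_give_undefined_r_factors(self):
        coll = _collection_from_obs([[1, 2, 3], [2, 3, 4]], [5.0, 7.0], [0.5, 0.7])
        st = statistics(coll, P1, n_bins=1)
        assert st.overall.r_merge is None
        assert st.overall.cc_half is None

    def test_cc_half_decreases_with_noise(self):
        group = SpaceGroupSetting.from_symbol("P 41 21 2")
        ccs = []
        for noise in (50.0, 5.0, 1.0):
            vals = []
            for seed in range(3):
                cfg = SimulationConfig(
                    space_group="P 41 21 2", d_min=3.5, n_datasets=6, noise=noise,
                    scale_range=(1, 1), b_range=(0, 0), sampling="random",
                    multiplicity=6.0, seed=seed,
                )
                coll, _ = simulate(cfg)
                vals.append(statistics(coll, group).overall.cc_half)
            ccs.append(np.mean(vals))
        assert ccs[0] > ccs[1] > ccs[2]


@pytest.fixture(scope="module")
def group():
    return SpaceGroupSetting.from_symbol("P 41 21 2")


class TestResolutionEstimate:
    def _decaying(self, seed=4):
        cfg = SimulationConfig(
            space_group="P 41 21 2", d_min=1.8, n_datasets=10, noise=0.25,
            noise_model="flat", wilson_b=35.0, scale_range=(1, 1), b_range=(0, 0),
            sampling="random", multiplicity=10.0, seed=seed,
        )
        return simulate(cfg)[0]

    def test_high_cc_everywhere_returns_data_edge(self, group):
        cfg = SimulationConfig(
            space_group="P 41 21 2", d_min=3.0, n_datasets=8, noise=50.0,
            scale_range=(1, 1), b_range=(0, 0), sampling="random", multiplicity=8.0,
            seed=5,
        )
        coll, _ = simulate(cfg)
        d = estimate_resolution(coll, group)
        assert d == pytest.approx(statistics(coll, group).overall.d_min, abs=0.01)

    def test_tanh_generate_and_recover(self):
        # oracle: sample a known tanh curve, fit, recover the crossing
        c0, s0, r = 0.95, 0.35, 0.08
        s = np.linspace(0.1, 0.55, 20)
        cc = 0.5 * c0 * (1 - np.tanh((s - s0) / r))
        fit_c0, fit_s0, fit_r = tanh_fit(s, cc)
        assert fit_s0 == pytest.approx(s0, abs=1e-6)
        s_cross_true = s0 + r * np.arctanh(1 - 2 * 0.3 / c0)
        s_cross_fit = fit_s0 + fit_r * np.arctanh(1 - 2 * 0.3 / fit_c0)
        assert s_cross_fit == pytest.approx(s_cross_true, abs=1e-6)

    def test_crossing_recovered_within_one_bin(self, group):
        coll = self._decaying()
        st = statistics(coll, group)
        d_est = estimate_resolution(coll, group, cc_cutoff=0.3)
        # locate the bins bracketing CC = 0.3
        cc = np.array([b.cc_half for b in st.bins])
        below = np.flatnonzero(cc < 0.3)
        hi = st.bins[below[0] - 1].d_max if below.size else st.overall.d_min
        lo = st.bins[min(below[0], len(st.bins) - 1)].d_min if below.size else st.overall.d_min
        width = st.bins[-1].d_max - st.bins[-1].d_min
        assert lo - abs(width) <= d_est <= hi + abs(width)

    def test_stricter_cutoff_never_extends_resolution(self, group):
        coll = self._decaying()
        d3 = estimate_resolution(coll, group, cc_cutoff=0.3)
        d5 = estimate_resolution(coll, group, cc_cutoff=0.5)
        assert d5 >= d3 - 1e-9

    def test_invariant_to_uniform_rescaling(self, group):
        coll = self._decaying()
        boosted = [r.copy() for r in coll.reflection_sets]
        for r in boosted:
            r.intensity = r.intensity * 100.0
            r.sigma = r.sigma * 100.0
        coll2 = DatasetCollection(boosted, list(coll.metas))
        assert estimate_resolution(coll, group) == pytest.approx(
            estimate_resolution(coll2, group), rel=1e-9
        )


class TestDamageCurves:
    def _sim(self, damage, seed):
        cfg = SimulationConfig(
            space_group="P 41 21 2", d_min=3.0, n_datasets=8, noise=20.0,
            scale_range=(1, 1), b_range=(0, 0), damage_b_per_image=damage,
            sampling="random", multiplicity=8.0, seed=seed,
        )
        return simulate(cfg)[0]

    def test_damage_raises_rcp_over_null_spread(self, group):
        null_deltas, damaged_deltas = [], []
        for seed in range(5):
            r0 = damage_curves(self._sim(0.0, seed), group).r_cp
            r1 = damage_curves(self._sim(2.0, seed), group).r_cp
            null_deltas.append(r0[-1] - r0[0])
            damaged_deltas.append(r1[-1] - r1[0])
        spread = 2 * np.std(null_deltas) + 1e-6
        assert np.mean(damaged_deltas) > np.mean(null_deltas) + spread

    def test_rcp_scale_invariant(self, group):
        coll = self._sim(1.0, 11)
        r1 = damage_curves(coll, group).r_cp
        doubled = [r.copy() for r in coll.reflection_sets]
        for r in doubled:
            r.intensity = r.intensity * 2.0
            r.sigma = r.sigma * 2.0
        r2 = damage_curves(DatasetCollection(doubled, list(coll.metas)), group).r_cp
        assert np.allclose(r1, r2, equal_nan=True)

    def test_single_image_gives_empty_curve(self, group):
        coll = self._sim(0.0, 12)
        squashed = [r.copy() for r in coll.reflection_sets]
        for r in squashed:
            r.image_number = np.ones_like(r.image_number)
        curves = damage_curves(DatasetCollection(squashed, list(coll.metas)), group)
        assert curves.r_cp.size == 0

    def test_completeness_vs_dose_consistency(self, group):
        coll = self._sim(0.0, 13)
        curves = damage_curves(coll, group)
        st = statistics(coll, group)
        assert curves.completeness_vs_dose[-1] == pytest.approx(
            st.overall.completeness, abs=0.2
        )
        assert np.all(np.diff(curves.completeness_vs_dose) >= -1e-9)

    def test_truncating_images_never_raises_completeness(self, group):
        coll = self._sim(0.0, 14)
        full = damage_curves(coll, group).completeness_vs_dose
        half_max = int(np.max([r.image_number.max() for r in coll.reflection_sets]) // 2)
        cut = [r.select(r.image_number <= half_max) for r in coll.reflection_sets]
        short = damage_curves(DatasetCollection(cut, list(coll.metas)), group)
        for j, v in zip(short.image, short.completeness_vs_dose):
            assert v <= full[j - 1] + 1e-9


class TestAbsences:
    @pytest.mark.parametrize("seed", range(3))
    def test_p21_screw_detected(self, seed):
        pat = SpaceGroupSetting.from_symbol("P 1 2/m 1")
        cfg = SimulationConfig(
            space_group="P 1 21 1", cell=(45.2, 54.7, 116.5, 90, 100.4, 90),
            d_min=4.0, n_datasets=8, noise=15.0, sampling="random",
            multiplicity=8.0, seed=seed,
        )
        coll, _ = simulate(cfg)
        scores, sg = detect_absences(merge(coll, pat), pat)
        assert sg == "P 1 21 1"

    @pytest.mark.parametrize("seed", range(3))
    def test_p2_screw_rejected(self, seed):
        pat = SpaceGroupSetting.from_symbol("P 1 2/m 1")
        cfg = SimulationConfig(
            space_group="P 1 2 1", cell=(45.2, 54.7, 116.5, 90, 100.4, 90),
            d_min=4.0, n_datasets=8, noise=15.0, sampling="random",
            multiplicity=8.0, seed=seed,
        )
        coll, _ = simulate(cfg)
        scores, sg = detect_absences(merge(coll, pat), pat)
        assert sg == "P 1 2 1"
        twofold = [s for s in scores if s.screw_symbol == "2(1)"]
        assert twofold and twofold[0].likelihood < 0.5

    def test_p41212_full_symbol(self):
        pat = SpaceGroupSetting.from_symbol("P 41 21 2")
        cfg = SimulationConfig(
            space_group="P 41 21 2", d_min=3.0, n_datasets=10, noise=15.0,
            sampling="random", multiplicity=10.0, seed=3,
        )
        coll, _ = simulate(cfg)
        scores, sg = detect_absences(merge(coll, pat), pat)
        assert sg == "P 41 21 2"

    def test_no_screw_candidates_returns_symmorphic_group(self):
        group = SpaceGroupSetting.from_symbol("P 1")
        coll = _collection_from_obs([[1, 2, 3], [2, 3, 4]], [5.0, 7.0], [1.0, 1.0])
        scores, sg = detect_absences(merge(coll, group), group)
        assert scores == []
        assert sg == "P 1"

    def test_unmeasured_axis_gives_uninformative_likelihood(self):
        pat = SpaceGroupSetting.from_symbol("P 1 2/m 1")
        # no (0, k, 0) reflections present at all
        coll = _collection_from_obs(
            [[1, 2, 3], [2, 3, 4], [1, 1, 1], [3, 1, 2]],
            [5.0, 7.0, 4.0, 6.0],
            [1.0, 1.0, 1.0, 1.0],
        )
        scores, _ = detect_absences(merge(coll, pat), pat)
        assert scores[0].likelihood == 0.5
        assert scores[0].z_score is None


class TestResolutionCutoffApplication:
    def test_cutoff_removes_only_high_resolution_data(self):
        cfg = SimulationConfig(
            space_group="P 41 21 2", d_min=2.5, n_datasets=4, noise=20.0,
            sampling="random", multiplicity=6.0, seed=6,
        )
        coll, _ = simulate(cfg)
        cut = apply_resolution_cutoff(coll, 3.0)
        from multimerge.refl_model import d_spacings

        for refl in cut.reflection_sets:
            cell = cut.meta(refl.dataset_id).cell
            assert d_spacings(refl.indices, cell).min() >= 3.0 - 1e-6
        assert cut.total_observations() < coll.total_observations()
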
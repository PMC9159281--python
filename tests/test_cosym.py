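"""Correlation-embedding symmetry analysis and non-isomorphism mode."""

import math

import numpy as np
import pytest
import scipy.integrate

from multimerge import cosym
from multimerge.cosym import (
    CosymEmbedding,
    RijMatrix,
    analyse_symmetry,
    assign_reindex,
    compute_rij,
    cosym_nonisomorphism,
    elbow_point,
    element_likelihood,
    minimize_embedding,
    score_elements,
    score_subgroups,
    select_dimensions,
    _trunc_lorentzian_pdf,
)
from multimerge.refl_model import (
    DatasetCollection,
    ExperimentMeta,
    ReflectionSet,
    SpaceGroupSetting,
    SymmetryOperation,
    UnitCell,
)
from multimerge.synthetic import SimulationConfig, simulate


def _two_dataset_collection(I1, I2, H=None):
    H = np.array(H) if H is not None else np.array([[1, 2, 3], [2, 3, 4], [1, 3, 5], [2, 4, 6], [3, 4, 5]])
    refls = []
    for i, I in enumerate((I1, I2)):
        refls.append(
            ReflectionSet(
                dataset_id=i,
                indices=H[: len(I)],
                intensity=np.asarray(I, dtype=float),
                sigma=np.ones(len(I)),
                image_number=np.ones(len(I), dtype=int),
            )
        )
    metas = [
        ExperimentMeta(dataset_id=i, cell=UnitCell(20, 20, 20), orientation=np.eye(3))
        for i in range(2)
    ]
    return DatasetCollection(refls, metas)


class TestComputeRij:
    def test_self_correlation_is_one(self):
        coll = _two_dataset_collection([10, 20, 30, 40, 50], [11, 19, 33, 38, 52])
        rij = compute_rij(coll, SpaceGroupSetting(symbol="P 1"), min_common=3)
        assert rij.values[0, 0] == 1.0
        assert np.allclose(rij.values, rij.values.T)

    def test_too_few_common_reflections_gives_zero(self):
        # datasets share only 2 reflections
        H1 = [[1, 2, 3], [2, 3, 4], [5, 6, 7]]
        H2 = [[1, 2, 3], [2, 3, 4], [8, 9, 10]]
        refls = [
            ReflectionSet(0, np.array(H1), np.array([1.0, 2, 3]), np.ones(3), np.ones(3, int)),
            ReflectionSet(1, np.array(H2), np.array([1.0, 2, 3]), np.ones(3), np.ones(3, int)),
        ]
        metas = [
            ExperimentMeta(dataset_id=i, cell=UnitCell(20, 20, 20), orientation=np.eye(3))
            for i in range(2)
        ]
        coll = DatasetCollection(refls, metas)
        rij = compute_rij(coll, SpaceGroupSetting(symbol="P 1"), min_common=3)
        assert rij.values[0, 1] == 0.0
        rij2 = compute_rij(coll, SpaceGroupSetting(symbol="P 1"), min_common=2)
        assert rij2.values[0, 1] != 0.0

    def test_matches_brute_force_pearson_oracle(self):
        # 2 datasets x 2 ops, shared general-position reflections with
        # hand-listed intensities; compare every entry to a direct Pearson
        rng = np.random.default_rng(3)
        H = np.array([[1, 2, 3], [2, 3, 5], [1, 3, 4], [3, 4, 6], [2, 5, 7], [1, 4, 6]])
        I1 = np.array([5.0, 1.0, 3.0, 7.0, 2.0, 4.0])
        I2 = np.array([5.5, 0.8, 3.3, 6.5, 2.2, 3.9])
        op = SymmetryOperation.from_matrix([[-1, 0, 0], [0, -1, 0], [0, 0, 1]])
        lattice = SpaceGroupSetting(
            symbol="P 2/m", operations=[SymmetryOperation.identity(), op]
        )
        coll = _two_dataset_collection(I1, I2, H=H)
        rij = compute_rij(coll, lattice, min_common=3)

        norm = cosym.normalized_datasets(coll)
        from multimerge.refl_model import decode_hkl, encode_hkl

        def copy_vals(i, k):
            codes, vals = norm[i]
            hkl = decode_hkl(codes)
            R = lattice.rotations()[k].rot_array
            keys = cosym._friedel_codes(hkl @ R)
            return dict(zip(keys.tolist(), vals))

        ops = lattice.rotations()
        # general-position filter of the implementation
        for a in range(4):
            for b in range(4):
                if a == b:
                    continue
                i, k = divmod(a, 2)
                j, l = divmod(b, 2)
                va, vb = copy_vals(i, k), copy_vals(j, l)
                common = sorted(set(va) & set(vb))
                rel = ops[k].inverse() * ops[l]
                keep = []
                for c in common:
                    g = decode_hkl(np.array([c]))[0]
                    fixed = False
                    for opx in ops:
                        if opx.is_identity:
                            continue
                        img = g @ opx.rot_array
                        if max(
                            cosym._friedel_codes(np.array([img]))[0],
                            0,
                        ) == cosym._friedel_codes(np.array([g]))[0]:
                            fixed = True
                    if not fixed:
                        keep.append(c)
                if len(keep) < 3:
                    expected = 0.0
                else:
                    x = [va[c] for c in keep]
                    y = [vb[c] for c in keep]
                    expected = float(np.corrcoef(x, y)[0, 1])
                assert rij.values[a, b] == pytest.approx(expected, abs=1e-9)


class TestMinimizeEmbedding:
    def _rij(self, values):
        v = np.asarray(values, dtype=float)
        return RijMatrix(values=v, counts=np.full_like(v, 100, dtype=int), n=v.shape[0], m=1)

    def test_perfect_correlation_collapses_to_one_cluster(self):
        rij = self._rij(np.ones((4, 4)))
        emb = minimize_embedding(rij, 2, seed=1)
        assert emb.functional_value < 1e-6
        cos = emb.cos_angle_matrix()
        assert np.all(cos > 0.999)

    def test_two_cluster_structure_recovered(self):
        r = np.full((4, 4), 0.0)
        r[:2, :2] = 0.9
        r[2:, 2:] = 0.9
        np.fill_diagonal(r, 1.0)
        rij = self._rij(r)
        emb = minimize_embedding(rij, 2, seed=1)
        cos = emb.cos_angle_matrix()
        assert cos[0, 1] > 0.95 and cos[2, 3] > 0.95
        assert abs(cos[0, 2]) < 0.2
        # functional matches a multi-restart brute-force minimum
        best = min(
            minimize_embedding(rij, 2, seed=s).functional_value for s in range(12)
        )
        assert emb.functional_value == pytest.approx(best, abs=1e-4)

    def test_same_seed_is_deterministic(self):
        r = np.full((4, 4), 0.5)
        np.fill_diagonal(r, 1.0)
        rij = self._rij(r)
        a = minimize_embedding(rij, 2, seed=5)
        b = minimize_embedding(rij, 2, seed=5)
        assert np.array_equal(a.coords, b.coords)
        c = minimize_embedding(rij, 2, seed=6)
        assert a.functional_value == pytest.approx(c.functional_value, abs=1e-6)

    def test_invalid_dimension_rejected(self):
        rij = self._rij(np.eye(3))
        with pytest.raises(ValueError):
            minimize_embedding(rij, 1)


class TestSelectDimensions:
    def test_elbow_oracle(self):
        # brute-force elbow on a synthetic curve with a sharp corner at 3
        curve = [(2, 10.0), (3, 1.0), (4, 0.9), (5, 0.8), (6, 0.7)]
        pts = np.array(curve, dtype=float)
        x = (pts[:, 0] - 2) / 4.0
        y = (pts[:, 1] - 10.0) / 10.0
        vx, vy = x[-1] - x[0], y[-1] - y[0]
        n = math.hypot(vx, vy)
        dist = np.abs(vx * (y[0] - y) - (x[0] - x) * vy) / n
        assert elbow_point(curve) == int(pts[np.argmax(dist), 0]) == 3

    def test_flat_curve_returns_minimum_dimension(self):
        assert elbow_point([(2, 5.0), (3, 4.8), (4, 4.6), (5, 4.4)]) == 2

    def test_m_equals_two_short_circuits(self):
        r = np.eye(4)
        rij = RijMatrix(values=r, counts=np.full((4, 4), 10), n=2, m=2)
        d, curve = select_dimensions(rij, max_dim=2)
        assert d == 2


class TestElementScoring:
    def test_densities_integrate_to_one(self):
        for centre in (0.0, 1.0):
            val, _ = scipy.integrate.quad(
                lambda cc: _trunc_lorentzian_pdf(cc, centre), -1, 1
            )
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_likelihood_limits(self):
        assert element_likelihood(1.0) > 0.9
        assert element_likelihood(0.0) < 0.1
        assert 0.0 < element_likelihood(0.5) < 1.0

    def test_parallel_copies_score_operation_present(self):
        # two datasets, twofold lattice; copies coincide -> cc = 1
        op = SymmetryOperation.from_matrix([[-1, 0, 0], [0, -1, 0], [0, 0, 1]])
        lattice = SpaceGroupSetting(
            symbol="P 2/m", operations=[SymmetryOperation.identity(), op]
        )
        coords = np.array([[1.0, 0.0]] * 4)
        emb = CosymEmbedding(coords=coords, d=2, functional_value=0.0, seed=0, n=2, m=2)
        scores = score_elements(emb, lattice)
        assert len(scores) == 1
        assert scores[0].cc == pytest.approx(1.0)
        assert scores[0].likelihood > 0.9
        assert scores[0].z_cc == pytest.approx(10.0)

    def test_orthogonal_copies_score_operation_absent(self):
        op = SymmetryOperation.from_matrix([[-1, 0, 0], [0, -1, 0], [0, 0, 1]])
        lattice = SpaceGroupSetting(
            symbol="P 2/m", operations=[SymmetryOperation.identity(), op]
        )
        coords = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        emb = CosymEmbedding(coords=coords, d=2, functional_value=0.0, seed=0, n=2, m=2)
        scores = score_elements(emb, lattice)
        assert scores[0].cc == pytest.approx(0.0)
        assert scores[0].likelihood < 0.1


class TestSubgroupScoring:
    def _lattice_222(self):
        return SpaceGroupSetting(
            symbol="P m m m",
            operations=[
                SymmetryOperation.identity(),
                SymmetryOperation.from_matrix([[-1, 0, 0], [0, -1, 0], [0, 0, 1]]),
                SymmetryOperation.from_matrix([[-1, 0, 0], [0, 1, 0], [0, 0, -1]]),
                SymmetryOperation.from_matrix([[1, 0, 0], [0, -1, 0], [0, 0, -1]]),
            ],
        )

    def test_genuine_twofold_ranks_monoclinic_over_triclinic(self):
        from multimerge.cosym import ElementScore

        lattice = self._lattice_222()
        ops = lattice.rotations()
        scores = [
            ElementScore(ops[1], cc=1.0, z_cc=10.0, likelihood=0.95, n_pairs=10),
            ElementScore(ops[2], cc=0.0, z_cc=0.0, likelihood=0.05, n_pairs=10),
            ElementScore(ops[3], cc=0.0, z_cc=0.0, likelihood=0.05, n_pairs=10),
        ]
        sub = score_subgroups(scores, lattice)
        assert sub[0].patterson_group.order == 2  # the monoclinic choice
        triclinic = [s for s in sub if s.patterson_group.order == 1][0]
        assert sub[0].likelihood > triclinic.likelihood

    def test_posterior_sums_to_one(self):
        from multimerge.cosym import ElementScore

        lattice = self._lattice_222()
        ops = lattice.rotations()
        scores = [
            ElementScore(op, cc=0.4, z_cc=4.0, likelihood=0.5, n_pairs=5)
            for op in ops
            if not op.is_identity
        ]
        sub = score_subgroups(scores, lattice)
        assert sum(s.likelihood for s in sub) == pytest.approx(1.0, abs=1e-6)

    def test_all_subgroups_enumerated_for_222(self):
        sub = score_subgroups([], self._lattice_222())
        # 1, three C2s, and 222 itself
        assert sorted(s.patterson_group.order for s in sub) == [1, 2, 2, 2, 4]


class TestFullAnalysis:
    def test_single_dataset_is_an_error(self, clean_p41212_collection):
        coll, _ = clean_p41212_collection
        single = coll.subset([0])
        with pytest.raises(ValueError):
            analyse_symmetry(single)

    def test_clean_tetragonal_recovers_full_patterson_group(
        self, clean_p41212_collection
    ):
        coll, _ = clean_p41212_collection
        res = analyse_symmetry(coll)
        assert res.best_group.symbol == "P 4/m m m"
        assert all(op.is_identity for op in res.per_dataset_reindex)
        assert res.subgroup_scores[0].likelihood > 0.9

    def test_planted_ambiguity_resolved(self, ambiguous_p4_collection):
        coll, truth = ambiguous_p4_collection
        res = analyse_symmetry(coll)
        assert res.best_group.symbol == "P 4/m"
        tf = np.array([not op.is_identity for op in truth.reindex_ops])
        af = np.array([not op.is_identity for op in res.per_dataset_reindex])
        acc = max(np.mean(tf == af), np.mean(tf != af))  # global gauge freedom
        assert acc == 1.0

    def test_reindexing_improves_mean_pairwise_cc(self, ambiguous_p4_collection):
        from multimerge.clustering import pairwise_dataset_cc

        coll, _ = ambiguous_p4_collection
        res = analyse_symmetry(coll)
        before = pairwise_dataset_cc(coll, res.best_group)
        after = pairwise_dataset_cc(
            cosym.apply_reindex(coll, res.per_dataset_reindex), res.best_group
        )
        tri = np.triu_indices_from(before, 1)
        assert after[tri].mean() >= before[tri].mean()

    def test_functional_non_increasing_in_dimension(self, ambiguous_p4_collection):
        coll, _ = ambiguous_p4_collection
        res = analyse_symmetry(coll)
        vals = [f for _, f in res.dimension_curve]
        assert all(b <= a * 1.01 for a, b in zip(vals[:-1], vals[1:]))

    def test_rij_model_consistency(self, ambiguous_p4_collection):
        # |r_ab - |x_a||x_b| cos(angle)| should be small after minimisation
        coll, _ = ambiguous_p4_collection
        res = analyse_symmetry(coll)
        X = res.embedding.coords
        model = X @ X.T
        resid = np.abs(res.rij.values - model)
        tri = np.triu_indices_from(resid, 1)
        used = res.rij.counts[tri] >= res.rij.min_common
        assert np.median(resid[tri][used]) < 0.05


class TestNonIsomorphismMode:
    def test_homogeneous_data_gives_cos_angles_near_one(self, clean_p41212_collection):
        coll, _ = clean_p41212_collection
        group = SpaceGroupSetting.from_symbol("P 41 21 2")
        emb, cosmat = cosym_nonisomorphism(coll, group, seed=1)
        tri = np.triu_indices_from(cosmat, 1)
        assert np.mean(cosmat[tri] > 0.9) > 0.95

    def test_two_populations_separate(self):
        cfg = SimulationConfig(
            space_group="P 41 21 2",
            d_min=3.2,
            n_datasets=14,
            noise=15.0,
            n_populations=2,
            between_cc=0.7,
            sampling="random",
            multiplicity=10.0,
            seed=31,
        )
        coll, truth = simulate(cfg)
        group = SpaceGroupSetting.from_symbol("P 41 21 2")
        emb, cosmat = cosym_nonisomorphism(coll, group, seed=1)
        pop = truth.population
        same = cosmat[np.ix_(pop == 0, pop == 0)]
        cross = cosmat[np.ix_(pop == 0, pop == 1)]
        assert same[np.triu_indices_from(same, 1)].mean() > cross.mean()

    def test_noisier_dataset_has_shorter_vector(self):
        # same data, one dataset with doubled noise -> shorter |x|
        rng = np.random.default_rng(5)
        n_refl = 400
        H = np.column_stack(
            [rng.integers(1, 12, n_refl), rng.integers(1, 12, n_refl), rng.integers(1, 12, n_refl)]
        )
        true_I = rng.exponential(1.0, n_refl)
        refls, metas = [], []
        for i in range(6):
            noise_scale = 1.0 if i != 5 else 2.0
            I = true_I + rng.normal(0, 0.3 * noise_scale, n_refl)
            refls.append(
                ReflectionSet(i, H, I, np.full(n_refl, 0.3), np.ones(n_refl, int))
            )
            metas.append(
                ExperimentMeta(dataset_id=i, cell=UnitCell(20, 20, 20), orientation=np.eye(3))
            )
        coll = DatasetCollection(refls, metas)
        emb, _ = cosym_nonisomorphism(coll, SpaceGroupSetting(symbol="P 1"), seed=1)
        lengths = emb.lengths()
        assert lengths[5] < lengths[:5].min()
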
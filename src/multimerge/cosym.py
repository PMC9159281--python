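"""Symmetry analysis and indexing-ambiguity resolution by correlation
embedding.

Each data set is represented by m symmetry-related copies (one per operation
of the maximum lattice group).  The (n*m)^2 matrix of pairwise Pearson
correlations between copies is approximated by inner products of unit-ball
vectors x, obtained by L-BFGS minimisation of

    F(x) = sum_{a<b} (r_ab - x_a . x_b)^2 .

Genuine symmetry operations relate copies whose vectors are parallel
(cos-angle ~ 1); absent operations give near-orthogonal clusters.  Vector
lengths estimate each data set's signal (inversely related to its random
error), so the same machinery with m = 1 doubles as a non-isomorphism
analysis: angles between per-dataset vectors measure systematic differences.

Symmetry elements are scored with truncated-Lorentzian likelihood models and
combined over lattice subgroups to rank candidate Patterson groups; the
winning group then fixes a per-dataset re-indexing operation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .refl_model import (
    DatasetCollection,
    SpaceGroupSetting,
    SymmetryOperation,
    d_spacings,
    encode_hkl,
    map_to_asu,
    max_lattice_group,
)

logger = logging.getLogger(__name__)

LORENTZIAN_WIDTH = 0.1  # gamma = sigma(CC), lower-bounded width of CC scores


@dataclass
class RijMatrix:
    values: np.ndarray  # (n*m, n*m) in [-1, 1]
    counts: np.ndarray  # common-reflection counts
    n: int
    m: int
    min_common: int = 3


@dataclass
class CosymEmbedding:
    coords: np.ndarray  # (n*m, d)
    d: int
    functional_value: float
    seed: int
    n: int = 0
    m: int = 1
    converged: bool = True

    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.coords, axis=1)

    def cos_angle_matrix(self) -> np.ndarray:
        norms = self.lengths()
        safe = np.where(norms > 1e-12, norms, 1.0)
        unit = self.coords / safe[:, None]
        return np.clip(unit @ unit.T, -1.0, 1.0)


@dataclass
class ElementScore:
    operation: SymmetryOperation
    cc: float
    z_cc: float
    likelihood: float
    n_pairs: int = 0


@dataclass
class SubgroupScore:
    patterson_group: SpaceGroupSetting
    likelihood: float
    net_z: float
    z_plus: float
    z_minus: float
    delta: float
    reindex_op: SymmetryOperation


@dataclass
class SymmetryResult:
    element_scores: list
    subgroup_scores: list
    best_group: SpaceGroupSetting
    per_dataset_reindex: list
    embedding: CosymEmbedding = None
    rij: RijMatrix = None
    lattice: SpaceGroupSetting = None
    dimension_curve: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# intensity normalization

def normalized_datasets(collection: DatasetCollection, n_bins: int = 10):
    """Per-dataset quasi-E^2 normalization: I / <I> within resolution bins.

    Removes the Wilson falloff and per-dataset scale so that correlation
    coefficients reflect intensity correlation rather than common falloff.
    Returns per-dataset (indices, normalized intensity) with duplicate raw
    indices averaged.
    """
    out = []
    for refl in collection.reflection_sets:
        cell = collection.meta(refl.dataset_id).cell
        d = d_spacings(refl.indices, cell)
        s = 1.0 / d**2
        # a bin needs several reflections for a usable mean
        n_bins = max(1, min(n_bins, refl.n_obs // 5))
        edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
        edges[0] -= 1e-9
        edges[-1] += 1e-9
        which = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
        norm = np.ones_like(refl.intensity)
        for b in range(n_bins):
            sel = which == b
            if sel.any():
                mean = np.mean(refl.intensity[sel])
                norm[sel] = mean if mean > 0 else 1.0
        inorm = refl.intensity / norm
        # average duplicate observations of the same raw index
        codes = encode_hkl(refl.indices)
        uniq, inv = np.unique(codes, return_inverse=True)
        sums = np.bincount(inv, weights=inorm)
        cnts = np.bincount(inv)
        out.append((uniq, sums / cnts))
    return out


# ---------------------------------------------------------------------------
# the Rij matrix

def _friedel_codes(hkl: np.ndarray) -> np.ndarray:
    """Encode indices after merging Friedel mates (lexicographically greater)."""
    c_plus = encode_hkl(hkl)
    c_minus = encode_hkl(-np.asarray(hkl, dtype=int))
    return np.maximum(c_plus, c_minus)


def compute_rij(
    collection: DatasetCollection,
    lattice: SpaceGroupSetting,
    min_common: int = 3,
) -> RijMatrix:
    """Pairwise Pearson CCs between all symmetry copies of all data sets.

    Entry (ik, jl) correlates data set i re-indexed by operation k with data
    set j re-indexed by operation l over their common reflections (Friedel
    mates merged).  Pairs with fewer than ``min_common`` common reflections
    are assumed uncorrelated (r = 0), following the default of three.
    """
    if collection.n == 0:
        raise ValueError("empty collection")
    from .refl_model import decode_hkl

    ops = lattice.rotations()
    n, m = collection.n, len(ops)
    norm = normalized_datasets(collection)

    # union of all keys over datasets and ops -> dense (n*m, K) matrix
    key_arrays = []
    for (codes, vals) in norm:
        hkl = decode_hkl(codes)
        for op in ops:
            key_arrays.append(_friedel_codes(hkl @ op.rot_array))
    all_keys = np.unique(np.concatenate(key_arrays))
    K = all_keys.size
    Z = np.zeros((n * m, K))
    M = np.zeros((n * m, K))
    for i, (codes, vals) in enumerate(norm):
        hkl = decode_hkl(codes)
        for k, op in enumerate(ops):
            keys = _friedel_codes(hkl @ op.rot_array)
            # several raw indices can land on the same Friedel key: average
            uk, inv = np.unique(keys, return_inverse=True)
            v = np.bincount(inv, weights=vals) / np.bincount(inv)
            cols = np.searchsorted(all_keys, uk)
            row = i * m + k
            Z[row, cols] = v
            M[row, cols] = 1.0

    # Correlations are computed over general-position reflections only.
    # Reflections on special zones (fixed, up to Friedel, by some
    # non-identity lattice operation) match symmetry-equivalent copies of
    # themselves under any indexing choice, which inflates r between copies
    # that the embedding model treats as orthogonal; at small reflection
    # counts this washes out the cluster structure entirely.  When m = 1
    # (non-isomorphism mode) every reflection is general and nothing is
    # excluded.
    G = decode_hkl(all_keys)
    inv_ops = [op.inverse() for op in ops]
    rel_index = np.empty((m, m), dtype=int)
    rot_index = {op.rot: idx for idx, op in enumerate(ops)}
    for k in range(m):
        for l in range(m):
            rel_index[k, l] = rot_index[(inv_ops[k] * ops[l]).rot]
    base_codes = _friedel_codes(G)
    general = np.ones(K, dtype=bool)
    for op in ops:
        if not op.is_identity:
            general &= _friedel_codes(G @ op.rot_array) != base_codes
    keep_by_T = np.broadcast_to(general[None, :], (m, K))

    r = np.zeros((n * m, n * m))
    counts = np.zeros((n * m, n * m), dtype=int)
    cache = {}
    for t in range(m):
        key_t = keep_by_T[t].tobytes()
        if key_t in cache:
            rt, cnt = cache[key_t]
        else:
            keep = keep_by_T[t].astype(float)
            Mk = M * keep
            Zk = Z * keep
            cnt = Mk @ M.T  # = sum over kept columns of M_a M_b
            Sa = Zk @ M.T
            Sb = Mk @ Z.T
            Sab = Zk @ Z.T
            Saa = (Zk * Z) @ M.T
            Sbb = Mk @ (Z * Z).T
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = cnt * Sab - Sa * Sb
                var_a = cnt * Saa - Sa**2
                var_b = cnt * Sbb - Sb**2
                denom = np.sqrt(np.maximum(var_a, 0) * np.maximum(var_b, 0))
                rt = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
            cache[key_t] = (rt, cnt)
        sel = np.kron(np.ones((n, n), dtype=bool), rel_index == t)
        r[sel] = rt[sel]
        counts[sel] = cnt.astype(int)[sel]
    r[counts < min_common] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    counts = np.maximum(counts, counts.T)
    return RijMatrix(values=r, counts=counts, n=n, m=m, min_common=min_common)


# ---------------------------------------------------------------------------
# embedding

def minimize_embedding(rij: RijMatrix, d: int, seed: int = 42) -> CosymEmbedding:
    """Minimize F = sum_{a<b} (r_ab - x_a.x_b)^2 over (n*m) d-vectors."""
    nm = rij.values.shape[0]
    if not 2 <= d <= max(2, nm):
        raise ValueError(f"dimension must be in [2, {nm}]")
    r = rij.values
    rng = np.random.default_rng(seed)
    x0 = rng.random((nm, d))

    def fg(flat):
        X = flat.reshape(nm, d)
        E = r - X @ X.T
        np.fill_diagonal(E, 0.0)
        f = 0.5 * float(np.sum(E * E))
        g = -2.0 * E @ X
        # vector lengths estimate CC* <= 1; a hinge penalty on |x| > 1 also
        # lifts the degeneracy of the pair terms (dot products alone do not
        # pin down directions when norms may exceed 1)
        excess = np.maximum(0.0, np.sum(X * X, axis=1) - 1.0)
        f += float(np.sum(excess**2))
        g += 4.0 * excess[:, None] * X
        return f, g.ravel()

    res = scipy.optimize.minimize(
        fg,
        x0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 100, "gtol": 1e-5, "ftol": 1e-12},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        logger.warning("embedding minimization did not converge: %s", res.message)
    X = res.x.reshape(nm, d)
    return CosymEmbedding(
        coords=X,
        d=d,
        functional_value=float(res.fun),
        seed=seed,
        n=rij.n,
        m=rij.m,
        converged=bool(res.success),
    )


def select_dimensions(rij: RijMatrix, max_dim: int | None = None, seed: int = 42):
    """Choose the embedding dimension from the functional-vs-d elbow.

    Runs the minimisation for each d in 2..m and picks the point of maximum
    perpendicular distance from the chord joining the curve endpoints
    (axes normalised to [0, 1] first).  Returns (d, curve).
    """
    m = rij.m if max_dim is None else max_dim
    if m <= 2:
        emb = minimize_embedding(rij, 2, seed)
        return 2, [(2, emb.functional_value)]
    curve = []
    for d in range(2, m + 1):
        emb = minimize_embedding(rij, d, seed)
        curve.append((d, emb.functional_value))
    d = elbow_point(curve)
    return d, curve


def elbow_point(curve, min_salience: float = 0.1) -> int:
    """Max perpendicular distance from the chord between curve endpoints.

    The x axis is normalised to [0, 1] and the y axis to units of the
    initial functional value, so chord distance measures how sharply the
    curve bends relative to the misfit it started from.  Extra dimensions
    always absorb a little noise, giving a gently convex curve with no real
    elbow; a curve that stays within ``min_salience`` of its chord
    everywhere therefore has no meaningful elbow and the most parsimonious
    dimension -- the lower end of the range -- is returned.
    """
    pts = np.asarray(curve, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    xr = np.ptp(x) or 1.0
    yr = abs(y[0]) or 1.0
    xn, yn = (x - x[0]) / xr, (y - y[0]) / yr
    vx, vy = xn[-1] - xn[0], yn[-1] - yn[0]
    norm = math.hypot(vx, vy) or 1.0
    dist = np.abs(vx * (yn[0] - yn) - (xn[0] - xn) * vy) / norm
    if np.max(dist) < min_salience:
        return int(x[0])
    return int(x[int(np.argmax(dist))])


# ---------------------------------------------------------------------------
# scoring

def _trunc_lorentzian_pdf(cc: np.ndarray, centre: float, gamma: float = LORENTZIAN_WIDTH):
    """Lorentzian centred at ``centre``, truncated and normalised on [-1, 1]."""
    cc = np.asarray(cc, dtype=float)
    norm = gamma * (math.atan((1 - centre) / gamma) - math.atan((-1 - centre) / gamma))
    return (gamma**2 / ((cc - centre) ** 2 + gamma**2)) / norm


def element_likelihood(cc: float, p_prior: float = 0.5) -> float:
    """p(S | CC) with truncated-Lorentzian models centred at 1 (S) and 0 (!S)."""
    ps = float(_trunc_lorentzian_pdf(cc, 1.0)) * p_prior
    pn = float(_trunc_lorentzian_pdf(cc, 0.0)) * (1.0 - p_prior)
    return ps / (ps + pn)


def score_elements(embedding: CosymEmbedding, lattice: SpaceGroupSetting):
    """Score each non-identity lattice operation from mean cos-angles.

    For operation S the estimate of CC_S is the average cos-angle over all
    pairs of symmetry copies related by S (relative operation k2 o k1^-1).
    """
    ops = lattice.rotations()
    m = len(ops)
    n = embedding.n
    if m < 2:
        return []
    cosmat = embedding.cos_angle_matrix()
    rot_index = {op.rot: idx for idx, op in enumerate(ops)}
    inv = [ops[k].inverse() for k in range(m)]
    # rel[k1][k2] = relative operation between copies k1 and k2 (row-vector
    # hkl convention, matching compute_rij)
    rel = np.empty((m, m), dtype=int)
    for k1 in range(m):
        for k2 in range(m):
            rel[k1, k2] = rot_index[(inv[k1] * ops[k2]).rot]
    # Only copy pairs of the same data set are used: any (unknown) indexing
    # choice applied to a data set cancels in the relative operation between
    # its own copies, so the estimate is invariant to unresolved indexing
    # ambiguities.  Cross-dataset pairs would fold the ambiguity into every
    # element score.
    sums = np.zeros(m)
    cnts = np.zeros(m, dtype=int)
    for i in range(n):
        for k1 in range(m):
            a = i * m + k1
            for k2 in range(k1 + 1, m):
                b = i * m + k2
                for s in {rel[k1, k2], rel[k2, k1]}:
                    sums[s] += cosmat[a, b]
                    cnts[s] += 1
    scores = []
    for k, op in enumerate(ops):
        if op.is_identity:
            continue
        if cnts[k] == 0:
            scores.append(ElementScore(op, float("nan"), float("nan"), 0.5, 0))
            continue
        cc = float(sums[k] / cnts[k])
        scores.append(
            ElementScore(op, cc, 10.0 * cc, element_likelihood(cc), int(cnts[k]))
        )
    return scores


def _enumerate_subgroups(ops):
    """All subgroups of the (small) proper rotation group, as index frozensets."""
    m = len(ops)
    rot_index = {op.rot: i for i, op in enumerate(ops)}
    prod = [[rot_index[(ops[a] * ops[b]).rot] for b in range(m)] for a in range(m)]
    id_idx = next(i for i, op in enumerate(ops) if op.is_identity)

    def close(seed):
        cur = set(seed) | {id_idx}
        changed = True
        while changed:
            changed = False
            for a in list(cur):
                for b in list(cur):
                    c = prod[a][b]
                    if c not in cur:
                        cur.add(c)
                        changed = True
        return frozenset(cur)

    subgroups = {frozenset({id_idx})}
    # grow by repeatedly adjoining single generators (reaches every subgroup
    # of these small soluble groups)
    frontier = list(subgroups)
    while frontier:
        new_frontier = []
        for sg in frontier:
            for g in range(m):
                if g in sg:
                    continue
                cand = close(sg | {g})
                if cand not in subgroups:
                    subgroups.add(cand)
                    new_frontier.append(cand)
        frontier = new_frontier
    return sorted(subgroups, key=lambda s: (len(s), sorted(s)))


def score_subgroups(element_scores, lattice: SpaceGroupSetting):
    """Rank all Patterson subgroups of the lattice group.

    Each subgroup's likelihood multiplies, over all non-identity lattice
    operations, the density of the observed CC under "present" (centre 1)
    or "absent" (centre 0); the posterior is normalised over candidates.
    Zcc+/Zcc- are the mean z-scores of member/non-member elements.
    """
    ops = lattice.rotations()
    score_by_rot = {es.operation.rot: es for es in element_scores}
    subgroups = _enumerate_subgroups(ops)
    results = []
    logls = []
    for sg in subgroups:
        logl = 0.0
        z_in, z_out = [], []
        for i, op in enumerate(ops):
            if op.is_identity:
                continue
            es = score_by_rot.get(op.rot)
            if es is None or not np.isfinite(es.cc):
                continue
            if i in sg:
                logl += math.log(_trunc_lorentzian_pdf(es.cc, 1.0))
                z_in.append(es.z_cc)
            else:
                logl += math.log(_trunc_lorentzian_pdf(es.cc, 0.0))
                z_out.append(es.z_cc)
        logls.append(logl)
        member_ops = [ops[i] for i in sorted(sg)]
        setting = SpaceGroupSetting(
            symbol="", centring=lattice.centring, operations=member_ops
        )
        sgm = setting.gemmi_spacegroup(add_inversion=True)
        setting.symbol = (
            sgm.xhm() if sgm is not None else f"point group (order {len(member_ops)})"
        )
        delta = max((lattice.deltas.get(op, 0.0) for op in member_ops), default=0.0)
        results.append(
            SubgroupScore(
                patterson_group=setting,
                likelihood=0.0,
                net_z=(np.mean(z_in) if z_in else 0.0) - (np.mean(z_out) if z_out else 0.0),
                z_plus=float(np.mean(z_in)) if z_in else 0.0,
                z_minus=float(np.mean(z_out)) if z_out else 0.0,
                delta=float(delta),
                reindex_op=SymmetryOperation.identity(),
            )
        )
    logls = np.array(logls)
    post = np.exp(logls - logls.max())
    post /= post.sum()
    for r, p in zip(results, post):
        r.likelihood = float(p)
    results.sort(key=lambda r: (-r.likelihood, -r.patterson_group.order))
    return results


def coset_representatives(lattice: SpaceGroupSetting, subgroup: SpaceGroupSetting):
    """Right-coset representatives of the subgroup inside the lattice group."""
    sub_rots = {op.rot for op in subgroup.rotations()}
    reps = []
    covered = set()
    for op in lattice.rotations():
        if op.rot in covered:
            continue
        reps.append(op)
        for s in subgroup.rotations():
            covered.add((s * op).rot)
    return reps


def assign_reindex(
    embedding: CosymEmbedding,
    best_group: SpaceGroupSetting,
    lattice: SpaceGroupSetting,
):
    """Per-dataset re-indexing operation resolving the indexing ambiguity.

    A high-density coordinate is chosen as the cluster seed; for each data
    set the symmetry copy nearest the seed determines its re-indexing
    operation (reduced to a coset representative of the lattice group over
    the chosen Patterson group).
    """
    ops = lattice.rotations()
    m = len(ops)
    n = embedding.n
    X = embedding.coords
    # density = number of other points within 0.1 of each point (ties ->
    # larger vector wins, which prefers well-determined data sets)
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    density = np.sum(d2 < 0.1**2, axis=1)
    seed_idx = int(np.lexsort((np.linalg.norm(X, axis=1), density))[-1])
    seed = X[seed_idx]

    reps = coset_representatives(lattice, best_group)
    rep_of = {}
    for rep in reps:
        for s in best_group.rotations():
            rep_of[(s * rep).rot] = rep
    assignments = []
    for i in range(n):
        dists = [np.sum((X[i * m + k] - seed) ** 2) for k in range(m)]
        k_best = int(np.argmin(dists))
        assignments.append(rep_of[ops[k_best].rot])
    return assignments


def apply_reindex(collection: DatasetCollection, operations) -> DatasetCollection:
    """Return a collection with each data set's indices re-indexed."""
    new_sets = []
    for refl, op in zip(collection.reflection_sets, operations):
        new = refl.copy()
        new.indices = op.apply_hkl(refl.indices)
        new_sets.append(new)
    return DatasetCollection(new_sets, list(collection.metas))


def analyse_symmetry(
    collection: DatasetCollection,
    min_common: int = 3,
    seed: int = 42,
    dimensions: int | None = None,
    angular_tolerance: float = 5.0,
) -> SymmetryResult:
    """Full symmetry analysis: lattice group, embedding, Patterson group,
    and per-dataset re-indexing operations."""
    if collection.n < 2:
        raise ValueError("symmetry analysis requires at least 2 data sets")
    centring = collection.metas[0].centring
    lattice = max_lattice_group(collection.mean_cell(), centring, angular_tolerance)
    rij = compute_rij(collection, lattice, min_common)
    if dimensions is not None:
        d, curve = dimensions, []
    else:
        d, curve = select_dimensions(rij, seed=seed)
    embedding = minimize_embedding(rij, d, seed)
    element_scores = score_elements(embedding, lattice)
    subgroup_scores = score_subgroups(element_scores, lattice)
    best = subgroup_scores[0].patterson_group
    reindex = assign_reindex(embedding, best, lattice)
    return SymmetryResult(
        element_scores=element_scores,
        subgroup_scores=subgroup_scores,
        best_group=best,
        per_dataset_reindex=reindex,
        embedding=embedding,
        rij=rij,
        lattice=lattice,
        dimension_curve=curve,
    )


def cosym_nonisomorphism(
    collection: DatasetCollection,
    known_group: SpaceGroupSetting,
    seed: int = 42,
    dimensions: int | None = None,
    min_common: int = 3,
):
    """Non-isomorphism mode: no symmetry expansion (m = 1).

    Indices are first merged in the known Patterson group, so the n x n
    correlation matrix reflects only scale/systematic differences.  Returns
    (embedding, cos_angle_matrix); vector lengths estimate each data set's
    signal (inversely related to its random error).
    """
    mapped_sets = []
    for refl in collection.reflection_sets:
        new = refl.copy()
        new.indices = map_to_asu(refl.indices, known_group)
        mapped_sets.append(new)
    mapped = DatasetCollection(mapped_sets, list(collection.metas))
    identity_group = SpaceGroupSetting(symbol="P 1", centring="P")
    rij = compute_rij(mapped, identity_group, min_common)
    if dimensions is None:
        max_d = min(8, max(2, mapped.n - 1))
        d, _ = select_dimensions(rij, max_dim=max_d, seed=seed)
    else:
        d = dimensions
    embedding = minimize_embedding(rij, d, seed)
    return embedding, embedding.cos_angle_matrix()
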
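"""Unit-cell filtering, intensity-based hierarchical clustering and
delta-CC1/2 outlier-dataset rejection.

Three complementary views of non-isomorphism are provided:

* clustering on unit-cell parameters (preliminary filter for grossly
  non-isomorphous crystals),
* average-linkage clustering on pairwise intensity correlations
  (distance 1 - r) and on cosines of embedding-vector angles
  (distance 1 - cos),
* iterative whole-dataset rejection by the change in overall CC1/2 on
  leaving each data set out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .refl_model import (
    DatasetCollection,
    SpaceGroupSetting,
    d_spacings,
    encode_hkl,
    map_to_asu,
)
from . import merging

logger = logging.getLogger(__name__)

DELTA_CC_SIGMA_DEFAULT = 3.0
UNIT_CELL_GAP_RATIO = 5.0  # a merge counts as an outlier join above this jump
UNIT_CELL_GAP_FLOOR = 1.0  # ... and only beyond this absolute height (~1 A)


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix (n-1, 4)
    leaves: list  # dataset ids in input order
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, height: float) -> list:
        """Cluster membership (lists of dataset ids) at the given height."""
        labels = sch.fcluster(self.linkage, t=height, criterion="distance")
        out = {}
        for ds, lab in zip(self.leaves, labels):
            out.setdefault(lab, []).append(ds)
        return sorted(out.values(), key=len, reverse=True)


@dataclass
class ClusterInfo:
    dataset_ids: list
    height: float
    completeness: float | None = None
    multiplicity: float | None = None


@dataclass
class ClusterReport:
    clusters: list  # ClusterInfo per internal dendrogram node
    selected: list = field(default_factory=list)  # clusters meeting criteria
    criteria: dict = field(default_factory=dict)


def _cluster_metrics(collection: DatasetCollection, ids, group: SpaceGroupSetting):
    sub = collection.subset(ids)
    H = np.concatenate([r.indices for r in sub.reflection_sets])
    keys = encode_hkl(map_to_asu(H, group))
    uniq = np.unique(keys)
    cell = sub.mean_cell()
    d = d_spacings(H, cell)
    possible = merging.total_unique(cell, group, float(d.min()), float(d.max()))
    return 100.0 * uniq.size / possible.size, keys.size / uniq.size


def _dendrogram_clusters(Z: np.ndarray, leaves: list):
    """Member sets of every internal node, smallest merge height first."""
    n = len(leaves)
    members = {i: [leaves[i]] for i in range(n)}
    out = []
    for step, (a, b, h, _) in enumerate(Z):
        node = n + step
        members[node] = members[int(a)] + members[int(b)]
        out.append((sorted(members[node]), float(h)))
    return out


def unit_cell_cluster(metas, threshold: float | None = None):
    """Ward clustering on 6-vector cell representations; reject outliers.

    Cells are represented as (a, b, c, scaled angles) with angles in
    radians scaled by the mean cell edge, so a degree of angular deviation
    counts comparably to an Angstrom.  The default cut looks for a large
    gap in the sequence of merge heights: within-population merges sit at
    the measurement-noise level, so an outlier join shows up as a jump by
    more than ``UNIT_CELL_GAP_RATIO`` beyond an absolute floor.  Data sets
    outside the largest cluster at the cut are rejected.  Returns
    (dendrogram, retained ids, rejected ids, cell table).
    """
    if len(metas) < 2:
        return None, [m.dataset_id for m in metas], [], []
    ids = [m.dataset_id for m in metas]
    cells = np.array([m.cell.parameters for m in metas])
    edge_scale = np.mean(cells[:, :3])
    vecs = np.column_stack([cells[:, :3], np.radians(cells[:, 3:]) * edge_scale])
    Z = sch.linkage(vecs, method="ward")
    dendro = Dendrogram(linkage=Z, leaves=ids, method="ward")
    heights = np.sort(Z[:, 2])
    if threshold is None:
        threshold = np.inf
        for lo, hi in zip(heights[:-1], heights[1:]):
            if hi > UNIT_CELL_GAP_FLOOR and hi > UNIT_CELL_GAP_RATIO * max(lo, 1e-9):
                threshold = 0.5 * (lo + hi)
                break
    clusters = dendro.cut(threshold)
    retained = sorted(clusters[0])
    rejected = sorted(set(ids) - set(retained))
    if rejected:
        logger.info("unit-cell filter rejected data set(s) %s", rejected)
    return dendro, retained, rejected, cells


def pairwise_dataset_cc(collection: DatasetCollection, group: SpaceGroupSetting, min_common: int = 3):
    """n x n Pearson CC of ASU-merged intensities over common reflections."""
    n = collection.n
    merged = []
    for refl in collection.reflection_sets:
        keys = encode_hkl(map_to_asu(refl.indices, group))
        uniq, inv = np.unique(keys, return_inverse=True)
        vals = np.bincount(inv, weights=refl.intensity) / np.bincount(inv)
        merged.append((uniq, vals))
    r = np.eye(n)
    warned = False
    for i in range(n):
        ki, vi = merged[i]
        for j in range(i + 1, n):
            kj, vj = merged[j]
            common, ia, ib = np.intersect1d(ki, kj, return_indices=True)
            if common.size < max(2, min_common):
                if not warned:
                    logger.warning(
                        "dataset pair with < %d common reflections; CC taken as 0",
                        min_common,
                    )
                    warned = True
                continue
            a, b = vi[ia], vj[ib]
            va, vb = a.std(), b.std()
            if va > 0 and vb > 0:
                r[i, j] = r[j, i] = float(np.corrcoef(a, b)[0, 1])
    return r


def cc_cluster(
    collection: DatasetCollection,
    group: SpaceGroupSetting,
    min_completeness: float | None = None,
    min_multiplicity: float | None = None,
    max_clusters: int | None = None,
):
    """Average-linkage clustering on d = 1 - r between data sets."""
    r = pairwise_dataset_cc(collection, group)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    return _intensity_cluster(
        collection, group, dist, "cc", min_completeness, min_multiplicity, max_clusters
    )


def cos_angle_cluster(
    collection: DatasetCollection,
    group: SpaceGroupSetting,
    cos_angle_matrix: np.ndarray,
    min_completeness: float | None = None,
    min_multiplicity: float | None = None,
    max_clusters: int | None = None,
):
    """Average-linkage clustering on d = 1 - cos(angle(x_i, x_j))."""
    dist = 1.0 - cos_angle_matrix
    np.fill_diagonal(dist, 0.0)
    return _intensity_cluster(
        collection, group, dist, "cos-angle", min_completeness, min_multiplicity, max_clusters
    )


def _intensity_cluster(
    collection, group, dist, label, min_completeness, min_multiplicity, max_clusters
):
    ids = [r.dataset_id for r in collection.reflection_sets]
    dist = np.maximum(dist, 0.0)
    condensed = ssd.squareform((dist + dist.T) / 2.0, checks=False)
    Z = sch.linkage(condensed, method="average")
    dendro = Dendrogram(linkage=Z, leaves=ids, method="average")
    infos = []
    for members, h in _dendrogram_clusters(Z, ids):
        comp, mult = _cluster_metrics(collection, members, group)
        infos.append(
            ClusterInfo(dataset_ids=members, height=h, completeness=comp, multiplicity=mult)
        )
    infos.sort(key=lambda c: c.height)
    selected = [
        c
        for c in infos
        if (min_completeness is None or c.completeness >= min_completeness)
        and (min_multiplicity is None or c.multiplicity >= min_multiplicity)
    ]
    if max_clusters is not None:
        selected = selected[:max_clusters]
    report = ClusterReport(
        clusters=infos,
        selected=selected,
        criteria={
            "method": label,
            "min_completeness": min_completeness,
            "min_multiplicity": min_multiplicity,
            "max_clusters": max_clusters,
        },
    )
    return dendro, report


# ---------------------------------------------------------------------------
# delta-CC1/2 filtering

def overall_cc_half(collection: DatasetCollection, group: SpaceGroupSetting, exclude=None):
    """Overall CC1/2 via the seeded random half-set split."""
    sets = [
        r for r in collection.reflection_sets if exclude is None or r.dataset_id != exclude
    ]
    H = np.concatenate([r.indices for r in sets])
    I = np.concatenate([r.intensity for r in sets])
    keys = encode_hkl(map_to_asu(H, group))
    uniq, inv = np.unique(keys, return_inverse=True)
    rng = np.random.default_rng(merging.CC_HALF_SPLIT_SEED)
    cc, _ = merging._half_set_cc(I, inv, uniq.size, rng)
    return cc


@dataclass
class FilterCycle:
    cycle: int
    cc_overall: float
    delta_cc: dict  # dataset id -> delta CC1/2 on excluding it
    removed: list
    pct_reflections_removed: float


def delta_cc_half_filter(
    collection: DatasetCollection,
    group: SpaceGroupSetting,
    sigma_cutoff: float = DELTA_CC_SIGMA_DEFAULT,
    max_cycles: int = 6,
    rescale: bool = False,
):
    """Iterative whole-dataset rejection by delta-CC1/2.

    Per cycle: delta_i = CC1/2(without i) - CC1/2(all); values are
    standardised robustly (median / MAD, with a sample-std floor that guards
    the MAD estimate at the typical 10-100 dataset scale) and data sets
    whose standardised delta exceeds ``sigma_cutoff`` are removed, then the
    survivors are rescaled if requested.  Stops when no outliers remain,
    at ``max_cycles``, or rather than removing more than half of the data
    sets.  Returns (filtered collection, per-cycle log).
    """
    current = collection
    log = []
    n_start = collection.n
    total_obs = collection.total_observations()
    for cycle in range(1, max_cycles + 1):
        if current.n < 3:
            break
        cc_all = overall_cc_half(current, group)
        if cc_all is None:
            break
        deltas = {}
        for refl in current.reflection_sets:
            cc_wo = overall_cc_half(current, group, exclude=refl.dataset_id)
            deltas[refl.dataset_id] = (cc_wo if cc_wo is not None else cc_all) - cc_all
        vals = np.array(list(deltas.values()))
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        sigma = max(1.4826 * mad, float(np.std(vals)))
        if sigma <= 0:
            removed = []
        else:
            removed = [d for d, v in deltas.items() if (v - med) / sigma > sigma_cutoff]
        if current.n - len(removed) < max(3, n_start // 2):
            logger.warning("delta-CC1/2 filter would remove too many data sets; stopping")
            removed = []
        kept = [r.dataset_id for r in current.reflection_sets if r.dataset_id not in removed]
        pct = 100.0 * (
            sum(r.n_obs for r in current.reflection_sets if r.dataset_id in removed)
            / total_obs
        )
        log.append(
            FilterCycle(
                cycle=cycle,
                cc_overall=cc_all,
                delta_cc=deltas,
                removed=sorted(removed),
                pct_reflections_removed=pct,
            )
        )
        if not removed:
            break
        logger.info(
            "delta-CC1/2 cycle %d: removed %s (%.1f%% of reflections)",
            cycle,
            sorted(removed),
            pct,
        )
        current = current.subset(kept)
        if rescale:
            from .scaling import scale as _scale

            current = _scale(current, group).collection
    return current, log
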
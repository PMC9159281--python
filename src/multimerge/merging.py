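"""Merging of symmetry equivalents and data-quality statistics.

Covers inverse-variance-weighted merging, the standard unmerged agreement
statistics (R_merge, the multiplicity-corrected R_meas and the
precision-indicating R_pim), half-set correlations CC1/2 and CC_anom,
completeness and multiplicity overall and in resolution bins, the tanh-fit
resolution cutoff, cumulative radiation-damage indicators (R_cp, scale and
R_merge versus image number, completeness versus dose with image number as
the dose proxy), and screw-axis detection from systematic absences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .refl_model import (
    CENTRING_VECTORS,
    DatasetCollection,
    SpaceGroupSetting,
    UnitCell,
    d_spacings,
    decode_hkl,
    encode_hkl,
    map_to_asu,
)

logger = logging.getLogger(__name__)

N_BINS_DEFAULT = 20
CC_HALF_SPLIT_SEED = 20211215  # fixed seed for the random half-set split


@dataclass
class MergedSet:
    indices: np.ndarray  # unique ASU indices (n, 3)
    intensity: np.ndarray
    sigma: np.ndarray
    multiplicity: np.ndarray
    anomalous: bool = False
    # populated when anomalous merging is requested
    i_plus: np.ndarray | None = None
    sig_plus: np.ndarray | None = None
    n_plus: np.ndarray | None = None
    i_minus: np.ndarray | None = None
    sig_minus: np.ndarray | None = None
    n_minus: np.ndarray | None = None


@dataclass
class BinStats:
    d_max: float
    d_min: float
    n_unique: int
    completeness: float  # percent
    multiplicity: float
    r_merge: float | None
    r_meas: float | None
    r_pim: float | None
    cc_half: float | None
    cc_anom: float | None
    i_over_sigma: float | None


@dataclass
class MergeStatistics:
    overall: BinStats
    bins: list
    highest_shell: BinStats


@dataclass
class DamageCurves:
    image: np.ndarray
    scale_vs_image: np.ndarray
    r_merge_vs_image: np.ndarray
    r_cp: np.ndarray
    completeness_vs_dose: np.ndarray


@dataclass
class AbsenceScore:
    axis: str  # e.g. "2(1) [0 k 0]"
    screw_symbol: str
    n_absent_obs: int
    mean_i_over_sigma: float | None
    z_score: float | None
    likelihood: float  # probability the screw is present


def _gather(collection: DatasetCollection):
    H = np.concatenate([r.indices for r in collection.reflection_sets])
    I = np.concatenate([r.intensity for r in collection.reflection_sets])
    s = np.concatenate([r.sigma for r in collection.reflection_sets])
    img = np.concatenate([r.image_number for r in collection.reflection_sets])
    did = np.concatenate(
        [np.full(r.n_obs, r.dataset_id) for r in collection.reflection_sets]
    )
    return H, I, s, img, did


def _weighted_merge(keys, I, sig):
    uniq, inv = np.unique(keys, return_inverse=True)
    w = 1.0 / sig**2
    sw = np.bincount(inv, weights=w)
    swi = np.bincount(inv, weights=w * I)
    n = np.bincount(inv)
    return uniq, swi / sw, 1.0 / np.sqrt(sw), n, inv


def merge(
    collection: DatasetCollection, group: SpaceGroupSetting, anomalous: bool = False
) -> MergedSet:
    """Inverse-variance weighted mean per unique ASU reflection."""
    H, I, sig, _, _ = _gather(collection)
    asu = map_to_asu(H, group, anomalous=False)
    keys = encode_hkl(asu)
    uniq, Im, sm, n, _ = _weighted_merge(keys, I, sig)
    merged = MergedSet(
        indices=decode_hkl(uniq),
        intensity=Im,
        sigma=sm,
        multiplicity=n,
        anomalous=anomalous,
    )
    if anomalous:
        asu_a = map_to_asu(H, group, anomalous=True)
        plus = np.all(asu_a == asu, axis=1)  # canonical Friedel branch
        out = {}
        for sign, sel in (("plus", plus), ("minus", ~plus)):
            if sel.any():
                u2, I2, s2, n2, _ = _weighted_merge(keys[sel], I[sel], sig[sel])
                pos = np.searchsorted(uniq, u2)
                Iv = np.full(uniq.size, np.nan)
                sv = np.full(uniq.size, np.nan)
                nv = np.zeros(uniq.size, dtype=int)
                Iv[pos], sv[pos], nv[pos] = I2, s2, n2
            else:
                Iv = np.full(uniq.size, np.nan)
                sv = np.full(uniq.size, np.nan)
                nv = np.zeros(uniq.size, dtype=int)
            out[sign] = (Iv, sv, nv)
        merged.i_plus, merged.sig_plus, merged.n_plus = out["plus"]
        merged.i_minus, merged.sig_minus, merged.n_minus = out["minus"]
    return merged


def total_unique(cell: UnitCell, group: SpaceGroupSetting, d_min: float, d_max: float | None = None):
    """Encoded unique ASU indices theoretically measurable in [d_min, d_max]."""
    from .synthetic import full_sphere_indices  # shared index generator

    H = full_sphere_indices(cell, d_min, group.centring)
    if d_max is not None:
        d = d_spacings(H, cell)
        H = H[d <= d_max + 1e-9]
    return np.unique(encode_hkl(map_to_asu(H, group)))


def _r_factor_sums(I, inv, n_grp):
    """Per-observation |I - <I>_others-inclusive| sums for R factors.

    Returns (numerators for merge/meas/pim, denominator) restricted to
    groups with multiplicity >= 2.
    """
    n = np.bincount(inv, minlength=n_grp)
    mean = np.bincount(inv, weights=I, minlength=n_grp) / np.maximum(n, 1)
    multi = n[inv] >= 2
    dev = np.abs(I - mean[inv])
    nn = n[inv].astype(float)
    num_merge = dev[multi].sum()
    num_meas = (dev * np.sqrt(nn / np.maximum(nn - 1, 1)))[multi].sum()
    num_pim = (dev * np.sqrt(1.0 / np.maximum(nn - 1, 1)))[multi].sum()
    den = I[multi].sum()
    return num_merge, num_meas, num_pim, den, int(multi.sum())


def _half_set_cc(I, inv, n_grp, rng):
    """CC1/2 by a seeded random split of each group's observations."""
    order = np.argsort(inv, kind="stable")
    shuffled = order.copy()
    # random permutation within groups
    start = 0
    inv_sorted = inv[order]
    boundaries = np.flatnonzero(np.diff(inv_sorted)) + 1
    for seg in np.split(np.arange(order.size), boundaries):
        if seg.size > 1:
            shuffled[seg] = order[seg][rng.permutation(seg.size)]
    half = np.zeros(order.size, dtype=bool)
    # alternate assignment within each group
    pos_in_group = np.zeros(order.size, dtype=int)
    pos = np.arange(order.size)
    seg_starts = np.concatenate([[0], boundaries])
    for s, seg in zip(seg_starts, np.split(pos, boundaries)):
        pos_in_group[seg] = np.arange(seg.size)
    half[shuffled] = pos_in_group % 2 == 0

    def group_means(sel):
        cnt = np.bincount(inv[sel], minlength=n_grp)
        mean = np.bincount(inv[sel], weights=I[sel], minlength=n_grp) / np.maximum(cnt, 1)
        return mean, cnt

    m1, c1 = group_means(half)
    m2, c2 = group_means(~half)
    both = (c1 > 0) & (c2 > 0)
    if both.sum() < 3:
        return None, both
    cc = np.corrcoef(m1[both], m2[both])[0, 1]
    return float(cc), both


def _cc_anom(I, sig, inv_anom, plus, n_grp, rng):
    """Half-set correlation of anomalous differences I(+) - I(-)."""
    dI_half = []
    for h in range(2):
        sel = np.arange(I.size) % 2 == h  # deterministic alternating split
        dd = {}
        for sign, branch in (("p", plus), ("m", ~plus)):
            ss = sel & branch
            cnt = np.bincount(inv_anom[ss], minlength=n_grp)
            mean = np.bincount(inv_anom[ss], weights=I[ss], minlength=n_grp) / np.maximum(
                cnt, 1
            )
            dd[sign] = (mean, cnt)
        ok = (dd["p"][1] > 0) & (dd["m"][1] > 0)
        diff = np.where(ok, dd["p"][0] - dd["m"][0], np.nan)
        dI_half.append(diff)
    both = np.isfinite(dI_half[0]) & np.isfinite(dI_half[1])
    if both.sum() < 3:
        return None
    return float(np.corrcoef(dI_half[0][both], dI_half[1][both])[0, 1])


def statistics(
    collection: DatasetCollection,
    group: SpaceGroupSetting,
    n_bins: int = N_BINS_DEFAULT,
    d_min: float | None = None,
    anomalous: bool = False,
) -> MergeStatistics:
    """Overall and per-resolution-bin merging statistics.

    Bins are equal-volume in 1/d^3.  Completeness is measured against the
    full theoretically observable unique set of the Patterson group within
    the data's resolution range.  R factors and CCs are reported as None
    (undefined) when no group has multiplicity >= 2.
    """
    H, I, sig, _, _ = _gather(collection)
    cell = collection.mean_cell()
    d = d_spacings(H, cell)
    if d_min is not None:
        keep = d >= d_min - 1e-9
        H, I, sig, d = H[keep], I[keep], sig[keep], d[keep]
    asu = map_to_asu(H, group)
    keys = encode_hkl(asu)
    d_lo, d_hi = float(d.min()), float(d.max())
    s3 = 1.0 / d**3
    edges = np.linspace(1.0 / d_hi**3, 1.0 / d_lo**3, n_bins + 1)
    edges[-1] += 1e-12
    which = np.clip(np.searchsorted(edges, s3, side="right") - 1, 0, n_bins - 1)

    possible = total_unique(cell, group, d_lo, d_hi)
    d_possible = d_spacings(decode_hkl(possible), cell)
    s3_possible = 1.0 / d_possible**3
    which_possible = np.clip(
        np.searchsorted(edges, s3_possible, side="right") - 1, 0, n_bins - 1
    )

    rng = np.random.default_rng(CC_HALF_SPLIT_SEED)

    def stats_for(sel, sel_possible, d_max_bin, d_min_bin):
        kk = keys[sel]
        uniq, inv = np.unique(kk, return_inverse=True)
        n_grp = uniq.size
        n_obs = int(sel.sum())
        n_possible = int(sel_possible.sum())
        completeness = 100.0 * n_grp / n_possible if n_possible else 0.0
        mult = n_obs / n_grp if n_grp else 0.0
        nm, ns, npim, den, n_multi = _r_factor_sums(I[sel], inv, n_grp)
        if n_multi and den != 0:
            r_merge, r_meas, r_pim = nm / den, ns / den, npim / den
        else:
            r_merge = r_meas = r_pim = None
        cc_half, _ = _half_set_cc(I[sel], inv, n_grp, rng) if n_multi else (None, None)
        ccan = None
        if anomalous and n_obs:
            asu_a = map_to_asu(H[sel], group, anomalous=True)
            plus = np.all(asu_a == asu[sel], axis=1)
            ccan = _cc_anom(I[sel], sig[sel], inv, plus, n_grp, rng)
        ios = float(np.mean(I[sel] / sig[sel])) if n_obs else None
        return BinStats(
            d_max=d_max_bin,
            d_min=d_min_bin,
            n_unique=n_grp,
            completeness=completeness,
            multiplicity=mult,
            r_merge=r_merge,
            r_meas=r_meas,
            r_pim=r_pim,
            cc_half=cc_half,
            cc_anom=ccan,
            i_over_sigma=ios,
        )

    bins = []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        bins.append(
            stats_for(
                sel,
                which_possible == b,
                edges[b] ** (-1 / 3),
                edges[b + 1] ** (-1 / 3),
            )
        )
    overall = stats_for(np.ones(keys.size, dtype=bool), np.ones(possible.size, dtype=bool), d_hi, d_lo)
    return MergeStatistics(overall=overall, bins=bins, highest_shell=bins[-1] if bins else overall)


# ---------------------------------------------------------------------------
# resolution estimation

def tanh_fit(s, cc):
    """Fit CC(s) = c0/2 * (1 - tanh((s - s0)/r)); returns (c0, s0, r)."""
    s = np.asarray(s, dtype=float)
    cc = np.asarray(cc, dtype=float)
    half = 0.5 * cc.max()
    i0 = int(np.argmin(np.abs(cc - half)))
    p0 = [min(1.0, cc.max()), s[i0], max(1e-3, 0.2 * (s.max() - s.min()))]

    def model(s, c0, s0, r):
        return 0.5 * c0 * (1 - np.tanh((s - s0) / r))

    import warnings

    with warnings.catch_warnings():
        # near-flat curves (no falloff inside the data) have a degenerate
        # covariance; only the fitted values are used
        warnings.simplefilter("ignore", scipy.optimize.OptimizeWarning)
        popt, _ = scipy.optimize.curve_fit(model, s, cc, p0=p0, maxfev=5000)
    return popt


def estimate_resolution(
    collection: DatasetCollection,
    group: SpaceGroupSetting,
    cc_cutoff: float = 0.3,
    n_bins: int = N_BINS_DEFAULT,
) -> float:
    """Resolution where a tanh fit to binned CC1/2 crosses ``cc_cutoff``.

    Falls back to the last bin with CC1/2 >= cutoff if the fit fails, and
    returns the data edge if the fitted curve never crosses the cutoff.
    """
    stats = statistics(collection, group, n_bins=n_bins)
    pts = [
        (0.5 * (1 / b.d_max + 1 / b.d_min), b.cc_half)
        for b in stats.bins
        if b.cc_half is not None
    ]
    if len(pts) < 5:
        raise ValueError("need at least 5 resolution bins with defined CC1/2")
    s = np.array([p[0] for p in pts])
    cc = np.array([p[1] for p in pts])
    data_edge = stats.overall.d_min
    try:
        c0, s0, r = tanh_fit(s, cc)
        if not 0 < cc_cutoff < c0:
            return data_edge
        arg = 1.0 - 2.0 * cc_cutoff / c0
        s_cut = s0 + r * np.arctanh(arg)
        if s_cut >= s.max() or s_cut <= 0:
            return data_edge
        return float(1.0 / s_cut)
    except Exception:
        logger.warning("tanh fit failed; falling back to last bin above cutoff")
        above = np.flatnonzero(cc >= cc_cutoff)
        if above.size == 0:
            return float(1.0 / s[0])
        return float(1.0 / s[above[-1]])


def apply_resolution_cutoff(collection: DatasetCollection, d_min: float) -> DatasetCollection:
    new_sets = []
    for refl in collection.reflection_sets:
        cell = collection.meta(refl.dataset_id).cell
        d = d_spacings(refl.indices, cell)
        new_sets.append(refl.select(d >= d_min - 1e-9))
    return DatasetCollection(new_sets, list(collection.metas))


# ---------------------------------------------------------------------------
# radiation-damage indicators

def damage_curves(
    collection: DatasetCollection,
    group: SpaceGroupSetting,
    scaled: "object | None" = None,
) -> DamageCurves:
    """Per-image damage indicators with image number as the dose proxy.

    R_cp(j) is the cumulative pairwise R factor over all observations with
    image number <= j across all data sets; completeness-vs-dose uses the
    first j images of every data set.
    """
    H, I, sig, img, did = _gather(collection)
    if np.unique(img).size < 2:
        return DamageCurves(
            image=np.array([], dtype=int),
            scale_vs_image=np.array([]),
            r_merge_vs_image=np.array([]),
            r_cp=np.array([]),
            completeness_vs_dose=np.array([]),
        )
    asu = map_to_asu(H, group)
    keys = encode_hkl(asu)
    uniq, inv = np.unique(keys, return_inverse=True)
    n_grp = uniq.size
    cell = collection.mean_cell()
    d = d_spacings(H, cell)
    possible = total_unique(cell, group, float(d.min()), float(d.max()))
    j_max = int(img.max())
    images = np.arange(1, j_max + 1)

    mean_scale = np.full(j_max, np.nan)
    r_merge_img = np.full(j_max, np.nan)
    r_cp = np.full(j_max, np.nan)
    comp = np.zeros(j_max)

    # per-image R_merge: contribution of image-j observations against the
    # overall group means
    n_all = np.bincount(inv, minlength=n_grp)
    mean_all = np.bincount(inv, weights=I, minlength=n_grp) / np.maximum(n_all, 1)
    inv_scales = None
    if scaled is not None and getattr(scaled, "inverse_scales", None):
        inv_scales = np.concatenate(
            [scaled.inverse_scales[r.dataset_id] for r in collection.reflection_sets]
        )
    for j in images:
        sel_j = img == j
        if inv_scales is not None and sel_j.any():
            mean_scale[j - 1] = float(np.mean(inv_scales[sel_j]))
        multi = sel_j & (n_all[inv] >= 2)
        if multi.any():
            den = I[multi].sum()
            if den != 0:
                r_merge_img[j - 1] = np.abs(I[multi] - mean_all[inv[multi]]).sum() / den
        sel_cum = img <= j
        kk = inv[sel_cum]
        cnt = np.bincount(kk, minlength=n_grp)
        mean_c = np.bincount(kk, weights=I[sel_cum], minlength=n_grp) / np.maximum(cnt, 1)
        mm = cnt[kk] >= 2
        den = I[sel_cum][mm].sum()
        if mm.any() and den != 0:
            r_cp[j - 1] = np.abs(I[sel_cum][mm] - mean_c[kk[mm]]).sum() / den
        comp[j - 1] = 100.0 * np.unique(keys[sel_cum]).size / possible.size
    return DamageCurves(
        image=images,
        scale_vs_image=mean_scale,
        r_merge_vs_image=r_merge_img,
        r_cp=r_cp,
        completeness_vs_dose=comp,
    )


def rcp_curve(collection: DatasetCollection, group: SpaceGroupSetting) -> DamageCurves:
    return damage_curves(collection, group)


def completeness_vs_dose(collection: DatasetCollection, group: SpaceGroupSetting):
    curves = damage_curves(collection, group)
    return curves.image, curves.completeness_vs_dose


# ---------------------------------------------------------------------------
# screw-axis detection / space-group assignment

_AXIS_DIRECTIONS = {  # direct axis -> axial reflection class selector
    "a": (np.array([1, 0, 0]), lambda H: (H[:, 1] == 0) & (H[:, 2] == 0), 0),
    "b": (np.array([0, 1, 0]), lambda H: (H[:, 0] == 0) & (H[:, 2] == 0), 1),
    "c": (np.array([0, 0, 1]), lambda H: (H[:, 0] == 0) & (H[:, 1] == 0), 2),
}

# rotation order about axis -> candidate screws as (symbol, period):
# reflections on the axis with index not divisible by the period are absent
_SCREW_CANDIDATES = {
    2: [("2(1)", 2)],
    3: [("3(1)", 3)],
    4: [("4(2)", 2), ("4(1)", 4)],
    6: [("6(3)", 2), ("6(2)", 3), ("6(1)", 6)],
}

ABSENCE_Z_MID = 3.0  # logistic midpoint of the z -> likelihood mapping
ABSENCE_Z_SCALE = 3.0


def _axis_order(group: SpaceGroupSetting, axis_vec: np.ndarray) -> int:
    best = 1
    for op in group.rotations():
        R = op.rot_array
        if np.array_equal(axis_vec @ R, axis_vec):  # axis fixed in hkl space
            best = max(best, op.order())
    return best


def screw_likelihood(z: float, z_reference: float | None = None) -> float:
    """Probability the screw is present, decreasing in the absence z-score.

    When the strength of genuinely present axial reflections is available
    (``z_reference``: the same statistic computed on the reflection class
    the screw allows), the call is a two-hypothesis comparison: the screw
    predicts z ~ N(0, 1), its absence predicts z near the reference.
    Without a reference the fallback is a logistic in z alone.
    """
    if z_reference is not None and z_reference > ABSENCE_Z_MID:
        sig_p = max(1.0, z_reference / 2.0)
        log_p_absent = -0.5 * z * z  # N(0, 1), constants cancel below
        log_p_present = -0.5 * ((z - z_reference) / sig_p) ** 2 - math.log(sig_p)
        m = max(log_p_absent, log_p_present)
        pa = math.exp(log_p_absent - m)
        pp = math.exp(log_p_present - m)
        return pa / (pa + pp)
    return 1.0 / (1.0 + math.exp((z - ABSENCE_Z_MID) / ABSENCE_Z_SCALE))


def detect_absences(merged: MergedSet, group: SpaceGroupSetting):
    """Score candidate screw axes from merged axial intensities.

    For each screw allowed by the Patterson group the z-score is the mean
    I/sigma of the expected-absent axial reflections times sqrt(count);
    values near zero support the screw.  Individual likelihoods multiply
    into a posterior over the allowed non-enantiogenic space groups.
    Returns (scores, space_group_symbol).
    """
    H = merged.indices
    scores = []
    axes_with_candidates = []
    for name, (vec, selector, comp) in _AXIS_DIRECTIONS.items():
        order = _axis_order(group, vec)
        cands = _SCREW_CANDIDATES.get(order, [])
        if not cands:
            continue
        on_axis = selector(np.abs(H)) | selector(np.abs(H))
        for symbol, period in cands:
            if _class_absent_by_centring(group.centring, name, period):
                continue
            idx = np.abs(H[:, comp])
            absent_class = on_axis & (idx % period != 0) & (idx != 0)
            allowed_class = on_axis & (idx % period == 0) & (idx != 0)
            n = int(absent_class.sum())
            if n == 0:
                scores.append(
                    AbsenceScore(
                        axis=f"{symbol} [{name}]",
                        screw_symbol=symbol,
                        n_absent_obs=0,
                        mean_i_over_sigma=None,
                        z_score=None,
                        likelihood=0.5,
                    )
                )
                continue
            ios = float(
                np.mean(merged.intensity[absent_class] / merged.sigma[absent_class])
            )
            z = ios * math.sqrt(n)
            z_ref = None
            n_ref = int(allowed_class.sum())
            if n_ref:
                z_ref = float(
                    np.mean(merged.intensity[allowed_class] / merged.sigma[allowed_class])
                    * math.sqrt(n_ref)
                )
            scores.append(
                AbsenceScore(
                    axis=f"{symbol} [{name}]",
                    screw_symbol=symbol,
                    n_absent_obs=n,
                    mean_i_over_sigma=ios,
                    z_score=float(z),
                    likelihood=screw_likelihood(z, z_ref),
                )
            )
        axes_with_candidates.append((name, comp, order, cands))
    sg_symbol = _assemble_space_group(group, scores)
    return scores, sg_symbol


def _class_absent_by_centring(centring: str, axis_name: str, period: int) -> bool:
    """Whether lattice centring already extinguishes the tested class."""
    comp = {"a": 0, "b": 1, "c": 2}[axis_name]
    for v in CENTRING_VECTORS.get(centring, []):
        # axial reflection (0..n..0): phase = n * v[comp]; absent for odd n if
        # v[comp] is a half integer etc.
        frac = float(v[comp])
        if frac > 0 and (frac * 1) % 1.0 != 0.0:
            return True
    return False


def _assemble_space_group(group: SpaceGroupSetting, scores) -> str:
    """Best non-enantiogenic space-group symbol from screw-axis scores.

    Starts from the acentric symmorphic symbol of the rotation group and
    substitutes the winning screw on each principal axis.  Enantiomorphic
    pairs (e.g. 4(1)/4(3)) are reported as the low-index member.
    """
    base = SpaceGroupSetting(
        symbol="", centring=group.centring, operations=group.rotations()
    )
    sg = base.gemmi_spacegroup(add_inversion=False)
    if sg is None:
        return "unknown"
    symbol = sg.xhm()
    by_axis = {}
    for sc in scores:
        axis = sc.axis.split("[")[1].rstrip("]")
        by_axis.setdefault(axis, []).append(sc)
    parts = symbol.split()
    # decide the winning screw per axis: among candidates whose absence
    # pattern is supported (likelihood > 0.5), the largest period wins --
    # e.g. a genuine 4(1) also satisfies the 4(2) test (odd l is a subset
    # of l != 4n) but not vice versa
    for axis, cand in by_axis.items():
        passing = [s for s in cand if s.likelihood > 0.5 and s.z_score is not None]
        if not passing:
            continue
        def period(s):
            order, sub = int(s.screw_symbol[0]), int(s.screw_symbol[2])
            return order // math.gcd(sub, order)

        best = max(passing, key=period)
        digit = best.screw_symbol[0]
        sub = best.screw_symbol.replace("(", "").replace(")", "")
        # replace the axis symbol in the Hermann-Mauguin short symbol
        axis_pos = {"a": 1, "b": 2, "c": 3}
        # monoclinic: "P 1 2 1" -> unique axis position; otherwise replace
        # the first matching rotation digit after the lattice letter
        replaced = False
        for i in range(1, len(parts)):
            if parts[i] == digit:
                if len(parts) == 4 and i != axis_pos.get(axis, i):
                    continue
                parts[i] = sub
                replaced = True
                break
        if not replaced:
            for i in range(1, len(parts)):
                if parts[i].startswith(digit):
                    parts[i] = sub + parts[i][len(digit):]
                    break
    return " ".join(parts)
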
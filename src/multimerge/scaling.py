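"""Physical-model scaling of multi-crystal collections.

Each data set d is corrected by a smoothly varying inverse scale

    g_d(phi, s) = k_d(phi) * exp(-2 * B_d(phi) * sin^2(theta)/lambda^2)
                  [* A_d(direction)  when the absorption term is enabled]

where k_d and B_d are interpolated from control values on a rotation-angle
grid (one control point per 15 degrees; a single point, i.e. a constant, for
small wedges).  Parameters are refined by alternating

1. update of the merged reference intensities (inverse-variance weighted
   means over symmetry-equivalent groups of g-corrected observations),
2. per-dataset weighted linear fits of log(I_obs / I_ref) against the
   control-point basis (log-scale columns and -2 s^2 B columns),
3. rejection of observations deviating > 6 sigma from their group mean, and
4. optional refinement of a single error model sigma'^2 = a^2 (sigma^2 +
   (b I)^2) shared across all data sets,

until the weighted merging residual stops decreasing.  The mean log-scale
and mean B over all data sets are constrained to zero (gauge fixing: only
relative scales are determinable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.special

from .refl_model import (
    DatasetCollection,
    SpaceGroupSetting,
    d_spacings,
    encode_hkl,
    map_to_asu,
)

logger = logging.getLogger(__name__)

SMALL_WEDGE_THRESHOLD = 60.0  # degrees; below this no absorption correction
CONTROL_SPACING = 15.0  # degrees between scale/B control points
OUTLIER_SIGMA = 6.0
MAX_CYCLES = 8
ABSORPTION_PRESETS = {  # harmonic order, restraint weight
    "low": (4, 1.0),
    "medium": (6, 0.1),
    "high": (8, 0.01),
}


@dataclass
class ModelConfig:
    absorption: bool = False
    absorption_strength: str = "low"
    error_model: bool = True
    anomalous: bool = False


@dataclass
class DatasetModel:
    dataset_id: int
    phi_grid: np.ndarray  # control-point rotation angles (degrees)
    log_scale: np.ndarray  # control values, dimensionless
    b_values: np.ndarray  # control values, A^2
    absorption_coeffs: np.ndarray | None = None

    def mid_scale(self) -> float:
        return float(np.exp(np.mean(self.log_scale)))

    def mid_b(self) -> float:
        return float(np.mean(self.b_values))


@dataclass
class ScalingModel:
    datasets: list
    strength: str = "low"


@dataclass
class ErrorModel:
    a: float = 1.0
    b: float = 0.02

    def adjusted_sigma(self, sigma, intensity):
        return self.a * np.sqrt(sigma**2 + (self.b * intensity) ** 2)


def select_model(metas, threshold: float = SMALL_WEDGE_THRESHOLD, override=None) -> ModelConfig:
    """Automatic scaling-model selection based on wedge width.

    Small wedges sample too few scattering paths for an absorption surface,
    so they get smooth scale + B only; large wedges add the absorption term
    at the requested strength (default low).  An explicit override wins.
    """
    if override is not None:
        return override
    max_width = max(m.scan_width for m in metas)
    return ModelConfig(absorption=max_width >= threshold)


def _control_grid(meta):
    n_ctrl = max(1, int(round(meta.scan_width / CONTROL_SPACING)))
    if n_ctrl == 1:
        return np.array([meta.scan_start + meta.scan_width / 2.0])
    return meta.scan_start + np.linspace(0, meta.scan_width, n_ctrl)


def _basis_weights(phi, grid):
    """Gaussian-kernel interpolation weights, normalised per observation."""
    if grid.size == 1:
        return np.ones((phi.size, 1))
    sig = CONTROL_SPACING
    w = np.exp(-((phi[:, None] - grid[None, :]) ** 2) / (2 * sig**2))
    return w / w.sum(axis=1, keepdims=True)


def _sph_harm_basis(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Real even-order spherical harmonics evaluated on unit vectors."""
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1, 1))
    phi = np.arctan2(y, x)
    cols = []
    for l in range(2, lmax + 1, 2):
        for mo in range(-l, l + 1):
            ylm = scipy.special.sph_harm_y(l, abs(mo), theta, phi)
            if mo < 0:
                cols.append(np.sqrt(2) * ylm.imag)
            elif mo == 0:
                cols.append(ylm.real)
            else:
                cols.append(np.sqrt(2) * ylm.real)
    return np.column_stack(cols)


@dataclass
class ScaledCollection:
    collection: DatasetCollection  # intensities/sigmas on the common scale
    inverse_scales: dict  # dataset_id -> per-observation applied g
    model: ScalingModel = None
    error_model: ErrorModel = None
    residuals: list = field(default_factory=list)
    n_rejected: int = 0


def scale(
    collection: DatasetCollection,
    group: SpaceGroupSetting,
    config: ModelConfig | None = None,
    anomalous: bool = False,
    max_cycles: int = MAX_CYCLES,
) -> ScaledCollection:
    """Scale all data sets onto a common relative scale.

    Observations are grouped by their canonical index under ``group``
    (Friedel pairs kept separate when ``anomalous``); see the module
    docstring for the refinement scheme.  Returns the scaled collection
    (original observations divided by the refined inverse scale, with error-
    model-adjusted sigmas) plus the fitted models.
    """
    if config is None:
        config = select_model(collection.metas)
    cell = collection.mean_cell()

    ids, obs_id, keys, phi, s2q, I, sig, img = [], [], [], [], [], [], [], []
    grids = {}
    for refl in collection.reflection_sets:
        meta = collection.meta(refl.dataset_id)
        asu = map_to_asu(refl.indices, group, anomalous=anomalous)
        k = encode_hkl(asu)
        d = d_spacings(refl.indices, meta.cell)
        p = meta.scan_start + (refl.image_number - 0.5) * (meta.scan_width / meta.images)
        ids.append(np.full(refl.n_obs, refl.dataset_id))
        keys.append(k)
        phi.append(p)
        s2q.append(1.0 / (4.0 * d**2))
        I.append(refl.intensity)
        sig.append(refl.sigma)
        img.append(refl.image_number)
        grids[refl.dataset_id] = _control_grid(meta)
    ids = np.concatenate(ids)
    keys = np.concatenate(keys)
    phi = np.concatenate(phi)
    s2q = np.concatenate(s2q)
    I = np.concatenate(I)
    sig = np.concatenate(sig)

    uniq_keys, grp = np.unique(keys, return_inverse=True)
    n_grp = uniq_keys.size
    grp_sizes = np.bincount(grp)
    if int((grp_sizes >= 2).sum()) == 0:
        raise ValueError("no symmetry-equivalent groups with >= 2 observations")

    dataset_ids = [r.dataset_id for r in collection.reflection_sets]
    basis = {}
    abs_basis = {}
    lmax, restraint = ABSORPTION_PRESETS.get(config.absorption_strength, (4, 1.0))
    for refl in collection.reflection_sets:
        did = refl.dataset_id
        sel = ids == did
        basis[did] = _basis_weights(phi[sel], grids[did])
        if config.absorption:
            meta = collection.meta(did)
            A = meta.cell.orthogonalization_matrix()
            Bm = np.linalg.inv(A).T
            v = (Bm @ refl.indices.T).T
            v = v / np.linalg.norm(v, axis=1, keepdims=True)
            abs_basis[did] = _sph_harm_basis(v, lmax)

    log_g = np.zeros(I.size)  # per-observation log inverse scale
    params = {
        did: np.zeros(2 * grids[did].size + (abs_basis[did].shape[1] if did in abs_basis else 0))
        for did in dataset_ids
    }
    emodel = ErrorModel() if config.error_model else ErrorModel(a=1.0, b=0.0)
    active = np.ones(I.size, dtype=bool)
    residuals = []
    rounds_of_rejection = 0

    def group_reference(gvals, weights, mask):
        num = np.bincount(grp[mask], weights=(gvals * weights)[mask], minlength=n_grp)
        den = np.bincount(grp[mask], weights=weights[mask], minlength=n_grp)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    for cycle in range(max_cycles):
        g = np.exp(log_g)
        Ic = I / g
        sigc = emodel.adjusted_sigma(sig, np.abs(I)) / g
        w = 1.0 / sigc**2
        ref = group_reference(Ic, w, active)

        # weighted residual over groups with >= 2 active observations
        cnt = np.bincount(grp[active], minlength=n_grp)
        ok = (cnt[grp] >= 2) & active & np.isfinite(ref[grp])
        resid = float(np.sum(w[ok] * (Ic[ok] - ref[grp][ok]) ** 2) / max(1, ok.sum()))
        residuals.append(resid)

        # per-dataset linearised fit of log(I/ref)
        for did in dataset_ids:
            sel = (ids == did) & ok & (I > 0) & (ref[grp] > 0)
            if sel.sum() < 3:
                continue
            in_sel = sel[ids == did]  # rows of this dataset's basis to use
            Bsel = basis[did][in_sel]
            cols = [Bsel, -2.0 * s2q[sel][:, None] * Bsel]
            if did in abs_basis:
                cols.append(abs_basis[did][in_sel])
            X = np.column_stack(cols)
            y = np.log(I[sel] / ref[grp][sel])
            snr = np.clip(I[sel] / emodel.adjusted_sigma(sig[sel], np.abs(I[sel])), 0, 50)
            wts = snr**2
            XtW = X.T * wts
            H = XtW @ X
            # light ridge + absorption restraint for stability
            reg = np.full(H.shape[0], 1e-6)
            n_sb = 2 * grids[did].size
            if did in abs_basis:
                reg[n_sb:] = restraint
            H[np.diag_indices_from(H)] += reg
            try:
                params[did] = np.linalg.solve(H, XtW @ y)
            except np.linalg.LinAlgError:
                continue

        # gauge fix: mean log-scale and mean B across datasets -> 0
        mean_ls = np.mean([np.mean(params[d][: grids[d].size]) for d in dataset_ids])
        mean_b = np.mean(
            [np.mean(params[d][grids[d].size : 2 * grids[d].size]) for d in dataset_ids]
        )
        for did in dataset_ids:
            nc = grids[did].size
            params[did][:nc] -= mean_ls
            params[did][nc : 2 * nc] -= mean_b
        # recompute per-observation log g
        for did in dataset_ids:
            sel = ids == did
            nc = grids[did].size
            ls = basis[did] @ params[did][:nc]
            bb = basis[did] @ params[did][nc : 2 * nc]
            lg = ls - 2.0 * bb * s2q[sel]
            if did in abs_basis:
                lg = lg + abs_basis[did] @ params[did][2 * nc :]
            log_g[sel] = lg

        # outlier rejection (<= 5 rounds overall)
        if rounds_of_rejection < 5:
            g = np.exp(log_g)
            Ic = I / g
            sigc = emodel.adjusted_sigma(sig, np.abs(I)) / g
            w = 1.0 / sigc**2
            ref = group_reference(Ic, w, active)
            cnt = np.bincount(grp[active], minlength=n_grp)
            dev = np.abs(Ic - ref[grp]) / sigc
            new_out = active & (cnt[grp] >= 3) & (dev > OUTLIER_SIGMA)
            if new_out.any():
                active &= ~new_out
                rounds_of_rejection += 1

        # error-model refinement
        if config.error_model:
            emodel = _refine_error_model(I, sig, np.exp(log_g), grp, n_grp, active, emodel)

        if cycle >= 1 and residuals[-1] > 0 and abs(residuals[-2] - residuals[-1]) < 1e-4 * residuals[-2]:
            break

    g = np.exp(log_g)
    new_sets = []
    inverse_scales = {}
    for refl in collection.reflection_sets:
        sel = ids == refl.dataset_id
        new = refl.copy()
        new.intensity = I[sel] / g[sel]
        new.sigma = emodel.adjusted_sigma(sig[sel], np.abs(I[sel])) / g[sel]
        new_sets.append(new)
        inverse_scales[refl.dataset_id] = g[sel]
    ds_models = []
    for did in dataset_ids:
        nc = grids[did].size
        ds_models.append(
            DatasetModel(
                dataset_id=did,
                phi_grid=grids[did],
                log_scale=params[did][:nc].copy(),
                b_values=params[did][nc : 2 * nc].copy(),
                absorption_coeffs=params[did][2 * nc :].copy() if did in abs_basis else None,
            )
        )
    logger.info(
        "scaling finished after %d cycle(s); %d observation(s) rejected",
        len(residuals),
        int((~active).sum()),
    )
    return ScaledCollection(
        collection=DatasetCollection(new_sets, list(collection.metas)),
        inverse_scales=inverse_scales,
        model=ScalingModel(datasets=ds_models, strength=config.absorption_strength),
        error_model=emodel,
        residuals=residuals,
        n_rejected=int((~active).sum()),
    )


def _refine_error_model(I, sig, g, grp, n_grp, active, current: ErrorModel) -> ErrorModel:
    """Fit (a, b) so standardized within-group deviations have unit variance."""
    Ic = I / g
    cnt = np.bincount(grp[active], minlength=n_grp)
    ok = active & (cnt[grp] >= 2)
    if ok.sum() < 20:
        return current
    mean = np.bincount(grp[ok], weights=Ic[ok], minlength=n_grp) / np.maximum(
        np.bincount(grp[ok], minlength=n_grp), 1
    )
    delta = Ic[ok] - mean[grp[ok]]
    # unbiased scaling for deviation from a group mean of n obs
    nn = cnt[grp[ok]].astype(float)
    corr = np.sqrt(nn / np.maximum(nn - 1.0, 1.0))
    delta = delta * corr
    sig_ok = sig[ok] / g[ok]
    I_ok = np.abs(I[ok]) / g[ok]

    def cost(p):
        a, b = p
        s = abs(a) * np.sqrt(sig_ok**2 + (b * I_ok) ** 2)
        z = delta / s
        # match the variance of z to 1 within intensity quantile bins
        qs = np.quantile(I_ok, np.linspace(0, 1, 6))
        qs[-1] += 1
        out = []
        for lo, hi in zip(qs[:-1], qs[1:]):
            m = (I_ok >= lo) & (I_ok < hi)
            if m.sum() > 5:
                out.append(np.std(z[m]) - 1.0)
        return np.array(out)

    try:
        res = scipy.optimize.least_squares(
            cost, [max(current.a, 0.1), max(current.b, 1e-3)], bounds=([1e-3, 0.0], [10.0, 0.5])
        )
        a, b = res.x
        return ErrorModel(a=float(abs(a)), b=float(b))
    except Exception:
        return current
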
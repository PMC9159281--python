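"""Geometric diagnostics: unit-cell refinement against 2-theta, crystal
orientation analysis and reciprocal-space coverage.

* :func:`refine_cell_2theta` -- constrained least squares of cell
  parameters against observed Bragg angles.
* :func:`stereographic_projection` / :func:`orientation_uniformity` --
  where do the crystal axes point relative to the beam, and is the
  distribution compatible with random orientations?
* :func:`multiplicity_map` / :func:`missing_reflections` -- coverage of
  reciprocal space: per-plane multiplicities and connected regions of
  unobserved reflections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.optimize
import scipy.stats

from .refl_model import (
    CENTRING_VECTORS,
    SpaceGroupSetting,
    UnitCell,
    d_spacings,
    decode_hkl,
    encode_hkl,
    map_to_asu,
)

logger = logging.getLogger(__name__)

# free metric parameters per lattice-system constraint
CELL_CONSTRAINTS = {
    "triclinic": ("a", "b", "c", "alpha", "beta", "gamma"),
    "monoclinic-b": ("a", "b", "c", "beta"),
    "orthorhombic": ("a", "b", "c"),
    "tetragonal": ("a=b", "c"),
    "hexagonal": ("a=b(120)", "c"),
    "rhombohedral-H": ("a=b(120)", "c"),
    "cubic": ("a=b=c",),
}


def _cell_from_params(p, constraint: str, cell0: UnitCell) -> UnitCell:
    c = constraint
    if c == "triclinic":
        return UnitCell(*p)
    if c == "monoclinic-b":
        a, b, cc, beta = p
        return UnitCell(a, b, cc, 90.0, beta, 90.0)
    if c == "orthorhombic":
        return UnitCell(p[0], p[1], p[2])
    if c == "tetragonal":
        return UnitCell(p[0], p[0], p[1])
    if c in ("hexagonal", "rhombohedral-H"):
        return UnitCell(p[0], p[0], p[1], 90.0, 90.0, 120.0)
    if c == "cubic":
        return UnitCell(p[0], p[0], p[0])
    raise ValueError(f"unknown constraint {constraint!r}; choose from {sorted(CELL_CONSTRAINTS)}")


def _params_from_cell(cell: UnitCell, constraint: str):
    c = constraint
    if c == "triclinic":
        return list(cell.parameters)
    if c == "monoclinic-b":
        return [cell.a, cell.b, cell.c, cell.beta]
    if c == "orthorhombic":
        return [cell.a, cell.b, cell.c]
    if c in ("tetragonal", "hexagonal", "rhombohedral-H"):
        return [cell.a, cell.c]
    if c == "cubic":
        return [cell.a]
    raise ValueError(f"unknown constraint {constraint!r}")


PARAM_NAMES = {
    "triclinic": ["a", "b", "c", "alpha", "beta", "gamma"],
    "monoclinic-b": ["a", "b", "c", "beta"],
    "orthorhombic": ["a", "b", "c"],
    "tetragonal": ["a", "c"],
    "hexagonal": ["a", "c"],
    "rhombohedral-H": ["a", "c"],
    "cubic": ["a"],
}


def two_theta_from_cell(indices, cell: UnitCell, wavelength: float):
    d = d_spacings(indices, cell)
    ratio = wavelength / (2.0 * d)
    if np.any(ratio > 1):
        raise ValueError("reflection beyond the limiting sphere for this wavelength")
    return np.degrees(2.0 * np.arcsin(ratio))


def refine_cell_2theta(
    indices,
    two_theta_obs,
    cell0: UnitCell,
    wavelength: float,
    constraint: str = "triclinic",
    weights=None,
):
    """Least-squares refinement of cell parameters against observed 2-theta.

    Returns (refined cell, dict of parameter esds).  Raises on rank
    deficiency, naming the unconstrained parameter.
    """
    indices = np.atleast_2d(np.asarray(indices, dtype=int))
    tt = np.asarray(two_theta_obs, dtype=float)
    w = np.ones_like(tt) if weights is None else np.asarray(weights, dtype=float)
    p0 = _params_from_cell(cell0, constraint)
    names = PARAM_NAMES[constraint]
    if tt.size < len(p0):
        raise ValueError(f"need at least {len(p0)} observations for {constraint}")

    def resid(p):
        try:
            cell = _cell_from_params(p, constraint, cell0)
        except ValueError:
            return np.full(tt.size, 1e6)
        return np.sqrt(w) * (two_theta_from_cell(indices, cell, wavelength) - tt)

    res = scipy.optimize.least_squares(resid, p0, method="lm", xtol=1e-14, ftol=1e-14)
    J = res.jac
    JTJ = J.T @ J
    col_norm = np.linalg.norm(J, axis=0)
    if np.any(col_norm < 1e-10):
        bad = names[int(np.argmin(col_norm))]
        raise ValueError(f"parameter {bad!r} is unconstrained by these observations")
    dof = max(1, tt.size - len(p0))
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(JTJ) * s2
    except np.linalg.LinAlgError as exc:
        raise ValueError("normal matrix is singular (rank-deficient refinement)") from exc
    esds = {nm: float(math.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
    return _cell_from_params(res.x, constraint, cell0), esds


# ---------------------------------------------------------------------------
# orientation analysis

@dataclass
class ProjectionPoint:
    dataset_id: int
    x: float
    y: float
    axis: tuple

    @property
    def radius(self) -> float:
        return math.hypot(self.x, self.y)


def _lab_axis_vectors(meta, axis, group: SpaceGroupSetting | None, include_symmetry: bool):
    """Unit lab-frame directions of the reciprocal axis (and symmetry copies)."""
    A = meta.cell.orthogonalization_matrix()
    Bm = np.linalg.inv(A).T
    h = np.asarray(axis, dtype=float)
    if not h.any():
        raise ValueError("zero axis")
    variants = [h]
    if include_symmetry and group is not None:
        seen = {tuple(h)}
        for op in group.rotations():
            hv = np.asarray(op.apply_hkl(np.rint(h).astype(int)), dtype=float)
            for cand in (hv, -hv):
                t = tuple(cand)
                if t not in seen:
                    seen.add(t)
                    variants.append(cand)
    out = []
    for hv in variants:
        v = meta.orientation @ (Bm @ hv)
        n = np.linalg.norm(v)
        if n > 0:
            out.append(v / n)
    return out


def stereographic_projection(
    metas,
    axis,
    group: SpaceGroupSetting | None = None,
    include_symmetry: bool = True,
):
    """Stereographic projection of a crystal axis for every data set.

    The beam is along +z (into the page).  Directions are folded to the
    +z hemisphere and projected from the antipode: a point at the origin
    means the axis is parallel to the beam, the unit circle perpendicular.
    """
    points = []
    for meta in metas:
        for v in _lab_axis_vectors(meta, axis, group, include_symmetry):
            if v[2] < 0:
                v = -v
            denom = 1.0 + v[2]
            points.append(
                ProjectionPoint(
                    dataset_id=meta.dataset_id,
                    x=float(v[0] / denom),
                    y=float(v[1] / denom),
                    axis=tuple(int(a) for a in np.rint(np.asarray(axis)).astype(int)),
                )
            )
    return points


def orientation_uniformity(metas, axis, alpha: float = 0.01):
    """Test of isotropy of an axis-direction distribution.

    Uses the Bingham-style statistic on the scatter matrix of the (axial)
    unit directions: T = 15 n / 2 * (trace(S^2) - 1/3), asymptotically
    chi-squared with 5 degrees of freedom under isotropy.  Returns
    (statistic, p_value, flagged); statistic is None for < 5 data sets.
    """
    vs = []
    for meta in metas:
        v = _lab_axis_vectors(meta, axis, None, False)[0]
        vs.append(v)
    if len(vs) < 5:
        return None, None, False
    V = np.asarray(vs)
    S = V.T @ V / len(vs)
    T = 15.0 * len(vs) / 2.0 * (float(np.trace(S @ S)) - 1.0 / 3.0)
    p = float(scipy.stats.chi2.sf(T, df=5))
    return T, p, p < alpha


# ---------------------------------------------------------------------------
# multiplicity maps and missing regions

_PLANES = {
    "hk0": (0, 1, 2),
    "h0l": (0, 2, 1),
    "0kl": (1, 2, 0),
}


def multiplicity_map(merged, group: SpaceGroupSetting, plane: str = "0kl"):
    """Multiplicity on a grid of the chosen zero-level reciprocal plane.

    Returns (grid, (axis1 range, axis2 range), histogram) where grid[i, j]
    is the multiplicity of the unique reflection equivalent to the plane
    point; 0 marks missing reflections.
    """
    if plane not in _PLANES:
        raise ValueError(f"unknown plane {plane!r}; valid: {sorted(_PLANES)}")
    i1, i2, iz = _PLANES[plane]
    H = merged.indices
    lut = {int(c): int(n) for c, n in zip(encode_hkl(H), merged.multiplicity)}
    lim1 = int(np.abs(H[:, i1]).max()) if H.size else 0
    lim2 = int(np.abs(H[:, i2]).max()) if H.size else 0
    r1 = np.arange(-lim1, lim1 + 1)
    r2 = np.arange(-lim2, lim2 + 1)
    grid = np.zeros((r1.size, r2.size), dtype=int)
    pts = np.zeros((r1.size * r2.size, 3), dtype=int)
    a, b = np.meshgrid(r1, r2, indexing="ij")
    pts[:, i1] = a.ravel()
    pts[:, i2] = b.ravel()
    asu = map_to_asu(pts, group)
    codes = encode_hkl(asu)
    vals = np.array([lut.get(int(c), 0) for c in codes])
    grid = vals.reshape(r1.size, r2.size)
    hist = np.bincount(merged.multiplicity.astype(int))
    return grid, (r1, r2), hist


_CENTRED_TO_PRIMITIVE = {
    # columns of M express the primitive basis in the centred basis;
    # Miller indices transform as h_p = M^T h_c
    "P": np.eye(3),
    "C": np.array([[0.5, 0.5, 0], [-0.5, 0.5, 0], [0, 0, 1.0]]),
    "A": np.array([[1.0, 0, 0], [0, 0.5, -0.5], [0, 0.5, 0.5]]),
    "B": np.array([[0.5, 0, -0.5], [0, 1.0, 0], [0.5, 0, 0.5]]),
    "I": np.array([[-0.5, 0.5, 0.5], [0.5, -0.5, 0.5], [0.5, 0.5, -0.5]]),
    "F": np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]),
    "R": np.array([[2 / 3, -1 / 3, -1 / 3], [1 / 3, 1 / 3, -2 / 3], [1 / 3, 1 / 3, 1 / 3]]).T,
}


@dataclass
class MissingRegion:
    indices: np.ndarray  # unique ASU indices (centred/original setting)
    count: int
    fraction_pct: float  # of total unique reflections
    d_range: tuple  # (d_max, d_min) in Angstrom


def missing_reflections(
    observed_unique: np.ndarray,
    cell: UnitCell,
    group: SpaceGroupSetting,
    d_min: float,
    exclude_absent=None,
):
    """Connected regions of missing reflections in reciprocal space.

    The complete index set to ``d_min`` is generated in the primitive
    setting (centred cells are mapped to primitive so lattice absences do
    not fragment the analysis), the observed unique set is expanded to the
    full sphere by the group operations plus Friedel, and unobserved
    indices are grouped by 26-connectivity on the integer grid.  Regions
    are reported with their member unique indices (original setting),
    counts, percentage of the total unique set and resolution range,
    sorted by size.

    ``exclude_absent`` may be a callable hkl -> bool marking additional
    (e.g. screw-axis) systematic absences in the original setting.
    """
    M = _CENTRED_TO_PRIMITIVE.get(group.centring)
    if M is None:
        raise ValueError(f"unsupported centring {group.centring!r}")
    Ac = cell.orthogonalization_matrix()
    Ap = Ac @ M
    Gp = Ap.T @ Ap
    cell_p = _cell_from_metric(Gp)

    from .synthetic import full_sphere_indices

    Hp = full_sphere_indices(cell_p, d_min, "P")
    # transform primitive indices back to the original (possibly centred)
    # setting: h_c = (M^T)^-1 h_p -- integral for lattice-allowed reflections
    Minv_T = np.linalg.inv(M.T)
    Hc_f = Hp @ Minv_T.T
    Hc = np.rint(Hc_f).astype(int)
    ok = np.all(np.abs(Hc_f - Hc) < 1e-6, axis=1)
    Hp, Hc = Hp[ok], Hc[ok]
    if exclude_absent is not None:
        keep = ~np.array([bool(exclude_absent(h)) for h in Hc])
        Hp, Hc = Hp[keep], Hc[keep]

    # expand observed unique set to the full sphere
    observed_unique = np.atleast_2d(np.asarray(observed_unique, dtype=int))
    obs_codes = set()
    for op in group.rotations():
        t = observed_unique @ op.rot_array
        obs_codes.update(encode_hkl(t).tolist())
        obs_codes.update(encode_hkl(-t).tolist())
    observed = np.array([int(c) in obs_codes for c in encode_hkl(Hc)])

    total_asu = np.unique(encode_hkl(map_to_asu(Hc, group))).size

    missing = ~observed
    if not missing.any():
        return []
    # label missing points on a dense integer grid, 26-connectivity
    mins = Hp.min(axis=0)
    shape = Hp.max(axis=0) - mins + 1
    grid = np.zeros(shape, dtype=bool)
    coords = Hp - mins
    grid[coords[missing, 0], coords[missing, 1], coords[missing, 2]] = True
    labels, n_lab = scipy.ndimage.label(grid, structure=np.ones((3, 3, 3), dtype=int))
    lab_per_point = labels[coords[:, 0], coords[:, 1], coords[:, 2]]

    # unique-code sets per connected component; symmetry copies of one
    # physical region appear as separate components that map back to the
    # same unique reflections, so components sharing any unique code are
    # merged (union-find) before reporting
    comp_codes = []
    for lab in range(1, n_lab + 1):
        sel = missing & (lab_per_point == lab)
        comp_codes.append(set(encode_hkl(map_to_asu(Hc[sel], group)).tolist()))
    parent = list(range(len(comp_codes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    code_owner = {}
    for i, codes in enumerate(comp_codes):
        for c in codes:
            if c in code_owner:
                ra, rb = find(code_owner[c]), find(i)
                if ra != rb:
                    parent[rb] = ra
            else:
                code_owner[c] = i
    merged_sets = {}
    for i, codes in enumerate(comp_codes):
        merged_sets.setdefault(find(i), set()).update(codes)

    regions = []
    for codes in merged_sets.values():
        arr = np.array(sorted(codes), dtype=np.int64)
        hkl = decode_hkl(arr)
        d = d_spacings(hkl, cell)
        regions.append(
            MissingRegion(
                indices=hkl,
                count=int(arr.size),
                fraction_pct=100.0 * arr.size / total_asu,
                d_range=(float(d.max()), float(d.min())),
            )
        )
    regions.sort(key=lambda r: -r.count)
    return regions


def _cell_from_metric(G: np.ndarray) -> UnitCell:
    a, b, c = np.sqrt(np.diag(G))
    al = math.degrees(math.acos(G[1, 2] / (b * c)))
    be = math.degrees(math.acos(G[0, 2] / (a * c)))
    ga = math.degrees(math.acos(G[0, 1] / (a * b)))
    return UnitCell(a, b, c, al, be, ga)
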
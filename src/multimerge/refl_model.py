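"""Core reflection/crystal data model, symmetry arithmetic and file I/O.

The in-memory containers here are shared by every downstream stage:

* :class:`UnitCell` -- direct-cell parameters with metric-tensor helpers.
* :class:`SymmetryOperation` -- a proper rotation (plus optional fractional
  translation) acting on fractional coordinates; Miller indices transform as
  row vectors, ``h' = h @ rot``.
* :class:`SpaceGroupSetting` -- a set of operations plus lattice centring.
* :class:`ReflectionSet` / :class:`ExperimentMeta` / :class:`DatasetCollection`
  -- unmerged observations of one crystal and their experiment metadata.

The native on-disk format is deliberately plain: a tab-separated reflection
table (``h k l intensity sigma image``) and a YAML metadata sidecar per data
set, so fixtures are human-readable and diffable.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# Encoding of (h,k,l) triples into single integers, used for fast grouping.
# Supports |index| < 512, far beyond anything a macromolecular cell needs.
_ENC_OFF = 512
_ENC_BASE = 1024

CENTRING_VECTORS = {
    "P": [],
    "A": [(0, Fraction(1, 2), Fraction(1, 2))],
    "B": [(Fraction(1, 2), 0, Fraction(1, 2))],
    "C": [(Fraction(1, 2), Fraction(1, 2), 0)],
    "I": [(Fraction(1, 2), Fraction(1, 2), Fraction(1, 2))],
    "F": [
        (0, Fraction(1, 2), Fraction(1, 2)),
        (Fraction(1, 2), 0, Fraction(1, 2)),
        (Fraction(1, 2), Fraction(1, 2), 0),
    ],
    # rhombohedral lattice handled in the hexagonal (H) setting throughout
    "R": [
        (Fraction(2, 3), Fraction(1, 3), Fraction(1, 3)),
        (Fraction(1, 3), Fraction(2, 3), Fraction(2, 3)),
    ],
}


def encode_hkl(hkl: np.ndarray) -> np.ndarray:
    """Map integer index triples to unique integers, monotone in (h,k,l)."""
    h = np.asarray(hkl, dtype=np.int64)
    return ((h[..., 0] + _ENC_OFF) * _ENC_BASE + (h[..., 1] + _ENC_OFF)) * _ENC_BASE + (
        h[..., 2] + _ENC_OFF
    )


def decode_hkl(codes: np.ndarray) -> np.ndarray:
    c = np.asarray(codes, dtype=np.int64)
    l = c % _ENC_BASE - _ENC_OFF
    c = c // _ENC_BASE
    k = c % _ENC_BASE - _ENC_OFF
    h = c // _ENC_BASE - _ENC_OFF
    return np.stack([h, k, l], axis=-1)


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must lie in (0, 180)")
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise ValueError("metric tensor not positive definite")

    @property
    def parameters(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def metric_tensor(self) -> np.ndarray:
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor())

    def orthogonalization_matrix(self) -> np.ndarray:
        """Columns are the cell basis vectors in a Cartesian frame."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
        return np.array(
            [
                [a, b * cg, c * cb],
                [0, b * sg, c * (ca - cb * cg) / sg],
                [0, 0, c * v / sg],
            ]
        )

    def volume(self) -> float:
        return float(math.sqrt(np.linalg.det(self.metric_tensor())))

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.parameters)


def d_spacings(indices: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Resolution d = 1/|s| in Angstrom for each Miller index."""
    H = np.asarray(indices, dtype=float)
    gstar = cell.reciprocal_metric_tensor()
    s2 = np.einsum("...i,ij,...j->...", H, gstar, H)
    return 1.0 / np.sqrt(s2)


@dataclass(frozen=True)
class SymmetryOperation:
    """Rotation acting on fractional coordinates, ``x' = rot @ x + trans``.

    Miller indices transform as row vectors: ``h' = h @ rot``.
    """

    rot: tuple  # 3x3 nested tuple of ints
    trans: tuple = (Fraction(0), Fraction(0), Fraction(0))

    @classmethod
    def from_matrix(cls, rot, trans=(0, 0, 0)) -> "SymmetryOperation":
        R = np.asarray(rot)
        Ri = np.rint(R).astype(int)
        if not np.allclose(R, Ri, atol=1e-9):
            raise ValueError("rotation must be an integer matrix")
        if abs(round(np.linalg.det(Ri))) != 1:
            raise ValueError("|det(rotation)| must be 1")
        t = tuple(Fraction(x).limit_denominator(24) for x in trans)
        return cls(tuple(tuple(int(v) for v in row) for row in Ri), t)

    @classmethod
    def identity(cls) -> "SymmetryOperation":
        return cls.from_matrix(np.eye(3, dtype=int))

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=int)

    @property
    def trans_array(self) -> np.ndarray:
        return np.array([float(t) for t in self.trans])

    def apply_hkl(self, hkl: np.ndarray) -> np.ndarray:
        return np.asarray(hkl, dtype=int) @ self.rot_array

    def __mul__(self, other: "SymmetryOperation") -> "SymmetryOperation":
        # composition: (self o other)(x) = self(other(x))
        R = self.rot_array @ other.rot_array
        t = [
            sum(Fraction(self.rot[i][j]) * other.trans[j] for j in range(3)) + self.trans[i]
            for i in range(3)
        ]
        t = [x % 1 for x in t]
        return SymmetryOperation.from_matrix(R, t)

    def inverse(self) -> "SymmetryOperation":
        Rinv = np.rint(np.linalg.inv(self.rot_array)).astype(int)
        t = (-Rinv @ np.array([[f] for f in self.trans], dtype=object)).flatten()
        return SymmetryOperation.from_matrix(Rinv, [Fraction(x) % 1 for x in t])

    @property
    def is_identity(self) -> bool:
        return self.rot == ((1, 0, 0), (0, 1, 0), (0, 0, 1)) and all(
            t == 0 for t in self.trans
        )

    def order(self) -> int:
        R = self.rot_array
        P = R.copy()
        for k in range(1, 13):
            if np.array_equal(P, np.eye(3, dtype=int)):
                return k
            P = P @ R
        raise ValueError("operation order exceeds 12")

    def hkl_triplet(self) -> str:
        """Re-index operator in the conventional 'h,k,l' notation."""
        names = "hkl"
        parts = []
        R = self.rot_array
        for j in range(3):  # output component j = sum_i h_i R[i, j]
            terms = ""
            for i in range(3):
                c = R[i, j]
                if c == 0:
                    continue
                sign = "-" if c < 0 else ("+" if terms else "")
                mag = "" if abs(c) == 1 else str(abs(c))
                terms += f"{sign}{mag}{names[i]}"
            parts.append(terms or "0")
        return ",".join(parts)

    def to_gemmi(self) -> gemmi.Op:
        op = gemmi.Op()
        den = gemmi.Op.DEN
        op.rot = [[int(v) * den for v in row] for row in self.rot]
        op.tran = [int(round(float(t) * den)) for t in self.trans]
        return op


@dataclass
class SpaceGroupSetting:
    """A (possibly symmorphic) symmetry setting: operations + centring."""

    symbol: str
    centring: str = "P"
    operations: list = field(default_factory=lambda: [SymmetryOperation.identity()])
    deltas: dict = field(default_factory=dict)  # op -> metric deviation (deg)

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroupSetting":
        sg = gemmi.SpaceGroup(symbol)
        gops = sg.operations()
        seen, ops = set(), []
        for op in gops.sym_ops:
            R = np.array(op.rot) // gemmi.Op.DEN
            if round(np.linalg.det(R)) != 1:
                continue  # proper rotations only; Friedel handled separately
            key = tuple(map(tuple, R))
            if key in seen:
                continue
            seen.add(key)
            t = [Fraction(x, gemmi.Op.DEN) for x in op.tran]
            ops.append(SymmetryOperation.from_matrix(R, t))
        centring = sg.hm[0] if sg.hm[0] != "H" else "R"
        return cls(symbol=sg.xhm(), centring=centring, operations=ops)

    @property
    def order(self) -> int:
        return len(self.operations)

    def rotations(self) -> list[SymmetryOperation]:
        seen, out = set(), []
        for op in self.operations:
            if op.rot not in seen:
                seen.add(op.rot)
                out.append(SymmetryOperation.from_matrix(op.rot_array))
            # closure under composition is assumed and checked in tests
        return out

    def gemmi_spacegroup(self, add_inversion: bool = True):
        """Match against gemmi's tables (Patterson group if add_inversion)."""
        ops = []
        for op in self.rotations():
            ops.append(op.to_gemmi())
            if add_inversion:
                inv = SymmetryOperation.from_matrix(-op.rot_array)
                ops.append(inv.to_gemmi())
        cen = [gemmi.Op().translated([0, 0, 0])]
        den = gemmi.Op.DEN
        for v in CENTRING_VECTORS.get(self.centring, []):
            ops.append(
                gemmi.Op().translated([int(round(float(x) * den)) for x in v])
            )
        try:
            gops = gemmi.GroupOps(ops)
            return gemmi.find_spacegroup_by_ops(gops)
        except Exception:
            return None


def _gcd3(v) -> int:
    return math.gcd(math.gcd(abs(int(v[0])), abs(int(v[1]))), abs(int(v[2])))


def _axis_obliquity(R: np.ndarray, cell: UnitCell) -> float:
    """Le Page-style delta: angle between direct and reciprocal axis of R.

    For a proper rotation of order > 1 the direct-space axis is the
    eigenvector of R with eigenvalue +1 and the reciprocal-space axis the
    corresponding eigenvector of R^T; if the cell metric exactly supports the
    operation the two are parallel.
    """
    A = cell.orthogonalization_matrix()
    Astar = np.linalg.inv(A).T

    def unit_eigvec(M):
        w, v = np.linalg.eig(M)
        i = int(np.argmin(np.abs(w - 1.0)))
        vec = np.real(v[:, i])
        return vec / np.linalg.norm(vec)

    u = unit_eigvec(R)  # fractional, direct space
    h = unit_eigvec(R.T)  # fractional, reciprocal space
    du = A @ u
    dh = Astar @ h
    cosang = abs(float(du @ dh) / (np.linalg.norm(du) * np.linalg.norm(dh)))
    return math.degrees(math.acos(min(1.0, cosang)))


def _preserves_centring(R: np.ndarray, centring: str) -> bool:
    vs = CENTRING_VECTORS.get(centring, [])
    lattice = [np.array([0.0, 0.0, 0.0])] + [np.array([float(x) for x in v]) for v in vs]
    for v in lattice[1:]:
        img = (R @ v) % 1.0
        if not any(np.allclose(img, w % 1.0, atol=1e-9) for w in lattice):
            return False
    return True


def max_lattice_group(
    cell: UnitCell, centring: str = "P", angular_tolerance: float = 5.0
) -> SpaceGroupSetting:
    """Highest proper lattice symmetry compatible with the cell metric.

    Enumerates candidate two-fold axes as integer direct/reciprocal row pairs
    (u, h) with ``u . h = 2`` (the rotation is then ``u h^T - I``), keeps
    those whose Le Page obliquity is within ``angular_tolerance`` and that
    preserve the centring lattice, and closes the set under composition.
    Friedel/inversion symmetry is excluded; only proper operations are
    returned.  Per-operation deltas are reported in ``.deltas``.
    """
    I3 = np.eye(3, dtype=int)
    twofolds: dict[tuple, float] = {}
    rng = range(-2, 3)
    for u in ((a, b, c) for a in rng for b in rng for c in rng):
        if u == (0, 0, 0) or _gcd3(u) != 1:
            continue
        for h in ((a, b, c) for a in rng for b in rng for c in rng):
            if h == (0, 0, 0) or _gcd3(h) != 1:
                continue
            dot = u[0] * h[0] + u[1] * h[1] + u[2] * h[2]
            if dot not in (1, 2):
                continue
            # twofold about direct axis u with reciprocal axis h:
            # R = 2 u h^T / (u.h) - I  (integer in both admissible cases)
            R = (2 // dot) * np.outer(u, h) - I3
            key = tuple(map(tuple, R))
            if key in twofolds:
                continue
            delta = _axis_obliquity(R, cell)
            if delta <= angular_tolerance and _preserves_centring(R, centring):
                twofolds[key] = delta

    def closure(keys):
        # composite operations inherit the worst delta of their generators
        mats = {k: (np.array(k), twofolds[k]) for k in keys}
        mats[tuple(map(tuple, I3))] = (I3, 0.0)
        changed = True
        while changed and len(mats) <= 24:
            changed = False
            items = list(mats.values())
            for Ra, da in items:
                for Rb, db in items:
                    P = Ra @ Rb
                    k = tuple(map(tuple, P))
                    d = max(da, db)
                    if k not in mats:
                        mats[k] = (P, d)
                        changed = True
                    elif d < mats[k][1]:
                        mats[k] = (P, d)
        return mats

    keys = sorted(twofolds, key=lambda k: twofolds[k])
    mats = closure(keys)
    while len(mats) > 24 and keys:  # degenerate tolerance: drop worst axis
        keys = keys[:-1]
        mats = closure(keys)

    ops, deltas = [], {}
    for k, (R, d) in mats.items():
        op = SymmetryOperation.from_matrix(R)
        ops.append(op)
        deltas[op] = min(d, twofolds.get(k, d))
    ops.sort(key=lambda o: (o.order(), o.hkl_triplet()))
    setting = SpaceGroupSetting(symbol="", centring=centring, operations=ops, deltas=deltas)
    sg = setting.gemmi_spacegroup(add_inversion=True)
    setting.symbol = sg.xhm() if sg is not None else f"lattice group (order {len(ops)})"
    return setting


def map_to_asu(
    indices: np.ndarray, setting: SpaceGroupSetting, anomalous: bool = False
) -> np.ndarray:
    """Canonical orbit representative of each index under the Patterson group.

    The representative is the lexicographically greatest member of the orbit
    (Friedel mates included unless ``anomalous``); a fixed deterministic
    convention that is idempotent and oracle-checkable.
    """
    H = np.atleast_2d(np.asarray(indices, dtype=int))
    mats = [op.rot_array for op in setting.rotations()]
    cands = np.stack([H @ R for R in mats])  # (m, N, 3)
    if not anomalous:
        cands = np.concatenate([cands, -cands])
    codes = encode_hkl(cands)
    best = np.argmax(codes, axis=0)
    out = cands[best, np.arange(H.shape[0])]
    return out


@dataclass
class ReflectionSet:
    dataset_id: int
    indices: np.ndarray  # (n, 3) int
    intensity: np.ndarray
    sigma: np.ndarray
    image_number: np.ndarray  # 1-based

    def __post_init__(self):
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=int))
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.image_number = np.asarray(self.image_number, dtype=int)
        n = len(self.intensity)
        if not (self.indices.shape == (n, 3) and len(self.sigma) == n == len(self.image_number)):
            raise ValueError("reflection arrays must have equal length")
        if np.any(encode_hkl(self.indices) == encode_hkl(np.zeros(3, dtype=int))):
            raise ValueError("(0,0,0) is not a valid observation index")

    @property
    def n_obs(self) -> int:
        return len(self.intensity)

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(
            self.dataset_id,
            self.indices[mask],
            self.intensity[mask],
            self.sigma[mask],
            self.image_number[mask],
        )

    def copy(self) -> "ReflectionSet":
        return self.select(np.ones(self.n_obs, dtype=bool))


@dataclass
class ExperimentMeta:
    dataset_id: int
    cell: UnitCell
    orientation: np.ndarray  # 3x3 orthonormal, crystal -> laboratory
    scan_start: float = 0.0
    scan_width: float = 10.0
    images: int = 10
    wavelength: float = 1.0
    centring: str = "P"

    def __post_init__(self):
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3) or not np.allclose(
            self.orientation @ self.orientation.T, np.eye(3), atol=1e-6
        ):
            raise ValueError("orientation must be a 3x3 orthonormal matrix")
        if self.scan_width <= 0:
            raise ValueError("scan_width must be positive")


@dataclass
class DatasetCollection:
    reflection_sets: list
    metas: list

    def __post_init__(self):
        ids = [r.dataset_id for r in self.reflection_sets]
        if len(set(ids)) != len(ids):
            raise ValueError("dataset ids must be unique")
        if sorted(ids) != sorted(m.dataset_id for m in self.metas):
            raise ValueError("one metadata record required per reflection set")
        self._meta_by_id = {m.dataset_id: m for m in self.metas}

    @property
    def n(self) -> int:
        return len(self.reflection_sets)

    def meta(self, dataset_id: int) -> ExperimentMeta:
        return self._meta_by_id[dataset_id]

    def mean_cell(self) -> UnitCell:
        p = np.mean([m.cell.parameters for m in self.metas], axis=0)
        return UnitCell(*p)

    def subset(self, ids: Iterable[int]) -> "DatasetCollection":
        ids = set(ids)
        return DatasetCollection(
            [r for r in self.reflection_sets if r.dataset_id in ids],
            [m for m in self.metas if m.dataset_id in ids],
        )

    def total_observations(self) -> int:
        return int(sum(r.n_obs for r in self.reflection_sets))


# ---------------------------------------------------------------------------
# Native file format

_REFL_SUFFIX = ".refl.tsv"
_META_SUFFIX = ".meta.yaml"
REFL_COLUMNS = ["h", "k", "l", "intensity", "sigma", "image"]


def _meta_path_for(refl_path: Path) -> Path:
    name = refl_path.name
    if not name.endswith(_REFL_SUFFIX):
        raise ValueError(f"reflection file {refl_path} does not end in {_REFL_SUFFIX}")
    return refl_path.with_name(name[: -len(_REFL_SUFFIX)] + _META_SUFFIX)


def write_collection(collection: DatasetCollection, directory, prefix: str = "dataset"):
    """Write each data set as <prefix>_<id>.refl.tsv + .meta.yaml; return paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for refl in collection.reflection_sets:
        meta = collection.meta(refl.dataset_id)
        stem = f"{prefix}_{refl.dataset_id:03d}"
        rpath = directory / (stem + _REFL_SUFFIX)
        df = pd.DataFrame(
            {
                "h": refl.indices[:, 0],
                "k": refl.indices[:, 1],
                "l": refl.indices[:, 2],
                "intensity": refl.intensity,
                "sigma": refl.sigma,
                "image": refl.image_number,
            }
        )
        df.to_csv(rpath, sep="\t", index=False, float_format="%.17g")
        mpath = directory / (stem + _META_SUFFIX)
        doc = {
            "dataset_id": int(meta.dataset_id),
            "cell": [float(x) for x in meta.cell.parameters],
            "orientation": [float(x) for x in meta.orientation.flatten()],
            "scan_start": float(meta.scan_start),
            "scan_width": float(meta.scan_width),
            "images": int(meta.images),
            "wavelength": float(meta.wavelength),
            "centring": meta.centring,
        }
        mpath.write_text(yaml.safe_dump(doc, sort_keys=False))
        paths.append(rpath)
    return paths


def read_collection(paths: Sequence) -> DatasetCollection:
    """Read reflection-table/metadata file pairs into a collection.

    ``paths`` lists the reflection tables; each must have a YAML sidecar next
    to it.  Observations with sigma <= 0 are dropped (count logged).
    """
    refls, metas = [], []
    for p in paths:
        rpath = Path(p)
        mpath = _meta_path_for(rpath)
        if not mpath.exists():
            raise FileNotFoundError(f"missing metadata sidecar for {rpath.name}: {mpath}")
        try:
            df = pd.read_csv(rpath, sep="\t", float_precision="round_trip")
        except Exception as exc:
            raise ValueError(f"malformed reflection table {rpath}: {exc}") from exc
        missing = [c for c in REFL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{rpath}: missing columns {missing}")
        bad = ~np.isfinite(df[REFL_COLUMNS[3:]].to_numpy()).all(axis=1)
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise ValueError(f"{rpath}: malformed row at line {line}")
        doc = yaml.safe_load(mpath.read_text())
        meta = ExperimentMeta(
            dataset_id=int(doc["dataset_id"]),
            cell=UnitCell(*doc["cell"]),
            orientation=np.array(doc["orientation"], dtype=float).reshape(3, 3),
            scan_start=float(doc.get("scan_start", 0.0)),
            scan_width=float(doc.get("scan_width", 10.0)),
            images=int(doc.get("images", 10)),
            wavelength=float(doc.get("wavelength", 1.0)),
            centring=str(doc.get("centring", "P")),
        )
        keep = df["sigma"].to_numpy() > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("%s: dropped %d observation(s) with sigma <= 0", rpath.name, n_drop)
        df = df[keep]
        refl = ReflectionSet(
            dataset_id=meta.dataset_id,
            indices=df[["h", "k", "l"]].to_numpy(dtype=int),
            intensity=df["intensity"].to_numpy(dtype=float),
            sigma=df["sigma"].to_numpy(dtype=float),
            image_number=df["image"].to_numpy(dtype=int),
        )
        refls.append(refl)
        metas.append(meta)
    return DatasetCollection(refls, metas)


def write_merged_mtz(path, indices, intensity, sigma, cell: UnitCell, spacegroup: str):
    """Export merged intensities as an MTZ file (H K L IMEAN SIGIMEAN)."""
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup(spacegroup)
    mtz.set_cell_for_all(cell.to_gemmi())
    mtz.add_dataset("merged")
    mtz.add_column("IMEAN", "J")
    mtz.add_column("SIGIMEAN", "Q")
    data = np.column_stack([np.asarray(indices, dtype=float), intensity, sigma])
    mtz.set_data(data)
    mtz.write_to_file(str(path))
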
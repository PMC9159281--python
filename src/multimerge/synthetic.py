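"""Ground-truth multi-crystal simulator.

Generates :class:`DatasetCollection` objects with the statistical structure
the analysis stages assume, with every planted effect recorded in a
:class:`GroundTruth` so recovery can be scored exactly:

* true intensities drawn from the acentric Wilson distribution (exponential,
  with mean falling off as ``exp(-B_wilson / 2d^2)``);
* per-dataset observations from a simplified rotation sweep (Ewald-sphere
  crossings of a wedge about the lab x axis) or a random subsample;
* optional indexing ambiguity (a lattice operation applied to a subset of
  data sets), non-isomorphous subpopulations at a target intensity
  correlation, per-image B-factor decay (radiation damage), preferential
  orientation, and permuted-intensity outlier data sets;
* Gaussian measurement noise calibrated to a target <I/sigma>.

Non-isomorphous populations share complex structure factors with amplitude
weight alpha: for unit complex-Gaussian F, corr(|F1|^2, |F2|^2) = alpha^2,
so alpha = sqrt(rho) plants an intensity correlation of exactly rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .refl_model import (
    CENTRING_VECTORS,
    DatasetCollection,
    ExperimentMeta,
    ReflectionSet,
    SpaceGroupSetting,
    SymmetryOperation,
    UnitCell,
    d_spacings,
    encode_hkl,
    map_to_asu,
    write_collection,
)

import gemmi


@dataclass
class SimulationConfig:
    space_group: str = "P 41 21 2"
    cell: tuple = (79.1, 79.1, 38.0, 90.0, 90.0, 90.0)
    n_datasets: int = 20
    images_per_dataset: int = 10
    wedge_width: float = 10.0  # degrees per crystal, typical small-wedge regime
    d_min: float = 3.0
    wilson_b: float = 20.0  # A^2
    scale_range: tuple = (0.5, 2.0)
    b_range: tuple = (0.0, 10.0)  # A^2 relative B spread
    noise: float | None = 10.0  # target <I/sigma>; None = (near) noiseless
    # "proportional": sigma tracks the local Wilson mean (uniform I/sigma);
    # "flat": constant absolute sigma anchored at the resolution edge, so
    # I/sigma and CC1/2 genuinely fall off with resolution
    noise_model: str = "proportional"
    ambiguity_op: str | None = None  # e.g. "k,h,-l"
    ambiguity_fraction: float = 0.5
    n_populations: int = 1
    between_cc: float = 0.7
    damage_b_per_image: float = 0.0  # A^2 added to B per image (dose proxy)
    orientation_axis: tuple | None = None  # reciprocal axis drawn toward beam
    orientation_sigma_deg: float = 10.0
    n_outliers: int = 0
    outlier_kind: str = "permuted"
    sampling: str = "sweep"  # "sweep" | "random"
    multiplicity: float = 6.0  # random sampling: total obs = unique * multiplicity
    wavelength: float = 1.0
    seed: int = 0


@dataclass
class GroundTruth:
    asu_codes: np.ndarray  # encoded unique ASU indices
    true_intensity: np.ndarray  # population-0 merged intensities
    population_intensities: np.ndarray  # (n_pop, n_unique)
    scales: np.ndarray  # per-dataset scale factor
    b_factors: np.ndarray  # per-dataset relative B (A^2)
    reindex_ops: list  # applied ambiguity op per dataset
    population: np.ndarray  # per-dataset population label
    outliers: np.ndarray  # dataset ids of planted outliers
    patterson: SpaceGroupSetting = None
    config: SimulationConfig = None

    def intensity_lookup(self, population: int = 0):
        order = np.argsort(self.asu_codes)
        return self.asu_codes[order], self.population_intensities[population][order]


def _centring_of(symbol: str) -> str:
    letter = gemmi.SpaceGroup(symbol).hm[0]
    return "R" if letter == "H" else letter


def full_sphere_indices(cell: UnitCell, d_min: float, centring: str = "P") -> np.ndarray:
    """All Miller indices with d >= d_min, lattice (centring) absences removed."""
    gstar = cell.reciprocal_metric_tensor()
    hmax = int(math.ceil(cell.a / d_min)) + 1
    kmax = int(math.ceil(cell.b / d_min)) + 1
    lmax = int(math.ceil(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    H = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    H = H[np.any(H != 0, axis=1)]
    s2 = np.einsum("ni,ij,nj->n", H.astype(float), gstar, H.astype(float))
    H = H[s2 <= 1.0 / d_min**2 + 1e-12]
    for v in CENTRING_VECTORS.get(centring, []):
        phase = H @ np.array([float(x) for x in v])
        H = H[np.isclose(phase % 1.0, 0.0, atol=1e-9) | np.isclose(phase % 1.0, 1.0, atol=1e-9)]
    return H


def choose_d_min(cell: UnitCell, space_group: str, target_unique: int) -> float:
    """Resolution limit giving approximately the requested unique count."""
    patterson = SpaceGroupSetting.from_symbol(space_group)
    centring = _centring_of(space_group)
    lo, hi = 1.0, 20.0
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        H = full_sphere_indices(cell, mid, centring)
        n = np.unique(encode_hkl(map_to_asu(H, patterson))).size
        if n > target_unique:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _oriented_toward_beam(
    recip_axis_cart: np.ndarray, sigma_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Orientation placing the given crystal direction near the beam (+z)."""
    v = recip_axis_cart / np.linalg.norm(recip_axis_cart)
    target = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, target)
    if np.linalg.norm(axis) < 1e-12:
        base = np.eye(3) if v @ target > 0 else _axis_angle(np.array([1.0, 0, 0]), math.pi)
    else:
        ang = math.acos(np.clip(v @ target, -1, 1))
        base = _axis_angle(axis, ang)
    tilt_axis = rng.normal(size=3)
    tilt_axis /= np.linalg.norm(tilt_axis)
    tilt = math.radians(abs(rng.normal(0.0, sigma_deg)))
    spin = _axis_angle(target, rng.uniform(0, 2 * math.pi))
    return _axis_angle(tilt_axis, tilt) @ spin @ base


def _sweep_observations(
    H: np.ndarray,
    cell: UnitCell,
    orientation: np.ndarray,
    scan_start: float,
    wedge_width: float,
    n_images: int,
    wavelength: float,
):
    """Ewald-sphere crossings of a rotation wedge about the lab x axis.

    Beam is along -z (incident wavevector s0 = (0, 0, -1/lambda)).  Returns
    (indices, image_numbers) for every crossing inside the wedge.
    """
    A = cell.orthogonalization_matrix()
    Bmat = np.linalg.inv(A).T  # reciprocal basis, Cartesian columns
    V = (orientation @ Bmat @ H.T).T  # lab-frame reciprocal vectors at phi=0
    r2 = np.sum(V * V, axis=1)
    c = 0.5 * wavelength * r2  # required z-component / (1/lambda) scaling
    # (R_x(phi) v)_z = -v_y sin(phi) + v_z cos(phi) = rho sin(phi + psi)
    rho = np.hypot(V[:, 1], V[:, 2])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(rho > 0, c / np.where(rho > 0, rho, 1.0), 2.0)
    crossing = np.abs(ratio) <= 1.0
    psi = np.arctan2(V[:, 2], -V[:, 1])
    base = np.arcsin(np.clip(ratio, -1, 1))
    out_idx, out_img = [], []
    img_width = wedge_width / n_images
    for phi in (base - psi, math.pi - base - psi):
        deg = np.degrees(phi) % 360.0
        rel = (deg - scan_start) % 360.0
        inside = crossing & (rel < wedge_width)
        img = np.floor(rel[inside] / img_width).astype(int) + 1
        out_idx.append(H[inside])
        out_img.append(np.clip(img, 1, n_images))
    return np.concatenate(out_idx), np.concatenate(out_img)


def simulate(config: SimulationConfig):
    """Simulate a multi-crystal collection; returns (collection, truth)."""
    rng = np.random.default_rng(config.seed)
    cell = UnitCell(*config.cell)
    centring = _centring_of(config.space_group)
    patterson = SpaceGroupSetting.from_symbol(config.space_group)
    patterson.centring = centring
    sg_ops = gemmi.SpaceGroup(config.space_group).operations()

    H_sphere = full_sphere_indices(cell, config.d_min, centring)
    asu = map_to_asu(H_sphere, patterson)
    codes_sphere = encode_hkl(asu)
    uniq_codes, inverse = np.unique(codes_sphere, return_inverse=True)
    n_unique = uniq_codes.size

    from .refl_model import decode_hkl

    uniq_hkl = decode_hkl(uniq_codes)
    d_uniq = d_spacings(uniq_hkl, cell)
    wilson_mean = np.exp(-config.wilson_b / (2.0 * d_uniq**2))

    # acentric Wilson intensities via complex structure factors; populations
    # share F with amplitude weight alpha = sqrt(rho) -> intensity CC = rho
    def draw_F(size):
        return (rng.normal(size=size) + 1j * rng.normal(size=size)) / math.sqrt(2.0)

    F0 = draw_F(n_unique)
    alpha = math.sqrt(max(0.0, min(1.0, config.between_cc)))
    pops = []
    for p in range(config.n_populations):
        if p == 0:
            F = F0
        else:
            F = alpha * F0 + math.sqrt(1 - alpha**2) * draw_F(n_unique)
        pops.append(np.abs(F) ** 2 * wilson_mean)
    pop_I = np.stack(pops)

    # systematic (screw-axis) absences of the true space group: intensity 0
    absent = np.array([sg_ops.is_systematically_absent(list(h)) for h in uniq_hkl])
    pop_I[:, absent] = 0.0

    amb_op = None
    if config.ambiguity_op is not None:
        amb_op = _op_from_hkl_triplet(config.ambiguity_op)
    n = config.n_datasets
    scales = rng.uniform(*config.scale_range, size=n)
    bfacs = rng.uniform(*config.b_range, size=n)
    population = (
        rng.integers(0, config.n_populations, size=n)
        if config.n_populations > 1
        else np.zeros(n, dtype=int)
    )
    flip = np.zeros(n, dtype=bool)
    if amb_op is not None:
        k = int(round(config.ambiguity_fraction * n))
        flip[rng.permutation(n)[:k]] = True
    outlier_ids = np.array(
        sorted(rng.permutation(n)[: config.n_outliers]), dtype=int
    )

    A = cell.orthogonalization_matrix()
    Bmat = np.linalg.inv(A).T
    refl_sets, metas, reindex_ops = [], [], []
    d_sphere = d_spacings(H_sphere, cell)
    wilson_sphere = np.exp(-config.wilson_b / (2.0 * d_sphere**2))
    for i in range(n):
        if config.orientation_axis is not None:
            U = _oriented_toward_beam(
                Bmat @ np.asarray(config.orientation_axis, dtype=float),
                config.orientation_sigma_deg,
                rng,
            )
        else:
            U = _random_rotation(rng)
        scan_start = float(rng.uniform(0, 360.0))
        if config.sampling == "sweep":
            H_obs, images = _sweep_observations(
                H_sphere,
                cell,
                U,
                scan_start,
                config.wedge_width,
                config.images_per_dataset,
                config.wavelength,
            )
        elif config.sampling == "random":
            n_obs = int(round(n_unique * config.multiplicity / n))
            pick = rng.choice(H_sphere.shape[0], size=min(n_obs, H_sphere.shape[0]), replace=False)
            H_obs = H_sphere[pick]
            images = rng.integers(1, config.images_per_dataset + 1, size=H_obs.shape[0])
        else:
            raise ValueError(f"unknown sampling mode {config.sampling!r}")
        if H_obs.shape[0] == 0:
            continue
        iu = np.searchsorted(uniq_codes, encode_hkl(map_to_asu(H_obs, patterson)))
        I_true = pop_I[population[i]][iu]
        d_obs = d_spacings(H_obs, cell)
        s2q = 1.0 / (4.0 * d_obs**2)  # sin^2(theta)/lambda^2
        b_eff = bfacs[i] + config.damage_b_per_image * (images - 1)
        factor = scales[i] * np.exp(-2.0 * b_eff * s2q)
        wilson_here = np.exp(-config.wilson_b / (2.0 * d_obs**2))
        if config.noise is None:
            sigma_true = 1e-8 * np.maximum(wilson_here, 1e-30)
            noise = 0.0
        else:
            if config.noise_model == "flat":
                edge_mean = math.exp(-config.wilson_b / (2.0 * config.d_min**2))
                sigma_true = np.full_like(wilson_here, edge_mean / config.noise)
            else:
                sigma_true = wilson_here / config.noise
            noise = rng.normal(0.0, 1.0, size=I_true.shape) * sigma_true
        I_obs = factor * (I_true + noise)
        sig_obs = factor * sigma_true
        if i in outlier_ids and config.outlier_kind == "permuted":
            I_obs = I_obs[rng.permutation(I_obs.size)]
        op = amb_op if (amb_op is not None and flip[i]) else SymmetryOperation.identity()
        H_final = op.apply_hkl(H_obs)
        refl_sets.append(
            ReflectionSet(
                dataset_id=i,
                indices=H_final,
                intensity=I_obs,
                sigma=sig_obs,
                image_number=images,
            )
        )
        metas.append(
            ExperimentMeta(
                dataset_id=i,
                cell=cell,
                orientation=U,
                scan_start=scan_start,
                scan_width=config.wedge_width,
                images=config.images_per_dataset,
                wavelength=config.wavelength,
                centring=centring,
            )
        )
        reindex_ops.append(op)

    collection = DatasetCollection(refl_sets, metas)
    truth = GroundTruth(
        asu_codes=uniq_codes,
        true_intensity=pop_I[0],
        population_intensities=pop_I,
        scales=scales,
        b_factors=bfacs,
        reindex_ops=reindex_ops,
        population=population,
        outliers=outlier_ids,
        patterson=patterson,
        config=config,
    )
    return collection, truth


def _op_from_hkl_triplet(triplet: str) -> SymmetryOperation:
    """Parse 'k,h,-l' style triplets into the matrix acting on (h,k,l)."""
    cols = triplet.replace(" ", "").split(",")
    if len(cols) != 3:
        raise ValueError(f"bad hkl triplet: {triplet!r}")
    R = np.zeros((3, 3), dtype=int)
    names = {"h": 0, "k": 1, "l": 2}
    import re

    term = re.compile(r"([+-]?)(\d*)([hkl])")
    for j, expr in enumerate(cols):
        consumed = 0
        for mo in term.finditer(expr):
            sign = -1 if mo.group(1) == "-" else 1
            coef = int(mo.group(2)) if mo.group(2) else 1
            R[names[mo.group(3)], j] += sign * coef
            consumed += len(mo.group(0))
        if consumed != len(expr):
            raise ValueError(f"bad hkl triplet: {triplet!r}")
    return SymmetryOperation.from_matrix(R)


# ---------------------------------------------------------------------------
# named fixtures

FIXTURES = {
    "tetragonal-clean": SimulationConfig(
        space_group="P 41 21 2",
        n_datasets=10,
        d_min=3.2,
        noise=20.0,
        scale_range=(0.8, 1.2),
        b_range=(0.0, 3.0),
        seed=101,
    ),
    "R3H-ambiguity": SimulationConfig(
        space_group="R 3 :H",
        cell=(98.76, 98.76, 136.77, 90.0, 90.0, 120.0),
        n_datasets=12,
        d_min=6.0,
        wedge_width=15.0,
        noise=20.0,
        ambiguity_op="k,h,-l",
        ambiguity_fraction=0.5,
        seed=102,
    ),
    "two-population": SimulationConfig(
        space_group="P 41 21 2",
        n_datasets=16,
        d_min=3.2,
        noise=20.0,
        n_populations=2,
        between_cc=0.7,
        seed=103,
    ),
    "damaged": SimulationConfig(
        space_group="P 41 21 2",
        n_datasets=12,
        d_min=3.0,
        noise=20.0,
        damage_b_per_image=1.5,
        seed=104,
    ),
    "preferred-orientation": SimulationConfig(
        space_group="P 41 21 2",
        n_datasets=24,
        d_min=3.5,
        noise=15.0,
        orientation_axis=(0, 0, 1),
        orientation_sigma_deg=10.0,
        seed=105,
    ),
    "planted-outlier": SimulationConfig(
        space_group="P 41 21 2",
        n_datasets=24,
        d_min=3.2,
        noise=15.0,
        n_outliers=1,
        seed=106,
    ),
    "P21-absences": SimulationConfig(
        space_group="P 1 21 1",
        cell=(45.23, 54.68, 116.54, 90.0, 100.35, 90.0),
        n_datasets=12,
        d_min=4.0,
        wedge_width=20.0,
        noise=20.0,
        seed=107,
    ),
}


def make_fixture(name: str, directory, seed: int | None = None):
    """Write a named simulated collection (plus truth sidecar) to disk."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    config = FIXTURES[name]
    if seed is not None:
        config = SimulationConfig(**{**asdict(config), "seed": seed})
    collection, truth = simulate(config)
    directory = Path(directory)
    paths = write_collection(collection, directory, prefix=name.replace("-", "_"))
    sidecar = {
        "fixture": name,
        "space_group": config.space_group,
        "seed": config.seed,
        "scales": [float(x) for x in truth.scales],
        "b_factors": [float(x) for x in truth.b_factors],
        "population": [int(x) for x in truth.population],
        "outliers": [int(x) for x in truth.outliers],
        "reindex": [op.hkl_triplet() for op in truth.reindex_ops],
    }
    (directory / f"{name}.truth.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return paths, truth
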
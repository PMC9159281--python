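"""End-to-end multi-crystal workflow with a machine-readable report.

Stage order: read -> unit-cell filter -> symmetry analysis & re-indexing ->
2-theta cell refinement -> scaling -> resolution estimation -> re-scale at
the cutoff -> systematic absences / space group -> merging statistics ->
optional clustering / delta-CC1/2 filtering -> damage, orientation and
missing-region diagnostics.  Every stage's results land in a single JSON-
serialisable report with the configuration echoed for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import clustering, cosym, geometry, merging, scaling
from .refl_model import (
    DatasetCollection,
    SpaceGroupSetting,
    UnitCell,
    d_spacings,
    read_collection,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    space_group: str | None = None  # override automatic determination
    unit_cell: tuple | None = None
    dimensions: int | None = None
    min_common: int = 3
    cc_half_cutoff: float = 0.3
    filter_method: str | None = None  # None | "deltacchalf"
    deltacchalf_sigma: float = 3.0
    clustering_method: str | None = None  # None | "unit-cell" | "cc" | "cos-angle"
    unit_cell_threshold: float | None = None
    max_clusters: int | None = None
    min_completeness: float | None = None
    min_multiplicity: float | None = None
    absorption: str = "low"
    anomalous: bool = False
    d_min: float | None = None
    seed: int = 42
    resolution_cutoff_pass: bool = True  # second scaling pass at the cutoff

    def validate(self):
        if self.min_common < 1:
            raise ValueError("min_common must be >= 1")
        if not 0 < self.cc_half_cutoff < 1:
            raise ValueError("cc_half_cutoff must be in (0, 1)")
        if self.filter_method not in (None, "deltacchalf"):
            raise ValueError(f"unknown filter method {self.filter_method!r}")
        if self.clustering_method not in (None, "unit-cell", "cc", "cos-angle"):
            raise ValueError(f"unknown clustering method {self.clustering_method!r}")
        return self


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, float) and (obj != obj):  # NaN
        return None
    return obj


def run(paths, config: PipelineConfig | None = None) -> dict:
    """Run the full workflow on the given reflection-file paths.

    Returns the report as a plain dict (JSON-serialisable).
    """
    config = (config or PipelineConfig()).validate()
    report = {
        "version": __version__,
        "config": _jsonable(asdict(config)),
        "stages": [],
    }
    t_start = time.time()

    def stage(name):
        logger.info("stage: %s", name)
        report["stages"].append(name)

    try:
        stage("read")
        collection = read_collection(paths)
    except Exception as exc:
        raise StageError("read", exc) from exc
    if collection.n < 1:
        raise StageError("read", ValueError("no data sets"))
    report["n_datasets_input"] = collection.n
    if config.unit_cell is not None:
        cell = UnitCell(*config.unit_cell)
        for meta in collection.metas:
            meta.cell = cell

    # --- unit-cell filter -------------------------------------------------
    try:
        stage("unit-cell-filter")
        dendro, retained, rejected, cells = clustering.unit_cell_cluster(
            collection.metas, threshold=config.unit_cell_threshold
        )
        report["unit_cell_filter"] = {
            "rejected": rejected,
            "retained": retained,
            "cell_parameters": _jsonable(cells),
            "histograms": _jsonable(
                {
                    name: np.histogram(np.asarray(cells)[:, i], bins=10)[0]
                    for i, name in enumerate(["a", "b", "c", "alpha", "beta", "gamma"])
                }
                if len(cells)
                else {}
            ),
        }
        if rejected:
            collection = collection.subset(retained)
    except Exception as exc:
        raise StageError("unit-cell-filter", exc) from exc

    # --- symmetry analysis ------------------------------------------------
    try:
        stage("symmetry")
        if collection.n >= 2 and config.space_group is None:
            sym = cosym.analyse_symmetry(
                collection,
                min_common=config.min_common,
                seed=config.seed,
                dimensions=config.dimensions,
            )
            group = sym.best_group
            collection = cosym.apply_reindex(collection, sym.per_dataset_reindex)
            report["symmetry"] = {
                "lattice_group": sym.lattice.symbol,
                "lattice_order": sym.lattice.order,
                "dimensions": sym.embedding.d,
                "dimension_curve": _jsonable(sym.dimension_curve),
                "elements": [
                    {
                        "operation": e.operation.hkl_triplet(),
                        "likelihood": round(e.likelihood, 3),
                        "z_cc": None if e.z_cc != e.z_cc else round(e.z_cc, 3),
                        "cc": None if e.cc != e.cc else round(e.cc, 3),
                    }
                    for e in sym.element_scores
                ],
                "subgroups": [
                    {
                        "patterson_group": s.patterson_group.symbol,
                        "likelihood": round(s.likelihood, 4),
                        "net_z": round(s.net_z, 2),
                        "z_plus": round(s.z_plus, 2),
                        "z_minus": round(s.z_minus, 2),
                        "delta": round(s.delta, 2),
                        "reindex_op": s.reindex_op.hkl_triplet(),
                    }
                    for s in sym.subgroup_scores
                ],
                "best_patterson_group": group.symbol,
                "reindex": [op.hkl_triplet() for op in sym.per_dataset_reindex],
            }
        else:
            if collection.n < 2:
                logger.info("single data set: skipping symmetry analysis")
                report["symmetry"] = {"skipped": "single data set"}
            if config.space_group is not None:
                group = SpaceGroupSetting.from_symbol(config.space_group)
                group.centring = collection.metas[0].centring
                report.setdefault("symmetry", {})["user_space_group"] = config.space_group
            else:
                group = SpaceGroupSetting.from_symbol("P 1")
    except Exception as exc:
        raise StageError("symmetry", exc) from exc

    # --- unit-cell refinement against 2-theta ------------------------------
    try:
        stage("cell-refinement")
        refined = _refine_mean_cell(collection, group)
        report["refined_cell"] = _jsonable(
            {
                "parameters": refined[0].parameters,
                "esds": refined[1],
                "constraint": refined[2],
            }
        )
        best_cell = refined[0]
    except Exception as exc:
        raise StageError("cell-refinement", exc) from exc

    # --- scaling ------------------------------------------------------------
    try:
        stage("scaling")
        model_config = scaling.select_model(collection.metas)
        model_config.absorption_strength = config.absorption
        scaled = scaling.scale(
            collection, group, config=model_config, anomalous=config.anomalous
        )
        report["scaling"] = {
            "absorption": model_config.absorption,
            "error_model": {"a": scaled.error_model.a, "b": scaled.error_model.b},
            "residuals": _jsonable(scaled.residuals),
            "n_rejected": scaled.n_rejected,
            "per_dataset": [
                {
                    "dataset_id": m.dataset_id,
                    "scale": round(m.mid_scale(), 4),
                    "b_factor": round(m.mid_b(), 3),
                }
                for m in scaled.model.datasets
            ],
        }
        work = scaled.collection
    except Exception as exc:
        raise StageError("scaling", exc) from exc

    # --- resolution estimate + second scaling pass --------------------------
    try:
        stage("resolution")
        if config.d_min is not None:
            d_cut = config.d_min
            report["resolution"] = {"d_min": d_cut, "source": "user"}
        else:
            try:
                d_cut = merging.estimate_resolution(work, group, cc_cutoff=config.cc_half_cutoff)
                report["resolution"] = {
                    "d_min": round(d_cut, 3),
                    "cc_half_cutoff": config.cc_half_cutoff,
                    "source": "tanh fit",
                }
            except ValueError:
                d_cut = None
                report["resolution"] = {"d_min": None, "source": "insufficient bins"}
        if d_cut is not None and config.resolution_cutoff_pass:
            cut = merging.apply_resolution_cutoff(collection, d_cut)
            if cut.total_observations() > 0:
                scaled = scaling.scale(
                    cut, group, config=model_config, anomalous=config.anomalous
                )
                work = scaled.collection
    except Exception as exc:
        raise StageError("resolution", exc) from exc

    # --- optional clustering / filtering ------------------------------------
    try:
        if config.clustering_method == "cc":
            stage("cc-clustering")
            dendro, rep = clustering.cc_cluster(
                work,
                group,
                min_completeness=config.min_completeness,
                min_multiplicity=config.min_multiplicity,
                max_clusters=config.max_clusters,
            )
            report["cc_clusters"] = _cluster_report_json(dendro, rep)
        elif config.clustering_method == "cos-angle":
            stage("cos-angle-clustering")
            emb, cosmat = cosym.cosym_nonisomorphism(work, group, seed=config.seed)
            dendro, rep = clustering.cos_angle_cluster(
                work,
                group,
                cosmat,
                min_completeness=config.min_completeness,
                min_multiplicity=config.min_multiplicity,
                max_clusters=config.max_clusters,
            )
            report["cos_angle_clusters"] = _cluster_report_json(dendro, rep)
            report["cos_angle_clusters"]["vector_lengths"] = _jsonable(emb.lengths())
        if config.filter_method == "deltacchalf":
            stage("deltacchalf-filter")
            work, cycles = clustering.delta_cc_half_filter(
                work, group, sigma_cutoff=config.deltacchalf_sigma
            )
            report["deltacchalf"] = [
                {
                    "cycle": c.cycle,
                    "cc_half": round(c.cc_overall, 4),
                    "removed": c.removed,
                    "pct_reflections_removed": round(c.pct_reflections_removed, 2),
                }
                for c in cycles
            ]
    except Exception as exc:
        raise StageError("filtering", exc) from exc

    # --- absences / space group ---------------------------------------------
    try:
        stage("space-group")
        merged = merging.merge(work, group, anomalous=config.anomalous)
        scores, sg_symbol = merging.detect_absences(merged, group)
        report["space_group"] = {
            "symbol": sg_symbol,
            "patterson_group": group.symbol,
            "screw_axes": [
                {
                    "axis": s.axis,
                    "n_absent_obs": s.n_absent_obs,
                    "z_score": None if s.z_score is None else round(s.z_score, 2),
                    "likelihood": round(s.likelihood, 3),
                }
                for s in scores
            ],
        }
    except Exception as exc:
        raise StageError("space-group", exc) from exc

    # --- statistics -----------------------------------------------------------
    try:
        stage("statistics")
        stats = merging.statistics(work, group, anomalous=config.anomalous)
        report["merging_statistics"] = _stats_json(stats)
    except Exception as exc:
        raise StageError("statistics", exc) from exc

    # --- diagnostics -----------------------------------------------------------
    try:
        stage("diagnostics")
        curves = merging.damage_curves(work, group, scaled=scaled)
        report["damage"] = _jsonable(
            {
                "image": curves.image,
                "scale_vs_image": curves.scale_vs_image,
                "r_merge_vs_image": curves.r_merge_vs_image,
                "r_cp": curves.r_cp,
                "completeness_vs_dose": curves.completeness_vs_dose,
            }
        )
        proj = {}
        uniform = {}
        for axis in ((1, 0, 0), (0, 0, 1)):
            pts = geometry.stereographic_projection(work.metas, axis, group)
            proj["".join(map(str, axis))] = [
                {"dataset_id": p.dataset_id, "x": round(p.x, 4), "y": round(p.y, 4)}
                for p in pts
            ]
            stat, p, flagged = geometry.orientation_uniformity(work.metas, axis)
            uniform["".join(map(str, axis))] = {
                "statistic": None if stat is None else round(stat, 2),
                "p_value": None if p is None else round(p, 5),
                "flagged": flagged,
            }
        report["orientation"] = {"projections": proj, "uniformity": uniform}
        if d_cut is not None:
            H = merged.indices
            regions = geometry.missing_reflections(H, best_cell, group, max(d_cut, 1.0))
            report["missing_regions"] = [
                {
                    "count": r.count,
                    "fraction_pct": round(r.fraction_pct, 2),
                    "d_range": [round(r.d_range[0], 2), round(r.d_range[1], 2)],
                }
                for r in regions
            ]
    except Exception as exc:
        raise StageError("diagnostics", exc) from exc

    report["n_datasets_final"] = work.n
    report["runtime_s"] = round(time.time() - t_start, 2)
    return report


def _cluster_report_json(dendro, rep):
    return {
        "linkage": _jsonable(dendro.linkage),
        "leaves": list(dendro.leaves),
        "method": dendro.method,
        "clusters": [
            {
                "dataset_ids": c.dataset_ids,
                "height": round(c.height, 4),
                "completeness": None if c.completeness is None else round(c.completeness, 1),
                "multiplicity": None if c.multiplicity is None else round(c.multiplicity, 2),
            }
            for c in rep.clusters
        ],
        "selected": [c.dataset_ids for c in rep.selected],
    }


def _stats_json(stats):
    def bs(b):
        rnd = lambda v, k=4: None if v is None else round(v, k)
        return {
            "d_max": round(b.d_max, 3),
            "d_min": round(b.d_min, 3),
            "n_unique": b.n_unique,
            "completeness": rnd(b.completeness, 1),
            "multiplicity": rnd(b.multiplicity, 2),
            "r_merge": rnd(b.r_merge),
            "r_meas": rnd(b.r_meas),
            "r_pim": rnd(b.r_pim),
            "cc_half": rnd(b.cc_half),
            "cc_anom": rnd(b.cc_anom),
            "i_over_sigma": rnd(b.i_over_sigma, 2),
        }

    return {
        "overall": bs(stats.overall),
        "bins": [bs(b) for b in stats.bins],
        "highest_shell": bs(stats.highest_shell),
    }


def _refine_mean_cell(collection: DatasetCollection, group: SpaceGroupSetting):
    """Refine the best overall cell against synthetic-centroid 2-theta.

    Observed Bragg angles are derived from each data set's own cell (the
    per-crystal analogue of integrated centroid positions), pooled, and fit
    under the constraint implied by the Patterson group.
    """
    constraint = _constraint_for_group(group)
    H_all, tt_all = [], []
    for refl in collection.reflection_sets:
        meta = collection.meta(refl.dataset_id)
        n = min(refl.n_obs, 200)
        idx = np.linspace(0, refl.n_obs - 1, n).astype(int)
        H = refl.indices[idx]
        tt = geometry.two_theta_from_cell(H, meta.cell, meta.wavelength)
        H_all.append(H)
        tt_all.append(tt)
    H = np.concatenate(H_all)
    tt = np.concatenate(tt_all)
    wavelength = float(np.mean([m.wavelength for m in collection.metas]))
    cell, esds = geometry.refine_cell_2theta(
        H, tt, collection.mean_cell(), wavelength, constraint=constraint
    )
    return cell, esds, constraint


def _constraint_for_group(group: SpaceGroupSetting) -> str:
    orders = sorted(op.order() for op in group.rotations())
    n = len(orders)
    if group.centring == "R" or 3 in orders and max(orders) in (3, 6):
        return "rhombohedral-H" if group.centring == "R" else "hexagonal"
    if max(orders, default=1) == 4:
        return "tetragonal"
    if n >= 4 and max(orders) == 2:
        return "orthorhombic"
    if n == 2:
        return "monoclinic-b"
    if orders.count(3) >= 4:
        return "cubic"
    return "triclinic"


def write_report(report: dict, path):
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
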
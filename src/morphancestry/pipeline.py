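"""End-to-end orchestration of the two ancestry-correction routes.

The **genetic-PC route** runs selection → symmetrization → GPA → covariate
PLSR correction → ancestry PLSR correction (first k genetic PCs) →
permutation tables → effect maps. The **consensus route** reuses the same
covariate-corrected cohort, builds regional consensus faces, applies the
(optionally admixture-weighted) consensus correction, re-runs the
permutation tests and compares the two methods' regional faces.

Every run is driven by a single config (YAML-loadable), is deterministic
given its seed, and writes a JSON run report with a checksummed manifest of
every emitted file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, synthetic_cohort
from .covariate_model import (STANDARD_COVARIATES, ancestry_correct, correct,
                              exaggerate, single_pc_effect)
from .consensus import build_consensus, retest_after_consensus, \
    apply_consensus_correction
from .effect_maps import (compare_correction_methods, max_ancestry_shift,
                          normal_displacement, vertex_normals)
from .perm_test import subgroup_tests
from .regional_select import select_cohort
from .shape_align import gpa, symmetrize_cohort, centroid_size

__all__ = ["PipelineConfig", "RunReport", "run_genetic_pc_route",
           "run_consensus_route", "prepare_corrected_cohort"]

log = logging.getLogger("morphancestry")


@dataclass
class PipelineConfig:
    """Protocol constants and run settings.

    Defaults are the full study protocol: 186 individuals per region, the
    first 4 ancestry PCs for correction, 20 PCs for the visualization base
    face and the test tables, 96% shape-PCA variance, 10,000 permutations,
    4x regional / 8x single-PC exaggeration.
    """

    output_dir: str = "results/run"
    seed: int = 0
    simulate: dict | None = None        # GeneratorConfig overrides, or None
    shapes_path: str | None = None
    covariates_path: str | None = None
    eigenvec_path: str | None = None
    q_path: str | None = None
    template_path: str | None = None
    regions: tuple[str, ...] = synthetic_cohort.DEFAULT_REGIONS
    n_per_region: int = 186
    k_ancestry_pcs: int = 4
    k_visual_pcs: int = 20
    var_threshold: float = 0.96
    B: int = 10_000
    exaggeration: dict = field(default_factory=lambda: {"regional": 4, "single_pc": 8})
    weighted_consensus: bool = False

    def __post_init__(self) -> None:
        if not self.k_ancestry_pcs <= self.k_visual_pcs:
            raise ValueError("k_ancestry_pcs must be <= k_visual_pcs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["regions"] = list(payload["regions"])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    route: str
    config_hash: str
    seed: int
    timings: dict[str, float]
    warnings: list[str]
    manifest: dict[str, str]            # relative path -> sha256

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, root: Path):
        self.root = root
        self.entries: dict[str, str] = {}

    def add(self, path: Path) -> None:
        self.entries[str(path.relative_to(self.root))] = _sha256(path)

    def add_df(self, df: pd.DataFrame, path: Path, **kwargs) -> None:
        df.to_csv(path, index=False, float_format="%.10g", **kwargs)
        self.add(path)


def _load_inputs(cfg: PipelineConfig):
    """Simulate or load the raw cohort (shapes + covariates + PCs + Q)."""
    if cfg.simulate is not None:
        gen_kwargs = dict(cfg.simulate)
        gen_kwargs.setdefault("seed", cfg.seed)
        gen_kwargs.setdefault("n_per_region", cfg.n_per_region)
        gcfg = synthetic_cohort.GeneratorConfig(**gen_kwargs)
        cohort = synthetic_cohort.generate_cohort(gcfg)
        return (cohort.shapes, cohort.covariates, cohort.pcs, cohort.q,
                cohort.template)
    template = io_formats.read_template_json(cfg.template_path)
    shapes = io_formats.read_shapes(cfg.shapes_path, template)
    covariates = io_formats.CovariateTable(pd.read_csv(cfg.covariates_path))
    pcs = io_formats.read_eigenvec(cfg.eigenvec_path)
    q = io_formats.read_q(cfg.q_path, shapes.ids, cfg.regions)
    return shapes, covariates, pcs, q, template


def prepare_corrected_cohort(cfg: PipelineConfig):
    """Shared front end of both routes: select → symmetrize → GPA →
    covariate-correct. Returns a dict of the intermediates."""
    shapes, covariates, pcs, q, template = _load_inputs(cfg)

    assignment = select_cohort(q, cfg.n_per_region, seed=cfg.seed,
                               region_names=list(cfg.regions))
    mask = assignment.selected_mask()
    shapes = shapes.subset(mask)
    pcs = pcs.subset(mask)
    q = q.subset(mask)
    cov = io_formats.CovariateTable(covariates.table.loc[mask].copy())
    labels = assignment.table.loc[mask, "region"].to_numpy()

    sym = symmetrize_cohort(shapes, template)
    aligned = gpa(sym)
    cov.table["centroid_size"] = aligned.centroid_sizes

    X = cov.design_matrix(STANDARD_COVARIATES)
    corrected = correct(aligned.shapes, X,
                        predictor_names=list(STANDARD_COVARIATES))
    return {
        "template": template, "assignment": assignment, "labels": labels,
        "aligned": aligned, "corrected": corrected, "pcs": pcs, "q": q,
        "covariates": cov,
    }


def _checksum_shapes(shapes) -> str:
    return hashlib.sha256(np.ascontiguousarray(shapes.coords).tobytes()).hexdigest()[:16]


def run_genetic_pc_route(cfg: PipelineConfig, prepared: dict | None = None
                         ) -> RunReport:
    """Genetic-PC ancestry description: correct with the first k ancestry
    PCs, tabulate per-PC permutation tests for every regional group, and
    export regional/single-PC effect faces and displacement maps."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    timings: dict[str, float] = {}
    warns: list[str] = []

    t0 = time.time()
    prepared = prepared or prepare_corrected_cohort(cfg)
    timings["prepare"] = time.time() - t0
    corrected, pcs, labels = prepared["corrected"], prepared["pcs"], prepared["labels"]
    template = prepared["template"]
    log.info("prepared corrected cohort: n=%d, L=%d",
             corrected.shapes.n, corrected.shapes.n_landmarks)

    manifest.add_df(prepared["assignment"].counts(), out / "regional_counts.csv")

    t0 = time.time()
    anc_corrected, effect = ancestry_correct(
        corrected, pcs, k=cfg.k_ancestry_pcs, labels=labels)
    timings["ancestry_correct"] = time.time() - t0

    # visualization base face: covariates + first k_visual_pcs PCs removed
    k_vis = min(cfg.k_visual_pcs, pcs.n_pcs)
    vis_corrected = correct(
        corrected.shapes, pcs.scores[:, :k_vis],
        predictor_names=[f"PC{j+1}" for j in range(k_vis)])
    base_face = vis_corrected.shapes.coords.mean(axis=0)

    normals = vertex_normals(base_face, template.triangulation)
    shift = max_ancestry_shift(corrected.shapes, anc_corrected.shapes)
    io_formats.write_scalar_map(template, shift, out / "max_ancestry_shift")
    manifest.add(out / "max_ancestry_shift.ply")
    manifest.add(out / "max_ancestry_shift.csv")

    regional_faces = {}
    for region, field_ in effect.per_region.items():
        face = exaggerate(base_face, field_, cfg.exaggeration["regional"])
        regional_faces[region] = base_face + field_
        io_formats.write_mesh_ply(face, template.triangulation,
                                  out / f"regional_face_{region}.ply")
        manifest.add(out / f"regional_face_{region}.ply")
        nd = normal_displacement(base_face, base_face + field_, normals)
        io_formats.write_scalar_map(template, nd,
                                    out / f"regional_displacement_{region}")
        manifest.add(out / f"regional_displacement_{region}.csv")
        manifest.add(out / f"regional_displacement_{region}.ply")

    for j in range(1, cfg.k_ancestry_pcs + 1):
        per_indiv, _ = single_pc_effect(corrected, pcs, exclude=j,
                                        k=cfg.k_ancestry_pcs)
        for region in dict.fromkeys(labels.tolist()):
            field_ = per_indiv[labels == region].mean(axis=0)
            face = exaggerate(base_face, field_,
                              cfg.exaggeration["single_pc"])
            io_formats.write_mesh_ply(
                face, template.triangulation,
                out / f"single_pc_face_PC{j}_{region}.ply")
            manifest.add(out / f"single_pc_face_PC{j}_{region}.ply")

    t0 = time.time()
    table = subgroup_tests(
        pcs.scores, corrected.shapes, labels,
        pc_list=list(range(1, k_vis + 1)),
        combos=[list(range(1, cfg.k_ancestry_pcs + 1))],
        var_threshold=cfg.var_threshold, B=cfg.B, seed=cfg.seed)
    timings["permutation_tests"] = time.time() - t0
    manifest.add_df(table, out / "perm_table_long.csv")
    pivot = table.pivot(index="predictor_set", columns="group", values="p")
    pivot.to_csv(out / "perm_table_pvalues.csv", float_format="%.4g")
    manifest.add(out / "perm_table_pvalues.csv")

    for region, field_ in effect.per_region.items():
        df = pd.DataFrame(field_, columns=["dx", "dy", "dz"])
        df.insert(0, "landmark_index", np.arange(1, len(field_) + 1))
        manifest.add_df(df, out / f"regional_effect_field_{region}.csv")

    report = RunReport(
        route="genetic_pc",
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        timings=timings,
        warnings=warns,
        manifest=manifest.entries,
    )
    report.save(out / "run_report_genetic_pc.json")
    # stash intermediates so the consensus route can share them
    prepared["_pc_route"] = {
        "base_face": base_face,
        "regional_faces": regional_faces,
        "perm_table": table,
        "corrected_checksum": _checksum_shapes(corrected.shapes),
    }
    return report


def run_consensus_route(cfg: PipelineConfig, prepared: dict | None = None
                        ) -> RunReport:
    """Consensus-face ancestry description: build regional consensus faces
    from the covariate-corrected cohort, apply (weighted) consensus
    correction, re-run the permutation tests, and compare against the
    genetic-PC regional faces."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    timings: dict[str, float] = {}
    warns: list[str] = []

    t0 = time.time()
    prepared = prepared or prepare_corrected_cohort(cfg)
    timings["prepare"] = time.time() - t0
    corrected, pcs, labels = prepared["corrected"], prepared["pcs"], prepared["labels"]
    template = prepared["template"]

    t0 = time.time()
    store = build_consensus(corrected.shapes, labels)
    timings["consensus"] = time.time() - t0
    for path in store.save(out / "consensus_store"):
        manifest.add(path)

    q = prepared["q"].proportions if cfg.weighted_consensus else None
    t0 = time.time()
    retest = retest_after_consensus(
        store, pcs, labels,
        pc_list=list(range(1, min(cfg.k_visual_pcs, pcs.n_pcs) + 1)),
        var_threshold=cfg.var_threshold, B=cfg.B, seed=cfg.seed, q=q)
    timings["retest"] = time.time() - t0
    manifest.add_df(retest, out / "perm_table_before_after_consensus.csv")

    corrected_cohort = apply_consensus_correction(store, labels=labels, q=q)
    df = pd.DataFrame({"id": corrected_cohort.ids})
    manifest.add_df(df, out / "consensus_corrected_ids.csv")

    if "_pc_route" not in prepared:
        run_genetic_pc_route(cfg, prepared)
    pc_route = prepared["_pc_route"]
    base_face = pc_route["base_face"]
    consensus_faces = {
        r: base_face + (store.faces[r].mean_shape - store.grand_mean)
        for r in store.faces}
    t0 = time.time()
    comparison = compare_correction_methods(
        pc_route["regional_faces"], consensus_faces, base_face,
        template.triangulation)
    timings["method_comparison"] = time.time() - t0
    summary_rows = []
    for region, emap in comparison.items():
        io_formats.write_scalar_map(
            template, emap.normal_displacement,
            out / f"method_comparison_displacement_{region}")
        manifest.add(out / f"method_comparison_displacement_{region}.csv")
        manifest.add(out / f"method_comparison_displacement_{region}.ply")
        io_formats.write_scalar_map(
            template, emap.angle_difference,
            out / f"method_comparison_angle_{region}")
        manifest.add(out / f"method_comparison_angle_{region}.csv")
        manifest.add(out / f"method_comparison_angle_{region}.ply")
        summary_rows.append({"region": region, **emap.summary()})
    manifest.add_df(pd.DataFrame(summary_rows),
                    out / "method_comparison_summary.csv")

    report = RunReport(
        route="consensus",
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        timings=timings,
        warnings=warns,
        manifest=manifest.entries,
    )
    report.save(out / "run_report_consensus.json")
    return report
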
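"""End-to-end orchestration: simulate -> align -> skeleton stats -> decode.

A single YAML-configurable run generates a synthetic cohort, registers every
animal's FA map to the anatomical template, runs the skeleton permutation
analysis for the four sex-by-direction contrasts, transfers the significant
clusters onto the expression grid, and scores the gene panel against them.
Every stage seeds its randomness from the run's global seed with a fixed
offset, so stages are independently reproducible and a re-run with the same
config produces byte-identical outputs (NIfTI files are written
uncompressed so hashes are stable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .core_volumes import AffineTransform, Volume, write_volume
from .expression_overlap import (
    classify_genes,
    exclusivity_report,
    load_gene_panel,
    map_clusters_to_expression_grid,
    overexpressed_lists,
    render_report,
    transport_mask,
)
from .registration import RegistrationConfig, affine_register, resample
from .skeleton_stats import analyze_cohort
from .synthetic_data import (
    CohortSpec,
    ExpressionPanelSpec,
    PhantomSpec,
    make_energy_maps,
    make_fa_cohort,
    make_template,
)

__all__ = ["RunConfig", "StatsConfig", "OverlapConfig", "validate_config", "run_pipeline"]


@dataclass
class StatsConfig:
    fa_threshold: float = 0.2
    n_perm: int = 500
    alpha: float = 0.05
    search_radius: int = 4


@dataclass
class OverlapConfig:
    alpha: float = 0.05
    correction: Optional[str] = None
    exclude_cluster_from_skeleton: bool = False


@dataclass
class RunConfig:
    """Everything a run needs; serializable to/from YAML."""

    outdir: str = "runs/demo"
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    expression: ExpressionPanelSpec = field(default_factory=ExpressionPanelSpec)
    registration: RegistrationConfig = field(
        default_factory=lambda: RegistrationConfig(
            metric="ncc", rot_search_deg=0.0, coarse_search=False
        )
    )
    stats: StatsConfig = field(default_factory=StatsConfig)
    overlap: OverlapConfig = field(default_factory=OverlapConfig)

    def __post_init__(self) -> None:
        # fan the global seed out to the stochastic stages by fixed offsets
        self.phantom.rng_seed = int(self.seed)
        self.cohort.rng_seed = int(self.seed) + 1
        self.expression.rng_seed = int(self.seed) + 2

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw: dict = {}
        if "outdir" in d:
            kw["outdir"] = d["outdir"]
        if "seed" in d:
            kw["seed"] = int(d["seed"])
        if "phantom" in d:
            ph = dict(d["phantom"])
            if "grid_shape" in ph:
                ph["grid_shape"] = tuple(int(v) for v in ph["grid_shape"])
            kw["phantom"] = PhantomSpec(**ph)
        if "cohort" in d:
            co = dict(d["cohort"])
            if "n_per_group" in co:
                co["n_per_group"] = tuple(int(v) for v in co["n_per_group"])
            if "misalignment_sd" in co:
                co["misalignment_sd"] = tuple(float(v) for v in co["misalignment_sd"])
            kw["cohort"] = CohortSpec(**co)
        if "expression" in d:
            ex = dict(d["expression"])
            if "enriched_sets" in ex:
                ex["enriched_sets"] = {
                    region: (tuple(genes), float(factor))
                    for region, (genes, factor) in ex["enriched_sets"].items()
                }
            kw["expression"] = ExpressionPanelSpec(**ex)
        if "registration" in d:
            kw["registration"] = RegistrationConfig(**d["registration"])
        if "stats" in d:
            kw["stats"] = StatsConfig(**d["stats"])
        if "overlap" in d:
            kw["overlap"] = OverlapConfig(**d["overlap"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [enc(v) for v in obj]
            return obj
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "phantom": enc(self.phantom),
            "cohort": enc(self.cohort),
            "expression": {
                "genes": list(self.expression.genes),
                "enriched_sets": {
                    r: [list(g), f] for r, (g, f) in self.expression.enriched_sets.items()
                },
                "baseline_level": self.expression.baseline_level,
                "noise_sigma": self.expression.noise_sigma,
                "rng_seed": self.expression.rng_seed,
            },
            "registration": enc(self.registration),
            "stats": enc(self.stats),
            "overlap": enc(self.overlap),
        }


def validate_config(config: RunConfig) -> List[str]:
    """Collect every invariant violation as a named-key message (no throw)."""
    issues: List[str] = []
    issues += [f"cohort: {m}" for m in config.cohort.validate()]
    issues += [f"registration: {m}" for m in config.registration.validate()]
    st = config.stats
    if st.n_perm < 1:
        issues.append("stats.n_perm must be >= 1")
    if not (0 < st.alpha < 1):
        issues.append("stats.alpha must lie in (0, 1)")
    if not (0 < st.fa_threshold < 1):
        issues.append("stats.fa_threshold must lie in (0, 1)")
    if st.search_radius < 0:
        issues.append("stats.search_radius must be >= 0")
    ov = config.overlap
    if not (0 < ov.alpha < 1):
        issues.append("overlap.alpha must lie in (0, 1)")
    if ov.correction not in (None, "bh"):
        issues.append("overlap.correction must be null or 'bh'")
    if np.asarray(config.phantom.spacing).min() <= 0:
        issues.append("phantom.spacing must be > 0")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and persist) the run manifest.

    The manifest records the full config, per-stage seeds and wall times,
    SHA-256 hashes of every output file, and the headline results (clusters
    per contrast, overexpressed gene lists, exclusive sets).  A stage
    failure persists the partial manifest before re-raising with the stage
    name.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
        "summary": {},
    }

    def persist():
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)

    def record(stage: str, t0: float, files: Dict[str, Path]):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for k, p in files.items():
            manifest["outputs"][k] = {"path": str(p), "sha256": _sha256(p)}
        persist()

    stage = "simulate"
    try:
        t0 = time.time()
        template = make_template(config.phantom)
        animals = make_fa_cohort(config.phantom, config.cohort)
        files: Dict[str, Path] = {}
        sim_dir = outdir / "simulate"
        sim_dir.mkdir(exist_ok=True)
        write_volume(template, sim_dir / "template.nii")
        files["template"] = sim_dir / "template.nii"
        meta_rows = []
        truth = {}
        for meta, vol, t_true in animals:
            p = sim_dir / f"fa_{meta.animal_id}.nii"
            write_volume(vol, p)
            files[f"fa_{meta.animal_id}"] = p
            meta_rows.append({"animal_id": meta.animal_id, "sex": meta.sex,
                              "genotype": meta.genotype, "file": p.name})
            truth[meta.animal_id] = t_true.to_dict("animal", "template")
        pd.DataFrame(meta_rows).to_csv(sim_dir / "meta.tsv", sep="\t", index=False)
        files["meta"] = sim_dir / "meta.tsv"
        with open(sim_dir / "true_transforms.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        files["true_transforms"] = sim_dir / "true_transforms.json"
        manifest["stages"]["simulate_seeds"] = {
            "phantom": config.phantom.rng_seed, "cohort": config.cohort.rng_seed}
        record(stage, t0, files)
    except Exception:
        manifest["failed_stage"] = stage
        persist()
        raise

    stage = "register"
    try:
        t0 = time.time()
        misaligned = any(j > 0 for j in config.cohort.misalignment_sd)
        grid = config.phantom.diffusion_grid()
        from .synthetic_data import base_fa_map
        target = base_fa_map(config.phantom)
        aligned: List[Volume] = []
        est_transforms = {}
        for meta, vol, _t_true in animals:
            if misaligned:
                t_est = affine_register(vol, target, config.registration)
            else:
                t_est = AffineTransform.identity()
            est_transforms[meta.animal_id] = t_est.to_dict("animal", "template")
            aligned.append(resample(vol, t_est, grid, mode="trilinear"))
        reg_dir = outdir / "register"
        reg_dir.mkdir(exist_ok=True)
        with open(reg_dir / "estimated_transforms.json", "w") as fh:
            json.dump(est_transforms, fh, indent=1, sort_keys=True)
        record(stage, t0, {"estimated_transforms": reg_dir / "estimated_transforms.json"})
    except Exception:
        manifest["failed_stage"] = stage
        persist()
        raise

    stage = "skeleton_stats"
    try:
        t0 = time.time()
        metas = [m for m, _, _ in animals]
        skel, results = analyze_cohort(
            aligned, metas,
            fa_threshold=config.stats.fa_threshold,
            search_radius=config.stats.search_radius,
            n_perm=config.stats.n_perm,
            alpha=config.stats.alpha,
            seed=config.seed + 3,
        )
        st_dir = outdir / "stats"
        st_dir.mkdir(exist_ok=True)
        files = {}
        write_volume(skel.mean_fa, st_dir / "mean_fa.nii")
        files["mean_fa"] = st_dir / "mean_fa.nii"
        write_volume(Volume(skel.mask.data.astype(np.float32), skel.mask.affine_vox2world),
                     st_dir / "skeleton_mask.nii")
        files["skeleton_mask"] = st_dir / "skeleton_mask.nii"
        cluster_rows = []
        for cname, res in results.items():
            write_volume(res.p_map(), st_dir / f"{cname}_corrp.nii")
            files[f"{cname}_corrp"] = st_dir / f"{cname}_corrp.nii"
            write_volume(res.tfce_map(), st_dir / f"{cname}_tfce.nii")
            files[f"{cname}_tfce"] = st_dir / f"{cname}_tfce.nii"
            label = np.zeros(skel.mean_fa.shape, dtype=np.float32)
            for cl in res.clusters:
                label[tuple(cl.voxels.T)] = cl.cluster_id
                peak_vox = cl.voxels[0]
                cluster_rows.append({
                    "contrast": cname, "cluster_id": cl.cluster_id, "size": cl.size,
                    "peak_stat": round(cl.peak_stat, 4),
                    "first_voxel": " ".join(map(str, peak_vox)),
                })
            write_volume(Volume(label, skel.mean_fa.affine_vox2world),
                         st_dir / f"{cname}_clusters.nii")
            files[f"{cname}_clusters"] = st_dir / f"{cname}_clusters.nii"
        pd.DataFrame(cluster_rows, columns=["contrast", "cluster_id", "size",
                                            "peak_stat", "first_voxel"]
                     ).to_csv(st_dir / "clusters.tsv", sep="\t", index=False)
        files["clusters"] = st_dir / "clusters.tsv"
        manifest["summary"]["contrasts"] = {
            c: {"n_significant_voxels": int((results[c].corrected_p < config.stats.alpha).sum()),
                "n_clusters": len(results[c].clusters)}
            for c in results
        }
        record(stage, t0, files)
    except Exception:
        manifest["failed_stage"] = stage
        persist()
        raise

    stage = "expression_overlap"
    try:
        t0 = time.time()
        energy = make_energy_maps(config.phantom, config.expression)
        expr_grid = config.phantom.expression_grid()
        identity = AffineTransform.identity()  # shared world frame, grids differ
        cluster_masks = {
            c: map_clusters_to_expression_grid(results[c].clusters, identity, expr_grid, grid)
            for c in results
        }
        skel_expr = transport_mask(skel.mask, identity, expr_grid)
        panel = load_gene_panel()
        gene_results = classify_genes(
            energy, cluster_masks, skel_expr, panel=panel,
            alpha=config.overlap.alpha, correction=config.overlap.correction,
            exclude_cluster_from_skeleton=config.overlap.exclude_cluster_from_skeleton,
        )
        lists = overexpressed_lists(gene_results)
        excl = exclusivity_report(lists, panel)
        rep_dir = outdir / "expression"
        render_report(gene_results, excl, rep_dir)
        files = {k: rep_dir / f"{k}.tsv" for k in ("gene_overlap", "table2_matrix")}
        files["exclusivity"] = rep_dir / "exclusivity.json"
        manifest["summary"]["overexpressed"] = lists
        manifest["summary"]["exclusive"] = excl.exclusive
        manifest["summary"]["n_gene_results"] = len(
            [r for r in gene_results if r.status != "no_map"])
        record(stage, t0, files)
    except Exception:
        manifest["failed_stage"] = stage
        persist()
        raise

    persist()
    return manifest
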
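"""Synthetic brain phantoms with known ground truth.

The real study rests on inputs that cannot be redistributed here: ex vivo
diffusion MRI of a hemideletion mouse cohort and atlas in situ hybridization
energy volumes.  This module generates stand-ins for every one of them with
plantable, exactly known ground truth, so each downstream stage (alignment,
skeleton statistics, expression decoding) can be tested end to end:

* a brain-shaped template with internal structures -- a "callosal" sheet, a
  medial "peristriatal" tube and a "cerebellar" blob -- defined analytically
  in world coordinates;
* per-animal FA volumes on a 0.125 mm grid: tract-like high-FA structures,
  sex-by-genotype FA offsets, additive Gaussian noise and a small random
  affine misalignment per animal (whose true transform is returned);
* per-gene expression "energy" volumes on a 0.2 mm grid: log-normal baseline
  inside the brain, a -1 missing-data sentinel outside, and multiplicative
  enrichment of chosen gene subsets inside chosen structures.

The default cohort (6 male WT, 4 male del/+, 6 female WT, 5 female del/+)
and the default effect pattern (male-only FA increase in the medial tube,
both-sex FA decrease in the callosal sheet, small female-only cerebellar
increase) mirror the study conditions the pipeline is meant to analyse.
Everything is bit-deterministic under (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core_volumes import AffineTransform, Volume, volume_from_spacing
from .expression_overlap import available_genes, load_gene_panel
from .registration import resample

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "ExpressionPanelSpec",
    "AnimalMeta",
    "make_template",
    "make_fa_cohort",
    "make_energy_maps",
    "make_misaligned_pair",
    "structure_masks",
    "brain_mask",
]

GROUPS = ("male_wt", "male_del", "female_wt", "female_del")

#: FA plateau of each tract-like structure and of brain background.
FA_LEVELS = {"sheet": 0.60, "tube": 0.60, "blob": 0.55}
FA_BACKGROUND = 0.10


def _default_structures(grid_shape, spacing) -> Dict[str, dict]:
    """Structure geometry in world mm, scaled to the grid's world extent."""
    shape = np.asarray(grid_shape, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    if sp.shape == ():
        sp = np.repeat(sp, 3)
    extent = shape * sp
    c = extent / 2.0
    b = 0.42 * extent  # brain semi-axes
    return {
        "brain": {"type": "ellipsoid", "center": c.tolist(), "semiaxes": b.tolist()},
        "sheet": {
            "type": "slab",
            "center": [c[0], c[1], c[2] + 0.35 * b[2]],
            "normal_axis": 2,
            "half_thickness": 1.6 * float(sp[2]),
            "half_extent": [0.70 * b[0], 0.55 * b[1]],
        },
        "tube": {
            "type": "cylinder",
            "center": [c[0], c[1] + 0.14 * b[1], c[2] - 0.15 * b[2]],
            "axis": 1,
            "radius": 2.8 * float(sp[0]),
            "half_length": 0.50 * b[1],
        },
        "blob": {
            "type": "sphere",
            "center": [c[0], c[1] - 0.72 * b[1], c[2] - 0.15 * b[2]],
            "radius": 0.20 * b[1],
        },
    }


@dataclass
class PhantomSpec:
    """Geometry of the synthetic brain and its internal structures."""

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    spacing: float = 0.125
    expression_spacing: float = 0.2
    structures: Optional[Dict[str, dict]] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.structures is None:
            self.structures = _default_structures(self.grid_shape, self.spacing)
        extent = np.asarray(self.grid_shape) * self.spacing
        for name, s in self.structures.items():
            center = np.asarray(s["center"], dtype=float)
            if np.any(center < 0) or np.any(center > extent):
                raise ValueError(f"structure {name!r} centre {center} lies outside the grid")

    def diffusion_grid(self) -> Volume:
        return volume_from_spacing(np.zeros(self.grid_shape, dtype=float), self.spacing)

    def expression_grid(self) -> Volume:
        extent = np.asarray(self.grid_shape) * self.spacing
        shape = tuple(int(np.ceil(e / self.expression_spacing)) for e in extent)
        return volume_from_spacing(np.zeros(shape, dtype=float), self.expression_spacing,
                                   missing_value=-1.0)


@dataclass
class CohortSpec:
    """Group sizes, planted effects and nuisance parameters of a cohort.

    ``effect_map`` maps structure name -> {group -> FA offset} with groups in
    ``("male_wt", "male_del", "female_wt", "female_del")``.  The default
    counts (6, 4, 6, 5) match the analysed cohort of 12 wild types and 9
    del/+ animals; ``misalignment_sd`` is (mm, deg, scale) jitter.
    """

    n_per_group: Tuple[int, int, int, int] = (6, 4, 6, 5)  # male_wt, male_del, female_wt, female_del
    effect_map: Dict[str, Dict[str, float]] = field(default_factory=lambda: {
        "tube": {"male_del": 0.15},
        "sheet": {"male_del": -0.10, "female_del": -0.10},
        "blob": {"female_del": 0.05},
    })
    noise_sd: float = 0.03
    misalignment_sd: Tuple[float, float, float] = (0.15, 1.5, 0.01)
    rng_seed: int = 0

    def validate(self) -> List[str]:
        issues = []
        if any(n < 2 for n in self.n_per_group):
            issues.append("n_per_group: every group needs >= 2 animals for statistics")
        if self.noise_sd < 0:
            issues.append("noise_sd must be >= 0")
        if any(j < 0 for j in self.misalignment_sd):
            issues.append("misalignment_sd entries must be >= 0")
        for s, groups in self.effect_map.items():
            for g in groups:
                if g not in GROUPS:
                    issues.append(f"effect_map[{s!r}]: unknown group {g!r}")
        return issues


@dataclass
class ExpressionPanelSpec:
    """Which genes get synthetic energy maps and where enrichment is planted.

    ``enriched_sets`` maps structure name -> (gene subset, multiplicative
    enrichment factor > 1).  The default panel is every gene of the deletion
    panel with an available map (26 genes) and plants a three-gene set in the
    medial tube -- the structure carrying the male-specific FA increase -- so
    the end-to-end recovery of that exclusive set can be verified.
    """

    genes: Optional[Sequence[str]] = None
    enriched_sets: Dict[str, Tuple[Tuple[str, ...], float]] = field(default_factory=lambda: {
        "tube": (("Mvp", "Sez6l2", "Taok2"), 3.0),
        "sheet": (("Kctd13", "AldoA"), 3.0),
        "blob": (("Kif22",), 3.0),
    })
    baseline_level: float = 1.0
    noise_sigma: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genes is None:
            self.genes = tuple(available_genes(load_gene_panel()))
        self.genes = tuple(self.genes)
        for region, (subset, factor) in self.enriched_sets.items():
            unknown = set(subset) - set(self.genes)
            if unknown:
                raise ValueError(f"enriched_sets[{region!r}] names genes outside the panel: {sorted(unknown)}")
            if factor <= 1:
                raise ValueError(f"enrichment factor for {region!r} must be > 1, got {factor}")


@dataclass
class AnimalMeta:
    animal_id: str
    sex: str        # "male" | "female"
    genotype: str   # "wt" | "del"

    @property
    def group(self) -> str:
        return f"{self.sex}_{self.genotype}"


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _world_coords(grid: Volume) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = [np.arange(s, dtype=float) for s in grid.shape]
    I, J, K = np.meshgrid(*idx, indexing="ij")
    A = grid.affine_vox2world
    x = A[0, 0] * I + A[0, 1] * J + A[0, 2] * K + A[0, 3]
    y = A[1, 0] * I + A[1, 1] * J + A[1, 2] * K + A[1, 3]
    z = A[2, 0] * I + A[2, 1] * J + A[2, 2] * K + A[2, 3]
    return x, y, z


def _structure_mask(s: dict, x, y, z) -> np.ndarray:
    kind = s["type"]
    c = np.asarray(s["center"], dtype=float)
    if kind == "ellipsoid":
        a = np.asarray(s["semiaxes"], dtype=float)
        return ((x - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2 + ((z - c[2]) / a[2]) ** 2 <= 1.0
    if kind == "sphere":
        r = float(s["radius"])
        return (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r * r
    if kind == "slab":
        axes = [x, y, z]
        n = int(s["normal_axis"])
        in_plane = [i for i in range(3) if i != n]
        he = np.asarray(s["half_extent"], dtype=float)
        m = np.abs(axes[n] - c[n]) <= float(s["half_thickness"])
        for hi, ai in zip(he, in_plane):
            m &= np.abs(axes[ai] - c[ai]) <= hi
        return m
    if kind == "cylinder":
        axes = [x, y, z]
        ax = int(s["axis"])
        perp = [i for i in range(3) if i != ax]
        r = float(s["radius"])
        m = (axes[perp[0]] - c[perp[0]]) ** 2 + (axes[perp[1]] - c[perp[1]]) ** 2 <= r * r
        m &= np.abs(axes[ax] - c[ax]) <= float(s["half_length"])
        return m
    raise ValueError(f"unknown structure type {kind!r}")


def structure_masks(spec: PhantomSpec, grid: Volume, soft: bool = True) -> Dict[str, np.ndarray]:
    """Evaluate every structure of ``spec`` on ``grid``.

    Soft masks are the hard analytic masks smoothed by a 1-voxel Gaussian
    (values in [0, 1]); they give structures gentle edges at any resolution.
    All structures are clipped to the brain shell.
    """
    x, y, z = _world_coords(grid)
    brain = _structure_mask(spec.structures["brain"], x, y, z)
    out: Dict[str, np.ndarray] = {}
    for name, s in spec.structures.items():
        m = _structure_mask(s, x, y, z)
        if name != "brain":
            m = m & brain
        out[name] = ndimage.gaussian_filter(m.astype(float), sigma=1.0) if soft else m
    return out


def brain_mask(spec: PhantomSpec, grid: Volume) -> np.ndarray:
    x, y, z = _world_coords(grid)
    return _structure_mask(spec.structures["brain"], x, y, z)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_template(spec: PhantomSpec) -> Volume:
    """A smooth anatomical template: brain shell plus internal contrast.

    Background is exactly 0; internal structures modulate the intensity so
    that registration metrics have something to lock onto.  A faint smooth
    seeded texture breaks the symmetry of the analytic shapes.
    """
    grid = spec.diffusion_grid()
    masks = structure_masks(spec, grid, soft=True)
    hard_brain = brain_mask(spec, grid)
    data = 0.9 * masks["brain"]
    data += 0.45 * masks.get("tube", 0.0)
    data -= 0.30 * masks.get("sheet", 0.0)
    data += 0.25 * masks.get("blob", 0.0)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.rng_seed, spawn_key=(0,)))
    texture = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=2.5)
    data += 0.15 * texture * masks["brain"]
    data = np.clip(data, 0.0, None)
    data[~hard_brain] = 0.0
    return Volume(data, grid.affine_vox2world)


def base_fa_map(spec: PhantomSpec) -> Volume:
    """Noise-free group-mean FA template: tracts high, background low."""
    grid = spec.diffusion_grid()
    masks = structure_masks(spec, grid, soft=True)
    hard_brain = brain_mask(spec, grid)
    fa = FA_BACKGROUND * masks["brain"]
    for name, level in FA_LEVELS.items():
        if name in masks:
            fa = np.maximum(fa, level * masks[name])
    fa[~hard_brain] = np.minimum(fa[~hard_brain], 0.0)
    return Volume(np.clip(fa, 0.0, 1.0), grid.affine_vox2world)


def _random_affine_params(rng: np.random.Generator, mm: float, deg: float, scale: float) -> np.ndarray:
    p = AffineTransform.identity_params()
    p[:3] = rng.normal(0.0, mm, 3) if mm > 0 else 0.0
    p[3:6] = rng.normal(0.0, deg, 3) if deg > 0 else 0.0
    p[6:9] = 1.0 + (rng.normal(0.0, scale, 3) if scale > 0 else 0.0)
    return p


def make_misaligned_pair(
    vol: Volume,
    jitter: Tuple[float, float, float],
    seed: int,
    pad_frac: float = 0.0,
    params: Optional[np.ndarray] = None,
) -> Tuple[Volume, AffineTransform]:
    """Jitter ``vol`` by a random affine; return (moving, true transform).

    The returned transform ``T`` maps the moving volume's world frame back
    onto ``vol``'s: ``resample(moving, T, vol)`` realigns the pair, so ``T``
    is exactly what a registration of ``moving`` to ``vol`` should recover.
    Zero jitter returns the identity and an untouched copy.

    ``pad_frac`` enlarges the moving grid by that fraction per side so that
    large jitters do not clip anatomy out of the field of view (a clipped
    brain has no consistent true alignment).  ``params`` overrides the random
    draw with explicit transform parameters.
    """
    mm, deg, scale = jitter
    if any(j < 0 for j in (mm, deg, scale)):
        raise ValueError("jitter scales must be >= 0")
    if params is None:
        rng = np.random.default_rng(seed)
        params = _random_affine_params(rng, mm, deg, scale)
    center = vol.world_center()
    t_true = AffineTransform.from_params(params, center=center)
    if np.allclose(t_true.matrix, np.eye(4)) and pad_frac == 0.0:
        return vol.copy(), t_true
    if pad_frac > 0:
        pad = np.ceil(pad_frac * np.asarray(vol.shape)).astype(int)
        shape = tuple(int(s + 2 * p) for s, p in zip(vol.shape, pad))
        affine = vol.affine_vox2world.copy()
        affine[:3, 3] -= affine[:3, :3] @ pad.astype(float)
        grid = Volume(np.zeros(shape), affine, vol.missing_value)
    else:
        grid = vol
    moving = resample(vol, t_true.inverse(), grid, mode="trilinear")
    return moving, t_true


def make_fa_cohort(
    phantom: PhantomSpec, cohort: CohortSpec
) -> List[Tuple[AnimalMeta, Volume, AffineTransform]]:
    """Simulate per-animal FA maps with planted group effects.

    Each animal's FA volume is the tract template plus its group's FA offsets
    on the named structures, plus voxelwise Gaussian noise, clipped to
    [0, 1], then warped by a small random affine misalignment.  The true
    misalignment transform is returned per animal (identity when
    ``misalignment_sd`` is all zero).
    """
    issues = cohort.validate()
    if issues:
        raise ValueError("; ".join(issues))
    base = base_fa_map(phantom)
    grid = phantom.diffusion_grid()
    soft = structure_masks(phantom, grid, soft=True)

    group_offset = {g: np.zeros(phantom.grid_shape) for g in GROUPS}
    for sname, per_group in cohort.effect_map.items():
        if sname not in soft:
            raise ValueError(f"effect_map names unknown structure {sname!r}")
        for g, off in per_group.items():
            group_offset[g] = group_offset[g] + off * soft[sname]

    sexes = ("male", "male", "female", "female")
    genos = ("wt", "del", "wt", "del")
    ss = np.random.SeedSequence(entropy=cohort.rng_seed, spawn_key=(1,))
    out: List[Tuple[AnimalMeta, Volume, AffineTransform]] = []
    animal_idx = 0
    mm, deg, sc = cohort.misalignment_sd
    for gi, n in enumerate(cohort.n_per_group):
        g = GROUPS[gi]
        for _ in range(n):
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=cohort.rng_seed, spawn_key=(1, animal_idx)))
            fa = base.data + group_offset[g]
            if cohort.noise_sd > 0:
                fa = fa + rng.normal(0.0, cohort.noise_sd, fa.shape)
            over = max(fa.max() - 1.0, -fa.min())
            if over > 0.2:
                warnings.warn(
                    f"planted effects push FA {over:.2f} beyond [0,1]; clipping", stacklevel=2
                )
            fa = np.clip(fa, 0.0, 1.0)
            vol = Volume(fa, grid.affine_vox2world)
            params = _random_affine_params(rng, mm, deg, sc)
            t_true = AffineTransform.from_params(params, center=vol.world_center())
            if not np.allclose(t_true.matrix, np.eye(4)):
                vol = resample(vol, t_true.inverse(), vol, mode="trilinear")
            meta = AnimalMeta(animal_id=f"{g}_{animal_idx:02d}", sex=sexes[gi], genotype=genos[gi])
            out.append((meta, vol, t_true))
            animal_idx += 1
    return out


def make_energy_maps(
    phantom: PhantomSpec,
    panel: ExpressionPanelSpec,
    cluster_regions: Optional[Dict[str, np.ndarray]] = None,
) -> Dict[str, Volume]:
    """Per-gene expression energy volumes on the coarse expression grid.

    Inside the brain each gene gets i.i.d. log-normal energy around
    ``baseline_level``; outside the brain every voxel is the -1 sentinel.
    Genes listed in ``panel.enriched_sets`` are multiplied by their factor
    inside the named structure (or inside an explicitly supplied region mask
    from ``cluster_regions``).
    """
    grid = phantom.expression_grid()
    hard = structure_masks(phantom, grid, soft=False)
    inside = hard["brain"]
    regions: Dict[str, np.ndarray] = {k: v for k, v in hard.items() if k != "brain"}
    if cluster_regions:
        regions.update({k: np.asarray(v, dtype=bool) for k, v in cluster_regions.items()})
    for rname, (subset, _) in panel.enriched_sets.items():
        if rname not in regions:
            raise ValueError(f"enriched_sets names unknown region {rname!r}")

    gene_region_factor: Dict[str, List[Tuple[np.ndarray, float]]] = {}
    for rname, (subset, factor) in panel.enriched_sets.items():
        for g in subset:
            gene_region_factor.setdefault(g, []).append((regions[rname], factor))

    out: Dict[str, Volume] = {}
    for i, gene in enumerate(panel.genes):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=panel.rng_seed, spawn_key=(2, i)))
        data = np.full(grid.shape, -1.0)
        vals = panel.baseline_level * rng.lognormal(mean=0.0, sigma=panel.noise_sigma,
                                                    size=int(inside.sum()))
        data[inside] = vals
        for mask, factor in gene_region_factor.get(gene, []):
            m = mask & inside
            data[m] *= factor
        out[gene] = Volume(data, grid.affine_vox2world, missing_value=-1.0)
    return out
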
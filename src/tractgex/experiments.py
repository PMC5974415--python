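"""Reproducible validation studies of the pipeline's statistical machinery.

Each function here runs a self-contained simulation study on synthetic
phantoms and returns its summary numbers.  They back the package's
acceptance checks and can be re-run from the command line via
``scripts/acceptance.py``; problem sizes (grids, cohort counts,
permutations, trial counts) are the study conditions stated in the methods
note.
"""

from __future__ import annotations

import itertools
from typing import Dict

import numpy as np

from .core_volumes import AffineTransform, Volume
from .expression_overlap import (
    classify_genes,
    exclusivity_report,
    load_gene_panel,
    map_clusters_to_expression_grid,
    overexpressed_lists,
    ranksum_test,
    transport_mask,
)
from .registration import RegistrationConfig, affine_register, histogram_qc, resample
from .skeleton_stats import (
    analyze_cohort,
    permutation_group_test,
    project_onto_skeleton,
    skeletonize,
    build_mean_fa,
    tfce,
)
from .synthetic_data import (
    CohortSpec,
    ExpressionPanelSpec,
    PhantomSpec,
    make_energy_maps,
    make_fa_cohort,
    make_misaligned_pair,
    make_template,
    structure_masks,
)

__all__ = [
    "tfce_closed_form_check",
    "ranksum_enumeration_check",
    "null_calibration",
    "power_tube_detection",
    "registration_recovery",
    "end_to_end_recovery",
    "histogram_qc_checks",
]


# ---------------------------------------------------------------------------
# TFCE closed form
# ---------------------------------------------------------------------------

def tfce_closed_form_check(height: float = 2.0, H: float = 2.0, E: float = 0.5) -> Dict[str, float]:
    """Isolated-voxel TFCE vs the analytic integral h^(H+1)/(H+1).

    A single supra-threshold voxel has extent 1 at every threshold, so its
    enhanced score is the plain integral of h^H from 0 to its height; with
    dh = h/1000 the Riemann sum should match to a fraction of a percent.
    """
    arr = np.zeros((5, 5, 5))
    arr[2, 2, 2] = height
    out = tfce(arr, E=E, H=H, dh=height / 1000.0)
    expected = height ** (H + 1) / (H + 1)
    rel_err = abs(out[2, 2, 2] - expected) / expected
    return {"value": float(out[2, 2, 2]), "expected": float(expected),
            "rel_err_pct": 100.0 * float(rel_err)}


# ---------------------------------------------------------------------------
# Rank-sum exactness
# ---------------------------------------------------------------------------

def _bruteforce_ranksum_p(x, y, alternative="two-sided") -> float:
    """Independent oracle: exhaustive permutation distribution of the
    rank-sum W of the first sample (midranks), two-sided by tail symmetry."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = rankdata(pooled)
    w_obs = ranks[:n].sum()
    ws = np.array([
        ranks[list(idx)].sum() for idx in itertools.combinations(range(len(pooled)), n)
    ])
    mu = ws.mean()
    eps = 1e-9
    if alternative == "greater":
        return float(np.mean(ws >= w_obs - eps))
    if alternative == "less":
        return float(np.mean(ws <= w_obs + eps))
    hi = max(w_obs, 2 * mu - w_obs)
    lo = min(w_obs, 2 * mu - w_obs)
    return float(min(1.0, np.mean(ws >= hi - eps) + np.mean(ws <= lo + eps)))


def ranksum_enumeration_check(seed: int = 0, n_cases: int = 200) -> Dict[str, float]:
    """Implemented rank-sum vs exhaustive enumeration for all n+m <= 10.

    Random integer samples (hence plenty of ties); reports the maximum
    absolute p-value discrepancy and the worked-example p for
    {1,2,3} vs {4,5,6}.
    """
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(2, 8))
        m = int(rng.integers(2, 11 - n)) if n < 9 else 2
        x = rng.integers(0, 6, n).astype(float)
        y = rng.integers(0, 6, m).astype(float)
        _, p = ranksum_test(x, y)
        p_oracle = _bruteforce_ranksum_p(x, y)
        max_diff = max(max_diff, abs(p - p_oracle))
    _, p_worked = ranksum_test([1, 2, 3], [4, 5, 6])
    return {"max_abs_p_diff": float(max_diff), "worked_example_p": float(p_worked)}


# ---------------------------------------------------------------------------
# Permutation / TFCE validity
# ---------------------------------------------------------------------------

def _null_cohort_spec(seed: int, noise_sd: float = 0.03) -> CohortSpec:
    return CohortSpec(
        n_per_group=(6, 6, 2, 2),
        effect_map={},
        noise_sd=noise_sd,
        misalignment_sd=(0.0, 0.0, 0.0),
        rng_seed=seed,
    )


def _male_test(phantom: PhantomSpec, cohort: CohortSpec, n_perm: int, seed: int,
               alpha: float = 0.05):
    """Generate a cohort and run the male del/+ vs WT skeleton test."""
    animals = make_fa_cohort(phantom, cohort)
    males = [(m, v) for m, v, _ in animals if m.sex == "male"]
    vols = [v for _, v in males]
    labels = np.array([m.genotype == "del" for m, _ in males])
    mean_fa = build_mean_fa(vols)
    skel = skeletonize(mean_fa)
    proj = np.stack([project_onto_skeleton(v, skel) for v in vols])
    inc, dec = permutation_group_test(
        proj, labels, skeleton=skel, n_perm=n_perm, alpha=alpha, seed=seed,
        contrast_names=("male_increase", "male_decrease"),
    )
    return skel, inc, dec


def null_calibration(
    n_datasets: int = 200,
    n_perm: int = 500,
    seed: int = 0,
    grid_shape=(64, 64, 64),
    alphas=(0.01, 0.05, 0.1),
) -> Dict[str, float]:
    """False-positive calibration of the FWE-corrected skeleton test.

    ``n_datasets`` independent cohorts (6 vs 6 animals, no planted effect)
    are analysed; for each alpha the fraction of skeleton voxels (both
    directions pooled) declared significant is reported together with the
    Monte-Carlo standard error of an alpha-level binomial over the datasets.
    Family-wise control makes the voxel fraction far smaller than alpha.
    """
    phantom = PhantomSpec(grid_shape=tuple(grid_shape), rng_seed=seed)
    sig = {a: 0 for a in alphas}
    total = 0
    for ds in range(n_datasets):
        cohort = _null_cohort_spec(seed=seed * 100003 + ds)
        _, inc, dec = _male_test(phantom, cohort, n_perm=n_perm, seed=seed + ds)
        for a in alphas:
            sig[a] += int((inc.corrected_p < a).sum() + (dec.corrected_p < a).sum())
        total += 2 * len(inc.corrected_p)
    out: Dict[str, float] = {"n_datasets": float(n_datasets), "total_tests": float(total)}
    for a in alphas:
        out[f"fpr_at_{a:g}"] = sig[a] / total
        out[f"mc_se_at_{a:g}"] = float(np.sqrt(a * (1 - a) / n_datasets))
    return out


def power_tube_detection(
    effect_d: float = 3.0,
    n_replicates: int = 3,
    n_perm: int = 500,
    seed: int = 0,
    grid_shape=(64, 64, 64),
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Detection power for a planted tube effect of size d (Cohen's d).

    The male del/+ group receives an FA offset of ``d * noise_sd`` on the
    medial tube; power is the fraction of tube skeleton voxels reaching
    corrected p < alpha in the increase direction, averaged over replicate
    cohorts (6 vs 6).
    """
    phantom = PhantomSpec(grid_shape=tuple(grid_shape), rng_seed=seed)
    masks = structure_masks(phantom, phantom.diffusion_grid(), soft=False)
    fractions = []
    for rep in range(n_replicates):
        cohort = CohortSpec(
            n_per_group=(6, 6, 2, 2),
            effect_map={"tube": {"male_del": effect_d * 0.03}},
            noise_sd=0.03,
            misalignment_sd=(0.0, 0.0, 0.0),
            rng_seed=seed * 7919 + rep,
        )
        skel, inc, _ = _male_test(phantom, cohort, n_perm=n_perm, seed=seed + rep, alpha=alpha)
        tube_skel = masks["tube"][tuple(skel.voxel_indices.T)]
        if tube_skel.sum() == 0:
            fractions.append(0.0)
            continue
        detected = (inc.corrected_p < alpha) & tube_skel
        fractions.append(detected.sum() / tube_skel.sum())
    return {
        "power_pct": 100.0 * float(np.mean(fractions)),
        "per_replicate_pct": [100.0 * float(f) for f in fractions],
        "effect_d": effect_d,
    }


# ---------------------------------------------------------------------------
# Registration recovery
# ---------------------------------------------------------------------------

def _transform_errors(t_est: AffineTransform, t_true: AffineTransform, vol: Volume):
    d = t_est.matrix @ np.linalg.inv(t_true.matrix)
    c = vol.world_center()
    trans_err = float(np.linalg.norm((d[:3, :3] @ c + d[:3, 3]) - c))
    U, _, Vt = np.linalg.svd(d[:3, :3])
    R = U @ Vt
    ang = float(np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1.0, 1.0))))
    return trans_err, ang


def registration_recovery(
    n_trials: int = 20,
    seed: int = 0,
    grid_shape=(48, 48, 48),
    spacing: float = 0.25,
    max_trans_mm: float = 5.0,
    max_rot_deg: float = 20.0,
    scale_range=(0.9, 1.1),
) -> Dict[str, float]:
    """Planted-transform recovery accuracy over random affine jitters.

    Each trial jitters the anatomical template by a random affine
    (translation of up to ``max_trans_mm`` mm, rotations within
    +/-``max_rot_deg`` deg per axis, anisotropic scale in ``scale_range``),
    generated on a padded grid so no anatomy is clipped, then registers the
    jittered volume back.  Reports median translation error in voxels and
    median rotation error in degrees.
    """
    phantom = PhantomSpec(grid_shape=tuple(grid_shape), spacing=spacing, rng_seed=seed)
    tpl = make_template(phantom)
    cfg = RegistrationConfig(metric="ncc", rot_search_deg=30.0, rot_search_step_deg=15.0)
    trans_errs, rot_errs = [], []
    for trial in range(n_trials):
        rng = np.random.default_rng(seed * 10007 + trial)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        params = np.concatenate([
            direction * rng.uniform(0.0, max_trans_mm),
            rng.uniform(-max_rot_deg, max_rot_deg, 3),
            rng.uniform(scale_range[0], scale_range[1], 3),
            np.zeros(3),
        ])
        moving, t_true = make_misaligned_pair(tpl, (0, 0, 0), seed=trial,
                                              pad_frac=0.5, params=params)
        t_est = affine_register(moving, tpl, cfg)
        te, ae = _transform_errors(t_est, t_true, tpl)
        trans_errs.append(te / spacing)
        rot_errs.append(ae)
    return {
        "median_translation_err_voxels": float(np.median(trans_errs)),
        "median_rotation_err_deg": float(np.median(rot_errs)),
        "n_trials": float(n_trials),
        "translation_errs_voxels": [float(v) for v in trans_errs],
        "rotation_errs_deg": [float(v) for v in rot_errs],
    }


# ---------------------------------------------------------------------------
# End-to-end recovery of the planted exclusive gene set
# ---------------------------------------------------------------------------

def end_to_end_recovery(
    seed: int = 0,
    n_perm: int = 500,
    grid_shape=(64, 64, 64),
    register: bool = True,
) -> Dict[str, object]:
    """Full pipeline on the default synthetic cohort.

    Simulates the 6/4/6/5 cohort with misalignments, registers every FA map
    back to the template anatomy, runs the four-contrast skeleton analysis,
    transfers clusters to the expression grid, scores the 26-gene panel and
    reports the recovered per-contrast lists and the male-increase exclusive
    set against the planted one.
    """
    phantom = PhantomSpec(grid_shape=tuple(grid_shape), rng_seed=seed)
    cohort = CohortSpec(rng_seed=seed + 1)
    panel_spec = ExpressionPanelSpec(rng_seed=seed + 2)
    if not register:
        cohort.misalignment_sd = (0.0, 0.0, 0.0)
    animals = make_fa_cohort(phantom, cohort)
    grid = phantom.diffusion_grid()
    if register:
        from .synthetic_data import base_fa_map
        target = base_fa_map(phantom)
        cfg = RegistrationConfig(metric="ncc", rot_search_deg=0.0, coarse_search=False)
        aligned = [resample(v, affine_register(v, target, cfg), grid) for _, v, _ in animals]
    else:
        aligned = [v for _, v, _ in animals]
    metas = [m for m, _, _ in animals]
    skel, results = analyze_cohort(aligned, metas, n_perm=n_perm, seed=seed + 3)

    energy = make_energy_maps(phantom, panel_spec)
    expr_grid = phantom.expression_grid()
    identity = AffineTransform.identity()
    cluster_masks = {
        c: map_clusters_to_expression_grid(r.clusters, identity, expr_grid, grid)
        for c, r in results.items()
    }
    skel_expr = transport_mask(skel.mask, identity, expr_grid)
    panel = load_gene_panel()
    gene_results = classify_genes(energy, cluster_masks, skel_expr, panel=panel)
    lists = overexpressed_lists(gene_results)
    excl = exclusivity_report(lists, panel)
    planted = sorted(panel_spec.enriched_sets["tube"][0], key=str.lower)
    recovered = excl.exclusive.get("male_increase", [])
    return {
        "planted_exclusive": planted,
        "recovered_exclusive": recovered,
        "exact_match": recovered == planted,
        "overexpressed_lists": lists,
        "n_significant_voxels": {c: int((r.corrected_p < r.alpha).sum())
                                 for c, r in results.items()},
    }


# ---------------------------------------------------------------------------
# Histogram QC
# ---------------------------------------------------------------------------

def histogram_qc_checks(seed: int = 0, grid_shape=(48, 48, 48)) -> Dict[str, float]:
    """Histogram-divergence scores for identity, permutation and rigid moves.

    A smooth energy-like map is compared against (a) itself, (b) a voxel
    permutation of itself (same histogram by construction), and (c) a rigid
    resampling of itself (small interpolation-induced divergence expected).
    """
    phantom = PhantomSpec(grid_shape=tuple(grid_shape), spacing=0.25, rng_seed=seed)
    from scipy import ndimage
    rng = np.random.default_rng(seed)
    grid = phantom.diffusion_grid()
    from .synthetic_data import brain_mask
    inside = brain_mask(phantom, grid)
    smooth = ndimage.gaussian_filter(rng.lognormal(0.0, 0.5, phantom.grid_shape), 2.0)
    data = np.where(inside, smooth, -1.0)
    vol = Volume(data, grid.affine_vox2world, missing_value=-1.0)

    identity_score = histogram_qc(vol, vol).score

    permuted = data.copy()
    vals = permuted[inside]
    permuted[inside] = rng.permutation(vals)
    score_perm = histogram_qc(vol, Volume(permuted, grid.affine_vox2world, -1.0)).score

    params = AffineTransform.identity_params()
    params[:3] = (0.5, -0.3, 0.4)
    params[3:6] = (4.0, -3.0, 5.0)
    t = AffineTransform.from_params(params, center=vol.world_center())
    moved = resample(vol, t, vol, mode="trilinear")
    score_rigid = histogram_qc(vol, moved).score

    return {
        "identity_score": float(identity_score),
        "permutation_score": float(score_perm),
        "rigid_score": float(score_rigid),
    }
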
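"""Gene panel, rank-sum test, cluster transport and overexpression calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tractgex.core_volumes import AffineTransform, Volume, volume_from_spacing
from tractgex.expression_overlap import (
    GenePanel,
    available_genes,
    classify_genes,
    exclusivity_report,
    extract_sample,
    load_contrast_gene_lists,
    load_gene_panel,
    map_clusters_to_expression_grid,
    overexpressed_lists,
    ranksum_test,
    render_report,
    transport_mask,
)
from tractgex.experiments import _bruteforce_ranksum_p
from tractgex.skeleton_stats import Cluster


class TestGenePanel:
    def test_packaged_panel_counts(self):
        panel = load_gene_panel()
        assert len(panel) == 27
        assert len(available_genes(panel)) == 26
        assert not panel.is_available("Prrt2")

    def test_symbol_canonicalization(self):
        panel = load_gene_panel()
        assert panel.canonical("MVP") == "Mvp"
        assert panel.canonical("taok2") == "Taok2"
        assert panel.canonical("Erk1") == "Mapk3"     # via alias list
        with pytest.raises(KeyError, match="Nonexistent"):
            panel.canonical("Nonexistent")

    def test_duplicate_symbols_rejected(self):
        import pandas as pd
        df = pd.DataFrame({
            "gene_symbol": ["A", "A"], "gene_name": ["x", "y"],
            "aliases": ["", ""], "plane": ["Sagittal"] * 2,
            "experiment_id": ["1", "2"],
        })
        with pytest.raises(ValueError, match="duplicate"):
            GenePanel(df)

    def test_malformed_panel_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene_symbol\tgene_name\nA\tx\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_gene_panel(p)

    def test_contrast_lists_fixture_counts(self):
        lists = load_contrast_gene_lists()
        assert {k: len(v) for k, v in lists.items()} == {
            "male_increase": 7, "male_decrease": 8,
            "female_increase": 3, "female_decrease": 5,
        }


class TestRanksum:
    def test_worked_example_separated_samples(self):
        stat, p = ranksum_test([1, 2, 3], [4, 5, 6])
        assert stat == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p = ranksum_test([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0)

    def test_swap_symmetry_two_sided(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 15)
        _, p1 = ranksum_test(x, y)
        _, p2 = ranksum_test(y, x)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranksum_test([], [1.0])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 5), min_size=2, max_size=6),
        y=st.lists(st.integers(0, 5), min_size=2, max_size=6),
        alternative=st.sampled_from(["two-sided", "greater", "less"]),
    )
    def test_matches_enumeration_oracle_small_samples(self, x, y, alternative):
        """For pooled sizes <= 12 (ties included) the implemented p equals an
        independent exhaustive permutation enumeration."""
        _, p = ranksum_test(x, y, alternative=alternative)
        p_oracle = _bruteforce_ranksum_p(np.asarray(x, float), np.asarray(y, float),
                                         alternative)
        assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_large_sample_normal_approximation_reasonable(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 1, 300)
        _, p = ranksum_test(x, y)
        from scipy import stats
        ref = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestSampling:
    def _grid(self, data, missing=None):
        return volume_from_spacing(np.asarray(data, float), 0.2, missing_value=missing)

    def test_constant_map_returns_constant_values(self):
        vol = self._grid(np.full((5, 5, 5), 2.5))
        mask = self._grid(np.ones((5, 5, 5)))
        vals = extract_sample(vol, mask)
        assert vals.size == 125 and np.all(vals == 2.5)

    def test_missing_voxels_excluded(self, rng):
        data = rng.random((5, 5, 5))
        mask = np.zeros((5, 5, 5))
        mask.ravel()[:15] = 1
        data.ravel()[:3] = -1.0
        vals = extract_sample(self._grid(data, -1.0), self._grid(mask))
        assert vals.size == 12

    def test_pooling_is_additive_over_disjoint_masks(self, rng):
        data = rng.random((6, 6, 6))
        m1 = np.zeros((6, 6, 6)); m1.ravel()[:10] = 1
        m2 = np.zeros((6, 6, 6)); m2.ravel()[50:55] = 1
        v1 = extract_sample(self._grid(data), self._grid(m1))
        v2 = extract_sample(self._grid(data), self._grid(m2))
        both = extract_sample(self._grid(data), self._grid(m1 + m2))
        assert both.size == v1.size + v2.size == 15

    def test_empty_intersection_rejected(self):
        vol = self._grid(np.full((4, 4, 4), -1.0), -1.0)
        mask = self._grid(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="no non-missing"):
            extract_sample(vol, mask)


class TestClusterTransport:
    def test_identity_same_grid_reproduces_voxels(self):
        grid = volume_from_spacing(np.zeros((8, 8, 8)), 0.2)
        vox = np.array([(1, 2, 3), (4, 4, 4)])
        cl = Cluster(cluster_id=1, voxels=vox, space="diffusion", peak_stat=3.0)
        mask = map_clusters_to_expression_grid([cl], AffineTransform.identity(), grid, grid)
        assert mask.data.sum() == 2
        assert mask.data[1, 2, 3] and mask.data[4, 4, 4]

    def test_translation_moves_centroid(self):
        grid = volume_from_spacing(np.zeros((10, 10, 10)), 0.2)
        vox = np.array([(4, 4, 4), (4, 4, 5), (4, 5, 4)])
        cl = Cluster(cluster_id=1, voxels=vox, space="diffusion", peak_stat=1.0)
        p = AffineTransform.identity_params()
        p[:3] = (0.4, 0.0, 0.0)  # +2 voxels at 0.2 mm
        t = AffineTransform.from_params(p)
        mask = map_clusters_to_expression_grid([cl], t, grid, grid)
        before = vox.mean(axis=0)
        after = np.argwhere(mask.data).mean(axis=0)
        np.testing.assert_allclose(after, before + [2, 0, 0], atol=0.5)

    def test_empty_cluster_list_warns(self):
        grid = volume_from_spacing(np.zeros((4, 4, 4)), 0.2)
        with pytest.warns(UserWarning, match="no clusters"):
            mask = map_clusters_to_expression_grid([], AffineTransform.identity(), grid, grid)
        assert not mask.data.any()

    def test_resolution_change_preserves_every_cluster(self):
        fine = volume_from_spacing(np.zeros((16, 16, 16)), 0.125)
        coarse = volume_from_spacing(np.zeros((10, 10, 10)), 0.2)
        cl = Cluster(cluster_id=1, voxels=np.array([(8, 8, 8)]), space="diffusion",
                     peak_stat=1.0)
        mask = map_clusters_to_expression_grid([cl], AffineTransform.identity(), coarse, fine)
        assert mask.data.sum() >= 1

    def test_transport_mask_round_trip(self):
        grid = volume_from_spacing(np.zeros((8, 8, 8)), 0.2)
        m = np.zeros((8, 8, 8), bool)
        m[2:5, 2:5, 2:5] = True
        out = transport_mask(Volume(m, grid.affine_vox2world), AffineTransform.identity(), grid)
        np.testing.assert_array_equal(out.data, m)


def _toy_setup(rng, enriched=("Mvp",), factor=3.0, n_genes=None):
    """Small expression grid with a cluster mask inside a bigger skeleton."""
    panel = load_gene_panel()
    genes = available_genes(panel) if n_genes is None else available_genes(panel)[:n_genes]
    shape = (12, 12, 12)
    skel = np.zeros(shape, bool)
    skel[2:10, 2:10, 5] = True
    clus = np.zeros(shape, bool)
    clus[4:8, 4:8, 5] = True
    energy = {}
    for g in genes:
        vals = rng.lognormal(0, 0.3, shape)
        if g in enriched:
            vals[clus] *= factor
        energy[g] = volume_from_spacing(vals, 0.2, missing_value=-1.0)
    grid = volume_from_spacing(np.zeros(shape), 0.2)
    masks = {"male_increase": Volume(clus, grid.affine_vox2world)}
    return panel, energy, masks, Volume(skel, grid.affine_vox2world)


class TestClassifyGenes:
    def test_planted_enrichment_recovered_exactly(self, rng):
        panel, energy, masks, skel = _toy_setup(rng, enriched=("Mvp", "Taok2"))
        results = classify_genes(energy, masks, skel, panel=panel)
        lists = overexpressed_lists(results)
        assert lists["male_increase"] == ["Mvp", "Taok2"]

    def test_underexpressed_gene_excluded_with_direction(self, rng):
        panel, energy, masks, skel = _toy_setup(rng)
        low = energy["Spn"].data.copy()
        low[np.asarray(masks["male_increase"].data, bool)] /= 4.0
        energy["Spn"] = Volume(low, energy["Spn"].affine_vox2world, -1.0)
        results = classify_genes(energy, masks, skel, panel=panel)
        spn = next(r for r in results if r.gene == "Spn")
        assert spn.direction == "under"
        assert "Spn" not in overexpressed_lists(results)["male_increase"]

    def test_unavailable_gene_reported_as_no_map(self, rng):
        panel, energy, masks, skel = _toy_setup(rng)
        results = classify_genes(energy, masks, skel, panel=panel)
        prrt2 = [r for r in results if r.gene == "Prrt2"]
        assert len(prrt2) == 1 and prrt2[0].status == "no_map"
        assert np.isnan(prrt2[0].p_value)

    def test_empty_cluster_mask_flags_no_clusters(self, rng):
        panel, energy, masks, skel = _toy_setup(rng)
        empty = Volume(np.zeros(skel.shape, bool), skel.affine_vox2world)
        results = classify_genes(energy, {"female_increase": empty}, skel, panel=panel)
        assert all(r.status == "no_clusters" for r in results if r.status != "no_map")

    def test_invariant_under_monotone_transform(self, rng):
        """Rank statistics ignore any strictly increasing remap of one gene."""
        panel, energy, masks, skel = _toy_setup(rng)
        res1 = classify_genes(energy, masks, skel, panel=panel)
        remapped = dict(energy)
        e = energy["Cdipt"]
        remapped["Cdipt"] = Volume(np.where(e.data == -1.0, -1.0, np.exp(e.data)),
                                   e.affine_vox2world, -1.0)
        res2 = classify_genes(remapped, masks, skel, panel=panel)
        p1 = next(r for r in res1 if r.gene == "Cdipt").p_value
        p2 = next(r for r in res2 if r.gene == "Cdipt").p_value
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestExclusivity:
    def test_published_fixture_male_exclusive_trio(self):
        rep = exclusivity_report(load_contrast_gene_lists())
        assert rep.exclusive["male_increase"] == ["Mvp", "Sez6l2", "Taok2"]

    def test_identical_lists_have_empty_exclusive_sets(self):
        lists = {c: ["Mvp", "Taok2"] for c in
                 ("male_increase", "male_decrease", "female_increase", "female_decrease")}
        rep = exclusivity_report(lists)
        assert all(v == [] for v in rep.exclusive.values())

    def test_pairwise_disjoint_lists_are_fully_exclusive(self):
        lists = {"male_increase": ["Mvp"], "male_decrease": ["Taok2"],
                 "female_increase": ["Spn"], "female_decrease": ["Qprt"]}
        rep = exclusivity_report(lists)
        assert rep.exclusive == {k: v for k, v in lists.items()}

    def test_unknown_symbol_raises_naming_it(self):
        with pytest.raises(KeyError, match="Imaginary1"):
            exclusivity_report({"male_increase": ["Imaginary1"]})


class TestRenderReport:
    def test_row_count_and_determinism(self, rng, tmp_path):
        panel, energy, masks, skel = _toy_setup(rng)
        results = classify_genes(energy, masks, skel, panel=panel)
        excl = exclusivity_report(overexpressed_lists(results), panel)
        render_report(results, excl, tmp_path / "a")
        render_report(results, excl, tmp_path / "b")
        a = (tmp_path / "a" / "gene_overlap.tsv").read_bytes()
        b = (tmp_path / "b" / "gene_overlap.tsv").read_bytes()
        assert a == b
        n_lines = a.decode().strip().count("\n")
        assert n_lines == 27  # header + 27 genes x 1 contrast

    def test_empty_results_give_header_only(self, tmp_path):
        rep = exclusivity_report({})
        overlap, matrix, excl = render_report([], rep, tmp_path)
        assert overlap.empty
        assert (tmp_path / "gene_overlap.tsv").exists()
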
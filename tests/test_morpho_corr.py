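"""Morphology-expression correlation framework: split hygiene, top-k gene
selection, held-out clustering, distance CDFs and the shape classifier."""

import numpy as np
import pandas as pd
import pytest

from gliamorph import expression as E, morpho_corr as MC


def _synthetic_tables(seed=0, n=200, n_genes=30, planted=6, effect=5.0):
    """Cells with features and expression where the first `planted` genes
    track cell_area monotonically."""
    rng = np.random.default_rng(seed)
    cells = [f"c{i}" for i in range(n)]
    area = rng.uniform(200, 2000, size=n)
    feats = pd.DataFrame(
        {
            "cell_area": area,
            "n_terminal_points": rng.poisson(5, n) + area / 400,
            "solidity": rng.uniform(0.3, 1.0, n),
        },
        index=cells,
    )
    base = rng.poisson(60, size=(n, n_genes)).astype(float)
    scale = 1 + (effect - 1) * (area - area.min()) / np.ptp(area)
    base[:, :planted] *= scale[:, None]
    counts = pd.DataFrame(
        rng.poisson(base), index=cells, columns=[f"g{i}" for i in range(n_genes)]
    )
    return feats, E.lognormalize(counts)


class TestCorrelate:
    def test_rank_identical_gene_gets_rho_one(self):
        rng = np.random.default_rng(0)
        n = 60
        cells = [f"c{i}" for i in range(n)]
        area = rng.uniform(10, 100, n)
        feats = pd.DataFrame({"cell_area": area}, index=cells)
        expr = pd.DataFrame({"twin": np.exp(area / 30)}, index=cells)
        corr = MC.correlate(feats, expr, seed=1)
        assert corr.rho.loc["twin", "cell_area"] == pytest.approx(1.0)

    def test_null_gene_has_small_correlation(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 500
            cells = [f"c{i}" for i in range(n)]
            feats = pd.DataFrame({"f": rng.normal(size=n)}, index=cells)
            expr = pd.DataFrame({"g": rng.normal(size=n)}, index=cells)
            corr = MC.correlate(feats, expr, seed=seed)
            if abs(corr.rho.loc["g", "f"]) < 0.15:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_planted_pairs_stable_across_split_seeds(self):
        feats, ln = _synthetic_tables(seed=5)
        r1 = MC.correlate(feats, ln, seed=1).rho.loc["g0", "cell_area"]
        r2 = MC.correlate(feats, ln, seed=2).rho.loc["g0", "cell_area"]
        assert r1 > 0.8 and r2 > 0.8

    def test_train_test_are_disjoint_and_cover(self):
        feats, ln = _synthetic_tables(seed=7, n=80)
        corr = MC.correlate(feats, ln, seed=3)
        assert set(corr.train_cells) & set(corr.test_cells) == set()
        assert len(corr.train_cells) + len(corr.test_cells) == 80

    def test_constant_gene_flagged_zero(self):
        rng = np.random.default_rng(1)
        n = 40
        cells = [f"c{i}" for i in range(n)]
        feats = pd.DataFrame({"f": rng.normal(size=n)}, index=cells)
        expr = pd.DataFrame({"flat": np.ones(n)}, index=cells)
        corr = MC.correlate(feats, expr, seed=0)
        assert corr.rho.loc["flat", "f"] == 0.0
        assert ("flat", "f") in corr.flagged

    def test_spearman_invariant_under_monotone_transform(self):
        feats, ln = _synthetic_tables(seed=11, n=100)
        c1 = MC.correlate(feats, ln, seed=4).rho
        c2 = MC.correlate(feats.rank(), np.exp(ln / 5), seed=4).rho
        np.testing.assert_allclose(c1, c2, atol=1e-9)


class TestTopGeneSets:
    def test_single_feature_returns_k_genes(self):
        feats, ln = _synthetic_tables(seed=2)
        corr = MC.correlate(feats[["cell_area"]], ln, seed=0)
        union, perf = MC.top_gene_sets(corr, k=5)
        assert len(union) == 5
        assert perf["cell_area"] == union

    def test_identical_features_union_is_k(self):
        feats, ln = _synthetic_tables(seed=3)
        feats2 = pd.DataFrame(
            {"a": feats["cell_area"], "b": feats["cell_area"]}, index=feats.index
        )
        corr = MC.correlate(feats2, ln, seed=0)
        union, _ = MC.top_gene_sets(corr, k=5)
        assert len(union) == 5

    def test_planted_correlates_recovered(self):
        feats, ln = _synthetic_tables(seed=4, planted=6)
        corr = MC.correlate(feats, ln, seed=0)
        union, _ = MC.top_gene_sets(corr, k=5)
        planted = {f"g{i}" for i in range(6)}
        assert len(planted & set(union)) / len(planted) >= 0.8


class TestClusterHeldout:
    def test_planted_populations_align_with_shape_classes(self):
        rng = np.random.default_rng(8)
        n = 120
        cells = [f"c{i}" for i in range(n)]
        labels = pd.Series(np.r_[np.ones(60), np.full(60, 4)], index=cells)
        base = rng.poisson(20, size=(n, 10)).astype(float)
        base[60:, :4] *= 4  # ramified cells upregulate 4 genes
        ln = E.lognormalize(pd.DataFrame(
            base.astype(int), index=cells, columns=[f"g{i}" for i in range(10)]
        ))
        cl, ari = MC.cluster_heldout(ln, [f"g{i}" for i in range(4)], labels, cells)
        assert ari > 0.8

    def test_random_genes_on_shuffled_labels_near_zero(self):
        aris = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = 80
            cells = [f"c{i}" for i in range(n)]
            labels = pd.Series(rng.integers(1, 6, n), index=cells)
            ln = E.lognormalize(pd.DataFrame(
                rng.poisson(20, size=(n, 8)), index=cells,
                columns=[f"g{i}" for i in range(8)],
            ))
            _, ari = MC.cluster_heldout(ln, [f"g{i}" for i in range(8)], labels, cells)
            aris.append(ari)
        assert abs(np.median(aris)) < 0.1

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(3)
        n = 40
        cells = [f"c{i}" for i in range(n)]
        labels = pd.Series(rng.integers(1, 6, n), index=cells)
        ln = E.lognormalize(pd.DataFrame(
            rng.poisson(25, size=(n, 6)), index=cells,
            columns=[f"g{i}" for i in range(6)],
        ))
        genes = [f"g{i}" for i in range(6)]
        c1, a1 = MC.cluster_heldout(ln, genes, labels, cells)
        c2, a2 = MC.cluster_heldout(ln, genes[::-1], labels, cells)
        pd.testing.assert_series_equal(c1, c2)


class TestRegionStratified:
    def test_single_region_counts_all_one(self):
        feats, ln = _synthetic_tables(seed=6, n=60)
        regions = pd.Series("cortex", index=feats.index)
        per_region, counts = MC.region_stratified_top_genes(
            feats, ln, regions, seed=0
        )
        assert set(per_region) == {"cortex"}
        assert (counts == 1).all()

    def test_planted_gene_found_in_every_region(self):
        frames_f, frames_l, region_labels = [], [], []
        for r, seed in enumerate((21, 22, 23)):
            f, l = _synthetic_tables(seed=seed, n=80)
            f.index = [f"r{r}_{c}" for c in f.index]
            l.index = f.index
            frames_f.append(f)
            frames_l.append(l)
            region_labels += [f"region{r}"] * 80
        feats = pd.concat(frames_f)
        ln = pd.concat(frames_l)
        regions = pd.Series(region_labels, index=feats.index)
        per_region, counts = MC.region_stratified_top_genes(feats, ln, regions, seed=0)
        assert counts.max() == 3  # bounded by and reaching the region count
        planted = {f"g{i}" for i in range(6)}
        assert any(g in planted for g in counts[counts == 3].index)

    def test_small_region_skipped_with_warning(self):
        feats, ln = _synthetic_tables(seed=9, n=60)
        regions = pd.Series(["big"] * 55 + ["tiny"] * 5, index=feats.index)
        with pytest.warns(UserWarning, match="tiny"):
            per_region, _ = MC.region_stratified_top_genes(feats, ln, regions, seed=0)
        assert "tiny" not in per_region


class TestDistanceCDF:
    def test_centroid_and_edge_molecules(self, disk_cell):
        from gliamorph.containers import TranscriptTable

        cx, cy = disk_cell.soma_centroid
        mask = disk_cell.max_projection("total")
        ys, xs = np.nonzero(mask)
        far = np.argmax(np.hypot(xs - cx, ys - cy))
        df = pd.DataFrame(
            {
                "gene": ["g", "g"],
                "x": [cx, float(xs[far])],
                "y": [cy, float(ys[far])],
                "z": [0, 0],
            }
        )
        out = MC.transcript_distance_cdf(disk_cell, TranscriptTable(df))
        assert out["normalized_distance"].iloc[0] == pytest.approx(0.0)
        assert out["normalized_distance"].iloc[1] == pytest.approx(1.0)

    def test_uniform_disk_matches_square_law(self, cfg):
        """Uniform placement in a disk has CDF(x) = x^2."""
        from gliamorph import synthetic as S

        # large disk so pixel discretization does not distort the law
        disk = S.simulate_cell(
            S.ShapeParams(soma_radius=60, n_primary_branches=0, image_size=160),
            seed=3,
            plane_noise=0.0,
        )
        genes = [S.GeneModel("u", 5000.0, process_logodds=-20.0)]
        tx = S.simulate_transcripts(disk, genes, seed=1, config=cfg)
        out = MC.transcript_distance_cdf(disk, tx)
        d = np.sort(out["normalized_distance"].to_numpy())
        ecdf = np.arange(1, len(d) + 1) / len(d)
        ks = np.abs(ecdf - d**2).max()
        assert len(d) >= 4000
        assert ks < 0.05


class TestClassifier:
    @staticmethod
    def _shape_linked(seed=0, n_per_class=100, effect=4.0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_class
        cells = [f"c{i}" for i in range(n)]
        y = pd.Series(["amoeboid"] * n_per_class + ["ramified"] * n_per_class,
                      index=cells)
        base = rng.poisson(20, size=(n, 12)).astype(float)
        base[n_per_class:, :6] *= effect
        ln = E.lognormalize(pd.DataFrame(
            base.astype(int), index=cells, columns=[f"g{i}" for i in range(12)]
        ))
        return ln, y

    def test_perfectly_separating_gene_gives_auroc_one(self):
        n = 80
        cells = [f"c{i}" for i in range(n)]
        y = pd.Series(["amoeboid"] * 40 + ["ramified"] * 40, index=cells)
        counts = pd.DataFrame(
            {"sep": np.r_[np.full(40, 5), np.full(40, 500)],
             "noise": np.full(n, 20)},
            index=cells,
        )
        ln = E.lognormalize(counts)
        report = MC.train_classifier(ln, ["sep", "noise"], y, seed=0)
        assert report.auroc == 1.0

    def test_importances_sum_to_one(self):
        ln, y = self._shape_linked(seed=1)
        report = MC.train_classifier(ln, list(ln.columns), y, seed=2)
        assert (report.importances >= 0).all()
        assert report.importances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_class_is_error(self):
        ln, y = self._shape_linked(seed=2)
        with pytest.raises(ValueError, match="2 classes"):
            MC.train_classifier(ln, list(ln.columns), pd.Series("ramified", index=ln.index), seed=0)

    def test_train_test_disjoint(self):
        ln, y = self._shape_linked(seed=3)
        report = MC.train_classifier(ln, list(ln.columns), y, seed=4)
        assert set(report.train_cells) & set(report.test_cells) == set()


class TestAvgCorrelation:
    def test_singleton_set_equals_its_gene(self):
        feats, ln = _synthetic_tables(seed=10, n=60)
        corr = MC.correlate(feats, ln, seed=0)
        out = MC.avg_compartment_correlation(corr, {"solo": ["g0"]})
        assert out.loc["solo", "cell_area"] == pytest.approx(
            corr.rho.loc["g0", "cell_area"]
        )

    def test_gene_and_negated_copy_average_to_zero(self):
        rng = np.random.default_rng(4)
        n = 60
        cells = [f"c{i}" for i in range(n)]
        f = rng.normal(size=n)
        feats = pd.DataFrame({"f": f}, index=cells)
        expr = pd.DataFrame({"up": f + rng.normal(0, 1e-9, n), "down": -f},
                            index=cells)
        corr = MC.correlate(feats, expr, seed=0)
        out = MC.avg_compartment_correlation(corr, {"pair": ["up", "down"]})
        assert abs(out.loc["pair", "overall"]) < 1e-6

    def test_missing_gene_warns_and_skips(self):
        feats, ln = _synthetic_tables(seed=12, n=60)
        corr = MC.correlate(feats, ln, seed=0)
        with pytest.warns(UserWarning, match="absent"):
            out = MC.avg_compartment_correlation(corr, {"s": ["g0", "ghost"]})
        assert out.loc["s", "overall"] == pytest.approx(
            corr.rho.loc["g0"].to_numpy().mean()
        )

    def test_process_genes_correlate_more_with_ramification(self):
        """Planted process genes track branching features more strongly."""
        rng = np.random.default_rng(13)
        n = 300
        cells = [f"c{i}" for i in range(n)]
        ramification = rng.uniform(0, 1, n)
        feats = pd.DataFrame(
            {"n_terminal_points": 3 + 20 * ramification + rng.normal(0, 1, n)},
            index=cells,
        )
        base = rng.poisson(20, size=(n, 10)).astype(float)
        base[:, :3] *= 1 + 2 * ramification[:, None]  # process-enriched genes
        ln = E.lognormalize(pd.DataFrame(
            base.astype(int), index=cells, columns=[f"g{i}" for i in range(10)]
        ))
        corr = MC.correlate(feats, ln, seed=0)
        out = MC.avg_compartment_correlation(
            corr, {"process": ["g0", "g1", "g2"], "soma": ["g5", "g6", "g7"]}
        )
        assert out.loc["process", "overall"] > out.loc["soma", "overall"]
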
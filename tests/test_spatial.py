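"""Spatial statistics: Ripley K analytics and calibration, co-localization
radius/counting oracles, null conservation and network construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from gliamorph import spatial as sp
from gliamorph.containers import SOMA, TranscriptTable


@pytest.fixture(scope="module")
def box_domain(cfg):
    vox = np.argwhere(np.ones((6, 60, 60), bool))
    return sp.voxels_to_um(vox, cfg)


class TestRipleyK:
    def test_two_points_step_function(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        K = sp.ripley_k3d(pts, volume_um3=50.0, radii=np.array([0.5, 1.0, 2.0]))
        np.testing.assert_allclose(K, [0.0, 50.0, 50.0])

    def test_monotone_in_radius(self, cfg, box_domain):
        rng = np.random.default_rng(0)
        pts = sp._sample_uniform(rng, 50, box_domain, cfg)
        K = sp.ripley_k3d(pts, 100.0, np.linspace(0.2, 3, 15))
        assert (np.diff(K) >= 0).all()

    def test_csr_mean_matches_sphere_volume(self):
        """In a cube, E[K(r)] = (4/3) pi r^3 for r much smaller than the side."""
        rng = np.random.default_rng(1)
        side = 30.0
        radii = np.array([0.3, 0.6, 1.0])
        ks = []
        for _ in range(200):
            pts = rng.uniform(0, side, size=(500, 3))
            ks.append(sp.ripley_k3d(pts, side**3, radii))
        mean_k = np.mean(ks, axis=0)
        expected = 4 / 3 * np.pi * radii**3
        # no edge correction: a small downward boundary bias remains
        np.testing.assert_allclose(mean_k, expected, rtol=0.05)

    def test_single_point_is_error(self):
        with pytest.raises(ValueError):
            sp.ripley_k3d(np.zeros((1, 3)), 1.0, np.array([1.0]))

    def test_h_transform_zero_centered_for_csr_k(self):
        radii = np.array([0.5, 1.0])
        k_csr = 4 / 3 * np.pi * radii**3
        np.testing.assert_allclose(sp.h_transform(k_csr, radii), 0.0, atol=1e-12)


class TestRipleyEnvelope:
    def test_same_seed_identical_envelopes(self, cfg, box_domain):
        rng = np.random.default_rng(2)
        pts = sp._sample_uniform(rng, 40, box_domain, cfg)
        radii = np.array([0.5, 1.0])
        a = sp.ripley_envelope([pts], [box_domain], radii, 100, seed=7, config=cfg)
        b = sp.ripley_envelope([pts], [box_domain], radii, 100, seed=7, config=cfg)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)
        np.testing.assert_array_equal(a.flag, b.flag)

    def test_envelope_ordering_and_flags(self, cfg, box_domain):
        rng = np.random.default_rng(3)
        pts = sp._sample_uniform(rng, 40, box_domain, cfg)
        res = sp.ripley_envelope(
            [pts], [box_domain], np.array([0.5, 1.0, 2.0]), 100, seed=1, config=cfg
        )
        assert (res.lower <= res.upper).all()
        outside = (res.h_obs > res.upper) | (res.h_obs < res.lower)
        np.testing.assert_array_equal(outside, res.flag != 0)

    def test_tiny_domain_is_error(self, cfg):
        vox = sp.voxels_to_um(np.argwhere(np.ones((1, 2, 2), bool)), cfg)
        with pytest.raises(ValueError, match="voxels"):
            sp.ripley_envelope(
                [np.zeros((5, 3))], [vox], np.array([1.0]), 100, 0, cfg
            )

    def test_thomas_clusters_flagged_as_clustered(self, cfg, box_domain):
        rng = np.random.default_rng(4)
        hits = 0
        for trial in range(20):
            parents = sp._sample_uniform(rng, 6, box_domain, cfg)
            pts = parents[rng.integers(6, size=60)].copy()
            pts[:, :2] += rng.normal(0, 1.0, size=(60, 2))
            res = sp.ripley_envelope(
                [pts], [box_domain], np.array([1.0, 1.5, 2.0]), 100,
                seed=trial, config=cfg,
            )
            hits += res.clustered
        assert hits >= 18

    def test_process_averaging_uses_each_process(self, cfg, ramified_cell, mixed_panel):
        from gliamorph import synthetic as S

        tx = S.simulate_transcripts(ramified_cell, mixed_panel, seed=5, config=cfg)
        res = sp.ripley_cell_gene(
            ramified_cell, tx, "proc_hi", "process", cfg,
            radii=np.array([0.5, 1.0]), n_null=50, seed=0,
        )
        assert res.n_domains >= 1
        assert res.n_points >= 2


class TestColocRadius:
    def test_definitional_percentile(self):
        d = np.arange(1.0, 101.0)
        assert sp.coloc_radius(d, 5.0) == pytest.approx(5.95)

    def test_all_equal_distances(self):
        assert sp.coloc_radius(np.full(30, 2.5), 5.0) == 2.5

    @given(st.floats(1.0, 50.0), st.floats(1.0, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_percentile(self, p1, p2):
        rng = np.random.default_rng(0)
        d = rng.exponential(2.0, size=200)
        lo, hi = sorted((p1, p2))
        assert sp.coloc_radius(d, lo) <= sp.coloc_radius(d, hi)

    def test_too_few_distances_is_error(self):
        with pytest.raises(ValueError):
            sp.coloc_radius(np.ones(5), 5.0)


class TestPairCounts:
    def _table(self, genes, coords):
        df = pd.DataFrame(coords, columns=["x", "y", "z"])
        df.insert(0, "gene", genes)
        df["compartment"] = SOMA
        df["cell_id"] = "c"
        return TranscriptTable(df)

    def test_one_a_one_b_within_radius(self, cfg, disk_cell):
        cx, cy = disk_cell.soma_centroid
        t = self._table(
            ["A", "B"], [[cx, cy, 0], [cx + 0.5 / cfg.pixel_size, cy, 0]]
        )
        genes, counts = sp.coloc_counts(disk_cell, t, SOMA, 1.0, cfg)
        assert genes == ["A", "B"]
        assert counts.tolist() == [1]

    def test_one_a_two_b_counts_two(self, cfg, disk_cell):
        cx, cy = disk_cell.soma_centroid
        dx = 0.4 / cfg.pixel_size
        t = self._table(
            ["A", "B", "B"],
            [[cx, cy, 0], [cx + dx, cy, 0], [cx - dx, cy, 0]],
        )
        _, counts = sp.coloc_counts(disk_cell, t, SOMA, 1.0, cfg)
        assert counts.tolist() == [2]

    def test_same_gene_pairs_excluded(self, cfg, disk_cell):
        cx, cy = disk_cell.soma_centroid
        t = self._table(["A", "A"], [[cx, cy, 0], [cx + 1, cy, 0]])
        genes, counts = sp.coloc_counts(disk_cell, t, SOMA, 5.0, cfg)
        assert counts.sum() == 0

    def test_matches_brute_force(self, cfg, disk_cell):
        rng = np.random.default_rng(1)
        cx, cy = disk_cell.soma_centroid
        n = 60
        coords = np.column_stack(
            [
                cx + rng.uniform(-15, 15, n),
                cy + rng.uniform(-15, 15, n),
                rng.integers(0, 3, n),
            ]
        )
        genes = rng.choice(["A", "B", "C"], size=n).tolist()
        t = self._table(genes, coords)
        r = 1.2
        gene_list, counts = sp.coloc_counts(disk_cell, t, SOMA, r, cfg)
        # brute force over all molecule pairs
        pts = sp.transcripts_to_um(t.df, cfg)
        brute = {}
        for i in range(n):
            for j in range(i + 1, n):
                if genes[i] == genes[j]:
                    continue
                if np.linalg.norm(pts[i] - pts[j]) <= r:
                    key = tuple(sorted((genes[i], genes[j])))
                    brute[key] = brute.get(key, 0) + 1
        for idx, pair in enumerate(sp.pair_names(gene_list)):
            assert counts[idx] == brute.get(pair, 0)


class TestColocNull:
    def test_counts_conserved_and_deterministic(self, cfg, ramified_cell, mixed_panel):
        from gliamorph import synthetic as S

        tx = S.simulate_transcripts(ramified_cell, mixed_panel, seed=6, config=cfg)
        cc1 = sp.coloc_null(ramified_cell, tx, SOMA, 1.0, cfg, n_null=120, seed=3)
        cc2 = sp.coloc_null(ramified_cell, tx, SOMA, 1.0, cfg, n_null=120, seed=3)
        np.testing.assert_array_equal(cc1.null, cc2.null)
        # per-gene molecule counts are preserved by construction: the null
        # can never count more pairs than molecules allow
        n_soma = (tx.df["compartment"] == SOMA).sum()
        assert cc1.null.max() <= n_soma * (n_soma - 1) / 2

    def test_null_mean_matches_geometric_expectation(self, cfg):
        """One molecule each of two genes: P(close pair) from geometry."""
        from gliamorph import synthetic as S

        disk = S.simulate_cell(
            S.ShapeParams(soma_radius=25, n_primary_branches=0, image_size=80),
            seed=9, plane_noise=0.0,
        )
        cx, cy = disk.soma_centroid
        df = pd.DataFrame(
            {
                "gene": ["A", "B"],
                "x": [cx, cy],
                "y": [cy, cx],
                "z": [0, 0],
                "compartment": [SOMA, SOMA],
                "cell_id": ["c", "c"],
            }
        )
        r = 1.0
        cc = sp.coloc_null(disk, TranscriptTable(df), SOMA, r, cfg, n_null=5000, seed=1)
        # brute-force Monte-Carlo of the same geometry, independent stream
        vox = sp.voxels_to_um(np.argwhere(disk.soma), cfg)
        rng = np.random.default_rng(123)
        a = sp._sample_uniform(rng, 20000, vox, cfg)
        b = sp._sample_uniform(rng, 20000, vox, cfg)
        p_close = (np.linalg.norm(a - b, axis=1) <= r).mean()
        assert cc.null.mean() == pytest.approx(p_close, rel=0.10)


class TestColocSignificance:
    def _fake_coloc(self, cell_id, genes, observed, null):
        return sp.CellColoc(cell_id, genes, np.asarray(observed), np.asarray(null), 1.0)

    def test_two_planted_triads_become_two_components(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(8)]
        n_pairs = len(sp.pair_names(genes))
        names = sp.pair_names(genes)
        triad1 = {("g0", "g1"), ("g0", "g2"), ("g1", "g2")}
        triad2 = {("g3", "g4"), ("g3", "g5"), ("g4", "g5")}
        colocs = []
        for c in range(6):
            null = rng.poisson(3.0, size=(200, n_pairs))
            obs = null.mean(axis=0).copy()
            for idx, pair in enumerate(names):
                if pair in triad1 | triad2:
                    obs[idx] = 30.0
            colocs.append(self._fake_coloc(f"c{c}", genes, obs, null))
        table, net = sp.coloc_significance(colocs, seed=1)
        comps = [set(map(tuple, map(sorted, net.graph.subgraph(c).edges))) for c in net.components]
        assert len(net.components) == 2
        assert {frozenset({"g0", "g1", "g2"}), frozenset({"g3", "g4", "g5"})} == {
            frozenset(c) for c in net.components
        }
        # every node got a (component, cluster) label
        assert set(net.cluster_labels) == {"g0", "g1", "g2", "g3", "g4", "g5"}

    def test_isolated_pair_dropped_from_network_but_significant(self):
        rng = np.random.default_rng(1)
        genes = ["a", "b", "c"]
        names = sp.pair_names(genes)
        colocs = []
        for c in range(6):
            null = rng.poisson(3.0, size=(200, len(names)))
            obs = null.mean(axis=0).copy()
            obs[names.index(("a", "b"))] = 30.0
            colocs.append(self._fake_coloc(f"c{c}", genes, obs, null))
        table, net = sp.coloc_significance(colocs, seed=0)
        row = table[(table["gene_a"] == "a") & (table["gene_b"] == "b")].iloc[0]
        assert row["padj"] < 0.05
        assert net.graph.number_of_edges() == 0  # 2-gene component dropped

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(2)
        genes = ["a", "b", "c", "d"]
        names = sp.pair_names(genes)
        colocs = []
        for c in range(5):
            null = rng.poisson(2.0, size=(150, len(names)))
            obs = null.mean(axis=0) + rng.normal(0, 0.5, len(names))
            colocs.append(self._fake_coloc(f"c{c}", genes, obs, null))
        t1, _ = sp.coloc_significance(colocs, seed=0)
        t2, _ = sp.coloc_significance(colocs[::-1], seed=0)
        pd.testing.assert_frame_equal(t1, t2)

    def test_no_pairs_gives_empty_network(self):
        table, net = sp.coloc_significance([], seed=0)
        assert len(table) == 0
        assert net.graph.number_of_nodes() == 0
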
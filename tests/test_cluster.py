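"""Sensor adjacency, cluster formation and the permutation null."""

import numpy as np
import pandas as pd
import pytest

from erpiat import (
    Montage,
    SubjectContrast,
    build_adjacency,
    build_design,
    form_clusters,
    permutation_null,
    report_clusters,
)
from erpiat.montage import make_hemisphere_montage
from oracles import clusters_bruteforce


def random_graph(n_ch, rng, p_edge=0.3):
    """Random montage-free adjacency for oracle comparisons."""
    labels = tuple(f"E{i+1}" for i in range(n_ch))
    positions = rng.uniform(-90, 90, (n_ch, 3))
    pairs = tuple(
        (a, b)
        for a in range(n_ch)
        for b in range(a + 1, n_ch)
        if rng.random() < p_edge
    )
    from erpiat.cluster import AdjacencyGraph

    return AdjacencyGraph(labels=labels, positions=positions,
                          distance_threshold_mm=0.0, pairs=pairs)


class TestBuildAdjacency:
    def test_two_channels_within_threshold(self):
        m = Montage(labels=("a", "b"), positions=np.array([[0, 0, 0], [30, 0, 0.]]))
        assert build_adjacency(m, 40.0).pairs == ((0, 1),)

    def test_zero_threshold_gives_no_pairs(self):
        m = Montage(labels=("a", "b"), positions=np.array([[0, 0, 0], [30, 0, 0.]]))
        assert build_adjacency(m, 0.0).pairs == ()

    def test_symmetric_irreflexive_and_matches_allpairs_scan(self):
        montage = make_hemisphere_montage(64)
        graph = build_adjacency(montage, 40.0)
        d = montage.distances()
        expected = {(a, b) for a in range(64) for b in range(a + 1, 64)
                    if d[a, b] <= 40.0}
        assert set(graph.pairs) == expected
        assert all(a != b for a, b in graph.pairs)

    def test_region_partition_blocks_cross_region_pairs(self):
        montage = make_hemisphere_montage(16)
        region = {lab: ("left" if montage.positions[i, 0] < 0 else "right")
                  for i, lab in enumerate(montage.labels)}
        graph = build_adjacency(montage, 200.0, region=region)
        for a, b in graph.pairs:
            assert region[montage.labels[a]] == region[montage.labels[b]]


class TestFormClusters:
    def setup_method(self):
        self.m2 = Montage(labels=("a", "b"), positions=np.array([[0, 0, 0], [30, 0, 0.]]))
        self.F = np.array([[5.0, 6.0, 1.0], [2.0, 7.0, 1.0]])

    def test_all_subthreshold_yields_nothing(self):
        graph = build_adjacency(self.m2, 40.0)
        assert form_clusters(self.F, 10.0, graph) == []

    def test_neighboring_channels_merge_through_shared_timepoint(self):
        graph = build_adjacency(self.m2, 40.0)
        clusters = form_clusters(self.F, 4.0, graph)
        assert len(clusters) == 1
        assert clusters[0].mass == pytest.approx(18.0)
        assert sorted(clusters[0].cells) == [(0, 0), (0, 1), (1, 1)]

    def test_non_neighbors_stay_separate(self):
        graph = build_adjacency(self.m2, 10.0)
        masses = [c.mass for c in form_clusters(self.F, 4.0, graph)]
        assert masses == [11.0, 7.0]  # descending

    def test_matches_bruteforce_on_random_fields(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            graph = random_graph(8, rng)
            F = rng.exponential(2.0, (8, 20))
            mine = {
                (frozenset(c.cells), round(c.mass, 9))
                for c in form_clusters(F, 3.0, graph)
            }
            ref = {(cells, round(mass, 9))
                   for cells, mass in clusters_bruteforce(F, 3.0, graph.pairs)}
            assert mine == ref

    def test_matches_mne_cluster_labelling(self):
        """Independent cross-check against mne's cluster machinery."""
        mne_stats = pytest.importorskip("mne.stats")
        from mne.stats.cluster_level import _find_clusters
        from scipy.sparse import lil_matrix

        rng = np.random.default_rng(22)
        n_ch, n_t = 8, 20
        for _ in range(20):
            graph = random_graph(n_ch, rng)
            adj = lil_matrix((n_ch, n_ch))
            for a, b in graph.pairs:
                adj[a, b] = adj[b, a] = 1
            F = rng.exponential(2.0, (n_ch, n_t))
            combined = mne_stats.combine_adjacency(adj.tocsr(), n_t)
            mine = {frozenset(c.cells) for c in form_clusters(F, 3.0, graph)}
            ref = set()
            out, _ = _find_clusters(F.reshape(-1), threshold=3.0, adjacency=combined)
            for cl in out:
                idx = np.asarray(cl)
                if idx.dtype == bool:
                    idx = np.flatnonzero(idx)
                ref.add(frozenset((int(i) // n_t, int(i) % n_t) for i in idx))
            assert mine == ref

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(23)
        graph = random_graph(8, rng)
        F = rng.exponential(2.0, (8, 20))
        lo = form_clusters(F, 2.0, graph)
        hi = form_clusters(F, 4.0, graph)
        assert sum(len(c.cells) for c in hi) <= sum(len(c.cells) for c in lo)
        if lo and hi:
            assert hi[0].mass <= lo[0].mass


def _null_contrast_study(n=24, nch=8, nt=20, seed=0):
    rng = np.random.default_rng(seed)
    montage = make_hemisphere_montage(nch)
    pids = [f"P{i:03d}" for i in range(n)]
    cov = pd.DataFrame({
        "participant_id": pids,
        "group": ["control"] * (n // 2) + ["sibs"] * (n // 2),
        "age_months": rng.integers(156, 217, n),
        "gender": rng.choice(["female", "male"], n),
    })
    dscores = pd.DataFrame({"participant_id": pids, "d": rng.normal(0, 0.3, n)})
    design = build_design(cov, dscores)
    contrasts = [
        SubjectContrast(participant_id=pid, delta=rng.standard_normal((nch, nt)),
                        n_epochs_death=12, n_epochs_life=12, sampling_rate=25.0,
                        window=(-200.0, 600.0), channel_names=montage.labels)
        for pid in pids
    ]
    return contrasts, design, build_adjacency(montage, 80.0)


class TestPermutationNull:
    def test_deterministic_under_fixed_seed(self):
        contrasts, design, graph = _null_contrast_study(seed=31)
        a = permutation_null(contrasts, design, "d_score", graph,
                             n_permutations=100, seed=5)
        b = permutation_null(contrasts, design, "d_score", graph,
                             n_permutations=100, seed=5)
        np.testing.assert_array_equal(a.null_distribution, b.null_distribution)
        assert [c.p_corrected for c in a.clusters] == [c.p_corrected for c in b.clusters]

    def test_p_values_valid_and_floored(self):
        contrasts, design, graph = _null_contrast_study(seed=32)
        res = permutation_null(contrasts, design, "group", graph,
                               n_permutations=100, seed=6)
        for c in res.clusters:
            assert 1.0 / 101 <= c.p_corrected <= 1.0

    def test_unknown_regressor_rejected(self):
        contrasts, design, graph = _null_contrast_study(seed=33)
        with pytest.raises(KeyError):
            permutation_null(contrasts, design, "nonsense", graph, n_permutations=100)

    def test_too_few_permutations_rejected(self):
        contrasts, design, graph = _null_contrast_study(seed=34)
        with pytest.raises(ValueError):
            permutation_null(contrasts, design, "group", graph, n_permutations=50)


class TestReportClusters:
    def test_index_to_ms_arithmetic(self):
        """Cluster spanning samples 48-70 at 250 Hz, epoch start -200 ms."""
        contrasts, design, _ = _null_contrast_study(seed=35, nch=2, nt=80)
        for c in contrasts:
            c.sampling_rate = 250.0
            c.window = (-200.0, 120.0)
        montage = make_hemisphere_montage(2)
        graph = build_adjacency(montage, 200.0)
        # plant one strong cluster on channel 0, samples 48..70
        for i, c in enumerate(contrasts):
            c.delta[:] = np.random.default_rng(100 + i).standard_normal(c.delta.shape) * 0.01
            c.delta[0, 48:71] = design.X[i, 1] * 5.0
        res = permutation_null(contrasts, design, "group", graph,
                               n_permutations=100, seed=7)
        table = report_clusters(res)
        top = table.iloc[0]
        assert top["start_ms"] == pytest.approx(-200.0 + 48 * 4.0)
        assert top["end_ms"] == pytest.approx(-200.0 + 70 * 4.0)

    def test_empty_result_gives_empty_table(self):
        contrasts, design, graph = _null_contrast_study(seed=36)
        res = permutation_null(contrasts, design, "d_score", graph,
                               n_permutations=100, seed=8, cluster_forming_p=1e-9)
        table = report_clusters(res)
        assert len(table) == 0
        assert list(table.columns)[:4] == ["cluster", "regressor", "start_ms", "end_ms"]

    def test_rows_sorted_by_descending_mass(self):
        contrasts, design, graph = _null_contrast_study(seed=37)
        res = permutation_null(contrasts, design, "group", graph,
                               n_permutations=100, seed=9)
        table = report_clusters(res)
        if len(table) > 1:
            assert list(table["mass"]) == sorted(table["mass"], reverse=True)
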
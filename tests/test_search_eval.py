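"""Cosine baselines, the evaluation battery and network-edge filtering."""

import itertools

import numpy as np
import pytest

from transexion.search_eval import (
    ScoredPair,
    cosine_score,
    evaluate,
    library_search,
    network_edges,
)
from transexion.training import PairSamplingConfig

from .conftest import make_spectrum, random_spectrum


def optimal_assignment_cosine(a, b, tol=0.02, mode="plain"):
    """Brute force over all one-to-one peak assignments (oracle)."""
    shift = (a.precursor_mz - b.precursor_mz) if mode == "modified" else None
    na, nb = len(a), len(b)
    idx_b = list(range(nb))
    best = 0.0
    for perm in itertools.permutations(idx_b, min(na, nb)):
        total = 0.0
        for i, j in zip(range(na), perm):
            d = abs(a.peaks[i].mz - b.peaks[j].mz)
            ok = d <= tol + 1e-9
            if mode == "modified" and not ok:
                ok = abs((a.peaks[i].mz - b.peaks[j].mz) - shift) <= tol + 1e-9
            if ok:
                total += a.peaks[i].intensity * b.peaks[j].intensity
        best = max(best, total)
    # also consider subsets implicitly: unmatched pairs contribute 0
    denom = float(np.linalg.norm(a.intensity) * np.linalg.norm(b.intensity))
    return best / denom if denom else 0.0


class TestCosine:
    def test_identical_spectra_score_one(self):
        s = make_spectrum([100.0, 150.0, 210.5], [50.0, 100.0, 25.0], 300.0)
        assert cosine_score(s, s) == pytest.approx(1.0)
        assert cosine_score(s, s, mode="modified") == pytest.approx(1.0)

    def test_disjoint_spectra_score_zero(self):
        a = make_spectrum([100.0, 150.0], precursor_mz=300.0)
        b = make_spectrum([120.0, 170.0], precursor_mz=300.0)
        assert cosine_score(a, b) == 0.0
        assert cosine_score(a, b, mode="modified") == 0.0

    @pytest.mark.parametrize("mode", ["plain", "modified"])
    def test_three_peak_toy_matches_assignment_oracle(self, mode):
        rng = np.random.default_rng(17)
        for _ in range(30):
            a = random_spectrum(rng, max_peaks=3, spectrum_id="a")
            b = random_spectrum(rng, max_peaks=3, spectrum_id="b")
            got = cosine_score(a, b, mode=mode)
            want = optimal_assignment_cosine(a, b, mode=mode)
            assert got == pytest.approx(want, abs=1e-9)

    def test_modified_cosine_detects_precursor_shifted_analog(self):
        a = make_spectrum([100.0, 150.0, 200.0], [100, 80, 60], precursor_mz=250.0)
        b = make_spectrum([114.02, 164.02, 214.02], [100, 80, 60], precursor_mz=264.02)
        assert cosine_score(a, b) == 0.0
        assert cosine_score(a, b, mode="modified") == pytest.approx(1.0)

    def test_modified_requires_precursor(self):
        a = make_spectrum([100.0], precursor_mz=None)
        b = make_spectrum([100.0], precursor_mz=200.0)
        with pytest.raises(ValueError, match="precursor"):
            cosine_score(a, b, mode="modified")

    def test_symmetry(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            a = random_spectrum(rng, max_peaks=8)
            b = random_spectrum(rng, max_peaks=8)
            assert cosine_score(a, b) == pytest.approx(cosine_score(b, a), abs=1e-9)
            assert cosine_score(a, b, mode="modified") == pytest.approx(
                cosine_score(b, a, mode="modified"), abs=1e-9
            )

    def test_matches_matchms_on_random_spectra(self):
        # independent implementation cross-check
        from matchms import Spectrum as MSpectrum
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(19)
        sim = CosineGreedy(tolerance=0.02)
        for _ in range(10):
            a = random_spectrum(rng, max_peaks=10)
            b = random_spectrum(rng, max_peaks=10)
            ma = MSpectrum(
                mz=a.mz, intensities=a.intensity, metadata={}, metadata_harmonization=False
            )
            mb = MSpectrum(
                mz=b.mz, intensities=b.intensity, metadata={}, metadata_harmonization=False
            )
            want = float(sim.pair(ma, mb)["score"])
            got = cosine_score(a, b)
            assert got == pytest.approx(want, abs=1e-6)


def _pairs_from_arrays(scores, labels):
    return [
        ScoredPair(f"q{i}", f"r{i}", float(s), float(l))
        for i, (s, l) in enumerate(zip(scores, labels))
    ]


class TestEvaluate:
    def test_perfect_predictor_identities(self):
        rng = np.random.default_rng(20)
        labels = rng.uniform(0, 1, size=40)
        report = evaluate(_pairs_from_arrays(labels, labels))
        assert report.pearson_r == pytest.approx(1.0)
        for b, (mse, n) in report.per_bin_mse.items():
            assert mse == pytest.approx(0.0)
        for c, curve in report.pr_curves.items():
            # at threshold just above c, precision and recall are both 1
            exact = [pt for pt in curve if pt[0] > c]
            assert any(
                p == pytest.approx(1.0) and r == pytest.approx(1.0)
                for _, p, r in exact
            )

    def test_constant_predictor_r_zero_with_warning(self):
        labels = np.linspace(0, 1, 11)
        pairs = _pairs_from_arrays(np.full(11, 0.5), labels)
        with pytest.warns(UserWarning, match="degenerate"):
            report = evaluate(pairs)
        assert report.pearson_r == 0.0

    def test_pr_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(21)
        scores = rng.uniform(0, 1, size=20)
        labels = rng.uniform(0, 1, size=20)
        report = evaluate(_pairs_from_arrays(scores, labels))
        for c, curve in report.pr_curves.items():
            for t, precision, recall in curve:
                pred = scores >= t
                pos = labels > c
                tp = int((pred & pos).sum())
                fp = int((pred & ~pos).sum())
                fn = int((~pred & pos).sum())
                want_p = tp / (tp + fp) if tp + fp else 1.0
                want_r = tp / (tp + fn) if tp + fn else 0.0
                assert precision == pytest.approx(want_p)
                assert recall == pytest.approx(want_r)

    def test_recall_monotone_in_threshold(self):
        rng = np.random.default_rng(22)
        scores = rng.uniform(0, 1, size=50)
        labels = rng.uniform(0, 1, size=50)
        report = evaluate(_pairs_from_arrays(scores, labels))
        for curve in report.pr_curves.values():
            recalls = [r for _, _, r in curve]  # thresholds descending order?
            ts = [t for t, _, _ in curve]
            # curve is sorted by descending threshold: recall non-decreasing
            assert ts == sorted(ts, reverse=True)
            assert recalls == sorted(recalls)

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(23)
        scores = rng.uniform(0, 1, size=30)
        labels = rng.uniform(0, 1, size=30)
        pairs = _pairs_from_arrays(scores, labels)
        r1 = evaluate(pairs)
        r2 = evaluate(pairs[::-1])
        assert r1.pearson_r == pytest.approx(r2.pearson_r)
        assert set(r1.per_bin_mse) == set(r2.per_bin_mse)
        for b in r1.per_bin_mse:
            assert r1.per_bin_mse[b][0] == pytest.approx(r2.per_bin_mse[b][0])
            assert r1.per_bin_mse[b][1] == r2.per_bin_mse[b][1]

    def test_empty_bin_absent_not_zero(self):
        pairs = _pairs_from_arrays([0.1, 0.9], [0.05, 0.95])
        report = evaluate(pairs)
        assert set(report.per_bin_mse) == {0, 9}

    def test_unlabeled_pairs_rejected(self):
        with pytest.raises(ValueError, match="tanimoto_label"):
            evaluate([ScoredPair("q", "r", 0.5)])


class TestNetworkEdges:
    def test_all_below_threshold_empty(self):
        sim = {("a", "b"): 0.5, ("b", "c"): 0.6}
        assert network_edges(sim) == []

    def test_triangle_with_topk_two(self):
        sim = {("a", "b"): 0.9, ("b", "c"): 0.9, ("a", "c"): 0.9}
        edges = network_edges(sim, top_k_per_node=2)
        assert len(edges) == 3

    def test_symmetrization_averages(self):
        sim = {("a", "b"): 0.9, ("b", "a"): 0.7}
        edges = network_edges(sim)
        assert edges == [("a", "b", pytest.approx(0.8))]

    def test_family_splitting_matches_union_find_oracle(self):
        rng = np.random.default_rng(24)
        nodes = [f"n{i}" for i in range(10)]
        sim = {}
        for i in range(10):
            for j in range(i + 1, 10):
                sim[(nodes[i], nodes[j])] = float(rng.uniform(0.4, 1.0))
        edges = network_edges(sim, threshold=0.6, top_k_per_node=3, max_family_size=4)

        # oracle: union-find over returned edges; every component <= 4
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b, s in edges:
            assert s > 0.6
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        sizes = {}
        for n in nodes:
            sizes[find(n)] = sizes.get(find(n), 0) + 1
        assert all(v <= 4 for v in sizes.values())

    def test_node_order_invariance(self):
        rng = np.random.default_rng(25)
        nodes = [f"n{i}" for i in range(8)]
        items = []
        for i in range(8):
            for j in range(i + 1, 8):
                items.append(((nodes[i], nodes[j]), float(rng.uniform(0.5, 1.0))))
        e1 = network_edges(dict(items))
        e2 = network_edges(dict(reversed(items)))
        assert e1 == e2


class TestLibrarySearch:
    def test_empty_library_rejected(self):
        import transexion as tx

        model = tx.init_model(
            tx.ModelConfig(embed_dim=8, heads_per_block=(50, 10), hidden_dim=32,
                           tx_ffn_dim=64, seed=0)
        )
        q = make_spectrum([100.0], precursor_mz=200.0)
        with pytest.raises(ValueError, match="non-empty"):
            library_search(model, q, [])

    def test_top_n_larger_than_library_returns_all(self):
        import transexion as tx

        model = tx.init_model(
            tx.ModelConfig(embed_dim=8, heads_per_block=(50, 10), hidden_dim=32,
                           tx_ffn_dim=64, seed=0)
        )
        rng = np.random.default_rng(26)
        q = random_spectrum(rng, 5, "q")
        lib = [random_spectrum(rng, 5, f"ref{i}") for i in range(4)]
        hits = library_search(model, q, lib, top_n=100)
        assert len(hits) == 4
        scores = [h.y_sim for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_ranking_deterministic(self):
        import transexion as tx

        model = tx.init_model(
            tx.ModelConfig(embed_dim=8, heads_per_block=(50, 10), hidden_dim=32,
                           tx_ffn_dim=64, seed=0)
        )
        rng = np.random.default_rng(27)
        q = random_spectrum(rng, 5, "q")
        lib = [random_spectrum(rng, 5, f"ref{i}") for i in range(5)]
        r1 = library_search(model, q, lib)
        r2 = library_search(model, q, lib)
        assert [(h.reference_id, h.y_sim) for h in r1] == [
            (h.reference_id, h.y_sim) for h in r2
        ]
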
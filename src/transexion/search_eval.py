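"""Spectral library search, classical cosine baselines, evaluation metrics
and molecular-network edge export.

Evaluation mirrors structure-aware library-search practice: precision-recall
sweeps at several Tanimoto cut-offs defining "structural analog", squared
error of the predicted score against the structural similarity per
equal-width similarity bin, and the overall Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .encoding import encode_pair
from .model import SimilarityModel, predict_batch
from .spectra_io import Spectrum
from .training import PairSamplingConfig, bin_index

__all__ = [
    "ScoredPair",
    "EvalReport",
    "library_search",
    "cosine_score",
    "evaluate",
    "network_edges",
]

DEFAULT_CUTOFFS = (0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class ScoredPair:
    query_id: str
    reference_id: str
    y_sim: float
    tanimoto_label: Optional[float] = None
    baseline_scores: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class EvalReport:
    """Precision-recall sweeps, per-bin squared error, Pearson correlation.

    ``pr_curves[c]`` is a list of (score threshold, precision, recall) for
    analog cut-off c; ``per_bin_mse[b]`` is (mean squared error, number of
    pairs) for occupied similarity bin b.
    """

    pr_curves: Dict[float, List[Tuple[float, float, float]]]
    per_bin_mse: Dict[int, Tuple[float, int]]
    pearson_r: float


def library_search(
    model: SimilarityModel,
    query: Spectrum,
    library: Sequence[Spectrum],
    top_n: Optional[int] = None,
    batch_size: int = 256,
) -> List[ScoredPair]:
    """Score a query against every reference; return the top_n best matches.

    Ties in score are broken lexicographically on reference id so rankings
    are reproducible.
    """
    if not library:
        raise ValueError("library_search requires a non-empty library")
    encs = [encode_pair(query, ref) for ref in library]
    scores: List[float] = []
    for i in range(0, len(encs), batch_size):
        scores.extend(predict_batch(model, encs[i : i + batch_size]).tolist())
    pairs = [
        ScoredPair(query.spectrum_id, ref.spectrum_id, float(s))
        for ref, s in zip(library, scores)
    ]
    pairs.sort(key=lambda p: (-p.y_sim, p.reference_id))
    return pairs if top_n is None else pairs[:top_n]


def cosine_score(
    a: Spectrum,
    b: Spectrum,
    tol: float = 0.02,
    mode: str = "plain",
) -> float:
    """Classical (modified) cosine similarity of two spectra.

    Peaks are matched greedily by descending intensity product, each peak
    used at most once. ``plain`` matches peaks with |mz_a - mz_b| <= tol;
    ``modified`` additionally allows matches shifted by the precursor mass
    difference. The score is the sum of matched intensity products divided
    by the product of the spectra's intensity norms, hence in [0, 1].
    """
    if mode not in ("plain", "modified"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cosine_score requires non-empty spectra")
    shift = 0.0
    if mode == "modified":
        if a.precursor_mz is None or b.precursor_mz is None:
            raise ValueError("modified cosine requires both precursor m/z")
        shift = a.precursor_mz - b.precursor_mz

    mza, ia = a.mz, a.intensity
    mzb, ib = b.mz, b.intensity
    cands: List[Tuple[float, int, int]] = []
    seen = set()
    for off in ([0.0] if mode == "plain" else [0.0, shift]):
        d = np.abs(mza[:, None] - mzb[None, :] - off)
        for i, j in zip(*np.nonzero(d <= tol + 1e-9)):
            if (i, j) not in seen:
                seen.add((i, j))
                cands.append((float(ia[i] * ib[j]), int(i), int(j)))
    # greedy: strongest intensity product first; deterministic tie-break
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set = set()
    used_b: set = set()
    total = 0.0
    for prod, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += prod
    denom = float(np.linalg.norm(ia) * np.linalg.norm(ib))
    return total / denom if denom > 0 else 0.0


def _pr_sweep(
    scores: np.ndarray, labels: np.ndarray, cutoff: float
) -> List[Tuple[float, float, float]]:
    """Precision/recall at every unique score threshold for one analog
    cut-off (positive = label > cutoff; predicted = score >= threshold)."""
    positives = labels > cutoff
    n_pos = int(positives.sum())
    out: List[Tuple[float, float, float]] = []
    for t in np.unique(scores)[::-1]:
        predicted = scores >= t
        tp = int((predicted & positives).sum())
        n_pred = int(predicted.sum())
        precision = tp / n_pred if n_pred else 1.0
        recall = tp / n_pos if n_pos else 0.0
        out.append((float(t), precision, recall))
    return out


def evaluate(
    pairs: Sequence[ScoredPair],
    cfg: PairSamplingConfig = PairSamplingConfig(),
    cutoffs: Iterable[float] = DEFAULT_CUTOFFS,
) -> EvalReport:
    """Full evaluation battery over labeled scored pairs."""
    labeled = [p for p in pairs if p.tanimoto_label is not None]
    if not labeled:
        raise ValueError("evaluate requires pairs with tanimoto_label")
    scores = np.array([p.y_sim for p in labeled], dtype=float)
    labels = np.array([p.tanimoto_label for p in labeled], dtype=float)

    pr_curves = {float(c): _pr_sweep(scores, labels, float(c)) for c in cutoffs}

    per_bin: Dict[int, Tuple[float, int]] = {}
    bins = np.array([bin_index(l, cfg.num_bins) for l in labels])
    se = (scores - labels) ** 2
    for b in sorted(set(bins.tolist())):
        mask = bins == b
        per_bin[int(b)] = (float(se[mask].mean()), int(mask.sum()))

    if np.std(scores) == 0 or np.std(labels) == 0:
        warnings.warn("degenerate predictor or labels: Pearson r reported as 0")
        r = 0.0
    else:
        from scipy.stats import pearsonr

        r = float(pearsonr(scores, labels)[0])
    return EvalReport(pr_curves=pr_curves, per_bin_mse=per_bin, pearson_r=r)


def network_edges(
    similarity: Mapping[Tuple[str, str], float],
    threshold: float = 0.6,
    top_k_per_node: int = 10,
    max_family_size: int = 100,
) -> List[Tuple[str, str, float]]:
    """Molecular-network edges from pairwise similarity scores.

    Scores for (a, b) and (b, a) are averaged (symmetrization). Edges with
    score <= threshold are dropped; each node keeps only its top_k strongest
    edges; components larger than max_family_size are split by repeatedly
    removing their weakest edge. Output is sorted by (source, target) with
    source < target, independent of input order.
    """
    import networkx as nx

    sym: Dict[Tuple[str, str], List[float]] = {}
    for (a, b), s in similarity.items():
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        sym.setdefault(key, []).append(float(s))
    edges = {k: sum(v) / len(v) for k, v in sym.items()}
    edges = {k: s for k, s in edges.items() if s > threshold}

    # per-node top-k: keep an edge only if it ranks in the top k for both? —
    # GNPS convention: an edge survives if it is in the top k of *either*
    # endpoint is too permissive; require both endpoints to list it.
    by_node: Dict[str, List[Tuple[float, Tuple[str, str]]]] = {}
    for (a, b), s in edges.items():
        by_node.setdefault(a, []).append((s, (a, b)))
        by_node.setdefault(b, []).append((s, (a, b)))
    keep_count: Dict[Tuple[str, str], int] = {}
    for node, lst in by_node.items():
        lst.sort(key=lambda t: (-t[0], t[1]))
        for s, key in lst[:top_k_per_node]:
            keep_count[key] = keep_count.get(key, 0) + 1
    edges = {k: s for k, s in edges.items() if keep_count.get(k, 0) == 2}

    g = nx.Graph()
    for (a, b), s in edges.items():
        g.add_edge(a, b, weight=s)
    # split oversized molecular families by removing weakest edges
    changed = True
    while changed:
        changed = False
        for comp in [c for c in nx.connected_components(g)]:
            if len(comp) > max_family_size:
                sub = g.subgraph(comp)
                weakest = min(
                    sub.edges(data="weight"),
                    key=lambda e: (e[2], min(e[0], e[1]), max(e[0], e[1])),
                )
                g.remove_edge(weakest[0], weakest[1])
                changed = True

    out = [
        (min(a, b), max(a, b), float(d["weight"])) for a, b, d in g.edges(data=True)
    ]
    out.sort()
    return out
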
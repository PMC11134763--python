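"""Post-hoc explanation of a similarity score.

The predicted score is attributed back to (query fragment, reference
fragment) pairs by gradient-weighted attention relevance propagation in the
Deep Taylor style: within each tower's transformer encoder, per-layer
attention maps are weighted by their gradients (negative parts clamped to
zero, averaged over heads) and rolled out across layers; the CLS row of the
rollout assigns a relevance to every aligned-matrix data row; each row's
relevance is then distributed over its non-PAD cells in proportion to the
gradient magnitude at the embedded tokens, and every cell is mapped to the
reference fragment that produced its token. Fragment-tower cells map
directly onto fragment pairs; loss-tower cells map through the neutral-loss
-> fragment correspondence. The final relevance matrix is the sum of both
towers, each scaled by its (clamped) gradient x input contribution to the
fusion head.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .encoding import PairEncoding
from .model import SimilarityModel, Tower, pack_batch

__all__ = [
    "RelevanceMatrix",
    "IonAssociation",
    "QueryIonExplanation",
    "ExplanationReport",
    "relevance",
    "top_associations",
    "report_to_tsv",
    "render_heatmap",
]


@dataclass(frozen=True)
class RelevanceMatrix:
    """Nonnegative per-(query fragment, reference fragment) contributions."""

    scores: np.ndarray  # (s_q, s_r), >= 0
    query_mz: np.ndarray
    reference_mz: np.ndarray
    fragment_tower: Optional[np.ndarray] = None
    loss_tower: Optional[np.ndarray] = None


@dataclass(frozen=True)
class IonAssociation:
    reference_mz: float
    relevance: float
    shift: float  # reference_mz - query_mz, 2 dp


@dataclass(frozen=True)
class QueryIonExplanation:
    query_mz: float
    total_relevance: float
    associations: Tuple[IonAssociation, ...]


@dataclass(frozen=True)
class ExplanationReport:
    rows: Tuple[QueryIonExplanation, ...]
    y_sim: Optional[float] = None


def _attention_rollout(tower: Tower) -> np.ndarray:
    """Chefer-style rollout: R <- R + mean_h(clamp(grad * attn)) @ R."""
    maps = tower.encoder.attention_maps
    n_rows = maps[0].data.shape[-1]
    R = np.eye(n_rows, dtype=np.float64)
    for attn in maps:
        if attn.grad is None:
            raise RuntimeError("attention gradients missing; backward() not run")
        weighted = np.clip(attn.grad * attn.data, 0.0, None)  # (1,H,R,R)
        a_bar = weighted.mean(axis=1)[0].astype(np.float64)
        R = R + a_bar @ R
    return R


def _tower_cell_relevance(
    tower: Tower, aligned_provenance: np.ndarray, row_budget: np.ndarray
) -> np.ndarray:
    """Distribute per-row relevance onto non-PAD cells by gradient magnitude.

    Returns a (n_data_rows, n_cols) grid of cell relevances; rows whose
    cells are all PAD keep zero relevance (nothing to attribute to).
    """
    emb = tower.rows.last_embedded  # (1, R, C, E)
    if emb is None or emb.grad is None:
        raise RuntimeError("embedding gradients missing; backward() not run")
    g = np.linalg.norm(emb.grad[0].astype(np.float64), axis=-1)  # (R, C)
    n_rows, n_cols = aligned_provenance.shape
    cell = np.zeros((n_rows - 1, n_cols))
    for i in range(1, n_rows):
        mask = aligned_provenance[i] >= 0
        if not mask.any():
            continue
        w = g[i] * mask
        tot = w.sum()
        if tot <= 0:
            w = mask.astype(float)
            tot = w.sum()
        cell[i - 1] = row_budget[i - 1] * w / tot
    return cell


def relevance(model: SimilarityModel, pair: PairEncoding) -> RelevanceMatrix:
    """Pairwise fragment relevance for one encoded spectrum pair."""
    if not any(p.requires_grad for p in model.parameters().values()):
        raise RuntimeError("model gradients are disabled")
    s_q = len(pair.query_mz)
    s_r = len(pair.reference_mz)
    if s_q == 0 or s_r == 0:
        raise ValueError("relevance requires the pair's m/z axes (use encode_pair)")

    model.eval()
    model.zero_grad()
    frag_tokens, fmask, loss_tokens, lmask = pack_batch([pair])
    y = model.forward(frag_tokens, fmask, loss_tokens, lmask)
    y.backward(np.ones_like(y.data))

    # tower contributions at the fusion input: clamped gradient x input
    z = model.last_fused_input
    d = z.data.shape[-1] // 2
    gi = np.clip(z.grad[0] * z.data[0], 0.0, None).astype(np.float64)
    w_frag, w_loss = float(gi[:d].sum()), float(gi[d:].sum())
    if w_frag + w_loss <= 0:
        w_frag = w_loss = 0.5
    total = w_frag + w_loss

    out = np.zeros((s_q, s_r))
    breakdown = {}
    for name, tower, aligned, weight, q_map, r_map in (
        (
            "fragment",
            model.fragment_tower,
            pair.fragment_matrix,
            w_frag / total,
            np.arange(s_q),
            np.arange(s_r),
        ),
        (
            "loss",
            model.loss_tower,
            pair.loss_matrix,
            w_loss / total,
            pair.query_loss_origin,
            pair.reference_loss_origin,
        ),
    ):
        R = _attention_rollout(tower)
        row_rel = R[0, 1:].copy()  # relevance of data rows seen from CLS
        tot = row_rel.sum()
        row_rel = (row_rel / tot if tot > 0 else row_rel) * weight
        cell = _tower_cell_relevance(tower, aligned.provenance, row_rel)
        grid = np.zeros((s_q, s_r))
        prov = aligned.provenance[1:]
        for i in range(cell.shape[0]):
            if i >= len(q_map):
                break  # padded degenerate loss row
            qi = int(q_map[i])
            cols = np.nonzero(prov[i] >= 0)[0]
            for c in cols:
                rj = int(r_map[prov[i, c]])
                grid[qi, rj] += cell[i, c]
        breakdown[name] = grid
        out += grid

    return RelevanceMatrix(
        scores=out,
        query_mz=np.asarray(pair.query_mz, dtype=float),
        reference_mz=np.asarray(pair.reference_mz, dtype=float),
        fragment_tower=breakdown["fragment"],
        loss_tower=breakdown["loss"],
    )


def top_associations(
    rel: RelevanceMatrix, q: int = 20, k: int = 3
) -> ExplanationReport:
    """Rank query ions by total relevance and keep their top-k reference ions.

    Query-ion ties are broken toward higher m/z; association ties toward the
    smaller absolute mass shift, then lower reference m/z.
    """
    row_tot = rel.scores.sum(axis=1)
    order = sorted(
        range(len(row_tot)), key=lambda i: (-row_tot[i], -rel.query_mz[i])
    )[: min(q, len(row_tot))]
    rows: List[QueryIonExplanation] = []
    for i in order:
        shifts = rel.reference_mz - rel.query_mz[i]
        assoc_order = sorted(
            range(len(rel.reference_mz)),
            key=lambda j: (-rel.scores[i, j], abs(shifts[j]), rel.reference_mz[j]),
        )[: min(k, len(rel.reference_mz))]
        assocs = tuple(
            IonAssociation(
                reference_mz=float(rel.reference_mz[j]),
                relevance=float(rel.scores[i, j]),
                shift=round(float(shifts[j]), 2),
            )
            for j in assoc_order
        )
        rows.append(
            QueryIonExplanation(
                query_mz=float(rel.query_mz[i]),
                total_relevance=float(row_tot[i]),
                associations=assocs,
            )
        )
    return ExplanationReport(rows=tuple(rows))


def report_to_tsv(report: ExplanationReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_mz\treference_mz\tshift\trelevance\trank\n")
        for row in report.rows:
            for rank, a in enumerate(row.associations, start=1):
                fh.write(
                    f"{row.query_mz:.2f}\t{a.reference_mz:.2f}\t{a.shift:+.2f}"
                    f"\t{a.relevance:.6f}\t{rank}\n"
                )


def render_heatmap(report: ExplanationReport, out: str | Path) -> Path:
    """Render the association heatmap (darker = more relevant), annotated
    with mass shifts, and write a TSV twin next to the image."""
    if not report.rows:
        raise ValueError("cannot render an empty explanation report")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    ref_mzs = sorted(
        {a.reference_mz for row in report.rows for a in row.associations}
    )
    ref_idx = {mz: j for j, mz in enumerate(ref_mzs)}
    grid = np.zeros((len(report.rows), len(ref_mzs)))
    for i, row in enumerate(report.rows):
        for a in row.associations:
            grid[i, ref_idx[a.reference_mz]] = a.relevance

    fig, ax = plt.subplots(
        figsize=(max(4, 0.6 * len(ref_mzs)), max(3, 0.45 * len(report.rows)))
    )
    ax.imshow(grid, cmap="Greys", aspect="auto")
    ax.set_xticks(range(len(ref_mzs)), [f"{m:.2f}" for m in ref_mzs], rotation=90)
    ax.set_yticks(
        range(len(report.rows)), [f"{r.query_mz:.2f}" for r in report.rows]
    )
    ax.set_xlabel("reference product ion m/z")
    ax.set_ylabel("query product ion m/z")
    vmax = grid.max() or 1.0
    for i, row in enumerate(report.rows):
        for a in row.associations:
            j = ref_idx[a.reference_mz]
            dark = grid[i, j] / vmax > 0.5
            ax.text(
                j,
                i,
                f"{a.shift:+.2f}",
                ha="center",
                va="center",
                fontsize=7,
                color="white" if dark else "black",
            )
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    report_to_tsv(report, out.with_suffix(".tsv"))
    return out
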
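"""Pair encoding: mass-difference matrices and tokenized aligned matrices.

A (query, reference) spectrum pair is encoded as two integer token grids,
one per tower:

* the fragment grid, from the product-ion m/z values of both spectra;
* the neutral-loss grid, from the hypothetical neutral-loss spectra
  (precursor m/z minus fragment m/z).

For each grid, the s_q x s_r matrix of absolute m/z differences (MDM) is
split into nominal mass (integer Da) and mass defect (hundredths). Each
query fragment becomes one row of a fixed-width matrix whose columns index
nominal masses 0..299; the cell at column c holds the defect token (0-99)
of a mass difference with nominal mass c, or PAD when no difference with
that nominal mass exists. A CLS row is prepended as the aggregation slot
for the transformer. All arithmetic is done in integer hundredths of a Da,
so the nominal/defect split is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .spectra_io import Peak, Spectrum

__all__ = [
    "PAD_TOKEN",
    "CLS_TOKEN",
    "VOCAB_SIZE",
    "NOMINAL_CUTOFF",
    "MassDifferenceMatrix",
    "AlignedMatrix",
    "PairEncoding",
    "neutral_loss_spectrum",
    "mass_difference_matrix",
    "aligned_matrix",
    "encode_pair",
]

PAD_TOKEN = 100
CLS_TOKEN = 101
VOCAB_SIZE = 102
NOMINAL_CUTOFF = 300  # only mass differences below 300 Da are encoded


def _to_centi(mz: np.ndarray) -> np.ndarray:
    """m/z values (2-dp grid) to exact integer hundredths of a Da."""
    return np.rint(np.asarray(mz, dtype=float) * 100).astype(np.int64)


@dataclass(frozen=True)
class MassDifferenceMatrix:
    """Absolute m/z differences between every query and reference fragment.

    ``values[i, j] == |query_mz[i] - reference_mz[j]|`` on the 2-dp grid.
    Rows index query fragments, columns index reference fragments.
    """

    values: np.ndarray  # (s_q, s_r) float, 2 dp
    query_mz: np.ndarray  # (s_q,)
    reference_mz: np.ndarray  # (s_r,)
    reference_intensity: np.ndarray  # (s_r,) relative %

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class AlignedMatrix:
    """Tokenized aligned matrix: (n+1) x 300 integer grid.

    Row 0 is all CLS; data row i (1-based) encodes query fragment i-1.
    ``provenance[i, c]`` is the reference-fragment index whose mass
    difference produced the token at data cell (i, c), or -1 for PAD/CLS.
    """

    tokens: np.ndarray  # (n+1, 300) int
    provenance: np.ndarray  # (n+1, 300) int, -1 where PAD or CLS

    @property
    def n_rows(self) -> int:
        return self.tokens.shape[0]


@dataclass(frozen=True)
class PairEncoding:
    """Model input for one (query, reference) pair: both towers' grids.

    ``query_loss_origin[r]`` is the index of the query fragment whose
    neutral loss is encoded by data row r+1 of ``loss_matrix`` (and
    similarly for the reference side), which lets explanation scores
    computed on the loss grid be mapped back onto fragments.
    """

    fragment_matrix: AlignedMatrix
    loss_matrix: AlignedMatrix
    query_loss_origin: np.ndarray  # (n_losses_q,) -> query fragment index
    reference_loss_origin: np.ndarray  # (n_losses_r,) -> reference fragment index
    query_mz: np.ndarray = field(default_factory=lambda: np.zeros(0))
    reference_mz: np.ndarray = field(default_factory=lambda: np.zeros(0))


def neutral_loss_spectrum(
    s: Spectrum, return_origin: bool = False
) -> Spectrum | Tuple[Spectrum, np.ndarray]:
    """Hypothetical neutral-loss spectrum: precursor m/z minus fragment m/z.

    Losses <= 0 (fragment at or above the precursor) are dropped; the loss
    inherits the fragment's intensity. With ``return_origin=True`` also
    returns, for each loss peak in ascending-m/z order, the index of the
    fragment it came from.
    """
    if s.precursor_mz is None:
        raise ValueError(
            f"precursor required for neutral loss (spectrum {s.spectrum_id!r})"
        )
    prec_c = int(np.rint(s.precursor_mz * 100))
    entries = []
    for idx, p in enumerate(s.peaks):
        loss_c = prec_c - int(np.rint(p.mz * 100))
        if loss_c > 0:
            entries.append((loss_c, p.intensity, idx))
    entries.sort()
    peaks = tuple(Peak(c / 100.0, inten) for c, inten, _ in entries)
    out = Spectrum(
        peaks=peaks,
        precursor_mz=s.precursor_mz,
        spectrum_id=s.spectrum_id + "|neutral_loss",
        structure_key=s.structure_key,
    )
    if return_origin:
        return out, np.array([idx for _, _, idx in entries], dtype=np.int64)
    return out


def mass_difference_matrix(query: Spectrum, reference: Spectrum) -> MassDifferenceMatrix:
    """All-against-all absolute m/z differences, query rows x reference cols."""
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("mass_difference_matrix requires non-empty spectra")
    q = _to_centi(query.mz)
    r = _to_centi(reference.mz)
    diff = np.abs(q[:, None] - r[None, :])
    return MassDifferenceMatrix(
        values=diff / 100.0,
        query_mz=query.mz,
        reference_mz=reference.mz,
        reference_intensity=reference.intensity,
    )


def aligned_matrix(
    mdm: MassDifferenceMatrix, cutoff: float = float(NOMINAL_CUTOFF)
) -> AlignedMatrix:
    """Tokenize an MDM into the aligned matrix.

    Each difference d < cutoff lands in column floor(d) with token
    round((d - floor(d)) * 100). When two reference fragments give the same
    nominal mass for one query fragment, the defect of the more intense
    reference fragment wins (ties: smaller reference m/z). Cells with no
    difference are PAD; a CLS row is prepended.
    """
    n_q, n_r = mdm.shape
    m = int(cutoff)
    diff_c = np.rint(mdm.values * 100).astype(np.int64)  # integer hundredths
    cols = diff_c // 100
    defects = diff_c % 100

    tokens = np.full((n_q + 1, m), PAD_TOKEN, dtype=np.int64)
    prov = np.full((n_q + 1, m), -1, dtype=np.int64)
    tokens[0, :] = CLS_TOKEN

    # process reference fragments from weakest to strongest so that the
    # strongest (ties: smaller m/z processed last wins -> iterate larger mz
    # first within equal intensity) overwrites earlier entries
    order = sorted(
        range(n_r),
        key=lambda j: (mdm.reference_intensity[j], -mdm.reference_mz[j]),
    )
    for j in order:
        mask = diff_c[:, j] < m * 100
        rows = np.nonzero(mask)[0]
        tokens[rows + 1, cols[rows, j]] = defects[rows, j]
        prov[rows + 1, cols[rows, j]] = j
    return AlignedMatrix(tokens=tokens, provenance=prov)


def encode_pair(query: Spectrum, reference: Spectrum) -> PairEncoding:
    """Build both towers' aligned matrices for a preprocessed spectrum pair."""
    frag = aligned_matrix(mass_difference_matrix(query, reference))
    q_loss, q_origin = neutral_loss_spectrum(query, return_origin=True)
    r_loss, r_origin = neutral_loss_spectrum(reference, return_origin=True)
    if len(q_loss) == 0 or len(r_loss) == 0:
        # degenerate but legal: an all-PAD single data row keeps the tower
        # shape well-defined when one side has no positive losses
        loss = AlignedMatrix(
            tokens=np.vstack(
                [
                    np.full((1, NOMINAL_CUTOFF), CLS_TOKEN, dtype=np.int64),
                    np.full(
                        (max(len(q_loss), 1), NOMINAL_CUTOFF), PAD_TOKEN, dtype=np.int64
                    ),
                ]
            ),
            provenance=np.full(
                (max(len(q_loss), 1) + 1, NOMINAL_CUTOFF), -1, dtype=np.int64
            ),
        )
    else:
        loss = aligned_matrix(mass_difference_matrix(q_loss, r_loss))
    return PairEncoding(
        fragment_matrix=frag,
        loss_matrix=loss,
        query_loss_origin=q_origin,
        reference_loss_origin=r_origin,
        query_mz=query.mz,
        reference_mz=reference.mz,
    )
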
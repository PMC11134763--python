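"""Structure-supervised training.

Labels are structural similarities in [0, 1]: Tanimoto scores on path-based
(Daylight-style) fingerprints for real structures, or exact moiety-Jaccard
for synthetic molecules. Because random spectrum pairs are heavily skewed
toward low similarity, each epoch resamples a balanced pair set: similarity
is split into B equal-width bins, and every spectrum contributes at most one
random partner per occupied bin. Test pairs are built the same way with at
most k partners per bin, guarded against train/test structure overlap. The
network is fit by Adam on the mean squared error between the predicted
score and the label, with early stopping on validation MSE.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .encoding import PairEncoding, encode_pair
from .model import ModelConfig, SimilarityModel, pack_batch, predict_batch
from .nn import Adam
from .spectra_io import Spectrum
from .synthetic import SyntheticLibrary

__all__ = [
    "StructureRecord",
    "PairSamplingConfig",
    "TrainConfig",
    "SpectrumLibrary",
    "fingerprint_from_smiles",
    "load_structures",
    "tanimoto",
    "bin_index",
    "sample_epoch_pairs",
    "make_test_pairs",
    "train",
]

FINGERPRINT_BITS = 2048


@dataclass(frozen=True)
class StructureRecord:
    """A molecular structure as a fixed-length fingerprint bit set."""

    structure_key: str
    fingerprint: np.ndarray  # bool, length FINGERPRINT_BITS

    def __post_init__(self) -> None:
        fp = np.asarray(self.fingerprint, dtype=bool)
        object.__setattr__(self, "fingerprint", fp)


def fingerprint_from_smiles(smiles: str, n_bits: int = FINGERPRINT_BITS) -> np.ndarray:
    """Path-based hashed fingerprint (RDKit's Daylight-like RDKFingerprint)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES: {smiles!r}")
    bv = Chem.RDKFingerprint(mol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(bv.GetOnBits())] = True
    return arr


def load_structures(path: str | Path) -> Dict[str, StructureRecord]:
    """Read a TSV/CSV sidecar of (structure_key, SMILES) into records."""
    import pandas as pd

    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, header=None, names=["key", "smiles"], comment="#")
    out: Dict[str, StructureRecord] = {}
    for key, smiles in zip(df["key"], df["smiles"]):
        out[str(key)] = StructureRecord(str(key), fingerprint_from_smiles(str(smiles)))
    return out


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a n b| / |a u b| on equal-length bit sets; 0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


@dataclass(frozen=True)
class PairSamplingConfig:
    """Equal-width similarity binning for balanced pair construction."""

    num_bins: int = 10
    max_test_pairs_per_bin: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_bins < 1:
            raise ValueError("num_bins must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    symmetrize_pairs: bool = False  # also use each sampled pair with roles swapped

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def bin_index(score: float, num_bins: int = 10) -> int:
    """Bin of a similarity in [0,1]: [l, u) bins, final bin closed at 1."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"similarity {score} outside [0, 1]")
    return min(int(score * num_bins), num_bins - 1)


class SpectrumLibrary:
    """Spectra plus a structural-similarity oracle over structure keys."""

    def __init__(
        self,
        spectra: Sequence[Spectrum],
        similarity_fn: Callable[[str, str], float],
    ):
        missing = [s.spectrum_id for s in spectra if s.structure_key is None]
        if missing:
            raise ValueError(f"spectra without structure_key: {missing[:5]}")
        self.spectra = list(spectra)
        self._similarity_fn = similarity_fn
        self._cache: Dict[Tuple[str, str], float] = {}

    @classmethod
    def from_structures(
        cls, spectra: Sequence[Spectrum], records: Dict[str, StructureRecord]
    ) -> "SpectrumLibrary":
        def sim(a: str, b: str) -> float:
            return tanimoto(records[a].fingerprint, records[b].fingerprint)

        return cls(spectra, sim)

    @classmethod
    def from_synthetic(
        cls, library: SyntheticLibrary, split: Optional[str] = None
    ) -> "SpectrumLibrary":
        spectra = library.spectra if split is None else library.spectra_for_split(split)
        return cls(spectra, library.similarity)

    def similarity(self, key_a: str, key_b: str) -> float:
        k = (key_a, key_b) if key_a <= key_b else (key_b, key_a)
        v = self._cache.get(k)
        if v is None:
            v = float(self._similarity_fn(*k))
            self._cache[k] = v
        return v

    @property
    def structure_keys(self) -> set:
        return {s.structure_key for s in self.spectra}

    def __len__(self) -> int:
        return len(self.spectra)


LabeledPair = Tuple[str, str, float]  # (query_id, reference_id, label)


def sample_epoch_pairs(
    library: SpectrumLibrary,
    cfg: PairSamplingConfig,
    epoch_seed: int,
) -> List[LabeledPair]:
    """One balanced epoch: per spectrum, one random partner per occupied bin."""
    if len(library) < 2:
        raise ValueError("need at least 2 spectra to form pairs")
    rng = np.random.default_rng(epoch_seed)
    spectra = library.spectra
    pairs: List[LabeledPair] = []
    for s in spectra:
        by_bin: Dict[int, List[Tuple[str, float]]] = {}
        for t in spectra:
            if t.spectrum_id == s.spectrum_id:
                continue
            label = library.similarity(s.structure_key, t.structure_key)
            by_bin.setdefault(bin_index(label, cfg.num_bins), []).append(
                (t.spectrum_id, label)
            )
        for b in sorted(by_bin):
            cands = by_bin[b]
            tid, label = cands[int(rng.integers(0, len(cands)))]
            pairs.append((s.spectrum_id, tid, label))
    return pairs


def make_test_pairs(
    test_set: SpectrumLibrary,
    reference_set: SpectrumLibrary,
    cfg: PairSamplingConfig,
) -> List[LabeledPair]:
    """Balanced evaluation pairs: per test spectrum, <= k per similarity bin.

    Test and reference sets must not share structure keys (information
    leakage guard).
    """
    overlap = test_set.structure_keys & reference_set.structure_keys
    if overlap:
        raise ValueError(
            f"information leakage: shared structure keys {sorted(overlap)[:5]}"
        )
    rng = np.random.default_rng(cfg.seed)
    pairs: List[LabeledPair] = []
    for s in test_set.spectra:
        by_bin: Dict[int, List[Tuple[str, float]]] = {}
        for t in reference_set.spectra:
            label = test_set._similarity_fn(s.structure_key, t.structure_key)
            by_bin.setdefault(bin_index(label, cfg.num_bins), []).append(
                (t.spectrum_id, label)
            )
        for b in sorted(by_bin):
            cands = by_bin[b]
            take = min(cfg.max_test_pairs_per_bin, len(cands))
            idx = rng.choice(len(cands), size=take, replace=False)
            for i in sorted(int(x) for x in idx):
                pairs.append((s.spectrum_id, cands[i][0], cands[i][1]))
    return pairs


class _EncodingCache:
    """Pair encodings keyed by (query_id, reference_id)."""

    def __init__(self, spectra: Iterable[Spectrum]):
        self.by_id = {s.spectrum_id: s for s in spectra}
        self._cache: Dict[Tuple[str, str], PairEncoding] = {}

    def get(self, qid: str, rid: str) -> PairEncoding:
        key = (qid, rid)
        enc = self._cache.get(key)
        if enc is None:
            enc = encode_pair(self.by_id[qid], self.by_id[rid])
            self._cache[key] = enc
        return enc


def _mse_of(model: SimilarityModel, encs: List[PairEncoding], labels: np.ndarray,
            batch_size: int) -> float:
    preds = []
    for i in range(0, len(encs), batch_size):
        preds.append(predict_batch(model, encs[i : i + batch_size]))
    pred = np.concatenate(preds)
    return float(np.mean((pred - labels) ** 2))


def train(
    model: SimilarityModel,
    library: SpectrumLibrary,
    train_cfg: TrainConfig = TrainConfig(),
    sampling_cfg: PairSamplingConfig = PairSamplingConfig(),
    validation: Optional[SpectrumLibrary] = None,
    verbose: bool = False,
) -> Tuple[SimilarityModel, List[Dict[str, float]]]:
    """Fit the model; returns (best-validation model, per-epoch history).

    Each epoch resamples the balanced pair set with an epoch-indexed seed,
    minimizes MSE with Adam, and evaluates validation MSE on a fixed pair
    set (validation spectra paired against the training library). Training
    stops after ``patience`` epochs without validation improvement; the
    best-validation parameters are restored before returning.
    """
    if validation is not None:
        overlap = validation.structure_keys & library.structure_keys
        if overlap:
            raise ValueError(
                f"information leakage: validation shares structures {sorted(overlap)[:5]}"
            )

    params = model.parameters()
    opt = Adam(
        params,
        lr=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay,
    )
    cache = _EncodingCache(
        library.spectra + (validation.spectra if validation is not None else [])
    )

    val_pairs: List[LabeledPair] = []
    val_encs: List[PairEncoding] = []
    val_labels = np.zeros(0)
    if validation is not None:
        val_pairs = make_test_pairs(validation, library, sampling_cfg)
        val_encs = [cache.get(q, r) for q, r, _ in val_pairs]
        val_labels = np.array([lab for _, _, lab in val_pairs])

    rng = np.random.default_rng(train_cfg.seed)
    history: List[Dict[str, float]] = []
    best_val = np.inf
    best_state: Optional[Dict[str, np.ndarray]] = None
    best_epoch = -1
    stall = 0

    for epoch in range(train_cfg.max_epochs):
        epoch_seed = int(
            np.random.default_rng([train_cfg.seed, epoch]).integers(0, 2**31 - 1)
        )
        pairs = sample_epoch_pairs(library, sampling_cfg, epoch_seed)
        if train_cfg.symmetrize_pairs:
            pairs = pairs + [(r, q, lab) for q, r, lab in pairs]
        order = rng.permutation(len(pairs))

        model.train()
        total, count = 0.0, 0
        for start in range(0, len(pairs), train_cfg.batch_size):
            chunk = [pairs[i] for i in order[start : start + train_cfg.batch_size]]
            encs = [cache.get(q, r) for q, r, _ in chunk]
            labels = np.array([lab for _, _, lab in chunk], dtype=np.float32)
            y = model.forward(*pack_batch(encs))
            loss = ((y - labels) ** 2).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(chunk)
            count += len(chunk)

        entry: Dict[str, float] = {"epoch": epoch, "train_mse": total / max(count, 1)}
        if validation is not None:
            entry["val_mse"] = _mse_of(
                model, val_encs, val_labels, train_cfg.batch_size
            )
            if entry["val_mse"] < best_val - 1e-6:
                best_val = entry["val_mse"]
                best_state = {k: p.data.copy() for k, p in params.items()}
                best_epoch = epoch
                stall = 0
            else:
                stall += 1
        history.append(entry)
        if verbose:
            print(
                f"epoch {epoch:3d}  train_mse {entry['train_mse']:.4f}"
                + (f"  val_mse {entry['val_mse']:.4f}" if validation else "")
            )
        if validation is not None and stall >= train_cfg.patience:
            break

    if best_state is not None:
        for k, p in params.items():
            p.data = best_state[k]
    model.eval()
    return model, history
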
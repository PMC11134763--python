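"""Synthetic spectra with known ground-truth structural similarity.

Molecules are modelled as linear chains of moieties drawn from a small
alphabet of realistic residue/modification masses (CH2 14.02, O 15.99,
H2O 18.01, ...). An MS/MS spectrum of a molecule consists of peaks at the
masses of contiguous sub-chains (plus a proton adduct), with lognormal
intensities and optional spurious peaks. Analog families are built by
swapping one or two moieties of a shared scaffold, so that analog pairs
show exactly the 0.00 Da matches and small characteristic mass shifts
(+14.02, +15.99, ...) that structure-aware spectral comparison exploits.

Ground-truth similarity is the multiset Jaccard index of the two molecules'
moiety masses — exactly computable, symmetric, 1 iff the multisets match.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .spectra_io import Peak, Spectrum, preprocess

__all__ = [
    "MOIETY_ALPHABET",
    "NoiseConfig",
    "SyntheticMolecule",
    "SyntheticLibrary",
    "true_similarity",
    "spectrum_from_molecule",
    "generate_library",
    "make_analog_pair",
]

# moiety masses in Da (2 dp); includes the classic analog deltas
MOIETY_ALPHABET: Dict[str, float] = {
    "CH2": 14.02,
    "NH": 15.01,
    "O": 15.99,
    "H2O": 18.01,
    "C2H2": 26.02,
    "CO": 27.99,
    "C2H4": 28.05,
    "CH2O": 30.01,
    "S": 31.97,
    "Cl": 34.97,
    "C2H2O": 42.01,
    "C3H6": 42.05,
    "CO2": 44.00,
    "C4H8": 56.06,
    "Gly": 57.02,
    "C3H7N": 57.06,
    "C5H6": 66.05,
    "C4H4O": 68.03,
    "Ala": 71.04,
    "C6H4": 76.03,
    "Ser": 87.03,
    "Pro": 97.05,
    "Val": 99.07,
    "C4H7NO2": 101.05,
    "Leu": 113.08,
    "Asn": 114.04,
}

PROTON_MASS = 1.01  # adduct mass on the 2-dp grid


@dataclass(frozen=True)
class NoiseConfig:
    """What imperfect acquisition adds to the ideal fragment ladder.

    A fragment's base abundance is a stable property of the sub-chain
    (fragmentation propensity travels with the substructure, so analog
    molecules sharing a sub-chain produce it with similar abundance);
    ``intensity_sigma`` is the per-acquisition lognormal jitter on top.
    """

    intensity_sigma: float = 0.3  # lognormal acquisition jitter
    spurious_peak_prob: float = 0.1  # chance of one random noise peak
    max_peaks: int = 10  # strongest fragments kept per spectrum


@dataclass(frozen=True)
class SyntheticMolecule:
    """A linear chain of moieties; the chain order fixes fragmentation."""

    moieties: Tuple[float, ...]  # masses in Da, chain order
    molecule_id: str

    def __post_init__(self) -> None:
        if not (3 <= len(self.moieties) <= 12):
            raise ValueError("molecules carry 3-12 moieties")
        if self.total_mass > 1000.0:
            raise ValueError("total mass exceeds 1000 Da")

    @property
    def total_mass(self) -> float:
        return round(sum(self.moieties), 2)

    @property
    def multiset(self) -> Counter:
        return Counter(int(round(m * 100)) for m in self.moieties)


def true_similarity(a: SyntheticMolecule, b: SyntheticMolecule) -> float:
    """Multiset Jaccard of moiety masses: |a n b| / |a u b|."""
    ca, cb = a.multiset, b.multiset
    inter = sum((ca & cb).values())
    union = sum((ca | cb).values())
    return inter / union if union else 0.0


def _fragment_ladder(mol: SyntheticMolecule) -> List[Tuple[float, Tuple[int, int]]]:
    """All proper contiguous sub-chains as (protonated mass, bond positions).

    Duplicate masses keep the first (smallest-position) representative.
    """
    masses_c = [int(round(m * 100)) for m in mol.moieties]
    L = len(masses_c)
    by_mass: Dict[int, Tuple[int, int]] = {}
    for i in range(L):
        acc = 0
        for j in range(i, L):
            acc += masses_c[j]
            if j - i + 1 < L:  # proper fragment, not the intact chain
                mz_c = acc + int(round(PROTON_MASS * 100))
                if mz_c not in by_mass:
                    by_mass[mz_c] = (i, j)
    return [(c / 100.0, pos) for c, pos in sorted(by_mass.items())]


def _base_abundance(pos: Tuple[int, int], landscape_seed: int) -> float:
    """Fragmentation propensity of the sub-chain between bond positions
    (i, j): cleaving the same backbone bonds has the same propensity, so
    corresponding fragments of analog molecules share their abundance."""
    r = np.random.default_rng([landscape_seed & 0x7FFFFFFF, pos[0], pos[1]])
    return float(r.lognormal(mean=3.0, sigma=1.0))


def spectrum_from_molecule(
    mol: SyntheticMolecule,
    rng: np.random.Generator,
    noise: NoiseConfig = NoiseConfig(),
    spectrum_id: Optional[str] = None,
    landscape_seed: int = 0,
) -> Spectrum:
    """Simulate one spectrum: fragment ladder with bond-position-determined
    base abundances, acquisition jitter, and the strongest peaks kept."""
    ladder = _fragment_ladder(mol)
    base = np.array([_base_abundance(pos, landscape_seed) for _, pos in ladder])
    inten = base * rng.lognormal(mean=0.0, sigma=noise.intensity_sigma, size=len(ladder))
    order = np.argsort(-inten)
    keep = sorted(order[: noise.max_peaks])
    peaks = [Peak(ladder[i][0], float(inten[i])) for i in keep]
    if rng.random() < noise.spurious_peak_prob:
        noise_mz = round(float(rng.uniform(50.0, min(900.0, mol.total_mass))), 2)
        if all(abs(noise_mz - p.mz) > 1.6 for p in peaks):
            peaks.append(Peak(noise_mz, float(np.exp(3.0 - 2.0))))
    raw = Spectrum(
        peaks=tuple(sorted(peaks, key=lambda p: p.mz)),
        precursor_mz=round(mol.total_mass + PROTON_MASS, 2),
        spectrum_id=spectrum_id or mol.molecule_id,
        structure_key=mol.molecule_id,
    )
    return preprocess(raw)


@dataclass
class SyntheticLibrary:
    """Molecules, their spectra and a structure-disjoint split."""

    molecules: Dict[str, SyntheticMolecule]
    spectra: List[Spectrum]
    split_assignment: Dict[str, str]  # molecule_id -> train/validation/test

    def similarity(self, key_a: str, key_b: str) -> float:
        return true_similarity(self.molecules[key_a], self.molecules[key_b])

    def spectra_for_split(self, split: str) -> List[Spectrum]:
        return [
            s for s in self.spectra if self.split_assignment[s.structure_key] == split
        ]


def _random_scaffold(
    rng: np.random.Generator, length: int, masses: Optional[Sequence[float]] = None
) -> List[float]:
    if masses is None:
        masses = list(MOIETY_ALPHABET.values())
    while True:
        seq = [float(rng.choice(masses)) for _ in range(length)]
        if sum(seq) + PROTON_MASS <= 1000.0 - 120.0:
            return seq


def generate_library(
    n_molecules: int = 200,
    spectra_per_molecule: int = 1,
    noise_cfg: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    family_size: int = 6,
    split_fractions: Tuple[float, float, float] = (0.85, 0.05, 0.10),
) -> SyntheticLibrary:
    """Generate analog families of molecules with spectra and splits.

    Each family draws its own small moiety vocabulary (so unrelated families
    rarely share substructure, as for real compound classes) and a scaffold
    chain; members differ from the scaffold by one or two single-moiety
    swaps at random positions, or are a structural isomer of it (an adjacent
    transposition: identical moiety multiset, hence similarity 1, with a
    partly different fragment ladder). This spreads pair similarity over the
    whole range, including the near-identical top bin that real libraries
    owe to isomers and duplicated structures. Splits are assigned per
    molecule so train/validation/test never share a structure.
    """
    if n_molecules < 2:
        raise ValueError("need at least 2 molecules")
    rng = np.random.default_rng(seed)
    masses = sorted(MOIETY_ALPHABET.values())
    molecules: Dict[str, SyntheticMolecule] = {}
    midx = 0
    while len(molecules) < n_molecules:
        length = int(rng.integers(4, 11))
        vocab = rng.choice(masses, size=6, replace=False)
        scaffold = _random_scaffold(rng, length, vocab)
        for _ in range(min(family_size, n_molecules - len(molecules))):
            seq = list(scaffold)
            n_swaps = int(rng.integers(0, 3))
            if n_swaps == 0:  # isomer: transpose one adjacent moiety pair
                pos = int(rng.integers(0, len(seq) - 1))
                seq[pos], seq[pos + 1] = seq[pos + 1], seq[pos]
            for _ in range(n_swaps):
                pos = int(rng.integers(0, len(seq)))
                seq[pos] = float(rng.choice(masses))
            if sum(seq) + PROTON_MASS > 1000.0:
                seq = list(scaffold)
            mol_id = f"MOL{midx:04d}"
            molecules[mol_id] = SyntheticMolecule(tuple(seq), mol_id)
            midx += 1

    spectra: List[Spectrum] = []
    for mol_id, mol in molecules.items():
        for r in range(spectra_per_molecule):
            sid = mol_id if spectra_per_molecule == 1 else f"{mol_id}_r{r}"
            spectra.append(
                spectrum_from_molecule(mol, rng, noise_cfg, sid, landscape_seed=seed)
            )

    ids = list(molecules)
    perm = rng.permutation(len(ids))
    n_train = int(round(split_fractions[0] * len(ids)))
    n_val = int(round(split_fractions[1] * len(ids)))
    split: Dict[str, str] = {}
    for rank, idx in enumerate(perm):
        if rank < n_train:
            split[ids[idx]] = "train"
        elif rank < n_train + n_val:
            split[ids[idx]] = "validation"
        else:
            split[ids[idx]] = "test"
    return SyntheticLibrary(molecules=molecules, spectra=spectra, split_assignment=split)


def make_analog_pair(
    delta: float = 15.99,
    seed: int = 0,
    length: int = 7,
    noise_cfg: NoiseConfig = NoiseConfig(spurious_peak_prob=0.0),
) -> Tuple[SyntheticMolecule, SyntheticMolecule, Spectrum, Spectrum, int]:
    """A controlled analog pair: reference = query with one moiety heavier
    by ``delta`` Da at a random chain position.

    Returns (query molecule, reference molecule, query spectrum, reference
    spectrum, swap position). Fragments not covering the swap position match
    exactly between the two spectra; fragments covering it differ by delta.
    """
    rng = np.random.default_rng(seed)
    scaffold = _random_scaffold(rng, length)
    pos = int(rng.integers(0, length))
    ref_seq = list(scaffold)
    ref_seq[pos] = round(ref_seq[pos] + delta, 2)
    query = SyntheticMolecule(tuple(scaffold), f"query_d{delta}_s{seed}")
    reference = SyntheticMolecule(tuple(ref_seq), f"reference_d{delta}_s{seed}")
    sq = spectrum_from_molecule(query, rng, noise_cfg, landscape_seed=seed)
    sr = spectrum_from_molecule(reference, rng, noise_cfg, landscape_seed=seed)
    return query, reference, sq, sr, pos
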
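"""Labels, balanced pair sampling and the training loop."""

import numpy as np
import pytest

import transexion as tx
from transexion.model import ModelConfig, init_model
from transexion.training import (
    PairSamplingConfig,
    SpectrumLibrary,
    TrainConfig,
    bin_index,
    fingerprint_from_smiles,
    make_test_pairs,
    sample_epoch_pairs,
    tanimoto,
    train,
)

from .conftest import make_spectrum

TINY_MODEL = ModelConfig(
    embed_dim=8, heads_per_block=(50, 10), hidden_dim=32, tx_ffn_dim=64, seed=0
)


class TestTanimoto:
    def test_identical_nonempty(self):
        fp = np.zeros(2048, dtype=bool)
        fp[[3, 99, 500]] = True
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint(self):
        a = np.zeros(16, dtype=bool)
        b = np.zeros(16, dtype=bool)
        a[:4] = True
        b[8:] = True
        assert tanimoto(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(8, dtype=bool)
        b = np.zeros(8, dtype=bool)
        a[[1, 2, 3]] = True
        b[[2, 3, 4]] = True
        assert tanimoto(a, b) == 0.5

    def test_both_empty_defined_as_zero(self):
        z = np.zeros(8, dtype=bool)
        assert tanimoto(z, z) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(np.zeros(8, dtype=bool), np.zeros(16, dtype=bool))

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random(64) < 0.3
            b = rng.random(64) < 0.3
            s = tanimoto(a, b)
            assert s == tanimoto(b, a)
            assert 0.0 <= s <= 1.0
            if s == 1.0 and a.any():
                np.testing.assert_array_equal(a, b)

    def test_matches_rdkit_on_real_structures(self):
        # independent oracle: RDKit's own Tanimoto on the same bit vectors
        from rdkit import Chem, DataStructs

        pairs = [
            ("CCO", "CCN"),
            ("c1ccccc1O", "c1ccccc1N"),
            ("CC(=O)Oc1ccccc1C(=O)O", "CC(=O)Nc1ccc(O)cc1"),
        ]
        for sa, sb in pairs:
            bva = Chem.RDKFingerprint(Chem.MolFromSmiles(sa), fpSize=2048)
            bvb = Chem.RDKFingerprint(Chem.MolFromSmiles(sb), fpSize=2048)
            want = DataStructs.TanimotoSimilarity(bva, bvb)
            got = tanimoto(fingerprint_from_smiles(sa), fingerprint_from_smiles(sb))
            assert got == pytest.approx(want, abs=1e-12)


def test_load_structures_and_library_labels(tmp_path):
    """The fingerprint path: structures TSV -> records -> pair labels."""
    from pathlib import Path

    from transexion.training import load_structures

    records = load_structures(Path(__file__).parent / "data" / "structures.tsv")
    assert len(records) == 12
    assert all(r.fingerprint.shape == (2048,) for r in records.values())
    spectra = [
        make_spectrum([100.0, 150.0], precursor_mz=300.0, spectrum_id=k,
                      structure_key=k)
        for k in list(records)[:4]
    ]
    lib = SpectrumLibrary.from_structures(spectra, records)
    s = lib.similarity("S01", "S03")  # ethanol vs propanol: related
    d = lib.similarity("S01", "S05")  # ethanol vs benzene: unrelated
    assert 0.0 <= d < s <= 1.0
    assert lib.similarity("S01", "S01") == 1.0


class TestBinning:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.0, 0), (0.05, 0), (0.1, 1), (0.55, 5), (0.9, 9), (0.95, 9), (1.0, 9)],
    )
    def test_equal_width_bins_last_closed(self, score, expected):
        assert bin_index(score, 10) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_index(1.2, 10)


def _toy_library(sims: dict, n: int, prefix="m") -> SpectrumLibrary:
    """Library of n single-structure spectra with an explicit similarity table."""
    spectra = [
        make_spectrum(
            [100.0 + i, 150.0 + i],
            precursor_mz=400.0,
            spectrum_id=f"{prefix}{i}",
            structure_key=f"{prefix}{i}",
        )
        for i in range(n)
    ]

    def sim(a, b):
        if a == b:
            return 1.0
        return sims.get((a, b), sims.get((b, a), 0.0))

    return SpectrumLibrary(spectra, sim)


class TestEpochSampling:
    def test_partners_in_two_bins_give_two_pairs(self):
        sims = {("m0", "m1"): 0.05, ("m0", "m2"): 0.95}
        lib = _toy_library(sims, 3)
        pairs = sample_epoch_pairs(lib, PairSamplingConfig(), epoch_seed=0)
        mine = [p for p in pairs if p[0] == "m0"]
        assert len(mine) == 2
        assert {p[1] for p in mine} == {"m1", "m2"}

    def test_at_most_num_bins_pairs_per_spectrum(self):
        rng = np.random.default_rng(5)
        sims = {
            (f"m{i}", f"m{j}"): float(rng.random())
            for i in range(12)
            for j in range(i + 1, 12)
        }
        lib = _toy_library(sims, 12)
        pairs = sample_epoch_pairs(lib, PairSamplingConfig(), epoch_seed=1)
        counts = {}
        for q, r, lab in pairs:
            counts[q] = counts.get(q, 0) + 1
            assert q != r
            expected = 1.0 if q == r else sims.get((q, r), sims.get((r, q)))
            assert lab == pytest.approx(expected)
            assert bin_index(lab) == bin_index(lab)  # label valid in [0,1]
        assert all(c <= 10 for c in counts.values())

    def test_label_lies_in_its_bin_exhaustively(self):
        rng = np.random.default_rng(6)
        sims = {
            (f"m{i}", f"m{j}"): float(rng.random())
            for i in range(8)
            for j in range(i + 1, 8)
        }
        lib = _toy_library(sims, 8)
        pairs = sample_epoch_pairs(lib, PairSamplingConfig(), epoch_seed=2)
        # per spectrum, at most one pair per bin and the label is in the bin
        seen = set()
        for q, r, lab in pairs:
            b = bin_index(lab)
            assert (q, b) not in seen
            seen.add((q, b))

    def test_seed_determinism(self):
        sims = {("m0", "m1"): 0.4, ("m0", "m2"): 0.45, ("m1", "m2"): 0.2}
        lib = _toy_library(sims, 3)
        p1 = sample_epoch_pairs(lib, PairSamplingConfig(), epoch_seed=7)
        p2 = sample_epoch_pairs(lib, PairSamplingConfig(), epoch_seed=7)
        assert p1 == p2


class TestTestPairs:
    def test_full_bins_give_thirty_pairs(self):
        rng = np.random.default_rng(8)
        # one test spectrum, 40 references spread over all 10 bins
        sims = {}
        refs = {}
        for i in range(40):
            sims[("t0", f"m{i}")] = (i % 10) / 10.0 + 0.05
        test = _toy_library({}, 1, prefix="t")
        ref = _toy_library({}, 40, prefix="m")
        test._similarity_fn = lambda a, b: sims.get((a, b), sims.get((b, a), 0.0))
        pairs = make_test_pairs(test, ref, PairSamplingConfig(seed=0))
        assert len(pairs) == 30
        per_bin = {}
        for q, r, lab in pairs:
            per_bin.setdefault(bin_index(lab), []).append(r)
        assert all(len(v) == 3 for v in per_bin.values())
        assert all(len(set(v)) == len(v) for v in per_bin.values())

    def test_scarce_bin_gives_single_pair(self):
        sims = {("t0", "m0"): 0.35}
        test = _toy_library({}, 1, prefix="t")
        ref = _toy_library({}, 1, prefix="m")
        test._similarity_fn = lambda a, b: sims.get((a, b), sims.get((b, a), 0.0))
        pairs = make_test_pairs(test, ref, PairSamplingConfig(seed=0))
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(0.35)

    def test_leakage_guard(self):
        lib = _toy_library({}, 3)
        with pytest.raises(ValueError, match="leakage"):
            make_test_pairs(lib, lib, PairSamplingConfig())

    def test_determinism(self):
        rng = np.random.default_rng(9)
        sims = {("t0", f"m{i}"): float(rng.random()) for i in range(15)}
        test = _toy_library({}, 1, prefix="t")
        ref = _toy_library({}, 15, prefix="m")
        test._similarity_fn = lambda a, b: sims.get((a, b), sims.get((b, a), 0.0))
        cfg = PairSamplingConfig(seed=4)
        assert make_test_pairs(test, ref, cfg) == make_test_pairs(test, ref, cfg)


class TestTrainLoop:
    def test_one_epoch_smoke(self):
        lib = tx.generate_library(n_molecules=10, seed=3)
        slib = SpectrumLibrary.from_synthetic(lib)
        model = init_model(TINY_MODEL)
        model, history = train(
            model, slib, TrainConfig(seed=0, max_epochs=1), PairSamplingConfig()
        )
        assert len(history) == 1
        assert np.isfinite(history[0]["train_mse"])

    def test_loss_decreases_on_fixed_tiny_set(self):
        lib = tx.generate_library(n_molecules=6, seed=4)
        slib = SpectrumLibrary.from_synthetic(lib)
        model = init_model(TINY_MODEL)
        cfg = TrainConfig(seed=0, max_epochs=50, learning_rate=1e-3)
        model, history = train(model, slib, cfg, PairSamplingConfig())
        first = np.mean([h["train_mse"] for h in history[:5]])
        last = np.mean([h["train_mse"] for h in history[-5:]])
        assert last < first

    def test_validation_leakage_guard(self):
        lib = tx.generate_library(n_molecules=10, seed=3)
        slib = SpectrumLibrary.from_synthetic(lib)
        with pytest.raises(ValueError, match="leakage"):
            train(
                init_model(TINY_MODEL),
                slib,
                TrainConfig(max_epochs=1),
                PairSamplingConfig(),
                validation=slib,
            )
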
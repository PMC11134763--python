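import numpy as np
import pytest

from transexion.spectra_io import Peak, Spectrum


def make_spectrum(
    mzs, intensities=None, precursor_mz=500.0, spectrum_id="s", structure_key=None
) -> Spectrum:
    if intensities is None:
        intensities = [100.0] * len(mzs)
    return Spectrum(
        peaks=tuple(Peak(m, i) for m, i in zip(mzs, intensities)),
        precursor_mz=precursor_mz,
        spectrum_id=spectrum_id,
        structure_key=structure_key,
    )


def random_spectrum(
    rng: np.random.Generator, max_peaks: int = 30, spectrum_id: str = "s"
) -> Spectrum:
    """A random preprocessed-looking spectrum on the 2-dp grid."""
    n = int(rng.integers(1, max_peaks + 1))
    mzs = np.unique(np.round(rng.uniform(10.0, 990.0, size=n), 2))
    intensities = rng.uniform(0.2, 100.0, size=len(mzs))
    prec = round(float(mzs.max()) + float(rng.uniform(1.0, 50.0)), 2)
    return make_spectrum(mzs.tolist(), intensities.tolist(), prec, spectrum_id)


@pytest.fixture(scope="session")
def synthetic_study():
    """The 200-molecule parameter-recovery study: library, trained model and
    held-out predictions, shared by the slow end-to-end checks."""
    import transexion as tx
    from transexion.model import predict_batch
    from transexion.training import (
        PairSamplingConfig,
        SpectrumLibrary,
        TrainConfig,
        _EncodingCache,
        make_test_pairs,
        train,
    )

    lib = tx.generate_library(n_molecules=200, seed=0)
    train_lib = SpectrumLibrary.from_synthetic(lib, "train")
    val_lib = SpectrumLibrary.from_synthetic(lib, "validation")
    test_lib = SpectrumLibrary.from_synthetic(lib, "test")

    model = tx.init_model(tx.ModelConfig(seed=0))
    model, history = train(
        model,
        train_lib,
        TrainConfig(seed=0, max_epochs=50, patience=50),
        PairSamplingConfig(seed=0),
        validation=val_lib,
    )

    pairs = make_test_pairs(test_lib, train_lib, PairSamplingConfig(seed=1))
    cache = _EncodingCache(lib.spectra)
    encs = [cache.get(q, r) for q, r, _ in pairs]
    preds = np.concatenate(
        [predict_batch(model, encs[i : i + 256]) for i in range(0, len(encs), 256)]
    )
    return {
        "library": lib,
        "train_lib": train_lib,
        "model": model,
        "history": history,
        "test_pairs": pairs,
        "test_predictions": preds,
    }
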
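"""Reading, writing and preprocessing of MS/MS spectra.

Spectra are plain peak lists (m/z in Da, intensity) with a precursor m/z.
Preprocessing follows the conventions of structure-aware spectral library
search: m/z rounded to two decimals, intensities rescaled to percent of the
base peak, low-intensity and out-of-range peaks removed, and a 3-Da
non-maximum suppression that keeps only the highest peak in each local
neighbourhood (isotope satellites and chemical noise around a large peak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np

__all__ = [
    "Peak",
    "Spectrum",
    "read_spectra",
    "write_spectra",
    "preprocess",
    "EmptySpectrumError",
    "SpectrumParseError",
]


class SpectrumParseError(ValueError):
    """A record in a spectrum file could not be parsed."""


class EmptySpectrumError(ValueError):
    """Preprocessing removed every peak of a spectrum."""


@dataclass(frozen=True)
class Peak:
    """A single product-ion peak: m/z in Da, intensity (relative % after
    preprocessing, arbitrary units before)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if not (self.intensity > 0):
            raise ValueError(f"peak intensity must be positive, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """An MS/MS spectrum: peaks sorted ascending by m/z plus precursor m/z.

    ``structure_key`` optionally links the spectrum to a structure record
    (e.g. the first block of an InChIKey, or a synthetic molecule id) and is
    what train/test splits are made disjoint on.
    """

    peaks: tuple[Peak, ...]
    precursor_mz: Optional[float] = None
    spectrum_id: str = ""
    structure_key: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            object.__setattr__(
                self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
            )
        if self.precursor_mz is not None and not (self.precursor_mz > 0):
            raise ValueError("precursor_mz must be positive when present")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return replace(self, peaks=tuple(peaks))


def _spectrum_from_arrays(
    mz: Sequence[float],
    intensity: Sequence[float],
    precursor_mz: Optional[float],
    spectrum_id: str,
    structure_key: Optional[str] = None,
) -> Spectrum:
    peaks = tuple(
        Peak(float(m), float(i)) for m, i in zip(mz, intensity) if float(i) > 0
    )
    return Spectrum(
        peaks=peaks,
        precursor_mz=precursor_mz,
        spectrum_id=spectrum_id,
        structure_key=structure_key,
    )


def read_spectra(path: str | Path, format: Optional[str] = None) -> List[Spectrum]:
    """Read spectra from an MGF or MSP file.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"mgf"`` or ``"msp"``; inferred from the file suffix when omitted.

    Peaks are returned raw (no preprocessing). A record without a precursor
    field yields a spectrum with ``precursor_mz=None``; the error is deferred
    until something (e.g. neutral-loss derivation) actually needs it.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mgf":
        return _read_mgf(path)
    if fmt == "msp":
        return _read_msp(path)
    raise ValueError(f"unsupported spectrum format: {fmt!r} (expected mgf or msp)")


def _read_mgf(path: Path) -> List[Spectrum]:
    from pyteomics import mgf

    out: List[Spectrum] = []
    try:
        with mgf.MGF(str(path)) as reader:
            for idx, rec in enumerate(reader):
                try:
                    params = rec.get("params", {})
                    pep = params.get("pepmass")
                    prec = None
                    if pep is not None:
                        prec = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
                    title = str(params.get("title", f"spectrum_{idx}"))
                    skey = params.get("structure_key")
                    out.append(
                        _spectrum_from_arrays(
                            rec["m/z array"],
                            rec["intensity array"],
                            prec,
                            title,
                            str(skey) if skey is not None else None,
                        )
                    )
                except Exception as exc:  # noqa: BLE001 - re-raise with record index
                    raise SpectrumParseError(
                        f"malformed MGF record {idx} in {path}: {exc}"
                    ) from exc
    except SpectrumParseError:
        raise
    except Exception as exc:  # pyteomics-level failure
        raise SpectrumParseError(f"could not parse MGF file {path}: {exc}") from exc
    return out


def _read_msp(path: Path) -> List[Spectrum]:
    from matchms.importing import load_from_msp

    out: List[Spectrum] = []
    for idx, ms in enumerate(load_from_msp(str(path), metadata_harmonization=False)):
        if ms is None:
            raise SpectrumParseError(f"malformed MSP record {idx} in {path}")
        meta = {k.lower(): v for k, v in ms.metadata.items()}
        prec = meta.get("precursormz") or meta.get("precursor_mz")
        prec_f = float(prec) if prec not in (None, "") else None
        name = str(meta.get("name") or meta.get("compound_name") or f"spectrum_{idx}")
        out.append(
            _spectrum_from_arrays(ms.peaks.mz, ms.peaks.intensities, prec_f, name)
        )
    return out


def write_spectra(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (``BEGIN IONS``/``END IONS`` blocks).

    m/z values are written with two decimals, matching the preprocessing
    grid, so a write/read round trip preserves peak lists exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            if s.precursor_mz is not None:
                fh.write(f"PEPMASS={s.precursor_mz:.2f}\n")
            if s.structure_key is not None:
                fh.write(f"STRUCTURE_KEY={s.structure_key}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.2f} {p.intensity:.6g}\n")
            fh.write("END IONS\n")


def _round2(x: float) -> float:
    # decimal-faithful half-up rounding on the hundredths grid; avoids
    # banker's-rounding surprises for values like 0.125
    return math.floor(x * 100 + 0.5) / 100.0


def preprocess(
    s: Spectrum,
    min_rel_intensity: float = 0.1,
    mz_min: float = 10.0,
    mz_max: float = 1000.0,
    window: float = 3.0,
) -> Spectrum:
    """Clean a raw spectrum for encoding.

    Pipeline (order matters — relative intensities must exist before the
    percent threshold is applied):

    1. round m/z to 2 decimals, merging equal-m/z peaks by keeping the
       larger intensity;
    2. rescale intensities to % of the base peak;
    3. drop peaks below ``min_rel_intensity`` percent;
    4. drop peaks with m/z outside [``mz_min``, ``mz_max``];
    5. window denoising: walk peaks by descending intensity (ties: lower
       m/z first) and keep a peak only if no already-kept peak lies within
       ``window / 2`` Da of it.

    Raises
    ------
    EmptySpectrumError
        if every peak is removed.
    """
    if len(s) == 0:
        raise EmptySpectrumError(f"spectrum {s.spectrum_id!r} has no peaks")

    merged: dict[float, float] = {}
    for p in s.peaks:
        mz = _round2(p.mz)
        if p.intensity > merged.get(mz, 0.0):
            merged[mz] = p.intensity

    base = max(merged.values())
    peaks = [
        (mz, 100.0 * inten / base)
        for mz, inten in merged.items()
        if 100.0 * inten / base >= min_rel_intensity and mz_min <= mz <= mz_max
    ]

    radius = window / 2.0
    kept: list[tuple[float, float]] = []
    for mz, inten in sorted(peaks, key=lambda t: (-t[1], t[0])):
        if all(abs(mz - kmz) > radius for kmz, _ in kept):
            kept.append((mz, inten))

    if not kept:
        raise EmptySpectrumError(
            f"empty spectrum after preprocessing: {s.spectrum_id!r}"
        )
    # rescale again: the base peak may have been removed by the m/z range cut
    top = max(i for _, i in kept)
    out = [Peak(mz, 100.0 * i / top) for mz, i in sorted(kept)]
    return s.with_peaks(out)
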
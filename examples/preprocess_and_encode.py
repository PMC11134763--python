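"""Preprocess two spectra and inspect their pair encoding.

Builds a toy analog pair (one peak shifted by +14.02 Da, one shared), cleans
both spectra, and prints the mass-difference matrix plus where its entries
land in the aligned token grid.
"""

import numpy as np

from transexion import (
    Peak,
    Spectrum,
    aligned_matrix,
    mass_difference_matrix,
    neutral_loss_spectrum,
    preprocess,
)

query = Spectrum(
    peaks=(Peak(157.134, 820.0), Peak(213.159, 1000.0), Peak(213.8, 3.0)),
    precursor_mz=400.00,
    spectrum_id="query",
)
reference = Spectrum(
    peaks=(Peak(171.15, 64.0), Peak(213.16, 80.0)),
    precursor_mz=414.02,
    spectrum_id="reference",
)

q = preprocess(query)  # rounds to 2 dp, rescales to %, removes the satellite
r = preprocess(reference)
print("query peaks after preprocessing:", [(p.mz, round(p.intensity, 1)) for p in q.peaks])
print("reference peaks:", [(p.mz, round(p.intensity, 1)) for p in r.peaks])

mdm = mass_difference_matrix(q, r)
print("\nmass-difference matrix (Da):\n", mdm.values)
# the 14.02 Da entries are the methylene (CH2) shift between the analogs;
# the 0.00 entry is the shared product ion

am = aligned_matrix(mdm)
for i in range(1, am.tokens.shape[0]):
    cols = np.nonzero(am.tokens[i] != 100)[0]
    print(
        f"query ion {q.peaks[i - 1].mz}: tokens",
        {int(c): int(am.tokens[i, c]) for c in cols},
    )
# a difference d is stored as token round(100*(d - floor(d))) in column
# floor(d): 14.02 -> token 2 in column 14, 0.00 -> token 0 in column 0

nl = neutral_loss_spectrum(q)
print("\nquery neutral losses (precursor - fragment):", [p.mz for p in nl.peaks])
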
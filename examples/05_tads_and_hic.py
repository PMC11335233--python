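"""Genomic context: TAD containment and Hi-C matrix comparison.

Shows the 200 kb tolerance rule for assigning interactions to TADs, and the
pseudocounted log2 ratio of two binned contact matrices.
"""

import numpy as np
import pandas as pd

from loop4c import ContactMatrix, TadSet, log2_ratio, tad_overlap

tads = TadSet(
    intervals=pd.DataFrame(
        {
            "chrom": ["chr7", "chr7"],
            "start": [1_000_000, 1_400_000],
            "end": [3_000_000, 2_200_000],
            "name": ["TAD1", "subTAD1a"],
        }
    )
)

just_outside = ("chr7", 3_100_000, 3_150_000)  # 100-150 kb past the TAD edge
print("interaction 100 kb beyond the TAD edge:")
print("  tolerance 200 kb ->", tad_overlap(just_outside, tads, 200_000))
print("  tolerance 0      ->", tad_overlap(just_outside, tads, 0))
nested = ("chr7", 1_500_000, 2_000_000)
print("interaction inside nested TADs ->", tad_overlap(nested, tads, 0))

bins = pd.DataFrame(
    {"chrom": "chr7", "start": np.arange(4) * 250_000, "end": np.arange(1, 5) * 250_000}
)
rng = np.random.default_rng(0)
wt = ContactMatrix(bins, rng.uniform(1, 20, (4, 4)))
ko = ContactMatrix(bins, wt.values * 2.0)  # KO doubles every contact
ratio = log2_ratio(wt, ko, pseudocount=0.0001)
print("log2(WT/KO) with a uniform 2x KO gain (should be ~ -1 everywhere):")
print(np.round(ratio, 3))
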
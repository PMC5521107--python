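"""Published ovine linkage-map summary used as a reference input.

Per-chromosome statistics of the 6448-SNP sex-averaged linkage map
estimated on the International Mapping Flock for the 26 sheep autosomes
(OAR1-OAR26): physical size in Mb on Ovine Genome v3.1 (last SNP
position), number of linkage SNPs, the earlier microsatellite-era genetic
size, the updated genetic size in cM, and the printed cM/Mb ratio. These
printed values are inputs to the map-summary arithmetic (ratio-vs-length
correlation, genome totals, mean ratio), not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

# chromosome, physical_mb, n_snps, genetic_cm_previous, genetic_cm, ratio
_ROWS = [
    ("OAR1", 275, 675, 341, 323, 1.17),
    ("OAR2", 249, 598, 308, 292, 1.17),
    ("OAR3", 224, 575, 321, 273, 1.22),
    ("OAR4", 119, 321, 129, 155, 1.30),
    ("OAR5", 107, 285, 153, 152, 1.43),
    ("OAR6", 116, 303, 155, 144, 1.24),
    ("OAR7", 100, 281, 134, 137, 1.37),
    ("OAR8", 90, 243, 125, 124, 1.38),
    ("OAR9", 94, 261, 126, 126, 1.34),
    ("OAR10", 86, 202, 100, 116, 1.34),
    ("OAR11", 62, 173, 119, 110, 1.78),
    ("OAR12", 77, 206, 94, 112, 1.45),
    ("OAR13", 83, 241, 132, 130, 1.56),
    ("OAR14", 62, 167, 116, 118, 1.90),
    ("OAR15", 80, 190, 109, 110, 1.37),
    ("OAR16", 71, 205, 81, 87, 1.22),
    ("OAR17", 72, 196, 121, 114, 1.59),
    ("OAR18", 69, 187, 120, 115, 1.68),
    ("OAR19", 60, 177, 75, 108, 1.81),
    ("OAR20", 51, 159, 81, 86, 1.70),
    ("OAR21", 49, 113, 74, 79, 1.60),
    ("OAR22", 50, 149, 85, 83, 1.67),
    ("OAR23", 62, 160, 76, 90, 1.45),
    ("OAR24", 42, 113, 89, 84, 2.01),
    ("OAR25", 45, 133, 69, 77, 1.72),
    ("OAR26", 44, 135, 70, 76, 1.75),
]


def sheep_linkage_summary() -> pd.DataFrame:
    """The published 26-autosome linkage-map summary as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=[
        "chromosome", "physical_mb", "n_snps", "genetic_cm_previous",
        "genetic_cm", "ratio_cm_per_mb"])
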
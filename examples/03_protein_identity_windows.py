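"""Windowed protein-identity evidence from an identity table.

Builds a small table of proteins with identities to each ancestor,
computes the 250-kb identity-majority statistic and the per-chromosome
summary.
"""

import pandas as pd

from allohe.layout import Chromosome, GenomeLayout
from allohe.proteins import (iaa_evidence, pairwise_identity,
                             summarize_chromosomes)

# identity of two diverged proteins, computed by the built-in aligner
print("identity:", pairwise_identity("MKVLATSGRE" * 5, "MKVLATSGRE" * 4 + "MKVIATSGRE"))

layout = GenomeLayout("hybrid", (Chromosome("chr1_a", 1_000_000, "a"),))
records = pd.DataFrame(
    [
        # window 0 (0-250 kb): proteins more similar to ancestor A -> expected
        ("p0", "chr1_a", 50_000, 99.0, 94.0),
        ("p1", "chr1_a", 120_000, 98.5, 93.0),
        ("p2", "chr1_a", 200_000, 99.2, 95.1),
        # window 1 (250-500 kb): proteins more similar to ancestor F -> HE signal
        ("p3", "chr1_a", 300_000, 94.0, 99.0),
        ("p4", "chr1_a", 420_000, 93.5, 99.4),
    ],
    columns=["protein_id", "chromosome", "anchor", "iaa_a", "iaa_f"],
)
ev = iaa_evidence(records, layout)
print(ev.to_frame()[["start", "end", "n_proteins", "iaa_diff", "flag_iaa"]]
      .head(4).to_string(index=False))
# iaa_diff = %F-leaning - %A-leaning; a positive value on a subgenome-a
# window flags a candidate homoeologous exchange.

print(summarize_chromosomes(records).to_string(index=False))
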
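"""Published worked-example values from the aortic-dissection discovery set.

The GSE52093 discovery analysis (7 dissected ascending aortas vs 5 donor
controls, Illumina HumanHT-12 v4) published a summary table of its top 25
genes — group means (AvExp), log2 fold-change, moderated t, p and q — and
the detection-filter yield of the array.  These printed values serve as
inputs for worked examples: recomputing logFC from the printed group
means, or the expressed-probe fraction from the printed probe counts,
checks the package's conventions (case-minus-control orientation, q
monotone in p) against an independently produced report.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_top25_table", "EXPRESSED_PROBES", "TOTAL_PROBES"]

#: Detection-filter yield on the discovery array: probes with detection
#: p < 0.05 in at least 5 of the 12 samples, out of all probes on the array.
EXPRESSED_PROBES = 22043
TOTAL_PROBES = 47323


def load_top25_table() -> pd.DataFrame:
    """Top-25 differential-expression summary table (symbol-indexed)."""
    path = resources.files("expmods").joinpath("data/top25_de_table.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    return df.set_index("symbol")
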
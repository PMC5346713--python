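"""The published 26-miRNA TNBC ancestry panel bundled with the package.

The table lists, for each miRNA of the panel, its cytoband, miRBase-style
1-based locus coordinates, the copy-number call of its cytoband in the
case cohort (gain or loss), the expression direction, the log2 fold change
between the two patient groups and the raw t-test p-value.  It serves as a
reference fixture for the concordance rule and for locus bookkeeping.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .integrate import ConcordanceRecord, concordant

PANEL_RESOURCE = "tnbc_aa_nhw_panel.tsv"


def load_reference_panel() -> pd.DataFrame:
    """The bundled panel as a DataFrame (one row per miRNA)."""
    ref = resources.files("mircna.data") / PANEL_RESOURCE
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def reference_panel_records() -> list[ConcordanceRecord]:
    """The bundled panel re-scored through the concordance predicate."""
    records = []
    for row in load_reference_panel().itertuples(index=False):
        records.append(ConcordanceRecord(
            mirna_id=row.mirna, band=row.cytoband, cna_direction=row.cna,
            expression_direction="up" if row.log2fc > 0 else "down",
            log2fc=float(row.log2fc), p_value=float(row.p_value),
            concordant=concordant(row.cna, float(row.log2fc))))
    return records
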
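"""Bundled reference table of published differential-abundance results.

The packaged TSV lists the 109 molecules (51 metabolites, 26 lipids,
32 proteins) reported as significant at nominal p < 0.05, with the lowest
nominal p-value, its BH-adjusted value, and the signed robust fold change
(tFC).  Only the winning test's p-value is published, so all three
per-test p fields of each record carry that minimum.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .diffstats import DifferentialRecord


def load_reference_table() -> pd.DataFrame:
    """The bundled reference table as a DataFrame."""
    with resources.files("pairomics.data").joinpath("differential_reference.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_records() -> list[DifferentialRecord]:
    """The reference table as DifferentialRecord objects.

    Every row is flagged significant (membership in the table is the
    published significance call).
    """
    df = load_reference_table()
    return [
        DifferentialRecord(
            feature_id=r.feature_id,
            layer=r.layer,
            p_paired_t=r.min_p,
            p_wilcoxon=r.min_p,
            p_sign=r.min_p,
            min_p=r.min_p,
            bh_paired_t=r.bh_p,
            bh_wilcoxon=r.bh_p,
            bh_sign=r.bh_p,
            tfc=r.tfc,
            significant=True,
        )
        for r in df.itertuples(index=False)
    ]
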
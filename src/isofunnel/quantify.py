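"""FPKM quantification and per-sample isoform-usage fractions.

FPKM normalizes a transcript's read count by transcript length (kb) and
library depth (millions of counted fragments):

    FPKM_ij = count_ij * 1e9 / (length_i * total_j)

The library total is the sum of all transcript counts in the sample; no
separate "mapped reads" figure exists in a count-matrix-only pipeline.

The isoform fraction (FR) of transcript *i* in sample *j* is its FPKM as a
percentage of its gene's summed FPKM in that sample.  Where a gene is not
expressed at all in a sample the fraction is undefined (NaN), never zero:
imputing 0 would manufacture usage shifts out of missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

CONTROL = "control"
TREATED = "treated"


@dataclass
class CountMatrix:
    """Integer counts (features x samples) plus a sample->condition map."""

    counts: pd.DataFrame
    condition: pd.Series  # index = sample ids, values in {control, treated}

    def __post_init__(self) -> None:
        self.condition = pd.Series(self.condition)
        if self.counts.isna().any().any():
            raise DataError("count matrix contains missing cells")
        if (self.counts.values < 0).any():
            raise DataError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.condition.index)
        if missing:
            raise DataError(f"samples without a condition label: {sorted(missing)}")
        bad = set(self.condition.loc[list(self.counts.columns)]) - {CONTROL, TREATED}
        if bad:
            raise DataError(f"unknown condition labels: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition[s] == condition]


def fpkm(counts: pd.DataFrame, lengths: dict[str, int] | pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million counted fragments."""
    lengths = pd.Series(lengths)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise DataError(f"missing transcript lengths for: {list(missing[:5])}")
    lens = lengths.loc[counts.index].astype(float)
    if (lens <= 0).any():
        raise DataError("transcript lengths must be positive")
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        zero = list(totals.index[totals <= 0])
        raise DataError(f"zero library total in sample(s): {zero}")
    return counts.astype(float).mul(1e9).div(lens, axis=0).div(totals, axis=1)


def isoform_fractions(fpkm_matrix: pd.DataFrame,
                      tx_to_gene: dict[str, str]) -> pd.DataFrame:
    """Per-sample isoform fractions in percent; NaN where the gene's total
    FPKM is zero in that sample."""
    missing = [t for t in fpkm_matrix.index if t not in tx_to_gene]
    if missing:
        raise DataError(f"transcripts absent from tx2gene map: {missing[:5]}")
    genes = pd.Series({t: tx_to_gene[t] for t in fpkm_matrix.index})
    gene_totals = fpkm_matrix.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        fr = 100.0 * fpkm_matrix / gene_totals
    return fr.where(gene_totals > 0)


def condition_means(fr: pd.DataFrame, condition: pd.Series) -> pd.DataFrame:
    """Arithmetic condition means of defined (non-NaN) fractions.

    Returns one row per transcript with the control/treated mean FR and the
    number of samples contributing to each mean; transcripts with an
    all-undefined condition keep a NaN mean (callers exclude them from
    switch testing).
    """
    condition = pd.Series(condition)
    ctrl = [s for s in fr.columns if condition[s] == CONTROL]
    trt = [s for s in fr.columns if condition[s] == TREATED]
    if not ctrl or not trt:
        raise DataError("both conditions must contribute at least one sample")
    return pd.DataFrame(
        {
            "fr_control_mean": fr[ctrl].mean(axis=1),
            "fr_treated_mean": fr[trt].mean(axis=1),
            "n_control": fr[ctrl].notna().sum(axis=1),
            "n_treated": fr[trt].notna().sum(axis=1),
        }
    )
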
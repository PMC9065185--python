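"""Isoform-switch detection: the ΔFR statistic, switch states and
transfrag class codes.

ΔFR is the change in an isoform's condition-mean usage fraction,
treated minus control, in percentage points.  An isoform whose usage rises
significantly after exposure is in the "PS-on" state, one whose usage falls
is "PS-off"; a gene is called switched ("PS-ISO") when at least one of its
isoforms reaches a state.

Each isoform is additionally labelled with a transfrag class code relative
to a reference exon chain, using the standard comparison alphabet restricted
to the four codes this pipeline tallies:

=  identical intron chain (a "complete" event)
k  query contains the reference (the reference's intron chain is a
   contiguous subchain of the query's and the query spans the reference)
j  multi-exon query sharing at least one junction with the reference
e  single-exon query overlapping a reference intron and an adjacent exon
   (a possible pre-mRNA fragment)

Codes are assigned most-specific-first: =, k, j, e, other.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ExonChain, TranscriptModel, genes_of
from .errors import ClassificationError, DataError
from .quantify import CONTROL, TREATED, condition_means

PS_ON = "PS-on"
PS_OFF = "PS-off"
NONE = "none"

DEFAULT_ALPHA = 0.05
#: |ΔFR| above which a record is highlighted in the volcano table, in
#: percentage points (the 0.8 threshold on the 0-1 fraction scale).
VOLCANO_HIGHLIGHT = 80.0


def delta_fr(fr_treated_mean: float, fr_control_mean: float) -> float:
    """ΔFR = mean treated FR − mean control FR, in percentage points."""
    return fr_treated_mean - fr_control_mean


# ---------------------------------------------------------------------------
# significance of a usage shift


def switch_test(
    fr_control,
    fr_treated,
    method: str = "welch_t",
    max_exact: int = 10_000,
    n_resamples: int = 9999,
    seed: int | None = 0,
) -> float:
    """Two-sided p-value for a difference in per-sample isoform fractions.

    ``welch_t`` is the default (a permutation test cannot reach p < 0.05 at
    the 3-vs-3 design: its two-sided granularity there is 2/20 = 0.1).
    ``permutation`` uses the absolute difference of group means as the
    statistic and enumerates all label assignments when there are at most
    ``max_exact`` of them, otherwise samples ``n_resamples`` assignments.
    """
    a = np.asarray(fr_control, dtype=float)
    b = np.asarray(fr_treated, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if method == "welch_t":
        if len(a) < 2 or len(b) < 2:
            raise DataError("welch_t requires >=2 defined samples per condition")
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 and vb == 0:
            return 1.0 if a.mean() == b.mean() else 0.0
        na, nb = len(a), len(b)
        se2 = va / na + vb / nb
        t = (b.mean() - a.mean()) / np.sqrt(se2)
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        return float(2.0 * stats.t.sf(abs(t), df))
    if method == "permutation":
        if len(a) < 1 or len(b) < 1:
            raise DataError("permutation requires >=1 defined sample per condition")
        pooled = np.concatenate([a, b])
        n, nb = len(pooled), len(b)
        observed = abs(b.mean() - a.mean())
        tol = 1e-12 * max(1.0, observed)
        if math.comb(n, nb) <= max_exact:
            count = total = 0
            for idx in combinations(range(n), nb):
                mask = np.zeros(n, dtype=bool)
                mask[list(idx)] = True
                stat = abs(pooled[mask].mean() - pooled[~mask].mean())
                count += stat >= observed - tol
                total += 1
            return count / total
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_resamples):
            perm = rng.permutation(n)
            stat = abs(pooled[perm[:nb]].mean() - pooled[perm[nb:]].mean())
            count += stat >= observed - tol
        return (count + 1) / (n_resamples + 1)
    raise ValueError(f"unknown method {method!r}")


def classify_state(delta_fr_value: float, p_value: float,
                   alpha: float = DEFAULT_ALPHA) -> str:
    """PS-on for a significant usage rise, PS-off for a significant fall."""
    if not (np.isfinite(delta_fr_value) and np.isfinite(p_value)):
        return NONE
    if p_value < alpha and delta_fr_value > 0:
        return PS_ON
    if p_value < alpha and delta_fr_value < 0:
        return PS_OFF
    return NONE


# ---------------------------------------------------------------------------
# transfrag class codes


def _is_contiguous_subchain(sub: tuple, full: tuple) -> bool:
    if not sub:
        return True
    k = len(sub)
    return any(full[i:i + k] == sub for i in range(len(full) - k + 1))


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_transfrag(query: ExonChain, reference: ExonChain) -> str:
    """Class code of ``query`` relative to ``reference`` (=, k, j, e, other)."""
    if query.strand != reference.strand:
        raise ClassificationError("cannot compare chains on opposite strands")
    q_introns, r_introns = query.introns, reference.introns
    q_span, r_span = query.span, reference.span

    if q_introns == r_introns and _overlaps(q_span, r_span):
        return "="
    if (
        _is_contiguous_subchain(r_introns, q_introns)
        and q_span[0] <= r_span[0]
        and q_span[1] >= r_span[1]
    ):
        return "k"
    if query.is_multi_exon and set(q_introns) & set(r_introns):
        return "j"
    if not query.is_multi_exon:
        exon = query.intervals[0]
        for i, intron in enumerate(r_introns):
            if _overlaps(exon, intron) and (
                _overlaps(exon, reference.intervals[i])
                or _overlaps(exon, reference.intervals[i + 1])
            ):
                return "e"
    return "other"


# ---------------------------------------------------------------------------
# the per-isoform switch table and event bookkeeping


def build_switch_table(
    fr: pd.DataFrame,
    condition: pd.Series,
    models: list[TranscriptModel],
    method: str = "welch_t",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Assemble SwitchRecords for every testable isoform.

    A record needs a defined condition mean on both sides and, for the Welch
    test, at least two defined samples per condition; others are dropped.
    The class code compares each isoform against its gene's longest isoform
    (the reference structure); the reference isoform itself is "=".
    """
    condition = pd.Series(condition)
    by_gene = genes_of(models)
    by_id = {m.transcript_id: m for m in models}
    reference = {
        g: max(txs, key=lambda m: (m.length, m.transcript_id))
        for g, txs in by_gene.items()
    }
    means = condition_means(fr, condition)
    ctrl = [s for s in fr.columns if condition[s] == CONTROL]
    trt = [s for s in fr.columns if condition[s] == TREATED]
    min_n = 2 if method == "welch_t" else 1

    rows = []
    for tid in fr.index:
        model = by_id.get(tid)
        if model is None:
            raise DataError(f"transcript {tid!r} absent from annotation")
        m = means.loc[tid]
        if (
            np.isnan(m.fr_control_mean)
            or np.isnan(m.fr_treated_mean)
            or m.n_control < min_n
            or m.n_treated < min_n
        ):
            continue
        p = switch_test(fr.loc[tid, ctrl], fr.loc[tid, trt], method=method)
        dfr = delta_fr(m.fr_treated_mean, m.fr_control_mean)
        rows.append(
            {
                "gene_id": model.gene_id,
                "transcript_id": tid,
                "fr_control_mean": m.fr_control_mean,
                "fr_treated_mean": m.fr_treated_mean,
                "delta_fr": dfr,
                "p_value": p,
                "state": classify_state(dfr, p, alpha),
                "class_code": classify_transfrag(
                    model.chain, reference[model.gene_id].chain
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "transcript_id", "fr_control_mean", "fr_treated_mean",
            "delta_fr", "p_value", "state", "class_code",
        ],
    )


def count_events(records: pd.DataFrame) -> dict:
    """Tally class codes within each ΔFR sign stratum.

    "complete" counts the "=" records; records with ΔFR exactly 0 belong to
    neither stratum.
    """
    codes = ["j", "k", "e", "complete", "other"]
    tally = {"dfr_positive": dict.fromkeys(codes, 0),
             "dfr_negative": dict.fromkeys(codes, 0)}
    for _, rec in records.iterrows():
        if rec.delta_fr > 0:
            stratum = tally["dfr_positive"]
        elif rec.delta_fr < 0:
            stratum = tally["dfr_negative"]
        else:
            continue
        key = "complete" if rec.class_code == "=" else rec.class_code
        stratum[key] += 1
    return tally


def volcano_table(records: pd.DataFrame,
                  highlight: float = VOLCANO_HIGHLIGHT) -> pd.DataFrame:
    """(ΔFR, −log10 p) pairs with a |ΔFR| highlight flag for plotting."""
    if (records["p_value"] <= 0).any():
        raise DataError("volcano requires strictly positive p-values")
    return pd.DataFrame(
        {
            "gene_id": records["gene_id"],
            "transcript_id": records["transcript_id"],
            "delta_fr": records["delta_fr"],
            "neg_log10_p": -np.log10(records["p_value"]),
            "highlight": records["delta_fr"].abs() > highlight,
        }
    )


def switch_gene_set(records: pd.DataFrame) -> set[str]:
    """Genes with at least one isoform in a PS-on or PS-off state (PS-ISO)."""
    return set(records.loc[records["state"] != NONE, "gene_id"])
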
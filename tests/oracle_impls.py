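"""Independent brute-force oracles used by the test suite.

Every function here recomputes a pipeline quantity from first principles —
scalar loops, exhaustive enumeration, base-level set arithmetic — and stays
deliberately independent of the package's vectorized/library-backed code
paths it checks against.
"""

from __future__ import annotations

import math

import numpy as np


def fpkm_loop(counts, lengths):
    """Scalar-loop FPKM: count * 1e9 / (length * library total)."""
    out = np.zeros(counts.shape, dtype=float)
    totals = [sum(counts.iloc[:, j]) for j in range(counts.shape[1])]
    for i, tid in enumerate(counts.index):
        for j in range(counts.shape[1]):
            out[i, j] = counts.iloc[i, j] * 1e9 / (lengths[tid] * totals[j])
    return out


def fractions_loop(fpkm, tx_to_gene):
    """Scalar-loop isoform fractions in percent; NaN for zero gene totals."""
    out = np.full(fpkm.shape, np.nan)
    for j in range(fpkm.shape[1]):
        gene_tot = {}
        for tid in fpkm.index:
            gene_tot.setdefault(tx_to_gene[tid], 0.0)
            gene_tot[tx_to_gene[tid]] += fpkm.iloc[list(fpkm.index).index(tid), j]
        for i, tid in enumerate(fpkm.index):
            tot = gene_tot[tx_to_gene[tid]]
            if tot > 0:
                out[i, j] = 100.0 * fpkm.iloc[i, j] / tot
    return out


def condition_means_loop(fr, condition):
    """NaN-excluding per-condition means, one transcript at a time."""
    rows = {}
    for tid in fr.index:
        means = {}
        for cond in ("control", "treated"):
            vals = [
                fr.loc[tid, s]
                for s in fr.columns
                if condition[s] == cond and not math.isnan(fr.loc[tid, s])
            ]
            means[cond] = sum(vals) / len(vals) if vals else float("nan")
        rows[tid] = means
    return rows


def size_factors_loop(counts):
    """Median-of-ratios size factors by explicit looping, geomean rescaled."""
    genes = list(counts.index)
    log_gm = {
        g: sum(math.log(c) for c in counts.loc[g]) / counts.shape[1]
        for g in genes
    }
    raw = []
    for s in counts.columns:
        ratios = sorted(math.log(counts.loc[g, s]) - log_gm[g] for g in genes)
        n = len(ratios)
        mid = (
            ratios[n // 2]
            if n % 2
            else 0.5 * (ratios[n // 2 - 1] + ratios[n // 2])
        )
        raw.append(math.exp(mid))
    gm = math.exp(sum(math.log(r) for r in raw) / len(raw))
    return [r / gm for r in raw]


def bh_step_up(pvals):
    """Textbook BH: sort, multiply by m/rank, enforce monotone from the top."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def welch_t_p(a, b):
    """Closed-form two-sided Welch t p-value (b vs a)."""
    from scipy import stats

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (mb - ma) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def km_brute(times, events):
    """Product-limit estimator by explicit risk-set recomputation.

    Returns (event_times, survival) and the median (smallest t with
    S(t) <= 0.5, NaN if never reached).  Subjects censored at an event time
    remain at risk for that event.
    """
    pairs = sorted(zip(times, events))
    event_times = sorted({t for t, e in pairs if e == 1})
    s = 1.0
    curve = []
    for t in event_times:
        at_risk = sum(1 for ti, _ in pairs if ti >= t)
        deaths = sum(1 for ti, ei in pairs if ti == t and ei == 1)
        s *= 1.0 - deaths / at_risk
        curve.append((t, s))
    median = float("nan")
    for t, sv in curve:
        if sv <= 0.5 + 1e-12:
            median = t
            break
    return curve, median


def logrank_brute(time_a, event_a, time_b, event_b):
    """Log-rank chi-square via the O-E / hypergeometric-variance sums."""
    from scipy import stats

    recs = [(t, e, 0) for t, e in zip(time_a, event_a)] + [
        (t, e, 1) for t, e in zip(time_b, event_b)
    ]
    event_times = sorted({t for t, e, _ in recs if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n = sum(1 for ti, _, _ in recs if ti >= t)
        n_a = sum(1 for ti, _, g in recs if ti >= t and g == 0)
        d = sum(1 for ti, ei, _ in recs if ti == t and ei == 1)
        d_a = sum(1 for ti, ei, g in recs if ti == t and ei == 1 and g == 0)
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return chi2, float(stats.chi2.sf(chi2, 1))


def complete_linkage_heights(points):
    """O(n^3) agglomerative complete linkage; returns sorted merge heights."""
    clusters = [[i] for i in range(len(points))]

    def dist(c1, c2):
        return max(
            math.dist(points[i], points[j]) for i in c1 for j in c2
        )

    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return sorted(heights)


def hypergeom_tail(k, m, big_k, n):
    """P(X >= k) for X ~ Hypergeom(universe m, successes big_k, draws n)."""
    total = 0.0
    for x in range(k, min(big_k, n) + 1):
        total += (
            math.comb(big_k, x) * math.comb(m - big_k, n - x) / math.comb(m, n)
        )
    return min(1.0, total)


def classify_transfrag_brute(query_exons, ref_exons):
    """Class code by direct base-level predicate evaluation.

    Written against the code definitions only (base sets and junction
    tuples), independent of the package's interval arithmetic.
    """

    def introns(exons):
        return [
            (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
        ]

    def bases(iv):
        return set(range(iv[0], iv[1]))

    q_introns, r_introns = introns(query_exons), introns(ref_exons)
    q_span = bases((query_exons[0][0], query_exons[-1][1]))
    r_span = bases((ref_exons[0][0], ref_exons[-1][1]))

    if q_introns == r_introns and q_span & r_span:
        return "="

    contiguous = False
    if not r_introns:
        contiguous = True
    else:
        joined = ";".join(map(str, q_introns))
        want = ";".join(map(str, r_introns))
        contiguous = want in joined and (
            # guard against substring matches across tuple boundaries
            any(
                q_introns[i : i + len(r_introns)] == r_introns
                for i in range(len(q_introns) - len(r_introns) + 1)
            )
        )
    if (
        contiguous
        and query_exons[0][0] <= ref_exons[0][0]
        and query_exons[-1][1] >= ref_exons[-1][1]
    ):
        return "k"

    if len(query_exons) > 1 and set(q_introns) & set(r_introns):
        return "j"

    if len(query_exons) == 1:
        exon = bases(query_exons[0])
        for i, intr in enumerate(r_introns):
            if exon & bases(intr) and (
                exon & bases(ref_exons[i]) or exon & bases(ref_exons[i + 1])
            ):
                return "e"
    return "other"
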
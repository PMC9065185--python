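"""The candidate-gene funnel.

Stages, in order:

1. exposure DEGs (up/down at |FC| > 2, p < 0.05) are intersected with a
   disease-cohort DEG list (an input file, optionally direction-annotated);
2. the result is intersected with the switch-gene set (PS-ISO);
3. survivors are filtered on overall-survival association in a patient
   cohort — upregulated genes must be high-worse, downregulated high-better,
   at p < alpha, and must pass the FPKM eligibility rule;
4. a user-supplied membrane-annotation flag selects the final candidates.

Each stage's output is a subset of its input, so stage counts are monotone
non-increasing.  A generic hypergeometric over-representation test against
user-supplied gene-set collections is provided for annotating the DEG list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import DataError
from .survival import HIGH_BETTER, HIGH_WORSE, CutoffResult, os_association

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"


@dataclass
class FunnelResult:
    deg_up: set[str]
    deg_down: set[str]
    deg_cohort: set[str]
    ps_iso: set[str]
    deg_cohort_overlap: set[str]
    co_occurrence: set[str]
    direction: dict[str, str]
    survival_pass: set[str] = field(default_factory=set)
    survival_results: dict[str, CutoffResult] = field(default_factory=dict)
    candidates: list[str] = field(default_factory=list)

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "deg_exposure": len(self.deg_up | self.deg_down),
            "deg_cohort_overlap": len(self.deg_cohort_overlap),
            "co_occurrence": len(self.co_occurrence),
            "survival_pass": len(self.survival_pass),
            "candidates": len(self.candidates),
        }


def intersect_funnel(
    deg_up: set[str],
    deg_down: set[str],
    deg_cohort: set[str],
    ps_iso: set[str],
    cohort_direction: dict[str, str] | None = None,
) -> FunnelResult:
    """Stage the intersections: (exposure DEG ∩ cohort DEG) ∩ PS-ISO.

    Direction is carried from the exposure DEG sets.  When the cohort list
    carries direction, concordance is required; otherwise membership alone
    suffices.
    """
    deg_up, deg_down = set(deg_up), set(deg_down)
    if deg_up & deg_down:
        raise DataError("a gene cannot be both up- and downregulated")
    deg_exposure = deg_up | deg_down
    deg_cohort, ps_iso = set(deg_cohort), set(ps_iso)

    overlap = deg_exposure & deg_cohort
    if cohort_direction:
        overlap = {
            g for g in overlap
            if cohort_direction.get(g) is None
            or cohort_direction[g] == (UP if g in deg_up else DOWN)
        }
    co = overlap & ps_iso
    if not overlap and deg_exposure and deg_cohort:
        warnings.warn(
            "exposure and cohort DEG lists share no genes; check that both "
            "use the same identifier namespace",
            stacklevel=2,
        )
    return FunnelResult(
        deg_up=deg_up,
        deg_down=deg_down,
        deg_cohort=deg_cohort,
        ps_iso=ps_iso,
        deg_cohort_overlap=overlap,
        co_occurrence=co,
        direction={g: (UP if g in deg_up else DOWN) for g in co},
    )


def survival_filter(
    direction: dict[str, str],
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    horizon_years: float = 5.0,
    **os_kwargs,
) -> tuple[set[str], dict[str, CutoffResult]]:
    """Keep genes whose OS association is significant and concordant.

    Upregulated genes must be high-worse, downregulated high-better, at the
    best-cutoff log-rank p < alpha; genes failing the FPKM eligibility rule
    are dropped with a log entry.
    """
    kept: set[str] = set()
    results: dict[str, CutoffResult] = {}
    for gene, sign in sorted(direction.items()):
        res = os_association(cohort, gene, horizon_years=horizon_years,
                             **os_kwargs)
        results[gene] = res
        if not res.eligible:
            logger.info("gene %s ineligible under the FPKM rule; dropped", gene)
            continue
        wanted = HIGH_WORSE if sign == UP else HIGH_BETTER
        if res.direction == wanted and res.logrank_p < alpha:
            kept.add(gene)
    return kept, results


def annotation_filter(genes, membrane_flags: dict[str, bool]) -> list[str]:
    """Keep membrane-annotated genes; missing flags count as False."""
    out = []
    for g in sorted(genes):
        if g not in membrane_flags:
            logger.info("gene %s has no membrane annotation; treated as "
                        "non-membrane", g)
        if membrane_flags.get(g, False):
            out.append(g)
    return out


def run_funnel(
    deg_up: set[str],
    deg_down: set[str],
    deg_cohort: set[str],
    ps_iso: set[str],
    survival_cohort: pd.DataFrame,
    membrane_flags: dict[str, bool],
    alpha: float = 0.05,
    cohort_direction: dict[str, str] | None = None,
    **os_kwargs,
) -> FunnelResult:
    """Execute the full funnel and return stage sets plus final candidates."""
    res = intersect_funnel(deg_up, deg_down, deg_cohort, ps_iso,
                           cohort_direction=cohort_direction)
    res.survival_pass, res.survival_results = survival_filter(
        res.direction, survival_cohort, alpha=alpha, **os_kwargs
    )
    res.candidates = annotation_filter(res.survival_pass, membrane_flags)
    return res


# ---------------------------------------------------------------------------
# over-representation


def ora_hypergeometric(
    query: set[str],
    collections: dict[str, set[str]],
    universe: set[str] | int,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    ``universe`` is the background gene universe (a set, or its size when
    every set is known to be drawn from it).  P-values are BH-adjusted
    across the collections and rows are sorted by p.
    """
    if isinstance(universe, int):
        m = universe
        in_universe = None
    else:
        universe = set(universe)
        m = len(universe)
        if not query <= universe:
            raise DataError("query genes must lie inside the universe")
        in_universe = universe
    n_query = len(query)
    if n_query > m:
        raise DataError("query larger than the universe")

    rows = []
    for name, genes in collections.items():
        genes = set(genes)
        if in_universe is not None:
            if not genes <= in_universe:
                raise DataError(f"gene set {name!r} is not inside the universe")
        elif len(genes) > m:
            raise DataError(f"gene set {name!r} larger than the universe")
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, m, len(genes), n_query))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(genes),
                "universe_size": m,
                "query_size": n_query,
                "p_value": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                      "universe_size", "query_size", "p_value"])
    out["p_adj"] = bh_adjust(out["p_value"].values) if len(out) else []
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# small file readers for the user-supplied tables


def read_gene_set_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (set_name, gene) -> named gene sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene"])
    return {name: set(grp["gene"]) for name, grp in df.groupby("set_name")}


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT-like file: set name, description, then member genes, tab-separated."""
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"malformed GMT line: {line[:60]!r}")
        out[parts[0]] = set(parts[2:])
    return out


def read_membrane_flags(path: str | Path) -> dict[str, bool]:
    """Two-column TSV (gene, flag) with flag in {0,1,true,false,yes,no}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "flag"])
    truthy = {"1", "true", "yes", "y"}
    return {
        str(r.gene): str(r.flag).strip().lower() in truthy
        for r in df.itertuples()
    }
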
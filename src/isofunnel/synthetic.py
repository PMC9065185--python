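"""Synthetic data with planted ground truth.

Every downstream stage of the pipeline is exercised on data generated here:
a transcript annotation (genes with 1-5 isoforms), two-condition
negative-binomial transcript counts with planted differential expression and
planted isoform switches, an expression-linked survival cohort, and small
bench-assay tables.  Each generator returns its output paired with a
:class:`SimTruth` record naming exactly what was planted.

Count model.  Gene *g* has a latent abundance ``a_g`` (lognormal) and a
usage vector over its isoforms (Dirichlet, sorted so the first isoform is
dominant).  Expected transcript counts are usage- and length-weighted so
that (i) the gene's expected total count is invariant to usage
redistribution and (ii) the FPKM-derived isoform fraction recovers the
planted usage exactly:

    mu_ij = a_g * 2^(lfc_g * treated) * u_i * len_i / sum_k(u_k len_k) * d_j

Sampling is gamma-Poisson with a per-gene, per-sample gamma factor shared by
the gene's isoforms, so gene-level counts are negative binomial with
variance ``mu + alpha mu^2`` (``alpha`` = ``nb_dispersion``) — matching the
Wald-test stage's model — while isoform fractions retain only the
count-level (Poisson) noise, as usage ratios cancel the shared factor.

Switch planting moves ``switch_magnitude`` percentage points of usage from
the dominant to the second isoform in the treated condition, reproducing a
dominant-isoform flip while conserving the gene total.

The survival cohort is exponential proportional hazards with a binary
threshold covariate: the hazard is multiplied by ``hazard_ratio`` for
subjects whose expression exceeds the latent cutoff (placed at the median
of the lognormal expression distribution), with administrative censoring
at five years.

A single global seed fans out to per-stage substreams, so each generator is
reproducible on its own.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import ExonChain, TranscriptModel, genes_of, write_gtf
from .errors import ConfigurationError, GenerationError
from .quantify import CONTROL, TREATED, CountMatrix

_STAGES = ("annotation", "counts", "survival", "assays", "funnel")


@dataclass
class SimConfig:
    # design
    n_genes: int = 500
    isoform_count_weights: tuple = (0.35, 0.30, 0.20, 0.10, 0.05)
    exon_length_range: tuple = (100, 1500)
    n_control: int = 3   # three replicates per group, as in the exposure study
    n_treated: int = 3
    # planted effects
    de_fraction: float = 0.06
    de_log2fc: float = 3.0
    switch_fraction: float = 0.06
    switch_magnitude: float = 60.0  # percentage points of usage moved
    allow_de_switch_overlap: bool = False
    # count model
    nb_dispersion: float = 0.05
    library_size_mean: float = 1_000_000.0
    library_size_cv: float = 0.1
    abundance_sigma: float = 1.0
    # survival cohort
    n_subjects: int = 200
    hazard_ratio: float = 4.0
    latent_cutoff: float = 8.0  # FPKM; median of the expression distribution
    expression_sigma: float = 0.6
    baseline_median_days: float = 900.0
    censoring_years: float = 5.0
    # assay tables
    qpcr_delta_delta_ct: float = -1.29
    qpcr_noise_sd_ct: float = 0.15
    n_qpcr_replicates: int = 3
    cytotox_pct_without_ps: float = 30.0
    cytotox_delta: float = 20.0
    cytotox_noise_sd: float = 2.0
    n_wells: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.isoform_count_weights, dtype=float)
        if w.size != 5 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ConfigurationError(
                "isoform_count_weights must be 5 non-negative probabilities "
                "summing to 1"
            )
        for name in ("de_fraction", "switch_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.switch_magnitude <= 100.0:
            raise ConfigurationError("switch_magnitude must lie in (0, 100]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.library_size_mean <= 0:
            raise ConfigurationError("library_size_mean must be positive")
        lo, hi = self.exon_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid exon_length_range")
        if self.n_genes < 1 or self.n_control < 1 or self.n_treated < 1:
            raise ConfigurationError("n_genes and replicate counts must be >= 1")
        if self.hazard_ratio <= 0:
            raise ConfigurationError("hazard_ratio must be positive")
        if self.censoring_years < 0:
            raise ConfigurationError("censoring_years must be >= 0")

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage substream of the single global seed."""
        idx = _STAGES.index(stage)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STAGES))[idx]
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("isoform_count_weights", "exon_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc


@dataclass
class SwitchTruth:
    isoform_up: str
    isoform_down: str
    planted_delta_fr: float  # percentage points, for the falling isoform

    def __post_init__(self) -> None:
        if abs(self.planted_delta_fr) > 100.0:
            raise ConfigurationError("planted ΔFR must lie within ±100 points")


@dataclass
class SimTruth:
    de_genes: dict = field(default_factory=dict)          # gene -> signed log2FC
    switch_genes: dict = field(default_factory=dict)      # gene -> SwitchTruth
    survival_gene: str | None = None
    hazard_ratio: float | None = None
    latent_cutoff: float | None = None
    assay_delta_delta_ct: float | None = None
    assay_delta_cytotoxicity: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimConfig) -> list[TranscriptModel]:
    """Generate gene models with 1-5 isoforms sharing strand and locus.

    The first isoform of each gene carries the full exon chain; further
    isoforms drop internal exons (keeping the terminal ones, so all isoforms
    of a gene overlap) or shorten the final exon to stay distinct.
    """
    rng = config.rng("annotation")
    lo, hi = config.exon_length_range
    weights = np.asarray(config.isoform_count_weights, dtype=float)
    models: list[TranscriptModel] = []
    cursor = 1000
    for g in range(1, config.n_genes + 1):
        gene_id = f"G{g:05d}"
        n_iso = int(rng.choice(5, p=weights)) + 1
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(3, 8))
        starts, exons = cursor, []
        pos = cursor
        for _ in range(n_exons):
            length = int(rng.integers(lo, hi + 1))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(200, 2001))
        full = tuple(exons)
        chains = [full]
        for _ in range(n_iso - 1):
            chain = None
            for _attempt in range(20):
                keep = [True] + [rng.random() > 0.35 for _ in full[1:-1]] + [True]
                cand = tuple(e for e, k in zip(full, keep) if k)
                if cand not in chains:
                    chain = cand
                    break
            if chain is None:  # fall back: shorten the last exon uniquely
                trim = full
                while trim in chains:
                    s, e = trim[-1]
                    trim = trim[:-1] + ((s, max(s + 1, e - int(rng.integers(1, lo)))),)
                chain = trim
            chains.append(chain)
        for i, chain in enumerate(chains, start=1):
            models.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.t{i}",
                    gene_id=gene_id,
                    chain=ExonChain(intervals=chain, strand=strand),
                )
            )
        cursor = pos + 10_000
    return models


# ---------------------------------------------------------------------------
# counts


def _usage_vectors(rng, genes, switch_set, magnitude):
    """Control and treated usage per gene; switches move `magnitude` of the
    dominant isoform's usage to the second isoform in the treated condition."""
    usage_c, usage_t = {}, {}
    for gene_id, txs in genes.items():
        k = len(txs)
        if k == 1:
            u = np.array([1.0])
        else:
            u = np.sort(rng.dirichlet(np.full(k, 1.5)))[::-1]
        if gene_id in switch_set:
            if k == 1:
                raise GenerationError(
                    f"cannot plant a switch in single-isoform gene {gene_id}"
                )
            if u[0] < magnitude + 0.05:
                new0 = magnitude + (1.0 - magnitude) * rng.uniform(0.1, 0.5)
                rest = u[1:] * (1.0 - new0) / u[1:].sum()
                u = np.concatenate([[new0], rest])
            ut = u.copy()
            ut[0] -= magnitude
            ut[1] += magnitude
        else:
            ut = u
        usage_c[gene_id], usage_t[gene_id] = u, ut
    return usage_c, usage_t


def _mean_matrix(genes, usage, abundance, lfc, depths, treated: bool):
    """Expected transcript counts for one condition's samples.

    The gene's expected total is ``a_g * 2^lfc * depth`` independent of
    usage, and the per-isoform share is usage- and length-weighted so FPKM
    fractions equal usage.
    """
    rows, index = [], []
    for gene_id, txs in genes.items():
        u = usage[gene_id]
        lens = np.array([t.length for t in txs], dtype=float)
        w = u * lens
        share = w / w.sum() if w.sum() > 0 else np.full(len(w), 1.0 / len(w))
        scale = 2.0 ** lfc.get(gene_id, 0.0) if treated else 1.0
        for t, s in zip(txs, share):
            rows.append(abundance[gene_id] * scale * s * depths)
            index.append(t.transcript_id)
    return pd.DataFrame(np.vstack(rows), index=index,
                        columns=[f"s{j}" for j in range(len(depths))])


def simulate_counts(
    annotation: list[TranscriptModel],
    config: SimConfig,
    de_genes: dict[str, float] | list[str] | None = None,
    switch_genes: list[str] | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """Two-condition transcript-level NB counts with planted DE and switches.

    ``de_genes`` may be an explicit gene->signed-log2FC map (or list, signs
    drawn at random); ``switch_genes`` an explicit gene list.  By default
    both sets are sampled at the configured fractions, disjointly unless
    ``allow_de_switch_overlap`` is set.
    """
    if not annotation:
        raise GenerationError("annotation must be non-empty")
    rng = config.rng("counts")
    genes = genes_of(annotation)
    gene_ids = list(genes)
    multi = [g for g in gene_ids if len(genes[g]) > 1]

    if switch_genes is None:
        n_sw = round(config.switch_fraction * len(gene_ids))
        if n_sw > len(multi):
            raise GenerationError(
                f"cannot plant {n_sw} switches: only {len(multi)} genes have "
                ">=2 isoforms"
            )
        switch_genes = [str(g) for g in rng.choice(multi, size=n_sw,
                                                   replace=False)]
    else:
        bad = [g for g in switch_genes if len(genes.get(g, [])) < 2]
        if bad:
            raise GenerationError(
                f"cannot plant a switch in single-isoform gene(s) {bad}"
            )
    switch_set = set(switch_genes)

    if de_genes is None:
        pool = gene_ids if config.allow_de_switch_overlap else [
            g for g in gene_ids if g not in switch_set
        ]
        n_de = round(config.de_fraction * len(gene_ids))
        if n_de > len(pool):
            raise GenerationError("not enough genes available for DE planting")
        chosen = rng.choice(pool, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc = {str(g): float(s * config.de_log2fc)
               for g, s in zip(chosen, signs)}
    elif isinstance(de_genes, dict):
        lfc = {g: float(v) for g, v in de_genes.items()}
    else:
        signs = rng.choice([-1.0, 1.0], size=len(de_genes))
        lfc = {g: float(s * config.de_log2fc) for g, s in zip(de_genes, signs)}
    if not config.allow_de_switch_overlap and set(lfc) & switch_set:
        raise ConfigurationError(
            "DE and switch gene sets overlap; set allow_de_switch_overlap"
        )

    magnitude = config.switch_magnitude / 100.0
    usage_c, usage_t = _usage_vectors(rng, genes, switch_set, magnitude)
    abundance = {g: float(rng.lognormal(np.log(5.0), config.abundance_sigma))
                 for g in gene_ids}

    n_c, n_t = config.n_control, config.n_treated
    total_abundance = sum(abundance.values())
    lib = config.library_size_mean * rng.lognormal(
        -0.5 * config.library_size_cv**2, config.library_size_cv, n_c + n_t
    )
    depths = lib / total_abundance

    mu_c = _mean_matrix(genes, usage_c, abundance, lfc, depths[:n_c], False)
    mu_t = _mean_matrix(genes, usage_t, abundance, lfc, depths[n_c:], True)
    mu = np.hstack([mu_c.values, mu_t.values])

    gene_index = np.repeat(np.arange(len(gene_ids)),
                           [len(genes[g]) for g in gene_ids])
    alpha = config.nb_dispersion
    if alpha > 0:
        gene_factor = rng.gamma(1.0 / alpha, alpha,
                                size=(len(gene_ids), n_c + n_t))
        mu = mu * gene_factor[gene_index, :]
    counts = rng.poisson(mu)

    samples = [f"ctrl_{i + 1}" for i in range(n_c)] + [
        f"ps_{i + 1}" for i in range(n_t)
    ]
    counts_df = pd.DataFrame(counts, index=mu_c.index, columns=samples)
    condition = pd.Series(
        {s: (CONTROL if s.startswith("ctrl") else TREATED) for s in samples}
    )
    truth = SimTruth(
        de_genes=lfc,
        switch_genes={
            g: SwitchTruth(
                isoform_up=genes[g][1].transcript_id,
                isoform_down=genes[g][0].transcript_id,
                planted_delta_fr=-config.switch_magnitude,
            )
            for g in sorted(switch_set)
        },
    )
    return CountMatrix(counts=counts_df, condition=condition), truth


# ---------------------------------------------------------------------------
# survival cohort


def simulate_survival_cohort(
    config: SimConfig,
    gene_id: str = "GENE_SURV",
    null_genes: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, SimTruth]:
    """Exponential proportional-hazards cohort with a threshold covariate.

    The hazard is multiplied by ``hazard_ratio`` when the gene's FPKM
    exceeds ``latent_cutoff``; extra ``null_genes`` receive expression
    columns unlinked to survival.  Follow-up is administratively censored
    at ``censoring_years``.
    """
    rng = config.rng("survival")
    n = config.n_subjects
    expr = rng.lognormal(np.log(config.latent_cutoff), config.expression_sigma, n)
    base_rate = np.log(2.0) / config.baseline_median_days
    rate = base_rate * np.where(expr > config.latent_cutoff,
                                config.hazard_ratio, 1.0)
    t = rng.exponential(1.0 / rate)
    horizon = config.censoring_years * 365.0
    event = (t <= horizon).astype(int)
    time = np.minimum(t, horizon)
    cohort = pd.DataFrame(
        {
            "subject_id": [f"P{i + 1:04d}" for i in range(n)],
            "time_days": time,
            "event": event,
            f"fpkm_{gene_id}": expr,
        }
    )
    for g in null_genes:
        cohort[f"fpkm_{g}"] = rng.lognormal(
            np.log(config.latent_cutoff), config.expression_sigma, n
        )
    truth = SimTruth(
        survival_gene=gene_id,
        hazard_ratio=config.hazard_ratio,
        latent_cutoff=config.latent_cutoff,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# assay tables


def simulate_assay_tables(config: SimConfig) -> tuple[dict, SimTruth]:
    """qPCR Ct table and cytotoxicity plate table with known truths.

    With the noise parameters at 0 the planted ΔΔCt and Δcytotoxicity are
    recovered exactly by the assay-metrics stage.
    """
    rng = config.rng("assays")
    n = config.n_qpcr_replicates
    ref_base, dct_base = 18.0, 6.0
    rows = []
    for group, shift in ((CONTROL, 0.0), (TREATED, config.qpcr_delta_delta_ct)):
        for i in range(n):
            noise = rng.normal(0.0, config.qpcr_noise_sd_ct, 2)
            rows.append(
                {
                    "sample": f"{group}_{i + 1}",
                    "group": group,
                    "target_ct": ref_base + dct_base + shift + noise[0],
                    "reference_ct": ref_base + noise[1],
                }
            )
    qpcr = pd.DataFrame(rows)

    rows = []
    for drug in ("drug_A", "drug_B"):
        for cond, pct in (
            ("without_ps", config.cytotox_pct_without_ps),
            ("with_ps", config.cytotox_pct_without_ps + config.cytotox_delta),
        ):
            for w in range(config.n_wells):
                rows.append(
                    {
                        "drug": drug,
                        "condition": cond,
                        "well": w + 1,
                        "pct_cytotoxicity": pct
                        + rng.normal(0.0, config.cytotox_noise_sd),
                    }
                )
    cytotox = pd.DataFrame(rows)
    truth = SimTruth(
        assay_delta_delta_ct=config.qpcr_delta_delta_ct,
        assay_delta_cytotoxicity=config.cytotox_delta,
    )
    return {"qpcr": qpcr, "cytotoxicity": cytotox}, truth


# ---------------------------------------------------------------------------
# end-to-end funnel dataset


@dataclass
class FunnelDataset:
    annotation: list[TranscriptModel]
    counts: CountMatrix
    truth: SimTruth
    planted_gene: str
    deg_cohort: set[str]
    cohort_direction: dict[str, str]
    survival_cohort: pd.DataFrame
    membrane_flags: dict[str, bool]


def simulate_funnel_dataset(config: SimConfig) -> FunnelDataset:
    """A dataset in which exactly one gene is simultaneously upregulated,
    isoform-switched, hazard-linked (high-worse) and membrane-flagged.

    Decoys exercise every stage: genes that are DE-and-in-cohort but not
    switched, switched-and-in-cohort but not DE, DE-and-switched but absent
    from the cohort list, a co-occurring gene with null survival, and a
    membrane-flagged gene that never reaches the funnel's final stage.
    """
    annotation = simulate_annotation(config)
    genes = genes_of(annotation)
    gene_ids = list(genes)
    multi = [g for g in gene_ids if len(genes[g]) > 1]
    rng = config.rng("funnel")

    n_sw = max(2, round(config.switch_fraction * len(gene_ids)))
    n_de = max(2, round(config.de_fraction * len(gene_ids)))
    if n_sw + 1 > len(multi):
        raise GenerationError("too few multi-isoform genes for the funnel design")
    sw = [str(g) for g in rng.choice(multi, size=n_sw, replace=False)]
    planted, decoy_survival = sw[0], sw[1]

    de_pool = [g for g in gene_ids if g not in set(sw)]
    de_extra = [str(g) for g in rng.choice(de_pool, size=n_de - 2,
                                           replace=False)]
    lfc = {planted: config.de_log2fc, decoy_survival: config.de_log2fc}
    signs = rng.choice([-1.0, 1.0], size=len(de_extra))
    lfc.update({g: float(s * config.de_log2fc) for g, s in zip(de_extra, signs)})

    cfg = dataclasses.replace(config, allow_de_switch_overlap=True)
    counts, truth = simulate_counts(annotation, cfg, de_genes=lfc,
                                    switch_genes=sw)

    # cohort list: the planted gene, the survival decoy, half of the other DE
    # genes, and a couple of switched-only genes
    deg_cohort = {planted, decoy_survival}
    deg_cohort.update(de_extra[: max(1, len(de_extra) // 2)])
    deg_cohort.update(sw[2 : 2 + max(1, (n_sw - 2) // 2)])
    cohort_direction = {g: ("up" if lfc.get(g, 1.0) > 0 else "down")
                        for g in deg_cohort}

    # every cohort-listed gene may reach the survival stage (e.g. via a
    # false-positive DEG or switch call), so all of them get expression
    null_pool = sorted(deg_cohort - {planted})
    cohort_df, surv_truth = simulate_survival_cohort(
        config, gene_id=planted, null_genes=tuple(null_pool)
    )
    truth.survival_gene = surv_truth.survival_gene
    truth.hazard_ratio = surv_truth.hazard_ratio
    truth.latent_cutoff = surv_truth.latent_cutoff

    membrane_off_funnel = next(g for g in gene_ids if g not in deg_cohort)
    membrane_flags = {g: False for g in gene_ids}
    membrane_flags[planted] = True
    membrane_flags[membrane_off_funnel] = True

    return FunnelDataset(
        annotation=annotation,
        counts=counts,
        truth=truth,
        planted_gene=planted,
        deg_cohort=deg_cohort,
        cohort_direction=cohort_direction,
        survival_cohort=cohort_df,
        membrane_flags=membrane_flags,
    )


# ---------------------------------------------------------------------------
# serialization helpers used by the CLI


def write_outputs(outdir: str | Path, config: SimConfig) -> None:
    """Write GTF, counts TSV, condition map, survival TSV, assay tables and
    the truth JSON for one simulation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    write_gtf(annotation, outdir / "annotation.gtf")
    counts, truth = simulate_counts(annotation, config)
    counts.counts.rename_axis("transcript_id").to_csv(
        outdir / "counts.tsv", sep="\t"
    )
    counts.condition.rename_axis("sample").rename("condition").to_csv(
        outdir / "conditions.tsv", sep="\t"
    )
    cohort, surv_truth = simulate_survival_cohort(config)
    cohort.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    tables, assay_truth = simulate_assay_tables(config)
    tables["qpcr"].to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
    tables["cytotoxicity"].to_csv(outdir / "cytotoxicity.tsv", sep="\t",
                                  index=False)
    truth.survival_gene = surv_truth.survival_gene
    truth.hazard_ratio = surv_truth.hazard_ratio
    truth.latent_cutoff = surv_truth.latent_cutoff
    truth.assay_delta_delta_ct = assay_truth.assay_delta_delta_ct
    truth.assay_delta_cytotoxicity = assay_truth.assay_delta_cytotoxicity
    truth.to_json(outdir / "truth.json")
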
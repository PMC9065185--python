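import numpy as np
import pandas as pd
import pytest
from scipy import stats

import isofunnel as iso
from isofunnel.errors import ConfigurationError, GenerationError
from isofunnel.synthetic import _mean_matrix, _usage_vectors


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"isoform_count_weights": (0.5, 0.5, 0.5, 0, 0)},
            {"de_fraction": 1.5},
            {"switch_magnitude": 0.0},
            {"nb_dispersion": -1.0},
            {"library_size_mean": 0.0},
            {"exon_length_range": (500, 100)},
            {"hazard_ratio": -2.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            iso.SimConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_genes: 7\nseed: 3\nde_fraction: 0.0\n")
        cfg = iso.SimConfig.from_yaml(path)
        assert (cfg.n_genes, cfg.seed, cfg.de_fraction) == (7, 3, 0.0)


class TestSimulateAnnotation:
    def test_forced_single_isoform(self):
        cfg = iso.SimConfig(n_genes=1, isoform_count_weights=(1, 0, 0, 0, 0))
        models = iso.simulate_annotation(cfg)
        assert len(models) == 1

    def test_same_seed_gives_byte_identical_gtf(self, tmp_path):
        cfg = iso.SimConfig(n_genes=25, seed=5)
        for name in ("a.gtf", "b.gtf"):
            iso.write_gtf(iso.simulate_annotation(cfg), tmp_path / name)
        assert (tmp_path / "a.gtf").read_bytes() == (
            tmp_path / "b.gtf"
        ).read_bytes()

    def test_isoform_count_histogram_within_binomial_bounds(self):
        # 1 vs 2 isoforms at 50/50: exact central 99% binomial interval
        cfg = iso.SimConfig(
            n_genes=100, isoform_count_weights=(0.5, 0.5, 0, 0, 0), seed=2
        )
        genes = iso.genes_of(iso.simulate_annotation(cfg))
        n_single = sum(1 for txs in genes.values() if len(txs) == 1)
        lo = stats.binom.ppf(0.005, 100, 0.5)
        hi = stats.binom.ppf(0.995, 100, 0.5)
        assert lo <= n_single <= hi

    def test_isoforms_share_strand_and_overlap(self, small_dataset):
        for txs in iso.genes_of(small_dataset["models"]).values():
            strands = {t.chain.strand for t in txs}
            assert len(strands) == 1
            spans = [t.chain.span for t in txs]
            lo = max(s for s, _ in spans)
            hi = min(e for _, e in spans)
            assert lo < hi  # all isoforms overlap pairwise


class TestSimulateCounts:
    def test_no_planting_gives_empty_truth(self):
        cfg = iso.SimConfig(n_genes=20, de_fraction=0, switch_fraction=0,
                            seed=1)
        models = iso.simulate_annotation(cfg)
        _, truth = iso.simulate_counts(models, cfg)
        assert truth.de_genes == {} and truth.switch_genes == {}

    def test_counts_are_nonnegative_integers(self, small_dataset):
        counts = small_dataset["counts"].counts
        assert (counts.values >= 0).all()
        assert np.issubdtype(counts.values.dtype, np.integer)

    def test_switch_in_single_isoform_gene_rejected(self):
        cfg = iso.SimConfig(n_genes=4, isoform_count_weights=(1, 0, 0, 0, 0),
                            switch_fraction=0, seed=0)
        models = iso.simulate_annotation(cfg)
        with pytest.raises(GenerationError):
            iso.simulate_counts(models, cfg, switch_genes=["G00001"])

    def test_overlap_without_flag_rejected(self):
        cfg = iso.SimConfig(n_genes=10, seed=0,
                            isoform_count_weights=(0, 1, 0, 0, 0))
        models = iso.simulate_annotation(cfg)
        with pytest.raises(ConfigurationError):
            iso.simulate_counts(models, cfg, de_genes={"G00001": 2.0},
                                switch_genes=["G00001"])

    def test_expected_gene_totals_conserved_under_switching(self):
        # usage redistribution must not change a gene's expected count
        cfg = iso.SimConfig(n_genes=12, seed=4,
                            isoform_count_weights=(0, 0.5, 0.5, 0, 0))
        models = iso.simulate_annotation(cfg)
        genes = iso.genes_of(models)
        rng = cfg.rng("counts")
        switch_set = set(list(genes)[:6])
        usage_c, usage_t = _usage_vectors(rng, genes, switch_set, 0.6)
        abundance = {g: 10.0 for g in genes}
        depths = np.array([1000.0])
        mu_c = _mean_matrix(genes, usage_c, abundance, {}, depths, False)
        mu_t = _mean_matrix(genes, usage_t, abundance, {}, depths, True)
        t2g = pd.Series(iso.tx2gene(models))
        tot_c = mu_c.groupby(t2g.loc[mu_c.index]).sum()
        tot_t = mu_t.groupby(t2g.loc[mu_t.index]).sum()
        np.testing.assert_allclose(tot_c.values, tot_t.values, rtol=1e-12)
        np.testing.assert_allclose(tot_c.values, 10.0 * 1000.0, rtol=1e-12)

    def test_planted_delta_fr_realized_on_average(self):
        # mean realized dominant-isoform FR shift across seeds ≈ −60 points
        diffs = []
        for seed in range(60):
            cfg = iso.SimConfig(
                n_genes=20, seed=seed, switch_fraction=0.2, de_fraction=0,
                isoform_count_weights=(0, 0.5, 0.5, 0, 0),
            )
            models = iso.simulate_annotation(cfg)
            counts, truth = iso.simulate_counts(models, cfg)
            fpkm = iso.fpkm(counts.counts, iso.transcript_lengths(models))
            fr = iso.isoform_fractions(fpkm, iso.tx2gene(models))
            means = iso.condition_means(fr, counts.condition)
            for st in truth.switch_genes.values():
                m = means.loc[st.isoform_down]
                diffs.append(m.fr_treated_mean - m.fr_control_mean)
        assert np.mean(diffs) == pytest.approx(-60.0, abs=3.0)

    def test_poisson_limit_at_zero_dispersion(self):
        # fixed library sizes: the property concerns the count noise alone
        cfg = iso.SimConfig(n_genes=300, nb_dispersion=0.0, de_fraction=0,
                            switch_fraction=0, seed=8, n_control=10,
                            n_treated=10, library_size_cv=0.0,
                            isoform_count_weights=(1, 0, 0, 0, 0))
        models = iso.simulate_annotation(cfg)
        counts, _ = iso.simulate_counts(models, cfg)
        ctrl = counts.counts[counts.samples_in("control")]
        ratio = ctrl.var(axis=1, ddof=1) / ctrl.mean(axis=1)
        assert ratio.mean() == pytest.approx(1.0, abs=0.15)

    def test_truth_identifiers_exist_in_annotation(self, small_dataset):
        truth = small_dataset["truth"]
        ids = {m.transcript_id for m in small_dataset["models"]}
        gene_ids = {m.gene_id for m in small_dataset["models"]}
        assert set(truth.de_genes) <= gene_ids
        for g, st in truth.switch_genes.items():
            assert g in gene_ids
            assert {st.isoform_up, st.isoform_down} <= ids

    def test_determinism_of_counts(self, small_config):
        models = iso.simulate_annotation(small_config)
        c1, _ = iso.simulate_counts(models, small_config)
        c2, _ = iso.simulate_counts(models, small_config)
        pd.testing.assert_frame_equal(c1.counts, c2.counts)


class TestSimulateSurvival:
    def test_zero_censoring_time_censors_everything(self):
        cfg = iso.SimConfig(censoring_years=0.0, n_subjects=30, seed=1)
        cohort, _ = iso.simulate_survival_cohort(cfg)
        assert (cohort["time_days"] == 0).all()
        assert (cohort["event"] == 0).all()

    def test_high_hazard_group_dies_earlier(self):
        worse = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = iso.SimConfig(seed=seed, hazard_ratio=4.0)
            cohort, truth = iso.simulate_survival_cohort(cfg)
            hi = cohort["fpkm_GENE_SURV"] > truth.latent_cutoff
            _, med_hi = iso.km_estimate(cohort.time_days[hi], cohort.event[hi])
            _, med_lo = iso.km_estimate(cohort.time_days[~hi],
                                        cohort.event[~hi])
            if np.isnan(med_lo):  # low group never reaches S=0.5
                med_lo = np.inf
            worse += med_hi < med_lo
        assert worse / n_seeds >= 0.95

    def test_null_hazard_gives_uniform_logrank_p(self):
        ps = []
        for seed in range(150):
            cfg = iso.SimConfig(seed=seed, hazard_ratio=1.0, n_subjects=80)
            cohort, truth = iso.simulate_survival_cohort(cfg)
            hi = (cohort["fpkm_GENE_SURV"] > truth.latent_cutoff).values
            _, p = iso.logrank_test(
                cohort.time_days[~hi], cohort.event[~hi],
                cohort.time_days[hi], cohort.event[hi],
            )
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSimulateAssays:
    def test_noise_free_planting_recovered_exactly(self):
        cfg = iso.SimConfig(qpcr_noise_sd_ct=0.0, cytotox_noise_sd=0.0,
                            qpcr_delta_delta_ct=0.0, cytotox_delta=20.0,
                            seed=0)
        tables, truth = iso.simulate_assay_tables(cfg)
        rq = iso.qpcr_relative_quantities(tables["qpcr"])
        assert rq.loc["treated", "rq"] == pytest.approx(1.0, abs=1e-12)
        deltas = iso.cytotoxicity_deltas(tables["cytotoxicity"])
        np.testing.assert_allclose(deltas["delta_cytotoxicity"], 20.0,
                                   atol=1e-12)
        assert (deltas["call"] == "resistance").all()

    def test_noisy_rq_recovers_planted_fold_change_on_average(self):
        rqs = []
        for seed in range(200):
            cfg = iso.SimConfig(qpcr_noise_sd_ct=1.0,
                                qpcr_delta_delta_ct=-1.0, seed=seed)
            tables, _ = iso.simulate_assay_tables(cfg)
            rqs.append(
                iso.qpcr_relative_quantities(tables["qpcr"]).loc["treated",
                                                                 "rq"]
            )
        # planted RQ = 2^1 = 2; Ct noise is log-normal on the RQ scale
        assert np.median(rqs) == pytest.approx(2.0, rel=0.10)
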
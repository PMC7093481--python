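"""Synthetic-data generator: determinism, degenerate params, sampling checks."""

import numpy as np
import pytest

from epishore.pipeline import run_sample
from epishore.reference import AmpliconError
from epishore.simulate import (
    CohortConfig,
    PopulationConfig,
    emit_clone_reads,
    emit_expression,
    emit_probe_table,
    generate_population,
    make_fixture_reference,
    sample_epiallele_reads,
    simulate_cohort,
)
from epishore.stats import correlate


class TestFixtureReference:
    def test_default_layout_realized(self):
        spec = make_fixture_reference(seed=0)
        assert [len(spec.cpg_index.in_region(lab)) for lab in "OSI"] == [2, 9, 13]

    def test_deterministic_under_seed(self):
        a = make_fixture_reference(seed=42)
        b = make_fixture_reference(seed=42)
        assert a.sequence == b.sequence and a.snp == b.snp
        c = make_fixture_reference(seed=43)
        assert c.sequence != a.sequence

    def test_enough_conversion_qc_sites(self):
        spec = make_fixture_reference(seed=0)
        cpgs = set(spec.cpg_index.positions)
        n_noncpg_c = sum(
            1 for i, b in enumerate(spec.sequence) if b == "C" and i not in cpgs
        )
        assert n_noncpg_c >= 10

    def test_custom_layout(self):
        spec = make_fixture_reference(layout=(3, 5, 4), seed=1)
        assert [len(spec.cpg_index.in_region(lab)) for lab in "OSI"] == [3, 5, 4]

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError):
            make_fixture_reference(layout=(0, 9, 13))


class TestGeneratePopulation:
    def test_degenerate_parameters_force_unmethylated_shore(self, spec):
        cfg = PopulationConfig(n_cells=50, p_hypo_wt=1.0, m_low=0.0)
        pop = generate_population(cfg, spec, np.random.default_rng(0))
        s_idx = [
            pop.cpg_positions.index(p) for p in spec.s_region_positions()
        ]
        assert not pop.methylation["WT"][:, s_idx].any()
        assert pop.hypo_state["WT"].all()

    def test_hypo_fraction_within_three_se(self, spec):
        n = 10_000
        cfg = PopulationConfig(n_cells=n, p_hypo_wt=0.6)
        pop = generate_population(cfg, spec, np.random.default_rng(1))
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(pop.wt_hypo_fraction - 0.6) < 3 * se

    def test_constitutive_regions_ignore_latent_state(self, spec):
        """O stays hyper-biased and I hypo-biased even when every allele is hypo."""
        cfg = PopulationConfig(n_cells=2000, p_hypo_wt=1.0, m_low=0.1, m_high=0.9)
        pop = generate_population(cfg, spec, np.random.default_rng(2))
        o_idx = [pop.cpg_positions.index(p) for p in spec.cpg_index.in_region("O")]
        i_idx = [pop.cpg_positions.index(p) for p in spec.cpg_index.in_region("I")]
        assert pop.methylation["WT"][:, o_idx].mean() == pytest.approx(0.9, abs=0.03)
        assert pop.methylation["WT"][:, i_idx].mean() == pytest.approx(0.1, abs=0.03)

    def test_same_seed_reproduces(self, spec):
        cfg = PopulationConfig(n_cells=100)
        a = generate_population(cfg, spec, np.random.default_rng(7))
        b = generate_population(cfg, spec, np.random.default_rng(7))
        assert np.array_equal(a.methylation["KO"], b.methylation["KO"])


class TestEmitCloneReads:
    def test_snp_base_frequencies_near_half(self, spec):
        cfg = PopulationConfig(n_cells=500, n_reads=1000)
        rng = np.random.default_rng(3)
        pop = generate_population(cfg, spec, rng)
        reads, truth = emit_clone_reads(pop, spec, cfg, rng, "L", "P6")
        frac_wt = (truth.allele == "WT").mean()
        se = np.sqrt(0.25 / 1000)
        assert abs(frac_wt - 0.5) < 4 * se

    def test_total_conversion_failure_fails_qc(self, spec):
        cfg = PopulationConfig(n_cells=50, n_reads=30, conversion_failure=1.0)
        rng = np.random.default_rng(4)
        pop = generate_population(cfg, spec, rng)
        reads, _ = emit_clone_reads(pop, spec, cfg, rng, "L", "P6")
        calls, report = run_sample(reads, spec)
        assert report.n_pass == 0
        assert report.rejections["incomplete_conversion"] == 30

    def test_deterministic_reads_under_seed(self, spec):
        cfg = PopulationConfig(n_cells=50, n_reads=20, error_rate=0.01)

        def emit(seed):
            rng = np.random.default_rng(seed)
            pop = generate_population(cfg, spec, rng)
            reads, _ = emit_clone_reads(pop, spec, cfg, rng, "L", "P6")
            return [r.sequence for r in reads]

        assert emit(5) == emit(5)
        assert emit(5) != emit(6)


class TestEmitExpression:
    def test_noise_free_expression_equals_hypo_fraction(self, spec):
        cfg = PopulationConfig(
            n_cells=200, expr_noise_sd=0.0, expr_slope=1.0, expr_baseline=0.0
        )
        rng = np.random.default_rng(8)
        pop = generate_population(cfg, spec, rng)
        table = emit_expression(pop, cfg, rng, "L", "P6")
        mrna = table[table.target == "mRNA"]["intensity"]
        assert np.allclose(mrna, pop.wt_hypo_fraction)
        assert (table[table.target == "reference"]["intensity"] == 1.0).all()


class TestCohort:
    def test_cohort_shape(self, spec):
        samples = simulate_cohort(
            spec, CohortConfig(n_lines=3), seed=1, with_reads=False
        )
        assert len(samples) == 6  # 3 lines x 2 passages
        assert {s.passage_label for s in samples} == {"P6", "P20"}

    def test_wider_ko_dispersion_raises_ko_variance(self, spec):
        """Lines whose KO-state probability is drawn from a wider range show
        larger cross-line RM-ratio variance on the KO allele in nearly all
        cohorts."""
        wins = 0
        cohort = CohortConfig(
            p_hypo_range=(0.35, 0.65),
            p_hypo_range_ko=(0.02, 0.98),
            population=PopulationConfig(n_cells=150),
        )
        s_pos = spec.s_region_positions()
        for seed in range(100):
            samples = simulate_cohort(spec, cohort, seed=seed, with_reads=False)
            wt = [
                s.population.true_rm_ratio("WT", s_pos)
                for s in samples
                if s.passage_label == "P6"
            ]
            ko = [
                s.population.true_rm_ratio("KO", s_pos)
                for s in samples
                if s.passage_label == "P6"
            ]
            if np.var(ko, ddof=1) > np.var(wt, ddof=1):
                wins += 1
        assert wins >= 95


class TestEpialleleFastPath:
    def test_matches_binomial_mixture_moments(self, rng):
        counts, states = sample_epiallele_reads(rng, 20_000, p_hypo=0.5)
        # hypo reads: Binom(9, 0.9); hyper reads: Binom(9, 0.1)
        assert counts[states].mean() == pytest.approx(8.1, abs=0.05)
        assert counts[~states].mean() == pytest.approx(0.9, abs=0.05)


class TestProbeTable:
    def test_layout_and_negative_coupling(self, rng):
        table = emit_probe_table(rng)
        assert sorted(table.probe_id.unique()) == [
            "cg01529092", "cg14164380", "cg15385562",
        ]
        assert table.cell_line.nunique() == 12
        shore = table[table.probe_id == "cg14164380"]
        assert shore.beta.between(0.19, 0.70).all()
        res = correlate(shore.beta.to_numpy(), shore.expression.to_numpy())
        assert res.r < -0.5
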
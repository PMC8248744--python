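"""Forward-simulator behaviour: founder construction, haplodiploid
transmission, drift and selection dynamics, and the emission models."""

import numpy as np
import pandas as pd
import pytest

from conftest import fixed_population
from hapbsa._rng import substream
from hapbsa.config import CausalLocus, QpcrSettings, SimConfig
from hapbsa.layout import GenomeLayout
from hapbsa.simulate import (
    FounderGenomes,
    advance_generation,
    emit_dose_response,
    emit_pool_reads,
    emit_qpcr,
    f1_population,
    make_founders,
    simulate_experiment,
)


def _manual_founders(male_allele):
    layout = GenomeLayout.from_lengths([10_000])
    n = len(male_allele)
    return FounderGenomes(
        layout=layout,
        chrom=np.repeat("chr1", n),
        pos=np.arange(1, n + 1) * 100,
        strain_is_het=np.zeros(n, dtype=bool),
        male_allele=np.asarray(male_allele, dtype=np.uint8),
    )


class TestFounders:
    def test_all_alt_male_makes_every_site_informative(self):
        f = _manual_founders(np.ones(50))
        assert f.informative.all()
        assert (f.sites_table()["transmitted_allele"] == "alt").all()

    def test_male_identical_to_mother_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate founders"):
            _manual_founders(np.zeros(50))

    def test_half_of_strain_het_sites_are_informative(self):
        cfg = SimConfig(seed=1)
        f = make_founders(cfg)
        het = f.strain_is_het
        frac = f.informative[het].mean()
        n = int(het.sum())
        # binomial(n, 1/2) three-sigma band around the random haplotype draw
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_strain_hom_sites_always_informative(self):
        cfg = SimConfig(seed=1)
        f = make_founders(cfg)
        assert f.informative[~f.strain_is_het].all()


class TestDynamics:
    def test_neutral_martingale(self):
        """Without selection the replicate-mean transmitted-allele frequency
        stays at the F1 heterozygote value of 1/2."""
        cfg = SimConfig(
            chromosome_lengths=(400_000, 200_000),
            snp_density=0.001,
            causal_loci=(),
            cnv_locus=None,
            n_females=200,
            seed=5,
        )
        founders = make_founders(cfg)
        means = []
        for rep in range(30):
            rng = substream(cfg.seed, "martingale", rep)
            state = f1_population(founders, cfg, rng)
            for _ in range(cfg.n_generations):
                state = advance_generation(state, cfg, rng)
            means.append(state.allele_frequency().mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 0.5) < 3 * se

    def test_strong_recessive_selection_reaches_near_fixation(self):
        """s=0.9, h=0 for 35 generations drives the resistant allele above
        0.95 in the selected treatment."""
        cfg = SimConfig(
            chromosome_lengths=(600_000, 300_000),
            snp_density=0.001,
            causal_loci=(CausalLocus("chr1", 300_000, 0.9, 0.0),),
            cnv_locus=None,
            n_females=300,
            seed=2,
        )
        founders = make_founders(cfg)
        rng = substream(cfg.seed, "sel")
        state = f1_population(founders, cfg, rng, treatment="selected")
        for _ in range(35):
            state = advance_generation(state, cfg, rng)
        idx = founders.informative_index("chr1", 300_000)
        assert state.allele_frequency()[idx] > 0.95

    def test_selection_monotonicity(self):
        """Mean final causal-allele frequency is non-decreasing in s."""
        means = []
        for s in (0.0, 0.3, 0.8):
            finals = []
            for rep in range(8):
                cfg = SimConfig(
                    chromosome_lengths=(400_000, 200_000),
                    snp_density=0.001,
                    causal_loci=(CausalLocus("chr1", 200_000, s, 0.1),),
                    cnv_locus=None,
                    n_females=200,
                    n_generations=15,
                    seed=100 + rep,
                )
                founders = make_founders(cfg)
                rng = substream(cfg.seed, "mono", rep)
                state = f1_population(founders, cfg, rng, treatment="selected")
                for _ in range(cfg.n_generations):
                    state = advance_generation(state, cfg, rng)
                idx = founders.informative_index("chr1", 200_000)
                finals.append(state.allele_frequency()[idx])
            means.append(np.mean(finals))
        assert means[0] <= means[1] <= means[2]

    def test_same_seed_reproduces_experiment(self, small_config):
        a = simulate_experiment(small_config, emit_rna=False)
        b = simulate_experiment(small_config, emit_rna=False)
        for name in a.pools:
            np.testing.assert_array_equal(a.pools[name].dna_alt, b.pools[name].dna_alt)
            np.testing.assert_array_equal(
                a.pools[name].gene_rna_counts, b.pools[name].gene_rna_counts
            )
        pd.testing.assert_frame_equal(a.causal_truth, b.causal_truth)


class TestPoolEmission:
    def test_zero_frequency_gives_zero_alt_reads(self, dosage_config):
        state = fixed_population(dosage_config, resistant=False)
        sample = emit_pool_reads(state, dosage_config, substream(0, "x"), name="S")
        assert sample.dna_alt.sum() == 0

    def test_mean_alt_fraction_at_half_frequency(self):
        cfg = SimConfig(
            chromosome_lengths=(500_000, 250_000),
            snp_density=0.002,
            causal_loci=(),
            cnv_locus=None,
            n_females=100,
            dna_depth_mean=100.0,
            seed=9,
        )
        founders = make_founders(cfg)
        state = f1_population(founders, cfg, substream(9, "f1"))  # all het: freq 1/2
        sample = emit_pool_reads(state, cfg, substream(9, "reads"), name="P")
        inf = founders.informative
        depth = sample.dna_ref[inf] + sample.dna_alt[inf]
        frac = sample.dna_alt[inf].sum() / depth.sum()
        assert abs(frac - 0.5) < 0.01

    def test_fixed_cnv_triples_relative_gene_coverage(self, dosage_config):
        """A 3-copy block fixed in the population shows ~3x the DNA coverage
        of flanking single-copy genes."""
        from hapbsa.simulate import gene_annotation, make_founders

        founders = make_founders(dosage_config)
        state = fixed_population(dosage_config, resistant=True, founders=founders)
        sample = emit_pool_reads(state, dosage_config, substream(1, "cnv"), name="R")
        ann = gene_annotation(dosage_config)
        in_cnv = ann["in_cnv"].to_numpy()
        ratio = sample.gene_dna_coverage[in_cnv].mean() / sample.gene_dna_coverage[~in_cnv].mean()
        assert in_cnv.sum() == 5
        assert ratio == pytest.approx(3.0, rel=0.1)


class TestQpcrEmission:
    def _cfg(self, sd):
        return SimConfig(qpcr=QpcrSettings(efficiency=2.0, ct0=30.0, noise_sd=sd), seed=0)

    def test_tripled_copies_shift_ct_by_log_e_three(self):
        cfg = self._cfg(0.0)
        table = emit_qpcr({"a": 1.0, "b": 3.0}, cfg, substream(0, "q"))
        ct = table.groupby(["sample", "amplicon"])["ct"].mean()
        shift = ct[("a", "CPR")] - ct[("b", "CPR")]
        assert shift == pytest.approx(np.log(3.0) / np.log(2.0))
        assert ct[("a", "VGSC")] == pytest.approx(ct[("b", "VGSC")])

    def test_equal_copies_give_identical_ct(self):
        cfg = self._cfg(0.0)
        table = emit_qpcr({"a": 2.0, "b": 2.0}, cfg, substream(0, "q"))
        cts = table[table["amplicon"] == "CPR"]["ct"]
        assert cts.nunique() == 1

    def test_replicate_noise_sd_recovered(self):
        cfg = SimConfig(
            qpcr=QpcrSettings(efficiency=2.0, ct0=30.0, noise_sd=0.1, n_replicates=1000),
            seed=0,
        )
        table = emit_qpcr({"a": 1.0}, cfg, substream(4, "q"))
        sd = table[table["amplicon"] == "CPR"]["ct"].std()
        assert sd == pytest.approx(0.1, rel=0.1)

    def test_non_positive_copies_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            emit_qpcr({"a": 0.0}, self._cfg(0.0), substream(0, "q"))


class TestDoseResponseEmission:
    def test_mortality_half_at_lc50(self):
        cfg = SimConfig(seed=0)
        lc50 = 10 ** cfg.dose_response["R"].log10_lc50
        table = emit_dose_response([("R", 1.0)], cfg, [lc50], 20_000, substream(2, "d"))
        assert table["dead"].iloc[0] / table["n"].iloc[0] == pytest.approx(0.5, abs=0.02)

    def test_mixture_lies_between_pure_curves(self):
        cfg = SimConfig(seed=0)
        doses = [10.0, 100.0, 1000.0]
        pure_r = emit_dose_response([("R", 1.0)], cfg, doses, 5000, substream(3, "r"))
        pure_s = emit_dose_response([("S", 1.0)], cfg, doses, 5000, substream(3, "s"))
        mix = emit_dose_response([("R", 0.5), ("S", 0.5)], cfg, doses, 5000, substream(3, "m"))
        for d in range(len(doses)):
            lo = pure_r["dead"].iloc[d] / 5000
            hi = pure_s["dead"].iloc[d] / 5000
            m = mix["dead"].iloc[d] / 5000
            assert min(lo, hi) - 0.03 <= m <= max(lo, hi) + 0.03

    def test_invalid_inputs_rejected(self):
        cfg = SimConfig(seed=0)
        with pytest.raises(ValueError, match="dose"):
            emit_dose_response([("R", 1.0)], cfg, [0.0], 100, substream(0, "d"))
        with pytest.raises(ValueError, match="sum to 1"):
            emit_dose_response([("R", 0.4)], cfg, [10.0], 100, substream(0, "d"))


def test_lethal_selection_on_fixed_susceptible_population_is_extinction():
    """With s=1 against every genotype present, selection leaves no
    survivors and the error names the generation."""
    from hapbsa.simulate import ExtinctionError, PopulationState

    cfg = SimConfig(
        chromosome_lengths=(200_000, 100_000),
        snp_density=0.001,
        causal_loci=(CausalLocus("chr1", 100_000, 1.0, 0.0),),
        cnv_locus=None,
        n_females=50,
        seed=1,
    )
    founders = make_founders(cfg)
    s = founders.n_informative
    females = np.zeros((50, 2, s), dtype=np.uint8)  # no resistant alleles anywhere
    males = np.zeros((cfg.n_males, s), dtype=np.uint8)
    state = PopulationState(females, males, 3, "selected", founders)
    with pytest.raises(ExtinctionError, match="generation 4"):
        advance_generation(state, cfg, substream(1, "ext"))
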
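"""Selection-simulator dynamics against analytic oracles."""

import numpy as np
import pytest
from scipy import stats

from satselseq.simulate import (
    CampaignConfig,
    ExtinctionError,
    FitnessMap,
    NNS_CODONS_SORTED,
    Population,
    expected_two_variant_frequency,
    initial_population,
    run_campaign,
    select_generation,
    simulate_reads,
)


class TestInitialPopulation:
    def test_uniform_draw_close_to_expected(self):
        pop = initial_population(3200, rng=np.random.default_rng(0))
        counts = np.array([pop.counts[c] for c in NNS_CODONS_SORTED])
        # multinomial cell SD = sqrt(n p (1-p)) ~ 9.85 at n=3200, p=1/32
        sd = np.sqrt(3200 * (1 / 32) * (31 / 32))
        assert pop.total == 3200
        assert np.all(np.abs(counts - 100) < 5 * sd)

    def test_one_hot_skew(self):
        skew = np.zeros(32)
        skew[4] = 1.0
        pop = initial_population(500, skew=skew, rng=np.random.default_rng(1))
        assert pop.counts[NNS_CODONS_SORTED[4]] == 500

    def test_deterministic_under_fixed_seed(self):
        a = initial_population(1000, rng=np.random.default_rng(42))
        b = initial_population(1000, rng=np.random.default_rng(42))
        assert a.counts == b.counts

    def test_wrong_skew_length_rejected(self):
        with pytest.raises(ValueError):
            initial_population(10, skew=np.ones(3))


class TestSelectGeneration:
    def test_stop_codons_eliminated_when_unfit(self):
        pop = initial_population(3200, rng=np.random.default_rng(2))
        nxt = select_generation(pop, FitnessMap(), 3200, rng=np.random.default_rng(3))
        assert nxt.counts.get("TAG", 0) == 0
        assert nxt.generation == 1

    def test_uniform_fitness_is_neutral(self):
        """χ² against the parent frequencies is not rejected at α=0.01."""
        pop = Population({c: 100 for c in NNS_CODONS_SORTED})
        nxt = select_generation(
            pop, FitnessMap.flat(1.0), 100_000, rng=np.random.default_rng(4)
        )
        observed = np.array([nxt.counts.get(c, 0) for c in NNS_CODONS_SORTED])
        chi2 = stats.chisquare(observed, np.full(32, 100_000 / 32))
        assert chi2.pvalue > 0.01

    def test_two_variant_expectation(self):
        """Mean selected frequency over 50 seeds within 2 SE of p·w/Σp·w."""
        pop = Population({"CTG": 500, "TAC": 500})  # L vs Y, equal start
        fitness = FitnessMap.from_aa({"L": 2.0, "Y": 1.0})
        expected = expected_two_variant_frequency(0.5, 2.0, 1.0)
        assert expected == pytest.approx(2 / 3)
        B = 1000
        freqs = []
        for seed in range(50):
            nxt = select_generation(pop, fitness, B, rng=np.random.default_rng(seed))
            freqs.append(nxt.counts.get("CTG", 0) / B)
        freqs = np.array(freqs)
        se = freqs.std(ddof=1) / np.sqrt(len(freqs))
        assert abs(freqs.mean() - expected) < 2 * se

    def test_all_zero_fitness_is_extinction(self):
        pop = Population({"TAG": 100})
        with pytest.raises(ExtinctionError):
            select_generation(pop, FitnessMap(), 100, rng=np.random.default_rng(0))

    def test_neutral_martingale_over_seeds(self):
        """Mean G3 frequency across 100 seeds within 3 SE of the G0 value."""
        p0 = np.array([0.5, 0.3, 0.2])
        pop = Population({"CTG": 500, "TAC": 300, "TGC": 200})
        B = 1000
        finals = []
        for seed in range(100):
            cur = pop
            rng = np.random.default_rng(1000 + seed)
            for _ in range(3):
                cur = select_generation(cur, FitnessMap.flat(1.0), B, rng=rng)
            finals.append(
                [cur.counts.get(c, 0) / B for c in ("CTG", "TAC", "TGC")]
            )
        finals = np.array(finals)
        for k in range(3):
            se = finals[:, k].std(ddof=1) / 10.0
            assert abs(finals[:, k].mean() - p0[k]) < 3 * se


class TestSimulateReads:
    def test_exact_read_count_and_noiseless_identity(self, ref, panel, barcodes):
        pop = initial_population(200, rng=np.random.default_rng(5))
        reads, truth = simulate_reads(
            pop, panel[0], ref, "G2", barcodes, 1000, error_rate=0.0,
            rng=np.random.default_rng(6),
        )
        assert len(reads) == 1000
        assert sum(truth.values()) == 1000
        lib_ref_len = len(ref.cds_window)
        for read_id, seq in reads[:20]:
            _, gen, codon, _ = read_id.split(":")
            payload = seq[barcodes.payload_offset :]
            assert gen == "G2"
            assert len(payload) == lib_ref_len
            assert payload[panel[0].nns_codon_start : panel[0].nns_codon_start + 3] == codon

    def test_substitution_rate_matches_binomial(self, ref, panel, barcodes):
        eps = 0.003
        pop = Population({"CTG": 1})
        reads, _ = simulate_reads(
            pop, panel[0], ref, "G0", barcodes, 2000, error_rate=eps,
            rng=np.random.default_rng(7),
        )
        template, _ = simulate_reads(
            pop, panel[0], ref, "G0", barcodes, 1, error_rate=0.0,
            rng=np.random.default_rng(8),
        )
        clean = template[0][1]
        total = mismatches = 0
        for _, seq in reads:
            mismatches += sum(a != b for a, b in zip(seq, clean))
            total += len(seq)
        se = np.sqrt(eps * (1 - eps) / total)
        assert abs(mismatches / total - eps) < 3 * se


class TestCampaign:
    def test_favored_variant_frequency_increases(self, ref, panel):
        config = CampaignConfig(
            libraries=panel[:1], ref=ref,
            fitness=FitnessMap.from_aa({"L": 10.0}),  # others default 1
            initial_depth=5_000, bottleneck=5_000, generations=3,
            reads_per_sample=500, error_rate=0.0, seed=11,
        )
        truth = run_campaign(config).population_truth
        lib_id = panel[0].library_id
        series = []
        for t in range(4):
            gen = truth[(truth.library == lib_id) & (truth.generation == f"G{t}")]
            leu = gen[gen.codon.isin(["CTG", "CTC", "TTG"])]["pop_frequency"].sum()
            series.append(leu)
        assert all(b > a for a, b in zip(series, series[1:]))

    def test_generation_zero_only_campaign(self, ref, panel):
        config = CampaignConfig(
            libraries=panel[:1], ref=ref, fitness=FitnessMap(),
            initial_depth=1000, bottleneck=1000, generations=0,
            reads_per_sample=100, error_rate=0.0, seed=3,
        )
        result = run_campaign(config)
        assert set(result.reads) == {(panel[0].library_id, "G0")}

    def test_campaign_is_deterministic_under_seed(self, ref, panel):
        def run():
            config = CampaignConfig(
                libraries=panel[:1], ref=ref, fitness=FitnessMap(),
                initial_depth=500, bottleneck=500, generations=1,
                reads_per_sample=200, error_rate=0.001, seed=99,
            )
            return run_campaign(config)

        a, b = run(), run()
        assert a.all_reads() == b.all_reads()
        assert a.population_truth.equals(b.population_truth)

    def test_low_bottleneck_warns_about_representation(self, ref, panel):
        with pytest.warns(UserWarning, match="10-fold"):
            CampaignConfig(
                libraries=panel[:1], ref=ref, fitness=FitnessMap(),
                bottleneck=100, seed=0,
            )

    def test_noiseless_demux_reproduces_truth_exactly(self, noiseless_campaign, decoder):
        table, _ = decoder.tabulate(noiseless_campaign.all_reads())
        assert table.rejects == {}
        observed = {
            (lib, gen, codon): n for (lib, gen, codon), n in table.counts.items()
        }
        truth = {
            (row.library, row.generation, row.codon): row.read_count
            for row in noiseless_campaign.read_truth.itertuples()
        }
        assert observed == truth
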
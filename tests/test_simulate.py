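import numpy as np
import pandas as pd
import pytest

from bsamap.io import GenomeLayout
from bsamap.simulate import (
    BC1,
    ConfigError,
    SimConfig,
    build_bulks,
    haldane_r,
    sample_reads,
    simulate_experiment,
    simulate_population,
)
from bsamap.snp_index import compute_snp_index


def _cfg(**kw):
    base = dict(
        genome=GenomeLayout([("chr1", 2_000_000)]),
        causal_chrom="chr1",
        causal_pos=1_000_000,
        seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestMendelianSegregation:
    def test_f2_mutant_fraction_is_one_quarter(self):
        pop = simulate_population(_cfg(n_plants=10_000))
        frac = float(np.mean(pop.phenotype == "mutant"))
        # binomial 3-sigma band around 1/4
        sigma = np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(frac - 0.25) < 3 * sigma

    def test_bc1_mutant_fraction_is_one_half(self):
        pop = simulate_population(_cfg(cross_type=BC1, n_plants=10_000))
        frac = float(np.mean(pop.phenotype == "mutant"))
        sigma = np.sqrt(0.25 / 10_000)
        assert abs(frac - 0.5) < 3 * sigma

    def test_bc1_has_no_homozygous_reference(self):
        pop = simulate_population(_cfg(cross_type=BC1, n_plants=500))
        assert pop.dosage.min() >= 1

    def test_phenotype_tracks_causal_genotype(self):
        pop = simulate_population(_cfg(n_plants=2000))
        bb = pop.dosage[:, pop.causal_index] == 2
        assert np.array_equal(bb, pop.phenotype == "mutant")


class TestRecombination:
    @pytest.mark.parametrize("dist_bp", [100_000, 1_000_000, 5_000_000])
    def test_recombinant_fraction_matches_haldane(self, dist_bp):
        genome = GenomeLayout([("c", 10_000_000)])
        cfg = SimConfig(
            genome=genome, causal_chrom="c", causal_pos=1,
            snp_positions={"c": [1, 1 + dist_bp]},
            cross_type=BC1, n_plants=20_000, seed=3,
        )
        pop = simulate_population(cfg)
        # BC1 dosage - 1 recovers the single F1 gamete's alleles
        gam = pop.dosage - 1
        rec = float(np.mean(gam[:, 0] != gam[:, 1]))
        r = haldane_r(dist_bp / 1e6 * cfg.cm_per_mb)
        sigma = np.sqrt(r * (1 - r) / 20_000)
        assert abs(rec - r) < 4 * sigma

    def test_zero_distance_never_recombines(self):
        # adjacent base pairs: d ~ 3e-6 cM, r(d) ~ 3e-8 -> no recombinant
        genome = GenomeLayout([("c", 100)])
        cfg = SimConfig(
            genome=genome, causal_chrom="c", causal_pos=10,
            snp_positions={"c": [10, 11]}, cross_type=BC1, n_plants=2000, seed=1,
        )
        pop = simulate_population(cfg)
        gam = pop.dosage - 1
        assert np.array_equal(gam[:, 0], gam[:, 1])


class TestBulks:
    def test_study_design_bulks_are_disjoint(self):
        pop = simulate_population(_cfg(n_plants=185, seed=11))
        a, b = build_bulks(pop, 21)
        assert len(a) == len(b) == 21
        assert not set(a) & set(b)
        assert all(pop.phenotype[a] == "mutant") and all(pop.phenotype[b] == "wild")

    def test_zero_bulk_size(self):
        pop = simulate_population(_cfg(n_plants=50))
        a, b = build_bulks(pop, 0)
        assert len(a) == len(b) == 0

    def test_insufficient_plants_names_deficit(self):
        pop = simulate_population(_cfg(n_plants=20, seed=2))
        with pytest.raises(ConfigError, match="mutant"):
            build_bulks(pop, 19)


class TestPooledReads:
    def test_mutant_bulk_index_near_one_at_causal(self):
        cfg = _cfg(n_plants=185, error_rate=0.0, mean_depth=50.0, seed=5)
        counts, pop, _ = simulate_experiment(cfg)
        idx = compute_snp_index(counts)
        causal = idx[idx["pos"] == cfg.causal_pos].iloc[0]
        assert causal["indexA"] == 1.0

    def test_wild_bulk_allele_freq_one_third_at_causal(self):
        # exact conditional expectation: green plants are 1/3 AA : 2/3 AB
        freqs = []
        for s in range(300):
            cfg = _cfg(n_plants=185, seed=1000 + s)
            pop = simulate_population(cfg)
            _, b = build_bulks(pop)
            p = pop.dosage[b, pop.causal_index].sum() / (2 * len(b))
            freqs.append(p)
        sem = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 1 / 3) < 3 * sem

    def test_unlinked_delta_centred_on_zero(self):
        genome = GenomeLayout([("c1", 1_000_000), ("c2", 1_000_000)])
        deltas = []
        for s in range(200):
            cfg = SimConfig(
                genome=genome, causal_chrom="c1", causal_pos=500_000,
                snp_positions={"c1": [500_000], "c2": [500_000]},
                n_plants=185, seed=2000 + s,
            )
            counts, _, _ = simulate_experiment(cfg)
            idx = compute_snp_index(counts)
            deltas.append(float(idx[idx["chrom"] == "c2"]["delta"].iloc[0]))
        sem = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * sem + 1e-9

    def test_same_seed_bit_identical(self):
        cfg = _cfg(n_plants=100, seed=9)
        c1, _, _ = simulate_experiment(cfg)
        c2, _, _ = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(c1, c2)


class TestConfigValidation:
    def test_causal_outside_genome(self):
        with pytest.raises(ConfigError, match="outside"):
            _cfg(causal_pos=3_000_000)

    def test_bad_error_rate(self):
        with pytest.raises(ConfigError):
            _cfg(error_rate=0.7)

    def test_bad_cross_type(self):
        with pytest.raises(ConfigError):
            _cfg(cross_type="F3")
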
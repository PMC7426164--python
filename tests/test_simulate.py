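"""Simulator dynamics: closed forms, drift, mutation, emitters."""

import math

import numpy as np
import pytest

from ltsp_recovery import growth as gk
from ltsp_recovery.classify import classify_rnapc
from ltsp_recovery.simulate import (
    GenotypeSpec,
    PopulationState,
    SimulationConfig,
    dilute,
    emit_clone_sample,
    emit_od_curves,
    grow_cycle,
    mutate,
    run_experiment,
    synthetic_cds_complement,
    trajectory_frame,
    write_plate_csv,
)

NO_MUTATION = dict(mu_reversion=0.0, mu_compensation=0.0)


def spec_map(*specs):
    return {s.genotype_id: s for s in specs}


class TestGrowCycle:
    def test_single_wildtype_multiplies_by_dilution_factor(self):
        cfg = SimulationConfig(**NO_MUTATION)
        state = PopulationState(0, {"wt": 1000.0})
        grown = grow_cycle(state, spec_map(GenotypeSpec("wt", 1.0)), cfg)
        assert grown.counts["wt"] == pytest.approx(1000.0 * 100.0)

    def test_log2_odds_gap_grows_by_selection_differential(self):
        cfg = SimulationConfig(**NO_MUTATION)
        specs = spec_map(GenotypeSpec("fast", 1.0), GenotypeSpec("slow", 0.8))
        state = PopulationState(0, {"fast": 1e6, "slow": 1e6})
        grown = grow_cycle(state, specs, cfg)
        gap = math.log2(grown.counts["fast"] / grown.counts["slow"])
        assert gap == pytest.approx(cfg.g * 0.2, abs=1e-12)

    def test_equal_rates_leave_frequencies_unchanged(self):
        cfg = SimulationConfig(**NO_MUTATION)
        specs = spec_map(GenotypeSpec("a", 0.9), GenotypeSpec("b", 0.9))
        state = PopulationState(0, {"a": 300.0, "b": 700.0})
        grown = grow_cycle(state, specs, cfg)
        assert grown.frequencies == pytest.approx(state.frequencies)

    def test_empty_population_rejected(self):
        cfg = SimulationConfig(**NO_MUTATION)
        with pytest.raises(ValueError):
            grow_cycle(PopulationState(0, {}), {}, cfg)


class TestDilute:
    def test_single_genotype_gets_all_draws(self):
        cfg = SimulationConfig(bottleneck_n=5000, **NO_MUTATION)
        out = dilute(PopulationState(0, {"wt": 1e8}), cfg, np.random.default_rng(0))
        assert out.counts == {"wt": 5000}
        assert out.cycle == 1

    def test_zero_frequency_genotype_never_sampled(self):
        cfg = SimulationConfig(bottleneck_n=5000, **NO_MUTATION)
        out = dilute(
            PopulationState(0, {"a": 1e8, "ghost": 0.0}), cfg, np.random.default_rng(1)
        )
        assert "ghost" not in out.counts

    def test_binomial_moments_of_bottleneck(self):
        cfg = SimulationConfig(bottleneck_n=1000, **NO_MUTATION)
        rng = np.random.default_rng(7)
        state = PopulationState(0, {"a": 1e9, "b": 1e9})
        freqs = np.array(
            [dilute(state, cfg, rng).counts.get("a", 0) / 1000 for _ in range(10_000)]
        )
        se_mean = 0.5 / math.sqrt(1000 * 10_000)
        assert abs(freqs.mean() - 0.5) < 4 * se_mean
        assert freqs.var() == pytest.approx(0.25 / 1000, rel=0.1)


class TestMutate:
    def test_no_mutation_rates_no_new_genotypes(self):
        cfg = SimulationConfig(**NO_MUTATION)
        specs = spec_map(GenotypeSpec("an", 0.8, carries_anrnapc=True))
        state = PopulationState(0, {"an": 1e8})
        out, new_specs = mutate(state, specs, cfg, np.random.default_rng(0))
        assert out.counts == state.counts
        assert new_specs == specs

    def test_full_recovery_compensated_rate_is_wildtype(self):
        cfg = SimulationConfig(
            mu_reversion=0.0, mu_compensation=1e-4, compensation_rate_recovery=1.0
        )
        specs = spec_map(GenotypeSpec("an", 0.8, carries_anrnapc=True))
        state = PopulationState(0, {"an": 1e7})
        _, new_specs = mutate(state, specs, cfg, np.random.default_rng(0))
        assert new_specs["an::comp"].relative_rate == pytest.approx(1.0)
        assert new_specs["an::comp"].carries_anrnapc

    def test_partial_recovery_reduces_cost_fraction(self):
        cfg = SimulationConfig(
            mu_reversion=0.0, mu_compensation=1e-4, compensation_rate_recovery=0.5
        )
        specs = spec_map(GenotypeSpec("an", 0.8, carries_anrnapc=True))
        _, new_specs = mutate(
            PopulationState(0, {"an": 1e7}), specs, cfg, np.random.default_rng(0)
        )
        assert new_specs["an::comp"].relative_rate == pytest.approx(0.9)

    def test_reverted_genotype_restores_wildtype_rate(self):
        cfg = SimulationConfig(mu_reversion=1e-4, mu_compensation=0.0)
        specs = spec_map(GenotypeSpec("an", 0.8, mutator=True, carries_anrnapc=True))
        _, new_specs = mutate(
            PopulationState(0, {"an": 1e7}), specs, cfg, np.random.default_rng(0)
        )
        rev = new_specs["an::rev"]
        assert rev.relative_rate == pytest.approx(1.0)
        assert not rev.carries_anrnapc
        assert rev.mutator  # mutator background is inherited

    def test_mutator_factor_scales_event_counts(self):
        state = PopulationState(0, {"an": 1e6})
        events = {True: 0, False: 0}
        for is_mut in (True, False):
            cfg = SimulationConfig(
                mu_reversion=1e-9, mu_compensation=0.0, mutator_factor=100.0
            )
            specs = spec_map(
                GenotypeSpec("an", 0.8, mutator=is_mut, carries_anrnapc=True)
            )
            rng = np.random.default_rng(11)
            for _ in range(3000):
                out, _ = mutate(state, specs, cfg, rng)
                events[is_mut] += out.counts.get("an::rev", 0)
        # Poisson expectation scales by the mutator factor (x100); with
        # ~20 vs ~2000 expected totals the ratio is loose but decisive
        assert events[True] > 20 * max(events[False], 1)


class TestRunExperiment:
    def test_identical_seeds_identical_trajectories(self):
        specs = [GenotypeSpec("an", 0.8, carries_anrnapc=True), GenotypeSpec("wt", 1.0)]
        cfg = SimulationConfig(bottleneck_n=10_000, cycles=8, seed=5)
        a = run_experiment({"an": 9000, "wt": 1000}, specs, cfg)
        b = run_experiment({"an": 9000, "wt": 1000}, specs, cfg)
        assert trajectory_frame(a).equals(trajectory_frame(b))
        assert a.mean_relative_rate == b.mean_relative_rate

    def test_single_wildtype_mean_rate_constant(self):
        cfg = SimulationConfig(bottleneck_n=1000, cycles=6, seed=0, **NO_MUTATION)
        res = run_experiment({"wt": 1000}, [GenotypeSpec("wt", 1.0)], cfg)
        assert res.mean_relative_rate == pytest.approx([1.0] * 6)

    def test_neutral_two_genotype_drift_preserves_mean_frequency(self):
        specs = [GenotypeSpec("a", 1.0), GenotypeSpec("b", 1.0)]
        finals = []
        for seed in range(2000):
            cfg = SimulationConfig(
                bottleneck_n=500, cycles=8, seed=seed, **NO_MUTATION
            )
            res = run_experiment({"a": 150, "b": 350}, specs, cfg)
            finals.append(res.states[-1].counts.get("a", 0) / 500)
        mean = np.mean(finals)
        se = np.std(finals, ddof=1) / math.sqrt(len(finals))
        assert abs(mean - 0.3) < 3 * se

    def test_bottleneck_conservation_every_cycle(self):
        specs = [GenotypeSpec("an", 0.8, carries_anrnapc=True), GenotypeSpec("wt", 1.0)]
        cfg = SimulationConfig(
            bottleneck_n=20_000, cycles=12, seed=3,
            mu_reversion=1e-7, mu_compensation=4e-7,
        )
        res = run_experiment({"an": 18_000, "wt": 2_000}, specs, cfg)
        for state in res.states:
            assert state.total == 20_000
            assert sum(state.frequencies.values()) == pytest.approx(1.0)

    def test_unknown_genotype_in_initial_counts_rejected(self):
        cfg = SimulationConfig(**NO_MUTATION)
        with pytest.raises(ValueError, match="unknown"):
            run_experiment({"mystery": 10}, [GenotypeSpec("wt", 1.0)], cfg)

    def test_compensation_outcomes_outnumber_reversions_k_to_one(self):
        # with k equally likely compensatory targets, equal per-site rates
        # and full cost recovery, the first recovery event to establish is
        # compensation with probability k/(k+1)
        k = 4
        comp = rev = 0
        spec = [GenotypeSpec("an", 0.8, mutator=True, carries_anrnapc=True)]
        for seed in range(150):
            cfg = SimulationConfig(
                bottleneck_n=100_000, cycles=16, seed=seed,
                mu_reversion=1e-9, mu_compensation=k * 1e-9,
                mutator_factor=100.0, compensation_rate_recovery=1.0,
            )
            res = run_experiment({"an": 100_000}, spec, cfg)
            final = res.states[-1]
            top = max(final.counts, key=final.counts.get)
            if top.endswith("::comp"):
                comp += 1
            elif top.endswith("::rev"):
                rev += 1
        decided = comp + rev
        assert decided > 50
        p_hat = comp / decided
        p_exp = k / (k + 1)
        se = math.sqrt(p_exp * (1 - p_exp) / decided)
        assert abs(p_hat - p_exp) < 3 * se


class TestEmitCloneSample:
    def test_fixed_population_all_clones_carry_allele(self):
        spec = GenotypeSpec("an", 0.8, mutator=True, carries_anrnapc=True,
                            base_mutation_load=3.0)
        state = PopulationState(0, {"an": 10_000})
        clones = emit_clone_sample(
            state, spec_map(spec), 10, (0.76, 0.24), np.random.default_rng(0)
        )
        assert len(clones) == 10
        assert all(classify_rnapc(c).startswith("anRNAPC") for c in clones)
        assert all(c.mutator for c in clones)

    def test_zero_load_only_founder_mutations(self):
        spec = GenotypeSpec("an", 0.8, carries_anrnapc=True, base_mutation_load=0.0)
        state = PopulationState(0, {"an": 100})
        clones = emit_clone_sample(
            state, spec_map(spec), 5, (0.76, 0.24), np.random.default_rng(1)
        )
        sets = {c.mutations for c in clones}
        assert len(sets) == 1  # identical founder-defined genomes

    def test_reverted_genotype_lacks_allele_and_compensated_adds_rnapc(self):
        base = GenotypeSpec("an", 0.8, carries_anrnapc=True)
        cfg = SimulationConfig()
        rev = GenotypeSpec("an::rev", 1.0, parent_id="an", derivation="reversion")
        comp = GenotypeSpec(
            "an::comp", 1.0, carries_anrnapc=True, parent_id="an",
            derivation="compensation",
        )
        specs = spec_map(base, rev, comp)
        state = PopulationState(16, {"an": 100, "an::rev": 100, "an::comp": 100})
        clones = emit_clone_sample(
            state, specs, 30, (0.76, 0.24), np.random.default_rng(2)
        )
        cats = {c.clone_id: classify_rnapc(c) for c in clones}
        assert len(set(cats.values())) >= 2  # mixture sampled

    def test_passenger_class_split_follows_site_fractions(self):
        spec = GenotypeSpec("wt", 1.0, base_mutation_load=50.0)
        state = PopulationState(0, {"wt": 1000})
        clones = emit_clone_sample(
            state, spec_map(spec), 40, (0.7, 0.3), np.random.default_rng(3)
        )
        ns = syn = 0
        for c in clones:
            for m in c.mutations:
                if m.gene.startswith("gene"):
                    ns += m.mclass == "nonsynonymous"
                    syn += m.mclass == "synonymous"
        total = ns + syn
        se = math.sqrt(0.7 * 0.3 / total)
        assert abs(ns / total - 0.7) < 3 * se


class TestEmitOdCurves:
    def test_zero_noise_exponential_round_trip_exact(self):
        curves = emit_od_curves(
            [GenotypeSpec("x", 0.8)], np.random.default_rng(0),
            carrying_capacity=float("inf"), noise_sd=0.0, additive_sd=0.0,
            lag_min=0.0,
        )
        est = gk.fit_exponential_rate(curves[0])
        assert est.rate == pytest.approx(0.8 * 0.025, abs=1e-6)

    def test_noisy_logistic_relative_rate_within_two_percent(self):
        rng = np.random.default_rng(12345)
        curves = emit_od_curves(
            [GenotypeSpec("s", 0.8), GenotypeSpec("wt", 1.0)], rng, replicates=8
        )
        est = {c.sample_id: gk.fit_exponential_rate(c) for c in curves}
        wt = np.mean([e.rate for k, e in est.items() if k.startswith("wt") and e.qualified])
        s = np.mean([e.rate for k, e in est.items() if k.startswith("s.") and e.qualified])
        assert 100 * s / wt == pytest.approx(80.0, abs=2.0)

    def test_zero_rate_flat_curve_unqualified(self):
        curves = emit_od_curves(
            [GenotypeSpec("still", 1.0)], np.random.default_rng(0),
            wildtype_rate_per_min=0.0, noise_sd=0.0, additive_sd=0.0,
        )
        assert not gk.fit_exponential_rate(curves[0]).qualified

    def test_plate_round_trip_via_csv(self, tmp_path):
        curves = emit_od_curves(
            [GenotypeSpec("a", 1.0)], np.random.default_rng(4), replicates=2
        )
        path = tmp_path / "plate.csv"
        write_plate_csv(curves, path)
        back = gk.read_plate_csv(path)
        assert [c.sample_id for c in back] == [c.sample_id for c in curves]
        assert back[0].od == pytest.approx(curves[0].od)


class TestSyntheticCds:
    def test_composition_matches_usage_exactly(self, k12_usage):
        genes = synthetic_cds_complement(k12_usage, scale=10, seed=9)
        from collections import Counter

        counts = Counter()
        for g in genes:
            codons = [g[i: i + 3] for i in range(0, len(g), 3)]
            assert codons[-1] == "TAA"
            counts.update(codons[:-1])
        for codon, per1000 in k12_usage.items():
            assert counts[codon] == round(per1000 * 10)

    def test_site_ratio_matches_usage_weighting(self, k12_usage, k12_sites):
        from ltsp_recovery.selection import site_counts

        genes = synthetic_cds_complement(k12_usage, scale=20, seed=0)
        assert site_counts(genes).ratio == pytest.approx(k12_sites.ratio, rel=1e-6)

    def test_seed_changes_order_not_composition(self, k12_usage):
        a = synthetic_cds_complement(k12_usage, scale=5, seed=1)
        b = synthetic_cds_complement(k12_usage, scale=5, seed=2)
        assert a != b
        assert sorted("".join(a)) == sorted("".join(b))
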
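"""Simulator: determinism, population statistics, Mendelian bookkeeping,
noise channels, and their closed-form consequences."""

import math

import numpy as np

from hla_concord.nomenclature import Resolution
from hla_concord.synthetic_data import (
    DEFAULT_DRB1_LINKAGE,
    NoiseProfile,
    SimulationConfig,
    apply_noise,
    estimate_noise_rates,
    render_truth,
    replay_events,
    simulate_duplicates,
    simulate_families,
    simulate_population,
    simulate_study,
)
from hla_concord.trio_consistency import evaluate_trios, score_trio_at_locus
from hla_concord.duplicate_concordance import evaluate_pairs

from _helpers import oracle_trio_score


class TestDeterminismAndFrequencies:
    def test_identical_seed_identical_output(self):
        b1 = simulate_study(SimulationConfig(n_families=20, seed=5,
                                             dropout_rate=0.1,
                                             truncation_rate=0.1,
                                             mistyping_rate=0.1))
        b2 = simulate_study(SimulationConfig(n_families=20, seed=5,
                                             dropout_rate=0.1,
                                             truncation_rate=0.1,
                                             mistyping_rate=0.1))
        for sid in b1.typings:
            for locus, call in b1.typings[sid].calls.items():
                assert call.alleles == b2.typings[sid].calls[locus].alleles
        assert b1.events == b2.events

    def test_different_seed_differs(self):
        b1 = simulate_study(SimulationConfig(n_families=20, seed=5))
        b2 = simulate_study(SimulationConfig(n_families=20, seed=6))
        assert any(
            b1.typings[sid].calls[l].alleles != b2.typings[sid].calls[l].alleles
            for sid in b1.typings for l in b1.typings[sid].calls)

    def test_founder_allele_frequencies_recovered(self):
        """Observed founder haplotype frequencies sit within 3 binomial SE
        of the configured categorical distribution."""
        cfg = SimulationConfig(loci=("A",), seed=123)
        n = 10_000
        truth = simulate_population(cfg, n)
        pool = truth.pools["A"]
        counts = {a: 0 for a in pool}
        for s in truth.samples.values():
            for h in s.haplotypes:
                counts[h["A"]] += 1
        n_hap = 2 * n
        from hla_concord.synthetic_data import default_frequencies

        for a, p in zip(pool, default_frequencies(len(pool))):
            se = math.sqrt(p * (1 - p) / n_hap)
            assert abs(counts[a] / n_hap - p) <= 3 * se + 1e-6


class TestDrbLinkage:
    def test_paralog_presence_follows_drb1_group(self):
        truth = simulate_population(SimulationConfig(seed=9), 500)
        for s in truth.samples.values():
            for h in s.haplotypes:
                expected = DEFAULT_DRB1_LINKAGE[h["DRB1"].fields[0]]
                carried = [n for n in ("DRB3", "DRB4", "DRB5") if n in h]
                assert carried == ([expected] if expected else [])

    def test_null_linked_group_yields_no_secondary_gene(self):
        linkage = {g: None for g in DEFAULT_DRB1_LINKAGE}
        cfg = SimulationConfig(seed=9, drb1_linkage=linkage)
        truth = simulate_population(cfg, 50)
        for s in truth.samples.values():
            assert s.true_unit() == ()

    def test_child_alleles_subset_of_parental_union(self):
        truth = simulate_families(SimulationConfig(n_families=100, seed=17))
        for trio in truth.trios:
            child = truth.samples[trio.child_id]
            father = truth.samples[trio.father_id]
            mother = truth.samples[trio.mother_id]
            parental = set()
            for s in (father, mother):
                for h in s.haplotypes:
                    parental.update((l, a) for l, a in h.items())
            for h in child.haplotypes:
                assert all((l, a) in parental for l, a in h.items())
            # DRB345 haplotype bookkeeping: the child's true unit is
            # drawn from the pooled parental units
            pooled = [*father.true_unit(), *mother.true_unit()]
            for a in child.true_unit():
                assert a in pooled
                pooled.remove(a)


class TestNoiseChannels:
    def test_zero_rates_leave_truth_intact(self):
        truth = simulate_families(SimulationConfig(n_families=10, seed=3))
        clean = render_truth(truth)
        rng = np.random.default_rng(0)
        observed, events = apply_noise(
            clean, NoiseProfile("x", truth.config.loci), truth.pools, rng)
        assert events == []
        for sid in clean:
            for locus, call in clean[sid].calls.items():
                assert observed[sid].calls[locus].alleles == call.alleles

    def test_forced_dropout_blanks_every_table(self):
        bundle = simulate_study(SimulationConfig(n_families=30, seed=3,
                                                 dropout_rate=1.0))
        table, _ = evaluate_trios(bundle.typings, bundle.trios)
        for row in table.rows:
            assert row.n == 0 and row.pct == (None, None, None)

    def test_event_log_replays_to_observed(self):
        truth = simulate_families(SimulationConfig(
            n_families=30, seed=21, dropout_rate=0.1, truncation_rate=0.15,
            mistyping_rate=0.05))
        clean = render_truth(truth)
        rng = np.random.default_rng(truth.config.seed)
        observed, events = apply_noise(
            clean, truth.config.noise_profile(), truth.pools, rng)
        replayed = replay_events(clean, events)
        for sid in clean:
            for locus in clean[sid].calls:
                assert replayed[sid].calls[locus].alleles \
                    == observed[sid].calls[locus].alleles

    def test_rates_recovered_from_observed_vs_truth_diffs(self):
        """Channel-rate estimators agree exactly with the event log and
        sit within 3 binomial SE of the configured rates (>=1e4 slots)."""
        d, t, m = 0.05, 0.10, 0.03
        cfg = SimulationConfig(seed=31, dropout_rate=d, truncation_rate=t,
                               mistyping_rate=m)
        truth = simulate_population(cfg, 700)
        clean = render_truth(truth)
        rng = np.random.default_rng(cfg.seed)
        observed, events = apply_noise(clean, cfg.noise_profile(),
                                       truth.pools, rng)
        est = estimate_noise_rates(clean, observed)
        assert est.n_slots >= 10_000
        # the log is a complete account: diff counts equal event counts
        kinds = {"dropout": 0, "truncation": 0, "mistyping": 0}
        for ev in events:
            kinds[ev.kind] += 1
        assert (est.n_dropout, est.n_truncation, est.n_mistyping) \
            == (kinds["dropout"], kinds["truncation"], kinds["mistyping"])
        for rate, estimate, denom in (
                (d, est.dropout, est.n_slots),
                (t, est.truncation, est.n_slots - est.n_dropout),
                (m, est.mistyping,
                 est.n_slots - est.n_dropout - est.n_truncation)):
            se = math.sqrt(rate * (1 - rate) / denom)
            assert abs(estimate - rate) <= 3 * se

    def test_child_mistyping_matches_enumerated_expectation(self):
        """With mistyping on children only (other noise 0), the mean trio
        score at a regular locus matches the exactly enumerated
        expectation within 3 SE at 2,000 trios.

        The oracle enumerates, per trio, every noise outcome of the two
        child slots (intact, or replaced by each of the K-1 alternative
        pool alleles, uniformly) and averages the exhaustively enumerated
        transmission score over that distribution.
        """
        m = 0.10
        cfg = SimulationConfig(n_families=2_000, seed=77)
        truth = simulate_families(cfg)
        clean = render_truth(truth)
        rng = np.random.default_rng(cfg.seed)
        child_ids = [t.child_id for t in truth.trios]
        profile = NoiseProfile("sim", cfg.loci, mistyping_rate=m)
        observed, _ = apply_noise(clean, profile, truth.pools, rng,
                                  samples=child_ids)

        pool = truth.pools["A"]
        K = len(pool)

        def outcomes(a):
            yield 1.0 - m, a
            for x in pool:
                if x != a:
                    yield m / (K - 1), x

        exact_mean = 0.0
        exact_var = 0.0
        obs_scores = []
        from hla_concord.typing_io import GenotypeCall

        for trio in truth.trios:
            child = clean[trio.child_id].calls["A"]
            father = clean[trio.father_id].calls["A"]
            mother = clean[trio.mother_id].calls["A"]
            e1 = e2 = 0.0
            for p1, a1 in outcomes(child.alleles[0]):
                for p2, a2 in outcomes(child.alleles[1]):
                    s = oracle_trio_score(
                        GenotypeCall(child.locus, (a1, a2)), father,
                        mother, Resolution(3))
                    e1 += p1 * p2 * s
                    e2 += p1 * p2 * s * s
            exact_mean += e1
            exact_var += e2 - e1 * e1
            obs_scores.append(score_trio_at_locus(
                trio, observed, "A", Resolution(3)).score)
        n = len(truth.trios)
        se = math.sqrt(exact_var) / n
        assert abs(sum(obs_scores) / n - exact_mean / n) <= 3 * se


class TestSimulateDuplicates:
    def test_noise_free_duplicates_fully_concordant(self):
        cfg = SimulationConfig(seed=13)
        rng = np.random.default_rng(cfg.seed)
        truth = simulate_population(cfg, 50, rng)
        pa = NoiseProfile("panel", cfg.loci)
        pb = NoiseProfile("exome", cfg.loci)
        oa, ob, pairs, _ = simulate_duplicates(truth, pa, pb, rng)
        table, _ = evaluate_pairs(oa, ob, pairs)
        for row in table.rows:
            assert row.pct == (100.0, 100.0, 100.0)

    def test_panel_without_a_locus_drops_it_from_the_report(self):
        cfg = SimulationConfig(loci=("A", "B", "DOA"), seed=13)
        rng = np.random.default_rng(cfg.seed)
        truth = simulate_population(cfg, 20, rng)
        pa = NoiseProfile("panel", ("A", "B"))  # DOA not targeted
        pb = NoiseProfile("exome", ("A", "B", "DOA"))
        oa, ob, pairs, _ = simulate_duplicates(truth, pa, pb, rng)
        table, _ = evaluate_pairs(oa, ob, pairs)
        assert [r.locus for r in table.rows] == ["A", "B"]

    def test_one_sided_truncation_hits_only_field3(self):
        """Truncation at rate t in one dataset leaves field-1/2
        concordance at 100% and puts field-3 concordance at its
        enumerated per-slot expectation 100(1-t), within 3 binomial SE
        at 1,000 pairs."""
        t = 0.20
        cfg = SimulationConfig(seed=29)
        rng = np.random.default_rng(cfg.seed)
        n = 1_000
        truth = simulate_population(cfg, n, rng)
        pa = NoiseProfile("exome", cfg.loci, truncation_rate=t)
        pb = NoiseProfile("panel", cfg.loci)
        oa, ob, pairs, _ = simulate_duplicates(truth, pa, pb, rng)
        table, _ = evaluate_pairs(oa, ob, pairs)
        rows = {r.locus: r for r in table.rows}
        row = rows["A"]  # regular diploid locus: every slot truncatable
        assert row.pct[0] == 100.0 and row.pct[1] == 100.0
        # score per pair = (X1 + X2)/2 with Xi ~ Bernoulli(1-t)
        se = 100 * math.sqrt(t * (1 - t) / (2 * n))
        assert abs(row.pct[2] - 100 * (1 - t)) <= 3 * se
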
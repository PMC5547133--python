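"""Emission model, transitions, Viterbi decoding and haplotype inference."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nipthap.hmm import (
    RECOMB_FLOOR,
    EmissionModel,
    GeneticMap,
    ObservedSite,
    emission_posterior,
    expected_proportions,
    infer_fetal_haplotypes,
    recombination_probability,
    transition_matrix,
    viterbi,
)
from nipthap.phasing import InfoClass, phase_trio
from nipthap.simulator import SimConfig, simulate_family, simulate_plasma


class TestExpectedProportions:
    def test_paternal_site_half_fetal_fraction(self):
        prob0, prob1 = expected_proportions(InfoClass.PATERNAL, True, f=0.10, error_rate=0.0)
        assert prob0 == pytest.approx(0.05)
        assert prob1 == pytest.approx(0.0)

    def test_maternal_site_dosage_imbalance(self):
        prob0, prob1 = expected_proportions(InfoClass.MATERNAL, True, f=0.10, error_rate=0.0)
        assert prob0 == pytest.approx(0.50)
        assert prob1 == pytest.approx(0.45)

    def test_informative_allele_on_hap1_swaps_roles(self):
        a = expected_proportions(InfoClass.PATERNAL, True, f=0.08, error_rate=0.002)
        b = expected_proportions(InfoClass.PATERNAL, False, f=0.08, error_rate=0.002)
        assert a == (b[1], b[0])

    def test_zero_fetal_fraction_indistinguishable(self):
        for cls in (InfoClass.PATERNAL, InfoClass.MATERNAL):
            prob0, prob1 = expected_proportions(cls, True, f=0.0, error_rate=0.003)
            assert prob0 == pytest.approx(prob1)

    @pytest.mark.parametrize("f", [-0.1, 1.0, 1.5])
    def test_invalid_fraction_rejected(self, f):
        with pytest.raises(ValueError):
            expected_proportions(InfoClass.PATERNAL, True, f=f)

    def test_uninformative_class_rejected(self):
        with pytest.raises(ValueError):
            expected_proportions(InfoClass.UNINFORMATIVE, True, f=0.1)


def _posterior_oracle(k, n, prob0, prob1):
    """Exact rational posterior: binomial coefficients cancel."""
    p0, p1 = Fraction(prob0), Fraction(prob1)
    l0 = p0**k * (1 - p0) ** (n - k)
    l1 = p1**k * (1 - p1) ** (n - k)
    if l0 + l1 == 0:
        return (Fraction(1, 2), Fraction(1, 2))
    return (l0 / (l0 + l1), l1 / (l0 + l1))


class TestEmissionPosterior:
    def test_zero_reads_of_fetal_allele_favors_noncarrier_state(self):
        # k=0 has probability 1 under the non-carrying haplotype (prob1=0)
        # and 0.95^100 under the carrier, so the posterior is ~1 for Hap 1
        site = ObservedSite(pos=1, info_class=InfoClass.PATERNAL,
                            informative_on_hap0=True, k=0, n_reads=100)
        b0, b1 = emission_posterior(site, EmissionModel(f=0.10, error_rate=0.0))
        assert b1 == pytest.approx(1.0 / (1.0 + 0.95 ** 100), rel=1e-9)
        assert b1 > 0.99

    def test_equal_proportions_give_uniform_posterior(self):
        site = ObservedSite(pos=1, info_class=InfoClass.PATERNAL,
                            informative_on_hap0=True, k=3, n_reads=50)
        b0, b1 = emission_posterior(site, EmissionModel(f=0.0, error_rate=0.004))
        assert b0 == pytest.approx(0.5)
        assert b1 == pytest.approx(0.5)

    def test_posteriors_normalize(self, rng):
        model = EmissionModel(f=0.04, error_rate=0.005)
        for _ in range(50):
            n = int(rng.integers(1, 300))
            k = int(rng.integers(0, n + 1))
            cls = InfoClass.PATERNAL if rng.random() < 0.5 else InfoClass.MATERNAL
            site = ObservedSite(pos=1, info_class=cls,
                                informative_on_hap0=bool(rng.random() < 0.5), k=k, n_reads=n)
            b0, b1 = emission_posterior(site, model)
            assert b0 + b1 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k,n,f,cls", [
        (3, 100, 0.04, InfoClass.PATERNAL),
        (0, 40, 0.02, InfoClass.PATERNAL),
        (55, 120, 0.10, InfoClass.MATERNAL),
        (12, 200, 0.01, InfoClass.PATERNAL),
        (97, 200, 0.03, InfoClass.MATERNAL),
    ])
    def test_matches_exact_rational_evaluation(self, k, n, f, cls):
        model = EmissionModel(f=f, error_rate=0.005)
        site = ObservedSite(pos=1, info_class=cls, informative_on_hap0=True, k=k, n_reads=n)
        prob0, prob1 = model.site_proportions(site)
        expect = _posterior_oracle(k, n, prob0, prob1)
        got = emission_posterior(site, model)
        for g, e in zip(got, expect):
            assert abs(g - float(e)) <= 1e-10 * max(float(e), 1e-300)


class TestTransitions:
    def test_zero_distance_floored(self):
        gmap = GeneticMap.constant(1.0)
        a = transition_matrix(100, 101, gmap)  # ~1e-8 Morgan, below the floor
        assert a[0, 1] == pytest.approx(RECOMB_FLOOR)
        assert np.allclose(a.sum(axis=1), 1.0)

    def test_one_centimorgan_haldane(self):
        # 1 cM at 1 cM/Mb is 1 Mb: P = (1 - exp(-0.02)) / 2
        gmap = GeneticMap.constant(1.0)
        a = transition_matrix(1, 1_000_001, gmap)
        assert a[0, 1] == pytest.approx(0.5 * (1 - math.exp(-0.02)), rel=1e-12)
        assert a[0, 1] == pytest.approx(0.009901, abs=5e-7)

    def test_free_recombination_limit(self):
        p = recombination_probability(1e6)
        assert p == pytest.approx(0.5)

    def test_out_of_order_positions_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(200, 100, GeneticMap.constant())

    def test_tabulated_map_interpolation(self):
        gmap = GeneticMap.from_table([0, 1_000_000, 2_000_000], [0.0, 2.0, 2.5])
        assert gmap.cm_at(500_000) == pytest.approx(1.0)
        assert gmap.genetic_distance_morgan(1_000_000, 2_000_000) == pytest.approx(0.005)


def _brute_force_best(log_b, log_a):
    n = log_b.shape[0]
    best_score, best_path = -np.inf, None
    for mask in range(2 ** n):
        path = [(mask >> j) & 1 for j in range(n)]
        score = math.log(0.5) + log_b[0, path[0]]
        for j in range(1, n):
            score += log_a[j - 1, path[j - 1], path[j]] + log_b[j, path[j]]
        if score > best_score:
            best_score, best_path = score, path
    return best_score, best_path


def _path_score(path, log_b, log_a):
    score = math.log(0.5) + log_b[0, path[0]]
    for j in range(1, len(path)):
        score += log_a[j - 1, path[j - 1], path[j]] + log_b[j, path[j]]
    return score


class TestViterbi:
    def test_single_site_argmax(self):
        res = viterbi(np.log([[0.99, 0.01]]), np.empty((0, 2, 2)))
        assert list(res.path) == [0]

    def test_ties_break_toward_no_recombination(self):
        log_b = np.zeros((3, 2))  # emissions carry no information
        log_a = np.log(np.tile([[0.6, 0.4], [0.4, 0.6]], (2, 1, 1)))
        res = viterbi(log_b, log_a)
        assert res.n_recombinations == 0

    @given(st.data())
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_exhaustive_enumeration(self, data):
        n = data.draw(st.integers(1, 8))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        log_b = np.log(rng.dirichlet([1, 1], size=n) + 1e-12)
        probs = rng.uniform(1e-4, 0.5, size=n - 1) if n > 1 else np.empty(0)
        log_a = np.log(np.stack([
            np.array([[1 - p, p], [p, 1 - p]]) for p in probs
        ])) if n > 1 else np.empty((0, 2, 2))
        res = viterbi(log_b, log_a)
        best_score, _ = _brute_force_best(log_b, log_a)
        assert _path_score(list(res.path), log_b, log_a) == pytest.approx(best_score, abs=1e-9)

    def test_label_symmetry(self, rng):
        n = 30
        log_b = np.log(rng.dirichlet([1, 1], size=n))
        probs = rng.uniform(1e-4, 0.4, size=n - 1)
        log_a = np.log(np.stack([np.array([[1 - p, p], [p, 1 - p]]) for p in probs]))
        res = viterbi(log_b, log_a)
        flipped = viterbi(log_b[:, ::-1], log_a)
        assert np.array_equal(res.path, 1 - flipped.path)
        assert np.allclose(res.log_odds, -flipped.log_odds)


def _decode_family(cfg, seed=None):
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    family = simulate_family(cfg, rng)
    plasma = simulate_plasma(family, rng, include_strand=False)
    panel = phase_trio(family.trio_sites())
    return family, infer_fetal_haplotypes(
        panel, plasma, f=cfg.f, gene_interval=cfg.gene_interval,
        genetic_map=GeneticMap.constant(cfg.recomb_rate_cm_per_mb),
        error_rate=cfg.error_rate, f_floor=0.01,
    )


class TestInference:
    def test_no_recombination_chain_decodes_to_constant_path(self):
        cfg = SimConfig(n_snps=1607, f=0.10, mean_depth=200, seed=11,
                        fetal_pat_hap=0, fetal_mat_hap=0,
                        crossovers_pat=(), crossovers_mat=())
        _, inference = _decode_family(cfg)
        assert inference.paternal_call == "P0"
        assert inference.maternal_call == "M0"
        assert inference.paternal.n_recombinations == 0
        assert np.all(inference.paternal.path == 0)

    def test_label_symmetric_truth(self):
        cfg = SimConfig(n_snps=800, f=0.10, mean_depth=200, seed=12,
                        fetal_pat_hap=1, fetal_mat_hap=1,
                        crossovers_pat=(), crossovers_mat=())
        _, inference = _decode_family(cfg)
        assert inference.paternal_call == "P1"
        assert inference.maternal_call == "M1"

    def test_crossover_between_edge_and_gene_calls_state_at_gene(self):
        # one forced paternal crossover at 25% of the window: the majority of
        # the chain carries Hap 0 but the gene locus (centre) carries Hap 1
        cfg = SimConfig(n_snps=1607, f=0.15, mean_depth=300, seed=13,
                        fetal_pat_hap=0, fetal_mat_hap=0,
                        crossovers_pat=(500_000,), crossovers_mat=())
        family, inference = _decode_family(cfg)
        assert family.truth_pat_hap == 1
        assert inference.paternal_call == "P1"
        assert inference.paternal.n_recombinations == 1

    def test_decoded_switch_count_matches_simulated_crossovers(self):
        cfg = SimConfig(n_snps=1607, f=0.15, mean_depth=300, seed=14,
                        fetal_pat_hap=0, fetal_mat_hap=1,
                        crossovers_pat=(700_000, 1_400_000), crossovers_mat=(1_000_000,))
        _, inference = _decode_family(cfg)
        assert inference.paternal.n_recombinations == 2
        assert inference.maternal.n_recombinations == 1

    def test_low_fetal_fraction_refuses_maternal_call(self):
        cfg = SimConfig(n_snps=400, f=0.005, mean_depth=200, seed=15,
                        fetal_pat_hap=0, fetal_mat_hap=0,
                        crossovers_pat=(), crossovers_mat=())
        _, inference = _decode_family(cfg)
        assert inference.maternal_refused
        assert inference.maternal_call is None
        assert inference.maternal is not None  # chain still decoded for diagnostics

    def test_signal_strength_increases_with_fetal_fraction(self):
        """Mean per-site |emission evidence| on the paternal chain grows with f."""
        means = []
        for f in (0.02, 0.05, 0.10):
            per_site = []
            for seed in range(3):
                cfg = SimConfig(n_snps=600, f=f, mean_depth=200, seed=100 + seed,
                                fetal_pat_hap=0, fetal_mat_hap=0,
                                crossovers_pat=(), crossovers_mat=())
                _, inf = _decode_family(cfg)
                track = inf.paternal.emission_log_odds
                per_site.append(abs(track[-1]) / len(track))
            means.append(np.mean(per_site))
        assert means[0] < means[1] < means[2]
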
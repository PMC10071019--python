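import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyp2cphase.em import (
    HaplotypeFrequencyModel,
    PhasingError,
    diplotype_posteriors,
    em_haplotype_frequencies,
    enumerate_diplotypes,
)
from cyp2cphase.genotypes import MISSING
from cyp2cphase.simulate import CohortConfig, generate_cohort

from .oracles import brute_force_configs, maximize_loglik

# haplotypes over the 2-SNP panel, as alt-dosage tuples
TG, TA, CG, CA = (1, 0), (1, 1), (0, 0), (0, 1)


class TestEnumerate:
    def test_double_homozygote_single_config(self):
        assert enumerate_diplotypes([2, 0]) == [(TG, TG)]

    def test_double_heterozygote_two_configs(self):
        configs = enumerate_diplotypes([1, 1])
        assert len(configs) == 2
        assert set(configs) == {(min(TG, CA), max(TG, CA)), (min(TA, CG), max(TA, CG))}

    def test_three_het_loci_give_four_configs(self):
        configs = enumerate_diplotypes([1, 1, 1, 0])
        assert len(configs) == 4
        assert configs == brute_force_configs([1, 1, 1, 0])

    def test_missing_call_rejected(self):
        with pytest.raises(PhasingError, match="missing"):
            enumerate_diplotypes([1, MISSING])

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=6))
    def test_matches_exhaustive_enumeration(self, genotype):
        """2^(h-1) pinned configs equal brute force over all 2^h assignments."""
        configs = enumerate_diplotypes(genotype)
        h = genotype.count(1)
        assert len(configs) == (2 ** (h - 1) if h else 1)
        assert sorted(configs) == brute_force_configs(genotype)
        for a, b in configs:
            assert tuple(x + y for x, y in zip(a, b)) == tuple(genotype)


class TestPosteriors:
    def test_unique_config_posterior_one(self):
        post = diplotype_posteriors([2, 0], {TG: 1.0})
        assert post == {(TG, TG): 1.0}

    def test_uniform_frequencies_split_evenly(self):
        post = diplotype_posteriors([1, 1], {TG: 0.25, TA: 0.25, CG: 0.25, CA: 0.25})
        assert all(abs(p - 0.5) < 1e-12 for p in post.values())

    def test_hand_computed_double_het_posterior(self):
        # weights: {TG,CA} = 2*0.5*0.05; {TA,CG} = 2*0.3*0.15
        post = diplotype_posteriors([1, 1], {TG: 0.5, TA: 0.3, CG: 0.15, CA: 0.05})
        expected = (2 * 0.3 * 0.15) / (2 * 0.5 * 0.05 + 2 * 0.3 * 0.15)
        assert post[(min(TA, CG), max(TA, CG))] == pytest.approx(expected)

    def test_incompatible_sample_flagged(self):
        with pytest.raises(PhasingError, match="incompatible"):
            diplotype_posteriors([2, 0], {CG: 1.0})

    @given(
        st.lists(st.integers(0, 2), min_size=2, max_size=4),
        st.integers(0, 2**31 - 1),
    )
    def test_posteriors_normalised(self, genotype, seed):
        rng = np.random.default_rng(seed)
        haps = sorted({h for cfg in brute_force_configs(genotype) for h in cfg})
        freqs = dict(zip(haps, rng.dirichlet(np.ones(len(haps)))))
        post = diplotype_posteriors(genotype, freqs)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)


class TestEMFit:
    def test_monomorphic_cohort_fixed_point(self, panel2, make_matrix_fn):
        m = make_matrix_fn(panel2, [[2, 0]] * 10)
        res = em_haplotype_frequencies(m)
        assert res.freqs[TG] == pytest.approx(1.0)
        assert res.converged
        assert np.allclose(res.loglik_trace, res.loglik_trace[0])

    def test_toy_cohort_matches_likelihood_maximizer(self, toy_matrix):
        """EM on {(T/T,G/G),(C/T,G/G),(C/T,G/A)} finds the global MLE
        (TG=2/3, CG=CA=1/6, TA=0), independently verified by direct
        simplex maximization of the brute-force likelihood."""
        res = HaplotypeFrequencyModel(toy_matrix).fit()
        assert res.freqs[TG] == pytest.approx(2 / 3, abs=1e-3)
        assert res.freqs[CG] == pytest.approx(1 / 6, abs=1e-3)
        assert res.freqs[CA] == pytest.approx(1 / 6, abs=1e-3)
        assert res.freqs[TA] == pytest.approx(0.0, abs=1e-3)
        assert res.loglik == pytest.approx(-3.8190850098, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_em_attains_oracle_loglik_small_instances(self, seed, panel2, panel4,
                                                      make_matrix_fn):
        """On <=3-SNP, <=8-sample instances EM reaches the independently
        maximized likelihood within 1e-6."""
        rng = np.random.default_rng(seed)
        panel = panel4.subset(["rs2860840", "rs11188059", "rs4244285"]) \
            if seed % 2 else panel2
        n = int(rng.integers(2, 9))
        dosages = rng.integers(0, 3, size=(n, len(panel)))
        m = make_matrix_fn(panel, dosages)
        model = HaplotypeFrequencyModel(m)
        res = model.fit(n_restarts=5, seed=seed)
        oracle_ll, _ = maximize_loglik(
            [tuple(row) for row in dosages], model.haplotypes, n_restarts=30, seed=seed
        )
        assert res.loglik >= oracle_ll - 1e-6

    def test_loglik_trace_monotone(self, panel2, make_matrix_fn):
        rng = np.random.default_rng(42)
        for _ in range(10):
            dosages = rng.integers(0, 3, size=(rng.integers(2, 20), 2))
            res = em_haplotype_frequencies(make_matrix_fn(panel2, dosages))
            assert np.all(np.diff(res.loglik_trace) >= -1e-10)

    def test_frequencies_on_simplex(self, toy_matrix):
        res = HaplotypeFrequencyModel(toy_matrix).fit()
        assert res.freq_array.min() >= 0
        assert res.freq_array.sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_samples_excluded_and_counted(self, panel2, make_matrix_fn):
        m = make_matrix_fn(panel2, [[2, 0], [MISSING, 0], [1, 0]])
        res = em_haplotype_frequencies(m)
        assert res.n_samples_used == 2
        assert res.n_excluded_missing == 1

    def test_all_samples_missing_is_error(self, panel2, make_matrix_fn):
        m = make_matrix_fn(panel2, [[MISSING, 0], [0, MISSING]])
        with pytest.raises(PhasingError, match="no samples"):
            HaplotypeFrequencyModel(m)

    def test_consistency_rmse_shrinks_with_n(self):
        """Estimated frequencies converge to generating truth as n grows."""
        freqs = {"TG": 0.49, "TA": 0.47, "CG": 0.04}
        truth_tg = 0.49

        def rmse(n, n_rep, seed0):
            errs = []
            for r in range(n_rep):
                cfg = CohortConfig("c", n, dict(freqs))
                cohort = generate_cohort(cfg, seed=seed0 + r)
                res = em_haplotype_frequencies(cohort.matrix)
                errs.append(res.freqs.get(TG, 0.0) - truth_tg)
            return float(np.sqrt(np.mean(np.square(errs))))

        assert rmse(500, 100, 1000) < rmse(50, 100, 2000)


class TestDiplotypeCalls:
    def test_certain_call_included(self, panel2, make_matrix_fn):
        res = em_haplotype_frequencies(make_matrix_fn(panel2, [[2, 0]] * 5))
        calls = res.call_diplotypes()
        assert all(c.posterior == pytest.approx(1.0) and c.included for c in calls)

    def test_fifty_fifty_double_het_excluded(self, panel2, make_matrix_fn):
        # symmetric cohort: both phasings equally likely for the double het
        m = make_matrix_fn(panel2, [[1, 1]] * 4)
        res = em_haplotype_frequencies(m)
        call = res.call_diplotypes()[0]
        assert call.posterior == pytest.approx(0.5, abs=1e-6)
        assert not call.included
        assert call.ambiguous

    def test_threshold_boundary_inclusive(self, panel2, make_matrix_fn):
        m = make_matrix_fn(panel2, [[2, 0], [1, 0], [1, 1], [0, 0]])
        res = em_haplotype_frequencies(m)
        for c in res.call_diplotypes(threshold=1.0):
            if c.posterior == 1.0:
                assert c.included
        # setting the threshold to an achieved posterior keeps that sample in
        calls = res.call_diplotypes()
        for c in calls:
            again = [
                x for x in res.call_diplotypes(threshold=c.posterior)
                if x.sample_id == c.sample_id
            ][0]
            assert again.included

    def test_at_most_one_het_always_posterior_one(self, panel4, make_matrix_fn):
        rng = np.random.default_rng(3)
        dosages = []
        for _ in range(20):
            row = (2 * rng.integers(0, 2, size=4)).tolist()
            if rng.random() < 0.7:
                row[rng.integers(0, 4)] = 1
            dosages.append(row)
        res = em_haplotype_frequencies(make_matrix_fn(panel4, dosages))
        for c in res.call_diplotypes():
            n_het = int((res.model.matrix.dosages[
                res.model.matrix.sample_ids.index(c.sample_id)] == 1).sum())
            if n_het <= 1:
                assert c.posterior == pytest.approx(1.0)

    def test_tie_break_is_lexicographic(self, panel2, make_matrix_fn):
        m = make_matrix_fn(panel2, [[1, 1]] * 4)
        res = em_haplotype_frequencies(m)
        call = res.call_diplotypes()[0]
        labels = sorted([
            (res.model.panel.hap_str(call.hap_a), res.model.panel.hap_str(call.hap_b))
        ])
        # lexicographically first of {CA,TG} and {CG,TA} is (CA, TG)
        assert labels[0] == ("CA", "TG")

    def test_restricted_refit_uses_included_subset(self, panel2, make_matrix_fn):
        # all four homozygote classes present, so the double het stays at
        # posterior 0.5 and drops out of the restricted refit
        m = make_matrix_fn(panel2, [[2, 0], [0, 2], [2, 2], [0, 0], [1, 1]])
        res = em_haplotype_frequencies(m, restrict_to_included=True)
        assert res.n_samples_used == 4
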
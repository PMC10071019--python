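import numpy as np
import pytest

from cyp2cphase.em import em_haplotype_frequencies
from cyp2cphase.genotypes import MISSING
from cyp2cphase.simulate import (
    CohortConfig,
    CohortConfigError,
    cohort_presets,
    generate_cohort,
    get_preset,
)

TG = (1, 0)


class TestGeneration:
    def test_single_haplotype_cohort(self):
        cohort = generate_cohort(CohortConfig("c", 20, {"TG": 1.0}), seed=1)
        assert np.array_equal(
            cohort.matrix.dosages, np.tile([2, 0], (20, 1))
        )
        assert all(pair == (TG, TG) for pair in cohort.truth_diplotypes)

    def test_truth_unphases_to_matrix(self):
        cfg = CohortConfig("c", 200, {"TG": 0.5, "TA": 0.3, "CG": 0.2})
        cohort = generate_cohort(cfg, seed=3)
        for i, (a, b) in enumerate(cohort.truth_diplotypes):
            assert tuple(cohort.matrix.dosages[i]) == tuple(
                x + y for x, y in zip(a, b)
            )

    def test_empirical_frequencies_within_binomial_bound(self):
        freqs = {"TG": 0.5, "TA": 0.3, "CG": 0.2}
        cohort = generate_cohort(CohortConfig("c", 1000, freqs), seed=11)
        counts = cohort.truth_hap_counts()
        panel = cohort.matrix.panel
        for label, f in freqs.items():
            hap = [h for h in counts if panel.hap_str(h) == label]
            emp = counts[hap[0]] / 2000
            bound = 3 * np.sqrt(f * (1 - f) / 2000)
            assert abs(emp - f) < bound

    def test_fixed_seed_reproducible(self):
        cfg = CohortConfig("c", 50, {"TG": 0.6, "CG": 0.4}, missing_rate=0.1)
        a = generate_cohort(cfg, seed=42)
        b = generate_cohort(cfg, seed=42)
        assert np.array_equal(a.matrix.dosages, b.matrix.dosages)
        assert a.truth_diplotypes == b.truth_diplotypes

    def test_missingness_rate_applied(self):
        cfg = CohortConfig("c", 500, {"TG": 0.6, "CG": 0.4}, missing_rate=0.2)
        cohort = generate_cohort(cfg, seed=5)
        frac = (cohort.matrix.dosages == MISSING).mean()
        assert 0.15 < frac < 0.25

    def test_unnormalised_frequencies_require_flag(self):
        cfg = CohortConfig("c", 10, {"TG": 0.5, "CG": 0.3})
        with pytest.raises(CohortConfigError, match="sum to"):
            generate_cohort(cfg, seed=0)
        cfg_ok = CohortConfig("c", 10, {"TG": 0.5, "CG": 0.3}, renormalize=True)
        with pytest.warns(UserWarning, match="renormalizing"):
            generate_cohort(cfg_ok, seed=0)

    def test_bad_configs_rejected(self):
        with pytest.raises(CohortConfigError):
            CohortConfig("c", 0, {"TG": 1.0})
        with pytest.raises(CohortConfigError):
            CohortConfig("c", 5, {"TG": -0.5, "CG": 1.5})
        with pytest.raises(CohortConfigError):
            CohortConfig("c", 5, {})


class TestPresets:
    def test_all_study_cohorts_in_both_modes(self):
        presets = cohort_presets()
        for cohort, n in [("1kg_nat", 68), ("hgdp", 61), ("kaingang", 54)]:
            assert presets[f"{cohort}_table1"].n == n
            assert presets[f"{cohort}_table3"].n == n
        assert presets["guarani_table1"].n == 33

    def test_hgdp_combined_preset_values(self):
        cfg = get_preset("hgdp_table3")
        assert cfg.hap_freqs == {
            "*1CG": 0.238, "*1TA": 0.107, "*1TG": 0.598, "*2CG": 0.057
        }
        assert cfg.normalized

    def test_kaingang_two_snp_preset_values(self):
        cfg = get_preset("kaingang_table1")
        assert cfg.hap_freqs == {"TG": 0.490, "TA": 0.471, "CG": 0.038, "CA": 0.0}
        assert not cfg.normalized and cfg.renormalize  # printed column sums to 0.999

    def test_badly_unnormalised_column_ships_verbatim_and_renormalized(self):
        verbatim = get_preset("guarani_table3_verbatim")
        assert verbatim.freq_sum == pytest.approx(0.839)
        assert not verbatim.renormalize
        with pytest.raises(CohortConfigError):
            generate_cohort(verbatim, seed=0)
        renorm = get_preset("guarani_table3_renormalized")
        assert renorm.normalized

    def test_combined_presets_use_cohort_panels(self):
        assert len(get_preset("hgdp_table3").panel) == 6
        assert len(get_preset("kaingang_table3").panel) == 4
        assert len(get_preset("hgdp_table1").panel) == 2

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError, match="unknown preset"):
            get_preset("nope")


class TestEndToEndRecovery:
    def test_pipeline_recovers_generating_frequencies(self):
        """EM on large synthetic cohorts is nearly unbiased for every
        normalized preset's generating frequencies (|bias| < 0.02 at
        n=500 over replicates)."""
        from dataclasses import replace

        for name in ("hgdp_table1", "hgdp_table3", "1kg_nat_table3"):
            cfg = replace(get_preset(name), n=500)
            panel = cfg.panel
            errs = {label: [] for label in cfg.hap_freqs}
            for rep in range(20):
                cohort = generate_cohort(cfg, seed=5000 + rep)
                res = em_haplotype_frequencies(cohort.matrix)
                freqs = res.frequencies
                from cyp2cphase.simulate import expand_label

                for label, f in cfg.hap_freqs.items():
                    hap_str = panel.hap_str(expand_label(label, panel))
                    errs[label].append(freqs.get(hap_str, 0.0) - f)
            for label, e in errs.items():
                assert abs(np.mean(e)) < 0.02, f"{name}:{label}"

    def test_truth_vs_called_diplotype_agreement(self):
        """Called diplotypes agree with the generating truth for nearly
        all included individuals (the study haplotype sets admit at most
        one ambiguous double-het configuration)."""
        cfg = get_preset("1kg_nat_table3")
        agree = total = 0
        for rep in range(20):
            cohort = generate_cohort(cfg, seed=7000 + rep)
            res = em_haplotype_frequencies(cohort.matrix)
            truth = dict(zip(cohort.matrix.sample_ids, cohort.truth_diplotypes))
            for call in res.call_diplotypes():
                if call.included:
                    total += 1
                    if (call.hap_a, call.hap_b) == truth[call.sample_id]:
                        agree += 1
        assert agree / total >= 0.99
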
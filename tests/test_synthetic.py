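"""Synthetic generator: determinism, null calibration, shift recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq

from prspipe import scoring
from prspipe.synthetic import (
    FREQ_EPS,
    SimulationConfig,
    SimulationError,
    calibrate_frequency_shift,
    simulate_cohort_genotypes,
    simulate_followup_phenotypes,
    simulate_score_cohort,
    simulate_study,
    simulate_summary_stats,
)

from conftest import make_sumstats


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_snps=0), dict(causal_fraction=1.5), dict(maf_range=(0.0, 0.3)),
         dict(maf_range=(0.4, 0.2)), dict(maf_range=(0.1, 0.6)),
         dict(missing_rate=1.0), dict(n_cases=0)],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            SimulationConfig(**kwargs)

    def test_defaults_match_study_design(self):
        c = SimulationConfig()
        assert (c.n_cases, c.n_controls, c.delta_target) == (22, 307, 0.41)


class TestSummaryStats:
    def test_deterministic_given_seed(self):
        c = SimulationConfig(n_snps=200, seed=5)
        a = simulate_summary_stats(c)
        b = simulate_summary_stats(c)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_null_gwas_p_values_uniform(self):
        """With no causal variants, reported P ~ Uniform(0,1): KS at
        alpha=0.01 passes over five seeds."""
        c = SimulationConfig(n_snps=1000, causal_fraction=0.0)
        for seed in range(5):
            ss = simulate_summary_stats(c, seed=seed)
            _, p = stats.kstest(ss.table["p_value"], "uniform")
            assert p > 0.01

    def test_reported_effects_converge_with_gwas_size(self):
        """Estimation noise shrinks as 1/sqrt(n_gwas): the deviation from
        the true effect at n_gwas=1e8 is ~100x smaller than at 1e4."""
        devs = {}
        for n_gwas in (10_000, 100_000_000):
            c = SimulationConfig(n_snps=500, causal_fraction=1.0, n_gwas=n_gwas, seed=3)
            ss = simulate_summary_stats(c)
            # near-noiseless reference run isolates the estimation error
            ss2 = simulate_summary_stats(
                SimulationConfig(n_snps=500, causal_fraction=1.0,
                                 n_gwas=10**12, seed=3)
            )
            devs[n_gwas] = np.abs(ss.table["weight"] - ss2.table["weight"]).max()
        ratio = devs[10_000] / devs[100_000_000]
        assert 30 < ratio < 300  # sqrt(1e4) = 100, Monte-Carlo slack

    def test_unique_ids_and_maf_range(self):
        c = SimulationConfig(n_snps=300, maf_range=(0.1, 0.3), seed=1)
        ss = simulate_summary_stats(c)
        assert ss.table["id"].is_unique
        f = ss.table["effect_allele_freq"]
        assert f.between(0.1, 0.3).all()
        assert ((ss.table["p_value"] > 0) & (ss.table["p_value"] <= 1)).all()


class TestCalibrateFrequencyShift:
    def test_zero_target_gives_zero_lambda(self):
        ss = make_sumstats(["a", "b"], ["G", "G"], ["A", "A"], [0.2, -0.1],
                           p=[0.01, 0.02], freq=[0.3, 0.4])
        shift = calibrate_frequency_shift(ss, 0.5, 0.0)
        assert shift.lambda_ == 0.0
        np.testing.assert_allclose(
            shift.case_freq.to_numpy(), ss.table["effect_allele_freq"]
        )

    @pytest.mark.parametrize("d", [0.2, 0.41, 0.7, -0.3])
    def test_single_variant_closed_form_matches_root_finder(self, d):
        """One variant, w=1, f=0.5: lambda from the closed form equals the
        numerically root-found solution of the defining equation."""
        ss = make_sumstats(["a"], ["G"], ["A"], [1.0], p=[0.01], freq=[0.5])
        shift = calibrate_frequency_shift(ss, 0.5, d)
        w, f = 1.0, 0.5

        def gap(lam):
            f_case = f + lam * w * f * (1 - f)
            return w * 2 * (f_case - f) - d * np.sqrt(w**2 * 2 * f * (1 - f))

        lam_numeric = brentq(gap, -100, 100)
        assert shift.lambda_ == pytest.approx(lam_numeric, rel=1e-10)
        assert shift.lambda_ == pytest.approx(d / np.sqrt(0.5), rel=1e-12)

    def test_all_zero_weights_unsolvable(self):
        ss = make_sumstats(["a"], ["G"], ["A"], [0.0], p=[0.01], freq=[0.5])
        with pytest.raises(SimulationError, match="zero"):
            calibrate_frequency_shift(ss, 0.5, 0.41)

    def test_nothing_past_threshold_rejected(self):
        ss = make_sumstats(["a"], ["G"], ["A"], [0.5], p=[0.9], freq=[0.5])
        with pytest.raises(SimulationError, match="threshold"):
            calibrate_frequency_shift(ss, 0.001, 0.41)

    def test_clipping_counted_and_bounds_respected(self):
        ss = make_sumstats(["a"], ["G"], ["A"], [5.0], p=[0.01], freq=[0.49])
        shift = calibrate_frequency_shift(ss, 0.5, 5.0)
        assert shift.n_clipped == 1
        assert shift.case_freq.max() <= 1 - FREQ_EPS

    @pytest.mark.parametrize("delta_target", [0.2, 0.41, 0.58])
    def test_monte_carlo_recovery_of_target_delta(self, delta_target):
        """Observed standardized case/reference score gap over >=500
        genotype replicates lands within +/-0.05 of the target."""
        config = SimulationConfig(n_snps=500, missing_rate=0.0,
                                  delta_target=delta_target, seed=17)
        ss = simulate_summary_stats(config)
        threshold = 0.1
        shift = calibrate_frequency_shift(ss, threshold, delta_target)
        included = ss.table["p_value"] < threshold
        w = ss.table.loc[included, "weight"].to_numpy()
        f_ctrl = ss.table.loc[included, "effect_allele_freq"].to_numpy()
        f_case = shift.case_freq.loc[ss.table.loc[included, "id"]].to_numpy()
        rng = np.random.default_rng(1234)
        n_case, n_ctrl = config.n_cases, config.n_controls
        deltas = np.empty(500)
        for r in range(500):
            g_case = rng.binomial(2, f_case, size=(n_case, f_case.size))
            g_ctrl = rng.binomial(2, f_ctrl, size=(n_ctrl, f_ctrl.size))
            raw = np.concatenate([g_case @ w, g_ctrl @ w])
            z = (raw - raw.mean()) / raw.std(ddof=1)
            deltas[r] = z[:n_case].mean() - z[n_case:].mean()
        assert deltas.mean() == pytest.approx(delta_target, abs=0.05)


class TestCohortGenotypes:
    def _setup(self, **kwargs):
        config = SimulationConfig(n_snps=200, seed=21, **kwargs)
        ss = simulate_summary_stats(config)
        shift = calibrate_frequency_shift(ss, 0.5, config.delta_target)
        return config, ss, shift

    def test_no_missing_when_rate_zero(self):
        config, ss, shift = self._setup(missing_rate=0.0)
        matrix, labels = simulate_cohort_genotypes(ss, shift, config)
        assert not np.isnan(matrix.dosage).any()
        from prspipe.qc import compute_sample_call_rates

        assert (compute_sample_call_rates(matrix).table["call_rate"] == 1.0).all()

    def test_label_counts_and_determinism(self):
        config, ss, shift = self._setup()
        m1, l1 = simulate_cohort_genotypes(ss, shift, config)
        m2, l2 = simulate_cohort_genotypes(ss, shift, config)
        assert l1.n_case == 22 and l1.n_control == 307
        np.testing.assert_array_equal(m1.dosage, m2.dosage)
        pd.testing.assert_frame_equal(m1.variants, m2.variants)

    def test_info_scores_span_filter_boundary(self):
        config, ss, shift = self._setup()
        matrix, _ = simulate_cohort_genotypes(ss, shift, config)
        info = matrix.variants["info_score"]
        assert (info > 0.5).all() and (info <= 1.0).all()
        assert (info > 0.9).any() and (info <= 0.9).any()

    def test_null_tilt_case_control_means_differ_only_by_noise(self):
        """lambda=0: per-variant case/control dosage mean t-tests reject at
        ~alpha over 1000 variants."""
        config = SimulationConfig(n_snps=1000, n_cases=150, n_controls=150,
                                  missing_rate=0.0, seed=8)
        ss = simulate_summary_stats(config)
        shift = calibrate_frequency_shift(ss, 0.5, 0.0)
        assert shift.lambda_ == 0.0
        matrix, labels = simulate_cohort_genotypes(ss, shift, config)
        # compare on the effect-allele scale via harmonization
        from prspipe.qc import harmonize

        hz = harmonize(ss, matrix, drop_ambiguous=False)
        case = hz.dosage[labels.is_case.astype(bool)]
        ctrl = hz.dosage[~labels.is_case.astype(bool)]
        _, p = stats.ttest_ind(case, ctrl, axis=0)
        assert (p < 0.001).mean() < 0.01

    def test_binomial_expectation_of_dosage_mean(self):
        """f=0.3 with many controls: mean effect-allele dosage ~ 2f = 0.6."""
        config = SimulationConfig(n_snps=5, n_cases=2, n_controls=10_000,
                                  maf_range=(0.3, 0.3), missing_rate=0.0, seed=4)
        ss = simulate_summary_stats(config)
        shift = calibrate_frequency_shift(ss, 1.0, 0.0)
        matrix, labels = simulate_cohort_genotypes(ss, shift, config)
        from prspipe.qc import harmonize

        hz = harmonize(ss, matrix, drop_ambiguous=False)
        ctrl_mean = hz.dosage[~labels.is_case.astype(bool)].mean()
        assert ctrl_mean == pytest.approx(0.6, abs=0.02)


class TestScoreCohort:
    def test_moments(self):
        scores, labels = simulate_score_cohort(0.41, 5000, 5000, seed=2)
        x = scores.raw_score
        assert x[labels.is_case].mean() == pytest.approx(0.41, abs=0.05)
        assert x[~labels.is_case].mean() == pytest.approx(0.0, abs=0.05)
        assert x.std() == pytest.approx(1.0, abs=0.05)

    def test_boundary_single_case_passes_through(self):
        scores, labels = simulate_score_cohort(0.41, 1, 5, seed=0)
        assert labels.n_case == 1
        from prspipe.association import AssociationError, ttest_case_control

        with pytest.raises(AssociationError):
            ttest_case_control(scores, labels)


class TestFollowupPhenotypes:
    def test_null_effects_recover_base_rates(self):
        scores, _ = simulate_score_cohort(0.0, 2000, 1, seed=6)
        phen = simulate_followup_phenotypes(
            scores,
            symptom_effects={"wheezing": 0.0},
            base_rates={"wheezing": 5 / 19},
            seed=6,
        )
        prev = phen.data["wheezing"].mean()
        # binomial 99.9% interval around 5/19 at n=2001
        se = np.sqrt((5 / 19) * (14 / 19) / 2001)
        assert abs(prev - 5 / 19) < 3.3 * se

    def test_bad_base_rate_rejected(self):
        scores, _ = simulate_score_cohort(0.0, 3, 1, seed=0)
        with pytest.raises(SimulationError):
            simulate_followup_phenotypes(
                scores, symptom_effects={"wheezing": 0.0},
                base_rates={"wheezing": 1.2}, seed=0,
            )

    def test_all_thirteen_canonical_columns_present(self):
        scores, _ = simulate_score_cohort(0.41, 19, 1, seed=9)
        phen = simulate_followup_phenotypes(scores, seed=9)
        assert len(phen.symptoms) == 12
        by_domain = {}
        for s, d in phen.domains.items():
            by_domain.setdefault(d, []).append(s)
        assert len(by_domain["asthma"]) == 5
        assert len(by_domain["allergic rhinitis"]) == 4
        assert len(by_domain["atopic dermatitis"]) == 2
        assert len(by_domain["food allergy"]) == 1


class TestSimulateStudy:
    def test_deterministic_and_writes_all_inputs(self, tmp_path):
        config = SimulationConfig(n_snps=150, seed=13)
        s1 = simulate_study(config, outdir=tmp_path / "a")
        s2 = simulate_study(config, outdir=tmp_path / "b")
        np.testing.assert_array_equal(s1.matrix.dosage, s2.matrix.dosage)
        for trait in s1.sumstats:
            pd.testing.assert_frame_equal(s1.sumstats[trait].table, s2.sumstats[trait].table)
        a = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert "genotypes.vcf" in a and "phenotypes.csv" in a
        assert sum(n.endswith("_sumstats.tsv") for n in a) == 5
        for name in a:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_shared_panel_across_traits(self):
        config = SimulationConfig(n_snps=100, seed=13)
        study = simulate_study(config)
        ids = None
        for ss in study.sumstats.values():
            if ids is None:
                ids = list(ss.table["id"])
            assert list(ss.table["id"]) == ids
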
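import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gazesurprise.pupil import process_epoch_frame
from gazesurprise.simulate import GeneratorConfig, generate_foreperiod_pupil
from gazesurprise.stats import (
    DegenerateFitError,
    HickLaw,
    MixedModelResult,
    fit_anticipatory_zip,
    fit_hick,
    fit_latency_velocity_lmms,
    fit_memory_glmm,
    fit_pupil_lmm,
    lr_test,
    subject_condition_means,
)


class TestHick:
    def test_noiseless_exact_recovery(self):
        rows = [(200.0 + 25.0 * math.log2(c), c)
                for c in (1, 2, 3, 4) for _ in range(34)]
        df = pd.DataFrame(rows, columns=["latency", "condition"])
        fit = fit_hick(df)
        assert fit.slope == pytest.approx(25.0, abs=1e-9)
        assert fit.intercept == pytest.approx(200.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_latencies_give_zero_slope(self):
        df = pd.DataFrame({"latency": [220.0] * 8,
                           "condition": [1, 2, 3, 4] * 2})
        fit = fit_hick(df)
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            HickLaw([200.0, 210.0], [2, 2])
        with pytest.raises(ValueError):
            HickLaw([200.0, 210.0], [2, 5])

    def test_f_test_against_scipy(self):
        rng = np.random.default_rng(0)
        c = np.tile([1, 2, 3, 4], 34)
        y = 210.0 + 12.0 * np.log2(c) + rng.normal(0, 20, len(c))
        fit = HickLaw(y, c).fit()
        lin = sps.linregress(np.log2(c), y)
        assert fit.slope == pytest.approx(lin.slope)
        assert fit.f_pvalue == pytest.approx(lin.pvalue, rel=1e-6)
        assert fit.df_resid == len(c) - 2


class TestLrTest:
    def _mk(self, ll, k, n=100):
        return MixedModelResult(model_id="x", fixed_effects=[], sigma2=1.0,
                                tau00=0.0, loglike=ll, n_params=k, n_obs=n)

    def test_identical_models(self):
        chi2, df, p = lr_test(self._mk(-50.0, 3), self._mk(-50.0, 3))
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_chi2_and_p(self):
        chi2, df, p = lr_test(self._mk(-44.0, 6), self._mk(-50.0, 3))
        assert chi2 == pytest.approx(12.0)
        assert df == 3
        assert p == pytest.approx(sps.chi2.sf(12.0, 3))

    def test_negative_statistic_clipped(self):
        with pytest.warns(UserWarning):
            chi2, _, p = lr_test(self._mk(-50.1, 6), self._mk(-50.0, 3))
        assert chi2 == 0.0 and p == 1.0

    def test_mismatched_models_rejected(self):
        with pytest.raises(ValueError):
            lr_test(self._mk(-50.0, 3, n=100), self._mk(-50.0, 2, n=90))
        with pytest.raises(ValueError):
            lr_test(self._mk(-50.0, 2), self._mk(-50.0, 3))


def _pupil_frame(rng, n_subj=34, n_per=20, effects=(0.24, 0.08, 0.09, 0.05),
                 subj_sd=0.1, noise_sd=0.4):
    rows = []
    for s in range(n_subj):
        b = rng.normal(0, subj_sd)
        for c in (1, 2, 3, 4):
            vals = effects[c - 1] + b + rng.normal(0, noise_sd, n_per)
            rows += [(f"s{s:02d}", c, v) for v in vals]
    return pd.DataFrame(rows, columns=["subject", "condition",
                                       "window_mean_mm"])


class TestPupilLmm:
    def test_contrast_recovery(self):
        rng = np.random.default_rng(1)
        df = _pupil_frame(rng)
        a0, a1, (chi2, df_lr, p) = fit_pupil_lmm(df)
        assert df_lr == 3
        fe = a1.effect("SU1 - SU4")
        assert abs(fe.beta - (0.24 - 0.05)) < 2 * fe.se
        assert a1.loglike >= a0.loglike

    def test_null_effect_rarely_significant(self):
        rng = np.random.default_rng(2)
        n_sig = 0
        n_sim = 60
        for _ in range(n_sim):
            df = _pupil_frame(rng, n_subj=8, n_per=6,
                              effects=(0.1, 0.1, 0.1, 0.1))
            _, _, (_, _, p) = fit_pupil_lmm(df)
            n_sig += p < 0.05
        # 3 binomial SDs above the nominal 5%
        assert n_sig / n_sim <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sim)

    def test_tau00_recovered_from_generated_epochs(self):
        # 80 subjects keep the variance-component sampling error ~16%
        cfg = GeneratorConfig(seed=21, n_subjects=80, trials_per_condition=10)
        epochs = generate_foreperiod_pupil(cfg)
        _, wins = process_epoch_frame(epochs)
        _, a1, _ = fit_pupil_lmm(wins)
        tau_true = cfg.pupil_subject_effect_sd ** 2
        assert abs(a1.tau00 - tau_true) <= 0.30 * tau_true + 0.002

    def test_single_subject_rejected(self):
        df = _pupil_frame(np.random.default_rng(3), n_subj=1)
        with pytest.raises(ValueError):
            fit_pupil_lmm(df)


class TestLatencyVelocityLmms:
    def _trials(self, rng, lat=(215.8, 233.5, 244.8, 247.8),
                vel=(402.8, 385.6, 384.5, 382.2), n_subj=24, n_per=20):
        rows = []
        for s in range(n_subj):
            bl = rng.normal(0, 40.0)
            bv = rng.normal(0, 64.0)
            for c in (1, 2, 3, 4):
                for _ in range(n_per):
                    rows.append((f"s{s:02d}", c, True,
                                 lat[c - 1] + bl + rng.normal(0, 54.0),
                                 vel[c - 1] + bv + rng.normal(0, 67.0)))
        return pd.DataFrame(rows, columns=["subject", "condition", "kept",
                                           "vg_latency", "vg_peak_velocity"])

    def test_contrast_signs_and_extra_contrasts(self):
        rng = np.random.default_rng(4)
        out = fit_latency_velocity_lmms(self._trials(rng))
        c1, d1 = out["C1"], out["D1"]
        for k in (2, 3, 4):
            assert c1.effect(f"SU1 - SU{k}").beta < 0   # SU1 fastest
            assert d1.effect(f"SU1 - SU{k}").beta > 0   # SU1 most vigorous
        assert c1.effect("SU2 - SU3").beta < 0
        names = [fe.name for fe in c1.fixed_effects]
        assert "SU3 - SU4" in names
        assert out["C_lr"][1] == 3 and out["C_lr"][2] < 0.01

    def test_null_lr_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(80):
            tr = self._trials(rng, lat=(230.0,) * 4, vel=(390.0,) * 4,
                              n_subj=8, n_per=5)
            out = fit_latency_velocity_lmms(tr)
            pvals.append(out["C_lr"][2])
        d, p = sps.kstest(pvals, "uniform")
        assert p > 0.01


class TestAnticipatoryZip:
    def _counts(self, rng, lams=(5.5, 1.4, 1.0, 0.95), n_subj=34,
                zi_prob=0.0, subj_sd=0.5):
        rows = []
        for s in range(n_subj):
            b = rng.normal(0, subj_sd)
            for c in (1, 2, 3, 4):
                if rng.random() < zi_prob:
                    y = 0
                else:
                    y = rng.poisson(lams[c - 1] * math.exp(b))
                rows.append((f"s{s:02d}", c, y))
        return pd.DataFrame(rows, columns=["subject", "condition", "count"])

    def test_irr_recovery(self):
        rng = np.random.default_rng(6)
        counts = self._counts(rng, lams=(8.0, 2.0, 2.0, 2.0))
        b0, b1, (chi2, df, p) = fit_anticipatory_zip(counts)
        fe = b1.effect("SU1 - SU2")
        assert abs(fe.beta - math.log(4.0)) < 2 * fe.se
        assert fe.irr == pytest.approx(math.exp(fe.beta))
        assert df == 3 and p < 0.001

    def test_no_zero_inflation_pushes_zi_intercept_down(self):
        rng = np.random.default_rng(7)
        counts = self._counts(rng, lams=(8.0, 4.0, 4.0, 4.0))
        _, b1, _ = fit_anticipatory_zip(counts)
        assert b1.zi_intercept.beta < -2.0

    def test_true_zero_inflation_detected(self):
        rng = np.random.default_rng(8)
        counts = self._counts(rng, lams=(8.0, 6.0, 6.0, 6.0), zi_prob=0.4)
        _, b1, _ = fit_anticipatory_zip(counts)
        # logit(0.4) = -0.405
        assert -1.5 < b1.zi_intercept.beta < 0.5

    def test_all_zero_counts_degenerate(self):
        counts = pd.DataFrame({"subject": ["a", "a", "b", "b"],
                               "condition": [1, 2, 1, 2],
                               "count": [0, 0, 0, 0]})
        with pytest.raises(DegenerateFitError):
            fit_anticipatory_zip(counts)

    def test_permuted_labels_destroy_the_effect(self):
        # within-subject label shuffles null the condition effect: the
        # log-IRR estimates collapse around 0 instead of log(4)
        rng = np.random.default_rng(9)
        betas = []
        n_sim = 25
        for _ in range(n_sim):
            counts = self._counts(rng, lams=(8.0, 2.0, 2.0, 2.0), n_subj=20)
            perm = counts.copy()
            perm["condition"] = (perm.groupby("subject")["condition"]
                                 .transform(rng.permutation).to_numpy())
            _, b1, _ = fit_anticipatory_zip(perm)
            betas.append(b1.effect("SU1 - SU2").beta)
        betas = np.asarray(betas)
        assert abs(betas.mean()) < 3 * betas.std(ddof=1) / math.sqrt(n_sim)
        assert np.median(np.abs(betas)) < 0.5 * math.log(4.0)

    def test_null_counts_give_nominal_ci_coverage(self):
        # on genuinely exchangeable (no-effect) data the Wald CI of the
        # log IRR covers 0 at roughly the nominal rate
        rng = np.random.default_rng(13)
        covered = 0
        n_sim = 40
        for _ in range(n_sim):
            counts = self._counts(rng, lams=(3.0, 3.0, 3.0, 3.0), n_subj=20)
            _, b1, _ = fit_anticipatory_zip(counts)
            fe = b1.effect("SU1 - SU2")
            covered += fe.ci_low <= 0.0 <= fe.ci_high
        assert covered / n_sim >= 0.85


class TestMemoryGlmm:
    def _memory(self, rng, acc=0.976, or_per_item=1.0, n_subj=34, n_per=5):
        base = math.log(acc / (1 - acc))
        rows = []
        for s in range(n_subj):
            b = rng.normal(0, 1.0)
            for mi in (1, 2, 3, 4):
                logit = base + math.log(or_per_item) * mi + b
                p = 1.0 / (1.0 + math.exp(-logit))
                for _ in range(n_per):
                    rows.append((f"s{s:02d}", mi, int(rng.random() < p)))
        return pd.DataFrame(rows, columns=["subject", "mi", "correct"])

    def test_flat_accuracy_gives_null_mi_effect(self):
        rng = np.random.default_rng(10)
        e0, e1, (chi2, df, p) = fit_memory_glmm(self._memory(rng))
        fe = e1.effect("MI")
        assert fe.ci_low <= 0.0 <= fe.ci_high
        assert df == 1

    def test_strong_mi_effect_detected(self):
        rng = np.random.default_rng(11)
        mem = self._memory(rng, acc=0.976, or_per_item=0.3)
        _, e1, (chi2, df, p) = fit_memory_glmm(mem)
        assert e1.effect("MI").beta < 0
        assert p < 0.01

    def test_all_correct_raises_separation_flag(self):
        mem = self._memory(np.random.default_rng(12))
        mem["correct"] = 1
        _, e1, _ = fit_memory_glmm(mem)
        assert "separation" in e1.flags


def test_subject_condition_means_only_uses_kept_trials():
    df = pd.DataFrame({
        "subject": ["a"] * 4, "condition": [1, 1, 2, 2],
        "kept": [True, False, True, True],
        "vg_latency": [200.0, 999.0, 240.0, 260.0]})
    out = subject_condition_means(df)
    assert out.loc[out["condition"] == 1, "latency"].item() == 200.0
    assert out.loc[out["condition"] == 2, "latency"].item() == 250.0
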
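"""Hick's-law regression, mixed models and likelihood-ratio comparison.

The hypothesis-driven models mirror the study's stages:

* A0/A1 -- Gaussian LMM of baseline-corrected foreperiod pupil window
  means on surprise condition (subject random intercept);
* B0/B1 -- zero-inflated Poisson GLMM of per-subject anticipatory
  saccade counts (random intercept in the count part, intercept-only
  zero inflation);
* C0/C1, D0/D1 -- Gaussian LMMs of trial-level visually-guided latency
  and peak velocity;
* E0/E1 -- binomial GLMM of memory-task accuracy on memory load;
* HL -- ordinary least squares of latency on log2(number of choices).

Surprise enters the LMMs as a 4-level factor with SU1 as reference;
contrasts are reported as SU1 minus the other condition, matching the
convention of the reported tables.  Gaussian models are fitted by
maximum likelihood with statsmodels MixedLM; the ZIP and binomial
random-intercept models use an adaptive Gauss-Hermite marginal
likelihood written here (no ML mixed-model machinery for those
families exists in the scientific Python stack).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1


class DegenerateFitError(ValueError):
    """Raised when a model cannot be identified from the data
    (e.g. all-zero counts in the ZIP model)."""


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class FixedEffect:
    name: str
    beta: float
    se: float
    stat: float
    p: float
    ci_low: float
    ci_high: float
    irr: float | None = None     # exponentiated contrast, count models
    irr_se: float | None = None


@dataclass
class MixedModelResult:
    """A fitted mixed model: fixed effects, variance components, LL."""

    model_id: str
    fixed_effects: list[FixedEffect]
    sigma2: float
    tau00: float
    loglike: float
    n_params: int
    n_obs: int
    family: str = "gaussian"
    zi_intercept: FixedEffect | None = None
    flags: list[str] = field(default_factory=list)

    def effect(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(name)

    def summary(self) -> str:
        lines = [f"Model {self.model_id} ({self.family}), "
                 f"n = {self.n_obs}, LL = {self.loglike:.1f}, "
                 f"sigma2 = {self.sigma2:.3g}, tau00 = {self.tau00:.3g}"]
        for fe in self.fixed_effects:
            irr = f", IRR = {fe.irr:.2f}" if fe.irr is not None else ""
            lines.append(
                f"  {fe.name}: beta = {fe.beta:.3f} (SE {fe.se:.3f}), "
                f"stat = {fe.stat:.2f}, p = {fe.p:.4g}, "
                f"95% CI [{fe.ci_low:.3f}, {fe.ci_high:.3f}]{irr}")
        if self.zi_intercept is not None:
            z = self.zi_intercept
            lines.append(f"  ZI intercept: {z.beta:.3f} (SE {z.se:.3f})")
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "family": self.family,
            "loglike": self.loglike,
            "sigma2": self.sigma2,
            "tau00": self.tau00,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "fixed_effects": [vars(fe) for fe in self.fixed_effects],
            "flags": list(self.flags),
        }
        if self.zi_intercept is not None:
            d["zi_intercept"] = vars(self.zi_intercept)
        return d


def lr_test(full: MixedModelResult, null: MixedModelResult
            ) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested models: chi2, df, p.

    ``chi2 = 2 (LL_full - LL_null)``; negative values from optimizer
    noise are clipped at 0 with a warning.  Models must be fitted on
    the same observations with the full model strictly larger (or
    identical, in which case chi2 = 0, p = 1).
    """
    if full.n_obs != null.n_obs:
        raise ValueError("models fitted on different numbers of observations")
    df = full.n_params - null.n_params
    if df < 0:
        raise ValueError("the 'full' model has fewer parameters than the null")
    chi2 = 2.0 * (full.loglike - null.loglike)
    if chi2 < 0:
        if chi2 < -1e-6:
            warnings.warn(f"negative LR statistic ({chi2:.3g}) clipped to 0")
        chi2 = 0.0
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p


# --------------------------------------------------------------------------
# Hick's law
# --------------------------------------------------------------------------

@dataclass
class HickFit:
    """OLS fit of latency on log2(number of choice alternatives)."""

    slope: float          # ms per log2 unit
    intercept: float      # ms
    slope_se: float
    r_squared: float
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n_obs: int

    @property
    def slope_ci(self) -> tuple[float, float]:
        tcrit = stats.t.ppf(0.975, self.df_resid)
        return (self.slope - tcrit * self.slope_se,
                self.slope + tcrit * self.slope_se)

    def predict(self, n_choices: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.log2(np.asarray(n_choices, float))

    def summary(self) -> str:
        lo, hi = self.slope_ci
        return (f"Hick's law: RT = {self.intercept:.1f} "
                f"+ {self.slope:.1f} * log2(C) ms\n"
                f"  slope 95% CI [{lo:.1f}, {hi:.1f}], R^2 = "
                f"{self.r_squared:.3f}, F[{self.df_model},{self.df_resid}] = "
                f"{self.f_stat:.2f}, p = {self.f_pvalue:.4g}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "slope", "intercept", "slope_se", "r_squared", "f_stat",
            "f_pvalue", "df_model", "df_resid", "n_obs")}


class HickLaw:
    """Hick's-law regression model.

    Parameters
    ----------
    latency_ms : array-like
        Latencies (typically subject-by-condition mean latencies).
    n_choices : array-like
        Number of response alternatives per observation, in {1, 2, 3, 4}.
    """

    def __init__(self, latency_ms, n_choices):
        y = np.asarray(latency_ms, float)
        c = np.asarray(n_choices, float)
        if len(y) != len(c) or len(y) < 2:
            raise ValueError("need matching latency/choice arrays, length >= 2")
        if not np.isin(c, (1, 2, 3, 4)).all():
            raise ValueError("n_choices must be in {1, 2, 3, 4}")
        if len(np.unique(c)) < 2:
            raise ValueError("need at least 2 distinct choice counts")
        self.y = y
        self.log2c = np.log2(c)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, latency_col: str = "latency",
                   choices_col: str = "condition") -> "HickLaw":
        return cls(df[latency_col].to_numpy(), df[choices_col].to_numpy())

    def fit(self) -> HickFit:
        X = sm.add_constant(self.log2c)
        res = sm.OLS(self.y, X).fit()
        return HickFit(
            slope=float(res.params[1]), intercept=float(res.params[0]),
            slope_se=float(res.bse[1]), r_squared=float(res.rsquared),
            f_stat=float(res.fvalue), f_pvalue=float(res.f_pvalue),
            df_model=int(res.df_model), df_resid=int(res.df_resid),
            n_obs=int(res.nobs))


def fit_hick(mean_latencies: pd.DataFrame,
             latency_col: str = "latency",
             choices_col: str = "condition") -> HickFit:
    """Hick's-law OLS on subject-by-condition mean latencies."""
    return HickLaw.from_frame(mean_latencies, latency_col, choices_col).fit()


# --------------------------------------------------------------------------
# Gaussian LMMs (statsmodels MixedLM, ML)
# --------------------------------------------------------------------------

def _wald_ci(beta: float, se: float) -> tuple[float, float]:
    return beta - 1.96 * se, beta + 1.96 * se


def _fit_gaussian_lmm(df: pd.DataFrame, response: str, model_prefix: str,
                      extra_contrasts: bool = False
                      ) -> tuple[MixedModelResult, MixedModelResult,
                                 tuple[float, int, float]]:
    """Null (intercept-only) and full (condition factor) LMMs plus LR test.

    ``df`` needs columns ``response``, ``condition`` (1..4) and
    ``subject``.  Contrasts are reported as SU1 minus SUk.  With
    ``extra_contrasts`` the SU2-SU3 and SU3-SU4 comparisons are added.
    """
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects for a mixed model")
    data = df[[response, "condition", "subject"]].dropna().copy()
    data["condition"] = pd.Categorical(data["condition"],
                                       categories=[1, 2, 3, 4])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null = smf.mixedlm(f"{response} ~ 1", data,
                           groups=data["subject"]).fit(reml=False)
        full = smf.mixedlm(f"{response} ~ C(condition, Treatment(1))", data,
                           groups=data["subject"]).fit(reml=False)

    def _result(res, model_id, contrasts):
        fes = [FixedEffect(
            name="Intercept (SU1)" if contrasts else "Intercept",
            beta=float(res.fe_params.iloc[0]),
            se=float(res.bse_fe.iloc[0]),
            stat=float(res.fe_params.iloc[0] / res.bse_fe.iloc[0]),
            p=float(res.pvalues.iloc[0]),
            ci_low=_wald_ci(res.fe_params.iloc[0], res.bse_fe.iloc[0])[0],
            ci_high=_wald_ci(res.fe_params.iloc[0], res.bse_fe.iloc[0])[1])]
        if contrasts:
            names = list(res.fe_params.index)
            for k in (2, 3, 4):
                col = [n for n in names if f"[T.{k}]" in n][0]
                j = names.index(col)
                # model coefficient is SUk - SU1; report SU1 - SUk
                beta = -float(res.fe_params.iloc[j])
                se = float(res.bse_fe.iloc[j])
                fes.append(FixedEffect(
                    name=f"SU1 - SU{k}", beta=beta, se=se, stat=beta / se,
                    p=float(res.pvalues.iloc[j]),
                    ci_low=_wald_ci(beta, se)[0], ci_high=_wald_ci(beta, se)[1]))
            if extra_contrasts:
                cov = res.cov_params()
                for a, b in ((2, 3), (3, 4)):
                    ca = [n for n in names if f"[T.{a}]" in n][0]
                    cb = [n for n in names if f"[T.{b}]" in n][0]
                    # beta_a - beta_b = (SUa - SU1) - (SUb - SU1) = SUa - SUb
                    beta = float(res.fe_params[ca] - res.fe_params[cb])
                    se = float(np.sqrt(cov.loc[ca, ca] + cov.loc[cb, cb]
                                       - 2.0 * cov.loc[ca, cb]))
                    z = beta / se
                    fes.append(FixedEffect(
                        name=f"SU{a} - SU{b}", beta=beta, se=se, stat=z,
                        p=float(2 * stats.norm.sf(abs(z))),
                        ci_low=_wald_ci(beta, se)[0],
                        ci_high=_wald_ci(beta, se)[1]))
        return MixedModelResult(
            model_id=model_id, fixed_effects=fes,
            sigma2=float(res.scale),
            tau00=float(np.asarray(res.cov_re)[0, 0]),
            loglike=float(res.llf),
            n_params=len(res.fe_params) + 2,  # + sigma2 + tau00
            n_obs=int(res.nobs))

    r0 = _result(null, f"{model_prefix}0", contrasts=False)
    r1 = _result(full, f"{model_prefix}1", contrasts=True)
    return r0, r1, lr_test(r1, r0)


def fit_pupil_lmm(window_means: pd.DataFrame,
                  response: str = "window_mean_mm"):
    """Models A0/A1: pupil window means on surprise condition."""
    return _fit_gaussian_lmm(window_means, response, "A")


def fit_latency_velocity_lmms(trials: pd.DataFrame) -> dict:
    """Models C0/C1 (latency) and D0/D1 (peak velocity) on kept trials.

    ``trials`` is the detection module's per-trial table; only kept
    trials contribute.  Latency contrasts additionally include SU2-SU3
    and SU3-SU4.
    """
    kept = trials[trials["kept"]]
    c0, c1, c_lr = _fit_gaussian_lmm(
        kept.rename(columns={"vg_latency": "latency"}), "latency", "C",
        extra_contrasts=True)
    d0, d1, d_lr = _fit_gaussian_lmm(
        kept.rename(columns={"vg_peak_velocity": "velocity"}), "velocity", "D")
    return {"C0": c0, "C1": c1, "C_lr": c_lr,
            "D0": d0, "D1": d1, "D_lr": d_lr}


# --------------------------------------------------------------------------
# Gauss-Hermite random-intercept GLMMs (ZIP and binomial)
# --------------------------------------------------------------------------

_GH_N = 31
_gh_z, _gh_w = np.polynomial.hermite_e.hermegauss(_GH_N)
_gh_logw = np.log(_gh_w / _gh_w.sum())


def _gh_loglik(obs_loglik, subj_codes: np.ndarray, n_subjects: int) -> float:
    """Marginal log-likelihood: integrate the random intercept by GH quadrature.

    ``obs_loglik`` is an (n_obs, n_nodes) matrix of conditional
    per-observation log-likelihoods at each quadrature node.
    """
    per_subj = np.zeros((n_subjects, _GH_N))
    np.add.at(per_subj, subj_codes, obs_loglik)
    return float(special.logsumexp(per_subj + _gh_logw[None, :], axis=1).sum())


def _zip_negll(params: np.ndarray, X: np.ndarray, y: np.ndarray,
               subj_codes: np.ndarray, n_subjects: int) -> float:
    p = X.shape[1]
    beta, gamma0, log_sigma = params[:p], params[p], params[p + 1]
    sigma = math.exp(log_sigma)
    eta = X @ beta
    M = eta[:, None] + sigma * _gh_z[None, :]
    M = np.clip(M, -30.0, 30.0)
    lam = np.exp(M)
    log_pi = -np.logaddexp(0.0, -gamma0)      # log sigmoid(gamma0)
    log_1mpi = -np.logaddexp(0.0, gamma0)
    zero = y == 0
    ll = np.empty_like(M)
    # y = 0: log(pi + (1 - pi) e^{-lambda})
    ll[zero] = np.logaddexp(log_pi, log_1mpi - lam[zero])
    ypos = y[~zero][:, None]
    ll[~zero] = (log_1mpi + ypos * M[~zero] - lam[~zero]
                 - special.gammaln(ypos + 1.0))
    return -_gh_loglik(ll, subj_codes, n_subjects)


def _bernoulli_negll(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                     subj_codes: np.ndarray, n_subjects: int,
                     ridge: float = 0.0) -> float:
    p = X.shape[1]
    beta, log_sigma = params[:p], params[p]
    sigma = math.exp(log_sigma)
    eta = X @ beta
    M = eta[:, None] + sigma * _gh_z[None, :]
    yy = y[:, None]
    ll = -(np.logaddexp(0.0, -M) * yy + np.logaddexp(0.0, M) * (1.0 - yy))
    out = -_gh_loglik(ll, subj_codes, n_subjects)
    if ridge:
        out += ridge * float(beta @ beta)
    return out


def _fit_glmm(negll, x0: np.ndarray, bounds, args) -> tuple[np.ndarray, float, np.ndarray, list[str]]:
    flags: list[str] = []
    res = optimize.minimize(negll, x0, args=args, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-11})
    if not res.success:
        flags.append(f"optimizer: {res.message}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            H = approx_hess1(res.x, negll, args=args)
            cov = np.linalg.pinv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except Exception:
            se = np.full_like(res.x, np.nan)
            flags.append("hessian failed")
    if not np.all(np.isfinite(se)):
        flags.append("non-finite standard errors")
    return res.x, -float(res.fun), se, flags


def fit_anticipatory_zip(counts: pd.DataFrame
                         ) -> tuple[MixedModelResult, MixedModelResult,
                                    tuple[float, int, float]]:
    """Models B0/B1: zero-inflated Poisson GLMM of anticipatory counts.

    ``counts`` has columns subject, condition (1..4), count (anticipatory
    saccades per subject and condition).  The count part has a subject
    random intercept; the excess-zero part is intercept-only.  Reports
    incidence rate ratios of SU1 against each other condition.
    """
    y = counts["count"].to_numpy(float)
    if (y == 0).all():
        raise DegenerateFitError(
            "all counts are zero: the ZIP count part is unidentified "
            "(every observation is absorbed by the zero-inflation intercept)")
    subj_codes, _ = pd.factorize(counts["subject"])
    n_subj = subj_codes.max() + 1
    cond = counts["condition"].to_numpy(int)
    X1 = np.column_stack([np.ones(len(y))]
                         + [(cond == k).astype(float) for k in (2, 3, 4)])
    X0 = X1[:, :1]

    def _run(X, model_id):
        p = X.shape[1]
        mean_pos = max(y[y > 0].mean() if (y > 0).any() else 1.0, 0.5)
        x0 = np.concatenate([[math.log(mean_pos)], np.zeros(p - 1),
                             [-2.0, 0.0]])
        bounds = [(-20, 20)] * p + [(-12.0, 8.0), (-5.0, 3.0)]
        params, ll, se, flags = _fit_glmm(
            _zip_negll, x0, bounds, (X, y, subj_codes, n_subj))
        beta, gamma0, log_sigma = params[:p], params[p], params[p + 1]
        fes = [FixedEffect(name="Intercept (SU1)" if p > 1 else "Intercept",
                           beta=float(beta[0]), se=float(se[0]),
                           stat=float(beta[0] / se[0]) if se[0] else np.nan,
                           p=float(2 * stats.norm.sf(abs(beta[0] / se[0])))
                           if se[0] else np.nan,
                           ci_low=_wald_ci(beta[0], se[0])[0],
                           ci_high=_wald_ci(beta[0], se[0])[1],
                           irr=float(np.exp(beta[0])))]
        for j, k in enumerate((2, 3, 4)):
            if p == 1:
                break
            b, s = float(beta[j + 1]), float(se[j + 1])
            irr = math.exp(-b)          # rate(SU1) / rate(SUk)
            fes.append(FixedEffect(
                name=f"SU1 - SU{k}", beta=-b, se=s,
                stat=-b / s if s else np.nan,
                p=float(2 * stats.norm.sf(abs(b / s))) if s else np.nan,
                ci_low=_wald_ci(-b, s)[0], ci_high=_wald_ci(-b, s)[1],
                irr=irr, irr_se=irr * s))
        zi = FixedEffect(name="ZI intercept", beta=float(gamma0),
                         se=float(se[p]),
                         stat=float(gamma0 / se[p]) if se[p] else np.nan,
                         p=float(2 * stats.norm.sf(abs(gamma0 / se[p])))
                         if se[p] else np.nan,
                         ci_low=_wald_ci(gamma0, se[p])[0],
                         ci_high=_wald_ci(gamma0, se[p])[1])
        return MixedModelResult(
            model_id=model_id, fixed_effects=fes,
            sigma2=float(np.exp(beta[0])),   # Poisson: variance = mean at SU1
            tau00=float(math.exp(log_sigma) ** 2),
            loglike=ll, n_params=p + 2, n_obs=len(y),
            family="zip", zi_intercept=zi, flags=flags)

    r0 = _run(X0, "B0")
    r1 = _run(X1, "B1")
    return r0, r1, lr_test(r1, r0)


def fit_memory_glmm(memory: pd.DataFrame
                    ) -> tuple[MixedModelResult, MixedModelResult,
                               tuple[float, int, float]]:
    """Models E0/E1: binomial GLMM of memory accuracy on memory load.

    ``memory`` has columns subject, mi (1..4) and correct (0/1).  The
    number of memory items enters as a continuous covariate.  Complete
    separation (all responses identical) is flagged and handled with a
    small ridge penalty on the fixed effects.
    """
    y = memory["correct"].to_numpy(float)
    subj_codes, _ = pd.factorize(memory["subject"])
    n_subj = subj_codes.max() + 1
    mi = memory["mi"].to_numpy(float)
    separation = (y == y[0]).all()
    ridge = 1e-2 if separation else 0.0
    X1 = np.column_stack([np.ones(len(y)), mi])
    X0 = X1[:, :1]

    def _run(X, model_id):
        p = X.shape[1]
        pbar = min(max(y.mean(), 1e-3), 1 - 1e-3)
        x0 = np.concatenate([[math.log(pbar / (1 - pbar))], np.zeros(p - 1),
                             [0.0]])
        bounds = [(-15, 15)] * p + [(-5.0, 3.0)]
        params, ll, se, flags = _fit_glmm(
            _bernoulli_negll, x0, bounds, (X, y, subj_codes, n_subj, ridge))
        if separation:
            flags = ["separation"] + flags
        beta, log_sigma = params[:p], params[p]
        names = ["Intercept"] + (["MI"] if p > 1 else [])
        fes = []
        for j, nm in enumerate(names):
            b, s = float(beta[j]), float(se[j])
            fes.append(FixedEffect(
                name=nm, beta=b, se=s, stat=b / s if s else np.nan,
                p=float(2 * stats.norm.sf(abs(b / s))) if s else np.nan,
                ci_low=_wald_ci(b, s)[0], ci_high=_wald_ci(b, s)[1]))
        return MixedModelResult(
            model_id=model_id, fixed_effects=fes,
            sigma2=float(np.pi ** 2 / 3),   # latent logistic residual variance
            tau00=float(math.exp(log_sigma) ** 2),
            loglike=ll, n_params=p + 1, n_obs=len(y),
            family="binomial", flags=flags)

    r0 = _run(X0, "E0")
    r1 = _run(X1, "E1")
    return r0, r1, lr_test(r1, r0)


# --------------------------------------------------------------------------
# summaries used by the pipeline
# --------------------------------------------------------------------------

def subject_condition_means(trials: pd.DataFrame, value: str = "vg_latency"
                            ) -> pd.DataFrame:
    """Per-subject, per-condition means of a kept-trial measure."""
    kept = trials[trials["kept"]]
    out = (kept.groupby(["subject", "condition"], observed=True)[value]
           .mean().reset_index().rename(columns={value: "latency"}))
    return out


def condition_means(trials: pd.DataFrame, value: str = "vg_latency"
                    ) -> dict[int, float]:
    """Condition means of a kept-trial measure (pooled over trials)."""
    kept = trials[trials["kept"]]
    g = kept.groupby("condition", observed=True)[value].mean()
    return {int(k): float(v) for k, v in g.items()}
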
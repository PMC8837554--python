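"""Bayesian four-model classification of risk alleles by migraine subtype.

For each variant we observe paired effect estimates (b_MO, b_MA) for
migraine without aura (MO) and with aura (MA), with standard errors
(se_MO, se_MA). The estimators are correlated (coefficient c, here 0.148)
because the two subtype analyses share controls. Four generating models are
compared:

* NULL - no effect in either subtype;
* MO / MA - a nonzero effect, prior N(0, tau^2), in one subtype only;
* BOTH - a nonzero effect in both subtypes, mixing the fixed-effect model
  (identical effects) and the independent-effects model with equal weights.

Each model's marginal likelihood is the bivariate Gaussian density of the
observed estimates at mean zero with covariance Sigma + P_m, where Sigma is
the sampling covariance and P_m the model's prior effect covariance
(tau = 0.2 on the log-odds scale). Posteriors follow from Bayes' rule under
equal prior model weights; a variant is labelled when one model exceeds 95%
posterior probability and is otherwise "unresolved". The companion
difference test checks effect equality with a normal approximation that
accounts for the estimator correlation, at the Bonferroni level 0.05/123.

All densities are evaluated in log space with log-sum-exp for the BOTH
mixture, since standard errors span orders of magnitude.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

MODELS = ("NULL", "MO", "MA", "BOTH")

#: Bonferroni-corrected level for the effect-equality test over 123 loci.
DIFFERENCE_ALPHA = 0.05 / 123


class DomainError(ValueError):
    """Inputs outside the statistic's domain (se <= 0, \\|c\\| >= 1, ...)."""


class InsufficientDataError(ValueError):
    """Too few qualifying variants for a stable estimate."""


@dataclass
class SubtypePrior:
    """Prior specification of the four-model comparison."""

    tau: float = 0.2
    model_prior: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    both_mixture: tuple[float, float] = (0.5, 0.5)
    corr: float = 0.148

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise DomainError("tau must be > 0")
        if abs(sum(self.model_prior) - 1) > 1e-9 or min(self.model_prior) < 0:
            raise DomainError("model_prior must be a probability vector")
        if abs(sum(self.both_mixture) - 1) > 1e-9 or min(self.both_mixture) < 0:
            raise DomainError("both_mixture must be a probability vector")
        if not -1 < self.corr < 1:
            raise DomainError("corr must be in (-1, 1)")


@dataclass
class SubtypePosterior:
    """Posterior of one variant over the four models plus the equality test."""

    log_ml: dict[str, float]
    posterior: dict[str, float]
    label: str
    diff_z: float
    diff_p: float
    diff_flag: bool


def _log_bvn(b1, b2, v1, v12, v2):
    """Log density of (b1, b2) under N(0, [[v1, v12], [v12, v2]])."""
    det = v1 * v2 - v12 ** 2
    if np.any(det <= 0):
        raise DomainError("model covariance is not positive definite")
    quad = (v2 * b1 ** 2 - 2 * v12 * b1 * b2 + v1 * b2 ** 2) / det
    return -np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * quad


def log_marginal_likelihoods(b_mo, se_mo, b_ma, se_ma,
                             prior: SubtypePrior | None = None) -> dict[str, np.ndarray]:
    """Log marginal likelihood of each model; vectorized over variants."""
    prior = prior or SubtypePrior()
    b1 = np.asarray(b_mo, dtype=float)
    b2 = np.asarray(b_ma, dtype=float)
    s1 = np.asarray(se_mo, dtype=float)
    s2 = np.asarray(se_ma, dtype=float)
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise DomainError("standard errors must be > 0")
    c, t2 = prior.corr, prior.tau ** 2
    v1, v12, v2 = s1 ** 2, c * s1 * s2, s2 ** 2

    out = {
        "NULL": _log_bvn(b1, b2, v1, v12, v2),
        "MO": _log_bvn(b1, b2, v1 + t2, v12, v2),
        "MA": _log_bvn(b1, b2, v1, v12, v2 + t2),
    }
    w_fix, w_ind = prior.both_mixture
    log_fix = _log_bvn(b1, b2, v1 + t2, v12 + t2, v2 + t2)
    log_ind = _log_bvn(b1, b2, v1 + t2, v12, v2 + t2)
    with np.errstate(divide="ignore"):
        out["BOTH"] = logsumexp(
            np.stack([log_fix + np.log(w_fix), log_ind + np.log(w_ind)]), axis=0)
    return out


def posterior_probabilities(log_ml: dict[str, np.ndarray],
                            prior: SubtypePrior | None = None) -> dict[str, np.ndarray]:
    """Posterior model probabilities from log marginal likelihoods."""
    prior = prior or SubtypePrior()
    with np.errstate(divide="ignore"):
        logw = np.stack([log_ml[m] + np.log(prior.model_prior[i])
                         for i, m in enumerate(MODELS)])
    logw -= logsumexp(logw, axis=0)
    post = np.exp(logw)
    post /= post.sum(axis=0)  # exact unit sum at machine precision
    return {m: post[i] for i, m in enumerate(MODELS)}


def difference_test(b_mo, se_mo, b_ma, se_ma, corr: float = 0.148,
                    alpha: float = DIFFERENCE_ALPHA):
    """Normal-approximation test of effect equality between the subtypes.

    ``z = (b_MO - b_MA) / sqrt(se_MO^2 + se_MA^2 - 2 c se_MO se_MA)``;
    two-sided p; flag = p < alpha. Raises :class:`DomainError` when the
    variance of the difference is non-positive (possible only for \\|c\\|
    near 1 with unequal standard errors).
    """
    s1 = np.asarray(se_mo, dtype=float)
    s2 = np.asarray(se_ma, dtype=float)
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise DomainError("standard errors must be > 0")
    var = s1 ** 2 + s2 ** 2 - 2 * corr * s1 * s2
    if np.any(var <= 0):
        raise DomainError("non-positive variance for the effect difference")
    z = (np.asarray(b_mo, dtype=float) - np.asarray(b_ma, dtype=float)) / np.sqrt(var)
    p = 2 * stats.norm.sf(np.abs(z))
    return z, p, p < alpha


def classify_variant(b_mo: float, se_mo: float, b_ma: float, se_ma: float,
                     prior: SubtypePrior | None = None,
                     threshold: float = 0.95,
                     alpha: float = DIFFERENCE_ALPHA) -> SubtypePosterior:
    """Classify a single variant; see the module docstring for the model."""
    prior = prior or SubtypePrior()
    log_ml = log_marginal_likelihoods(b_mo, se_mo, b_ma, se_ma, prior)
    post = posterior_probabilities(log_ml, prior)
    label = max(MODELS, key=lambda m: post[m])
    if post[label] <= threshold:
        label = "unresolved"
    z, p, flag = difference_test(b_mo, se_mo, b_ma, se_ma, prior.corr, alpha)
    return SubtypePosterior(
        log_ml={m: float(log_ml[m]) for m in MODELS},
        posterior={m: float(post[m]) for m in MODELS},
        label=label, diff_z=float(z), diff_p=float(p), diff_flag=bool(flag))


def classify_table(mo: pd.DataFrame, ma: pd.DataFrame,
                   prior: SubtypePrior | None = None,
                   threshold: float = 0.95,
                   alpha: float = DIFFERENCE_ALPHA) -> pd.DataFrame:
    """Classify every shared variant of two subtype tables.

    Tables follow the summary-statistics dialect and are joined on SNP.
    """
    prior = prior or SubtypePrior()
    merged = mo.merge(ma, on="SNP", suffixes=("_MO", "_MA"))
    log_ml = log_marginal_likelihoods(
        merged["BETA_MO"], merged["SE_MO"], merged["BETA_MA"], merged["SE_MA"],
        prior)
    post = posterior_probabilities(log_ml, prior)
    z, p, flag = difference_test(
        merged["BETA_MO"], merged["SE_MO"], merged["BETA_MA"], merged["SE_MA"],
        prior.corr, alpha)
    out = merged[["SNP"]].copy()
    for m in MODELS:
        out[f"LOG_ML_{m}"] = log_ml[m]
    pp = np.stack([post[m] for m in MODELS])
    for i, m in enumerate(MODELS):
        out[f"PP_{m}"] = pp[i]
    arg = pp.argmax(axis=0)
    labels = np.array(MODELS, dtype=object)[arg]
    labels[pp.max(axis=0) <= threshold] = "unresolved"
    out["LABEL"] = labels
    out["DIFF_Z"] = z
    out["DIFF_P"] = p
    out["DIFF_FLAG"] = flag
    return out


def estimate_correlation(stats_mo: pd.DataFrame, stats_ma: pd.DataFrame,
                         maf_min: float = 0.05, p_floor: float = 1e-4,
                         min_variants: int = 100) -> float:
    """Estimator correlation c from common, non-associated variants.

    Empirical Pearson correlation of the effect estimates over variants with
    MAF > *maf_min* and p > *p_floor* in both subtype analyses — variants
    whose estimates are dominated by sampling noise, so their correlation
    reflects the shared-control dependence rather than true effects.
    """
    merged = stats_mo.merge(stats_ma, on="SNP", suffixes=("_MO", "_MA"))
    maf_mo = np.minimum(merged["EAF_MO"], 1 - merged["EAF_MO"])
    maf_ma = np.minimum(merged["EAF_MA"], 1 - merged["EAF_MA"])
    keep = (maf_mo > maf_min) & (maf_ma > maf_min) \
        & (merged["P_MO"] > p_floor) & (merged["P_MA"] > p_floor)
    sub = merged.loc[keep]
    if len(sub) < min_variants:
        raise InsufficientDataError(
            f"only {len(sub)} qualifying variants (< {min_variants})")
    return float(np.corrcoef(sub["BETA_MO"], sub["BETA_MA"])[0, 1])


DirectionTest = namedtuple("DirectionTest", ["p", "n_agree", "n_total"])


def direction_concordance(betas_a, betas_b) -> DirectionTest:
    """Exact two-sided binomial test of effect-direction agreement.

    Pairs with a zero effect on either side carry no direction and are
    dropped. The two-sided p is ``min(1, 2 * min(tail probabilities))`` of
    Binomial(n, 1/2) at the observed agreement count.
    """
    a = np.asarray(betas_a, dtype=float)
    b = np.asarray(betas_b, dtype=float)
    nonzero = (a != 0) & (b != 0)
    a, b = a[nonzero], b[nonzero]
    n = a.size
    if n == 0:
        return DirectionTest(p=float("nan"), n_agree=0, n_total=0)
    k = int((np.sign(a) == np.sign(b)).sum())
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return DirectionTest(p=float(min(1.0, 2 * min(lower, upper))),
                         n_agree=k, n_total=n)
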
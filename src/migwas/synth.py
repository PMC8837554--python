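"""Synthetic multi-cohort GWAS summary statistics with known ground truth.

Emulates the structure that the downstream pipeline assumes about real
consortium data: block-diagonal LD with AR(1) decay inside blocks, a
polygenic spike-and-slab effect model, per-cohort / per-variant variation in
sample size and imputation quality, occasional allele flips on
strand-ambiguous SNPs, and paired subtype (MO = migraine without aura,
MA = migraine with aura) statistics whose estimators are correlated through
shared controls.

The noise model follows the meta-analysis assumptions: each cohort's
log-odds estimate is Gaussian around the LD-induced marginal effect with a
standard error satisfying the effective-sample-size identity
``1/(f(1-f) se^2) = 2 N t (1-t) I`` for case proportion ``t`` and imputation
info ``I``. Estimates of variants in the same LD block are correlated with
the reference correlation r, which makes the conditional-analysis oracle
exact.

All randomness flows through one seeded ``numpy`` generator hierarchy; the
seed in :class:`SimConfig` fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dialect import SUMSTATS_COLUMNS, write_sumstats
from .ld import LDPanel

# Case/control counts of the five study collections pooled in the overall
# meta-analysis, and the subtype analyses' totals.
DEFAULT_COHORT_CASES = (29_209, 53_109, 10_881, 1_084, 7_801)
DEFAULT_COHORT_CONTROLS = (172_931, 230_876, 330_170, 4_857, 32_423)
DEFAULT_MO_COUNTS = (15_055, 682_301)
DEFAULT_MA_COUNTS = (14_624, 703_852)

_BASES = ("A", "C", "G", "T")
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Configuration of the synthetic GWAS generator.

    Parameters
    ----------
    n_variants, n_blocks
        Panel size and number of independent LD blocks (blocks partition the
        variants near-evenly).
    block_decay
        AR(1) correlation decay rho in [0, 1): r between variants i, j of the
        same block is ``rho ** |i - j|``.
    n_cases, n_controls
        Per-cohort counts; defaults follow the five study collections of the
        overall migraine meta-analysis.
    causal_fraction, effect_sd
        Spike-and-slab effect model: each variant is causal with this
        probability, causal log-odds effects are N(0, effect_sd^2).
    maf_range, info_range
        Uniform sampling ranges for the minor-allele frequency and the
        per-cohort/per-variant imputation info.
    subtype_model_probs
        Prior over the generating models (NULL, MO, MA, BOTH) used by
        :func:`simulate_subtype_pairs`.
    subtype_corr
        Correlation c of the MO/MA effect estimators induced by shared
        controls; default 0.148.
    tau
        Prior s.d. of a nonzero subtype log-odds effect; default 0.2.
    subtype_se
        Standard error of subtype effect estimates: a scalar or a (lo, hi)
        range sampled uniformly per variant.
    flip_fraction
        Fraction of strand-ambiguous (A/T, G/C) SNPs emitted allele-flipped
        per cohort, to exercise the QC concordance audit.
    missing_rate
        Per-cohort probability that a variant is absent from that cohort.
    """

    n_variants: int = 2_000
    n_blocks: int = 100
    block_decay: float = 0.6
    n_cases: tuple[int, ...] = DEFAULT_COHORT_CASES
    n_controls: tuple[int, ...] = DEFAULT_COHORT_CONTROLS
    causal_fraction: float = 0.01
    effect_sd: float = 0.05
    maf_range: tuple[float, float] = (0.01, 0.5)
    info_range: tuple[float, float] = (0.7, 1.0)
    subtype_model_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    subtype_corr: float = 0.148
    tau: float = 0.2
    subtype_se: float | tuple[float, float] = 0.02
    mo_counts: tuple[int, int] = DEFAULT_MO_COUNTS
    ma_counts: tuple[int, int] = DEFAULT_MA_COUNTS
    flip_fraction: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigError("n_variants must be >= 1")
        if not 1 <= self.n_blocks <= self.n_variants:
            raise ConfigError("n_blocks must be in [1, n_variants]")
        if not 0 <= self.block_decay < 1:
            raise ConfigError("block_decay must be in [0, 1)")
        self.n_cases = tuple(int(n) for n in np.atleast_1d(self.n_cases))
        self.n_controls = tuple(int(n) for n in np.atleast_1d(self.n_controls))
        if len(self.n_cases) != len(self.n_controls):
            raise ConfigError("n_cases and n_controls must have equal length")
        if any(n <= 0 for n in self.n_cases + self.n_controls):
            raise ConfigError("every cohort needs > 0 cases and > 0 controls")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        lo, hi = self.info_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("info_range must lie within (0, 1]")
        if not 0 <= self.causal_fraction <= 1:
            raise ConfigError("causal_fraction must be a probability")
        if abs(sum(self.subtype_model_probs) - 1) > 1e-9 or min(self.subtype_model_probs) < 0:
            raise ConfigError("subtype_model_probs must be non-negative and sum to 1")
        if not -1 < self.subtype_corr < 1:
            raise ConfigError("subtype_corr must be in (-1, 1)")
        if self.tau <= 0:
            raise ConfigError("tau must be > 0")

    @property
    def n_cohorts(self) -> int:
        return len(self.n_cases)

    def block_slices(self) -> list[slice]:
        """Near-even partition of the variants into LD blocks."""
        bounds = np.linspace(0, self.n_variants, self.n_blocks + 1).astype(int)
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


MODEL_LABELS = ("NULL", "MO", "MA", "BOTH")


def _rng_children(config: SimConfig, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(config.seed).spawn(n)]


def simulate_ld_panel(config: SimConfig) -> LDPanel:
    """Block-diagonal signed LD with AR(1) decay within blocks.

    Within a block, ``r(i, j) = rho**|i-j|``; across blocks, r = 0. The AR(1)
    structure is positive definite for any rho in [0, 1), so the panel is
    always a valid correlation matrix.
    """
    r = np.eye(config.n_variants)
    rho = config.block_decay
    for sl in config.block_slices():
        m = sl.stop - sl.start
        idx = np.arange(m)
        r[sl, sl] = rho ** np.abs(idx[:, None] - idx[None, :])
    variants = [f"rs{i + 1}" for i in range(config.n_variants)]
    return LDPanel(variants=variants, r=r)


def _variant_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant identities: ids, coordinates, allele pairs and true EAF."""
    n = config.n_variants
    slices = config.block_slices()
    chrom = np.empty(n, dtype=int)
    bp = np.empty(n, dtype=int)
    pos = {}
    for b, sl in enumerate(slices):
        c = b % 22 + 1
        chrom[sl] = c
        start = pos.get(c, 1_000_000)
        steps = rng.integers(2_000, 20_000, size=sl.stop - sl.start)
        p = start + np.cumsum(steps)
        bp[sl] = p
        pos[c] = int(p[-1]) + 500_000  # keep blocks on a chromosome apart

    pairs = [(a, b) for i, a in enumerate(_BASES) for b in _BASES[i + 1:]]
    pick = rng.integers(0, len(pairs), size=n)
    swap = rng.random(n) < 0.5
    ea = np.array([pairs[k][0] for k in pick])
    oa = np.array([pairs[k][1] for k in pick])
    ea, oa = np.where(swap, oa, ea), np.where(swap, ea, oa)

    maf = rng.uniform(*config.maf_range, size=n)
    eaf = np.where(rng.random(n) < 0.5, maf, 1 - maf)
    return pd.DataFrame({
        "SNP": [f"rs{i + 1}" for i in range(n)],
        "CHR": chrom.astype(str), "BP": bp, "EA": ea, "OA": oa, "EAF": eaf,
    })


def _truth_labels(config: SimConfig, causal: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Generating-model label per variant; non-causal variants are NULL."""
    labels = np.full(config.n_variants, "NULL", dtype=object)
    p = np.asarray(config.subtype_model_probs[1:], dtype=float)
    if p.sum() == 0:
        p = np.array([0.0, 0.0, 1.0])
    p = p / p.sum()
    k = int(causal.sum())
    labels[causal] = rng.choice(MODEL_LABELS[1:], size=k, p=p)
    return labels


def _ar1_block(config: SimConfig, sl: slice) -> np.ndarray:
    m = sl.stop - sl.start
    idx = np.arange(m)
    return config.block_decay ** np.abs(idx[:, None] - idx[None, :])


def simulate_cohorts(
        config: SimConfig,
        panel: LDPanel | None = None) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Draw per-cohort summary-statistics tables over *panel*.

    Returns ``(truth, cohort_tables)`` where *truth* records each variant's
    true effects and generating label, and each cohort table follows the
    shared dialect. Standard errors satisfy the effective-sample-size
    identity exactly for the emitted EAF; effect estimates within an LD block
    are correlated with the panel r.

    With ``panel=None`` the config's implicit AR(1) block correlation is
    used directly, block by block, without materializing the dense panel —
    the statistical model is identical but panel sizes far beyond dense
    storage become tractable.
    """
    if panel is not None and len(panel) != config.n_variants:
        raise ConfigError("panel size does not match config.n_variants")
    rng_var, rng_eff, *rng_cohorts = _rng_children(config, 2 + config.n_cohorts)

    variants = _variant_frame(config, rng_var)
    n = config.n_variants
    causal = rng_eff.random(n) < config.causal_fraction
    beta = np.where(causal, rng_eff.normal(0.0, config.effect_sd, size=n), 0.0)
    labels = _truth_labels(config, causal, rng_eff)
    beta_mo = np.where(np.isin(labels, ("MO", "BOTH")), beta, 0.0)
    beta_ma = np.where(np.isin(labels, ("MA", "BOTH")), beta, 0.0)

    truth = variants.copy()
    truth = truth.rename(columns={"EAF": "TRUE_EAF"})
    truth["BETA_TRUE"] = beta
    truth["BETA_MO_TRUE"] = beta_mo
    truth["BETA_MA_TRUE"] = beta_ma
    truth["MODEL"] = labels

    slices = config.block_slices()
    blocks = [panel.r[sl, sl] if panel is not None else _ar1_block(config, sl)
              for sl in slices]
    chol = [np.linalg.cholesky(R + 1e-10 * np.eye(len(R))) for R in blocks]

    ambiguous = np.array([{a, b} in _AMBIGUOUS
                          for a, b in zip(variants["EA"], variants["OA"])])

    tables = []
    for (ncase, nctrl), rng in zip(zip(config.n_cases, config.n_controls), rng_cohorts):
        total = ncase + nctrl
        t = ncase / total
        info = rng.uniform(*config.info_range, size=n)
        eaf = np.clip(variants["EAF"].to_numpy() + rng.normal(0, 0.004, size=n),
                      1e-3, 1 - 1e-3)
        # se from the N_eff identity: 1/(f(1-f) se^2) = 2 N t (1-t) I
        se = 1.0 / np.sqrt(2 * total * t * (1 - t) * info * eaf * (1 - eaf))

        bhat = np.empty(n)
        for sl, R, L in zip(slices, blocks, chol):
            z_joint = beta[sl] / se[sl]
            z_mu = R @ z_joint
            g = rng.standard_normal(sl.stop - sl.start)
            bhat[sl] = se[sl] * (z_mu + L @ g)
        p = 2 * stats.norm.sf(np.abs(bhat / se))

        df = variants.copy()
        df["EAF"] = eaf
        df["BETA"] = bhat
        df["SE"] = se
        df["P"] = p
        df["INFO"] = info
        df["N_CASES"] = ncase
        df["N_CONTROLS"] = nctrl

        flip = ambiguous & (rng.random(n) < config.flip_fraction)
        df.loc[flip, "EAF"] = 1 - df.loc[flip, "EAF"]
        df.loc[flip, "BETA"] = -df.loc[flip, "BETA"]

        if config.missing_rate > 0:
            present = rng.random(n) >= config.missing_rate
            df = df.loc[present].reset_index(drop=True)
        tables.append(df[SUMSTATS_COLUMNS])
    return truth, tables


def simulate_subtype_pairs(
        config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired MO/MA summary statistics with hidden generating labels.

    Labels are drawn from ``subtype_model_probs``; nonzero effects are
    N(0, tau^2) under the labelled model. BOTH mixes the fixed-effect model
    (identical effect in both subtypes) and the independent-effects model
    with equal weights. Estimates are drawn from a bivariate Gaussian around
    the true effects with estimator correlation ``subtype_corr``.

    Returns ``(truth, mo_table, ma_table)``.
    """
    rng_var, rng_eff, rng_noise = _rng_children(config, 3)
    variants = _variant_frame(config, rng_var)
    n = config.n_variants
    labels = rng_eff.choice(MODEL_LABELS, size=n,
                            p=np.asarray(config.subtype_model_probs))
    tau = config.tau
    draw = rng_eff.normal(0.0, tau, size=(n, 2))
    fixed = rng_eff.random(n) < 0.5  # BOTH mixture component
    b_mo = np.zeros(n)
    b_ma = np.zeros(n)
    is_mo = labels == "MO"
    is_ma = labels == "MA"
    is_both = labels == "BOTH"
    b_mo[is_mo] = draw[is_mo, 0]
    b_ma[is_ma] = draw[is_ma, 1]
    b_mo[is_both] = draw[is_both, 0]
    b_ma[is_both] = np.where(fixed[is_both], draw[is_both, 0], draw[is_both, 1])

    if np.isscalar(config.subtype_se):
        se_mo = np.full(n, float(config.subtype_se))
        se_ma = np.full(n, float(config.subtype_se))
    else:
        lo, hi = config.subtype_se
        se_mo = rng_noise.uniform(lo, hi, size=n)
        se_ma = rng_noise.uniform(lo, hi, size=n)

    c = config.subtype_corr
    g1 = rng_noise.standard_normal(n)
    g2 = rng_noise.standard_normal(n)
    e_mo = g1
    e_ma = c * g1 + np.sqrt(1 - c ** 2) * g2
    bhat_mo = b_mo + se_mo * e_mo
    bhat_ma = b_ma + se_ma * e_ma

    truth = variants.rename(columns={"EAF": "TRUE_EAF"}).copy()
    truth["BETA_MO_TRUE"] = b_mo
    truth["BETA_MA_TRUE"] = b_ma
    truth["MODEL"] = labels
    truth["BOTH_FIXED"] = is_both & fixed

    def table(bhat, se, counts):
        df = variants.copy()
        df["BETA"] = bhat
        df["SE"] = se
        df["P"] = 2 * stats.norm.sf(np.abs(bhat / se))
        df["INFO"] = 1.0
        df["N_CASES"], df["N_CONTROLS"] = counts
        return df[SUMSTATS_COLUMNS]

    return (truth,
            table(bhat_mo, se_mo, config.mo_counts),
            table(bhat_ma, se_ma, config.ma_counts))


def write_simulation(out_dir, config: SimConfig) -> None:
    """Run the generator end to end and write all outputs under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = simulate_ld_panel(config)
    panel.write(out / "panel")
    truth, tables = simulate_cohorts(config, panel)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    for i, df in enumerate(tables, start=1):
        write_sumstats(df, out / f"cohort{i}.tsv")
    sub_truth, mo, ma = simulate_subtype_pairs(config)
    sub_truth.to_csv(out / "subtype_truth.tsv", sep="\t", index=False)
    write_sumstats(mo, out / "subtype_mo.tsv")
    write_sumstats(ma, out / "subtype_ma.tsv")
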
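"""Inverse-variance weighted fixed-effect meta-analysis and diagnostics.

Pools harmonized per-cohort log-odds estimates with weights ``w = 1/se^2``,
tracks a per-cohort direction string (``+``/``-``/``?``), converts the
pooled EAF and SE into an effective sample size
``N_eff = 1/(f(1-f) se^2)`` (which approximates ``2 N t (1-t) I`` for total
sample size N, case proportion t and imputation info I), filters variants
with very low N_eff, and reports the genomic inflation factor
``lambda_GC = median(chi2) / qchisq(0.5, df=1)``.

Two-sided p-values are computed in log space so that genome-wide
comparisons at extreme z do not round to zero; the table carries both ``P``
(clipped to the smallest subnormal float) and ``MLOG10P``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .qc import DataError

#: chi-square(1) median, the null reference for lambda_GC.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

_SMALLEST = np.nextafter(0, 1)  # smallest positive subnormal double

#: Variant identity columns carried into the pooled table.
_ID_COLS = ["SNP", "CHR", "BP", "EA", "OA"]


def _log10_two_sided_p(z: np.ndarray) -> np.ndarray:
    """-log10 of the two-sided normal p-value, stable for huge \\|z\\|."""
    logp = np.log(2.0) + stats.norm.logsf(np.abs(z))
    return -logp / np.log(10.0)


def ivw_meta(cohorts: list[pd.DataFrame],
             names: list[str] | None = None) -> pd.DataFrame:
    """Pool per-cohort tables by fixed-effect inverse-variance weighting.

    Variants are keyed by their SNP id; a variant absent from a cohort
    contributes ``?`` to its direction string. Pooled EAF is the
    weight-averaged effect-allele frequency. Raises :class:`DataError` on a
    non-positive standard error, naming the cohort and variant.
    """
    if not cohorts:
        raise ValueError("at least one cohort table is required")
    names = names or [f"cohort{i + 1}" for i in range(len(cohorts))]
    for name, df in zip(names, cohorts):
        bad = df.loc[df["SE"] <= 0, "SNP"]
        if len(bad):
            raise DataError(f"non-positive SE in {name} at variant {bad.iloc[0]}")

    all_ids = pd.concat([df[_ID_COLS] for df in cohorts]).drop_duplicates("SNP")
    all_ids = all_ids.set_index("SNP")
    n = len(all_ids)
    order = {snp: i for i, snp in enumerate(all_ids.index)}

    sw = np.zeros(n)          # sum of weights
    swb = np.zeros(n)         # sum of w * beta
    swf = np.zeros(n)         # sum of w * eaf
    k = np.zeros(n, dtype=int)
    direction = np.full((len(cohorts), n), "?", dtype=object)

    for j, df in enumerate(cohorts):
        idx = np.array([order[s] for s in df["SNP"]])
        w = 1.0 / df["SE"].to_numpy(dtype=float) ** 2
        b = df["BETA"].to_numpy(dtype=float)
        np.add.at(sw, idx, w)
        np.add.at(swb, idx, w * b)
        np.add.at(swf, idx, w * df["EAF"].to_numpy(dtype=float))
        np.add.at(k, idx, 1)
        direction[j, idx] = np.where(b >= 0, "+", "-")

    beta = swb / sw
    se = 1.0 / np.sqrt(sw)
    z = beta / se
    eaf = swf / sw
    mlog10p = _log10_two_sided_p(z)
    p = np.maximum(np.power(10.0, -np.minimum(mlog10p, 323.0)), _SMALLEST)

    out = all_ids.reset_index()
    out["EAF"] = eaf
    out["BETA_META"] = beta
    out["SE_META"] = se
    out["Z"] = z
    out["P"] = p
    out["MLOG10P"] = mlog10p
    out["N_EFF"] = effective_sample_size(eaf, se)
    out["DIRECTION"] = ["".join(direction[:, i]) for i in range(n)]
    out["N_COHORTS"] = k
    return out


def effective_sample_size(eaf, se):
    """``N_eff = 1 / (f (1-f) se^2)`` for effect-allele frequency f.

    Accepts scalars or arrays; raises on degenerate inputs (f in {0, 1} or
    se = 0) where the quantity is undefined.
    """
    f = np.asarray(eaf, dtype=float)
    s = np.asarray(se, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise DataError("EAF must lie strictly inside (0, 1)")
    if np.any(s <= 0):
        raise DataError("SE must be > 0")
    out = 1.0 / (f * (1 - f) * s ** 2)
    return float(out) if out.ndim == 0 else out


def filter_by_neff(meta_table: pd.DataFrame, min_neff: float = 5000):
    """Drop variants with ``N_EFF < min_neff`` (low-precision estimates).

    Returns ``(filtered, n_excluded)``.
    """
    keep = meta_table["N_EFF"] >= min_neff
    return meta_table.loc[keep].reset_index(drop=True), int((~keep).sum())


def genomic_inflation(z=None, p=None, chi2=None) -> float:
    """Genomic inflation factor: median observed chi2 over the null median.

    Provide exactly one of z-scores, two-sided p-values or chi-square(1)
    statistics.
    """
    given = [x for x in (z, p, chi2) if x is not None]
    if len(given) != 1:
        raise ValueError("provide exactly one of z, p or chi2")
    if z is not None:
        x = np.asarray(z, dtype=float) ** 2
    elif p is not None:
        x = stats.chi2.isf(np.asarray(p, dtype=float), df=1)
    else:
        x = np.asarray(chi2, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise DataError("no finite statistics for lambda_GC")
    return float(np.median(x) / CHI2_1_MEDIAN)
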
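"""Auxiliary enrichment and heritability statistics.

Two small bespoke analyses: a leave-one-out prediction-interval test for
tissue-level cis-eQTL enrichment of lead variants, and the conversion of an
observed-scale SNP heritability to the liability scale given the disease
prevalence and the sample case proportion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class DegenerateFitError(ValueError):
    """A leave-one-out regression cannot be fitted (constant predictor)."""


def eqtl_enrichment_loo(counts: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Leave-one-out eQTL enrichment test across tissues.

    *counts* has one row per tissue with columns TISSUE, OBSERVED (number of
    lead variants that are significant cis-eQTLs in the tissue) and
    PREDICTOR (overall number of genes with at least one significant
    cis-eQTL in the tissue). For each tissue, an ordinary least-squares
    regression of OBSERVED on PREDICTOR is fitted on the *other* tissues and
    a ``level`` prediction interval is formed at the held-out tissue's
    predictor value; tissues whose observed count falls above (below) the
    interval are flagged "enriched" ("depleted").
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if len(counts) < 3:
        raise ValueError("at least 3 tissues are required for a leave-one-out fit")
    obs = counts["OBSERVED"].to_numpy(dtype=float)
    pred = counts["PREDICTOR"].to_numpy(dtype=float)
    if np.any(obs < 0) or np.any(pred < 0):
        raise ValueError("counts must be non-negative")

    rows = []
    for i in range(len(counts)):
        mask = np.ones(len(counts), dtype=bool)
        mask[i] = False
        x, y = pred[mask], obs[mask]
        if np.ptp(x) == 0:
            raise DegenerateFitError(
                f"constant predictor when leaving out tissue "
                f"{counts['TISSUE'].iloc[i]}")
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        frame = fit.get_prediction(
            sm.add_constant(np.array([pred[i]]), has_constant="add")
        ).summary_frame(alpha=1 - level)
        lo = float(frame["obs_ci_lower"].iloc[0])
        hi = float(frame["obs_ci_upper"].iloc[0])
        flag = "enriched" if obs[i] > hi else "depleted" if obs[i] < lo else ""
        rows.append({
            "TISSUE": counts["TISSUE"].iloc[i],
            "OBSERVED": obs[i], "PREDICTOR": pred[i],
            "FIT": float(frame["mean"].iloc[0]),
            "PI_LOW": lo, "PI_HIGH": hi, "FLAG": flag,
        })
    return pd.DataFrame(rows)


def liability_h2(h2_obs: float, prevalence_k: float,
                 case_prop_p: float) -> tuple[float, float]:
    """Observed-scale heritability converted to the liability scale.

    Under the liability-threshold model with population prevalence K and
    sample case proportion P,

        h2_liability = h2_obs * K^2 (1-K)^2 / (P (1-P) z^2),

    where z is the standard normal density at the liability threshold
    ``Phi^{-1}(1-K)``. Returns ``(h2_liability, conversion_factor)``.
    """
    if h2_obs < 0:
        raise ValueError("h2_obs must be >= 0")
    if not 0 < prevalence_k < 1 or not 0 < case_prop_p < 1:
        raise ValueError("prevalence and case proportion must be in (0, 1)")
    k, p = prevalence_k, case_prop_p
    z = stats.norm.pdf(stats.norm.ppf(1 - k))
    factor = k ** 2 * (1 - k) ** 2 / (p * (1 - p) * z ** 2)
    return h2_obs * factor, factor
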
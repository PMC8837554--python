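"""Stepwise conditional analysis per risk locus from summary statistics.

Works entirely from meta-analysis z-scores and a reference LD panel, in the
style of summary-statistic joint regression: conditioning the z-score of a
candidate c on a selected set s via the LD matrix R,

    z_c|s = (z_c - R_cs R_ss^{-1} z_s) / sqrt(1 - R_cs R_ss^{-1} R_sc).

Starting from the locus lead, the minimum-p candidate is added while its
conditional p stays below the genome-wide threshold. Because the z-scores
come from a meta-analysis where per-variant sample sizes vary widely,
candidates are first restricted to SNPs (no indels) whose effective sample
size lies within +-10% of the lead's — otherwise conditioning produces
spurious p-values. When the lead itself is excluded by that window (e.g. it
is an indel), the best remaining candidate in LD (r^2 > 0.3) with it seeds
the procedure instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDPanel
from .loci import GWS_P, Locus

_BASES = {"A", "C", "G", "T"}


@dataclass
class ConditionalResult:
    """Outcome of the stepwise procedure for one locus."""

    seed: str | None
    selected: list[str]
    steps: list[pd.DataFrame] = field(default_factory=list)
    stopping_reason: str = ""
    dropped: list[str] = field(default_factory=list)

    @property
    def secondary(self) -> list[str]:
        """Conditionally independent signals beyond the seed variant."""
        return self.selected[1:]


def _is_snp(ea: str, oa: str) -> bool:
    return ea in _BASES and oa in _BASES


def neff_window(members: pd.DataFrame, lead: str,
                tolerance: float = 0.10) -> pd.DataFrame:
    """SNP members whose N_eff lies within ``(1 +- tolerance)`` of the lead's.

    Indels are excluded regardless of their N_eff. The window is anchored at
    the lead's N_eff even when the lead itself is an indel (and therefore
    not a candidate).
    """
    at_lead = members.loc[members["SNP"] == lead]
    if at_lead.empty:
        raise ValueError(f"lead {lead} not among locus members")
    lead_neff = float(at_lead["N_EFF"].iloc[0])
    is_snp = np.array([_is_snp(a, b) for a, b in zip(members["EA"], members["OA"])])
    neff = members["N_EFF"].to_numpy(dtype=float)
    keep = is_snp & (neff >= (1 - tolerance) * lead_neff) \
        & (neff <= (1 + tolerance) * lead_neff)
    return members.loc[keep].reset_index(drop=True)


def _zscores(candidates: pd.DataFrame) -> np.ndarray:
    if "Z" in candidates.columns:
        return candidates["Z"].to_numpy(dtype=float)
    return (candidates["BETA_META"] / candidates["SE_META"]).to_numpy(dtype=float)


def stepwise_conditional(candidates: pd.DataFrame, panel: LDPanel,
                         p_stop: float = GWS_P,
                         seed: str | None = None,
                         max_steps: int = 10,
                         collinearity_r2: float = 0.95) -> ConditionalResult:
    """Forward selection by conditional z-scores against reference LD.

    *seed* (default: the minimum-p candidate) starts the selected set. At
    each step every remaining candidate's conditional z and two-sided p are
    computed; the minimum-p candidate is added while p < *p_stop*.
    Candidates absent from the panel, nearly collinear with the selected set
    (r^2 > *collinearity_r2*) or with numerically non-positive conditional
    variance are dropped and logged.
    """
    dropped = [s for s in candidates["SNP"] if not panel.has(s)]
    cand = candidates.loc[candidates["SNP"].map(panel.has)].reset_index(drop=True)
    if cand.empty:
        return ConditionalResult(seed=None, selected=[],
                                 stopping_reason="no candidates",
                                 dropped=dropped)
    snps = list(cand["SNP"])
    z = dict(zip(snps, _zscores(cand)))
    p_marg = 2 * stats.norm.sf(np.abs(np.array([z[s] for s in snps])))
    order = {s: (p, s) for s, p in zip(snps, p_marg)}
    if seed is None:
        seed = min(snps, key=lambda s: order[s])
    if seed not in snps:
        raise ValueError(f"seed {seed} not among panel-covered candidates")

    selected = [seed]
    remaining = [s for s in snps if s != seed]
    steps: list[pd.DataFrame] = []
    reason = "no conditional GWS"
    while remaining and len(steps) < max_steps:
        R_ss = panel.submatrix(selected)
        z_s = np.array([z[s] for s in selected])
        rows = []
        drop_now = []
        for c in remaining:
            r_cs = np.array([panel.corr(c, s) for s in selected])
            if np.max(r_cs ** 2) > collinearity_r2:
                drop_now.append(c)
                continue
            try:
                sol = np.linalg.solve(R_ss, np.column_stack([r_cs, z_s]))
            except np.linalg.LinAlgError:
                drop_now.append(c)
                continue
            var = 1.0 - float(r_cs @ sol[:, 0])
            assert var <= 1 + 1e-8, "conditional variance above 1 for a PSD panel"
            if var < 1e-8:
                drop_now.append(c)
                continue
            z_cond = (z[c] - float(r_cs @ sol[:, 1])) / np.sqrt(var)
            p_cond = 2 * stats.norm.sf(abs(z_cond))
            rows.append({"SNP": c, "Z_COND": z_cond, "P_COND": p_cond})
        for c in drop_now:
            remaining.remove(c)
            dropped.append(c)
        if not rows:
            reason = "no candidates"
            break
        step = pd.DataFrame(rows)
        steps.append(step)
        best = step.sort_values(["P_COND", "SNP"], kind="mergesort").iloc[0]
        if best["P_COND"] < p_stop:
            selected.append(str(best["SNP"]))
            remaining.remove(str(best["SNP"]))
            reason = "max steps" if len(steps) >= max_steps else reason
        else:
            reason = "no conditional GWS"
            break
    else:
        if not remaining:
            reason = "exhausted candidates"
    return ConditionalResult(seed=seed, selected=selected, steps=steps,
                             stopping_reason=reason, dropped=dropped)


def condition_locus(locus: Locus, meta_table: pd.DataFrame, panel: LDPanel,
                    neff_tol: float = 0.10, p_stop: float = GWS_P,
                    lead_ld_r2: float = 0.3) -> ConditionalResult:
    """Run the N_eff window and the stepwise procedure for one locus.

    The seed is the locus lead when it survives the window; otherwise the
    minimum-p candidate in LD (r^2 > *lead_ld_r2*) with the lead. With no
    eligible candidate the result reports ``stopping_reason`` "no
    candidates".
    """
    members = meta_table.loc[meta_table["SNP"].isin(locus.members)]
    lead = locus.lead
    if lead is None:
        raise ValueError("locus has no lead variant; run name_and_lead first")
    candidates = neff_window(members, lead, neff_tol)
    if candidates.empty:
        return ConditionalResult(seed=None, selected=[],
                                 stopping_reason="no candidates")
    cand_snps = set(candidates["SNP"])
    if lead in cand_snps and panel.has(lead):
        seed = lead
    else:
        in_ld = [s for s in candidates["SNP"]
                 if panel.has(s) and panel.has(lead) and
                 panel.r2(lead, s) > lead_ld_r2]
        if not in_ld:
            return ConditionalResult(seed=None, selected=[],
                                     stopping_reason="no candidates")
        sub = candidates.loc[candidates["SNP"].isin(in_ld)]
        zsub = np.abs(_zscores(sub))
        seed = str(sub["SNP"].iloc[int(np.argmax(zsub))])
    return stepwise_conditional(candidates, panel, p_stop=p_stop, seed=seed)
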
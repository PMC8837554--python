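"""Cohort harmonization and variant-level quality control.

Each cohort is harmonized to a reference panel (matched by chromosome,
position and alleles, with indels recoded to I/D and multiallelic positions
dropped) and then filtered by the study's variant-level exclusion rules:
MAF, imputation info, Hardy-Weinberg equilibrium, missingness and
effect-allele-frequency discrepancy against the reference.

Strand-ambiguous (A/T, G/C) SNPs are *not* filtered; instead
:func:`audit_strand_ambiguous` reports, per MAF stratum, how often two
cohorts agree on which allele is the minor one — near-perfect agreement at
low MAF indicates consistent strand labelling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .dialect import SchemaError, validate_sumstats

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})

#: Order in which a failing variant is attributed to an exclusion rule.
EXCLUSION_ORDER = [
    "multiallelic", "match_failure", "maf", "info",
    "hwe", "missingness", "eaf_discrepancy",
]


class DataError(ValueError):
    """Malformed or inconsistent summary-statistics data."""


@dataclass
class QCThresholds:
    """Variant-level exclusion thresholds.

    Variants are retained when MAF > ``maf_min``, info > ``info_min``,
    HWE p > ``hwe_p_min``, missingness < ``missingness_max`` and the
    EAF difference to the reference is <= the per-class discrepancy bound
    (0.30 for SNPs, 0.20 for indels). HWE and missingness apply only when
    the columns are present.
    """

    maf_min: float = 0.01
    info_min: float = 0.6
    hwe_p_min: float = 1e-6
    missingness_max: float = 0.05
    eaf_discrepancy_snp: float = 0.30
    eaf_discrepancy_indel: float = 0.20

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        for name in ("info_min", "hwe_p_min", "missingness_max",
                     "eaf_discrepancy_snp", "eaf_discrepancy_indel"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QCReport:
    """Per-rule exclusion counts plus the retained variant count."""

    n_input: int
    exclusions: dict[str, int]
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + sum(self.exclusions.values()):
            raise ValueError("exclusions + retained must equal input count")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _is_indel_allele(a: str) -> bool:
    return len(a) > 1 or a in ("I", "D", "-")


def _recode_indels(df: pd.DataFrame) -> pd.DataFrame:
    """Recode indel allele pairs to I (longer) / D (shorter), in place-ish."""
    ea = df["EA"].str.upper().to_numpy(dtype=object)
    oa = df["OA"].str.upper().to_numpy(dtype=object)
    for i in range(len(ea)):
        a, b = ea[i], oa[i]
        if {a, b} == {"I", "D"}:
            continue
        if _is_indel_allele(a) or _is_indel_allele(b):
            la = 0 if a == "-" else len(a)
            lb = 0 if b == "-" else len(b)
            if la != lb:
                ea[i], oa[i] = ("I", "D") if la > lb else ("D", "I")
    out = df.copy()
    out["EA"] = ea
    out["OA"] = oa
    return out


def _key_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Uppercased, indel-recoded copy with a position key column."""
    out = _recode_indels(df)
    out["_POS"] = out["CHR"].astype(str) + ":" + out["BP"].astype(str)
    out["_PAIR"] = [frozenset(p) for p in zip(out["EA"], out["OA"])]
    return out


def _drop_multiallelic(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop every row at a position carrying more than one allele pair."""
    n_pairs = df.groupby("_POS")["_PAIR"].transform("nunique")
    multi = n_pairs > 1
    return df.loc[~multi], int(multi.sum())


def harmonize_to_reference(
        cohort: pd.DataFrame,
        reference: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Harmonize a cohort table to a reference panel.

    Variants are matched by chromosome, position and alleles (after
    uppercasing and I/D indel recoding). Where the cohort's effect/other
    alleles are swapped relative to the reference, BETA is negated and EAF
    replaced by 1 - EAF. Multiallelic positions and unmatched variants are
    dropped. The harmonized table gains ``REF_EAF`` and ``IS_INDEL`` columns.

    Returns ``(harmonized, exclusions)`` with per-rule drop counts under the
    keys ``multiallelic`` and ``match_failure``.
    """
    validate_sumstats(cohort, ["CHR", "BP", "EA", "OA", "EAF", "BETA"])
    validate_sumstats(reference, ["CHR", "BP", "EA", "OA", "EAF"])

    cohort = cohort.drop(columns=["REF_EAF", "IS_INDEL"], errors="ignore")
    co = _key_frame(cohort)
    key = co["_POS"].astype(str) + ":" + co["_PAIR"].map(
        lambda p: "/".join(sorted(p)))
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise DataError(f"duplicate variant key within cohort: {dup}")
    co, n_multi_cohort = _drop_multiallelic(co)

    ref = _key_frame(reference)
    ref, _ = _drop_multiallelic(ref)
    lookup = ref[["_POS", "EA", "OA", "EAF"]].rename(
        columns={"EA": "_REF_EA", "OA": "_REF_OA", "EAF": "REF_EAF"})

    co = co.reset_index(drop=True).merge(lookup, on="_POS", how="left")
    same = (co["EA"] == co["_REF_EA"]) & (co["OA"] == co["_REF_OA"])
    swapped = (co["EA"] == co["_REF_OA"]) & (co["OA"] == co["_REF_EA"])
    n_multi = n_multi_cohort
    n_unmatched = int((~(same | swapped)).sum())

    out = co.loc[same | swapped].reset_index(drop=True)
    swapped = swapped.loc[same | swapped].reset_index(drop=True).to_numpy()
    if len(out):
        out.loc[swapped, "BETA"] = -out.loc[swapped, "BETA"]
        out.loc[swapped, "EAF"] = 1 - out.loc[swapped, "EAF"]
        ea = out["EA"].to_numpy(dtype=object)
        oa = out["OA"].to_numpy(dtype=object)
        ea[swapped], oa[swapped] = oa[swapped].copy(), ea[swapped].copy()
        out["EA"], out["OA"] = ea, oa
    out = out.drop(columns=["_REF_EA", "_REF_OA"])
    out["IS_INDEL"] = out["_PAIR"].map(lambda p: p == frozenset({"I", "D"}))
    out = out.drop(columns=["_POS", "_PAIR"])
    return out, {"multiallelic": n_multi, "match_failure": n_unmatched}


def apply_qc_filters(
        harmonized: pd.DataFrame,
        thresholds: QCThresholds | None = None,
        harmonize_exclusions: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the variant-level exclusion rules to a harmonized table.

    Each excluded variant is attributed to the *first* failing rule in
    :data:`EXCLUSION_ORDER`. HWE and missingness rules are skipped when the
    ``HWE_P`` / ``MISSINGNESS`` columns are absent. Pass the exclusion
    counts returned by :func:`harmonize_to_reference` to fold them into the
    report.
    """
    thresholds = thresholds or QCThresholds()
    df = harmonized
    eaf = df["EAF"].to_numpy(dtype=float)
    if np.any((eaf < 0) | (eaf > 1)):
        raise DataError("EAF outside [0, 1]")

    maf = np.minimum(eaf, 1 - eaf)
    fail = {}
    fail["maf"] = ~(maf > thresholds.maf_min)
    if "INFO" in df.columns:
        fail["info"] = ~(df["INFO"].to_numpy(dtype=float) > thresholds.info_min)
    else:
        fail["info"] = np.zeros(len(df), dtype=bool)
    if "HWE_P" in df.columns:
        fail["hwe"] = ~(df["HWE_P"].to_numpy(dtype=float) > thresholds.hwe_p_min)
    else:
        fail["hwe"] = np.zeros(len(df), dtype=bool)
    if "MISSINGNESS" in df.columns:
        fail["missingness"] = ~(
            df["MISSINGNESS"].to_numpy(dtype=float) < thresholds.missingness_max)
    else:
        fail["missingness"] = np.zeros(len(df), dtype=bool)
    if "REF_EAF" in df.columns:
        diff = np.abs(eaf - df["REF_EAF"].to_numpy(dtype=float))
        is_indel = df["IS_INDEL"].to_numpy(dtype=bool) if "IS_INDEL" in df.columns \
            else np.zeros(len(df), dtype=bool)
        bound = np.where(is_indel, thresholds.eaf_discrepancy_indel,
                         thresholds.eaf_discrepancy_snp)
        fail["eaf_discrepancy"] = diff > bound
    else:
        fail["eaf_discrepancy"] = np.zeros(len(df), dtype=bool)

    exclusions = dict(harmonize_exclusions or {})
    attributed = np.zeros(len(df), dtype=bool)
    for rule in EXCLUSION_ORDER:
        if rule not in fail:
            exclusions.setdefault(rule, 0)
            continue
        hit = fail[rule] & ~attributed
        exclusions[rule] = exclusions.get(rule, 0) + int(hit.sum())
        attributed |= hit

    retained = df.loc[~attributed].reset_index(drop=True)
    n_input = len(df) + sum((harmonize_exclusions or {}).values())
    report = QCReport(n_input=n_input, exclusions=exclusions,
                      n_retained=len(retained))
    return retained, report


def _is_ambiguous(ea: pd.Series, oa: pd.Series) -> np.ndarray:
    return np.array([{a, b} in _AMBIGUOUS for a, b in zip(ea, oa)])


def audit_strand_ambiguous(
        table_a: pd.DataFrame, table_b: pd.DataFrame,
        maf_thresholds: list[float] | tuple[float, ...] = (0.25, 0.4),
) -> pd.DataFrame:
    """Minor-allele concordance of strand-ambiguous SNPs between two cohorts.

    For each MAF stratum (no threshold, then below/above each threshold,
    stratified by table A's MAF) reports the proportion of shared A/T and
    G/C SNPs whose minor allele is the same allele in both tables. SNPs with
    EAF exactly 0.5 in either table have no defined minor allele and are
    skipped; an empty stratum reports NaN, not 0.
    """
    for t in maf_thresholds:
        if not 0 < t < 0.5:
            raise ValueError("maf_thresholds must lie in (0, 0.5)")
    a = table_a.loc[_is_ambiguous(table_a["EA"], table_a["OA"])]
    merged = a.merge(table_b, on="SNP", suffixes=("_A", "_B"))
    eaf_a = merged["EAF_A"].to_numpy(dtype=float)
    eaf_b = merged["EAF_B"].to_numpy(dtype=float)
    defined = (eaf_a != 0.5) & (eaf_b != 0.5)
    merged = merged.loc[defined]
    eaf_a, eaf_b = eaf_a[defined], eaf_b[defined]
    minor_a = np.where(eaf_a < 0.5, merged["EA_A"], merged["OA_A"])
    minor_b = np.where(eaf_b < 0.5, merged["EA_B"], merged["OA_B"])
    agree = minor_a == minor_b
    maf = np.minimum(eaf_a, 1 - eaf_a)

    rows = [("all", np.ones(len(merged), dtype=bool))]
    for t in maf_thresholds:
        rows.append((f"MAF<{t}", maf < t))
        rows.append((f"MAF>{t}", maf > t))
    out = []
    for label, mask in rows:
        n = int(mask.sum())
        prop = float(agree[mask].mean()) if n else float("nan")
        out.append({"STRATUM": label, "N": n, "CONCORDANCE": prop})
    return pd.DataFrame(out)
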
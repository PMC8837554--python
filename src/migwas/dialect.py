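"""Tab-delimited GWAS summary-statistics dialect shared by all pipeline stages.

One row per variant with a fixed header::

    SNP CHR BP EA OA EAF BETA SE P INFO N_CASES N_CONTROLS

Coordinates are 1-based inclusive; BETA is the log-odds effect of the effect
allele EA relative to the other allele OA. Extra columns (e.g. HWE_P,
MISSINGNESS, or downstream meta-analysis columns) are carried through
untouched.
"""

from __future__ import annotations

import pandas as pd

#: Required columns of the summary-statistics dialect, in canonical order.
SUMSTATS_COLUMNS = [
    "SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P",
    "INFO", "N_CASES", "N_CONTROLS",
]

_DTYPES = {
    "SNP": str, "CHR": str, "EA": str, "OA": str,
}


class SchemaError(ValueError):
    """A table is missing required columns of the dialect."""


def validate_sumstats(df: pd.DataFrame, required: list[str] | None = None) -> None:
    """Raise :class:`SchemaError` if *df* lacks required dialect columns."""
    required = required if required is not None else SUMSTATS_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"summary-statistics table missing columns: {missing}")


def read_sumstats(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics table."""
    df = pd.read_csv(path, sep="\t", dtype=_DTYPES)
    validate_sumstats(df, required)
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
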
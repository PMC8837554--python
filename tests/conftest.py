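import numpy as np
import pandas as pd
import pytest

from migwas.ld import LDPanel


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_gws_table(snps, chroms, positions, pvals, ea=None, oa=None):
    """Small genome-wide significant table in the shared dialect."""
    n = len(snps)
    return pd.DataFrame({
        "SNP": snps,
        "CHR": [str(c) for c in chroms],
        "BP": positions,
        "EA": ea or ["A"] * n,
        "OA": oa or ["G"] * n,
        "P": pvals,
    })


def panel_from_pairs(snps, pairs):
    """LD panel with the given signed r for listed pairs, zero elsewhere."""
    n = len(snps)
    idx = {s: i for i, s in enumerate(snps)}
    r = np.eye(n)
    for a, b, val in pairs:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = val
    return LDPanel(variants=list(snps), r=r)


def random_correlation(rng, m):
    """Random full-rank correlation matrix via a Wishart-style factor."""
    w = rng.normal(size=(m, m + 3))
    s = w @ w.T
    d = 1.0 / np.sqrt(np.diag(s))
    return d[:, None] * s * d[None, :]
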
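"""Reference LD panel: signed pairwise allelic correlations over a variant set.

The panel plays the role of an external reference (e.g. a biobank sample):
downstream algorithms must tolerate variants that are absent from it, in
which case their LD is *unknown* rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class LDPanel:
    """Dense signed correlation matrix ``r`` over an ordered variant panel.

    ``r`` is symmetric with unit diagonal; ``r**2`` is the usual LD measure.
    Variants not in :attr:`variants` have unknown LD (see :meth:`has`).
    """

    variants: list[str]
    r: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variants)
        if self.r.shape != (n, n):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({n}, {n})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD correlations outside [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variants)}

    def __len__(self) -> int:
        return len(self.variants)

    def has(self, variant: str) -> bool:
        """Whether LD is known for *variant*."""
        return variant in self._index

    def corr(self, a: str, b: str) -> float:
        """Signed correlation r between two panel variants."""
        return float(self.r[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.corr(a, b) ** 2

    def submatrix(self, variants: list[str]) -> np.ndarray:
        """Dense r matrix restricted to *variants* (all must be in the panel)."""
        idx = [self._index[v] for v in variants]
        return self.r[np.ix_(idx, idx)]

    # -- persistence: dense whitespace-delimited matrix + sidecar variant list

    def write(self, prefix) -> None:
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".ld"), self.r, fmt="%.6g")
        prefix.with_suffix(".vars").write_text("\n".join(self.variants) + "\n")

    @classmethod
    def read(cls, prefix) -> "LDPanel":
        prefix = Path(prefix)
        variants = prefix.with_suffix(".vars").read_text().split()
        r = np.loadtxt(prefix.with_suffix(".ld"), ndmin=2)
        return cls(variants=variants, r=r)
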
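"""Risk-locus definition from genome-wide significant (GWS) variants.

The algorithm mirrors standard GWAS post-processing:

1. *Index variants*: greedy P-ordered clumping — repeatedly take the
   remaining GWS variant with the smallest p-value and discard all GWS
   variants in LD with it (r^2 > 0.1). Variants with unknown reference LD
   become singleton index candidates, optionally resolved against a
   secondary LD panel first (a candidate in LD with an existing index
   replaces it when its p-value is smaller).
2. *Blocks*: around each index, the interval spanning all GWS variants in
   high LD (r^2 > 0.6) with it; an index with no high-LD partner yields a
   1-bp locus. Blocks closer than 250 kb (end-to-start) are merged.
3. *Assignment*: every remaining GWS variant joins its nearest locus
   (boundary distance on the same chromosome), boundaries are updated and a
   final merge pass is applied.

Each locus is led by its minimum-p member and named after the nearest
protein-coding gene (or nearest noncoding gene when no protein-coding gene
lies within 250 kb), with a "Near" prefix when the lead variant does not
overlap any gene transcript.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ld import LDPanel

GWS_P = 5e-8


class ConsistencyError(ValueError):
    """Inputs disagree (e.g. an index variant missing from the GWS table)."""


@dataclass
class Locus:
    """A genomic risk interval (1-based inclusive) with its variants."""

    chrom: str
    start: int
    end: int
    index_variants: list[str]
    members: list[str]
    lead: str | None = None
    lead_p: float | None = None
    name: str | None = None
    is_near: bool | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start > end")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def _variant_order(gws: pd.DataFrame) -> pd.DataFrame:
    """Deterministic p-ascending order; ties by (CHR, BP, EA, OA)."""
    df = gws.copy()
    if "MLOG10P" in df.columns:
        df["_SCORE"] = -df["MLOG10P"].astype(float)
    else:
        df["_SCORE"] = np.log10(df["P"].astype(float))
    return df.sort_values(["_SCORE", "CHR", "BP", "EA", "OA"],
                          kind="mergesort").reset_index(drop=True)


def select_index_variants(gws: pd.DataFrame, panel: LDPanel,
                          r2_index: float = 0.1,
                          panel2: LDPanel | None = None) -> list[str]:
    """Greedy P-ordered clumping of GWS variants at ``r^2 < r2_index``.

    Variants covered by *panel* are clumped greedily. Variants with unknown
    LD are resolved against *panel2* when provided (in LD with an index:
    absorbed, or replacing the index if their p is smaller) and otherwise
    promoted to singleton index candidates.
    """
    if gws.empty:
        return []
    ordered = _variant_order(gws)
    score = dict(zip(ordered["SNP"], ordered["_SCORE"]))
    known = [s for s in ordered["SNP"] if panel.has(s)]
    unknown = [s for s in ordered["SNP"] if not panel.has(s)]

    indices: list[str] = []
    remaining = list(known)
    while remaining:
        top = remaining[0]
        indices.append(top)
        remaining = [v for v in remaining[1:]
                     if panel.r2(top, v) <= r2_index]

    for v in unknown:
        partners = []
        if panel2 is not None and panel2.has(v):
            partners = [(panel2.r2(v, ix), ix) for ix in indices
                        if panel2.has(ix) and panel2.r2(v, ix) > r2_index]
        if partners:
            r2_best, ix_best = max(partners)
            if score[v] < score[ix_best]:
                indices[indices.index(ix_best)] = v
        else:
            indices.append(v)

    return sorted(indices, key=lambda s: score[s])


def _merge_pass(loci: list[Locus], merge_gap: int) -> list[Locus]:
    """Merge same-chromosome loci separated by less than *merge_gap* bp."""
    loci = sorted(loci, key=lambda lo: (lo.chrom, lo.start, lo.end))
    out: list[Locus] = []
    for lo in loci:
        if out and out[-1].chrom == lo.chrom and lo.start - out[-1].end < merge_gap:
            prev = out[-1]
            prev.start = min(prev.start, lo.start)
            prev.end = max(prev.end, lo.end)
            prev.index_variants = prev.index_variants + lo.index_variants
            prev.members = prev.members + [m for m in lo.members
                                           if m not in prev.members]
        else:
            out.append(lo)
    return out


def define_loci(indices: list[str], gws: pd.DataFrame, panel: LDPanel,
                r2_block: float = 0.6, merge_gap: int = 250_000) -> list[Locus]:
    """Build risk loci around *indices* in three passes.

    (1) span the high-LD block of each index and merge blocks closer than
    *merge_gap*; (2) assign every remaining GWS variant to its nearest locus
    (boundary distance, ties to the lower-coordinate locus) and update
    boundaries; (3) final merge pass. On output, same-chromosome loci are
    separated by at least *merge_gap*.
    """
    snps = set(gws["SNP"])
    for ix in indices:
        if ix not in snps:
            raise ConsistencyError(f"index variant {ix} not in the GWS table")
    info = gws.set_index("SNP")

    loci: list[Locus] = []
    for ix in indices:
        chrom = str(info.loc[ix, "CHR"])
        positions = [int(info.loc[ix, "BP"])]
        members = [ix]
        if panel.has(ix):
            for v in gws["SNP"]:
                if v != ix and str(info.loc[v, "CHR"]) == chrom \
                        and panel.has(v) and panel.r2(ix, v) > r2_block:
                    positions.append(int(info.loc[v, "BP"]))
                    members.append(v)
        loci.append(Locus(chrom=chrom, start=min(positions), end=max(positions),
                          index_variants=[ix], members=members))
    loci = _merge_pass(loci, merge_gap)

    assigned = {m for lo in loci for m in lo.members}
    snapshot = [(lo.chrom, lo.start, lo.end) for lo in loci]
    for v in gws["SNP"]:
        if v in assigned:
            continue
        chrom = str(info.loc[v, "CHR"])
        bp = int(info.loc[v, "BP"])
        best = None
        for lo, (c, start, end) in zip(loci, snapshot):
            if c != chrom:
                continue
            dist = 0 if start <= bp <= end else min(abs(bp - start), abs(bp - end))
            key = (dist, start)
            if best is None or key < best[0]:
                best = (key, lo)
        if best is None:
            raise ConsistencyError(
                f"GWS variant {v} on chromosome {chrom} has no locus to join")
        lo = best[1]
        lo.members.append(v)
        lo.start = min(lo.start, bp)
        lo.end = max(lo.end, bp)

    return _merge_pass(loci, merge_gap)


# -- gene annotation and naming ---------------------------------------------

def read_gene_bed(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open) with name and biotype.

    Expected columns: chrom, start, end, name, biotype. Converted to
    1-based inclusive coordinates.
    """
    genes = pd.read_csv(path, sep="\t", header=None,
                        names=["CHR", "START", "END", "NAME", "BIOTYPE"],
                        dtype={"CHR": str})
    genes["START"] = genes["START"].astype(int) + 1
    genes["END"] = genes["END"].astype(int)
    return genes


def name_and_lead(locus: Locus, gws: pd.DataFrame,
                  genes: pd.DataFrame | None,
                  window: int = 250_000) -> Locus:
    """Set the lead variant (minimum p among members) and the locus name.

    The name is the nearest protein-coding gene to the lead variant, or the
    nearest noncoding gene when no protein-coding gene lies within *window*
    bp; "Near" is prefixed when the lead does not overlap any transcript.
    With no gene available at all the name falls back to ``chr:pos``.
    """
    ordered = _variant_order(gws[gws["SNP"].isin(locus.members)])
    lead = ordered.iloc[0]
    locus.lead = str(lead["SNP"])
    locus.lead_p = float(lead["P"])
    pos = int(lead["BP"])

    if genes is None or genes.empty:
        locus.name = f"chr{locus.chrom}:{pos}"
        locus.is_near = True
        return locus
    g = genes.loc[genes["CHR"].astype(str) == str(locus.chrom)].copy()
    if g.empty:
        locus.name = f"chr{locus.chrom}:{pos}"
        locus.is_near = True
        return locus

    g["DIST"] = np.maximum.reduce([
        np.zeros(len(g)), g["START"].to_numpy() - pos, pos - g["END"].to_numpy()])
    g = g.sort_values(["DIST", "START", "NAME"], kind="mergesort")
    locus.is_near = not bool((g["DIST"] == 0).any())

    pc = g.loc[g["BIOTYPE"] == "protein_coding"]
    if len(pc) and pc["DIST"].iloc[0] <= window:
        name = str(pc["NAME"].iloc[0])
    else:
        nc = g.loc[g["BIOTYPE"] != "protein_coding"]
        if len(nc):
            name = str(nc["NAME"].iloc[0])
        else:
            locus.name = f"chr{locus.chrom}:{pos}"
            locus.is_near = True
            return locus
    locus.name = f"Near {name}" if locus.is_near else name
    return locus


def call_risk_loci(meta_table: pd.DataFrame, panel: LDPanel,
                   genes: pd.DataFrame | None = None,
                   gws_p: float = GWS_P,
                   r2_index: float = 0.1, r2_block: float = 0.6,
                   merge_gap: int = 250_000,
                   panel2: LDPanel | None = None) -> list[Locus]:
    """End-to-end locus calling on a meta-analysis table."""
    gws = meta_table.loc[meta_table["P"] < gws_p].reset_index(drop=True)
    indices = select_index_variants(gws, panel, r2_index, panel2=panel2)
    loci = define_loci(indices, gws, panel, r2_block, merge_gap)
    return [name_and_lead(lo, gws, genes) for lo in loci]


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame([{
        "CHR": lo.chrom, "START": lo.start, "END": lo.end,
        "N_MEMBERS": len(lo.members), "LEAD_SNP": lo.lead,
        "LEAD_P": lo.lead_p, "NAME": lo.name,
    } for lo in loci])


def write_loci(loci: list[Locus], prefix) -> None:
    """Write the locus table (TSV) and memberships (JSON) under *prefix*."""
    prefix = Path(prefix)
    loci_table(loci).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    payload = [{
        "chrom": lo.chrom, "start": lo.start, "end": lo.end,
        "index_variants": lo.index_variants, "members": lo.members,
        "lead": lo.lead, "name": lo.name, "is_near": lo.is_near,
    } for lo in loci]
    prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2))
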
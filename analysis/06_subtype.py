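#!/usr/bin/env python
"""Classify variants as NULL / MO / MA / BOTH from paired subtype data.

The estimator correlation c is estimated the way the study does it — from
a genome-wide, predominantly null set of common variants without strong
subtype association (a separate 20,000-variant all-NULL simulation at the
generating c = 0.148); estimating it on the lead-variant-like set itself
would be upward-biased by the many true shared effects there. Every
variant of the lead-like set is then classified by the four-model Bayesian
comparison (tau = 0.2, equal model priors, 95% labelling threshold) and
tested for effect-size equality at the Bonferroni level 0.05/123.
Recovery is summarized against the hidden generating labels.

Inputs: scratch/sim/subtype_*.tsv. Outputs: results/subtype_labels.tsv,
results/subtype_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from migwas.dialect import read_sumstats
from migwas.subtype import SubtypePrior, classify_table, estimate_correlation
from migwas.synth import SimConfig, simulate_subtype_pairs

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main():
    mo = read_sumstats(SIM / "subtype_mo.tsv")
    ma = read_sumstats(SIM / "subtype_ma.tsv")
    truth = pd.read_csv(SIM / "subtype_truth.tsv", sep="\t",
                        dtype={"SNP": str})

    null_cfg = SimConfig(n_variants=20_000,
                         subtype_model_probs=(1, 0, 0, 0), seed=2028)
    _, null_mo, null_ma = simulate_subtype_pairs(null_cfg)
    c_hat = estimate_correlation(null_mo, null_ma)
    prior = SubtypePrior(corr=c_hat)
    table = classify_table(mo, ma, prior)
    table.to_csv(RESULTS / "subtype_labels.tsv", sep="\t", index=False,
                 float_format="%.6g")

    merged = table.merge(truth[["SNP", "MODEL"]], on="SNP")
    label_counts = merged["LABEL"].value_counts().to_dict()
    labelled = merged[merged["LABEL"] != "unresolved"]
    precision = float((labelled["LABEL"] == labelled["MODEL"]).mean()) \
        if len(labelled) else float("nan")
    n_diff = int(merged["DIFF_FLAG"].sum())

    summary = {
        "estimated_corr": c_hat,
        "n_variants": len(merged),
        "label_counts": label_counts,
        "assigned_label_precision": precision,
        "n_difference_flags": n_diff,
    }
    (RESULTS / "subtype_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(f"estimated estimator correlation c = {c_hat:.4f} "
          f"(generator truth 0.148)")
    print(f"labels at 95% posterior: {label_counts}")
    print(f"precision of assigned labels vs generating model: "
          f"{precision:.3f}")
    print(f"{n_diff} variants with MO/MA effect difference at 0.05/123")


if __name__ == "__main__":
    main()
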
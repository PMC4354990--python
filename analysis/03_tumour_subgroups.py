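#!/usr/bin/env python
"""Supervised discovery of the two Wilms-tumour subgroups.

Three-tissue moderated ANOVA on complete trios -> consensus clustering of
the genome-wide-significant CpGs (p < 5e-8) -> subgroup assignment
(tumours clustering apart from the rests are group-1) -> chi-square test
of the association between group-1 membership and bilateral disease ->
Bartlett comparison of probe-wise variance between the two groups."""

import argparse
import json
from pathlib import Path

import pandas as pd

from trioepi import diffmeth
from trioepi.io import load_cohort
from trioepi.pipeline import assign_wt_subgroups
from trioepi.subtypes import bartlett_per_probe, cluster_association, consensus_cluster


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixture-dir", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = load_cohort(args.fixture_dir)
    trio = cohort.samples[cohort.samples["tissue"].isin(("NK", "NR", "WT"))]
    beta = cohort.beta[trio.index]

    anova = diffmeth.fit_anova3(beta, trio)
    sig = diffmeth.significant_probes(anova, fdr=None, p=5e-8)
    print(f"ANOVA: {len(sig)} CpGs at genome-wide significance (p < 5e-8)")

    clust = consensus_cluster(beta.loc[sig], k=3, n_resamples=500, seed=args.seed)
    subgroups = assign_wt_subgroups(clust.assignments, trio)
    n1 = int((subgroups == "group1").sum())
    n2 = int((subgroups == "group2").sum())
    print(f"WT subgroups: group-1 n = {n1}, group-2 n = {n2}")

    wt = trio[trio["tissue"] == "WT"].copy()
    wt["subgroup"] = wt["patient_id"].map(subgroups)
    chi2, df, p, table = cluster_association(
        pd.Series(wt["subgroup"].values, index=wt.index),
        pd.Series(wt["laterality"].values, index=wt.index),
    )
    print(f"subgroup x laterality: chi2 = {chi2:.2f} (df {df}), P = {p:.3g}")
    print(table.to_string())

    g1s = list(wt.index[wt["subgroup"] == "group1"])
    g2s = list(wt.index[wt["subgroup"] == "group2"])
    comp = bartlett_per_probe(beta, {"group1": g1s, "group2": g2s}, alpha=0.01)
    ratio = comp.counts["group1"] / max(comp.counts["group2"], 1)
    print(f"hypervariability: {comp.counts['group1']} probes more variable in "
          f"group-1 vs {comp.counts['group2']} in group-2 "
          f"({ratio:.1f}x, of {comp.n_significant} significant)")

    out = {
        "n_genomewide_cpgs": len(sig),
        "n_group1": n1, "n_group2": n2,
        "laterality_chi2": chi2, "laterality_p": p,
        "hypervariable_group1": comp.counts["group1"],
        "hypervariable_group2": comp.counts["group2"],
        "subgroups": subgroups.to_dict(),
    }
    (args.out_dir / "03_subgroups.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
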
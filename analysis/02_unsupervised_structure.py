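#!/usr/bin/env python
"""Unsupervised structure of the cohort: consensus clustering and MDS of the
top-1% most variable probes, and probe-wise variance comparisons.

Expects the fixture from 01_simulate_cohort.py.  Reports how the three
tissue types separate without supervision, how dispersed each tissue is
in the embedding, and how many probes show significantly higher variance
in NR/WT than in NK (the hallmark of the precursor lesion and tumour
methylomes)."""

import argparse
from pathlib import Path

import numpy as np

from trioepi.io import load_cohort
from trioepi.preprocess import top_variable
from trioepi.subtypes import bartlett_per_probe, consensus_cluster, mds


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

    top = top_variable(beta, fraction=0.01)
    clust = consensus_cluster(beta.loc[top], k=3, n_resamples=500, seed=args.seed)
    comp = clust.assignments.to_frame().join(trio["tissue"])
    table = comp.groupby(["cluster", "tissue"]).size().unstack(fill_value=0)
    table.to_csv(args.out_dir / "02_cluster_composition.tsv", sep="\t")
    print("consensus clusters (top 1% IQR probes) x tissue:")
    print(table.to_string())

    coords = mds(beta.loc[top], n_dims=2)
    coords.join(trio["tissue"]).to_csv(args.out_dir / "02_mds_coordinates.tsv", sep="\t")
    for tissue in ("NK", "NR", "WT"):
        pts = coords.loc[trio.index[trio["tissue"] == tissue]].to_numpy()
        disp = np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean()
        print(f"MDS dispersion {tissue}: {disp:.3f}")

    groups = {t: list(trio.index[trio["tissue"] == t]) for t in ("NK", "NR", "WT")}
    for a, b in (("NK", "NR"), ("NK", "WT")):
        res = bartlett_per_probe(beta, {a: groups[a], b: groups[b]}, alpha=0.01)
        print(f"variance comparison {a} vs {b}: "
              f"N_{a}>{b} = {res.counts[a]}, N_{b}>{a} = {res.counts[b]} "
              f"(of {res.n_significant} significant probes)")
        # the full per-probe table is large; keep it out of results/
        res.table.to_csv(Path("scratch") / f"02_bartlett_{a}_vs_{b}.tsv", sep="\t")


if __name__ == "__main__":
    main()
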
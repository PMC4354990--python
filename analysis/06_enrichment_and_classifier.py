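#!/usr/bin/env python
"""Feature enrichment of KR-DMRs and the mean+1SD hypermethylation
classifier.

Tests whether hypermethylated kidney-rest DMR probes fall inside the
bivalent-domain feature set more often than equal-sized random draws
from the probe universe (multisampling enrichment, empirical p), then
classifies each group-1 tumour as hypermethylated at each hyper-WT-DMR
when its mean beta exceeds the NR-cohort mean plus one SD — the
frequency table is the biomarker readout."""

import argparse
import json
from pathlib import Path

import pandas as pd

from trioepi import diffmeth, dmr, enrich
from trioepi.io import load_cohort
from trioepi.preprocess import filter_probes


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
    subgroups = json.loads((args.out_dir / "03_subgroups.json").read_text())["subgroups"]
    g1 = sorted(p for p, s in subgroups.items() if s == "group1")

    filtered, _ = filter_probes(beta, cohort.probes,
                                drop_flags=("sex_chromosome", "snp_at_target", "multimap"))
    universe = list(filtered.index)
    lassos = dmr.compute_lassos(cohort.probes)

    nr_mvps = diffmeth.fit_paired(beta, trio, "NR", "NK")
    kr_dmrs = dmr.call_dmrs(nr_mvps, cohort.probes, lassos)
    rows = []
    for direction in ("hyper", "hypo"):
        probes = sorted({p for r in kr_dmrs if r.direction == direction
                         for p in r.probe_ids if p in filtered.index})
        if not probes:
            continue
        for res in enrich.multisample_enrichment(probes, universe, cohort.probes,
                                                 cohort.features, n_resamples=100,
                                                 seed=args.seed):
            rows.append({"query": f"{direction}-KR-DMR", **res.__dict__})
            print(f"{direction}-KR-DMR in {res.feature_name}: observed "
                  f"{res.observed_fraction:.1%} vs null {res.null_mean_fraction:.1%} "
                  f"-> {res.enrichment_pp:+.1f} pp, empirical P = {res.empirical_p:.3g}")
    pd.DataFrame(rows).to_csv(args.out_dir / "06_enrichment.tsv", sep="\t", index=False)

    wt_mvps = diffmeth.fit_paired(beta, trio, "WT", "NR", patients=g1)
    wt_dmrs = [r for r in dmr.call_dmrs(wt_mvps, cohort.probes, lassos)
               if r.direction == "hyper"]
    tumours = sorted(s for s in trio.index
                     if trio.at[s, "tissue"] == "WT" and trio.at[s, "patient_id"] in g1)
    rests = sorted(trio.index[trio["tissue"] == "NR"])
    calls, freq = enrich.classify_hypermethylation(beta, wt_dmrs, tumours, rests)
    freq.to_csv(args.out_dir / "06_hypermethylation_frequencies.tsv", sep="\t", index=False)
    print("\nhypermethylated tumours per hyper-WT-DMR (mean+1SD rule):")
    print(freq[["dmr", "frequency"]].to_string(index=False))


if __name__ == "__main__":
    main()
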
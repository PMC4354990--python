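#!/usr/bin/env python
"""Comparison of NR and WT methylomes with embryonic kidney (EK).

The EK samples are unmatched, so both contrasts use the reference-free
adjustment with an unpaired design; pheno-MVPs are filtered at p < 0.01
AND |delta beta| > 0.2, and the hypermethylated set is tested for
enrichment in the PRC2-target feature set."""

import argparse
import json
from pathlib import Path

from trioepi.io import load_cohort
from trioepi.pipeline import RunConfig, run_ek_comparison


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixture-dir", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cohort = load_cohort(args.fixture_dir)
    report = run_ek_comparison(cohort, RunConfig(seed=args.seed))
    for contrast, payload in report["contrasts"].items():
        print(f"{contrast}: {payload['n_mvps']} pheno-MVPs "
              f"(p < 0.01, |dB| > 0.2): {payload['n_hyper']} hyper, "
              f"{payload['n_hypo']} hypo")
        for e in payload.get("enrichment", []):
            print(f"  {e['feature_name']}: {e['enrichment_pp']:+.1f} pp, "
                  f"empirical P = {e['empirical_p']:.3g}")
    args.out_dir.mkdir(parents=True, exist_ok=True)
    (args.out_dir / "07_ek_comparison.json").write_text(
        json.dumps(report["contrasts"], indent=1, default=str)
    )


if __name__ == "__main__":
    main()
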
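"""End-to-end orchestration of the trio analysis and the embryonic-kidney
comparison.

The trio analysis runs, in order: probe filtering -> three-tissue
moderated ANOVA -> consensus clustering of the genome-wide-significant
CpGs -> WT subgroup assignment -> per-subgroup paired WT-NR MVPs -> DMR
calling -> NK-NR MVPs/DMRs -> reference-free pheno-MVPs for both
contrasts -> MVP overlap statistics -> feature enrichment -> DMR
hypermethylation classification.  Every stage's headline counts go into
a JSON-serialisable run report; tables are written as TSV/BED when an
output directory is given.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import deconv, diffmeth, dmr, enrich, preprocess, subtypes
from .io import Cohort, TISSUES, write_bed

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and seeds for the full pipeline (defaults are the study's
    printed operating points: MVPs at FDR < 0.01, genome-wide ANOVA
    significance at p < 5e-8, probe-lasso minimum 10 bp / 3 significant
    probes / 1 kb merging, top 1% variable probes, pheno-MVPs at
    p < 0.01 with |delta-beta| > 0.2)."""

    fdr: float = 0.01
    genomewide_p: float = 5e-8
    min_sig_probes: int = 3
    min_lasso_bp: float = 10.0
    merge_gap_bp: float = 1000.0
    top_frac: float = 0.01
    reffree_p: float = 0.01
    reffree_delta_beta: float = 0.2
    reffree_d: int = 3
    n_bootstrap: int = 100
    consensus_resamples: int = 200
    consensus_k: int | None = 3
    drop_flags: tuple = ("sex_chromosome", "snp_at_target", "multimap")
    seed: int = 0
    contrasts: tuple = (("NR", "NK"), ("WT", "NR"))

    def validate(self, cohort: Cohort) -> None:
        for name in ("fdr", "genomewide_p", "min_lasso_bp", "merge_gap_bp",
                     "top_frac", "reffree_p", "reffree_delta_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        tissues = set(cohort.samples["tissue"])
        unknown = tissues - set(TISSUES)
        if unknown:
            raise ValueError(f"unknown tissue labels {sorted(unknown)}")
        for a, b in self.contrasts:
            if a not in tissues or b not in tissues:
                raise ValueError(f"contrast {a}-{b} references a tissue absent from the sheet")


def assign_wt_subgroups(
    assignments: pd.Series, samples: pd.DataFrame, override: dict | None = None
) -> pd.Series:
    """Label each WT-bearing patient group1/group2 from cluster membership.

    Tumours in a WT-dominant cluster (more than half of its members are
    WT) are distinct from the rests -> group-1; tumours sharing a
    cluster with their precursor NRs -> group-2.  ``override`` maps
    patient id to an explicit label.
    """
    tissue = samples.loc[assignments.index, "tissue"]
    wt_dominant = set()
    for c in assignments.unique():
        members = assignments.index[assignments == c]
        frac_wt = (tissue.loc[members] == "WT").mean()
        if frac_wt > 0.5:
            wt_dominant.add(c)
    labels = {}
    for s in assignments.index:
        if tissue[s] != "WT":
            continue
        patient = samples.at[s, "patient_id"]
        labels[patient] = "group1" if assignments[s] in wt_dominant else "group2"
    if override:
        labels.update(override)
    return pd.Series(labels, name="subgroup")


def run_trio_analysis(
    cohort: Cohort, config: RunConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Execute the full matched-trio analysis; returns the run report dict."""
    config = config or RunConfig()
    config.validate(cohort)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": asdict(config), "stages": {}}

    def _stage(name, payload):
        report["stages"][name] = payload
        logger.info("stage %s: %s", name, payload)

    trio_samples = cohort.samples[cohort.samples["tissue"].isin(("NK", "NR", "WT"))]
    beta = cohort.beta[trio_samples.index]

    # 1. filtering: the ANOVA excludes sex-chromosome/SNP/multimapping probes
    filtered, filt_report = preprocess.filter_probes(
        beta, cohort.probes, drop_flags=config.drop_flags
    )
    _stage("filter", {
        "probes_in": filt_report.probes_in,
        "probes_out": filt_report.probes_out,
        "removed_by_flag": filt_report.probes_removed_by_flag,
    })

    # 2. three-tissue moderated ANOVA on complete trios
    anova = diffmeth.fit_anova3(filtered, trio_samples)
    anova_sig = diffmeth.significant_probes(anova, fdr=None, p=config.genomewide_p)
    _stage("anova", {"n_tested": int(anova["p"].notna().sum()),
                     "n_genomewide": len(anova_sig)})
    if out is not None:
        anova.to_csv(out / "anova_mvps.tsv", sep="\t")

    # 3. consensus clustering of the significant CpGs; WT subgroup assignment
    clust = subtypes.consensus_cluster(
        beta.loc[anova_sig],
        k=config.consensus_k,
        n_resamples=config.consensus_resamples,
        seed=config.seed,
    )
    subgroups = assign_wt_subgroups(clust.assignments, trio_samples)
    g1 = sorted(subgroups.index[subgroups == "group1"])
    g2 = sorted(subgroups.index[subgroups == "group2"])
    _stage("subtypes", {"k": clust.k, "n_group1": len(g1), "n_group2": len(g2)})
    if out is not None:
        clust.assignments.to_frame().join(subgroups, on=None, how="left").to_csv(
            out / "clusters.tsv", sep="\t"
        )

    # 4. paired WT-NR MVPs per subgroup (matched design: flagged probes kept)
    lassos = dmr.compute_lassos(cohort.probes, min_lasso_bp=config.min_lasso_bp)
    paired_results = {}
    dmr_results: dict[str, list] = {}
    for label, patients in (("group1", g1), ("group2", g2)):
        if len(patients) < 2:
            paired_results[label] = None
            _stage(f"mvp_WT-NR_{label}", {"n_pairs": len(patients), "n_mvps": 0,
                                          "skipped": "fewer than 2 pairs"})
            continue
        mvps = diffmeth.fit_paired(beta, trio_samples, "WT", "NR", patients=patients)
        sig = diffmeth.significant_probes(mvps, fdr=config.fdr)
        paired_results[label] = mvps
        _stage(f"mvp_WT-NR_{label}", {"n_pairs": len(patients), "n_mvps": len(sig)})
        if out is not None:
            mvps.to_csv(out / f"mvps_WT-NR_{label}.tsv", sep="\t")

    # 5. DMRs for the group-1 WT-NR contrast
    if paired_results.get("group1") is not None:
        wt_dmrs = dmr.call_dmrs(
            paired_results["group1"], cohort.probes, lassos,
            sig_fdr=config.fdr, min_sig_probes=config.min_sig_probes,
            merge_gap_bp=config.merge_gap_bp,
        )
    else:
        wt_dmrs = []
    dmr_results["WT-NR"] = wt_dmrs
    _stage("dmr_WT-NR", _dmr_counts(wt_dmrs))

    # 6. NK-NR contrast: paired MVPs and KR-DMRs
    nr_mvps = diffmeth.fit_paired(beta, trio_samples, "NR", "NK")
    nr_sig = diffmeth.significant_probes(nr_mvps, fdr=config.fdr)
    kr_dmrs = dmr.call_dmrs(
        nr_mvps, cohort.probes, lassos,
        sig_fdr=config.fdr, min_sig_probes=config.min_sig_probes,
        merge_gap_bp=config.merge_gap_bp,
    )
    dmr_results["NR-NK"] = kr_dmrs
    _stage("mvp_NR-NK", {"n_mvps": len(nr_sig)})
    _stage("dmr_NR-NK", _dmr_counts(kr_dmrs))
    if out is not None:
        nr_mvps.to_csv(out / "mvps_NR-NK.tsv", sep="\t")
        for key, regions in dmr_results.items():
            frame = dmr.dmrs_to_frame(regions)
            frame.to_csv(out / f"dmrs_{key}.tsv", sep="\t", index=False)
            if len(frame):
                write_bed(frame, out / f"dmrs_{key}.bed",
                          extra_cols=["n_significant", "direction", "combined_p"])

    # 7. reference-free pheno-MVPs for both contrasts
    overlaps = {}
    for (a, b), raw, label in (
        (("NR", "NK"), nr_mvps, "NR-NK"),
        (("WT", "NR"), paired_results.get("group1"), "WT-NR_group1"),
    ):
        patients = g1 if label.endswith("group1") else None
        if patients is not None and len(patients) < 2:
            overlaps[label] = {"skipped": "fewer than 2 group-1 pairs"}
            _stage(f"pheno_mvp_{label}", overlaps[label])
            continue
        reffree = deconv.reffree_fit(
            beta, trio_samples, a, b, paired=True, d=config.reffree_d,
            n_bootstrap=config.n_bootstrap, seed=config.seed, patients=patients,
        )
        pheno = set(reffree.p.index[(reffree.p < config.reffree_p).fillna(False)])
        payload = {"n_pheno_mvps": len(pheno)}
        if raw is not None:
            limma_sig = diffmeth.significant_probes(raw, fdr=config.fdr)
            n_shared, frac = deconv.overlap_mvps(limma_sig, pheno)
            payload.update({"n_uncorrected_mvps": len(limma_sig),
                            "n_overlap": n_shared, "fraction_of_uncorrected": frac})
        overlaps[label] = payload
        _stage(f"pheno_mvp_{label}", payload)

    # 8. enrichment of KR-DMR probes in the provided feature sets
    universe = list(filtered.index)
    enrich_rows = []
    for direction in ("hyper", "hypo"):
        probes = sorted({
            p for r in kr_dmrs if r.direction == direction for p in r.probe_ids
            if p in filtered.index
        })
        if not probes or not cohort.features:
            continue
        for res in enrich.multisample_enrichment(
            probes, universe, cohort.probes, cohort.features,
            n_resamples=config.n_bootstrap, seed=config.seed,
        ):
            enrich_rows.append({"query": f"{direction}_KR-DMR", **res.__dict__})
    _stage("enrichment", {"n_tests": len(enrich_rows)})
    if out is not None and enrich_rows:
        pd.DataFrame(enrich_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # 9. hypermethylation classification of hyper-WT-DMRs in group-1 tumours
    hyper_wt = [r for r in wt_dmrs if r.direction == "hyper"]
    tumours = sorted(
        trio_samples.index[(trio_samples["tissue"] == "WT")
                           & trio_samples["patient_id"].isin(g1)]
    )
    rests = sorted(trio_samples.index[trio_samples["tissue"] == "NR"])
    if hyper_wt and len(tumours) >= 1 and len(rests) >= 2:
        calls, freq = enrich.classify_hypermethylation(beta, hyper_wt, tumours, rests)
        _stage("hypermethylation", {
            "n_dmrs": len(hyper_wt),
            "frequencies": dict(zip(freq["dmr"], freq["frequency"])),
        })
        if out is not None:
            calls.to_csv(out / "hypermethylation_calls.tsv", sep="\t", index=False)
            freq.to_csv(out / "hypermethylation_freq.tsv", sep="\t", index=False)
    else:
        _stage("hypermethylation", {"n_dmrs": len(hyper_wt), "skipped": "insufficient samples"})

    report["enrichment"] = enrich_rows
    report["overlaps"] = overlaps
    if out is not None:
        (out / "run_report.json").write_text(json.dumps(_jsonable(report), indent=1))
    return report


def run_ek_comparison(
    cohort: Cohort, config: RunConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Unpaired reference-free contrasts of NR and WT against embryonic
    kidney, with pheno-MVPs at p < ``reffree_p`` AND |delta-beta| >
    ``reffree_delta_beta`` and enrichment of the hyper-MVPs."""
    config = config or RunConfig()
    ek = cohort.samples.index[cohort.samples["tissue"] == "EK"]
    if len(ek) < 2:
        raise ValueError("need >= 2 EK samples")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": asdict(config), "contrasts": {}}

    filtered, _ = preprocess.filter_probes(
        cohort.beta, cohort.probes, drop_flags=config.drop_flags
    )
    universe = list(filtered.index)

    for tissue in ("NR", "WT"):
        res = deconv.reffree_fit(
            cohort.beta, cohort.samples, tissue, "EK", paired=False,
            d=config.reffree_d, n_bootstrap=config.n_bootstrap, seed=config.seed,
        )
        mask = ((res.p < config.reffree_p)
                & (res.coef.abs() > config.reffree_delta_beta)).fillna(False)
        hyper = sorted(res.p.index[mask & (res.coef > 0)])
        hypo = sorted(res.p.index[mask & (res.coef < 0)])
        payload = {"n_mvps": int(mask.sum()), "n_hyper": len(hyper), "n_hypo": len(hypo)}
        if hyper and cohort.features:
            hyper_in_universe = [p for p in hyper if p in filtered.index]
            if hyper_in_universe:
                enr = enrich.multisample_enrichment(
                    hyper_in_universe, universe, cohort.probes, cohort.features,
                    n_resamples=config.n_bootstrap, seed=config.seed,
                )
                payload["enrichment"] = [r.__dict__ for r in enr]
        report["contrasts"][f"{tissue}-EK"] = payload
        if out is not None:
            pd.DataFrame({"coef": res.coef, "p": res.p}).to_csv(
                out / f"pheno_mvps_{tissue}-EK.tsv", sep="\t"
            )
    if out is not None:
        (out / "ek_report.json").write_text(json.dumps(_jsonable(report), indent=1))
    return report


def _dmr_counts(regions) -> dict:
    hyper = sum(1 for r in regions if r.direction == "hyper")
    return {"n_dmrs": len(regions), "n_hyper": hyper, "n_hypo": len(regions) - hyper}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
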
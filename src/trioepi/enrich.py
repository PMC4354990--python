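"""Resampling ("multisampling") enrichment of probe sets in genomic feature
sets, and the mean+1SD DMR hypermethylation classifier."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import probes_in_intervals


@dataclass
class EnrichmentResult:
    feature_name: str
    observed_fraction: float
    null_mean_fraction: float
    enrichment_pp: float      # observed - null mean, in percentage points
    empirical_p: float
    side: str                 # 'positive' or 'negative'
    n_resamples: int
    query_size: int


def multisample_enrichment(
    query_probes,
    universe,
    ann: pd.DataFrame,
    features: dict[str, pd.DataFrame],
    n_resamples: int = 100,
    seed: int = 0,
    side: str = "auto",
) -> list[EnrichmentResult]:
    """Empirical feature enrichment of a probe set against equal-size draws
    from the probe universe.

    For each feature set, the observed in-feature fraction of the query
    is compared with ``n_resamples`` draws of the same size taken
    without replacement from ``universe`` (all post-filter probes).
    Enrichment is reported in percentage points; the empirical p is
    ``(1 + #{draws at least as extreme}) / (1 + n_resamples)``, with the
    side (>= observed for positive enrichment, <= for negative) chosen
    by the sign of the enrichment when ``side="auto"``.  Its floor is
    1/(n_resamples + 1) (0.0099 at the default 100 resamples).

    ``side="positive"`` (or ``"negative"``) fixes the direction; only a
    fixed-side p is exactly uniform under the null — the adaptive choice
    reports the smaller tail and is therefore bounded near one half.
    """
    if side not in ("auto", "positive", "negative"):
        raise ValueError("side must be 'auto', 'positive' or 'negative'")
    universe = pd.Index(universe)
    query = pd.Index(query_probes)
    if len(query) > len(universe):
        raise ValueError("query is larger than the probe universe")
    if not query.isin(universe).all():
        raise ValueError("query probes must be a subset of the universe")

    sub_ann = ann.loc[universe]
    rng = np.random.default_rng(seed)
    draws = [rng.choice(len(universe), size=len(query), replace=False) for _ in range(n_resamples)]

    results = []
    for name in sorted(features):
        inside = probes_in_intervals(sub_ann, features[name]).to_numpy()
        q_idx = universe.get_indexer(query)
        observed = float(inside[q_idx].mean()) if len(query) else float("nan")
        null = np.array([inside[d].mean() for d in draws])
        null_mean = float(null.mean())
        enrichment = (observed - null_mean) * 100.0
        this_side = side if side != "auto" else (
            "positive" if observed >= null_mean else "negative"
        )
        if this_side == "positive":
            p = (1.0 + int((null >= observed).sum())) / (1.0 + n_resamples)
        else:
            p = (1.0 + int((null <= observed).sum())) / (1.0 + n_resamples)
        results.append(
            EnrichmentResult(
                feature_name=name,
                observed_fraction=observed,
                null_mean_fraction=null_mean,
                enrichment_pp=enrichment,
                empirical_p=p,
                side=this_side,
                n_resamples=n_resamples,
                query_size=len(query),
            )
        )
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def classify_hypermethylation(
    beta: pd.DataFrame,
    dmrs,
    tumour_samples: list[str],
    reference_samples: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean+1SD hypermethylation calls per DMR per tumour.

    For each region, every sample's DMR level is the NA-robust mean beta
    over the member probes.  The reference (NR-cohort) threshold is the
    mean of the per-reference-sample DMR levels plus one sample standard
    deviation (ddof = 1); a tumour is called hypermethylated when its
    level is strictly greater.  Returns the per-call table and a per-DMR
    frequency table with ``"x of n"`` strings.
    """
    if len(reference_samples) < 2:
        raise ValueError("reference cohort must have >= 2 samples (SD undefined)")

    calls = []
    freq = []
    for r in dmrs:
        probe_ids = [p for p in r.probe_ids if p in beta.index]
        levels = beta.loc[probe_ids].mean(axis=0, skipna=True)
        ref = levels[reference_samples]
        ref_mean = float(ref.mean())
        ref_sd = float(ref.std(ddof=1))
        threshold = ref_mean + ref_sd
        n_hyper = 0
        for s in tumour_samples:
            level = float(levels[s])
            call = level > threshold
            n_hyper += int(call)
            calls.append({
                "dmr": r.name or f"{r.chrom}:{r.start}-{r.end}",
                "sample": s,
                "tumour_mean": level,
                "reference_mean": ref_mean,
                "reference_sd": ref_sd,
                "threshold": threshold,
                "hypermethylated": call,
            })
        freq.append({
            "dmr": r.name or f"{r.chrom}:{r.start}-{r.end}",
            "n_hypermethylated": n_hyper,
            "n_tumours": len(tumour_samples),
            "frequency": f"{n_hyper} of {len(tumour_samples)}",
        })
    return pd.DataFrame(calls), pd.DataFrame(freq)
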
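"""Synthetic matched-trio methylome cohorts with known ground truth.

The generator emulates the statistical structure of a 450k study of 20
matched normal-kidney (NK) / nephrogenic-rest (NR) / Wilms-tumour (WT)
trios plus a few unmatched embryonic-kidney (EK) samples:

* every sample is a Dirichlet mixture of ``d`` latent cell-type
  methylomes (default ``d = 3``), with tissue-specific mixture
  concentrations so that cell composition differs systematically between
  tissues;
* beta-values arise by mixing cell-type beta profiles, then adding
  patient random effects, planted tissue effects and measurement noise on
  the logit scale, and mapping back through the logistic function — so
  every value stays strictly inside (0, 1);
* NK-vs-NR differences are planted as contiguous kidney-rest DMRs
  (KR-DMRs, 55% hypermethylated in NR by default), carried by both NR and
  WT tissue;
* WT samples split into two subgroups: group-1 tumours (13 of 20 by
  default) additionally carry planted WT-DMR shifts versus their rests
  (73.6% hypomethylated by default) and an inflated probe-level noise SD
  (a hypervariable epigenome); group-2 tumours are drawn from the same
  distribution as their rests;
* a nominated fraction of hypermethylated KR-DMRs is placed inside a
  "bivalent domain" feature set, and a fraction of planted NR/WT-vs-EK
  probes inside a "PRC2 target" set, on top of random background
  coverage, so resampling enrichment has signal to find.

A :class:`TruthManifest`-style dict records planted regions, per-probe
effects, subgroup labels and true mixture proportions for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Cohort, write_beta, write_probes, write_samples, write_bed

_EPS = 1e-6


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1 - _EPS)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class DMRPlan:
    """How many regions to plant for one contrast, and how strong.

    ``hyper_fraction`` is the fraction of regions shifted upward in the
    test tissue relative to the reference tissue.
    """

    count: int
    delta_beta: float = 0.3
    hyper_fraction: float = 0.5
    min_probes: int = 4
    max_probes: int = 8


@dataclass
class ScatterPlan:
    """Scattered probe-level effects with no regional structure.

    Most differentially methylated positions in the study are isolated
    CpGs rather than members of a region (tens of thousands of MVPs
    versus a few hundred DMRs), so both contrasts plant scattered
    singleton effects on top of the contiguous DMRs.
    """

    count: int = 1000
    delta_beta: float = 0.3
    hyper_fraction: float = 0.5


@dataclass
class EKPlan:
    """Scattered probe-level NR/WT-vs-EK effects (no regional structure)."""

    count: int = 250
    delta_beta: float = 0.3
    hyper_fraction: float = 0.527
    prc2_fraction: float = 0.2


@dataclass
class SimConfig:
    """Study-condition parameters for :func:`simulate_cohort`.

    Defaults reproduce the study scale: 20 matched trios, ``d = 3``
    latent cell types, 13/20 group-1 tumours, KR-DMRs 55% hypermethylated
    and WT-DMRs 73.6% hypomethylated, with planted-region counts scaled
    to the 20,000-probe array emulated here.
    """

    n_patients: int = 20
    n_probes: int = 20_000
    n_cell_types: int = 3
    frac_group1: float = 13 / 20
    kr_dmrs: DMRPlan = field(default_factory=lambda: DMRPlan(count=30, hyper_fraction=0.55))
    wt_dmrs: DMRPlan = field(default_factory=lambda: DMRPlan(count=30, hyper_fraction=1 - 0.736))
    kr_scatter: ScatterPlan = field(default_factory=lambda: ScatterPlan(count=1000, hyper_fraction=0.55))
    wt_scatter: ScatterPlan = field(default_factory=lambda: ScatterPlan(count=1000, hyper_fraction=1 - 0.736))
    ek_mvps: EKPlan = field(default_factory=EKPlan)
    n_ek: int = 4
    hypervariability_sd_multiplier: float = 1.5
    feature_enrichment: float = 0.15
    feature_background: float = 0.04
    prc2_background: float = 0.03
    precision: float = 0.30           # logit-scale measurement-noise SD
    patient_sd: float = 0.15          # logit-scale patient random-effect SD
    sample_effect_sd: float = 0.10    # logit-scale per-array global intensity wobble
    mixture_fraction: float = 0.30    # fraction of probes with cell-type-specific levels
    mixture_effect_sd: float = 1.5    # logit-scale spread of cell-type offsets
    alphas: dict[str, tuple] | None = None  # Dirichlet concentrations per tissue
    n_bilateral: int = 9              # bilateral patients, all assigned to group-1
    missing_rate: float = 0.0
    seed: int = 0

    def resolved_alphas(self) -> dict[str, np.ndarray]:
        """Per-tissue Dirichlet concentrations; WT_group2 always equals NR."""
        defaults = {
            "NK": (8.0, 2.0, 2.0),
            "NR": (2.0, 6.0, 4.0),
            "WT_group1": (2.0, 6.0, 4.0),  # same as NR unless confounding is requested
            "EK": (1.0, 3.0, 8.0),
        }
        if self.alphas:
            defaults.update(self.alphas)
        d = self.n_cell_types
        out = {}
        for key, a in defaults.items():
            a = np.asarray(a, dtype=float)
            if len(a) != d:
                # pad/trim to d components keeping total concentration comparable
                a = np.resize(a, d)
            out[key] = a
        out["WT_group2"] = out["NR"].copy()
        return out

    def validate(self) -> None:
        for name, frac in [
            ("frac_group1", self.frac_group1),
            ("feature_enrichment", self.feature_enrichment),
            ("feature_background", self.feature_background),
            ("missing_rate", self.missing_rate),
            ("kr hyper_fraction", self.kr_dmrs.hyper_fraction),
            ("wt hyper_fraction", self.wt_dmrs.hyper_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.n_cell_types < 1:
            raise ValueError("n_cell_types must be >= 1")
        for name, plan in [("kr_dmrs", self.kr_dmrs), ("wt_dmrs", self.wt_dmrs)]:
            if not 0.0 < plan.delta_beta < 1.0:
                raise ValueError(f"{name}.delta_beta must lie in (0, 1)")
            if plan.min_probes < 3:
                raise ValueError(f"{name}.min_probes must be >= 3 for recoverable regions")
        planted = (
            (self.kr_dmrs.count + self.wt_dmrs.count) * self.kr_dmrs.max_probes
            + self.kr_scatter.count + self.wt_scatter.count + self.ek_mvps.count
        )
        if planted > self.n_probes:
            raise ValueError(
                f"planted probes ({planted}) exceed n_probes ({self.n_probes})"
            )
        if self.hypervariability_sd_multiplier < 1.0:
            raise ValueError("hypervariability_sd_multiplier must be >= 1")


# ---------------------------------------------------------------------------
# genome layout


def _generate_genome(rng: np.random.Generator, n_probes: int) -> pd.DataFrame:
    """Probe coordinates with island/open-sea density structure.

    Probes are laid out along four chromosomes as alternating dense
    CpG-island blocks (gaps 30-300 bp) and sparse open-sea stretches
    (gaps 800-5,000 bp), mimicking the non-uniform probe spacing of the
    array.  Returns a frame with chrom, pos, block id and island flag.
    """
    chroms = ["chr1", "chr2", "chr3", "chr4"]
    per_chrom = np.full(len(chroms), n_probes // len(chroms))
    per_chrom[: n_probes % len(chroms)] += 1

    rows = []
    block_id = 0
    for chrom, n in zip(chroms, per_chrom):
        pos = 10_000
        made = 0
        while made < n:
            if rng.random() < 0.35:  # island block
                size = min(int(rng.integers(5, 16)), n - made)
                gaps = rng.integers(30, 301, size=size)
                island = True
            else:  # open-sea stretch
                size = min(int(rng.integers(1, 6)), n - made)
                gaps = rng.integers(800, 5_001, size=size)
                island = False
            for g in gaps:
                pos += int(g)
                rows.append((chrom, pos, block_id, island))
            made += size
            block_id += 1
            pos += int(rng.integers(2_000, 20_000))  # inter-block spacer
    genome = pd.DataFrame(rows, columns=["chrom", "pos", "block", "island"])
    genome.index = [f"cg{i:08d}" for i in range(len(genome))]
    genome.index.name = "probe_id"
    return genome


def _assign_categories(rng: np.random.Generator, genome: pd.DataFrame) -> pd.DataFrame:
    """Gene-feature and CGI-relation categories correlated with density."""
    n = len(genome)
    island = genome["island"].to_numpy()
    gene_feature = np.empty(n, dtype=object)
    cgi = np.empty(n, dtype=object)
    isl_features = ["TSS200", "TSS1500", "1stExon", "5'UTR"]
    sea_features = ["Body", "IGR", "3'UTR"]
    gene_feature[island] = rng.choice(isl_features, size=int(island.sum()), p=[0.4, 0.3, 0.15, 0.15])
    gene_feature[~island] = rng.choice(sea_features, size=int((~island).sum()), p=[0.45, 0.45, 0.1])
    cgi[island] = rng.choice(["island", "shore"], size=int(island.sum()), p=[0.75, 0.25])
    cgi[~island] = rng.choice(["shelf", "open_sea"], size=int((~island).sum()), p=[0.15, 0.85])
    ann = genome[["chrom", "pos"]].copy()
    ann["gene_feature"] = gene_feature
    ann["cgi_relation"] = cgi
    for flag in ("sex_chromosome", "snp_at_target", "multimap"):
        ann[flag] = rng.random(n) < 0.01
    return ann


def _pick_dmr_runs(
    rng: np.random.Generator,
    genome: pd.DataFrame,
    plan: DMRPlan,
    used_blocks: set[int],
) -> list[np.ndarray]:
    """Choose ``plan.count`` disjoint contiguous probe runs inside island blocks."""
    block_sizes = genome.groupby("block").size()
    island_blocks = genome.loc[genome["island"], "block"].unique()
    candidates = [b for b in island_blocks if block_sizes[b] >= plan.min_probes and b not in used_blocks]
    if len(candidates) < plan.count:
        raise ValueError(
            f"genome has only {len(candidates)} eligible island blocks for {plan.count} regions"
        )
    chosen = rng.choice(np.asarray(candidates), size=plan.count, replace=False)
    runs = []
    positions = {b: np.flatnonzero((genome["block"] == b).to_numpy()) for b in chosen}
    for b in chosen:
        idx = positions[b]
        size = int(rng.integers(plan.min_probes, min(plan.max_probes, len(idx)) + 1))
        start = int(rng.integers(0, len(idx) - size + 1))
        runs.append(idx[start : start + size])
        used_blocks.add(int(b))
    return runs


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full synthetic trio cohort plus its ground-truth manifest.

    Deterministic given ``config.seed``.  Returns a :class:`~trioepi.io.Cohort`
    whose ``truth`` dict is the manifest (planted regions, per-probe
    effects, subgroup labels, true mixture proportions).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    d = config.n_cell_types
    alphas = config.resolved_alphas()

    genome = _generate_genome(rng, config.n_probes)
    ann = _assign_categories(rng, genome)
    n = len(genome)

    # --- planted regions ---------------------------------------------------
    used_blocks: set[int] = set()
    kr_runs = _pick_dmr_runs(rng, genome, config.kr_dmrs, used_blocks)
    wt_runs = _pick_dmr_runs(rng, genome, config.wt_dmrs, used_blocks)

    planted_mask = np.zeros(n, dtype=bool)
    for run in kr_runs + wt_runs:
        planted_mask[run] = True

    free = np.flatnonzero(~planted_mask)
    kr_sc_idx = rng.choice(free, size=config.kr_scatter.count, replace=False)
    planted_mask[kr_sc_idx] = True
    free = np.flatnonzero(~planted_mask)
    wt_sc_idx = rng.choice(free, size=config.wt_scatter.count, replace=False)
    planted_mask[wt_sc_idx] = True
    free = np.flatnonzero(~planted_mask)
    ek_idx = rng.choice(free, size=config.ek_mvps.count, replace=False)
    planted_mask[ek_idx] = True

    free = np.flatnonzero(~planted_mask)
    n_mix = int(round(config.mixture_fraction * n))
    mix_idx = rng.choice(free, size=min(n_mix, len(free)), replace=False)
    mix_mask = np.zeros(n, dtype=bool)
    mix_mask[mix_idx] = True

    # --- baseline methylome ------------------------------------------------
    comp = rng.choice(3, size=n, p=[0.35, 0.40, 0.25])
    beta0 = np.where(
        comp == 0, rng.uniform(0.05, 0.25, size=n),
        np.where(comp == 1, rng.uniform(0.75, 0.95, size=n), rng.uniform(0.30, 0.70, size=n)),
    )
    # islands skew unmethylated, as on the real array
    isl = genome["island"].to_numpy()
    swap = isl & (comp == 1) & (rng.random(n) < 0.7)
    beta0[swap] = rng.uniform(0.05, 0.25, size=int(swap.sum()))

    def _plant(runs_or_idx, plan_delta, hyper_fraction, rng):
        """Assign directions and re-baseline planted probes so beta0 +/- delta stays inside (0,1)."""
        groups = runs_or_idx
        n_hyper = int(round(hyper_fraction * len(groups)))
        order = rng.permutation(len(groups))
        directions = np.empty(len(groups), dtype=object)
        directions[order[:n_hyper]] = "hyper"
        directions[order[n_hyper:]] = "hypo"
        delta = np.zeros(n)
        for run, direction in zip(groups, directions):
            run = np.atleast_1d(run)
            if direction == "hyper":
                beta0[run] = rng.uniform(0.15, 1 - plan_delta - 0.10, size=len(run))
                delta[run] = plan_delta
            else:
                beta0[run] = rng.uniform(plan_delta + 0.10, 0.85, size=len(run))
                delta[run] = -plan_delta
        return directions, delta

    kr_dirs, kr_delta = _plant(kr_runs, config.kr_dmrs.delta_beta, config.kr_dmrs.hyper_fraction, rng)
    wt_dirs, wt_delta = _plant(wt_runs, config.wt_dmrs.delta_beta, config.wt_dmrs.hyper_fraction, rng)
    kr_sc_dirs, kr_sc_delta = _plant(
        [np.array([i]) for i in kr_sc_idx],
        config.kr_scatter.delta_beta, config.kr_scatter.hyper_fraction, rng,
    )
    wt_sc_dirs, wt_sc_delta = _plant(
        [np.array([i]) for i in wt_sc_idx],
        config.wt_scatter.delta_beta, config.wt_scatter.hyper_fraction, rng,
    )
    kr_delta = kr_delta + kr_sc_delta
    wt_delta = wt_delta + wt_sc_delta
    ek_dirs, ek_delta = _plant(
        [np.array([i]) for i in ek_idx],
        config.ek_mvps.delta_beta, config.ek_mvps.hyper_fraction, rng,
    )

    m0 = _logit(beta0)
    # logit shifts achieving the configured beta-scale effect at the baseline level
    kr_shift = np.where(kr_delta != 0, _logit(np.clip(beta0 + kr_delta, _EPS, 1 - _EPS)) - m0, 0.0)
    wt_shift = np.where(wt_delta != 0, _logit(np.clip(beta0 + wt_delta, _EPS, 1 - _EPS)) - m0, 0.0)
    ek_shift = np.where(ek_delta != 0, _logit(np.clip(beta0 + ek_delta, _EPS, 1 - _EPS)) - m0, 0.0)

    # --- latent cell-type profiles -----------------------------------------
    offsets = np.zeros((n, d))
    offsets[mix_mask] = rng.normal(0.0, config.mixture_effect_sd, size=(int(mix_mask.sum()), d))
    cell_profiles = _expit(m0[:, None] + offsets)  # probes x d beta profiles

    # --- sample sheet -------------------------------------------------------
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    n_g1 = int(round(config.frac_group1 * config.n_patients))
    g1_patients = set(rng.choice(patients, size=n_g1, replace=False))
    n_bilat = min(config.n_bilateral, n_g1)
    bilat = set(rng.choice(sorted(g1_patients), size=n_bilat, replace=False))

    rows = []
    for p in patients:
        subgroup = "group1" if p in g1_patients else "group2"
        lat = "bilateral" if p in bilat else "unilateral"
        for tissue in ("NK", "NR", "WT"):
            rows.append((f"{p}_{tissue}", p, tissue, lat, subgroup if tissue == "WT" else ""))
    for j in range(config.n_ek):
        rows.append((f"EK{j + 1:02d}", f"EKD{j + 1:02d}", "EK", "NA", ""))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "tissue", "laterality", "subgroup"]
    ).set_index("sample_id")

    # --- signal assembly ----------------------------------------------------
    patient_effects = {p: rng.normal(0.0, config.patient_sd, size=n) for p in patients}
    beta = np.empty((n, len(samples)))
    proportions = {}
    for j, (sid, row) in enumerate(samples.iterrows()):
        tissue = row["tissue"]
        if tissue == "WT":
            key = "WT_group1" if row["subgroup"] == "group1" else "WT_group2"
        else:
            key = tissue
        w = rng.dirichlet(alphas[key])
        proportions[sid] = w.tolist()
        mixed = cell_profiles @ w
        m = _logit(mixed)
        if tissue != "EK":
            m = m + patient_effects[row["patient_id"]]
            m = m + ek_shift  # NR/WT/NK share the post-embryonic state except...
        if tissue in ("NR", "WT"):
            m = m + kr_shift
        if tissue == "WT" and row["subgroup"] == "group1":
            m = m + wt_shift
        sd = config.precision
        if tissue == "WT" and row["subgroup"] == "group1":
            sd = sd * config.hypervariability_sd_multiplier
        m = m + rng.normal(0.0, config.sample_effect_sd)  # array-level shift
        m = m + rng.normal(0.0, sd, size=n)
        beta[:, j] = np.clip(_expit(m), _EPS, 1 - _EPS)

    beta_df = pd.DataFrame(beta, index=genome.index, columns=samples.index)
    if config.missing_rate > 0:
        miss = rng.random(beta_df.shape) < config.missing_rate
        beta_df = beta_df.mask(miss)

    # --- truth manifest ------------------------------------------------------
    def _region_record(kind, i, run, direction, delta):
        pos = genome["pos"].to_numpy()[run]
        return {
            "id": f"{kind}{i + 1:03d}",
            "kind": kind,
            "chrom": genome["chrom"].iloc[run[0]],
            "start": int(pos.min() - 1),  # 0-based half-open spanning member probes
            "end": int(pos.max()),
            "probe_ids": list(genome.index[run]),
            "direction": direction,
            "delta_beta": float(delta),
        }

    regions = [
        _region_record("KR", i, run, kr_dirs[i], config.kr_dmrs.delta_beta * (1 if kr_dirs[i] == "hyper" else -1))
        for i, run in enumerate(kr_runs)
    ] + [
        _region_record("WT", i, run, wt_dirs[i], config.wt_dmrs.delta_beta * (1 if wt_dirs[i] == "hyper" else -1))
        for i, run in enumerate(wt_runs)
    ]

    probe_truth = {}
    for rec in regions:
        for pid in rec["probe_ids"]:
            probe_truth[pid] = {
                "contrast": rec["kind"], "region": rec["id"],
                "direction": rec["direction"], "delta_beta": rec["delta_beta"],
            }
    for plan, idx_arr, dirs, kind in (
        (config.kr_scatter, kr_sc_idx, kr_sc_dirs, "KR"),
        (config.wt_scatter, wt_sc_idx, wt_sc_dirs, "WT"),
        (config.ek_mvps, ek_idx, ek_dirs, "EK"),
    ):
        for i, idx_ in enumerate(idx_arr):
            pid = genome.index[idx_]
            probe_truth[pid] = {
                "contrast": kind, "region": None, "direction": dirs[i],
                "delta_beta": plan.delta_beta * (1 if dirs[i] == "hyper" else -1),
            }

    # --- feature sets ---------------------------------------------------------
    # The study's developmental loci recur across contrasts: loci
    # hypermethylated in NR vs NK are the same poised loci marked bivalent /
    # PRC2-target in embryonic stem cells, and the NR/WT-vs-EK hyper effects
    # hit them again.  Feature membership is therefore drawn from the planted
    # hypermethylation loci, plus random background coverage elsewhere.
    pos_arr = genome["pos"].to_numpy()

    def _probe_interval(i, tag, pad=40):
        return (genome["chrom"].iloc[i], max(0, pos_arr[i] - 1 - pad), pos_arr[i] + pad, tag)

    # bivalent domains are kilobase-scale in embryonic stem cells: planted
    # loci chosen as in-feature get domain-sized intervals so a whole called
    # region (including interior probes) falls inside
    hyper_kr = [r for r in regions if r["kind"] == "KR" and r["direction"] == "hyper"]
    n_in = int(round(config.feature_enrichment * len(hyper_kr)))
    in_feature = [r["id"] for r in hyper_kr[:n_in]]
    bival_rows = [
        (r["chrom"], max(0, r["start"] - 500), r["end"] + 500, f"bival_{r['id']}")
        for r in hyper_kr[:n_in]
    ]
    kr_hyper_scatter = kr_sc_idx[np.array([d_ == "hyper" for d_ in kr_sc_dirs], dtype=bool)]
    n_sc_in = int(round(config.feature_enrichment * len(kr_hyper_scatter)))
    bival_in_idx = set(int(i) for i in kr_hyper_scatter[:n_sc_in])
    bival_rows += [_probe_interval(i, f"bival_sc{k}", pad=500)
                   for k, i in enumerate(sorted(bival_in_idx))]
    n_bg = int(round(config.feature_background * n))
    bival_bg_pool = np.flatnonzero(~planted_mask)
    bg_idx = rng.choice(bival_bg_pool, size=n_bg, replace=False)
    bival_rows += [_probe_interval(i, f"bival_bg{k}") for k, i in enumerate(bg_idx)]

    hyper_ek = ek_idx[np.array([d_ == "hyper" for d_ in ek_dirs], dtype=bool)]
    prc2_frac = config.ek_mvps.prc2_fraction
    prc2_idx = list(hyper_ek[: int(round(prc2_frac * len(hyper_ek)))])
    prc2_idx += list(kr_hyper_scatter[: int(round(prc2_frac * len(kr_hyper_scatter)))])
    prc2_rows = [_probe_interval(i, f"prc2_{k}") for k, i in enumerate(sorted(set(int(i) for i in prc2_idx)))]
    prc2_rows += [
        (r["chrom"], max(0, r["start"] - 100), r["end"] + 100, f"prc2_{r['id']}")
        for r in hyper_kr[: int(round(prc2_frac * len(hyper_kr)))]
    ]
    n_prc2_bg = int(round(config.prc2_background * n))
    prc2_bg = rng.choice(np.flatnonzero(~planted_mask), size=n_prc2_bg, replace=False)
    prc2_rows += [_probe_interval(i, f"prc2_bg{k}") for k, i in enumerate(prc2_bg)]

    def _bed(rows):
        bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        return bed.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    features = {"bivalent_domains": _bed(bival_rows), "prc2_targets": _bed(prc2_rows)}

    truth = {
        "config": _config_dict(config),
        "regions": regions,
        "probes": probe_truth,
        "mixture_sensitive": list(genome.index[mix_mask]),
        "samples": {
            sid: {
                "patient": samples.at[sid, "patient_id"],
                "tissue": samples.at[sid, "tissue"],
                "subgroup": samples.at[sid, "subgroup"],
                "proportions": proportions[sid],
            }
            for sid in samples.index
        },
        "hyper_kr_in_feature": in_feature,
    }

    ann = ann.loc[genome.index]
    return Cohort(beta=beta_df, probes=ann, samples=samples, features=features, truth=truth)


def _config_dict(config: SimConfig) -> dict:
    out = asdict(config)
    if out.get("alphas"):
        out["alphas"] = {k: list(v) for k, v in out["alphas"].items()}
    return out


def zero_effect_config(seed: int = 0, **overrides) -> SimConfig:
    """A null cohort: no planted WT effects, no hypervariability, identical
    WT/NR mixture distributions — group-1 and group-2 tumours are drawn
    from the same distribution as their rests."""
    cfg = SimConfig(
        wt_dmrs=DMRPlan(count=0, hyper_fraction=0.0, min_probes=3),
        wt_scatter=ScatterPlan(count=0, hyper_fraction=0.0),
        hypervariability_sd_multiplier=1.0,
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def confounded_config(seed: int = 0, **overrides) -> SimConfig:
    """A cohort whose WT cell composition differs systematically from NR
    (tissue-correlated mixture confounding) with no planted WT effects —
    every WT-vs-NR signal at mixture-sensitive probes is composition-driven.

    The mixture regime is deliberately strong (dispersed Dirichlet
    weights, well-separated cell-type profiles): this is the setting the
    reference-free adjustment exists for, and the latent structure must
    be identifiable from within-tissue variability.
    """
    cfg = SimConfig(
        wt_dmrs=DMRPlan(count=0, hyper_fraction=0.0, min_probes=3),
        wt_scatter=ScatterPlan(count=0, hyper_fraction=0.0),
        hypervariability_sd_multiplier=1.0,
        mixture_effect_sd=3.0,
        alphas={
            "NK": (2.8, 0.7, 0.7),
            "NR": (0.7, 2.1, 1.4),
            # composition shifted halfway from NR towards NK
            "WT_group1": (1.75, 1.4, 1.05),
            "EK": (0.35, 1.05, 2.8),
        },
        seed=seed,
    )
    cfg.frac_group1 = 1.0  # all pairs confounded
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort bundle in the on-disk formats used by :mod:`trioepi.io`.

    Round-trips losslessly through ``load_cohort`` to within 1e-9.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out_dir / "beta.tsv",
        "probes": out_dir / "probes.csv",
        "samples": out_dir / "samples.csv",
        "truth": out_dir / "truth.json",
    }
    write_beta(cohort.beta, paths["beta"])
    write_probes(cohort.probes, paths["probes"])
    write_samples(cohort.samples, paths["samples"])
    feat_dir = out_dir / "features"
    feat_dir.mkdir(exist_ok=True)
    for name, bed in cohort.features.items():
        path = feat_dir / f"{name}.bed"
        write_bed(bed, path)
        paths[f"features/{name}"] = path
    if cohort.truth is not None:
        paths["truth"].write_text(json.dumps(cohort.truth, indent=1))
    return paths
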
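"""Probe-lasso detection of differentially methylated regions.

The array's probes are spaced very unevenly — tens of base pairs apart
inside CpG islands and promoters, kilobases apart in intergenic regions —
so a fixed window would over-merge dense regions and fragment sparse
ones.  The probe lasso adapts: each probe gets a window ("lasso") whose
radius is the category-specific typical nearest-neighbour distance for
its gene-feature x CGI-relation class, floored at half a global minimum
lasso size (10 bp by default).

Calling then proceeds in five steps:

1. mark probes significant at FDR < ``sig_fdr`` (default 0.01);
2. connect two significant probes when each lies inside the other's
   lasso (mutual containment — symmetric and order-independent); take
   connected components with at least ``min_sig_probes`` (default 3)
   significant probes as candidate regions;
3. absorb every probe, significant or not, whose position falls inside
   the union of the member lassos;
4. merge candidate regions on one chromosome whose bounds are less than
   ``merge_gap_bp`` (default 1,000) apart;
5. combine member-probe p-values into one region p by Stouffer's method,
   one-sided and aligned to the region's direction (the sign of the mean
   delta-beta over significant members).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LassoSpec:
    """Per-category lasso radii in bp plus the global fallback radius."""

    radii: dict[tuple[str, str], float]
    default: float
    min_lasso_bp: float = 10.0
    quantile: float = 0.5

    def probe_radii(self, ann: pd.DataFrame) -> pd.Series:
        keys = list(zip(ann["gene_feature"], ann["cgi_relation"]))
        return pd.Series([self.radii.get(k, self.default) for k in keys], index=ann.index)


@dataclass
class DMR:
    chrom: str
    start: int  # 0-based half-open, spanning first to last member probe
    end: int
    probe_ids: list[str]
    sig_probe_ids: list[str]
    n_significant: int
    direction: str
    mean_delta: float
    combined_p: float
    merged_from: int = 1
    name: str = ""
    member_positions: list[int] = field(default_factory=list)


def _nearest_neighbour_distances(ann: pd.DataFrame) -> np.ndarray:
    """Distance from each probe to its nearest neighbour on the same
    chromosome (probes without a neighbour are skipped)."""
    out = []
    for _, sub in ann.groupby("chrom"):
        pos = np.sort(sub["pos"].to_numpy())
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        nn = np.minimum(np.r_[gaps, np.inf], np.r_[np.inf, gaps])
        out.append(nn)
    if not out:
        return np.array([])
    return np.concatenate(out)


def compute_lassos(
    ann: pd.DataFrame, min_lasso_bp: float = 10.0, quantile: float = 0.5
) -> LassoSpec:
    """Category-specific lasso radii from within-category nearest-neighbour
    distances.

    The radius for a gene-feature x CGI-relation category is the given
    quantile (median by default) of the nearest-neighbour distances among
    that category's probes, floored at ``min_lasso_bp / 2``.  Categories
    with fewer than two usable probes inherit the quantile of the global
    distance distribution.
    """
    if ann.shape[0] == 0:
        raise ValueError("empty probe annotation")
    global_nn = _nearest_neighbour_distances(ann)
    floor = min_lasso_bp / 2.0
    default = max(float(np.quantile(global_nn, quantile)) if global_nn.size else floor, floor)

    radii: dict[tuple[str, str], float] = {}
    for key, sub in ann.groupby(["gene_feature", "cgi_relation"]):
        nn = _nearest_neighbour_distances(sub)
        if nn.size == 0:
            radii[key] = default
        else:
            radii[key] = max(float(np.quantile(nn, quantile)), floor)
    return LassoSpec(radii=radii, default=default, min_lasso_bp=min_lasso_bp, quantile=quantile)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def call_dmrs(
    mvp: pd.DataFrame,
    ann: pd.DataFrame,
    lassos: LassoSpec,
    sig_fdr: float = 0.01,
    min_sig_probes: int = 3,
    merge_gap_bp: float = 1000.0,
) -> list[DMR]:
    """Call DMRs from an MVP table and probe annotation (see module docs).

    ``mvp`` and ``ann`` must share probe ids; an empty list is returned
    when no probe reaches significance.
    """
    shared = mvp.index.intersection(ann.index)
    if len(shared) < len(mvp.index) or len(shared) < len(ann.index):
        missing = len(mvp.index.symmetric_difference(ann.index))
        raise ValueError(f"mvp table and annotation differ on {missing} probe ids")

    ann = ann.sort_values(["chrom", "pos"], kind="mergesort")
    mvp = mvp.loc[ann.index]
    radii = lassos.probe_radii(ann)

    sig = (mvp["fdr"] < sig_fdr).fillna(False).to_numpy()
    regions: list[DMR] = []

    for chrom, sub in ann.groupby("chrom", sort=True):
        idx = sub.index
        pos = sub["pos"].to_numpy()
        rad = radii.loc[idx].to_numpy()
        is_sig = sig[ann.index.get_indexer(idx)]
        s_pos = pos[is_sig]
        s_rad = rad[is_sig]
        s_ids = idx[is_sig]
        k = len(s_pos)
        if k < min_sig_probes:
            continue

        # mutual lasso containment among significant probes
        uf = _UnionFind(k)
        for i in range(k):
            j = i + 1
            while j < k and s_pos[j] - s_pos[i] <= s_rad[i]:
                if s_pos[j] - s_pos[i] <= s_rad[j]:
                    uf.union(i, j)
                j += 1

        comps: dict[int, list[int]] = {}
        for i in range(k):
            comps.setdefault(uf.find(i), []).append(i)

        for members in comps.values():
            if len(members) < min_sig_probes:
                continue
            m_pos = s_pos[members]
            m_rad = s_rad[members]
            # all probes inside the union of member lassos
            lo = m_pos - m_rad
            hi = m_pos + m_rad
            inside = np.zeros(len(pos), dtype=bool)
            for a, b in zip(lo, hi):
                inside |= (pos >= a) & (pos <= b)
            member_ids = list(idx[inside])
            member_pos = pos[inside]
            order = np.argsort(member_pos, kind="mergesort")
            member_ids = [member_ids[i] for i in order]
            member_pos = member_pos[order]
            regions.append(
                DMR(
                    chrom=chrom,
                    start=int(member_pos.min() - 1),
                    end=int(member_pos.max()),
                    probe_ids=member_ids,
                    sig_probe_ids=list(s_ids[members]),
                    n_significant=len(members),
                    direction="",
                    mean_delta=float("nan"),
                    combined_p=float("nan"),
                    member_positions=list(member_pos),
                )
            )

    regions = _merge_regions(regions, merge_gap_bp)
    for r in regions:
        _finalize_region(r, mvp)
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    for i, r in enumerate(regions):
        r.name = f"DMR{i + 1:04d}"
    return regions


def _merge_regions(regions: list[DMR], merge_gap_bp: float) -> list[DMR]:
    """Merge regions on one chromosome whose bound-to-bound gap is below
    ``merge_gap_bp``; summed significant counts, unioned members.
    Idempotent: re-running changes nothing."""
    merged: list[DMR] = []
    by_chrom: dict[str, list[DMR]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        current = rs[0]
        for nxt in rs[1:]:
            gap = nxt.start - current.end
            if gap < merge_gap_bp:
                seen = set(current.probe_ids)
                for pid, p in zip(nxt.probe_ids, nxt.member_positions):
                    if pid not in seen:
                        current.probe_ids.append(pid)
                        current.member_positions.append(p)
                        seen.add(pid)
                order = np.argsort(current.member_positions, kind="mergesort")
                current.probe_ids = [current.probe_ids[i] for i in order]
                current.member_positions = [current.member_positions[i] for i in order]
                current.sig_probe_ids = sorted(set(current.sig_probe_ids) | set(nxt.sig_probe_ids))
                current.n_significant += nxt.n_significant
                current.start = min(current.start, nxt.start)
                current.end = max(current.end, nxt.end)
                current.merged_from += nxt.merged_from
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    return merged


def _finalize_region(region: DMR, mvp: pd.DataFrame) -> None:
    """Direction from significant members; Stouffer combination over all
    member probes with one-sided p aligned to the region direction."""
    sig_delta = mvp.loc[region.sig_probe_ids, "delta_beta"]
    region.mean_delta = float(sig_delta.mean())
    region.direction = "hyper" if region.mean_delta >= 0 else "hypo"
    sign = 1.0 if region.direction == "hyper" else -1.0

    p = mvp.loc[region.probe_ids, "p"].to_numpy()
    delta = mvp.loc[region.probe_ids, "delta_beta"].to_numpy()
    ok = np.isfinite(p) & np.isfinite(delta)
    p, delta = p[ok], delta[ok]
    one_sided = np.where(np.sign(delta) == sign, p / 2.0, 1.0 - p / 2.0)
    one_sided = np.clip(one_sided, 1e-300, 1 - 1e-16)
    z = stats.norm.isf(one_sided)
    region.combined_p = float(stats.norm.sf(z.sum() / np.sqrt(len(z))))


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Flatten a DMR list into a BED-like frame (one row per region)."""
    rows = [
        {
            "chrom": r.chrom, "start": r.start, "end": r.end, "name": r.name,
            "n_probes": len(r.probe_ids), "n_significant": r.n_significant,
            "direction": r.direction, "mean_delta": r.mean_delta,
            "combined_p": r.combined_p, "merged_from": r.merged_from,
        }
        for r in dmrs
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "n_probes", "n_significant",
                 "direction", "mean_delta", "combined_p", "merged_from"],
    )


def summarize_dmrs(dmrs: list[DMR], ann: pd.DataFrame) -> pd.DataFrame:
    """Aggregate called regions by direction: region counts, size statistics
    and member-probe composition by gene feature and CGI relation
    (fractions sum to 1 within each facet and direction)."""
    if not dmrs:
        return pd.DataFrame()
    rows = []
    for direction in ("hyper", "hypo"):
        sub = [r for r in dmrs if r.direction == direction]
        if not sub:
            continue
        widths = np.array([r.end - r.start for r in sub], dtype=float)
        probe_ids = [pid for r in sub for pid in r.probe_ids]
        cats = ann.loc[probe_ids]
        row = {
            "direction": direction,
            "n_regions": len(sub),
            "n_probes": len(probe_ids),
            "width_mean": widths.mean(),
            "width_median": float(np.median(widths)),
        }
        for facet in ("gene_feature", "cgi_relation"):
            frac = cats[facet].value_counts(normalize=True)
            for cat, f in frac.items():
                row[f"{facet}:{cat}"] = float(f)
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)


def region_overlap_stats(
    called: list[DMR],
    truth: list[dict],
    direction_aware: bool = False,
    true_probes: set[str] | None = None,
) -> dict[str, float]:
    """Sensitivity (truth regions overlapped by a call) and precision
    (calls at genuinely affected loci) at interval level; intervals are
    0-based half-open and overlap iff they share at least one base.

    ``true_probes`` optionally names additional planted single-probe
    effects: a call also counts as a true discovery when it contains one
    of them (scattered true effects can legitimately aggregate into a
    called region without matching a planted interval).
    """
    def _overlaps(a_chrom, a_start, a_end, b) -> bool:
        return a_chrom == b["chrom"] and a_start < b["end"] and b["start"] < a_end

    hit_truth = 0
    for t in truth:
        for c in called:
            if _overlaps(c.chrom, c.start, c.end, t) and (
                not direction_aware or c.direction == t["direction"]
            ):
                hit_truth += 1
                break
    hit_called = 0
    for c in called:
        ok = any(
            _overlaps(c.chrom, c.start, c.end, t)
            and (not direction_aware or c.direction == t["direction"])
            for t in truth
        )
        if not ok and true_probes:
            ok = any(p in true_probes for p in c.probe_ids)
        if ok:
            hit_called += 1
    return {
        "sensitivity": hit_truth / len(truth) if truth else float("nan"),
        "precision": hit_called / len(called) if called else float("nan"),
        "n_called": float(len(called)),
        "n_truth": float(len(truth)),
    }
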
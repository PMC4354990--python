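import numpy as np
import pandas as pd
import pytest

from trioepi import dmr


def make_ann(positions, chrom="chr1", feature="TSS200", cgi="island"):
    return pd.DataFrame(
        {
            "chrom": [chrom] * len(positions),
            "pos": list(positions),
            "gene_feature": [feature] * len(positions),
            "cgi_relation": [cgi] * len(positions),
        },
        index=[f"cg{i:04d}" for i in range(len(positions))],
    )


def make_mvp(ann, sig_probes, delta=0.3):
    sig = ann.index.isin(sig_probes)
    return pd.DataFrame(
        {
            "delta_beta": np.where(sig, delta, 0.01),
            "p": np.where(sig, 1e-6, 0.5),
            "fdr": np.where(sig, 1e-4, 0.9),
        },
        index=ann.index,
    )


class TestComputeLassos:
    def test_equal_spacing_gives_median_distance(self):
        ann = make_ann(range(100, 1100, 100))
        spec = dmr.compute_lassos(ann)
        assert spec.radii[("TSS200", "island")] == 100.0

    def test_minimum_lasso_floor(self):
        """Dense spacing of 4 bp is floored at half the 10 bp minimum size."""
        ann = make_ann(range(100, 180, 4))
        spec = dmr.compute_lassos(ann, min_lasso_bp=10)
        assert spec.radii[("TSS200", "island")] == 5.0

    def test_sparse_category_inherits_global_quantile(self):
        ann = pd.concat([
            make_ann(range(100, 1100, 100), feature="TSS200"),
            make_ann([5000], feature="Body").rename(index={"cg0000": "cgBody"}),
        ])
        spec = dmr.compute_lassos(ann)
        assert spec.radii[("Body", "island")] == spec.default

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            dmr.compute_lassos(make_ann([]))


class TestCallDmrs:
    def test_no_significant_probes_gives_empty_list(self):
        ann = make_ann(range(100, 600, 100))
        mvp = make_mvp(ann, sig_probes=[])
        assert dmr.call_dmrs(mvp, ann, dmr.compute_lassos(ann)) == []

    def test_connectivity_and_interior_inclusion(self):
        """Significant probes at 100/150/200 (radius ~50-100) connect; a
        non-significant probe at 1,120 and a lone significant probe at 5,000
        stay outside."""
        positions = [100, 150, 200, 1120, 5000]
        ann = make_ann(positions)
        mvp = make_mvp(ann, sig_probes=["cg0000", "cg0001", "cg0002", "cg0004"])
        lassos = dmr.LassoSpec(radii={("TSS200", "island"): 100.0}, default=100.0)
        regions = dmr.call_dmrs(mvp, ann, lassos)
        assert len(regions) == 1
        r = regions[0]
        assert r.n_significant == 3
        assert set(r.probe_ids) == {"cg0000", "cg0001", "cg0002"}
        assert (r.start, r.end) == (99, 200)
        assert r.direction == "hyper"

    def test_mutual_containment_is_required(self):
        """A probe with a tiny lasso between two wide-lasso probes stays
        disconnected from them even though it sits inside their lassos."""
        ann = pd.concat([
            make_ann([1000, 1100], feature="TSS200"),
            make_ann([1050], feature="Body").rename(index={"cg0000": "cgMID"}),
        ])
        mvp = make_mvp(ann, sig_probes=list(ann.index))
        lassos = dmr.LassoSpec(
            radii={("TSS200", "island"): 100.0, ("Body", "island"): 10.0}, default=100.0
        )
        regions = dmr.call_dmrs(mvp, ann, lassos, min_sig_probes=2)
        assert len(regions) == 1
        assert set(regions[0].sig_probe_ids) == {"cg0000", "cg0001"}
        # the disconnected probe is still swallowed as an interior member
        assert "cgMID" in regions[0].probe_ids

    def test_merge_below_one_kilobase(self):
        positions = [100, 150, 200, 1100, 1150, 1200]
        ann = make_ann(positions)
        mvp = make_mvp(ann, sig_probes=list(ann.index))
        lassos = dmr.LassoSpec(radii={("TSS200", "island"): 60.0}, default=60.0)
        regions = dmr.call_dmrs(mvp, ann, lassos, merge_gap_bp=1000)
        assert len(regions) == 1
        assert regions[0].merged_from == 2
        assert regions[0].n_significant == 6

    def test_gap_at_threshold_not_merged(self):
        positions = [100, 150, 200, 1300, 1350, 1400]
        ann = make_ann(positions)
        mvp = make_mvp(ann, sig_probes=list(ann.index))
        lassos = dmr.LassoSpec(radii={("TSS200", "island"): 60.0}, default=60.0)
        regions = dmr.call_dmrs(mvp, ann, lassos, merge_gap_bp=1000)
        # gap = 1299 - 200 = 1099 >= 1000 -> stays two regions
        assert len(regions) == 2

    def test_order_invariance(self, rng):
        ann = make_ann(sorted(rng.choice(range(100, 20000), size=60, replace=False)))
        sig = list(rng.choice(ann.index, size=20, replace=False))
        mvp = make_mvp(ann, sig_probes=sig)
        lassos = dmr.compute_lassos(ann)
        base = dmr.call_dmrs(mvp, ann, lassos)
        perm = rng.permutation(len(ann))
        shuffled = dmr.call_dmrs(mvp.iloc[perm], ann.iloc[perm], lassos)
        assert [set(r.probe_ids) for r in base] == [set(r.probe_ids) for r in shuffled]

    def test_mvp_annotation_mismatch_rejected(self):
        ann = make_ann([100, 200, 300])
        mvp = make_mvp(ann, sig_probes=[]).iloc[:2]
        with pytest.raises(ValueError, match="probe ids"):
            dmr.call_dmrs(mvp, ann, dmr.compute_lassos(ann))


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_dmrs(mvp, ann, radii, sig_fdr=0.01, min_sig=3, merge_gap=1000.0):
    """Independent all-pairs implementation of the probe-lasso rules."""
    ann = ann.sort_values(["chrom", "pos"])
    sig_ids = [p for p in ann.index if mvp.at[p, "fdr"] < sig_fdr]
    # all-pairs mutual containment graph
    adj = {p: set() for p in sig_ids}
    for a in sig_ids:
        for b in sig_ids:
            if a >= b or ann.at[a, "chrom"] != ann.at[b, "chrom"]:
                continue
            gap = abs(ann.at[a, "pos"] - ann.at[b, "pos"])
            if gap <= radii[a] and gap <= radii[b]:
                adj[a].add(b)
                adj[b].add(a)
    seen, comps = set(), []
    for p in sig_ids:
        if p in seen:
            continue
        stack, comp = [p], set()
        while stack:
            q = stack.pop()
            if q in comp:
                continue
            comp.add(q)
            stack.extend(adj[q] - comp)
        seen |= comp
        if len(comp) >= min_sig:
            comps.append(comp)
    regions = []
    for comp in comps:
        chrom = ann.at[next(iter(comp)), "chrom"]
        members = set()
        for p in ann.index[ann["chrom"] == chrom]:
            pos = ann.at[p, "pos"]
            if any(abs(pos - ann.at[m, "pos"]) <= radii[m] for m in comp):
                members.add(p)
        pos = [ann.at[m, "pos"] for m in members]
        regions.append({
            "chrom": chrom, "start": min(pos) - 1, "end": max(pos),
            "members": members, "n_sig": len(comp),
        })
    regions.sort(key=lambda r: (r["chrom"], r["start"], r["end"]))
    merged = []
    for r in regions:
        if merged and merged[-1]["chrom"] == r["chrom"] and r["start"] - merged[-1]["end"] < merge_gap:
            merged[-1]["end"] = max(merged[-1]["end"], r["end"])
            merged[-1]["start"] = min(merged[-1]["start"], r["start"])
            merged[-1]["members"] |= r["members"]
            merged[-1]["n_sig"] += r["n_sig"]
        else:
            merged.append(dict(r))
    return merged


def random_lasso_fixture(rng, max_probes=200):
    n = int(rng.integers(20, max_probes + 1))
    chroms = rng.choice(["chr1", "chr2"], size=n)
    rows = []
    for chrom in ("chr1", "chr2"):
        count = int((chroms == chrom).sum())
        pos = np.sort(rng.choice(np.arange(50, 50_000), size=count, replace=False))
        rows += [(chrom, int(p)) for p in pos]
    features = rng.choice(["TSS200", "Body", "IGR"], size=n)
    cgis = rng.choice(["island", "open_sea"], size=n)
    ann = pd.DataFrame({
        "chrom": [r[0] for r in rows], "pos": [r[1] for r in rows],
        "gene_feature": features, "cgi_relation": cgis,
    }, index=[f"cg{i:04d}" for i in range(n)])
    sig_frac = rng.uniform(0.1, 0.5)
    sig = rng.random(n) < sig_frac
    mvp = pd.DataFrame({
        "delta_beta": rng.normal(0, 0.2, size=n),
        "p": np.where(sig, 1e-5, rng.uniform(0.05, 1, size=n)),
        "fdr": np.where(sig, 1e-3, rng.uniform(0.05, 1, size=n)),
    }, index=ann.index)
    return ann, mvp


@pytest.mark.parametrize("case_seed", range(40))
def test_call_dmrs_equals_brute_force_oracle(case_seed):
    rng = np.random.default_rng(1000 + case_seed)
    ann, mvp = random_lasso_fixture(rng)
    lassos = dmr.compute_lassos(ann)
    radii = lassos.probe_radii(ann)
    got = dmr.call_dmrs(mvp, ann, lassos)
    expected = brute_force_dmrs(mvp, ann, radii)
    assert len(got) == len(expected)
    for g, e in zip(got, expected):
        assert (g.chrom, g.start, g.end) == (e["chrom"], e["start"], e["end"])
        assert set(g.probe_ids) == e["members"]
        assert g.n_significant == e["n_sig"]


def test_merge_is_idempotent(rng):
    ann, mvp = random_lasso_fixture(rng)
    lassos = dmr.compute_lassos(ann)
    regions = dmr.call_dmrs(mvp, ann, lassos)
    again = dmr._merge_regions([r for r in regions], merge_gap_bp=1000)
    assert [(r.chrom, r.start, r.end) for r in again] == [
        (r.chrom, r.start, r.end) for r in regions
    ]


class TestSummaries:
    def test_all_hyper_toy_set(self):
        ann = make_ann([100, 150, 200])
        mvp = make_mvp(ann, sig_probes=list(ann.index), delta=0.4)
        regions = dmr.call_dmrs(mvp, ann, dmr.compute_lassos(ann))
        summary = dmr.summarize_dmrs(regions, ann)
        assert set(summary["direction"]) == {"hyper"}

    def test_counts_match_brute_tally(self, rng):
        ann, mvp = random_lasso_fixture(rng)
        regions = dmr.call_dmrs(mvp, ann, dmr.compute_lassos(ann))
        if not regions:
            pytest.skip("fixture produced no regions")
        summary = dmr.summarize_dmrs(regions, ann)
        for _, row in summary.iterrows():
            subset = [r for r in regions if r.direction == row["direction"]]
            assert row["n_regions"] == len(subset)
            assert row["n_probes"] == sum(len(r.probe_ids) for r in subset)

    def test_empty_input(self):
        assert dmr.summarize_dmrs([], make_ann([100])).empty

    def test_stouffer_direction_alignment(self):
        """A coherent region's combined p must be far smaller than any member's."""
        ann = make_ann([100, 150, 200])
        mvp = make_mvp(ann, sig_probes=list(ann.index))
        regions = dmr.call_dmrs(mvp, ann, dmr.compute_lassos(ann))
        assert regions[0].combined_p < mvp["p"].min()
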
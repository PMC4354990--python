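import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trioepi import enrich
from trioepi.dmr import DMR


def toy_universe(n=500, chrom="chr1"):
    ann = pd.DataFrame(
        {"chrom": [chrom] * n, "pos": np.arange(1000, 1000 + 100 * n, 100)},
        index=[f"cg{i:04d}" for i in range(n)],
    )
    return ann


def feature_over(ann, probe_ids, pad=10):
    rows = [
        (ann.at[p, "chrom"], ann.at[p, "pos"] - 1 - pad, ann.at[p, "pos"] + pad, p)
        for p in probe_ids
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestMultisampleEnrichment:
    def test_feature_covering_everything_gives_zero_enrichment(self):
        ann = toy_universe(100)
        features = {"all": pd.DataFrame(
            [("chr1", 0, 10_000_000, "all")], columns=["chrom", "start", "end", "name"]
        )}
        res = enrich.multisample_enrichment(
            list(ann.index[:20]), list(ann.index), ann, features, n_resamples=50, seed=0
        )[0]
        assert res.observed_fraction == 1.0
        assert res.null_mean_fraction == 1.0
        assert res.enrichment_pp == 0.0

    def test_pure_in_feature_query_hits_floor(self):
        """A query that is exactly the 50 in-feature probes of a 5,000-probe
        universe: p at the floor 1/(n+1), null mean near the hypergeometric
        expectation 50/5000."""
        ann = toy_universe(5000)
        inside = list(ann.index[:50])
        features = {"f": feature_over(ann, inside)}
        res = enrich.multisample_enrichment(
            inside, list(ann.index), ann, features, n_resamples=100, seed=1
        )[0]
        assert res.observed_fraction == 1.0
        assert np.isclose(res.empirical_p, 1 / 101)
        expect = 50 / 5000
        se = np.sqrt(expect * (1 - expect) / 50 / 100)  # MC error of the null mean
        assert abs(res.null_mean_fraction - expect) < 3 * se + 1e-9

    def test_null_mean_matches_hypergeometric(self, rng):
        ann = toy_universe(2000)
        in_feature = list(rng.choice(ann.index, size=300, replace=False))
        features = {"f": feature_over(ann, in_feature)}
        query = list(rng.choice(ann.index, size=100, replace=False))
        res = enrich.multisample_enrichment(
            query, list(ann.index), ann, features, n_resamples=200, seed=2
        )[0]
        expect = 300 / 2000
        se = np.sqrt(expect * (1 - expect) / 100 / 200)
        assert abs(res.null_mean_fraction - expect) < 4 * se

    def test_negative_enrichment_supported(self, rng):
        ann = toy_universe(1000)
        in_feature = list(ann.index[:400])
        features = {"f": feature_over(ann, in_feature)}
        query = list(ann.index[-100:])  # entirely outside
        res = enrich.multisample_enrichment(
            query, list(ann.index), ann, features, n_resamples=100, seed=3
        )[0]
        assert res.side == "negative"
        assert res.enrichment_pp < -30
        assert np.isclose(res.empirical_p, 1 / 101)

    def test_empirical_p_uniform_under_null(self):
        """The fixed-side empirical p is uniform when the query is itself a
        random draw from the universe (the adaptive side reports the
        smaller tail and is bounded near one half by construction)."""
        ann = toy_universe(5000)
        rng = np.random.default_rng(9)
        in_feature = list(rng.choice(ann.index, size=1000, replace=False))
        features = {"f": feature_over(ann, in_feature)}
        ps = []
        for i in range(150):
            query = list(rng.choice(ann.index, size=400, replace=False))
            res = enrich.multisample_enrichment(
                query, list(ann.index), ann, features,
                n_resamples=100, seed=i, side="positive",
            )[0]
            ps.append(res.empirical_p)
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.12

    def test_query_outside_universe_rejected(self):
        ann = toy_universe(50)
        with pytest.raises(ValueError):
            enrich.multisample_enrichment(
                ["ghost"], list(ann.index), ann, {"f": feature_over(ann, [ann.index[0]])}
            )

    def test_oversized_query_rejected(self):
        ann = toy_universe(50)
        with pytest.raises(ValueError):
            enrich.multisample_enrichment(
                list(ann.index), list(ann.index[:10]), ann,
                {"f": feature_over(ann, [ann.index[0]])},
            )


def toy_dmr(probe_ids, name="DMR1"):
    return DMR(
        chrom="chr1", start=0, end=1000, probe_ids=list(probe_ids),
        sig_probe_ids=list(probe_ids), n_significant=len(probe_ids),
        direction="hyper", mean_delta=0.3, combined_p=1e-5, name=name,
    )


class TestHypermethylationClassifier:
    def test_mean_plus_sd_rule_exact(self):
        """Reference per-sample means {0.4, 0.5, 0.6}: SD = 0.1, threshold 0.6;
        0.65 is called, 0.60 is not (strict inequality)."""
        beta = pd.DataFrame(
            {"nr1": [0.4] * 3, "nr2": [0.5] * 3, "nr3": [0.6] * 3,
             "t_hi": [0.65] * 3, "t_eq": [0.60] * 3},
            index=["cg1", "cg2", "cg3"],
        )
        calls, freq = enrich.classify_hypermethylation(
            beta, [toy_dmr(["cg1", "cg2", "cg3"])], ["t_hi", "t_eq"], ["nr1", "nr2", "nr3"]
        )
        assert np.isclose(calls["threshold"].iloc[0], 0.6)
        by_sample = calls.set_index("sample")["hypermethylated"]
        assert bool(by_sample["t_hi"]) and not bool(by_sample["t_eq"])
        assert freq["frequency"].iloc[0] == "1 of 2"

    def test_reference_cohort_too_small(self):
        beta = pd.DataFrame({"nr1": [0.4], "t": [0.9]}, index=["cg1"])
        with pytest.raises(ValueError):
            enrich.classify_hypermethylation(beta, [toy_dmr(["cg1"])], ["t"], ["nr1"])

    def test_null_call_rate_near_normal_tail(self, rng):
        """Tumours drawn from the reference distribution are called at about
        P(X > mu + sd) ~ 0.16."""
        n_dmrs, n_ref, n_tum = 400, 20, 20
        calls_frac = []
        dmrs, frames = [], {}
        cols = [f"nr{i}" for i in range(n_ref)] + [f"t{i}" for i in range(n_tum)]
        vals = rng.normal(0.5, 0.05, size=(n_dmrs * 3, len(cols)))
        beta = pd.DataFrame(np.clip(vals, 0, 1), columns=cols,
                            index=[f"cg{i}" for i in range(n_dmrs * 3)])
        dmr_list = [toy_dmr([f"cg{3*i}", f"cg{3*i+1}", f"cg{3*i+2}"], name=f"D{i}")
                    for i in range(n_dmrs)]
        calls, _ = enrich.classify_hypermethylation(
            beta, dmr_list, [f"t{i}" for i in range(n_tum)], [f"nr{i}" for i in range(n_ref)]
        )
        rate = calls["hypermethylated"].mean()
        assert abs(rate - 0.16) < 0.05

    def test_planted_shift_gives_full_frequency(self, rng):
        cols = [f"nr{i}" for i in range(13)] + [f"t{i}" for i in range(13)]
        base = rng.normal(0.4, 0.03, size=(4, 26))
        beta = pd.DataFrame(np.clip(base, 0, 1), columns=cols,
                            index=["cg1", "cg2", "cg3", "cg4"])
        beta.loc[:, [f"t{i}" for i in range(13)]] += 0.3
        _, freq = enrich.classify_hypermethylation(
            beta, [toy_dmr(["cg1", "cg2", "cg3", "cg4"])],
            [f"t{i}" for i in range(13)], [f"nr{i}" for i in range(13)]
        )
        assert freq["frequency"].iloc[0] == "13 of 13"

    def test_invariant_to_probe_order_and_na_probes(self, rng):
        beta = pd.DataFrame(
            rng.uniform(0.3, 0.7, size=(3, 6)),
            columns=["nr1", "nr2", "nr3", "t1", "t2", "t3"],
            index=["cg1", "cg2", "cg3"],
        )
        with_na = beta.copy()
        with_na.loc["cgNA"] = np.nan
        a, _ = enrich.classify_hypermethylation(
            beta, [toy_dmr(["cg1", "cg2", "cg3"])], ["t1", "t2", "t3"], ["nr1", "nr2", "nr3"]
        )
        b, _ = enrich.classify_hypermethylation(
            with_na, [toy_dmr(["cg3", "cgNA", "cg1", "cg2"])],
            ["t1", "t2", "t3"], ["nr1", "nr2", "nr3"]
        )
        assert np.allclose(a["tumour_mean"], b["tumour_mean"])
        assert (a["hypermethylated"] == b["hypermethylated"]).all()

    def test_complement_conservation(self, rng):
        """On a toy universe, a query's enrichment and its complement's are
        linked by the exact in-feature bookkeeping identity."""
        ann = toy_universe(200)
        in_feature = list(ann.index[:40])
        features = {"f": feature_over(ann, in_feature)}
        query = list(rng.choice(ann.index, size=80, replace=False))
        complement = [p for p in ann.index if p not in set(query)]
        res_q = enrich.multisample_enrichment(query, list(ann.index), ann, features,
                                              n_resamples=50, seed=4)[0]
        res_c = enrich.multisample_enrichment(complement, list(ann.index), ann, features,
                                              n_resamples=50, seed=4)[0]
        total_in = res_q.observed_fraction * 80 + res_c.observed_fraction * 120
        assert np.isclose(total_in, 40)
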
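"""Per-CpG differential methylation with empirical-Bayes variance moderation.

Two designs cover the study's contrasts:

* :func:`fit_paired` — within-patient differences between two tissues,
  tested with a moderated one-sample t statistic (equivalent, for
  complete pairs, to a patient-blocked two-group linear model);
* :func:`fit_anova3` — a three-level tissue factor with patient blocks,
  tested with a moderated F statistic on the 2-df tissue term.

Variance moderation follows the standard empirical-Bayes hierarchy: the
per-probe residual variances s_g^2 are modelled as scaled-F draws around
a prior variance s0^2 with d0 prior degrees of freedom, the
hyper-parameters estimated by method of moments on log variances, and
the posterior variance

    s~_g^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df)

replaces s_g^2 in the t/F denominators, adding d0 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ModerationParams:
    """Empirical-Bayes shrinkage hyper-parameters.

    ``d0`` may be ``inf`` (all probe variances consistent with a common
    value); ``d0 = 0`` switches moderation off.
    """

    d0: float
    s0_sq: float
    df: float

    def posterior(self, s_sq: np.ndarray) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s_sq, dtype=float), self.s0_sq)
        if self.d0 == 0:
            return np.asarray(s_sq, dtype=float)
        return (self.d0 * self.s0_sq + self.df * s_sq) / (self.d0 + self.df)


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 80) -> float:
    """Solve trigamma(y) = x for y > 0 by damped Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if y <= 0:
            y = 1e-8
        if abs(dif) < tol * (y + 1):
            break
    return float(y)


def moderate_variances(s_sq: np.ndarray, df: float) -> tuple[ModerationParams, np.ndarray]:
    """Fit (d0, s0^2) by method of moments on log variances and return the
    posterior (shrunken) variances.

    Probes with zero sample variance are excluded from hyper-parameter
    estimation but still receive a finite posterior variance, keeping the
    moderated statistics defined.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if df <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    x = s_sq[np.isfinite(s_sq)]
    if x.size == 0 or not (x > 0).any():
        raise ValueError("all probe variances are zero or missing")
    # offset exact zeros away from zero, as a scaled-chi-square draw cannot be 0
    m = float(np.median(x))
    x = np.maximum(x, 1e-5 * m if m > 0 else 1e-12)

    z = np.log(x)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if x.size > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2.0))

    if excess <= 0 or x.size == 1:
        # variances consistent with one common value: its MLE is the mean
        d0 = math.inf
        s0_sq = float(np.mean(x))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(
            e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    params = ModerationParams(d0=d0, s0_sq=s0_sq, df=df)
    return params, params.posterior(s_sq)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagated)."""
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = np.isfinite(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


def _paired_differences(
    beta: pd.DataFrame, samples: pd.DataFrame, tissue_a: str, tissue_b: str
) -> pd.DataFrame:
    """Within-patient beta differences (tissue_a - tissue_b), one column per
    patient with exactly one sample of each tissue."""
    diffs = {}
    for patient, sub in samples.groupby("patient_id"):
        a = sub.index[sub["tissue"] == tissue_a]
        b = sub.index[sub["tissue"] == tissue_b]
        if len(a) == 1 and len(b) == 1:
            diffs[patient] = beta[a[0]] - beta[b[0]]
    if len(diffs) < 2:
        raise ValueError(
            f"need >= 2 complete {tissue_a}/{tissue_b} pairs, found {len(diffs)}"
        )
    return pd.DataFrame(diffs)


def fit_paired(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    tissue_a: str,
    tissue_b: str,
    moderate: bool = True,
    patients: list[str] | None = None,
) -> pd.DataFrame:
    """Moderated paired differential methylation of ``tissue_a`` versus
    ``tissue_b`` (the reference).

    Returns an MVP table indexed by probe with columns ``delta_beta``
    (mean within-patient difference), ``t`` (moderated t), ``p``, ``fdr``
    (BH-adjusted), ``direction`` (hyper/hypo w.r.t. the reference) and
    ``n_pairs``.  Probes with any missing difference are reported with
    NaN statistics and excluded from the FDR ranking.
    """
    if patients is not None:
        samples = samples[samples["patient_id"].isin(patients)]
    diffs = _paired_differences(beta, samples, tissue_a, tissue_b)
    n = diffs.shape[1]
    complete = diffs.notna().all(axis=1)

    d = diffs.to_numpy()
    mean = np.nanmean(d, axis=1)
    with np.errstate(invalid="ignore"):
        s_sq = np.nanvar(d, axis=1, ddof=1)
    df = n - 1

    mean = np.where(complete, mean, np.nan)
    s_sq = np.where(complete, s_sq, np.nan)

    if moderate:
        params, post = moderate_variances(s_sq[complete], df)
        s_tilde = np.full_like(s_sq, np.nan)
        s_tilde[complete.to_numpy()] = post
        # total df capped at the pooled residual df across probes
        total_df = min(params.d0 + df, df * int(complete.sum()))
    else:
        params = ModerationParams(d0=0.0, s0_sq=0.0, df=df)
        s_tilde = s_sq
        total_df = df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s_tilde / n)
    p = 2.0 * stats.t.sf(np.abs(t), total_df)

    table = pd.DataFrame(
        {
            "delta_beta": mean,
            "t": t,
            "p": p,
            "fdr": bh_adjust(pd.Series(p, index=diffs.index)),
            "direction": np.where(mean >= 0, "hyper", "hypo"),
            "n_pairs": n,
        },
        index=diffs.index,
    )
    table.attrs["moderation"] = params
    table.attrs["contrast"] = f"{tissue_a}-{tissue_b}"
    return table


def _design_matrices(
    samples: pd.DataFrame, tissues: tuple[str, ...], blocked: bool
) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    """Sample order plus full (tissue + block) and reduced (block-only)
    design matrices for complete trios."""
    complete = []
    for patient, sub in samples.groupby("patient_id"):
        if all((sub["tissue"] == t).sum() == 1 for t in tissues):
            complete.append(patient)
    if len(complete) < 2:
        raise ValueError(f"need >= 2 complete trios, found {len(complete)}")
    keep = samples[samples["patient_id"].isin(complete) & samples["tissue"].isin(tissues)]
    keep = keep.sort_values(["patient_id", "tissue"], kind="mergesort")

    n = len(keep)
    tissue_dummies = np.zeros((n, len(tissues) - 1))
    for j, t in enumerate(tissues[1:]):
        tissue_dummies[:, j] = (keep["tissue"] == t).to_numpy(dtype=float)
    if blocked:
        patients_sorted = sorted(complete)
        block = np.zeros((n, len(patients_sorted) - 1))
        for j, pat in enumerate(patients_sorted[1:]):
            block[:, j] = (keep["patient_id"] == pat).to_numpy(dtype=float)
        base = np.column_stack([np.ones(n), block])
    else:
        base = np.ones((n, 1))
    full = np.column_stack([base, tissue_dummies])
    return keep.index, full, base


def fit_anova3(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    tissues: tuple[str, ...] = ("NK", "NR", "WT"),
    moderate: bool = True,
    blocked: bool = True,
) -> pd.DataFrame:
    """Moderated F test of the three-level tissue factor, patient-blocked.

    Patients lacking any of the three tissues are dropped.  Returns a
    table with per-tissue mean betas, the moderated ``F`` (2 df
    numerator), ``p``, ``fdr`` and the between-tissue range
    ``delta_beta`` (max minus min tissue mean).
    """
    order, x_full, x_red = _design_matrices(samples, tissues, blocked)
    y = beta[order].to_numpy()
    complete = ~np.isnan(y).any(axis=1)

    q_full, _ = np.linalg.qr(x_full)
    q_red, _ = np.linalg.qr(x_red)
    rank_full = np.linalg.matrix_rank(x_full)
    rank_red = np.linalg.matrix_rank(x_red)
    df_num = rank_full - rank_red
    df_res = y.shape[1] - rank_full
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    yc = np.where(complete[:, None], y, 0.0)
    rss_full = np.sum((yc - (yc @ q_full) @ q_full.T) ** 2, axis=1)
    rss_red = np.sum((yc - (yc @ q_red) @ q_red.T) ** 2, axis=1)
    s_sq = np.where(complete, rss_full / df_res, np.nan)
    ms_num = np.where(complete, (rss_red - rss_full) / df_num, np.nan)

    if moderate:
        params, post = moderate_variances(s_sq[complete], df_res)
        s_tilde = np.full_like(s_sq, np.nan)
        s_tilde[complete] = post
        total_df = min(params.d0 + df_res, df_res * int(complete.sum()))
    else:
        params = ModerationParams(d0=0.0, s0_sq=0.0, df=df_res)
        s_tilde = s_sq
        total_df = df_res

    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_num / s_tilde
    p = stats.f.sf(f, df_num, total_df)
    # identically-zero numerator and denominator: no evidence, p = 1
    degenerate = complete & (np.abs(ms_num) < 1e-12)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)

    tissue_of = samples.loc[order, "tissue"]
    means = {t: beta[order[(tissue_of == t).to_numpy()]].mean(axis=1) for t in tissues}
    mean_df = pd.DataFrame(means, index=beta.index)

    table = pd.DataFrame(
        {
            "F": pd.Series(f, index=beta.index),
            "p": pd.Series(p, index=beta.index),
            "fdr": bh_adjust(pd.Series(p, index=beta.index)),
            "delta_beta": mean_df.max(axis=1) - mean_df.min(axis=1),
        },
        index=beta.index,
    )
    for t in tissues:
        table[f"mean_{t}"] = mean_df[t]
    table.attrs["moderation"] = params
    table.attrs["n_trios"] = x_full.shape[0] // len(tissues)
    return table


def significant_probes(mvp: pd.DataFrame, fdr: float | None = 0.01, p: float | None = None) -> list[str]:
    """Probe ids passing an FDR and/or raw-p threshold (strict '<', as in
    calling MVPs at FDR < 0.01 or genome-wide significance p < 5e-8)."""
    mask = pd.Series(True, index=mvp.index)
    if fdr is not None:
        mask &= mvp["fdr"] < fdr
    if p is not None:
        mask &= mvp["p"] < p
    return list(mvp.index[mask.fillna(False)])
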
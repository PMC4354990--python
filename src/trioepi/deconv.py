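"""Reference-free cell-composition adjustment ("pheno-MVP" calling).

Bulk methylation is a mixture: each sample's beta profile is a weighted
average of the methylomes of its constituent cell types, and tissues
that differ in composition show methylation differences that have
nothing to do with phenotype.  Without reference profiles for the
constituent cell types, the mixture structure must be estimated from the
data itself:

1. fit the design (patient pairs + tissue, or group means) per probe by
   OLS — coefficients ``B`` and residuals ``E``;
2. the top ``d`` left singular vectors ``U`` of ``E`` span the
   probe-space directions along which cell composition varies between
   samples of the same tissue (``d`` is the assumed number of cell
   types; the study's operating point is ``d = 3``);
3. composition-mediated tissue differences live in the same probe-space
   directions (mixture weights sum to one, so a mean composition shift
   between tissues moves the coefficient vector inside span(U));
   the adjusted coefficients are the raw ones with their projection onto
   span(U) removed:  ``B_adj = B - U (U^T B)``;
4. uncertainty by a full-procedure bootstrap — resampling patients with
   replacement (paired designs keep pairs intact) or samples within
   groups (unpaired), repeating steps 1-3 — with per-probe p-values from
   a Student-t approximation, ``p = 2 * P(T_{u-1} > |coef| / SE_boot)``
   with ``u`` the number of independent resampling units (patients for
   paired designs), so the p-value resolution does not collapse at the
   default 100 replicates while the reference respects the limited
   number of patients behind the SE (a raw resampling-fraction mode is
   also available).

The latent dimension can be estimated from the residual matrix by
permutation parallel analysis (:func:`estimate_dimension`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DeconvResult:
    d: int
    coef: pd.Series            # adjusted coefficients, delta-beta scale
    unadjusted: pd.Series      # design-only OLS coefficients
    p: pd.Series               # bootstrap p per probe, uncorrected
    se: pd.Series
    loadings: np.ndarray       # probes x d latent methylome directions
    scores: np.ndarray         # samples x d latent scores
    n_bootstrap: int
    p_mode: str


def estimate_dimension(
    residuals: np.ndarray,
    n_permutations: int = 20,
    percentile: float = 95.0,
    seed: int = 0,
    max_d: int = 10,
) -> int:
    """Latent dimension of a residual matrix by permutation parallel analysis.

    Each observed singular value is compared with the given percentile of
    the matching singular values of ``n_permutations`` matrices obtained
    by independently permuting every column of the residuals; ``d`` is
    the number of leading singular values above their permutation
    threshold, stopping at the first that drops below.  All-zero
    residuals give ``d = 0``.
    """
    e = np.asarray(residuals, dtype=float)
    if not np.any(e):
        return 0
    rng = np.random.default_rng(seed)
    obs = np.linalg.svd(e, compute_uv=False)
    k = min(len(obs), max_d)
    perm = np.empty((n_permutations, len(obs)))
    for b in range(n_permutations):
        shuffled = np.empty_like(e)
        for j in range(e.shape[1]):
            shuffled[:, j] = rng.permutation(e[:, j])
        perm[b] = np.linalg.svd(shuffled, compute_uv=False)
    thresh = np.percentile(perm, percentile, axis=0)
    d = 0
    for i in range(k):
        if obs[i] > thresh[i]:
            d += 1
        else:
            break
    return d


def _paired_design(samples: pd.DataFrame, tissue_a: str, tissue_b: str):
    """Sample order, design matrix [patient dummies | tissue indicator] over
    complete pairs, and the patient grouping for the bootstrap."""
    pairs = []
    for patient, sub in samples.groupby("patient_id"):
        a = sub.index[sub["tissue"] == tissue_a]
        b = sub.index[sub["tissue"] == tissue_b]
        if len(a) == 1 and len(b) == 1:
            pairs.append((patient, a[0], b[0]))
    if len(pairs) < 2:
        raise ValueError(f"need >= 2 complete {tissue_a}/{tissue_b} pairs")
    order = [s for _, a, b in pairs for s in (a, b)]
    n = len(order)
    x = np.zeros((n, len(pairs) + 1))
    for i in range(len(pairs)):
        x[2 * i, i] = 1.0
        x[2 * i + 1, i] = 1.0
        x[2 * i, -1] = 1.0  # tissue_a indicator
    groups = [(2 * i, 2 * i + 1) for i in range(len(pairs))]
    return order, x, groups


def _unpaired_design(samples: pd.DataFrame, tissue_a: str, tissue_b: str):
    a = list(samples.index[samples["tissue"] == tissue_a])
    b = list(samples.index[samples["tissue"] == tissue_b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 samples of each of {tissue_a}, {tissue_b}")
    order = a + b
    n = len(order)
    x = np.ones((n, 2))
    x[len(a):, 1] = 0.0  # tissue_a indicator
    groups = [tuple(range(len(a))), tuple(range(len(a), n))]
    return order, x, groups


def _fit_adjusted(y: np.ndarray, x: np.ndarray, d: int):
    """One pass of steps 1-3: OLS, residual SVD, coefficient projection."""
    xtx_inv = np.linalg.pinv(x.T @ x)
    b = y @ x @ xtx_inv  # probes x p
    if d == 0:
        return b, b, np.zeros((y.shape[0], 0)), np.zeros((y.shape[1], 0))
    e = y - b @ x.T
    u, s, vt = np.linalg.svd(e, full_matrices=False)
    u_d = u[:, :d]
    scores = (vt[:d].T * s[:d])
    b_adj = b - u_d @ (u_d.T @ b)
    return b_adj, b, u_d, scores


def reffree_fit(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    tissue_a: str,
    tissue_b: str,
    paired: bool = True,
    d: int = 3,
    n_bootstrap: int = 100,
    seed: int = 0,
    p_mode: str = "normal",
    patients: list[str] | None = None,
) -> DeconvResult:
    """Cell-mixture-adjusted differential methylation of ``tissue_a`` versus
    ``tissue_b`` with bootstrap p-values (see module docs).

    The coefficient of interest is on the delta-beta scale (mean
    ``tissue_a`` minus ``tissue_b`` after adjustment).  Deterministic
    given ``seed``.
    """
    if n_bootstrap < 10:
        raise ValueError("n_bootstrap must be >= 10")
    if p_mode not in ("normal", "fraction"):
        raise ValueError("p_mode must be 'normal' or 'fraction'")
    if patients is not None:
        samples = samples[samples["patient_id"].isin(patients) | (samples["tissue"] == tissue_b)]
        if paired:
            samples = samples[samples["patient_id"].isin(patients)]

    build = _paired_design if paired else _unpaired_design
    order, x, groups = build(samples, tissue_a, tissue_b)
    y_df = beta[order]
    complete = y_df.notna().all(axis=1)
    y = y_df.loc[complete].to_numpy()

    max_d = y.shape[1] - np.linalg.matrix_rank(x)
    if d > max_d:
        raise ValueError(f"d={d} is not below the residual rank ({max_d})")

    b_adj, b_raw, u_d, scores = _fit_adjusted(y, x, d)
    coef = b_adj[:, -1]
    unadj = b_raw[:, -1]

    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, y.shape[0]))
    n_groups = len(groups)
    for it in range(n_bootstrap):
        take = rng.integers(0, n_groups, size=n_groups)
        if paired:
            cols = [c for g in take for c in groups[g]]
            xb = x[cols].copy()
            # re-key patient dummies so repeated patients stay distinct blocks
            xb[:, :-1] = 0.0
            for i in range(n_groups):
                xb[2 * i, i] = 1.0
                xb[2 * i + 1, i] = 1.0
        else:
            cols = []
            for g in groups:
                g = list(g)
                cols.extend(rng.choice(g, size=len(g), replace=True))
            xb = x[cols]
        yb = y[:, cols]
        boot[it] = _fit_adjusted(yb, xb, d)[0][:, -1]

    n_units = n_groups if paired else y.shape[1]
    # the n-out-of-n bootstrap of a mean underestimates its variance by
    # (n-1)/n; rescale the SE accordingly
    se = boot.std(axis=0, ddof=1) * np.sqrt(n_units / (n_units - 1))
    # t reference df: resampling units (patients for paired designs, samples
    # otherwise) minus the mean parameters and the d latent covariates that
    # are all estimated from the same units
    df_units = max((n_units - 1 - d) if paired else (n_units - 2 - d), 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        if p_mode == "normal":
            p = 2.0 * stats.t.sf(np.abs(coef) / se, df_units)
        else:
            centered = np.abs(boot - coef[None, :])
            p = (1.0 + (centered >= np.abs(coef)[None, :]).sum(axis=0)) / (1.0 + n_bootstrap)
    p = np.where(se == 0, 1.0, p)

    idx = y_df.index[complete]
    full = beta.index

    def _expand(values):
        s = pd.Series(np.nan, index=full)
        s.loc[idx] = values
        return s

    return DeconvResult(
        d=d,
        coef=_expand(coef),
        unadjusted=_expand(unadj),
        p=_expand(p),
        se=_expand(se),
        loadings=u_d,
        scores=scores,
        n_bootstrap=n_bootstrap,
        p_mode=p_mode,
    )


def overlap_mvps(mvp_a, mvp_b) -> tuple[int, float]:
    """Exact intersection count of two probe sets and its fraction of the
    first set."""
    a, b = set(mvp_a), set(mvp_b)
    n = len(a & b)
    return n, (n / len(a) if a else float("nan"))
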
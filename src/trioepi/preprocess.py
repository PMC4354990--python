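"""Probe filtering, variable-probe selection, scale transforms and
cross-platform concordance."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_CLIP = 1e-6


@dataclass
class FilterReport:
    probes_in: int
    probes_removed_by_detection: int
    probes_removed_by_flag: dict[str, int] = field(default_factory=dict)
    probes_out: int = 0
    samples_removed: int = 0


def filter_probes(
    beta: pd.DataFrame,
    ann: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    drop_flags: set[str] | tuple[str, ...] = (),
    detection_threshold: float = 0.01,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop probes with poor detection in ANY sample, or with a set drop flag.

    A probe fails detection if any sample's detection p exceeds
    ``detection_threshold`` (default 0.01).  ``drop_flags`` names boolean
    annotation columns (e.g. ``sex_chromosome``, ``snp_at_target``,
    ``multimap``); a probe is dropped if any requested flag is set.
    """
    probes_in = beta.shape[0]
    keep = pd.Series(True, index=beta.index)

    removed_detection = 0
    if detection_p is not None:
        if not detection_p.index.equals(beta.index) or not detection_p.columns.equals(beta.columns):
            raise ValueError("detection p-value matrix is not aligned to the beta matrix")
        bad = (detection_p > detection_threshold).any(axis=1)
        removed_detection = int((keep & bad).sum())
        keep &= ~bad

    removed_by_flag: dict[str, int] = {}
    for flag in drop_flags:
        if flag not in ann.columns:
            raise KeyError(f"annotation has no flag column {flag!r}")
        flagged = ann.loc[beta.index, flag].astype(bool)
        removed_by_flag[flag] = int((keep & flagged).sum())
        keep &= ~flagged

    out = beta.loc[keep]
    report = FilterReport(
        probes_in=probes_in,
        probes_removed_by_detection=removed_detection,
        probes_removed_by_flag=removed_by_flag,
        probes_out=out.shape[0],
    )
    return out, report


def top_variable(beta: pd.DataFrame, fraction: float = 0.01, statistic: str = "iqr") -> list[str]:
    """The ceil(fraction * n_probes) probes with the largest spread across all
    samples (interquartile range by default), ties broken by probe id."""
    if beta.shape[0] == 0:
        raise ValueError("empty beta matrix")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if statistic == "iqr":
        q75 = beta.quantile(0.75, axis=1)
        q25 = beta.quantile(0.25, axis=1)
        spread = q75 - q25
    elif statistic == "sd":
        spread = beta.std(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    n_take = math.ceil(fraction * beta.shape[0])
    order = pd.DataFrame({"spread_": spread.to_numpy(), "id_": list(beta.index)})
    order = order.sort_values(["spread_", "id_"], ascending=[False, True], kind="mergesort")
    return list(order["id_"].iloc[:n_take])


def beta_to_m(beta, clip: float = _CLIP):
    """M = log2(beta / (1 - beta)); beta clipped to [clip, 1 - clip]."""
    b = np.clip(np.asarray(beta, dtype=float), clip, 1 - clip)
    m = np.log2(b / (1 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m


def m_to_beta(m):
    b = 1.0 / (1.0 + np.power(2.0, -np.asarray(m, dtype=float)))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index)
    return b


def concordance(
    array_beta: pd.Series,
    bs_counts: pd.DataFrame,
) -> tuple[float, float, pd.DataFrame]:
    """Array-vs-bisulfite-sequencing agreement over shared CpGs.

    ``bs_counts`` needs columns ``methylated`` and ``total``; the
    per-CpG sequencing estimate is methylated / total.  Returns the
    Pearson correlation with the array betas, the median absolute
    difference, and the per-CpG table.  Zero-coverage CpGs are excluded
    (and counted in the table attrs).
    """
    shared = array_beta.index.intersection(bs_counts.index)
    counts = bs_counts.loc[shared]
    covered = counts["total"] > 0
    n_zero = int((~covered).sum())
    counts = counts.loc[covered]
    if counts.shape[0] < 2:
        raise ValueError("need >= 2 covered CpGs to compute a correlation")
    prop = counts["methylated"] / counts["total"]
    beta = array_beta.loc[counts.index]
    r = float(np.corrcoef(prop, beta)[0, 1])
    diffs = (prop - beta).abs()
    table = pd.DataFrame({
        "beta": beta, "methylated": counts["methylated"], "total": counts["total"],
        "proportion": prop, "abs_diff": diffs,
    })
    table.attrs["zero_coverage_excluded"] = n_zero
    return r, float(diffs.median()), table
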
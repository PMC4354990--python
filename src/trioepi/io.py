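"""Readers and writers for the on-disk cohort artefacts.

Conventions, stated once and tested at the boundaries:

* ``beta.tsv`` — tab-separated, probe rows, sample columns, header row of
  sample ids, first column ``probe_id``.  Values are methylation fractions
  in [0, 1]; missing values are written as ``NA``.
* ``probes.csv`` — Illumina-manifest-like annotation: ``probe_id, chrom,
  pos, gene_feature, cgi_relation, sex_chromosome, snp_at_target,
  multimap``.  ``pos`` is the 1-based coordinate of the interrogated CpG
  (MAPINFO convention).
* ``samples.csv`` — ``sample_id, patient_id, tissue, laterality`` and an
  optional ``subgroup`` column.  Tissue codes: NK (normal kidney), NR
  (nephrogenic rest), WT (Wilms tumour), EK (embryonic kidney).
* BED files — 0-based half-open intervals.  A 1-based probe position
  ``pos`` falls in ``[start, end)`` iff ``start <= pos - 1 < end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_FEATURES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")
CGI_RELATIONS = ("island", "shore", "shelf", "open_sea")
TISSUES = ("NK", "NR", "WT", "EK")
PROBE_FLAGS = ("sex_chromosome", "snp_at_target", "multimap")


class CohortValidationError(ValueError):
    """Raised when an on-disk artefact violates the format contract."""


# ---------------------------------------------------------------------------
# beta matrix


def read_beta(path: str | Path) -> pd.DataFrame:
    """Read a probe x sample beta-value TSV into a float DataFrame.

    Raises :class:`CohortValidationError` naming the offending probe/sample
    for duplicate ids, non-numeric cells or values outside [0, 1].
    ``NA`` cells become ``NaN``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise CohortValidationError(f"duplicate probe id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise CohortValidationError(f"duplicate sample id {dup!r} in {path}")
    for col in df.columns:
        if df[col].dtype == object:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise CohortValidationError(
                    f"non-numeric value {bad.iloc[0]!r} at probe {bad.index[0]!r}, "
                    f"sample {col!r} in {path}"
                )
    values = df.astype(float)
    out_of_range = (values < 0) | (values > 1)
    if out_of_range.any().any():
        col = out_of_range.any(axis=0).idxmax()
        row = out_of_range[col].idxmax()
        raise CohortValidationError(
            f"beta value {values.at[row, col]} outside [0, 1] at probe {row!r}, "
            f"sample {col!r} in {path}"
        )
    values.index.name = "probe_id"
    return values


def write_beta(beta: pd.DataFrame, path: str | Path) -> None:
    """Write a beta matrix as TSV with 9-decimal precision (lossless to 1e-9)."""
    out = beta.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.9f", na_rep="NA")


# ---------------------------------------------------------------------------
# probe annotation and sample sheet


def read_probes(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, index_col="probe_id")
    required = {"chrom", "pos", "gene_feature", "cgi_relation"}
    missing = required - set(ann.columns)
    if missing:
        raise CohortValidationError(f"probe annotation missing columns {sorted(missing)}")
    if ann.index.has_duplicates:
        raise CohortValidationError("duplicate probe ids in annotation")
    if (ann["pos"] < 1).any():
        raise CohortValidationError("probe positions must be >= 1 (1-based)")
    bad_gf = set(ann["gene_feature"]) - set(GENE_FEATURES)
    if bad_gf:
        raise CohortValidationError(f"unknown gene_feature categories {sorted(bad_gf)}")
    bad_ci = set(ann["cgi_relation"]) - set(CGI_RELATIONS)
    if bad_ci:
        raise CohortValidationError(f"unknown cgi_relation categories {sorted(bad_ci)}")
    for flag in PROBE_FLAGS:
        if flag not in ann.columns:
            ann[flag] = False
        else:
            ann[flag] = ann[flag].astype(bool)
    return ann


def write_probes(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out.index.name = "probe_id"
    out.to_csv(path)


def read_samples(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, index_col="sample_id")
    required = {"patient_id", "tissue"}
    missing = required - set(sheet.columns)
    if missing:
        raise CohortValidationError(f"sample sheet missing columns {sorted(missing)}")
    bad = set(sheet["tissue"]) - set(TISSUES)
    if bad:
        raise CohortValidationError(f"unknown tissue labels {sorted(bad)}")
    if "laterality" not in sheet.columns:
        sheet["laterality"] = "NA"
    return sheet


def write_samples(sheet: pd.DataFrame, path: str | Path) -> None:
    out = sheet.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a >=3-column BED file into a sorted (chrom, start, end[, name]) frame.

    Intervals are 0-based half-open.  Malformed lines are reported with
    their 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CohortValidationError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise CohortValidationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise CohortValidationError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, name))
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return bed.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_bed(bed: pd.DataFrame, path: str | Path, extra_cols: list[str] | None = None) -> None:
    """Write sorted BED4(+); ``extra_cols`` are appended after the name column."""
    cols = ["chrom", "start", "end"]
    if "name" in bed.columns:
        cols.append("name")
    if extra_cols:
        cols.extend(extra_cols)
    out = bed.sort_values(["chrom", "start", "end"], kind="mergesort")
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def probes_in_intervals(ann: pd.DataFrame, bed: pd.DataFrame) -> pd.Series:
    """Boolean membership of each annotated probe in the union of BED intervals.

    Probe positions are 1-based; a probe is inside iff ``pos - 1`` lies in
    some half-open ``[start, end)``.
    """
    inside = pd.Series(False, index=ann.index)
    for chrom, sub in bed.groupby("chrom"):
        mask = ann["chrom"] == chrom
        if not mask.any():
            continue
        pos0 = ann.loc[mask, "pos"].to_numpy() - 1
        starts, ends = _merged_arrays(sub)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        inside.loc[mask] = ok
    return inside


def _merged_arrays(bed_chrom: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping intervals of one chromosome into disjoint sorted arrays."""
    ivals = bed_chrom[["start", "end"]].sort_values("start").to_numpy()
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    arr = np.asarray(merged)
    return arr[:, 0], arr[:, 1]


# ---------------------------------------------------------------------------
# cohort bundle


@dataclass
class Cohort:
    """A validated, loaded cohort: the central in-memory bundle.

    ``beta`` rows are ordered by (chrom, pos) of the annotation; ``probes``
    shares the same index.  ``features`` maps feature-set names to BED
    frames.  ``truth`` is present only for synthetic cohorts.
    """

    beta: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame
    features: dict[str, pd.DataFrame] = field(default_factory=dict)
    truth: dict | None = None

    def complete_trios(self) -> list[str]:
        """Patients with exactly one NK, one NR and one WT sample."""
        out = []
        for patient, sub in self.samples.groupby("patient_id"):
            counts = sub["tissue"].value_counts()
            if all(counts.get(t, 0) == 1 for t in ("NK", "NR", "WT")):
                out.append(patient)
        return sorted(out)

    def tissue_samples(self, tissue: str) -> list[str]:
        return list(self.samples.index[self.samples["tissue"] == tissue])


def load_cohort(directory: str | Path) -> Cohort:
    """Load ``beta.tsv``, ``probes.csv``, ``samples.csv`` (+ ``features/*.bed``,
    ``truth.json``) from a directory, cross-check ids and order probes by
    genomic position.

    Samples present in only one of sheet/matrix are a hard error.  Patients
    with incomplete trios are retained but logged; paired analyses skip them.
    """
    directory = Path(directory)
    beta = read_beta(directory / "beta.tsv")
    probes = read_probes(directory / "probes.csv")
    samples = read_samples(directory / "samples.csv")

    missing_in_matrix = set(samples.index) - set(beta.columns)
    if missing_in_matrix:
        raise CohortValidationError(
            f"samples in sheet but not in beta matrix: {sorted(missing_in_matrix)}"
        )
    extra_in_matrix = set(beta.columns) - set(samples.index)
    if extra_in_matrix:
        raise CohortValidationError(
            f"samples in beta matrix but not in sheet: {sorted(extra_in_matrix)}"
        )
    missing_probes = set(beta.index).symmetric_difference(probes.index)
    if missing_probes:
        raise CohortValidationError(
            f"{len(missing_probes)} probes not shared between beta matrix and annotation"
        )

    probes = probes.sort_values(["chrom", "pos"], kind="mergesort")
    beta = beta.loc[probes.index, list(samples.index)]

    features: dict[str, pd.DataFrame] = {}
    feat_dir = directory / "features"
    if feat_dir.is_dir():
        for bed_path in sorted(feat_dir.glob("*.bed")):
            features[bed_path.stem] = read_bed(bed_path)

    truth = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        import json

        truth = json.loads(truth_path.read_text())

    cohort = Cohort(beta=beta, probes=probes, samples=samples, features=features, truth=truth)
    n_trios = len(cohort.complete_trios())
    n_patients = samples.loc[samples["tissue"] != "EK", "patient_id"].nunique()
    logger.info(
        "loaded cohort: %d probes, %d samples, %d complete trios",
        beta.shape[0], beta.shape[1], n_trios,
    )
    if n_trios < n_patients:
        logger.warning(
            "%d patient(s) lack a complete NK/NR/WT trio and are excluded from paired analyses",
            n_patients - n_trios,
        )
    return cohort
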
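"""Paired tumor/blood copy-number cohorts and their tabular on-disk layouts.

A cohort holds, for one chromosome, an ``n x m`` copy-number (CN) matrix per
tissue: one row per patient, one column per locus, diploid baseline 2.  Two
plain-text layouts are supported:

``interleaved``
    One row per *sample*, alternating cancer/blood per patient (observation
    rows: ``cancer, blood, cancer, blood, ...``), a ``group`` column carrying
    the tissue label.
``paired-columns``
    One row per *patient*, and for every locus two adjacent columns
    (``loc_<j>_cancer``, ``loc_<j>_blood``).

Files are TSV by default; a comma delimiter is sniffed from the header line.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

INTERLEAVED = "interleaved"
PAIRED_COLUMNS = "paired-columns"
LAYOUTS = (INTERLEAVED, PAIRED_COLUMNS)

CANCER = "cancer"
BLOOD = "blood"

_GROUP_COLUMN_NAMES = {"group", "true group", "true_group", "truegroup"}


class CohortStructureError(ValueError):
    """The file or matrices do not have the required paired structure."""


class CohortParseError(ValueError):
    """A cell could not be parsed as a copy-number value."""


def default_patient_ids(n: int) -> list[str]:
    return [f"P{i}" for i in range(1, n + 1)]


@dataclass
class PairedCohort:
    """CN matrices for paired cancer/blood samples on one chromosome.

    ``cancer_cn`` and ``blood_cn`` are ``n x m`` float arrays aligned by
    patient (rows) and locus (columns); ``loci`` are 1-based ordered locus
    indices.
    """

    chromosome_id: str
    patient_ids: list[str]
    loci: list[int]
    cancer_cn: np.ndarray
    blood_cn: np.ndarray

    def __post_init__(self) -> None:
        self.cancer_cn = np.asarray(self.cancer_cn, dtype=float)
        self.blood_cn = np.asarray(self.blood_cn, dtype=float)
        if self.cancer_cn.ndim != 2 or self.blood_cn.ndim != 2:
            raise CohortStructureError("CN matrices must be 2-dimensional")
        if self.cancer_cn.shape != self.blood_cn.shape:
            raise CohortStructureError(
                f"cancer {self.cancer_cn.shape} and blood {self.blood_cn.shape} "
                "matrices must have identical shape"
            )
        n, m = self.cancer_cn.shape
        if len(self.patient_ids) != n:
            raise CohortStructureError("patient_ids length must match row count")
        if len(self.loci) != m:
            raise CohortStructureError("loci length must match column count")
        if m and not np.all(np.diff(self.loci) > 0):
            raise CohortStructureError("locus order must be strictly increasing")
        for name, mat in (("cancer", self.cancer_cn), ("blood", self.blood_cn)):
            if mat.size and not np.all(np.isfinite(mat)):
                raise CohortParseError(f"non-finite value in {name} matrix")
            if mat.size and np.any(mat < 0):
                raise CohortParseError(f"negative copy number in {name} matrix")

    @property
    def n(self) -> int:
        return self.cancer_cn.shape[0]

    @property
    def m(self) -> int:
        return self.cancer_cn.shape[1]

    def validate(self, strict_range: bool = False, low: float = 1.0, high: float = 3.0) -> None:
        """Check population invariants; optionally warn on values outside [low, high]."""
        if self.n < 2:
            raise CohortStructureError("a cohort requires at least 2 patients")
        if self.m < 1:
            raise CohortStructureError("a cohort requires at least 1 locus")
        if strict_range:
            for name, mat in (("cancer", self.cancer_cn), ("blood", self.blood_cn)):
                out = np.sum((mat < low) | (mat > high))
                if out:
                    warnings.warn(
                        f"{out} {name} CN values outside [{low}, {high}] "
                        f"on {self.chromosome_id}",
                        stacklevel=2,
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairedCohort):
            return NotImplemented
        return (
            self.chromosome_id == other.chromosome_id
            and self.patient_ids == other.patient_ids
            and list(self.loci) == list(other.loci)
            and self.cancer_cn.shape == other.cancer_cn.shape
            and np.array_equal(self.cancer_cn, other.cancer_cn)
            and np.array_equal(self.blood_cn, other.blood_cn)
        )


@dataclass
class UnlabeledSampleMatrix:
    """2n samples by d features, with held-out tissue labels.

    ``true_labels`` exist only for evaluation; the clustering path never
    reads them.  Row order is the interleaved observation order: patient 1
    cancer, patient 1 blood, patient 2 cancer, ...
    """

    sample_ids: list[str]
    true_labels: np.ndarray  # evaluation-only
    values: np.ndarray
    feature_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.true_labels = np.asarray(self.true_labels, dtype=object)
        if self.values.ndim != 2:
            raise CohortStructureError("sample matrix must be 2-dimensional")
        if len(self.sample_ids) != self.values.shape[0]:
            raise CohortStructureError("sample_ids length must match row count")
        if self.true_labels.shape[0] != self.values.shape[0]:
            raise CohortStructureError("true_labels length must match row count")
        if not self.feature_ids:
            self.feature_ids = list(range(1, self.values.shape[1] + 1))
        if len(self.feature_ids) != self.values.shape[1]:
            raise CohortStructureError("feature_ids length must match column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def to_unlabeled(cohort: PairedCohort) -> UnlabeledSampleMatrix:
    """Stack a cohort into the 2n x m unlabeled matrix used for clustering."""
    cohort.validate()
    n, m = cohort.n, cohort.m
    values = np.empty((2 * n, m), dtype=float)
    values[0::2] = cohort.cancer_cn
    values[1::2] = cohort.blood_cn
    sample_ids, labels = [], []
    for pid in cohort.patient_ids:
        sample_ids.extend([f"{pid}_{CANCER}", f"{pid}_{BLOOD}"])
        labels.extend([CANCER, BLOOD])
    return UnlabeledSampleMatrix(
        sample_ids=sample_ids,
        true_labels=np.array(labels, dtype=object),
        values=values,
        feature_ids=list(cohort.loci),
    )


# ---------------------------------------------------------------------------
# reading


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _locus_index(name: str, ordinal: int) -> int:
    m = re.search(r"(\d+)\s*$", str(name).replace(",", ""))
    return int(m.group(1)) if m else ordinal


def _numeric_block(df: pd.DataFrame, path: Path) -> np.ndarray:
    """Parse a sub-frame to floats, naming the first offending cell.

    Uses Python/numpy float parsing (correctly rounded) rather than pandas'
    fast parser so that full-precision values round-trip bit-exactly.
    """
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        vals = df[col].to_numpy()
        try:
            out[:, j] = vals.astype(np.float64)
        except (ValueError, TypeError):
            for i, v in enumerate(vals):
                try:
                    float(v)
                except (ValueError, TypeError):
                    raise CohortParseError(
                        f"{path}: cannot parse value {v!r} at data row {i + 1}, "
                        f"column {col!r}"
                    ) from None
            raise
        bad = ~np.isfinite(out[:, j])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortParseError(
                f"{path}: missing or non-finite value at data row {row + 1}, column {col!r}"
            )
    return out


def read_cohort(path: str | Path, layout: str, chromosome_id: str | None = None) -> PairedCohort:
    """Read a paired cohort from a TSV/CSV file in the given layout."""
    path = Path(path)
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if chromosome_id is None:
        chromosome_id = path.stem
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if layout == INTERLEAVED:
        return _read_interleaved(df, path, chromosome_id)
    return _read_paired_columns(df, path, chromosome_id)


def _read_interleaved(df: pd.DataFrame, path: Path, chromosome_id: str) -> PairedCohort:
    lower = [str(c).strip().lower() for c in df.columns]
    try:
        g = next(i for i, c in enumerate(lower) if c in _GROUP_COLUMN_NAMES)
    except StopIteration:
        raise CohortStructureError(f"{path}: no group column found (expected one of {sorted(_GROUP_COLUMN_NAMES)})")
    locus_cols = list(df.columns[g + 1 :])
    if not locus_cols:
        raise CohortStructureError(f"{path}: no locus columns after the group column")
    rows = len(df)
    if rows == 0 or rows % 2:
        raise CohortStructureError(f"{path}: interleaved layout requires an even number of data rows, got {rows}")
    groups = [str(v).strip().lower() for v in df.iloc[:, g]]
    for i, grp in enumerate(groups):
        expected = CANCER if i % 2 == 0 else BLOOD
        if grp != expected:
            raise CohortStructureError(
                f"{path}: data row {i + 1} has group {grp!r}, expected {expected!r} "
                "(strict cancer/blood alternation starting with cancer)"
            )
    values = _numeric_block(df[locus_cols], path)
    loci = [_locus_index(c, j + 1) for j, c in enumerate(locus_cols)]
    n = rows // 2
    return PairedCohort(
        chromosome_id=chromosome_id,
        patient_ids=default_patient_ids(n),
        loci=loci,
        cancer_cn=values[0::2],
        blood_cn=values[1::2],
    )


def _read_paired_columns(df: pd.DataFrame, path: Path, chromosome_id: str) -> PairedCohort:
    cols = list(df.columns)
    if len(cols) < 3:
        raise CohortStructureError(f"{path}: paired-columns layout requires patient + per-locus column pairs")
    patient_ids = [str(v) for v in df.iloc[:, 0]]
    cancer_cols: dict[int, str] = {}
    blood_cols: dict[int, str] = {}
    for ordinal, c in enumerate(cols[1:], start=1):
        name = str(c).strip().lower()
        if name.endswith("_cancer") or name.endswith(" cancer"):
            cancer_cols[_locus_index(name[: -len("_cancer")], ordinal)] = c
        elif name.endswith("_blood") or name.endswith(" blood"):
            blood_cols[_locus_index(name[: -len("_blood")], ordinal)] = c
        else:
            raise CohortStructureError(f"{path}: column {c!r} is neither *_cancer nor *_blood")
    if set(cancer_cols) != set(blood_cols):
        raise CohortStructureError(
            f"{path}: mismatched locus sets between cancer ({len(cancer_cols)}) "
            f"and blood ({len(blood_cols)}) columns"
        )
    loci = sorted(cancer_cols)
    cancer = _numeric_block(df[[cancer_cols[j] for j in loci]], path)
    blood = _numeric_block(df[[blood_cols[j] for j in loci]], path)
    return PairedCohort(
        chromosome_id=chromosome_id,
        patient_ids=patient_ids,
        loci=loci,
        cancer_cn=cancer,
        blood_cn=blood,
    )


# ---------------------------------------------------------------------------
# writing


def write_cohort(cohort: PairedCohort, path: str | Path, layout: str, sep: str = "\t") -> None:
    """Write a cohort to disk; round-trips bit-exactly through read_cohort."""
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    if cohort.m < 1:
        raise CohortStructureError("refusing to write a cohort with no loci (m = 0)")
    cohort.validate()
    path = Path(path)
    # floats are written with shortest-repr so read_cohort(write_cohort(x)) == x
    try:
        with open(path, "w") as fh:
            if layout == INTERLEAVED:
                header = ["observation", "group"] + [f"loc_{j}" for j in cohort.loci]
                fh.write(sep.join(header) + "\n")
                for i in range(cohort.n):
                    for group, mat in ((CANCER, cohort.cancer_cn), (BLOOD, cohort.blood_cn)):
                        obs = 2 * i + (1 if group == CANCER else 2)
                        cells = [str(obs), group] + [repr(float(v)) for v in mat[i]]
                        fh.write(sep.join(cells) + "\n")
            else:
                header = ["patient"]
                for j in cohort.loci:
                    header += [f"loc_{j}_cancer", f"loc_{j}_blood"]
                fh.write(sep.join(header) + "\n")
                for i, pid in enumerate(cohort.patient_ids):
                    cells = [str(pid)]
                    for j in range(cohort.m):
                        cells.append(repr(float(cohort.cancer_cn[i, j])))
                        cells.append(repr(float(cohort.blood_cn[i, j])))
                    fh.write(sep.join(cells) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing cohort to {path}: {exc}") from exc
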
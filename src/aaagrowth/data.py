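"""Domain types and delimited-text I/O for longitudinal diameter cohorts.

A cohort is a collection of subjects, each carrying a time-ordered series of
ultrasound diameter measurements (mm) on a common time axis (years since each
subject's first screen), optional baseline covariates, and a record of how the
series ended (surgery referral, death, loss to follow-up, or administrative
censoring).  Screens known only to lie below a detection bound (e.g. aortas
measuring under 30 mm, which are not followed up) are represented as
left-censored records.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Measurement",
    "Subject",
    "LongitudinalDataset",
    "CohortSummary",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
]

TERMINATION_MODES = ("administrative", "surgery", "death", "lost")


@dataclass(frozen=True)
class Measurement:
    """One scan: either an observed diameter or a left-censored bound.

    Exactly one of ``value`` / ``censored_below`` is present.  ``time`` is in
    years since the subject's time origin and must be non-negative; diameters
    are in mm.
    """

    time: float
    value: float | None = None
    censored_below: float | None = None

    def __post_init__(self) -> None:
        if (self.value is None) == (self.censored_below is None):
            raise ValueError(
                "exactly one of value / censored_below must be given "
                f"(got value={self.value}, censored_below={self.censored_below})"
            )
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(f"time must be a non-negative real, got {self.time}")
        if self.value is not None and not (math.isfinite(self.value) and self.value > 0):
            raise ValueError(f"value must be a positive real, got {self.value}")
        if self.censored_below is not None and not (
            math.isfinite(self.censored_below) and self.censored_below > 0
        ):
            raise ValueError(f"censored_below must be positive, got {self.censored_below}")

    @property
    def is_censored(self) -> bool:
        return self.censored_below is not None


@dataclass(frozen=True)
class Subject:
    """A subject's measurement series plus time-constant baseline covariates."""

    subject_id: str
    measurements: tuple[Measurement, ...]
    covariates: dict[str, float] = field(default_factory=dict)
    termination: str | None = None

    def __post_init__(self) -> None:
        if len(self.measurements) == 0:
            raise ValueError(f"subject {self.subject_id!r} has no measurements")
        times = [m.time for m in self.measurements]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"subject {self.subject_id!r}: measurement times must be strictly increasing"
            )
        if self.termination is not None and self.termination not in TERMINATION_MODES:
            raise ValueError(
                f"termination must be one of {TERMINATION_MODES} or None, got {self.termination!r}"
            )
        object.__setattr__(self, "measurements", tuple(self.measurements))

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time for m in self.measurements], dtype=float)

    @property
    def values(self) -> np.ndarray:
        """Observed diameters; NaN for censored records."""
        return np.array(
            [m.value if m.value is not None else np.nan for m in self.measurements],
            dtype=float,
        )

    @property
    def n_scans(self) -> int:
        return len(self.measurements)

    @property
    def follow_up_years(self) -> float:
        return self.measurements[-1].time - self.measurements[0].time

    def first_k(self, k: int) -> "Subject":
        """A copy keeping only the first *k* scans (for prediction-set builds)."""
        if k < 1 or k > self.n_scans:
            raise ValueError(f"k must be in [1, {self.n_scans}], got {k}")
        return replace(self, measurements=self.measurements[:k], termination=None)


@dataclass(frozen=True)
class LongitudinalDataset:
    """A validated cohort: unique subject ids, at least one observed diameter."""

    subjects: tuple[Subject, ...]
    time_origin_label: str = "screening"

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes[:5]}")
        if not any(m.value is not None for s in self.subjects for m in s.measurements):
            raise ValueError("dataset must contain at least one non-censored measurement")
        object.__setattr__(self, "subjects", tuple(self.subjects))

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for s in self.subjects:
            for k in s.covariates:
                if k not in names:
                    names.append(k)
        return tuple(names)

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per measurement."""
        rows = []
        for s in self.subjects:
            for m in s.measurements:
                row: dict[str, object] = {
                    "subject_id": s.subject_id,
                    "time": m.time,
                    "value": m.value if m.value is not None else "",
                    "censored_below": m.censored_below if m.is_censored else "",
                    "termination": s.termination or "",
                }
                for name in self.covariate_names:
                    v = s.covariates.get(name)
                    row[name] = "" if v is None else v
                rows.append(row)
        cols = ["subject_id", "time", "value", "censored_below", "termination"]
        cols += list(self.covariate_names)
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class CohortSummary:
    n_subjects: int
    n_measurements: int
    n_censored: int
    mean_scans_per_subject: float
    mean_follow_up_years: float
    baseline_histogram: dict[str, int]
    termination_fractions: dict[str, float]


_RESERVED_COLUMNS = {"subject_id", "time", "value", "censored_below", "termination"}


def read_cohort(path_or_buffer, time_origin_label: str = "screening") -> LongitudinalDataset:
    """Read a cohort from comma-separated text.

    Required columns: ``subject_id``, ``time``, ``value``.  Optional:
    ``censored_below`` (a bound in mm; when set, ``value`` must be empty),
    ``termination``, plus any number of numeric covariate columns.  Rows are
    grouped by subject and sorted by time; duplicate (subject, time) pairs,
    negative times and non-numeric values are rejected.
    """
    df = pd.read_csv(path_or_buffer, dtype={"subject_id": str},
                     float_precision="round_trip")
    return dataset_from_frame(df, time_origin_label=time_origin_label)


def dataset_from_frame(
    df: pd.DataFrame, time_origin_label: str = "screening"
) -> LongitudinalDataset:
    """Build a validated dataset from a long-format frame (see read_cohort)."""
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    missing = {"subject_id", "time", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    covariate_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]

    numeric_cols = ["time", "value"]
    if "censored_below" in df.columns:
        numeric_cols.append("censored_below")
    for col in numeric_cols + covariate_cols:
        try:
            col_data = df[col]
            if col_data.dtype == object:
                col_data = col_data.mask(col_data == "", np.nan)
            df[col] = pd.to_numeric(col_data)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric entry in column {col!r}: {exc}") from exc
    if (df["time"] < 0).any():
        bad = df.loc[df["time"] < 0].iloc[0]
        raise ValueError(f"negative time {bad['time']} for subject {bad['subject_id']!r}")
    dup = df.duplicated(subset=["subject_id", "time"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate (subject, time) pair: ({bad['subject_id']!r}, {bad['time']})"
        )

    subjects = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("time")
        measurements = []
        for _, row in grp.iterrows():
            value = row["value"]
            bound = row.get("censored_below", np.nan)
            measurements.append(
                Measurement(
                    time=float(row["time"]),
                    value=None if pd.isna(value) else float(value),
                    censored_below=None if pd.isna(bound) else float(bound),
                )
            )
        covariates = {}
        for c in covariate_cols:
            v = grp[c].iloc[0]
            if not pd.isna(v) and v != "":
                covariates[c] = float(v)
        term = None
        if "termination" in grp.columns:
            t = grp["termination"].iloc[0]
            if isinstance(t, str) and t:
                term = t
        subjects.append(
            Subject(
                subject_id=str(sid),
                measurements=tuple(measurements),
                covariates=covariates,
                termination=term,
            )
        )
    return LongitudinalDataset(subjects=tuple(subjects), time_origin_label=time_origin_label)


def write_cohort(dataset: LongitudinalDataset, path) -> None:
    """Write a cohort as comma-separated text, losslessly round-trippable.

    The censor column is only emitted when censored records exist, and
    covariate columns only when at least one subject carries them.
    """
    df = dataset.to_frame()
    if not any(m.is_censored for s in dataset for m in s.measurements):
        df = df.drop(columns=["censored_below"])
    if not any(s.termination for s in dataset):
        df = df.drop(columns=["termination"])
    # %.17g guarantees bit-exact round-tripping of binary doubles
    df.to_csv(path, index=False, float_format="%.17g")


def summarize_cohort(dataset: LongitudinalDataset, bin_width: float = 2.0) -> CohortSummary:
    """Descriptive summary: size, scan intensity, follow-up, baseline histogram.

    The baseline histogram bins each subject's first *observed* diameter into
    ``bin_width``-mm bins (censored-only subjects are excluded from it).
    Invariant to subject ordering.
    """
    n = len(dataset)
    n_meas = sum(s.n_scans for s in dataset)
    n_cens = sum(m.is_censored for s in dataset for m in s.measurements)
    mean_scans = n_meas / n if n else float("nan")
    mean_fu = float(np.mean([s.follow_up_years for s in dataset])) if n else float("nan")

    baselines = []
    for s in dataset:
        for m in s.measurements:
            if m.value is not None:
                baselines.append(m.value)
                break
    hist: dict[str, int] = {}
    if baselines:
        lo = bin_width * math.floor(min(baselines) / bin_width)
        hi = bin_width * math.ceil(max(baselines) / bin_width)
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, _ = np.histogram(baselines, bins=edges)
        for left, c in zip(edges[:-1], counts):
            hist[f"[{left:g},{left + bin_width:g})"] = int(c)

    term_counts: dict[str, int] = {}
    for s in dataset:
        if s.termination:
            term_counts[s.termination] = term_counts.get(s.termination, 0) + 1
    term_frac = {k: v / n for k, v in sorted(term_counts.items())}

    return CohortSummary(
        n_subjects=n,
        n_measurements=n_meas,
        n_censored=n_cens,
        mean_scans_per_subject=mean_scans,
        mean_follow_up_years=mean_fu,
        baseline_histogram=hist,
        termination_fractions=term_frac,
    )


def cohort_to_string(dataset: LongitudinalDataset) -> str:
    buf = io.StringIO()
    write_cohort(dataset, buf)
    return buf.getvalue()
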
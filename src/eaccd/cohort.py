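"""Patient-level cohort handling.

Reads factor-coded censored-survival patient tables, excludes records with
unknown values (no imputation), aggregates patients into *combinations* —
the subsets sharing one tuple of factor levels, e.g. ``T4N1M1`` — and splits
cohorts by diagnosis year into training and validation sets.  Combinations,
not individual patients, are the unit that the clustering machinery in
:mod:`eaccd.eaccd_core` operates on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .survival_stats import SurvivalSample

logger = logging.getLogger("eaccd.cohort")

#: Marker for a missing / unknown cell, kept through reading and handled at
#: filtering time (records with unknown values are excluded, never imputed).
UNKNOWN = "unknown"

TIME_COL = "time_months"
EVENT_COL = "event"
YEAR_COL = "year"
ID_COL = "id"


class CohortFormatError(ValueError):
    """The input table does not match the expected schema."""


class RowParseError(ValueError):
    """A data row holds an unparseable value.

    ``row`` is the 1-based index of the offending data row (header excluded).
    """

    def __init__(self, message: str, row: int):
        super().__init__(message)
        self.row = row


@dataclass(frozen=True)
class FactorScheme:
    """Ordered factors and their allowed level codes.

    The default scheme codes the seven prostate-cancer prognostic variables:
    tumor extent T, nodal spread N, distant metastasis M, PSA category P,
    Grade Group G, age category A and race category R.
    """

    factors: tuple[str, ...]
    levels: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.factors) != set(self.levels):
            raise ValueError("factors and level table must cover the same names")
        for f, lv in self.levels.items():
            if len(set(lv)) != len(lv):
                raise ValueError(f"duplicate level codes for factor {f!r}")

    def subset(self, factors: Sequence[str]) -> "FactorScheme":
        """Restrict the scheme to ``factors``, kept in scheme order."""
        missing = [f for f in factors if f not in self.levels]
        if missing:
            raise ValueError(f"unknown factors: {missing}")
        ordered = tuple(f for f in self.factors if f in set(factors))
        return FactorScheme(ordered, {f: self.levels[f] for f in ordered})

    def level_rank(self, factor: str, level: str) -> int:
        return self.levels[factor].index(level)

    def label(self, levels: Mapping[str, str], factors: Sequence[str] | None = None) -> str:
        """Concatenated level codes in scheme factor order, e.g. ``T4N1M1``."""
        use = factors if factors is not None else self.factors
        ordered = [f for f in self.factors if f in set(use)]
        return "".join(levels[f] for f in ordered)


DEFAULT_SCHEME = FactorScheme(
    factors=("T", "N", "M", "P", "G", "A", "R"),
    levels={
        "T": ("T1", "T2a", "T2bc", "T3", "T4"),
        "N": ("N0", "N1"),
        "M": ("M0", "M1"),
        "P": ("P1", "P2", "P3"),
        "G": ("G1", "G2", "G3", "G4", "G5"),
        "A": ("A0", "A1"),
        "R": ("R1", "R2", "R3"),
    },
)

#: The five staging variables shared with the AJCC TNM system.
CORE_FACTORS = ("T", "N", "M", "P", "G")


@dataclass(frozen=True)
class Combination:
    """One factor-level tuple; ``levels`` is ((factor, level), ...) in scheme order."""

    levels: tuple[tuple[str, str], ...]
    label: str

    def level_map(self) -> dict[str, str]:
        return dict(self.levels)


@dataclass(frozen=True)
class CombinationCohort:
    """The patients sharing one combination, with their survival sample."""

    combination: Combination
    times: np.ndarray
    events: np.ndarray

    @property
    def size(self) -> int:
        return len(self.times)

    @property
    def label(self) -> str:
        return self.combination.label

    def sample(self) -> SurvivalSample:
        return SurvivalSample(self.times, self.events)


@dataclass(frozen=True)
class CombinationSet:
    """Ordered collection of combination cohorts over a fixed factor subset."""

    cohorts: tuple[CombinationCohort, ...]
    factors: tuple[str, ...]
    dropped_patients: int = 0

    @property
    def n(self) -> int:
        return len(self.cohorts)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.cohorts)

    @property
    def n_patients(self) -> int:
        return int(sum(c.size for c in self.cohorts))


def _normalize_cell(value: object) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    text = str(value).strip()
    if text == "" or text.lower() == UNKNOWN:
        return UNKNOWN
    return text


def read_patient_table(path, scheme: FactorScheme | None = None) -> pd.DataFrame:
    """Read a patient CSV into a validated DataFrame.

    Expected columns: the scheme's factor columns, ``time_months`` (months,
    nonnegative real) and ``event`` (1 = death from prostate cancer,
    0 = censored), plus optional ``year`` and ``id``.  When ``scheme`` is
    None the factor columns are inferred from the header: the five core
    factors T, N, M, P, G are required and A, R are picked up if present.

    Unknown cells (blank or the literal ``unknown``) are preserved as
    markers, not dropped — exclusion happens in :func:`filter_records`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    header = list(raw.columns)

    if scheme is None:
        missing_core = [f for f in CORE_FACTORS if f not in header]
        if missing_core:
            raise CohortFormatError(f"missing required column {missing_core[0]!r}")
        scheme = DEFAULT_SCHEME.subset([f for f in DEFAULT_SCHEME.factors if f in header])
    for f in scheme.factors:
        if f not in header:
            raise CohortFormatError(f"missing required column {f!r}")
    for col in (TIME_COL, EVENT_COL):
        if col not in header:
            raise CohortFormatError(f"missing required column {col!r}")

    n = len(raw)
    out = pd.DataFrame(index=pd.RangeIndex(n))
    if ID_COL in header:
        out[ID_COL] = [_normalize_cell(v) for v in raw[ID_COL]]
    else:
        out[ID_COL] = [str(i + 1) for i in range(n)]

    for f in scheme.factors:
        allowed = set(scheme.levels[f])
        vals = [_normalize_cell(v) for v in raw[f]]
        for i, v in enumerate(vals):
            if v != UNKNOWN and v not in allowed:
                raise RowParseError(
                    f"invalid level {v!r} for factor {f!r} in row {i + 1}", row=i + 1
                )
        out[f] = vals

    times = np.full(n, np.nan)
    for i, v in enumerate(_normalize_cell(x) for x in raw[TIME_COL]):
        if v == UNKNOWN:
            continue
        try:
            t = float(v)
        except ValueError:
            raise RowParseError(
                f"cannot parse {TIME_COL}={v!r} in row {i + 1}", row=i + 1
            ) from None
        if t < 0:
            raise RowParseError(f"negative {TIME_COL} in row {i + 1}", row=i + 1)
        times[i] = t
    out[TIME_COL] = times

    events = np.full(n, np.nan)
    for i, v in enumerate(_normalize_cell(x) for x in raw[EVENT_COL]):
        if v == UNKNOWN:
            continue
        try:
            e = float(v)
        except ValueError:
            raise RowParseError(
                f"cannot parse {EVENT_COL}={v!r} in row {i + 1}", row=i + 1
            ) from None
        if e not in (0.0, 1.0):
            raise RowParseError(f"{EVENT_COL} must be 0 or 1 in row {i + 1}", row=i + 1)
        events[i] = e
    out[EVENT_COL] = events

    if YEAR_COL in header:
        years = np.full(n, np.nan)
        for i, v in enumerate(_normalize_cell(x) for x in raw[YEAR_COL]):
            if v == UNKNOWN:
                continue
            try:
                years[i] = int(float(v))
            except ValueError:
                raise RowParseError(
                    f"cannot parse {YEAR_COL}={v!r} in row {i + 1}", row=i + 1
                ) from None
        out[YEAR_COL] = years

    return out


#: First-failing-reason precedence for the exclusion report.
EXCLUSION_REASONS = ("unknown_time", "unknown_event", "unknown_factor")


def filter_records(
    records: pd.DataFrame, factors: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep records with known time, event and requested factor levels.

    Multi-reason records are counted once, under the first failing reason in
    the fixed order time -> event -> factor.  Conservation holds on every
    input: ``len(kept) + sum(report.values()) == len(records)``.
    """
    if not list(factors):
        raise ValueError("at least one factor is required")
    missing = [f for f in factors if f not in records.columns]
    if missing:
        raise CohortFormatError(f"missing required column {missing[0]!r}")

    time_bad = records[TIME_COL].isna().to_numpy()
    event_bad = records[EVENT_COL].isna().to_numpy()
    factor_bad = np.zeros(len(records), dtype=bool)
    for f in factors:
        factor_bad |= (records[f] == UNKNOWN).to_numpy()

    reason = np.where(
        time_bad, 0, np.where(event_bad, 1, np.where(factor_bad, 2, -1))
    )
    report = {name: int((reason == i).sum()) for i, name in enumerate(EXCLUSION_REASONS)}
    kept = records.loc[reason == -1].copy()
    kept[EVENT_COL] = kept[EVENT_COL].astype(int)
    logger.info("exclusion report: %s", json.dumps(report))
    return kept, report


def build_combinations(
    records: pd.DataFrame,
    factors: Sequence[str],
    min_combo_size: int = 25,
    scheme: FactorScheme = DEFAULT_SCHEME,
) -> CombinationSet:
    """Aggregate filtered records into combinations of at least ``min_combo_size``.

    Patients in sub-threshold combinations are excluded and counted in
    ``dropped_patients``.  Cohorts are ordered by level rank in scheme factor
    order (lexicographic by label for the default coding), which fixes all
    downstream tie-breaking.
    """
    if min_combo_size < 1:
        raise ValueError("min_combo_size must be positive")
    ordered_factors = tuple(f for f in scheme.factors if f in set(factors))
    if len(ordered_factors) != len(set(factors)):
        unknown = sorted(set(factors) - set(scheme.factors))
        raise ValueError(f"factors not in scheme: {unknown}")

    groups: dict[tuple[str, ...], np.ndarray] = {}
    if len(records):
        grouped = records.groupby(list(ordered_factors), sort=False)
        for key, sub in grouped:
            key = key if isinstance(key, tuple) else (key,)
            groups[tuple(key)] = sub.index.to_numpy()

    def rank_key(key: tuple[str, ...]) -> tuple[int, ...]:
        return tuple(scheme.level_rank(f, lv) for f, lv in zip(ordered_factors, key))

    cohorts: list[CombinationCohort] = []
    dropped = 0
    for key in sorted(groups, key=rank_key):
        idx = groups[key]
        if len(idx) < min_combo_size:
            dropped += len(idx)
            continue
        levels = tuple(zip(ordered_factors, key))
        combo = Combination(levels=levels, label="".join(key))
        cohorts.append(
            CombinationCohort(
                combination=combo,
                times=records.loc[idx, TIME_COL].to_numpy(dtype=float),
                events=records.loc[idx, EVENT_COL].to_numpy(dtype=int),
            )
        )
    if not cohorts:
        raise ValueError(
            f"no combination reaches min_combo_size={min_combo_size}; "
            "try a smaller min_combo_size"
        )
    if dropped:
        logger.info("dropped %d patients in sub-threshold combinations", dropped)
    return CombinationSet(tuple(cohorts), ordered_factors, dropped_patients=dropped)


def split_by_year(
    records: pd.DataFrame,
    train_years: Iterable[int],
    validation_years: Iterable[int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into train/validation by diagnosis year.

    Records outside both year sets (or with unknown year) are dropped with a
    logged count.
    """
    train_set, val_set = set(train_years), set(validation_years)
    if train_set & val_set:
        raise ValueError(f"overlapping year sets: {sorted(train_set & val_set)}")
    if YEAR_COL not in records.columns:
        raise CohortFormatError(f"missing required column {YEAR_COL!r}")
    years = records[YEAR_COL]
    in_train = years.isin(train_set).to_numpy()
    in_val = years.isin(val_set).to_numpy()
    n_dropped = int((~in_train & ~in_val).sum())
    if n_dropped:
        logger.info("dropped %d records outside both year sets", n_dropped)
    return records.loc[in_train].copy(), records.loc[in_val].copy()
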
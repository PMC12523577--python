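"""End-to-end prognostic system: fitting, assignment, evaluation, (de)serialization.

:class:`EACCD` is a scikit-learn-style estimator.  ``fit`` runs the whole
pipeline — exclusion filtering, combination building, initial Gehan
dissimilarities, the PAM ensemble, minimax-linkage clustering, the
C-index-vs-groups curve and knee selection, the final cut and survival
ordering — and stores everything needed to stage new patients and audit the
fit.  ``predict`` maps factor-level tuples to group indices (1 = best
survival); combinations unseen in training are strictly unassigned (-1).

The five- and seven-variable systems are the same code path parameterized
only by the factor list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import survival_stats as ss
from .cohort import (
    DEFAULT_SCHEME,
    EVENT_COL,
    TIME_COL,
    UNKNOWN,
    FactorScheme,
    build_combinations,
    filter_records,
)
from .eaccd_core import (
    CIndexCurve,
    Dendrogram,
    cindex_curve,
    cut_dendrogram,
    ensemble_dissimilarity,
    initial_dissimilarity_matrix,
    knee_point,
    minimax_linkage,
    order_groups,
)

__all__ = [
    "EACCD",
    "EvaluationReport",
    "adjacent_separation_table",
    "assign_group",
    "evaluate_system",
    "export_system",
    "fit_system",
    "import_system",
    "order_groups",
    "system_to_json",
]

logger = logging.getLogger("eaccd.prognostic_system")

SCHEMA_VERSION = 1

#: Marker returned by ``predict`` for combinations unseen in training.
UNASSIGNED = -1


@dataclass(frozen=True)
class EvaluationReport:
    """Held-out evaluation of a fitted system."""

    cindex: ss.CIndexResult
    group_curves: dict[int, ss.SurvivalCurve]
    adjacent_tests: tuple[dict, ...]
    unassigned_count: int
    n_assigned: int


class EACCD(BaseEstimator):
    """Ensemble clustering of factor-level combinations into prognostic groups.

    Parameters
    ----------
    factors : sequence of str, optional
        Factor columns to use; default: every scheme factor present in X.
    min_combo_size : int, default 25
        Minimum patients per combination; smaller combinations are dropped.
    n_groups : int, optional
        Fixed number of groups; default selects the knee of the C-index curve.
    g_range : (int, int), optional
        Group counts scored on the C-index curve; default (2, n combinations).
    k_range : (int, int), optional
        Ensemble partition sizes; default the full range (1, n) with uniform
        weights 1/n.
    horizon : float, default 60.0
        Months; restricted-mean-survival horizon used to order groups.
    max_swap_iters : int, default 200
        Cap on PAM SWAP iterations per k.
    scheme : FactorScheme, optional
        Factor coding; defaults to the seven-variable prostate scheme.
    random_state : int, default 0
        Seed for the bootstrap C-index interval in evaluation.

    Attributes (after fit)
    ----------------------
    combinations_ : CombinationSet
    dissimilarity_initial_, dissimilarity_learned_ : DissimilarityMatrix
    dendrogram_ : Dendrogram
    cindex_curve_ : CIndexCurve
    n_groups_ : int
    group_map_ : dict[str, int]   combination label -> group (1 = best survival)
    group_curves_ : dict[int, SurvivalCurve]
    train_cindex_ : CIndexResult
    """

    def __init__(
        self,
        factors=None,
        min_combo_size: int = 25,
        n_groups: int | None = None,
        g_range: tuple[int, int] | None = None,
        k_range: tuple[int, int] | None = None,
        horizon: float = 60.0,
        max_swap_iters: int = 200,
        scheme: FactorScheme | None = None,
        random_state: int = 0,
    ):
        self.factors = factors
        self.min_combo_size = min_combo_size
        self.n_groups = n_groups
        self.g_range = g_range
        self.k_range = k_range
        self.horizon = horizon
        self.max_swap_iters = max_swap_iters
        self.scheme = scheme
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def _resolve(self, X: pd.DataFrame) -> tuple[FactorScheme, tuple[str, ...]]:
        scheme = self.scheme if self.scheme is not None else DEFAULT_SCHEME
        if self.factors is not None:
            factors = tuple(f for f in scheme.factors if f in set(self.factors))
            missing = set(self.factors) - set(factors)
            if missing:
                raise ValueError(f"factors not in scheme: {sorted(missing)}")
        else:
            factors = tuple(f for f in scheme.factors if f in X.columns)
        if not factors:
            raise ValueError("no usable factor columns found")
        return scheme, factors

    @staticmethod
    def _to_table(X: pd.DataFrame, y) -> pd.DataFrame:
        """Accept (table with time/event columns, y=None) or (factors, y=(time, event))."""
        df = X.copy()
        if y is not None:
            arr = np.asarray(y)
            if arr.dtype.names:  # structured, scikit-survival style
                names = {n.lower(): n for n in arr.dtype.names}
                df[TIME_COL] = np.asarray(arr[names["time"]], dtype=float)
                df[EVENT_COL] = np.asarray(arr[names["event"]], dtype=float)
            else:
                arr = np.atleast_2d(np.asarray(arr, dtype=float))
                if arr.shape[0] == 2 and arr.shape[1] == len(df):
                    arr = arr.T
                df[TIME_COL] = arr[:, 0]
                df[EVENT_COL] = arr[:, 1]
        if TIME_COL not in df.columns or EVENT_COL not in df.columns:
            raise ValueError(f"need {TIME_COL!r} and {EVENT_COL!r} columns or a y argument")
        return df

    def fit(self, X: pd.DataFrame, y=None) -> "EACCD":
        df = self._to_table(X, y)
        scheme, factors = self._resolve(df)
        kept, report = filter_records(df, factors)
        combos = build_combinations(kept, factors, self.min_combo_size, scheme)
        if combos.n < 3:
            raise ValueError(
                f"only {combos.n} combinations survive filtering; at least 3 are required"
            )

        dis0 = initial_dissimilarity_matrix(combos)
        dis = ensemble_dissimilarity(
            dis0, k_range=self.k_range, max_swap_iters=self.max_swap_iters
        )
        dendro = minimax_linkage(dis)

        g_lo, g_hi = self.g_range if self.g_range is not None else (2, combos.n)
        g_hi = min(g_hi, combos.n)
        curve = cindex_curve(dendro, combos, (g_lo, g_hi), self.horizon)
        n_groups = int(self.n_groups) if self.n_groups is not None else knee_point(curve)
        ordered = order_groups(cut_dendrogram(dendro, n_groups), combos, self.horizon)

        self.scheme_ = scheme
        self.factors_ = factors
        self.exclusion_report_ = report
        self.combinations_ = combos
        self.dissimilarity_initial_ = dis0
        self.dissimilarity_learned_ = dis
        self.dendrogram_ = dendro
        self.cindex_curve_ = curve
        self.n_groups_ = n_groups
        self.group_map_ = {c.label: int(g) for c, g in zip(combos.cohorts, ordered)}
        self._finalize_groups()
        return self

    def _finalize_groups(self) -> None:
        """Derive per-group curves and the training C-index from the group map."""
        combos = self.combinations_
        groups = np.array([self.group_map_[c.label] for c in combos.cohorts])
        sizes = [c.size for c in combos.cohorts]
        pooled = ss.pool_samples(*(c.sample() for c in combos.cohorts))
        risk = np.repeat(groups, sizes)
        self.train_cindex_ = ss.harrell_c(risk, pooled)
        self.group_curves_ = {}
        for g in sorted(set(groups)):
            gsample = ss.pool_samples(
                *(c.sample() for c, gg in zip(combos.cohorts, groups) if gg == g)
            )
            self.group_curves_[int(g)] = ss.km_curve(gsample)

    # -------------------------------------------------------------- predict

    def _check_fitted(self) -> None:
        if not hasattr(self, "group_map_"):
            raise ValueError("this EACCD instance is not fitted yet")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Group index per row (1 = best survival); UNASSIGNED (-1) if the
        combination was not seen in training.  Unknown or missing levels are
        usage errors."""
        self._check_fitted()
        missing = [f for f in self.factors_ if f not in X.columns]
        if missing:
            raise ValueError(f"missing required column {missing[0]!r}")
        out = np.empty(len(X), dtype=int)
        for pos, (_, row) in enumerate(X.iterrows()):
            out[pos] = self._assign(dict(row[list(self.factors_)]))
        return out

    def _assign(self, levels: dict[str, str]) -> int:
        for f in self.factors_:
            v = levels.get(f)
            if v is None or v == UNKNOWN:
                raise ValueError(f"level for factor {f!r} is missing or unknown")
            if v not in self.scheme_.levels[f]:
                raise ValueError(f"unknown {f} level {v!r}")
        label = self.scheme_.label(levels, self.factors_)
        return self.group_map_.get(label, UNASSIGNED)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Harrell's C of the predicted group index on assigned patients."""
        df = self._to_table(X, y)
        groups = self.predict(df)
        mask = groups != UNASSIGNED
        sample = ss.SurvivalSample(
            df[TIME_COL].to_numpy(dtype=float)[mask],
            df[EVENT_COL].to_numpy(dtype=float)[mask].astype(int),
        )
        return ss.harrell_c(groups[mask], sample).c


# ----------------------------------------------------------------- wrappers


def fit_system(records: pd.DataFrame, factors=None, **params) -> EACCD:
    """Fit an :class:`EACCD` system on a patient table (thin wrapper)."""
    return EACCD(factors=factors, **params).fit(records)


def assign_group(system: EACCD, levels: dict[str, str]) -> int:
    """Group index for one patient's factor levels; UNASSIGNED if unseen."""
    system._check_fitted()
    return system._assign(levels)


def evaluate_system(
    system: EACCD,
    validation: pd.DataFrame,
    bootstrap: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
) -> EvaluationReport:
    """Stage a held-out patient table and measure the system on it.

    Assigns every patient by exact combination lookup; patients that cannot
    be assigned (unknown values or unseen combinations) are excluded and
    counted.  Reports Harrell's C with a percentile-bootstrap CI
    (``bootstrap`` = 0 skips the interval), per-group Kaplan–Meier curves,
    and log-rank tests with O/E hazard ratios for every adjacent group pair.
    """
    system._check_fitted()
    if len(validation) == 0:
        raise ValueError("validation table is empty")
    kept, _ = filter_records(validation, system.factors_)
    groups = (
        system.predict(kept) if len(kept) else np.array([], dtype=int)
    )
    mask = groups != UNASSIGNED
    n_assigned = int(mask.sum())
    unassigned = len(validation) - n_assigned
    if n_assigned == 0:
        raise ValueError("no validation patient could be assigned to a group")
    if unassigned:
        logger.info("evaluation: %d of %d patients unassigned", unassigned, len(validation))

    groups = groups[mask]
    sample = ss.SurvivalSample(
        kept[TIME_COL].to_numpy(dtype=float)[mask],
        kept[EVENT_COL].to_numpy(dtype=int)[mask],
    )
    cindex = ss.harrell_c(groups, sample)
    if bootstrap:
        seed_ = system.random_state if seed is None else seed
        cindex = ss.with_ci(
            cindex, ss.bootstrap_ci_cindex(groups, sample, B=bootstrap, alpha=alpha, seed=seed_)
        )

    curves: dict[int, ss.SurvivalCurve] = {}
    by_group: dict[int, ss.SurvivalSample] = {}
    for g in sorted(set(groups.tolist())):
        sub = groups == g
        by_group[g] = ss.SurvivalSample(sample.times[sub], sample.events[sub])
        curves[g] = ss.km_curve(by_group[g])

    adjacent: list[dict] = []
    for g in range(1, system.n_groups_):
        lo, hi = g, g + 1
        if lo not in by_group or hi not in by_group:
            continue
        try:
            res = ss.logrank_test(by_group[hi], by_group[lo])
            adjacent.append(
                {
                    "group_low": lo,
                    "group_high": hi,
                    "p_value": res.p,
                    "oe_hazard_ratio": res.oe_hazard_ratio,
                }
            )
        except ValueError:
            adjacent.append(
                {"group_low": lo, "group_high": hi, "p_value": None, "oe_hazard_ratio": None}
            )
    return EvaluationReport(
        cindex=cindex,
        group_curves=curves,
        adjacent_tests=tuple(adjacent),
        unassigned_count=unassigned,
        n_assigned=n_assigned,
    )


def adjacent_separation_table(report: EvaluationReport, alpha: float = 0.05) -> pd.DataFrame:
    """One row per adjacent group pair: p-value, significance at ``alpha``,
    and whether the O/E hazard ratio points in the expected direction
    (higher-numbered group at higher risk)."""
    rows = []
    for t in report.adjacent_tests:
        hr = t["oe_hazard_ratio"]
        rows.append(
            {
                "group_low": t["group_low"],
                "group_high": t["group_high"],
                "p_value": t["p_value"],
                "significant": (t["p_value"] is not None) and t["p_value"] < alpha,
                "oe_hazard_ratio": hr,
                "direction_expected": hr is not None and hr > 1.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group_low",
            "group_high",
            "p_value",
            "significant",
            "oe_hazard_ratio",
            "direction_expected",
        ],
    )


# ------------------------------------------------------------ serialization


class SchemaError(ValueError):
    """A system document does not match the expected schema/version."""


def _curve_doc(curve: ss.SurvivalCurve) -> dict:
    return {
        "event_times": curve.event_times.tolist(),
        "survival": curve.survival.tolist(),
        "at_risk": curve.at_risk.tolist(),
        "n": int(curve.n),
    }


def _curve_from_doc(doc: dict) -> ss.SurvivalCurve:
    return ss.SurvivalCurve(
        np.asarray(doc["event_times"], dtype=float),
        np.asarray(doc["survival"], dtype=float),
        np.asarray(doc["at_risk"], dtype=int),
        int(doc["n"]),
    )


def export_system(system: EACCD) -> dict:
    """Lossless-for-assignment JSON document of a fitted system."""
    system._check_fitted()
    c = system.train_cindex_
    return {
        "schema_version": SCHEMA_VERSION,
        "factors": list(system.factors_),
        "scheme": {
            "factors": list(system.scheme_.factors),
            "levels": {f: list(v) for f, v in system.scheme_.levels.items()},
        },
        "params": {
            "min_combo_size": system.min_combo_size,
            "n_groups": system.n_groups,
            "g_range": list(system.g_range) if system.g_range else None,
            "k_range": list(system.k_range) if system.k_range else None,
            "horizon": system.horizon,
            "max_swap_iters": system.max_swap_iters,
            "random_state": system.random_state,
        },
        "n_groups": system.n_groups_,
        "group_map": system.group_map_,
        "dendrogram": system.dendrogram_.to_dict(),
        "cindex_curve": [[g, c_] for g, c_ in system.cindex_curve_.points],
        "train_cindex": {
            "c": c.c,
            "concordant": c.concordant,
            "discordant": c.discordant,
            "tied_risk": c.tied_risk,
            "comparable": c.comparable,
        },
        "group_curves": {str(g): _curve_doc(cv) for g, cv in system.group_curves_.items()},
        "exclusion_report": system.exclusion_report_,
    }


def system_to_json(system: EACCD) -> str:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    return json.dumps(export_system(system), sort_keys=True, separators=(",", ":"))


def import_system(doc: dict | str) -> EACCD:
    """Rebuild a fitted system from :func:`export_system` output.

    Assignment behavior and stored statistics round-trip exactly; the
    dissimilarity matrices and per-combination samples are not serialized.
    """
    if isinstance(doc, str):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"not a valid system document: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {doc.get('schema_version') if isinstance(doc, dict) else None!r}"
        )
    params = doc["params"]
    scheme = FactorScheme(
        tuple(doc["scheme"]["factors"]),
        {f: tuple(v) for f, v in doc["scheme"]["levels"].items()},
    )
    system = EACCD(
        factors=tuple(doc["factors"]),
        min_combo_size=params["min_combo_size"],
        n_groups=params["n_groups"],
        g_range=tuple(params["g_range"]) if params["g_range"] else None,
        k_range=tuple(params["k_range"]) if params["k_range"] else None,
        horizon=params["horizon"],
        max_swap_iters=params["max_swap_iters"],
        scheme=scheme,
        random_state=params["random_state"],
    )
    system.scheme_ = scheme
    system.factors_ = tuple(doc["factors"])
    system.n_groups_ = int(doc["n_groups"])
    system.group_map_ = {k: int(v) for k, v in doc["group_map"].items()}
    system.dendrogram_ = Dendrogram.from_dict(doc["dendrogram"])
    system.cindex_curve_ = CIndexCurve(tuple((int(g), float(c)) for g, c in doc["cindex_curve"]))
    tc = doc["train_cindex"]
    system.train_cindex_ = ss.CIndexResult(
        c=tc["c"],
        concordant=tc["concordant"],
        discordant=tc["discordant"],
        tied_risk=tc["tied_risk"],
        comparable=tc["comparable"],
    )
    system.group_curves_ = {int(g): _curve_from_doc(cv) for g, cv in doc["group_curves"].items()}
    system.exclusion_report_ = doc.get("exclusion_report", {})
    return system
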
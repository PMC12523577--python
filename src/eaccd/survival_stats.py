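"""Censored-data statistical primitives.

Kaplan–Meier curves (via lifelines), restricted mean survival time, the
Gehan generalized-Wilcoxon two-sample statistic and its effect size, the
two-sample log-rank test with observed/expected hazard ratios, and Harrell's
concordance index with a percentile-bootstrap confidence interval.

The Gehan effect size is the engine of the clustering pipeline: the initial
dissimilarity between two patient cohorts is r = |z| / sqrt(N), where z is
the Gehan statistic W normalized by its permutation variance and N is the
pooled sample size.  U-scores are computed by a sorted sweep in O(m log m);
an O(m^2) pair-enumeration oracle lives in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats as sps

logger = logging.getLogger("eaccd.survival_stats")


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival observations: times in months, event in {0, 1}."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if len(t) and t.min() < 0:
            raise ValueError("survival times must be nonnegative")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("events must be 0 (censored) or 1 (death)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return len(self.times)


def pool_samples(*samples: SurvivalSample) -> SurvivalSample:
    return SurvivalSample(
        np.concatenate([s.times for s in samples]),
        np.concatenate([s.events for s in samples]),
    )


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier step function: S(0) = 1, right-continuous, one step per event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.event_times, t, side="right"))
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass(frozen=True)
class TwoSampleTestResult:
    """Two-sample test summary; effect_size = |z| / sqrt(pooled n)."""

    statistic: float
    variance: float
    z: float
    p: float
    effect_size: float
    oe_hazard_ratio: float | None = None


@dataclass(frozen=True)
class CIndexResult:
    """Harrell concordance over comparable censored pairs; tied risks count 0.5."""

    c: float
    concordant: int
    discordant: int
    tied_risk: int
    comparable: int
    ci_low: float | None = None
    ci_high: float | None = None


def km_curve(sample: SurvivalSample) -> SurvivalCurve:
    """Product-limit survival estimator.

    Censoring tied with an event time leaves the risk set after the event
    (the standard convention).  With no events the curve is identically 1.
    """
    if len(sample) == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter().fit(sample.times, sample.events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    survival = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return SurvivalCurve(event_times, survival, at_risk, n=len(sample))


def rmst(curve: SurvivalCurve, horizon: float) -> float:
    """Restricted mean survival time: area under S(t) on [0, horizon], months."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    mask = curve.event_times < horizon
    knots = np.concatenate([[0.0], curve.event_times[mask], [horizon]])
    heights = np.concatenate([[1.0], curve.survival[mask]])
    return float(np.sum(np.diff(knots) * heights))


def gehan_u_scores(pooled: SurvivalSample) -> np.ndarray:
    """Gehan U-score of each observation on the pooled sample.

    U_s = #{t : s definitively outlives t} - #{t : s definitively dies
    before t}.  "s definitively outlives t" iff (time_s > time_t and t is an
    event) or (equal times, s censored, t an event).  Sums to zero by
    antisymmetry.
    """
    t, e = pooled.times, pooled.events
    m = len(t)
    if m == 0:
        raise ValueError("empty sample")
    event_times = np.sort(t[e == 1])
    censor_times = np.sort(t[e == 0])
    all_times = np.sort(t)

    ev_before = np.searchsorted(event_times, t, side="left")
    ev_at = np.searchsorted(event_times, t, side="right") - ev_before
    longer = ev_before + np.where(e == 0, ev_at, 0)

    n_after = m - np.searchsorted(all_times, t, side="right")
    cen_lo = np.searchsorted(censor_times, t, side="left")
    cen_at = np.searchsorted(censor_times, t, side="right") - cen_lo
    shorter = np.where(e == 1, n_after + cen_at, 0)
    return (longer - shorter).astype(np.int64)


def gehan_effect_size(a: SurvivalSample, b: SurvivalSample) -> TwoSampleTestResult:
    """Gehan–Wilcoxon statistic W over sample ``a`` with permutation variance.

    W = sum of a's U-scores on the pooled sample; Var = n_a n_b sum(U^2) /
    (N (N-1)); z = W / sqrt(Var); effect_size = |z| / sqrt(N).  A degenerate
    pool (Var = 0, e.g. everything censored) has effect size 0 by convention,
    so structurally identical cohorts cluster together.
    """
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must be nonempty")
    pooled = pool_samples(a, b)
    u = gehan_u_scores(pooled)
    n = na + nb
    w = float(u[:na].sum())
    var = na * nb * float((u.astype(float) ** 2).sum()) / (n * (n - 1))
    if var <= 0:
        return TwoSampleTestResult(w, 0.0, 0.0, 1.0, 0.0)
    z = w / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TwoSampleTestResult(w, var, float(z), p, float(abs(z) / np.sqrt(n)))


def _counts_at(sorted_times: np.ndarray, ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(#at risk just before ts, #exactly at ts) for each time in ts."""
    lo = np.searchsorted(sorted_times, ts, side="left")
    hi = np.searchsorted(sorted_times, ts, side="right")
    return len(sorted_times) - lo, hi - lo


def logrank_test(a: SurvivalSample, b: SurvivalSample) -> TwoSampleTestResult:
    """Two-sample log-rank test with O/E hazard-ratio direction.

    Sums observed-minus-expected events for ``a`` with the hypergeometric
    variance over distinct event times; chi-square p on 1 df.
    oe_hazard_ratio = (O_a/E_a) / (O_b/E_b) when all four terms are positive.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if a.events.sum() + b.events.sum() == 0:
        raise ValueError("log-rank test undefined: no events in the pooled sample")

    ts = np.unique(np.concatenate([a.times[a.events == 1], b.times[b.events == 1]]))
    ta_sorted = np.sort(a.times)
    tb_sorted = np.sort(b.times)
    ea_sorted = np.sort(a.times[a.events == 1])
    eb_sorted = np.sort(b.times[b.events == 1])

    n1, _ = _counts_at(ta_sorted, ts)
    n2, _ = _counts_at(tb_sorted, ts)
    _, d1 = _counts_at(ea_sorted, ts)
    _, d2 = _counts_at(eb_sorted, ts)
    nj = n1 + n2
    dj = d1 + d2

    e1 = dj * n1 / nj
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(
            nj > 1,
            dj * (n1 / nj) * (n2 / nj) * (nj - dj) / np.maximum(nj - 1, 1),
            0.0,
        )
    o_a, e_a, var = float(d1.sum()), float(e1.sum()), float(v.sum())
    o_b, e_b = float(d2.sum()), float(dj.sum() - e1.sum())

    if var > 0:
        z = (o_a - e_a) / np.sqrt(var)
        p = float(sps.chi2.sf(z * z, df=1))
    else:
        z, p = 0.0, 1.0
    hr = None
    if min(o_a, o_b, e_a, e_b) > 0:
        hr = (o_a / e_a) / (o_b / e_b)
    n = len(a) + len(b)
    return TwoSampleTestResult(
        o_a - e_a, var, float(z), p, float(abs(z) / np.sqrt(n)), oe_hazard_ratio=hr
    )


def harrell_c(risk: np.ndarray, sample: SurvivalSample) -> CIndexResult:
    """Harrell's C-index for an ordinal risk score.

    Comparable pairs (i, j): time_i < time_j with i an event, or tied times
    with i an event and j censored.  A pair is concordant when the
    earlier-event member carries strictly higher risk; tied risks count 0.5.
    """
    r = np.asarray(risk, dtype=float)
    t, e = sample.times, sample.events
    if len(r) != len(t):
        raise ValueError("risk vector and sample must have equal length")
    ei = e[:, None] == 1
    lt = t[:, None] < t[None, :]
    eq = t[:, None] == t[None, :]
    comparable = (lt & ei) | (eq & ei & (e[None, :] == 0))
    higher = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    conc = int((comparable & higher).sum())
    tied_risk = int((comparable & tied).sum())
    total = int(comparable.sum())
    disc = total - conc - tied_risk
    if total == 0:
        raise ValueError("C-index undefined: no comparable pairs")
    return CIndexResult(
        c=(conc + 0.5 * tied_risk) / total,
        concordant=conc,
        discordant=disc,
        tied_risk=tied_risk,
        comparable=total,
    )


def bootstrap_ci_cindex(
    risk: np.ndarray,
    sample: SurvivalSample,
    B: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for Harrell's C over patient resamples.

    Deterministic given ``seed``.  Replicates whose resample has no
    comparable pair are dropped with a logged count.
    """
    if B < 50:
        raise ValueError("B must be at least 50")
    r = np.asarray(risk, dtype=float)
    n = len(sample)
    rng = np.random.default_rng(seed)
    values = []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(
                harrell_c(r[idx], SurvivalSample(sample.times[idx], sample.events[idx])).c
            )
        except ValueError:
            dropped += 1
    if dropped:
        logger.info("bootstrap: dropped %d degenerate replicates", dropped)
    if not values:
        raise ValueError("all bootstrap replicates degenerate")
    low, high = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high)


def with_ci(result: CIndexResult, ci: tuple[float, float]) -> CIndexResult:
    return replace(result, ci_low=ci[0], ci_high=ci[1])
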
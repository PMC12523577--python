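"""AJCC TNM prostate-cancer staging (8th Edition / 9th Version), the baseline.

Maps coarse (G, T, N, M, P) level tuples onto the nine prognostic substages
I, IIA, IIB, IIC, IIIA, IIIB, IIIC, IVA, IVB and their four principal stages.
Coarse T levels only (T1, T2a, T2bc, T3, T4); PSA categories follow the
cohort coding P1 < 10, P2 10-<20, P3 >= 20 ng/mL.

The printed staging table leaves one cell uncovered: Grade Group 1 with
T2bc, N0, M0 and PSA < 10.  ``lenient`` mode (the default) assigns it IIA,
consistent with the official 8th-Edition rule; ``strict`` mode refuses it.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import DEFAULT_SCHEME

SUBSTAGES = ("I", "IIA", "IIB", "IIC", "IIIA", "IIIB", "IIIC", "IVA", "IVB")
PRINCIPAL_STAGES = ("I", "II", "III", "IV")


class UncoveredCellError(ValueError):
    """Strict mode hit the (G1, T2bc, N0, M0, P1) cell absent from the printed table."""


def _check_level(factor: str, value: str) -> None:
    if value not in DEFAULT_SCHEME.levels[factor]:
        raise ValueError(f"unknown {factor} level {value!r}")


def stage_of(G: str, T: str, N: str, M: str, P: str, mode: str = "lenient") -> str:
    """AJCC substage of one coarse (G, T, N, M, P) tuple; first matching rule wins."""
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    for factor, value in (("G", G), ("T", T), ("N", N), ("M", M), ("P", P)):
        _check_level(factor, value)

    if M == "M1":
        return "IVB"
    if N == "N1":
        return "IVA"
    if G == "G5":
        return "IIIC"
    if T in ("T3", "T4"):
        return "IIIB"
    if P == "P3":
        return "IIIA"
    # From here: G1-G4, T1/T2a/T2bc, N0, M0, P1/P2.
    if G in ("G3", "G4"):
        return "IIC"
    if G == "G2":
        return "IIB"
    if P == "P2":
        return "IIA"
    if T in ("T1", "T2a"):
        return "I"
    # G1, T2bc, N0, M0, P1 — not covered by the printed table.
    if mode == "lenient":
        return "IIA"
    raise UncoveredCellError(
        "(G1, T2bc, N0, M0, P1) is not covered by the printed staging table"
    )


def principal_stage_of(substage: str) -> str:
    """Roman-numeral prefix of a substage: IIA/IIB/IIC -> II, etc."""
    if substage not in SUBSTAGES:
        raise ValueError(f"unknown substage {substage!r}")
    return substage.rstrip("ABC")


def substage_rank(substage: str) -> int:
    """Ordinal severity 1 (I) .. 9 (IVB), usable as a risk score."""
    return SUBSTAGES.index(substage) + 1


def enumerate_stage_table(mode: str = "lenient") -> pd.DataFrame:
    """Stage every coarse (G, T, N, M, P) tuple — 300 rows.

    In strict mode the uncovered cell is flagged (``covered`` False,
    substage NA) instead of raising.
    """
    lv = DEFAULT_SCHEME.levels
    rows = []
    for g, t, n, m, p in product(lv["G"], lv["T"], lv["N"], lv["M"], lv["P"]):
        try:
            sub = stage_of(g, t, n, m, p, mode=mode)
            rows.append((g, t, n, m, p, sub, principal_stage_of(sub), True))
        except UncoveredCellError:
            rows.append((g, t, n, m, p, pd.NA, pd.NA, False))
    return pd.DataFrame(
        rows, columns=["G", "T", "N", "M", "P", "substage", "principal", "covered"]
    )


class AjccStager(BaseEstimator):
    """Stateless estimator applying the AJCC substage mapping to a factor table.

    ``predict`` returns substage codes; ``predict_risk`` the ordinal
    severity 1..9, suitable as the risk score in a concordance index.
    """

    def __init__(self, mode: str = "lenient"):
        self.mode = mode

    def fit(self, X=None, y=None) -> "AjccStager":
        if self.mode not in ("strict", "lenient"):
            raise ValueError("mode must be 'strict' or 'lenient'")
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in ("G", "T", "N", "M", "P") if f not in X.columns]
        if missing:
            raise ValueError(f"missing required column {missing[0]!r}")
        return np.array(
            [
                stage_of(r["G"], r["T"], r["N"], r["M"], r["P"], mode=self.mode)
                for _, r in X.iterrows()
            ],
            dtype=object,
        )

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        return np.array([substage_rank(s) for s in self.predict(X)])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return a copy of X with ``substage`` and ``principal_stage`` columns."""
        out = X.copy()
        sub = self.predict(X)
        out["substage"] = sub
        out["principal_stage"] = [principal_stage_of(s) for s in sub]
        return out
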
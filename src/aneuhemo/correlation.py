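"""Spearman correlation screening with strong-pair flagging.

The screen computes rank correlations between every radiomic-feature column
and every parameter column (grouped into morphology / WSS / vortex
categories), overall and per subgroup, and flags "strong" pairs: |rho| (or
signed rho) above a threshold together with p below alpha.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman",
    "CorrelationScreenResult",
    "correlation_screen",
    "cohort_screening_summary",
    "round_half_up",
]


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(
    x, y, exact_max_n: int = 0
) -> tuple[float, float]:
    """Spearman rho (midranks) with a two-sided p-value.

    Pairs with a missing value in either vector are dropped.  The p-value
    uses the t approximation t = rho * sqrt((n-2) / (1-rho^2)) with n-2
    degrees of freedom; |rho| = 1 gives p = 0.  If ``exact_max_n`` >= n,
    the p-value is instead the exact permutation tail probability
    P(|rho_perm| >= |rho|) over all n! rank permutations (n <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    rx = _midranks(x)
    ry = _midranks(y)
    if rx.std() == 0 or ry.std() == 0:
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))

    if 3 <= n <= exact_max_n:
        if exact_max_n > 10:
            raise ValueError("exact permutation p limited to n <= 10")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total

    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, min(1.0, p)


@dataclass
class CorrelationScreenResult:
    table: pd.DataFrame  # feature, parameter, category, subgroup, rho, p, n, strong
    rho_threshold: float
    alpha: float
    mode: str
    skipped_subgroups: list

    def strong_pairs(self) -> pd.DataFrame:
        return self.table[self.table["strong"]].reset_index(drop=True)


def correlation_screen(
    cohort: pd.DataFrame,
    features: list[str],
    categories: dict[str, list[str]],
    rho_threshold: float = 0.7,
    alpha: float = 0.05,
    subgroups: str | None = "subgroup",
    mode: str = "abs",
) -> CorrelationScreenResult:
    """All feature x parameter Spearman correlations, overall and per subgroup.

    ``mode='abs'`` flags |rho| > threshold (default, since strong negative
    correlations are reported too); ``mode='signed'`` flags rho > threshold.
    Subgroups with fewer than 3 cases are skipped and listed in the result.
    """
    if mode not in ("abs", "signed"):
        raise ValueError("mode must be 'abs' or 'signed'")
    missing = [
        c
        for c in features + [p for cols in categories.values() for p in cols]
        if c not in cohort.columns
    ]
    if missing:
        raise KeyError(f"columns not in cohort: {missing}")

    groups: list[tuple[str, pd.DataFrame]] = [("all", cohort)]
    skipped = []
    if subgroups is not None and subgroups in cohort.columns:
        for name in sorted(cohort[subgroups].dropna().unique()):
            sub = cohort[cohort[subgroups] == name]
            if len(sub) < 3:
                skipped.append(str(name))
                continue
            groups.append((str(name), sub))

    rows = []
    for category in sorted(categories):
        for feat in features:
            for param in categories[category]:
                for gname, sub in groups:
                    x = sub[feat].to_numpy(dtype=float)
                    y = sub[param].to_numpy(dtype=float)
                    n = int((np.isfinite(x) & np.isfinite(y)).sum())
                    if n < 3:
                        rho, p = math.nan, math.nan
                    else:
                        rho, p = spearman(x, y)
                    magnitude = abs(rho) if mode == "abs" else rho
                    strong = bool(
                        np.isfinite(rho)
                        and np.isfinite(p)
                        and magnitude > rho_threshold
                        and p < alpha
                    )
                    rows.append(
                        {
                            "category": category,
                            "feature": feat,
                            "parameter": param,
                            "subgroup": gname,
                            "rho": rho,
                            "p": p,
                            "n": n,
                            "strong": strong,
                        }
                    )
    table = pd.DataFrame(rows)
    return CorrelationScreenResult(
        table=table,
        rho_threshold=rho_threshold,
        alpha=alpha,
        mode=mode,
        skipped_subgroups=skipped,
    )


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (printed-table style), e.g. 9.0909 -> 9.1."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_screening_summary(log: pd.DataFrame) -> dict:
    """Counts and half-up one-decimal percentages from a screening log.

    ``log`` needs columns: case_id, included (bool), exclusion_reason
    (blank/NaN for included cases), type; optional location.  Exclusion
    percentages are relative to all identified cases; type and location
    percentages are relative to included cases.
    """
    if len(log) == 0:
        raise ValueError("empty screening log")
    required = {"case_id", "included", "exclusion_reason", "type"}
    missing = required - set(log.columns)
    if missing:
        raise KeyError(f"screening log missing columns: {sorted(missing)}")
    if log["case_id"].duplicated().any():
        raise ValueError("duplicated case ids")

    n_identified = len(log)
    included = log[log["included"].astype(bool)]
    n_included = len(included)
    if included["type"].isna().any() or (included["type"] == "").any():
        raise ValueError("included case missing type label")

    excluded = log[~log["included"].astype(bool)]
    exclusions = {}
    for reason, sub in excluded.groupby("exclusion_reason"):
        exclusions[str(reason)] = {
            "count": len(sub),
            "percent_of_identified": round_half_up(100.0 * len(sub) / n_identified),
        }
    types = {}
    for tname, sub in included.groupby("type"):
        types[str(tname)] = {
            "count": len(sub),
            "percent_of_included": round_half_up(100.0 * len(sub) / n_included),
        }
    out = {
        "n_identified": n_identified,
        "n_included": n_included,
        "n_excluded": n_identified - n_included,
        "exclusions": exclusions,
        "types": types,
    }
    if "location" in log.columns:
        locations = {}
        loc = included[included["location"].notna() & (included["location"] != "")]
        for lname, sub in loc.groupby("location"):
            locations[str(lname)] = {
                "count": len(sub),
                "percent_of_included": round_half_up(100.0 * len(sub) / n_included),
            }
        out["locations"] = locations
    return out
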
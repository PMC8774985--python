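"""Twin intraclass correlations and cohort descriptive tables.

The ICC here is the double-entry Pearson correlation: each pair contributes
both orderings (x1, x2) and (x2, x1), which makes the estimate invariant to
the arbitrary labelling of twin 1 vs twin 2.  Confidence intervals use the
Fisher z transform with the number of pairs as the effective sample size
(double entry does not double the information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import TwinDataset, DegenerateVarianceError

__all__ = ["ICCResult", "intraclass_correlation", "icc_table", "descriptive_table"]


@dataclass(frozen=True)
class ICCResult:
    zygosity: str
    estimate: float
    ci95: tuple[float, float]
    n_pairs: int


def _double_entry_pearson(x1: np.ndarray, x2: np.ndarray) -> float:
    u = np.concatenate([x1, x2])
    v = np.concatenate([x2, x1])
    su, sv = np.std(u), np.std(v)
    if su == 0 or sv == 0:
        raise DegenerateVarianceError("zero variance in a double-entry column")
    return float(np.corrcoef(u, v)[0, 1])


def intraclass_correlation(
    x1: np.ndarray, x2: np.ndarray,
    zygosity: str = "",
    level: float = 0.95,
) -> ICCResult:
    """Double-entry Pearson ICC with a Fisher-z confidence interval.

    ``x1``/``x2`` are the per-pair values of the two co-twins (any ordering).
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    n = x1.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    r = _double_entry_pearson(x1, x2)
    r = max(min(r, 1.0), -1.0)
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        zse = 1.0 / math.sqrt(n - 3)
        q = float(norm.ppf(0.5 + level / 2))
        ci = (math.tanh(z - q * zse), math.tanh(z + q * zse))
    else:
        ci = (r, r)
    return ICCResult(zygosity=zygosity, estimate=r, ci95=ci, n_pairs=n)


def icc_table(
    dataset: TwinDataset,
    variables: dict[str, str] | None = None,
    *,
    by_tertile: str | None = None,
) -> pd.DataFrame:
    """MZ/DZ ICCs per variable, optionally within moderator tertile groups.

    ``variables`` maps display labels to dataset columns; defaults to the
    standardized phenotypes and moderators if present.
    """
    if variables is None:
        variables = {lbl: col for lbl, col in (
            ("Inattention", "y_inattention"),
            ("Hyperactivity/impulsivity", "y_hyperactivity"),
            ("High-sugar food", "m_sugar"),
            ("Unhealthy dietary pattern", "m_unhealthy"),
        ) if col in dataset.df.columns}
    rows = []
    for label, col in variables.items():
        x1, x2, is_mz = dataset.pair_arrays(col)
        groups: list[tuple[str, np.ndarray]] = [("all", np.ones_like(is_mz, dtype=bool))]
        if by_tertile:
            d = dataset.df
            t1 = d[d["twin_order"] == 1].set_index("pair_id")[by_tertile]
            t2 = d[d["twin_order"] == 2].set_index("pair_id")[by_tertile]
            t2 = t2.loc[t1.index]
            concordant = (t1.to_numpy() == t2.to_numpy())
            for level in ("low", "middle", "high"):
                # pairs concordant for the tertile define the group
                groups.append((level, concordant & (t1.to_numpy() == level)))
        for gname, gmask in groups:
            for zname, zmask in (("MZ", is_mz), ("DZ", ~is_mz)):
                m = gmask & zmask
                res = intraclass_correlation(x1[m], x2[m], zname)
                rows.append({
                    "variable": label, "group": gname, "zygosity": zname,
                    "icc": res.estimate, "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1], "n_pairs": res.n_pairs,
                })
    return pd.DataFrame(rows)


def descriptive_table(
    dataset: TwinDataset,
    grouping: str = "unhealthy_tertile",
) -> pd.DataFrame:
    """Cohort description by moderator tertile: means +- SD and counts (%).

    Produces age mean+-SD, sex and zygosity counts with percentages, and raw
    symptom-score means+-SD for the total column and each tertile group.
    Empty groups are reported with n = 0 rather than raising.
    """
    d = dataset.df
    if grouping not in d.columns:
        raise KeyError(f"grouping column {grouping!r} not present; run prepare() first")
    groups = {"total": d}
    for level in ("low", "middle", "high"):
        groups[level] = d[d[grouping] == level]

    rows = []
    for name, g in groups.items():
        n = len(g)
        row: dict = {"group": name, "n": n}
        if n == 0:
            row["note"] = "empty group"
            rows.append(row)
            continue
        row["age_mean"] = float(g["age"].mean())
        row["age_sd"] = float(g["age"].std(ddof=1)) if n > 1 else float("nan")
        for sx in ("male", "female"):
            cnt = int((g["sex"] == sx).sum())
            row[f"{sx}_n"] = cnt
            row[f"{sx}_pct"] = 100.0 * cnt / n
        for zy in ("MZ", "DZ"):
            cnt = int((g["zygosity"] == zy).sum())
            row[f"{zy}_n"] = cnt
            row[f"{zy}_pct"] = 100.0 * cnt / n
        for col, lbl in (("inattention_raw", "inattention"),
                         ("hyperactivity_raw", "hyperactivity")):
            row[f"{lbl}_mean"] = float(g[col].mean())
            row[f"{lbl}_sd"] = float(g[col].std(ddof=1)) if n > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
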
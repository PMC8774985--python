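"""Twin-cohort data model, CSV ingestion, food-frequency scoring and phenotype transforms.

The analysis operates on a per-individual table (one row per twin, two rows
per pair) holding zygosity, sex, age, the two ADHD symptom-dimension scores
(inattention, hyperactivity/impulsivity) and dietary moderator scores in
servings/day.  This module turns such a table into an analysis-ready
:class:`TwinDataset`: food-frequency categories become servings/day, item
servings are summed into the high-sugar and unhealthy food scores, scores are
cut into tertiles, and symptom counts are log-transformed, standardized and
residualized on age and sex.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FFQ_CATEGORIES",
    "HIGH_SUGAR_ITEMS",
    "UNHEALTHY_ITEMS",
    "HIGH_SUGAR_CUTPOINTS",
    "UNHEALTHY_CUTPOINTS",
    "FFQMapping",
    "TwinRecord",
    "TwinPair",
    "TwinDataset",
    "LoadReport",
    "TransformMetadata",
    "SchemaError",
    "StructuralError",
    "VocabularyError",
    "CompletenessError",
    "DegenerateVarianceError",
    "default_ffq_mapping",
    "ffq_to_servings",
    "compose_food_score",
    "assign_tertile",
    "transform_phenotype",
    "load_twin_table",
]


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class StructuralError(ValueError):
    """Pair structure of the table is broken (e.g. a pair_id with >2 rows)."""


class VocabularyError(ValueError):
    """A categorical value is outside its allowed vocabulary."""


class CompletenessError(ValueError):
    """A required item or variable is absent (missing is never silently zero)."""


class DegenerateVarianceError(ValueError):
    """A variable that must vary is constant."""


# ---------------------------------------------------------------------------
# Food-frequency questionnaire scoring
# ---------------------------------------------------------------------------

#: The eight consumption-frequency response categories, in increasing order.
FFQ_CATEGORIES: tuple[str, ...] = (
    "never",
    "1-3 times/month",
    "1-2 times/week",
    "3-4 times/week",
    "5-6 times/week",
    "1 time/day",
    "2 times/day",
    "3 times/day",
)

#: Items whose summed servings/day form the high-sugar food score.
HIGH_SUGAR_ITEMS: tuple[str, ...] = (
    "cookies", "crackers", "cake", "chocolate", "candy", "ice cream",
    "jam", "berry cream", "juice", "energy drink", "honey", "ketchup",
)

#: Items whose summed servings/day form the unhealthy food score (23 items).
UNHEALTHY_ITEMS: tuple[str, ...] = (
    "pizza", "sausage", "fried potato", "french fries", "minced meat/meatball",
    "pork", "beef", "cookies", "crackers", "cake", "chocolate", "candy",
    "ice cream", "jam", "berry cream", "juice", "energy drink", "hamburgers",
    "chips", "dressing", "mayonnaise", "cream", "ketchup",
)

#: Published tertile cutpoints (servings/day) for the two food scores.
HIGH_SUGAR_CUTPOINTS: tuple[float, float] = (1.56, 2.90)
UNHEALTHY_CUTPOINTS: tuple[float, float] = (2.61, 4.00)

ITEM_SETS: dict[str, tuple[str, ...]] = {
    "high_sugar": HIGH_SUGAR_ITEMS,
    "unhealthy": UNHEALTHY_ITEMS,
}


def _canon(value: str) -> str:
    """Canonicalize a categorical token: trim, casefold, unify dashes."""
    return (
        str(value).strip().casefold()
        .replace("–", "-").replace("—", "-").replace("−", "-")
    )


@dataclass(frozen=True)
class FFQMapping:
    """Conversion from frequency categories to servings/day plus the item sets.

    The default mapping follows the midpoint convention: a category covering
    ``k1``–``k2`` times per period maps to ``(k1+k2)/2`` divided by the days
    in the period.  The mapping is configuration, not doctrine: pass your own
    ``servings`` dict to change the convention.
    """

    servings: Mapping[str, float] = field(default_factory=lambda: dict(
        zip(FFQ_CATEGORIES, (0.0, 2.0 / 30, 1.5 / 7, 3.5 / 7, 5.5 / 7, 1.0, 2.0, 3.0))
    ))
    high_sugar_items: tuple[str, ...] = HIGH_SUGAR_ITEMS
    unhealthy_items: tuple[str, ...] = UNHEALTHY_ITEMS

    def __post_init__(self) -> None:
        vals = [self.servings[c] for c in FFQ_CATEGORIES if c in self.servings]
        if len(vals) != len(FFQ_CATEGORIES):
            missing = [c for c in FFQ_CATEGORIES if c not in self.servings]
            raise VocabularyError(f"FFQ mapping missing categories: {missing}")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("FFQ mapping must be strictly increasing across categories")
        if vals[0] != 0.0:
            raise ValueError("'never' must map to 0 servings/day")

    def item_set(self, name: str) -> tuple[str, ...]:
        if name == "high_sugar":
            return self.high_sugar_items
        if name == "unhealthy":
            return self.unhealthy_items
        raise VocabularyError(f"unknown item set {name!r}; expected 'high_sugar' or 'unhealthy'")


def default_ffq_mapping() -> FFQMapping:
    return FFQMapping()


def ffq_to_servings(category: str, mapping: FFQMapping | None = None) -> float:
    """Convert one frequency-response category to servings/day.

    >>> ffq_to_servings("never")
    0.0
    >>> ffq_to_servings("3 times/day")
    3.0
    """
    mapping = mapping or default_ffq_mapping()
    key = _canon(category)
    table = {_canon(k): v for k, v in mapping.servings.items()}
    if key not in table:
        raise VocabularyError(
            f"unknown FFQ category {category!r}; expected one of {FFQ_CATEGORIES}"
        )
    return float(table[key])


def compose_food_score(
    item_servings: Mapping[str, float],
    item_set: str,
    mapping: FFQMapping | None = None,
) -> float:
    """Sum per-item servings/day over a named item list.

    Every item in the list must be present in ``item_servings``; a missing
    item raises :class:`CompletenessError` rather than counting as zero.
    """
    mapping = mapping or default_ffq_mapping()
    items = mapping.item_set(item_set)
    servings = {_canon(k): v for k, v in item_servings.items()}
    total = 0.0
    for item in items:
        key = _canon(item)
        if key not in servings:
            raise CompletenessError(f"item {item!r} missing from input for score {item_set!r}")
        v = float(servings[key])
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"servings for item {item!r} must be finite and >= 0, got {v}")
        total += v
    return total


def assign_tertile(
    servings: float,
    score: str | None = None,
    cutpoints: tuple[float, float] | None = None,
) -> str:
    """Assign a servings/day value to ``low`` / ``middle`` / ``high``.

    Pass explicit ``cutpoints`` or a ``score`` name ('high_sugar' /
    'unhealthy') to use the published cutpoints.  Boundary closure: the
    boundaries belong to the outer categories (``low`` iff servings <= lower
    cutpoint, ``high`` iff servings >= upper).
    """
    if cutpoints is None:
        defaults = {"high_sugar": HIGH_SUGAR_CUTPOINTS, "unhealthy": UNHEALTHY_CUTPOINTS}
        if score not in defaults:
            raise VocabularyError(f"score must be one of {sorted(defaults)} "
                                  f"when cutpoints are not given, got {score!r}")
        cutpoints = defaults[score]
    lower, upper = cutpoints
    if not lower < upper:
        raise ValueError(f"cutpoints must satisfy lower < upper, got {cutpoints}")
    if not math.isfinite(servings) or servings < 0:
        raise ValueError(f"servings must be finite and >= 0, got {servings}")
    if servings <= lower:
        return "low"
    if servings >= upper:
        return "high"
    return "middle"


# ---------------------------------------------------------------------------
# Phenotype transform
# ---------------------------------------------------------------------------

@dataclass
class TransformMetadata:
    """Everything needed to re-apply or audit the phenotype transform."""

    log_offset: float
    pre_mean: float
    pre_sd: float
    covariate_coefs: dict[str, float]
    post_mean: float
    post_sd: float
    method: str  # 'standardize_then_residualize' | 'residualize_then_standardize'
    ddof: int

    def to_dict(self) -> dict:
        return asdict(self)


def _zscore(x: np.ndarray, ddof: int) -> tuple[np.ndarray, float, float]:
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=ddof))
    if sd == 0.0 or not math.isfinite(sd):
        raise DegenerateVarianceError("phenotype has zero variance after transform")
    return (x - mu) / sd, mu, sd


def transform_phenotype(
    raw_scores: Sequence[float] | np.ndarray,
    age: Sequence[float] | np.ndarray | None = None,
    sex: Sequence[int] | np.ndarray | None = None,
    *,
    log_offset: float = 1.0,
    ddof: int = 1,
    method: str = "standardize_then_residualize",
) -> tuple[np.ndarray, TransformMetadata]:
    """Log-transform, standardize and residualize symptom counts.

    The pipeline is ``y = log(raw + offset)`` -> z-score (sample SD,
    ``ddof=1``) -> ordinary-least-squares residualization on age and sex ->
    re-standardization, so the returned scores have mean 0 and SD 1 and are
    empirically uncorrelated with the covariates.  ``method`` flips whether
    standardization happens before or after residualization; both end with
    mean 0 / SD 1 output.

    ``sex`` may be coded 0/1 or 1/2; only contrasts matter after centering.
    """
    x = np.asarray(raw_scores, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("raw_scores must be a 1-D array with at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("raw_scores contain non-finite values")
    if np.any(x + log_offset <= 0):
        raise ValueError("raw + log_offset must be positive for the log transform")
    if np.unique(x).size < 2:
        raise DegenerateVarianceError("raw scores are constant")

    y = np.log(x + log_offset)

    covs: list[np.ndarray] = []
    names: list[str] = []
    for nm, c in (("age", age), ("sex", sex)):
        if c is not None:
            arr = np.asarray(c, dtype=float)
            if arr.shape != x.shape:
                raise ValueError(f"covariate {nm!r} length mismatch")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"covariate {nm!r} contains non-finite values")
            covs.append(arr)
            names.append(nm)

    coefs: dict[str, float] = {}

    def _residualize(v: np.ndarray) -> np.ndarray:
        if not covs:
            return v
        X = np.column_stack([np.ones_like(v)] + covs)
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        for nm, b in zip(names, beta[1:]):
            coefs[nm] = float(b)
        return v - X @ beta

    if method == "standardize_then_residualize":
        z, mu, sd = _zscore(y, ddof)
        r = _residualize(z)
    elif method == "residualize_then_standardize":
        r = _residualize(y)
        mu, sd = float(np.mean(y)), float(np.std(y, ddof=ddof))
    else:
        raise ValueError(f"unknown method {method!r}")

    out, post_mu_shift, post_sd = _zscore(r, ddof)
    meta = TransformMetadata(
        log_offset=log_offset, pre_mean=mu, pre_sd=sd, covariate_coefs=coefs,
        post_mean=post_mu_shift, post_sd=post_sd, method=method, ddof=ddof,
    )
    return out, meta


# ---------------------------------------------------------------------------
# Records, pairs, dataset
# ---------------------------------------------------------------------------

ZYGOSITY_VOCAB = {"mz": "MZ", "dz": "DZ"}
SEX_VOCAB = {"male": "male", "female": "female", "1": "male", "2": "female",
             "m": "male", "f": "female"}

#: Canonical column names of the per-individual table.
CANONICAL_COLUMNS = (
    "pair_id", "twin_order", "zygosity", "sex", "age",
    "inattention_raw", "hyperactivity_raw",
    "sugar_servings", "unhealthy_servings",
)


@dataclass(frozen=True)
class TwinRecord:
    """One twin individual with phenotypes, moderators and covariates."""

    pair_id: str
    twin_order: int
    zygosity: str
    sex: str
    age: float
    inattention_raw: float
    hyperactivity_raw: float
    sugar_servings: float
    unhealthy_servings: float
    ses: str | None = None

    def __post_init__(self) -> None:
        if self.twin_order not in (1, 2):
            raise StructuralError(f"twin_order must be 1 or 2, got {self.twin_order}")
        if self.zygosity not in ("MZ", "DZ"):
            raise VocabularyError(f"zygosity must be MZ or DZ, got {self.zygosity!r}")
        if self.sex not in ("male", "female"):
            raise VocabularyError(f"sex must be male or female, got {self.sex!r}")
        for nm in ("age", "inattention_raw", "hyperactivity_raw",
                   "sugar_servings", "unhealthy_servings"):
            v = getattr(self, nm)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{nm} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class TwinPair:
    """A complete twin pair; member1/member2 follow twin_order."""

    zygosity: str
    member1: TwinRecord
    member2: TwinRecord

    def __post_init__(self) -> None:
        if self.member1.pair_id != self.member2.pair_id:
            raise StructuralError("pair members must share pair_id")
        if self.member1.zygosity != self.member2.zygosity:
            raise StructuralError(
                f"pair {self.member1.pair_id}: zygosity differs between members")
        if {self.member1.twin_order, self.member2.twin_order} != {1, 2}:
            raise StructuralError(
                f"pair {self.member1.pair_id}: twin_order must be {{1,2}}")


@dataclass
class LoadReport:
    rows_read: int = 0
    pairs_formed: int = 0
    singletons_dropped: list[str] = field(default_factory=list)
    incomplete_dropped: list[str] = field(default_factory=list)

    @property
    def pairs_dropped(self) -> int:
        return len(self.singletons_dropped) + len(self.incomplete_dropped)


class TwinDataset:
    """A cohort of complete twin pairs backed by a per-individual DataFrame.

    The frame has two rows per pair (``twin_order`` 1 and 2) and the
    canonical columns plus any derived analysis columns (standardized
    phenotypes ``y_inattention`` / ``y_hyperactivity``, standardized
    moderators ``m_sugar`` / ``m_unhealthy``, tertile labels).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        *,
        transform_metadata: dict | None = None,
        tertile_cutpoints: dict[str, tuple[float, float]] | None = None,
        load_report: LoadReport | None = None,
    ) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        counts = df["pair_id"].value_counts()
        bad = counts[counts != 2]
        if len(bad):
            raise StructuralError(f"pair_ids without exactly 2 rows: {list(bad.index)[:10]}")
        zy_n = df.groupby("pair_id")["zygosity"].nunique()
        if (zy_n > 1).any():
            raise StructuralError(
                f"zygosity differs within pairs: {list(zy_n[zy_n > 1].index)[:10]}")
        order_ok = df.groupby("pair_id")["twin_order"].agg(
            lambda s: sorted(s.tolist()) == [1, 2])
        if not order_ok.all():
            raise StructuralError(
                f"twin_order not {{1,2}} in pairs: {list(order_ok[~order_ok].index)[:10]}")
        self.df = df.sort_values(["pair_id", "twin_order"], kind="stable").reset_index(drop=True)
        self.transform_metadata = transform_metadata or {}
        self.tertile_cutpoints = tertile_cutpoints or {}
        self.load_report = load_report

    # -- structure -----------------------------------------------------------

    @property
    def n_pairs(self) -> int:
        return len(self.df) // 2

    @property
    def n_individuals(self) -> int:
        return len(self.df)

    def zygosity_counts(self) -> dict[str, int]:
        per_pair = self.df.loc[self.df["twin_order"] == 1, "zygosity"]
        out = per_pair.value_counts().to_dict()
        return {"MZ": int(out.get("MZ", 0)), "DZ": int(out.get("DZ", 0))}

    def pairs(self) -> Iterator[TwinPair]:
        rec_cols = [c for c in CANONICAL_COLUMNS] + (
            ["ses"] if "ses" in self.df.columns else [])
        for _, grp in self.df.groupby("pair_id", sort=False):
            rows = grp.sort_values("twin_order")
            members = [
                TwinRecord(**{
                    k: (int(r[k]) if k == "twin_order" else r[k]) for k in rec_cols
                })
                for _, r in rows.iterrows()
            ]
            yield TwinPair(zygosity=members[0].zygosity,
                           member1=members[0], member2=members[1])

    def pair_arrays(self, column: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (value_twin1, value_twin2, is_mz) arrays, one entry per pair."""
        if column not in self.df.columns:
            raise SchemaError(f"column {column!r} not present (is the dataset prepared?)")
        d = self.df
        t1 = d[d["twin_order"] == 1].set_index("pair_id")
        t2 = d[d["twin_order"] == 2].set_index("pair_id")
        idx = t1.index
        x1 = t1[column].to_numpy(dtype=float)
        x2 = t2.loc[idx, column].to_numpy(dtype=float)
        is_mz = (t1["zygosity"] == "MZ").to_numpy()
        return x1, x2, is_mz

    # -- derived analysis columns -------------------------------------------

    def prepare(
        self,
        *,
        log_offset: float = 1.0,
        method: str = "standardize_then_residualize",
        cutpoints: dict[str, tuple[float, float]] | None = None,
        overwrite: bool = False,
    ) -> "TwinDataset":
        """Attach standardized phenotypes, moderators and tertiles in place.

        Phenotypes are transformed with :func:`transform_phenotype` using age
        and sex as covariates; moderators are z-scored servings/day; tertiles
        use the published cutpoints unless overridden.
        """
        d = self.df
        if "y_inattention" in d.columns and not overwrite:
            return self
        sex01 = (d["sex"] == "male").astype(float).to_numpy()
        meta: dict[str, dict] = dict(self.transform_metadata)
        for raw, out in (("inattention_raw", "y_inattention"),
                         ("hyperactivity_raw", "y_hyperactivity")):
            y, m = transform_phenotype(
                d[raw].to_numpy(dtype=float), age=d["age"].to_numpy(dtype=float),
                sex=sex01, log_offset=log_offset, method=method)
            d[out] = y
            meta[out] = m.to_dict()
        for raw, out in (("sugar_servings", "m_sugar"),
                         ("unhealthy_servings", "m_unhealthy")):
            v = d[raw].to_numpy(dtype=float)
            sd = float(np.std(v, ddof=1))
            if sd == 0:
                raise DegenerateVarianceError(f"{raw} has zero variance")
            d[out] = (v - float(np.mean(v))) / sd
            meta[out] = {"mean": float(np.mean(v)), "sd": sd}
        cps = {"high_sugar": HIGH_SUGAR_CUTPOINTS, "unhealthy": UNHEALTHY_CUTPOINTS}
        if cutpoints:
            cps.update(cutpoints)
        d["sugar_tertile"] = [assign_tertile(v, cutpoints=cps["high_sugar"])
                              for v in d["sugar_servings"]]
        d["unhealthy_tertile"] = [assign_tertile(v, cutpoints=cps["unhealthy"])
                                  for v in d["unhealthy_servings"]]
        self.transform_metadata = meta
        self.tertile_cutpoints = {k: tuple(v) for k, v in cps.items()}
        return self

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path: str | Path, *, metadata_sidecar: bool = True) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        if metadata_sidecar and (self.transform_metadata or self.tertile_cutpoints):
            side = path.with_suffix(path.suffix + ".meta.json")
            side.write_text(json.dumps({
                "transform_metadata": self.transform_metadata,
                "tertile_cutpoints": {k: list(v) for k, v in self.tertile_cutpoints.items()},
            }, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "TwinDataset":
        return load_twin_table(path, **kwargs)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {c: c for c in CANONICAL_COLUMNS}

_NUMERIC_COLS = ("age", "inattention_raw", "hyperactivity_raw",
                 "sugar_servings", "unhealthy_servings")


def load_twin_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    require: Sequence[str] = _NUMERIC_COLS,
) -> TwinDataset:
    """Read a per-individual CSV into a :class:`TwinDataset`.

    ``schema`` maps canonical column names to the file's column names.
    Only pairs with both members present and complete on ``require`` are
    retained; singletons and incomplete pairs are dropped and listed in the
    attached :class:`LoadReport`.  A ``pair_id`` with more than two rows is a
    :class:`StructuralError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = raw.rename(columns={v: k for k, v in colmap.items()})
    if "ses" in raw.columns and "ses" not in df.columns:
        df["ses"] = raw["ses"]

    report = LoadReport(rows_read=len(df))

    # vocabulary canonicalization
    zy = df["zygosity"].map(lambda s: ZYGOSITY_VOCAB.get(_canon(s)))
    if zy.isna().any():
        bad = sorted(df.loc[zy.isna(), "zygosity"].unique())
        raise StructuralError(f"unrecognized zygosity values: {bad}")
    df["zygosity"] = zy
    sx = df["sex"].map(lambda s: SEX_VOCAB.get(_canon(s)))
    if sx.isna().any():
        bad = sorted(df.loc[sx.isna(), "sex"].unique())
        raise VocabularyError(f"unrecognized sex values: {bad}")
    df["sex"] = sx

    for col in _NUMERIC_COLS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[parsed.isna() & df[col].notna()]
        if len(bad_rows):
            # +2: header line and 1-based file rows
            raise ValueError(
                f"non-numeric value in column {col!r} at file row(s) "
                f"{[int(i) + 2 for i in bad_rows[:10]]}")
        # python float() is correctly-rounded, so decimal text round-trips
        df[col] = np.array([float(v) if isinstance(v, str) else np.nan
                            for v in df[col]])
    df["twin_order"] = pd.to_numeric(df["twin_order"], errors="raise").astype(int)

    counts = df["pair_id"].value_counts()
    over = counts[counts > 2]
    if len(over):
        raise StructuralError(f"pair_ids with more than 2 rows: {list(over.index)[:10]}")
    singles = counts[counts == 1]
    if len(singles):
        report.singletons_dropped = sorted(singles.index.tolist())
        df = df[~df["pair_id"].isin(singles.index)]

    complete = df.groupby("pair_id")[list(require)].transform(
        lambda s: s.notna()).all(axis=1)
    pair_complete = complete.groupby(df["pair_id"]).transform("all")
    dropped = sorted(df.loc[~pair_complete, "pair_id"].unique().tolist())
    if dropped:
        report.incomplete_dropped = dropped
        df = df[pair_complete]

    report.pairs_formed = len(df) // 2
    return TwinDataset(df.reset_index(drop=True), load_report=report)
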
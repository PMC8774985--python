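"""Publication-style rendering of fit and comparison tables."""

from __future__ import annotations

import math

import pandas as pd

from .ace import FitResult, standardize
from .moderation import ModelComparison

__all__ = ["format_p", "comparison_frame", "render_comparison_tsv",
           "render_univariate_tsv"]


def format_p(p: float | None) -> str:
    """Journal-style p formatting: 2 decimals above 0.01, 3 decimals down to
    0.001, '<0.001' below."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return f"{p:.3f}"
    return f"{p:.2f}"


def comparison_frame(comparison: ModelComparison) -> pd.DataFrame:
    """Comparison table as a DataFrame in the published column order."""
    rows = []
    for r in comparison.rows:
        rows.append({
            "Model": r.model,
            "EP": r.ep,
            "-2lnL": round(r.neg2lnL, 2) if math.isfinite(r.neg2lnL) else "",
            "df": r.df,
            "chi2": "" if r.chi2 is None else round(r.chi2, 2),
            "ddf": "" if r.delta_df is None else r.delta_df,
            "p-Value": format_p(r.p_value),
            "AIC": round(r.aic, 2) if math.isfinite(r.aic) else "",
            "note": r.note,
        })
    return pd.DataFrame(rows)


def render_comparison_tsv(comparison: ModelComparison, path) -> None:
    comparison_frame(comparison).to_csv(path, sep="\t", index=False)


def render_univariate_tsv(fits: dict[str, FitResult], path) -> None:
    """Univariate model summary (per-spec variance shares, deviance, AIC)."""
    rows = []
    for spec, fit in fits.items():
        dec = standardize(fit)
        rows.append({
            "Model": spec,
            "EP": fit.ep,
            "-2lnL": round(fit.neg2lnL, 2),
            "df": fit.df,
            "A": round(dec.A, 2),
            "C": round(dec.C, 2),
            "E": round(dec.E, 2),
            "AIC(df)": round(fit.neg2lnL - 2 * fit.df, 2),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
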
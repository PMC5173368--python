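"""Indicator-based conservation relevance ranking of caves.

Each cave receives one point per biodiversity indicator present: species
richness above the upper quartile across all analyzed caves, presence of
troglobites, presence of rare troglobites, and presence of a resident bat
population. The integer score (0-4 with default unit weights) maps to a
proposed relevance category — 3-4 maximal, 2 high, 1 mid, 0 low — and is
compared against the reported (legislation-based) relevance labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_COLUMNS",
    "DEFAULT_WEIGHTS",
    "CATEGORY_OF_SCORE",
    "CATEGORY_ORDER",
    "richness_cutoff",
    "score_caves",
    "rank_caves",
    "compare_to_reported",
    "RelevanceRanking",
    "ReportedComparison",
]

INDICATOR_COLUMNS = ("high_richness", "troglobites", "rare_troglobites", "bat_population")
DEFAULT_WEIGHTS: dict[str, float] = {c: 1.0 for c in INDICATOR_COLUMNS}
#: Proposed category per default-weight score.
CATEGORY_OF_SCORE = {0: "low", 1: "mid", 2: "high", 3: "maximal", 4: "maximal"}
CATEGORY_ORDER = ("low", "mid", "high", "maximal")


def richness_cutoff(richness) -> float:
    """Upper quartile of species richness (linear interpolation between
    order statistics). A cave counts as high-richness iff its richness
    STRICTLY exceeds this threshold."""
    vals = pd.Series(richness).dropna().astype(float).to_numpy()
    if vals.size < 4:
        raise ValueError("need at least 4 non-missing richness values")
    return float(np.percentile(vals, 75))


def score_caves(table: pd.DataFrame,
                weights: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Per-cave weighted indicator scores.

    Returns a frame with the four 0/1 indicators and the weighted ``score``.
    Missing indicator values propagate to a missing score (reported, never
    imputed as absence).
    """
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    unknown = set(weights) - set(INDICATOR_COLUMNS)
    if unknown:
        raise ValueError(f"unknown indicator weights: {sorted(unknown)}")
    if any(w < 0 for w in weights.values()):
        raise ValueError("indicator weights must be non-negative")
    for col in ("richness", "troglobites", "rare_troglobites", "bat_population"):
        if col not in table.columns:
            raise KeyError(f"column {col!r} missing from cave table")

    threshold = richness_cutoff(table["richness"])
    rich = pd.to_numeric(table["richness"], errors="coerce")
    out = pd.DataFrame(index=table.index)
    if "cave_id" in table.columns:
        out["cave_id"] = table["cave_id"]
    out["high_richness"] = (rich > threshold).astype(float).where(rich.notna())
    for col in ("troglobites", "rare_troglobites", "bat_population"):
        vals = pd.to_numeric(table[col], errors="coerce")
        out[col] = vals.astype(float).where(vals.notna())
    score = np.zeros(len(out))
    for col in INDICATOR_COLUMNS:
        score = score + weights.get(col, 0.0) * out[col].to_numpy(dtype=float)
    out["score"] = score
    out.attrs["richness_threshold"] = threshold
    out.attrs["weights"] = weights
    return out


@dataclass
class RelevanceRanking:
    """Proposed relevance categories with summary shares.

    ``offset_share`` is the fraction of scored caves proposed as ``high``,
    i.e. the caves whose impact would require compensation offsets under
    the proposed scheme.
    """

    table: pd.DataFrame
    richness_threshold: float
    category_shares: dict[str, float]
    offset_share: float
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    n_scored: int = 0
    n_missing: int = 0


def rank_caves(scores: pd.DataFrame,
               category_of_score: Mapping[float, str] | None = None) -> RelevanceRanking:
    """Map indicator scores to proposed relevance categories.

    With default unit weights the mapping is 3-4 → maximal, 2 → high,
    1 → mid, 0 → low. Non-default weights produce non-integer scores, for
    which an explicit ``category_of_score`` mapping must be supplied.
    """
    weights = scores.attrs.get("weights", dict(DEFAULT_WEIGHTS))
    default_weights = all(np.isclose(weights.get(c, 1.0), 1.0) for c in INDICATOR_COLUMNS)
    if category_of_score is None:
        if not default_weights:
            raise ValueError(
                "non-default weights require an explicit score→category mapping")
        category_of_score = CATEGORY_OF_SCORE

    valid = scores["score"].notna()
    if valid.sum() == 0:
        raise ValueError("no cave has a complete indicator score")
    table = scores.copy()

    def to_cat(s):
        if pd.isna(s):
            return pd.NA
        key = int(s) if float(s).is_integer() else float(s)
        if key not in category_of_score:
            raise ValueError(f"score {s} has no category mapping")
        return category_of_score[key]

    table["proposed_relevance"] = table["score"].map(to_cat)
    scored = table.loc[valid, "proposed_relevance"]
    shares = {cat: float((scored == cat).mean()) for cat in CATEGORY_ORDER}
    return RelevanceRanking(
        table=table,
        richness_threshold=float(scores.attrs.get("richness_threshold", np.nan)),
        category_shares=shares,
        offset_share=shares["high"],
        weights=dict(weights),
        n_scored=int(valid.sum()),
        n_missing=int((~valid).sum()),
    )


@dataclass
class ReportedComparison:
    """Contingency of proposed vs reported relevance plus headline summaries."""

    crosstab: pd.DataFrame
    reported_high_or_above_share: float
    reported_share_by_score: pd.DataFrame
    median_area_score3plus: float
    chi2: float
    chi2_df: int
    chi2_p: float
    n: int


def compare_to_reported(ranking: RelevanceRanking,
                        table: pd.DataFrame) -> ReportedComparison:
    """Cross-tabulate the proposed ranking against reported relevance labels.

    Also reports the share of caves the current scheme places at maximal or
    high relevance (the offset burden of the status quo), the distribution
    of reported categories at each indicator count, and the median area of
    caves with three or more indicators.
    """
    if "reported_relevance" not in table.columns:
        raise KeyError("table has no reported_relevance column")
    merged = ranking.table.join(table[["reported_relevance"]], how="left",
                                rsuffix="_t")
    merged["reported_relevance"] = merged["reported_relevance"].where(
        merged["reported_relevance"].isin(CATEGORY_ORDER))
    ok = merged["proposed_relevance"].notna() & merged["reported_relevance"].notna()
    if ok.sum() == 0:
        raise ValueError("no overlap between scored and labeled caves")
    sub = merged.loc[ok]
    crosstab = pd.crosstab(sub["proposed_relevance"], sub["reported_relevance"])
    crosstab = crosstab.reindex(index=list(CATEGORY_ORDER),
                                columns=list(CATEGORY_ORDER), fill_value=0)
    reported_high = float(sub["reported_relevance"].isin(["maximal", "high"]).mean())

    by_score = (
        sub.assign(score_int=sub["score"].astype(int))
        .groupby("score_int")["reported_relevance"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(CATEGORY_ORDER), fill_value=0.0)
    )

    if "area_m2" in table.columns:
        areas = pd.to_numeric(
            table.loc[ranking.table.index, "area_m2"], errors="coerce")
        sel = ranking.table["score"] >= 3
        median_area = float(areas[sel].median()) if sel.any() else float("nan")
    else:
        median_area = float("nan")

    from scipy.stats import chi2_contingency

    nonzero = crosstab.loc[crosstab.sum(axis=1) > 0, crosstab.sum(axis=0) > 0]
    if nonzero.shape[0] > 1 and nonzero.shape[1] > 1:
        chi2, p, dof, _ = chi2_contingency(nonzero.to_numpy())
    else:
        chi2, p, dof = np.nan, np.nan, 0
    return ReportedComparison(
        crosstab=crosstab,
        reported_high_or_above_share=reported_high,
        reported_share_by_score=by_score,
        median_area_score3plus=median_area,
        chi2=float(chi2),
        chi2_df=int(dof),
        chi2_p=float(p),
        n=int(ok.sum()),
    )
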
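"""Model specifications and design-matrix construction.

Terms are column names, optionally wrapped in ``log(...)`` for a natural-log
transform (the idiom for cave area), and interactions are pairs of such
terms rendered as ``"a:b"``. The design always carries an intercept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = ["ModelSpec", "build_design", "complete_cases", "term_source_columns"]

_LOG_RE = re.compile(r"^log\((?P<col>[^()]+)\)$")


def _split_interaction(term: str) -> tuple[str, ...]:
    # split on ':' outside parentheses
    parts, depth, cur = [], 0, []
    for ch in term:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == ":" and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return tuple(p.strip() for p in parts)


def normalize_interaction(pair) -> str:
    if isinstance(pair, str):
        parts = _split_interaction(pair)
    else:
        parts = tuple(pair)
    if len(parts) != 2:
        raise ValueError(f"interaction must pair exactly two terms: {pair!r}")
    return ":".join(sorted(parts))


def term_source_columns(term: str) -> list[str]:
    """Raw data columns a (possibly transformed / interaction) term reads."""
    cols = []
    for part in _split_interaction(term):
        m = _LOG_RE.match(part)
        cols.append(m.group("col").strip() if m else part)
    return cols


def _eval_base_term(term: str, data: pd.DataFrame) -> np.ndarray:
    m = _LOG_RE.match(term)
    if m:
        col = m.group("col").strip()
        vals = np.asarray(data[col], dtype=float)
        if np.any(vals <= 0):
            bad = data.index[vals <= 0][:5].tolist()
            raise ValueError(
                f"log({col}) requires strictly positive values; offending rows: {bad}")
        return np.log(vals)
    return np.asarray(data[term], dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """A mixed model with one random intercept.

    ``fixed_terms`` are main effects; ``interactions`` pairwise products of
    main-effect terms. ``variance_strata`` names a column defining residual
    variance groups for the heteroscedastic (varIdent-style) Gaussian model.
    """

    response: str
    family: Literal["gaussian", "bernoulli"]
    fixed_terms: tuple[str, ...] = ()
    interactions: tuple[str, ...] = ()
    group: str = "report_id"
    variance_strata: str | None = None
    estimation: Literal["ML", "REML"] = "ML"

    def __init__(self, response, family, fixed_terms=(), interactions=(),
                 group="report_id", variance_strata=None, estimation="ML"):
        if family not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown family {family!r}")
        if estimation not in ("ML", "REML"):
            raise ValueError(f"unknown estimation {estimation!r}")
        inter = tuple(normalize_interaction(p) for p in interactions)
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "fixed_terms", tuple(fixed_terms))
        object.__setattr__(self, "interactions", inter)
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "variance_strata", variance_strata)
        object.__setattr__(self, "estimation", estimation)

    @property
    def all_terms(self) -> tuple[str, ...]:
        return self.fixed_terms + self.interactions

    def source_columns(self) -> list[str]:
        cols: list[str] = [self.response, self.group]
        for t in self.all_terms:
            cols.extend(term_source_columns(t))
        if self.variance_strata:
            cols.append(self.variance_strata)
        seen, out = set(), []
        for c in cols:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def drop(self, term: str) -> "ModelSpec":
        if term in self.fixed_terms:
            return replace(self, fixed_terms=tuple(t for t in self.fixed_terms if t != term))
        if term in self.interactions:
            return replace(self, interactions=tuple(t for t in self.interactions if t != term))
        raise ValueError(f"term {term!r} not in spec")

    def add_interaction(self, pair) -> "ModelSpec":
        name = normalize_interaction(pair)
        if name in self.interactions:
            raise ValueError(f"interaction {name!r} already present")
        return replace(self, interactions=self.interactions + (name,))

    def add_term(self, term: str) -> "ModelSpec":
        if term in self.fixed_terms:
            raise ValueError(f"term {term!r} already present")
        return replace(self, fixed_terms=self.fixed_terms + (term,))

    def with_estimation(self, estimation: str) -> "ModelSpec":
        return replace(self, estimation=estimation)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (self.response == other.response
                and self.family == other.family
                and self.group == other.group
                and set(self.all_terms) <= set(other.all_terms))


def complete_cases(data: pd.DataFrame, spec: ModelSpec) -> pd.Index:
    """Rows with no missing value in any column the spec reads."""
    cols = spec.source_columns()
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns absent from data: {missing}")
    mask = data[cols].notna().all(axis=1)
    return data.index[mask]


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix (intercept first) and term names for spec's fixed part."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    base_cache: dict[str, np.ndarray] = {}

    def base(term: str) -> np.ndarray:
        if term not in base_cache:
            base_cache[term] = _eval_base_term(term, data)
        return base_cache[term]

    for t in spec.fixed_terms:
        cols.append(base(t))
        names.append(t)
    for t in spec.interactions:
        a, b = _split_interaction(t)
        cols.append(base(a) * base(b))
        names.append(t)
    X = np.column_stack(cols)
    return X, names


def check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise a named error when the design is column-rank deficient."""
    from scipy.linalg import qr

    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # pivoted QR puts the aliased columns last in the pivot order
        _, _, piv = qr(X, mode="economic", pivoting=True)
        aliased = [names[piv[i]] for i in range(r, len(names))]
        raise np.linalg.LinAlgError(
            f"singular design: aliased terms {sorted(aliased)}")
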
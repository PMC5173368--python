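"""LRT-based model selection protocol.

Backward elimination of main effects (drop the term with the highest
non-significant single-term LRT p-value, one per round, at α = 0.05),
followed by a search over first-degree interactions among the retained main
effects, an optional variance-function comparison under REML, and residual
spatial-autocorrelation diagnostics. Every test is recorded in a
:class:`SelectionTrace` so the elimination path is auditable.

All nested fits within a trace share one fixed complete-case row set (the
complete cases of the starting specification), so every LRT compares models
fitted to identical observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd

from .formula import ModelSpec, complete_cases, normalize_interaction
from .glmm import fit_glmm
from .lmm import fit_lmm
from .results import FittedModel, LRTResult, lrt
from .spatial import ScaleProfile, scale_profile

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "backward_eliminate",
    "interaction_search",
    "add_variance_function",
    "residual_profile",
    "augment_with_predictor",
]

Action = Literal["drop", "keep", "add_interaction", "add_variance_function"]


def _fit(spec: ModelSpec, data: pd.DataFrame, rows: pd.Index) -> FittedModel:
    if spec.family == "gaussian":
        return fit_lmm(spec, data, rows=rows)
    return fit_glmm(spec, data, rows=rows)


@dataclass
class SelectionStep:
    action: Action
    term: str
    lrt: LRTResult | None

    def to_dict(self) -> dict:
        d = {"action": self.action, "term": self.term}
        if self.lrt is not None:
            d.update(chi2=self.lrt.chi2, df=self.lrt.df, p=self.lrt.p)
        return d


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    final_spec: ModelSpec
    final_model: FittedModel
    rows: pd.Index
    alpha: float = 0.05
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "steps": [s.to_dict() for s in self.steps],
            "final_terms": list(self.final_spec.all_terms),
            "n_obs": int(self.final_model.n_obs),
            "error": self.error,
        }


def backward_eliminate(full_spec: ModelSpec, data: pd.DataFrame,
                       alpha: float = 0.05) -> SelectionTrace:
    """Sequentially drop non-significant predictors by single-term LRTs.

    Each round refits the current model with every term removed in turn;
    the term with the highest p ≥ ``alpha`` is dropped (ties broken by term
    name for determinism). Stops when every remaining term is significant,
    recording a ``keep`` step with its final LRT for each survivor.
    Fit failures abort with the partial trace attached to the raised error.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not full_spec.fixed_terms:
        raise ValueError("full_spec must contain at least one fixed term")
    spec = full_spec.with_estimation("ML")
    rows = complete_cases(data, spec)
    steps: list[SelectionStep] = []

    current = _fit(spec, data, rows)
    while True:
        droppable = [t for t in spec.fixed_terms
                     if not any(t in i.split(":") for i in spec.interactions)]
        droppable += list(spec.interactions)
        if not droppable:
            break
        tests: list[tuple[str, LRTResult]] = []
        for term in sorted(droppable):
            try:
                reduced = _fit(spec.drop(term), data, rows)
            except Exception as exc:  # propagate with partial trace
                exc.trace = SelectionTrace(steps, spec, current, rows, alpha,
                                           error=f"fit failed dropping {term!r}: {exc}")
                raise
            res = lrt(current, reduced)
            res.term = term
            tests.append((term, res))
        worst_term, worst = max(tests, key=lambda tr: (tr[1].p, tr[0]))
        if worst.p >= alpha and len(tests) > 0:
            steps.append(SelectionStep("drop", worst_term, worst))
            spec = spec.drop(worst_term)
            current = _fit(spec, data, rows)
            if not spec.all_terms:
                break
        else:
            for term, res in tests:
                steps.append(SelectionStep("keep", term, res))
            break
    return SelectionTrace(steps=steps, final_spec=spec, final_model=current,
                          rows=rows, alpha=alpha)


def interaction_search(base: SelectionTrace, data: pd.DataFrame,
                       alpha: float = 0.05,
                       exhaustive: bool = False) -> SelectionTrace:
    """Search first-degree interactions among the retained main effects.

    Greedy forward mode (default): each round adds the candidate interaction
    with the smallest LRT p < ``alpha`` against the current model, until no
    candidate improves. Exhaustive mode enumerates every interaction subset
    (allowed for ≤ 5 retained mains) and picks the best-loglik subset whose
    members are each individually significant within it.
    """
    spec = base.final_spec
    rows = base.rows
    mains = list(spec.fixed_terms)
    candidates = [normalize_interaction((a, b)) for a, b in combinations(mains, 2)]
    candidates = [c for c in candidates if c not in spec.interactions]
    steps = list(base.steps)
    current = base.final_model

    if exhaustive:
        if len(mains) > 5:
            raise ValueError("exhaustive interaction search limited to ≤ 5 mains")
        best_spec, best_model = spec, current
        for k in range(1, len(candidates) + 1):
            for subset in combinations(candidates, k):
                trial = spec
                for c in subset:
                    trial = trial.add_interaction(c)
                model = _fit(trial, data, rows)
                ok = True
                for c in subset:
                    res = lrt(model, _fit(trial.drop(c), data, rows))
                    if res.p >= alpha:
                        ok = False
                        break
                if ok and model.loglik > best_model.loglik + 1e-9:
                    best_spec, best_model = trial, model
        for c in best_spec.interactions:
            if c not in spec.interactions:
                res = lrt(best_model, _fit(best_spec.drop(c), data, rows))
                res.term = c
                steps.append(SelectionStep("add_interaction", c, res))
        return SelectionTrace(steps, best_spec, best_model, rows, alpha)

    while candidates:
        tests = []
        for cand in sorted(candidates):
            trial_spec = spec.add_interaction(cand)
            try:
                trial = _fit(trial_spec, data, rows)
            except np.linalg.LinAlgError:
                continue  # aliased interaction (e.g. binary with itself)
            res = lrt(trial, current)
            res.term = cand
            tests.append((cand, res, trial_spec, trial))
        if not tests:
            break
        cand, best, trial_spec, trial = min(tests, key=lambda t: (t[1].p, t[0]))
        if best.p < alpha:
            steps.append(SelectionStep("add_interaction", cand, best))
            spec, current = trial_spec, trial
            candidates.remove(cand)
        else:
            break
    return SelectionTrace(steps, spec, current, rows, alpha)


def add_variance_function(base: SelectionTrace, data: pd.DataFrame,
                          strata: str, alpha: float = 0.05) -> SelectionTrace:
    """Compare the final model with and without a per-stratum residual SD.

    Both fits use REML with identical fixed effects (variance parameters are
    the only difference, so the restricted likelihoods are comparable); the
    extension is kept when the LRT on the extra SDs is significant.
    """
    from dataclasses import replace as dc_replace

    spec_reml = base.final_spec.with_estimation("REML")
    homo = fit_lmm(spec_reml, data, rows=base.rows)
    hetero_spec = dc_replace(spec_reml, variance_strata=strata)
    hetero = fit_lmm(hetero_spec, data, rows=base.rows)
    res = lrt(hetero, homo)
    res.term = f"varIdent({strata})"
    steps = list(base.steps)
    steps.append(SelectionStep("add_variance_function", f"varIdent({strata})", res))
    if res.p < alpha:
        return SelectionTrace(steps, hetero_spec, hetero, base.rows, alpha)
    return SelectionTrace(steps, base.final_spec, base.final_model, base.rows, alpha)


def residual_profile(model: FittedModel, coords: np.ndarray,
                     bands=None, n_bands: int = 20,
                     style: str = "W") -> ScaleProfile:
    """Moran correlogram of model residuals across distance bands.

    Residuals are conditional on the estimated group effects:
    response-scale for the Gaussian family, Pearson for Bernoulli. ``coords``
    must align with the rows the model was fitted on.
    """
    if model.residuals is None:
        raise ValueError("model carries no residuals")
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != model.n_obs:
        raise ValueError(
            f"coords rows ({coords.shape[0]}) != model n_obs ({model.n_obs})")
    resid = np.asarray(model.residuals, dtype=float)
    if np.allclose(resid, resid[0]):
        raise ValueError("residuals are constant; Moran profile undefined")
    return scale_profile(coords, resid, stat="moran", bands=bands,
                         n_bands=n_bands, style=style)


def augment_with_predictor(final_spec: ModelSpec, extra_term: str,
                           data: pd.DataFrame) -> tuple[FittedModel, LRTResult]:
    """Refit the final model with one extra predictor and test it by LRT.

    Complete cases are recomputed for the augmented column set (the extra
    predictor may be observed on a subset of caves), and the base model is
    refitted on the same subset so the LRT is valid.
    """
    augmented_spec = final_spec.with_estimation("ML").add_term(extra_term)
    rows = complete_cases(data, augmented_spec)
    base = _fit(final_spec.with_estimation("ML"), data, rows)
    augmented = _fit(augmented_spec, data, rows)
    res = lrt(augmented, base)
    res.term = extra_term
    return augmented, res
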
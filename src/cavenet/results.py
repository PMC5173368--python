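"""Shared result containers for fitted mixed models and likelihood-ratio tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .formula import ModelSpec

__all__ = ["FittedModel", "LRTResult", "lrt"]


@dataclass
class FittedModel:
    """A fitted LMM or Bernoulli GLMM with one random intercept.

    ``coefficients`` / ``std_errors`` / ``t_or_z`` / ``p_values`` are keyed
    by term name (including ``intercept``). ``residual_sd`` is a float for
    the homoscedastic Gaussian model, a per-stratum mapping when a variance
    function is used, and ``None`` for the Bernoulli family. ``residuals``
    are conditional on the estimated group effects (response-scale for the
    Gaussian family, Pearson for Bernoulli).
    """

    spec: ModelSpec
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_or_z: dict[str, float]
    p_values: dict[str, float]
    random_sd: float
    residual_sd: float | Mapping[str, float] | None
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    estimation: str
    boundary: bool = False
    separation: bool = False
    row_index: pd.Index | None = None
    group_effects: dict = field(default_factory=dict)
    fitted: np.ndarray | None = None      # conditional fitted values
    residuals: np.ndarray | None = None

    @property
    def beta(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))

    @property
    def n_fixed(self) -> int:
        return len(self.coefficients)

    def summary_frame(self) -> pd.DataFrame:
        """Table mirroring the usual report: term, estimate, SE, t/z, p."""
        return pd.DataFrame(
            {
                "term": list(self.coefficients),
                "estimate": list(self.coefficients.values()),
                "se": [self.std_errors[t] for t in self.coefficients],
                "t_or_z": [self.t_or_z[t] for t in self.coefficients],
                "p": [self.p_values[t] for t in self.coefficients],
            }
        )


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested models: chi2, df, upper-tail p."""

    chi2: float
    df: int
    p: float
    term: str | None = None

    @classmethod
    def from_logliks(cls, ll_full: float, ll_reduced: float, df: int,
                     term: str | None = None) -> "LRTResult":
        chi2 = max(0.0, 2.0 * (ll_full - ll_reduced))
        return cls(chi2=chi2, df=df, p=float(chi2_dist.sf(chi2, df)), term=term)


def lrt(full: FittedModel, reduced: FittedModel) -> LRTResult:
    """LRT of two nested fits on identical rows, both fitted by ML.

    ``chi2 = 2 (loglik_full - loglik_reduced)`` clamped at zero; df is the
    fixed-parameter count difference (plus any extra residual-variance
    parameters for a variance-function comparison, which must be run under
    REML with identical fixed effects).
    """
    if not reduced.spec.is_nested_in(full.spec):
        raise ValueError("reduced model is not nested in the full model")
    same_var_structure = full.spec.variance_strata == reduced.spec.variance_strata
    if same_var_structure:
        if full.estimation != "ML" or reduced.estimation != "ML":
            raise ValueError("fixed-effect LRTs require ML fits")
    else:
        if set(full.spec.all_terms) != set(reduced.spec.all_terms):
            raise ValueError(
                "variance-function LRT requires identical fixed effects")
        if full.estimation != reduced.estimation:
            raise ValueError("variance-function LRT requires matching estimation")
    if full.n_obs != reduced.n_obs:
        raise ValueError(
            f"n_obs differ ({full.n_obs} vs {reduced.n_obs}): refit both models "
            "on the intersection of complete-case rows")
    if (full.row_index is not None and reduced.row_index is not None
            and not full.row_index.equals(reduced.row_index)):
        raise ValueError("models were fitted on different rows")

    df = full.n_fixed - reduced.n_fixed
    if not same_var_structure:
        df += _n_var_params(full) - _n_var_params(reduced)
    if df <= 0:
        df_eff = max(df, 1)
        if set(full.spec.all_terms) == set(reduced.spec.all_terms) and same_var_structure:
            # identical models: chi2 = 0, p = 1 by convention
            return LRTResult(chi2=0.0, df=df_eff, p=1.0)
        raise ValueError("full model has no extra parameters")
    if 2.0 * (full.loglik - reduced.loglik) < -1e-6:
        import warnings

        warnings.warn(
            f"loglik decreased when adding parameters "
            f"({full.loglik:.6f} < {reduced.loglik:.6f}); chi2 clamped at 0",
            RuntimeWarning, stacklevel=2)
    return LRTResult.from_logliks(full.loglik, reduced.loglik, df)


def _n_var_params(model: FittedModel) -> int:
    rs = model.residual_sd
    if rs is None or np.isscalar(rs):
        return 1
    return len(rs)
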
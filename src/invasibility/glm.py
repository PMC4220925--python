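"""GLM fitting, dispersion diagnostics and VIF-constrained forward selection.

Occurrence (presence/absence) responses are modelled with a binomial family
and logit link; four-class density codes are modelled as counts with a
Poisson family and log link. Overdispersion is estimated as the Pearson
chi-square over the residual degrees of freedom; when it exceeds 1 the
quasi-likelihood variants (same fit, inflated standard errors, QAIC in place
of AIC) are the appropriate reporting scale.

Model search is forward: starting from the intercept-only model, at each
step the candidate yielding the lowest AIC is added, but only candidates
whose addition keeps every variance inflation factor at or below the cap
(default 3.0) are admissible; the search stops when no admissible addition
lowers the AIC. The accepted path is recorded in a :class:`SelectionTrace`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

FAMILIES = {
    "binomial_logit": lambda: sm.families.Binomial(),
    "poisson_log": lambda: sm.families.Poisson(),
    "gaussian_identity": lambda: sm.families.Gaussian(),
    "quasibinomial_logit": lambda: sm.families.Binomial(),
    "quasipoisson_log": lambda: sm.families.Poisson(),
}

_QUASI = {"quasibinomial_logit", "quasipoisson_log"}


@dataclass(frozen=True)
class GlmSpec:
    """Family, response column and ordered predictor terms of one GLM."""

    family: str
    response: str
    terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {sorted(FAMILIES)}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("terms must be unique")


@dataclass
class GlmFit:
    """A fitted GLM: coefficients plus the deviance/AIC/dispersion summary."""

    spec: GlmSpec
    coefficients: dict[str, float]
    null_deviance: float
    residual_deviance: float
    aic: float
    dispersion: float
    converged: bool
    nobs: int
    df_resid: float
    result: object | None = None  # statsmodels handle, for diagnostics

    @property
    def explained_fraction(self) -> float:
        """Explained deviance D = 1 - residual/null."""
        if self.null_deviance <= 0:
            raise ValueError("null deviance is 0: constant response")
        return 1.0 - self.residual_deviance / self.null_deviance


def fit_glm(spec: GlmSpec, data: pd.DataFrame) -> GlmFit:
    """Fit a GLM by IRLS, with deviance, AIC and Pearson dispersion.

    The design always contains an intercept. For the quasi families the
    point estimates equal the base-family fit; the dispersion is estimated
    from the Pearson statistic and the reported AIC is the QAIC
    (-2*loglik/dispersion + 2k).
    """
    cols = [spec.response, *spec.terms]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns not in data: {missing}")
    if data[cols].isna().any().any():
        raise ValueError("missing values in model columns; drop them first")
    y = data[spec.response].to_numpy(dtype=float)
    _check_response(spec.family, y)
    X = sm.add_constant(data[list(spec.terms)].astype(float), has_constant="add")

    family = FAMILIES[spec.family]()
    model = sm.GLM(y, X, family=family)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=100, tol=1e-8)
            converged = bool(getattr(res, "converged", True))
        except PerfectSeparationError as err:
            raise RuntimeError(f"separation in binomial fit: {err}") from err

    df_resid = float(res.df_resid)
    dispersion = float(res.pearson_chi2 / df_resid) if df_resid > 0 else float("nan")
    aic = float(res.aic)
    if spec.family in _QUASI:
        k = len(res.params)
        aic = float(-2 * res.llf / dispersion + 2 * k)
    return GlmFit(
        spec=spec,
        coefficients=dict(zip(X.columns, map(float, res.params))),
        null_deviance=float(res.null_deviance),
        residual_deviance=float(res.deviance),
        aic=aic,
        dispersion=dispersion,
        converged=converged,
        nobs=int(res.nobs),
        df_resid=df_resid,
        result=res,
    )


def _check_response(family: str, y: np.ndarray) -> None:
    if family in ("binomial_logit", "quasibinomial_logit"):
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial response must be binary 0/1")
    elif family in ("poisson_log", "quasipoisson_log"):
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("Poisson response must be non-negative integers")


def check_dispersion(fit: GlmFit) -> tuple[float, bool]:
    """Pearson dispersion and whether a quasi family is called for (>1)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    if fit.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    return fit.dispersion, fit.dispersion > 1.0


def vif(design: pd.DataFrame, term: str) -> float:
    """Variance inflation factor of ``term`` against the other columns.

    1/(1-R²) from regressing the term (with intercept) on the remaining
    design columns. A single-column design has VIF 1 by convention; perfect
    collinearity yields ``inf``.
    """
    if term not in design.columns:
        raise ValueError(f"{term!r} not in design")
    others = [c for c in design.columns if c != term]
    if not others:
        return 1.0
    y = design[term].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(design)),
                         design[others].to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return float("inf")
    r2 = 1.0 - float(resid @ resid) / tss
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def max_vif(design: pd.DataFrame) -> float:
    """Largest VIF over the design's columns (1.0 for a single column)."""
    if design.shape[1] <= 1:
        return 1.0
    return max(vif(design, c) for c in design.columns)


@dataclass(frozen=True)
class SelectionStep:
    """One accepted forward-selection step."""

    term: str
    aic_before: float
    aic_after: float
    deviance_reduction: float
    max_vif: float


@dataclass
class SelectionTrace:
    """The accepted forward path: ordered steps and the final term set."""

    steps: list[SelectionStep] = field(default_factory=list)
    final_terms: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"step": i + 1, "term": s.term, "aic_before": s.aic_before,
             "aic_after": s.aic_after,
             "deviance_reduction": s.deviance_reduction,
             "max_vif": s.max_vif}
            for i, s in enumerate(self.steps)
        ])


def forward_select(
    candidates: Sequence[str],
    family: str,
    response: str,
    data: pd.DataFrame,
    vif_cap: float = 3.0,
) -> tuple[GlmFit, SelectionTrace]:
    """AIC forward selection under a VIF constraint.

    From the intercept-only model, repeatedly fit each remaining candidate
    added to the current terms, discard candidates whose addition pushes any
    VIF above ``vif_cap``, and accept the admissible candidate with the
    lowest AIC if it improves on the current AIC. AIC ties are broken by the
    larger single-step deviance reduction, then lexicographically. An empty
    candidate list returns the intercept-only fit with an empty trace.
    """
    current = fit_glm(GlmSpec(family, response, ()), data)
    trace = SelectionTrace()
    remaining = list(dict.fromkeys(candidates))
    while remaining:
        best: tuple[float, float, str, GlmFit, float] | None = None
        for cand in remaining:
            terms = (*current.spec.terms, cand)
            mv = max_vif(data[list(terms)])
            if mv > vif_cap:
                continue
            try:
                fit = fit_glm(GlmSpec(family, response, terms), data)
            except RuntimeError:
                continue  # separation: candidate not usable
            if not fit.converged:
                continue
            drop = current.residual_deviance - fit.residual_deviance
            key = (fit.aic, -drop, cand)
            if best is None or key < (best[0], best[1], best[2]):
                best = (fit.aic, -drop, cand, fit, mv)
        if best is None or best[0] >= current.aic:
            break
        aic_after, neg_drop, term, fit, mv = best
        trace.steps.append(SelectionStep(
            term=term, aic_before=current.aic, aic_after=aic_after,
            deviance_reduction=-neg_drop, max_vif=mv))
        current = fit
        remaining.remove(term)
    trace.final_terms = current.spec.terms
    return current, trace


def transform_predictors(
    data: pd.DataFrame,
    log_vars: Sequence[str] = (),
    proportion_vars: Sequence[str] = (),
) -> pd.DataFrame:
    """Apply the standard pre-modelling transforms to predictor columns.

    Linear measurements get log(x+1) (natural log); proportions get
    arcsin(sqrt(x)). Percentage columns (values above 1) are divided by 100
    before the arcsine transform. Returns a copy; untouched columns pass
    through.
    """
    out = data.copy()
    for v in log_vars:
        if (out[v] < 0).any():
            raise ValueError(f"log transform needs {v!r} >= 0")
        out[v] = np.log1p(out[v].astype(float))
    for v in proportion_vars:
        x = out[v].astype(float)
        if x.max() > 1.0:
            x = x / 100.0
        if (x < 0).any() or (x > 1).any():
            raise ValueError(f"proportion {v!r} must lie in [0, 1] after scaling")
        out[v] = np.arcsin(np.sqrt(x))
    return out
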
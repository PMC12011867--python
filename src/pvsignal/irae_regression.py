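"""Multivariable logistic model of immune-related adverse events.

Models the probability that a cohort report describes an immune-related
adverse event (irAE) as a function of age group (<65 reference vs ≥65),
weight group (<50 kg reference, 50–100, >100) and off-label use (yes as
reference, matching the published coding even though it is the unusual
direction).  Fitting is maximum likelihood via iteratively reweighted least
squares (IRLS) with step-halving; Wald intervals come from the inverse
observed information, so OR = exp(β) with CI exp(β ∓ 1.96·se).

Spontaneous-report data carry no structured irAE field; the outcome is
defined by a configurable PT list, defaulting to every PT beginning
``immune-mediated``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CaseReport
from .descriptives import normalize_age, normalize_weight

IRAE_PREFIX = "immune-mediated"

AGE_LEVELS = ("<65", ">=65")
WEIGHT_LEVELS = ("<50", "50-100", ">100")
OFFLABEL_LEVELS = ("yes", "no")


class SeparationError(RuntimeError):
    """Complete separation: a coefficient diverges, ML estimate is infinite."""


class RankDeficiencyError(ValueError):
    """Aliased (linearly dependent) design columns."""


def label_irae(report: CaseReport,
               irae_pts: Optional[Sequence[str]] = None) -> bool:
    """True when any reaction PT is in ``irae_pts``.

    With ``irae_pts=None`` the default rule applies: any PT starting with
    'immune-mediated'.  An explicitly empty list is a configuration error.
    """
    if irae_pts is None:
        return any(pt.startswith(IRAE_PREFIX) for pt in report.reactions)
    if not irae_pts:
        raise ValueError("irae_pts must be None (default rule) or non-empty")
    wanted = {pt.casefold() for pt in irae_pts}
    return any(pt in wanted for pt in report.reactions)


@dataclass
class RegressionDesign:
    """Design matrix with intercept and dummy-coded covariates.

    Rows are restricted to reports with all covariates observed (listwise
    deletion); ``n_dropped`` records how many were lost to missingness.
    """

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    n_dropped: int = 0

    @property
    def n_used(self) -> int:
        return len(self.y)


def build_design(cohort: Sequence[CaseReport],
                 irae_pts: Optional[Sequence[str]] = None) -> RegressionDesign:
    """Design for the irAE model from cohort reports.

    Covariates: age ≥65 (vs <65), weight 50–100 and >100 kg (vs <50), and
    off-label 'no' (vs 'yes'), each dummy-coded against the stated reference.
    """
    rows, outcomes = [], []
    dropped = 0
    for report in cohort:
        age = normalize_age(report.demographics.age_value,
                            report.demographics.age_unit)
        weight = normalize_weight(report.demographics.weight_value,
                                  report.demographics.weight_unit)
        if age is None or weight is None:
            dropped += 1
            continue
        rows.append([
            1.0,
            1.0 if age >= 65 else 0.0,
            1.0 if 50 <= weight <= 100 else 0.0,
            1.0 if weight > 100 else 0.0,
            0.0 if report.off_label_flag else 1.0,
        ])
        outcomes.append(1.0 if label_irae(report, irae_pts) else 0.0)
    return RegressionDesign(
        y=np.asarray(outcomes),
        X=np.asarray(rows).reshape(-1, 5),
        columns=["intercept", "age>=65", "weight50-100", "weight>100",
                 "offlabel_no"],
        n_dropped=dropped,
    )


@dataclass
class FitResult:
    columns: list[str]
    coefficients: np.ndarray
    covariance: np.ndarray
    n_used: int
    converged: bool
    iterations: int
    log_likelihood: float
    log_likelihood_path: list[float] = field(default_factory=list)

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def odds_ratios(self) -> pd.DataFrame:
        """OR = exp(β) with Wald 95% CI and two-sided p-values."""
        from scipy.stats import norm

        se = self.standard_errors
        beta = self.coefficients
        z = beta / se
        return pd.DataFrame({
            "term": self.columns,
            "coef": beta,
            "se": se,
            "or": np.exp(beta),
            "or_lo": np.exp(beta - 1.96 * se),
            "or_hi": np.exp(beta + 1.96 * se),
            "p": 2 * norm.sf(np.abs(z)),
        })


def _log_likelihood(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(design: RegressionDesign, max_iter: int = 100,
                 tol: float = 1e-8) -> FitResult:
    """Maximum-likelihood logistic fit via IRLS with step-halving.

    Converges when the largest absolute coefficient change drops below
    ``tol``.  Diverging coefficients (fitted probabilities pinned at 0/1)
    raise :class:`SeparationError` naming the worst covariate; linearly
    dependent columns raise :class:`RankDeficiencyError`.
    """
    y, X = design.y, design.X
    if len(y) == 0:
        raise ValueError("empty design")
    if not (0 < y.sum() < len(y)):
        raise ValueError("outcome needs at least one event and one non-event")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, design.columns)
        raise RankDeficiencyError(f"design is rank deficient; aliased: {aliased}")

    beta = np.zeros(X.shape[1])
    ll = _log_likelihood(y, X, beta)
    path = [ll]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w = p * (1.0 - p)
        if np.max(np.abs(beta)) > 30.0 or w.min() < 1e-12 and np.max(np.abs(beta)) > 15.0:
            worst = design.columns[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"complete or quasi-complete separation (diverging coefficient "
                f"for '{worst}')")
        XtW = X.T * w
        try:
            step = np.linalg.solve(XtW @ X, X.T @ (y - p))
        except np.linalg.LinAlgError as err:
            raise SeparationError(f"information matrix singular: {err}") from err
        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new = _log_likelihood(y, X, candidate)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta_new = beta + scale * step
        change = np.max(np.abs(beta_new - beta))
        beta, ll = beta_new, _log_likelihood(y, X, beta_new)
        path.append(ll)
        if change < tol:
            converged = True
            break
    if not converged and np.max(np.abs(beta)) > 15.0:
        worst = design.columns[int(np.argmax(np.abs(beta)))]
        raise SeparationError(
            f"no convergence in {max_iter} iterations; diverging coefficient "
            f"for '{worst}' suggests separation")
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    info = (X.T * (p * (1 - p))) @ X
    covariance = np.linalg.inv(info)
    return FitResult(
        columns=list(design.columns),
        coefficients=beta,
        covariance=covariance,
        n_used=design.n_used,
        converged=converged,
        iterations=iterations,
        log_likelihood=ll,
        log_likelihood_path=path,
    )


def _aliased_columns(X: np.ndarray, columns: Sequence[str]) -> list[str]:
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(columns[j])
    return aliased


def _format_p(p: float) -> str:
    return "<0.01" if p < 0.01 else f"{p:.2f}"


def report_table(fit: FitResult) -> pd.DataFrame:
    """Publication-shaped OR table with explicit reference rows."""
    if not fit.converged:
        raise RuntimeError("fit did not converge")
    ors = fit.odds_ratios().set_index("term")

    def row(variable: str, level: str, term: Optional[str]) -> dict[str, str]:
        if term is None:
            return {"Variable": f"  {level}",
                    "Adjusted OR (95%CI)": "1.00 (Reference)", "P": ""}
        r = ors.loc[term]
        return {
            "Variable": f"  {level}",
            "Adjusted OR (95%CI)": f"{r['or']:.2f} ({r['or_lo']:.2f}-{r['or_hi']:.2f})",
            "P": _format_p(float(r["p"])),
        }

    rows = [
        {"Variable": "Age(years)", "Adjusted OR (95%CI)": "", "P": ""},
        row("age", "<65", None),
        row("age", ">=65", "age>=65"),
        {"Variable": "Weight (kg)", "Adjusted OR (95%CI)": "", "P": ""},
        row("weight", "<50", None),
        row("weight", "50-100", "weight50-100"),
        row("weight", ">100", "weight>100"),
        {"Variable": "Off-label use", "Adjusted OR (95%CI)": "", "P": ""},
        row("offlabel", "Yes", None),
        row("offlabel", "No", "offlabel_no"),
    ]
    return pd.DataFrame(rows, columns=["Variable", "Adjusted OR (95%CI)", "P"])
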
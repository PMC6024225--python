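"""Mendelian randomization estimators for correlated instruments.

The central model is a zero-intercept generalized weighted linear regression
of the outcome associations on the exposure associations,

    beta_outcome_j = theta * beta_exposure_j + eps_j,   Var(eps) = Sigma,
    Sigma_{j1 j2} = se_outcome_{j1} * se_outcome_{j2} * rho_{j1 j2},

where rho is the signed LD correlation between variants j1 and j2.  The GLS
solution

    theta_hat = (X' Sigma^-1 X)^-1 X' Sigma^-1 Y,
    se(theta_hat) = sqrt((X' Sigma^-1 X)^-1)

generalizes the inverse-variance weighted (IVW) estimator to instruments in
linkage disequilibrium; with identity rho it reduces to the textbook IVW
formula, and with a single variant to the Wald ratio.  Standard errors
follow the fixed-denominator convention of summary-data MR: exposure-side
sampling uncertainty is ignored, which is accurate when instruments are
strongly associated with the exposure.

When the LD matrix is near-singular (dense fine-mapped regions), Sigma is
numerically unstable; :class:`PCStabilizedIVW` projects the data onto the
leading principal components of a weighted correlation matrix before
applying GLS.

Estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``); module-level functions operating on
:class:`~mrld.summary_io.HarmonizedSet` wrap them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

from .summary_io import HarmonizedSet

#: Fixed 97.5% normal quantile so printed 95% CIs round-trip bit-stably.
Z_95 = 1.959964

#: Condition numbers of Sigma beyond this trip an explicit error pointing
#: the caller at PC stabilization.
DEFAULT_COND_MAX = 1e8


class EstimationError(ValueError):
    pass


class WeakInstrumentError(EstimationError):
    pass


class ConditionNumberError(EstimationError):
    """Sigma is numerically singular; use PC-stabilized estimation."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the outcome scale per unit exposure."""

    theta: float
    se_theta: float
    pvalue: float
    n_variants: int
    method: str  # "wald" | "ivw_correlated" | "pc_ivw" | "fixed_effect_meta"
    pc_k: int | None = None
    trait_scale: str | None = None

    def __post_init__(self) -> None:
        if not (self.se_theta > 0):
            raise EstimationError("se_theta must be positive")


@dataclass(frozen=True)
class OddsRatioRecord:
    """exp-transformed estimate with a symmetric-on-log-scale CI."""

    or_point: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def _two_sided_p(theta: float, se: float) -> float:
    return float(2 * norm.sf(abs(theta / se)))


def _make_estimate(theta, se, n_variants, method, pc_k=None, trait_scale=None):
    return MREstimate(float(theta), float(se), _two_sided_p(theta, se),
                      int(n_variants), method, pc_k, trait_scale)


def _build_sigma(se: np.ndarray, rho: np.ndarray) -> np.ndarray:
    return np.outer(se, se) * rho


def _gls(X: np.ndarray, Y: np.ndarray, sigma: np.ndarray):
    """Zero-intercept GLS via symmetric factorization (no explicit inverse)."""
    try:
        c, low = linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError:
        ev = np.linalg.eigvalsh(sigma)
        if ev.min() < -1e-10 * max(abs(ev.max()), 1.0):
            raise EstimationError("outcome covariance is not positive semi-definite")
        raise ConditionNumberError(
            "outcome covariance is numerically singular; use PCStabilizedIVW"
        ) from None
    siX = linalg.cho_solve((c, low), X)
    xtsx = float(X @ siX)
    theta = float(siX @ Y) / xtsx
    se = math.sqrt(1.0 / xtsx)
    return theta, se


class _SummaryMRBase(RegressorMixin, BaseEstimator):
    """Shared fit bookkeeping for summary-data MR estimators."""

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single column of exposure betas")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape or X.ndim != 1:
            raise ValueError("X and y must be aligned 1-d vectors")
        if len(X) == 0:
            raise ValueError("empty input")
        return X, y

    def predict(self, X):
        if not hasattr(self, "theta_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted")
        X = np.asarray(X, dtype=float)
        x = X[:, 0] if X.ndim == 2 else X
        return self.theta_ * x

    def estimate_(self) -> MREstimate:
        if not hasattr(self, "theta_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted")
        return _make_estimate(self.theta_, self.se_theta_, self.n_variants_,
                              self._method_tag, getattr(self, "pc_k_", None))


class WaldRatio(_SummaryMRBase):
    """Single-variant causal estimate beta_outcome / beta_exposure.

    The standard error is se_outcome / |beta_exposure| (first order,
    exposure uncertainty ignored).
    """

    _method_tag = "wald"

    def fit(self, X, y, se_outcome=None):
        X, y = self._validate(X, y)
        if len(X) != 1:
            raise ValueError("WaldRatio takes exactly one variant")
        if se_outcome is None:
            raise ValueError("se_outcome is required")
        se_y = float(np.asarray(se_outcome).reshape(-1)[0])
        if X[0] == 0:
            raise WeakInstrumentError(
                "beta_exposure is zero: Wald ratio undefined (weak instrument)"
            )
        self.theta_ = float(y[0] / X[0])
        self.se_theta_ = se_y / abs(float(X[0]))
        self.pvalue_ = _two_sided_p(self.theta_, self.se_theta_)
        self.n_variants_ = 1
        return self


class CorrelatedIVW(_SummaryMRBase):
    """Generalized IVW: zero-intercept GLS with covariance se·rho·se.

    Parameters
    ----------
    cond_max : float
        Maximum acceptable condition number of Sigma; beyond it a
        :class:`ConditionNumberError` directs the caller to
        :class:`PCStabilizedIVW`.
    weights : {"outcome_se", "exposure_se"}
        Which standard errors build Sigma.  ``outcome_se`` is the
        established generalized-IVW weighting and the default;
        ``exposure_se`` exists for sensitivity analysis only.
    """

    _method_tag = "ivw_correlated"

    def __init__(self, cond_max: float = DEFAULT_COND_MAX,
                 weights: str = "outcome_se"):
        self.cond_max = cond_max
        self.weights = weights

    def fit(self, X, y, se_outcome=None, ld=None, se_exposure=None):
        X, y = self._validate(X, y)
        k = len(X)
        if se_outcome is None:
            raise ValueError("se_outcome is required")
        se_y = np.asarray(se_outcome, dtype=float).reshape(-1)
        if se_y.shape != X.shape or not np.all(se_y > 0):
            raise ValueError("se_outcome must be positive and aligned with X")
        rho = np.eye(k) if ld is None else np.asarray(ld, dtype=float)
        if rho.shape != (k, k):
            raise ValueError("LD matrix shape mismatch")
        if self.weights == "exposure_se":
            if se_exposure is None:
                raise ValueError("weights='exposure_se' requires se_exposure")
            se_w = np.asarray(se_exposure, dtype=float).reshape(-1)
        elif self.weights == "outcome_se":
            se_w = se_y
        else:
            raise ValueError(f"unknown weights {self.weights!r}")
        sigma = _build_sigma(se_w, rho)
        ev = np.linalg.eigvalsh(sigma)
        if ev.min() < -1e-10 * max(abs(ev.max()), 1.0):
            raise EstimationError("outcome covariance is not positive semi-definite")
        cond = np.inf if ev.min() <= 0 else float(ev.max() / ev.min())
        if cond > self.cond_max:
            raise ConditionNumberError(
                f"covariance condition number {cond:.3g} exceeds "
                f"{self.cond_max:.3g}; use PCStabilizedIVW"
            )
        self.theta_, self.se_theta_ = _gls(X, y, sigma)
        self.pvalue_ = _two_sided_p(self.theta_, self.se_theta_)
        self.n_variants_ = k
        self.condition_number_ = cond
        return self


class PCStabilizedIVW(_SummaryMRBase):
    """Generalized IVW on the leading principal components.

    The weighted matrix

        Psi_{j1 j2} = beta_x_{j1} beta_x_{j2} rho_{j1 j2}
                      / (se_y_{j1} se_y_{j2})

    is eigendecomposed; the smallest number k of leading components whose
    eigenvalue sum reaches ``variance_kept`` (default 0.99) of the total is
    retained, negative eigenvalues (noisy external LD) being clamped to zero
    first.  X, Y and Sigma are projected through the k leading eigenvectors
    and the GLS formula applied in the projected space.  With
    ``variance_kept = 1`` on full-rank input this reproduces
    :class:`CorrelatedIVW` exactly.

    ``weighted=False`` PCA-decomposes the raw correlation matrix instead.
    """

    _method_tag = "pc_ivw"

    def __init__(self, variance_kept: float = 0.99, weighted: bool = True):
        self.variance_kept = variance_kept
        self.weighted = weighted

    def fit(self, X, y, se_outcome=None, ld=None):
        if not (0 < self.variance_kept <= 1):
            raise ValueError("variance_kept must lie in (0, 1]")
        X, y = self._validate(X, y)
        k = len(X)
        if k < 2:
            raise ValueError("PC stabilization needs at least 2 variants")
        if se_outcome is None:
            raise ValueError("se_outcome is required")
        se_y = np.asarray(se_outcome, dtype=float).reshape(-1)
        if se_y.shape != X.shape or not np.all(se_y > 0):
            raise ValueError("se_outcome must be positive and aligned with X")
        rho = np.eye(k) if ld is None else np.asarray(ld, dtype=float)
        if self.weighted:
            w = X / se_y
            psi = np.outer(w, w) * rho
        else:
            psi = rho
        evals, evecs = np.linalg.eigh(psi)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evals = np.where(evals > 1e-10 * max(abs(evals[0]), 1.0), evals, 0.0)
        total = float(evals.sum())
        if total <= 0:
            raise EstimationError("weighted correlation matrix has no positive eigenvalues")
        csum = np.cumsum(evals) / total
        n_pc = int(np.searchsorted(csum, self.variance_kept - 1e-12) + 1)
        n_pc = min(n_pc, int(np.count_nonzero(evals)))
        lam = evecs[:, :n_pc]
        sigma = _build_sigma(se_y, rho)
        Xt, Yt = lam.T @ X, lam.T @ y
        sig_t = lam.T @ sigma @ lam
        self.theta_, self.se_theta_ = _gls(Xt, Yt, sig_t)
        self.pvalue_ = _two_sided_p(self.theta_, self.se_theta_)
        self.n_variants_ = k
        self.pc_k_ = n_pc
        return self


# ---------------------------------------------------------------------------
# Functional wrappers over HarmonizedSet


def wald_ratio(beta_x: float, beta_y: float, se_y: float) -> MREstimate:
    est = WaldRatio().fit([beta_x], [beta_y], se_outcome=[se_y])
    return est.estimate_()


def ivw_correlated(h: HarmonizedSet, cond_max: float = DEFAULT_COND_MAX,
                   weights: str = "outcome_se") -> MREstimate:
    """Generalized IVW over a harmonized variant set."""
    est = CorrelatedIVW(cond_max=cond_max, weights=weights).fit(
        h.beta_exposure, h.beta_outcome, se_outcome=h.se_outcome,
        ld=h.ld.r, se_exposure=h.se_exposure,
    )
    return est.estimate_()


def pc_ivw(h: HarmonizedSet, variance_kept: float = 0.99,
           weighted: bool = True) -> MREstimate:
    """PC-stabilized generalized IVW over a harmonized variant set."""
    est = PCStabilizedIVW(variance_kept=variance_kept, weighted=weighted).fit(
        h.beta_exposure, h.beta_outcome, se_outcome=h.se_outcome, ld=h.ld.r,
    )
    return est.estimate_()


def to_odds_ratio(est: MREstimate, level: float = 0.95) -> OddsRatioRecord:
    """exp-transform a log-odds-scale estimate into an OR with CI."""
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    z = Z_95 if level == 0.95 else float(norm.ppf((1 + level) / 2))
    return OddsRatioRecord(
        or_point=math.exp(est.theta),
        ci_low=math.exp(est.theta - z * est.se_theta),
        ci_high=math.exp(est.theta + z * est.se_theta),
        level=level,
    )


def meta_fixed_effect(estimates: Sequence[MREstimate]) -> MREstimate:
    """Fixed-effect inverse-variance pooling of independent estimates."""
    if not estimates:
        raise ValueError("no estimates to pool")
    scales = {e.trait_scale for e in estimates if e.trait_scale is not None}
    if len(scales) > 1:
        raise EstimationError(f"cannot pool estimates on mixed scales: {sorted(scales)}")
    if len(estimates) == 1:
        return estimates[0]
    w = np.array([0.0 if math.isinf(e.se_theta) else e.se_theta ** -2
                  for e in estimates])
    if w.sum() <= 0:
        raise EstimationError("all pooled estimates have infinite se")
    theta = float(np.sum(w * [e.theta for e in estimates]) / w.sum())
    se = float(w.sum() ** -0.5)
    return _make_estimate(theta, se, sum(e.n_variants for e in estimates),
                          "fixed_effect_meta",
                          trait_scale=next(iter(scales)) if scales else None)
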
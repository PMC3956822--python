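"""Phylogenetic generalized least squares with Pagel's λ.

The model: for a response vector y over n species related by a phylogeny
with covariance matrix C (see :mod:`phylofid.trees`),

    y = X β + ε,   ε ~ N(0, σ² V(λ)),   V(λ) = λ C + (1 − λ) diag(C),

i.e. λ multiplies the off-diagonal elements of C.  λ = 1 is pure Brownian
motion (equivalent to Felsenstein's independent contrasts), λ = 0 removes
all phylogenetic correlation (ordinary least squares when the tree is
ultrametric).  λ is estimated by maximum likelihood on [0, 1], either for a
trait alone (phylogenetic signal) or for the residual errors of a
regression, and the fitted value then defines the GLS error structure.

Estimation is full ML throughout (not REML), so log-likelihoods and AICc are
comparable across models with different fixed effects.  The profiled
log-likelihood at a given λ sets β to its GLS estimate and σ² to RSS/n:

    log L(λ) = −½ [ n log(2π σ̂²) + n + log |V(λ)| ].

All linear algebra goes through a Cholesky factor of V(λ); an explicit
inverse is never formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import PhyloCovariance

__all__ = [
    "PGLS",
    "PGLSResults",
    "LambdaEstimate",
    "SingularCovarianceError",
    "CollinearityError",
    "estimate_lambda",
    "aicc",
]

#: grid used to seed the bounded λ search (the profile can be multimodal
#: near the boundaries, so a plain local optimizer is not trusted alone)
_LAMBDA_GRID = np.linspace(0.0, 1.0, 21)
_LAMBDA_XATOL = 1e-6
_COND_LIMIT = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    """λ-transformed covariance is (numerically) singular."""


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike's information criterion with the small-sample correction.

    AICc = −2 log L + 2k + 2k(k+1)/(n − k − 1); undefined for n ≤ k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} must exceed k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class LambdaEstimate:
    """ML estimate of Pagel's λ with boundary likelihood-ratio tests.

    ``p_vs_0`` tests H0: λ=0 (no phylogenetic signal), ``p_vs_1`` tests
    H0: λ=1 (full Brownian signal), each via P(χ²₁ ≥ 2 Δ log L).  With
    ``boundary_mixture`` the 50:50 point-mass mixture appropriate for a
    boundary null halves the p-value.
    """

    lambda_hat: float
    loglik_at_hat: float
    loglik_at_0: float
    loglik_at_1: float
    p_vs_0: float
    p_vs_1: float
    grid: np.ndarray = field(default=None, repr=False)
    grid_loglik: np.ndarray = field(default=None, repr=False)

    def significant_vs_0(self, alpha: float = 0.05) -> bool:
        return self.p_vs_0 < alpha


def _diagnose_singular(C: PhyloCovariance | None, V: np.ndarray) -> str:
    msg = "lambda-transformed covariance is singular"
    n = V.shape[0]
    best, pair = np.inf, None
    for i in range(n):
        for j in range(i + 1, n):
            d = np.max(np.abs(V[i] - V[j]))
            if d < best:
                best, pair = d, (i, j)
    if pair is not None and C is not None:
        ti, tj = C.taxa[pair[0]], C.taxa[pair[1]]
        msg += (f"; most similar covariance rows belong to taxa "
                f"{ti!r} and {tj!r} (max row difference {best:.3g})")
    return msg


class PGLS:
    """Phylogenetic GLS regression model.

    Parameters
    ----------
    endog : (n,) array-like
        Response values, one per taxon, aligned with ``covariance``.
    exog : (n, p) array-like or None
        Predictor columns *without* an intercept; the model always adds one.
        ``None`` or zero columns gives the intercept-only model used for
        phylogenetic-signal estimation.
    covariance : PhyloCovariance or (n, n) ndarray
        Phylogenetic covariance in the same taxon order as ``endog``.
    exog_names : sequence of str, optional
        Predictor names for reporting (defaults ``x1..xp``).
    """

    def __init__(self, endog, exog, covariance, *, exog_names=None,
                 taxa=None):
        y = np.asarray(endog, dtype=float).ravel()
        if exog is None:
            X = np.empty((y.size, 0))
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
        if isinstance(covariance, PhyloCovariance):
            self.cov = covariance
        else:
            M = np.asarray(covariance, dtype=float)
            labels = list(taxa) if taxa is not None else [
                f"t{i}" for i in range(M.shape[0])]
            self.cov = PhyloCovariance(labels, M)
        n = y.size
        if X.shape[0] != n or self.cov.n != n:
            raise ValueError("endog, exog and covariance sizes disagree")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValueError("endog/exog contain non-finite values")
        self.endog = y
        self.exog = np.column_stack([np.ones(n), X])
        if exog_names is None:
            exog_names = [f"x{i + 1}" for i in range(X.shape[1])]
        self.exog_names = ["const"] + list(exog_names)
        self.nobs = n

    # -- constructors --------------------------------------------------

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       predictors, covariance: PhyloCovariance) -> "PGLS":
        """Build a model from a species-indexed DataFrame.

        The covariance is re-aligned to the DataFrame's index (species
        labels matched after whitespace/underscore normalization).
        """
        cov = covariance.align(list(data.index))
        predictors = list(predictors)
        exog = data[predictors].to_numpy(float) if predictors else None
        return cls(data[response].to_numpy(float), exog, cov,
                   exog_names=predictors)

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame,
                     covariance: PhyloCovariance) -> "PGLS":
        """Minimal formula interface: ``"response ~ a + b"`` (``"y ~ 1"``
        for intercept-only).  Terms are plain column names."""
        lhs, _, rhs = formula.partition("~")
        response = lhs.strip()
        terms = [t.strip() for t in rhs.split("+")]
        predictors = [t for t in terms if t not in ("", "1")]
        return cls.from_dataframe(data, response, predictors, covariance)

    # -- likelihood core -----------------------------------------------

    def _whiten(self, lam: float):
        V = self.cov.lambda_transform(lam).matrix
        try:
            L = linalg.cholesky(V, lower=True)
        except linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                _diagnose_singular(self.cov, V) + f" at lambda={lam:.6g}"
            ) from exc
        d = np.diag(L)
        if d.max() / d.min() > math.sqrt(_COND_LIMIT):
            # cheap proxy; confirm with an honest condition number
            if np.linalg.cond(V) > _COND_LIMIT:
                raise SingularCovarianceError(
                    _diagnose_singular(self.cov, V)
                    + f" (condition number > {_COND_LIMIT:.0e}) at lambda={lam:.6g}"
                )
        z = linalg.solve_triangular(L, self.endog, lower=True)
        W = linalg.solve_triangular(L, self.exog, lower=True)
        logdet = 2.0 * np.sum(np.log(d))
        return L, z, W, logdet

    def _fit_fixed(self, lam: float):
        L, z, W, logdet = self._whiten(lam)
        n, p = W.shape
        Q, R = np.linalg.qr(W)
        rdiag = np.abs(np.diag(R))
        if p and rdiag.min() <= 1e-10 * max(rdiag.max(), 1.0):
            bad = [self.exog_names[i] for i in np.where(
                rdiag <= 1e-10 * max(rdiag.max(), 1.0))[0]]
            raise CollinearityError(
                f"design matrix is rank deficient (columns {bad})")
        beta = linalg.solve_triangular(R, Q.T @ z, lower=False)
        resid_white = z - W @ beta
        rss = float(resid_white @ resid_white)
        sigma2_ml = rss / n
        if sigma2_ml <= 0:
            sigma2_ml = np.finfo(float).tiny
        llf = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + n + logdet)
        # classical GLS covariance of beta, unbiased variance estimate
        dof = max(n - p, 1)
        Rinv = linalg.solve_triangular(R, np.eye(p), lower=False)
        cov_beta = (rss / dof) * (Rinv @ Rinv.T)
        # whitened-space R^2 around the GLS intercept-only fit at this lambda
        w0 = W[:, 0]
        b0 = float(w0 @ z) / float(w0 @ w0)
        tss = float(np.sum((z - w0 * b0) ** 2))
        rsq = 1.0 - rss / tss if tss > 0 else 0.0
        return {
            "beta": beta, "cov_beta": cov_beta, "llf": llf, "rss": rss,
            "sigma2_ml": sigma2_ml, "rsquared": min(max(rsq, 0.0), 1.0),
            "logdet": logdet,
        }

    def loglike(self, lam: float) -> float:
        """Profiled GLS log-likelihood at ``lam`` (β and σ² maximized out)."""
        return self._fit_fixed(lam)["llf"]

    def _maximize_lambda(self):
        grid_ll = np.array([self.loglike(l) for l in _LAMBDA_GRID])
        if not np.all(np.isfinite(grid_ll)):
            bad = _LAMBDA_GRID[~np.isfinite(grid_ll)][0]
            raise FloatingPointError(
                f"non-finite GLS log-likelihood at lambda={bad:.3f}")
        i = int(np.argmax(grid_ll))
        lo = _LAMBDA_GRID[max(i - 1, 0)]
        hi = _LAMBDA_GRID[min(i + 1, _LAMBDA_GRID.size - 1)]
        best_lam, best_ll = _LAMBDA_GRID[i], grid_ll[i]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda l: -self.loglike(float(np.clip(l, 0.0, 1.0))),
                bounds=(lo, hi), method="bounded",
                options={"xatol": _LAMBDA_XATOL})
            lam_opt = float(np.clip(res.x, 0.0, 1.0))
            ll_opt = -res.fun
            if ll_opt > best_ll:
                best_lam, best_ll = lam_opt, ll_opt
        return best_lam, best_ll, grid_ll

    def estimate_lambda(self, boundary_mixture: bool = False) -> LambdaEstimate:
        """ML estimate of λ with likelihood-ratio tests against both
        boundaries (λ=0: no signal; λ=1: Brownian motion)."""
        lam, llhat, grid_ll = self._maximize_lambda()
        ll0 = float(grid_ll[0])
        ll1 = float(grid_ll[-1])
        if ll0 >= llhat:
            lam, llhat = 0.0, ll0
        if ll1 > llhat:
            lam, llhat = 1.0, ll1
        scale = 0.5 if boundary_mixture else 1.0
        p0 = float(stats.chi2.sf(max(2.0 * (llhat - ll0), 0.0), df=1)) * scale
        p1 = float(stats.chi2.sf(max(2.0 * (llhat - ll1), 0.0), df=1)) * scale
        return LambdaEstimate(
            lambda_hat=lam, loglik_at_hat=llhat, loglik_at_0=ll0,
            loglik_at_1=ll1, p_vs_0=min(p0, 1.0), p_vs_1=min(p1, 1.0),
            grid=_LAMBDA_GRID.copy(), grid_loglik=grid_ll)

    # -- fitting -------------------------------------------------------

    def fit(self, lambda_mode: str = "ml",
            lambda_value: float | None = None) -> "PGLSResults":
        """Fit the regression.

        ``lambda_mode``:
          * ``"ml"`` — λ estimated by maximum likelihood from the model's
            residual errors (the default analysis);
          * ``"fixed0"`` — λ=0 (ordinary least squares on an ultrametric
            tree);
          * ``"fixed1"`` — λ=1 (equivalent to independent contrasts);
          * ``"fixed_value"`` — λ supplied via ``lambda_value``.
        """
        if lambda_mode == "ml":
            lam, _, _ = self._maximize_lambda()
        elif lambda_mode == "fixed0":
            lam = 0.0
        elif lambda_mode == "fixed1":
            lam = 1.0
        elif lambda_mode == "fixed_value":
            if lambda_value is None:
                raise ValueError("lambda_value required for fixed_value mode")
            if not 0.0 <= lambda_value <= 1.0:
                raise ValueError("lambda_value must lie in [0, 1]")
            lam = float(lambda_value)
        else:
            raise ValueError(f"unknown lambda_mode {lambda_mode!r}")
        parts = self._fit_fixed(lam)
        # k for AICc: intercept + slopes + residual variance, + 1 when
        # lambda itself was estimated
        k = self.exog.shape[1] + 1 + (1 if lambda_mode == "ml" else 0)
        return PGLSResults(self, lam, lambda_mode, parts, k)


class PGLSResults:
    """Fitted PGLS regression: estimates, uncertainties, diagnostics."""

    def __init__(self, model: PGLS, lam: float, lambda_mode: str, parts, k):
        self.model = model
        self.lambda_ = lam
        self.lambda_mode = lambda_mode
        self.nobs = model.nobs
        self.k_params = k
        self.params = pd.Series(parts["beta"], index=model.exog_names)
        self.bse = pd.Series(np.sqrt(np.diag(parts["cov_beta"])),
                             index=model.exog_names)
        self.cov_params = pd.DataFrame(parts["cov_beta"],
                                       index=model.exog_names,
                                       columns=model.exog_names)
        self.llf = parts["llf"]
        self.rsquared = parts["rsquared"]
        self.sigma2_ml = parts["sigma2_ml"]
        self.fittedvalues = pd.Series(model.exog @ parts["beta"],
                                      index=model.cov.taxa)
        # residuals on the observation scale, not the whitened scale
        self.resid = pd.Series(model.endog, index=model.cov.taxa) \
            - self.fittedvalues

    @property
    def df_resid(self) -> int:
        return self.nobs - self.model.exog.shape[1]

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), df=self.df_resid),
            index=self.params.index)

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k_params, self.nobs)

    def conf_int(self, alpha: float = 0.05, use_t: bool = False) -> pd.DataFrame:
        """Wald confidence intervals (normal quantile by default; ``use_t``
        switches to Student-t with residual df)."""
        if use_t:
            q = stats.t.ppf(1.0 - alpha / 2.0, df=self.df_resid)
        else:
            q = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse,
             "upper": self.params + q * self.bse})

    def summary(self) -> str:
        lines = [
            "Phylogenetic GLS regression (Pagel's lambda)",
            "=" * 60,
            f"No. observations: {self.nobs:>6d}    lambda mode: {self.lambda_mode}",
            f"Log-likelihood:  {self.llf:>10.4f}    lambda:      {self.lambda_:.4f}",
            f"AICc:            {self.aicc:>10.4f}    R-squared:   {self.rsquared:.4f}",
            "-" * 60,
            f"{'':<16s}{'coef':>10s}{'std err':>10s}{'t':>8s}{'P>|t|':>8s}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<16s}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>8.3f}")
        lines.append("=" * 60)
        return "\n".join(lines)

    def plot_fit(self, predictor: str, ax=None):
        """Scatter of the response against one predictor with the marginal
        fitted line (all other predictors held at their means)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = self.model.exog_names
        j = names.index(predictor)
        x = self.model.exog[:, j]
        ax.scatter(x, self.model.endog, s=18, alpha=0.8)
        grid = np.linspace(x.min(), x.max(), 50)
        others = self.model.exog.mean(axis=0) @ self.params.to_numpy() \
            - x.mean() * self.params.iloc[j]
        ax.plot(grid, others + self.params.iloc[j] * grid, color="C3")
        ax.set_xlabel(predictor)
        ax.set_ylabel("response")
        ax.set_title(f"PGLS fit (lambda={self.lambda_:.2f})")
        return ax

    def to_record(self) -> dict:
        """Flat dict for TSV/JSON serialization."""
        rec = {
            "response": "y",
            "predictors": "+".join(self.model.exog_names[1:]) or "1",
            "lambda": self.lambda_, "lambda_mode": self.lambda_mode,
            "loglik": self.llf, "aicc": self.aicc, "n_obs": self.nobs,
            "k_params": self.k_params, "r_squared": self.rsquared,
        }
        for name in self.params.index:
            rec[f"coef_{name}"] = self.params[name]
            rec[f"se_{name}"] = self.bse[name]
        return rec


def estimate_lambda(y, C: PhyloCovariance, X=None,
                    boundary_mixture: bool = False) -> LambdaEstimate:
    """Phylogenetic signal of a trait (or of regression residuals).

    Intercept-only by default: the classic per-trait λ estimate.  Pass
    ``X`` (predictors, no intercept column) to profile λ for the residual
    errors of a regression instead.
    """
    return PGLS(y, X, C).estimate_lambda(boundary_mixture=boundary_mixture)
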
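"""Transformed-GLM engine for species-area curves.

The model: species richness S at sampled area A is Box-Cox transformed,
Z = psi(S; lambda), and Z is assumed to follow an exponential-family
distribution (normal, gamma or inverse Gaussian) whose mean is tied to a
linear predictor in functions of A through a link, g(mu) = x' beta.

For fixed lambda the coefficients are maximum-likelihood estimates obtained
by iteratively reweighted least squares (IRLS); the dispersion is profiled
out per family.  The transformation exponent itself is estimated by profile
likelihood: the total log-likelihood carries the Jacobian term
(lambda - 1) * sum(ln s), so values at different lambda are comparable on
the same untransformed data, and a confidence interval for lambda follows
from inverting the likelihood-ratio test against the chi-square(1) law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .data import SARDataset
from .families import Family, Link, get_family, get_link
from .terms import DesignMatrix, GSAMSpec, build_design_matrix
from .transform import TransformedResponse, boxcox

__all__ = ["GSAM", "GSAMResults", "ProfileTrace", "irls_fit", "ConvergenceError"]

DEFAULT_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.05), 10)


class ConvergenceError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# IRLS

def irls_fit(X: np.ndarray, z: np.ndarray, family: Family, link: Link,
             tol: float = 1e-10, maxiter: int = 100, max_halvings: int = 20):
    """Fit GLM coefficients by iteratively reweighted least squares.

    Weights w_i = [g'(mu_i)]**-2 / V(mu_i); working response
    y*_i = eta_i + (z_i - mu_i) g'(mu_i); update beta = (X'WX)^-1 X'W y*.
    The update is step-halved back toward the previous iterate whenever the
    fitted means leave the family support.  Convergence is declared on a
    relative deviance change below ``tol``.

    Returns ``(beta, mu, eta, weights, deviance, converged, n_iter)``.
    """
    X = np.asarray(X, float)
    z = np.asarray(z, float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than p={p} observations, got n={n}")
    if family.positive_support and not family.in_support(z):
        raise ValueError(f"{family.name} family requires a positive response; "
                         "the transformed richness is not all positive")

    mu = z.astype(float).copy()
    if family.positive_support or link.name in ("reciprocal", "inverse_squared",
                                                "log"):
        mu = np.maximum(mu, 1e-6)
    eta = link.g(mu)
    beta = None
    dev = family.deviance(z, mu)

    def wls(mu, eta):
        gprime = link.deriv(mu)
        w = 1.0 / (gprime ** 2 * family.variance(mu))
        y_work = eta + (z - mu) * gprime
        sw = np.sqrt(w)
        b, *_ = np.linalg.lstsq(X * sw[:, None], y_work * sw, rcond=None)
        return b, w

    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        beta_new, w = wls(mu, eta)
        # step-halving: retreat toward the previous beta while the candidate
        # means leave the family support (or the link's domain)
        step = 1.0
        for _ in range(max_halvings + 1):
            cand = beta_new if beta is None else beta + step * (beta_new - beta)
            eta_c = X @ cand
            with np.errstate(all="ignore"):
                mu_c = link.inverse(eta_c)
            ok = (np.all(np.isfinite(mu_c))
                  and (not family.positive_support or np.all(mu_c > 0))
                  and (link.name not in ("reciprocal", "inverse_squared")
                       or np.all(mu_c > 0)))
            if ok:
                break
            if beta is None:
                raise ConvergenceError(
                    "initial IRLS step left the family support")
            step /= 2.0
        else:
            raise ConvergenceError(
                "IRLS step-halving exhausted: fitted means leave the "
                f"{family.name} support")
        beta, eta, mu = cand, eta_c, mu_c
        dev_new = family.deviance(z, mu)
        if abs(dev_new - dev) <= tol * (abs(dev) + 1e-12):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    gprime = link.deriv(mu)
    weights = 1.0 / (gprime ** 2 * family.variance(mu))
    return beta, mu, eta, weights, dev, converged, it


# --------------------------------------------------------------------------
# Profile trace

@dataclass(frozen=True)
class ProfileTrace:
    """Profile log-likelihood of the Box-Cox exponent over a grid.

    ``ci`` is the likelihood-ratio confidence interval at ``level``:
    {lambda : 2[l_p(lambda_hat) - l_p(lambda)] <= chi2_1 quantile}.
    """

    grid: np.ndarray
    profile_loglik: np.ndarray
    lambda_hat: float
    loglik_hat: float
    ci: tuple
    level: float

    def contains(self, lam: float) -> bool:
        return self.ci[0] <= lam <= self.ci[1]


# --------------------------------------------------------------------------
# Results

class GSAMResults:
    """Fitted generalized species-area model.

    Attributes
    ----------
    params : ndarray
        Coefficient MLEs, in term order.
    bse : ndarray
        Standard errors from phi_hat * (X'WX)^-1 at convergence.
    scale : float
        Moment (Pearson-type) dispersion estimate with n - p denominator;
        used for standard errors and original-scale prediction.
    scale_mle : float
        Maximum-likelihood dispersion; enters the reported log-likelihood
        and hence AIC/BIC and the lambda profile.
    llf : float
        Jacobian-corrected log-likelihood, comparable across lambda.
    """

    def __init__(self, model: "GSAM", spec: GSAMSpec, lam: float,
                 beta, mu, eta, weights, deviance, converged, n_iter,
                 transformed: TransformedResponse,
                 profiled: bool = False, profile: ProfileTrace | None = None):
        self.model = model
        self.spec = spec
        self.lam = float(lam)
        self.params = np.asarray(beta, float)
        self.fittedvalues = np.asarray(mu, float)   # transformed scale
        self.eta = np.asarray(eta, float)
        self.weights = np.asarray(weights, float)
        self.deviance = float(deviance)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.transformed = transformed
        self.profiled = profiled
        self.profile = profile

        X = model.exog(spec)
        z = transformed.values
        self.nobs = n = X.shape[0]
        self.df_model = p = X.shape[1]
        self.df_resid = n - p
        fam = model._family_obj(spec)
        mu = self.fittedvalues
        pearson = float(np.sum((z - mu) ** 2 / fam.variance(mu)))
        self.scale = pearson / (n - p)
        self.scale_mle = fam.dispersion_mle(z, mu)
        self.llf = fam.loglik(z, mu, self.scale_mle) + transformed.log_jacobian

        XtWX = (X * self.weights[:, None]).T @ X
        self.cov_params = self.scale * np.linalg.inv(XtWX)
        self.bse = np.sqrt(np.diag(self.cov_params))

    # -- information criteria ------------------------------------------------
    @property
    def k_params(self) -> int:
        """Parameters counted by AIC/BIC: p coefficients, the dispersion,
        plus one for a profiled Box-Cox exponent."""
        return self.df_model + 1 + (1 if self.profiled else 0)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.nobs)

    # -- inference -----------------------------------------------------------
    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald intervals for the coefficients.

        For the normal family with identity link the exact finite-sample
        theory applies, so Student-t quantiles on n - p degrees of freedom
        are used; the other families rely on the asymptotic normal quantile.
        """
        if self.spec.family == "normal" and self.spec.link == "identity":
            q = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        else:
            q = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - q * self.bse,
                                self.params + q * self.bse])

    def tvalues(self):
        return self.params / self.bse

    # -- prediction ----------------------------------------------------------
    def predict(self, area=None, scale: str = "original") -> np.ndarray:
        """Expected richness at the given areas.

        ``scale="transformed"`` returns the fitted mean of the Box-Cox
        variable; ``scale="original"`` back-transforms it with the
        second-order (variance) correction for E[S].
        """
        from .selection import predict_original
        if area is None:
            mu = self.fittedvalues
        else:
            X = build_design_matrix(np.asarray(area, float), self.spec,
                                    check_rank=False).values
            mu = self.model._link_obj(self.spec).inverse(X @ self.params)
        if scale == "transformed":
            return mu
        if scale != "original":
            raise ValueError("scale must be 'original' or 'transformed'")
        fam = self.model._family_obj(self.spec)
        return predict_original(mu, self.lam, self.scale, fam,
                                shift=self.model.shift)

    # -- reporting -----------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "link": self.spec.link,
            "lambda": self.lam,
            "lambda_profiled": self.profiled,
            "terms": [t.label for t in self.spec.terms],
            "coefficients": self.params.tolist(),
            "standard_errors": self.bse.tolist(),
            "dispersion": self.scale,
            "dispersion_mle": self.scale_mle,
            "loglik": self.llf,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n": int(self.nobs),
        }

    def summary(self) -> str:
        spec = self.spec
        lam = (f"{self.lam:.4f} (profiled)" if self.profiled
               else f"{self.lam:g} (fixed)")
        lines = [
            "Generalized species-area model",
            "=" * 62,
            f"Family: {spec.family:<18} Link: {spec.link}",
            f"Box-Cox lambda: {lam:<22} N obs: {self.nobs}",
            f"Log-likelihood: {self.llf:<12.4f} AIC: {self.aic:.4f}  "
            f"BIC: {self.bic:.4f}",
            f"Dispersion: {self.scale:.6g}   Converged: {self.converged} "
            f"({self.n_iter} iter)",
            "-" * 62,
            f"{'term':<12}{'coef':>12}{'std err':>12}{'z':>9}"
            f"{'[0.025':>10}{'0.975]':>10}",
        ]
        ci = self.conf_int()
        for j, t in enumerate(spec.terms):
            lines.append(
                f"{t.label:<12}{self.params[j]:>12.4f}{self.bse[j]:>12.4f}"
                f"{self.params[j] / self.bse[j]:>9.2f}"
                f"{ci[j, 0]:>10.4f}{ci[j, 1]:>10.4f}")
        if self.profile is not None:
            lo, hi = self.profile.ci
            lines.append("-" * 62)
            lines.append(f"lambda {100 * self.profile.level:.0f}% LR interval: "
                         f"({lo:.3f}, {hi:.3f})")
        lines.append("=" * 62)
        return "\n".join(lines)

    def __repr__(self):
        return (f"<GSAMResults {self.spec.family}/{self.spec.link} "
                f"lambda={self.lam:g} llf={self.llf:.3f}>")


# --------------------------------------------------------------------------
# Model

class GSAM:
    """Generalized species-area model bound to a dataset.

    Parameters
    ----------
    data : SARDataset
        The (area, richness) observations.
    spec : GSAMSpec
        Systematic component, family, link and Box-Cox mode.
    shift : bool
        Box-Cox convention at lambda = 1: ``True`` (default) uses the genuine
        member z = s - 1, ``False`` the identity z = s.  Only the intercept
        is affected.

    Examples
    --------
    >>> from gsam import GSAM, GSAMSpec, hymenoptera
    >>> from gsam.terms import intercept, log_area_power, inverse_area_power
    >>> spec = GSAMSpec(terms=(intercept(), log_area_power(2),
    ...                        inverse_area_power(1)), lam=1.0)
    >>> res = GSAM(hymenoptera(), spec).fit()
    >>> res.params.round(4)
    array([101.9707,  20.6625, -46.1669])
    """

    def __init__(self, data: SARDataset, spec: GSAMSpec, shift: bool = True):
        if not isinstance(data, SARDataset):
            data = SARDataset(np.asarray(data)[:, 0], np.asarray(data)[:, 1])
        if len(data) <= spec.p:
            raise ValueError(f"{spec.p}-coefficient model needs at least "
                             f"{spec.p + 1} records; got {len(data)}")
        self.data = data
        self.spec = spec
        self.shift = shift
        self._X = build_design_matrix(data.area, spec)

    # cached building blocks -------------------------------------------------
    def exog(self, spec=None) -> np.ndarray:
        return self._X.values

    @property
    def design(self) -> DesignMatrix:
        return self._X

    def _family_obj(self, spec=None) -> Family:
        return get_family(self.spec.family)

    def _link_obj(self, spec=None) -> Link:
        return get_link(self.spec.link)

    # fitting ----------------------------------------------------------------
    def fit(self, lam: float | None = None, grid=None,
            level: float = 0.95) -> GSAMResults:
        """Maximum-likelihood fit.

        A numeric ``lam`` (or a numeric ``spec.lam``) fixes the Box-Cox
        exponent; otherwise it is profiled over ``grid`` and the model is
        refit at the maximizer, with the LR confidence interval attached.
        """
        if lam is None:
            lam = self.spec.lam
        if lam is not None:
            return self._fit_fixed(float(lam))
        trace = self.profile_lambda(grid=grid, level=level)
        res = self._fit_fixed(trace.lambda_hat)
        res.profiled = True
        res.profile = trace
        return res

    def _fit_fixed(self, lam: float) -> GSAMResults:
        tr = boxcox(self.data.species, lam, shift=self.shift)
        fam, link = self._family_obj(), self._link_obj()
        beta, mu, eta, w, dev, conv, it = irls_fit(
            self.exog(), tr.values, fam, link)
        if not conv:
            warnings.warn(f"IRLS did not converge in {it} iterations "
                          f"(lambda={lam:g})", RuntimeWarning, stacklevel=2)
        return GSAMResults(self, self.spec, lam, beta, mu, eta, w, dev,
                           conv, it, tr)

    def loglik_at(self, lam: float) -> float:
        """Profile log-likelihood value at a fixed Box-Cox exponent."""
        return self._fit_fixed(lam).llf

    # profile likelihood -----------------------------------------------------
    def profile_lambda(self, grid=None, level: float = 0.95,
                       refine: bool = True) -> ProfileTrace:
        """Profile the likelihood over the Box-Cox exponent.

        Fits the model at every grid value, refines the maximizer between
        its two grid neighbours by bounded scalar optimization, and inverts
        the LR test for the confidence interval.  Isolated grid failures are
        recorded as gaps; all failing is fatal.
        """
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
        vals = np.full(grid.size, np.nan)
        for i, lam in enumerate(grid):
            try:
                vals[i] = self.loglik_at(lam)
            except Exception as exc:  # noqa: BLE001 — recorded as a gap
                warnings.warn(f"profile gap at lambda={lam:g}: {exc}",
                              RuntimeWarning, stacklevel=2)
        ok = np.isfinite(vals)
        if not ok.any():
            raise ConvergenceError("no Box-Cox grid value admitted a fit")
        i_max = int(np.nanargmax(vals))
        lam_hat, ll_hat = float(grid[i_max]), float(vals[i_max])

        if refine:
            lo = grid[max(i_max - 1, 0)]
            hi = grid[min(i_max + 1, grid.size - 1)]
            if hi > lo:
                opt = optimize.minimize_scalar(
                    lambda l: -self.loglik_at(l), bounds=(lo, hi),
                    method="bounded", options={"xatol": 1e-6})
                if -opt.fun >= ll_hat:
                    lam_hat, ll_hat = float(opt.x), float(-opt.fun)

        thresh = ll_hat - 0.5 * stats.chi2.ppf(level, df=1)
        ci = self._invert_lr(grid, vals, lam_hat, thresh)
        return ProfileTrace(grid, vals, lam_hat, ll_hat, ci, level)

    def _invert_lr(self, grid, vals, lam_hat, thresh):
        def f(lam):
            return self.loglik_at(lam) - thresh

        ok = np.isfinite(vals)
        below = ok & (vals < thresh)
        # lower endpoint: last grid point below threshold left of lam_hat
        lo = grid[0]
        left = np.nonzero(below & (grid < lam_hat))[0]
        if left.size:
            a = grid[left[-1]]
            b = min(lam_hat, grid[left[-1] + 1]) if left[-1] + 1 < grid.size \
                else lam_hat
            try:
                lo = optimize.brentq(f, a, b, xtol=1e-6)
            except ValueError:
                lo = a
        right = np.nonzero(below & (grid > lam_hat))[0]
        hi = grid[-1]
        if right.size:
            b = grid[right[0]]
            a = max(lam_hat, grid[right[0] - 1]) if right[0] >= 1 else lam_hat
            try:
                hi = optimize.brentq(f, a, b, xtol=1e-6)
            except ValueError:
                hi = b
        return (float(lo), float(hi))

    # LR test ----------------------------------------------------------------
    def lr_test_lambda(self, lam0: float, grid=None):
        """Likelihood-ratio test of the Box-Cox exponent against ``lam0``.

        Returns ``(statistic, p_value)`` with the statistic referred to the
        chi-square distribution on one degree of freedom.
        """
        trace = self.profile_lambda(grid=grid, refine=True)
        ll0 = self.loglik_at(float(lam0))
        w = max(0.0, 2.0 * (trace.loglik_hat - ll0))
        return w, float(stats.chi2.sf(w, df=1))
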
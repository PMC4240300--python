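"""Crossed random-intercepts logistic regression via the Laplace approximation.

The model for binary outcome ``y_i`` with fixed-effect row ``x_i`` and two
crossed grouping factors (participant ``p(i)`` and candidate response letter
``l(i)``) is

    y_i ~ Bernoulli(sigmoid(x_i' beta + a_{p(i)} + c_{l(i)})),
    a_p ~ N(0, sigma_a^2),   c_l ~ N(0, sigma_c^2)   (independent).

Because the factors are crossed, the marginal likelihood does not factor over
clusters; it is approximated by a single joint Laplace expansion around the
mode of the penalised log-likelihood over all random effects:

    ll(beta, sigma) ~= g(u_hat) + q/2 * log(2*pi) - 1/2 * logdet H(u_hat),

with ``g`` the joint log-density of data and random effects, ``u_hat`` its
mode (found by damped Newton, exploiting the sparse two-factor structure of
the Hessian), ``q`` the total number of random effects and ``H`` the negative
Hessian of ``g`` at the mode.  The outer optimisation over ``beta`` and the
log random-effect SDs uses L-BFGS-B from fixed starting values (fixed effects
at 0, variances at 1), so fits are deterministic given the data.

Wald standard errors for the fixed effects condition on the estimated
variance parameters (the Schur complement of the joint (beta, u) Hessian),
matching common mixed-model practice; p-values are two-sided normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import expit
from scipy.stats import norm

from .exceptions import SeparationWarning

_LOG_2PI = np.log(2.0 * np.pi)


def _factorize(values) -> tuple[np.ndarray, np.ndarray]:
    codes, levels = pd.factorize(np.asarray(values), sort=True)
    if (codes < 0).any():
        raise ValueError("grouping factor contains missing values")
    return codes.astype(np.int64), np.asarray(levels)


class CrossedRandomLogit:
    """Logistic model with two crossed random intercepts.

    Parameters
    ----------
    endog : array-like of 0/1
    exog : 2-D array, n x p
        Fixed-effect design including any intercept column.
    groups_a, groups_b : array-like
        Level labels of the two crossed grouping factors (e.g. participant
        and candidate response letter), one per row.
    exog_names, group_names : sequences of str, optional
    """

    def __init__(self, endog, exog, groups_a, groups_b, exog_names=None,
                 group_names=("participant", "response")):
        self.endog = np.asarray(endog, dtype=np.float64).ravel()
        exog = np.asarray(exog, dtype=np.float64)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.exog = exog
        if len(self.endog) != exog.shape[0]:
            raise ValueError("endog and exog length mismatch")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        self.ia, self.levels_a = _factorize(groups_a)
        self.ib, self.levels_b = _factorize(groups_b)
        self.qa, self.qb = len(self.levels_a), len(self.levels_b)
        if self.qa < 2 or self.qb < 2:
            raise ValueError("each grouping factor needs at least 2 levels")
        for j in range(exog.shape[1]):
            col = exog[:, j]
            if np.ptp(col) == 0 and not np.allclose(col, 1.0):
                raise ValueError(f"feature column {j} is constant")
        self.nobs = len(self.endog)
        self.k_fe = exog.shape[1]
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(self.k_fe)
        ]
        self.group_names = tuple(group_names)
        self._iab = self.ia * self.qb + self.ib  # combined index for cross blocks
        self._u_warm = np.zeros(self.qa + self.qb)

    # -- joint (data + random effects) log density ------------------------

    def _joint(self, beta, u, var_a, var_b):
        eta = self.exog @ beta + u[self.ia] + u[self.qa + self.ib]
        ll = float(self.endog @ eta - np.logaddexp(0.0, eta).sum())
        ua, ub = u[: self.qa], u[self.qa :]
        ll -= 0.5 * (ua @ ua / var_a + self.qa * (_LOG_2PI + np.log(var_a)))
        ll -= 0.5 * (ub @ ub / var_b + self.qb * (_LOG_2PI + np.log(var_b)))
        return ll, eta

    def _hessian_blocks(self, w, var_a, var_b):
        da = np.bincount(self.ia, weights=w, minlength=self.qa) + 1.0 / var_a
        db = np.bincount(self.ib, weights=w, minlength=self.qb) + 1.0 / var_b
        C = np.bincount(self._iab, weights=w, minlength=self.qa * self.qb)
        return da, db, C.reshape(self.qa, self.qb)

    def _mode(self, beta, var_a, var_b, u0, tol=1e-9, maxiter=60):
        """Damped Newton ascent to the mode of the penalised log-likelihood."""
        qa, qb = self.qa, self.qb
        u = u0.copy()
        f, eta = self._joint(beta, u, var_a, var_b)
        H = None
        for _ in range(maxiter):
            mu = expit(eta)
            resid = self.endog - mu
            grad = np.concatenate(
                [
                    np.bincount(self.ia, weights=resid, minlength=qa) - u[:qa] / var_a,
                    np.bincount(self.ib, weights=resid, minlength=qb) - u[qa:] / var_b,
                ]
            )
            w = mu * (1.0 - mu) + 1e-12
            da, db, C = self._hessian_blocks(w, var_a, var_b)
            H = np.zeros((qa + qb, qa + qb))
            H[np.arange(qa), np.arange(qa)] = da
            H[qa:, qa:][np.arange(qb), np.arange(qb)] = db
            H[:qa, qa:] = C
            H[qa:, :qa] = C.T
            cho = linalg.cho_factor(H, lower=True, check_finite=False)
            step = linalg.cho_solve(cho, grad, check_finite=False)
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                f_new, eta_new = self._joint(beta, u_new, var_a, var_b)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            gain = f_new - f
            u, f, eta = u_new, f_new, eta_new
            if abs(gain) < tol and float(np.abs(grad).max()) < 1e-7:
                break
        # refresh curvature at the final mode
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        da, db, C = self._hessian_blocks(w, var_a, var_b)
        H = np.zeros((qa + qb, qa + qb))
        H[np.arange(qa), np.arange(qa)] = da
        H[qa:, qa:][np.arange(qb), np.arange(qb)] = db
        H[:qa, qa:] = C
        H[qa:, :qa] = C.T
        cho = linalg.cho_factor(H, lower=True, check_finite=False)
        logdet = 2.0 * float(np.log(np.diag(cho[0])).sum())
        return u, f, w, cho, logdet

    def _split_params(self, params):
        beta = np.asarray(params[: self.k_fe], dtype=float)
        sd_a, sd_b = np.exp(params[self.k_fe]), np.exp(params[self.k_fe + 1])
        return beta, sd_a**2, sd_b**2

    def loglike(self, params, warm: bool = True) -> float:
        """Laplace-approximate marginal log-likelihood at ``params``.

        ``params`` is ``[beta..., log sd_a, log sd_b]``.
        """
        beta, var_a, var_b = self._split_params(params)
        u0 = self._u_warm if warm else np.zeros(self.qa + self.qb)
        u, f, _, _, logdet = self._mode(beta, var_a, var_b, u0)
        if warm:
            self._u_warm = u
        q = self.qa + self.qb
        return f + 0.5 * q * _LOG_2PI - 0.5 * logdet

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        start_params=None,
        maxiter: int = 200,
        gtol: float = 1e-5,
        penalty: float = 0.0,
    ) -> "CrossedRandomLogitResults":
        """Maximise the Laplace marginal likelihood.

        Starts from fixed effects 0 and unit variances unless overridden.
        Quasi-separation (|beta| drifting beyond 10) triggers a warning and a
        ridge-penalised refit (flagged on the results object).
        """
        if start_params is None:
            start_params = np.zeros(self.k_fe + 2)  # log sd = 0 -> variance 1
        x0 = np.asarray(start_params, dtype=float)

        def negll(x):
            ll = self.loglike(x)
            if penalty > 0.0:
                ll -= penalty * float(np.sum(x[: self.k_fe] ** 2))
            return -ll

        bounds = [(-30.0, 30.0)] * self.k_fe + [(-6.0, 3.0)] * 2
        res = optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
        )
        beta = res.x[: self.k_fe]
        if penalty == 0.0 and np.abs(beta).max() > 10.0:
            warnings.warn(
                "possible quasi-separation (|coefficient| > 10); refitting with a "
                "small ridge penalty",
                SeparationWarning,
                stacklevel=2,
            )
            out = self.fit(start_params=start_params, maxiter=maxiter, gtol=gtol, penalty=1e-3)
            out.penalized = True
            return out

        beta, var_a, var_b = self._split_params(res.x)
        u, f, w, cho, logdet = self._mode(var_a=var_a, var_b=var_b, beta=beta, u0=self._u_warm)
        self._u_warm = u
        llf = f + 0.5 * (self.qa + self.qb) * _LOG_2PI - 0.5 * logdet

        cov = self._fe_cov(beta, w, cho)
        bse = np.sqrt(np.diag(cov))
        return CrossedRandomLogitResults(
            model=self,
            params=beta,
            cov_params=cov,
            bse=bse,
            re_sd={self.group_names[0]: np.sqrt(var_a), self.group_names[1]: np.sqrt(var_b)},
            llf=float(llf),
            converged=bool(res.success),
            penalized=penalty > 0.0,
            n_outer_iter=int(res.nit),
            random_effects={
                self.group_names[0]: pd.Series(u[: self.qa], index=self.levels_a),
                self.group_names[1]: pd.Series(u[self.qa :], index=self.levels_b),
            },
        )

    def _fe_cov(self, beta, w, cho):
        """Fixed-effect covariance conditional on the variance parameters.

        Schur complement of the joint (beta, u) negative Hessian at the mode:
        ``inv(X'WX - X'WZ H^-1 Z'WX)``.
        """
        X = self.exog
        XtWX = (X * w[:, None]).T @ X
        XtWZ = np.empty((self.k_fe, self.qa + self.qb))
        for j in range(self.k_fe):
            wx = w * X[:, j]
            XtWZ[j, : self.qa] = np.bincount(self.ia, weights=wx, minlength=self.qa)
            XtWZ[j, self.qa :] = np.bincount(self.ib, weights=wx, minlength=self.qb)
        inner = linalg.cho_solve(cho, XtWZ.T, check_finite=False)
        info = XtWX - XtWZ @ inner
        return linalg.inv(info)


@dataclass
class CrossedRandomLogitResults:
    """Fitted crossed random-intercepts logistic model."""

    model: CrossedRandomLogit
    params: np.ndarray
    cov_params: np.ndarray
    bse: np.ndarray
    re_sd: dict
    llf: float
    converged: bool
    penalized: bool
    n_outer_iter: int
    random_effects: dict = field(repr=False, default_factory=dict)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            },
            index=self.model.exog_names,
        )

    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = [
            "Crossed random-intercepts logistic model (Laplace)",
            f"  n obs: {self.nobs}   groups: "
            + ", ".join(
                f"{name} ({len(self.random_effects[name])} levels, sd={sd:.4f})"
                for name, sd in self.re_sd.items()
            ),
            f"  log-likelihood: {self.llf:.4f}   converged: {self.converged}"
            + ("   [ridge-penalised: separation]" if self.penalized else ""),
            "",
            self.to_frame().to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)
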
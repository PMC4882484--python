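"""Maximum-likelihood logistic mixed-effects regression.

Fits the binary mixed logit

    y_ij ~ Bernoulli(logistic(x_ij . beta + b_i [+ c_g]))
    b_i ~ N(0, sigma_id^2),   c_g ~ N(0, sigma_group^2)

by maximising the marginal likelihood, integrating the random intercepts
out numerically. With a single random factor (participants) the integral
factorises over subjects and is evaluated by adaptive Gauss-Hermite
quadrature centred on each subject's posterior mode (one node recovers the
Laplace approximation exactly). With a second, coarser random factor
(nationality) the joint integral is evaluated by a blockwise Laplace
approximation at the joint posterior mode, exploiting the arrowhead
structure of the Hessian (subjects are conditionally independent given
their group's intercept).

Standard errors come from the inverse numerical Hessian of the marginal
log-likelihood at the optimum, optionally supplemented by a parametric
bootstrap (simulate from the fitted model, refit, take the SD of the
replicate estimates). Wald intervals use the conventional 1.96 constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, logsumexp, roots_hermite
from scipy.stats import norm

__all__ = [
    "DataError",
    "ConvergenceError",
    "FitResult",
    "MixedLogit",
    "fit_logistic_mixed",
    "parametric_bootstrap_se",
    "wald_ci",
    "wald_test",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_SIGMA_FLOOR = 1e-8  # below this a variance component is treated as exactly zero


class DataError(ValueError):
    """Raised for data that cannot support the requested fit."""


class ConvergenceError(RuntimeError):
    """Raised when the optimiser fails and no usable fit exists."""


def wald_ci(coefficient: float, se: float, constant: float = 1.96) -> tuple[float, float]:
    """95% Wald interval, coefficient +/- 1.96 * SE."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return coefficient - constant * se, coefficient + constant * se


def wald_test(coefficient: float, se: float) -> tuple[float, float]:
    """Wald z statistic and two-sided normal p-value for a zero null."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    z = coefficient / se
    return z, float(2.0 * norm.sf(abs(z)))


def _bern_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-row Bernoulli log-likelihood, stable for large |eta|."""
    return y * eta - np.logaddexp(0.0, eta)


@dataclass
class FitResult:
    """Estimates and diagnostics from one mixed-logit fit."""

    coefficients: dict[str, float]
    se_hessian: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    z_values: dict[str, float]
    p_values: dict[str, float]
    log_likelihood: float
    deviance: float
    n_parameters: int
    variance_components: dict[str, float]
    converged: bool
    n_obs: int
    se_bootstrap: dict[str, float] | None = None
    n_boot_dropped: int = 0
    model_id: int | str | None = None
    _design: "MixedLogit | None" = field(default=None, repr=False, compare=False)

    @property
    def se(self) -> dict[str, float]:
        """Reported SEs: bootstrap when computed, else Hessian-based."""
        return self.se_bootstrap if self.se_bootstrap is not None else self.se_hessian

    def summary(self):
        """Coefficient table (one row per fixed effect) as a DataFrame."""
        import pandas as pd

        names = list(self.coefficients)
        return pd.DataFrame(
            {
                "coefficient": [self.coefficients[k] for k in names],
                "se": [self.se[k] for k in names],
                "ci_lower": [self.ci_lower[k] for k in names],
                "ci_upper": [self.ci_upper[k] for k in names],
                "z": [self.z_values[k] for k in names],
                "p": [self.p_values[k] for k in names],
            },
            index=names,
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "se_hessian": self.se_hessian,
            "se_bootstrap": self.se_bootstrap,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "z_values": self.z_values,
            "p_values": self.p_values,
            "log_likelihood": self.log_likelihood,
            "deviance": self.deviance,
            "n_parameters": self.n_parameters,
            "variance_components": self.variance_components,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_boot_dropped": self.n_boot_dropped,
            "model_id": self.model_id,
        }


class MixedLogit:
    """Marginal-likelihood machinery for one design.

    Parameters
    ----------
    X
        (n, p) fixed-effect design matrix (including the intercept column).
    y
        (n,) binary responses.
    subject
        (n,) integer subject codes ``0..S-1``.
    group
        Optional (n,) integer codes ``0..G-1`` for a second (coarse) random
        intercept factor; every subject must belong to exactly one group.
    names
        Fixed-effect names, length p.
    nodes
        Gauss-Hermite nodes for the subject integral (1 = Laplace). The
        two-factor likelihood always uses the joint Laplace approximation.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        subject: np.ndarray,
        group: np.ndarray | None = None,
        names: Sequence[str] | None = None,
        nodes: int = 15,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.subject = np.asarray(subject, dtype=np.intp)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise DataError("X and y shapes are inconsistent")
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise DataError("responses must be coded 0/1")
        if self.y.min() == self.y.max():
            raise DataError("responses are all identical; the logit is not identified")
        self.n_subjects = int(self.subject.max()) + 1
        if self.n_subjects < 2:
            raise DataError("need at least 2 subjects")
        self.group = None if group is None else np.asarray(group, dtype=np.intp)
        self.n_groups = 0 if self.group is None else int(self.group.max()) + 1
        if self.group is not None:
            subj_grp = np.full(self.n_subjects, -1, dtype=np.intp)
            subj_grp[self.subject] = self.group
            if np.any(subj_grp < 0):
                raise DataError("every subject needs at least one row")
            if np.any(subj_grp[self.subject] != self.group):
                raise DataError("subjects must be nested within groups")
            self.subject_group = subj_grp
        self.names = list(names) if names is not None else [
            f"x{j}" for j in range(self.X.shape[1])
        ]
        if len(self.names) != self.X.shape[1]:
            raise DataError("names length must match X columns")
        if nodes < 1:
            raise ValueError("nodes must be >= 1")
        z, w = roots_hermite(nodes)
        self._ghq = (z, np.log(w))
        self._b_warm = np.zeros(self.n_subjects)
        self._c_warm = np.zeros(max(self.n_groups, 1))

    # -- subject-level posterior modes -----------------------------------

    def _subject_objective(self, eta0, b, sigma):
        ll = np.bincount(
            self.subject, weights=_bern_loglik(eta0 + b[self.subject], self.y),
            minlength=self.n_subjects,
        )
        return ll - 0.5 * b**2 / sigma**2

    def _subject_modes(self, eta0, sigma, b0):
        """Vectorised damped Newton for each subject's penalised mode."""
        b = b0.copy()
        obj = self._subject_objective(eta0, b, sigma)
        for _ in range(60):
            p = expit(eta0 + b[self.subject])
            g = (
                np.bincount(self.subject, weights=self.y - p, minlength=self.n_subjects)
                - b / sigma**2
            )
            curv = (
                np.bincount(self.subject, weights=p * (1 - p), minlength=self.n_subjects)
                + 1.0 / sigma**2
            )
            step = np.clip(g / curv, -10.0, 10.0)
            if np.max(np.abs(step)) < 1e-10:
                break
            # Per-subject step halving keeps the concave objective increasing.
            for _ in range(25):
                new_obj = self._subject_objective(eta0, b + step, sigma)
                bad = new_obj < obj - 1e-12
                if not np.any(bad):
                    break
                step[bad] *= 0.5
            b = b + step
            obj = self._subject_objective(eta0, b, sigma)
        p = expit(eta0 + b[self.subject])
        curv = (
            np.bincount(self.subject, weights=p * (1 - p), minlength=self.n_subjects)
            + 1.0 / sigma**2
        )
        return b, curv

    def _loglik_single(self, eta0, sigma):
        """Adaptive GHQ marginal log-likelihood, one random factor."""
        if sigma < _SIGMA_FLOOR:
            return float(np.sum(_bern_loglik(eta0, self.y)))
        b_hat, curv = self._subject_modes(eta0, sigma, self._b_warm)
        self._b_warm = b_hat
        sd_hat = 1.0 / np.sqrt(curv)
        z, logw = self._ghq
        terms = np.empty((z.size, self.n_subjects))
        for k in range(z.size):
            bk = b_hat + np.sqrt(2.0) * sd_hat * z[k]
            ll_data = np.bincount(
                self.subject,
                weights=_bern_loglik(eta0 + bk[self.subject], self.y),
                minlength=self.n_subjects,
            )
            terms[k] = logw[k] + z[k] ** 2 - 0.5 * bk**2 / sigma**2 + ll_data
        ll_i = (
            logsumexp(terms, axis=0)
            + 0.5 * np.log(2.0) + np.log(sd_hat)
            - np.log(sigma) - 0.5 * _LOG_2PI
        )
        return float(np.sum(ll_i))

    # -- two-factor joint Laplace ----------------------------------------

    def _joint_objective(self, eta0, b, c, sigma_id, sigma_g):
        eta = eta0 + b[self.subject] + c[self.group]
        return (
            float(np.sum(_bern_loglik(eta, self.y)))
            - 0.5 * float(np.sum(b**2)) / sigma_id**2
            - 0.5 * float(np.sum(c**2)) / sigma_g**2
        )

    def _loglik_two_factor(self, eta0, sigma_id, sigma_g):
        if sigma_g < _SIGMA_FLOOR:
            # Group variance at the boundary: the factor drops out.
            z_save = self._ghq
            self._ghq = (np.array([0.0]), np.array([0.5 * np.log(np.pi)]))
            try:
                return self._loglik_single(eta0, sigma_id)
            finally:
                self._ghq = z_save
        S, G = self.n_subjects, self.n_groups
        b, c = self._b_warm.copy(), self._c_warm.copy()
        obj = self._joint_objective(eta0, b, c, sigma_id, sigma_g)
        for _ in range(100):
            eta = eta0 + b[self.subject] + c[self.group]
            p = expit(eta)
            w = p * (1 - p)
            gb = np.bincount(self.subject, weights=self.y - p, minlength=S) - b / sigma_id**2
            gc = np.bincount(self.group, weights=self.y - p, minlength=G) - c / sigma_g**2
            Ws = np.bincount(self.subject, weights=w, minlength=S)
            Wg = np.bincount(self.group, weights=w, minlength=G)
            A = Ws + 1.0 / sigma_id**2
            D = Wg + 1.0 / sigma_g**2
            # Schur complement on the group block is diagonal because each
            # subject sits in exactly one group.
            M = D - np.bincount(self.subject_group, weights=Ws**2 / A, minlength=G)
            rhs = gc - np.bincount(self.subject_group, weights=Ws * gb / A, minlength=G)
            dc = rhs / M
            db = (gb - Ws * dc[self.subject_group]) / A
            step_norm = max(np.max(np.abs(db), initial=0.0), np.max(np.abs(dc), initial=0.0))
            if step_norm < 1e-10:
                break
            scale = 1.0
            for _ in range(30):
                new_obj = self._joint_objective(
                    eta0, b + scale * db, c + scale * dc, sigma_id, sigma_g
                )
                if new_obj >= obj - 1e-12:
                    break
                scale *= 0.5
            b = b + scale * db
            c = c + scale * dc
            obj = new_obj
        self._b_warm, self._c_warm = b, c
        eta = eta0 + b[self.subject] + c[self.group]
        p = expit(eta)
        w = p * (1 - p)
        Ws = np.bincount(self.subject, weights=w, minlength=S)
        Wg = np.bincount(self.group, weights=w, minlength=G)
        A = Ws + 1.0 / sigma_id**2
        D = Wg + 1.0 / sigma_g**2
        M = D - np.bincount(self.subject_group, weights=Ws**2 / A, minlength=G)
        logdet = float(np.sum(np.log(A)) + np.sum(np.log(M)))
        return (
            obj
            - 0.5 * logdet
            - S * np.log(sigma_id)
            - G * np.log(sigma_g)
        )

    # -- public likelihood / fitting -------------------------------------

    def loglik(self, beta: np.ndarray, sigma_id: float, sigma_group: float | None = None):
        """Marginal log-likelihood at the given parameters."""
        eta0 = self.X @ np.asarray(beta, dtype=float)
        if self.group is None:
            if sigma_group not in (None, 0, 0.0):
                raise ValueError("model has no group factor")
            if sigma_id < _SIGMA_FLOOR:
                return float(np.sum(_bern_loglik(eta0, self.y)))
            return self._loglik_single(eta0, sigma_id)
        sigma_group = 0.0 if sigma_group is None else sigma_group
        if sigma_id < _SIGMA_FLOOR:
            raise NotImplementedError("sigma_id at zero with a group factor is unsupported")
        return self._loglik_two_factor(eta0, sigma_id, sigma_group)

    def _start_beta(self) -> np.ndarray:
        """Plain (fixed-effects only) logistic regression via IRLS."""
        X, y = self.X, self.y
        beta = np.zeros(X.shape[1])
        for _ in range(50):
            eta = X @ beta
            p = expit(eta)
            w = np.maximum(p * (1 - p), 1e-10)
            # One ridge-stabilised Newton step.
            H = (X * w[:, None]).T @ X + 1e-8 * np.eye(X.shape[1])
            g = X.T @ (y - p)
            step = np.linalg.solve(H, g)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        return beta

    def fit(
        self,
        fix_sigma_id: float | None = None,
        start: np.ndarray | None = None,
        names: Sequence[str] | None = None,
        model_id: int | str | None = None,
    ) -> FitResult:
        """Maximise the marginal likelihood and assemble a :class:`FitResult`."""
        p = self.X.shape[1]
        has_group = self.group is not None
        free_sigma_id = fix_sigma_id is None

        def unpack(theta):
            beta = theta[:p]
            i = p
            if free_sigma_id:
                sid = theta[i]
                i += 1
            else:
                sid = fix_sigma_id
            sg = theta[i] if has_group else None
            return beta, sid, sg

        def nll(theta):
            beta, sid, sg = unpack(theta)
            return -self.loglik(beta, sid, sg)

        x0 = list(start) if start is not None else list(self._start_beta())
        bounds: list[tuple[float | None, float | None]] = [(None, None)] * p
        if free_sigma_id:
            x0.append(1.0)
            bounds.append((_SIGMA_FLOOR, None))
        if has_group:
            x0.append(0.3)
            bounds.append((0.0, None))
        x0 = np.asarray(x0, dtype=float)

        self._b_warm = np.zeros(self.n_subjects)
        self._c_warm = np.zeros(max(self.n_groups, 1))
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-6, "eps": 1e-6},
        )
        beta_hat, sid_hat, sg_hat = unpack(res.x)
        converged = bool(res.success)
        if not converged and not np.isfinite(res.fun):
            raise ConvergenceError(f"mixed-logit optimisation failed: {res.message}")

        ll = -float(res.fun)
        variance = {"sigma_id": float(sid_hat)}
        if has_group:
            variance["sigma_group"] = float(sg_hat)
        n_par = p + (1 if free_sigma_id else 0) + (1 if has_group else 0)
        if fix_sigma_id is not None:
            variance["sigma_id"] = float(fix_sigma_id)

        se = self._hessian_se(nll, res.x, bounds)
        names = list(names) if names is not None else self.names
        coef = dict(zip(names, map(float, beta_hat)))
        se_map = dict(zip(names, map(float, se[:p])))
        ci_lo, ci_hi, zmap, pmap = {}, {}, {}, {}
        for k in names:
            if np.isfinite(se_map[k]) and se_map[k] > 0:
                ci_lo[k], ci_hi[k] = wald_ci(coef[k], se_map[k])
                zmap[k], pmap[k] = wald_test(coef[k], se_map[k])
            else:
                ci_lo[k] = ci_hi[k] = zmap[k] = pmap[k] = float("nan")
        return FitResult(
            coefficients=coef,
            se_hessian=se_map,
            ci_lower=ci_lo,
            ci_upper=ci_hi,
            z_values=zmap,
            p_values=pmap,
            log_likelihood=ll,
            deviance=-2.0 * ll,
            n_parameters=n_par,
            variance_components=variance,
            converged=converged,
            n_obs=int(self.y.size),
            model_id=model_id,
            _design=self,
        )

    def _hessian_se(self, nll, theta, bounds) -> np.ndarray:
        """SEs from the inverse central-difference Hessian at the optimum.

        Parameters stuck at a bound are profiled out of the Hessian (their
        SE is reported as NaN).
        """
        theta = np.asarray(theta, dtype=float)
        k = theta.size
        free = np.ones(k, dtype=bool)
        for i, (lo, hi) in enumerate(bounds):
            if lo is not None and theta[i] - lo < 1e-6:
                free[i] = False
            if hi is not None and hi - theta[i] < 1e-6:
                free[i] = False
        idx = np.where(free)[0]
        m = idx.size
        h = 1e-4 * np.maximum(1.0, np.abs(theta[idx]))
        H = np.zeros((m, m))
        f0 = nll(theta)
        for a in range(m):
            ia = idx[a]
            ea = np.zeros(k)
            ea[ia] = h[a]
            fpp = nll(theta + ea)
            fmm = nll(theta - ea)
            H[a, a] = (fpp - 2.0 * f0 + fmm) / h[a] ** 2
            for bb in range(a + 1, m):
                ib = idx[bb]
                eb = np.zeros(k)
                eb[ib] = h[bb]
                fab = nll(theta + ea + eb)
                fa_b = nll(theta + ea - eb)
                f_ab = nll(theta - ea + eb)
                f_a_b = nll(theta - ea - eb)
                H[a, bb] = H[bb, a] = (fab - fa_b - f_ab + f_a_b) / (4.0 * h[a] * h[bb])
        se = np.full(k, np.nan)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            with np.errstate(invalid="ignore"):
                se[idx] = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian; SEs unavailable", RuntimeWarning)
        return se


def fit_logistic_mixed(
    trials,
    model_spec=1,
    coding: str = "default",
    nodes: int = 15,
    fix_sigma_id: float | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Fit a mixed logit to a trial table under one of the ladder models.

    ``model_spec`` may be a model id (1, 2, 3) or a
    :class:`~boubakit.model_selection.ModelSpec`. Model 1 (shared slopes,
    participant intercepts only) also serves as the separate-group "base"
    model when ``trials`` contains a single group.
    """
    from .model_selection import build_design_matrix, model_spec as _resolve

    spec = _resolve(model_spec) if not hasattr(model_spec, "fixed_terms") else model_spec
    dm = build_design_matrix(trials, spec, coding=coding)
    ml = MixedLogit(
        dm.X, dm.y, dm.subject, group=dm.group, names=dm.names, nodes=nodes
    )
    fit = ml.fit(fix_sigma_id=fix_sigma_id, model_id=spec.model_id)
    if n_boot:
        parametric_bootstrap_se(fit, n_boot=n_boot, seed=seed)
    return fit


def parametric_bootstrap_se(
    fit: FitResult,
    n_boot: int = 200,
    seed: int | None = None,
) -> dict[str, float]:
    """Parametric-bootstrap SEs: simulate from the fit, refit, take SDs.

    Mutates ``fit.se_bootstrap`` (and the Wald columns, which are refreshed
    from the bootstrap SEs) and returns the SE map. Non-converging
    replicates are dropped and counted; more than 10% drops raises a
    warning.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50 for a usable SE")
    ml = fit._design
    if ml is None:
        raise ValueError("fit carries no design; refit with this package first")
    rng = np.random.default_rng(seed)
    beta = np.array([fit.coefficients[k] for k in ml.names])
    sid = fit.variance_components.get("sigma_id", 0.0)
    sg = fit.variance_components.get("sigma_group", 0.0)
    eta_fixed = ml.X @ beta
    draws = []
    dropped = 0
    for _ in range(n_boot):
        b = rng.normal(0.0, sid, size=ml.n_subjects)
        eta = eta_fixed + b[ml.subject]
        if ml.group is not None and sg > 0:
            c = rng.normal(0.0, sg, size=ml.n_groups)
            eta = eta + c[ml.group]
        y_star = (rng.random(ml.y.size) < expit(eta)).astype(float)
        if y_star.min() == y_star.max():
            dropped += 1
            continue
        ml_star = MixedLogit(
            ml.X, y_star, ml.subject, group=ml.group, names=ml.names,
            nodes=ml._ghq[0].size,
        )
        try:
            res = ml_star.fit(start=beta)
        except (ConvergenceError, DataError):
            dropped += 1
            continue
        if not res.converged:
            dropped += 1
            continue
        draws.append([res.coefficients[k] for k in ml.names])
    if len(draws) < 2:
        raise ConvergenceError("all bootstrap replicates failed")
    if dropped > 0.1 * n_boot:
        warnings.warn(
            f"{dropped}/{n_boot} bootstrap replicates dropped", RuntimeWarning
        )
    sds = np.std(np.asarray(draws), axis=0, ddof=1)
    fit.se_bootstrap = dict(zip(ml.names, map(float, sds)))
    fit.n_boot_dropped = dropped
    for k in ml.names:
        if fit.se_bootstrap[k] > 0:
            fit.ci_lower[k], fit.ci_upper[k] = wald_ci(fit.coefficients[k], fit.se_bootstrap[k])
            fit.z_values[k], fit.p_values[k] = wald_test(fit.coefficients[k], fit.se_bootstrap[k])
    return fit.se_bootstrap
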
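"""Mixed-effects models for repeated-measures choice and looking data.

Two model families over a common result type:

* :class:`LinearMixedModel` — Gaussian responses with independent
  random-intercept factors (variance components).  REML (default) or ML via
  profiled likelihood; Wald t statistics with Satterthwaite-style degrees of
  freedom (delta method on the variance parameters, as in lmerTest).
* :class:`BinomialMixedModel` — logistic models with random intercepts,
  fitted by adaptive Gauss-Hermite quadrature for a single factor and by a
  Laplace approximation for crossed factors.  Reports Wald z and odds ratios.

Also here: stepwise backwards elimination (interactions before their main
effects) and a signed-rank test with tie correction that returns the normal
approximation Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

__all__ = [
    "MixedModelResult",
    "LinearMixedModel",
    "BinomialMixedModel",
    "ConvergenceError",
    "backwards_eliminate",
    "wilcoxon_signed_rank",
    "odds_ratio",
]


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach a maximum of the (restricted) likelihood."""


def odds_ratio(estimate: float) -> float:
    """exp(log-odds estimate)."""
    return float(np.exp(estimate))


def _encode_groups(groups: dict) -> dict:
    out = {}
    for name, labels in groups.items():
        codes, levels = pd.factorize(np.asarray(labels))
        out[name] = (codes, len(levels))
    return out


def _zmat(codes: np.ndarray, q: int) -> np.ndarray:
    z = np.zeros((len(codes), q))
    z[np.arange(len(codes)), codes] = 1.0
    return z


@dataclass
class MixedModelResult:
    """Fixed-effect table plus variance components for one fitted model."""

    family: str
    names: list
    params: pd.Series
    bse: pd.Series
    stat: pd.Series  # t (gaussian) or z (binomial)
    pvalues: pd.Series
    df: pd.Series | None  # Satterthwaite df (gaussian only)
    vcomp: dict  # random-intercept variances by factor name
    sigma2: float | None  # residual variance (gaussian only)
    loglik: float
    n: int
    converged: bool
    cov_params: np.ndarray
    dropped_factors: list = field(default_factory=list)
    method: str = ""

    def odds_ratios(self) -> pd.Series:
        if self.family != "binomial":
            raise ValueError("odds ratios are defined for binomial fits only")
        return np.exp(self.params)

    def summary(self) -> str:
        rows = []
        statname = "z" if self.family == "binomial" else "t"
        for name in self.names:
            row = {
                "term": name,
                "estimate": self.params[name],
                "SEM": self.bse[name],
                statname: self.stat[name],
                "p": self.pvalues[name],
            }
            if self.family == "binomial":
                row["odds_ratio"] = np.exp(self.params[name])
            if self.df is not None:
                row["df"] = self.df[name]
            rows.append(row)
        tab = pd.DataFrame(rows).to_string(index=False, float_format=lambda v: f"{v:.4f}")
        vc = ", ".join(f"{k}={v:.4f}" for k, v in self.vcomp.items()) or "none"
        extra = f"  residual var={self.sigma2:.4f}" if self.sigma2 is not None else ""
        return (
            f"{self.family} mixed model ({self.method}), n={self.n}, "
            f"logLik={self.loglik:.3f}\nrandom-intercept variances: {vc}{extra}\n{tab}"
        )

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "n": self.n,
            "loglik": self.loglik,
            "vcomp": {k: float(v) for k, v in self.vcomp.items()},
            "sigma2": None if self.sigma2 is None else float(self.sigma2),
            "terms": {},
            "dropped_factors": list(self.dropped_factors),
        }
        for name in self.names:
            t = {
                "estimate": float(self.params[name]),
                "se": float(self.bse[name]),
                "stat": float(self.stat[name]),
                "p": float(self.pvalues[name]),
            }
            if self.df is not None:
                t["df"] = float(self.df[name])
            if self.family == "binomial":
                t["odds_ratio"] = float(np.exp(self.params[name]))
            d["terms"][name] = t
        return d


def _as_design(X) -> tuple:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


# ---------------------------------------------------------------------------
# Gaussian linear mixed model


class LinearMixedModel:
    """Gaussian mixed model with independent random-intercept factors.

    Parameters
    ----------
    X : DataFrame or array, fixed-effect design (include the intercept column)
    y : response vector
    groups : mapping factor name -> per-row labels
    reml : restricted (True) or full (False) maximum likelihood
    """

    def __init__(self, X, y, groups: dict | None = None, reml: bool = True):
        self.Xmat, self.names = _as_design(X)
        self.y = np.asarray(y, dtype=float)
        self.groups = groups or {}
        self.reml = reml
        enc = _encode_groups(self.groups)
        self.group_names = list(enc.keys())
        self.Z = [_zmat(codes, q) for codes, q in enc.values()]
        self.ZZt = [z @ z.T for z in self.Z]
        for name, (codes, q) in enc.items():
            if q < 2:
                raise ValueError(f"random factor {name!r} has < 2 levels")

    # -- profiled (restricted) log-likelihood over variance ratios theta ----
    def _profile(self, theta: np.ndarray):
        n, p = self.Xmat.shape
        V = np.eye(n)
        for t, zz in zip(theta, self.ZZt):
            V += t * zz
        c, low = cho_factor(V, lower=True)
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        vi_x = cho_solve((c, low), self.Xmat)
        vi_y = cho_solve((c, low), self.y)
        xtvx = self.Xmat.T @ vi_x
        beta = np.linalg.solve(xtvx, self.Xmat.T @ vi_y)
        r = self.y - self.Xmat @ beta
        q = float(r @ cho_solve((c, low), r))
        if self.reml:
            dof = n - p
            sigma2 = q / dof
            sign, logdet_x = np.linalg.slogdet(xtvx)
            ll = -0.5 * (
                logdet_v + logdet_x + dof * (np.log(2 * np.pi * sigma2) + 1)
            )
        else:
            sigma2 = q / n
            ll = -0.5 * (logdet_v + n * (np.log(2 * np.pi * sigma2) + 1))
        cov_beta = sigma2 * np.linalg.inv(xtvx)
        return ll, beta, sigma2, cov_beta

    def _neg_reml_var_scale(self, var: np.ndarray) -> float:
        """-2 * (restricted) loglik as a function of variance-scale params
        (sigma_1^2..sigma_K^2, sigma_e^2); used for the Satterthwaite Hessian."""
        n, p = self.Xmat.shape
        se2 = var[-1]
        if se2 <= 0 or np.any(var[:-1] < 0):
            return np.inf
        V = se2 * np.eye(n)
        for v, zz in zip(var[:-1], self.ZZt):
            V += v * zz
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        vi_x = cho_solve((c, low), self.Xmat)
        xtvx = self.Xmat.T @ vi_x
        beta = np.linalg.solve(xtvx, self.Xmat.T @ cho_solve((c, low), self.y))
        r = self.y - self.Xmat @ beta
        q = float(r @ cho_solve((c, low), r))
        out = logdet_v + q + n * np.log(2 * np.pi)
        if self.reml:
            sign, logdet_x = np.linalg.slogdet(xtvx)
            out += logdet_x - p * np.log(2 * np.pi)
        return 0.5 * out

    def _cov_beta_var_scale(self, var: np.ndarray) -> np.ndarray:
        n = len(self.y)
        V = var[-1] * np.eye(n)
        for v, zz in zip(var[:-1], self.ZZt):
            V += v * zz
        c, low = cho_factor(V, lower=True)
        vi_x = cho_solve((c, low), self.Xmat)
        return np.linalg.inv(self.Xmat.T @ vi_x)

    def fit(self, drop_zero_variance: bool = False) -> MixedModelResult:
        n, p = self.Xmat.shape
        k = len(self.Z)
        if k == 0:
            theta = np.empty(0)
            message = "no random factors: generalized least squares"
            success = True
        else:
            def obj(log_theta):
                ll, *_ = self._profile(np.exp(log_theta))
                return -ll

            res = optimize.minimize(
                obj,
                x0=np.zeros(k),
                method="L-BFGS-B",
                bounds=[(-14.0, 10.0)] * k,
                options={"ftol": 1e-13, "gtol": 1e-9},
            )
            if not res.success:
                # L-BFGS-B line searches can abort at machine precision;
                # polish deterministically and accept if not worse
                res2 = optimize.minimize(
                    obj, res.x, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
                )
                if res2.fun <= res.fun + 1e-8:
                    res = res2
                else:
                    raise ConvergenceError(f"LMM optimizer failed: {res.message}")
            theta = np.clip(np.exp(res.x), np.exp(-14.0), np.exp(10.0))
            message, success = str(res.message), True
        ll, beta, sigma2, cov_beta = self._profile(theta)
        vcomp = {name: float(t * sigma2) for name, t in zip(self.group_names, theta)}

        if drop_zero_variance:
            dead = [
                name for name, v in vcomp.items() if v < 1e-5 * max(np.var(self.y), 1e-12)
            ]
            if dead:
                keep = {g: lab for g, lab in self.groups.items() if g not in dead}
                sub = LinearMixedModel(
                    pd.DataFrame(self.Xmat, columns=self.names), self.y, keep, self.reml
                ).fit(drop_zero_variance=False)
                sub.dropped_factors = dead + sub.dropped_factors
                return sub

        self._var_hat = np.append(theta * sigma2, sigma2)
        bse = np.sqrt(np.diag(cov_beta))
        dfs = np.array([self._satterthwaite_df(np.eye(p)[j]) for j in range(p)])
        tval = beta / bse
        pval = 2 * stats.t.sf(np.abs(tval), dfs)
        idx = self.names
        return MixedModelResult(
            family="gaussian",
            names=list(idx),
            params=pd.Series(beta, index=idx),
            bse=pd.Series(bse, index=idx),
            stat=pd.Series(tval, index=idx),
            pvalues=pd.Series(pval, index=idx),
            df=pd.Series(dfs, index=idx),
            vcomp=vcomp,
            sigma2=float(sigma2),
            loglik=float(ll),
            n=n,
            converged=success,
            cov_params=cov_beta,
            method="REML" if self.reml else "ML",
        )

    # -- Satterthwaite df for a contrast c'beta ------------------------------
    def _satterthwaite_df(self, c: np.ndarray) -> float:
        n, p = self.Xmat.shape
        fallback = max(n - p, 1)
        var = getattr(self, "_var_hat", None)
        if var is None or len(var) == 1:  # no random factors -> classical df
            return float(fallback)

        def var_c(v):
            return float(c @ self._cov_beta_var_scale(v) @ c)

        steps = np.maximum(1e-4 * np.abs(var), 1e-10)
        g = np.zeros(len(var))
        for j, h in enumerate(steps):
            e = np.zeros(len(var))
            e[j] = h
            g[j] = (var_c(var + e) - var_c(np.maximum(var - e, 1e-12))) / (
                var[j] + e[j] - max(var[j] - h, 1e-12)
            )
        # asymptotic covariance of the variance estimates: inverse Hessian
        m = len(var)
        H = np.zeros((m, m))
        f0 = self._neg_reml_var_scale(var)
        for i in range(m):
            for j in range(i, m):
                hi, hj = steps[i], steps[j]
                ei = np.zeros(m); ei[i] = hi
                ej = np.zeros(m); ej[j] = hj
                if i == j:
                    fpp = self._neg_reml_var_scale(var + ei)
                    fmm = self._neg_reml_var_scale(np.maximum(var - ei, 1e-12))
                    H[i, i] = (fpp - 2 * f0 + fmm) / hi**2
                else:
                    fpp = self._neg_reml_var_scale(var + ei + ej)
                    fpm = self._neg_reml_var_scale(np.maximum(var + ei - ej, 1e-12))
                    fmp = self._neg_reml_var_scale(np.maximum(var - ei + ej, 1e-12))
                    fmm = self._neg_reml_var_scale(np.maximum(var - ei - ej, 1e-12))
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi * hj)
        try:
            A = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            return float(fallback)
        v = var_c(var)
        denom = float(g @ A @ g)
        if not np.isfinite(denom) or denom <= 0:
            return float(fallback)
        df = 2 * v**2 / denom
        return float(np.clip(df, 1.0, fallback))

    def contrast(self, result: MixedModelResult, weights: dict) -> dict:
        """Estimate, SE, t, Satterthwaite df and p for a linear combination
        of fixed effects, e.g. a simple slope {term_a: 1, term_ab: 1}."""
        c = np.zeros(len(self.names))
        for name, wgt in weights.items():
            c[self.names.index(name)] = wgt
        est = float(c @ result.params.to_numpy())
        se = float(np.sqrt(c @ result.cov_params @ c))
        df = self._satterthwaite_df(c)
        t = est / se
        return {
            "estimate": est,
            "se": se,
            "t": t,
            "df": df,
            "p": float(2 * stats.t.sf(abs(t), df)),
        }


# ---------------------------------------------------------------------------
# Binomial (logistic) mixed model


class BinomialMixedModel:
    """Logistic mixed model with random intercepts.

    A single random factor integrates the random effect by adaptive
    Gauss-Hermite quadrature (``agq_nodes`` nodes around the per-group
    Laplace mode); crossed factors use the Laplace approximation.
    """

    def __init__(self, X, y, groups: dict, agq_nodes: int = 15):
        self.Xmat, self.names = _as_design(X)
        self.y = np.asarray(y, dtype=float)
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("binomial response must be binary 0/1")
        self.groups = dict(groups)
        enc = _encode_groups(self.groups)
        self.group_names = list(enc.keys())
        self.codes = [codes for codes, _ in enc.values()]
        self.qs = [q for _, q in enc.values()]
        self.agq_nodes = agq_nodes
        self._gh = np.polynomial.hermite.hermgauss(agq_nodes)

    # -- single-factor adaptive quadrature ----------------------------------
    def _negll_agq(self, params: np.ndarray) -> float:
        p = self.Xmat.shape[1]
        beta, theta = params[:p], float(np.exp(params[p]))
        codes, q = self.codes[0], self.qs[0]
        eta0 = self.Xmat @ beta
        u = np.zeros(q)
        for _ in range(100):
            eta = eta0 + u[codes]
            mu = expit(eta)
            g1 = np.bincount(codes, self.y - mu, minlength=q) - u / theta
            w = np.bincount(codes, mu * (1 - mu), minlength=q) + 1.0 / theta
            step = g1 / w
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break
        s = 1.0 / np.sqrt(w)
        x_j, w_j = self._gh
        uj = u[None, :] + np.sqrt(2.0) * s[None, :] * x_j[:, None]  # (nodes, q)
        eta_j = eta0[None, :] + uj[:, codes]
        ll_obs = self.y[None, :] * eta_j - np.logaddexp(0.0, eta_j)
        h = np.vstack(
            [np.bincount(codes, ll_obs[j], minlength=q) for j in range(len(x_j))]
        )
        h += -(uj**2) / (2 * theta) - 0.5 * np.log(2 * np.pi * theta)
        lse = h + x_j[:, None] ** 2 + np.log(w_j)[:, None]
        m = np.max(lse, axis=0)
        ll_g = m + np.log(np.sum(np.exp(lse - m), axis=0)) + 0.5 * np.log(2.0) + np.log(s)
        return -float(np.sum(ll_g))

    # -- crossed-factor Laplace ----------------------------------------------
    def _negll_laplace(self, params: np.ndarray) -> float:
        p = self.Xmat.shape[1]
        beta = params[:p]
        thetas = np.exp(params[p:])
        Z = np.hstack([_zmat(c, q) for c, q in zip(self.codes, self.qs)])
        dinv = np.concatenate(
            [np.full(q, 1.0 / t) for q, t in zip(self.qs, thetas)]
        )
        eta0 = self.Xmat @ beta
        u = np.zeros(Z.shape[1])

        def pen_ll(uvec):
            eta = eta0 + Z @ uvec
            return float(
                np.sum(self.y * eta - np.logaddexp(0.0, eta)) - 0.5 * np.sum(dinv * uvec**2)
            )

        cur = pen_ll(u)
        H = None
        for _ in range(100):
            eta = eta0 + Z @ u
            mu = expit(eta)
            grad = Z.T @ (self.y - mu) - dinv * u
            w = mu * (1 - mu)
            H = (Z * w[:, None]).T @ Z + np.diag(dinv)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                return np.inf
            # step-halving line search on the penalized log-likelihood
            t = 1.0
            for _ in range(30):
                new = pen_ll(u + t * step)
                if new >= cur - 1e-12:
                    break
                t /= 2
            u = u + t * step
            if abs(new - cur) < 1e-11 and np.max(np.abs(t * step)) < 1e-8:
                cur = new
                break
            cur = new
        eta = eta0 + Z @ u
        mu = expit(eta)
        w = mu * (1 - mu)
        H = (Z * w[:, None]).T @ Z + np.diag(dinv)
        sign, logdet_h = np.linalg.slogdet(H)
        logdet_d = float(np.sum([q * np.log(t) for q, t in zip(self.qs, thetas)]))
        return -(cur - 0.5 * logdet_d - 0.5 * logdet_h)

    def _negll(self, params: np.ndarray) -> float:
        if len(self.groups) == 1:
            return self._negll_agq(params)
        return self._negll_laplace(params)

    def _start(self) -> np.ndarray:
        # plain logistic IRLS for starting fixed effects
        beta = np.zeros(self.Xmat.shape[1])
        for _ in range(30):
            eta = self.Xmat @ beta
            mu = expit(eta)
            w = np.maximum(mu * (1 - mu), 1e-6)
            z = eta + (self.y - mu) / w
            wx = self.Xmat * w[:, None]
            try:
                new = np.linalg.solve(self.Xmat.T @ wx, wx.T @ z)
            except np.linalg.LinAlgError:
                break
            if np.max(np.abs(new - beta)) < 1e-8:
                beta = new
                break
            beta = np.clip(new, -10, 10)
        return np.concatenate([beta, np.zeros(len(self.groups))])

    def fit(self, drop_zero_variance: bool = True) -> MixedModelResult:
        if not self.groups:
            raise ValueError("BinomialMixedModel requires at least one random factor")
        p = self.Xmat.shape[1]
        x0 = self._start()
        bounds = [(None, None)] * p + [(-16.0, 8.0)] * len(self.groups)
        res = optimize.minimize(
            self._negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8},
        )
        if not res.success:
            res2 = optimize.minimize(
                self._negll, res.x, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 4000},
            )
            if res2.fun <= res.fun + 1e-8:
                res2.x[p:] = np.clip(res2.x[p:], -16.0, 8.0)
                res = res2
            else:
                raise ConvergenceError(
                    f"binomial mixed model failed to converge: {res.message}; "
                    f"|grad|={np.max(np.abs(res.jac)):.3g}; x={res.x}"
                )
        params = res.x
        thetas = np.exp(params[p:])
        vcomp = {name: float(t) for name, t in zip(self.group_names, thetas)}

        if drop_zero_variance:
            dead = [name for name, v in vcomp.items() if v < 1e-5]
            if dead and len(dead) < len(self.groups):
                keep = {g: lab for g, lab in self.groups.items() if g not in dead}
                sub = BinomialMixedModel(
                    pd.DataFrame(self.Xmat, columns=self.names),
                    self.y,
                    keep,
                    self.agq_nodes,
                ).fit(drop_zero_variance=False)
                sub.dropped_factors = dead + sub.dropped_factors
                return sub

        cov = self._cov_params(params)
        beta = params[:p]
        bse = np.sqrt(np.diag(cov)[:p])
        z = beta / bse
        pv = 2 * stats.norm.sf(np.abs(z))
        idx = self.names
        return MixedModelResult(
            family="binomial",
            names=list(idx),
            params=pd.Series(beta, index=idx),
            bse=pd.Series(bse, index=idx),
            stat=pd.Series(z, index=idx),
            pvalues=pd.Series(pv, index=idx),
            df=None,
            vcomp=vcomp,
            sigma2=None,
            loglik=float(-res.fun),
            n=len(self.y),
            converged=bool(res.success),
            cov_params=cov[:p, :p],
            method="AGQ" if len(self.groups) == 1 else "Laplace",
        )

    def _cov_params(self, params: np.ndarray) -> np.ndarray:
        m = len(params)
        H = np.zeros((m, m))
        steps = np.maximum(1e-4 * np.abs(params), 1e-5)
        f0 = self._negll(params)
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m); ei[i] = steps[i]
                ej = np.zeros(m); ej[j] = steps[j]
                if i == j:
                    H[i, i] = (
                        self._negll(params + ei) - 2 * f0 + self._negll(params - ei)
                    ) / steps[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        self._negll(params + ei + ej)
                        - self._negll(params + ei - ej)
                        - self._negll(params - ei + ej)
                        + self._negll(params - ei - ej)
                    ) / (4 * steps[i] * steps[j])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        d = np.diag(cov).copy()
        bad = d <= 0
        if np.any(bad):  # boundary variance params can break positive-definiteness
            cov = np.linalg.pinv(H[: len(params), : len(params)])
        return cov


# ---------------------------------------------------------------------------
# backwards elimination and the signed-rank test


def _components(term: str) -> set:
    return set(term.split(":"))


def backwards_eliminate(build_fit, candidate_terms, stay_p: float = 0.1):
    """Stepwise removal of the weakest fixed term until all retained terms
    have p < stay_p.

    ``build_fit(terms)`` must return a :class:`MixedModelResult` for the model
    containing exactly ``terms`` (plus whatever the caller always includes,
    e.g. the intercept).  Interaction terms are written ``"a:b"`` and are
    removed before the main effects they contain.

    Returns (final_result, elimination_log).
    """
    current = list(candidate_terms)
    log_rows = []
    fit = build_fit(current)
    while current:
        protected = set()
        for t in current:
            if ":" in t:
                protected |= _components(t)
        removable = [
            t
            for t in current
            if t in fit.pvalues.index
            and fit.pvalues[t] >= stay_p
            and t not in protected
        ]
        if not removable:
            break
        worst = max(removable, key=lambda t: fit.pvalues[t])
        log_rows.append({"term": worst, "p": float(fit.pvalues[worst])})
        current.remove(worst)
        fit = build_fit(current)
    return fit, log_rows


def wilcoxon_signed_rank(x, y=None):
    """Signed-rank test with zero differences dropped; tie-corrected normal Z.

    Returns (Z, p).  All-zero differences give exactly (0.0, 1.0).
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    if len(d) == 0:
        raise ValueError("empty input")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        return 0.0, 1.0
    z = (w_pos - mu) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))
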
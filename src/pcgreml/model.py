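"""REML estimation of the GREML linear mixed model.

The model is ``y = X beta + g + e`` with ``g ~ N(0, tau * K)`` for a genomic
relationship matrix ``K`` and ``e ~ N(0, sigma2 * I)``; heritability is
``h2 = tau / (tau + sigma2)``.  The restricted likelihood is the likelihood
of error contrasts, so variance-component estimates are free of the
fixed-effect estimation bias.

Two fitting strategies are provided behind one interface:

* single GRM — eigendecompose ``K`` once, rotate ``y`` and ``X`` into the
  eigenbasis where ``V = tau*K + sigma2*I`` is diagonal, and maximise the
  profile restricted likelihood over the heritability ratio
  ``gamma = tau/(tau+sigma2)`` by bounded scalar optimisation (``sigma2``
  profiles out in closed form).  This is exact and, once the spectrum is
  cached, costs O(n p^2) per likelihood evaluation — which is what makes
  sweeps over hundreds of PC counts and replicate studies cheap.
* several GRMs — average-information (AI) REML on ``(tau_1..tau_C, sigma2)``
  with EM fallback steps whenever an AI update leaves the feasible region.

Standard errors come from the inverse AI matrix at the optimum, matching
the convention of the mainstream GREML software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .genotype import GRM

_LOG2PI = np.log(2.0 * np.pi)
GAMMA_EPS = 1e-8
BOUNDARY_TOL = 1e-6


def _as_eigen(grm_eigen) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(grm_eigen, GRM):
        return grm_eigen.eigen
    vals, vecs = grm_eigen
    return np.asarray(vals, dtype=float), np.asarray(vecs, dtype=float)


def _check_design(X: np.ndarray) -> float:
    """Validate full column rank; return log|X'X|."""
    XtX = X.T @ X
    sign, logdet = np.linalg.slogdet(XtX)
    if sign <= 0 or np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix X is rank deficient (duplicated covariate?)")
    return logdet


def restricted_loglik(y, X, grm_eigen, tau: float, sigma2: float) -> float:
    """Restricted log-likelihood of ``V = tau*K + sigma2*I`` at fixed values.

    Includes the ``+ 0.5 log|X'X|`` normalisation so the value is invariant
    to the choice of error-contrast basis (equivalently, to invertible
    re-parametrisations of the fixed-effect design).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    if tau < 0 or sigma2 < 0 or tau + sigma2 <= 0:
        raise ValueError("need tau, sigma2 >= 0 and not both zero")
    vals, vecs = _as_eigen(grm_eigen)
    logdet_xtx = _check_design(X)
    yt = vecs.T @ y
    Xt = vecs.T @ X
    d = tau * vals + sigma2
    if (d <= 0).any():
        raise ValueError("V is singular for the given (tau, sigma2)")
    n, p = X.shape
    Xd = Xt / d[:, None]
    XtVX = Xt.T @ Xd
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' V^-1 X is singular")
    rhs = Xd.T @ yt
    beta = np.linalg.solve(XtVX, rhs)
    quad = yt @ (yt / d) - rhs @ beta
    return -0.5 * (
        (n - p) * _LOG2PI + np.sum(np.log(d)) + logdet_xvx - logdet_xtx + quad
    )


@dataclass
class VarianceDecomposition:
    """Unbiased split of the phenotypic variance into three shares.

    ``var_fixed_unbiased`` subtracts the estimation-noise inflation
    ``tr(C X Cov(beta) X') / (n-1)`` from the empirical variance of
    ``X beta_hat`` (C is the centering projector), so the covariate share is
    estimated without upward bias.  Shares sum to 1.
    """

    share_fixed: float
    share_genetic: float
    share_residual: float
    var_fixed_unbiased: float
    var_fixed_naive: float
    var_fixed_raw: float  # unbiased value before any clamping at 0
    tau: float
    sigma2: float
    var_total: float
    clamped: bool = False


class GREML:
    """GREML linear mixed model (statsmodels-style model object).

    Parameters
    ----------
    y : array (n,)
        Phenotype vector.
    X : array (n, p)
        Fixed-effect design (include the intercept column explicitly, or use
        :meth:`from_dataframe` / helpers in :mod:`pcgreml.pipeline`).
    grm : GRM or sequence of GRM
        One genomic relationship matrix for the standard model, several for
        the multi-component (e.g. per-chromosome) model.

    ``fit()`` returns a :class:`GREMLResults`.
    """

    def __init__(self, y, X, grm):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("y and X have incompatible shapes")
        if isinstance(grm, GRM):
            self.grms: list[GRM] = [grm]
        else:
            self.grms = list(grm)
        if not self.grms:
            raise ValueError("at least one GRM is required")
        for g in self.grms:
            if g.n != self.y.shape[0]:
                raise ValueError("GRM dimension does not match y")
        n, p = self.X.shape
        if n < p + 2:
            raise ValueError("need n >= p_fixed + 2 observations")
        if np.var(self.y) == 0:
            raise ValueError("phenotype has zero variance")
        self._logdet_xtx = _check_design(self.X)

    @classmethod
    def from_dataframe(cls, data, phenotype: str, grm, covariates=(), pcs=None, n_pcs: int = 0):
        """Build a model from a phenotype/covariate DataFrame.

        ``covariates`` are column names; "sex" is recoded F=1/M=0.  An
        intercept is always prepended; the first ``n_pcs`` columns of
        ``pcs`` are appended as fixed effects.
        """
        y = data[phenotype].to_numpy(dtype=float)
        cols = [np.ones(len(data))]
        for c in covariates:
            col = data[c]
            if c == "sex":
                cols.append((col == "F").astype(float).to_numpy())
            else:
                cols.append(col.to_numpy(dtype=float))
        if n_pcs:
            cols.append(np.asarray(pcs)[:, :n_pcs].T)
        X = np.column_stack([np.atleast_2d(c).reshape(len(data), -1) for c in cols])
        return cls(y, X, grm)

    # -- single-GRM profile machinery ---------------------------------

    def _rotated(self):
        vals, vecs = self.grms[0].eigen
        return vals, vecs.T @ self.y, vecs.T @ self.X

    def _profile(self, gamma: float, vals, yt, Xt):
        """Profile restricted log-likelihood over the scale s = tau+sigma2.

        Returns (loglik, s_hat, beta, XtWX) at the given heritability ratio.
        """
        n, p = Xt.shape
        w = gamma * vals + (1.0 - gamma)
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return -np.inf, 0.0, np.zeros(p), XtWX
        rhs = Xw.T @ yt
        beta = np.linalg.solve(XtWX, rhs)
        quad = yt @ (yt / w) - rhs @ beta
        if quad <= 0:
            return np.inf, 0.0, beta, XtWX  # degenerate: y in span(X)
        s = quad / (n - p)
        ll = -0.5 * (
            (n - p) * (_LOG2PI + 1.0 + np.log(s))
            + np.sum(np.log(w))
            + logdet_xwx
            - self._logdet_xtx
        )
        return ll, s, beta, XtWX

    def _fit_single(self) -> "GREMLResults":
        vals, yt, Xt = self._rotated()
        n, p = Xt.shape

        def nll(g):
            return -self._profile(g, vals, yt, Xt)[0]

        # coarse grid (denser near the boundaries) then bounded refinement
        grid = np.unique(
            np.concatenate(
                [
                    [GAMMA_EPS],
                    np.logspace(-6, -1, 11),
                    np.linspace(0.05, 1.0 - GAMMA_EPS, 40),
                    1.0 - np.logspace(-6, -2, 6),
                ]
            )
        )
        lls = np.array([-nll(g) for g in grid])
        if np.isposinf(lls).any():  # y lies in span(X): no residual variance
            res = GREMLResults(
                model=self,
                variance_components=np.array([0.0, 0.0]),
                beta=np.linalg.lstsq(self.X, self.y, rcond=None)[0],
                beta_cov=np.zeros((p, p)),
                vc_cov=np.zeros((2, 2)),
                llf_restricted=np.nan,
                converged=True,
                boundary=True,
                degenerate=True,
                n_used=n,
                p_fixed=p,
            )
            return res
        best = int(np.nanargmax(lls))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        if hi > lo:
            opt = optimize.minimize_scalar(
                nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
            )
            gamma_hat, ll_hat = opt.x, -opt.fun
            if lls[best] > ll_hat:  # refinement never loses to the grid
                gamma_hat, ll_hat = grid[best], lls[best]
        else:
            gamma_hat, ll_hat = grid[best], lls[best]
        # compare against the boundary gamma = 0 explicitly
        ll0 = self._profile(0.0, vals, yt, Xt)[0]
        if ll0 >= ll_hat:
            gamma_hat, ll_hat = 0.0, ll0

        _, s, beta, XtWX = self._profile(gamma_hat, vals, yt, Xt)
        tau = gamma_hat * s
        sigma2 = (1.0 - gamma_hat) * s
        boundary = gamma_hat < BOUNDARY_TOL
        d = tau * vals + sigma2
        Xd = Xt / d[:, None]
        XtVX = Xt.T @ Xd
        beta_cov = np.linalg.inv(XtVX)

        # AI matrix at the optimum (V_tau = K, V_sigma = I, rotated basis)
        cho = linalg.cho_factor(XtVX)

        def applyP(v):
            return v / d - Xd @ linalg.cho_solve(cho, Xd.T @ v)

        r = applyP(yt)
        t_tau = vals * r
        t_sig = r
        Pt_tau = applyP(t_tau)
        Pt_sig = applyP(t_sig)
        AI = 0.5 * np.array(
            [[t_tau @ Pt_tau, t_tau @ Pt_sig], [t_sig @ Pt_tau, t_sig @ Pt_sig]]
        )
        vc_cov, ai_singular = _invert_ai(AI)

        return GREMLResults(
            model=self,
            variance_components=np.array([tau, sigma2]),
            beta=beta,
            beta_cov=beta_cov,
            vc_cov=vc_cov,
            llf_restricted=ll_hat,
            converged=True,
            boundary=boundary,
            ai_singular=ai_singular,
            n_used=n,
            p_fixed=p,
        )

    # -- multi-GRM AI-REML --------------------------------------------

    def _fit_multi(self, max_iter: int = 200) -> "GREMLResults":
        y, X = self.y, self.X
        n, p = X.shape
        Ks = [g.K for g in self.grms]
        C = len(Ks)
        vy = float(np.var(y, ddof=1))
        theta = np.array([0.5 * vy / C] * C + [0.5 * vy])
        tol = 1e-6 * vy
        floor = 1e-10 * vy
        converged = False
        AI = np.eye(C + 1)

        def build_V(th):
            V = th[C] * np.eye(n)
            for c in range(C):
                V += th[c] * Ks[c]
            return V

        def llf_at(th):
            try:
                cho = linalg.cho_factor(build_V(th))
            except np.linalg.LinAlgError:
                return -np.inf
            ViX = linalg.cho_solve(cho, X)
            Viy = linalg.cho_solve(cho, y)
            XtVX = X.T @ ViX
            sgn, logdet_xvx = np.linalg.slogdet(XtVX)
            if sgn <= 0:
                return -np.inf
            beta_rhs = ViX.T @ y
            quad = y @ Viy - beta_rhs @ np.linalg.solve(XtVX, beta_rhs)
            logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
            return -0.5 * (
                (n - p) * _LOG2PI + logdet_v + logdet_xvx - self._logdet_xtx + quad
            )

        llf_cur = llf_at(theta)
        for it in range(max_iter):
            cho = linalg.cho_factor(build_V(theta))
            Vinv = linalg.cho_solve(cho, np.eye(n))
            VinvX = Vinv @ X
            XtVX = X.T @ VinvX
            cho_x = linalg.cho_factor(XtVX)
            # P v = V^-1 v - V^-1 X (X'V^-1X)^-1 X'V^-1 v
            Py = Vinv @ y - VinvX @ linalg.cho_solve(cho_x, VinvX.T @ y)
            Vps = Ks + [np.eye(n)]
            t = [Va @ Py for Va in Vps]
            Pt = [
                Vinv @ ta - VinvX @ linalg.cho_solve(cho_x, VinvX.T @ ta) for ta in t
            ]
            AI = 0.5 * np.array([[t[a] @ Pt[b] for b in range(C + 1)] for a in range(C + 1)])
            # scores: -0.5 (tr(P V_a) - y'P V_a P y); with symmetric A, B:
            # tr(A B) = sum(A * B), avoiding C+1 dense products
            S = VinvX @ linalg.cho_solve(cho_x, VinvX.T)
            trPV = np.array(
                [np.sum(Vinv * Va) - np.sum(S * Va) for Va in Vps]
            )
            yPVPy = np.array([Py @ ta for ta in t])
            score = -0.5 * (trPV - yPVPy)

            # AI step with likelihood-guarded halving; EM (always uphill,
            # but slow) as the fallback when the AI direction fails —
            # needed because near-collinear GRMs make the AI matrix
            # ill-conditioned and raw Newton-like steps can diverge
            new = None
            llf_new = -np.inf
            if it >= 2:
                try:
                    # active-set: components stuck at the boundary with the
                    # likelihood still decreasing in them stay fixed, the AI
                    # system is solved over the free components only
                    pinned = (theta <= floor * 1.001) & (score < 0)
                    free = ~pinned
                    delta = np.zeros(C + 1)
                    delta[free] = np.linalg.solve(
                        AI[np.ix_(free, free)], score[free]
                    )
                    lam = 1.0
                    while lam >= 1.0 / 1024:
                        cand = np.maximum(theta + lam * delta, floor)
                        llf_cand = llf_at(cand)
                        if llf_cand >= llf_cur - 1e-10:
                            new, llf_new = cand, llf_cand
                            break
                        lam /= 2.0
                except np.linalg.LinAlgError:
                    pass
            if new is None:
                new = np.maximum(theta + theta**2 * (yPVPy - trPV) / n, floor)
                llf_new = llf_at(new)
            if np.abs(new - theta).max() < tol:
                theta = new
                converged = True
                break
            theta, llf_cur = new, llf_new
        theta = np.maximum(theta, 0.0)

        # final quantities at the estimate
        V = theta[C] * np.eye(n)
        for c in range(C):
            V += theta[c] * Ks[c]
        cho = linalg.cho_factor(V)
        Vinv = linalg.cho_solve(cho, np.eye(n))
        VinvX = Vinv @ X
        XtVX = X.T @ VinvX
        beta_cov = np.linalg.inv(XtVX)
        beta = beta_cov @ (VinvX.T @ y)
        quad = y @ (Vinv @ y) - (VinvX.T @ y) @ beta
        sign, logdet_v = np.linalg.slogdet(V)
        sign_x, logdet_xvx = np.linalg.slogdet(XtVX)
        llf = -0.5 * (
            (n - p) * _LOG2PI + logdet_v + logdet_xvx - self._logdet_xtx + quad
        )
        vc_cov, ai_singular = _invert_ai(AI)
        return GREMLResults(
            model=self,
            variance_components=theta,
            beta=beta,
            beta_cov=beta_cov,
            vc_cov=vc_cov,
            llf_restricted=llf,
            converged=converged,
            boundary=bool((theta[:-1] < BOUNDARY_TOL * vy).any()),
            ai_singular=ai_singular,
            n_used=n,
            p_fixed=p,
        )

    def fit(self) -> "GREMLResults":
        """Maximise the restricted likelihood; returns a results object."""
        if len(self.grms) == 1:
            return self._fit_single()
        return self._fit_multi()

    def loglike_restricted(self, tau, sigma2) -> float:
        """Restricted log-likelihood at given components (single-GRM model)."""
        if len(self.grms) != 1:
            raise ValueError("pointwise likelihood only for the single-GRM model")
        return restricted_loglik(self.y, self.X, self.grms[0], tau, sigma2)


def _invert_ai(AI: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert the average-information matrix, flagging near-singularity."""
    singular = not np.isfinite(AI).all() or np.linalg.cond(AI) > 1e10
    if singular:
        cov = np.linalg.pinv(AI, hermitian=True)
    else:
        cov = np.linalg.inv(AI)
    return cov, singular


@dataclass
class GREMLResults:
    """REML estimates with uncertainties and diagnostics.

    ``variance_components`` is ``[tau_1, ..., tau_C, sigma2]``; for the
    single-GRM model it is simply ``[tau, sigma2]``.  ``vc_cov`` is the
    inverse average-information matrix in the same ordering.
    """

    model: GREML
    variance_components: np.ndarray
    beta: np.ndarray
    beta_cov: np.ndarray
    vc_cov: np.ndarray
    llf_restricted: float
    converged: bool
    boundary: bool
    n_used: int
    p_fixed: int
    degenerate: bool = False
    ai_singular: bool = False

    @property
    def taus(self) -> np.ndarray:
        return self.variance_components[:-1]

    @property
    def tau(self) -> float:
        return float(self.taus.sum())

    @property
    def sigma2(self) -> float:
        return float(self.variance_components[-1])

    @property
    def h2(self) -> float:
        tot = self.tau + self.sigma2
        if tot == 0:
            raise ZeroDivisionError("tau + sigma2 is zero; heritability undefined")
        return self.tau / tot

    @property
    def h2_se(self) -> float:
        return heritability_with_se(self)[1]

    @property
    def vc_se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vc_cov), 0.0, None))

    @property
    def total_variance(self) -> float:
        """tau + sigma2 (the covariate share is reported separately)."""
        return self.tau + self.sigma2

    @property
    def total_variance_se(self) -> float:
        return float(np.sqrt(max(self.vc_cov.sum(), 0.0)))

    def decompose(self) -> VarianceDecomposition:
        return decompose_variance(self, self.model.X)

    def summary(self) -> str:
        lines = ["GREML variance components (REML)"]
        lines.append(f"  n = {self.n_used}, fixed effects = {self.p_fixed}, "
                     f"GRMs = {len(self.model.grms)}")
        se = self.vc_se
        for c, t in enumerate(self.taus):
            lines.append(f"  tau_{c + 1}    = {t:.6g} (se {se[c]:.3g})")
        lines.append(f"  sigma2   = {self.sigma2:.6g} (se {se[-1]:.3g})")
        try:
            h2, h2se = heritability_with_se(self)
            lines.append(f"  h2       = {h2:.4f} (se {h2se:.4f})")
        except ZeroDivisionError:
            lines.append("  h2       = undefined (zero total variance)")
        lines.append(f"  restricted loglik = {self.llf_restricted:.6f}")
        flags = [
            name
            for name, val in [
                ("converged", self.converged),
                ("boundary", self.boundary),
                ("degenerate", self.degenerate),
                ("AI-singular", self.ai_singular),
            ]
            if val
        ]
        lines.append("  flags: " + (", ".join(flags) if flags else "none"))
        return "\n".join(lines)


# -- module-level operation surface -----------------------------------


def fit_reml_single(y, X, grm: GRM) -> GREMLResults:
    """Fit the single-GRM model by profile-likelihood REML."""
    return GREML(y, X, grm).fit()


def fit_reml_multi(y, X, grms) -> GREMLResults:
    """Fit the multi-GRM model by AI-REML with EM fallback."""
    grms = [grms] if isinstance(grms, GRM) else list(grms)
    if len(grms) == 1:
        return GREML(y, X, grms[0]).fit()
    return GREML(y, X, grms).fit()


def heritability_with_se(fit: GREMLResults) -> tuple[float, float]:
    """``h2 = tau/(tau+sigma2)`` with a delta-method standard error.

    For the multi-GRM model tau is the sum of the genetic components and the
    gradient is taken over all components.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; heritability unreliable")
    tau, sigma2 = fit.tau, fit.sigma2
    tot = tau + sigma2
    if tot == 0:
        raise ZeroDivisionError("tau + sigma2 is zero")
    C = fit.taus.size
    grad = np.empty(C + 1)
    grad[:C] = sigma2 / tot**2
    grad[C] = -tau / tot**2
    var = float(grad @ fit.vc_cov @ grad)
    return tau / tot, float(np.sqrt(max(var, 0.0)))


def decompose_variance(fit: GREMLResults, X=None, grm=None) -> VarianceDecomposition:
    """Three-way split of the phenotypic variance, covariate share unbiased.

    The naive estimator — the empirical variance of the fitted fixed part
    ``X beta_hat`` — is inflated by the sampling noise of ``beta_hat``; its
    expectation exceeds the true centered variance of ``X beta`` by
    ``tr(C X Cov(beta_hat) X') / (n-1)``.  Subtracting that trace gives the
    unbiased estimate used here.  A negative corrected value (possible with
    many covariates) is clamped to 0 with a warning.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    X = fit.model.X if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    xb = X @ fit.beta
    xb_c = xb - xb.mean()
    naive = float(xb_c @ xb_c) / (n - 1)
    Xc = X - X.mean(axis=0)
    correction = float(np.sum(fit.beta_cov * (Xc.T @ Xc))) / (n - 1)
    var_fixed = naive - correction
    raw = var_fixed
    clamped = False
    if var_fixed < 0:
        warnings.warn(
            f"unbiased covariate variance {var_fixed:.3g} < 0; clamped to 0",
            stacklevel=2,
        )
        var_fixed = 0.0
        clamped = True
    tau, sigma2 = fit.tau, fit.sigma2
    var_total = var_fixed + tau + sigma2
    if var_total <= 0:
        raise ValueError("total variance is not positive")
    return VarianceDecomposition(
        share_fixed=var_fixed / var_total,
        share_genetic=tau / var_total,
        share_residual=sigma2 / var_total,
        var_fixed_unbiased=var_fixed,
        var_fixed_naive=naive,
        var_fixed_raw=raw,
        tau=tau,
        sigma2=sigma2,
        var_total=var_total,
        clamped=clamped,
    )
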
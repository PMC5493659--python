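"""Variance-component estimation on a genomic relationship matrix.

Heritability (h2) and the genetic correlation (r_g) between two traits are
estimated under the standard bivariate linear mixed model

    [y1; y2] ~ N(Xb,  Vg (x) G  +  Ve (x) I)

where G is the genomic relationship matrix (GRM), Vg the 2x2 genetic
(co)variance matrix and Ve a diagonal residual covariance (the two traits'
residuals are modelled as independent; each trait has its own intercept as
the only fixed effect).  h2_k = Vg_kk / (Vg_kk + Ve_kk) and
r_g = Vg_12 / sqrt(Vg_11 Vg_22).

Because both random terms share the single GRM, a one-off eigendecomposition
G = U D U' rotates the model into n independent 2x2 blocks, making every
restricted-likelihood quantity O(n).  The restricted likelihood is maximised
by average-information (AI) updates with step-halving from a moment-based
start; if the AI path stalls, a derivative-free simplex search on the exact
restricted likelihood (in an unconstrained parameterisation) finishes the
job.  Variance components are floored at 1e-8 and convergence is declared
when the restricted log-likelihood changes by less than 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["BivariateEstimate", "reml_bivariate", "reml_univariate"]

VAR_FLOOR = 1e-8


@dataclass
class BivariateEstimate:
    """REML estimates for a trait pair."""

    h2_1: float
    h2_2: float
    r_g: float
    se_h2_1: float
    se_h2_2: float
    se_r_g: float
    converged: bool
    loglik: float
    vg: np.ndarray  # 2x2 genetic covariance
    ve: np.ndarray  # 2x2 diagonal residual covariance


class _BivariateREML:
    """Restricted likelihood of the rotated bivariate model.

    Parameters are theta = (g11, g22, g12, e11, e22).
    """

    def __init__(self, y1: np.ndarray, y2: np.ndarray, grm: np.ndarray):
        n = len(y1)
        d, U = np.linalg.eigh(grm)
        self.d = np.maximum(d, 0.0)
        self.t1 = U.T @ y1
        self.t2 = U.T @ y2
        self.u = U.T @ np.ones(n)
        self.n = n

    # -- restricted log-likelihood (up to a constant) -----------------------
    def loglik(self, theta: np.ndarray) -> float:
        out = self._blocks(theta)
        if out is None:
            return -np.inf
        return out["ll"]

    def _blocks(self, theta: np.ndarray):
        g11, g22, g12, e11, e22 = theta
        d = self.d
        a = g11 * d + e11
        b = g12 * d
        c = g22 * d + e22
        det = a * c - b * b
        if np.any(det <= 0) or np.any(a <= 0):
            return None
        ia, ib, ic = c / det, -b / det, a / det
        u, t1, t2 = self.u, self.t1, self.t2
        C = np.array(
            [
                [np.sum(u * u * ia), np.sum(u * u * ib)],
                [np.sum(u * u * ib), np.sum(u * u * ic)],
            ]
        )
        rhs = np.array(
            [np.sum(u * (ia * t1 + ib * t2)), np.sum(u * (ib * t1 + ic * t2))]
        )
        sign_c, logdet_c = np.linalg.slogdet(C)
        if sign_c <= 0:
            return None
        beta = np.linalg.solve(C, rhs)
        r1 = t1 - u * beta[0]
        r2 = t2 - u * beta[1]
        p1 = ia * r1 + ib * r2
        p2 = ib * r1 + ic * r2
        ypy = float(r1 @ p1 + r2 @ p2)
        ll = -0.5 * (float(np.sum(np.log(det))) + logdet_c + ypy)
        return dict(ia=ia, ib=ib, ic=ic, C=C, p1=p1, p2=p2, ll=ll)

    # -- score vector and average-information matrix ------------------------
    def score_ai(self, theta: np.ndarray):
        blk = self._blocks(theta)
        if blk is None:
            return None
        ia, ib, ic = blk["ia"], blk["ib"], blk["ic"]
        p1, p2, C = blk["p1"], blk["p2"], blk["C"]
        d, u = self.d, self.u
        Cinv = np.linalg.inv(C)
        one = np.ones_like(d)

        # A_k Py in block form: (v1, v2) per component k
        Av = [
            (d * p1, np.zeros_like(p1)),  # g11
            (np.zeros_like(p1), d * p2),  # g22
            (d * p2, d * p1),             # g12
            (p1, np.zeros_like(p1)),      # e11
            (np.zeros_like(p1), p2),      # e22
        ]

        def P_apply(v1, v2):
            w1 = ia * v1 + ib * v2
            w2 = ib * v1 + ic * v2
            xv = np.array([np.sum(u * w1), np.sum(u * w2)])
            gam = Cinv @ xv
            w1 -= u * (ia * gam[0] + ib * gam[1])
            w2 -= u * (ib * gam[0] + ic * gam[1])
            return w1, w2

        PAv = [P_apply(v1, v2) for v1, v2 in Av]

        # tr(P A_k) = tr(V^-1 A_k) - tr(C^-1 X'V^-1 A_k V^-1 X)
        u2 = u * u

        def S(m11, m12, m22):
            return np.array(
                [[np.sum(u2 * m11), np.sum(u2 * m12)],
                 [np.sum(u2 * m12), np.sum(u2 * m22)]]
            )

        weights = [d, d, d, one, one]
        tr_vinv = [
            np.sum(d * ia),
            np.sum(d * ic),
            2 * np.sum(d * ib),
            np.sum(ia),
            np.sum(ic),
        ]
        S_mats = [
            S(d * ia * ia, d * ia * ib, d * ib * ib),
            S(d * ib * ib, d * ib * ic, d * ic * ic),
            S(2 * d * ia * ib, d * (ia * ic + ib * ib), 2 * d * ib * ic),
            S(ia * ia, ia * ib, ib * ib),
            S(ib * ib, ib * ic, ic * ic),
        ]
        tr_pa = [tv - float(np.trace(Cinv @ s)) for tv, s in zip(tr_vinv, S_mats)]

        ypapy = [
            float(np.sum(d * p1 * p1)),
            float(np.sum(d * p2 * p2)),
            2 * float(np.sum(d * p1 * p2)),
            float(np.sum(p1 * p1)),
            float(np.sum(p2 * p2)),
        ]
        score = np.array([-0.5 * (t - q) for t, q in zip(tr_pa, ypapy)])

        k = len(Av)
        AI = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * (
                    float(Av[i][0] @ PAv[j][0]) + float(Av[i][1] @ PAv[j][1])
                )
        return score, AI, blk["ll"]


def _clip_theta(theta: np.ndarray) -> np.ndarray:
    g11, g22, g12, e11, e22 = theta
    g11 = max(g11, VAR_FLOOR)
    g22 = max(g22, VAR_FLOOR)
    e11 = max(e11, VAR_FLOOR)
    e22 = max(e22, VAR_FLOOR)
    bound = 0.99999 * np.sqrt(g11 * g22)
    g12 = np.clip(g12, -bound, bound)
    return np.array([g11, g22, g12, e11, e22])


def reml_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    grm: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> BivariateEstimate:
    """Bivariate GRM-based REML.

    Traits are standardized internally, so the returned (co)variance
    components are on the correlation scale; h2 and r_g are scale-free
    anyway.  h2 estimates are clipped to [0, 1] and |r_g| to 1 at the
    boundary.  ``converged`` is False if neither the AI iteration nor the
    fallback simplex search reached the likelihood tolerance.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    grm = np.asarray(grm, dtype=float)
    n = len(y1)
    if len(y2) != n or grm.shape != (n, n):
        raise ValueError("y1, y2 and grm dimensions disagree")
    if y1.std() == 0 or y2.std() == 0:
        raise ValueError("zero-variance trait")
    y1 = (y1 - y1.mean()) / y1.std()
    y2 = (y2 - y2.mean()) / y2.std()

    model = _BivariateREML(y1, y2, grm)
    rp = float(np.corrcoef(y1, y2)[0, 1])
    theta = _clip_theta(np.array([0.5, 0.5, 0.5 * rp, 0.5, 0.5]))

    ll_old = model.loglik(theta)
    converged = False
    for _ in range(max_iter):
        out = model.score_ai(theta)
        if out is None:
            break
        score, AI, ll_here = out
        try:
            delta = np.linalg.solve(AI + 1e-8 * np.eye(5), score)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        accepted = False
        for _ in range(30):
            cand = _clip_theta(theta + step * delta)
            ll_new = model.loglik(cand)
            if np.isfinite(ll_new) and ll_new >= ll_here - 1e-12:
                theta, accepted = cand, True
                break
            step *= 0.5
        if not accepted:
            break
        if abs(ll_new - ll_old) < tol:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new

    if not converged:
        # simplex search on an unconstrained parameterisation
        def unpack(z):
            g11, g22 = np.exp(z[0]), np.exp(z[1])
            g12 = np.tanh(z[2]) * np.sqrt(g11 * g22)
            return _clip_theta(np.array([g11, g22, g12, np.exp(z[3]), np.exp(z[4])]))

        def neg(z):
            ll = model.loglik(unpack(z))
            return -ll if np.isfinite(ll) else 1e12

        z0 = np.array(
            [
                np.log(theta[0]),
                np.log(theta[1]),
                np.arctanh(
                    np.clip(theta[2] / np.sqrt(theta[0] * theta[1]), -0.999, 0.999)
                ),
                np.log(theta[3]),
                np.log(theta[4]),
            ]
        )
        res = optimize.minimize(
            neg, z0, method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": tol, "xatol": 1e-8},
        )
        cand = unpack(res.x)
        if model.loglik(cand) >= ll_old:
            theta = cand
            ll_old = model.loglik(cand)
            converged = bool(res.success)

    g11, g22, g12, e11, e22 = theta
    h2_1 = float(np.clip(g11 / (g11 + e11), 0.0, 1.0))
    h2_2 = float(np.clip(g22 / (g22 + e22), 0.0, 1.0))
    r_g = float(np.clip(g12 / np.sqrt(g11 * g22), -1.0, 1.0))

    # delta-method standard errors from the inverse average information
    se = np.full(3, np.nan)
    out = model.score_ai(theta)
    if out is not None:
        _, AI, _ = out
        try:
            cov = np.linalg.inv(AI + 1e-8 * np.eye(5))
            j_h1 = np.array(
                [e11 / (g11 + e11) ** 2, 0, 0, -g11 / (g11 + e11) ** 2, 0]
            )
            j_h2 = np.array(
                [0, e22 / (g22 + e22) ** 2, 0, 0, -g22 / (g22 + e22) ** 2]
            )
            j_rg = np.array(
                [
                    -r_g / (2 * g11),
                    -r_g / (2 * g22),
                    1.0 / np.sqrt(g11 * g22),
                    0,
                    0,
                ]
            )
            se = np.sqrt(
                np.maximum(
                    [j @ cov @ j for j in (j_h1, j_h2, j_rg)], 0.0
                )
            )
        except np.linalg.LinAlgError:
            pass

    return BivariateEstimate(
        h2_1, h2_2, r_g, float(se[0]), float(se[1]), float(se[2]),
        converged, float(ll_old),
        vg=np.array([[g11, g12], [g12, g22]]),
        ve=np.diag([e11, e22]),
    )


def reml_univariate(y: np.ndarray, grm: np.ndarray, tol: float = 1e-8):
    """Single-trait GRM REML; returns (h2, loglik).

    Same rotated-model likelihood as the bivariate case with 1x1 blocks,
    maximised over (log sigma_g^2, log sigma_e^2).
    """
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise ValueError("zero-variance trait")
    y = (y - y.mean()) / y.std()
    n = len(y)
    d, U = np.linalg.eigh(np.asarray(grm, dtype=float))
    d = np.maximum(d, 0.0)
    t = U.T @ y
    u = U.T @ np.ones(n)

    def negll(z):
        g, e = np.exp(z)
        m = g * d + e
        if np.any(m <= 0):
            return 1e12
        im = 1.0 / m
        C = np.sum(u * u * im)
        beta = np.sum(u * t * im) / C
        r = t - u * beta
        return 0.5 * (np.sum(np.log(m)) + np.log(C) + np.sum(r * r * im))

    res = optimize.minimize(
        negll, np.log([0.5, 0.5]), method="Nelder-Mead",
        options={"fatol": tol, "xatol": 1e-10, "maxiter": 2000},
    )
    g, e = np.exp(res.x)
    return float(np.clip(g / (g + e), 0.0, 1.0)), -float(res.fun)
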
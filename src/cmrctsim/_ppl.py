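"""Breslow partial-likelihood engine for (penalised) Cox models.

Everything here works on a time-sorted view of the data.  Risk sets are
suffixes of the sorted arrays, so every risk-set sum is a suffix sum over
"segments" delimited by the distinct event times: per-segment totals come
from one ``bincount`` pass over the subjects and the suffix accumulation is
a cumulative sum over the (few) event boundaries.  Cluster frailty terms use
the same trick on a combined segment-x-cluster index, which keeps the cost
of a Newton iteration at O(N (p + 1)) regardless of the number of clusters.

Ties are handled with the Breslow approximation throughout (event times are
continuous in this simulator, so ties have measure zero anyway).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln


class FitError(RuntimeError):
    """Raised when a Cox fit is impossible (e.g. no events)."""


def _rcumsum(a: np.ndarray) -> np.ndarray:
    """Reverse (suffix) cumulative sum along axis 0."""
    return np.cumsum(a[::-1], axis=0)[::-1]


class SurvSorted:
    """Censored survival data sorted by time, with event-boundary indexing.

    Parameters
    ----------
    y : observed times.
    event : 1 when the event of interest was observed (NOT the censoring
        indicator).
    X : covariate matrix, shape (N, p); p may be 0.
    cluster : optional integer cluster labels (frailty / sandwich unit).
    """

    def __init__(self, y, event, X, cluster=None):
        y = np.asarray(y, dtype=float)
        d = np.asarray(event).astype(bool)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.shape[0]:
            X = X.T
        n = y.shape[0]
        order = np.argsort(y, kind="stable")
        self.n = n
        self.y = y[order]
        self.d = d[order]
        self.X = X[order] if X.size else np.empty((n, 0))
        self.p = self.X.shape[1]
        if cluster is not None:
            g = np.asarray(cluster)[order]
            codes, self.g = np.unique(g, return_inverse=True)
            self.K = len(codes)
            self.cluster_codes = codes
        else:
            self.g = None
            self.K = 0
            self.cluster_codes = None
        # first/last index of each tie group, per row
        self.first = np.searchsorted(self.y, self.y, side="left")
        self.last = np.searchsorted(self.y, self.y, side="right")
        self.ev = np.flatnonzero(self.d)
        self.ev_first = self.first[self.ev]
        self.n_events = int(self.d.sum())
        # distinct event boundaries; row i belongs to segment seg[i] = number
        # of boundaries at or before i, so the risk set of boundary e is
        # exactly the rows with seg >= e + 1
        self.B = np.unique(self.ev_first)
        self.nB = len(self.B)
        self.seg = np.searchsorted(self.B, np.arange(n), side="right")
        self.ev_bidx = np.searchsorted(self.B, self.ev_first)
        if self.K:
            self.D_k = np.bincount(self.g[self.ev], minlength=self.K).astype(float)
            self._segg = self.seg * self.K + self.g

    def suffix(self, v: np.ndarray) -> np.ndarray:
        """Risk-set sums of a subject-level vector at each event boundary."""
        t = np.bincount(self.seg, weights=v, minlength=self.nB + 1)
        c = np.cumsum(t)
        return c[-1] - c[:-1]

    def suffix_by_cluster(self, v: np.ndarray) -> np.ndarray:
        """Per-cluster risk-set sums at each boundary, shape (nB, K)."""
        t = np.bincount(self._segg, weights=v, minlength=(self.nB + 1) * self.K)
        c = np.cumsum(t.reshape(self.nB + 1, self.K), axis=0)
        return c[-1][None, :] - c[:-1]


def _loglik_only(sd: SurvSorted, eta: np.ndarray) -> float:
    w = np.exp(eta)
    S0 = sd.suffix(w)[sd.ev_bidx]
    return float(eta[sd.ev].sum() - np.log(S0).sum())


def _ngh(sd: SurvSorted, beta: np.ndarray, b: np.ndarray | None):
    """Breslow log-likelihood, gradient and information.

    Over the m = p (+ K when ``b`` is given) combined coefficients; the
    frailty block exploits that indicator-column products vanish between
    clusters, so its S2 diagonal equals its S1.
    """
    p, K = sd.p, (sd.K if b is not None else 0)
    eta = sd.X @ beta if p else np.zeros(sd.n)
    if K:
        eta = eta + b[sd.g]
    w = np.exp(eta)

    S0 = sd.suffix(w)[sd.ev_bidx]
    inv0 = 1.0 / S0
    loglik = float(eta[sd.ev].sum() - np.log(S0).sum())

    m = p + K
    E = len(sd.ev)
    abar = np.empty((E, m))
    grad = np.empty(m)
    info = np.empty((m, m))

    for j in range(p):
        abar[:, j] = sd.suffix(w * sd.X[:, j])[sd.ev_bidx] * inv0
    if K:
        abar[:, p:] = sd.suffix_by_cluster(w)[sd.ev_bidx] * inv0[:, None]

    if p:
        grad[:p] = sd.X[sd.ev].sum(axis=0) - abar[:, :p].sum(axis=0)
    if K:
        grad[p:] = sd.D_k - abar[:, p:].sum(axis=0)

    info[:] = -abar.T @ abar
    for j in range(p):
        for l in range(j, p):
            v = float((sd.suffix(w * sd.X[:, j] * sd.X[:, l])[sd.ev_bidx] * inv0).sum())
            info[j, l] += v
            if l != j:
                info[l, j] += v
    if K:
        # S2 frailty diagonal equals S1 (indicators are idempotent)
        info[p:, p:][np.diag_indices(K)] += abar[:, p:].sum(axis=0)
        for j in range(p):
            v = (sd.suffix_by_cluster(w * sd.X[:, j])[sd.ev_bidx] * inv0[:, None]).sum(axis=0)
            info[j, p:] += v
            info[p:, j] += v
    return loglik, grad, info


def _penalty(kind: str, b: np.ndarray, theta: float):
    """Penalty value, gradient and Hessian-diagonal for the frailty terms.

    'gaussian': normal random intercepts, -b^2/(2 theta).
    'gamma'   : Therneau's penalty (b - e^b)/theta + const, whose maximiser
                coincides with the EM solution for gamma(mean 1, var theta)
                multiplicative frailties.
    """
    if kind == "gaussian":
        return (
            -0.5 * float(b @ b) / theta,
            -b / theta,
            np.full(b.shape, 1.0 / theta),
        )
    if kind == "gamma":
        eb = np.exp(b)
        nu = 1.0 / theta
        return (
            nu * float((b - eb).sum()),
            nu * (1.0 - eb),
            nu * eb,
        )
    raise ValueError(kind)


def newton_cox(
    sd: SurvSorted,
    penalty: str | None = None,
    theta: float = 0.0,
    beta0: np.ndarray | None = None,
    b0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 50,
):
    """Maximise the (penalised) Breslow partial likelihood by Newton-Raphson.

    Returns (beta, b, loglik_penalised, cov, info_penalised, converged,
    n_iter); ``cov`` is the inverse penalised information over (beta, b).
    """
    if sd.n_events == 0:
        raise FitError("no observed events")
    p, K = sd.p, sd.K
    use_frailty = penalty is not None and K > 0
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    if use_frailty:
        b = np.zeros(K) if b0 is None else np.asarray(b0, dtype=float).copy()
    else:
        b = np.zeros(0)

    def objective(beta_, b_):
        eta = sd.X @ beta_ if p else np.zeros(sd.n)
        if use_frailty:
            eta = eta + b_[sd.g]
        ll = _loglik_only(sd, eta)
        if use_frailty:
            ll += _penalty(penalty, b_, theta)[0]
        return ll

    def eval_ngh(beta_, b_):
        if use_frailty:
            ll, grad, info = _ngh(sd, beta_, b_)
            pen_ll, pen_g, pen_h = _penalty(penalty, b_, theta)
            ll += pen_ll
            grad[p:] += pen_g
            info[p:, p:][np.diag_indices(K)] += pen_h
        else:
            ll, grad, info = _ngh(sd, beta_, None)
        return ll, grad, info

    ll_old = None
    converged = False
    it = 0
    ll_pen = np.nan
    info_pen = None
    for it in range(1, max_iter + 1):
        ll, grad, info = eval_ngh(beta, b)
        ll_pen, info_pen = ll, info
        # stop on vanishing score (or stalled objective): the quantities at
        # the current point then serve directly as the final ones
        if np.abs(grad).max() < 1e-6 or (
            ll_old is not None and abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0)
        ):
            converged = True
            break
        ll_old = ll
        try:
            cf = cho_factor(info)
            step = cho_solve(cf, grad)
        except np.linalg.LinAlgError:
            info = info + np.eye(info.shape[0]) * (1e-8 + 1e-8 * np.abs(np.diag(info)).max())
            cf = cho_factor(info)
            step = cho_solve(cf, grad)
        scale = 1.0
        for _ in range(20):  # step-halving against divergence
            beta_new = beta + scale * step[:p]
            b_new = b + scale * step[p:] if use_frailty else b
            ll_new = objective(beta_new, b_new)
            if np.isfinite(ll_new) and (ll_new >= ll - 1e-12):
                break
            scale *= 0.5
        beta, b = beta_new, b_new
    else:
        ll_pen, grad, info_pen = eval_ngh(beta, b)
    try:
        cov = np.linalg.inv(info_pen)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info_pen)
    return beta, b, ll_pen, cov, info_pen, converged, it


def score_residuals(sd: SurvSorted, beta: np.ndarray) -> np.ndarray:
    """Per-subject score residuals of a plain Cox fit (sorted order).

    U_i = d_i (x_i - xbar(y_i)) - w_i [x_i G(y_i) - Gx(y_i)] with
    G(t) = sum_{events <= t} 1/S0 and Gx(t) = sum_{events <= t} xbar/S0.
    Summed within clusters these give the meat of the cluster-grouped
    sandwich variance.
    """
    p = sd.p
    eta = sd.X @ beta if p else np.zeros(sd.n)
    w = np.exp(eta)
    S0_rows = _rcumsum(w)
    S1_rows = _rcumsum(w[:, None] * sd.X)
    S0 = S0_rows[sd.ev_first]
    xbar_ev = S1_rows[sd.ev_first] / S0[:, None]

    incr0 = np.zeros(sd.n)
    incr0[sd.ev] = 1.0 / S0
    incrX = np.zeros((sd.n, p))
    incrX[sd.ev] = xbar_ev / S0[:, None]
    G = np.cumsum(incr0)[sd.last - 1]
    Gx = np.cumsum(incrX, axis=0)[sd.last - 1]

    U = -w[:, None] * (sd.X * G[:, None] - Gx)
    U[sd.ev] += sd.X[sd.ev] - xbar_ev
    return U


def robust_cov(sd: SurvSorted, beta: np.ndarray, info: np.ndarray) -> np.ndarray:
    """Cluster-grouped sandwich covariance A^{-1} B A^{-1}."""
    U = score_residuals(sd, beta)
    if sd.K:
        Ucl = np.zeros((sd.K, sd.p))
        np.add.at(Ucl, sd.g, U)
    else:
        Ucl = U
    Ainv = np.linalg.inv(info)
    return Ainv @ (Ucl.T @ Ucl) @ Ainv


def fit_lognormal(sd: SurvSorted, theta: float | None = None, theta0: float = 0.1,
                  outer_tol: float = 1e-4, max_outer: int = 50):
    """Penalised Cox with normal cluster random intercepts.

    With ``theta`` fixed this is a single penalised Newton solve.  Otherwise
    the variance is profiled by the Laplace/REML-type fixed point
    ``theta = (b'b + tr(V_bb)) / K`` (V the inverse penalised information),
    with Aitken extrapolation to accelerate the linearly convergent
    iteration.  Collapse to theta ~ 0 returns a plain Cox fit, variance 0.
    """
    if theta is not None:
        if theta <= 0:
            beta, b, ll, cov, info, conv, _ = newton_cox(sd)
            return beta, np.zeros(sd.K), 0.0, ll, cov, conv
        beta, b, ll, cov, info, conv, _ = newton_cox(sd, "gaussian", theta)
        return beta, b, theta, ll, cov, conv
    theta_c = theta0
    beta0 = b0 = None
    conv_outer = False
    hist: list[float] = []
    p = sd.p
    beta = b = cov = None
    ll = np.nan
    for _ in range(max_outer):
        beta, b, ll, cov, info, conv, _ = newton_cox(
            sd, "gaussian", theta_c, beta0=beta0, b0=b0
        )
        theta_new = (float(b @ b) + float(np.trace(cov[p:, p:]))) / sd.K
        if theta_new < 1e-5:
            theta_c = 0.0
            break
        if abs(theta_new - theta_c) <= outer_tol * (theta_c + 1e-3):
            theta_c = theta_new
            conv_outer = conv
            break
        hist.append(theta_new)
        # Aitken delta-squared acceleration on the fixed-point sequence
        if len(hist) >= 3:
            t0_, t1_, t2_ = hist[-3:]
            denom = t2_ - 2.0 * t1_ + t0_
            if abs(denom) > 1e-12:
                acc = t0_ - (t1_ - t0_) ** 2 / denom
                if acc > 0 and abs(acc - t2_) < max(t2_, 0.01):
                    theta_new = acc
                    hist.clear()
        theta_c = theta_new
        beta0, b0 = beta, b
    if theta_c == 0.0:
        beta, b, ll, cov, info, conv, _ = newton_cox(sd)
        return beta, np.zeros(sd.K), 0.0, ll, cov, conv
    return beta, b, theta_c, ll, cov, conv_outer


def _gamma_profile_ll(sd: SurvSorted, beta: np.ndarray, b: np.ndarray, theta: float) -> float:
    """Observed-data log-likelihood for gamma frailty, baseline profiled out.

    Klein's EM profile: with the Breslow baseline computed from the current
    (beta, b), integrate the gamma(1/theta, 1/theta) frailties analytically.
    """
    p = sd.p
    eta_x = sd.X @ beta if p else np.zeros(sd.n)
    w = np.exp(eta_x + b[sd.g])
    S0 = sd.suffix(w)[sd.ev_bidx]
    incr = np.zeros(sd.n)
    incr[sd.ev] = 1.0 / S0
    Lam0 = np.cumsum(incr)[sd.last - 1]  # baseline cumulative hazard at each y_i
    A_k = np.bincount(sd.g, weights=Lam0 * np.exp(eta_x), minlength=sd.K)
    nu = 1.0 / theta
    ll = float(
        (nu * np.log(nu) - gammaln(nu)) * sd.K
        + gammaln(nu + sd.D_k).sum()
        - ((nu + sd.D_k) * np.log(nu + A_k)).sum()
    )
    ll += float(eta_x[sd.ev].sum() - np.log(S0).sum())
    return ll


def fit_gamma(sd: SurvSorted, theta: float | None = None,
              bounds: tuple[float, float] = (1e-4, 4.0)):
    """Penalised Cox with multiplicative gamma(mean 1, var theta) frailties.

    The inner problem at fixed theta is the penalised Newton solve whose
    stationary point equals the EM estimate; theta itself is chosen by golden
    section on the EM profile (observed-data) likelihood.  If the profile
    prefers the boundary near zero the fit collapses to plain Cox.
    """
    if theta is not None:
        if theta <= 0:
            beta, b, ll, cov, info, conv, _ = newton_cox(sd)
            return beta, np.zeros(sd.K), 0.0, ll, cov, conv
        beta, b, ll, cov, info, conv, _ = newton_cox(sd, "gamma", theta)
        return beta, b, theta, ll, cov, conv
    cache: dict[float, tuple] = {}
    warm = {"beta": None, "b": None}

    def prof(log_t: float) -> float:
        t = float(np.exp(log_t))
        beta, b, ll, cov, info, conv, _ = newton_cox(
            sd, "gamma", t, beta0=warm["beta"], b0=warm["b"]
        )
        warm["beta"], warm["b"] = beta, b
        cache[t] = (beta, b, ll, cov, conv)
        return _gamma_profile_ll(sd, beta, b, t)

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, d = lo, hi
    c_, b_ = d - invphi * (d - a), a + invphi * (d - a)
    fc, fb = prof(c_), prof(b_)
    for _ in range(40):
        if fc >= fb:
            d, b_, fb = b_, c_, fc
            c_ = d - invphi * (d - a)
            fc = prof(c_)
        else:
            a, c_, fc = c_, b_, fb
            b_ = a + invphi * (d - a)
            fb = prof(b_)
        if d - a < 1e-3:
            break
    theta_hat = float(np.exp((a + d) / 2.0))
    best = prof(np.log(theta_hat))
    if theta_hat <= bounds[0] * 1.5 or best <= _null_gamma_profile(sd) + 1e-8:
        beta, b, ll, cov, info, conv, _ = newton_cox(sd)
        return beta, np.zeros(sd.K), 0.0, ll, cov, conv
    beta, b, ll, cov, conv = cache[min(cache, key=lambda t: abs(t - theta_hat))]
    return beta, b, theta_hat, ll, cov, conv


def _null_gamma_profile(sd: SurvSorted) -> float:
    """Limit of the gamma profile likelihood as theta -> 0 (plain Cox).

    The frailty-integral term per cluster tends to -A_k, and with the
    Breslow baseline sum(A_k) = n_events, so the profile limit is the plain
    partial likelihood minus the event count.
    """
    beta, b, ll, cov, info, conv, _ = newton_cox(sd)
    eta = sd.X @ beta if sd.p else np.zeros(sd.n)
    return _loglik_only(sd, eta) - sd.n_events
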
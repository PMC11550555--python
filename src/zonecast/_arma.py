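"""Exact Gaussian likelihood ARMA engine.

Implements maximum-likelihood estimation of a stationary ARMA(p, q) process
with an optional constant mean, via the Harvey state-space representation and
a Kalman filter with exact (stationary) initialisation.  The innovation
variance is concentrated out of the likelihood, and AR/MA coefficients are
optimised through the partial-autocorrelation transform so the search space
is unconstrained while the fitted process stays stationary and invertible.

This is the workhorse behind the AICc model-selection grid, where tens of
thousands of candidate fits are needed; the filter loop is numba-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import optimize

__all__ = ["arma_loglike", "fit_arma", "ArmaFit"]

_LOG2PI = float(np.log(2.0 * np.pi))


def pacf_to_coeffs(z: np.ndarray) -> np.ndarray:
    """Map unconstrained reals to stationary AR coefficients.

    Each ``z_i`` is squashed to a partial autocorrelation in (-1, 1), then the
    Durbin-Levinson recursion converts the PACF sequence to AR coefficients
    ``a`` such that ``1 - a_1 B - ... - a_m B^m`` has all roots outside the
    unit circle.
    """
    z = np.asarray(z, dtype=float)
    m = z.size
    if m == 0:
        return z
    r = z / np.sqrt(1.0 + z * z)
    a = np.zeros(m)
    for k in range(m):
        a_new = a.copy()
        a_new[k] = r[k]
        for i in range(k):
            a_new[i] = a[i] - r[k] * a[k - 1 - i]
        a = a_new
    return a


def coeffs_to_pacf(a: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pacf_to_coeffs` (valid for stationary coefficients)."""
    a = np.asarray(a, dtype=float).copy()
    m = a.size
    r = np.zeros(m)
    for k in range(m - 1, -1, -1):
        r[k] = a[k]
        if k > 0:
            d = 1.0 - r[k] * r[k]
            prev = (a[:k] + r[k] * a[k - 1 :: -1][:k][::-1]) / d
            # a_prev[i] = (a[i] + r_k * a[k-1-i]) / (1 - r_k^2)
            prev = np.array([(a[i] + r[k] * a[k - 1 - i]) / d for i in range(k)])
            a = prev
    z = r / np.sqrt(np.clip(1.0 - r * r, 1e-12, None))
    return z


@njit(cache=True)
def _kalman_concentrated(x, mu, phi, theta):  # pragma: no cover - numba
    """Concentrated log-likelihood of ARMA(p,q)+mean via the Kalman filter.

    Harvey representation: state dimension r = max(p, q+1), unit innovation
    variance during filtering; sigma2 is concentrated out at the end.
    Returns (loglike, sigma2_hat, innovations, innovation_variances,
    predicted_state_at_n_plus_1, predicted_cov).
    """
    n = x.shape[0]
    p = phi.shape[0]
    q = theta.shape[0]
    r = max(p, q + 1)

    T = np.zeros((r, r))
    for i in range(p):
        T[i, 0] = phi[i]
    for i in range(r - 1):
        T[i, i + 1] = 1.0
    R = np.zeros(r)
    R[0] = 1.0
    for i in range(q):
        R[i + 1] = theta[i]
    RR = np.outer(R, R)

    # stationary initial covariance P = sum_k T^k RR' T'^k via doubling:
    # quadratic convergence since the AR polynomial is kept stationary
    P = RR.copy()
    Tk = T.copy()
    for _ in range(60):
        P = P + Tk @ P @ Tk.T
        nrm = 0.0
        for i in range(r):
            for j in range(r):
                nrm += np.abs(Tk[i, j])
        if nrm < 1e-14:
            break
        Tk = Tk @ Tk

    a = np.zeros(r)
    v = np.empty(n)
    F = np.empty(n)
    TP0 = np.empty(r)
    Ta = np.empty(r)
    W = np.empty((r, r))
    Pn = np.empty((r, r))
    ssq = 0.0
    logdet = 0.0
    for t in range(n):
        vt = x[t] - mu - a[0]
        Ft = P[0, 0]
        if Ft < 1e-300:
            Ft = 1e-300
        v[t] = vt
        F[t] = Ft
        ssq += vt * vt / Ft
        logdet += np.log(Ft)
        # exploit companion structure: (T M)[i,:] = phi_i*M[0,:] + M[i+1,:]
        for i in range(r):
            pi = phi[i] if i < p else 0.0
            nxt = P[i + 1, 0] if i + 1 < r else 0.0
            TP0[i] = pi * P[0, 0] + nxt
            na = a[i + 1] if i + 1 < r else 0.0
            Ta[i] = pi * a[0] + na
        for i in range(r):
            a[i] = Ta[i] + TP0[i] / Ft * vt
        # W = T P ; Pn = W T' - TP0 TP0'/F + RR
        for i in range(r):
            pi = phi[i] if i < p else 0.0
            for j in range(r):
                nxt = P[i + 1, j] if i + 1 < r else 0.0
                W[i, j] = pi * P[0, j] + nxt
        for i in range(r):
            for j in range(r):
                pj = phi[j] if j < p else 0.0
                nxt = W[i, j + 1] if j + 1 < r else 0.0
                Pn[i, j] = pj * W[i, 0] + nxt - TP0[i] * TP0[j] / Ft + RR[i, j]
        for i in range(r):
            for j in range(r):
                P[i, j] = Pn[i, j]
    sigma2 = ssq / n
    if sigma2 < 1e-300:
        sigma2 = 1e-300
    ll = -0.5 * (n * (_LOG2PI + 1.0 + np.log(sigma2)) + logdet)
    return ll, sigma2, v, F, a, P


@njit(cache=True)
def _pacf_to_coeffs_nb(z):  # pragma: no cover - numba
    m = z.shape[0]
    a = np.zeros(m)
    if m == 0:
        return a
    r = z / np.sqrt(1.0 + z * z)
    for k in range(m):
        a_new = a.copy()
        a_new[k] = r[k]
        for i in range(k):
            a_new[i] = a[i] - r[k] * a[k - 1 - i]
        a = a_new
    return a


@njit(cache=True)
def _nll_nb(params, x, p, q, with_const, mu0, scale):  # pragma: no cover - numba
    i = 0
    mu = 0.0
    if with_const:
        mu = params[0] * scale + mu0
        i = 1
    phi = _pacf_to_coeffs_nb(params[i : i + p])
    theta = -_pacf_to_coeffs_nb(params[i + p : i + p + q])
    ll, _, _, _, _, _ = _kalman_concentrated(x, mu, phi, theta)
    if not np.isfinite(ll):
        return 1e12
    return -ll


def arma_loglike(x, mu, phi, theta):
    """Exact log-likelihood of an ARMA(p,q) model with mean ``mu``.

    The innovation variance is set to its conditional MLE (concentrated
    likelihood), so the value returned is the profile log-likelihood
    maximised over sigma2.
    """
    x = np.ascontiguousarray(x, dtype=float)
    phi = np.ascontiguousarray(phi, dtype=float)
    theta = np.ascontiguousarray(theta, dtype=float)
    ll, sigma2, _, _, _, _ = _kalman_concentrated(x, float(mu), phi, theta)
    return ll, sigma2


class ArmaFit:
    """Fitted ARMA(p, q) (+ constant mean) model on a stationary series."""

    def __init__(self, x, p, q, with_const, mu, phi, theta, sigma2, loglike):
        self.x = np.asarray(x, dtype=float)
        self.p = int(p)
        self.q = int(q)
        self.with_const = bool(with_const)
        self.mu = float(mu)
        self.phi = np.asarray(phi, dtype=float)
        self.theta = np.asarray(theta, dtype=float)
        self.sigma2 = float(sigma2)
        self.loglike = float(loglike)

    @property
    def n_params(self) -> int:
        """Estimated parameter count, innovation variance included."""
        return self.p + self.q + (1 if self.with_const else 0) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.loglike + 2.0 * self.n_params

    @property
    def aicc(self) -> float:
        n = self.x.size
        k = self.n_params
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)

    def residuals(self) -> np.ndarray:
        """One-step-ahead Kalman innovations (non-standardised)."""
        _, _, v, _, _, _ = _kalman_concentrated(
            self.x, self.mu, np.ascontiguousarray(self.phi), np.ascontiguousarray(self.theta)
        )
        return v

    def predict_mean_var(self, h: int):
        """h-step forecasts of the (stationary) series with variances.

        Means come from iterating the transition matrix on the final
        predicted state; variances use the standard psi-weight expansion
        conditional on the estimated parameters.
        """
        x = self.x
        phi = np.ascontiguousarray(self.phi)
        theta = np.ascontiguousarray(self.theta)
        _, _, _, _, a, _ = _kalman_concentrated(x, self.mu, phi, theta)
        r = max(self.p, self.q + 1)
        T = np.zeros((r, r))
        T[: self.p, 0] = self.phi
        for i in range(r - 1):
            T[i, i + 1] = 1.0
        means = np.empty(h)
        state = a.copy()
        for i in range(h):
            means[i] = self.mu + state[0]
            state = T @ state
        psi = _arma2ma(self.phi, self.theta, h)
        var = self.sigma2 * np.cumsum(psi**2)
        return means, var


def _arma2ma(phi, theta, h):
    """First ``h`` psi-weights of the ARMA MA(inf) representation."""
    psi = np.zeros(h)
    psi[0] = 1.0
    for j in range(1, h):
        s = theta[j - 1] if j - 1 < len(theta) else 0.0
        for i in range(min(j, len(phi))):
            s += phi[i] * psi[j - 1 - i]
        psi[j] = s
    return psi


def fit_arma(x, p: int, q: int, with_const: bool = True) -> ArmaFit:
    """Exact-MLE fit of ARMA(p, q) with optional constant mean.

    Parameters are optimised in the PACF-transformed space (stationary and
    invertible by construction) with L-BFGS-B on the concentrated
    log-likelihood.
    """
    x = np.ascontiguousarray(x, dtype=float)
    n = x.size
    if n <= p + q + (1 if with_const else 0) + 1:
        raise ValueError("series too short for ARMA(%d,%d)" % (p, q))
    mu0 = float(np.mean(x)) if with_const else 0.0

    if p == 0 and q == 0:
        if with_const:
            mu = mu0
        else:
            mu = 0.0
        ll, s2 = arma_loglike(x, mu, np.empty(0), np.empty(0))
        return ArmaFit(x, p, q, with_const, mu, [], [], s2, ll)

    scale = float(np.std(x)) or 1.0

    def unpack(params):
        i = 0
        if with_const:
            mu = params[0] * scale + mu0
            i = 1
        else:
            mu = 0.0
        phi = pacf_to_coeffs(params[i : i + p])
        theta = -pacf_to_coeffs(params[i + p : i + p + q])
        return mu, phi, theta

    args = (x, p, q, with_const, mu0, scale)
    options = {"maxiter": 60, "ftol": 1e-8, "gtol": 5e-5}
    n_free = (1 if with_const else 0) + p + q
    best = optimize.minimize(
        _nll_nb, np.zeros(n_free), args=args, method="L-BFGS-B", options=options
    )
    if q > 0:
        # second start with mild AR/MA pull; zero starts can stall on the
        # flat region of the MA likelihood
        x1 = np.full(n_free, 0.2)
        if with_const:
            x1[0] = 0.0
        res2 = optimize.minimize(_nll_nb, x1, args=args, method="L-BFGS-B", options=options)
        if res2.fun < best.fun:
            best = res2
    mu, phi, theta = unpack(best.x)
    ll, s2 = arma_loglike(x, mu, phi, theta)
    return ArmaFit(x, p, q, with_const, mu, phi, theta, s2, ll)
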
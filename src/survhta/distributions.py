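"""The seven parametric survival families used for extrapolation.

Each family exposes the censored-likelihood ingredients (log density, log
survival), the hazard, the inverse survival function (for inverse-transform
sampling and comonotone coupling), and the transformed estimation scale
(log for strictly positive parameters, identity for real-valued ones) on
which maximisation and the covariance are defined.

Parameterizations
-----------------
exponential   rate λ > 0                      S(t) = exp(-λ t)
weibull       shape k > 0, scale σ > 0        S(t) = exp(-(t/σ)^k)
gompertz      shape a ∈ R, rate b > 0         h(t) = b e^{a t}; a < 0 gives an
                                              improper survival plateau e^{b/a}
lognormal     meanlog μ ∈ R, sdlog σ > 0
loglogistic   shape k > 0, scale σ > 0        S(t) = 1 / (1 + (t/σ)^k)
gamma         shape α > 0, rate β > 0
gengamma      mu ∈ R, sigma > 0, Q ∈ R        three-parameter log-time form:
              with w = (ln t - μ)/σ and a = Q^{-2}, the variable
              a·exp(Q w) is Gamma(a, 1); Q = 0 is the log-normal limit,
              Q = 1 Weibull, Q = σ gamma.  This reparameterization is the
              numerically stable one standard in HTA survival work.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import special, stats

_LOG_EPS = -745.0  # log of smallest positive double, used as a floor


class ParameterError(ValueError):
    """Invalid family name or parameter vector."""


def _safe_log(x):
    return np.log(np.clip(x, np.exp(_LOG_EPS), None))


class Family:
    """Base class; subclasses define the distribution via class attributes
    and the four kernel methods on the natural parameter scale."""

    name: str = ""
    param_names: Tuple[str, ...] = ()
    transforms: Tuple[str, ...] = ()  # "log" (positive) or "id" (real)

    # -- parameter plumbing -------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def validate(self, params: Dict[str, float]) -> np.ndarray:
        try:
            vec = np.array([float(params[p]) for p in self.param_names])
        except KeyError as exc:
            raise ParameterError(
                f"{self.name} requires parameters {self.param_names}") from exc
        for v, tr, nm in zip(vec, self.transforms, self.param_names):
            if not np.isfinite(v):
                raise ParameterError(f"{self.name}: parameter {nm} not finite")
            if tr == "log" and v <= 0:
                raise ParameterError(
                    f"{self.name}: parameter {nm} must be strictly positive")
        return vec

    def to_transformed(self, vec: np.ndarray) -> np.ndarray:
        return np.array([np.log(v) if tr == "log" else v
                         for v, tr in zip(vec, self.transforms)])

    def from_transformed(self, theta: np.ndarray) -> np.ndarray:
        return np.array([np.exp(v) if tr == "log" else v
                         for v, tr in zip(theta, self.transforms)])

    def as_dict(self, vec: np.ndarray) -> Dict[str, float]:
        return dict(zip(self.param_names, (float(v) for v in vec)))

    # -- kernels (natural scale, vectorized over t) -------------------------
    def log_pdf(self, t, vec):  # pragma: no cover - abstract
        raise NotImplementedError

    def log_sf(self, t, vec):  # pragma: no cover - abstract
        raise NotImplementedError

    def sf(self, t, vec):
        return np.exp(self.log_sf(np.asarray(t, float), vec))

    def hazard(self, t, vec):
        t = np.asarray(t, float)
        return np.exp(self.log_pdf(t, vec) - self.log_sf(t, vec))

    def isf(self, u, vec):
        """Time t at which S(t) = u; +inf where the plateau mass exceeds u."""
        raise NotImplementedError  # pragma: no cover - abstract

    def init_params(self, times: np.ndarray, events: np.ndarray) -> np.ndarray:
        """Deterministic method-of-moments starting values on the natural scale."""
        raise NotImplementedError  # pragma: no cover - abstract


def _logmoments(times, events):
    """Mean/sd of log event times with sane floors; falls back to all times
    when there are very few events."""
    logs = np.log(times[events == 1]) if events.sum() >= 3 else np.log(times)
    return float(np.mean(logs)), float(max(np.std(logs), 0.2))


def _exp_rate(times, events):
    return max(float(events.sum()), 0.5) / float(times.sum())


class Exponential(Family):
    name = "exponential"
    param_names = ("rate",)
    transforms = ("log",)

    def log_pdf(self, t, vec):
        (rate,) = vec
        return np.log(rate) - rate * t

    def log_sf(self, t, vec):
        (rate,) = vec
        return -rate * np.asarray(t, float)

    def isf(self, u, vec):
        (rate,) = vec
        return -np.log(u) / rate

    def init_params(self, times, events):
        return np.array([_exp_rate(times, events)])


class Weibull(Family):
    name = "weibull"
    param_names = ("shape", "scale")
    transforms = ("log", "log")

    def log_pdf(self, t, vec):
        k, s = vec
        z = t / s
        return np.log(k / s) + (k - 1) * _safe_log(z) - z ** k

    def log_sf(self, t, vec):
        k, s = vec
        return -(np.asarray(t, float) / s) ** k

    def isf(self, u, vec):
        k, s = vec
        return s * (-np.log(u)) ** (1.0 / k)

    def init_params(self, times, events):
        mlog, slog = _logmoments(times, events)
        shape = min(max(np.pi / (np.sqrt(6.0) * slog), 0.2), 10.0)
        scale = np.exp(mlog + np.euler_gamma / shape)
        return np.array([shape, scale])


class Gompertz(Family):
    name = "gompertz"
    param_names = ("shape", "rate")
    transforms = ("id", "log")
    _A_EPS = 1e-9

    def log_pdf(self, t, vec):
        a, b = vec
        t = np.asarray(t, float)
        if abs(a) < self._A_EPS:
            return np.log(b) - b * t
        return np.log(b) + a * t - (b / a) * np.expm1(a * t)

    def log_sf(self, t, vec):
        a, b = vec
        t = np.asarray(t, float)
        if abs(a) < self._A_EPS:
            return -b * t
        return -(b / a) * np.expm1(a * t)

    def isf(self, u, vec):
        a, b = vec
        u = np.asarray(u, float)
        if abs(a) < self._A_EPS:
            return -np.log(u) / b
        arg = 1.0 - (a / b) * np.log(u)
        # a < 0: survival plateaus at exp(b/a); u below it is never reached
        out = np.where(arg > 0, np.log(np.clip(arg, 1e-300, None)) / a, np.inf)
        return out

    def plateau(self, vec) -> float:
        """Improper mass S(∞); positive only for negative shape."""
        a, b = vec
        return float(np.exp(b / a)) if a < -self._A_EPS else 0.0

    def init_params(self, times, events):
        return np.array([1e-3, _exp_rate(times, events)])


class LogNormal(Family):
    name = "lognormal"
    param_names = ("meanlog", "sdlog")
    transforms = ("id", "log")

    def log_pdf(self, t, vec):
        mu, sg = vec
        t = np.asarray(t, float)
        z = (np.log(t) - mu) / sg
        return -0.5 * z * z - np.log(t * sg) - 0.5 * np.log(2 * np.pi)

    def log_sf(self, t, vec):
        mu, sg = vec
        z = (np.log(np.asarray(t, float)) - mu) / sg
        return special.log_ndtr(-z)

    def isf(self, u, vec):
        mu, sg = vec
        return np.exp(mu + sg * special.ndtri(1.0 - np.asarray(u, float)))

    def init_params(self, times, events):
        mlog, slog = _logmoments(times, events)
        return np.array([mlog, slog])


class LogLogistic(Family):
    name = "loglogistic"
    param_names = ("shape", "scale")
    transforms = ("log", "log")

    def log_pdf(self, t, vec):
        k, s = vec
        z = _safe_log(np.asarray(t, float) / s) * k
        # f(t) = (k/s)(t/s)^{k-1} / (1+(t/s)^k)^2
        return np.log(k) - np.log(s) + (1 - 1.0 / k) * z - 2 * np.logaddexp(0.0, z)

    def log_sf(self, t, vec):
        k, s = vec
        z = _safe_log(np.asarray(t, float) / s) * k
        return -np.logaddexp(0.0, z)

    def isf(self, u, vec):
        k, s = vec
        u = np.asarray(u, float)
        return s * ((1.0 - u) / u) ** (1.0 / k)

    def init_params(self, times, events):
        mlog, slog = _logmoments(times, events)
        shape = min(max(np.pi / (np.sqrt(3.0) * slog), 0.2), 10.0)
        return np.array([shape, np.exp(mlog)])


class Gamma(Family):
    name = "gamma"
    param_names = ("shape", "rate")
    transforms = ("log", "log")

    def log_pdf(self, t, vec):
        a, b = vec
        t = np.asarray(t, float)
        return a * np.log(b) + (a - 1) * _safe_log(t) - b * t - special.gammaln(a)

    def log_sf(self, t, vec):
        a, b = vec
        # regularized upper incomplete gamma
        return _safe_log(special.gammaincc(a, b * np.asarray(t, float)))

    def isf(self, u, vec):
        a, b = vec
        return special.gammainccinv(a, np.asarray(u, float)) / b

    def init_params(self, times, events):
        t = times[events == 1] if events.sum() >= 3 else times
        m, v = float(np.mean(t)), float(max(np.var(t), 1e-6))
        shape = min(max(m * m / v, 0.05), 50.0)
        return np.array([shape, shape / m])


class GenGamma(Family):
    name = "gengamma"
    param_names = ("mu", "sigma", "Q")
    transforms = ("id", "log", "id")
    _Q_EPS = 1e-6

    def log_pdf(self, t, vec):
        mu, sg, q = vec
        t = np.asarray(t, float)
        w = (np.log(t) - mu) / sg
        if abs(q) < self._Q_EPS:
            return -0.5 * w * w - np.log(t * sg) - 0.5 * np.log(2 * np.pi)
        a = q ** -2
        return (np.log(abs(q)) - np.log(sg * t) + a * np.log(a)
                - special.gammaln(a) + a * (q * w - np.exp(q * w)))

    def log_sf(self, t, vec):
        mu, sg, q = vec
        t = np.asarray(t, float)
        w = (np.log(t) - mu) / sg
        if abs(q) < self._Q_EPS:
            return special.log_ndtr(-w)
        a = q ** -2
        u = a * np.exp(q * w)
        if q > 0:
            return _safe_log(special.gammaincc(a, u))
        return _safe_log(special.gammainc(a, u))

    def isf(self, u, vec):
        mu, sg, q = vec
        u = np.asarray(u, float)
        if abs(q) < self._Q_EPS:
            return np.exp(mu + sg * special.ndtri(1.0 - u))
        a = q ** -2
        g = special.gammainccinv(a, u) if q > 0 else special.gammaincinv(a, u)
        return np.exp(mu + sg * np.log(np.clip(q * q * g, 1e-300, None)) / q)

    def init_params(self, times, events):
        mlog, slog = _logmoments(times, events)
        return np.array([mlog, slog, 1.0])  # Q=1 starts at the Weibull sub-model


FAMILIES: Dict[str, Family] = {
    f.name: f for f in (Exponential(), Weibull(), Gompertz(), LogNormal(),
                        LogLogistic(), Gamma(), GenGamma())
}

FAMILY_NAMES: Tuple[str, ...] = tuple(FAMILIES)


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ParameterError(
            f"unknown family {name!r}; choose one of {sorted(FAMILIES)}") from None
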
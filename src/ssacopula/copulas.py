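"""Bivariate Archimedean copulas and rank-space estimation.

Implements the three one-parameter Archimedean families used for modelling
the serial dependence of heart-rate residuals — Clayton (lower-tail
dependence), Frank (symmetric) and Gumbel (upper-tail dependence) — together
with:

* rank transforms / pseudo-observations ``r_i / (n + 1)``,
* the empirical copula (rank-space indicator average),
* canonical maximum-likelihood fitting of the family parameter theta on
  pseudo-observations,
* a Cramer-von Mises goodness-of-fit distance between each fitted family and
  the empirical copula, used for family selection,
* conditional CDFs (h-functions, the partial derivative of C with respect to
  the conditioning argument) and seeded conditional inverse-transform
  sampling.

theta = 0 for Clayton/Frank and theta = 1 for Gumbel are the independence
limits; values within ``INDEPENDENCE_TOL`` of them are evaluated as the
independence copula (removable singularity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CopulaFitError",
    "Copula",
    "IndependenceCopula",
    "ClaytonCopula",
    "FrankCopula",
    "GumbelCopula",
    "make_copula",
    "rank_transform",
    "pseudo_observations",
    "EmpiricalCopula",
    "empirical_copula",
    "generator",
    "copula_cdf",
    "conditional_cdf",
    "conditional_sample",
    "fit_ml",
    "GofResult",
    "gof_select",
]

logger = logging.getLogger(__name__)

FAMILIES = ("clayton", "frank", "gumbel")

#: |theta| (Clayton, Frank) or |theta - 1| (Gumbel) below this is treated as
#: the independence copula.
INDEPENDENCE_TOL = 1e-8

_BISECT_TOL = 1e-10
_BISECT_MAXITER = 200
_EPS = 1e-12


class CopulaFitError(RuntimeError):
    """Maximum-likelihood estimation of a copula parameter failed."""


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------


class Copula:
    """Base bivariate copula.

    Subclasses implement the interior formulas on (0,1)^2; this class patches
    the boundary identities C(u,0) = C(0,v) = 0, C(u,1) = u, C(1,v) = v
    exactly and provides generic conditional sampling.
    """

    family: str = "base"

    def __init__(self, theta: float):
        self.theta = float(theta)
        self._validate_theta()

    def _validate_theta(self) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    # interior formulas -----------------------------------------------------
    def _cdf(self, u, v):
        raise NotImplementedError

    def _logpdf(self, u, v):
        raise NotImplementedError

    def _h(self, v, u):
        """Conditional CDF h(v | u) = dC(u, v)/du on the interior."""
        raise NotImplementedError

    def _h_inv(self, p, u):
        """Inverse of ``_h`` in v; default is vectorised bisection."""
        return _bisect_h(self._h, p, u)

    def generator(self, t):
        raise NotImplementedError

    # public surface --------------------------------------------------------
    def cdf(self, u, v):
        u_arr, v_arr = np.broadcast_arrays(np.asarray(u, float), np.asarray(v, float))
        if np.any((u_arr < 0) | (u_arr > 1) | (v_arr < 0) | (v_arr > 1)):
            raise ValueError("copula arguments must lie in [0, 1]")
        ui = np.clip(u_arr, _EPS, 1.0 - _EPS)
        vi = np.clip(v_arr, _EPS, 1.0 - _EPS)
        with np.errstate(over="ignore", under="ignore"):
            out = np.asarray(self._cdf(ui, vi), dtype=float)
        out = np.where(u_arr <= 0.0, 0.0, out)
        out = np.where(v_arr <= 0.0, 0.0, out)
        out = np.where(u_arr >= 1.0, v_arr, out)
        out = np.where(v_arr >= 1.0, np.where(u_arr >= 1.0, 1.0, u_arr), out)
        return out if out.ndim else float(out)

    def logpdf(self, u, v):
        u_arr = np.clip(np.asarray(u, float), _EPS, 1.0 - _EPS)
        v_arr = np.clip(np.asarray(v, float), _EPS, 1.0 - _EPS)
        with np.errstate(over="ignore", under="ignore", divide="ignore", invalid="ignore"):
            out = np.asarray(self._logpdf(u_arr, v_arr), dtype=float)
        return out if out.ndim else float(out)

    def pdf(self, u, v):
        return np.exp(self.logpdf(u, v))

    def conditional_cdf(self, v, given_u):
        v_arr = np.clip(np.asarray(v, float), _EPS, 1.0 - _EPS)
        u_arr = np.clip(np.asarray(given_u, float), _EPS, 1.0 - _EPS)
        with np.errstate(over="ignore", under="ignore"):
            out = np.clip(np.asarray(self._h(v_arr, u_arr), dtype=float), 0.0, 1.0)
        return out if out.ndim else float(out)

    def inverse_conditional_cdf(self, p, given_u):
        p_arr = np.clip(np.asarray(p, float), _EPS, 1.0 - _EPS)
        u_arr = np.clip(np.asarray(given_u, float), _EPS, 1.0 - _EPS)
        with np.errstate(over="ignore", under="ignore"):
            out = np.asarray(self._h_inv(p_arr, u_arr), dtype=float)
        out = np.clip(out, _EPS, 1.0 - _EPS)
        return out if out.ndim else float(out)

    def conditional_sample(self, given_u: float, n_samples: int, rng) -> np.ndarray:
        """Draw ``n_samples`` of V | U = given_u by inverse transform."""
        n_samples = int(n_samples)
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0.0 < given_u < 1.0):
            raise ValueError("given_u must lie strictly inside (0, 1)")
        rng = np.random.default_rng(rng)
        p = rng.random(n_samples)
        return np.asarray(self.inverse_conditional_cdf(p, given_u), dtype=float)

    def to_dict(self) -> dict:
        return {"family": self.family, "theta": self.theta}

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}(theta={self.theta:.6g})"


class IndependenceCopula(Copula):
    """C(u, v) = u v; the theta-free independence model (GoF fallback)."""

    family = "independence"

    def __init__(self, theta: float = 0.0):
        super().__init__(theta)

    def _validate_theta(self) -> None:
        pass

    def generator(self, t):
        return -np.log(np.asarray(t, float))

    def _cdf(self, u, v):
        return u * v

    def _logpdf(self, u, v):
        return np.zeros(np.broadcast(u, v).shape)

    def _h(self, v, u):
        return v + 0.0 * u

    def _h_inv(self, p, u):
        return p + 0.0 * u


class ClaytonCopula(Copula):
    """Clayton copula, theta >= -1, theta != 0; lower-tail dependent for theta > 0.

    C(u,v) = max(u^-theta + v^-theta - 1, 0)^(-1/theta); the generator is
    phi(t) = (t^-theta - 1)/theta.
    """

    family = "clayton"

    def _validate_theta(self) -> None:
        if self.theta < -1.0 or abs(self.theta) < INDEPENDENCE_TOL:
            raise ValueError(
                f"clayton theta must satisfy theta >= -1 and theta != 0, got {self.theta}"
            )

    def generator(self, t):
        t = np.asarray(t, float)
        if np.any((t <= 0) | (t > 1)):
            raise ValueError("generator argument must lie in (0, 1]")
        return (t ** (-self.theta) - 1.0) / self.theta

    def _base(self, u, v):
        return u ** (-self.theta) + v ** (-self.theta) - 1.0

    def _cdf(self, u, v):
        base = self._base(u, v)
        return np.where(base > 0.0, np.maximum(base, _EPS) ** (-1.0 / self.theta), 0.0)

    def _logpdf(self, u, v):
        th = self.theta
        base = self._base(u, v)
        ok = base > 0.0
        safe = np.maximum(base, _EPS)
        lp = (
            np.log1p(th)
            - (1.0 + th) * (np.log(u) + np.log(v))
            - (2.0 + 1.0 / th) * np.log(safe)
        )
        return np.where(ok, lp, -np.inf)

    def _h(self, v, u):
        th = self.theta
        base = self._base(u, v)
        ok = base > 0.0
        safe = np.maximum(base, _EPS)
        h = u ** (-(1.0 + th)) * safe ** (-(1.0 + 1.0 / th))
        # outside the support (possible only for theta < 0) C == 0, so h == 0
        return np.where(ok, h, 0.0)

    def _h_inv(self, p, u):
        th = self.theta
        if th < 0.0:
            return _bisect_h(self._h, p, u)
        inner = (p ** (-th / (1.0 + th)) - 1.0) * u ** (-th) + 1.0
        return inner ** (-1.0 / th)


class FrankCopula(Copula):
    """Frank copula, theta real, theta != 0; symmetric dependence.

    C(u,v) = -(1/theta) ln(1 + (e^{-theta u} - 1)(e^{-theta v} - 1)/(e^{-theta} - 1));
    generator phi(t) = -ln((e^{-theta t} - 1)/(e^{-theta} - 1)).
    """

    family = "frank"

    def _validate_theta(self) -> None:
        if not np.isfinite(self.theta) or abs(self.theta) < INDEPENDENCE_TOL:
            raise ValueError(f"frank theta must be finite and nonzero, got {self.theta}")

    def generator(self, t):
        t = np.asarray(t, float)
        if np.any((t <= 0) | (t > 1)):
            raise ValueError("generator argument must lie in (0, 1]")
        th = self.theta
        return -np.log(np.expm1(-th * t) / np.expm1(-th))

    def _cdf(self, u, v):
        th = self.theta
        return -np.log1p(np.expm1(-th * u) * np.expm1(-th * v) / np.expm1(-th)) / th

    def _logpdf(self, u, v):
        th = self.theta
        # c = theta (1 - e^-theta) e^{-theta(u+v)} / D^2 with
        # D = (1 - e^-theta) - (1 - e^{-theta u})(1 - e^{-theta v})
        g = th * (-np.expm1(-th))  # > 0 for every theta != 0
        D = -np.expm1(-th) - np.expm1(-th * u) * np.expm1(-th * v)
        return np.log(g) - th * (u + v) - 2.0 * np.log(np.abs(D))

    def _h(self, v, u):
        th = self.theta
        num = np.exp(-th * u) * np.expm1(-th * v)
        den = np.expm1(-th) + np.expm1(-th * u) * np.expm1(-th * v)
        return num / den

    def _h_inv(self, p, u):
        th = self.theta
        B = p * np.expm1(-th) / (np.exp(-th * u) - p * np.expm1(-th * u))
        return -np.log1p(B) / th


class GumbelCopula(Copula):
    """Gumbel copula, theta >= 1; upper-tail dependent, theta = 1 is independence.

    C(u,v) = exp(-((-ln u)^theta + (-ln v)^theta)^(1/theta)); generator
    phi(t) = (-ln t)^theta.
    """

    family = "gumbel"

    def _validate_theta(self) -> None:
        if self.theta < 1.0:
            raise ValueError(f"gumbel theta must satisfy theta >= 1, got {self.theta}")

    @property
    def _is_independence(self) -> bool:
        return abs(self.theta - 1.0) < INDEPENDENCE_TOL

    def generator(self, t):
        t = np.asarray(t, float)
        if np.any((t <= 0) | (t > 1)):
            raise ValueError("generator argument must lie in (0, 1]")
        return (-np.log(t)) ** self.theta

    def _cdf(self, u, v):
        if self._is_independence:
            return u * v
        th = self.theta
        A = (-np.log(u)) ** th + (-np.log(v)) ** th
        return np.exp(-(A ** (1.0 / th)))

    def _logpdf(self, u, v):
        if self._is_independence:
            return np.zeros(np.broadcast(u, v).shape)
        th = self.theta
        x = -np.log(u)
        y = -np.log(v)
        A = x**th + y**th
        s = A ** (1.0 / th)
        return (
            -s
            + (th - 1.0) * (np.log(x) + np.log(y))
            + (x + y)
            + (2.0 / th - 2.0) * np.log(A)
            + np.log1p((th - 1.0) / s)
        )

    def _h(self, v, u):
        if self._is_independence:
            return v + 0.0 * u
        th = self.theta
        x = -np.log(u)
        y = -np.log(v)
        A = x**th + y**th
        return np.exp(-(A ** (1.0 / th))) * A ** (1.0 / th - 1.0) * x ** (th - 1.0) / u

    def _h_inv(self, p, u):
        if self._is_independence:
            return p + 0.0 * u
        return _bisect_h(self._h, p, u)


def _bisect_h(h, p, u, tol: float = _BISECT_TOL, maxiter: int = _BISECT_MAXITER):
    """Vectorised bisection solve of ``h(v, u) = p`` for v in (0, 1)."""
    p_arr, u_arr = np.broadcast_arrays(np.asarray(p, float), np.asarray(u, float))
    lo = np.full(p_arr.shape, _EPS)
    hi = np.full(p_arr.shape, 1.0 - _EPS)
    for _ in range(maxiter):
        mid = 0.5 * (lo + hi)
        below = h(mid, u_arr) < p_arr
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
        if np.max(hi - lo) < tol:
            break
    return 0.5 * (lo + hi)


_COPULA_CLASSES = {
    "clayton": ClaytonCopula,
    "frank": FrankCopula,
    "gumbel": GumbelCopula,
    "independence": IndependenceCopula,
}


def make_copula(family: str, theta: float = 0.0) -> Copula:
    """Instantiate a copula by family name; near-singular theta values for
    Clayton/Frank (|theta| < 1e-8) collapse to the independence copula."""
    fam = str(family).lower()
    if fam not in _COPULA_CLASSES:
        raise ValueError(f"unknown copula family {family!r}; choose from {sorted(_COPULA_CLASSES)}")
    if fam in ("clayton", "frank") and abs(theta) < INDEPENDENCE_TOL:
        return IndependenceCopula()
    if fam == "gumbel" and abs(theta - 1.0) < INDEPENDENCE_TOL:
        return GumbelCopula(1.0)
    return _COPULA_CLASSES[fam](theta)


# ---------------------------------------------------------------------------
# rank space
# ---------------------------------------------------------------------------


def rank_transform(x) -> np.ndarray:
    """Map a sample to pseudo-observations ``rank_i / (n + 1)`` in (0, 1).

    Ties receive average ranks, which keeps the output strictly inside the
    unit interval and symmetric; any strictly increasing transform of ``x``
    leaves the result unchanged.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("rank_transform needs a 1-D sample of length >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample contains non-finite values")
    return stats.rankdata(arr, method="average") / (arr.size + 1.0)


def pseudo_observations(x, y):
    """Componentwise rank transform of a paired sample: ``(u, v)`` in (0,1)^2."""
    u = rank_transform(x)
    v = rank_transform(y)
    if u.size != v.size:
        raise ValueError("x and y must have equal length")
    return u, v


class EmpiricalCopula:
    """Rank-space empirical copula of a paired sample.

    ``C_e(a, b)`` is the fraction of pseudo-observation pairs with
    ``u_i <= a`` and ``v_i <= b``.
    """

    def __init__(self, u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if u.shape != v.shape or u.ndim != 1 or u.size < 1:
            raise ValueError("u and v must be equal-length 1-D arrays")
        if np.any((u <= 0) | (u >= 1) | (v <= 0) | (v >= 1)):
            raise ValueError("pseudo-observations must lie strictly inside (0, 1)")
        self.u = u
        self.v = v
        self.n = int(u.size)

    @classmethod
    def from_data(cls, x, y) -> "EmpiricalCopula":
        return cls(*pseudo_observations(x, y))

    def __call__(self, a, b):
        a_arr = np.atleast_1d(np.asarray(a, dtype=float))
        b_arr = np.atleast_1d(np.asarray(b, dtype=float))
        a_arr, b_arr = np.broadcast_arrays(a_arr, b_arr)
        if np.any((a_arr < 0) | (a_arr > 1) | (b_arr < 0) | (b_arr > 1)):
            raise ValueError("evaluation points must lie in [0, 1]")
        hit = (self.u[None, :] <= a_arr.ravel()[:, None]) & (
            self.v[None, :] <= b_arr.ravel()[:, None]
        )
        out = hit.mean(axis=1).reshape(a_arr.shape)
        return out if np.ndim(a) or np.ndim(b) else float(out.ravel()[0])


def empirical_copula(u, v, a, b):
    """Functional form of :class:`EmpiricalCopula`: C_e(a, b) for pseudo-obs."""
    return EmpiricalCopula(u, v)(a, b)


# ---------------------------------------------------------------------------
# functional convenience surface
# ---------------------------------------------------------------------------


def generator(family: str, theta: float, t):
    """Archimedean generator phi(t) for the given family and parameter."""
    return make_copula(family, theta).generator(t)


def copula_cdf(model: Copula, u, v):
    return model.cdf(u, v)


def conditional_cdf(model: Copula, v, given_u):
    return model.conditional_cdf(v, given_u)


def conditional_sample(model: Copula, given_u: float, n_samples: int, seed) -> np.ndarray:
    return model.conditional_sample(given_u, n_samples, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

# parameter transforms: theta = _to_theta(s) maps the unconstrained optimiser
# variable into the family's domain.
_TRANSFORMS = {
    "clayton": (lambda s: -1.0 + np.exp(s), lambda th: np.log(th + 1.0)),
    "frank": (lambda s: s, lambda th: th),
    "gumbel": (lambda s: 1.0 + np.exp(s), lambda th: np.log(max(th - 1.0, 1e-8))),
}


def _tau_start(family: str, tau: float) -> float:
    """Method-of-moments-style start value from Kendall's tau."""
    tau = float(np.clip(tau, -0.95, 0.95))
    if family == "clayton":
        return float(np.clip(2.0 * tau / (1.0 - tau), -0.9, 50.0)) or 0.5
    if family == "frank":
        # small-theta linearisation tau ~ theta / 9, as a start value only
        return float(np.clip(9.0 * tau, -35.0, 35.0)) or 0.5
    if family == "gumbel":
        return float(np.clip(1.0 / (1.0 - max(tau, 0.0)), 1.001, 50.0))
    raise ValueError(family)


_MIDPOINT_START = {"clayton": 1.0, "frank": 2.0, "gumbel": 2.0}


def _negloglik(theta: float, family: str, u, v) -> float:
    try:
        cop = make_copula(family, theta)
    except ValueError:
        return 1e10
    lp = cop.logpdf(u, v)
    if not np.all(np.isfinite(lp)):
        return 1e10
    return -float(np.mean(lp))


def fit_ml(u, v, family: str) -> float:
    """Canonical maximum-likelihood estimate of theta on pseudo-observations.

    One-dimensional search over an unconstrained reparameterisation of the
    family's domain (Nelder-Mead), multi-started from a Kendall-tau guess and
    a domain midpoint; the better optimum is kept.
    """
    fam = str(family).lower()
    if fam not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be equal-length 1-D arrays")
    if u.size < 10:
        raise ValueError(f"need at least 10 pairs to fit a copula, got {u.size}")
    if np.any((u <= 0) | (u >= 1) | (v <= 0) | (v >= 1)):
        raise ValueError("pseudo-observations must lie strictly inside (0, 1)")

    to_theta, from_theta = _TRANSFORMS[fam]
    tau = stats.kendalltau(u, v).statistic
    if not np.isfinite(tau):
        tau = 0.0
    starts = {from_theta(_tau_start(fam, tau)), from_theta(_MIDPOINT_START[fam])}

    best = None
    for s0 in starts:
        res = optimize.minimize(
            lambda s: _negloglik(to_theta(s[0]), fam, u, v),
            x0=[s0],
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise CopulaFitError(
            f"ML estimation failed for family {fam!r}: "
            f"optimizer status {getattr(best, 'message', 'no result')}"
        )
    theta = float(to_theta(best.x[0]))
    # snap to the independence limit inside its numerical neighbourhood
    if fam in ("clayton", "frank") and abs(theta) < INDEPENDENCE_TOL:
        theta = 0.0
    if fam == "gumbel":
        theta = max(theta, 1.0)
    return theta


@dataclass(frozen=True)
class GofResult:
    """Family selection by Cramer-von Mises distance to the empirical copula."""

    family: str
    theta: float
    distances: dict
    thetas: dict

    @property
    def copula(self) -> Copula:
        return make_copula(self.family, self.theta)


def gof_select(u, v, families=FAMILIES, max_eval_points: int = 2000) -> GofResult:
    """Fit every candidate family by ML and pick the one whose CDF is closest
    to the empirical copula in Cramer-von Mises distance.

    The distance is ``sum_i (C_e(u_i, v_i) - C_theta(u_i, v_i))^2`` over the
    pseudo-observations (an evenly spaced subsample of at most
    ``max_eval_points`` points keeps the empirical-copula evaluation bounded;
    ML always uses the full sample).  If every fit fails, the independence
    copula is returned and the event logged.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size < 30:
        raise ValueError(f"need at least 30 pairs for family selection, got {u.size}")
    emp = EmpiricalCopula(u, v)
    if u.size > max_eval_points:
        idx = np.linspace(0, u.size - 1, max_eval_points).astype(int)
    else:
        idx = np.arange(u.size)
    ce = emp(u[idx], v[idx])

    distances: dict = {}
    thetas: dict = {}
    for fam in families:
        try:
            theta = fit_ml(u, v, fam)
        except (CopulaFitError, ValueError) as exc:
            logger.warning("ML fit failed for %s: %s", fam, exc)
            continue
        thetas[fam] = theta
        ct = make_copula(fam, theta).cdf(u[idx], v[idx])
        distances[fam] = float(np.sum((ce - ct) ** 2))
    if not distances:
        logger.warning("all copula fits failed; falling back to independence")
        return GofResult(family="independence", theta=0.0, distances={}, thetas={})
    best = min(distances, key=distances.get)
    return GofResult(family=best, theta=thetas[best], distances=distances, thetas=thetas)
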
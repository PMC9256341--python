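"""Parametric NBU(2) alternative families and Pitman asymptotic efficiency.

Three lifetime families indexed by theta, each reducing to the unit
exponential at its null value:

* linear failure rate (LFR):  survival ``exp(-x - theta x^2 / 2)``, null theta = 0
* Weibull:                    survival ``exp(-x^theta)``, null theta = 1
* Makeham:                    survival ``exp(-x - theta (x + e^{-x} - 1))``, null theta = 0

Sampling is by inverse transform on the cumulative hazard H (H(X) is unit
exponential): LFR and Weibull invert in closed form, Makeham by bisection
(H is strictly increasing so the root is unique; H(x) >= x gives the upper
bracket and H(x) <= (1+theta) x the lower one).

Pitman asymptotic efficiency is defined at the kernel level: with

    mu(theta) = s E_theta[X e^{-sX}] - phi_theta(s) (1 - phi_theta(s))

the efficiency is PAE = |mu'(theta0)| / sigma_0(s).  Differentiating under
the integral and integrating by parts gives

    mu'(theta0) = s^2 [ (2/(1+s)) I0 - I1 ],
    I0 = int_0^inf e^{-sx} G(x) dx,   I1 = int_0^inf x e^{-sx} G(x) dx,

where G = d(survival)/d(theta) at the null: -(x^2/2) e^{-x} for LFR,
-x ln(x) e^{-x} for Weibull, -(x + e^{-x} - 1) e^{-x} for Makeham.  For LFR
this reduces to the closed form mu'(theta0) = s^2/(1+s)^4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .core import SurvivalSample, sigma0_sq

__all__ = [
    "AlternativeFamily",
    "lfr",
    "weibull",
    "makeham",
    "family_from_spec",
    "FAMILY_BUILDERS",
    "sample_family",
    "mu_prime_at_null",
    "pae",
    "pare",
]


@dataclass(frozen=True)
class AlternativeFamily:
    """A parametric lifetime family used for power and efficiency studies."""

    name: str
    theta: float
    null_theta: float
    survival: Callable[[np.ndarray], np.ndarray]
    _draw: Callable[[tuple, np.random.Generator], np.ndarray]
    dsurv_dtheta_null: Callable[[np.ndarray], np.ndarray]

    def draw(self, size, rng: np.random.Generator) -> np.ndarray:
        """Draw lifetimes of the given shape using the supplied generator."""
        return self._draw(size, rng)


def _makeham_invert(E: np.ndarray, theta: float) -> np.ndarray:
    # solve (1+theta) x + theta (e^{-x} - 1) = E by bisection; root in [E/(1+theta), E]
    lo = E / (1 + theta)
    hi = E.copy()
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        low_side = (1 + theta) * mid + theta * (np.exp(-mid) - 1) < E
        lo = np.where(low_side, mid, lo)
        hi = np.where(low_side, hi, mid)
    return 0.5 * (lo + hi)


def lfr(theta: float) -> AlternativeFamily:
    """Linear failure rate family, hazard 1 + theta x; exponential at theta = 0."""
    if theta < 0:
        raise ValueError("LFR requires theta >= 0")

    def surv(x):
        x = np.asarray(x, dtype=float)
        return np.exp(-x - theta * x**2 / 2)

    def draw(size, rng):
        E = rng.exponential(size=size)
        if theta == 0:
            return E
        return (-1 + np.sqrt(1 + 2 * theta * E)) / theta

    return AlternativeFamily(
        name="lfr",
        theta=theta,
        null_theta=0.0,
        survival=surv,
        _draw=draw,
        dsurv_dtheta_null=lambda x: -(np.asarray(x, float) ** 2 / 2) * np.exp(-np.asarray(x, float)),
    )


def weibull(theta: float) -> AlternativeFamily:
    """Weibull family with shape theta >= 1; exponential at theta = 1."""
    if theta < 1:
        raise ValueError("Weibull requires theta >= 1")

    def surv(x):
        x = np.asarray(x, dtype=float)
        return np.exp(-(x**theta))

    def dsurv(x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = -x[pos] * np.log(x[pos]) * np.exp(-x[pos])
        return out

    return AlternativeFamily(
        name="weibull",
        theta=theta,
        null_theta=1.0,
        survival=surv,
        _draw=lambda size, rng: rng.exponential(size=size) ** (1.0 / theta),
        dsurv_dtheta_null=dsurv,
    )


def makeham(theta: float) -> AlternativeFamily:
    """Makeham family, hazard 1 + theta (1 - e^{-x}); exponential at theta = 0."""
    if theta < 0:
        raise ValueError("Makeham requires theta >= 0")

    def surv(x):
        x = np.asarray(x, dtype=float)
        return np.exp(-x - theta * (x + np.exp(-x) - 1))

    def draw(size, rng):
        E = rng.exponential(size=size)
        if theta == 0:
            return E
        return _makeham_invert(E, theta)

    def dsurv(x):
        x = np.asarray(x, dtype=float)
        return -(x + np.exp(-x) - 1) * np.exp(-x)

    return AlternativeFamily(
        name="makeham",
        theta=theta,
        null_theta=0.0,
        survival=surv,
        _draw=draw,
        dsurv_dtheta_null=dsurv,
    )


FAMILY_BUILDERS: dict[str, Callable[[float], AlternativeFamily]] = {
    "lfr": lfr,
    "weibull": weibull,
    "makeham": makeham,
}


def family_from_spec(spec: str) -> AlternativeFamily:
    """Build a family from a "name:theta" string, e.g. "lfr:2" or "weibull:4"."""
    try:
        name, _, theta_str = spec.partition(":")
        builder = FAMILY_BUILDERS[name.strip().lower()]
        theta = float(theta_str)
    except (KeyError, ValueError) as exc:
        raise ValueError(
            f"cannot parse family spec {spec!r}; expected one of "
            f"{sorted(FAMILY_BUILDERS)} as 'name:theta'"
        ) from exc
    return builder(theta)


def sample_family(
    family: AlternativeFamily, n: int, seed: int | None = None
) -> SurvivalSample:
    """Draw one SurvivalSample of size n from the family."""
    rng = np.random.default_rng(seed)
    return SurvivalSample(family.draw(n, rng))


def mu_prime_at_null(family: AlternativeFamily, s: float) -> float:
    """Kernel-level drift slope mu'(theta0) by adaptive quadrature.

    The Weibull integrands contain x ln(x), so the domain is split at x = 1
    where the logarithm changes sign.
    """
    if not s > 0:
        raise ValueError("s must be positive")
    G = family.dsurv_dtheta_null

    def integrate(f):
        total = 0.0
        for a, b in ((0.0, 1.0), (1.0, np.inf)):
            val, err = quad(f, a, b, epsabs=1e-10, epsrel=1e-10, limit=200)
            if not np.isfinite(val) or err > 1e-6:
                raise ArithmeticError(
                    f"quadrature failed on ({a}, {b}): value={val}, err={err}"
                )
            total += val
        return total

    i0 = integrate(lambda x: np.exp(-s * x) * G(x))
    i1 = integrate(lambda x: x * np.exp(-s * x) * G(x))
    return s**2 * ((2.0 / (1 + s)) * i0 - i1)


def pae(family: AlternativeFamily, s: float) -> float:
    """Pitman asymptotic efficiency |mu'(theta0)| / sigma_0(s)."""
    return float(abs(mu_prime_at_null(family, s)) / np.sqrt(sigma0_sq(s)))


def pare(family: AlternativeFamily, s1: float, s2: float) -> float:
    """Pitman asymptotic relative efficiency of s1 versus s2 for one family."""
    return pae(family, s1) / pae(family, s2)
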
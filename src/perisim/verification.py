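"""Independent closed-form oracles and convergence studies.

Everything here is evaluated from analytic expressions (special functions on
radii), never through the mesh solvers, so it can serve as an independent
reference for them.

Tolerances used by the verification suite are collected in
:data:`TOLERANCES` so tests cite a single source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TOLERANCES",
    "sphere_pressure_oracle",
    "sphere_reaction_diffusion_oracle",
    "sphere_diffusion_transient_oracle",
    "ConvergenceReport",
    "run_convergence",
]

#: Fixed verification tolerances (relative unless noted).
TOLERANCES = {
    "pressure_oracle_rel": 5e-3,      # numerical sphere IFP vs closed form
    "reaction_diffusion_rel": 1e-2,   # steady transport vs closed form
    "budget_rel": 1e-2,               # global fluid/mass closure
    "steady_vs_transient": 1e-2,      # of C0, pointwise
    "volume_rel": 1e-2,               # mesh volume vs analytic
    "cross_backend": 1e-2,            # radial-1D vs axisymmetric sphere
}


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def sphere_pressure_oracle(R: float, r_n: float, tissue) -> Callable:
    """Closed-form steady IFP in a sphere of radius ``R`` with a zero-source
    core of radius ``r_n`` (may be 0).

    In the viable shell the radial problem
    ``(1/r^2)(r^2 P')' = (a/K)(P - P_ss)`` has the general solution
    ``P = P_ss + (A sinh(alpha r) + B cosh(alpha r))/r`` with
    ``alpha = sqrt(a/K)``; the constants follow from ``P(R) = 0`` and zero
    flux at the core interface (or boundedness at the origin when
    ``r_n = 0``).  The core pressure is the constant interface value.
    """
    from .params import effective_pressure

    a = tissue.L_p * tissue.S_over_V
    K = tissue.K
    P_ss = effective_pressure(tissue)
    alpha = np.sqrt(a / K)

    if r_n <= 0.0:
        def profile(r):
            r = np.asarray(r, dtype=float)
            out = np.empty_like(r)
            small = r < 1e-12 * R
            # sinh(x)/x -> 1 as x -> 0
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(
                    small, alpha,
                    np.sinh(np.minimum(alpha * r, 700.0)) / np.where(small, 1.0, r),
                )
            out = P_ss * (1.0 - (R / np.sinh(min(alpha * R, 700.0))) * frac)
            return out
        return profile

    # Two-constant shell solution in the well-conditioned exponential basis
    #   E1(r) = exp(alpha (r - R))/r   (decays inward from the surface)
    #   E2(r) = exp(-alpha (r - r_n))/r (decays outward from the interface)
    # so both basis functions are O(1) where their condition applies; the
    # classical sinh/cosh basis loses all precision for alpha*R >> 1.
    delta = np.exp(-alpha * (R - r_n))
    # P(R) = 0 and P'(r_n) = 0
    M = np.array([
        [1.0 / R, delta / R],
        [delta * (alpha * r_n - 1.0) / r_n ** 2,
         -(alpha * r_n + 1.0) / r_n ** 2],
    ])
    AB = np.linalg.solve(M, np.array([-P_ss, 0.0]))

    def profile(r):
        r = np.asarray(r, dtype=float)
        shell = np.maximum(r, r_n)
        e1 = np.exp(alpha * (shell - R)) / shell
        e2 = np.exp(-alpha * (shell - r_n)) / shell
        val = P_ss + AB[0] * e1 + AB[1] * e2
        core_val = P_ss + AB[0] * delta / r_n + AB[1] / r_n
        return np.where(r < r_n, core_val, val)

    return profile


def sphere_reaction_diffusion_oracle(R: float, D: float, k_e: float,
                                     C0: float) -> Callable:
    """Steady reaction-diffusion profile in a sphere with surface value C0.

    ``C(r) = C0 (R/r) sinh(phi r)/sinh(phi R)``, ``phi = sqrt(k_e/D)``;
    evaluated in a numerically stable exponential form for large ``phi R``.
    """
    if k_e < 0:
        raise ValueError("k_e must be >= 0")
    if k_e == 0.0:
        return lambda r: C0 * np.ones_like(np.asarray(r, dtype=float))
    phi = np.sqrt(k_e / D)

    def profile(r):
        r = np.asarray(r, dtype=float)
        small = r < 1e-12 * R
        rr = np.where(small, 1.0, r)
        # sinh(phi r)/sinh(phi R) = e^{phi(r-R)} (1-e^{-2 phi r})/(1-e^{-2 phi R})
        num = np.exp(phi * (r - R)) * (1.0 - np.exp(-2.0 * phi * rr))
        den = 1.0 - np.exp(-2.0 * phi * R)
        out = C0 * (R / rr) * num / den
        # r -> 0 limit: C0 R phi e^{-phi R}-ish; evaluate exactly
        center = C0 * R * phi * 2.0 * np.exp(-phi * R) / den
        return np.where(small, center, out)

    return profile


def sphere_diffusion_transient_oracle(R: float, D: float, C0: float,
                                      n_terms: int = 200) -> Callable:
    """Transient pure-diffusion series for a sphere with fixed surface value.

    ``C(r,t)/C0 = 1 + (2R/(pi r)) sum_n ((-1)^n/n) sin(n pi r/R)
    exp(-D n^2 pi^2 t / R^2)`` (zero initial condition).
    """
    n = np.arange(1, n_terms + 1)

    def profile(r, t):
        r = np.asarray(r, dtype=float)
        small = r < 1e-9 * R
        rr = np.where(small, 1.0, r)
        terms = ((-1.0) ** n / n)[None, :] \
            * np.sin(np.outer(rr, n) * np.pi / R) \
            * np.exp(-D * (n * np.pi / R) ** 2 * t)[None, :]
        out = 1.0 + (2.0 * R / (np.pi * rr)) * terms.sum(axis=1)
        center = 1.0 + 2.0 * np.sum(((-1.0) ** n)
                                    * np.exp(-D * (n * np.pi / R) ** 2 * t))
        return C0 * np.clip(np.where(small, center, out), 0.0, 1.0)

    return profile


# ---------------------------------------------------------------------------
# Convergence studies
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Metric values over a mesh-refinement ladder."""

    h: list
    values: list
    observed_order: float
    extrapolated: float
    monotone: bool

    def to_rows(self):
        return [{"h": h, "value": v} for h, v in zip(self.h, self.values)]


def run_convergence(case: Callable[[float], float],
                    h_levels: Sequence[float],
                    reference: float | None = None) -> ConvergenceReport:
    """Evaluate ``case(h)`` over at least three refinement levels.

    With a ``reference`` value (e.g. an oracle), the observed order is fitted
    from the error decay; otherwise from successive differences, with a
    Richardson-extrapolated limit.  Non-monotone decay yields
    ``monotone=False`` (a warning condition, not an error).
    """
    h_levels = list(h_levels)
    if len(h_levels) < 3:
        raise ValueError("need at least 3 refinement levels")
    vals = [float(case(h)) for h in h_levels]
    h = np.asarray(h_levels, dtype=float)
    if reference is not None:
        err = np.abs(np.asarray(vals) - reference)
        err = np.maximum(err, 1e-300)
        p = float(np.polyfit(np.log(h), np.log(err), 1)[0])
        extrap = float(reference)
        mono = bool(np.all(np.diff(err) < 0))
    else:
        d1 = abs(vals[-2] - vals[-3])
        d2 = abs(vals[-1] - vals[-2])
        ratio = h[-2] / h[-1]
        p = float(np.log(max(d1, 1e-300) / max(d2, 1e-300)) / np.log(ratio))
        extrap = vals[-1] + (vals[-1] - vals[-2]) / (ratio ** p - 1.0) \
            if d2 > 0 else vals[-1]
        mono = d2 <= d1
    return ConvergenceReport(h=list(h_levels), values=vals,
                             observed_order=p, extrapolated=extrap,
                             monotone=mono)
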
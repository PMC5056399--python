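"""Large-genome analytic machinery: potentials, phases, and the WKB
mutator fraction.

In the L -> infinity limit the class distributions follow the ansatz
P_l ~ v1(x) e^{L u(x,t)}, Q_l ~ v2(x) e^{L u(x,t)} with x = 1 - 2l/L, and
the dynamics reduce to a Hamilton-Jacobi equation.  The steady-state mean
fitness is the maximum over x of the upper branch V_plus(x) of the 2x2
coefficient matrix

    [[ f(x) - mu1 (1 - sqrt(1-x^2)) - alpha1,  alpha2 ],
     [ alpha1,  g(x) - mu2 (1 - sqrt(1-x^2)) - alpha2 ]]

For uni-directional switching (alpha2 = 0) the matrix is triangular and
the two diagonal branches compete, producing the mixed / mutator /
non-selective phase structure.  The WKB concatenation analysis of the
driven mutator chain yields the finite-L fate of the wild allele through
the exponential discriminant K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize, minimize_scalar

from .landscapes import CompositePart, FitnessLandscape
from .params import MutatorParams

PHASES = ("mixed", "mutator", "non_selective")
BORDER_TOL = 1e-12


def _sqrt1mx2(x):
    return np.sqrt(np.clip(1.0 - np.asarray(x, dtype=float) ** 2, 0.0, None))


def _maximize_on_interval(fun: Callable[[np.ndarray], np.ndarray],
                          lo: float = -1.0, hi: float = 1.0,
                          n: int = 2001) -> tuple[float, float]:
    """Grid scan plus bounded local refinement; ties broken toward larger x."""
    xs = np.linspace(lo, hi, n)
    vals = np.asarray(fun(xs), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite landscape values during maximization")
    i = n - 1 - int(np.argmax(vals[::-1]))  # rightmost maximizer
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, n - 1)]
    res = minimize_scalar(lambda t: -float(fun(np.array([t]))[0]),
                          bounds=(a, b), method="bounded",
                          options={"xatol": 1e-13})
    if -res.fun >= vals[i]:
        return float(res.x), float(-res.fun)
    return float(xs[i]), float(vals[i])


# ---------------------------------------------------------------------------
# potential branches

@dataclass(frozen=True)
class PotentialCurve:
    """Eigenvalue branches V_plus >= V_minus of the HJE coefficient matrix."""

    x: np.ndarray
    V_plus: np.ndarray
    V_minus: np.ndarray
    argmax_plus: float
    argmax_minus: float


def _branches(params: MutatorParams, landscape: FitnessLandscape,
              x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-15):
        raise ValueError("potential defined on |x| <= 1")
    loss = 1.0 - _sqrt1mx2(x)
    d1 = np.asarray(landscape.f(x), float) - params.mu1 * loss - params.alpha1
    d2 = np.asarray(landscape.g(x), float) - params.mu2 * loss - params.alpha2
    mean = 0.5 * (d1 + d2)
    half = 0.5 * (d1 - d2)
    root = np.sqrt(half * half + params.alpha1 * params.alpha2)
    return mean + root, mean - root


def potential(params: MutatorParams, landscape: FitnessLandscape,
              x_grid: Optional[np.ndarray] = None) -> PotentialCurve:
    """Evaluate both potential branches on a grid and locate their maxima."""
    if x_grid is None:
        x_grid = np.linspace(-1.0, 1.0, 2001)
    Vp, Vm = _branches(params, landscape, x_grid)
    xp, _ = _maximize_on_interval(lambda t: _branches(params, landscape, t)[0])
    xm, _ = _maximize_on_interval(lambda t: _branches(params, landscape, t)[1])
    return PotentialCurve(x=np.asarray(x_grid, float), V_plus=Vp, V_minus=Vm,
                          argmax_plus=xp, argmax_minus=xm)


def mean_fitness_general(params: MutatorParams,
                         landscape: FitnessLandscape) -> float:
    """Analytic mean fitness R = max_x V_plus(x).

    For alpha1*alpha2 > 0 the upper branch alone carries the Perron mode;
    for uni-directional switching the upper branch is the pointwise max of
    the two decoupled diagonal branches, so its maximum still covers both
    candidate phases.  Not meaningful for single-peak landscapes (use
    :func:`single_peak_solution`).
    """
    if landscape.kind == "single_peak":
        raise ValueError("use single_peak_solution for single-peak landscapes")
    _, val = _maximize_on_interval(
        lambda t: _branches(params, landscape, t)[0])
    return val


def _classical_max(fit: Callable, mu: float) -> tuple[float, float]:
    """max_x [fit(x) - mu (1 - sqrt(1-x^2))] and its maximizer."""
    def fun(x):
        return np.asarray(fit(x), float) - mu * (1.0 - _sqrt1mx2(x))
    xstar, val = _maximize_on_interval(fun)
    return val, xstar


def mixed_phase_fitness(params: MutatorParams,
                        landscape: FitnessLandscape) -> float:
    """R_mix = max_x [f(x) - mu1 (1 - sqrt(1-x^2))] - alpha1 (alpha2 = 0)."""
    if not params.uni_directional:
        raise ValueError("mixed-phase closed form requires alpha2 = 0")
    val, _ = _classical_max(landscape.f, params.mu1)
    return val - params.alpha1


def mutator_phase_fitness(params: MutatorParams,
                          landscape: FitnessLandscape) -> float:
    """R_mu = max_x [g(x) - mu2 (1 - sqrt(1-x^2))]."""
    val, _ = _classical_max(landscape.g, params.mu2)
    return val


def linear_border_slope(mu1: float, mu2: float, a: float,
                        k_hi: float = 50.0) -> float:
    """Critical slope k_c where the mixed and mutator mean fitness cross.

    Solves sqrt(k^2+mu1^2) - mu1 - a = sqrt(k^2+mu2^2) - mu2 by bisection;
    requires mu2 > mu1 and 0 < a < mu2 - mu1.
    """
    def diff(k):
        return (math.sqrt(k * k + mu1 * mu1) - mu1 - a
                - (math.sqrt(k * k + mu2 * mu2) - mu2))
    if not (mu2 > mu1 and 0.0 < a < mu2 - mu1):
        raise ValueError("border requires mu2 > mu1 and 0 < a < mu2 - mu1")
    return brentq(diff, 1e-12, k_hi, xtol=1e-12)


# ---------------------------------------------------------------------------
# surplus and mutator fraction for bidirectional switching

def surplus_and_ratio(params: MutatorParams, landscape: FitnessLandscape,
                      R: Optional[float] = None
                      ) -> tuple[float, float, float]:
    """Surplus s, component ratio v2/v1 and infinite-L mutator fraction q.

    With alpha1*alpha2 != 0 both sub-populations peak at the same surplus
    (s1 = s2 = s), determined by requiring the zero-momentum 2x2 matrix
    [[f(s)-a1, a2], [a1, g(s)-a2]] to have R as its top eigenvalue.  The
    eigenvector gives the component ratio and q = v2/(v1+v2).  For f = g
    this reduces to f(s) = R and q = alpha1/(alpha1+alpha2).
    """
    a1, a2 = params.alpha1, params.alpha2
    if a1 * a2 == 0.0:
        raise ValueError("surplus_and_ratio requires alpha1 * alpha2 != 0")
    if R is None:
        R = mean_fitness_general(params, landscape)

    def top(x):
        x = np.asarray(x, dtype=float)
        d1 = np.asarray(landscape.f(x), float) - a1
        d2 = np.asarray(landscape.g(x), float) - a2
        mean = 0.5 * (d1 + d2)
        half = 0.5 * (d1 - d2)
        return mean + np.sqrt(half * half + a1 * a2)

    xs = np.linspace(-1.0, 1.0, 4001)
    vals = top(xs) - R
    sign = np.sign(vals)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size == 0:
        raise ValueError("no stationary surplus in (-1, 1): boundary-dominated")
    i = crossings[-1]  # rightmost root (ties toward larger x)
    s = brentq(lambda t: float(top(t) - R), xs[i], xs[i + 1], xtol=1e-14)
    fs = float(np.asarray(landscape.f(np.array([s])), float)[0])
    ratio = (R - fs + a1) / a2
    q = ratio / (1.0 + ratio)
    return float(s), float(ratio), float(q)


# ---------------------------------------------------------------------------
# phases

@dataclass
class PhaseResult:
    """Phase label plus analytic mean fitness and order parameters."""

    phase: str
    R: float
    s: Optional[float] = None
    s1: Optional[float] = None
    s2: Optional[float] = None
    q: Optional[float] = None
    method: dict = field(default_factory=dict)


def single_peak_solution(J: float, a: float, mu: float,
                         mu1: float = 1.0) -> PhaseResult:
    """Closed-form phase structure of the single-peak landscape.

    Candidate mean fitnesses are R_mix = J - mu1 - a, R_mu = J - mu and
    R_ns = 0; the realized phase maximizes them.  Parameters exactly on a
    border (a = J - mu1, mu = J, a + mu1 = mu) return a border label.  In
    the mixed phase the wild-chain class weights are geometric,
    P_l = P_0 J^{-l}, with P_0 = ((J-mu1-a)/J) (mu-mu1-a)/(mu-mu1), and
    the L -> infinity mutator fraction is
    q = 1 - (J-mu1-a)(mu-mu1-a) / ((J-mu1)(mu-mu1)).
    """
    if J <= 0:
        raise ValueError("single-peak height J must be positive")
    R_mix = J - mu1 - a
    R_mu = J - mu
    R_ns = 0.0
    cands = {"mixed": R_mix, "mutator": R_mu, "non_selective": R_ns}
    best = max(cands.values())
    winners = [k for k, v in cands.items() if abs(v - best) <= BORDER_TOL]
    if len(winners) > 1:
        return PhaseResult(phase="border:" + "-".join(sorted(winners)), R=best,
                           method={"R": "tied closed forms"})
    phase = winners[0]
    if phase == "non_selective":
        return PhaseResult(phase=phase, R=0.0, s=0.0, q=None,
                           method={"R": "R_ns = 0", "s": "non-selective"})
    if phase == "mutator":
        return PhaseResult(phase=phase, R=R_mu, s=1.0, s2=1.0, q=1.0,
                           method={"R": "R_mu = J - mu"})
    P0 = ((J - mu1 - a) / J) * (mu - mu1 - a) / (mu - mu1)
    one_minus_q = P0 * J / (J - mu1)
    q = 1.0 - one_minus_q
    return PhaseResult(phase="mixed", R=R_mix, s=1.0, s1=1.0, s2=1.0, q=q,
                       method={"R": "R_mix = J - mu1 - a",
                               "q": "geometric wild chain, L -> infinity",
                               "P0": P0})


def classify_phase(params: MutatorParams,
                   landscape: FitnessLandscape) -> PhaseResult:
    """Phase label and analytic observables at a parameter point.

    Uni-directional switching gives the three-phase structure; with back
    mutation present (alpha2 > 0) the potential maximum and the
    stationarity condition at the common surplus determine R, s and q.
    """
    if landscape.kind == "single_peak":
        return single_peak_solution(float(landscape.params["J"]),
                                    params.alpha1, params.mu2, params.mu1)
    if not params.uni_directional:
        R = mean_fitness_general(params, landscape)
        s, ratio, q = surplus_and_ratio(params, landscape, R)
        phase = "non_selective" if abs(s) < 1e-9 else "mixed"
        return PhaseResult(phase=phase, R=R, s=s, s1=s, s2=s, q=q,
                           method={"R": "max V_plus", "q": "v2/(v1+v2)"})
    R_mix = mixed_phase_fitness(params, landscape)
    R_mu = mutator_phase_fitness(params, landscape)
    if abs(R_mix - R_mu) <= 1e-9:
        return PhaseResult(phase="border:mixed-mutator", R=R_mix,
                           method={"R": "R_mix = R_mu"})
    if R_mix > R_mu:
        # bulk of the population is mutator-type; its surplus solves f(s) = R
        s2 = _fitness_level_root(landscape.f, R_mix)
        s1 = _fitness_level_root(landscape.f, R_mix + params.alpha1)
        phase = "mixed"
        if s2 is not None and abs(s2) < 1e-9:
            phase = "non_selective"
        return PhaseResult(phase=phase, R=R_mix, s=s2, s1=s1, s2=s2, q=None,
                           method={"R": "V_plus branch (wild) - alpha1",
                                   "q": "finite-L: wkb_mutator_fraction"})
    _, xstar = _classical_max(landscape.g, params.mu2)
    s2 = _fitness_level_root(landscape.g, R_mu)
    phase = "mutator" if abs(xstar) > 1e-9 else "non_selective"
    return PhaseResult(phase=phase, R=R_mu, s=s2 if phase == "mutator" else 0.0,
                       s2=s2, q=1.0, method={"R": "classical chain at mu2"})


def _fitness_level_root(fit: Callable, level: float,
                        lo: float = -1.0, hi: float = 1.0) -> Optional[float]:
    """Rightmost solution of fit(x) = level on [lo, hi] (None if absent)."""
    xs = np.linspace(lo, hi, 4001)
    vals = np.asarray(fit(xs), float) - level
    sign = np.sign(vals)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size == 0:
        return None
    i = crossings[-1]
    return float(brentq(lambda t: float(np.asarray(fit(np.array([t])))[0]) - level,
                        xs[i], xs[i + 1], xtol=1e-14))


# ---------------------------------------------------------------------------
# WKB mutator fraction (uni-directional, smooth landscape, mixed phase)

@dataclass
class WKBResult:
    """Finite-L fate of the wild allele from the WKB concatenation.

    ``exponent`` is L*W with W the log-gain of the mutator peak over the
    wild peak; K = exp(-exponent) is the exponential discriminant: K near
    1 means the wild type keeps a finite share, K << 1 means the mutator
    allele takes over.  ``one_minus_q`` includes the Gaussian-width
    prefactor; the exponent is the asymptotically exact part.
    """

    one_minus_q: float
    K: float
    s1: float
    s2: float
    s3: float
    exponent: float
    validity: bool


def wkb_mutator_fraction(params: MutatorParams, landscape: FitnessLandscape,
                         L: Optional[int] = None) -> WKBResult:
    """Wild-allele fraction 1 - q of the uni-directional model at finite L.

    The wild chain's stationary Hamilton-Jacobi profile u(x) peaks at s1
    (f(s1) = R + alpha1).  The driven mutator chain follows the wild
    profile on [s3, 1] where Q_l ~ a P_l / [(mu2-mu1)(f-R) - mu2 a], and
    switches at s3 (where that denominator vanishes, equivalently where
    the two WKB momenta match smoothly) onto its own homogeneous branch,
    which climbs to the mutator peak s2 (f(s2) = R).  The accumulated
    log-gain W = u(s3) + int_{s2}^{s3} |u_Q'(x)| dx sets
    q/(1-q) ~ (a/Delta) sqrt(u''(s1)/u_Q''(s2)) e^{L W}.
    """
    if not params.uni_directional:
        raise ValueError("WKB analysis applies to alpha2 = 0")
    if landscape.kind == "single_peak":
        raise ValueError("WKB analysis requires a smooth landscape")
    if "g_params" in landscape.params:
        raise ValueError("WKB analysis implemented for f = g")
    if params.mu2 <= params.mu1:
        raise ValueError("mutator must raise the mutation rate (mu2 > mu1)")
    L = params.L if L is None else int(L)
    mu1, mu2, a = params.mu1, params.mu2, params.alpha1
    f = landscape.f
    R = mixed_phase_fitness(params, landscape)
    R_mu = mutator_phase_fitness(params, landscape)
    delta = R - R_mu
    if a == 0.0:
        return WKBResult(one_minus_q=1.0, K=1.0, s1=float("nan"),
                         s2=float("nan"), s3=float("nan"), exponent=0.0,
                         validity=True)
    if delta <= 0:
        raise ValueError("parameters are not in the mixed phase")
    s1 = _fitness_level_root(f, R + a)
    s2 = _fitness_level_root(f, R)
    s3 = _fitness_level_root(f, R + mu2 * a / (mu2 - mu1))
    _, xstar = _classical_max(f, mu1)
    ok = (s1 is not None and s2 is not None and s3 is not None
          and s2 < s1 < s3 < 1.0 and s3 < xstar + 1e-9)

    def momentum(x, B_of_x):
        B = B_of_x(x)
        disc = B * B - (1.0 - x * x)
        if disc < 0:
            raise ValueError("WKB branch turned complex; outside validity")
        return 0.5 * math.log((B + math.sqrt(disc)) / (1.0 + x))

    if not ok:
        return WKBResult(one_minus_q=float("nan"), K=float("nan"),
                         s1=s1 or float("nan"), s2=s2 or float("nan"),
                         s3=s3 or float("nan"), exponent=float("nan"),
                         validity=False)

    def fx(x):
        return float(np.asarray(f(np.array([x])), float)[0])

    B_wild = lambda x: (R + mu1 + a - fx(x)) / mu1
    B_mut = lambda x: (R + mu2 - fx(x)) / mu2
    u_s3 = quad(lambda x: momentum(x, B_wild), s1, s3, limit=400)[0]
    gain = quad(lambda x: momentum(x, B_mut), s2, s3, limit=400)[0]
    W = u_s3 - gain          # gain < 0: the homogeneous branch climbs
    exponent = L * W
    K = math.exp(-exponent)
    eps = 1e-6
    fp1 = (fx(s1 + eps) - fx(s1 - eps)) / (2 * eps)
    fp2 = (fx(s2 + eps) - fx(s2 - eps)) / (2 * eps)
    curv_ratio = (fp1 / (2.0 * mu1 * s1)) / (fp2 / (2.0 * mu2 * s2))
    ratio = (a / delta) * math.sqrt(abs(curv_ratio)) * math.exp(exponent)
    return WKBResult(one_minus_q=1.0 / (1.0 + ratio), K=K, s1=s1, s2=s2,
                     s3=s3, exponent=exponent, validity=True)


def small_a_asymptotics(k: float, a: float, mu: float, L: int,
                        mu1: float = 1.0) -> dict:
    """Closed-form 1 - q for linear fitness at small a and large mu/mu1.

    Expanding the WKB exponent quadratically around the common peak
    s* = (sqrt(k^2+mu1^2) - mu1)/k gives W ~ a^2 / (4 k s* (mu - mu1)),
    so q/(1-q) ~ (a/Delta0) sqrt(mu/mu1) e^{L W}.  The crossover genome
    length L* = 1/W separates the small-L regime (mutators a small
    minority, q ~ a/Delta0) from the large-L regime where the mutator
    allele takes over exponentially.
    """
    if k <= 0:
        raise ValueError("linear slope k must be positive")
    sstar = (math.sqrt(k * k + mu1 * mu1) - mu1) / k
    W = a * a / (4.0 * k * sstar * (mu - mu1))
    delta0 = ((math.sqrt(k * k + mu1 * mu1) - mu1)
              - (math.sqrt(k * k + mu * mu) - mu))
    exponent = L * W
    ratio = (a / delta0) * math.sqrt(mu / mu1) * math.exp(exponent)
    one_minus_q = 1.0 / (1.0 + ratio)
    validity = (a <= 0.5 * delta0) and (mu >= 5.0 * mu1)
    return {"one_minus_q": one_minus_q, "exponent": exponent,
            "L_crossover": math.inf if W == 0 else 1.0 / W,
            "validity": validity}


# ---------------------------------------------------------------------------
# d-dimensional landscapes

def multidim_potential(parts: Sequence[CompositePart], alpha1: float,
                       alpha2: float) -> tuple[float, np.ndarray, Callable]:
    """Mean fitness of an additive multi-part genome with a mutator gene.

    Each part i contributes fitness f_i(x_i) (wild) / g_i(x_i) (mutator)
    and mutation loss mu_i / nu_i times (1 - sqrt(1-x_i^2)); the 2x2
    switch structure is unchanged.  R is the maximum of V_plus over the
    free coordinates (pinned/lethal parts are confined to x_i = 1).
    Returns (R, maximizing x vector, V_plus callable).
    """
    parts = tuple(parts)
    d = len(parts)
    if d > 4:
        raise ValueError("grid optimizer supports d <= 4")
    free = [i for i, p in enumerate(parts) if not p.pinned]

    def V_plus(xvec: np.ndarray) -> float:
        xvec = np.asarray(xvec, dtype=float)
        d1 = -alpha1
        d2 = -alpha2
        for p, xi in zip(parts, xvec):
            loss = 1.0 - math.sqrt(max(1.0 - xi * xi, 0.0))
            d1 += float(np.asarray(p.f(np.array([xi])), float)[0]) - p.mu * loss
            d2 += float(np.asarray(p.g(np.array([xi])), float)[0]) - p.nu * loss
        mean = 0.5 * (d1 + d2)
        half = 0.5 * (d1 - d2)
        return mean + math.sqrt(half * half + alpha1 * alpha2)

    x0 = np.ones(d)
    if not free:
        return V_plus(x0), x0, V_plus
    npts = {1: 201, 2: 41, 3: 17, 4: 11}[len(free)]
    grids = [np.linspace(-1.0, 1.0, npts)] * len(free)
    best_val = -math.inf
    best = x0.copy()
    for combo in np.stack(np.meshgrid(*grids, indexing="ij"),
                          axis=-1).reshape(-1, len(free)):
        x = x0.copy()
        x[free] = combo
        v = V_plus(x)
        if v > best_val or (v == best_val and np.all(x >= best)):
            best_val, best = v, x.copy()

    def neg(xfree):
        x = x0.copy()
        x[free] = np.clip(xfree, -1.0, 1.0)
        return -V_plus(x)

    res = minimize(neg, best[free], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
    if -res.fun > best_val:
        best_val = -res.fun
        best[free] = np.clip(res.x, -1.0, 1.0)
    return float(best_val), best, V_plus


# ---------------------------------------------------------------------------
# phase diagram grids

def phase_diagram_single_peak(J: float, a_values: Sequence[float],
                              mu_values: Sequence[float], mu1: float = 1.0):
    """Tabulate (a, mu, phase, R, s, q) over a grid for the single peak."""
    import pandas as pd

    rows = []
    for a in a_values:
        for mu in mu_values:
            r = single_peak_solution(J, a, mu, mu1=mu1)
            rows.append({"a": a, "mu": mu, "phase": r.phase, "R": r.R,
                         "s": r.s, "q": r.q})
    return pd.DataFrame(rows)
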
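"""The Eigen-model variant of the mutator-gene quasispecies.

Here replication and mutation are coupled: an offspring genome is copied
with per-nucleotide errorless probability w (wild type) or w^mu (mutator
type), giving the per-genome mutation kernel
Q_ij = w^{L-d(i,j)} (1-w)^{d(i,j)} with d the Hamming distance.  Fitness
is Wrightian (multiplicative per generation), background 1, peak A.  The
wild chain is damped by e^{-h} per replication, the complementary flux
1 - e^{-h} feeding the mutator chain (no back switching, matching the
uni-directional parallel model).

For symmetric (class-dependent) fitness the mutation kernel reduces
exactly to Hamming classes through a two-binomial convolution, which is
what makes L ~ 10^3 tractable and provides the small-L brute-force
oracle equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

from .landscapes import class_grid, lognormal_effective_peak_height
from .params import CKEigenMapping, EigenParams, MutatorParams


# ---------------------------------------------------------------------------
# mutation kernels

def class_kernel(L: int, w: float) -> np.ndarray:
    """Class-to-class mutation matrix M[l, l'] = P(class l' -> class l).

    From a parent in class l', the number of back flips among its l'
    mutated sites is Binomial(l', 1-w) and the number of new forward
    flips Binomial(L-l', 1-w); the exact class kernel is their (reversed)
    convolution.  Columns sum to 1 by construction (binomial identity).
    """
    if not 0.0 < w <= 1.0:
        raise ValueError(f"w must be in (0, 1], got {w!r}")
    from scipy.signal import fftconvolve

    M = np.zeros((L + 1, L + 1))
    p = 1.0 - w
    conv = np.convolve if L <= 256 else fftconvolve
    for lp in range(L + 1):
        back = binom.pmf(np.arange(lp + 1), lp, p)
        fwd = binom.pmf(np.arange(L - lp + 1), L - lp, p)
        col = conv(fwd, back[::-1])
        M[:, lp] = np.clip(col[:L + 1], 0.0, None)
    return M


def _popcount_table(L: int) -> np.ndarray:
    counts = np.zeros(2 ** L, dtype=np.int64)
    idx = np.arange(2 ** L, dtype=np.uint64)
    for b in range(L):
        counts += ((idx >> np.uint64(b)) & np.uint64(1)).astype(np.int64)
    return counts


def sequence_kernel(L: int, w: float) -> np.ndarray:
    """Full 2^L x 2^L mutation matrix Q_ij = w^{L-d} (1-w)^d (L <= 12)."""
    if L > 12:
        raise ValueError("sequence kernel limited to L <= 12")
    lut = _popcount_table(L)
    idx = np.arange(2 ** L)
    D = lut[np.bitwise_xor.outer(idx, idx)]
    return w ** (L - D) * (1.0 - w) ** D


def _class_fitness(params: EigenParams,
                   r: Optional[np.ndarray] = None) -> np.ndarray:
    """Wrightian fitness per class; default is the single peak (A, 1, ..)."""
    if r is None:
        r = np.ones(params.L + 1)
        r[0] = params.A
    else:
        r = np.asarray(r, dtype=float)
        if r.shape != (params.L + 1,):
            raise ValueError("class fitness must have length L+1")
    return r


# ---------------------------------------------------------------------------
# analytic mean fitness and borders

def eigen_continuous_R(params: EigenParams,
                       landscape=None) -> tuple[float, str]:
    """Analytic mean fitness of the coupled model and its phase.

    Candidates: the mixed phase inherits the classical Eigen mean fitness
    of the wild chain damped by e^{-h}; the mutator phase is the classical
    value at mutation parameter mu*gamma; the non-selective value is the
    background fitness 1.  For the single-peak landscape these are
    A e^{-(h+gamma)}, A e^{-mu gamma} and 1.  A smooth symmetric Wrightian
    landscape f(x) may be supplied instead, in which case the classical
    expression max_x f(x) e^{-gamma (1 - sqrt(1-x^2))} is used per chain.
    """
    g, mu, h, A = params.gamma, params.mu, params.h, params.A
    if landscape is None or getattr(landscape, "kind", None) == "single_peak":
        if landscape is not None:
            A = float(landscape.params["J"])
        R_mix = A * math.exp(-(h + g))
        R_mu = A * math.exp(-mu * g)
        R_ns = 1.0
    else:
        from .phase import _maximize_on_interval

        def damped(fit, gam):
            fn = lambda x: np.asarray(fit(x), float) * np.exp(
                -gam * (1.0 - np.sqrt(np.clip(1 - np.asarray(x) ** 2, 0, None))))
            return _maximize_on_interval(fn)[1]

        R_mix = math.exp(-h) * damped(landscape.f, g)
        R_mu = damped(landscape.g, mu * g)
        R_ns = 1.0
    cands = {"mixed": R_mix, "mutator": R_mu, "non_selective": R_ns}
    phase = max(cands, key=cands.get)
    ties = [k for k, v in cands.items() if abs(v - cands[phase]) <= 1e-12]
    if len(ties) > 1:
        phase = "border:" + "-".join(sorted(ties))
    return cands[max(cands, key=cands.get)], phase


def eigen_phase_borders(A: float, mu: float) -> dict:
    """The three phase borders in the (gamma, h) plane and the triple point.

    non-selective / mutator: mu*gamma = ln A  (vertical line)
    non-selective / mixed:   h = ln A - gamma
    mixed / mutator:         h = (mu - 1) gamma
    """
    if A <= 1:
        raise ValueError("peak fitness A must exceed the background 1")
    lnA = math.log(A)
    gamma_star = lnA / mu
    return {
        "ns_mutator_gamma": gamma_star,
        "ns_mixed": lambda gamma: lnA - np.asarray(gamma, dtype=float),
        "mixed_mutator": lambda gamma: (mu - 1.0) * np.asarray(gamma, dtype=float),
        "triple_point": (gamma_star, (mu - 1.0) * gamma_star),
    }


# ---------------------------------------------------------------------------
# single-peak mutator fraction

def eigen_single_peak_q(params: EigenParams) -> dict:
    """Mutator-allele fraction in the mixed phase of the single peak.

    Master-class balance (back mutations dropped, O(1/L)):
    R = Q A e^{-h};  P (Re^h - 1) = (A-1) p0;
    q0 = (1 - e^{-h}) Q A p0 / (R - A e^{-mu gamma});
    Qm (R - 1) = (A-1) q0 + (e^h - 1) R P;  q = Qm / (Qm + P).
    """
    g, mu, h, A = params.gamma, params.mu, params.h, params.A
    Q = math.exp(-g)
    R = Q * A * math.exp(-h)
    if R <= 1.0 or Q * A <= 1.0:
        raise ValueError("parameters are outside the mixed (selective) phase")
    if R <= A * math.exp(-mu * g):
        raise ValueError("mutator phase dominates; mixed-phase algebra invalid")
    p0 = 1.0
    P = p0 * (A - 1.0) / (Q * A - 1.0)
    q0 = (1.0 - math.exp(-h)) * Q * A * p0 / (R - A * math.exp(-mu * g))
    Qm = ((A - 1.0) * q0 + (math.exp(h) - 1.0) * R * P) / (R - 1.0)
    q = Qm / (Qm + P)
    return {"q": q, "R": R, "p0_over_P": p0 / P, "q0_over_P": q0 / P}


def eigen_single_peak_q_smallparam(params: EigenParams) -> float:
    """Leading small-parameter form q ~ h / (A - 1 - gamma).

    Valid for h << 1, gamma << 1 and A - 1 << 1 (the regime where the
    model maps onto one generation of the parallel model); the h/mu term
    is dropped.
    """
    denom = params.A - 1.0 - params.gamma
    if denom <= 0:
        raise ValueError("requires A - 1 > gamma (selective phase)")
    return params.h / denom


# ---------------------------------------------------------------------------
# discrete-time iteration

@dataclass
class EigenTrajectory:
    p: np.ndarray              # wild-class occupancies per step (n+1, L+1)
    q: np.ndarray              # mutator-class occupancies
    growth: np.ndarray         # pre-normalization growth factor per step


def eigen_discrete_iterate(params: EigenParams,
                           initial: Optional[tuple[np.ndarray, np.ndarray]] = None,
                           n_steps: int = 100,
                           r: Optional[np.ndarray] = None,
                           reduced: bool = True) -> EigenTrajectory:
    """Iterate the discrete-time coupled model.

    p' = e^{-h} M_w (r p);  q' = M_m (r q) + (1 - e^{-h}) M_w (r p),
    renormalized each step; the growth factor converges to the dominant
    eigenvalue of the transfer matrix (the continuous-time R).  With
    ``reduced=False`` the full 2^L sequence space is iterated (L <= 12);
    class aggregation of that trajectory matches the reduced one exactly
    for symmetric fitness.
    """
    L = params.L
    rcls = _class_fitness(params, r)
    if reduced:
        M = class_kernel(L, params.w)
        Mm = class_kernel(L, params.w_mutator)
        rvec = rcls
        size = L + 1
        if initial is None:
            p = np.zeros(size); p[0] = 1.0
            q = np.zeros(size)
        else:
            p, q = (np.asarray(v, dtype=float).copy() for v in initial)
    else:
        if L > 12:
            raise ValueError("full iteration limited to L <= 12")
        M = sequence_kernel(L, params.w)
        Mm = sequence_kernel(L, params.w_mutator)
        lut = _popcount_table(L)
        rvec = rcls[lut]
        size = 2 ** L
        if initial is None:
            p = np.zeros(size); p[0] = 1.0
            q = np.zeros(size)
        else:
            p, q = (np.asarray(v, dtype=float).copy() for v in initial)
    eh = math.exp(-params.h)
    ps, qs, growth = [p.copy()], [q.copy()], []
    for _ in range(n_steps):
        born_w = M @ (rvec * p)
        pn = eh * born_w
        qn = Mm @ (rvec * q) + (1.0 - eh) * born_w
        tot = pn.sum() + qn.sum()
        growth.append(tot / (p.sum() + q.sum()))
        p, q = pn / tot, qn / tot
        ps.append(p.copy())
        qs.append(q.copy())
    return EigenTrajectory(p=np.array(ps), q=np.array(qs),
                           growth=np.array(growth))


def transfer_matrix(params: EigenParams,
                    r: Optional[np.ndarray] = None) -> np.ndarray:
    """Dense class-reduced transfer matrix of the discrete iteration."""
    L = params.L
    rcls = _class_fitness(params, r)
    M = class_kernel(L, params.w) * rcls[None, :]
    Mm = class_kernel(L, params.w_mutator) * rcls[None, :]
    eh = math.exp(-params.h)
    top = np.hstack([eh * M, np.zeros_like(M)])
    bottom = np.hstack([(1.0 - eh) * M, Mm])
    return np.vstack([top, bottom])


def transfer_matrix_top(params: EigenParams,
                        r: Optional[np.ndarray] = None) -> float:
    """Dominant eigenvalue of the discrete transfer matrix.

    The transfer matrix is block triangular (no back switching), so its
    spectrum is the union of the two block spectra; each block M diag(r)
    is exactly symmetrizable by d_l sqrt(r_l) with d_l = sqrt(C(L, l))
    (the kernel is reversible for the binomial weights), so the top
    eigenvalue is computed by a well-conditioned symmetric eigensolve.
    Limited to L <= 500 where the similarity weights stay in range.
    """
    L = params.L
    if L > 500:
        raise ValueError("symmetrized transfer eigensolve limited to L <= 500")
    rcls = _class_fitness(params, r)
    if np.any(rcls <= 0):
        raise ValueError("requires strictly positive Wrightian fitness")
    from scipy.special import gammaln

    l = np.arange(L + 1)
    logd = 0.5 * (gammaln(L + 1) - gammaln(l + 1) - gammaln(L - l + 1))
    # the kernel is reversible wrt the binomial weights d^2, so
    # M diag(r) is symmetrized by c_l = sqrt(r_l) / d_l
    scale = np.sqrt(rcls) * np.exp(-logd)

    def block_top(w):
        M = class_kernel(L, w) * rcls[None, :]
        S = M * (scale[:, None] / scale[None, :])
        S = 0.5 * (S + S.T)   # symmetric up to roundoff
        return float(np.linalg.eigvalsh(S)[-1])

    eh = math.exp(-params.h)
    return max(eh * block_top(params.w), block_top(params.w_mutator))


# ---------------------------------------------------------------------------
# random (log-normal) landscape

def lognormal_effective_peak(params: EigenParams, variance: float,
                             mean: float = 0.0) -> tuple[float, float]:
    """Effective single-peak height of a log-normal landscape and its q.

    The 2^L i.i.d. log-normal Wrightian draws are dominated by their
    maximum A_max = exp(mean + sigma sqrt(2 L ln 2)) while the bulk sits
    at fitness ~ 1, so the random landscape behaves like a single peak of
    height A_max; q follows from the single-peak algebra.
    """
    A_max = lognormal_effective_peak_height(params.L, variance, mean=mean)
    p = EigenParams(L=params.L, gamma=params.gamma, mu=params.mu,
                    h=params.h, A=A_max)
    try:
        q = eigen_single_peak_q(p)["q"]
    except ValueError:
        q = None                     # outside the mixed (selective) phase
    return A_max, q


# ---------------------------------------------------------------------------
# Crow-Kimura <-> Eigen mapping

def ck_eigen_map(params: MutatorParams, J: float, tau: float) -> EigenParams:
    """Map the parallel model observed per generation tau to Eigen form.

    gamma = tau mu1, mutator ratio mu2/mu1, h = tau alpha1, and Wrightian
    peak A = exp(tau J) (background Malthusian fitness 0 -> Wrightian 1).
    Exact for single-peak mean fitness: R_eigen = exp(tau R_ck) in every
    phase, so the phase borders map onto each other.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if params.mu1 <= 0:
        raise ValueError("mapping requires mu1 > 0")
    return EigenParams(L=params.L, gamma=tau * params.mu1,
                       mu=params.mu2 / params.mu1,
                       h=tau * params.alpha1, A=math.exp(tau * J))


def eigen_ck_map(params: EigenParams, tau: float) -> tuple[MutatorParams, float]:
    """Inverse of :func:`ck_eigen_map`; returns (MutatorParams, J)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    mu1 = params.gamma / tau
    return (MutatorParams(L=params.L, mu1=mu1, mu2=params.mu * mu1,
                          alpha1=params.h / tau, alpha2=0.0),
            math.log(params.A) / tau)


def mapping_record(params: MutatorParams, J: float, tau: float) -> CKEigenMapping:
    return CKEigenMapping(tau=tau, U=tau * params.mu1, S=tau * J,
                          h=tau * params.alpha1)
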
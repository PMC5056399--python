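"""Exact finite-genome numerics for the two-chain mutator model.

The linearized system couples two birth-death chains over Hamming classes
l = 0..L (wild-type chain P, mutator chain Q).  Class transitions carry the
combinatorial coefficients (L - l + 1) and (l + 1) on the per-site rate
mu/L; the chains are coupled by the switch rates alpha1 (P -> Q) and
alpha2 (Q -> P).  The steady state of the nonlinear model is the dominant
eigenpair of this operator; the mean fitness R is its Perron eigenvalue.

The class operator is strongly non-normal (its eigenvector matrix is
exponentially ill-conditioned in L), so generic nonsymmetric eigensolvers
return pseudo-eigenpairs with deceptively small residuals.  Both chains
are, however, exactly symmetrized by the same diagonal similarity
d_l = sqrt(C(L, l)) (the Ehrenfest weights), and for alpha1*alpha2 > 0 an
additional sqrt(alpha2/alpha1) scaling of the mutator block renders the
whole coupled operator symmetric pentadiagonal.  All dominant eigenpairs
are therefore computed in the symmetric basis (LAPACK banded selected
eigensolve / Lanczos) and transformed back in log space, which is
backward-stable and resolves eigenvector components over hundreds of
orders of magnitude.  For uni-directional switching the operator is block
triangular: the spectrum is the union of the two symmetric block spectra
and the driven chain follows from an M-matrix banded solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded
from scipy.sparse.linalg import splu

from .landscapes import FitnessLandscape, class_grid
from .params import MutatorParams
from .state import Observables, PopulationState, observables


class ConvergenceError(RuntimeError):
    """Eigen-iteration failed; carries the iteration count."""

    def __init__(self, message: str, iterations: int):
        super().__init__(f"{message} (after {iterations} iterations)")
        self.iterations = iterations


@dataclass
class LinearOperator2Chain:
    """The 2(L+1)-dimensional linear operator in interleaved ordering.

    Component 2l is P_l, component 2l+1 is Q_l, which keeps the matrix
    pentadiagonal (class transitions at offsets +-2, switch couplings at
    +-1).  Off-diagonal entries are non-negative (Metzler structure), so
    a diagonal shift makes the matrix non-negative and Perron-Frobenius
    applies.
    """

    params: MutatorParams
    landscape: FitnessLandscape
    matrix: sp.csr_matrix
    fitness: np.ndarray  # interleaved (f(x_0), g(x_0), f(x_1), ...)

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self.matrix @ v

    def split(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Deinterleave a vector into (P, Q) chain components."""
        return v[0::2], v[1::2]

    def interleave(self, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
        v = np.empty(2 * (self.params.L + 1))
        v[0::2] = P
        v[1::2] = Q
        return v


def build_operator(params: MutatorParams,
                   landscape: FitnessLandscape) -> LinearOperator2Chain:
    """Assemble the coupled two-chain operator for the linearized system."""
    L = params.L
    l = np.arange(L + 1)
    fv, gv = landscape.profile(L)
    # inflow to class l from l-1 carries (L - (l-1)) = (L - l + 1); from l+1
    # carries (l + 1); per-site rate is the per-genome rate divided by L.
    sub = (L - (l[1:] - 1)) / L          # coefficient on P_{l-1}
    sup = (l[:-1] + 1) / L               # coefficient on P_{l+1}
    n = 2 * (L + 1)
    diag = np.empty(n)
    diag[0::2] = fv - params.mu1 - params.alpha1
    diag[1::2] = gv - params.mu2 - params.alpha2
    off_p1 = np.zeros(n - 1)             # offset +1
    off_p1[0::2] = params.alpha2         # (P_l, Q_l) coupling
    off_m1 = np.zeros(n - 1)             # offset -1
    off_m1[0::2] = params.alpha1         # (Q_l, P_l) coupling
    off_p2 = np.zeros(n - 2)             # offset +2: class l <- l+1
    off_p2[0::2] = params.mu1 * sup
    off_p2[1::2] = params.mu2 * sup
    off_m2 = np.zeros(n - 2)             # offset -2: class l <- l-1
    off_m2[0::2] = params.mu1 * sub
    off_m2[1::2] = params.mu2 * sub
    A = sp.diags([off_m2, off_m1, diag, off_p1, off_p2], [-2, -1, 0, 1, 2],
                 format="csr")
    fitness = np.empty(n)
    fitness[0::2] = fv
    fitness[1::2] = gv
    return LinearOperator2Chain(params=params, landscape=landscape,
                                matrix=A, fitness=fitness)


# ---------------------------------------------------------------------------
# Perron eigenpair

def _log_binom_sqrt(L: int) -> np.ndarray:
    """log d_l with d_l = sqrt(C(L, l)), the chain-symmetrizing weights."""
    from scipy.special import gammaln

    l = np.arange(L + 1)
    return 0.5 * (gammaln(L + 1) - gammaln(l + 1) - gammaln(L - l + 1))


def _sym_offdiag(L: int) -> np.ndarray:
    """Symmetrized class coupling sqrt((l+1)(L-l))/L between l and l+1."""
    l = np.arange(L)
    return np.sqrt((l + 1.0) * (L - l)) / L


def _chain_top_value(L: int, mu: float, outflow: float,
                     fit: np.ndarray) -> float:
    """Top eigenvalue of one chain via its symmetrized tridiagonal form."""
    from scipy.linalg import eig_banded

    ab = np.zeros((2, L + 1))
    ab[1] = fit - mu - outflow
    ab[0, 1:] = mu * _sym_offdiag(L)
    w = eig_banded(ab, lower=False, eigvals_only=True, select="i",
                   select_range=(L, L))
    return float(w[0])


def _coupled_top_value(params: MutatorParams, fv: np.ndarray,
                       gv: np.ndarray) -> float:
    """Top eigenvalue of the coupled symmetric form (alpha1*alpha2 > 0)."""
    from scipy.linalg import eig_banded

    L = params.L
    n = 2 * (L + 1)
    off = _sym_offdiag(L)
    ab = np.zeros((3, n))
    ab[2, 0::2] = fv - params.mu1 - params.alpha1
    ab[2, 1::2] = gv - params.mu2 - params.alpha2
    ab[1, 1::2] = np.sqrt(params.alpha1 * params.alpha2)
    ab[0, 2::2] = params.mu1 * off
    ab[0, 3::2] = params.mu2 * off
    w = eig_banded(ab, lower=False, eigvals_only=True, select="i",
                   select_range=(n - 1, n - 1))
    return float(w[0])


def _inverse_iterate(A: sp.spmatrix, lam: float, tol: float = 1e-10,
                     maxit: int = 10) -> tuple[np.ndarray, float, int]:
    """Perron eigenvector by inverse iteration at a known eigenvalue.

    With the shift a hair above lam, (t I - A) is an M-matrix, so the
    solves preserve positivity and amplify the Perron direction by
    1/(t - lam).  The iteration is monitored through the residual (the
    operator is non-normal, so a handful of iterations may be needed to
    purge pseudo-mode contamination); components below the underflow
    range of the peak come out as exact zeros.
    """
    n = A.shape[0]
    t = lam + 1e-12 * max(1.0, abs(lam))
    lu = splu((t * sp.identity(n, format="csc") - A.tocsc()).tocsc(),
              permc_spec="COLAMD")
    v = np.ones(n) / n
    best, best_res = None, np.inf
    for it in range(1, maxit + 1):
        v = lu.solve(v)
        if not np.all(np.isfinite(v)):
            raise ConvergenceError("inverse iteration overflow", it)
        v = np.clip(v, 0.0, None)
        s = v.sum()
        if s == 0:
            raise ConvergenceError("inverse iteration collapsed", it)
        v /= s
        res = float(np.linalg.norm(A @ v - lam * v) / np.linalg.norm(v))
        if res < best_res:
            best, best_res = v, res
        if res <= tol * max(1.0, abs(lam)):
            return v, res, it
    if best_res <= 1e-8 * max(1.0, abs(lam)):
        warnings.warn(f"inverse iteration stalled at residual {best_res:.2e}")
        return best, best_res, maxit
    raise ConvergenceError(
        f"inverse iteration did not converge (residual {best_res:.2e})", maxit)


@dataclass
class SteadyStateResult:
    """Dominant eigenpair of the linearized system plus observables."""

    R_numeric: float
    state: PopulationState
    observables: Observables
    residual: float
    iterations: int
    degenerate: bool = False

    def summary(self) -> str:
        o = self.observables
        lines = [
            f"mean fitness R      {self.R_numeric: .10f}",
            f"mutator fraction q  {o.q: .6g}",
            f"surplus s           {o.s: .6g}",
            f"surplus s1 (wild)   {o.s1 if o.s1 is not None else 'absent'}",
            f"surplus s2 (mut)    {o.s2 if o.s2 is not None else 'absent'}",
            f"residual            {self.residual:.3e}",
        ]
        if self.degenerate:
            lines.append("warning: near-degenerate block Perron roots")
        return "\n".join(lines)


def steady_state(params: MutatorParams,
                 landscape: FitnessLandscape) -> SteadyStateResult:
    """Steady state of the mutator model as the dominant eigenpair."""
    op = build_operator(params, landscape)
    L = params.L
    fv, gv = landscape.profile(L)
    degenerate = False
    if params.alpha1 > 0.0 and params.alpha2 > 0.0:
        lam = _coupled_top_value(params, fv, gv)
    else:
        # block-triangular: spectrum is the union of the two chain spectra
        lam_p = _chain_top_value(L, params.mu1, params.alpha1, fv)
        lam_q = _chain_top_value(L, params.mu2, params.alpha2, gv)
        degenerate = abs(lam_p - lam_q) < 1e-10
        lam = max(lam_p, lam_q)
    v, res, it = _inverse_iterate(op.matrix, lam)
    P, Q = op.split(v)
    state = PopulationState(P, Q, normalized=True)
    obs = observables(state, landscape)
    return SteadyStateResult(R_numeric=lam, state=state, observables=obs,
                             residual=res, iterations=it,
                             degenerate=degenerate)


# ---------------------------------------------------------------------------
# nonlinear dynamics

@dataclass
class TrajectoryPoint:
    t: float
    state: PopulationState
    observables: Observables


def integrate_nonlinear(params: MutatorParams, landscape: FitnessLandscape,
                        initial: Optional[PopulationState] = None,
                        t_end: float = 100.0,
                        t_eval: Optional[Sequence[float]] = None,
                        rtol: float = 1e-10, atol: float = 1e-12,
                        ) -> list[TrajectoryPoint]:
    """Integrate the nonlinear (normalized) replicator-mutator system.

    The normalized probabilities obey dv/dt = A v - (r.v) v where A is the
    linear two-chain operator and r.v the instantaneous mean fitness, so
    total probability is conserved exactly by the equations; the integrator
    is required to respect it to 1e-9.  Default initial condition is all
    mass in the wild-type reference class.
    """
    op = build_operator(params, landscape)
    if initial is None:
        initial = PopulationState.reference(params.L)
    if not initial.normalized:
        initial = initial.normalize()
    if initial.L != params.L:
        raise ValueError("initial state length does not match params.L")
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    if t_end == 0:
        return [TrajectoryPoint(0.0, initial, observables(initial, landscape))]
    v0 = op.interleave(initial.P, initial.Q)
    A = op.matrix
    Ad = A.toarray()
    r = op.fitness
    ident = np.eye(A.shape[0])

    def rhs(t, v):
        Av = A @ v
        return Av - (r @ v) * v

    def jac(t, v):
        return Ad - (r @ v) * ident - np.outer(v, r)

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 21)
    sol = solve_ivp(rhs, (0.0, float(t_end)), v0, method="LSODA", jac=jac,
                    t_eval=np.asarray(t_eval, dtype=float),
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    out = []
    for tk, vk in zip(sol.t, sol.y.T):
        if vk.min() < -1e-12:
            warnings.warn(
                f"clipping negative probabilities (min {vk.min():.2e}) at t={tk}")
        vk = np.clip(vk, 0.0, None)
        total = vk.sum()
        if abs(total - 1.0) > 1e-9:
            raise RuntimeError(
                f"probability conservation violated at t={tk}: total={total!r}")
        vk = vk / total
        P, Q = op.split(vk)
        st = PopulationState(P, Q, normalized=True)
        out.append(TrajectoryPoint(float(tk), st, observables(st, landscape)))
    return out


# ---------------------------------------------------------------------------
# generation-function solution (linear fitness, uni-directional switching)

def generation_function_solve(params: MutatorParams,
                              landscape: FitnessLandscape
                              ) -> tuple[float, PopulationState]:
    """Exact steady state for f = g = kx with alpha2 = 0.

    The generating function P(z) = sum_l P_l z^l of the wild chain obeys a
    first-order ODE whose polynomial (degree-L) solutions exist only when
    R = sqrt(k^2 + mu1^2) - mu1 - alpha1; then
    P(z) prop. (z + k/mu1 + sqrt((k/mu1)^2 + 1))^L, i.e. the class weights
    are binomial.  The driven mutator chain follows from a tridiagonal
    solve at that R.  Valid in the mixed phase (R above the mutator-chain
    Perron root).
    """
    if landscape.kind != "linear":
        raise ValueError("generation-function solution requires a linear landscape")
    if not params.uni_directional:
        raise ValueError("generation-function solution requires alpha2 = 0")
    if "g_params" in landscape.params:
        raise ValueError("generation-function solution requires f = g")
    k = float(landscape.params["k"])
    mu1, mu2, a = params.mu1, params.mu2, params.alpha1
    L = params.L
    R = np.sqrt(k * k + mu1 * mu1) - mu1 - a
    R_mut = np.sqrt(k * k + mu2 * mu2) - mu2
    if R <= R_mut + 1e-12:
        raise ValueError("parameters are in the mutator phase; the wild-chain "
                         "polynomial solution is not the dominant mode")
    # P_l prop. C(L, l) * (-ztilde)^(L-l) with ztilde the negative root of
    # mu1 z^2 + 2 k z - mu1; work in logs to avoid overflow.
    mz = (k + np.sqrt(k * k + mu1 * mu1)) / mu1     # = -ztilde > 1
    l = np.arange(L + 1)
    from scipy.special import gammaln
    logP = (gammaln(L + 1) - gammaln(l + 1) - gammaln(L - l + 1)
            + (L - l) * np.log(mz))
    logP -= logP.max()
    P = np.exp(logP)
    # driven mutator chain: (R I - T_Q) Q = a P, T_Q tridiagonal
    x = class_grid(L)
    sub = mu2 * (L - (l[1:] - 1)) / L
    sup = mu2 * (l[:-1] + 1) / L
    diag = k * x - mu2
    ab = np.zeros((3, L + 1))
    ab[0, 1:] = -sup
    ab[1, :] = R - diag
    ab[2, :-1] = -sub
    Q = solve_banded((1, 1), ab, a * P)
    if Q.min() < -1e-9 * max(Q.max(), 1.0):
        raise RuntimeError("driven-chain solve produced negative weights")
    Q = np.clip(Q, 0.0, None)
    state = PopulationState(P, Q).normalize()
    return float(R), state


# ---------------------------------------------------------------------------
# brute-force sequence-space oracle

def _popcounts(L: int) -> np.ndarray:
    idx = np.arange(2 ** L, dtype=np.uint32)
    counts = np.zeros(2 ** L, dtype=np.int64)
    for b in range(L):
        counts += (idx >> b) & 1
    return counts


def brute_force_sequence_model(params: MutatorParams,
                               landscape: FitnessLandscape,
                               ) -> tuple[float, np.ndarray, PopulationState]:
    """Dominant eigenpair of the full 2 * 2^L sequence-space generator.

    Every sequence mutates each site at per-site rate mu/L and switches
    mutator state at alpha1/alpha2; fitness depends only on the Hamming
    class.  Serves as the exact oracle for the class-reduced operator:
    class-aggregated marginals and the eigenvalue must match it.
    """
    L = params.L
    if L > 12:
        raise ValueError("brute-force model limited to L <= 12")
    N = 2 ** L
    lclass = _popcounts(L)
    x = 1.0 - 2.0 * lclass / L
    fv = np.asarray(landscape.f(x), dtype=float)
    gv = np.asarray(landscape.g(x), dtype=float)
    idx = np.arange(N)

    def chain_matrix(mu, outflow, diag_fit):
        rows, cols, vals = [], [], []
        for b in range(L):
            rows.append(idx)
            cols.append(idx ^ (1 << b))
            vals.append(np.full(N, mu / L))
        rows.append(idx)
        cols.append(idx)
        vals.append(diag_fit - mu - outflow)
        return sp.csr_matrix((np.concatenate(vals),
                              (np.concatenate(rows), np.concatenate(cols))),
                             shape=(N, N))

    # per-site mutation is symmetric in sequence space, so each block is
    # already symmetric; only the switch coupling needs rescaling.
    T1 = chain_matrix(params.mu1, params.alpha1, fv)
    T2 = chain_matrix(params.mu2, params.alpha2, gv)

    def block_top(T):
        from scipy.sparse.linalg import eigsh

        vals, vecs = eigsh(T, k=1, which="LA", tol=0)
        y = vecs[:, 0]
        if y[np.argmax(np.abs(y))] < 0:
            y = -y
        return float(vals[0]), np.clip(y, 0.0, None)

    a1, a2 = params.alpha1, params.alpha2
    if a1 > 0.0 and a2 > 0.0:
        c = np.sqrt(a2 / a1)
        S = sp.bmat([[T1, np.sqrt(a1 * a2) * sp.identity(N)],
                     [np.sqrt(a1 * a2) * sp.identity(N), T2]], format="csr")
        lam, y = block_top(S)
        Pseq, Qseq = y[:N], y[N:] / c
    else:
        lam1, y1 = block_top(T1)
        lam2, y2 = block_top(T2)
        if a1 == 0.0 and a2 == 0.0:
            lam = max(lam1, lam2)
            Pseq = y1 if lam1 >= lam2 else np.zeros(N)
            Qseq = y2 if lam2 > lam1 else np.zeros(N)
        elif a2 == 0.0:
            if lam1 > lam2:
                lam = lam1
                Pseq = y1
                Qseq = splu((lam * sp.identity(N, format="csc")
                             - T2.tocsc()).tocsc()).solve(a1 * y1)
            else:
                lam, Pseq, Qseq = lam2, np.zeros(N), y2
        else:
            if lam2 > lam1:
                lam = lam2
                Qseq = y2
                Pseq = splu((lam * sp.identity(N, format="csc")
                             - T1.tocsc()).tocsc()).solve(a2 * y2)
            else:
                lam, Pseq, Qseq = lam1, np.zeros(N), y1
    Pseq = np.clip(Pseq, 0.0, None)
    Qseq = np.clip(Qseq, 0.0, None)
    total = Pseq.sum() + Qseq.sum()
    Pseq, Qseq = Pseq / total, Qseq / total
    v = np.concatenate([Pseq, Qseq])
    P = np.bincount(lclass, weights=Pseq, minlength=L + 1)
    Q = np.bincount(lclass, weights=Qseq, minlength=L + 1)
    state = PopulationState(P, Q, normalized=True)
    return float(lam), v, state
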
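"""Population state over Hamming classes and its steady-state observables."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .landscapes import FitnessLandscape, class_grid

NORM_TOL = 1e-12


@dataclass
class PopulationState:
    """Hamming-class weights of the two sub-populations.

    ``P[l]`` and ``Q[l]`` are the weights of wild-type and mutator-type
    sequences with l mutations in the regular genome part.  When
    ``normalized`` is set the weights are probabilities summing to one
    jointly.
    """

    P: np.ndarray
    Q: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.P.shape != self.Q.shape or self.P.ndim != 1:
            raise ValueError("P and Q must be 1-d arrays of equal length L+1")
        if np.any(self.P < 0) or np.any(self.Q < 0):
            raise ValueError("class weights must be non-negative")
        if self.normalized:
            total = self.P.sum() + self.Q.sum()
            if abs(total - 1.0) > NORM_TOL:
                raise ValueError(f"normalized state must sum to 1, got {total!r}")

    @property
    def L(self) -> int:
        return self.P.size - 1

    def normalize(self) -> "PopulationState":
        total = self.P.sum() + self.Q.sum()
        if total <= 0:
            raise ValueError("cannot normalize an empty state")
        return PopulationState(self.P / total, self.Q / total, normalized=True)

    @classmethod
    def reference(cls, L: int) -> "PopulationState":
        """All mass in the wild-type reference class (l = 0)."""
        P = np.zeros(L + 1)
        P[0] = 1.0
        return cls(P, np.zeros(L + 1), normalized=True)

    @classmethod
    def uniform(cls, L: int) -> "PopulationState":
        w = np.full(L + 1, 0.5 / (L + 1))
        return cls(w.copy(), w.copy(), normalized=True)


@dataclass(frozen=True)
class Observables:
    """Steady-state order parameters.

    R is the mean fitness, s the total surplus (population mean of
    x = 1 - 2l/L), s1/s2 the per-type surpluses (None when the type has
    no mass), and q the mutator fraction.
    """

    R: float
    s: float
    q: float
    s1: Optional[float] = None
    s2: Optional[float] = None

    def __post_init__(self) -> None:
        if not -1e-12 <= self.q <= 1 + 1e-12:
            raise ValueError(f"mutator fraction q out of [0, 1]: {self.q}")


def observables(state: PopulationState, landscape: FitnessLandscape) -> Observables:
    """Mean fitness, surpluses and mutator fraction of a normalized state.

    R = sum f(x_l) P_l + sum g(x_l) Q_l;  s, s1, s2 are expectations of
    x_l over the whole population and the two sub-populations; q is the
    total mutator mass.  A conditional surplus is reported as None (not
    zero) when its sub-population carries no mass.
    """
    st = state if state.normalized else state.normalize()
    L = st.L
    x = class_grid(L)
    fv, gv = landscape.profile(L)
    pmass = st.P.sum()
    qmass = st.Q.sum()
    R = float(fv @ st.P + gv @ st.Q)
    s = float(x @ st.P + x @ st.Q)
    s1 = float(x @ st.P / pmass) if pmass > 0 else None
    s2 = float(x @ st.Q / qmass) if qmass > 0 else None
    return Observables(R=R, s=s, q=float(qmass), s1=s1, s2=s2)
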
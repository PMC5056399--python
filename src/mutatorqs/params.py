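"""Parameter containers for the mutator-gene quasispecies models.

The binary-genome models track two sub-populations: wild-type sequences
(normal state of the mutator gene, per-genome mutation rate ``mu1``) and
mutator-type sequences (mutant state, per-genome rate ``mu2``, typically
10-100x larger). ``alpha1`` and ``alpha2`` are the forward (wild -> mutator)
and backward (mutator -> wild) switch rates of the mutator gene itself.

All rates are per-genome; per-site rates are obtained by dividing by the
regular genome length ``L`` inside the solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field


def _check_rate(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


@dataclass(frozen=True)
class MutatorParams:
    """Rates of the parallel (Crow-Kimura) mutator model.

    Parameters
    ----------
    L : int
        Length of the regular part of the genome (number of binary sites,
        excluding the mutator gene itself). Hamming classes run l = 0..L.
    mu1, mu2 : float
        Per-genome mutation rates of the wild-type and mutator-type
        sub-populations.
    alpha1, alpha2 : float
        Forward (wild -> mutator) and backward (mutator -> wild) switch
        rates of the mutator gene. ``alpha2 = 0`` is the uni-directional
        model with its three-phase structure.
    """

    L: int
    mu1: float
    mu2: float
    alpha1: float
    alpha2: float = 0.0

    def __post_init__(self) -> None:
        if int(self.L) != self.L or self.L < 1:
            raise ValueError(f"L must be a positive integer, got {self.L!r}")
        object.__setattr__(self, "L", int(self.L))
        for name in ("mu1", "mu2", "alpha1", "alpha2"):
            _check_rate(name, getattr(self, name))

    @property
    def uni_directional(self) -> bool:
        """True when back mutation of the mutator gene is absent."""
        return self.alpha2 == 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MutatorParams":
        return cls(L=d["L"], mu1=d["mu1"], mu2=d["mu2"],
                   alpha1=d["alpha1"], alpha2=d.get("alpha2", 0.0))


@dataclass(frozen=True)
class EigenParams:
    """Parameters of the Eigen-model (coupled mutation-selection) variant.

    The per-nucleotide errorless-copy probability ``w`` gives a per-genome
    errorless probability Q = w^L = exp(-gamma) with genome mutation
    parameter gamma = -L ln w.  The mutator type copies with parameter
    ``mu * gamma`` (``mu`` is the rate ratio, mirroring mu2/mu1 of the
    parallel model).  ``h`` is the per-replication wild -> mutator switch
    probability parameter (transition probability 1 - e^-h ~ h) and ``A``
    the Wrightian fitness of the peak sequence (background fitness 1).
    """

    L: int
    gamma: float
    mu: float = 1.0
    h: float = 0.0
    A: float = 1.0

    def __post_init__(self) -> None:
        if int(self.L) != self.L or self.L < 1:
            raise ValueError(f"L must be a positive integer, got {self.L!r}")
        object.__setattr__(self, "L", int(self.L))
        for name in ("gamma", "mu", "h"):
            _check_rate(name, getattr(self, name))
        if not math.isfinite(self.A) or self.A <= 0:
            raise ValueError(f"A must be positive, got {self.A!r}")

    @property
    def w(self) -> float:
        """Per-nucleotide errorless-copy probability of the wild type."""
        return math.exp(-self.gamma / self.L)

    @property
    def w_mutator(self) -> float:
        return math.exp(-self.mu * self.gamma / self.L)

    @property
    def Q(self) -> float:
        """Per-genome errorless-copy probability e^-gamma."""
        return math.exp(-self.gamma)

    @classmethod
    def from_w(cls, L: int, w: float, mu: float = 1.0, h: float = 0.0,
               A: float = 1.0) -> "EigenParams":
        if not 0.0 < w <= 1.0:
            raise ValueError(f"w must be in (0, 1], got {w!r}")
        return cls(L=L, gamma=-L * math.log(w), mu=mu, h=h, A=A)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CKEigenMapping:
    """Discrete-generation mapping between the two model conventions.

    A Crow-Kimura (Malthusian) system observed over one generation of
    duration ``tau`` behaves like a discrete-time Eigen model with
    Wrightian fitness exp(tau * Malthusian fitness), mutation parameter
    U = tau * mu and switch probability parameter h = tau * alpha1.
    """

    tau: float
    U: float
    S: float
    h: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
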
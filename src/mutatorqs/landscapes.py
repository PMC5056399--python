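"""Symmetric fitness landscapes on the Hamming-class coordinate.

A symmetric landscape assigns fitness to a sequence through the mean spin
x = 1 - 2l/L of its Hamming class l (distance from the all-"+" reference
sequence), so r_l = f(x_l).  Wild-type and mutator-type sub-populations may
carry different maps f and g; by default g = f.

Families
--------
linear          f(x) = k x
quadratic       f(x) = c x^2 / 2
single_peak     f(1) = J exactly at class l = 0, baseline elsewhere
tabulated       explicit per-class values r_0..r_L
composite_d     additive multi-part genome, parts weighted by lengths y_i
lognormal_random  seeded log-normal Wrightian draws over sequence space,
                  summarised by their extreme-value effective peak

Values are Malthusian (growth rates) on the Crow-Kimura side; the Eigen
module converts explicitly to Wrightian (multiplicative) fitness where
needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

KINDS = ("linear", "quadratic", "single_peak", "tabulated", "composite_d",
         "lognormal_random")


def class_grid(L: int) -> np.ndarray:
    """x_l = 1 - 2l/L for l = 0..L (l = 0 is the reference class, x = 1)."""
    l = np.arange(L + 1)
    return 1.0 - 2.0 * l / L


@dataclass(frozen=True)
class FitnessLandscape:
    """A pair of symmetric fitness maps (f for wild-type, g for mutator)."""

    kind: str
    f: Callable[[np.ndarray], np.ndarray]
    g: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)

    def profile(self, L: int) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate (f, g) on the class grid of length L+1."""
        x = class_grid(L)
        fv = np.asarray(self.f(x), dtype=float)
        gv = np.asarray(self.g(x), dtype=float)
        if fv.shape != x.shape or gv.shape != x.shape:
            raise ValueError("landscape maps must be vectorized over x")
        if not (np.all(np.isfinite(fv)) and np.all(np.isfinite(gv))):
            raise ValueError("landscape produced non-finite values on the class grid")
        return fv, gv

    def to_frame(self, L: int):
        """Per-class table (l, x_l, f, g) for inspection / CSV dump."""
        import pandas as pd

        x = class_grid(L)
        fv, gv = self.profile(L)
        return pd.DataFrame({"l": np.arange(L + 1), "x": x, "f": fv, "g": gv})

    def to_dict(self) -> dict:
        return {"kind": self.kind, **self.params}


def _linear(k: float):
    return lambda x: k * np.asarray(x, dtype=float)


def _quadratic(c: float):
    return lambda x: 0.5 * c * np.asarray(x, dtype=float) ** 2


def _single_peak(J: float, baseline: float):
    def fn(x):
        x = np.asarray(x, dtype=float)
        return np.where(x == 1.0, J, baseline)
    return fn


def make_landscape(kind: str, *, g_params: dict | None = None,
                   **params) -> FitnessLandscape:
    """Build a landscape family member.

    Parameters
    ----------
    kind : str
        One of ``linear`` (k), ``quadratic`` (c), ``single_peak`` (J,
        optional baseline=0), ``tabulated`` (values), ``lognormal_random``
        (L, variance, optional mean=0, seed).  ``composite_d`` landscapes
        are built with :func:`make_composite`.
    g_params : dict, optional
        Parameters for a distinct mutator-type map of the same family;
        by default g = f.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown landscape kind {kind!r}; expected one of {KINDS}")

    def build(p: dict):
        if kind == "linear":
            return _linear(float(p["k"]))
        if kind == "quadratic":
            return _quadratic(float(p["c"]))
        if kind == "single_peak":
            J = float(p["J"])
            if J <= 0:
                raise ValueError(f"single-peak height J must be positive, got {J}")
            return _single_peak(J, float(p.get("baseline", 0.0)))
        if kind == "tabulated":
            values = np.asarray(p["values"], dtype=float)
            if values.ndim != 1 or values.size < 2:
                raise ValueError("tabulated landscape needs a 1-d array of class values")
            Ltab = values.size - 1

            def fn(x, values=values, Ltab=Ltab):
                x = np.asarray(x, dtype=float)
                l = np.rint((1.0 - x) * Ltab / 2.0).astype(int)
                if np.any(l < 0) or np.any(l > Ltab):
                    raise ValueError("x outside [-1, 1] for tabulated landscape")
                return values[l]

            return fn
        if kind == "lognormal_random":
            A_max = lognormal_effective_peak_height(
                int(p["L"]), float(p["variance"]), mean=float(p.get("mean", 0.0)))
            return _single_peak(A_max, 1.0)
        raise AssertionError(kind)

    if kind == "composite_d":
        raise ValueError("use make_composite() for composite_d landscapes")
    f = build(params)
    g = build({**params, **g_params}) if g_params else f
    return FitnessLandscape(kind=kind, f=f, g=g,
                            params={**params, **({"g_params": g_params} if g_params else {})})


@dataclass(frozen=True)
class CompositePart:
    """One genome segment of a d-dimensional landscape.

    ``y`` is the relative length (weights sum to 1), ``f``/``g`` the
    per-part fitness maps of x_i = 1 - 2 l_i/(L y_i), ``mu``/``nu`` the
    wild/mutator per-genome mutation rates acting on this part, and
    ``pinned`` marks a lethal part whose coordinate is confined to x_i = 1.
    """

    y: float
    f: Callable[[np.ndarray], np.ndarray]
    g: Callable[[np.ndarray], np.ndarray]
    mu: float
    nu: float
    pinned: bool = False

    def __post_init__(self) -> None:
        if self.y <= 0:
            raise ValueError(f"part weight y must be positive, got {self.y}")


def make_composite(parts: Sequence[CompositePart]) -> tuple[CompositePart, ...]:
    parts = tuple(parts)
    total = sum(p.y for p in parts)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"part weights y_i must sum to 1, got {total}")
    return parts


# ---------------------------------------------------------------------------
# log-normal random (Wrightian) landscapes

def lognormal_wrightians(L: int, variance: float, seed: int,
                         mean: float = 0.0, full: bool | None = None):
    """Seeded log-normal Wrightian fitness draws over sequence space.

    ln r_i ~ Normal(mean, variance), i.i.d. over the 2^L sequences.  For
    L <= 20 (``full`` defaulting to True there) the full vector is
    returned together with its maximum; for larger L only the summary
    (the extreme-value effective peak height) is produced, since the
    random landscape behaves like a single-peak landscape whose peak is
    the maximal draw while the bulk of sequences sit at fitness ~ 1.

    Returns
    -------
    dict with keys ``A_max`` (closed-form effective peak),
    ``empirical_max`` and ``values`` (None unless enumerated).
    """
    if variance <= 0:
        raise ValueError(f"variance must be positive, got {variance}")
    if full is None:
        full = L <= 20
    if full and L > 20:
        raise ValueError("full enumeration limited to L <= 20")
    A_closed = lognormal_effective_peak_height(L, variance, mean=mean)
    values = None
    emp = None
    if full:
        rng = np.random.default_rng(seed)
        values = np.exp(rng.normal(mean, math.sqrt(variance), size=2 ** L))
        emp = float(values.max())
    return {"A_max": A_closed, "empirical_max": emp, "values": values}


def lognormal_effective_peak_height(L: int, variance: float,
                                    mean: float = 0.0) -> float:
    """Leading-order extreme value of 2^L i.i.d. log-normal draws.

    max_i r_i ~ exp(mean + sigma * sqrt(2 ln 2^L)); the bulk of the
    distribution contributes fitness ~ e^mean (taken as the background 1
    for mean = 0), so the random landscape is summarised by an effective
    single peak of this height.
    """
    if variance <= 0:
        raise ValueError(f"variance must be positive, got {variance}")
    sigma = math.sqrt(variance)
    return math.exp(mean + sigma * math.sqrt(2.0 * L * math.log(2.0)))
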
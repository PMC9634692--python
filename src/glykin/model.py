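r"""Three-species competing-pathway kinetics of aminoacyl-primer extension.

A primer population starts as a mixture of 2'(3')-aminoacylated primer
(fraction ``p_gly0``) and native RNA primer (``1 - p_gly0``).  Under
pseudo-first-order conditions (saturating activated substrate) three
irreversible reactions compete:

* the aminoacylated primer extends through its amino group to the
  phosphoramidate-linked +1 product ("NP+1" band) at rate ``k1``;
* the aminoacyl ester hydrolyses, returning the primer to native RNA,
  at rate ``k2``;
* the native primer extends through its 3'-hydroxyl to the canonical
  phosphodiester +1 product ("OP+1" band) at rate ``k3``.

With ``P_gly``, ``P_rna``, ``P_gly+1``, ``P_rna+1`` the four species
fractions, the linear system

.. math::

    dP_{gly}/dt   &= -(k_1 + k_2)\,P_{gly} \\
    dP_{rna}/dt   &= k_2 P_{gly} - k_3 P_{rna} \\
    dP_{gly+1}/dt &= k_1 P_{gly} \\
    dP_{rna+1}/dt &= k_3 P_{rna}

has the closed-form solution implemented by :func:`eval_closed_form`;
:func:`integrate_numeric` solves the same system numerically and serves as
an independent oracle in the test suite.  All rates are per hour and all
times are hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ComputationError, InputDomainError

__all__ = [
    "RateConstants",
    "InitialComposition",
    "SpeciesState",
    "Trajectory",
    "eval_closed_form",
    "integrate_numeric",
    "simulate_trajectory",
    "branching_yield",
]

#: relative tolerance below which |k3 - (k1+k2)| is treated as the
#: degenerate (equal-eigenvalue) case of the native-primer solution
DEGENERATE_RTOL = 1e-9

_CONSERVATION_ATOL = 1e-9


@dataclass(frozen=True)
class RateConstants:
    """Pseudo-first-order rate constants of the reaction network, per hour.

    Parameters
    ----------
    k1 : float
        Extension of the aminoacylated primer (phosphoramidate formation).
    k2 : float
        Hydrolysis of the aminoacyl ester (aminoacylated -> native primer).
    k3 : float
        Extension of the native RNA primer (phosphodiester formation).
    """

    k1: float
    k2: float
    k3: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise InputDomainError(
                    f"rate constant {name}={value!r} must be finite and >= 0"
                )


@dataclass(frozen=True)
class InitialComposition:
    """Initial primer composition; ``p_rna0 = 1 - p_gly0`` is implied."""

    p_gly0: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_gly0 <= 1.0) or not math.isfinite(self.p_gly0):
            raise InputDomainError(
                f"p_gly0={self.p_gly0!r} must lie in [0, 1]"
            )

    @property
    def p_rna0(self) -> float:
        return 1.0 - self.p_gly0


@dataclass(frozen=True)
class SpeciesState:
    """Fractions of the four primer species at one time point (hours)."""

    t: float
    p_gly: float
    p_rna: float
    p_gly1: float
    p_rna1: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise InputDomainError(f"t={self.t!r} must be >= 0")
        total = self.p_gly + self.p_rna + self.p_gly1 + self.p_rna1
        if abs(total - 1.0) > _CONSERVATION_ATOL:
            raise InputDomainError(
                f"species fractions sum to {total!r}, not 1 within "
                f"{_CONSERVATION_ATOL}"
            )
        for name in ("p_gly", "p_rna", "p_gly1", "p_rna1"):
            value = getattr(self, name)
            # tiny negative round-off is tolerated by the same margin as
            # conservation; genuine domain violations still raise
            if value < -_CONSERVATION_ATOL or value > 1.0 + _CONSERVATION_ATOL:
                raise InputDomainError(
                    f"fraction {name}={value!r} outside [0, 1]"
                )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_gly, self.p_rna, self.p_gly1, self.p_rna1)


@dataclass(frozen=True)
class Trajectory:
    """Ordered sequence of :class:`SpeciesState` on a strictly increasing grid."""

    states: tuple[SpeciesState, ...]

    def __post_init__(self) -> None:
        times = [s.t for s in self.states]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InputDomainError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[SpeciesState]:
        return iter(self.states)

    def __getitem__(self, i: int) -> SpeciesState:
        return self.states[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def fractions(self, species: str) -> np.ndarray:
        return np.array([getattr(s, species) for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        """Serializable table with columns t_h, p_gly, p_rna, p_gly1, p_rna1."""
        return pd.DataFrame(
            {
                "t_h": self.times,
                "p_gly": self.fractions("p_gly"),
                "p_rna": self.fractions("p_rna"),
                "p_gly1": self.fractions("p_gly1"),
                "p_rna1": self.fractions("p_rna1"),
            }
        )


def _validate_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InputDomainError("times must be a nonempty 1-D sequence")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise InputDomainError("times must be finite and >= 0")
    if np.any(np.diff(t) <= 0):
        raise InputDomainError("times must be strictly increasing")
    return t


def _fractions(
    rates: RateConstants, init: InitialComposition, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized closed-form species fractions at times ``t`` (validated)."""
    k1, k2, k3 = rates.k1, rates.k2, rates.k3
    kg = k1 + k2  # total consumption rate of the aminoacylated primer
    p0 = init.p_gly0
    pr0 = init.p_rna0

    eg = np.exp(-kg * t)
    p_gly = p0 * eg
    if kg > 0:
        p_gly1 = (k1 / kg) * p0 * (1.0 - eg)
    else:
        p_gly1 = np.zeros_like(t)

    er = np.exp(-k3 * t)
    if kg == 0.0 and k3 == 0.0:
        p_rna = np.full_like(t, pr0)
    elif abs(k3 - kg) < DEGENERATE_RTOL * max(k3, kg):
        # equal-eigenvalue limit: the general solution's denominator
        # (k3 - kg) vanishes and the feed term becomes secular
        p_rna = pr0 * er + k2 * p0 * t * er
    else:
        p_rna = pr0 * er + k2 * p0 * (eg - er) / (k3 - kg)

    p_rna1 = 1.0 - p_gly - p_rna - p_gly1
    return p_gly, p_rna, p_gly1, p_rna1


def eval_closed_form(
    rates: RateConstants, init: InitialComposition, t: float
) -> SpeciesState:
    """Analytic species fractions at a single time ``t`` (hours).

    Raises
    ------
    InputDomainError
        If ``t`` is negative or non-finite.
    """
    if not math.isfinite(t) or t < 0:
        raise InputDomainError(f"t={t!r} must be finite and >= 0")
    arr = np.array([t], dtype=float)
    p_gly, p_rna, p_gly1, p_rna1 = _fractions(rates, init, arr)
    return SpeciesState(
        t=t,
        p_gly=float(p_gly[0]),
        p_rna=float(p_rna[0]),
        p_gly1=float(p_gly1[0]),
        p_rna1=float(p_rna1[0]),
    )


def simulate_trajectory(
    rates: RateConstants, init: InitialComposition, times: Sequence[float]
) -> Trajectory:
    """Closed-form trajectory on a strictly increasing time grid."""
    t = _validate_times(times)
    p_gly, p_rna, p_gly1, p_rna1 = _fractions(rates, init, t)
    states = tuple(
        SpeciesState(
            t=float(ti),
            p_gly=float(a),
            p_rna=float(b),
            p_gly1=float(c),
            p_rna1=float(d),
        )
        for ti, a, b, c, d in zip(t, p_gly, p_rna, p_gly1, p_rna1)
    )
    return Trajectory(states)


def integrate_numeric(
    rates: RateConstants, init: InitialComposition, times: Sequence[float]
) -> Trajectory:
    """Numerically integrated trajectory of the reaction network ODEs.

    Independent of the closed-form path: the right-hand sides are coded
    directly from the rate laws and solved with a stiff-capable
    high-accuracy integrator.  Used as the brute-force oracle for
    :func:`eval_closed_form`.
    """
    t = _validate_times(times)
    k1, k2, k3 = rates.k1, rates.k2, rates.k3

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        p_gly, p_rna, p_gly1, p_rna1 = y
        return [
            -(k1 + k2) * p_gly,
            k2 * p_gly - k3 * p_rna,
            k1 * p_gly,
            k3 * p_rna,
        ]

    y0 = [init.p_gly0, init.p_rna0, 0.0, 0.0]
    t_span = (0.0, float(t[-1]) if t[-1] > 0 else 1e-12)
    sol = solve_ivp(
        rhs,
        t_span,
        y0,
        method="LSODA",
        t_eval=t,
        rtol=1e-11,
        atol=1e-13,
    )
    if not sol.success:
        raise ComputationError(
            f"ODE integration failed for rates={rates!r}, init={init!r}: "
            f"{sol.message}"
        )
    states = tuple(
        SpeciesState(
            t=float(ti),
            p_gly=float(y[0]),
            p_rna=float(y[1]),
            p_gly1=float(y[2]),
            p_rna1=float(y[3]),
        )
        for ti, y in zip(sol.t, sol.y.T)
    )
    return Trajectory(states)


def branching_yield(rates: RateConstants, init: InitialComposition) -> float:
    """Asymptotic fraction of all primer converted to the NP+1 product.

    This is the t -> infinity limit of the NP+1 fraction,
    ``p_gly0 * k1 / (k1 + k2)``: the branching ratio between productive
    extension and ester hydrolysis, scaled by the acylated fraction.

    Raises
    ------
    InputDomainError
        If ``k1 + k2 == 0`` (the aminoacylated pool never reacts and the
        limit is undefined as a yield).
    """
    kg = rates.k1 + rates.k2
    if kg == 0:
        raise InputDomainError(
            "branching yield undefined when k1 + k2 = 0 (no consumption "
            "of the aminoacylated primer)"
        )
    return init.p_gly0 * rates.k1 / kg
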
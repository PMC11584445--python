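"""Explosive Cox ("coxplosive") microfailure process.

The process counts microfailures in a loaded specimen as a function of the
tensile strain ``eps`` (strain plays the role time plays in an ordinary
renewal process).  Between the (k-1)-th and k-th microfailure the strain
increment is exponentially distributed,

    d_eps_k ~ Exp(lambda_k),        lambda_k = lam * alpha**(-(k - 1)),

with 0 < alpha < 1 and lam > 0 (units 1/strain).  Because the rates grow
geometrically, the expected increments ``alpha**(k-1) / lam`` form a
convergent geometric series: infinitely many microfailures accumulate before
the finite strain ``mu_inf = 1 / ((1 - alpha) * lam)``, i.e. the process is
explosive, which is how macroscopic fracture at a finite strain is
represented.  The per-event log-growth of the hazard, ``beta = -ln(alpha)``,
is the deterioration rate of the material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ModelParams",
    "SimulatedSequence",
    "rate",
    "expected_increment",
    "mu_infinity",
    "mu_segment",
    "deterioration_rate",
    "simulate",
    "count_curve",
]

MuConvention = Literal["telescoping", "shifted"]


@dataclass(frozen=True)
class ModelParams:
    """Parameter pair (alpha, lam) of the explosive microfailure process.

    Parameters
    ----------
    alpha
        Geometric decay ratio of the expected inter-event strain increments,
        strictly inside (0, 1).  Values near 1 mean slow deterioration and
        many events; values near 0 mean near-immediate explosion.
    lam
        Rate of the first inter-event increment, units 1/strain, > 0.
    """

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (self.lam > 0.0):
            raise ValueError(f"lam must be > 0, got {self.lam}")

    @property
    def beta(self) -> float:
        """Deterioration rate ``-ln(alpha)`` (dimensionless, > 0)."""
        return -float(np.log(self.alpha))


@dataclass(frozen=True)
class SimulatedSequence:
    """One realization of the microfailure process.

    ``cum_strains`` are the strains at which successive microfailures occur
    (strictly increasing partial sums of ``increments``).  ``stop_reason``
    records whether the simulation hit the event cap or the explosion was
    reached numerically (an increment fell below the resolution threshold).
    """

    increments: np.ndarray
    cum_strains: np.ndarray
    rng_seed: int | None
    stop_reason: Literal["max_events", "increment_underflow"]

    def __post_init__(self) -> None:
        if len(self.increments) < 1:
            raise ValueError("a simulated sequence holds at least one event")

    def __len__(self) -> int:
        return len(self.cum_strains)

    @property
    def total_strain(self) -> float:
        """Strain of the last simulated microfailure (finite-sample eps_inf)."""
        return float(self.cum_strains[-1])


def _check_index(k) -> np.ndarray:
    k = np.asarray(k)
    if not np.issubdtype(k.dtype, np.integer):
        if not np.all(k == np.floor(k)):
            raise ValueError("event index k must be integer")
    if np.any(k < 1):
        raise ValueError("event index k must be >= 1")
    return k


def rate(k, p: ModelParams):
    """Hazard rate ``lambda_k = lam * alpha**(-k+1)`` of the k-th increment.

    Strictly increasing in k: each microfailure embrittles the material, so
    the next one arrives, in expectation, after a shorter strain increment.
    Accepts scalar or array ``k`` (k >= 1).
    """
    k = _check_index(k)
    out = p.lam * p.alpha ** (-(k - 1.0))
    return float(out) if out.ndim == 0 else out


def expected_increment(k, p: ModelParams):
    """Expected strain increment before the k-th event, ``alpha**(k-1)/lam``.

    Strictly decreasing in k — the new-better-than-used-in-expectation
    property of the damage accumulation process.
    """
    k = _check_index(k)
    out = p.alpha ** (k - 1.0) / p.lam
    return float(out) if out.ndim == 0 else out


def mu_infinity(p: ModelParams) -> float:
    """Expected total strain accumulated over the infinite event sequence.

    The geometric series of expected increments sums to
    ``1 / ((1 - alpha) * lam)``; the process explodes at a finite strain
    whose mean this is.
    """
    return 1.0 / ((1.0 - p.alpha) * p.lam)


def mu_segment(
    i: int,
    j: float,
    p: ModelParams,
    convention: MuConvention = "telescoping",
) -> float:
    """Expected strain accumulated between microfailures i and j (0 <= i < j).

    With ``E(d_eps_k) = alpha**(k-1)/lam`` the sum over k = i+1..j telescopes
    to ``(alpha**i - alpha**j) / ((1 - alpha) * lam)`` (the default
    "telescoping" convention), which is additive over abutting segments and
    satisfies ``mu_segment(0, inf) == mu_infinity``.  The "shifted"
    convention uses ``alpha**(j+1)`` in place of ``alpha**j`` — an index
    convention found in some formulations, kept for comparison; it is not
    additive and is never the default.

    ``j`` may be ``math.inf``/``np.inf``.
    """
    if i < 0:
        raise ValueError(f"segment start i must be >= 0, got {i}")
    if not (j > i):
        raise ValueError(f"segment must have j > i, got i={i}, j={j}")
    a = p.alpha
    a_j = 0.0 if np.isinf(j) else a ** (j + 1 if convention == "shifted" else j)
    return (a**i - a_j) / ((1.0 - a) * p.lam)


def deterioration_rate(p: ModelParams) -> float:
    """Per-event log-growth of the hazard rate, ``beta = -ln(alpha)`` > 0.

    Constant in k for the geometric rate law: the model has constant
    deterioration.
    """
    return p.beta


def simulate(
    p: ModelParams,
    seed: int | np.random.Generator | None = None,
    max_events: int = 2000,
    min_increment: float = 1e-12,
) -> SimulatedSequence:
    """Draw one realization of the microfailure strain sequence.

    Increments ``d_eps_k ~ Exp(lambda_k)`` are drawn for k = 1, 2, ... until
    either ``max_events`` events have occurred or a drawn increment falls
    below ``min_increment`` (the explosion has been reached at the working
    resolution; the sub-threshold draw is kept so the recorded last strain
    sits at the numerical asymptote).  At least one event is always returned.

    Parameters
    ----------
    p
        Process parameters.
    seed
        Integer seed or ``numpy.random.Generator``; an integer gives a
        reproducible run and is recorded on the result.
    max_events
        Hard cap on the number of events (>= 1).
    min_increment
        Strain resolution below which the cascade is considered to have
        exploded (>= 0; 0 disables the rule and always runs to the cap).
    """
    if max_events < 1:
        raise ValueError("max_events must be >= 1")
    if min_increment < 0:
        raise ValueError("min_increment must be >= 0")
    if isinstance(seed, np.random.Generator):
        rng, recorded = seed, None
    else:
        rng, recorded = np.random.default_rng(seed), seed

    k = np.arange(max_events, dtype=float)
    # Exp(lambda_k) == Exp(1) / lambda_k; one vectorized draw is
    # distributionally identical to the sequential scheme.
    increments = rng.exponential(size=max_events) * (p.alpha**k) / p.lam
    stop_reason: str = "max_events"
    if min_increment > 0.0:
        below = np.nonzero(increments < min_increment)[0]
        if below.size:
            # keep the first sub-threshold draw; guarantees >= 1 event
            increments = increments[: below[0] + 1]
            stop_reason = "increment_underflow"
    return SimulatedSequence(
        increments=increments,
        cum_strains=np.cumsum(increments),
        rng_seed=recorded,
        stop_reason=stop_reason,  # type: ignore[arg-type]
    )


def count_curve(events, strain_grid) -> np.ndarray:
    """Microfailure count N(eps) evaluated on a strain grid.

    ``N(eps)`` is the number of events with strain <= eps (closed at eps):
    a right-continuous, nondecreasing step function.  ``events`` may be a
    :class:`SimulatedSequence`, an object with a ``strains`` attribute
    (e.g. an event sequence), or a sorted array of event strains.
    """
    if isinstance(events, SimulatedSequence):
        strains = events.cum_strains
    else:
        strains = getattr(events, "strains", events)
    strains = np.asarray(strains, dtype=float)
    grid = np.asarray(strain_grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0):
        raise ValueError("strain_grid must be a 1-D ascending array")
    return np.searchsorted(strains, grid, side="right")
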
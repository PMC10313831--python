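"""Readouts of lattice states and trajectories.

Physical length of the complex uses a three-term model: naked ssDNA extends
``m`` nm per nt under the constant buffer flow, ssDNA under a 20-nt-mode RPA
extends ``alpha * m`` per nt and under a 30-nt-mode RPA ``beta * m`` per nt,
so ``length = m * (free_nt + alpha*20*N20 + beta*30*N30)``.  The 20-nt mode
yields the longer complex (``alpha > beta`` under the shipped defaults).
Fluorescence intensity is proportional to the number of bound molecules (one
fluorophore per RPA heterotrimer, mode-independent).  Both are reported as
normalized increments relative to the 30-min reference point,
``(x_t - x_ref) / x_ref``, which makes them independent of ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lattice import (
    FLBM30_FOOTPRINT,
    PBM20_FOOTPRINT,
    LatticeState,
    Mode,
    Trajectory,
)

__all__ = [
    "LengthModel",
    "GapProfile",
    "model_length",
    "normalized_increment",
    "attach_normalized_observables",
    "p20",
    "occupancy_fractions",
    "gap_profile",
    "count_gaps_ge",
    "gap_size_histogram",
]

#: Sentinel for P20 on an empty lattice (0/0); propagates as NaN.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class LengthModel:
    """Length-scaling parameters: nm/nt of naked ssDNA and the relative unit
    extensions of 20-nt-mode and 30-nt-mode bound ssDNA."""

    m: float = 0.3
    alpha: float = 1.9
    beta: float = 1.15

    def __post_init__(self) -> None:
        if self.m <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("m, alpha, beta must all be > 0")


def model_length(state: LatticeState, length_model: LengthModel) -> float:
    """Physical complex length in nm: ``m*(free + alpha*20*N20 + beta*30*N30)``."""
    n20, n30 = state.n20, state.n30
    free = state.L - PBM20_FOOTPRINT * n20 - FLBM30_FOOTPRINT * n30
    return length_model.m * (
        free
        + length_model.alpha * PBM20_FOOTPRINT * n20
        + length_model.beta * FLBM30_FOOTPRINT * n30
    )


def length_from_counts(
    n20: np.ndarray, n30: np.ndarray, L: int, length_model: LengthModel
) -> np.ndarray:
    """Vectorized :func:`model_length` on count series."""
    n20 = np.asarray(n20, dtype=float)
    n30 = np.asarray(n30, dtype=float)
    free = L - PBM20_FOOTPRINT * n20 - FLBM30_FOOTPRINT * n30
    return length_model.m * (
        free
        + length_model.alpha * PBM20_FOOTPRINT * n20
        + length_model.beta * FLBM30_FOOTPRINT * n30
    )


def normalized_increment(values: np.ndarray, times: np.ndarray, reference_time: float) -> np.ndarray:
    """``(x_t - x_ref)/x_ref`` with ``x_ref`` the value at ``reference_time``.

    The reference sample is the last sampled time <= ``reference_time``.
    Raises ``ValueError`` when the reference value is not positive.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    idx = int(np.searchsorted(times, reference_time, side="right")) - 1
    if idx < 0:
        raise ValueError("reference_time precedes the first sample")
    ref = values[idx]
    if not ref > 0:
        raise ValueError(f"degenerate reference value {ref!r} at t={times[idx]}")
    return (values - ref) / ref


def attach_normalized_observables(traj: Trajectory, length_model: LengthModel) -> Trajectory:
    """Fill ``norm_length`` and ``norm_intensity`` on a trajectory in place.

    Intensity is the bound-molecule count.  A zero reference count leaves
    ``norm_intensity`` as NaN rather than raising, since sparse replicates can
    legitimately carry no molecule at the reference time.
    """
    lengths = length_from_counts(traj.n20, traj.n30, traj.L, length_model)
    traj.norm_length = normalized_increment(lengths, traj.times, traj.reference_time)
    counts = traj.n_bound.astype(float)
    try:
        traj.norm_intensity = normalized_increment(counts, traj.times, traj.reference_time)
    except ValueError:
        traj.norm_intensity = np.full_like(counts, np.nan)
    return traj


def p20(n20: int | LatticeState, n30: int | None = None) -> float:
    """Fraction of bound RPA in the 20-nt mode; NaN when nothing is bound."""
    if isinstance(n20, LatticeState):
        state = n20
        n20, n30 = state.n20, state.n30
    total = n20 + n30
    if total == 0:
        return UNDEFINED
    return n20 / total


def occupancy_fractions(state: LatticeState) -> tuple[float, float, float]:
    """(f20, f30, f_free): lattice fractions covered by each mode and free."""
    f20 = PBM20_FOOTPRINT * state.n20 / state.L
    f30 = FLBM30_FOOTPRINT * state.n30 / state.L
    return f20, f30, 1.0 - f20 - f30


@dataclass
class GapProfile:
    """Multiset of naked-ssDNA run lengths at one time point."""

    time: float
    gaps: list[int]
    include_terminal: bool = True

    def __post_init__(self) -> None:
        if any(g < 1 for g in self.gaps):
            raise ValueError("every gap length must be >= 1")


def gap_profile(state: LatticeState, include_terminal: bool = True) -> GapProfile:
    """Maximal runs of free nucleotides.

    With ``include_terminal`` the runs touching either lattice end count as
    gaps (naked terminal ssDNA is accessible too); otherwise only runs flanked
    by two bound molecules are reported.
    """
    gaps: list[int] = []
    pos = 0
    first = True
    for m in state.molecules:
        if m.start > pos and (include_terminal or not first):
            gaps.append(m.start - pos)
        pos = m.end
        first = False
    if pos < state.L and include_terminal and state.molecules:
        gaps.append(state.L - pos)
    if not state.molecules and include_terminal and state.L > 0:
        gaps = [state.L]
    return GapProfile(time=state.time, gaps=gaps, include_terminal=include_terminal)


def count_gaps_ge(profile: GapProfile, min_size: int = 18) -> int:
    """Number of gaps at least ``min_size`` nt long (default: the 18-nt span
    six 3-nt-footprint Rad51 monomers need to nucleate a filament)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return sum(1 for g in profile.gaps if g >= min_size)


def gap_size_histogram(
    profiles: Sequence[GapProfile],
    bin_edges: Sequence[float],
    cutoff: float = 30.0,
):
    """Pooled normalized gap-size histogram across an ensemble of profiles.

    Returns ``(fractions, fraction_below_cutoff, sd_below_cutoff)`` where
    ``fractions`` follow ``bin_edges`` (numpy.histogram convention) and sum to
    one, ``fraction_below_cutoff`` is computed on the pooled gaps, and
    ``sd_below_cutoff`` is the SD of the per-replicate below-cutoff fraction
    (NaN for replicates with no gaps).
    """
    all_gaps = np.array([g for p in profiles for g in p.gaps], dtype=float)
    if all_gaps.size == 0:
        raise ValueError("no gaps in the ensemble")
    counts, _ = np.histogram(all_gaps, bins=np.asarray(bin_edges, dtype=float))
    fractions = counts / all_gaps.size
    below = float(np.mean(all_gaps < cutoff))
    per_rep = np.array(
        [
            np.mean(np.asarray(p.gaps) < cutoff) if p.gaps else np.nan
            for p in profiles
        ]
    )
    sd = float(np.nanstd(per_rep, ddof=0)) if np.any(~np.isnan(per_rep)) else float("nan")
    return fractions, below, sd
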
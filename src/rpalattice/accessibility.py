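"""Rad51-relevant ssDNA accessibility of simulated RPA-coated lattices.

A Rad51 filament nucleus needs six monomers at 3 nt each, i.e. an 18-nt run
of naked ssDNA, so accessibility is summarized as the number of gaps of at
least 18 nt per lattice.  Because DBD-D (the 3'-most domain of a 30-nt-mode
RPA) can transiently release its 10 nt, a gap whose 5'-flanking molecule is
in the 30-nt mode is effectively 10 nt larger for nucleation purposes.
Rad51 displacement kinetics are not modeled; measured displacement
efficiencies are treated as external inputs and related to simulated gap
counts by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lattice import LatticeState, Mode
from .observables import GapProfile, count_gaps_ge, gap_profile

__all__ = [
    "AccessibilitySummary",
    "accessible_gap_counts",
    "effective_gap_profile",
    "displacement_correlation",
]

RAD51_NUCLEATION_NT = 18
DBD_D_NT = 10


@dataclass(frozen=True)
class AccessibilitySummary:
    """Mean +- SD (across replicates) of the count of gaps >= threshold."""

    condition: str
    time_s: float
    mean: float
    sd: float
    threshold: int = RAD51_NUCLEATION_NT
    per_replicate: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("mean and sd must be >= 0")


def accessible_gap_counts(
    states: Sequence[LatticeState],
    threshold: int = RAD51_NUCLEATION_NT,
    include_terminal: bool = True,
    condition: str = "",
    effective: bool = False,
) -> AccessibilitySummary:
    """Per-replicate counts of gaps >= ``threshold``, aggregated to mean +- SD.

    With ``effective`` the DBD-D-release bonus (see
    :func:`effective_gap_profile`) is applied before counting.
    """
    if not states:
        raise ValueError("empty ensemble")
    counts = []
    for st in states:
        prof = (
            effective_gap_profile(st, include_terminal=include_terminal)
            if effective
            else gap_profile(st, include_terminal=include_terminal)
        )
        counts.append(count_gaps_ge(prof, threshold))
    arr = np.asarray(counts, dtype=float)
    return AccessibilitySummary(
        condition=condition,
        time_s=states[0].time,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)),
        threshold=threshold,
        per_replicate=tuple(counts),
    )


def effective_gap_profile(state: LatticeState, include_terminal: bool = True) -> GapProfile:
    """Gap profile where each gap 5'-flanked by a 30-nt-mode RPA gains 10 nt.

    Only the 5' flank contributes: DBD-D sits at the 3' end of its footprint,
    so it borders a gap only from the gap's 5' side.  Gaps flanked 5' by a
    20-nt-mode molecule or by the lattice end keep their raw size.
    """
    gaps: list[int] = []
    pos = 0
    left_mode: Mode | None = None  # None = lattice end
    for m in state.molecules:
        if m.start > pos:
            is_terminal = left_mode is None
            if include_terminal or not is_terminal:
                g = m.start - pos
                if left_mode is Mode.FLBM30:
                    g += DBD_D_NT
                gaps.append(g)
        pos = m.end
        left_mode = m.mode
    if pos < state.L and state.molecules and include_terminal:
        g = state.L - pos
        if left_mode is Mode.FLBM30:
            g += DBD_D_NT
        gaps.append(g)
    if not state.molecules and include_terminal and state.L > 0:
        gaps = [state.L]
    return GapProfile(time=state.time, gaps=gaps, include_terminal=include_terminal)


def displacement_correlation(
    gap_counts: Sequence[float], efficiencies: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of displacement efficiency on mean gap count: (slope, intercept, r2)."""
    x = np.asarray(gap_counts, dtype=float)
    y = np.asarray(efficiencies, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in gap counts")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(slope), float(intercept), r2
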
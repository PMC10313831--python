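"""Event-driven stochastic simulation of multi-mode RPA binding on a 1D ssDNA lattice.

The model is a continuous-time Markov chain on configurations of non-overlapping
RPA footprints on an ``L``-nt lattice.  Each bound molecule is in one of two
modes: a 20-nt partial binding mode (PBM20; DNA-binding domains A, B, C engaged)
or a 30-nt full-length mode (FLBM30; DBD-D additionally engages the 10 nt on the
3' side of the footprint).  Four elementary reactions connect configurations:

* bind      -- a PBM20 lands on any fully free 20-nt window, propensity
               ``fold * k_bind`` per window (mass action on available sites),
* unbind    -- a PBM20 leaves, rate ``k_off20`` per PBM20,
* extend    -- a PBM20 whose 10 nt immediately 3' are free (and on-lattice)
               converts to FLBM30, rate ``k_ext`` per extendable molecule,
* retract   -- an FLBM30 releases DBD-D and reverts to PBM20, rate ``k_retr``.

FLBM30 cannot unbind directly; it must retract first.  Volume exclusion is
exact.  Coordinates are 0-based, half-open ``[start, start + footprint)``; the
5' end (tether side) is index 0.  Lattices shorter than 20 nt are legal and
simply admit no binding.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Mode",
    "BoundRPA",
    "LatticeState",
    "RateSet",
    "Phase",
    "Protocol",
    "Trajectory",
    "EnsembleResult",
    "NoEventPossible",
    "free_windows",
    "extendable",
    "propensities",
    "ssa_step",
    "simulate",
    "ensemble",
    "three_step_protocol",
]

PBM20_FOOTPRINT = 20
FLBM30_FOOTPRINT = 30
EXTENSION_NT = FLBM30_FOOTPRINT - PBM20_FOOTPRINT  # 10 nt engaged by DBD-D


class Mode(Enum):
    """Binding mode of one RPA molecule."""

    PBM20 = PBM20_FOOTPRINT
    FLBM30 = FLBM30_FOOTPRINT

    @property
    def footprint(self) -> int:
        return self.value


@dataclass(frozen=True)
class BoundRPA:
    """One bound RPA molecule: 5'-most occupied nucleotide and binding mode."""

    start: int
    mode: Mode

    @property
    def footprint(self) -> int:
        return self.mode.footprint

    @property
    def end(self) -> int:
        """One past the 3'-most occupied nucleotide (half-open)."""
        return self.start + self.mode.footprint


@dataclass
class LatticeState:
    """Positions and modes of all bound RPA molecules at one time point.

    ``molecules`` is kept strictly sorted by ``start``; footprints are pairwise
    disjoint (volume exclusion).  ``validate`` checks both invariants.
    """

    L: int
    molecules: list[BoundRPA] = field(default_factory=list)
    time: float = 0.0

    def validate(self) -> None:
        prev_end = 0
        prev_start = -1
        for mol in self.molecules:
            if mol.start <= prev_start:
                raise ValueError("molecules not strictly sorted by start")
            if mol.start < prev_end:
                raise ValueError("overlapping footprints")
            if mol.start < 0 or mol.end > self.L:
                raise ValueError("footprint outside lattice")
            prev_start, prev_end = mol.start, mol.end
        prev_end  # noqa: B018

    @property
    def n20(self) -> int:
        return sum(1 for m in self.molecules if m.mode is Mode.PBM20)

    @property
    def n30(self) -> int:
        return sum(1 for m in self.molecules if m.mode is Mode.FLBM30)

    @property
    def occupied_nt(self) -> int:
        return sum(m.footprint for m in self.molecules)

    @property
    def free_nt(self) -> int:
        return self.L - self.occupied_nt

    def occupancy_vector(self) -> np.ndarray:
        """Per-site occupancy: 0 free, 20 under a PBM20, 30 under an FLBM30."""
        occ = np.zeros(self.L, dtype=np.int8)
        for m in self.molecules:
            occ[m.start : m.end] = m.footprint
        return occ

    def copy(self) -> "LatticeState":
        return LatticeState(self.L, list(self.molecules), self.time)


@dataclass(frozen=True)
class RateSet:
    """Kinetic parameters of one buffer condition.

    k_bind   binding propensity per fully free 20-nt window per second at fold 1
             (absorbs the fold-1 RPA concentration),
    k_off20  dissociation rate per PBM20 molecule (s^-1),
    k_ext    DBD-D engagement rate per extendable PBM20 (s^-1),
    k_retr   DBD-D release rate per FLBM30 (s^-1).
    """

    label: str
    k_bind: float
    k_off20: float
    k_ext: float
    k_retr: float

    def __post_init__(self) -> None:
        for name in ("k_bind", "k_off20", "k_ext", "k_retr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Phase:
    """One segment of the flow protocol: duration, free-RPA fold, rate set label."""

    duration: float
    fold: float
    rate_label: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("phase duration must be > 0")
        if self.fold < 0:
            raise ValueError("fold must be >= 0")


@dataclass(frozen=True)
class Protocol:
    """Ordered phase schedule with a reference time for normalized observables."""

    phases: tuple[Phase, ...]
    reference_time: float = 1800.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if not 0 <= self.reference_time <= self.total_duration:
            raise ValueError("reference_time outside protocol duration")

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)

    def boundaries(self) -> list[float]:
        out, t = [], 0.0
        for p in self.phases:
            t += p.duration
            out.append(t)
        return out


def three_step_protocol(
    fold: float,
    treat_label: str,
    pre_label: str = "150mM",
    pre_fold: float = 1.0,
    pre_duration: float = 1800.0,
    treat_duration: float = 600.0,
) -> Protocol:
    """The standard curtain schedule: 30-min fold-1 pretreatment in the standard
    (150 mM) buffer, then a 10-min treatment at ``fold`` under ``treat_label``."""
    return Protocol(
        phases=(
            Phase(pre_duration, pre_fold, pre_label),
            Phase(treat_duration, fold, treat_label),
        ),
        reference_time=pre_duration,
    )


# ---------------------------------------------------------------------------
# elementary queries


def _gaps_with_bounds(state: LatticeState) -> list[tuple[int, int]]:
    """Maximal free runs as (start, length), terminal runs included."""
    gaps = []
    pos = 0
    for m in state.molecules:
        if m.start > pos:
            gaps.append((pos, m.start - pos))
        pos = m.end
    if pos < state.L:
        gaps.append((pos, state.L - pos))
    return gaps


def free_windows(state: LatticeState, width: int) -> set[int]:
    """All start positions s with [s, s+width) entirely free."""
    if not 1 <= width <= state.L:
        raise ValueError(f"width {width} out of range for L={state.L}")
    out: set[int] = set()
    for gstart, glen in _gaps_with_bounds(state):
        for s in range(gstart, gstart + glen - width + 1):
            out.add(s)
    return out


def _n_free_windows(state: LatticeState, width: int) -> int:
    return sum(max(0, glen - width + 1) for _, glen in _gaps_with_bounds(state))


def extendable(state: LatticeState) -> set[BoundRPA]:
    """PBM20 molecules whose 10 nt immediately 3' of the footprint are free."""
    out: set[BoundRPA] = set()
    mols = state.molecules
    for i, m in enumerate(mols):
        if m.mode is not Mode.PBM20:
            continue
        if m.start + FLBM30_FOOTPRINT > state.L:
            continue
        nxt = mols[i + 1].start if i + 1 < len(mols) else state.L
        if nxt >= m.start + FLBM30_FOOTPRINT:
            out.add(m)
    return out


def propensities(
    state: LatticeState, rates: RateSet, fold: float
) -> tuple[float, float, float, float]:
    """Channel totals (bind, unbind, extend, retract)."""
    a_bind = fold * rates.k_bind * _n_free_windows(state, PBM20_FOOTPRINT)
    a_unbind = rates.k_off20 * state.n20
    a_extend = rates.k_ext * len(extendable(state))
    a_retract = rates.k_retr * state.n30
    return (a_bind, a_unbind, a_extend, a_retract)


class NoEventPossible(Exception):
    """Raised when all propensities vanish; the caller advances to the next phase."""


# ---------------------------------------------------------------------------
# simulation engine
#
# The engine keeps parallel lists of starts and footprints (sorted by start)
# and incremental N20/N30 counters so each event is O(N) in the number of
# bound molecules.


class _Engine:
    __slots__ = ("L", "starts", "fps", "n20", "n30")

    def __init__(self, L: int, starts: list[int] | None = None, fps: list[int] | None = None):
        self.L = L
        self.starts = starts if starts is not None else []
        self.fps = fps if fps is not None else []
        self.n20 = sum(1 for f in self.fps if f == PBM20_FOOTPRINT)
        self.n30 = len(self.fps) - self.n20

    @classmethod
    def from_state(cls, state: LatticeState) -> "_Engine":
        return cls(
            state.L,
            [m.start for m in state.molecules],
            [m.footprint for m in state.molecules],
        )

    def to_state(self, time: float) -> LatticeState:
        mode_of = {PBM20_FOOTPRINT: Mode.PBM20, FLBM30_FOOTPRINT: Mode.FLBM30}
        return LatticeState(
            self.L,
            [BoundRPA(s, mode_of[f]) for s, f in zip(self.starts, self.fps)],
            time,
        )

    # -- gap / window bookkeeping -------------------------------------------------

    def gaps(self) -> list[tuple[int, int]]:
        gaps = []
        pos = 0
        for s, f in zip(self.starts, self.fps):
            if s > pos:
                gaps.append((pos, s - pos))
            pos = s + f
        if pos < self.L:
            gaps.append((pos, self.L - pos))
        return gaps

    def n_windows(self) -> int:
        w = PBM20_FOOTPRINT - 1
        return sum(glen - w for _, glen in self.gaps() if glen > w)

    def extendable_indices(self) -> list[int]:
        out = []
        n = len(self.starts)
        for i in range(n):
            if self.fps[i] != PBM20_FOOTPRINT:
                continue
            s = self.starts[i]
            if s + FLBM30_FOOTPRINT > self.L:
                continue
            nxt = self.starts[i + 1] if i + 1 < n else self.L
            if nxt >= s + FLBM30_FOOTPRINT:
                out.append(i)
        return out

    def propensities(self, rates: RateSet, fold: float):
        a_bind = fold * rates.k_bind * self.n_windows() if fold * rates.k_bind > 0 else 0.0
        a_unbind = rates.k_off20 * self.n20
        ext_idx: list[int] | None = None
        if rates.k_ext > 0 and self.n20 > 0:
            ext_idx = self.extendable_indices()
            a_extend = rates.k_ext * len(ext_idx)
        else:
            a_extend = 0.0
        a_retract = rates.k_retr * self.n30
        return (a_bind, a_unbind, a_extend, a_retract), ext_idx

    # -- event execution ----------------------------------------------------------

    def do_bind(self, rng: np.random.Generator) -> int:
        w = PBM20_FOOTPRINT - 1
        gaps = [(gs, glen - w) for gs, glen in self.gaps() if glen > w]
        weights = np.array([nwin for _, nwin in gaps], dtype=float)
        gi = int(rng.choice(len(gaps), p=weights / weights.sum()))
        offset = int(rng.integers(gaps[gi][1]))
        s = gaps[gi][0] + offset
        i = bisect.bisect_left(self.starts, s)
        self.starts.insert(i, s)
        self.fps.insert(i, PBM20_FOOTPRINT)
        self.n20 += 1
        return s

    def _pick_mode_index(self, footprint: int, rng: np.random.Generator) -> int:
        idx = [i for i, f in enumerate(self.fps) if f == footprint]
        return idx[int(rng.integers(len(idx)))]

    def do_unbind(self, rng: np.random.Generator) -> int:
        i = self._pick_mode_index(PBM20_FOOTPRINT, rng)
        s = self.starts.pop(i)
        self.fps.pop(i)
        self.n20 -= 1
        return s

    def do_extend(self, ext_idx: list[int], rng: np.random.Generator) -> int:
        i = ext_idx[int(rng.integers(len(ext_idx)))]
        self.fps[i] = FLBM30_FOOTPRINT
        self.n20 -= 1
        self.n30 += 1
        return self.starts[i]

    def do_retract(self, rng: np.random.Generator) -> int:
        i = self._pick_mode_index(FLBM30_FOOTPRINT, rng)
        self.fps[i] = PBM20_FOOTPRINT
        self.n30 -= 1
        self.n20 += 1
        return self.starts[i]

    def step(self, rates: RateSet, fold: float, rng: np.random.Generator):
        """One Gillespie event.  Returns (event_name, waiting_time)."""
        (a_bind, a_unbind, a_extend, a_retract), ext_idx = self.propensities(rates, fold)
        a_tot = a_bind + a_unbind + a_extend + a_retract
        if a_tot <= 0.0:
            raise NoEventPossible
        tau = rng.exponential(1.0 / a_tot)
        r = rng.random() * a_tot
        if r < a_bind:
            self.do_bind(rng)
            return "bind", tau
        r -= a_bind
        if r < a_unbind:
            self.do_unbind(rng)
            return "unbind", tau
        r -= a_unbind
        if r < a_extend:
            if ext_idx is None:
                ext_idx = self.extendable_indices()
            self.do_extend(ext_idx, rng)
            return "extend", tau
        self.do_retract(rng)
        return "retract", tau


def ssa_step(
    state: LatticeState,
    rates: RateSet,
    fold: float,
    rng: np.random.Generator,
) -> tuple[str, float, LatticeState]:
    """One exact stochastic-simulation event from ``state``.

    Returns (event name, exponential waiting time, new state).  Raises
    :class:`NoEventPossible` when every channel has zero propensity.
    """
    eng = _Engine.from_state(state)
    event, tau = eng.step(rates, fold, rng)
    return event, tau, eng.to_state(state.time + tau)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Sampled counts and derived observables of one replicate."""

    times: np.ndarray
    n20: np.ndarray
    n30: np.ndarray
    free_fraction: np.ndarray
    reference_time: float
    L: int
    seed: int
    norm_length: np.ndarray | None = None
    norm_intensity: np.ndarray | None = None
    snapshots: dict[float, LatticeState] = field(default_factory=dict)

    @property
    def n_bound(self) -> np.ndarray:
        return self.n20 + self.n30

    def to_frame(self, replicate: int | None = None):
        import pandas as pd

        d = {
            "time_s": self.times,
            "N20": self.n20,
            "N30": self.n30,
            "free_fraction": self.free_fraction,
            "norm_length": self.norm_length
            if self.norm_length is not None
            else np.full_like(self.times, np.nan, dtype=float),
            "norm_intensity": self.norm_intensity
            if self.norm_intensity is not None
            else np.full_like(self.times, np.nan, dtype=float),
        }
        df = pd.DataFrame(d)
        if replicate is not None:
            df.insert(len(df.columns), "replicate", replicate)
        return df


def simulate(
    protocol: Protocol,
    rate_sets: Mapping[str, RateSet],
    L: int,
    seed: int,
    sample_dt: float = 5.0,
    snapshot_times: Sequence[float] = (1800.0, 2400.0),
    length_model=None,
) -> Trajectory:
    """Simulate one replicate from the empty lattice through all phases.

    Counts are recorded every ``sample_dt`` seconds; full lattice states are
    retained at each requested ``snapshot_times`` that lies within the
    protocol.  Fully reproducible from ``seed``.
    """
    if sample_dt <= 0:
        raise ValueError("sample_dt must be > 0")
    for ph in protocol.phases:
        if ph.rate_label not in rate_sets:
            raise KeyError(f"unknown rate label {ph.rate_label!r}")

    rng = np.random.default_rng(seed)
    eng = _Engine(L)
    total = protocol.total_duration
    sample_times = np.arange(0.0, total + 0.5 * sample_dt, sample_dt)
    sample_times[-1] = min(sample_times[-1], total)
    snap_req = sorted(t for t in snapshot_times if 0.0 <= t <= total)

    n20_out = np.zeros(len(sample_times), dtype=np.int64)
    n30_out = np.zeros(len(sample_times), dtype=np.int64)
    snapshots: dict[float, LatticeState] = {}

    t = 0.0
    si = 0  # next sample index
    ki = 0  # next snapshot index
    phase_start = 0.0
    for phase in protocol.phases:
        phase_end = phase_start + phase.duration
        rates = rate_sets[phase.rate_label]
        while t < phase_end:
            a, ext_idx = eng.propensities(rates, phase.fold)
            a_tot = sum(a)
            if a_tot <= 0.0:
                t_next = phase_end
            else:
                t_next = t + rng.exponential(1.0 / a_tot)
            t_event = min(t_next, phase_end)
            # fill samples and snapshots falling in [t, t_event)
            while si < len(sample_times) and sample_times[si] < t_event:
                n20_out[si], n30_out[si] = eng.n20, eng.n30
                si += 1
            while ki < len(snap_req) and snap_req[ki] < t_event:
                snapshots[snap_req[ki]] = eng.to_state(snap_req[ki])
                ki += 1
            if t_next > phase_end or a_tot <= 0.0:
                t = phase_end
                break
            # execute the chosen event at t_next
            r = rng.random() * a_tot
            a_bind, a_unbind, a_extend, a_retract = a
            if r < a_bind:
                eng.do_bind(rng)
            elif r < a_bind + a_unbind:
                eng.do_unbind(rng)
            elif r < a_bind + a_unbind + a_extend:
                if ext_idx is None:
                    ext_idx = eng.extendable_indices()
                eng.do_extend(ext_idx, rng)
            else:
                eng.do_retract(rng)
            t = t_next
        phase_start = phase_end

    while si < len(sample_times):
        n20_out[si], n30_out[si] = eng.n20, eng.n30
        si += 1
    while ki < len(snap_req):
        snapshots[snap_req[ki]] = eng.to_state(snap_req[ki])
        ki += 1

    occupied = PBM20_FOOTPRINT * n20_out + FLBM30_FOOTPRINT * n30_out
    traj = Trajectory(
        times=sample_times,
        n20=n20_out,
        n30=n30_out,
        free_fraction=(L - occupied) / L,
        reference_time=protocol.reference_time,
        L=L,
        seed=seed,
        snapshots=snapshots,
    )
    if length_model is not None:
        from .observables import attach_normalized_observables

        attach_normalized_observables(traj, length_model)
    return traj


@dataclass
class EnsembleResult:
    """Replicate trajectories plus per-time mean/SD of every observable."""

    trajectories: list[Trajectory]
    times: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]

    def states_at(self, t: float) -> list[LatticeState]:
        return [tr.snapshots[t] for tr in self.trajectories if t in tr.snapshots]

    def summary_frame(self):
        import pandas as pd

        d = {"time_s": self.times}
        for key in self.mean:
            d[f"{key}_mean"] = self.mean[key]
            d[f"{key}_sd"] = self.sd[key]
        return pd.DataFrame(d)


_OBSERVABLE_KEYS = ("n20", "n30", "n_bound", "free_fraction", "norm_length", "norm_intensity")


def ensemble(
    protocol: Protocol,
    rate_sets: Mapping[str, RateSet],
    L: int,
    n_rep: int,
    seed_base: int,
    sample_dt: float = 5.0,
    snapshot_times: Sequence[float] = (1800.0, 2400.0),
    length_model=None,
) -> EnsembleResult:
    """Run ``n_rep`` replicates (replicate r uses seed ``seed_base + r``) and
    summarize per-time mean and SD of each observable."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    trajs = [
        simulate(
            protocol,
            rate_sets,
            L,
            seed=seed_base + r,
            sample_dt=sample_dt,
            snapshot_times=snapshot_times,
            length_model=length_model,
        )
        for r in range(n_rep)
    ]
    times = trajs[0].times
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for key in _OBSERVABLE_KEYS:
        vals = [getattr(tr, key) for tr in trajs]
        if any(v is None for v in vals):
            continue
        stack = np.vstack([np.asarray(v, dtype=float) for v in vals])
        mean[key] = stack.mean(axis=0)
        sd[key] = stack.std(axis=0, ddof=0)
    return EnsembleResult(trajs, times, mean, sd)
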
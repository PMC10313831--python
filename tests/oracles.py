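"""Independent brute-force / exact oracles used by the test suite.

Everything here is deliberately implemented by a different route than the
package (per-site scans, exhaustive enumeration, dynamic programming, matrix
exponentials) so tests compare two independent computations.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from rpalattice.lattice import BoundRPA, LatticeState, Mode, RateSet


# ---------------------------------------------------------------------------
# per-site scans


def occupancy_vector(state: LatticeState) -> np.ndarray:
    occ = np.zeros(state.L, dtype=bool)
    for m in state.molecules:
        occ[m.start : m.end] = True
    return occ


def scan_free_windows(state: LatticeState, width: int) -> set[int]:
    occ = occupancy_vector(state)
    return {
        s for s in range(state.L - width + 1) if not occ[s : s + width].any()
    }


def scan_extendable(state: LatticeState) -> set[BoundRPA]:
    occ = occupancy_vector(state)
    out = set()
    for m in state.molecules:
        if m.mode is not Mode.PBM20:
            continue
        if m.start + 30 > state.L:
            continue
        if not occ[m.start + 20 : m.start + 30].any():
            out.add(m)
    return out


def rle_gaps(state: LatticeState, include_terminal: bool) -> list[int]:
    """Gap multiset via run-length encoding of the occupancy vector."""
    occ = occupancy_vector(state)
    gaps, runs = [], []
    start = None
    for i, o in enumerate(occ):
        if not o and start is None:
            start = i
        elif o and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, state.L - start))
    for s, ln in runs:
        terminal = s == 0 or s + ln == state.L
        if include_terminal or not terminal:
            gaps.append(ln)
    return gaps


# ---------------------------------------------------------------------------
# irreversible RSA jamming coverage (exact expectation by DP)


def rsa_expected_coverage(L: int, k: int = 20) -> float:
    """Expected occupied sites at jamming for uniform random sequential
    adsorption of k-mers on an L-site lattice, by the interval recursion."""
    E = [Fraction(0)] * (L + 1)
    for n in range(k, L + 1):
        m = n - k + 1  # number of feasible positions
        E[n] = Fraction(k) + Fraction(2, m) * sum(E[i] for i in range(0, n - k + 1))
    return float(E[L])


# ---------------------------------------------------------------------------
# exact equilibrium enumeration (reversible lattice gas, one or two modes)


def equilibrium_moments(L: int, a: float, b: float = 0.0):
    """Exact equilibrium means of the reversible footprint gas on L sites.

    Configuration weight ``a**N20 * (a*b)**N30`` with ``a = fold*k_bind/k_off20``
    per molecule and ``b = k_ext/k_retr`` (``b = 0`` excludes the 30-nt mode).
    Returns (E[N20], E[N30]) by suffix dynamic programming.
    """
    c = a * b
    Z = [0.0] * (L + 31)
    M20 = [0.0] * (L + 31)
    M30 = [0.0] * (L + 31)
    Z[L] = 1.0
    for i in range(L - 1, -1, -1):
        Z[i] = Z[i + 1]
        M20[i] = M20[i + 1]
        M30[i] = M30[i + 1]
        if i + 20 <= L:
            Z[i] += a * Z[i + 20]
            M20[i] += a * (Z[i + 20] + M20[i + 20])
            M30[i] += a * M30[i + 20]
        if i + 30 <= L and c > 0:
            Z[i] += c * Z[i + 30]
            M20[i] += c * M20[i + 30]
            M30[i] += c * (Z[i + 30] + M30[i + 30])
    return M20[0] / Z[0], M30[0] / Z[0]


def equilibrium_p20(L: int, a: float, b: float) -> float:
    """Stationary P20 = E[N20 / (N20+N30) | N>0] by full enumeration."""
    configs = enumerate_configs(L)
    num = 0.0
    den = 0.0
    for mols in configs:
        n20 = sum(1 for _, fp in mols if fp == 20)
        n30 = len(mols) - n20
        if n20 + n30 == 0:
            continue
        w = a**n20 * (a * b) ** n30
        num += w * (n20 / (n20 + n30))
        den += w
    return num / den


def enumerate_configs(L: int) -> list[tuple[tuple[int, int], ...]]:
    """All configurations of disjoint 20/30-nt footprints on L sites."""
    out: list[tuple[tuple[int, int], ...]] = []

    def rec(pos: int, acc: tuple[tuple[int, int], ...]):
        out.append(acc)
        for s in range(pos, L):
            for fp in (20, 30):
                if s + fp <= L:
                    rec(s + fp, acc + ((s, fp),))

    rec(0, ())
    return out


# ---------------------------------------------------------------------------
# master equation on an enumerable lattice


def build_master_equation(L: int, rates: RateSet, fold: float):
    """States and generator matrix Q (Q[i, j] = rate i->j) for the full chain."""
    states = enumerate_configs(L)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))

    def free_ok(mols, s, fp):
        for ms, mfp in mols:
            if s < ms + mfp and ms < s + fp:
                return False
        return 0 <= s and s + fp <= L

    for i, mols in enumerate(states):
        # bind: each feasible 20-window individually at rate fold*k_bind
        for s in range(0, L - 20 + 1):
            if free_ok(mols, s, 20):
                new = tuple(sorted(mols + ((s, 20),)))
                Q[i, index[new]] += fold * rates.k_bind
        for m in mols:
            s, fp = m
            rest = tuple(x for x in mols if x != m)
            if fp == 20:
                Q[i, index[tuple(sorted(rest))]] += rates.k_off20
                if s + 30 <= L and free_ok(rest, s, 30):
                    new = tuple(sorted(rest + ((s, 30),)))
                    Q[i, index[new]] += rates.k_ext
            else:
                new = tuple(sorted(rest + ((s, 20),)))
                Q[i, index[new]] += rates.k_retr
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return states, Q


def master_equation_probabilities(L: int, rates: RateSet, fold: float, t: float):
    """P(state, t) from the empty lattice, via the matrix exponential."""
    from scipy.linalg import expm

    states, Q = build_master_equation(L, rates, fold)
    p0 = np.zeros(len(states))
    p0[states.index(())] = 1.0
    return states, p0 @ expm(Q * t)


# ---------------------------------------------------------------------------
# misc


def brute_force_pick_end(candidates) -> float:
    """Exhaustive 3-window scan with the documented tie rule (variances equal
    up to a 1e-9 relative rounding band tie toward the smaller mean)."""
    cand = sorted(float(c) for c in candidates)
    stats = []
    for i in range(len(cand) - 2):
        w = cand[i : i + 3]
        stats.append((float(np.var(w)), float(np.mean(w))))
    vmin = min(v for v, _ in stats)
    return min(mu for v, mu in stats if v <= vmin * (1 + 1e-9))


def random_state(rng: np.random.Generator, L: int) -> LatticeState:
    """A random valid lattice state by rejection placement."""
    mols: list[BoundRPA] = []
    occ = np.zeros(L, dtype=bool)
    for _ in range(rng.integers(0, 6)):
        fp = int(rng.choice([20, 30]))
        if L < fp:
            continue
        s = int(rng.integers(0, L - fp + 1))
        if occ[s : s + fp].any():
            continue
        occ[s : s + fp] = True
        mols.append(BoundRPA(s, Mode.PBM20 if fp == 20 else Mode.FLBM30))
    mols.sort(key=lambda m: m.start)
    return LatticeState(L, mols)
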
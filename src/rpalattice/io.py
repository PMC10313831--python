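"""Delimited-text I/O with provenance headers.

Every table written by the pipeline starts with ``#``-prefixed comment lines
recording the package version, configuration hash and seeds, so reruns are
attributable and bit-identical for identical inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .lattice import EnsembleResult, Mode
from .observables import GapProfile

__all__ = [
    "write_table",
    "read_table",
    "trajectories_frame",
    "snapshots_frame",
    "gap_profiles_frame",
]


def provenance_lines(meta: Mapping[str, object]) -> list[str]:
    from . import __version__

    lines = [f"# rpalattice version: {__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    return lines


def write_table(path, frame: pd.DataFrame, meta: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(meta or {}):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def trajectories_frame(ens: EnsembleResult) -> pd.DataFrame:
    return pd.concat(
        [tr.to_frame(replicate=r) for r, tr in enumerate(ens.trajectories)],
        ignore_index=True,
    )


def snapshots_frame(ens: EnsembleResult) -> pd.DataFrame:
    rows = []
    for r, tr in enumerate(ens.trajectories):
        for t, state in sorted(tr.snapshots.items()):
            for mol in state.molecules:
                rows.append(
                    {"replicate": r, "time_s": t, "start": mol.start,
                     "mode": "PBM20" if mol.mode is Mode.PBM20 else "FLBM30"}
                )
    return pd.DataFrame(rows, columns=["replicate", "time_s", "start", "mode"])


def gap_profiles_frame(profiles_by_rep: Mapping[int, Iterable[GapProfile]]) -> pd.DataFrame:
    rows = []
    for r, profiles in profiles_by_rep.items():
        for prof in profiles:
            for g in prof.gaps:
                rows.append({"replicate": r, "time_s": prof.time, "gap_length": g})
    return pd.DataFrame(rows, columns=["replicate", "time_s", "gap_length"])
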
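"""Regenerate the shipped default parameters.

Fits the two-mode binding model to the printed endpoint summaries shipped in
``rpalattice/data/observations_printed.csv`` (weighted least squares with
common random numbers; mean-field pre-fit followed by stochastic coordinate
descent) and rewrites the ``rate_sets`` / ``length_model`` blocks of
``rpalattice/data/defaults.yaml`` in place.  Run from the repository root:

    python scripts/calibrate_defaults.py [--seed 12345] [--n-rep 8]

This is the provenance of the shipped defaults; it is deterministic for a
given seed.
"""

from __future__ import annotations

import argparse
import datetime
import importlib.resources as resources
from pathlib import Path

import yaml

from rpalattice.calibrate import ObservationSet, RPABindingModel

DATA = Path(__file__).resolve().parent.parent / "src" / "rpalattice" / "data"

START = {
    "150mM.k_bind": 4.5e-6,
    "150mM.k_off20": 2e-5,
    "150mM.k_ext": 0.01,
    "150mM.k_retr": 1e-3,
    "15mM.k_bind": 4.5e-6,
    "15mM.k_off20": 1e-4,
    "15mM.k_ext": 1e-3,
    "15mM.k_retr": 1e-3,
    "alpha": 2.2,
    "beta": 1.15,
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=12345)
    ap.add_argument("--n-rep", type=int, default=8)
    ap.add_argument("--max-sweeps", type=int, default=4)
    args = ap.parse_args()

    obs = ObservationSet.from_csv(DATA / "observations_printed.csv")
    model = RPABindingModel(obs, L=5000, n_rep=args.n_rep, sample_dt=30.0)
    res = model.fit(start_params=START, seed=args.seed, max_sweeps=args.max_sweeps,
                    use_meanfield_prefit="nm")
    print(res.summary())

    cfg_path = DATA / "defaults.yaml"
    doc = yaml.safe_load(cfg_path.read_text())
    params = res.params
    for label in ("150mM", "15mM"):
        for name in ("k_bind", "k_off20", "k_ext", "k_retr"):
            doc["rate_sets"][label][name] = float(f"{params[f'{label}.{name}']:.6g}")
    doc["length_model"]["alpha"] = float(f"{params['alpha']:.6g}")
    doc["length_model"]["beta"] = float(f"{params['beta']:.6g}")
    doc["provenance"] = (
        "rate_sets/length_model fitted to data/observations_printed.csv by "
        f"scripts/calibrate_defaults.py (seed={args.seed}, n_rep={args.n_rep}, "
        f"weighted SSE={res.sse:.3f}, {datetime.date.today().isoformat()})"
    )
    cfg_path.write_text(yaml.safe_dump(doc, sort_keys=False))
    print(f"\nwrote {cfg_path}")


if __name__ == "__main__":
    main()
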
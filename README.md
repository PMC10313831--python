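# rpalattice

Stochastic lattice model of multiple Replication Protein A (RPA) molecules
dynamically binding long single-stranded DNA (ssDNA), with the observables,
calibration machinery and image-analysis tools needed to connect the model to
single-molecule ssDNA-curtain experiments.

## Who this is for

Single-molecule biophysicists and DNA-repair researchers who want to ask how
a population of large-footprint ssDNA-binding proteins organizes on a long
substrate: how much naked ssDNA remains exposed between neighbouring
proteins, how that exposure depends on protein concentration, salt and
binding mode, and whether the residual gaps are long enough (≥ 18 nt) for a
Rad51 filament to nucleate on an RPA-coated strand.

## The model

RPA binds ssDNA in two stable footprint modes: a 20-nt *partial binding
mode* (DNA-binding domains A, B, C engaged) and a 30-nt *full-length mode*
(DBD-D additionally engages the 10 nt on the 3′ side).  On a lattice of
`L` nt (default 5000) with exact volume exclusion, the continuous-time
Markov chain has four reactions:

```
free 20-nt window  --(fold · k_bind)-->  PBM20          (binding)
PBM20              --(k_off20)------->   empty          (dissociation)
PBM20 + free 10 nt 3' --(k_ext)----->    FLBM30         (DBD-D engagement)
FLBM30             --(k_retr)-------->   PBM20          (DBD-D release)
```

`fold` is the free-RPA concentration multiplier of a flow phase (0 for a
protein-free wash).  The 30-nt mode cannot dissociate directly; it must
release DBD-D first.  Trajectories are generated by an exact Gillespie
algorithm; the empty lattice plus a phased protocol (30-min pretreatment at
fold 1, then 10 min at the treatment fold) reproduces the three-step curtain
schedule.

Observables: the physical complex length is
`m · (free_nt + α·20·N20 + β·30·N30)` with α > β (20-nt-mode ssDNA is the
more extended conformation); fluorescence intensity is the bound-molecule
count; both are reported as normalized increments relative to the 30-min
reference point, `(x_t − x_ref)/x_ref`.  Gap statistics (multiset of naked
runs, counts of runs ≥ 18 nt, effective gaps under transient DBD-D release)
quantify Rad51-relevant accessibility.

Calibration is a statsmodels-style model/results pair: `RPABindingModel`
wraps an observation table (normalized length/intensity/free-fraction
summaries per condition and fold, absolute or paired-difference records) and
`fit()` minimizes the sem-weighted squared error with common random numbers
(optional mean-field pre-fit, coordinate-descent polish), returning
`RPABindingResults` with estimates, objective log and `summary()`.

The kymograph module renders TIRFM-like position×time images of a tethered
ssDNA–RPA complex (PSF blur, shot/read noise, ground-truth end positions)
and implements the step-edge end tracker: four per-column edge detectors
(two-plateau step fit, maximal drop, mean-threshold and two-class-threshold
crossings) combined by the minimal-variance three-candidate rule.

## Worked example

Simulate the 25-fold, 150 mM NaCl treatment under the shipped calibrated
parameters and summarize the ensemble:

```python
import numpy as np
import rpalattice as rp
from rpalattice.accessibility import accessible_gap_counts

cfg = rp.default_config()
proto = cfg.protocol("fold25_150mM")          # 1800 s at fold 1, 600 s at fold 25
ens = rp.ensemble(proto, cfg.rate_sets, cfg.lattice_length, n_rep=20,
                  seed_base=1, length_model=cfg.length_model)
i30 = int(np.argmin(np.abs(ens.times - 1800.0)))
print(f"free fraction at 30 min: {ens.mean['free_fraction'][i30]:.3f}")
print(f"free fraction at 40 min: {ens.mean['free_fraction'][-1]:.3f}")
print(f"norm. length increment 30->40 min: {100*ens.mean['norm_length'][-1]:+.1f}%")
print(f"norm. intensity increment 30->40 min: {100*ens.mean['norm_intensity'][-1]:+.1f}%")
acc = accessible_gap_counts(ens.states_at(2400.0), threshold=18)
print(f"gaps >= 18 nt per 5-knt ssDNA at 40 min: {acc.mean:.1f} +- {acc.sd:.1f}")
```

Output:

```
free fraction at 30 min: 0.824
free fraction at 40 min: 0.379
norm. length increment 30->40 min: +34.9%
norm. intensity increment 30->40 min: +278.7%
gaps >= 18 nt per 5-knt ssDNA at 40 min: 41.5 +- 5.8
```

Read: the dilute 30-min pretreatment leaves ~82% of the lattice naked; ten
minutes at 25-fold RPA drives occupancy to ~62%, lengthening the complex by
~35% as molecules load and shift toward the extended 20-nt mode — yet ~40
gaps of Rad51-nucleation size survive per 5000-nt molecule, because volume
exclusion jams the lattice long before full coverage.

The same pipeline is scriptable from the shell:

```bash
rpalattice simulate --protocol fold25_150mM --n-rep 20 --out out/
rpalattice gaps --protocol fold10_150mM --time 2400 --out gaps/
rpalattice kymo-sim --out kymo/ && rpalattice kymo-track kymo/kymograph.tif --truth kymo/truth.csv
rpalattice report
```

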
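# synergyflow

Modular-control analysis of cutting manoeuvres: muscle-synergy extraction
from surface EMG, cross-condition comparison under balance perturbations,
knee co-contraction and centre-of-mass (CoM) power kinetics.

## The problem

During a 90° side-step cut, the nervous system coordinates ~16 lower-limb
and trunk muscles. A compact description models the muscles-by-time
envelope matrix **X** (M muscles × K cycle points, values in [0, 1]) as a
small set of **motor modules**:

```
X ≈ S · P
```

where **S** (M × N) holds non-negative muscle weightings (one column per
module) and **P** (N × K) the non-negative activation signals that drive
them across the movement cycle. Both factors are found by non-negative
matrix factorization (NMF) with multiplicative updates minimizing the
Frobenius error; reconstruction quality is the variance accounted for,

```
VAF = 1 − SSE / SST,   SST = Σ X²  (uncentered)
```

and the number of modules N is the smallest count whose VAF clears an 80 %
floor once the VAF-vs-N curve has flattened. The package asks, on data with
known ground truth: when a support-surface translation perturbs the
manoeuvre at initial contact, is the change carried by the muscle
weightings or by the activation signals? The tools for that question are

* matched cosine similarities (normalized scalar products, "similar" if
  r > 0.80) between module sets,
* **fixed-factor cross-reconstruction**: rebuild perturbed EMG holding one
  unperturbed factor fixed and iterating the NMF update of the free factor
  1000 times — if weightings are preserved but timing changes, fixing
  weightings reconstructs far better than fixing activations,
* knee **co-contraction ratio** CCR = mean(BF, ST) / mean(VM, VL, RF) and
  **index** CCI = mean(BF, ST, VM, VL, RF) × CCR in three epochs (PRE: 10 ms
  before contact; LA: contact → negative CoM-power peak; PRP: ±25 ms around
  the positive CoM-power peak),
* kinetics: 20 N threshold stance detection, CoM power F·v/m (W/kg),
  external work of the load-acceptance and propulsion phases, approach
  speed, horizontal force peaks.

No human data ship with the package; the `synthetic` module generates
envelope and kinetic data with planted modules, cycle-locked Gaussian
activation bumps, clipped additive noise, and a perturbed condition that
down-scales the hamstring/gluteal module during load acceptance — so every
analysis can be validated against ground truth.

## Worked example

```bash
synergyflow simulate --out data/subj01 --seed 5 --n-upt 6
synergyflow run --config data/subj01/study.yaml
```

which prints `selected 5 modules; report written to data/subj01/report.json`.
The same thing in Python:

```python
from synergyflow import pipeline
cfg = pipeline.simulate_subject("data/subj01", seed=5, n_upt=6)
report = pipeline.run_subject(cfg)
print(report["n_modules"])                         # 5  (planted: 5)
print(report["upt"]["peak_timing_pct"])            # [10.6, 37.2, 63.8, 81.9, 95.5]
print(report["similarity"]["weightings"]["pairs"]) # [0.998, 0.996, 0.994, 1.0, 1.0]
print(report["cross_reconstruction"])
# {'weightings':  {'vaf_fixed_upt': 0.998, 'vaf_random_baseline': 0.517},
#  'activations': {'vaf_fixed_upt': 0.991, 'vaf_random_baseline': 0.401}}
print(report["cocontraction"]["UPT"]["la"]["ccr"], # 3.61
      report["cocontraction"]["PTB"]["la"]["ccr"]) # 2.80  (reduced by the perturbation)
```

Reading the numbers: the VAF-curve rule recovers the planted dimensionality
(5); activation peaks land at the planted 10/37/64/83/95 % cycle positions;
weighting similarity between conditions stays ≈ 1 because the perturbation
only rescales activation signals; fixing the unperturbed weightings
reconstructs the perturbed EMG better than a random-matrix baseline; and
the load-acceptance CCR drops in the perturbed condition because the
hamstring-weighted module was down-scaled there.

Individual stages are also exposed (`synergyflow preprocess | factorize |
compare | crossfit | kinetics | cocontraction`); see `--help` on each.

## Layout

```
src/synergyflow/
  preprocess.py     band-pass, rectify/low-pass envelopes, 200-point cycle
                    normalization, the two amplitude-normalization schemes
  factorization.py  multiplicative-update NMF, VAF, dimensionality selection
  analysis.py       similarity, module matching, fixed-factor reconstruction
  cocontraction.py  epoch windows, CCR/CCI
  kinetics.py       stance events, CoM power/work, speed, force peaks
  synthetic.py      ground-truth generators (envelopes and kinetics)
  pipeline.py       per-subject UPT-vs-PTB workflow, study config
  io.py             EMG CSV / kinetics TSV / JSON sidecar formats
  cli.py            click command group (`synergyflow`)
docs/methods.md     model, assumptions, parameter choices, limitations
```
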
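# qibc — cell-cycle-resolved quantitative image-based cytometry

`qibc` quantifies drug toxicity readouts from multi-channel fluorescence
microscopy at the single-cell level and resolved by cell-cycle position.  It
is built for the kind of question PARP-inhibitor biology poses: a genotoxic
drug that damages only replicating cells produces a response invisible in
population averages, because the S-phase subpopulation is diluted by G1 and
G2 cells.  Quantitative image-based cytometry (QIBC) treats every segmented
nucleus as a cytometry event — total DAPI as DNA content, per-channel mean
intensities as marker levels — and gates analyses on the cell-cycle stage
inferred from those features.

The package provides, as importable modules behind a thin `qibc` CLI:

* **simulate** — a ground-truth generator for asynchronous cell populations
  (stage mixture, 2C–4C DNA content, S-restricted EdU, Cyclin A ramp,
  H3pS10-marked condensed mitoses, stage-gated drug effects, chromatin-bound
  PARP1 trapping under pre-extraction), rendered to noisy 12-bit images with
  label masks, or emitted directly as measured feature tables.
* **imaging** — dynamic background correction, intensity-based nucleus
  segmentation (Otsu + distance-transform watershed), Laplacian-of-Gaussian
  focus detection, exact per-nucleus feature extraction.
* **staging** — per-batch DNA-content normalization
  (`C = 2 · total DAPI / G1 mode`), 2C–4C filtering, mitotic classification
  by chromatin condensation (mean DAPI) and/or H3pS10, 1D/2D/4D staging and
  early/mid/late S binning.
* **quantify** — stage-gated summaries, two-sided Mann–Whitney comparisons
  with rank-biserial effect sizes, subpopulation dynamic range,
  PARP-trapping cell-cycle-independence profiles, mitotic condensation
  metrics.
* **screen** — per-well staged summaries and robust per-gene z-scores
  (`z = (v − median)/(1.4826·MAD)`) of S-phase γH2AX across siRNA replicate
  wells, with hit ranking and replicate-concordance QC.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

An untreated population versus one with a 4-fold S-phase-restricted γH2AX
induction (4,000 cells each), staged from DAPI + EdU and quantified:

```python
import dataclasses, pandas as pd
from qibc import staging, quantify
from qibc.simulate import SimulationParams, DrugEffects, simulate_features

base = SimulationParams(n_cells=4000, markers=("gh2ax", "edu"), seed=1)
treated = dataclasses.replace(
    base, drug_effects=DrugEffects(s_phase_gh2ax_fold=4.0), seed=2)

cells = pd.concat([
    simulate_features(base, meta={"condition": "untreated"}),
    simulate_features(treated, meta={"condition": "olaparib"}),
], ignore_index=True)

staged = staging.bin_s_phase(staging.stage_cells(cells, ("dapi", "edu")))
print(quantify.dynamic_range(staged, "olaparib", "untreated", "gh2ax")
      .round(2).to_string(index=False))
```

```
 gate  fold_change  n_treated  n_reference flag
  all         2.02       3968         3964
    S         4.02       1350         1384
mid_S         4.05        460          483
```

The whole-population fold change (2.02) understates the true S-phase effect
because G1/G2 cells dilute it; gating on S or mid-S recovers the full
4-fold induction — the dynamic-range gain that motivates subpopulation
focusing.  A Mann–Whitney comparison of 400 mid-S cells per condition gives
`U=158905, p=8.6e-129, rank-biserial=-0.99`: cohorts of a few hundred cells
are ample to discriminate treated from untreated.

The same analysis runs end-to-end from rendered images:

```bash
qibc run --config examples/demo.json --out results/demo --seed 1
```

which renders four conditions (untreated; PARPi with S-phase γH2AX
induction, EdU slow-down and PAR suppression; PARPi+MMS pre-extracted with
PARP1 trapping; PARPi+ATRi with mitotic damage) across eight channels
including RAD51 foci, then segments, stages and quantifies, and writes
`features.csv`, `staged.csv`, `summaries.csv` and a reproducibility manifest
(seed, parameter hash, per-stage row counts).  Identical config and seed
reproduce byte-identical tables.

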
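# acinarca

Analysis and modelling of intravital Ca²⁺ signalling in salivary-gland
acinar cells.

In vivo GCaMP imaging of the stimulated submandibular gland shows Ca²⁺
signals that are fast (~1 Hz trains of sub-2 s transients), confined to
within ~3 µm of the apical membrane, and recruited in a graded way with
nerve-stimulation strength — about a third of 32 µm field subdivisions
respond at 1 Hz stimulation (latency ≈ 6.7 s) versus nearly all at 10 Hz
(latency ≈ 1.7 s), when a standing apical–basal gradient forms with basal
Ca²⁺ at ~25–30% of apical. `acinarca` is for researchers who want to
quantify such recordings or explore how a purely apical Ca²⁺ signal can
still drive fluid secretion. It provides:

* **imaging** — movie I/O (multi-page TIFF + JSON metadata), 3-frame
  averaging, %ΔF/F₀ conversion, SD images, rigid registration;
* **grids** — the field-level workflow: 32 µm grid traces, the 4σ
  responder criterion, latency, peak ΔF/F, fluctuation SD, rank sorting
  across stimulation strengths, linear regression;
* **rois** — automated apical-ROI detection (difference image →
  threshold → binary dilation/erosion → labelling) and oscillation peak
  counting (resample → zero-phase low-pass → zero-phase high-pass →
  prominence-based peaks mapped back to the raw trace);
* **linescan** — apical/cytosolic/basal 3 µm ROI kinetics and
  maximum-response spatial profiles normalised to a reference;
* **synthetic** — a generator of movies and line scans with ground-truth
  event logs, calibrated to the statistics above, so every analysis stage
  is testable without recordings;
* **model** — a multiscale single-cell model: a closed-cell Class-I
  Ca²⁺ oscillator on a 1-D apical–basal chain (IP₃R trigger-zone release,
  fast linear buffering folded into effective coefficients, no RyR,
  V_PLC as the stimulation proxy) coupled to an ion-transport/osmotic
  module with apical TMEM16a, KCa channels on both membranes, a 70/30
  basolateral/apical Na⁺/K⁺-ATPase split, NKCC1, an anion exchanger and a
  paracellular Na⁺ pathway.

The model's core question: with no propagated Ca²⁺ wave, what sustains
the K⁺ conductance that keeps Cl⁻ (and hence water) flowing? Placing KCa
channels in the apical membrane answers it — removing them (at fixed
total KCa conductance) cuts steady-state secretion by about a third, and
secretion is maximal when apical and basolateral densities are equal.

## Worked example

Render a synthetic field at the 5 Hz preset, analyse it with the grid
workflow, and run the calibrated secretion model:

```
$ acinarca simulate-movie --preset 5 --seed 7 --pixel-um 2 --out demo/
wrote demo/movie.tif (49/64 grids responding)

$ acinarca analyze-grid demo/movie.tif --grid-um 32 --out demo/metrics.csv
76.6% of grids responding -> demo/metrics.csv

$ acinarca run-model --vplc 0.008 --t-end 500 --out demo/model.h5
frequency 0.59 Hz, latency 1.97 s -> demo/model.h5
```

The first command writes a 30 s movie (12 s stimulation from t = 10 s)
whose ground-truth event log records 49 of 64 grids responding; the grid
analysis recovers 76.6% responding (49/64), each grid classified by a
ΔF/F excursion above 4× its baseline SD. The model run reports apical
Ca²⁺ oscillations at 0.59 Hz (within the 0.5–1 Hz band observed at
strong stimulation) with a 1.97 s latency after stimulus onset; the
stored traces also give a basal/apical Ca²⁺ elevation ratio of 28% and a
secretion time course rising from ≈0 to its oscillatory steady state.

From Python:

```python
from acinarca import model

result = model.simulate(t_end_s=500.0, stim_onset_s=100.0)
freq, latency = model.oscillation_metrics(result)   # 0.59 Hz, 1.97 s
ratio = model.apical_basal_ratio(result)            # 0.281
rho, q = model.sweep_apical_kca([0.0, 1.0])
print(100 * (1 - q[0] / q[1]))                      # 34.7 (% drop)
```

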
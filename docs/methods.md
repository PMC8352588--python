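# Methods

This note records the models, algorithms and numerical choices behind
`acinarca`, and what the synthetic benchmarks do and do not establish.

## Scientific setting

Submandibular-gland acinar cells secrete saliva when parasympathetic
stimulation raises cytosolic Ca²⁺. In vivo GCaMP imaging shows behaviour
quite unlike classical in vitro preparations: at physiological stimulation
strengths the Ca²⁺ signal consists of fast (~1 Hz) trains of brief (<2 s)
transients confined within ~3 µm of the apical plasma membrane, with no
propagated apical-to-basal wave; at strong (10 Hz) stimulation a standing
gradient forms in which basal Ca²⁺ reaches only ~25–30% of the apical
level. Recruitment is stimulus-dependent — roughly a third of 32 µm field
subdivisions respond at 1 Hz nerve stimulation (latency ≈ 6.7 s) versus
nearly all at 10 Hz (latency ≈ 1.7 s). The package implements (i) the
image-analysis workflow that quantifies those statistics, (ii) a synthetic
movie generator that emulates them with known ground truth so that every
analysis stage is testable without recordings, and (iii) a multiscale
single-cell model in which a purely apical Ca²⁺ signal nevertheless drives
sustained fluid secretion, because Ca²⁺-activated K⁺ (KCa) channels and
Na⁺/K⁺-ATPase are present on the apical membrane.

## Image analysis

*Grid workflow.* Movies (30 s, 10 fps; acquisition at 30 fps is averaged
in groups of three by `frame_average`) are converted to %ΔF/F₀ with the
per-pixel mean of the up-to-100 pre-stimulus frames as F₀. The field is
divided into 32 × 32 µm grids (8 × 8 on a 256 µm field); each grid's
spatial-mean trace is classified as *responding* when it exceeds 4× its
baseline standard deviation (sample SD, strictly greater-than) during the
stimulus window. Latency is the first supra-threshold frame minus stimulus
onset; an option requires k consecutive supra-threshold frames, but
single-frame exceedance is the default. Non-responding grids are excluded
from latency averages. Note the 4σ rule has a small irreducible
false-positive rate (≈1–2% of grids over a 120-frame stimulus window)
that is independent of the noise SD, since the threshold scales with the
noise estimate.

*Subcellular workflow.* Apical ROIs are found from a difference image
(mean stimulated frame − mean pre-stimulus frame), thresholded (Otsu by
default), smoothed by binary dilation then erosion (disk radius 2 px
each), with components below 20 px discarded. Per-ROI traces feed a
peak counter: resample to 20 Hz, zero-phase (forward–backward) Butterworth
low-pass at 4 Hz and high-pass at 0.05 Hz (order 3), local-maximum
detection with prominence ≥ 4× the baseline SD of the filtered trace, and
mapping of each detected peak to the nearest raw-trace local maximum
within ±0.3 s. The filter corners are not dictated by the experimental
protocol; they were chosen once to pass 0.2–1.5 Hz oscillations while
removing drift, and are exposed in `PeakParams`.

*Line scans.* Three caller-positioned 3 µm ROIs (apical, cytosolic before
the nucleus, basal distal to it) summarise position × time scans; each
ROI's pre-stimulus fluorescence is its own F₀. The spatial profile at the
time of maximum response — located on a 0.5 s boxcar-smoothed whole-line
mean to avoid selecting a single noisy line — is expressed as a
percentage of a reference maximum (by convention, the 10 Hz response of
the same line).

## Synthetic recordings

The generator builds fields of acini, one per 32 µm grid square: a lumen
line at the square centre with 2–5 cells tiled on both sides, each with a
contiguous apical band (3 µm) against the lumen and a nucleus rendered as
a disk of reduced baseline fluorescence and attenuated signal. Per-acinus
latent variables (response quantile, sensitivity, latency deviate) are
drawn from the geometry seed and therefore *shared across stimulation
conditions*, which reproduces the experimental observation that the same
regions are the most responsive at every stimulus strength.

Responding acini emit renewal trains of transients (rate ≈ 1 Hz, 10% CV,
per-event lognormal amplitude) starting at onset + latency; each
transient is a 0.1 s linear rise followed by a 0.4 s exponential decay,
truncated at 1.5 s. The apical band carries the full amplitude; the rest
of the cell a `basal_fraction`-scaled copy. Noise is additive Gaussian on
ΔF/F (default 2%). Presets anchor the calibration: responder probability
0.34 / 0.985, latency 6.72 ± 0.79 s / 1.70 ± 0.27 s and basal fraction
0.03 / 0.27 at the 1 and 10 Hz presets respectively, with the 3 and 5 Hz
presets interpolating monotonically (0.60/0.80 responder probability,
4.5/3.0 s latency — interpolated values, not measured ones).

What the generator does *not* emulate: photon shot noise and detector
statistics (noise is Gaussian on ΔF/F), optical blur, indicator binding
kinetics and saturation, breathing motion beyond optional rigid drift,
and irregular tissue morphology (acini are rectilinear). Passing
parameter-recovery tests therefore establishes the correctness and
statistical calibration of the analysis code under the stated noise
model, not robustness to every artefact of intravital microscopy.

## The secretion model

### Ca²⁺ module (closed cell, Class I)

Cytosolic Ca²⁺ c(x,t) lives on a 1-D apical–basal chain (40 compartments
over 12 µm; apical region = first 3 µm, basal region = last 3 µm) and
obeys

    ∂c/∂t = D_c ∂²c/∂x² + (J_release − J_SERCA + J_leak) / w,

with effective (buffered) diffusion D_c = 10 µm²/s, a volume scaling
factor w, and a well-mixed ER pool c_er (cytosol/ER volume ratio γ = 5)
so that w·⟨c⟩ + c_er/γ is exactly conserved — there are no plasma-membrane
Ca²⁺ fluxes. IP₃ is well mixed (D_p = 100 × D_c) and follows
dp/dt = V_PLC − k_p·p with Ca²⁺-independent production; V_PLC is the
stimulation proxy (default 0.008 µM/s, applied from t = 100 s).

IP₃R release enters over the apical trigger-zone ER (the compartments
within 3 µm of the apical membrane), gated by the zone-mean Ca²⁺:

    P_open = [p²/(p²+K_p²)] · [b + (1−b)·c/(c+K_act)] · h,
    dh/dt = (h_∞(c) − h)/τ_h,   h_∞ = K_inh²/(K_inh² + c²),

a two-variable Class-I reduction (fast activation by Ca²⁺ and IP₃, slow
inactivation h, τ_h = 0.8 s, constitutive openness b = 0.11 for ignition
from rest). RyR flux is an explicit parameter fixed at 0. Oscillations are
relaxation cycles of the (c, h) pair; the SERCA half-point (0.1 µM, just
above rest) makes uptake saturate early so that the release–uptake balance
destabilises at the operating point — placing the operating Ca²⁺ on the
steep branch of the activation curve is what admits a limit cycle at all.

Two spatial features compensate for the reduction from the original 3-D
fingered-apical-membrane geometry to a 1-D chain, and both are exposed as
parameters: (i) a fraction (0.32) of the IP₃R flux is distributed along
the whole cell, standing in for apical membrane that wraps partially
around the cell and brings release sites close to nominally basal
cytosol; (ii) SERCA density is apically weighted (full in the trigger
zone, 15% outside) with a 4× band at 4–7 µm representing the perigranular
mitochondrial belt that limits Ca²⁺ spread into the mid-cell. Without (i)
the basal/apical ratio cannot exceed a few percent in 1-D; without (ii)
the 25–35% basal/apical ratio and the apical confinement of the model
line scan (>60% of the ΔCa integral in the apical third) are mutually
exclusive.

### Secretion module

Na⁺, K⁺ and Cl⁻ are well mixed in the cell and in a small lumen (5% of
cell volume). Apical membrane: TMEM16a Cl⁻ channels (Hill 3 in local
Ca²⁺, half-point 0.5 µM), KCa channels, and 30% of the Na⁺/K⁺-ATPase;
basolateral: KCa, 70% of the pump, NKCC1 (electroneutral 1Na:1K:2Cl, a
product-ratio thermodynamic form), a Cl⁻/HCO₃⁻-style anion exchanger
(linear relaxation toward a Cl⁻ equilibrium), and a small Na⁺ leak. Each
membrane patch senses the Ca²⁺ of its adjacent compartment, so the
basolateral KCa population is activated compartment-by-compartment by the
spatial Ca²⁺ profile — basolateral membrane near the apical pole is
strongly activated even with no apical KCa at all, which is why secretion
does not collapse at zero apical density. A paracellular Na⁺ conductance
driven by the transepithelial potential closes the circuit; osmotic water
fluxes across both membranes set cell volume and the secretion rate
q = L_a·(Osm_lumen − Osm_cell). At steady state the lumen solute load
equals 2× the apical Cl⁻ efflux regardless of how the K⁺ current splits
between the membranes (charge balance), so secretion tracks Cl⁻ transport
— the apical KCa density ρ matters through the potentials, not through
the osmolyte bookkeeping.

Membrane potentials are fast algebraic variables: channel currents are
ohmic, so cell and lumen charge balance form a 2 × 2 linear system solved
exactly at every step (a capacitive formulation is unnecessary; if every
conductance is zero the potentials are held, making the all-transport-off
state an exact fixed point). The apical KCa density sweep redistributes a
fixed total KCa conductance by relative density ρ and membrane area
fraction (apical 20%): apical share = ρf/(ρf + 1 − f), conserving the
total exactly at every ρ.

### Numerics

Operator splitting per 1 ms step: ions/volume first (Heun), then the
volume-rescaled Ca²⁺ step (implicit backward-Euler diffusion via a
precomputed dense inverse — the matrix is constant — with explicit
reactions). Cytosolic Ca²⁺ and IP₃ are rescaled by w_old/w_new after each
volume update, which keeps the closed-cell total conserved to machine
precision and produces the rising oscillation baseline as the cell loses
volume during secretion. Sub-steps validate positivity *before* mutating
the state; a violation halves dt (up to 10 times) and retries. The
resting state baked into `initial_state` is the numerically solved fixed
point of the transport system, with the lumen osmolyte term chosen to
minimise resting secretion (≈1.6% of the stimulated rate; it cannot reach
zero because the residual apical Cl⁻ conductance sets a floor of
2·J_Cl/Osm).

Readouts: oscillation frequency by peak counting (the package's own
zero-phase detector, prominence ≥ max(25% of range, 0.02 µM)) over the
final 100 s of a 500 s run; latency as the first apical rise of 0.05 µM
above rest; the basal/apical ratio as time-averaged supra-rest elevations
over the final 100 s. Default problem sizes: 500 s runs at dt = 1 ms for
calibrated readouts, 300 s for the five-point density sweep (the plateau
shape is established well before then), and 128 µm fields at 2 µm/px for
the 200-field recovery ensembles, whose statistics depend on grid count
rather than pixel count.

*Grid convergence.* Doubling the compartment count changes frequency,
gradient ratio and mean secretion by 1–2%. Pointwise trace comparison is
meaningful only over the phase-locked onset window (first ~15 s, several
full cycles, <5% RMS): beyond that, the ~1% frequency difference
decoheres spike phases and raw RMS measures timing offsets rather than
spatial convergence — a property of any relaxation oscillator, not of
this discretisation.

### Calibration

Free parameters without literature anchors (k_IPR, τ_h, SERCA scale, KCa
and TMEM16a half-points, the distributed-release fraction, paracellular
conductance) were fixed by a deterministic coordinate search against three
anchor behaviours at V_PLC = 0.008 µM/s — oscillation frequency in
0.5–1 Hz, basal/apical ratio in 25–35%, and a ~35% secretion drop at
ρ = 0 — and the calibrated set ships as the package default.
`model.calibrate()` re-runs the search. With the defaults the model gives
frequency 0.59 Hz, ratio 28.1%, drop 34.7%, and monotone trends over
V_PLC ∈ {0.002 … 0.008} (frequency and secretion nondecreasing, latency
nonincreasing, with subthreshold — non-oscillating — behaviour at the
lowest drive).

## Known limitations

Single uncoupled cell only: no acinus-level coupling, no gap-junction
Ca²⁺ exchange, no stochastic IP₃R gating (hence no low-frequency baseline
spiking at weak stimulation), no store-operated entry (closed cell), and
a reduced 1-D geometry whose compensating parameters (distributed-release
fraction, uptake profile) are effective descriptions rather than measured
quantities. The imaging pipeline assumes rigid-translation motion at
most; the generator's simplifications are listed above.
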
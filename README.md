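# endoquant

Quantification pipelines for measuring **endocytosis and fusion-pore
closure** in secretory cells, for electrophysiologists and imaging labs who
record:

- **whole-cell membrane capacitance** (calyx of Held, chromaffin cells) —
  depolarization evokes a capacitance jump ΔCm_peak proportional to
  exocytosed membrane, followed by an endocytic decay;
- **synapto-pHluorin (SypH) fluorescence** at hippocampal boutons — rises on
  exocytosis, falls on endocytosis/re-acidification;
- **three-channel fusion-spot traces** (F_PH membrane label, F_655 bath dye,
  F_FFN false-transmitter cargo) — single-vesicle fusion outcomes and pore
  closure;
- **EM vesicle tables** — HRP(+) vesicle and bulk-endosome densities per
  μm² of synaptic cross-section.

Because such datasets are rarely deposited, the package ships seeded
synthetic-data generators for every modality, so each estimator is validated
by **parameter recovery**: simulate at known ground truth, analyze, and
check the truth comes back.

## The statistics at the core

For a capacitance trace Cm(t) after a depolarizing step (the 0.25 s
post-stimulus artifact window is excluded):

- ΔCm_peak — post-stimulus peak plateau minus the 1 s pre-stimulus baseline;
- decay fits Cm(t) = c + A·e^(−t/τ) or c + A₁·e^(−t/τ₁) + A₂·e^(−t/τ₂)
  (τ₁ < τ₂, weight₁ = A₁/(A₁+A₂));
- Rate_decay — minus the least-squares slope of Cm over a protocol-specific
  window (0.5–4 s after a single 20 ms step; 0.5–1.5 s after a 10×20 ms
  train at 10 Hz);
- **Rate_decay_n = Rate_decay / ΔCm_peak** — the normalized endocytic rate
  (for a mono decay, 1 − e^(−1/τ) of the jump is retrieved in the first
  second);
- five endocytic modes from the decay: no-endo (<30% of ΔCm), slow (τ>6 s),
  fast (0.6–6 s), ultrafast (<0.6 s), overshoot (>130% of ΔCm); plus ICa
  peak binning (160–360 / 400–900 / 1000–1800 pA).

SypH experiments are normalized to a 100% baseline per bouton and averaged;
the pipeline reports the peak rise **ΔF/F (%)** and the initial decay rate
normalized to ΔF/F (**%/s**, slope over a 4–10 s post-peak window).

Fusion spots are classified as **close-fusion** (kiss-and-run: F_655 dims
after pore closure traps the bleaching dye while F_PH is sustained or decays
with a delay), **stay-fusion** (both sustained), or **shrink-fusion**
(parallel decline of F_PH, F_655 and spot size); pre-spots are tested for
**pre-close** by the same dim-while-sustained signature. Release time is
**T_FFN**, the 20–80% decay time of F_FFN. Per cell: Prob_close-fusion,
Prob_pre-close, mean T_FFN; cells with fewer than five fusion events are
excluded from group aggregates.

EM rows are classified by the bulk-endosome rule (diameter ≥ 80 nm or
cross-section area above that of an 80 nm vesicle, ~0.005 μm²); per-profile
HRP(+) vesicle density and HRP(+) bulk-endosome area are reported per μm².

Group reporting is mean ± s.e.m. with unpaired two-tailed Student's t-tests
(p<0.05 \*, p<0.01 \*\*, p<0.001 \*\*\*).

## Worked example

```python
import endoquant as eq
from endoquant.synthetic import CmGroundTruth, simulate_cm_recording

truth = CmGroundTruth(decay_model="mono", jump_fF=531.0, tau_s=10.2,
                      noise_sd_fF=10.0)
rec = simulate_cm_recording(truth, eq.depol_20ms(), seed=7, cell_id="calyx01")
kin = eq.analyze_recording(rec, model="mono")
print(f"dCm_peak      = {kin.delta_cm_peak_fF:.1f} fF")
print(f"tau           = {kin.fit.tau_s:.2f} s")
print(f"Rate_decay    = {kin.rate_decay_fF_per_s:.1f} fF/s")
print(f"Rate_decay_n  = {kin.rate_decay_n_per_s:.4f} /s")
print(f"1s retrieval  = {100*kin.first_second_retrieval:.1f} %")
print(f"mode          = {kin.mode}")
```

prints

```
dCm_peak      = 527.1 fF
tau           = 10.22 s
Rate_decay    = 42.8 fF/s
Rate_decay_n  = 0.0812 /s
1s retrieval  = 9.3 %
mode          = slow
```

The analyzer recovers the generating jump (531 fF) and time constant
(10.2 s) from a noisy trace; Rate_decay_n says ~8% of the exocytosed
membrane was being retrieved per second at the start of the decay, and the
mono fit implies 9.3% retrieved within the first second — a slow-mode cell.

A full simulate → analyze → report run over all four modalities (two
conditions, with t-test comparisons between them):

```sh
endoquant run-all --seed 7 --out demo_run
```

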
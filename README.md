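# vasodyn

Quantification tools for longitudinal studies of cerebral amyloid
angiopathy (CAA) in transgenic mouse models, where the question is
whether spontaneous arteriolar **vasomotion** declines before cerebral
blood flow (CBF), cerebrovascular reactivity (CVR) and microbleeds.
`vasodyn` implements the three layers of that quantification chain and
a synthetic-data generator that produces every input with known ground
truth:

1. **Vessel dynamics** (two-photon imaging). From 5-minute vessel
   diameter traces, the *vasomotion peak* — the maximum one-sided
   spectral amplitude `2|X_k|/N` of the mean-normalized diameter in the
   0.04–0.13 Hz band. From high-rate line-scan diameter traces,
   *beat-to-beat pulsatility* as the mean absolute detrended normalized
   diameter (for a pure cardiac sinusoid of relative amplitude *a* this
   equals 2*a*/π) and as the spectral amplitude at the heart-rate
   frequency, with a measurement excluded when the spectral heart-rate
   estimate differs by more than 50 % from the rate obtained from RBC
   velocity. RBC velocity itself comes from line-scan kymographs via
   Radon-projection angle maximization (velocity ∝ tan of the streak
   angle).

2. **ASL quantification** (pCASL MRI). CBF from label/control pairs
   via the single-compartment Buxton model,

   CBF = λ · ΔM · e^(PLD/T1b) / (2 · α · T1t · M0t · (1 − e^(−τ/T1t))),

   with λ = 0.9 mL/g, T1b = 2430 ms (9.4 T) and α = 0.80 by default;
   ROI time profiles cleaned by a ±2 SD outlier rule plus a three-point
   moving average; CVR as the relative CBF increase of the hypercapnic
   block (minute 6–10) over baseline (minute 1–5).

3. **Cohort statistics.** A ledger of linear mixed-effects models in
   lme4-style notation, e.g.
   `log10(Vasomotion) ~ Abeta + Age * Genotype + (1|Mouse) + (1|FOV)`,
   fitted by maximum likelihood and compared by AIC/BIC, plus the
   secondary tests: Mann–Whitney U (exact for small samples), Spearman
   rank correlation (exact permutation p for n ≤ 9), two-way ANOVA with
   Šídák-corrected planned comparisons, ICC(2,1) and Cohen's kappa.

A seeded pipeline (`vasodyn run`) chains simulate → quantify →
aggregate → statistics and writes a manifest with checksums, so runs
are byte-for-byte reproducible.

## Worked example

```python
import numpy as np
import vasodyn as v
from vasodyn.asl import buxton_cbf, compute_cvr, pairwise_delta, roi_timeprofile

# vasomotion: a 300 s trace with a 5 % oscillation at 0.1 Hz
trace, _ = v.gen_diameter_trace(v.TraceSimConfig(
    duration=300, sampling_rate=2, vasomotion_amplitude=0.05,
    vasomotion_frequency=0.1))
res = v.compute_vasomotion_peak(trace)
print(f"vasomotion peak {res.peak_amplitude:.4f} at {res.peak_frequency:.2f} Hz")

# ASL: noiseless series planted at CBF 100 mL/100 g/min with CVR 0.4
series, _ = v.gen_asl_series(v.ASLSimConfig(true_cbf=100.0, cvr=0.4))
maps = np.stack([buxton_cbf(d, series.m0t, series.params)
                 for d in pairwise_delta(series)])
prof = roi_timeprofile(maps, np.ones(series.m0t.shape, bool), series.pair_times)
print(f"baseline CBF {prof._window_values(prof.baseline_window).mean():.1f}, "
      f"CVR {compute_cvr(prof):.1f} %")

# mixed-model ledger on a simulated longitudinal cohort
table, _ = v.gen_cohort(v.CohortSimConfig(seed=1))
ledger, _ = v.model_ledger(table, [
    "log10(Vasomotion) ~ Abeta + Age + (1|Mouse) + (1|FOV)",
    "log10(Vasomotion) ~ Abeta + Age * Genotype + (1|Mouse) + (1|FOV)"])
print(ledger[["model", "aic", "selected"]].to_string(index=False))
```

Output:

```
vasomotion peak 0.0500 at 0.10 Hz
baseline CBF 100.0, CVR 40.0 %
                                                           model        aic  selected
           log10(Vasomotion) ~ Abeta + Age + (1|Mouse) + (1|FOV) -87.641908     False
log10(Vasomotion) ~ Abeta + Age * Genotype + (1|Mouse) + (1|FOV) -91.787152      True
```

The vasomotion peak recovers the planted 5 % amplitude exactly (a
sinusoid with an integer number of cycles in the window leaks into a
single FFT bin); the noiseless ASL series round-trips through the
Buxton model to the planted CBF and CVR; and the ledger prefers the
model containing the age × genotype interaction that the cohort
generator planted (a decline of 0.097 log10-units per month in
transgenic animals).

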
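# replicyto

Cytometric analysis of DNA-replication labelling, for cell biologists who
quantify S-phase activity with pulse-labelled thymidine analogues (BrdU,
EdU, TFdU) by image or flow cytometry — and for anyone who needs a fully
simulated, ground-truthed test bed for such pipelines.

After a pulse, a fraction *F* of cells (the replicating, "R" population)
carries specific nuclear label signal on top of the staining background; the
rest ("non-R") shows background only. Whether the two populations can be
told apart depends on the signal-to-noise of the detection chemistry, which
this package summarises with the **R/non-R ratio**: order the *N* nuclei by
mean nuclear signal, then

```
R/non-R = mean(top (F − 0.1)·N nuclei) / mean(bottom (0.9 − F)·N nuclei)
```

The 0.1-wide guard bands exclude nuclei of ambiguous status, so the
statistic is defined for F ∈ (0.1, 0.9). For a 30-minute BrdU pulse in
HeLa-like populations F ≈ 0.44; ratios of about 3 or more allow reliable
classification of replicating cells, while ratios around 2 do not.

The package provides four layers:

- **`replicyto.population`** — a generative model of labelled populations:
  G1/S/G2M phase structure (G2/M DNA content = 2× G1, CV broadening),
  Bernoulli(F) labelling coupled to S phase, lognormal specific/background
  signals, optional protein channels (e.g. the two FUCCI reporters), and
  multiplicative `ProtocolEffect`s (signal scaling, per-channel protein
  retention, exponential wash decay). Named presets reproduce documented
  antibody/fixation/HCl conditions, calibrated analytically so their
  expected trimmed R/non-R hits the condition's target ratio.
- **`replicyto.render` / `replicyto.segment`** — image formation (disc
  nuclei, Gaussian PSF, Poisson + read noise, 16-bit multi-page TIFF) and
  the CellProfiler-equivalent stage: Otsu/fixed thresholding, 8-connected
  components, optional watershed splitting, per-nucleus mean/integrated
  intensities.
- **`replicyto.stats`** — R/non-R, signal intensity, labelled-fraction
  estimation (2-component Gaussian mixture or Otsu on log signal),
  replicating-cell classification with a separability flag, FUCCI-style
  percent-of-control normalisation, replicate aggregation (mean ± SD), and
  bivariate (label × DNA content) G1/S/G2M profiling.
- **`replicyto.pipeline` / CLI `replicyto`** — seeded, byte-reproducible
  orchestration of simulate → render → segment → quantify → stats with a
  YAML config, manifest and checksums.

## Worked example

```python
import numpy as np
from dataclasses import replace
from replicyto import (preset, sample_population, apply_protocol,
                       sample_flow_events, r_non_r_ratio,
                       classify_replicating, cell_cycle_profile)

params, effect = preset("brdu_30min")          # F = 0.44, target ratio 6
pop = apply_protocol(sample_population(replace(params, seed=21)), effect)
ev = sample_flow_events(pop, acq_cv=0.03, seed=5)

rr = r_non_r_ratio(ev["label"].to_numpy(), params.f_labelled)
print(f"R/non-R = {rr.ratio:.2f}  (R mean {rr.r_mean:.0f} AU over "
      f"{rr.n_r} nuclei, non-R mean {rr.nonr_mean:.0f} AU over {rr.n_nonr})")

_, report = classify_replicating(ev["label"].to_numpy())
print(f"separable = {report.separable}, estimated F = {report.f_estimate:.3f}")

prof = cell_cycle_profile(ev["dna"].to_numpy(), ev["label"].to_numpy())
print(f"G1 {prof.frac_g1:.3f}  S {prof.frac_s:.3f}  G2M {prof.frac_g2m:.3f}")
```

prints (10,000 nuclei, seed 21):

```
R/non-R = 5.97  (R mean 518 AU over 3400 nuclei, non-R mean 87 AU over 4600)
separable = True, estimated F = 0.438
G1 0.396  S 0.438  G2M 0.166
```

The ratio of ~6 means the mean signal of the 34% most-labelled nuclei is six
times the mean of the 46% least-labelled — comfortably above the ≈3 limit,
so replicating cells classify cleanly, and the recovered S fraction matches
the simulated labelled fraction.

The same analysis runs from the shell:

```sh
replicyto run --preset brdu_30min --n-cells 2000 --seed 21 --outdir out/
replicyto profile --measurements out/events_flow.csv
```

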
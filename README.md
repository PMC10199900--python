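# porecall

Simulation, event detection, population statistics and per-event
classification for solid-state nanopore recordings of single amino
acids.

Atomically thin nanopores (e.g. in single-layer MoS₂) have a sensing
region comparable to the size of one amino acid. When an amino acid is
driven electrophoretically through such a pore it transiently blocks
the open-pore ionic current I₀; the **relative current blockade
ΔI/I₀** and the **dwell time Δt** of each translocation event carry
enough information to tell amino acids apart — down to single chemical
groups (S vs T), isomers (L vs I) and post-translational modifications
(Y vs phospho-Y). `porecall` provides the full analysis chain used in
such experiments, plus a calibrated simulator so every stage can be
validated against known ground truth:

- **signal models** — per-analyte blockade populations as one- or
  two-component Gaussians on ΔI/I₀ (or ΔI in nA), with a lognormal
  dwell model; a packaged parameter table covers the published
  (analyte, device) populations.
- **trace simulator** — open-pore baseline at I₀ with white noise,
  non-overlapping Poisson event arrivals, rectangular blockades scaled
  ohmically with the applied bias, a causal 2nd-order Bessel
  acquisition filter at 10 kHz, 100 kHz sampling, and an exhaustive
  ground-truth table.
- **event detection** — zero-phase 2nd-order Butterworth low-pass
  (10 kHz), 300 ms moving-average baseline with event masking,
  dual-threshold (5σ open / 2.5σ boundary) event calling against a
  robust noise estimate, per-event features (Δt, I₀ local, ΔI, ΔI/I₀),
  and exclusion of events with Δt < 0.1 ms.
- **density statistics** — normal-kernel KDE with mode calling
  (“mean peak values”), Gaussian-mixture EM fits for bimodal
  populations, Welch two-sample z-tests, dwell-vs-blockade heatmaps.
- **classification** — per-event encoding (fixed-length normalised
  waveform + scalar features), a transparent class-conditional
  Gaussian Bayes baseline, and an LSTM sequence classifier
  (LSTM → mean-over-time pooling → four fully connected layers →
  softmax) implemented in numpy with seeded, reproducible training.

Estimators follow scikit-learn conventions (`fit`/`transform`/
`predict`, fitted attributes with trailing underscores), and a thin
`porecall` command-line interface chains the stages
(`simulate | detect | fit | classify | report`).

## Worked example

Simulate glycine and alanine on the same device model, run detection,
locate the blockade peaks, test their separation, and train the
baseline classifier:

```python
import numpy as np
import pandas as pd
import porecall as pc

frames = {}
for label, seed in [("G", 1), ("A", 2)]:
    frame, truth, trace = pc.simulate_events((label, "Device #4"), 1000, seed=seed)
    frames[label] = frame
    fit = pc.kde_fit(frame["rel_blockade"])
    print(f"{label}: {len(frame)} events, dI/I0 peak at {fit.mode:.3f} "
          f"(sample sd {frame['rel_blockade'].std():.3f})")

z = pc.two_sample_ztest(frames["G"]["rel_blockade"], frames["A"]["rel_blockade"])
print(f"z = {z.statistic:.1f}, two-sided P < 0.0001" if z.p_value < 1e-4 else z)

data = pd.concat(frames.values(), ignore_index=True).dropna(subset=["label"])
S = np.column_stack([data["rel_blockade"], np.log10(data["dwell_s"])])
y = data["label"].to_numpy(dtype=object)
tr, va, te = pc.split_dataset(list(range(len(y))), seed=0, labels=y)
model = pc.GaussianBayesClassifier().fit(S[np.array(tr)], y[np.array(tr)])
rep = pc.evaluate(model.predict(S[np.array(te)]), y[np.array(te)])
print(f"held-out identification accuracy: {100 * rep.average_accuracy:.2f}%")
```

Output:

```
G: 1137 events, dI/I0 peak at 0.229 (sample sd 0.017)
A: 1111 events, dI/I0 peak at 0.295 (sample sd 0.021)
z = -80.4, two-sided P < 0.0001
held-out identification accuracy: 96.44%
```

The recovered peaks sit on the generative population means (0.229 and
0.295): the detection chain neither shifts nor broadens the blockade
populations appreciably. The z statistic confirms the two populations
are separated far beyond chance, and the held-out accuracy is close to
the analytic Bayes limit for this pair of distributions (~96%).

The same flow is available from the shell:

```sh
porecall simulate --config run.yaml --seed 1 --out out/
porecall detect   --config run.yaml --out out/
porecall fit      --config run.yaml --out out/
porecall classify --config run.yaml --out out/
```

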
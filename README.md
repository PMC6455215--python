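# gss-hdemg

Non-invasive decoding of motoneuron activity from high-density surface EMG
(HDsEMG) by **guided source separation (GSS)**: template clustering proposes
the starting points, gradient Convolution Kernel Compensation (CKC) does the
source separation, an EM-Kalman stage accelerates it, and adaptive
soft-thresholding turns the estimates into motor-unit (MU) firing trains.

## Who this is for

Researchers in neurophysiology, motor control and myoelectric interfacing
who want to extract individual MU spike trains from multichannel surface
EMG recorded with electrode grids, and to benchmark decomposition methods
on synthetic signals with known ground truth. The package contains:

* a synthetic HDsEMG generator (MU pool with recruitment and rate coding,
  parametric spatio-temporal MUAP surrogate, colored noise at exact SNR);
* the preprocessing chain (band-pass, single-differential montage, delayed
  extension, eigenvalue whitening / "convolutive sphering");
* the guided initialization (adaptive detection threshold, 2-ms active
  segments, sub-sample alignment, OPTICS clustering with ε = ∞, valley
  extraction);
* the decomposition engine (CKC estimator, gradient updates with the
  attenuated contrast f(x) = α·log(1+x²), PNR-maximizing threshold search
  with bootstrap CI, marginal-spike correlation rescue, scalar-gain
  EM-Kalman acceleration);
* physiological screening, duplicate removal, and the validation metrics
  (RoA / sensitivity / precision at ±0.5 ms, PNR, SIR, decomposability).

## The model in brief

EMG is a convolutive mixture of MU firing trains and MUAP waveforms.
Extension (R = 30 delayed repetitions per channel) and whitening make the
mixture approximately instantaneous and uncorrelated; the spike train of MU
*j* is then estimated as

```
ť_j = r_jᵀ R_XX⁻¹ X          (R_XX = I after whitening)
r_j ← r_j + η(g) · X f(ť_j),  f(x) = α(x) log(1 + x²)
```

where the MU filter `r_j` is initialized from the observation column at a
cluster representative of the template-clustering stage, instead of at a
random or peak sample. The pulse-to-noise ratio
`PNR = 10 log10(E[ť²|ť≥thr]/E[ť²|ť<thr])` drives both the spike/noise
threshold and the per-MU quality report. See `docs/methods.md` for the full
account.

## Worked example

```python
from gss_hdemg import SimConfig, EMGDecomposer

sim = SimConfig()                      # 5 s, 7×6 grid @4096 Hz, 80-MU pool
rec, truth = sim.simulate(excitation=10.0, snr_db=30.0, seed=42)
dec = EMGDecomposer(random_state=42).fit(rec)
records = dec.score_against(truth)

print(f"kept MUs: {len(dec.patterns_)}")
for r in sorted(records, key=lambda r: -r["roa"]):
    if r["identified"]:
        print(f"  MU {r['true_mu']:3d}: RoA {r['roa']:.2f}  "
              f"Se {r['sensitivity']:.2f}  Pr {r['precision']:.2f}  "
              f"PNR {r['pnr_db']:.1f} dB  MDR {r['mdr_est_hz']:.1f} Hz")
```

prints

```
kept MUs: 9
  MU  22: RoA 1.00  Se 1.00  Pr 1.00  PNR 24.8 dB  MDR 9.1 Hz
  MU  19: RoA 1.00  Se 1.00  Pr 1.00  PNR 25.9 dB  MDR 8.9 Hz
  MU   4: RoA 0.94  Se 0.94  Pr 1.00  PNR 24.7 dB  MDR 10.1 Hz
  MU  54: RoA 0.86  Se 0.88  Pr 0.97  PNR 27.8 dB  MDR 8.6 Hz
  MU  72: RoA 0.86  Se 0.86  Pr 1.00  PNR 25.8 dB  MDR 8.5 Hz
  MU  45: RoA 0.86  Se 0.95  Pr 0.89  PNR 24.5 dB  MDR 8.9 Hz
  MU  38: RoA 0.83  Se 0.83  Pr 1.00  PNR 25.7 dB  MDR 9.3 Hz
  MU  51: RoA 0.81  Se 0.81  Pr 1.00  PNR 23.2 dB  MDR 9.8 Hz
```

Each line is one decomposed motor unit matched (within ±0.5 ms, after
constant-lag alignment) against the simulated ground truth: RoA is the rate
of agreement TP/(TP+FN+FP), PNR the pulse-to-noise ratio of its spike-train
estimate, MDR its mean discharge rate. At 30 dB SNR and 10% excitation the
pipeline typically recovers 7–9 superficial MUs with RoA 0.8–1.0.

The same chain is available from the shell:

```
gss-hdemg simulate --mvc 10 --snr 30 --duration 5 --rows 7 --cols 6 \
    --n-mus 80 --seed 1 --out /tmp/sig
gss-hdemg decompose --signal /tmp/sig --out /tmp/dec --seed 1
gss-hdemg score --est /tmp/dec/firings.tsv --truth /tmp/sig/truth.tsv \
    --report /tmp/report.json
gss-hdemg benchmark --out /tmp/bench --seed 1 --replicates 2
```

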
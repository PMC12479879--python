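# eodsort

Unsupervised separation of electric organ discharges (EODs) from pairs of
free-swimming pulse-type weakly electric fish (*Gnathonemus petersii*).

Pulse-type mormyrids emit brief (~200–400 µs) biphasic electric pulses for
electrolocation and communication, at rates that can exceed 100 Hz. When two
fish swim freely in one tank, a two-channel electrode recording captures an
interleaved stream of thousands of pulses, and attributing each pulse to its
emitter is the bottleneck of every social-electrophysiology experiment.
Supervised classifiers need solo recordings of each fish for training —
extra handling, extra stress, and extra session-to-session variability.

`eodsort` separates the two fish without any training data:

1. **Detection** — running-median baseline removal; peaks of the squared
   signal above a 5 mV threshold with a 400 µs refractory spacing, per
   channel; cross-channel coincidences merged to the larger-amplitude
   channel; a ±300 µs window (31 samples at 50 kHz) cut around each
   absolute-maximum peak, peak-normalized and polarity-canonicalized.
2. **Features** — a continuous wavelet transform of each snippet with a
   generalized Morse wavelet (γ = 3, P² = 60, β = P²/γ = 20, 12 voices per
   octave, 15-zero padding per side), cropped to 31 time samples,
   max-normalized, and flattened (56 scales × 31 = 1736 dimensions).
3. **Embedding + clustering** — t-SNE (perplexity 50) to 2-D, then
   average-linkage hierarchical clustering with Euclidean distance cut at
   two clusters; cluster quality scored by the average silhouette (SS) and
   the CDbw composed-density index.
4. **Identity assignment** — clusters mapped to fish A/B from their mean
   signed amplitude per channel (position and orientation give each fish a
   characteristic amplitude/polarity signature).

Supervised baselines (scalogram-template Pearson correlation and an
RBF-SVM with sequential hyperparameter search over 10-fold CV), evaluation
metrics (aligned accuracy, Matthews correlation coefficient, runtime per
EOD), a ground-truth synthetic dyad simulator, and two EOD sonification
schemes (pulse-wise bursts and IPI-driven FM melodies) round out the
toolkit.

## Worked example

```python
import eodsort as es

# simulate a 120 s dyad of two clearly distinct fish, with ground truth
recording, truth = es.easy_dyad(seed=1, duration_s=120.0)

# run the full unsupervised pipeline
result, events = es.separate(
    recording, config=es.SeparationConfig(perplexity=50, seed=1))
scores = es.evaluate_run(events, truth, elapsed_s=0.0,
                         tol_s=1.0 / recording.fs)
print(f"n={scores.n_matched}  acc={scores.acc:.4f}  mcc={scores.mcc:.4f}  "
      f"SS={result.ss:.3f}")
```

prints

```
n=1936  acc=0.9990  mcc=0.9979  SS=0.778
```

i.e. of the 1936 detected-and-matched EODs, 99.90 % were assigned to the
correct fish after the (nominal) cluster labels were aligned to the truth,
the Matthews correlation coefficient of the aligned confusion matrix is
0.998, and the two clusters in the embedding are compact (silhouette 0.78).

The same pipeline is scriptable from the shell:

```sh
eodsort simulate --seed 1 --duration 120 --out d1/
eodsort separate --in d1/dyad.wav --perplexity 50 --seed 1 \
    --out d1/labeled.csv --embedding d1/embedding.csv
eodsort evaluate --pred d1/labeled.csv --truth d1/truth.csv \
    --out d1/metrics.json
eodsort sonify --mode fm --events d1/labeled.csv --out d1/dyad_fm.wav
eodsort bench --dyads 10 --seed 1 --out bench.csv
```

Estimator classes (`MorseScalogram`, `TSNEPairSeparator`,
`TemplateCorrelationClassifier`, `ScalogramSVC`) follow scikit-learn
conventions and compose with its pipelines and model selection.

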
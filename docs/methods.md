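# Methods

## Signal model and detection

A dyad recording is a two-channel voltage series (volts) sampled at 50 kHz
from two bipolar electrode dipoles. Each EOD appears on both channels as a
scaled, possibly sign-flipped copy of the fish's stereotyped biphasic pulse:
the amplitude split between channels tracks the fish's position, and the
recorded polarity its orientation relative to the dipoles.

Detection subtracts a running-median isoline per channel (kernel 5 ms — an
order of magnitude wider than the 200–400 µs pulses, so the median tracks
electrode drift without attenuating pulses; a kernel below three pulse
widths is rejected as a configuration error). The cleaned signal is squared
so a single threshold catches the dominant phase regardless of polarity;
squared-signal peaks above `threshold_V² = (5 mV)²` with a 400 µs minimum
spacing are detected per channel. The threshold is interpreted in original
amplitude units — squaring is a peak-enhancement device, not a change of
threshold scale. Detections coincident across channels within 200 µs (half
the refractory spacing) are the same physical pulse seen by both dipoles
and collapse to one event on the channel with the larger |amplitude|.
Snippets of ±300 µs (31 samples at 50 kHz; in general
`2·round(window_us·fs/1e6)+1`) are cut around the absolute-maximum sample,
divided by the absolute maximum, and multiplied by −1 when the extremum is
negative, so every stored waveform peaks at +1 at its center. Events closer
than the half-window to a recording edge are dropped (a partial window
would corrupt the normalization), with a logged count. The estimated noise
floor (RMS 0.2 mV) is carried as metadata; detection is not adaptive.

## Morse-wavelet features

Each snippet is zero-padded by 15 samples per side (31 → 61) and analyzed
with a generalized Morse wavelet, defined in the frequency domain as
Ψ(ω) = 2·(eγ/β)^(β/γ)·ω^β·e^(−ω^γ) for ω > 0 (analytic, peak value 2 at
ω_p = (β/γ)^(1/γ)), with γ = 3 and β = P²/γ = 20. The CWT is computed as an
inverse FFT of the padded snippet's spectrum multiplied by the scaled
wavelet, per scale; the padding suppresses circular wrap-around. Magnitudes
are cropped back to the central 31 columns and divided by the maximal
coefficient.

The scale grid is geometric with 12 voices per octave over 1–25 kHz
(56 scales), spanning the energy of 200–400 µs biphasic pulses up to the
Nyquist frequency. The band is a package choice — exposed in
`MorseParams` — because different wavelet toolboxes default to different
grids; nothing downstream depends on individual coefficient values, only on
the normalized scalogram as a pattern. Flattened scalograms give
d = 56 × 31 = 1736 features per EOD. Time-domain (raw snippet) and
frequency-domain (zero-padded 64-point FFT magnitude, max-normalized)
representations are provided for comparison; on a 24-fish analog the
time-frequency representation yields the most compact per-fish clusters
(checked as a direction, not a value, in the test suite).

## Unsupervised separation

t-SNE embeds the n × 1736 feature matrix into 2-D at perplexity 50 (the
toolkit validates n ≥ 3·perplexity). The implementation is scikit-learn's
Barnes-Hut t-SNE with deterministic PCA initialization, 750 iterations and
standard early exaggeration; results are reproducible for a fixed seed but
not across seeds, which is inherent to the method. The embedding — not the
feature matrix — is clustered: average-linkage (UPGMA) agglomeration on
Euclidean distances, cut at exactly two clusters. Cluster ids are ordered
by size (ties by lowest member index) for determinism. Above 30,000 events
the linkage runs on a uniform 30,000-point subsample and remaining points
inherit their nearest clustered neighbor's label (O(n²) linkage memory).

Quality metrics: the average silhouette score, and the CDbw
composed-density index for non-spherical clusters. CDbw summarizes each
cluster by 10 boundary representatives found by farthest-point traversal
from the centroid; compactness is the mean fraction of cluster points
within one RMS radius of the representatives shrunk toward the centroid
over factors s ∈ {0.1, …, 0.8}; cohesion divides compactness by the mean
density change across shrink factors; separation contrasts the closest
representative-pair distance with the point density at pair midpoints. The
index is the product cohesion × separation × compactness: dimensionally it
scales with the coordinates, so only comparisons on the same data are
meaningful — which is how it is used (labelings against each other,
representations against each other). Published variants of this index
differ in normalization details; this implementation fixes the
representative count and shrink set as defaults and exposes both.

Cluster→fish identity uses the per-cluster mean signed peak amplitude per
channel: clusters are ordered by (dominant channel, descending polarity)
and named A, B. Identical signatures are flagged ambiguous rather than
raised, since they carry real information (e.g. two fish sharing a
corner). A recording containing a single fish still yields two clusters
(k is fixed); the low silhouette triggers a warning in the result.

For perplexity selection over labeled dyad suites, the grid is restricted
to 30–120 and the returned value maximizes median MCC with median accuracy
and runtime as tie-breakers; the full score table is returned for
inspection.

## Supervised baselines

The template-correlation baseline averages the normalized scalograms of
each fish's solo recording into one template and assigns each dyad EOD to
the fish with the higher Pearson correlation; exact ties (including
zero-variance degenerate scalograms) go to the first fish, with a logged
count. The SVM baseline trains an RBF-kernel classifier on the 5,000
top-SNR solo EODs per fish — SNR ranked by the raw pre-normalization
|peak amplitude|, since normalized snippets all peak at 1 — with features
standardized by stored per-column mean and SD (classes are balanced by
construction, so plain column statistics are the appropriate weights).
Hyperparameters (C ∈ [1e−2, 1e3], γ ∈ [1e−6, 1e1], log-spaced) are chosen
by a seeded sequential search: a coarse grid scored by k-fold CV accuracy,
then a shrinking local refinement around the incumbent, within a fixed
evaluation budget. With fewer solo EODs than requested, all are used with
a warning.

## Evaluation

Cluster labels are nominal: predictions are aligned to truth by the better
of the two label permutations (aligned accuracy is ≥ 0.5 by construction,
which is why chance-level performance reads as ~0.5 only in expectation
and slightly above for finite n). Predicted and truth events are matched
1:1 greedily by nearest time within one sample (tolerance configurable);
unmatched events on either side are excluded from the confusion matrix and
reported as counts. MCC uses the direct formula with the zero-denominator →
0 convention. Runtime per EOD includes SVM training time for SVM runs and
is reported only — it is hardware-dependent and never asserted. The
body-parameter analysis computes Pearson r and two-sided p (t transform,
n − 2 df, no multiplicity correction) between per-dyad metrics and per-dyad
absolute body-measure differences.

## Synthetic dyad simulator

The simulator generates the study conditions the separation method
assumes, with ground truth:

* **Waveforms** — two raised-cosine lobes (positive width τ1, negative
  width τ2, amplitude ratio < 0, per-lobe asymmetry skew), total duration
  constrained to 200–400 µs. `make_fish(seed, divergence)` draws parameters
  around a population center (τ1 = 120 µs, τ2 = 160 µs, ratio −0.7,
  skew 0.25, amplitude 50 mV) with relative spreads scaled by `divergence`;
  divergence 0 returns the population mean for every seed. Draws are
  clamped to the physiological domain and to amplitudes comfortably above
  the 5 mV detection threshold.
* **Discharge times** — a gamma renewal process (shape 3, mean IPI set by
  the scenario's rate). Gamma nests the exponential (shape 1) and
  regular-train limits and gives the refractory-like regularity of real
  pulse trains. Trains from the two fish are independent, so cross-fish
  coincidences occur with positive probability; coincidences within 400 µs
  are flagged in the recording metadata, never suppressed.
* **Amplitude and polarity** — each fish follows a reflected random walk
  x(t) ∈ [0, 1] between the two dipoles; channel gains are
  0.15 + 0.7·(1−x) and 0.15 + 0.7·x (an opposite-corner projection
  stand-in, not field physics), and a Poisson process of orientation flips
  (0.05 Hz) reverses the pulse sign on both channels.
* **Noise and drift** — additive white noise (default RMS 0.2 mV, the
  noise floor of the real recording setup this emulates) and a slow
  sinusoidal baseline drift (1 mV, 0.2 Hz) exercising the median filter.

What the simulator does **not** model: electric-field geometry (gains are a
smooth proxy, so amplitude cues are cleaner than reality), waveform change
with water temperature or fatigue, interactive discharge behavior (echo
responses, cessations), and overlapping-pulse waveform superposition
artifacts beyond simple summation. Passing benchmarks on synthetic dyads
therefore demonstrates the pipeline's mechanics and its sensitivity to
waveform divergence, not field robustness on real tanks; the honest-failure
check (divergence-0 dyads must score at chance) guards against the
pipeline exploiting simulator artifacts.

## Benchmark problem sizes

The standard benchmark suite is ten dyads of 120 s at ~8 Hz mean rate per
fish (~1,900 detected EODs per dyad), divergence drawn in 0.7–0.9, noise
RMS 0.2 mV, perplexity 50, one seed per dyad. These sizes give renewal
counts large enough for stable medians while keeping a full suite run in
minutes on one CPU. Unit tests use 20–60 s scenes and 100–600-point
embeddings for the same reason.

## Sonification

Pulse-wise mode renders one Hann-enveloped sinusoid burst (12 ms; 440 Hz
for fish A, 660 Hz for B) per event, optionally amplitude-scaled by the
event's recorded |peak amplitude| relative to the session maximum so
approach/retreat is audible; overlapping bursts sum and the output is
peak-normalized to 0.9. FM mode assigns each fish a carrier (220/330 Hz —
a musical fifth apart, so synchrony reads as consonance) modulated by the
smoothed discharge rate: the raw rate is 1/IPI between consecutive events,
zero before the first event and hard-zeroed 2 s after the last; smoothing
is a causal first-order exponential (τ = 0.25 s) initialized at the first
defined rate so a regular train reads out its exact rate. Instantaneous
frequency is carrier·2^(dev·(r−r_ref)/r_ref) with r_ref the session-median
rate and dev = 1 octave — exponential, so equal rate ratios sound as equal
intervals — and phase is accumulated by integration, keeping the tone
phase-continuous. All synthesis parameters are package choices exposed in
`SonifyConfig`; configurations whose worst-case instantaneous frequency
reaches Nyquist are rejected at construction.

## Numerical and design notes

* Events CSVs are written with 17-significant-digit floats and read with
  round-trip float parsing, so read(write(x)) is lossless.
* WAV recordings use float32 (PCM would quantize millivolt signals);
  the raw container is interleaved float32 with a JSON sidecar (fs,
  channel count, volt scale). Calibration to volts is the user's
  responsibility; the containers store calibrated volts.
* Average-linkage merge ties are theoretically broken lexicographically;
  on continuous embeddings exact ties have measure zero, and the
  implementation's determinism is what tests rely on.
* The silhouette of singleton clusters is 0 by convention; a single
  cluster raises.
* t-SNE embeds duplicated inputs to nearly coincident points but the
  Barnes-Hut approximation keeps them from being exactly equal; tests
  assert closeness relative to the embedding's span.

## Known limitations

Dyads only (k = 2 is fixed); offline only; no video/position fusion; the
identity map depends on a stable amplitude signature and is flagged — not
fixed — when ambiguous; CDbw values are comparable only within a dataset;
real-data validation requires recordings and labels the user supplies.
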
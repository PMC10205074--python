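# segtag

Frequency-tagged MEG analysis of syllable- and word-level speech
processing, with a ground-truth simulator for every stage.

## The problem

When listeners hear isochronous syllables presented at 4 Hz that pair up
into disyllabic words, the word rate (2 Hz) exists only for a brain that
can group the syllables — the acoustics are flat at 2 Hz.  Neural spectra
therefore separate processing levels by frequency: a 4 Hz response indexes
syllable-level (acoustic) tracking, while a 2 Hz response indexes
word-level grouping, whether driven by lexical knowledge or by
syllable-to-syllable transition statistics.  This package implements the
full analysis chain for such experiments:

* **Stimulus construction** (`segtag.lexicon`, `segtag.audio`,
  `segtag.corpus`): synthetic disyllabic lexicons with controlled
  transitional-probability (TP) structure, 38-syllable / 19-unit sequences
  at a 250 ms inter-onset interval, repeated-syllable targets in 29% of
  trials, and the six-measurement within- vs between-word TP contrast
  (TP(s2|s1) = freq(s1,s2)/freq(s1), Laplace smoothing, Mann-Whitney with
  Bonferroni correction).
* **Simulation** (`segtag.forward`, `segtag.simulate`): a quasi-dipolar
  toy forward model with labeled ROIs, and trials containing
  envelope-locked 4 Hz auditory responses, condition-dependent 2 Hz
  responses, optional 4 Hz → 2 Hz cross-frequency dependence, and
  spatially correlated 1/f noise — all with recorded ground truth.
* **Sensor analysis** (`segtag.preprocess`, `segtag.spectral`): zero-phase
  Butterworth filtering, z-score artifact rejection, epoching (−2.1–9.6 s)
  and downsampling, evoked power at 0.1111 Hz resolution with the
  neighbor-bin contrast (target bin minus mean of bins ±2–3), jackknife
  trial-wise power and polynomial block trends with BIC comparison.
* **Source analysis** (`segtag.beamform`, `segtag.envelope`,
  `segtag.cfc`): DICS and LCMV beamformers with common filters (λ = 10%),
  cerebro-acoustic coherence between the cochlear (ERB-scale filterbank)
  speech envelope and beamformed sources at 4 Hz, and cross-frequency
  coupling as Gaussian-copula mutual information
  MI = −½ log₂(1 − r²) between 4 Hz and 2 Hz power envelopes.
* **Statistics** (`segtag.cluster`): cluster-based Monte-Carlo permutation
  tests (cluster α = 0.05, minimum two suprathreshold neighbors, two-sided
  at the 2.5/97.5 permutation percentiles), nonparametric ROI tests with
  Bonferroni correction, and the split-plot mixed ANOVA
  (between: experiment; within: condition × hemisphere).

## Worked example

```python
import numpy as np
from segtag.lexicon import build_lexicon, generate_sequence
from segtag.corpus import within_between_contrast
from segtag.forward import make_forward_model
from segtag.simulate import SimulationConfig, simulate_trials
from segtag.beamform import csd, dics_filter, source_power_contrast

# words with predictable second syllables vs. random pseudo-words
words = build_lexicon(40, "native_like", seed=1)
pseudo = build_lexicon(60, "random", seed=2)
seqs = [generate_sequence(words, 19, seed=i) for i in range(30)]
c = within_between_contrast(seqs, words, "identity", n_tests=6)
print(f"identity TP within={c.within.mean():.2f} between={c.between.mean():.2f} "
      f"diff={c.diff:.2f} p={c.p_value:.1e}")

# simulate a word-level (2 Hz) response and localize it
fwd = make_forward_model(32, (5, 5, 4), seed=0)
trials = []
for i in range(12):
    s = generate_sequence(words, 19, seed=i); s.condition = "words"
    trials.append(s)
cfg = SimulationConfig(fs_hz=600.0, snr=2.0,
                       effect_2hz={"words": {"frontal": 1.0}}, seed=0)
ds = simulate_trials(fwd, cfg, trials)
filt = dics_filter(fwd, csd(ds.data, ds.fs_hz, ds.t_start_s, (1.333, 4.666)))
contrast, _ = source_power_contrast(filt, ds.data, ds.fs_hz, ds.t_start_s, 2.0)
top = fwd.source_positions[np.argsort(contrast)[-8:]]
planted = fwd.source_positions[fwd.roi_labels["frontal"]]
err = np.linalg.norm(top[:, None] - planted[None], axis=2).min(axis=1)
print(f"top 2 Hz sources within one grid step of planted ROI: "
      f"{np.sum(err <= 0.81)}/8")
```

Output:

```
identity TP within=0.99 between=0.06 diff=0.94 p=4.1e-182
top 2 Hz sources within one grid step of planted ROI: 8/8
```

The TP line shows the word-structure signature: within-word transitions
are nearly deterministic (0.99) while between-word transitions are near
chance (0.06).  The localization line shows the DICS neighbor-bin
contrast at 2 Hz peaking at and immediately around the region where the
word-level response was planted (the beamformer's point spread is about
one 0.8 cm grid step).

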
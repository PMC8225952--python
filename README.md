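# cetasong

Analysis tools for bidirectional acoustic interactions between human-played
sound objects and a singing humpback whale.

In interactive playback experiments, studio-prepared sound objects —
*concrete sound elements* (CSEs), in the sense of musique concrète — are
played underwater to a singing whale, and the whale's *song units* (harmonic
or pulsed vocalizations bounded by silences) are recorded and annotated.
`cetasong` implements the full analysis chain for such sessions, for
bioacousticians and art–science practitioners working on whale–human
acoustic exchange:

* **annotations** — timed event tables (TSV), audio slicing, and
  tokenization of unit-label strings ("C2C2D" → `C2, C2, D`; a unit token is
  one capital letter plus an optional sub-class number).
* **features** — spectrograms (512-point FFT, Blackman–Harris window, 75%
  overlap), the 5 basic descriptors per event (duration, spectral min, max,
  bandwidth, peak), the 74-descriptor extended set (spectral shape
  statistics, MFCCs, chroma, with delta counterparts), and per-category
  dispersion (mean pairwise Euclidean distance).
* **catspace** — z-scoring, PCA with explained-variance ratios,
  unit-category × CSE-category mean-distance matrices, and a seeded 2-D
  t-SNE map (delegated to scikit-learn).
* **sequences** — the stimulus–response pattern analysis: the response to a
  stimulus is the unit sequence emitted before the next stimulus, and
  repeatability is measured with the token-level **normalized Levenshtein
  similarity index** (NLSI),

  $$\mathrm{NLSI}(a, b) = \frac{d_L(a, b)}{\max(|a|, |b|)} \in [0, 1],$$

  where $d_L$ counts single-*unit* insertions, deletions and substitutions
  (never characters — `C2` is one symbol). 0 means identical sequences,
  1 maximally different. Per stimulus the package reports all pairwise
  indices, their range, the set median, a generalized median (hill-climbing
  over single-token edits), and counts of phrase motifs such as `C2C2D`.
* **synth** — a fully seeded synthetic-session engine built on the
  mass–damper–spring valve model of the whale vocal generator,

  $$m_s \ddot z + r_s \dot z + k_s (z - z_0) = p_r - p_m,$$

  with quasi-static orifice flow and a downstream air-sac compartment that
  produces genuine self-sustained oscillation above a threshold blowing
  pressure. Tonal (f0 < 100 Hz, formants ≤ 8 kHz) and pulsed units with
  attack–sustain–release envelopes are rendered into whole stimulus–response
  sessions driven by phrase grammars with controllable token noise, so every
  analysis stage is testable without any field recording.

The package ships the printed annotation summaries of a 2018 interaction
session off La Réunion Island (unit/CSE occurrence counts and the
stimulus → response sequence strings) as plain-text fixtures.

## Worked example

```python
from cetasong import (load_response_fixture, summarize_indices, set_median,
                      generalized_median, count_motif, tokenize_label_string)

responses = load_response_fixture()
seqs = responses["PP1"]["sequences"]
print("responses after PP1:", [str(s) for s in seqs])
summary = summarize_indices(seqs, "PP1")
print("NLSI range:", summary.formatted())
print("set median:", set_median(seqs).median)
ccd = count_motif(seqs, tokenize_label_string("CCD"))
c2c2d = count_motif(seqs, tokenize_label_string("C2C2D"))
print("sequences containing CCD:", ccd[1], "| containing C2C2D:", c2c2d[1])
```

prints

```
responses after PP1: ['MCCD', 'CCD', 'C2C2C2D', 'C2C2C2D', 'C2DC2C2D', 'C2C2DC2']
NLSI range: 0–1
set median: C2C2C2D
sequences containing CCD: 2 | containing C2C2D: 4
```

Read: the six unit sequences the whale emitted after the stimulus `PP1`
range from identical (two literal repeats of `C2C2C2D`, NLSI 0) to maximally
different (NLSI 1); their best single representative is `C2C2C2D`; two of
the six carry the `CCD` phrase core and the other four carry `C2C2D`
instead — a token-level distinction a character-level comparison would miss.

## Command line

```bash
cetasong simulate  --scenario scenario.yaml --out-dir out/   # WAV + TSV
cetasong features  --audio out/session.wav --annotations out/annotations.tsv --out-dir out/
cetasong catspace  --features-csv out/extended_features.csv --out-dir out/
cetasong sequences --annotations out/annotations.tsv --out-dir out/
cetasong report    --out-dir out/
```

Every stage writes a `manifest.json` (inputs, parameters, seed, version);
deterministic stages re-run bit-identically from it.

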
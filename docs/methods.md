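# Methods

This note documents the models, conventions and numerical choices behind
`cetasong`, in the order a session flows through the pipeline.

## Event model and tokenization

Events are half-open intervals `[onset, offset)` in seconds from file start.
Overlapping events are legal but must differ in onset: in manual annotation
of mixed unit/CSE passages, distinct start times are what make overlaps
classifiable, and the table enforces exactly that invariant. Unit labels are
one capital letter plus an optional sub-class number (`C`, `C2`, `C4`);
tokenization is greedy longest-match, so digits always bind to the preceding
letter and joining the tokens reproduces the string exactly. Any capital
letter is accepted even if a particular session's repertoire skips some
letters. CSE labels (`P5DOF`, `WFG1`) are atomic category names and are
never tokenized — stimuli are single symbols in the sequence analysis, not
sequences.

## Stimulus–response sequence analysis

The response to one stimulus occurrence is the ordered unit labels with
onsets strictly between that stimulus's start and the next stimulus's start
(or end of session). Empty responses are retained, so per-stimulus response
counts always equal occurrence counts — a cross-check the synthetic sessions
exercise.

Distances are token-level Levenshtein: one edit inserts, deletes or
substitutes one *unit*. The normalized index divides by the longer
sequence's token count. That denominator is a deliberate choice: it is the
unique simple normalizer that (a) bounds the index in [0, 1] for every pair
and (b) makes 1 mean "maximally different at this length". Reporting rounds
half-up to two decimals and trims trailing zeros ("0.5", not "0.50");
single-response stimuli report "NC" (not computable) rather than a number.

Medians: the *set median* minimizes total distance over input members, with
ties broken by shorter length then lexicographic token order (so results are
input-order independent). The *generalized median* hill-climbs from the set
median over the single-token edit neighborhood (substitutions, insertions,
deletions drawn from the observed alphabet), accepting strict improvements.
The algorithmic contract is the bound `total(generalized) ≤ total(set)`, not
global optimality — exact generalized-median search is exponential. Motif
counting is contiguous token-subsequence matching; `(C,C,D)` does not match
inside `(C2,C2,D)`, which is precisely why motif splits double as a
tokenizer correctness check.

## Valve oscillator

The vocal generator (paired arytenoid cartilages with membrane, like a
double reed) is modeled as a single-mode pressure-controlled valve:

    m_s z̈ + r_s ż + k_s (z − z0) = p_r − p_m

with per-unit-area coefficients, so the right-hand side is the transvalve
pressure. Defaults (`m_s = 1 kg/m²`, `k_s = 2.5×10⁵ Pa/m`, `r_s = 25`,
`z0 = 1 mm`, slit width 0.2 m) put the natural frequency near 80 Hz — inside
the sub-100 Hz fundamental band of tonal units — with a quality factor of
about 20.

Airflow follows the laminar quasi-static orifice law
`U = w·z·√(2Δp/ρ)`. A purely algebraic coupling of this kind makes the
aerodynamic force on the valve conservative, so it cannot feed energy into
the oscillation against damping; a sustained regime needs one dynamic
element. The anatomy supplies a natural one: the laryngeal sac downstream of
the valve. With coupling on, the sac is a lumped compartment of acoustic
compliance `C` (default 3.6×10⁻⁷ m³/Pa, a ~50 L air volume) vented through a
resistance `R` (10⁴ Pa·s/m³); its pressure `p_m` integrates the inflow and
reduces the transvalve drop. The loop aperture → flow → sac pressure →
closing force is a lagged negative feedback; above a threshold blowing
pressure the equilibrium undergoes a Hopf-type instability and the clamp and
√-flow saturations bound a stable limit cycle. The tests locate this
threshold by bisection over constant-pressure runs (it falls between 100 and
200 Pa at the defaults) and verify decay below and sustained periodic
oscillation above.

Integration is fixed-step classical Runge–Kutta at an oversampling factor
(default 4× the output rate; tests use 10× for closed-form comparisons). The
aperture is clamped at zero with inelastic contact (closing velocity
zeroed); the clamp can be disabled to integrate the pure linear oscillator
for closed-form checks. Radiated sound is taken proportional to the time
derivative of flow — the simplest monopole-like radiation proxy; no
underwater propagation is modeled.

## Unit rendering and sessions

Tonal units are additive harmonic stacks at the contour-modulated
fundamental (six contour classes: flat, up/downsweep, convex, concave,
modulated), each harmonic weighted 1/n and by a Lorentzian formant-resonance
gain; formant centers are capped at 8 kHz. Pulsed units are decaying-burst
trains at the pulse rate — the regime reached when membrane tension and
airflow drop together — so their envelope autocorrelation peaks at the pulse
period. Both are shaped by a linear attack–sustain–release envelope and
peak-normalized; rendered duration equals the envelope total to within one
sample.

Session generation is a pure function of its scenario: a stimulus schedule,
a per-stimulus grammar of weighted phrase patterns, per-token
substitution/insertion/deletion rates, an inter-unit silence range, and a
seed. Per-category timbres (fundamental, contour, envelope, formants) derive
from a stable hash of the label, so the same label renders identically
across sessions. Default output is 48 kHz mono WAV, written at 24-bit PCM to
match typical field recordings (16/32-bit selectable). What the generator
emulates is the *statistical and mechanical* structure the analysis assumes —
interleaved stimuli and responses, grammar-driven sequences, tonal/pulsed
spectra with plausible envelopes. It does not attempt faithful whale timbre,
singer variability beyond token noise, ocean noise, or propagation; tests
passing on synthetic sessions validate the pipeline's bookkeeping and
statistics, not detection or classification performance on real recordings.

## Acoustic features

Spectrograms use a 512-sample FFT with the Blackman–Harris window at 75%
overlap (hop 128), frames counted as `floor((L − nfft)/hop) + 1`. The basic
set's spectral min/max are the lowest/highest frequencies whose
event-averaged magnitude lies within a floor of the spectral peak; the floor
is −20 dB by default — a fixed, documented convention, since visual
annotation practice has no single published criterion. `bandwidth =
fmax − fmin` holds exactly by construction, and silent segments are flagged
rather than given fabricated numbers.

The extended set has exactly 74 components: 8 frame-level descriptors with
delta counterparts (ZCR, energy, energy entropy over 10 sub-blocks, spectral
centroid, spread, spectral entropy, flux, 90%-power roll-off), 6 unpaired
summaries (magnitude-weighted spectral bandwidth, flatness, RMS, Rényi
entropy of order α = 2, Shannon entropy in bits, spectral kurtosis about the
centroid), 13 MFCCs (26 triangular mel filters, log, orthonormal DCT-II) and
13 chroma with deltas for both. Chroma is 12 pitch-class bins (A440
reference) plus a per-frame chroma-deviation summary as the 13th component —
the interpretation adopted to honor the 13-per-set count, recorded here as a
design choice. Frame-level values aggregate by arithmetic mean; deltas by
the mean absolute frame-to-frame difference. Analysis frames are 1024
samples with 512 hop (Hann) — fixed documented defaults where toolbox
conventions vary. All values are finite for any finite input; entropies and
moments of an empty spectrum are defined as zero.

## Category space

All distance work happens in z-scored space: the descriptor sets mix Hz,
seconds, bits and ratios, so raw Euclidean distances would be dominated by
scale. Features constant up to float round-off are dropped with a logged
notice. PCA is the eigendecomposition of the sample covariance, components
sign-fixed by making each one's largest-magnitude loading positive; the full
projection reconstructs the input to 1e-10. The between-category matrix
averages Euclidean distances over all (unit event, CSE event) pairs per
label pair, with per-column means and the grand mean over unit–unit pairs.
The 2-D map delegates to scikit-learn's t-SNE under a fixed seed with
perplexity capped below the row count; this package owns only
preprocessing, seeding and output shaping, and the pipeline continues
without the map if the optimizer is unavailable.

The numeric cells of the published per-category dispersion and
distance tables, and the published PCA variance percentages, derive from raw
recordings that are not deposited; they are treated as non-reproducible
here. The operations that produce them are instead validated on synthetic
data with known structure: planted Gaussian spread against the closed-form
mean pairwise distance, planted covariance spectra at n = 2000, planted
cluster offsets in the distance matrix, and invariance properties
(row-order, translation, orthogonal rotation).

## Problem sizes and determinism

Test and acceptance runs use deliberately small problem sizes — 8 kHz
synthetic sessions of a few stimuli, sub-second valve integrations at 4–10×
oversampling, 2000-sample PCA draws, 100-response classification runs —
chosen so the whole suite completes in well under a minute while leaving
every statistical check comfortably powered. Every stochastic stage takes an
explicit seed (scenario seed, embedding seed, per-replicate seeds in
Monte-Carlo tests); identical seeds give bit-identical sessions, tables and
embeddings.

## Known limitations

* The generalized median is a local optimum; printed representatives from
  other implementations may differ while satisfying the same total-distance
  bound.
* The valve model is single-mode: no vertical phase difference, no chaotic
  regime characterization, no turbulence (real flows in both the instrument
  and the animal are substantially turbulent; the laminar simplification is
  the standard modeling idealization and is what the simulator implements).
* The feature definitions follow fixed in-package conventions; absolute
  feature values are not interchangeable with other toolboxes' outputs,
  though all within-package comparisons are self-consistent.
* Automatic unit detection is out of scope; annotation is assumed given
  (manual in the field, generated in simulation).
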
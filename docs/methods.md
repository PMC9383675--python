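# Methods

## Model

Each base α ∈ {A, C, G, T} of a length-*N* sequence defines an indicator
vector X_{α,k} ∈ {0,1}. The alternating cumulative series

    Φ_k = Σ_{j=1..k} (−1)^{j−1} X_{α,j}

is an integer walk (|Φ_k| ≤ ⌈k/2⌉) whose absolute increments invert it
exactly: X_{α,k} = |Φ_k − Φ_{k−1}| with Φ_0 = 0. The series is treated
as the phase of a discretized complex wave

    ψ_n(k) = A (−1)^{k−1} X_{α,k} exp(i n π Φ_k / λ_N),
    λ_N = Φ_N,   A = 1/√N₊₁,

where N₊₁ is the number of ones and n ≥ 1 an integer mode. The model's
assumptions are minimal: positions are treated as independent ticks of a
one-dimensional lattice, and no physical energy or momentum is ascribed
to the modes. Three identities pin the construction down and are what
the test suite checks:

- normalization: Σ_k |ψ_n(k)|² = A² Σ X² = 1 for every mode;
- support: ψ_n(k) = 0 exactly where X_{α,k} = 0, and
  |ψ_n(k)|² = X_{α,k}/N₊₁ independent of n (modes differ only in phase,
  so the construction is not translation-symmetric: shifting positions
  changes |ψ|² wherever the indicators differ);
- endpoint: at k = N the phase is exactly nπ, so by Euler's identity
  ψ_n(N) = (−1)^n (−1)^{N−1} X_{α,N}/√N₊₁.

Degenerate inputs are hard errors, not regularized: an all-zero
projection has no normalizable wave (A undefined), and a balanced series
(λ_N = 0) has no phase scale. Both raise `ValueError` with the cause
named; the alternating series and its inversion remain available for
such inputs.

The amplitude's sign ambiguity (±1/√N₊₁) is resolved to the positive
root throughout; a global sign changes no modulus, spectrum or audio.
Mode defaults to n = 1 and any integer n ≥ 1 is accepted.

## Sequence handling

FASTA input is read with Biopython, uppercased, with U folded onto T so
one code path serves DNA and RNA. Non-ACGT characters (IUPAC ambiguity
codes) are retained in the symbol string, counted, reported with a
warning, and score 0 in all four projections — so per base the zero/one
census still satisfies N₀ + N₊₁ = N, while the four channels sum
positionwise to at most 1 (exactly 1 for pure-ACGT input). All reported
positions are 1-based.

## Synthetic baselines

The generator draws i.i.d. Bernoulli(p) binary strings and i.i.d.
nucleotide strings with per-base weights, using numpy's default PCG64
generator with an explicit seed recorded in a JSON manifest; identical
specs give bitwise-identical output across platforms. The canonical
binary comparison densities are 50/50 and 70/30 ones/zeros. The
`omicron-like` preset (weights A 0.30, C 0.18, G 0.20, T 0.32 at
N = 29613) mimics the base composition of a sequenced SARS-CoV-2 Omicron
genome so end-to-end runs resemble real input in length and census.

What the synthetic data does *not* emulate: codon structure, GC skew
along the genome, repeats, or any positional correlation — the draws are
independent by design (lag-1 autocorrelation of a long draw is checked
to be ≈ 0). Passing tests therefore demonstrate the correctness of the
transform and pipeline, not any biological property of real genomes;
runs on real FASTA files exercise exactly the same code path.

## Sonification

A series component (Re ψ, Im ψ, or |ψ|; default Re) is expanded
sample-and-hold — each point held for `samples_per_point` samples
(default 23) — then convolved with a unit-sum Gaussian kernel truncated
at 4σ (σ default `samples_per_point/4`, i.e. ~5.8 samples) to give the
stepped signal a continuous spectrum, and finally peak-normalized to 0.9
full scale (≈ −0.9 dBFS headroom against quantization and smoothing
overshoot). Defaults: 4096 Hz sample rate, 16-bit PCM, mono; a 29613-
base genome then plays for ≈ 166 s. Quantization is round-to-nearest of
sample × 32767; an identically-zero series yields a silent track with a
warning rather than an error. Smoothing with a unit-sum kernel conserves
total signal mass (away from array edges) and never raises the peak.

## Spectrograms and frequency offset

The STFT uses frames of `window_length` samples (default 256, i.e.
16 Hz resolution at 4096 Hz) advanced by `hop_length` (default 128) with
a Hann window. Frames are built by strided views and transformed with
the real FFT; no padding is applied, so the column count is exactly
floor((n_samples − window)/hop) + 1 and the frequency axis spans
0..rate/2. scipy's high-level STFT wrappers are not used because their
boundary padding and detrending would break this exact frame contract;
the framing construction here is the standard one. Rendering converts to
dB relative to the global peak with a −80 dB floor (linear magnitudes
are kept in the data structure).

The frequency offset — useful for lifting low-frequency content into a
visually clearer band, conventionally 400 Hz — is a single-sideband
shift: the analytic signal (Hilbert transform) is modulated by
exp(2πi·f·t) and the real part taken, so a tone at f lands at f + offset
with no mirror image. Ring modulation was rejected because its mirror
sideband would alter the visual line density being compared. Content
pushed past Nyquist is an error; the signal band edge is estimated as
the highest frequency bin above 1e−4 of the spectral peak. A cosmetic
variant (`--axis-offset-hz`) relabels the plot axis without touching the
data, for cases where the offset is presentational only.

## Numerical choices

- Φ is accumulated in exact integer arithmetic; the phase is formed from
  the rational multiple r = nΦ/λ_N in one step (no incremental complex
  multiplication). r is reduced modulo 2 before the trig evaluation
  (a sinpi/cospi-style construction), so integer r — in particular the
  endpoint, where r = n — yields an exactly real value.
- Tolerances: normalization is asserted to 1e−9 relative (accumulation
  over up to 1e5 terms), the endpoint identity to 1e−12 absolute, and
  mode-independence of the modulus to 1e−15 relative (a one-ulp hypot
  effect).
- WAV round trips are exact to the quantization step 1/32767; declared
  duration is exactly sample count / rate.

## Problem sizes

The default suite exercises strings up to 1e5 (random) and all 2^12
strings of length 12 (exhaustive inversion), 1000-record FASTA round
trips, two-second audio fixtures and a full simulate→wave→sonify→
spectrogram chain at genome-like length; it completes in well under a
minute. `scripts/acceptance.py` uses a length-10000 Bernoulli(0.3)
string, the scale at which the normalization contract is reported.

## Known limitations

- The mapping from series points to audio (hold length, smoothing width,
  output level) has no canonical convention; the defaults above are
  plain and documented, but other renderings of the same series are
  equally valid and will sound different.
- Balanced projections (λ_N = 0) are rejected rather than given a
  limiting treatment; they occur with probability ~N^{−1/2} for balanced
  random strings and essentially never for real genomes.
- Spectrogram comparison between variants is visual only; no difference
  statistic is computed.
- Audio→series inversion (recovering Φ from a recorded WAV) is out of
  scope.
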
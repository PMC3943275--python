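# Methods

This note records the model the codec implements, the choices that were
genuinely open, and what the synthetic evaluation does and does not show.

## Signal model and pipeline

The codec treats S-EMG as a wide-sense-stationary-per-window, band-limited
process digitized at rate `fs` (typically 2 kHz) with `R`-bit words
(typically 16). Each `N = 2048` sample window is mapped to the wavelet
domain by an orthonormal transform; the spectral energy of EMG decays with
frequency, so coefficient magnitude tends to fall with index once the
coefficients are ordered coarse→fine. The bit-allocation curves exploit
exactly this: they spend `Q` bits on the lowest sub-band, `L` on the
highest, and interpolate with a decreasing curve whose shape (linear,
square-root, exponential, rotated-tanh) is the codec's main tuning choice.

Default operating point: `N=2048, M=16, wavelet=db4, levels=8, shape=rht,
Q=10, L=2, α=0.4, β=0.5`. `Q` is the rate dial; sweeping it from 15 down
to `L` traces the CF–PRD curve.

## Transform

* "Daubechies-4" is read as the 4-vanishing-moment (8-tap) filter, PyWavelets'
  `db4`; any orthogonal wavelet can be selected.
* Periodized (circular) boundary handling keeps the map exactly orthonormal
  and the coefficient count equal to `N`. Symmetric extension would break
  both the Parseval identity the quantizer's analysis relies on and the
  clean `N/M` sub-band geometry.
* `N` divisible by `2^levels` is enforced; with the defaults the
  approximation block holds `2048/2^8 = 8` coefficients.
* All arithmetic is double precision; integers only reappear at the final
  reconstruction, rounded half-away-from-zero and clamped to the `R`-bit
  range.

Orthonormality bounds the coefficient *energy* by the signal energy, not
the coefficient *maximum*: a window can concentrate enough energy into one
coefficient to push it past `2^(R−1)`. The transform module exposes a
counter for such events and the quantizer clamps them (below) rather than
assuming they cannot happen.

## Bit allocation

* "intsup" is implemented as the ceiling. It is the only rounding for which
  the linear, square-root and exponential curves hit their stated endpoints
  `B[0]=Q`, `B[M−1]=L` exactly, which is the contract the shapes advertise.
  A guard of 1e−9 is subtracted before `ceil` so that an endpoint computed
  as `Q + 1 ulp` does not round to `Q+1`.
* The square-root and exponential closures are `ξ = Q/√C`,
  `C = Q²(1−M)/(L²−Q²)` and `b = Q^(1/p)`, `p = (1−M)/(log L/log Q − 1)`;
  both were validated by the endpoint identity over the whole grid
  `Q ∈ 4..15`, `L ∈ 1..Q−1`, `M ∈ {4,8,16,32}`.
* The exponential shape needs `Q, L ≥ 2` (logs); the degenerate `L = Q`
  case falls back to a flat allocation for all shapes.
* The rotated-tanh curve is not endpoint-pinned by construction, so its
  output is clamped into `[L, Q]`; `α ≥ 0` keeps it non-increasing. The
  defaults `α = 0.4, β = 0.5` put the sigmoid midpoint at mid-spectrum
  with a moderate transition, which behaved as a reasonable middle ground
  between the linear and exponential extremes.
* A sub-band allocated zero bits (`L = 0`) is discarded: its symbols are
  forced to zero at the quantizer.

## Quantizer

`int` in the quantization law is truncation toward zero, making the
quantizer odd-symmetric (no DC bias); the decoder mirrors it, so the choice
only redistributes distortion within one step. The divisor is `2^(R−1)`
exactly. Symbols are clamped to `[−λ_m, +λ_m]`; clamps are counted and
logged because they fall outside the one-step error bound
`|X − X̂| < 2^(R−1)/λ_m` that holds everywhere else.

## Entropy coder

The coder is an adaptive order-0 binary-renormalization arithmetic coder
(32-bit integer state, underflow-bit handling). Model choices:

* one frequency model per *distinct* bit width `B` present in the plan
  (sub-bands with equal width share statistics; alphabets of different
  widths differ by orders of magnitude and must not be mixed);
* counts start at 1 (Laplace prior) over the `2^(B+1)+1`-symbol alphabet,
  grow by 32 per occurrence, and are halved at a ceiling; the increment of
  32 makes adaptation fast enough that highly redundant streams (e.g. a
  constant symbol) approach zero bits per symbol within one window;
* a Fenwick tree backs each model: O(log A) frequency updates, cumulative
  queries, and decoder symbol search;
* models reset every window, so each window payload is independently
  decodable and a corrupted window cannot poison its successors.

Each payload carries a 4-byte count of coded bits and an arithmetic-coded
CRC-32 of the symbol vector. The bit count makes truncation detectable
even when the lost bytes are flush padding the decoder would never read;
the CRC catches bit corruption and decoding under a mismatched allocation
plan. Decoding never returns silently wrong symbols.

## Container

Little-endian fixed header (magic `SEMG`, version, `fs`, `R`, `K`, `N`,
`M`, levels, wavelet name, shape, `Q`, `L`, `α`, `β` as float32, window
count, pad count) protected by CRC-32, then length-prefixed window
payloads. The stream is fully self-describing — decoding uses only the
bytes. The reported compressed size `C_S` (hence CF) counts the whole
file including the header: a conservative accounting convention, stated
here because header overhead is a real cost of any practical container.
`α`/`β` are normalized to float32 at encode time so the in-memory stream
equals its on-disk parse bit for bit.

Zero-padding of the final window plus the stored `K` is this package's
convention for non-multiple-of-`N` lengths; zeros are the neutral fill
for an orthonormal transform, and PRD is always computed on the first `K`
samples only.

## Synthetic surrogate signals

The generator produces band-limited (default 20–450 Hz, 4th-order
zero-phase Butterworth) Gaussian noise at 2 kHz/16 bit:

* *isometric*: constant envelope at a target RMS, emulating a held
  contraction;
* *dynamic*: the carrier gated by a periodic burst envelope (default 1 Hz,
  duty 0.5, 50 ms raised-cosine ramps) over a 1 %-of-full-scale noise
  floor, emulating cyclic exercise.

The default RMS is 0.1 of full scale. This mirrors the gain staging of
real acquisition chains — peaks of a Gaussian process sit near 4.5 σ, so
an RMS much above ~0.15 of full scale would regularly hit the ADC rails —
and it keeps the wavelet coefficients inside the `2^(R−1)` dynamic range
that the quantizer's near-lossless limit presumes. Banks jitter the RMS
by ±20 % per signal and derive per-signal seeds from a master seed.

What the surrogate does **not** model: motor-unit firing statistics, the
spectral tilt of real EMG within the 20–450 Hz band (the surrogate is flat
in-band), fatigue-related spectral compression, movement artifacts, and
power-line interference. Consequences: absolute CF/PRD numbers on
surrogates are pessimistic relative to physiological recordings (a flat
in-band spectrum is close to incompressible noise), and the evaluation
here demonstrates correctness, monotone rate-distortion behavior and
relative shape rankings — not the absolute rate-distortion performance
attainable on real signal banks.

## Evaluation choices

* Rate-distortion sweeps vary `Q` from 15 down to `L` at fixed `L` for
  each shape; the exact parameter grids behind published bank-level curves
  are generally not reported, so the swept grid is documented in the
  report itself (one CSV row per point).
* Bank-level curves average PRD per shape within 1-percentage-point CF
  bins; comparisons across shapes use only CF bins where every shape has
  points ("matched CF").
* Test and acceptance runs use seconds-long bank signals (4 s × 14
  signals) and a 10 s fixed signal: every stage runs end to end at these
  sizes and the measured properties (losslessness, monotonicity,
  endpoint identities, error bounds) are size-invariant.

## Known limitations

* The arithmetic coder is pure Python; throughput is roughly 10⁵ symbols/s
  per core (≈1 s per minute of 2 kHz signal per Q setting), fine for
  evaluation, slow for bulk archival work.
* Single-channel only; no streaming decode (whole file in memory).
* CF can be negative at near-lossless settings on noise-like input — the
  entropy stage cannot compress what has no redundancy, and the container
  adds header overhead. This is reported honestly rather than clipped.
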
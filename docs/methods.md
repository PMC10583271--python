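# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `nusbench`.  It describes what the code computes; every
number quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## Signal model

A synthetic peak is a separable product of one-dimensional signals.  Along
dimension *d* with spectral width `sw_d`, the evolution time at 0-based
grid index *k* is `t = k / sw_d`, and the two quadrature factors are

    R: env(t) · cos(2π ν_d t + φ_d)
    I: env(t) · sin(2π ν_d t + φ_d)
    env(t) = exp(−π Δ_d t) · ∏_J cos(π J t)

* `ν_d` — frequency, stored as a signed Hz offset from the carrier.
* `Δ_d` — decay, defined as the Lorentzian full width at half maximum in
  Hz, so the time envelope is `exp(−π Δ t)`.  `Δ = 0` models constant-time
  evolution (no decay), as in the constant-time dimensions of real
  triple-resonance experiments.
* `φ_d` — zero-order phase in degrees.
* Each coupling `J` is a cosine modulation `cos(π J t)`, which splits the
  peak into a doublet separated by exactly `J` Hz (verified against a
  brute-force DFT in the tests).

Hypercomplex data carry `2^D` real components for `D` dimensions; component
`c` is a bitmask whose bit `j` selects the sine factor of `dims[j]`.  This
is the States layout: a 3D experiment records 4 complex FIDs per indel, and
full component sampling keeps all of them at every scheduled indel.
Simulation is linear in the peak table, so injected data equal reference
plus synthetic element-wise, and the synthetic-only data set is always
available for processing in isolation.

Group-delay ("negative time") points are simulated as zero-valued
placeholder points prepended to every direct-dimension vector; the choice
of zero values is the package's own, since only their placement is
specified by acquisition practice.

The solvent signal adds, to every 1D direct-dimension vector, one
exponentially decaying signal of fixed linewidth whose amplitude, phase,
and frequency are drawn uniformly within user bounds, independently per
vector from a seeded generator.  An exponential envelope was chosen for the
fixed shape; the draws emulate the scan-to-scan instability of a real
solvent resonance.

## Synthetic reference data

`make_synthetic_reference` stands in for a measured uniformly sampled
experiment: `n_peaks` random peaks (uniform frequencies within ±0.4 sw,
linewidths 10–40 Hz, amplitudes 0.5–2) plus i.i.d. Gaussian noise of
standard deviation `noise_sigma` (default 0.05, i.e. ~10–40× below peak
time-domain amplitudes) on every hypercomplex point.  What it deliberately
does **not** emulate: t1-noise and other correlated artifacts, baseline
distortion beyond the optional solvent signal, mixed-phase composite
lineshapes, and temperature / field drift.  Tests passing on this generator
therefore demonstrate algorithmic correctness and calibrated arithmetic,
not robustness to every pathology of real spectrometers.

## Placement programs

`gen_sim_tab` places strips (groups of peaks sharing the two
strip-defining coordinates, e.g. the ¹H,¹⁵N plane) by a small
keyword=value program: `novel` draws from positions whose z-projected
empty-region mask is set, `existing` draws from detected peak coordinates,
and `offset` displaces an existing coordinate by a stated ppm.  Five
canonical presets mirror the evaluation design: strong closely spaced
pairs (resolution), strong isolated peaks (frequency accuracy), and
variable-intensity isolated peaks (sensitivity), plus offset and classic
paired placements.  Default per-peak randomization: linewidth ±20 %, phase
±5°, optional couplings uniform in 3–12 Hz, amplitudes fixed at 5 for the
"strong" presets and uniform in 0.2–2.0 for the sensitivity preset.  These
magnitudes are the package's defaults — chosen as typical of backbone
triple-resonance data — and are all exposed in the program grammar.

## Spectrum characterization

* **Noise**: `1.4826 × MAD` about the median of all intensities — robust to
  the sparse strong peaks that sit on top of the noise floor (within 2 % of
  σ with 10 spikes of 100 σ present).
* **Peak picking**: strict local maxima over face-adjacent neighbors
  (plateaus yield no peak — unambiguous and testable), refined by a
  separable per-axis 3-point parabolic fit, exact for quadratic bumps.
  Peaks at array edges keep their grid position with no linewidth estimate.
  Results are sorted by interpolated height and truncated (1500 by default
  for evaluation; 256 for reference characterization).
* **Empty-region mask**: a point is empty when its axis-aligned
  neighborhood of half-width `ceil(2 × median linewidth)` points per
  dimension has rms < 1.15 σ and maximum ≤ 5.0 σ.  The center point is
  included in the region; neighborhoods are truncated at spectrum edges
  (box sums by cumulative-sum sweeps, maxima by a constant-padded maximum
  filter).  The criteria are scale-free, and raising σ can only add empty
  points.  2D projections use AND along the dropped axis, so a projected
  position is empty only if it is empty everywhere along that axis.

## Sampling schedules

Indel weights are separable, `w(k) = ∏_d exp(−π R_d k_d / sw_d)`, so the
sampling density decays like the signal envelope under the decay convention
above; `R_d = 0` (constant time) gives uniform weighting.  Weighted
sampling without replacement uses exponential (Efraimidis–Spirtes) keys,
which is equivalent in distribution to sequential draws with
renormalization — the test suite verifies the equivalence against a
brute-force sequential-draw oracle.  The first indel (largest signal) and
the last indel (defines the grid extent) are always forced.  Indels are
stored in canonical (row-major) order; coverage is reported to one decimal
place as 100 × indels / grid volume.

## Processing and reconstruction

The DFT chain applies, per dimension: first-point scaling (0.5 by default),
a cosine-power window `cos(πk/2(n−1))^p` (p = 2 by default, 0 disables),
zero filling by doublings, FFT, frequency-domain phase correction, and
States recombination (the quadrature pair of each dimension forms a complex
interferogram; only the real part continues to the next dimension).
Spectral axes run high-to-low frequency (increasing index = decreasing
ppm).  The direct-dimension region of interest is extracted after the
direct transform; the pre-extraction size is recorded in the spectrum
provenance because the contest size rule measures the direct dimension
before extraction.

**Size rule**: each spectral dimension may not exceed
`nextpow2(n_points) × 2³` ("rounding up to the next Fourier number and
three zero fills").  "Fourier number" is interpreted as the next power of
two, and the boundary is inclusive — both recorded assumptions.

**IST.**  Per direct-frequency plane, the hypercomplex indirect components
are mapped to complex grids by a lossless (bijective) combination: `R + iI`
for one indirect dimension; for two, the P/N-type pair
`Z₁ = (RR − II) + i(IR + RI)`, `Z₂ = (RR + II) + i(IR − RI)`.  Each
iteration transforms the current grid estimate to the frequency domain,
soft-thresholds at `f_i × max|F|` with `f_i` decaying geometrically from
0.99 to 0.01 over the iteration budget (all parameters exposed), inverse
transforms, and restores the measured values at scheduled indels.
`exit_mode="data_replacement"` exits after the restore, so the
reconstruction's time-domain samples equal the measured NUS data exactly
(residual < 10⁻¹⁵ relative in the acceptance run); `"post_threshold"`
exits after the thresholding step and generally leaves a nonzero residual
at measured points.  The final spectrum is produced by the same States
chain as the baseline DFT, so with full sampling IST reproduces the DFT
spectrum to machine precision.  With threshold 0 and one iteration the
post-threshold variant reduces to the zero-filled DFT of the expanded NUS
data.  No apodization is applied inside the iteration itself; the
configured indirect processing is applied to the reconstructed full grid.

**Degenerate inputs**: non-finite NUS data raise a numeric error;
`iterations < 1` is rejected; an all-constant spectrum yields noise 0 with
a warning; a neighborhood larger than the spectrum yields an all-zero mask
with a warning.

## Metrics

Distances are Euclidean in Hz across all spectral dimensions (a ppm
distance is available via `obs_mhz=`, which reweights axes by their observe
frequencies).  Matching is greedy nearest-first one-to-one within a
per-dimension tolerance box, with candidates ordered by tolerance-scaled
distance; on random instances it attains the brute-force maximum matching
size in almost all cases, and the rare suboptimal assignment is part of the
documented contract.  Defaults: matching tolerance = per-dimension median
injected linewidth; M1 cap `d_max` = 2× the largest injected linewidth —
both explicit and configurable, since only the existence of a cap is
prescribed by the scoring design.

* **M1** = 1 − H/d_max with H the symmetric Hausdorff distance over peak
  positions, every point-to-set distance capped at d_max.  The directed
  distance from an empty set is 0 and to an empty set is d_max; two empty
  sets are flagged not-applicable.  Because M1 is set-based, spurious weak
  picks saturate it quickly at low picking thresholds — small M1 values on
  otherwise good reconstructions are expected behavior, not a defect.
* **M2/M5** = max(Pearson r, 0) between injected amplitudes and recovered
  heights; unmatched injected peaks enter at height 0; zero variance in
  either vector gives 0 with a degenerate flag.  One implementation serves
  both identifiers (historically two independent implementations of the
  same quantity).  The correlation is reported as r, not r².
* **M3** = matched / injected.  **M4** = recovered peaks matching neither
  an injected nor a supplied reference peak, divided by recovered count;
  flagged not-applicable when nothing was recovered.  For ranking, M4 is
  oriented as 1 − FPR so every metric is higher-is-better; the raw value is
  retained in records.

## Ranking and aggregation

Per (metric, experiment, table, schedule) column, contestants are sorted by
oriented score descending; percentile = 100(n − rank)/(n − 1) for n > 1
(100 for a single participant), and tied scores receive the mean percentile
of their tied span.  The formula and tie rule are the package's own
choices, as is the JSON record schema.  Percentiles are invariant under
strictly monotone transformations of the raw scores within a column and are
recomputed from raw scores on every call, since adding a submission changes
every percentile but no raw score.  Challenge aggregation averages
percentiles over the selected columns, using only the columns in which a
contestant participated.

## File formats

Schedules are plain text (one indel per line, 0-based indices, `#` metadata
lines carrying the seed and generating command); peak tables are
tab-separated text with per-dimension frequency/decay/phase/coupling
columns (couplings comma-joined, `-` when absent); challenge configurations
are JSON.  FIDs, NUS data, and spectra use a portable single-file container
— an 8-byte magic, a JSON header (kind, shape, acquisition metadata or axis
calibrations), then raw little-endian float64 bytes — with bit-exact round
trips.  The container is self-describing and easy to read from any
language; malformed headers raise errors naming the offending field.

## Problem sizes used in tests and the acceptance run

Toy experiments use 64 direct × 64 indirect points (2D) and
32 × 16 × 20 (3D); single-peak recovery runs 20 schedule seeds at 50 %
coverage with 100 IST iterations; metric range checks use 1000 random
instances and 100 brute-force Hausdorff comparisons; mask checks use a
40³ noise spectrum.  These sizes were chosen so the full suite completes in
seconds while every check retains its statistical meaning at the stated
tolerances.

## Known limitations

* IST height fidelity degrades for broad decaying indirect lineshapes: a
  Lorentzian is not sparse, and at 50 % coverage the converged
  data-replacement solution can misestimate peak height by ~10 % even
  though the position is recovered exactly.  The quantitative recovery
  guarantee (height within 5 %) is stated and tested for constant-time
  (zero-decay) indirect evolution.
* IST is implemented for one or two indirect dimensions (2D/3D
  experiments).
* Mixed-time acquisition, partial component sampling, Poisson-gap and
  quantile samplers, and threshold-free (ROC-based) peak-picking evaluation
  are out of scope; alternative reconstruction algorithms are reachable
  only through the external-script interface.
* Bruker/Varian raw formats are not read; digital-filter handling is
  limited to inserting and honoring group-delay placeholder points.
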
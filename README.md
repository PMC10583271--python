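# nusbench

Quantitative evaluation of nonuniform sampling (NUS) and spectral
reconstruction in multidimensional NMR.

Non-Fourier methods that reconstruct spectra from nonuniformly sampled
time-domain data are nonlinear: their artifacts depend on the signals, the
sampling schedule, and algorithm parameters, and there is no formal theory
that predicts their performance. `nusbench` makes the comparison empirical
and objective.  It injects **synthetic peaks with known parameters**
(position, intensity, linewidth, phase, couplings) into measured or
simulated time-domain data, subsamples the result with an exponentially
biased schedule, reconstructs the spectrum, and scores how well the known
peaks are recovered.  Because the ground truth is exact, recovery can be
quantified instead of judged by eye.

It is aimed at NMR spectroscopists and methods developers who want to
benchmark reconstruction algorithms, choose sampling coverage, or tune
processing parameters against reproducible, self-contained challenges.

## What it computes

**Simulation.**  A peak contributes, separably per dimension *d* at
evolution time *t = k / sw_d*,

```
A · exp(−π Δ_d t) · ∏_J cos(π J t) · {cos, sin}(2π ν_d t + φ_d)
```

across the 2^D hypercomplex quadrature components (States convention; four
complex FIDs per indel for 3D data).  Δ is the Lorentzian full width at
half maximum in Hz, and each coupling J splits the peak into a doublet
separated by J Hz.

**Sampling.**  On the indirect Nyquist grid, indel (k₁,…,k_D) is drawn
without replacement with weight `∏_d exp(−π R_d k_d / sw_d)`; R_d = 0 gives
uniform sampling (constant-time dimensions).  The first and last indels are
always forced.

**Reconstruction.**  A baseline DFT chain (apodization, zero fill,
transform, phase, States recombination) and iterative soft thresholding
(IST): alternate soft thresholding in the frequency domain at a decreasing
fraction of the current maximum with restoration of the measured values at
scheduled indels.  Both exit variants are provided — exiting after data
replacement (the reconstruction then matches the measured NUS data exactly)
or after the thresholding step.  External reconstruction scripts plug in
through a four-argument command contract and are subject to the contest
size rule (each dimension at most the next power of two times 2³).

**Scoring.**  Recovered peaks (local maxima, parabolic interpolation, the
1500 most intense retained) are compared with the injected ones:

| metric | meaning |
|--------|---------|
| M1 | frequency accuracy: 1 − H/d_max, H the symmetric Hausdorff distance with per-point cap d_max |
| M2, M5 | intensity linearity: Pearson correlation of injected amplitudes vs recovered heights (unrecovered peaks count as height 0) |
| M3 | true positive rate: fraction of injected peaks recovered |
| M4 | false positive rate: fraction of recovered peaks matching nothing |

All metrics lie in [0, 1].  Rank lists per (metric, experiment, table,
schedule) convert scores to percentiles — a representation independent of
the number of contestants — and challenges aggregate by averaging
percentiles over parameter combinations.

## Worked example

```sh
# a 2D 1H/15N test experiment: config + reference data + 2 known peaks
# (see tests/ and docs/methods.md for how these files are produced)
nusbench simulate --table table.tsv --config config.json \
    --out synthetic.nusb --inject reference.nusb --combined-out combined.nusb
nusbench gen-schedule --grid 64 --n-indels 16 --decay-rates 0 --sw 1600 \
    --seed 7 --out schedule.txt
nusbench subsample --fid combined.nusb --schedule schedule.txt --out nus.nusb
nusbench reconstruct --nus nus.nusb --config config.json --out recon.nusb \
    --iterations 100
```

which prints

```
wrote synthetic FID: synthetic.nusb
wrote combined FID: combined.nusb
wrote 16 indels (25.0 % coverage) to schedule.txt
wrote NUS data (16 indels) to nus.nusb
wrote spectrum (128, 128) to recon.nusb
```

Scoring the reconstruction against the injected table
(`evaluate_reconstruction(spectrum, table, config)`) yields

```
M3 = 1.00   both injected peaks recovered
M2 = M5 = 1.00   recovered heights perfectly linear in injected amplitudes
M4 = 0.99   most of the 1500 low-threshold picks are noise, hence "false"
M1 = 0.00   the symmetric Hausdorff cap is saturated by those same
            spurious weak picks
```

The M1/M4 values illustrate an important property of the scoring design:
with a deliberately low peak-picking threshold, set-based metrics are
dominated by spurious weak maxima, while the matched-pair metrics (M2/M3/M5)
isolate recovery of the known peaks.  Raising the detection threshold or
supplying the reference peak list (`reference_peaks=...`) moves M1 and M4
accordingly.

A full project evaluation — every (experiment × table × schedule × script)
combination, JSON records, CSV rank lists, percentile aggregation — runs via

```sh
nusbench run  PROJECT --plan plan.json
nusbench rank PROJECT --out ranks.csv
nusbench report PROJECT --challenge '{"metrics": ["M1", "M3", "M5"]}'
nusbench status PROJECT
```

## Layout

```
src/nusbench/core_model.py    domain types, containers, file formats, units
src/nusbench/simulate.py      FID simulation, solvent signal, injection
src/nusbench/characterize.py  noise, peak picking, empty-region mask
src/nusbench/peakgen.py       program-driven synthetic peak placement
src/nusbench/sampling.py      biased schedule generation, subsampling
src/nusbench/reconstruct.py   DFT chain, IST, size rule, external scripts
src/nusbench/metrics.py       peak matching and the M1–M5 metrics
src/nusbench/evaluate.py      records, rank lists, aggregation, workflow
src/nusbench/cli.py           the `nusbench` command
```

See `docs/methods.md` for the model, parameter, and design details.
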
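# Methods

This note documents the models, algorithms and numerical choices behind
`mzlsh`: what is computed, under which assumptions, and which design
decisions were genuinely open.

## Problem setting

Centroided MS1 raw data from LC-MS or LC-IMS-MS acquisitions is a large set
of *mass axes*: for every retention-time index (`frame`) and, when ion
mobility is recorded, every mobility index (`scan`), a list of
`(m/z, intensity)` peaks.  Signals of interest are isotopic patterns —
series of peaks spaced `Δ/z` apart (`Δ = 1.003355` Da, the ¹³C–¹²C mass
difference; `z` the charge) — that recur across neighbouring time points as
an analyte elutes.  Electronic noise does not recur.  `mzlsh` classifies
peaks as signal or noise by detecting this *self-similarity* with
locality-sensitive hashing, without assuming anything about the pattern
shape; an optional averagine reference database additionally estimates
monoisotopic m/z and charge (deisotoping).

## Windows and binning

Each mass axis is cut into compact intervals (*windows*) of length
`L = 10` m/z on two staggered grids: starts at `k·L` and at `k·L + L/2`
(anchor 0, half-open intervals, boundary peaks belong to the upper window).
The offset grid guarantees that any pattern of extent ≤ `L/2 = 5` Da is
wholly contained in at least one window.  Windows with no peaks are never
materialised: an all-zero vector has no defined hash direction and carries
no information.  For hashing, a window is binned at `0.1` m/z resolution
into a `d = 100` vector `I` (`bin = floor((mz − start)/0.1)`, intensities
within a bin summed); 0.1 m/z still resolves charge-5 spacing (0.2 m/z)
while keeping the vectors small.

## Similarity, hashing, amplification

Two windows are compared by cosine similarity
`s = ⟨I_i, I_j⟩ / (‖I_i‖‖I_j‖)`, which is invariant under positive
rescaling of either vector — the classifier is therefore blind to absolute
intensity.  The matching LSH family is sign random projection:
`h(I) = sign(⟨I, r⟩)` with `r` standard normal, so a single bit agrees with
probability `p = 1 − arccos(s)/π`.  Bits are AND/OR amplified: `m` bands of
`n` bits each; two windows *collide* when at least one band key is equal,
with probability

    P_{m,n}(s) = 1 − (1 − pⁿ)ᵐ .

`n` sharpens the sigmoid (stricter similarity threshold), `m` shifts it
back toward recall.  Numerical conventions: `sign(0) := +1` (binned
integer-like data can produce exact zeros; any fixed convention preserves
the LSH guarantee); band keys pack their `n ≤ 64` bits little-endian into
one integer; direction vectors are drawn band-major from a single seeded
generator so that families with the same `(d, seed)` share direction
prefixes across `(m, n)` sweeps.  Intensities enter the hash un-normalised
(scale invariance makes normalisation redundant).

## Classification by collision

All band keys of the processed unit — the whole input by default, one frame
at a time with `--per-frame` — are counted in a per-band *collision table*;
keys with count ≥ 2 are collided.  A window is signal iff one of its keys
is collided; a peak is signal iff any window containing it (up to two, one
per grid) is signal.  Both grids feed one shared table: two overlapping
windows over the same pattern have shifted bin vectors and hence low mutual
similarity, so systematic cross-grid self-collision does not occur.  A
bucket with two occurrences counts as a collision even when both stem from
the same mass axis.  The baseline classifier is a single global intensity
cutoff (signal iff `intensity ≥ t`), the reduction of signal-to-noise
thresholding under a global noise estimate; unlike the LSH calls it is not
scale invariant.

## Synthetic benchmark generator

The generator emulates the two window populations used for controlled
evaluation; windows are produced directly (each with its own frame index),
not embedded into full frames.

*Noise-only windows* (label `noise_1`): `k ~ Poisson(λ_p) + 1` peaks
(`λ_p = 4`), positions uniform in the window, intensities i.i.d.
exponential.  The exponential parameter is exposed with two
parametrizations; the default treats `λ_e = 15` as the *scale* (mean
intensity 15).  This is a deliberate design choice: with the rate reading
(mean 1/15) noise would sit 3–4 orders of magnitude below every signal
maximum of the intensity series (32–1000), making the series and the
intensity baseline degenerate; a mean of 15 is the only reading under which
the six-step series spans meaningful signal-to-noise ratios.

*Signal windows* (labels `signal` + `noise_2` overlay): a six-peak
averagine pattern with the mono peak at the window centre, max-normalised
and scaled to the dataset maximum `max_intensity ∈ {1000, 500, 250, 125,
64, 32}`; per accepted (mass, charge) combination the original window plus
two copies at half intensity model the recurrence over time (copies are
separate windows — folding them into one window would defeat the
self-similarity rationale).  Every signal window receives an independent
noise overlay.  With the mono at the exact centre, the charge-1 pattern's
sixth isotopologue (+5.0168 m/z) falls just outside the half-open window
and is dropped; z ≥ 2 windows carry all six pattern peaks.

*Grid and m/z filter.*  Monoisotopic masses run 150–5000 u in 10 u steps.
The benchmark tally this generator replicates (14107 noise-only + 4338 signal-bearing =
18445 windows) pins down the acceptance filter only up to convention, and
no convention with charges 1–5 and a filter on the mono m/z reproduces it
(the stated grid gives 1878 accepted combinations, i.e. 5634 windows).
The tally is reproduced exactly by: `m/z = M/z`, the full window
`[m/z − 5, m/z + 5]` required inside `[150, 2000]`, charges 1–4
(consistent with an off-by-one `range(1, 5)` iteration in the generator
that produced the tally).
This *replication convention* is the default; the stated-grid convention
(protonated m/z `(M + z·1.007276)/z`, mono-peak filter, charges 1–5) is
selectable via `mz_convention` / `filter_scope` / `charges`, and the
manifest always records which convention produced the counts.  The
noise-window count (14107) is a free parameter defaulting to the benchmark
value.

## Averagine model and reference search

A neutral mass `M` maps to `M/111.1254` averagine residues of composition
C 4.9384, H 7.7583, N 1.3577, O 1.4773, S 0.0417 (Senko's average residue);
fractional element counts are kept.  The aggregated isotopologue
distribution (by nucleon-count shift) is the convolution of per-element
natural-abundance distributions; fractional counts enter through truncated
power series `exp(c · log p)` — exact for integer `c`, and clipping the
tiny (≲1e-4 relative) negative tail coefficients that the truncation can
produce for sub-unity counts.  Pattern peak `k` sits at
`(M + z·m_p + k·Δ)/z` with `m_p = 1.007276` Da.

The reference database renders patterns for masses 150–1800 Da (step
10 Da by default — the source range is fixed but the step is a free
parameter, so database sizes are configuration-dependent) and charges 1–5
on a 1e-5 Da grid over `[−1, +9]` Da around the mono peak, binned by
summation to 1e-2 Da (1000 bins, mono at bin 100), max-normalised, and
hashed with a shared `(m, n) = (64, 32)` family of dimension 1000.

*Query alignment* is the one genuinely open design point: an acquisition
window's offset against the reference grid is unknown.  Both reference and
query vectors are therefore *base-peak anchored* — cyclically rolled so the
most intense bin sits at a fixed anchor — before hashing and scoring.
Because noise can promote the wrong bin to base peak, the `±Δ/z` rolls of
the query are also scored and the best variant reported together with the
shift applied.  Candidates are all patterns sharing ≥ 1 band key; the
explicit cosine is computed for each, and the best match is returned if it
scores ≥ 0.6 (ties: lowest charge, then lowest mass).  The known failure
mode — matches shifted by whole isotopologue spacings `k·Δ/z` — is
surfaced, not hidden: `isotope_shift` reports the nearest integer shift of
a match against a reference position, and the evaluation tallies shifted
matches separately.

## Evaluation protocol

On labeled synthetic data, TPR/FPR are computed over `signal` and `noise_1`
peaks only; `noise_2` peaks are excluded because window-level classification
necessarily assigns them their window's call — removing noise interleaved
with a pattern is downstream feature-finding's job.  The LSH classifier
yields one ROC point per `(m, n)`; the intensity baseline sweeps the
quantile range of observed intensities.  On frame-indexed data with a
precursor list, signal windows become 2-d points (window-centre m/z, scan);
a precursor is kept when its nearest point is closer than 5 units in
Manhattan distance (the literal unit mix of m/z and scan indices, with
optional per-axis scale factors), and data reduction is one minus the kept
fraction of windows (and of peaks).  Deisotoping results are tallied
nested in 3-d (m/z, scan, charge, radius 10): k1 within the radius, k2 ⊆ k1
with exact charge, k3 ⊆ k2 with exact mono m/z.  Frame sweeps average these
metrics over seeded samples of frames (default 50 frames after skipping the
first 1500; fewer frames are used, with a warning, when the input is
smaller).

## What the synthetic benchmark does and does not show

The generator reproduces the statistical structure of the benchmark —
pattern recurrence, per-window noise, the intensity series — but not
several properties of real acquisitions: chemical noise (which is
self-similar and is deliberately classified as signal), m/z-dependent peak
widths and centroiding error, correlated noise across scans, or realistic
pattern placement (every synthetic pattern is centred in its window, which
makes same-charge patterns at different masses mutually similar and drives
the signal-peak recall of all tested `(m, n)` settings to 1.0 at high
signal-to-noise).  Passing the synthetic checks therefore demonstrates the
correctness of the machinery and the tunability of the operating point,
not end-to-end performance on real data.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run at the full benchmark scale
for the dataset tallies and the ROC comparison (18445 windows, five seeds),
10⁴ Monte-Carlo trials per similarity/setting pair for the
collision-probability agreement, 100 random instances (≤ 50 windows) for
the brute-force collision-table oracle, and 500 noisy queries against the
bundled 830-pattern reference database for recovery; these sizes were
chosen so the whole suite completes in a few minutes on one CPU while
keeping Monte-Carlo standard errors small.

## Known limitations

- Native vendor formats (Bruker TDF) are out of scope; convert to mzML or
  the TSV dialect first.  The mzML reader handles centroided MS1 spectra
  with 32/64-bit float arrays (zlib or uncompressed) only.
- The collision table is exact, not probabilistic, so memory grows with the
  number of distinct band keys (~`m` × windows).
- Reference search assumes one dominant pattern per window; overlapping
  patterns are matched by whichever dominates the base peak.
- The replication convention for the benchmark grid is an inference from
  the window tally it reproduces, not a documented fact; both conventions
  are exposed and recorded in the manifest.
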
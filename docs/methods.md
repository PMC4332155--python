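# Methods

## Kinetic model

One transcription unit is parameterized by `k` (initiation events/min), `v`
(elongation, nt/s), `d` (degradation initiation, 1/min) and `L` (nt).
Assumptions, in the order they matter:

1. **Stationarity before the drug.** Initiation is Poisson with rate `k`
   long enough before t = 0 that every position is at steady state; the
   expected copy number of any synthesized position is then `k/d`.
2. **Constant elongation.** A polymerase initiated at `t0` reaches position
   `x` at `t0 + x/(60 v)`. All time arithmetic is in minutes; `v` is kept in
   nt/s because that is how elongation rates are reported, so `60` appears
   exactly once as a conversion factor.
3. **Single rate-limiting degradation step.** An RNase binds at/near the 5′
   end at rate `d`; everything after that is fast. Ribosomes move at the
   same speed as RNAP and the degradation front trails the last ribosome,
   so position `x` is removed `x/(60 v)` minutes after binding. This is the
   minimal mechanism that makes the fitted exponential lifetime equal at
   every position of a transcript, which is what the per-segment fits are
   designed to detect.
4. **Initiation inhibitor** (rifampicin scenario): no initiations after
   t = 0, elongation continues. Integrating the per-molecule presence
   interval over stationary initiation times gives the delayed single
   exponential `y(x,t) = exp(−d·max(0, t − x/(60 v)))`.
5. **Elongation inhibitor** (streptolydigin scenario): elongation halts at
   t = 0 and every synthesized position decays as `exp(−d t)` with no
   positional delay. This is the control scenario that distinguishes
   residual synthesis from drug-uptake artifacts.

For the post-transcriptional variant (RNase binds only after the full
transcript exists, offset `E′ ~ Exp(d)` past the synthesis time
`S = L/(60 v)`), the same integral gives, with `a = x/(60 v)` and
`m = max(t − a, 0)`:

    y = 1 − d·m/(d·S + 1)            m ≤ S      (delay, then linear)
    y = exp(−d(m − S))/(d·S + 1)     m > S      (exponential tail)

The linear phase reflects waiting for already-started molecules to finish;
as d → ∞ the 5′-end curve becomes exactly `1 − t/S`. The closed form is
verified in the tests against direct numerical quadrature of the survival
integral (agreement ≤ 1e−6 over a grid of x, t, d, v, L) and dominates the
co-transcriptional curve everywhere, as it must.

The probability that a molecule is degraded co-transcriptionally is
`1 − exp(−r)` with `r = d·L/(60 v)` (binding time `Exp(d)` vs synthesis
time `S`): 39.3% at r = 0.5, 63.2% at r = 1, monotone in r.

## Synthetic data generator

`simulate_stochastic` draws molecules event by event: initiation times
uniform on a stationary window, binding offsets `Exp(d)`, presence interval
of position x equal to `(60v(t−t0−E), 60v(t−t0)] ∩ [0, L]`. Molecules are
pooled over `n_cells` cells (default 1000): a quenched aliquot of a culture
contains ~10⁸ cells, so single-cell molecule-number fluctuations are
invisible in the data and the dominant noise is sequencing shot noise.
1000 cells keeps residual population noise below the Poisson read noise at
the default depth while staying cheap; raising `n_cells` makes the
empirical survival converge on the closed form (used by the oracle tests at
n_cells = 10,000). Per-bin read counts are Poisson with mean
`depth × (molecule coverage averaged over the bin's positions, per cell)`;
spike-in species are Poisson around fixed expectations at every time point.
The burn-in is 10× the slowest timescale (`max(1/d, L/(60 v))`); below 5×
the generator refuses to run (non-stationary start). With `d = 0` no steady
state exists, so burn-in falls back to 10× the synthesis time; counts are
then constant in expectation once the last pre-drug polymerase has passed.

Under the elongation-inhibitor scenario each molecule present at t = 0 is
removed whole after a fresh `Exp(d)` wait. Memorylessness of the binding
step makes the per-position expectation exactly `exp(−d t)`; only the
(slightly narrower) per-bin count variance distinguishes this from a
mechanistic front model, and nothing downstream uses that variance.

Defaults emulate an exponential-phase population: lifetimes lognormal with
mean 2.5 min and CV 1, elongation rates truncated-normal (25, 14) nt/s on
[5, 80], lengths uniform 600–15,000 nt, weak promoters
(`k ~ loguniform(0.2, 2)` /min, of order one engaged polymerase per unit),
sampling grid 0, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 10 min (sub-minute early,
where short-lived RNAs decay), and `depth = 400` reads per transcript copy
per 300-nt bin, which reproduces the few-percent root-N error bars of a
deep bacterial RNA-seq time course. The drug-action lag defaults to 0
(rifampicin acts in < 30 s) but is exposed for sensitivity tests.

`simulate_expected` produces the noise-free surface. Each bin is
represented by its **midpoint** position: the position-average of delayed
exponentials across a bin is not itself a delayed exponential (the corner
is smoothed by ~d·w²/24 with w the bin's time width), so a
midpoint-resolution expectation is the choice that makes the noiseless
pipeline an exact fixed point of the fit model (the estimator is exact on
its own expectation). The stochastic simulator
still averages molecule coverage over all bin positions; the difference
(≲2×10⁻³ in relative abundance at default parameters) is far below shot
noise.

**What the generator does not emulate:** sequence-dependent coverage bias,
fragmentation/library artifacts, rRNA contamination, position-correlated
read noise, RNase-site heterogeneity within a transcript, and cleavage
between ribosomes. Passing recovery tests therefore demonstrates
correctness of the estimator under the model's own assumptions — not
robustness to real-library artifacts, which would need real data.

## Preprocessing

Bins are 0-based, half-open, anchored at the strand-resolved 5′ end of each
transcription unit; the trailing partial bin is dropped so every bin has
equal shot noise (a 1,200-nt unit gives exactly 4 bins). Units with
overlapping genomic spans are excluded pairwise, strand-blind by default
(coverage on either strand of an overlap cannot be attributed cleanly when
libraries or annotations are imperfect); `same_strand_only=True` relaxes
this. Per time point, counts are divided by the mean of the spike-in
species' totals (relative to t = 0), then each bin's series by its t = 0
value. The two normalizations commute with the joint closed form
`n_bt·f_0/(f_t·n_b0)` (property-tested). Bins with a t = 0 count below 20
(configurable) are dropped with a logged warning: dividing by a small count
makes the whole series unstable. Uncertainties are root-N on raw counts
propagated through both normalizations, treating spike totals (≥10⁴ reads)
as noiseless; cells with zero counts get the uncertainty of a count of 1 so
that weights remain finite.

## Fitting

Model per segment: `y = A` for `t ≤ P`, `A·exp(−(t−P)/T)` after, fitted by
`scipy.optimize.curve_fit` (trust-region reflective, bounds `P ∈ [0, t_max]`,
`T > 0`, `A > 0`, absolute sigma). `A` is fitted rather than pinned at 1 to
absorb normalization noise in the t = 0 reference. Initialization: `P0` =
first time the series drops below 0.7, `T0` from a log-linear regression of
the points after `P0`, `A0 = 1`; this sidesteps the piecewise objective's
local minima. A converged fit with fewer than two time points beyond the
fitted delay (or a delay pinned at the end of the grid — e.g. a constant
series) is flagged `non_identified` and excluded from downstream averages;
non-convergence is flagged, never dropped silently.

Delays are regressed against bin midpoints (the delay is the passage time
of the "last average polymerase" through the segment; midpoint is the
natural summary, with `position="start"/"end"` switches). `v = 1/(60·slope)`,
with the standard error by the delta method. At least 4 usable segments
(≥ 1,200 nt) are required; shorter transcripts still get lifetimes
(`lifetime_only`). Transcript lifetimes are unweighted means of converged
segment lifetimes; weighting by fit precision would bias toward
fast-decaying segments whose late points carry little information.
Filters: `se(v)/v > 1` → `high_uncertainty`; non-positive fitted rate →
`nonsensical_rate`. Filtering is idempotent and every discard carries its
reason code. A transcript is `lifetime_consistent` when every consecutive
segment pair's lifetime ratio is ≤ 2 — the flag that singles out
differentially stable polycistronic messages.

## Downstream analysis

Synthesis rates are back-calculated as steady-state abundance divided by
mean lifetime. Abundance–rate coefficients of determination are computed on
log scale (rates and abundances are positive and span decades; a
`log_scale=False` switch exists), making them invariant to abundance units.
The genome-average profile aligns transcripts by their 5′ ends (bin index);
transcription-unit boundaries stand in for start codons since no CDS model
is in scope — for bacterial operons the 5′ UTR offset is small relative to
a 300-nt bin. Condition comparisons report means, SDs and the lifetime CV
per condition side by side; they assert nothing, since cross-condition
differences are empirical claims about data, not properties of the code.

## Numerical and testing choices

* Tolerances: the post-transcriptional closed form must agree with
  quadrature to 1e−6; noiseless pipeline recovery to 1e−4 per parameter;
  stochastic recovery is judged by the median relative error (≤ 10%) over
  10 seeds × 50 transcripts at default depth — sizes chosen so the whole
  suite runs in a couple of minutes on one core.
* Degenerate inputs: `d = 0` makes steady-state abundance undefined
  (explicit error) but simulates fine; constant series fit to a pinned
  delay and are flagged; zero spike-in totals are a hard error; empty
  genomes/annotations are explicit errors.
* Determinism: a single `numpy` Generator seeded from the config drives
  every draw; same seed ⇒ byte-identical outputs. The committed golden
  fixture is compared numerically (rtol 1e−7) so that last-ulp BLAS
  differences across CPUs do not masquerade as regressions; byte-identity
  is asserted between same-seed runs within a session.
* Floats are serialized with `repr` (shortest round-trip representation),
  so written datasets re-read bit-exactly.

## Known limitations

* The elongation rate is assumed constant along a transcript; pause sites
  or operon-internal promoters will show up as delay-vs-position
  nonlinearity, which the OLS flattens rather than flags (inspect
  `plot_delay_vs_position`).
* Lifetimes much longer than the sampling window (τ ≳ 15 min on the
  default 10-min grid) are reported with large uncertainty and often only
  as `lifetime_only`; extending the grid is the remedy.
* `p_cotx` uses the fitted `v` and mean lifetime of the whole transcript;
  for lifetime-inconsistent transcripts the single-`d` model is already
  wrong and the probability should be read as descriptive.
* Spike-in noise is ignored in the error model (valid for ≥10⁴ spike reads
  per species per time point).
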
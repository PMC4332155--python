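# rifdecay

Genome-wide estimation of bacterial mRNA lifetimes and RNA polymerase
elongation rates from transcription-inhibitor run-out RNA-seq time courses.

## The problem

The classic way to measure mRNA stability in bacteria is to block
transcription initiation with rifampicin and follow the decay of each
transcript by RNA-seq. Rifampicin only traps *free* polymerase: RNAPs
already elongating keep synthesizing, so a position `x` nt from a
transcript's 5′ end keeps being replenished until the last pre-drug
polymerase passes it. The observed decay curve at each position is
therefore **not** a simple exponential — it is a *delayed* exponential, flat
until the polymerase passage time and exponential afterwards. Ignoring the
delay inflates lifetime estimates; modelling it yields, from one
experiment, both

* the RNA lifetime τ (min) of each 300-nt segment, and
* the elongation rate v (nt/s) of each transcription unit, because the
  delay grows linearly with distance from the 5′ end.

`rifdecay` implements that analysis for anyone working on bacterial RNA
decay kinetics: a kinetic model of coupled transcription/translation/
degradation, a synthetic-data generator with the full statistical structure
of the experiment, the preprocessing (binning, spike-in and time-zero
normalization), the per-segment fits and elongation-rate regression with
quality filters, and the downstream classification of transcripts as co- or
post-transcriptionally degraded.

## The model

A transcription unit of length `L` is described by an initiation rate `k`
(1/min), a constant elongation rate `v` (nt/s, shared by RNAP and the
trailing ribosomes), and a degradation-initiation rate `d` (1/min) — a
single rate-limiting RNase binding at the 5′ end, after which a degradation
front trails the last ribosome at speed `v`. With initiation blocked at
t = 0, the expected relative abundance at position x is

    y(x, t) = 1                              t ≤ x/(60 v)
    y(x, t) = exp(−d (t − x/(60 v)))         t > x/(60 v)

if RNase can bind at any time after initiation (co-transcriptional
degradation). If it can bind only after the full transcript exists
(post-transcriptional), the curve is instead flat, then linear, then
exponential, and in the limit d → ∞ the 5′-end decay is exactly the linear
ramp `1 − t/(L/(60 v))`. Both closed forms are in
`rifdecay.kinetic_model`. The probability that a molecule loses its 5′ end
before its 3′ end is synthesized is

    P(co-transcriptional) = 1 − exp(−r),   r = d·L/(60 v)

the synthesis-time/lifetime ratio: r = 0.5 already gives ≈40%, and any
transcript with r > 1 exceeds 63%.

Each segment's data are fitted to `y(t) = A` for `t ≤ P`,
`y(t) = A·exp(−(t−P)/T)` for `t > P` by weighted nonlinear least squares;
the per-segment delays `P_i` are regressed against segment midpoints to
give `v = 1/(60·slope)`. Transcripts need ≥ 1,200 nt (4 complete 300-nt
bins) for a rate; fits with relative rate uncertainty above 1 or a
non-positive slope are discarded with reason codes.

## Worked example

Simulate one run-out experiment for a 6-kb operon transcribed at
21.4 nt/s with a 2.5-min lifetime, then recover both numbers:

```python
import rifdecay as rd

kin = rd.TranscriptKinetics("argCBH-like", k=1.0, v=21.4, d=0.4, L=6000)
cfg = rd.ExperimentConfig(rng_seed=1)          # 0–10 min sampling grid
ds = rd.simulate_stochastic([kin], cfg)        # molecules + Poisson reads
m = rd.matrices_from_dataset(ds)["argCBH-like"]  # normalized decay matrix
fits = rd.fit_matrix(m)                        # delayed-exponential fits
elong = rd.fit_elongation_rate(fits)
res = rd.summarize_transcript("argCBH-like", fits, kin.L, elong)
print(f"v_hat = {elong.v:.1f} +/- {elong.se:.1f} nt/s")
print(f"tau_bar = {res.tau_bar:.2f} min, ratio = {res.ratio:.2f}, "
      f"p_cotx = {res.p_cotx:.2f}")
```

prints

```
v_hat = 20.9 +/- 0.5 nt/s
tau_bar = 2.45 min, ratio = 1.95, p_cotx = 0.86
```

i.e. the elongation rate is recovered within its standard error, the mean
segment lifetime within 2%, and — because synthesizing this operon takes
about twice its lifetime — an estimated 86% of its molecules start being
degraded before they are finished (`ratio` is the synthesis-time/lifetime
ratio; `p_cotx = 1 − exp(−ratio)`).

The same pipeline runs from the shell on files (GFF3/BED12 annotation,
bedGraph or TSV coverage, spike-in TSV):

```
rifdecay run --seed 1 --out out/          # simulate + preprocess + fit + analyze
rifdecay simulate --seed 1 --out sim/     # or stage by stage
rifdecay preprocess --dataset sim/dataset.yaml --out bins/
rifdecay fit --bins bins/ --annotation sim/annotation.gff3 --out fit/
rifdecay analyze --results fit/transcripts.tsv --abundance ab.tsv --out report.json
```

Every run writes a manifest (seed, thresholds, input hashes) and an
exclusion log with reason codes.

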
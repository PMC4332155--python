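"""Synthetic rifampicin/streptolydigin run-out datasets.

Generates per-bin read-count time courses with the statistical structure the
downstream analysis assumes: stationary transcription at rate k per unit,
constant elongation at v nt/s, single rate-limiting RNase binding at rate d,
a degradation front trailing at v, Poisson sequencing noise per bin, and
non-decaying spike-in species at fixed expected totals.

Two drug scenarios are supported:

* ``initiation_inhibitor`` (rifampicin): no new initiations after t = 0,
  already-loaded polymerases run out — position-dependent decay delays.
* ``elongation_inhibitor`` (streptolydigin): elongation halts at t = 0 and
  every position decays immediately at rate d, with no delay.

``simulate_expected`` produces noise-free expectations (each bin represented
by its midpoint position, so the noiseless pipeline is an exact identity
onto the delayed-exponential fit model); ``simulate_stochastic`` draws an
event-driven realization, molecule by molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetic_model import (
    SEC_PER_MIN,
    TranscriptKinetics,
    cotranscriptional_abundance,
    steady_state_abundance,
    synthesis_time,
)

#: Post-inhibitor sampling grid (min). The study design calls for sub-minute
#: resolution early (where short-lived species decay) and sparser late points.
DEFAULT_TIME_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)

#: Spike-in species (added to lysate, not degraded in vivo) and their
#: expected total read counts per time point.
DEFAULT_SPIKE_INS = (("ssrA", 50_000.0), ("ssrS", 50_000.0), ("rnpB", 50_000.0))

SCENARIOS = ("initiation_inhibitor", "elongation_inhibitor")

_SYN_CHROM = "synchr"
_TU_GAP = 1_000  # nt between consecutive synthetic transcription units


@dataclass
class ExperimentConfig:
    """Run-out experiment design.

    depth is the expected number of reads per transcript copy per complete
    bin; 400 gives the few-percent root-N error bars typical of a deep
    bacterial RNA-seq time course.
    """

    rng_seed: int
    time_grid: tuple = DEFAULT_TIME_GRID
    scenario: str = "initiation_inhibitor"
    bin_size: int = 300
    depth: float = 400.0
    spike_ins: tuple = DEFAULT_SPIKE_INS
    inhibitor_lag: float = 0.0  # min; drug action delay (< 30 s in vivo)
    burn_in_factor: float = 10.0  # multiples of the slowest timescale
    n_cells: int = 1000  # cells pooled per lysate in the stochastic draw

    def __post_init__(self) -> None:
        tg = tuple(float(t) for t in self.time_grid)
        if len(tg) == 0 or tg[0] != 0.0 or list(tg) != sorted(tg):
            raise ValueError("time_grid must be sorted and start at 0")
        if len(set(tg)) != len(tg):
            raise ValueError("time_grid has duplicate entries")
        self.time_grid = tg
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not self.depth > 0:
            raise ValueError("depth must be > 0")
        if self.rng_seed is None:
            raise ValueError("rng_seed must be set explicitly")
        if self.inhibitor_lag < 0:
            raise ValueError("inhibitor_lag must be >= 0")
        if self.burn_in_factor < 5.0:
            raise ValueError(
                "burn-in below 5x the slowest timescale gives a non-stationary "
                f"start; got factor {self.burn_in_factor}"
            )
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class SimulatedDataset:
    """A simulated run-out dataset plus its ground truth.

    ``bin_counts[tid]`` is an (n_bins, n_times) array of reads per complete
    300-nt bin (floats for expectation-only datasets, integers for
    stochastic ones).  ``expected_rel[tid]`` holds the model's expected
    relative abundance at each bin midpoint.  ``cotx_fraction[tid]`` is the
    realized fraction of simulated molecules whose 5' end was degraded
    before synthesis completed (NaN for expectation-only datasets).
    """

    config: ExperimentConfig
    kinetics: list
    units: pd.DataFrame  # transcript_id, chrom, start, end, strand, length
    bin_starts: dict
    bin_counts: dict
    expected_rel: dict
    spike_counts: pd.DataFrame  # name, time_min, reads
    cotx_fraction: dict = field(default_factory=dict)

    @property
    def truth(self) -> pd.DataFrame:
        """Ground-truth kinetic parameters, one row per transcription unit."""
        return pd.DataFrame(
            [
                {"transcript_id": kin.transcript_id, "k": kin.k, "v": kin.v,
                 "d": kin.d, "L": kin.L}
                for kin in self.kinetics
            ]
        )

    def expected_position_abundance(self, transcript_id: str, x, t):
        """Model-expected relative abundance at arbitrary positions/times."""
        kin = next(k for k in self.kinetics if k.transcript_id == transcript_id)
        return _relative_abundance(x, t, kin, self.config)


def _layout_units(kinetics) -> pd.DataFrame:
    """Place synthetic transcription units on one chromosome, 1 kb apart,
    alternating strands (exercises 5'-end resolution downstream)."""
    rows, cursor = [], 0
    for i, kin in enumerate(kinetics):
        strand = "+" if i % 2 == 0 else "-"
        rows.append(
            {"transcript_id": kin.transcript_id, "chrom": _SYN_CHROM,
             "start": cursor, "end": cursor + kin.L, "strand": strand,
             "length": kin.L}
        )
        cursor += kin.L + _TU_GAP
    return pd.DataFrame(rows, columns=["transcript_id", "chrom", "start",
                                       "end", "strand", "length"])


def _complete_bin_starts(L: int, bin_size: int) -> np.ndarray:
    return np.arange(0, (L // bin_size) * bin_size, bin_size)


def _relative_abundance(x, t, kin: TranscriptKinetics, cfg: ExperimentConfig):
    """Expected relative abundance under the configured drug scenario."""
    t_eff = np.maximum(np.asarray(t, dtype=float) - cfg.inhibitor_lag, 0.0)
    if cfg.scenario == "initiation_inhibitor":
        return cotranscriptional_abundance(x, t_eff, kin)
    # elongation inhibitor: immediate exponential decay at every position
    out = np.exp(-kin.d * t_eff) * np.ones_like(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def simulate_expected(kinetics, cfg: ExperimentConfig) -> SimulatedDataset:
    """Noise-free expectations: bin count = depth x (k/d) x relative abundance
    evaluated at the bin midpoint.  Requires d > 0 for every transcript."""
    if not kinetics:
        raise ValueError("kinetics list is empty")
    times = np.asarray(cfg.time_grid)
    bin_starts, bin_counts, expected_rel = {}, {}, {}
    for kin in kinetics:
        ss = steady_state_abundance(kin)  # raises for d == 0
        starts = _complete_bin_starts(kin.L, cfg.bin_size)
        mids = starts + cfg.bin_size / 2.0
        rel = _relative_abundance(mids[:, None], times[None, :], kin, cfg)
        bin_starts[kin.transcript_id] = starts
        expected_rel[kin.transcript_id] = rel
        bin_counts[kin.transcript_id] = cfg.depth * ss * rel
    spikes = pd.DataFrame(
        [
            {"name": name, "time_min": t, "reads": expect}
            for name, expect in cfg.spike_ins
            for t in cfg.time_grid
        ]
    )
    return SimulatedDataset(
        config=cfg, kinetics=list(kinetics), units=_layout_units(kinetics),
        bin_starts=bin_starts, bin_counts=bin_counts, expected_rel=expected_rel,
        spike_counts=spikes,
        cotx_fraction={k.transcript_id: math.nan for k in kinetics},
    )


def _simulate_molecules(kin: TranscriptKinetics, cfg: ExperimentConfig,
                        rng: np.random.Generator):
    """Draw initiation times and RNase binding offsets for one unit, pooled
    over ``cfg.n_cells`` cells (total initiation rate k x n_cells, as in a
    bulk lysate where molecule-number fluctuations of single cells average
    out and sequencing shot noise dominates).

    Returns (t0, E, n_total, n_cotx): initiation times on
    (-burn_in, inhibitor_lag], Exponential(d) binding offsets from
    initiation, the number of molecules drawn, and how many of them had
    their 5' end bound before synthesis completed (E < synthesis time).
    Molecules already fully degraded at t = 0 (t0 + E + S < 0) are dropped
    from the returned arrays — they contribute no coverage at any sampled
    time — but are counted in n_total/n_cotx.
    """
    S = synthesis_time(kin)
    timescale = S if kin.d == 0 else max(S, 1.0 / kin.d)
    burn_in = cfg.burn_in_factor * timescale
    window = burn_in + cfg.inhibitor_lag
    n = rng.poisson(kin.k * cfg.n_cells * window)
    t0 = cfg.inhibitor_lag - rng.uniform(0.0, window, n)
    E = rng.exponential(1.0 / kin.d, n) if kin.d > 0 else np.full(n, np.inf)
    n_cotx = int(np.sum(E < S))
    visible = t0 + E + S >= 0.0
    return t0[visible], E[visible], n, n_cotx


def _bin_coverage(lo: np.ndarray, hi: np.ndarray, starts: np.ndarray,
                  bin_size: int) -> np.ndarray:
    """Mean molecule coverage per bin: sum over molecules of the overlap of
    (lo, hi] with each bin, divided by bin width."""
    b0 = starts[:, None]
    b1 = b0 + bin_size
    ov = np.clip(np.minimum(hi[None, :], b1) - np.maximum(lo[None, :], b0),
                 0.0, None)
    return ov.sum(axis=1) / bin_size


def simulate_stochastic(kinetics, cfg: ExperimentConfig) -> SimulatedDataset:
    """Event-driven realization of the run-out experiment.

    Per molecule initiated at t0: position x exists from ``t0 + x/(60 v)``
    until ``x/(60 v)`` after the RNase bound at ``t0 + E``, E ~ Exp(d)
    (binding may precede completion — co-transcriptional degradation).
    Under the elongation inhibitor, synthesis and the degradation front halt
    at t = 0 and each surviving molecule is removed after a fresh Exp(d)
    wait (memorylessness of the binding step).  Molecules are pooled over
    ``cfg.n_cells`` cells, as in a bulk lysate.  Per-bin counts are Poisson
    with mean depth x (molecule coverage averaged over bin positions, per
    cell); spike-ins are Poisson at their configured expectations at every
    time.  Fully reproducible under ``cfg.rng_seed``.
    """
    if not kinetics:
        raise ValueError("kinetics list is empty")
    rng = np.random.default_rng(cfg.rng_seed)
    times = np.asarray(cfg.time_grid)
    lag = cfg.inhibitor_lag
    bin_starts, bin_counts, expected_rel, cotx_fraction = {}, {}, {}, {}
    for kin in kinetics:
        nt_per_min = SEC_PER_MIN * kin.v
        starts = _complete_bin_starts(kin.L, cfg.bin_size)
        mids = starts + cfg.bin_size / 2.0
        t0, E, n_total, n_cotx = _simulate_molecules(kin, cfg, rng)
        cotx_fraction[kin.transcript_id] = (
            n_cotx / n_total if n_total else math.nan
        )
        mean = np.empty((len(starts), len(times)))
        if cfg.scenario == "initiation_inhibitor":
            for j, t in enumerate(times):
                hi = np.clip(nt_per_min * (t - t0), 0.0, kin.L)
                lo = np.clip(nt_per_min * (t - t0 - E), 0.0, kin.L)
                mean[:, j] = _bin_coverage(lo, hi, starts, cfg.bin_size)
        else:
            # synthesis/front halt at t = lag; fresh Exp(d) removal after
            hi0 = np.clip(nt_per_min * (lag - t0), 0.0, kin.L)
            lo0 = np.clip(nt_per_min * (lag - t0 - E), 0.0, kin.L)
            removal = lag + (
                rng.exponential(1.0 / kin.d, len(t0)) if kin.d > 0
                else np.full(len(t0), np.inf)
            )
            for j, t in enumerate(times):
                if t <= lag:
                    hi = np.clip(nt_per_min * (t - t0), 0.0, kin.L)
                    lo = np.clip(nt_per_min * (t - t0 - E), 0.0, kin.L)
                else:
                    alive = removal > t
                    hi, lo = hi0[alive], lo0[alive]
                mean[:, j] = _bin_coverage(lo, hi, starts, cfg.bin_size)
        bin_starts[kin.transcript_id] = starts
        bin_counts[kin.transcript_id] = rng.poisson(
            cfg.depth * mean / cfg.n_cells
        )
        expected_rel[kin.transcript_id] = _relative_abundance(
            mids[:, None], times[None, :], kin, cfg
        )
    spikes = pd.DataFrame(
        [
            {"name": name, "time_min": t,
             "reads": int(rng.poisson(expect))}
            for name, expect in cfg.spike_ins
            for t in cfg.time_grid
        ]
    )
    return SimulatedDataset(
        config=cfg, kinetics=list(kinetics), units=_layout_units(kinetics),
        bin_starts=bin_starts, bin_counts=bin_counts, expected_rel=expected_rel,
        spike_counts=spikes, cotx_fraction=cotx_fraction,
    )


# ---------------------------------------------------------------------------
# default synthetic genome
# ---------------------------------------------------------------------------

def generate_genome(n_transcripts: int = 50, rng_seed: int = 0,
                    length_range=(600, 15_000), v_mean: float = 25.0,
                    v_sd: float = 14.0, v_bounds=(5.0, 80.0),
                    tau_mean: float = 2.5, tau_cv: float = 1.0,
                    k_range=(0.2, 2.0)) -> list:
    """Draw a plausible bacterial transcription-unit population.

    Defaults emulate the measured exponential-phase population: lifetimes
    lognormal with mean 2.5 min and CV 1, elongation rates a truncated
    normal (25, 14) nt/s, lengths uniform 600-15,000 nt, and weak promoters
    (k ~ loguniform 0.2-2 events/min, i.e. on the order of one engaged
    polymerase per unit).
    """
    rng = np.random.default_rng(rng_seed)
    sigma2 = math.log(1.0 + tau_cv**2)
    mu = math.log(tau_mean) - sigma2 / 2.0
    kins = []
    for i in range(n_transcripts):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        v = float(np.clip(rng.normal(v_mean, v_sd), *v_bounds))
        tau = float(rng.lognormal(mu, math.sqrt(sigma2)))
        k = float(np.exp(rng.uniform(math.log(k_range[0]),
                                     math.log(k_range[1]))))
        kins.append(TranscriptKinetics(f"tu{i:03d}", k=k, v=v, d=1.0 / tau, L=L))
    return kins


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_dataset(ds: SimulatedDataset, out_dir, counts_format: str = "bedgraph"):
    """Write a dataset as plain-text files consumable by :mod:`rifdecay.preprocess`.

    Emits annotation as GFF3 and BED12, one coverage file per time point
    (bedGraph with one interval per complete bin, value = per-position
    coverage density = bin count / bin size; or a per-position TSV), a
    spike-in table, the ground-truth kinetics, and a ``dataset.yaml``
    manifest mapping time points to files.  Floats are written with
    ``repr`` so read-back is bit-exact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if counts_format not in ("bedgraph", "tsv"):
        raise ValueError("counts_format must be 'bedgraph' or 'tsv'")

    units = ds.units.set_index("transcript_id")
    write_annotation_gff3(ds.units, out / "annotation.gff3")
    write_annotation_bed12(ds.units, out / "annotation.bed")

    count_files = []
    for j, t in enumerate(ds.config.time_grid):
        suffix = "bedgraph" if counts_format == "bedgraph" else "tsv"
        fname = f"counts_t{j:02d}.{suffix}"
        count_files.append(fname)
        with open(out / fname, "w") as fh:
            if counts_format == "tsv":
                fh.write("transcript_id\tposition\tcount\n")
            for kin in ds.kinetics:
                tid = kin.transcript_id
                starts = ds.bin_starts[tid]
                counts = ds.bin_counts[tid][:, j]
                u = units.loc[tid]
                bs = ds.config.bin_size
                for s, c in zip(starts, counts):
                    dens = float(c) / bs
                    if counts_format == "bedgraph":
                        if u.strand == "+":
                            g0, g1 = u.start + s, u.start + s + bs
                        else:
                            g0, g1 = u.end - s - bs, u.end - s
                        fh.write(f"{u.chrom}\t{g0}\t{g1}\t{dens!r}\n")
                    else:
                        for pos in range(int(s), int(s) + bs):
                            fh.write(f"{tid}\t{pos}\t{dens!r}\n")

    ds.spike_counts.to_csv(out / "spikes.tsv", sep="\t", index=False)
    ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest = {
        "scenario": ds.config.scenario,
        "bin_size": ds.config.bin_size,
        "depth": ds.config.depth,
        "rng_seed": ds.config.rng_seed,
        "annotation": "annotation.gff3",
        "spikes": "spikes.tsv",
        "truth": "truth.tsv",
        "time_grid": [float(t) for t in ds.config.time_grid],
        "counts_format": counts_format,
        "counts_files": count_files,
    }
    with open(out / "dataset.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out / "dataset.yaml"


def write_annotation_gff3(units: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for u in units.itertuples():
            fh.write(
                f"{u.chrom}\trifdecay\ttranscription_unit\t{u.start + 1}\t"
                f"{u.end}\t.\t{u.strand}\t.\tID={u.transcript_id}\n"
            )


def write_annotation_bed12(units: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for u in units.itertuples():
            L = u.end - u.start
            fh.write(
                f"{u.chrom}\t{u.start}\t{u.end}\t{u.transcript_id}\t0\t"
                f"{u.strand}\t{u.start}\t{u.end}\t0\t1\t{L},\t0,\n"
            )
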
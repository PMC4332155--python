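"""From per-position coverage + annotation to normalized decay matrices.

Pipeline per transcription unit (TU): map coverage to 5'-relative
coordinates, sum into complete 300-nt bins anchored at the 5' end (trailing
partial bin dropped), rescale each time point by the mean of the spike-in
species' total reads (relative to t = 0), then divide each bin's series by
its t = 0 value.  Uncertainties are propagated as root-N shot noise on the
raw counts through both normalizations.

Coordinates: bins are indexed in nt from the TU's 5' end (strand-resolved),
0-based half-open ``[start, start + bin_size)``.  TUs whose genomic spans
overlap any other annotated TU are excluded (strand-blind by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("rifdecay")

UNIT_COLUMNS = ["transcript_id", "chrom", "start", "end", "strand", "length"]


@dataclass
class BinnedDecayMatrix:
    """Normalized relative-abundance decay surface for one transcription unit.

    ``normalized[i, j]`` is the relative abundance of bin ``bin_starts[i]``
    at ``time_grid[j]``; the t = 0 column is exactly 1 for every retained
    bin.  ``sigma`` carries the propagated root-N uncertainty (strictly
    positive wherever defined).
    """

    transcript_id: str
    bin_starts: np.ndarray  # nt from 5' end, 0-based half-open bins
    time_grid: np.ndarray  # min
    raw_counts: np.ndarray  # (n_bins, n_times)
    normalized: np.ndarray  # (n_bins, n_times), t=0 column == 1
    sigma: np.ndarray  # (n_bins, n_times)

    @property
    def n_bins(self) -> int:
        return len(self.bin_starts)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def load_annotation(path) -> pd.DataFrame:
    """Parse transcription units from GFF3 or BED (12 or 6 column).

    Returns a frame with ``transcript_id, chrom, start, end, strand,
    length``; ``start``/``end`` are 0-based half-open genomic coordinates.
    Positions downstream are always reported relative to the 5' end, which
    for a minus-strand unit is the genomic right edge.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12", ".bed6"):
        units = _load_bed(path)
    else:
        units = _load_gff3(path)
    if (units["length"] <= 0).any():
        bad = units.loc[units["length"] <= 0, "transcript_id"].tolist()
        raise ValueError(f"zero-length annotation features: {bad}")
    if units["transcript_id"].duplicated().any():
        raise ValueError("duplicate transcript_id in annotation")
    return units.reset_index(drop=True)


def _load_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 record")
            chrom, _src, _type, start, end, _score, strand, _frame, attrs = parts
            tid = None
            for kv in attrs.split(";"):
                key, _, val = kv.strip().partition("=")
                if key in ("ID", "Name") and tid is None:
                    tid = val
            if tid is None:
                raise ValueError(f"{path}:{lineno}: record lacks ID attribute")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be + or -")
            start0, end0 = int(start) - 1, int(end)  # GFF3 is 1-based inclusive
            rows.append((tid, chrom, start0, end0, strand, end0 - start0))
    return pd.DataFrame(rows, columns=UNIT_COLUMNS)


def _load_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED needs >= 6 columns")
            chrom, start, end, tid, _score, strand = parts[:6]
            start0, end0 = int(start), int(end)
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be + or -")
            rows.append((tid, chrom, start0, end0, strand, end0 - start0))
    return pd.DataFrame(rows, columns=UNIT_COLUMNS)


def exclude_overlapping(units: pd.DataFrame,
                        same_strand_only: bool = False) -> pd.DataFrame:
    """Drop every unit whose genomic span intersects another unit's span.

    Both members of an overlapping pair are removed (conservative reading:
    such regions cannot be attributed to a single unit).  By default
    overlap is strand-blind; ``same_strand_only`` restricts the test to
    units on the same strand.
    """
    drop = set()
    group_cols = ["chrom", "strand"] if same_strand_only else ["chrom"]
    for _, grp in units.groupby(group_cols):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        ids = g["transcript_id"].to_numpy()
        hi = -np.inf
        hi_idx = None
        for i in range(len(g)):
            if starts[i] < hi:  # overlaps some earlier, still-open unit
                drop.add(ids[i])
                drop.add(ids[hi_idx])
            if ends[i] > hi:
                hi, hi_idx = ends[i], i
    if drop:
        logger.info("excluded %d overlapping units: %s", len(drop),
                    ",".join(sorted(drop)))
    return units[~units["transcript_id"].isin(drop)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# coverage readers
# ---------------------------------------------------------------------------

def load_counts_tsv(path) -> pd.DataFrame:
    """Per-position counts: columns transcript_id, position (nt from the 5'
    end, 0-based), count."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "position", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df


def load_counts_bedgraph(path) -> pd.DataFrame:
    """bedGraph coverage: chrom, start, end (0-based half-open), value
    (reads per position)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    df = df[~df["chrom"].str.startswith(("track", "browser", "#"))]
    df = df.astype({"start": int, "end": int, "value": float})
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: empty or inverted bedGraph interval")
    return df


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_counts(positions: np.ndarray, counts: np.ndarray, length: int,
               bin_size: int = 300) -> np.ndarray:
    """Sum per-position counts into complete 5'-anchored bins.

    Positions are nt from the 5' end, 0-based; bins are half-open
    ``[j*bin_size, (j+1)*bin_size)``.  The trailing partial bin (< bin_size
    nt) is dropped, so a 1,200-nt unit yields exactly 4 bins.
    """
    n_bins = length // bin_size
    out = np.zeros(n_bins)
    positions = np.asarray(positions)
    counts = np.asarray(counts, dtype=float)
    idx = positions // bin_size
    keep = (positions >= 0) & (idx < n_bins)
    np.add.at(out, idx[keep].astype(int), counts[keep])
    return out


def bin_intervals(rel_start: np.ndarray, rel_end: np.ndarray,
                  value: np.ndarray, length: int,
                  bin_size: int = 300) -> np.ndarray:
    """Sum interval coverage (value = reads per position over
    [rel_start, rel_end)) into complete 5'-anchored bins."""
    n_bins = length // bin_size
    b0 = np.arange(n_bins) * bin_size
    ov = np.clip(
        np.minimum(np.asarray(rel_end)[None, :], (b0 + bin_size)[:, None])
        - np.maximum(np.asarray(rel_start)[None, :], b0[:, None]),
        0, None,
    )
    return ov @ np.asarray(value, dtype=float)


def _to_relative(unit, g_start: np.ndarray, g_end: np.ndarray):
    """Genomic half-open interval -> 5'-relative half-open interval."""
    if unit.strand == "+":
        return g_start - unit.start, g_end - unit.start
    return unit.end - g_end, unit.end - g_start


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def spike_scale_factors(spikes: pd.DataFrame, time_grid) -> np.ndarray:
    """Per-time-point scale factor: mean over spike-in species of that
    species' total reads, divided by the same mean at t = 0.

    Counts are later divided by this factor, so t = 0 is unchanged and a
    time point whose spike totals halved has its counts doubled.
    """
    totals = spikes.groupby(["name", "time_min"])["reads"].sum().unstack()
    missing = [t for t in time_grid if t not in totals.columns]
    if missing:
        raise ValueError(f"spike-in table lacks time points {missing}")
    totals = totals[list(time_grid)]
    if (totals <= 0).any().any():
        bad = totals.columns[(totals <= 0).any(axis=0)].tolist()
        raise ValueError(
            f"spike-in species with zero total reads at time(s) {bad}; "
            "cannot normalize"
        )
    factor = totals.mean(axis=0).to_numpy()
    return factor / factor[0]


def spike_normalize(binned: np.ndarray, spikes: pd.DataFrame,
                    time_grid) -> np.ndarray:
    """Rescale a (n_bins, n_times) count matrix by the spike-in factors."""
    return binned / spike_scale_factors(spikes, time_grid)[None, :]


def relative_abundance(transcript_id: str, bin_starts: np.ndarray,
                       raw: np.ndarray, scaled: np.ndarray, time_grid,
                       min_t0_count: float = 20.0) -> BinnedDecayMatrix:
    """Divide each bin's spike-scaled series by its t = 0 value.

    Bins whose raw t = 0 count is below ``min_t0_count`` are dropped (the
    division is unstable); drops are logged.  Uncertainty per cell combines
    the shot noise of the cell's raw count and of its t = 0 reference:
    sigma^2 = (s_t / n_0')^2 * max(n_t, 1) + rel^2 / n_0, with s_t the
    spike rescaling applied at that time (spike totals are large, their
    noise is neglected).
    """
    raw = np.asarray(raw, dtype=float)
    scaled = np.asarray(scaled, dtype=float)
    time_grid = np.asarray(time_grid, dtype=float)
    keep = raw[:, 0] >= min_t0_count
    if not keep.all():
        dropped = np.asarray(bin_starts)[~keep]
        logger.warning(
            "%s: dropped %d bin(s) with t=0 count < %g (bin starts %s)",
            transcript_id, int((~keep).sum()), min_t0_count, dropped.tolist(),
        )
    raw, scaled = raw[keep], scaled[keep]
    bin_starts = np.asarray(bin_starts)[keep]
    rel = scaled / scaled[:, [0]]
    # per-time spike rescaling factor, recovered from any nonzero cell
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(raw > 0, scaled / np.where(raw > 0, raw, 1.0), np.nan)
    if raw.size:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-zero column
            s_t = np.nanmedian(ratio, axis=0)
        s_t = np.where(np.isnan(s_t), 1.0, s_t)
    else:
        s_t = np.ones(len(time_grid))
    var = (s_t[None, :] / scaled[:, [0]]) ** 2 * np.maximum(raw, 1.0) \
        + rel**2 / raw[:, [0]]
    return BinnedDecayMatrix(
        transcript_id=transcript_id, bin_starts=bin_starts,
        time_grid=time_grid, raw_counts=raw, normalized=rel,
        sigma=np.sqrt(var),
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_matrices(units: pd.DataFrame, binned_raw: dict, spikes: pd.DataFrame,
                   time_grid, min_t0_count: float = 20.0,
                   bin_size: int = 300) -> dict:
    """Normalize per-unit raw binned counts into decay matrices."""
    factors = spike_scale_factors(spikes, time_grid)
    out = {}
    for tid, raw in binned_raw.items():
        raw = np.asarray(raw, dtype=float)
        length = int(units.set_index("transcript_id").loc[tid, "length"])
        starts = np.arange(0, (length // bin_size) * bin_size, bin_size)
        scaled = raw / factors[None, :]
        out[tid] = relative_abundance(tid, starts, raw, scaled, time_grid,
                                      min_t0_count=min_t0_count)
    return out


def preprocess_dataset(dataset_manifest, bin_size: int | None = None,
                       min_t0_count: float = 20.0,
                       same_strand_only: bool = False) -> dict:
    """File-based pipeline: read a ``dataset.yaml`` manifest written by
    :func:`rifdecay.synthetic_data.write_dataset` (or hand-assembled with the
    same keys) and return {transcript_id: BinnedDecayMatrix}."""
    manifest_path = Path(dataset_manifest)
    with open(manifest_path) as fh:
        man = yaml.safe_load(fh)
    base = manifest_path.parent
    bin_size = int(bin_size or man.get("bin_size", 300))
    time_grid = [float(t) for t in man["time_grid"]]

    units = exclude_overlapping(
        load_annotation(base / man["annotation"]),
        same_strand_only=same_strand_only,
    )
    spikes = pd.read_csv(base / man["spikes"], sep="\t")

    binned = {
        u.transcript_id: np.zeros((u.length // bin_size, len(time_grid)))
        for u in units.itertuples() if u.length >= bin_size
    }
    fmt = man.get("counts_format", "bedgraph")
    for j, fname in enumerate(man["counts_files"]):
        path = base / fname
        if fmt == "tsv":
            df = load_counts_tsv(path)
            for tid, grp in df.groupby("transcript_id"):
                if tid not in binned:
                    continue
                length = binned[tid].shape[0] * bin_size
                binned[tid][:, j] = bin_counts(
                    grp["position"].to_numpy(), grp["count"].to_numpy(),
                    length, bin_size,
                )
        else:
            df = load_counts_bedgraph(path)
            for u in units.itertuples():
                if u.transcript_id not in binned:
                    continue
                sel = df[(df["chrom"] == u.chrom) & (df["end"] > u.start)
                         & (df["start"] < u.end)]
                if sel.empty:
                    continue
                r0, r1 = _to_relative(u, sel["start"].to_numpy(),
                                      sel["end"].to_numpy())
                binned[u.transcript_id][:, j] = bin_intervals(
                    r0, r1, sel["value"].to_numpy(), u.length, bin_size,
                )
    return build_matrices(units, binned, spikes, time_grid,
                          min_t0_count=min_t0_count, bin_size=bin_size)


def matrices_from_dataset(ds, min_t0_count: float = 20.0) -> dict:
    """In-memory shortcut: normalize a SimulatedDataset's bin counts without
    the file round trip (identical arithmetic to the file path)."""
    binned = {tid: np.asarray(c, dtype=float)
              for tid, c in ds.bin_counts.items()}
    return build_matrices(ds.units, binned, ds.spike_counts,
                          ds.config.time_grid, min_t0_count=min_t0_count,
                          bin_size=ds.config.bin_size)


def write_matrices(matrices: dict, out_dir) -> None:
    """One TSV per unit: bin_start, one ``t_<min>`` column per time point,
    and matching ``se_<min>`` uncertainty columns."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tid, m in matrices.items():
        df = pd.DataFrame({"bin_start": m.bin_starts})
        for j, t in enumerate(m.time_grid):
            df[f"t_{t:g}"] = m.normalized[:, j]
        for j, t in enumerate(m.time_grid):
            df[f"se_{t:g}"] = m.sigma[:, j]
        for j, t in enumerate(m.time_grid):
            df[f"raw_{t:g}"] = m.raw_counts[:, j]
        df.to_csv(out / f"bins_{tid}.tsv", sep="\t", index=False)


def read_matrices(in_dir) -> dict:
    """Inverse of :func:`write_matrices`."""
    out = {}
    for path in sorted(Path(in_dir).glob("bins_*.tsv")):
        tid = path.stem[len("bins_"):]
        df = pd.read_csv(path, sep="\t")
        tcols = [c for c in df.columns if c.startswith("t_")]
        times = np.array([float(c[2:]) for c in tcols])
        order = np.argsort(times)
        times = times[order]
        norm = df[tcols].to_numpy()[:, order]
        sig = df[[f"se_{t:g}" for t in times]].to_numpy()
        raw = df[[f"raw_{t:g}" for t in times]].to_numpy()
        out[tid] = BinnedDecayMatrix(
            transcript_id=tid, bin_starts=df["bin_start"].to_numpy(),
            time_grid=times, raw_counts=raw, normalized=norm, sigma=sig,
        )
    return out
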
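"""Downstream analysis: synthesis-rate back-calculation, abundance-rate
correlations, co-transcriptional classification, condition comparison and
the genome-averaged decay profile."""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .kinetic_model import p_from_ratio


@dataclass
class ConditionSummary:
    """Population summary of one growth/drug condition."""

    label: str
    n_transcripts: int
    lifetime_mean: float  # min
    lifetime_sd: float
    elongation_mean: float  # nt/s
    elongation_sd: float
    n_elongation: int
    fraction_ratio_gt1: float  # synthesis time exceeds 5'-end lifetime
    r2_synthesis: float  # log abundance ~ log synthesis rate
    r2_degradation: float  # log abundance ~ log degradation rate


def back_calculate_synthesis(results: pd.DataFrame,
                             abundance: pd.Series) -> pd.Series:
    """Per-transcript synthesis-rate estimate k_hat = steady-state abundance
    / mean lifetime (abundance units per min).

    ``results`` needs columns transcript_id and tau_bar; ``abundance`` is
    indexed by transcript_id (steady-state / t = 0 abundance, any
    proportional unit).
    """
    tau = results.set_index("transcript_id")["tau_bar"]
    common = tau.index.intersection(abundance.index)
    return (abundance.loc[common] / tau.loc[common]).rename("k_hat")


def abundance_correlations(abundance: pd.Series, k_hat: pd.Series,
                           tau_bar: pd.Series,
                           log_scale: bool = True) -> tuple[float, float]:
    """R^2 of (log) abundance against (log) synthesis rate and against
    (log) degradation rate 1/tau.  Returns (r2_synthesis, r2_degradation).
    Invariant to rescaling the abundance units."""
    common = abundance.index.intersection(k_hat.index) \
                            .intersection(tau_bar.index)
    if len(common) < 2:
        raise ValueError("need at least 2 transcripts for a correlation")
    a = abundance.loc[common].to_numpy(dtype=float)
    k = k_hat.loc[common].to_numpy(dtype=float)
    deg = 1.0 / tau_bar.loc[common].to_numpy(dtype=float)
    ok = (a > 0) & (k > 0) & (deg > 0) & np.isfinite(a * k * deg)
    a, k, deg = a[ok], k[ok], deg[ok]
    if len(a) < 2:
        raise ValueError("fewer than 2 transcripts with positive finite values")
    if log_scale:
        a, k, deg = np.log(a), np.log(k), np.log(deg)

    def r2(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return 0.0
        return float(stats.linregress(x, y).rvalue ** 2)

    return r2(k, a), r2(deg, a)


def classify_cotranscriptional(results: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Flag transcripts whose synthesis time exceeds the 5'-end lifetime.

    Returns a table (transcript_id, ratio, cotranscriptional flag, p_cotx =
    1 - exp(-ratio)) over transcripts with a measured rate, plus the
    population fraction with ratio > 1.  Empty input gives an empty table
    and NaN fraction.
    """
    cols = ["transcript_id", "ratio", "cotranscriptional", "p_cotx"]
    measured = results[np.isfinite(results.get("ratio",
                                               pd.Series(dtype=float)))] \
        if len(results) else results
    if len(measured) == 0:
        return pd.DataFrame(columns=cols), math.nan
    table = pd.DataFrame({
        "transcript_id": measured["transcript_id"].to_numpy(),
        "ratio": measured["ratio"].to_numpy(dtype=float),
    })
    table["cotranscriptional"] = table["ratio"] > 1.0
    table["p_cotx"] = p_from_ratio(table["ratio"].to_numpy())
    return table[cols], float(table["cotranscriptional"].mean())


def summarize_condition(label: str, results: pd.DataFrame,
                        abundance: pd.Series) -> ConditionSummary:
    """Build the population summary used for condition comparisons."""
    tau = results["tau_bar"].to_numpy(dtype=float)
    tau = tau[np.isfinite(tau)]
    v = results["v_hat"].to_numpy(dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    _, frac = classify_cotranscriptional(results)
    k_hat = back_calculate_synthesis(results, abundance)
    r2s, r2d = abundance_correlations(
        abundance, k_hat, results.set_index("transcript_id")["tau_bar"])
    return ConditionSummary(
        label=label, n_transcripts=len(tau),
        lifetime_mean=float(np.mean(tau)), lifetime_sd=float(np.std(tau)),
        elongation_mean=float(np.mean(v)) if v.size else math.nan,
        elongation_sd=float(np.std(v)) if v.size else math.nan,
        n_elongation=int(v.size), fraction_ratio_gt1=frac,
        r2_synthesis=r2s, r2_degradation=r2d,
    )


def compare_conditions(a: ConditionSummary, b: ConditionSummary) -> dict:
    """Side-by-side report of two conditions, including the coefficient of
    variation of lifetimes (narrower CV = more uniform stability)."""
    if not isinstance(a, ConditionSummary) or not isinstance(b, ConditionSummary):
        raise TypeError("compare_conditions expects two ConditionSummary")
    da, db = asdict(a), asdict(b)
    report = {"conditions": [a.label, b.label], "a": da, "b": db,
              "difference": {}}
    for key in da:
        if key == "label":
            continue
        if isinstance(da[key], (int, float)) and isinstance(db[key], (int, float)):
            report["difference"][key] = db[key] - da[key]
    report["lifetime_cv"] = {
        a.label: a.lifetime_sd / a.lifetime_mean if a.lifetime_mean else math.nan,
        b.label: b.lifetime_sd / b.lifetime_mean if b.lifetime_mean else math.nan,
    }
    report["lifetime_mean_ratio"] = (
        b.lifetime_mean / a.lifetime_mean if a.lifetime_mean else math.nan
    )
    return report


def genome_average_profile(matrices) -> pd.DataFrame:
    """Average relative abundance per (bin index, time) over all transcripts.

    Transcripts are aligned by their 5' ends (bin index = bin_start /
    bin_size); each cell averages the transcripts that have data at that
    bin, so trailing bins of long transcripts average over fewer units.
    Returns a DataFrame indexed by bin index with one column per time point.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no decay matrices supplied")
    time_grid = matrices[0].time_grid
    for m in matrices:
        if not np.array_equal(m.time_grid, time_grid):
            raise ValueError("matrices sampled on different time grids")
    bs = None
    for m in matrices:
        if m.n_bins >= 2:
            bs = float(np.diff(np.sort(m.bin_starts)).min())
            break
    bs = bs or 300.0
    sums, counts = {}, {}
    for m in matrices:
        for i, start in enumerate(m.bin_starts):
            idx = int(round(start / bs))
            sums[idx] = sums.get(idx, 0.0) + m.normalized[i]
            counts[idx] = counts.get(idx, 0) + 1
    index = sorted(sums)
    data = np.vstack([sums[i] / counts[i] for i in index])
    return pd.DataFrame(data, index=pd.Index(index, name="bin_index"),
                        columns=[f"t_{t:g}" for t in time_grid])


# ---------------------------------------------------------------------------
# basic figures
# ---------------------------------------------------------------------------

def plot_decay(matrix, fits=None, ax=None):
    """Decay curves of one transcript's bins (log ordinate), optionally with
    the fitted delayed exponentials overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = matrix.time_grid
    for i, start in enumerate(matrix.bin_starts):
        line, = ax.plot(t, matrix.normalized[i], "o",
                        label=f"bin {int(start)}")
        if fits is not None:
            f = fits[i]
            tt = np.linspace(0, t[-1], 200)
            yy = f.A * np.exp(-np.maximum(tt - f.P, 0.0) / f.T)
            ax.plot(tt, yy, "-", color=line.get_color(), alpha=0.6)
    ax.set_yscale("log")
    ax.set_xlabel("time after inhibitor (min)")
    ax.set_ylabel("relative abundance")
    ax.set_title(matrix.transcript_id)
    ax.legend(fontsize="small")
    return ax


def plot_delay_vs_position(fits, elong=None, bin_size: int = 300, ax=None):
    """Segment delay against bin midpoint with the linear elongation fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.array([f.bin_start + bin_size / 2 for f in fits])
    P = np.array([f.P for f in fits])
    ax.errorbar(x, P, yerr=[f.se_P for f in fits], fmt="o")
    if elong is not None:
        xx = np.linspace(0, x.max() * 1.05, 50)
        ax.plot(xx, elong.intercept + elong.slope * xx, "-",
                label=f"v = {elong.v:.1f} nt/s")
        ax.legend()
    ax.set_xlabel("position from 5' end (nt)")
    ax.set_ylabel("delay P (min)")
    return ax
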
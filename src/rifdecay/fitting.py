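"""Delayed-exponential segment fits and per-transcript elongation rates.

Each 300-nt segment's relative abundance y(t) is fitted by weighted
nonlinear least squares to the run-out model

    y(t) = A                      for t <= P
    y(t) = A exp(-(t - P) / T)    for t >  P

where P (min) is the polymerase passage time — the moment the last
pre-inhibitor polymerase cleared the segment — and T (min) the exponential
lifetime of the segment.  The plateau amplitude A is fitted (initialized at
1) to absorb normalization noise.

Delays P_i are then regressed linearly against segment midpoint positions;
the slope (min/nt) is the reciprocal elongation rate, v = 1/(60 slope) nt/s.
Only transcripts of >= 1,200 nt (>= 4 complete bins) are eligible.  Quality
filters discard transcripts with relative rate uncertainty above 1
(se(v)/v > 1) or a non-positive fitted rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .kinetic_model import SEC_PER_MIN, p_from_ratio
from .preprocess import BinnedDecayMatrix

logger = logging.getLogger("rifdecay")

QC_OK = "ok"
QC_LIFETIME_ONLY = "lifetime_only"  # < 4 usable bins: no elongation rate
QC_NONSENSICAL = "nonsensical_rate"  # non-positive fitted rate
QC_HIGH_UNCERTAINTY = "high_uncertainty"  # se(v)/v > 1


@dataclass
class SegmentFit:
    """Delayed-exponential fit of one 300-nt segment."""

    transcript_id: str
    bin_start: float  # nt from 5' end
    P: float  # delay (min)
    T: float  # lifetime (min)
    A: float  # plateau amplitude
    se_P: float
    se_T: float
    se_A: float
    residual_norm: float
    converged: bool
    qc: str = QC_OK  # "ok" or "non_identified" (no decay within the grid)


@dataclass
class ElongationFit:
    v: float  # nt/s
    se: float  # nt/s
    slope: float  # min/nt
    slope_se: float
    intercept: float  # min (reported, unused)
    n_segments: int


@dataclass
class TranscriptResult:
    """Per-transcript summary of segment fits."""

    transcript_id: str
    v_hat: float = math.nan  # nt/s
    se_v: float = math.nan
    tau_bar: float = math.nan  # min, unweighted mean of segment lifetimes
    lifetime_consistent: bool | None = None  # consecutive segments within 2x
    synthesis_time: float = math.nan  # min, L/(60 v_hat)
    ratio: float = math.nan  # synthesis_time / tau_bar
    p_cotx: float = math.nan  # 1 - exp(-ratio)
    n_bins: int = 0
    length: int = 0
    qc_status: str = QC_OK
    discard_reasons: list = field(default_factory=list)


def _model(t, A, P, T):
    return A * np.exp(-np.maximum(t - P, 0.0) / T)


def _initial_guess(times, y):
    """P0 = first time the curve drops below 0.7; T0 from a log-linear
    regression of the points after P0.  Avoids the piecewise objective's
    local minima."""
    below = times[y < 0.7]
    P0 = float(below[0]) if below.size else float(times[-1])
    tail = (times > P0) & (y > 0)
    if tail.sum() >= 2:
        slope = stats.linregress(times[tail], np.log(y[tail])).slope
        T0 = -1.0 / slope if slope < 0 else float(times[-1])
    else:
        T0 = max(P0, float(times[-1]) / 4.0)
    T0 = min(max(T0, 1e-3), 10.0 * float(times[-1]))
    return 1.0, min(P0, float(times[-1])), T0


def fit_segment(times, y, sigma=None, transcript_id: str = "",
                bin_start: float = 0.0) -> SegmentFit:
    """Weighted NLS fit of the plateau-then-exponential model.

    Requires >= 5 time points including t = 0 with y(0) = 1.  Bounds:
    P in [0, max(times)], T > 0, A > 0.  Standard errors come from the fit
    covariance (absolute sigma).  Non-convergence is flagged, never
    silently dropped; a fit whose delay pins at the end of the grid (fewer
    than 2 points past P) is marked ``non_identified``.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if times.size < 5 or times.size < 4 + 1:
        raise ValueError("need at least 5 time points (3 parameters + 1)")
    if times[0] != 0.0:
        raise ValueError("time grid must include t = 0 as first point")
    if not math.isclose(y[0], 1.0, rel_tol=1e-6):
        raise ValueError("series must be normalized: y(0) = 1")
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("uncertainties must be positive")

    A0, P0, T0 = _initial_guess(times, y)
    tmax = float(times[-1])
    kwargs = {}
    if sigma is not None:
        kwargs = {"sigma": sigma, "absolute_sigma": True}
    try:
        popt, pcov = optimize.curve_fit(
            _model, times, y, p0=[A0, P0, T0],
            bounds=([1e-12, 0.0, 1e-9], [np.inf, tmax, np.inf]),
            maxfev=20_000, **kwargs,
        )
        converged = True
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        popt = np.array([A0, P0, T0])
        pcov = np.full((3, 3), np.nan)
        converged = False
    A, P, T = (float(p) for p in popt)
    se = np.sqrt(np.diag(pcov))
    resid = y - _model(times, *popt)
    if sigma is not None:
        resid = resid / sigma
    n_decay = int(np.sum(times > P))
    qc = QC_OK if (converged and n_decay >= 2 and P < tmax * (1 - 1e-9)) \
        else "non_identified" if converged else QC_OK
    return SegmentFit(
        transcript_id=transcript_id, bin_start=bin_start, P=P, T=T, A=A,
        se_A=float(se[0]), se_P=float(se[1]), se_T=float(se[2]),
        residual_norm=float(np.linalg.norm(resid)), converged=converged,
        qc=qc,
    )


def fit_matrix(matrix: BinnedDecayMatrix) -> list:
    """Fit every bin of a decay matrix."""
    return [
        fit_segment(matrix.time_grid, matrix.normalized[i],
                    sigma=matrix.sigma[i],
                    transcript_id=matrix.transcript_id,
                    bin_start=float(matrix.bin_starts[i]))
        for i in range(matrix.n_bins)
    ]


def _usable(fits) -> list:
    return [f for f in fits if f.converged and f.qc == QC_OK]


def fit_elongation_rate(fits, bin_size: int = 300,
                        position: str = "midpoint") -> ElongationFit | None:
    """OLS of segment delays P_i (min) against bin positions (nt).

    Returns None when fewer than 4 usable segment fits are available (the
    1,200-nt minimum-length rule).  ``position`` selects bin midpoint
    (default), start or end as the regressor.
    """
    fits = _usable(fits)
    if len(fits) < 4:
        return None
    offset = {"start": 0.0, "midpoint": bin_size / 2.0,
              "end": float(bin_size)}[position]
    x = np.array([f.bin_start + offset for f in fits])
    P = np.array([f.P for f in fits])
    res = stats.linregress(x, P)
    slope, slope_se = float(res.slope), float(res.stderr)
    if slope > 0:
        v = 1.0 / (SEC_PER_MIN * slope)
        se_v = slope_se / (SEC_PER_MIN * slope**2)
    else:
        v, se_v = (math.inf if slope == 0 else -1.0 /
                   (SEC_PER_MIN * abs(slope))), math.nan
    return ElongationFit(v=v, se=se_v, slope=slope, slope_se=slope_se,
                         intercept=float(res.intercept), n_segments=len(fits))


def summarize_transcript(transcript_id: str, fits, length: int,
                         elong: ElongationFit | None = None,
                         bin_size: int = 300) -> TranscriptResult:
    """Aggregate segment fits into a TranscriptResult.

    tau_bar is the unweighted mean of converged segment lifetimes;
    ``lifetime_consistent`` is True iff every consecutive pair of segments
    has a lifetime ratio <= 2 (None when fewer than 2 segments carry a
    lifetime).  The synthesis time, ratio and co-transcriptional
    probability use the fitted elongation rate.
    """
    res = TranscriptResult(transcript_id=transcript_id, length=length)
    with_T = [f for f in fits if f.converged and f.qc == QC_OK]
    res.n_bins = len(fits)
    if with_T:
        res.tau_bar = float(np.mean([f.T for f in with_T]))
        if len(with_T) >= 2:
            Ts = np.array([f.T for f in sorted(with_T,
                                               key=lambda f: f.bin_start)])
            ratios = np.maximum(Ts[1:], Ts[:-1]) / np.minimum(Ts[1:], Ts[:-1])
            res.lifetime_consistent = bool(np.all(ratios <= 2.0))
    if elong is None:
        res.qc_status = QC_LIFETIME_ONLY
        return res
    res.v_hat, res.se_v = elong.v, elong.se
    if elong.slope > 0 and np.isfinite(elong.v):
        res.synthesis_time = length / (SEC_PER_MIN * elong.v)
        if res.tau_bar > 0:
            res.ratio = res.synthesis_time / res.tau_bar
            res.p_cotx = p_from_ratio(res.ratio)
    return res


def apply_filters(results, max_se_ratio: float = 1.0) -> tuple[list, list]:
    """Discard transcripts with non-positive fitted rates or relative rate
    uncertainty above ``max_se_ratio``; reasons are recorded on the result
    and logged.  Idempotent: filtering the kept list again changes nothing.
    Lifetime-only transcripts (no rate measured) pass through untouched.
    """
    kept, discarded = [], []
    for r in results:
        if r.qc_status == QC_LIFETIME_ONLY:
            kept.append(r)
            continue
        reasons = []
        if not (np.isfinite(r.v_hat) and r.v_hat > 0):
            reasons.append(QC_NONSENSICAL)
        elif not np.isfinite(r.se_v) or r.se_v / r.v_hat > max_se_ratio:
            reasons.append(QC_HIGH_UNCERTAINTY)
        if reasons:
            r.qc_status = reasons[0]
            r.discard_reasons = reasons
            discarded.append(r)
            logger.info("discarding %s: %s", r.transcript_id,
                        ",".join(reasons))
        else:
            kept.append(r)
    return kept, discarded


def fit_dataset(matrices: dict, lengths: dict, bin_size: int = 300,
                min_length: int = 1200,
                max_se_ratio: float = 1.0) -> tuple[list, list, list]:
    """Fit all transcripts: returns (segment fits, kept results, discarded).

    Transcripts shorter than ``min_length`` (fewer than min_length/bin_size
    complete bins) get lifetimes but no elongation rate.
    """
    all_fits, results = [], []
    for tid in sorted(matrices):
        m = matrices[tid]
        fits = fit_matrix(m)
        all_fits.extend(fits)
        L = int(lengths[tid])
        elong = fit_elongation_rate(fits, bin_size=bin_size) \
            if L >= min_length else None
        results.append(summarize_transcript(tid, fits, L, elong,
                                            bin_size=bin_size))
    kept, discarded = apply_filters(results, max_se_ratio=max_se_ratio)
    return all_fits, kept, discarded
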
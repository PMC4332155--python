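import numpy as np
import pytest

import rifdecay as rd


@pytest.fixture
def kin():
    """A mid-sized transcript: 3 kb, 25 nt/s, 2.5 min lifetime."""
    return rd.TranscriptKinetics("tu", k=1.0, v=25.0, d=0.4, L=3000)


@pytest.fixture
def default_cfg():
    return rd.ExperimentConfig(rng_seed=1234)


def make_units(spans, chrom="chr", strand="+"):
    """Build an annotation frame from (id, start, end[, strand]) tuples."""
    import pandas as pd

    rows = []
    for span in spans:
        tid, start, end = span[:3]
        s = span[3] if len(span) > 3 else strand
        rows.append({"transcript_id": tid, "chrom": chrom, "start": start,
                     "end": end, "strand": s, "length": end - start})
    return pd.DataFrame(rows, columns=["transcript_id", "chrom", "start",
                                       "end", "strand", "length"])


def analytic_matrix(kin, time_grid=rd.DEFAULT_TIME_GRID, bin_size=300,
                    d_by_bin=None):
    """A noiseless BinnedDecayMatrix straight from the delayed-exponential
    model (optionally with a different decay rate per bin, for building
    transcripts with a lifetime step)."""
    times = np.asarray(time_grid, dtype=float)
    starts = np.arange(0, (kin.L // bin_size) * bin_size, bin_size)
    mids = starts + bin_size / 2.0
    rows = []
    for i, mid in enumerate(mids):
        d = kin.d if d_by_bin is None else d_by_bin[i]
        delay = mid / (60.0 * kin.v)
        rows.append(np.exp(-d * np.maximum(times - delay, 0.0)))
    norm = np.vstack(rows)
    raw = 1000.0 * norm
    sigma = np.sqrt(np.maximum(raw, 1.0)) / raw[:, [0]] \
        + norm * np.sqrt(1.0 / raw[:, [0]])
    return rd.BinnedDecayMatrix(
        transcript_id=kin.transcript_id, bin_starts=starts, time_grid=times,
        raw_counts=raw, normalized=norm, sigma=sigma,
    )
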
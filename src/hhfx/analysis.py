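"""Validation statistics for comparing two simulations of the same network.

The accuracy of the fixed-point/PWL machine is judged against the
double-precision reference by the statistics the field actually looks at:
interspike-interval (ISI) distributions and their histogram correlation,
per-neuron mean firing rates with a paired t-test, smoothed population
activity, and the timing jitter of the first synchronous population burst.
Everything here is a pure function of recorded spike events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .neuron import DT

__all__ = ["SpikeTrainSet", "isi_stats", "relative_isi_error",
           "population_activity", "isi_histogram_correlation",
           "mfr_compare", "peak_jitter", "and_density_trace"]


@dataclass
class SpikeTrainSet:
    """Per-neuron sorted spike times (ms) over a common duration."""

    trains: List[np.ndarray]
    duration: float
    n: int

    def __post_init__(self):
        if len(self.trains) != self.n:
            raise ValueError("need one train per neuron")

    def pooled_isis(self) -> np.ndarray:
        """All per-neuron consecutive ISIs, pooled across neurons."""
        isis = [np.diff(t) for t in self.trains if len(t) >= 2]
        return np.concatenate(isis) if isis else np.empty(0)

    def rates(self) -> np.ndarray:
        """Per-neuron firing rate in spikes/s."""
        return np.array([len(t) for t in self.trains]) / (self.duration / 1000.0)


def isi_stats(train: np.ndarray, duration: float | None = None,
              transient_frac: float = 0.1) -> Tuple[np.ndarray, float]:
    """ISIs of one spike train and their steady-state mean.

    The mean excludes intervals that end inside the initial transient (the
    first `transient_frac` of the duration; pass 0 to keep everything), so
    a tonic regime's asymptotic period is measured rather than the approach
    to it.  Fewer than two spikes give an empty result and a nan mean.
    """
    train = np.asarray(train, dtype=float)
    if len(train) < 2:
        return np.empty(0), float("nan")
    isis = np.diff(train)
    if duration is None:
        t0 = train[0] + transient_frac * (train[-1] - train[0])
    else:
        t0 = transient_frac * duration
    keep = isis[train[1:] >= t0]
    if len(keep) == 0:
        keep = isis
    return isis, float(keep.mean())


def relative_isi_error(isi_ref: float, isi_test: float) -> float:
    """|ISI_ref - ISI_test| / ISI_ref * 100 (percent)."""
    if isi_ref <= 0:
        raise ValueError("reference ISI must be positive")
    return abs(isi_ref - isi_test) / isi_ref * 100.0


def population_activity(trains: SpikeTrainSet, window: int = 128) -> np.ndarray:
    """Per-iteration population spike count smoothed by a centered boxcar.

    window is in iterations (128 iterations = 1 ms); window=1 returns the
    raw counts, whose sum is the total number of spikes.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n_iter = int(round(trains.duration / DT))
    counts = np.zeros(n_iter)
    for t in trains.trains:
        if len(t):
            its = np.clip(np.round(np.asarray(t) / DT).astype(int),
                          0, n_iter - 1)
            np.add.at(counts, its, 1.0)
    if window == 1:
        return counts
    kernel = np.ones(window) / window
    return np.convolve(counts, kernel, mode="same")


def isi_histogram_correlation(a: SpikeTrainSet, b: SpikeTrainSet,
                              bin_width: float = 0.15,
                              central_frac: float = 0.99) -> float:
    """Pearson correlation of the two binned pooled-ISI histograms.

    A common bin grid (bin_width ms) spans the range of the most probable
    ISIs: the central `central_frac` quantile range of both sets' pooled
    ISIs combined.  Degenerate (zero-variance) histograms raise ValueError.
    """
    ia, ib = a.pooled_isis(), b.pooled_isis()
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("need spikes in both train sets")
    pooled = np.concatenate([ia, ib])
    qlo = (1.0 - central_frac) / 2.0
    lo, hi = np.quantile(pooled, [qlo, 1.0 - qlo])
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 3:
        edges = np.array([lo, lo + bin_width, lo + 2 * bin_width])
    ha, _ = np.histogram(ia, bins=edges)
    hb, _ = np.histogram(ib, bins=edges)
    if ha.std() == 0 or hb.std() == 0:
        raise ValueError("degenerate (zero-variance) ISI histogram")
    return float(np.corrcoef(ha, hb)[0, 1])


def mfr_compare(a: SpikeTrainSet, b: SpikeTrainSet) -> Tuple[float, float, float]:
    """Mean firing rates of the two sets and a paired-sample t-test p-value
    over per-neuron rates.  All-zero differences (identical rates) give
    p = 1 by convention."""
    if a.n != b.n:
        raise ValueError("train sets must have the same number of neurons")
    ra, rb = a.rates(), b.rates()
    diff = ra - rb
    if np.all(diff == 0):
        p = 1.0
    else:
        p = float(stats.ttest_rel(ra, rb).pvalue)
    return float(ra.mean()), float(rb.mean()), p


def peak_jitter(act_a: np.ndarray, act_b: np.ndarray,
                prominence_frac: float = 0.5) -> float:
    """Timing difference (ms) of the first prominent population burst.

    The first burst is the first contiguous region where the activity
    reaches `prominence_frac` of its global maximum; the peak is the argmax
    inside that region, and the jitter is |t_a - t_b| with indices converted
    through dt.  Raises if either series is silent.
    """
    def first_peak(x):
        x = np.asarray(x, dtype=float)
        if x.max() <= 0:
            raise ValueError("no activity, no burst peak")
        above = x >= prominence_frac * x.max()
        start = int(np.argmax(above))
        end = start
        while end < len(x) and above[end]:
            end += 1
        return start + int(np.argmax(x[start:end]))
    return abs(first_peak(act_a) - first_peak(act_b)) * DT


def and_density_trace(result) -> Tuple[np.ndarray, float]:
    """Per-iteration maximum density of AND(spike vector, connectivity row)
    from a run recorded with record_and_density; returns (trace, max)."""
    if result.and_density is None:
        raise ValueError("run was not recorded with record_and_density")
    trace = np.asarray(result.and_density)
    return trace, float(trace.max()) if len(trace) else 0.0
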
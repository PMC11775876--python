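"""Inter-beat-interval screening and 30-s mean heart rate.

Beat series arrive as R-peak times; deviant intervals (too short or too
long relative to the local average and variance of surrounding intervals)
are interpolated when isolated or excluded when they occur in longer runs.
The exact thresholds of the original recording software are unpublished;
the rule here (|IBI - local mean| > k * local SD over a centred window of
``local_n`` intervals, excluding the interval itself) is a documented
stand-in following standard HRV artifact-screening practice.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import BeatSeries

DEFAULT_LOCAL_N = 20
DEFAULT_K = 3.0
MIN_INTERVALS_PER_WINDOW = 10


def flag_deviant_beats(
    beats: BeatSeries, local_n: int = DEFAULT_LOCAL_N, k: float = DEFAULT_K
) -> np.ndarray:
    """Boolean mask of deviant intervals (deterministic).

    Series with fewer than ``local_n + 1`` intervals fall back to global
    statistics (still excluding the interval under test).
    """
    ibi = np.asarray(beats.ibi_ms, dtype=float)
    n = len(ibi)
    deviant = np.zeros(n, dtype=bool)
    if n < 2:
        return deviant
    half = local_n // 2
    for i in range(n):
        if n <= local_n:
            neigh = np.delete(ibi, i)
        else:
            lo = max(0, i - half)
            hi = min(n, lo + local_n + 1)
            lo = max(0, hi - local_n - 1)
            neigh = np.delete(ibi[lo:hi], i - lo)
        mu = neigh.mean()
        sd = neigh.std()
        deviant[i] = abs(ibi[i] - mu) > k * sd
    return deviant


def correct_beats(
    beats: BeatSeries, flags: np.ndarray, max_interp_run: int = 3
) -> BeatSeries:
    """Interpolate isolated deviant intervals; exclude longer runs.

    Runs of up to ``max_interp_run`` consecutive deviants are replaced by
    linear interpolation between the neighbouring valid intervals; longer
    runs (and runs touching the series boundary) are marked ``excluded``.
    The number of intervals never changes.
    """
    ibi = np.asarray(beats.ibi_ms, dtype=float).copy()
    flags = np.asarray(flags, dtype=bool)
    out_flags = np.full(len(ibi), "ok", dtype=object)
    i = 0
    n = len(ibi)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flags[j + 1]:
            j += 1
        run = j - i + 1
        has_neighbors = i - 1 >= 0 and j + 1 < n
        if run <= max_interp_run and has_neighbors:
            left, right = ibi[i - 1], ibi[j + 1]
            for m in range(i, j + 1):
                frac = (m - (i - 1)) / (j + 2 - i)
                ibi[m] = left + (right - left) * frac
            out_flags[i:j + 1] = "interpolated"
        else:
            out_flags[i:j + 1] = "excluded"
        i = j + 1
    return BeatSeries(r_peak_ms=beats.r_peak_ms.copy(), ibi_ms=ibi, flags=out_flags)


def window_hr(
    beats: BeatSeries, windows: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Mean heart rate per 30-s window from the corrected interval series.

    An interval belongs to the window containing its end-beat time
    (half-open windows prevent double counting). Windows with fewer than 10
    usable (non-excluded) intervals are HR-invalid. Default heart-rate form
    is 60000 / mean(IBI); ``hr_mode='rate_mean'`` averages 60000/IBI instead.
    """
    cfg = config or RunConfig()
    wlen = cfg.window_len_s
    end_t_s = beats.r_peak_ms[1:] / 1000.0
    usable = beats.flags != "excluded"
    ibi = beats.ibi_ms

    windows = windows.copy()
    hr = np.full(len(windows), np.nan)
    valid = np.zeros(len(windows), dtype=bool)
    for row_i, (_, row) in enumerate(windows.iterrows()):
        t0 = row["start_s"]
        sel = usable & (end_t_s >= t0) & (end_t_s < t0 + wlen)
        if sel.sum() >= MIN_INTERVALS_PER_WINDOW:
            vals = ibi[sel]
            if cfg.hr_mode == "rate_mean":
                hr[row_i] = float(np.mean(60000.0 / vals))
            else:
                hr[row_i] = 60000.0 / float(np.mean(vals))
            valid[row_i] = True
    windows["mean_hr_bpm"] = hr
    windows["hr_valid"] = valid
    return windows
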
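"""Sliding-window genome composition scans and X-vs-autosome tests.

Gene density (feature starts per Mb) and TE abundance (percent of window bp
covered by merged intervals) in sliding windows, and per-autosome two-sided
Mann–Whitney U tests against the X chromosome's windows with Holm step-down
correction across comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["density_windows", "compare_chromosomes", "merge_intervals", "holm_adjust"]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values across a family of comparisons."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/abutting [start, end) intervals (n × 2 array)."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def _window_starts(chrom_length: int, window: float, step: float) -> np.ndarray:
    starts = np.arange(0, max(chrom_length - window, 0) + 1, step, dtype=float)
    if len(starts) == 0:
        starts = np.array([0.0])
    return starts


def density_windows(
    features,
    chrom_length: int,
    window: float = 1e6,
    step: float = 0.2e6,
    mode: str = "count_per_mb",
) -> pd.DataFrame:
    """Sliding-window feature density track.

    ``features`` is an (n × 2) array-like of [start, end) intervals (or a
    DataFrame with start/end columns). ``count_per_mb`` counts feature starts
    per window scaled to per-Mb; ``percent_bp`` reports the percentage of
    window bp covered by the merged intervals — invariant to how an interval
    is split into abutting pieces. The terminal window may be shorter than
    ``window``.
    """
    if step > window:
        raise ValueError("step must be <= window")
    if isinstance(features, pd.DataFrame):
        iv = features[["start", "end"]].to_numpy(np.int64)
    else:
        iv = np.asarray(features, dtype=np.int64).reshape(-1, 2)
    if len(iv) and (iv[:, 0].min() < 0 or iv[:, 1].max() > chrom_length):
        raise ValueError("features extend outside [0, chrom_length)")
    starts = _window_starts(chrom_length, window, step)
    ends = np.minimum(starts + window, chrom_length)
    if mode == "count_per_mb":
        fstarts = np.sort(iv[:, 0]) if len(iv) else np.array([], dtype=np.int64)
        counts = np.searchsorted(fstarts, ends) - np.searchsorted(fstarts, starts)
        values = counts / ((ends - starts) / 1e6)
    elif mode == "percent_bp":
        merged = merge_intervals(iv)
        ms, me = merged[:, 0], merged[:, 1]
        values = np.empty(len(starts))
        for k, (ws, we) in enumerate(zip(starts, ends)):
            cov = np.clip(np.minimum(me, we) - np.maximum(ms, ws), 0, None).sum()
            values[k] = 100.0 * cov / (we - ws)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame({"start": starts.astype(np.int64),
                         "end": ends.astype(np.int64), "value": values})


def compare_chromosomes(
    track_x: pd.DataFrame,
    autosome_tracks: dict[str, pd.DataFrame],
    min_windows: int = 10,
) -> pd.DataFrame:
    """Mann–Whitney U of X windows vs each autosome, Holm-adjusted.

    Two-sided test per autosome on the window values; the Holm step-down
    adjustment is applied across all comparisons in the call.
    """
    x_vals = track_x["value"].to_numpy(float)
    if len(x_vals) < min_windows:
        raise ValueError(f"X track has {len(x_vals)} windows; need >= {min_windows}")
    rows = []
    for chrom, track in autosome_tracks.items():
        vals = track["value"].to_numpy(float)
        if len(vals) < min_windows:
            raise ValueError(f"{chrom} track has {len(vals)} windows; need >= {min_windows}")
        u, p = stats.mannwhitneyu(x_vals, vals, alternative="two-sided")
        rows.append({"chrom": chrom, "U": float(u), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = holm_adjust(out["p_raw"])
    return out
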
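"""Genetic-map anchoring, Marey maps, recombination rates and segmentation.

Anchors transcript-derived genetic-map markers to genomic coordinates from a
12-column tabular alignment hit table (``-outfmt 6`` dialect), builds
sex-specific Marey maps (genetic position in cM against physical position in
bp) smoothed by isotonic regression, estimates windowed recombination rates
in cM/Mb, and segments each chromosome into distal recombining and
pericentromeric rarely-recombining regions.

Coordinates are 0-based half-open internally; the hit table's 1-based
inclusive subject coordinates are converted on input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "MareyMap",
    "RecombinationProfile",
    "RegionSegmentation",
    "anchor_markers",
    "build_marey_map",
    "recombination_rate",
    "segment_regions",
    "windows_in_region",
    "pseudoautosomal_boundary",
]

REGION_LABELS = ("distal_p", "pericentromeric", "distal_q")


@dataclass
class MareyMap:
    chrom: str
    sex: str
    points: pd.DataFrame  # pos, cm, cm_fit, outlier (sorted by pos)


@dataclass
class RecombinationProfile:
    chrom: str
    sex: str
    windows: pd.DataFrame  # start, end, rate, rate_filled, n_markers


@dataclass
class RegionSegmentation:
    chrom: str
    chrom_length: int
    boundaries: tuple[float, float] | None  # (distal_p end, distal_q start)

    @property
    def intervals(self) -> list[tuple[int, int, str]]:
        """Labeled intervals partitioning [0, chrom_length) exactly."""
        L = self.chrom_length
        if self.boundaries is None:
            return [(0, L, "distal_p")]
        b1, b2 = (int(round(b)) for b in self.boundaries)
        out = []
        if b1 > 0:
            out.append((0, b1, "distal_p"))
        out.append((b1, b2, "pericentromeric"))
        if b2 < L:
            out.append((b2, L, "distal_q"))
        return out

    def label_at(self, pos) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos))
        out = np.full(pos.shape, "distal_p", dtype=object)
        if self.boundaries is not None:
            b1, b2 = self.boundaries
            out[(pos >= b1) & (pos < b2)] = "pericentromeric"
            out[pos >= b2] = "distal_q"
        return out


# ---------------------------------------------------------------------------
# anchoring


def anchor_markers(
    hits: pd.DataFrame,
    min_identity: float = 97.0,
    min_length: int = 100,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Resolve each marker to one genomic position from its alignment hits.

    Hits must carry at least qseqid, sseqid, pident, length, sstart, send
    (1-based inclusive). Hits failing the strict identity/length filters are
    discarded; for each surviving marker the modal chromosome (most passing
    hits, ties broken by summed alignment length) is selected and all its
    passing hits are collapsed to the minimum start coordinate — markers are
    expressed genes whose exon hits share the gene's lowest position.

    Returns a frame with marker_id, chrom, position (0-based), n_hits_used.
    """
    if min_identity < 0 or min_length < 0:
        raise ValueError("thresholds must be >= 0")
    if hits.empty:
        return pd.DataFrame(columns=["marker_id", "chrom", "position", "n_hits_used"])
    df = hits.copy()
    df["start0"] = np.minimum(df["sstart"], df["send"]) - 1  # to 0-based
    passing = df[(df["pident"] > min_identity) & (df["length"] > min_length)]
    if chrom_lengths is not None:
        unknown = ~passing["sseqid"].isin(chrom_lengths)
        if unknown.any():
            for chrom in passing.loc[unknown, "sseqid"].unique():
                warnings.warn(f"hit references unknown chromosome {chrom!r}; skipped")
            passing = passing[~unknown]
    rows = []
    for marker, sub in passing.groupby("qseqid", sort=True):
        stats = (
            sub.groupby("sseqid")
            .agg(n=("length", "size"), total_len=("length", "sum"))
            .sort_values(["n", "total_len"], ascending=False)
        )
        chrom = stats.index[0]
        chosen = sub[sub["sseqid"] == chrom]
        rows.append(
            {
                "marker_id": marker,
                "chrom": chrom,
                "position": int(chosen["start0"].min()),
                "n_hits_used": int(len(chosen)),
            }
        )
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "position", "n_hits_used"])


# ---------------------------------------------------------------------------
# Marey map


def build_marey_map(
    anchors: pd.DataFrame,
    markers: pd.DataFrame,
    sex: str = "female",
    chrom: str | None = None,
    outlier_threshold: float = 5.0,
) -> MareyMap:
    """Join anchors with map positions and fit a monotone Marey map.

    The smoothed genetic position is the least-squares monotone (isotonic)
    regression of cM on bp. Markers whose raw cM deviates from the fit by
    more than ``outlier_threshold`` cM are flagged, not removed.
    """
    cm_col = f"cm_{sex}"
    if cm_col not in markers.columns:
        raise ValueError(f"markers table lacks column {cm_col!r}")
    merged = anchors.merge(markers, on="marker_id", how="inner")
    merged = merged[merged[cm_col].notna()]
    if chrom is None:
        if merged["chrom"].nunique() > 1:
            raise ValueError("multiple chromosomes present; pass chrom=")
        chrom = merged["chrom"].iloc[0] if len(merged) else "NA"
    merged = merged[merged["chrom"] == chrom]
    if len(merged) < 2:
        raise ValueError(f"need >= 2 anchored markers on {chrom}, got {len(merged)}")
    merged = merged.sort_values(["position", cm_col]).reset_index(drop=True)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fit = iso.fit_transform(merged["position"].to_numpy(float), merged[cm_col].to_numpy(float))
    points = pd.DataFrame(
        {
            "marker_id": merged["marker_id"],
            "pos": merged["position"].astype(np.int64),
            "cm": merged[cm_col].astype(float),
            "cm_fit": fit,
        }
    )
    points["outlier"] = (points["cm"] - points["cm_fit"]).abs() > outlier_threshold
    return MareyMap(chrom=chrom, sex=sex, points=points)


# ---------------------------------------------------------------------------
# windowed recombination rate


def recombination_rate(
    marey: MareyMap,
    chrom_length: int,
    window: float = 10e6,
    step: float = 2e6,
) -> RecombinationProfile:
    """Sliding-window recombination rates from the smoothed Marey map.

    Per window, rate = (max − min smoothed cM of contained markers) divided
    by the bp span of those markers, in cM/Mb. Windows with fewer than two
    markers get a null rate; ``rate_filled`` interpolates nulls linearly on
    window midpoints (for segmentation only).
    """
    if window < step:
        raise ValueError("window must be >= step")
    pos = marey.points["pos"].to_numpy(float)
    cm = marey.points["cm_fit"].to_numpy(float)
    starts = np.arange(0, max(chrom_length - window, 0) + 1, step, dtype=float)
    if len(starts) == 0:
        starts = np.array([0.0])
    rows = []
    for s in starts:
        e = min(s + window, chrom_length)
        lo, hi = np.searchsorted(pos, [s, e])
        n = hi - lo
        if n >= 2:
            span = pos[hi - 1] - pos[lo]
            rate = (cm[lo:hi].max() - cm[lo:hi].min()) / (span / 1e6) if span > 0 else 0.0
        else:
            rate = np.nan
        rows.append({"start": s, "end": e, "rate": rate, "n_markers": int(n)})
    win = pd.DataFrame(rows)
    win["rate_filled"] = win["rate"].interpolate(limit_direction="both")
    win["rate_filled"] = win["rate_filled"].fillna(0.0)
    return RecombinationProfile(chrom=marey.chrom, sex=marey.sex, windows=win)


# ---------------------------------------------------------------------------
# segmentation


def _ramp_crossing(mid, rate, run_edge, direction, half):
    """Interpolated bp where the windowed rate crosses the half-amplitude level.

    Window-averaging smears a step landscape into a linear ramp spanning one
    window width; the crossing of the midpoint between the recombining
    plateau and the suppressed level is an unbiased estimate of the step
    position. Scans outward from the outermost suppressed window
    (``run_edge``) in ``direction`` (−1 left, +1 right) to the first window
    at or above the half level and interpolates on window midpoints. Returns
    None when no flanking window reaches the half level.
    """
    prev = run_edge
    k = run_edge + direction
    while 0 <= k < len(rate):
        if rate[k] >= half:
            r_hi, r_lo = rate[k], rate[prev]
            frac = (r_hi - half) / (r_hi - r_lo) if r_hi > r_lo else 0.5
            return mid[k] + frac * (mid[prev] - mid[k])
        prev = k
        k += direction
    return None


def segment_regions(
    profile: RecombinationProfile,
    chrom_length: int,
    threshold: float = 0.25,
    min_run: int = 3,
) -> RegionSegmentation:
    """Partition a chromosome into distal_p / pericentromeric / distal_q.

    Windows with (interpolated) rate below ``threshold`` cM/Mb are suppressed.
    The pericentromeric region is the longest contiguous suppressed run of at
    least ``min_run`` windows that contains — or failing that is nearest to —
    the chromosome midpoint. Its boundaries are placed where the window-rate
    ramp crosses halfway between the flanking recombining plateau and the
    suppressed level; a flank with no recombining windows pins the boundary
    to the chromosome end. No qualifying run yields an empty pericentromeric
    interval.
    """
    win = profile.windows
    if len(win) < min_run:
        raise ValueError(f"profile has {len(win)} windows; need >= {min_run}")
    rate = win["rate_filled"].to_numpy(float)
    mid = ((win["start"] + win["end"]) / 2.0).to_numpy(float)
    suppressed = rate < threshold
    runs = []
    i = 0
    while i < len(rate):
        if suppressed[i]:
            j = i
            while j + 1 < len(rate) and suppressed[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    runs = [r for r in runs if r[1] - r[0] + 1 >= min_run]
    if not runs:
        return RegionSegmentation(chrom=profile.chrom, chrom_length=chrom_length, boundaries=None)
    center = chrom_length / 2.0

    def run_score(r):
        lo, hi = mid[r[0]], mid[r[1]]
        dist = 0.0 if lo <= center <= hi else min(abs(lo - center), abs(hi - center))
        return (dist, -(r[1] - r[0]))

    i0, i1 = min(runs, key=run_score)
    level_lo = float(np.median(rate[i0 : i1 + 1]))

    b1 = b2 = None
    if i0 > 0:
        left = rate[:i0]
        plateau = float(np.median(left[left >= threshold])) if (left >= threshold).any() else threshold
        b1 = _ramp_crossing(mid, rate, i0, -1, (plateau + level_lo) / 2.0)
    if b1 is None:
        b1 = 0.0
    if i1 < len(rate) - 1:
        right = rate[i1 + 1 :]
        plateau = float(np.median(right[right >= threshold])) if (right >= threshold).any() else threshold
        b2 = _ramp_crossing(mid, rate, i1, +1, (plateau + level_lo) / 2.0)
    if b2 is None:
        b2 = float(chrom_length)
    b1 = float(np.clip(b1, 0, chrom_length))
    b2 = float(np.clip(b2, b1, chrom_length))
    return RegionSegmentation(chrom=profile.chrom, chrom_length=chrom_length, boundaries=(b1, b2))


def windows_in_region(
    profile: RecombinationProfile,
    segmentation: RegionSegmentation,
    labels: tuple[str, ...] = ("distal_p", "distal_q"),
    full_containment: bool = True,
) -> pd.DataFrame:
    """Subset profile windows falling in the given segmentation labels.

    With ``full_containment`` (default) a window must lie entirely inside one
    labeled interval; boundary-straddling windows, whose rates mix the two
    regimes, are excluded.
    """
    win = profile.windows
    keep = np.zeros(len(win), dtype=bool)
    for start, end, label in segmentation.intervals:
        if label not in labels:
            continue
        if full_containment:
            keep |= (win["start"].to_numpy() >= start) & (win["end"].to_numpy() <= end)
        else:
            m = (win["start"] + win["end"]).to_numpy() / 2.0
            keep |= (m >= start) & (m < end)
    return win[keep]


# ---------------------------------------------------------------------------
# PAR boundary


def pseudoautosomal_boundary(
    segmentation: RegionSegmentation,
    marker_positions: pd.DataFrame,
) -> dict[str, float | tuple[float, float]]:
    """Compare the segmentation boundary with marker sex-linkage labels.

    ``marker_positions`` needs columns position and linkage
    ('pseudoautosomal' or 'sex_linked'). Returns the distal_p/pericentromeric
    boundary together with the bp interval between the last pseudoautosomal
    and the first sex-linked anchored marker.
    """
    linked = marker_positions[marker_positions["linkage"] == "sex_linked"]
    if linked.empty:
        raise ValueError("no sex-linked markers")
    par = marker_positions[marker_positions["linkage"] == "pseudoautosomal"]
    interval_start = float(par["position"].max()) if len(par) else 0.0
    interval_end = float(linked["position"].min())
    if segmentation.boundaries is None:
        boundary = float(segmentation.chrom_length)
    else:
        boundary = float(segmentation.boundaries[0])
    return {
        "boundary": boundary,
        "marker_interval": (interval_start, interval_end),
    }
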
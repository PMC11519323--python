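"""Insulation scores, local score minima, and insulated-region annotation.

For each bin i the raw insulation statistic is the mean balanced contact
over the square of pairs crossing the bin — rows ``i-w .. i-1`` against
columns ``i+1 .. i+w`` with ``w = window_bp / bin_size`` — so every included
contact reaches at most ``window_bp`` away from i on each side. The score is
the log2 ratio of this mean to the mean raw statistic over the valid bins of
the same chromosome arm, making it invariant to the global scale of the
balanced matrix. Bins with a score below a threshold (default −0.25) that
contain a windowed local minimum are merged into "insulated regions".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ContactMap, InsulationTrack

__all__ = [
    "InsulatedRegion",
    "insulation_track",
    "local_minima",
    "insulated_regions",
    "regions_to_frame",
]


@dataclass(frozen=True)
class InsulatedRegion:
    """A maximal run of sub-threshold bins around one insulation minimum."""

    chrom: str
    start: int  # bp
    end: int  # bp
    start_bin: int
    end_bin: int  # exclusive
    min_bin: int
    min_score: float


def insulation_track(
    cmap: ContactMap,
    window_bp: int = 50_000,
    exclude: pd.DataFrame | None = None,
    min_valid_frac: float = 0.5,
) -> InsulationTrack:
    """Per-bin insulation score on a balanced map.

    A bin is valid when the full window fits inside its chromosome arm, it
    does not overlap ``exclude`` (BED-like DataFrame), and at least
    ``min_valid_frac`` of the window's pixels involve two unmasked bins;
    the window mean is taken over those valid pixels. The focal bin's own
    row and column never enter the window, so a masked focal bin still
    carries a score as long as its window is well covered. Arms shorter
    than ``2*w + 1`` bins yield an all-invalid track.
    """
    if not cmap.balanced:
        raise ValueError("insulation requires a balanced map")
    bs = cmap.bins.bin_size
    if window_bp < bs:
        raise ValueError("window must cover at least one bin")
    if window_bp % bs != 0:
        raise ValueError("window_bp must be a multiple of bin_size")
    w = window_bp // bs
    n = cmap.n_bins
    score = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    excluded = _exclusion_flags(cmap.bins, exclude)
    mat = cmap.counts

    for _, _, sl in cmap.bins.arm_slices():
        lo, hi = sl.start, sl.stop
        raw = np.full(hi - lo, np.nan)
        for i in range(lo + w, hi - w):
            if excluded[i]:
                continue
            sub = mat[i - w : i, i + 1 : i + w + 1]
            finite = np.isfinite(sub)
            if finite.sum() < min_valid_frac * w * w:
                continue
            raw[i - lo] = sub[finite].mean()
        defined = np.isfinite(raw)
        if defined.sum() == 0:
            continue
        arm_mean = raw[defined].mean()
        if arm_mean <= 0:
            continue
        with np.errstate(divide="ignore"):
            arm_score = np.log2(raw / arm_mean)
        score[lo:hi] = arm_score
        valid[lo:hi] = defined & np.isfinite(arm_score)
    score[~valid] = np.nan
    return InsulationTrack(cmap.bins, score, valid, window_bp)


def _exclusion_flags(bins, exclude: pd.DataFrame | None) -> np.ndarray:
    flags = np.zeros(bins.n_bins, dtype=bool)
    if exclude is None or len(exclude) == 0:
        return flags
    bdf = bins.df
    for _, row in exclude.iterrows():
        hit = (
            (bdf["chrom"] == row["chrom"])
            & (bdf["start"] < row["end"])
            & (bdf["end"] > row["start"])
        )
        flags |= hit.to_numpy()
    return flags


def local_minima(track: InsulationTrack, span: int = 10) -> np.ndarray:
    """Bins whose score is the minimum of the centered window of ``span`` bins.

    A bin qualifies when it is valid, at least ``ceil(span/2)`` bins from
    any validity edge, and its score equals the window minimum with no
    equal-scoring bin to its left in the window (plateaus report their
    leftmost bin; later members of a tie are suppressed).
    """
    if span < 3:
        raise ValueError("span must be >= 3")
    half = span // 2
    guard = int(np.ceil(span / 2))
    score, valid = track.score, track.valid
    n = len(score)
    out = []
    for i in range(n):
        if not valid[i]:
            continue
        lo, hi = i - half, i + half + 1
        if lo < 0 or hi > n or not valid[lo:hi].all():
            continue
        # distance to nearest validity edge must be >= guard
        left_ok = i - guard >= 0 and valid[i - guard : i].all()
        right_ok = i + guard < n and valid[i + 1 : i + guard + 1].all()
        if not (left_ok and right_ok):
            continue
        window = score[lo:hi]
        m = window.min()
        if score[i] != m:
            continue
        ties = np.flatnonzero(window == m) + lo
        if ties[0] != i:
            continue  # leftmost of the plateau wins
        out.append(i)
    # suppress equal-valued minima that fall within one window of each other
    kept: list[int] = []
    for i in out:
        if kept and i - kept[-1] <= half and score[i] == score[kept[-1]]:
            continue
        kept.append(i)
    return np.array(kept, dtype=int)


def insulated_regions(
    track: InsulationTrack,
    minima: np.ndarray,
    threshold: float = -0.25,
) -> list[InsulatedRegion]:
    """Sub-threshold runs of bins around local insulation minima.

    Each minimum with score below ``threshold`` is extended to the maximal
    contiguous run of valid sub-threshold bins containing it; a run holding
    several minima is split at the maximum-score bin between consecutive
    minima, so every region contains exactly one minimum.
    """
    score, valid = track.score, track.valid
    n = len(score)
    below = valid & (score < threshold)
    surviving = [int(m) for m in minima if below[m]]
    regions: list[InsulatedRegion] = []
    used: set[tuple[int, int]] = set()
    for m in surviving:
        a = m
        while a > 0 and below[a - 1]:
            a -= 1
        b = m + 1
        while b < n and below[b]:
            b += 1
        if (a, b) in used:
            continue
        used.add((a, b))
        inside = [x for x in surviving if a <= x < b]
        # split runs holding >= 2 minima at the max-score bin between them
        cuts = [a]
        for left, right in zip(inside[:-1], inside[1:]):
            cut = left + 1 + int(np.argmax(score[left + 1 : right]))
            cuts.append(cut)
        cuts.append(b)
        for k, m_k in enumerate(inside):
            # the split bin itself joins the right-hand region
            regions.append(_make_region(track, cuts[k], cuts[k + 1], m_k))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _make_region(track: InsulationTrack, a: int, b: int, m: int) -> InsulatedRegion:
    bdf = track.bins.df
    return InsulatedRegion(
        chrom=bdf["chrom"].iloc[m],
        start=int(bdf["start"].iloc[a]),
        end=int(bdf["end"].iloc[b - 1]),
        start_bin=a,
        end_bin=b,
        min_bin=m,
        min_score=float(track.score[m]),
    )


def regions_to_frame(regions: list[InsulatedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "start_bin": r.start_bin,
                "end_bin": r.end_bin,
                "min_bin": r.min_bin,
                "min_score": r.min_score,
            }
            for r in regions
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "start_bin",
            "end_bin",
            "min_bin",
            "min_score",
        ],
    )
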
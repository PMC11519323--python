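"""Figure-level summaries: pileups, border profiles, decay curves,
track correlations, rank tests, and expression-quintile anchor profiles.

Pileups operate on observed/expected values so distance decay does not
dominate the average; profiles are simple signed-distance histograms or
overlap-weighted track means around point features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ContactMap, InsulationTrack
from .domains import OEMatrix

__all__ = [
    "Pileup",
    "Profile",
    "locus_pileup",
    "rescaled_domain_pileup",
    "point_profile",
    "signal_profile",
    "decay_curve",
    "track_correlation",
    "rank_group_compare",
    "expression_quintile_anchor_profiles",
]


@dataclass
class Pileup:
    matrix: np.ndarray  # mean O/E over contributing windows
    flank_bp: int
    n_loci: int
    n_skipped: int
    n_interior: int | None = None  # rescaled-domain pileups only


@dataclass
class Profile:
    centers_bp: np.ndarray  # signed distance of each step bin center
    values: np.ndarray  # mean value or normalized count per step bin
    n_loci: int
    step_bp: int
    flank_bp: int


def _arm_bounds(bins) -> tuple[np.ndarray, np.ndarray]:
    lo = np.empty(bins.n_bins, dtype=int)
    hi = np.empty(bins.n_bins, dtype=int)
    for _, _, sl in bins.arm_slices():
        lo[sl] = sl.start
        hi[sl] = sl.stop
    return lo, hi


def locus_pileup(oe: OEMatrix, loci: list[int], flank_bp: int) -> Pileup:
    """Element-wise mean of (2w+1)x(2w+1) O/E windows centered on loci.

    Loci whose window does not fit inside their chromosome arm are skipped
    (and counted); zero usable loci is an error.
    """
    w = flank_bp // oe.bins.bin_size
    lo, hi = _arm_bounds(oe.bins)
    stack = []
    skipped = 0
    for i in loci:
        if i - w < lo[i] or i + w + 1 > hi[i]:
            skipped += 1
            continue
        stack.append(oe.oe[i - w : i + w + 1, i - w : i + w + 1])
    if not stack:
        raise ValueError("no usable loci for pileup")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.stack(stack), axis=0)
    return Pileup(mean, flank_bp, len(stack), skipped)


def rescaled_domain_pileup(
    oe: OEMatrix,
    domains: list[tuple[int, int]],
    flank_bp: int = 100_000,
    n_interior: int = 20,
) -> Pileup:
    """Mean O/E window over domains with interiors rescaled to a fixed size.

    Each domain ``[a, b)`` contributes a window of ``f`` native-resolution
    flank bins on each side plus ``n_interior`` interior positions obtained
    by nearest-bin lookup. Domains shorter than 2 bins or whose flanks leave
    the arm are skipped (and counted).
    """
    f = flank_bp // oe.bins.bin_size
    lo, hi = _arm_bounds(oe.bins)
    stack = []
    skipped = 0
    for a, b in domains:
        length = b - a
        if length < 2 or a - f < lo[a] or b + f > hi[b - 1]:
            skipped += 1
            continue
        interior = a + np.minimum(
            ((np.arange(n_interior) + 0.5) * length / n_interior).astype(int),
            length - 1,
        )
        sel = np.concatenate([np.arange(a - f, a), interior, np.arange(b, b + f)])
        stack.append(oe.oe[np.ix_(sel, sel)])
    if not stack:
        raise ValueError("no usable domains for pileup")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.stack(stack), axis=0)
    return Pileup(mean, flank_bp, len(stack), skipped, n_interior=n_interior)


def _step_edges(flank_bp: int, step_bp: int) -> np.ndarray:
    n = int(np.ceil(flank_bp / step_bp))
    return np.arange(-n, n + 1) * step_bp


def point_profile(
    borders_bp: np.ndarray,
    features_bp: np.ndarray,
    flank_bp: int = 25_000,
    step_bp: int = 2000,
    orientations: np.ndarray | None = None,
) -> Profile:
    """Histogram of signed feature-to-border distances, normalized per border.

    ``orientations`` (+1/-1 per border) flips signed distances for
    minus-oriented borders; the default pools both directions unoriented.
    """
    borders = np.asarray(borders_bp, dtype=float)
    features = np.asarray(features_bp, dtype=float)
    edges = _step_edges(flank_bp, step_bp)
    counts = np.zeros(len(edges) - 1)
    for k, b in enumerate(borders):
        d = features - b
        if orientations is not None and orientations[k] < 0:
            d = -d
        d = d[(d >= edges[0]) & (d < edges[-1])]
        counts += np.histogram(d, bins=edges)[0]
    values = counts / max(len(borders), 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return Profile(centers, values, len(borders), step_bp, flank_bp)


def signal_profile(
    borders_bp: np.ndarray,
    track: pd.DataFrame,
    flank_bp: int = 25_000,
    step_bp: int = 2000,
    chrom: str | None = None,
) -> Profile:
    """Overlap-weighted mean track value per signed-distance step bin.

    Step bins never covered by the track are NaN (missing, not zero).
    ``track`` is a bedGraph-like DataFrame; when ``chrom`` is given only
    that chromosome's intervals are used.
    """
    t = track if chrom is None else track[track["chrom"] == chrom]
    ts = t["start"].to_numpy(dtype=float)
    te = t["end"].to_numpy(dtype=float)
    tv = t["value"].to_numpy(dtype=float)
    edges = _step_edges(flank_bp, step_bp)
    nb = len(edges) - 1
    wsum = np.zeros(nb)
    vsum = np.zeros(nb)
    for b in np.asarray(borders_bp, dtype=float):
        for k in range(nb):
            lo, hi = b + edges[k], b + edges[k + 1]
            ov = np.minimum(te, hi) - np.maximum(ts, lo)
            sel = ov > 0
            if sel.any():
                wsum[k] += ov[sel].sum()
                vsum[k] += (ov[sel] * tv[sel]).sum()
    with np.errstate(invalid="ignore"):
        values = np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1.0), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return Profile(centers, values, len(borders_bp), step_bp, flank_bp)


def decay_curve(cmap: ContactMap, per_arm: bool = False) -> pd.DataFrame:
    """Mean contact per bin distance over valid pairs.

    Returns a DataFrame with ``chrom``, ``arm``, ``distance`` (bp), ``mean``
    and ``n_pairs``; genome-wide rows use chrom ``"*"``. Masked bins (NaN
    entries) are excluded from the denominators.
    """
    bs = cmap.bins.bin_size
    rows = []
    genome: dict[int, list[float]] = {}
    for chrom, arm, sl in cmap.bins.arm_slices():
        sub = cmap.counts[sl, sl]
        m = sub.shape[0]
        for d in range(m):
            diag = np.diagonal(sub, offset=d)
            finite = np.isfinite(diag)
            if not finite.any():
                continue
            s, k = float(diag[finite].sum()), int(finite.sum())
            if per_arm:
                rows.append((chrom, arm, d * bs, s / k, k))
            acc = genome.setdefault(d, [0.0, 0])
            acc[0] += s
            acc[1] += k
    for d in sorted(genome):
        s, k = genome[d]
        rows.append(("*", "", d * bs, s / k, k))
    return pd.DataFrame(rows, columns=["chrom", "arm", "distance", "mean", "n_pairs"])


def track_correlation(tracks: list[InsulationTrack]) -> np.ndarray:
    """Pairwise Pearson correlation over bins valid in both tracks."""
    k = len(tracks)
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, 1.0)
    for a, b in itertools.combinations(range(k), 2):
        common = tracks[a].valid & tracks[b].valid
        if common.sum() < 3:
            continue
        x, y = tracks[a].score[common], tracks[b].score[common]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        out[a, b] = out[b, a] = float(np.corrcoef(x, y)[0, 1])
    return out


def rank_group_compare(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when the smaller group has <= 8 values and there are
    no ties; normal approximation with tie correction otherwise. Two
    identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    ties = len(np.unique(pooled)) < pooled.size
    if min(x.size, y.size) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def expression_quintile_anchor_profiles(
    loops: pd.DataFrame,
    genes: pd.DataFrame,
    track: pd.DataFrame,
    bins,
    flank_bp: int = 10_000,
    step_bp: int = 2000,
) -> tuple[list[Profile], pd.DataFrame]:
    """Profiles of a signal around distal loop anchors, split by the
    expression quintile of the gene at the other anchor.

    Keeps loops with exactly one anchor bin overlapping a gene; the other
    (distal) anchor's bin center is profiled. Quintiles are assigned on the
    interacting gene's ``expression`` (ascending; ties broken by input
    order, so the split is deterministic), with sizes differing by at most
    1. Returns the 5 profiles (lowest quintile first) and the per-loop
    assignment table.
    """
    bdf = bins.df
    recs = []
    for _, lp in loops.iterrows():
        hits = []
        for which in ("bin_i", "bin_j"):
            a = int(lp[which])
            s, e = bdf["start"].iloc[a], bdf["end"].iloc[a]
            chrom = bdf["chrom"].iloc[a]
            sel = (
                (genes["chrom"] == chrom)
                & (genes["start"] < e)
                & (genes["end"] > s)
            )
            hits.append(np.flatnonzero(sel.to_numpy()))
        if (len(hits[0]) > 0) == (len(hits[1]) > 0):
            continue  # zero or two gene anchors: not a gene-distal pair
        gene_side = 0 if len(hits[0]) else 1
        gidx = int(hits[gene_side][0])
        distal = int(lp["bin_j" if gene_side == 0 else "bin_i"])
        center = (bdf["start"].iloc[distal] + bdf["end"].iloc[distal]) / 2.0
        recs.append(
            {
                "bin_i": int(lp["bin_i"]),
                "bin_j": int(lp["bin_j"]),
                "gene_index": gidx,
                "expression": float(genes["expression"].iloc[gidx]),
                "distal_center": center,
                "chrom": bdf["chrom"].iloc[distal],
            }
        )
    if len(recs) < 5:
        raise ValueError("need at least 5 gene-interacting loops")
    table = pd.DataFrame(recs)
    order = np.lexsort((np.arange(len(table)), table["expression"].to_numpy()))
    quint = np.empty(len(table), dtype=int)
    for q, chunk in enumerate(np.array_split(order, 5)):
        quint[chunk] = q
    table["quintile"] = quint
    profiles = []
    for q in range(5):
        sel = table[table["quintile"] == q]
        profiles.append(
            signal_profile(
                sel["distal_center"].to_numpy(), track, flank_bp, step_bp
            )
        )
    return profiles, table
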
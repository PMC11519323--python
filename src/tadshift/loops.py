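"""Distance-conditioned significance calling of chromatin contacts.

The model assigns each intrachromosomal bin pair in a distance range
(default 4-100 kb) a contact probability from a non-parametric, monotone
distance prior: bias-corrected counts are pooled into equal-occupancy
distance bins, the per-distance mean is adjusted to be non-increasing
(isotonic regression), and probabilities are normalized over the modeled
pairs. Each pair's observed count is then tested against
``Binomial(N, p_pair)`` where ``N`` is the total contact count over modeled
pairs and ``p_pair`` re-introduces the bin biases multiplicatively; q-values
come from Benjamini-Hochberg over all modeled pairs, zero-count pairs
included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .core import ContactMap

__all__ = [
    "DecayModel",
    "distance_expected_model",
    "loop_significance",
    "call_loops",
    "compare_loop_sets",
    "anchor_overlap_fraction",
]

SIZE_SMALL, SIZE_MID, SIZE_LARGE = "<10kb", "10-50kb", ">50kb"


@dataclass
class DecayModel:
    """Monotone per-distance contact probability over the modeled range.

    ``biases`` holds the band-refined per-bin multipliers (see
    :func:`distance_expected_model`); significance testing should use these
    rather than the genome-wide balancing biases.
    """

    distances_bp: np.ndarray  # modeled distances, ascending
    prob: np.ndarray  # per-pair probability at each distance
    n_pairs: np.ndarray  # modeled pairs at each distance
    d_min: int
    d_max: int
    biases: np.ndarray | None = None
    method: str = "equal-occupancy + isotonic"

    def prob_at(self, dist_bp: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.distances_bp, dist_bp)
        if np.any(self.distances_bp[np.clip(idx, 0, len(self.prob) - 1)] != dist_bp):
            raise KeyError("distance outside modeled grid")
        return self.prob[idx]


def _modeled_pairs(cmap: ContactMap, biases: np.ndarray, d_min: int, d_max: int):
    """Index arrays (i, j, dist_bp) of in-range pairs with both bins valid."""
    bs = cmap.bins.bin_size
    codes = cmap.bins.arm_codes()
    n = cmap.n_bins
    ok = cmap.mask & np.isfinite(biases) & (biases > 0)
    ii, jj, dd = [], [], []
    for d_bins in range(max(1, -(-d_min // bs)), d_max // bs + 1):
        dist = d_bins * bs
        if dist < d_min or dist > d_max:
            continue
        i = np.arange(n - d_bins)
        j = i + d_bins
        keep = ok[i] & ok[j] & (codes[i] == codes[j])
        ii.append(i[keep])
        jj.append(j[keep])
        dd.append(np.full(keep.sum(), dist))
    return (np.concatenate(ii), np.concatenate(jj), np.concatenate(dd))


def _pooled_profile(
    corrected: np.ndarray,
    dist: np.ndarray,
    dists: np.ndarray,
    npairs: np.ndarray,
    n_occupancy_bins: int,
) -> np.ndarray:
    """Equal-occupancy pooling + isotonic non-increase of per-pair means."""
    mass = np.array([corrected[dist == d].sum() for d in dists])
    cum = np.cumsum(mass)
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate model: no contact mass in range")
    if n_occupancy_bins >= len(dists):
        group = np.arange(len(dists))  # one group per distance: no pooling
    else:
        edges = np.searchsorted(
            cum, np.linspace(0, total, n_occupancy_bins + 1)[1:-1]
        )
        group = np.zeros(len(dists), dtype=int)
        for e in edges:
            group[e + 1 :] += 1
    raw_prob = np.empty(len(dists))
    for g in np.unique(group):
        sel = group == g
        raw_prob[sel] = mass[sel].sum() / npairs[sel].sum()
    iso = IsotonicRegression(increasing=False)
    return iso.fit_transform(dists.astype(float), raw_prob, sample_weight=npairs)


def distance_expected_model(
    cmap: ContactMap,
    biases: np.ndarray,
    d_min: int = 4000,
    d_max: int = 100_000,
    n_occupancy_bins: int = 40,
    bias_refine_iter: int = 4,
) -> DecayModel:
    """Fit the monotone distance prior on a raw map plus balancing biases.

    Pools bias-corrected counts into ``n_occupancy_bins`` contiguous
    distance groups of approximately equal total contact mass, assigns each
    distance the group's mean per-pair probability, enforces monotone
    non-increase, and normalizes so the probabilities sum to 1 over the
    modeled pairs.

    Genome-wide balancing biases compensate a chromosome-end bin's missing
    long-range partners by deflating it, which misstates its short-range
    expectation inside the modeled band. ``bias_refine_iter`` rounds of
    Sinkhorn-style refinement therefore re-fit the per-bin multipliers
    against the band-restricted expected counts, alternating with the
    distance profile; the refined vector is returned on the model and is
    the one significance testing should use.
    """
    if cmap.balanced:
        raise ValueError("model is fit on the raw map (biases supplied separately)")
    i, j, dist = _modeled_pairs(cmap, biases, d_min, d_max)
    obs = cmap.counts[i, j]
    dists = np.unique(dist)
    if len(dists) < n_occupancy_bins:
        raise ValueError(
            f"only {len(dists)} distinct distances in range; "
            f"reduce n_occupancy_bins (= {n_occupancy_bins})"
        )
    npairs = np.array([(dist == d).sum() for d in dists])
    d_index = np.searchsorted(dists, dist)
    b = biases.astype(float).copy()
    n = len(b)
    prob = None
    for it in range(bias_refine_iter + 1):
        corrected = obs / (b[i] * b[j])
        prob = _pooled_profile(corrected, dist, dists, npairs, n_occupancy_bins)
        if it == bias_refine_iter:
            break
        mu = prob[d_index] * b[i] * b[j]
        obs_sum = np.bincount(
            np.concatenate([i, j]), weights=np.concatenate([obs, obs]), minlength=n
        )
        mu_sum = np.bincount(
            np.concatenate([i, j]), weights=np.concatenate([mu, mu]), minlength=n
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(mu_sum > 0, obs_sum / mu_sum, 1.0)
        b = b * np.sqrt(ratio)
    norm = float((prob * npairs).sum())
    prob = prob / norm
    return DecayModel(dists, prob, npairs, d_min, d_max, biases=b)


def loop_significance(
    cmap: ContactMap, model: DecayModel, biases: np.ndarray
) -> pd.DataFrame:
    """Binomial upper-tail p-values and BH q-values for every modeled pair.

    ``p_pair = prob(d_ij) * b_i * b_j / Z`` with ``Z`` restoring
    ``sum(p_pair) = 1``; the observed count is tested against
    ``Binomial(N, p_pair)`` with ``N`` the total count over modeled pairs.
    """
    i, j, dist = _modeled_pairs(cmap, biases, model.d_min, model.d_max)
    obs = cmap.counts[i, j]
    N = int(round(obs.sum()))
    p_pair = model.prob_at(dist) * biases[i] * biases[j]
    p_pair = p_pair / p_pair.sum()
    if np.any(p_pair >= 1):
        raise ValueError("degenerate model: a single pair carries all mass")
    pvals = stats.binom.sf(obs - 1, N, p_pair)
    pvals = np.clip(pvals, 0.0, 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "bin_i": i,
            "bin_j": j,
            "distance": dist,
            "observed": obs,
            "expected_prob": p_pair,
            "expected_count": p_pair * N,
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    table["size_class"] = _size_class(table["distance"].to_numpy())
    return table


def _size_class(dist: np.ndarray, breaks: tuple[int, int] = (10_000, 50_000)):
    lo, hi = breaks
    return np.where(dist < lo, SIZE_SMALL, np.where(dist <= hi, SIZE_MID, SIZE_LARGE))


def call_loops(
    table: pd.DataFrame,
    q_max: float = 0.05,
    size_breaks: tuple[int, int] = (10_000, 50_000),
) -> pd.DataFrame:
    """Rows with q strictly below ``q_max``, size-classed by distance."""
    out = table[table["q_value"] < q_max].copy()
    out["size_class"] = _size_class(out["distance"].to_numpy(), size_breaks)
    return out.reset_index(drop=True)


def compare_loop_sets(
    a: pd.DataFrame,
    b: pd.DataFrame,
    tol_bins: int = 1,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Flag loops of ``a`` that have a match in ``b`` within ``tol_bins``.

    Returns ``a`` with a ``shared`` column plus the shared fraction per
    size class. Both tables must come from maps on the same bin table
    (callers enforce this; the bin indices are compared directly).
    """
    a = a.copy()
    bi = b["bin_i"].to_numpy()
    bj = b["bin_j"].to_numpy()
    shared = np.zeros(len(a), dtype=bool)
    for k, (i, j) in enumerate(zip(a["bin_i"].to_numpy(), a["bin_j"].to_numpy())):
        shared[k] = bool(
            np.any((np.abs(bi - i) <= tol_bins) & (np.abs(bj - j) <= tol_bins))
        )
    a["shared"] = shared
    fractions = {}
    for cls in (SIZE_SMALL, SIZE_MID, SIZE_LARGE):
        sel = a["size_class"] == cls
        fractions[cls] = float(shared[sel.to_numpy()].mean()) if sel.any() else np.nan
    return a, fractions


def anchor_overlap_fraction(
    loops: pd.DataFrame, annotation: pd.DataFrame, bins
) -> float:
    """Fraction of unique loop anchor bins intersecting >=1 annotation interval."""
    anchors = np.unique(
        np.concatenate([loops["bin_i"].to_numpy(), loops["bin_j"].to_numpy()])
    )
    if anchors.size == 0:
        return 0.0
    bdf = bins.df
    hits = 0
    for a in anchors:
        chrom = bdf["chrom"].iloc[a]
        s, e = bdf["start"].iloc[a], bdf["end"].iloc[a]
        sel = (
            (annotation["chrom"] == chrom)
            & (annotation["start"] < e)
            & (annotation["end"] > s)
        )
        hits += int(sel.any())
    return hits / anchors.size
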
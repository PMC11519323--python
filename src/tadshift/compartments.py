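"""A/B compartment assignment from the contact-correlation eigenvector.

Per chromosome arm, the balanced map is aggregated to coarse bins, distance
normalized (O/E), converted to the Pearson correlation matrix across coarse
bins, and summarized by the eigenvector of the largest eigenvalue. The
eigenvector's sign is arbitrary, so it is oriented to correlate positively
with a reference activity track (e.g. gene density); positive entries are
labeled A, negative B. Arms whose leading eigenvalue does not clearly
dominate (``lambda_1 / lambda_2`` below ``min_gap_ratio``) carry no labels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import BinTable, CompartmentTrack, ContactMap

__all__ = ["coarsen_map", "compartment_eigenvector", "compartment_swap_fraction"]


def coarsen_map(cmap: ContactMap, coarse_bin_bp: int) -> ContactMap:
    """Sum balanced fine-bin values into coarse bins.

    A coarse bin is valid when at least half of its fine bins are unmasked;
    sums are NaN-aware over valid fine bins.
    """
    if coarse_bin_bp % cmap.bins.bin_size != 0:
        raise ValueError("coarse_bin_bp must be a multiple of bin_size")
    fine = cmap.bins.df
    group_key = (
        fine["chrom"].astype(str)
        + "\x00"
        + fine["arm"].astype(str)
        + "\x00"
        + (fine["start"] // coarse_bin_bp).astype(str).str.zfill(9)
    )
    codes, uniq = pd.factorize(group_key, sort=False)
    n_coarse = len(uniq)
    rows = []
    mask = np.zeros(n_coarse, dtype=bool)
    agg = np.zeros((n_coarse, n_coarse))
    member = [np.flatnonzero(codes == g) for g in range(n_coarse)]
    c = np.where(np.isfinite(cmap.counts), cmap.counts, 0.0)
    for g, mem in enumerate(member):
        rows.append(
            {
                "chrom": fine["chrom"].iloc[mem[0]],
                "start": int(fine["start"].iloc[mem[0]]),
                "end": int(fine["end"].iloc[mem[-1]]),
                "arm": fine["arm"].iloc[mem[0]],
            }
        )
        mask[g] = cmap.mask[mem].mean() >= 0.5
    for g, mem in enumerate(member):
        for h in range(g, n_coarse):
            block = c[np.ix_(mem, member[h])]
            agg[g, h] = agg[h, g] = block.sum()
    coarse_bins = BinTable(pd.DataFrame(rows), coarse_bin_bp)
    agg[~mask, :] = np.nan
    agg[:, ~mask] = np.nan
    biases = np.where(mask, 1.0, np.nan)
    return ContactMap(coarse_bins, agg, mask=mask, biases=biases, balanced=True)


def compartment_eigenvector(
    cmap: ContactMap,
    coarse_bin_bp: int = 50_000,
    reference: pd.DataFrame | None = None,
    min_gap_ratio: float = 3.0,
    min_valid_bins: int = 10,
) -> CompartmentTrack:
    """Leading eigenvector of the coarse O/E correlation matrix, per arm.

    ``reference`` is a bedGraph-like DataFrame whose per-coarse-bin mean
    orients the eigenvector sign (positive correlation = A side positive).
    Arms with fewer than ``min_valid_bins`` valid coarse bins, a degenerate
    correlation matrix, or an eigenvalue gap below ``min_gap_ratio`` are
    left undefined (with a warning).
    """
    if not cmap.balanced:
        raise ValueError("compartment analysis requires a balanced map")
    coarse = coarsen_map(cmap, coarse_bin_bp)
    n = coarse.n_bins
    value = np.full(n, np.nan)
    label = np.full(n, "", dtype=object)
    ref_vals = _reference_per_bin(coarse.bins, reference)
    for chrom, arm, sl in coarse.bins.arm_slices():
        idx = np.arange(sl.start, sl.stop)
        valid = coarse.mask[idx]
        vidx = idx[valid]
        if vidx.size < min_valid_bins:
            warnings.warn(f"arm {chrom}/{arm or 'whole'}: too few valid coarse bins")
            continue
        sub = coarse.counts[np.ix_(vidx, vidx)]
        oe = _oe_small(sub)
        # column-center to remove the shared coverage/arm-end component,
        # which otherwise dominates the spectrum even without compartments
        oe = oe - oe.mean(axis=0, keepdims=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.corrcoef(oe)
        if not np.all(np.isfinite(corr)):
            warnings.warn(f"arm {chrom}/{arm or 'whole'}: degenerate correlation")
            continue
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        lam1, lam2 = evals[order[0]], max(evals[order[1]], 1e-12)
        if lam1 / lam2 < min_gap_ratio:
            warnings.warn(
                f"arm {chrom}/{arm or 'whole'}: no dominant eigenvalue "
                f"(gap ratio {lam1 / lam2:.2f} < {min_gap_ratio})"
            )
            continue
        vec = evecs[:, order[0]]
        sign = 1.0
        if ref_vals is not None:
            r = ref_vals[vidx]
            ok = np.isfinite(r)
            if ok.sum() >= 3 and np.std(r[ok]) > 0 and np.std(vec[ok]) > 0:
                c = np.corrcoef(vec[ok], r[ok])[0, 1]
                if c < 0:
                    sign = -1.0
        vec = vec * sign
        value[vidx] = vec
        label[vidx] = np.where(vec > 0, "A", "B")
    return CompartmentTrack(
        coarse.bins, value, label, coarse_bin_bp,
        reference="user track" if reference is not None else "none",
    )


def _oe_small(sub: np.ndarray, min_mean_value: float = 10.0) -> np.ndarray:
    """Distance-normalize a small dense arm matrix.

    Distances whose mean aggregated value falls below ``min_mean_value``
    are dominated by Poisson sparsity (shared zero patterns masquerade as
    correlation), so their entries are set to the neutral ratio 1 and carry
    no variance into the correlation matrix.
    """
    m = sub.shape[0]
    oe = np.ones_like(sub)
    for d in range(m):
        diag = np.diagonal(sub, offset=d)
        e = diag.mean()
        if e < min_mean_value:
            continue
        vals = diag / e
        i = np.arange(m - d)
        oe[i, i + d] = vals
        oe[i + d, i] = vals
    return oe


def _reference_per_bin(bins: BinTable, reference: pd.DataFrame | None):
    if reference is None:
        return None
    bdf = bins.df
    out = np.full(bins.n_bins, np.nan)
    for k in range(bins.n_bins):
        chrom, s, e = bdf["chrom"].iloc[k], bdf["start"].iloc[k], bdf["end"].iloc[k]
        sel = reference[
            (reference["chrom"] == chrom)
            & (reference["start"] < e)
            & (reference["end"] > s)
        ]
        if len(sel):
            ov = np.minimum(sel["end"], e) - np.maximum(sel["start"], s)
            out[k] = float(np.average(sel["value"], weights=ov))
    return out


def compartment_swap_fraction(a: CompartmentTrack, b: CompartmentTrack) -> float:
    """Fraction of co-labeled coarse bins whose A/B label differs."""
    if not a.bins.equals(b.bins):
        raise ValueError("compartment tracks are on different coarse bins")
    la, lb = a.label, b.label
    both = (la != "") & (lb != "")
    if not both.any():
        raise ValueError("no co-labeled bins")
    return float(np.mean(la[both] != lb[both]))
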
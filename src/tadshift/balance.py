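"""ICE-style iterative matrix correction and low-coverage bin filtering.

The correction removes multiplicative per-bin biases by repeatedly dividing
rows and columns by their marginal relative to the mean marginal, until the
bias vector changes by less than ``eps_threshold`` between iterations (the
convergence measure ``eps`` is the maximum absolute relative change of the
bias vector). The balanced matrix is ``raw[i, j] / (b_i * b_j)``; masked
rows and columns are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ContactMap

__all__ = ["BalanceResult", "NonConvergenceError", "select_valid_bins", "ice_balance"]


class NonConvergenceError(RuntimeError):
    """Raised when iterative correction fails to reach ``eps_threshold``."""

    def __init__(self, message: str, final_eps: float, n_iterations: int):
        super().__init__(message)
        self.final_eps = final_eps
        self.n_iterations = n_iterations


@dataclass
class BalanceResult:
    biases: np.ndarray  # NaN on masked bins
    n_iterations: int
    final_eps: float


def select_valid_bins(cmap: ContactMap, min_marginal_quantile: float = 0.02) -> np.ndarray:
    """Mask low-coverage bins by raw-marginal quantile.

    A bin is masked if its marginal is zero or lies strictly below the given
    quantile of the nonzero marginals. Returns the boolean mask (True =
    valid); the caller attaches it with ``cmap.with_mask``.
    """
    if not 0.0 <= min_marginal_quantile < 1.0:
        raise ValueError("min_marginal_quantile must lie in [0, 1)")
    marg = cmap.marginals()
    mask = marg > 0
    if min_marginal_quantile > 0 and mask.any():
        cut = np.quantile(marg[mask], min_marginal_quantile)
        mask &= marg >= cut
    return mask


def ice_balance(
    cmap: ContactMap, eps_threshold: float = 1e-4, max_iter: int = 200
) -> tuple[ContactMap, BalanceResult]:
    """Balance a raw contact map by iterative correction.

    Returns the balanced map (values ``raw / (b_i b_j)``, NaN on masked
    bins, bin marginals equalized over valid bins) and the bias vector with
    convergence diagnostics. Raises :class:`NonConvergenceError` if ``eps``
    does not drop below ``eps_threshold`` within ``max_iter`` iterations —
    including the disconnected case where an unmasked bin has no contacts.
    """
    if cmap.balanced:
        raise ValueError("map is already balanced")
    mask = cmap.mask.copy()
    if mask.sum() < 2:
        raise ValueError("need at least 2 unmasked bins to balance")
    raw = np.where(np.isnan(cmap.counts), 0.0, cmap.counts)
    n = cmap.n_bins
    b = np.ones(n)
    eps = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        work = raw / np.outer(b, b)
        work[~mask, :] = 0.0
        work[:, ~mask] = 0.0
        marg = work.sum(axis=1)
        valid_marg = marg[mask]
        mean_marg = valid_marg.mean()
        if mean_marg == 0:
            raise NonConvergenceError(
                "all marginals zero on unmasked bins", np.inf, it
            )
        update = np.ones(n)
        update[mask] = marg[mask] / mean_marg
        if np.any(update[mask] == 0):
            raise NonConvergenceError(
                "zero marginal on an unmasked bin (disconnected block); "
                "mask it with select_valid_bins",
                np.inf,
                it,
            )
        b_new = b * update
        eps = float(np.max(np.abs(b_new[mask] - b[mask]) / b[mask]))
        b = b_new
        if eps < eps_threshold:
            break
    else:
        raise NonConvergenceError(
            f"no convergence after {max_iter} iterations (eps={eps:.3g})",
            eps,
            max_iter,
        )
    biases = np.where(mask, b, np.nan)
    balanced = raw / np.outer(b, b)
    balanced[~mask, :] = np.nan
    balanced[:, ~mask] = np.nan
    out = replace(cmap, counts=balanced, mask=mask, biases=biases, balanced=True)
    return out, BalanceResult(biases=biases, n_iterations=it, final_eps=eps)
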
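"""Shared fixtures: tiny hand-built maps and cached demo analyses."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from tadshift import balance, domains, insulation, synth
from tadshift.core import BinTable, ContactMap


def make_bins(n: int, bin_size: int = 2000, chrom: str = "chr1") -> BinTable:
    starts = np.arange(n) * bin_size
    return BinTable(
        pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + bin_size}),
        bin_size,
    )


def make_map(counts: np.ndarray, bin_size: int = 2000) -> ContactMap:
    counts = np.asarray(counts, dtype=float)
    return ContactMap(make_bins(len(counts), bin_size), counts)


def balanced_from_values(values: np.ndarray, bin_size: int = 2000) -> ContactMap:
    """Wrap a symmetric value matrix as an already-balanced map (biases 1)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    return ContactMap(
        make_bins(n, bin_size),
        values,
        mask=np.ones(n, dtype=bool),
        biases=np.ones(n),
        balanced=True,
    )


def analyze(preset: str, seed: int = 1, **kw) -> SimpleNamespace:
    """Run simulate -> balance -> insulation -> domains on a demo preset."""
    cfg = synth.demo_config(preset, seed=seed, **kw)
    cmap, truth = synth.simulate(cfg)
    mask = balance.select_valid_bins(cmap)
    bmap, result = balance.ice_balance(cmap.with_mask(mask))
    track = insulation.insulation_track(bmap)
    minima = insulation.local_minima(track)
    regions = insulation.insulated_regions(track, minima)
    oe = domains.observed_over_expected(bmap, 500_000)
    bounds = sorted(
        {r.start_bin for r in regions}
        | {r.end_bin for r in regions}
        | {0, cmap.n_bins}
    )
    cands = domains.refine_candidates(
        oe, domains.candidate_domains(np.array(bounds, dtype=int), cmap.bins)
    )
    calls = domains.call_domains(oe, cands)
    return SimpleNamespace(
        config=cfg,
        cmap=cmap,
        truth=truth,
        bmap=bmap,
        balance_result=result,
        track=track,
        minima=minima,
        regions=regions,
        oe=oe,
        calls=calls,
    )


@pytest.fixture(scope="session")
def demo():
    """Null / WT-like / mutant-like demo analyses at the study conditions
    (500 bins of 2 kb, depth 1e6, one fixed seed)."""
    return {p: analyze(p, seed=1) for p in ("null", "wt", "mutant")}


@pytest.fixture(scope="session")
def checkerboard():
    """Compartment demo: irregular A/B blocks, 2 Mb at 2 kb, depth 2e6."""
    cfg = synth.demo_config("compartment", n_bins=1000, depth=2e6, seed=1)
    cmap, truth = synth.simulate(cfg)
    mask = balance.select_valid_bins(cmap)
    bmap, _ = balance.ice_balance(cmap.with_mask(mask))
    return SimpleNamespace(cmap=cmap, truth=truth, bmap=bmap)


def boundary_recovery(regions, boundaries, tol_bins: int = 2) -> float:
    hits = sum(
        any(r.start_bin - tol_bins <= b <= r.end_bin + tol_bins for r in regions)
        for b in boundaries
    )
    return hits / len(boundaries)


def basepair_jaccard(calls, truth_domains, n_bins: int) -> float:
    cov_c = np.zeros(n_bins, dtype=bool)
    cov_t = np.zeros(n_bins, dtype=bool)
    for c in calls:
        cov_c[c.start_bin : c.end_bin] = True
    for a, b in truth_domains:
        cov_t[a:b] = True
    return (cov_c & cov_t).sum() / (cov_c | cov_t).sum()
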
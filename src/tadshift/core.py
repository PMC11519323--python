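"""Core in-memory containers for binned Hi-C data.

All genomic coordinates are 0-based, half-open; conversion to and from
1-based conventions happens only at I/O boundaries (see :mod:`tadshift.io`).
Contact matrices are held dense in memory (Arabidopsis-scale arms at 2-kb
resolution are a few thousand bins) and serialized as sparse upper-triangle
triplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["BinTable", "ContactMap", "InsulationTrack", "CompartmentTrack"]


@dataclass(frozen=True)
class BinTable:
    """Uniform genomic bins tiling one or more chromosomes.

    Parameters
    ----------
    df
        Columns ``chrom``, ``start``, ``end`` and optionally ``arm``. Bins
        must be sorted, non-overlapping and tile each chromosome exactly;
        every non-terminal bin has length ``bin_size`` (the terminal bin of
        a chromosome may be shorter).
    bin_size
        Nominal bin width in base pairs.
    """

    df: pd.DataFrame
    bin_size: int

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        required = {"chrom", "start", "end"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"bin table missing columns: {sorted(missing)}")
        if "arm" not in df.columns:
            df = df.assign(arm="")
        df["arm"] = df["arm"].fillna("").astype(str)
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"bins do not tile chromosome {chrom}")
            widths = ends - starts
            if np.any(widths <= 0):
                raise ValueError(f"non-positive bin on chromosome {chrom}")
            if np.any(widths[:-1] != self.bin_size) or widths[-1] > self.bin_size:
                raise ValueError(
                    f"non-terminal bin width != {self.bin_size} on {chrom}"
                )
        object.__setattr__(self, "df", df)

    @classmethod
    def from_chrom_sizes(
        cls,
        chrom_sizes: dict[str, int],
        bin_size: int,
        arms: dict[str, list[tuple[str, int, int]]] | None = None,
    ) -> "BinTable":
        """Tile chromosomes with fixed-size bins.

        ``arms`` optionally maps chromosome name to ``(label, start, end)``
        spans; a bin gets the label of the arm containing its start.
        """
        rows = []
        for chrom, length in chrom_sizes.items():
            starts = np.arange(0, length, bin_size)
            ends = np.minimum(starts + bin_size, length)
            labels = [""] * len(starts)
            if arms and chrom in arms:
                for name, a0, a1 in arms[chrom]:
                    for k, s in enumerate(starts):
                        if a0 <= s < a1:
                            labels[k] = name
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "arm": labels}
                )
            )
        return cls(pd.concat(rows, ignore_index=True), bin_size)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    def arm_codes(self) -> np.ndarray:
        """Integer code per bin identifying its (chrom, arm) group."""
        key = self.df["chrom"].astype(str) + "\x00" + self.df["arm"].astype(str)
        return pd.factorize(key, sort=False)[0]

    def arm_slices(self) -> list[tuple[str, str, slice]]:
        """Contiguous (chrom, arm, slice) spans in bin order."""
        codes = self.arm_codes()
        out: list[tuple[str, str, slice]] = []
        start = 0
        for i in range(1, len(codes) + 1):
            if i == len(codes) or codes[i] != codes[start]:
                row = self.df.iloc[start]
                out.append((row["chrom"], row["arm"], slice(start, i)))
                start = i
        return out

    def bin_of(self, chrom: str, pos: int) -> int:
        """Index of the bin containing position ``pos`` on ``chrom``."""
        sel = self.df[(self.df["chrom"] == chrom)]
        hit = sel[(sel["start"] <= pos) & (pos < sel["end"])]
        if hit.empty:
            raise KeyError(f"position {chrom}:{pos} outside bin table")
        return int(hit.index[0])

    def equals(self, other: "BinTable") -> bool:
        a = self.df[["chrom", "start", "end"]].reset_index(drop=True)
        b = other.df[["chrom", "start", "end"]].reset_index(drop=True)
        return self.bin_size == other.bin_size and a.equals(b)


@dataclass
class ContactMap:
    """A symmetric binned contact matrix with per-bin validity and biases.

    ``counts`` holds raw integer-valued counts when ``balanced`` is False and
    the bias-corrected values when True. ``mask`` marks valid bins; balanced
    values on masked rows/columns are NaN. ``biases`` is present iff
    ``balanced``.
    """

    bins: BinTable
    counts: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    biases: np.ndarray | None = None
    balanced: bool = False

    def __post_init__(self) -> None:
        n = self.bins.n_bins
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")
        if not self.balanced:
            if np.any(self.counts < 0):
                raise ValueError("negative contact counts")
        if not np.allclose(
            np.nan_to_num(self.counts), np.nan_to_num(self.counts.T), rtol=0, atol=0
        ):
            raise ValueError("counts matrix is not symmetric")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length mismatch")
        if (self.biases is not None) != self.balanced:
            raise ValueError("biases must be present iff map is balanced")

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def marginals(self) -> np.ndarray:
        """Row sums over valid columns (NaN-aware)."""
        c = np.where(np.isnan(self.counts), 0.0, self.counts)
        return c.sum(axis=1)

    def with_mask(self, mask: np.ndarray) -> "ContactMap":
        return replace(self, mask=np.asarray(mask, dtype=bool))

    def total(self) -> float:
        """Sum of counts over unordered pairs (diagonal counted once)."""
        c = np.where(np.isnan(self.counts), 0.0, self.counts)
        return float(np.triu(c).sum())


@dataclass
class InsulationTrack:
    """Per-bin insulation score: log2 of the cross-bin contact mean relative
    to the arm-wide mean. ``valid`` flags bins where the score is defined."""

    bins: BinTable
    score: np.ndarray
    valid: np.ndarray
    window_bp: int

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.bins.n_bins
        if self.score.shape != (n,) or self.valid.shape != (n,):
            raise ValueError("track length mismatch with bin table")
        if self.window_bp % self.bins.bin_size != 0:
            raise ValueError("window_bp must be a multiple of bin_size")


@dataclass
class CompartmentTrack:
    """Leading-eigenvector compartment assignment on coarse bins.

    ``value`` is the oriented eigenvector entry, ``label`` one of
    ``"A"``, ``"B"`` or ``""`` (undefined).
    """

    bins: BinTable  # coarse bins
    value: np.ndarray
    label: np.ndarray
    coarse_bin_bp: int
    reference: str = ""

    def __post_init__(self) -> None:
        n = self.bins.n_bins
        self.value = np.asarray(self.value, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        if self.value.shape != (n,) or self.label.shape != (n,):
            raise ValueError("track length mismatch with coarse bin table")
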
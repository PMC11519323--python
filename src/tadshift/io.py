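"""Reading and writing the pipeline's external formats.

Contact matrices travel as a pair of plain-text TSV files: a bin table
(``chrom  start  end  [arm]``) and sparse upper-triangle triplets
(``bin1  bin2  count``, 0-based bin indices, each unordered pair stored once
with ``bin1 <= bin2``). Balanced maps additionally carry a per-bin ``bias``
column on the bin table. Interval inputs use the community dialects: BED
(0-based half-open), bedGraph, GFF3 gene records (1-based inclusive,
converted on read), and BEDPE for loop anchor pairs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import BinTable, ContactMap

__all__ = [
    "load_contact_map",
    "write_contact_map",
    "read_intervals",
    "write_bed",
    "write_bedgraph",
    "write_bedpe",
]

_STRANDS = {"+", "-", "."}


def load_contact_map(bins_path: str, triplets_path: str) -> ContactMap:
    """Load a contact map from a bin table and a sparse triplet file.

    Raises ``ValueError`` for duplicate bin pairs, negative counts, or bin
    indices outside the bin table. A ``mask`` column (0/1) and a ``bias``
    column on the bin table are honored when present.
    """
    bdf = pd.read_csv(bins_path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in bdf.columns:
            raise ValueError(f"bins file missing column {col!r}")
    sizes = (bdf["end"] - bdf["start"]).to_numpy()
    bin_size = int(sizes.max())
    bias = None
    if "bias" in bdf.columns:
        bias = bdf["bias"].to_numpy(dtype=float)
    mask = None
    if "mask" in bdf.columns:
        mask = bdf["mask"].to_numpy(dtype=bool)
    keep = [c for c in ("chrom", "start", "end", "arm") if c in bdf.columns]
    bins = BinTable(bdf[keep], bin_size)

    tdf = pd.read_csv(triplets_path, sep="\t")
    for col in ("bin1", "bin2", "count"):
        if col not in tdf.columns:
            raise ValueError(f"triplets file missing column {col!r}")
    i = tdf["bin1"].to_numpy(dtype=int)
    j = tdf["bin2"].to_numpy(dtype=int)
    v = tdf["count"].to_numpy(dtype=float)
    n = bins.n_bins
    bad = (i < 0) | (i >= n) | (j < 0) | (j >= n)
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise ValueError(f"bin index out of range in triplet ({i[k]}, {j[k]})")
    balanced = bias is not None
    if not balanced and np.any(v < 0):
        k = int(np.flatnonzero(v < 0)[0])
        raise ValueError(f"negative count in triplet ({i[k]}, {j[k]})")
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    pair_key = lo.astype(np.int64) * n + hi
    uniq, counts_per = np.unique(pair_key, return_counts=True)
    if np.any(counts_per > 1):
        key = int(uniq[np.argmax(counts_per > 1)])
        raise ValueError(
            f"duplicate bin pair ({key // n}, {key % n}) in triplet file"
        )
    mat = np.zeros((n, n), dtype=float)
    mat[lo, hi] = v
    mat[hi, lo] = v
    return ContactMap(bins, mat, mask=mask, biases=bias, balanced=balanced)


def write_contact_map(cmap: ContactMap, out_prefix: str) -> dict[str, str]:
    """Write ``<prefix>.bins.tsv`` and ``<prefix>.triplets.tsv``.

    Rows are emitted in ascending (bin1, bin2) order so identical maps
    produce byte-identical files. Returns the written paths.
    """
    bins_path = f"{out_prefix}.bins.tsv"
    trip_path = f"{out_prefix}.triplets.tsv"
    os.makedirs(os.path.dirname(os.path.abspath(bins_path)), exist_ok=True)
    bdf = cmap.bins.df.copy()
    bdf["mask"] = cmap.mask.astype(int)
    if cmap.balanced:
        bdf["bias"] = cmap.biases
    _write_tsv(bdf, bins_path)
    c = np.where(np.isnan(cmap.counts), 0.0, cmap.counts)
    iu, ju = np.triu_indices(cmap.n_bins)
    vals = c[iu, ju]
    nz = vals != 0
    tdf = pd.DataFrame({"bin1": iu[nz], "bin2": ju[nz], "count": vals[nz]})
    _write_tsv(tdf, trip_path)
    return {"bins": bins_path, "triplets": trip_path}


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_intervals(path: str, format: str) -> pd.DataFrame:
    """Read genomic intervals in one of ``bed``, ``bedgraph``, ``gff_genes``,
    ``bedpe``.

    Returns a DataFrame with 0-based half-open coordinates:

    - ``bed``: chrom/start/end plus optional name, score, strand;
    - ``bedgraph``: chrom/start/end/value (a signal track);
    - ``gff_genes``: gene records only, with ``tss`` — the 0-based position
      of the transcribed 5' base (``start`` for ``+`` strand, ``end - 1``
      for ``-``);
    - ``bedpe``: chrom1/start1/end1/chrom2/start2/end2 anchor pairs.
    """
    readers = {
        "bed": _read_bed,
        "bedgraph": _read_bedgraph,
        "gff_genes": _read_gff_genes,
        "bedpe": _read_bedpe,
    }
    if format not in readers:
        raise ValueError(f"unknown interval format {format!r}")
    return readers[format](path)


def _data_lines(path: str):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _read_bed(path: str) -> pd.DataFrame:
    rows = []
    for lineno, f in _data_lines(path):
        if len(f) < 3:
            raise ValueError(f"{path}:{lineno}: BED line has <3 fields")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-integer coordinate") from e
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end")
        name = f[3] if len(f) > 3 else ""
        strand = f[5] if len(f) > 5 and f[5] in _STRANDS else "."
        value = np.nan
        if len(f) > 4:
            try:
                value = float(f[4])
            except ValueError:
                value = np.nan
        rows.append((f[0], start, end, name, value, strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "value", "strand"]
    )


def _read_bedgraph(path: str) -> pd.DataFrame:
    rows = []
    for lineno, f in _data_lines(path):
        if len(f) < 4:
            raise ValueError(f"{path}:{lineno}: bedGraph line has <4 fields")
        try:
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: malformed bedGraph fields") from e
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _read_gff_genes(path: str) -> pd.DataFrame:
    """GFF3 gene features; 1-based inclusive converted to 0-based half-open.

    The TSS is the transcribed 5' base: position ``start`` for + strand
    genes and ``end - 1`` (the last covered base) for - strand genes.
    """
    rows = []
    for lineno, f in _data_lines(path):
        if len(f) < 8:
            raise ValueError(f"{path}:{lineno}: GFF line has <8 fields")
        if f[2] != "gene":
            continue
        try:
            start1, end1 = int(f[3]), int(f[4])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-integer GFF coordinate") from e
        if start1 < 1 or end1 < start1:
            raise ValueError(f"{path}:{lineno}: invalid GFF span")
        strand = f[6] if f[6] in _STRANDS else "."
        start, end = start1 - 1, end1
        tss = start if strand != "-" else end - 1
        name = ""
        if len(f) > 8:
            for kv in f[8].split(";"):
                if kv.startswith(("ID=", "Name=")):
                    name = kv.split("=", 1)[1]
                    break
        rows.append((f[0], start, end, name, strand, tss))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "strand", "tss"]
    )


def _read_bedpe(path: str) -> pd.DataFrame:
    rows = []
    for lineno, f in _data_lines(path):
        if len(f) < 6:
            raise ValueError(f"{path}:{lineno}: BEDPE line has <6 fields")
        try:
            rows.append(
                (f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]))
            )
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: malformed BEDPE fields") from e
    return pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
    )


def write_bed(df: pd.DataFrame, path: str, cols: list[str] | None = None) -> str:
    """Write intervals as headerless BED (chrom/start/end + extra columns)."""
    cols = cols or [c for c in df.columns if c not in ("chrom", "start", "end")]
    out = df[["chrom", "start", "end", *cols]]
    out.to_csv(path, sep="\t", index=False, header=False, float_format="%.10g")
    return path


def write_bedgraph(df: pd.DataFrame, path: str) -> str:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.10g"
    )
    return path


def write_bedpe(df: pd.DataFrame, path: str, extra: list[str] | None = None) -> str:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    out = df[cols + (extra or [])]
    out.to_csv(path, sep="\t", index=False, header=False, float_format="%.10g")
    return path
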
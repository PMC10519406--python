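"""Gene-relative coordinates and the fixed metagene bin grid.

Gene bodies are mapped onto a normalized axis where the transcription start
site (TSS) is 0 and the transcription end site (TES) is 1, taking the coding
strand into account.  Flanking sequence maps below 0 (upstream) and above 1
(downstream).  Features are then aggregated on a fixed grid of equal-width
bins — by default 42 bins spanning [-0.5, 1.5], which gives half a gene
length of flank on either side and good resolution at the TSS and TES.

All genomic coordinates are 0-based half-open (BED convention), both in
memory and in files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (gene_id, chrom, start, end, strand).

    Returns a copy with integer coordinates.  Raises ``ValueError`` on
    duplicate gene ids, non-positive lengths, or bad strands.
    """
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    g = genes.reset_index(drop=True).copy()
    g["start"] = g["start"].astype(np.int64)
    g["end"] = g["end"].astype(np.int64)
    if (g["end"] <= g["start"]).any():
        bad = g.loc[g["end"] <= g["start"], "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r} has non-positive length")
    if g["gene_id"].duplicated().any():
        dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    if not g["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return g


def gene_anchors(genes: pd.DataFrame) -> pd.DataFrame:
    """Return per-gene TSS/TES anchor coordinates as boundary positions.

    On the + strand tss = start and tes = end; on the - strand tss = end and
    tes = start (the half-open interval boundary nearest the first
    transcribed base).
    """
    minus = genes["strand"].to_numpy() == "-"
    tss = np.where(minus, genes["end"], genes["start"]).astype(np.int64)
    tes = np.where(minus, genes["start"], genes["end"]).astype(np.int64)
    out = genes.copy()
    out["tss"] = tss
    out["tes"] = tes
    return out


def relative_position(gene, pos):
    """Map genomic position(s) to the gene-relative axis (TSS=0, TES=1).

    ``gene`` is a mapping/row with start, end, strand.  The map is affine:
    r = (pos - tss) / (tes - tss), signed so that on the - strand larger
    genomic coordinates give smaller relative positions.  A 1-kb flank of a
    4-kb gene therefore spans -0.25..0 upstream: flanks scale with gene
    length (see :func:`relative_positions` for the fixed-flank alternative).
    """
    start, end = int(gene["start"]), int(gene["end"])
    if end <= start:
        raise ValueError("zero-length gene has no relative coordinate system")
    if gene["strand"] == "-":
        tss, tes = end, start
    else:
        tss, tes = start, end
    return (np.asarray(pos, dtype=float) - tss) / (tes - tss)


def relative_positions(
    gene,
    pos,
    mode: str = "gene_length",
    flank_bp: int = 1000,
    flank_units: float = 0.5,
):
    """Like :func:`relative_position` with a configurable flank scale.

    mode="gene_length" (default): one affine map, flanks scaled by gene
    length.  mode="fixed": inside the body identical, but positions outside
    [0, 1] are rescaled so that ``flank_bp`` of genomic flank spans
    ``flank_units`` of relative axis regardless of gene length.
    """
    r = relative_position(gene, pos)
    if mode == "gene_length":
        return r
    if mode != "fixed":
        raise ValueError(f"unknown flank mode {mode!r}")
    L = int(gene["end"]) - int(gene["start"])
    scale = (L / flank_bp) * flank_units
    r = np.asarray(r, dtype=float).copy()
    up = r < 0
    down = r > 1
    r[up] = r[up] * scale
    r[down] = 1 + (r[down] - 1) * scale
    return r


@dataclass(frozen=True)
class BinGrid:
    """Equal-width bins over the relative-coordinate axis.

    Bins are left-closed right-open, except the last bin which also includes
    the right edge, so every position in [lo, hi] maps to exactly one bin.
    """

    lo: float = -0.5
    hi: float = 1.5
    n_bins: int = 42
    edges: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not self.lo < self.hi:
            raise ValueError("require lo < hi")
        object.__setattr__(
            self, "edges", np.linspace(self.lo, self.hi, self.n_bins + 1)
        )

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2

    def bin_index(self, positions) -> np.ndarray:
        """Bin index per position; -1 for positions outside [lo, hi]."""
        r = np.asarray(positions, dtype=float)
        idx = np.floor((r - self.lo) / self.width).astype(np.int64)
        idx[r == self.hi] = self.n_bins - 1  # closed right edge of last bin
        idx[(r < self.lo) | (r > self.hi)] = -1
        return idx


def make_bin_grid(lo: float = -0.5, hi: float = 1.5, n_bins: int = 42) -> BinGrid:
    return BinGrid(lo=lo, hi=hi, n_bins=n_bins)


@dataclass
class BinnedProfile:
    """Per-bin aggregated values; NaN where a bin received no observations."""

    grid: BinGrid
    values: np.ndarray
    n_obs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.grid.edges[:-1],
                "bin_hi": self.grid.edges[1:],
                "value": self.values,
                "n_obs": self.n_obs,
            }
        )


_AGGREGATORS = {"mean": np.mean, "median": np.median}


def bin_aggregate(positions, values, grid: BinGrid, aggregator: str = "mean") -> BinnedProfile:
    """Aggregate per-observation values into grid bins.

    Positions outside [grid.lo, grid.hi] are dropped; empty bins are NaN
    with n_obs = 0.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.shape != values.shape:
        raise ValueError("positions and values must have the same length")
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"aggregator must be one of {sorted(_AGGREGATORS)}")
    agg = _AGGREGATORS[aggregator]
    idx = grid.bin_index(positions)
    keep = idx >= 0
    idx, values = idx[keep], values[keep]
    out = np.full(grid.n_bins, np.nan)
    n_obs = np.bincount(idx, minlength=grid.n_bins).astype(np.int64)
    for b in np.unique(idx):
        out[b] = agg(values[idx == b])
    return BinnedProfile(grid=grid, values=out, n_obs=n_obs)


def filter_isolated_genes(genes: pd.DataFrame, min_gap: int = 2000) -> pd.DataFrame:
    """Keep genes at least ``min_gap`` bp from their nearest neighboring gene body.

    The distance between half-open intervals [a,b) and [c,d) with b <= c is
    c - b; overlapping intervals have distance 0.  Genes alone on their
    chromosome are always kept.  Idempotent: the surviving set is already
    mutually isolated.
    """
    genes = validate_genes(genes)
    keep_ids = []
    for _, sub in genes.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(sub) == 1:
            keep_ids.extend(sub["gene_id"])
            continue
        # pairwise gaps; fine at annotation scale, exact for nested intervals
        gap = np.maximum(starts[None, :] - ends[:, None], starts[:, None] - ends[None, :])
        gap = np.maximum(gap, 0)
        np.fill_diagonal(gap, np.iinfo(np.int64).max)
        nearest = gap.min(axis=1)
        keep_ids.extend(sub.loc[nearest >= min_gap, "gene_id"])
    return genes[genes["gene_id"].isin(set(keep_ids))].reset_index(drop=True)


def window_midpoint_positions(gene, window_starts, window_ends):
    """Relative positions of fixed-width windows, by window midpoint."""
    mids = (np.asarray(window_starts, dtype=float) + np.asarray(window_ends, dtype=float)) / 2
    return relative_position(gene, mids)
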
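"""Readers and writers for the genomic text formats the pipeline touches.

All coordinates in files are 0-based half-open (BED convention).  Missing
values in tidy outputs are written as "NA".  Formats:

* BED4 chromatin-state tracks: chrom, start, end, integer state id.
* BED12 gene models (strand required; the gene body is one interval).
* GFF3 gene models (``gene`` features; 1-based inclusive on disk, converted
  to 0-based half-open in memory).
* bedGraph-like CpG methylation: chrom, start, end(=start+1), percent.
* Tab-delimited tables with mandatory header rows for expression matrices,
  haplotype probabilities, covariates and founder SNPs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

NA = "NA"


@dataclass
class StateTrack:
    """One strain's chromatin-state segmentation: sorted disjoint segments."""

    strain: str
    segments: pd.DataFrame  # chrom, start, end, state

    def __post_init__(self):
        self.segments = self.segments.reset_index(drop=True)
        seg = self.segments
        for chrom, sub in seg.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (np.diff(starts) < 0).any():
                raise ValueError(f"track {self.strain}: segments unsorted on {chrom}")
            bad = np.flatnonzero(ends[:-1] > starts[1:])
            if len(bad):
                i = sub.index[bad[0]]
                raise ValueError(
                    f"track {self.strain}: overlapping segments on {chrom}: "
                    f"rows {i} and {i+1} "
                    f"([{seg.loc[i,'start']},{seg.loc[i,'end']}) vs "
                    f"[{seg.loc[i+1,'start']},{seg.loc[i+1,'end']}))")


def read_state_track(path, strain: str | None = None) -> StateTrack:
    """Read a BED4 state track; unsorted input is sorted with a warning."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 BED columns")
            try:
                state = int(parts[3])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer state {parts[3]!r}")
            rows.append((parts[0], int(parts[1]), int(parts[2]), state, ln))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "line"])
    sorted_df = df.sort_values(["chrom", "start", "end"], kind="stable")
    if not sorted_df.index.equals(df.index):
        warnings.warn(f"{path}: unsorted segments; sorting", UserWarning, stacklevel=2)
    # overlap check with original line numbers in the message
    for chrom, sub in sorted_df.groupby("chrom", sort=False):
        ends = sub["end"].to_numpy()
        starts = sub["start"].to_numpy()
        bad = np.flatnonzero(ends[:-1] > starts[1:])
        if len(bad):
            l1 = sub["line"].to_numpy()[bad[0]]
            l2 = sub["line"].to_numpy()[bad[0] + 1]
            raise ValueError(f"{path}: overlapping segments at lines {l1} and {l2}")
    return StateTrack(strain=strain or path.stem,
                      segments=sorted_df.drop(columns="line"))


def write_state_track(track: StateTrack, path) -> None:
    track.segments.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# genes

def read_bed12_genes(path) -> pd.DataFrame:
    """Gene bodies from a BED12 (or BED6+) file: name, strand required."""
    cols = ["gene_id", "chrom", "start", "end", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)
    if df.shape[1] < 6:
        raise ValueError("BED gene file needs >= 6 columns (strand required)")
    genes = df.iloc[:, [3, 0, 1, 2, 5]].copy()
    genes.columns = ["gene_id", "chrom", "start", "end", "strand"]
    return genes.reset_index(drop=True)


def write_bed12_genes(genes: pd.DataFrame, path) -> None:
    n = len(genes)
    sizes = (genes["end"] - genes["start"]).astype(str) + ","
    bed = pd.DataFrame({
        0: genes["chrom"], 1: genes["start"], 2: genes["end"],
        3: genes["gene_id"], 4: 0, 5: genes["strand"],
        6: genes["start"], 7: genes["end"], 8: "0,0,0", 9: 1,
        10: sizes, 11: "0,",
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gff3_genes(path, feature: str = "gene") -> pd.DataFrame:
    """Gene bodies from GFF3 ``gene`` lines (converted to 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
            rows.append((gid, parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# methylation

def read_methylation_bedgraph(path) -> pd.DataFrame:
    """Single-base methylation calls: chrom, start, end, percent -> chrom/pos/percent."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "percent"])
    return pd.DataFrame({"chrom": df["chrom"], "pos": df["start"].astype(int),
                         "percent": df["percent"].astype(float)})


def write_methylation_bedgraph(calls: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"chrom": calls["chrom"], "start": calls["pos"].astype(int),
                        "end": calls["pos"].astype(int) + 1,
                        "percent": calls["percent"]})
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# delimited tables

def write_expression(expr: pd.DataFrame, path) -> None:
    """Expression matrix; (strain, replicate) columns flattened to strain:rep."""
    out = expr.copy()
    if isinstance(out.columns, pd.MultiIndex):
        out.columns = [f"{s}:{r}" for s, r in out.columns]
    out.to_csv(path, sep="\t", na_rep=NA, index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA)
    if all(":" in c for c in df.columns):
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split(":", 1)) for c in df.columns], names=["strain", "rep"])
    return df


def write_hap_probs(hap_probs: dict, path) -> None:
    """Long table: gene_id, individual, one column per founder."""
    frames = []
    for gene_id, df in hap_probs.items():
        f = df.reset_index(names="individual")
        f.insert(0, "gene_id", gene_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", na_rep=NA, index=False)


def read_hap_probs(path) -> dict:
    df = pd.read_csv(path, sep="\t", na_values=NA)
    out = {}
    for gene_id, sub in df.groupby("gene_id", sort=False):
        out[gene_id] = sub.drop(columns="gene_id").set_index("individual")
    return out


def write_table(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=NA, index_col=index_col)


# ---------------------------------------------------------------------------
# configuration & provenance

@dataclass
class PipelineConfig:
    """Run configuration: input paths, grid, thresholds, seed, outputs."""

    inputs: dict = field(default_factory=dict)
    grid_lo: float = -0.5
    grid_hi: float = 1.5
    n_bins: int = 42
    min_gap: int = 2000
    min_cpm: float = 1.0
    min_reps: int = 2
    emission_threshold: float = 0.3
    n_perm: int = 1000
    seed: int = 0
    covariates: list = field(default_factory=lambda: ["sex", "diet", "generation"])
    outdir: str = "epistate_out"

    def validate_paths(self) -> None:
        missing = [str(p) for p in self.inputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {', '.join(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def write_provenance(config: PipelineConfig, outdir, extra: dict | None = None) -> Path:
    """Record config hash, seed and package version alongside outputs."""
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    record = {
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }
    if extra:
        record.update(extra)
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path
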
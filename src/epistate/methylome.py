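"""Merged strain methylome, strain-specific CpG catalog, and methylation profiles.

Per-strain replicate CpG calls (percent methylation at single positions) are
merged into one methylome: at each site the percent is averaged over the
replicates that detected it and rounded to the nearest of {0, 50, 100},
reflecting that a CpG in a (near-)clonal tissue is unmethylated, hemi-
methylated or fully methylated.  Ties round upward (25 -> 50, 75 -> 100).

A CpG site is *strain specific* when it is present in every replicate of at
least one strain and absent from every replicate of at least one other
strain.  Where an analysis requires a value at a site a strain lacks, the
missing site is treated as 0% methylated (an absent CpG cannot be
methylated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import AssociationEffect, DegenerateDataWarning, _fit_eq1, \
    _strain_means, _zscore_rows, rank_normal
from .coords import BinGrid, BinnedProfile, bin_aggregate, relative_position, validate_genes


def round_methylation(percent) -> np.ndarray:
    """Round percent methylation to the nearest of {0, 50, 100}; ties up."""
    p = np.asarray(percent, dtype=float)
    out = np.where(p < 25, 0.0, np.where(p < 75, 50.0, 100.0))
    return out


@dataclass
class Methylome:
    """Merged multi-strain methylome.

    sites: sorted unique (chrom, pos) table.
    percent: sites x strains rounded percent in {0,50,100}; NaN = absent.
    n_detected: sites x strains replicate detection counts.
    n_reps: replicates per strain.
    """

    sites: pd.DataFrame
    percent: pd.DataFrame
    n_detected: pd.DataFrame
    n_reps: dict = field(default_factory=dict)

    @property
    def strains(self):
        return list(self.percent.columns)

    def percent_filled(self) -> pd.DataFrame:
        """Rounded percent with missing sites treated as 0% (unmethylated)."""
        return self.percent.fillna(0.0)

    def __len__(self):
        return len(self.sites)


def merge_replicates(calls: dict) -> Methylome:
    """Merge per-strain replicate CpG calls into a :class:`Methylome`.

    ``calls``: strain -> list of DataFrames (chrom, pos, percent), percent in
    [0, 100].  A site is present for a strain if detected in >= 1 replicate;
    its value is the replicate mean rounded to {0,50,100}.  Per-replicate
    detection counts are kept for the strain-specific predicate, where
    "present" means detected in all replicates.
    """
    for strain, reps in calls.items():
        for df in reps:
            p = df["percent"].to_numpy(dtype=float)
            if ((p < 0) | (p > 100)).any():
                raise ValueError(f"strain {strain}: percent outside [0, 100]")
    all_sites = pd.concat(
        [df[["chrom", "pos"]] for reps in calls.values() for df in reps],
        ignore_index=True,
    ).drop_duplicates().sort_values(["chrom", "pos"]).reset_index(drop=True)
    idx = pd.MultiIndex.from_frame(all_sites)
    percent = {}
    detected = {}
    n_reps = {}
    for strain, reps in calls.items():
        n_reps[strain] = len(reps)
        sums = pd.Series(0.0, index=idx)
        cnt = pd.Series(0, index=idx)
        for df in reps:
            s = df.set_index(["chrom", "pos"])["percent"].astype(float)
            s = s[~s.index.duplicated()]
            sums = sums.add(s.reindex(idx, fill_value=0.0), fill_value=0.0)
            cnt = cnt.add(s.notna().reindex(idx, fill_value=False).astype(int))
        with np.errstate(invalid="ignore"):
            mean = sums.to_numpy() / np.where(cnt.to_numpy() > 0, cnt.to_numpy(), np.nan)
        vals = np.full(len(idx), np.nan)
        det = cnt.to_numpy() > 0
        vals[det] = round_methylation(mean[det])
        percent[strain] = vals
        detected[strain] = cnt.to_numpy()
    return Methylome(
        sites=all_sites,
        percent=pd.DataFrame(percent, index=idx),
        n_detected=pd.DataFrame(detected, index=idx),
        n_reps=n_reps,
    )


@dataclass
class StrainSpecificCatalog:
    flags: pd.Series            # bool per site (aligned to methylome index)
    fraction: float             # flagged / total
    per_strain_presence: pd.Series  # among flagged sites, fraction present per strain


def strain_specific_sites(methylome: Methylome) -> StrainSpecificCatalog:
    """Catalog CpG sites present in all replicates of some strain and absent
    from all replicates of some other strain.  Invariant to strain order."""
    det = methylome.n_detected
    n_reps = pd.Series(methylome.n_reps)
    all_present = det.eq(n_reps, axis=1)
    all_absent = det.eq(0)
    flags = all_present.any(axis=1) & all_absent.any(axis=1)
    flagged = det[flags]
    presence = (flagged > 0).mean(axis=0) if flags.any() else pd.Series(
        np.nan, index=det.columns)
    return StrainSpecificCatalog(
        flags=flags,
        fraction=float(flags.mean()) if len(flags) else float("nan"),
        per_strain_presence=presence,
    )


# ---------------------------------------------------------------------------
# spatial profiles

def _sites_near_gene(sites: pd.DataFrame, gene, flank: int = 1000):
    """Index range of sorted sites within gene body +/- flank bp."""
    pos = sites["pos"].to_numpy()
    lo = np.searchsorted(pos, gene["start"] - flank, side="left")
    hi = np.searchsorted(pos, gene["end"] + flank, side="right")
    return lo, hi


def cpg_density_profile(methylome: Methylome, genes: pd.DataFrame, grid: BinGrid,
                        flank: int = 1000) -> BinnedProfile:
    """Mean inverse inter-CpG distance per bin around expressed genes.

    Each CpG carries 1 / (distance in bp to the next CpG downstream on the
    same chromosome); the last site of a chromosome contributes nothing.
    Values are placed at the site's gene-relative position and averaged per
    bin.  High values mean densely packed CpGs (CpG islands near the TSS).
    """
    genes = validate_genes(genes)
    positions, values = [], []
    for chrom, sub in methylome.sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if len(pos) < 2:
            continue
        inv = 1.0 / np.diff(pos)
        site_pos = pos[:-1]
        gsub = genes[genes["chrom"] == chrom]
        order = np.argsort(site_pos)
        sp, iv = site_pos[order], inv[order]
        for _, gene in gsub.iterrows():
            lo = np.searchsorted(sp, gene["start"] - flank, side="left")
            hi = np.searchsorted(sp, gene["end"] + flank, side="right")
            if hi <= lo:
                continue
            positions.append(relative_position(gene, sp[lo:hi]))
            values.append(iv[lo:hi])
    if not positions:
        return BinnedProfile(grid, np.full(grid.n_bins, np.nan),
                             np.zeros(grid.n_bins, dtype=np.int64))
    return bin_aggregate(np.concatenate(positions), np.concatenate(values),
                         grid, aggregator="mean")


def methylation_profile(methylome: Methylome, genes: pd.DataFrame, grid: BinGrid,
                        flank: int = 1000) -> BinnedProfile:
    """Median rounded percent methylation per bin, across sites and strains.

    Only observed (present) strain values contribute; the typical picture is
    an unmethylated valley at the TSS and high methylation intragenically.
    """
    genes = validate_genes(genes)
    perc = methylome.percent.to_numpy()
    positions, values = [], []
    for chrom, sub_idx in methylome.sites.groupby("chrom", sort=False).groups.items():
        sub = methylome.sites.loc[sub_idx]
        pos = sub["pos"].to_numpy()
        block = perc[sub_idx]
        for _, gene in genes[genes["chrom"] == chrom].iterrows():
            lo = np.searchsorted(pos, gene["start"] - flank, side="left")
            hi = np.searchsorted(pos, gene["end"] + flank, side="right")
            if hi <= lo:
                continue
            rel = relative_position(gene, pos[lo:hi])
            vals = block[lo:hi]
            for j in range(vals.shape[1]):
                ok = np.isfinite(vals[:, j])
                positions.append(rel[ok])
                values.append(vals[ok, j])
    if not positions:
        return BinnedProfile(grid, np.full(grid.n_bins, np.nan),
                             np.zeros(grid.n_bins, dtype=np.int64))
    return bin_aggregate(np.concatenate(positions), np.concatenate(values),
                         grid, aggregator="median")


# ---------------------------------------------------------------------------
# methylation-expression association

def gene_bin_methylation(methylome: Methylome, genes: pd.DataFrame, grid: BinGrid,
                         flank: int = 1000) -> dict:
    """Per-strain (genes x bins) mean percent methylation, missing sites = 0%.

    Bins that contain no CpG site at all for a gene are NaN (no observation);
    bins with sites that a given strain lacks contribute 0% for that strain.
    """
    genes = validate_genes(genes)
    strains = methylome.strains
    filled = methylome.percent_filled().to_numpy()
    mats = {s: np.full((len(genes), grid.n_bins), np.nan) for s in strains}
    for chrom, sub_idx in methylome.sites.groupby("chrom", sort=False).groups.items():
        sub = methylome.sites.loc[sub_idx]
        pos = sub["pos"].to_numpy()
        block = filled[sub_idx]
        for i, gene in genes[genes["chrom"] == chrom].iterrows():
            lo = np.searchsorted(pos, gene["start"] - flank, side="left")
            hi = np.searchsorted(pos, gene["end"] + flank, side="right")
            if hi <= lo:
                continue
            rel = relative_position(gene, pos[lo:hi])
            idx = grid.bin_index(rel)
            keep = idx >= 0
            if not keep.any():
                continue
            idx = idx[keep]
            vals = block[lo:hi][keep]
            counts = np.bincount(idx, minlength=grid.n_bins)
            for k, s in enumerate(strains):
                sums = np.bincount(idx, weights=vals[:, k], minlength=grid.n_bins)
                nz = counts > 0
                mats[s][i, nz] = sums[nz] / counts[nz]
    return {s: pd.DataFrame(m, index=genes["gene_id"],
                            columns=pd.RangeIndex(grid.n_bins, name="bin"))
            for s, m in mats.items()}


def associate_methylation_expression(methylome: Methylome, expr: pd.DataFrame,
                                     genes: pd.DataFrame, grid: BinGrid,
                                     context: str = "across_genes",
                                     flank: int = 1000) -> list[AssociationEffect]:
    """Position-dependent association of percent methylation with expression.

    Per bin, the predictor is the rank-normal mean percent methylation of
    CpGs in that bin (absent sites contribute 0%); contexts mirror the
    chromatin-state fits.  Only positional associations are computed — the
    effect of methylation on expression is position dependent, so a
    whole-gene summary is not meaningful.
    """
    if context not in ("across_genes", "across_strains"):
        raise ValueError(f"unknown context {context!r}")
    means = _strain_means(expr)
    meth = gene_bin_methylation(methylome, genes, grid, flank=flank)
    strains = [s for s in means.columns if s in meth]
    effects = []
    for b in range(grid.n_bins):
        if context == "across_genes":
            betas, los, his, r2s, ns = [], [], [], [], []
            for strain in strains:
                x = meth[strain][b]
                common = means.index.intersection(x.index)
                xv = x.loc[common].to_numpy(dtype=float)
                yv = means.loc[common, strain].to_numpy(dtype=float)
                ok = np.isfinite(xv) & np.isfinite(yv)
                xv, yv = xv[ok], yv[ok]
                if len(xv) < 10 or np.ptp(xv) == 0:
                    continue
                eff = _fit_eq1(rank_normal(yv), rank_normal(xv), "methylation",
                               context, bin=b)
                betas.append(eff.beta); los.append(eff.ci_lo); his.append(eff.ci_hi)
                r2s.append(eff.r2); ns.append(eff.n)
            if betas:
                effects.append(AssociationEffect(
                    state="methylation", beta=float(np.mean(betas)),
                    ci_lo=float(np.mean(los)), ci_hi=float(np.mean(his)),
                    r2=float(np.mean(r2s)), n=int(sum(ns)), context=context, bin=b))
        else:
            x_wide = pd.DataFrame({s: meth[s][b] for s in strains})
            common = means.index.intersection(x_wide.index)
            ez = _zscore_rows(means.loc[common, strains])
            pz = _zscore_rows(x_wide.loc[common])
            ok = ez.notna().all(axis=1) & pz.notna().all(axis=1)
            if ok.sum() < 10:
                continue
            y = ez[ok].to_numpy().ravel()
            x = pz[ok].to_numpy().ravel()
            effects.append(_fit_eq1(rank_normal(y), rank_normal(x),
                                    "methylation", context, bin=b))
    return effects


# ---------------------------------------------------------------------------
# chromatin-state conditioning

def condition_on_state(methylome: Methylome, tracks: dict, state: int):
    """Restrict the methylome to CpGs lying in a given chromatin state.

    Conditioning is per strain: a CpG stays present for strain s only if it
    falls inside one of strain s's segments of ``state``.  Returns
    (subset_methylome, summary) where summary holds the per-strain and
    pooled mean percent methylation of retained site-values.
    """
    keep = {}
    for strain in methylome.strains:
        mask = np.zeros(len(methylome), dtype=bool)
        track = tracks.get(strain)
        if track is None:
            keep[strain] = mask
            continue
        seg = track.segments[track.segments["state"] == state]
        for chrom, ss in seg.groupby("chrom", sort=False):
            sel = methylome.sites["chrom"] == chrom
            pos = methylome.sites.loc[sel, "pos"].to_numpy()
            starts = ss["start"].to_numpy()
            ends = ss["end"].to_numpy()
            j = np.searchsorted(starts, pos, side="right") - 1
            inside = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
            mask[np.flatnonzero(sel.to_numpy())[inside]] = True
        keep[strain] = mask
    if not any(m.any() for m in keep.values()):
        warnings.warn(f"state {state} absent from all tracks: empty subset",
                      DegenerateDataWarning, stacklevel=2)
    percent = methylome.percent.copy()
    n_detected = methylome.n_detected.copy()
    for strain, mask in keep.items():
        percent.loc[~mask, strain] = np.nan
        n_detected.loc[~mask, strain] = 0
    any_kept = n_detected.gt(0).any(axis=1).to_numpy()
    sub = Methylome(
        sites=methylome.sites[any_kept].reset_index(drop=True),
        percent=percent[any_kept],
        n_detected=n_detected[any_kept],
        n_reps=dict(methylome.n_reps),
    )
    per_strain_mean = sub.percent.mean(axis=0) if len(sub) else pd.Series(
        np.nan, index=methylome.percent.columns)
    all_vals = sub.percent.to_numpy()
    summary = {
        "state": state,
        "n_sites": int(len(sub)),
        "mean_percent": float(np.nanmean(all_vals)) if len(sub) and
        np.isfinite(all_vals).any() else float("nan"),
        "per_strain_mean": per_strain_mean,
    }
    return sub, summary
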
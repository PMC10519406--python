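"""Chromatin-state composition of gene bodies and its association with expression.

The model throughout is a marginal simple linear regression

    y_e = beta * x_s + epsilon

where y_e is rank-normal-transformed expression and x_s the rank-normal
state proportion (or per-bin state presence).  Each state is fit
independently: the quantities of interest are marginal effects, not a joint
decomposition.  Three contexts are supported:

* across genes — one fit per strain over genes, then pooled by averaging
  the per-strain effects and confidence bounds;
* across strains — expression and proportions z-scored per gene across
  strains, concatenated over genes, rank-normalized and fit once;
* positional — either of the above per spatial bin, with the predictor
  being the mean presence (0/1 window indicator) of the state in the bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtri
from scipy.stats import chi2, rankdata

from .coords import BinGrid, relative_position, validate_genes


class DegenerateDataWarning(UserWarning):
    pass


def rank_normal(values, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Midranks are used for ties; ranks r are mapped through the inverse
    standard normal CDF at (r - offset) / (n - 2*offset + 1), i.e.
    (r - 0.375) / (n + 0.25) at the default.  A constant vector maps to all
    zeros and raises a :class:`DegenerateDataWarning`.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("rank_normal requires a 1-D array of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("rank_normal requires finite values")
    if np.ptp(x) == 0:
        warnings.warn("constant input: rank-normal scores degenerate to 0",
                      DegenerateDataWarning, stacklevel=2)
        return np.zeros_like(x)
    r = rankdata(x)
    n = x.size
    return ndtri((r - offset) / (n - 2 * offset + 1))


@dataclass
class AssociationEffect:
    """One marginal effect: standardized slope with 95% CI and R^2."""

    state: object
    beta: float
    ci_lo: float
    ci_hi: float
    r2: float
    n: int
    context: str
    bin: int | None = None

    def to_dict(self):
        return asdict(self)


def effects_to_frame(effects) -> pd.DataFrame:
    return pd.DataFrame([e.to_dict() for e in effects])


def _fit_eq1(y: np.ndarray, x: np.ndarray, state, context: str, bin=None) -> AssociationEffect:
    """OLS of y on x with intercept; slope, 95% CI, R^2."""
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    lo, hi = fit.conf_int()[1]
    return AssociationEffect(
        state=state, beta=float(fit.params[1]), ci_lo=float(lo), ci_hi=float(hi),
        r2=float(fit.rsquared), n=int(len(y)), context=context, bin=bin,
    )


# ---------------------------------------------------------------------------
# state proportions

def state_proportions(track, genes: pd.DataFrame, n_states: int) -> pd.DataFrame:
    """Fraction of each gene body covered by each chromatin state.

    ``track`` is a :class:`~epistate.io.StateTrack` (sorted disjoint
    segments).  Returns a genes x states DataFrame whose rows sum to the
    covered fraction of the gene (1 when the track fully covers it).  Genes
    with zero track coverage get an all-NaN row and a warning.
    """
    genes = validate_genes(genes)
    out = np.zeros((len(genes), n_states))
    covered = np.zeros(len(genes))
    for chrom, seg in track.segments.groupby("chrom", sort=False):
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        states = seg["state"].to_numpy()
        sub = genes[genes["chrom"] == chrom]
        for i, row in sub.iterrows():
            g0, g1 = row["start"], row["end"]
            lo = np.searchsorted(ends, g0, side="right")
            hi = np.searchsorted(starts, g1, side="left")
            if hi <= lo:
                continue
            ov = np.minimum(ends[lo:hi], g1) - np.maximum(starts[lo:hi], g0)
            ov = np.clip(ov, 0, None)
            np.add.at(out[i], states[lo:hi] - 1, ov)
            covered[i] += ov.sum()
    lengths = (genes["end"] - genes["start"]).to_numpy(dtype=float)
    props = out / lengths[:, None]
    uncovered = covered == 0
    if uncovered.any():
        warnings.warn(
            f"{int(uncovered.sum())} gene(s) with no track coverage: rows set to NaN",
            DegenerateDataWarning, stacklevel=2)
        props[uncovered] = np.nan
    return pd.DataFrame(
        props, index=genes["gene_id"],
        columns=pd.RangeIndex(1, n_states + 1, name="state"),
    )


# ---------------------------------------------------------------------------
# association fits

def _strain_means(expr: pd.DataFrame) -> pd.DataFrame:
    """Collapse a genes x (strain, replicate) matrix to strain means."""
    if isinstance(expr.columns, pd.MultiIndex):
        return expr.T.groupby(level=0).mean().T
    return expr


def associate_across_genes(expr: pd.DataFrame, props: dict, state: int):
    """Per-strain across-gene fits for one state, plus the pooled effect.

    ``expr``: genes x (strain, replicate) or genes x strain; replicates are
    averaged per strain before rank-normalization.  ``props``: mapping
    strain -> genes x states proportion table.  Returns
    (per_strain_effects, pooled_effect, anova_p).  The pooled effect is the
    arithmetic mean of the per-strain betas and CI bounds; ``anova_p`` is a
    one-way strain-homogeneity test of the per-strain betas (Cochran's Q
    against chi-square, weighting each strain by its bootstrap SE), so that
    homogeneous effects give a calibrated, non-significant p.
    """
    means = _strain_means(expr)
    per_strain = {}
    boot = {}
    rng = np.random.default_rng(0)  # bootstrap resampling only, fixed
    for strain in means.columns:
        if strain not in props:
            continue
        p = props[strain]
        common = means.index.intersection(p.index)
        y_raw = means.loc[common, strain].to_numpy(dtype=float)
        x_raw = p.loc[common, state].to_numpy(dtype=float)
        ok = np.isfinite(y_raw) & np.isfinite(x_raw)
        y_raw, x_raw = y_raw[ok], x_raw[ok]
        if len(y_raw) < 10:
            raise ValueError(f"need >= 10 genes per strain, got {len(y_raw)}")
        if np.ptp(x_raw) == 0:
            warnings.warn(f"state {state} constant in strain {strain}; effect missing",
                          DegenerateDataWarning, stacklevel=2)
            continue
        eff = _fit_eq1(rank_normal(y_raw), rank_normal(x_raw), state, "across_genes")
        per_strain[strain] = eff
        # bootstrap betas for the homogeneity ANOVA
        n = len(y_raw)
        bb = []
        for _ in range(100):
            idx = rng.integers(0, n, n)
            xb, yb = x_raw[idx], y_raw[idx]
            if np.ptp(xb) == 0:
                continue
            yr, xr = rank_normal(yb), rank_normal(xb)
            xr_c = xr - xr.mean()
            bb.append(float(xr_c @ (yr - yr.mean()) / (xr_c @ xr_c)))
        boot[strain] = bb
    if not per_strain:
        raise ValueError(f"state {state}: no strain yielded a fit")
    betas = np.array([e.beta for e in per_strain.values()])
    los = np.array([e.ci_lo for e in per_strain.values()])
    his = np.array([e.ci_hi for e in per_strain.values()])
    pooled = AssociationEffect(
        state=state, beta=float(betas.mean()), ci_lo=float(los.mean()),
        ci_hi=float(his.mean()),
        r2=float(np.mean([e.r2 for e in per_strain.values()])),
        n=int(sum(e.n for e in per_strain.values())), context="across_genes_pooled",
    )
    ses = np.array([np.std(boot[s], ddof=1) if len(boot.get(s, [])) >= 2 else np.nan
                    for s in per_strain])
    ok = np.isfinite(ses) & (ses > 0)
    if ok.sum() >= 2:
        w = 1.0 / ses[ok] ** 2
        bw = float((w * betas[ok]).sum() / w.sum())
        q = float((w * (betas[ok] - bw) ** 2).sum())
        anova_p = float(chi2.sf(q, ok.sum() - 1))
    else:
        anova_p = np.nan
    return per_strain, pooled, anova_p


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score across columns; zero-variance rows become NaN."""
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    z = df.sub(mu, axis=0).div(sd, axis=0)
    z[sd == 0] = np.nan
    return z


def associate_across_strains(expr: pd.DataFrame, props: dict, state: int) -> AssociationEffect:
    """Across-strain fit for one state.

    Expression (strain means) and state proportions are each z-scored per
    gene across strains; all standardized values are concatenated into two
    long vectors, rank-normalized and fit with the simple-regression model.
    Genes with zero cross-strain variance in either variable are dropped.
    """
    means = _strain_means(expr)
    strains = [s for s in means.columns if s in props]
    if len(strains) < 2:
        raise ValueError("across-strain association requires >= 2 strains")
    prop_wide = pd.DataFrame({s: props[s][state] for s in strains})
    common = means.index.intersection(prop_wide.index)
    ez = _zscore_rows(means.loc[common, strains])
    pz = _zscore_rows(prop_wide.loc[common])
    ok = ez.notna().all(axis=1) & pz.notna().all(axis=1)
    if not ok.any():
        raise ValueError(
            "no gene varies across strains in both expression and state "
            f"{state} proportion; across-strain model is undefined")
    y = ez[ok].to_numpy().ravel()
    x = pz[ok].to_numpy().ravel()
    return _fit_eq1(rank_normal(y), rank_normal(x), state, "across_strains")


def associate_per_gene(expr: pd.DataFrame, props: dict, state: int) -> pd.DataFrame:
    """Per-gene across-strain effect: one slope + 95% CI per gene.

    For each gene, expression strain means are regressed on the state
    proportion across strains (n = number of strains).  Genes with a
    constant predictor are skipped.  Used for null-calibration checks.
    """
    means = _strain_means(expr)
    strains = [s for s in means.columns if s in props]
    prop_wide = pd.DataFrame({s: props[s][state] for s in strains})
    common = means.index.intersection(prop_wide.index)
    rows = []
    for g in common:
        x = prop_wide.loc[g].to_numpy(dtype=float)
        y = means.loc[g, strains].to_numpy(dtype=float)
        if np.ptp(x[np.isfinite(x)]) == 0 or not np.isfinite(x).all():
            continue
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        lo, hi = fit.conf_int()[1]
        rows.append((g, float(fit.params[1]), float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["gene_id", "beta", "ci_lo", "ci_hi"]).set_index("gene_id")


def positional_state_presence(tracks: dict, genes: pd.DataFrame, grid: BinGrid,
                              state: int) -> dict:
    """Per-strain (genes x bins) mean presence of one state.

    Each track window is assigned the gene-relative position of its midpoint;
    within a bin the 0/1 state indicator of contributing windows is averaged.
    Bins with no windows for a gene are NaN.
    """
    genes = validate_genes(genes)
    out = {}
    for strain, track in tracks.items():
        mat = np.full((len(genes), grid.n_bins), np.nan)
        counts = np.zeros((len(genes), grid.n_bins))
        hits = np.zeros((len(genes), grid.n_bins))
        for chrom, seg in track.segments.groupby("chrom", sort=False):
            starts = seg["start"].to_numpy()
            ends = seg["end"].to_numpy()
            states = seg["state"].to_numpy()
            mids = (starts + ends) / 2.0
            for i, row in genes[genes["chrom"] == chrom].iterrows():
                L = row["end"] - row["start"]
                span = int(np.ceil((grid.hi - 1) * L)) if grid.hi > 1 else 0
                span_lo = int(np.ceil(-grid.lo * L)) if grid.lo < 0 else 0
                lo = np.searchsorted(mids, row["start"] - span_lo, side="left")
                hi = np.searchsorted(mids, row["end"] + span, side="right")
                if hi <= lo:
                    continue
                rel = relative_position(row, mids[lo:hi])
                idx = grid.bin_index(rel)
                keep = idx >= 0
                np.add.at(counts[i], idx[keep], 1)
                np.add.at(hits[i], idx[keep], (states[lo:hi][keep] == state))
        nz = counts > 0
        mat[nz] = hits[nz] / counts[nz]
        out[strain] = pd.DataFrame(mat, index=genes["gene_id"],
                                   columns=pd.RangeIndex(grid.n_bins, name="bin"))
    return out


def associate_positional(expr: pd.DataFrame, tracks: dict, genes: pd.DataFrame,
                         grid: BinGrid, state: int,
                         context: str = "across_genes") -> list[AssociationEffect]:
    """Per-bin association of one state's local presence with expression.

    context="across_genes": per bin, per-strain fits over genes pooled by
    averaging (as in :func:`associate_across_genes`).  context=
    "across_strains": per bin, per-gene standardization across strains then
    a single concatenated fit.  Bins with no observations (or a constant
    predictor) yield no effect — missing, never zero-filled.
    """
    if context not in ("across_genes", "across_strains"):
        raise ValueError(f"unknown context {context!r}")
    means = _strain_means(expr)
    presence = positional_state_presence(tracks, genes, grid, state)
    strains = [s for s in means.columns if s in presence]
    effects = []
    for b in range(grid.n_bins):
        if context == "across_genes":
            betas, los, his, r2s, ns = [], [], [], [], []
            for strain in strains:
                x = presence[strain][b]
                common = means.index.intersection(x.index)
                xv = x.loc[common].to_numpy(dtype=float)
                yv = means.loc[common, strain].to_numpy(dtype=float)
                ok = np.isfinite(xv) & np.isfinite(yv)
                xv, yv = xv[ok], yv[ok]
                if len(xv) < 10 or np.ptp(xv) == 0:
                    continue
                eff = _fit_eq1(rank_normal(yv), rank_normal(xv), state, context, bin=b)
                betas.append(eff.beta); los.append(eff.ci_lo); his.append(eff.ci_hi)
                r2s.append(eff.r2); ns.append(eff.n)
            if betas:
                effects.append(AssociationEffect(
                    state=state, beta=float(np.mean(betas)), ci_lo=float(np.mean(los)),
                    ci_hi=float(np.mean(his)), r2=float(np.mean(r2s)),
                    n=int(sum(ns)), context=context, bin=b))
        else:
            x_wide = pd.DataFrame({s: presence[s][b] for s in strains})
            common = means.index.intersection(x_wide.index)
            ez = _zscore_rows(means.loc[common, strains])
            pz = _zscore_rows(x_wide.loc[common])
            ok = ez.notna().all(axis=1) & pz.notna().all(axis=1)
            if ok.sum() < 10:
                continue
            y = ez[ok].to_numpy().ravel()
            x = pz[ok].to_numpy().ravel()
            effects.append(_fit_eq1(rank_normal(y), rank_normal(x), state, context, bin=b))
    return effects


# ---------------------------------------------------------------------------
# expression filter

def filter_expression(cpm: pd.DataFrame, min_cpm: float = 1.0, min_reps: int = 2):
    """Drop transcripts with < ``min_cpm`` in ``min_reps`` or more replicates.

    Applied over all replicate columns jointly.  Returns (filtered, report)
    where report has kept/dropped counts.
    """
    below = (cpm < min_cpm).sum(axis=1)
    keep = below < min_reps
    report = {"n_in": int(len(cpm)), "n_kept": int(keep.sum()),
              "n_dropped": int((~keep).sum())}
    return cpm[keep], report
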
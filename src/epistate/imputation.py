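"""Imputation of founder genomic features into an outbred population.

Each Diversity Outbred (DO) individual's genome is a mosaic of eight founder
haplotypes, summarized near any locus by an individuals x founders matrix of
haplotype probabilities.  A founder feature — the chromatin-state one-hot
code, SNP-allele one-hot code, or percent methylation along a gene — is a
founders x levels x positions array; multiplying the two imputes the
expected local feature for every DO individual:

    imputed[i, l, p] = sum_f haps[i, f] * founder[f, l, p]

Association scans then regress (covariate-residualized) DO expression of a
transcript on one imputed level at one position at a time, so that every
feature class is tested with a single degree of freedom and variance
explained (R^2) is comparable across classes with different numbers of
levels (8 haplotypes, 14 states, 4 SNP alleles, 1 methylation level).

Because any imputed feature inherits association from the haplotypes it was
imputed through, significance is assessed against a permutation null that
shuffles founder labels on the feature array (leaving haplotype
probabilities and expression untouched), re-imputes and re-scans.  The
empirical p-value is the fraction of permutations whose max R^2 meets or
exceeds the observed one — with no +1 correction, so p = 0 is possible and
is flagged as "< 1/n_perm".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kruskal, kstest


def impute_feature(haps: np.ndarray, founder: np.ndarray) -> np.ndarray:
    """Probability-weighted mixture of founder features.

    haps: (individuals, F); founder: (F, levels, positions).  Linear in
    haps; one-hot haplotype rows reproduce the founder's feature exactly,
    and for one-hot founder features level-sums stay 1 wherever haplotype
    rows sum to 1.
    """
    haps = np.asarray(haps, dtype=float)
    founder = np.asarray(founder, dtype=float)
    if haps.ndim != 2 or founder.ndim != 3 or haps.shape[1] != founder.shape[0]:
        raise ValueError(
            f"dimension mismatch: haps {haps.shape} vs founder {founder.shape}")
    return np.einsum("if,flp->ilp", haps, founder)


def residualize(variables: np.ndarray, covariates: pd.DataFrame | np.ndarray | None):
    """Residuals of each variable after projecting onto covariates + intercept.

    variables: (n, ...) array; the first axis indexes individuals.  Collinear
    covariate columns are handled by a least-squares pseudo-inverse fit (a
    warning is issued when the design is rank deficient).  With no
    covariates the variables are simply centered.
    """
    v = np.asarray(variables, dtype=float)
    n = v.shape[0]
    if covariates is None or (hasattr(covariates, "shape") and
                              np.size(covariates) == 0):
        return v - v.reshape(n, -1).mean(axis=0).reshape(v.shape[1:])
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows must match individuals")
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient covariate design; collinear columns "
                      "absorbed by least squares", UserWarning, stacklevel=2)
    flat = v.reshape(n, -1)
    coef, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ coef
    return resid.reshape(v.shape)


@dataclass
class ScanResult:
    """Single-df scan over (level, position) cells for one transcript."""

    beta: np.ndarray   # (levels, positions); NaN where predictor constant
    r2: np.ndarray     # (levels, positions)
    n: int
    levels: list = field(default_factory=list)
    positions: np.ndarray | None = None

    def max_r2(self) -> float:
        return float(np.nanmax(self.r2)) if np.isfinite(self.r2).any() else float("nan")

    def argmax(self):
        """(level index, position index) of the maximum R^2."""
        flat = np.where(np.isfinite(self.r2), self.r2, -np.inf)
        l, p = np.unravel_index(np.argmax(flat), flat.shape)
        return int(l), int(p)


def single_df_scan(expr_resid: np.ndarray, imputed: np.ndarray,
                   levels=None, positions=None) -> ScanResult:
    """Simple regression of expression on each imputed (level, position) cell.

    Closed-form over all cells at once: beta = Sxy/Sxx, R^2 = Sxy^2/(Sxx*Syy).
    Cells with a constant predictor are NaN (missing), not zero.
    """
    y = np.asarray(expr_resid, dtype=float)
    X = np.asarray(imputed, dtype=float)
    n = y.shape[0]
    if X.shape[0] != n:
        raise ValueError("imputed array rows must match individuals")
    if n < 20:
        raise ValueError("single-df scan requires >= 20 individuals")
    yc = y - y.mean()
    syy = yc @ yc
    Xc = X - X.mean(axis=0)
    sxx = np.einsum("ilp,ilp->lp", Xc, Xc)
    sxy = np.einsum("i,ilp->lp", yc, Xc)
    # a predictor with negligible spread is constant — including the float
    # noise residualization leaves on an all-ones indicator column
    ms = np.einsum("ilp,ilp->lp", X, X) / n
    tol_sd = 1e-8 * np.maximum(1.0, np.sqrt(ms))
    ok = sxx > n * tol_sd ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
        r2 = np.where(ok, sxy ** 2 / (np.where(ok, sxx, 1.0) * syy), np.nan)
    if syy == 0:
        r2 = np.full_like(beta, np.nan)
    return ScanResult(beta=beta, r2=r2, n=n,
                      levels=list(levels) if levels is not None else [],
                      positions=np.asarray(positions) if positions is not None else None)


def class_max_r2(scans: dict) -> pd.DataFrame:
    """Per-transcript, per-feature-class maximum R^2 over levels x positions.

    ``scans``: transcript -> {class_name -> ScanResult}.  Returns a tidy
    transcripts x classes table of maxima (the paired-comparison quantity).
    """
    rows = {}
    for transcript, by_class in scans.items():
        rows[transcript] = {cls: scan.max_r2() for cls, scan in by_class.items()}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("transcript")


@dataclass
class PermutationNull:
    observed_r2: float
    permuted_r2: np.ndarray
    n_perm: int

    @property
    def pvalue(self) -> float:
        return empirical_pvalue(self.observed_r2, self.permuted_r2)

    @property
    def below_resolution(self) -> bool:
        """True when no permutation reached the observed R^2 (p reported as 0,
        interpret as < 1/n_perm)."""
        return self.pvalue == 0.0


def permutation_null(founder: np.ndarray, haps: np.ndarray,
                     expr_resid: np.ndarray, n_perm: int = 1000,
                     rng=None, seed=None) -> PermutationNull:
    """Founder-label permutation null for one transcript's feature scan.

    Each permutation shuffles the founder axis of the feature array,
    re-imputes and re-scans; haplotype probabilities and expression stay
    fixed, preserving the haplotype-expression association while breaking
    the feature-haplotype assignment.  The statistic is the max R^2 over
    levels x positions.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    F = founder.shape[0]
    obs = single_df_scan(expr_resid, impute_feature(haps, founder)).max_r2()
    perms = np.empty(n_perm)
    for k in range(n_perm):
        order = rng.permutation(F)
        perms[k] = single_df_scan(
            expr_resid, impute_feature(haps, founder[order])).max_r2()
    return PermutationNull(observed_r2=obs, permuted_r2=perms, n_perm=n_perm)


def transcript_rng(global_seed: int, transcript_id) -> np.random.Generator:
    """Independent, reproducible RNG stream per transcript.

    Seeded from (global_seed, stable hash of the transcript id) so results
    do not depend on the order transcripts are processed in.
    """
    h = 2166136261
    for ch in str(transcript_id).encode():
        h = ((h ^ ch) * 16777619) % (1 << 32)  # FNV-1a
    return np.random.default_rng(np.random.SeedSequence([int(global_seed), h]))


def empirical_pvalue(observed_r2: float, permuted_r2s) -> float:
    """Fraction of permutations meeting or exceeding the observed R^2."""
    perms = np.asarray(permuted_r2s, dtype=float)
    if perms.size < 1:
        raise ValueError("need at least one permutation")
    return float(np.count_nonzero(perms >= observed_r2) / perms.size)


@dataclass
class UniformityReport:
    ks_stat: float
    ks_pvalue: float
    kruskal_stat: float
    kruskal_pvalue: float
    n: int

    def rejects(self, alpha: float = 0.01) -> bool:
        return self.ks_pvalue < alpha


def uniformity_check(pvalues) -> UniformityReport:
    """Test a set of empirical p-values for uniformity on (0, 1).

    Reports a one-sample Kolmogorov-Smirnov statistic against U(0,1) and a
    rank-based two-sample comparison (Kruskal-Wallis) of the observed
    p-values against a deterministic uniform reference grid.  A uniform
    distribution means the feature carries no association beyond the
    imputation itself; an excess of small p-values means it does.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 20:
        raise ValueError("uniformity check requires >= 20 p-values")
    ks = kstest(p, "uniform")
    ref = (np.arange(p.size) + 0.5) / p.size
    kw = kruskal(p, ref)
    return UniformityReport(ks_stat=float(ks.statistic), ks_pvalue=float(ks.pvalue),
                            kruskal_stat=float(kw.statistic),
                            kruskal_pvalue=float(kw.pvalue), n=int(p.size))


# ---------------------------------------------------------------------------
# per-gene report

@dataclass
class GeneReport:
    """Aligned per-position view of one gene's imputation results.

    r2_by_class: positions x classes max-over-levels R^2 profile.
    founder_states / founder_snps / founder_methylation: founders x positions.
    haplotype_beta: founders x positions scan slopes.
    founder_expression: per-founder mean expression in the founder panel.
    flagged: positions where a non-haplotype class beats the best
    single-haplotype R^2 anywhere in the gene.
    """

    gene_id: str
    positions: np.ndarray
    r2_by_class: pd.DataFrame
    founder_states: pd.DataFrame | None
    founder_snps: pd.DataFrame | None
    founder_methylation: pd.DataFrame | None
    haplotype_beta: pd.DataFrame | None
    founder_expression: pd.Series | None
    flagged: np.ndarray
    warnings: list = field(default_factory=list)


def gene_report(gene_id: str, scans: dict, positions: np.ndarray,
                founder_states: pd.DataFrame | None = None,
                founder_snps: pd.DataFrame | None = None,
                founder_methylation: pd.DataFrame | None = None,
                founder_expression: pd.Series | None = None) -> GeneReport:
    """Assemble the per-gene, per-position report.

    ``scans``: class name -> ScanResult for this gene; must include a
    "haplotype" class for the reference line.  Missing panels produce a
    partial report with a warning rather than an error.
    """
    positions = np.asarray(positions)
    warns = []
    profiles = {}
    for cls, scan in scans.items():
        with np.errstate(invalid="ignore"):
            prof = np.where(np.isfinite(scan.r2).any(axis=0),
                            np.nanmax(np.where(np.isfinite(scan.r2), scan.r2, -np.inf),
                                      axis=0), np.nan)
        # snap this class's scan positions onto the reference grid (nearest),
        # keeping the max where several scan positions land on one grid point
        scan_pos = scan.positions if scan.positions is not None else positions[:len(prof)]
        aligned = np.full(len(positions), np.nan)
        if len(scan_pos):
            nearest = np.abs(np.asarray(scan_pos, dtype=float)[:, None]
                             - positions[None, :].astype(float)).argmin(axis=1)
            for src, dst in enumerate(nearest):
                v = prof[src]
                if np.isnan(v):
                    continue
                aligned[dst] = v if np.isnan(aligned[dst]) else max(aligned[dst], v)
        profiles[cls] = aligned
    r2_by_class = pd.DataFrame(profiles, index=pd.Index(positions, name="position"))
    if "haplotype" in scans:
        hap_best = scans["haplotype"].max_r2()
        others = [c for c in r2_by_class.columns if c != "haplotype"]
        if others and np.isfinite(hap_best):
            non_hap = r2_by_class[others].max(axis=1).to_numpy()
            flagged = np.nan_to_num(non_hap, nan=-np.inf) > hap_best
        else:
            flagged = np.zeros(len(positions), dtype=bool)
    else:
        warns.append("no haplotype scan provided; flagging skipped")
        hap_best = float("nan")
        flagged = np.zeros(len(positions), dtype=bool)
    hb = None
    if "haplotype" in scans:
        scan = scans["haplotype"]
        hb_cols = scan.positions if scan.positions is not None \
            else np.arange(scan.beta.shape[1])
        hb = pd.DataFrame(scan.beta, index=scan.levels or None,
                          columns=pd.Index(hb_cols, name="position"))
    for name, panel in [("founder state track", founder_states),
                        ("founder SNPs", founder_snps),
                        ("founder methylation", founder_methylation),
                        ("founder expression", founder_expression)]:
        if panel is None:
            warns.append(f"{name} not provided; panel omitted")
    return GeneReport(
        gene_id=gene_id, positions=positions, r2_by_class=r2_by_class,
        founder_states=founder_states, founder_snps=founder_snps,
        founder_methylation=founder_methylation,
        haplotype_beta=hb, founder_expression=founder_expression,
        flagged=flagged, warnings=warns,
    )
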
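"""High-level orchestration of the DO imputation-and-scan workflow.

Given a founder panel and a DO population, these helpers build the founder
feature arrays per gene, residualize covariates, run single-df scans for
every feature class, collect per-class max-R^2 tables, and drive the
founder-label permutation null.  The position grid for scans is every
founder-track window midpoint from 1 kb upstream of the TSS to 1 kb
downstream of the TES (SNP scans use SNP coordinates in that span).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imputation import (
    GeneReport,
    PermutationNull,
    ScanResult,
    empirical_pvalue,
    gene_report,
    impute_feature,
    permutation_null,
    residualize,
    single_df_scan,
    transcript_rng,
)
from .sim import DOPopulation, FounderPanel, founder_feature_array, states_at

FEATURE_CLASSES = ("haplotype", "state", "snp", "methylation")


def _covariate_matrix(do_pop: DOPopulation, covariates) -> np.ndarray | None:
    cols = [c for c in covariates if c in do_pop.covariates.columns]
    if not cols:
        return None
    return do_pop.covariates[cols].to_numpy(dtype=float)


def scan_gene(panel: FounderPanel, do_pop: DOPopulation, gene_id: str,
              classes=FEATURE_CLASSES,
              covariates=("sex", "diet", "generation")) -> dict:
    """Run the single-df scan for one transcript over each feature class.

    Expression and all imputed predictors are residualized on the covariate
    columns before fitting, so covariate variance is excluded from every
    R^2.  Returns class name -> :class:`ScanResult`.
    """
    C = _covariate_matrix(do_pop, covariates)
    y = residualize(do_pop.expression[gene_id].to_numpy(dtype=float), C)
    haps = do_pop.hap_probs[gene_id].to_numpy(dtype=float)
    out = {}
    for cls in classes:
        if cls == "haplotype":
            imputed = haps[:, :, None]
            positions = np.array([_marker_position(panel, gene_id)])
            levels = do_pop.founders
        else:
            founder, positions, levels = founder_feature_array(
                panel, gene_id, cls, founders=do_pop.founders)
            if founder.shape[2] == 0:
                out[cls] = ScanResult(beta=np.empty((founder.shape[1], 0)),
                                      r2=np.empty((founder.shape[1], 0)),
                                      n=len(y), levels=list(levels),
                                      positions=positions)
                continue
            imputed = impute_feature(haps, founder)
        out[cls] = single_df_scan(y, residualize(imputed, C),
                                  levels=levels, positions=positions)
    return out


def _marker_position(panel: FounderPanel, gene_id: str) -> int:
    g = panel.genes.set_index("gene_id").loc[gene_id]
    return int(g["end"] - 1) if g["strand"] == "-" else int(g["start"])


def scan_all(panel: FounderPanel, do_pop: DOPopulation, gene_ids=None,
             classes=FEATURE_CLASSES,
             covariates=("sex", "diet", "generation")) -> dict:
    gene_ids = list(gene_ids) if gene_ids is not None else list(panel.genes["gene_id"])
    return {g: scan_gene(panel, do_pop, g, classes, covariates) for g in gene_ids}


def permutation_pvalues(panel: FounderPanel, do_pop: DOPopulation,
                        feature: str = "state", n_perm: int = 1000,
                        seed: int = 0, gene_ids=None,
                        covariates=("sex", "diet", "generation")) -> pd.DataFrame:
    """Founder-permutation empirical p-values for one feature class.

    One independent RNG stream per transcript (seeded from the global seed
    and the transcript id) keeps results order-independent.  Covariates are
    residualized out of expression and of every (re-)imputed predictor
    before each scan.  Returns a table (observed_r2, pvalue, n_perm).
    """
    gene_ids = list(gene_ids) if gene_ids is not None else list(panel.genes["gene_id"])
    C = _covariate_matrix(do_pop, covariates)
    rows = []
    for gene_id in gene_ids:
        y = residualize(do_pop.expression[gene_id].to_numpy(dtype=float), C)
        haps = do_pop.hap_probs[gene_id].to_numpy(dtype=float)
        founder, positions, _ = founder_feature_array(
            panel, gene_id, feature, founders=do_pop.founders)
        if founder.shape[2] == 0:
            rows.append((gene_id, np.nan, np.nan))
            continue
        rng = transcript_rng(seed, gene_id)
        obs = single_df_scan(
            y, residualize(impute_feature(haps, founder), C)).max_r2()
        if not np.isfinite(obs):
            # feature monomorphic across founders everywhere in the span
            rows.append((gene_id, np.nan, np.nan))
            continue
        perms = np.empty(n_perm)
        F = founder.shape[0]
        for k in range(n_perm):
            order = rng.permutation(F)
            perms[k] = single_df_scan(
                y, residualize(impute_feature(haps, founder[order]), C)).max_r2()
        rows.append((gene_id, obs, empirical_pvalue(obs, perms)))
    return pd.DataFrame(rows, columns=["gene_id", "observed_r2", "pvalue"]) \
        .set_index("gene_id").assign(n_perm=n_perm)


def build_gene_report(panel: FounderPanel, do_pop: DOPopulation, gene_id: str,
                      covariates=("sex", "diet", "generation")) -> GeneReport:
    """Full per-gene report: scans for all classes plus founder panels."""
    scans = scan_gene(panel, do_pop, gene_id, covariates=covariates)
    _, positions, _ = founder_feature_array(panel, gene_id, "state",
                                            founders=do_pop.founders)
    g = panel.genes.set_index("gene_id").loc[gene_id]
    founder_states = pd.DataFrame(
        {f: states_at(panel.tracks[f], g["chrom"], positions)
         for f in do_pop.founders}).T
    founder_states.columns = pd.Index(positions, name="position")
    snp_sel = panel.snps[(panel.snps["chrom"] == g["chrom"]) &
                         (panel.snps["pos"] >= g["start"] - 1000) &
                         (panel.snps["pos"] < g["end"] + 1000)]
    founder_snps = snp_sel.set_index("pos")[list(do_pop.founders)].T \
        if len(snp_sel) else None
    meth_arr, meth_pos, _ = founder_feature_array(panel, gene_id, "methylation",
                                                  founders=do_pop.founders)
    founder_meth = pd.DataFrame(meth_arr[:, 0, :], index=do_pop.founders,
                                columns=pd.Index(meth_pos, name="position"))
    from .methylome import round_methylation
    founder_meth = pd.DataFrame(round_methylation(founder_meth.to_numpy()),
                                index=founder_meth.index, columns=founder_meth.columns)
    strain_means = panel.expression.T.groupby(level=0).mean().T \
        if isinstance(panel.expression.columns, pd.MultiIndex) else panel.expression
    founder_expr = strain_means.loc[gene_id, do_pop.founders] \
        if gene_id in strain_means.index else None
    # align class R^2 profiles on the state-track position grid
    return gene_report(gene_id, scans, positions,
                       founder_states=founder_states, founder_snps=founder_snps,
                       founder_methylation=founder_meth,
                       founder_expression=founder_expr)
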
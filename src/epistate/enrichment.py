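"""Fold enrichment of genomic feature sets and emission-signature alignment.

Fold enrichment (FE) follows the overlap-enrichment convention of chromatin
segmentation tools, computed here at base-pair resolution over merged
intervals:

    FE = (overlap_bp / feature_bp) / (annotation_bp / genome_bp)

i.e. how concentrated the feature set is within the annotation relative to
the annotation's genome-wide footprint.  FE is symmetric in the two roles
(both orders equal overlap * G / (f * a)).

Chromatin-state models with different state counts are aligned by reducing
each state's histone-mark emission probabilities to a binary
presence/absence signature at a threshold (default 0.3): with M binary
marks the signature space has 2^M members, so models can be compared on a
common code regardless of how many states they were trained with.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/adjacent (chrom, start, end) intervals."""
    if len(intervals) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = []
    df = intervals.sort_values(["chrom", "start", "end"])
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def covered_bp(intervals: pd.DataFrame) -> int:
    m = merge_intervals(intervals)
    if len(m) == 0:
        return 0
    return int((m["end"] - m["start"]).sum())


def overlap_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total bp in the intersection of two interval sets (merged first)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    total = 0
    for chrom, sa in ma.groupby("chrom", sort=False):
        sb = mb[mb["chrom"] == chrom]
        if len(sb) == 0:
            continue
        # sweep over merged, sorted, disjoint intervals
        as_, ae = sa["start"].to_numpy(), sa["end"].to_numpy()
        bs, be = sb["start"].to_numpy(), sb["end"].to_numpy()
        i = j = 0
        while i < len(as_) and j < len(bs):
            lo = max(as_[i], bs[j])
            hi = min(ae[i], be[j])
            if hi > lo:
                total += hi - lo
            if ae[i] < be[j]:
                i += 1
            else:
                j += 1
    return int(total)


def fold_enrichment(features: pd.DataFrame, annotation: pd.DataFrame,
                    genome_bp: int) -> float:
    """Base-pair fold enrichment of ``features`` within ``annotation``.

    0 for disjoint sets; NaN (with a warning) when the feature set is empty.
    Raises if genome_bp is smaller than either set's footprint.
    """
    f_bp = covered_bp(features)
    a_bp = covered_bp(annotation)
    if genome_bp < f_bp or genome_bp < a_bp:
        raise ValueError("genome_bp smaller than covered bp of an interval set")
    if f_bp == 0:
        warnings.warn("empty feature set: fold enrichment undefined", UserWarning,
                      stacklevel=2)
        return float("nan")
    if a_bp == 0:
        return float("nan")
    ov = overlap_bp(features, annotation)
    return (ov / f_bp) / (a_bp / genome_bp)


def enrichment_ratio(fe_specific: float, fe_shared: float) -> float:
    """Ratio of raw fold enrichments (specific / shared).

    The ratio is of raw FE values — any log transform is for display only.
    Values above 1 mean the specific set is the more enriched one.
    """
    if fe_shared == 0:
        warnings.warn("shared fold enrichment is 0: ratio undefined", UserWarning,
                      stacklevel=2)
        return float("nan")
    return fe_specific / fe_shared


def align_model_states(emissions: pd.DataFrame, threshold: float = 0.3):
    """Assign each state a binary mark-presence signature at ``threshold``.

    ``emissions``: states x marks probabilities in [0,1].  Returns
    (signatures, collisions): signatures maps state -> tuple of 0/1 bits
    (mark emission >= threshold); collisions lists groups of states sharing
    a signature (reported, never merged).  With M marks there are 2^M
    possible signatures.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    vals = emissions.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("emission probabilities must lie in [0, 1]")
    bits = (vals >= threshold).astype(int)
    signatures = {state: tuple(row) for state, row in zip(emissions.index, bits)}
    by_sig = {}
    for state, sig in signatures.items():
        by_sig.setdefault(sig, []).append(state)
    collisions = [states for states in by_sig.values() if len(states) > 1]
    return signatures, collisions


def match_models(emissions_a: pd.DataFrame, emissions_b: pd.DataFrame,
                 threshold: float = 0.3) -> pd.DataFrame:
    """Match states of two models by shared binary emission signature.

    Returns a table (state_a, state_b, signature) of all cross-model pairs
    with identical signatures; when each model's signatures are unique the
    match restricted to shared signatures is a bijection.
    """
    sig_a, _ = align_model_states(emissions_a, threshold)
    sig_b, _ = align_model_states(emissions_b, threshold)
    rows = []
    for sa, siga in sig_a.items():
        for sb, sigb in sig_b.items():
            if siga == sigb:
                rows.append((sa, sb, "".join(map(str, siga))))
    return pd.DataFrame(rows, columns=["state_a", "state_b", "signature"])
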
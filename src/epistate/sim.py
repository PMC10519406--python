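"""Synthetic founder-panel and outbred-population data with known ground truth.

The generator emulates the statistical structure the analysis assumes,
without simulating reads or upstream processing:

* a founder panel of (by default) 9 inbred strains x 3 replicates: one
  synthetic chromosome, genes laid out non-overlapping with configurable
  isolation, per-strain chromatin-state tracks in fixed 200-bp windows with
  14 states built from 4 binary histone marks, a CpG methylome with
  strain-specific sites and {0,50,100}% levels, and normalized expression
  that depends linearly on gene-body state proportions
  (expr = sum_k beta_k * proportion_k + noise);

* a Diversity-Outbred-style population whose individuals are mosaics of two
  founder haplotypes with Poisson-distributed crossovers, haplotype
  probabilities at the marker nearest each gene's TSS, and expression driven
  by the true diplotype state at a known causal position plus balanced
  sex/diet covariate effects.

Everything is deterministic under a fixed seed, and every causal choice is
recorded in :class:`SimTruth` for parameter-recovery tests.  Expression is
generated directly on the normalized scale (the pipeline consumes
already-normalized expression), and crossovers are placed uniformly along
the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coords import BinGrid, validate_genes
from .io import StateTrack
from .methylome import Methylome, merge_replicates

MARK_NAMES = ["H3K4me1", "H3K4me3", "H3K27me3", "H3K27ac"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel and DO population."""

    n_strains: int = 9
    n_reps: int = 3
    n_genes: int = 300
    genome_length: int | None = None     # auto-sized from the gene layout
    window: int = 200
    n_states: int = 14
    n_marks: int = 4
    emission_high: float = 0.9
    emission_low: float = 0.05
    state_betas: np.ndarray | None = None          # per-state true effects
    methyl_beta_profile: np.ndarray | None = None  # per-bin true methylation effect
    cpg_rate: float = 0.005              # baseline sites per bp
    cpg_tss_boost: float = 4.0           # density multiplier within 500 bp of TSS
    strain_specific_cpg_frac: float = 0.178
    meth_switch_rate: float = 0.1        # per-strain methylation level flips
    noise_sd: float = 0.5                # strain-level expression noise
    rep_noise_sd: float = 0.2            # replicate-level expression noise
    n_do: int = 200
    recomb_rate: float = 1.0             # expected crossovers per gamete
    seed: int = 0
    # layout / structure knobs
    gene_length_range: tuple = (2000, 6000)
    isolated_frac: float = 0.9
    state_switch_rate: float = 0.15      # per-strain per-window state flips
    tss_only_states: tuple = ()          # states confined to TSS windows
    tss_state_genes_frac: float = 0.5
    hap_blur_concentration: float | None = None  # None = exact dosages
    sex_effect: float = 0.0
    diet_effect: float = 0.0
    snps_per_gene: float = 5.0
    do_causal_rel_pos: float = 0.5
    body_dirichlet_alpha: float = 0.03   # per-gene body-composition heterogeneity
    plant_causal: bool = True            # make causal states polymorphic across strains
    causal_carrier_frac: float = 0.5     # strains carrying the causal state

    def betas(self) -> np.ndarray:
        if self.state_betas is None:
            return np.zeros(self.n_states)
        b = np.asarray(self.state_betas, dtype=float)
        if b.shape != (self.n_states,):
            raise ValueError("state_betas must have length n_states")
        return b

    def validate(self) -> "SimConfig":
        if not 0 < self.emission_low < self.emission_high < 1:
            raise ValueError("require 0 < emission_low < emission_high < 1")
        if self.n_states > 2 ** self.n_marks:
            raise ValueError(
                f"n_states={self.n_states} exceeds the {2**self.n_marks} distinct "
                f"binary signatures available with {self.n_marks} marks")
        for name in ("strain_specific_cpg_frac", "isolated_frac",
                     "state_switch_rate", "meth_switch_rate",
                     "tss_state_genes_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(s < 1 or s > self.n_states for s in self.tss_only_states):
            raise ValueError("tss_only_states must be valid state ids")
        self.betas()
        return self


@dataclass
class SimTruth:
    """Ground truth behind a simulated dataset."""

    state_betas: np.ndarray
    causal_states: list
    tss_only_states: tuple
    gene_table: pd.DataFrame                 # layout + isolated / tss-state flags
    methyl_beta_profile: np.ndarray | None = None
    strain_specific_sites: pd.Series | None = None
    do_causal_position: pd.Series | None = None   # per-gene causal bp (window midpoint)
    covariate_effects: dict = field(default_factory=dict)


@dataclass
class FounderPanel:
    config: SimConfig
    genes: pd.DataFrame
    tracks: dict                 # strain -> StateTrack
    methyl_calls: dict           # strain -> list of replicate DataFrames
    methylome: Methylome
    expression: pd.DataFrame     # genes x MultiIndex(strain, rep)
    emissions: pd.DataFrame      # states x marks
    snps: pd.DataFrame
    truth: SimTruth

    @property
    def strains(self):
        return list(self.tracks)

    @property
    def genome_length(self) -> int:
        return int(self.config.genome_length)


@dataclass
class DOPopulation:
    founders: list
    individuals: list
    hap_probs: dict              # gene_id -> DataFrame individuals x founders
    expression: pd.DataFrame     # individuals x genes
    covariates: pd.DataFrame
    gametes: list                # per individual: ((breaks, founders), (breaks, founders))
    truth: SimTruth


def state_signatures(n_states: int, n_marks: int) -> np.ndarray:
    """Distinct binary mark signatures for states 1..n_states.

    Signatures are the integers 2^M - 1 down to 0 as bit vectors, so state 1
    carries every mark and later states progressively fewer.
    """
    codes = np.arange(2 ** n_marks - 1, -1, -1)[:n_states]
    return ((codes[:, None] >> np.arange(n_marks - 1, -1, -1)) & 1).astype(int)


def emission_matrix(config: SimConfig) -> pd.DataFrame:
    sig = state_signatures(config.n_states, config.n_marks)
    em = np.where(sig == 1, config.emission_high, config.emission_low)
    marks = MARK_NAMES[: config.n_marks] if config.n_marks <= len(MARK_NAMES) \
        else [f"mark{i+1}" for i in range(config.n_marks)]
    return pd.DataFrame(em, index=pd.RangeIndex(1, config.n_states + 1, name="state"),
                        columns=marks)


def _round_to(x, step):
    return int(round(x / step) * step)


def _layout_genes(config: SimConfig, rng) -> pd.DataFrame:
    """Sequential gene layout; most genes isolated (>= 2 kb to any neighbor),
    a configurable fraction placed in close pairs (< 2 kb gap)."""
    w = config.window
    lo, hi = config.gene_length_range
    rows = []
    cur = _round_to(3000, w)
    i = 0

    def draw_len():
        return max(w, _round_to(rng.uniform(lo, hi), w))

    def big_gap():
        return _round_to(rng.uniform(2400, 6000), w)

    def small_gap():
        return max(w, _round_to(rng.uniform(300, 1800), w))

    while i < config.n_genes:
        pair = (rng.random() > config.isolated_frac) and (i + 1 < config.n_genes)
        L1 = draw_len()
        strand1 = "+" if rng.random() < 0.5 else "-"
        if pair:
            g1 = (f"gene{i+1:04d}", "chr1", cur, cur + L1, strand1, False)
            cur2 = cur + L1 + small_gap()
            L2 = draw_len()
            strand2 = "+" if rng.random() < 0.5 else "-"
            g2 = (f"gene{i+2:04d}", "chr1", cur2, cur2 + L2, strand2, False)
            rows.extend([g1, g2])
            cur = cur2 + L2 + big_gap()
            i += 2
        else:
            rows.append((f"gene{i+1:04d}", "chr1", cur, cur + L1, strand1, True))
            cur = cur + L1 + big_gap()
            i += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "isolated"])


def _context_weights(config: SimConfig) -> dict:
    """Per-context categorical state weights (promoter / body / intergenic)."""
    S = config.n_states
    prom = 0.6 ** np.arange(S)
    body = np.ones(S)
    inter = np.full(S, 0.3 / S)
    inter[-1] += 0.7
    weights = {"promoter": prom, "body": body, "intergenic": inter}
    for w in weights.values():
        for s in config.tss_only_states:
            w[s - 1] = 0.0
    return {k: w / w.sum() for k, w in weights.items()}


def _segments_from_windows(states: np.ndarray, window: int, chrom="chr1") -> pd.DataFrame:
    """Run-length encode a per-window state vector into BED-like segments."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change]) * window
    ends = np.concatenate([change, [len(states)]]) * window
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                         "state": states[np.concatenate([[0], change])]})


def states_at(track: StateTrack, chrom: str, positions) -> np.ndarray:
    """State id at each genomic position (track must cover the positions)."""
    seg = track.segments[track.segments["chrom"] == chrom]
    starts = seg["start"].to_numpy()
    ends = seg["end"].to_numpy()
    st = seg["state"].to_numpy()
    pos = np.asarray(positions, dtype=float)
    j = np.searchsorted(starts, pos, side="right") - 1
    if (j < 0).any() or (pos >= ends[np.clip(j, 0, None)]).any():
        raise ValueError("position outside track coverage")
    return st[j]


def simulate_founder_panel(config: SimConfig) -> FounderPanel:
    """Generate the founder panel under the configured study conditions."""
    config = replace(config).validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    genes = _layout_genes(config, rng)
    auto_len = int(genes["end"].max() + 3000)
    auto_len += (-auto_len) % config.window
    if config.genome_length is None:
        config = replace(config, genome_length=auto_len)
    elif config.genome_length < auto_len:
        raise ValueError(f"genome_length {config.genome_length} too small for "
                         f"the gene layout (needs >= {auto_len})")
    G = config.genome_length
    w = config.window
    n_w = G // w
    strains = [f"S{i+1}" for i in range(config.n_strains)]

    # --- chromatin-state tracks -------------------------------------------
    context = np.zeros(n_w, dtype=int)  # 0 intergenic, 1 body, 2 promoter
    anchors = validate_genes(genes)
    minus = anchors["strand"] == "-"
    tss_base = np.where(minus, anchors["end"] - 1, anchors["start"]).astype(int)
    # promoter band sits in the upstream flank; the gene body proper is
    # governed by the gene-level composition (body context wins inside)
    plus = (anchors["strand"] == "+").to_numpy()
    for gi, tb in enumerate(tss_base):
        if plus[gi]:
            lo, hi = max(0, (tb - 400) // w), max(0, tb // w)
        else:
            lo, hi = min(n_w, (tb + 1) // w + 1), min(n_w, (tb + 400) // w + 1)
        context[lo:hi] = 2
    for _, g in anchors.iterrows():
        context[g["start"] // w: g["end"] // w] = 1
    weights = _context_weights(config)
    base = np.empty(n_w, dtype=int)
    for ci, name in enumerate(["intergenic", "promoter"]):
        m = context == (0 if name == "intergenic" else 2)
        base[m] = rng.choice(config.n_states, size=m.sum(), p=weights[name]) + 1
    # gene bodies: per-gene Dirichlet composition, so state proportions vary
    # across genes the way chromatin composition varies across real genes
    tss_mask = np.array([s in config.tss_only_states
                         for s in range(1, config.n_states + 1)])
    alpha = np.full(config.n_states, config.body_dirichlet_alpha)
    for _, g in anchors.iterrows():
        m = context.copy()[g["start"] // w: g["end"] // w] == 1
        idx = np.arange(g["start"] // w, g["end"] // w)[m]
        if len(idx) == 0:
            continue
        wg = rng.dirichlet(alpha)
        wg[tss_mask] = 0.0
        wg = wg / wg.sum()
        base[idx] = rng.choice(config.n_states, size=len(idx), p=wg) + 1

    tss_gene_mask = np.zeros(len(genes), dtype=bool)
    if config.tss_only_states:
        tss_gene_mask = rng.random(len(genes)) < config.tss_state_genes_frac
        st_cycle = list(config.tss_only_states)
        for k, gi in enumerate(np.flatnonzero(tss_gene_mask)):
            base[tss_base[gi] // w] = st_cycle[k % len(st_cycle)]

    allowed = np.array([s for s in range(1, config.n_states + 1)
                        if s not in config.tss_only_states])
    # Across-strain variation is block-structured: a variant block spans a
    # few consecutive windows and an arbitrary subset of strains (a strain
    # distribution pattern) carries an alternative state there, the way
    # shared ancestry groups strains at real variants.
    window_states = {strain: base.copy() for strain in strains}
    mean_len = 3.0
    n_blocks = rng.poisson(config.state_switch_rate * n_w / mean_len)
    for _ in range(n_blocks):
        w0 = rng.integers(0, n_w)
        w1 = min(n_w, w0 + 1 + rng.geometric(1.0 / mean_len))
        carriers = rng.random(config.n_strains) < 0.4
        if not carriers.any() or carriers.all():
            carriers[rng.integers(config.n_strains)] ^= True
        alt = int(rng.choice(allowed))
        for si, strain in enumerate(strains):
            if carriers[si]:
                window_states[strain][w0:w1] = alt

    # plant each gene's causal state polymorphically at its causal window,
    # so the state segregates across strains (and hence across DO founders)
    betas = config.betas()
    causal_list = [s + 1 for s in np.flatnonzero(betas != 0)
                   if (s + 1) not in config.tss_only_states]
    if config.plant_causal and causal_list:
        for gi, g in anchors.iterrows():
            L = g["end"] - g["start"]
            off = min(int(np.floor(config.do_causal_rel_pos * L / w)) * w, L - w)
            cw = (g["start"] + off) // w
            c_state = causal_list[gi % len(causal_list)]
            # the causal state must group several strains (and, among the
            # first 8, several DO founders): a single-carrier "state" would
            # be indistinguishable from one haplotype
            n_head = min(8, config.n_strains)
            for _ in range(100):
                carriers = rng.random(config.n_strains) < config.causal_carrier_frac
                if 2 <= carriers[:n_head].sum() <= n_head - 2:
                    break
            for si, strain in enumerate(strains):
                if carriers[si]:
                    window_states[strain][cw] = c_state
                elif window_states[strain][cw] == c_state:
                    window_states[strain][cw] = int(
                        rng.choice(allowed[allowed != c_state]))

    tracks = {strain: StateTrack(strain=strain,
                                 segments=_segments_from_windows(st, w))
              for strain, st in window_states.items()}

    # --- methylome ---------------------------------------------------------
    n_base_sites = rng.poisson(config.cpg_rate * G)
    pos = rng.integers(0, G, size=n_base_sites)
    extra = []
    boost_rate = config.cpg_rate * max(config.cpg_tss_boost - 1.0, 0.0)
    for tb in tss_base:
        k = rng.poisson(boost_rate * 1000)
        extra.append(rng.integers(max(0, tb - 500), min(G, tb + 500), size=k))
    pos = np.unique(np.concatenate([pos] + extra)) if extra else np.unique(pos)
    n_sites = len(pos)

    # site context for methylation level
    site_ctx = np.zeros(n_sites, dtype=int)  # 0 intergenic, 1 body, 2 tss
    for _, g in anchors.iterrows():
        site_ctx[(pos >= g["start"]) & (pos < g["end"])] = 1
    for tb in tss_base:
        site_ctx[(pos >= tb - 500) & (pos < tb + 500)] = 2
    level_probs = {0: (0.25, 0.25, 0.50), 1: (0.10, 0.15, 0.75), 2: (0.80, 0.15, 0.05)}
    levels = np.array([0.0, 50.0, 100.0])
    base_level = np.empty(n_sites)
    for ci, p in level_probs.items():
        m = site_ctx == ci
        base_level[m] = rng.choice(levels, size=m.sum(), p=p)

    specific = rng.random(n_sites) < config.strain_specific_cpg_frac
    present = np.ones((n_sites, config.n_strains), dtype=bool)
    for i in np.flatnonzero(specific):
        k = rng.integers(1, config.n_strains)  # 1..n_strains-1 strains carry it
        carriers = rng.choice(config.n_strains, size=k, replace=False)
        present[i] = False
        present[i, carriers] = True

    strain_level = np.tile(base_level[:, None], (1, config.n_strains))
    flip = rng.random((n_sites, config.n_strains)) < config.meth_switch_rate
    strain_level[flip] = rng.choice(levels, size=int(flip.sum()))

    raw_ranges = {0.0: (0.0, 20.0), 50.0: (35.0, 65.0), 100.0: (80.0, 100.0)}
    methyl_calls = {}
    for si, strain in enumerate(strains):
        reps = []
        det = present[:, si]
        for _ in range(config.n_reps):
            vals = np.empty(int(det.sum()))
            lv = strain_level[det, si]
            for level, (a, b) in raw_ranges.items():
                m = lv == level
                vals[m] = rng.uniform(a, b, size=int(m.sum()))
            reps.append(pd.DataFrame({"chrom": "chr1", "pos": pos[det],
                                      "percent": vals}))
        methyl_calls[strain] = reps
    methylome = merge_replicates(methyl_calls)

    # --- expression --------------------------------------------------------
    betas = config.betas()
    n_genes = len(genes)
    props = np.zeros((n_genes, config.n_strains, config.n_states))
    for gi, g in anchors.iterrows():
        wlo, whi = g["start"] // w, g["end"] // w
        for si, strain in enumerate(strains):
            counts = np.bincount(window_states[strain][wlo:whi] - 1,
                                 minlength=config.n_states)
            props[gi, si] = counts / (whi - wlo)
    strain_expr = props @ betas + rng.normal(0, config.noise_sd,
                                             size=(n_genes, config.n_strains))

    if config.methyl_beta_profile is not None:
        profile = np.asarray(config.methyl_beta_profile, dtype=float)
        grid = BinGrid(n_bins=len(profile))
        from .methylome import gene_bin_methylation
        meth_bins = gene_bin_methylation(methylome, genes, grid)
        for si, strain in enumerate(strains):
            m = meth_bins[strain].to_numpy() / 100.0
            strain_expr[:, si] += np.nansum(m * profile[None, :], axis=1)

    cols = pd.MultiIndex.from_product([strains, [f"r{j+1}" for j in range(config.n_reps)]],
                                      names=["strain", "rep"])
    expr = pd.DataFrame(
        np.repeat(strain_expr, config.n_reps, axis=1)
        + rng.normal(0, config.rep_noise_sd, size=(n_genes, len(cols))),
        index=pd.Index(genes["gene_id"], name="gene_id"), columns=cols)

    # --- SNPs ---------------------------------------------------------------
    nucs = np.array(list("ACGT"))
    snp_rows = []
    for gi, g in anchors.iterrows():
        k = rng.poisson(config.snps_per_gene)
        sp = np.sort(rng.integers(max(0, g["start"] - 1000),
                                  min(G, g["end"] + 1000), size=k))
        for p_ in np.unique(sp):
            ref, alt = rng.choice(4, size=2, replace=False)
            alleles = np.where(rng.random(config.n_strains) < 0.3,
                               nucs[alt], nucs[ref])
            snp_rows.append(("chr1", int(p_), nucs[ref], nucs[alt], *alleles))
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt", *strains]) \
        .drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)

    truth = SimTruth(
        state_betas=betas,
        causal_states=[s + 1 for s in np.flatnonzero(betas != 0)],
        tss_only_states=config.tss_only_states,
        gene_table=genes.assign(tss_state=tss_gene_mask),
        methyl_beta_profile=(None if config.methyl_beta_profile is None
                             else np.asarray(config.methyl_beta_profile, dtype=float)),
        strain_specific_sites=pd.Series(specific, index=pd.MultiIndex.from_arrays(
            [np.repeat("chr1", n_sites), pos], names=["chrom", "pos"])),
    )
    return FounderPanel(config=config, genes=genes[["gene_id", "chrom", "start",
                                                    "end", "strand"]],
                        tracks=tracks, methyl_calls=methyl_calls,
                        methylome=methylome, expression=expr,
                        emissions=emission_matrix(config), snps=snps, truth=truth)


# ---------------------------------------------------------------------------
# DO population

def _draw_gamete(rng, genome_length: int, recomb_rate: float, n_founders: int):
    n_x = rng.poisson(recomb_rate)
    breaks = np.sort(rng.integers(1, genome_length, size=n_x))
    founders = rng.integers(0, n_founders, size=n_x + 1)
    return breaks, founders


def _founder_at(gamete, pos) -> int:
    breaks, founders = gamete
    return int(founders[np.searchsorted(breaks, pos, side="right")])


def simulate_do_population(config: SimConfig, panel: FounderPanel) -> DOPopulation:
    """Simulate a DO-style population descended from the first 8 panel strains."""
    config = replace(config, genome_length=panel.config.genome_length).validate()
    if panel.config.n_strains < 8:
        raise ValueError("a DO population requires >= 8 founder strains")
    founders = panel.strains[:8]
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    G = panel.genome_length
    n = config.n_do
    individuals = [f"DO{i+1:04d}" for i in range(n)]
    gametes = [(_draw_gamete(rng, G, config.recomb_rate, 8),
                _draw_gamete(rng, G, config.recomb_rate, 8)) for _ in range(n)]

    anchors = validate_genes(panel.genes)
    minus = anchors["strand"] == "-"
    tss_base = np.where(minus, anchors["end"] - 1, anchors["start"]).astype(int)

    hap_probs = {}
    for gi, g in anchors.iterrows():
        marker = int(np.clip(tss_base[gi], 0, G - 1))
        probs = np.zeros((n, 8))
        for i, (g1, g2) in enumerate(gametes):
            probs[i, _founder_at(g1, marker)] += 0.5
            probs[i, _founder_at(g2, marker)] += 0.5
        if config.hap_blur_concentration is not None and \
                np.isfinite(config.hap_blur_concentration):
            alpha = config.hap_blur_concentration * probs + 0.05
            probs = np.vstack([rng.dirichlet(a) for a in alpha])
        hap_probs[g["gene_id"]] = pd.DataFrame(probs, index=individuals,
                                               columns=founders)

    # covariates: balanced binary sex and diet, cyclic DO generation
    sex = np.arange(n) % 2
    diet = (np.arange(n) // 2) % 2
    generation = np.arange(n) % 3 + 1
    covariates = pd.DataFrame({"sex": sex, "diet": diet, "generation": generation},
                              index=individuals)

    betas = config.betas()
    w = config.window
    causal_pos = {}
    expr = np.empty((n, len(anchors)))
    for gi, g in anchors.iterrows():
        L = g["end"] - g["start"]
        off = int(np.floor(config.do_causal_rel_pos * L / w)) * w
        off = min(off, L - w)
        mid = g["start"] + off + w // 2
        causal_pos[g["gene_id"]] = mid
        founder_states = np.array(
            [states_at(panel.tracks[f], "chr1", [mid])[0] for f in founders])
        x = np.zeros((n, config.n_states))
        for i, (g1, g2) in enumerate(gametes):
            x[i, founder_states[_founder_at(g1, mid)] - 1] += 0.5
            x[i, founder_states[_founder_at(g2, mid)] - 1] += 0.5
        expr[:, gi] = (x @ betas + config.sex_effect * sex
                       + config.diet_effect * diet
                       + rng.normal(0, config.noise_sd, size=n))

    truth = replace(
        panel.truth,
        do_causal_position=pd.Series(causal_pos, name="causal_position"),
        covariate_effects={"sex": config.sex_effect, "diet": config.diet_effect},
    )
    return DOPopulation(
        founders=founders, individuals=individuals, hap_probs=hap_probs,
        expression=pd.DataFrame(expr, index=individuals,
                                columns=anchors["gene_id"]),
        covariates=covariates, gametes=gametes, truth=truth)


# ---------------------------------------------------------------------------
# founder feature arrays for imputation

SNP_LEVELS = ["A", "C", "G", "T"]


def founder_feature_array(panel: FounderPanel, gene_id: str, feature: str,
                          founders=None, flank: int = 1000):
    """Founders x levels x positions array for one gene (body +/- flank).

    feature="state": one-hot chromatin-state indicators at every track
    window midpoint in the span (levels = states 1..S).
    feature="methylation": one continuous level, the mean merged percent of
    CpGs in each window (absent strains contribute 0%; windows without CpGs
    are 0%).
    feature="snp": one-hot A/C/G/T founder alleles at SNP positions in the
    span (levels = 4); positions are the SNP coordinates.

    Returns (array, positions, levels).
    """
    if founders is None:
        founders = panel.strains[:8]
    cfg = panel.config
    g = panel.genes.set_index("gene_id").loc[gene_id]
    G = panel.genome_length
    w = cfg.window
    lo = max(0, int(g["start"]) - flank)
    hi = min(G, int(g["end"]) + flank)

    if feature == "snp":
        sel = panel.snps[(panel.snps["chrom"] == g["chrom"]) &
                         (panel.snps["pos"] >= lo) & (panel.snps["pos"] < hi)]
        positions = sel["pos"].to_numpy()
        arr = np.zeros((len(founders), 4, len(positions)))
        for fi, f in enumerate(founders):
            alleles = sel[f].to_numpy()
            for li, nuc in enumerate(SNP_LEVELS):
                arr[fi, li] = alleles == nuc
        return arr, positions, SNP_LEVELS

    lo -= lo % w
    mids = np.arange(lo, hi, w) + w // 2
    mids = mids[mids < G]
    if feature == "state":
        arr = np.zeros((len(founders), cfg.n_states, len(mids)))
        for fi, f in enumerate(founders):
            st = states_at(panel.tracks[f], g["chrom"], mids)
            arr[fi, st - 1, np.arange(len(mids))] = 1.0
        return arr, mids, list(range(1, cfg.n_states + 1))
    if feature == "methylation":
        filled = panel.methylome.percent_filled()
        sites = panel.methylome.sites
        sel = (sites["chrom"] == g["chrom"]).to_numpy()
        pos = sites["pos"].to_numpy()[sel]
        arr = np.zeros((len(founders), 1, len(mids)))
        widx = np.searchsorted(mids - w // 2, pos, side="right") - 1
        inside = (widx >= 0) & (widx < len(mids)) & \
            (pos < (mids[np.clip(widx, 0, len(mids) - 1)] + w // 2))
        for fi, f in enumerate(founders):
            vals = filled[f].to_numpy()[sel]
            sums = np.bincount(widx[inside], weights=vals[inside], minlength=len(mids))
            cnts = np.bincount(widx[inside], minlength=len(mids))
            nz = cnts > 0
            arr[fi, 0, nz] = sums[nz] / cnts[nz]
        return arr, mids, ["percent_methylation"]
    raise ValueError(f"unknown feature {feature!r}")


# ---------------------------------------------------------------------------
# fixture files

def write_fixtures(panel: FounderPanel, do_pop: DOPopulation | None, outdir) -> dict:
    """Write the panel (and optionally the DO population) as standard files.

    BED4 state tracks, bedGraph methylation per strain replicate, BED12
    genes, and tab-delimited expression / haplotype / covariate / SNP
    tables.  Round-trips losslessly through the package readers.  Returns a
    name -> path manifest.
    """
    from pathlib import Path

    from . import io as eio

    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    (outdir / "methylation").mkdir(exist_ok=True)
    manifest = {}
    genes_path = outdir / "genes.bed"
    eio.write_bed12_genes(panel.genes, genes_path)
    manifest["genes"] = genes_path
    for strain, track in panel.tracks.items():
        p = outdir / "tracks" / f"{strain}.bed"
        eio.write_state_track(track, p)
        manifest[f"track:{strain}"] = p
    for strain, reps in panel.methyl_calls.items():
        for j, df in enumerate(reps, start=1):
            p = outdir / "methylation" / f"{strain}.r{j}.bedgraph"
            eio.write_methylation_bedgraph(df, p)
            manifest[f"methylation:{strain}:r{j}"] = p
    expr_path = outdir / "expression.tsv"
    eio.write_expression(panel.expression, expr_path)
    manifest["expression"] = expr_path
    cfg_path = outdir / "sim_config.yaml"
    dump_config(panel.config, cfg_path)
    manifest["sim_config"] = cfg_path
    snp_path = outdir / "snps.tsv"
    eio.write_table(panel.snps, snp_path, index=False)
    manifest["snps"] = snp_path
    if do_pop is not None:
        hp = outdir / "do_hap_probs.tsv"
        eio.write_hap_probs(do_pop.hap_probs, hp)
        manifest["do_hap_probs"] = hp
        de = outdir / "do_expression.tsv"
        eio.write_table(do_pop.expression, de)
        manifest["do_expression"] = de
        cov = outdir / "do_covariates.tsv"
        eio.write_table(do_pop.covariates, cov)
        manifest["do_covariates"] = cov
    return manifest


def load_fixtures(outdir):
    """Read fixture files back: (genes, tracks, methyl_calls, expression)."""
    from pathlib import Path

    from . import io as eio

    outdir = Path(outdir)
    genes = eio.read_bed12_genes(outdir / "genes.bed")
    tracks = {}
    for p in sorted((outdir / "tracks").glob("*.bed")):
        tracks[p.stem] = eio.read_state_track(p, strain=p.stem)
    methyl_calls = {}
    for p in sorted((outdir / "methylation").glob("*.bedgraph")):
        strain = p.name.split(".")[0]
        methyl_calls.setdefault(strain, []).append(eio.read_methylation_bedgraph(p))
    expr = eio.read_expression(outdir / "expression.tsv")
    return genes, tracks, methyl_calls, expr


def dump_config(config: SimConfig, path) -> None:
    import yaml

    data = {}
    for k in config.__dataclass_fields__:
        v = getattr(config, k)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        data[k] = v
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def load_config(path) -> SimConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    for k in ("state_betas", "methyl_beta_profile"):
        if data.get(k) is not None:
            data[k] = np.asarray(data[k], dtype=float)
    for k in ("gene_length_range", "tss_only_states"):
        if data.get(k) is not None:
            data[k] = tuple(data[k])
    known = {k: v for k, v in data.items() if k in SimConfig.__dataclass_fields__}
    return SimConfig(**known)


def load_panel(outdir) -> FounderPanel:
    """Rebuild a :class:`FounderPanel` from a fixture directory.

    The ground truth is not stored in fixture files; the returned panel
    carries an empty :class:`SimTruth`.
    """
    from pathlib import Path

    from . import io as eio

    outdir = Path(outdir)
    config = load_config(outdir / "sim_config.yaml")
    genes, tracks, methyl_calls, expr = load_fixtures(outdir)
    snps = eio.read_table(outdir / "snps.tsv", index_col=None)
    truth = SimTruth(state_betas=config.betas(),
                     causal_states=[s + 1 for s in np.flatnonzero(config.betas() != 0)],
                     tss_only_states=config.tss_only_states,
                     gene_table=genes.copy())
    return FounderPanel(config=config, genes=genes, tracks=tracks,
                        methyl_calls=methyl_calls,
                        methylome=merge_replicates(methyl_calls),
                        expression=expr, emissions=emission_matrix(config),
                        snps=snps, truth=truth)
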
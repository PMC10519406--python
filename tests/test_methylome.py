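import numpy as np
import pandas as pd
import pytest

import epistate as ep
from epistate.io import StateTrack
from epistate.methylome import (gene_bin_methylation, merge_replicates,
                                round_methylation, strain_specific_sites)


def _calls(spec):
    """spec: strain -> list of {pos: percent} replicate dicts."""
    out = {}
    for strain, reps in spec.items():
        out[strain] = [pd.DataFrame({"chrom": "chr1",
                                     "pos": list(d), "percent": list(d.values())})
                       for d in reps]
    return out


class TestRounding:
    @pytest.mark.parametrize("raw,expected", [
        ([20.0, 30.0, 40.0], 50.0),   # mean 30 -> nearest of {0,50,100}
        ([0.0, 0.0, 0.0], 0.0),
        ([10.0, 10.0, 10.0], 0.0),    # 10 is nearer 0 than 50
        ([90.0, 90.0, 90.0], 100.0),
    ])
    def test_replicate_mean_rounds_to_three_levels(self, raw, expected):
        calls = _calls({"A": [{100: v} for v in raw]})
        m = merge_replicates(calls)
        assert m.percent["A"].iloc[0] == expected

    @pytest.mark.parametrize("value,expected", [
        (25.0, 50.0), (75.0, 100.0),  # ties round upward
        (24.999, 0.0), (74.999, 50.0),
    ])
    def test_tie_rounding_goes_up(self, value, expected):
        assert round_methylation([value])[0] == expected

    def test_idempotent_on_already_rounded_values(self):
        for v in (0.0, 50.0, 100.0):
            calls = _calls({"A": [{10: v}]})
            m = merge_replicates(calls)
            assert m.percent["A"].iloc[0] == v

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(ValueError, match="percent"):
            merge_replicates(_calls({"A": [{1: 105.0}]}))


class TestMergeReplicates:
    def test_presence_requires_single_replicate(self):
        calls = _calls({"A": [{100: 80.0}, {}, {}]})
        m = merge_replicates(calls)
        assert m.n_detected["A"].iloc[0] == 1
        assert m.percent["A"].iloc[0] == 100.0

    def test_absent_site_is_nan_but_fill_gives_zero(self):
        calls = _calls({"A": [{100: 80.0}], "B": [{200: 40.0}]})
        m = merge_replicates(calls)
        assert np.isnan(m.percent.loc[("chr1", 100), "B"])
        assert m.percent_filled().loc[("chr1", 100), "B"] == 0.0

    def test_sites_sorted_and_unique(self):
        calls = _calls({"A": [{300: 10.0, 100: 10.0}], "B": [{100: 90.0}]})
        m = merge_replicates(calls)
        assert list(m.sites["pos"]) == [100, 300]


class TestStrainSpecificCatalog:
    def test_present_all_of_one_absent_all_of_other_flagged(self):
        calls = _calls({"A": [{5: 80}, {5: 90}, {5: 70}],
                        "B": [{}, {}, {}],
                        "C": [{5: 60}, {}, {5: 50}]})
        cat = strain_specific_sites(merge_replicates(calls))
        assert cat.flags.iloc[0]

    def test_no_fully_present_strain_not_flagged(self):
        calls = _calls({"A": [{5: 80}, {5: 90}, {}],
                        "B": [{5: 60}, {}, {5: 50}]})
        cat = strain_specific_sites(merge_replicates(calls))
        assert not cat.flags.iloc[0]

    def test_present_everywhere_not_flagged(self):
        calls = _calls({"A": [{5: 80}], "B": [{5: 10}]})
        cat = strain_specific_sites(merge_replicates(calls))
        assert not cat.flags.iloc[0]

    def test_invariant_to_strain_order(self):
        spec = {"A": [{1: 80}, {1: 70}], "B": [{}, {}], "C": [{1: 10}, {}]}
        cat1 = strain_specific_sites(merge_replicates(_calls(spec)))
        rev = dict(reversed(list(spec.items())))
        cat2 = strain_specific_sites(merge_replicates(_calls(rev)))
        assert cat1.fraction == cat2.fraction
        assert (cat1.flags.to_numpy() == cat2.flags.to_numpy()).all()

    def test_emitted_fraction_matches_config(self, small_panel):
        cat = strain_specific_sites(small_panel.methylome)
        frac = small_panel.config.strain_specific_cpg_frac
        n = len(small_panel.methylome)
        tol = 4 * np.sqrt(frac * (1 - frac) / n)
        assert abs(cat.fraction - frac) < tol


class TestDensityProfile:
    def test_inverse_gap_values(self):
        calls = _calls({"A": [{100: 0.0, 110: 0.0}]})
        m = merge_replicates(calls)
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "start": [0], "end": [400], "strand": ["+"]})
        prof = ep.cpg_density_profile(m, genes, ep.make_bin_grid(n_bins=1, lo=0, hi=1))
        assert prof.values[0] == pytest.approx(0.1)  # 1 / 10 bp

    def test_uniform_spacing_gives_flat_profile(self):
        pos = dict.fromkeys(range(0, 2000, 50), 0.0)
        m = merge_replicates(_calls({"A": [pos]}))
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "start": [0], "end": [2000], "strand": ["+"]})
        prof = ep.cpg_density_profile(m, genes, ep.make_bin_grid(n_bins=4, lo=0, hi=1))
        assert np.allclose(prof.values, 0.02)

    def test_positive_where_defined(self, small_panel):
        prof = ep.cpg_density_profile(small_panel.methylome, small_panel.genes,
                                      ep.make_bin_grid())
        vals = prof.values[np.isfinite(prof.values)]
        assert (vals > 0).all()

    def test_matches_brute_force_pairwise_scan(self):
        rng = np.random.default_rng(4)
        grid = ep.make_bin_grid(n_bins=6)
        for _ in range(10):
            pos = np.sort(rng.choice(5000, size=rng.integers(5, 60),
                                     replace=False))
            m = merge_replicates(_calls({"A": [dict.fromkeys(map(int, pos), 0.0)]}))
            gs = int(rng.integers(500, 2500))
            ge = gs + int(rng.integers(500, 2000))
            genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                                  "start": [gs], "end": [ge], "strand": ["+"]})
            prof = ep.cpg_density_profile(m, genes, grid)
            # brute force: every site except the chromosome's last carries
            # 1/(next - this); collect those within 1 kb of the gene
            vals = {b: [] for b in range(grid.n_bins)}
            for i in range(len(pos) - 1):
                if not (gs - 1000 <= pos[i] < ge + 1000):
                    continue
                r = (pos[i] - gs) / (ge - gs)
                b = grid.bin_index([r])[0]
                if b >= 0:
                    vals[b].append(1.0 / (pos[i + 1] - pos[i]))
            for b in range(grid.n_bins):
                if vals[b]:
                    assert prof.values[b] == pytest.approx(np.mean(vals[b]),
                                                           abs=1e-12)
                else:
                    assert np.isnan(prof.values[b])


class TestMethylationProfile:
    def test_bin_medians(self):
        calls = _calls({"A": [{10: 0.0, 20: 0.0, 30: 100.0}]})
        m = merge_replicates(calls)
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "start": [0], "end": [40], "strand": ["+"]})
        prof = ep.methylation_profile(m, genes, ep.make_bin_grid(n_bins=1, lo=0, hi=1))
        assert prof.values[0] == 0.0  # median of {0, 0, 100}

    def test_tss_valley_recovered_from_simulation(self, small_panel):
        prof = ep.methylation_profile(small_panel.methylome, small_panel.genes,
                                      ep.make_bin_grid())
        tss = np.nanmean(prof.values[10:12])
        body = np.nanmean(prof.values[18:30])
        assert tss < body


class TestMethylationAssociation:
    def test_negative_tss_methylation_effect_recovered(self):
        profile = np.zeros(42)
        profile[10:12] = -3.0  # methylation at the TSS suppresses expression
        cfg = ep.SimConfig(n_genes=250, seed=13, methyl_beta_profile=profile)
        panel = ep.simulate_founder_panel(cfg)
        eff = ep.associate_methylation_expression(
            panel.methylome, panel.expression, panel.genes, ep.make_bin_grid())
        by_bin = {e.bin: e for e in eff}
        tss_effects = [by_bin[b] for b in (10, 11) if b in by_bin]
        assert tss_effects and all(e.beta < 0 and e.ci_hi < 0 for e in tss_effects)

    def test_null_bins_mostly_cover_zero(self, small_panel):
        eff = ep.associate_methylation_expression(
            small_panel.methylome, small_panel.expression, small_panel.genes,
            ep.make_bin_grid())
        cover = np.mean([e.ci_lo <= 0 <= e.ci_hi for e in eff])
        assert cover >= 0.85

    def test_strain_without_cpgs_contributes_zeros(self):
        calls = _calls({"A": [{100: 100.0, 150: 100.0}], "B": [{900: 50.0}]})
        m = merge_replicates(calls)
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "start": [0], "end": [400], "strand": ["+"]})
        bins = gene_bin_methylation(m, genes, ep.make_bin_grid(n_bins=1, lo=0, hi=1))
        # strain B lacks both sites in the bin: value 0, not missing
        assert bins["B"].iloc[0, 0] == 0.0
        assert bins["A"].iloc[0, 0] == 100.0


class TestConditionOnState:
    def _setup(self):
        calls = _calls({"A": [{250: 100.0}], "B": [{250: 100.0}]})
        m = merge_replicates(calls)
        tracks = {
            "A": StateTrack("A", pd.DataFrame(
                [("chr1", 200, 400, 3)], columns=["chrom", "start", "end", "state"])),
            "B": StateTrack("B", pd.DataFrame(
                [("chr1", 200, 400, 14)], columns=["chrom", "start", "end", "state"])),
        }
        return m, tracks

    def test_containment_is_per_strain(self):
        m, tracks = self._setup()
        sub, summary = ep.condition_on_state(m, tracks, 3)
        assert sub.n_detected.loc[("chr1", 250), "A"] > 0
        assert sub.n_detected.loc[("chr1", 250), "B"] == 0
        assert summary["state"] == 3 and summary["n_sites"] == 1

    def test_absent_state_warns_and_empties(self):
        m, tracks = self._setup()
        with pytest.warns(UserWarning, match="absent"):
            sub, _ = ep.condition_on_state(m, tracks, 7)
        assert len(sub) == 0

    def test_union_over_states_recovers_all_covered_sites(self, small_panel):
        m = small_panel.methylome
        total = np.zeros((len(m), len(m.strains)), dtype=bool)
        for state in range(1, 15):
            sub, _ = ep.condition_on_state(m, small_panel.tracks, state)
            idx = pd.MultiIndex.from_frame(m.sites)
            mask = sub.n_detected.gt(0).reindex(idx, fill_value=False)
            total |= mask.to_numpy()
        # tracks partition the genome, so the union over the 14 per-state
        # subsets must equal the full per-strain detection pattern
        assert (total == m.n_detected.gt(0).to_numpy()).all()
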
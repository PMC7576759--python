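"""Stratified statistics: classification rules, weighting schemes, worked
hand-enumeration examples and independent numeric oracles."""

import numpy as np
import pandas as pd
import pytest

from robustome import annotate, genetic_code as gc, stats

from conftest import make_mutations, make_residue


def events_frame(rows):
    """Minimal event table from (position, codon_position, ddg, ...) dicts."""
    defaults = {
        "protein_id": "P1", "position": 1, "wt_aa": "A", "wt_codon": "GCT",
        "mut_codon": "GTT", "codon_position": 2, "wt_base": "C", "mut_base": "T",
        "mut_aa": "V", "event_class": "missense", "titv": "transition",
        "ddg": 1.0, "rsa": 50.0, "rsa_stratum": "surface", "protein_length": 100,
    }
    return pd.DataFrame([{**defaults, **row} for row in rows])


class TestClassifyDdg:
    @pytest.mark.parametrize(
        "ddg,label",
        [(-0.7, "stabilizing"), (-0.5, "neutral"), (0.0, "neutral"),
         (0.5, "neutral"), (0.51, "destabilizing"), (-0.51, "stabilizing")],
    )
    def test_thresholds_with_neutral_boundaries(self, ddg, label):
        assert stats.classify_ddg(ddg) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            stats.classify_ddg(float("nan"))

    def test_series_matches_scalar(self):
        vals = pd.Series([-2.0, -0.5, 0.5, 3.0])
        assert list(stats.classify_ddg_series(vals)) == [stats.classify_ddg(v) for v in vals]


class TestFitnessClassify:
    @pytest.mark.parametrize(
        "fitness,label",
        [(0.4, "deleterious"), (0.5, "neutral"), (1.0, "neutral"),
         (1.25, "neutral"), (1.3, "advantageous")],
    )
    def test_thresholds(self, fitness, label):
        # wt = 1, lof = 0: deleterious below 0.5, advantageous above 1.25
        assert stats.fitness_classify(fitness, wt_score=1.0, lof_score=0.0) == label

    def test_degenerate_thresholds_rejected(self):
        with pytest.raises(ValueError):
            stats.fitness_classify(0.5, wt_score=0.1, lof_score=1.0)


class TestSummarize:
    def test_two_event_arithmetic(self):
        ev = events_frame([{"ddg": 0.0}, {"ddg": 1.0}])
        out = stats.summarize(ev.assign(stratum="all"), "stratum")
        row = out.iloc[0]
        assert row["n"] == 2
        assert row["mean_ddg"] == pytest.approx(0.5)
        assert (row["frac_stabilizing"], row["frac_neutral"], row["frac_destabilizing"]) \
            == (0.0, 0.5, 0.5)

    def test_fractions_sum_to_one_per_stratum(self, small_dataset):
        result = annotate.expand_events(small_dataset.residues, small_dataset.mutations)
        out = stats.summarize(result.events, "rsa_stratum")
        total = out["frac_stabilizing"] + out["frac_neutral"] + out["frac_destabilizing"]
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_pooled_equals_count_weighted_stratum_mean(self, small_dataset):
        result = annotate.expand_events(small_dataset.residues, small_dataset.mutations)
        out = stats.summarize(result.events, "rsa_stratum")
        pooled = (out["n"] * out["mean_ddg"]).sum() / out["n"].sum()
        assert pooled == pytest.approx(result.events["ddg"].mean(), abs=1e-12)

    def test_empty_stratum_reported_not_dropped(self):
        ev = events_frame([{"ddg": 1.0, "titv": "transversion"}])
        out = stats.summarize(ev, "titv", categories=["transition", "transversion"])
        row = out[out["titv"] == "transition"].iloc[0]
        assert row["n"] == 0 and np.isnan(row["mean_ddg"])


GGG_DDG = {"R": 1.0, "W": 2.0, "E": 1.0, "A": 0.5, "V": 0.5}


class TestPositionMeans:
    def test_ggg_with_synonymous_and_degeneracy(self):
        res = make_residue(codon="GGG")
        mut = make_mutations(wt_aa="G", ddg_by_target=GGG_DDG)
        ev = annotate.expand_events(res, mut, include_synonymous=True).events
        out = stats.position_means(ev, "with_syn_and_degeneracy").set_index("codon_position")
        assert out.loc[1, "mean_ddg"] == pytest.approx(4 / 3)  # Arg, Arg, Trp
        assert out.loc[2, "mean_ddg"] == pytest.approx(2 / 3)  # Glu, Ala, Val
        assert out.loc[3, "mean_ddg"] == pytest.approx(0.0)  # all synonymous

    def test_ggg_without_mode_has_empty_third_position(self):
        res = make_residue(codon="GGG")
        mut = make_mutations(wt_aa="G", ddg_by_target=GGG_DDG)
        ev = annotate.expand_events(res, mut, include_synonymous=False).events
        out = stats.position_means(ev, "without").set_index("codon_position")
        assert out.loc[3, "n"] == 0 and np.isnan(out.loc[3, "mean_ddg"])
        # degeneracy collapsed: Arg counted once at position I
        assert out.loc[1, "n"] == 2
        assert out.loc[1, "mean_ddg"] == pytest.approx(1.5)

    def test_tta_position_iii_mean(self):
        res = make_residue(codon="TTA")
        mut = make_mutations(ddg_by_target={"F": 2.0, "I": 1.0, "V": 1.0, "S": 0.5})
        ev = annotate.expand_events(res, mut, include_synonymous=True).events
        out = stats.position_means(ev, "with_syn_and_degeneracy").set_index("codon_position")
        assert out.loc[3, "mean_ddg"] == pytest.approx(4 / 3)  # {0, 2.0, 2.0}

    def test_mode_mismatch_rejected(self):
        res = make_residue(codon="GGG")
        mut = make_mutations(wt_aa="G", ddg_by_target=GGG_DDG)
        ev = annotate.expand_events(res, mut, include_synonymous=False).events
        with pytest.raises(ValueError):
            stats.position_means(ev, "with_syn_and_degeneracy")

    def test_all_synonymous_means_zero(self):
        res = make_residue(codon="GGG")
        ev = annotate.expand_events(res, make_mutations(wt_aa="G"),
                                    include_synonymous=True).events
        syn = ev[ev["event_class"] == "synonymous"]
        out = stats.position_means(syn, "with_syn_and_degeneracy")
        populated = out[out["n"] > 0]
        assert (populated["mean_ddg"] == 0).all()


class TestWeightedClassFractions:
    def test_equal_weights_equal_pooled_by_position(self, small_dataset):
        ev = annotate.expand_events(
            small_dataset.residues, small_dataset.mutations, include_synonymous=True
        ).events
        weighted = stats.weighted_class_fractions(ev, (1 / 3, 1 / 3, 1 / 3))
        manual = {label: 0.0 for label in stats.CLASS_LABELS}
        for p in (1, 2, 3):
            sub = ev[ev["codon_position"] == p]
            frac = stats.classify_ddg_series(sub["ddg"]).value_counts(normalize=True)
            for label in stats.CLASS_LABELS:
                manual[label] += frac.get(label, 0.0) / 3
        for label in stats.CLASS_LABELS:
            assert weighted[label] == pytest.approx(manual[label], abs=1e-12)

    def test_toy_two_position_weights(self):
        # position I all destabilizing, position III all neutral, II unweighted
        ev = events_frame(
            [{"codon_position": 1, "ddg": 2.0}] * 3 + [{"codon_position": 3, "ddg": 0.0}] * 2
        )
        out = stats.weighted_class_fractions(ev, (0.2, 0.0, 0.8))
        assert out == {"stabilizing": 0.0, "neutral": 0.8, "destabilizing": pytest.approx(0.2)}

    def test_single_position_weight_selects_that_position(self):
        ev = events_frame(
            [{"codon_position": 1, "ddg": 2.0}, {"codon_position": 3, "ddg": 0.0}]
        )
        out = stats.weighted_class_fractions(ev, (0.0, 0.0, 1.0))
        assert out["neutral"] == 1.0

    def test_empty_weighted_position_renormalizes_with_warning(self):
        ev = events_frame([{"codon_position": 1, "ddg": 2.0}])
        with pytest.warns(UserWarning, match="renormalizing"):
            out = stats.weighted_class_fractions(ev, stats.TRANSLATION_ERROR_FREQS)
        assert out["destabilizing"] == pytest.approx(1.0)

    def test_synonymous_events_count_as_neutral(self):
        ev = events_frame(
            [{"codon_position": 1, "ddg": 0.0, "event_class": "synonymous"},
             {"codon_position": 1, "ddg": 5.0}]
        )
        out = stats.weighted_class_fractions(ev, (1.0, 0.0, 0.0))
        assert out["neutral"] == pytest.approx(0.5)


class TestPearson:
    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r = stats.pearson(x, y).r
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 5.0])
        assert stats.pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert stats.pearson(x, -x).r == pytest.approx(-1.0)

    def test_two_point_case_is_unit_correlation(self):
        assert abs(stats.pearson([0.0, 1.0], [3.0, 5.0]).r) == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        out = stats.pearson([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert not out.valid and np.isnan(out.r)

    def test_position_error_frequency_anticorrelation(self):
        # published per-position means with synonymous mutations and
        # degeneracy versus the translation-error frequencies
        out = stats.pearson([31.3, 6.2, 62.5], [0.64, 0.91, 0.16])
        assert out.r == pytest.approx(-0.996, abs=1e-3)

    def test_blosum_class_anticorrelation(self):
        means = [1.58, 1.15, 1.11, 0.83, 0.56, 0.33, 0.28, 0.25]
        out = stats.pearson(list(range(-4, 4)), means)
        assert round(out.r, 2) == -0.97


class TestTitvMeans:
    def test_toy_with_synonymous(self):
        ev = events_frame(
            [{"titv": "transition", "ddg": 0.0, "event_class": "synonymous"},
             {"titv": "transversion", "ddg": 1.0}]
        )
        out = stats.titv_means(ev, include_synonymous=True).set_index("titv")
        assert out.loc["transition", "mean_ddg"] == 0.0
        assert out.loc["transversion", "mean_ddg"] == 1.0

    def test_without_synonymous_transitions_empty(self):
        ev = events_frame(
            [{"titv": "transition", "ddg": 0.0, "event_class": "synonymous"},
             {"titv": "transversion", "ddg": 1.0}]
        )
        out = stats.titv_means(ev, include_synonymous=False).set_index("titv")
        assert out.loc["transition", "n"] == 0
        assert np.isnan(out.loc["transition", "mean_ddg"])


LYS_DDG = {"Q": 1.0, "E": 2.0, "T": 0.5, "R": 1.5, "I": 3.0, "N": 1.0, "M": 2.5}


def lys_pools():
    """Hand enumeration of the AAA/AAG used-versus-synonymous event pools.

    Values and per-position weights (random model, each position 1/3 split
    equally over its non-nonsense events) written out explicitly.
    """
    used = [  # AAA: I -> Q, E (TAA is stop); II -> T, R, I; III -> N, N, syn
        (1.0, 1 / 6), (2.0, 1 / 6),
        (0.5, 1 / 9), (1.5, 1 / 9), (3.0, 1 / 9),
        (1.0, 1 / 9), (1.0, 1 / 9), (0.0, 1 / 9),
    ]
    syn = [  # AAG: I -> Q, E (TAG is stop); II -> T, R, M; III -> N, N, syn
        (1.0, 1 / 6), (2.0, 1 / 6),
        (0.5, 1 / 9), (1.5, 1 / 9), (2.5, 1 / 9),
        (1.0, 1 / 9), (1.0, 1 / 9), (0.0, 1 / 9),
    ]

    def mv(pool):
        vals = np.array([v for v, _ in pool])
        wts = np.array([w for _, w in pool])
        wts = wts / wts.sum()
        m = (vals * wts).sum()
        return m, (wts * (vals - m) ** 2).sum()

    return mv(used), mv(syn)


class TestCodonUsageDelta:
    def make_lys_tables(self, codon="AAA"):
        res = make_residue(codon=codon)
        mut = make_mutations(wt_aa="K", ddg_by_target=LYS_DDG)
        return res, mut

    def test_hand_enumerated_oracle(self):
        (mu, vu), (ms, vs) = lys_pools()
        res, mut = self.make_lys_tables("AAA")
        out = stats.codon_usage_delta(res, mut, weighting="random")
        assert out.mean_used == pytest.approx(mu, abs=1e-12)
        assert out.mean_syn == pytest.approx(ms, abs=1e-12)
        assert out.delta_pct == pytest.approx(100 * (ms - mu) / np.sqrt(vu + vs), abs=1e-9)

    def test_antisymmetric_under_codon_swap(self):
        res_a, mut = self.make_lys_tables("AAA")
        res_g, _ = self.make_lys_tables("AAG")
        d_a = stats.codon_usage_delta(res_a, mut, weighting="random")
        d_g = stats.codon_usage_delta(res_g, mut, weighting="random")
        assert d_a.delta_pct == pytest.approx(-d_g.delta_pct, abs=1e-9)

    def test_symmetric_family_gives_zero(self):
        # GAT and GAC (Asp) expand to identical target multisets
        res = make_residue(codon="GAT")
        mut = make_mutations(
            wt_aa="D",
            ddg_by_target={"E": 1.0, "N": 2.0, "A": 1.0, "G": 1.0, "V": 1.0,
                           "H": 1.0, "Y": 1.0},
        )
        for weighting in ("random", "translation"):
            out = stats.codon_usage_delta(res, mut, weighting=weighting)
            assert out.delta_pct == pytest.approx(0.0, abs=1e-9)

    def test_single_codon_families_excluded(self):
        res = pd.concat(
            [make_residue(codon="AAA"), make_residue(position=2, codon="ATG")],
            ignore_index=True,
        )
        mut = pd.concat(
            [self.make_lys_tables()[1],
             make_mutations(position=2, wt_aa="M",
                            ddg_by_target={"I": 1.0, "L": 1.0, "V": 1.0, "T": 1.0,
                                           "R": 1.0, "K": 1.0})],
            ignore_index=True,
        )
        out = stats.codon_usage_delta(res, mut)
        assert out.n_excluded == 1 and out.n_residues == 1


class TestBiasClassify:
    def usage_with(self, overrides):
        from robustome.synthetic import family_fractions

        fractions = family_fractions(0.0)
        fractions.update(overrides)
        return stats.CodonUsageTable(organism="toy", fractions=fractions)

    def test_strong_two_codon_bias(self):
        usage = self.usage_with({"AAA": 0.70, "AAG": 0.30})
        assert stats.bias_classify("AAA", usage) == "biased"  # 40% deviation
        assert stats.bias_classify("AAG", usage) == "biased"

    def test_mild_two_codon_deviation_unbiased(self):
        usage = self.usage_with({"AAA": 0.52, "AAG": 0.48})
        assert stats.bias_classify("AAA", usage) == "unbiased"  # 4% < 12.5%
        assert stats.bias_classify("AAG", usage) == "unbiased"

    def test_exact_equiprobability_unbiased(self):
        usage = self.usage_with({})
        labels = stats.classify_usage_table(usage)
        assert (labels["label"] == "unbiased").all()

    def test_single_codon_family_rejected(self):
        with pytest.raises(stats.CodonUsageError):
            stats.bias_classify("ATG", self.usage_with({}))

    def test_uniform_nucleotide_freqs_match_equiprobability(self):
        usage = stats.CodonUsageTable(
            organism="toy",
            fractions=self.usage_with({}).fractions,
            nucleotide_freqs={b: 0.25 for b in "ACGT"},
        )
        for codon in ("AAA", "GGC", "CTT"):
            assert usage.expected_fraction(codon, "nucleotide_freq") == pytest.approx(
                usage.expected_fraction(codon, "equiprobability")
            )

    def test_family_sum_validation(self):
        fractions = self.usage_with({}).fractions
        fractions["AAA"] = 0.9  # family no longer sums to 1
        with pytest.raises(stats.CodonUsageError):
            stats.CodonUsageTable(organism="bad", fractions=fractions)


class TestGcDelta:
    def test_lys_aaa_gains_third_of_gc(self):
        out = stats.gc_delta(make_residue(codon="AAA"))
        assert out.mean_delta_pct == pytest.approx(100 / 3)

    def test_lys_aag_is_symmetric(self):
        out = stats.gc_delta(make_residue(codon="AAG"))
        assert out.mean_delta_pct == pytest.approx(-100 / 3)

    def test_balanced_pair_averages_to_zero(self):
        res = pd.concat(
            [make_residue(codon="AAA"), make_residue(position=2, codon="AAG")],
            ignore_index=True,
        )
        assert stats.gc_delta(res).mean_delta_pct == pytest.approx(0.0)

    def test_single_codon_families_excluded(self):
        res = pd.concat(
            [make_residue(codon="AAA"), make_residue(position=2, codon="TGG")],
            ignore_index=True,
        )
        out = stats.gc_delta(res)
        assert out.n_excluded == 1


class TestRsaProfile:
    def test_constant_ddg_flat_profile(self):
        rng = np.random.default_rng(3)
        ev = events_frame(
            [{"ddg": 1.5, "rsa": float(r)} for r in rng.uniform(0, 100, 500)]
        )
        prof = stats.rsa_profile(ev)
        assert np.allclose(prof.bins["mean_ddg"], 1.5)
        assert prof.linear["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_bin_convention(self):
        ev = events_frame([{"ddg": 1.0, "rsa": 0.5}, {"ddg": 2.0, "rsa": 100.0}])
        prof = stats.rsa_profile(ev)
        assert prof.bins["bin_left"].tolist() == [0.0, 99.0]

    def test_linear_slope_recovery_above_threshold(self):
        rng = np.random.default_rng(11)
        rsa = rng.uniform(20.5, 100, 4000)
        ddg = -0.01 * rsa + 1.2 + rng.normal(0, 0.05, rsa.size)
        ev = events_frame([{"ddg": d, "rsa": float(r)} for r, d in zip(rsa, ddg)])
        prof = stats.rsa_profile(ev)
        assert prof.linear["slope"] == pytest.approx(-0.01, abs=0.001)
        assert prof.linear["r2"] > 0.9

    def test_sparse_side_omits_fit(self):
        ev = events_frame([{"ddg": 1.0, "rsa": 5.0}, {"ddg": 1.0, "rsa": 50.0},
                           {"ddg": 1.2, "rsa": 60.0}, {"ddg": 1.1, "rsa": 80.0}])
        prof = stats.rsa_profile(ev)
        assert prof.quadratic is None
        assert prof.linear is not None


class TestProteinSummary:
    def test_two_residue_toy(self):
        ev = events_frame(
            [{"position": 1, "rsa": 10.0, "rsa_stratum": "core", "ddg": 2.0,
              "protein_length": 2},
             {"position": 2, "rsa": 60.0, "rsa_stratum": "surface", "ddg": 0.5,
              "protein_length": 2}]
        )
        out = stats.protein_summary(ev).iloc[0]
        assert out["mean_ddg"] == pytest.approx(1.25)
        assert out["core_to_length"] == pytest.approx(0.5)
        assert out["mean_ddg_surface"] == pytest.approx(0.5)

    def test_all_core_ratio_one(self):
        ev = events_frame(
            [{"position": i, "rsa": 5.0, "rsa_stratum": "core", "protein_length": 3}
             for i in (1, 2, 3)]
        )
        assert stats.protein_summary(ev).iloc[0]["core_to_length"] == 1.0

    @pytest.mark.parametrize("length,bin_", [(200, "<=200"), (201, "200-400"),
                                             (400, "200-400"), (401, ">400")])
    def test_length_bins_boundary_inclusive(self, length, bin_):
        assert stats.length_bin(length) == bin_


class TestCompositionProfile:
    def test_all_core_valine(self):
        res = pd.concat(
            [make_residue(position=i, codon="GTT", rsa=5.0, length=150) for i in (1, 2)],
            ignore_index=True,
        )
        out = stats.composition_profile(res)
        row = out[out["length_bin"] == "<=200"].iloc[0]
        assert row["hydrophobic_fraction"] == 1.0

    def test_no_core_flagged_undefined(self):
        res = make_residue(codon="GTT", rsa=80.0, length=150)
        out = stats.composition_profile(res)
        row = out[out["length_bin"] == "<=200"].iloc[0]
        assert row["n_core"] == 0 and np.isnan(row["hydrophobic_fraction"])


class TestHydrophobicityCorrelation:
    def test_t_content_positively_correlated(self):
        assert stats.hydrophobicity_correlation("T").r > 0.4

    def test_a_content_anticorrelated(self):
        assert stats.hydrophobicity_correlation("A").r < -0.1

    def test_weaker_for_c_and_g(self):
        for base in ("C", "G"):
            assert abs(stats.hydrophobicity_correlation(base).r) < \
                stats.hydrophobicity_correlation("T").r
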
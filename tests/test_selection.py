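"""Fixation model, MK machinery, NG86 counting, and contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from uorfevolve.models import MkInput, SelectionModelParams, TranscriptModel
from uorfevolve.selection import (
    annotate_uorf_snp_effects,
    asymptotic_mk,
    classify_fixed_aug_origins,
    mutational_opportunity,
    ng86_omega_binned,
    ng86_pair,
    overall_relative_fixation,
    pic_contrasts,
    pic_correlation,
    pnps_by_daf,
    relative_fixation_prob,
)
from uorfevolve.annotate import find_and_classify_uaugs


def closed_form_f(ne, s):
    """Haldane/Kimura fixation probability at h = 1/2, relative to neutral."""
    return 2 * ne * (1 - math.exp(-s)) / (1 - math.exp(-2 * ne * s))


class TestFixationModel:
    def test_neutral_limit(self):
        assert relative_fixation_prob(SelectionModelParams(1000, 0.0)) == 1.0

    @pytest.mark.parametrize("ne", [10, 100, 1000, 10_000])
    @pytest.mark.parametrize("s", [0.001, -0.001, 0.01, -0.01, 0.05, -0.05])
    def test_closed_form_oracle(self, ne, s):
        f = relative_fixation_prob(SelectionModelParams(ne, s))
        try:
            c = closed_form_f(ne, s)
        except OverflowError:
            c = 0.0
        if c < 1e-250:  # both sides underflow for 2Ne|s| >> 700
            assert f < 1e-250
        else:
            assert abs(f - c) / c < 1e-6

    @pytest.mark.parametrize("h", [0.1, 0.5, 1.0])
    def test_direction_of_selection(self, h):
        up = relative_fixation_prob(SelectionModelParams(500, 0.005, h))
        down = relative_fixation_prob(SelectionModelParams(500, -0.005, h))
        assert up > 1 > down

    def test_worked_mixture_example(self):
        params = SelectionModelParams(100, 0.01)
        assert relative_fixation_prob(params) == pytest.approx(2.3015, abs=1e-4)
        assert relative_fixation_prob(
            SelectionModelParams(100, -0.01)
        ) == pytest.approx(0.3146, abs=1e-4)
        overall, frac = overall_relative_fixation(params)
        assert overall == pytest.approx(0.5511, abs=1e-3)
        assert frac == pytest.approx(0.2088, abs=1e-3)

    def test_zero_s_mixture(self):
        overall, frac = overall_relative_fixation(SelectionModelParams(1000, 0.0))
        assert overall == pytest.approx(1.0)
        assert frac == pytest.approx(0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SelectionModelParams(-5, 0.01)
        with pytest.raises(ValueError):
            SelectionModelParams(100, 0.01, h=1.5)
        with pytest.raises(ValueError):
            SelectionModelParams(100, 0.01, p_neutral=0.5, p_del=0.5, p_ben=0.5)


class TestAsymptoticMk:
    def test_flat_ratio_gives_zero_alpha(self):
        # P_test/P_neutral constant = D_test/D_neutral => alpha(x) = 0
        mk = MkInput([0.2, 0.4, 0.6, 0.8], [2000] * 4, [1000] * 4, 200, 100)
        res = asymptotic_mk(mk, fit_mode="linear", n_boot=10, seed=0)
        assert res.alpha_per_bin == pytest.approx([0.0] * 4, abs=1e-12)
        assert res.alpha_asym == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_worked_example(self):
        mk = MkInput(
            [0.1, 0.3, 0.5, 0.7, 0.9],
            [1700, 1500, 1300, 1100, 900],
            [1000] * 5,
            d_test=200,
            d_neutral=100,
        )
        res = asymptotic_mk(mk, fit_mode="linear", n_boot=50, seed=1)
        assert res.alpha_per_bin == pytest.approx(
            [0.15, 0.25, 0.35, 0.45, 0.55], abs=1e-12
        )
        assert res.alpha_asym == pytest.approx(0.6, abs=1e-9)
        assert res.ci[0] <= res.alpha_asym <= res.ci[1]

    def test_sparse_neutral_bins_merged(self):
        mk = MkInput(
            [0.15, 0.35, 0.55, 0.75],
            [10, 10, 10, 10],
            [2, 50, 50, 50],
            d_test=20,
            d_neutral=10,
        )
        res = asymptotic_mk(mk, fit_mode="linear", n_boot=10, seed=0)
        assert len(res.daf_bins) == 3  # first two bins merged

    def test_zero_d_test_errors(self):
        mk = MkInput([0.5], [10], [10], d_test=0, d_neutral=10)
        with pytest.raises(ValueError):
            asymptotic_mk(mk)


class TestSnpEffects:
    def _model_with_norf(self):
        # uORF codons: ATG TTT TAA starting at utr offset 0
        return TranscriptModel(
            "t", "g", "ATGTTTTAAC", "ATGCCCTGA", "",
            chromosome="c", strand="+", exons=[(0, 19)], cds_genomic=[(10, 19)],
        )

    @pytest.mark.parametrize(
        "alt,expected",
        [("C", "synonymous"), ("A", "nonsynonymous")],  # TTT->TTC Phe, TTT->TTA Leu
    )
    def test_third_position_effects(self, alt, expected):
        model = self._model_with_norf()
        recs = find_and_classify_uaugs(model)
        snps = pd.DataFrame(
            [{"chromosome": "c", "position": 5, "ref": "T", "alt": alt,
              "ancestral": "T", "daf": 0.2}]
        )
        out = annotate_uorf_snp_effects(snps, recs, [model])
        assert len(out) == 1
        assert out[0].effect == expected

    def test_reference_mismatch_excluded(self):
        model = self._model_with_norf()
        recs = find_and_classify_uaugs(model)
        snps = pd.DataFrame(
            [{"chromosome": "c", "position": 5, "ref": "G", "alt": "A",
              "ancestral": "G", "daf": 0.2}]
        )
        assert annotate_uorf_snp_effects(snps, recs, [model]) == []

    def test_conflicting_frames_ambiguous(self):
        # two overlapping uORFs in different frames over the same SNP
        model = TranscriptModel(
            "t", "g", "ATGATGTTTTAGCTAAC", "ATGCCCTGA", "",
            chromosome="c", strand="+", exons=[(0, 26)], cds_genomic=[(17, 26)],
        )
        recs = find_and_classify_uaugs(model)
        assert len(recs) >= 2
        snps = pd.DataFrame(
            [{"chromosome": "c", "position": 8, "ref": "T", "alt": "C",
              "ancestral": "T", "daf": 0.3}]
        )
        out = annotate_uorf_snp_effects(snps, recs, [model])
        assert len(out) == 1
        # effect must be one consistent call or flagged ambiguous
        assert out[0].effect in {"synonymous", "nonsynonymous", "ambiguous"}


class TestPnps:
    def test_counts_and_ratio(self):
        from uorfevolve.models import SnpRecord

        snps = [
            SnpRecord("c", 1, "T", "A", "T", 0.1, "nonsynonymous"),
            SnpRecord("c", 2, "T", "A", "T", 0.12, "nonsynonymous"),
            SnpRecord("c", 3, "T", "C", "T", 0.15, "synonymous"),
        ]
        df, rho = pnps_by_daf(snps, [0.0, 0.5, 1.0], ["AAA"])
        assert df.iloc[0]["pnps"] == pytest.approx(2.0)
        assert np.isnan(df.iloc[1]["pnps"])  # no synonymous SNPs in bin 2

    def test_opportunity_enumeration_glycine(self):
        # GGG: all three third-position changes are Gly->Gly
        n, s = mutational_opportunity(["GGG"])
        assert (n, s) == (6.0, 3.0)

    def test_opportunity_skips_stops(self):
        assert mutational_opportunity(["TAA"]) == (0.0, 0.0)


class TestNg86:
    def test_worked_pair(self):
        nd, sd, n, s = ng86_pair("AAAAAA", "AAGGAA")
        assert (nd, sd) == (1.0, 1.0)
        assert s == pytest.approx(2 / 3)
        assert n == pytest.approx(16 / 3)
        assert (nd / n) / (sd / s) == pytest.approx(0.125)

    def test_identical_sequences_give_missing_omega(self):
        bins = ng86_omega_binned([(("AAATTT", "AAATTT"), 0.0)], n_bins=1)
        assert bins[0].omega is None

    def test_site_counts_sum_to_three_per_codon(self):
        rng = np.random.default_rng(17)
        sense = [c for c in
                 ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
                 if c not in {"TAA", "TAG", "TGA"}]
        for mode in ("nonsynonymous", "exclude"):
            for _ in range(50):
                codons = rng.choice(sense, size=20)
                seq = "".join(codons)
                nd, sd, n, s = ng86_pair(seq, seq, stop_mode=mode)
                assert n + s == pytest.approx(3 * 20)

    def test_multihit_pathway_averaging(self):
        # TTT -> GTA: paths TTT->GTT->GTA (non, non) and TTT->TTA->GTA
        # (non, non): both nonsynonymous twice
        nd, sd, _, _ = ng86_pair("TTT", "GTA")
        assert nd + sd == pytest.approx(2.0)

    def test_binning_by_kozak_score(self):
        pairs = [(("AAAAAA", "AAGGAA"), float(i)) for i in range(10)]
        bins = ng86_omega_binned(pairs, n_bins=5)
        assert len(bins) == 5
        assert all(b.kozak_min <= b.kozak_max for b in bins)


class TestPic:
    def test_two_leaf_closed_form(self):
        cs = pic_contrasts("(A:1,B:1);", {"A": 3, "B": 1})
        assert cs.contrasts == pytest.approx([2 / math.sqrt(2)], abs=1e-10)

    def test_three_leaf_closed_form(self):
        cs = pic_contrasts("((A:1,B:1):1,C:2);", {"A": 3, "B": 1, "C": 2})
        assert sorted(np.abs(cs.contrasts)) == pytest.approx(
            [0.0, math.sqrt(2)], abs=1e-10
        )

    def test_identical_tip_values_zero_contrasts(self):
        cs = pic_contrasts("((A:1,B:2):1,(C:1,D:3):2);", dict.fromkeys("ABCD", 7.0))
        assert cs.contrasts == pytest.approx([0.0] * 3, abs=1e-12)

    def test_matches_independent_reference_values(self):
        # |contrasts| from ape::pic on the same tree and data
        expected = [0.8410304645, 0.8700391885, 1.3435028843, 1.5556349186]
        cs = pic_contrasts(
            "(((A:0.7,B:1.3):0.5,C:2.1):0.4,(D:0.9,E:1.1):1.6);",
            {"A": 1.2, "B": 3.4, "C": 0.5, "D": 2.2, "E": 4.1},
        )
        assert sorted(np.abs(cs.contrasts)) == pytest.approx(expected, abs=1e-8)

    def test_brute_force_on_random_trees(self):
        # independent recursion over nested-tuple trees
        def brute_tree(node, values):
            """Returns (value, extended_branch, contrasts) bottom-up."""
            child, blen = node
            if isinstance(child, str):
                return values[child], blen, []
            (ln, rn) = child
            xl, bl, cl = brute_tree(ln, values)
            xr, br, cr = brute_tree(rn, values)
            tot = bl + br
            c = (xl - xr) / math.sqrt(tot)
            xa = (br * xl + bl * xr) / tot
            return xa, blen + bl * br / tot, cl + cr + [c]

        def to_newick(node):
            child, blen = node
            if isinstance(child, str):
                return f"{child}:{blen}"
            return f"({to_newick(child[0])},{to_newick(child[1])}):{blen}"

        rng = np.random.default_rng(23)
        for t in range(50):
            labels = [f"s{i}" for i in range(6)]
            nodes = [(lab, float(rng.uniform(0.1, 2.0))) for lab in labels]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                b = nodes.pop(j)
                a = nodes.pop(i)
                nodes.append(((a, b), float(rng.uniform(0.1, 2.0))))
            tree = nodes[0]
            values = {lab: float(rng.normal()) for lab in labels}
            _, _, expected = brute_tree(tree, values)
            newick = f"({to_newick(tree[0][0])},{to_newick(tree[0][1])});"
            got = pic_contrasts(newick, values)
            assert sorted(np.abs(got.contrasts)) == pytest.approx(
                sorted(np.abs(expected)), abs=1e-10
            )

    def test_correlation_of_proportional_traits(self):
        tree = "(((A:0.7,B:1.3):0.5,C:2.1):0.4,(D:0.9,E:1.1):1.6);"
        x = {"A": 1.2, "B": 3.4, "C": 0.5, "D": 2.2, "E": 4.1}
        y = {k: 2 * v for k, v in x.items()}
        r, p = pic_correlation(tree, x, y)
        assert r == pytest.approx(1.0)

    def test_negative_branch_length_errors(self):
        with pytest.raises(ValueError):
            pic_contrasts("(A:1,B:-1);", {"A": 1, "B": 2})

    def test_tip_mismatch_errors(self):
        with pytest.raises(ValueError):
            pic_contrasts("(A:1,B:1);", {"A": 1, "C": 2})


class TestPolarization:
    SPECIES = ["human", "chimp", "gorilla", "orang"]

    def test_acg_to_atg_is_cpg(self):
        df = classify_fixed_aug_origins(
            {"s": ["GATG", "GACG", "GACG", "GACG", "GACG"]},
            self.SPECIES, "macaque",
        )
        row = df.iloc[0]
        assert row.branch == 1 and row.cpg_derived and not row.homoplasy

    def test_cgtg_to_catg_is_cpg(self):
        df = classify_fixed_aug_origins(
            {"s": ["CATG", "CGTG", "CGTG", "CGTG", "CGTG"]},
            self.SPECIES, "macaque",
        )
        assert df.iloc[0].cpg_derived

    def test_ttg_ancestor_not_cpg(self):
        df = classify_fixed_aug_origins(
            {"s": ["GATG", "GTTG", "GTTG", "GTTG", "GTTG"]},
            self.SPECIES, "macaque",
        )
        row = df.iloc[0]
        assert row.branch == 1 and not row.cpg_derived

    def test_deeper_branch_assignment(self):
        df = classify_fixed_aug_origins(
            {"s": ["GATG", "GATG", "GACG", "GACG", "GACG"]},
            self.SPECIES, "macaque",
        )
        assert df.iloc[0].branch == 2

    def test_non_nested_pattern_flagged_homoplasy(self):
        df = classify_fixed_aug_origins(
            {"s": ["GATG", "GTTG", "GATG", "GTTG", "GTTG"]},
            self.SPECIES, "macaque",
        )
        assert df.iloc[0].homoplasy
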
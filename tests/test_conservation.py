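"""Branch length scores, SNR curves, MAF presence, peptide screens."""

import numpy as np
import pytest

from uorfevolve.conservation import (
    PhylogeneticTree,
    branch_length_score,
    infer_origination_branch,
    parse_maf,
    peptide_conservation_search,
    presence_profile_from_maf,
    snr_curve,
)
from uorfevolve.models import PresenceProfile


def _profile(present, all_species, ref):
    return PresenceProfile(
        "site", ref, {sp: sp in present for sp in all_species}
    )


class TestBls:
    def test_all_present_is_one(self, four_taxon_tree):
        tree = PhylogeneticTree(four_taxon_tree)
        res = branch_length_score(_profile("ABCD", "ABCD", "A"), tree)
        assert res.bls == pytest.approx(1.0)

    def test_sister_pair_spans_third(self, four_taxon_tree):
        tree = PhylogeneticTree(four_taxon_tree)
        res = branch_length_score(_profile("AB", "ABCD", "A"), tree)
        assert res.b0 == pytest.approx(2.0)
        assert res.bls == pytest.approx(1 / 3)

    def test_cross_clade_pair(self, four_taxon_tree):
        tree = PhylogeneticTree(four_taxon_tree)
        res = branch_length_score(_profile("AC", "ABCD", "A"), tree)
        # path A-root-C spans both cherry edges and both internal edges
        assert res.b0 == pytest.approx(4.0)

    def test_reference_only_is_zero(self, four_taxon_tree):
        tree = PhylogeneticTree(four_taxon_tree)
        res = branch_length_score(_profile("A", "ABCD", "A"), tree)
        assert res.b0 == 0.0 and res.bls == 0.0

    def test_monotone_in_presence(self, four_taxon_tree):
        tree = PhylogeneticTree(four_taxon_tree)
        prev = 0.0
        for present in ("A", "AB", "ABC", "ABCD"):
            bls = branch_length_score(_profile(present, "ABCD", "A"), tree).bls
            assert bls >= prev
            prev = bls

    def test_unknown_species_errors(self, four_taxon_tree):
        tree = PhylogeneticTree(four_taxon_tree)
        with pytest.raises(ValueError, match="not in tree"):
            branch_length_score(_profile("AZ", "ABCDZ", "A"), tree)

    def test_brute_force_oracle_random_trees(self):
        def brute_b0(tree, present):
            # sum of branch lengths on the union of tip-to-tip paths
            pdm = tree.tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.tree.taxon_namespace}
            leaves = {
                leaf.taxon.label: leaf for leaf in tree.tree.leaf_node_iter()
            }
            edges = set()
            ids = sorted(present)
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    # walk up from both tips to their MRCA, collecting edges
                    mrca = pdm.mrca(taxa[a], taxa[b])
                    for tip in (a, b):
                        node = leaves[tip]
                        while node is not mrca:
                            edges.add(node)
                            node = node.parent_node
            return sum(e.edge.length or 0.0 for e in edges)

        rng = np.random.default_rng(31)
        for t in range(100):
            labels = [f"s{i}" for i in range(8)]
            nodes = [f"{lab}:{rng.uniform(0.05, 2):.6f}" for lab in labels]
            while len(nodes) > 2:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                b = nodes.pop(j)
                a = nodes.pop(i)
                nodes.append(f"({a},{b}):{rng.uniform(0.05, 2):.6f}")
            newick = f"({nodes[0]},{nodes[1]});"
            tree = PhylogeneticTree(newick)
            k = int(rng.integers(1, 9))
            present = set(rng.choice(labels, size=k, replace=False))
            got = branch_length_score(_profile(present, labels, labels[0] if labels[0] in present else next(iter(present))), tree)
            expected = brute_b0(tree, present)
            assert got.b0 == pytest.approx(expected, abs=1e-10)


class TestOrigination:
    def test_reference_only_terminal_branch(self, four_taxon_tree):
        tree = PhylogeneticTree(four_taxon_tree)
        assert infer_origination_branch(_profile("A", "ABCD", "A"), tree) == "A"

    def test_all_present_root(self, four_taxon_tree):
        tree = PhylogeneticTree(four_taxon_tree)
        assert infer_origination_branch(_profile("ABCD", "ABCD", "A"), tree) == "root"

    def test_gain_with_implied_loss(self):
        tree = PhylogeneticTree("((H:1,C:1):1,G:2);")
        # present H and G: one gain above MRCA(H,C,G) = root, loss in C
        assert infer_origination_branch(_profile("HG", "HCG", "H"), tree) == "root"
        # present H and C: gain on the (H,C) ancestral branch
        assert infer_origination_branch(_profile("HC", "HCG", "H"), tree) == "C,H"


class TestSnr:
    def test_worked_example(self):
        curve = snr_curve([0.8, 0.6, 0.2], [0.9, 0.1, 0.1, 0.1], [0.0, 0.5])
        assert curve.snr[0] == pytest.approx(1.0)
        assert curve.snr[1] == pytest.approx((2 / 3) / (1 / 4))

    def test_null_signal_equals_background(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, size=4000)
        curve = snr_curve(vals[:2000], vals[2000:], [0.0, 0.25, 0.5, 0.75])
        for s in curve.snr:
            assert s == pytest.approx(1.0, abs=0.15)

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            snr_curve([], [0.5], [0.0])


MAF = """##maf version=1
a score=12.0
s human.chr1 10 9 + 1000 CCATGGGTT
s chimp.chr1 0 9 + 900 CCATGGGTT
s mouse.chr1 0 9 + 800 CCA-GGGTT
s rat.chr1 0 9 + 800 ccatgggtt

"""


class TestMafPresence:
    def test_gap_rule_and_softmask(self):
        blocks = parse_maf(MAF)
        profile = presence_profile_from_maf(
            blocks, "s1", "chr1", 12, ["human", "chimp", "mouse", "rat", "dog"],
            reference="human",
        )
        assert profile.presence["human"]
        assert profile.presence["chimp"]
        assert not profile.presence["mouse"]  # gap in the triplet columns
        assert profile.presence["rat"]  # lowercase atg tolerated
        assert not profile.presence["dog"]  # absent from the block

    def test_uncovered_site_errors(self):
        blocks = parse_maf(MAF)
        with pytest.raises(ValueError, match="not covered"):
            presence_profile_from_maf(
                blocks, "s", "chr1", 500, ["human"], reference="human"
            )

    def test_insertion_columns_skipped_in_reference(self):
        maf = (
            "##maf version=1\n"
            "a score=1.0\n"
            "s ref.c 0 6 + 100 AC--ATG\n"
            "s sp2.c 0 7 + 100 ACGGATG\n\n"
        )
        profile = presence_profile_from_maf(
            parse_maf(maf), "s", "c", 2, ["ref", "sp2"], reference="ref"
        )
        assert profile.presence["ref"] and profile.presence["sp2"]


class TestPeptideSearch:
    REF = "MKLVAGSTRQWELNPQ"  # 16 aa
    DNA = (
        "ATGAAACTGGTTGCAGGTTCAACACGTCAATGGGAACTGAACCCGCAA"
    )  # encodes REF

    def test_identical_target_matches(self):
        res = peptide_conservation_search(
            "p", self.REF, {"B": self.DNA}, identity_threshold=0.3
        )
        m = res.matches["B"]
        assert m.matched and m.identity == pytest.approx(1.0)

    def test_early_stop_disrupts(self):
        # stop codon at codon 3 of 16 (< 80% of the match)
        dna = self.DNA[:6] + "TAA" + self.DNA[9:]
        res = peptide_conservation_search("p", self.REF, {"B": dna})
        assert not res.matches["B"].matched
        assert res.matches["B"].disrupted_in_first_80pct

    def test_late_frameshift_tolerated(self):
        # 1-nt deletion at ~90% of the peptide: head is clean, matched
        cut = 3 * 14  # within codon 15 of 16
        dna = self.DNA[:cut] + self.DNA[cut + 1 :]
        res = peptide_conservation_search("p", self.REF, {"B": dna})
        assert res.matches["B"].matched

    def test_non_aug_start_rejected(self):
        dna = "CTG" + self.DNA[3:]
        res = peptide_conservation_search("p", self.REF, {"B": dna})
        assert not res.matches["B"].matched
        assert not res.matches["B"].first_codon_atg

    def test_short_reference_errors(self):
        with pytest.raises(ValueError):
            peptide_conservation_search("p", "MKLV", {"B": self.DNA})

    def test_stop_in_reference_errors(self):
        with pytest.raises(ValueError):
            peptide_conservation_search("p", "MKL*VAGSTRQ", {"B": self.DNA})

    def test_peptide_bls_from_matches(self, four_taxon_tree):
        tree = PhylogeneticTree(four_taxon_tree)
        res = peptide_conservation_search(
            "p", self.REF,
            {"B": self.DNA, "C": "ACGT" * 12, "D": "ACGT" * 12},
            tree=tree, reference="A",
        )
        assert res.peptide_bls == pytest.approx(1 / 3)


class TestConservationRecovery:
    """Generator ground truth: conserved sites score higher."""

    def _dataset(self, n_sites=40, body=40, seed=19, boost=0.9):
        from uorfevolve.synthetic import SynthSpec, gen_alignment_set

        spec = SynthSpec(seed=seed, conservation_boost=boost)
        rng = np.random.default_rng(seed)
        sites = []
        for i in range(n_sites):
            seq = "".join("ACGT"[b] for b in rng.integers(4, size=body))
            sites.append((f"s{i}", seq[:5] + "ATG" + seq[8:], 5))
        maf_text, truth = gen_alignment_set(spec, sites)
        return spec, parse_maf(maf_text), truth

    def test_conserved_sites_outscore_background(self):
        spec, blocks, truth = self._dataset()
        tree = PhylogeneticTree(spec.tree_newick)
        sig, bg = [], []
        for sid, info in truth["sites"].items():
            profile = presence_profile_from_maf(
                blocks, sid, "chrS", info["aug_start"], tree.species,
                spec.reference_species,
            )
            bls = branch_length_score(profile, tree).bls
            (sig if info["conserved"] else bg).append(bls)
        assert np.mean(sig) > np.mean(bg)
        curve = snr_curve(sig, bg, [0.0, 0.5])
        assert curve.snr[1] is None or curve.snr[1] > 1.0

    def test_peptide_bls_below_start_bls(self):
        # start triplets are boosted but peptide bodies drift, so
        # peptide-level conservation trails start-codon conservation
        from uorfevolve.synthetic import SynthSpec, gen_alignment_set
        from Bio.Seq import Seq as _Seq

        spec = SynthSpec(seed=29, conservation_boost=1.0)
        rng = np.random.default_rng(29)
        sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in {"TAA", "TAG", "TGA"}]
        sites = []
        for i in range(12):
            body = "".join(sense[j] for j in rng.integers(61, size=14))
            sites.append((f"s{i}", "CC" + "ATG" + body + "TAACC", 2))
        maf_text, truth = gen_alignment_set(spec, sites)
        blocks = parse_maf(maf_text)
        tree = PhylogeneticTree(spec.tree_newick)
        start_bls, pep_bls = [], []
        for i, block in enumerate(blocks):
            info = truth["sites"][f"s{i}"]
            if not info["conserved"]:
                continue
            profile = presence_profile_from_maf(
                blocks, f"s{i}", "chrS", info["aug_start"], tree.species,
                spec.reference_species,
            )
            start_bls.append(branch_length_score(profile, tree).bls)
            ref_row = next(r for r in block if r.id.startswith("A."))
            ref_dna = str(ref_row.seq)[2:]
            pep = str(_Seq(ref_dna[: 3 * 15]).translate())
            targets = {
                r.id.partition(".")[0]: str(r.seq)[2:]
                for r in block
                if not r.id.startswith("A.")
            }
            res = peptide_conservation_search(
                f"s{i}", pep, targets, identity_threshold=0.3,
                min_codons=10, tree=tree, reference="A",
            )
            pep_bls.append(res.peptide_bls)
        assert np.mean(pep_bls) <= np.mean(start_bls)
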
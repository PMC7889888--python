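"""Branch-length-score (BLS) conservation of uORF start codons and
peptides over multiple-species alignments.

BLS of a site = B0 / total tree length, where B0 is the branch length
of the minimal subtree spanning the species in which the orthologous
triplet is an exact AUG.  Signal-to-noise curves compare uoAUGs against
background triplets at increasing BLS cutoffs.
"""

from __future__ import annotations

import io
from typing import Optional, Sequence

import dendropy
import numpy as np
from Bio import AlignIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .models import BlsResult, PeptideConservation, PresenceProfile, SnrCurve, SpeciesMatch


class PhylogeneticTree:
    """A rooted tree with branch lengths, wrapping dendropy."""

    def __init__(self, newick: str):
        self.tree = dendropy.Tree.get(data=newick, schema="newick")
        self.total_length = 0.0
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None:
                if edge.length < 0:
                    raise ValueError("negative branch length")
                self.total_length += edge.length
        if self.total_length <= 0:
            raise ValueError("tree has no positive branch lengths")
        self.species = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


def branch_length_score(profile: PresenceProfile, tree: PhylogeneticTree) -> BlsResult:
    """B0 and BLS of the present-species spanning subtree.

    B0 sums the branch lengths of edges strictly below the MRCA of the
    present species that lead to at least one present tip; a single
    present species spans no edges (BLS 0).
    """
    present = set(profile.present_species)
    unknown = present - set(tree.species)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    if len(present) <= 1:
        return BlsResult(profile.site_id, 0.0, 0.0)
    n_present: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            n_present[node] = int(node.taxon.label in present)
        else:
            n_present[node] = sum(n_present[c] for c in node.child_nodes())
    total = len(present)
    # MRCA = deepest node containing all present tips
    mrca = tree.tree.seed_node
    changed = True
    while changed:
        changed = False
        for c in mrca.child_nodes():
            if n_present[c] == total:
                mrca = c
                changed = True
                break
    b0 = 0.0
    for node in mrca.preorder_iter():
        if node is mrca:
            continue
        if n_present[node] > 0 and node.edge.length:
            b0 += node.edge.length
    return BlsResult(profile.site_id, b0, b0 / tree.total_length)


def infer_origination_branch(profile: PresenceProfile, tree: PhylogeneticTree) -> str:
    """Single-gain (Dollo) parsimony origination branch of a site.

    The gain is placed on the branch subtending the MRCA of all present
    species (losses implied inside the clade where needed).  Returns
    the tip label for a reference-only site, "root" when all tips are
    present or the MRCA is the root, and otherwise the sorted
    comma-joined tips of the MRCA clade.
    """
    present = set(profile.present_species)
    if len(present) == 1:
        return next(iter(present))
    n_present: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            n_present[node] = int(node.taxon.label in present)
        else:
            n_present[node] = sum(n_present[c] for c in node.child_nodes())
    mrca = tree.tree.seed_node
    changed = True
    while changed:
        changed = False
        for c in mrca.child_nodes():
            if n_present[c] == len(present):
                mrca = c
                changed = True
                break
    if mrca is tree.tree.seed_node:
        return "root"
    return ",".join(sorted(leaf.taxon.label for leaf in mrca.leaf_iter()))


def snr_curve(
    signal_bls: Sequence[float],
    background_bls: Sequence[float],
    cutoffs: Sequence[float],
) -> SnrCurve:
    """fraction(signal >= c) / fraction(background >= c) per cutoff."""
    if not len(signal_bls) or not len(background_bls):
        raise ValueError("signal and background must be nonempty")
    sig = np.asarray(signal_bls, float)
    bg = np.asarray(background_bls, float)
    snr, sfrac, bfrac = [], [], []
    for c in cutoffs:
        fs = float((sig >= c).mean())
        fb = float((bg >= c).mean())
        sfrac.append(fs)
        bfrac.append(fb)
        snr.append(fs / fb if fb > 0 else None)
    return SnrCurve(list(cutoffs), snr, sfrac, bfrac)


# ---------------------------------------------------------------------------
# MAF presence profiles


def parse_maf(maf) -> list:
    """Parse MAF blocks from a path, file handle, or literal text."""
    if isinstance(maf, str) and "\n" in maf:
        handle = io.StringIO(maf)
    elif hasattr(maf, "read"):
        handle = maf
    else:
        handle = open(maf)
    return list(AlignIO.parse(handle, "maf"))


def presence_profile_from_maf(
    maf,
    site_id: str,
    chrom: str,
    start: int,
    species_list: Sequence[str],
    reference: str,
) -> PresenceProfile:
    """Presence/absence of an exact AUG at orthologous positions.

    ``start`` is the 0-based position of the A in reference (+ strand)
    coordinates; src fields are "species.chrom".  A species is present
    iff its aligned triplet at the reference columns is gap-free ATG
    (case-insensitive; N counts as absent).  The first block covering
    the site in the reference provides the call.
    """
    blocks = maf if isinstance(maf, list) else parse_maf(maf)
    presence = {sp: False for sp in species_list}
    for block in blocks:
        ref_rec = None
        for rec in block:
            sp, _, rchrom = rec.id.partition(".")
            if sp == reference and rchrom == chrom:
                ref_rec = rec
                break
        if ref_rec is None:
            continue
        rstart = ref_rec.annotations["start"]
        rsize = ref_rec.annotations["size"]
        if not (rstart <= start and start + 3 <= rstart + rsize):
            continue
        # columns holding the three reference bases
        cols = []
        pos = rstart
        for col, ch in enumerate(str(ref_rec.seq)):
            if ch != "-":
                if pos >= start:
                    cols.append(col)
                    if len(cols) == 3:
                        break
                pos += 1
        if len(cols) < 3:
            continue
        for rec in block:
            sp = rec.id.partition(".")[0]
            if sp not in presence:
                continue
            triplet = "".join(str(rec.seq)[c] for c in cols).upper()
            presence[sp] = triplet == "ATG"
        return PresenceProfile(site_id=site_id, reference=reference, presence=presence)
    raise ValueError(f"site {site_id} at {chrom}:{start} not covered in reference")


# ---------------------------------------------------------------------------
# peptide conservation


def _protein_aligner(match=2.0, mismatch=-1.0, open_gap=-4.0, extend=-1.0):
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend
    return aligner


def peptide_conservation_search(
    site_id: str,
    ref_peptide: str,
    target_utr_dna: dict[str, str],
    identity_threshold: float = 0.3,
    min_codons: int = 10,
    tree: Optional[PhylogeneticTree] = None,
    reference: str = "ref",
) -> PeptideConservation:
    """Screen target UTRs for a conserved uORF peptide.

    For each species the reference peptide is locally aligned against
    the three forward-frame translations of the target.  A species
    matches when (1) the first aligned target codon is AUG, (2) no stop
    codon or indel disrupts the first 80% of the match, and (3) the
    identity over the aligned region exceeds ``identity_threshold``.
    When a tree is supplied, the matched species (plus the reference)
    give a peptide BLS via :func:`branch_length_score`.
    """
    if "*" in ref_peptide:
        raise ValueError("reference peptide contains a stop symbol")
    if len(ref_peptide) < min_codons:
        raise ValueError(f"reference peptide shorter than {min_codons} codons")
    aligner = _protein_aligner()
    matches: dict[str, SpeciesMatch] = {}
    for species, dna in target_utr_dna.items():
        best = None
        for frame in range(3):
            sub = dna[frame:].upper()
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            trans = str(Seq(sub).translate())
            alns = aligner.align(ref_peptide, trans)
            if not len(alns):
                continue
            aln = alns[0]
            cand = _evaluate_match(species, frame, aln, trans, identity_threshold)
            if best is None or cand[1] > best[1]:
                best = (cand[0], cand[1])
        if best is None:
            matches[species] = SpeciesMatch(species, False, 0.0, False, True)
        else:
            matches[species] = best[0]
    result = PeptideConservation(site_id=site_id, matches=matches)
    if tree is not None:
        presence = {sp: m.matched for sp, m in matches.items()}
        presence[reference] = True
        profile = PresenceProfile(site_id=site_id, reference=reference, presence=presence)
        result.peptide_bls = branch_length_score(profile, tree).bls
    return result


def _evaluate_match(species, frame, aln, trans, identity_threshold):
    ref_aln, tgt_aln = aln[0], aln[1]
    length = len(ref_aln)
    n_ident = sum(
        1 for a, b in zip(ref_aln, tgt_aln) if a == b and a != "-"
    )
    identity = n_ident / length if length else 0.0
    tgt_start = aln.aligned[1][0][0] if len(aln.aligned[1]) else 0
    first_codon_atg = False
    if length:
        # aligned[1] gives target (translated) segment coordinates
        codon_dna_start = frame + 3 * tgt_start
        first_codon_atg = trans[tgt_start : tgt_start + 1] == "M"
        del codon_dna_start
    cut = int(np.ceil(0.8 * length))
    head_ref = ref_aln[:cut]
    head_tgt = tgt_aln[:cut]
    disrupted = "*" in head_tgt or "-" in head_ref or "-" in head_tgt
    matched = bool(
        first_codon_atg and not disrupted and identity > identity_threshold
    )
    sm = SpeciesMatch(
        species=species,
        matched=matched,
        identity=identity,
        first_codon_atg=first_codon_atg,
        disrupted_in_first_80pct=disrupted,
        frame=frame,
    )
    return sm, aln.score
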
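"""Synthetic-data generators with known ground truth.

Each generator emulates the statistical structure of one class of real
input — transcript models with controllable uAUG depletion, tree-wise
alignments with elevated conservation at designated sites, MK-style
site-frequency data with a chosen adaptive fraction, genotype-dependent
translation-efficiency panels, and Kozak-dependent initiation signal —
and returns the realized ground truth alongside the data.

UTR composition follows a first-order Markov chain, which by
construction matches the dinucleotide-preserving null of the O/E
permutation statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import find_and_classify_uaugs
from .models import MkInput, TranscriptModel

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")


def default_transition_matrix() -> np.ndarray:
    """Mildly non-uniform base transitions with CpG depletion."""
    m = np.full((4, 4), 0.25)
    m[1, 2] = 0.10  # C->G depleted (CpG)
    m[1, 0] = 0.30
    m[1, 3] = 0.35
    m[1, 1] = 0.25
    return m / m.sum(axis=1, keepdims=True)


@dataclass
class SynthSpec:
    """Parameters of all generators; defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 300
    utr5_median: float = 150.0
    utr5_sigma: float = 0.6
    utr3_median: float = 300.0
    cds_codons_range: tuple[int, int] = (100, 400)
    transition: np.ndarray = field(default_factory=default_transition_matrix)
    uaug_retention: float = 1.0
    class_retention: Optional[dict[str, float]] = None  # per nORF/oORF/NTE
    # alignment generator
    tree_newick: str = (
        "(((A:0.10,B:0.10):0.10,(C:0.10,D:0.10):0.10):0.10,"
        "((E:0.10,F:0.10):0.10,(G:0.10,H:0.10):0.10):0.10);"
    )
    reference_species: str = "A"
    substitution_rate: float = 0.8  # per unit branch length, per site
    conservation_boost: float = 0.9
    # MK generator
    mk_true_alpha: float = 0.4
    mk_n_bins: int = 20
    mk_neutral_poly: int = 20000
    mk_d_neutral: int = 5000
    mk_test_scale: float = 0.5
    mk_deleterious_weight: float = 1.0
    mk_deleterious_decay: float = 15.0
    # TE panel
    te_n_individuals: int = 60
    te_n_canonical: int = 30
    te_n_noncanonical: int = 30
    te_effect_beta: float = 0.4
    te_noise_sd: float = 0.5
    # TIS
    tis_n_sites: int = 500
    tis_mean_rpf: float = 30.0
    tis_rna_cov_median: float = 10.0
    kozak_pwm_true: Optional[np.ndarray] = None


def _stationary(transition: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(vals - 1)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _markov_seq(n: int, transition: np.ndarray, rng: np.random.Generator) -> str:
    pi = _stationary(transition)
    if not np.all(transition.sum(axis=1) > 0):
        raise ValueError("degenerate transition matrix")
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(4, p=pi)
    # cumulative rows for fast inverse-CDF sampling
    cum = transition.cumsum(axis=1)
    u = rng.random(n)
    for i in range(1, n):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i])
    return "".join(_BASES[s] for s in states)


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    sense = [
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in _STOPS
    ]
    body = rng.choice(len(sense), size=n_codons - 2)
    stop = _STOPS[rng.integers(3)]
    return "ATG" + "".join(sense[i] for i in body) + stop


def gen_transcriptome(
    spec: SynthSpec, seed: Optional[int] = None
) -> tuple[list[TranscriptModel], dict]:
    """Markov-composed transcripts with controlled uAUG retention.

    Each uAUG arising in a 5'UTR is independently retained with the
    (class-specific) retention probability; otherwise one of its three
    bases is mutated.  Newly created uAUGs receive their own draw.
    The truth records initial/final uAUG counts and realized retention.
    """
    base_seed = (spec.seed if seed is None else seed) & 0x7FFFFFFF
    models = []
    n_initial = 0
    n_final = 0
    per_class = {"nORF": [0, 0], "oORF": [0, 0], "NTE": [0, 0]}
    for g in range(spec.n_genes):
        # per-gene streams: sequences are identical across retention
        # settings under the same seed (common random numbers)
        rng = np.random.default_rng([base_seed, g, 0])
        rng_dep = np.random.default_rng([base_seed, g, 1])
        u5 = max(9, int(round(rng.lognormal(np.log(spec.utr5_median), spec.utr5_sigma))))
        u3 = max(9, int(round(rng.lognormal(np.log(spec.utr3_median), spec.utr5_sigma))))
        codons = int(rng.integers(*spec.cds_codons_range))
        model = TranscriptModel(
            transcript_id=f"tx{g:05d}",
            gene_id=f"gene{g:05d}",
            utr5_seq=_markov_seq(u5, spec.transition, rng),
            cds_seq=_random_cds(codons, rng),
            utr3_seq=_markov_seq(u3, spec.transition, rng),
            is_longest=True,
        )
        ni, nf = _apply_depletion(model, spec, rng_dep, per_class)
        n_initial += ni
        n_final += nf
        models.append(model)
    truth = {
        "n_uaug_initial": n_initial,
        "n_uaug_final": n_final,
        "realized_retention": n_final / n_initial if n_initial else None,
        "retention_requested": spec.uaug_retention,
        "class_retention": spec.class_retention,
        "per_class_counts": {k: tuple(v) for k, v in per_class.items()},
    }
    return models, truth


def _count_atg(seq: str) -> int:
    count, pos = 0, seq.find("ATG")
    while pos != -1:
        count += 1
        pos = seq.find("ATG", pos + 1)
    return count


def _window_atg_count(seq: list[str], pos: int) -> int:
    lo = max(0, pos - 2)
    return _count_atg("".join(seq[lo : pos + 3]))


def _destroy_atg(utr: list[str], offset: int, rng) -> bool:
    """Remove one AUG occurrence while preserving dinucleotide counts.

    Swaps one of the AUG's bases with a character elsewhere that has
    the same left and right neighbors (so the dinucleotide multiset is
    untouched), rejecting swaps that would create or destroy any other
    AUG.  Returns False when no safe swap exists.
    """
    n = len(utr)
    for p in (offset + int(k) for k in rng.permutation(3)):
        if p == 0 or p >= n - 1:
            continue  # endpoint characters are fixed under the null
        left, right, base = utr[p - 1], utr[p + 1], utr[p]
        candidates = [
            j
            for j in range(1, n - 1)
            if utr[j] != base
            and utr[j - 1] == left
            and utr[j + 1] == right
            and not (offset - 2 <= j <= offset + 4)
        ]
        rng.shuffle(candidates)
        for j in candidates:
            before = _window_atg_count(utr, p) + _window_atg_count(utr, j)
            utr[p], utr[j] = utr[j], utr[p]
            after = _window_atg_count(utr, p) + _window_atg_count(utr, j)
            if after == before - 1:
                return True
            utr[p], utr[j] = utr[j], utr[p]  # revert unsafe swap
    return False


def _apply_depletion(model, spec, rng, per_class) -> tuple[int, int]:
    """Thin uAUGs per-occurrence without disturbing composition.

    Each uAUG is independently retained with its (class-specific)
    retention probability; a non-retained uAUG is removed by a
    context-matched character swap that leaves the dinucleotide
    multiset — and hence the permutation-null expectation — exactly
    unchanged, so the O/E ratio recovers the retention parameter.
    When no safe swap exists (short or extreme sequences) the uAUG is
    destroyed by a plain point mutation instead.
    """
    recs = find_and_classify_uaugs(model)
    for r in recs:
        if r.klass in per_class:
            per_class[r.klass][0] += 1
    n_initial = len(recs)
    retentions = [spec.uaug_retention]
    if spec.class_retention:
        retentions += list(spec.class_retention.values())
    if min(retentions) < 1.0:
        utr = list(model.utr5_seq)
        for r in recs:
            keep = spec.uaug_retention
            if spec.class_retention:
                keep = spec.class_retention.get(r.klass, keep)
            if rng.random() >= keep:
                if not _destroy_atg(utr, r.site.utr_offset, rng):
                    off = r.site.utr_offset + int(rng.integers(3))
                    choices = [b for b in _BASES if b != utr[off]]
                    utr[off] = choices[int(rng.integers(3))]
        model.utr5_seq = "".join(utr)
    final = find_and_classify_uaugs(model)
    for r in final:
        if r.klass in per_class:
            per_class[r.klass][1] += 1
    return n_initial, len(final)


# ---------------------------------------------------------------------------
# alignments on a tree


def gen_alignment_set(
    spec: SynthSpec,
    sequences: Sequence[tuple[str, str, int]],
    seed: Optional[int] = None,
) -> tuple[str, dict]:
    """Evolve reference UTRs down the tree; emit MAF text plus truth.

    ``sequences`` is a list of (site_id, reference_sequence,
    aug_offset); roughly half the sites (chosen at random) are
    designated conserved and have their AUG triplet restored with
    probability ``conservation_boost`` after the substitutions on each
    branch.  The reference species keeps the original sequence.
    """
    import dendropy

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    tree = dendropy.Tree.get(data=spec.tree_newick, schema="newick")
    n = len(sequences)
    conserved = set(rng.choice(n, size=n // 2, replace=False).tolist())
    blocks = []
    truth_sites = {}
    offset = 0
    for i, (site_id, refseq, aug_off) in enumerate(sequences):
        tip_seqs = _evolve_site(
            tree, refseq, aug_off, i in conserved, spec, rng
        )
        tip_seqs[spec.reference_species] = refseq
        lines = [f"a score=0.0"]
        for sp in sorted(tip_seqs):
            seq = tip_seqs[sp]
            start = offset if sp == spec.reference_species else 0
            src_size = offset + len(refseq) + 10_000 if sp == spec.reference_species else len(seq)
            lines.append(
                f"s {sp}.chrS {start} {len(seq)} + {src_size} {seq}"
            )
        blocks.append("\n".join(lines))
        truth_sites[site_id] = {
            "conserved": i in conserved,
            "ref_start": offset,
            "aug_start": offset + aug_off,
        }
        offset += len(refseq)
    maf_text = "##maf version=1\n" + "\n\n".join(blocks) + "\n"
    truth = {
        "conserved_fraction": len(conserved) / n if n else 0.0,
        "boost": spec.conservation_boost,
        "sites": truth_sites,
    }
    return maf_text, truth


def _evolve_site(tree, refseq, aug_off, is_conserved, spec, rng):
    seqs = {}
    state = {tree.seed_node: refseq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = state[node.parent_node]
        bl = node.edge.length or 0.0
        p_sub = min(0.75, spec.substitution_rate * bl)
        arr = list(parent_seq)
        hit = rng.random(len(arr)) < p_sub
        for i in np.flatnonzero(hit):
            choices = [b for b in _BASES if b != arr[i]]
            arr[i] = choices[int(rng.integers(3))]
        if is_conserved and rng.random() < spec.conservation_boost:
            arr[aug_off : aug_off + 3] = list("ATG")
        child_seq = "".join(arr)
        state[node] = child_seq
        if node.is_leaf():
            seqs[node.taxon.label] = child_seq
    return seqs


# ---------------------------------------------------------------------------
# MK dataset


def gen_mk_dataset(
    spec: SynthSpec, seed: Optional[int] = None
) -> tuple[MkInput, dict]:
    """Binned SFS data with a known adaptive fraction of fixations.

    The neutral SFS follows the standard-neutral 1/x expectation; the
    test class adds a deleterious component concentrated at low DAF
    (exponential decay) on top of a scaled neutral shape.  D_test is
    set so the expected adaptive fraction of test fixations equals
    ``mk_true_alpha``; counts are Poisson-sampled around expectations.
    """
    if not 0.0 <= spec.mk_true_alpha < 1.0:
        raise ValueError("mk_true_alpha must be in [0, 1)")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k = spec.mk_n_bins
    x = (np.arange(k) + 0.5) / k
    neutral_shape = (1.0 / x) / (1.0 / x).sum()
    e_neutral = spec.mk_neutral_poly * neutral_shape
    del_shape = np.exp(-spec.mk_deleterious_decay * x)
    del_shape /= del_shape.sum()
    e_test = (
        spec.mk_test_scale * e_neutral
        + spec.mk_deleterious_weight * spec.mk_test_scale
        * spec.mk_neutral_poly * del_shape
    )
    p_neutral = rng.poisson(e_neutral)
    p_test = rng.poisson(e_test)
    d_neutral = spec.mk_d_neutral
    e_d_test = spec.mk_test_scale * d_neutral / (1.0 - spec.mk_true_alpha)
    d_test = int(rng.poisson(e_d_test))
    realized_alpha = 1.0 - spec.mk_test_scale * d_neutral / d_test if d_test else np.nan
    mk = MkInput(
        daf_bins=x.tolist(),
        p_test=p_test.tolist(),
        p_neutral=p_neutral.tolist(),
        d_test=d_test,
        d_neutral=d_neutral,
    )
    truth = {
        "true_alpha": spec.mk_true_alpha,
        "realized_alpha": float(realized_alpha),
        "test_scale": spec.mk_test_scale,
    }
    return mk, truth


def naive_alpha(mk: MkInput) -> float:
    """Classic (non-asymptotic) MK alpha pooling all polymorphisms."""
    p_test, p_neutral = sum(mk.p_test), sum(mk.p_neutral)
    return 1.0 - (mk.d_neutral / mk.d_test) * (p_test / p_neutral)


# ---------------------------------------------------------------------------
# neutral codon-pair evolution (for NG86 calibration)


def gen_neutral_codon_pairs(
    n_pairs: int,
    codons_per_pair: int,
    p_sub: float = 0.03,
    seed: int = 0,
) -> list[tuple[tuple[str, str], float]]:
    """Codon-aligned pairs diverged under site-neutral substitution.

    Every site mutates independently with probability ``p_sub`` to a
    uniform different base (no selection on amino acids), so omega is
    1 in expectation.  Stop-containing codons are skipped by the NG86
    counter.  Each pair carries a random 'Kozak score' for binning.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_pairs):
        n = 3 * codons_per_pair
        s1 = "".join(_BASES[b] for b in rng.integers(4, size=n))
        arr = list(s1)
        hit = rng.random(n) < p_sub
        for j in np.flatnonzero(hit):
            choices = [b for b in _BASES if b != arr[j]]
            arr[j] = choices[int(rng.integers(3))]
        out.append(((s1, "".join(arr)), float(rng.normal())))
    return out


# ---------------------------------------------------------------------------
# TE panel


def gen_te_panel(
    spec: SynthSpec, seed: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Genotype + translation-efficiency panel with known effect sizes.

    Genotypes (non-uORF allele counts) are Binomial(2, f) with allele
    frequency f ~ U(0.1, 0.5); log2 TE = beta * genotype + N(0, sd).
    Canonical variants carry beta = ``te_effect_beta``; noncanonical
    variants are null (beta = 0).
    Returns (variants, genotypes, te, truth).
    """
    if spec.te_n_individuals < 10:
        raise ValueError("need at least 10 individuals")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    individuals = [f"ind{i:03d}" for i in range(spec.te_n_individuals)]
    rows, geno_rows, te_rows, betas = [], [], [], {}
    n_total = spec.te_n_canonical + spec.te_n_noncanonical
    for v in range(n_total):
        canonical = v < spec.te_n_canonical
        beta = spec.te_effect_beta if canonical else 0.0
        vid, gene = f"var{v:04d}", f"gene{v:04d}"
        f = rng.uniform(0.1, 0.5)
        g = rng.binomial(2, f, size=spec.te_n_individuals)
        y = beta * g + rng.normal(0, spec.te_noise_sd, size=spec.te_n_individuals)
        maf = min(g.mean() / 2, 1 - g.mean() / 2)
        rows.append(
            {"variant_id": vid, "gene_id": gene, "canonical": canonical, "maf": maf}
        )
        geno_rows.append(pd.Series(g, index=individuals, name=vid))
        te_rows.append(pd.Series(y, index=individuals, name=gene))
        betas[vid] = beta
    variants = pd.DataFrame(rows)
    genotypes = pd.DataFrame(geno_rows)
    te = pd.DataFrame(te_rows)
    truth = {"betas": betas, "beta_canonical": spec.te_effect_beta}
    return variants, genotypes, te, truth


# ---------------------------------------------------------------------------
# TIS dataset


def gen_tis_dataset(
    spec: SynthSpec, seed: Optional[int] = None
) -> tuple[pd.DataFrame, dict]:
    """Initiation signal proportional to 2^(Kozak score), plus noise.

    True per-site scores are N(0, 1.5); expected initiating-RPF counts
    scale as 2^score (normalized to ``tis_mean_rpf`` on average) and
    are Poisson-sampled; RNA coverage is log-normal.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.tis_n_sites
    score = rng.normal(0.0, 1.5, size=n)
    rel = np.power(2.0, score)
    cov = rng.lognormal(np.log(spec.tis_rna_cov_median), 0.4, size=n)
    lam = spec.tis_mean_rpf * rel / rel.mean() * (cov / spec.tis_rna_cov_median)
    rpf = rng.poisson(lam)
    reads = cov * 2.0
    df = pd.DataFrame(
        {
            "site_id": [f"site{i:05d}" for i in range(n)],
            "true_score": score,
            "rpf": rpf,
            "rna_cov": cov,
            "rna_reads": reads,
        }
    )
    truth = {"model": "rpf ~ Poisson(c * 2^score * cov)", "n_sites": n}
    return df, truth


def truth_to_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
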
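"""Population-genetic machinery for uORF gain and constraint.

Covers: Kimura-diffusion fixation probabilities with dominance, the
neutral/deleterious/beneficial mixture model of uORF fate, parsimony
polarization of newly fixed uAUGs with CpG-context classification, the
asymptotic McDonald-Kreitman estimator of alpha, pN/pS by derived-
allele-frequency bin, Nei-Gojobori (NG86) omega on Kozak-binned
concatenated alignments, and Felsenstein's phylogenetic independent
contrasts.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import integrate, optimize, stats

from .models import (
    ContrastSet,
    MkInput,
    MkResult,
    OmegaBin,
    SelectionModelParams,
    SnpRecord,
    UorfRecord,
)

# ---------------------------------------------------------------------------
# Kimura diffusion fixation probability


def relative_fixation_prob(params: SelectionModelParams) -> float:
    """Fixation probability of a new mutation relative to neutral.

    f(s) = 2 Ne * int_0^{1/(2Ne)} G(x) dx / int_0^1 G(x) dx with
    G(x) = exp[-4 Ne s h x - 2 Ne s (1-2h) x^2].  Evaluated by adaptive
    quadrature (relative tolerance 1e-9); the neutral limit f(0) = 1 is
    taken by continuity when |4 Ne s| < 1e-8.  The exponent is shifted
    by its maximum over [0, 1] before exponentiation (the shift cancels
    in the ratio), so strong selection does not overflow.
    """
    ne, s, h = params.ne, params.s, params.h
    if abs(4.0 * ne * s) < 1e-8:
        return 1.0
    a = 4.0 * ne * s * h
    b = 2.0 * ne * s * (1.0 - 2.0 * h)

    def phi(x):
        return -a * x - b * x * x

    candidates = [0.0, 1.0]
    if b != 0.0:
        xc = -a / (2.0 * b)
        if 0.0 < xc < 1.0:
            candidates.append(xc)
    m = max(phi(x) for x in candidates)

    def g(x: float) -> float:
        return np.exp(phi(x) - m)

    x0 = 1.0 / (2.0 * ne)
    # the integrand concentrates where phi peaks; give the adaptive
    # routine interior break points on the decay scale
    scale = 1.0 / max(abs(a) + abs(b), 1.0)
    pts = {min(1.0, k * scale) for k in (1, 5, 20)}
    pts |= {max(0.0, 1.0 - k * scale) for k in (1, 5, 20)}
    pts = sorted(p for p in pts if 0.0 < p < 1.0)
    num, _ = integrate.quad(g, 0.0, x0, epsrel=1e-11, epsabs=0, limit=200)
    den, _ = integrate.quad(
        g, 0.0, 1.0, epsrel=1e-11, epsabs=0, limit=200, points=pts or None
    )
    if den <= 0 or not np.isfinite(num) or not np.isfinite(den):
        raise ArithmeticError(
            f"quadrature failed for Ne={ne}, s={s}, h={h}: num={num}, den={den}"
        )
    return 2.0 * ne * num / den


def overall_relative_fixation(params: SelectionModelParams) -> tuple[float, float]:
    """Mixture-model fixation probability and adaptive fraction.

    overall = p1 + p2 f(-s) + p3 f(s) where p1/p2/p3 are the neutral,
    deleterious and beneficial fractions of new uORFs; the second value
    is the fraction of fixed uORFs driven by positive selection,
    p3 f(s) / overall.
    """
    f_ben = relative_fixation_prob(
        SelectionModelParams(params.ne, params.s, params.h)
    )
    f_del = relative_fixation_prob(
        SelectionModelParams(params.ne, -params.s, params.h)
    )
    overall = params.p_neutral + params.p_del * f_del + params.p_ben * f_ben
    if overall <= 0:
        raise ArithmeticError("overall fixation probability is zero")
    return overall, params.p_ben * f_ben / overall


def wright_fisher_fixation(
    ne: int,
    s: float,
    h: float = 0.5,
    n_rep: int = 100_000,
    seed: int = 0,
    max_gen: Optional[int] = None,
) -> tuple[float, float]:
    """Forward Wright-Fisher estimate of the relative fixation probability.

    Simulates ``n_rep`` new mutations (initial frequency 1/(2Ne)) in a
    diploid population with genotype fitnesses 1 : 1+hs : 1+s and
    returns (relative fixation probability, Monte-Carlo s.e.), both on
    the same scale as :func:`relative_fixation_prob` (neutral = 1).
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * ne
    if max_gen is None:
        max_gen = 200 * two_n
    p = np.full(n_rep, 1.0 / two_n)
    active = np.ones(n_rep, dtype=bool)
    fixed = 0
    for _ in range(max_gen):
        if not active.any():
            break
        pa = p[active]
        q = 1.0 - pa
        wbar = pa * pa * (1 + s) + 2 * pa * q * (1 + h * s) + q * q
        p_next = (pa * pa * (1 + s) + pa * q * (1 + h * s)) / wbar
        pa = rng.binomial(two_n, p_next) / two_n
        newly_fixed = pa >= 1.0
        fixed += int(newly_fixed.sum())
        still = (pa > 0.0) & ~newly_fixed
        idx = np.flatnonzero(active)
        p[idx] = pa
        active[idx] = still
    frac = fixed / n_rep
    rel = frac * two_n
    se = two_n * np.sqrt(frac * (1 - frac) / n_rep)
    return rel, se


# ---------------------------------------------------------------------------
# polarization of newly fixed uAUGs


def classify_fixed_aug_origins(
    site_contexts: dict[str, list[str]],
    species: Sequence[str],
    outgroup: str,
) -> pd.DataFrame:
    """Assign each fixed uAUG gain to a branch and flag CpG origins.

    ``site_contexts`` maps site id -> list of 4-mers (one upstream base
    + the triplet) ordered as ``species`` (reference first, then
    successively deeper ingroup species) followed by the outgroup.
    Presence means the triplet (positions 1..3) is ATG.  Under
    single-gain parsimony on the ladder topology, the gain branch is
    the shallowest branch whose clade is exactly the set of
    AUG-carrying species; non-nested patterns are flagged homoplasy and
    excluded.  A gain is CpG-derived when the ancestral triplet was ACG
    (C->T before G) or the ancestral 4-mer was CGTG giving CATG (G->A
    after C, a CpG on the opposite strand).
    """
    order = list(species) + [outgroup]
    rows = []
    for site_id, contexts in site_contexts.items():
        if len(contexts) != len(order):
            raise ValueError(f"site {site_id}: expected {len(order)} states")
        present = [c[1:4].upper() == "ATG" for c in contexts]
        if not present[0]:
            continue  # not a gain in the reference lineage
        k = 0
        while k < len(present) and present[k]:
            k += 1
        if any(present[k:]):
            rows.append({"site": site_id, "branch": None, "cpg_derived": None,
                         "homoplasy": True})
            continue
        # gain on the branch subtending species[0..k-1]; ancestral
        # state read from the nearest species outside that clade
        anc = contexts[k].upper()
        der = contexts[0].upper()
        cpg = anc[1:4] == "ACG" or (anc == "CGTG" and der == "CATG")
        rows.append(
            {"site": site_id, "branch": k, "cpg_derived": bool(cpg),
             "homoplasy": False}
        )
    return pd.DataFrame(rows, columns=["site", "branch", "cpg_derived", "homoplasy"])


# ---------------------------------------------------------------------------
# asymptotic McDonald-Kreitman


def _merge_sparse_bins(
    x: np.ndarray, p_test: np.ndarray, p_neutral: np.ndarray, min_neutral: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x, p_test, p_neutral = list(x), list(p_test), list(p_neutral)
    while len(x) > 1 and min(p_neutral) < min_neutral:
        i = int(np.argmin(p_neutral))
        j = i - 1 if i > 0 else i + 1
        lo, hi = min(i, j), max(i, j)
        w = p_neutral[lo] + p_neutral[hi]
        x[lo] = (
            (x[lo] * p_neutral[lo] + x[hi] * p_neutral[hi]) / w
            if w > 0
            else 0.5 * (x[lo] + x[hi])
        )
        p_test[lo] += p_test[hi]
        p_neutral[lo] += p_neutral[hi]
        del x[hi], p_test[hi], p_neutral[hi]
    return np.asarray(x, float), np.asarray(p_test, float), np.asarray(p_neutral, float)


def _alpha_fit(
    x: np.ndarray, alpha: np.ndarray, fit_mode: str
) -> tuple[str, tuple, float]:
    def expo(xv, a, b, c):
        return a + b * np.exp(-c * xv)

    if fit_mode in ("auto", "exponential") and len(x) >= 4:
        try:
            sl, ic = np.polyfit(x, alpha, 1)
            p0 = (ic + sl, -sl, 1.0)
            popt, _ = optimize.curve_fit(expo, x, alpha, p0=p0, maxfev=10_000)
            if popt[2] >= 0 and np.isfinite(popt).all():
                return "exponential", tuple(popt), float(expo(1.0, *popt))
        except (RuntimeError, TypeError):
            pass
        if fit_mode == "exponential":
            raise RuntimeError("exponential fit failed to converge")
    slope, intercept = np.polyfit(x, alpha, 1)
    return "linear", (float(intercept), float(slope)), float(intercept + slope)


def asymptotic_mk(
    mk: MkInput,
    fit_mode: str = "auto",
    n_boot: int = 599,
    seed: int = 0,
    fit_range: tuple[float, float] = (0.1, 0.9),
    min_neutral_per_bin: int = 5,
) -> MkResult:
    """Asymptotic MK estimate of the adaptive fraction of fixations.

    alpha(x) = 1 - (D_neutral/D_test) * (P_test(x)/P_neutral(x)) is fit
    over DAF bins within ``fit_range`` with an exponential
    a + b exp(-c x) (linear fallback when that fit fails or c < 0);
    alpha_asym is the fit evaluated at x = 1.  Bins are merged until
    every neutral bin holds at least ``min_neutral_per_bin`` counts.
    The CI is a percentile bootstrap resampling bin counts as
    independent binomials conditioned on the class totals.
    """
    if mk.d_test <= 0:
        raise ValueError("d_test must be positive")
    x0 = np.asarray(mk.daf_bins, float)
    in_range = (x0 >= fit_range[0]) & (x0 <= fit_range[1])
    if not in_range.any():
        raise ValueError("no DAF bins inside the fit range")
    x, pt, pn = _merge_sparse_bins(
        x0[in_range],
        np.asarray(mk.p_test, float)[in_range],
        np.asarray(mk.p_neutral, float)[in_range],
        min_neutral_per_bin,
    )
    if (pn <= 0).any():
        raise ValueError("neutral bin with zero counts after merging")
    ratio_d = mk.d_neutral / mk.d_test
    alpha = 1.0 - ratio_d * (pt / pn)
    fit_kind, fit_params, alpha_asym = _alpha_fit(x, alpha, fit_mode)

    rng = np.random.default_rng(seed)
    tot_t, tot_n = pt.sum(), pn.sum()
    boots = []
    for _ in range(n_boot):
        bt = rng.binomial(int(tot_t), pt / tot_t)
        bn = rng.binomial(int(tot_n), pn / tot_n)
        keep = bn > 0
        if keep.sum() < 2:
            continue
        a_b = 1.0 - ratio_d * (bt[keep] / bn[keep])
        try:
            _, _, asym_b = _alpha_fit(x[keep], a_b, fit_mode)
        except RuntimeError:
            continue
        if np.isfinite(asym_b):
            boots.append(asym_b)
    if boots:
        ci = (
            float(np.percentile(boots, 2.5)),
            float(np.percentile(boots, 97.5)),
        )
    else:
        ci = (float("nan"), float("nan"))
    return MkResult(
        alpha_per_bin=[float(a) for a in alpha],
        daf_bins=[float(v) for v in x],
        fit_kind=fit_kind,
        fit_params=fit_params,
        alpha_asym=float(alpha_asym),
        ci=ci,
    )


# ---------------------------------------------------------------------------
# SNP effect annotation and pN/pS

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"


def _aa(codon: str) -> str:
    if codon in _CODON_TABLE.stop_codons:
        return "*"
    return _CODON_TABLE.forward_table[codon]


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def annotate_uorf_snp_effects(
    snps: pd.DataFrame,
    records: Sequence[UorfRecord],
    models,
) -> list[SnpRecord]:
    """Classify SNPs hitting uORF codons as (non)synonymous.

    ``snps`` needs columns chromosome, position (0-based), ref, alt,
    daf.  Each SNP is mapped to every overlapping uORF codon (excluding
    the CDS-overlapping portion of oORFs, repeat-masked starts, and
    no_stop records); the call is synonymous only if the amino acid is
    unchanged in every frame hit, nonsynonymous only if changed in
    every frame, otherwise ambiguous.  Alleles mismatching the
    transcript reference base are excluded.
    """
    from .annotate import mrna_to_genomic

    by_tx = {m.transcript_id: m for m in models}
    # genomic position -> list of (codon string, index within codon, strand)
    hits: dict[tuple[str, int], list[tuple[str, int, str]]] = {}
    for rec in records:
        if rec.klass == "no_stop" or rec.stop_mrna_offset is None:
            continue
        if rec.site.in_repeat:
            continue
        model = by_tx[rec.site.transcript_id]
        end = rec.stop_mrna_offset
        if rec.klass == "oORF":
            end = min(end, model.caug_offset)  # non-CDS-overlapping portion
        mrna = model.mrna
        for cstart in range(rec.site.mrna_offset, end - 2, 3):
            codon = mrna[cstart : cstart + 3]
            for k in range(3):
                gpos = mrna_to_genomic(model, cstart + k)
                if gpos is None:
                    continue
                hits.setdefault((model.chromosome, gpos), []).append(
                    (codon, k, model.strand)
                )
    out = []
    for row in snps.itertuples(index=False):
        key = (row.chromosome, int(row.position))
        if key not in hits:
            continue
        effects = set()
        valid = True
        for codon, k, strand in hits[key]:
            ref, alt = row.ref.upper(), row.alt.upper()
            if strand == "-":
                ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
            if codon[k] != ref:
                valid = False
                break
            mutated = codon[:k] + alt + codon[k + 1 :]
            effects.add("synonymous" if _aa(mutated) == _aa(codon) else "nonsynonymous")
        if not valid:
            continue
        effect = effects.pop() if len(effects) == 1 else "ambiguous"
        out.append(
            SnpRecord(
                chromosome=row.chromosome,
                position=int(row.position),
                ref=row.ref,
                alt=row.alt,
                ancestral=getattr(row, "ancestral", row.ref),
                daf=float(row.daf),
                effect=effect,
                region="uorf",
            )
        )
    return out


def mutational_opportunity(opportunity_seqs: Sequence[str]) -> tuple[float, float]:
    """(nonsynonymous, synonymous) single-step mutation counts.

    Enumerates all 9 single-nucleotide changes of every codon under a
    uniform mutation model; changes to stop codons count as
    nonsynonymous, stop codons themselves are skipped.
    """
    n_non = n_syn = 0
    for seq in opportunity_seqs:
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _CODON_TABLE.stop_codons or set(codon) - set(_BASES):
                continue
            for k in range(3):
                for b in _BASES:
                    if b == codon[k]:
                        continue
                    mutated = codon[:k] + b + codon[k + 1 :]
                    if _aa(mutated) == _aa(codon):
                        n_syn += 1
                    else:
                        n_non += 1
    return float(n_non), float(n_syn)


def pnps_by_daf(
    snps: Sequence[SnpRecord],
    bin_edges: Sequence[float],
    opportunity_seqs: Sequence[str],
) -> tuple[pd.DataFrame, float]:
    """pN/pS per DAF bin against the mutational-opportunity expectation.

    Returns the per-bin table and the Spearman correlation of pN/pS
    with the bin median DAF (ambiguous SNPs must be removed upstream).
    """
    usable = [s for s in snps if s.effect in ("nonsynonymous", "synonymous")]
    n_opp, s_opp = mutational_opportunity(opportunity_seqs)
    expected = n_opp / s_opp if s_opp > 0 else np.nan
    edges = list(bin_edges)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [s for s in usable if lo <= s.daf < hi]
        nn = sum(s.effect == "nonsynonymous" for s in in_bin)
        ns = sum(s.effect == "synonymous" for s in in_bin)
        dafs = [s.daf for s in in_bin]
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "median_daf": float(np.median(dafs)) if dafs else np.nan,
                "nN": nn,
                "nS": ns,
                "pnps": nn / ns if ns > 0 else np.nan,
                "expected_pnps": expected,
            }
        )
    df = pd.DataFrame(rows)
    ok = df.dropna(subset=["pnps", "median_daf"])
    rho = (
        float(stats.spearmanr(ok["median_daf"], ok["pnps"]).statistic)
        if len(ok) > 2
        else np.nan
    )
    return df, rho


# ---------------------------------------------------------------------------
# NG86 omega


@lru_cache(maxsize=None)
def _codon_sites(codon: str, stop_mode: str = "nonsynonymous") -> tuple[float, float]:
    """Per-codon (nonsynonymous, synonymous) site counts.

    With ``stop_mode="nonsynonymous"`` changes to stop codons count as
    nonsynonymous; with ``"exclude"`` they are disallowed and each
    position's single site is split over the remaining changes (the
    yn00 convention).  Either way every position contributes one site,
    so N + S = 3 per codon.
    """
    n = s = 0.0
    for k in range(3):
        syn = non = stops = 0
        for b in _BASES:
            if b == codon[k]:
                continue
            mutated = codon[:k] + b + codon[k + 1 :]
            if mutated in _CODON_TABLE.stop_codons:
                if stop_mode == "exclude":
                    stops += 1
                    continue
                non += 1
                continue
            if _aa(mutated) == _aa(codon):
                syn += 1
            else:
                non += 1
        tot = syn + non
        if tot:
            s += syn / tot
            n += non / tot
        elif stops:
            n += 1.0  # only stop changes possible; site kept nonsynonymous
    return n, s


@lru_cache(maxsize=None)
def _pair_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Nd, Sd) between two codons, averaged over mutational pathways.

    Pathways passing through a stop codon are excluded unless every
    pathway does.
    """
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for perm in itertools.permutations(diff):
        cur = c1
        nd = sd = 0
        via_stop = False
        for k in perm:
            nxt = cur[:k] + c2[k] + cur[k + 1 :]
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            if nxt in _CODON_TABLE.stop_codons and nxt != c2:
                via_stop = True
            cur = nxt
        paths.append((nd, sd, via_stop))
    clean = [(nd, sd) for nd, sd, stop in paths if not stop]
    use = clean if clean else [(nd, sd) for nd, sd, _ in paths]
    nd = sum(p[0] for p in use) / len(use)
    sd = sum(p[1] for p in use) / len(use)
    return nd, sd


def ng86_pair(
    seq1: str, seq2: str, stop_mode: str = "nonsynonymous"
) -> tuple[float, float, float, float]:
    """(Nd, Sd, N, S) for one codon-aligned pair; gap codons skipped."""
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be codon-aligned, equal length, length % 3 == 0")
    nd = sd = n = s = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if "-" in c1 + c2 or set(c1 + c2) - set(_BASES):
            continue
        if c1 in _CODON_TABLE.stop_codons or c2 in _CODON_TABLE.stop_codons:
            continue
        dn, ds = _pair_path_counts(c1, c2)
        nd += dn
        sd += ds
        n1, s1 = _codon_sites(c1, stop_mode)
        n2, s2 = _codon_sites(c2, stop_mode)
        n += (n1 + n2) / 2.0
        s += (s1 + s2) / 2.0
    return nd, sd, n, s


def _omega(nd, sd, n, s, correction: str) -> tuple[Optional[float], str]:
    if sd == 0 or s == 0 or n == 0:
        return None, "no synonymous differences" if sd == 0 else "no sites"
    pn, ps = nd / n, sd / s
    if correction == "jukes_cantor":
        if pn >= 0.75 or ps >= 0.75:
            return None, "proportion >= 3/4, JC correction undefined"
        dn = -0.75 * np.log(1 - 4.0 * pn / 3.0)
        ds = -0.75 * np.log(1 - 4.0 * ps / 3.0)
        if ds <= 0:
            return None, "zero corrected synonymous divergence"
        return float(dn / ds), ""
    return float(pn / ps), ""


def ng86_omega_binned(
    aligned_pairs: Sequence[tuple[tuple[str, str], float]],
    n_bins: int = 1000,
    correction: str = "none",
    stop_mode: str = "nonsynonymous",
) -> list[OmegaBin]:
    """omega per Kozak-score bin of concatenated uORF alignments.

    Pairs are sorted by Kozak score, cut into ``n_bins`` equal-count
    bins, concatenated within bins, and scored with NG86 pathway
    counting.
    """
    ranked = sorted(aligned_pairs, key=lambda p: p[1])
    chunks = [c for c in np.array_split(np.arange(len(ranked)), n_bins) if len(c)]
    out = []
    for b, idx in enumerate(chunks):
        nd = sd = n = s = 0.0
        scores = []
        for i in idx:
            (s1, s2), score = ranked[i]
            dn, ds, dn_sites, ds_sites = ng86_pair(s1, s2, stop_mode)
            nd += dn
            sd += ds
            n += dn_sites
            s += ds_sites
            scores.append(score)
        omega, reason = _omega(nd, sd, n, s, correction)
        out.append(
            OmegaBin(
                bin_index=b,
                kozak_min=min(scores),
                kozak_max=max(scores),
                nd=nd,
                sd=sd,
                n_sites=n,
                s_sites=s,
                omega=omega,
                reason=reason,
            )
        )
    return out


def median_omega(bins: Sequence[OmegaBin]) -> float:
    vals = [b.omega for b in bins if b.omega is not None]
    return float(np.median(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# phylogenetic independent contrasts


def _as_dendropy_tree(tree):
    import dendropy

    if isinstance(tree, dendropy.Tree):
        return tree.clone(depth=1)
    return dendropy.Tree.get(data=str(tree), schema="newick")


def pic_contrasts(tree, tip_values: dict[str, float]) -> ContrastSet:
    """Felsenstein's standardized independent contrasts.

    At each internal node of the (bifurcating) tree the contrast is
    (x_left - x_right)/sqrt(b_left + b_right); the ancestral value is
    the branch-length-weighted mean and the parent branch is lengthened
    by b_l b_r / (b_l + b_r).  Polytomies are resolved with zero-length
    edges; zero-length sister pairs fall back on an unweighted mean.
    """
    t = _as_dendropy_tree(tree)
    t.resolve_polytomies()
    tips = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    if tips != set(tip_values):
        raise ValueError(
            f"tip/value mismatch: tree {sorted(tips)} vs values {sorted(tip_values)}"
        )
    contrasts: list[float] = []
    node_ids: list[str] = []
    state: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            state[node] = (tip_values[node.taxon.label], node.edge.length or 0.0)
            if node.edge.length is not None and node.edge.length < 0:
                raise ValueError("negative branch length")
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError("tree must be bifurcating after polytomy resolution")
        (x1, b1), (x2, b2) = state[children[0]], state[children[1]]
        if b1 < 0 or b2 < 0:
            raise ValueError("negative branch length")
        tot = b1 + b2
        contrasts.append((x1 - x2) / np.sqrt(tot) if tot > 0 else 0.0)
        node_ids.append(
            ",".join(sorted(leaf.taxon.label for leaf in node.leaf_iter()))
        )
        xa = (b2 * x1 + b1 * x2) / tot if tot > 0 else 0.5 * (x1 + x2)
        extra = b1 * b2 / tot if tot > 0 else 0.0
        state[node] = (xa, (node.edge.length or 0.0) + extra)
    return ContrastSet(n_tips=len(tips), contrasts=contrasts, node_ids=node_ids)


def pic_correlation(
    tree, trait_x: dict[str, float], trait_y: dict[str, float]
) -> tuple[float, float]:
    """Correlation of two traits' contrasts, regression through origin.

    Returns (r, two-sided p) with r = sum(xy)/sqrt(sum x^2 sum y^2)
    over contrasts and p from the t distribution with n-1 df.
    """
    cx = pic_contrasts(tree, trait_x)
    cy = pic_contrasts(tree, trait_y)
    x = np.asarray(cx.contrasts)
    y = np.asarray(cy.contrasts)
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return float("nan"), float("nan")
    r = float((x * y).sum() / denom)
    df = len(x) - 1
    if df <= 0 or abs(r) >= 1:
        return r, 0.0 if abs(r) >= 1 else float("nan")
    tstat = r * np.sqrt(df / (1 - r * r))
    p = 2 * stats.t.sf(abs(tstat), df)
    return r, float(p)
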
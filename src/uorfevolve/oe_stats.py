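"""Observed/expected (O/E) triplet statistics under dinucleotide-
preserving permutation.

The null model shuffles each UTR while preserving its exact multiset of
overlapping dinucleotides (Altschul-Erickson Euler-path shuffling),
which controls both for base composition and for dinucleotide-biased
mutation (e.g. CpG->TpG).  The O/E ratio is n_obs / median(shuffled
counts), with a 95% CI of [n_obs/q97.5, n_obs/q2.5].
"""

from __future__ import annotations

import warnings
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .annotate import find_and_classify_uaugs
from .models import OEResult, TranscriptModel

_VALID = frozenset("ACGT")


_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
_BASES_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact overlapping-dinucleotide multiset.

    Altschul-Erickson: sample a uniform random arborescence toward the
    terminal vertex (by rejection over last-exit-edge assignments),
    permute the remaining out-edges, and walk the Euler path.  The
    first/last nucleotide and the dinucleotide count vector are
    invariant; the draw is uniform over Eulerian orderings.
    """
    n = len(seq)
    if n < 2:
        raise ValueError("sequence must have length >= 2")
    codes = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.max() == 255:
        raise ValueError("sequence must be over {A,C,G,T}")
    src, dst = codes[:-1], codes[1:]
    last = int(codes[-1])
    succ = [dst[src == v] for v in range(4)]
    verts = [v for v in range(4) if len(succ[v]) and v != last]

    if not verts:
        # single out-vertex: any permutation of its edges is Eulerian
        perm = succ[last][rng.permutation(len(succ[last]))]
        out = np.concatenate(([codes[0]], perm))
        return _BASES_BYTES[out].tobytes().decode()

    # rejection-sample the last-exit edge of every non-terminal vertex
    # so that following those edges always reaches the terminal vertex
    while True:
        exit_edge = {v: int(succ[v][rng.integers(len(succ[v]))]) for v in verts}
        ok = True
        for v in verts:
            seen = {v}
            cur = v
            while cur != last:
                cur = exit_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    order: list[list[int]] = [[] for _ in range(4)]
    for v in range(4):
        edges = succ[v]
        if not len(edges):
            continue
        rest = edges.tolist()
        if v != last:
            rest.remove(exit_edge[v])
        perm = [rest[j] for j in rng.permutation(len(rest))]
        if v != last:
            perm.append(exit_edge[v])
        order[v] = perm

    result = np.empty(n, dtype=np.uint8)
    result[0] = cur = int(codes[0])
    ptr = [0, 0, 0, 0]
    for i in range(1, n):
        nxt = order[cur][ptr[cur]]
        ptr[cur] += 1
        result[i] = nxt
        cur = nxt
    return _BASES_BYTES[result].tobytes().decode()


def count_overlapping(seq: str, triplet: str) -> int:
    count = 0
    pos = seq.find(triplet)
    while pos != -1:
        count += 1
        pos = seq.find(triplet, pos + 1)
    return count


def count_triplet_occurrences(seqs: Sequence[str], triplet: str) -> int:
    """Total overlapping occurrences of ``triplet`` across sequences."""
    return sum(count_overlapping(s, triplet) for s in seqs)


def _usable(seqs: Sequence[str]) -> list[str]:
    usable = []
    skipped = 0
    for s in seqs:
        if len(s) >= 3 and set(s) <= _VALID:
            usable.append(s)
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} sequences (too short or ambiguous bases)")
    return usable


def oe_ratio(
    seqs: Sequence[str],
    triplet: str = "ATG",
    n_perm: int = 1000,
    seed: int = 0,
    scope: str = "utr5",
) -> OEResult:
    """O/E ratio of a triplet over a set of sequences.

    Each permutation replicate independently shuffles every sequence
    and re-counts; quantiles are taken over the summed counts.
    Per-replicate RNG streams are derived from (seed, replicate) so the
    result is independent of evaluation order.
    """
    usable = _usable(seqs)
    if not usable:
        raise ValueError("no usable sequences of length >= 3")
    n_obs = count_triplet_occurrences(usable, triplet)
    counts = perm_counts(usable, triplet, n_perm, seed)
    return _oe_from_counts(triplet, scope, n_obs, counts, n_perm)


def perm_counts(
    seqs: Sequence[str], triplet: str, n_perm: int, seed: int
) -> np.ndarray:
    counts = np.empty(n_perm, dtype=np.int64)
    for rep in range(n_perm):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, rep])
        counts[rep] = sum(
            count_overlapping(dinucleotide_shuffle(s, rng), triplet) for s in seqs
        )
    return counts


def _oe_from_counts(
    triplet: str, scope: str, n_obs: int, counts: np.ndarray, n_perm: int
) -> OEResult:
    med = float(np.percentile(counts, 50))
    q025 = float(np.percentile(counts, 2.5))
    q975 = float(np.percentile(counts, 97.5))
    if med <= 0:
        return OEResult(triplet, scope, n_obs, None, None, None, None, n_perm)
    ratio = n_obs / med
    ci_low = n_obs / q975 if q975 > 0 else None
    ci_high = n_obs / q025 if q025 > 0 else None
    return OEResult(triplet, scope, n_obs, med, ratio, ci_low, ci_high, n_perm)


# ---------------------------------------------------------------------------
# partitioned O/E


def oe_by_partition(
    models: Sequence[TranscriptModel],
    labeler: Callable[[TranscriptModel], str],
    triplet: str = "ATG",
    n_perm: int = 1000,
    seed: int = 0,
    region: str = "utr5",
) -> list[OEResult]:
    """One O/E result per partition label (e.g. autosome vs X/Z)."""
    groups: dict[str, list[str]] = {}
    for m in models:
        seq = getattr(m, f"{region}_seq")
        groups.setdefault(labeler(m), []).append(seq)
    results = []
    for label in sorted(groups):
        seqs = [s for s in groups[label] if len(s) >= 3 and set(s) <= _VALID]
        if not seqs:
            continue
        results.append(
            oe_ratio(seqs, triplet, n_perm, seed, scope=f"{region}:{label}")
        )
    return results


def oe_positional(
    models: Sequence[TranscriptModel],
    L: int = 100,
    triplet: str = "ATG",
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, OEResult]:
    """O/E within L nt of the CDS start (proximal) vs the rest (distal).

    Each 5'UTR is split at distance L upstream of the cAUG and the two
    subregions are scored as separate sequence sets.
    """
    proximal, distal = [], []
    for m in models:
        u = m.utr5_seq
        if len(u) >= 3 and set(u) <= _VALID:
            proximal.append(u[-L:])
            if len(u) > L:
                distal.append(u[:-L])
    out = {}
    if any(len(s) >= 3 for s in proximal):
        out["proximal"] = oe_ratio(
            [s for s in proximal if len(s) >= 3], triplet, n_perm, seed,
            scope=f"proximal_L{L}",
        )
    if any(len(s) >= 3 for s in distal):
        out["distal"] = oe_ratio(
            [s for s in distal if len(s) >= 3], triplet, n_perm, seed,
            scope=f"distal_L{L}",
        )
    return out


def oe_by_class(
    models: Sequence[TranscriptModel],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, OEResult]:
    """Class-specific O/E (nORF / oORF / NTE).

    Observed class counts come from the real transcripts; expected
    counts re-classify each shuffled 5'UTR against the real CDS, so the
    null respects the transcript's own geometry.
    """
    usable = [m for m in models if len(m.utr5_seq) >= 3 and set(m.utr5_seq) <= _VALID]
    if not usable:
        raise ValueError("no usable transcripts")
    classes = ("nORF", "oORF", "NTE")
    obs = {k: 0 for k in classes}
    for m in usable:
        for rec in find_and_classify_uaugs(m):
            if rec.klass in obs:
                obs[rec.klass] += 1
    counts = {k: np.empty(n_perm, dtype=np.int64) for k in classes}
    for rep in range(n_perm):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, rep])
        tally = {k: 0 for k in classes}
        for m in usable:
            shuffled = TranscriptModel(
                transcript_id=m.transcript_id,
                gene_id=m.gene_id,
                utr5_seq=dinucleotide_shuffle(m.utr5_seq, rng),
                cds_seq=m.cds_seq,
                utr3_seq=m.utr3_seq,
            )
            for rec in find_and_classify_uaugs(shuffled):
                if rec.klass in tally:
                    tally[rec.klass] += 1
        for k in classes:
            counts[k][rep] = tally[k]
    return {
        k: _oe_from_counts("ATG", f"class:{k}", obs[k], counts[k], n_perm)
        for k in classes
    }


def oe_by_expression(
    models: Sequence[TranscriptModel],
    expression: dict[str, float],
    k: int = 20,
    triplet: str = "ATG",
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[OEResult], float]:
    """O/E per expression bin plus Spearman rho of bin rank vs ratio.

    Genes are sorted by the supplied expression value and cut into k
    equal-count bins (bin 0 = lowest expression).
    """
    scored = sorted(
        (m for m in models if m.gene_id in expression),
        key=lambda m: (expression[m.gene_id], m.gene_id),
    )
    if len(scored) < k:
        raise ValueError("fewer transcripts than bins")
    bins = np.array_split(np.arange(len(scored)), k)
    results = []
    for b, idx in enumerate(bins):
        seqs = [
            scored[i].utr5_seq
            for i in idx
            if len(scored[i].utr5_seq) >= 3 and set(scored[i].utr5_seq) <= _VALID
        ]
        if not seqs:
            continue
        results.append(oe_ratio(seqs, triplet, n_perm, seed, scope=f"bin:expr_q{b}"))
    ranks = [int(r.scope.split("_q")[1]) for r in results if r.ratio is not None]
    ratios = [r.ratio for r in results if r.ratio is not None]
    rho = float(stats.spearmanr(ranks, ratios).statistic) if len(ratios) > 2 else np.nan
    return results, rho


def triplet_spectrum(
    utr5_seqs: Sequence[str],
    utr3_seqs: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
):
    """O/E for all 64 triplets in 5' vs 3' UTRs, with relative O/E.

    Shuffled replicate sequences are generated once per region and all
    64 triplets are counted on them, so the 64 rows share one null
    ensemble per region.
    """
    import itertools

    import pandas as pd

    triplets = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
    rows = []
    region_stats = {}
    for region, seqs in (("utr5", utr5_seqs), ("utr3", utr3_seqs)):
        usable = _usable(seqs)
        obs = {t: count_triplet_occurrences(usable, t) for t in triplets}
        counts = {t: np.empty(n_perm, dtype=np.int64) for t in triplets}
        for rep in range(n_perm):
            rng = np.random.default_rng([seed & 0x7FFFFFFF, rep])
            shuffled = [dinucleotide_shuffle(s, rng) for s in usable]
            for t in triplets:
                counts[t][rep] = count_triplet_occurrences(shuffled, t)
        region_stats[region] = {
            t: _oe_from_counts(t, region, obs[t], counts[t], n_perm) for t in triplets
        }
    for t in triplets:
        r5 = region_stats["utr5"][t]
        r3 = region_stats["utr3"][t]
        rel = (
            r5.ratio / r3.ratio
            if r5.ratio is not None and r3.ratio not in (None, 0)
            else np.nan
        )
        rows.append(
            {
                "triplet": t,
                "ratio_utr5": r5.ratio,
                "ci_low_utr5": r5.ci_low,
                "ci_high_utr5": r5.ci_high,
                "ratio_utr3": r3.ratio,
                "ci_low_utr3": r3.ci_low,
                "ci_high_utr3": r3.ci_high,
                "relative_oe": rel,
            }
        )
    return pd.DataFrame(rows)
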
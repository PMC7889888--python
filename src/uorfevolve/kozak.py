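"""Kozak context PWM construction, log-odds scoring, PWM distances,
normalized translation-initiation signals, and genotype-TE regression.

The PWM covers the 7 informative slots around a start codon (-6..-1
and +4); the invariant AUG itself is not scored.  Scores are log2
odds against a background (uniform by default), in bits.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import extract_context
from .models import KozakPwm, TisSignal, TranscriptModel

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_SLOTS = (0, 1, 2, 3, 4, 5, 9)  # informative positions within the 10-mer


def build_pwmk(
    models: Sequence[TranscriptModel],
    pseudocount: float = 0.01,
    background: Optional[np.ndarray] = None,
) -> KozakPwm:
    """Position probability matrix of CDS-start (cAUG) Kozak contexts.

    Contexts shorter than 6 nt of 5'UTR are N-padded and the N slots
    are skipped in counting.  probs[i][b] = (count + pc) / (total + 4 pc).
    """
    counts = np.zeros((7, 4))
    n_contexts = 0
    for m in models:
        if not m.is_valid():
            continue
        ctx = extract_context(m.mrna, m.caug_offset)
        used = False
        for row, slot in enumerate(_SLOTS):
            b = ctx[slot]
            if b in _BASE_IDX:
                counts[row, _BASE_IDX[b]] += 1
                used = True
        if used:
            n_contexts += 1
    if n_contexts == 0:
        raise ValueError("no usable Kozak contexts")
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = (counts + pseudocount) / (totals + 4 * pseudocount)
    probs[np.squeeze(totals, 1) == 0] = 0.25  # positions with no data: flat
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return KozakPwm(
        probs=probs, pseudocount=pseudocount, background=bg, n_contexts=n_contexts
    )


def kozak_score(context: str, pwm: KozakPwm) -> float:
    """log2-odds Kozak score (bits) of a 10-mer -6..+4 context.

    Positions +1..+3 must be ATG (checked, not scored); N positions
    contribute 0.
    """
    if len(context) != 10:
        raise ValueError("context must be a 10-mer (-6..+4)")
    ctx = context.upper()
    if ctx[6:9] != "ATG":
        raise ValueError("context positions +1..+3 must be ATG")
    score = 0.0
    for row, slot in enumerate(_SLOTS):
        b = ctx[slot]
        if b in _BASE_IDX:
            j = _BASE_IDX[b]
            score += np.log2(pwm.probs[row, j] / pwm.background[j])
    return float(score)


def consensus_context(pwm: KozakPwm) -> str:
    """The maximal-scoring 10-mer under the PWM."""
    bases = "ACGT"
    ctx = []
    odds = np.log2(pwm.probs / pwm.background[None, :])
    for row in range(6):
        ctx.append(bases[int(np.argmax(odds[row]))])
    ctx.append("ATG")
    ctx.append(bases[int(np.argmax(odds[6]))])
    return "".join(ctx)


def pwmk_distance(a: KozakPwm, b: KozakPwm) -> float:
    """Euclidean distance between PWMs, normalized by column count."""
    if a.probs.shape != b.probs.shape:
        raise ValueError("PWM shape mismatch")
    return float(np.sqrt(((a.probs - b.probs) ** 2).sum()) / a.probs.shape[0])


def score_records(records, pwm: KozakPwm) -> None:
    """Attach Kozak scores to uORF records in place."""
    for rec in records:
        rec.kozak_score = kozak_score(rec.site.context_seq, pwm)


# ---------------------------------------------------------------------------
# TIS signal


def normalized_tis_signal(
    rpf_counts: Sequence[int],
    rna_cov: Sequence[float],
    rna_reads: Sequence[float],
    min_rpf: int = 2,
    min_rna: float = 4,
    site_ids: Optional[Sequence[str]] = None,
) -> list[TisSignal]:
    """Initiating-RPF signal normalized by RNA coverage, with filters.

    The window is the -1..+4 region around the start codon (upstream of
    this call); normalized = RPF count / mean RNA coverage, defined
    only for positive coverage; a site passes when it has at least
    ``min_rpf`` initiating RPFs and ``min_rna`` RNA reads.
    """
    n = len(rpf_counts)
    ids = site_ids if site_ids is not None else [str(i) for i in range(n)]
    out = []
    for sid, rpf, cov, reads in zip(ids, rpf_counts, rna_cov, rna_reads):
        if cov > 0:
            norm = rpf / cov
            passes = rpf >= min_rpf and reads >= min_rna
        else:
            norm, passes = None, False
        out.append(TisSignal(sid, int(rpf), float(cov), float(reads), norm, passes))
    return out


def tis_kozak_correlation(
    scores: Sequence[float],
    signals: Sequence[TisSignal],
    n_bins: int = 50,
) -> float:
    """Spearman rho of Kozak score vs normalized TIS signal, binned.

    Sites failing the read filters are dropped; the rest are cut into
    equal-count score bins and rho is computed between the bin mean
    score and bin mean normalized signal.
    """
    pairs = [
        (sc, sig.normalized)
        for sc, sig in zip(scores, signals)
        if sig.passes_filter and sig.normalized is not None
    ]
    if len(pairs) < max(3, n_bins):
        n_bins = max(3, len(pairs) // 2)
    if len(pairs) < 3:
        return float("nan")
    pairs.sort(key=lambda p: p[0])
    chunks = np.array_split(np.arange(len(pairs)), n_bins)
    xs, ys = [], []
    for idx in chunks:
        if not len(idx):
            continue
        xs.append(np.mean([pairs[i][0] for i in idx]))
        ys.append(np.mean([pairs[i][1] for i in idx]))
    return float(stats.spearmanr(xs, ys).statistic)


# ---------------------------------------------------------------------------
# TE-genotype regression


def te_genotype_regression(
    variants: pd.DataFrame,
    genotypes: pd.DataFrame,
    te: pd.DataFrame,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """OLS of log2 translation efficiency on non-uORF allele count.

    ``variants``: variant_id, gene_id, canonical (bool), plus optional
    maf; ``genotypes``: variants x individuals matrix of non-uORF
    allele counts {0,1,2}; ``te``: genes x individuals matrix of log2
    TE.  Variants with MAF < ``min_maf``, fewer than 3 informative
    individuals, or a constant genotype are skipped with a reason.
    A positive slope means the uORF allele represses CDS translation.
    """
    rows = []
    for v in variants.itertuples(index=False):
        vid, gene = v.variant_id, v.gene_id
        row = {"variant_id": vid, "gene_id": gene,
               "canonical": bool(v.canonical), "slope": np.nan,
               "intercept": np.nan, "p_value": np.nan, "n": 0, "reason": ""}
        if vid not in genotypes.index or gene not in te.index:
            row["reason"] = "missing data"
            rows.append(row)
            continue
        g = genotypes.loc[vid]
        y = te.loc[gene]
        common = g.index.intersection(y.index)
        g, y = g[common].astype(float), y[common].astype(float)
        ok = g.notna() & y.notna()
        g, y = g[ok], y[ok]
        maf = getattr(v, "maf", None)
        if maf is None or (isinstance(maf, float) and np.isnan(maf)):
            freq = g.mean() / 2.0
            maf = min(freq, 1 - freq)
        if maf < min_maf:
            row["reason"] = "maf below threshold"
            rows.append(row)
            continue
        if len(g) < 3 or g.nunique() < 2:
            row["reason"] = "constant genotype" if g.nunique() < 2 else "too few individuals"
            rows.append(row)
            continue
        res = stats.linregress(g.to_numpy(), y.to_numpy())
        row.update(
            slope=float(res.slope),
            intercept=float(res.intercept),
            p_value=float(res.pvalue),
            n=int(len(g)),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def slope_summary(regression: pd.DataFrame) -> dict[str, float]:
    """Median regression slope per variant class."""
    ok = regression[regression["reason"] == ""]
    out = {}
    for label, canonical in (("canonical", True), ("noncanonical", False)):
        vals = ok.loc[ok["canonical"] == canonical, "slope"].dropna()
        out[f"median_slope_{label}"] = float(vals.median()) if len(vals) else float("nan")
    return out
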
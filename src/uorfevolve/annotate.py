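"""Transcript loading and uAUG annotation/classification.

Every AUG in an annotated 5'UTR is located and classified by where the
first in-frame stop codon falls relative to the main CDS:

* nORF  — the stop ends at or before the CDS start (nonoverlapping uORF);
* oORF  — out of frame with the CDS and the stop ends downstream of the
  CDS start (overlapping uORF);
* NTE   — in frame with the CDS, sharing its stop codon (N-terminal
  extension);
* no_stop — no in-frame stop before the transcript end (bookkept but
  excluded from downstream uORF statistics).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .models import STOP_CODONS, TranscriptModel, UAugSite, UorfRecord

logger = logging.getLogger(__name__)

_TSV_REQUIRED = ["transcript_id", "gene_id", "utr5_seq", "cds_seq", "utr3_seq"]


# ---------------------------------------------------------------------------
# loading


def load_transcripts_tsv(path) -> list[TranscriptModel]:
    """Load transcript models from a TSV with sequence columns.

    Required columns: transcript_id, gene_id, utr5_seq, cds_seq,
    utr3_seq. Optional: chromosome, strand.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"transcript TSV missing columns: {missing}")
    models = []
    for row in df.itertuples(index=False):
        models.append(
            TranscriptModel(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                utr5_seq=row.utr5_seq.upper(),
                cds_seq=row.cds_seq.upper(),
                utr3_seq=row.utr3_seq.upper(),
                chromosome=getattr(row, "chromosome", ""),
                strand=getattr(row, "strand", "+"),
            )
        )
    _mark_longest(models)
    return models


def load_transcripts_gff(gff_path, fasta_path) -> list[TranscriptModel]:
    """Load transcript models from GFF3/GTF plus a genome FASTA.

    5'UTR/CDS/3'UTR sequences are reconstructed from exon and CDS
    features; minus-strand transcripts are reverse-complemented into
    mRNA orientation.  Lowercase (soft-masked) stretches of the FASTA
    are recorded as repeat intervals in mRNA coordinates.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genome = Fasta(str(fasta_path), sequence_always_upper=False)

    models = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        if tx.seqid not in genome:
            raise ValueError(f"sequence for contig {tx.seqid!r} missing from FASTA")
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(tx, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="CDS"))
        if not exons:
            exons = [(tx.start - 1, tx.end)]
        if not cds:
            logger.warning("transcript %s has no CDS features; skipped", tx.id)
            continue
        try:
            model = _assemble_model(tx, exons, cds, genome)
        except ValueError as exc:
            raise ValueError(f"malformed feature hierarchy for {tx.id}: {exc}")
        models.append(model)
    _mark_longest(models)
    return models


def _assemble_model(tx, exons, cds, genome) -> TranscriptModel:
    chrom = tx.seqid
    strand = tx.strand
    raw = "".join(str(genome[chrom][s:e]) for s, e in exons)
    if strand == "-":
        raw = str(Seq(raw).reverse_complement())
    mask = [c.islower() for c in raw]
    mrna = raw.upper()

    # genomic position of each mRNA base, in mRNA orientation
    positions = []
    for s, e in exons:
        positions.extend(range(s, e))
    if strand == "-":
        positions.reverse()
    cds_pos = set()
    for s, e in cds:
        cds_pos.update(range(s, e))
    idx = [i for i, p in enumerate(positions) if p in cds_pos]
    if not idx:
        raise ValueError("CDS intervals do not overlap exons")
    lo, hi = idx[0], idx[-1] + 1
    if hi - lo != len(cds_pos):
        raise ValueError("CDS positions not contiguous within the spliced mRNA")

    gene_id = tx.attributes.get("gene_id", [None])[0]
    if gene_id is None:
        parents = tx.attributes.get("Parent", [])
        gene_id = parents[0] if parents else tx.id

    softmask = _runs(mask)
    return TranscriptModel(
        transcript_id=tx.id,
        gene_id=gene_id,
        utr5_seq=mrna[:lo],
        cds_seq=mrna[lo:hi],
        utr3_seq=mrna[hi:],
        chromosome=chrom,
        strand=strand,
        exons=exons,
        cds_genomic=cds,
        softmask=softmask,
    )


def _runs(mask: list[bool]) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def load_transcripts(annotation, genome=None) -> list[TranscriptModel]:
    """Dispatch to GFF3+FASTA or TSV loading based on the arguments."""
    if genome is not None:
        return load_transcripts_gff(annotation, genome)
    return load_transcripts_tsv(annotation)


def _mark_longest(models: list[TranscriptModel]) -> None:
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or len(m.mrna) > len(cur.mrna)
            or (len(m.mrna) == len(cur.mrna) and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    chosen = {m.transcript_id for m in best.values()}
    for m in models:
        m.is_longest = m.transcript_id in chosen


def mrna_to_genomic(model: TranscriptModel, mrna_offset: int) -> Optional[int]:
    """Genomic position of one mRNA base (0-based), or None without exons."""
    if not model.exons:
        return None
    off = mrna_offset
    if model.strand == "-":
        off = len(model.mrna) - 1 - mrna_offset
    for s, e in model.exons:
        if off < e - s:
            return s + off
        off -= e - s
    raise IndexError("mRNA offset outside transcript")


# ---------------------------------------------------------------------------
# filtering


def select_longest_and_filter_utrs(
    models: list[TranscriptModel],
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Keep one transcript per gene, then drop outlier-length 5'UTRs.

    The longest mRNA per gene wins (ties to the lexicographically
    smallest transcript_id).  Among the kept set, transcripts whose
    5'UTR length strictly exceeds mean + 3 x sample s.d. of 5'UTR
    lengths are removed as likely annotation artifacts.  Returns the
    surviving models plus a removal report.
    """
    if not models:
        raise ValueError("empty transcript list")
    _mark_longest(models)
    kept = [m for m in models if m.is_longest]
    removed = [(m.transcript_id, "not_longest") for m in models if not m.is_longest]

    lengths = np.array([len(m.utr5_seq) for m in kept], dtype=float)
    if len(lengths) > 1:
        threshold = lengths.mean() + 3 * lengths.std(ddof=1)
    else:
        threshold = lengths.mean()
    survivors = []
    for m in kept:
        if len(m.utr5_seq) > threshold:
            removed.append((m.transcript_id, "utr5_outlier"))
        else:
            survivors.append(m)
    if not survivors:
        warnings.warn("all transcripts removed by UTR-length filter")
    report = pd.DataFrame(removed, columns=["transcript_id", "reason"])
    return survivors, report


# ---------------------------------------------------------------------------
# uAUG discovery & classification


def find_and_classify_uaugs(model: TranscriptModel) -> list[UorfRecord]:
    """One record per ATG occurrence in the 5'UTR (overlaps allowed).

    Scanning proceeds codon-wise from each uAUG through the whole mRNA;
    the first UAA/UAG/UGA encountered sets the class.  Assumes the CDS
    carries no internal in-frame stop, so a frame-0 stop past the CDS
    start is the CDS's own stop (NTE).
    """
    mrna = model.mrna
    utr5 = model.utr5_seq
    caug = model.caug_offset
    records = []
    start = utr5.find("ATG")
    while start != -1:
        site = UAugSite(
            transcript_id=model.transcript_id,
            utr_offset=start,
            mrna_offset=start,
            chromosome=model.chromosome,
            genomic_pos=mrna_to_genomic(model, start),
            strand=model.strand,
            context_seq=extract_context(mrna, start),
            in_repeat=_overlaps_softmask(model, start, start + 3),
        )
        stop_off = None
        for i in range(start, len(mrna) - 2, 3):
            if mrna[i : i + 3] in STOP_CODONS:
                stop_off = i
                break
        frame_offset = (caug - start) % 3
        if stop_off is None:
            klass, length, pep = "no_stop", 0, ""
        else:
            length = (stop_off - start) // 3
            pep = str(Seq(mrna[start:stop_off]).translate())
            if stop_off + 3 <= caug:
                klass = "nORF"
            elif frame_offset == 0:
                klass = "NTE"
            else:
                klass = "oORF"
        records.append(
            UorfRecord(
                site=site,
                klass=klass,
                stop_mrna_offset=stop_off,
                length_codons=length,
                peptide=pep,
                frame_offset=frame_offset,
            )
        )
        start = utr5.find("ATG", start + 1)
    return records


def extract_context(mrna: str, aug_offset: int) -> str:
    """10-mer Kozak context (-6..+4); out-of-transcript positions are N."""
    left = mrna[max(0, aug_offset - 6) : aug_offset]
    left = "N" * (6 - len(left)) + left
    right = mrna[aug_offset : aug_offset + 4]
    right = right + "N" * (4 - len(right))
    return left + right


def _overlaps_softmask(model: TranscriptModel, lo: int, hi: int) -> bool:
    return any(s < hi and lo < e for s, e in model.softmask)


def exclude_uaugs_in_other_cds(
    records: list[UorfRecord], all_models: list[TranscriptModel]
) -> list[UorfRecord]:
    """Drop uAUGs whose AUG overlaps any same-strand annotated CDS.

    Requires genomic coordinates (GFF3+FASTA mode); with TSV-loaded
    models the filter is skipped with a warning.
    """
    by_tx = {m.transcript_id: m for m in all_models}
    if not any(m.cds_genomic for m in all_models):
        warnings.warn("no genomic CDS coordinates available; CDS-overlap filter skipped")
        return list(records)
    cds_by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for m in all_models:
        cds_by_key.setdefault((m.chromosome, m.strand), []).extend(m.cds_genomic)
    kept = []
    for rec in records:
        model = by_tx[rec.site.transcript_id]
        span = [mrna_to_genomic(model, rec.site.mrna_offset + k) for k in range(3)]
        ivals = cds_by_key.get((model.chromosome, model.strand), [])
        hit = any(
            pos is not None and s <= pos < e for pos in span for s, e in ivals
        )
        if not hit:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# summaries and I/O

CLASSES = ("nORF", "oORF", "NTE")


def composition_summary(
    records_by_species: dict[str, list[UorfRecord]],
) -> pd.DataFrame:
    """Per-species class percentages plus cross-species mean and s.e.

    no_stop records are excluded before percentages are computed; a
    species with zero stop-terminated uAUGs gets missing percentages.
    """
    rows = []
    for species, recs in records_by_species.items():
        recs = [r for r in recs if r.klass != "no_stop"]
        n = len(recs)
        row = {"species": species, "n_uaug": n}
        for k in CLASSES:
            row[f"pct_{k}"] = (
                100.0 * sum(r.klass == k for r in recs) / n if n else np.nan
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    summary = {"species": "MEAN", "n_uaug": df["n_uaug"].sum()}
    se_row = {"species": "SE", "n_uaug": np.nan}
    for k in CLASSES:
        vals = df[f"pct_{k}"].dropna()
        summary[f"pct_{k}"] = vals.mean() if len(vals) else np.nan
        se_row[f"pct_{k}"] = (
            vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        )
    return pd.concat([df, pd.DataFrame([summary, se_row])], ignore_index=True)


def records_to_frame(records: Iterable[UorfRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "transcript_id": r.site.transcript_id,
                "utr_offset": r.site.utr_offset,
                "mrna_offset": r.site.mrna_offset,
                "chromosome": r.site.chromosome,
                "genomic_pos": r.site.genomic_pos,
                "strand": r.site.strand,
                "klass": r.klass,
                "stop_mrna_offset": r.stop_mrna_offset,
                "length_codons": r.length_codons,
                "peptide": r.peptide,
                "frame_offset": r.frame_offset,
                "context_seq": r.site.context_seq,
                "in_repeat": r.site.in_repeat,
                "kozak_score": r.kozak_score,
            }
        )
    return pd.DataFrame(rows)


def write_records_bed(records: Iterable[UorfRecord], path) -> None:
    """BED6+4: name=transcript:utr_offset; extras klass, stop, length, kozak."""
    with open(path, "w") as fh:
        for r in records:
            start = r.site.genomic_pos if r.site.genomic_pos is not None else r.site.mrna_offset
            name = f"{r.site.transcript_id}:{r.site.utr_offset}"
            extras = [
                r.klass,
                "" if r.stop_mrna_offset is None else str(r.stop_mrna_offset),
                str(r.length_codons),
                "" if r.kozak_score is None else f"{r.kozak_score:.4f}",
            ]
            fh.write(
                "\t".join(
                    [
                        r.site.chromosome or ".",
                        str(start),
                        str(start + 3),
                        name,
                        "0",
                        r.site.strand,
                        *extras,
                    ]
                )
                + "\n"
            )


def read_records_bed(path) -> pd.DataFrame:
    cols = [
        "chromosome",
        "start",
        "end",
        "name",
        "score",
        "strand",
        "klass",
        "stop_mrna_offset",
        "length_codons",
        "kozak_score",
    ]
    return pd.read_csv(path, sep="\t", names=cols, keep_default_na=False)


def utr_annotation_fraction(models: list[TranscriptModel]) -> float:
    """Fraction of genes with an annotated (nonempty) 5'UTR."""
    genes: dict[str, bool] = {}
    for m in models:
        genes[m.gene_id] = genes.get(m.gene_id, False) or bool(m.utr5_seq)
    if not genes:
        return 0.0
    return sum(genes.values()) / len(genes)


def species_passes_annotation_filter(
    models: list[TranscriptModel], min_frac: float = 0.25
) -> bool:
    """Keep a species only if enough genes carry 5'UTR annotation.

    Species where fewer than ``min_frac`` of protein-coding genes have
    an annotated 5'UTR are excluded from comparative analyses (sparse
    annotation would bias every downstream statistic).
    """
    return utr_annotation_fraction(models) > min_frac
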
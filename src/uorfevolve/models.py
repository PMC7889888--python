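"""Core domain types shared across the package.

Coordinates are 0-based, half-open everywhere. Sequences are stored in
mRNA orientation (minus-strand genes are reverse-complemented on load).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class TranscriptModel:
    """One mRNA with its 5'UTR / CDS / 3'UTR split out.

    ``exons`` and ``cds_genomic`` are genomic intervals (0-based,
    half-open, ascending on the + strand); they are empty in TSV mode,
    where only the sequences are known.
    """

    transcript_id: str
    gene_id: str
    utr5_seq: str
    cds_seq: str
    utr3_seq: str
    chromosome: str = ""
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_genomic: list[tuple[int, int]] = field(default_factory=list)
    is_longest: bool = False
    # mRNA-coordinate intervals that were soft-masked (lowercase) in the
    # source FASTA; used to flag uAUGs falling in repeats
    softmask: list[tuple[int, int]] = field(default_factory=list)

    @property
    def mrna(self) -> str:
        return self.utr5_seq + self.cds_seq + self.utr3_seq

    @property
    def caug_offset(self) -> int:
        """mRNA offset of the annotated CDS start codon (cAUG)."""
        return len(self.utr5_seq)

    def is_valid(self) -> bool:
        """CDS starts with ATG, length a multiple of 3 and >= 3."""
        return (
            len(self.cds_seq) >= 3
            and len(self.cds_seq) % 3 == 0
            and self.cds_seq[:3] == "ATG"
        )


@dataclass
class UAugSite:
    """An AUG triplet found in a 5'UTR."""

    transcript_id: str
    utr_offset: int
    mrna_offset: int
    chromosome: str = ""
    genomic_pos: Optional[int] = None  # genomic position of the A (strand-aware)
    strand: str = "+"
    context_seq: str = ""  # 10-mer, -6..+4 around the AUG, N-padded
    in_repeat: bool = False


@dataclass
class UorfRecord:
    """A classified uAUG: nORF, oORF, NTE, or no_stop."""

    site: UAugSite
    klass: str
    stop_mrna_offset: Optional[int]  # start of the stop codon, None if no stop
    length_codons: int  # codons excluding the stop; 0 when no stop
    peptide: str
    frame_offset: int  # (cAUG_offset - uAUG_offset) mod 3
    kozak_score: Optional[float] = None


@dataclass
class OEResult:
    """Observed/expected triplet counts with a permutation CI."""

    triplet: str
    scope: str
    n_obs: int
    n_exp_median: Optional[float]
    ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_perm: int


@dataclass
class SelectionModelParams:
    """Parameters of the diffusion fixation model and the fate mixture.

    ``ne`` is the diploid effective population size; ``s`` the selection
    coefficient of the uORF-creating allele; ``h`` the dominance
    coefficient.  ``p_neutral/p_del/p_ben`` are the fractions of new
    uORFs that are neutral, deleterious, beneficial.
    """

    ne: float
    s: float
    h: float = 0.5
    p_neutral: float = 0.20
    p_del: float = 0.75
    p_ben: float = 0.05

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("ne must be positive")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        ps = (self.p_neutral, self.p_del, self.p_ben)
        if min(ps) < 0 or abs(sum(ps) - 1.0) > 1e-12:
            raise ValueError("mixture fractions must be nonnegative and sum to 1")


@dataclass
class MkInput:
    """Binned polymorphism and divergence counts for the MK framework.

    ``daf_bins`` are representative derived-allele frequencies (bin
    midpoints), ascending in (0, 1). ``p_test``/``p_neutral`` are
    polymorphism counts per bin for the test class (e.g. uAUG-creating
    SNPs in 5'UTRs) and the neutral reference (AUG-creating SNPs in
    introns); ``d_test``/``d_neutral`` are fixed-difference counts.
    """

    daf_bins: list[float]
    p_test: list[int]
    p_neutral: list[int]
    d_test: int
    d_neutral: int

    def __post_init__(self) -> None:
        if not (len(self.daf_bins) == len(self.p_test) == len(self.p_neutral)):
            raise ValueError("bin vectors must have equal length")
        if self.d_neutral <= 0:
            raise ValueError("d_neutral must be positive")
        if min(self.p_test) < 0 or min(self.p_neutral) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class MkResult:
    alpha_per_bin: list[float]
    daf_bins: list[float]
    fit_kind: str  # "exponential" or "linear"
    fit_params: tuple
    alpha_asym: float
    ci: tuple[float, float]


@dataclass
class SnpRecord:
    chromosome: str
    position: int
    ref: str
    alt: str
    ancestral: str
    daf: float
    effect: str  # nonsynonymous | synonymous | ambiguous
    region: str = "uorf"


@dataclass
class OmegaBin:
    bin_index: int
    kozak_min: float
    kozak_max: float
    nd: float
    sd: float
    n_sites: float
    s_sites: float
    omega: Optional[float]
    reason: str = ""


@dataclass
class PresenceProfile:
    site_id: str
    reference: str
    presence: dict[str, bool]

    def __post_init__(self) -> None:
        self.presence[self.reference] = True

    @property
    def present_species(self) -> list[str]:
        return [sp for sp, p in self.presence.items() if p]


@dataclass
class BlsResult:
    site_id: str
    b0: float
    bls: float


@dataclass
class SnrCurve:
    cutoffs: list[float]
    snr: list[Optional[float]]
    signal_frac: list[float]
    background_frac: list[float]


@dataclass
class SpeciesMatch:
    """Peptide-conservation call for one target species."""

    species: str
    matched: bool
    identity: float
    first_codon_atg: bool
    disrupted_in_first_80pct: bool
    frame: Optional[int] = None


@dataclass
class PeptideConservation:
    site_id: str
    matches: dict[str, SpeciesMatch]
    peptide_bls: Optional[float] = None


@dataclass
class KozakPwm:
    """Position probability matrix over the 7 informative Kozak slots.

    Positions are -6..-1 and +4 relative to the AUG (the invariant
    +1..+3 AUG itself is not scored).  ``probs`` is 7x4 over A,C,G,T.
    """

    probs: "np.ndarray"  # type: ignore[name-defined]  # (7, 4)
    pseudocount: float
    background: "np.ndarray"  # (4,)
    n_contexts: int

    POSITIONS = (-6, -5, -4, -3, -2, -1, 4)


@dataclass
class TisSignal:
    site_id: str
    init_rpf_count: int
    rna_mean_cov: float
    rna_reads: float
    normalized: Optional[float]
    passes_filter: bool


@dataclass
class ContrastSet:
    n_tips: int
    contrasts: list[float]
    node_ids: list[str]
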
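"""Precursor-peptide discovery: annotated small CDS in the neighborhood, or
unannotated ORFs in 1000 bp windows flanking the candidate gene cluster.

ORF rule (six frames): start codon (default bacterial set ATG/GTG/TTG) to
the next in-frame stop; per stop only the longest qualifying ORF is kept
(nested starts collapse); an ORF must *begin* inside the scan window but may
run past its edge. ORFs whose nucleotides include N are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from rippmine.formats_io import GenomeRecord
from rippmine.neighborhood import Neighborhood

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})

DEFAULT_MIN_LEN_AA = 20
DEFAULT_MAX_LEN_AA = 120
DEFAULT_WINDOW_BP = 1000


@dataclass(frozen=True)
class OrfCandidate:
    """An open reading frame, 0-based half-open genomic coordinates
    (``end`` includes the stop codon)."""

    genome_id: str
    start: int
    end: int
    strand: str
    nt_sequence: str  # reading direction, includes stop codon
    aa_sequence: str  # translation without the stop
    start_codon: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length not divisible by 3")
        if len(self.aa_sequence) != (self.end - self.start) // 3 - 1:
            raise ValueError("aa_sequence inconsistent with interval")

    @property
    def length_aa(self) -> int:
        return len(self.aa_sequence)


@dataclass(frozen=True)
class PrecursorCandidate:
    """A putative precursor peptide with provenance."""

    source: str  # {"annotated", "orf_scan"}
    peptide: str
    genome_id: str
    start: int
    end: int
    strand: str
    cluster_id: Optional[int] = None
    provenance: tuple = ()

    @property
    def candidate_id(self) -> str:
        return f"{self.genome_id}:{self.start}-{self.end}({self.strand})"


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate(nt: str) -> str:
    aa = str(Seq(nt).translate())
    return aa[:-1] if aa.endswith("*") else aa


def enumerate_orfs(
    genome: GenomeRecord,
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    max_len_aa: int = DEFAULT_MAX_LEN_AA,
    starts: frozenset = DEFAULT_START_CODONS,
    windows: Optional[Sequence[tuple[int, int]]] = None,
) -> list[OrfCandidate]:
    """All qualifying ORFs on both strands, sorted by genomic start.

    ``windows``: optional genomic intervals; when given, an ORF qualifies
    only if the 5' base of its start codon lies inside one of them. Per
    (strand, frame, stop codon) the earliest qualifying start codon wins.
    """
    seq = genome.sequence
    length = len(seq)

    def in_window(pos: int) -> bool:
        if windows is None:
            return True
        return any(w0 <= pos < w1 for w0, w1 in windows)

    out: list[OrfCandidate] = []
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for frame in range(3):
            pending: list[int] = []
            for p in range(frame, length - 2, 3):
                codon = s[p : p + 3]
                if codon in STOP_CODONS:
                    for q in pending:
                        orf = _qualify(
                            genome.id, s, strand, length, q, p,
                            min_len_aa, max_len_aa, in_window,
                        )
                        if orf is not None:
                            out.append(orf)
                            break
                    pending = []
                elif codon in starts:
                    pending.append(p)
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def _qualify(genome_id, s, strand, length, q, p, min_len_aa, max_len_aa, in_window):
    len_aa = (p - q) // 3
    if not min_len_aa <= len_aa <= max_len_aa:
        return None
    five_prime = q if strand == "+" else length - 1 - q
    if not in_window(five_prime):
        return None
    nt = s[q : p + 3]
    if "N" in nt:
        logger.warning("dropping ORF with ambiguous bases at %d (%s strand)", q, strand)
        return None
    if strand == "+":
        start, end = q, p + 3
    else:
        start, end = length - (p + 3), length - q
    return OrfCandidate(
        genome_id=genome_id,
        start=start,
        end=end,
        strand=strand,
        nt_sequence=nt,
        aa_sequence=_translate(nt),
        start_codon=nt[:3],
    )


def flank_windows(
    genome: GenomeRecord, nb: Neighborhood, window_bp: int = DEFAULT_WINDOW_BP
) -> list[tuple[int, int]]:
    """The 5' and 3' scan windows flanking the cluster span, clipped to the
    contig."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    span0, span1 = nb.cluster_span
    length = len(genome.sequence)
    wins = [
        (max(0, span0 - window_bp), span0),
        (span1, min(length, span1 + window_bp)),
    ]
    return [(a, b) for a, b in wins if a < b]


def scan_flanks(
    genome: GenomeRecord,
    nb: Neighborhood,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    max_len_aa: int = DEFAULT_MAX_LEN_AA,
    starts: frozenset = DEFAULT_START_CODONS,
) -> list[OrfCandidate]:
    """Unannotated-ORF scan of the two windows flanking the cluster span."""
    wins = flank_windows(genome, nb, window_bp)
    return enumerate_orfs(
        genome,
        min_len_aa=min_len_aa,
        max_len_aa=max_len_aa,
        starts=starts,
        windows=wins,
    )


def find_annotated_peptides(
    nb: Neighborhood,
    genome: GenomeRecord,
    max_len: int = DEFAULT_MAX_LEN_AA,
    min_len: int = 1,
) -> list[PrecursorCandidate]:
    """Small annotated CDS features in the neighborhood (anchor excluded)."""
    out = []
    for f in nb.context:
        if f.feature_id == nb.anchor_id or f.kind != "CDS":
            continue
        aa = genome.translate_feature(f)
        if min_len <= len(aa) <= max_len:
            out.append(
                PrecursorCandidate(
                    source="annotated",
                    peptide=aa,
                    genome_id=nb.genome_id,
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                    provenance=((nb.genome_id, f.start, f.end, f.strand, "annotated"),),
                )
            )
    return out


def pool_candidates(
    per_genome: Sequence[tuple[GenomeRecord, Iterable]],
    cluster_id: Optional[int] = None,
) -> list[PrecursorCandidate]:
    """Merge candidates from the genomes of one SSN cluster.

    OrfCandidates are lifted to PrecursorCandidates (source="orf_scan").
    Exact duplicate peptides are deduplicated with provenance kept; when an
    annotated CDS and a scanned ORF cover the same interval of the same
    genome the annotated evidence wins.
    """
    flat: list[PrecursorCandidate] = []
    for genome, cands in per_genome:
        for c in cands:
            if isinstance(c, OrfCandidate):
                flat.append(
                    PrecursorCandidate(
                        source="orf_scan",
                        peptide=c.aa_sequence,
                        genome_id=c.genome_id,
                        start=c.start,
                        end=c.end,
                        strand=c.strand,
                        provenance=((c.genome_id, c.start, c.end, c.strand, "orf_scan"),),
                    )
                )
            else:
                flat.append(c)
    if not flat:
        logger.warning("no precursor candidates pooled for cluster %s", cluster_id)
        return []
    # annotated wins over orf_scan for the same genomic interval
    by_interval: dict[tuple, PrecursorCandidate] = {}
    for c in flat:
        key = (c.genome_id, c.start, c.end, c.strand)
        prev = by_interval.get(key)
        if prev is None or (prev.source == "orf_scan" and c.source == "annotated"):
            by_interval[key] = c
    # dedupe identical peptides, keeping provenance
    by_peptide: dict[str, list[PrecursorCandidate]] = {}
    for key in sorted(by_interval):
        c = by_interval[key]
        by_peptide.setdefault(c.peptide, []).append(c)
    out = []
    for peptide, group in by_peptide.items():
        provenance = tuple(p for c in group for p in c.provenance)
        lead = group[0]
        source = "annotated" if any(c.source == "annotated" for c in group) else "orf_scan"
        out.append(
            PrecursorCandidate(
                source=source,
                peptide=peptide,
                genome_id=lead.genome_id,
                start=lead.start,
                end=lead.end,
                strand=lead.strand,
                cluster_id=cluster_id,
                provenance=provenance,
            )
        )
    out.sort(key=lambda c: (c.genome_id, c.start, c.end, c.strand))
    return out
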
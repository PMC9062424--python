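"""Readers/writers for FASTA, GFF3, GenBank, and network files.

All genomic coordinates are 0-based half-open internally; GFF3 and GenBank
conventions are converted at the I/O boundary. Protein sequences may contain
``X`` in addition to the 20 canonical letters; DNA is restricted to ACGTN.
"""

from __future__ import annotations

import re
import urllib.parse
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

if TYPE_CHECKING:  # pragma: no cover
    from rippmine.ssn import SsnGraph

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

FASTA_WRAP = 60


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique id."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = _first_illegal(self.sequence, PROTEIN_ALPHABET)
        if bad is not None:
            raise FormatError(
                f"illegal character {self.sequence[bad]!r} at position {bad} "
                f"in protein record {self.id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature on a genome, 0-based half-open."""

    feature_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    product: str = ""
    translation: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"feature {self.feature_id!r}: unknown strand {self.strand!r}"
            )

    @property
    def length_flag(self) -> bool:
        """True when a CDS without a stored translation has a length not
        divisible by 3 (annotation slop; allowed but flagged)."""
        return (
            self.kind == "CDS"
            and self.translation is None
            and (self.end - self.start) % 3 != 0
        )


@dataclass
class GenomeRecord:
    """A DNA sequence plus its ordered annotated features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty genome sequence for {self.id!r}")
        bad = _first_illegal(self.sequence, DNA_ALPHABET)
        if bad is not None:
            raise FormatError(
                f"illegal character {self.sequence[bad]!r} at position {bad} "
                f"in genome {self.id!r}"
            )
        for f in self.features:
            if f.end > len(self.sequence):
                raise FormatError(
                    f"feature {f.feature_id!r} extends beyond genome "
                    f"{self.id!r} (end {f.end} > length {len(self.sequence)})"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def feature_by_id(self, feature_id: str) -> GeneFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(f"no feature {feature_id!r} in genome {self.id!r}")

    def translate_feature(self, feat: GeneFeature) -> str:
        """Translation of a CDS feature (stored one if present, else from
        the genome sequence, trailing stop removed)."""
        if feat.translation is not None:
            return feat.translation
        nt = self.sequence[feat.start:feat.end]
        if feat.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
        return aa[:-1] if aa.endswith("*") else aa


def _first_illegal(seq: str, alphabet: frozenset[str]) -> Optional[int]:
    for i, c in enumerate(seq):
        if c not in alphabet:
            return i
    return None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, molecule: str = "auto"):
    """Read a FASTA file into ProteinRecords or (feature-less) GenomeRecords.

    Parameters
    ----------
    path : str or Path
        FASTA file.
    molecule : {"auto", "protein", "dna"}
        With "auto" the molecule type is inferred from the alphabet of the
        whole file (everything within ACGTN -> DNA).
    """
    path = Path(path)
    raw = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = re.sub(r"[\s\-.]", "", str(rec.seq)).upper()
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw.append((rec.id, seq, rec.description))
    if not raw:
        raise FormatError(f"no FASTA records in {path}")
    if molecule == "auto":
        is_dna = all(set(seq) <= DNA_ALPHABET for _, seq, _ in raw)
        molecule = "dna" if is_dna else "protein"
    if molecule == "dna":
        return [GenomeRecord(id=i, sequence=s) for i, s, _ in raw]
    if molecule == "protein":
        return [ProteinRecord(id=i, sequence=s, description=d) for i, s, d in raw]
    raise ValueError(f"unknown molecule type {molecule!r}")


def write_fasta(records: Iterable, path) -> None:
    """Write protein or genome records as FASTA wrapped at 60 columns."""
    with open(path, "w") as fh:
        for rec in records:
            desc = getattr(rec, "description", "")
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# Annotations (GFF3 + FASTA, GenBank)

_GFF_ESCAPE = re.compile(r"%[0-9A-Fa-f]{2}")


def read_annotations(path, dialect: str, fasta_path=None) -> GenomeRecord:
    """Read an annotated genome.

    dialect "genbank": single-record GenBank flat file.
    dialect "gff3+fasta": GFF3 file plus genome FASTA, either as a separate
    file (``fasta_path``) or embedded after a ``##FASTA`` directive.
    """
    if dialect == "genbank":
        return _read_genbank(path)
    if dialect == "gff3+fasta":
        return _read_gff3(path, fasta_path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_genbank(path) -> GenomeRecord:
    recs = list(SeqIO.parse(str(path), "genbank"))
    if len(recs) != 1:
        raise FormatError(f"expected exactly 1 GenBank record in {path}, got {len(recs)}")
    rec = recs[0]
    feats = []
    n_cds = 0
    for f in rec.features:
        if f.type != "CDS":
            continue
        n_cds += 1
        if f.location.strand not in (1, -1):
            raise FormatError(f"unknown strand for CDS #{n_cds} in {path}")
        quals = f.qualifiers
        fid = (quals.get("locus_tag") or quals.get("gene") or [f"cds{n_cds}"])[0]
        feats.append(
            GeneFeature(
                feature_id=fid,
                start=int(f.location.start),
                end=int(f.location.end),
                strand="+" if f.location.strand == 1 else "-",
                kind="CDS",
                product=(quals.get("product") or [""])[0],
                translation=(quals.get("translation") or [None])[0],
            )
        )
    return GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), features=feats)


def _read_gff3(path, fasta_path) -> GenomeRecord:
    lines = Path(path).read_text().splitlines()
    feature_lines: list[str] = []
    fasta_lines: list[str] = []
    in_fasta = False
    for line in lines:
        if line.startswith("##FASTA"):
            in_fasta = True
            continue
        (fasta_lines if in_fasta else feature_lines).append(line)

    if fasta_path is not None:
        genomes = read_fasta(fasta_path, molecule="dna")
        if len(genomes) != 1:
            raise FormatError(f"expected a single sequence in {fasta_path}")
        genome_id, sequence = genomes[0].id, genomes[0].sequence
    elif fasta_lines:
        entries = _parse_fasta_lines(fasta_lines)
        if len(entries) != 1:
            raise FormatError(f"expected a single embedded sequence in {path}")
        genome_id, sequence = entries[0]
    else:
        raise FormatError(f"no genome sequence for GFF3 file {path}")

    feats = []
    n = 0
    for line in feature_lines:
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"malformed GFF3 line: {line!r}")
        seqid, _src, ftype, start1, end1, _score, strand, _phase, attrs = cols
        n += 1
        if strand not in ("+", "-"):
            raise FormatError(f"unknown strand {strand!r} on GFF3 line {n}")
        attrd = _parse_gff_attrs(attrs)
        start = int(start1) - 1  # GFF3 is 1-based inclusive
        end = int(end1)
        if end > len(sequence):
            raise FormatError(
                f"feature on line {n} ends at {end} beyond contig length "
                f"{len(sequence)}"
            )
        feats.append(
            GeneFeature(
                feature_id=attrd.get("ID", f"feature{n}"),
                start=start,
                end=end,
                strand=strand,
                kind="CDS" if ftype == "CDS" else "other",
                product=attrd.get("product", ""),
                translation=attrd.get("translation"),
            )
        )
    return GenomeRecord(id=genome_id, sequence=sequence, features=feats)


def _parse_fasta_lines(lines: list[str]) -> list[tuple[str, str]]:
    entries: list[tuple[str, list[str]]] = []
    for line in lines:
        if line.startswith(">"):
            entries.append((line[1:].split()[0], []))
        elif line.strip():
            if not entries:
                raise FormatError("sequence data before FASTA header")
            entries[-1][1].append(line.strip().upper())
    return [(i, "".join(parts)) for i, parts in entries]


def _parse_gff_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        k, v = chunk.split("=", 1)
        out[k] = urllib.parse.unquote(v)
    return out


def write_gff3(genome: GenomeRecord, path, fasta_path=None) -> None:
    """Write a genome as GFF3 (0-based half-open converted back to 1-based
    inclusive). Sequence goes to ``fasta_path`` if given, else is embedded."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.sequence)}\n")
        for f in genome.features:
            attrs = [f"ID={urllib.parse.quote(f.feature_id, safe='')}"]
            if f.product:
                attrs.append(f"product={urllib.parse.quote(f.product, safe='')}")
            if f.translation:
                attrs.append(f"translation={f.translation}")
            ftype = "CDS" if f.kind == "CDS" else "region"
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "rippmine",
                        ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
        if fasta_path is None:
            fh.write("##FASTA\n")
            fh.write(f">{genome.id}\n")
            for i in range(0, len(genome.sequence), FASTA_WRAP):
                fh.write(genome.sequence[i : i + FASTA_WRAP] + "\n")
    if fasta_path is not None:
        write_fasta([genome], fasta_path)


# ---------------------------------------------------------------------------
# Coordinate conversions (kept explicit so the involution is testable)


def to_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


def from_gff3_coords(start1: int, end1: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# Network I/O

_EDGE_COLUMNS = ("source", "target", "pct_identity", "bitscore", "evalue")


def write_network(graph: "SsnGraph", path, dialect: str = "edge-list") -> None:
    """Write a similarity network; round-trips node ids, edges, and edge
    attributes to 6 significant digits.

    dialect "edge-list": TSV with header; isolated nodes are emitted as rows
    with an empty target. dialect "graphml": GraphML XML for network viewers.
    """
    if dialect == "edge-list":
        _write_edge_list(graph, path)
    elif dialect == "graphml":
        _write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")


def _write_edge_list(graph, path) -> None:
    touched = set()
    for e in graph.edges:
        touched.add(e.a)
        touched.add(e.b)
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_COLUMNS) + "\n")
        for e in sorted(graph.edges, key=lambda e: (e.a, e.b)):
            fh.write(
                f"{e.a}\t{e.b}\t{e.pct_identity:.6g}\t{e.bitscore:.6g}"
                f"\t{e.evalue:.6g}\n"
            )
        for nid in sorted(set(graph.node_ids) - touched):
            fh.write(f"{nid}\t\t\t\t\n")


def _write_graphml(graph, path) -> None:
    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    for key, typ in (("pct_identity", "double"), ("bitscore", "double"), ("evalue", "double")):
        ET.SubElement(
            root, "key", id=key, **{"for": "edge", "attr.name": key, "attr.type": typ}
        )
    g = ET.SubElement(root, "graph", id="SSN", edgedefault="undirected")
    for nid in sorted(graph.node_ids):
        ET.SubElement(g, "node", id=nid)
    for e in sorted(graph.edges, key=lambda e: (e.a, e.b)):
        el = ET.SubElement(g, "edge", source=e.a, target=e.b)
        for key, val in (
            ("pct_identity", e.pct_identity),
            ("bitscore", e.bitscore),
            ("evalue", e.evalue),
        ):
            d = ET.SubElement(el, "data", key=key)
            d.text = f"{val:.6g}"
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_network(path, dialect: str = "edge-list"):
    """Read a network written by :func:`write_network`.

    Returns ``(node_ids, edges)`` where edges are
    :class:`rippmine.ssn.SimilarityEdge`; sequences are not recoverable from
    network files.
    """
    from rippmine.ssn import SimilarityEdge

    node_ids: set[str] = set()
    edges = []
    if dialect == "edge-list":
        lines = Path(path).read_text().splitlines()
        if not lines or tuple(lines[0].split("\t")) != _EDGE_COLUMNS:
            raise FormatError(f"bad edge-list header in {path}")
        for line in lines[1:]:
            cols = line.split("\t")
            if len(cols) != 5:
                raise FormatError(f"malformed edge row: {line!r}")
            src, tgt = cols[0], cols[1]
            node_ids.add(src)
            if tgt:
                node_ids.add(tgt)
                edges.append(
                    SimilarityEdge(
                        a=src,
                        b=tgt,
                        pct_identity=float(cols[2]),
                        bitscore=float(cols[3]),
                        evalue=float(cols[4]),
                    )
                )
    elif dialect == "graphml":
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        tree = ET.parse(path)
        graph_el = tree.getroot().find("g:graph", ns)
        if graph_el is None:
            raise FormatError(f"no <graph> element in {path}")
        for n in graph_el.findall("g:node", ns):
            node_ids.add(n.attrib["id"])
        for el in graph_el.findall("g:edge", ns):
            attrs = {d.attrib["key"]: float(d.text) for d in el.findall("g:data", ns)}
            edges.append(
                SimilarityEdge(
                    a=el.attrib["source"],
                    b=el.attrib["target"],
                    pct_identity=attrs.get("pct_identity", 0.0),
                    bitscore=attrs.get("bitscore", 0.0),
                    evalue=attrs.get("evalue", 0.0),
                )
            )
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")
    return sorted(node_ids), edges
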
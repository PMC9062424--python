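"""Synthetic fixtures with planted ground truth.

Generates (a) protein families with block-structured pairwise identity so
similarity-network clustering has a known answer, (b) genomes carrying an
anchor gene, neighbor genes, and a precursor ORF either annotated or hidden
in a flanking window that is otherwise scrubbed of qualifying ORFs, and
(c) theoretical fragment ladders with planted -2 Da ring sites and seeded
ppm noise. All randomness flows from one integer seed per call.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from rippmine import ms
from rippmine.formats_io import GeneFeature, GenomeRecord, ProteinRecord, write_fasta, write_gff3
from rippmine.precursor import (
    DEFAULT_MAX_LEN_AA,
    DEFAULT_MIN_LEN_AA,
    DEFAULT_START_CODONS,
    DEFAULT_WINDOW_BP,
    enumerate_orfs,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"
STOPS = ("TAA", "TAG", "TGA")

_table = CodonTable.unambiguous_dna_by_id[11]
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    CODONS_BY_AA.setdefault(aa, ())
    CODONS_BY_AA[aa] = CODONS_BY_AA[aa] + (codon,)


class ParameterError(ValueError):
    """Infeasible generation parameters."""


class GenerationError(RuntimeError):
    """Constraint satisfaction failed within the retry budget."""


@dataclass
class PlantedTruth:
    """Ground truth for generated fixtures, serializable as JSON."""

    family_blocks: list = field(default_factory=list)
    bgc_locations: dict = field(default_factory=dict)
    planted_motifs: list = field(default_factory=list)
    planted_mod_sites: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))

    def merge(self, other: "PlantedTruth") -> None:
        self.family_blocks.extend(other.family_blocks)
        self.bgc_locations.update(other.bgc_locations)
        self.planted_motifs.extend(other.planted_motifs)
        self.planted_mod_sites.extend(other.planted_mod_sites)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n)) if n > 0 else ""


def _random_protein(rng: np.random.Generator, n: int, start_met: bool = False) -> str:
    core = "".join(rng.choice(list(AA20), size=n))
    return ("M" + core[1:]) if start_met else core


def back_translate(rng: np.random.Generator, protein: str, stop: bool = True) -> str:
    """Uniform codon choice under the standard genetic code."""
    codons = [CODONS_BY_AA[aa][rng.integers(len(CODONS_BY_AA[aa]))] for aa in protein]
    if stop:
        codons.append(STOPS[rng.integers(3)])
    return "".join(codons)


# ---------------------------------------------------------------------------
# Protein families


def make_family(
    blocks: Sequence[tuple[int, float, float]],
    seq_length_range: tuple[int, int] = (340, 450),
    seed: int = 0,
) -> tuple[list[ProteinRecord], PlantedTruth]:
    """Block-structured protein family.

    Each block (size, within_identity, between_identity) gets an independent
    random ancestor; members are ancestor copies with substitutions at a
    rate chosen so expected pairwise within-block identity matches the
    target. Independent ancestors keep between-block identity far below any
    usable network threshold (the between target is validated, not tuned).
    """
    for size, within, between in blocks:
        if size < 1:
            raise ParameterError("block size must be >= 1")
        if not 0 < within <= 100:
            raise ParameterError("within_identity must be in (0, 100]")
        if within <= between:
            raise ParameterError(
                f"within_identity {within} must exceed between_identity {between}"
            )
    lo, hi = seq_length_range
    if not 0 < lo <= hi:
        raise ParameterError("bad sequence length range")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth = PlantedTruth()
    for b, (size, within, _between) in enumerate(blocks, start=1):
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_protein(rng, length)
        # P(match) ~ (1-d)^2 for independent per-member substitution rate d
        d = 1.0 - math.sqrt(within / 100.0)
        member_ids = []
        for m in range(1, size + 1):
            chars = list(ancestor)
            mask = rng.random(length) < d
            for i in np.flatnonzero(mask):
                choices = [a for a in AA20 if a != chars[i]]
                chars[i] = choices[rng.integers(len(choices))]
            rid = f"b{b}_m{m}"
            member_ids.append(rid)
            records.append(
                ProteinRecord(id=rid, sequence="".join(chars), description=f"block {b}")
            )
        truth.family_blocks.append(
            {"block_id": b, "member_ids": member_ids, "target_within_identity": within}
        )
    return records, truth


# ---------------------------------------------------------------------------
# Genomes


def _break_start(seq_chars: list[str], orf, mutable, rng: np.random.Generator) -> bool:
    """Mutate one base of an ORF's start codon so it is no longer a start.

    Options per strand are (genomic position, allowed replacement bases);
    returns False when no start-codon base may be touched."""
    if orf.strand == "+":
        options = [
            (orf.start, "C"),          # first base: no start codon begins with C
            (orf.start + 1, "ACG"),    # second base must be T in every start
            (orf.start + 2, "ACT"),    # third base must be G
        ]
    else:
        options = [
            (orf.end - 1, "G"),        # complements to C in reading direction
            (orf.end - 2, "CGT"),
            (orf.end - 3, "AGT"),
        ]
    options = [(p, bases) for p, bases in options if mutable(p)]
    if not options:
        return False
    pos, bases = options[rng.integers(len(options))]
    seq_chars[pos] = bases[rng.integers(len(bases))]
    return True


def _break_stop(seq_chars: list[str], orf, mutable) -> bool:
    """Mutate the ORF's stop codon so the frame reads through (the ORF then
    extends to a later stop). Setting the first reading base of the stop to
    C kills TAA/TAG/TGA alike and can create no start codon."""
    pos = orf.end - 3 if orf.strand == "+" else orf.start + 2
    if not mutable(pos):
        return False
    seq_chars[pos] = "C" if orf.strand == "+" else "G"
    return True


def _scrub_windows(
    seq_chars: list[str],
    genome_id: str,
    windows: list[tuple[int, int]],
    forbidden: list[tuple[int, int]],
    protected: Optional[tuple[int, int, str]],
    min_len_aa: int,
    max_len_aa: int,
    starts: frozenset,
    rng: np.random.Generator,
) -> bool:
    """Destroy every ORF the flank scan would report except the protected
    one. Start codons outside forbidden intervals are point-mutated; ORFs
    whose start codon is untouchable (it overlaps the planted precursor)
    are instead extended past ``max_len_aa`` by reading through their stop
    codons. Returns False when a clean state is unreachable."""

    def mutable(pos: int) -> bool:
        return not any(s <= pos < e for s, e in forbidden)

    for _ in range(120):
        genome = GenomeRecord(id=genome_id, sequence="".join(seq_chars))
        orfs = enumerate_orfs(
            genome, min_len_aa=min_len_aa, max_len_aa=max_len_aa,
            starts=starts, windows=windows,
        )
        offenders = [
            o for o in orfs if protected is None or (o.start, o.end, o.strand) != protected
        ]
        if not offenders:
            return True
        progressed = False
        for o in offenders:
            if _break_start(seq_chars, o, mutable, rng) or _break_stop(
                seq_chars, o, mutable
            ):
                progressed = True
        if not progressed:
            return False
    return False


def make_genome(
    anchor: ProteinRecord,
    n_neighbors: int,
    precursor: str,
    hidden: bool = True,
    flank_offset_bp: int = 200,
    seed: int = 0,
    *,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_orf_len_aa: int = DEFAULT_MIN_LEN_AA,
    max_orf_len_aa: int = DEFAULT_MAX_LEN_AA,
    starts: frozenset = DEFAULT_START_CODONS,
    neighbor_len_range: tuple[int, int] = (150, 250),
    gap_range: tuple[int, int] = (50, 200),
    max_tries: int = 1000,
) -> tuple[GenomeRecord, PlantedTruth]:
    """A genome with an anchor CDS, flanking neighbor CDS, and a precursor
    ORF that is either annotated inside the cluster or hidden in the 3'
    flanking window ``flank_offset_bp`` beyond the outermost cluster gene.

    Flank DNA is random but scrubbed so no spurious ORF of at least
    ``min_orf_len_aa`` residues starts in either flanking window."""
    if len(precursor) < 10:
        raise ParameterError("precursor must be >= 10 aa")
    if hidden:
        if precursor[0] != "M":
            raise ParameterError("hidden precursor must start with Met (ATG start)")
        if flank_offset_bp + 3 * len(precursor) + 3 > window_bp:
            raise ParameterError("hidden precursor does not fit in the flank window")
    if flank_offset_bp < 0 or n_neighbors < 0:
        raise ParameterError("negative geometry parameter")

    master = np.random.default_rng(seed)
    genome_id = f"g_{anchor.id}_s{seed}"
    pad = 30

    for _attempt in range(max_tries):
        rng = np.random.default_rng(master.integers(0, 2**62))
        neighbors = []
        for i in range(n_neighbors):
            ln = int(rng.integers(neighbor_len_range[0], neighbor_len_range[1] + 1))
            prot = _random_protein(rng, ln, start_met=True)
            strand = "+" if rng.integers(2) else "-"
            neighbors.append((f"nbr{i + 1}", prot, strand))
        n_left = n_neighbors // 2

        seq_parts: list[str] = []
        features: list[GeneFeature] = []
        pos = 0

        def emit(s: str) -> None:
            nonlocal pos
            seq_parts.append(s)
            pos += len(s)

        def emit_cds(fid: str, prot: str, strand: str, product: str) -> None:
            nt = back_translate(rng, prot)
            if strand == "-":
                nt = str(Seq(nt).reverse_complement())
            features.append(
                GeneFeature(
                    feature_id=fid,
                    start=pos,
                    end=pos + len(nt),
                    strand=strand,
                    kind="CDS",
                    product=product,
                    translation=prot,
                )
            )
            emit(nt)

        def emit_gap() -> None:
            emit(_random_dna(rng, int(rng.integers(gap_range[0], gap_range[1] + 1))))

        emit(_random_dna(rng, window_bp + pad))  # left flank
        for fid, prot, strand in neighbors[:n_left]:
            emit_cds(fid, prot, strand, "hypothetical protein")
            emit_gap()
        emit_cds("anchor", anchor.sequence, "+", "radical SAM family protein")
        if not hidden:
            emit_gap()
            emit_cds("precursor", precursor, "+", "putative precursor peptide")
        for fid, prot, strand in neighbors[n_left:]:
            emit_gap()
            emit_cds(fid, prot, strand, "hypothetical protein")

        span0 = min(f.start for f in features)
        span1 = max(f.end for f in features)
        assert span1 == pos

        protected = None
        if hidden:
            emit(_random_dna(rng, flank_offset_bp))
            pre_nt = back_translate(rng, precursor)
            p_start = pos
            emit(pre_nt)
            protected = (p_start, pos, "+")
            emit(_random_dna(rng, window_bp + pad - flank_offset_bp - len(pre_nt)))
        else:
            emit(_random_dna(rng, window_bp + pad))

        seq_chars = list("".join(seq_parts))
        windows = [(span0 - window_bp, span0), (span1, span1 + window_bp)]
        forbidden = [(f.start, f.end) for f in features]
        if protected is not None:
            forbidden.append(protected[:2])
        if not _scrub_windows(
            seq_chars, genome_id, windows, forbidden, protected,
            min_orf_len_aa, max_orf_len_aa, starts, rng,
        ):
            continue

        genome = GenomeRecord(id=genome_id, sequence="".join(seq_chars), features=features)
        truth = PlantedTruth()
        truth.bgc_locations[genome_id] = {
            "anchor": [int(features_by_id(features, "anchor").start),
                       int(features_by_id(features, "anchor").end), "+"],
            "anchor_protein_id": anchor.id,
            "neighbors": [
                [f.feature_id, int(f.start), int(f.end), f.strand]
                for f in features
                if f.feature_id.startswith("nbr")
            ],
            "precursor": {
                "start": int(protected[0]) if hidden else int(features_by_id(features, "precursor").start),
                "end": int(protected[1]) if hidden else int(features_by_id(features, "precursor").end),
                "strand": "+",
                "hidden": hidden,
                "peptide": precursor,
            },
            "flank_offset_bp": flank_offset_bp,
            "cluster_span": [int(span0), int(span1)],
        }
        return genome, truth
    raise GenerationError(
        f"could not satisfy the no-spurious-ORF constraint in {max_tries} tries"
    )


def features_by_id(features: Sequence[GeneFeature], fid: str) -> GeneFeature:
    return next(f for f in features if f.feature_id == fid)


# ---------------------------------------------------------------------------
# Fragment ladders


def make_ladder(
    peptide: ms.Peptide,
    mod_sites: Sequence[int],
    series: str = "y",
    noise_ppm: float = 0.0,
    seed: int = 0,
    z: int = 1,
) -> list[tuple[ms.IonSpec, float]]:
    """Theoretical ladder with rings planted at ``mod_sites`` (Val positions)
    and multiplicative Gaussian ppm noise."""
    for s in mod_sites:
        if peptide.residues[s] != "V":
            raise ParameterError(f"planted mod site {s} is not Val")
    mods = [ms.ModificationEvent(s) for s in mod_sites]
    theo = ms.fragment_ladder(peptide, mods=mods, series=series, z=z)
    rng = np.random.default_rng(seed)
    out = []
    for spec, m in theo:
        obs = m * (1.0 + rng.normal(0.0, noise_ppm * 1e-6)) if noise_ppm > 0 else m
        out.append((spec, obs))
    return out


# ---------------------------------------------------------------------------
# Full mining bundle

DEFAULT_BLOCK_PRECURSORS = (
    "MW" + "TVGG" * 4,          # tandem-repeat precursor
    "MW" + "DC" * 6,            # dipeptide-repeat precursor
    "MWAANYAANHASKL",           # residue-class motif precursor
)


def make_bundle(
    out_dir,
    seed: int = 0,
    blocks: Sequence[tuple[int, float, float]] = ((5, 90.0, 20.0),) * 3,
    precursors: Sequence[str] = DEFAULT_BLOCK_PRECURSORS,
    seq_length_range: tuple[int, int] = (340, 450),
    n_neighbors: int = 4,
    flank_offset_bp: int = 200,
    min_orf_len_aa: int = 12,
    hidden: bool = True,
) -> dict:
    """Write a complete synthetic mining input set with planted truth.

    Produces ``family.fasta``, one GFF3 (embedded FASTA) genome per family
    member with that member as anchor, and ``truth.json``. Returns paths
    plus the merged PlantedTruth.
    """
    if len(precursors) != len(blocks):
        raise ParameterError("one precursor peptide per block required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "genomes").mkdir(exist_ok=True)

    records, truth = make_family(blocks, seq_length_range, seed=seed)
    write_fasta(records, out_dir / "family.fasta")

    rng = np.random.default_rng(seed + 1)
    genome_paths = []
    member_block = {
        m: bi for bi, blk in enumerate(truth.family_blocks) for m in blk["member_ids"]
    }
    for rec in records:
        bi = member_block[rec.id]
        genome, gtruth = make_genome(
            rec,
            n_neighbors=n_neighbors,
            precursor=precursors[bi],
            hidden=hidden,
            flank_offset_bp=flank_offset_bp,
            seed=int(rng.integers(0, 2**62)),
            min_orf_len_aa=min_orf_len_aa,
        )
        path = out_dir / "genomes" / f"{genome.id}.gff3"
        write_gff3(genome, path)
        genome_paths.append(str(path))
        truth.merge(gtruth)

    from rippmine.motifs import find_tandem_repeats

    for bi, pep in enumerate(precursors):
        for hit in find_tandem_repeats(pep):
            truth.planted_motifs.append(
                {
                    "block_id": bi + 1,
                    "peptide": pep,
                    "motif": hit.unit,
                    "start": hit.start,
                    "copies": hit.copies,
                }
            )

    truth.to_json(out_dir / "truth.json")
    return {
        "family_fasta": str(out_dir / "family.fasta"),
        "genomes": genome_paths,
        "truth_json": str(out_dir / "truth.json"),
        "truth": truth,
        "min_orf_len_aa": min_orf_len_aa,
    }
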
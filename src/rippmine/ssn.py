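"""Sequence similarity network construction, thresholding, and clustering.

Pairwise similarity is Smith-Waterman (BLOSUM62, affine gaps 11/1 in BLAST
convention: a gap of length L costs 11 + L). E-values use Karlin-Altschul
statistics with gapped BLOSUM62 constants (lambda = 0.267, K = 0.041) and a
per-pair m*n search space, so absolute values differ from any particular
BLAST release; thresholds are parameters for that reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from rippmine.formats_io import PROTEIN_ALPHABET, ProteinRecord

KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041

GAP_OPEN = 11
GAP_EXTEND = 1

BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class SimilarityEdge:
    """Thresholdable pairwise-alignment summary between two proteins."""

    a: str
    b: str
    bitscore: float
    evalue: float
    pct_identity: float
    aln_length: int = 0

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-edge on {self.a!r}")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError(f"pct_identity {self.pct_identity} out of [0,100]")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass(frozen=True)
class SsnParams:
    """Network thresholds; defaults follow the mining protocol this package
    reproduces (E <= 1e-80, identity >= 40%, lengths 340-450 aa)."""

    evalue_max: float = 1e-80
    pid_min: float = 40.0
    len_min: int = 340
    len_max: int = 450
    karlin_lambda: float = KARLIN_LAMBDA
    karlin_k: float = KARLIN_K
    gap_open: int = GAP_OPEN
    gap_extend: int = GAP_EXTEND

    def __post_init__(self) -> None:
        if self.len_min > self.len_max:
            raise ValueError("len_min > len_max")
        if self.evalue_max <= 0 or self.pid_min < 0:
            raise ValueError("thresholds must be positive")


@dataclass
class SsnGraph:
    """Length-filtered nodes plus threshold-surviving similarity edges."""

    nodes: dict[str, ProteinRecord]
    edges: list[SimilarityEdge]
    params: SsnParams = field(default_factory=SsnParams)

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.a not in self.nodes or e.b not in self.nodes:
                raise ValueError(f"edge {e.a}-{e.b} references missing node")

    @property
    def node_ids(self) -> list[str]:
        return list(self.nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.a,
                e.b,
                pct_identity=e.pct_identity,
                bitscore=e.bitscore,
                evalue=e.evalue,
            )
        return g


@dataclass(frozen=True)
class ClusterAssignment:
    cluster_id: int  # 1-based size rank
    member_ids: tuple[str, ...]
    representative_id: str
    n_sequences: int


def _make_aligner(params: SsnParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = BLOSUM62
    # Biopython charges open_gap_score for the first gap position, so a gap
    # of length L scores open + (L-1)*extend; shift by one extend to match
    # the BLAST convention open + L*extend.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(
    x: ProteinRecord,
    y: ProteinRecord,
    params: Optional[SsnParams] = None,
) -> SimilarityEdge:
    """Local-align two proteins and derive the thresholdable edge quantities.

    pct_identity uses alignment columns (including gap columns) as the
    denominator; bitscore = (lambda*raw - ln K) / ln 2 and
    evalue = m*n*2^-bitscore with m, n the full sequence lengths.
    """
    params = params or SsnParams()
    for rec in (x, y):
        if set(rec.sequence) - PROTEIN_ALPHABET:
            raise ValueError(f"non-protein alphabet in record {rec.id!r}")
    aligner = _make_aligner(params)
    alignments = aligner.align(x.sequence, y.sequence)
    raw = alignments.score
    aln = alignments[0]
    identities, mismatches, gaps = (
        aln.counts().identities,
        aln.counts().mismatches,
        aln.counts().gaps,
    )
    columns = identities + mismatches + gaps
    pct = 100.0 * identities / columns if columns else 0.0
    bitscore = (params.karlin_lambda * raw - math.log(params.karlin_k)) / math.log(2)
    evalue = x.length * y.length * math.pow(2.0, -min(bitscore, 1e4))
    return SimilarityEdge(
        a=x.id,
        b=y.id,
        bitscore=bitscore,
        evalue=evalue,
        pct_identity=pct,
        aln_length=columns,
    )


def build_ssn(records: Sequence[ProteinRecord], params: Optional[SsnParams] = None) -> SsnGraph:
    """Length-filter records, align all retained pairs, keep edges passing
    both the E-value and identity thresholds."""
    params = params or SsnParams()
    if not records:
        raise ValueError("no records to network")
    retained = [r for r in records if params.len_min <= r.length <= params.len_max]
    nodes = {r.id: r for r in retained}
    if len(nodes) != len(retained):
        raise ValueError("duplicate record ids")
    edges = []
    for i in range(len(retained)):
        for j in range(i + 1, len(retained)):
            e = align_pair(retained[i], retained[j], params)
            if e.evalue <= params.evalue_max and e.pct_identity >= params.pid_min:
                edges.append(e)
    return SsnGraph(nodes=nodes, edges=edges, params=params)


def cluster_ssn(graph: SsnGraph) -> list[ClusterAssignment]:
    """Connected components ranked by size (desc), ties by smallest member
    id; representative = medoid by summed pct_identity over in-component
    edges (ties by smallest id). Isolated nodes form singleton clusters."""
    g = graph.to_networkx()
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c[0]))
    pid_sum: dict[str, float] = {nid: 0.0 for nid in graph.nodes}
    for e in graph.edges:
        pid_sum[e.a] += e.pct_identity
        pid_sum[e.b] += e.pct_identity
    out = []
    for rank, members in enumerate(components, start=1):
        rep = min(members, key=lambda m: (-pid_sum[m], m))
        out.append(
            ClusterAssignment(
                cluster_id=rank,
                member_ids=tuple(members),
                representative_id=rep,
                n_sequences=len(members),
            )
        )
    return out


def select_analysis_clusters(
    clusters: Sequence[ClusterAssignment],
    min_nodes: int = 2,
    min_sequences: int = 4,
    max_rank: int = 118,
) -> list[ClusterAssignment]:
    """Clusters worth manual analysis: rank within ``max_rank``, multiple
    nodes, and at least ``min_sequences`` member sequences ("more than
    three" read strictly as >= 4)."""
    return [
        c
        for c in clusters
        if c.cluster_id <= max_rank
        and len(c.member_ids) >= min_nodes
        and c.n_sequences >= min_sequences
    ]


def tighten(params: SsnParams, pid_min: Optional[float] = None, evalue_max: Optional[float] = None) -> SsnParams:
    """Convenience for threshold-monotonicity experiments."""
    kwargs = {}
    if pid_min is not None:
        kwargs["pid_min"] = pid_min
    if evalue_max is not None:
        kwargs["evalue_max"] = evalue_max
    return replace(params, **kwargs)
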
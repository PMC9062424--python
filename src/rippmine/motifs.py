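"""Conserved-core detection on pooled precursor candidates.

Three complementary detectors: a progressive multiple alignment with
per-column conservation scoring, a maximal exact tandem-repeat finder
(primitive units only), and residue-class pattern matching (e.g.
Aro-Xaa-Xaa-Asn with Aro = {W, Y}).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP = "-"
MSA_GAP_OPEN = 10.0
MSA_GAP_EXTEND = 0.5
CONSENSUS_THRESHOLD = 0.8

AA = "ACDEFGHIKLMNPQRSTVWY"
WILDCARD = None  # Xaa


@dataclass(frozen=True)
class MotifPattern:
    """An ordered residue-class pattern; ``None`` elements are Xaa."""

    name: str
    elements: tuple[Optional[frozenset[str]], ...]
    min_copies: int = 1

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern has no elements")
        for el in self.elements:
            if el is not None and not el:
                raise ValueError("empty residue class")

    def __len__(self) -> int:
        return len(self.elements)


def pattern(name: str, spec: str, aro: frozenset[str] = frozenset("WY")) -> MotifPattern:
    """Build a pattern from a dash-separated spec, e.g. "Aro-X-X-N".

    Tokens: single residue letters, "X"/"Xaa" wildcard, "Aro" (configurable
    aromatic class), or bracketed sets like "[WYF]".
    """
    elements: list[Optional[frozenset[str]]] = []
    for tok in spec.split("-"):
        tok = tok.strip()
        if tok in ("X", "Xaa", "x"):
            elements.append(WILDCARD)
        elif tok == "Aro":
            elements.append(aro)
        elif tok.startswith("[") and tok.endswith("]"):
            elements.append(frozenset(tok[1:-1]))
        elif len(tok) == 1 and tok in AA:
            elements.append(frozenset(tok))
        else:
            raise ValueError(f"bad pattern token {tok!r}")
    return MotifPattern(name=name, elements=tuple(elements))


def default_patterns(aro: frozenset[str] = frozenset("WY")) -> list[MotifPattern]:
    """The residue-class motifs this pipeline screens precursor pools for."""
    return [
        pattern("aro-x-x-asn", "Aro-X-X-N", aro=aro),
        pattern("asp-cys", "D-C"),
        pattern("tyr-asn-arg-x-(his-asn-arg)2", "Y-N-R-X-H-N-R-H-N-R"),
        pattern("his-x-ser", "H-X-S"),
    ]


def match_pattern(peptide: str, pat: MotifPattern) -> list[tuple[int, str]]:
    """All (possibly overlapping) positions where the pattern matches."""
    k = len(pat)
    out = []
    for i in range(len(peptide) - k + 1):
        if all(
            el is WILDCARD or peptide[i + j] in el
            for j, el in enumerate(pat.elements)
        ):
            out.append((i, peptide[i : i + k]))
    return out


# ---------------------------------------------------------------------------
# Tandem repeats


@dataclass(frozen=True)
class RepeatHit:
    """A maximal exact tandem array of a primitive unit."""

    peptide_id: str
    start: int
    unit: str
    period: int
    copies: int

    def __post_init__(self) -> None:
        if self.period != len(self.unit):
            raise ValueError("period != len(unit)")

    @property
    def span(self) -> int:
        return self.period * self.copies


def _primitive(unit: str) -> bool:
    p = len(unit)
    for d in range(1, p):
        if p % d == 0 and unit == unit[:d] * (p // d):
            return False
    return True


def find_tandem_repeats(
    peptide: str,
    min_period: int = 2,
    max_period: int = 6,
    min_copies: int = 2,
    peptide_id: str = "",
) -> list[RepeatHit]:
    """All maximal exact tandem arrays with a primitive unit.

    Maximality: the array extends neither left nor right by a full unit.
    Rotated phases of one array collapse to the leftmost start. Partial
    trailing copies do not count toward ``copies``. Sorted by
    (start, period).
    """
    if not peptide:
        raise ValueError("empty peptide")
    n = len(peptide)
    hits = []
    for p in range(min_period, max_period + 1):
        run_start = None
        for i in range(n - p + 1):
            matches = i < n - p and peptide[i] == peptide[i + p]
            if matches and run_start is None:
                run_start = i
            elif not matches and run_start is not None:
                run_len = i - run_start  # positions with s[j] == s[j+p]
                copies = (run_len + p) // p
                unit = peptide[run_start : run_start + p]
                if copies >= min_copies and _primitive(unit):
                    hits.append(
                        RepeatHit(
                            peptide_id=peptide_id,
                            start=run_start,
                            unit=unit,
                            period=p,
                            copies=copies,
                        )
                    )
                run_start = None
    hits.sort(key=lambda h: (h.start, h.period))
    return hits


# ---------------------------------------------------------------------------
# Progressive multiple alignment


@dataclass
class MsaResult:
    """Aligned peptides with per-column conservation.

    Conservation of a column = fraction of its non-gap residues equal to
    the modal non-gap residue; all-gap columns score 0.
    """

    ids: list[str]
    aligned: list[str]
    conservation: list[float]
    consensus: str

    def __post_init__(self) -> None:
        widths = {len(a) for a in self.aligned}
        if len(widths) > 1:
            raise ValueError("aligned rows differ in length")


def _pairwise_identity(a: str, b: str) -> float:
    """Identity fraction of a global BLOSUM62 alignment (gap columns count
    in the denominator). Used only to build the guide tree."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -MSA_GAP_OPEN
    aligner.extend_gap_score = -MSA_GAP_EXTEND
    aln = aligner.align(a, b)[0]
    c = aln.counts()
    columns = c.identities + c.mismatches + c.gaps
    return c.identities / columns if columns else 0.0


def _col_score(col_a: list[str], col_b: list[str]) -> float:
    """Average BLOSUM62 score over residue pairs; gaps contribute 0."""
    total = 0.0
    for x in col_a:
        if x == GAP:
            continue
        for y in col_b:
            if y != GAP:
                total += BLOSUM62[x][y]
    return total / (len(col_a) * len(col_b))


def _profile_align(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment (Gotoh affine gaps). Ties prefer
    diagonal, then a gap in profile B, for determinism."""
    cols_a = [[r[i] for r in rows_a] for i in range(len(rows_a[0]))]
    cols_b = [[r[i] for r in rows_b] for i in range(len(rows_b[0]))]
    n, m = len(cols_a), len(cols_b)
    NEG = float("-inf")
    open_cost = MSA_GAP_OPEN + MSA_GAP_EXTEND
    ext_cost = MSA_GAP_EXTEND

    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in A (consume B)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in B (consume A)
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -open_cost - (j - 1) * ext_cost
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = -open_cost - (i - 1) * ext_cost
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - ext_cost, H[i][j - 1] - open_cost)
            F[i][j] = max(F[i - 1][j] - ext_cost, H[i - 1][j] - open_cost)
            diag = H[i - 1][j - 1] + _col_score(cols_a[i - 1], cols_b[j - 1])
            H[i][j] = max(diag, F[i][j], E[i][j])

    # traceback
    out_a: list[list[str]] = []
    out_b: list[list[str]] = []
    gap_a = [GAP] * len(rows_a)
    gap_b = [GAP] * len(rows_b)
    i, j = n, m
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + _col_score(
                cols_a[i - 1], cols_b[j - 1]
            ):
                out_a.append(cols_a[i - 1])
                out_b.append(cols_b[j - 1])
                i, j = i - 1, j - 1
                continue
            if i > 0 and H[i][j] == F[i][j]:
                state = "F"
                continue
            state = "E"
            continue
        if state == "F":
            out_a.append(cols_a[i - 1])
            out_b.append(gap_b)
            if F[i][j] == H[i - 1][j] - open_cost or i == 1:
                state = "H"
            i -= 1
            continue
        # state == "E"
        out_a.append(gap_a)
        out_b.append(cols_b[j - 1])
        if E[i][j] == H[i][j - 1] - open_cost or j == 1:
            state = "H"
        j -= 1

    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(col[r] for col in out_a) for r in range(len(rows_a))]
    new_b = ["".join(col[r] for col in out_b) for r in range(len(rows_b))]
    return new_a, new_b


def align_peptides(
    peptides: Sequence[str],
    ids: Optional[Sequence[str]] = None,
    consensus_threshold: float = CONSENSUS_THRESHOLD,
) -> MsaResult:
    """Progressive multiple alignment.

    Guide order: single linkage on pairwise global identity; profile-profile
    Needleman-Wunsch (BLOSUM62, gap open 10, extend 0.5); deterministic with
    ties broken by input order.
    """
    if len(peptides) < 2:
        raise ValueError("need at least 2 peptides to align")
    ids = list(ids) if ids is not None else [f"p{i}" for i in range(len(peptides))]
    if len(ids) != len(peptides):
        raise ValueError("ids/peptides length mismatch")

    k = len(peptides)
    sim = {}
    for i in range(k):
        for j in range(i + 1, k):
            sim[(i, j)] = _pairwise_identity(peptides[i], peptides[j])

    # single-linkage agglomeration; each cluster is (member indices, rows)
    clusters: list[tuple[list[int], list[str]]] = [([i], [peptides[i]]) for i in range(k)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                link = max(
                    sim[(min(x, y), max(x, y))]
                    for x in clusters[a][0]
                    for y in clusters[b][0]
                )
                key = (-link, clusters[a][0][0], clusters[b][0][0])
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        members_a, rows_a = clusters[a]
        members_b, rows_b = clusters[b]
        new_a, new_b = _profile_align(rows_a, rows_b)
        merged = (members_a + members_b, new_a + new_b)
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)]
        clusters.append(merged)

    members, rows = clusters[0]
    order = sorted(range(len(members)), key=lambda r: members[r])
    aligned = [rows[r] for r in order]

    width = len(aligned[0])
    conservation = []
    consensus_chars = []
    for c in range(width):
        col = [row[c] for row in aligned]
        residues = [x for x in col if x != GAP]
        if not residues:
            conservation.append(0.0)
            consensus_chars.append(GAP)
            continue
        counts: dict[str, int] = {}
        for x in residues:
            counts[x] = counts.get(x, 0) + 1
        modal = min(counts, key=lambda x: (-counts[x], x))
        frac = counts[modal] / len(residues)
        conservation.append(frac)
        consensus_chars.append(modal if frac >= consensus_threshold else "x")
    return MsaResult(
        ids=ids,
        aligned=aligned,
        conservation=conservation,
        consensus="".join(consensus_chars),
    )


# ---------------------------------------------------------------------------
# Candidate scoring


@dataclass(frozen=True)
class ScoreWeights:
    conservation: float = 1.0
    repeat: float = 0.25
    pattern: float = 0.5
    repeat_cap: int = 6


def score_precursor(
    msa: Optional[MsaResult],
    repeat_hits: dict[str, list[RepeatHit]],
    pattern_hits: dict[str, list[tuple[int, str]]],
    weights: ScoreWeights = ScoreWeights(),
) -> list[tuple[str, float, dict]]:
    """Rank candidates by conservation + repeat + pattern evidence.

    score = w_cons * mean conservation over the candidate's non-gap columns
    + w_rep * min(max repeat copies, cap) + w_pat * number of pattern hits.
    Without an alignment (single candidate) the conservation term is 0.
    Deterministic; ties broken by candidate id.
    """
    cand_ids = sorted(set(repeat_hits) | set(pattern_hits) | set(msa.ids if msa else []))
    if not cand_ids:
        raise ValueError("no candidates to score")
    scored = []
    for cid in cand_ids:
        cons = 0.0
        if msa is not None and cid in msa.ids:
            row = msa.aligned[msa.ids.index(cid)]
            core = [msa.conservation[i] for i, ch in enumerate(row) if ch != GAP]
            cons = sum(core) / len(core) if core else 0.0
        reps = repeat_hits.get(cid, [])
        max_copies = max((h.copies for h in reps), default=0)
        pats = pattern_hits.get(cid, [])
        score = (
            weights.conservation * cons
            + weights.repeat * min(max_copies, weights.repeat_cap)
            + weights.pattern * len(pats)
        )
        evidence = {
            "mean_conservation": cons,
            "max_repeat_copies": max_copies,
            "n_pattern_hits": len(pats),
        }
        scored.append((cid, score, evidence))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored
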
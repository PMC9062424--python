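"""Independent brute-force oracles used to check pipeline implementations.

Each oracle is written from the operation's definition, not its
implementation: dynamic-programming local alignment (Gotoh), breadth-first
connected components, exhaustive six-frame ORF enumeration, per-start
tandem-repeat counting, and elemental-composition mass summation from free
amino-acid molecular formulas.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Smith-Waterman local score, affine gaps in BLAST convention
    (length-L gap costs gap_open + L*gap_extend). Plain Gotoh DP."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    open_cost = gap_open + gap_extend
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - open_cost)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - open_cost)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + _B62[a[i - 1]][b[j - 1]], E[i][j], F[i][j]
            )
            if H[i][j] > best:
                best = H[i][j]
    return best


def bfs_components(node_ids, edges) -> list[frozenset]:
    """Connected components via explicit breadth-first search."""
    adj: dict[str, set[str]] = {n: set() for n in node_ids}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps = []
    for n in node_ids:
        if n in seen:
            continue
        queue = [n]
        seen.add(n)
        comp = {n}
        while queue:
            cur = queue.pop(0)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return comps


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def orf_enumeration(
    seq: str,
    min_len_aa: int,
    max_len_aa: int,
    starts: frozenset,
    windows=None,
) -> set[tuple[int, int, str]]:
    """Exhaustive six-frame ORF enumeration: per (strand, frame, stop) the
    earliest start codon after the previous stop that satisfies length
    bounds, start-in-window, and no-N, wins. Returns genomic intervals."""
    L = len(seq)

    def in_window(pos: int) -> bool:
        if windows is None:
            return True
        return any(w0 <= pos < w1 for w0, w1 in windows)

    out = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            stop_positions = [
                p for p in range(frame, L - 2, 3) if s[p : p + 3] in STOPS
            ]
            prev_stop = frame - 3
            for stop in stop_positions:
                for q in range(prev_stop + 3, stop, 3):
                    if s[q : q + 3] not in starts:
                        continue
                    len_aa = (stop - q) // 3
                    if not min_len_aa <= len_aa <= max_len_aa:
                        continue
                    five_prime = q if strand == "+" else L - 1 - q
                    if not in_window(five_prime):
                        continue
                    if "N" in s[q : stop + 3]:
                        continue
                    if strand == "+":
                        out.add((q, stop + 3, "+"))
                    else:
                        out.add((L - (stop + 3), L - q, "-"))
                    break
                prev_stop = stop
    return out


def _primitive(unit: str) -> bool:
    p = len(unit)
    return not any(
        p % d == 0 and unit == unit[:d] * (p // d) for d in range(1, p)
    )


def tandem_repeats(
    s: str, min_period: int = 2, max_period: int = 6, min_copies: int = 2
) -> set[tuple[int, str, int]]:
    """Per-start O(n^3) enumeration of maximal primitive tandem arrays.

    A start is the leftmost phase iff the period-p self-match predicate
    fails just left of it. Returns (start, unit, copies) tuples."""
    n = len(s)
    out = set()
    for p in range(min_period, max_period + 1):
        for i in range(n - 2 * p + 1):
            unit = s[i : i + p]
            if not _primitive(unit):
                continue
            c = 1
            while s[i + c * p : i + (c + 1) * p] == unit:
                c += 1
            if c < min_copies:
                continue
            if i > 0 and i + p <= n and s[i - 1] == s[i - 1 + p]:
                continue  # not the leftmost phase of its array
            out.add((i, unit, c))
    return out


# free amino-acid molecular formulas (C, H, N, O, S); residue = molecule - H2O
FREE_AA_FORMULAS = {
    "G": (2, 5, 1, 2, 0),
    "A": (3, 7, 1, 2, 0),
    "S": (3, 7, 1, 3, 0),
    "P": (5, 9, 1, 2, 0),
    "V": (5, 11, 1, 2, 0),
    "T": (4, 9, 1, 3, 0),
    "C": (3, 7, 1, 2, 1),
    "L": (6, 13, 1, 2, 0),
    "I": (6, 13, 1, 2, 0),
    "N": (4, 8, 2, 3, 0),
    "D": (4, 7, 1, 4, 0),
    "Q": (5, 10, 2, 3, 0),
    "K": (6, 14, 2, 2, 0),
    "E": (5, 9, 1, 4, 0),
    "M": (5, 11, 1, 2, 1),
    "H": (6, 9, 3, 2, 0),
    "F": (9, 11, 1, 2, 0),
    "R": (6, 14, 4, 2, 0),
    "Y": (9, 11, 1, 3, 0),
    "W": (11, 12, 2, 2, 0),
}

ATOM_MASSES = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
}


def peptide_mass(residues: str, amide: bool = False) -> float:
    """Neutral monoisotopic mass via whole-molecule atom counting."""
    atoms = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0}
    for aa in residues:
        c, h, n, o, s = FREE_AA_FORMULAS[aa]
        atoms["C"] += c
        atoms["H"] += h
        atoms["N"] += n
        atoms["O"] += o
        atoms["S"] += s
    # each peptide bond condenses out one water
    n_bonds = len(residues) - 1
    atoms["H"] -= 2 * n_bonds
    atoms["O"] -= n_bonds
    if amide:  # replace C-terminal OH with NH2
        atoms["O"] -= 1
        atoms["H"] += 1
        atoms["N"] += 1
    return sum(ATOM_MASSES[el] * k for el, k in atoms.items())
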
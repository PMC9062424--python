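"""Peptide monoisotopic mass engine and -2 Da modification arithmetic.

Masses are built from elemental compositions with fixed monoisotopic atomic
masses; charge carriers are protons only and only monoisotopic peaks are
modeled. The modification of interest is a cyclopropane ring formed on a Val
side chain by loss of two hydrogen atoms (neutral delta = -2 x H).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

# Monoisotopic atomic masses (Da)
MASS_H = 1.0078250319
MASS_C = 12.0
MASS_N = 14.0030740
MASS_O = 15.9949146
MASS_S = 31.9720707
MASS_PROTON = 1.0072765

MASS_13C = 13.0033548
MASS_15N = 15.0001089
DELTA_13C = MASS_13C - MASS_C
DELTA_15N = MASS_15N - MASS_N

WATER = 2 * MASS_H + MASS_O
# amide C-terminus: -OH +NH2 relative to the free acid
AMIDE_ADJUST = (MASS_N + 2 * MASS_H) - (MASS_O + MASS_H)

# ring closure between the Val gamma carbons loses two H atoms
RING_DELTA = -2 * MASS_H

# residue = amino acid minus water; formulas as (C, H, N, O, S) atom counts
RESIDUE_FORMULAS: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

_ATOM_MASSES = (MASS_C, MASS_H, MASS_N, MASS_O, MASS_S)

RESIDUE_MASSES: dict[str, float] = {
    aa: sum(n * m for n, m in zip(f, _ATOM_MASSES))
    for aa, f in RESIDUE_FORMULAS.items()
}

# label name -> (extra 13C count, extra 15N count)
ISOTOPE_LABELS: dict[str, tuple[int, int]] = {
    "13C5_15N": (5, 1),  # uniformly labeled Val
}


def label_delta(label: str | tuple[int, int]) -> float:
    """Mass shift of an isotope label (name or (n13C, n15N) counts)."""
    if isinstance(label, str):
        try:
            n13c, n15n = ISOTOPE_LABELS[label]
        except KeyError:
            raise ValueError(f"unknown isotope label {label!r}") from None
    else:
        n13c, n15n = label
    return n13c * DELTA_13C + n15n * DELTA_15N


@dataclass(frozen=True)
class Peptide:
    """A residue chain with terminal state and per-residue isotope labels.

    ``labels`` maps 0-based residue index -> label name or (n13C, n15N).
    """

    residues: str
    c_terminus: str = "free_acid"
    n_terminus: str = "free"
    labels: tuple[tuple[int, str | tuple[int, int]], ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(RESIDUE_FORMULAS)
        if bad:
            raise ValueError(f"non-canonical residues {sorted(bad)} in peptide")
        if self.c_terminus not in ("free_acid", "amide"):
            raise ValueError(f"unknown C-terminus {self.c_terminus!r}")
        if self.n_terminus != "free":
            raise ValueError(f"unknown N-terminus {self.n_terminus!r}")
        for pos, _ in self.labels:
            if not 0 <= pos < len(self.residues):
                raise ValueError(f"label position {pos} outside peptide")

    def __len__(self) -> int:
        return len(self.residues)

    def label_map(self) -> dict[int, float]:
        return {pos: label_delta(lab) for pos, lab in self.labels}

    def val_sites(self) -> list[int]:
        return [i for i, aa in enumerate(self.residues) if aa == "V"]


@dataclass(frozen=True)
class ModificationEvent:
    """One cyclopropane ring closure (-2 H) at a Val residue."""

    site: int
    kind: str = "cyclopropane_ring"

    @property
    def delta(self) -> float:
        return RING_DELTA


def _check_mods(p: Peptide, mods: Iterable[ModificationEvent]) -> list[ModificationEvent]:
    mods = list(mods)
    for m in mods:
        if not 0 <= m.site < len(p):
            raise ValueError(f"modification site {m.site} outside peptide")
        if p.residues[m.site] != "V":
            raise ValueError(
                f"modification site {m.site} is {p.residues[m.site]!r}, not Val"
            )
    return mods


@dataclass(frozen=True)
class IonSpec:
    """A fragment-ion specification.

    b/y ions use ``index`` (number of residues from the respective terminus);
    internal b/y-type ions use ``(start, end)`` residue bounds (half-open).
    """

    series: str  # {"b", "y", "internal_by"}
    index: Optional[int] = None
    start: Optional[int] = None
    end: Optional[int] = None
    z: int = 1
    n_mods_contained: int = 0

    def residue_range(self, n_residues: int) -> tuple[int, int]:
        """Half-open residue-index range covered by this fragment."""
        if self.series == "b":
            return (0, self.index)
        if self.series == "y":
            return (n_residues - self.index, n_residues)
        if self.series == "internal_by":
            return (self.start, self.end)
        raise ValueError(f"unknown ion series {self.series!r}")


def monoisotopic_mass(p: Peptide, mods: Sequence[ModificationEvent] = ()) -> float:
    """Neutral monoisotopic mass in Da."""
    mods = _check_mods(p, mods)
    mass = sum(RESIDUE_MASSES[aa] for aa in p.residues) + WATER
    if p.c_terminus == "amide":
        mass += AMIDE_ADJUST
    mass += sum(p.label_map().values())
    mass += sum(m.delta for m in mods)
    return round(mass, 6)


def mz(neutral_mass: float, z: int) -> float:
    """m/z of the z-fold protonated ion."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + z * MASS_PROTON) / z


def modification_series(base_mz: float, z: int, n_max: int) -> list[float]:
    """Predicted m/z for 0..n_max ring modifications from a base m/z.

    Each modification removes two H atoms from the neutral species, i.e.
    2 x 1.0078250 / z on the m/z scale.
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    step = 2 * MASS_H / z
    return [base_mz - n * step for n in range(n_max + 1)]


def ppm_error(observed: float, predicted: float) -> tuple[float, float]:
    """Relative mass error as (value truncated to one decimal, full value).

    Truncation (not round-half-up) is the reporting convention; the full
    precision value is also returned.
    """
    if predicted <= 0:
        raise ValueError("predicted m/z must be positive")
    full = abs(observed - predicted) / predicted * 1e6
    truncated = math.floor(full * 10 + 1e-9) / 10
    return truncated, full


def fragment_ladder(
    p: Peptide,
    mods: Sequence[ModificationEvent] = (),
    series: str = "y",
    z: int = 1,
) -> list[tuple[IonSpec, float]]:
    """Theoretical b, y, or internal b/y-type fragment ions.

    A modification (or isotope label) contributes to a fragment iff its
    residue index lies within the fragment. b_i = first i residues + proton;
    y_j = last j residues + water (+ amide adjustment) + proton; internal
    ions are bare residue sums + proton. Sorted by index.
    """
    mods = _check_mods(p, mods)
    if z < 1:
        raise ValueError("charge must be >= 1")
    n = len(p)
    labels = p.label_map()
    prefix = [0.0] * (n + 1)
    for i, aa in enumerate(p.residues):
        prefix[i + 1] = prefix[i] + RESIDUE_MASSES[aa] + labels.get(i, 0.0)

    def _segment(a: int, b: int) -> tuple[float, int]:
        contained = [m for m in mods if a <= m.site < b]
        return prefix[b] - prefix[a] + sum(m.delta for m in contained), len(contained)

    out: list[tuple[IonSpec, float]] = []
    if series == "b":
        for i in range(1, n + 1):
            mass, k = _segment(0, i)
            out.append((IonSpec("b", index=i, z=z, n_mods_contained=k), mz(mass, z)))
    elif series == "y":
        cterm = WATER + (AMIDE_ADJUST if p.c_terminus == "amide" else 0.0)
        for j in range(1, n + 1):
            mass, k = _segment(n - j, n)
            out.append(
                (IonSpec("y", index=j, z=z, n_mods_contained=k), mz(mass + cterm, z))
            )
    elif series == "internal_by":
        for a in range(1, n - 1):
            for b in range(a + 1, n):
                mass, k = _segment(a, b)
                out.append(
                    (
                        IonSpec("internal_by", start=a, end=b, z=z, n_mods_contained=k),
                        mz(mass, z),
                    )
                )
        out.sort(key=lambda t: (t[0].start, t[0].end))
    else:
        raise ValueError(f"unknown ion series {series!r}")
    return out


@dataclass
class LocalizationResult:
    """Outcome of modification-site localization from an observed ladder."""

    assignments: list[frozenset[int]]
    mixture: bool
    conflict: Optional[IonSpec] = None
    per_ion_explained: dict = field(default_factory=dict)

    @property
    def unique(self) -> Optional[frozenset[int]]:
        return self.assignments[0] if len(self.assignments) == 1 else None


def localize_modifications(
    p: Peptide,
    observed: Sequence[tuple[IonSpec, float]],
    tol_ppm: float = 10.0,
    max_mods: Optional[int] = None,
) -> LocalizationResult:
    """Find ring-site assignments consistent with an observed fragment ladder.

    Every subset of the peptide's Val positions (up to ``max_mods`` rings) is
    tested; an assignment is admitted iff every observed ion matches its
    predicted m/z within ``tol_ppm``. When no single assignment explains all
    ions but each ion is individually explained by at least one, the ladder
    can only arise from a mixture of differently modified species and the
    ``mixture`` flag is raised (nonprocessive modification signature).
    """
    sites = p.val_sites()
    if max_mods is None:
        max_mods = len(sites)
    candidates = [
        frozenset(combo)
        for n in range(0, max_mods + 1)
        for combo in itertools.combinations(sites, n)
    ]

    n_res = len(p)

    def _predict(spec: IonSpec, assignment: frozenset[int]) -> float:
        a, b = spec.residue_range(n_res)
        mods = [ModificationEvent(s) for s in assignment if a <= s < b]
        ladder = {
            _ion_key(ion): m
            for ion, m in fragment_ladder(p, mods=mods, series=spec.series, z=spec.z)
        }
        return ladder[_ion_key(spec)]

    consistent = []
    per_ion: dict = {}
    first_conflict: Optional[IonSpec] = None
    for assignment in candidates:
        ok = True
        for spec, obs_mz in observed:
            pred = _predict(spec, assignment)
            matched = ppm_error(obs_mz, pred)[1] <= tol_ppm
            if matched:
                per_ion.setdefault(_ion_key(spec), set()).add(assignment)
            else:
                ok = False
        if ok:
            consistent.append(assignment)

    all_ions_explained = all(
        _ion_key(spec) in per_ion for spec, _ in observed
    )
    mixture = not consistent and all_ions_explained and len(observed) > 0
    if not consistent and not all_ions_explained:
        for spec, _ in observed:
            if _ion_key(spec) not in per_ion:
                first_conflict = spec
                break
    consistent.sort(key=lambda a: (len(a), sorted(a)))
    return LocalizationResult(
        assignments=consistent,
        mixture=mixture,
        conflict=first_conflict,
        per_ion_explained=per_ion,
    )


def _ion_key(spec: IonSpec) -> tuple:
    return (spec.series, spec.index, spec.start, spec.end, spec.z)
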
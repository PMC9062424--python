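"""Gene-neighborhood extraction around an anchor CDS (the +/-k context)."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from rippmine.formats_io import GeneFeature, GenomeRecord

DEFAULT_PRODUCT_KEYWORDS = ("radical SAM",)


@dataclass
class Neighborhood:
    """Up to k CDS features on each side of the anchor, in genomic order."""

    genome_id: str
    anchor_id: str
    context: list[GeneFeature]
    k: int
    cluster_span: tuple[int, int]

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.context]
        if self.anchor_id not in ids:
            raise ValueError("anchor not in context")
        starts = [f.start for f in self.context]
        if starts != sorted(starts):
            raise ValueError("context not sorted by start")

    @property
    def anchor(self) -> GeneFeature:
        return next(f for f in self.context if f.feature_id == self.anchor_id)


def extract_neighborhood(genome: GenomeRecord, anchor_id: str, k: int = 10) -> Neighborhood:
    """The anchor CDS plus up to k CDS features on each side by genomic
    order, regardless of strand; silently truncated at contig ends. The
    cluster span is the [min start, max end) envelope of the context."""
    cds = [f for f in genome.features if f.kind == "CDS"]
    idx = next((i for i, f in enumerate(cds) if f.feature_id == anchor_id), None)
    if idx is None:
        raise KeyError(f"anchor CDS {anchor_id!r} not found in genome {genome.id!r}")
    context = cds[max(0, idx - k) : idx + k + 1]
    span = (min(f.start for f in context), max(f.end for f in context))
    return Neighborhood(
        genome_id=genome.id,
        anchor_id=anchor_id,
        context=context,
        k=k,
        cluster_span=span,
    )


def find_anchors(
    genome: GenomeRecord,
    family_members: Iterable,
    product_keywords: Sequence[str] = DEFAULT_PRODUCT_KEYWORDS,
) -> list[str]:
    """CDS features matching the protein family, in genomic order.

    ``family_members`` may contain sequences or objects with a ``sequence``
    attribute. Exact translation matches take precedence over product-text
    keyword matches; keyword matching is case-insensitive substring search.
    """
    member_seqs = {getattr(m, "sequence", m) for m in family_members}
    exact, keyword = [], []
    patterns = [re.compile(re.escape(kw), re.IGNORECASE) for kw in product_keywords]
    for f in genome.features:
        if f.kind != "CDS":
            continue
        if genome.translate_feature(f) in member_seqs:
            exact.append(f.feature_id)
        elif any(p.search(f.product) for p in patterns):
            keyword.append(f.feature_id)
    return exact if exact else keyword
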
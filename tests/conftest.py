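from __future__ import annotations

import pytest

from rippmine.formats_io import GeneFeature, GenomeRecord, ProteinRecord
from rippmine.synthetic import make_family, make_genome

TVG_PRECURSOR = "MW" + "TVGG" * 4


@pytest.fixture(scope="session")
def family_block5():
    """One 5-member block at 90% within-block identity."""
    records, truth = make_family([(5, 90.0, 20.0)], (340, 450), seed=7)
    return records, truth


@pytest.fixture(scope="session")
def three_block_family():
    records, truth = make_family(
        [(4, 90.0, 20.0), (4, 90.0, 20.0), (3, 85.0, 20.0)], (340, 450), seed=21
    )
    return records, truth


@pytest.fixture(scope="session")
def tvg_genome(family_block5):
    """Genome with a hidden TVGG x4 precursor planted 200 bp past the
    cluster, plus its planted truth."""
    records, _ = family_block5
    genome, truth = make_genome(
        records[0],
        n_neighbors=4,
        precursor=TVG_PRECURSOR,
        hidden=True,
        flank_offset_bp=200,
        seed=3,
        min_orf_len_aa=12,
    )
    return genome, truth


@pytest.fixture()
def toy_genome():
    """Hand-built genome: 7 CDS features with stored translations."""
    seq = "A" * 4000
    prots = {
        "g1": "MAAAAAAAAAA",
        "g2": "MCCCCCCCCCC",
        "anchor": "MDDDDDDDDDD",
        "g4": "MEEEEEEEEEE",
        "g5": "MFFFFFFFFFF",
        "g6": "M" + "G" * 200,
        "g7": "MHHHHHHHHHH",
    }
    feats = []
    pos = 100
    for i, (fid, prot) in enumerate(prots.items()):
        length = 3 * (len(prot) + 1)
        feats.append(
            GeneFeature(
                feature_id=fid,
                start=pos,
                end=pos + length,
                strand="+" if i % 2 == 0 else "-",
                kind="CDS",
                product="radical SAM protein" if fid == "anchor" else "hypothetical",
                translation=prot,
            )
        )
        pos += length + 80
    return GenomeRecord(id="toy", sequence=seq, features=feats)


@pytest.fixture()
def protein(request):
    def _mk(pid, seq):
        return ProteinRecord(id=pid, sequence=seq)

    return _mk
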
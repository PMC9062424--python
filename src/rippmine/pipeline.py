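"""End-to-end orchestration: family FASTA + genomes -> SSN -> clusters ->
neighborhoods -> precursor candidates -> motif report; and peptide config +
observed m/z -> modification/localization report.

Everything is deterministic: the same config produces byte-identical
reports (no timestamps are written)."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import yaml

from rippmine import __version__, motifs as motif_mod, ms
from rippmine.formats_io import read_annotations, read_fasta, write_fasta, write_network
from rippmine.neighborhood import extract_neighborhood, find_anchors
from rippmine.precursor import find_annotated_peptides, pool_candidates, scan_flanks
from rippmine.ssn import SsnParams, build_ssn, cluster_ssn, select_analysis_clusters

logger = logging.getLogger("rippmine.pipeline")


class ConfigError(ValueError):
    """Missing or inconsistent run configuration (CLI exit code 2)."""


PROTOCOL_DEFAULTS = {
    "ssn": {"evalue_max": 1e-80, "pid_min": 40.0, "len_min": 340, "len_max": 450},
    "neighborhood": {"k": 10},
    "scan": {"window_bp": 1000, "min_len_aa": 20, "max_len_aa": 120},
    "select": {"min_nodes": 2, "min_sequences": 4, "max_rank": 118},
}


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return cfg


def _merged(cfg: dict, section: str) -> dict:
    out = dict(PROTOCOL_DEFAULTS.get(section, {}))
    out.update(cfg.get(section) or {})
    return out


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_mining(cfg: dict, out_dir=None) -> dict:
    """Run the full mining pipeline from a config mapping.

    Required keys: ``family_fasta``, ``genomes`` (list of GFF3/GenBank
    paths), ``out_dir`` (unless passed explicitly). Threshold sections
    ``ssn``, ``neighborhood``, ``scan``, ``select`` default to the protocol
    values (E <= 1e-80, identity >= 40%, lengths 340-450, k = 10,
    window = 1000 bp)."""
    family_fasta = cfg.get("family_fasta")
    genome_paths = cfg.get("genomes")
    out_dir = Path(out_dir or cfg.get("out_dir") or "")
    if not family_fasta or not Path(family_fasta).exists():
        raise ConfigError(f"family_fasta missing or absent: {family_fasta!r}")
    if not genome_paths:
        raise ConfigError("no genomes configured")
    genome_paths = sorted(str(p) for p in genome_paths)
    for p in genome_paths:
        if not Path(p).exists():
            raise ConfigError(f"genome file absent: {p}")
    if not str(out_dir):
        raise ConfigError("out_dir not configured")
    out_dir.mkdir(parents=True, exist_ok=True)

    ssn_cfg = _merged(cfg, "ssn")
    nb_cfg = _merged(cfg, "neighborhood")
    scan_cfg = _merged(cfg, "scan")
    select_cfg = _merged(cfg, "select")
    seed = int(cfg.get("seed", 0))

    log_lines: list[str] = []

    def log(stage: str, **kv) -> None:
        line = f"{stage}: " + " ".join(f"{k}={v}" for k, v in kv.items())
        logger.info(line)
        log_lines.append(line)

    family = read_fasta(family_fasta, molecule="protein")
    log("family", path=family_fasta, n_records=len(family))

    params = SsnParams(**ssn_cfg)
    graph = build_ssn(family, params)
    log(
        "ssn",
        evalue_max=params.evalue_max, pid_min=params.pid_min,
        len_min=params.len_min, len_max=params.len_max,
        nodes=len(graph.nodes), edges=len(graph.edges),
        filtered_out=len(family) - len(graph.nodes),
    )
    write_network(graph, out_dir / "network.tsv", dialect="edge-list")

    clusters = cluster_ssn(graph)
    selected = select_analysis_clusters(clusters, **select_cfg)
    log("clusters", total=len(clusters), selected=len(selected), **select_cfg)
    member_to_cluster = {m: c.cluster_id for c in clusters for m in c.member_ids}
    seq_to_member = {}
    for rec in family:
        seq_to_member.setdefault(rec.sequence, rec.id)

    with open(out_dir / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tsize\trepresentative\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.n_sequences}\t{c.representative_id}"
                f"\t{';'.join(c.member_ids)}\n"
            )

    # neighborhoods and candidates, grouped by SSN cluster
    per_cluster: dict[int, list] = {}
    nb_rows = []
    for gpath in genome_paths:
        dialect = "genbank" if gpath.endswith((".gb", ".gbk", ".genbank")) else "gff3+fasta"
        genome = read_annotations(gpath, dialect)
        anchors = find_anchors(genome, family)
        log("anchors", genome=genome.id, n=len(anchors))
        for anchor_id in anchors:
            nb = extract_neighborhood(genome, anchor_id, k=int(nb_cfg["k"]))
            translation = genome.translate_feature(nb.anchor)
            member = seq_to_member.get(translation)
            cid = member_to_cluster.get(member)
            if cid is None:
                continue
            for f in nb.context:
                nb_rows.append(
                    (cid, genome.id, f.feature_id, f.start, f.end, f.strand,
                     f.product, f.feature_id == anchor_id)
                )
            annotated = find_annotated_peptides(
                nb, genome,
                max_len=int(scan_cfg["max_len_aa"]),
                min_len=int(scan_cfg["min_len_aa"]),
            )
            orfs = scan_flanks(
                genome, nb,
                window_bp=int(scan_cfg["window_bp"]),
                min_len_aa=int(scan_cfg["min_len_aa"]),
                max_len_aa=int(scan_cfg["max_len_aa"]),
            )
            log(
                "scan", genome=genome.id, cluster=cid,
                window_bp=scan_cfg["window_bp"], annotated=len(annotated),
                orf_candidates=len(orfs),
            )
            per_cluster.setdefault(cid, []).append((genome, list(annotated) + list(orfs)))

    with open(out_dir / "neighborhoods.tsv", "w") as fh:
        fh.write("cluster_id\tgenome\tfeature_id\tstart\tend\tstrand\tproduct\tis_anchor\n")
        for row in sorted(nb_rows):
            fh.write("\t".join(str(x) for x in row) + "\n")

    # motif analysis per selected cluster
    selected_ids = [c.cluster_id for c in selected]
    all_candidates = []
    motif_rows = []
    report: dict = {"clusters": {}}
    for cid in selected_ids:
        pooled = pool_candidates(per_cluster.get(cid, []), cluster_id=cid)
        all_candidates.extend(pooled)
        if not pooled:
            report["clusters"][cid] = {"candidates": 0}
            continue
        ids = [c.candidate_id for c in pooled]
        peptides = [c.peptide for c in pooled]
        msa = (
            motif_mod.align_peptides(peptides, ids=ids) if len(peptides) >= 2 else None
        )
        repeat_hits = {
            i: motif_mod.find_tandem_repeats(p, peptide_id=i)
            for i, p in zip(ids, peptides)
        }
        pattern_hits = {
            i: [
                (pat.name, start, matched)
                for pat in motif_mod.default_patterns()
                for start, matched in motif_mod.match_pattern(p, pat)
            ]
            for i, p in zip(ids, peptides)
        }
        ranking = motif_mod.score_precursor(
            msa,
            repeat_hits,
            {i: [(s, m) for _, s, m in hits] for i, hits in pattern_hits.items()},
        )
        log("motifs", cluster=cid, candidates=len(pooled))
        for rank, (cand_id, score, evidence) in enumerate(ranking, start=1):
            for h in repeat_hits[cand_id]:
                motif_rows.append(
                    (cid, rank, cand_id, f"repeat:{h.unit}", h.start, h.copies, f"{score:.4f}")
                )
            for name, start, matched in pattern_hits[cand_id]:
                motif_rows.append(
                    (cid, rank, cand_id, f"pattern:{name}", start, matched, f"{score:.4f}")
                )
            if not repeat_hits[cand_id] and not pattern_hits[cand_id]:
                motif_rows.append((cid, rank, cand_id, "none", "", "", f"{score:.4f}"))
        report["clusters"][cid] = {
            "candidates": len(pooled),
            "ranking": [
                {"candidate": cand_id, "score": score, **evidence}
                for cand_id, score, evidence in ranking
            ],
            "consensus": msa.consensus if msa else None,
        }

    class _Named:
        def __init__(self, id_, sequence):
            self.id, self.sequence, self.description = id_, sequence, ""

    write_fasta(
        [_Named(f"cluster{c.cluster_id}|{c.candidate_id}", c.peptide) for c in all_candidates],
        out_dir / "candidates.fasta",
    )
    with open(out_dir / "motifs.tsv", "w") as fh:
        fh.write("cluster_id\trank\tcandidate\tmotif\tstart\tdetail\tscore\n")
        for row in motif_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": {
            "ssn": ssn_cfg, "neighborhood": nb_cfg,
            "scan": scan_cfg, "select": select_cfg,
        },
        "inputs": {
            "family_fasta": {"path": str(family_fasta), "sha256": _sha256(family_fasta)},
            "genomes": [{"path": p, "sha256": _sha256(p)} for p in genome_paths],
        },
        "counts": {
            "family_records": len(family),
            "ssn_nodes": len(graph.nodes),
            "ssn_edges": len(graph.edges),
            "clusters": len(clusters),
            "selected_clusters": len(selected),
            "candidates": len(all_candidates),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    report["manifest"] = manifest
    return report


# ---------------------------------------------------------------------------
# MS verification


def _peptide_from_config(cfg: dict) -> Optional[ms.Peptide]:
    if "sequence" not in cfg:
        return None
    labels = tuple(
        (int(pos), lab) for pos, lab in sorted((cfg.get("labels") or {}).items())
    )
    return ms.Peptide(
        residues=cfg["sequence"],
        c_terminus=cfg.get("c_terminus", "free_acid"),
        labels=labels,
        name=cfg.get("name", ""),
    )


def run_ms_verify(
    peptide_cfg: dict,
    observed: Sequence[float],
    match_tol_ppm: float = 10.0,
) -> dict:
    """Match observed precursor-ion m/z values against the predicted
    modification series and report Δppm errors and inferred ring counts.

    ``peptide_cfg`` must provide ``z`` and ``n_max`` and either ``base_mz``
    directly or a peptide definition (sequence, c_terminus, labels) from
    which the [M+zH]z+ m/z is computed."""
    if "z" not in peptide_cfg or "n_max" not in peptide_cfg:
        raise ConfigError("peptide config must set z and n_max")
    z = int(peptide_cfg["z"])
    n_max = int(peptide_cfg["n_max"])
    peptide = _peptide_from_config(peptide_cfg)
    if "base_mz" in peptide_cfg:
        base_mz = float(peptide_cfg["base_mz"])
    elif peptide is not None:
        base_mz = ms.mz(ms.monoisotopic_mass(peptide), z)
    else:
        raise ConfigError("peptide config needs base_mz or a sequence")

    series = ms.modification_series(base_mz, z, n_max)
    predictions = [
        {"n_mods": n, "predicted_mz": round(mz_n, 4)} for n, mz_n in enumerate(series)
    ]
    matches, unmatched = [], []
    inferred = set()
    for obs in observed:
        best = min(range(len(series)), key=lambda n: abs(obs - series[n]))
        trunc, full = ms.ppm_error(obs, series[best])
        if full <= match_tol_ppm:
            inferred.add(best)
            matches.append(
                {
                    "observed_mz": obs,
                    "n_mods": best,
                    "predicted_mz": round(series[best], 4),
                    "dppm": trunc,
                    "dppm_full": full,
                }
            )
        else:
            unmatched.append({"observed_mz": obs, "nearest_n": best, "dppm_full": full})
    return {
        "base_mz": base_mz,
        "z": z,
        "predictions": predictions,
        "matches": matches,
        "unmatched": unmatched,
        "inferred_mod_counts": sorted(inferred),
    }


def read_observed_mz(path) -> list[float]:
    """One m/z per line; blank lines and # comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if line:
            out.append(float(line))
    return out
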
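# rippmine

Offline genome mining for RiPP (ribosomally synthesized and
post-translationally modified peptide) pathways anchored on a radical-SAM
enzyme family, together with the mass-spectrometric arithmetic used to
verify a cyclopropane-ring (−2 Da per event) peptide modification.

The pipeline reproduces, as reusable library code, the classic mining
workflow:

1. **ssn** — all-vs-all Smith–Waterman (BLOSUM62, affine gaps 11/1) over a
   protein family; Karlin–Altschul E-values; edges thresholded at
   E ≤ 1e-80 and ≥ 40% identity with a 340–450 aa length filter; connected
   components ranked by size, medoid representatives, and a
   multiple-nodes/≥4-sequences selection rule capped at rank 118.
2. **neighborhood** — ±k (default 10) CDS gene context around an anchor
   gene located by exact translation match or product keyword.
3. **precursor** — annotated small CDS in the neighborhood plus a
   six-frame ORF scan (bacterial starts ATG/GTG/TTG) of the 1000 bp windows
   flanking the candidate cluster.
4. **motifs** — progressive multiple alignment with per-column
   conservation, maximal exact tandem-repeat detection (e.g. TVGG×4,
   (DC)×6), residue-class patterns (Aro-Xaa-Xaa-Asn with Aro = {W,Y},
   Tyr-Asn-Arg-Xaa-(His-Asn-Arg)₂, His-Xaa-Ser), and evidence-weighted
   candidate ranking.
5. **ms** — monoisotopic mass engine (elemental compositions, amidated
   C-termini, ¹³C₅/¹⁵N labels), [M+zH]ᶻ⁺ m/z, −2 Da modification series,
   truncated Δppm reporting, b/y/internal fragment ladders, and
   modification-site localization with a mixture (nonprocessivity) flag.
6. **assays** — Beer–Lambert conversions (ferrozine iron 562 nm,
   methylene-blue sulfide 670 nm, peptide A₂₈₀) and molar equivalents.
7. **synthetic** — generators for protein families with block-structured
   identity, genomes with planted (annotated or hidden) precursor ORFs in
   scrubbed flanks, and fragment ladders with planted ring sites — all
   seeded and with machine-readable ground truth for validation.

## CLI

```sh
rippmine simulate --out bundle/ --seed 7            # synthetic inputs + truth.json
rippmine ssn --family family.fasta --out net        # network + clusters
rippmine neighborhood --genome g.gff3 --anchor anchor --k 10
rippmine scan --genome g.gff3 --anchor anchor --window-bp 1000
rippmine motifs --peptides candidates.fasta
rippmine mine --config run.yaml                     # end-to-end
rippmine ms-verify --peptide-config pep.yaml --observed obs.txt
```

`mine` reads a YAML config (`family_fasta`, `genomes`, `out_dir`, optional
`ssn`/`neighborhood`/`scan`/`select` threshold sections; unset thresholds
default to the protocol values above) and writes `clusters.tsv`,
`network.tsv`, `neighborhoods.tsv`, `candidates.fasta`, `motifs.tsv`,
`manifest.json` (parameters + input hashes), and `run.log`. Runs are
deterministic: identical configs give byte-identical outputs. Exit code 2
signals a configuration error.

`ms-verify` takes a peptide config (either `base_mz` or a sequence with
terminus/labels, plus `z` and `n_max`) and a plain list of observed m/z
values, and reports the predicted modification series, matched ions with
truncated Δppm, and inferred modification counts.

## Layout

```
src/rippmine/
  formats_io.py   FASTA / GFF3 / GenBank / network I/O, coordinate conventions
  ssn.py          pairwise alignment, thresholding, clustering, selection
  neighborhood.py ±k gene context extraction, anchor location
  precursor.py    annotated peptide + flanking-window ORF discovery
  motifs.py       MSA, tandem repeats, residue-class patterns, scoring
  ms.py           masses, fragment ladders, Δppm, localization
  assays.py       Beer–Lambert / equivalents arithmetic
  synthetic.py    seeded fixture generators with planted truth
  pipeline.py     orchestration, config handling, manifests
  cli.py          click command group
tests/            unit + property tests, oracles.py (independent brute-force
                  checks), test_acceptance.py (one test per criterion)
```
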
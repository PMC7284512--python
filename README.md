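# liriopogon

Two-tier DNA-barcode identification for living collections of *Liriope* and
*Ophiopogon* ("Liriopogon") plants.

**Tier 1 (rbcL):** each query amplicon is aligned to the packaged rbcL
reference and its bases are read at a panel of 15 informative SNP positions.
A single G/A SNP at position 431 separates the two genera; the full
15-position haplotype (Types 1–6) assigns *Ophiopogon* accessions to species
or species groups by nearest-row Hamming match.

**Tier 2 (nrITS):** queries and labelled references are projected onto the
ITS reference frame, Kimura 2-parameter distances are computed with pairwise
deletion, and a neighbor-joining bootstrap majority-rule (≥50%) consensus
tree places each query in a labelled clade (Liriope-muscari, Liriope-spicata,
B2, B3a, B3b, jaburan-branch). Where tree placement cannot separate
*O. planiscapus* from *O. bodinieri*, a three-SNP ITS triplet (positions
46/231/545) decides, outranking tree placement on conflict.

A decision engine combines both tiers per accession, compares the result
against the (synonym-normalized) original label, and tallies collection-level
outcomes: confirmed, newly identified, species-level and genus-level
misidentifications.

A synthetic-data module generates seeded two-locus collections realizing any
panel haplotype and clade signature — including a packaged 73-accession
reconstruction of a national *Liriope*/*Ophiopogon* collection — so the full
pipeline is testable offline.

## CLI

```bash
# emit the packaged 73-accession synthetic collection
liriopogon simulate --seed 42 --collection --out-dir sim_out

# run the full verification pipeline
liriopogon -v verify \
    --rbcl sim_out/rbcl.fasta --its sim_out/its.fasta \
    --its-refs sim_out/its_references.fasta \
    --manifest sim_out/manifest.tsv \
    --out-dir verify_out --bootstrap 100 --seed 42

# panel structure / validation
liriopogon panel-validate

# ITS bootstrap consensus tree only
liriopogon tree --its sim_out/its.fasta --its-refs sim_out/its_references.fasta
```

`verify` writes `report.tsv`, `report.json` (with a tallies block), the
point-estimate NJ tree (`its_nj.nwk`) and the bootstrap consensus tree
(`its_consensus.nwk`, supports as internal-node labels). Missing loci degrade
gracefully: accessions present in only one FASTA are flagged single-locus.
A YAML config file (`--config`) can mirror the numeric flags; flags override
the file.

## Package layout

| module | contents |
| --- | --- |
| `liriopogon.panel` | haplotype panel + ITS triplet data structures, validation, consensus diffs |
| `liriopogon.seqio` | FASTA/manifest I/O, global affine-gap alignment, reference coordinate maps |
| `liriopogon.haplotyper` | SNP profile extraction, genus call, nearest-haplotype call |
| `liriopogon.phylogeny` | K2P, neighbor joining, bootstrap consensus, clade assignment, triplet |
| `liriopogon.decision` | label normalization, identification rule table, status, report |
| `liriopogon.synthetic_data` | seeded generators + packaged 73-accession truth manifest |
| `liriopogon.cli` | `verify` / `simulate` / `panel-validate` / `tree` subcommands |

Panel coordinates are 1-based positions in the packaged reference sequences
(`src/liriopogon/data/panel.json`); the rbcLa sub-region spans positions
1–540 of the rbcL reference. Truth-manifest rows carry `source=recorded`
(per-accession attested) or `source=reconstructed` (filled to match category
totals).
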
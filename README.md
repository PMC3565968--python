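# glycopipe

Analysis pipeline for shotgun N-glycoproteomics based on deglycosylated
(PNGase F–treated) peptide identifications:

- **sequon scanning** — enumerate putative N-glycosylation sites
  (N-X-S/T, X ≠ proline) in protein FASTA files;
- **glycosite mapping** — match deglycosylated peptides (N→D at formerly
  glycosylated asparagines) onto proteins, call sites, flag multi-sequon
  ambiguity, and apply identification filters (probability threshold,
  degenerate-protein grouping, single-hit removal, sequon-free removal);
- **quantification** — stoichiometry-normalized spectral counting
  (summed peptide spectra ÷ distinct detected glycosites), low/medium/high
  abundance tiers, and single-reference copies-per-cell calibration;
- **statistics** — per-protein sequon occupancy and set glycosylation
  rates, stoichiometry grouping with the low-TM/high-TM split,
  a Kyte–Doolittle sliding-window TM predictor (precomputed TM counts,
  including TMHMM short-format output, can be supplied instead),
  functional-class summaries and cross-species sequon/TM profiles;
- **comparison/enrichment** — overlap statistics (intersections,
  asymmetric percentages, Jaccard) and exact hypergeometric term
  enrichment with Benjamini–Hochberg correction;
- **synthetic data** — a fully deterministic generator of proteomes with
  planted TM segments, sequons, per-sequon occupancy and abundance-driven
  PSM tables, used as ground truth for every recovery test.

All coordinates are 1-based and inclusive on the protein sequence.

## CLI

The `glyco` entry point wires the stages together:

```sh
glyco scan     --fasta proteome.fasta --out sites.tsv --counts-out counts.tsv
glyco map      --fasta proteome.fasta --psms psms.tsv --min-prob 0.9 --out mapped.tsv
glyco quantify --fasta proteome.fasta --psms psms.tsv \
               --ref-accession Lifr --ref-copies 100 --out profiles.tsv
glyco stats    --profiles profiles.tsv --classes classes.tsv --tm tm.tsv --out statsdir/
glyco xspecies --orthologs groups.tsv --fasta-dir proteomes/ --out xspecies.tsv
glyco compare  --set A.txt --set B.txt [--set C.txt]
glyco enrich   --query q.txt --background bg.txt --annotations ann.tsv
glyco simulate proteome|psms|cohort --seed 1 --out simdir/
glyco run      --config run.cfg
```

PSM tables are TSVs with columns `peptide`, `proteins`
(semicolon-separated), `spectra` and optional `probability` (default 1.0).
Pipeline configs are flat INI files with `[input]`, `[filter]`, `[map]`,
`[quantify]`, `[simulate]` and `[output]` sections; every key has a CLI
override. Example:

```ini
[input]
fasta = proteome.fasta
psms = psms.tsv
[filter]
min_probability = 0.9
drop_single_hits = true
[output]
dir = out/
```

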
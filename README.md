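# hemoshotgun

Gene-model-aware shotgun proteomics identification and quantification:

- **Sequence databases** with protein → transcript → gene-model provenance,
  decoy construction by sequence reversal (or seeded shuffling), and
  identical-sequence partitioning (`hemoshotgun.db`).
- **In-silico tryptic digestion** — fully and semi-tryptic peptides, missed
  cleavages, Keil proline rule, monoisotopic masses with fixed
  carbamidomethyl and variable oxidation shifts (`hemoshotgun.digest`).
- **Peptide evidence classification** into six classes (1a, 1b, 2a, 2b,
  3a, 3b) by how unambiguously a peptide implies protein sequences,
  transcripts and gene models (`hemoshotgun.classify`).
- **Parsimonious protein inference**: unequivocal sequence identifications,
  gene-model groups, absorption of ambiguous peptides, exact/greedy
  minimal set cover for the remainder, and a minimum-PSM support rule
  (`hemoshotgun.infer`).
- **Target–decoy FDR** at spectrum, peptide and protein level, plus
  score-cutoff selection against a maximum PSM-level FDR
  (`hemoshotgun.fdr`).
- **Differential abundance** on spectral counts between two conditions:
  median-of-ratios size factors, local-regression dispersion fit, a
  two-sided NB conditional exact test, and top-decile calling with exact
  ±Inf log2 fold changes (`hemoshotgun.diffexp`).
- **Synthetic data**: block-structured gene models realizing every
  evidence class with known ground truth, and negative-binomial PSM
  simulation with decoy contamination (`hemoshotgun.simulate`).
- **Reports and orchestration**: condition-overlap (Venn) summaries,
  candidate-cytokine filtering of annotation tables, per-category
  unequivocal peptide tallies, and a deterministic end-to-end pipeline
  (`hemoshotgun.report`).

## CLI

```sh
# full synthetic end-to-end run (deterministic under --seed)
hemoshotgun run --seed 1 --out out/

# individual stages
hemoshotgun simulate --seed 1 --out sim/
hemoshotgun db --fasta targets.fasta --decoy-method reverse --out both.fasta
hemoshotgun digest --fasta both.fasta --max-missed 2 --semi --out peptides.tsv
hemoshotgun classify --db sim/db.fasta --psms sim/psms.tsv --out classified.tsv
hemoshotgun infer --db sim/db.fasta --classified classified.tsv --out groups.tsv
hemoshotgun fdr --db sim/db.fasta --classified classified.tsv --out fdr.tsv
hemoshotgun diffexp --counts counts.tsv --out results.tsv
hemoshotgun report --classified classified.tsv --out report.json
```

All tabular I/O is TSV with header rows; databases are FASTA with
`>protein_id gene=G transcript=T` headers. `run` writes every artifact
(database, PSMs, classified PSMs, groups, census, FDR report, counts,
differential-abundance and MA tables, overlap summary) plus a key-value
manifest, and two runs with the same seed are byte-identical.

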
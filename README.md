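# plastevo

Comparative analysis of plastid (chloroplast) protein-coding genes across a
set of related taxa.  Given per-gene coding sequences (or annotated GenBank
plastomes), a fixed tree topology, and a gene→ontology table, the pipeline
answers four questions a plastome comparative study asks:

1. **Which genes are pseudogenized or lost, and where?**  Each (gene,
   taxon) CDS is aligned to an intact reference and the first lesion —
   frameshift, premature stop codon, or truncating deletion — is located in
   reference-codon coordinates, yielding a shaded gene × taxon status
   matrix.
2. **How does the alignment vary along the genome?**  100-bp window tracks
   of GC content, gap proportion, and Fitch parsimony substitution counts
   on the fixed topology.
3. **How fast does each gene evolve, and under what selection?**  Per-gene
   maximum-likelihood rate scalers on the pseudogene-masked concatenation;
   gene-wide Kn/Ks (dN/dS) by the Nei–Gojobori counting method; two
   independent site-level selection detectors — a parsimony-based counting
   test and an empirical-Bayes (α, β) rate grid — combined by the
   conservative rule that a site counts as selected only when **both**
   methods flag it; plus a per-branch Kn/Ks screen.
4. **Do selected sites concentrate in particular functional groups?**
   Pairwise Fisher exact tests over seven gene ontologies
   (ATP synthesis, cytochrome/electron transport, *ndh*, photosynthesis,
   translation, transcription, other) with Holm–Bonferroni adjustment.

A first-class synthetic-data generator simulates codon evolution on a tree
under an MG94-style model (per-site ω classes, per-gene rate multipliers)
and injects known pseudogene lesions, so every stage is testable end-to-end
against ground truth without downloading anything.  See
[docs/methods.md](docs/methods.md) for models, parameters and design
decisions.

## Worked example

Simulate a small dataset with 8 planted lesions and run the full pipeline:

```bash
plastevo simulate --seed 5 --n-taxa 12 --n-genes 8 --n-lesions 8 --out data
plastevo all --mode fasta --input-dir data --tree data/tree.nwk \
             --ontology data/ontology.tsv --seed 5 --out run1
```

The non-intact rows of `run1/pseudogene_calls.tsv`:

```
gene   taxon  status      lesion_kind     first_lesion_codon  intact_fraction
atpA   t11    pseudogene  frameshift      228                 0.754153
atpB   t02    absent      truncation      1                   0.0
ndhA   t01    pseudogene  truncation      145                 0.426036
petA   t03    pseudogene  frameshift      73                  0.517986
psaA   t10    pseudogene  frameshift      154                 0.390306
rpoA   t10    pseudogene  premature_stop  152                 0.587549
rps2   t03    pseudogene  premature_stop  78                  0.244444
rps2   t06    absent      truncation      1                   0.0
```

All eight planted lesions are recovered: the two whole-gene deletions come
back as `absent`, the stop codons are located exactly (rpoA codon 152,
rps2 codon 78), and `intact_fraction` — the preserved fraction of the
reading frame — is what shades the status heatmap (`run1/status_matrix.tsv`).

`run1/gene_rates.tsv` gives each gene's rate scaler relative to the masked
concatenate (here all genes were simulated at rate 1, and the estimates sit
within a few percent of it):

```
gene   rate_scaler  relative_rate  parsimony_rate
atpA   0.9783       0.9737         1.1118
atpB   1.0431       1.0382         1.1667
matK   0.9971       0.9924         1.1635
```

`run1/gene_summary.tsv` is the per-gene selection table — alignment sites,
counting-test flags, EB-grid flags in both directions, the confirmed
(consensus) positions, and NG86 Kn/Ks:

```
gene   n_sites  methodA_sites  methodB_pos  methodB_neg  confirmed_positions  kn_ks
atpA   301      0              1            230                               0.447
atpB   190      0              12           158                               0.409
matK   106      1              4            90           28                   0.376
```

With the default simulation mixture (75% of sites at ω = 0.3) most sites
are detected as purifying (`methodB_neg`), Kn/Ks sits well below 1, and the
two-method consensus flags only strongly supported sites (here one site in
*matK*).  `run1/report.json` records per-stage counts and the config hash;
re-running the same command reproduces every table byte-for-byte.

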
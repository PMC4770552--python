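# nirktools

Sequence classification and pathway-inventory analysis for copper-containing
nitrite reductase (NirK), the enzyme catalysing the defining step of
denitrification (NO2− → NO). Full-length NirK proteins fall into two
phylogenetically distinct clades: Clade II carries two diagnostic ~7-aa
deletions, coinciding with the linker and tower loops, that Clade I lacks,
alongside a characteristic active-site motif shift (TRPHL-type → SSFHV-type
around the active-site His237). `nirktools` is aimed at microbial ecologists
and comparative genomicists who need to (i) validate and clade-type candidate
NirK sequences, (ii) quantify why degenerate *nirK* PCR primers miss most
Clade II organisms, and (iii) classify genome gene inventories into
denitrification / DNRA (dissimilatory nitrate reduction to ammonium)
pathway categories.

## What it computes

* **Residue validation and clade typing** — each candidate protein is
  globally aligned (affine-gap Needleman–Wunsch, BLOSUM62) to a 375-aa
  reference NirK and checked for the seven copper-ligand residues (His59,
  His64, His99, Cys100, His110, Met115, His298) and two active-site residues
  (Asp62, His237) in reference numbering. Clade II is called when both the
  linker and tower 7-aa deletion regions are present; 5-mer motifs around
  His237 and Asp62, terminal-extension domains (c-type heme C-X2-C-H-X50-M,
  cupredoxin C-X4-H-X4-M) and per-genome copy counts are reported alongside.
* **Phylogeny** — neighbour joining on amino-acid "number of differences"
  distances with complete deletion (every gapped column removed), with
  column-bootstrap support on internal edges.
* **Primer coverage** — IUPAC-degenerate binding-site search (mismatch =
  disjoint base sets), per-clade per-position mismatch profiles, sequence
  logos (information content in bits) of binding regions, and in-silico PCR
  under a mismatch budget with an optional clean-3′ requirement.
* **Pathway inventories** — genomes with a nitrite reductase are classified
  by nor/nosZ presence into complete / −nor / −nos / −nor−nos
  denitrification categories and by nrfA/nirB (paired with napA/narG) into
  non-exclusive DNRA labels; gene pairs are screened for non-random
  co-occurrence with the exact hypergeometric model plus the phi
  coefficient, Benjamini–Hochberg corrected.
* **Synthetic data** — a generator plants all of the above structure
  (clades, motifs, indels, extensions, primer-site mismatches, gene
  inventories with exact pairwise odds ratios) with full truth tables, so
  the whole pipeline is testable without downloads.

## Worked example

Run the numbered drivers from the repository root (each writes its tables
under `results/pipeline/`):

```sh
python analysis/01_simulate.py
python analysis/02_classify.py
python analysis/03_phylogeny.py
python analysis/04_primers.py
python analysis/05_inventory.py
```

`01` generates 60 synthetic NirK sequences (30 per clade, 4 Bacillus-type,
8 % substitution noise) plus a 249-genome inventory. `02` then reports:

```
validated NirK: 60/60
clade recovery vs truth: 100.0 %
His237 motif recovery: 100.0 %
mean pairwise identity, overall: 85.5 %
```

— every sequence passes the nine residue rules and the indel-based clade
caller matches the generator's truth exactly; identity is high because the
synthetic cohort shares one backbone. `04` recovers the clade-biased primer
mismatches planted at positions 1, 5, 12 and 17:

```
II    0.30  0.0  0.00  0.0  0.23  ...  0.27  0.0  0.0  0.0  0.0  0.43
largest Clade II excess at primer position 17 (+0.43 over Clade I)
```

— Clade I binds almost perfectly while a third of Clade II sequences
mismatch at the 3′-terminal position, the classic clade-biased coverage
failure. `05` summarises the simulated inventory and the gene screen:

```
simulated cohort: 249 genomes, 24.5 % complete denitrifiers, 66.3 % with
combined denitrification+DNRA, 4.4 % multi-copy
narG-nrfA: phi = -0.18, p_lt = 0.0023, q_BH = 0.028 (significant)
survey-table rebuild: Total combined = 66.7 % over 249 genomes
```

— the planted narG–nrfA avoidance (odds ratio 0.2) is detected as a
significant negative phi, and rebuilding a cohort from the published
per-phylum summary percentages reproduces the printed 66.7 % total of
genomes carrying both pathways.

The same stages are available as a CLI over a single YAML config:

```sh
nirktools run-all --config analysis/config.yaml --outdir results/pipeline
```

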
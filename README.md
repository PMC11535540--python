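# ladscreen

Statistics and pipeline code for finding regulators of gene expression in
**lamina-associated domains (LADs)** — the large, nuclear-lamina-contacting
chromatin domains in which most genes are repressed. The package implements
the computational stages of a reporter-based search for such regulators in
human cells, and a synthetic-data generator that lets every stage run, and
be tested, without any sequencing data:

1. **Gene-trap screen scoring** (`screen_stats`). A haploid insertional
   screen sorts mutagenized cells into HIGH and LOW reporter-expression
   pools and maps gene-trap integrations in each. For gene *g* with *a*
   unique sense (disruptive) insertions in HIGH and *b* in LOW, out of pool
   totals *T<sub>H</sub>* and *T<sub>L</sub>*, the **mutational index** is
   the normalized odds ratio

   MI(g) = [ a / (T<sub>H</sub> − a) ] / [ b / (T<sub>L</sub> − b) ]

   MI > 1 flags a putative repressor of the reporter, MI < 1 a putative
   activator. Significance per gene is a two-sided Fisher's exact test on
   [[a, T<sub>H</sub>−a], [b, T<sub>L</sub>−b]], Benjamini–Hochberg-adjusted
   across testable genes (*fcpv*). Sense insertions are counted from the
   TSS through the stop codon of each gene's longest-ORF transcript, after
   excluding base pairs claimed by more than one gene.

2. **LAD gene annotation** (`lad_annotation`). A gene's NL-association
   score is the overlap-weighted mean of a DamID log₂-ratio track over the
   gene body ± 10 kb; genes with score > 0 are LAD genes. The same
   machinery scores promoter windows (TSS ± 500 bp), per-gene signal
   changes between conditions, and gain/loss of the most proximal peak.

3. **Expression-matched differential response** (`differential_response`).
   Given a DE table, inactive genes (control TPM < 0.3) are dropped, genes
   are classified up/down at adjusted p < 0.05, and an iLAD control set is
   drawn to match the LAD expression distribution by walking the TPM-sorted
   gene list in blocks of 20 and sampling, per block, as many iLAD genes as
   there are LAD genes. Up/down proportions are contrasted with Fisher's
   exact test; log₂FC location and spread with rank-sum and Levene tests.

4. **TRIP barcode analysis** (`trip_analysis`). Barcoded reporters
   integrated throughout the genome are quantified in gDNA and cDNA;
   expression per barcode is the cDNA share divided by the gDNA share
   (barcodes with gDNA ≤ 100 in any sample are discarded), knockdown
   effects are per-barcode log₂ fold changes, and LAD vs iLAD integrations
   are contrasted with a rank-sum test.

The synthetic generator (`synthetic_data`) plants known effects — per-gene
HIGH/LOW odds θ, LAD intervals under a two-level Gaussian track, stratified
response fractions over a realistic LAD-depressed expression mixture, and a
log₂ knockdown shift on LAD barcodes — so every claim the pipeline makes
can be checked against ground truth.

Intended users: computational biologists re-analyzing insertional screens
or LAD-related perturbation data, and method developers who need a fully
synthetic, deterministic testbed for these analyses.

## Worked example

The `analysis/` scripts run the whole story at screen scale (seed 1):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_score_screen.py
python analysis/03_annotate_lads.py
python analysis/04_differential_response.py
python analysis/05_trip_contrast.py
```

which prints, among other lines:

```
screen: 633227 HIGH / 634180 LOW unique insertions, 2000 genes (50 planted repressors, 50 activators)
2000 genes tested; 103 hits at fcpv < 0.05 (51 repressors, 52 activators)
recovery of 100 planted effects: sensitivity 1.00, FDR 0.029
2000 genes scored; 636 called LAD
midpoint-in-LAD agreement: 99.9% (disagreements sit at LAD borders, where the +/-10 kb flank mixes signal)
LAD: 170 genes, 18.2% up, 8.2% down
matched-iLAD: 169 genes, 6.5% up, 8.9% down
Fisher p (up) = 1.49e-03, (down) = 8.49e-01; rank-sum p = 8.82e-02, Levene p = 5.45e-02
570/600 barcodes pass the gDNA filter (191 LAD, 379 iLAD)
LAD - iLAD mean log2FC = 0.510 (planted knockdown effect 0.5), rank-sum p = 4.33e-31
mean control replicate rank correlation rho = 0.678
```

Reading this: the screen recovers all 100 planted regulators with ~3%
false discoveries and essentially no hits among the 1,900 neutral genes;
gene-level LAD calls agree with the planted domains except at borders;
after expression matching, upregulation upon the simulated perturbation is
about three times more frequent among LAD genes than among equally
expressed iLAD genes (Fisher p ≈ 1.5 × 10⁻³); and the TRIP contrast
recovers the planted 0.5 log₂ knockdown effect to within 0.01.

The same pipeline is available as one deterministic command:

```bash
ladscreen run-all --seed 1 --outdir out/      # demo scale, byte-reproducible
ladscreen --help                              # individual subcommands
```

## Layout

```
src/ladscreen/       library: formats_io, synthetic_data, screen_stats,
                     lad_annotation, differential_response, trip_analysis,
                     benchmarks, cli
analysis/            numbered narrative drivers over the library
scripts/acceptance.py
docs/methods.md      models, conventions, parameter choices, limitations
tests/               pytest suite incl. statistical acceptance checks
```
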
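# phylokaryo

Diagnostic-polymorphism discovery and phylogenomic karyotype painting
for genomes admixed between two ancestral taxa.

Cultivated citrus — mandarins, tangors, tangelos, orangelos,
grapefruits — are largely mosaics of two ancestral gene pools,
*C. reticulata* (RET) and *C. maxima* (MAX).  Given a biallelic
genotype matrix (VCF or TSV) over reference accessions of both taxa
plus admixed query varieties, `phylokaryo`:

1. **filters** calls and loci (read depth < 5 → missing; > 50% missing
   or MAF < 0.05 dropped; < 30% missing required among the references);
2. **detects and masks introgressions** in the reference accessions
   themselves, from moving-average heterozygosity (120-marker windows,
   step 40; flag above Ho = 0.40) and similarity to the two taxon
   centroids (60-marker windows, step 20, on loci with first-pass
   G_ST > 0.5; flag when the other taxon's centroid is at least as
   close as the own);
3. **selects diagnostic polymorphisms (DPs)**: loci whose inter-taxon
   differentiation on the masked references reaches Nei's
   G_ST = (He_tot − (He_ret + He_max)/2)/He_tot ≥ 0.9,
   oriented by per-taxon major alleles;
4. **paints karyotypes**: successive 20-DP windows are called RET/RET,
   MAX/MAX or RET/MAX when the best configuration outnumbers the
   runner-up ≥ 2-fold (undetermined otherwise), merged into segments,
   with genome-wide admixture prop_max = (2·n_max_hom + n_het)/(2·n_scored).

A first-class synthetic-data module generates ancestral gene pools,
reference panels (optionally with planted introgressions) and admixed
mosaic genomes (F1, BC(n), arbitrary blocks) with full ground truth, so
every stage is testable without external data.  See `docs/methods.md`
for the estimators, conventions and design choices.

## Worked example

`examples/` holds one short script per capability.  End to end
(`python examples/04_karyotype_painting.py`), on a simulated dataset of
2 chromosomes × 1,500 loci, 11 + 6 references and three queries — a
two-block mosaic, an F1 and a pure MAX accession — with 12.6% missing
calls:

```
diagnostic panel: 947 polymorphisms (of 2783 QC-passed loci)

karyotype segments (state over successive 20-DP windows):
  sample chrom  bp_start   bp_end   state  n_windows
  mosaic     1     49445  9066366 RET/RET          6
  mosaic     1   9099903 10808214   UNDET          1
  mosaic     1  10816604 22280898 MAX/MAX         10
  mosaic     1  22433446 29978503 RET/RET          7
  mosaic     2     36256  8823217 RET/MAX          6
  mosaic     2   8880272 29161249 RET/RET         17
  ...

genome-wide admixture:
  mosaic: estimated MAX fraction 0.285 (truth 0.275, 822 DPs scored)
  f1: estimated MAX fraction 0.498 (truth 0.500, 812 DPs scored)
  pure_max: estimated MAX fraction 0.993 (truth 1.000, 838 DPs scored)
```

The painted MAX/MAX block on chromosome 1 recovers the planted
10–22 Mb homozygous introgression (window resolution ≈ 0.5 Mb here);
the F1 paints RET/MAX along its whole genome with half-and-half
admixture.

The same stages are available from the shell:

```sh
phylokaryo simulate --outdir sim --seed 5
phylokaryo discover --genotypes sim/genotypes.tsv --panel sim/panel.tsv --outdir disc
phylokaryo paint    --genotypes sim/genotypes.tsv --panel sim/panel.tsv \
                    --dp-panel disc/diagnostic_panel.tsv --outdir paint --plot
phylokaryo dissim   --genotypes sim/genotypes.tsv --out dissim.tsv
```

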
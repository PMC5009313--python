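# arraybsa

Marker discovery by **bulked segregant analysis (BSA) on subtracted-gDNA
diversity arrays**, built for the strawberry day-neutrality use case but
applicable to any microarray whose printed features are trait-enriched
genomic fragments hybridized with contrasting DNA bulks.

In BSA, the DNA of progeny sharing a phenotype is pooled into bulks
(here: strong/intermediate/weak day-neutral `DN1`/`DN2`/`DN3` versus
short-day `SD`), so that only loci linked to the trait differ between
bulks.  Each bulk is hybridized to a subtracted diversity array and the
per-feature signal-to-noise ratios (SNR) are compared between bulks.
A feature is called a putative trait-linked marker when **three
statistics agree**:

1. **Stepwise discriminant function analysis (DFA)** with Wilks' lambda
   Λ = det(W)/det(T) as the selection criterion (entry p < 0.05,
   removal p > 0.10), validated by a reciprocal biological-replicate
   train/test split using Fisher's linear classification functions;
2. **Fisher's ratio** ranking, F = (M₁ − M₂)² / (V₁ + V₂) per feature
   (top 10 per comparison);
3. **Independent-samples t-tests** (pooled or Welch, resolved by
   Levene's test) at p < 0.05.

The triple intersection of the three feature sets, per three-way Venn
partition, is the marker call.  A genome-context module annotates a
marker locus with genes inside a genetic window (base pairs per
centiMorgan derived from a 100 cM-per-chromosome assumption), and a
synthetic-data module emulates the whole experiment — an F1 population
under an allele-dosage model, bulks, and log-normal array signals with
one planted marker — so the pipeline can be exercised and validated
without the original slides.

## Worked example

Simulate a study (287 subtracted features plus controls, 4 bulks × 2
biological × 6 technical replicates, one planted marker whose expected
DN1/SD fingerprint ratio is 3) and run the full pipeline:

```sh
arraybsa simulate --seed 7 --out run7
arraybsa run --input run7 --out run7/results
```

which prints, for seed 7:

```
simulated run written to run7
planted marker: FS001
...
putative markers: FS001, FS254
```

The planted feature `FS001` is recovered in the triple intersection
(together with chance co-selections; see `docs/methods.md` on the
false-positive behaviour of stepwise selection at 287 candidate features
and 24 cases).  `run7/results/` contains the QC report, the per-bulk
fingerprint matrix, one statistics table per comparison (group means and
SDs, Fisher's ratio, t, df, p, test variant), the DFA report with the
Wilks'-lambda trace and per-direction accuracies, the Venn partition and
the marker report, plus the resolved configuration for the audit trail.

The same analysis is available as a library:

```python
from arraybsa import simulate_study, analyze_matrix

study = simulate_study(seed=7)
result = analyze_matrix(study.matrix)
print(result.report.marker_ids)          # ['FS001', 'FS254']
print(study.truth.planted_feature)       # 'FS001'
```

Annotate a marker locus with genes within 5 cM:

```sh
arraybsa annotate --gff genes.gff3 --chrom-lengths lengths.tsv \
    --chromosome LG6 --start 14315954 --end 14316207 --cm 5
```

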
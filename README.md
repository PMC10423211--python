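# chtii

Detection of potential immunosuppressive **clonal hematopoietic (CH)
mutations in tumor-infiltrating immune (TII) cells** from matched
tumor/normal-blood somatic variant calls.

## The problem

Clonal hematopoiesis lets somatic mutations accumulate in an expanding
clone of blood cells; when those cells infiltrate a tumor, their mutations
show up in the tumor sample too. A variant that is somatic, present at a
clonal-but-not-germline allele fraction **in both the blood and the tumor
sample**, recurrent across a cohort, rare in the population, predicted
deleterious, and in a gene expressed by immune cells is a candidate
*immunosuppressive* CH mutation in TII cells — it cannot drive tumor growth,
but it may blunt the anti-tumor immune response.

`chtii` implements this selection as a four-stage funnel over a MAF-dialect
variant table plus supporting annotation, single-cell and bulk-expression
inputs:

1. **Protein-altering selection** — keep missense, nonsense, frameshift,
   in-frame indel and splice-site calls that pass the caller quality gate
   (LOD ≥ 4.0, base quality ≥ 10).
2. **CH-in-TII window** — keep variants with VAF strictly between 2% and
   25% in *both* samples, where VAF = alt/(ref+alt); the 2% floor is the
   accepted clonal-hematopoiesis threshold and the 25% ceiling excludes
   heterozygous germline variants. Wilson binomial confidence intervals
   quantify VAF uncertainty at each depth.
3. **Non-passenger filters** — cohort recurrence (sample fraction > 5%),
   population rarity (gnomAD-style frequency < 10⁻⁴), exclusion of
   hypermutable immune gene families (IG/TR/HLA/KIR/LILR), deleteriousness
   consensus (SIFT *and* PolyPhen agree, or the variant is truncating), and
   expression of the gene in ≥ 1 tumor-infiltrating immune cell
   (single-cell raw count > 0).
4. **Differential expression** — per candidate, a two-sided Welch *t* test
   with Satterthwaite degrees of freedom compares bulk expression between
   carrier and non-carrier samples; Benjamini–Hochberg adjustment flags SDE
   genes (q < 0.05), which are tabulated against top-level pathways.

A first-class synthetic cohort generator (`chtii.simulate_cohort`) emits
all six input tables with planted ground truth — true CH variants, germline
and sub-threshold noise variants, and passenger somatics each built to fail
exactly one named filter — so the entire funnel is testable without any
protected data.

## Worked example

```python
import chtii

cohort = chtii.simulate_cohort(chtii.well_separated_config(seed=1))
result = chtii.run_pipeline_on_cohort(cohort)
for s in result.funnel.to_records():
    print(f"{s['name']:<24}{s['input_count']:>6}{s['output_count']:>6}"
          f"  {s['percent_of_previous']}")
print(sorted(result.candidates['variant_id']) ==
      sorted(cohort.ground_truth.planted_ch_ids()))
```

prints

```
quality_gate_rows         3941  3509  89.0
distinct_variants           28    28  100.0
protein_altering            28    28  100.0
ch_in_tii                   28    13  46.4
sample_fraction             13    12  92.3
population_rarity           12    11  91.7
hypermutable_exclusion      11    10  90.9
deleterious_consensus       10     9  90.0
immune_expression            9     8  88.9
True
```

The quality gate drops the low-quality noise calls; the VAF window removes
germline (VAF ≈ 0.5) and sub-2% variants; each of the five planted
passenger somatics falls at exactly its named filter stage; and the eight
surviving candidates are exactly the eight planted CH-in-TII variants
(`True`). `result.candidates` carries per-candidate VAF mean ± SD, sample
fraction, population frequency, immune expression counts and SDE-gene
counts; `result.pathway_counts` is the pathways × candidates table.

The same flow is available from a shell:

```sh
chtii simulate --config sim.yaml --out bundle/
chtii run-bundle --bundle bundle/ --out out/
chtii report --in out/
```

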
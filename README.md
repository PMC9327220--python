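# machkit

Convert MaCH/minimac imputed dosage filesets into PLINK-compatible filesets.

Large cohort studies distributed through dbGaP (for example the Women's
Health Initiative) ship pre-imputed genotypes as MaCH/minimac `mldose` +
`mlinfo` file pairs, one per chromosome, with each chromosome's samples
sharded across *consent groups*. None of the mainstream GWAS tools consume
that format directly. `machkit` takes those filesets all the way to
analysis-ready PLINK filesets:

1. **convert-mac** — recombine consent groups per chromosome, run a
   structural QC check, transpose the sample-major dosage matrix to the
   SNP-major `pdat`/`pfam` form, concatenate chromosomes genome-wide, then
   emit (a) a hard-called PLINK1 `bed`/`bim`/`fam` fileset and (b) a
   dosage-preserving VCF with a `GT:DS` FORMAT.
2. **correct-files** — restore the chromosome and base-pair position
   metadata lost in conversion (recovered from `chr:pos` variant IDs) and
   optionally fill in sample sex from a `FID IID SEX` table.
3. **combine-datasets** — intersect the SNPs of two or more harmonized
   filesets and merge their samples into one fileset.
4. **synth** — generate conformant multi-chromosome, multi-group synthetic
   filesets with known ground truth, so the whole pipeline is testable
   without access-controlled data.

## The core transformations

A **dosage** d ∈ [0, 2] is the imputed expected count of allele *Al1* for
one individual at one SNP. The mldose file is sample-major (row =
individual: ID token, mode token, then one dosage per SNP); the mlinfo file
lists the SNPs (name, alleles, Freq1, MAF, Quality, Rsq) under one header
line. For n SNPs the combined pair must satisfy the structural identity

    dose columns  =  info lines + 1        (n + 2 = (n + 1) + 1)

which is the QC check run on every chromosome after group combination.

**Hard call** at threshold t < 0.5: with r the nearest integer in {0, 1, 2},

    genotype(d) = r        if |d − r| ≤ t        (2 → hom Al1, 1 → het, 0 → hom Al2)
                  missing  otherwise

(default t = 0.1, the PLINK convention; boundary inclusive). Hard calls go
into the PLINK1 binary fileset, which retains dosages only to 2 decimal
places on its text dosage path; the VCF `DS` field preserves them to ~4
decimal places (max round-trip error ≤ 5×10⁻⁵).

## Worked example

```sh
machkit synth --out demo/in --seed 1 --noise-sd 0.05
# wrote 4 dose + 2 info files under demo/in

machkit convert-mac \
    --dose-dir demo/in/group1 --info-dir demo/in/info \
    --dose-dir demo/in/group2 --info-dir demo/in/info \
    --project whi_demo --out demo/out
# wrote demo/out/whi_demo.pdat, demo/out/whi_demo.bed, demo/out/whi_demo.dose.vcf.gz

machkit correct-files --bfile demo/out/whi_demo --out demo/corrected
# variants examined:   10
# chrom/pos corrected: 10
# already correct:     0
# unparseable IDs:     0
```

The generated study has 8 samples split across 2 consent groups and 5 SNPs
on each of 2 chromosomes. The QC report (`demo/out/whi_demo.qc.txt`) shows
the structural identity holding on each chromosome — 6 info lines (header +
5 SNPs) against 7 dose columns (ID + mode + 5 dosages):

```
info lines (incl. header): 6
dose columns:              7
expected dose columns:     info lines + 1 = 7
result: PASS
```

The genome-wide `whi_demo.pdat` is the SNP-major transposition, one row per
SNP with 2-decimal dosages:

```
SNP A1 A2 F0000->I0000 F0001->I0001 F0002->I0002 ...
1:2 A T 1.05 1.01 0.01 0.99 0.98 1.01 0.97 0.01
1:22 G T 2.00 0.00 2.00 0.96 1.93 1.92 2.00 1.00
```

and after `correct-files` the bim carries real chromosome/position values
recovered from the `chr:pos` IDs (they are written as 0 by the conversion):

```
1	1:2	0.0	2	A	T
1	1:22	0.0	22	G	T
```

Merging two harmonized studies:

```sh
machkit combine-datasets --bfile studyA/corrected --bfile studyB/corrected \
    --project merged --out merged/
```

writes `merged/merged.bed/.bim/.fam`, the common-SNP list (one ID per line,
usable with PLINK `--extract`) and a merge report.

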
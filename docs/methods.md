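# Methods

## File semantics and the structural QC identity

An mldose file is a whitespace-delimited sample-major matrix: one row per
individual holding the sample-ID token (`FID->IID`; tokens without the
separator are used for both fields, and a token with several separators
splits at the first), a mode token (`ML_DOSE` or `DOSE`, preserved
verbatim), and one dosage per SNP. The companion mlinfo file has one header
line and one row per SNP. All readers sniff the two gzip magic bytes rather
than trusting extensions, accept runs of spaces/tabs and CRLF line ends, and
map the tokens `NA`, `-9`, `.`, `-` to missing.

Because the dose row adds exactly two non-dosage columns (ID and mode) while
the info file adds exactly one non-SNP line (the header), a combined
(dose, info) pair for n SNPs must satisfy *dose columns = info lines + 1*.
This identity is the per-chromosome QC check; the column count is taken from
the first data row and verified constant across rows (a ragged file yields a
failed report naming the offending row, not an exception, so the report can
be inspected).

Dosages are interpreted as the expected count of allele **Al1** (the MaCH
convention; the format itself does not label the counted allele). A1/A2
orientation is carried through unchanged everywhere — no minor-allele
re-ordering is ever applied, so outputs are deterministic and independent of
sample frequencies.

## Consent-group combination

Group dose files are concatenated row-wise in the order given; the combined
info file is the first group's. Two failure modes that would silently
corrupt data are checked loudly: all groups' info files must list the
identical SNPs (name, order, alleles) — a column-wise misalignment would
scramble every downstream dosage — and sample IDs must be unique across
groups. Likewise, genome-wide concatenation of the per-chromosome SNP-major
tables verifies that every chromosome carries the identical sample roster
rather than assuming it, since reusing a single pfam file presumes it.

## Hard calling

With threshold t ∈ [0, 0.5) and r the nearest integer in {0, 1, 2}, a dosage
is called r when |d − r| ≤ t and set missing otherwise; missing input stays
missing. The boundary is inclusive, with an absolute slack of 1e-9 so that
decimal boundary values (e.g. 1.9 at t = 0.1, whose binary representation
puts |d − r| a hair above 0.1) are kept. Default t = 0.1 follows the common
PLINK hard-call convention. Two consequences are load-bearing for the tests:
integer dosages are lossless at any t > 0, and the missing count is
monotonically non-increasing in t.

## PLINK1 binary encoding

`.bed` output is SNP-major: three magic bytes `6C 1B 01`, then per variant
ceil(n/4) bytes with sample k in bits (2k mod 8)..(2k mod 8)+1 of byte
floor(k/4), encoding 00 = hom A1, 01 = missing, 10 = het, 11 = hom A2; pad
bits are zero. Packing and unpacking are vectorised numpy shift/mask
operations; tests cross-check them against an independent
`numpy.unpackbits` decoder and a hand-derived byte fixture. Sample-major
(mode byte 0x00) files are refused rather than transposed.

Conversion writes chromosome 0 / position 0 into the bim — the dosage
formats carry positions only inside the `chr:pos` variant name — and the
correction stage restores both by parsing IDs of shape `chr:pos` or
`chr:pos:ref:alt` with chromosome codes 1–22, X, Y, XY, MT. IDs that do not
match (rs numbers) are counted and left untouched, never guessed. The
operation is idempotent and never alters record count, order or alleles.

## The dosage-preserving VCF

PLINK1's text dosage path keeps 2 decimal places, so a second output path
preserves the dosages: a VCFv4.2 file with REF = A2, ALT = A1 and per-sample
`GT:DS`, DS being the allele-A1 (= ALT) dosage written with 4 fixed decimal
places (round-trip error ≤ 5×10⁻⁵) and GT the hard call (`./.` when
missing). Records sort by (chromosome, position); unparseable IDs get
CHROM `.` / POS 0, a warning, and sort last. The record text is produced by
the package itself because the fixed-decimal DS formatting is part of the
output contract; compression is BGZF (via pysam) so indexed tools accept the
file, and tests read it back through pysam's VCF reader.

## Merging

Merging is restricted to already-harmonized PLINK1 filesets. The variant
intersection keeps first-dataset order; an empty intersection is refused
explicitly. Every common SNP must agree on chromosome, position and the
(A1, A2) pair with identical orientation — an A1/A2 swap is *not* repaired
by flipping and complementing, because silent flips on pre-harmonized data
hide genuine strand or naming errors; it is reported as a harmonization
error for the user to resolve. Sample rosters must be disjoint; genotype
blocks are copied with no recoding, so extracting one input's samples from
the merge reproduces that input restricted to the common SNPs exactly.
Chrom/pos correction is applied to each input before intersecting, since
merge inputs typically come straight from conversion.

## Synthetic data generator

Per SNP j and sample i: allele-1 frequency f_j ~ Uniform(0.05, 0.95), true
genotype g_ij ~ Binomial(2, f_j), dosage d_ij = clip(g_ij + N(0, σ), 0, 2).
Defaults: 8 samples, 5 SNPs per chromosome, 2 chromosomes, 2 consent groups,
σ = 0.05, seed 1. The frequency bounds avoid monomorphic SNPs; σ = 0.05 is a
mild imputation-uncertainty level at which hard calls at t = 0.1 are lost at
a rate near 2·(1 − Φ(t/σ)) ≈ 4.6%, shrunk by clipping at the 0/2 edges (the
observed rate on generated data sits around 3%). The truncated-Gaussian
noise model was chosen for this analytic tractability; it does not emulate
LD structure, population stratification, realistic MAF spectra or
systematically varying imputation quality, so passing tests demonstrate
format and arithmetic correctness, not robustness to those features of real
cohorts. Positions are drawn without replacement from 1..10·m per
chromosome and sorted, guaranteeing unique, increasing `chr:pos` names;
mlinfo Freq1/MAF are computed from the generated dosages while Quality and
Rsq are drawn Uniform(0.3, 1) as plausible metrics. Everything derives from
one `numpy.random.default_rng(seed)` stream, so identical calls write
byte-identical files.

## Numerical and design choices

* Dosage text is written with fixed decimals (pdat default 2, matching what
  PLINK1's dosage path retains; mldose and VCF DS default 4); the
  corresponding round-trip bound is 0.5·10⁻ᵈ.
* Dosages outside [0, 2] by more than 1e-6 are format errors; within the
  tolerance they are accepted as float-formatting noise.
* mlinfo columns are matched by position against the MaCH header
  (`SNP Al1 Al2 Freq1 MAF Quality Rsq`); an unexpected header warns but
  parses, so minimac variants with extra trailing columns work.
* Chromosomes process in natural order 1..22 (then X, Y when requested);
  `--chroms auto` detects which chromosomes have files.
* Empty inputs degrade gracefully: a 0-sample dose block writes an empty
  file, a 0-variant fileset writes a 3-byte (magic-only) `.bed`.
* All conversion stages are deterministic; randomness exists only in the
  generator, controlled by its seed.

## Problem sizes used in checks

The test-suite and acceptance measurements run at desk scale, chosen to
exercise every code path while completing in seconds: the structural QC
check on the default 8×(2×5) two-group study; precision bounds on a
100-sample × 200-SNP random dosage table (20 000 cells); genotype-recovery
rates on a 40-sample × 100-SNP two-chromosome study, exact at σ = 0 and
compared against a direct file-level recomputation at σ = 0.05. The
streaming mldose reader means nothing in the design caps cohort size; the
transpose currently materialises the chromosome matrix in memory, which is
the main limitation for very large cohorts.
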
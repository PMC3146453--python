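# Methods

This note documents the models and procedures implemented in `exocap`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show
about real data.

## Capture target design

**Genome-wide gene sampling.** The design goal is a few thousand genes
spread evenly along and across chromosomes under a total base-pair budget.
Chromosome visit counts are fixed up front by largest-remainder
apportionment of the requested gene count to chromosome lengths, rather
than by a stochastic round-robin: "proportionally more often" admits both
readings, and the deterministic one makes designs reproducible and
testable (same annotation + config + seed ⇒ byte-identical BED). On each
visit, the chosen gene is the one whose midpoint is nearest the midpoint
of the largest contiguous span of that chromosome not yet containing a
selected gene's footprint. Ties (equidistant genes; equal-length spans)
break toward the lower genomic coordinate. A chromosome that runs out of
genes forfeits its remaining visits, which are re-apportioned over the
chromosomes that still have genes (with a warning).

**Per-gene exon selection.** Candidate genes contribute every exon,
uncapped and with no minimum length. For other genes the exon carrying
the 5' UTR is always included (regulatory interest), then exons are drawn
uniformly without replacement until the running total first exceeds
`per_gene_bp_cap` (default 1,500 bp) — the crossing exon is kept, then
selection stops. Exons shorter than `min_exon_bp` (default 40 bp) are
never drawn. The UTR exon itself is exempt from the 40 bp floor: the
contract "the 5'-UTR exon is always included" is taken as primary, since
the regulatory motivation for including it does not depend on its length.
A gene whose every exon exceeds the cap instead contributes
`long_first_exon_end_bp` (default 750 bp) from each end of its 5'-terminal
exon. The "5'-UTR exon" is resolved from the annotation (the exon
containing the `five_prime_UTR` feature), which for a '−' strand gene is
normally the highest-coordinate exon.

**Redundancy screen.** An exon is rejected iff some ungapped window of
exactly `redundancy_window_bp` (40) bases aligned against any
already-collected exon, on either strand, has identity strictly greater
than `redundancy_identity` (0.90) — i.e. ≥ 37/40 matches at defaults; N
never counts as a match. The screen is implemented as exact k-mer-seeded
diagonal scanning (BLAST-style seeding as inspiration, but the contract is
the window-identity rule, not any aligner's behaviour): with at most
`mm = 40 − 37 = 3` mismatches in a qualifying window, the window must
contain an exact run of at least ⌈(40−mm)/(mm+1)⌉ = 10 matching bases, so
a seed length of k = 10 makes the seeded scan *complete* — it can never
miss a window the exhaustive oracle would find. (A longer seed such as 12
would be faster but can miss 37/40 windows.) The test suite verifies the
screen against a seeding-free all-diagonals oracle.

**Budget accounting.** Candidate genes are processed first; if they alone
exceed `total_bp_budget` that is an error. Genome-wide genes are then
processed in selection order until the gene count is reached or the
budget is met, so the total may overshoot by at most one gene's
contribution.

## Read filtering

Reads must arrive sorted by (chromosome, position); the filters are
streaming and raise on unsorted input. "Uniquely mapped" is
operationalised as mapping quality ≥ `min_mapq` (default 1), since the
original mapper's internal uniqueness flag is not available generically —
any SAM-producing mapper can feed the pipeline. A read is on-target if at
least one aligned base overlaps a capture target. PCR duplicates are
groups with identical (chromosome, leftmost position, strand); with fixed
36 bp ungapped reads this equals full-span identity. The survivor
maximises the sum of base qualities, with ties broken by lexicographically
smallest read id so the result is independent of input order. Reads whose
CIGAR contains anything but aligned matches are rejected with a warning;
indel handling is out of scope. Note that at high coverage distinct
templates occasionally coincide in position and strand; such chance
collisions are indistinguishable from PCR duplicates by this criterion and
are removed with them (the duplicate-rate recovery test therefore runs at
low depth, where collisions are negligible).

## Empirical quality recalibration

After filtering and duplicate removal, every aligned base falls in the bin
of its reported quality; a base is a mismatch if it differs from the
reference (reference-N positions and non-ACGT read bases are skipped).
The error rate per bin is the *ratio of mismatches to matches*, m/M,
following the original formulation; the proportion m/(m+M) is available
via `rate_mode="mismatch_over_total"` and differs only at O(e²).
Replacement qualities are round(−10·log₁₀ e) (half-up), clamped to
[2, 41] — the plausible range for this instrument generation; a bin with
no mismatches maps to 41, a bin with no matches to 2. Qualities absent
from the table map to the nearest observed bin (ties toward the lower
quality). All mismatches are treated as sequencer error, so known-variant
positions are *not* excluded by default (an optional mask argument
exists); for an individual genuinely diverged from the reference this
deflates qualities severely, which is why `average_tables` exists: the
averaged per-bin error rates of closer relatives stand in for the
divergent sample's true error profile. Averaging is arithmetic over the
tables in which a bin was observed (M > 0), with replacement qualities
recomputed from the averaged rates; per-sample tables are built
explicitly and averaging is an explicit user action.

## Diploid consensus genotyping

At each targeted position covered by at least one surviving read, the
caller scores the 10 unordered genotypes {x,y} over {A,C,G,T}, treating
base calls as independent draws:

    P(b | {x,y}) = ½ [p(b|x) + p(b|y)],   p(b|x) = 1−e if b = x, else e/3,
    e = 10^(−q/10).

The prior puts 1 − θ_het − θ_hom on the reference homozygote and θ_het/3
on each heterozygote carrying the reference allele; the remaining mass
θ_hom is spread equally over the six genotypes without the reference
allele (the model gives no reason to privilege non-reference homozygotes
over non-reference heterozygotes a priori, and these genotypes are rare
enough that the split is inconsequential). Defaults: θ_het = 0.001
(mirroring the conventional per-site variant-rate parameter) and
θ_hom = θ_het/2; sweeping `--theta` scales both, which mirrors the
variant-rate sensitivity analysis a mapper's rate parameter would be swept
through. This is deliberately an independent-error Bayesian model, not a
reimplementation of any particular legacy caller's dependent-error
correction: the accept/reject thresholds, not caller internals, define
the downstream contract.

The consensus quality is round(−10·log₁₀(1 − posterior of the best
genotype)), capped at 99; posterior ties break toward genotypes carrying
the reference allele, then by a fixed genotype order. One structural
consequence worth knowing: a homozygous-non-reference call's quality grows
by roughly one bit per concordant read against the reference-carrying
heterozygote, so such sites need ~12× to clear quality 30 even with
perfect reads — at thin coverage, fixed differences drop out of the
callable set before heterozygotes do.

High-confidence calls require depth ≥ 8 and quality ≥ 30 (both
configurable); the number of retained targeted positions is the callable-
base denominator used by the summaries. All individuals are treated as
diploid everywhere, including the X chromosome (the study animals this
models were all female).

## Variant classification and summaries

A high-confidence call equal to the reference is dropped; a single-base
call differing from it is a fixed difference; an ambiguity-code call is a
heterozygous SNP, including the rare heterozygote with no reference
allele. That rare case counts as one heterozygous SNP and contributes each
of its two ref→alt substitutions at weight ½ to the Ts/Tv ratio.
Percentages are reported half-up at 2 decimals; call-set overlap
fractions at whole percents. Known-variant concordance: a position match
is a called variant at a known position; an allele mismatch is a position
match whose genotype alleles are disjoint from the known alleles; no
coordinate-convention heuristics are applied. Sanger concordance requires
genotype equality (IUPAC, case-insensitive) — this reading reproduces all
published counts on the packaged verification table — and a false positive
is a pipeline variant where the Sanger genotype equals the reference.
"Total genotyped bases" counts targeted positions passing the 8×/Q30
thresholds only; flanking covered positions outside targets are never
counted.

## Synthetic data

The generator emulates the study conditions at desk scale: a
multi-chromosome genome with non-overlapping genes (exon/intron structure
drawn from configurable ranges, every gene's transcription-first exon
flagged as 5'-UTR), individuals diverged at ~0.5% fixed substitutions and
~0.1% heterozygosity (the published scale for a congeneric wild species
vs a domestic reference; the wild-species figure is a stand-in, not an
estimate), and 36 bp single-end reads at a configurable on-target depth
with 75% off-target reads (matching the observed 20–29% on-target
fractions), 10% PCR duplicates, and per-quality error rates with mass at
Q30–Q35. Each stage draws from its own child seed (numpy `SeedSequence`
spawning), so adding a stage never perturbs earlier draws and everything
is bit-reproducible. Fixed and heterozygous edit sites are kept disjoint
by drawing all edited positions in a single without-replacement sample.
Reads carry their true origin (MAPQ 60, with a configurable fraction
flagged MAPQ 0 to exercise the uniqueness filter; duplicates inherit
position, strand and MAPQ but re-draw their base-call errors), so mapping
is bypassed entirely.

What passing tests therefore show: the pipeline's logic — filtering,
recalibration arithmetic, the caller's posterior, the classification and
summaries — recovers known truth under an idealised error model. What
they do not show: robustness to mapping error, indels, cycle-dependent or
context-dependent sequencer error, capture-efficiency variation between
probes, or reference bias from real cross-species alignment. Off-target
reads here are uniform over non-target sequence, not concentrated in
paralogues.

## Problem sizes and numerical choices

The end-to-end harness (`exocap.pipeline.end_to_end_recovery`) runs a
1 Mb two-chromosome genome, 120 genes (5 candidates), an 80-gene /
150 kb-budget design (~110 kb of targets), divergence 0.005,
heterozygosity 0.001, 20× on-target depth, 10% duplicates and Q30 error
0.001 — large enough that the recovered fixed-difference and
heterozygous-SNP counts have tight 3-SD binomial bands (a few hundred
truth sites in the callable region) while the full run stays within a few
minutes on one CPU. Genotype posteriors are computed in log space with a
max-subtraction before exponentiation; the consensus-quality error term
is floored at 1e−10 (hence the 99 cap). Phred rounding is half-up
everywhere. Degenerate inputs are defined explicitly: empty read streams
yield empty outputs and zero statistics; a zero-depth simulation warns
and returns nothing; recalibration of zero aligned bases, summaries over
zero genotyped bases, and averaging of zero tables are errors.

## Known limitations

Single-sample calling only; no indels or structural variation; no
paired-end or optical-duplicate logic; no per-cycle or dinucleotide
covariates in recalibration; one transcript model per gene; Ts/Tv and
concordance summaries assume biallelic sites. The redundancy screen is
quadratic in the number of collected exons in the worst case (linear scans
per accepted exon), which is ample at the few-thousand-exon design scale
it targets.
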
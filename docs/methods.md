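# Methods

jellyseq re-implements, at desk scale, the comparative small-RNA and
transcriptome analysis used to ask whether royal jelly from two honey bee
species (*Apis mellifera*, *A. cerana*) carries different miRNA repertoires and
whether bees reared on either jelly show transcriptome differences attributable
to those miRNAs.  The original raw sequencing is not publicly available, so the
package pairs each analysis stage with a synthetic-data generator that plants
known ground truth; every guarantee below is stated against that ground truth.

## Read cleaning and tag accounting

Raw small-RNA reads (insert + 3' adapter, Phred+33) are assigned exactly one
category in a fixed order:

    low_quality -> adapter3_null -> insert_null -> adapter5_contaminant
                -> too_short -> polyA -> clean

* `low_quality`: mean Phred < 20 or any `N` (the threshold is configurable; the
  original study never defined its low-quality rule, so this default is an
  explicit assumption).
* `adapter3_null`: the 3' adapter starts at position 0 — an adapter-only read
  with a null insert.
* `insert_null`: an empty read, or no 3' adapter anywhere (the insert boundary
  cannot be recovered), or an adapter found only beyond the insert-size window.
* `adapter5_contaminant`: the trimmed insert contains the 5' adapter.
* `too_short`: insert shorter than 18 nt (configurable floor; maximum 44 nt).
* `polyA`: >= 90% adenine in the trimmed insert (configurable).

The non-low-quality categories partition the high-quality reads exactly;
percentages are reported against high-quality reads with half-up rounding to
two decimals, matching the conventions of sequencing-facility cleaning reports.
Length distributions (10–44 nt) are compared between libraries with a Pearson
chi-square contingency test (scipy), dropping bins empty in both libraries.

Clean inserts are collapsed to unique tags with per-library copy counts;
single-read tags (combined count < 2 by default) are discarded.  Tags are
mapped to both genome strands by exhaustive windowed comparison allowing 0 or 1
substitutions; when a perfect locus exists, one-mismatch loci are suppressed
(best-stratum convention).  Annotation precedence is miRNA (exact catalog
match, T/U-insensitive) > rRNAetc (best locus overlapping an rRNA feature, or a
configured contaminant sequence) > unann; unmapped tags are reported
separately.  A tag carries exactly one class, so class counts partition both
unique-tag and read totals.

## Hairpin folding and the three candidate criteria

For each candidate tag locus a 100-nt genomic window is extracted (centred on
the mature span, truncated at contig ends, reverse-complemented for
minus-strand loci) and folded with a Zuker-style dynamic program under a
simplified nearest-neighbour energy model:

| parameter | default | unit |
|---|---|---|
| stack, closing pair G:C / C:G | -3.0 | kcal/mol per stacked step |
| stack, closing pair A:U / U:A | -2.0 | kcal/mol |
| stack, wobble G:U / U:G | -1.0 | kcal/mol |
| hairpin-loop penalty | +4.0 | kcal/mol per loop |
| bulge penalty | +3.0 | kcal/mol per unpaired nt |
| internal-loop penalty | +2.0 | kcal/mol per unpaired nt |
| minimum loop | 3 | nt |
| maximum interior loop | 30 | unpaired nt |

Pairs gain energy only when stacked; multibranch loops are charged at the
internal-loop rate per unpaired nucleotide; exterior bases are free; dangling
ends and coaxial stacking are ignored.  This model is a deliberate surrogate
for a full thermodynamic folder (the original study used RNAfold/MIREAP): its
virtue is that the same closed-form energy evaluator defines both the DP and an
exhaustive enumeration over all non-crossing structures, so the DP is verified
*exactly* on every sequence up to 25 nt (the 30-nt interior-loop cap cannot
bind there).  Energies are therefore comparable only within this model, not
with Turner-parameter tools.

A candidate passes if all three criteria hold:

* **(a)** the mature span lies entirely 5' or 3' of the terminal loop of the
  dominant stem (the hairpin loop with the most enclosing pairs) and contains
  no unpaired run longer than 4 nt — the quantification of "no large internal
  loops or bulges", which the source analysis left unquantified;
* **(b)** window MFE strictly below -20 kcal/mol;
* **(c)** the locus lies in an intergenic region or an intron (exonic and
  rRNA loci fail).

The positional reading of (a) matters: random window flanks occasionally
recruit one or two mature-end bases into a small flank helix, which does not
displace the mature from its arm and is correctly tolerated.

Mature sequences are reconciled against a miRBase-style catalog by exact
sequence identity (configurable mismatch allowance, ties broken
lexicographically by name); per-library known-miRNA inventories are compared as
name sets (specific/shared).

## Differential expression

**Altered miRNAs.**  A miRNA is evaluable only with >= 10 copies in *both*
libraries; evaluable miRNAs are called up/down on a two-fold raw copy-number
difference (boundary inclusive).  Raw copies are the default because the
decision rule is stated in copy numbers; per-million normalisation is available
behind a flag since library sizes differ.

**Genes.**  Expression is RPKM = 1e9 * count / (library_size * length); the
effect measure is log2(RPKM_1/RPKM_2).  The equal-expression probability
conditions on the total n = x + y of the two library-size-offset Poisson
counts:

    x | n ~ Binomial(n, N1/(N1+N2)),   p = 2 * min(P(X<=x), P(X>=x)), capped at 1.

This conditional-binomial pmf is proportional to the classical
digital-expression form `(N2/N1)^y (x+y)!/(x! y! (1+N2/N1)^(x+y+1))` (the
formula is reproduced here as a reconstruction; the source typesets it as an
unreadable figure).  The conditional formulation is used because it is exactly
symmetric under swapping (x, N1) with (y, N2), a property the module guarantees;
the predictive form differs from it by a factor N1/N2 at the pmf level and
breaks that symmetry at order of the point mass.  p-values are adjusted by
Benjamini–Hochberg step-up; a gene is called up/down iff FDR < 0.001 and
|log2 ratio| > 1.  Genes zero in both samples are excluded; a single zero gets
a 0.5-count pseudo-offset for the reported ratio only (the p-value always uses
raw integers).  The exact test is discrete: at shallow coverage the doubled
tail rule is conservative, leaving an atom at p = 1 of roughly the pmf at the
binomial median (~0.04 at 300-read coverage).  Calibration is therefore
assessed on well-covered genes (mean ~1000 reads, where the Kolmogorov–Smirnov
distance to uniform is ~0.03); at low counts p-values err conservative, never
anticonservative, under the Poisson null.

## Target prediction

miRNA:transcript hybridisation reuses the same energy parameters for an
intermolecular duplex: monotone antiparallel pairing chains, stacking for
adjacent pairs, bulge/internal rates for skipped nucleotides, no intramolecular
pairing, empty duplex at 0.  The O(m·w) four-state alignment DP is verified
against exhaustive enumeration of all monotone chains for |miRNA| <= 12,
|window| <= 15.  Transcripts are scanned in 60-nt windows advancing by 30 nt;
the single lowest-energy site strictly below the cutoff (default -20 kcal/mol,
mirroring the hairpin threshold) is reported per (miRNA, transcript) pair, ties
resolved leftmost.  An optional seed constraint demands contiguous pairing of
miRNA positions 2–8 (off by default, matching pure MFE ranking).

Because the surrogate stacks are deeper than calibrated thermodynamic
parameters, -20 kcal/mol is a permissive cutoff on long sequences: spurious
sub--20 duplexes accumulate roughly linearly with scanned length (~1.5% per
60-nt window, ~36% over a 900-nt transcript).  The specificity guarantee
(<5% per-gene false positives with no planted site) is therefore stated for the
3' target region — the last 60 nt of the transcript, where the generator plants
true sites and where miRNA regulation canonically acts.  Full-transcript scans
are supported but should be read with a stricter cutoff; this is a known
limitation of the surrogate energy scale.

The DEG/target overlap report counts differentially expressed genes targeted by
at least one supplied miRNA and their proportion (one decimal, half-up).

## Synthetic data: what it emulates, and what it does not

`synthio` generates (deterministically per seed, byte-for-byte):

* a toy chromosome (default 20 kb) tiled exactly by genes (exons/introns),
  rRNAs and intergenic gaps, with hairpin precursors (stem 26 bp, loop 8 nt,
  mature 20–22 nt on the 5' arm) overwritten into intergenic, intronic or —
  for negative tests — exonic sequence;
* small-RNA libraries with a nine-class read mixture (defaults: 15% mature
  miRNA, 30% rRNA fragments, 43.5% degradation, 10% too-short, ~1.5% adapter /
  polyA / low-quality failure modes, echoing the relative magnitudes of a real
  cleaning report) and per-hairpin expression weights so two libraries can
  differ;
* two-sample gene counts, negative-binomial with variance mu + d·mu²
  (Poisson at d = 0), sample-2 means scaled by 2^log2_fold and the
  library-size ratio; defaults plant |log2 fold| = 3 in 5% of 1000 genes at
  dispersion 0.05;
* planted perfect or seed-only target sites in gene 3' regions.

Not emulated: base-call error models, quality-score realism beyond a single
low-quality class, chimeric reads, strand-of-origin realism (reads are emitted
forward-strand; mapping still checks both strands), spliced or indel-tolerant
alignment, and biological sequence composition.  Passing tests demonstrate
algorithmic correctness and statistical calibration under the stated generative
assumptions — not performance on real libraries, where adapter variants,
quality artefacts and repeat structure are harsher.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GFF3 output converts to
  1-based inclusive.
* Percentages: decimal half-up rounding (2 decimals; 1 for the target-overlap
  proportion), so printed tables match recomputation exactly.
* Fold/duplex tie-breaks: the DP traceback prefers hairpin closure, then
  stacking, and site scanning prefers the leftmost window/site on energy ties.
* T and U are synonyms on input everywhere; genomes are written in DNA,
  folding operates on RNA internally.
* Problem sizes in tests and the acceptance script (500/200 oracle cases, 40
  planted hairpins, 10,000-read libraries, 50-kb mapping genomes, 5,000-gene
  calibrations) are chosen to make every exhaustive comparison exact and every
  stochastic bound comfortably estimable on a single CPU.

## Known limitations

* The energy model is a surrogate; absolute kcal/mol values are not comparable
  with RNAfold/RNAhybrid outputs, and the -20 thresholds are calibrated only
  within this model.
* One pooled sample per condition: the equal-expression test models sampling
  noise only; biological replication and dispersion estimation are explicitly
  out of scope, so calls on overdispersed real data overstate certainty.
* The mapper is substitution-only (<= 1 mismatch), as the analysis it mirrors
  specified; indels and spliced alignment are unsupported.
* Published summary tables are used by tests purely as arithmetic worked
  examples of the reporting functions; the original libraries cannot be, and
  are not, re-analysed.
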
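# Methods

This note records the models implemented in `ltsp_recovery`, the
parameter choices that matter, and what the synthetic-data generator
does and does not emulate.

## Growth-rate estimation

A well's exponential rate is the maximal slope of ln OD₆₀₀ versus time
over sliding windows of five consecutive readings (10-minute sampling),
fit by ordinary least squares and accepted only when the window's
R² exceeds 0.99 (strictly). Choices the estimator makes where the
procedure leaves room:

- **Logarithm base.** Natural log. Relative rates are ratios, so the
  base cancels; ln is the convention for exponential rate constants.
- **OD floor.** Readings at or below `od_floor = 0.01` are excluded
  before the log transform as blank/noise-dominated. Inputs are assumed
  background-corrected; no blank subtraction is performed.
- **Ties and degenerate windows.** Among equal maximal slopes the
  earliest window wins (determinism). A window with zero variance in
  ln OD (flat signal) has an undefined R² and never qualifies, so a
  flat curve yields an unqualified estimate rather than a zero rate.
- **Window length.** Fixed at five points by default but exposed as a
  parameter.

Relative growth rate is 100 × (sample rate / wild-type rate), with the
wild-type reference taken as the mean over the qualified wild-type
wells of the same plate. A recovery trajectory over dilution cycles is
summarised by its maximal relative rate and the first cycle at or above
a 90% threshold (reported N/A when never reached).

## Mutation identity and "new" mutations

A mutation's identity is its (position, alt allele) pair, 1-based on
the reference (NC_000913 coordinates for the organism modelled).
Annotation strings do not participate in identity; this is also what
makes reversion detectable, as the ancestral clone's derived allele
disappears from a descendant. New mutations are a set difference
against either a single ancestral clone or the union of everything ever
seen in sequenced clones of the same population. Large deletions count
as single events regardless of span. Mutator status is curated
metadata; a helper can flag clones hitting a configurable
mismatch-repair gene list (default mutS, mutL, mutH, uvrD — the list is
configuration, not a claim of completeness).

## RNAPC classification and outcomes

The three convergent antagonistically pleiotropic sites (RpoB 1272,
RpoC 334, RpoC 428) are configuration with those defaults. A clone's
category is the first matching of: configured site hit (coding mutation
with the matching residue number) > any other rpoA/rpoB/rpoC mutation >
none. A clone hitting two configured sites (never observed) is reported
under the lexicographically first and logged.

Outcome calls compare end-state genotypes only: **reversion** when the
founder's anRNAPC allele (nucleotide identity) is absent from the
descendant; **compensation** when it is retained and at least one
additional RNAPC mutation appeared; **retained** otherwise;
**not applicable** when the founder carried no anRNAPC allele. Two
consequences are worth stating plainly: a same-codon second
substitution that restores the ancestral amino acid but not the
ancestral nucleotide is classified as compensation, and a compensatory
mutation that preceded a later reversion is indistinguishable from
plain reversion in end-point data.

## Fractional site counting, dN/dS, and the χ² test

For each position of a sense codon, the three possible substitutions
are enumerated; the position contributes the synonymous fraction
(substitutions preserving the amino acid, over three) to S and the
complement to N. Under the default `stop_as_ns` policy, substitutions
creating a stop count as nonsynonymous, so every sense codon
contributes exactly 3 sites; `exclude_stop_targets` instead drops stop
targets from the denominator, for sensitivity analysis. Terminal stop
codons are excluded from counting; internal stops raise unless
configured to skip the record. The genetic code defaults to NCBI
translation table 11.

dN/dS for n nonsynonymous and s synonymous observed mutations is
(n/N)/(s/S), undefined (reported N/A) when s = 0. Observed nonsense,
frameshift and noncoding mutations belong to neither class. The
enrichment test is a two-category χ² goodness of fit with expected
counts (n+s)·N/(N+S) and (n+s)·S/(N+S), 1 degree of freedom, no
continuity correction (the tested counts are large where significance
is claimed; the statistic is computed explicitly and cross-checked
against scipy's goodness-of-fit in the tests).

### The coding-sequence complement

Fractional site counts over a CDS set depend only on its codon
composition. The package therefore carries the published codon-usage
composition of the E. coli K-12 MG1655 coding complement (61 sense
codons, per-1000 frequencies, `data/ecoli_k12_codon_usage.tsv`) and can
either weight per-codon contributions by it directly or generate a
synthetic CDS complement with exactly that composition
(`synthetic_cds_complement`; composition is deterministic, only codon
order depends on the seed). Both routes give a genome-wide N:S site
ratio of 3.251 — within the 3.2–3.3 window implied jointly by the
published mutation counts and dN/dS values — and reproduce the
published two-decimal dN/dS figures. Counting over a user-supplied
FASTA of real coding sequences is supported through the same code path
and is preferable when the sequence set is at hand; exact third-decimal
agreement can vary with annotation release.

## Serial-dilution simulator

The simulator is the package's synthetic-data generator; its defaults
are the experimental regime where stated, and documented illustrative
values elsewhere.

**Transfer regime.** Daily 1:100 dilution for 16 cycles;
`generations_per_cycle` defaults to log₂(dilution factor) ≈ 6.64, the
regrowth that restores pre-dilution density.

**Growth.** Deterministic within a cycle: genotype *i* multiplies by
2^(g·r_i/max r), where r_i is its growth rate relative to wild type and
the fastest genotype present completes exactly g doublings.
Consequence (used as a closed-form check): with two genotypes and no
mutation, the per-cycle change in log₂ abundance odds is exactly
g·(r₁−r₂)/max r. Stochasticity enters only at the bottleneck and
through mutation; bottleneck drift dominates at 1:100 transfers, and
keeping growth deterministic keeps the closed forms exact.

**Bottleneck.** A multinomial sample of `bottleneck_n` cells
(default 10⁶, scaled down from the ~10⁸ cells a real 0.1 ml transfer of
saturated LB carries; drift is therefore somewhat stronger than in the
flask experiments).

**Mutation.** Applied at cycle boundaries with expected counts
cells × g × μ, Poisson-drawn — not per-division lineage tracking, which
is adequate for frequency-scale questions. Reversion moves cells to a
derived genotype with the allele removed and the wild-type rate
restored; compensation retains the allele and removes a configured
fraction of the cost (default 1.0, i.e. full recovery, which is the
assumption under which the k-compensatory-targets : 1-reversion-target
outcome ratio is a clean k:1). Mutator genotypes multiply both rates by
`mutator_factor` (default 100, the order of magnitude of
mismatch-repair deficiency). Defaults μ_rev = 1×10⁻¹⁰ and
μ_comp = 4×10⁻¹⁰ per genome per generation encode a single reversion
target and a handful of compensatory targets at a realistic per-base
scale; they are illustrative, not estimates — the experiments report
neither bottleneck sizes nor mutation rates. A compensated genotype
still carries the allele and may subsequently revert, which slightly
depresses the observed compensation:reversion outcome ratio below k.

**Detection.** Comparisons to clone-sequencing observations model
detection as a 10-clone sample drawn by genotype frequency, matching
the sequencing depth of the experiments, not as a hard frequency
threshold.

**Clone tables.** Sampled clones carry fabricated founder-defining
mutations (the anRNAPC allele at RpoB 1272 where carried, a
mismatch-repair mutation for mutators, a neutral marker; reverted
derivations drop the allele, compensated ones add a secondary RNAPC
mutation at an experimentally observed compensatory site — RpoC 1075 or
RpoB 546) plus Poisson-distributed passenger mutations whose NS:S split
follows supplied site fractions.

**OD curves.** Logistic growth sampled every 10 minutes over 12 hours:
wild-type rate 0.025/min (≈28-minute doubling in fresh LB), inoculation
OD 0.05, carrying capacity 1.4, 60-minute lag. Measurement noise has a
component proportional to the signal (sd 0.002 relative) plus a small
absolute floor (sd 0.0005 OD units); a purely absolute noise term of
plate-reader magnitude makes the max-of-noisy-windows estimator
systematically volatile at low OD, which real readers avoid because
their relative error shrinks as the signal grows. An infinite carrying
capacity yields exact exponentials for round-trip checks. Under these
defaults, averaging eight replicate wells recovers a configured 80%
relative rate within 2 percentage points.

**What the generator does not emulate.** The 127-day starvation phase
itself (death phase, dormancy, balancing selection), within-cycle
resource kinetics and lag/stationary physiology differences between
genotypes, linkage between passenger mutations and fitness, sequencing
or variant-calling error, and real plate artifacts (edge effects,
condensation). Passing tests therefore show that the analysis code
implements its statistics correctly and that the population dynamics
follow their closed forms — not that any particular biological value is
re-measured.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run entirely from generated
inputs: site counting over a ~10⁵-codon synthetic complement, 10⁴
neutral-drift replicates at bottleneck 10³, 200 reversion/compensation
runs at bottleneck 10⁵, 100 allele-loss runs at bottleneck 10⁶, and
8-replicate synthetic plates; everything completes in seconds on one
CPU. Seeds are threaded explicitly (`numpy.random.default_rng`);
identical seeds give identical trajectories. Floating-point tolerances:
exact-arithmetic claims are asserted at 10⁻⁹–10⁻¹², stochastic means at
three standard errors of the replicate set.
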
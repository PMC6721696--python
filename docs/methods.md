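# Methods

This note documents the models and procedures implemented in `hapedit`,
the parameters that matter, the design decisions taken where the design
was genuinely open, and the limits of what the test suite demonstrates.

## The phasing model

Each family is nuclear: two founder slots (genotyped parents or
all-missing placeholders) and one or more genotyped children.  Phasing is
purely observational — no population haplotype frequencies, no likelihood
maximization.  The phaser performs three steps per family:

1. **Transmission resolution.**  For each child and marker, the unordered
   child genotype is matched against both parental genotypes.  If exactly
   one assignment of the child's two alleles to (father, mother) is
   Mendelian-consistent, the transmitted alleles are fixed; if both are,
   the marker is uninformative for that meiosis; if neither is, the marker
   is a Mendelian inconsistency and is nulled for the whole family (a
   warning is logged; the family is kept, because an isolated bad call
   would otherwise only create unphased or singleton variants downstream).
   A missing parent constrains nothing, so children of placeholder
   founders still resolve wherever the typed parent forces the split.

2. **Origin anchoring and propagation.**  Each parent's two haplotypes are
   filled by constraint propagation.  Homozygous parent markers assign
   both haplotypes directly.  For heterozygous or untyped markers, each
   meiosis carries a single region-wide origin label (hap1/hap2): the
   first informative meiosis anchors the labeling, later meioses are
   labeled only when a marker where both haplotypes are known and differ
   forces the choice.  Labeled meioses write their transmitted alleles
   onto the corresponding haplotype (with the complementary allele on the
   other haplotype at parent-heterozygous markers).  The loop runs to a
   fixpoint.  One deliberate deviation from "only what is forced": for an
   *untyped* parent, a meiosis compatible with hap1 while hap2 is still
   entirely empty is merged onto hap1.  Strictly, haploidentity of two
   such children is not provable, but without the merge an ungenotyped
   founder could never accumulate a transmitted haplotype from compatible
   children; this is the same most-likely-gene-flow assumption a
   likelihood phaser makes, and it is exercised and bounded by the
   truth-based simulation tests.

3. **Crossover detection.**  After the fixpoint, each meiosis gets an
   origin vector over the markers where both parental haplotypes are
   defined and differ.  A vector containing both hap1 and hap2 calls marks
   an apparent within-region crossover, and all subjects of such families
   are removed before any counting.  Detection is intrinsically
   incomplete: a crossover between two haplotypes that are identical on
   one side of the breakpoint produces a transmitted haplotype equal to a
   parental one and is invisible (and inconsequential); breakpoints in the
   outermost marker intervals can also lack informative flanking markers.
   Simulation shows the detector has no false positives, while its misses
   are dominated by these silent events — the flagged fraction therefore
   sits slightly below the simulated crossover fraction, within binomial
   error at the rates studied (1% per meiosis).

Unresolved positions stay at the sentinel `.`; soundness (no phased allele
ever contradicts an observed genotype) holds by construction and is
asserted against simulation truth.  When a meiosis's origin is never
resolved (a parent effectively homozygous at every resolved marker), the
transmission is booked as haplotype 1 for DIS/FC accounting only — allele
assignment never uses this default, and in the common case the two
haplotypes are then indistinguishable anyway.

## Panel editing

**Coverage** is the fraction of all founder haplotypes (including
placeholders and all-undefined ones) with a phased allele at a SNP — it is
computed once, before editing, and is the single source of truth for every
later coverage comparison.

**Pre-triage** keeps roughly `retain_fraction_target` (default 0.365) of
the panel, apportioned across six MAF categories — (0,5], (5,10], (10,20],
(20,30], (30,40], (40,50] percent — in the bell-shaped ratio 4:3:6:12:7:5
(largest-remainder apportionment, quotas truncated to bin populations).
Within the quotas the selection maximizes total coverage subject to a
spatial constraint: no gap between consecutive retained SNPs, nor between
a region boundary and the nearest retained SNP, may exceed
`spatial_gap_factor` (default 3.0) times the mean expected spacing
(region length / retained count).  The boundary clause is deliberate:
without it a selection clustered at one end of the region would satisfy a
consecutive-gaps-only rule while being exactly the grossly asymmetric
layout the rule exists to prevent.  The optimization is solved exactly as
a small mixed-integer program (HiGHS via `scipy.optimize.milp`, relative
gap 0), with coverage quantized to 1e-6 and a low-order position term so
that coverage ties break deterministically toward lower positions and the
optimum is provably unique; an exhaustive-enumeration oracle in the test
suite confirms the optimum on random panels.  If the constraints are
infeasible the gap rule is dropped with a warning and per-bin top coverage
is used.

**Redundancy elimination** works on the catalog of fully-phased haplotype
variants, sorted by descending count (ties lexicographic).  The top-mass
prefixes are the smallest prefixes of that ordering reaching
`alone_rule_mass` (default 0.90) and `redundancy_mass` (default 0.95) of
the fully-phased haplotype count, boundary variant included (inclusion is
unspecified in principle; including it is the deterministic choice).
A SNP that changes *alone* in some prefix variant (differing from the top
variant at exactly that SNP) is protected.  SNP groups are redundant when
they induce the identical two-class partition of the redundancy prefix
(equivalently: exactly two joint allele combinations); each group keeps
its highest-coverage member (ties: lower position) — or all protected
members, the others being dropped.  Note that under the default masses a
protected SNP can never sit in a redundant group (a lone change inside the
90% prefix forces a third joint combination inside the 95% prefix); the
protection rule only bites under non-default mass settings, and is tested
there.  Dropping, re-sorting and re-checking repeats until no group
remains; each drop can only promote partially defined haplotypes to
fully-phased status, so the fully-phased count is non-decreasing (asserted
every iteration).  Singleton variants participate in all mass arithmetic.
With `pre_triage_enabled=false` the same loop runs on the full panel — the
alternative editing route.

## Cataloging and reference correlation

Variant names are frozen at first cataloging in descending-count order;
ranks are competition-style ("1224": tied counts share a rank).
Percentages are reported to one decimal, ratios to two.  Cross-tabulation
joins reference labels (opaque strings) on (family, founder, haplotype
index): per variant, the modal label with its share of labeled copies; per
label group, the dominant variant's share of the whole group and of its
fully-defined members, plus the unphased remainder.  Modal ties are broken
lexicographically and flagged.  The discriminating-SNP search scores a
k-subset by (i) no class carrying the other's dominant k-sequence,
(ii) the summed dominant-sequence fractions, (iii) the number of positions
at which the two dominant sequences differ — the last criterion makes the
surrogate robust to single unphased positions and makes the forced case
(classes differing at exactly k SNPs) return exactly those SNPs.  The
search is exhaustive up to 200,000 subsets, then a deterministic greedy
forward selection; class order only swaps the output labels.

## The DIS/FC assay

Unknown phenotypes are carried through reading and phasing and mapped to
unaffected only at assignment time.  Equalization keeps founders with
exactly one fully-phased DIS and one fully-phased FC haplotype, so DIS and
FC totals are equal and every founder contributes both haplotypes or
neither.  The per-variant statistic (D−F)²/(D+F) is the Pearson
goodness-of-fit of the two counts against equal expectation; summed over
the k variants with both counts ≥ `min_count` (default 5) it is referred
to χ²(k−1), with Bonferroni factor k.  No continuity correction is
applied.  Totals are accumulated from unrounded per-variant values; table
display rounds to two decimals.  Ratio display conventions: a zero FC
count is an infinite ratio (susceptibility, shown as NaN in the table); a
zero DIS count displays 0.00 (protective).  Boundary ratios 0.5 and 1.0
classify as neutral.  p-values are computed in double precision, which
represents the assay's extreme tails (≈1e-247) without underflow.

## The synthetic-data generator

The generator emulates the structure the method assumes: a pool of
`n_conserved` (default 16) distinct conserved haplotype sequences over the
panel, with geometrically decaying frequencies (ratio 0.717, giving a top
frequency near 28.3% — the scale of the most frequent conserved MHC
haplotype in T1D family data — and a tail of rare variants; the top
frequency can be pinned exactly).  Per-marker MAFs emerge from the pool
and are attached to the markers.  Families draw four founder haplotypes
from the pool; each meiosis picks a parental haplotype uniformly, with a
within-region crossover at a uniform breakpoint with probability
`recombination_fraction` (default 0).  A child is affected with
probability `prevalence × rr(h₁) × rr(h₂)` (multiplicative two-haplotype
model, capped at 1; default prevalence 0.05, all relative risks 1).  No
penetrance model is claimed by the method itself; multiplicative risk is
the simplest model that produces DIS/FC enrichment in a known direction.
A recombinant transmitted haplotype carries the risk of its 5'-segment
source (negligible at the recombination rates studied).
Affected-sib-pair ascertainment rejection-samples each family until ≥2
children are affected (aborting after a configurable attempt cap).
Missingness is injected last: whole founders with probability
`missing_founder_prob` (their PED rows are omitted on export, exercising
the placeholder path) and individual calls with `missing_call_prob`.  One
master seed drives everything; each family uses a substream derived from
(seed, family index), so earlier families are invariant to the family
count.

What the generator does *not* emulate: realistic recombination maps and
hotspots, genotyping error (as opposed to missingness), linkage
disequilibrium decay within conserved haplotypes, multi-generation
pedigrees, and population stratification.  Passing tests therefore
demonstrate the pipeline's internal correctness and calibration under the
assumed family structure, not robustness to those real-data features.

## Study conditions used by the checks

The simulation-based checks run at sizes chosen to make their statistics
informative while staying desk-scale: phasing truth on 500 families × 50
SNPs (≥10⁵ genotype calls); crossover rates on 500 families at 1%
recombination per meiosis; triage-rule oracle equivalence on 200 random
panels of ≤10 SNPs / ≤20 variants; planted redundancy on a 37-SNP panel
with 10 planted redundant SNPs over 16 pool variants; null calibration
over 500 replicates of 150 families (no ascertainment, prevalence 0.3,
six-haplotype pool so that most variants clear the count threshold);
effect recovery over 60 replicates of 200 affected-sib-pair families with
one haplotype at relative risk 3.  The null rejection rate sits within the
3σ binomial band around the nominal 5% (slightly conservative, as expected
when sub-threshold variants are excluded from a k−1-df sum).

## Known limitations

- The conservative phaser leaves more positions undefined than a
  likelihood phaser would; this is by design (coverage-driven triage is
  the next stage) but means absolute fully-phased percentages depend on
  family informativeness.
- With an untyped parent, compatible siblings are merged onto one
  transmitted haplotype; pathological genotype patterns can in principle
  blend the two parental haplotypes, which full genotyping rules out.
- Crossover detection cannot see silent crossovers (identical flanking
  segments) and is weaker in families with an ungenotyped parent.
- Redundancy is a combinatorial criterion on the top-mass variants, not an
  LD statistic; panels whose variant spectrum shifts drastically between
  iterations could in principle oscillate, though each iteration strictly
  shrinks the panel, so termination is guaranteed.
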
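# Methods

This note documents the models behind `wtfkit`, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
conventions used throughout.

## Coordinate and sequence conventions

All coordinates are 1-based inclusive (GFF3 native) everywhere inside the
package; the BED writer is the single point of conversion to 0-based
half-open. Gene sequences are stored 5'→3' on the + strand (minus-strand
genes are reverse-complemented on ingest). `N` bases are tolerated in
genomes; windows containing `N` are excluded from k-mer seeding, and
recombination/distance statistics use pairwise deletion of gap/`N` taxa at
each site (site pairs with fewer than 4 complete taxa are skipped).

## The family simulator

`family_sim.simulate_family` evolves a multi-locus gene family forward in
time along a random coalescent-shaped, ultrametric strain genealogy
(Kingman waiting times, rescaled so root-to-tip depth equals `generations`).
Each generation, every family member independently draws:

- **point mutations** — Binomial(L, `mu`) sites, uniform placement; under
  `infinite_sites=True` no site is ever hit twice (a feasibility check
  rejects parameter sets whose expected mutation count exceeds the gene
  length);
- **duplication** (prob. `dup_rate`) — the gene is copied to a brand-new
  locus with freshly drawn flanking sequence;
- **gene conversion** (prob. `conv_rate`) — a tract with uniform start and
  geometric length (mean `tract_len_mean`, truncated at the gene ends) is
  copied in from a uniformly chosen co-resident family member, with donor,
  acceptor and breakpoints logged;
- **pseudogenization** (prob. `pseudo_rate`) — a stop codon is written into
  a random in-frame codon before the final 10% of the CDS (always exonic by
  construction).

Genes are gap-free, so every copy lives on the ancestral coordinate system:
per-locus (and pooled) **true alignments** need no aligner, and
`inject_single_crossover` can place exact single-breakpoint chimeras on the
same coordinates. Each locus carries unique left/right flanks (default
1000 bp) inherited down the tree and mutating at `mu`, which is what makes
flank-based locus assignment a testable inference problem. Emitted genomes
are one contig per strain: `spacer + left flank + gene + right flank` per
locus. The truth log records every event plus a final registry (strain,
locus, span, coding status); the registry's `status` is the *sequence-level*
coding status — drifting point mutations can disrupt a CDS just as the
explicit stop-gain channel can, and both are truth — while `pseudo_event`
marks the explicit channel separately.

**Default study conditions** (chosen once, for realism at desk scale):
5 strains, 8 loci, 400 generations, `mu = 2e-5` (≈1.6% strain divergence,
and roughly a third of family members carrying a disruption — similar in
spirit to the high pseudogene load seen in real spore-killer families),
`dup_rate = 1e-4`, `conv_rate = 2e-4`, `tract_len_mean = 300`,
`pseudo_rate = 1e-4`, six-exon 2 kb ancestor (1680 bp CDS). The
**conversion-power benchmark** used by the test suite is a deliberately
diverged-paralog condition: 4 loci × 5 strains, 800 generations,
`mu = 5e-5` (≈8% between-locus divergence — conservative for a family whose
real members are clustered at a 50% identity threshold) and
`conv_rate = 1.5e-3`, keeping replicates with ≥10 logged conversion events.

What the simulator does **not** emulate: indels within genes (alignment
inference is out of scope, so simulated genes are gap-free), selection on
sequence content, transposon/LTR insertion mechanics, and any preference of
new duplicates for particular genomic neighborhoods. Passing tests therefore
demonstrate correct inference *given correct alignments* and realistic
point-substitution structure; they do not exercise aligner error or
structural variation.

## Drive dynamics

Haploid-dominant life cycle with obligate outcrossing: random pairing,
meiosis into a tetrad of four spores, per-spore killing, Wright–Fisher
resampling of N haploids from the surviving pool. Every poison carried by
either parent is present in the ascus; a spore survives a poison with
probability 1 if any of its own genes' antidotes covers it, else `1 − c`
(killing efficiency, a free parameter — no empirical estimate exists for
any real family member). Survival multiplies independently across distinct
poisons; carrying a driver is cost-free by default (`cost` is exposed),
consistent with knockout experiments finding no vegetative fitness effect.

Enumerating the three mating classes gives the infinite-N recursion
`p' = p / (1 − c·p·(1−p))`, which the implementation cross-checks against
the explicit enumeration in the test suite. The three canonical scenarios
share one machinery: `novel_driver` (drives), `duplicate_same_specificity`
(exactly neutral — the fixed ancestral antidote rescues every spore), and
`recombinant_novel_specificity` (drives against the fixed ancestral
background). Fixation probabilities are vectorized Monte Carlo with a
precomputed frequency-to-expectation map and binomial standard errors.

## Recombination statistics

**Homoplasy (PHI-style) test.** For each pair of parsimony-informative
sites within `w` bp (default 100; distance measured on the ungapped
consensus), the *refined incompatibility* score is the minimum number of
extra steps any tree requires for the pair — computed as the cycle rank
E − V + C of the state-intersection graph, which is 0 exactly for
compatible pairs (verified against exhaustive tree enumeration scored by
Fitch parsimony). The statistic is the mean score over nearby pairs. Under
clonal evolution homoplasy is independent of inter-site distance; under
recombination nearby sites are *more* compatible than distant ones, so the
permutation p-value is the lower tail — the add-one-corrected fraction of
informative-site permutations with statistic ≤ observed (1000 permutations
by default, seed-reproducible). On clonal infinite-sites data all pair
scores are 0 and p = 1 exactly; under clonal recurrent mutation the test
stays calibrated (measured type-I ≈ 0.05 at α = 0.05) because homoplasy
carries no spatial signal.

**Triplet breakpoint scan.** For an ordered triple (P, Q, C), informative
sites are columns where C matches exactly one of P, Q; the ±1 walk's
maximum descent from its running maximum is the statistic. Its exact
p-value — the probability that a uniformly random arrangement of the m
up-steps and n down-steps reaches descent ≥ k — is computed by an exact
integer dynamic programme over (ups used, deficit), verified against
complete arrangement enumeration for all m, n ≤ 6. The reported breakpoint
interval spans the maximal-descent run (peak column + 1 through trough
column). Multiple testing across triplets uses Dunn–Šidák (Bonferroni
available).

**Rmin.** Biallelic sites only (>2-state sites excluded); every
four-gamete-incompatible pair defines an open interval that must contain a
crossover; the maximal set of pairwise disjoint intervals (greedy by right
endpoint, equivalent to Hudson–Kaplan thinning) gives the minimum number of
recombination events, reported per ungapped bp. Per-bp Rmin is the package's
comparative recombination-rate statistic for regions (full gene / exon 1 /
remainder) and groups; it preserves rankings, not absolute
population-scaled rates — likelihood/regression-based ρ = 4Nₑr estimation
is deliberately out of scope.

## Annotation

The homology search is a seeded local alignment: exact k-mer seeds
(default 11) on both strands grouped by diagonal, candidate windows aligned
by banded edit-distance alignment whose path is then scored with the
declared scheme (match +1, mismatch −2, gap open −5, extend −2). E-values
use the extreme-value form E = K·m·n·e^(−λS) with λ solved from the score
scheme at uniform base composition and K calibrated once on shuffled-
sequence score distributions (cached); the default cutoff is 1e-5. The
E-value scale cannot match any external tool's bit-for-bit — the cutoff's
*semantics* (reject chance-level hits at desk scale) are what is preserved.
Overlapping hits from different queries merge at ≥50% overlap of the
shorter interval.

Exon structures transfer from the reference model with the highest
candidate identity (ties broken by reference order and logged); boundaries
map through the pairwise alignment, with gap-landing boundaries flagged.
A candidate below 0.5 identity to every reference is rejected as a
non-member. Pseudogene calls use three rules (premature stop before the
final 10% of codons, spliced length ≢ 0 mod 3, missing start codon) — no
published criteria exist for the real family, so the rules are a documented
choice mirrored by the simulator's sequence-level truth. Poison-start
detection looks for an in-frame ATG in the first 30 nt of exon 2, or an ATG
in the last 30 nt of intron 1 whose frame runs continuously into exon 2
(the 30 nt window is a documented choice, configurable). Locus assignment
joins genes of different strains whose available flanks both align at
≥0.8 identity (a cheap shared-k-mer prefilter skips hopeless pairs);
connected components are loci, labelled by their lexicographically smallest
member so the result is invariant to input order. Genes within `flank_len`
of a contig end fall back to single-flank mode, flagged.

## Exon networks and identity

Pairwise identity is computed from the optimal global alignment with free
end gaps (match +1, mismatch −1, gap −2) as **matches / length of the
shorter sequence**. The denominator choice matters: excluding unaligned
ends from the denominator makes *any* positive-scoring chance overlap
exceed 50% identity by algebra (m > x + 2g implies m/(m+x+g) > 1/2), which
would dissolve the 0.50 clustering threshold; dividing by the shorter
length keeps chance similarity near 0.1 and diverged homologs high. Because
distinct optimal-score alignments can differ in match count, arguments are
canonically ordered before aligning so the function is exactly symmetric.
Graph edges appear at identity ≥ threshold (default 0.50); a strictness
flag switches to >. Components with ≥2 members are clusters, ordered by
size then smallest member; raising the threshold can only refine the
partition (property-tested).

## Trees and grouping

Distances: p-distance, JC69 (−¾·ln(1 − 4p/3), saturated pairs p ≥ 0.75
capped at 5.0 and flagged) and K2P, all with pairwise deletion. Neighbor
joining is the canonical Q-matrix algorithm with deterministic tie-breaking
by smallest taxon-label pair and negative branch estimates clamped to 0; it
is validated against additive matrices, random true trees, and scikit-bio's
implementation. NJ (plus optional column bootstrap) substitutes for
likelihood tree inference because downstream stages consume only the
grouping structure, not support values. Group assignment takes user-supplied
anchor genes — group boundaries in the real data were drawn by eye on a
tree, so anchors are inherently user input — and labels every leaf inside
the smallest clade containing a group's anchors (midpoint rooting if
unrooted; nested clades resolve to the smallest, with a warning).
Ladder-likeness is the Colless index normalized by its caterpillar maximum
(n−1)(n−2)/2; polytomies score their two largest subtrees; trees with <3
leaves are defined as 0.

## Chimeras and isoforms

Chimeras join exons 1..k of parent A (with A's introns) to exons k+1..end
of parent B, the junction falling where A's exon k ends and B's following
intron begins. The antidote CDS is the spliced sequence from the exon-1
start codon; the poison start prefers the exon-2 ATG over the intron-1 ATG
(no precedence is documented for the real genes; this order is a choice),
and a retained intron tail is included in frame for intron-1 starts.
`insert_poison_start` adds an ATG at the first codon boundary at the start
of exon 2 — the spliced product gains exactly one Met codon — and the
insertion is recorded so it can be reverted byte-identically.
`compare_poison_antidote` reports identity of the exon-(k+1)..end protein
segments between each poison and each antidote; this is a sequence-level
proxy for specificity and deliberately makes no claim about functional
detoxification, which is a wet-lab phenotype.

## Problem sizes and determinism

The test suite and acceptance script run entirely on simulated data at
desk scale: 20-taxon × 2 kb alignments for recombination statistics (50
clonal-null replicates in the acceptance script; 200 finite-sites
replicates for type-I calibration; 100 conversion-laden replicates for
power), 5-strain × 8-locus genomes for annotation recovery, N = 10⁴ and
500 replicates for Wright–Fisher checks, and 100 random 8 × 20 matrices
for the Rmin oracle. Every stochastic component takes an explicit integer
seed and is bit-reproducible; the only caches (Karlin–Altschul λ and K) are
seeded constants.

## Known limitations

- No indel evolution or alignment inference; real-data use requires
  externally produced alignments (any aligned FASTA is accepted).
- The E-value calibration is internal; absolute E-values differ from other
  search tools even though the threshold semantics match.
- Rmin is a lower bound on recombination events and is used only
  comparatively.
- The drive model ignores selfing/mating-type structure, spore-count
  compensation, aneuploid rescue, linkage and spatial structure.
- Anchor-based grouping cannot guarantee correspondence to any particular
  published group labelling; it reproduces whatever the supplied anchors
  define.
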
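# wtfkit

Analysis toolkit for **poison-antidote spore-killer gene families** — the
*wtf* family of fission yeast and systems like it.

Many *wtf* genes are one-gene meiotic drivers: a short transcript isoform
encodes a spore-killing poison, and a long isoform (starting one exon
earlier) encodes the matching antidote. All four spores of an ascus are
exposed to the poison; only spores inheriting the gene express the antidote
and survive, so the driver is transmitted to more than half of the viable
spores. The family diversifies fast — copy number varies strain to strain,
pseudogenes are common, and non-allelic gene conversion shuffles sequence
between members. A duplicate with the ancestral specificity cannot spread
(its poison is already detoxified by the ancestral antidote carried by every
spore), but a recombinant coupling a **novel** poison with its own antidote
can drive to fixation. `wtfkit` packages the comparative-genomic and
population-genetic machinery needed to study this process without any
external data downloads:

- **`family_sim`** — forward-time simulator of a multi-locus gene family on
  a random strain genealogy with point mutation, duplication to new loci,
  inter-member gene conversion (known breakpoints), pseudogenizing
  stop-gains, and locus-identifying flanks; emits genomes (FASTA), gene
  models (GFF3), exact "true" alignments and a full ground-truth event log.
- **`annotation`** — seeded local-alignment homology search (k-mer seeding,
  extreme-value E-values, default cutoff 1e-5), exon-structure transfer from
  reference models, pseudogene calling, poison-start (exon-2-ATG /
  intron-1-ATG) detection, solo-LTR flanking flags, and synteny-based locus
  assignment from 1 kb flanks.
- **`exon_network`** — all-vs-all exon identity (coverage-aware,
  free-end-gap global alignment), similarity graph at an identity threshold
  (default 0.50), connected-component clusters, identity heatmap table.
- **`recombination`** — pairwise homoplasy (PHI-style) permutation test,
  triplet breakpoint scan with exact maximum-descent p-values
  (Dunn–Šidák corrected), and Hudson–Kaplan minimum-recombination counts
  (Rmin) per ungapped bp for region/group comparisons.
- **`phylo_grouping`** — p/JC69/K2P distances, neighbor joining, anchor-based
  group assignment, and normalized Colless "ladder-likeness".
- **`chimera_isoform`** — exon-swap chimeras (e.g. exons 1–5 of one parent +
  exon 6 of another), poison/antidote isoform derivation, engineered
  poison-start insertion, PY-motif ([L/P]PxY) scanning, and a sequence-level
  comparison of poison vs antidote C-terminal segments.
- **`drive_dynamics`** — haploid Wright–Fisher model of poison-antidote
  drive with per-spore killing efficiency `c`. The deterministic recursion is
  `p' = p / (1 − c·p·(1−p))`.

## Worked example

Simulate a conversion-laden family of 20 gene copies (4 loci × 5 strains,
2 kb genes, ~8% between-locus divergence), then test for recombination:

```python
from wtfkit.family_sim import FamilySimParams, simulate_family
from wtfkit.recombination import phi_test, rmin

sim = simulate_family(FamilySimParams(
    n_strains=5, n_loci=4, generations=800, mu=5e-5,
    conv_rate=1.5e-3, dup_rate=0.0, pseudo_rate=0.0, seed=5))
print(len(sim.truth.events_of("conversion")))   # 16 logged conversion events
aln = sim.family_alignment()                    # 20 taxa x 2000 columns
res = phi_test(aln, seed=1)
print(res.statistic, res.p_perm)                # 0.1188  0.000999
print(rmin(aln).rmin)                           # 50
```

The homoplasy statistic (mean incompatibility of nearby informative-site
pairs) is *low* relative to its permutation null — nearby sites share local
trees while distant ones conflict — so p ≈ 0.001 (the smallest value 1000
permutations can resolve) correctly flags the 16 conversion events, and the
four-gamete bound requires at least 50 recombination events. On a clonal
control (`make_clonal_null`) the statistic is exactly 0 and p = 1.

Population consequence of the same distinction:

```python
from wtfkit.drive_dynamics import DriveParams, estimate_fixation_prob
rec = estimate_fixation_prob(DriveParams(N=1000, c=1.0, p0=0.01, seed=7),
                             "recombinant_novel_specificity", 500)
neu = estimate_fixation_prob(DriveParams(N=1000, c=0.0, p0=0.01, seed=8),
                             "novel_driver", 500)
print(rec.probability, neu.probability)         # 0.366  vs  0.020
```

A recombinant with a novel specificity fixes ~18× more often than a neutral
allele at the same starting frequency; a duplicate with the ancestral
specificity is exactly neutral (`duplicate_same_specificity`).

A CLI mirrors the library: `wtfkit simulate-family | simulate-drive |
annotate | exon-net | recomb | phylo | chimera` (see `wtfkit --help`).

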
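# Methods

## Scope and data model

The package analyses one aligned regulatory region across taxa. The central
object is an `Alignment` of equal-length IUPAC DNA rows (gaps `-` allowed;
`U` rejected — the data are genomic DNA; lowercase input is uppercased so
soft-masking cannot alter GC counts), paired 1:1 with a `SampleMetadata`
table assigning each sequence a species, a clade group (Haplorhini,
Strepsirrhini, or outgroup) and a behavior (Diurnal or Nocturnal). Outgroup
rows never enter the two-group statistics. All coordinates are 0-based,
half-open.

## Trimming

`trim_gappyout` removes gap-rich columns before analysis. Ambiguity codes
are not gaps: only `-` counts toward a column's gap fraction, matching the
distinction between alignment gaps and ambiguous base calls.

* **fixed** (default, `g_max = 0.2`): drop every column whose gap fraction
  exceeds the threshold. Deterministic and easy to reason about; with the
  defaults a deletion shared by ≥3 of 14 rows is removed.
* **auto**: sort the distinct per-column gap scores (1 − gap fraction)
  ascending, pair each score with the fraction of columns a cut at that
  score would remove, compute slopes between consecutive points of that
  curve, and cut at the point with the largest increase between consecutive
  slopes; columns strictly below the cut are removed. With fewer than three
  distinct scores the elbow is undefined: one distinct score keeps
  everything, two removes the gappier class. This is a documented,
  deterministic analogue of "gappyout"-style trimming, not a bit-exact
  replication of any external tool; users with real data can also pre-trim
  externally and run the pipeline with trimming disabled.

`complete_deletion` retains exactly the columns where every row is an
unambiguous A/C/G/T — the site filter applied before distance and
likelihood computations. Both the trimmed alignment length and each row's
ungapped length after trimming are reported, since either convention may be
wanted when summarising per-sequence coverage.

## GC content and the window scan

GC of any fragment is `100·(#G+#C)/(#A+#C+#G+#T)`; gaps and all ambiguity
codes are excluded from numerator and denominator (an ambiguous base
contributes nothing, not 0.5). A fragment with no unambiguous bases is
undefined and drops out of group statistics.

The scan slides a 500-column window in steps of 25 (both configurable).
Only complete windows are emitted, so every test carries equal information.
Per window, each group's mean, SD and a 95 % CI half-width
(`t_{0.975,n−1}·s/√n`) are computed, and the groups are compared with
Welch's unequal-variance *t*-test (two-sided; Welch–Satterthwaite df). The
degenerate case of two constant, equal groups returns t = 0, p = 1.

Multiplicity is handled by Bonferroni: the per-window level is `α/m`, where
m counts only testable windows (both groups with ≥2 defined values). m is
data-driven — for a ~3.3 kb trimmed alignment the scan has 113–114 windows,
giving a level of ≈0.00044 at α = 0.05 — so the level adapts when windows
become untestable (e.g. heavy deletions). Maximal runs of significant
windows at consecutive starts (exactly one step apart) merge into core
regions scored by the mean between-group GC difference.

The whole-region group summary (one GC value per sequence, Welch test
between groups) is the same machinery applied to single "windows" covering
the entire row; fed with the study panel's printed per-sequence GC values
it reproduces the published group means and p-values, which is the
package's printed-data cross-check.

## E-box conservation

`find_motif_sites` locates exact, possibly overlapping matches on the
gap-stripped reference row. CACGTG is its own reverse complement, so one
strand suffices; non-palindromic motifs are searched on both strands with
the strand reported. Hits are projected to alignment columns through the
reference's gap structure, and each taxon's characters at those columns are
classified: conserved, substituted (with per-offset from→to changes),
ambiguous (e.g. an S heterozygote), or gapped. The trait-partition test
asks, per motif offset, whether the observed characters split perfectly by
trait level; taxa with a gap anywhere in the motif are excluded (absence of
the site is not an allele), as are ambiguous characters at the offset. The
default reference is the human-like row when present.

## Phylogenetics

The substitution model is HKY85 — empirical base frequencies (counted from
the complete-deletion matrix, not ML-optimised; standard and cheaper, and
exposed as a config point), a transition/transversion rate ratio κ — with
among-site rate variation as a discrete gamma: n = 4 equal-probability
categories whose rates are the bin means (computed from incomplete gamma
functions), normalised to average 1. The rate matrix is scaled to one
expected substitution per site per unit branch length. Transition matrices
come from the symmetrised eigendecomposition `S = D^{1/2} Q D^{-1/2}`,
which is exact for a reversible Q and keeps likelihood invariant under
re-rooting (a property the test suite checks explicitly).

Likelihoods use Felsenstein pruning over site patterns compressed with
multiplicities, with per-node rescaling against underflow. The search:

1. start tree: neighbor joining on Kimura-2-parameter distances
   (`d = −½ln(1−2P−Q) − ¼ln(1−2Q)`; saturated pairs are flagged and capped
   at 5 substitutions/site); Q-criterion ties break on the
   lexicographically smallest cluster pair, and negative NJ branch lengths
   are clamped to zero with a warning;
2. cycles of bounded one-dimensional optimisation (branch lengths to
   tolerance 1e−6 within [1e−8, 10]; κ within [0.05, 100]; α likewise
   unless fixed) and nearest-neighbor-interchange sweeps that accept only
   improvements, until a full cycle gains < 1e−4 log-likelihood units.
   α can be fixed (the pipeline default fixes it at 1.9765, the shape
   value reported for this region) or jointly optimised.

Bootstrap supports resample complete-deletion columns with replacement;
each replicate refits from the ML tree (branch lengths + NNI, substitution
parameters held fixed) and the support of each internal split of the
reference tree is the percentage of replicate trees containing it. The
seed is mandatory, so supports are exactly reproducible.

The monophyly test roots the tree at the outgroup and, for each trait
level, finds the smallest clade containing all that level's tips; the
number of intruders (clade size minus level size) is reported. On the
species-tree fixture for the study panel, the diurnal taxa are not
monophyletic (the nocturnal owl monkey and tarsier nest inside Haplorhini;
5 intruders), while the two suborders are — the tree reflects phylogeny,
not diel habit.

## Synthetic data

The generator evolves each site independently along a given tree under HKY
with a discrete-gamma rate draw per site, but with a position-dependent
equilibrium: at position x the stationary frequencies are
`π_G = π_C = g(x)/2`, `π_A = π_T = (1−g(x))/2` for a piecewise-linear GC
profile g (default: ramp from 55 % distal to 62 % near the third planted
E-box, then easing to 60 % — the proximal GC rise typical of promoter
regions). Matrix exponentials are cached per (GC-bin, category-scaled
branch length) pair; GC is binned at 0.0025 for caching, far below the
noise floor of a 500-site window.

Trait-linked cores depress the target GC by `delta_gc` for the maximal
subtrees whose tips all carry the affected trait. Because composition
relaxes toward a new equilibrium at roughly one unit per unit branch
length, merely switching the equilibrium on primate-scale branches
(0.03–0.08 substitutions/site) would realise only a small fraction of the
shift at the tips. The generator therefore applies the shift as a
compositional jump at the stem of each affected subtree — core sites are
redrawn from the shifted equilibrium there — followed by ordinary evolution
under the shifted equilibrium inside the subtree. This emulates convergent
compositional shifts old enough to be near their new equilibrium, which is
the regime the window scan is designed to detect; it is a modelling choice,
not a mechanism claim.

E-box hexamers are overwritten post hoc at fixed positions (conservation
state is all the analysis reads), with optional per-tip substitutions —
the paper-like preset plants the heterozygous S in the greater-galago row
of the first E-box and the two singleton substitutions (C→T tarsier-like,
C→A marmoset-like) in the second. Deletions are applied as `-` runs: one
130 bp deletion in the marmoset/owl-monkey/tarsier rows inside the core
region, plus optional scattered 1–10 bp deletions (rate 1e−4 per site per
tip in the preset) that never touch motif columns. Everything planted is
recorded in a truth JSON.

Presets: `paper_like_config` (14 primates on a species-tree-shaped newick
with plausible promoter-scale branch lengths, 4 kb, one core at columns
[L/4, 3L/8) with ΔGC = 0.08 affecting the nocturnal taxa),
`star_null_config` (the same panel with no shared internal branches and no
cores — the exchangeable null), and `six_taxon_config` (three
well-separated cherries, 5 kb — strong signal for topology/bootstrap
checks). `table1_fixture` returns the 15-row panel metadata and the
species-tree newick, and the module also carries the panel's printed
per-sequence GC values for the printed-data cross-checks.

### What the synthetic data does and does not emulate

It reproduces the statistical structure the analysis assumes:
tree-structured substitution, a proximal GC ramp, trait-linked
compositional cores, conserved motifs with isolated substitutions, and
indels. It does not attempt the real sequences, context-dependent (CpG)
mutation, selection on motifs (motifs are overwritten, not evolved under
constraint), or recombination/alignment error. Passing recovery tests
therefore show the pipeline detects the signal class it targets under its
own assumptions — not that real promoters satisfy those assumptions.

### Calibration and a known limitation

Family-wise error control of the Bonferroni scan is a statement about
independent samples. Under the exchangeable null (star phylogeny, no
cores) the measured FWER is below α, as it should be. Under the species
tree with no cores the same scan is markedly anti-conservative (observed
FWER ≈ 0.3–0.4 at α = 0.05): the diel trait is confounded with clades
(all catarrhines diurnal, all galagos nocturnal), so shared-ancestry GC
drift produces group differences that a taxa-as-independent-samples t-test
mistakes for signal. No multiplicity correction can repair that; it is a
property of applying Welch's test across phylogenetically structured taxa,
and the reason comparative studies treat "the difference might simply
reflect phylogeny" as a caveat. Both numbers are reported by the
acceptance script so the contrast is visible rather than hidden.

## Numerical choices and problem sizes

* Branch lengths live in [1e−8, 10]; K80 saturation cap 5.0.
* Likelihood rescaling is per internal node, per category, tracked in log
  space; category mixing uses log-sum-exp.
* NNI tie-breaks: first improving alternative wins within an edge; sweeps
  repeat only while something improves.
* The default test and acceptance runs use scaled-down problem sizes chosen
  to exercise every code path with comfortable statistical margins: 4 kb /
  14 taxa for scan recovery, 200 star-null replicates for the FWER
  estimate, 5 kb / 6 taxa with 100 bootstrap replicates for tree behaviour.
* Determinism: every stochastic step takes an explicit seed; the same
  config and seed give byte-identical FASTA/TSV/JSON outputs.

## Limitations

* The window scan inherits the published test's phylogenetic
  non-independence (above); a phylogeny-aware contrast (e.g. generalised
  least squares on the tree) is out of scope by design.
* The trimming "auto" rule is an elbow heuristic, not a reimplementation of
  any specific tool's internals.
* The ML search is NNI-only hill climbing; for the small taxon sets this
  pipeline targets that reliably finds the optimum, but it is not an
  SPR/TBR search and offers no model selection beyond fixing or fitting α.
* Bootstrap replicates refit from the reference tree with substitution
  parameters fixed — the standard fast approximation; supports on very weak
  data may be slightly optimistic.
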
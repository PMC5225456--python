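# Methods

## The screen

`mirprop` implements a two-arm computational screen for miRNAs that
regulate a gene program of interest (here: drug-addiction genes profiled
in the nucleus accumbens), followed by the small sequence/assay
computations used to validate an individual candidate.

**Arm 1 — network prioritization.** Each conserved miRNA family is
represented by its predicted target set. Because a miRNA that hits a
transcription factor perturbs the TF's whole regulon, the direct-target
perturbation is diffused through a directed TF→gene regulatory network
and the diffused profile is tested for enrichment of high-reliability
addiction genes (the NPES statistic).

**Arm 2 — expression screen.** A two-group (control vs chronic-treatment)
miRNA microarray is median-normalized per array and filtered on group
fold change (≥ 1.25 up or ≤ 0.75 down, inclusive and asymmetric as
stated).

Candidates are the differentially expressed miRNAs whose family is
significant in arm 1, ranked significance-first (family q ascending, then
NPES descending, then miRNA id).

## Network propagation

The operator is random walk with restart. With
`T[v,u] = 1/indegree(v)` for each regulation edge `u → v` (each gene's
incoming weights sum to 1; parentless genes receive nothing), the effect
vector solves

    p = (1 − α)·T p + α·p0,      p0 uniform on the family's targets,

iterated to L1 change < `tolerance` (default 1e-8), equivalently
`p = α (I − (1−α)T)⁻¹ p0`, which is the dense oracle used in tests.
Defaults: `restart_alpha = 0.5`, `max_iterations = 1000`. Direction
follows regulation (TF → regulon); an `upstream` mode transposes `T`.

Numerical notes:

* Convergence is guaranteed: `T` is row-sub-stochastic, so
  ρ((1−α)T) ≤ 1−α < 1.
* **Mass is not conserved.** In-degree normalization gives every child the
  full (normalized) mass of its parents, so a hub regulator with several
  single-parent children duplicates mass and ‖p‖₁ may exceed 1 (e.g. a
  depth-2 binary tree at α = 0.3 yields ‖p‖₁ ≈ 1.31). Only the ranking of
  effects is consumed downstream, where overall scale is irrelevant.
* Families with no target inside the gene universe are skipped and
  logged, mirroring the upstream conservation filter.
* Ranking ties (ubiquitous among genes the walk never reaches, all at
  effect 0) break lexicographically by gene id, so every ranking is
  machine-reproducible.

## NPES and significance

Genes are ranked by descending propagated effect and walked top-down.
With addiction-gene weights `w_g = log(reliability_g)` (natural log;
configurable base), a scored gene at rank `i` adds `w_i / Σ|w|` and an
unscored gene subtracts `1/(N − N_hit)`. NPES is the maximum of the
running sum; the leading edge is the set of scored genes at or before the
first rank attaining it. Weights may be negative (reliability < 1);
they are used as-is, with the normalizing constant Σ|w| taken over
absolute values, so NPES stays in [−1, 1] and is invariant to positive
rescaling of all weights.

Significance is a gene-label permutation null: which universe genes carry
the weights is re-drawn uniformly without replacement (the effect ranking
stays fixed), NPES is recomputed, and

    p = (1 + #{null NPES ≥ observed}) / (1 + n_permutations)

(default 1000 permutations; the achievable minimum is 1/(n+1)). The
choice of a gene-label null rather than a target-set null keeps the fixed
network fixed and is calibrated by construction; the acceptance script
measures an empirical type-I error of ≈ 0.05 at nominal 0.05. Across
families, Benjamini–Hochberg q-values (statsmodels) control the FDR at
0.05; negative NPES is reported but never flagged significant, since the
screen seeks positive enrichment only. The permutation null is computed
in vectorized batches (increment matrix → cumulative sum → row maxima),
so a 1000-permutation test on a 500-gene universe takes milliseconds.

## Differential expression

Each array is divided by its own median and rescaled by the grand mean of
the original medians (scale-preserving; idempotent to floating-point
tolerance). Group summaries are arithmetic means by default (`median`
available); fold change is CH/CS on the linear scale. Thresholds are
inclusive and compared with a 1e-9 relative tolerance so a signal at
exactly 1.25× passes regardless of normalization arithmetic. No variance
filter or moderated test is applied: the screen is fold-change-only by
design, with the enrichment arm carrying the statistical burden.

A caveat worth knowing: median normalization is not exactly the identity
even on noise-free data. If a truly changed miRNA sits near an array's
median, its change shifts that median and rescales the whole column by a
fraction of a percent. This is immaterial for the default planted folds
(0.5 and 2.0) but flips folds placed exactly at the 1.25/0.75 boundary at
some seeds; the filter-exactness check therefore applies the filter to the
noise-free matrix directly, whose columns are on a common scale by
construction.

## Synthetic study conditions

The generator produces every input with planted ground truth. Defaults
(one integer seed reproduces everything; each generator derives a child
RNG stream):

| parameter | default | role |
|---|---|---|
| n_genes / n_tfs | 500 / 50 | gene universe; TFs are the first 50 ids |
| edges_per_tf | 10 | each TF regulates 10 distinct genes |
| attachment | in-degree + 1 | preferential attachment ⇒ hub targets |
| n_addiction_genes | 100 | membership ∝ in-degree + 1 |
| reliability | log-normal(1, 1) | largest scores on most-regulated genes |
| n_families / targets_per_family | 50 / 30 | conservation drawn U(2, 6) |
| planted_family_count | 1 (`fam001`) | planted families are the first ids |
| planted_overlap_fraction | 0.6 | fraction of targets from the enriched pool |
| enriched pool | addiction genes ∪ TFs upstream of them | |
| n_mirnas_on_array | 300 | family members + anonymous filler probes |
| samples_per_group | 4 | CS (control) vs CH (treated) |
| planted folds | miR-001a × 0.5, miR-005b × 2.0 | a down-regulated planted-family member (the validated-candidate phenotype) plus an up-regulated background decoy |
| signal_log_sd / array_scale_sd | 0.25 / 0.3 | per-signal noise; per-array scale the normalization must undo |

Every fifth family carries two array members, so candidate miRNA counts
can exceed family counts, as in the real screen's 16-miRNAs/14-families
pattern.

What the generator emulates: hub-structured regulation, heavy-tailed
evidence scores concentrated on regulated genes, a planted
addiction-targeting family, and multiplicative array effects. What it
does not: realistic genome-scale topology, probe-level microarray noise
(dye bias, spatial artifacts), correlated miRNA co-expression, or
database-version effects. Consequently, passing the planted-recovery
check shows the pipeline's stages compose correctly and detect the
planted structure under the stated noise; it does not certify performance
on real TargetScan/HTRIdb/KARG inputs, whose headline counts depend on
database versions.

With these conditions, note that many *background* families also reach
significance: background targets hit TFs by chance, TF regulons
concentrate on hubs, and addiction genes are hub-biased — so their
enrichment is real, not a calibration failure (the calibration check uses
scores placed independently of the ranking, where type-I error is ≈5%).
The planted family is distinguished by construction strength, and the DE
arm provides the discriminating intersection.

## Problem sizes in the checks

The oracle comparisons use 50 random digraphs of ≤200 genes (propagation)
and 100 random lists of ≤1000 genes (running sum); null calibration uses
2000 lists of 200 genes with 20 scored genes and 500 permutations each;
planted recovery runs the full default-size pipeline on 20 seeds with
1000 permutations per family. The whole acceptance script completes in
well under a minute on one CPU apart from the calibration sweep, which
dominates at a few seconds.

## Sequence and assay utilities

Seed = miRNA positions 2–8. Motifs: 7mer-m8 = revcomp(2–8);
6mer = revcomp(2–7); 7mer-A1 = 6mer + `A`; 8mer = 7mer-m8 + `A` (the
site's A1 adenosine is literal, independent of the miRNA's first base).
Scanning reports each locus once as its longest matching type
(`report_all=True` exposes nested matches). Coordinates are 0-based
half-open on the supplied insert. Of the eight published miR-218 3′UTR
inserts, four carry 7mer-m8 sites (Gabrb3, GluR2, Nrxn1, Mecp2 — the
Mecp2 site at [22, 29)), two carry 7mer-A1 (Dnmt3a, Ube3a) and two carry
full 8mers (Sema6b, Gng3), which subsume their nested 7mers.

Seed-region mutants replace the matched site with its complement (not
reverse complement), abolishing Watson–Crick pairing while preserving
length; the mutant is re-scanned, a reverse-complement fallback is tried
if the substitution accidentally creates a new canonical site, and an
error is raised otherwise. The construct actually used in the published
assay is not recoverable; this rule is the package's own deterministic
choice.

Dual-luciferase wells are normalized as Renilla/Firefly per well, divided
by the mean scramble-treatment ratio of the same UTR construct (so each
construct's scramble group has mean 1). qPCR relative expression is
2^−ΔΔCt with ΔΔCt = ΔCt(treated) − ΔCt(control), ΔCt = Ct_target −
Ct_reference; swapping groups inverts the result.

## Known limitations

* The propagation operator, restart probability and convergence rule are
  this package's declared contract; published network-propagation tools
  differ in operator details, and results are not interchangeable.
* The permutation/FDR procedure is likewise a declared choice; the screen
  it emulates did not state one.
* Genuine TargetScan/HTRIdb/KARG/GEO file layouts are out of scope; the
  readers define minimal tab-separated dialects that an adapter layer
  would map real exports onto.
* With add-one p-values and m families under BH, a family can only reach
  q ≤ 0.05 when its p is at the permutation floor for m ≳ 50; raise
  `n_permutations` when screening many families at strict FDR.
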
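# Methods

## Fragment coordinate system

The unit of analysis is the restriction fragment of the primary six-cutter.
Digestion scans the forward strand for the literal recognition motif
(HindIII A^AGCTT, EcoRI G^AATTC, Csp6I G^TAC — standard REBASE
specificities) and cuts at `motif_start + cut_offset`; all three motifs are
palindromic, so forward-strand scanning is complete, and non-palindromic
motifs are rejected rather than silently mishandled. Fragments tile each
chromosome without gaps (0-based, half-open, BED convention) and the tiling
is asserted after every digestion. A fragment with no secondary-enzyme
motif is flagged *blind*: it cannot form the nested ligation circle and is
excluded from statistics by default (toggle available). Counting is at
whole-primary-fragment resolution; the finer fragment-*end* resolution used
by some 4C tools (splitting primary fragments at secondary sites) is
deliberately not implemented — interactions are reported at fragment
resolution throughout, and the simplification is isolated in the
restriction module.

## Quantification

Each mapped read increments the fragment containing its 5′ alignment
position (4C reads begin at restriction sites, making the 5′ end the
unambiguous anchor; strand-aware when reading BAM). Duplicates are kept.
RPKM = raw / (fragment_kb × total_mapped_millions); the fragment-length
normalisation follows RPKM's literal definition and is switchable for
count tables produced under a unit-length convention. The bait fragment
and 2 fragments on each side are excluded from all statistics
(self-ligation and incomplete digestion dominate there); exclusion is
silently truncated at chromosome ends. Library QC is the cis fraction —
reads on the bait chromosome over all mapped reads — with a 0.40 floor.

## Cis interaction calling

* **Variance-stabilising transform**: x = log2(RPKM + 1). Monotone,
  parameter-free, 0 at 0; sqrt(RPKM) is available as an alternative. No
  count-model VST is fitted — with two replicates per condition there is
  too little replication to estimate per-fragment dispersions stably.
* **Decay trend**: isotonic (monotone non-increasing) regression of x on
  log10 distance, fitted separately per sample and per side of the bait
  (upstream/downstream), requiring ≥ 10 fragments per side. Isotonic
  regression enforces exactly the one property the physics implies —
  monotone decay — without choosing a spline family, and has an exact
  pool-adjacent-violators oracle for testing. Distances are measured
  bait-fragment midpoint to fragment midpoint; prediction between fitted
  knots is linear interpolation in log10 d, clipped at the range ends.
* **Scale**: σ = 1.4826 × median |residual| per side, floored at 1e-6 so a
  degenerate flat profile cannot produce infinite z-scores. The robust
  (MAD) estimator keeps planted or real enrichments from inflating σ.
* **Significance**: z = (x − fitted)/σ; one-sided upper-tail normal p
  (only gained contacts are called); BH adjustment per sample across the
  whole ±2 Mb window (excluded and blind fragments omitted from m). A
  fragment is significant iff z ≥ z_threshold and FDR ≤ 0.05 in **all**
  replicates; the default z threshold is 2.0, with 1.5 intended for
  weak-signal baits.
* **Merging**: runs of significant fragments separated by at most one
  non-significant fragment merge into a single reported interaction,
  scored by the cross-replicate mean z of the member fragments. The gap
  tolerance is a parameter; no published merging rule exists to match.

## Differential contacts

For each fragment, the replicate-averaged z-scores of the two conditions
are compared as ratio = max(z̄_num, ε)/max(z̄_den, ε) with ε = 0.1 guarding
non-positive means. A fragment is condition-gaining iff the ratio in that
orientation is ≥ 1.5 **and** the gaining condition itself calls the
fragment significant (z and FDR in every replicate) — without the
significance requirement the rule would report ratios between two noise
fragments. Both orientations are tested; they can never fire together
for thresholds > 1 because the two ratios are reciprocal.

**Known limitation**: a ratio of two noisy z-scores is itself noisy. On
synthetic data where both conditions carry identical planted signal
(fold 4), roughly 10% of significant fragments still cross the 1.5 ratio
across exchangeable draws; the rate falls as planted z grows. Under a
fully exchangeable null with no planted signal, differential calls are
essentially absent (≲ 0.05% of fragments) because the gaining-condition
significance requirement screens them out. A count-model differential test
(negative-binomial Wald) would control the matched-signal case more
tightly but is out of scope here.

## Trans domains

Fragments of each non-bait chromosome (blind and excluded removed) are
pooled into consecutive windows of k = 20; the window signal is
log2(summed RPKM + 1). Each replicate's track is segmented by a Gaussian
hidden Markov model fitted by EM with 10 seeded restarts (max-likelihood
converged fit wins, ties to the lowest seed; restarts that fail to
converge or leave unreachable states are discarded). The state count is
chosen by BIC over {2, 3}: capping at 3 preserves the no/low/high reading,
while the BIC step prevents a two-level track from being force-split into
three states — the maximum-likelihood 3-state fit on background-plus-block
data frequently splits the *block*, which would truncate real domains.
States are relabelled by ascending emission mean and the top state is
always reported as "high", making the label invariant to initialisation
and to the selected state count. A window is domain-eligible when high in
n = 2 replicates; maximal eligible runs are the reported domains. The
replicate-support reading of n follows the study design (two biological
replicates per condition).

## Genomic context

An interaction is assigned to a TAD iff it lies within the TAD expanded by
the tolerance (200 kb by default) on both sides — containment, not mere
intersection, reflecting TADs as insulating containers; an intersect mode
is available by flag. TADs and subTADs may nest; all qualifying TADs are
returned. Hi-C comparison is the elementwise log2((A + pc)/(B + pc)) of
two normalised matrices on an identical bin grid (dense TSV or COO input;
binary Hi-C containers are out of scope); "increased" bins are marked by a
configurable log2-ratio threshold (default 1.0), a documented stand-in for
a published definition that is external to this package.

## Synthetic data

The generator emulates the statistical shape of fragment-level 4C data,
not its sequence-level mechanics:

* expected RPKM decays as a·(d/1 kb)^(−α) with α = 1 (power-law decay on
  the 1 kb–2 Mb scale); expected *counts* carry the fragment length so the
  decay law holds on the RPKM scale. Distances are floored at 1 kb; the
  bait-proximal self-ligation peak is not emulated because those fragments
  are excluded from analysis anyway.
* raw counts are negative-binomial via a gamma–Poisson mixture with shape
  r (variance μ + μ²/r), independent across replicates; blind fragments
  draw 0. The default r = 20 (a DESeq2-style dispersion of 0.05) sits in
  the range reported for replicate 4C libraries and makes a 4-fold planted
  contact a comfortably callable effect, which is how the method behaves
  on real data of this design; r is fully configurable, and the caller's
  null calibration is verified separately down to r = 0.2.
* libraries have 1 M mapped reads with ~70% on the cis chromosome (clear
  of the 40% QC floor); trans background is flat in expected RPKM.
* planted structure: individual cis fragments at fold > 1, and window runs
  on a trans chromosome, each with a (diet, timepoint) activity mask so
  condition-specific interactomes can be emulated. Ground truth is
  serialised with every fixture; no test reads numbers from prose.
* two map routes: a genome route (uniform random DNA with motifs at their
  background rate — one six-cutter site per ~4 kb, so the default 5 Mb cis
  + 2 Mb trans genome yields ~1,200 + ~500 fragments) exercising the
  digestion machinery end to end, and a direct route drawing a random
  tiling with an exact fragment count (used for the 2,000-fragment
  calibration fixtures). Every output is a pure function of
  (config, seed).

What passing tests on this generator do **not** show: robustness to PCR
duplicates and primer artefacts, undigested-template background,
mappability holes, or dispersion heterogeneity across fragments — real
libraries contain all four, and the QC and exclusion rules only partially
address them.

## Orchestration

A study is 2 diets × 2 timepoints × n replicates per bait, validated for
completeness before running (missing cells are reported explicitly).
Temporal classification pools the merged intervals of the two timepoints
and merges on ≥ 1 bp overlap: intervals supported by both are stable
contacts, the rest belong to their single timepoint; the three classes
partition the pooled set by construction. Fragment-identity matching is
available as an alternative. All outputs are plain TSV/BED with no
timestamps, so a rerun on identical inputs is byte-identical; the run
report echoes every effective threshold, enzyme and seed.

## Problem sizes used in the checks

Calibration and recovery checks run on 2,000-fragment fixtures (50 null
simulations; 10 recovery seeds at fold 4; 5 seeds per fold for the dose
response), trans segmentation on 300-window tracks over 5 seeds, and the
oracle comparisons on 100 random genomes (1–50 kb), 1,000 isotonic
instances and all BH vectors up to length 8 on a seeded grid. These sizes
were chosen to estimate each rate stably while keeping the whole suite
fast enough to run on every change.
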
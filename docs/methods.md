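# Methods

This note records the models, parameter choices and numerical conventions
behind each stage, what the synthetic benchmark does and does not emulate,
and the known limitations.

## Hit calling

Each kinase assay is normalized per array: z = (I − μ)/σ with μ, σ over
the non-blacklisted spots of that array (population σ, n-denominator; at
hundreds of spots the n−1 distinction is far below the 3-SD decision
boundary). A spot is a hit when z ≥ `sd_multiplier` (default 3.0, the
standard cutoff for this assay type). Per-array normalization makes the
call invariant under affine rescaling of an array, which absorbs
exposure/labeling differences between assays.

The blacklist is learned from the no-kinase control array with the same
rule (`control_sd_multiplier`, default 3.0): proteins above μ + 3σ of the
control autophosphorylate or bind ATP and are removed from every assay
before normalization. Degenerate arrays (σ = 0) yield no hits/no
blacklist, with a warning.

Intensities are used untransformed by default; a `log_transform` flag
(log1p before z-scoring) exists because spot intensities are often
right-skewed, but it is off by default. Replicate agreement is reported as
Pearson r of log1p intensities over shared proteins (≥ 3 required).

## Naive-Bayes refinement

Three pair features: tissue co-expression (Pearson r over tissues where
both proteins are measured; missing if fewer than 3 shared tissues),
co-localization (shared subcellular compartment, binary), and PPI
(direct edge or ≥ 1 shared neighbor — path length ≤ 2 as the reading of
"indirect" interaction; binary).

The continuous co-expression feature is discretized into `n_bins = 5`
equal-width bins on [−1, 1]; binary features into {0, 1}. Every feature
has an explicit *missing* bin rather than imputation: annotation coverage
differs systematically between kinase families, and that information is
itself weakly predictive. Bin probabilities carry a Laplace pseudocount of
1. The L-score is the sum over features of log2 P(bin|positive)/
P(bin|negative). A feature with a single observed value across both
training sets is degenerate and its LLR is forced to exactly 0.

p-values are empirical against the trained negative-set scores:
p = (1 + #{negatives ≥ L})/(n_neg + 1). The +1 smoothing keeps p in
(0, 1] and makes negative-set p-values super-uniform. Because L takes
finitely many values (bin combinations), these p-values are conservative:
the realized fraction of null edges passing p < α sits at or slightly
below α. Refinement keeps edges with p < α (default 0.05); the combined
set is the pair-level union with literature-known KSRs, known edges
winning (they carry no p-value; overlap is flagged, and the refined
scores are retained on overlapping edges).

Cross-validation folds the positives k ways (default 5), trains on the
rest (negatives bootstrap-resampled per fold), ranks raw edges by L-score
(stable ties: kinase then substrate id), and compares held-out recovery in
the top-n against the random expectation n/|raw|, where n is the refined
count at α, floored at ⌈α·|raw|⌉ so an uninformative model is scored
against a non-empty list (and correctly yields enrichment ≈ 1).

## M3 motif discovery

Windows are 15-mers centered on the phosphosite, padded with `-` at
protein termini; the pad is a 21st alphabet letter with its own background
frequency, which avoids biasing against near-terminal sites. Unknown
residues (X) are encoded like the pad (uninformative).

Scores are log-odds in bits, Σ_j log2 fg(w_j, j)/bg(w_j, j), against a
background PWM built from *all* phosphosite windows of the same residue
class — pS/pT and pY chemistry and flanking composition differ, and a
dual-specificity kinase yields one motif per class. The center column is
included in scoring.

The search: (1) frequency matrix from all foreground windows
(pseudocount 0.5), score every window; (2) top `seed_size = 10` windows
(ties broken lexicographically on the window string, then protein id and
position — full determinism) seed the PWM; (3) iteratively admit the
single best remaining window, rebuilding the PWM each time. A candidate is
admitted only if its score is strictly positive *and* at least the random
cutoff: the `cutoff_percentile = 0.99` quantile of `n_random = 10 000`
windows resampled with replacement from the class background, rescored
each iteration against the current seed PWM (the conservative reading of
an ambiguous stopping rule). The search also stops at the kinase's
substrate count, or when windows run out. Foregrounds smaller than
`seed_size` become the seed set outright, with a warning.

The strictly-positive requirement covers the degenerate foreground ==
background case (all scores 0, cutoff 0): without it the search would
absorb everything at score 0.

Consensus strings: per column, uppercase letter when the top amino acid
holds ≥ 0.5 probability, lowercase in [0.25, 0.5), `x` otherwise; the
center renders as the class letter (s/t/y).

In the full pipeline, motif discovery for a kinase is restricted to its
declared residue class (kinome-family knowledge, carried as metadata by
the generator): without this, a serine kinase whose substrates happen to
carry a few decoy tyrosine sites would receive a meaningless Y "motif"
fitted to those decoys, which then re-assigns its own training windows as
false site edges. Classes with fewer than `min_foreground = 3` peptides
are skipped.

## Motif comparison

Similarity between two PWMs is the mean Pearson correlation of the
20-dimensional probability columns (pad row dropped, columns
renormalized), excluding the center column — it is class-constrained in
both motifs and would inflate similarity. A narrower motif is
center-aligned and padded with background columns; zero-variance columns
contribute correlation 0 by definition. Significance comes from shuffling
the non-center columns of one motif (p = (1 + #{null ≥ score})/(n+1),
default 999 permutations): the null preserves per-column information
content, a stricter reference than i.i.d. random columns. No offset
search is performed — the phospho-center fixes the register. The p < 0.05
convention is the default matching cutoff, exposed as a parameter.

## Site assignment and map metrics

"Unambiguously assigned" is operationalized as: the site's window scores
at or above the kinase motif's own random cutoff (`final_cutoff`),
overridable via `min_score`. A site may be claimed by several kinases.
Known/novel status is flagged against the site-specific known list;
recovery rate = 100·recovered/known, FNR = 100 − recovery,
TPR = 100·recovered/edges. Reported percentages use one decimal (two when
below 1%); exact values are retained.

This cutoff choice is deliberately conservative at benchmark scale: the
background from which the cutoff is resampled contains the kinase's own
substrate sites, and when those make up more than ~1% of the class
background (inevitable with a desk-scale proteome; negligible against a
real phosphoproteome of tens of thousands of sites) the 99th-percentile
cutoff climbs into the planted score range and true sites below it are
rejected. Default-benchmark site recall (~0.5) reflects this; precision
stays at 1.0. In the noiseless, fully-sharp limit all planted windows tie
at the maximum score, the cutoff equals that score, and assignment is
exact (precision = recall = 1), which the test suite pins.

## Synthetic benchmark

Defaults (one realization per seed; all randomness flows through a single
`numpy` generator — byte-identical outputs on reruns):

- 6 kinases (every fifth a tyrosine kinase; S/T kinases get a fixed
  acceptor, 80% serine), 300 proteins of length 80–160 drawn i.i.d. from
  proteome-average amino-acid frequencies (hard-coded table).
- 10 substrates per kinase (sampled disjointly), 3 true sites per
  substrate at non-overlapping window slots, windows drawn from the
  kinase's planted PWM (`motif_sharpness = 0.9` probability mass on a
  random consensus letter per column, remainder background-proportional)
  and spliced into the sequence.
- 6 decoy sites per protein at naturally occurring S/T/Y residues — with
  true sites, ~6–7 sites per protein, matching in-vivo phosphoproteome
  density (~70k sites over ~10k proteins).
- Spot intensities: baseline 10 + signal 8 on true pairs and blacklist
  proteins (8× the default noise SD of 1, so default 3-SD calling operates
  well off the boundary; the signal is absolute so the noise → 0 limit is
  meaningful), Gaussian noise, clipped at 0. 10 blacklist proteins light
  up on every array including the control.
- Annotations: 15 tissues (independent N(0,1) profiles give null
  co-expression SD ≈ 0.27, matching the intended N(0, 0.3) null); true
  substrates are generated at Pearson ρ ~ N(0.6, 0.2) to their kinase.
  Compartments from a weighted 8-label pool with forced sharing on true
  pairs (target rates 0.8 vs ~0.2); a random PPI graph with planted direct
  edges (target feature rates 0.7 vs ~0.1). The compartment and graph
  constructions hit their targets approximately (collision and
  shared-neighbor rates are controlled by label weights and mean degree);
  `simulate_pair_features` draws features *directly* at the stated rates
  for calibration-sensitive tests. 10% of proteins lack each annotation.
- 30% of true pairs are exported as "known" (training positives and the
  known site-specific list), leaving held-out truth for cross-validation.

What the generator does **not** emulate: protein domain structure and
sequence correlations (sequences are i.i.d.), substrate sharing between
kinases (substrate sets are disjoint), multi-motif kinases, abundance-
dependent MS detection bias, and spatial array artifacts. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated generative model, not performance on real arrays.

## Problem sizes

The default benchmark (6 kinases × 300 proteins, ~780 sites, 10 000-window
cutoff resampling per iteration, 10 000 Bayes negatives) runs end to end
in a few seconds on one core; the full test suite, including the
500-pair permutation-null calibration and ten-seed recovery sweeps,
completes in well under a minute.

## Known limitations

- The empirical p-value's discreteness makes refinement slightly
  conservative (see above); with 5 bins the effect is a percentage point
  or two at α = 0.05.
- Site assignment reports no multiplicity control when several kinases
  claim one site; whether real maps capped multiplicity is unknown.
- Ambiguous MS site localizations are out of scope: site tables are
  assumed to carry unambiguous single-residue rows, and rows that
  contradict the sequence are dropped and counted rather than rescued.
- The cross-validation enrichment depends on the negative-pool
  composition; pools accidentally enriched for true-pair-like features
  deflate it.
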
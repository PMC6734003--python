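# Methods

## The model

`m6acall` detects m6A at the level of reference sites, from aggregate
base-calling behaviour rather than raw signal. The underlying assumption
is that a base-caller trained on unmodified RNA responds to a modified
base — and, through the 5-mer context the pore reads, to its immediate
neighbours — with a *systematic* change in its output: per-base quality
drops, mismatch and deletion frequencies rise. Insertions also occur but
are not reproducible across replicates, so they are extracted and then
ignored by the default models. Because the effect is systematic, it
survives averaging over reads, and a site's feature vector becomes a
stable fingerprint of its modification status.

A support vector machine is trained on windows from a fully
characterized pair of conditions (modified vs unmodified versions of the
same sequences) and applied per site. Per-replicate probabilities
s₁..sₙ are merged into a modification score M (1 if every replicate is
at or above 0.5, otherwise their mean; the boundary is inclusive), and a
site is called modified when M_wt/M_ko > 1.5 and M_wt > 0.5. Division by
M_ko = 0 yields an infinite ratio by policy, so such sites are callable
whenever M_wt qualifies; this degenerate case is not otherwise special.

## Sequence design

Training constructs must present every 5-mer to the pore with minimal
secondary structure (structured RNA translocates poorly and folds during
in vitro transcription). The generator walks a randomized Eulerian
circuit on the 4-mer de Bruijn multigraph in which each 5-mer edge has a
configurable multiplicity (default 10), giving a superstring in which
every 5-mer occurs exactly `kmer_copies` times (~10.3 kb at the
default). Twenty candidates are generated per design and scored with
`structure_penalty` — the number of position pairs whose
`min_stem_len`-long words (default 6) are perfect reverse complements
separated by at least `min_loop_len` (default 3) unpaired bases — a
deterministic O(L log L) proxy for a thermodynamic folding prediction.
The scorer is deliberately pluggable: it ranks candidates, nothing more.
The winning superstring is cut into `n_parts` (default 4) synthesis
parts; each non-final part duplicates k−1 letters past its cut so every
5-mer survives the split, and cut points are placed so emitted part
lengths are as equal as possible (tolerance 10% by default). Sequences
are stored DNA-sense (U→T, uppercase) because base-called reads and
alignments use T. No promoter or restriction-site handling is done.

## The read simulator

The simulator emits, per read, one record for every reference position
(call A/C/G/T or DEL, integer Phred quality clamped to [1, 40], and any
inserted bases left-anchored to the position they follow), plus per-read
current events for every 5-mer window. Outcome per position is a single
categorical draw (deletion with p_del, mismatch with p_mis, else match),
so empirical frequencies converge exactly to the configured
probabilities; substitutions are uniform over the three non-reference
letters unless a profile is given. Reads are full length — fragmentation
is irrelevant to per-site frequency statistics — and the number of
modified reads is deterministic, `round(coverage x fraction)`, which
removes one noise source from mixture experiments. Replicates derive
independent sub-seeds from a CRC32 hash of (seed, condition, replicate),
so every dataset is a reproducible function of its arguments.

Modification effects add `mismatch_delta` (+0.10), `deletion_delta`
(+0.05), `quality_shift` (−3 Phred) and, for event windows covering a
modified base, `current_shift` (+3 pA) at modified positions of modified
reads; `insertion_delta` defaults to 0, making insertion frequency
condition-independent. A fraction of each delta bleeds to neighbours
(0.25 at ±1, 0.1 at ±2), reflecting the 5-mer context the pore reads;
set `neighbor_bleed=(0,0)` to disable. These effect sizes are tunable
defaults chosen to be of the order seen in direct RNA data, not measured
constants.

Three deterministic k-mer-dependent components add realism, all derived
from a CRC32 hash of the centred 5-mer (so they are identical across
runs, replicates and conditions, like a pore's true k-mer response):

* baseline current level, spread 8 pA — pore current is strongly k-mer
  dependent, which is what makes a raw current value a poor site
  classifier (a ±3 pA shift hides inside an 8 pA between-k-mer spread);
* baseline mismatch/deletion rates (lognormal, σ=0.3) and base quality
  (normal, σ=1 Phred) — base-caller error is context dependent;
* the modification deltas themselves (lognormal, σ=0.4) — the
  contribution of each feature varies across k-mers, which is also what
  makes error patterns *reproducible across replicates of the same
  condition* but not across conditions.

What the simulator does **not** emulate: raw squiggle/translocation
physics, read truncation and coverage decay, alignment artefacts
(clipping, multi-mapping), homopolymer-specific deletion behaviour, and
any k-mer structure in *which* sites are modified. Passing tests
therefore demonstrate that the pipeline's statistics, classifier and
calling logic behave correctly under the stated error model — not that
real sequencing runs will reach the same accuracies.

## Feature extraction

Coordinates are 1-based (SAM convention; BED output is 0-based
half-open). The denominator of every per-site frequency is the spanning
coverage, reads that call the position **or delete it**; with that
single denominator, match + mismatch + deletion fractions sum to one and
insertion frequency is orthogonal. Mean quality is the arithmetic mean
of Phred values over non-deleted calls (not error-probability
averaging). Positions with zero coverage are emitted with missing
frequencies rather than dropped, and windows containing them are
flagged `has_missing` and skipped by the predictor with a recorded
reason. Reads are not quality- or MAPQ-filtered by default. Current
window statistics are the mean and sample standard deviation (ddof 1;
0 for a single read) of per-read window means.

## Classifier

Feature sets: `single:q0`, `single:mis0`, `single:del0`,
`single:curr_mean`, `single:curr_sd`, `combined3` (default) and
`extended15` (±2 context). `combined3` excludes current features
(poor predictors) and context features (the context model inflates false
positives on control k-mers). Training splits 75/25 stratified by label,
standardizes with training-split statistics only, fits each kernel with
the library's default regularization (recorded in the model metadata)
and Platt-calibrated probabilities, and keeps the kernel with the best
held-out accuracy, ties resolved linear → poly → rbf. Windows whose
5-mer contains more than one A are excluded upstream of training: in a
fully modified construct every A of such a k-mer is modified, an
arrangement that does not occur in vivo. No class re-weighting is done;
designed training sets are balanced by construction. Models serialize as
a versioned archive (spec, scaler parameters, fitted SVM); loading an
archive with a different format version is refused.

## Site calling

Candidate sites are centres of RRACH matches (full IUPAC degeneracy
supported; the motif must be a 5-mer); multi-A 5-mers are excluded by
default and the exclusion is applied uniformly, in training and calling
alike. Sites must reach `min_coverage` (default 5) in **every** sample;
the permissive 1-read variant is available as `min_coverage=1`.
Matching is single-strand (transcript coordinates), as direct RNA reads
are sense-strand. Replicate merging generalizes the three-replicate rule
to n replicates (all ≥ threshold → 1, else mean; default n = 3).
Stoichiometry is `(observed − unmodified) / (fully modified −
unmodified)` mismatch frequency, clipped to [0, 1]; calibration with
`fully modified ≤ unmodified` is rejected as degenerate. Per-site
stoichiometry estimates are noisy at moderate coverage (the denominator
is a ~0.1 frequency difference); averages over sites are accurate to a
few percent at coverage 500.

## Study designs used in tests and the acceptance script

Simulated studies are sized for a single CPU while keeping every
comparison statistically meaningful:

* **Motif arrays** for calling experiments: after multi-A exclusion the
  only single-A RRACH 5-mers are GGACC and GGACT, so random sequence
  yields ~2 usable sites/kb. Calling simulations instead use a dense
  array of planted GGACC/GGACT motifs separated by A-free spacers
  (every RRACH match is then a planted site, verified by the motif
  scanner itself): 150 sites for wt/ko calling, 300 for mixture curves.
* **Random references** for feature-set comparisons: current-intensity
  features are only realistically "poor" when sites span many 5-mer
  contexts, so those experiments use all single-A adenines of a 5 kb
  random sequence (~420 sites, ~840 windows).
* Coverage 100 for classification and calling, 450–500-read pools for
  mixtures and stoichiometry, 3 replicates per condition, wild-type
  stoichiometry 0.5 and knockout 0.
* The wt/ko classifier is trained on simulated data whose methylation
  fraction matches the wild-type design (0.5 vs 0). Under this
  simulator, feature values mix linearly in the methylated fraction, so
  a classifier trained on fully modified reads places 50%-methylated
  sites exactly on its decision boundary; training at matched
  stoichiometry is the appropriate design, and the training tool leaves
  the choice to the user.

## Known limitations

* Per-site only; no per-molecule calls and no modification-type
  identity.
* The structure penalty is a stem counter, not a folding energy; designs
  minimize pairable stems, not predicted minimum free energy.
* The simulator's linear mixing understates real cooperative or
  context-coupled effects; accuracy figures on simulated data
  characterize the pipeline, not biology.
* `scan_motif` assumes transcript-strand coordinates; genomic,
  double-stranded scanning would need strand-aware extension.
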
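# Methods

## Scope and model

`meaphys` analyzes stimulus-locked extracellular recordings from the
medial amygdala (MeA) together with the social-preference behavior of
the same model system: male mice whose preference for female over male
conspecific cues depends on oxytocin signaling.  The package covers the
analysis chain only — spike-event tables in, statistics out.  Spike
sorting, video tracking and all wet-lab procedures are out of scope.

### Trial windows and responsiveness

Each stimulus presentation defines two half-open windows around its
onset `t0`: a pre window `[t0 - 20 s, t0)` and a post window
`[t0, t0 + 40 s)`.  Half-open boundaries prevent an onset-coincident
spike from being counted twice.  Per-trial firing rates are spike counts
divided by window length.  A unit is *responsive* to a stimulus when a
Kruskal–Wallis test comparing the per-trial pre rates against the
per-trial post rates gives `p <= alpha`.  With two groups this is the
standard reduction of a non-parametric ANOVA (equivalent to a Wilcoxon
rank-sum up to tie handling) and extends unchanged if more window groups
are ever compared.  Degenerate input (all rates identical) returns
`p = 1` by convention; fewer than 3 trials is an error.

The detection threshold defaults to `alpha = 0.01` (the convention for
unit counts) and is configurable, because published fraction plots in
this literature also appear at `alpha = 0.05`; every output table
records the alpha that produced it.

### Response strength and categorization

Response strength is the normalized index

    strength = (post - pre) / (post + pre)

computed on **trial-averaged** rates (a ratio of means, not a mean of
per-trial ratios), bounded in [-1, 1], antisymmetric under pre/post
exchange, and 0 when both means are 0.  A unit's category is the
stimulus with the maximal strength among stimuli that are both
significant and excitatory (`strength > 0`); purely suppressed units
stay `nonresponsive` so a suppressing stimulus is never reported as the
"strongest response", while the suppression itself remains visible in
the profile table.  Vehicle-control stimuli (`control`, `ringers`,
`saline`) are tested but can never win.  Strength ties break by smaller
p-value, then by the fixed order female, male, predator, with a logged
warning.

Selectivity coordinates rectify the three strengths at zero and
normalize them to the 2-simplex; a responsive unit whose rectified
strengths are all zero (purely suppressed) maps to the centroid with a
`degenerate` flag.

### Baseline drug effects

Stimulus-free firing across an injection is compared between two
flanking epochs (10 min each by default): rates are count/duration and
significance is a rank-sum test on per-10 s bin counts.  Epochs that
overlap any stimulus response window are rejected.

### Population statistics

Fractions of responsive/categorized units are compared with seeded
permutation tests on the statistic `|f_a - f_b|` with add-one smoothing
`p = (1 + #{null >= obs}) / (1 + n_perm)`, `n_perm = 10,000` by default
(below 1,000 is refused unless forced).  Two schemes are exposed and the
output names which was used:

* **pooled** (unpaired), for populations of different animals: units are
  pooled and re-split at the original sizes.  For 0/1 flags the re-split
  count is exactly hypergeometric, so the null is drawn from that
  distribution directly — identical in law to shuffling and much
  faster; non-binary values fall back to explicit shuffles.
* **paired**, for the same units tracked across an injection: each
  unit's before/after labels are swapped independently with probability
  1/2 (a sign-flip of its paired difference).

A t statistic on 0/1 membership data is monotone in the difference of
fractions, so inference from this statistic is equivalent to a
"permutation t-test" on the same data.  Per-category comparisons are
reported without cross-category correction, mirroring per-stimulus
asterisks in this literature.

Paired response strengths (units responding in either epoch) are
compared with a two-sided Wilcoxon signed-rank test: zero differences
are dropped; up to 25 non-zero pairs the exact sign-flip distribution is
computed by convolution over doubled midranks (exact even with tied
magnitudes, which scipy's exact method does not cover); above that,
scipy's tie-corrected normal approximation is used.

### Behavior

The preference score `(t_A - t_B) / (t_A + t_B)` applies identically to
interaction-zone dwell times (3-chamber assay; the interaction zone is
every point within 5 cm of the enclosure-cup boundary, closed) and to
odor-investigation durations.  Zone occupancy is counted sample-by-sample
at the trajectory rate with no interpolation; boundary points count as
inside.  Group bias is tested by comparing choice-phase scores against
habituation-phase scores in the same arena (paired t test when the same
animals ran both phases), which controls for innate spatial bias; the
set of comparisons passed in one call forms one Holm–Šídák family
(statsmodels `multipletests`).  Per-animal scores are averaged by
default (*mean of ratios*); a *ratio of means* reduction is available
and reports name the one used, since published group scores are
sometimes consistent with either.

The habituation/dishabituation protocol (three presentations each of
saline, a first urinary odor, a second urinary odor) is analyzed with a
one-way repeated-measures ANOVA over the nine slots followed by Fisher's
LSD t tests of adjacent slots using the ANOVA error term — which reduces
to the plain paired t test in a two-condition design.  LSD pairs are
flagged significant only when the omnibus test passes (classic LSD
protection); an ungated mode exists because protocols differ.  A
significant within-block decline marks habituation; a significant
increase at a block transition marks dishabituation.

## Synthetic data generator

The generator exists so every downstream stage is testable without
recordings; its defaults are the study conditions of the reference
experiments.

* **Population**: unit categories are one seeded multinomial draw of the
  prevalence vector.  Baseline rates are log-normal (median 3 spikes/s,
  sigma 0.5 in log space) — a standard heavy-tailed model for cortical
  and amygdalar baseline rates.
* **Responses**: a boxcar gain over exactly the 40 s analysis window
  after each matching onset (no decay): the simplest kernel the
  detection statistic is sensitive to, since only mean window rates are
  analyzed.  Category `c` responds to stimulus `c` with gain 4 by
  default and to everything else with gain 1; arbitrary per-category
  gain tables are accepted.
* **Schedule**: each stimulus receives 6–12 repetitions (uniform draw),
  randomly interleaved, with onsets 80 s apart (>= pre + post window;
  the inter-trial interval is an assumption — session timing beyond the
  windows is not constrained by the analysis).
* **Spiking**: each unit is an inhomogeneous Poisson process sampled
  exactly per constant-rate segment (count ~ Poisson(rate x duration),
  times uniform).  Every unit has its own RNG stream keyed by
  (master seed, unit index), so spike trains are reproducible under
  population resizing.
* **Drug effect**: a step at the injection boundary, flanked by two
  10 min stimulus-free baselines.  Baselines multiply by
  `baseline_factor`; response gains scale their evoked component,
  `g -> 1 + factor * (g - 1)`, so `factor = 0` abolishes a response
  while units that never responded (g = 1) are untouched.  A plain
  multiplicative factor on the gain would suppress non-responders during
  the stimulus window and manufacture spurious post-drug responses,
  which is not what an acute receptor antagonist does.  No wash-in
  kinetics: only before/after aggregates are analyzed.
* **Behavior**: per-animal durations are gamma-distributed with the
  configured mean/SD (shape = (mean/sd)^2), guaranteeing non-negativity;
  zero SD returns the mean exactly.  Cohort presets carry the published
  group moments (SD reconstructed as SEM x sqrt(n)).  Trajectories for
  zone tests are piecewise-constant visits to anchor points with exactly
  known dwell times.

Presets encode the reference populations: `control_male_config` (106
units; 25 female / 1 male / 14 predator responders) and
`antagonist_config` (129 units; 21 female / 1 male / 1 predator
responders; post-boundary female gain abolished, baselines x 0.8).
Prevalences are integer unit counts over the recorded population so
expected fractions equal the published percentages at printed precision.

### What the generator does not emulate

Real MeA units show response latencies and adaptation within the 40 s
window, correlated noise across simultaneously recorded units,
multi-stimulus tuning, drifting baselines, and occasional unit loss
across a session.  Passing tests therefore demonstrate correctness of
the statistics under the generative assumptions (independent Poisson
units, boxcar responses, step drug effects), not robustness to every
property of real recordings.

## Simulation sizes and numerical choices

* Parameter recovery runs 20 seeds x 106 units with 8 repetitions per
  stimulus and gain 4; recovered category fractions are compared with
  the generating prevalences within 3 single-session binomial SDs.  The
  ~0.3–0.5 percentage-point upward bias of recovered fractions is the
  false-positive categorization rate of null units (about alpha per
  stimulus, halved by the strength > 0 requirement, split across
  categories) and is well inside that band.
* The antagonist signature runs 20 seeds x 129 units and requires, per
  seed: female fraction and strengths fall significantly, male/predator
  fractions show no significant fall.
* Detector calibration uses 1,000 null units with 10 repetitions;
  measured type-I error at alpha = 0.01 is slightly conservative (about
  0.007–0.009) as expected for rank tests on small discrete samples,
  inside the binomial CI.
* Null calibration of the pooled permutation test uses Bernoulli(0.2)
  groups of 8,000: permutation p-values are valid at any size but
  attain the nominal level only as the discreteness of the statistic
  vanishes, so the calibration is checked in the large-sample regime.
* Comparisons of floating statistics against enumeration oracles use a
  3-Monte-Carlo-SD band plus the add-one smoothing granularity.
* All randomness flows from explicit seeds through named
  `numpy.random.SeedSequence` streams; identical configs give
  byte-identical output tables.

## Known limitations

* The denominator convention for "fraction responding" is the full
  population passed in; with tracked-unit designs, only units present in
  both epochs are counted (exclusions logged).
* The pooled permutation test's p-values are conservative for small
  populations (discreteness), as is any exact resampling test.
* `group_preference` assumes each animal has both measures in each
  phase and silently (but loggedly) drops incomplete animals.
* The repeated-measures ANOVA assumes sphericity; no Greenhouse–Geisser
  correction is applied, matching the classical LSD workflow it feeds.
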
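# Methods

## Data model and frequencies

The analysis unit is the TCR-beta clonotype, identified by its CDR3
amino-acid sequence (a config flag extends the identity key to
`(CDR3, V gene)`; the default matches how such clonotypes are usually
reported). Non-productive rearrangements (out-of-frame or containing a
stop codon) are parsed and retained for accounting but excluded from
frequency denominators and all downstream analysis: culture-well
frequencies describe functional T cells. Within a well, duplicate identity
keys are merged by summing template counts before anything else; the
frequency of clone *c* in well *w* is `templates_cw / Σ productive
templates of w`, so each well's productive frequencies sum to 1.

Each participant is analyzed per assay batch against that batch's own
DMSO wells. A participant cultured in two batches (e.g. one batch with
S2S + NL63/229E/OC43 and a second with S2S + HKU1 only) gets two
independent sets of calls reported side by side; batches are never pooled
into one positivity test, because control wells are batch-specific.

## Positivity rule

The sentence defining a positive response ("mean frequency greater than
0.1% in at least two replicates, with at least a 5-fold increase over the
DMSO controls") is ambiguous between a per-replicate and a mean reading.
It is implemented as three conjunctive clauses with independent
parameters, the strictest reading consistent with the words:

1. frequency `> min_mean_frequency` (default 0.001) in
   `≥ min_positive_replicates` (default 2) individual replicates;
2. mean frequency over **all** replicates of the condition
   `> min_mean_frequency` — absences count as zero, so dropout is
   penalized rather than ignored;
3. mean `≥ fold_over_dmso` (default 5) times the DMSO mean.

Either looser reading is recoverable by relaxing the corresponding
parameter. Comparisons follow the wording: strict `>` for "greater than
0.1%", inclusive `≥` for "at least 5-fold".

**DMSO floor.** A clone absent from every control well would produce an
infinite fold. Under the default `detection-floor` policy the DMSO mean
enters the denominator as `max(mean, 1/T)` where `T` is the summed
productive templates across the batch's DMSO wells — the smallest nonzero
frequency the controls could have detected. Alternatives: `none`
(infinite fold; clause 3 auto-passes) and a fixed pseudo-frequency.
Clonotypes observed only in DMSO are never tested (no antigen signal to
evaluate).

## Reactivity labels

Cross-reactive: positive for S2S and ≥ 1 common-cold pool of the same
batch. Mono-reactive: positive only for S2S, and S2S mean
`≥ mono_dominance_fold` (default 5) × the clone's mean in every other
antigen pool, where an undetected pool mean enters at the DMSO detection
floor (dominance is then effectively satisfied). The two published
definitions leave a gap — a clone positive only for S2S whose dominance
over some sub-threshold CCC signal is below 5-fold — and festkit reports
it as an explicit `unclassified` label rather than forcing the dichotomy;
summary tables emit percentages both over all S2S-positive clones and
over the mono/cross dichotomy alone so either denominator is available.

## Diversity

Spike-specific diversity uses the participant's full S2S-positive set
(mono + cross + unclassified). Per S2S replicate, frequencies of subset
members detected in that replicate are renormalized to sum to 1 and
summarized by Shannon's index in bits (`log_base` configurable). A
replicate in which no subset clone was detected is skipped with a log
entry, not scored as `H = 0`: an undefined distribution has no entropy,
and 0 would conflate dropout with monoclonality. Participant indices are
the arithmetic mean over contributing replicates.

Groups of participant means are compared with a two-sided Mann-Whitney U
test. The exact null distribution is used when the pooled sample has at
most 12 observations and no ties — study-scale groups of 4–10 per arm sit
inside enumeration range, and small-sample nonparametric p-values depend
on exactness — otherwise midranks with the tie-corrected normal
approximation (a fully tied pooled sample short-circuits to p = 1). The
exact two-sided p equals `min(1, 2·P(U ≥ max(U₁,U₂)))` under enumeration
of all group assignments; the test suite verifies this against a
brute-force oracle for every group size with n ≤ 10. Shannon's index is
conventionally a whole-repertoire statistic; `whole_repertoire_diversity`
applies the same index to un-subset vectors for that use.

## CDR3 homology

Cores are the CDR3 minus its first `trim_left` = 3 and last
`trim_right` = 3 residues; sequences with no residue left after trimming
are excluded with a warning (the rule is undefined for them, and padding
would fabricate sequence). Pairwise distances are unit-cost Levenshtein
edit distances (computed with edlib; verified in tests against an
exhaustive recursive oracle and for the metric axioms). Duplicate cores
remain separate leaves at distance 0 — identical cores shared between
participants or groups are the signal of interest.

The tree is built by neighbor joining, the standard distance-based method
and exact on additive matrices (verified on random 4–8 leaf trees).
Determinism choices: ties in the Q criterion resolve to the
lexicographically smallest label pair; a negative branch length is clamped
to zero with the deficit moved to its sister branch, preserving the pair's
total length; the final three lineages join at a trifurcating root
(unrooted representation). Internal nodes are named `n1, n2, …` in join
order so clades can be addressed; `extract_clade` returns the leaves on
the smaller side of the chosen edge (overridable) with their distance
submatrix, and records the full matrix's min/max so heatmaps drawn from
several clades share one fixed color scale. All S2S-positive clones are
pooled for the tree by default, mono- and cross-reactive alike.

## Synthetic studies

The generator emulates the cultured-replicate design: one baseline clone
probability vector per study, shared by all wells; reactive clones
multiplied by `expansion_fold` in their reactive conditions and
renormalized; template counts drawn multinomially per well at `depth`;
DMSO wells sample the unmodified baseline.

Defaults (the simulated study conditions):

* baseline: lognormal(μ = 0, σ = 2) weights renormalized — a standard
  heavy-tailed repertoire shape; `zipf` alternative with configurable
  exponent;
* design per participant: 96 mono-reactive S2S clones and 4 cross-reactive
  clones (three S2S+HKU1, one S2S+HKU1+NL63), plus 13/8/11/16 clones
  mono-reactive to NL63/229E/OC43/HKU1 — the per-antigen breadths and the
  ~96%/4% mono/cross split this mirrors are typical of a vaccinated
  participant's spike response, with cross-reactivity dominated by HKU1;
* `expansion_fold` 50, `depth` 100,000 templates/well, 3 replicates,
  all six conditions;
* designed clones draw their baselines from the upper half of the weight
  distribution and are floored at a baseline frequency of 5 × 10⁻⁴, so the
  default design is detectable rather than buried in the sampling tail
  (both overridable);
* noise is multinomial resampling only; an optional Dirichlet-multinomial
  mode (`overdispersion` = concentration scale) adds culture-to-culture
  variability for stress tests.

What the generator does **not** model: sequence-dependent antigen
recognition (reactivity is a designed label), nonspecific culture drift
beyond resampling noise (unless overdispersion is enabled), V/J gene
usage structure, PCR/sequencing error, and shared clones between
participants. Passing recovery tests therefore demonstrates that the
calling rules behave correctly under the stated sampling model, not that
they are robust to all noise in real cultures.

`evaluate_recovery` scores a study against its truth table: per-condition
sensitivity over designed clones, false-positive rate over
background-clone tests, and a mono/cross confusion matrix over detected
designed S2S clones.

## Numerical and scale choices

* Frequencies are fractions internally; percents appear only in outputs.
* Fold comparisons are floating-point; the inclusive 5-fold boundary is
  honored as written (a mean of exactly 5 × the control mean is positive).
* Outputs are deterministic: clonotype keys sorted lexicographically,
  conditions in a fixed order, every table headed by the parameter values
  used, and a JSON run-config snapshot accompanies each bundle.
* Test and acceptance problem sizes — 150–2,000 background clones,
  depths of 2 × 10⁴–10⁵, 20 seeds for averaged recovery statistics — were
  chosen as the smallest scales at which the measured rates stabilize;
  the defaults above remain the reference study design.

## Known limitations

* Only the threshold criteria are implemented for positivity; no
  additional FDR-controlled per-clone significance stage is applied (the
  three-clause API is the hook for adding one).
* Neighbor joining is quadratic in memory and cubic in time; pooled
  analyses beyond a few thousand sequences would need a sparser approach.
* The exact Mann-Whitney path requires tie-free data; tied small samples
  fall back to the midrank normal approximation.
* Heatmap rendering itself is out of scope; the exported clade submatrix
  and recorded color-scale range are the tested artifact.
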
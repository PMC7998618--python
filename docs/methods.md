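# Methods

This note documents the model, the numerical choices, and the limits of
what the synthetic validation demonstrates. It is the package's own
account; every number mentioned is computed by the test suite or the demo.

## The modeling problem

The pipeline targets the common situation of a small steady-state bulk
RNAseq design — a handful of treatment conditions, a few replicates each —
plus curated interaction resources of uneven quality, and a set of gene
co-expression modules (e.g. WGCNA colors, computed upstream and supplied as
a gene→module table; module detection itself is out of scope). The goal is
a dynamic, executable model: a probabilistic Boolean network whose
attractors reproduce the observed condition states and whose response to
node interventions predicts module-level up-/down-regulation.

## Network assembly

**Alias resolution.** Gene naming is normalized in two layers: a
canonicalization (uppercase, strip `.`, `-`, `_`) handles stylistic
variation, and an alias graph (union of all supplied alias pair tables over
canonicalized names) handles genuine synonyms; connected components are
synonym classes, represented by their lexicographically smallest member for
reproducibility. Resolution is total: unknown names form singletons.

**Edge score.** `score = (N_references + N_resources + 10·c̄)·TFMUL`, where
`N_references` sums reference counts over all merged records,
`N_resources` counts distinct resources, `c̄` is the per-record mean of the
resource-supplied confidences (0 where a resource provides none), and
`TFMUL = 2` for transcription-factor sources. Averaging the confidence over
records (rather than summing) is a deliberate reading of the scoring
recipe: it is the only one consistent with the score floor of 2 for a
single zero-confidence record, which the acceptance checks pin down.

**In-degree pruning.** In-edges are ranked by descending score (ties broken
by source id); the top three are always admitted, and the k-th (k > 3) only
if `score > k_retained − 1` where `k_retained` is the number already
admitted. The first rejection drops all lower-ranked edges. Boolean rules
over N inputs need 2^N configurations constrained by only ~18 samples, so
bounding in-degree is what keeps inference from being pure prior.

**Connecting paths.** Stranded module genes are reconnected through
directed paths of ≤ 4 nodes (endpoints included) running either from the
orphan into a seed component or from the component to the orphan; the
direction is deliberately symmetric because regulation in either direction
couples the gene to the module dynamics. Intermediate nodes are drawn from
outside the components. Only minimum-length paths per orphan are added, all
of them on ties.

**Finalization.** Sink removal is iterated to a fixed point — removing a
sink can expose another, and a node that cannot reach any cycle can never
drive the dynamics. Weak components below 4 nodes are then discarded.

## Rule inference

**Normalization.** Per gene, values at/below the 20th percentile map to 0,
at/above the 80th to 1, linear in between (numpy's linear-interpolation
percentile convention). A gene whose two percentiles coincide is mapped to
0.5 everywhere with a warning: such a gene cannot be called ON or OFF from
these data, and 0.5 is the uninformative value in this calculus.

**Transcript/active split.** Edges from transcription factors are
transcriptional; all others are post-translational, signed by annotation
and positive when unannotated. A node with any post-translational in-edge
splits into `X_T` (transcript, measured) and `X_A` (active protein,
latent); out-edges leave from `X_A`. Activation follows the
inhibitory-dominant sloppy logic
`X_A = X_T · min(Σact, 1) · max(1 − Σinh, 0)`, the activator factor omitted
when a node has no activators (a node nobody activates is active unless
deactivated). The coupled per-sample system `X_A − F(X_A) = 0` is solved
with scipy's hybrid Powell root finder started at `X_A = X_T`, to residual
< 1e-8 (default, `tol` knob); a damped fixed-point iteration
`x ← (x + F(x))/2` takes over when the root finder stalls — notably on
singular systems with a continuum of fixed points (symmetric mutual
inhibition), where the damped map converges to the symmetric solution.
Every factor of F maps into [0, 1], so the final clip to [0, 1] only
guards float error. Non-convergence of both routes (not observed on any
tested fixture) raises with the offending nodes named. In the
dynamic system the `X_A` nodes carry the deterministic Boolean counterpart
of the same inhibitory-dominant form — the data only constrain
transcription, so the activation logic is structural, not inferred.

**Estimator.** A configuration's probability is the support-weighted mean
of the target's normalized value, shrunk toward 0.5 by one pseudo-
observation (`prior_weight`, default 1.0). This keeps three properties that
the rest of the pipeline relies on: unsupported configurations are exactly
0.5, adding an ON observation at a configuration never lowers its
probability, and with growing support the estimate converges to the
empirical mean. The prior strength is a genuine free choice; 1.0 is the
weakest smoothing that keeps the no-data behavior exact, and it is exposed
as a config knob.

**Significance pruning.** A regulator's significance is the maximum
absolute output change it can cause over the 2^(N−1) contexts of the other
regulators. Regulators below threshold 0.1 are removed one at a time
(lowest first, ties lexicographic for determinism) with re-inference after
each removal; the loop runs at most N times. The keep condition is
significance ≥ threshold; exact ties at the threshold are kept. A node that
loses every regulator becomes a source for all later analyses.

## Pseudo-attractors

Rounding `f(c)` at 0.5 yields the closest deterministic system; since
forward and backward single-node transition probabilities sum to 1,
removing sub-0.5 transitions makes pseudo-attractors exactly the terminal
SCCs of the deterministic general-asynchronous state transition graph.
Entries exactly at 0.5 round to 1 — transitions *below* 0.5 are the absent
ones — and are logged, because the deterministic approximation is genuinely
ill-defined there.

The update scheme is general asynchronous (one node per step) throughout,
for consistency between attractor detection and walk simulation; a
synchronous scheme would find different complex attractors.

Source nodes are pinned per condition by mean normalized value > 0.5
(exact ties pin OFF, logged), constants propagated to a fixed point
(confluently — substitution order cannot matter, which the tests check by
randomizing it), and the residual free system searched exhaustively up to a
bound of 20 free nodes (2^20 states; the practical sweet spot is ≤ 12).
Beyond the bound the search refuses with an instruction to pin more
sources rather than silently subsampling the state space. Oscillating
nodes (varying within a terminal SCC) count 0.5 in module activation and
in start-state averaging — the unbiased value for a cycling node — and
average start states threshold at > 0.5 with ties resolving OFF.

## Interventions

**Edge profiles and influence.** `avgON`/`avgOFF` are unweighted means over
co-regulator contexts. The four scores live on the edge's sign branch
(positive: NON = 1 − avgOFF, SON = avgON; negative: NOFF = avgOFF,
SOFF = 1 − avgON; the other pair zero). When avgON = avgOFF the edge has no
net direction and all four scores are 0 — both branches presuppose a strict
sign. The influence index weights necessity double under KO and sufficiency
double under CA (turning OFF a necessary regulator, or ON a sufficient
one, suffices to control the target), summed over a node's targets inside
the module; KO/DOWN and KO/UP (and CA likewise) are antisymmetric by
construction.

**Walks.** One step = one node-update attempt (whether or not the value
changes); the start state is step 0. Source nodes hold their start value —
they have no update rule, and the pinning that selected the start state is
part of the condition being simulated. Intervened nodes (both `_T` and `_A`
forms of split genes) are held and never selected. Per-walk RNGs derive
from the master seed by counter, so runs are reproducible and walks
independent. Defaults are 100 walks × 5000 steps; the first crossing from
the start band (low < 1/4, intermediate 1/4–3/4 inclusive of both edges) is
recorded, censored at 5001. Crossings into the high band (> 3/4) are not
scored: they are rare by construction of the band edges, and a module
starting high is skipped with an explicit error. The walk engine keeps an
incremental count of ON module members and stops a walk at its first
crossing, which is what makes the 100×5000 default cheap in the common
case.

**Statistics.** Two-sided Mann–Whitney U (scipy, tie-corrected asymptotic
at these sample sizes — censoring piles ties at 5001, which a rank test
tolerates; two identical constant samples are reported as p = 1 directly,
where the normal approximation would be 0/0). BH correction runs over the
whole batch of (intervention, condition, module) tests in one family.
Classification, at adjusted p < 0.05: a module starting low that switches
slower was stabilized low (downregulating), faster destabilized
(upregulating); starting intermediate the mapping flips. Direction of
"slower" is the ratio of mean switching times.

## Synthetic ground truth

The generator emulates the statistical structure the pipeline assumes, not
real biology. Rules are drawn uniformly from a family spanning the
functional forms the inference must recover: single-regulator
identity/negation, two-input AND/OR with random literal signs, and the
three-input inhibitory-dominant form. Models are rejection-sampled (from
seed-derived streams, so generation is deterministic) until weakly
connected with at least one source node and one feedback loop. Expression
pins each condition's sources to a distinct pattern, relaxes to a
pseudo-attractor, and emits ON genes from FPKM range [20, 200], OFF genes
from [0, 2] — separated enough that 20/80 normalization recovers states
whenever a gene differs across conditions — with multiplicative lognormal
replicate noise (sd 0.2 on the log scale by default) and optional dropout.
Interaction tables perturb names by case/punctuation styling and alias
substitution, both recoverable; decoy edges carry one reference and zero
confidence so score pruning can be exercised against them.

What passing on synthetic data does **not** show: robustness to library-
size and batch effects, read-level noise, genes whose true logic lies
outside the rule family, in-degrees above 3, or module assignments that
disagree with the network structure. Real HGNC-scale naming chaos is only
caricatured. The 6×3 design is small by construction; rules with ≥ 3
regulators are only weakly constrained by 18 samples, which is precisely
why the significance-pruning and in-degree bounds exist.

## Problem sizes and defaults

Demo and test fixtures use 10–20-node models (3–4 modules, max in-degree
3), exhaustive attractor search at ≤ 12 free nodes, and the full
100 × 5000 walk budget where the statistical contract is asserted (the
packaged demo scales to 20 × 2000 to stay interactive). Knobs and defaults:
percentiles 20/80, significance threshold 0.1, max path nodes 4, bands
1/4 and 3/4, 100 walks, 5000 steps, alpha 0.05, `prior_weight` 1.0,
exhaustive bound 20. The pipeline logs any deviation from these defaults
at startup.

## Known limitations

- The exhaustive attractor search is exponential in free nodes; large
  systems need stronger pinning (stable-motif-style reduction is not
  implemented).
- Mann–Whitney on heavily censored distributions loses power when both
  arms censor at 5001; the classification is then "none" even if the true
  effect is merely slower than the walk budget.
- The activation solver returns one fixed point (reached from the initial
  guess `X_A = X_T`); systems with multiple sloppy-logic fixed points
  (e.g. symmetric mutual inhibition) get a single solution, and the choice
  of initial guess is part of the method's definition here.
- Intervention start states reuse the wild-type average attractor state;
  an intervention that immediately pushes a module into the high band is
  skipped rather than scored.
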
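# Methods

## Model and procedure

The classifier is a small set of weighted fuzzy if-then rules over features
normalized to [0, 1], applied with single-winner inference. The pipeline has
four stages.

**1. Antecedent vocabulary.** Fifteen fixed fuzzy sets: the homogeneous
triangular Ruspini partitions of [0, 1] at granularities 2, 3, 4 and 5
(peaks at i/(k−1), each interior triangle spanning its two neighbouring
peaks, boundary half-triangles clipped to the interval) plus one don't-care
(DC) set with membership identically 1. Within each partition the
memberships sum to exactly 1 everywhere. Offering four granularities at once
lets rule induction pick the coarsest term that discriminates, which keeps
rules short; no set is tuned during training. The DC set is modelled as a
real membership function so that the product compatibility needs no
special-casing, but DC slots do not count toward rule length. Index order is
fixed (DC = 0, then granularity 2→5, small→large within each) and serialized
rule bases refer to these indices.

**2. Rule induction.** Every antecedent touching 1–3 features (all non-DC
label assignments over all feature subsets of that size) is scored in a
vectorized pass: compatibility is the product of per-feature memberships,
confidence the class share of the antecedent's compatibility mass, support
the class mass over m, the consequent the class of maximal confidence, and
the certainty factor CF the margin between the two class confidences.
Antecedents that cover no pattern, tie exactly in confidence, or have CF = 0
yield no rule: an uncovered subspace gives no information, a tie admits no
principled consequent, and a zero-weight rule can never win a pattern.
Survivors of the minimum-confidence/support thresholds are grouped by consequent
class, sorted by confidence × support (both quality measures matter; either
alone can be gamed by very narrow or very broad rules) and the top Q/2 per
class retained. A class with fewer survivors than its quota is allowed with
a warning: small datasets may simply not contain Q/2 rules per class.
The all-DC antecedent of length 0 is excluded from enumeration — its CF
reduces to the class-prior imbalance and it carries no feature information.

**3. Single-winner classification.** A pattern takes the class of the rule
maximizing compatibility × CF. If no selected rule attains a positive score
the pattern is rejected, and rejections count as errors in every accuracy
figure (NCCP counts *correctly classified* patterns only). Ties between
rules of the same class resolve to the lowest rule index; an exact tie
across classes is rejected — the conservative convention for
winner-take-all inference.

**4. Genetic rule-subset selection.** Subsets of the Q candidates are binary
strings evolved under the scalarized fitness f(S) = w1·NCCP − w2·NOR −
w3·NOA (weights nonnegative, summing to 1). Despite the multi-objective
framing, the search itself is a single-objective GA over the scalarization;
a weight sweep recovers the accuracy/interpretability trade-off table.
Per generation: parents are drawn by binary tournament, recombined by
two-point crossover with probability p_c, and mutated with biased rates —
p_10 = min(1, PA_10·(1 + w2 + w3)) for 1→0 and p_01 = min(1, PA_01·(1 + w1))
for 0→1 — so interpretability pressure drains rules faster than accuracy
pressure adds them. Every evaluated string is first cleaned of unnecessary
rules and the cleaned string is what survives (Lamarckian write-back). The
next population is the top n_pop of parents and children.

*Unnecessary-rule removal* clears every selected rule that never attains the
per-pattern maximal score on the training set. All rules tied at a
pattern's maximum are kept, not only the first: removing a max-tied rule
could change that pattern's prediction, whereas removing strictly dominated
rules provably leaves every prediction — hence NCCP — unchanged while NOR
and NOA can only shrink. The operation is idempotent.

*Parsimony tie-break.* Population ranking and the returned best individual
order first by fitness, then by fewer rules, then by fewer conditions. This
costs nothing in fitness and resolves the frequent exact ties created by a
rule whose marginal training gain exactly balances its complexity penalty —
in keeping with the interpretability objectives, the leaner classifier wins.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| max_rule_length | 3 | longest antecedent enumerated; rules beyond 3 conditions stop being readable and the enumeration grows as C(n,L)·14^L |
| min_confidence | 0.6 | candidate screening floor; a rule should be right for a clear majority of its mass |
| min_support | 0.05 | floor on covered mass; discards rules firing on a single odd sample |
| Q | 300 | candidate pool size (150 per class) |
| criterion | product | pre-screening sort key (confidence, support, or product) |
| top_k | 10 | features kept after signal-to-noise ranking \|µ₁−µ₋₁\|/(σ₁+σ₋₁); a handful of genes is what the rule bases can use, and more features only add noise candidates |
| w1, w2, w3 | 0.5, 0.3, 0.2 | accuracy / rule count / rule length emphasis |
| n_pop | 50 | GA population |
| p_c | 0.9 | two-point crossover probability |
| PA_10, PA_01 | 0.1, 0.01 | base mutation rates before the weight scaling |
| max_generations | 200 | stopping point; an optional stagnation window can stop earlier |

The screening thresholds, Q and the GA settings are configuration values
with sensible defaults, not quantities the method prescribes.

## Synthetic data generator

The generator emulates the shape of two-class expression studies: m per
class in the tens, hundreds of features, a small informative subset.
Informative features are Gaussian with class-conditional means 0 and
shift·σ (default shift 3, σ = 1); noise features are N(0, σ²) in both
classes; values are min–max normalized with training statistics (held-out
values clipped into [0, 1]); optional missing cells are inserted uniformly
at a configurable rate. Defaults: 30 samples per class for training and for
testing, 200 features, 5 informative.

What it does *not* emulate: heavy-tailed and skewed intensity
distributions, feature–feature correlation (co-regulated genes), batch
effects, and class imbalance. Passing tests therefore demonstrate that the
pipeline recovers well-separated independent signals at realistic sample
sizes — not that it handles correlated or artefact-laden real microarray
data, where feature ranking and rule screening face collinear candidates.

Missing values are treated as don't-care at classification time (membership
1), the least-commitment reading of fuzzy systems' tolerance of missing
data; a feature missing everywhere is an error.

## Numerical choices and degenerate inputs

- Normalization statistics come from the training partition only, with
  held-out values clipped; a global-normalization switch exists for
  reproducing workflows that scale over all samples. Constant features map
  to 0.5 and are flagged.
- Membership evaluation raises on inputs outside [0, 1] rather than
  clipping silently: out-of-range values indicate missed normalization.
- Feature-ranking ties break on the lower feature index; candidate-rule
  sorting ties break on the antecedent index tuple — both make runs
  deterministic.
- Exact confidence ties and empty subspaces produce no rule (mirroring each
  other: neither admits a principled consequent).
- All GA randomness flows from one seeded generator; identical
  configuration and seed reproduce byte-identical artifacts.

## Validation problem sizes

The oracle-equivalence checks run exact comparisons (1e−12) of the
vectorized rule statistics against scalar reference loops on datasets of up
to 10 patterns × 3 features, and of the GA against exhaustive enumeration
on pools of ≤ 15 rules (2^Q subsets scored through the independent
per-pattern classifier path). End-to-end behaviour is assessed over 20
seeded replicates of the default synthetic conditions, and the
interpretability-pressure comparison over 10 replicates at two weight
settings. These sizes keep every exhaustive oracle exact while exercising
the same code paths as full-scale runs.

## Known limitations

- Two-class problems only; the certainty factor is defined as a two-class
  confidence margin.
- The scalarized GA returns one operating point per weight vector, not a
  Pareto front; closely spaced weight vectors can return the same subset.
- Candidate enumeration is exhaustive over the post-ranking feature set; it
  is not meant for hundreds of features without prior ranking.
- With strongly overlapping classes the screening thresholds can leave a
  class short of candidates; the pipeline proceeds with a warning, but the
  resulting rule bases may be one-sided.
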
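# fuzzyrules

Interpretable weighted-fuzzy-rule classifiers for two-class, high-dimensional
expression data (microarray gene expression, proteomic spectra), with genetic
selection of small rule subsets.

## The problem

Expression matrices from cancer studies typically have tens of samples and
thousands of features. Black-box classifiers can separate tumour from normal
tissue on such data, but a clinician cannot read an SVM. Fuzzy if-then rules
can: a model like *"if gene A is large and gene B is relatively small, the
sample is cancer"* is directly interpretable — provided the rule base stays
small and the rules stay short. This package trades classification accuracy
against exactly those two complexity measures.

## The model

Each feature is first min–max normalized to [0, 1] and described by a fixed
vocabulary of 15 fuzzy sets: four homogeneous triangular (Ruspini) partitions
of the unit interval with 2, 3, 4 and 5 linguistic terms
(small … large), plus a "don't care" set whose membership is identically 1.
A weighted fuzzy rule has the form

    R_q:  if x_1 is A_q1 and … and x_n is A_qn, then class C_q with CF_q

where each A_qi is one vocabulary set and CF_q ∈ [0, 1] is the rule's
certainty factor. For a pattern x_p, the compatibility with rule q is the
product µ_q(x_p) = Π_i µ_Aqi(x_pi). Over m training patterns:

* **confidence** c(A_q ⇒ h) = Σ_{p: y_p=h} µ_q(x_p) / Σ_p µ_q(x_p)
* **support**  s(A_q ⇒ h) = Σ_{p: y_p=h} µ_q(x_p) / m
* the consequent C_q is the class of maximal confidence, and for two classes
  CF_q = c(A_q ⇒ C_q) − c(A_q ⇒ ¬C_q).

Candidate rules with at most 3 conditions are enumerated, screened by
minimum confidence and support, and the top Q/2 per class kept under a
pre-screening criterion (confidence × support by default). A pattern is then
classified by the **single winner rule**: the selected rule maximizing
µ_q(x_p)·CF_q (rejection if no rule fires).

From the Q candidates, a genetic algorithm over binary inclusion strings
r_1…r_Q picks the final rule subset S by maximizing the scalarized
three-objective fitness

    f(S) = w1·NCCP(S) − w2·NOR(S) − w3·NOA(S),   w1 + w2 + w3 = 1, w ≥ 0

where NCCP is the number of correctly classified training patterns, NOR the
number of rules and NOA the total number of antecedent conditions. Biased
mutation (the 1→0 rate scaled up by w2 + w3) and removal of rules that never
win a pattern keep the strings lean; the weight vector expresses the user's
accuracy-versus-interpretability preference.

## Worked example

Train on a synthetic dataset shaped like a small expression study
(30 samples per class, 200 features, 5 of them informative at a 3-sd
class-mean shift):

```python
import fuzzyrules as fr
from fuzzyrules.cli import RunConfig, run_training
from fuzzyrules.classifier import render_rules

cfg = RunConfig(synthetic=fr.SyntheticSpec(seed=7), seed=7,
                ga=fr.GAConfig(seed=7))
res = run_training(cfg)
print(render_rules(res.rule_base))
```

prints

```
Rule 1: If the feature g135 is “large”, then the sample is Cancer with CF=91.37%.
Rule 2: If the feature g178 is “relatively small”, then the sample is Normal with CF=96.30%.

        g178  g135  CF      Class
Rule 1  –     L3    0.9137  Cancer
Rule 2  MS4   –     0.9630  Normal
```

and `res.summary` reports `train_accuracy 0.983`, `test_accuracy 0.90`,
`n_rules 2`, `average_rule_length 1.0`: two one-condition rules classify the
held-out samples at 90% accuracy, and both selected features (g135, g178)
are among the five planted informative ones. Raising w2/w3 shrinks the rule
base further; raising w1 trades size for training accuracy.

The same pipeline is scriptable from the shell:

```sh
fuzzyrules synth --out-dir data/ --seed 7          # write a fixture dataset
fuzzyrules train --config run.yaml                 # rule base + trace + summary
fuzzyrules classify --rules runs/latest/rulebase.json --data data/test.csv --out pred.csv
fuzzyrules sweep --config run.yaml --grid grid.yaml --out tradeoff.csv
```

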
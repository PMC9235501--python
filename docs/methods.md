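# Methods

## Model

`ontoball` couples two components in one embedding space of dimension
`n`:

1. **Ontology geometry.** Each class `c` is an n-ball with center
   `fη(c)` and radius `rη(c)`; each relation `r` is a translation
   vector.  The ontology's axioms are first normalized to the four EL
   normal forms (NF1 `C⊑D`, NF2 `C⊓D⊑E`, NF3 `C⊑∃R.D`, NF4 `∃R.C⊑D`);
   each definition axiom `C ≡ D ⊓ ∃R.E` is rewritten into
   `C⊑D` (NF1), `C⊑∃R.E` (NF3), `∃R.E⊑X` (NF4) and `D⊓X⊑C` (NF2) with
   one fresh class `X` naming the existential restriction.  The rewrite
   preserves entailment in both directions; the test suite verifies
   this with an exhaustive finite-interpretation checker on domains of
   up to three elements.  Each normal form contributes a hinge loss
   with margin `γ` that vanishes exactly when the corresponding ball
   configuration realizes the axiom.

2. **Protein encoder.** A protein's binary domain-annotation vector
   `x ∈ {0,1}^V` passes through two residual MLP blocks
   (`DropOut(BatchNorm(ReLU(Wx+b)))`, output `h + Block2(h)`) into the
   same space.  The score of class `c` for protein `p` is
   `σ(fη(p)·(hF + fη(c)) + rη(c))` where `hF` is the embedding of the
   reserved `hasFunction` relation.

Training minimizes `BCE + L_NF1 + L_NF2 + L_NF3 + L_NF4` with Adam.
Classes that appear in axioms but have no training annotations are
excluded from the BCE term yet still constrained by the NF losses; this
is the zero-shot mechanism — their balls are positioned entirely by the
axioms they share with trained classes.

### Assumptions

* The subclass hierarchy restricted to named (non-fresh) classes is a
  DAG; annotations obey the true-path rule after propagation.
* Only the three OBO-expressible axiom shapes (is_a, relationship,
  paired intersection_of) are ingested.  Nested class expressions,
  unions, disjointness and role chains are out of scope and rejected
  with a clear message.
* Protein evidence is carried entirely by the binary feature vector;
  sequence data are treated as opaque (the splitter consumes an
  aligner's tabular output, never sequences themselves).

## Parameters that matter

| parameter | default | meaning / rationale |
|-----------|---------|---------------------|
| `n` | 1024 (64 for the synthetic fixture) | embedding dimension; matches the protein encoder output. The fixture needs far fewer dimensions than a 50 000-class ontology, and 64 keeps a CPU fit in seconds |
| `gamma` | 0.1 | hinge margin of the NF losses; gives each containment a small slack so satisfied axioms stop producing gradient |
| radius map | softplus | radii are stored unconstrained and mapped through softplus, keeping `rη ≥ 0` without clipping gradients |
| `lr`, `batch_size` | 1e-3, 64 | conventional Adam settings; the contract is the loss, not the schedule |
| `epochs`, `patience` | 100, 10 (300, 40 for the fixture) | with ~4 optimizer steps per epoch at fixture scale, the longer schedule is what convergence requires |
| `dropout` | 0.5 | inside each MLP block, training mode only |
| `class_batchnorm` | on | batch normalization over the class-center matrix regularizes the geometry during training; frozen running statistics are used at prediction time |
| `nf_batch_size` | 256 | per-step sample from each NF list; full lists are used whenever they are smaller, and always for reported loss breakdowns |
| checkpoint metric | validation Fmax | early stopping / model selection; switchable to validation loss |
| evidence whitelist | 13 experimental codes (EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC, HTP, HDA, HMP, HGI, HEP) | applied when reading annotation tables |
| identity threshold / fractions | 50% / 81:9:10 | similarity-group splitting: proteins above the identity threshold share a group; *groups* (not proteins) are dealt to train/valid/test, so protein-level fractions deviate slightly |
| IC | conditional, bits | `IC(c) = −log₂ P(c | direct parents)` over the propagated corpus (the form Smin uses); a marginal `−log P(c)` variant and natural-log base are switchable. Never-annotated classes fall back to a pseudocount (default 1) |

## Design choices where the design was open

* **No deep-learning framework.**  The model's gradients are computed
  by a small purpose-built reverse-mode autodiff engine over numpy
  arrays (`ontoball.autodiff`), gradient-checked against finite
  differences.  All loss formulas are written once over ops that accept
  plain arrays or taped tensors, so evaluation and training share one
  implementation.
* **Model/Results API.**  `FunctionPredictionModel` holds the data and
  architecture choice; `fit()` returns a `FunctionPredictionResults`
  carrying parameters, per-epoch loss history, `predict()`,
  `evaluate()` and `summary()` — the two-object pattern familiar from
  statistical modelling libraries.  The CLI is a thin shell over these
  objects.
* **Fresh classes** participate in every NF loss but are never
  prediction targets and are hidden from ancestor closures of real
  classes.
* **Score propagation** (ancestor score ≥ descendant score) is
  available at prediction time but off by default; evaluation instead
  propagates *labels*, which is what the metrics assume.
* **Combination rule.**  "Model + similarity" rows use the convex
  combination `α·model + (1−α)·DiamondScore` with `α` tuned on the
  validation split by Fmax over a 0.01 grid.
* **Prediction-score head.**  The transpose in the scoring expression
  is read as an inner product between the protein embedding and
  `hF + fη(c)`; the only additive bias is the class radius.
* **Fmax convention.**  Precision is averaged over proteins with at
  least one prediction at the threshold; recall over all annotated
  proteins; thresholds on a 0.01 grid.  Sub-ontology roots are excluded
  from evaluation targets since propagation predicts them trivially.
* **Degenerate evaluation classes** (all-positive or all-negative in
  the evaluated set) are excluded from class-centric AUC with a logged
  count.

## The synthetic study

The generator (`ontoball.synthetic`) emulates the statistical structure
the method needs, at desk scale chosen for fast single-CPU runs:
60 classes (8 of them defined), 2 relations, 6 existential axioms,
maximum hierarchy depth 4, 300 proteins, vocabulary of 200 features.

* Each base class owns a disjoint block of 3 characteristic features.
  A protein samples one plus Poisson(1) primary leaf classes; its
  label set is the true-path closure.  Characteristic features of
  annotated classes switch on with probability 0.9, all other features
  with background probability 0.02.  When the two rates are set equal
  the features become iid coins — the no-signal control.
* **Honest definitions:** genus `D` and filler `E` of every definition
  are internal classes from different branches, and a protein receives
  the defined class exactly when its generative annotations contain
  both `D` and `E`.  Zero-shot recovery of a held-out defined class is
  therefore information-theoretically possible from the features of
  `D` and `E`, but never trivially readable from a dedicated feature
  (defined classes own no feature block).
* The synthetic all-vs-all hit table assigns percent identity
  proportional to the Jaccard overlap of two proteins' primary leaf
  sets (scaled into 85–100% of it), so near-duplicate proteins form
  groups for the splitter and annotation transfer carries real signal.

What the fixture does **not** emulate: real sequence evolution, GO's
topology statistics (tens of thousands of classes, deep multiple
inheritance), feature co-occurrence beyond class membership, or
annotation incompleteness.  Passing tests therefore demonstrate the
*mechanisms* — axiom-constrained geometry, zero-shot transfer through
definitions, leakage-controlled splitting — not field performance on
UniProt-scale corpora.

## Numerical notes

* Euclidean norms used in losses add 1e-12 inside the square root so
  the gradient stays finite at coincident centers; the induced value
  error is far below test tolerances.
* Binary cross-entropy is computed from logits in the numerically
  stable form `softplus(z) − y·z`.
* Hinge ties (`max`/`min` at equality) route gradient to the first
  argument.
* Batch normalization uses momentum 0.1 and eps 1e-5; evaluation mode
  always uses running statistics, and dropout is the identity.
* All randomness flows from explicit `numpy` generators seeded by the
  configuration; two runs with the same seed on one machine are
  bitwise identical, which the test suite asserts end to end.

## Known limitations

* Fitting is plain-numpy on one CPU; the implementation targets
  desk-scale studies (hundreds of proteins, tens of classes), not
  UniProt-scale training.
* The NF1 loss typically retains residual slack on dense hierarchies —
  perfect ball nesting of a DAG is not generally achievable in low
  dimension — which is expected and does not prevent the prediction
  head from separating classes.
* Zero-shot quality depends on how informative a held-out class's
  definition is; classes whose only axiom is a subclass edge are
  positioned by the hierarchy alone and score much closer to chance,
  a contrast the test suite checks explicitly.
* The brute-force entailment checker covers interpretations with at
  most three elements; it is a soundness probe for the rewrite shapes
  used here, not a general EL reasoner.
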
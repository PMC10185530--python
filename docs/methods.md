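# Methods

This note documents the models, defaults and design decisions behind the
package, and what the synthetic benchmark does and does not establish.

## Problem setting

The classifier answers a pairwise question: given an enzyme (amino-acid
sequence) and a small molecule (SMILES/InChI/Molfile), is the molecule a
substrate? Training data consist of positive annotations only; negatives
must be manufactured, and evaluation must control for enzyme homology,
because two near-identical sequences shared between train and test would
trivially inflate every metric.

## Negative sampling

For each positive pair (enzyme e, substrate s) the sampler draws
`n_per_positive = 3` distinct molecules m uniformly at random from the
pool, subject to:

* **window** — Tanimoto similarity T(m, s) within
  [`lower_bound` = 0.7, `upper_bound` = 0.95] over the similarity
  fingerprint (default: 1024-bit ECFP, radius 3; a path-based topological
  fingerprint is available via `fingerprint_kind="path"` because either
  is a defensible similarity input). The window makes negatives *hard*
  (similar to true substrates) while excluding near-duplicates;
* **relaxation** — if the window holds too few candidates, the lower bound
  drops in steps of `relaxation_step = 0.2` (clamped at 0) until enough
  candidates exist;
* **frequency cap** — molecule m may be sampled at most
  `cap_factor = 3` × (its occurrence count among the positives), which
  matches the negative molecule frequency distribution to the positive
  one. Molecules never seen among positives are never sampled;
* **no contradiction** — m must not be a known substrate of e, and a pair
  (e, m) is emitted at most once.

Positives are processed in seeded random order so cap consumption does not
favour early enzymes. Because `cap_factor` equals `n_per_positive`, the
total cap capacity exactly equals demand; a strict cap therefore leaves a
small end-of-run shortfall in essentially every run. The default policy
`on_exhaustion = "lift_cap"` lifts the cap for the affected positive
(flagging the event in the report, typically ~1% of positives on the
benchmark), which preserves the exact 3:1 augmentation ratio; the
alternative `"shortfall"` policy emits fewer negatives instead.

## Identity-aware splitting

Pairwise identity = identical aligned positions / length of the shorter
sequence, under global alignment with free end gaps (match +1, mismatch 0,
gap open −10, gap extend −1, via Biopython's PairwiseAligner). These
parameters reproduce the conventions of the standard greedy clustering
tools. Clustering is greedy-incremental (longest first, join the first
cluster whose representative is within `identity_threshold` = 80%),
followed by a single-linkage merge pass so the guarantee "no cross-cluster
pair above the threshold" holds *exactly*, not just against
representatives. Whole clusters are shuffled (seeded) into the test set
until the test **pair** fraction reaches `test_fraction` = 0.2; cluster
granularity makes exact 20% unattainable, so the nearest fraction at or
above the target is taken. Test enzymes are banded by maximum identity to
any training enzyme with half-open intervals [0, 40), [40, 60), [60, 80],
the threshold itself falling in the top band. CV folds (default 5) are
enzyme-disjoint and balanced by pair count (greedy largest-first into the
lightest fold).

## Molecule representations

* **ECFP** — 1024 bits, radius 3, structure-only invariants, implicit
  hydrogens, chirality not hashed (RDKit Morgan generator). 512/2048-bit
  variants are a parameter. A collision report lists distinct molecules
  with identical fingerprints (long homologs differing beyond the radius).
* **Task-specific fingerprint** — a directed message-passing network:
  messages live on directed bond edges; an edge update aggregates messages
  of edges feeding its source atom *excluding its own reverse*; after
  `mp_steps` = 3 rounds (depth is a free parameter; 3 covers the
  radius-3 neighbourhood), atom states are read out by element-wise mean
  into `hidden_dim` = 100 dimensions. A 100/32 fully-connected head on
  [fingerprint ‖ 50-d enzyme context] serves Michaelis-constant (KM)
  regression pre-training (log10-scale, standardized targets) and binary
  classification fine-tuning. Optimizer: Adam (lr 5e-3 default at desk
  scale), ReLU activations, Glorot initialization; the network runs on a
  small in-package numpy reverse-mode autodiff core, which keeps the
  dependency footprint minimal and is fully adequate at the hidden sizes
  used here.

## Enzyme representations

The per-residue embedding source is pluggable: precomputed matrices from
any protein language model are read from disk (manifest + whitespace
matrices); a miniature randomly initialized transformer (d = 32, 2 layers,
single-head attention, sinusoidal positions) serves as a desk-scale
stand-in. The full 1280-d pretrained transformer is deliberately not
re-implemented or re-trained — only its interface contract is.

* **Mean pooling** — the whole-enzyme baseline vector is the element-wise
  mean over residue embeddings.
* **PCA context** — the 50-component PCA of pooled vectors provides the
  compact enzyme context for fingerprint training; it is fitted on the
  training partition only, and fitting on test-tagged vectors raises.
* **Task token** — an extra token, initialized to the residue mean, is
  appended after the last residue and updated through the encoder exactly
  like a residue token; after the final layer it is concatenated with the
  molecule's ECFP and passed to a 256/32 head (configurable) trained
  end-to-end on substrate classification. The trained token is the
  task-specific enzyme vector. `use_extra_token=False` gives the ablation
  (post-hoc mean pooling of final residue states). Sequences beyond the
  encoder's positional capacity are truncated with a warning.
* **Identity profiles** — the fast, training-free representation used by
  the default pipeline: each enzyme is described by its percent identity
  to a fixed anchor panel (every 3rd enzyme of the input). This classic
  sequence-kernel representation uses no labels, and its axes are shared
  across homologous families, which lets tree ensembles transfer rules
  learned on one family to a related held-out family; raw random-projection
  embeddings do not transfer this way, because a held-out family occupies
  feature ranges the trees never saw.

## Classifier and model selection

XGBoost with the logistic objective on [enzyme ‖ molecule] vectors; label-0
rows carry sample weight `negative_weight` ∈ (0, 1]. The custom loss
**2·FNR² + FPR^1.3** is a *model-selection* criterion: it is computed from
each CV fold's confusion at threshold 0.5 and averaged over folds (mean of
per-fold losses, not pooled confusion), and the seeded random search
(default space: learning rate log-U[0.01, 0.31], depth 4–14, λ/α
log-U[0.1, 10], max delta step 0–5, min child weight [0.1, 10], rounds
50–500, negative weight [0.1, 1]) returns the argmin. The squared FNR term
penalizes missed substrates more strongly than false positives, countering
the 3:1 negative excess. Scores ≥ 0.5 are positive; scores in [0.4, 0.6]
(closed interval) are flagged uncertain. Baselines (logistic regression
with penalty/C search; random forest with tree-count search) run through
the same grouped-CV machinery.

Statistical comparisons: McNemar's test on paired predictions (exact
two-sided binomial when the discordant count b + c < 25, else chi-squared
with continuity correction) and the two-sided Mann–Whitney U test on
per-example 0/1 error indicators (exact enumeration of rank splits with
mid-rank ties when both samples have ≤ 8 observations, else the normal
approximation with tie correction).

## Synthetic benchmark

The generator emulates the statistical structure of real corpora at desk
scale; defaults were fixed once and define the study conditions.

* **Enzymes** — 8 families × 12 members, length 200, substitution-only
  mutation (no indels, so identity arithmetic stays exact). Families come
  in 4 superfamilies of 2; family ancestors diverge from the superfamily
  ancestor at rates (0.22, 0.22, 0.14, 0.14), placing sibling families at
  ~56% and ~68% identity — below the 80% clustering threshold, populating
  the 40–60 and 60–80 evaluation bands — while members mutate at rate 0.05
  (~90% within-family identity).
* **Molecules** — 6 scaffolds × 30 homologs sharing a ~25-atom backbone;
  each scaffold carries a distinct tail group (alcohol, amine, carboxylic
  acid, amide, thiol, nitrile) and homologs differ in a small distal
  terminal segment, so within-pool Tanimoto similarities densely populate
  the sampler's 0.7–0.95 window and a few terminal pairs collide to
  identical radius-3 fingerprints.
* **Binding rule** — an enzyme binds molecule m iff m's scaffold carries
  its superfamily's tail motif AND m's terminal-size rank falls in its
  family's window (16 of 30 ranks, shifted by 2 between siblings). The
  rule is structure-determined on both sides, so it can be learned from
  training families and transferred to held-out sibling families; the
  window shift leaves each family a few exclusive substrates, which
  surface as unseen molecules in the test set. Labels flip with
  probability 0.02 within the enzyme's scaffold (a realistic annotation
  noise level), and only (possibly noisy) positives are emitted — the
  pipeline, like a real corpus, starts from positives alone. The hidden
  truth is retained for tests only.
* **Encoder test sets** — a separate diverse pool (chains of widely
  varying length, tails, branches, rings) feeds the KM-regression and
  classification tests of the neural encoders; planted log-KM is linear
  in three substructure indicators plus a context term, with pseudo-enzyme
  contexts shared across molecules so the context cannot act as a
  memorization key.

**What passing tests show, and do not show.** The benchmark demonstrates
that each mechanism behaves as specified (window/cap/ratio guarantees,
leakage-free splits, rule recovery AUC > 0.9 across held-out clusters,
seen > unseen stratification, uncertainty-band behaviour). It does not
demonstrate transfer to real enzymes: real sequence–function relationships
are far less separable than the planted rule, real molecule pools are more
heterogeneous than homolog series, and real annotation noise is not
uniform. Absolute metric values on the benchmark should not be read as
forecasts for real corpora.

## Experiment sizing

The defaults are sized for a single CPU: the full pipeline on the default
benchmark runs in ~10 s; the KM pre-training experiment uses 100 molecules
× 3 contexts for 60 epochs (~6 s); the 5-seed pre-training comparison
~30 s; the task-token experiments use 16 enzymes × 12 molecules at d = 32
(~2 s per fit). The learning-curve experiment runs on a broad-family
variant (16 families × 3 members, 4 families per superfamily, window
12/shift 2) because on the default benchmark a handful of members per
family already saturates held-out AUC at the 30% training fraction,
leaving no trend to measure; with many small families, subsampling
enzymes removes whole families and the size effect is real. The curve is
averaged over three enzyme orderings to damp ordering noise.

## Numerical conventions and degenerate inputs

Tanimoto of two all-zero fingerprints is defined as 1.0, but such
molecules are rejected upstream (≥ 1 heavy atom required). ROC-AUC gives
ties half credit (mid-rank U statistic). MCC is reported as missing when
any confusion marginal is zero. Single-atom molecules have no bond
messages; their fingerprint is the readout of the transformed atom
features. Single-class training inputs raise; constant KM targets train
with a warning. All stochastic stages consume explicit seeds and are
bit-reproducible; XGBoost runs single-threaded for determinism.

## Known limitations

* The sampler treats all positives' evidence tiers equally; tier-specific
  sampling policies are not implemented.
* Greedy clustering with the merge pass can chain clusters together in
  dense identity landscapes (single-linkage behaviour); for corpora with a
  continuous identity spectrum an external cluster file can be supplied
  instead.
* The miniature transformer is a mechanism stand-in, not a pretrained
  model; task-token vectors extracted from it carry no biological prior.
* Calibration of prediction scores (Platt/isotonic) is out of scope; the
  [0.4, 0.6] uncertainty band is a reporting convention, not a calibrated
  credibility interval.
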
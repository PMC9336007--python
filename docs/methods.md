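# Methods

## Task and pipeline

`bioevent` extracts biomedical events from text annotated in BioNLP standoff
format. An *event* is a typed trigger word plus role-typed arguments
(`Theme`, `Cause`); arguments are entities or, in nested events, other
events. The event-type taxonomy (19 types by default, the MLEE inventory)
partitions into *simple* types (one trigger, one Theme) and *complex* types
(`Binding`, `Regulation`, `Positive_regulation`, `Negative_regulation`),
which may take multiple and/or event-valued arguments.

The pipeline has five stages:

1. **Representation.** Two embedding tables per model: a frozen table x_t
   (loaded from word2vec-text vectors, or seeded uniform random in
   [-0.05, 0.05] when no vector file is supplied) and a trainable table
   x'_t initialized as its copy. The *sentence embedding* is the
   per-sentence mean of their difference, d_0 = (1/n) Σ_t (x'_t − x_t):
   exactly zero at initialization and growing where fine-tuning has moved
   words, i.e. a summary of the task-relevant words in the sentence.
   Out-of-vocabulary tokens map to an UNK row set to the mean of all loaded
   vectors; PAD is all-zero and re-zeroed after every update.
2. **Reading-gate BiLSTM.** An LSTM cell with both input streams in every
   gate and a third state vector d_t ("sentence memory") initialized from
   d_0 (linearly projected when the embedding and hidden dimensions
   differ) and decayed per step by a sigmoid reading gate:
   d_t = r_t ⊙ d_{t−1}, c_t = i_t ⊙ c̃_t + f_t ⊙ c_{t−1} + tanh(d_t),
   h_t = o_t ⊙ tanh(c_t). The output equation is the standard LSTM one —
   the only reading in which the output gate has a consumer. With d_0 = 0
   the d-pathway vanishes identically (bitwise), giving the plain-BiLSTM
   ablation baseline. Directions are combined by element-wise summation
   (concatenation available via `combine="concat"`); both directions share
   the same d_0, which is order-invariant by construction.
3. **Trigger identification.** BIO tagging over sentence tokens
   (2·19 + 1 = 39 tags). Word-level attention condenses the token states
   into one attended context h* = tanh(H softmax(wᵀ tanh(H))ᵀ); each token
   is classified from [h_i ; h*] by a softmax layer. This resolves the
   tension between a single attended sentence vector and per-token labels:
   the pure-sentence-vector reading cannot label individual tokens. Decoding
   repairs stray I- tags by opening a new run (no CRF/Viterbi).
4. **Fine-grained argument detection.** Candidates are sentence fragments
   (trigger tokens, target tokens, everything between). Simple-type
   triggers pair with every same-sentence entity; complex-type triggers
   additionally pair with every other trigger. The candidate's instance
   vector is the mean over fragment positions of [h_j ; h*] plus two
   indicator features (target-is-trigger, target-precedes-trigger), since
   the unordered fragment destroys orientation. Candidates sharing a
   trigger ("relevant arguments") form a group; sentence-level attention
   weights the group's instance vectors against each other
   (out_i = tanh(v_i · α_i)) before classification. Two disjoint label
   spaces and heads — {NONE, Theme} for simple candidates,
   {NONE, CTheme, CCause} for complex ones — are trained jointly with
   summed cross-entropy; a single unioned coarse head is the
   non-fine-grained baseline. A residual variant of the group attention
   (out_i = tanh(v_i · α_i + v_i)) exists behind a flag, off by default,
   because the published form lets a near-zero weight annihilate an
   instance before its own classification.
5. **Assembly.** Per trigger, predicted edges combine by type class:
   simple types take the single highest-probability Theme; Binding merges
   all Themes into one event; Regulation-family types build one event per
   Theme, each paired with the best Cause if present (an event-valued
   argument binds to the first event assembled for the target trigger).
   Nesting resolves by fixpoint iteration (at most one round per trigger);
   unresolved references are dropped and logged. An optional learned
   filter — a hinge-loss linear classifier over md5-hashed sparse features
   (bag-of-words between argument extremes; role pattern and per-role
   counts; target types and edge labels) — vets structures per round
   (post-hoc mode behind a flag). Assembled documents always pass
   structure validation.

## Scoring

Precision, recall and F are computed from TP/FP/FN counts with 0/0 := 0.
Matching is exact and one-to-one: triggers by (span, type); argument edges
by (trigger span+type, role, target span); events recursively by trigger
and full argument structure. Under exact matching, one-to-one assignment
reduces to multiset intersection of canonical forms, which is maximal (the
tests verify this against an exhaustive bipartite oracle). An
approximate-span trigger mode (overlap suffices) is available behind a
flag; exact is the default because it is the strictest reproducible choice.

## Hyper-parameters

Published defaults are kept: embedding and sentence-embedding dimension
200, hidden size 200, 2 BiLSTM layers, dropout 0.5 (between layers and
before classifiers, disabled at inference), batch size 64, 100 epochs,
Adadelta. `learning_rate` multiplies Adadelta's adaptive step; the default
0.001 follows the published configuration, but note that Adadelta's
original formulation corresponds to multiplier 1.0, and with 0.001 the
effective step (~1e-6) is too small to fit small corpora in few epochs.
The package's own tests and the acceptance script therefore train with
Adadelta at `learning_rate=1.0` and desk-scale model sizes (embedding and
hidden dimension 12–24, 1 layer, dropout 0 — dropout's regularization is
counterproductive when the goal is fitting a 20-sentence corpus), which
are recorded with each run. All randomness flows from a single integer
seed; training is single-threaded and bitwise reproducible.

## Synthetic corpora

The generator emulates the structure the method exploits, not biomedical
grammar: template sentences over a closed ~160-word vocabulary, with typed
entities, a regulation-dominant event-type skew, multi-Theme Binding
events (`binding_multi_theme_prob`, default 0.4), nested Regulation-family
events (`nesting_prob`, default 0.35; Cause- and Theme-nesting both
generated), and distractor entities that yield NONE candidates. A fraction
`ambiguity_rate` (default 0.3) of trigger slots uses a word shared between
two event types; every sentence deterministically contains cue words
specific to the true type, so trigger disambiguation is learnable from
sentence context — the property the sentence-embedding pathway targets.
Default `complex_fraction` is 0.55, matching the dominance of complex
events in multi-level corpora. For n ≥ 100 sentences the first 19
sentences cycle through all event types once, guaranteeing full type
coverage; the remainder is sampled i.i.d. from the configured skew.

What the generator does *not* emulate: real biomedical syntax, paraphrase
variety, cross-sentence arguments, discontinuous triggers, annotation
noise. Passing tests on these corpora therefore demonstrate mechanism
correctness and learnability under controlled conditions, not performance
on real corpora.

`corrupt_predictions` degrades gold annotations at a controlled rate
(delete or retype, 50/50) to test assembly and scoring under imperfect
inputs.

## Numerical choices

Everything runs in float64 on a minimal reverse-mode autodiff tape
(`bioevent.autodiff`), which keeps scalar-loop oracle comparisons at
1e-10 and analytic-vs-numerical gradient checks at 1e-4 meaningful.
Softmax and log-softmax subtract the row maximum before exponentiation.
Cross-entropy selects the gold-class probability before the log, so a
certain correct prediction gives exactly 0. Argmax ties break to the
lowest index. Weights initialize Glorot-uniform; attention vectors uniform
in [-0.1, 0.1]; biases at zero. Gate activations are sigmoids and
therefore lie strictly in (0, 1).

## Problem sizes used by the test suite and acceptance script

Pure-NumPy training on one CPU sets the scale: capacity (overfitting)
checks use a 20-sentence corpus, ≤100 epochs, embedding/hidden 24/24,
1 layer. Ablation-direction comparisons use 120 training / 60 held-out
sentences, three model seeds, and assert the direction of the mean
difference only, never magnitudes. The sentence-embedding comparison runs
in the fully ambiguous regime (`ambiguity_rate=1.0`: every trigger word is
shared between two event types and resolvable only from cue words placed
early in a long sentence) with a deliberately small hidden state
(12), so held-out trigger F isolates disambiguation from global sentence
context — the mechanism the d0 pathway supplies; at lower ambiguity or
larger hidden sizes a plain BiLSTM carries the cue locally and the
comparison measures nothing. The attention and fine-grained comparisons
use nesting-heavy corpora (`complex_fraction=0.7`, `nesting_prob=0.6`).
Exact sizes are in `tests/test_acceptance.py` and `scripts/acceptance.py`.

## What the ablation comparisons show — and do not

The three ablation-direction comparisons are mechanism checks under
controlled conditions, and their outcomes at desk scale are mixed in an
instructive way; the corresponding tests assert the expected directions
and are allowed to fail rather than being weakened.

* **Multi-level vs word-level attention** (complex-edge F): holds in the
  probed regime.
* **Sentence embeddings vs plain BiLSTM** (trigger F on fully ambiguous
  corpora): does **not** hold robustly. With random-initialized rather
  than corpus-pretrained tables, the d0 signal is pure fine-tuning drift;
  its held-out effect sits at the noise floor (fractions of a point,
  sign varying by seed and corpus draw, slightly negative on the mean in
  the final configuration). A genuine test of this mechanism needs real
  pretrained vectors, whose acquisition is out of scope.
* **Fine-grained vs unioned heads** (event F): does **not** hold. In the
  template grammar the surface realization of Theme arguments is the same
  for simple and complex events, so sharing one head across modes is
  strictly beneficial with little data. Separate heads pay off only when
  simple and complex argument realizations diverge — a property of real
  corpora that the templates do not emulate.

## Known limitations

* Within-sentence arguments only; gold cross-sentence edges would be
  dropped from training and unreachable in evaluation (the generator never
  produces them).
* Overlapping gold triggers cannot be expressed in BIO; the longer span is
  kept and the clash logged.
* An event-valued argument binds to the first event of the target trigger,
  not to all of them (no event duplication).
* The structure filter is deliberately simpler than a full feature-template
  system; it shares only the three feature families' spirit.
* Training dependency-based word vectors is out of scope; vectors are
  loaded from word2vec text format or random-initialized.
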
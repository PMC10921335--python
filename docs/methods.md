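# Methods

This note records the models implemented in `topicrisk`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Preprocessing

Cleaning strips URLs, e-mail addresses and symbol noise by regular
expression, using a conservative whitelist (letters, digits, CJK, basic
punctuation survive; everything else — emoticons, dingbats, control
characters — is removed).  A whitelist was preferred over an emoji
blacklist because the space of noise symbols is open-ended.  Cleaning is
idempotent and never mutates the stored raw text.

Segmentation is pluggable.  The default backend splits on whitespace after
protecting user-dictionary terms by longest-match replacement, which is
sufficient for the ASCII pseudo-word corpora the generator emits and for
Latin-script text.  A dictionary-aware CJK segmenter can be substituted at
the pipeline level; every downstream module consumes token lists only.
Longest-match protection means a dictionary term is emitted as one token
wherever it appears verbatim, which is also how dictionary-aware
segmenters for Chinese behave.

The ultrashort filter drops comments with fewer than `min_tokens` tokens
(default 3).  The threshold is not dictated by the method; 3 removes
one/two-word replies ("Thank you!") while keeping minimal symptom reports
("pollen sneezing today").  Vocabulary ranking is count-descending with
lexicographic tie-break so that coverage curves are deterministic.
`min_count` defaults to 1 (no pruning).

## Topic dictionary

Seeds are the deduplicated union of tokens from risk-factor phrase spans.
Expansion repeatedly adds, for every current member, its `topn` nearest
vocabulary neighbors by cosine over the input-matrix rows.  The loop stops
after `iterations` rounds or at a fixed point, whichever comes first —
the expansion loop needs an explicit bound because nearest-neighbor
adoption alone rarely reaches a fixed point before absorbing the
vocabulary.  Neighbor lists exclude the query word and current members.
`similarity_floor` defaults to −1 (pure top-n rule; no cut).

Weights: risk-factor words get `risk_weight` (default 2.0), other topics
`default_weight` (default 1.0).  A word belongs to at most one topic; on
conflict the higher weight wins, first-come on ties.  The weight
multiplies the word's topic-loss term during embedding training, so
risk-factor words exert proportionally more supervision.

## Topic-enhanced embedding

Training examples come from a ±c sliding window (c defaults to 5) over
each comment; one comment is one batch.  The loss has two parts:

* `L_cont`: mean negative log-likelihood of each context word given the
  center word's input vector.  Full softmax when `negative_samples = 0`
  (the default, suitable for vocabularies up to a few thousand words);
  the standard negative-sampling objective with a unigram^0.75 noise
  distribution otherwise.
* `L_topic`: mean over dictionary-labeled centers of the
  dictionary-weight-scaled cross-entropy of the true topic under a
  softmax over a separate topic-output matrix, computed from the center
  word's input vector.

`L_s = L_cont + λ·L_topic`, λ default 1.0.  Words absent from the
dictionary contribute nothing to `L_topic`: forcing a "background"
prediction for unlabeled words would fabricate supervision.  A
(K+1)-class variant with a background class exists behind
`background_class=True` for experiments.

Losses are averaged per batch (per comment), and the per-epoch log stores
batch-mean values; the logged `L_s` is derived from the logged component
means so the decomposition identity holds exactly in floating point.  The
training sequence is the comment's token sequence; its length plays the
role of the sequence-length bound in the window enumeration (the symbol
is sometimes conflated with the vocabulary size in the literature; here
it is always the sequence length).

Initialization: input matrix uniform in [−0.5/d, 0.5/d], output matrices
zero, seeded by `rng_seed`; SGD with learning rate 0.025 and linear decay
to ~0 over the run; epochs default 5.  No frequent-word subsampling by
default.  All gradients are analytic and checked against central finite
differences (relative error < 1e-4) in the tests; with λ = 0 the
trajectory coincides with an independently written plain Skip-gram
baseline to < 1e-10 per parameter, which is the package's strongest
correctness anchor.

`most_similar` ranks by cosine over input-matrix rows with stable
vocabulary-index tie-breaking.  Vectors are exchanged in word2vec text
format with full-precision `repr` floats so that save/load round-trips
are bit-exact.

## Convolutional classifier

Comments are represented as a `max_len × d` matrix of their token vectors
(tail truncation, zero padding, zero rows for out-of-vocabulary tokens).
Kernel widths {2, 3, 4} with 64 filters each, ReLU, global max-pooling,
one affine layer, 2-class softmax; dropout 0.5 on the pooled features
(inverted dropout, seeded); Adam with learning rate 3e-3; 10 epochs;
batch size 32.  Embedding rows are frozen: the classifier is a pure
consumer of the vector file.

One internal normalization matters: the norm of trained embedding rows
depends on corpus size and epochs, and convolutional feature scales
inherit it.  `train_classifier` therefore fixes `input_scale` — the
reciprocal of the mean nonzero-row norm over its training set — inside
the parameter object, and every forward pass applies it.  Public
`vectorize` output is unscaled.

Evaluation follows the standard protocol: stratified 90/10 split,
stratified 10-fold cross-validation on the training portion (stratified
because the labeled set is near-balanced), confusion counts per fold, and
accuracy / precision / recall / F1 recomputed from the stored counts on
access so the metric identities cannot drift.  The decision threshold
defaults to 0.5 and is configurable (recall-oriented deployments lower
it; the method's goal is to miss as few risk factors as possible).

## Single-pass clustering with review

Documents are embedded as the unweighted mean of their in-vocabulary
token vectors (an IDF-weighted mean is available via `idf_weights` and
the `token_weights` argument of `doc_vector`).  All-OOV documents have
zero norm, are quarantined, and are reported separately rather than
clustered.

The single pass processes documents in input order: each joins the
category with the highest centroid cosine if that cosine ≥ θ, otherwise
founds a new category; centroids update incrementally as member means.
θ is a required-attention knob with default 0.5: the similarity threshold
is the one free parameter of single-pass clustering and should be chosen
per corpus; 0.5 is the conventional midpoint for cosine similarities of
mean-of-word-vector documents.  Matching is against evolving centroids,
not individual members.

Because early documents found categories whose centroids later drift, the
plain single pass is order-sensitive and strands stragglers as
singletons.  The review pass runs once after all documents are seen: each
singleton is re-scored against all non-singleton centroids and merged
where the best cosine clears θ.  Singletons are not merged with each
other (that would re-run the original problem), and merged singletons are
not revisited, so the sweep terminates and neither the category count nor
the singleton count can increase.  The review report lists each
category's size and most-central members for the human reviewer, whose
merge/relabel decisions can be applied back with a full audit log.

## TextRank keywords

Each category is one document: members' token lists are concatenated and
a co-occurrence graph built (undirected edge per token pair at distance
< window, weight = pair count, no self-loops; window 5).  Scores iterate

    S(u) = (1 − dfac) + dfac · Σ_{v∈N(u)} w(u,v)/deg_w(v) · S(v)

from uniform initialization with damping 0.85 until the largest change
drops below 1e-6 (max 200 iterations) — the conventional TextRank
settings.  Isolated nodes score exactly 1 − dfac.  The test oracle is a
closed-form linear solve of the fixed-point equations, not another
iteration, so implementation and oracle cannot share a bug.  Reported
keyword weights are score shares of the category's total mass, so a
top-10 listing sums to less than 1; raw scores are available from
`textrank` directly.

## Synthetic corpora

The generator plants `n_topics` topic vocabularies of `words_per_topic`
ASCII pseudo-words plus a Zipfian background vocabulary (exponent 1.1 —
heavy-tailed, so a small top-ranked slice of the vocabulary dominates
token coverage as in real comment corpora).  Risk comments draw each
token from their topic with probability `topic_purity` (default 0.9),
else from the background; non-risk comments draw background only.  Label
and ultrashort allocations are exact (`round(n·fraction)`), not binomial.
Everything is driven by one integer seed through numpy's PCG64.

Preset configurations fix the benchmark conditions used throughout the
tests and the acceptance script: the embedding benchmark (2 topics × 50
words, 2000 comments, purity 0.9), the labeled set (n = 400, balanced),
and the clustering benchmark (5 topics × 30 words, 500 risk documents,
purity 0.95).  These sizes keep every benchmark within a few minutes on
one CPU while leaving all effects far from the decision boundaries of the
assertions.

What the generator does **not** emulate: natural-language grammar and
discourse, polysemy, topic overlap, comment-length/label correlation,
spam, or the vocabulary scale of a real platform corpus.  Passing tests
therefore demonstrate that the algorithms behave as specified under
controlled planted structure — not that any particular accuracy carries
over to real social-media text, where class separation is far weaker.

## Pipeline

`topicrisk run` executes synth → preprocess → dictionary → embed →
classify → cluster → keywords from one YAML config.  The dictionary stage
expands seeds against a short plain Skip-gram run (expansion precedes the
topic-supervised training that consumes the dictionary); the embed stage
then trains the topic-enhanced model.  Every artifact is hashed
(SHA-256) into a manifest; reruns resume from the last completed stage,
manifests from a different config are refused as stale, and wall-clock
timings go to the log rather than the manifest so identically seeded runs
are byte-identical.  Stage on/off flags and the output directory are
excluded from the config fingerprint because they do not affect artifact
content.

## Known limitations

* The whitespace segmenter cannot exercise genuinely unsegmented CJK
  input; only the dictionary-protection path is shared with a real CJK
  backend.
* Full-softmax context loss is quadratic in vocabulary size; switch to
  negative sampling (`negative_samples=5`) beyond a few thousand words.
* The review pass is a single sweep by design; pathological orderings can
  still leave recoverable singletons if every non-singleton centroid is
  below θ at review time.
* Cluster identity depends on document order (inherent to single-pass);
  the review pass reduces but does not eliminate it.
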
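# Methods

## Document model

An article is raw text split into paragraphs and, within each paragraph,
into sentences. All coordinates are 0-based, half-open character spans into
the article's raw text; paragraph texts are joined with a fixed two-newline
separator, and answer character offsets from SQuAD-dialect input are
remapped into these global coordinates at load time, which makes loading
reversible (round-trip tested) and gives every downstream step a single
coordinate system.

Sentence segmentation is rule-based and deterministic: a run of
sentence-final punctuation followed by whitespace closes a sentence unless
the preceding token is on a short abbreviation guard list (e.g., i.e.,
etc., fig., al., …). A learned segmenter would handle prose edge cases
better, but a deterministic one makes every downstream count reproducible,
and the synthetic generator writes unambiguous boundaries on purpose.
Consequence: sentence counts on real articles depend on this segmenter and
are not comparable across toolchains.

The *gold sentence* of a question is the sentence containing the answer's
start character; an answer that spans several sentences is attributed to
the sentence of its start (the window parameter recovers the remainder).
When no offsets exist (BioASQ-style records), gold sentences are found by
token matching — every sentence whose normalized token sequence contains a
gold answer's tokens contiguously — and the *target paragraph* aggregates
all paragraphs owning a match, in document order. Token matching can
return non-answer sentences when answers are short and frequent; that is a
property of the data, not a bug, and the empty result is representable.

## Answer metrics

Token-level F1/EM normalization: lowercase, remove Unicode punctuation
(removal, not replacement, so hyphenated tokens merge: `T-UCstem1` →
`tucstem1`), remove the articles a/an/the, split on whitespace. Token
counting is multiset, multi-reference aggregation takes the best F1 (ties:
first reference). The article-removal variant was chosen because it is the
only variant consistent with the worked-example scores the implementation
is validated against (0.14 and 0.92 on the vaccine-delivery example; the
variant without article removal yields 0.13 and 0.93). A reader abstention
scores 0 against a non-empty gold and 1 against an empty one. Whether the
exact-match metric should also remove articles cannot be decided from the
validation values; the same normalization is applied uniformly.

Context F1 (the optimization objective) deliberately uses a *different*
tokenization: lowercase, punctuation stripped, whitespace split, **no**
article removal — it is a plain word count of the selected context against
the target paragraph, and nothing constrains the articles-removed variant
there.

## Readers

The reader contract is `predict(question, context) -> (answer | abstain,
confidence)`, with confidence unbounded and only required to be comparable
across contexts for a fixed question. A transformer reader adapter would
define confidence as the sum of start- and end-span scores; none is
required by any test, and no attempt is made to reproduce the confidence
magnitudes of any particular model.

The scripted reader emits its planted answer iff the answer sentence is
present in the context (exact sentence-text containment) and at least
`min_support` support sentences are present; confidence is `c_base +
c_per_support · (#supports present)` when answering and the constant
`c_abstain` otherwise (defaults 2.0 / 1.5 / 0.5). This reproduces the
qualitative behaviour that motivates utility estimation — relevant but
insufficient context yields abstention — while staying exhaustively
verifiable (the emission rule is tested over all sentence subsets). One
simplification matters for label analysis: real readers' confidence varies
even while abstaining, whereas the scripted reader's does not, so contexts
that lack the answer sentence all carry leave-one-out labels of exactly
zero and the cross-scenario label ordering is strict only for the
sufficient-context scenario.

## Utility signals and ensemble

u1 and u2 are leave-one-sentence-out differences (answer F1 and reader
confidence, respectively); deleting a sentence re-joins the remainder with
single spaces. Reader calls are memoized on (question, exact context
string), so scoring S sentences costs S+1 reader calls; the cache is
equivalence-tested against uncached recomputation. u3 is question–sentence
cosine similarity.

The default embedder is a hashed bag-of-words term-frequency encoder
(dimension 2¹⁶, keyed blake2b hash, fixed seed, L2-normalized) — a
deterministic, dependency-free stand-in for a trained bi-encoder that any
`embed(text) -> unit vector` object can replace. Texts with no tokens
embed to the zero vector and score cosine 0.

Because u2 is reader-scaled and unbounded while u3 lives in [−1, 1], each
signal is min–max rescaled to [0, 1] across the candidate sentences of one
question before the weighted ensemble. This makes the weights
interpretable and the peak threshold *h* (a fraction of the maximum)
meaningful. A constant signal rescales to all zeros (it carries no
ranking information). The ensemble accepts any positive weights rather
than weights strictly inside (0, 1); endpoint weights are harmless under
the normalized mean.

A learned estimator can replace the oracles at inference through the
`estimate_utility(question, sentence, context)` contract. The shipped
baseline is ridge regression on five lexical features (question-token
overlap, overlap fraction, sentence length, relative position, cosine to
the question), trained on generated triplets and serialized as JSON. It is
a floor, not a ceiling: it captures lexical relevance, not multi-sentence
sufficiency.

## Extraction

Candidates are the sentences of the top-k retrieved paragraphs. Peaks are
all candidates with ensemble score ≥ h·max — a global relative threshold,
not local maxima (a local-maxima variant exists behind a flag for
comparison). Each peak contributes the w sentences before and after it,
with distance measured in article sentence index but membership clipped to
the candidate set, so a window never imports a sentence that was never
scored; whether windows should be allowed to cross into non-retrieved
paragraphs is genuinely open, and the clipped reading was chosen for
consistency. Selection is superset-monotone as h decreases or w increases,
and the argmax sentence is always selected — these are structural
invariants, tested over random score vectors.

Degenerate case: if every candidate ties after rescaling (max score 0),
every candidate would be a "peak" at any h; instead the fallback keeps the
earliest argmax and its window only, preventing an uninformative score
profile from selecting the entire document.

Baseline policies for comparison: the full article, the top-k paragraphs
concatenated in document order (k = 6 by default), the target paragraph,
and a uniformly random paragraph as a floor.

## Training-data generation

Triplets (question, focus sentence, context) are sampled under four
context-quality scenarios: (1) the target paragraph verbatim; (2) a
contiguous run of 1–5 sentences around the gold sentence excluding the
gold sentence itself, sampled by drawing a length and an offset within the
target paragraph and deleting the gold sentence if covered; (3) the
adjacent paragraph, preferring the preceding one when both neighbours
exist (a deterministic preference, documented rather than coin-flipped);
(4) with equal probability, the paragraph furthest from the target by
paragraph-index distance or a paragraph from another article. The focus
sentence is uniform over the context; labels are computed live with the
reader, so stored labels are exactly recomputable from stored contexts.
Unsatisfiable scenario/question pairs (e.g., adjacent paragraph in a
single-paragraph article) are skipped and tallied. How many triplets to
draw per scenario per question is configuration (default 1/2/1/1 per
question); nothing hinges on the historical split sizes of any particular
external dataset, which are likewise configuration.

## Parameter optimization

The loss is L = −(α·obj1 + (1−α)·obj2), minimized per α over the grid
0.05…0.95 in steps of 0.05. The alternative parenthesization
−(α·obj1) + (1−α)·obj2 — which *rewards small* context F1 — is also
implemented (`sign_convention="as_printed"`) because the scalarization is
genuinely ambiguous as written; the default is the reading consistent with
the target paragraph being desirable, and under it the returned optimum is
never Pareto-dominated within its own trace (tested).

The default backend is seeded random search over bounded ranges (k ∈
[1, 10], w ∈ [1, 5], h ∈ [0, 1], ω ∈ [0.05, 1]); a model-based backend
(Gaussian-process surrogate, Matérn 5/2, expected improvement over random
candidate pools) is available behind the same interface. Random search was
made the default for determinism and testability: both backends are
seeded, but the GP's usefulness at desk-scale budgets is marginal.
Objective values do not depend on α, so evaluations are cached across the
α-sweep.

## Synthetic corpus: what it emulates, and what it does not

Defaults: 8 paragraphs per article, 6 sentences per paragraph, 3 questions
per article (the headline 200-question study uses 50 articles × 4
questions, seed 0), 2 support sentences per question, 6 question tokens, a
2-token globally-unique nonsense answer, distractor leak rate ρ = 0.2, a
400-word filler vocabulary. Support sentences are planted *contiguously
around* the answer sentence inside the target paragraph — the design
premise of windowed extraction is that the needed information is local to
the answer, and the generator instantiates that premise; the answer
sentence carries half the question's tokens and each support a third,
while each distractor paragraph receives ⌈ρ·6⌉ leaked question tokens.

Passing tests on this corpus therefore show that the pipeline recovers
planted local answer/support structure under lexical retrieval noise; they
do not show robustness to the ways real articles are harder: supports far
from the answer or in other paragraphs, paraphrase with no lexical overlap
between question and context (where the hashed-BoW embedder is blind),
ambiguous sentence boundaries, imperfect gold annotations, or reader
idiosyncrasies such as confidence varying under abstention. Answer tokens
are globally unique by construction so that offset-based and token-match
gold location agree exactly; real short answers recur, and token matching
then over-returns sentences.

## Numerical and degenerate-input conventions

Ties in paragraph ranking keep the earlier paragraph; retrieved paragraphs
are returned in document order (rank order behind a flag) so concatenation
preserves article flow. Ties in the overlap reader go to the earliest
sentence. An answer offset falling in inter-sentence whitespace belongs to
the following sentence. Empty or whitespace-only text segments to no
sentences; an empty reader context yields abstention, not an error; a
reader exception during evaluation is recorded as an abstention and
tallied. Significant-change counting uses strict inequality at the 0.5
threshold, and "worse despite good context" requires only that the gold
sentence was selected (the stricter "and its surroundings" reading is not
quantifiable and is deliberately not used). Embedder unit norm is enforced
to 1e-9 except for the zero vector of token-less text.

## Problem sizes

The test suite runs the full pipeline at desk scale: the headline recovery
simulation uses 200 questions (50 articles, ~2,400 sentences) with the
confidence oracle and scripted reader; oracle-equivalence checks enumerate
all 2⁸ sentence subsets of an 8-sentence scripted article and 1,000-draw
random-input comparisons for each metric; searches use budgets of 6–15
evaluations on 8-question validation sets. These sizes were chosen so the
whole suite completes in well under a minute while every claim is still
measured, not asserted.
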
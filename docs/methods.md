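# Methods

## Problem setting

The pipeline targets comment streams from recovery-oriented web forums,
where users describe treating withdrawal symptoms with named substances.
The unit of association is the sentence: a substance and an effect
mentioned in the same sentence are taken as potentially related, without
any claim of causality or favorability. The goal is a ranked table of
symptom–remedy candidates strong enough to merit expert review.

## Sentence segmentation

Forum text is noisy, so segmentation is rule-based and pluggable: a
sentence ends at a run of `[.!?]` (optionally followed by closing quotes
or brackets) that is itself followed by whitespace, or at a newline.
Runs are never split internally, so ellipses stay intact; a dotted
abbreviation stop-list (`e.g.`, `i.e.`, `Dr.`, `vs.`, …) suppresses
false splits; mid-token periods (decimals, paths) never split. The
segmenter guarantees that sentence spans cover all non-whitespace text
and that `body[start:end] == text` for every sentence, which downstream
gold-offset bookkeeping relies on.

Deletion is detected from the body (`[deleted]` / `[removed]`), not the
author field, because body replacement is how the platform marks
removed content and the corpus summaries count non-deleted bodies.

## Entity extraction and evaluation

Extraction is behind a file contract (mention JSONL with sentence-level
character offsets); the shipped reference extractor is a
case-insensitive, word-boundary-anchored gazetteer with left-to-right
longest-match, non-overlapping semantics. Ties at the same start
resolve to the longer surface; scanning resumes at each match end.
Statistical NER models are deliberately out of scope here — the
downstream pipeline is extractor-agnostic, and any model that emits the
same JSONL plugs in.

Evaluation is exact match: a prediction counts iff a gold mention with
identical sentence, boundaries *and* label exists, one-to-one.
Precision, recall and F1 are reported per label and overall as
percentages; degenerate denominators yield 0 by convention. Hold-out
splits are drawn at the comment level (default 20%), half-up rounding
of the test-set size, seeded.

## Deduplication

Entity mentions are fused into single tokens (internal whitespace →
underscore, lowercased) and embeddings are trained on the resulting
token stream. Because no pretrained-embedding dependency is wanted, the
embeddings are count-based, the classic construction that approximates
skip-gram factorization:

1. symmetric windowed co-occurrence counts (default window 5, minimum
   token frequency 5);
2. PMI reweighting with context-distribution smoothing (counts raised
   to 0.75 on the context side), clipped at zero;
3. row-wise L2 normalization, so token frequency does not dominate the
   spectrum;
4. truncated SVD (ARPACK with a seeded start vector; singular vectors
   sign-fixed by making each column's largest-magnitude entry
   positive), embedding = U·√Σ, rows L2-normalized;
5. concatenation with a hashed character-n-gram block (3–4-grams of the
   `<token>`-padded surface, CRC32-hashed into 32 dimensions), weighted
   so cosine similarity blends 70% distributional and 30% orthographic
   signal.

For this construction the SVD rank behaves as a smoothing parameter
rather than a capacity parameter: too high a rank preserves
token-idiosyncratic noise and under-merges variants. The default rank
is d = 50, which on corpora with vocabularies of a few hundred tokens
merges misspelling variants reliably while keeping distinct entities
apart; d, window, minimum frequency and the subword weight are all
configurable.

Clustering is agglomerative with average linkage on cosine distance,
cut at threshold τ = 0.3, run separately per label so no cluster can
mix substances and effects. Surfaces absent from the embedding
vocabulary become singletons rather than being dropped. Each cluster is
replaced by its most frequent member (ties broken lexicographically for
determinism). The expert-review table applies a second many-to-one
merge (chains are resolved to their fixpoint) and attaches categories;
exporting a review template and re-importing it unchanged is the
identity.

## Co-occurrence network and PPMI

Counting uses presence semantics: a sentence contributes at most 1 to
an edge count c and at most 1 to each node count n(x), which guarantees
p(s,e) ≤ min(p(s), p(e)). N is the total sentence count of the
non-deleted corpus — including sentences without mentions — because the
probabilities are per-sentence occurrence rates. PPMI uses log base 2,
the standard collocation convention; the ego-network default thresholds
(PPMI ≥ 1.5, count ≥ 10) are interpreted in this base. Since the
ranking min–max-scales PPMI, switching to natural log rescales all
values by a constant and leaves every downstream ranking unchanged.

## Ranking

Edge score = (minmax(ln c) + minmax(PPMI)) / 2, with the min–max taken
over the full edge set of the network (one scaler before per-symptom
selection, not a per-symptom scaler; this is a config choice). The log
reduces count skewness. If a component is constant its scaled value is
defined as 0. Per symptom, candidates need count ≥ 5 and a category
outside the excluded set ({opioid} by default); the top k = 10 are
kept, ties broken by higher count then name. Some symptoms have fewer
than k eligible substances, so the pair table may hold fewer than
|symptoms|·k rows. Quintile boundaries over the score-ranked table are
ceil((q−1)n/5) .. ceil(qn/5); per-quintile validity is the
integer-rounded share of rows labeled as approved/common treatment,
potentially useful, or home/natural remedy.

A default withdrawal-symptom list (16 effect names) ships as an
editable text file; the rank stage reads whichever file the config
points at.

All printed percentages round half-up at the precision of the table
they appear in (2 decimals for deduplication reductions, 1 for
frequency tables, integers for quintile validity).

## Synthetic corpus generator

The generator emulates the statistical structure the pipeline assumes:

* **Lexicon** — pseudo-word canonicals built from a syllable inventory,
  with per-entity variants generated by single/double character edits
  or truncations, globally unique by construction; Zipf base
  frequencies within each label; substances carry a cycling
  pharmacological category whose first slot is *opioid* so the
  exclusion path is always exercised.
* **Association model** — a joint table p(s,e) over canonical pairs.
  `plant_associations` starts from the independence joint, multiplies
  chosen cells by a strength factor and renormalizes; an engineered
  joint can also be supplied directly.
* **Sentence model** — each sentence draws one mutually exclusive
  event: a pair from the joint with probability r (the co-mention
  rate, default 0.3), a lone substance or lone effect drawn from the
  marginals with probability √r − r each, or nothing. With these
  calibrated lone rates the sentence-level occurrence probabilities are
  p(s,e) = r·joint(s,e) and p(s) = √r·marginal(s), so the
  sentence-level PMI equals the model's analytic PMI *exactly* — the
  network stage's PPMI estimates converge to `true_pmi` with no
  asymptotic bias.
* **Surface realization** — a mention uses the canonical surface with
  probability 0.55 and a uniform variant otherwise (so the canonical is
  the most frequent member of its cluster); each entity owns three
  dedicated context tokens, one or two of which accompany every
  mention — the shared-context signal the embedding stage learns from;
  sentences are padded with 3–8 Zipf-distributed filler tokens from a
  fixed vocabulary. Comments hold 1–4 sentences; a configured fraction
  of bodies is replaced by `[deleted]` or `[removed]` (half each) and
  carries no annotations. Gold mentions satisfy
  `sentence[start:end] == surface` by construction.

What the generator does **not** model: grammar, threading and user
dynamics, cross-sentence associations, label ambiguity (no surface is
both a substance and an effect), and context overlap between distinct
entities. Passing the synthetic suites therefore demonstrates the
correctness of the statistical machinery and its implementation, not
extraction or deduplication quality on real forum language — on real
data the extractor and the clustering threshold both face much harder
ambiguity.

## Problem sizes and numerical choices

The validation suites use corpora of roughly 20,000–50,000 sentences
(8,000–20,000 comments), which is where the empirical PPMI of a planted
pair stabilizes to within ±0.15 of its analytic value and variant
recovery exceeds 90%; larger corpora sharpen both but add nothing
qualitative. Convergence of the empirical joint to the planted joint is
checked in total-variation distance (< 0.02 at ~50,000 sentences on a
5×3 entity grid, 3 seeds). All randomness flows through explicit seeds
(numpy `default_rng`); SVD start vectors are seeded and single-threaded
ARPACK keeps embeddings bit-reproducible; file exports serialize floats
with `repr` so export → import round trips are field-exact, and full
pipeline reruns are byte-identical.

## Known limitations

* Association ≠ causation or efficacy: "X cured my Y", "X did nothing
  for my Y" and "X gave me Y" all count identically.
* Only same-sentence co-occurrence is modeled.
* The gazetteer extractor cannot find surfaces it has not been given;
  its perfect synthetic scores reflect the complete-lexicon setting.
* Expert judgment (corrected names, categories, pair validity labels)
  enters only through imported tables; the package does no clinical
  reasoning.
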
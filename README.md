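# remedynet

Mining substance–effect associations from social-media comment streams.

People undergoing opioid withdrawal discuss self-treatment extensively in
web forums: which over-the-counter drugs, supplements and home remedies
they take for which symptoms. `remedynet` implements a pipeline for
turning such a comment stream into a ranked table of candidate
symptom–remedy associations suitable for pharmacovigilance screening:

1. **Corpus handling** — read pushshift-dialect JSONL comments, drop
   `[deleted]`/`[removed]` bodies, segment sentences, summarize per
   subreddit.
2. **Entity extraction** — tag SUBSTANCE and EFFECT spans with a
   pluggable extractor (a gazetteer reference implementation ships; a
   statistical NER model can substitute via the same mention JSONL), and
   score extractors by exact span+label match (precision/recall/F1).
3. **Deduplication** — misspellings and slang (`cigarettes, ciggarettes,
   ciggs, cigs`) are merged by training word embeddings with entity
   mentions fused into single tokens, clustering entity surfaces
   (agglomerative, average linkage, cosine distance), and replacing each
   cluster by its most frequent member. An expert-review TSV can apply a
   second manual merge and attach pharmacological categories.
4. **Co-occurrence network** — a bipartite graph over canonical
   substances and effects. For sentence-occurrence probabilities
   p(s), p(e), p(s,e) estimated over N corpus sentences, each edge
   carries its count c and

   PPMI(s,e) = max(0, log₂ p(s,e) − log₂ p(s) − log₂ p(e)),

   co-occurrence above chance, clipped at zero. Filtered ego networks
   (default PPMI ≥ 1.5, count ≥ 10) support single-entity exploration.
5. **Ranking** — each edge's association score averages min–max-scaled
   ln c and min–max-scaled PPMI; per withdrawal symptom the top-k
   substances are selected after excluding opioid-category substances
   and edges with count < 5. Quintile summaries report how many of the
   strongest pairs are plausible treatments.
6. **Synthetic corpora** — a generator plants a known joint distribution
   p(s,e) over entities, emits gold character-offset annotations and
   surface-form variants, and makes the analytic PMI of every planted
   pair exactly recoverable, so each stage is verified against ground
   truth without any external data.

## Worked example

```python
import remedynet as rn
from remedynet import conet, corpus as C, normalize as N, rank
from remedynet.entities import Mention

lex = rn.build_lexicon(n_substances=8, n_effects=5, variants_per_entity=2, seed=11)
model = rn.plant_associations(lex, n_strong_pairs=6, strength=5.0, seed=12)
s, e = model.planted[0]
print(f"planted pair: ({s}, {e})  analytic PMI = {rn.true_pmi(model, s, e):.3f}")

comments, gold = rn.generate_corpus(lex, model, n_comments=8000,
                                    deleted_fraction=0.06, seed=13)
stream, counts = rn.filter_nondeleted(comments)
kept = list(stream)
sents = [x for c in kept for x in C.segment_sentences(c)]
print(f"comments: {counts.total} total, {counts.nondeleted} nondeleted")

truth = {N.entity_token(a): N.entity_token(b)
         for a, b in lex.surface_to_canonical.items()}
cats = {N.entity_token(x.canonical): x.category for x in lex.entries}
by = {}
for m in gold.mentions:
    by.setdefault((m.comment_id, m.sentence_index), []).append(
        Mention(m.comment_id, m.sentence_index, m.start, m.end,
                truth[N.entity_token(m.surface)], m.label))
net = conet.compute_ppmi(conet.build_network(
    (by[k] for k in sorted(by)), N=len(sents), categories=cats))
rank.edge_scores(net)
for i, edge in enumerate(rank.top_remedies(net, N.entity_token(e), k=3,
                                           min_count=5), 1):
    print(f"{i}. {edge.substance}  count={edge.count}  "
          f"ppmi={edge.ppmi:.3f}  score={edge.score:.3f}")
```

prints

```
planted pair: (zolphal, budancet)  analytic PMI = 0.630
comments: 8000 total, 7509 nondeleted
1. fenpradan  count=483  ppmi=0.351  score=0.531
2. zuremcetcol  count=67  ppmi=0.000  score=0.195
3. oxfen  count=49  ppmi=0.000  score=0.159
```

`fenpradan` — a substance planted as strongly associated with the
symptom `budancet` — ranks first by the composite score. The other
planted substance for this symptom, `zolphal`, carries the generator's
*opioid* category and is therefore excluded from remedy candidacy, which
is exactly the behavior wanted when screening for non-opioid remedies.

## Command line

The same chain runs from a shell via file-handoff stages
(`generate → summarize → extract → evaluate → normalize → network →
rank → stats`):

```
remedynet init-config config.yaml
remedynet run-all --config config.yaml
remedynet ego <outdir>/network <node> --min-ppmi 1.5 --min-count 10
```

Every stage is deterministic given the config seed and idempotent;
artifacts are plain TSV/JSONL.

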
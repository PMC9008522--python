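"""Embedding training, clustering, canonical mapping, review round-trip."""

import numpy as np
import pytest

import remedynet as rn
from remedynet import corpus as C
from remedynet import normalize as N
from remedynet.corpus import Sentence
from remedynet.entities import Mention
from remedynet.errors import (
    CoverageError,
    InvalidAnnotationError,
    InvalidParameterError,
)

from conftest import nondeleted_sentences


def _sent(text, cid="c1", idx=0):
    return Sentence(comment_id=cid, index=idx, text=text, start=0, end=len(text))


class TestMergeEntityTokens:
    # hand-built token lists for annotated sentences
    FIXTURE = [
        ("restless leg syndrome sucks",
         [(0, 21, "restless leg syndrome", "EFFECT")],
         ["restless_leg_syndrome", "sucks"]),
        ("no mentions here", [], ["no", "mentions", "here"]),
        ("Kratom helped my RLS a lot.",
         [(0, 6, "Kratom", "SUBSTANCE"), (17, 20, "RLS", "EFFECT")],
         ["kratom", "helped", "my", "rls", "a", "lot"]),
        ("took 2 ibuprofen, slept",
         [(7, 16, "ibuprofen", "SUBSTANCE")],
         ["took", "2", "ibuprofen", "slept"]),
        ("black tar then black tar again",
         [(0, 9, "black tar", "SUBSTANCE"), (15, 24, "black tar", "SUBSTANCE")],
         ["black_tar", "then", "black_tar", "again"]),
        ("weird   spacing  here",
         [(8, 15, "spacing", "EFFECT")],
         ["weird", "spacing", "here"]),
        ("ALL CAPS TEXT", [], ["all", "caps", "text"]),
        ("end mention rls",
         [(12, 15, "rls", "EFFECT")],
         ["end", "mention", "rls"]),
        ("rls at start",
         [(0, 3, "rls", "EFFECT")],
         ["rls", "at", "start"]),
        ("punct! inside? ok.", [], ["punct", "inside", "ok"]),
    ]

    @pytest.mark.parametrize("text,spans,expected", FIXTURE)
    def test_fixture(self, text, spans, expected):
        s = _sent(text)
        ms = [Mention("c1", 0, a, b, surf, lab) for a, b, surf, lab in spans]
        assert N.merge_entity_tokens([s], ms) == [expected]

    def test_overlap_rejected(self):
        s = _sent("black tar heroin")
        ms = [
            Mention("c1", 0, 0, 9, "black tar", "SUBSTANCE"),
            Mention("c1", 0, 6, 16, "tar heroin", "SUBSTANCE"),
        ]
        with pytest.raises(InvalidAnnotationError):
            N.merge_entity_tokens([s], ms)


class TestTrainEmbeddings:
    def _stream(self):
        rng = np.random.default_rng(0)
        vocab = [f"w{i}" for i in range(30)]
        return [
            [vocab[int(i)] for i in rng.integers(0, 30, size=8)]
            for _ in range(300)
        ]

    def test_deterministic_under_seed(self):
        stream = self._stream()
        a = N.train_embeddings(stream, d=10, min_freq=2, seed=3)
        b = N.train_embeddings(stream, d=10, min_freq=2, seed=3)
        assert a.tokens == b.tokens
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_min_freq_excludes_rare_tokens(self):
        stream = [["common", "alsocommon"]] * 10 + [["rareword"]]
        t = N.train_embeddings(stream, d=5, min_freq=5)
        assert "common" in t and "rareword" not in t

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(InvalidParameterError):
            N.train_embeddings([["once"]], min_freq=5)

    def test_variant_closer_to_canonical_than_filler(self):
        """Variants share their canonical's contexts, so cosine(variant,
        canonical) should beat cosine(variant, random filler)."""
        wins = trials = 0
        for seed in (1, 2, 3):
            lex = rn.build_lexicon(6, 4, 3, seed=seed)
            model = rn.plant_associations(lex, 4, 4.0, seed=seed + 10)
            comments, gold = rn.generate_corpus(lex, model, 3000, 0.0,
                                                seed=seed + 20)
            sents = nondeleted_sentences(comments)
            emb = N.train_embeddings(N.merge_entity_tokens(sents, gold.mentions))
            truth = lex.surface_to_canonical
            rng = np.random.default_rng(seed)
            fillers = [w for w in rn.synthetic.FILLER_VOCAB if w in emb]
            triples = [
                (v, e.canonical)
                for e in lex.entries
                for v in e.variants
                if v in emb and e.canonical in emb
            ]
            pick = rng.permutation(len(triples))[:20]
            for i in pick:
                v, canon = triples[int(i)]
                filler = fillers[int(rng.integers(0, len(fillers)))]
                trials += 1
                if emb.cosine(v, canon) > emb.cosine(v, filler):
                    wins += 1
        assert trials >= 40
        assert wins / trials >= 0.9


class TestClustering:
    def _table(self, vectors):
        toks = sorted(vectors)
        return N.EmbeddingTable(
            tokens=toks,
            matrix=np.vstack([vectors[t] for t in toks]),
            frequencies={t: 10 for t in toks},
        )

    def test_identical_vectors_cluster_together(self):
        v = np.array([1.0, 0.0, 0.0])
        emb = self._table({"a": v, "b": v, "c": np.array([0.0, 1.0, 0.0])})
        clusters = N.cluster_entities(
            emb, {"a": "SUBSTANCE", "b": "SUBSTANCE", "c": "SUBSTANCE"}, tau=0.3
        )
        members = {cl.members for cl in clusters}
        assert ("a", "b") in members and ("c",) in members

    def test_orthogonal_vectors_stay_singletons(self):
        emb = self._table(
            {"a": np.array([1.0, 0, 0]), "b": np.array([0, 1.0, 0]),
             "c": np.array([0, 0, 1.0])}
        )
        clusters = N.cluster_entities(
            emb, {t: "EFFECT" for t in "abc"}, tau=0.3
        )
        assert all(len(cl.members) == 1 for cl in clusters)

    def test_labels_never_mix(self):
        v = np.array([1.0, 0.0])
        emb = self._table({"a": v, "b": v})
        clusters = N.cluster_entities(emb, {"a": "SUBSTANCE", "b": "EFFECT"})
        assert all(len(cl.members) == 1 for cl in clusters)

    def test_oov_surfaces_become_singletons(self):
        emb = self._table({"a": np.array([1.0, 0.0])})
        clusters = N.cluster_entities(
            emb, {"a": "EFFECT", "ghost": "EFFECT"}, tau=0.3
        )
        assert any(cl.members == ("ghost",) for cl in clusters)

    def test_invalid_tau(self):
        emb = self._table({"a": np.array([1.0, 0.0])})
        with pytest.raises(InvalidParameterError):
            N.cluster_entities(emb, {"a": "EFFECT"}, tau=0.0)


class TestCanonicalize:
    def test_most_frequent_member_wins(self):
        cl = [N.Cluster("SUBSTANCE", ("cigarettes", "cigs", "ciggs"))]
        cmap = N.canonicalize(cl, {"cigarettes": 100, "cigs": 20, "ciggs": 5})
        assert all(cmap.mapping[s] == "cigarettes" for s in
                   ("cigarettes", "cigs", "ciggs"))

    def test_singleton_maps_to_itself(self):
        cmap = N.canonicalize([N.Cluster("EFFECT", ("rls",))], {"rls": 3})
        assert cmap.mapping == {"rls": "rls"}

    def test_tie_breaks_lexicographically(self):
        cl = [N.Cluster("EFFECT", ("bbb", "aaa"))]
        cmap = N.canonicalize(cl, {"aaa": 5, "bbb": 5})
        assert cmap.mapping["bbb"] == "aaa"


class TestApplyMap:
    def _map(self):
        return N.canonicalize(
            [N.Cluster("SUBSTANCE", ("cigarettes", "cigs"))],
            {"cigarettes": 100, "cigs": 20},
        )

    def test_surface_replaced(self):
        m = Mention("c1", 0, 0, 4, "cigs", "SUBSTANCE")
        out = N.apply_map([m], self._map())
        assert out[0].surface == "cigarettes"
        assert (out[0].start, out[0].end, out[0].label) == (0, 4, "SUBSTANCE")

    def test_idempotent(self):
        m = Mention("c1", 0, 0, 4, "cigs", "SUBSTANCE")
        once = N.apply_map([m], self._map())
        twice = N.apply_map(once, self._map())
        assert once == twice

    def test_identity_map(self):
        cmap = N.canonicalize([N.Cluster("EFFECT", ("rls",))], {"rls": 1})
        m = Mention("c1", 0, 0, 3, "rls", "EFFECT")
        assert N.apply_map([m], cmap) == [m]

    def test_missing_surface_raises_coverage_error(self):
        m = Mention("c1", 0, 0, 7, "unknown", "SUBSTANCE")
        with pytest.raises(CoverageError, match="unknown"):
            N.apply_map([m], self._map())


class TestReviewRoundtrip:
    def _map(self):
        return N.canonicalize(
            [
                N.Cluster("SUBSTANCE", ("imodium", "immodium")),
                N.Cluster("SUBSTANCE", ("loperamide",)),
                N.Cluster("EFFECT", ("rls",)),
            ],
            {"imodium": 50, "immodium": 5, "loperamide": 30, "rls": 9},
        )

    def test_merge_brand_into_generic(self, tmp_path):
        p = tmp_path / "review.tsv"
        p.write_text(
            "canonical\tcorrected_name\tcategory\n"
            "imodium\tloperamide\tantidiarrheal\n"
        )
        out = N.review_roundtrip(self._map(), str(p))
        assert out.mapping["imodium"] == "loperamide"
        assert out.mapping["immodium"] == "loperamide"
        assert out.mapping["loperamide"] == "loperamide"
        assert out.categories["loperamide"] == "antidiarrheal"

    def test_empty_review_is_identity(self, tmp_path):
        p = tmp_path / "review.tsv"
        p.write_text("canonical\tcorrected_name\tcategory\n")
        out = N.review_roundtrip(self._map(), str(p))
        assert out.mapping == self._map().mapping

    def test_export_import_round_trip(self, tmp_path):
        cmap = self._map()
        review = tmp_path / "review.tsv"
        cmap.export_review(str(review))
        out = N.review_roundtrip(cmap, str(review))
        assert out.mapping == cmap.mapping
        # and the TSV serialization of the map itself round-trips
        tsv = tmp_path / "map.tsv"
        cmap.to_tsv(str(tsv))
        back = N.CanonicalMap.from_tsv(str(tsv))
        assert back.mapping == cmap.mapping
        assert back.frequencies == cmap.frequencies
        assert back.labels == cmap.labels

    def test_unknown_canonical_rejected(self, tmp_path):
        p = tmp_path / "review.tsv"
        p.write_text("canonical\tcorrected_name\tcategory\nnope\tx\t\n")
        with pytest.raises(KeyError):
            N.review_roundtrip(self._map(), str(p))


def test_reduction_percentages_consistent(small_corpus, small_lexicon):
    """Unique-entity reduction is non-negative and exactly
    100*(before-after)/before on the learned map."""
    comments, gold, _ = small_corpus
    sents = nondeleted_sentences(comments)
    emb = N.train_embeddings(
        N.merge_entity_tokens(sents, gold.mentions), min_freq=3
    )
    surfaces, freqs = {}, {}
    for m in gold.mentions:
        t = N.entity_token(m.surface)
        surfaces[t] = m.label
        freqs[t] = freqs.get(t, 0) + 1
    cmap = N.canonicalize(N.cluster_entities(emb, surfaces), freqs)
    cmap.validate()
    before, after = cmap.n_surfaces, cmap.n_canonicals
    assert after <= before
    pct = rn.percent_reduction(before, after, 6)
    assert pct == pytest.approx(100.0 * (before - after) / before, abs=1e-5)
    # no cluster mixes labels
    for surf, canon in cmap.mapping.items():
        assert cmap.labels[surf] == cmap.labels[canon]
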
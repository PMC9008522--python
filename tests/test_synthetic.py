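"""Generator contracts: determinism, planted structure, gold validity."""

import math

import numpy as np
import pytest

import remedynet as rn
from remedynet import corpus as C
from remedynet.errors import InvalidParameterError, UndefinedPMIError

from conftest import nondeleted_sentences


class TestBuildLexicon:
    def test_surface_count_bookkeeping(self):
        lex = rn.build_lexicon(5, 3, 2, seed=7)
        assert len(lex.entries) == 8
        surfaces = [s for e in lex.entries for s in e.surfaces]
        assert len(surfaces) == 8 * 3
        assert len(set(surfaces)) == 24  # globally unique

    def test_deterministic_under_seed(self):
        a = rn.build_lexicon(5, 3, 2, seed=7)
        b = rn.build_lexicon(5, 3, 2, seed=7)
        assert a == b

    def test_different_seeds_differ(self):
        a = rn.build_lexicon(5, 3, 2, seed=7)
        b = rn.build_lexicon(5, 3, 2, seed=8)
        assert {s for e in a.entries for s in e.variants} != {
            s for e in b.entries for s in e.variants
        }

    @pytest.mark.parametrize("bad", [(0, 3, 2), (5, 0, 2), (5, 3, 0), (-1, 3, 2)])
    def test_rejects_nonpositive_counts(self, bad):
        with pytest.raises(InvalidParameterError):
            rn.build_lexicon(*bad, seed=1)

    def test_labels_and_variant_shapes(self):
        lex = rn.build_lexicon(4, 4, 3, seed=3)
        assert all(e.label in ("SUBSTANCE", "EFFECT") for e in lex.entries)
        assert all(len(e.variants) == 3 for e in lex.entries)

    def test_tsv_round_trip_preserves_structure(self, tmp_path, small_lexicon):
        p = str(tmp_path / "lex.tsv")
        small_lexicon.to_tsv(p)
        back = rn.SyntheticLexicon.from_tsv(p)
        assert back.surface_to_canonical == small_lexicon.surface_to_canonical
        assert back.surface_to_label == small_lexicon.surface_to_label


class TestPlantAssociations:
    def test_strength_one_is_independence(self, small_lexicon):
        m = rn.plant_associations(small_lexicon, 3, 1.0, seed=5)
        outer = np.outer(m.p_substance, m.p_effect)
        np.testing.assert_allclose(m.joint, outer, atol=1e-12)
        for s, e in m.planted:
            assert rn.true_pmi(m, s, e) == pytest.approx(0.0, abs=1e-9)

    def test_zero_pairs_equals_baseline(self, small_lexicon):
        m0 = rn.plant_associations(small_lexicon, 0, 5.0, seed=5)
        m1 = rn.plant_associations(small_lexicon, 0, 1.0, seed=6)
        np.testing.assert_allclose(m0.joint, m1.joint)
        assert m0.planted == ()

    def test_joint_normalized_and_planted_pmi_positive(self, small_lexicon):
        m = rn.plant_associations(small_lexicon, 4, 5.0, seed=5)
        assert m.joint.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            m.p_substance, m.joint.sum(axis=1), atol=1e-12
        )
        for s, e in m.planted:
            assert rn.true_pmi(m, s, e) > 0

    def test_invalid_strength_and_pair_count(self, small_lexicon):
        with pytest.raises(InvalidParameterError):
            rn.plant_associations(small_lexicon, 1, 0.0, seed=1)
        with pytest.raises(InvalidParameterError):
            rn.plant_associations(small_lexicon, 16, 2.0, seed=1)  # > 5x3


class TestTruePmi:
    def test_engineered_joint_arithmetic(self, engineered_model):
        lex, model = engineered_model
        s, e = model.planted[0]
        assert rn.true_pmi(model, s, e) == pytest.approx(math.log2(2.5), abs=1e-12)

    def test_negative_pmi(self):
        # p(s,e)=0.05 with p(s)=p(e)=0.5 => log2(0.2)
        joint = np.array([[0.05, 0.45], [0.45, 0.05]])
        m = rn.AssociationModel.from_joint(["s1", "s2"], ["e1", "e2"], joint)
        assert rn.true_pmi(m, "s1", "e1") == pytest.approx(
            math.log2(0.2), abs=1e-12
        )

    def test_unknown_name_and_zero_marginal(self):
        joint = np.array([[1.0, 0.0], [0.0, 0.0]])
        m = rn.AssociationModel.from_joint(["s1", "s2"], ["e1", "e2"], joint)
        with pytest.raises(LookupError):
            rn.true_pmi(m, "nope", "e1")
        with pytest.raises(UndefinedPMIError):
            rn.true_pmi(m, "s2", "e1")


class TestGenerateCorpus:
    def test_no_deletion_means_all_kept(self, small_lexicon):
        m = rn.plant_associations(small_lexicon, 2, 3.0, seed=1)
        comments, _ = rn.generate_corpus(small_lexicon, m, 100, 0.0, seed=2)
        assert len(comments) == 100
        assert not any(c.is_deleted for c in comments)

    def test_deleted_count_within_binomial_bounds(self, small_lexicon):
        m = rn.plant_associations(small_lexicon, 2, 3.0, seed=1)
        comments, gold = rn.generate_corpus(small_lexicon, m, 1000, 0.1, seed=3)
        n_del = sum(c.is_deleted for c in comments)
        # binomial(1000, 0.1) 99% interval
        assert 76 <= n_del <= 125
        deleted_ids = {c.id for c in comments if c.is_deleted}
        assert not deleted_ids & {m.comment_id for m in gold.mentions}

    def test_both_deletion_markers_used(self, small_lexicon):
        m = rn.plant_associations(small_lexicon, 2, 3.0, seed=1)
        comments, _ = rn.generate_corpus(small_lexicon, m, 500, 0.2, seed=4)
        bodies = {c.body for c in comments if c.is_deleted}
        assert bodies == {"[deleted]", "[removed]"}

    def test_gold_slicing_invariant(self, small_corpus):
        comments, gold, _ = small_corpus
        sent_by_key = {
            (s.comment_id, s.index): s
            for s in nondeleted_sentences(comments)
        }
        assert gold.mentions
        for m in gold.mentions:
            s = sent_by_key[(m.comment_id, m.sentence_index)]
            assert s.text[m.start : m.end] == m.surface

    def test_every_gold_surface_in_lexicon(self, small_corpus, small_lexicon):
        _, gold, _ = small_corpus
        known = set(small_lexicon.surface_to_canonical)
        assert {m.surface for m in gold.mentions} <= known

    def test_byte_identical_under_seed(self, small_lexicon):
        m = rn.plant_associations(small_lexicon, 2, 3.0, seed=1)
        a, ga = rn.generate_corpus(small_lexicon, m, 150, 0.1, seed=5)
        b, gb = rn.generate_corpus(small_lexicon, m, 150, 0.1, seed=5)
        assert [c.to_json() for c in a] == [c.to_json() for c in b]
        assert ga.mentions == gb.mentions

    def test_invalid_deleted_fraction(self, small_lexicon):
        m = rn.plant_associations(small_lexicon, 2, 3.0, seed=1)
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(InvalidParameterError):
                rn.generate_corpus(small_lexicon, m, 10, bad, seed=1)

    def test_model_lexicon_mismatch_rejected(self, small_lexicon):
        other = rn.build_lexicon(5, 3, 2, seed=99)
        m = rn.plant_associations(other, 2, 3.0, seed=1)
        with pytest.raises(InvalidParameterError):
            rn.generate_corpus(small_lexicon, m, 10, 0.0, seed=1)


def test_empirical_joint_converges_to_model():
    """Sentence-level pair frequencies match the planted joint (TV < 0.02)."""
    for seed in (11, 12, 13):
        lex = rn.build_lexicon(5, 3, 2, seed=seed)
        model = rn.plant_associations(lex, 3, 4.0, seed=seed + 50)
        comments, gold = rn.generate_corpus(lex, model, 20000, 0.0, seed=seed + 90)
        truth = lex.surface_to_canonical
        sub_idx = {s: i for i, s in enumerate(model.substances)}
        eff_idx = {e: j for j, e in enumerate(model.effects)}
        counts = np.zeros_like(model.joint)
        for mlist in gold.by_sentence().values():
            subs = {truth[m.surface] for m in mlist if m.label == "SUBSTANCE"}
            effs = {truth[m.surface] for m in mlist if m.label == "EFFECT"}
            for s in subs:
                for e in effs:
                    counts[sub_idx[s], eff_idx[e]] += 1
        emp = counts / counts.sum()
        tv = 0.5 * np.abs(emp - model.joint).sum()
        assert tv < 0.02, f"seed {seed}: TV distance {tv:.4f}"
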
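"""Topic models: biterm extraction, closed forms at K=1, determinism,
perplexity, topic-count selection, vocabulary clustering and chi-square
topic weights."""

import itertools
import math

import numpy as np
import pytest

from sentispace.corpus import Corpus, Document
from sentispace.features import Vocabulary, build_vocabulary
from sentispace.synthetic import GeneratorConfig, make_corpus
from sentispace.topics import (
    BtmState,
    PpmiSvdEmbedding,
    WordClusterMap,
    biterm_probability,
    cluster_vocabulary,
    extract_biterms,
    fit_btm,
    fit_lda,
    perplexity,
    reduce_corpus,
    select_k,
    topic_weights_chisq,
)

from conftest import make_token_corpus


class TestExtractBiterms:
    def test_three_tokens_three_pairs(self):
        assert set(extract_biterms(["a", "b", "c"])) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_single_token_no_biterms(self):
        assert extract_biterms(["a"]) == []

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_combinatorial_count(self, n):
        toks = [f"t{i}" for i in range(n)]
        assert len(extract_biterms(toks)) == n * (n - 1) // 2

    def test_identical_word_pairs_kept(self):
        assert extract_biterms(["a", "a"]) == [("a", "a")]

    def test_pairs_sorted_within(self):
        for a, b in extract_biterms(["z", "m", "a"]):
            assert a <= b

    def test_window_restricts_pairs(self):
        toks = ["a", "b", "c", "d"]
        assert len(extract_biterms(toks, window=1)) == 3


class TestBtmClosedForms:
    def test_k1_theta_exact_and_phi_smoothed_frequencies(self):
        corpus = make_token_corpus([["a", "b"], ["a", "c", "a"]])
        st = fit_btm(corpus, K=1, alpha=1.0, beta=0.01, iterations=5, seed=0)
        assert st.theta[0] == 1.0
        # K=1: all biterms in topic 0; n_{w|1} = word occurrences over biterms
        vocab = st.vocabulary
        word_counts = {"a": 0, "b": 0, "c": 0}
        for pair in [("a", "b")] + extract_biterms(["a", "c", "a"]):
            word_counts[pair[0]] += 1
            word_counts[pair[1]] += 1
        B = 1 + 3
        M = 3
        for w, c in word_counts.items():
            expected = (c + 0.01) / (2 * B + M * 0.01)
            assert st.phi[0, vocab.index[w]] == pytest.approx(expected, abs=1e-15)

    def test_gibbs_smoke_one_doc_two_words(self):
        corpus = make_token_corpus([["a", "b"]])
        st = fit_btm(corpus, K=1, alpha=2.0, beta=0.5, iterations=3, seed=1)
        assert st.theta[0] == 1.0
        # single biterm: phi = (1 + beta) / (2 + M beta) for each word
        expected = (1 + 0.5) / (2 + 2 * 0.5)
        assert st.phi[0, 0] == expected
        assert st.phi[0, 1] == expected

    def test_distributions_sum_to_one(self):
        cfg = GeneratorConfig(seed=3, n_documents=100, K_true=2, vocab_size=50)
        corpus, _ = make_corpus(cfg)
        st = fit_btm(corpus, K=4, iterations=50, seed=2)
        assert st.theta.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(st.phi.sum(axis=1), 1.0, atol=1e-12)
        assert (st.phi >= 0).all()

    def test_bit_reproducible_for_fixed_seed(self):
        cfg = GeneratorConfig(seed=3, n_documents=60, K_true=2, vocab_size=40)
        corpus, _ = make_corpus(cfg)
        a = fit_btm(corpus, K=3, iterations=30, seed=9)
        b = fit_btm(corpus, K=3, iterations=30, seed=9)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.array_equal(a.phi, b.phi)
        c = fit_btm(corpus, K=3, iterations=30, seed=10)
        assert not np.array_equal(a.assignments, c.assignments)

    def test_argument_errors(self):
        corpus = make_token_corpus([["a", "b"]])
        with pytest.raises(ValueError):
            fit_btm(corpus, K=0)
        with pytest.raises(ValueError):
            fit_btm(make_token_corpus([["a"]]), K=2)


class TestBitermProbability:
    def _uniform_state(self, words, K=1):
        M = len(words)
        return BtmState(
            K=K,
            theta=np.full(K, 1.0 / K),
            phi=np.full((K, M), 1.0 / M),
            vocabulary=Vocabulary(words=tuple(words)),
            biterms=np.empty((0, 2), dtype=np.int64),
            assignments=np.empty(0, dtype=np.int64),
            alpha=1.0,
            beta=0.01,
            iterations=0,
            seed=0,
        )

    def test_k1_product_form(self):
        corpus = make_token_corpus([["a", "b", "c", "a"]])
        st = fit_btm(corpus, K=1, iterations=5, seed=0)
        p = biterm_probability(st, ("a", "b"))
        expected = st.theta[0] * st.phi[0, st.vocabulary.index["a"]] * st.phi[0, st.vocabulary.index["b"]]
        assert p == pytest.approx(expected)

    def test_sums_to_one_over_ordered_pairs(self):
        cfg = GeneratorConfig(seed=5, n_documents=40, K_true=2, vocab_size=12)
        corpus, _ = make_corpus(cfg)
        st = fit_btm(corpus, K=3, iterations=30, seed=1)
        words = st.vocabulary.words
        total = sum(
            biterm_probability(st, (w1, w2))
            for w1, w2 in itertools.product(words, repeat=2)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_symmetric(self):
        st = self._uniform_state(["a", "b", "c"])
        assert biterm_probability(st, ("a", "b")) == biterm_probability(st, ("b", "a"))

    def test_out_of_vocabulary_raises(self):
        st = self._uniform_state(["a", "b"])
        with pytest.raises(KeyError):
            biterm_probability(st, ("a", "zz"))


class TestLda:
    def test_k1_degenerate(self):
        corpus = make_token_corpus([["a", "b"], ["c", "a"]])
        st = fit_lda(corpus, K=1, iterations=5, seed=0)
        assert np.allclose(st.doc_topic, 1.0)
        assert st.phi.shape == (1, 3)

    def test_default_hyperparameters(self):
        corpus = make_token_corpus([["a", "b"], ["c", "a"]])
        st = fit_lda(corpus, K=5, iterations=2, seed=0)
        assert st.alpha == pytest.approx(50.0 / 5)
        assert st.beta == 0.01

    def test_fixed_seed_reproducibility(self):
        cfg = GeneratorConfig(seed=4, n_documents=50, K_true=2, vocab_size=30)
        corpus, _ = make_corpus(cfg)
        a = fit_lda(corpus, K=3, iterations=20, seed=7)
        b = fit_lda(corpus, K=3, iterations=20, seed=7)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.doc_topic, b.doc_topic)

    def test_distributions_sum_to_one(self):
        cfg = GeneratorConfig(seed=4, n_documents=50, K_true=2, vocab_size=30)
        corpus, _ = make_corpus(cfg)
        st = fit_lda(corpus, K=3, iterations=20, seed=7)
        assert np.allclose(st.doc_topic.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(st.phi.sum(axis=1), 1.0, atol=1e-12)


class TestPerplexity:
    def _uniform_btm(self, words):
        M = len(words)
        return BtmState(
            K=2,
            theta=np.array([0.5, 0.5]),
            phi=np.full((2, M), 1.0 / M),
            vocabulary=Vocabulary(words=tuple(words)),
            biterms=np.empty((0, 2), dtype=np.int64),
            assignments=np.empty(0, dtype=np.int64),
            alpha=1.0,
            beta=0.01,
            iterations=0,
            seed=0,
        )

    def test_uniform_model_perplexity_equals_vocab_size(self):
        words = [f"w{i}" for i in range(7)]
        st = self._uniform_btm(words)
        heldout = make_token_corpus([[words[0], words[3], words[5], words[6]]])
        assert perplexity(st, heldout) == pytest.approx(7.0, rel=1e-12)

    def test_perplexity_at_least_one(self):
        cfg = GeneratorConfig(seed=6, n_documents=60, K_true=2, vocab_size=30)
        corpus, _ = make_corpus(cfg)
        st = fit_btm(corpus, K=2, iterations=30, seed=2)
        assert perplexity(st, corpus) >= 1.0

    def test_hand_computation_two_word_vocab(self):
        # phi puts p on word a, 1-p on b; doc [a,b,a,b] scores only odd
        # positions [b,b] under document completion
        p = 0.73
        st = BtmState(
            K=1,
            theta=np.array([1.0]),
            phi=np.array([[p, 1 - p]]),
            vocabulary=Vocabulary(words=("a", "b")),
            biterms=np.empty((0, 2), dtype=np.int64),
            assignments=np.empty(0, dtype=np.int64),
            alpha=1.0,
            beta=0.01,
            iterations=0,
            seed=0,
        )
        heldout = make_token_corpus([["a", "b", "a", "b"]])
        expected = math.exp(-math.log(1 - p))
        assert perplexity(st, heldout) == pytest.approx(expected, rel=1e-12)

    def test_no_scorable_tokens_raises(self):
        st = self._uniform_btm(["a", "b"])
        with pytest.raises(ValueError):
            perplexity(st, make_token_corpus([["zz", "yy"]]))


class TestSelectK:
    def test_single_candidate(self):
        cfg = GeneratorConfig(seed=8, n_documents=60, K_true=2, vocab_size=30)
        corpus, _ = make_corpus(cfg)
        assert select_k(corpus, [3], seed=0, iterations=10) == 3

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            select_k(Corpus([Document("d", "a b", tokens=["a", "b"])]), [])


class TestVocabularyClustering:
    class _BlobEmbedding:
        """Two well-separated synthetic blobs in 2-D."""

        name = "blobs"
        dimension = 2

        def __init__(self, words, labels):
            rng = np.random.default_rng(0)
            self._vecs = {
                w: np.array([10.0 * lab, 0.0]) + rng.normal(0, 0.1, 2)
                for w, lab in zip(words, labels)
            }

        def embed(self, word):
            return self._vecs[word]

    def test_identity_when_clusters_equal_vocab(self):
        corpus = make_token_corpus(
            [["a", "b"], ["b", "c"], ["c", "a"], ["a", "a", "a"], ["b"]]
        )
        vocab = build_vocabulary(corpus)
        emb = PpmiSvdEmbedding(corpus, vocab, dimension=2)
        cmap = cluster_vocabulary(vocab, emb, len(vocab), corpus.vocabulary_counts(), seed=0)
        assert cmap.mapping == {w: w for w in vocab.words}

    def test_two_blobs_recovered(self):
        words = [f"w{i}" for i in range(10)]
        labels = [0] * 5 + [1] * 5
        vocab = Vocabulary(words=tuple(words))
        emb = self._BlobEmbedding(words, labels)
        freqs = {w: 10 - i for i, w in enumerate(words)}  # w0 and w5 most frequent
        cmap = cluster_vocabulary(vocab, emb, 2, freqs, seed=0)
        assert cmap.representatives == {"w0", "w5"}
        for w, lab in zip(words, labels):
            assert cmap[w] == ("w0" if lab == 0 else "w5")

    def test_representatives_map_to_themselves(self):
        corpus = make_token_corpus([["a", "b", "c", "d", "a", "b"]])
        vocab = build_vocabulary(corpus)
        emb = PpmiSvdEmbedding(corpus, vocab, dimension=2)
        cmap = cluster_vocabulary(vocab, emb, 2, corpus.vocabulary_counts(), seed=0)
        for rep in cmap.representatives:
            assert cmap[rep] == rep

    def test_too_many_clusters_raises(self):
        vocab = Vocabulary(words=("a", "b"))
        emb = self._BlobEmbedding(["a", "b"], [0, 1])
        with pytest.raises(ValueError):
            cluster_vocabulary(vocab, emb, 3, {}, seed=0)


class TestReduceCorpus:
    def test_identity_map(self):
        corpus = make_token_corpus([["a", "b"]])
        cmap = WordClusterMap(mapping={"a": "a", "b": "b"}, n_clusters=2)
        out = reduce_corpus(corpus, cmap)
        assert out[0].tokens == ["a", "b"]

    def test_substitution(self):
        corpus = make_token_corpus([["a", "b", "r"]])
        cmap = WordClusterMap(mapping={"a": "r", "b": "r", "r": "r"}, n_clusters=1)
        out = reduce_corpus(corpus, cmap)
        assert out[0].tokens == ["r", "r", "r"]

    def test_reduced_vocab_counts(self):
        corpus = make_token_corpus([["a", "b"], ["c", "d"]])
        cmap = WordClusterMap(
            mapping={"a": "a", "b": "a", "c": "c", "d": "c"}, n_clusters=2
        )
        out = reduce_corpus(corpus, cmap)
        assert set(out.vocabulary_counts()) == {"a", "c"}
        assert sum(out.vocabulary_counts().values()) == 4  # token count preserved

    def test_uncovered_token_listed(self):
        corpus = make_token_corpus([["a", "zz"]])
        cmap = WordClusterMap(mapping={"a": "a"}, n_clusters=1)
        with pytest.raises(KeyError, match="zz"):
            reduce_corpus(corpus, cmap)


class TestTopicWeights:
    def test_single_topic_weight_one(self):
        w = topic_weights_chisq([0, 0, 0], ["jan", "feb", "jan"], K=1)
        assert w == pytest.approx([1.0])

    def test_uniform_table_uniform_weights(self):
        topics = [0, 1, 0, 1, 0, 1, 0, 1]
        months = ["jan", "jan", "feb", "feb", "jan", "jan", "feb", "feb"]
        w = topic_weights_chisq(topics, months, K=2)
        assert w == pytest.approx([0.5, 0.5])

    def test_planted_month_specific_topic_gets_largest_weight(self):
        # topic 2 appears only in march; topics 0 and 1 spread evenly
        topics, months = [], []
        for m in ("jan", "feb", "mar"):
            for t in (0, 1):
                topics += [t] * 10
                months += [m] * 10
        topics += [2] * 10
        months += ["mar"] * 10
        w = topic_weights_chisq(topics, months, K=3)
        assert np.argmax(w) == 2
        assert w.sum() == pytest.approx(1.0)

    def test_zero_expected_cell_raises(self):
        with pytest.raises(ValueError):
            topic_weights_chisq([0, 1], ["jan", "feb"], K=3)  # topic 2 never occurs
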
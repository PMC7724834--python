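import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locinfer.errors import ExtractorError, TagValidationError, TrainingError
from locinfer.extract import (
    ALLOWED_INITIAL,
    ALLOWED_TRANSITIONS,
    NEG_INF,
    STATES,
    BaselinePosTagger,
    HmmModel,
    extract_gazetteer,
    extract_ner,
    extract_pos,
    loc_spans,
    train_hmm,
    viterbi_decode,
)
from locinfer.segmentation import segment


class TestSegment:
    def test_accurate_longest_match_walk(self):
        tokens = segment("坐标成都交友", {"坐标", "成都", "交友"}, "accurate")
        assert [t.text for t in tokens] == ["坐标", "成都", "交友"]

    def test_empty_text(self):
        assert segment("", {"成都"}, "accurate") == []
        assert segment("", {"成都"}, "full") == []

    def test_full_mode_includes_nested_words(self):
        tokens = segment("长沙市", {"长沙", "长沙市"}, "full")
        texts = {t.text for t in tokens}
        assert {"长沙", "长沙市"} <= texts

    def test_accurate_partitions_text(self):
        text = "我在成都交友吗"
        tokens = segment(text, {"成都", "交友"}, "accurate")
        assert "".join(t.text for t in tokens) == text
        ends = [t.end for t in tokens]
        starts = [t.start for t in tokens]
        assert starts == [0] + ends[:-1]

    @settings(derandomize=True, max_examples=100)
    @given(
        st.text(alphabet="成都交友坐标长沙市在", max_size=12),
        st.sets(st.sampled_from(["成都", "交友", "坐标", "长沙", "长沙市"]), max_size=5),
    )
    def test_offsets_slice_back_to_surface(self, text, dictionary):
        for mode in ("accurate", "full"):
            for tok in segment(text, dictionary, mode):
                assert text[tok.start : tok.end] == tok.text


class TestGazetteerExtractor:
    def test_single_city_mention(self, tiny_gazetteer, corpus_factory):
        corpus = corpus_factory(("A", "1", "坐标成都交友"))
        mentions = extract_gazetteer(corpus, tiny_gazetteer)
        assert len(mentions) == 1
        (m,) = mentions
        assert m.surface == "成都"
        assert {u.canonical_name for u in m.units} == {"成都"}
        assert corpus.posts_of("A")[0].clean_text[m.start : m.end] == m.surface

    def test_no_gazetteer_surface_no_mentions(self, tiny_gazetteer, corpus_factory):
        corpus = corpus_factory(("A", "1", "吃饭没呀"))
        assert extract_gazetteer(corpus, tiny_gazetteer) == []

    def test_adjacent_province_and_city(self, tiny_gazetteer, corpus_factory):
        corpus = corpus_factory(("A", "1", "湖南长沙"))
        names = {
            u.canonical_name
            for m in extract_gazetteer(corpus, tiny_gazetteer, level_filter="both")
            for u in m.units
        }
        assert names == {"湖南", "长沙"}

    def test_level_filter_province_only(self, tiny_gazetteer, corpus_factory):
        corpus = corpus_factory(("A", "1", "湖南长沙"))
        mentions = extract_gazetteer(corpus, tiny_gazetteer, level_filter="province")
        assert {m.surface for m in mentions} == {"湖南"}

    def test_full_mode_is_superset_of_accurate(self, gaz, corpus_factory):
        corpus = corpus_factory(
            ("A", "1", "坐标长沙市交友"), ("A", "2", "湖南长沙人"), ("B", "3", "在北京")
        )
        def keyset(mode):
            return {
                (m.user_id, m.post_id, m.start, m.end)
                for m in extract_gazetteer(corpus, gaz, mode=mode)
            }
        assert keyset("accurate") <= keyset("full")


class TestPosExtractor:
    def test_baseline_tagger_finds_place(self, gaz, corpus_factory):
        corpus = corpus_factory(("A", "1", "我在北京"))
        mentions = extract_pos(corpus, BaselinePosTagger(gaz), gaz)
        assert {m.surface for m in mentions} == {"北京"}

    def test_no_ns_tokens(self, gaz, corpus_factory):
        corpus = corpus_factory(("A", "1", "吃饭没呀"))
        assert extract_pos(corpus, BaselinePosTagger(gaz), gaz) == []

    def test_non_canonicalizable_ns_dropped(self, gaz, corpus_factory):
        from locinfer.segmentation import Token

        class MockTagger:
            def tag(self, text):
                return [(Token(text, 0, len(text)), "ns")] if text else []

        corpus = corpus_factory(("A", "1", "故宫"))
        assert extract_pos(corpus, MockTagger(), gaz) == []

    def test_adapter_failure_names_post(self, gaz, corpus_factory):
        class Broken:
            def tag(self, text):
                raise RuntimeError("boom")

        corpus = corpus_factory(("A", "p9", "任何"))
        with pytest.raises(ExtractorError, match="p9"):
            extract_pos(corpus, Broken(), gaz)


class TestTrainHmm:
    def test_single_sentence_counts(self):
        model = train_hmm([("我在成都", ["O", "O", "B-LOC", "E-LOC"])])
        row = model.transition_logprob["B-LOC"]
        finite = {k: v for k, v in row.items() if v > NEG_INF}
        assert max(finite, key=finite.get) == "E-LOC"
        model.validate()

    def test_all_O_corpus_is_degenerate_but_valid(self):
        model = train_hmm([("吃饭啦", ["O", "O", "O"])])
        model.validate()
        # LOC emissions exist only through smoothing
        assert model.emission_logprob["B-LOC"]["<UNK>"] < 0

    def test_rows_sum_to_one(self):
        model = train_hmm(
            [
                ("我在成都", ["O", "O", "B-LOC", "E-LOC"]),
                ("长沙交友", ["B-LOC", "E-LOC", "O", "O"]),
            ]
        )
        for state in STATES:
            total = sum(
                math.exp(lp)
                for lp in model.transition_logprob[state].values()
                if lp > NEG_INF
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_training_set_rejected(self):
        with pytest.raises(TrainingError):
            train_hmm([])

    @pytest.mark.parametrize(
        "tags",
        [
            ["M-LOC", "O"],  # cannot start mid-span
            ["O", "M-LOC"],  # O cannot enter M
            ["B-LOC", "B-LOC"],  # B cannot follow B
            ["O", "B-LOC"],  # ends mid-span
        ],
    )
    def test_invalid_tag_sequences_rejected(self, tags):
        with pytest.raises(TagValidationError):
            train_hmm([("你好", tags)])

    def test_json_round_trip(self, tmp_path):
        model = train_hmm([("我在成都", ["O", "O", "B-LOC", "E-LOC"])])
        path = tmp_path / "hmm.json"
        model.save(path)
        loaded = HmmModel.load(path)
        assert loaded.to_json() == model.to_json()
        assert viterbi_decode("我在成都", loaded) == viterbi_decode("我在成都", model)


def brute_force_decode(text, model):
    """Independent oracle: enumerate all |states|^n tag paths."""
    best_score = NEG_INF
    best_paths = []
    for path in itertools.product(model.states, repeat=len(text)):
        score = model.initial_logprob.get(path[0], NEG_INF) + model.emission(
            path[0], text[0]
        )
        for prev, cur, ch in zip(path, path[1:], text[1:]):
            score += model.transition_logprob[prev].get(cur, NEG_INF) + model.emission(
                cur, ch
            )
        if score > best_score + 1e-12:
            best_score = score
            best_paths = [list(path)]
        elif score > best_score - 1e-12:
            best_paths.append(list(path))
    return best_score, best_paths


def random_model(rng):
    """A smoothed model trained on a random labeled sample."""
    chars = "我在成都长沙交友啦"
    n = int(rng.integers(2, 7))
    text = "".join(rng.choice(list(chars), size=n))
    tags = random_valid_tags(rng, n)
    return train_hmm([(text, tags)])


def random_valid_tags(rng, n):
    tags = []
    state = str(rng.choice(ALLOWED_INITIAL))
    tags.append(state)
    for _ in range(n - 1):
        state = str(rng.choice(ALLOWED_TRANSITIONS[state]))
        tags.append(state)
    if tags[-1] == "B-LOC":
        tags[-1] = "S-LOC" if len(tags) == 1 or tags[-2] in ("E-LOC", "S-LOC", "O") else "E-LOC"
    elif tags[-1] == "M-LOC":
        tags[-1] = "E-LOC"
    return tags


class TestViterbi:
    def test_empty_text(self):
        model = train_hmm([("我在成都", ["O", "O", "B-LOC", "E-LOC"])])
        assert viterbi_decode("", model) == []

    def test_recovers_single_training_sentence(self):
        tags = ["O", "O", "B-LOC", "E-LOC"]
        model = train_hmm([("我在成都", tags)])
        assert viterbi_decode("我在成都", model) == tags

    def test_matches_exhaustive_enumeration(self):
        import numpy as np

        rng = np.random.default_rng(20240901)
        for _ in range(50):
            model = random_model(rng)
            length = int(rng.integers(1, 7))
            text = "".join(rng.choice(list("我在成都长沙外"), size=length))
            decoded = viterbi_decode(text, model)
            best_score, best_paths = brute_force_decode(text, model)
            assert decoded in best_paths


class TestLocSpans:
    @pytest.mark.parametrize(
        "tags,spans",
        [
            (["O", "B-LOC", "E-LOC", "O"], [(1, 3)]),
            (["S-LOC", "O", "B-LOC", "M-LOC", "E-LOC"], [(0, 1), (2, 5)]),
            (["O", "O"], []),
            (["B-LOC", "M-LOC"], [(0, 2)]),  # trailing unfinished span kept
        ],
    )
    def test_span_extraction(self, tags, spans):
        assert loc_spans(tags) == spans


class TestNerExtractor:
    def make_model(self):
        return train_hmm(
            [
                ("我在成都", ["O", "O", "B-LOC", "E-LOC"]),
                ("成都交友", ["B-LOC", "E-LOC", "O", "O"]),
                ("坐标成都啦", ["O", "O", "B-LOC", "E-LOC", "O"]),
            ]
        )

    def test_decoded_span_becomes_mention(self, tiny_gazetteer, corpus_factory):
        corpus = corpus_factory(("A", "1", "我在成都"))
        mentions = extract_ner(corpus, self.make_model(), tiny_gazetteer)
        assert {m.surface for m in mentions} == {"成都"}
        assert all(m.source == "ner" for m in mentions)

    def test_non_gazetteer_span_dropped(self, tiny_gazetteer, corpus_factory):
        # model trained so that 天府广场 decodes as LOC, yet it cannot resolve
        model = train_hmm(
            [("我在天府广场", ["O", "O", "B-LOC", "M-LOC", "M-LOC", "E-LOC"])]
        )
        corpus = corpus_factory(("A", "1", "我在天府广场"))
        assert extract_ner(corpus, model, tiny_gazetteer) == []

    def test_all_O_decode_no_mentions(self, tiny_gazetteer, corpus_factory):
        model = train_hmm([("吃饭没呀", ["O"] * 4)])
        corpus = corpus_factory(("A", "1", "吃饭没呀"))
        assert extract_ner(corpus, model, tiny_gazetteer) == []
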
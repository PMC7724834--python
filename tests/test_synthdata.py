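import pytest
from scipy import stats

from locinfer.corpus import default_stopwords, preprocess, read_posts
from locinfer.errors import GenerationError
from locinfer.evaluate import compute_metrics, read_gold
from locinfer.extract import train_hmm
from locinfer.gazetteer import CITY, Gazetteer
from locinfer.pipeline import infer_user_locations, preset
from locinfer.synthdata import (
    BARE_TEMPLATES,
    DEFAULT_CITY_WEIGHTS,
    DISTRACTOR_TEMPLATES,
    MODE_TEMPLATES,
    POI_TEMPLATES,
    SimParams,
    default_poi_list,
    generate_corpus,
    read_ner_labels,
    write_fixture,
)


def concat_posts(corpus, uid):
    return "".join(p.clean_text for p in corpus.posts_of(uid))


class TestTemplateHygiene:
    """The generator's fixed strings must not collide with the things the
    pipeline keys on, or offsets and gold labels would silently drift."""

    def fragments(self):
        frags = list(BARE_TEMPLATES) + list(DISTRACTOR_TEMPLATES) + list(POI_TEMPLATES)
        for templates in MODE_TEMPLATES.values():
            for pre, suf in templates:
                frags.extend([pre, suf])
        return [f.replace("{loc}", "").replace("{poi}", "") for f in frags if f]

    def test_no_gazetteer_surface_inside_fixed_strings(self, gaz):
        surfaces = gaz.surfaces()
        for frag in self.fragments():
            assert not any(s in frag for s in surfaces), frag

    def test_no_stopword_inside_fixed_strings(self):
        stop = default_stopwords()
        for frag in self.fragments():
            assert not any(s in frag for s in stop), frag

    def test_pois_contain_no_gazetteer_surface(self, gaz):
        surfaces = gaz.surfaces()
        for poi in default_poi_list():
            assert not gaz.canonicalize(poi)
            assert not any(s in poi for s in surfaces), poi

    def test_fixed_strings_survive_preprocessing(self):
        for frag in self.fragments():
            assert preprocess(frag) == frag, frag


class TestGenerate:
    def test_seeded_determinism(self, gaz, tmp_path):
        params = SimParams(n_users=100, posts_per_user=3, seed=7)
        dirs = []
        for name in ("a", "b"):
            corpus, gold, labels = generate_corpus(params, gaz)
            paths = write_fixture(corpus, gold, labels, tmp_path / name, params=params)
            dirs.append(paths)
        for key in ("corpus", "gold", "ner_train", "params"):
            assert dirs[0][key].read_bytes() == dirs[1][key].read_bytes()

    def test_prefix_stability_under_n_users(self, gaz):
        small, gold_s, _ = generate_corpus(SimParams(n_users=5, seed=3), gaz)
        large, gold_l, _ = generate_corpus(SimParams(n_users=12, seed=3), gaz)
        for uid in small.users:
            assert small.users[uid] == large.users[uid]
            assert gold_s[uid] == gold_l[uid]

    def test_perfect_recovery_conditions(self, gaz):
        params = SimParams(
            n_users=80, p_distractor=0.0, p_poi=0.0, p_keyword=1.0, seed=5
        )
        corpus, gold, _ = generate_corpus(params, gaz)
        inferences = infer_user_locations(corpus, gaz, preset("gazetteer"))
        pred = {uid: inf.locations for uid, inf in inferences.items()}
        rep = compute_metrics(pred, gold)
        assert rep.ratios() == {"S": 1.0, "C": 1.0, "T": 1.0, "P": 1.0}

    def test_single_location_when_multi_disabled(self, gaz):
        params = SimParams(n_users=60, p_multi_location=0.0, seed=2,
                           mode_weights={"former_keyword": 1.0})
        _, gold, _ = generate_corpus(params, gaz)
        for units in gold.values():
            assert len({u.canonical_name for u in units}) == 1

    def test_gold_always_recoverable_from_posts(self, gaz):
        params = SimParams(n_users=120, p_keyword=0.8, p_distractor=0.5, seed=9)
        corpus, gold, _ = generate_corpus(params, gaz)
        for uid, units in gold.items():
            text = concat_posts(corpus, uid)
            for u in units:
                assert u.canonical_name in text

    def test_distractors_never_coincide_with_gold(self, gaz):
        params = SimParams(
            n_users=60, p_keyword=1.0, p_distractor=1.0, p_poi=0.0, seed=4
        )
        corpus, gold, _ = generate_corpus(params, gaz)
        inferences = infer_user_locations(corpus, gaz, preset("gazetteer"))
        for uid, inf in inferences.items():
            extra = inf.locations - gold[uid]
            assert extra, "every post carries a distractor"  # p_distractor=1
            assert gold[uid] <= inf.locations
            # the distractor units are disjoint from gold by name too
            gold_names = {u.canonical_name for u in gold[uid]}
            assert not {u.canonical_name for u in extra} & gold_names

    def test_clean_text_matches_preprocessing(self, gaz):
        params = SimParams(n_users=40, seed=6)
        corpus, _, _ = generate_corpus(params, gaz)
        for post in corpus.iter_posts():
            assert preprocess(post.raw_text) == post.clean_text

    def test_ner_tags_align_with_clean_text(self, gaz):
        params = SimParams(n_users=40, seed=6)
        corpus, _, labels = generate_corpus(params, gaz)
        posts = list(corpus.iter_posts())
        assert len(labels) == len(posts)
        for (text, tags), post in zip(labels, posts):
            assert text == post.clean_text
            assert len(tags) == len(text)
            # every labeled span is a contiguous place string
            from locinfer.extract import validate_tags

            validate_tags(text, tags)

    def test_location_frequencies_match_distribution(self, gaz):
        # isolate the sampling step: one location per user, no pattern that
        # adds provinces to gold
        weights = {m: w for m, w in
                   {"former_keyword": 0.5, "later_keyword": 0.5}.items()}
        params = SimParams(
            n_users=2000, p_multi_location=0.0, mode_weights=weights, seed=11
        )
        _, gold, _ = generate_corpus(params, gaz)
        names = sorted(DEFAULT_CITY_WEIGHTS)
        total_w = sum(DEFAULT_CITY_WEIGHTS.values())
        observed = {n: 0 for n in names}
        for units in gold.values():
            (name,) = {u.canonical_name for u in units}
            observed[name] += 1
        exp = [params.n_users * DEFAULT_CITY_WEIGHTS[n] / total_w for n in names]
        obs = [observed[n] for n in names]
        result = stats.chisquare(obs, exp)
        assert result.pvalue > 0.01

    def test_zero_users_yields_valid_empty_files(self, gaz, tmp_path):
        corpus, gold, labels = generate_corpus(SimParams(n_users=0, seed=1), gaz)
        paths = write_fixture(corpus, gold, labels, tmp_path)
        assert read_posts(paths["corpus"]).n_users == 0
        assert paths["gold"].read_text(encoding="utf-8") == ""
        assert read_ner_labels(paths["ner_train"]) == []

    def test_invalid_probability_rejected(self, gaz):
        with pytest.raises(GenerationError):
            generate_corpus(SimParams(n_users=1, p_keyword=1.5), gaz)

    def test_empty_gazetteer_rejected(self):
        with pytest.raises(GenerationError):
            generate_corpus(SimParams(n_users=1), Gazetteer([]))


class TestFixtureRoundTrip:
    def test_corpus_round_trips_through_read_posts(self, gaz, tmp_path):
        params = SimParams(n_users=30, seed=8)
        corpus, gold, labels = generate_corpus(params, gaz)
        paths = write_fixture(corpus, gold, labels, tmp_path)
        assert read_posts(paths["corpus"]) == corpus

    def test_gold_parses_against_gazetteer(self, gaz, tmp_path):
        params = SimParams(n_users=30, seed=8)
        corpus, gold, labels = generate_corpus(params, gaz)
        paths = write_fixture(corpus, gold, labels, tmp_path)
        assert read_gold(paths["gold"], gaz) == gold

    def test_ner_labels_trainable(self, gaz, tmp_path):
        params = SimParams(n_users=30, seed=8)
        _, _, labels = generate_corpus(params, gaz)
        model = train_hmm(labels)
        model.validate()
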
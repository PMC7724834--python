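import textwrap

import pytest

from locinfer.corpus import Post, UserCorpus, preprocess
from locinfer.gazetteer import bundled_gazetteer, load_gazetteer


@pytest.fixture(scope="session")
def gaz():
    """The packaged China gazetteer."""
    return bundled_gazetteer()


@pytest.fixture()
def tiny_gazetteer(tmp_path):
    """Two provinces, two cities, one alias each: 6 surface forms."""
    path = tmp_path / "gaz.csv"
    path.write_text(
        textwrap.dedent(
            """\
            level,canonical_name,parent_province,aliases
            province,四川,,
            province,湖南,,
            city,成都,四川,成都市
            city,长沙,湖南,长沙市
            """
        ),
        encoding="utf-8",
    )
    return load_gazetteer(path)


def make_post(user_id: str, post_id: str, raw: str) -> Post:
    return Post(
        user_id=user_id,
        post_id=post_id,
        timestamp="",
        raw_text=raw,
        clean_text=preprocess(raw),
    )


def make_corpus(*posts) -> UserCorpus:
    """Build a corpus from (user_id, post_id, raw_text) triples."""
    return UserCorpus(make_post(u, p, t) for u, p, t in posts)


@pytest.fixture()
def corpus_factory():
    return make_corpus
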
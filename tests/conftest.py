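from __future__ import annotations

from datetime import datetime, timezone

import pytest

from fluortweets.corpus_io import TweetRecord


def ts(iso: str) -> datetime:
    return datetime.fromisoformat(iso).replace(tzinfo=timezone.utc)


def rec(id: str, text: str, when: str = "2017-06-15T12:00:00",
        author: str | None = None, gender: str = "unknown") -> TweetRecord:
    return TweetRecord(
        id=id, text=text, created_at=ts(when), author_id=author or f"a_{id}", gender=gender
    )


@pytest.fixture
def tiny_corpus() -> list[TweetRecord]:
    """Five posts: an original, its retweet, an unrelated match, a non-match."""
    return [
        rec("t1", "New fluoride varnish guidance for clinics", "2017-02-01T09:00:00",
            author="alice", gender="female"),
        rec("t2", "RT @alice: New fluoride varnish guidance for clinics",
            "2017-02-02T10:00:00", author="bob", gender="male"),
        rec("t3", "Worried that fluoride lowers IQ in children", "2018-05-10T17:30:00",
            author="carol", gender="female"),
        rec("t4", "brushing twice a day", "2019-01-05T08:00:00", author="dan"),
        rec("t5", "TOPICAL FLUORIDE works wonders after my visit", "2019-11-20T22:15:00",
            author="erin", gender="female"),
    ]
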
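"""Text normalization: raw post text to a sequence of word tokens.

The tokenizer is a fixed seven-step pipeline, applied in order:

1. strip one leading retweet marker of the form ``RT @name:``;
2. remove URLs;
3. remove ``@mention`` tokens;
4. lowercase;
5. delete ``#`` so hashtag words survive as plain words;
6. replace every remaining non-alphanumeric character with a space
   (non-ASCII letters are first transliterated to ASCII where a standard
   Unicode decomposition exists, else dropped);
7. split on whitespace.

Stripping the retweet marker makes a retweet tokenize identically to its
original, which is what lets the downstream word-level edit-distance
deduplication collapse retweets onto originals. No stemming and no stop-word
removal: the comparison downstream is of surface word forms only.
"""

from __future__ import annotations

import re
import unicodedata

__all__ = ["TokenSeq", "extract_hashtags", "normalize_text"]

#: An ordered sequence of normalized word tokens (each matches ``[a-z0-9]+``).
TokenSeq = tuple[str, ...]

_RT_PREFIX = re.compile(r"^\s*rt\s+@\w+\s*:\s*", re.IGNORECASE)
_URL = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION = re.compile(r"@\w+")
_HASHTAG = re.compile(r"#[0-9A-Za-z]+")
_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_text(text: str) -> TokenSeq:
    """Tokenize raw post text; empty input yields an empty sequence.

    Idempotent on its own output: re-normalizing the space-joined tokens
    returns the same sequence.
    """
    t = _RT_PREFIX.sub("", text, count=1)
    t = _URL.sub(" ", t)
    t = _MENTION.sub(" ", t)
    t = t.lower()
    t = t.replace("#", "")
    t = unicodedata.normalize("NFKD", t).encode("ascii", "ignore").decode("ascii")
    t = _NON_ALNUM.sub(" ", t)
    return tuple(t.split())


def extract_hashtags(text: str) -> list[str]:
    """Each maximal ``#``+alphanumeric run, lowercased, ``#`` retained.

    Order of appearance is kept and duplicates are preserved, so the result
    can be counted directly for hashtag frequency tables.
    """
    return [tag.lower() for tag in _HASHTAG.findall(text)]
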
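"""Text normalization shared by every module that looks at query text.

All matching in the package happens on normalized text: lower-case, tokens
are runs of ``[a-z0-9']``, joined by single spaces. Normalization is
idempotent, so text that went through ingest can be re-normalized freely.
"""

from __future__ import annotations

import re

_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize(text: str) -> list[str]:
    """Split already- or not-yet-normalized text into tokens."""
    return _TOKEN_RE.findall(text.lower())


def normalize(text: str) -> str:
    """Lower-case and whitespace-normalize; punctuation becomes token breaks."""
    return " ".join(tokenize(text))


def contains_phrase(text: str, phrase: str) -> bool:
    """True if ``phrase`` occurs in ``text`` as a contiguous token run.

    Both arguments must be normalized; token boundaries are respected, so
    "i have" does not match inside "i haven't" ("haven't" is one token).
    """
    return f" {phrase} " in f" {text} "
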
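"""Shared text normalization used by every lookup in the workflow.

Translation tables are authoritative for anything beyond case, whitespace
and diacritics; normalization here is deliberately minimal so that a term
match never depends on locale or input encoding quirks.
"""

from __future__ import annotations

import unicodedata

__all__ = ["normalize", "collapse_ws"]


def collapse_ws(text: str) -> str:
    """Collapse internal whitespace runs to single spaces and strip ends."""
    return " ".join(text.split())


def normalize(text: str) -> str:
    """Normalization applied before any table lookup.

    Unicode NFKD, diacritics stripped, case-folded, whitespace collapsed.
    Idempotent: ``normalize(normalize(x)) == normalize(x)``.
    """
    decomposed = unicodedata.normalize("NFKD", text)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return collapse_ws(stripped.casefold())
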
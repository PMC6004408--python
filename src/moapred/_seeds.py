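"""Deterministic seed derivation.

All randomness in the package flows from a single root seed; component-level
seeds are derived by hashing the root with a path of string tokens, so any
component can be rerun independently yet reproducibly, regardless of
iteration order elsewhere.
"""

from __future__ import annotations

import hashlib


def derive_seed(root: int, *tokens) -> int:
    """Derive a sub-seed (< 2**31) from a root seed and a token path."""
    payload = "|".join([str(int(root)), *map(str, tokens)])
    digest = hashlib.sha256(payload.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
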
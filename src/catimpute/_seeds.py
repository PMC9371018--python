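"""Deterministic seed derivation.

All randomness in a multi-stage run flows from one user-visible master seed.
Per-stage seeds are derived by hashing the master seed together with stable
string tokens naming the stage, so results do not depend on the order in
which stages execute.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *tokens: object) -> int:
    """Derive a child seed (< 2**31) from a master seed and stage tokens."""
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for tok in tokens:
        h.update(b"\x1f")
        h.update(str(tok).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
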
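"""Shared helpers: deterministic substream seeding."""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *context: str) -> int:
    """Stable 32-bit substream seed from a master seed and string context.

    Hash-based derivation keeps substreams independent of each other and of
    iteration order: adding a trait (or reordering rows) never perturbs the
    stream another trait sees.
    """
    h = hashlib.sha256(":".join([str(master_seed), *context]).encode()).digest()
    return int.from_bytes(h[:4], "big")
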
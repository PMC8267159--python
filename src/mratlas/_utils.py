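"""Small shared helpers."""
from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Derive a 32-bit child seed from a master seed and string tokens.

    Stable across processes and Python versions (unlike ``hash``), so
    pipeline runs are reproducible given the master seed alone.
    """
    key = "|".join([str(int(master_seed)), *map(str, tokens)])
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**32)
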
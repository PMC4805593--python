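"""Deterministic seed derivation for labelled Monte-Carlo streams.

One master seed is expanded into independent child seeds via SHA-256 of the
(master, stream label, index) triple.  No global RNG state is used anywhere
in the package.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, stream_label: str, index: int = 0) -> int:
    """Collision-resistant child seed in [0, 2**31) from a labelled stream."""
    payload = f"{int(master)}:{stream_label}:{int(index)}".encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:8], "little") % (2**31)
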
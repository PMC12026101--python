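"""Small shared helpers: seed derivation and identifier checks."""

from __future__ import annotations

import hashlib
from collections.abc import Sequence

from .exceptions import ValidationError

_SEED_MOD = 2**31


def derive_seed(seed: int, label: str) -> int:
    """Derive a stage- or signature-specific seed from a top-level seed.

    All randomness in a run flows from one integer seed; each consumer gets an
    independent stream keyed by a fixed text label, so stages are individually
    reproducible and insensitive to execution order.
    """
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % _SEED_MOD


def check_unique(ids: Sequence[str], what: str) -> None:
    """Raise ValidationError naming the first duplicate identifier, if any."""
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for ident in ids:
            if ident in seen:
                raise ValidationError(f"duplicate {what} identifier: {ident!r}")
            seen.add(ident)
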
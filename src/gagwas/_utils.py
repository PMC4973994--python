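"""Small shared helpers: seed derivation and logging."""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger("gagwas")


def derive_seed(global_seed: int, *labels: str) -> int:
    """Derive a per-stage seed deterministically from a global seed.

    Hashing the global seed together with stage/stratum labels keeps the
    stages statistically independent yet fully reproducible.  The result is
    always below 2**31.
    """
    key = f"{int(global_seed)}:" + ":".join(str(x) for x in labels)
    digest = hashlib.sha256(key.encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)
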
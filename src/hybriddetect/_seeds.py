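"""Stable derivation of per-stage seeds from one global seed.

Each stochastic stage receives a seed obtained by hashing the pair
(global seed, stage name) with SHA-256 and truncating to 31 bits.  Adding
a new stage therefore never shifts the random stream of an existing one.
"""

import hashlib


def derive_seed(global_seed: int, stage: str) -> int:
    """Return a deterministic 31-bit seed for `stage` under `global_seed`."""
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
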
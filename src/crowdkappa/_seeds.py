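"""Deterministic seed derivation.

Every random stage of the pipeline consumes a seed derived from one
top-level integer by stable hashing of the stage name, so enlarging one
stage (say the crowd) never perturbs another (say the truth draw) and the
whole run is reproducible from a single ``--seed``.
"""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *labels: str) -> int:
    """Derive a child seed < 2**31 from ``seed`` and a label path."""
    key = ":".join([str(int(seed)), *labels]).encode("utf-8")
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
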
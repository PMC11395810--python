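"""Seed plumbing: one user-facing integer seed fans out to per-stage
sub-seeds via a splitmix64-style hash, so adding a stage never perturbs
another stage's random stream."""

from __future__ import annotations

_MASK = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK
    return x ^ (x >> 31)


def spawn_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from a master seed."""
    h = _splitmix64(seed & _MASK)
    for ch in stage:
        h = _splitmix64(h ^ ord(ch))
    return h % (2**31 - 1)
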
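"""Global FLOP accounting for conv/linear/attention/scan primitives.

Convention: FLOPs = 2 x multiply-accumulates; elementwise and
normalization operations are excluded. Activate with ``flop_counter()``;
primitives report their MAC counts through :func:`add_macs`.
"""

from __future__ import annotations

from contextlib import contextmanager

_ACTIVE: list = []


@contextmanager
def flop_counter():
    """Context manager yielding a one-element list accumulating FLOPs."""
    box = [0]
    _ACTIVE.append(box)
    try:
        yield box
    finally:
        _ACTIVE.remove(box)


def add_macs(n_macs: int):
    if _ACTIVE:
        fl = 2 * int(n_macs)
        for box in _ACTIVE:
            box[0] += fl


def counting() -> bool:
    return bool(_ACTIVE)
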
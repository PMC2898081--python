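"""TSS-relative coordinate conventions.

Internally every position around a TSS is a 0-based offset where offset 0 is
the first transcribed base and offsets increase downstream of transcription.
Reports and figures in this field use a skip-zero display convention
(..., -2, -1, +1, +2, ...): there is no position 0, and +1 denotes the first
transcribed base.  The two helpers below convert between the conventions;
the display convention is applied only at report/plot time.
"""

from __future__ import annotations

import numpy as np


def display_to_offset(coord: int) -> int:
    """Convert a skip-zero display coordinate (+1 = first base) to an internal offset.

    ``+1 -> 0``, ``+40 -> 39``, ``-1 -> -1``, ``-500 -> -500``.
    """
    if coord == 0:
        raise ValueError("display coordinates have no position 0")
    return coord - 1 if coord > 0 else coord


def offset_to_display(offset):
    """Convert internal 0-based offsets to skip-zero display coordinates.

    Accepts scalars or arrays: ``0 -> +1``, ``39 -> +40``, ``-1 -> -1``.
    """
    offset = np.asarray(offset)
    out = np.where(offset >= 0, offset + 1, offset)
    return int(out) if out.ndim == 0 else out
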
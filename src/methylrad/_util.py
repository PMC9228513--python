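"""Small shared helpers."""
from __future__ import annotations

import math

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def truncate(x: float, ndigits: int = 0) -> float:
    """Truncate (not round) ``x`` towards zero to ``ndigits`` decimals.

    Genome-wide site densities are conventionally reported truncated
    (e.g. 741,956,528 / 63,634,074 = 11.6597... -> 11.65).
    """
    factor = 10 ** ndigits
    value = math.trunc(x * factor) / factor
    return value if ndigits > 0 else int(value)


def site_id(contig: str, pos: int) -> str:
    """Table-style site key, e.g. ``Chr23_13388333``."""
    return f"{contig}_{pos}"
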
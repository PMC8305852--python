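"""Shared constants and small numeric helpers."""
from __future__ import annotations

import math

# Parental-origin labels. P1 is the high-glucosinolate parent (LP08 in the
# motivating cross), P2 the low one (LP21); HET marks residual heterozygosity,
# MISSING an uninformative genotype, NA an unlabeled gene/interval.
P1 = "P1"
P2 = "P2"
HET = "HET"
MISSING = "MISSING"
NA = "NA"

ORIGIN_LABELS = (P1, P2, HET)
CALL_LABELS = (P1, P2, HET, MISSING)


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero, the convention of printed metabolite tables.

    Python's built-in ``round`` is banker's rounding; concentration tables
    round 0.5 up. A small absolute guard absorbs float representation error
    in sums of printed 1-2 decimal values (e.g. 417.45 stored as 417.44999...).
    """
    scale = 10.0 ** decimals
    scaled = abs(x) * scale
    return math.copysign(math.floor(scaled + 0.5 + 1e-9), x) / scale
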
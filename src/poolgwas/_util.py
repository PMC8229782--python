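"""Small shared helpers."""

from __future__ import annotations

import re

import pandas as pd

_CHROM_RE = re.compile(r"^(?:chr)?(\d+)$", re.IGNORECASE)
_SPECIAL = {"x": 23, "y": 24, "m": 25, "mt": 25}


def chrom_rank(chrom: str) -> str:
    """Sortable key giving natural chromosome order (chr2 before chr10)."""
    name = str(chrom)
    m = _CHROM_RE.match(name)
    if m:
        return f"{int(m.group(1)):04d}"
    stripped = name.lower().removeprefix("chr")
    if stripped in _SPECIAL:
        return f"{_SPECIAL[stripped]:04d}"
    return "9999" + name


def sort_by_position(df: pd.DataFrame, chrom: str = "chrom", pos: str = "pos") -> pd.DataFrame:
    """Stable sort by (natural chromosome order, position)."""
    return df.sort_values(
        [chrom, pos],
        key=lambda s: s.map(chrom_rank) if s.name == chrom else s,
        kind="mergesort",
    ).reset_index(drop=True)
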
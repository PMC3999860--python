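"""Lesion-fate classification: restored to C/G, converted to T/A, or other.

Every introduced base lesion pairs the mismatched pyrimidine (T, hmU, U) or
an abasic site against a G.  Repair that copies the G strand restores the
C/G pair; for T/G, copying the T strand instead converts the site to T/A.
In top-strand readout, restoration reproduces the reference base (C for
top-strand lesions, G for bottom-strand ones) and conversion reads T (top)
or A (bottom).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference import LesionSpec, ReporterReference

__all__ = ["classify_fate", "fate_summary"]

FATES = ("restored", "converted", "other")


def classify_fate(
    clone_sequence: str,
    lesion: LesionSpec,
    reference: ReporterReference,
) -> dict[int, str]:
    """Per-position fate of an introduced lesion in one ok-class clone.

    Returns mapping ``top-strand position -> restored | converted | other``.
    SSB and 0 MM specifications carry no base lesion and yield an empty map.
    """
    if not lesion.is_base_lesion:
        return {}
    if len(clone_sequence) != reference.length:
        raise ValueError("clone/reference length mismatch; classify ok clones only")
    fates: dict[int, str] = {}
    converted_base = lesion.converted_top_base()
    for pos in lesion.lesion_positions:
        if pos >= len(clone_sequence):
            raise ValueError(f"lesion position {pos} outside clone")
        base = clone_sequence[pos]
        if base == reference.top_sequence[pos]:
            fates[pos] = "restored"
        elif base == converted_base:
            fates[pos] = "converted"
        else:
            fates[pos] = "other"
    return fates


def fate_summary(
    fates: Iterable[tuple[str, str, str]],
) -> pd.DataFrame:
    """Summarize fates pooled per (lesion_type, strand) group.

    ``fates`` yields ``(lesion_type, strand, fate)`` triples, one per
    classified lesion.  Returns a table with columns n_lesions,
    pct_restored, pct_converted, pct_other; percentages sum to 100 per group.
    """
    rows = list(fates)
    if not rows:
        warnings.warn("no classified lesions; empty fate table", stacklevel=2)
        return pd.DataFrame(
            columns=["lesion_type", "strand", "n_lesions",
                     "pct_restored", "pct_converted", "pct_other"]
        )
    df = pd.DataFrame(rows, columns=["lesion_type", "strand", "fate"])
    out = []
    for (lesion_type, strand), group in df.groupby(["lesion_type", "strand"], sort=True):
        n = len(group)
        counts = group["fate"].value_counts()
        out.append(
            {
                "lesion_type": lesion_type,
                "strand": strand,
                "n_lesions": n,
                "pct_restored": 100.0 * counts.get("restored", 0) / n,
                "pct_converted": 100.0 * counts.get("converted", 0) / n,
                "pct_other": 100.0 * counts.get("other", 0) / n,
            }
        )
    return pd.DataFrame(out)
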
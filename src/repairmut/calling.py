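"""Mutation calling on sequenced clone cassettes.

Clones are plasmid Sanger reads of a fixed cassette, so the primary path is
an equal-length, gap-free comparison against the reference; a banded
edit-distance alignment (edlib) is used only to triage unequal-length clones
into small_indel / deleted, never for substitution calls.  The 8-bp random
bar code between its fixed flanks identifies independent transformation
events and is excluded from substitution calling (it is a designed element,
not a mutation).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib

from .reference import LesionSpec, ReporterReference
from .simulate import CloneRecord

__all__ = [
    "MutationRecord",
    "BarcodeError",
    "extract_barcode",
    "classify_clone",
    "call_mutations",
    "dedupe_clones",
    "parse_clone_fasta",
    "mutation_table",
]

logger = logging.getLogger(__name__)

BARCODE_FLANK_5 = "GAGCTCTA"
BARCODE_FLANK_3 = "TACGTACG"


class BarcodeError(ValueError):
    """Bar-code flanks missing, duplicated, or mis-spaced."""


@dataclass(frozen=True)
class MutationRecord:
    """One called substitution in top-strand readout."""

    clone_id: str
    position: int  # 0-based top-strand coordinate
    ref_base: str
    alt_base: str
    region: str
    context5: str | None  # base 5' on the top strand, None at the edge
    context3: str | None
    is_lesion_site: bool = False

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base equals alt_base")


def _find_all(haystack: str, needle: str) -> list[int]:
    return [m.start() for m in re.finditer(f"(?={re.escape(needle)})", haystack)]


def extract_barcode(clone_sequence: str) -> str:
    """Read the 8-bp bar code between its fixed flanking octamers.

    Requires each flank exactly once, in order, 8 bases apart.
    """
    hits5 = _find_all(clone_sequence, BARCODE_FLANK_5)
    hits3 = _find_all(clone_sequence, BARCODE_FLANK_3)
    if len(hits5) != 1:
        raise BarcodeError(
            f"flank {BARCODE_FLANK_5} found {len(hits5)} times; expected once"
        )
    if len(hits3) != 1:
        raise BarcodeError(
            f"flank {BARCODE_FLANK_3} found {len(hits3)} times; expected once"
        )
    start = hits5[0] + len(BARCODE_FLANK_5)
    if hits3[0] != start + 8:
        raise BarcodeError(
            f"flanks spaced {hits3[0] - start} bases apart; expected 8"
        )
    return clone_sequence[start : start + 8]


def _reporter_deletion_span(
    clone_sequence: str, reference: ReporterReference
) -> int:
    """Total reference bases absent from the aligned clone within the
    promoter+supF+MM reporter span (edlib global alignment).

    Summed rather than longest-run: the optimal alignment of a large
    deletion scatters it into fragments separated by spurious 1-2 bp
    matches, but the total deleted footprint is preserved.
    """
    result = edlib.align(clone_sequence, reference.top_sequence, task="path")
    cigar = result["cigar"] or ""
    ref_pos = 0
    deleted = 0
    r_start = reference.regions["promoter"][0]
    r_end = reference.regions["mm_region"][1]
    for length, op in re.findall(r"(\d+)([=XIDM])", cigar):
        length = int(length)
        if op in ("=", "X", "M"):
            ref_pos += length
        elif op == "D":  # bases present in reference, absent in clone
            overlap = min(ref_pos + length, r_end) - max(ref_pos, r_start)
            if overlap > 0:
                deleted += overlap
            ref_pos += length
        # op == "I": clone-only bases, reference position unchanged
    return deleted


def classify_clone(
    clone_sequence: str,
    reference: ReporterReference,
    deletion_span: int = 50,
) -> str:
    """Triage a clone into ``ok`` / ``small_indel`` / ``deleted``.

    ``deleted`` means the aligned clone lacks at least ``deletion_span``
    contiguous reference bases within the reporter span; other length
    differences are ``small_indel``; equal-length gap-free clones are ``ok``.
    """
    if not clone_sequence:
        raise ValueError("empty clone sequence")
    if len(clone_sequence) == len(reference.top_sequence):
        return "ok"
    if _reporter_deletion_span(clone_sequence, reference) >= deletion_span:
        return "deleted"
    return "small_indel"


def call_mutations(
    clone_sequence: str,
    reference: ReporterReference,
    lesion: LesionSpec | None = None,
    clone_id: str = "clone",
) -> list[MutationRecord]:
    """Call substitutions on an equal-length, gap-free clone.

    One record per mismatching position, sorted by position, with 5'/3'
    contexts taken from the reference top strand.  Bar-code positions are
    skipped; lesion positions are flagged ``is_lesion_site`` (they report the
    lesion's fate, not an induced mutation).
    """
    ref_seq = reference.top_sequence
    if len(clone_sequence) != len(ref_seq):
        raise ValueError(
            f"length mismatch ({len(clone_sequence)} vs {len(ref_seq)}); "
            "triage with classify_clone first"
        )
    b_start, b_end = reference.regions["barcode"]
    lesion_positions = set(lesion.lesion_positions) if lesion else set()
    records = []
    n = len(ref_seq)
    for pos in range(n):
        if b_start <= pos < b_end:
            continue
        if clone_sequence[pos] == ref_seq[pos]:
            continue
        records.append(
            MutationRecord(
                clone_id=clone_id,
                position=pos,
                ref_base=ref_seq[pos],
                alt_base=clone_sequence[pos],
                region=reference.region_of(pos),
                context5=ref_seq[pos - 1] if pos > 0 else None,
                context3=ref_seq[pos + 1] if pos < n - 1 else None,
                is_lesion_site=pos in lesion_positions,
            )
        )
    return records


def dedupe_clones(
    clones: Sequence[CloneRecord],
    mutations_by_clone: Mapping[str, Sequence[MutationRecord]],
) -> list[CloneRecord]:
    """Collapse sibling clones of one transformation event.

    Clones within a transfection sharing both the bar code and the full
    mutation set are siblings and collapse to one; identical mutation sets
    under different bar codes are independent events and are all kept.
    Clones whose bar code could not be read are kept with a warning.
    """
    kept: list[CloneRecord] = []
    seen: set[tuple[str, str, frozenset]] = set()
    for clone in clones:
        try:
            barcode = extract_barcode(clone.sequence)
        except BarcodeError as exc:
            logger.warning("%s: %s; kept without dedup", clone.clone_id, exc)
            kept.append(clone)
            continue
        mutations = frozenset(
            (m.position, m.ref_base, m.alt_base)
            for m in mutations_by_clone.get(clone.clone_id, ())
        )
        key = (clone.transfection_id, barcode, mutations)
        if key in seen:
            continue
        seen.add(key)
        kept.append(clone)
    return kept


def parse_clone_fasta(path) -> list[CloneRecord]:
    """Read clones from FASTA with ``id|transfection|condition|barcode|color|class``
    headers (missing trailing fields default sensibly)."""
    from Bio import SeqIO

    clones = []
    for record in SeqIO.parse(str(path), "fasta"):
        fields = record.description.split("|")
        clones.append(
            CloneRecord(
                clone_id=fields[0],
                transfection_id=fields[1] if len(fields) > 1 else "tx1",
                condition=fields[2] if len(fields) > 2 else "unknown",
                barcode=fields[3] if len(fields) > 3 else "",
                sequence=str(record.seq).upper(),
                color=fields[4] if len(fields) > 4 else "white",
                clone_class=fields[5] if len(fields) > 5 else "ok",
            )
        )
    return clones


def mutation_table(
    mutations: Iterable[MutationRecord],
    clones_by_id: Mapping[str, CloneRecord] | None = None,
):
    """Mutation records as a tidy DataFrame (1-based positions for reports)."""
    import pandas as pd

    rows = []
    for m in mutations:
        clone = clones_by_id.get(m.clone_id) if clones_by_id else None
        rows.append(
            {
                "clone_id": m.clone_id,
                "transfection": clone.transfection_id if clone else "",
                "condition": clone.condition if clone else "",
                "pos_1based": m.position + 1,
                "ref": m.ref_base,
                "alt": m.alt_base,
                "region": m.region,
                "context5": m.context5 or "",
                "context3": m.context3 or "",
                "is_lesion_site": m.is_lesion_site,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clone_id", "transfection", "condition", "pos_1based", "ref",
            "alt", "region", "context5", "context3", "is_lesion_site",
        ],
    )
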
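"""Episome reference model: coordinates, strands, and sequence composition.

The reporter episome is a circular shuttle vector whose *top strand* is the
FASTA record's sequence as given (5'->3').  Every mutation in the pipeline is
reported in terms of this top strand; the bottom strand is its reverse
complement, with bottom-strand coordinate ``j`` pairing with top coordinate
``length - 1 - j``.  Coordinates are 0-based, half-open internally; reports
use 1-based closed intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "ReporterReference",
    "LesionSpec",
    "KmerTable",
    "ReferenceValidationError",
    "load_reference",
    "load_lesion_table",
    "revcomp",
    "map_readout",
    "background_kmer_fractions",
]

VALID_BASES = frozenset("ACGT")
REQUIRED_REGIONS = ("promoter", "supf", "mm_region", "barcode", "backbone")
#: regions that must not overlap one another (backbone may span everything)
CORE_REGIONS = ("promoter", "supf", "mm_region", "barcode")
#: default span for sequence-composition backgrounds ("reporter region")
REPORTER_REGIONS = ("promoter", "supf", "mm_region")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

LESION_TYPES = frozenset({"TG", "hmUG", "UG", "abG", "SSB", "none"})


class ReferenceValidationError(ValueError):
    """Raised when a reference, region file, or lesion table fails validation."""


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (A/C/G/T only)."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ReferenceValidationError(
            f"invalid character(s) {sorted(bad)} in sequence; expected A/C/G/T"
        )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReporterReference:
    """Annotated top-strand episome cassette.

    Parameters
    ----------
    name : record identifier
    top_sequence : top strand, 5'->3', over {A,C,G,T}
    regions : region name -> half-open ``(start, end)`` in top-strand
        coordinates; must include promoter, supf, mm_region, barcode and
        backbone.  The core regions must be mutually non-overlapping.
    """

    name: str
    top_sequence: str
    regions: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        bad = set(self.top_sequence) - VALID_BASES
        if bad:
            raise ReferenceValidationError(
                f"top_sequence: invalid character(s) {sorted(bad)}"
            )
        for name in REQUIRED_REGIONS:
            if name not in self.regions:
                raise ReferenceValidationError(f"regions: missing region {name!r}")
        n = len(self.top_sequence)
        for name, (start, end) in self.regions.items():
            if not (0 <= start < end <= n):
                raise ReferenceValidationError(
                    f"regions[{name!r}]: interval out of range "
                    f"[{start}, {end}) on length-{n} sequence"
                )
        spans = sorted(self.regions[name] for name in CORE_REGIONS)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ReferenceValidationError(
                    f"core regions overlap: [{s1},{e1}) and [{s2},{e2})"
                )

    @property
    def length(self) -> int:
        return len(self.top_sequence)

    @property
    def bottom_sequence(self) -> str:
        return revcomp(self.top_sequence)

    def strand_sequence(self, strand: str) -> str:
        if strand == "top":
            return self.top_sequence
        if strand == "bottom":
            return self.bottom_sequence
        raise ReferenceValidationError(f"unknown strand {strand!r}")

    def to_top(self, position: int, strand: str) -> int:
        """Top-strand coordinate of position ``position`` on ``strand``."""
        if strand == "top":
            return position
        if strand == "bottom":
            return self.length - 1 - position
        raise ReferenceValidationError(f"unknown strand {strand!r}")

    def region_of(self, position: int) -> str:
        """Most specific named region containing ``position``.

        Core regions take precedence over backbone (which may be annotated as
        the full remainder of the episome).
        """
        for name in CORE_REGIONS:
            start, end = self.regions[name]
            if start <= position < end:
                return name
        return "backbone"

    def region_slice(self, name: str) -> str:
        start, end = self.regions[name]
        return self.top_sequence[start:end]


@dataclass(frozen=True)
class LesionSpec:
    """An introduced mispair or lesion on a defined strand of the episome.

    ``lesion_positions`` are top-strand coordinates of the affected base
    pair(s).  For base lesions (TG/hmUG/UG/abG) the lesion-carrying strand
    holds the mismatched base opposite a G; restoration rewrites it to C, so
    the reference top base at each position is C for top-strand lesions and G
    for bottom-strand lesions.  For SSB the positions mark the nick site and
    no base changes.
    """

    oligo_id: str
    lesion_type: str
    strand: str
    lesion_positions: tuple[int, ...] = ()
    reference_pair: str = "C/G"

    def __post_init__(self) -> None:
        if self.lesion_type not in LESION_TYPES:
            raise ReferenceValidationError(
                f"lesion_type {self.lesion_type!r} not in {sorted(LESION_TYPES)}"
            )
        if self.strand not in ("top", "bottom"):
            raise ReferenceValidationError(f"strand {self.strand!r}")
        if self.lesion_type == "none" and self.lesion_positions:
            raise ReferenceValidationError("lesion_type 'none' must have no positions")

    @property
    def is_base_lesion(self) -> bool:
        return self.lesion_type in ("TG", "hmUG", "UG", "abG")

    def converted_top_base(self) -> str:
        """Top-strand readout of a converted (T/A) lesion site."""
        return "T" if self.strand == "top" else "A"

    def validate_against(self, reference: ReporterReference) -> None:
        mm_start, mm_end = reference.regions["mm_region"]
        for pos in self.lesion_positions:
            if not (mm_start <= pos < mm_end):
                raise ReferenceValidationError(
                    f"lesion {self.oligo_id}: position {pos} outside mm_region "
                    f"[{mm_start}, {mm_end})"
                )
            if self.is_base_lesion:
                expected = "C" if self.strand == "top" else "G"
                actual = reference.top_sequence[pos]
                if actual != expected:
                    raise ReferenceValidationError(
                        f"lesion {self.oligo_id}: reference top base at {pos} is "
                        f"{actual}, expected {expected} for a {self.strand}-strand "
                        f"{self.lesion_type} lesion"
                    )


@dataclass
class KmerTable:
    """Fractional k-mer composition table.

    ``side`` records what the table tallies: the 5'/3' context of mutated
    bases, or a background composition over a reference span.
    """

    k: int
    side: str
    fractions: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ReferenceValidationError("k must be >= 1")
        if self.side not in ("five_prime", "three_prime", "center", "background"):
            raise ReferenceValidationError(f"unknown side {self.side!r}")
        if self.n > 0:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ReferenceValidationError(
                    f"fractions sum to {total}, expected 1"
                )

    def get(self, kmer: str) -> float:
        return self.fractions.get(kmer, 0.0)


def load_reference(fasta_path, regions_path) -> ReporterReference:
    """Load a single-record FASTA plus a BED region annotation.

    The BED file is 0-based half-open with the region name in column 4 and
    must name all of promoter, supf, mm_region, barcode and backbone.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ReferenceValidationError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    record = records[0]
    regions: dict[str, tuple[int, int]] = {}
    with open(regions_path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ReferenceValidationError(
                    f"{regions_path}:{line_no}: BED line needs >=4 columns"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ReferenceValidationError(
                    f"{regions_path}:{line_no}: non-integer coordinates"
                ) from exc
            regions[parts[3]] = (start, end)
    return ReporterReference(
        name=record.id, top_sequence=str(record.seq).upper(), regions=regions
    )


def load_lesion_table(path) -> list[LesionSpec]:
    """Read a lesion-specification TSV.

    Columns: oligo_id, lesion_type, strand, positions (semicolon-separated
    top-strand coordinates; empty for 0 MM), reference_pair.
    """
    lesions = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("oligo_id", "lesion_type", "strand", "positions"):
            if name not in idx:
                raise ReferenceValidationError(f"{path}: missing column {name!r}")
        for line in handle:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            raw = parts[idx["positions"]].strip()
            positions = tuple(int(p) for p in raw.split(";") if p) if raw else ()
            pair = (
                parts[idx["reference_pair"]]
                if "reference_pair" in idx and len(parts) > idx["reference_pair"]
                else "C/G"
            )
            lesions.append(
                LesionSpec(
                    oligo_id=parts[idx["oligo_id"]],
                    lesion_type=parts[idx["lesion_type"]],
                    strand=parts[idx["strand"]],
                    lesion_positions=positions,
                    reference_pair=pair or "C/G",
                )
            )
    return lesions


def map_readout(
    position: int,
    strand: str,
    ref_base: str,
    alt_base: str,
    reference: ReporterReference,
) -> tuple[int, str, str]:
    """Map a strand-local substitution to top-strand readout.

    Top-strand events pass through unchanged; a bottom-strand event at bottom
    coordinate ``j`` becomes top coordinate ``length - 1 - j`` with both bases
    complemented.  Applying the map twice (with the strand toggled) restores
    the original record.
    """
    seq = reference.strand_sequence(strand)
    if not (0 <= position < reference.length):
        raise ReferenceValidationError(
            f"position {position} out of range on length-{reference.length} reference"
        )
    if seq[position] != ref_base:
        raise ReferenceValidationError(
            f"ref_base {ref_base!r} disagrees with {strand} strand base "
            f"{seq[position]!r} at position {position}"
        )
    if strand == "top":
        return position, ref_base, alt_base
    return (
        reference.length - 1 - position,
        ref_base.translate(_COMPLEMENT),
        alt_base.translate(_COMPLEMENT),
    )


def kmer_fractions_of(sequences: Iterable[str], k: int, center_base: str | None = None) -> KmerTable:
    """Tally overlapping top-strand k-mers of one or more linear sequences.

    With ``center_base`` set (odd k), only k-mers whose central base matches
    are tallied — the background for base-centred context tables.
    """
    counts: dict[str, int] = {}
    n = 0
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if center_base is not None and kmer[k // 2] != center_base:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
            n += 1
    fractions = {kmer: c / n for kmer, c in counts.items()} if n else {}
    return KmerTable(k=k, side="background", fractions=fractions, n=n)


def background_kmer_fractions(
    reference: ReporterReference,
    region_names: Sequence[str] = REPORTER_REGIONS,
    k: int = 2,
    center_base: str | None = None,
) -> KmerTable:
    """Background k-mer composition over named regions of the top strand.

    Windows are tallied within each region (linear, no wraparound, no windows
    spanning region junctions).  Regions shorter than k are excluded with a
    warning; if all are too short an error is raised.
    """
    if k < 1:
        raise ReferenceValidationError("k must be >= 1")
    usable = []
    for name in region_names:
        if name not in reference.regions:
            raise ReferenceValidationError(f"unknown region {name!r}")
        seq = reference.region_slice(name)
        if len(seq) < k:
            warnings.warn(
                f"region {name!r} shorter than k={k}; excluded from background",
                stacklevel=2,
            )
            continue
        usable.append(seq)
    if not usable:
        raise ReferenceValidationError(
            f"all regions {list(region_names)} shorter than k={k}"
        )
    return kmer_fractions_of(usable, k, center_base=center_base)
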
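"""Mutation-spectrum summaries in top-strand readout.

Per-base mutation fractions and fates, identity-and-fate substitution-class
tables, dinucleotide/trinucleotide context spectra (paired with the
reporter-region background composition), and the clustered/unclustered clone
partition.  Lesion-site records are excluded from all spectra: they report
lesion fate, not induced mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import MutationRecord
from .reference import KmerTable, ReporterReference, background_kmer_fractions

__all__ = [
    "SpectrumTable",
    "ClusterPartition",
    "per_base_spectrum",
    "identity_fate_summary",
    "kmer_context_spectrum",
    "trinucleotide_of_G",
    "cluster_partition",
]


def _induced(mutations: Iterable[MutationRecord]) -> list[MutationRecord]:
    return [m for m in mutations if not m.is_lesion_site]


@dataclass
class SpectrumTable:
    """Per-position fraction of total mutations and per-alt-base split."""

    n_sequences: int
    n_mutations: int
    table: pd.DataFrame  # columns: position, ref, fraction, to_A/C/G/T

    def position_fractions(self) -> pd.Series:
        return self.table.set_index("position")["fraction"]


def per_base_spectrum(
    mutations: Iterable[MutationRecord],
    reference: ReporterReference,
    n_sequences: int = 0,
) -> SpectrumTable:
    """Fraction of total induced mutations contributed by each position,
    split by the base each was mutated to."""
    records = _induced(mutations)
    total = len(records)
    if total == 0:
        empty = pd.DataFrame(
            columns=["position", "ref", "fraction", "to_A", "to_C", "to_G", "to_T"]
        )
        return SpectrumTable(n_sequences=n_sequences, n_mutations=0, table=empty)
    counts: dict[int, dict[str, int]] = {}
    for m in records:
        counts.setdefault(m.position, {}).setdefault(m.alt_base, 0)
        counts[m.position][m.alt_base] += 1
    rows = []
    for pos in sorted(counts):
        by_alt = counts[pos]
        row = {
            "position": pos,
            "ref": reference.top_sequence[pos],
            "fraction": sum(by_alt.values()) / total,
        }
        for base in "ACGT":
            row[f"to_{base}"] = by_alt.get(base, 0) / total
        rows.append(row)
    return SpectrumTable(
        n_sequences=n_sequences, n_mutations=total, table=pd.DataFrame(rows)
    )


def identity_fate_summary(
    mutations: Iterable[MutationRecord],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Substitution classes (ref base -> alt base) as percent of group total.

    ``groups`` maps clone_id to a group label (e.g. the lesion strand and
    fate quadrant); without it all mutations form one group.  Twelve classes
    (4 ref x 3 alt) per group; empty groups are omitted.
    """
    records = _induced(mutations)
    rows = []
    for m in records:
        label = groups.get(m.clone_id, "all") if groups else "all"
        rows.append({"group": label, "ref": m.ref_base, "alt": m.alt_base})
    if not rows:
        return pd.DataFrame(columns=["group", "ref", "alt", "n", "percent"])
    df = pd.DataFrame(rows)
    out = []
    for label, group in df.groupby("group", sort=True):
        n_total = len(group)
        by_class = group.groupby(["ref", "alt"]).size()
        for (ref, alt), n in by_class.items():
            out.append(
                {
                    "group": label,
                    "ref": ref,
                    "alt": alt,
                    "n": int(n),
                    "percent": 100.0 * n / n_total,
                }
            )
    return pd.DataFrame(out)


def kmer_context_spectrum(
    mutations: Iterable[MutationRecord],
    reference: ReporterReference,
    k: int = 2,
    side: str = "three_prime",
) -> KmerTable:
    """Dinucleotide (or trinucleotide) context spectrum of mutated bases.

    For k=2 the tallied k-mer is the mutated base with its 5' or 3'
    reference neighbor on the top strand; for k=3 both neighbors (``side``
    is recorded as ``center``).  Mutations at a cassette edge lacking the
    needed neighbor are excluded from the tally.
    """
    if k not in (2, 3):
        raise ValueError(f"unsupported k={k}; expected 2 or 3")
    if side not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown side {side!r}")
    records = _induced(mutations)
    counts: dict[str, int] = {}
    n = 0
    for m in records:
        if k == 3:
            if m.context5 is None or m.context3 is None:
                continue
            kmer = m.context5 + m.ref_base + m.context3
        elif side == "five_prime":
            if m.context5 is None:
                continue
            kmer = m.context5 + m.ref_base
        else:
            if m.context3 is None:
                continue
            kmer = m.ref_base + m.context3
        counts[kmer] = counts.get(kmer, 0) + 1
        n += 1
    fractions = {kmer: c / n for kmer, c in counts.items()} if n else {}
    return KmerTable(
        k=k, side="center" if k == 3 else side, fractions=fractions, n=n
    )


def trinucleotide_of_G(
    mutations: Iterable[MutationRecord],
    reference: ReporterReference,
    region_names: Sequence[str] | None = None,
) -> tuple[KmerTable, KmerTable]:
    """NpGpN context of mutated-G records, with a G-centred background.

    Returns ``(spectrum, background)``; the background tallies G-centred
    trinucleotides over the reporter region (or ``region_names``).
    """
    g_records = [
        m
        for m in _induced(mutations)
        if m.ref_base == "G" and m.context5 is not None and m.context3 is not None
    ]
    counts: dict[str, int] = {}
    for m in g_records:
        kmer = m.context5 + "G" + m.context3
        counts[kmer] = counts.get(kmer, 0) + 1
    n = len(g_records)
    spectrum = KmerTable(
        k=3,
        side="center",
        fractions={kmer: c / n for kmer, c in counts.items()} if n else {},
        n=n,
    )
    kwargs = {"region_names": region_names} if region_names else {}
    background = background_kmer_fractions(reference, k=3, center_base="G", **kwargs)
    return spectrum, background


@dataclass
class ClusterPartition:
    """Clustered (>1 induced mutation per sequence) vs unclustered clones."""

    labels: dict[str, str] = field(default_factory=dict)
    n_clustered: int = 0
    n_unclustered: int = 0

    @property
    def fraction_clustered(self) -> float:
        total = self.n_clustered + self.n_unclustered
        return self.n_clustered / total if total else 0.0


#: the sequenced reporter cassette -- the span over which clusters are scored
CASSETTE_REGIONS = ("promoter", "supf", "mm_region")


def cluster_partition(
    mutations_by_clone: Mapping[str, Sequence[MutationRecord]],
    regions: Sequence[str] | None = CASSETTE_REGIONS,
) -> ClusterPartition:
    """Partition mutated clones by induced-mutation count.

    A clone is ``clustered`` iff it carries two or more induced (non-lesion-
    site) mutations within the analyzed cassette (by default the sequenced
    promoter+supF+MM span); clones with no such mutations are not labelled.
    Pass ``regions=None`` to count over the whole clone.
    """
    partition = ClusterPartition()
    region_set = set(regions) if regions is not None else None
    for clone_id, records in mutations_by_clone.items():
        induced = _induced(records)
        if region_set is not None:
            induced = [m for m in induced if m.region in region_set]
        n = len(induced)
        if n == 0:
            continue
        label = "clustered" if n >= 2 else "unclustered"
        partition.labels[clone_id] = label
        if label == "clustered":
            partition.n_clustered += 1
        else:
            partition.n_unclustered += 1
    return partition
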
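"""Mechanistic stochastic simulator of repair-induced APOBEC mutagenesis.

Model
-----
A defined mispair (T/G, hmU/G, U/G, ab/G) or single-strand break is carried
on one strand of a circular reporter episome.  Base excision repair nicks 5'
of the lesion; non-canonical mismatch repair can hijack the intermediate and
resect the lesion strand, exposing a stretch of the complementary strand as
a single-stranded repair template.  Single-strand-specific APOBEC cytidine
deaminases then attack template cytosines, preferring the C of TpC.  Each
deaminated C registers, after replication, as a transition (C->T on the
template) or, via abasic-site bypass, a transversion (C->G / C->A).  On the
top-strand readout a bottom-template TpC deamination appears as a mutated G
with 3' A (the GpA signature).

Lesion fate is decided by template choice: using the G strand as template
restores C/G; using the T strand of a T/G converts it to T/A (~25% of the
time by default).  U/G, hmU/G and ab/G are almost always restored.  T/G
mutagenesis reaches the whole episome (modelled as a migrating D-loop);
BER/MMR-driven exposure decays with distance (geometric resection length,
mean 300 nt by default), reproducing the near/far strand asymmetry.

Simulated transfections add blue/white colony counts, reporter deletions and
small indels at configured rates, and a fresh random 8-bp bar code per clone.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .reference import LesionSpec, ReporterReference, map_readout

__all__ = [
    "SimParams",
    "RepairEvent",
    "CloneRecord",
    "TransfectionCounts",
    "ColonyDataset",
    "simulate_repair_event",
    "simulate_random_nick_event",
    "realize_clone",
    "simulate_transfection",
    "simulate_experiment",
    "transfection_rng",
]

logger = logging.getLogger(__name__)

#: calibrated per-colony probabilities that a colony yields a white,
#: undeleted, mutated episome (percent mutation frequency / 100)
DEFAULT_PER_COLONY_MUT_PROB = {
    "TG_top": 0.00107,
    "hmUG_top": 0.00182,
    "UG_top": 0.00726,
    "abG_top": 0.0078,
    "TG_bottom": 0.0023,
    "UG_bottom": 0.0008,
    "SSB_near": 0.0073,
    "SSB_far": 0.0004,
    "noMM": 0.00025,
}

#: single-strand exposure mechanism per condition (fallback: lesion type)
DEFAULT_EXPOSURE_MECHANISM = {
    "TG": "dloop",
    "UG": "ber_mmr",
    "hmUG": "ber_mmr",
    "abG": "ber_mmr",
    "SSB_near": "ber_mmr",
    "SSB_far": "ssbr",
    "SSB": "ber_mmr",
    "noMM": "ber_mmr",
    "none": "ber_mmr",
}

DEFAULT_CLUSTER_SIZE_PMF = {1: 0.73, 2: 0.17, 3: 0.07, 4: 0.03}


@dataclass
class SimParams:
    """Generator configuration; defaults are the study calibration."""

    seed: int = 0
    per_colony_mut_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PER_COLONY_MUT_PROB)
    )
    tg_template_choice: float = 0.75
    restore_prob: dict[str, float] = field(
        default_factory=lambda: {"UG": 0.99, "hmUG": 0.99, "abG": 1.0}
    )
    exposure_mechanism: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE_MECHANISM)
    )
    exposure_len_mean: float = 300.0
    cluster_size_pmf: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_SIZE_PMF)
    )
    p_five_prime_T: float = 0.80
    p_transition: float = 0.5
    deletion_rate: float = 0.03
    indel_rate: float = 0.05
    deletion_span: int = 50

    def __post_init__(self) -> None:
        probs = [
            self.tg_template_choice,
            self.p_five_prime_T,
            self.p_transition,
            self.deletion_rate,
            self.indel_rate,
            *self.per_colony_mut_prob.values(),
            *self.restore_prob.values(),
            *self.cluster_size_pmf.values(),
        ]
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        total = sum(self.cluster_size_pmf.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cluster_size_pmf sums to {total}, expected 1")

    def mechanism_for(self, condition: str, lesion_type: str) -> str:
        if condition in self.exposure_mechanism:
            return self.exposure_mechanism[condition]
        return self.exposure_mechanism.get(lesion_type, "ber_mmr")


@dataclass(frozen=True)
class RepairEvent:
    """One repaired lesion: template choice, exposure window, deaminations.

    ``exposure`` is ``(start, length)`` in template-strand coordinates on the
    circular episome; ``deaminations`` are ``(template_position, outcome)``
    pairs where the outcome is the base replacing the deaminated template C
    (T = transition readout; G/A = transversions).
    """

    condition: str
    lesion: LesionSpec
    template_strand: str
    fate: str  # restored | converted | none
    exposure: tuple[int, int]
    deaminations: tuple[tuple[int, str], ...] = ()

    def exposure_contains(self, template_pos: int, length: int) -> bool:
        start, span = self.exposure
        if span >= length:
            return True
        offset = (template_pos - start) % length
        return offset < span


@dataclass
class CloneRecord:
    """One sequenced colony's recovered episome cassette."""

    clone_id: str
    transfection_id: str
    condition: str
    barcode: str
    sequence: str
    color: str  # blue | white
    clone_class: str = "ok"  # ok | small_indel | deleted


@dataclass
class TransfectionCounts:
    transfection_id: str
    condition: str
    total_colonies: int
    n_blue: int
    n_white: int
    n_white_deleted: int

    @property
    def n_white_undeleted(self) -> int:
        return self.n_white - self.n_white_deleted


@dataclass
class ColonyDataset:
    """Counts, sequenced clones and the underlying event log of a simulation."""

    transfections: list[TransfectionCounts] = field(default_factory=list)
    clones: list[CloneRecord] = field(default_factory=list)
    events: dict[str, RepairEvent] = field(default_factory=dict)

    def extend(self, other: "ColonyDataset") -> None:
        self.transfections.extend(other.transfections)
        self.clones.extend(other.clones)
        self.events.update(other.events)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for clone in self.clones:
                fh.write(
                    f">{clone.clone_id}|{clone.transfection_id}|{clone.condition}"
                    f"|{clone.barcode}|{clone.color}|{clone.clone_class}\n"
                )
                for i in range(0, len(clone.sequence), 70):
                    fh.write(clone.sequence[i : i + 70] + "\n")

    def write_counts(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "transfection\tcondition\ttotal\tblue\twhite\twhite_deleted\t"
                "white_undeleted\n"
            )
            for t in self.transfections:
                fh.write(
                    f"{t.transfection_id}\t{t.condition}\t{t.total_colonies}\t"
                    f"{t.n_blue}\t{t.n_white}\t{t.n_white_deleted}\t"
                    f"{t.n_white_undeleted}\n"
                )

    def write_event_log(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "clone_id\tcondition\ttemplate_strand\tfate\texposure_start\t"
                "exposure_len\tdeaminations\n"
            )
            for clone_id, ev in self.events.items():
                deams = ";".join(f"{p}:{b}" for p, b in ev.deaminations)
                fh.write(
                    f"{clone_id}\t{ev.condition}\t{ev.template_strand}\t{ev.fate}\t"
                    f"{ev.exposure[0]}\t{ev.exposure[1]}\t{deams}\n"
                )


# ---------------------------------------------------------------------------
# strand indexing (cached per sequence: C positions and their TpC status)

@lru_cache(maxsize=8)
def _strand_index(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Sorted C positions on ``seq`` and whether each has a circular 5' T."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    cpos = np.flatnonzero(arr == b"C")
    five = arr[(cpos - 1) % len(seq)]
    return cpos, five == b"T"


def _candidates_in_exposure(
    seq: str, exposure: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Template C positions (and TpC flags) inside a circular window."""
    n = len(seq)
    cpos, is_tpc = _strand_index(seq)
    start, span = exposure
    if span >= n:
        return cpos, is_tpc
    start %= n
    end = start + span
    if end <= n:
        lo, hi = np.searchsorted(cpos, [start, end])
        sel = slice(lo, hi)
        return cpos[sel], is_tpc[sel]
    hi1 = np.searchsorted(cpos, n, side="left")
    lo1 = np.searchsorted(cpos, start)
    hi2 = np.searchsorted(cpos, end - n)
    idx = np.concatenate([np.arange(lo1, hi1), np.arange(0, hi2)])
    return cpos[idx], is_tpc[idx]


def _other(strand: str) -> str:
    return "bottom" if strand == "top" else "top"


def _anchor_position(lesion: LesionSpec) -> int:
    """5'-most lesion position on the lesion strand (the BER nick anchor)."""
    if lesion.strand == "top":
        return min(lesion.lesion_positions)
    return max(lesion.lesion_positions)


def _exposure_window(
    anchor_lesion_coord: int, template_is_lesion_strand: bool, span: int, n: int
) -> tuple[int, int]:
    """Template-strand window covering the ``span`` nt 5' of the lesion on
    the lesion-carrying strand (circular coordinates).

    The physical span is always [anchor - span, anchor) in lesion-strand
    coordinates; it is expressed on whichever strand serves as template.
    """
    span = min(span, n)
    if template_is_lesion_strand:
        return ((anchor_lesion_coord - span) % n, span)
    return ((n - anchor_lesion_coord) % n, span)


def _barcode_template_positions(
    reference: ReporterReference, template_strand: str
) -> frozenset[int]:
    b_start, b_end = reference.regions["barcode"]
    n = reference.length
    if template_strand == "top":
        return frozenset(range(b_start, b_end))
    return frozenset(n - 1 - p for p in range(b_start, b_end))


def _draw_cluster_size(pmf: Mapping[int, float], rng: np.random.Generator) -> int:
    sizes = sorted(pmf)
    probs = np.array([pmf[s] for s in sizes])
    return int(rng.choice(sizes, p=probs / probs.sum()))


def _draw_outcome(params: SimParams, rng: np.random.Generator) -> str:
    if rng.random() < params.p_transition:
        return "T"
    return "G" if rng.random() < 0.5 else "A"


def _place_deaminations(
    template_seq: str,
    exposure: tuple[int, int],
    excluded: frozenset[int],
    count: int,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[tuple[int, str], ...]:
    cpos, is_tpc = _candidates_in_exposure(template_seq, exposure)
    if excluded:
        keep = ~np.isin(cpos, list(excluded))
        cpos, is_tpc = cpos[keep], is_tpc[keep]
    tpc = list(cpos[is_tpc])
    non_tpc = list(cpos[~is_tpc])
    had_tpc, had_non_tpc = bool(tpc), bool(non_tpc)
    deaminations: list[tuple[int, str]] = []
    for _ in range(count):
        if not tpc and not non_tpc:
            logger.debug("no template C available in exposure window")
            break
        want_tpc = rng.random() < params.p_five_prime_T
        pool = tpc if want_tpc else non_tpc
        if not pool:
            # the window never exposed this context class: deaminate any C;
            # exhausted mid-event: the deamination is simply not realized
            had_any = had_tpc if want_tpc else had_non_tpc
            if had_any:
                continue
            logger.debug("no %s context exposed; falling back to any C",
                         "TpC" if want_tpc else "non-TpC")
            pool = non_tpc if want_tpc else tpc
        pos = pool.pop(int(rng.integers(len(pool))))
        deaminations.append((int(pos), _draw_outcome(params, rng)))
    return tuple(sorted(deaminations))


def simulate_repair_event(
    lesion: LesionSpec,
    params: SimParams,
    rng: np.random.Generator,
    reference: ReporterReference,
    condition: str | None = None,
) -> RepairEvent:
    """Simulate the repair of one introduced lesion.

    Template choice sets the fate (G-strand template restores C/G; the
    T-strand template of a T/G converts it to T/A), the exposure window is
    drawn 5' of the lesion per mechanism, and APOBEC deaminations are placed
    on exposed template cytosines with the configured TpC preference.
    """
    if lesion.lesion_type == "none":
        raise ValueError("0 MM condition: use simulate_random_nick_event")
    if condition is None:
        condition = f"{lesion.lesion_type}_{lesion.strand}"
    n = reference.length

    if lesion.lesion_type == "TG":
        restored = rng.random() < params.tg_template_choice
        fate = "restored" if restored else "converted"
    elif lesion.lesion_type == "SSB":
        fate = "none"
        restored = True
    else:
        restored = rng.random() < params.restore_prob.get(lesion.lesion_type, 1.0)
        fate = "restored" if restored else "converted"

    # restored events use the G strand (opposite the lesion) as template;
    # converted events the lesion strand itself
    template_strand = _other(lesion.strand) if restored else lesion.strand

    mechanism = params.mechanism_for(condition, lesion.lesion_type)
    anchor_top = _anchor_position(lesion)
    anchor = anchor_top if lesion.strand == "top" else n - 1 - anchor_top
    if mechanism == "dloop":
        exposure = (0, n)
    elif mechanism == "ssbr":
        exposure = (0, 0)  # distal SSBs are handled non-mutagenically
    else:
        span = int(rng.geometric(1.0 / params.exposure_len_mean))
        exposure = _exposure_window(
            anchor, template_strand == lesion.strand, span, n
        )

    deaminations: tuple[tuple[int, str], ...] = ()
    if exposure[1] > 0:
        # lesion base pairs never double as deamination targets; the bar-code
        # slot is regenerated per clone, so hits there are unobservable
        excluded = frozenset(
            p if template_strand == "top" else n - 1 - p
            for p in lesion.lesion_positions
        ) | _barcode_template_positions(reference, template_strand)
        count = _draw_cluster_size(params.cluster_size_pmf, rng)
        deaminations = _place_deaminations(
            reference.strand_sequence(template_strand),
            exposure,
            excluded,
            count,
            params,
            rng,
        )

    return RepairEvent(
        condition=condition,
        lesion=lesion,
        template_strand=template_strand,
        fate=fate,
        exposure=exposure,
        deaminations=deaminations,
    )


def simulate_random_nick_event(
    params: SimParams,
    reference: ReporterReference,
    rng: np.random.Generator,
    strand: str | None = None,
    condition: str = "noMM",
) -> RepairEvent:
    """Repair of a spontaneous nick on a random strand/position (0 MM control).

    Downstream processing is identical to BER/MMR-driven exposure, so over
    many events G- and C-readout mutations arise in equal proportion.
    """
    if strand is None:
        strand = "top" if rng.random() < 0.5 else "bottom"
    n = reference.length
    nick_top = int(rng.integers(n))
    nick = LesionSpec(
        oligo_id="random_nick",
        lesion_type="SSB",
        strand=strand,
        lesion_positions=(nick_top,),
    )
    template_strand = _other(strand)
    span = int(rng.geometric(1.0 / params.exposure_len_mean))
    nick_on_strand = nick_top if strand == "top" else n - 1 - nick_top
    exposure = _exposure_window(nick_on_strand, False, span, n)
    deaminations = _place_deaminations(
        reference.strand_sequence(template_strand),
        exposure,
        _barcode_template_positions(reference, template_strand),
        _draw_cluster_size(params.cluster_size_pmf, rng),
        params,
        rng,
    )
    return RepairEvent(
        condition=condition,
        lesion=nick,
        template_strand=template_strand,
        fate="none",
        exposure=exposure,
        deaminations=deaminations,
    )


_BASES = "ACGT"


def random_barcode(rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, 8))


def event_substitutions(
    event: RepairEvent, reference: ReporterReference
) -> list[tuple[int, str, str]]:
    """Top-strand readout ``(position, ref, alt)`` of an event's deaminations."""
    subs = []
    for template_pos, outcome in event.deaminations:
        subs.append(
            map_readout(template_pos, event.template_strand, "C", outcome, reference)
        )
    return sorted(subs)


def realize_clone(
    event: RepairEvent,
    reference: ReporterReference,
    rng: np.random.Generator,
    clone_id: str = "clone",
    transfection_id: str = "tx",
    params: SimParams | None = None,
) -> CloneRecord:
    """Construct the mutant top-strand episome sequence for one event.

    Writes the lesion fate at the lesion site(s), maps every deamination to
    top-strand readout, and installs a fresh random bar code.  The clone is
    white iff at least one substitution falls in the promoter or supF region
    (reporter-inactivation simplification).
    """
    seq = list(reference.top_sequence)
    if event.fate == "converted":
        converted = event.lesion.converted_top_base()
        for pos in event.lesion.lesion_positions:
            seq[pos] = converted
    subs = event_substitutions(event, reference)
    for pos, _ref, alt in subs:
        seq[pos] = alt

    barcode = random_barcode(rng)
    b_start, b_end = reference.regions["barcode"]
    seq[b_start:b_end] = list(barcode)

    p_start, p_end = reference.regions["promoter"]
    s_start, s_end = reference.regions["supf"]
    white = any(
        p_start <= pos < p_end or s_start <= pos < s_end for pos, _r, _a in subs
    )
    return CloneRecord(
        clone_id=clone_id,
        transfection_id=transfection_id,
        condition=event.condition,
        barcode=barcode,
        sequence="".join(seq),
        color="white" if white else "blue",
        clone_class="ok",
    )


def _inject_small_indel(
    sequence: str, reference: ReporterReference, rng: np.random.Generator
) -> str:
    """Insert or delete 1-3 nt at a random reporter-region position."""
    p_start, _ = reference.regions["promoter"]
    _, mm_end = reference.regions["mm_region"]
    pos = int(rng.integers(p_start, mm_end))
    size = int(rng.integers(1, 4))
    if rng.random() < 0.5:
        return sequence[:pos] + sequence[pos + size :]
    insert = "".join(_BASES[i] for i in rng.integers(0, 4, size))
    return sequence[:pos] + insert + sequence[pos:]


def _deleted_clone_sequence(
    reference: ReporterReference, barcode: str
) -> str:
    """Episome missing the entire supF region (a reporter deletion)."""
    seq = list(reference.top_sequence)
    b_start, b_end = reference.regions["barcode"]
    seq[b_start:b_end] = list(barcode)
    s_start, s_end = reference.regions["supf"]
    return "".join(seq[:s_start] + seq[s_end:])


def _draw_white_event(
    condition: str,
    lesion: LesionSpec,
    reference: ReporterReference,
    params: SimParams,
    rng: np.random.Generator,
    clone_id: str,
    transfection_id: str,
    max_tries: int = 100_000,
) -> tuple[RepairEvent, CloneRecord]:
    mechanism = params.mechanism_for(condition, lesion.lesion_type)
    background = lesion.lesion_type == "none" or mechanism == "ssbr"
    p_start, p_end = reference.regions["promoter"]
    s_start, s_end = reference.regions["supf"]
    for _ in range(max_tries):
        if background:
            event = simulate_random_nick_event(
                params, reference, rng, condition=condition
            )
        else:
            event = simulate_repair_event(
                lesion, params, rng, reference, condition=condition
            )
        # cheap whiteness check before building the full clone sequence
        white = any(
            p_start <= pos < p_end or s_start <= pos < s_end
            for pos, _r, _a in event_substitutions(event, reference)
        )
        if not white:
            continue
        clone = realize_clone(
            event, reference, rng, clone_id=clone_id,
            transfection_id=transfection_id, params=params,
        )
        return event, clone
    raise RuntimeError(
        f"condition {condition}: no white clone in {max_tries} event draws"
    )


def simulate_transfection(
    condition: str,
    n_colonies: int,
    lesion: LesionSpec,
    reference: ReporterReference,
    params: SimParams,
    rng: np.random.Generator,
    transfection_id: str = "tx1",
) -> ColonyDataset:
    """Simulate one transfection's blue/white screen and sequenced clones.

    Each colony independently yields a white undeleted mutated episome with
    the condition's calibrated probability; reporter-deleted white colonies
    are added so they make up ``deletion_rate`` of whites, and
    ``indel_rate`` of sequenced undeleted clones carry small indels.
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    if condition not in params.per_colony_mut_prob:
        raise ValueError(
            f"unknown condition {condition!r}; known: "
            f"{sorted(params.per_colony_mut_prob)}"
        )
    p = params.per_colony_mut_prob[condition]
    n_mutated = int(rng.binomial(n_colonies, p))
    p_del = (
        p * params.deletion_rate / (1.0 - params.deletion_rate)
        if params.deletion_rate < 1.0
        else 0.0
    )
    n_deleted = int(rng.binomial(n_colonies, p_del))
    n_white = n_mutated + n_deleted

    dataset = ColonyDataset()
    dataset.transfections.append(
        TransfectionCounts(
            transfection_id=transfection_id,
            condition=condition,
            total_colonies=n_colonies,
            n_blue=n_colonies - n_white,
            n_white=n_white,
            n_white_deleted=n_deleted,
        )
    )
    for i in range(n_mutated):
        clone_id = f"{transfection_id}.c{i:05d}"
        event, clone = _draw_white_event(
            condition, lesion, reference, params, rng, clone_id, transfection_id
        )
        if rng.random() < params.indel_rate:
            clone.clone_class = "small_indel"
            clone.sequence = _inject_small_indel(clone.sequence, reference, rng)
        dataset.clones.append(clone)
        dataset.events[clone_id] = event
    for i in range(n_deleted):
        barcode = random_barcode(rng)
        dataset.clones.append(
            CloneRecord(
                clone_id=f"{transfection_id}.d{i:05d}",
                transfection_id=transfection_id,
                condition=condition,
                barcode=barcode,
                sequence=_deleted_clone_sequence(reference, barcode),
                color="white",
                clone_class="deleted",
            )
        )
    return dataset


def transfection_rng(seed: int, transfection_id: str) -> np.random.Generator:
    """Reproducible, order-independent substream for one transfection.

    Derived by stable hashing (CRC-32) of the transfection id mixed into a
    seed sequence with the master seed.
    """
    key = zlib.crc32(transfection_id.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def simulate_experiment(
    conditions: Sequence[str],
    lesions: Mapping[str, LesionSpec],
    reference: ReporterReference,
    params: SimParams,
    n_transfections: int = 2,
    n_colonies: int = 50_000,
) -> ColonyDataset:
    """Simulate a full multi-condition, multi-transfection experiment."""
    dataset = ColonyDataset()
    for condition in conditions:
        if condition not in lesions:
            raise ValueError(
                f"no lesion specification for condition {condition!r}"
            )
        for t in range(n_transfections):
            tid = f"{condition}.t{t + 1:02d}"
            rng = transfection_rng(params.seed, tid)
            dataset.extend(
                simulate_transfection(
                    condition,
                    n_colonies,
                    lesions[condition],
                    reference,
                    params,
                    rng,
                    transfection_id=tid,
                )
            )
    return dataset
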
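"""Default synthetic episome and lesion catalog.

The study system is a circular SV40-based shuttle vector carrying a supF
reporter cassette (promoter + supF tRNA gene), a mismatch (MM) region
immediately 3' of the reporter into which defined mispairs are ligated, and
an 8-bp random bar code between fixed flanking octamers.  The MM-region top
strand and the bar-code flanks used here are the assay's actual
oligonucleotide sequences; the promoter, supF and backbone spans are deterministic synthetic
stand-ins (the assay only requires their base composition and layout, not
their biological identity).

Layout (top-strand coordinates, 0-based half-open), mirroring the FM1
geometry in which top-strand lesions sit <50 bp from the cis 3' end of the
reporter while bottom-strand lesions face the ~5 kb way around the circle:

    promoter [100,160) - supf [160,245) - mm_region [245,298)
    - GAGCTCTA [298,306) - barcode [306,314) - TACGTACG [314,322)
    - backbone [322,5000)
"""

from __future__ import annotations

import numpy as np

from .reference import LesionSpec, ReporterReference

__all__ = [
    "MM1_TOP",
    "BARCODE_FLANK_5",
    "BARCODE_FLANK_3",
    "default_reference",
    "default_lesion_catalog",
    "write_reference_files",
    "write_lesion_table",
]

#: MM1 duplex top strand (53 bp) as synthesized for the assay, overhangs removed
MM1_TOP = "CCTCCTCAGCTGACGTCGGACGGAGGCGGCGGAACCTAGGTACCTCAGCCCGA"
#: fixed octamers flanking the 8-bp random bar code
BARCODE_FLANK_5 = "GAGCTCTA"
BARCODE_FLANK_3 = "TACGTACG"

_EPISOME_LENGTH = 5000
_LAYOUT = {
    "promoter": (100, 160),
    "supf": (160, 245),
    "mm_region": (245, 298),
    "barcode": (306, 314),
    "backbone": (322, 5000),
}
_FLANK5_SPAN = (298, 306)
_FLANK3_SPAN = (314, 322)
#: placeholder bar code in the reference (clones carry fresh random ones)
_REFERENCE_BARCODE = "ACTGGTCA"
#: fixed construction seed -- the reference is a constant of the study design
_CONSTRUCTION_SEED = 20140429

_BASES = np.array(list("ACGT"))


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def default_reference() -> ReporterReference:
    """Build the default synthetic FM1-like episome (deterministic)."""
    rng = np.random.default_rng(_CONSTRUCTION_SEED)
    seq = list(_BASES[rng.integers(0, 4, _EPISOME_LENGTH)])

    def write(start: int, fragment: str) -> None:
        seq[start : start + len(fragment)] = list(fragment)

    mm_start = _LAYOUT["mm_region"][0]
    write(mm_start, MM1_TOP)
    write(_FLANK5_SPAN[0], BARCODE_FLANK_5)
    write(_LAYOUT["barcode"][0], _REFERENCE_BARCODE)
    write(_FLANK3_SPAN[0], BARCODE_FLANK_3)

    # the bar-code flanks must occur exactly once so extraction is unambiguous
    top = "".join(seq)
    for flank, span in ((BARCODE_FLANK_5, _FLANK5_SPAN), (BARCODE_FLANK_3, _FLANK3_SPAN)):
        for hit in _find_all(top, flank):
            if hit != span[0]:
                middle = hit + len(flank) // 2
                current = seq[middle]
                seq[middle] = "A" if current != "A" else "C"
        top = "".join(seq)

    return ReporterReference(name="FM1syn", top_sequence=top, regions=dict(_LAYOUT))


def default_lesion_catalog() -> dict[str, LesionSpec]:
    """Condition name -> lesion specification for the default episome.

    Top-strand base lesions occupy the two AatII-site cytosines of MM1
    (offsets 13 and 16 in the duplex); bottom-strand lesions the guanine
    pair partners at offsets 11 and 14.  Oligo ids follow the assay's
    oligonucleotide numbering where a direct counterpart exists.
    """
    mm = _LAYOUT["mm_region"][0]
    top_c = (mm + 13, mm + 16)
    top_g = (mm + 11, mm + 14)
    return {
        "TG_top": LesionSpec("6", "TG", "top", top_c),
        "hmUG_top": LesionSpec("19", "hmUG", "top", top_c),
        "UG_top": LesionSpec("9", "UG", "top", top_c),
        "abG_top": LesionSpec("16", "abG", "top", (mm + 13,)),
        "TG_bottom": LesionSpec("6b", "TG", "bottom", top_g),
        "UG_bottom": LesionSpec("9b", "UG", "bottom", top_g),
        "SSB_near": LesionSpec("ssb_t", "SSB", "top", (mm + 13,)),
        "SSB_far": LesionSpec("ssb_b", "SSB", "bottom", (mm + 13,)),
        "noMM": LesionSpec("0MM", "none", "top"),
    }


def write_reference_files(fasta_path, bed_path) -> None:
    """Serialize the default reference as FASTA + BED."""
    ref = default_reference()
    with open(fasta_path, "w") as fh:
        fh.write(f">{ref.name} synthetic shuttle-vector episome\n")
        for i in range(0, ref.length, 70):
            fh.write(ref.top_sequence[i : i + 70] + "\n")
    with open(bed_path, "w") as fh:
        for name, (start, end) in ref.regions.items():
            fh.write(f"{ref.name}\t{start}\t{end}\t{name}\n")


def write_lesion_table(path) -> None:
    """Serialize the default lesion catalog as TSV."""
    with open(path, "w") as fh:
        fh.write("condition\toligo_id\tlesion_type\tstrand\tpositions\treference_pair\n")
        for condition, lesion in default_lesion_catalog().items():
            positions = ";".join(str(p) for p in lesion.lesion_positions)
            fh.write(
                f"{condition}\t{lesion.oligo_id}\t{lesion.lesion_type}\t"
                f"{lesion.strand}\t{positions}\t{lesion.reference_pair}\n"
            )
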
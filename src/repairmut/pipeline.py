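"""End-to-end orchestration: simulate -> call -> fate -> spectra -> frequencies.

A single :class:`RunConfig` (YAML-loadable) drives either a simulated
experiment or analysis of observed clone FASTA + colony-count tables.  All
randomness flows from the config seed; identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import calling, episome, fates, freqstats, spectra
from .reference import ReporterReference, LesionSpec, load_lesion_table, load_reference
from .simulate import (
    CloneRecord,
    ColonyDataset,
    SimParams,
    TransfectionCounts,
    simulate_experiment,
)

__all__ = ["RunConfig", "AnalysisResult", "analyze_dataset", "run_pipeline"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``simulate`` (condition list etc.) or ``observed``
    (clones_fasta + counts_tsv paths) must be active.
    """

    out_dir: str = "repairmut_out"
    seed: int = 0
    reference_fasta: str | None = None  # None -> built-in synthetic episome
    regions_bed: str | None = None
    lesion_table: str | None = None  # None -> built-in catalog
    simulate: dict | None = None  # conditions, n_colonies, n_transfections, params
    observed: dict | None = None  # clones_fasta, counts_tsv
    control_condition: str = "noMM"
    kmer_ks: tuple[int, ...] = (2,)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.observed is None):
            raise ValueError("exactly one of simulate/observed must be configured")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "kmer_ks" in raw:
            raw["kmer_ks"] = tuple(raw["kmer_ks"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_inputs(
    config: RunConfig,
) -> tuple[ReporterReference, dict[str, LesionSpec]]:
    if config.reference_fasta:
        reference = load_reference(config.reference_fasta, config.regions_bed)
    else:
        reference = episome.default_reference()
    if config.lesion_table:
        lesions = {}
        with open(config.lesion_table) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        if "condition" in header:
            # condition-keyed table (the format write_lesion_table emits)
            table = pd.read_csv(config.lesion_table, sep="\t", dtype=str).fillna("")
            for _, row in table.iterrows():
                positions = tuple(
                    int(p) for p in str(row["positions"]).split(";") if p
                )
                lesions[row["condition"]] = LesionSpec(
                    oligo_id=row["oligo_id"],
                    lesion_type=row["lesion_type"],
                    strand=row["strand"],
                    lesion_positions=positions,
                    reference_pair=row.get("reference_pair", "C/G") or "C/G",
                )
        else:
            for spec in load_lesion_table(config.lesion_table):
                lesions[f"{spec.lesion_type}_{spec.strand}"] = spec
    else:
        lesions = episome.default_lesion_catalog()
    for condition, lesion in lesions.items():
        if lesion.lesion_positions:
            lesion.validate_against(reference)
    return reference, lesions


@dataclass
class AnalysisResult:
    """Everything the analysis stages compute from one dataset."""

    mutation_table: pd.DataFrame
    fate_table: pd.DataFrame
    frequency_results: dict[str, freqstats.FrequencyResult]
    comparisons: list[dict]
    spectrum_tables: dict[str, spectra.SpectrumTable]
    kmer_tables: dict[str, dict]  # condition -> {"five_prime": KmerTable, ...}
    cluster: spectra.ClusterPartition
    n_clones: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict:
        conditions = {}
        for condition, result in sorted(self.frequency_results.items()):
            conditions[condition] = {
                "mean_pct_frequency": result.mean,
                "sem": None if pd.isna(result.sem) else result.sem,
                "n_transfections": len(result.frequencies),
            }
        fate = {
            f"{row.lesion_type}_{row.strand}": {
                "n_lesions": int(row.n_lesions),
                "pct_restored": row.pct_restored,
                "pct_converted": row.pct_converted,
                "pct_other": row.pct_other,
            }
            for row in self.fate_table.itertuples()
        }
        context = {}
        for condition, tables in sorted(self.kmer_tables.items()):
            three = tables.get("three_prime")
            if three is not None and three.n:
                g_total = sum(
                    f for kmer, f in three.fractions.items() if kmer[0] == "G"
                )
                context[condition] = {
                    "n_context_mutations": three.n,
                    "gpa_fraction_of_g": (
                        three.get("GA") / g_total if g_total else None
                    ),
                }
        return {
            "schema_version": SCHEMA_VERSION,
            "conditions": conditions,
            "fates": fate,
            "comparisons": self.comparisons,
            "cluster": {
                "n_clustered": self.cluster.n_clustered,
                "n_unclustered": self.cluster.n_unclustered,
                "fraction_clustered": self.cluster.fraction_clustered,
            },
            "context": context,
            "n_clones": self.n_clones,
        }


def analyze_dataset(
    dataset: ColonyDataset,
    reference: ReporterReference,
    lesions: Mapping[str, LesionSpec],
    control_condition: str = "noMM",
    kmer_ks: Sequence[int] = (2,),
) -> AnalysisResult:
    """Run calling, fate, spectrum, cluster and frequency stages on a dataset."""
    if not dataset.clones and not dataset.transfections:
        raise ValueError("no clones in dataset")

    # --- triage + calling -------------------------------------------------
    ok_clones: list[CloneRecord] = []
    n_by_class = {"ok": 0, "small_indel": 0, "deleted": 0}
    for clone in dataset.clones:
        cls = calling.classify_clone(clone.sequence, reference)
        n_by_class[cls] += 1
        if cls == "ok":
            ok_clones.append(clone)
    mutations_by_clone = {
        clone.clone_id: calling.call_mutations(
            clone.sequence,
            reference,
            lesions.get(clone.condition),
            clone_id=clone.clone_id,
        )
        for clone in ok_clones
    }
    ok_clones = calling.dedupe_clones(ok_clones, mutations_by_clone)
    clones_by_id = {c.clone_id: c for c in ok_clones}
    mutations_by_clone = {c.clone_id: mutations_by_clone[c.clone_id] for c in ok_clones}
    all_mutations = [m for records in mutations_by_clone.values() for m in records]

    # --- fates ------------------------------------------------------------
    fate_rows = []
    for clone in ok_clones:
        lesion = lesions.get(clone.condition)
        if lesion is None or not lesion.is_base_lesion:
            continue
        for fate in fates.classify_fate(clone.sequence, lesion, reference).values():
            fate_rows.append((lesion.lesion_type, lesion.strand, fate))
    fate_table = fates.fate_summary(fate_rows)

    # --- frequencies ------------------------------------------------------
    counts_by_condition: dict[str, list[TransfectionCounts]] = {}
    for t in dataset.transfections:
        counts_by_condition.setdefault(t.condition, []).append(t)
    frequency_results = {
        condition: freqstats.FrequencyResult.from_counts(
            condition,
            [(t.n_white_undeleted, t.total_colonies) for t in counts],
        )
        for condition, counts in counts_by_condition.items()
    }
    comparisons = []
    control = frequency_results.get(control_condition)
    if control is not None:
        lesion_conditions = [
            c for c in sorted(frequency_results) if c != control_condition
        ]
        family = max(1, len(lesion_conditions))
        pooled = {
            condition: (
                sum(t.n_white_undeleted for t in counts),
                sum(t.total_colonies for t in counts),
            )
            for condition, counts in counts_by_condition.items()
        }
        for condition in lesion_conditions:
            comparisons.append(
                frequency_results[condition].compare(
                    control, pooled[condition], pooled[control_condition],
                    family_size=family,
                )
            )

    # --- spectra / contexts / clusters ------------------------------------
    mutations_by_condition: dict[str, list] = {}
    sequences_by_condition: dict[str, int] = {}
    for clone in ok_clones:
        mutations_by_condition.setdefault(clone.condition, []).extend(
            mutations_by_clone[clone.clone_id]
        )
        sequences_by_condition[clone.condition] = (
            sequences_by_condition.get(clone.condition, 0) + 1
        )
    spectrum_tables = {
        condition: spectra.per_base_spectrum(
            records, reference, n_sequences=sequences_by_condition[condition]
        )
        for condition, records in mutations_by_condition.items()
    }
    kmer_tables: dict[str, dict] = {}
    for condition, records in mutations_by_condition.items():
        tables: dict = {}
        for k in kmer_ks:
            for side in ("five_prime", "three_prime"):
                key = side if k == 2 else f"k{k}_{side}"
                tables[key] = spectra.kmer_context_spectrum(
                    records, reference, k=k, side=side
                )
        kmer_tables[condition] = tables
    cluster = spectra.cluster_partition(mutations_by_clone)

    return AnalysisResult(
        mutation_table=calling.mutation_table(all_mutations, clones_by_id),
        fate_table=fate_table,
        frequency_results=frequency_results,
        comparisons=comparisons,
        spectrum_tables=spectrum_tables,
        kmer_tables=kmer_tables,
        cluster=cluster,
        n_clones=n_by_class,
    )


def _load_observed(config: RunConfig) -> ColonyDataset:
    observed = config.observed or {}
    clones = calling.parse_clone_fasta(observed["clones_fasta"])
    if not clones:
        raise ValueError("no clones in observed input")
    dataset = ColonyDataset(clones=clones)
    counts_path = observed.get("counts_tsv")
    if counts_path:
        table = pd.read_csv(counts_path, sep="\t")
        for row in table.itertuples():
            dataset.transfections.append(
                TransfectionCounts(
                    transfection_id=str(row.transfection),
                    condition=str(row.condition),
                    total_colonies=int(row.total),
                    n_blue=int(row.blue),
                    n_white=int(row.white),
                    n_white_deleted=int(row.white_deleted),
                )
            )
    return dataset


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run and write the report bundle.

    Writes clones/counts (simulated runs), the mutation table, fate table,
    spectrum and k-mer tables, frequency results and a machine-readable
    ``summary.json``; returns the summary dict.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, lesions = _load_inputs(config)

    if config.simulate is not None:
        sim = dict(config.simulate)
        params_kwargs = sim.get("params") or {}
        params = SimParams(seed=config.seed, **params_kwargs)
        conditions = sim.get("conditions") or list(lesions)
        dataset = simulate_experiment(
            conditions,
            lesions,
            reference,
            params,
            n_transfections=int(sim.get("n_transfections", 2)),
            n_colonies=int(sim.get("n_colonies", 50_000)),
        )
        dataset.write_fasta(out / "clones.fasta")
        dataset.write_counts(out / "counts.tsv")
        dataset.write_event_log(out / "events.tsv")
    else:
        dataset = _load_observed(config)

    logger.info("dataset ready (%.1fs): %d clones", time.time() - t0, len(dataset.clones))
    result = analyze_dataset(
        dataset,
        reference,
        lesions,
        control_condition=config.control_condition,
        kmer_ks=config.kmer_ks,
    )

    header = f"# repairmut config_hash={config.config_hash()} seed={config.seed}\n"
    with open(out / "mutations.tsv", "w") as fh:
        fh.write(header)
        result.mutation_table.to_csv(fh, sep="\t", index=False)
    with open(out / "fates.tsv", "w") as fh:
        fh.write(header)
        result.fate_table.to_csv(fh, sep="\t", index=False)
    freq_rows = []
    for condition, res in sorted(result.frequency_results.items()):
        freq_rows.append(
            {
                "condition": condition,
                "mean_pct": res.mean,
                "sem": res.sem,
                "n_transfections": len(res.frequencies),
            }
        )
    with open(out / "frequencies.tsv", "w") as fh:
        fh.write(header)
        pd.DataFrame(freq_rows).to_csv(fh, sep="\t", index=False)
    for condition, table in result.spectrum_tables.items():
        path = out / f"spectrum_{condition}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            table.table.to_csv(fh, sep="\t", index=False)
    kmer_rows = []
    for condition, tables in result.kmer_tables.items():
        for side, table in tables.items():
            for kmer, fraction in sorted(table.fractions.items()):
                kmer_rows.append(
                    {
                        "condition": condition,
                        "side": side,
                        "kmer": kmer,
                        "fraction": fraction,
                        "n": table.n,
                    }
                )
    with open(out / "kmer_contexts.tsv", "w") as fh:
        fh.write(header)
        pd.DataFrame(
            kmer_rows, columns=["condition", "side", "kmer", "fraction", "n"]
        ).to_csv(fh, sep="\t", index=False)

    summary = result.summary()
    summary["config_hash"] = config.config_hash()
    summary["seed"] = config.seed
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline done in %.1fs -> %s", time.time() - t0, out)
    return summary
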
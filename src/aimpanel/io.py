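"""Readers, writers and run configuration.

The genotyper CSV dialect used throughout is:

    Sample,Marker,Reads_A,Reads_C,Reads_G,Reads_T,Genotype

with ``Genotype`` a two-letter nucleotide pair or ``NN``. Unknown columns are
preserved on each record as opaque metadata. Malformed rows are collected
into an error report instead of aborting the whole file.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .qc import GenotypeCall, ReadCountRecord, genotype_str

GENOTYPER_COLUMNS = ("Sample", "Marker", "Reads_A", "Reads_C", "Reads_G", "Reads_T", "Genotype")
_OPTIONAL_COLUMNS = ("True_Genotype",)


@dataclass(frozen=True)
class PanelDefinition:
    """One marker's panel metadata; positions are 1-based and informational only."""

    marker: str
    chromosome: str
    position: int
    alleles: tuple[str, str]
    panel: str
    amplicon_length: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be positive for {self.marker}")
        if len(set(self.alleles)) != 2:
            raise ValidationError(f"alleles of {self.marker} must be two distinct nucleotides")
        if self.amplicon_length < 1:
            raise ValidationError(f"amplicon length must be positive for {self.marker}")


def read_panel_tsv(path: str | Path) -> list[PanelDefinition]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker", "chromosome", "position", "allele1", "allele2", "panel", "amplicon_length"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"panel file missing columns: {sorted(missing)}")
    definitions = []
    seen: set[tuple[str, str]] = set()
    for row in frame.itertuples(index=False):
        key = (row.panel, row.marker)
        if key in seen:
            raise FormatError(f"duplicate marker {row.marker} within panel {row.panel}")
        seen.add(key)
        definitions.append(
            PanelDefinition(
                marker=row.marker,
                chromosome=row.chromosome,
                position=int(row.position),
                alleles=(row.allele1, row.allele2),
                panel=row.panel,
                amplicon_length=int(row.amplicon_length),
            )
        )
    return definitions


def write_panel_tsv(definitions: Sequence[PanelDefinition], path: str | Path) -> None:
    rows = [
        {
            "marker": d.marker,
            "chromosome": d.chromosome,
            "position": d.position,
            "allele1": d.alleles[0],
            "allele2": d.alleles[1],
            "panel": d.panel,
            "amplicon_length": d.amplicon_length,
        }
        for d in definitions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotyper_csv(path: str | Path) -> tuple[list[ReadCountRecord], list[dict]]:
    """Parse read-count records; returns (records, row-level error report)."""
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise FormatError(f"{path} is empty")
        missing = [c for c in GENOTYPER_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path} is missing mandatory columns: {missing}")
        known = set(GENOTYPER_COLUMNS) | set(_OPTIONAL_COLUMNS)
        extra_cols = [c for c in reader.fieldnames if c not in known]
        records: list[ReadCountRecord] = []
        errors: list[dict] = []
        n_rows = 0
        for line_no, row in enumerate(reader, start=2):
            n_rows += 1
            try:
                records.append(
                    ReadCountRecord(
                        sample=row["Sample"],
                        marker=row["Marker"],
                        reads_a=int(row["Reads_A"]),
                        reads_c=int(row["Reads_C"]),
                        reads_g=int(row["Reads_G"]),
                        reads_t=int(row["Reads_T"]),
                        called_genotype=None if row["Genotype"] == "NN" else row["Genotype"],
                        true_genotype=(
                            None
                            if row.get("True_Genotype") in (None, "", "NN")
                            else row["True_Genotype"]
                        ),
                        extra={c: row[c] for c in extra_cols},
                    )
                )
            except (ValueError, ValidationError) as exc:
                errors.append({"line": line_no, "row": dict(row), "error": str(exc)})
    if n_rows == 0:
        raise FormatError(f"{path} contains a header but no data rows")
    return records, errors


def write_genotyper_csv(
    records: Iterable[ReadCountRecord], path: str | Path, include_truth: bool = True
) -> None:
    path = Path(path)
    columns = list(GENOTYPER_COLUMNS) + (["True_Genotype"] if include_truth else [])
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for r in records:
            row = [
                r.sample,
                r.marker,
                r.reads_a,
                r.reads_c,
                r.reads_g,
                r.reads_t,
                genotype_str(r.called_genotype),
            ]
            if include_truth:
                row.append(genotype_str(r.true_genotype))
            writer.writerow(row)


def write_calls_tsv(calls: Sequence[GenotypeCall], path: str | Path) -> None:
    rows = [
        {
            "sample": c.sample,
            "marker": c.marker,
            "genotype": genotype_str(c.genotype),
            "depth": c.depth,
            "hb": "" if c.hb is None else f"{c.hb:.6g}",
            "noise": "" if c.noise is None else f"{c.noise:.6g}",
            "criteria_set": "" if c.criteria_set is None else c.criteria_set,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_qc_report(
    missingness: dict[str, float],
    acceptance_by_marker: dict[str, float],
    path: str | Path,
    extra: Optional[dict] = None,
) -> None:
    report = {
        "per_sample_missingness": missingness,
        "per_marker_acceptance_rate": acceptance_by_marker,
    }
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


@dataclass
class RunConfig:
    """End-to-end pipeline settings; the defaults reproduce the published
    thresholds (depth 45 / 20-44, Hb windows 0.3-3.0 and 0.7-1.3, 10%
    missingness, alpha 0.05, z gate 1.64, 1,000,000 Markov-chain steps)."""

    output_dir: str = "results"
    seed: int = 0

    # simulation scenario
    n_populations: int = 3
    n_markers: int = 60
    fst: float = 0.10
    n_individuals: int = 40
    depth_mean: float = 200.0
    depth_dispersion: float = 8.0
    allele_bias: float = 0.5
    error_rate: float = 0.0

    # QC thresholds
    min_depth_confident: int = 45
    moderate_depth_low: int = 20
    moderate_depth_high: int = 44
    hb_confident_low: float = 0.3
    hb_confident_high: float = 3.0
    hb_moderate_low: float = 0.7
    hb_moderate_high: float = 1.3
    max_missing: float = 0.10

    # statistics
    alpha: float = 0.05
    z_threshold: float = 1.64
    hwe_method: str = "enumeration"
    hwe_steps: int = 1_000_000
    ld_permutations: int = 199
    ld_bonferroni_family: str = "per_population"  # or "global"
    pseudocount: float = 0.5

    def to_file(self, path: str | Path) -> None:
        # output_dir is a runtime location, not an analysis setting; leaving
        # it out keeps serialised configs (and manifests) path-independent
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in fields(self)
            if f.name != "output_dir"
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name not in values:
                continue
            raw_value = values[f.name]
            if f.type == "int":
                kwargs[f.name] = int(raw_value)
            elif f.type == "float":
                kwargs[f.name] = float(raw_value)
            else:
                kwargs[f.name] = raw_value
        return cls(**kwargs)

    def as_dict(self) -> dict:
        return asdict(self)
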
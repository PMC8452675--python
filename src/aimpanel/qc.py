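"""Genotype-call quality control.

Turns per-nucleotide read counts into accepted genotype calls, computes the
heterozygote-balance and noise metrics, applies the sample-level missingness
filter and merges marker panels with an explicit duplicate-preference rule.

Acceptance rules (defaults):

* confident calls: depth >= 45 reads and, for heterozygotes,
  0.3 <= Hb <= 3.0 (criteria set 1);
* moderate-depth calls: depth 20-44, zero noise and, for heterozygotes,
  0.7 <= Hb <= 1.3 (criteria set 2);
* anything else is ``NN`` (no data).

Hb is the read count of the alphabetically first nucleotide of the called
genotype divided by the count of the other nucleotide; noise is the fraction
of reads showing a nucleotide absent from the called genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigurationError, ValidationError

NUCLEOTIDES = ("A", "C", "G", "T")

Genotype = tuple[str, str]


def normalize_genotype(genotype: Iterable[str] | str | None) -> Optional[Genotype]:
    """Return an unordered genotype as an alphabetically sorted pair.

    Accepts a two-character string (``"AG"``), a pair of nucleotides, or
    ``None``/``"NN"`` for a missing call.
    """
    if genotype is None:
        return None
    pair = tuple(genotype)
    if len(pair) != 2:
        raise ValidationError(f"genotype must have exactly two alleles, got {genotype!r}")
    if pair == ("N", "N"):
        return None
    for allele in pair:
        if allele not in NUCLEOTIDES:
            raise ValidationError(f"invalid nucleotide {allele!r} in genotype {genotype!r}")
    return tuple(sorted(pair))  # type: ignore[return-value]


def genotype_str(genotype: Optional[Genotype]) -> str:
    return "NN" if genotype is None else "".join(genotype)


@dataclass
class ReadCountRecord:
    """Per sample/locus read counts plus the upstream caller's genotype.

    ``true_genotype`` is optional simulator ground truth used to measure QC
    accuracy; ``extra`` carries unknown input columns as opaque metadata.
    """

    sample: str
    marker: str
    reads_a: int
    reads_c: int
    reads_g: int
    reads_t: int
    called_genotype: Optional[Genotype] = None
    true_genotype: Optional[Genotype] = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nuc in NUCLEOTIDES:
            if self.count(nuc) < 0:
                raise ValidationError(
                    f"negative read count for {nuc} at {self.sample}/{self.marker}"
                )
        self.called_genotype = normalize_genotype(self.called_genotype)
        self.true_genotype = normalize_genotype(self.true_genotype)

    def count(self, nucleotide: str) -> int:
        return {
            "A": self.reads_a,
            "C": self.reads_c,
            "G": self.reads_g,
            "T": self.reads_t,
        }[nucleotide]

    @property
    def depth(self) -> int:
        return self.reads_a + self.reads_c + self.reads_g + self.reads_t


@dataclass
class GenotypeCall:
    """QC decision for one record.

    ``genotype`` is ``None`` (NN) exactly when ``criteria_set`` is ``None``.
    ``hb`` is defined only for heterozygous called genotypes.
    """

    sample: str
    marker: str
    genotype: Optional[Genotype]
    depth: int
    hb: Optional[float]
    noise: Optional[float]
    criteria_set: Optional[int]

    def __post_init__(self) -> None:
        if (self.genotype is None) != (self.criteria_set is None):
            raise ValidationError("genotype is NN iff no acceptance criteria fired")


@dataclass
class AIMProfile:
    """One individual's genotype calls over a marker panel."""

    sample: str
    genotypes: dict[str, Optional[Genotype]]
    panel: dict[str, str] = field(default_factory=dict)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.genotypes)

    def missing_fraction(self) -> float:
        if not self.genotypes:
            raise ValidationError(f"profile {self.sample} has no markers")
        n_missing = sum(1 for g in self.genotypes.values() if g is None)
        return n_missing / len(self.genotypes)

    def n_called(self) -> int:
        return sum(1 for g in self.genotypes.values() if g is not None)


def heterozygote_balance(record: ReadCountRecord) -> Optional[float]:
    """Hb = reads of the alphabetically first genotype nucleotide / reads of the other.

    Returns ``None`` for homozygous or missing calls (not applicable) and
    ``math.inf`` when the second allele has zero reads, which fails every
    acceptance window downstream.
    """
    genotype = record.called_genotype
    if genotype is None or genotype[0] == genotype[1]:
        return None
    numerator = record.count(genotype[0])
    denominator = record.count(genotype[1])
    if denominator == 0:
        return math.inf
    return numerator / denominator


def noise_fraction(record: ReadCountRecord) -> float:
    """Fraction of reads showing a nucleotide absent from the called genotype."""
    if record.depth == 0:
        raise ValidationError(
            f"noise undefined at zero depth ({record.sample}/{record.marker})"
        )
    if record.called_genotype is None:
        raise ValidationError("noise requires a called genotype")
    on_target = sum(record.count(n) for n in set(record.called_genotype))
    return (record.depth - on_target) / record.depth


def apply_acceptance_criteria(
    record: ReadCountRecord,
    *,
    min_depth_confident: int = 45,
    moderate_depth: tuple[int, int] = (20, 44),
    hb_window_confident: tuple[float, float] = (0.3, 3.0),
    hb_window_moderate: tuple[float, float] = (0.7, 1.3),
) -> GenotypeCall:
    """Accept or reject the upstream genotype call; all bounds are inclusive.

    Failures of both criteria sets map to an NN call, never an exception.
    """
    genotype = record.called_genotype
    depth = record.depth
    if genotype is None or depth == 0:
        return GenotypeCall(record.sample, record.marker, None, depth, None, None, None)

    hb = heterozygote_balance(record)
    noise = noise_fraction(record)
    is_het = genotype[0] != genotype[1]

    def hb_ok(window: tuple[float, float]) -> bool:
        if not is_het:
            return True
        assert hb is not None
        return window[0] <= hb <= window[1]

    criteria: Optional[int] = None
    if depth >= min_depth_confident and hb_ok(hb_window_confident):
        criteria = 1
    elif moderate_depth[0] <= depth <= moderate_depth[1] and noise == 0 and hb_ok(
        hb_window_moderate
    ):
        criteria = 2

    if criteria is None:
        return GenotypeCall(record.sample, record.marker, None, depth, hb, noise, None)
    return GenotypeCall(record.sample, record.marker, genotype, depth, hb, noise, criteria)


def profiles_from_calls(
    calls: Iterable[GenotypeCall],
    panel_name: str = "panel",
    marker_order: Optional[Sequence[str]] = None,
) -> list[AIMProfile]:
    """Group per-locus calls into per-sample profiles over a common marker set."""
    by_sample: dict[str, dict[str, Optional[Genotype]]] = {}
    markers_seen: dict[str, None] = {}
    for call in calls:
        by_sample.setdefault(call.sample, {})[call.marker] = call.genotype
        markers_seen.setdefault(call.marker, None)
    markers = list(marker_order) if marker_order is not None else list(markers_seen)
    profiles = []
    for sample, genotypes in by_sample.items():
        full = {m: genotypes.get(m) for m in markers}
        profiles.append(
            AIMProfile(sample=sample, genotypes=full, panel={m: panel_name for m in markers})
        )
    return profiles


def filter_samples(
    profiles: Sequence[AIMProfile], max_missing: float = 0.10
) -> tuple[list[AIMProfile], list[AIMProfile], dict[str, float]]:
    """Split profiles into retained/excluded by missingness.

    A profile is excluded iff its missing fraction is strictly greater than
    ``max_missing``. The report maps sample -> missing fraction.
    """
    if not profiles:
        raise ValidationError("no profiles supplied to filter_samples")
    panel = set(profiles[0].markers)
    for profile in profiles:
        if set(profile.markers) != panel:
            raise ValidationError(
                f"profile {profile.sample} does not share the common marker panel"
            )
    report = {p.sample: p.missing_fraction() for p in profiles}
    retained = [p for p in profiles if report[p.sample] <= max_missing]
    excluded = [p for p in profiles if report[p.sample] > max_missing]
    return retained, excluded, report


def merge_panels(
    profiles_by_panel: Mapping[str, Sequence[AIMProfile]],
    preference: Mapping[str, str],
) -> list[AIMProfile]:
    """Merge per-panel profiles into combined profiles, one genotype per marker.

    Markers present in several panels must have an entry in ``preference``
    naming the panel whose call is kept (even if that call is NN). Provenance
    is recorded per marker in the combined profiles.
    """
    if not profiles_by_panel:
        raise ValidationError("no panels supplied")
    panel_markers: dict[str, set[str]] = {}
    panel_samples: dict[str, dict[str, AIMProfile]] = {}
    for panel, profiles in profiles_by_panel.items():
        if not profiles:
            raise ValidationError(f"panel {panel} has no profiles")
        markers = set(profiles[0].markers)
        for profile in profiles:
            if set(profile.markers) != markers:
                raise ValidationError(
                    f"profiles within panel {panel} disagree on the marker set"
                )
        panel_markers[panel] = markers
        panel_samples[panel] = {p.sample: p for p in profiles}

    sample_sets = [set(s) for s in panel_samples.values()]
    if any(s != sample_sets[0] for s in sample_sets[1:]):
        raise ValidationError("panels do not cover the same samples")

    marker_sources: dict[str, list[str]] = {}
    for panel in sorted(panel_markers):
        for marker in panel_markers[panel]:
            marker_sources.setdefault(marker, []).append(panel)

    source_of: dict[str, str] = {}
    for marker, panels in marker_sources.items():
        if len(panels) == 1:
            source_of[marker] = panels[0]
        else:
            chosen = preference.get(marker)
            if chosen is None:
                raise ConfigurationError(
                    f"marker {marker} duplicated across panels {panels} "
                    "but has no preference entry"
                )
            if chosen not in panels:
                raise ConfigurationError(
                    f"preference for {marker} names panel {chosen!r} "
                    f"which does not contain it (candidates: {panels})"
                )
            source_of[marker] = chosen

    marker_order = sorted(source_of)
    combined = []
    for sample in sorted(sample_sets[0]):
        genotypes = {
            m: panel_samples[source_of[m]][sample].genotypes[m] for m in marker_order
        }
        combined.append(
            AIMProfile(
                sample=sample,
                genotypes=genotypes,
                panel={m: source_of[m] for m in marker_order},
            )
        )
    return combined
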
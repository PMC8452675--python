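"""Synthetic multi-population data generator.

Produces reference allele frequencies under the Balding-Nichols model
(beta-distributed population frequencies around an ancestral value, with a
per-population FST), Hardy-Weinberg genotype profiles, two-way admixed
profiles, and an amplicon-style read-count layer with configurable depth,
heterozygote allele bias and per-read error rate.

All randomness flows from one root seed. Each operation draws from its own
substream, derived as ``default_rng([seed, stream_code])`` with the codes in
``_STREAMS``, so stages are reproducible independently of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .qc import AIMProfile, Genotype, NUCLEOTIDES, ReadCountRecord

_STREAMS = {"frequencies": 11, "genotypes": 12, "admixture": 13, "reads": 14}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic scenario; round-trips via key/value text."""

    n_populations: int
    n_markers: int
    ancestral_freqs: tuple[float, ...]
    fst: tuple[float, ...]
    n_individuals: tuple[int, ...]
    admixture: Optional[tuple[str, str, float]] = None
    depth_mean: float = 200.0
    depth_dispersion: float = 8.0  # negative-binomial size; inf = Poisson
    allele_bias: float = 0.5
    error_rate: float = 0.0
    clamp_eps: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.n_markers < 1:
            raise ValidationError("need at least one population and one marker")
        object.__setattr__(self, "ancestral_freqs", tuple(float(p) for p in self.ancestral_freqs))
        object.__setattr__(self, "fst", tuple(float(f) for f in self.fst))
        object.__setattr__(self, "n_individuals", tuple(int(n) for n in self.n_individuals))
        if len(self.ancestral_freqs) != self.n_markers:
            raise ValidationError("ancestral_freqs length must equal n_markers")
        if len(self.fst) != self.n_populations:
            raise ValidationError("fst length must equal n_populations")
        if len(self.n_individuals) != self.n_populations:
            raise ValidationError("n_individuals length must equal n_populations")
        for p in self.ancestral_freqs:
            if not (0.0 < p < 1.0) or not math.isfinite(p):
                raise ValidationError(f"ancestral frequency {p} outside (0, 1)")
        for f in self.fst:
            if not (0.0 <= f < 1.0) or not math.isfinite(f):
                raise ValidationError(f"fst {f} outside [0, 1)")
        for n in self.n_individuals:
            if n < 1:
                raise ValidationError("sample sizes must be >= 1")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValidationError("error_rate must lie in [0, 0.5)")
        if not (0.0 < self.allele_bias < 1.0):
            raise ValidationError("allele_bias must lie in (0, 1)")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValidationError("depth model parameters must be positive")
        if not (0.0 < self.clamp_eps < 0.5):
            raise ValidationError("clamp_eps must lie in (0, 0.5)")
        if self.admixture is not None:
            pop_a, pop_b, alpha = self.admixture
            if not (0.0 <= float(alpha) <= 1.0):
                raise ValidationError("admixture proportion must lie in [0, 1]")
            if pop_a not in self.populations or pop_b not in self.populations:
                raise ValidationError("admixture names an unknown population")

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(f"POP{k + 1}" for k in range(self.n_populations))

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(f"M{j + 1:04d}" for j in range(self.n_markers))

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"n_populations = {self.n_populations}",
            f"n_markers = {self.n_markers}",
            "ancestral_freqs = " + ",".join(repr(p) for p in self.ancestral_freqs),
            "fst = " + ",".join(repr(f) for f in self.fst),
            "n_individuals = " + ",".join(str(n) for n in self.n_individuals),
            "admixture = "
            + (
                "none"
                if self.admixture is None
                else f"{self.admixture[0]},{self.admixture[1]},{self.admixture[2]!r}"
            ),
            f"depth_mean = {self.depth_mean!r}",
            f"depth_dispersion = {self.depth_dispersion!r}",
            f"allele_bias = {self.allele_bias!r}",
            f"error_rate = {self.error_rate!r}",
            f"clamp_eps = {self.clamp_eps!r}",
            f"seed = {self.seed}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        values: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        admix_raw = values.get("admixture", "none")
        admixture: Optional[tuple[str, str, float]] = None
        if admix_raw.lower() != "none":
            pop_a, pop_b, alpha = admix_raw.split(",")
            admixture = (pop_a, pop_b, float(alpha))
        return cls(
            n_populations=int(values["n_populations"]),
            n_markers=int(values["n_markers"]),
            ancestral_freqs=tuple(float(x) for x in values["ancestral_freqs"].split(",")),
            fst=tuple(float(x) for x in values["fst"].split(",")),
            n_individuals=tuple(int(x) for x in values["n_individuals"].split(",")),
            admixture=admixture,
            depth_mean=float(values.get("depth_mean", 200.0)),
            depth_dispersion=float(values.get("depth_dispersion", 8.0)),
            allele_bias=float(values.get("allele_bias", 0.5)),
            error_rate=float(values.get("error_rate", 0.0)),
            clamp_eps=float(values.get("clamp_eps", 1e-3)),
            seed=int(values.get("seed", 0)),
        )


@dataclass
class FrequencySet:
    """Per population x marker allele-1 frequencies plus allele labels."""

    markers: tuple[str, ...]
    populations: tuple[str, ...]
    alleles: tuple[Genotype, ...]  # (allele-1, allele-2) per marker
    freqs: np.ndarray  # shape (n_populations, n_markers)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.populations), len(self.markers)):
            raise ValidationError("frequency matrix shape disagrees with labels")
        if len(self.alleles) != len(self.markers):
            raise ValidationError("need one allele pair per marker")
        if not np.all((self.freqs > 0.0) & (self.freqs < 1.0)):
            raise ValidationError("all frequencies must lie strictly inside (0, 1)")

    def population_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None

    def frequencies(self, population: str) -> np.ndarray:
        return self.freqs[self.population_index(population)]

    def to_frame(self) -> pd.DataFrame:
        data = {
            "marker": self.markers,
            "allele1": [a[0] for a in self.alleles],
            "allele2": [a[1] for a in self.alleles],
        }
        for k, pop in enumerate(self.populations):
            data[pop] = self.freqs[k]
        return pd.DataFrame(data)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencySet":
        frame = pd.read_csv(path, sep="\t", dtype={"marker": str})
        populations = tuple(c for c in frame.columns if c not in ("marker", "allele1", "allele2"))
        return cls(
            markers=tuple(frame["marker"]),
            populations=populations,
            alleles=tuple(zip(frame["allele1"], frame["allele2"])),
            freqs=frame[list(populations)].to_numpy().T,
        )

    def subset(self, markers: Sequence[str]) -> "FrequencySet":
        index = {m: j for j, m in enumerate(self.markers)}
        cols = [index[m] for m in markers]
        return FrequencySet(
            markers=tuple(markers),
            populations=self.populations,
            alleles=tuple(self.alleles[j] for j in cols),
            freqs=self.freqs[:, cols],
        )


def sample_reference_frequencies(config: SimulationConfig) -> FrequencySet:
    """Draw per-population frequencies from the Balding-Nichols beta law.

    For ancestral frequency p and differentiation F the beta shapes are
    p(1-F)/F and (1-p)(1-F)/F, giving mean p and variance p(1-p)F. F = 0
    returns the ancestral frequencies exactly. Draws are clamped into
    [eps, 1-eps] so downstream log-likelihoods stay finite.
    """
    rng = _rng(config.seed, "frequencies")
    ancestral = np.asarray(config.ancestral_freqs)
    freqs = np.empty((config.n_populations, config.n_markers))
    for k, fst in enumerate(config.fst):
        if fst == 0.0:
            freqs[k] = ancestral
        else:
            scale = (1.0 - fst) / fst
            freqs[k] = rng.beta(ancestral * scale, (1.0 - ancestral) * scale)
    eps = config.clamp_eps
    np.clip(freqs, eps, 1.0 - eps, out=freqs)

    allele_pairs = []
    for _ in config.markers:
        pair = rng.choice(len(NUCLEOTIDES), size=2, replace=False)
        a1, a2 = NUCLEOTIDES[pair[0]], NUCLEOTIDES[pair[1]]
        allele_pairs.append((a1, a2))
    return FrequencySet(
        markers=config.markers,
        populations=config.populations,
        alleles=tuple(allele_pairs),
        freqs=freqs,
    )


def _genotype_from_dosage(dosage: int, alleles: Genotype) -> Genotype:
    a1, a2 = alleles
    if dosage == 2:
        return (a1, a1)
    if dosage == 1:
        return tuple(sorted((a1, a2)))  # type: ignore[return-value]
    return (a2, a2)


def simulate_genotypes(
    freqs: FrequencySet,
    population: str,
    n: int,
    seed: int,
    sample_prefix: Optional[str] = None,
) -> list[AIMProfile]:
    """Draw n complete HWE profiles from one population's frequencies."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    p = freqs.frequencies(population)
    rng = _rng(seed, "genotypes")
    dosages = rng.binomial(2, p, size=(n, len(freqs.markers)))
    prefix = sample_prefix if sample_prefix is not None else population
    profiles = []
    for i in range(n):
        genotypes = {
            marker: _genotype_from_dosage(int(dosages[i, j]), freqs.alleles[j])
            for j, marker in enumerate(freqs.markers)
        }
        profiles.append(AIMProfile(sample=f"{prefix}_S{i + 1:04d}", genotypes=genotypes))
    return profiles


def simulate_admixed_profile(
    freqs: FrequencySet,
    pop_a: str,
    pop_b: str,
    alpha: float,
    seed: int,
    sample: str = "ADMIXED_S0001",
) -> AIMProfile:
    """One profile whose allele copies come from pop_a w.p. alpha, else pop_b."""
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError("alpha must lie in [0, 1]")
    p_a = freqs.frequencies(pop_a)
    p_b = freqs.frequencies(pop_b)
    rng = _rng(seed, "admixture")
    m = len(freqs.markers)
    from_a = rng.random((m, 2)) < alpha
    p_copy = np.where(from_a, p_a[:, None], p_b[:, None])
    is_allele1 = rng.random((m, 2)) < p_copy
    dosages = is_allele1.sum(axis=1)
    genotypes = {
        marker: _genotype_from_dosage(int(dosages[j]), freqs.alleles[j])
        for j, marker in enumerate(freqs.markers)
    }
    return AIMProfile(sample=sample, genotypes=genotypes)


def _draw_depths(rng: np.random.Generator, config: SimulationConfig, size: int) -> np.ndarray:
    if math.isinf(config.depth_dispersion):
        return rng.poisson(config.depth_mean, size=size)
    r = config.depth_dispersion
    p = r / (r + config.depth_mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_read_counts(
    profiles: Sequence[AIMProfile],
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> list[ReadCountRecord]:
    """Amplicon-style read counts for each non-missing genotype.

    Total depth per locus is negative-binomial (Poisson when the dispersion
    is infinite); heterozygote reads split binomially with ``allele_bias``
    on the alphabetically first allele; each read is replaced by a uniformly
    chosen other nucleotide with probability ``error_rate``. The simulated
    genotype is stored both as the proposed call and as ground truth.
    """
    rng = _rng(config.seed if seed is None else seed, "reads")
    records = []
    for profile in profiles:
        genotyped = [(m, g) for m, g in profile.genotypes.items() if g is not None]
        depths = _draw_depths(rng, config, len(genotyped))
        for (marker, genotype), depth in zip(genotyped, depths):
            depth = int(depth)
            counts = dict.fromkeys(NUCLEOTIDES, 0)
            if genotype[0] == genotype[1]:
                counts[genotype[0]] = depth
            else:
                first = int(rng.binomial(depth, config.allele_bias))
                counts[genotype[0]] = first
                counts[genotype[1]] = depth - first
            if config.error_rate > 0.0:
                for nuc in NUCLEOTIDES:
                    source = counts[nuc]
                    if source == 0:
                        continue
                    n_err = int(rng.binomial(source, config.error_rate))
                    if n_err == 0:
                        continue
                    counts[nuc] -= n_err
                    others = [n for n in NUCLEOTIDES if n != nuc]
                    split = rng.multinomial(n_err, [1 / 3] * 3)
                    for other, extra in zip(others, split):
                        counts[other] += int(extra)
            records.append(
                ReadCountRecord(
                    sample=profile.sample,
                    marker=marker,
                    reads_a=counts["A"],
                    reads_c=counts["C"],
                    reads_g=counts["G"],
                    reads_t=counts["T"],
                    called_genotype=genotype,
                    true_genotype=genotype,
                )
            )
    return records


def write_profiles_tsv(profiles: Sequence[AIMProfile], path: str | Path) -> None:
    """Markers as rows, samples as columns, genotypes as two-letter strings."""
    if not profiles:
        raise ValidationError("no profiles to write")
    from .qc import genotype_str

    markers = profiles[0].markers
    data = {"marker": list(markers)}
    for profile in profiles:
        data[profile.sample] = [genotype_str(profile.genotypes[m]) for m in markers]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path) -> list[AIMProfile]:
    from .qc import normalize_genotype

    frame = pd.read_csv(path, sep="\t", dtype=str)
    markers = list(frame["marker"])
    profiles = []
    for sample in frame.columns[1:]:
        genotypes = {m: normalize_genotype(g) for m, g in zip(markers, frame[sample])}
        profiles.append(AIMProfile(sample=sample, genotypes=genotypes))
    return profiles
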
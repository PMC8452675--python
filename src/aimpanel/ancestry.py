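"""Likelihood-based population assignment with a z-score outlier gate.

A profile's log-likelihood under a candidate meta-population (HWE at
shrunken reference frequencies) is standardized against its analytic
expectation and standard deviation; z = (E[l] - l) / SD[l], so large
positive z means the profile fits worse than a typical member and the
meta-population is rejected at z > 1.64 (one-sided P < 0.05).

When the tested individual is part of the reference counts, its two allele
copies per non-missing marker are subtracted before frequency estimation
(leave-one-out, "out-of-sample"). Pairwise log likelihood-ratios between
candidate meta-populations carry a standard error, and profiles are
classified Accepted / Ambiguous / Rejected from the set of non-rejected
meta-populations and the significance of the likelihood differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DataIntegrityError, DegenerateModelError, ValidationError
from .qc import AIMProfile, Genotype

CATEGORIES = ("Accepted", "Ambiguous", "Rejected")


@dataclass
class ReferenceDatabase:
    """Allele counts per meta-population x marker plus allele labels.

    ``allele1``/``totals`` have shape (n_meta, n_markers); totals count
    allele copies (2 x individuals typed at the marker). References smaller
    than ``min_individuals`` trigger a warning, not an error.
    """

    meta_populations: tuple[str, ...]
    markers: tuple[str, ...]
    alleles: dict[str, Genotype]
    allele1: np.ndarray
    totals: np.ndarray
    population_map: dict[str, str] = field(default_factory=dict)
    min_individuals: int = 75

    def __post_init__(self) -> None:
        self.allele1 = np.asarray(self.allele1, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        shape = (len(self.meta_populations), len(self.markers))
        if self.allele1.shape != shape or self.totals.shape != shape:
            raise ValidationError("count matrices disagree with label dimensions")
        if np.any(self.allele1 < 0) or np.any(self.allele1 > self.totals):
            raise ValidationError("allele-1 counts must lie in [0, total]")
        for meta, sizes in zip(self.meta_populations, self.totals):
            if sizes.min() / 2.0 < self.min_individuals:
                warnings.warn(
                    f"reference {meta} has fewer than {self.min_individuals} "
                    "individuals at some marker",
                    stacklevel=2,
                )

    def meta_index(self, meta: str) -> int:
        try:
            return self.meta_populations.index(meta)
        except ValueError:
            raise KeyError(f"unknown meta-population {meta!r}") from None

    def marker_indices(self, markers: Sequence[str]) -> np.ndarray:
        index = {m: j for j, m in enumerate(self.markers)}
        return np.asarray([index[m] for m in markers], dtype=int)

    def subset(self, markers: Sequence[str]) -> "ReferenceDatabase":
        cols = self.marker_indices(markers)
        return ReferenceDatabase(
            meta_populations=self.meta_populations,
            markers=tuple(markers),
            alleles={m: self.alleles[m] for m in markers},
            allele1=self.allele1[:, cols],
            totals=self.totals[:, cols],
            population_map=dict(self.population_map),
            min_individuals=self.min_individuals,
        )

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[AIMProfile],
        origins: Mapping[str, str],
        alleles: Mapping[str, Genotype],
        population_map: Optional[Mapping[str, str]] = None,
        min_individuals: int = 75,
    ) -> "ReferenceDatabase":
        """Aggregate diploid profiles into per-meta-population allele counts.

        ``origins`` maps sample -> population; ``population_map`` (default
        identity) maps population -> meta-population.
        """
        pop_map = dict(population_map) if population_map else {}
        for pop in set(origins.values()):
            pop_map.setdefault(pop, pop)
        metas = tuple(sorted(set(pop_map[pop] for pop in set(origins.values()))))
        markers = tuple(profiles[0].markers)
        allele1 = np.zeros((len(metas), len(markers)))
        totals = np.zeros((len(metas), len(markers)))
        meta_of = {m: i for i, m in enumerate(metas)}
        for profile in profiles:
            if profile.sample not in origins:
                raise ValidationError(f"no origin recorded for sample {profile.sample}")
            k = meta_of[pop_map[origins[profile.sample]]]
            for j, marker in enumerate(markers):
                genotype = profile.genotypes.get(marker)
                if genotype is None:
                    continue
                a1 = alleles[marker][0]
                allele1[k, j] += sum(1 for a in genotype if a == a1)
                totals[k, j] += 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            db = cls(
                meta_populations=metas,
                markers=markers,
                alleles={m: tuple(alleles[m]) for m in markers},  # type: ignore[misc]
                allele1=allele1,
                totals=totals,
                population_map=pop_map,
                min_individuals=min_individuals,
            )
        return db

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for k, meta in enumerate(self.meta_populations):
            for j, marker in enumerate(self.markers):
                rows.append(
                    {
                        "meta_population": meta,
                        "marker": marker,
                        "allele1": self.alleles[marker][0],
                        "allele2": self.alleles[marker][1],
                        "allele1_count": int(self.allele1[k, j]),
                        "total_count": int(self.totals[k, j]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        population_map: Optional[Mapping[str, str]] = None,
        min_individuals: int = 75,
    ) -> "ReferenceDatabase":
        frame = pd.read_csv(path, sep="\t", dtype={"meta_population": str, "marker": str})
        metas = tuple(sorted(frame["meta_population"].unique()))
        markers = tuple(dict.fromkeys(frame["marker"]))
        alleles = {}
        allele1 = np.zeros((len(metas), len(markers)))
        totals = np.zeros((len(metas), len(markers)))
        marker_of = {m: j for j, m in enumerate(markers)}
        meta_of = {m: k for k, m in enumerate(metas)}
        for row in frame.itertuples(index=False):
            j = marker_of[row.marker]
            k = meta_of[row.meta_population]
            alleles[row.marker] = (row.allele1, row.allele2)
            allele1[k, j] = row.allele1_count
            totals[k, j] = row.total_count
        return cls(
            meta_populations=metas,
            markers=markers,
            alleles=alleles,
            allele1=allele1,
            totals=totals,
            population_map=dict(population_map) if population_map else {},
            min_individuals=min_individuals,
        )


def _profile_dosages(profile: AIMProfile, db: ReferenceDatabase) -> dict[str, int]:
    """Allele-1 dosage per non-missing marker shared with the database."""
    dosages = {}
    for marker, genotype in profile.genotypes.items():
        if genotype is None or marker not in db.alleles:
            continue
        a1 = db.alleles[marker][0]
        dosages[marker] = sum(1 for a in genotype if a == a1)
    return dosages


def estimate_frequencies(
    db: ReferenceDatabase,
    meta_population: str,
    exclude_profile: Optional[AIMProfile] = None,
    pseudocount: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Shrunken allele-1 frequencies and their sampling variances.

    frequency = (count + a) / (total + 2a), variance = f(1-f) / (total + 2a + 1),
    with pseudo-count a. With ``exclude_profile`` the individual's two allele
    copies per non-missing marker are subtracted first (leave-one-out).
    """
    k = db.meta_index(meta_population)
    counts = db.allele1[k].copy()
    totals = db.totals[k].copy()
    if exclude_profile is not None:
        index = {m: j for j, m in enumerate(db.markers)}
        for marker, dosage in _profile_dosages(exclude_profile, db).items():
            counts[index[marker]] -= dosage
            totals[index[marker]] -= 2
        if np.any(counts < 0) or np.any(totals < 0):
            raise DataIntegrityError(
                f"leave-one-out subtraction below zero for {exclude_profile.sample} "
                f"in {meta_population}"
            )
    freqs = (counts + pseudocount) / (totals + 2 * pseudocount)
    variances = freqs * (1.0 - freqs) / (totals + 2 * pseudocount + 1.0)
    return freqs, variances


def _genotype_logprobs(freqs: np.ndarray) -> np.ndarray:
    """log P(dosage) for dosages 0, 1, 2 under HWE; shape (n_markers, 3)."""
    q = np.asarray(freqs)
    probs = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)
    if np.any(probs <= 0):
        raise DegenerateModelError(
            "zero genotype probability; use a positive pseudo-count"
        )
    return np.log(probs)


def profile_loglik(
    profile: AIMProfile,
    db: ReferenceDatabase,
    meta_population: str,
    exclude_profile: Optional[AIMProfile] = None,
    pseudocount: float = 0.5,
) -> tuple[float, int]:
    """Sum of log genotype probabilities over non-missing markers.

    Missing markers contribute nothing; returns (l, loci used).
    """
    freqs, _ = estimate_frequencies(db, meta_population, exclude_profile, pseudocount)
    dosages = _profile_dosages(profile, db)
    if not dosages:
        return 0.0, 0
    markers = sorted(dosages)
    cols = db.marker_indices(markers)
    logp = _genotype_logprobs(freqs[cols])
    total = float(sum(logp[i, dosages[m]] for i, m in enumerate(markers)))
    return total, len(markers)


def loglik_moments(freqs: np.ndarray) -> tuple[float, float]:
    """Expectation and SD of the profile log-likelihood across the loci.

    Per locus E = sum_g P(g) log P(g) and Var = sum_g P(g) log^2 P(g) - E^2;
    loci are independent, so totals add and SD = sqrt(sum Var).
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if freqs.size == 0:
        raise ValidationError("empty locus set")
    logp = _genotype_logprobs(freqs)
    probs = np.exp(logp)
    expectation = (probs * logp).sum(axis=1)
    second = (probs * logp**2).sum(axis=1)
    variance = second - expectation**2
    return float(expectation.sum()), float(np.sqrt(variance.sum()))


def z_score(
    profile: AIMProfile,
    db: ReferenceDatabase,
    meta_population: str,
    loo: bool = False,
    pseudocount: float = 0.5,
) -> float:
    """Standardized log-likelihood z = (E[l] - l) / SD[l].

    Positive z means the profile is less likely than a typical member of the
    meta-population; the gate elsewhere rejects at z > 1.64 (one-sided).
    With ``loo`` the profile's own alleles are removed from the reference
    counts before estimating frequencies.
    """
    exclude = profile if loo else None
    freqs, _ = estimate_frequencies(db, meta_population, exclude, pseudocount)
    dosages = _profile_dosages(profile, db)
    if not dosages:
        raise ValidationError(
            f"profile {profile.sample} shares no non-missing marker with the database"
        )
    markers = sorted(dosages)
    cols = db.marker_indices(markers)
    logp = _genotype_logprobs(freqs[cols])
    loglik = float(sum(logp[i, dosages[m]] for i, m in enumerate(markers)))
    expectation, sd = loglik_moments(freqs[cols])
    if sd == 0.0:
        raise DegenerateModelError("all loci degenerate; z-score undefined")
    return (expectation - loglik) / sd


def log_lr(
    profile: AIMProfile,
    db: ReferenceDatabase,
    meta_a: str,
    meta_b: str,
    loo_meta: Optional[str] = None,
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """Pairwise log likelihood-ratio l_A - l_B over shared non-missing loci.

    The standard error is the square root of the summed per-locus variance of
    the log-ratio term under meta A's genotype distribution. ``loo_meta``
    names the meta-population (if any) whose counts contain the profile and
    must be corrected by leave-one-out.
    """
    exclude_a = profile if loo_meta == meta_a else None
    exclude_b = profile if loo_meta == meta_b else None
    freqs_a, _ = estimate_frequencies(db, meta_a, exclude_a, pseudocount)
    freqs_b, _ = estimate_frequencies(db, meta_b, exclude_b, pseudocount)
    dosages = _profile_dosages(profile, db)
    if not dosages:
        return 0.0, 0.0
    markers = sorted(dosages)
    cols = db.marker_indices(markers)
    logp_a = _genotype_logprobs(freqs_a[cols])
    logp_b = _genotype_logprobs(freqs_b[cols])
    diff = logp_a - logp_b
    value = float(sum(diff[i, dosages[m]] for i, m in enumerate(markers)))
    probs_a = np.exp(logp_a)
    mean_term = (probs_a * diff).sum(axis=1)
    var_term = (probs_a * diff**2).sum(axis=1) - mean_term**2
    return value, float(np.sqrt(var_term.sum()))


@dataclass
class AssignmentResult:
    """Full per-profile assignment record, re-derivable category included."""

    sample: str
    loglik: dict[str, float]
    expected_loglik: dict[str, float]
    sd_loglik: dict[str, float]
    z: dict[str, float]
    loglr: dict[tuple[str, str], tuple[float, float]]  # (value, SE)
    accepted: tuple[str, ...]
    category: str
    meta_category: dict[str, str]
    loci_used: int

    def best_meta(self) -> Optional[str]:
        if not self.accepted:
            return None
        return max(self.accepted, key=lambda m: self.loglik[m])


def _significantly_higher(
    meta: str,
    others: Sequence[str],
    loglr: Mapping[tuple[str, str], tuple[float, float]],
    critical: float,
) -> bool:
    for other in others:
        value, se = loglr[(meta, other)]
        if se == 0.0 or value / se <= critical:
            return False
    return True


def classify_profile(
    profile: AIMProfile,
    db: ReferenceDatabase,
    alpha: float = 0.05,
    z_threshold: float = 1.64,
    loo_meta: Optional[str] = None,
    pseudocount: float = 0.5,
) -> AssignmentResult:
    """Three-way classification of a profile against all meta-populations.

    Rejected when no meta-population passes the z gate (no LRs computed);
    Accepted when exactly one passes, or several pass but one likelihood is
    significantly higher than every other accepted one (one-sided normal
    test on log-LR / SE at ``alpha``); Ambiguous otherwise. ``meta_category``
    holds the same decision evaluated per tested meta-population.
    """
    critical = float(norm.ppf(1.0 - alpha))
    logliks: dict[str, float] = {}
    expectations: dict[str, float] = {}
    sds: dict[str, float] = {}
    zs: dict[str, float] = {}
    loci_used = 0
    for meta in db.meta_populations:
        exclude = profile if loo_meta == meta else None
        freqs, _ = estimate_frequencies(db, meta, exclude, pseudocount)
        dosages = _profile_dosages(profile, db)
        if not dosages:
            raise ValidationError(
                f"profile {profile.sample} shares no marker with the database"
            )
        markers = sorted(dosages)
        cols = db.marker_indices(markers)
        logp = _genotype_logprobs(freqs[cols])
        loglik_val = float(sum(logp[i, dosages[m]] for i, m in enumerate(markers)))
        expectation, sd = loglik_moments(freqs[cols])
        if sd == 0.0:
            raise DegenerateModelError(f"z-score undefined for {meta}")
        logliks[meta] = loglik_val
        expectations[meta] = expectation
        sds[meta] = sd
        zs[meta] = (expectation - loglik_val) / sd
        loci_used = len(markers)

    accepted = tuple(m for m in db.meta_populations if zs[m] <= z_threshold)
    loglr: dict[tuple[str, str], tuple[float, float]] = {}
    if accepted:
        # LRs only for non-rejected profiles; every ordered pair involving an
        # accepted meta-population is stored for the evidence report
        for meta in accepted:
            for other in db.meta_populations:
                if other == meta:
                    continue
                loglr[(meta, other)] = log_lr(
                    profile, db, meta, other, loo_meta=loo_meta, pseudocount=pseudocount
                )

    if not accepted:
        category = "Rejected"
    elif len(accepted) == 1:
        category = "Accepted"
    else:
        best = max(accepted, key=lambda m: logliks[m])
        rivals = [m for m in accepted if m != best]
        category = (
            "Accepted" if _significantly_higher(best, rivals, loglr, critical) else "Ambiguous"
        )

    meta_category = {}
    for meta in db.meta_populations:
        if meta not in accepted:
            meta_category[meta] = "Rejected"
        else:
            rivals = [m for m in accepted if m != meta]
            if not rivals or _significantly_higher(meta, rivals, loglr, critical):
                meta_category[meta] = "Accepted"
            else:
                meta_category[meta] = "Ambiguous"

    return AssignmentResult(
        sample=profile.sample,
        loglik=logliks,
        expected_loglik=expectations,
        sd_loglik=sds,
        z=zs,
        loglr=loglr,
        accepted=accepted,
        category=category,
        meta_category=meta_category,
        loci_used=loci_used,
    )


def cross_validate(
    db: ReferenceDatabase,
    profiles: Sequence[AIMProfile],
    origins: Mapping[str, str],
    panels: Optional[Mapping[str, Sequence[str]]] = None,
    alpha: float = 0.05,
    z_threshold: float = 1.64,
    loo: bool = True,
    pseudocount: float = 0.5,
    return_results: bool = False,
):
    """Leave-one-out category rates per origin x tested meta-population.

    Returns a long-format table with columns origin, size, tested, panel and
    the Accepted/Ambiguous/Rejected percentages, which sum to 100 per row.
    ``panels`` optionally maps a panel name to a marker subset; by default the
    full database is used under the panel name "all".
    """
    for profile in profiles:
        if profile.sample not in origins:
            raise ValidationError(f"profile {profile.sample} has no recorded origin")
        meta = db.population_map.get(origins[profile.sample], origins[profile.sample])
        if meta not in db.meta_populations:
            raise ValidationError(
                f"origin {origins[profile.sample]!r} of {profile.sample} is not in the database"
            )
    panel_map = {"all": list(db.markers)} if panels is None else {k: list(v) for k, v in panels.items()}

    rows = []
    results_by_panel: dict[str, list[AssignmentResult]] = {}
    for panel_name, markers in panel_map.items():
        sub_db = db.subset(markers)
        panel_results = results_by_panel.setdefault(panel_name, [])
        tallies: dict[tuple[str, str], dict[str, int]] = {}
        sizes: dict[str, int] = {}
        for profile in profiles:
            origin_meta = db.population_map.get(origins[profile.sample], origins[profile.sample])
            sizes[origin_meta] = sizes.get(origin_meta, 0) + 1
            result = classify_profile(
                profile,
                sub_db,
                alpha=alpha,
                z_threshold=z_threshold,
                loo_meta=origin_meta if loo else None,
                pseudocount=pseudocount,
            )
            panel_results.append(result)
            for tested in sub_db.meta_populations:
                cell = tallies.setdefault((origin_meta, tested), dict.fromkeys(CATEGORIES, 0))
                cell[result.meta_category[tested]] += 1
        for (origin_meta, tested), cell in sorted(tallies.items()):
            total = sum(cell.values())
            rows.append(
                {
                    "origin": origin_meta,
                    "size": sizes[origin_meta],
                    "tested": tested,
                    "panel": panel_name,
                    "accepted_pct": 100.0 * cell["Accepted"] / total,
                    "ambiguous_pct": 100.0 * cell["Ambiguous"] / total,
                    "rejected_pct": 100.0 * cell["Rejected"] / total,
                }
            )
    summary = pd.DataFrame(rows)
    if return_results:
        return summary, results_by_panel
    return summary


def summary_total_individuals(summary: pd.DataFrame) -> int:
    """Total individuals covered by a cross-validation summary table.

    Each origin's size is counted once regardless of how many tested
    meta-populations or panels appear in the table.
    """
    if "origin" not in summary.columns or "size" not in summary.columns:
        raise ValidationError("summary table must have 'origin' and 'size' columns")
    sizes = summary.drop_duplicates("origin")["size"]
    return int(sizes.sum())
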
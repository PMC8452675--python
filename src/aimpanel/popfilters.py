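"""Marker-independence filtering.

Per-population exact tests of Hardy-Weinberg equilibrium (full enumeration
over heterozygote configurations, with a Markov-chain estimator as an
alternative), pairwise linkage-disequilibrium exact tests on complete
two-locus genotypes (EM haplotype frequencies + permutation null),
Bonferroni correction, and pruning of linked marker pairs by a
performance-then-amplicon-length rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .errors import ConfigurationError, ValidationError
from .qc import AIMProfile, GenotypeCall

# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCountTable:
    """Genotype counts for one marker in one population (A = allele 1)."""

    marker: str
    population: str
    n_aa: int
    n_ab: int
    n_bb: int

    def __post_init__(self) -> None:
        if min(self.n_aa, self.n_ab, self.n_bb) < 0:
            raise ValidationError("genotype counts must be non-negative")
        if self.n == 0:
            raise ValidationError("empty genotype table")

    @property
    def n(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    @property
    def allele_counts(self) -> tuple[int, int]:
        return (2 * self.n_aa + self.n_ab, 2 * self.n_bb + self.n_ab)


def hwe_het_probabilities(n: int, n_allele1: int) -> tuple[np.ndarray, np.ndarray]:
    """All heterozygote counts compatible with the allele counts and their
    exact conditional probabilities (Levene distribution).

    P(n_ab | n, n_a) = n! / (n_aa! n_ab! n_bb!) * 2^n_ab * n_a! n_b! / (2n)!
    """
    n_a = n_allele1
    n_b = 2 * n - n_a
    minor = min(n_a, n_b)
    ks = np.arange(minor % 2, minor + 1, 2)
    n_aa = (n_a - ks) // 2
    n_bb = (n_b - ks) // 2
    log_p = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(ks + 1)
        - gammaln(n_bb + 1)
        + ks * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(log_p - log_p.max())
    probs /= probs.sum()
    return ks, probs


def _hwe_enumeration(table: GenotypeCountTable) -> float:
    ks, probs = hwe_het_probabilities(table.n, table.allele_counts[0])
    observed = probs[np.searchsorted(ks, table.n_ab)]
    # tolerance keeps ties included despite floating-point jitter
    return float(probs[probs <= observed * (1.0 + 1e-12)].sum())

def _hwe_markov_chain(table: GenotypeCountTable, steps: int, seed: Optional[int]) -> float:
    """Metropolis chain over heterozygote counts (switch moves of +/-2).

    The proposal picks a direction uniformly; the stationary law is the exact
    conditional distribution, so the visit fraction of states no more probable
    than the observed one estimates the enumeration p-value.
    """
    ks, probs = hwe_het_probabilities(table.n, table.allele_counts[0])
    if len(ks) == 1:
        return 1.0
    index = {int(k): i for i, k in enumerate(ks)}
    rng = np.random.default_rng(seed)
    state = index[table.n_ab]
    threshold = probs[state] * (1.0 + 1e-12)
    extreme = probs <= threshold
    hits = 0
    directions = rng.integers(0, 2, size=steps)
    accept_draws = rng.random(steps)
    for step in range(steps):
        proposal = state + (1 if directions[step] else -1)
        if 0 <= proposal < len(ks) and accept_draws[step] * probs[state] < probs[proposal]:
            state = proposal
        hits += bool(extreme[state])
    return hits / steps


def hwe_exact_test(
    table: GenotypeCountTable,
    method: str = "enumeration",
    steps: int = 1_000_000,
    seed: Optional[int] = None,
) -> float:
    """Exact HWE test conditional on allele counts.

    The p-value is the total probability of heterozygote configurations no
    more probable than the observed one. Monomorphic tables return 1.0.
    """
    n_a, n_b = table.allele_counts
    if n_a == 0 or n_b == 0:
        return 1.0
    if method == "enumeration":
        return _hwe_enumeration(table)
    if method == "markov_chain":
        if steps < 1:
            raise ValidationError("steps must be >= 1")
        return _hwe_markov_chain(table, steps, seed)
    raise ValidationError(f"unknown HWE method {method!r}")


# ---------------------------------------------------------------------------
# Multiple testing helpers
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-test level alpha / m; compare with p < threshold."""
    if m < 1:
        raise ValidationError("number of tests must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    return alpha / m


def count_marker_pairs(m: int) -> int:
    """Number of unordered marker pairs, m(m-1)/2."""
    if m < 2:
        raise ValidationError("need at least two markers to form pairs")
    return m * (m - 1) // 2


# ---------------------------------------------------------------------------
# Linkage-disequilibrium exact test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseLDResult:
    markers: tuple[str, str]
    population: str
    p_value: float
    statistic: float
    n: int


_HAP_DOSAGE = ((1, 1), (1, 0), (0, 1), (0, 0))  # allele-1 indicator at (locus1, locus2)

# flattened lookup tables over the 16 ordered haplotype pairs: the genotype
# cell (dosage1 * 3 + dosage2) each pair produces, and its haplotype tallies
_PAIR_CELL = np.empty(16, dtype=int)
_PAIR_HAPS = np.zeros((16, 4))
for _a, (_a1, _a2) in enumerate(_HAP_DOSAGE):
    for _b, (_b1, _b2) in enumerate(_HAP_DOSAGE):
        _idx = 4 * _a + _b
        _PAIR_CELL[_idx] = 3 * (_a1 + _b1) + (_a2 + _b2)
        _PAIR_HAPS[_idx, _a] += 1.0
        _PAIR_HAPS[_idx, _b] += 1.0
del _a, _b, _a1, _a2, _b1, _b2, _idx


def _genotype_table(dos1: np.ndarray, dos2: np.ndarray) -> np.ndarray:
    table = np.zeros((3, 3))
    np.add.at(table, (dos1, dos2), 1.0)
    return table


def _cell_probs(h: np.ndarray) -> np.ndarray:
    """Flattened 3x3 genotype probabilities under random union of haplotypes."""
    return np.bincount(_PAIR_CELL, weights=np.outer(h, h).ravel(), minlength=9)


def _loglik(counts9: np.ndarray, h: np.ndarray) -> float:
    probs = _cell_probs(h)
    mask = counts9 > 0
    return float((counts9[mask] * np.log(probs[mask])).sum())


def _em_haplotypes(table: np.ndarray, iterations: int = 100, tol: float = 1e-10) -> np.ndarray:
    """EM haplotype frequencies from unphased two-locus genotype counts.

    Only the double heterozygote cell is phase-ambiguous; every other cell
    contributes fixed haplotype counts.
    """
    counts9 = table.ravel()
    n = counts9.sum()
    h = np.full(4, 0.25)
    for _ in range(iterations):
        pair_w = np.outer(h, h).ravel()
        cell_w = np.bincount(_PAIR_CELL, weights=pair_w, minlength=9)
        denom = cell_w[_PAIR_CELL]
        share = np.divide(pair_w, denom, out=np.zeros(16), where=denom > 0)
        pair_n = counts9[_PAIR_CELL] * share
        new = (pair_n @ _PAIR_HAPS) / (2.0 * n)
        if np.abs(new - h).max() < tol:
            h = new
            break
        h = new
    return h


def _ld_statistic(table: np.ndarray) -> float:
    counts9 = table.ravel()
    n = counts9.sum()
    p1 = (table.sum(axis=1) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    p2 = (table.sum(axis=0) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    h_indep = np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])
    h_em = _em_haplotypes(table)
    # clip keeps EM zeros from producing -inf in cells with zero counts
    h_em = np.clip(h_em, 1e-12, None)
    h_em /= h_em.sum()
    return max(0.0, 2.0 * (_loglik(counts9, h_em) - _loglik(counts9, h_indep)))


def ld_exact_test(
    dosages1: Sequence[int],
    dosages2: Sequence[int],
    markers: tuple[str, str] = ("locus1", "locus2"),
    population: str = "",
    permutations: int = 999,
    seed: int = 0,
) -> PairwiseLDResult:
    """Permutation exact test of linkage between two unphased markers.

    The statistic is the likelihood ratio of EM haplotype frequencies against
    allele-frequency independence; the null distribution comes from permuting
    the second marker's genotype column; p = (1 + #{perm >= obs}) / (1 + B).
    Monomorphic markers give p = 1 by convention.
    """
    dos1 = np.asarray(dosages1, dtype=int)
    dos2 = np.asarray(dosages2, dtype=int)
    if dos1.shape != dos2.shape or dos1.ndim != 1:
        raise ValidationError("dosage vectors must be 1-D and equally long")
    if len(dos1) < 2:
        raise ValidationError("need at least two complete individuals")
    if np.any((dos1 < 0) | (dos1 > 2) | (dos2 < 0) | (dos2 > 2)):
        raise ValidationError("dosages must lie in {0, 1, 2}")
    n = len(dos1)
    if len(np.unique(dos1)) == 1 and dos1[0] != 1 or len(np.unique(dos2)) == 1 and dos2[0] != 1:
        return PairwiseLDResult(markers, population, 1.0, 0.0, n)

    observed = _ld_statistic(_genotype_table(dos1, dos2))
    rng = np.random.default_rng(seed)
    hits = 0
    shuffled = dos2.copy()
    for _ in range(permutations):
        rng.shuffle(shuffled)
        if _ld_statistic(_genotype_table(dos1, shuffled)) >= observed - 1e-9:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return PairwiseLDResult(markers, population, p, observed, n)


def dosage_matrix(
    profiles: Sequence[AIMProfile],
    markers: Sequence[str],
    alleles: Mapping[str, tuple[str, str]],
    complete_only: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Allele-1 dosage matrix (individuals x markers); optionally restricted
    to individuals with no missing call at the requested markers."""
    rows = []
    samples = []
    for profile in profiles:
        genotypes = [profile.genotypes.get(m) for m in markers]
        if complete_only and any(g is None for g in genotypes):
            continue
        row = []
        for m, g in zip(markers, genotypes):
            if g is None:
                row.append(-1)
            else:
                row.append(sum(1 for a in g if a == alleles[m][0]))
        rows.append(row)
        samples.append(profile.sample)
    if not rows:
        raise ValidationError("no individuals with complete profiles")
    return np.asarray(rows, dtype=int), samples


# ---------------------------------------------------------------------------
# Performance-based pruning of linked pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerPerformance:
    """Locus quality metrics used to choose which marker of a linked pair to keep."""

    marker: str
    dropouts: int
    mean_noise: float
    hb_deviation: float  # mean |Hb - 1| over accepted heterozygotes
    locus_balance: float  # mean share of a sample's reads at this locus
    amplicon_length: int

    def __post_init__(self) -> None:
        if (
            self.dropouts < 0
            or self.mean_noise < 0
            or self.hb_deviation < 0
            or self.locus_balance < 0
            or self.amplicon_length < 0
        ):
            raise ValidationError("performance metrics must be non-negative")


def marker_performance(
    calls: Iterable[GenotypeCall],
    amplicon_lengths: Mapping[str, int],
) -> dict[str, MarkerPerformance]:
    """Summarise per-marker QC metrics from genotype calls."""
    by_marker: dict[str, list[GenotypeCall]] = {}
    depth_by_sample: dict[str, int] = {}
    call_list = list(calls)
    for call in call_list:
        by_marker.setdefault(call.marker, []).append(call)
        depth_by_sample[call.sample] = depth_by_sample.get(call.sample, 0) + call.depth
    performances = {}
    for marker, marker_calls in by_marker.items():
        dropouts = sum(1 for c in marker_calls if c.genotype is None)
        noises = [c.noise for c in marker_calls if c.noise is not None]
        hbs = [c.hb for c in marker_calls if c.genotype is not None and c.hb is not None]
        shares = [
            c.depth / depth_by_sample[c.sample]
            for c in marker_calls
            if depth_by_sample[c.sample] > 0
        ]
        performances[marker] = MarkerPerformance(
            marker=marker,
            dropouts=dropouts,
            mean_noise=float(np.mean(noises)) if noises else 0.0,
            hb_deviation=float(np.mean([abs(h - 1.0) for h in hbs])) if hbs else 0.0,
            locus_balance=float(np.mean(shares)) if shares else 0.0,
            amplicon_length=int(amplicon_lengths.get(marker, 0)),
        )
    return performances


def prune_linked_markers(
    ld_results: Sequence[PairwiseLDResult],
    corrected_level: float,
    performance: Mapping[str, MarkerPerformance],
) -> tuple[list[str], list[str], list[dict]]:
    """Remove one marker per significant LD pair, keeping the better performer.

    Pairs significant at the corrected level are processed most significant
    first; a pair is skipped when one of its markers was already removed.
    "Better" is lexicographic: fewer dropouts, lower mean noise, smaller
    |Hb - 1| deviation, locus balance closest to the panel mean; exact ties
    go to the shorter amplicon, then to the lexicographically first marker ID.
    Returns (retained, removed, rationale log).
    """
    marker_universe = sorted(performance)
    significant = sorted(
        (r for r in ld_results if r.p_value < corrected_level),
        key=lambda r: (r.p_value, tuple(sorted(r.markers))),
    )
    mean_balance = (
        float(np.mean([performance[m].locus_balance for m in marker_universe]))
        if marker_universe
        else 0.0
    )

    def quality_key(marker: str) -> tuple:
        perf = performance[marker]
        return (
            perf.dropouts,
            perf.mean_noise,
            perf.hb_deviation,
            abs(perf.locus_balance - mean_balance),
        )

    removed: list[str] = []
    removed_set: set[str] = set()
    log: list[dict] = []
    for result in significant:
        m1, m2 = result.markers
        for m in (m1, m2):
            if m not in performance:
                raise ConfigurationError(f"no performance record for marker {m}")
        if m1 in removed_set or m2 in removed_set:
            log.append(
                {
                    "pair": [m1, m2],
                    "p_value": result.p_value,
                    "action": "skipped",
                    "reason": "a member was already removed",
                }
            )
            continue
        key1, key2 = quality_key(m1), quality_key(m2)
        if key1 != key2:
            loser = m1 if key1 > key2 else m2
            rule = "performance"
        else:
            len1 = performance[m1].amplicon_length
            len2 = performance[m2].amplicon_length
            if len1 != len2:
                loser = m1 if len1 > len2 else m2
                rule = "amplicon_length"
            else:
                loser = max(m1, m2)
                rule = "marker_id_tiebreak"
        removed.append(loser)
        removed_set.add(loser)
        log.append(
            {
                "pair": [m1, m2],
                "p_value": result.p_value,
                "action": "removed",
                "removed": loser,
                "rule": rule,
            }
        )
    retained = [m for m in marker_universe if m not in removed_set]
    return retained, removed, log
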
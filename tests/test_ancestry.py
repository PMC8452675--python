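import itertools
import math

import numpy as np
import pytest

from aimpanel.ancestry import (
    ReferenceDatabase,
    classify_profile,
    cross_validate,
    estimate_frequencies,
    log_lr,
    loglik_moments,
    profile_loglik,
    summary_total_individuals,
    z_score,
)
from aimpanel.errors import DataIntegrityError, ValidationError
from aimpanel.qc import AIMProfile


def genotype_probs(q):
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def moments_oracle(freqs):
    """Exhaustive enumeration of E[l] and Var[l] over all genotype combos."""
    per_locus = [genotype_probs(q) for q in freqs]
    expectation = 0.0
    second = 0.0
    for combo in itertools.product(range(3), repeat=len(freqs)):
        prob = math.prod(per_locus[i][g] for i, g in enumerate(combo))
        loglik = sum(math.log(per_locus[i][g]) for i, g in enumerate(combo))
        expectation += prob * loglik
        second += prob * loglik**2
    return expectation, math.sqrt(second - expectation**2)


class TestEstimateFrequencies:
    def test_symmetric_counts_with_half_pseudocount(self, db_factory):
        db = db_factory([[0.5]], totals=100)
        freqs, variances = estimate_frequencies(db, "META1")
        assert freqs[0] == pytest.approx(50.5 / 101)
        assert variances[0] == pytest.approx(freqs[0] * (1 - freqs[0]) / 102)

    def test_leave_one_out_arithmetic(self, db_factory, profile_factory):
        db = db_factory([[0.5]], totals=100)
        aa_profile = profile_factory([2])
        freqs, _ = estimate_frequencies(db, "META1", exclude_profile=aa_profile)
        assert freqs[0] == pytest.approx(48.5 / 99)

    def test_zero_pseudocount_degenerate(self, db_factory):
        db = db_factory([[0.0 + 1e-12]], totals=100)
        db.allele1[0, 0] = 0.0
        freqs, _ = estimate_frequencies(db, "META1", pseudocount=0.0)
        assert freqs[0] == 0.0  # flagged downstream as zero-probability genotype

    def test_loo_below_zero_is_integrity_error(self, db_factory, profile_factory):
        db = db_factory([[0.001]], totals=100)
        db.allele1[0, 0] = 1.0
        with pytest.raises(DataIntegrityError):
            estimate_frequencies(db, "META1", exclude_profile=profile_factory([2]))


class TestProfileLoglik:
    def test_single_heterozygote_closed_form(self, db_factory, profile_factory):
        db = db_factory([[0.5]], totals=10**9)  # shrinkage negligible
        loglik, n = profile_loglik(profile_factory([1]), db, "META1")
        assert loglik == pytest.approx(math.log(0.5), abs=1e-6)
        assert n == 1

    def test_all_missing_empty_sum(self, db_factory, profile_factory):
        db = db_factory([[0.5]])
        loglik, n = profile_loglik(profile_factory([None]), db, "META1")
        assert loglik == 0.0
        assert n == 0

    def test_additivity_over_markers(self, db_factory, profile_factory):
        rng = np.random.default_rng(3)
        q = rng.uniform(0.1, 0.9, 10)
        dosages = list(rng.integers(0, 3, 10))
        db = db_factory([q], totals=500)
        total, n = profile_loglik(profile_factory(dosages), db, "META1")
        assert n == 10
        singles = 0.0
        for j in range(10):
            single_db = db_factory([[q[j]]], totals=500, markers=[f"M{j + 1:04d}"])
            value, _ = profile_loglik(
                profile_factory([dosages[j]], markers=[f"M{j + 1:04d}"]), single_db, "META1"
            )
            singles += value
        assert total == pytest.approx(singles, abs=1e-10)


class TestLoglikMoments:
    def test_single_locus_half_frequency(self):
        expectation, sd = loglik_moments([0.5])
        assert expectation == pytest.approx(-1.0397, abs=1e-4)
        assert sd == pytest.approx(0.3466, abs=1e-4)

    def test_degenerate_limit(self):
        expectation, sd = loglik_moments([1 - 1e-9])
        assert -1e-6 < expectation < 0
        assert 0 < sd < 1e-3

    def test_independence_scaling(self):
        e1, sd1 = loglik_moments([0.37])
        e100, sd100 = loglik_moments([0.37] * 100)
        assert e100 == pytest.approx(100 * e1, rel=1e-12)
        assert sd100 == pytest.approx(10 * sd1, rel=1e-12)

    @pytest.mark.parametrize("n_loci", [1, 2, 3])
    def test_matches_exhaustive_enumeration(self, n_loci):
        rng = np.random.default_rng(n_loci)
        freqs = rng.uniform(0.05, 0.95, n_loci)
        expectation, sd = loglik_moments(freqs)
        oracle_e, oracle_sd = moments_oracle(freqs)
        assert expectation == pytest.approx(oracle_e, abs=1e-10)
        assert sd == pytest.approx(oracle_sd, abs=1e-10)

    def test_empty_locus_set_rejected(self):
        with pytest.raises(ValidationError):
            loglik_moments([])


class TestZScore:
    def test_single_locus_signs(self, db_factory, profile_factory):
        db = db_factory([[0.5]], totals=10**9)
        assert z_score(profile_factory([1]), db, "META1") == pytest.approx(-1.0, abs=1e-4)
        assert z_score(profile_factory([2]), db, "META1") == pytest.approx(1.0, abs=1e-4)
        assert z_score(profile_factory([0]), db, "META1") == pytest.approx(1.0, abs=1e-4)

    def test_z_is_standardized_loglik(self, db_factory, profile_factory):
        rng = np.random.default_rng(4)
        q = rng.uniform(0.2, 0.8, 30)
        db = db_factory([q], totals=600)
        profile = profile_factory(list(rng.integers(0, 3, 30)))
        freqs, _ = estimate_frequencies(db, "META1")
        loglik, _ = profile_loglik(profile, db, "META1")
        expectation, sd = loglik_moments(freqs)
        assert z_score(profile, db, "META1") == pytest.approx((expectation - loglik) / sd)

    def test_calibration_from_own_reference(self, db_factory):
        # profiles drawn from the shrunken reference frequencies themselves:
        # mean z ~ 0, var ~ 1, one-sided rejection at 1.64 ~ 5%
        rng = np.random.default_rng(5)
        m = 233
        db = db_factory([rng.uniform(0.1, 0.9, m)], totals=400)
        freqs, _ = estimate_frequencies(db, "META1")
        genotype_of = {2: ("A", "A"), 1: ("A", "G"), 0: ("G", "G")}
        zs = []
        for i in range(1000):
            dosages = rng.binomial(2, freqs)
            profile = AIMProfile(
                f"S{i}",
                {mk: genotype_of[d] for mk, d in zip(db.markers, dosages)},
            )
            zs.append(z_score(profile, db, "META1"))
        zs = np.array(zs)
        assert abs(zs.mean()) < 3 * zs.std() / math.sqrt(len(zs))
        assert abs(zs.var() - 1.0) < 0.10
        rejection = (zs > 1.64).mean()
        assert abs(rejection - 0.05) < 3 * math.sqrt(0.05 * 0.95 / len(zs))

    def test_loo_shifts_z_upward(self, frequency_set_factory, db_factory):
        # including the tested individual in its own reference flatters the fit
        from aimpanel.syndata import simulate_genotypes

        rng = np.random.default_rng(6)
        q = rng.uniform(0.2, 0.8, 100)
        freqs = frequency_set_factory([q])
        profiles = simulate_genotypes(freqs, "POP1", 60, seed=7)
        alleles = {m: ("A", "G") for m in freqs.markers}
        db = ReferenceDatabase.from_profiles(
            profiles, {p.sample: "POP1" for p in profiles}, alleles, min_individuals=1
        )
        diffs = [
            z_score(p, db, "POP1", loo=True) - z_score(p, db, "POP1", loo=False)
            for p in profiles
        ]
        assert np.mean(diffs) > 0
        assert np.min(diffs) > -1e-9  # LOO never flatters the fit


class TestLogLR:
    def test_same_meta_is_zero(self, db_factory, profile_factory):
        q = [0.3, 0.6, 0.8]
        db = db_factory([q, q], totals=400)
        value, _ = log_lr(profile_factory([1, 2, 0]), db, "META1", "META2")
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric(self, db_factory, profile_factory):
        rng = np.random.default_rng(8)
        db = db_factory(rng.uniform(0.1, 0.9, (2, 20)), totals=300)
        profile = profile_factory(list(rng.integers(0, 3, 20)))
        ab, _ = log_lr(profile, db, "META1", "META2")
        ba, _ = log_lr(profile, db, "META2", "META1")
        assert ab == pytest.approx(-ba, abs=1e-10)

    def test_telescoping(self, db_factory, profile_factory):
        rng = np.random.default_rng(9)
        db = db_factory(rng.uniform(0.1, 0.9, (3, 25)), totals=300)
        profile = profile_factory(list(rng.integers(0, 3, 25)))
        ab, _ = log_lr(profile, db, "META1", "META2")
        bc, _ = log_lr(profile, db, "META2", "META3")
        ac, _ = log_lr(profile, db, "META1", "META3")
        assert ab + bc == pytest.approx(ac, abs=1e-10)

    def test_mean_log_lr_grows_with_marker_count(self, db_factory):
        # expected log-LR is the summed per-locus KL divergence
        rng = np.random.default_rng(10)
        q = rng.uniform(0.15, 0.85, (2, 120))
        genotype_of = {2: ("A", "A"), 1: ("A", "G"), 0: ("G", "G")}
        means = []
        for m in (30, 120):
            db = db_factory(q[:, :m], totals=2000)
            freqs_a, _ = estimate_frequencies(db, "META1")
            values = []
            for i in range(300):
                dosages = rng.binomial(2, freqs_a)
                profile = AIMProfile(
                    f"S{i}", {mk: genotype_of[d] for mk, d in zip(db.markers, dosages)}
                )
                values.append(log_lr(profile, db, "META1", "META2")[0])
            means.append(np.mean(values))
        assert means[1] > means[0] > 0

    def test_se_closed_form_single_locus(self, db_factory, profile_factory):
        db = db_factory([[0.7], [0.3]], totals=10**9)
        _, se = log_lr(profile_factory([2]), db, "META1", "META2")
        probs = genotype_probs(0.7)
        diff = np.log(genotype_probs(0.7)) - np.log(genotype_probs(0.3))
        var = (probs * diff**2).sum() - ((probs * diff).sum()) ** 2
        assert se == pytest.approx(math.sqrt(var), abs=1e-4)


class TestClassifyProfile:
    def test_single_accepted_meta(self, db_factory, profile_factory):
        rng = np.random.default_rng(11)
        q1 = rng.uniform(0.05, 0.35, 80)
        q2 = 1.0 - q1  # strongly separated references
        db = db_factory([q1, q2], totals=500)
        dosages = list(rng.binomial(2, q1))  # a draw from META1
        result = classify_profile(profile_factory(dosages), db, z_threshold=1.64)
        assert result.accepted == ("META1",)
        assert result.category == "Accepted"
        assert result.meta_category["META2"] == "Rejected"

    def test_rejected_everywhere_no_lrs(self, db_factory, profile_factory):
        db = db_factory([np.full(60, 0.95), np.full(60, 0.9)], totals=500)
        result = classify_profile(profile_factory([0] * 60), db)
        assert result.category == "Rejected"
        assert result.accepted == ()
        assert result.loglr == {}

    def test_duplicate_references_ambiguous(self, db_factory, profile_factory):
        rng = np.random.default_rng(12)
        q = rng.uniform(0.3, 0.7, 80)
        db = db_factory([q, q], totals=500)
        dosages = list(rng.binomial(2, q))
        result = classify_profile(profile_factory(dosages), db)
        assert set(result.accepted) == {"META1", "META2"}
        assert result.category == "Ambiguous"

    def test_category_rederivable_from_stored_fields(self, db_factory, profile_factory):
        from scipy.stats import norm

        rng = np.random.default_rng(13)
        db = db_factory(rng.uniform(0.2, 0.8, (4, 60)), totals=400)
        critical = float(norm.ppf(0.95))
        for i in range(25):
            dosages = list(rng.integers(0, 3, 60))
            result = classify_profile(profile_factory(dosages, sample=f"S{i}"), db)
            accepted = tuple(m for m in db.meta_populations if result.z[m] <= 1.64)
            assert accepted == result.accepted
            if not accepted:
                assert result.category == "Rejected"
            elif len(accepted) == 1:
                assert result.category == "Accepted"
            else:
                best = max(accepted, key=lambda m: result.loglik[m])
                significant = all(
                    result.loglr[(best, other)][1] > 0
                    and result.loglr[(best, other)][0] / result.loglr[(best, other)][1]
                    > critical
                    for other in accepted
                    if other != best
                )
                assert result.category == ("Accepted" if significant else "Ambiguous")

    def test_z_vector_to_category_examples(self, db_factory, profile_factory):
        # indistinguishable references -> both accepted, no significant LR
        q = np.full(50, 0.5)
        db = db_factory([q, q], totals=500)
        result = classify_profile(profile_factory([1] * 50), db)
        assert result.category == "Ambiguous"
        assert result.meta_category == {"META1": "Ambiguous", "META2": "Ambiguous"}


class TestCrossValidate:
    def test_single_profile_single_meta(self, db_factory, profile_factory):
        rng = np.random.default_rng(14)
        q = rng.uniform(0.3, 0.7, 60)
        db = db_factory([q], totals=500, metas=["HOME"])
        dosages = list(rng.binomial(2, q))
        profile = profile_factory(dosages, sample="solo")
        summary = cross_validate(db, [profile], {"solo": "HOME"}, loo=False)
        assert len(summary) == 1
        assert summary.iloc[0]["accepted_pct"] == 100.0

    def test_rates_sum_to_100(self, frequency_set_factory):
        from aimpanel.syndata import simulate_genotypes

        rng = np.random.default_rng(15)
        q = rng.uniform(0.1, 0.9, (3, 50))
        freqs = frequency_set_factory(q)
        profiles = []
        origins = {}
        for pop in freqs.populations:
            drawn = simulate_genotypes(freqs, pop, 25, seed=16)
            profiles.extend(drawn)
            origins.update({p.sample: pop for p in drawn})
        alleles = {m: ("A", "G") for m in freqs.markers}
        db = ReferenceDatabase.from_profiles(profiles, origins, alleles, min_individuals=1)
        summary = cross_validate(db, profiles, origins)
        sums = summary["accepted_pct"] + summary["ambiguous_pct"] + summary["rejected_pct"]
        assert np.allclose(sums, 100.0)
        assert len(summary) == 9  # 3 origins x 3 tested

    def test_duplicate_meta_population_mostly_ambiguous(self, db_factory):
        rng = np.random.default_rng(17)
        q = rng.uniform(0.3, 0.7, 80)
        db = db_factory([q, q], totals=800, metas=["A", "B"])
        genotype_of = {2: ("A", "A"), 1: ("A", "G"), 0: ("G", "G")}
        profiles = []
        origins = {}
        for i in range(40):
            dosages = rng.binomial(2, q)
            profile = AIMProfile(
                f"S{i}", {m: genotype_of[d] for m, d in zip(db.markers, dosages)}
            )
            profiles.append(profile)
            origins[profile.sample] = "A"
        summary = cross_validate(db, profiles, origins, loo=False)
        own = summary[(summary["origin"] == "A") & (summary["tested"] == "A")].iloc[0]
        assert own["ambiguous_pct"] > own["accepted_pct"]

    def test_unmapped_profile_rejected(self, db_factory, profile_factory):
        db = db_factory([[0.5]], metas=["HOME"])
        with pytest.raises(ValidationError):
            cross_validate(db, [profile_factory([1], sample="x")], {})


class TestSummaryTotal:
    def test_counts_each_origin_once(self):
        import pandas as pd

        rows = []
        for origin, size in [("EU", 398), ("ME", 371), ("NA", 75), ("NEA", 149), ("SCA", 77)]:
            for tested in ["EU", "ME", "NA", "NEA", "SCA"]:
                rows.append(
                    {"origin": origin, "size": size, "tested": tested, "panel": "all",
                     "accepted_pct": 0.0, "ambiguous_pct": 0.0, "rejected_pct": 100.0}
                )
        assert summary_total_individuals(pd.DataFrame(rows)) == 1070


class TestReferenceDatabase:
    def test_tsv_roundtrip(self, tmp_path, db_factory):
        rng = np.random.default_rng(18)
        db = db_factory(rng.uniform(0.1, 0.9, (2, 5)), totals=150)
        db.to_tsv(tmp_path / "db.tsv")
        back = ReferenceDatabase.from_tsv(tmp_path / "db.tsv", min_individuals=1)
        assert back.meta_populations == db.meta_populations
        assert back.markers == db.markers
        np.testing.assert_allclose(back.allele1, db.allele1)
        np.testing.assert_allclose(back.totals, db.totals)

    def test_small_reference_warns(self):
        with pytest.warns(UserWarning):
            ReferenceDatabase(
                meta_populations=("META1",),
                markers=("M1",),
                alleles={"M1": ("A", "G")},
                allele1=np.array([[10.0]]),
                totals=np.array([[40.0]]),  # 20 individuals < 75
            )

    def test_count_consistency_enforced(self):
        with pytest.raises(ValidationError):
            ReferenceDatabase(
                meta_populations=("META1",),
                markers=("M1",),
                alleles={"M1": ("A", "G")},
                allele1=np.array([[50.0]]),
                totals=np.array([[40.0]]),
                min_individuals=1,
            )

    def test_from_profiles_counts(self, profile_factory):
        profiles = [
            profile_factory([2, 1], sample="a"),
            profile_factory([0, None], sample="b"),
        ]
        alleles = {"M0001": ("A", "G"), "M0002": ("A", "G")}
        db = ReferenceDatabase.from_profiles(
            profiles, {"a": "P1", "b": "P1"}, alleles, min_individuals=1
        )
        np.testing.assert_allclose(db.allele1, [[2.0, 1.0]])
        np.testing.assert_allclose(db.totals, [[4.0, 2.0]])
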
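"""Bootstrap SEs, the paired pick-1-by-1 test and the letter display."""

import math

import numpy as np
import pytest

from agestage import (
    IndividualRecord,
    bootstrap_population_parameters,
    bootstrap_statistic,
    letter_groups,
    make_cohort,
    paired_difference_test,
    summarize_cohort,
)
from agestage.bootstrap import BootstrapDistribution, PairedTestResult


def survivor(i):
    return IndividualRecord(
        f"S{i:03d}", (("egg", 1), ("adult", 1)), sex="M", fate="survived_to_natural_death"
    )


def casualty(i):
    return IndividualRecord(f"D{i:03d}", (("egg", 1),))


def binary_cohort(n_survive, n_total, label="c"):
    """Minimal cohort where pre-adult survival is the only varying statistic."""
    recs = [survivor(i) for i in range(n_survive)]
    recs += [casualty(i) for i in range(n_total - n_survive)]
    return make_cohort(label, recs)


class TestBootstrapStatistic:
    def test_degenerate_cohort_has_zero_se(self):
        cohort = binary_cohort(8, 8)
        dist = bootstrap_statistic(cohort, "preadult_survival", B=200, seed=1)
        assert np.all(dist.replicates == 100.0)
        assert dist.SE == 0.0

    def test_seeded_determinism(self):
        cohort = binary_cohort(5, 12)
        d1 = bootstrap_statistic(cohort, "preadult_survival", B=500, seed=7)
        d2 = bootstrap_statistic(cohort, "preadult_survival", B=500, seed=7)
        assert np.array_equal(d1.replicates, d2.replicates)
        d3 = bootstrap_statistic(cohort, "preadult_survival", B=500, seed=8)
        assert not np.array_equal(d1.replicates, d3.replicates)

    def test_se_invariant_to_individual_ordering(self):
        recs = [survivor(i) for i in range(5)] + [casualty(i) for i in range(7)]
        a = make_cohort("c", recs)
        b = make_cohort("c", list(reversed(recs)))
        da = bootstrap_statistic(a, "preadult_survival", B=400, seed=3)
        db = bootstrap_statistic(b, "preadult_survival", B=400, seed=3)
        assert np.array_equal(da.replicates, db.replicates)

    def test_proportion_se_matches_binomial_closed_form(self):
        n, k = 102, 49
        cohort = binary_cohort(k, n)
        dist = bootstrap_statistic(cohort, "preadult_survival", B=10_000, seed=42)
        p = k / n
        closed = 100.0 * math.sqrt(p * (1 - p) / n)
        assert dist.SE == pytest.approx(closed, rel=0.02)

    def test_fast_and_general_paths_agree(self, cohort_25c):
        fast = bootstrap_statistic(cohort_25c, "fecundity", B=60, seed=5)
        slow = bootstrap_statistic(
            cohort_25c,
            lambda co: summarize_cohort(co).fecundity.mean,
            B=60,
            seed=5,
            name="fecundity",
        )
        assert np.allclose(fast.replicates, slow.replicates, equal_nan=True)

    def test_invalid_replicates_counted_and_warned(self):
        # 1 female among 4: many resamples contain no female -> fecundity NaN
        recs = [
            IndividualRecord("F0", (("egg", 1), ("adult", 2)), sex="F",
                             fate="survived_to_natural_death", daily_eggs={2: 3}),
            *[casualty(i) for i in range(3)],
        ]
        cohort = make_cohort("c", recs)
        with pytest.warns(UserWarning, match="not estimable"):
            dist = bootstrap_statistic(cohort, "fecundity", B=500, seed=0)
        assert dist.n_invalid > 0
        assert dist.n_invalid + len(dist.values) == dist.B
        assert dist.high_invalid_warning

    def test_all_invalid_raises(self):
        cohort = make_cohort("c", [casualty(0), casualty(1)])
        with pytest.raises(ValueError, match="not estimable"):
            bootstrap_statistic(cohort, "fecundity", B=50, seed=0)

    def test_population_parameters_joint_replicates(self, cohort_25c):
        dists = bootstrap_population_parameters(cohort_25c, B=300, seed=9)
        r, lam, R0, T = (dists[k].replicates for k in ("r", "lambda", "R0", "T"))
        ok = np.isfinite(r)
        assert np.allclose(lam[ok], np.exp(r[ok]))
        assert np.allclose(T[ok], np.log(R0[ok]) / r[ok])


def make_dist(values, name="s"):
    arr = np.asarray(values, dtype=float)
    return BootstrapDistribution(
        statistic_name=name, B=len(arr), replicates=arr, seed=0,
        point_estimate=float(np.nanmean(arr)),
    )


class TestPairedTest:
    def test_self_comparison_is_null(self):
        d = make_dist(np.linspace(0, 10, 200))
        res = paired_difference_test(d, d)
        assert res.difference_CI == (0.0, 0.0)
        assert not res.significant

    def test_degenerate_shift_significant(self):
        a = make_dist(np.full(150, 10.0))
        b = make_dist(np.full(150, 7.0))
        res = paired_difference_test(a, b)
        assert res.difference_CI == (3.0, 3.0)
        assert res.significant

    def test_shifted_copy_detected(self, rng):
        base = rng.normal(50, 2, size=2000)
        delta = 5.0
        a = make_dist(base + delta + rng.normal(0, 0.1, size=2000))
        b = make_dist(base)
        res = paired_difference_test(a, b)
        d = a.replicates - b.replicates
        assert res.difference_CI == pytest.approx(
            (np.percentile(d, 2.5), np.percentile(d, 97.5))
        )
        assert res.significant
        assert res.difference_point_estimate == pytest.approx(delta, abs=0.05)

    def test_antisymmetry(self, rng):
        a = make_dist(rng.normal(3, 1, 500))
        b = make_dist(rng.normal(2, 1, 500))
        ab = paired_difference_test(a, b)
        ba = paired_difference_test(b, a)
        assert ab.difference_CI[0] == pytest.approx(-ba.difference_CI[1])
        assert ab.difference_CI[1] == pytest.approx(-ba.difference_CI[0])
        assert ab.significant == ba.significant

    def test_unequal_B_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            paired_difference_test(make_dist(np.zeros(100)), make_dist(np.zeros(101)))

    def test_too_few_valid_pairs_rejected(self):
        a = make_dist(np.full(150, np.nan))
        with pytest.raises(ValueError, match="valid replicate pairs"):
            paired_difference_test(a, make_dist(np.zeros(150)))


def fake_pairwise(labels, estimates, sig_pairs):
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            sig = frozenset((a, b)) in sig_pairs
            diff = estimates[a] - estimates[b]
            ci = (diff - 0.1, diff + 0.1) if sig else (min(diff, 0) - 1, max(diff, 0) + 1)
            out[(a, b)] = PairedTestResult(
                statistic_name="s", label_a=a, label_b=b,
                difference_point_estimate=diff, difference_CI=ci,
                significant=sig, n_pairs=1000,
            )
    return out


class TestLetterGroups:
    def test_all_pairs_significant(self):
        labels = ["hot", "mid", "cold"]
        est = {"hot": 30.0, "mid": 20.0, "cold": 10.0}
        pw = fake_pairwise(labels, est, {
            frozenset(p) for p in [("hot", "mid"), ("hot", "cold"), ("mid", "cold")]
        })
        assert letter_groups(labels, pw, est) == {"hot": "a", "mid": "b", "cold": "c"}

    def test_no_pair_significant(self):
        labels = ["x", "y", "z"]
        est = {"x": 3.0, "y": 2.0, "z": 1.0}
        assert letter_groups(labels, fake_pairwise(labels, est, set()), est) == {
            "x": "a", "y": "a", "z": "a"
        }

    def test_only_extremes_differ(self):
        labels = ["t1", "t2", "t3", "t4"]
        est = {"t1": 4.0, "t2": 3.0, "t3": 2.0, "t4": 1.0}
        pw = fake_pairwise(labels, est, {frozenset(("t1", "t4"))})
        assert letter_groups(labels, pw, est) == {
            "t1": "a", "t2": "ab", "t3": "ab", "t4": "b"
        }

    def test_shared_letter_iff_not_significant_when_transitive(self):
        labels = ["a1", "a2", "b1"]
        est = {"a1": 10.0, "a2": 9.0, "b1": 1.0}
        pw = fake_pairwise(labels, est, {frozenset(("a1", "b1")), frozenset(("a2", "b1"))})
        letters = letter_groups(labels, pw, est)
        for (a, b), res in pw.items():
            shared = set(letters[a]) & set(letters[b])
            assert res.significant == (not shared)
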
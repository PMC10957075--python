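"""Survey summaries, flag reduction, Fisher/Welch/chi-squared benchmarks."""

import math
from itertools import combinations

import numpy as np
import pytest

from ablint.detect import FlagAnnotation, LiabilityHit, SequenceProfile
from ablint.numbering import ImgtPosition
from ablint.reference import SeverityLevel
from ablint.stats import (
    BenchmarkRecord,
    ContingencyTable2x2,
    benchmark_flags,
    chi2_pairwise_bonferroni,
    fisher_exact,
    region_distribution,
    summarize_dataset,
    two_sample_t,
)


def fisher_enumeration_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p over all tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def make_profile(uid, n_hits, flagged=0, tag="DeAmdH", start=56):
    """Profile with n_hits liabilities, the first `flagged` germline-benign."""
    hits = []
    for i in range(n_hits):
        hits.append(
            LiabilityHit(
                chain_id=f"{uid}_H",
                chain_type="H",
                motif_tag=tag,
                severity=SeverityLevel.HIGH,
                residues=[(ImgtPosition(start), "N"), (ImgtPosition(start + 1), "G")],
                attribution="cdr",
                flags=FlagAnnotation(germline=(i < flagged)),
            )
        )
    return SequenceProfile(unit_id=uid, hits=hits)


class TestSummarizeDataset:
    def test_basic_counts(self):
        profiles = [make_profile(f"u{i}", n) for i, n in enumerate([2, 0, 3, 1])]
        s = summarize_dataset(profiles, combos=[()])
        assert s.n_units == 4
        assert s.pct_with_liability == pytest.approx(75.0)
        assert s.total_liabilities == 6
        assert s.mean_liabilities == pytest.approx(1.5)
        assert s.median_liabilities == pytest.approx(1.5)

    def test_empty_combo_removes_nothing(self):
        profiles = [make_profile("u0", 3, flagged=2)]
        s = summarize_dataset(profiles, combos=[()])
        assert s.remaining_liabilities["none"] == s.total_liabilities

    def test_known_benign_fraction(self):
        """Generator marks a known 40% of liabilities benign -> remaining 60%."""
        profiles = [make_profile(f"u{i}", 5, flagged=2) for i in range(10)]
        s = summarize_dataset(profiles, combos=[(), ("germline",)])
        assert s.total_liabilities == 50
        assert s.remaining_liabilities["germline"] == 30

    def test_monotonicity_and_conservation(self):
        rng = np.random.default_rng(0)
        flags = ["germline", "therapeutic", "surface"]
        combos = [()] + [(f,) for f in flags] + [
            tuple(c) for r in (2, 3) for c in combinations(flags, r)
        ]
        for trial in range(25):
            profiles = []
            for u in range(rng.integers(2, 8)):
                hits = []
                for i in range(rng.integers(0, 6)):
                    hits.append(
                        LiabilityHit(
                            chain_id=f"u{u}_H", chain_type="H", motif_tag="MetOx",
                            severity=SeverityLevel.MEDIUM,
                            residues=[(ImgtPosition(30 + i), "M")],
                            attribution="cdr",
                            flags=FlagAnnotation(
                                germline=bool(rng.integers(2)),
                                therapeutic=bool(rng.integers(2)),
                                surface=str(
                                    rng.choice(["exposed", "buried", "partial"])
                                ),
                            ),
                        )
                    )
                profiles.append(SequenceProfile(unit_id=f"u{u}", hits=hits))
            s = summarize_dataset(profiles, combos=combos)
            total = s.total_liabilities
            all_key = "germline+surface+therapeutic"
            for single in flags:
                assert s.remaining_liabilities[all_key] <= \
                    s.remaining_liabilities[single] <= total
                assert s.remaining_sequences[all_key] <= \
                    s.remaining_sequences[single] <= s.remaining_sequences["none"]
            # conservation: benign + non-benign = total for every combo
            for combo in combos:
                key = "+".join(sorted(combo)) if combo else "none"
                benign = sum(
                    sum(1 for h in p.hits if h.flags.benign_under(combo))
                    for p in profiles
                )
                assert benign + s.remaining_liabilities[key] == total

    def test_permutation_invariance(self):
        profiles = [make_profile(f"u{i}", n, flagged=n // 2)
                    for i, n in enumerate([2, 5, 0, 3])]
        a = summarize_dataset(profiles)
        b = summarize_dataset(profiles[::-1])
        assert a.to_dict() == b.to_dict()

    def test_grouping(self):
        p1 = make_profile("u1", 2)
        p1.species_label = "human"
        p2 = make_profile("u2", 4)
        p2.species_label = "nonhuman"
        grouped = summarize_dataset([p1, p2], group_by="species_label")
        assert grouped["human"].total_liabilities == 2
        assert grouped["nonhuman"].total_liabilities == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_dataset([])


class TestRegionDistribution:
    def test_cdr_and_boundary_bins(self):
        cdr = make_profile("u1", 2)  # NG at 56-57, CDR2
        boundary = make_profile("u2", 1, start=38)  # 38-39 straddles CDR1/FR2
        dist = region_distribution([cdr, boundary])
        assert dist["CDR2"] == 2
        assert dist["CDR1-FR2"] == 1

    def test_matches_recount(self, default_ref, small_cohort):
        from ablint.detect import profile_antibody

        units, _ = small_cohort
        profiles = [profile_antibody(u, default_ref) for u in units]
        dist = region_distribution(profiles)
        assert sum(dist.values()) == sum(p.n_liabilities for p in profiles)


class TestFisherExact:
    @pytest.mark.parametrize(
        "cells,significant",
        [
            (((5, 26), (4, 17)), False),   # germline flag: not significant
            (((10, 21), (17, 4)), True),   # surface flag
            (((5, 26), (10, 11)), True),   # therapeutic flag
            (((12, 19), (19, 2)), True),   # all flags
        ],
    )
    def test_oxidation_benchmark_significance_pattern(self, cells, significant):
        (a, b), (c, d) = cells
        p, _ = fisher_exact(ContingencyTable2x2(a, b, c, d))
        assert (p <= 0.05) == significant
        assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), abs=1e-12)

    def test_uniform_table_p_one(self):
        p, odds = fisher_exact(ContingencyTable2x2(1, 1, 1, 1))
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_matches_enumeration_on_small_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 16, size=4)
            if a + b + c + d == 0:
                continue
            p, _ = fisher_exact(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(
                fisher_enumeration_oracle(int(a), int(b), int(c), int(d)),
                abs=1e-10,
            )

    def test_odds_ratio_conventions(self):
        _, odds = fisher_exact(ContingencyTable2x2(5, 0, 1, 3))
        assert math.isinf(odds)
        _, odds = fisher_exact(ContingencyTable2x2(0, 5, 3, 1))
        assert odds == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestTwoSampleT:
    def test_identical_samples_p_one(self):
        assert two_sample_t([3.0, 3.0, 3.0], [3.0, 3.0]) == 1.0

    def test_separated_samples_significant(self):
        a = [0.0, 0.1, 0.05, 0.02]
        b = [100.0, 99.9, 99.95, 100.05]
        assert two_sample_t(a, b) < 1e-3

    def test_matches_frozen_welch_value(self):
        """Hand-computed Welch statistic: t = -7.7766, df = 5.9379."""
        a = [12.1, 14.3, 9.8, 11.0, 13.5]
        b = [22.4, 19.9, 25.1, 23.3]
        assert two_sample_t(a, b) == pytest.approx(2.504348e-4, rel=1e-5)

    def test_needs_two_per_sample(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestChi2Pairwise:
    def test_identical_histograms_p_adjusted_one(self):
        counts = {"a": [0, 1, 1, 2, 3] * 10, "b": [0, 1, 1, 2, 3] * 10}
        out = chi2_pairwise_bonferroni(counts)
        assert out[("a", "b")] == pytest.approx(1.0)

    def test_bonferroni_multiplies_by_pair_count(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        counts = {
            k: list(rng.poisson(lam, size=200))
            for k, lam in (("a", 2.0), ("b", 2.2), ("c", 4.0))
        }
        out = chi2_pairwise_bonferroni(counts)
        assert len(out) == 3  # three pairs
        for (x, y), p_adj in out.items():
            assert 0.0 <= p_adj <= 1.0
        # raw chi2 recomputed for one pair must give p_adj = min(1, 3p)
        from collections import Counter

        cx, cy = Counter(counts["a"]), Counter(counts["c"])
        top = max(list(cx) + list(cy))
        hx = [cx.get(k, 0) for k in range(top + 1)]
        hy = [cy.get(k, 0) for k in range(top + 1)]
        keep = [i for i in range(top + 1) if hx[i] + hy[i] > 0]
        obs = np.array([[hx[i] for i in keep], [hy[i] for i in keep]])
        expected = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        if expected.min() >= 1.0:  # no pooling path triggered
            raw = sps.chi2_contingency(obs)[1]
            assert out[("a", "c")] == pytest.approx(min(1.0, raw * 3))


class TestBenchmarkFlags:
    def _profiles_and_records(self, flagged_low=True):
        rng = np.random.default_rng(4)
        profiles, records = [], []
        for u in range(24):
            flagged = u % 2 == 0
            p = make_profile(f"t{u}", 1, flagged=1 if flagged else 0)
            profiles.append(p)
            value = float(rng.uniform(0, 10) if flagged and flagged_low
                          else rng.uniform(30, 80))
            records.append(
                BenchmarkRecord(
                    therapeutic_id=f"t{u}", motif="NG", imgt_position="56",
                    condition="deamidation_low_pH", value=value,
                )
            )
        return profiles, records

    def test_flagged_distribution_lower(self):
        profiles, records = self._profiles_and_records()
        out = benchmark_flags(records, profiles, combos=[("germline",)])
        bucket = out["percent_modification"]["deamidation_low_pH"]["germline"]
        assert np.median(bucket["flagged"]) < np.median(bucket["unflagged"])

    def test_training_exclusion_empties_comparison(self):
        profiles, records = self._profiles_and_records()
        records = [
            BenchmarkRecord(r.therapeutic_id, r.motif, r.imgt_position,
                            r.condition, r.value, in_flag_training=True)
            for r in records
        ]
        with pytest.warns(UserWarning, match="empty"):
            out = benchmark_flags(records, profiles, combos=[("germline",)])
        assert out["percent_modification"] == {}

    def test_unmatched_records_listed_not_fatal(self):
        profiles, records = self._profiles_and_records()
        stray = BenchmarkRecord("missing", "NG", "56",
                                "deamidation_low_pH", 5.0)
        out = benchmark_flags(records + [stray], profiles,
                              combos=[("germline",)])
        assert stray in out["unmatched"]

    def test_oxidation_contingency(self):
        """Methionine-annotated molecules sort into a 2x2 oxidation table."""
        profiles, records = [], []
        for u in range(30):
            flagged = u < 15
            hits = [
                LiabilityHit(
                    chain_id=f"t{u}_H", chain_type="H", motif_tag="MetOx",
                    severity=SeverityLevel.MEDIUM,
                    residues=[(ImgtPosition(30), "M")],
                    attribution="cdr",
                    flags=FlagAnnotation(surface="buried" if flagged else "exposed"),
                )
            ]
            profiles.append(SequenceProfile(unit_id=f"t{u}", hits=hits))
            oxidized = not flagged  # flag perfectly predicts non-oxidation
            records.append(
                BenchmarkRecord(f"t{u}", "M", "30", "oxidation",
                                1.0 if oxidized else 0.0)
            )
        out = benchmark_flags(records, profiles, combos=[("surface",)])
        entry = out["oxidation"]["surface"]
        assert entry["table"] == [[0, 15], [15, 0]]
        assert entry["p"] <= 0.05
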
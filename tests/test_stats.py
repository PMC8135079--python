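"""Regional ANOVA, Bonferroni correction, screens and the candidate cascade."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plf.ingest import SampleDesign
from plf.quant import RegionCountMatrix
from plf.reference import ProteinRecord, segment_fixed
from plf.stats import (
    bonferroni_correct,
    candidate_pipeline,
    intragroup_screen,
    presence_filter,
    regional_test,
    significance_tier,
)

from conftest import make_obs


def normalized_matrix(values_by_region, samples):
    """Hand-built normalized matrix: {(accession, idx): per-sample values}."""
    index = pd.MultiIndex.from_tuples(
        list(values_by_region), names=["accession", "region_index"]
    )
    values = pd.DataFrame(
        [values_by_region[k] for k in values_by_region],
        index=index,
        columns=samples,
        dtype=float,
    )
    meta = pd.DataFrame(
        [
            (acc, idx, (idx - 1) * 50 + 1, idx * 50, 50)
            for acc, idx in values_by_region
        ],
        columns=["accession", "region_index", "start", "end", "length"],
        index=index,
    )
    schemes = {}
    for acc in {a for a, _ in values_by_region}:
        n = max(i for a, i in values_by_region if a == acc)
        protein = ProteinRecord(accession=acc, sequence="A" * (50 * n))
        schemes[acc] = segment_fixed(protein, 50)
    return RegionCountMatrix(
        values=values, meta=meta, stage="normalized", schemes=schemes
    )


def paired_design_n(n, groups=("A", "B")):
    samples, subjects = {}, {}
    for i in range(1, n + 1):
        for g in groups:
            s = f"D{i}_{g}"
            samples[s] = g
            subjects[s] = f"D{i}"
    return SampleDesign(
        sample_to_group=samples, sample_to_subject=subjects, groups=groups
    )


def unpaired_design(n1, n2):
    groups = {f"a{i}": "A" for i in range(n1)} | {f"b{i}": "B" for i in range(n2)}
    return SampleDesign(sample_to_group=groups, groups=("A", "B"))


class TestRegionalTest:
    def test_paired_zero_differences(self):
        design = paired_design_n(4)
        g1 = [1.0, 2.0, 3.0, 4.0]
        matrix = normalized_matrix(
            {("P1", 1): g1 + g1}, [f"D{i}_A" for i in range(1, 5)] + [f"D{i}_B" for i in range(1, 5)]
        )
        out = regional_test(matrix, design, paired=True)
        assert out.loc[("P1", 1), "F"] == 0.0
        assert out.loc[("P1", 1), "p_raw"] == 1.0

    def test_paired_f_equals_squared_paired_t(self, rng):
        """Two-level repeated-measures ANOVA is the squared paired t test."""
        design = paired_design_n(7)
        samples = [f"D{i}_A" for i in range(1, 8)] + [f"D{i}_B" for i in range(1, 8)]
        for trial in range(300):
            g1 = rng.normal(5, 2, size=7)
            g2 = rng.normal(5 + rng.normal(0, 1), 2, size=7)
            matrix = normalized_matrix({("P1", 1): list(g1) + list(g2)}, samples)
            out = regional_test(matrix, design, paired=True)
            t, p = sps.ttest_rel(g2, g1)
            assert out.loc[("P1", 1), "F"] == pytest.approx(t**2, rel=1e-9)
            assert out.loc[("P1", 1), "p_raw"] == pytest.approx(p, rel=1e-9)

    def test_unpaired_f_equals_squared_pooled_t(self, rng):
        design = unpaired_design(5, 4)
        samples = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(4)]
        for trial in range(300):
            g1 = rng.normal(5, 2, size=5)
            g2 = rng.normal(6, 2, size=4)
            matrix = normalized_matrix({("P1", 1): list(g1) + list(g2)}, samples)
            out = regional_test(matrix, design, paired=False)
            t, p = sps.ttest_ind(g2, g1, equal_var=True)
            assert out.loc[("P1", 1), "F"] == pytest.approx(t**2, rel=1e-9)
            assert out.loc[("P1", 1), "p_raw"] == pytest.approx(p, rel=1e-9)

    def test_all_zero_region_untested(self):
        design = paired_design_n(3)
        samples = [f"D{i}_A" for i in range(1, 4)] + [f"D{i}_B" for i in range(1, 4)]
        matrix = normalized_matrix(
            {("P1", 1): [0.0] * 6, ("P1", 2): [1, 2, 3, 4, 5, 6]}, samples
        )
        out = regional_test(matrix, design, paired=True)
        assert not out.loc[("P1", 1), "tested"]
        assert np.isnan(out.loc[("P1", 1), "p_raw"])
        assert out.loc[("P1", 2), "tested"]

    def test_degenerate_zero_variance_unequal_means(self):
        """Constant-but-different groups give p=0 with the degenerate flag
        instead of an exception."""
        design = paired_design_n(3)
        samples = [f"D{i}_A" for i in range(1, 4)] + [f"D{i}_B" for i in range(1, 4)]
        matrix = normalized_matrix({("P1", 1): [1, 1, 1, 3, 3, 3]}, samples)
        out = regional_test(matrix, design, paired=True)
        assert out.loc[("P1", 1), "p_raw"] == 0.0
        assert out.loc[("P1", 1), "degenerate"]


class TestBonferroni:
    def _results(self, p_values, accessions=None):
        accessions = accessions or ["P1"] * len(p_values)
        index = pd.MultiIndex.from_tuples(
            [(a, i + 1) for i, a in enumerate(accessions)],
            names=["accession", "region_index"],
        )
        return pd.DataFrame(
            {
                "F": 1.0,
                "p_raw": p_values,
                "tested": [not np.isnan(p) for p in p_values],
                "degenerate": False,
                "n": 7,
            },
            index=index,
        )

    def test_multiplies_by_tested_family_size(self):
        out = bonferroni_correct(self._results([0.01] * 5))
        assert out["p_bonferroni"].iloc[0] == pytest.approx(0.05)

    def test_caps_at_one(self):
        out = bonferroni_correct(self._results([0.3] * 4))
        assert (out["p_bonferroni"] == 1.0).all()

    def test_single_region_family_is_identity(self):
        out = bonferroni_correct(self._results([0.123]))
        assert out["p_bonferroni"].iloc[0] == pytest.approx(0.123)

    def test_untested_regions_excluded_from_family(self):
        out = bonferroni_correct(self._results([0.01, np.nan, 0.02]))
        assert out["family_size"].iloc[0] == 2
        assert out["p_bonferroni"].iloc[0] == pytest.approx(0.02)
        assert np.isnan(out["p_bonferroni"].iloc[1])

    def test_per_protein_vs_experiment_wide(self):
        results = self._results([0.01, 0.01], accessions=["P1", "P2"])
        per_protein = bonferroni_correct(results, family="per_protein")
        np.testing.assert_allclose(per_protein["p_bonferroni"].to_numpy(), 0.01)
        wide = bonferroni_correct(results, family="experiment_wide")
        np.testing.assert_allclose(wide["p_bonferroni"].to_numpy(), 0.02)

    def test_corrected_never_below_raw(self, rng):
        p = rng.uniform(size=30)
        out = bonferroni_correct(self._results(list(p)))
        assert (out["p_bonferroni"] >= out["p_raw"] - 1e-15).all()

    def test_tiers(self):
        assert significance_tier(0.0005) == "***"
        assert significance_tier(0.005) == "**"
        assert significance_tier(0.05) == "*"
        assert significance_tier(0.051) == "ns"
        assert significance_tier(np.nan) == "ns"


class TestIntragroupScreen:
    def test_constant_within_group_never_flagged(self):
        design = unpaired_design(6, 6)
        samples = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
        matrix = normalized_matrix({("P1", 1): [5.0] * 6 + [9.0] * 6}, samples)
        flags = intragroup_screen(matrix, design, matrix.values.index, seed=0)
        assert not flags["intragroup_variable"].any()

    def test_bimodal_group_matches_split_enumeration_oracle(self):
        """A {0,0,0,10,10,10} group: brute-force enumeration of all 3-3
        splits fixes the expected flags.  Mixed splits put lows and highs
        in both halves, so the median split p is large and the default
        (median) rule does not fire; the min rule fires on the one split
        that separates the modes exactly."""
        design = unpaired_design(6, 6)
        samples = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
        matrix = normalized_matrix(
            {("P1", 1): [0.0, 0, 0, 10, 10, 10] + [5.0] * 6}, samples
        )
        values = np.array([0.0, 0, 0, 10, 10, 10])
        ps = []
        for c in combinations(range(6), 3):
            a = values[list(c)]
            b = values[[i for i in range(6) if i not in c]]
            if np.ptp(np.concatenate([a, b])) == 0:
                ps.append(1.0)
            else:
                ps.append(sps.ttest_ind(a, b, equal_var=True).pvalue)
        expected_median = bool(np.median(ps) < 0.05)
        expected_min = bool(np.min(ps) < 0.05)
        assert (expected_median, expected_min) == (False, True)

        flags = intragroup_screen(
            matrix, design, matrix.values.index, n_splits=20, seed=0
        )
        assert bool(flags.loc[("P1", 1), "intragroup_g1"]) == expected_median
        sensitive = intragroup_screen(
            matrix, design, matrix.values.index, n_splits=20, seed=0,
            split_agg="min",
        )
        assert bool(sensitive.loc[("P1", 1), "intragroup_g1"]) == expected_min
        assert not sensitive.loc[("P1", 1), "intragroup_g2"]

    def test_reproducible_under_seed(self, rng):
        design = unpaired_design(7, 7)
        samples = [f"a{i}" for i in range(7)] + [f"b{i}" for i in range(7)]
        regions = {
            ("P1", i): list(rng.gamma(2, 2, size=14)) for i in range(1, 6)
        }
        matrix = normalized_matrix(regions, samples)
        first = intragroup_screen(matrix, design, matrix.values.index, seed=42)
        second = intragroup_screen(matrix, design, matrix.values.index, seed=42)
        pd.testing.assert_frame_equal(first, second)

    def test_small_groups_skipped(self):
        design = unpaired_design(3, 3)
        samples = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        matrix = normalized_matrix({("P1", 1): [0, 5, 10, 1, 1, 1]}, samples)
        flags = intragroup_screen(matrix, design, matrix.values.index, seed=0)
        assert not flags["intragroup_variable"].any()

    def test_cv_strategy(self):
        design = unpaired_design(4, 4)
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        matrix = normalized_matrix(
            {("P1", 1): [0.1, 0.1, 20, 20, 3, 3, 3, 3]}, samples
        )
        flags = intragroup_screen(
            matrix, design, matrix.values.index, strategy="cv_threshold",
            cv_threshold=1.0,
        )
        assert flags.loc[("P1", 1), "intragroup_g1"]
        assert not flags.loc[("P1", 1), "intragroup_g2"]


class TestPresenceFilter:
    def test_single_group_protein_excluded(self):
        design = unpaired_design(2, 2)
        obs = make_obs(
            [("P1", "AAK", [3, 1, 0, 0]), ("P2", "CCK", [1, 0, 2, 1])],
            ["a0", "a1", "b0", "b1"],
        )
        out = presence_filter(obs, design)
        assert out.loc["P1", "excluded_single_group_presence"]
        assert not out.loc["P2", "excluded_single_group_presence"]

    def test_min_samples_threshold(self):
        design = unpaired_design(4, 4)
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        obs = make_obs([("P1", "AAK", [1, 1, 1, 0, 1, 1, 1, 1])], samples)
        lax = presence_filter(obs, design, min_samples=1)
        assert not lax.loc["P1", "excluded_single_group_presence"]
        strict = presence_filter(obs, design, min_samples=4)
        assert strict.loc["P1", "presence_g2"]
        assert not strict.loc["P1", "presence_g1"]
        assert strict.loc["P1", "excluded_single_group_presence"]


class TestCandidatePipeline:
    def _cascade(self, p_bonf, intragroup, presence_rows):
        index = pd.MultiIndex.from_tuples(
            list(p_bonf), names=["accession", "region_index"]
        )
        results = pd.DataFrame(
            {
                "F": 5.0,
                "p_raw": [p_bonf[k] for k in p_bonf],
                "tested": True,
                "degenerate": False,
                "n": 7,
                "family_size": 1,
                "p_bonferroni": [p_bonf[k] for k in p_bonf],
                "tier": "*",
            },
            index=index,
        )
        flags = pd.DataFrame(
            {
                "intragroup_g1": False,
                "intragroup_g2": False,
                "intragroup_variable": [intragroup.get(k, False) for k in p_bonf],
            },
            index=index,
        )
        presence = pd.DataFrame(
            presence_rows, columns=["presence_g1", "presence_g2"]
        ).rename_axis("accession")
        presence["excluded_single_group_presence"] = (
            presence["presence_g1"] != presence["presence_g2"]
        )
        return candidate_pipeline(results, flags, presence)

    def test_cascade_order_and_counts(self):
        report = self._cascade(
            p_bonf={("P1", 1): 0.01, ("P2", 1): 0.04, ("P3", 1): 0.5},
            intragroup={("P2", 1): True},
            presence_rows=pd.DataFrame(
                {"presence_g1": [True, True, True], "presence_g2": [True, True, True]},
                index=["P1", "P2", "P3"],
            ),
        )
        assert report.stage_regions == (2, 1, 1)
        assert report.candidate_proteins == ["P1"]

    def test_single_group_protein_removed_at_stage_three(self):
        report = self._cascade(
            p_bonf={("P1", 1): 0.01},
            intragroup={},
            presence_rows=pd.DataFrame(
                {"presence_g1": [True], "presence_g2": [False]}, index=["P1"]
            ),
        )
        assert report.stage_regions == (1, 1, 0)
        assert report.candidates.empty

    def test_empty_report_when_nothing_significant(self):
        report = self._cascade(
            p_bonf={("P1", 1): 0.9, ("P2", 1): 0.7},
            intragroup={},
            presence_rows=pd.DataFrame(
                {"presence_g1": [True, True], "presence_g2": [True, True]},
                index=["P1", "P2"],
            ),
        )
        assert report.stage_regions == (0, 0, 0)
        assert report.stage_proteins == (0, 0, 0)

    def test_recovers_planted_truth(self, small_experiment):
        """On a clean simulation the cascade reports the modified regions."""
        from plf.ingest import filter_exclusive, validate_design
        from plf.quant import build_region_matrix, normalize_counts

        exp = small_experiment
        obs = filter_exclusive(exp.observations)
        design = validate_design(exp.design, obs, paired=True)
        normalized = normalize_counts(
            build_region_matrix(obs, exp.schemes, exp.database)
        )
        tests = bonferroni_correct(regional_test(normalized, design, paired=True))
        sig = tests.index[(tests["p_bonferroni"] <= 0.05).fillna(False)]
        flags = intragroup_screen(normalized, design, sig, seed=1)
        presence = presence_filter(obs, design)
        report = candidate_pipeline(tests, flags, presence)
        truth = {(m.accession, m.region_index) for m in exp.truth.modified}
        recovered = truth & set(report.candidates.index)
        assert len(recovered) == len(truth)
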
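"""Regional significance testing and the candidate filter cascade.

Each region's normalized quantities are compared between the two groups
with a one-way ANOVA: repeated-measures with subject as blocking factor in
the paired design (F on 1 and n-1 df, equivalent to the squared paired t),
or ordinary one-way ANOVA in the unpaired design (F on 1 and n1+n2-2 df,
the squared pooled-variance t).  Raw p values are Bonferroni-corrected
within a family (the tested regions of the same protein by default), and
significant regions then pass through two screens: an intragroup-
variability screen and a both-groups-presence filter.  What survives are
the modification-associated candidate regions and proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from plf.errors import ValidationError
from plf.ingest import PeptideObservationSet, SampleDesign
from plf.quant import RegionCountMatrix

logger = logging.getLogger(__name__)

#: Significance tiers on the Bonferroni-corrected p value.
TIER_THRESHOLDS = (("***", 0.001), ("**", 0.01), ("*", 0.05))

BONFERRONI_FAMILIES = ("per_protein", "experiment_wide")
INTRAGROUP_STRATEGIES = ("split_half", "cv_threshold")


def significance_tier(p_corrected: float) -> str:
    """Map a corrected p value to its tier: *** <=0.001, ** <=0.01, * <=0.05."""
    if np.isnan(p_corrected):
        return "ns"
    for tier, threshold in TIER_THRESHOLDS:
        if p_corrected <= threshold:
            return tier
    return "ns"


def _paired_f(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, bool]:
    """Repeated-measures one-way ANOVA for two within-subject conditions.

    With two levels the group-by-subject interaction is the error term and
    F(1, n-1) = n * mean(d)^2 / var(d) with d the per-subject differences —
    identical to the squared paired t statistic.

    Returns (F, p, degenerate).
    """
    d = g2 - g1
    n = d.size
    mean_d = d.mean()
    var_d = d.var(ddof=1)
    if var_d == 0.0:
        if mean_d == 0.0:
            return 0.0, 1.0, False
        return np.inf, 0.0, True
    f = n * mean_d**2 / var_d
    p = float(sps.f.sf(f, 1, n - 1))
    return float(f), p, False


def _unpaired_f(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, bool]:
    """One-way ANOVA F for two independent groups (squared pooled t)."""
    n1, n2 = g1.size, g2.size
    diff = g2.mean() - g1.mean()
    ss_within = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
    df_within = n1 + n2 - 2
    if ss_within == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, False
        return np.inf, 0.0, True
    pooled = ss_within / df_within
    f = diff**2 / (pooled * (1.0 / n1 + 1.0 / n2))
    p = float(sps.f.sf(f, 1, df_within))
    return float(f), p, False


def regional_test(
    matrix: RegionCountMatrix, design: SampleDesign, paired: bool = True
) -> pd.DataFrame:
    """Test every region for a group difference.

    Returns a DataFrame on the matrix index with columns ``F``, ``p_raw``,
    ``tested``, ``degenerate`` and ``n``.  Regions that are all-zero in
    every sample are skipped (``tested`` False, p NaN); regions identical
    across all samples give F=0, p=1; zero within-group (or within-pair)
    variance with unequal means is flagged degenerate with p=0 so sparse
    data never aborts the pipeline.
    """
    if matrix.stage != "normalized":
        raise ValidationError(
            f"regional test expects a normalized matrix, got {matrix.stage!r}"
        )
    if paired:
        pairs = design.pairs()
        g1_cols = [p[1] for p in pairs]
        g2_cols = [p[2] for p in pairs]
        n_used = len(pairs)
    else:
        g1_cols = design.group_samples(design.g1)
        g2_cols = design.group_samples(design.g2)
        n_used = len(g1_cols) + len(g2_cols)

    g1_values = matrix.values[g1_cols].to_numpy(dtype=float)
    g2_values = matrix.values[g2_cols].to_numpy(dtype=float)

    records = []
    for i in range(g1_values.shape[0]):
        g1, g2 = g1_values[i], g2_values[i]
        if not g1.any() and not g2.any():
            records.append((np.nan, np.nan, False, False))
            continue
        all_values = np.concatenate([g1, g2])
        if np.all(all_values == all_values[0]):
            records.append((0.0, 1.0, True, False))
            continue
        f, p, degenerate = (_paired_f if paired else _unpaired_f)(g1, g2)
        records.append((f, p, True, degenerate))

    out = pd.DataFrame(
        records,
        columns=["F", "p_raw", "tested", "degenerate"],
        index=matrix.values.index,
    )
    out["n"] = n_used
    n_untested = int((~out["tested"]).sum())
    if n_untested:
        logger.info("%d all-zero regions left untested", n_untested)
    return out


def bonferroni_correct(
    results: pd.DataFrame, family: str = "per_protein"
) -> pd.DataFrame:
    """Bonferroni correction: p_bonferroni = min(1, p_raw * m).

    ``m`` counts only the *tested* regions of the family — the regions of
    the same protein (default) or all tested regions experiment-wide.
    Adds ``p_bonferroni``, ``family_size`` and ``tier`` columns.
    """
    if family not in BONFERRONI_FAMILIES:
        raise ValidationError(
            f"family must be one of {BONFERRONI_FAMILIES}, got {family!r}"
        )
    out = results.copy()
    tested = out["tested"]
    if family == "per_protein":
        m = (
            tested.groupby(level="accession")
            .transform("sum")
            .astype(int)
        )
    else:
        m = pd.Series(int(tested.sum()), index=out.index)
    out["family_size"] = m.where(tested, 0)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * m)
    out.loc[~tested, "p_bonferroni"] = np.nan
    out["tier"] = out["p_bonferroni"].map(significance_tier)
    return out


def _balanced_splits(
    samples: list[str], n_splits: int, rng: np.random.Generator
) -> list[tuple[list[str], list[str]]]:
    """Balanced split-halves of a sample list (floor/ceil halves when odd).

    Complementary duplicates are removed for even sizes by anchoring the
    first sample in the first half.  If more splits exist than requested,
    a seeded subsample is drawn.
    """
    n = len(samples)
    half = n // 2
    if n % 2 == 0:
        pool = [
            (list(c), [s for s in samples if s not in c])
            for c in combinations(samples, half)
            if samples[0] in c
        ]
    else:
        pool = [
            (list(c), [s for s in samples if s not in c])
            for c in combinations(samples, half)
        ]
    if len(pool) > n_splits:
        idx = rng.choice(len(pool), size=n_splits, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    return pool


def intragroup_screen(
    matrix: RegionCountMatrix,
    design: SampleDesign,
    sig_regions: pd.Index | list,
    strategy: str = "split_half",
    alpha_intra: float = 0.05,
    n_splits: int = 20,
    seed: int = 0,
    cv_threshold: float = 1.0,
    split_agg: str = "median",
) -> pd.DataFrame:
    """Flag significant regions whose signal is intragroup-heterogeneous.

    Default ``split_half`` strategy: within each group independently,
    enumerate balanced split-halves of its samples (capped at ``n_splits``
    by seeded subsampling), run the unpaired regional test between the two
    halves, and flag the region for that group when the ``split_agg``
    (median, or min for a more sensitive screen that catches bimodal
    groups any single split separates) of the raw p values across splits
    is below ``alpha_intra``.  Groups with fewer than 4 samples cannot be
    split and are skipped with a warning.

    ``cv_threshold`` strategy: flag when the within-group coefficient of
    variation of the normalized quantity exceeds ``cv_threshold``.

    Returns a DataFrame indexed like ``sig_regions`` with boolean columns
    ``intragroup_g1``, ``intragroup_g2`` and ``intragroup_variable``.
    """
    if strategy not in INTRAGROUP_STRATEGIES:
        raise ValidationError(
            f"strategy must be one of {INTRAGROUP_STRATEGIES}, got {strategy!r}"
        )
    if split_agg not in ("median", "min"):
        raise ValidationError(f"split_agg must be 'median' or 'min', got {split_agg!r}")
    aggregate = np.median if split_agg == "median" else np.min
    sig_index = pd.Index(sig_regions) if not isinstance(sig_regions, pd.Index) else sig_regions
    flags = pd.DataFrame(
        False, index=sig_index, columns=["intragroup_g1", "intragroup_g2"]
    )
    if len(sig_index) == 0:
        flags["intragroup_variable"] = pd.Series(dtype=bool)
        return flags

    rng = np.random.default_rng(seed)
    for col, group in (("intragroup_g1", design.g1), ("intragroup_g2", design.g2)):
        group_cols = design.group_samples(group)
        block = matrix.values.loc[sig_index, group_cols].to_numpy(dtype=float)
        if strategy == "cv_threshold":
            means = block.mean(axis=1)
            sds = block.std(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                cv = np.where(means > 0, sds / means, 0.0)
            flags[col] = cv > cv_threshold
            continue
        if len(group_cols) < 4:
            logger.warning(
                "group %r has %d samples; split-half screen skipped, nothing flagged",
                group,
                len(group_cols),
            )
            continue
        splits = _balanced_splits(group_cols, n_splits, rng)
        col_pos = {s: i for i, s in enumerate(group_cols)}
        for row, region in enumerate(sig_index):
            values = block[row]
            ps = []
            for half_a, half_b in splits:
                a = values[[col_pos[s] for s in half_a]]
                b = values[[col_pos[s] for s in half_b]]
                if np.all(np.concatenate([a, b]) == a[0]):
                    ps.append(1.0)
                    continue
                _, p, _ = _unpaired_f(a, b)
                ps.append(p)
            flags.loc[region, col] = bool(aggregate(ps) < alpha_intra)

    flags["intragroup_variable"] = flags["intragroup_g1"] | flags["intragroup_g2"]
    return flags


def presence_filter(
    obs: PeptideObservationSet, design: SampleDesign, min_samples: int = 1
) -> pd.DataFrame:
    """Per-protein presence-in-group flags.

    A protein is present in a group when at least ``min_samples`` of that
    group's samples have a nonzero total quantity for it.  Proteins
    detected in exactly one group are marked for exclusion: their regional
    differences reflect presence/absence, not structural modification.
    """
    if min_samples < 1:
        raise ValidationError(f"min_samples must be >= 1, got {min_samples}")
    totals = obs.table.groupby("accession")[obs.samples].sum()
    out = pd.DataFrame(index=totals.index)
    for col, group in (("presence_g1", design.g1), ("presence_g2", design.g2)):
        cols = design.group_samples(group)
        out[col] = (totals[cols] > 0).sum(axis=1) >= min_samples
    out["excluded_single_group_presence"] = out["presence_g1"] != out["presence_g2"]
    return out


@dataclass
class CandidateReport:
    """Outcome of the three-stage candidate filter cascade.

    Stage 1: regions with corrected p <= alpha and their proteins.
    Stage 2: after removing intragroup-variable regions.
    Stage 3: after removing proteins detected in only one group — the
    final modification-associated candidates.
    """

    results: pd.DataFrame  # full per-region table with all flags
    candidates: pd.DataFrame  # final candidate regions
    stage_regions: tuple[int, int, int]
    stage_proteins: tuple[int, int, int]
    alpha: float
    parameters: dict = field(default_factory=dict)

    @property
    def candidate_proteins(self) -> list[str]:
        if self.candidates.empty:
            return []
        return sorted(self.candidates.index.get_level_values("accession").unique())


def candidate_pipeline(
    test_results: pd.DataFrame,
    intragroup_flags: pd.DataFrame,
    presence: pd.DataFrame,
    alpha: float = 0.05,
) -> CandidateReport:
    """Run the filter cascade on corrected regional test results.

    ``test_results`` must carry ``p_bonferroni`` (from
    :func:`bonferroni_correct`); ``intragroup_flags`` covers at least the
    significant regions; ``presence`` comes from :func:`presence_filter`.
    """
    if "p_bonferroni" not in test_results.columns:
        raise ValidationError("run bonferroni_correct before candidate_pipeline")
    results = test_results.copy()

    significant = results["p_bonferroni"] <= alpha
    results["significant"] = significant.fillna(False)

    results["intragroup_variable"] = False
    common = results.index.intersection(intragroup_flags.index)
    results.loc[common, "intragroup_variable"] = intragroup_flags.loc[
        common, "intragroup_variable"
    ]

    accessions = results.index.get_level_values("accession")
    for col in ("presence_g1", "presence_g2", "excluded_single_group_presence"):
        mapped = presence[col].reindex(accessions)
        results[col] = mapped.to_numpy()
    results["excluded_single_group_presence"] = (
        results["excluded_single_group_presence"].fillna(True).astype(bool)
    )

    stage1 = results[results["significant"]]
    stage2 = stage1[~stage1["intragroup_variable"]]
    stage3 = stage2[~stage2["excluded_single_group_presence"]]
    results["candidate"] = results.index.isin(stage3.index)

    def _n_proteins(frame: pd.DataFrame) -> int:
        if frame.empty:
            return 0
        return frame.index.get_level_values("accession").nunique()

    report = CandidateReport(
        results=results,
        candidates=stage3,
        stage_regions=(len(stage1), len(stage2), len(stage3)),
        stage_proteins=(_n_proteins(stage1), _n_proteins(stage2), _n_proteins(stage3)),
        alpha=alpha,
    )
    logger.info(
        "candidate cascade: %d -> %d -> %d regions (%d -> %d -> %d proteins)",
        *report.stage_regions,
        *report.stage_proteins,
    )
    return report
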
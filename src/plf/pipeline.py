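"""End-to-end pipeline: ingest → map → normalize → summarize → test → filter.

`run_pipeline` drives the whole analysis from a :class:`RunConfig`, writes
tidy CSVs for every stage plus a JSON run manifest capturing all resolved
parameters, seeds and dropped-record counts, and returns the in-memory
results.  `export_profile` extracts the figure-ready per-protein table and
`pca_qc` projects samples onto the first two principal axes of the peptide
count matrix as a quick group-separation check.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from plf.errors import PLFError, ValidationError
from plf.ingest import (
    PeptideObservationSet,
    filter_exclusive,
    read_design,
    read_peptide_report,
    validate_design,
)
from plf.quant import (
    build_region_matrix,
    difference_profile,
    group_average,
    normalize_counts,
)
from plf.reference import (
    read_annotations,
    read_fasta,
    segment_by_annotation,
    segment_fixed,
)
from plf.stats import (
    CandidateReport,
    bonferroni_correct,
    candidate_pipeline,
    intragroup_screen,
    presence_filter,
    regional_test,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    Only the input paths and the group orientation have no defaults: the
    orientation (g1 = reference, differences reported as g2 − g1) is an
    explicit analytic decision, never inferred from file order.
    """

    fasta: str
    peptides: str
    design: str
    g1: str
    g2: str
    annotations: str | None = None
    mode: str = "fixed_step"  # "fixed_step" | "annotation"
    step: int = 50
    quantity_kind: str = "psm_count"
    normalization: str = "median_scale"
    paired: bool = True
    alpha: float = 0.05
    family: str = "per_protein"
    intragroup_strategy: str = "split_half"
    alpha_intra: float = 0.05
    n_splits: int = 20
    split_agg: str = "median"
    cv_threshold: float = 1.0
    presence_min_samples: int = 1
    seed: int = 0
    outdir: str = "plf_run"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """All in-memory stage outputs of one run."""

    config: RunConfig
    observations: PeptideObservationSet
    raw_matrix: object
    normalized_matrix: object
    summary: object
    profile: pd.DataFrame
    report: CandidateReport
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, (PLFError, OSError)):
                raise PLFError(f"[stage: {name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write all outputs to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    with _stage("reference"):
        database = read_fasta(config.fasta)

    with _stage("ingest"):
        obs = read_peptide_report(config.peptides, quantity_kind=config.quantity_kind)
        obs = filter_exclusive(obs)
        design = read_design(config.design, groups=(config.g1, config.g2))
        design = validate_design(design, obs, paired=config.paired)
    manifest["stages"]["ingest"] = {
        "peptide_rows": obs.n_rows,
        "proteins": len(obs.accessions),
        "samples": obs.samples,
        **{k: v for k, v in obs.provenance.items() if k != "source"},
    }

    with _stage("segmentation"):
        if config.mode == "fixed_step":
            schemes = {
                a: segment_fixed(database[a], config.step)
                for a in obs.accessions
                if a in database
            }
        elif config.mode == "annotation":
            if not config.annotations:
                raise ValidationError("annotation mode requires an annotations path")
            annotations = read_annotations(config.annotations, database=database)
            schemes = {
                a: segment_by_annotation(database[a], annotations)
                for a in obs.accessions
                if a in database
            }
        else:
            raise ValidationError(f"unknown mode {config.mode!r}")
        unknown = sorted(set(obs.accessions) - set(database))
        if unknown:
            raise ValidationError(
                f"report accessions absent from FASTA: {unknown[:10]}"
                + (" ..." if len(unknown) > 10 else "")
            )
    manifest["stages"]["segmentation"] = {
        "mode": config.mode,
        "step": config.step if config.mode == "fixed_step" else None,
        "proteins_segmented": len(schemes),
    }

    with _stage("mapping"):
        raw = build_region_matrix(obs, schemes, database)
    manifest["stages"]["mapping"] = dict(raw.log)

    with _stage("normalization"):
        normalized = normalize_counts(raw, method=config.normalization)
    manifest["stages"]["normalization"] = {"method": config.normalization}

    with _stage("summary"):
        summary = group_average(normalized, design)
        profile = difference_profile(summary)

    with _stage("testing"):
        tests = regional_test(normalized, design, paired=config.paired)
        tests = bonferroni_correct(tests, family=config.family)
    manifest["stages"]["testing"] = {
        "paired": config.paired,
        "family": config.family,
        "regions_tested": int(tests["tested"].sum()),
        "regions_untested": int((~tests["tested"]).sum()),
        "degenerate_regions": int(tests["degenerate"].sum()),
    }

    with _stage("filtering"):
        sig_index = tests.index[
            (tests["p_bonferroni"] <= config.alpha).fillna(False)
        ]
        flags = intragroup_screen(
            normalized,
            design,
            sig_index,
            strategy=config.intragroup_strategy,
            alpha_intra=config.alpha_intra,
            n_splits=config.n_splits,
            seed=config.seed,
            cv_threshold=config.cv_threshold,
            split_agg=config.split_agg,
        )
        presence = presence_filter(
            obs, design, min_samples=config.presence_min_samples
        )
        report = candidate_pipeline(tests, flags, presence, alpha=config.alpha)
    manifest["stages"]["filtering"] = {
        "intragroup_strategy": config.intragroup_strategy,
        "alpha_intra": config.alpha_intra,
        "n_splits": config.n_splits,
        "split_agg": config.split_agg,
        "seed": config.seed,
        "presence_min_samples": config.presence_min_samples,
        "stage_regions": list(report.stage_regions),
        "stage_proteins": list(report.stage_proteins),
    }

    with _stage("output"):
        raw.values.to_csv(outdir / "region_counts_raw.csv")
        normalized.values.round(9).to_csv(outdir / "region_counts_normalized.csv")
        profile_out = profile.copy()
        profile_out.to_csv(outdir / "group_summary.csv", index=False)
        results_out = report.results.join(profile[["start", "end", "d_per_aa"]])
        results_out.to_csv(outdir / "region_tests.csv")
        report.candidates.to_csv(outdir / "candidates.csv")
        manifest["orientation"] = (
            f"g1(reference)={config.g1}; g2={config.g2}; "
            f"d_per_aa=(mean_g2-mean_g1)/region_length; "
            "coordinates 1-based inclusive"
        )
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, default=str)

    return PipelineResult(
        config=config,
        observations=obs,
        raw_matrix=raw,
        normalized_matrix=normalized,
        summary=summary,
        profile=profile,
        report=report,
        manifest=manifest,
    )


def export_profile(accession: str, result: PipelineResult) -> pd.DataFrame:
    """Figure-ready table for one protein, ordered by region index.

    Columns: region_index, start, end, mean_g1, sd_g1, mean_g2, sd_g2,
    d_per_aa, p_bonferroni, tier — the numbers behind a regional bar/line
    profile plot.
    """
    profile = result.profile.reset_index(drop=True)
    rows = profile[profile["accession"] == accession]
    if rows.empty:
        raise ValidationError(f"accession {accession!r} was not analysed")
    tests = result.report.results.loc[[accession]][["p_bonferroni", "tier"]]
    tests = tests.reset_index(drop=False)
    merged = rows.merge(
        tests[["region_index", "p_bonferroni", "tier"]],
        on="region_index",
        how="left",
    )
    cols = [
        "region_index", "start", "end",
        "mean_g1", "sd_g1", "mean_g2", "sd_g2",
        "d_per_aa", "p_bonferroni", "tier",
    ]
    return merged.sort_values("region_index")[cols].reset_index(drop=True)


def pca_qc(obs: PeptideObservationSet) -> pd.DataFrame | None:
    """Project samples onto the first two principal axes of peptide counts.

    Peptides are the variables (columns), samples the observations; the
    matrix is column-centered.  Deterministic up to axis sign.  Returns
    None (with a warning) for fewer than 3 samples.
    """
    if len(obs.samples) < 3:
        logger.warning("PCA QC requires >= 3 samples; skipped")
        return None
    data = obs.table[obs.samples].to_numpy(dtype=float).T  # samples x peptides
    n_components = min(2, data.shape[0] - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(data)
    out = pd.DataFrame(
        coords,
        index=pd.Index(obs.samples, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return out
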
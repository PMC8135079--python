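"""Peptide-to-region mapping, summation, normalization and group profiles.

Each peptide occurrence donates its full per-sample quantity to every
region it overlaps by at least one residue — a peptide spanning a region
boundary is counted within both regions.  Regional sums are then scaled
per protein so that whole-protein abundance differences cancel (median-
ratio scaling by default), averaged per group, and differenced per region
on a per-amino-acid scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plf.errors import ValidationError
from plf.ingest import PeptideObservationSet, SampleDesign
from plf.reference import ProteinRecord, RegionScheme

logger = logging.getLogger(__name__)

NORMALIZATION_METHODS = ("median_scale", "proportion")

#: Column order of the region metadata block shared by all matrix stages.
_META_COLS = ["accession", "region_index", "start", "end", "length"]


@dataclass(frozen=True)
class PeptideOccurrence:
    """One exact placement of a peptide in its parent protein."""

    accession: str
    peptide: str
    start: int  # 1-based inclusive
    end: int  # = start + len(peptide) - 1


def locate_peptide(peptide: str, protein: ProteinRecord) -> list[PeptideOccurrence]:
    """All exact substring matches, leftmost first; overlaps allowed.

    Peptides containing ambiguity codes match only literally.  An empty
    result means the peptide does not occur in this protein.
    """
    if not peptide:
        raise ValidationError("peptide must be non-empty")
    peptide = peptide.upper()
    occurrences = []
    pos = protein.sequence.find(peptide)
    while pos != -1:
        occurrences.append(
            PeptideOccurrence(
                accession=protein.accession,
                peptide=peptide,
                start=pos + 1,
                end=pos + len(peptide),
            )
        )
        pos = protein.sequence.find(peptide, pos + 1)
    return occurrences


@dataclass
class RegionCountMatrix:
    """Region-by-sample quantities at one processing stage.

    ``values`` is indexed by (accession, region_index) with one column per
    sample; ``meta`` carries region coordinates and lengths on the same
    index.  Every region of every protein with at least one mapped peptide
    is present, including its all-zero regions.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    stage: str  # "raw" | "normalized"
    schemes: dict[str, RegionScheme]
    quantity_kind: str = "psm_count"
    log: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def protein_totals(self) -> pd.DataFrame:
        """Per-protein, per-sample totals summed over regions."""
        return self.values.groupby(level="accession").sum()


def build_region_matrix(
    obs: PeptideObservationSet,
    schemes: dict[str, RegionScheme],
    database: dict[str, ProteinRecord],
) -> RegionCountMatrix:
    """Map peptides onto regions and sum raw quantities.

    Every occurrence of a peptide contributes its full quantity to each
    region it overlaps (>= 1 residue).  Peptides with no exact match in
    their protein are excluded and counted in the matrix log; peptides
    occurring at several positions contribute at every occurrence.
    """
    missing = [a for a in obs.accessions if a not in database or a not in schemes]
    if missing:
        raise ValidationError(
            f"accessions missing from database or schemes: {sorted(missing)}"
        )

    touched: dict[str, bool] = {}
    sums: dict[tuple[str, int], np.ndarray] = {}
    n_samples = len(obs.samples)
    n_unmapped = 0
    n_multi = 0

    quantities = obs.table[obs.samples].to_numpy()
    for row_pos, (accession, peptide) in enumerate(
        zip(obs.table["accession"], obs.table["peptide"])
    ):
        occurrences = locate_peptide(peptide, database[accession])
        if not occurrences:
            n_unmapped += 1
            continue
        if len(occurrences) > 1:
            n_multi += 1
        touched[accession] = True
        vec = quantities[row_pos]
        scheme = schemes[accession]
        for occ in occurrences:
            for region in scheme.overlapping(occ.start, occ.end):
                key = (accession, region.index)
                if key not in sums:
                    sums[key] = np.zeros(n_samples, dtype=float)
                sums[key] += vec

    if n_unmapped:
        logger.warning("%d peptide rows had no exact match and were excluded", n_unmapped)
    if n_multi:
        logger.info("%d peptides occur at multiple positions; all occurrences counted", n_multi)

    index_rows = []
    meta_rows = []
    data = []
    for accession in sorted(touched):
        for region in schemes[accession]:
            index_rows.append((accession, region.index))
            meta_rows.append(
                (accession, region.index, region.start, region.end, region.length)
            )
            data.append(sums.get((accession, region.index), np.zeros(n_samples)))
    index = pd.MultiIndex.from_tuples(
        index_rows or [], names=["accession", "region_index"]
    )
    values = pd.DataFrame(
        np.array(data).reshape(len(data), n_samples) if data else
        np.empty((0, n_samples)),
        index=index,
        columns=obs.samples,
    )
    if obs.quantity_kind == "psm_count":
        values = values.round().astype(np.int64)
    meta = pd.DataFrame(meta_rows, columns=_META_COLS, index=index)
    return RegionCountMatrix(
        values=values,
        meta=meta,
        stage="raw",
        schemes=schemes,
        quantity_kind=obs.quantity_kind,
        log={
            "unmapped_peptides": n_unmapped,
            "multi_position_peptides": n_multi,
            "proteins_mapped": len(touched),
        },
    )


def normalize_counts(
    matrix: RegionCountMatrix, method: str = "median_scale"
) -> RegionCountMatrix:
    """Scale regional quantities per protein to cancel abundance differences.

    ``median_scale`` (default): per protein p with per-sample totals T_ps,
    every sample with T_ps > 0 is multiplied by median_s'(T_ps') / T_ps, so
    its scaled total equals the cross-sample median total.  ``proportion``:
    values are divided by T_ps (regional fraction of the protein total).
    Samples with T_ps = 0 stay zero under both methods.  The raw matrix is
    left untouched.
    """
    if matrix.stage != "raw":
        raise ValidationError(f"expected a raw matrix, got stage={matrix.stage!r}")
    if method not in NORMALIZATION_METHODS:
        raise ValidationError(
            f"method must be one of {NORMALIZATION_METHODS}, got {method!r}"
        )

    values = matrix.values.astype(float).copy()
    for accession, block in values.groupby(level="accession"):
        totals = block.sum(axis=0)
        nonzero = totals > 0
        factors = pd.Series(0.0, index=totals.index)
        if nonzero.any():
            if method == "median_scale":
                reference = float(np.median(totals))
                factors[nonzero] = reference / totals[nonzero]
            else:
                factors[nonzero] = 1.0 / totals[nonzero]
        values.loc[block.index] = block.to_numpy() * factors.to_numpy()

    return RegionCountMatrix(
        values=values,
        meta=matrix.meta.copy(),
        stage="normalized",
        schemes=matrix.schemes,
        quantity_kind=matrix.quantity_kind,
        log={**matrix.log, "normalization": method},
    )


@dataclass
class RegionGroupSummary:
    """Per-region group means/SDs (sample SD, n-1) on the normalized scale.

    ``table`` columns: the region metadata plus mean_g1, sd_g1, mean_g2,
    sd_g2.  ``g1`` is the reference group fixed by the design orientation.
    """

    table: pd.DataFrame
    g1: str
    g2: str
    n_g1: int
    n_g2: int


def group_average(
    matrix: RegionCountMatrix, design: SampleDesign
) -> RegionGroupSummary:
    """Arithmetic mean and sample SD per region per group."""
    if matrix.stage != "normalized":
        raise ValidationError(
            f"group averaging expects a normalized matrix, got {matrix.stage!r}"
        )
    for group in design.groups:
        if len(design.group_samples(group)) < 2:
            raise ValidationError(f"group {group!r} has fewer than 2 samples")
    g1_cols = design.group_samples(design.g1)
    g2_cols = design.group_samples(design.g2)
    table = matrix.meta.copy()
    table["mean_g1"] = matrix.values[g1_cols].mean(axis=1)
    table["sd_g1"] = matrix.values[g1_cols].std(axis=1, ddof=1)
    table["mean_g2"] = matrix.values[g2_cols].mean(axis=1)
    table["sd_g2"] = matrix.values[g2_cols].std(axis=1, ddof=1)
    return RegionGroupSummary(
        table=table,
        g1=design.g1,
        g2=design.g2,
        n_g1=len(g1_cols),
        n_g2=len(g2_cols),
    )


def difference_profile(summary: RegionGroupSummary) -> pd.DataFrame:
    """Per-aa difference d = (mean_g2 - mean_g1) / region length.

    Dividing by each region's true length (the last region of a fixed-step
    scheme may be shorter than the step) puts regions of unequal size on a
    common per-residue scale.  Swapping g1/g2 negates d exactly.
    """
    table = summary.table.copy()
    table["d_per_aa"] = (table["mean_g2"] - table["mean_g1"]) / table["length"]
    table.attrs["orientation"] = f"d = (mean[{summary.g2}] - mean[{summary.g1}]) / region_length"
    return table
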
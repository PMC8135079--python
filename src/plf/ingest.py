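"""Peptide report and sample design ingestion.

The canonical peptide report is a CSV with header ``accession,peptide``
followed by one column per sample; each row carries the spectral counts
(PSMs) — or, with caution, MS1 intensities — of one exclusive peptide of
one protein across all samples.  An absent peptide in a sample means zero
PSMs (spectral-counting semantics), so missing cells read as 0.

Search-engine scores, probability thresholds and FDR are upstream of this
tool; they travel only as provenance metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from plf.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

QUANTITY_KINDS = ("psm_count", "ms1_intensity")


@dataclass
class PeptideObservationSet:
    """Exclusive-peptide quantities: one row per (accession, peptide).

    ``table`` has columns ``accession``, ``peptide`` and one numeric column
    per sample id in ``samples`` (order preserved).  PSM counts are
    non-negative integers; MS1 intensities non-negative reals.
    """

    table: pd.DataFrame
    samples: list[str]
    quantity_kind: str = "psm_count"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.quantity_kind not in QUANTITY_KINDS:
            raise ValidationError(
                f"quantity_kind must be one of {QUANTITY_KINDS}, "
                f"got {self.quantity_kind!r}"
            )
        self.table = self.table.reset_index(drop=True)
        values = self.table[self.samples]
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative quantities are not allowed")
        if self.quantity_kind == "psm_count":
            arr = values.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("psm_count quantities must be integers")
            self.table[self.samples] = values.round().astype(np.int64)
        peptides = self.table["peptide"].str.upper()
        if not peptides.str.fullmatch("[A-Z]+").all():
            bad = self.table.loc[
                ~peptides.str.fullmatch("[A-Z]+"), "peptide"
            ].tolist()[:5]
            raise ValidationError(f"non-alphabetic peptide sequences: {bad}")
        self.table["peptide"] = peptides
        dup = self.table.duplicated(["accession", "peptide"]).sum()
        if dup:
            raise ValidationError(
                f"{dup} duplicate (accession, peptide) rows after ingestion"
            )

    @property
    def n_rows(self) -> int:
        return len(self.table)

    @property
    def accessions(self) -> list[str]:
        return list(pd.unique(self.table["accession"]))

    def quantities(self) -> pd.DataFrame:
        """Quantity matrix indexed by (accession, peptide)."""
        return self.table.set_index(["accession", "peptide"])[self.samples]

    def sample_totals(self) -> pd.Series:
        return self.table[self.samples].sum()


def read_peptide_report(
    path: str | Path,
    quantity_kind: str = "psm_count",
    provenance: dict | None = None,
) -> PeptideObservationSet:
    """Read the canonical peptide report CSV.

    Missing cells become 0 (logged); duplicate (accession, peptide) rows
    are summed (logged).  Non-numeric quantities raise a
    :class:`FormatError` naming the row and column.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={0: str, 1: str})
    cols = list(table.columns)
    if len(cols) < 2 or cols[0] != "accession" or cols[1] != "peptide":
        raise FormatError(
            f"{path}: header must start with 'accession,peptide', got {cols[:2]}"
        )
    samples = cols[2:]
    if not samples:
        raise FormatError(f"{path}: no sample columns found")

    numeric = table[samples].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & table[samples].notna()
    if bad.to_numpy().any():
        row_idx, col_idx = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric quantity at row {row_idx + 2}, "
            f"column {samples[col_idx]!r}: {table[samples].iat[row_idx, col_idx]!r}"
        )
    n_missing = int(numeric.isna().to_numpy().sum())
    if n_missing:
        logger.info("%s: %d missing cells read as 0", path, n_missing)
    table[samples] = numeric.fillna(0)

    if quantity_kind == "ms1_intensity":
        logger.warning(
            "MS1 intensities selected: spectral counts are the recommended "
            "quantity for complex, heavily modified tissue proteomes; "
            "interpret intensity-based profiles with caution"
        )

    n_dup = int(table.duplicated(["accession", "peptide"]).sum())
    if n_dup:
        logger.info(
            "%s: %d duplicate (accession, peptide) rows summed", path, n_dup
        )
        table = table.groupby(["accession", "peptide"], as_index=False, sort=False)[
            samples
        ].sum()

    prov = dict(provenance or {})
    prov.setdefault("source", str(path))
    prov["missing_cells_as_zero"] = n_missing
    prov["duplicate_rows_summed"] = n_dup
    return PeptideObservationSet(
        table=table, samples=samples, quantity_kind=quantity_kind, provenance=prov
    )


def write_peptide_report(obs: PeptideObservationSet, path: str | Path) -> None:
    obs.table[["accession", "peptide"] + obs.samples].to_csv(path, index=False)


def filter_exclusive(obs: PeptideObservationSet) -> PeptideObservationSet:
    """Drop every peptide sequence claimed by two or more accessions.

    Shared peptides cannot be attributed to a single protein region, so all
    their rows are removed.  Idempotent; the removal count is logged and
    recorded in provenance.
    """
    parents = obs.table.groupby("peptide")["accession"].nunique()
    shared = set(parents.index[parents > 1])
    keep = ~obs.table["peptide"].isin(shared)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "exclusivity filter removed %d rows (%d shared peptide sequences)",
            n_removed,
            len(shared),
        )
    if keep.all() and not shared:
        prov = dict(obs.provenance)
        prov["exclusivity_rows_removed"] = 0
        return PeptideObservationSet(
            table=obs.table.copy(),
            samples=list(obs.samples),
            quantity_kind=obs.quantity_kind,
            provenance=prov,
        )
    if not keep.any():
        logger.warning("exclusivity filter removed every row")
    prov = dict(obs.provenance)
    prov["exclusivity_rows_removed"] = n_removed
    return PeptideObservationSet(
        table=obs.table.loc[keep].reset_index(drop=True),
        samples=list(obs.samples),
        quantity_kind=obs.quantity_kind,
        provenance=prov,
    )


@dataclass
class SampleDesign:
    """Two-group sample design, optionally paired by subject.

    ``groups`` fixes the orientation used downstream: ``groups[0]`` is the
    reference (g1) and ``groups[1]`` the comparison group (g2); per-aa
    differences are (mean_g2 - mean_g1) / region length.
    """

    sample_to_group: dict[str, str]
    sample_to_subject: dict[str, str | None] = field(default_factory=dict)
    groups: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        observed = list(dict.fromkeys(self.sample_to_group.values()))
        if self.groups is None:
            if len(observed) != 2:
                raise ValidationError(
                    f"exactly two groups required, found {observed}"
                )
            self.groups = (observed[0], observed[1])
        else:
            self.groups = tuple(self.groups)  # type: ignore[assignment]
            if set(observed) != set(self.groups) or len(self.groups) != 2:
                raise ValidationError(
                    f"declared groups {self.groups} do not match design "
                    f"groups {observed}"
                )
        for sample in self.sample_to_group:
            self.sample_to_subject.setdefault(sample, None)

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_group)

    def group_samples(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]

    @property
    def g1(self) -> str:
        return self.groups[0]

    @property
    def g2(self) -> str:
        return self.groups[1]

    def pairs(self) -> list[tuple[str, str, str]]:
        """(subject, sample_in_g1, sample_in_g2) triples, sorted by subject."""
        by_subject: dict[str, dict[str, str]] = {}
        for sample, subject in self.sample_to_subject.items():
            if subject is None:
                raise ValidationError(
                    f"sample {sample!r} has no subject id; pairing impossible"
                )
            by_subject.setdefault(str(subject), {})[
                self.sample_to_group[sample]
            ] = sample
        triples = []
        for subject in sorted(by_subject):
            seen = by_subject[subject]
            if set(seen) != set(self.groups) or len(seen) != 2:
                raise ValidationError(
                    f"subject {subject!r} is not observed exactly once per group"
                )
        for subject in sorted(by_subject):
            seen = by_subject[subject]
            triples.append((subject, seen[self.g1], seen[self.g2]))
        return triples


def read_design(
    path: str | Path, groups: tuple[str, str] | None = None
) -> SampleDesign:
    """Read a design CSV with columns sample_id, group[, subject_id]."""
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    if "sample_id" not in table.columns or "group" not in table.columns:
        raise FormatError(
            f"{path}: design table requires columns sample_id, group"
        )
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    subjects: dict[str, str | None] = {}
    if "subject_id" in table.columns:
        for _, row in table.iterrows():
            subj = row["subject_id"]
            subjects[row["sample_id"]] = None if pd.isna(subj) else str(subj)
    return SampleDesign(
        sample_to_group=dict(zip(table["sample_id"], table["group"])),
        sample_to_subject=subjects,
        groups=groups,
    )


def validate_design(
    design: SampleDesign, obs: PeptideObservationSet, paired: bool = False
) -> SampleDesign:
    """Check design/report consistency; return the validated design.

    Every sample in the report must appear in the design and vice versa;
    each group needs at least two samples; paired mode additionally
    requires every subject to appear exactly once per group.
    """
    design_samples = set(design.samples)
    report_samples = set(obs.samples)
    missing = report_samples - design_samples
    if missing:
        raise ValidationError(
            f"samples in report but not in design: {sorted(missing)}"
        )
    extra = design_samples - report_samples
    if extra:
        raise ValidationError(
            f"samples in design but not in report: {sorted(extra)}"
        )
    for group in design.groups:
        n = len(design.group_samples(group))
        if n < 2:
            raise ValidationError(
                f"group {group!r} has {n} sample(s); at least 2 required"
            )
    if paired:
        design.pairs()  # raises naming the offending subject
    return design
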
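"""Protein sequence databases and region schemes.

Proteins are segmented into ordered, 1-based inclusive regions either by a
fixed amino-acid step size (the menu used in practice is 20, 40, 50, 80 or
100 aa; 50 aa is the usual choice) or by externally annotated domains,
repeats or regions.  Fixed-step schemes tile the protein exactly, with the
final region allowed to be shorter than the step; its true length is what
later divides the per-region group difference to give a per-aa profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from plf.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Step sizes offered by the reference analysis; others need an explicit override.
STANDARD_STEPS = (20, 40, 50, 80, 100)

# 20 canonical residues plus the ambiguity/rare codes tolerated in databases.
_ALLOWED_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYXUBZ")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a UniProt-style primary accession.

    Coordinates used throughout the package are 1-based and inclusive.
    """

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein record requires a non-empty accession")
        if not self.sequence:
            raise ValidationError(
                f"protein {self.accession!r} has an empty sequence"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _ALLOWED_RESIDUES
        if bad:
            raise ValidationError(
                f"protein {self.accession!r} contains non-amino-acid "
                f"characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotatedRegion:
    """A named interval (domain / repeat / region) on a protein."""

    accession: str
    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"annotation {self.label!r} on {self.accession}: require "
                f"1 <= start <= end, got start={self.start}, end={self.end}"
            )


class Region(NamedTuple):
    """One region of a scheme: 1-based index and inclusive coordinates."""

    index: int
    start: int
    end: int
    label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionScheme:
    """Ordered regions of one protein, produced by a segmentation mode."""

    accession: str
    mode: str  # "fixed_step" | "annotation"
    regions: list[Region] = field(default_factory=list)
    step: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_step", "annotation"):
            raise ValidationError(f"unknown segmentation mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def region_length(self, index: int) -> int:
        return self.regions[index - 1].length

    def overlapping(self, start: int, end: int) -> list[Region]:
        """Regions sharing at least one residue with [start, end]."""
        return [r for r in self.regions if r.start <= end and start <= r.end]


def _accession_from_header(header_id: str) -> str:
    """Extract accession from 'db|ACC|NAME' or bare first-token headers."""
    if "|" in header_id:
        fields = header_id.split("|")
        if len(fields) >= 2 and fields[1]:
            return fields[1]
    return header_id.split()[0]


def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Load a protein FASTA into an accession-keyed mapping.

    Accepts both UniProt ``>sp|ACC|NAME desc`` headers (accession taken
    from the second pipe field) and bare ``>ACC desc`` headers.

    Raises
    ------
    FormatError
        If the file contains no records.
    ValidationError
        If an accession appears more than once.
    """
    path = Path(path)
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = _accession_from_header(rec.id)
        if accession in records:
            raise ValidationError(
                f"duplicate accession {accession!r} in {path}"
            )
        records[accession] = ProteinRecord(
            accession=accession,
            sequence=str(rec.seq),
            description=rec.description,
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records with bare ``>ACC desc`` headers."""
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.accession,
            description=r.description if r.description != r.accession else "",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(Path(path)), "fasta")


def read_annotations(
    path: str | Path,
    database: dict[str, ProteinRecord] | None = None,
    strict: bool = False,
) -> list[AnnotatedRegion]:
    """Read a domain/repeat annotation table (CSV or TSV).

    Required header columns: ``accession,label,start,end`` with 1-based
    inclusive coordinates.  Rows violating ``1 <= start <= end``, rows whose
    end exceeds the protein length (when ``database`` is supplied) and rows
    with unknown accessions are skipped with a logged row number; with
    ``strict=True`` they raise :class:`ValidationError` instead.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python")
    required = {"accession", "label", "start", "end"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(
            f"annotation table {path} lacks columns: {sorted(missing)}"
        )

    out: list[AnnotatedRegion] = []
    skipped = 0
    for row_number, row in enumerate(table.itertuples(index=False), start=2):
        accession = str(row.accession)

        def _reject(reason: str) -> None:
            if strict:
                raise ValidationError(f"{path} row {row_number}: {reason}")
            logger.warning("%s row %d skipped: %s", path, row_number, reason)

        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            _reject(f"non-integer coordinates ({row.start!r}, {row.end!r})")
            skipped += 1
            continue
        if not (1 <= start <= end):
            _reject(f"invalid interval start={start}, end={end}")
            skipped += 1
            continue
        if database is not None:
            protein = database.get(accession)
            if protein is None:
                _reject(f"unknown accession {accession!r}")
                skipped += 1
                continue
            if end > protein.length:
                _reject(
                    f"end={end} exceeds length {protein.length} of {accession}"
                )
                skipped += 1
                continue
        out.append(
            AnnotatedRegion(
                accession=accession, label=str(row.label), start=start, end=end
            )
        )
    if skipped:
        logger.warning("%s: %d annotation rows skipped", path, skipped)
    return out


def segment_fixed(
    protein: ProteinRecord, step: int, allow_any_step: bool = False
) -> RegionScheme:
    """Tile a protein into consecutive fixed-size regions.

    Region 1 starts at residue 1, consecutive regions abut, and the last
    region ends at the protein length; every region has length ``step``
    except possibly the last.  ``step`` must come from the standard menu
    (20, 40, 50, 80, 100) unless ``allow_any_step`` is set.
    """
    if step <= 0:
        raise ValidationError(f"step must be positive, got {step}")
    if step not in STANDARD_STEPS and not allow_any_step:
        raise ValidationError(
            f"step {step} not in standard menu {STANDARD_STEPS}; "
            "pass allow_any_step=True to override"
        )
    n_regions = math.ceil(protein.length / step)
    regions = [
        Region(
            index=i,
            start=(i - 1) * step + 1,
            end=min(i * step, protein.length),
        )
        for i in range(1, n_regions + 1)
    ]
    return RegionScheme(
        accession=protein.accession, mode="fixed_step", regions=regions, step=step
    )


def segment_by_annotation(
    protein: ProteinRecord, annotations: Sequence[AnnotatedRegion]
) -> RegionScheme:
    """Build a scheme from annotated intervals, in start order.

    Regions are exactly the annotated intervals: gaps between domains are
    not covered (those residues are simply untested) and overlapping
    annotations are each kept as their own region.
    """
    own = sorted(
        (a for a in annotations if a.accession == protein.accession),
        key=lambda a: (a.start, a.end, a.label),
    )
    if not own:
        logger.warning(
            "no annotations for %s; scheme is empty", protein.accession
        )
    for a in own:
        if a.end > protein.length:
            raise ValidationError(
                f"annotation {a.label!r} end={a.end} exceeds length "
                f"{protein.length} of {protein.accession}"
            )
    regions = [
        Region(index=i, start=a.start, end=a.end, label=a.label)
        for i, a in enumerate(own, start=1)
    ]
    return RegionScheme(
        accession=protein.accession, mode="annotation", regions=regions
    )
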
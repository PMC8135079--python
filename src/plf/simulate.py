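"""Ground-truthed synthetic proteomes and peptide spectral-count reports.

The generator emulates the inputs of a two-group (optionally paired)
bottom-up proteomics experiment: a protein database, its in-silico tryptic
digest, and per-sample PSM counts drawn from a negative binomial whose
mean combines a per-peptide detectability, a log-normal subject effect
shared by both samples of a donor, and a multiplicative "modification"
effect applied to peptides overlapping a chosen region in one group.
Modelling modification as a detectability change on the affected region's
peptides mirrors the idea that structural modification alters a region's
exposure to trypsin, without modelling any chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from plf.errors import ValidationError
from plf.ingest import PeptideObservationSet, SampleDesign
from plf.reference import ProteinRecord, RegionScheme, segment_fixed

#: Approximate residue frequencies of a vertebrate proteome.  K+R ~11%
#: gives a mean tryptic fragment of ~9 aa, in the realistic 8-25 range.
DEFAULT_RESIDUE_FREQUENCIES: dict[str, float] = {
    "A": 0.083, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.014,
    "Q": 0.048, "E": 0.068, "G": 0.071, "H": 0.026, "I": 0.043,
    "L": 0.097, "K": 0.058, "M": 0.021, "F": 0.036, "P": 0.050,
    "S": 0.083, "T": 0.053, "W": 0.012, "Y": 0.027, "V": 0.061,
}


class DigestPeptide(NamedTuple):
    """A tryptic fragment with its 1-based coordinates in the parent."""

    accession: str
    sequence: str
    start: int
    end: int
    missed_cleavages: int


class ModifiedRegion(NamedTuple):
    """Ground-truth modification: δ multiplies peptide detectability for
    peptides overlapping the region, in samples of the affected group."""

    accession: str
    region_index: int
    group: str
    delta: float


@dataclass
class SimulationTruth:
    """All parameters of a simulated experiment, for recovery scoring.

    δ = 1 means unmodified; δ < 1 suppresses and δ > 1 elevates peptide
    yield in the affected region/group.  ``dispersion`` is the negative-
    binomial size parameter k (variance = μ + μ²/k); ``None`` means
    Poisson counts.
    """

    modified: list[ModifiedRegion] = field(default_factory=list)
    lambda_mean: float = 3.0
    lambda_sigma: float = 0.5
    subject_sd: float = 0.25
    dispersion: float | None = 8.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "modified": [m._asdict() for m in self.modified],
            "lambda_mean": self.lambda_mean,
            "lambda_sigma": self.lambda_sigma,
            "subject_sd": self.subject_sd,
            "dispersion": self.dispersion,
            "seed": self.seed,
        }


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (200, 600),
    residue_frequencies: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, ProteinRecord]:
    """Random protein database, reproducible under ``seed``.

    Default residue frequencies keep the expected tryptic fragment length
    around 9-10 aa so simulated digests resemble real ones.
    """
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 30:
        raise ValidationError("minimum protein length is 30 aa")
    freqs = residue_frequencies or DEFAULT_RESIDUE_FREQUENCIES
    residues = list(freqs)
    probs = np.array([freqs[r] for r in residues], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    width = len(str(n_proteins))
    database: dict[str, ProteinRecord] = {}
    for i in range(1, n_proteins + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        accession = f"SYN{i:0{width}d}"
        database[accession] = ProteinRecord(
            accession=accession,
            sequence=seq,
            description=f"synthetic protein {i}",
        )
    return database


def tryptic_digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    proline_rule: bool = True,
    length_range: tuple[int, int] | None = (5, 50),
) -> list[DigestPeptide]:
    """In-silico trypsin digest with up to ``max_missed`` missed cleavages.

    Trypsin cleaves C-terminal to K or R; with ``proline_rule`` on
    (default, matching the usual search-engine trypsin), a K/R followed by
    P is not cleaved.  All contiguous fragments with 0..max_missed
    internal sites are returned with their 1-based coordinates.  The
    optional length filter (default keep 5-50 aa, ``None`` to disable) is
    applied after generation.
    """
    if max_missed < 0:
        raise ValidationError("max_missed must be >= 0")
    seq = protein.sequence
    n = len(seq)
    # cut points: index i means a cut between seq[i-1] and seq[i]
    cuts = [0]
    for i in range(n - 1):
        if seq[i] in "KR" and not (proline_rule and seq[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(n)

    peptides: list[DigestPeptide] = []
    for i in range(len(cuts) - 1):
        for missed in range(max_missed + 1):
            j = i + missed + 1
            if j >= len(cuts):
                break
            start, end = cuts[i], cuts[j]
            peptides.append(
                DigestPeptide(
                    accession=protein.accession,
                    sequence=seq[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=missed,
                )
            )
    if length_range is not None:
        lo, hi = length_range
        peptides = [p for p in peptides if lo <= len(p.sequence) <= hi]
    return peptides


def paired_design(
    n_subjects: int, groups: tuple[str, str] = ("A", "B")
) -> SampleDesign:
    """A paired two-group design: one sample per subject per group."""
    sample_to_group: dict[str, str] = {}
    sample_to_subject: dict[str, str | None] = {}
    for i in range(1, n_subjects + 1):
        subject = f"D{i:02d}"
        for group in groups:
            sample = f"{subject}_{group}"
            sample_to_group[sample] = group
            sample_to_subject[sample] = subject
    return SampleDesign(
        sample_to_group=sample_to_group,
        sample_to_subject=sample_to_subject,
        groups=groups,
    )


def simulate_counts(
    digest: Sequence[DigestPeptide],
    design: SampleDesign,
    truth: SimulationTruth,
    schemes: dict[str, RegionScheme],
) -> tuple[PeptideObservationSet, SimulationTruth]:
    """Draw per-sample PSM counts for a digest under a ground truth.

    count(peptide i, sample s) ~ NB(mean λ_i · exp(u_subject(s)) · δ_is,
    size k), where λ_i is a log-normal per-peptide detectability with mean
    ``lambda_mean``, u a subject effect shared by the donor's two samples,
    and δ_is the product of the deltas of modified regions peptide i
    overlaps when s belongs to the affected group.  Poisson when
    ``dispersion`` is None.  Fully reproducible under ``truth.seed``.
    """
    for m in truth.modified:
        scheme = schemes.get(m.accession)
        if scheme is None or not (1 <= m.region_index <= len(scheme)):
            raise ValidationError(
                f"modified region ({m.accession}, {m.region_index}) does not "
                "exist in the schemes"
            )
        if m.delta < 0:
            raise ValidationError("delta must be >= 0")

    rng = np.random.default_rng(truth.seed)

    # Collapse duplicate (accession, sequence) fragments (e.g. internal
    # repeats) to one report row, remembering every coordinate instance.
    instances: dict[tuple[str, str], list[DigestPeptide]] = {}
    for p in digest:
        instances.setdefault((p.accession, p.sequence), []).append(p)
    keys = sorted(instances)

    n_pep = len(keys)
    lam = truth.lambda_mean * rng.lognormal(
        mean=-truth.lambda_sigma**2 / 2.0, sigma=truth.lambda_sigma, size=n_pep
    )

    samples = design.samples
    subject_effect: dict[str, float] = {}
    sample_effect = np.empty(len(samples))
    for j, s in enumerate(samples):
        subject = design.sample_to_subject.get(s)
        key = subject if subject is not None else f"__sample__{s}"
        if key not in subject_effect:
            subject_effect[key] = float(rng.normal(0.0, truth.subject_sd))
        sample_effect[j] = np.exp(subject_effect[key])

    modified_by_acc: dict[str, list[ModifiedRegion]] = {}
    for m in truth.modified:
        modified_by_acc.setdefault(m.accession, []).append(m)

    # delta factor per peptide per group
    delta = np.ones((n_pep, 2))
    group_pos = {g: i for i, g in enumerate(design.groups)}
    for i, (accession, _seq) in enumerate(keys):
        for m in modified_by_acc.get(accession, []):
            region = schemes[accession].regions[m.region_index - 1]
            hits = any(
                p.start <= region.end and region.start <= p.end
                for p in instances[(accession, _seq)]
            )
            if hits:
                delta[i, group_pos[m.group]] *= m.delta

    sample_groups = np.array([group_pos[design.sample_to_group[s]] for s in samples])
    mu = lam[:, None] * sample_effect[None, :] * delta[:, sample_groups]

    if truth.dispersion is None or np.isinf(truth.dispersion):
        counts = rng.poisson(mu)
    else:
        k = truth.dispersion
        p = k / (k + mu)
        counts = rng.negative_binomial(k, p)

    table = pd.concat(
        [
            pd.DataFrame(
                {
                    "accession": [a for a, _ in keys],
                    "peptide": [s for _, s in keys],
                }
            ),
            pd.DataFrame(counts, columns=list(samples)),
        ],
        axis=1,
    )
    obs = PeptideObservationSet(
        table=table,
        samples=list(samples),
        quantity_kind="psm_count",
        provenance={"source": "plf.simulate", "seed": truth.seed},
    )
    return obs, truth


@dataclass
class SimulatedExperiment:
    """A complete synthetic study bundle with its ground truth."""

    database: dict[str, ProteinRecord]
    schemes: dict[str, RegionScheme]
    digest: list[DigestPeptide]
    design: SampleDesign
    observations: PeptideObservationSet
    truth: SimulationTruth


def simulate_experiment(
    n_proteins: int = 200,
    n_modified: int = 20,
    delta: float = 0.25,
    n_subjects: int = 7,
    step: int = 50,
    length_range: tuple[int, int] = (200, 600),
    lambda_mean: float = 3.0,
    lambda_sigma: float = 0.5,
    subject_sd: float = 0.25,
    dispersion: float | None = 8.0,
    max_missed: int = 2,
    groups: tuple[str, str] = ("A", "B"),
    seed: int = 0,
) -> SimulatedExperiment:
    """Generate a full paired two-group experiment with known truth.

    ``n_modified`` proteins receive a single modified full-length region
    each (effect δ applied in the second group).  δ = 1 or n_modified = 0
    gives a pure null experiment.  Sub-seeds for the proteome and the
    counts are derived from ``seed``.
    """
    if n_modified > n_proteins:
        raise ValidationError("n_modified cannot exceed n_proteins")
    ss = np.random.SeedSequence(seed)
    proteome_seed, pick_seed, count_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    database = generate_proteome(
        n_proteins, length_range=length_range, seed=proteome_seed
    )
    schemes = {a: segment_fixed(p, step) for a, p in database.items()}
    digest: list[DigestPeptide] = []
    for protein in database.values():
        digest.extend(tryptic_digest(protein, max_missed=max_missed))

    rng = np.random.default_rng(pick_seed)
    accessions = sorted(database)
    chosen = rng.choice(len(accessions), size=n_modified, replace=False)
    modified = []
    for idx in sorted(chosen):
        accession = accessions[idx]
        scheme = schemes[accession]
        full = [r.index for r in scheme if r.length == step] or [
            r.index for r in scheme
        ]
        region_index = int(full[rng.integers(len(full))])
        modified.append(
            ModifiedRegion(
                accession=accession,
                region_index=region_index,
                group=groups[1],
                delta=delta,
            )
        )

    truth = SimulationTruth(
        modified=modified,
        lambda_mean=lambda_mean,
        lambda_sigma=lambda_sigma,
        subject_sd=subject_sd,
        dispersion=dispersion,
        seed=count_seed,
    )
    design = paired_design(n_subjects, groups=groups)
    observations, truth = simulate_counts(digest, design, truth, schemes)
    return SimulatedExperiment(
        database=database,
        schemes=schemes,
        digest=digest,
        design=design,
        observations=observations,
        truth=truth,
    )
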
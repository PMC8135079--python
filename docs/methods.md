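# Methods

## Model and assumptions

Peptide location fingerprinting treats the per-region sum of peptide
spectral counts (PSMs) as a readout of local peptide yield: how
efficiently trypsin releases, and the instrument detects, peptides from
that stretch of the protein. The method assumes that

- PSM counts are a usable semi-quantitative measure at the region level
  (regions pool enough peptides that integer counting noise averages
  out); MS1 precursor intensities are accepted as an alternative quantity
  but treated with caution — modified peptides shift in mass and drop out
  of intensity-based quantification more severely than out of counting;
- whole-protein abundance differences are a nuisance: they are removed by
  per-protein normalization so that surviving regional contrasts reflect
  *within-protein redistribution* of peptide yield, not expression;
- shared (non-exclusive) peptides are uninformative about location and
  are removed entirely before mapping.

Coordinates are 1-based inclusive everywhere; the convention is stated in
output headers and the run manifest.

## Pipeline stages and key decisions

**Segmentation.** Fixed-step schemes tile the protein exactly; the final
partial region is kept as its own region and its true length is the
divisor in the per-aa difference profile. The alternative (merging the
tail into the penultimate region) was rejected because dividing by a
per-region length only makes sense when each region keeps its own extent.
The step menu {20, 40, 50, 80, 100} aa is enforced (50 aa default — large
enough to pool counts for a stable test, small enough to resolve
structure in small proteins); other values require an explicit override
flag. Annotation-based schemes are exactly the annotated intervals, in
start order: gaps between domains are left untested and overlapping
annotations are each kept, since inventing linker regions would test
sequence the annotation source made no claim about.

**Mapping.** All exact occurrences of a peptide are used; a peptide
occurring at several positions contributes its full count at every
occurrence (rare for exclusive tryptic peptides; logged), because
discarding multi-site peptides would silently lose signal. A peptide
overlapping a region by ≥ 1 residue contributes its full count to that
region — the boundary-spanning rule generalized to any number of spanned
regions (tryptic peptides longer than a 50-aa step are practically
absent). Consequently regional totals over-count relative to the plain
PSM total by exactly the spanning multiplicity; conservation is checked
in tests at the residue level.

**Normalization.** Default `median_scale`: per protein, each sample's
regional counts are multiplied by (cross-sample median total) / (sample
total), leaving samples with zero total untouched at zero. This
reconciles "normalize by the individual protein's total" with "normalize
to the experiment's median count" in one rule whose post-condition —
every nonzero sample total equals the median raw total — is machine-
checkable to 1e−9. `proportion` (regional fraction of the protein total)
is provided as the alternative reading; the method used is recorded in
the manifest. Note a structural side-effect: when one region is strongly
suppressed in one group, scaling redistributes part of that loss onto the
protein's other regions (their normalized counts rise slightly in the
affected group). This is inherent to abundance cancellation, and it is
why false positives in simulations concentrate in other regions of truly
modified proteins.

**Group summary.** Arithmetic mean and sample SD (n−1) per region per
group on the normalized scale; the SD is the error-bar quantity for
profile figures. The per-aa difference is
`d = (mean_g2 − mean_g1) / region_length` with g1 (the reference group)
fixed explicitly in the configuration — the orientation is never inferred,
and swapping g1/g2 negates every d exactly.

**Regional test.** Paired designs use the two-condition repeated-measures
ANOVA, computed from per-subject differences: `F = n·mean(d)²/var(d)` on
(1, n−1) df — algebraically the squared paired t, which the tests exploit
as an independent oracle. Unpaired designs use the ordinary one-way ANOVA
(squared pooled-variance t) on (1, n₁+n₂−2) df. Degenerate inputs are
handled without exceptions: regions all-zero in every sample are skipped
and excluded from the correction family; regions identical across all
samples return F = 0, p = 1; zero within-group/within-pair variance with
unequal means returns p = 0 with a `degenerate` flag so sparse integer
data cannot abort a run.

**Multiple testing.** Bonferroni within the protein's *tested* regions by
default (`p_corr = min(1, m·p)`), matching the per-protein way regional
significance is reported; an experiment-wide family is available behind a
flag. Significance tiers on corrected p: \*≤0.05, \*\*≤0.01, \*\*\*≤0.001;
the cascade's gate is the loosest tier (corrected p ≤ 0.05).

**Intragroup screen.** No canonical test exists for "significant regions
driven by within-group heterogeneity", so the screen is explicitly
pluggable and its strategy plus parameters are written to the manifest.
Default: for each group independently, enumerate balanced split-halves of
its samples (capped at `n_splits = 20` by seeded subsampling; groups of
n < 4 cannot be split and are skipped), run the unpaired regional test
between halves, and flag when the aggregate of raw p across splits falls
below `alpha_intra = 0.05`. The aggregate is the **median** by default, a
deliberately conservative choice: mixed splits place samples from both
modes in both halves, so the median rule only fires when most partitions
of the group separate — fully bimodal groups (e.g. {0,0,0,10,10,10}) are
*not* flagged by it, as exhaustive split enumeration shows (median split
p ≈ 0.52). `split_agg="min"` provides a sensitive variant that does flag
any group some single split separates cleanly, and `cv_threshold` flags
on the within-group coefficient of variation instead. Screen flags should
be read as the package's own declared heuristic, not as a reconstruction
of any particular published exclusion list.

**Presence filter.** A protein is "present" in a group when ≥
`min_samples` (default 1) of its samples have a nonzero total; proteins
present in exactly one group are excluded at the final stage, since their
regional contrasts reflect presence/absence rather than structural
modification.

## Synthetic data generator

The generator emulates the input side of a paired two-group
spectral-counting study; its defaults are the study conditions used
throughout the tests and the acceptance script.

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 200 | database size |
| `length_range` | 200–600 aa | protein lengths (uniform) |
| residue frequencies | vertebrate-like | K+R ≈ 11.3% ⇒ mean tryptic fragment ≈ 9 aa |
| `n_subjects` | 7 | donors; one sample per donor per group |
| `max_missed` | 2 | missed cleavages in the digest; proline rule on |
| digest length filter | 5–50 aa | applied after generation, logged |
| `lambda_mean` | 3.0 | mean PSM detectability per peptide |
| `lambda_sigma` | 0.5 | log-normal per-peptide detectability spread (mean-preserving) |
| `subject_sd` | 0.25 | SD of the log-normal donor effect, shared across a donor's two samples |
| `dispersion` | 8.0 | negative-binomial size k (var = μ + μ²/k); `None` ⇒ Poisson |
| `n_modified`, `delta` | 20, 0.25 | proteins carrying one modified full-length region; δ multiplies detectability of overlapping peptides in group 2 |

Counts are drawn as
`NB(mean = λ_i · exp(u_subject) · δ_region, size = k)`. The negative
binomial (rather than Poisson) reflects donor-to-donor overdispersion of
PSM counts; λ ≈ 3 PSM/peptide gives region totals of a few tens of PSMs,
typical of mid-abundance tissue proteins; the shared donor effect
exercises the paired test (it cancels in per-subject differences);
modelling modification as a multiplicative detectability change on
peptides overlapping the region captures "altered exposure to trypsin"
without modelling chemistry.

What the generator does **not** emulate: peptide-level identification
error (all simulated peptides are correct), probability-weighted counts,
shared peptides between homologous proteins (collisions between random
sequences are vanishingly rare, so the exclusivity filter is exercised by
dedicated unit fixtures instead), modified-mass dropout, chromatographic
batch effects, and real protein families' repeat structure. Passing
recovery tests therefore demonstrate the *statistical machinery* —
mapping, normalization, paired testing, cascade — under realistic count
noise, not performance on real tissue data.

## Verification

Every layer has an independent oracle: the digest against exhaustive
cut-subset enumeration on short random sequences (with and without the
proline rule); region totals against a residue-by-residue brute-force
recomputation; the paired/unpaired F against the squared scipy t tests;
normalization against its median post-condition; and the cascade against
planted simulation truth. At the defaults above (paired n = 7, 200
proteins), a null simulation keeps the per-region rate of corrected
p ≤ 0.05 calls around 1% (Bonferroni conservatism), and a recovery
simulation with δ = 0.25 on one 50-aa region in 20 proteins is detected
with ≥ 70% sensitivity at a < 5% candidate rate among unmodified regions
— these repository thresholds were calibrated once by simulation and are
recomputed from scratch by `scripts/acceptance.py`. Problem sizes in the
test suite (30–200 proteins, ≤ 1,000 random test instances) keep the full
suite and the acceptance script in the tens-of-seconds range.

## Known limitations

- Exactly two groups; no covariates, no multi-factor or >2-level designs.
- Spectral counting is semi-quantitative; very short or poorly covered
  proteins yield few tested regions and little power.
- Median-ratio normalization redistributes a large single-region loss
  onto sibling regions (see above), slightly inflating false positives
  within truly modified proteins.
- The intragroup screen is a declared heuristic; with n = 7 per group its
  default (median) form is conservative and rarely excludes regions.
- Peptides are located by exact string match only; ambiguity codes match
  literally, and isoforms/signal-peptide processing are out of scope.
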
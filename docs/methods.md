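# Methods

## Scope and model

`colotype` implements a fully rule-based classification system — there is no
model fitting anywhere in the calling layer.  Every per-sample call is a
deterministic function of the input measurements and a small set of published
cut-offs, which makes the scientific content of the package (a) the exact
formulation of each rule, including boundary conventions, and (b) the exact
statistics used to compare cohorts of calls.  Both are documented here
together with the design decisions that were genuinely open.

## Methylation calling

Input is the methylation dosage ratio (Dm) per MS-MLPA probe, a fractional
methylation estimate in [0, ~1].  Because Dm is a ratio statistic it can
slightly exceed 1; values up to 1.2 are accepted and anything above is
flagged.

**Thresholds.** For each probe, the hypermethylation threshold is the mean Dm
of reference normal mucosae plus two standard deviations, clamped up to the
assay's technical floor (default 0.15) when the derived value is lower.  The
SD is the *sample* SD (ddof = 1): the reference cohorts are small (11–17
samples) and the n−1 estimator is the standard choice there.  Probes with
fewer than two non-missing reference values get no threshold and are flagged
unusable.  By default thresholds are cohort-specific (each cohort's tumors
are called against its own normals); a `pooled_reference` switch pools all
normals.

**Boundary convention.** All threshold comparisons are inclusive: Dm equal to
the threshold is methylated, and the gene-level HYPER/HYPO subgroups use
"equal to or higher/below" mean ± 2 SD.  One convention is applied uniformly
across probe calls and subgroups.  Inclusive comparisons are evaluated with a
1e-12-relative tolerance so that a value that equals the boundary
mathematically is not excluded by floating-point rounding of `mean + 2·sd`.

**Gene rule.** A gene is hypermethylated when methylated probes make up at
least one-fourth of its *observed* probes.  The published rule assumes
complete probe data; with missing probes we apply the fraction to the
observed subset and flag the call `low_coverage` when fewer than half the
gene's panel probes are observed.  A gene with no observed probes gets no
call.

**CIMP.** The score counts the five Weisenberger genes only (CACNA1G, IGF2,
NEUROG1, RUNX3, SOCS1); the other three CIMP-panel genes (CDKN2A, CRABP1,
MLH1) never enter the score.  ≥ 3/5 is positive.  A sample with any uncalled
score gene is INDETERMINATE rather than guessed.

**Continuous analyses.** Gene-level Dm is the arithmetic mean over the gene's
observed probes.  Both the per-probe and the gene-mean views are available,
since frequency analyses are probe-threshold-based while level comparisons
are gene-based.

## Immunoprofiling

Density comparisons are strict (`>` cut-off): a point is awarded only when the
count *exceeds* the cut-off, and PDCD1-high likewise requires exceeding the
regional cut-off.  Whether the original scoring counted exact ties as high is
not documented; ties at these continuous cut-offs are measure-zero events in
practice and the strict reading matches the wording of the rule.  CD274
positivity requires strictly more than 5 % of cells stained at moderate or
strong intensity — 5 % exactly is negative, and any percentage at weak/no
intensity is negative.  CD274 intensity is an ordinal label supplied with the
data (visual estimation); no image computation is attempted.  Samples missing
any of the four ICS densities get an explicit no-call with a reason rather
than a partial score, and no-calls propagate through the four-type
assignment.

## Genomic grouping

MSI requires at least one unstable marker among BAT25/BAT26; all observed
markers stable is MSS; no observed marker is UNKNOWN.  Hypermutation is
strictly more than 10 nonsynonymous mutations/Mb.  "Ultramutated-range"
(≥ 100/Mb) is an annotation, not a group, because the source classification
treats it descriptively.  The three molecular groups cover hypermutated-MSI,
hypermutated-MSS and non-hypermutated-MSS; non-hypermutated MSI — a
combination absent from the modelled cohorts — and any unknown input are
UNGROUPED rather than forced into a group.

## Statistics

**Two-sided exact p values** follow the "sum of all tables at most as
probable as the observed" definition, for 2×2 (via `scipy.stats.fisher_exact`)
and for r×c (Freeman–Halton, implemented here: depth-first enumeration of all
tables with the observed margins in log-factorial arithmetic, with a
1e-7-relative tolerance when comparing table probabilities to absorb
floating-point ties).  This is the convention of the standard statistical
packages; the alternative tail-doubling definition is not used.  When the
enumeration would exceed a node budget (default 2·10⁶ tables) the test falls
back to Monte Carlo: tables are sampled from the conditional distribution
with Patefield's algorithm (`scipy.stats.random_table`), and the estimate is
reported with its standard error and seed.  Tests are invariant under row and
column permutation.

**Two-group comparisons** are gated on normality: Shapiro–Wilk per group at
α = 0.05 (the gate's α is a package choice; the source analysis states the
gate but not its level).  Both groups passing routes to Student's *t* test;
otherwise Mann–Whitney U — exact enumeration for combined n ≤ 20 without
ties, normal approximation with tie and continuity correction otherwise.  Two
degenerate cases are defined explicitly: constant data in a group fails the
gate (Shapiro–Wilk is undefined there), and two groups with all values
identical give p = 1.  The gate can be bypassed (`method=`) when a specific
test is required.  Correlations are gated the same way between Pearson and
Spearman; zero marginal variance yields an undefined r flagged `degenerate`.

**Multiple testing** uses Bonferroni, `min(1, p·m)`.  Family sizes are not
hard-coded: every reported comparison row carries its family size so the
correction is auditable, and the default comparison set takes the family to
be the genes tested within one panel/comparison block.  The published
analyses do not state their family compositions, so this is configurable
rather than guessed.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
defaults set to the modelled study conditions: group sizes 17/31 (CA-CRC
normal/carcinoma) and 11/14/15 (LS normal/adenoma/carcinoma); normal-mucosa
NTSR1 Dm ~ 0.21 ± 0.15 with a +0.08 additive field-defect shift in CA-CRC
normals (applied to NTSR1 and the CIMP marker genes except MLH1); CIMP+
tumor fractions 0.39 / 0.24 (CA-CRC / LS); ICS-high probability 0.55; CD274
immune-cell positivity 0.52; PDCD1-high 0.58 (center) and 0.68 (margin); MSI
probability 1/31 (CA-CRC) and 1 (LS); a three-component burden mixture
(uniform on 1–10, 10.5–60 and 85–120 mutations/Mb with weights 17:8:2,
27/31 of tumors sequenced).

Dm values are drawn from Gaussians truncated to [0, 1.2] by redrawing.  Only
means and SDs are scientifically constrained; the distributional family is a
simulation choice.  Truncation at 0 compresses an injected additive shift
(for the NTSR1 scale, +0.08 nominal appears as ≈ +0.065 in the generated
means); the recovery tests therefore check against the truncated-normal
expectation, not the nominal shift.  IHC densities are lognormal around the
cut-offs, with a latent per-sample immune-active state that makes the four
section measurements correlated, as they are in real tumors.

Seeding: one master seed; metadata, methylation and IHC draw from separate
deterministically derived substreams (`SeedSequence(seed, spawn_key=...)`),
so regenerating one table never perturbs the others.

What the generator does **not** emulate: probe-level correlation beyond
shared gene effects, batch/run effects, FFPE degradation, tumor-cell-fraction
dilution of methylation signal, and any survival structure.  Passing
recovery tests therefore demonstrate that the pipeline detects effects of the
modelled size under clean distributional assumptions — not that it would
under assay artefacts.

The `printed` module is the complementary fixture: a deterministic per-sample
assignment consistent with every published summary count of the modelled
cohorts (labelled synthetic throughout — the underlying per-sample data were
never published).  Joint cells the publications do not pin down are filled by
a fixed convention (contiguous index ranges over samples ordered by ICS
score) and documented in the module.

## Problem sizes used in validation

The validation suite runs at deliberately modest sizes chosen to make the
checks sharp but quick: threshold-rule equivalence over random references of
2–40 normals; held-out false-positive rates on 500 samples against a
20-normal reference; CIMP oracle equivalence exhaustively over all per-gene
probe-call count patterns for 5 genes × ≤ 4 probes (and all 2¹⁰ binary
matrices at 2 probes); Freeman–Halton against full rational-arithmetic
enumeration for table totals ≤ 25; field-defect recovery power over 200
replicates at 10× group sizes (170 vs 110 normals); null family-wise error
over 200 replicates at published group sizes; type-I calibration over 1000
null replicates at n = 50 per group (asserted within two Monte-Carlo standard
errors of the nominal 5 %).

## Known limitations

* The calling rules assume the input Dm values are already normalised
  (dosage ratios out of the MLPA analysis software); no intra-run
  normalisation or peak processing is performed.
* Gene calls on partially observed probe sets are a pragmatic extension of a
  rule defined for complete data; the `low_coverage` flag should be consulted
  before interpreting such calls.
* The exact r×c test's Monte-Carlo fallback gives a stochastic p; the seed,
  replicate count and standard error are reported so results are reproducible
  and their precision is explicit.
* Bonferroni families mirror the default comparison blocks; analyses with a
  different multiplicity structure must configure families explicitly.
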
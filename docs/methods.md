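# Methods

This note documents the models, conventions, parameter choices and known
limitations of the `pzbd` package, module by module.

## Gapped-motif grammar and scanning (`pzbd.motifs`)

A ZB-motif is written in the field's compact notation: residue letters
are anchors, `x` is exactly one arbitrary residue, `xₙ` exactly *n*, and
`x_{a–b}` any count in [a, b]. Underscores, braces and en-dashes in
transcribed notation are tolerated; bracketed sets (`[CH]`) are accepted
for degenerate anchors. Adjacent gap tokens accumulate. Gap counts are
**exact positions**, not "up to": the motifs align at fixed spacings in
structure-based alignments of the domain, so a subscript means exactly
that many residues.

The scanner enumerates every placement and every gap realisation, so
overlapping matches and alternative realisations of a variable gap are
all reported (ordering: leftmost start, then catalog order, then
shortest realised gap). Classification only asks whether a pattern
matched, taking the highest-priority (catalog-order: canonical before
modified) pattern. The unknown-residue letter `X` in a sequence never
satisfies an anchor but does occupy gap positions — anchors must be
observed residues, gaps are purely positional.

Built-in catalogs per taxon:

| taxon | patterns (priority order) |
|---|---|
| bacteria-GluRS | `CxCx20-21Yx3C`, `CxCx20Yx3H` |
| bacteria-GluQRS | `CxCx11-28Yx3C` |
| archaea-GluRS | `CxCx14CxC`, `CxCx14CxH` |
| eukarya-GluRS | `CxCx20Yx3C`, `CxCx20Cx3C` |

The *E. coli* motif is sometimes transcribed in an alternative reading
ending `…CxH`; the catalogs follow the per-taxon survey groupings above,
and the alternative reading is deliberately not a catalog entry. A
"disrupted" report (`scan_disrupted`) lists near-miss placements where
at least a configurable number of anchors (default 2) match — e.g. the
naturally occurring `CxMx20Yx3W` variant — and is descriptive only,
never used for group assignment.

## pZBD extraction and grouping (`pzbd.classify`)

The pZBD window is the ungapped residue stretch **strictly between** the
last E3 column and the first E4 column of a user-supplied anchored
alignment; the anchor strands never count toward the length, because
domain-deleted sequences retain both strands and must measure near zero.
Anchor columns are inputs (YAML/`AnchorSpec`); the package does not
infer secondary structure.

Group assignment from (length, motif label): motif present → I or II by
catalog rank; otherwise V for length ≤ 17, IV for 31–36, III for ≥ 37.
Motif-free lengths 18–30 fall between the empirically observed
populations and are flagged `unassigned` rather than silently filed —
a deliberate refuse-to-guess zone. Motif-free lengths 37–45 go to
group III ("long") since the long population's lower tail extends below
the 46–54 bulk. Motif scanning for grouping uses the window widened by
3 residues per side so a motif whose terminal anchor sits on a strand
edge still counts.

## Structural geometry (`pzbd.geometry`)

PDB input is parsed with Biopython (first MODEL; alternate locations
resolved to the highest-occupancy conformer, ties to altloc A); a
pre-pass validates the fixed-width coordinate fields and reports the
offending line number. Hydrogens are ignored throughout.

Detector criteria (none of these thresholds comes from the enzyme
literature this package models; they are standard structural-biology
practice, exposed as function parameters):

* **Zn coordination** — candidate ligands are Cys SG, His ND1/NE2,
  Tyr OH and any other N/O atom within 2.8 Å of a Zn hetero atom;
  summarised per site by element counts in S/N/O order (e.g. `S3N1`).
* **H-bonds** — heavy-atom donor/acceptor N/O pairs (simplified
  per-residue tables; backbone N donates, backbone O accepts), at least
  one side-chain atom, distance ≤ 3.5 Å. "Long-range" means ordinal
  residue separation |i−j| ≥ 5 within a chain — ordinal index, not
  author numbering, so insertion codes cannot corrupt the separation.
* **Tyr–(i+4) bond** — Tyr OH within 3.5 Å of the backbone N of the
  residue four positions later in the same chain.
* **Cation–π** — Arg guanidinium centroid (CZ/NH1/NH2 mean) within
  6.0 Å of a Tyr/Phe/Trp six-ring centroid, and ≤ 45° between the ring
  normal (best-fit plane via SVD) and the centroid→cation vector;
  edge-on approaches are rejected. Aromatics with missing ring atoms are
  skipped with a warning.

Superposition solves the orthogonal Procrustes problem through
`scipy.spatial.transform.Rotation.align_vectors` (Kabsch; proper
rotation guaranteed) on centred coordinates; the RMSD is recomputed from
the fitted coordinates rather than taken from the solver's residual, for
full numerical precision. Fewer than three points, or collinear points
(rotation not unique), are errors.

## Genomic co-occurrence (`pzbd.genomes`)

Verdict logic per genome: a pZBD-deleted GluRS is *consistent* with the
redundancy model iff a direct Gln route exists (GlnRS or GluRS2) or the
indirect route is already broken (no gatCAB, or a tRNA^Gln 1/72 pair
that GatCAB cannot recognise):

    consistent = ¬deleted ∨ direct ∨ ¬indirect_intact

The recognition pair is a parameter (default `UA`, i.e. U1-A72).
Matching is **orientation-insensitive by default** — the literature
writes the same recognition element in both orders (U1-A72 as the
requirement, A¹-U⁷² for a genome described as satisfying it), so `AU`
and `UA` are treated as the same pair; `strict_orientation=True` gives
the literal reading. With the default, the packaged seven-taxon fixture
(`pzbd/data/pzbd_deleted_taxa.tsv`, encoded from published in-text
genome annotations) yields exactly one inconsistent genome,
*M. infernorum*. An unknown pair (`?`) conservatively treats the
indirect route as intact and records a note.

The association test is the classical two-sided exact test on the 2×2
table (deletion × direct route): with margins fixed, probabilities of
all admissible tables are computed with exact integer binomial
coefficients and those ≤ the observed table's probability are summed.
Tie comparison is exact (integer), avoiding the floating-point tie
epsilon some implementations need. The suite cross-checks against both
rational-arithmetic enumeration and `scipy.stats.fisher_exact`.

Gene presence/absence detection from raw genomes is out of scope; flags
arrive in the input TSV.

## Binding, kinetics, zinc (`pzbd.kinetics`)

Titrations are fitted with the exact quadratic 1:1 model by default
because the study regime (0.5 µM enzyme vs ~60 nM K_d) is strongly
depleting; the hyperbolic (Langmuir) form is available and agrees with
the quadratic fit in the L ≫ E limit (tested). Fits are bounded
trust-region least squares (K_d, k_cat, K_m ≥ 0) with deterministic
initialisation: a coarse 36-point log grid over the
dissociation/Michaelis constant with the linear parameters solved in
closed form at each grid point. Residuals are internally normalised by
max |y| so the optimizer's gradient-based stopping rule is meaningful
whatever the data units (rates are ~10⁻⁸ M/s); the parameter covariance
is invariant to this scaling. Standard errors are asymptotic
(σ²·(JᵀJ)⁻¹).

ΔΔG = RT·ln(K_variant/K_ref) with R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹
(1 cal ≡ 4.184 J) and T = 298.15 K — the titration temperature (25 °C),
which is the convention that reproduces the published free-energy
differences, even though the activity assays ran at 37 °C. Fold changes
are rounded half-to-even to 2 significant figures by default (3 where
the published values carry three).

Zinc stoichiometry: straight-line least squares through the A500
standards, inverse prediction of the background-subtracted sample
absorbance, ratio to protein concentration. Samples outside the
standards' absorbance range are flagged (warning, or error on request);
a calibration with no concentration spread is an error.

## Synthetic data (`pzbd.simulate`)

Each generator is deterministic given (spec, seed) — a single
`numpy.random.default_rng` stream per call — and returns machine-
readable truth.

* **Sequence cohorts.** Random background (uniform over the 20 amino
  acids) + fixed anchor-strand blocks + a pZBD of group-appropriate
  length: 46–54 for groups I–III, 31–36 for IV, 10–17 for V. Groups I/II
  get one planted realisation of the taxon's pattern; all groups are
  verified by running the scanner itself on the candidate window and
  rejection-sampling until the classification is exactly the planted
  group (so "motif-free" is guaranteed, not merely probable). The anchor
  blocks contain no C/H/Y, so no motif anchor can leak across the window
  boundary. The alignment right-pads each pZBD with gaps to the cohort
  maximum. Cohort members are independent — real phylogenetic covariance
  between sequences is deliberately not emulated, so classification
  accuracy on synthetic cohorts says nothing about alignment quality or
  anchor-column choice on real data (the published survey's exact group
  counts also depend on the authors' alignment and anchors, which are
  not republished here).
* **Structures.** An extended poly-alanine backbone (3.8 Å residue
  spacing, no polar side chains, hence no accidental detector hits) with
  the feature's atoms placed at the exact target geometry: tetrahedral
  Zn ligand directions, an Ser OG placed at the target distance from a
  backbone O, a Tyr OH near the (i+4) backbone N, or a planar six-ring
  plus a guanidinium triangle at the requested centroid distance and
  approach angle. Geometrically impossible specs error.
* **Genome tables.** `deleted ~ Bernoulli(p)`; the direct-route flag
  has baseline probability 0.5, with odds multiplied by the requested
  odds ratio for deleted genomes. Genomes without a direct route are
  filled with an intact indirect pathway (gatCAB + U1-A72) so every
  genome keeps a Gln-tRNA^Gln source.
* **Titration / rate / zinc series.** The exact forward models above
  plus multiplicative Gaussian noise. Defaults are the study conditions:
  K_d = 62.5 nM at 0.5 µM enzyme over 24 ligand additions (dense through
  the stoichiometric transition to 0.9 µM, sparser to 2.6 µM);
  k_cat = 5.3 s⁻¹, K_m = 65.4 µM over eight substrate concentrations in
  50–300 µM at 50 nM enzyme; a Zn:protein ratio of 0.93 at 10 µM protein
  against six ZnSO₄ standards. The titration design matters: in the
  strongly depleting regime K_d enters only through the curvature of the
  transition, so sparse designs inflate its variance substantially.

## Numerical and testing choices

* Scanner correctness is established against an independently written
  recursive backtracking enumerator: exhaustively for every sequence of
  length ≤ 12 over a two-letter alphabet (with short test patterns that
  can actually match at those lengths) and for 10⁴ random sequences of
  length ≤ 40 over a four-letter alphabet against the full bacterial
  catalog.
* Geometry detectors are checked for invariance under random rigid
  transforms (tolerance 10⁻⁶ via rounded signatures) and against naive
  all-pairs enumeration on ≤ 30-residue toy models.
* Published derived quantities are asserted within **one unit in the
  last printed digit**: recomputation shows the source mixes
  round-half-up and truncation in its in-text values (e.g. a 6.16-fold
  K_d ratio printed as "∼6", a 623.5-fold k_cat ratio printed as 623,
  ΔΔG 1.0771 printed as 1.07 but 0.4484 printed as 0.45), so exact
  agreement under any single rounding convention is not attainable;
  values that do reproduce exactly under round-half-even are asserted
  exactly as well.
* Simulation sizes in the tests and the acceptance script (20 replicate
  fits, 1000 null tables of 200 genomes, a 212-sequence cohort) were
  chosen to keep every run comfortably fast while leaving the acceptance
  margins clearly resolvable.

## Known limitations

* Group counts from *real* supplementary alignments are not reproduced —
  that requires the original alignment and the authors' E3/E4 anchor
  columns. The classification round trip is demonstrated on synthetic
  cohorts with planted composition.
* Only cation–π among the stacking interactions is detected; π–π and
  hydrophobic stacking have no published criteria in this context and
  are out of scope.
* Donor/acceptor chemistry is a heavy-atom simplification: no
  protonation-state or angle criteria for H-bonds.
* The binding module covers equilibrium 1:1 titrations only; two-step
  aminoacylation mechanisms, burst kinetics and tRNA-concentration
  dependence are not modelled.
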
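# Methods

## The model

`clock3` implements a deterministic mass-action model of the human
circadian clock that treats PER3 as a first-class network component.  Eight
genes are modelled — *PER1*, *PER2*, *PER3*, *CRY1*, *CRY2*, *BMAL1*, the
merged pair *CLOCK/NPAS2* and the merged pair *REV-ERBα/β* — together with
the kinases CKIδ/ε and GSK3β.  Every species is an mRNA, a promoter state,
or a protein/protein complex; every reaction is mass action of order 0–2, so
each state variable's derivative is a signed sum of rate terms.  The full
system has exactly 208 state variables and 100 named rate constants.

Proteins and complexes built from PER/CRY subunits are labelled in the
`x[P][C][K][L][B]` convention (PER content and phospho-state; CRY content;
bound kinase; location, cytoplasm 0 / nucleus 1; bound BMAL1–CLOCK/NPAS2
activator).  `x10000` is bare cytoplasmic PER1; its derivative is exactly
the six-term balance of translation (`tlpo·McPo`), degradation
(`upuo·x10000`), CKIδ/ε binding/unbinding (`ac`, `dc`) and PER1–PER3
pairing/unpairing (`an`, `dn`).  mRNAs use `Mn`/`Mc` prefixes (nuclear /
cytoplasmic); the oscillation marker is nuclear *BMAL1* mRNA, `MnB`.

### Feedback architecture

* The BMAL1–CLOCK/NPAS2 complex (`x000L1`) binds E-box promoters of the
  five *PER*/*CRY* genes and *REV-ERB*; transcription occurs from the
  activator-bound promoter state.
* CRY1/CRY2 repress in two ways: free nuclear CRY binds the promoter-bound
  activator (states `G<gene>AR1/AR2`), and CRY-containing species
  sequester the free activator in solution (`B` digit).  CRY1 and CRY2
  carry separate binding/unbinding and turnover rates; their kinetic
  asymmetry is what lets one knockout shorten and the other lengthen the
  period.
* REV-ERB closes the secondary loop by repressing *BMAL1* transcription
  (`GB`/`GBRev`).
* CKIδ/ε binds PER proteins and phosphorylates them; the kinase is released
  after each catalytic step.  Phosphorylated PER1/PER2 turn over faster.
  PER1/PER2 bind CRY only in the CKIδ/ε-bound state (phosphorylation
  licenses complex assembly); kinase- or CRY-carrying and phosphorylated
  species shuttle between compartments, bare unphosphorylated monomers do
  not.
* GSK3β binds CRY species and phosphorylates BMAL1 and REV-ERB; CKIδ/ε also
  phosphorylates CLOCK.  Phosphorylated BMAL1/CLOCK/REV-ERB forms are
  degradation-tagged.
* Nuclear PER1/PER2-containing complexes that carry CKIδ/ε engage the
  promoter-bound activator and phosphorylate its CLOCK subunit, evicting the
  complex from the E-box (BMAL1 is released, CLOCK leaves phosphorylated).
  This PER-delivered kinase attack on the DNA-bound activator is the arm
  through which PER1 and PER2 knockouts shorten the period.
* Both kinases are conserved pools — no synthesis or degradation reactions —
  and each gene's promoter states sum to a conserved total.  Both facts are
  verified symbolically from the stoichiometry at construction time.

### PER3

PER3 enters under four structural assumptions: it is phosphorylated by
CKIδ/ε; only within a PER1–PER3 pair; no PER2–PER3 pair exists; and PER3
interacts with CRY1, CRY2, and the BMAL1–CLOCK/NPAS2 activator.  The digit
table reserves codes for the excluded forms (free phospho-PER3, PER2–PER3)
so that relaxing an assumption visibly changes the inventory and is caught
against the shipped whitelist.

Kinetically, PER3's distinctive role is a phospho-gated CRY sink:

* PER3 monomers pair with PER1 (bare monomers via `an`/`dn`; in addition,
  CKIδ/ε-primed PER1 recruits PER3 together with any CRY cargo, sharing the
  same rates).
* PER3 and the pair bind CRY in any kinase state (`arcth`/`drcth`).
* The unphosphorylated pair has no first-order decay: it turns over by PER3
  phosphorylation (CKIδ/ε binding `acth`, catalysis `hoth`) followed by
  degradation of the phospho form (`uppth`), during which the PER1 partner
  survives and emerges phosphorylated.
* Free PER3 is comparatively short-lived (`upth`).

The pair pool size — hence the amount of CRY sequestered away from the
activator — is therefore controlled by the PER3 phosphorylation axis, which
is exactly the axis the human polymorphisms edit: the 4-repeat VNTR allele
(fewer CKIδ/ε sites, `hoth` × 0.6) lengthens the period, the 5-repeat
homozygote (`hoth` × 4) shortens it, the P864A SNP (`acth` × 0.2) lengthens
it, and the P415A/H417R double mutation (`an` × 0.2, PER3 degradation × 8)
shortens it, consistent with the chronotype phenotypes these variants are
associated with.

## Numerical integration

The reference solver is fixed-step forward Euler at dt = 0.005 h, chosen
for speed and bit-reproducibility; SciPy's BDF (the same stiff-solver family
as MATLAB's `ode15s`) provides the cross-check, with rtol 1e-6 / atol 1e-9.
Default runs integrate 600 h and discard a 360 h transient, leaving ten free-
running cycles so the "last two peaks" lie on the limit cycle.  The default
initial state is structured: free promoters at unit copy number, free
kinases at 1.0 a.u. (these set the conserved pool sizes), everything else at
0.1 a.u.; limit-cycle features are insensitive to the preset once the
transient is discarded, which the test suite exercises indirectly by
comparing solvers with different internal states.  Euler states are not
clamped: a negative excursion or overflow raises an instability error with
the failure time rather than being silently corrected.

Accuracy is validated two ways, as is standard for this model class:
step-halving (0.005 h vs 0.0025 h) and Euler vs BDF.  The *state error* of a
simulation is the mean over species and time of |Δ| scaled by each species'
trajectory maximum, measured over a 48 h window from identical initial
conditions.  The window matters: on a limit cycle two solvers with slightly
different effective periods drift apart in phase, so a pointwise comparison
over hundreds of hours measures accumulated phase drift (tens of percent by
construction) rather than local accuracy.  Period differences are therefore
reported separately, from full-length feature runs.  On the fitted ensemble
the per-simulation state errors are well below 0.3% and period differences
below 0.1% for step-halving (0.23% for the stiff cross-check bound).

## Oscillation features

Period = time between the last two peaks of the marker; amplitude = last
peak minus last trough; marker = nuclear *BMAL1* mRNA, switching to nuclear
*PER2* mRNA under *BMAL1* knockout.  Peaks are strict discrete local maxima
refined by three-point quadratic interpolation, which keeps period estimates
meaningful far below the grid spacing.  A trajectory is arrhythmic if fewer
than two peaks survive the transient or the final peak-to-trough excursion
is below 1% of the marker's overall range.  Feature extraction is
time-shift invariant and scale-equivariant (property-tested).

## Genetic perturbations and the condition registry

A knockout sets the gene's transcription rate to zero.  Variant
perturbations multiply every parameter tagged with the edited biochemical
role.  The registry holds 16 phenotype conditions over 12 genetic
backgrounds: a wild-type reference (rhythmic, 24 h ± 5%), eight knockout
conditions, and six PER3-variant conditions whose period shifts must fall
in the 2–6% chronotype band.  "Unchanged" means |Δperiod| < 0.5%;
directional calls must exceed a 0.25% numerical-noise floor taken from the
solver cross-check bounds.  The NPAS2 knockout is structurally a no-op
because CLOCK and NPAS2 are merged into one gene; the registry flags it via
its source tag.

## Parameter estimation (SRES)

Estimation uses a (μ, λ) evolution strategy with log-normal self-adaptive
mutation and stochastic-ranking survivor selection (pf = 0.45): neighbours
are compared by objective when both are feasible or with probability pf,
and by constraint violation otherwise.  Mutation acts in log10 parameter
space (rates are positive, priors span decades) with reflection at the box
bounds.  Full-scale runs use 5,000 generations, 3 parents, population 20;
the shipped ensemble was produced by warm-started, reduced-scale runs (tens
of generations, 300 h simulations) on top of a mechanistic tuning stage
(linear-stability analysis of the fixed point to locate the Hopf
bifurcation, followed by targeted parameter scans).  Because the system is
pure mass action, multiplying all 100 rates by one factor rescales time
exactly; fitted sets are normalised so the wild-type period is ~24 h, which
leaves all percent period shifts untouched.

The objective is a band-distance cost: each condition contributes zero when
its expected phenotype holds, the percentage-point distance to the nearest
band edge for period conditions, an expression-ratio shortfall for
expression conditions, and a fixed penalty (10) for rhythmicity mismatches;
integration failures contribute a large finite penalty (50).  A set is
feasible iff every condition is satisfied, so objective zero and
feasibility coincide by construction.

Parameter ranges: core rates keep ±50%-style boxes around their defaults;
PER3-specific rates get a 10× log-space inflation around their PER1/PER2
homolog values — the least-arbitrary biological prior for rates with no
measurements.  `refine_ranges` shrinks boxes to an inter-quantile band
(default 5th–95th) of the feasible ensemble, never widening beyond the
original limits.

## Validation

Leave-One-Out holds out each condition in turn, re-estimates on the rest,
and predicts the held-out phenotype by majority vote over the feasible sets
found (folds with fewer than five feasible sets are flagged low-power).
Accuracy is the fraction of correct folds; the per-set satisfaction rate is
reported alongside.  Leave-Sets-Out trains on knockout/wild-type conditions
only and evaluates each SNP/VNTR condition post hoc on the resulting
ensemble.  Full-model cross-validation at the published scale amounts to
16 × (hours of estimation) and is exposed through the CLI; the shipped test
and acceptance runs demonstrate the machinery at desk scale on the synthetic
benchmark oscillator, where ground truth is known and folds complete in
seconds.

## The synthetic benchmark oscillator

A nine-species activator–repressor relaxation oscillator (activator drives
its own gene and the repressor's; the repressor sequesters the activator
into a decaying complex) with a ~24 h default period.  It exists to give the
estimator and validation machinery a system with known ground truth; it is
not a reduction of the clock model.  Its condition registries are generated
from the true rates, so estimator feasibility and LOO accuracy have
unambiguous expected outcomes.

## Synthetic cohorts

The cohort generator emulates the *structure* of a two-locus chronotype
association study (n = 380 by default): Hardy–Weinberg genotypes at the SNP
(C/G) and VNTR (4/5-repeat) loci, adjusted-MEQ scores Gaussian around a
genotype-shifted mean (defaults: −3.5 MEQ points per G allele, −3.0 per
4-repeat allele, SD 9), trait-anxiety scores likewise (+2.0 / +1.5 points,
SD 8), ages uniform on 18–38, and chronotype classes from the adjusted MEQ
by the standard banding (≥ 59 morning, ≤ 41 evening).  MEQ age adjustment is
`score + 0.3512·(39.212 − age)`.  Odds ratios use Wald log-scale intervals
with Haldane–Anscombe 0.5 correction for zero cells; chi-squared is the
Pearson statistic with df always reported.  What passing tests show: the
estimators recover planted frequencies, odds ratios and group differences
from data with this generative structure.  What they do not show: anything
about a real cohort — real genotype–phenotype tables have linkage, selection
and reporting structure the generator does not model, and no real counts are
reproduced anywhere in the package.

## Numerical and design choices worth knowing

* dt = 0.005 h is validated by the step-halving and stiff-solver checks;
  doubling it destabilises Euler for fitted rate sets (the fastest
  binding fluxes approach the stability boundary).
* Degradation of a PER unit releases bound CKIδ/ε and leaves CRY/activator
  remainders as the corresponding species; CRY is protected from its own
  turnover while inside PER complexes.
* The 2–6% variant band is the binding constraint on fits: the VNTR-4,4 and
  P864A lengthening magnitudes are the hardest conditions to satisfy
  because slower PER3 phosphorylation both grows the pair pool (lengthens)
  and transiently sequesters PER1/CKIδ/ε (shortens); feasible sets must
  separate these arms.
* In the feasible region found here, the rates that single PER3 out from
  PER1/PER2 are its phosphorylation rate (an order of magnitude above the
  PER1/PER2 rates) and the PER1–PER3 pairing rate; the PER3 CKIδ/ε- and
  CRY-binding constants themselves sit at or below their PER1/PER2
  counterparts, and raising them breaks the variant-band conditions.  The
  mechanistic statement "PER3's distinctiveness lives in its kinase axis"
  survives, but it attaches to the catalytic step rather than the binding
  step in this reconstruction.
* Desk-scale problem sizes used by the shipped tests and acceptance script:
  300–600 h simulations, ensembles of a handful of fitted sets, SRES with
  tens of generations, benchmark LOO with population 8 and 5 generations.
  The library accepts full-scale configurations through the same interfaces.

## Known limitations

* The model is autonomous: no light input, so only free-running periods are
  predicted; entrained phase (chronotype per se) is outside the model.
* Heterozygous knockouts, gene dosage and allele-specific expression are not
  modelled; the VNTR heterozygote is the unmodified baseline.
* The species inventory beyond the five anchored x-codes and the reaction
  grammar are this package's own reconstruction under the stated structural
  constraints; other inventories satisfying the same constraints exist.
* Stochastic (Gillespie) simulation, spatial structure and SBML exchange are
  out of scope.
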
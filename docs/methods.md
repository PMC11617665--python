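# Methods

This note documents the models, numerical choices and known limitations
behind each stage of the pipeline, and what the synthetic-data tests do
and do not demonstrate about real screening data.

## Library curation

Records are standardized before any comparison: the largest organic
fragment is kept (ChEMBL-style entries frequently differ only by a
counter-ion) and charges are neutralized where valence-legal, using the
RDKit standardization utilities. The canonical SMILES of that parent is
the identity key for deduplication, and molecular weight is computed
from the same parent with average atomic weights. The three inclusion
criteria are applied in order — molecular weight window (160–1000 g/mol,
inclusive on both ends), deduplication, activity threshold (potency
> 100 µM removed; unannotated drug records exempt) — and each step's
surviving count is recorded, so the report reads as a curation funnel.
Among duplicates the most potent record survives (lowest potency value,
first-seen on ties): conservative for a reference set of actives, since
the best measured value is the one a screener would act on. Mixed
activity types (IC50 vs Ki) are compared on raw µM values without
conversion; converting would require assay context the inputs do not
carry. Stereochemistry is kept in the dedup key (two stereoisomers are
different compounds) but stripped from scaffold keys (a chemotype is a
constitutional concept).

## Scaffolds and chemotype overlap

The scaffold of a molecule is its ring systems plus the linkers
connecting them, with all side chains removed, under one retention rule:
an atom double-bonded to a ring or linker atom (carbonyl, thiocarbonyl,
imine, sulfone/sulfoxide oxygens, or any other exocyclic double bond)
stays in the scaffold together with its double bond — but without its
own substituents. So benzophenone keeps its bridging C=O (the carbonyl
carbon is a linker) while acetophenone reduces to benzene (its carbonyl
carbon hangs off a side chain), and a steroid 17-ketone keeps the
ring-attached oxygen.

The implementation computes a keep-set in two phases — iterative removal
of terminal non-ring atoms (which provably never touches linker atoms,
as they keep degree ≥ 2 toward their ring systems), then re-addition of
double-bonded partners of surviving atoms — and extracts the induced
submolecule with bond orders preserved. The test suite cross-checks it
on several hundred molecules against an independent oracle that removes
one eligible terminal atom per pass, recomputing ring/linker status on
the current graph each time. Linker direction for the imine rule is not
distinguished (C=N retained when either atom is ring/linker). Acyclic
molecules have no scaffold; they are tabulated separately and never
participate in overlap selection. Overlap selection returns search-set
compounds whose scaffold key occurs among the reference keys, in stable
input order.

Not covered (by design): element- or bond-abstracted framework levels,
scaffold trees, and tautomer-aware keys.

## Consensus docking funnel

Per-program scores are min–max normalized to [0, 1] after orienting so
larger is better (binding free energies in kcal/mol: lower is better;
ChemPLP fitness: higher is better); the best compound maps to 1, the
worst to 0. Normalization happens per program over that program's full
compound table *before* intersecting compound sets, so a compound
missing from another program cannot distort a program's scale. A ranked
list is quartile-gated with |Q1| = ⌊N/4⌋ (remainder to Q4, within-tie
order by compound id) — the only assignment consistent with a best
quartile of 268 from 1075 compounds. Consensus is the unweighted mean of
normalized scores (sum and min are available; the mean keeps the
consensus on the [0, 1] scale), with ties broken by the primary
program's normalized score and then id, making the ranking a
deterministic permutation independent of input row order.

## Inhibition kinetics

Percent inhibition is (1 − A_t/A_c) × 100 from corrected absorbances.
Dose–response curves use the Hill form %Inh = A₁₀₀ / (1 + (IC₅₀/I)^s),
which is 0 at I = 0 by continuity, half-maximal at I = IC₅₀, saturates
at A₁₀₀, and is log-symmetric about IC₅₀ when the cooperativity s = 1.
(Of the two readings of this expression's ambiguous typeset form, only
this one increases with inhibitor concentration, which is what defines
an IC₅₀.)

Rate data over a substrate × inhibitor grid are fitted *globally* — all
inhibitor levels simultaneously with shared parameters — rather than
per-curve: fewer parameters, and the inhibition constant is pinned by
the level-to-level pattern rather than by differences of per-curve
estimates. The four mechanisms are the classical reversible laws
(competitive raises apparent K_m; uncompetitive scales the S term;
noncompetitive scales the whole rate; mixed carries separate K_i and
K_i′). Fits are unweighted least squares (Levenberg–Marquardt via
lmfit); positivity is enforced by optimizing log-parameters, standard
errors come from the Jacobian-based covariance at the optimum mapped
back to the natural scale by the delta method, and models are compared
with AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1). Initial values:
V_max⁰ = 1.2·max(v), K_m⁰ = median(S), K_i⁰ = smallest positive
inhibitor level, A₁₀₀⁰ = max response, IC₅₀⁰ = concentration nearest
half-max, s⁰ = 1. Dose–response fitting refuses flat or inverted data
(no positive rank correlation between concentration and response)
rather than returning a meaningless optimum.

The Lineweaver–Burk transform (OLS of 1/v on 1/S per inhibitor level) is
provided as a diagnostic only: shared 1/v intercepts → competitive,
parallel slopes → uncompetitive, shared abscissa intercepts →
noncompetitive, within a relative-spread tolerance that defaults to 10%
(assay scale) and should be tightened for noise-free data. Reported
parameters always come from the nonlinear fit. The mechanism
auto-selection compares the three pure mechanisms by AICc; the mixed
model nests all of them, so including it by default would cost ~2 AICc
points for a redundant parameter and erode discrimination — it is
compared only when explicitly requested.

### Identifiability at the default study conditions

The default generator conditions are deliberate: inhibitor at
{0, 0.005, 0.040, 0.060} mM, substrate at {0.10, …, 0.50} mM, 3
replicates, 2% multiplicative noise, generating parameters
V_max = 36.06 mM/min, K_m = 25.71 mM, K_i = 0.0234 mM. Because the
substrate window lies ~50× below K_m, the rate law is effectively
linear in S (v ≈ (V_max/K_m)·S / (1 + I/K_i)), and the data determine
only the ratio V_max/K_m and K_i. K_i is recovered within a few percent
across seeds; V_max and K_m individually wander tens of percent along a
flat likelihood ridge (their estimates are almost perfectly correlated),
and no fitting procedure can do better on such a design. For the same
reason the competitive and pure-noncompetitive laws are nearly
observationally equivalent there (they differ only in whether the S term
is scaled by (1 + I/K_i), a ≤ 2% effect when S ≪ K_m), and the
extrapolated 1/v intercepts of a Lineweaver–Burk plot become
ill-determined — a caution against diagnosing mechanism from
double-reciprocal plots under these conditions. The mechanism-
discrimination test suite therefore uses K_m = 0.25 mM, centred in the
substrate window, which is how an assay intended to discriminate
mechanisms would be designed; there AICc identifies the generating
mechanism in ≥ 90% of seeded simulations at 2% noise.

## Structural analysis

Superposition is the closed-form least-squares rigid fit (SVD
construction with the determinant sign fixed, so reflections are never
returned); near-collinear selections trigger a conditioning warning.
Pose RMSD for docking validation uses identity atom correspondence in
input order and no superposition, matching re-docking conventions where
both poses share the receptor frame; graph-symmetry-corrected pose RMSD
(as symmetry-aware services compute) is out of scope. Trajectory RMSD
and RMSF default to the backbone C/CA/N atom-name selection.
RMSF references the time-mean structure after two alignment passes
(align to evolving mean); an optional separate alignment selection lets
the user align on a stable core so a mobile tail cannot drag the fit —
the standard practice for proteins with disordered regions. Contact
occupancy counts a residue in a frame if any ligand–residue heavy-atom
pair is within the cutoff (default 4 Å) and supports frame-window
restriction to separate binding modes. MM/PBSA aggregation computes
per-frame Δ = complex − receptor − ligand for each component, sums
ΔE_MM = ΔE_int + ΔE_elec + ΔE_vdw and ΔG_solv = ΔG_PB + ΔG_SA, and
reports mean ± sd over frames; the entropy term −TΔS is accepted as a
scalar or per-frame column (normal-mode analysis requires force-field
Hessians and is not reimplemented), and without it the result is
flagged as enthalpy-only. The combiner is agnostic to whether the
component table came from single- or multi-trajectory extraction.
Coordinates are Å throughout; the PDB reader (biotite-backed) tolerates
missing element columns by inferring the element from the atom name.

## Synthetic data

Every generator is driven by one seeded numpy Generator (same seed ⇒
identical bytes) and writes its planted ground truth beside the data.

* **Libraries** decorate a fixed pool of scaffolds (chosen to be their
  own scaffolds under the rules above) with alkyl/halide/ether side
  chains, topping up with butyl chains until the molecular weight enters
  the window, and plant configurable fractions of violations: MW
  outliers on both sides, duplicates rendered as non-canonical SMILES of
  an existing compound with a weaker activity, and weak actives
  (> 100 µM).
* **Docking scores** share one latent affinity per compound; program
  scores are affine transforms of the latent plus noise, with the
  latent weight calibrated via ρ = 2·sin(π·r_s/6) so the pairwise
  Spearman correlation matches the requested value. Defaults: 1075
  compounds, r_s = 0.85.
* **Kinetics** datasets apply multiplicative Gaussian noise
  (CV-parameterized) to the exact model curves — the standard error
  model for absorbance-derived rates, where error scales with signal.
* **Trajectories** are zig-zag toy backbones (non-collinear by
  construction) whose residues hop between +A and −A along y with
  independent, exactly balanced random sign sequences, so each atom's
  time mean is its base position and its fluctuation is exactly A under
  core alignment; an even frame count is required for the exact balance.
  An optional single-atom ligand sits at a fixed offset from a chosen
  residue's CA for exactly k of N frames, planting occupancy k/N (the
  geometry keeps every other residue outside the 4 Å cutoff; the contact
  residue should not be placed in the high-amplitude tail).
* **Energy tables** draw each system-component as a Gaussian around
  means chosen so the per-frame Δ components hit configured values
  (defaults sum to ΔH = −45.11 kcal/mol with per-component sd
  1.6 kcal/mol).

What these tests show: the arithmetic of every stage is correct against
independent oracles and planted truths, and the fitters are unbiased in
the small-noise limit. What they do not show: robustness to the failure
modes of real data — tautomers and charge states the standardizer does
not normalize, docking score distributions with heavy tails or program-
specific failures, assay artifacts (compound aggregation, absorbance
interference), force-field or continuum-solvent error in MM/PBSA
components, or atom-mapping ambiguity in pose RMSD.

## Problem sizes

Default test problem sizes are small by choice — 60-point kinetic
datasets, 100-frame trajectories and energy tables, ~10³-compound score
tables, a few hundred oracle molecules — because every quantity tested
is either exact (planted truths, closed forms) or already stable at
these sizes; the generators scale to larger inputs by configuration.
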
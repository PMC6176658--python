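# Methods

This note documents the models implemented in `hergscreen`, the choices
made where the protocol left details open, and what the synthetic-data
experiments do and do not demonstrate.

## Molecules and standardization

Molecules are RDKit mols with explicit hydrogens. Standardization assigns
the dominant pH 7.4 protonation state by SMARTS rules for the common
ionizable groups (carboxylic acids deprotonated, non-amide aliphatic
amines protonated) rather than a full pKa model; Gasteiger empirical
partial charges are used throughout, and a brief MMFF94 relaxation is the
geometry hook. The charge scheme and relaxation method are recorded in
provenance because descriptor energies depend on them. "Standard 3D
conformation" means a single seeded ETKDG embedding with a short MMFF
relaxation; `minimized` and `stochastic` (multi-conformer random-coordinate
embedding) variants are available and tagged. All stochastic operations
take an explicit integer seed; there is no global random state.

Pharmacophoric features: aromatic sites are aromatic-ring centroids;
hydrophobic sites are centroids of maximal connected fragments of at least
three non-aromatic carbons having no heteroatom neighbours (the threshold
is configurable — the literature never defines this feature precisely);
acceptors and donors are heteroatom/polar-hydrogen positions from SMARTS
definitions. Feature *kinds and counts* depend only on topology; positions
depend on the conformer.

## Interaction fields

The field of probe p at grid node x is
E(x) = Σ_atoms [E_LJ + E_el + E_hb], clamped above at +5 kcal/mol:

* E_LJ: 12-6 Lennard-Jones with per-element radii/well depths and
  geometric-mean combination with the probe.
* E_el: Coulomb with distance-dependent dielectric D(r) = 4r.
* E_hb: Gaussian in distance (centre 2.9 Å, width 0.5 Å), damped by
  cos² of the deviation from the donor/acceptor axis. The N1 (donor) probe
  targets acceptor atoms, the O (acceptor) probe targets polar hydrogens.
* The DRY probe carries no charge or H-bond term but receives a
  polar-proximity *penalty* (+1.5 kcal/mol Gaussian around H-bonding
  atoms), reflecting that hydrophobic probes disfavour polar surface.

The N1 H-bond strength (5.5 kcal/mol) is set so that an isolated carbonyl
acceptor reaches the −4.2 kcal/mol node cutoff on-axis once LJ repulsion
and electrostatics are included; the O probe strength (4.0) similarly
clears its −2.6 cutoff at hydroxyl donors. These parameters are a
simplified, documented stand-in for proprietary grid force fields:
absolute energies are not comparable to any commercial package, but the
hotspot geometry — ring faces, H-bond cones, molecular extremities — which
is all the correlograms encode, is preserved.

TIP (shape) is not an energy function: nodes within ±0.25 Å of the
solvent-accessible surface (union of spheres, water radius 1.4 Å) receive
a pseudo-energy of −1.0 kcal/mol, surviving the −0.75 cutoff exactly on
the surface shell. Buried necks between fused spheres are excluded by the
signed-distance definition.

Node extraction keeps energies at or below the per-probe cutoffs (DRY
−0.5, O −2.6, N1 −4.2, TIP −0.75 kcal/mol) and prunes to at most 100 nodes
by energy-weighted farthest-point selection (ties broken by grid index, so
the result is deterministic). Correlograms use 0.4 Å half-open bins over
0–40 Å; per probe pair and bin the encoder keeps the maximum |E_i·E_j|
(per-compound maximal encoding). The dataset-consistent variant re-selects,
among near-maximal candidate pairs (≥ 80% of the bin maximum), the product
closest to the dataset median of that bin; this is an approximation to
consistently-large encoding, and the per-compound maximal mode is the
default. Grid spacing defaults to 0.5 Å with a 5 Å margin. Rigid-motion
invariance holds up to grid re-snap drift; the test suite bounds this
empirically at fine spacing.

## PLS, cross-validation, variable selection

PLS1 by NIPALS on column-centred, unscaled X (energy-product variables
share units; autoscaling is available and recorded per model). At full
column rank the collapsed coefficient vector equals OLS, which the tests
assert against a normal-equations oracle. Leave-one-out q² uses the
fold-training mean in its denominator (the convention under which
SDEP = √(PRESS/N) is the cross-validated error); each fold refits
centring. The final model uses two latent variables by default — q²
degrades beyond LV2 on this class of data — while statistics are reported
for up to five.

FFD selection: per cycle, a balanced random two-level inclusion design
with 2·(V + D) rows and D ≈ 0.2·V dummy variables; each row's subset is
scored by LOO SDEP at the model's LV; a variable's effect is
mean(SDEP | excluded) − mean(SDEP | included). By default a variable is
retained only when its effect exceeds the mean absolute dummy effect, so
variables statistically indistinguishable from dummies are discarded with
the harmful ones (a retain-uncertain mode implements the conservative
alternative). Variables whose univariate |correlation| with y exceeds the
95th percentile of seeded noise-column correlations are never removed.
The applicability domain is the min/max box of the first two PCA scores of
the training descriptors, expanded by 10%.

## Efficiency metrics and templates

LipE = pIC50 − clogP; LE = 1.37·pIC50/HA where 1.37 = RT·ln10 at 298 K in
kcal/mol; FQ = LE / LE_scale(HA) with the published size-scaling fit
LE_scale(HA) = 0.0715 + 7.5328/HA + 25.7079/HA² − 361.4722/HA³ (valid from
8 heavy atoms). Template selection applies strict thresholds LipE > 4.0,
LE > 0.39 kcal/mol/HA, FQ > 1 and ranks by LipE, then FQ. The LE threshold
is sometimes printed with a spurious minus sign in the literature; a
negative bound would be vacuous for actives, so 0.39 is implemented (and
configurable).

## Pharmacophores

A model is 3 or 4 typed features with a symmetric distance matrix and a
per-pair tolerance (default 1.0 Å). The "Gaussian radius" of
feature-matching software is realized as this hard window because only
binary match outcomes are consumed downstream; a soft Gaussian score
(threshold 0.5) is exposed as an option. Embeddability in 3-space is
checked at construction by classical MDS refined with least squares,
allowing 0.5 Å slack for printed rounding; one packaged reference matrix
grossly violates the triangle inequality as printed and is therefore
loaded in non-strict mode with its deviation recorded in provenance.
Matching searches all injective, kind-compatible assignments of perceived
sites to model features (at most four features, so the search is trivially
cheap and exhaustive) over all conformers, deterministically.

The standard MCC formula is implemented, defined as 0 when any marginal is
zero. Recomputing MCC from the packaged confusion counts reproduces the
printed values within 0.01 for 23 of the 26 reference models; for three
closed-state rows the printed MCC is inconsistent with the printed counts
(the counts themselves follow the table's TP+TN and FP+FN structure, so
the MCCs are misprints). The package reports what the counts imply.

## Screening

Curation rules apply in a fixed order (duplicates → fragments → assay →
cell line) so each record has exactly one fate and the bookkeeping
identity input = retained + Σ removed holds on any input; replicate IC50s
merge by geometric mean and are flagged discordant beyond one log unit.
The diverse split seeds the test set by farthest-first traversal on
2048-bit radius-2 circular fingerprints; the test-set size is
N − round(0.8·N), which gives the conventional 41 of 207. Lipinski "pass"
allows one violation. The screening funnel persists every stage outcome;
pharmacophore and Lipinski filters commute, which is asserted on synthetic
libraries.

## Dose-response

Hill fits run in (log IC50, log nH) space (positivity by construction)
with Levenberg-Marquardt least squares; initial values are nH = 1 and the
geometric mean of the concentration range. Fits attach an extrapolation
warning when no concentration brackets half-block, and reject responses
that increase with concentration. No replicate weighting is applied by
default; inverse-variance weights are an option. Percent block is
100·(1 − y).

## Synthetic data: what it emulates and what it does not

`make_sar_dataset` assembles molecules from 8 drug-like scaffolds × 12
substituents spanning none-to-several donors/acceptors and aliphatic bulk,
embeds one seeded conformer each, and draws pIC50 = 5 + β·x + N(0, 0.3)
clipped to [3, 9], where x counts feature-pair (kind, 2 Å distance-bin)
occurrences. The five generating coefficients sit on bins chosen once for
good occupancy and conditioning across this library, with signs that
mirror hERG structure-activity lore (aromatic pairs, ring-adjacent
acceptors and hydrophobic bulk increase potency; donor-rich patterns
decrease it); hydrophobic bulk carries the largest weight. The generator
returns β, the bin labels and the descriptor matrix, so recovery
experiments are self-contained. Coefficient recovery is evaluated at
near-full-rank (12 latent variables) restricted to the generating bins —
two-LV coefficients are shrunk by construction and are not an estimate of
β. Noise is Gaussian on the log scale, the standard QSAR error model.

Pharmacophore actives are built geometrically: anchor points from the
model's 3-space embedding (jittered ≤ 0.15 Å per coordinate), with an
aromatic ring centred on each aromatic anchor, a propyl cluster on the
hydrophobic anchor and a carbonyl oxygen on the acceptor anchor, joined by
ether linkers that do not create spurious hydrophobic fragments. Decoys
use the same graph with random anchor geometry, so they carry the correct
feature kinds at wrong distances — a harder negative than feature-deficient
molecules. Bond lengths along linkers are not physical; these molecules
exercise feature geometry, not force fields.

The 14 Å correlogram fixture is a two-ring "dumbbell" with a polyether
linker and an ether cap under one face of each ring, so the exposed ring
faces dominate the hydrophobic field and the DRY–DRY maximum falls at the
inter-terminal distance.

Passing tests on these generators shows that each stage recovers known
structure under its own statistical assumptions (linear descriptor
response, log-normal noise, geometric feature matching). It does not show
that real hERG data satisfy those assumptions, that the simplified field
parameterization matches any commercial package's energies, or how the
pipeline performs on experimentally measured potencies.

## Problem sizes and numerics

Default experiment sizes — 200 compounds for recovery/selection studies,
50 + 50 actives/decoys for classification, 50 seeds for Hill recovery —
are the package's chosen study conditions. Energy fields clamp at
+5 kcal/mol inside clashes; LOO is computed by refitting every fold (the
"fast path" shares the fitting code and is asserted equal to explicit
refits to 1e-10); FFD designs and all generators are reproducible from
their seeds. Degenerate inputs (constant response, all-variables-removed
selection, non-bracketing dose ladders, non-embeddable matrices) raise
typed errors or attach warnings rather than returning silently.

## Known limitations

* The field parameterization is deliberately minimal: no explicit
  polarizability, no entropic water model, element-level LJ parameters.
* Protonation rules cover the common ionizable groups only; tautomers and
  stereoisomer enumeration are out of scope (input stereo annotations are
  honoured).
* The dataset-consistent correlogram mode approximates consistently-large
  encoding by a median-consistency rule; the exact published objective is
  not reproduced.
* Pharmacophore matching is hard-window and binary; partial matches score
  only through the optional soft mode.
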
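# Methods

This note records the models, conventions and numerical choices behind
`allofoot`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Structure handling

Structures are read with gemmi (mmCIF or PDB) and reduced to a
chains→residues→heavy-atoms hierarchy. Alternate conformations collapse
to the highest-occupancy conformer, ties broken by altloc identifier;
zero-occupancy atoms are dropped; waters and small-molecule heteroatoms
are kept apart from the polymer. Hydrogens are discarded by default:
the complexes of interest are medium-resolution X-ray models (~2.4 Å)
whose hydrogen positions would be model-dependent, so every geometric
criterion below is defined on heavy atoms.

Residue numbering is the mature-protein numbering of the HLA α chain
(epitope positions 14, 17, 19, 39, 90 and so on); a per-chain integer
offset reconciles author numbering in deposited files where needed, and
is validated in practice by checking that position 90 of the α chain is
an aspartate. Crystal asymmetric units with several complex copies are
analysed one copy at a time (first complete copy by default). Chains are
role-labelled (`hla_alpha`, `b2m`, `peptide`, `fab_heavy`, `fab_light`,
`receptor`); automatic assignment uses polymer length (α ≈ 275, β2m ≈ 99,
peptide ≤ 15 residues) but refuses to guess heavy versus light among
Fab-sized chains — for deposited Fab–HLA complexes the helper in
`allofoot.deposited` resolves the ambiguity by which Fab chain contacts
β2-microglobulin (the heavy chain, in this lateral binding mode).

## Surface areas and the footprint decomposition

SASA is Shrake–Rupley: each atom's sphere (van der Waals radius + 1.4 Å
probe) is sampled on a deterministic golden-spiral lattice (960 points by
default) and the unoccluded fraction scaled to the sphere area. Radii
default to the Chothia-type set C 1.70, N 1.55, O 1.52, S 1.80 Å and are
configurable. With the lattice and point count fixed the computation is
bit-reproducible. It is only *approximately* rotation invariant — the
lattice is global, so rigidly rotating a complex changes individual point
classifications; at 960 points the total footprint of the test complex
moves by ~0.3%, and the invariance test uses a 0.5% band accordingly. An
independent implementation by Gauss–Legendre quadrature over latitude
bands (`allofoot.gridsasa`) serves as numerical cross-check; the two
agree to well under 2% per atom on random clusters.

The footprint is the one-sided ΔSASA of the HLA side (α chain + β2m; the
presented peptide is excluded by default because the interface of
interest does not bury it, with a flag to include it). For the per-Fab-
chain decomposition, every surface point that is accessible with the Fab
absent and occluded with the Fab present is attributed to the Fab chain
whose atom buries it most deeply (largest sphere penetration; a
deterministic tie-break). This makes the decomposition an exact partition
of the total — the per-pair areas sum to the footprint to machine
precision — while reducing to the naive per-chain ΔSASA whenever the
heavy- and light-chain occlusion shadows do not overlap. A plain
symmetric ΔSASA of either side is also exposed for PISA-style
half-buried-area cross-checks.

## Contacts, hydrogen bonds, epitope segments

Contacts are cross-interface residue pairs whose closest heavy atoms lie
within 4.0 Å (configurable), found with a k-d tree and verified in tests
against an all-pairs oracle (exact set equality). Hydrogen bonds use
heavy-atom geometry: donor–acceptor distance ≤ 3.5 Å and an antecedent
angle proxy ≥ 90° at both ends (the angle between the bonded heavy-atom
antecedent, the donor/acceptor, and the partner atom), with donor and
acceptor atom templates for the standard residues; records are
deduplicated per donor–acceptor atom pair. Salt bridges are tagged when
formally charged side-chain atoms of opposite sign approach within 4.0 Å.
Both cutoffs are monotone: enlarging either criterion can only add
records, a property the tests exercise.

The epitope is the set of HLA-side residues appearing in at least one
contact. Its α-chain positions are partitioned into maximal runs where
consecutive members differ by at most 3 (the gap tolerance); with the
canonical epitope {14, 16–19, 39, 90} this yields the three discontinuous
segments characteristic of the lateral alloantibody footprint. Backbone
rearrangement on binding is reported as per-position Cα displacement
after Kabsch superposition of the unbound reference on a user-chosen
alignment range.

## Reactivity prediction

Panel sequences are assumed pre-aligned to mature α-chain numbering
(class-I α chains are length-conserved over the epitope region), so
variant calling is positional. Substitution effects follow a small rule
table: a hydrogen-bond-involved residue losing side-chain donor/acceptor
chemistry or ≥3 side-chain heavy atoms → `hbond_loss`; charge sign flip →
`charge_reversal`; charged→hydrophobic → `charge_to_hydrophobic`;
otherwise large truncation or `conservative`. Positions 90, 14, 17 are
*critical* (hydrogen-bond loss or any charge change there abrogates
binding); 19 and 39 are *weakening* (binding reduced, allele still
reactive) — all defaults overridable. An allele is predicted nonreactive
iff it carries at least one abrogating substitution; β2m is monomorphic
and excluded from the rules. Observed classes use the bead-assay
convention reactive ⇔ MFI ≥ 500. Whether a weakening-only variant should
ever cross the threshold is not decidable from structure alone; we chose
weakening → reactive, and the synthetic generator plants weakened alleles
in the reactive MFI band consistently with that choice.

## Superposition and clash scoring

Kabsch superposition (SVD with reflection correction) on Cα atoms of the
shared HLA α chain, positions 1–180 (the α1–α2 platform) by default;
collinear fits are rejected. The α chain alone is the default frame —
including β2m is supported but not default, since the receptor complexes
of interest share only the α-chain platform reliably. Steric
compatibility of the Fab with a superposed receptor is the count of
heavy-atom pairs with van der Waals overlap > 0.4 Å (the common clash
convention; configurable), which operationalizes "little or no steric
hindrance" as a small clash count. Only the ~50 kDa Fab is modeled;
whole-IgG geometry is out of scope.

## Kinetics

Single-cycle kinetics are simulated in closed form: per phase with
constant analyte concentration C, R(t) = R_eq + (R_0 − R_eq)e^(−k_obs t)
with k_obs = k_aC + k_d and R_eq = R_max C/(C + K_D), continuous across
boundaries; C = 0 gives pure exponential dissociation. Closed form was
chosen over numerical integration because it is exact for the 1:1 model
and makes half-life and steady-state tests analytic (half-life ln 2/k_d).
No mass-transport or bivalent-analyte terms are modeled. The default
design mirrors the assay: five injections at 2.5, 5, 10, 15, 20 nM
(increasing, endpoints as specified for the instrument protocol), 105 s
each, then 600 s dissociation, sampled at 1 Hz.

Fitting is Levenberg–Marquardt least squares over (k_a, k_d, R_max) in
log space (positivity by construction, steps clamped to avoid overflow).
The automatic initial guess takes k_d from a log-linear regression of the
dissociation tail and k_a from the early-association slope
(dR/dt ≈ k_a C R_max at R = 0). On the default design the fit recovers
noiseless parameters to ~1e-15 relative, has median relative error ≈2% at
1% R_max Gaussian noise, and is unbiased to <2% over 100 seeds at 0.5%
noise. The equilibrium constant is always reported as K_D = k_d/k_a
(≈3.2 nM for k_a = 1.04×10⁵ M⁻¹s⁻¹, k_d = 3.3×10⁻⁴ s⁻¹); the package
never adjusts it toward an externally quoted figure. Saturation curves
are fit to signal = B_max C/(K_D + C).

## Cytotoxicity statistics

cytotoxicity% = (experimental − baseline)/(maximum − baseline) × 100,
with below-baseline values reported as-is (they are informative about
assay noise). The Mann–Whitney test is exact by full enumeration of all
C(n₁+n₂, n₁) assignments of the pooled mid-ranks (observed tie pattern
fixed); the two-tailed p is the doubled smaller tail capped at 1 — the
convention under which complete separation gives 2/70 ≈ 0.0286 at 4 vs 4
and 2/20 = 0.10 at 3 vs 3, the smallest attainable levels at those sizes.
Beyond 20 combined observations the tie-corrected normal approximation is
used and flagged as non-exact. Kruskal–Wallis uses the tie-corrected H
with the chi-square approximation; Dunn's pairwise z statistics use the
tie-corrected pooled variance with Bonferroni family-wise adjustment by
default (any statsmodels adjustment accepted) — the correction family is
a convention choice, recorded here because reports rarely state it.

## Synthetic data: what it shows and what it does not

Toy complexes are assembled from idealized residue templates (fixed
internal geometry, side chains extended along one axis) placed rigidly,
so planted contacts, hydrogen bonds and buried patches are exact by
construction; ground truth is recomputed with plain all-pairs arithmetic
independent of the production neighbor-search code, and buried-area truth
comes from the quadrature oracle. The flagship complex reproduces the
*topology* of the lateral Fab–HLA engagement (three α-chain segments, the
light-chain bond to Asp90, four heavy-chain bonds to Arg17, a β2m patch
touching only the heavy chain) at roughly one-third the area scale of a
real interface, since probe residues rather than full CDR loops provide
the burial. Passing on these toys therefore demonstrates correctness of
the geometry engines and bookkeeping — not that a particular deposition
reproduces particular printed areas; the latter is checked separately
against the deposited structures when they are available locally
(`scripts/fetch_structures.py`).

Allele panels plant abrogating (90 D→A, 14 R→W, 17 R→S) and weakening
(19 E→K, 39 D→Y) substitutions on a randomized background and draw MFI
uniformly from bands (0–400 nonreactive, 600–20000 reactive) straddling
the 500 threshold with a margin, so planted concordance is 100% for any
threshold between the bands. Sensorgram noise is i.i.d. Gaussian —
no drift, no instrument noise spectrum. Cytotoxicity replicates are
scaled Beta draws (baseline ≈ 0.08–0.12, maximum ≈ 0.85–0.95) with a
complete-separation scenario that pins the exact-test boundary case and a
null scenario for calibration. All generators are seed-deterministic to
the byte.

## Problem sizes

Default test and acceptance runs use the sizes above: toy complexes of a
few hundred atoms, 50 random SASA clusters, 20-seed (noise study) and
100-seed (bias study) kinetics fits on ~1100-point sensorgrams, 10⁴
null-calibration simulations at 4 vs 4, and a 10⁵-draw vectorized
permutation oracle for Kruskal–Wallis. These sizes give Monte-Carlo
standard errors comfortably below the tested tolerances.

## Known limitations

* Finite-lattice SASA is not exactly rotation invariant (~0.3% at 960
  points); raise `n_sphere_points` where tighter invariance matters.
* Hydrogen-bond detection is geometric; without hydrogens, bifurcated and
  water-mediated bonds are invisible and borderline pairs near 3.5 Å flip
  with small coordinate changes — the criteria are configurable within
  chemically sensible ranges for that reason.
* Reactivity rules are a structural rationalization, not an energy model:
  they do not predict MFI magnitude, only class, and alleles outside the
  panel are not modeled.
* The 1:1 kinetics model ignores avidity of bivalent IgG and mass
  transport; fitted rates from real sensorgrams inherit those caveats.
* Heavy/light disambiguation for unannotated depositions relies on the
  β2m-contact heuristic, which is specific to laterally binding
  antibodies of this kind.
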
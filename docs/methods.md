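# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the synthetic data used to exercise them, and the numerical
and design choices made where several defensible options existed.

## Activity curation

Compounds are labelled from experimental potencies with strict per-assay
thresholds (active iff IC50 < 4100 nM, Ki < 1500 nM, or EC50 < 25 µM; all
configurable, boundaries inactive). A compound with several records is
active if **any** record passes — the permissive OR matches how activity
evidence across assay formats is usually pooled when actives are scarce. A
pre-labelled fold-change flag is accepted as activity evidence but never
computed.

pIC50 = −log10(IC50 in mol/L). Ki records convert assuming IC50 = 2·Ki,
the Cheng–Prusoff-style factor appropriate for competitive inhibition at
substrate concentration near K_m. When both an IC50 and a Ki record exist,
the IC50 is used directly so the ×2 assumption is avoided; within a
measure the most potent value wins. EC50 (functional potency) is **not**
convertible to pIC50 — mixing functional and binding potency scales
corrupts a regression target — so EC50-only compounds raise a conversion
error unless the caller explicitly overrides (the override treats the EC50
as an IC50 and is logged as such).

Deduplication keys on canonical isomeric SMILES: enantiomers and
diastereomers are distinct entries, since stereochemistry determines
activity at this receptor.

## Fingerprints, clustering, modal fingerprints

Fingerprints are sets of hashed radius-2 circular atom environments
(RDKit Morgan identifiers, sparse/unfolded). Like MOLPRINT-2D, these
describe each atom by its neighbourhood shells; the set representation
makes Tanimoto similarity exact rather than fold-collision-prone. Backend
and radius are pinned in `FINGERPRINT_CONFIG`.

Clustering is agglomerative on the 1 − Tanimoto distance matrix, cut to
`n_clusters` groups. Average linkage is the default — stable on small sets
and the common default in commercial cheminformatics suites; single and
complete linkage are exposed. The linkage criterion is genuinely open
(unspecified in the workflow this reproduces), hence config. After the
cut, every cluster smaller than `min_size` (default 3, i.e. singletons and
doubletons) is merged into one outlier cluster. This deterministic rule
replaces the manual cluster editing a modeller would do interactively;
inputs are sorted lexicographically by compound id first, so the partition
is independent of input order.

A modal fingerprint keeps the environments present in at least
`freq_threshold` (default 0.5) of a cluster's members; ranking a library
by Tanimoto to the modal fingerprint gives the cluster-level similarity
screen. Raising the threshold can only shrink the bit set (tested as a
property).

## Property-matched decoys

Decoys are presumed non-binders that look like the actives
physicochemically but not topologically, following the DUD-E methodology:
matching on MW, clogP, HBD, HBA, rotatable-bond count and net charge.
Because the published service queries ZINC, which is out of scope here,
selection runs over a user-supplied or synthetic candidate pool:

* eligibility: per-property z-scored distance to the active ≤
  `property_z_window` (default 0.5; z-scores over the pool — a constant
  pool property falls back to raw differences), and Tanimoto to **every**
  active < `tc_cutoff` (default 0.25);
* ranking: Euclidean distance in z-space, ties broken by compound id;
* assignment: greedy per active in input order, no decoy reuse, no
  backtracking. A shortfall raises an error naming the active — silent
  relaxation of decoy constraints would corrupt every downstream
  enrichment number.

Decoy matching operates on the neutral 2D structures: decoy generation
precedes protonation-state assignment in the workflow, and matching
neutral forms keeps the net-charge criterion meaningful for a pool
assembled from neutral fragments.

## Pharmacophores

Feature perception maps SMARTS rules (editable; defaults in
`featuredefs.py`) onto one conformer: each match contributes a feature at
the centroid of its matched heavy atoms. P and N features follow the
formal charges of the curated protonation state (N at the centroid of the
charged group — e.g. the whole carboxylate); R features sit at aromatic
ring centroids; H covers methyls, chain CH2 and aromatic halogens.
Protonation at pH 7.4 uses a rule set (protonate aliphatic amines,
deprotonate carboxylic/phosphinic/phosphonic/sulfonic acids) sufficient
for the zwitterionic GABA/baclofen chemotypes; one canonical protomer is
kept, and no tautomer enumeration is attempted.

A hypothesis is 3–7 typed features with coordinates; its pairwise distance
matrix, a tolerance (default 2 Å), a minimum intersite distance (default
2 Å, 1.5 Å useful for very similar compound series where the default
yields too few feature combinations) and a `min_match` rule (default: all
features). Matching builds the correspondence graph — node = kind-
compatible (hypothesis feature, molecule feature) pair, edge = mutually
consistent distances within tolerance — and searches cliques of size ≥
`min_match`. Each candidate clique (including sub-cliques, since a
maximal clique can fail the geometric gate while a subset passes) must
additionally superpose with Kabsch RMSD ≤ tolerance using **proper
rotations only**: distance-matrix matching alone cannot distinguish a
feature arrangement from its mirror image, and stereochemistry matters
for this target. The matcher is verified against a brute-force
enumeration oracle on random instances. A compound matches if any
conformer matches. Conformer generation defaults to 10 per rotatable bond
capped at 100 per compound (ETKDG, seeded).

Hypothesis generation enumerates k-subsets (k in `k_range`, default 3–5)
of each cluster member's features, filters by intersite distance, and
keeps candidates matched by at least `coverage` (default 0.5) of the
cluster. This reference-compound enumeration is the principal
simplification relative to full common-pharmacophore perception engines:
it explores fewer alignments but is exact, fast at cluster sizes of
interest, and produces hypotheses in the same representation the
evaluation stage consumes. Duplicates (same kind multiset, distance
matrices equivalent under a kind-preserving bijection within tolerance)
are collapsed, keeping the higher-coverage candidate; all tie-breaks are
lexicographic so generation is deterministic.

## Enrichment statistics

MCC is computed in its standard form, defined as 0 when any marginal
vanishes. GH uses Ha = TP (actives retrieved), Ht = TP + FP, A = TP + FN,
D = FP + TN. The source table this implementation reproduces prints
"Ha = TN", but its own printed values are only recovered with the standard
Ha = TP convention, which is therefore implemented. Two of the six printed
rows are internally inconsistent — one cluster's decoy total (FP + TN =
300) contradicts the stated 600 decoys generated for it, and another's
printed GH (0.95) does not follow from its own counts (the formula gives
≈0.86); the antagonist cluster's printed MCC (0.82) likewise computes to
0.81 from its counts while its GH does reproduce. The self-consistent
values are pinned in tests; the inconsistent ones are excluded and noted
here. The GH penalty denominator is D following the printed expression;
the common D − A variant is available as a flag and reproduces the same
2-d.p. reference values. Report tables round half-up to 2 decimals and
retain raw values.

## LIA models

The linear interaction approximation regresses pIC50 on three
bound-minus-free energy differences (van der Waals, electrostatic,
cavity), ordinary least squares, no intercept by default (the ansatz has
none; a flag adds one, requiring ≥ 4 training points instead of ≥ 3).
Fitting targets pIC50 directly rather than ΔG in kcal/mol; the unit
conversion is absorbed into the coefficients, and negative coefficients
are permitted and expected. Statistics:

* **R²** — squared Pearson correlation of predicted vs experimental on the
  training set. Stated explicitly because R² is ambiguous for no-intercept
  fits (the uncentered convention can differ wildly);
* **SD** — residual standard deviation, √(SS_res/(n − p));
* **p** — overall F-test of all coefficients against the null model (the
  zero function without intercept, the mean with one). A single p-value
  per model is reported and the test named, since the convention is
  otherwise underdetermined.

The fit is implemented via `numpy.linalg.lstsq` with an explicit rank
check and is cross-checked against statsmodels OLS in the test suite.
Predicted pIC50 ≥ 5.0 classifies a compound active (inclusive boundary;
pIC50 = 5 means IC50 = 10 µM, the conventional activity edge).

Energy descriptors come from a pluggable backend. The shipped
`LJCoulombBackend` is a deterministic single-pose surrogate, not a
molecular-mechanics sampling engine: 12-6 Lennard-Jones with
Lorentz–Berthelot combination over per-element parameters, Coulomb with
Gasteiger charges and distance-dependent dielectric ε(r) = 4r, free-state
terms from intramolecular non-bonded pairs (≥ 3 bonds apart), and a
cavity term proportional to an approximate solvent-accessible surface
area (pairwise sphere-overlap reduction, probe 1.4 Å, 0.0072 kcal/mol/Ų).
The surrogate's job is to exercise every downstream formula with
physically plausible, reproducible numbers; its absolute energies are not
meaningful, and published coefficient values that depend on proprietary
simulation energies are out of scope by design.

## Screening funnel

Stages run cheap-to-expensive with short-circuiting: (1) any-hypothesis
pharmacophore match; (2) docking score ≤ threshold — scores are external
inputs (CSV) or a bundled surrogate (negated pharmacophore fit quality);
the threshold is fixed, the mean score of reference actives (the
published protocol), or the poorest reference active's score for
sensitivity analysis; comparisons are boundary-inclusive with more
negative being better; (3) LIA-predicted pIC50 ≥ 5. Per-compound
provenance (stage outcomes, matched hypothesis, score, prediction) is
emitted, and stage counts telescope exactly — both verified as property
tests. Agonist and antagonist funnels (different hypotheses, thresholds
and LIA models per receptor conformation) are run separately by
configuring two funnels; cross-conformation consensus is left to the
caller.

## Synthetic data

`synthdata` generates every input:

* **Analogue series** — a scaffold with attachment points and substituent
  lists, fully enumerated; the default series is 4-aminobutanoic acid with
  a variable β-substituent (the 4-chlorophenyl member is baclofen),
  10 analogues, MW 103–262, at most one aromatic ring, zwitterionizable.
  Latent pIC50 = baseline (4.6) + per-substituent contribution (0–1.8) +
  Normal(0, noise_sd), emitted as Ki records via the inverse of the ×2
  conversion so curation round-trips the latent labels exactly.
* **Decoy candidate pools** — molecules assembled from a fixed fragment
  grammar (functional cap + branched aliphatic chain + functional cap)
  whose caps carry all H-bond donors/acceptors, weighted toward
  amine/amide/acid chemotypes so pools share the actives' property
  envelope while differing in topology. Given reference property vectors
  the generator stratifies: each candidate is manufactured around one
  reference (equal HBD/HBA/charge; MW, clogP, rotors within fixed
  windows), cycling references per accepted molecule so strata stay
  balanced — mirroring how DUD-E gathers per-active candidate sets. A
  5,000-molecule pool supports 50 decoys per active for a six-compound
  cluster with margin.
* **LIA descriptor sets** — deltas drawn from configurable normal
  distributions (defaults: vdW −30 ± 8, electrostatic −15 ± 6, cavity
  −3 ± 1.5 kcal/mol, spanning plausible small-ligand interaction
  magnitudes), pIC50 from the generating coefficients plus optional noise.
  Free terms are zero so the regression deltas equal the drawn values
  exactly.
* **Pocket models** — interaction sites on a sphere shell with random
  partial charges; synthetic stand-ins for a receptor site, used to
  exercise the surrogate energy backend.

What the synthetic data does **not** emulate: real GABA_B
structure–activity relationships (latent activities are controlled, not
realistic), conformational strain or binding-mode physics (the pocket and
energy backend are surrogates), assay noise structure, and the size and
redundancy of real vendor libraries. Passing tests therefore demonstrate
that the algorithms implement their contracts — thresholds, counts,
statistics, invariances — not that the pipeline would achieve any
particular enrichment on real screening data.

## Numerical choices and problem sizes

* Rounding in report tables: half-up to 2 decimals; raw values retained.
* Kabsch superposition: SVD with determinant correction; 1- and 2-point
  matchings degenerate gracefully (RMSD 0 and half the distance mismatch).
* Tie-breaks everywhere lexicographic by compound id / label.
* Degenerate inputs raise typed errors (`errors.py`) rather than
  returning sentinel values, except where a statistic has a conventional
  zero (MCC/GH with empty marginals).
* Test problem sizes: clusters of 4–6 compounds with 1–6 conformers,
  pools of 400–1,000 candidates for unit tests and 5,000 for the
  full-scale decoy run, 500 random matcher instances, 200 LIA noise
  replicates, 50 random funnel libraries — sizes chosen to exercise every
  code path at desk scale while the whole suite stays fast.

## Known limitations

* No docking engine: scores are external inputs or a transparent
  surrogate; pose generation, grids and receptor preparation are out of
  scope.
* No excluded-volume pharmacophore features; receptor-derived
  (e-Pharmacophore) hypotheses can be imported through the JSON format but
  not generated.
* The protonation rule set covers the amine/acid chemotypes in scope;
  exotic ionizable groups need a custom backend.
* Hypothesis generation enumerates reference-compound feature subsets; it
  will not find a consensus arrangement that no single reference conformer
  exhibits.
* clogP, donor/acceptor counts and charges are as defined by the pinned
  RDKit schemes; other toolkits' definitions will shift property windows
  slightly.
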
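# Methods

This note records the models, conventions and numerical choices behind
`footprintdock`, the assumptions they rest on, and what the synthetic
benchmarks do and do not demonstrate.

## Digestion model

A protease specificity rule is a set of P1 residues with C-terminal
cleavage; an optional P1′ exception set blocks cuts (off by default for the
built-ins — the bare specificities are used; the classical no-cut-before-
proline behaviour of trypsin/chymotrypsin can be enabled by constructing a
rule with `exceptions={"P"}`).  A P1 residue at the C-terminus yields no
site, since cutting there releases nothing.

Because limited proteolysis is deliberately partial, the observable
species are not the fully digested peptides but every fragment delimited
by any two of the *b* boundaries (N-terminus, each site, C-terminus):
exactly C(b, 2) fragments including the intact chain.  Fragments from
multi-protease digests are enumerated per protease, matching the
one-protease-per-experiment protocol the package targets.  Masses are
monoisotopic by default (average-mass mode for large MALDI-TOF fragments),
computed from elemental composition via pyteomics; mass additivity
(`m(a..c) = m(a..b) + m(b+1..c) − m(H₂O)`) holds to ≈1 pDa.

Non-goals: post-translational modifications, disulfide-linked species,
nonspecific cleavage.

## Relative cleavage propensity

Peaks are matched to theoretical singly protonated masses
(`m/z = M + 1.00728`) within a tolerance (default 0.5 Da, suitable for
MALDI linear mode; configurable in Da or ppm).  A peak is *unique* with
exactly one candidate, *ambiguous* with several (excluded from propensity
sums by default; an option splits intensity equally), *unassigned*
otherwise.

The per-site propensity at time *t* is the intensity share

    P(s, t) = Σ I(uniquely assigned fragments with boundary s)
              / Σ I(all uniquely assigned peaks, intact included).

This definition is a package convention, chosen because it is scale-free
(invariant under rescaling a spectrum), bounded in [0, 1], and directly
testable.  It is computed per replicate and then averaged (SD kept for
QC).  Time points with no assigned intensity are flagged undefined (NaN)
and excluded from replicate means.

A consequence of the share normalisation worth knowing: protecting one
site slightly *raises* the share of every other site (the denominator
shrinks).  The coupling is upward, so it cannot generate false-positive
protections, but "unchanged elsewhere" holds only to first order.

The `.csgnu` serialisation is a documented plain-text dialect (comment
header with protein/condition/times, then `site time propensity sd` rows
in blank-line-separated site blocks), round-trip exact to 6 decimals.

## Active and passive residues

Site *s* is **active** iff `P̄_free(s) ≥ ε` and
`(P̄_free(s) − P̄_bound(s)) / P̄_free(s) ≥ θ`, with θ = 0.20 and floor
ε = 0.01.  The threshold is interpreted as a *relative* decrease (20%
smaller than the free value), keeping the criterion scale-free; the
aggregate is the mean propensity over t > 0 (t = 0 carries no signal), with
a max-single-time-drop alternative available.  The comparison is monotone
in θ by construction.

**Passive** residues are non-active residues with relative solvent
accessibility ≥ 50% and a heavy atom within 6.5 Å of an active residue.
The accessibility backend is Shrake–Rupley (probe 1.4 Å, 960 points/atom)
normalised by extended Gly-X-Gly reference areas (Tien et al. theoretical
values, embedded as a constant table); the distance cutoff is a package
default — it is not a printed experimental constant — and is configurable.
For the final docking run, those surface neighbours are *promoted* to
active (a protease samples only its own cleavable residues, so the
experimentally identified set under-covers the interface); provenance is
tracked per residue (`LP/MS` vs `promoted-neighbor`).

A partner without LP/MS susceptibility enters passively only: either an
externally supplied residue list (e.g. interface predictions) or
whole-surface passivation.

## Restraint and parameter files

Each active residue is restrained to the union of the partner's
active+passive residues by one CNS-style `assign` statement with
effective-distance bounds `2.0 2.0 0.0`, emitted in deterministic order
(byte-exact golden file under test).  The run-parameter document is a flat
`key=value` dialect with the AIR block embedded between
`air_begin`/`air_end`, round-trip parsed.  Random AIR exclusion is both a
parameter flag (engine-side removal) and a local subset generator
(`⌈(1−f)·n⌉` kept per draw, seeded) for engines lacking the feature.

## Patch detection

Active residues frequently split into a true interface patch plus remote
false positives (allosteric loosening).  The heavy atoms of the active
residues — not the whole protein — form the point cloud; k-means
(k-means++ seeding, 20 restarts, fixed seed 0) clusters it, and each
residue joins the cluster holding the majority of its atoms (ties go to
the nearest cluster centroid).  Patches are reported largest-first.  A
default `k` is suggested as the smallest k ∈ 2..4 whose atom-cloud
silhouette reaches 0.6, else 1.  For multi-model (NMR) input the first
model is used by default.

## Two-stage docking protocol

*Filter*: all patches active, 50% of AIRs randomly excluded per structure
calculation; because this widens the sampling space, the structure counts
are raised to 4000 rigid-body / 400 annealing / 400 water-refined.  The
returned poses are clustered (7.5 Å, min size 4) and ranked; each cluster
is attributed to the patch nearest its best pose if within 5 Å (the
assignment cutoff separates the observed near/far regimes, roughly 2–4 Å
versus > 10 Å, cleanly), and the patch of the best-*scored* cluster wins —
score always beats cluster size, size only breaks exact ties.  A best
cluster on no patch is an error demanding manual review.  Both a single
combined filter run (default) and one-run-per-patch mode are provided.

*Final*: actives restricted to the winning patch, exposed neighbours
promoted, no random exclusion, same structure counts.

Docking is external; a mock-docker hook (`make_mock_poses`) stands in for
the engine during testing.

## Evaluation

iRMSD: interface residues are defined on the *reference* (any heavy atom
within 10 Å of the partner); their backbone (N, CA, C, O) atoms are
superposed by Kabsch/SVD (proper rotation enforced; degenerate/collinear
inputs rejected) and the RMSD of those atoms reported.  lRMSD: fit on the
larger chain's backbone, RMSD over the other chain without re-fitting
(equal sizes: first chain by file order).  fnat: residue pairs across
chains with any heavy-atom distance ≤ 5 Å (CAPRI convention); fraction of
reference contacts present in the model.  CAPRI *acceptable* applies all
three thresholds strictly.  For a multi-model reference the lowest-energy
(first configurable) model is used.

Pose clustering uses a pairwise interface-ligand RMSD — fit on the
receptor-side interface backbone (union of the two poses' 10 Å
interfaces, for symmetry), RMSD over the ligand-side interface backbone —
with greedy largest-neighbourhood (Daura) clustering: repeatedly take the
pose with the most neighbours within the cutoff as a centre (ties: lowest
input index), remove it with its neighbours, iterate; clusters below the
minimum size are discarded.  Cluster score is the mean of the four lowest
member scores; ranking is ascending with larger size breaking ties.
Engine scores come from a sidecar table; absent scores disable ranking
with a clear error.  The cluster→patch distance is the minimum heavy-atom
distance from the ligand to the patch residues of the single best-scored
member (averaging over members is available).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not MALDI physics.  Each site is cut independently with first-order
kinetics, `P(cut by t) = 1 − exp(−k·t)`; the default rate 0.02 min⁻¹
brings an accessible site to ~98% digestion at the last of the default
quench times (0, 1, 2, 5, 10, 20, 50, 100, 200 min) while early points
stay far from saturation.  Protection scales the bound-state rate by
(1 − ρ).  Populations of 10⁴ molecules are distributed over the 2^m cut
patterns; with intensity CV = 0 the expected populations are used
directly (a "zero-noise" run is fully deterministic), otherwise molecule
counts are drawn multinomially and intensities carry multiplicative
log-normal noise at the given CV (simple, positive, scale-free).
Triplicates are the default.  Secondary digestion of released fragments
is ignored — adequate for testing propensity *differences*, which is what
restraint derivation consumes, but a real digest shows fragment-of-
fragment species this model does not.

The toy complex is two parallel idealised poly-alanine α-helices
(backbone plus CB pseudo-side-chains, 30- and 20-residue chains, 9 Å axis
separation) — sufficient for the distance and relative-SASA rules and for
exact-value RMSD tests, but with none of the shape complexity, side-chain
packing or numbering gaps of real structures.  Mock docking output
perturbs the bound ligand rigidly (near-native) or reflects it to the
receptor's far side (incorrect), with strictly better scores for
near-native poses.  All generators are bit-reproducible per seed.

Passing the synthetic benchmarks therefore shows that the *inference
machinery* is correct under its own generative assumptions (independent
first-order sites, multiplicative noise, rigid poses); it does not show
robustness to correlated cleavage, secondary digestion, calibration drift
or flexible docking artefacts in real data.

## Benchmark problem sizes

The bundled benchmarks use a 30-residue substrate with six tryptic sites
(recovery and null checks over 20 independent seeds at 10% CV), the
30+20-residue toy complex, 16-pose mock docking sets, and 1,000 random
peptides for the mass oracle; these sizes keep the whole suite and the
acceptance script in the seconds-to-a-minute range on one CPU while
leaving every statistical margin (e.g. the ~38% propensity drop at
ρ = 0.6 versus the 20% threshold) wide.

## Known limitations

- The propensity formula is a stated convention; instruments and other
  software may normalise differently, so thresholds tuned here should be
  re-examined against a lab's own pipeline.
- Whole-molecule share normalisation couples sites (upward on
  protection elsewhere); per-site absolute quantification would decouple
  them but is not scale-free.
- Engine-side random AIR exclusion is carried as a single fraction; how
  the engine resamples it across stages is outside this package's control.
- k-means patching assumes roughly isotropic, separated patches; ring- or
  ribbon-shaped interfaces may split arbitrarily (surface-geodesic
  clustering is a deliberate non-goal).
- CAPRI tiers beyond "acceptable" (medium/high) are not computed.
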
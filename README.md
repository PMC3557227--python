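# footprintdock

Interface restraints for data-driven protein–protein docking from
limited-proteolysis / mass-spectrometry (LP/MS) time courses.

## The problem

When a folded protein is digested briefly with a sequence-specific
protease (limited proteolysis), accessible and flexible sites are cleaved
first.  In a complex, residues at the binding interface are shielded, so
their cleavage slows down.  Comparing MALDI-MS peak-list time courses of a
protein *free* versus *in complex* therefore reveals interface residues —
cheaply, from microlitres of unlabelled sample — which can drive
restraint-based docking against an external engine (e.g. HADDOCK) to
produce a structural model of the complex.

`footprintdock` implements the full desk-side workflow around the docking
engine:

1. **digestion** — cleavage-site detection for protease specificity rules
   (trypsin K/R, chymotrypsin Y/W/F/L/M, Glu-C/V8 D/E), enumeration of all
   partial-digest fragments, monoisotopic/average masses;
2. **spectra** — peak-list ingestion, assignment to theoretical [M+H]⁺
   masses, and the *relative cleavage propensity*
   `P(s,t) = Σ I(fragments bounded by site s) / Σ I(all assigned peaks)`
   per site and quench time, in triplicate (the `.csgnu` table);
3. **restraints** — a residue is *active* when
   `(P_free − P_bound)/P_free ≥ θ` with `θ = 0.20` (time-averaged,
   with a floor on `P_free`); *passive* residues are surface neighbours
   (relative Shrake–Rupley SASA ≥ 50%, heavy-atom distance rule); CNS-style
   ambiguous-interaction-restraint `.tbl` files and flat run-parameter
   documents are emitted;
4. **patchup** — k-means clustering of the active residues' heavy-atom
   cloud with majority-vote residue assignment, separating the true
   interface patch from remote false positives;
5. **pipeline** — the two-stage protocol: a *filter* docking run over all
   patches with 50% random AIR exclusion per structure (counts
   4000/400/400), score-prioritised patch choice from the returned pose
   clusters, then a *final* run restricted to the winning patch with
   exposed neighbours promoted to active and no random exclusion;
6. **evaluation** — CAPRI metrics against a reference complex: iRMSD
   (backbone RMSD over the reference's 10 Å interface after Kabsch
   superposition), lRMSD (fit on the larger chain, measure the other),
   fnat (fraction of native residue contacts at 5 Å); a model is
   *acceptable* iff iRMSD < 4 Å, lRMSD < 10 Å and fnat > 0.1.  Pose
   clustering is greedy largest-neighbourhood (Daura) at 7.5 Å with
   minimum cluster size 4; clusters are ranked by the mean of their four
   lowest engine scores;
7. **synthetic** — generators for everything above: first-order cleavage
   kinetics `P(cut by t) = 1 − exp(−kt)` with interface protection
   `k → k(1−ρ)`, triplicate log-normal intensity noise, an idealised
   two-helix toy complex, and mock docking output with ground-truth
   labels.

Docking itself is external: the package stops at restraint/parameter
emission and resumes at evaluation of returned models (engine scores are
consumed, never computed).

## Worked example

`examples/02_propensity_and_actives.py` simulates triplicate free/bound
time courses for a 30-residue protein whose tryptic sites 8 and 21 are 60%
protected by a partner, then derives active residues:

```
site  mean P(free)  mean P(bound)  relative drop
   5         0.183          0.204         -11.5%
   8         0.179          0.112         +37.5%
  12         0.183          0.199          -9.1%
  17         0.179          0.196          -9.8%
  21         0.176          0.112         +36.7%
  28         0.178          0.198         -11.6%
active residues (>=20% propensity drop): [8, 21]
```

Only the protected sites drop past the 20% threshold; unprotected sites
drift slightly *upward* (the propensity is an intensity share, so silencing
two sites renormalises the rest) and can never be false positives.

`examples/03_patches_filter_final.py` continues to patch detection and the
two-stage protocol, and `examples/04_evaluate_models.py` evaluates mock
docking output:

```
 cluster  size  score  irmsd  lrmsd  fnat          capri
       1     8  -79.2   0.43   1.00 0.769     acceptable
       2     8  -39.2   4.44  18.43 0.000 not_acceptable
```

The near-native cluster ranks first by engine score and is
CAPRI-acceptable; the wrong-face cluster is not.

There is also a thin CLI (`footprintdock digest|propensity|restraints|
patch|evaluate|simulate`) over the same functions.

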
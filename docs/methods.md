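# Methods

`idpcoev` detects and validates interprotein evolutionary couplings (ECs)
between intrinsically disordered proteins (IDPs) and their folded partners.
This note records the models, the surrogates, the tunable parameters and the
deliberate design choices, in the package's own terms.

## The coupling model

Given a paired alignment — one row per species, concatenating the closest
ortholog of the IDP segment and of the partner segment — residue co-variation
is modelled with a pairwise Potts model (Markov random field) over the
21-state alphabet (20 amino acids + gap; unknown letters map to gap):

    P(x) ∝ exp( Σ_i h_i(x_i) + Σ_{i<j} e_ij(x_i, x_j) )

The full likelihood is intractable, so the model is fitted by the standard
pseudolikelihood: minimise the weighted, L2-regularised sum over rows r and
columns i of −log P(x_i^r | x_{−i}^r). Properties and choices:

* **Weights.** Row r gets weight 1/|{rows with ≥ 80% identity to r}|
  (identity = matches over mutually non-gap positions divided by the shorter
  ungapped length). The effective sample size n_eff = Σ w_r. The data term
  is the weight-*averaged* pseudolikelihood, so the penalties below are
  relative to n_eff.
* **Regularisation.** λ_h = 0.01 on fields, λ_e = 0.2·(L−1) on couplings
  (L = total columns). These are the conventional defaults for
  pseudolikelihood direct-coupling analysis; nothing in the validation
  battery is sensitive to factor-of-two changes.
* **Optimisation.** L-BFGS from zero-initialised parameters, gradient
  tolerance 1e−5, default cap 500 iterations — deterministic, no seed.
  The analytic gradient is exposed (`plm.make_objective`) and is verified
  against central differences in the tests. Coupling *rankings* stabilise
  long before full convergence; the recovery benchmarks therefore run with
  a 60–100 iteration cap, which the tests show already separates planted
  pairs from background by an order of magnitude.
* **Scores.** The coupling strength of a column pair is the Frobenius norm
  of the 20×20 amino-acid block of e_ij (the gap state is excluded, as is
  conventional). The average product correction (APC)
  S′_ij = S_ij − S̄_i·S̄_j/S̄ (means over off-diagonal entries) removes
  conservation and phylogenetic background.

One empirical property worth recording: with L2 regularisation, a
(near-)conserved alignment does **not** drive coupling norms to numerical
zero. The cheap fields (λ_h small) saturate the conditionals first, and the
couplings settle where their residual gradient ~(1−p) balances 2λ_e·e —
around 0.1 in Frobenius norm, an order of magnitude below a genuinely
co-varying pair. Downstream thresholds live far above this floor.

## Scaled score and probability (documented surrogates)

The upstream web servers report a "scaled score" and a "probability" whose
exact forms are unpublished. This package defines documented surrogates with
the same reporting semantics:

* **Scaled score** = APC-corrected score divided by the mean of the positive
  APC scores, so 1 means "an average positive pair" and the reporting
  threshold scaled ≥ 1.30 keeps pairs clearly above average. Scale-invariant
  by construction.
* **Probability** = a one-dimensional, class-balanced logistic regression
  p(s) = σ(a·s + b), fitted on labelled synthetic data: a few small paired
  alignments with planted pairs spanning weak to strong coupling
  (strengths 0.25–0.8), scored by the same engine. Class balancing makes
  p(s) ≈ P(coupled | s) under equal priors, so p > 0.88 demands a
  likelihood ratio of about 7:1; a ridge on the slope keeps the curve soft
  when the calibration classes happen to be separable. A background-level
  score maps below 0.5.

  A per-run quantile anchoring (p = 0.88 pinned at each run's 88th score
  percentile) was considered and rejected: it passes 12% of pairs by
  construction, which destroys precision and contradicts the reporting
  threshold's purpose of excluding false positives. The "top 12%" phrasing
  attached to the original threshold is treated as a description of that
  server's score distribution, not as a mechanism to reproduce.

Pairs are reported as ECs when interprotein (one column on each side of the
boundary), scaled ≥ 1.30 and probability > 0.88 (boundaries exactly as
stated: score inclusive, probability exclusive). Columns with > 50% gaps are
masked from reporting — gappy disordered columns are the engine's known
failure mode.

## Structure mapping

Structures are read with gemmi (PDB/mmCIF); hydrogens are dropped, alternate
locations resolve to the highest-occupancy conformer, multi-model (NMR)
files use the first model and carry an `is_nmr` flag that excludes them from
the contact statistics (but not from distance analysis). The
UniProt↔structure numbering map is explicit configuration; no remote lookup.

* **Visibility.** A coupling is *invisible* when either residue is not
  covered by the numbering map (`not_in_construct`) or is mapped but has no
  atoms (`no_coordinates`). Visible + invisible partitions every EC set.
* **Interface (buried-surface surrogate).** Solvent accessibility by an
  internal Shrake–Rupley: Fibonacci sphere of 960 points/atom (5000-point
  spheres serve as the refinement reference; totals agree within 10%),
  probe 1.4 Å, vdW radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / P 1.80 /
  default 1.70 Å. A residue is interfacial when its SASA in the isolated
  chain exceeds its SASA in the complex by > 0.1 Å²; the pairwise interface
  area is (SASA_A + SASA_B − SASA_AB)/2, summed over partner chains. An
  override TSV can substitute reference interface assignments when they are
  available.
* **Bonds.** H-bond: interchain N/O pair ≤ 3.5 Å; salt bridge: basic
  side-chain N (Lys NZ, Arg NH1/NH2/NE, His ND1/NE2) vs acidic side-chain O
  (Asp OD1/OD2, Glu OE1/OE2) ≤ 4.0 Å. A geometry can count in both
  categories. The 3.5/4.0 Å cutoffs are field conventions, not fitted.
  Bond density is normalised per 1000 Å² of interface.
* **Contacts.** Interchain heavy-atom pairs within vdW-sum + 0.5 Å;
  residue-pair counts sum qualifying atom pairs; identical partner chains
  accumulate onto the same partner residue number. The spatial-grid
  implementation is tested for exact equality against an O(n²) scan.
* **Secondary structure.** A simplified Kabsch–Sander assignment: amide H
  rebuilt from geometry, bond energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with bond at
  E < −0.5; runs of i→i+4 turns give H, i→i+3 G, i→i+5 I, bridge patterns
  E/B, residual turns T, CA-kink bends (> 70°) S, else C. Grouping:
  G/H/I → helix, E/B → strand, S/T/C → loop. A reader for standard DSSP
  output files takes precedence when one is supplied. Limitations: no
  π-helix edge cases, and bridge detection between chains uses the same
  pattern tests as within chains without DSSP's full ladder bookkeeping.

## Statistics

* **Random-pair distance null.** For each visible coupling, one IDP and one
  partner interface residue are drawn uniformly (with replacement across
  draws) from the same interface, and their minimum heavy-atom distance
  recorded; 100 resamples by default. Coupling distances are compared to
  each resample with a Mann–Whitney U test. Simulations in the test suite
  verify the comparison is calibrated (type-I error 5% ± 2% at α = 0.05
  over 1000 repetitions when the "couplings" are themselves random pairs)
  and essentially always rejects (p < 0.01) when couplings are built in
  atomic contact on a ≥ 20 Å-wide interface. The RNG is counter-based
  (Philox) under a single recorded seed.
* **Mann–Whitney U.** Midrank ties; exact enumeration when n₁+n₂ ≤ 12 with
  no ties, else normal approximation with tie and continuity corrections
  (delegated to scipy; an independent enumeration oracle in the tests
  checks every sample-size combination up to 8).
* **Equal proportions.** 2×2 chi-square with continuity correction — the
  default two-sample proportion test of the referenced statistical
  environment; verified against hand-computed Yates arithmetic to 1e−6.
  Zero-margin tables return p = 1 with a warning.
* **Outliers.** Boxplot rule (beyond Q1 − 1.5·IQR or Q3 + 1.5·IQR),
  type-7 (linear-interpolation) quartiles, single-pass. Outlying coupling
  distances are excluded from the null comparison but kept, flagged, in all
  tables.
* **Distance histogram.** Bins [0, 8), [8, 10], (10, ∞) Å.
* **Composition.** Residue groups: hydrophobic GAVLMI, aromatic FYW, polar
  STCPNQ, negative DE, positive KRH. Categories: analyzed ranges, all
  interfaces, interfaces of EC-bearing vs EC-free complexes, EC residues;
  identical partner chains are counted once. Standard comparisons (EC
  interfaces vs all, EC residues vs all, EC vs no-EC interfaces) use the
  equal-proportions test, per side.
* **No multiple-testing correction** by default (reported p-values are raw,
  matching the analysis the package reimplements).

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
exercised; it emulates the *structure* of the real inputs, not their
biological detail.

* **Alignments.** Per-column background frequencies are Dirichlet draws
  tempered to a target Shannon entropy (default 3.0 bits — typical
  moderately variable alignment columns; uniform would be 4.32). A planted
  pair (i, j, s) copies the IDP column state through a fixed random
  permutation into the partner column with probability s, else samples
  independently — so s = 0 is exactly independent and s = 1 with no
  mutation makes the pair's mutual information equal the column entropy.
  Phylogenetic redundancy is a star tree: `n_species` total rows from
  ⌈n/redundancy⌉ ancestors, each with `redundancy` descendants mutated at
  rate `mutation_rate` (default 0.05/site). Defaults: redundancy 1 (every
  row independent); the benchmark conditions (500 rows, redundancy 3)
  are set explicitly where used. Gap-free by construction.
* **Complexes.** The IDP is an ideal-geometry chain (NeRF construction;
  helix φ/ψ = −57/−47, extended −140/140; backbone + CB stubs), the partner
  a three-helix-bundle decoy (antiparallel ideal helices, interpolated loop
  stubs — the decoy is not a continuous backbone through the loops, which
  none of the surface/contact/secondary-structure uses require). The IDP is
  docked by a rigid-body Powell search over seeded restarts minimising
  hinge penalties that pull every planted pair within
  `contact_distance_max` (default 5 Å) while keeping interchain atoms out
  of clash range; the result is verified (every planted pair in range, no
  interchain pair < 2.4 Å) or a `PlacementError` is raised — requests that
  are geometrically infeasible (e.g. planted pairs whose sequence spacings
  cannot be bridged by a rigid chain) fail loudly rather than silently
  degrade. Construct truncation (`idp_construct`) and unresolved windows
  (`unresolved_idp`) exercise the invisibility logic.
* **What passing tests show — and don't.** Synthetic alignments have no
  real phylogeny (star tree only), no gaps, no alignment error, and
  independent background columns; synthetic complexes have no real folds or
  side chains. Tests on them validate the machinery (recovery of planted
  signal, geometric bookkeeping, statistical calibration), not performance
  on real homolog sets, where alignment depth/quality dominates.

## Problem sizes

The shipped benchmarks run the planted-recovery condition (500 rows,
30+40 columns, redundancy 3, strength 0.8, 10 seeds) with a 60-iteration
optimiser cap, the distance-null calibration at 1000 simulated repetitions,
and SASA refinement at 5000 sphere points; these sizes keep a full suite run
in the minutes range on a single core while leaving every acceptance margin
wide (planted pairs lead the ranking by ~an order of magnitude, and the
type-I band is met with slack).

## Known limitations

* The scaled score and probability are calibrated surrogates: thresholds
  1.30/0.88 carry the same *semantics* as the published analysis but will
  not numerically reproduce a closed server's outputs on real complexes.
* Homology search is out of scope: paired alignments are built from
  user-supplied per-protein MSAs by best-identity pairing within species;
  the recorded e-value/iteration settings of the original searches are
  carried as run metadata only.
* The interface/bond/secondary-structure geometric surrogates approximate,
  but do not reproduce bit-for-bit, the closed services they stand in for;
  override inputs (interface TSV, DSSP files) restore fidelity when those
  outputs are available.
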
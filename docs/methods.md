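# Methods

## Scope and data model

The package operates on conformational ensembles of a single molecule:
ordered frames of atomic coordinates with shared atom/residue metadata
(`ConformationSet`). Internal units are nm and ps; multi-model PDB is the
canonical interchange format (Å on disk, converted on I/O), with XTC/DCD
available through an mdtraj adapter. Frames are assumed protein-only
(solvent and ions stripped); topology perception, hydrogen addition and
side-chain modeling are out of scope.

## Descriptors

* **R_G** — mass-weighted by default (a `mass_weighted=False` flag gives the
  geometric variant), in nm.
* **EE_DIST** — Euclidean distance between the first- and last-residue Cα.
* **RMSD** — optimal superposition (Kabsch: translation plus proper
  rotation, reflections disallowed) over a configurable selection,
  default Cα.
* **RMSF** — per-atom fluctuation about the time-average structure after
  two rounds of superpose-onto-mean, mirroring the usual Cα convention.
* **SASA** — Shrake–Rupley with Bondi van der Waals radii, probe radius
  0.14 nm (water-sized) and 960 quasi-uniform sphere points by default; the
  point count trades accuracy for cost and 960 keeps the isolated-sphere
  error well under 1%. Computed through mdtraj's implementation with the
  package's radii injected.
* **Moment summaries** use *population* moments, with skew m₃/m₂^1.5 and
  *excess* kurtosis m₄/m₂² − 3 (a Gaussian scores 0). Whether to use sample
  or population moments is a convention choice; reports flag it.

## Fingerprints

Torsions enter dimensionality reduction as (sin, cos) pairs so the ±180°
wrap is not a discontinuity. The Cα fingerprint uses consecutive distances,
pseudo-bond angles and pseudo-dihedrals — O(n) features that scale to long
chains; all-pairs distances are available behind a flag. The SASA
fingerprint defaults to all heavy atoms, with a polar-only (O/S) option
since carbon/nitrogen surface terms carry little solvent contrast. All
fingerprints are deterministic and rigid-motion invariant.

## Dimensionality reduction

* **Standardization** (zero mean, unit population σ per column) precedes
  every method; zero-variance columns are dropped with a warning.
* **PCA** is scikit-learn's full-SVD solver.
* **tICA** solves C(τ)v = λC(0)v with symmetrized covariance estimates over
  the overlapping window and a ridge of 1e-5·tr(C₀)/p on the diagonal of
  C₀ — enough to keep near-singular feature sets well-posed without
  visibly biasing the spectrum. Default lag 10 frames; the right lag
  depends on the trajectory's slowest timescales, so it is exposed in every
  interface.
* **tSNE** is implemented in its exact O(n²) form: per-row bisection of the
  Gaussian precision until each conditional distribution's perplexity
  matches the target (entropy tolerance 1e-5, i.e. perplexity error well
  below 1e-3), symmetrized joint P, and gradient descent on KL(P‖Q) with
  early exaggeration 12 for the first 250 iterations, momentum 0.5→0.8,
  per-parameter gains, and learning rate n/12. Initialization is the first
  two PCA scores scaled to σ = 1e-4, which makes a run deterministic
  independent of the seed; `init="random"` uses the seed. 1000 iterations
  by default; scans lower this (see below). The exact variant was chosen
  over Barnes–Hut because latent-space *density* drives center selection,
  and the exact gradient keeps the embedding reproducible to the byte.

## Clustering

k-means (seeded k-means++, Lloyd) and Ward agglomeration (Lance–Williams
via scipy linkage; deterministic, generic ties broken by the library's
lowest-index convention) operate on embeddings or feature matrices. GROMOS
clustering operates on raw conformations: the pairwise Kabsch RMSD matrix
over a selection (default Cα, the common backbone-clustering choice), then
greedily — the structure with most neighbors within the cutoff becomes a
center, it and its neighbors leave the pool. Neighbor-count ties resolve to
the lowest frame index for determinism. Validity indices: silhouette (mean
of (b−a)/max(a,b); singleton clusters score 0 so tiny clusters in small-k
scans do not poison the mean) and Davies–Bouldin (lower is better;
coincident centroids raise rather than return ∞).

## Ensemble design

`ss_int_scan` embeds the standardized fingerprint once per perplexity and
partitions each embedding at every requested ensemble size k. Each cell is
scored with the integrated silhouette score

SS_INT = ½ (s_low + s_high),

the arithmetic mean of the silhouette in the embedding and the silhouette
of the same partition in the standardized high-dimensional feature space
(Euclidean distance). The mean is the simplest symmetric combination of the
two quality measures; it lives in one function (`integrate_silhouettes`) so
an alternative weighting is a one-line change. Clustering happens in the
embedding, not the raw features, because the latent space is what the
center-selection density sees.

`density_centers` fits a per-cluster Gaussian KDE (Scott bandwidth) to that
cluster's 2-D points and picks the member of maximal density. Per-cluster
(rather than global) KDE avoids density bleeding from adjacent clusters.
Degenerate clusters (all points identical) and ties fall back to the lowest
frame index. Weights are cluster populations / n.

Sequential ensembles use stride ⌊n/k⌋ with offset ⌊stride/2⌋ — each pick
sits at the median of its stride window. GROMOS ensembles use the cluster
centers with population weights; their size emerges from the RMSD cutoff.

## Shift evaluation

Per-frame predicted shifts (generic TSV, or the SPARTA+ `pred.tab` dialect
read-only) are averaged over ensemble frames per (residue, nucleus);
uniform weighting is the default for the like-for-like CE/SE size
comparison, population weighting sits behind `use_weights=True`. Agreement
with a reference table is the squared Pearson correlation (r²) and the
RMSE in ppm, pooled over residues within each of HN, Hα, Cα, Cβ, C′, N.
Proline N pairs are excluded by default (common predictors omit them). The
CE-vs-SE *win fraction* counts strict wins only, so ties never inflate it.
Phosphorylation perturbations Δδ = δ_phospho − δ_control are classified
deshielded/shielded with default thresholds 0.05 ppm (¹H) and 0.2 ppm
(heavy nuclei).

## Synthetic generator

The generator emulates what matters to the pipeline: a multi-basin torsion
landscape with Markovian interconversion and state-coupled observables.

* **States** are per-residue (ϕ, ψ) targets from named basins — helix
  (−60, −45), PPII (−75, 150), extended (−120, 120).
* **Dynamics**: a reversible chain T = (1−ε)I + ε·1πᵀ with stationary
  occupancy π and switching rate ε (default ε = 0.05, expected dwells of
  tens of frames — persistent basins rather than i.i.d. draws).
* **Geometry**: ideal bond lengths/angles, ω = 180°, NeRF chain extension;
  atoms N, H, Cα, Cβ, C per residue so dihedral, Cα and SASA fingerprints
  all have content. Measured torsions reproduce the inputs to < 1e-6°.
  Angular noise is wrapped-Gaussian, default σ = 8° — basin widths well
  below the ≥ 45° basin separations, comparable to thermal torsion spread.
* **Shifts**: per-frame shift = state mean + Gaussian noise; state means
  are random-coil base values plus per-(state, residue) deviations whose
  scale per nucleus follows each nucleus' natural dispersion (0.25 ppm HN,
  2.5 ppm N, ...). The deviation pattern varies along the sequence, so a
  wrong state mixture distorts the residue *profile* (visible to r²), not
  just the offset. The reference table is the exact π-weighted state mean —
  the converged ensemble average. The shift model's pattern seed is fixed
  independently of the trajectory seed so replicate trajectories share one
  "molecule".

What the generator does *not* emulate: side-chain packing, sterics,
solvent, sequence-specific shift physics, or predictor systematic error.
Passing tests therefore demonstrate that the protocol recovers planted
ensemble structure and averages — not that any particular real protein's
ensemble is reproduced.

## Validation experiments and problem sizes

The test suite validates each primitive against independent oracles
(analytic spheres, rotation-grid superposition, O(n²) index formulas,
exhaustive Ward, hand-traced GROMOS), then the protocol end to end:

* On a balanced 3-state trajectory (n = 2000 frames, 12 residues, σ = 8°),
  the SS_INT scan over perplexities {10, 30, 50} × k ∈ {2..6} peaks at
  k = 3 for every perplexity; scans run tSNE at 500 iterations, which is
  converged for these sizes. The k = 3 density centers land in three
  distinct true states, and the population-weighted CE shift average
  matches the stationary reference within 3 combined standard errors
  (occupancy-sampling variance of the persistent chain plus per-frame
  shift noise) at every (residue, nucleus) pair.
* Center-hit robustness uses 20 replicate seeds at n = 500 frames
  (tSNE 300 iterations), requiring ≥ 19/20 full-coverage outcomes.
* The sparse-state experiment (π = (0.475, 0.475, 0.05), 20 seeds,
  n = 500, k ∈ {3, 5, 8, 10, 15, 20}) compares population-weighted CE
  against uniform SE on r² for HN and N; CE wins a majority of the 120
  cells per nucleus (≈ 0.62–0.69 across seeds). Population weighting is
  used for the CE average here because cluster populations are the
  protocol's estimate of basin occupancy; with uniform weights a k = 3 CE
  would deliberately mis-weight the rare basin at 1/3.

`scripts/acceptance.py` reruns both experiments from scratch for a given
seed and writes the computed quantities as JSON.

## Numerical choices and edge cases

* All tie-breaks (argmax over perplexities, density ties, GROMOS neighbor
  counts) resolve to the lowest index/value for determinism; full pipeline
  runs are byte-identical under a fixed seed.
* Standardization uses population σ; silhouette on precomputed distances is
  supported for RMSD-space scoring.
* tSNE reports the KL divergence of the final layout against the
  un-exaggerated P and falls back to the initial layout in the (unobserved
  in practice) event that optimization diverges, so final KL ≤ initial KL
  holds unconditionally.
* A zero-variance reference makes r² undefined; it is flagged rather than
  silently dropped, and RMSE is still reported.

## Known limitations

* Exact tSNE is O(n²) memory and time; trajectories beyond ~10⁴ frames
  should be strided before scanning.
* tICA assumes approximately stationary dynamics over the window; the
  default lag of 10 frames is a placeholder that should be set from the
  system's timescales.
* The GROMOS distance matrix is dense; for very long trajectories compute
  it on a subsample.
* SS_INT's equal weighting of the two silhouettes is a design choice, not
  a derived optimum; the hook is isolated for experimentation.
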
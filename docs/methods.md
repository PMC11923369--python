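# Methods

This note documents the models, conventions and numerical choices behind
`pincermd`, in the spirit of a package methods appendix: what each procedure
assumes, which defaults matter, and what the synthetic-data tests do and do
not demonstrate about real trajectories.

## The synthetic pincer model

The generator (`pincermd.synthetic`) emulates the statistical structure the
analysis relies on, with no physics:

- K internally rigid domains; each domain's residues sit on a fixed cubic
  lattice (3.8 Å spacing, zero-mean offsets) so the domain center of mass is
  exactly the domain anchor. One pseudo-atom per residue, named CA, element
  carbon, mass 1, which keeps every topology round-trippable through PDB and
  makes mass-weighted and geometric COM coincide.
- Two named jaw domains. The first jaw is fixed; the second is displaced
  along +x so that the jaw COM separation before noise is exactly

      d(t) = closed_distance + amplitude · (1 − cos(2π (t − phase)/period)).

  Defaults (closed 30 Å, amplitude 12.5 Å, i.e. a 30→55 Å sweep) put the
  open state in the >50 Å jaw-excursion regime of Argonaute-scale pincer
  motion. The raised cosine is smooth and bounded; two-state dwell behaviour
  is obtained in the period → 2 limit, where frames alternate exactly
  between the closed and open separations (several tests use this limit
  deliberately). No kinetics is modelled.
- Isotropic i.i.d. Gaussian noise per residue, axis and frame, with a
  per-domain σ (default 0.5 Å). For a static domain the expected RMSF is
  σ√3; rigid-body fitting absorbs 6 of the 3N noise degrees of freedom, so
  the recovered value carries a known √(1 − 6/3N) bias (≈1% at 100 atoms),
  which is why the calibration tests use ≥100 atoms.
- Frames default to 100,000 per trajectory at 10 ps stride (1 frame/10 ps,
  100,000 points per μs); tests and the acceptance script use 120–10,000
  frames and 32–150 atoms so the whole suite runs in minutes on one CPU.
- One `numpy` Generator per trajectory, seeded from the spec; identical
  spec + seed is bit-identical. Replicates share a spec and differ only in
  seed. The noise stream is drawn per domain even when that domain's σ is 0,
  so toggling one σ does not reshuffle the others.

What passing these tests shows: the estimators recover planted amplitudes,
phases, cluster structure and noise levels under the model's assumptions.
What it does not show: behaviour under anharmonic internal domain motion,
correlated (non-isotropic) fluctuations, solvent effects, or imperfect
topologies — real trajectories violate all four to some degree.

## Structural metrics

- **Superposition** is Kabsch via SVD with the determinant correction, so
  only proper rotations are returned; a reflection-related conformer keeps a
  nonzero RMSD. Two distinct points suffice (the minimum RMSD is unique even
  when the rotation is not, e.g. collinear selections); fully coincident
  selections are rejected.
- **RMSD series**: each frame is fitted to the reference frame (frame 0 by
  default) over the fit selection (all alpha carbons by default) and measured
  over the measurement selection — the fit-on-whole / measure-on-domain
  convention of common MD tooling. Both selections are explicit flags.
- **RMSF**: reference is the time-averaged structure after two passes of
  iterative superposition (fit CA by default); fluctuation is the per-residue
  RMS displacement from that average. With a moving jaw, fitting on the whole
  structure smears jaw motion into static domains (a real property of this
  convention, visible in `examples/02`); fitting on a static selection
  isolates it.
- **SASA** is Shrake–Rupley with a deterministic golden-spiral point set
  (960 points/atom by default), Bondi radii and a 1.4 Å probe. Quadrature
  error at 960 points is well under 1% for an isolated atom; unknown
  elements raise rather than guess.
- **Interdomain distances** are Euclidean distances between mass-weighted
  domain COMs, one series per unordered pair; summaries report mean, median
  and variance per pair.

## Statistical protocol

- **EWMA** uses the recursive (adjust-free) form with α = 2/(span+1); the
  default span is 10% of the series length (an absolute span of 1000 is the
  pipeline default for 100,000-point interdomain traces, falling back to 10%
  for short desk-scale series).
- The **"K-test metric"** of the decision rule is the two-sample
  Kolmogorov–Smirnov D statistic — the only bounded statistic consistent with
  thresholds at 0.45/0.55. A comparison is significant only if **all**
  replicates give D > 0.55 with p < 0.001, insignificant only if all give
  D < 0.45, else inconclusive. The rule is monotone in D by construction.
- Smoothing before testing makes consecutive points strongly autocorrelated,
  so nominal KS p-values are anti-conservative. The rule is implemented
  verbatim (that is the protocol), but `ks_compare(..., ess_correction=True)`
  exposes a diagnostic p-value recomputed with autocorrelation-based
  effective sample sizes (initial-positive-sequence truncation). It is off by
  default and not used by the verdict. Measured at desk scale (n = 1000,
  span 100): per-pair P(D > 0.55) ≈ 0.7% under the null, so the
  all-three-replicates rule fires in ≪0.5% of null trials while a unit mean
  shift is detected essentially always — the operating characteristics the
  acceptance tests check.
- **Wilcoxon** comparisons of mapped residue curves are two-sided, require
  ≥10 mapped pairs, and call a single comparison significant iff p < 0.001
  with a nonzero statistic; all-zero differences are insignificant by
  convention. Cross-replicate aggregation mirrors the KS rule.
- **No multiple-testing correction** is applied across comparison grids;
  outputs are raw per-comparison verdicts and say so in the manifest.
- **Discrete Fréchet distance** is the standard O(nm) dynamic program over
  the coupling lattice. RMSF curves are compared in value-only mode (the
  ground distance ignores the index), over the residue positions the
  sequence mapping has in common.
- **Equilibration cut**: the RMSD trace is EWMA-smoothed and the suggested
  production start is the first index i whose leading window [i, i+window)
  has least-squares slope ≤ slope_tol (defaults: window = 10% of length,
  slope_tol = 1e-4 Å/frame). A leading window is used so a flat trace cuts
  at 0 and the cut lands where the settled regime begins rather than one
  window-length after it; a trace that never settles returns a not-converged
  flag instead of an index.

## States, synchronization, clustering, projection

- **smooth_normalize** = EWMA (10% span default) then z-score; constant
  series are rejected rather than silently returned.
- **time_lag** scores each integer lag in [−max_lag, +max_lag] by the
  Pearson correlation between the fixed central window a[max_lag : n−max_lag]
  and the equally sized lag-shifted window of b. A pure shift therefore
  scores exactly 1 at its true lag whatever the signal shape, and every lag
  is scored on the same amount of data (a plain biased cross-correlation was
  measured to miss a planted 50-frame shift by one frame on an asymmetric
  raised-cosine, because edge terms outweigh one frame of misalignment).
  Positive lag means the second series trails the first; ties break toward
  the smallest |lag|; 2·max_lag must be smaller than the series length.
- **Clustering** features are superposed alpha-carbon coordinates, flattened
  — Euclidean distance on them is the mean-square deviation metric up to the
  constant 1/N. k-means (k-means++ init, fixed seed, n_init = 10) runs over
  k in the configured range (default 2–20, clipped to n_frames − 1); k
  minimizes the Davies–Bouldin score, and among candidates within 5% of the
  best score the tie-break prefers the k whose average within-cluster RMS
  deviation (in Å per alpha carbon) is closest to 4 Å. The 4 Å preference is
  implemented as a tie-break only, and on the RMS (not squared) scale, since
  a hard target in squared units would regularly override a clearly better
  Davies–Bouldin optimum. An all-identical-frames trajectory short-circuits
  to a single cluster with a warning.
- **Medoids** minimize the summed within-cluster squared feature distance,
  computed with the expansion m‖x‖² − 2x·S + Σ‖x‖² (no pairwise matrix);
  ties go to the lowest frame index. Medoids are always real frames.
- **Open/closed representatives** are the medoids with maximal/minimal jaw
  COM distance; ties to the lowest index; a single medoid serves both roles
  with a warning.
- **Residue mapping** is a global pairwise alignment (BLOSUM62, gap open 10,
  extend 0.5, end gaps free — the defaults of the classic global-alignment
  tools); the mapping is the aligned non-gap columns, strictly monotone in
  both coordinates.
- **Projection** stacks each medoid's alpha-carbon coordinates on the
  commonly mapped residues, rigidly superposes every medoid onto the first
  reference medoid, and embeds the (medoid × residue) × 3 matrix in 2-D.
  The UMAP parameterization (min_dist = 1, n_neighbours = 1000, clipped to
  n_rows − 1) is honoured when the optional dependency is installed; the
  default embedder is deterministic PCA, which the tests use because the
  stochastic embedder is not reproducible across library versions. The
  embedding config is serialized next to every projection output.

## Contacts

Thresholds are fixed, documented values in the style of the standard contact
tools (boundaries inclusive, distances Å, angles degrees): hydrogen bond
donor–acceptor ≤ 3.5 with ∠D–H···A ≥ 110° when an explicit hydrogen is
present (distance-only otherwise, donors being N/O/S heavy atoms that carry
polar hydrogens); salt bridge anion-O to cation-N ≤ 4.0; pi-cation ≤ 6.0
from the ring centroid and ≤ 60° off the ring normal; pi-stacking centroids
≤ 7.0 with normals ≤ 30°; t-stacking centroids ≤ 7.0 with normals 60–90°.
Ring normals come from the smallest principal axis of the ring atoms and are
sign-folded, so detection is orientation-independent. Residue pairs are
ordered (lower number first), making catalogues invariant to atom order;
aromatic residues with missing ring atoms are skipped with a warning, and
intra-residue pairs are never reported. Absolute hydrogen-bond counts depend
on the angle convention and are comparable across tools only qualitatively.

## Conserved segments

"Common subsequence" is implemented as longest common **substring**
(contiguous, exact, case-sensitive): the reported coordinate ranges of such
segments are contiguous intervals, which fixes the intent. The detector
builds a suffix automaton over the first sequence and sweeps each other
sequence through it (per-state best match, propagated down the suffix-link
tree); candidates are re-verified verbatim in every sequence before being
returned, and all ties at the winning length are reported with 1-based
inclusive coordinates. A brute-force enumeration oracle (substring-set
intersection with a binary search over the length) lives in the test suite
and in the acceptance script. Percent identity is matches over aligned
columns (×100), either ungapped on equal-length inputs or on a global
alignment where gap columns count as mismatches.

## Pipeline

`run_study` composes the stages per protein and per protein pair: metric
tables; the verdict grid (per-domain RMSD, EWMA → KS per matched replicate
index, aggregated by the rule); mean Fréchet distances on RMSF curves per
named selection over mapped residues; jaw-distance time lags; clustering,
medoids, open/closed PDB exports and the stacked projection; contact
catalogues on medoids; conserved segments when sequences are provided; and a
manifest echoing seed, versions, rule and configs — sufficient to reproduce
every number in the bundle. SASA is computed on an evenly strided frame
subsample (50 frames by default) because it is the one O(atoms²)-ish metric;
the stride is recorded. Stage outputs are pure functions of (inputs, config,
seed); on failure the completed outputs move to `partial/` and the stage
name is raised.

## Known limitations

- The verdict rule inherits the anti-conservative p-values discussed above;
  the D thresholds, not the p-values, do most of the work.
- Contact detection without explicit hydrogens is distance-only and will
  overcount relative to angle-aware counts.
- The clustering metric treats all alpha carbons equally; no attempt is made
  to reproduce any particular k-means variant's initialization beyond fixed
  seeding.
- Binary trajectory formats rely on the optional MDAnalysis adapter; native
  formats are deliberately text (multi-model PDB, CSV) at desk scale.
- The packaged domain map covers the one paralog whose ranges are published
  in full (AGO2); element selections (H1/L1/SL1/SL2/LL1) are packaged for
  all four paralogs.
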
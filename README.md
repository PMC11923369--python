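# pincermd

Comparative analysis of multi-domain protein MD trajectories, built around
the kind of question raised by the four human Argonaute paralogs (AGO1–4):
proteins that share ~90% of their sequence and the same N–L1–PAZ–L2–MID–PIWI
architecture, yet behave differently in replicated microsecond simulations.
`pincermd` is for structural bioinformaticians who have several replicated
trajectories of homologous proteins and want a defensible, reproducible answer
to "do these paralogs actually move differently, and where?"

## What it computes

**Structural metrics.** Whole-structure and per-domain RMSD after Kabsch
superposition (proper rotations only), per-residue RMSF about the iteratively
superposed time average, mass-weighted radius of gyration, Shrake–Rupley
solvent-accessible surface area (960 deterministic golden-spiral points per
atom, Bondi radii, 1.4 Å probe), and center-of-mass distances between all
domain pairs.

**Cross-replicate significance protocol.** A metric trace `x_t` (e.g. a
domain's RMSD over 100,000 frames at 10 ps/frame) is smoothed with an
exponentially weighted moving average,

    y_0 = x_0,   y_t = α x_t + (1 − α) y_{t−1},   α = 2/(span + 1),

with span = 10% of the series length. Two proteins' smoothed traces are
compared with the two-sample Kolmogorov–Smirnov statistic D, replicate by
replicate. The comparison is **significant** only when every replicate gives
D > 0.55 with p < 0.001, **insignificant** only when every replicate gives
D < 0.45, and inconclusive otherwise. Residue-indexed curves (RMSF over
aligned residues) are compared with the paired Wilcoxon signed-rank test and
with the discrete Fréchet ("dog-leash") distance

    F(A, B) = min over monotone couplings of max pointwise distance,

computed by dynamic programming.

**States, synchronization, clustering.** Jaw (e.g. PAZ–MID) distance traces
are smoothed, z-normalized and cross-correlated on a fixed central window to
estimate the integer time lag between two proteins' open/close motions.
Frames are clustered with k-means on superposed alpha-carbon coordinates, k
chosen by the Davies–Bouldin score (ties broken toward an average
within-cluster deviation of 4 Å); medoids — real frames, not centroids — are
extracted per cluster, the open and closed state representatives are the
medoids with extreme jaw distances, and medoid alpha-carbon coordinates
(restricted to residues shared across proteins via global sequence alignment)
are stacked and projected to 2-D (UMAP-parameterized, deterministic PCA
fallback).

**Contacts and conserved segments.** Geometric detection of hydrogen bonds
(backbone/side-chain subtypes), salt bridges, pi-cation, pi-stacking and
t-stacking on medoid frames, deduplicated into a (type, residue-pair)
catalogue with intra/interdomain labels; and detection of the longest
contiguous segment shared verbatim by k paralog sequences (suffix automaton;
LCS1/LCS2-style analysis), plus percent identity for companion nucleotide
segments.

**Synthetic data.** A first-class generator produces multi-domain "pincer"
trajectories — rigid domains, two jaws oscillating between a closed and an
open separation (default 30 → 55 Å, mirroring the >50 Å jaw excursions of
Argonaute-scale pincer motion), i.i.d. per-residue Gaussian noise, 10 ps
frame stride — so the entire pipeline is testable without downloading
trajectory archives.

## Worked example

`examples/` holds one short script per capability. The significance protocol
on two synthetic paralogs whose only difference is a 5× residue-noise
contrast (`python examples/03_significance_protocol.py`):

```
replicate 1: D = 0.978, p = 0.00e+00
replicate 2: D = 0.978, p = 0.00e+00
replicate 3: D = 0.978, p = 0.00e+00
verdict: significant (rule: D > 0.55 and p < 0.001 in ALL replicates)
Frechet distance between RMSF curves: 1.28 A (0 would mean identical flexibility profiles)
```

Every replicate pair separates cleanly (D near 1 with vanishing p), so the
rule calls the paralogs' whole-structure dynamics significantly different;
the 1.28 Å Fréchet distance says their per-residue flexibility profiles
differ by about that much at the worst point of the best alignment of the two
curves. State and synchronization analysis
(`python examples/04_states_and_clustering.py`):

```
chosen k = 2 (Davies-Bouldin = 0.078), medoid frames = [248, 197]
open state:   medoid 1, jaw distance 49.9 A
closed state: medoid 0, jaw distance 30.0 A
stroke = 19.9 A (generator plants 2 x amplitude = 20.0 A)
time lag between the systems: 60 frames (r = 1.000); the generator planted 60
```

The clustering recovers the two planted conformational states, the
open-minus-closed jaw distance recovers the planted 20 Å stroke, and the lag
estimator recovers the planted 60-frame phase shift exactly.

`pincermd` also ships a thin CLI (`pincermd simulate | metrics | compare |
cluster | contacts | segments | run-all`) over the same library; `run-all`
executes the full study from a YAML config and writes a report bundle with a
manifest sufficient to reproduce every number in it.

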
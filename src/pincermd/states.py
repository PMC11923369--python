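"""Open/close state analysis, synchronization, clustering and projection.

The open and closed conformations of a pincer-like multi-domain protein are
identified among cluster medoids by the extreme jaw (e.g. PAZ-MID)
center-of-mass distances.  Synchronization between two jaw-distance traces is
the integer time lag maximizing their cross-correlation after EWMA smoothing
and z-normalization.  Trajectories are clustered with k-means on superposed
alpha-carbon coordinates (Euclidean distance on this featurization is the
mean-square-deviation metric up to a constant factor), the cluster count
chosen by the Davies-Bouldin score with a tie-break preference for an average
within-cluster deviation near 4 Angstrom, and medoids are the member frames
minimizing summed within-cluster squared deviation.  Cross-protein residue
correspondence comes from global sequence alignment; aligned medoid
alpha-carbon coordinates are stacked and projected to 2-D (UMAP-parameterized
when available, deterministic PCA fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import davies_bouldin_score
from Bio import Align
from Bio.Align import substitution_matrices

from .metrics import MetricSeries, apply_transform, superpose, _mean_structure
from .stats import EwmaSpec, ewma
from .trajio import Trajectory

__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "ResidueMapping",
    "EmbedConfig",
    "smooth_normalize",
    "time_lag",
    "select_state_representatives",
    "cluster_frames",
    "extract_medoids",
    "map_residues",
    "stack_and_project",
]


# ---------------------------------------------------------------------------
# Smoothing / synchronization

def smooth_normalize(series: Sequence[float] | np.ndarray | MetricSeries,
                     span: int | None = None) -> np.ndarray:
    """EWMA smoothing (span = 10% of length by default) then z-normalization.

    The combination suppresses frame-level noise while keeping the inflection
    points of the large-scale motion comparable across proteins.
    """
    x = series.values if isinstance(series, MetricSeries) else \
        np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series must have at least 10 points")
    spec = EwmaSpec(span=span) if span is not None else EwmaSpec.fraction_of(x.size)
    smooth = ewma(x, spec)
    sd = smooth.std()
    if sd == 0.0:
        raise ValueError("zero variance after smoothing; cannot normalize")
    return (smooth - smooth.mean()) / sd


def time_lag(series_a: np.ndarray, series_b: np.ndarray,
             max_lag: int) -> tuple[int, float]:
    """Integer lag in [-max_lag, +max_lag] maximizing cross-correlation.

    Inputs are expected already smoothed and normalized (see
    :func:`smooth_normalize`).  A positive lag means ``series_b`` trails
    ``series_a`` by that many frames (``b[t] ~ a[t - lag]``).  The correlation
    at each lag is the Pearson correlation between the fixed central window
    ``a[max_lag : n - max_lag]`` and the corresponding lag-shifted window of
    ``b``, so a pure shift scores exactly 1 at its true lag regardless of the
    signal's shape, and every lag is scored on the same amount of data.
    Requires ``2 * max_lag < n``.  Ties are broken toward the smallest |lag|.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    n = a.size
    if 2 * max_lag >= n:
        raise ValueError("max_lag must be smaller than half the series length")
    x = a[max_lag:n - max_lag]
    xc = x - x.mean()
    xn = np.linalg.norm(xc)
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(lags.size)
    for k, lag in enumerate(lags):
        y = b[max_lag + lag:n - max_lag + lag]
        yc = y - y.mean()
        denom = xn * np.linalg.norm(yc)
        corr[k] = float(xc @ yc / denom) if denom > 0 else 0.0
    order = sorted(range(lags.size),
                   key=lambda k: (-corr[k], abs(int(lags[k])), int(lags[k])))
    best = order[0]
    return int(lags[best]), float(corr[best])


def select_state_representatives(medoids: Sequence[np.ndarray],
                                 jaw_distances: Sequence[float]
                                 ) -> tuple[int, int]:
    """Indices of the open (max jaw distance) and closed (min) medoids.

    Ties go to the lowest index.  A single medoid is returned for both roles
    with a warning.
    """
    d = np.asarray(jaw_distances, dtype=float)
    if len(medoids) != d.size:
        raise ValueError("one jaw distance per medoid is required")
    if d.size == 0:
        raise ValueError("at least one medoid is required")
    if d.size == 1:
        warnings.warn("single medoid: open and closed representatives coincide")
        return 0, 0
    open_idx = int(np.argmax(d))    # argmax/argmin return the first tie
    closed_idx = int(np.argmin(d))
    return open_idx, closed_idx


# ---------------------------------------------------------------------------
# Clustering

@dataclass(frozen=True)
class ClusterConfig:
    """k-means over superposed alpha-carbon coordinates with DB model selection."""

    k_range: tuple[int, int] = (2, 20)        # inclusive
    msd_preference: float = 4.0               # Angstrom, tie-break target
    db_tie_tolerance: float = 0.05            # ties = within 5% of the best DB
    seed: int = 0
    n_init: int = 10

    def ks(self, n_frames: int) -> list[int]:
        lo, hi = self.k_range
        hi = min(hi, n_frames - 1)
        if lo < 2 or lo > hi:
            raise ValueError(f"k_range {self.k_range} invalid for {n_frames} frames")
        return list(range(lo, hi + 1))


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray                  # per frame
    medoid_indices: tuple[int, ...]     # frame index per cluster
    cluster_rmsd: tuple[float, ...]     # avg within-cluster deviation (A)
    chosen_k: int
    db_score: float | None
    features: np.ndarray                # (n_frames, 3*n_ca) superposed CA coords
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(self.labels.size),
                             "cluster": self.labels})


def _featurize(traj: Trajectory) -> np.ndarray:
    ca = traj.topology.alpha_carbons()
    _, fitted = _mean_structure(traj, ca)
    return fitted[:, ca, :].reshape(traj.n_frames, -1)


def _avg_within_cluster_rmsd(features: np.ndarray, labels: np.ndarray,
                             n_ca: int) -> float:
    vals = []
    for c in np.unique(labels):
        member = features[labels == c]
        centroid = member.mean(axis=0)
        msd = np.mean(np.sum((member - centroid) ** 2, axis=1)) / n_ca
        vals.append(np.sqrt(msd))
    return float(np.mean(vals))


def _medoid_index(features: np.ndarray, member_frames: np.ndarray) -> int:
    """Member frame minimizing summed within-cluster squared deviation.

    sum_j ||x_i - x_j||^2 = m*||x_i||^2 - 2 x_i . S + sum_j ||x_j||^2; only the
    i-dependent part matters, so no pairwise matrix is formed.  Ties go to the
    lowest frame index.
    """
    x = features[member_frames]
    sq = np.sum(x ** 2, axis=1)
    s = x.sum(axis=0)
    cost = len(member_frames) * sq - 2.0 * (x @ s)
    return int(member_frames[int(np.argmin(cost))])


def cluster_frames(traj: Trajectory, config: ClusterConfig = ClusterConfig()
                   ) -> ClusterResult:
    """Cluster trajectory frames and extract per-cluster medoids.

    Frames are superposed onto the trajectory's iteratively refined average
    structure over alpha carbons and flattened; k-means (k-means++ init,
    fixed seed) runs for each k in the configured range; k is chosen by the
    Davies-Bouldin score, with ties (within ``db_tie_tolerance``) broken
    toward the k whose average within-cluster deviation is closest to
    ``msd_preference``.  Deterministic given the seed.  A trajectory whose
    frames are all identical degenerates to a single cluster with a warning.
    """
    features = _featurize(traj)
    n_ca = traj.topology.alpha_carbons().size
    if np.allclose(features, features[0], atol=1e-12):
        warnings.warn("all frames identical; returning a single-cluster result")
        return ClusterResult(
            labels=np.zeros(traj.n_frames, dtype=int), medoid_indices=(0,),
            cluster_rmsd=(0.0,), chosen_k=1, db_score=None,
            features=features, degenerate=True)

    candidates = []
    for k in config.ks(traj.n_frames):
        km = KMeans(n_clusters=k, init="k-means++", n_init=config.n_init,
                    random_state=config.seed)
        labels = km.fit_predict(features)
        if np.unique(labels).size < 2:
            continue
        db = davies_bouldin_score(features, labels)
        avg_rmsd = _avg_within_cluster_rmsd(features, labels, n_ca)
        candidates.append((k, db, avg_rmsd, labels))
    if not candidates:
        raise RuntimeError("clustering failed for every k in the range")
    best_db = min(db for _, db, _, _ in candidates)
    tied = [c for c in candidates
            if c[1] <= best_db * (1.0 + config.db_tie_tolerance)]
    k, db, avg_rmsd, labels = min(
        tied, key=lambda c: (abs(c[2] - config.msd_preference), c[0]))

    medoids, rmsds = [], []
    for c in range(k):
        member = np.flatnonzero(labels == c)
        medoids.append(_medoid_index(features, member))
        centroid = features[member].mean(axis=0)
        msd = np.mean(np.sum((features[member] - centroid) ** 2, axis=1)) / n_ca
        rmsds.append(float(np.sqrt(msd)))
    return ClusterResult(labels=labels, medoid_indices=tuple(medoids),
                         cluster_rmsd=tuple(rmsds), chosen_k=k,
                         db_score=float(db), features=features)


def extract_medoids(result: ClusterResult, traj: Trajectory) -> list[np.ndarray]:
    """Coordinate frames of the cluster medoids, in cluster order."""
    return [traj.coords[i] for i in result.medoid_indices]


# ---------------------------------------------------------------------------
# Cross-protein residue mapping

@dataclass(frozen=True)
class ResidueMapping:
    """Aligned-column pairs (1-based residue numbers), strictly increasing."""

    pairs: tuple[tuple[int, int], ...]
    score: float
    parameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a1, b1), (a2, b2) in zip(self.pairs, self.pairs[1:]):
            if a2 <= a1 or b2 <= b1:
                raise ValueError("mapping must be strictly increasing in both "
                                 "coordinates")

    def transpose(self) -> "ResidueMapping":
        return ResidueMapping(pairs=tuple((b, a) for a, b in self.pairs),
                              score=self.score, parameters=self.parameters)

    def as_dict(self) -> dict[int, int]:
        return {a: b for a, b in self.pairs}


_ALIGN_PARAMS = {"substitution_matrix": "BLOSUM62",
                 "open_gap_score": -10.0, "extend_gap_score": -0.5,
                 "end_gaps": "free", "mode": "global"}


def map_residues(seq_a: str, seq_b: str) -> ResidueMapping:
    """Global pairwise alignment -> residue-number correspondence.

    BLOSUM62 with gap open 10 / extend 0.5 and free end gaps; the mapping is
    the set of aligned non-gap columns, 1-based in both sequences.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    alignment = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for offset in range(a_end - a_start):
            pairs.append((a_start + offset + 1, b_start + offset + 1))
    return ResidueMapping(pairs=tuple(pairs), score=float(alignment.score),
                          parameters=dict(_ALIGN_PARAMS))


# ---------------------------------------------------------------------------
# Stacked medoid projection

@dataclass(frozen=True)
class EmbedConfig:
    """2-D embedding parameters, serialized with every projection output."""

    method: str = "pca"            # "pca" (deterministic) or "umap"
    min_dist: float = 1.0
    n_neighbours: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        return {"method": self.method, "min_dist": self.min_dist,
                "n_neighbours": self.n_neighbours, "seed": self.seed}


@dataclass(frozen=True)
class ProjectionResult:
    coords: np.ndarray            # (n_rows, 2)
    rows: pd.DataFrame            # protein, medoid, residue per row
    config: EmbedConfig

    def to_frame(self) -> pd.DataFrame:
        df = self.rows.copy()
        df["x"] = self.coords[:, 0]
        df["y"] = self.coords[:, 1]
        return df


def stack_and_project(medoid_sets: Mapping[str, Sequence[np.ndarray]],
                      ca_indices: Mapping[str, np.ndarray],
                      mappings: Mapping[str, ResidueMapping] | None,
                      reference: str,
                      config: EmbedConfig = EmbedConfig()) -> ProjectionResult:
    """Stack aligned medoid alpha-carbon coordinates and embed them in 2-D.

    ``medoid_sets`` maps protein name -> list of medoid coordinate frames;
    ``ca_indices`` maps protein name -> alpha-carbon atom indices ordered by
    residue; ``mappings`` maps each non-reference protein to its
    ResidueMapping from the reference (identity when None).  Medoids are
    restricted to the residue positions common to every protein, rigidly
    superposed onto the first reference medoid, and each (medoid, residue)
    alpha-carbon position becomes one 3-feature row of the embedding input.
    """
    if reference not in medoid_sets:
        raise ValueError(f"reference {reference!r} not among medoid sets")
    ref_ca = np.asarray(ca_indices[reference])
    n_ref = ref_ca.size

    # residue positions (1-based along the CA order) common to all proteins
    common_ref = set(range(1, n_ref + 1))
    per_protein_pos: dict[str, dict[int, int]] = {reference: {i: i for i in common_ref}}
    for name in medoid_sets:
        if name == reference:
            continue
        if mappings is None or name not in mappings:
            n_other = np.asarray(ca_indices[name]).size
            pairs = {i: i for i in range(1, min(n_ref, n_other) + 1)}
        else:
            pairs = mappings[name].as_dict()
        per_protein_pos[name] = pairs
        common_ref &= set(pairs)
    common = sorted(common_ref)
    if len(common) < 3:
        raise ValueError("fewer than 3 residue positions common to all proteins")

    ref_rows = np.asarray(ca_indices[reference])[[c - 1 for c in common]]
    ref_frame = np.asarray(medoid_sets[reference][0])[ref_rows]

    stacked, meta = [], []
    for name, medoids in medoid_sets.items():
        pos = per_protein_pos[name]
        own_ca = np.asarray(ca_indices[name])
        rows = own_ca[[pos[c] - 1 for c in common]]
        for m, frame in enumerate(medoids):
            sub = np.asarray(frame)[rows]
            rot, trans, _ = superpose(sub, ref_frame)
            sub = apply_transform(sub, rot, trans)
            stacked.append(sub)
            meta.extend({"protein": name, "medoid": m, "ref_position": c}
                        for c in common)
    matrix = np.concatenate(stacked, axis=0)

    if config.method == "pca":
        emb = PCA(n_components=2, random_state=config.seed).fit_transform(matrix)
    elif config.method == "umap":
        import umap  # optional dependency
        reducer = umap.UMAP(n_components=2, min_dist=config.min_dist,
                            n_neighbors=min(config.n_neighbours,
                                            matrix.shape[0] - 1),
                            random_state=config.seed)
        emb = np.asarray(reducer.fit_transform(matrix))
    else:
        raise ValueError(f"unknown embedding method {config.method!r}")
    return ProjectionResult(coords=emb, rows=pd.DataFrame(meta), config=config)
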
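"""Per-frame and per-trajectory structural metrics.

Superposition RMSD (Kabsch, proper rotations only), per-residue RMSF around
the iteratively superposed time-averaged structure, mass-weighted radius of
gyration, all-pairs interdomain center-of-mass distances and Shrake-Rupley
solvent-accessible surface area.  All lengths in Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajio import DomainMap, Topology, Trajectory

__all__ = [
    "MetricSeries",
    "DistanceMatrixSeries",
    "superpose",
    "apply_transform",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "interdomain_distances",
    "sasa",
    "VDW_RADII",
]


@dataclass(frozen=True)
class MetricSeries:
    """A time- or residue-indexed scalar curve with units and provenance."""

    index: np.ndarray
    values: np.ndarray
    index_kind: str          # "time-frames" | "residue-numbers"
    units: str               # "A", "A^2", "count", ...
    label: str = ""
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.index)
        vals = np.asarray(self.values, dtype=float)
        if len(idx) != len(vals):
            raise ValueError("index and values length mismatch")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in series {self.label!r}")
        object.__setattr__(self, "index", idx)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        col = f"{self.label or 'value'} ({self.units})"
        return pd.DataFrame({self.index_kind: self.index, col: self.values})


@dataclass(frozen=True)
class DistanceMatrixSeries:
    """COM-distance time series per unordered domain pair (Angstrom)."""

    series: Mapping[tuple[str, str], MetricSeries]

    def __post_init__(self) -> None:
        for (a, b) in self.series:
            if a == b:
                raise ValueError("diagonal entries are not allowed")

    def get(self, a: str, b: str) -> MetricSeries:
        key = (a, b) if (a, b) in self.series else (b, a)
        return self.series[key]

    def pairs(self) -> list[tuple[str, str]]:
        return list(self.series)

    def summary(self) -> pd.DataFrame:
        rows = []
        for (a, b), s in self.series.items():
            rows.append({
                "domain_i": a, "domain_j": b,
                "mean_A": float(np.mean(s.values)),
                "median_A": float(np.median(s.values)),
                "variance_A2": float(np.var(s.values)),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Superposition (Kabsch)

def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` over the selected atoms, where
    ``mobile @ rotation.T + translation`` best fits the reference in the
    least-squares sense over proper rotations (det = +1; reflections are never
    returned).

    Requires at least 2 distinct selected atoms.  For collinear selections the
    minimizing rotation is not unique but the returned RMSD still is; a fully
    degenerate selection (all atoms coincident) is rejected.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if selection is not None:
        mob_sel, ref_sel = mob[selection], ref[selection]
    else:
        mob_sel, ref_sel = mob, ref
    if len(mob_sel) != len(ref_sel):
        raise ValueError("mobile and reference selections differ in size")
    if len(mob_sel) < 2:
        raise ValueError("superposition needs at least 2 selected atoms")
    mob_c = mob_sel - mob_sel.mean(axis=0)
    ref_c = ref_sel - ref_sel.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 1:
        raise ValueError("selected atoms all coincide; superposition is degenerate")

    # Kabsch via SVD of the covariance, with the proper-rotation correction
    cov = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_sel.mean(axis=0) - rotation @ mob_sel.mean(axis=0)
    fitted = mob_sel @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_sel) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def _resolve_selection(traj: Trajectory,
                       selection: np.ndarray | Sequence[int] | None,
                       default_ca: bool = True) -> np.ndarray:
    if selection is None:
        return traj.topology.alpha_carbons() if default_ca \
            else np.arange(traj.n_atoms)
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    return sel


# ---------------------------------------------------------------------------
# RMSD / RMSF / Rg

def rmsd_series(traj: Trajectory, reference: int | np.ndarray = 0,
                selection: np.ndarray | Sequence[int] | None = None,
                fit_selection: np.ndarray | Sequence[int] | None = None,
                label: str = "RMSD") -> MetricSeries:
    """Per-frame RMSD against a reference frame after rigid superposition.

    Each frame is superposed on the reference over ``fit_selection`` (default:
    all alpha carbons, the whole-structure fit), then RMSD is measured over
    ``selection`` (default: the fit selection) - the fit-on-whole,
    measure-on-part convention used for per-domain RMSD curves.
    """
    fit_sel = _resolve_selection(traj, fit_selection)
    meas_sel = fit_sel if selection is None else _resolve_selection(traj, selection)
    ref = traj.coords[reference] if isinstance(reference, (int, np.integer)) \
        else np.asarray(reference, dtype=float)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        rot, trans, _ = superpose(traj.coords[f], ref, fit_sel)
        fitted = apply_transform(traj.coords[f][meas_sel], rot, trans)
        values[f] = np.sqrt(np.mean(np.sum((fitted - ref[meas_sel]) ** 2, axis=1)))
    return MetricSeries(index=np.arange(traj.n_frames), values=values,
                        index_kind="time-frames", units="A", label=label)


def _mean_structure(traj: Trajectory, fit_sel: np.ndarray,
                    n_iter: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superposed time-average; returns (mean, superposed stack)."""
    coords = traj.coords
    ref = coords.mean(axis=0)
    fitted = coords
    for _ in range(n_iter):
        fitted = np.empty_like(coords)
        for f in range(traj.n_frames):
            rot, trans, _ = superpose(coords[f], ref, fit_sel)
            fitted[f] = apply_transform(coords[f], rot, trans)
        ref = fitted.mean(axis=0)
    return ref, fitted


def rmsf(traj: Trajectory,
         selection: np.ndarray | Sequence[int] | None = None,
         superpose_selection: np.ndarray | Sequence[int] | None = None,
         label: str = "RMSF") -> MetricSeries:
    """Per-residue RMS fluctuation about the time-averaged position.

    Every frame is first superposed on the time-averaged structure (two
    iterative passes) over ``superpose_selection`` (default: alpha carbons);
    the residue-indexed fluctuation is then computed over ``selection``
    (default: alpha carbons).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fit_sel = _resolve_selection(traj, superpose_selection)
    meas_sel = _resolve_selection(traj, selection)
    mean, fitted = _mean_structure(traj, fit_sel)
    disp2 = np.sum((fitted[:, meas_sel, :] - mean[meas_sel]) ** 2, axis=2)
    values = np.sqrt(disp2.mean(axis=0))
    residues = traj.topology.resids[meas_sel]
    return MetricSeries(index=residues, values=values,
                        index_kind="residue-numbers", units="A", label=label)


def radius_of_gyration(traj: Trajectory, label: str = "Rg") -> MetricSeries:
    """Mass-weighted radius of gyration per frame (translation-invariant)."""
    masses = traj.topology.masses
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (traj.coords * masses[None, :, None]).sum(axis=1) / total
    delta = traj.coords - com[:, None, :]
    rg2 = (masses[None, :] * np.sum(delta ** 2, axis=2)).sum(axis=1) / total
    return MetricSeries(index=np.arange(traj.n_frames), values=np.sqrt(rg2),
                        index_kind="time-frames", units="A", label=label)


def interdomain_distances(traj: Trajectory,
                          domain_map: DomainMap) -> DistanceMatrixSeries:
    """Mass-weighted COM distance time series for every domain pair."""
    names = domain_map.domain_names
    masses = traj.topology.masses
    coms: dict[str, np.ndarray] = {}
    for name in names:
        idx = traj.topology.atom_indices_for_residues(domain_map.residues_of(name))
        if idx.size == 0:
            raise ValueError(f"domain {name!r} selects no atoms")
        w = masses[idx]
        coms[name] = (traj.coords[:, idx, :] * w[None, :, None]).sum(axis=1) / w.sum()
    series = {}
    frames = np.arange(traj.n_frames)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            dist = np.linalg.norm(coms[a] - coms[b], axis=1)
            series[(a, b)] = MetricSeries(
                index=frames, values=dist, index_kind="time-frames",
                units="A", label=f"COM {a}-{b}")
    return DistanceMatrixSeries(series=series)


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley with a deterministic golden-spiral sphere point set)

#: Bondi van der Waals radii (Angstrom)
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "F": 1.47, "CL": 1.75, "SE": 1.90}


def golden_spiral_points(n: int) -> np.ndarray:
    """n deterministic, near-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(coords: np.ndarray, elements: Sequence[str] | Topology,
         probe_radius: float = 1.4, n_points: int = 960,
         residue_ids: Sequence[int] | None = None
         ) -> tuple[float, dict[int, float]]:
    """Shrake-Rupley solvent-accessible surface area of one frame.

    Each atom's SASA is the fraction of ``n_points`` golden-spiral quadrature
    points on its solvent-expanded sphere (vdW + probe) not buried inside any
    neighbour's expanded sphere, times the sphere area.  Deterministic given
    ``n_points``.

    Returns ``(total, per_residue)`` in Angstrom^2.  ``per_residue`` is keyed
    by residue number when a Topology (or explicit ``residue_ids``) is given,
    else by atom index.
    """
    if isinstance(elements, Topology):
        if residue_ids is None:
            residue_ids = elements.resids
        elements = elements.elements
    xyz = np.asarray(coords, dtype=float)
    n_atoms = len(xyz)
    radii = np.empty(n_atoms)
    for i, el in enumerate(elements):
        try:
            radii[i] = VDW_RADII[el.upper()]
        except KeyError:
            raise ValueError(f"no van der Waals radius for element {el!r}")
    expanded = radii + probe_radius
    sphere = golden_spiral_points(n_points)

    tree = cKDTree(xyz)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = xyz[i] + expanded[i] * sphere
        neighbours = [j for j in tree.query_ball_point(xyz[i], max_reach)
                      if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2

    per_residue: dict[int, float] = {}
    keys = residue_ids if residue_ids is not None else range(n_atoms)
    for key, area in zip(keys, areas):
        per_residue[int(key)] = per_residue.get(int(key), 0.0) + float(area)
    return float(areas.sum()), per_residue


def sasa_series(traj: Trajectory, probe_radius: float = 1.4,
                n_points: int = 960,
                selection: np.ndarray | Sequence[int] | None = None,
                label: str = "SASA") -> MetricSeries:
    """Total SASA per frame (optionally summed over a residue selection)."""
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        total, per_res = sasa(traj.coords[f], traj.topology,
                              probe_radius=probe_radius, n_points=n_points)
        if selection is None:
            values[f] = total
        else:
            values[f] = sum(per_res.get(int(r), 0.0) for r in selection)
    return MetricSeries(index=np.arange(traj.n_frames), values=values,
                        index_kind="time-frames", units="A^2", label=label)
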
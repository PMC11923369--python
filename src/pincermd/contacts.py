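"""Geometric detection of weak interactions on PDB-convention topologies.

Types and thresholds (boundaries inclusive, distances in Angstrom, angles in
degrees):

* hydrogen bond (``hbbb``/``hbsb``/``hbss`` by backbone/side-chain subtype):
  donor-acceptor heavy-atom distance <= 3.5; when an explicit hydrogen is
  bonded to the donor, additionally angle D-H...A >= 110.
* salt bridge (``sb``): anionic O (Asp OD*, Glu OE*, C-terminal OXT) to
  cationic N (Lys NZ, Arg NH*/NE, His ND1/NE2) <= 4.0.
* pi-cation (``pc``): cationic N within 6.0 of an aromatic ring centroid and
  <= 60 degrees off the ring normal.
* pi-stacking (``ps``): ring centroids <= 7.0 apart, normals within 30.
* t-stacking (``ts``): ring centroids <= 7.0 apart, normals 60-90.

Rings: Phe/Tyr six-ring, His five-ring, Trp both rings; centroid is the
unweighted mean of ring atoms.  Aromatic residues with missing ring atoms are
skipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trajio import DomainMap, Topology, Trajectory

__all__ = [
    "ContactEvent",
    "CONTACT_TYPES",
    "detect_contacts",
    "hbond_count_series",
    "unique_contact_catalog",
    "catalog_to_table",
]

CONTACT_TYPES = ("hbbb", "hbsb", "hbss", "sb", "pc", "ps", "ts")

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# heavy-atom donors (N/O/S carrying at least one polar hydrogen)
_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
_ANIONIC: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}
_CATIONIC: dict[str, set[str]] = {
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
}
_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2")),
}

HB_DIST_MAX = 3.5
HB_ANGLE_MIN = 110.0
SB_DIST_MAX = 4.0
PC_DIST_MAX = 6.0
PC_ANGLE_MAX = 60.0
PS_DIST_MAX = 7.0
PS_ANGLE_MAX = 30.0
TS_DIST_MAX = 7.0
TS_ANGLE_MIN = 60.0
TS_ANGLE_MAX = 90.0


@dataclass(frozen=True)
class ContactEvent:
    """One detected interaction; residue pair ordered by residue number."""

    type: str
    res_i: int
    res_j: int
    resname_i: str
    resname_j: str
    atoms: tuple[str, str]
    distance: float
    angle: float | None = None
    frame: int | None = None

    def __post_init__(self) -> None:
        if self.type not in CONTACT_TYPES:
            raise ValueError(f"unknown contact type {self.type!r}")
        if self.res_i > self.res_j:
            raise ValueError("residue pair must be ordered (res_i <= res_j)")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.res_i, self.res_j)


def _hb_subtype(donor_name: str, acceptor_name: str) -> str:
    d_bb = donor_name in BACKBONE_ATOMS
    a_bb = acceptor_name in BACKBONE_ATOMS
    if d_bb and a_bb:
        return "hbbb"
    if d_bb or a_bb:
        return "hbsb"
    return "hbss"


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


class _Frame:
    """Indexed view over one coordinate frame of a topology."""

    def __init__(self, coords: np.ndarray, topology: Topology) -> None:
        self.xyz = np.asarray(coords, dtype=float)
        self.top = topology
        self.by_residue: dict[int, dict[str, int]] = {}
        for i in range(topology.n_atoms):
            self.by_residue.setdefault(int(topology.resids[i]), {})[
                topology.names[i]] = i

    def resname(self, resid: int) -> str:
        idx = next(iter(self.by_residue[resid].values()))
        return self.top.resnames[idx]

    def donors(self) -> list[tuple[int, str, int]]:
        out = []
        for resid, atoms in self.by_residue.items():
            resname = self.resname(resid)
            if "N" in atoms and resname != "PRO":
                out.append((resid, "N", atoms["N"]))
            for name in _SIDECHAIN_DONORS.get(resname, ()):
                if name in atoms:
                    out.append((resid, name, atoms[name]))
        return out

    def acceptors(self) -> list[tuple[int, str, int]]:
        out = []
        for resid, atoms in self.by_residue.items():
            resname = self.resname(resid)
            for name in ("O", "OXT"):
                if name in atoms:
                    out.append((resid, name, atoms[name]))
            for name in _SIDECHAIN_ACCEPTORS.get(resname, ()):
                if name in atoms:
                    out.append((resid, name, atoms[name]))
        return out

    def charged(self, table: Mapping[str, set[str]],
                extra_oxt: bool = False) -> list[tuple[int, str, int]]:
        out = []
        for resid, atoms in self.by_residue.items():
            resname = self.resname(resid)
            for name in table.get(resname, ()):
                if name in atoms:
                    out.append((resid, name, atoms[name]))
            if extra_oxt and "OXT" in atoms:
                out.append((resid, "OXT", atoms["OXT"]))
        return out

    def hydrogens_bonded_to(self, atom_index: int, resid: int,
                            cutoff: float = 1.25) -> list[int]:
        out = []
        for name, idx in self.by_residue[resid].items():
            if name.startswith("H"):
                if np.linalg.norm(self.xyz[idx] - self.xyz[atom_index]) <= cutoff:
                    out.append(idx)
        return out

    def rings(self) -> list[tuple[int, np.ndarray, np.ndarray]]:
        """(resid, centroid, unit normal) per complete aromatic ring."""
        out = []
        for resid, atoms in self.by_residue.items():
            resname = self.resname(resid)
            for ring_atoms in _RINGS.get(resname, ()):
                try:
                    pts = self.xyz[[atoms[a] for a in ring_atoms]]
                except KeyError:
                    warnings.warn(
                        f"residue {resname} {resid}: missing ring atoms; skipped")
                    continue
                centroid = pts.mean(axis=0)
                # normal = smallest principal axis of the ring points
                _, _, vt = np.linalg.svd(pts - centroid)
                out.append((resid, centroid, vt[2] / np.linalg.norm(vt[2])))
        return out


def _ordered(type_: str, r1: int, r2: int, n1: str, n2: str,
             atoms: tuple[str, str], dist: float, angle: float | None,
             frame: int | None) -> ContactEvent:
    if r1 <= r2:
        return ContactEvent(type_, r1, r2, n1, n2, atoms, dist, angle, frame)
    return ContactEvent(type_, r2, r1, n2, n1, (atoms[1], atoms[0]),
                        dist, angle, frame)


def detect_contacts(coords: np.ndarray, topology: Topology,
                    types: Iterable[str] = CONTACT_TYPES,
                    frame_id: int | None = None) -> list[ContactEvent]:
    """Detect all requested contact types in one frame.

    Detection is symmetric in atom order and every emitted event satisfies the
    geometric rule of its type (asserted before emission).
    """
    types = set(types)
    unknown = types - set(CONTACT_TYPES)
    if unknown:
        raise ValueError(f"unknown contact types: {sorted(unknown)}")
    frame = _Frame(coords, topology)
    events: list[ContactEvent] = []

    if types & {"hbbb", "hbsb", "hbss"}:
        events.extend(e for e in _detect_hbonds(frame, frame_id)
                      if e.type in types)
    if "sb" in types:
        events.extend(_detect_salt_bridges(frame, frame_id))
    if types & {"pc", "ps", "ts"}:
        rings = frame.rings()
        if "pc" in types:
            events.extend(_detect_pi_cation(frame, rings, frame_id))
        if types & {"ps", "ts"}:
            events.extend(e for e in _detect_stacking(frame, rings, frame_id)
                          if e.type in types)
    return events


def _detect_hbonds(frame: _Frame, frame_id: int | None) -> list[ContactEvent]:
    events = []
    for d_res, d_name, d_idx in frame.donors():
        for a_res, a_name, a_idx in frame.acceptors():
            if d_res == a_res:
                continue
            dist = float(np.linalg.norm(frame.xyz[d_idx] - frame.xyz[a_idx]))
            if dist > HB_DIST_MAX:
                continue
            angle = None
            hydrogens = frame.hydrogens_bonded_to(d_idx, d_res)
            if hydrogens:
                best = max(
                    _angle_deg(frame.xyz[d_idx] - frame.xyz[h],
                               frame.xyz[a_idx] - frame.xyz[h])
                    for h in hydrogens)
                if best < HB_ANGLE_MIN:
                    continue
                angle = best
            subtype = _hb_subtype(d_name, a_name)
            events.append(_ordered(subtype, d_res, a_res,
                                   frame.resname(d_res), frame.resname(a_res),
                                   (d_name, a_name), dist, angle, frame_id))
    return _dedupe(events)


def _detect_salt_bridges(frame: _Frame, frame_id: int | None) -> list[ContactEvent]:
    events = []
    anions = frame.charged(_ANIONIC, extra_oxt=True)
    cations = frame.charged(_CATIONIC)
    for a_res, a_name, a_idx in anions:
        for c_res, c_name, c_idx in cations:
            if a_res == c_res:
                continue
            dist = float(np.linalg.norm(frame.xyz[a_idx] - frame.xyz[c_idx]))
            if dist <= SB_DIST_MAX:
                events.append(_ordered("sb", a_res, c_res,
                                       frame.resname(a_res), frame.resname(c_res),
                                       (a_name, c_name), dist, None, frame_id))
    return _dedupe(events)


def _detect_pi_cation(frame: _Frame, rings, frame_id) -> list[ContactEvent]:
    events = []
    for c_res, c_name, c_idx in frame.charged(_CATIONIC):
        for r_res, centroid, normal in rings:
            if c_res == r_res:
                continue
            offset = frame.xyz[c_idx] - centroid
            dist = float(np.linalg.norm(offset))
            if dist > PC_DIST_MAX or dist == 0.0:
                continue
            angle = _angle_deg(offset, normal)
            angle = min(angle, 180.0 - angle)  # normal sign is arbitrary
            if angle <= PC_ANGLE_MAX:
                events.append(_ordered("pc", c_res, r_res,
                                       frame.resname(c_res), frame.resname(r_res),
                                       (c_name, "ring"), dist, angle, frame_id))
    return _dedupe(events)


def _detect_stacking(frame: _Frame, rings, frame_id) -> list[ContactEvent]:
    events = []
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            r1, c1, n1 = rings[i]
            r2, c2, n2 = rings[j]
            if r1 == r2:
                continue
            dist = float(np.linalg.norm(c1 - c2))
            if dist > PS_DIST_MAX:
                continue
            angle = _angle_deg(n1, n2)
            angle = min(angle, 180.0 - angle)
            if angle <= PS_ANGLE_MAX:
                type_ = "ps"
            elif TS_ANGLE_MIN <= angle <= TS_ANGLE_MAX:
                type_ = "ts"
            else:
                continue
            events.append(_ordered(type_, r1, r2,
                                   frame.resname(r1), frame.resname(r2),
                                   ("ring", "ring"), dist, angle, frame_id))
    return _dedupe(events)


def _dedupe(events: list[ContactEvent]) -> list[ContactEvent]:
    seen = set()
    out = []
    for e in events:
        key = (e.type, e.pair, e.atoms)
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


def hbond_count_series(traj: Trajectory):
    """Integer hydrogen-bond count per frame (all hb subtypes)."""
    from .metrics import MetricSeries
    counts = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        counts[f] = len(detect_contacts(traj.coords[f], traj.topology,
                                        types=("hbbb", "hbsb", "hbss"),
                                        frame_id=f))
    return MetricSeries(index=np.arange(traj.n_frames), values=counts,
                        index_kind="time-frames", units="count",
                        label="hydrogen bonds")


def unique_contact_catalog(medoids: Sequence[np.ndarray], topology: Topology,
                           domain_map: DomainMap | None = None,
                           types: Iterable[str] = CONTACT_TYPES
                           ) -> dict[tuple[str, int, int], dict]:
    """Union of (type, residue pair) occurrences over cluster medoids.

    Each entry records the residue names, how many medoids exhibited the
    contact and (when a DomainMap is given) the intra/interdomain labels.
    """
    if len(medoids) == 0:
        raise ValueError("at least one medoid frame is required")
    labels = None
    if domain_map is not None:
        labels = domain_map.label_residues(topology.residue_numbers)
    catalog: dict[tuple[str, int, int], dict] = {}
    for m, frame in enumerate(medoids):
        for event in detect_contacts(frame, topology, types=types, frame_id=m):
            key = (event.type, event.res_i, event.res_j)
            if key not in catalog:
                entry = {
                    "type": event.type,
                    "res_i": event.res_i, "res_j": event.res_j,
                    "resname_i": event.resname_i, "resname_j": event.resname_j,
                    "n_medoids_observed": 0,
                    "medoids": set(),
                }
                if labels is not None:
                    entry["domain_i"] = labels.get(event.res_i, DomainMap.UNK)
                    entry["domain_j"] = labels.get(event.res_j, DomainMap.UNK)
                    entry["span"] = ("intradomain"
                                     if entry["domain_i"] == entry["domain_j"]
                                     else "interdomain")
                catalog[key] = entry
            if m not in catalog[key]["medoids"]:
                catalog[key]["medoids"].add(m)
                catalog[key]["n_medoids_observed"] += 1
    return catalog


def catalog_to_table(catalog: dict[tuple[str, int, int], dict]) -> pd.DataFrame:
    rows = []
    for entry in catalog.values():
        row = {k: v for k, v in entry.items() if k != "medoids"}
        rows.append(row)
    columns = ["type", "res_i", "res_j", "resname_i", "resname_j",
               "domain_i", "domain_j", "span", "n_medoids_observed"]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=[c for c in columns if c in
                                     {"type", "res_i", "res_j", "resname_i",
                                      "resname_j", "n_medoids_observed"}])
    return df[[c for c in columns if c in df.columns]].sort_values(
        ["type", "res_i", "res_j"]).reset_index(drop=True)
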
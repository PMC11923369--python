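"""Reading and writing of topologies, trajectories, domain maps, sequences and tables.

Native formats are deliberately desk-scale and text-based: single-model PDB for
topologies, multi-model PDB or a documented CSV dialect for trajectories, JSON
for domain-map configuration, FASTA for sequences and RFC-4180 CSV for result
tables.  Binary MD formats are supported through an optional MDAnalysis adapter
behind the same contract.

All residue ranges are 1-based and inclusive on both ends.  Coordinates are in
Angstrom throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Topology",
    "Trajectory",
    "DomainMap",
    "Selection",
    "FormatError",
    "read_topology",
    "read_trajectory",
    "read_domain_map",
    "read_fasta",
    "write_fasta",
    "write_table",
    "write_json",
    "read_json",
    "write_topology_pdb",
    "write_trajectory_pdb",
    "write_trajectory_csv",
    "packaged_fixture_path",
]

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_AA1 = set("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class Topology:
    """Atom table: serials, names, residue numbers/names, masses, elements."""

    serials: np.ndarray
    names: tuple[str, ...]
    resids: np.ndarray
    resnames: tuple[str, ...]
    masses: np.ndarray
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.serials)
        if not (len(self.names) == len(self.resids) == len(self.resnames)
                == len(self.masses) == len(self.elements) == n):
            raise ValueError("topology columns have inconsistent lengths")
        if n and len(np.unique(self.serials)) != n:
            raise FormatError("duplicate atom serials in topology")

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    @property
    def residue_numbers(self) -> np.ndarray:
        """Unique residue numbers in order of first appearance."""
        _, idx = np.unique(self.resids, return_index=True)
        return self.resids[np.sort(idx)]

    def atom_indices_for_residues(self, residues: Iterable[int]) -> np.ndarray:
        wanted = set(int(r) for r in residues)
        missing = wanted - set(int(r) for r in self.resids)
        if missing:
            raise ValueError(f"residues not present in topology: {sorted(missing)}")
        return np.flatnonzero(np.isin(self.resids, sorted(wanted)))

    def alpha_carbons(self) -> np.ndarray:
        """Indices of CA atoms (one per residue in the pseudo-atom fixtures)."""
        idx = np.flatnonzero(np.asarray(self.names) == "CA")
        if idx.size == 0:
            raise ValueError("topology has no CA atoms")
        return idx


@dataclass(frozen=True)
class Trajectory:
    """A topology plus an ordered stack of coordinate frames (Angstrom)."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    stride_ps: float = 10.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if c.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords atom count {c.shape[1]} != topology atom count "
                f"{self.topology.n_atoms}")
        if not np.all(np.isfinite(c)):
            raise FormatError("non-finite coordinates in trajectory")
        if self.stride_ps <= 0:
            raise ValueError("stride_ps must be positive")
        object.__setattr__(self, "coords", c)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.stride_ps


@dataclass(frozen=True)
class DomainMap:
    """Named, ordered, non-overlapping 1-based inclusive residue ranges.

    Residues of a bound topology that fall outside every range are labelled
    ``UNK`` (unknown domain origin).
    """

    protein: str
    entries: tuple[tuple[str, int, int], ...]
    offset: int = 0  # added to config residue numbers to match a renumbered topology

    UNK = "UNK"

    def __post_init__(self) -> None:
        seen: list[tuple[int, int, str]] = []
        for name, start, end in self.entries:
            if start > end:
                raise ValueError(f"domain {name}: start {start} > end {end}")
            seen.append((start, end, name))
        seen.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(seen, seen[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping domain ranges: {n1} ({s1}-{e1}) and {n2} ({s2}-{e2})")

    @property
    def domain_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.entries)

    def shifted(self) -> "DomainMap":
        if self.offset == 0:
            return self
        return replace(
            self,
            entries=tuple((n, s + self.offset, e + self.offset)
                          for n, s, e in self.entries),
            offset=0)

    def residues_of(self, domain: str) -> range:
        for name, start, end in self.shifted().entries:
            if name == domain:
                return range(start, end + 1)
        raise KeyError(f"no domain named {domain!r} in map for {self.protein}")

    def label_residues(self, residue_numbers: Iterable[int]) -> dict[int, str]:
        """Map each residue number to its domain name, or UNK."""
        labels: dict[int, str] = {}
        entries = self.shifted().entries
        for r in residue_numbers:
            r = int(r)
            labels[r] = self.UNK
            for name, start, end in entries:
                if start <= r <= end:
                    labels[r] = name
                    break
        return labels

    def validate_against(self, topology: Topology) -> None:
        present = set(int(r) for r in topology.resids)
        for name, start, end in self.shifted().entries:
            missing = set(range(start, end + 1)) - present
            if missing:
                raise ValueError(
                    f"domain {name} of {self.protein} references residues absent "
                    f"from the topology: {sorted(missing)[:5]}...")


@dataclass(frozen=True)
class Selection:
    """A named explicit residue-number list (e.g. a catalytic tetrad)."""

    name: str
    residues: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"selection {self.name!r} is empty")

    def atom_indices(self, topology: Topology) -> np.ndarray:
        return topology.atom_indices_for_residues(self.residues)


# ---------------------------------------------------------------------------
# PDB topology / trajectory reading

def _parse_atom_line(line: str, lineno: int) -> tuple:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    if icode:
        raise FormatError(
            f"insertion code {icode!r} at line {lineno}: insertion codes are not "
            "supported; renumber the structure first")
    return serial, name, resname, chain, resseq, (x, y, z), element


_ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                   "S": 32.06, "P": 30.974}


def read_topology(path: str | Path) -> Topology:
    """Parse the first model of a PDB file into a :class:`Topology`.

    Atoms are kept in file order with their written 1-based residue numbering.
    Multi-chain files are rejected (pre-split chains before analysis).
    """
    path = Path(path)
    serials, names, resids, resnames, masses, elements = [], [], [], [], [], []
    chains: set[str] = set()
    in_first_model = True
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            rec = line[:6]
            if rec == "ENDMDL":
                in_first_model = False
            if not in_first_model:
                continue
            if rec == "ATOM  ":
                serial, name, resname, chain, resseq, _, element = \
                    _parse_atom_line(line, lineno)
                chains.add(chain or "A")
                if not element:
                    element = name[:1]
                serials.append(serial)
                names.append(name)
                resids.append(resseq)
                resnames.append(resname)
                elements.append(element)
                masses.append(_ELEMENT_MASSES.get(element.upper(), 1.0))
    if not serials:
        raise FormatError(f"no ATOM records found in {path}")
    if len(chains) > 1:
        raise FormatError(
            f"multiple chains {sorted(chains)} in {path}: single-chain input is "
            "required; pre-split the file per chain")
    if len(set(serials)) != len(serials):
        raise FormatError(f"duplicate atom serials in {path}")
    return Topology(
        serials=np.asarray(serials, dtype=int),
        names=tuple(names),
        resids=np.asarray(resids, dtype=int),
        resnames=tuple(resnames),
        masses=np.asarray(masses, dtype=float),
        elements=tuple(elements),
    )


def _read_trajectory_pdb(path: Path, topology: Topology,
                         stride_ps: float) -> Trajectory:
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] = []
    saw_model = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                current = []
            elif rec == "ATOM  ":
                *_, xyz, _el = _parse_atom_line(line, lineno)
                current.append(xyz)
            elif rec == "ENDMDL":
                _check_frame(current, len(frames), topology)
                frames.append(np.asarray(current, dtype=float))
                current = []
    if not saw_model and current:
        _check_frame(current, 0, topology)
        frames.append(np.asarray(current, dtype=float))
    if not frames:
        raise FormatError(f"no frames found in {path}")
    return Trajectory(topology=topology, coords=np.stack(frames),
                      stride_ps=stride_ps)


def _check_frame(xyz: Sequence, frame_index: int, topology: Topology) -> None:
    if len(xyz) != topology.n_atoms:
        raise FormatError(
            f"frame {frame_index}: {len(xyz)} atoms, topology has "
            f"{topology.n_atoms} (truncated or mismatched input)")
    if not np.all(np.isfinite(np.asarray(xyz, dtype=float))):
        raise FormatError(f"frame {frame_index}: non-finite coordinate")


def _read_trajectory_csv(path: Path, topology: Topology,
                         stride_ps: float) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "atom_index", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"trajectory CSV must have columns {sorted(required)}, got "
            f"{list(df.columns)}")
    if df[["x", "y", "z"]].isna().any().any() or \
            not np.all(np.isfinite(df[["x", "y", "z"]].to_numpy())):
        bad = int(df.index[df[["x", "y", "z"]].isna().any(axis=1) |
                           ~np.isfinite(df[["x", "y", "z"]]).all(axis=1)][0])
        raise FormatError(f"non-finite coordinate in CSV row {bad}")
    frames = []
    for fidx, group in df.groupby("frame", sort=True):
        group = group.sort_values("atom_index")
        if len(group) != topology.n_atoms:
            raise FormatError(
                f"frame {fidx}: {len(group)} atoms, topology has "
                f"{topology.n_atoms}")
        frames.append(group[["x", "y", "z"]].to_numpy(dtype=float))
    if not frames:
        raise FormatError(f"no frames found in {path}")
    return Trajectory(topology=topology, coords=np.stack(frames),
                      stride_ps=stride_ps)


def read_trajectory(path: str | Path, topology: Topology,
                    stride_ps: float = 10.0) -> Trajectory:
    """Read a multi-model PDB or columnar CSV trajectory against a topology.

    Optional adapter: any other extension is handed to MDAnalysis when it is
    installed (binary MD formats), under the same atom-count contract.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        return _read_trajectory_pdb(path, topology, stride_ps)
    if suffix == ".csv":
        return _read_trajectory_csv(path, topology, stride_ps)
    return _read_trajectory_mdanalysis(path, topology, stride_ps)


def _read_trajectory_mdanalysis(path: Path, topology: Topology,
                                stride_ps: float) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            f"unsupported trajectory format {path.suffix!r}; install MDAnalysis "
            "for binary MD format support") from exc
    universe = mda.Universe.empty(topology.n_atoms, trajectory=True)
    universe.load_new(str(path))
    frames = np.stack([universe.trajectory.ts.positions.copy()
                       for _ in universe.trajectory])
    for i, frame in enumerate(frames):
        _check_frame(frame, i, topology)
    return Trajectory(topology=topology, coords=frames.astype(float),
                      stride_ps=stride_ps)


# ---------------------------------------------------------------------------
# PDB / CSV writing

def write_topology_pdb(trajectory_or_topology, path: str | Path,
                       frame: int = 0) -> Path:
    """Write a single-model PDB (ATOM records, chain A, 1-based resSeq)."""
    if isinstance(trajectory_or_topology, Trajectory):
        top = trajectory_or_topology.topology
        coords = trajectory_or_topology.coords[frame]
    else:
        top = trajectory_or_topology
        coords = np.zeros((top.n_atoms, 3))
    path = Path(path)
    with open(path, "w") as out:
        _write_atom_records(out, top, coords)
        out.write("END\n")
    return path


def _write_atom_records(out, top: Topology, coords: np.ndarray) -> None:
    for i in range(top.n_atoms):
        name = top.names[i]
        # PDB convention: 1-3 char names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name
        out.write(
            "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
            "{resseq:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}"
            "{occ:>6.2f}{b:>6.2f}          {elem:>2s}\n".format(
                serial=int(top.serials[i]), name=name_field, alt="",
                res=top.resnames[i][:3], chain="A",
                resseq=int(top.resids[i]), icode="",
                x=coords[i, 0], y=coords[i, 1], z=coords[i, 2],
                occ=1.00, b=0.00, elem=top.elements[i][:2]))


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> Path:
    """Write a multi-model PDB (MODEL/ENDMDL per frame)."""
    path = Path(path)
    with open(path, "w") as out:
        for f in range(traj.n_frames):
            out.write(f"MODEL     {f + 1:>4d}\n")
            _write_atom_records(out, traj.topology, traj.coords[f])
            out.write("ENDMDL\n")
        out.write("END\n")
    return path


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    """Write the documented CSV dialect: frame, atom_index, x, y, z (Angstrom).

    Full float precision, so a write/read round trip is bit-identical.
    """
    path = Path(path)
    n_frames, n_atoms, _ = traj.coords.shape
    frame_col = np.repeat(np.arange(n_frames), n_atoms)
    atom_col = np.tile(np.arange(n_atoms), n_frames)
    flat = traj.coords.reshape(-1, 3)
    df = pd.DataFrame({"frame": frame_col, "atom_index": atom_col,
                       "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]})
    df.to_csv(path, index=False, float_format="%.17e")
    return path


# ---------------------------------------------------------------------------
# Domain maps, FASTA, tables

def read_domain_map(path: str | Path) -> tuple[DomainMap, dict[str, Selection]]:
    """Load a JSON domain-map config.

    Schema: ``{"protein": str, "offset": int?, "domains": [{"name","start","end"}],
    "selections": [{"name","residues"}]}``.  Returns the map and any named
    selections.  Overlapping domain ranges raise a validation error.
    """
    with open(path) as handle:
        cfg = json.load(handle)
    if "protein" not in cfg or "domains" not in cfg:
        raise FormatError(f"domain map {path} must define 'protein' and 'domains'")
    entries = tuple((d["name"], int(d["start"]), int(d["end"]))
                    for d in cfg["domains"])
    dmap = DomainMap(protein=cfg["protein"], entries=entries,
                     offset=int(cfg.get("offset", 0)))
    selections = {
        s["name"]: Selection(name=s["name"],
                             residues=tuple(int(r) for r in s["residues"]))
        for s in cfg.get("selections", [])
    }
    return dmap, selections


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped, multi-record) FASTA file.

    Non-amino-acid symbols are kept verbatim with a warning.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    for rec_id, seq in records:
        unusual = set(seq.upper()) - _AA1 - {"X", "*", "-"}
        if unusual:
            warnings.warn(
                f"record {rec_id}: non-amino-acid symbols kept verbatim: "
                f"{sorted(unusual)}")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path,
                width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        for rec_id, seq in records:
            out.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")
    return path


def write_table(rows, path: str | Path, **to_csv_kwargs) -> Path:
    """Write rows (DataFrame or list of dicts) as CSV with a header row."""
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False, **to_csv_kwargs)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        json.dump(obj, out, indent=2, sort_keys=True)
        out.write("\n")
    return path


def read_json(path: str | Path):
    with open(path) as handle:
        return json.load(handle)


def packaged_fixture_path(name: str) -> Path:
    """Path of a packaged data fixture (e.g. ``ago2_domains.json``)."""
    p = Path(__file__).parent / "data" / name
    if not p.exists():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return p
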
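"""Synthetic multi-domain "pincer" trajectories and planted-segment sequences.

The generator emulates the statistical structure the downstream analysis
assumes, without any physics: K internally rigid domains, two of which (the
"jaws") oscillate between a closed and an open separation with a raised-cosine
profile, plus i.i.d. isotropic Gaussian fluctuation per residue with a
per-domain amplitude.  One pseudo-atom per residue (named CA, element C,
mass 1) keeps every topology round-trippable through PDB.

Frames are sampled at a fixed stride (default 10 ps, i.e. 100,000 frames per
microsecond); replicate trajectories share a spec and differ only in the noise
realization.  Identical spec + seed reproduces bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trajio import Topology, Trajectory

__all__ = [
    "PincerSpec",
    "PlantedSegmentSpec",
    "CANONICAL_DOMAIN_NAMES",
    "generate_pincer_trajectory",
    "generate_replicates",
    "plant_lcs_sequences",
    "AMINO_ACIDS",
]

#: Domain naming mirrors the Argonaute architecture the model emulates.
CANONICAL_DOMAIN_NAMES = ("N", "L1", "PAZ", "L2", "MID", "PIWI")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class SpecValidationError(ValueError):
    """A generator spec field violates its invariant."""


@dataclass(frozen=True)
class PincerSpec:
    """Parameters of the synthetic pincer system.

    The jaw-pair center-of-mass separation before noise is
    ``closed_distance + amplitude * (1 - cos(2*pi*(t - phase)/period))``,
    so it sweeps [closed_distance, closed_distance + 2*amplitude]: with the
    defaults the jaws open from 30 to 55 Angstrom, the >50 Angstrom jaw
    excursion regime seen in Argonaute-scale pincer motion.
    """

    n_domains: int = 6
    residues_per_domain: int = 25
    jaw_pair: tuple[str, str] = ("PAZ", "MID")
    closed_distance: float = 30.0      # Angstrom
    amplitude: float = 12.5            # Angstrom, half peak-to-trough
    period: int = 20_000               # frames
    phase: int = 0                     # frames
    fluctuation_sigma: Mapping[str, float] | float = 0.5  # Angstrom per axis
    n_frames: int = 100_000
    stride_ps: float = 10.0
    seed: int = 0
    domain_names: tuple[str, ...] | None = None

    def resolved_domain_names(self) -> tuple[str, ...]:
        if self.domain_names is not None:
            return self.domain_names
        if self.n_domains <= len(CANONICAL_DOMAIN_NAMES):
            return CANONICAL_DOMAIN_NAMES[:self.n_domains]
        extra = tuple(f"D{i + 1}" for i in
                      range(len(CANONICAL_DOMAIN_NAMES), self.n_domains))
        return CANONICAL_DOMAIN_NAMES + extra

    def sigma_for(self, domain: str) -> float:
        if isinstance(self.fluctuation_sigma, Mapping):
            return float(self.fluctuation_sigma.get(domain, 0.0))
        return float(self.fluctuation_sigma)

    def validate(self) -> None:
        names = self.resolved_domain_names()
        if self.n_domains < 2:
            raise SpecValidationError("n_domains: need at least 2 domains")
        if len(names) != self.n_domains or len(set(names)) != self.n_domains:
            raise SpecValidationError("domain_names: must be n_domains unique names")
        if self.residues_per_domain < 1:
            raise SpecValidationError("residues_per_domain: must be >= 1")
        if self.amplitude < 0:
            raise SpecValidationError("amplitude: must be >= 0")
        if self.period < 2:
            raise SpecValidationError("period: must be >= 2")
        if self.n_frames < 1:
            raise SpecValidationError("n_frames: must be >= 1")
        if self.stride_ps <= 0:
            raise SpecValidationError("stride_ps: must be > 0")
        for jaw in self.jaw_pair:
            if jaw not in names:
                raise SpecValidationError(
                    f"jaw_pair: {jaw!r} is not a domain name {names}")
        if self.jaw_pair[0] == self.jaw_pair[1]:
            raise SpecValidationError("jaw_pair: the two jaws must differ")
        for d in names:
            if self.sigma_for(d) < 0:
                raise SpecValidationError(
                    f"fluctuation_sigma: sigma for {d} must be >= 0")


def _local_lattice(n_residues: int, spacing: float = 3.8) -> np.ndarray:
    """Fixed zero-mean residue offsets on a cubic lattice (rigid domain body)."""
    side = int(np.ceil(n_residues ** (1 / 3)))
    idx = np.arange(n_residues)
    grid = np.stack([idx % side, (idx // side) % side, idx // side ** 2], axis=1)
    offsets = grid.astype(float) * spacing
    return offsets - offsets.mean(axis=0)


def _domain_anchor_positions(spec: PincerSpec) -> dict[str, np.ndarray]:
    """Static COM anchors; only the second jaw moves away from its anchor."""
    names = spec.resolved_domain_names()
    jaw_a, jaw_b = spec.jaw_pair
    anchors: dict[str, np.ndarray] = {jaw_a: np.zeros(3)}
    # remaining domains sit on a circle in the y-z plane around the fixed jaw,
    # far enough apart that per-domain COM distances are unambiguous
    others = [n for n in names if n != jaw_a and n != jaw_b]
    radius = 45.0
    for i, name in enumerate(others):
        angle = 2 * np.pi * i / max(len(others), 1)
        anchors[name] = np.array(
            [0.0, radius * np.cos(angle), radius * np.sin(angle)])
    anchors[jaw_b] = np.zeros(3)  # displaced along +x by the jaw separation
    return anchors


def jaw_separation_profile(spec: PincerSpec) -> np.ndarray:
    """Noise-free jaw COM separation per frame (Angstrom)."""
    t = np.arange(spec.n_frames)
    return spec.closed_distance + spec.amplitude * (
        1.0 - np.cos(2.0 * np.pi * (t - spec.phase) / spec.period))


def _build_topology(spec: PincerSpec) -> Topology:
    names = spec.resolved_domain_names()
    n_atoms = spec.n_domains * spec.residues_per_domain
    return Topology(
        serials=np.arange(1, n_atoms + 1),
        names=("CA",) * n_atoms,
        resids=np.arange(1, n_atoms + 1),
        resnames=("GLY",) * n_atoms,
        masses=np.ones(n_atoms),
        elements=("C",) * n_atoms,
    )


def domain_map_for(spec: PincerSpec):
    """The DomainMap matching :func:`generate_pincer_trajectory`'s topology."""
    from .trajio import DomainMap
    names = spec.resolved_domain_names()
    entries = []
    start = 1
    for name in names:
        end = start + spec.residues_per_domain - 1
        entries.append((name, start, end))
        start = end + 1
    return DomainMap(protein="synthetic", entries=tuple(entries))


def generate_pincer_trajectory(spec: PincerSpec) -> Trajectory:
    """Generate one synthetic trajectory from a validated spec.

    Residues of each domain ride rigidly on their domain COM; the second jaw's
    COM is displaced along +x by the raised-cosine separation profile; i.i.d.
    Gaussian noise of the domain's sigma is then added independently per
    residue, axis and frame.
    """
    spec.validate()
    names = spec.resolved_domain_names()
    rng = np.random.default_rng(spec.seed)
    lattice = _local_lattice(spec.residues_per_domain)
    anchors = _domain_anchor_positions(spec)
    separation = jaw_separation_profile(spec)

    n_atoms = spec.n_domains * spec.residues_per_domain
    coords = np.empty((spec.n_frames, n_atoms, 3))
    jaw_b = spec.jaw_pair[1]
    for d, name in enumerate(names):
        sl = slice(d * spec.residues_per_domain, (d + 1) * spec.residues_per_domain)
        base = anchors[name] + lattice  # (R, 3)
        coords[:, sl, :] = base[None, :, :]
        if name == jaw_b:
            coords[:, sl, 0] += separation[:, None]
    for d, name in enumerate(names):
        sigma = spec.sigma_for(name)
        sl = slice(d * spec.residues_per_domain, (d + 1) * spec.residues_per_domain)
        noise = rng.standard_normal((spec.n_frames, spec.residues_per_domain, 3))
        if sigma > 0:
            coords[:, sl, :] += sigma * noise
        # sigma == 0 still consumes the draw so per-domain noise streams are
        # stable when a single sigma is toggled
    return Trajectory(topology=_build_topology(spec), coords=coords,
                      stride_ps=spec.stride_ps)


def generate_replicates(spec: PincerSpec, n: int,
                        seeds: Sequence[int]) -> list[Trajectory]:
    """n independent trajectories sharing a spec, differing only in noise."""
    if n != len(seeds):
        raise SpecValidationError(f"n={n} but {len(seeds)} seeds given")
    if len(set(seeds)) != len(seeds):
        raise SpecValidationError("seeds must be distinct")
    return [generate_pincer_trajectory(dataclasses.replace(spec, seed=int(s)))
            for s in seeds]


# ---------------------------------------------------------------------------
# Planted-segment sequences (fixture generator for the common-segment stage)

@dataclass(frozen=True)
class PlantedSegmentSpec:
    """k random sequences with one common segment planted at known positions."""

    alphabet: str = AMINO_ACIDS
    k: int = 4
    lengths: tuple[int, ...] = (400, 400, 400, 400)
    segment: str = ""
    positions: tuple[int, ...] = ()   # 1-based insert positions
    seed: int = 0

    def validate(self) -> None:
        if not self.segment:
            raise SpecValidationError("segment: must be non-empty")
        if set(self.segment) - set(self.alphabet):
            raise SpecValidationError("segment: contains symbols outside alphabet")
        if self.k < 2:
            raise SpecValidationError("k: need at least 2 sequences")
        if len(self.lengths) != self.k or len(self.positions) != self.k:
            raise SpecValidationError(
                "lengths/positions: must each have exactly k entries")
        for i, (length, pos) in enumerate(zip(self.lengths, self.positions)):
            if len(self.segment) > length:
                raise SpecValidationError(
                    f"segment longer than sequence {i} (len {length})")
            if pos < 1 or pos + len(self.segment) - 1 > length:
                raise SpecValidationError(
                    f"positions: segment does not fit in sequence {i} at {pos}")


def plant_lcs_sequences(spec: PlantedSegmentSpec) -> list[str]:
    """Uniform-background sequences with the segment planted verbatim."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(spec.alphabet))
    sequences = []
    for length, pos in zip(spec.lengths, spec.positions):
        chars = alphabet[rng.integers(0, len(alphabet), size=length)]
        seq = list("".join(chars))
        seq[pos - 1: pos - 1 + len(spec.segment)] = list(spec.segment)
        sequences.append("".join(seq))
    return sequences
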
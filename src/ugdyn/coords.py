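"""Inter-domain conformational coordinates for multi-domain proteins.

The three coordinates describe the dominant rigid-body motions of the
UGGT misfold-sensing arc:

* **CC1 "clamping"** (Angstrom): distance between the TRXL1 and TRXL3
  domain centers — the openness of the cleft between them.
* **CC2 "bending"** (degrees): angle at the TRXL2 center formed by the
  TRXL1, TRXL2, TRXL3 centers — tracks TRXL2 bending toward the
  GT24/beta-sandwich core across the central saddle.
* **CC3 "twisting"** (degrees): signed torsion of four Calpha atoms, two
  in TRXL2 and two in TRXL3 (Y518, F466, T863, I735 in CtUGGT author
  numbering) — the relative orientation of the TRXL2/TRXL3 pair.

Domain centers default to the geometric center of Calpha atoms.  Crystal
structures routinely lack loops inside a domain range; whatever atoms are
present are used and the count is reported, so coordinates stay
comparable across gapped models.  A mass-weighted heavy-atom mode is
provided for sensitivity checks against the center-of-mass convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geom import angle_deg, dihedral_deg, mass_of
from .errors import MissingResidueError, SelectionError
from .structures import Structure, Trajectory

__all__ = [
    "DomainScheme",
    "ConformationalCoordinates",
    "CT_UGGT_SCHEME",
    "domain_center",
    "clamping_cc1",
    "bending_cc2",
    "twisting_cc3",
    "ccs_for_structure",
    "ccs_for_trajectory",
]


@dataclass(frozen=True)
class DomainScheme:
    """Named residue-range sets (author numbering, inclusive) defining the
    domains, plus the ordered Calpha quadruple whose torsion is CC3."""

    domains: dict[str, tuple[tuple[int, int], ...]]
    cc3_quad: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for name, ranges in self.domains.items():
            spans = sorted(ranges)
            for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ValueError(f"domain {name}: overlapping ranges "
                                     f"{(lo1, hi1)} and {(lo2, hi2)}")
            for lo, hi in spans:
                if hi < lo:
                    raise ValueError(f"domain {name}: empty range {(lo, hi)}")
        if len(set(self.cc3_quad)) != 4:
            raise ValueError("cc3_quad must name 4 distinct residues")

    @classmethod
    def from_json(cls, path: str | Path) -> "DomainScheme":
        data = json.loads(Path(path).read_text())
        domains = {k: tuple((int(lo), int(hi)) for lo, hi in v)
                   for k, v in data["domains"].items()}
        return cls(domains=domains, cc3_quad=tuple(int(r) for r in data["cc3_quad"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"domains": {k: [list(r) for r in v] for k, v in self.domains.items()},
             "cc3_quad": list(self.cc3_quad)}, indent=2))


#: The CtUGGT seven-domain scheme (author numbering) and the twisting quad.
CT_UGGT_SCHEME = DomainScheme(
    domains={
        "TRXL1": ((45, 220),),
        "TRXL2": ((414, 656),),
        "TRXL3": ((667, 880),),
        "TRXL4": ((275, 410), (897, 950)),
        "bS1": ((28, 36), (225, 242), (957, 1037)),
        "bS2": ((1039, 1149),),
        "GT24": ((1197, 1475),),
    },
    cc3_quad=(518, 466, 863, 735),
)


@dataclass
class ConformationalCoordinates:
    """One conformer's coordinate triple.  A coordinate is None when the
    structure cannot support it (e.g. a deleted domain or an unresolved
    quad residue); ``n_atoms_used`` records how many atoms entered each
    domain center."""

    cc1: float | None
    cc2: float | None
    cc3: float | None
    n_atoms_used: dict[str, int] = field(default_factory=dict)

    def as_tuple(self) -> tuple[float | None, float | None, float | None]:
        return (self.cc1, self.cc2, self.cc3)


def _domain_atoms(structure: Structure, chain: str, domain_name: str,
                  scheme: DomainScheme, atom_mode: str):
    try:
        ranges = scheme.domains[domain_name]
    except KeyError:
        raise SelectionError(f"scheme has no domain named {domain_name!r}") from None
    names = {"CA"} if atom_mode == "calpha" else None
    atoms = structure.select(chain=chain, residues=ranges, atom_names=names,
                             include_het=False)
    if atom_mode == "heavy":
        atoms = [a for a in atoms if a.element.upper() != "H"]
    return atoms


def domain_center(
    structure: Structure, chain: str, domain_name: str,
    scheme: DomainScheme = CT_UGGT_SCHEME,
    atom_mode: str = "calpha", weighting: str = "geometric",
) -> np.ndarray:
    """Centroid of the domain's selected atoms (mass-weighted when
    ``weighting='mass'``).  Missing residues silently reduce the set."""
    center, _ = _domain_center_info(structure, chain, domain_name, scheme,
                                    atom_mode, weighting)
    return center


def _domain_center_info(structure, chain, domain_name, scheme,
                        atom_mode="calpha", weighting="geometric"):
    atoms = _domain_atoms(structure, chain, domain_name, scheme, atom_mode)
    if not atoms:
        raise SelectionError(
            f"domain {domain_name!r} has no selected atoms in chain {chain!r}"
        )
    xyz = np.array([a.coords for a in atoms])
    if weighting == "mass":
        w = np.array([mass_of(a.element) for a in atoms])
    elif weighting == "geometric":
        w = np.ones(len(atoms))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return np.average(xyz, axis=0, weights=w), len(atoms)


def clamping_cc1(structure: Structure, chain: str,
                 scheme: DomainScheme = CT_UGGT_SCHEME,
                 atom_mode: str = "calpha", weighting: str = "geometric") -> float:
    """Distance (Angstrom) between the TRXL1 and TRXL3 domain centers."""
    c1 = domain_center(structure, chain, "TRXL1", scheme, atom_mode, weighting)
    c3 = domain_center(structure, chain, "TRXL3", scheme, atom_mode, weighting)
    return float(np.linalg.norm(c1 - c3))


def bending_cc2(structure: Structure, chain: str,
                scheme: DomainScheme = CT_UGGT_SCHEME,
                atom_mode: str = "calpha", weighting: str = "geometric") -> float:
    """Angle (degrees, [0, 180]) at the TRXL2 center formed by the TRXL1,
    TRXL2, TRXL3 domain centers."""
    c1 = domain_center(structure, chain, "TRXL1", scheme, atom_mode, weighting)
    c2 = domain_center(structure, chain, "TRXL2", scheme, atom_mode, weighting)
    c3 = domain_center(structure, chain, "TRXL3", scheme, atom_mode, weighting)
    return angle_deg(c1, c2, c3)


def twisting_cc3(structure: Structure, chain: str,
                 scheme: DomainScheme = CT_UGGT_SCHEME) -> float:
    """Signed torsion (degrees, (-180, 180]) of the scheme's four quad
    Calpha atoms taken in order."""
    points = []
    for resnum in scheme.cc3_quad:
        cas = structure.select(chain=chain, residues=[resnum],
                               atom_names={"CA"}, include_het=False)
        if not cas:
            raise MissingResidueError(
                f"quad residue {resnum} has no Calpha in chain {chain!r} "
                f"of {structure.entry_id or 'structure'}"
            )
        points.append(cas[0].coords)
    return dihedral_deg(*points)


def ccs_for_structure(structure: Structure, chain: str | None = None,
                      scheme: DomainScheme = CT_UGGT_SCHEME,
                      atom_mode: str = "calpha",
                      weighting: str = "geometric") -> ConformationalCoordinates:
    """All three coordinates for one conformer.  Coordinates whose atoms
    are absent (deleted domains, unresolved quad residues) come back as
    None instead of raising."""
    if chain is None:
        chain = structure.first_protein_chain
    counts: dict[str, int] = {}
    centers: dict[str, np.ndarray] = {}
    for name in ("TRXL1", "TRXL2", "TRXL3"):
        try:
            centers[name], counts[name] = _domain_center_info(
                structure, chain, name, scheme, atom_mode, weighting)
        except SelectionError:
            counts[name] = 0
    cc1 = cc2 = cc3 = None
    if counts["TRXL1"] and counts["TRXL3"]:
        cc1 = float(np.linalg.norm(centers["TRXL1"] - centers["TRXL3"]))
    if counts["TRXL1"] and counts["TRXL2"] and counts["TRXL3"]:
        cc2 = angle_deg(centers["TRXL1"], centers["TRXL2"], centers["TRXL3"])
    try:
        cc3 = twisting_cc3(structure, chain, scheme)
    except MissingResidueError:
        cc3 = None
    return ConformationalCoordinates(cc1=cc1, cc2=cc2, cc3=cc3, n_atoms_used=counts)


def ccs_for_trajectory(trajectory: Trajectory, chain: str | None = None,
                       scheme: DomainScheme = CT_UGGT_SCHEME,
                       atom_mode: str = "calpha",
                       weighting: str = "geometric") -> list[ConformationalCoordinates]:
    """Per-frame coordinate records, frame order preserved."""
    topo = trajectory.topology
    if chain is None:
        chain = topo.first_protein_chain

    # resolve selections once against the topology, then reuse per frame
    domain_idx: dict[str, np.ndarray] = {}
    id_of = {id(a): i for i, a in enumerate(topo.atoms)}
    for name in ("TRXL1", "TRXL2", "TRXL3"):
        atoms = _domain_atoms(topo, chain, name, scheme, atom_mode)
        domain_idx[name] = np.array([id_of[id(a)] for a in atoms], dtype=int)
    quad_idx = []
    for resnum in scheme.cc3_quad:
        cas = topo.select(chain=chain, residues=[resnum], atom_names={"CA"},
                          include_het=False)
        quad_idx.append(id_of[id(cas[0])] if cas else -1)
    if weighting == "mass":
        weights = {n: np.array([mass_of(topo.atoms[i].element) for i in idx])
                   for n, idx in domain_idx.items()}
    else:
        weights = {n: np.ones(len(idx)) for n, idx in domain_idx.items()}

    out = []
    for frame in trajectory.frames:
        centers = {}
        counts = {}
        for name, idx in domain_idx.items():
            counts[name] = len(idx)
            if len(idx):
                centers[name] = np.average(frame[idx], axis=0, weights=weights[name])
        cc1 = cc2 = cc3 = None
        if counts["TRXL1"] and counts["TRXL3"]:
            cc1 = float(np.linalg.norm(centers["TRXL1"] - centers["TRXL3"]))
        if counts["TRXL1"] and counts["TRXL2"] and counts["TRXL3"]:
            cc2 = angle_deg(centers["TRXL1"], centers["TRXL2"], centers["TRXL3"])
        if all(i >= 0 for i in quad_idx):
            cc3 = dihedral_deg(*(frame[i] for i in quad_idx))
        out.append(ConformationalCoordinates(cc1, cc2, cc3, counts))
    return out
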
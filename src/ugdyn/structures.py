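"""Structure and trajectory containers, file I/O, and glycosylation-site
detection.

Structures are read with gemmi (PDB and mmCIF); trajectories come either
from multi-model PDB files (gemmi) or from DCD/XTC coordinate files paired
with a topology structure (MDAnalysis).  All geometry downstream is
heavy-atom or Calpha based: hydrogens are dropped at parse time, and
alternate locations are resolved to the blank/'A' conformer.  Residue
insertion codes are rejected rather than silently renumbered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AtomCountMismatchError,
    FormatError,
    ParseError,
    SelectionError,
)

__all__ = [
    "Atom",
    "Structure",
    "GlycosylationSite",
    "Trajectory",
    "DEFAULT_GLYCAN_RESIDUES",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "detect_glycosylation_sites",
    "sequence_coverage",
    "write_site_table",
    "read_site_table",
]

#: Chemical-component names accepted as glycan sugars when looking for the
#: covalent ASN(ND2)-C1 attachment.  PDB component naming has drifted over
#: the years, so the set is an argument everywhere it is used.
DEFAULT_GLYCAN_RESIDUES = frozenset(
    {"NAG", "NDG", "BMA", "MAN", "FUC", "FUL", "GAL", "GLA", "GLC", "BGC",
     "SIA", "SLB", "XYS", "XYP"}
)


@dataclass
class Atom:
    """One atom: element, PDB atom name, Cartesian coordinates in Angstrom,
    author residue numbering, 3-letter residue name, chain id, HETATM flag."""

    element: str
    name: str
    coords: np.ndarray
    residue_number: int
    residue_name: str
    chain_id: str
    is_heteroatom: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name} has non-finite or malformed coordinates")


@dataclass(frozen=True, order=True)
class GlycosylationSite:
    """An N-glycosylated residue.  ``evidence`` records how the site was
    established: a covalent link record in the file, the ND2-C1 distance
    heuristic, or a declaration (synthetic fixtures)."""

    chain_id: str
    residue_number: int
    evidence: str = "declared"  # covalent_link_record | distance_heuristic | declared


class Structure:
    """An ordered list of atoms plus light residue/chain indexing.

    ``sequence_lengths`` maps chain id to the full primary-sequence length
    (needed for coverage computation; optional).  ``links`` holds covalent
    connection records as ((chain, resnum, atom), (chain, resnum, atom))
    pairs when the source file declared them.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        entry_id: str = "",
        sequence_lengths: dict[str, int] | None = None,
        links: Sequence[tuple[tuple[str, int, str], tuple[str, int, str]]] = (),
    ):
        self.atoms: list[Atom] = list(atoms)
        self.entry_id = entry_id
        self.sequence_lengths = dict(sequence_lengths or {})
        self.links = list(links)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def first_protein_chain(self) -> str:
        for a in self.atoms:
            if not a.is_heteroatom:
                return a.chain_id
        raise SelectionError(f"{self.entry_id or 'structure'}: no protein atoms")

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with every atom's coordinates replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise AtomCountMismatchError(
                f"coordinate array has {coords.shape[0]} rows for {len(self.atoms)} atoms"
            )
        atoms = [
            Atom(a.element, a.name, c, a.residue_number, a.residue_name,
                 a.chain_id, a.is_heteroatom)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, self.entry_id, self.sequence_lengths, self.links)

    def select(
        self,
        chain: str | None = None,
        residues: Iterable[tuple[int, int]] | Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
        include_het: bool = True,
    ) -> list[Atom]:
        """Deterministic selection by chain, residue ranges/numbers and
        atom-name set.  ``residues`` accepts inclusive (lo, hi) pairs or
        plain residue numbers."""
        resnums: set[int] | None = None
        ranges: list[tuple[int, int]] = []
        if residues is not None:
            resnums = set()
            for r in residues:
                if isinstance(r, tuple):
                    ranges.append(r)
                else:
                    resnums.add(int(r))
        names = set(atom_names) if atom_names is not None else None
        out = []
        for a in self.atoms:
            if chain is not None and a.chain_id != chain:
                continue
            if not include_het and a.is_heteroatom:
                continue
            if names is not None and a.name not in names:
                continue
            if resnums is not None:
                n = a.residue_number
                if n not in resnums and not any(lo <= n <= hi for lo, hi in ranges):
                    continue
            out.append(a)
        return out

    def residue_numbers(self, chain: str, include_het: bool = False) -> list[int]:
        """Distinct residue numbers in a chain, in order of first appearance."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain_id == chain and (include_het or not a.is_heteroatom):
                seen.setdefault(a.residue_number, None)
        return list(seen)

    def residue_atoms(self, chain: str, residue_number: int) -> list[Atom]:
        return [a for a in self.atoms
                if a.chain_id == chain and a.residue_number == residue_number]


@dataclass
class Trajectory:
    """A topology structure plus one coordinate array per frame.

    Every frame row count must equal the topology atom count.  Source
    labels (which run a frame came from) survive fusion for plotting.
    """

    topology: Structure
    frames: list[np.ndarray] = field(default_factory=list)
    frame_times: np.ndarray | None = None  # ns
    source_labels: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.topology)
        checked = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise AtomCountMismatchError(
                    f"frame {i} has {f.shape[0]} atoms but topology has {n}"
                )
            checked.append(f)
        self.frames = checked

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def at_frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def coords_3d(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) array."""
        return np.array(self.frames, dtype=float)


# ---------------------------------------------------------------------------
# reading / writing

_STRUCTURE_FORMATS = {"pdb", "mmcif", "cif"}


def _guess_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    return {"cif": "mmcif", "mmcif": "mmcif", "pdb": "pdb", "ent": "pdb"}.get(suffix, suffix)


def _from_gemmi_model(model, entry_id: str, links) -> Structure:
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise ParseError(
                    f"{entry_id}: residue {chain.name}/{res.seqid.num}{res.seqid.icode} "
                    "carries an insertion code; renumber the file first"
                )
            is_het = res.het_flag == "H"
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                if atom.altloc not in ("", "A", "\x00"):
                    continue  # keep blank/'A' conformer only
                atoms.append(
                    Atom(
                        element=atom.element.name,
                        name=atom.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain.name,
                        is_heteroatom=is_het,
                    )
                )
    return Structure(atoms, entry_id=entry_id, links=links)


def _gemmi_links(st) -> list[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    links = []
    for con in st.connections:
        try:
            a = (con.partner1.chain_name, con.partner1.res_id.seqid.num,
                 con.partner1.atom_name)
            b = (con.partner2.chain_name, con.partner2.res_id.seqid.num,
                 con.partner2.atom_name)
        except Exception:  # pragma: no cover - malformed connection record
            continue
        links.append((a, b))
    return links


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure` (first model,
    single conformer, hydrogens dropped)."""
    import gemmi

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format or _guess_format(path)
    if fmt not in _STRUCTURE_FORMATS:
        raise FormatError(f"unsupported structure format {fmt!r} (use pdb or mmcif)")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: file contains no model")
    st.setup_entities()
    entry_id = st.name or path.stem
    return _from_gemmi_model(st[0], entry_id, _gemmi_links(st))


def _to_gemmi(structure: Structure, models: Sequence[np.ndarray] | None = None):
    import gemmi

    st = gemmi.Structure()
    st.name = structure.entry_id or "ugdyn"
    frame_list = models if models is not None else [None]
    for mi, frame in enumerate(frame_list):
        model = gemmi.Model(mi + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        res_map: dict[tuple[str, int], gemmi.Residue] = {}
        for ai, a in enumerate(structure.atoms):
            xyz = a.coords if frame is None else frame[ai]
            if np.any(np.asarray(xyz) > 9999.999) or np.any(np.asarray(xyz) < -999.999):
                raise FormatError(
                    f"coordinate {xyz} exceeds the fixed-width PDB field"
                )
            ch = chain_map.get(a.chain_id)
            if ch is None:
                model.add_chain(gemmi.Chain(a.chain_id))
                ch = model[a.chain_id]
                chain_map[a.chain_id] = ch
            key = (a.chain_id, a.residue_number)
            res = res_map.get(key)
            if res is None or res.name != a.residue_name:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                res.het_flag = "H" if a.is_heteroatom else "A"
                ch.add_residue(res)
                res = ch[-1]
                res_map[key] = res
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*map(float, xyz))
            at.occ = 1.0
            res.add_atom(at)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write a structure as standard PDB text (coordinates to 3 decimals,
    TER records between chains)."""
    if len(structure) == 0:
        raise ValueError("refusing to write an empty structure")
    if format != "pdb":
        raise FormatError(f"unsupported output format {format!r} (only pdb)")
    st = _to_gemmi(structure)
    st.write_pdb(str(path))


_TRAJ_FORMATS = {"multi_model_pdb", "dcd", "xtc"}


def read_trajectory(
    topology_path: str | Path,
    coords_path: str | Path | None = None,
    format: str | None = None,
) -> Trajectory:
    """Read a trajectory from a multi-model PDB, or from a DCD/XTC
    coordinate file paired with a PDB/mmCIF topology."""
    import gemmi

    if format is None:
        format = ("multi_model_pdb" if coords_path is None
                  else _guess_format(coords_path))
        if format in ("pdb", "mmcif"):
            format = "multi_model_pdb"
    if format not in _TRAJ_FORMATS:
        raise FormatError(f"unsupported trajectory format {format!r}")

    if format == "multi_model_pdb":
        path = Path(coords_path or topology_path)
        try:
            st = gemmi.read_structure(str(path))
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        if len(st) == 0:
            raise ParseError(f"{path}: no models found")
        topo = _from_gemmi_model(st[0], st.name or path.stem, _gemmi_links(st))
        frames = []
        for model in st:
            xyz = []
            for chain in model:
                for res in chain:
                    for atom in res:
                        if atom.element.is_hydrogen:
                            continue
                        if atom.altloc not in ("", "A", "\x00"):
                            continue
                        xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if len(xyz) != len(topo):
                raise AtomCountMismatchError(
                    f"model {model.num} has {len(xyz)} atoms, topology has {len(topo)}"
                )
            frames.append(np.array(xyz))
        return Trajectory(topo, frames)

    # DCD / XTC via MDAnalysis
    import MDAnalysis as mda

    topo = read_structure(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path), str(coords_path))
    if len(u.atoms) != len(topo):
        raise AtomCountMismatchError(
            f"coordinate file has {len(u.atoms)} atoms, topology has {len(topo)}"
        )
    frames = [np.array(ts.positions, dtype=float) for ts in u.trajectory]
    times = np.array([ts.time for ts in u.trajectory], dtype=float) / 1000.0  # ps -> ns
    return Trajectory(topo, frames, frame_times=times)


def write_trajectory(
    trajectory: Trajectory, topology_path: str | Path,
    coords_path: str | Path | None = None, format: str = "multi_model_pdb",
) -> None:
    """Write a trajectory.  ``multi_model_pdb`` writes one file (pass the
    same path twice or leave coords_path None); DCD/XTC write the topology
    as PDB plus a binary coordinate file."""
    if format not in _TRAJ_FORMATS:
        raise FormatError(f"unsupported trajectory format {format!r}")
    if format == "multi_model_pdb":
        st = _to_gemmi(trajectory.topology, models=trajectory.frames)
        st.write_pdb(str(coords_path or topology_path))
        return

    import MDAnalysis as mda

    write_structure(trajectory.topology, topology_path)
    n = len(trajectory.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path))
        with mda.Writer(str(coords_path), n_atoms=n) as w:
            for frame in trajectory.frames:
                u.atoms.positions = frame
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# glycosylation sites & coverage


def detect_glycosylation_sites(
    structure: Structure,
    max_bond: float = 2.0,
    glycan_residues: Iterable[str] = DEFAULT_GLYCAN_RESIDUES,
) -> list[GlycosylationSite]:
    """Find N-glycosylated asparagines.

    A site is an ASN whose ND2 atom lies within ``max_bond`` Angstrom of
    the C1 atom of a glycan sugar residue, or one named in a covalent link
    record connecting ND2 to a sugar C1.  Results are deduplicated and
    sorted by (chain, residue)."""
    glycan_residues = set(glycan_residues)
    sugar_c1 = [a for a in structure.atoms
                if a.is_heteroatom and a.residue_name in glycan_residues
                and a.name == "C1"]
    sugar_keys = {(a.chain_id, a.residue_number) for a in sugar_c1}

    found: dict[tuple[str, int], str] = {}

    # covalent link records take precedence
    for a, b in structure.links:
        for asn_side, sugar_side in ((a, b), (b, a)):
            if asn_side[2] != "ND2" or sugar_side[2] != "C1":
                continue
            if (sugar_side[0], sugar_side[1]) not in sugar_keys:
                continue
            res = structure.residue_atoms(asn_side[0], asn_side[1])
            if res and res[0].residue_name == "ASN":
                found[(asn_side[0], asn_side[1])] = "covalent_link_record"

    if sugar_c1:
        c1_xyz = np.array([a.coords for a in sugar_c1])
        for a in structure.atoms:
            if a.is_heteroatom or a.residue_name != "ASN" or a.name != "ND2":
                continue
            key = (a.chain_id, a.residue_number)
            if key in found:
                continue
            d = np.linalg.norm(c1_xyz - a.coords, axis=1)
            if np.any(d <= max_bond):
                found[key] = "distance_heuristic"

    return sorted(
        GlycosylationSite(chain_id=c, residue_number=r, evidence=e)
        for (c, r), e in found.items()
    )


def sequence_coverage(structure: Structure, chain_id: str) -> float:
    """Fraction of the chain's primary sequence with at least one resolved
    atom.  Requires ``structure.sequence_lengths[chain_id]``."""
    length = structure.sequence_lengths.get(chain_id)
    if not length:
        raise SelectionError(
            f"{structure.entry_id or 'structure'}: sequence length for chain "
            f"{chain_id!r} is unknown; set structure.sequence_lengths[{chain_id!r}]"
        )
    resolved = len(structure.residue_numbers(chain_id, include_het=False))
    return resolved / length


def write_site_table(sites, entry_id: str, path: str | Path) -> None:
    """TSV site list: entry_id, chain, resnum, evidence."""
    import pandas as pd

    pd.DataFrame(
        [(entry_id, s.chain_id, s.residue_number, s.evidence) for s in sites],
        columns=["entry_id", "chain", "resnum", "evidence"],
    ).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[GlycosylationSite]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [GlycosylationSite(str(r.chain), int(r.resnum), str(r.evidence))
            for r in df.itertuples()]
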
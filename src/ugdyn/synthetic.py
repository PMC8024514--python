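"""Seeded synthetic structures, trajectories and glycoprotein cohorts.

Every generator places pseudo-atoms (Calpha of ALA, so all production
Calpha selections work unmodified) with *exact* known geometry and then
optionally adds noise, so noise-free recovery tests are exact and noisy
recovery is a statistical test.  Each generator returns machine-readable
ground truth alongside the structure; downstream tests consume only the
structures plus the truth, never generator internals.

The conformer builder realises a requested (cc1, cc2, cc3) triple
exactly at the Calpha-geometric-center convention: domain centers are
placed to satisfy the clamp distance and bend angle, the four twisting
quad atoms are placed to realise the requested torsion, and the remaining
atoms of each domain blob are shifted so every domain centroid is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coords import CT_UGGT_SCHEME, ConformationalCoordinates, DomainScheme
from .reach import CohortEntry
from .structures import Atom, GlycosylationSite, Structure, Trajectory

__all__ = [
    "GeneratorSpec",
    "make_conformer",
    "make_cc_trajectory",
    "make_mode_trajectory",
    "make_glycoprotein",
    "make_cohort",
    "GlycoproteinFixture",
]


@dataclass
class GeneratorSpec:
    """Serialisable description of a generator run (used by the CLI).
    Identical specs produce bit-identical output."""

    kind: str                     # conformer | trajectory | cohort
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorSpec":
        data = json.loads(Path(path).read_text())
        return cls(kind=data["kind"], seed=int(data.get("seed", 0)),
                   params=dict(data.get("params", {})))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"kind": self.kind, "seed": self.seed, "params": self.params},
            indent=2, sort_keys=True))


# fixed anchor positions for the domains that do not enter any coordinate;
# far enough from the moving TRXL1/2/3 triangle to avoid overlap
_STATIC_CENTERS = {
    "TRXL4": np.array([-35.0, 0.0, 0.0]),
    "bS1": np.array([-60.0, 12.0, 3.0]),
    "bS2": np.array([-80.0, -8.0, -4.0]),
    "GT24": np.array([-105.0, 2.0, 6.0]),
}


def _domain_residue_numbers(scheme: DomainScheme, name: str, n: int,
                            exclude: set[int]) -> list[int]:
    out = []
    for lo, hi in scheme.domains[name]:
        for r in range(lo, hi + 1):
            if r in exclude:
                continue
            out.append(r)
            if len(out) == n:
                return out
    raise ValueError(f"domain {name} has fewer than {n} usable residues")


def _validate_targets(cc1: float, cc2: float, cc3: float) -> None:
    if not cc1 > 0:
        raise ValueError(f"cc1 must be positive, got {cc1}")
    if not 0.0 < cc2 < 180.0:
        raise ValueError(f"cc2 must lie in (0, 180) degrees, got {cc2}")
    if not -180.0 < cc3 <= 180.0:
        raise ValueError(f"cc3 must lie in (-180, 180] degrees, got {cc3}")


def _moving_centers(cc1: float, cc2: float):
    """TRXL1/TRXL2/TRXL3 centers realising the clamp distance and bend
    angle exactly, with TRXL2 at the origin in the xy-plane."""
    theta = np.radians(cc2)
    r = cc1 / (2.0 * np.sin(theta / 2.0))
    c1 = r * np.array([np.cos(theta / 2.0), np.sin(theta / 2.0), 0.0])
    c3 = r * np.array([np.cos(theta / 2.0), -np.sin(theta / 2.0), 0.0])
    return c1, np.zeros(3), c3


def _quad_points(c2: np.ndarray, c3: np.ndarray, cc3: float):
    """Positions for the quad atoms (p1, p2, p3, p4) = residues
    (518, 466, 863, 735): p2/p3 sit on the TRXL2/TRXL3 centers and
    p1/p4 are offset so the torsion equals cc3 exactly."""
    u = c3 - c2
    u = u / np.linalg.norm(u)
    n1 = np.array([0.0, 0.0, 1.0])
    n1 = n1 - np.dot(n1, u) * u
    n1 /= np.linalg.norm(n1)
    w = np.cross(n1, u)
    phi = np.radians(cc3)
    # IUPAC sign: torsion(p1,p2,p3,p4) = +cc3 with this handedness
    n2 = np.cos(phi) * n1 + np.sin(phi) * w
    a, b = 5.0, 4.0
    p1 = c2 + a * n1 - b * u
    p2 = c2.copy()
    p3 = c3.copy()
    p4 = c3 + a * n2 + b * u
    return p1, p2, p3, p4


class _ConformerLayout:
    """Residue numbering and frozen intra-domain offsets for one seed, so
    a whole trajectory shares a single 'molecule'."""

    def __init__(self, scheme: DomainScheme, seed: int,
                 n_atoms_per_domain: int, blob_radius: float):
        if n_atoms_per_domain < 4:
            raise ValueError("need at least 4 atoms per domain")
        self.scheme = scheme
        rng = np.random.default_rng(seed)
        quad = set(scheme.cc3_quad)
        self.residues: dict[str, list[int]] = {}
        self.offsets: dict[str, np.ndarray] = {}
        q1, q2, q3, q4 = scheme.cc3_quad
        for name in sorted(scheme.domains):
            n_free = n_atoms_per_domain
            if name in ("TRXL2", "TRXL3"):
                n_free -= 2
            self.residues[name] = _domain_residue_numbers(
                scheme, name, n_free, exclude=quad)
            self.offsets[name] = rng.normal(0.0, blob_radius / 2.0, (n_free, 3))
        # atom order: per domain (sorted names), quad atoms first for
        # TRXL2/TRXL3, then free atoms in residue order
        self.quad_residue_of_domain = {"TRXL2": (q1, q2), "TRXL3": (q3, q4)}
        self.atom_order: list[tuple[str, int]] = []
        for name in sorted(scheme.domains):
            for r in self.quad_residue_of_domain.get(name, ()):
                self.atom_order.append((name, r))
            for r in self.residues[name]:
                self.atom_order.append((name, r))

    def place(self, cc1: float, cc2: float, cc3: float) -> np.ndarray:
        """(n_atoms, 3) positions realising the CC triple exactly."""
        _validate_targets(cc1, cc2, cc3)
        c1, c2, c3 = _moving_centers(cc1, cc2)
        p518, p466, p863, p735 = _quad_points(c2, c3, cc3)
        centers = {"TRXL1": c1, "TRXL2": c2, "TRXL3": c3, **_STATIC_CENTERS}
        fixed = {"TRXL2": (p518, p466), "TRXL3": (p863, p735)}
        coords = []
        for name in sorted(self.scheme.domains):
            c = centers[name]
            off = self.offsets[name]
            if name in fixed:
                fa, fb = fixed[name]
                n_tot = off.shape[0] + 2
                # shift free atoms so the domain centroid is exactly c
                delta = (n_tot * c - fa - fb - (c + off).sum(axis=0)) / off.shape[0]
                coords.append(fa[None, :])
                coords.append(fb[None, :])
                coords.append(c + off + delta)
            else:
                coords.append(c + off - off.mean(axis=0))
        return np.vstack(coords)

    def topology(self, coords: np.ndarray, entry_id: str) -> Structure:
        atoms = [
            Atom(element="C", name="CA", coords=xyz, residue_number=r,
                 residue_name="ALA", chain_id="A")
            for (name, r), xyz in zip(self.atom_order, coords)
        ]
        st = Structure(atoms, entry_id=entry_id)
        st.sequence_lengths["A"] = len(atoms)
        return st


def make_conformer(
    cc_targets: tuple[float, float, float],
    seed: int = 0,
    scheme: DomainScheme = CT_UGGT_SCHEME,
    n_atoms_per_domain: int = 20,
    blob_radius: float = 6.0,
    entry_id: str = "synthetic_conformer",
) -> tuple[Structure, ConformationalCoordinates]:
    """Seven-domain pseudo-structure whose Calpha-geometric-center CC
    triple equals ``cc_targets`` exactly.  Returns the structure and the
    planted ground-truth record."""
    layout = _ConformerLayout(scheme, seed, n_atoms_per_domain, blob_radius)
    coords = layout.place(*cc_targets)
    st = layout.topology(coords, entry_id)
    counts = {name: len(layout.residues[name]) +
              (2 if name in ("TRXL2", "TRXL3") else 0)
              for name in scheme.domains}
    truth = ConformationalCoordinates(*map(float, cc_targets), n_atoms_used=counts)
    return st, truth


def make_cc_trajectory(
    cc1, cc2, cc3,
    n_frames: int = 6000,
    noise_sigma: float = 0.0,
    seed: int = 0,
    scheme: DomainScheme = CT_UGGT_SCHEME,
    n_atoms_per_domain: int = 20,
    blob_radius: float = 6.0,
    entry_id: str = "synthetic_traj",
) -> tuple[Trajectory, pd.DataFrame]:
    """Trajectory whose frame-t coordinates realise the planted CC series
    exactly, plus i.i.d. isotropic Gaussian atom noise of ``noise_sigma``
    Angstrom.  Scalars broadcast to constant series.  The default frame
    count matches the 6000-frame ensembles used for essential dynamics.

    Returns the trajectory and a DataFrame with the planted per-frame
    cc1/cc2/cc3 ground truth.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    raw = [np.asarray(s, dtype=float) for s in (cc1, cc2, cc3)]
    lengths = {a.shape[0] for a in raw if a.ndim > 0}
    if len(lengths) > 1:
        raise ValueError(f"cc series lengths differ: {sorted(lengths)}")
    if lengths:
        n_frames = lengths.pop()
    series = [a if a.ndim > 0 else np.full(n_frames, float(a)) for a in raw]

    layout = _ConformerLayout(scheme, seed, n_atoms_per_domain, blob_radius)
    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    frames = []
    for t in range(n_frames):
        xyz = layout.place(series[0][t], series[1][t], series[2][t])
        if noise_sigma > 0:
            xyz = xyz + noise_rng.normal(0.0, noise_sigma, xyz.shape)
        frames.append(xyz)
    topo = layout.topology(frames[0], entry_id)
    truth = pd.DataFrame({"frame": np.arange(n_frames),
                          "cc1": series[0], "cc2": series[1], "cc3": series[2]})
    return Trajectory(topo, frames), truth


def make_mode_trajectory(
    base_coords: np.ndarray,
    modes: list[np.ndarray],
    amplitudes: list[np.ndarray],
    noise_sigma: float = 0.0,
    seed: int = 0,
    entry_id: str = "synthetic_modes",
) -> tuple[Trajectory, np.ndarray]:
    """Frames = base + sum_k a_k(t) * mode_k (+ noise), with the planted
    modes orthonormalised first.  The exact oracle for covariance PCA.

    Returns the trajectory and the orthonormalised planted modes as rows
    of a (k, 3N) array."""
    base = np.asarray(base_coords, float)
    n = base.shape[0]
    M = np.array([np.asarray(m, float).ravel() for m in modes]).T  # (3N, k)
    Q, _ = np.linalg.qr(M)
    Q = Q.T  # (k, 3N)
    amps = np.array([np.asarray(a, float) for a in amplitudes])
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(amps.shape[1]):
        x = base.ravel() + amps[:, t] @ Q
        xyz = x.reshape(n, 3)
        if noise_sigma > 0:
            xyz = xyz + rng.normal(0.0, noise_sigma, xyz.shape)
        frames.append(xyz)
    atoms = [Atom("C", "CA", base[i], i + 1, "ALA", "A") for i in range(n)]
    topo = Structure(atoms, entry_id=entry_id)
    return Trajectory(topo, frames), Q


# ---------------------------------------------------------------------------
# glycoprotein fixtures


@dataclass
class GlycoproteinFixture:
    """A toy glycoprotein with planted sites and brute-force ground truth."""

    structure: Structure
    sites: list[GlycosylationSite]
    truth: pd.DataFrame                 # resnum, d1, d2 (NaN when absent)
    planted_exceed: np.ndarray | None   # bool per residue, exceedance plan only


def _trace_positions(n: int, geometry: str, rng: np.random.Generator) -> np.ndarray:
    """Calpha trace with 3.8 A spacing (helix uses the canonical alpha
    geometry whose consecutive-Calpha spacing is ~3.8 A)."""
    if geometry == "extended":
        return np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])
    if geometry == "helix":
        t = 100.0 * np.arange(n) * np.pi / 180.0
        return np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t),
                                1.5 * np.arange(n)])
    if geometry == "random_walk":
        pos = np.zeros((n, 3))
        d = np.array([1.0, 0.0, 0.0])
        for i in range(1, n):
            d = d + 0.6 * rng.standard_normal(3)
            d /= np.linalg.norm(d)
            pos[i] = pos[i - 1] + 3.8 * d
        return pos
    raise ValueError(f"unknown geometry {geometry!r}")


def _brute_force_reach(res_atoms: dict[int, np.ndarray],
                       site_residues: list[int]) -> pd.DataFrame:
    """Exhaustive double loop over atom pairs; the independent oracle."""
    rows = []
    for r, A in res_atoms.items():
        ds = []
        for s in site_residues:
            B = res_atoms[s]
            best = min(
                float(np.linalg.norm(a - b)) for a in A for b in B
            )
            ds.append(best)
        ds.sort()
        rows.append((r, ds[0], ds[1] if len(ds) > 1 else np.nan))
    return pd.DataFrame(rows, columns=["resnum", "d1", "d2"])


def make_glycoprotein(
    n_residues: int = 100,
    site_residues: tuple[int, ...] = (1,),
    seed: int = 0,
    geometry: str = "random_walk",
    realise: str = "declared",
    exceed_fraction: float | None = None,
    threshold: float = 70.0,
    entry_id: str = "synthetic_glyco",
    chain_id: str = "A",
) -> GlycoproteinFixture:
    """Toy glycoprotein chain with planted N-glycosylation sites.

    ``realise='declared'`` marks the sites by declaration only;
    ``'asn_nag'`` builds each site as an ASN with an ND2 atom plus a NAG
    heteroatom residue whose C1 sits 1.45 A from ND2, so the covalent
    detector finds exactly the planted sites.

    With ``exceed_fraction`` set, the chain geometry is replaced by a
    two-shell placement around the (single) site: each non-site residue
    independently lands beyond ``threshold`` with that probability, and
    the per-residue draw is recorded in ``planted_exceed``.
    """
    for s in site_residues:
        if not 1 <= s <= n_residues:
            raise ValueError(f"site residue {s} outside chain 1..{n_residues}")
    rng = np.random.default_rng(seed)
    planted = None

    if exceed_fraction is not None:
        if len(site_residues) != 1:
            raise ValueError("exceedance planting needs exactly one site")
        if not 0.0 <= exceed_fraction <= 1.0:
            raise ValueError("exceed_fraction must be in [0, 1]")
        site = site_residues[0]
        pos = np.zeros((n_residues, 3))
        planted = np.zeros(n_residues, dtype=bool)
        for i in range(n_residues):
            r = i + 1
            if r == site:
                continue
            far = rng.random() < exceed_fraction
            planted[i] = far
            radius = (rng.uniform(1.05 * threshold, 1.8 * threshold) if far
                      else rng.uniform(4.0, 0.95 * threshold))
            v = rng.standard_normal(3)
            pos[i] = radius * v / np.linalg.norm(v)
    else:
        pos = _trace_positions(n_residues, geometry, rng)

    site_set = set(site_residues)
    atoms: list[Atom] = []
    res_atoms: dict[int, list[np.ndarray]] = {}
    for i in range(n_residues):
        r = i + 1
        is_site = r in site_set
        resname = "ASN" if (is_site and realise == "asn_nag") else "ALA"
        atoms.append(Atom("C", "CA", pos[i], r, resname, chain_id))
        res_atoms.setdefault(r, []).append(pos[i])
        if is_site and realise == "asn_nag":
            nd2 = pos[i] + np.array([1.9, 0.0, 0.0])
            atoms.append(Atom("N", "ND2", nd2, r, "ASN", chain_id))
            res_atoms[r].append(nd2)

    het_atoms: list[Atom] = []
    if realise == "asn_nag":
        for k, s in enumerate(site_residues):
            nd2 = res_atoms[s][1]
            c1 = nd2 + np.array([1.45, 0.0, 0.0])
            het_atoms.append(Atom("C", "C1", c1, 2000 + k, "NAG", chain_id,
                                  is_heteroatom=True))
    elif realise != "declared":
        raise ValueError(f"unknown realisation {realise!r}")

    st = Structure(atoms + het_atoms, entry_id=entry_id)
    st.sequence_lengths[chain_id] = n_residues
    sites = [GlycosylationSite(chain_id, s,
                               "declared" if realise == "declared"
                               else "distance_heuristic")
             for s in sorted(site_set)]
    truth = _brute_force_reach(
        {r: np.array(v) for r, v in res_atoms.items()}, sorted(site_set))
    return GlycoproteinFixture(structure=st, sites=sites, truth=truth,
                               planted_exceed=planted)


def make_cohort(
    n_entries: int = 20,
    n_residues: int = 200,
    seed: int = 0,
    exceed_fraction: float | None = None,
    threshold: float = 70.0,
    n_sites: int = 1,
    geometry: str = "random_walk",
    realise: str = "declared",
    n_low_coverage: int = 0,
    n_no_glycan: int = 0,
) -> tuple[list[CohortEntry], list[GlycoproteinFixture]]:
    """A cohort of toy glycoproteins with per-entry ground truth.

    The first ``n_low_coverage`` entries are given a primary-sequence
    length that puts their coverage at exactly 0.90 (so the strict
    more-than-90% rule drops them) and the next ``n_no_glycan`` entries
    get no sites, for filter testing."""
    root = np.random.SeedSequence(seed)
    entry_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   root.spawn(n_entries)]
    entries, fixtures = [], []
    for k in range(n_entries):
        no_glycan = n_low_coverage <= k < n_low_coverage + n_no_glycan
        if exceed_fraction is not None:
            site_res = (1,)
        else:
            step = max(1, n_residues // max(n_sites, 1))
            site_res = tuple(1 + j * step for j in range(n_sites))
        fx = make_glycoprotein(
            n_residues=n_residues, site_residues=site_res,
            seed=entry_seeds[k], geometry=geometry, realise=realise,
            exceed_fraction=exceed_fraction, threshold=threshold,
            entry_id=f"synthetic_{k:03d}",
        )
        if k < n_low_coverage:
            # smallest length putting coverage at or below 0.90, so the
            # strict more-than-90% rule drops the entry
            length = int(np.ceil(n_residues / 0.9))
            while n_residues / length > 0.9:
                length += 1
            fx.structure.sequence_lengths["A"] = length
        coverage = n_residues / fx.structure.sequence_lengths["A"]
        sites = [] if no_glycan else fx.sites
        entries.append(CohortEntry(
            entry_id=fx.structure.entry_id, structure=fx.structure,
            chain="A", sites=sites, coverage=coverage))
        fixtures.append(fx)
    return entries, fixtures
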
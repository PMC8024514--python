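"""The Parodi-limit survey.

Monomeric UGGT can only reglucosylate an N-glycan that sits within some
maximum distance (the "Parodi limit", estimated at 70-80 Angstrom) of the
misfolded patch it recognises.  If that limit matters in vivo, residues of
real glycoproteins should rarely be farther than it from their nearest
N-glycosylation site.  This module measures exactly that over a cohort of
structures: per-residue distances to the closest and second-closest
glycosylation site, the all-pairs residue-residue distance control, their
histograms and cumulative distributions, per-entry radius of gyration, and
the fraction of residues within each threshold.

Distances are minimum heavy-atom inter-atomic distances between a residue
and the glycosylated asparagine (not the sugar atoms); a Calpha-Calpha
mode and a mean-distance reduction are available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError
from .structures import GlycosylationSite, Structure

__all__ = [
    "ResidueReach",
    "CohortEntry",
    "SurveyResult",
    "residue_pair_min_distance",
    "closest_two_glycans",
    "control_pairwise_distances",
    "radius_of_gyration",
    "filter_cohort",
    "run_survey",
]


@dataclass
class ResidueReach:
    """Distances (Angstrom) from one residue to its closest (d1) and
    second-closest (d2) glycosylation site; d2 is None with <2 sites."""

    entry_id: str
    chain: str
    residue_number: int
    d1: float
    d2: float | None = None


def _residue_coords(structure: Structure, chain: str, resnum: int,
                    atom_mode: str) -> np.ndarray:
    atoms = structure.residue_atoms(chain, resnum)
    if atom_mode == "calpha":
        atoms = [a for a in atoms if a.name == "CA"]
    else:
        atoms = [a for a in atoms if a.element.upper() != "H"]
    if not atoms:
        raise SelectionError(
            f"residue {chain}/{resnum} has no atoms for atom_mode={atom_mode!r}"
        )
    return np.array([a.coords for a in atoms])


def residue_pair_min_distance(
    structure: Structure,
    residue_a: tuple[str, int], residue_b: tuple[str, int],
    atom_mode: str = "heavy", reduction: str = "min",
) -> float:
    """Distance between two residues: the ``min`` (default) or ``mean``
    over all selected atom pairs."""
    A = _residue_coords(structure, *residue_a, atom_mode=atom_mode)
    B = _residue_coords(structure, *residue_b, atom_mode=atom_mode)
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    if reduction == "min":
        return float(d.min())
    if reduction == "mean":
        return float(d.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def _chain_residue_coords(structure: Structure, chain: str, atom_mode: str):
    """Per-residue coordinate blocks for protein residues of a chain."""
    resnums = structure.residue_numbers(chain, include_het=False)
    blocks = []
    kept = []
    for r in resnums:
        atoms = [a for a in structure.residue_atoms(chain, r) if not a.is_heteroatom]
        if atom_mode == "calpha":
            atoms = [a for a in atoms if a.name == "CA"]
        if not atoms:
            continue
        kept.append(r)
        blocks.append(np.array([a.coords for a in atoms]))
    return kept, blocks


def closest_two_glycans(
    structure: Structure, chain: str,
    sites: list[GlycosylationSite], atom_mode: str = "heavy",
    reduction: str = "min",
) -> list[ResidueReach]:
    """Per-residue d1/d2 to the glycosylation sites.  A glycosylated ASN
    is at distance 0 from its own site."""
    if not sites:
        raise SelectionError("no glycosylation sites: entry should have been "
                             "filtered out of the cohort")
    site_blocks = []
    for s in sites:
        site_blocks.append(
            _residue_coords(structure, s.chain_id, s.residue_number,
                            atom_mode=atom_mode))
    resnums, blocks = _chain_residue_coords(structure, chain, atom_mode)
    out = []
    for r, A in zip(resnums, blocks):
        ds = []
        for B in site_blocks:
            d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
            ds.append(float(d.min()) if reduction == "min" else float(d.mean()))
        ds.sort()
        out.append(ResidueReach(
            entry_id=structure.entry_id, chain=chain, residue_number=r,
            d1=ds[0], d2=ds[1] if len(ds) > 1 else None))
    return out


def control_pairwise_distances(
    structure: Structure, chain: str, atom_mode: str = "heavy",
) -> np.ndarray:
    """Minimum inter-atomic distance for every unordered residue pair in
    the chain (the size control): n(n-1)/2 values."""
    resnums, blocks = _chain_residue_coords(structure, chain, atom_mode)
    n = len(resnums)
    if n < 2:
        return np.empty(0)
    if all(len(b) == 1 for b in blocks):
        # common single-atom case (Calpha traces): one vectorised pass
        from scipy.spatial.distance import pdist

        return pdist(np.vstack(blocks))
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        A = blocks[i]
        for j in range(i + 1, n):
            B = blocks[j]
            out[k] = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2).min()
            k += 1
    return out


def radius_of_gyration(
    structure: Structure, chain: str,
    atom_mode: str = "heavy", weighting: str = "geometric",
) -> float:
    """Root-mean-square (optionally mass-weighted) distance of the chain's
    selected atoms from their centroid, in Angstrom."""
    from ._geom import mass_of

    atoms = [a for a in structure.select(chain=chain, include_het=False)
             if (a.name == "CA" if atom_mode == "calpha"
                 else a.element.upper() != "H")]
    if not atoms:
        raise SelectionError(f"no atoms in chain {chain!r}")
    xyz = np.array([a.coords for a in atoms])
    w = (np.array([mass_of(a.element) for a in atoms])
         if weighting == "mass" else np.ones(len(atoms)))
    center = np.average(xyz, axis=0, weights=w)
    return float(np.sqrt(np.average(((xyz - center) ** 2).sum(axis=1), weights=w)))


@dataclass
class CohortEntry:
    """One structure of a survey cohort with its chain of interest, its
    glycosylation sites, and the primary-sequence coverage of that chain."""

    entry_id: str
    structure: Structure
    chain: str
    sites: list[GlycosylationSite]
    coverage: float


def filter_cohort(
    entries: list[CohortEntry],
    min_coverage: float = 0.9, min_sites: int = 1,
) -> tuple[list[CohortEntry], list[tuple[str, str]]]:
    """Keep entries with coverage strictly above ``min_coverage`` (the
    cohort rule is "more than 90% of the primary sequence") and at least
    ``min_sites`` glycosylation sites.  Returns (kept, dropped-with-reason)."""
    kept, dropped = [], []
    for e in entries:
        if not (e.coverage > min_coverage):
            dropped.append((e.entry_id,
                            f"low_coverage:{e.coverage:.3f}<= {min_coverage:g}"))
        elif len(e.sites) < min_sites:
            dropped.append((e.entry_id, "no_glycan"))
        else:
            kept.append(e)
    return kept, dropped


def _histogram(values: np.ndarray, bin_width: float,
               upper: float | None = None):
    values = np.asarray(values, float)
    if values.size == 0:
        return np.array([0.0, bin_width]), np.array([0])
    hi = upper if upper is not None else float(values.max())
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts


def _cumulative(values: np.ndarray):
    """Sorted values and the fraction of the sample at or below each."""
    v = np.sort(np.asarray(values, float))
    if v.size == 0:
        return v, v
    return v, np.arange(1, v.size + 1) / v.size


@dataclass
class SurveyResult:
    """Pooled survey output over a cohort."""

    reach: list[ResidueReach]
    control: np.ndarray
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (edges, counts)
    cumulative: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (values, fraction)
    rog: dict[str, float]                                 # entry_id -> Angstrom
    median_rog: float
    fraction_within: dict[float, float]                   # threshold -> fraction
    filter_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def d1(self) -> np.ndarray:
        return np.array([r.d1 for r in self.reach])

    @property
    def d2(self) -> np.ndarray:
        return np.array([r.d2 for r in self.reach if r.d2 is not None])


def run_survey(
    cohort: list[CohortEntry],
    thresholds: tuple[float, ...] = (70.0, 80.0),
    bin_width: float = 1.0,
    atom_mode: str = "heavy",
    filter_log: list[tuple[str, str]] | None = None,
) -> SurveyResult:
    """Pool per-residue reach records and residue-residue controls over a
    (pre-filtered) cohort; build histograms, cumulative curves, per-entry
    radius of gyration and fraction-within-threshold statistics.

    The fraction-within statistic pools residues across all entries (each
    residue record counts once, matching a per-residue reading of the
    survey) rather than averaging per entry.
    """
    if not cohort:
        raise ValueError("empty cohort")
    reach: list[ResidueReach] = []
    controls = []
    rog: dict[str, float] = {}
    for e in cohort:
        reach.extend(closest_two_glycans(e.structure, e.chain, e.sites,
                                         atom_mode=atom_mode))
        controls.append(control_pairwise_distances(e.structure, e.chain,
                                                   atom_mode=atom_mode))
        rog[e.entry_id] = radius_of_gyration(e.structure, e.chain,
                                             atom_mode=atom_mode)
    control = np.concatenate(controls) if controls else np.empty(0)
    d1 = np.array([r.d1 for r in reach])
    d2 = np.array([r.d2 for r in reach if r.d2 is not None])

    upper = max(
        [d1.max() if d1.size else 0.0, d2.max() if d2.size else 0.0,
         control.max() if control.size else 0.0] + [max(thresholds, default=0.0)]
    )
    histograms = {
        "d1": _histogram(d1, bin_width, upper),
        "d2": _histogram(d2, bin_width, upper),
        "control": _histogram(control, bin_width, upper),
    }
    cumulative = {
        "d1": _cumulative(d1),
        "d2": _cumulative(d2),
        "control": _cumulative(control),
        "rog": _cumulative(np.array(list(rog.values()))),
    }
    fraction_within = {
        float(t): float((d1 < t).mean()) if d1.size else float("nan")
        for t in thresholds
    }
    return SurveyResult(
        reach=reach, control=control, histograms=histograms,
        cumulative=cumulative, rog=rog,
        median_rog=float(np.median(list(rog.values()))),
        fraction_within=fraction_within,
        filter_log=list(filter_log or []),
    )
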
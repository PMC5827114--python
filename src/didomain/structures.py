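"""Structure handling: parsing, selections, SASA, buried surface and geometry.

This module provides the structural primitives the rest of the pipeline
consumes: a light-weight atomic model read from PDB/mmCIF via gemmi,
inclusive author-numbered domain selections, a deterministic Shrake–Rupley
solvent-accessible surface area (SASA), difference-method buried surface
area for a two-domain interface, backbone amide N–H bond vectors for RDC
back-calculation, and heavy-atom contact residues.

Conventions
-----------
* Residue intervals use author numbering, 1-based, inclusive on both ends.
* SASA uses NACCESS-style heavy-atom radii (C 1.70, N 1.55, O 1.52,
  S 1.80 Å) with hydrogens excluded by default, probe radius 1.4 Å.
* Buried surface area is the total over both faces,
  ``SASA(A) + SASA(B) − SASA(A ∪ B)``, not halved.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "StructureModel",
    "DomainDefinition",
    "SasaResult",
    "StructureFormatError",
    "read_structure",
    "write_pdb",
    "shrake_rupley_sasa",
    "buried_surface_area",
    "nh_bond_vectors",
    "contact_residues",
    "DEFAULT_RADII",
]

#: NACCESS-style heavy-atom van der Waals radii (Å).
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.00,
    "SE": 1.90,
}


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed as the named format."""


@dataclasses.dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0


class StructureModel:
    """An atomic model: a flat list of atoms with cached coordinate arrays."""

    def __init__(self, atoms: Sequence[Atom]):
        if len(atoms) == 0:
            raise ValueError("structure model must contain at least one atom")
        coords = np.array([a.xyz for a in atoms], dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite atom coordinates")
        self.atoms: list[Atom] = list(atoms)
        self.coords: np.ndarray = coords

    def __len__(self) -> int:
        return len(self.atoms)

    def residues(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, resnum) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.resnum), None)
        return list(seen)

    def chain_residue_numbers(self, chain: str) -> list[int]:
        return sorted({a.resnum for a in self.atoms if a.chain == chain})

    def select(self, definition: "DomainDefinition") -> np.ndarray:
        """Boolean mask over atoms for a domain definition."""
        mask = np.array([definition.contains(a.chain, a.resnum) for a in self.atoms])
        return mask

    def subset(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel([a for a, m in zip(self.atoms, mask) if m])


@dataclasses.dataclass(frozen=True)
class DomainDefinition:
    """Named selection: a chain plus inclusive author-numbered intervals."""

    name: str
    chain: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ivals = sorted(self.intervals)
        for start, end in ivals:
            if start > end:
                raise ValueError(f"interval start {start} > end {end}")
        for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError("overlapping intervals in domain definition")
        object.__setattr__(self, "intervals", tuple(ivals))

    @classmethod
    def from_string(cls, name: str, spec: str) -> "DomainDefinition":
        """Parse ``"A:16-109,121-243"`` style selection strings."""
        chain, _, rest = spec.partition(":")
        if not rest:
            raise ValueError(f"selection {spec!r} must look like 'chain:start-end[,...]'")
        intervals = []
        for part in rest.split(","):
            start, _, end = part.partition("-")
            intervals.append((int(start), int(end or start)))
        return cls(name=name, chain=chain, intervals=tuple(intervals))

    def contains(self, chain: str, resnum: int) -> bool:
        if chain != self.chain:
            return False
        return any(s <= resnum <= e for s, e in self.intervals)

    def residue_ids(self) -> list[tuple[str, int]]:
        return [(self.chain, n) for s, e in self.intervals for n in range(s, e + 1)]

    def overlaps(self, other: "DomainDefinition") -> bool:
        if self.chain != other.chain:
            return False
        mine = {n for s, e in self.intervals for n in range(s, e + 1)}
        theirs = {n for s, e in other.intervals for n in range(s, e + 1)}
        return bool(mine & theirs)


@dataclasses.dataclass(frozen=True)
class SasaResult:
    """Per-atom accessible areas (Å²) from Shrake–Rupley quadrature."""

    areas: np.ndarray
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.areas.sum())


# ---------------------------------------------------------------------------
# I/O


def read_structure(
    path: str | Path,
    fmt: str | None = None,
    include_hetero: bool = False,
    model_index: int = 0,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Author residue numbering is preserved; alternate locations are resolved
    to the highest-occupancy conformer; waters and (by default) other
    heteroatoms are excluded.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no coordinate models")
    model = st[model_index]

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if residue.is_water():
                continue
            het = residue.het_flag == "H"
            if het and not include_hetero:
                continue
            # resolve altlocs to highest occupancy per atom name
            best: dict[str, "gemmi.Atom"] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        resname=residue.name.strip(),
                        name=atom.name,
                        element=atom.element.name.upper(),
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                    )
                )
    if not atoms:
        raise StructureFormatError(f"{path}: empty model after filtering")
    return StructureModel(atoms)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write fixed-width ATOM records (coordinates to 3 decimals)."""
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = a.xyz
        lines.append(
            f"ATOM  {i:5d} {name}{'':1s}{a.resname:<3s} {a.chain:1s}"
            f"{a.resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}"
            f"{0.0:6.2f}          {a.element:>2s}"
        )
    Path(path).write_text("\n".join(lines) + "\nEND\n")


# ---------------------------------------------------------------------------
# SASA


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radii(
    atoms: Iterable[Atom],
    radii: dict[str, float],
    default_radius: float | None,
) -> np.ndarray:
    out = []
    for a in atoms:
        r = radii.get(a.element)
        if r is None:
            if default_radius is None:
                raise ValueError(
                    f"no van der Waals radius for element {a.element!r} "
                    "and no default_radius configured"
                )
            r = default_radius
        out.append(r)
    return np.asarray(out, dtype=float)


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    selection: DomainDefinition | np.ndarray | None = None,
    radii: dict[str, float] | None = None,
    default_radius: float | None = None,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Per-atom solvent-accessible surface area by Shrake–Rupley quadrature.

    A deterministic golden-spiral point set is placed on each atom's expanded
    sphere (van der Waals radius + probe); a point is accessible if it lies
    outside every neighbouring expanded sphere.  ``selection`` restricts both
    the atoms reported *and* the occluding environment (pass a mask to keep
    the environment and zero out the rest yourself if needed).
    """
    radii = dict(DEFAULT_RADII if radii is None else radii)
    if selection is not None:
        mask = model.select(selection) if isinstance(selection, DomainDefinition) else np.asarray(selection, bool)
        if not mask.any():
            raise ValueError("empty selection")
        sub = model.subset(mask)
    else:
        sub = model
    if not include_hydrogens:
        keep = np.array([a.element != "H" for a in sub.atoms])
        if not keep.any():
            raise ValueError("selection contains only hydrogens")
        sub = sub.subset(keep)

    coords = sub.coords
    rad = _atom_radii(sub.atoms, radii, default_radius) + probe
    pts = _sphere_points(n_points)

    tree = cKDTree(coords)
    max_r = rad.max()
    areas = np.empty(len(sub), dtype=float)
    for i in range(len(sub)):
        neighbours = tree.query_ball_point(coords[i], rad[i] + max_r)
        neighbours = [j for j in neighbours if j != i]
        test = coords[i] + rad[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        if neighbours:
            nb = np.asarray(neighbours)
            d2 = ((test[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 >= (rad[nb] ** 2)[None, :]).all(axis=1)
        areas[i] = 4.0 * math.pi * rad[i] ** 2 * accessible.mean()
    return SasaResult(areas=areas, probe_radius=probe, n_points=n_points)


def buried_surface_area(
    model: StructureModel,
    sel_a: DomainDefinition,
    sel_b: DomainDefinition,
    probe: float = 1.4,
    n_points: int = 960,
    **kwargs,
) -> float:
    """Total buried surface (both faces): SASA(A) + SASA(B) − SASA(A ∪ B)."""
    if sel_a.overlaps(sel_b):
        raise ValueError("selections must be disjoint")
    mask_a = model.select(sel_a)
    mask_b = model.select(sel_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("empty selection")
    sasa_a = shrake_rupley_sasa(model.subset(mask_a), probe, n_points, **kwargs).total
    sasa_b = shrake_rupley_sasa(model.subset(mask_b), probe, n_points, **kwargs).total
    sasa_ab = shrake_rupley_sasa(model.subset(mask_a | mask_b), probe, n_points, **kwargs).total
    return sasa_a + sasa_b - sasa_ab


# ---------------------------------------------------------------------------
# Geometry


def nh_bond_vectors(
    model: StructureModel,
    selection: DomainDefinition | None = None,
    add_ideal_h: bool = False,
) -> tuple[list[tuple[tuple[str, int], np.ndarray]], list[tuple[tuple[str, int], str]]]:
    """Backbone amide N–H unit vectors per residue.

    Returns ``(vectors, skipped)`` where ``vectors`` is a list of
    ``((chain, resnum), unit_vector)`` and ``skipped`` records residues
    without an amide (prolines, chain starts, missing atoms) with a reason.
    With ``add_ideal_h`` an ideal amide proton is constructed from the N,
    CA and preceding C positions when no H is present in the model.
    """
    by_res: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    resnames: dict[tuple[str, int], str] = {}
    for a, xyz in zip(model.atoms, model.coords):
        if selection is not None and not selection.contains(a.chain, a.resnum):
            continue
        by_res.setdefault((a.chain, a.resnum), {})[a.name] = xyz
        resnames[(a.chain, a.resnum)] = a.resname
    # previous-residue carbonyl C may come from outside the selection
    all_c: dict[tuple[str, int], np.ndarray] = {
        (a.chain, a.resnum): xyz
        for a, xyz in zip(model.atoms, model.coords)
        if a.name == "C"
    }

    vectors: list[tuple[tuple[str, int], np.ndarray]] = []
    skipped: list[tuple[tuple[str, int], str]] = []
    for rid in sorted(by_res):
        atoms = by_res[rid]
        if resnames[rid] == "PRO":
            skipped.append((rid, "proline (no amide H)"))
            continue
        n = atoms.get("N")
        if n is None:
            skipped.append((rid, "missing backbone N"))
            continue
        h = atoms.get("H")
        if h is None:
            h = atoms.get("HN")
        if h is None:
            if not add_ideal_h:
                skipped.append((rid, "no amide H in model"))
                continue
            ca = atoms.get("CA")
            c_prev = all_c.get((rid[0], rid[1] - 1))
            if ca is None or c_prev is None:
                skipped.append((rid, "cannot build ideal H (chain start or missing atoms)"))
                continue
            u1 = (n - ca) / np.linalg.norm(n - ca)
            u2 = (n - c_prev) / np.linalg.norm(n - c_prev)
            direction = u1 + u2
            direction /= np.linalg.norm(direction)
            h = n + 1.02 * direction
        v = h - n
        norm = np.linalg.norm(v)
        if norm < 1e-6:
            skipped.append((rid, "degenerate N–H geometry"))
            continue
        vectors.append((rid, v / norm))
    return vectors, skipped


def contact_residues(
    model: StructureModel,
    sel_a: DomainDefinition,
    sel_b: DomainDefinition,
    cutoff: float = 5.0,
) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Residue pairs with any heavy-atom distance below ``cutoff`` Å.

    The criterion is the minimum distance over heavy atoms; the returned set
    contains ``((chainA, resA), (chainB, resB))`` pairs ordered (A, B).
    """
    if sel_a.overlaps(sel_b):
        raise ValueError("selections must be disjoint")
    heavy = np.array([a.element != "H" for a in model.atoms])
    mask_a = model.select(sel_a) & heavy
    mask_b = model.select(sel_b) & heavy
    ids = np.array([(a.chain, a.resnum) for a in model.atoms], dtype=object)
    xa, xb = model.coords[mask_a], model.coords[mask_b]
    if len(xa) == 0 or len(xb) == 0:
        return set()
    tree_b = cKDTree(xb)
    pairs = tree_b.query_ball_point(xa, cutoff)
    ids_a, ids_b = ids[mask_a], ids[mask_b]
    out: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    for i, hits in enumerate(pairs):
        for j in hits:
            out.add((tuple(ids_a[i]), tuple(ids_b[j])))
    return out
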
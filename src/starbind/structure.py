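"""Structural comparisons for protein dimers and their bound RNAs.

Three quantities support the dimerization model of Sam68/T-STAR:

- the backbone RMSD between two structures after optimal (Kabsch) rigid
  superposition over matched atoms;
- the buried dimer-interface area per monomer, computed as
  ``(SASA(A) + SASA(B) - SASA(A U B)) / 2`` with a Shrake-Rupley numerical
  solvent-accessible surface area;
- the Euclidean distance between the 3' end of one bound RNA chain and the
  5' end of the other, which shows the two RNAs exit the dimer on opposite
  sides (>50 A apart in the deposited structures), so one RNA molecule can
  only reach both KH grooves if its two (A/U)AA cores are far apart in
  sequence.

PDB files are parsed with gemmi: model 1 only, altloc blank or 'A', waters
excluded by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: van der Waals radii (A) for the elements present in protein/RNA models.
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_PROBE = 1.4
DEFAULT_SPHERE_POINTS = 960
BACKBONE_ATOMS = ("N", "CA", "C", "O")

__all__ = [
    "Atom",
    "StructureModel",
    "AtomSelection",
    "read_pdb",
    "superpose_kabsch",
    "best_dimer_rmsd",
    "sasa",
    "interface_area",
    "rna_end_distance",
]


@dataclass(frozen=True)
class Atom:
    chain: str
    resseq: int
    icode: str
    resname: str
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """Atom records of one coordinate model plus minimal metadata."""

    atoms: list[Atom]
    model_number: int = 1
    title: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def subset(self, atoms: Iterable[Atom]) -> "StructureModel":
        return StructureModel(atoms=list(atoms), model_number=self.model_number, title=self.title)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with ``x' = R x + t`` applied to every atom."""
        out = []
        for a in self.atoms:
            x, y, z = rotation @ np.array([a.x, a.y, a.z]) + translation
            out.append(Atom(a.chain, a.resseq, a.icode, a.resname, a.name, a.element, x, y, z))
        return StructureModel(atoms=out, model_number=self.model_number, title=self.title)


@dataclass(frozen=True)
class AtomSelection:
    """Chains, residue ranges and atom names used to pick atoms for an operation.

    ``chains=None`` selects every chain; ``residue_ranges`` are inclusive
    (start, end) residue-number pairs, ``None`` for all residues;
    ``atom_names=None`` selects every atom name (the protein backbone
    N/CA/C/O is the conventional choice for RMSD).
    """

    chains: tuple[str, ...] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: tuple[str, ...] | None = BACKBONE_ATOMS

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.residue_ranges is not None and not any(
            lo <= atom.resseq <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True

    def apply(self, model: StructureModel) -> list[Atom]:
        return [a for a in model.atoms if self.matches(a)]


WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb(path: str | Path, keep_waters: bool = False) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Model 1 only; alternate locations resolved by keeping blank or 'A';
    waters excluded unless ``keep_waters``.

    Raises
    ------
    ValueError
        If the file contains no atom records.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if not keep_waters and residue.name in WATER_NAMES:
                continue
            for atom in residue:
                if atom.altloc not in ("\x00", "", "A"):
                    continue
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resseq=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        resname=residue.name.strip(),
                        name=atom.name.strip(),
                        element=atom.element.name.upper(),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                    )
                )
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return StructureModel(
        atoms=atoms,
        model_number=model.num if hasattr(model, "num") else 1,
        title=st.name or Path(path).stem,
    )


def _kabsch(mobile_xyz: np.ndarray, target_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation/translation of mobile onto target; returns RMSD."""
    mc = mobile_xyz.mean(axis=0)
    tc = target_xyz.mean(axis=0)
    p = mobile_xyz - mc
    q = target_xyz - tc
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = tc - rotation @ mc
    diff = (p @ rotation.T) - q
    rmsd = float(np.sqrt((diff**2).sum() / len(p)))
    return rotation, translation, rmsd


def _match_atoms(
    mobile_atoms: Sequence[Atom],
    target_atoms: Sequence[Atom],
    chain_map: dict[str, str],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Correspondence by (mapped chain, residue number, insertion code, atom name).

    Only the intersection of common atoms is used; disordered residues absent
    from one model drop out (with a logged count).
    """
    target_index = {(a.chain, a.resseq, a.icode, a.name): a for a in target_atoms}
    mob, tgt = [], []
    unmatched = 0
    for a in mobile_atoms:
        key = (chain_map.get(a.chain, a.chain), a.resseq, a.icode, a.name)
        b = target_index.get(key)
        if b is None:
            unmatched += 1
            continue
        mob.append([a.x, a.y, a.z])
        tgt.append([b.x, b.y, b.z])
    if unmatched:
        logger.info("superposition: %d mobile atoms had no counterpart and were dropped", unmatched)
    if len(mob) < 3:
        missing = sorted(
            {(a.chain, a.resseq) for a in mobile_atoms
             if (chain_map.get(a.chain, a.chain), a.resseq, a.icode, a.name) not in target_index}
        )
        raise ValueError(
            f"fewer than 3 matched atoms for superposition; unmatched residues: {missing[:20]}"
        )
    return np.asarray(mob), np.asarray(tgt), unmatched


def superpose_kabsch(
    mobile: StructureModel,
    target: StructureModel,
    sel_mobile: AtomSelection | None = None,
    sel_target: AtomSelection | None = None,
    chain_map: dict[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of matched atoms (Kabsch algorithm).

    Atoms are put in correspondence by (mapped chain, residue number,
    insertion code, atom name); ``chain_map`` maps mobile chain ids onto
    target chain ids (identity by default).  Returns ``(rotation,
    translation, rmsd)`` with ``x_target ~ rotation @ x_mobile +
    translation`` and a proper rotation (det +1).
    """
    sel_mobile = sel_mobile or AtomSelection()
    sel_target = sel_target or AtomSelection()
    mobile_atoms = sel_mobile.apply(mobile)
    target_atoms = sel_target.apply(target)
    if not mobile_atoms or not target_atoms:
        raise ValueError("selection resolves to no atoms")
    mob, tgt, _ = _match_atoms(mobile_atoms, target_atoms, chain_map or {})
    return _kabsch(mob, tgt)


def best_dimer_rmsd(
    mobile: StructureModel,
    target: StructureModel,
    mobile_chains: tuple[str, str],
    target_chains: tuple[str, str],
    sel: AtomSelection | None = None,
) -> tuple[float, dict[str, str]]:
    """RMSD of a dimer-on-dimer superposition, minimized over chain pairing.

    Both mappings of the two mobile chains onto the two target chains are
    tried; the smaller RMSD and the winning mapping are returned (and the
    mapping logged).
    """
    sel = sel or AtomSelection()
    best: tuple[float, dict[str, str]] | None = None
    a, b = mobile_chains
    for mapping in ({a: target_chains[0], b: target_chains[1]},
                    {a: target_chains[1], b: target_chains[0]}):
        sel_mob = AtomSelection(chains=mobile_chains, residue_ranges=sel.residue_ranges,
                                atom_names=sel.atom_names)
        sel_tgt = AtomSelection(chains=target_chains, residue_ranges=sel.residue_ranges,
                                atom_names=sel.atom_names)
        try:
            _, _, rmsd = superpose_kabsch(mobile, target, sel_mob, sel_tgt, chain_map=mapping)
        except ValueError:
            continue
        if best is None or rmsd < best[0]:
            best = (rmsd, mapping)
    if best is None:
        raise ValueError("no chain mapping produced enough matched atoms")
    logger.info("dimer superposition: chain mapping %s gives RMSD %.3f A", best[1], best[0])
    return best


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    cos_theta = 1.0 - 2.0 * i / n
    sin_theta = np.sqrt(np.maximum(0.0, 1.0 - cos_theta**2))
    return np.column_stack([np.cos(phi) * sin_theta, np.sin(phi) * sin_theta, cos_theta])


def sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley), in A^2.

    Each atom's accessible sphere of radius ``r_atom + probe`` is sampled at
    ``sphere_points`` deterministic quasi-uniform points; points inside any
    neighbouring atom's accessible sphere are buried.  Hydrogens are not in
    the default radius table; an unknown element raises (no silent default
    radius).
    """
    radii = radii or DEFAULT_RADII
    unknown = sorted({a.element for a in model.atoms} - set(radii))
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {', '.join(unknown)}")
    n = len(model.atoms)
    if n == 0:
        return np.zeros(0)
    xyz = model.coordinates()
    r = np.array([radii[a.element] for a in model.atoms]) + probe
    points = _sphere_points(sphere_points)

    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    areas = np.zeros(n)
    for i in range(n):
        neighbours = [j for j in tree.query_ball_point(xyz[i], r[i] + r.max()) if j != i]
        test = xyz[i] + r[i] * points
        accessible = np.ones(sphere_points, dtype=bool)
        for j in neighbours:
            d2 = ((test - xyz[j]) ** 2).sum(axis=1)
            accessible &= d2 > r[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * math.pi * r[i] ** 2 * accessible.sum() / sphere_points
    return areas


def interface_area(
    model: StructureModel,
    group_a: AtomSelection,
    group_b: AtomSelection,
    probe: float = DEFAULT_PROBE,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
    radii: dict[str, float] | None = None,
) -> float:
    """Buried interface area per monomer: (SASA(A) + SASA(B) - SASA(A+B)) / 2.

    Only atoms picked by the two (disjoint) selections participate; anything
    else (RNA, heteroatoms) is excluded unless selected.
    """
    atoms_a = group_a.apply(model)
    atoms_b = group_b.apply(model)
    if not atoms_a or not atoms_b:
        raise ValueError("both groups must select at least one atom")
    ids_a = {id(a) for a in atoms_a}
    if any(id(a) in ids_a for a in atoms_b):
        raise ValueError("group_a and group_b overlap")
    kwargs = dict(probe=probe, sphere_points=sphere_points, radii=radii)
    area_a = sasa(model.subset(atoms_a), **kwargs).sum()
    area_b = sasa(model.subset(atoms_b), **kwargs).sum()
    area_ab = sasa(model.subset(atoms_a + atoms_b), **kwargs).sum()
    return float((area_a + area_b - area_ab) / 2.0)


_FIVE_PRIME_ATOMS = ("P", "O5'", "C5'")


def _chain_residues(model: StructureModel, chain: str) -> list[tuple[tuple[int, str], list[Atom]]]:
    order: dict[tuple[int, str], list[Atom]] = {}
    for a in model.atoms:
        if a.chain == chain:
            order.setdefault((a.resseq, a.icode), []).append(a)
    return sorted(order.items(), key=lambda kv: kv[0])


def rna_end_distance(
    model: StructureModel, chain_r1: str, chain_r2: str
) -> dict[str, float]:
    """Distance between the 3' end of one RNA chain and the 5' end of the other.

    The 3' terminus is the O3' atom of the last residue; the 5' terminus is
    the first residue's P if present, else O5', else C5'.  Both orderings are
    reported: keys ``"3'({r1})->5'({r2})"`` and ``"3'({r2})->5'({r1})"``.
    """
    if chain_r1 == chain_r2:
        raise ValueError("two distinct RNA chains are required")

    def terminal(chain: str, which: str) -> np.ndarray:
        residues = _chain_residues(model, chain)
        if not residues:
            raise ValueError(f"chain {chain!r} contains no residues")
        key, atoms = residues[-1] if which == "3'" else residues[0]
        by_name = {a.name: a for a in atoms}
        if which == "3'":
            atom = by_name.get("O3'")
            if atom is None:
                raise ValueError(f"chain {chain} residue {key[0]}: missing 3'-terminal O3'")
        else:
            atom = next((by_name[n] for n in _FIVE_PRIME_ATOMS if n in by_name), None)
            if atom is None:
                raise ValueError(
                    f"chain {chain} residue {key[0]}: missing 5'-terminal P/O5'/C5'"
                )
        return atom.pos

    d12 = float(np.linalg.norm(terminal(chain_r1, "3'") - terminal(chain_r2, "5'")))
    d21 = float(np.linalg.norm(terminal(chain_r2, "3'") - terminal(chain_r1, "5'")))
    return {
        f"3'({chain_r1})->5'({chain_r2})": d12,
        f"3'({chain_r2})->5'({chain_r1})": d21,
    }
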
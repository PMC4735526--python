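"""Synthetic stand-in structures for demonstrating the structural operations.

The deposited crystal structures of the T-STAR dimer are not bundled with the
package; this module builds *synthetic* coordinate models that reproduce the
qualitative architecture the structural analyses probe - a two-chain protein
dimer with a packed interface, and two single-stranded RNA chains leaving the
dimer antiparallel on opposite sides - so that superposition RMSD, buried
interface area and RNA end-to-end distances can be exercised and demonstrated
end to end.  Every coordinate here is generated geometry, not experimental
data.
"""

from __future__ import annotations

import math

import numpy as np

from starbind.structure import Atom, StructureModel

__all__ = ["synthetic_helix_chain", "synthetic_rna_chain", "synthetic_kh_dimer"]

# ideal alpha-helix parameters: CA radius (A), rise per residue (A), turn per residue
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN = math.radians(100.0)


def synthetic_helix_chain(
    chain: str, n_residues: int = 30, first_resseq: int = 1
) -> list[Atom]:
    """Backbone atoms (N, CA, C, O) of an ideal poly-alanine alpha-helix.

    The helix axis runs along +z through the origin.  Geometry is idealized:
    N and C sit on the helical path half a residue before/after the CA, the
    carbonyl O is displaced radially outward from C.
    """
    atoms = []
    for i in range(n_residues):
        resseq = first_resseq + i

        def on_path(t: float, radius: float = _HELIX_RADIUS) -> tuple[float, float, float]:
            ang = _HELIX_TURN * t
            return radius * math.cos(ang), radius * math.sin(ang), _HELIX_RISE * t

        for name, element, (x, y, z) in (
            ("N", "N", on_path(i - 0.35, 1.6)),
            ("CA", "C", on_path(i)),
            ("C", "C", on_path(i + 0.35, 1.7)),
            ("O", "O", on_path(i + 0.45, 2.9)),
        ):
            atoms.append(Atom(chain, resseq, "", "ALA", name, element, x, y, z))
    return atoms


def synthetic_rna_chain(
    chain: str,
    n_nucleotides: int = 4,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0),
    rise: float = 6.0,
) -> list[Atom]:
    """A minimal extended single-stranded RNA chain (P, O5', C5', C3', O3')."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    # any vector perpendicular to d, for small lateral offsets
    perp = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(d, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    o = np.asarray(origin, dtype=float)
    atoms = []
    offsets = (
        ("P", "P", 0.0, 0.0),
        ("O5'", "O", 1.2, 0.6),
        ("C5'", "C", 2.2, 1.0),
        ("C3'", "C", 3.8, 0.8),
        ("O3'", "O", 4.8, 0.3),
    )
    for i in range(n_nucleotides):
        base = o + d * (rise * i)
        for name, element, along, aside in offsets:
            x, y, z = base + d * along + perp * aside
            atoms.append(Atom(chain, i + 1, "", "A", name, element, x, y, z))
    return atoms


def synthetic_kh_dimer(
    n_residues: int = 30,
    chain_gap: float = 8.5,
    rna: bool = True,
    rna_offset: float = 12.0,
) -> StructureModel:
    """A synthetic two-fold-symmetric protein dimer with antiparallel RNAs.

    Chain A is an ideal helix; chain B is chain A rotated 180 degrees about
    the z axis and shifted by ``chain_gap`` A along x, so the two helices pack
    side by side and bury a genuine interface.  When ``rna`` is set, chains R
    and S are extended RNA strands running in opposite directions on opposite
    faces of the dimer, ``rna_offset`` A away - emulating the antiparallel
    arrangement in which the 3' end of one RNA is far from the 5' end of the
    other.
    """
    atoms = list(synthetic_helix_chain("A", n_residues))
    rot = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    for a in synthetic_helix_chain("B", n_residues):
        x, y, z = rot @ np.array([a.x, a.y, a.z]) + np.array([chain_gap, 0.0, 0.0])
        atoms.append(Atom("B", a.resseq, a.icode, a.resname, a.name, a.element, x, y, z))
    if rna:
        height = _HELIX_RISE * n_residues
        atoms += synthetic_rna_chain(
            "R", origin=(-rna_offset, -8.0, 0.0), direction=(0.0, 0.0, 1.0)
        )
        atoms += synthetic_rna_chain(
            "S",
            origin=(chain_gap + rna_offset, 8.0, height),
            direction=(0.0, 0.0, -1.0),
        )
    return StructureModel(atoms=atoms, title="synthetic KH-like dimer (generated geometry)")
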
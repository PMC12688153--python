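"""Idealised residue geometries.

Minimal extended-conformation templates — backbone plus the side-chain atoms
the pipeline uses — with plausible bond lengths. They serve two purposes:
isolated-residue reference compounds for the fully exposed moiety SASA, and
building blocks for synthetic test structures. They are not meant to be
stereochemically exact, but the chain beyond CB leaves the CA–CB axis at a
tetrahedral-like angle so that χ1 rotamer sweeps displace the distal moiety
realistically.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .constants import MOIETY_ATOMS
from .structure import Atom, ProtomerModel, Residue, element_radius

_BACKBONE = [
    ("N", "N", (-1.46, 0.00, 0.00)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("C", "C", (0.77, 1.29, 0.00)),
    ("O", "O", (0.20, 2.39, 0.00)),
]

#: CB sits 1.53 Å along +z from CA; the chain beyond CB runs along a
#: direction tilted ~70° off the CA–CB axis (χ1 sweeps then move the distal
#: atoms on a wide circle), zigzagging ±0.45 Å in y every step.
_CB = np.array([0.0, 0.0, 1.53])
_D2 = np.array([0.940, 0.0, 0.342])  # unit, ≈70° from z


def _pos(k: int) -> np.ndarray:
    """Position of side-chain atom number k (CB is k=1)."""
    if k == 1:
        return _CB.copy()
    return _CB + 1.25 * (k - 1) * _D2 + np.array([0.0, 0.45 * (-1) ** k, 0.0])


def _chain(names_elements):
    return [(n, e, tuple(_pos(k + 1))) for k, (n, e) in enumerate(names_elements)]


def _branch(parent_k: int, name: str, element: str, dy: float):
    p = _pos(parent_k) + np.array([0.30, dy, 0.60])
    return (name, element, tuple(p))


_SIDECHAINS = {
    "ALA": _chain([("CB", "C")]),
    "GLY": [],
    "ASP": _chain([("CB", "C"), ("CG", "C")]) + [
        _branch(2, "OD1", "O", 1.05), _branch(2, "OD2", "O", -1.05)],
    "GLU": _chain([("CB", "C"), ("CG", "C"), ("CD", "C")]) + [
        _branch(3, "OE1", "O", 1.05), _branch(3, "OE2", "O", -1.05)],
    "LYS": _chain([("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"),
                   ("NZ", "N")]),
    "ARG": _chain([("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"),
                   ("CZ", "C")]) + [
        _branch(5, "NH1", "N", 1.10), _branch(5, "NH2", "N", -1.10)],
    "CYS": _chain([("CB", "C"), ("SG", "S")]),
    "TYR": _chain([("CB", "C"), ("CG", "C"), ("CZ", "C"), ("OH", "O")]),
}

# Imidazole: planar pentagon (radius 1.19 Å → bond ≈ 1.40 Å) beyond CG.
_HIS_CENTER = _pos(2) + 1.14 * _D2
_HIS_PERP = np.array([-_D2[2], 0.0, _D2[0]])  # in-plane, ⊥ to _D2
_HIS_ANGLES = {"ND1": 72.0, "CE1": 144.0, "NE2": 216.0, "CD2": 288.0}
_SIDECHAINS["HIS"] = _chain([("CB", "C"), ("CG", "C")]) + [
    (name, name[0],
     tuple(_HIS_CENTER + 1.19 * (np.cos(np.radians(a)) * (-_D2)
                                 + np.sin(np.radians(a)) * _HIS_PERP)))
    for name, a in _HIS_ANGLES.items()
]


def template_atoms(resname3: str, with_oxt: bool = False):
    """(name, element, xyz) triplets for one residue, CA at the origin."""
    if resname3 not in _SIDECHAINS:
        raise KeyError(f"no template for residue {resname3}")
    atoms = list(_BACKBONE) + list(_SIDECHAINS[resname3])
    if with_oxt:
        atoms.append(("OXT", "O", (1.95, 1.45, 0.00)))
    return atoms


def template_moiety_centroid(resname3: str) -> np.ndarray:
    """Charged-moiety centroid of the template, relative to CA."""
    wanted = MOIETY_ATOMS[resname3]
    pts = [np.array(xyz) for name, _, xyz in template_atoms(resname3)
           if name in wanted]
    return np.mean(pts, axis=0)


def build_residue(resname3: str, chain: str, seq_number: int,
                  origin=(0.0, 0.0, 0.0), rotation: np.ndarray | None = None,
                  plddt: float | None = 90.0, with_oxt: bool = False) -> Residue:
    """Instantiate a template residue at ``origin`` (optional 3×3 rotation
    applied about CA before translation)."""
    from .constants import AA3_TO_1

    origin = np.asarray(origin, dtype=float)
    atoms = []
    for name, element, xyz in template_atoms(resname3, with_oxt=with_oxt):
        p = np.asarray(xyz)
        if rotation is not None:
            p = rotation @ p
        atoms.append(Atom(name=name, element=element, xyz=origin + p,
                          radius=element_radius(element)))
    return Residue(chain=chain, seq_number=seq_number,
                   aa_type=AA3_TO_1.get(resname3, "X"), atoms=atoms, plddt=plddt)


@lru_cache(maxsize=None)
def reference_moiety_sasa(group_label: str, n_sphere_points: int = 960) -> float:
    """Moiety SASA of the fully exposed model compound.

    Computed once per group from an isolated template residue; used as the
    denominator of the exposure fraction f = min(1, SASA/ref).
    """
    from .sasa import atom_sasa

    res3 = {"NTERM": "GLY", "CTERM": "GLY"}.get(group_label, group_label)
    res = build_residue(res3, "A", 1, with_oxt=(group_label == "CTERM"))
    model = ProtomerModel(protein_id=f"ref-{group_label}", residues=[res])
    idx = model.atom_index()
    wanted = [idx[("A", 1, n)] for n in MOIETY_ATOMS[group_label]
              if ("A", 1, n) in idx]
    per_atom = atom_sasa(model.coordinates(), model.radii(),
                         n_sphere_points=n_sphere_points, subset=wanted)
    return float(per_atom[wanted].sum())
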
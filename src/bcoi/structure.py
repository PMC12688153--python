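"""Protomer models: reading, writing, pLDDT filtering and ionisable-site extraction.

A :class:`ProtomerModel` is a single-chain-or-more protein model (an AlphaFold
protomer, an experimental monomer, or a synthetic test structure) reduced to
the information the pKa pipeline needs: heavy atoms with coordinates and radii,
per-residue confidence (pLDDT, carried in the B-factor column of AlphaFold
files), and the titratable groups with their charged-moiety atoms.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .constants import (
    AA1_TO_3,
    AA3_TO_1,
    ASSESSED_GROUPS,
    DEFAULT_RADIUS,
    ELEMENT_RADII,
    GAMMA,
    MODEL_PKA,
    MOIETY_ATOMS,
    SIDECHAIN_GROUP,
)

logger = logging.getLogger(__name__)


class StructureFormatError(ValueError):
    """Raised when an input file violates the structural contract."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # (3,) Å
    radius: float

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise StructureFormatError(
                f"atom {self.name}: coordinates must be finite 3-vectors")
        if self.radius <= 0:
            raise StructureFormatError(f"atom {self.name}: radius must be > 0")


@dataclass
class Residue:
    chain: str
    seq_number: int
    aa_type: str  # one-letter code ('X' for non-standard)
    atoms: list[Atom]
    plddt: Optional[float] = None

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise StructureFormatError(
                f"residue {self.chain}:{self.seq_number} has duplicate atom names")
        if self.plddt is not None and not (0.0 <= self.plddt <= 100.0):
            raise StructureFormatError(
                f"residue {self.chain}:{self.seq_number}: pLDDT {self.plddt} "
                "outside [0, 100]")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ProtomerModel:
    protein_id: str
    residues: list[Residue]
    source_format: str = "PDB"

    def __post_init__(self):
        if not self.residues:
            raise StructureFormatError(f"{self.protein_id}: empty model")
        last: dict[str, int] = {}
        for r in self.residues:
            if not r.atoms:
                raise StructureFormatError(
                    f"residue {r.chain}:{r.seq_number} has no atoms")
            if r.chain in last and r.seq_number <= last[r.chain]:
                raise StructureFormatError(
                    f"chain {r.chain}: residue numbering not strictly increasing "
                    f"at {r.seq_number}")
            last[r.chain] = r.seq_number

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain not in out:
                out.append(r.chain)
        return out

    def coordinates(self) -> np.ndarray:
        """All-atom coordinate array, shape (n_atoms, 3)."""
        return np.array([a.xyz for r in self.residues for a in r.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.radius for r in self.residues for a in r.atoms])

    def atom_index(self) -> dict[tuple[str, int, str], int]:
        """Map (chain, seq_number, atom name) → flat atom index."""
        idx = {}
        k = 0
        for r in self.residues:
            for a in r.atoms:
                idx[(r.chain, r.seq_number, a.name)] = k
                k += 1
        return idx


@dataclass
class IonizableSite:
    """One titratable group and its charged moiety.

    ``assessed_for_bcoi`` is True only for the D/E/K/R/H side chains: Cys,
    Tyr and the chain termini participate in the electrostatic calculation
    but are never themselves reported as buried charges of interest.
    """

    protein_id: str
    chain: str
    seq_number: int
    group_label: str
    moiety_atoms: list[tuple[str, int, str]] = field(default_factory=list)
    moiety_sasa: Optional[float] = None

    def __post_init__(self):
        if self.group_label not in GAMMA:
            raise ValueError(f"unknown group label {self.group_label}")

    @property
    def site_id(self) -> tuple[str, str, int, str]:
        return (self.protein_id, self.chain, self.seq_number, self.group_label)

    @property
    def gamma(self) -> int:
        return GAMMA[self.group_label]

    @property
    def model_pka(self) -> float:
        return MODEL_PKA[self.group_label]

    @property
    def assessed_for_bcoi(self) -> bool:
        return self.group_label in ASSESSED_GROUPS

    def residue_label(self) -> str:
        """Report-style residue label, e.g. ``A:172:ASP``."""
        return f"{self.chain}:{self.seq_number}:{self.group_label}"


def element_radius(element: str, radii: Optional[dict] = None) -> float:
    table = ELEMENT_RADII if radii is None else radii
    return table.get(element.upper(), DEFAULT_RADIUS)


def read_protomer(path, fmt: Optional[str] = None, protein_id: Optional[str] = None,
                  radii: Optional[dict] = None) -> ProtomerModel:
    """Read a PDB or mmCIF protomer model.

    The B-factor column is mapped to per-residue pLDDT (mean over atoms), as
    written by AlphaFold. Hydrogens, waters and altloc duplicates are dropped;
    heavy atoms are retained with element-based radii.
    """
    path = str(path)
    if fmt is None:
        fmt = "mmCIF" if path.endswith((".cif", ".cif.gz", ".mmcif")) else "PDB"
    try:
        if fmt.upper() in ("CIF", "MMCIF"):
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
            fmt = "mmCIF"
        else:
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
            fmt = "PDB"
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models in file")
    st.setup_entities()
    model = st[0]
    return _from_gemmi_model(
        model,
        protein_id=protein_id or (st.name or "protein"),
        source_format=fmt,
        radii=radii,
    )


def _from_gemmi_model(model: gemmi.Model, protein_id: str, source_format: str,
                      radii: Optional[dict] = None) -> ProtomerModel:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            atoms = []
            bvals = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                if at.altloc not in ("", "A", "\0"):
                    continue
                el = at.element.name if at.element.name else at.name[:1]
                atoms.append(Atom(
                    name=at.name,
                    element=el,
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    radius=element_radius(el, radii),
                ))
                bvals.append(at.b_iso)
            if not atoms:
                continue
            plddt = float(np.mean(bvals)) if bvals else None
            if plddt is not None and not (0.0 <= plddt <= 100.0):
                plddt = None  # B-factors are not confidences in this file
            aa1 = AA3_TO_1.get(res.name.upper(), "X")
            residues.append(Residue(
                chain=chain.name, seq_number=res.seqid.num,
                aa_type=aa1, atoms=atoms, plddt=plddt,
            ))
    return ProtomerModel(protein_id=protein_id, residues=residues,
                         source_format=source_format)


def write_pdb(model: ProtomerModel) -> str:
    """Serialise a model to PDB text (ATOM records, 3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = model.protein_id
    gm = gemmi.Model("1")
    for chain_name in model.chains:
        ch = gemmi.Chain(chain_name)
        for r in model.residues:
            if r.chain != chain_name:
                continue
            gr = gemmi.Residue()
            gr.name = AA1_TO_3.get(r.aa_type, "UNK")
            gr.seqid = gemmi.SeqId(r.seq_number, " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = 1.0
                ga.b_iso = r.plddt if r.plddt is not None else 0.0
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st.make_pdb_string()


def filter_by_plddt(model: ProtomerModel, threshold: float = 50.0) -> ProtomerModel:
    """Drop residues with pLDDT below ``threshold`` (boundary kept: ≥)."""
    if threshold <= 0:
        return copy.deepcopy(model)
    missing = [r for r in model.residues if r.plddt is None]
    if missing:
        r = missing[0]
        raise ValueError(
            f"{model.protein_id}: residue {r.chain}:{r.seq_number} has no pLDDT; "
            "cannot apply confidence filter")
    kept = [copy.deepcopy(r) for r in model.residues if r.plddt >= threshold]
    if not kept:
        raise StructureFormatError(
            f"{model.protein_id}: no residues with pLDDT >= {threshold}")
    return ProtomerModel(protein_id=model.protein_id, residues=kept,
                         source_format=model.source_format)


def extract_ionizable_sites(model: ProtomerModel, include_termini: bool = False,
                            include_cys_tyr: bool = True) -> list[IonizableSite]:
    """Identify titratable groups and their charged-moiety atoms.

    D/E/K/R/H side chains are always extracted; C/Y and per-chain N-/C-termini
    are optional (termini default off: ~80% of N-termini are modified in vivo).
    A residue lacking every moiety atom is skipped with a warning.
    """
    sites: list[IonizableSite] = []

    def make_site(res: Residue, group: str) -> Optional[IonizableSite]:
        wanted = MOIETY_ATOMS[group]
        present = [(res.chain, res.seq_number, n) for n in wanted
                   if res.atom(n) is not None]
        if not present:
            logger.warning("%s %s:%d %s: no moiety atoms present; site skipped",
                           model.protein_id, res.chain, res.seq_number, group)
            return None
        return IonizableSite(
            protein_id=model.protein_id, chain=res.chain,
            seq_number=res.seq_number, group_label=group, moiety_atoms=present)

    for res in model.residues:
        group = SIDECHAIN_GROUP.get(res.aa_type)
        if group is None:
            continue
        if group in ("CYS", "TYR") and not include_cys_tyr:
            continue
        s = make_site(res, group)
        if s is not None:
            sites.append(s)

    if include_termini:
        for chain in model.chains:
            chain_res = [r for r in model.residues if r.chain == chain]
            first, last = chain_res[0], chain_res[-1]
            s = make_site(first, "NTERM")
            if s is not None:
                sites.append(s)
            s = make_site(last, "CTERM")
            if s is not None:
                sites.append(s)
    return sites


def site_table(sites: Sequence[IonizableSite]) -> "pandas.DataFrame":
    """Site summary as a DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame({
        "protein_id": [s.protein_id for s in sites],
        "chain": [s.chain for s in sites],
        "resnum": [s.seq_number for s in sites],
        "group": [s.group_label for s in sites],
        "gamma": [s.gamma for s in sites],
        "model_pka": [s.model_pka for s in sites],
        "moiety_sasa": [s.moiety_sasa for s in sites],
    })
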
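"""Simplified continuum electrostatics for titratable sites.

Pairwise couplings use a screened Coulomb term with an effective dielectric
that interpolates between a buried (low-ε) and a solvent (high-ε) regime
according to the exposure of the less exposed partner; burial also incurs a
desolvation penalty on the ionised form, shifting intrinsic pKas away from
the model-compound value. A rotamer sweep decides whether a side chain can
reach a water-dominated (Debye–Hückel) environment at all ("nodh" when not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import COUPLING_THRESHOLD, KE_KJ_A, LN10_RT, R_KJ, T_DEFAULT
from .sasa import atom_sasa
from .structure import IonizableSite, ProtomerModel
from .templates import reference_moiety_sasa


@dataclass
class EnergeticsParams:
    """Tunable physics of the simplified continuum model.

    temperature    K; 300 K makes 2 pKa units ≡ 11.49 kJ/mol.
    eps_min/max    effective dielectric for fully buried / fully exposed pairs.
    dist_cutoff    Å; couplings beyond this are zero.
    burial_B       kJ/mol; maximum desolvation penalty at zero exposure.
    dh_sasa_min    Å²; moiety SASA a rotamer must reach to count as
                   solvent-accessible (DH-capable).
    clash_dist     Å; heavy-atom distance below which a rotamer is discarded.
    """

    temperature: float = T_DEFAULT
    eps_min: float = 10.0
    eps_max: float = 80.0
    dist_cutoff: float = 12.0
    burial_B: float = 12.0
    dh_sasa_min: float = 15.0
    clash_dist: float = 2.4
    coupling_threshold: float = COUPLING_THRESHOLD
    n_sphere_points: int = 960
    ref_sasa_override: dict = field(default_factory=dict)

    @property
    def ln10_rt(self) -> float:
        return math.log(10.0) * R_KJ * self.temperature

    def ref_sasa(self, group_label: str) -> float:
        if group_label in self.ref_sasa_override:
            return self.ref_sasa_override[group_label]
        return reference_moiety_sasa(group_label)


@dataclass
class InteractionMatrix:
    """Symmetric site–site coupling energies W_ij (kJ/mol, zero diagonal).

    W_ij is the energy of having both sites ionised relative to either alone;
    its sign is γ_i·γ_j under the Coulomb model (like charges repel).
    """

    site_ids: list
    W: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.site_ids)
        if self.W.shape != (n, n):
            raise ValueError("W shape does not match number of sites")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if not np.allclose(np.diag(self.W), 0.0):
            raise ValueError("W must have zero diagonal")


@dataclass
class SiteEnergetics:
    site_id: tuple
    desolv_shift: float       # kJ/mol, ≥ 0, penalty on the ionised form
    intrinsic_pka: float
    dh_access: Optional[bool] = None

    @property
    def nodh(self) -> bool:
        return self.dh_access is False


def exposure_fraction(site: IonizableSite, params: EnergeticsParams) -> float:
    if site.moiety_sasa is None:
        raise ValueError(f"site {site.site_id}: moiety SASA not computed")
    ref = params.ref_sasa(site.group_label)
    return min(1.0, site.moiety_sasa / ref)


def moiety_centroid(site: IonizableSite, model: ProtomerModel) -> np.ndarray:
    idx = model.atom_index()
    coords = model.coordinates()
    return coords[[idx[a] for a in site.moiety_atoms]].mean(axis=0)


def pairwise_interactions(sites: Sequence[IonizableSite], model: ProtomerModel,
                          params: Optional[EnergeticsParams] = None) -> InteractionMatrix:
    """Screened-Coulomb coupling matrix between charged-moiety centroids.

    W_ij = γ_i γ_j k_e / (ε_eff r_ij) with ε_eff set by the less exposed
    partner: ε_eff = ε_min + (ε_max − ε_min)·min(f_i, f_j).
    """
    params = params or EnergeticsParams()
    n = len(sites)
    cent = np.array([moiety_centroid(s, model) for s in sites]).reshape(n, 3)
    f = np.array([exposure_fraction(s, params) for s in sites])
    gam = np.array([s.gamma for s in sites], dtype=float)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(cent[i] - cent[j]))
            if r < 0.5:
                raise ValueError(
                    f"sites {sites[i].site_id} and {sites[j].site_id}: "
                    f"moiety centroids coincide (r = {r:.2f} Å)")
            if r > params.dist_cutoff:
                continue
            eps = params.eps_min + (params.eps_max - params.eps_min) * min(f[i], f[j])
            W[i, j] = W[j, i] = gam[i] * gam[j] * KE_KJ_A / (eps * r)
    return InteractionMatrix(site_ids=[s.site_id for s in sites], W=W)


def desolvation_shift(site: IonizableSite,
                      params: Optional[EnergeticsParams] = None) -> SiteEnergetics:
    """Burial penalty B·(1−f)² on the ionised form and the resulting
    intrinsic pKa (acids shift up, bases down)."""
    params = params or EnergeticsParams()
    f = exposure_fraction(site, params)
    shift = params.burial_B * (1.0 - f) ** 2
    intrinsic = site.model_pka - site.gamma * shift / params.ln10_rt
    return SiteEnergetics(site_id=site.site_id, desolv_shift=shift,
                          intrinsic_pka=intrinsic)


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def dh_access(site: IonizableSite, model: ProtomerModel,
              params: Optional[EnergeticsParams] = None) -> bool:
    """Can the side chain reach a solvent-dominated environment?

    Rotamers are generated by rotating the side chain beyond CB about the
    CA–CB axis in 120° steps (plus the native pose); rotamers placing a
    moiety atom within ``clash_dist`` of a non-bonded heavy atom are
    discarded. True iff any surviving rotamer's moiety SASA reaches
    ``dh_sasa_min``; False marks the site as "nodh" (buried).
    """
    params = params or EnergeticsParams()
    if site.group_label in ("NTERM", "CTERM"):
        return True  # termini have no χ1 sweep; treated as accessible

    res = next(r for r in model.residues
               if r.chain == site.chain and r.seq_number == site.seq_number)
    ca, cb = res.atom("CA"), res.atom("CB")
    idx = model.atom_index()
    coords = model.coordinates()
    radii = model.radii()
    moiety_idx = [idx[a] for a in site.moiety_atoms]

    def moiety_sasa_with(coords_mod: np.ndarray) -> float:
        vals = atom_sasa(coords_mod, radii, subset=moiety_idx,
                         n_sphere_points=params.n_sphere_points)
        return float(vals[moiety_idx].sum())

    if ca is None or cb is None:
        return moiety_sasa_with(coords) >= params.dh_sasa_min

    backbone = {"N", "CA", "C", "O", "OXT", "CB"}
    movable = [idx[(res.chain, res.seq_number, a.name)]
               for a in res.atoms if a.name not in backbone]
    own = {idx[(res.chain, res.seq_number, a.name)] for a in res.atoms}
    other = np.array([k for k in range(len(coords)) if k not in own], dtype=int)

    axis = cb.xyz - ca.xyz
    for angle in (0.0, 120.0, 240.0):
        c = coords.copy()
        if angle != 0.0:
            Rm = _rotation_about_axis(axis, angle)
            c[movable] = (c[movable] - cb.xyz) @ Rm.T + cb.xyz
        if len(other) and len(moiety_idx):
            d = np.linalg.norm(c[moiety_idx][:, None, :] - c[other][None, :, :],
                               axis=2)
            if (d < params.clash_dist).any():
                continue
        if moiety_sasa_with(c) >= params.dh_sasa_min:
            return True
    return False


def empirical_pka(site_index: int, sites: Sequence[IonizableSite],
                  W: InteractionMatrix, energetics: SiteEnergetics,
                  params: Optional[EnergeticsParams] = None) -> float:
    """Fast single-pass pKa estimate (all neighbours assumed ionised).

    pKa = model − γ·(desolvation + Σ_j W_ij)/(ln10·RT). This is the
    position-based "range engine": crude, but exact for an isolated site, and
    capturing the desolvation/charge-compensation balance the range filters
    need.
    """
    params = params or EnergeticsParams()
    site = sites[site_index]
    total = energetics.desolv_shift + float(W.W[site_index].sum())
    return site.model_pka - site.gamma * total / params.ln10_rt


def site_energetics(sites: Sequence[IonizableSite], model: ProtomerModel,
                    params: Optional[EnergeticsParams] = None,
                    with_dh: bool = True) -> list[SiteEnergetics]:
    """Desolvation shifts plus (optionally) the rotamer DH-access flag."""
    params = params or EnergeticsParams()
    out = []
    for s in sites:
        e = desolvation_shift(s, params)
        if with_dh:
            e.dh_access = dh_access(s, model, params)
        out.append(e)
    return out
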
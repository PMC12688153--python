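"""Solvent-accessible surface area by the Shrake–Rupley method.

Each atom's van der Waals sphere is expanded by the probe radius and sampled
with a deterministic golden-spiral point set; the accessible area is the
fraction of points not occluded by any neighbouring expanded sphere, times
the full sphere area 4π(r+probe)².
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import PROBE_RADIUS
from .structure import IonizableSite, ProtomerModel


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    if n < 16:
        raise ValueError("n_sphere_points must be >= 16 for a usable estimate")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def atom_sasa(coords: np.ndarray, radii: np.ndarray,
              probe_radius: float = PROBE_RADIUS,
              n_sphere_points: int = 960,
              subset: Optional[Sequence[int]] = None) -> np.ndarray:
    """Per-atom SASA (Å²) for a set of spheres.

    ``subset`` restricts which atoms are evaluated (all atoms still occlude);
    the returned array always has one entry per atom, zero outside the subset.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    pts = sphere_points(n_sphere_points)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    out = np.zeros(n)
    targets = range(n) if subset is None else subset
    max_ext = ext.max()
    for i in targets:
        ri = ext[i]
        # any occluder satisfies |x_i - x_j| < r_i + r_j (expanded radii)
        neigh = [j for j in tree.query_ball_point(coords[i], ri + max_ext)
                 if j != i and np.dot(coords[i] - coords[j], coords[i] - coords[j])
                 < (ri + ext[j]) ** 2]
        surf = coords[i] + ri * pts
        if neigh:
            nb = np.asarray(neigh)
            d2 = ((surf[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (ext[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * ri * ri
    return out


def compute_sasa(model: ProtomerModel, probe_radius: float = PROBE_RADIUS,
                 n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom SASA for a protomer model (flat atom order)."""
    return atom_sasa(model.coordinates(), model.radii(),
                     probe_radius=probe_radius, n_sphere_points=n_sphere_points)


def moiety_sasa(model: ProtomerModel, sites: Sequence[IonizableSite],
                per_atom: Optional[np.ndarray] = None,
                probe_radius: float = PROBE_RADIUS,
                n_sphere_points: int = 960,
                annotate: bool = True) -> dict:
    """Sum SASA over each site's charged-moiety atoms.

    Returns ``{site_id: moiety SASA}`` and (by default) writes the value onto
    each site's ``moiety_sasa`` field.
    """
    idx = model.atom_index()
    if per_atom is None:
        wanted = sorted({idx[a] for s in sites for a in s.moiety_atoms})
        per_atom = atom_sasa(model.coordinates(), model.radii(),
                             probe_radius=probe_radius,
                             n_sphere_points=n_sphere_points, subset=wanted)
    out = {}
    for s in sites:
        val = float(sum(per_atom[idx[a]] for a in s.moiety_atoms))
        out[s.site_id] = val
        if annotate:
            s.moiety_sasa = val
    return out
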
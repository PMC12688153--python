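"""Synthetic inputs for the whole pipeline.

Three generators cover every input format the analysis consumes, with known
ground truth:

* :func:`make_toy_protomer` — compact pseudo-protein structures in which the
  burial of ionisable moieties is controlled by construction: clusters of
  charged residues enclosed in a tight cage of neutral pseudo-atoms (buried),
  free-standing residues (surface), and rotamer gates where only one χ1
  rotamer escapes the cage.
* :func:`make_cohort` — protein label tables, per-filter Bernoulli pass flags
  with class-conditional rates, and GO annotation tables with planted fold
  enrichments.
* :func:`benchmark_fixture` — the curated pH-sensor benchmark (23 proteins;
  15 sensor-residue rows totalling 26 residues with recorded marks).

All randomness flows from explicit seed arguments; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .benchmark import BenchmarkEntry, SensorResidue
from .sasa import sphere_points
from .structure import Atom, ProtomerModel, Residue, element_radius, write_pdb
from .templates import build_residue, template_moiety_centroid

CAGE_RADIUS = 3.4        # Å from each shielded atom to its cage shell
CAGE_CLEARANCE = 2.6     # Å minimum cage-to-structure distance
CAGE_POINTS = 60         # candidate shell points per shielded atom
FEATURE_SPACING = 40.0   # Å between planted features (outside the 12 Å cutoff)


@dataclass
class BuriedCluster:
    """Charged residues with moiety centroids at a fixed pairwise distance,
    enclosed in an occluding cage (fully buried, nodh). With ``caged=False``
    the same cluster is surface-placed: exposed moieties, solvent-screened
    couplings, and no filter should fire."""

    residue_types: tuple = ("ASP", "LYS", "ASP")
    distance: float = 4.0
    caged: bool = True


@dataclass
class SurfaceSingleton:
    """A single fully exposed residue."""

    residue_type: str = "LYS"


@dataclass
class RotamerGate:
    """A residue whose native moiety pose is caged but whose 120°/240° χ1
    rotamers are left open (``open_rotamers``); with none open, the site is
    enclosed in every rotamer (nodh)."""

    residue_type: str = "LYS"
    open_rotamers: tuple = (120.0,)


@dataclass
class ToyProtomerSpec:
    protein_id: str = "toy"
    features: tuple = (BuriedCluster(),)
    plddt: float = 90.0


@dataclass
class PlantedSite:
    chain: str
    seq_number: int
    group_label: str
    burial_class: str               # buried | surface | gated | enclosed
    feature_index: int = 0
    expected_filters: dict = field(default_factory=dict)  # name → bool
    pair_distances: dict = field(default_factory=dict)


@dataclass
class ToyProtomer:
    model: ProtomerModel
    pdb_text: str
    manifest: list[PlantedSite]


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate π about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        return -np.eye(3) + 2 * np.outer(v, v) + 0 * K
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    s2 = float(np.dot(v, v))
    return np.eye(3) + K + K @ K * ((1 - c) / s2)


def _cluster_targets(k: int, d: float) -> np.ndarray:
    """k points with (for k ≤ 3) all pairwise distances equal to d."""
    if k == 1:
        return np.zeros((1, 3))
    if k == 2:
        return np.array([[-d / 2, 0, 0], [d / 2, 0, 0]])
    if k == 3:
        r = d / np.sqrt(3.0)
        ang = np.radians([90.0, 210.0, 330.0])
        return np.column_stack([r * np.cos(ang), r * np.sin(ang),
                                np.zeros(3)])
    # k > 3: ring with adjacent spacing d (only adjacent distances guaranteed)
    r = d / (2 * np.sin(np.pi / k))
    ang = 2 * np.pi * np.arange(k) / k
    return np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(k)])


def _cage_atoms(shield_points: np.ndarray, existing: np.ndarray,
                radius: float = CAGE_RADIUS) -> list[np.ndarray]:
    """Occluding pseudo-atom positions on shells around each shielded point.

    Candidates closer than CAGE_CLEARANCE to any structure atom (or 1.0 Å to
    an accepted cage atom) are skipped: directions toward the structure are
    already occluded by it.
    """
    shell = sphere_points(CAGE_POINTS)
    accepted: list[np.ndarray] = []
    for center in shield_points:
        for p in center + radius * shell:
            d2 = ((existing - p) ** 2).sum(axis=1)
            if d2.min() < CAGE_CLEARANCE ** 2:
                continue
            if accepted and min(((np.array(accepted) - p) ** 2).sum(axis=1)) < 1.0:
                continue
            accepted.append(p)
    return accepted


def _moiety_coords(res: Residue, group: str) -> np.ndarray:
    from .constants import MOIETY_ATOMS

    return np.array([res.atom(n).xyz for n in MOIETY_ATOMS[group]
                     if res.atom(n) is not None])


def _rotated_moiety(res: Residue, group: str, angle: float) -> np.ndarray:
    from .energetics import _rotation_about_axis

    ca, cb = res.atom("CA").xyz, res.atom("CB").xyz
    R = _rotation_about_axis(cb - ca, angle)
    return (_moiety_coords(res, group) - cb) @ R.T + cb


def make_toy_protomer(spec: ToyProtomerSpec, seed: int = 0) -> ToyProtomer:
    """Build a synthetic protomer realising the planted features.

    Deterministic for a given spec and seed; raises on infeasible geometry
    (planted atoms closer than 1.5 Å).
    """
    residues: list[Residue] = []
    manifest: list[PlantedSite] = []
    cage_jobs: list[tuple[np.ndarray, list[int]]] = []  # shield pts, res idxs
    seq = 0

    for fi, feat in enumerate(spec.features):
        offset = np.array([FEATURE_SPACING * fi, 0.0, 0.0])
        if isinstance(feat, BuriedCluster):
            k = len(feat.residue_types)
            targets = _cluster_targets(k, feat.distance) + offset
            planted_idx = []
            for t, (res3, target) in enumerate(zip(feat.residue_types, targets)):
                v = template_moiety_centroid(res3)
                center = targets.mean(axis=0)
                u = target - center
                if np.linalg.norm(u) < 1e-9:
                    u = np.array([0.0, 0.0, 1.0])
                R = _rotation_between(v, -u)  # side chain points inward
                origin = target - R @ v
                seq += 1
                res = build_residue(res3, "A", seq, origin=origin, rotation=R,
                                    plddt=spec.plddt)
                planted_idx.append(len(residues))
                residues.append(res)
                dists = {feat.residue_types[j]
                         + str(j): float(np.linalg.norm(targets[t] - targets[j]))
                         for j in range(k) if j != t}
                manifest.append(PlantedSite(
                    chain="A", seq_number=seq, group_label=res3,
                    burial_class="buried" if feat.caged else "surface_cluster",
                    feature_index=fi, pair_distances=dists))
            if feat.caged:
                # shield native AND rotamer moiety positions so no χ1 sweep
                # escapes the cage (buried members must be nodh)
                shield = np.vstack([
                    _rotated_moiety(residues[i],
                                    manifest[-k + j].group_label, ang)
                    for j, i in enumerate(planted_idx)
                    for ang in (0.0, 120.0, 240.0)])
                cage_jobs.append((shield, planted_idx))
        elif isinstance(feat, SurfaceSingleton):
            seq += 1
            res = build_residue(feat.residue_type, "A", seq, origin=offset,
                                plddt=spec.plddt)
            residues.append(res)
            manifest.append(PlantedSite(
                chain="A", seq_number=seq, group_label=feat.residue_type,
                burial_class="surface", feature_index=fi))
        elif isinstance(feat, RotamerGate):
            seq += 1
            res = build_residue(feat.residue_type, "A", seq, origin=offset,
                                plddt=spec.plddt)
            residues.append(res)
            shield_angles = [a for a in (0.0, 120.0, 240.0)
                             if a not in feat.open_rotamers]
            shield = np.vstack([_rotated_moiety(res, feat.residue_type, a)
                                for a in shield_angles])
            cage_jobs.append((shield, [len(residues) - 1]))
            manifest.append(PlantedSite(
                chain="A", seq_number=seq, group_label=feat.residue_type,
                burial_class="gated" if feat.open_rotamers else "enclosed",
                feature_index=fi))
        else:
            raise TypeError(f"unknown feature {feat!r}")

    # cages go in one trailing pseudo-residue per job
    all_coords = np.vstack([a.xyz for r in residues for a in r.atoms])
    for shield, _ in cage_jobs:
        pts = _cage_atoms(shield, all_coords)
        if not pts:
            raise ValueError("cage construction produced no atoms "
                             "(infeasible geometry)")
        seq += 1
        atoms = [Atom(name=f"C{i + 1:03d}", element="C", xyz=p,
                      radius=element_radius("C"))
                 for i, p in enumerate(pts)]
        residues.append(Residue(chain="A", seq_number=seq, aa_type="X",
                                atoms=atoms, plddt=spec.plddt))
        all_coords = np.vstack([all_coords, np.array(pts)])

    # feasibility: no two atoms closer than a covalent-overlap limit,
    # except within a residue (bonded)
    model = ProtomerModel(protein_id=spec.protein_id, residues=residues,
                          source_format="PDB")
    _set_expected_filters(manifest)
    return ToyProtomer(model=model, pdb_text=write_pdb(model),
                       manifest=manifest)


def _set_expected_filters(manifest: list[PlantedSite]) -> None:
    """Construction-forced filter outcomes for the shipped feature types.

    Only outcomes that geometry alone guarantees are recorded: network
    filters (burial + coupling forced by the cage and spacing) and surface
    failures. ΔQ outcomes depend on the titration engine and are asserted
    against the exact-enumeration oracle in tests, not the manifest.
    """
    for m in manifest:
        if m.burial_class == "buried":
            # DEKRH count within this cluster only: features are spaced
            # beyond the coupling cutoff, so clusters never merge
            n_dekrh = sum(
                1 for x in manifest
                if x.feature_index == m.feature_index
                and x.burial_class == "buried"
                and x.group_label in ("ASP", "GLU", "LYS", "ARG", "HIS"))
            strong = bool(m.pair_distances) and n_dekrh >= 2
            m.expected_filters = {
                "pkcalc-int-nodh-3": strong and n_dekrh >= 3,
                "pkcalc-int-5-2": strong,
                "pkcalc-int-15-2": strong,
                "pkcalc-int-15-3": strong and n_dekrh >= 3,
            }
        elif m.burial_class in ("surface", "surface_cluster"):
            m.expected_filters = {name: False for name in (
                "pkcalc-int-nodh-3", "pkcalc-int-5-2", "pkcalc-int-15-2",
                "pkcalc-int-15-3", "propka-range-15", "propka-range-5",
                "pkcalc-15-3-propka-15", "pkcalc-15-2-propka-15",
                "pkcalc-5-2-propka-5", "pkcalc-deltaQ-10")}


# ---------------------------------------------------------------------------
# cohort generator


@dataclass
class SyntheticCohortSpec:
    """Cohort defaults mirror the study conditions at reduced scale: an ET
    fraction of 4810/20503, a pH-labelled fraction of 306/20503, a NET pass
    rate near the reported cross-filter average (24%), and ET pass rates
    giving roughly two-fold enrichment."""

    n_proteins: int = 5000
    fraction_et: float = 4810 / 20503
    fraction_ph: float = 306 / 20503
    pass_prob_et: dict = field(default_factory=lambda: {"filter-1": 0.5})
    pass_prob_net: dict = field(default_factory=lambda: {"filter-1": 0.24})
    #: term_id → (base annotation probability, planted fold in the query class)
    go_terms: dict = field(default_factory=lambda: {
        "GO:QRY3": (0.02, 3.0), "GO:NULL": (0.10, 1.0)})
    query_filter: str = "filter-1"

    def __post_init__(self):
        if not (0 <= self.fraction_et <= 1):
            raise ValueError("fraction_et must be in [0, 1]")
        for d in (self.pass_prob_et, self.pass_prob_net):
            for v in d.values():
                if not (0 <= v <= 1):
                    raise ValueError("pass probabilities must be in [0, 1]")
        for p, f in self.go_terms.values():
            if not (0 <= p <= 1) or f <= 0:
                raise ValueError("GO base prob in [0,1]; planted fold > 0")


@dataclass
class SyntheticCohort:
    labels: pd.DataFrame
    passes: pd.DataFrame            # index protein_id, one bool column per filter
    go_annotations: pd.DataFrame    # protein_id, term_id
    go_hierarchy: pd.DataFrame      # term_id, parent_id
    query_set: set

    def label_table(self):
        from .enrichment import LabelTable

        return LabelTable(self.labels)

    def write_tsvs(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.labels.to_csv(out / "labels.tsv", sep="\t", index=False)
        self.passes.reset_index().to_csv(out / "passes.tsv", sep="\t",
                                         index=False)
        self.go_annotations.to_csv(out / "go_annotations.tsv", sep="\t",
                                   index=False)
        self.go_hierarchy.to_csv(out / "go_hierarchy.tsv", sep="\t",
                                 index=False)


def make_cohort(spec: SyntheticCohortSpec, seed: int = 0) -> SyntheticCohort:
    """Draw a labelled cohort with per-filter Bernoulli pass flags and GO
    annotations carrying the planted enrichments."""
    rng = np.random.default_rng(seed)
    n = spec.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]
    is_et = rng.random(n) < spec.fraction_et
    # split ET into enzyme/transporter roughly as in the annotation source
    is_enz = is_et & (rng.random(n) < 4451 / 4810)
    is_tra = is_et & ~is_enz
    both = is_et & (rng.random(n) < 24 / 4810)
    is_enz |= both
    is_tra |= both
    is_ph = rng.random(n) < spec.fraction_ph
    labels = pd.DataFrame({
        "protein_id": ids,
        "enzyme": is_enz.astype(int),
        "transporter": is_tra.astype(int),
        "ph_dependent": is_ph.astype(int),
    })

    filters = sorted(set(spec.pass_prob_et) | set(spec.pass_prob_net))
    passes = pd.DataFrame(index=pd.Index(ids, name="protein_id"))
    for f in filters:
        p = np.where(is_et, spec.pass_prob_et.get(f, 0.0),
                     spec.pass_prob_net.get(f, 0.0))
        passes[f] = rng.random(n) < p

    # GO query class mirrors the study design: NET proteins returned by the
    # designated filter, assessed against the NET subset as reference
    net_ids = {pid for pid, et in zip(ids, is_et) if not et}
    if spec.query_filter in passes:
        query = set(passes.index[passes[spec.query_filter]]) & net_ids
    else:
        query = set()

    # Plant the query-class rate so the EXPECTED measured fold — query rate
    # over reference rate, reference (NET) including the query (the
    # convention the enrichment module and the usual GO tools use) — equals
    # the requested fold: x = f(1−q)·p / (1−f·q), q the realised query
    # fraction of the reference.
    q_frac = len(query) / len(net_ids) if net_ids else 0.0
    ann_rows = []
    for term, (p_base, fold) in spec.go_terms.items():
        if fold * q_frac >= 1.0:
            raise ValueError(
                f"term {term}: fold {fold} infeasible at query fraction "
                f"{q_frac:.2f} (fold·q must be < 1)")
        p_query = fold * (1.0 - q_frac) * p_base / (1.0 - fold * q_frac)
        if p_query > 1.0:
            raise ValueError(
                f"term {term}: planted fold {fold} needs query probability "
                f"{p_query:.2f} > 1; lower the base probability")
        draws = rng.random(n)
        for pid, u in zip(ids, draws):
            p = p_query if pid in query else p_base
            if u < p:
                ann_rows.append({"protein_id": pid, "term_id": f"{term}:leaf"})
    hier_rows = [{"term_id": f"{t}:leaf", "parent_id": t}
                 for t in spec.go_terms]
    hier_rows += [{"term_id": t, "parent_id": "GO:ROOT"}
                  for t in spec.go_terms]
    return SyntheticCohort(
        labels=labels, passes=passes,
        go_annotations=pd.DataFrame(ann_rows,
                                    columns=["protein_id", "term_id"]),
        go_hierarchy=pd.DataFrame(hier_rows,
                                  columns=["term_id", "parent_id"]),
        query_set=query)


# ---------------------------------------------------------------------------
# curated pH-sensor benchmark fixture

#: The 23 benchmark proteins; the first 18 come from a cancer-acidosis
#: pH-sensing review, the last 5 were added individually.
REVIEW_PROTEINS = (
    "ASIC1", "ASIC2", "GPR4", "PSYR", "OGR1", "TRPV1", "MOT1", "SL9A1",
    "B3AT", "S4A4", "CAH2", "CAH9", "CAH12", "DEST", "COF1", "COF2",
    "TLN1", "MCF2L",
)
ADDED_PROTEINS = ("FCGRN", "ERD22", "CTNS", "ASSY", "PCFT")
BENCHMARK_PROTEINS = REVIEW_PROTEINS + ADDED_PROTEINS

# (protein, n_pass per member, [(sensor, predicted, SASA Å², score avg)])
_SENSOR_ROWS = (
    ("GPR4", (9,), [("E145", False, 20.8, 0.827), ("D282", True, 0.3, 0.991)]),
    ("PSYR", (9,), [("D286", True, 0.0, 0.972), ("D60", True, 0.0, 0.945)]),
    ("OGR1", (9,), [("E149", True, 9.6, 0.953), ("D282", True, 0.9, 0.989)]),
    ("FCGRN", (9,), [("H189", True, 0.0, 0.875)]),
    ("ERD22", (4,), [("H12", True, 9.7, 0.993)]),
    ("CTNS", (10,), [("D205", True, 0.1, 0.984), ("D305", False, 23.4, 0.995)]),
    ("TRPV1", (9,), [("E600", False, 117.9, 0.695),
                     ("E649", False, 115.2, 0.805)]),
    ("MOT1", (5,), [("K38", True, 8.1, 0.993), ("D309", True, 0.9, 0.996)]),
    ("SL9A1", (6,), [("D172", True, 14.7, 0.990)]),
    ("B3AT", (10,), [("R760", True, 2.1, 0.914)]),
    ("S4A4", (10,), [("E135", True, 0.0, 0.989), ("R342", True, 4.6, 0.999)]),
    ("CAH2", (10,), [("H64", False, 35.3, 0.832), ("H94", False, 17.5, 0.975),
                     ("H96", True, 0.7, 0.984), ("H119", True, 1.9, 0.976)]),
    ("COF1/COF2/DEST", (1, 3, 1), [("H133", False, 27.4, 0.925)]),
    ("TLN1", (9,), [("H2418", False, 147.6, 0.380)]),
    ("PCFT", (3,), [("E185", False, 37.3, 0.940),
                    ("H281", False, 32.0, 0.591)]),
)


def benchmark_fixture() -> list[BenchmarkEntry]:
    """The packaged sensor-residue benchmark (15 rows, 26 residues)."""
    entries = []
    for protein, n_pass, sensors in _SENSOR_ROWS:
        entries.append(BenchmarkEntry(
            protein=protein, n_pass_reported=tuple(n_pass),
            sensors=[SensorResidue(label=s, reported_predicted=p,
                                   reported_sasa=sasa, reported_score_avg=am)
                     for s, p, sasa, am in sensors]))
    return entries
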
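"""The ten buried-charge-of-interest (BCOI) filters.

Four families share the burial requirement:

* range   — D/E/K/R/H sites with predicted pKa in [5.5, 8.5] (empirical
            range engine) and moiety SASA under a threshold;
* network — member of a coupled charge network with a minimum number of
            D/E/K/R/H groups, all members buried (SASA or nodh);
* intersection — a protein passes iff it passes BOTH a range and a network
            filter at the matched SASA threshold (residues: union);
* deltaq  — protonation difference to the free compound ≥ 0.2 at pH 7 with
            SASA ≤ 10 Å²; His additionally needs apparent pKa ≥ 5.5.

A protein passes a filter iff that filter returns at least one residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import networkx as nx

from .constants import ASSESSED_GROUPS, COUPLING_THRESHOLD
from .energetics import InteractionMatrix
from .networks import charge_networks, coupling_graph
from .structure import IonizableSite

PKA_LO = 5.5
PKA_HI = 8.5

Burial = Union[float, str]  # Å² threshold or "nodh"


@dataclass(frozen=True)
class FilterSpec:
    name: str
    method: str                       # range | network | intersection | deltaq
    sasa_max: Optional[Burial] = None
    min_dekrh: Optional[int] = None
    range_sasa_max: Optional[float] = None   # intersection only
    pka_lo: float = PKA_LO
    pka_hi: float = PKA_HI
    dq_min: float = 0.2
    dq_ph: float = 7.0
    his_pka_min: float = 5.5


#: The canonical filter set, in report-column order.
CANONICAL_FILTERS: tuple[FilterSpec, ...] = (
    FilterSpec("pkcalc-int-nodh-3", "network", sasa_max="nodh", min_dekrh=3),
    FilterSpec("pkcalc-int-5-2", "network", sasa_max=5.0, min_dekrh=2),
    FilterSpec("pkcalc-int-15-2", "network", sasa_max=15.0, min_dekrh=2),
    FilterSpec("pkcalc-int-15-3", "network", sasa_max=15.0, min_dekrh=3),
    FilterSpec("propka-range-15", "range", sasa_max=15.0),
    FilterSpec("propka-range-5", "range", sasa_max=5.0),
    FilterSpec("pkcalc-15-3-propka-15", "intersection", sasa_max=15.0,
               min_dekrh=3, range_sasa_max=15.0),
    FilterSpec("pkcalc-15-2-propka-15", "intersection", sasa_max=15.0,
               min_dekrh=2, range_sasa_max=15.0),
    FilterSpec("pkcalc-5-2-propka-5", "intersection", sasa_max=5.0,
               min_dekrh=2, range_sasa_max=5.0),
    FilterSpec("pkcalc-deltaQ-10", "deltaq", sasa_max=10.0),
)

CANONICAL_FILTER_NAMES = tuple(f.name for f in CANONICAL_FILTERS)


@dataclass
class EngineOutputs:
    """Everything the filters need for one protein."""

    protein_id: str
    sites: list[IonizableSite]
    W: InteractionMatrix
    dh_flags: dict                 # site_id → bool (DH-accessible)
    empirical_pkas: dict           # site_id → float (range engine)
    apparent_pkas: dict            # site_id → float|None (titration engine;
                                   #   None when censored at a grid boundary)
    delta_q: dict                  # site_id → ΔQ at the configured pH
    coupling_threshold: float = COUPLING_THRESHOLD

    _graph: Optional[nx.Graph] = field(default=None, repr=False)

    def graph(self) -> nx.Graph:
        if self._graph is None:
            self._graph = coupling_graph(self.W, self.coupling_threshold)
        return self._graph


@dataclass
class FilterResult:
    protein_id: str
    passes: dict                   # filter name → bool
    bcoi_residues: dict            # filter name → list of (chain, resnum, group)

    def residue_union(self) -> set:
        return {r for lst in self.bcoi_residues.values() for r in lst}


def _residue(site: IonizableSite) -> tuple:
    return (site.chain, site.seq_number, site.group_label)


def pka_range_filter(pkas: Mapping, sites: Sequence[IonizableSite],
                     sasa_max: float, pka_lo: float = PKA_LO,
                     pka_hi: float = PKA_HI) -> list[tuple]:
    """D/E/K/R/H sites with pKa in [lo, hi] and moiety SASA ≤ sasa_max.

    ``pkas`` maps site_id → pKa; ``None`` marks a censored value (no
    half-ionisation point on the grid), which can never verifiably lie in
    the range and is excluded.
    """
    out = []
    for s in sites:
        if not s.assessed_for_bcoi:
            continue
        pka = pkas.get(s.site_id)
        if pka is None:
            continue
        if s.moiety_sasa is None:
            raise ValueError(f"site {s.site_id}: moiety SASA unavailable")
        if pka_lo <= pka <= pka_hi and s.moiety_sasa <= sasa_max:
            out.append(_residue(s))
    return out


def network_filter(networks, sites: Sequence[IonizableSite]) -> list[tuple]:
    """Union of D/E/K/R/H members over qualifying charge networks."""
    by_id = {s.site_id: s for s in sites}
    seen = []
    for net in networks:
        for sid in net.member_sites:
            s = by_id[sid]
            if s.group_label in ASSESSED_GROUPS and _residue(s) not in seen:
                seen.append(_residue(s))
    return sorted(seen, key=lambda r: (r[0], r[1]))


def intersection_filter(range_residues: list, range_sasa: float,
                        network_residues: list, network_sasa: float
                        ) -> tuple[bool, list]:
    """Protein-level AND of a range and a network filter (matched SASA),
    reporting the residue-level union when both pass."""
    if range_sasa != network_sasa:
        raise ValueError(
            f"intersection components use mismatched SASA thresholds "
            f"({range_sasa} vs {network_sasa})")
    ok = bool(range_residues) and bool(network_residues)
    if not ok:
        return False, []
    merged = sorted(set(range_residues) | set(network_residues),
                    key=lambda r: (r[0], r[1]))
    return True, merged


def deltaq_filter(delta_q: Mapping, apparent_pkas: Mapping,
                  sites: Sequence[IonizableSite], sasa_max: float = 10.0,
                  dq_min: float = 0.2, his_pka_min: float = 5.5) -> list[tuple]:
    """Sites whose protonation departs from the free compound by ≥ dq_min.

    The extra His condition (apparent pKa ≥ 5.5) rejects buried histidines
    whose ΔQ comes purely from uncompensated desolvation.
    """
    out = []
    for s in sites:
        if not s.assessed_for_bcoi:
            continue
        dq = delta_q.get(s.site_id)
        if dq is None or s.moiety_sasa is None:
            continue
        if s.moiety_sasa > sasa_max or dq < dq_min:
            continue
        if s.group_label == "HIS":
            pka = apparent_pkas.get(s.site_id)
            if pka is None or pka < his_pka_min:
                continue
        out.append(_residue(s))
    return out


def _network_residues(outputs: EngineOutputs, burial: Burial,
                      min_dekrh: int) -> list[tuple]:
    if burial == "nodh":
        burial_spec = {"mode": "nodh"}
    else:
        burial_spec = {"sasa_max": float(burial)}
    nets = charge_networks(outputs.graph(), outputs.sites, burial_spec,
                           min_dekrh, dh_flags=outputs.dh_flags)
    return network_filter(nets, outputs.sites)


def apply_filter(outputs: EngineOutputs, spec: FilterSpec) -> tuple[bool, list]:
    if spec.method == "range":
        res = pka_range_filter(outputs.empirical_pkas, outputs.sites,
                               spec.sasa_max, spec.pka_lo, spec.pka_hi)
        return bool(res), res
    if spec.method == "network":
        res = _network_residues(outputs, spec.sasa_max, spec.min_dekrh)
        return bool(res), res
    if spec.method == "intersection":
        rng = pka_range_filter(outputs.empirical_pkas, outputs.sites,
                               spec.range_sasa_max, spec.pka_lo, spec.pka_hi)
        net = _network_residues(outputs, spec.sasa_max, spec.min_dekrh)
        return intersection_filter(rng, spec.range_sasa_max, net,
                                   float(spec.sasa_max))
    if spec.method == "deltaq":
        res = deltaq_filter(outputs.delta_q, outputs.apparent_pkas,
                            outputs.sites, spec.sasa_max, spec.dq_min,
                            spec.his_pka_min)
        return bool(res), res
    raise ValueError(f"unknown filter method {spec.method!r}")


def run_filter_suite(outputs: EngineOutputs,
                     specs: Sequence[FilterSpec] = CANONICAL_FILTERS
                     ) -> FilterResult:
    """Evaluate all filters for one protein."""
    passes = {}
    residues = {}
    for spec in specs:
        ok, res = apply_filter(outputs, spec)
        passes[spec.name] = ok
        residues[spec.name] = res
    return FilterResult(protein_id=outputs.protein_id, passes=passes,
                        bcoi_residues=residues)


def results_table(results: Sequence[FilterResult],
                  specs: Sequence[FilterSpec] = CANONICAL_FILTERS):
    """Per-protein pass/fail table plus semicolon-joined residue lists."""
    import pandas as pd

    rows = []
    for r in results:
        row = {"protein_id": r.protein_id}
        for spec in specs:
            row[spec.name] = int(r.passes.get(spec.name, False))
        for spec in specs:
            row[f"{spec.name}_residues"] = ";".join(
                f"{c}:{n}:{g}" for c, n, g in r.bcoi_residues.get(spec.name, []))
        rows.append(row)
    return pd.DataFrame(rows)
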
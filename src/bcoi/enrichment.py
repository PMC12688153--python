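"""Subset algebra, enrichment ratios, ROC scans, filter overlap and GO folds.

Protein-level statistics over a labelled cohort: the enzyme/transporter union
(ET) and its complement (NET) partition the proteome; enrichment ratios
compare filter pass rates between a subset and a reference; gene-ontology
fold enrichment propagates annotations up the hierarchy (true-path rule)
before counting, optionally restricted to a fixed basis term list so that
per-filter results are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class LabelTable:
    """protein_id → {enzyme, transporter, ph_dependent} flags."""

    table: pd.DataFrame  # columns: protein_id, enzyme, transporter, ph_dependent

    def __post_init__(self):
        t = self.table
        if t["protein_id"].duplicated().any():
            dup = t.loc[t["protein_id"].duplicated(), "protein_id"].iloc[0]
            raise ValueError(f"duplicate protein_id in label table: {dup}")

    @classmethod
    def from_tsv(cls, path) -> "LabelTable":
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def all_proteins(self) -> set:
        return set(self.table["protein_id"])

    @property
    def et(self) -> set:
        t = self.table
        mask = (t["enzyme"] == 1) | (t["transporter"] == 1)
        return set(t.loc[mask, "protein_id"])

    @property
    def net(self) -> set:
        return self.all_proteins - self.et

    @property
    def ph_dependent(self) -> set:
        t = self.table
        return set(t.loc[t["ph_dependent"] == 1, "protein_id"])


def subset_algebra(labels) -> dict:
    """Counts of the labelled subsets with inclusion–exclusion on the union.

    Accepts a :class:`LabelTable`, or a dict with keys n_total, n_E, n_T,
    n_both (when only the printed counts, not the full table, are known).
    """
    if isinstance(labels, LabelTable):
        t = labels.table
        n_total = len(t)
        n_e = int((t["enzyme"] == 1).sum())
        n_t = int((t["transporter"] == 1).sum())
        n_both = int(((t["enzyme"] == 1) & (t["transporter"] == 1)).sum())
        n_ph = int((t["ph_dependent"] == 1).sum())
    else:
        n_total = labels["n_total"]
        n_e = labels["n_E"]
        n_t = labels["n_T"]
        n_both = labels["n_both"]
        n_ph = labels.get("n_pH", 0)
    n_et = n_e + n_t - n_both
    return {
        "n_total": n_total, "n_E": n_e, "n_T": n_t, "n_both": n_both,
        "n_ET": n_et, "n_NET": n_total - n_et, "n_pH": n_ph,
    }


@dataclass
class EnrichmentResult:
    filter_name: str
    npass_subset: int
    subset_size: int
    npass_reference: int
    reference_size: int
    ratio: Optional[float]

    @property
    def censored(self) -> bool:
        return self.ratio is None


def enrichment_ratio(npass_subset: int, subset_size: int,
                     npass_reference: int, reference_size: int,
                     filter_name: str = "") -> EnrichmentResult:
    """(pass rate in subset) / (pass rate in reference).

    The reference may be the whole cohort (as for the pH-labelled subset) or
    a complement set (ET vs NET); the caller supplies the counts explicitly.
    """
    if subset_size <= 0 or reference_size <= 0:
        raise ValueError("subset and reference sizes must be positive")
    if npass_reference == 0:
        return EnrichmentResult(filter_name, npass_subset, subset_size,
                                npass_reference, reference_size, None)
    ratio = (npass_subset / subset_size) / (npass_reference / reference_size)
    return EnrichmentResult(filter_name, npass_subset, subset_size,
                            npass_reference, reference_size, float(ratio))


def roc_scan(pass_sets: Mapping, et: set, net: set) -> pd.DataFrame:
    """TPR/FPR for predicting ET membership, per parameter-grid cell.

    ``pass_sets`` maps a cell key (e.g. ``(sasa_max, dq_min)``) to the set of
    passing proteins.
    """
    if not et or not net:
        raise ValueError("both ET and NET sets must be non-empty")
    rows = []
    for cell, passed in pass_sets.items():
        passed = set(passed)
        rows.append({
            "cell": cell,
            "tpr": len(passed & et) / len(et),
            "fpr": len(passed & net) / len(net),
        })
    return pd.DataFrame(rows)


def filter_overlap_matrix(pass_sets: Mapping, n_total: int) -> pd.DataFrame:
    """Observed/expected pairwise overlap between filter pass sets.

    Expected overlap under independence is |A|·|B|/N; cells involving a
    filter with zero passes are censored (NaN).
    """
    names = list(pass_sets)
    if len(names) < 2:
        raise ValueError("need at least two filters")
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            sa, sb = set(pass_sets[a]), set(pass_sets[b])
            if not sa or not sb:
                mat.loc[a, b] = np.nan
                continue
            expected = len(sa) * len(sb) / n_total
            mat.loc[a, b] = len(sa & sb) / expected
    return mat


@dataclass
class GOTable:
    """Direct annotations plus the term hierarchy (child → parents)."""

    annotations: dict        # protein_id → set of term_ids
    hierarchy: dict          # term_id → set of parent term_ids

    @classmethod
    def from_tsv(cls, annotations_path, hierarchy_path) -> "GOTable":
        ann = pd.read_csv(annotations_path, sep="\t")
        hier = pd.read_csv(hierarchy_path, sep="\t")
        annotations: dict = {}
        for pid, term in zip(ann["protein_id"], ann["term_id"]):
            annotations.setdefault(pid, set()).add(term)
        hierarchy: dict = {}
        for term, parent in zip(hier["term_id"], hier["parent_id"]):
            hierarchy.setdefault(term, set()).add(parent)
        return cls(annotations=annotations, hierarchy=hierarchy)

    def dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for term, parents in self.hierarchy.items():
            for p in parents:
                g.add_edge(term, p)
        for terms in self.annotations.values():
            g.add_nodes_from(terms)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"GO hierarchy contains a cycle: {cycle}")
        return g

    def propagated(self) -> dict:
        """protein_id → annotated terms closed over all ancestors
        (true-path rule)."""
        g = self.dag()
        closure: dict = {}

        def ancestors(term):
            if term not in closure:
                closure[term] = ({term} | nx.descendants(g, term)
                                 if term in g else {term})
            return closure[term]

        return {pid: set().union(*(ancestors(t) for t in terms))
                for pid, terms in self.annotations.items()}


def go_fold_enrichment(query: Iterable, reference: Iterable, go: GOTable,
                       basis: Optional[Sequence] = None) -> pd.DataFrame:
    """Per-term fold enrichment of ``query`` relative to ``reference``.

    fold(term) = (query hits/|query|) / (reference hits/|reference|), counted
    after hierarchy propagation. With ``basis`` supplied, the output has one
    row per basis term in order (terms without reference hits → NaN fold),
    which makes per-filter results line up for cross-filter heat maps.
    """
    query, reference = set(query), set(reference)
    if not query <= reference:
        raise ValueError("query must be a subset of the reference set")
    prop = go.propagated()
    terms = (set().union(*(prop.get(p, set()) for p in reference))
             if reference else set())
    rows = []
    basis_terms = list(basis) if basis is not None else sorted(terms)
    for term in basis_terms:
        q_hits = sum(1 for p in query if term in prop.get(p, ()))
        r_hits = sum(1 for p in reference if term in prop.get(p, ()))
        if r_hits == 0 or not query:
            fold = np.nan
        else:
            fold = (q_hits / len(query)) / (r_hits / len(reference))
        rows.append({"term_id": term, "query_hits": q_hits,
                     "reference_hits": r_hits, "fold": fold})
    return pd.DataFrame(rows)


def basis_terms(proteins: Iterable, go: GOTable) -> list:
    """Sorted union of propagated terms over a protein set — the basis
    hierarchy used to align per-filter GO results."""
    prop = go.propagated()
    return sorted(set().union(*(prop.get(p, set()) for p in proteins))
                  if proteins else set())


def subset_passrate_table(results_by_filter: Mapping,
                          subsets: Mapping) -> pd.DataFrame:
    """Percent pass/fail per labelled subset per filter (heat-map table)."""
    rows = []
    for fname, passed in results_by_filter.items():
        passed = set(passed)
        for sname, members in subsets.items():
            members = set(members)
            frac = len(passed & members) / len(members) if members else np.nan
            rows.append({"filter": fname, "subset": sname,
                         "pct_pass": 100.0 * frac,
                         "pct_fail": 100.0 * (1.0 - frac)})
    return pd.DataFrame(rows)
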
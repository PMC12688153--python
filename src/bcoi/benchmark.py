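"""Benchmarking BCOI predictions against curated pH-sensor proteins.

A small set of human proteins with experimentally characterised pH-dependent
function serves as the benchmark: protein-level recovery (how many filters
return the protein) and residue-level recovery (whether the literature
pH-sensing residues appear in any filter's BCOI list). Substitution
pathogenicity scores (e.g. AlphaMissense-style, one score per possible amino
acid replacement) are aggregated by averaging over the 19 substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import AA1_TO_3


@dataclass
class SensorResidue:
    label: str                     # one-letter type + sequence number, "H189"
    reported_predicted: bool       # check (True) or cross (False) in the source
    reported_sasa: float           # Å², moiety SASA in the protomer model
    reported_score_avg: float      # mean substitution pathogenicity, 0–1

    @property
    def aa_type(self) -> str:
        return self.label[0]

    @property
    def seq_number(self) -> int:
        return int(self.label[1:])

    @property
    def group_label(self) -> str:
        return AA1_TO_3[self.aa_type]


@dataclass
class BenchmarkEntry:
    """One benchmark row; ``protein`` may name several family members
    (e.g. the cofilin family) sharing the same sensor residue."""

    protein: str
    n_pass_reported: tuple         # filters returning the protein, one per member
    sensors: list[SensorResidue] = field(default_factory=list)
    filter_passes: Optional[dict] = None   # per-filter flags when available

    def __post_init__(self):
        for n in self.n_pass_reported:
            if not (0 <= n <= 10):
                raise ValueError(f"{self.protein}: n_pass {n} outside [0, 10]")

    @property
    def proteins(self) -> list[str]:
        return self.protein.split("/")


@dataclass
class BenchmarkReport:
    residues_recovered: int
    residues_total: int
    per_filter_fraction: Optional[dict]
    mean_n_pass: float
    n_proteins: int
    empty: bool = False

    @property
    def residue_fraction(self) -> float:
        if self.residues_total == 0:
            return float("nan")
        return self.residues_recovered / self.residues_total


def score_benchmark(entries: Sequence[BenchmarkEntry],
                    predictions: Optional[Mapping] = None) -> BenchmarkReport:
    """Count sensor-residue recovery over the benchmark.

    Without ``predictions``, the entries' own recorded marks are counted
    (fixture mode). With ``predictions`` (protein → FilterResult), a residue
    counts as recovered when it appears in any filter's BCOI list; per-filter
    protein-recovery fractions are then also computed.
    """
    if not entries:
        return BenchmarkReport(0, 0, None, float("nan"), 0, empty=True)

    recovered = 0
    total = 0
    for e in entries:
        for sensor in e.sensors:
            total += 1
            if predictions is None:
                recovered += int(sensor.reported_predicted)
            else:
                hit = False
                for name in e.proteins:
                    fr = predictions.get(name)
                    if fr is None:
                        raise ValueError(
                            f"benchmark entry {e.protein}: no prediction for "
                            f"{name}")
                    for residues in fr.bcoi_residues.values():
                        if any(num == sensor.seq_number
                               and grp == sensor.group_label
                               for _, num, grp in residues):
                            hit = True
                recovered += int(hit)

    all_names = [p for e in entries for p in e.proteins]
    n_pass = [n for e in entries for n in e.n_pass_reported]
    per_filter = None
    if predictions is not None:
        names = set()
        for fr in predictions.values():
            names.update(fr.passes)
        per_filter = {}
        for fname in sorted(names):
            hits = sum(1 for p in all_names
                       if predictions[p].passes.get(fname, False))
            per_filter[fname] = hits / len(all_names)
    return BenchmarkReport(
        residues_recovered=recovered, residues_total=total,
        per_filter_fraction=per_filter,
        mean_n_pass=float(np.mean(n_pass)) if n_pass else float("nan"),
        n_proteins=len(all_names))


def aggregate_substitution_scores(scores: Sequence[float]) -> float:
    """Arithmetic mean over the 19 possible amino acid substitutions."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (19,):
        raise ValueError(f"expected 19 substitution scores, got {scores.shape}")
    if not np.all(np.isfinite(scores)):
        raise ValueError("substitution scores must be finite")
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("substitution scores must lie in [0, 1]")
    return float(scores.mean())


def fixture_table(entries: Sequence[BenchmarkEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        for s in e.sensors:
            rows.append({
                "protein": e.protein,
                "n_pass": "/".join(str(n) for n in e.n_pass_reported),
                "sensor": s.label,
                "predicted": int(s.reported_predicted),
                "sasa": s.reported_sasa,
                "score_avg": s.reported_score_avg,
            })
    return pd.DataFrame(rows)
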
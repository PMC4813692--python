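"""Ranking and two-stage selection of sampled conformations.

Single scores are imperfect: the coarse-grained energy ranks compact,
sterically clean structures highly even when they violate the experimental
restraints, while the restraint bonus alone ignores physical plausibility.
The two-stage protocol combines them: take the ``k_filter`` (default ten)
lowest-energy structures as a coarse first filter, then re-rank those by a
second score (by default the Lorentzian restraint bonus).  The top-ranked
structure is the *first structure*; the ``k_report`` (default five) best are
kept for inspection, and the lowest-RMSD among them is the *best-of-k*
structure.  A first-structure RMSD below 6 Å to the reference is flagged as
correct topology.

Scores are pluggable: any external per-structure score table (CSV with
model id and value) can serve as primary or secondary criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import pandas as pd

from .mbs_search import ModelRecord, SearchResult
from .struct_analysis import CaStructure, ResidueSelection, superpose_rmsd

__all__ = [
    "Ranking",
    "SelectionReport",
    "rank_structures",
    "two_stage_select",
    "evaluate_selection",
    "read_score_table",
    "CORRECT_TOPOLOGY_RMSD",
]

CORRECT_TOPOLOGY_RMSD = 6.0  # Å

ScoreSpec = Union[str, Mapping[int, float], Callable[[ModelRecord], float]]


def _score_values(records: Sequence[ModelRecord], score: ScoreSpec) -> list[float]:
    """Per-record score values, ascending = better."""
    if callable(score):
        return [float(score(r)) for r in records]
    if isinstance(score, Mapping):
        try:
            return [float(score[r.model_id]) for r in records]
        except KeyError as exc:
            raise KeyError(f"score table missing model id {exc.args[0]}") from None
    if score == "energy":
        return [r.energy for r in records]
    if score == "physics":
        return [r.physics_energy for r in records]
    if score == "restraint_bonus":
        return [-r.restraint_bonus for r in records]  # more bonus = better
    if score == "n_satisfied":
        return [-float(r.n_satisfied) for r in records]
    if score == "combined":
        # physics-only energy plus a unit-weight restraint reward
        return [r.physics_energy - r.restraint_bonus for r in records]
    raise ValueError(f"unknown score {score!r}; expected 'energy', 'physics', "
                     f"'restraint_bonus', 'n_satisfied', 'combined', a mapping, "
                     f"or a callable")


@dataclass
class Ranking:
    model_ids: list[int]  # best first
    scores: list[float]  # the (ascending = better) values used
    score_name: str


@dataclass
class SelectionReport:
    first: int
    top_k: list[int]
    primary: str
    secondary: str
    rmsd: Optional[dict[int, float]] = None


def rank_structures(result: SearchResult, score: ScoreSpec = "energy") -> Ranking:
    """Full ordering of the ensemble under one score, ties broken by model id."""
    vals = _score_values(result.records, score)
    order = sorted(range(len(result.records)),
                   key=lambda k: (vals[k], result.records[k].model_id))
    return Ranking(
        model_ids=[result.records[k].model_id for k in order],
        scores=[vals[k] for k in order],
        score_name=score if isinstance(score, str) else "custom",
    )


def two_stage_select(
    result: SearchResult,
    primary: ScoreSpec = "energy",
    secondary: ScoreSpec = "restraint_bonus",
    k_filter: int = 10,
    k_report: int = 5,
) -> SelectionReport:
    """Coarse filter by the primary score, re-rank the survivors by the secondary.

    With an ensemble smaller than ``k_filter`` the whole ensemble passes the
    filter (a warning is emitted).
    """
    if len(result.records) < k_filter:
        warnings.warn(f"ensemble of {len(result.records)} smaller than k_filter={k_filter}; "
                      f"using the full ensemble", stacklevel=2)
    first_stage = rank_structures(result, primary).model_ids[:k_filter]
    by_id = {r.model_id: r for r in result.records}
    survivors = [by_id[i] for i in first_stage]
    vals = _score_values(survivors, secondary)
    order = sorted(range(len(survivors)), key=lambda k: (vals[k], survivors[k].model_id))
    ranked = [survivors[k].model_id for k in order]
    return SelectionReport(
        first=ranked[0],
        top_k=ranked[:k_report],
        primary=primary if isinstance(primary, str) else "custom",
        secondary=secondary if isinstance(secondary, str) else "custom",
    )


def evaluate_selection(
    report: SelectionReport,
    result: SearchResult,
    reference: CaStructure,
    selection: Optional[ResidueSelection] = None,
    sequence: Optional[str] = None,
) -> tuple[float, float]:
    """RMSD of the first structure and the best of the reported top-k.

    ``best_of_k <= first`` always, since the first structure is a member of
    the top-k set.
    """
    by_id = {r.model_id: r for r in result.records}
    rmsds = {}
    for mid in report.top_k:
        model = by_id[mid].conformation.to_ca_structure(sequence=sequence)
        rmsds[mid] = superpose_rmsd(model, reference, selection)
    report.rmsd = rmsds
    return rmsds[report.first], min(rmsds.values())


def read_score_table(path: str | Path, id_column: str = "model_id",
                     value_column: str = "value") -> dict[int, float]:
    """Import an external per-structure score table (CSV) as a score mapping."""
    df = pd.read_csv(path)
    for col in (id_column, value_column):
        if col not in df.columns:
            raise ValueError(f"score table {Path(path).name} lacks column {col!r}")
    return {int(i): float(v) for i, v in zip(df[id_column], df[value_column])}
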
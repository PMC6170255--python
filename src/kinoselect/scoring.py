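"""The composite selectivity score: on-target reward minus off-target penalties.

For a compound with measured percent inhibitions I_t over the chosen
on-target kinases and I_j over the M measured off-target kinases:

    G   = geometric mean of the on-target inhibitions (the inhibition score)
    P_b = (1/M) * sum_j I_j                       (broad-activity penalty)
    P_n = (1/M) * sum_j I_j * I_j / (I_j + G)     (near-magnitude penalty)
    S   = G - P_b - P_n                           (selectivity score)

P_b captures compounds that weakly inhibit almost the whole panel; P_n
captures compounds with a few off-targets comparable to or stronger than
the target, via the smooth weight I_j/(I_j + G) that approaches 1 when
I_j >> G and 0 when I_j << G.  No thresholds or binning are involved, and
only profiled (non-missing) cells ever enter a sum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedScoreError, ValidationError
from .matrix import InhibitionMatrix

logger = logging.getLogger(__name__)

#: Default cap on the number of on-target kinases (a usability guard, not math).
MAX_TARGETS = 10


@dataclass(frozen=True)
class TargetSet:
    """Ordered set of 1-10 on-target kinase names (cap overridable)."""

    kinases: tuple[str, ...]

    def __init__(self, kinases, *, max_targets: int = MAX_TARGETS):
        kin = tuple(str(k).strip() for k in kinases)
        if len(kin) < 1:
            raise ValidationError("target set needs at least one kinase")
        if len(set(kin)) != len(kin):
            dups = sorted({k for k in kin if kin.count(k) > 1})
            raise ValidationError(f"duplicate target kinases: {dups}")
        if len(kin) > max_targets:
            raise ValidationError(
                f"{len(kin)} targets exceeds the {max_targets}-target limit"
            )
        object.__setattr__(self, "kinases", kin)

    def __iter__(self):
        return iter(self.kinases)

    def __len__(self):
        return len(self.kinases)


@dataclass(frozen=True)
class ScoreRecord:
    """One compound's score decomposition and coverage counts.

    ``defined`` is False when none of the chosen targets was profiled for
    this compound; such compounds carry NaN components and rank last.
    """

    compound_id: str
    inhibition_score: float
    penalty_broad: float
    penalty_near: float
    selectivity_score: float
    n_targets_measured: int
    n_offtargets_measured: int
    defined: bool


@dataclass(frozen=True)
class OffTargetRecord:
    """A significant off-target: its inhibition and ratio to the target score."""

    kinase: str
    inhibition: float
    ratio: float  # inhibition / G; NaN when G == 0


def _split_row(row: pd.Series, targets: TargetSet) -> tuple[np.ndarray, np.ndarray]:
    """Measured target values and measured off-target values from one row."""
    missing = [k for k in targets if k not in row.index]
    if missing:
        raise ValidationError(f"target kinase(s) not in matrix: {sorted(missing)}")
    tvals = row[list(targets)].to_numpy(dtype=float)
    offs = row.drop(list(targets)).to_numpy(dtype=float)
    return tvals[np.isfinite(tvals)], offs[np.isfinite(offs)]


def inhibition_score(row: pd.Series, targets: TargetSet) -> float:
    """Geometric mean of the measured on-target inhibitions.

    A single target returns its own value; any zero target value forces the
    geometric mean to 0.  Raises :class:`UndefinedScoreError` when no target
    is measured for this compound.
    """
    tvals, _ = _split_row(row, targets)
    if tvals.size == 0:
        raise UndefinedScoreError("no target kinase measured for this compound")
    if tvals.size == 1:
        return float(tvals[0])
    if np.any(tvals == 0.0):
        return 0.0
    return float(math.exp(np.mean(np.log(tvals))))


def broad_penalty(row: pd.Series, targets: TargetSet) -> float:
    """Mean inhibition over the measured off-target kinases."""
    _, offs = _split_row(row, targets)
    if offs.size == 0:
        logger.warning("degenerate panel: no measured off-target kinases")
        return 0.0
    return float(np.mean(offs))


def near_penalty(row: pd.Series, targets: TargetSet, g: float) -> float:
    """Mean of I * I/(I + G) over measured off-targets.

    A term with I = 0 contributes 0 even when G = 0 (the 0/0 weight is
    resolved to 0: a kinase not inhibited at all carries no penalty).
    """
    _, offs = _split_row(row, targets)
    if offs.size == 0:
        logger.warning("degenerate panel: no measured off-target kinases")
        return 0.0
    terms = np.zeros_like(offs)
    nz = offs > 0.0
    terms[nz] = offs[nz] * offs[nz] / (offs[nz] + g)
    return float(np.mean(terms))


def selectivity_score(row: pd.Series, targets: TargetSet, compound_id: str | None = None) -> ScoreRecord:
    """Score one compound row: S = G - P_b - P_n over its profiled kinases."""
    cid = str(compound_id if compound_id is not None else row.name)
    tvals, offs = _split_row(row, targets)
    if tvals.size == 0:
        return ScoreRecord(
            compound_id=cid,
            inhibition_score=float("nan"),
            penalty_broad=float("nan"),
            penalty_near=float("nan"),
            selectivity_score=float("nan"),
            n_targets_measured=0,
            n_offtargets_measured=int(offs.size),
            defined=False,
        )
    g = inhibition_score(row, targets)
    p_b = broad_penalty(row, targets)
    p_n = near_penalty(row, targets, g)
    return ScoreRecord(
        compound_id=cid,
        inhibition_score=g,
        penalty_broad=p_b,
        penalty_near=p_n,
        selectivity_score=g - p_b - p_n,
        n_targets_measured=int(tvals.size),
        n_offtargets_measured=int(offs.size),
        defined=True,
    )


def significant_off_targets(
    row: pd.Series, targets: TargetSet, compound_id: str | None = None
) -> list[OffTargetRecord]:
    """Off-targets inhibited at least half as much as the target score G.

    The boundary I = 0.5 * G is included.  When G = 0 every off-target with
    any inhibition at all (I > 0) is significant.  Results are sorted by
    descending inhibition, ties by kinase name.
    """
    record = selectivity_score(row, targets, compound_id)
    if not record.defined:
        raise UndefinedScoreError(
            f"compound {record.compound_id!r} has no measured target; no score defined"
        )
    g = record.inhibition_score
    out: list[OffTargetRecord] = []
    for kinase, value in row.drop(list(targets)).items():
        v = float(value)
        if not np.isfinite(v):
            continue
        significant = v > 0.0 if g == 0.0 else v >= 0.5 * g
        if significant:
            ratio = v / g if g > 0.0 else float("nan")
            out.append(OffTargetRecord(kinase=str(kinase), inhibition=v, ratio=ratio))
    out.sort(key=lambda r: (-r.inhibition, r.kinase))
    return out


def rank_compounds(matrix: InhibitionMatrix, targets: TargetSet) -> pd.DataFrame:
    """Score every compound and return the ranked table.

    Columns: compound_id, inhibition_score, penalty_broad, penalty_near,
    selectivity_score, n_targets_measured, n_offtargets_measured,
    n_significant_offtargets, defined.  Defined compounds sort by descending
    S, then descending G, then compound_id; undefined compounds come last.
    """
    missing = [k for k in targets if k not in matrix.kinase_ids]
    if missing:
        raise ValidationError(f"target kinase(s) not in matrix: {sorted(missing)}")
    records = []
    for cid in matrix.compound_ids:
        row = matrix.data.loc[cid]
        rec = selectivity_score(row, targets, cid)
        n_sig = len(significant_off_targets(row, targets, cid)) if rec.defined else 0
        records.append({**rec.__dict__, "n_significant_offtargets": n_sig})
    table = pd.DataFrame.from_records(records)
    table["_rank_s"] = table["selectivity_score"].where(table["defined"], -np.inf)
    table["_rank_g"] = table["inhibition_score"].where(table["defined"], -np.inf)
    table = table.sort_values(
        by=["defined", "_rank_s", "_rank_g", "compound_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).drop(columns=["_rank_s", "_rank_g"])
    cols = [
        "compound_id", "inhibition_score", "penalty_broad", "penalty_near",
        "selectivity_score", "n_targets_measured", "n_offtargets_measured",
        "n_significant_offtargets", "defined",
    ]
    return table[cols].reset_index(drop=True)
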
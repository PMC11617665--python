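"""Consensus virtual-screening arithmetic on docking score tables.

Docking engines are consumed as score tables only.  Scores are min-max
normalized to [0, 1] per program after orienting them so that larger is
better: binding free energies (Vina, AutoDock 4.2, kcal/mol) are
lower-is-better, ChemPLP fitness (GOLD) is higher-is-better.  The best
compound of a program maps to 1, the worst to 0.  A ranked list sorted
best-first is split into quartiles Q1..Q4 with ``|Q1| = floor(N/4)`` (the
remainder goes to Q4), and the consensus score of a compound is the
unweighted mean of its per-program normalized scores (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DegenerateRangeError, ParameterError

logger = logging.getLogger(__name__)

#: default score orientation per docking program
ORIENTATIONS = {
    "vina": "lower_is_better",
    "autodock42": "lower_is_better",
    "gold": "higher_is_better",
}


@dataclass
class ScoreTable:
    """Per-program docking scores: compound id -> raw score."""

    program: str
    scores: dict[str, float]
    orientation: Optional[str] = None

    def __post_init__(self):
        if self.orientation is None:
            if self.program not in ORIENTATIONS:
                raise ParameterError(
                    f"unknown program {self.program!r}; pass orientation explicitly"
                )
            self.orientation = ORIENTATIONS[self.program]
        if self.orientation not in ("lower_is_better", "higher_is_better"):
            raise ParameterError(f"bad orientation {self.orientation!r}")


@dataclass
class ConsensusRanking:
    """Normalized per-program scores, consensus score and 1-based ranks."""

    normalized: dict[str, dict[str, float]]  # program -> id -> [0,1]
    consensus: dict[str, float]
    rank: dict[str, int]
    programs: list[str] = field(default_factory=list)

    def top(self, n: int) -> list[str]:
        order = sorted(self.rank, key=self.rank.get)
        return order[:n]


def normalize_scores(table: ScoreTable) -> dict[str, float]:
    """Min-max normalize so the best compound scores 1 and the worst 0."""
    values = np.asarray(list(table.scores.values()), dtype=float)
    if values.size < 2 or np.ptp(values) == 0:
        raise DegenerateRangeError(
            f"{table.program}: need >= 2 distinct scores to normalize"
        )
    lo, hi = values.min(), values.max()
    if table.orientation == "lower_is_better":
        normed = (hi - values) / (hi - lo)
    else:
        normed = (values - lo) / (hi - lo)
    return dict(zip(table.scores.keys(), normed.tolist()))


def quartile_partition(
    scores: Mapping[str, float], orientation: str = "lower_is_better"
) -> dict[str, str]:
    """Assign Q1..Q4 labels; Q1 holds the floor(N/4) best compounds.

    Q2 and Q3 also take floor(N/4) each; Q4 takes the remainder.  Ties in
    score are ordered by compound id.
    """
    n = len(scores)
    if n < 4:
        raise ParameterError(f"need at least 4 compounds for quartiles, got {n}")
    reverse = orientation == "higher_is_better"
    order = sorted(scores, key=lambda c: (-scores[c] if reverse else scores[c], c))
    q = n // 4
    labels = {}
    for pos, cid in enumerate(order):
        labels[cid] = "Q" + str(min(pos // q + 1, 4) if q else 4)
    return labels


class ConsensusRanker(BaseEstimator):
    """Aggregate several programs' normalized docking scores into one ranking.

    Parameters
    ----------
    aggregation : {"mean", "sum", "min"}
        How per-program normalized scores are combined; the default
        (unweighted mean) keeps the consensus on the [0, 1] scale.
    tie_break_program : str
        Program whose normalized score breaks consensus ties (then
        compound id, lexicographic).

    Attributes (after :meth:`fit`)
    ------------------------------
    normalized_ : dict  program -> {id: normalized score}
    consensus_ : dict   id -> aggregate score
    rank_ : dict        id -> 1-based rank (1 = best)
    ranking_ : pandas.DataFrame   one row per compound, best first
    """

    _AGGREGATORS: dict[str, Callable] = {
        "mean": np.mean,
        "sum": np.sum,
        "min": np.min,
    }

    def __init__(self, aggregation: str = "mean", tie_break_program: str = "vina"):
        self.aggregation = aggregation
        self.tie_break_program = tie_break_program

    def fit(self, tables: Sequence[ScoreTable], y=None):
        if self.aggregation not in self._AGGREGATORS:
            raise ParameterError(f"unknown aggregation {self.aggregation!r}")
        if not tables:
            raise ParameterError("need at least one score table")
        agg = self._AGGREGATORS[self.aggregation]
        # normalization happens per program over that program's full
        # compound set, before intersecting, so a missing entry elsewhere
        # does not distort a program's scale
        normalized = {t.program: normalize_scores(t) for t in tables}
        common = set.intersection(*(set(t.scores) for t in tables))
        union = set.union(*(set(t.scores) for t in tables))
        if not common:
            raise ParameterError("score tables share no compounds")
        dropped = union - common
        if dropped:
            logger.warning(
                "dropping %d compounds missing from at least one program", len(dropped)
            )
        consensus = {
            cid: float(agg([normalized[t.program][cid] for t in tables]))
            for cid in common
        }
        tie = normalized.get(self.tie_break_program, {})
        order = sorted(
            common, key=lambda c: (-consensus[c], -tie.get(c, 0.0), c)
        )
        self.programs_ = [t.program for t in tables]
        self.normalized_ = normalized
        self.consensus_ = consensus
        self.rank_ = {cid: i + 1 for i, cid in enumerate(order)}
        self.ranking_ = pd.DataFrame(
            {
                "compound_id": order,
                **{
                    f"norm_{p}": [normalized[p][c] for c in order]
                    for p in self.programs_
                },
                "consensus": [consensus[c] for c in order],
                "rank": np.arange(1, len(order) + 1),
            }
        )
        return self

    def transform(self, tables: Sequence[ScoreTable]) -> pd.DataFrame:
        return self.fit(tables).ranking_


def consensus_rank(
    tables: Sequence[ScoreTable], aggregation: str = "mean"
) -> ConsensusRanking:
    """Functional wrapper around :class:`ConsensusRanker`."""
    ranker = ConsensusRanker(aggregation=aggregation).fit(tables)
    return ConsensusRanking(
        normalized=ranker.normalized_,
        consensus=ranker.consensus_,
        rank=ranker.rank_,
        programs=ranker.programs_,
    )


def select_top_n(ranking: ConsensusRanking, n: int = 50) -> list[str]:
    """The ``n`` best compound ids by consensus rank."""
    if n > len(ranking.rank):
        raise ParameterError(f"n={n} exceeds ranking size {len(ranking.rank)}")
    return ranking.top(n)


def run_funnel(
    tables: Sequence[ScoreTable],
    primary_program: str = "vina",
    quartile: str = "Q1",
    top_n: int = 50,
    aggregation: str = "mean",
) -> tuple[ConsensusRanking, list[str], dict[str, str]]:
    """Full staged funnel: primary-program quartile gate, then consensus.

    The primary program's full table is partitioned into quartiles; only
    compounds in the requested quartile enter the consensus ranking over
    all programs, and the ``top_n`` best consensus compounds are returned.
    """
    by_program = {t.program: t for t in tables}
    if primary_program not in by_program:
        raise ParameterError(f"primary program {primary_program!r} not supplied")
    primary = by_program[primary_program]
    labels = quartile_partition(primary.scores, primary.orientation)
    survivors = {cid for cid, q in labels.items() if q == quartile}
    gated = [
        ScoreTable(
            t.program,
            {c: s for c, s in t.scores.items() if c in survivors},
            t.orientation,
        )
        for t in tables
    ]
    ranking = consensus_rank(gated, aggregation=aggregation)
    hits = select_top_n(ranking, min(top_n, len(ranking.rank)))
    return ranking, hits, labels


def read_score_csv(path: str | Path) -> list[ScoreTable]:
    """Read a long-format CSV with columns compound_id, program, score."""
    df = pd.read_csv(path)
    missing = {"compound_id", "program", "score"} - set(df.columns)
    if missing:
        raise ParameterError(f"{path}: missing columns {sorted(missing)}")
    tables = []
    for program, group in df.groupby("program", sort=False):
        tables.append(
            ScoreTable(
                str(program),
                dict(zip(group["compound_id"].astype(str), group["score"].astype(float))),
            )
        )
    return tables
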
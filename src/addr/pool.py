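"""Union of per-model candidate lists into a single pool.

Each candidate-generation model contributes a top-k ranked drug list; the
pool is their set union, with per-drug provenance (which models proposed
it, at what rank).  No score harmonization or rank aggregation is done —
the strategy is union-then-filter, with downstream literature evidence
doing the filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .ranker import RankedList

DEFAULT_TOP_K = 30


class ScoreTableError(ValueError):
    """Raised for malformed external score tables."""


def load_score_table(path, model_name: str, top_k: int = DEFAULT_TOP_K) -> RankedList:
    """Load an external model's ``drug_id``/``score`` TSV as a RankedList.

    Rows are sorted by descending score (drug id breaks ties), truncated to
    ``top_k``, and ranked 1..k.  Duplicate drug ids are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("drug_id", "score"):
        if col not in df.columns:
            raise ScoreTableError(f"score table missing column {col!r}")
    dupes = df["drug_id"][df["drug_id"].duplicated()]
    if len(dupes):
        raise ScoreTableError(f"duplicate drug_id {dupes.iloc[0]!r} in score table")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        bad = df.loc[scores.isna(), "drug_id"].iloc[0]
        raise ScoreTableError(f"non-numeric score for drug {bad!r}")
    df = df.assign(score=scores).sort_values(
        ["score", "drug_id"], ascending=[False, True]
    )
    df = df.head(top_k)
    entries = [
        (str(d), float(s), i + 1)
        for i, (d, s) in enumerate(zip(df["drug_id"], df["score"]))
    ]
    return RankedList(model_name=model_name, entries=entries)


@dataclass
class CandidatePool:
    """Set union of per-model candidate lists with provenance.

    ``members`` maps each drug to ``{model_name: rank}`` over the models
    that proposed it.
    """

    members: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    def models_for(self, drug_id: str) -> list[str]:
        return sorted(self.members.get(drug_id, ()))

    def best_rank(self, drug_id: str) -> int:
        return min(self.members[drug_id].values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug_id": d,
                "models": ";".join(self.models_for(d)),
                "best_rank": self.best_rank(d),
            }
            for d in self.drugs
        ]
        return pd.DataFrame(rows, columns=["drug_id", "models", "best_rank"])


def union_candidates(lists: Sequence[RankedList]) -> CandidatePool:
    """Union of the given ranked lists, keeping per-model rank provenance."""
    if not lists:
        raise ValueError("need at least one ranked list")
    members: dict[str, dict[str, int]] = {}
    for ranked in lists:
        for drug, _score, rank in ranked.entries:
            slot = members.setdefault(drug, {})
            # keep the best rank if a model (or name collision) repeats a drug
            slot[ranked.model_name] = min(slot.get(ranked.model_name, rank), rank)
    return CandidatePool(members=members)


def write_pool(pool: CandidatePool, path) -> None:
    pool.to_frame().to_csv(path, sep="\t", index=False)


def load_pool(path) -> CandidatePool:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "models": str})
    members: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        models = str(row.models).split(";") if row.models else []
        members[row.drug_id] = {m: int(row.best_rank) for m in models}
    return CandidatePool(members=members)
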
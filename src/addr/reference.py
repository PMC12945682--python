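"""Published per-drug evidence rates for the Alzheimer's candidate set.

The packaged table ``data/ad_candidate_evidence.tsv`` records, for the 17
Alzheimer's repurposing candidates that carried any positive literature
signal, the published abstract count, evidence rates (neutral/positive/
negative, to two decimals), the contributing graph model, the cohort
hazard ratio with its p-value ("NA" where not estimable), and the
registered clinical-trial footprint.  It serves as a fixed input for
re-running the stratification criteria and the trial cross-tabulation.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import pandas as pd

from .cohort import TrialOverlap
from .evidence import EvidenceProfile, profile_from_rates
from .pool import CandidatePool


def load_reference_table() -> pd.DataFrame:
    path = resources.files("addr").joinpath("data/ad_candidate_evidence.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype=str).fillna("")


def load_reference_candidates() -> tuple[
    CandidatePool, list[EvidenceProfile], list[TrialOverlap], pd.DataFrame
]:
    """The reference candidate set as pipeline-ready objects.

    Returns the candidate pool (with per-model provenance, ranked by row
    order within each model), the per-drug evidence profiles built from the
    published rates, the trial overlaps, and the raw table.
    """
    df = load_reference_table()
    members: dict[str, dict[str, int]] = {}
    rank_within: dict[str, int] = {}
    profiles: list[EvidenceProfile] = []
    overlaps: list[TrialOverlap] = []
    for row in df.itertuples(index=False):
        rank_within[row.model] = rank_within.get(row.model, 0) + 1
        members[row.drug_id] = {row.model: rank_within[row.model]}
        profiles.append(
            profile_from_rates(
                row.drug_id,
                total=int(row.n_abstracts),
                r_u=row.r_u,
                r_p=row.r_p,
                r_n=row.r_n,
            )
        )
        ids = tuple(i for i in str(row.trial_ids).split(";") if i)
        overlaps.append(
            TrialOverlap(row.drug_id, ids, trial_count=int(row.trial_count))
        )
    return CandidatePool(members=members), profiles, overlaps, df
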
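"""Cohort-based survival validation of candidate drugs.

Emulates validation against a longitudinal dementia cohort: participants
enter observation at different ages (left truncation), are followed over
repeated visits at which drug use is recorded, and either reach the
cognitive-decline event or are censored (right censoring).  Per drug, a
left-truncated right-censored Cox proportional-hazards model

    h(t | X) = h0(t) * exp(b_drug * X_drug + b_age * X_age + ... )

is fitted on the age timescale, adjusting for baseline age, sex,
education, marital status, and living situation.  The drug effect is
reported as the hazard ratio ``HR = exp(b_drug)``; HR < 1 indicates a
protective association with cognitive decline.

Chronic-use rule: a participant counts as exposed only when the drug is
documented at two or more consecutive visits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .evidence import (
    POTENTIALLY_THERAPEUTIC,
    EvidenceProfile,
    apply_criterion1,
    apply_criterion2,
)
from .pool import CandidatePool

DEFAULT_ALPHAS = {"strict": 0.05, "exploratory": 0.30}
DEFAULT_COVARIATES = ("age", "sex", "education", "marital", "living")

_MARITAL_LEVELS = ("married", "widowed", "divorced", "other")
_LIVING_LEVELS = ("with_partner", "alone", "other")
_REFERENCE_LEVELS = {"marital": "married", "living": "with_partner"}


@dataclass
class CohortTable:
    """Longitudinal cohort: per-participant spells plus per-visit records.

    ``participants`` columns: participant, entry_age, exit_age, event,
    age (baseline), sex, education, marital, living.
    ``visits`` columns: participant, visit_age, drugs (semicolon-joined
    drug ids, possibly empty), declined (event flag, monotone within a
    participant).
    """

    participants: pd.DataFrame
    visits: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.participants
        if (p["entry_age"] > p["exit_age"]).any():
            raise ValueError("entry_age must be <= exit_age")
        self.visits = self.visits.sort_values(
            ["participant", "visit_age"], kind="stable"
        ).reset_index(drop=True)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_events(self) -> int:
        return int(self.participants["event"].sum())

    def write(self, path) -> None:
        merged = self.visits.merge(self.participants, on="participant")
        merged.to_csv(path, sep="\t", index=False)


@dataclass
class CohortConfig:
    """Synthetic-cohort generator settings.

    ``drug_effects`` maps drug ids to true log hazard ratios for chronic
    exposure.  Event ages are exponential on the age timescale with rate
    ``baseline_hazard * exp(linear predictor)``; because the exponential is
    memoryless, drawing the residual time after entry is exactly the
    distribution conditional on being event-free at entry, which is the
    left-truncation sampling scheme.
    """

    n_participants: int = 1000
    drug_effects: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.08  # events per person-year
    entry_age_range: tuple[float, float] = (60.0, 85.0)
    visit_interval: float = 1.0  # years
    max_follow_up: float = 8.0  # administrative censoring horizon, years
    censoring_rate: float = 0.2  # probability of random early censoring
    exposure_fraction: float = 0.3  # chronic users per drug
    sporadic_fraction: float = 0.05  # single-visit (non-chronic) mentions
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.03,  # per year over 70
            "sex_female": -0.10,
            "education": -0.02,  # per year over 16
            "marital_widowed": 0.10,
            "marital_divorced": 0.05,
            "marital_other": 0.0,
            "living_alone": 0.10,
            "living_other": 0.05,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0,1]")


def generate_synthetic_cohort(config: CohortConfig) -> CohortTable:
    """Simulate a left-truncated, right-censored visit-based cohort.

    Deterministic given ``config.seed``.  With ``censoring_rate`` 1.0 every
    participant is censored before the event, so downstream fits are
    not-estimable; a warning is emitted for that degenerate setting.
    """
    if config.censoring_rate >= 1.0:
        warnings.warn("censoring_rate 1.0: cohort will contain no events")
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    lo, hi = config.entry_age_range
    entry = rng.uniform(lo, hi, size=n)
    sex = np.where(rng.random(n) < 0.57, "female", "male")
    education = np.clip(np.round(rng.normal(16.0, 3.0, size=n)), 6, 20)
    marital = rng.choice(_MARITAL_LEVELS, size=n, p=[0.63, 0.16, 0.12, 0.09])
    living = rng.choice(_LIVING_LEVELS, size=n, p=[0.62, 0.23, 0.15])

    eff = config.covariate_effects
    lp = (
        eff.get("age", 0.0) * (entry - 70.0)
        + eff.get("sex_female", 0.0) * (sex == "female")
        + eff.get("education", 0.0) * (education - 16.0)
    )
    for level in _MARITAL_LEVELS[1:]:
        lp = lp + eff.get(f"marital_{level}", 0.0) * (marital == level)
    for level in _LIVING_LEVELS[1:]:
        lp = lp + eff.get(f"living_{level}", 0.0) * (living == level)

    drug_ids = sorted(config.drug_effects)
    chronic = {}
    sporadic = {}
    for d in drug_ids:
        u = rng.random(n)
        chronic[d] = u < config.exposure_fraction
        sporadic[d] = (u >= config.exposure_fraction) & (
            u < config.exposure_fraction + config.sporadic_fraction
        )
        lp = lp + config.drug_effects[d] * chronic[d]

    rate = config.baseline_hazard * np.exp(lp)
    event_age = entry + rng.exponential(1.0 / rate, size=n)

    # censoring independent of the event process: dropouts get a uniform
    # dropout age within the follow-up window, everyone is administratively
    # censored at the horizon
    dropout = rng.random(n) < config.censoring_rate
    dropout_age = entry + rng.uniform(0.0, config.max_follow_up, size=n)
    censor_age = np.where(dropout, dropout_age, entry + config.max_follow_up)
    if config.censoring_rate >= 1.0:
        # degenerate contract: everything censored, no events at all
        censor_age = np.minimum(censor_age, event_age - 1e-9)
    exit_age = np.minimum(event_age, censor_age)
    event = event_age <= censor_age
    # numerical guard: keep a strictly positive observation window
    exit_age = np.maximum(exit_age, entry + 1e-6)

    participants = pd.DataFrame(
        {
            "participant": [f"p{i:06d}" for i in range(n)],
            "entry_age": entry,
            "exit_age": exit_age,
            "event": event,
            "age": entry,
            "sex": sex,
            "education": education,
            "marital": marital,
            "living": living,
        }
    )

    # visit schedule: entry, then every visit_interval until exit; every
    # participant gets at least two visits so chronic use is observable
    rows_participant: list[str] = []
    rows_age: list[float] = []
    rows_drugs: list[str] = []
    rows_declined: list[bool] = []
    for i in range(n):
        times = list(
            np.arange(entry[i], exit_age[i], config.visit_interval)
        )
        if len(times) < 2:
            times = [entry[i], entry[i] + (exit_age[i] - entry[i]) / 2.0]
        for k, t in enumerate(times):
            at_visit = []
            for d in drug_ids:
                if chronic[d][i] or (sporadic[d][i] and k == 0):
                    at_visit.append(d)
            rows_participant.append(participants["participant"].iat[i])
            rows_age.append(float(t))
            rows_drugs.append(";".join(at_visit))
            rows_declined.append(bool(event[i]) and t >= event_age[i])
    visits = pd.DataFrame(
        {
            "participant": rows_participant,
            "visit_age": rows_age,
            "drugs": rows_drugs,
            "declined": rows_declined,
        }
    )
    return CohortTable(participants=participants, visits=visits)


# ---------------------------------------------------------------------- #
# exposure


def chronic_exposure(cohort: CohortTable, drug_id: str) -> pd.Series:
    """Flag participants with the drug documented at >=2 consecutive visits.

    Visits are taken in age order within each participant; a single
    mention, or mentions separated by a drug-free visit, do not count.
    """
    v = cohort.visits  # already sorted by (participant, visit_age)
    present = v["drugs"].map(
        lambda s: drug_id in s.split(";") if isinstance(s, str) and s else False
    )
    same_participant = v["participant"].eq(v["participant"].shift())
    consecutive = present & present.shift(fill_value=False) & same_participant
    exposed_ids = set(v.loc[consecutive, "participant"])
    return pd.Series(
        [p in exposed_ids for p in cohort.participants["participant"]],
        index=cohort.participants["participant"],
        name="exposed",
    )


# ---------------------------------------------------------------------- #
# Cox fit


@dataclass
class CoxResult:
    """Per-drug hazard-ratio estimate from the left-truncated Cox fit."""

    drug_id: str
    status: str  # "ok" or "not-estimable"
    beta: Optional[float] = None
    hazard_ratio: Optional[float] = None
    p_value: Optional[float] = None
    n_exposed: int = 0
    n_events: int = 0
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status == "ok" and (
            self.hazard_ratio is None or self.hazard_ratio <= 0
        ):
            raise ValueError("ok result requires a positive hazard ratio")
        if self.status != "ok" and self.hazard_ratio is not None:
            raise ValueError("not-estimable result must not carry an HR")

    def render_hr(self) -> str:
        if self.status != "ok":
            return "NA"
        return f"{self.hazard_ratio:.2f}"


def _design_matrix(
    participants: pd.DataFrame, covariates: Sequence[str]
) -> pd.DataFrame:
    cols = {}
    if "age" in covariates:
        cols["age_c"] = participants["age"] - 70.0
    if "sex" in covariates:
        cols["sex_female"] = (participants["sex"] == "female").astype(float)
    if "education" in covariates:
        cols["education_c"] = participants["education"] - 16.0
    frame = pd.DataFrame(cols, index=participants.index)
    for cat in ("marital", "living"):
        if cat in covariates:
            dummies = pd.get_dummies(participants[cat], prefix=cat, dtype=float)
            ref = f"{cat}_{_REFERENCE_LEVELS[cat]}"
            dummies = dummies.drop(columns=[ref], errors="ignore")
            frame = pd.concat([frame, dummies], axis=1)
    return frame


def fit_cox(
    cohort: CohortTable,
    drug_id: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> CoxResult:
    """Fit the adjusted Cox model for one drug's chronic-use effect.

    Risk sets are defined by the (entry_age, exit_age] intervals, so
    participants only contribute after their entry (left truncation).
    Returns a ``not-estimable`` result (rendered "NA") when the drug is
    absent from the cohort, exposure is constant, or no events occur among
    the exposed.
    """
    participants = cohort.participants.reset_index(drop=True)
    ever_mentioned = cohort.visits["drugs"].map(
        lambda s: drug_id in s.split(";") if isinstance(s, str) and s else False
    )
    if not ever_mentioned.any():
        return CoxResult(drug_id, "not-estimable", reason="drug-absent")
    exposed = chronic_exposure(cohort, drug_id)
    exposed = exposed.loc[participants["participant"]].to_numpy()
    n_exposed = int(exposed.sum())
    n_events = int(participants["event"].sum())
    if exposed.all() or not exposed.any():
        return CoxResult(
            drug_id,
            "not-estimable",
            n_exposed=n_exposed,
            n_events=n_events,
            reason="constant-exposure",
        )
    if n_events == 0:
        return CoxResult(
            drug_id,
            "not-estimable",
            n_exposed=n_exposed,
            reason="no-events",
        )
    if int(participants["event"][exposed].sum()) == 0:
        return CoxResult(
            drug_id,
            "not-estimable",
            n_exposed=n_exposed,
            n_events=n_events,
            reason="no-exposed-events",
        )

    df = _design_matrix(participants, covariates)
    df.insert(0, "exposed", exposed.astype(float))
    df["entry_age"] = participants["entry_age"]
    df["exit_age"] = participants["exit_age"]
    df["event"] = participants["event"].astype(int)
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(
                df,
                duration_col="exit_age",
                event_col="event",
                entry_col="entry_age",
                show_progress=False,
            )
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        return CoxResult(
            drug_id,
            "not-estimable",
            n_exposed=n_exposed,
            n_events=n_events,
            reason=f"convergence: {exc}",
        )
    beta = float(fitter.params_["exposed"])
    p = float(fitter.summary.loc["exposed", "p"])
    return CoxResult(
        drug_id,
        "ok",
        beta=beta,
        hazard_ratio=float(np.exp(beta)),
        p_value=p,
        n_exposed=n_exposed,
        n_events=n_events,
    )


def flag_significance(
    result: CoxResult, alphas: Mapping[str, float] = DEFAULT_ALPHAS
) -> tuple[bool, bool]:
    """(strict, exploratory) significance flags for an estimable result."""
    if result.status != "ok":
        raise ValueError("significance flags require an ok result")
    return (
        result.p_value < alphas["strict"],
        result.p_value < alphas["exploratory"],
    )


# ---------------------------------------------------------------------- #
# clinical-trial overlap


@dataclass(frozen=True)
class TrialOverlap:
    """Registered-trial footprint for one drug.

    ``trial_count`` defaults to ``len(trial_ids)``; published tables
    sometimes print a larger count alongside a truncated id list, so an
    explicit count may exceed the listed ids but never undercut them.
    """

    drug_id: str
    trial_ids: tuple[str, ...] = ()
    trial_count: Optional[int] = None

    def __post_init__(self) -> None:
        count = self.trial_count
        if count is None:
            object.__setattr__(self, "trial_count", len(self.trial_ids))
        elif count < len(self.trial_ids):
            raise ValueError("trial_count below the number of listed trial ids")


def load_trials(path) -> list[TrialOverlap]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        ids = tuple(i for i in str(row.trial_ids).split(";") if i)
        count = int(row.trial_count) if str(row.trial_count) else None
        out.append(TrialOverlap(row.drug_id, ids, count))
    return out


def tabulate_trials(
    pool: CandidatePool,
    overlaps: Sequence[TrialOverlap],
    profiles: Sequence[EvidenceProfile],
) -> dict[str, int]:
    """Cross-tabulate trial-tested pool drugs against the evidence criteria.

    Returns counts of drugs with at least one registered trial and, among
    those, how many each criterion labels potentially therapeutic.
    """
    trials = {o.drug_id: o.trial_count for o in overlaps}
    prof_by_drug = {p.drug_id: p for p in profiles}
    n_tested = c1 = c2 = 0
    for drug in pool.drugs:
        if trials.get(drug, 0) < 1:
            continue
        n_tested += 1
        prof = prof_by_drug.get(drug)
        if prof is None:
            continue
        if apply_criterion1(prof) == POTENTIALLY_THERAPEUTIC:
            c1 += 1
        if apply_criterion2(prof) == POTENTIALLY_THERAPEUTIC:
            c2 += 1
    return {
        "trial_tested": n_tested,
        "criterion1_recovered": c1,
        "criterion2_recovered": c2,
    }


def load_cohort(path) -> CohortTable:
    """Read a long-format cohort TSV written by :meth:`CohortTable.write`."""
    merged = pd.read_csv(path, sep="\t", dtype={"participant": str, "drugs": str})
    merged["drugs"] = merged["drugs"].fillna("")
    participant_cols = [
        "participant",
        "entry_age",
        "exit_age",
        "event",
        "age",
        "sex",
        "education",
        "marital",
        "living",
    ]
    participants = (
        merged[participant_cols].drop_duplicates("participant").reset_index(drop=True)
    )
    visits = merged[["participant", "visit_age", "drugs", "declined"]]
    return CohortTable(participants=participants, visits=visits)


def write_cox_results(results: Sequence[CoxResult], path) -> None:
    rows = [
        {
            "drug_id": r.drug_id,
            "HR": r.render_hr(),
            "p": f"{r.p_value:.3g}" if r.status == "ok" else "NA",
            "status": r.status,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
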
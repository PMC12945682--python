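"""Literature-evidence triage: abstract judgment, rates, and stratification.

Each retrieved abstract about a candidate drug is judged positive (+1),
neutral (0), or negative (-1) with respect to the target disease.  Per
drug, the judgment counts ``(P, U, N)`` with total ``|T| = P + U + N``
yield the evidence rates::

    R_p = P / |T|,   R_u = U / |T|,   R_n = N / |T|

which always sum to 1.  Two stratification rules are applied:

Criterion 1 (conservative)
    ``NeutralRelation`` when ``R_u >= 0.99`` (overwhelmingly inconclusive
    evidence); otherwise ``PotentiallyTherapeutic`` when ``R_p >= R_n``,
    else ``PotentiallyAdverse``.  At an exact tie ``R_p == R_n`` the
    therapeutic branch wins.
Criterion 2 (sensitivity-oriented)
    ``PotentiallyTherapeutic`` whenever there is at least one positive
    judgment (``R_p > 0``), else ``NoPositiveSign``.

Drugs with no judged abstracts receive ``InsufficientKnowledge`` under
both rules.  Rates are kept as exact rationals; two-decimal rounding is
display-only.

The default judgment backend is a deterministic lexicon mock, so every
downstream computation is network-free.  An LLM-style backend adapter is
provided for callers who supply their own chat-completion callable; its
prompt must constrain the judgment to the supplied text only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .pool import CandidatePool

DEFAULT_YEAR_FLOOR = 2000
DEFAULT_ABSTRACT_CAP = 200
DEFAULT_NEUTRAL_THRESHOLD = Fraction(99, 100)

# stratification labels
NEUTRAL_RELATION = "NeutralRelation"
POTENTIALLY_THERAPEUTIC = "PotentiallyTherapeutic"
POTENTIALLY_ADVERSE = "PotentiallyAdverse"
INSUFFICIENT_KNOWLEDGE = "InsufficientKnowledge"
NO_POSITIVE_SIGN = "NoPositiveSign"


class CorpusError(ValueError):
    """Raised for invalid corpus records or generator profiles."""


class JudgmentError(RuntimeError):
    """Raised when an external judgment backend fails after retries."""


@dataclass(frozen=True)
class AbstractRecord:
    """One retrieved abstract for one candidate drug."""

    drug_id: str
    pmid: str
    year: int
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise CorpusError(f"empty abstract text (pmid {self.pmid})")


@dataclass(frozen=True)
class Judgment:
    """A single abstract-level evidence judgment: +1, 0, or -1."""

    value: int
    rationale: Optional[str] = None

    def __post_init__(self) -> None:
        if self.value not in (1, 0, -1):
            raise ValueError(f"judgment value must be +1, 0 or -1, got {self.value}")


# ---------------------------------------------------------------------- #
# judgment backends


def _load_lexicon(name: str) -> frozenset[str]:
    path = resources.files("addr").joinpath(f"data/lexicons/{name}.txt")
    tokens = set()
    for line in path.read_text().splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            tokens.add(line)
    return frozenset(tokens)


_WORD_RE = re.compile(r"[a-z0-9']+")


class LexiconJudge:
    """Deterministic keyword-based judgment backend.

    Positive iff the text contains a positive-lexicon token and no
    negative token; negative iff it contains a negative token and no
    positive token; neutral otherwise, including when both kinds appear.
    """

    def __init__(
        self,
        positive: Optional[Iterable[str]] = None,
        negative: Optional[Iterable[str]] = None,
    ) -> None:
        self.positive = frozenset(positive) if positive is not None else _load_lexicon("positive")
        self.negative = frozenset(negative) if negative is not None else _load_lexicon("negative")

    def judge(self, drug_id: str, record: AbstractRecord) -> Judgment:
        words = set(_WORD_RE.findall(record.text.lower()))
        has_pos = bool(words & self.positive)
        has_neg = bool(words & self.negative)
        if has_pos and not has_neg:
            return Judgment(1, "positive-lexicon token present")
        if has_neg and not has_pos:
            return Judgment(-1, "negative-lexicon token present")
        return Judgment(0, "no clear lexicon signal")


#: Prompt template for LLM-style backends.  Judgment must rest on the
#: supplied abstract alone ("context-only"), never on prior model knowledge
#: about the drug, and the reply must contain exactly one of the three labels.
CONTEXT_ONLY_PROMPT = (
    "You are assessing evidence about the drug {drug} and the disease "
    "{disease}. Read ONLY the abstract below; do not use any outside or "
    "prior knowledge about this drug. Reply with exactly one word - "
    "positive, neutral, or negative - describing what THIS abstract "
    "reports about the drug's effect on the disease.\n\nAbstract:\n{text}\n"
)

_LABEL_VALUES = {"positive": 1, "neutral": 0, "negative": -1}


class ChatJudge:
    """Adapter that turns a chat-completion callable into a judgment backend.

    ``complete`` maps a prompt string to a reply string.  Transient failures
    are retried ``max_retries`` times; an unparseable or failing call then
    raises :class:`JudgmentError` (callers record the abstract as unjudged
    and exclude it from ``|T|`` — it is never silently coerced to neutral).
    """

    def __init__(
        self,
        complete: Callable[[str], str],
        disease: str = "Alzheimer disease",
        prompt_template: str = CONTEXT_ONLY_PROMPT,
        max_retries: int = 3,
    ) -> None:
        self.complete = complete
        self.disease = disease
        self.prompt_template = prompt_template
        self.max_retries = max_retries

    def judge(self, drug_id: str, record: AbstractRecord) -> Judgment:
        prompt = self.prompt_template.format(
            drug=drug_id, disease=self.disease, text=record.text
        )
        last_error: Optional[Exception] = None
        for _ in range(self.max_retries):
            try:
                reply = self.complete(prompt)
            except Exception as exc:  # network or API failure: retry
                last_error = exc
                continue
            words = _WORD_RE.findall(reply.lower())
            labels = [w for w in words if w in _LABEL_VALUES]
            if len(set(labels)) == 1:
                return Judgment(_LABEL_VALUES[labels[0]], reply.strip())
            last_error = JudgmentError(f"unparseable reply: {reply!r}")
        raise JudgmentError(
            f"backend failed for pmid {record.pmid}: {last_error}"
        )


def classify_abstract(backend, drug_id: str, record: AbstractRecord) -> Judgment:
    """Judge one abstract with the given backend (exactly one judgment)."""
    return backend.judge(drug_id, record)


def judge_corpus(
    backend, records: Sequence[AbstractRecord]
) -> tuple[dict[str, list[Judgment]], int]:
    """Judge every record; returns per-drug judgments and the unjudged count.

    Records whose backend call ultimately fails are excluded from the
    judgment lists (and therefore from ``|T|``) rather than defaulted to
    neutral.
    """
    judged: dict[str, list[Judgment]] = {}
    unjudged = 0
    for rec in records:
        try:
            j = classify_abstract(backend, rec.drug_id, rec)
        except JudgmentError:
            unjudged += 1
            continue
        judged.setdefault(rec.drug_id, []).append(j)
    return judged, unjudged


# ---------------------------------------------------------------------- #
# evidence profiles


@dataclass
class EvidenceProfile:
    """Per-drug judgment counts, exact rates, and criterion labels."""

    drug_id: str
    total: int
    counts: Optional[tuple[int, int, int]] = None  # (P, U, N)
    r_p: Optional[Fraction] = None
    r_u: Optional[Fraction] = None
    r_n: Optional[Fraction] = None

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError("total must be >= 0")
        if self.counts is not None and sum(self.counts) != self.total:
            raise ValueError("counts must sum to total")
        if self.total > 0 and self.r_p is None:
            raise ValueError("rates required when total > 0")

    @property
    def has_evidence(self) -> bool:
        return self.total > 0

    def rounded_rates(self, digits: int = 2) -> tuple[float, float, float]:
        """Display-only rounding of (R_p, R_u, R_n)."""
        if not self.has_evidence:
            raise ValueError("no rates for an evidence-free profile")
        return tuple(round(float(r), digits) for r in (self.r_p, self.r_u, self.r_n))


def aggregate_rates(drug_id: str, judgments: Sequence[Judgment]) -> EvidenceProfile:
    """Aggregate abstract judgments into counts and exact rational rates."""
    p = sum(1 for j in judgments if j.value == 1)
    u = sum(1 for j in judgments if j.value == 0)
    n = sum(1 for j in judgments if j.value == -1)
    total = p + u + n
    if total == 0:
        return EvidenceProfile(drug_id=drug_id, total=0, counts=(0, 0, 0))
    return EvidenceProfile(
        drug_id=drug_id,
        total=total,
        counts=(p, u, n),
        r_p=Fraction(p, total),
        r_u=Fraction(u, total),
        r_n=Fraction(n, total),
    )


def profile_from_rates(
    drug_id: str, total: int, r_u, r_p, r_n
) -> EvidenceProfile:
    """Build a profile from published (possibly rounded) rates.

    Rates may be strings ("0.25"), floats, or Fractions; they are stored as
    exact rationals of their printed value.  Counts are left unknown.
    """
    to_frac = lambda v: v if isinstance(v, Fraction) else Fraction(str(v))
    return EvidenceProfile(
        drug_id=drug_id,
        total=total,
        r_p=to_frac(r_p),
        r_u=to_frac(r_u),
        r_n=to_frac(r_n),
    )


def apply_criterion1(
    profile: EvidenceProfile,
    neutral_threshold: Fraction = DEFAULT_NEUTRAL_THRESHOLD,
) -> str:
    """Conservative rule: skip near-all-neutral, else dominant signal wins."""
    if not profile.has_evidence:
        return INSUFFICIENT_KNOWLEDGE
    if profile.r_u >= neutral_threshold:
        return NEUTRAL_RELATION
    if profile.r_p >= profile.r_n:  # tie resolves to therapeutic
        return POTENTIALLY_THERAPEUTIC
    return POTENTIALLY_ADVERSE


def apply_criterion2(profile: EvidenceProfile) -> str:
    """Sensitivity rule: any positive evidence flags the drug."""
    if not profile.has_evidence:
        return INSUFFICIENT_KNOWLEDGE
    if profile.counts is not None:
        positive = profile.counts[0] >= 1
    else:
        positive = profile.r_p > 0
    return POTENTIALLY_THERAPEUTIC if positive else NO_POSITIVE_SIGN


# ---------------------------------------------------------------------- #
# stratification


@dataclass
class StratificationReport:
    """Pool-level counts under both criteria, with per-model contributions."""

    n_pool: int
    n_judged: int
    n_insufficient: int
    criterion1_counts: dict[str, int]
    criterion2_counts: dict[str, int]
    c1_therapeutic_by_model: dict[str, int]
    labels: pd.DataFrame  # per-drug: drug_id, models, total, criterion1, criterion2

    @property
    def insufficient_pct(self) -> float:
        """Share of the pool with no judged literature, as a percentage."""
        if self.n_pool == 0:
            return 0.0
        return round(100.0 * self.n_insufficient / self.n_pool, 2)


def stratify(
    pool: CandidatePool,
    profiles: Sequence[EvidenceProfile],
    neutral_threshold: Fraction = DEFAULT_NEUTRAL_THRESHOLD,
) -> StratificationReport:
    """Apply both criteria across the pool and tabulate the strata.

    Every profile must belong to a pool drug; pool drugs without a profile
    are treated as evidence-free (``InsufficientKnowledge``).  A drug
    contributed by several models is counted once per contributing model in
    the per-model breakdown.
    """
    by_drug: dict[str, EvidenceProfile] = {}
    for prof in profiles:
        if prof.drug_id not in pool.members:
            raise ValueError(f"profile for drug {prof.drug_id!r} outside the pool")
        if prof.drug_id in by_drug:
            raise ValueError(f"duplicate profile for drug {prof.drug_id!r}")
        by_drug[prof.drug_id] = prof

    rows = []
    c1_counts: dict[str, int] = {}
    c2_counts: dict[str, int] = {}
    by_model: dict[str, int] = {}
    n_insufficient = 0
    for drug in pool.drugs:
        prof = by_drug.get(drug) or EvidenceProfile(drug, 0, counts=(0, 0, 0))
        c1 = apply_criterion1(prof, neutral_threshold)
        c2 = apply_criterion2(prof)
        if not prof.has_evidence:
            n_insufficient += 1
        c1_counts[c1] = c1_counts.get(c1, 0) + 1
        c2_counts[c2] = c2_counts.get(c2, 0) + 1
        if c1 == POTENTIALLY_THERAPEUTIC:
            for model in pool.models_for(drug):
                by_model[model] = by_model.get(model, 0) + 1
        rows.append(
            {
                "drug_id": drug,
                "models": ";".join(pool.models_for(drug)),
                "total": prof.total,
                "criterion1": c1,
                "criterion2": c2,
            }
        )
    return StratificationReport(
        n_pool=pool.size,
        n_judged=pool.size - n_insufficient,
        n_insufficient=n_insufficient,
        criterion1_counts=c1_counts,
        criterion2_counts=c2_counts,
        c1_therapeutic_by_model=by_model,
        labels=pd.DataFrame(
            rows, columns=["drug_id", "models", "total", "criterion1", "criterion2"]
        ),
    )


# ---------------------------------------------------------------------- #
# synthetic corpus generator

_NEUTRAL_SENTENCES = (
    "the pharmacokinetics of {drug} were characterized in elderly participants",
    "a chromatographic assay quantified {drug} in plasma samples from patients",
    "{drug} was co-administered with standard care in a dosing study",
    "binding of {drug} to serum proteins was measured across concentrations",
    "this review summarizes the medicinal chemistry of {drug} derivatives",
)

_POSITIVE_SENTENCES = (
    "treatment with {drug} {token} cognitive performance in a transgenic mouse model",
    "{drug} showed {token} effects on memory consolidation in a pilot trial",
    "administration of {drug} {token} synaptic loss in hippocampal cultures",
)

_NEGATIVE_SENTENCES = (
    "chronic {drug} exposure {token} cognitive decline in treated participants",
    "{drug} was associated with {token} events in a retrospective cohort",
    "high-dose {drug} produced marked {token} in neuronal cultures",
)

# tokens drawn from the shipped lexicons, grouped by how they slot into the
# sentence templates grammatically
_POS_TOKENS = ("improved", "ameliorated", "attenuated", "beneficial", "neuroprotective")
_NEG_TOKENS = ("worsened", "adverse", "toxicity", "exacerbated", "harmful")


def generate_synthetic_corpus(
    profiles: Sequence[tuple[str, int, int, int]],
    seed: int = 0,
    cap: int = DEFAULT_ABSTRACT_CAP,
    year_floor: int = DEFAULT_YEAR_FLOOR,
) -> list[AbstractRecord]:
    """Emit abstracts with planted per-drug (P, U, N) judgment composition.

    For each ``(drug_id, P, U, N)`` profile, P abstracts carry a
    positive-lexicon token, N a negative-lexicon token, and U neither, so
    the lexicon backend recovers the planted counts exactly.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    records: list[AbstractRecord] = []
    pmid = 90_000_000
    for drug_id, p, u, n in profiles:
        if min(p, u, n) < 0:
            raise CorpusError(f"negative counts for drug {drug_id!r}")
        if p + u + n > cap:
            raise CorpusError(
                f"profile for {drug_id!r} exceeds the {cap}-abstract cap"
            )
        kinds = ["positive"] * p + ["neutral"] * u + ["negative"] * n
        for kind in kinds:
            pmid += 1
            year = int(rng.integers(year_floor, 2025))
            filler = _NEUTRAL_SENTENCES[rng.integers(len(_NEUTRAL_SENTENCES))]
            if kind == "positive":
                tmpl = _POSITIVE_SENTENCES[rng.integers(len(_POSITIVE_SENTENCES))]
                text = tmpl.format(drug=drug_id, token=rng.choice(_POS_TOKENS))
            elif kind == "negative":
                tmpl = _NEGATIVE_SENTENCES[rng.integers(len(_NEGATIVE_SENTENCES))]
                text = tmpl.format(drug=drug_id, token=rng.choice(_NEG_TOKENS))
            else:
                text = filler.format(drug=drug_id)
            records.append(
                AbstractRecord(
                    drug_id=drug_id, pmid=str(pmid), year=year, text=text + "."
                )
            )
    return records


def filter_corpus(
    records: Sequence[AbstractRecord],
    year_floor: int = DEFAULT_YEAR_FLOOR,
    cap: int = DEFAULT_ABSTRACT_CAP,
) -> list[AbstractRecord]:
    """Enforce retrieval limits: publication-year floor and per-drug cap."""
    kept: list[AbstractRecord] = []
    per_drug: dict[str, int] = {}
    for rec in records:
        if rec.year < year_floor:
            continue
        if per_drug.get(rec.drug_id, 0) >= cap:
            continue
        per_drug[rec.drug_id] = per_drug.get(rec.drug_id, 0) + 1
        kept.append(rec)
    return kept


def sample_for_audit(
    records: Sequence[AbstractRecord],
    judgments: Mapping[str, Sequence[Judgment]],
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Random sample of judged abstracts for manual review.

    Returns a frame with the abstract, its automatic judgment, and an empty
    ``human_judgment`` column to be filled in by reviewers; the agreement
    rate itself requires that human input.
    """
    offsets = {d: 0 for d in judgments}
    rows = []
    for rec in records:
        js = judgments.get(rec.drug_id)
        if js is None or offsets[rec.drug_id] >= len(js):
            continue
        j = js[offsets[rec.drug_id]]
        offsets[rec.drug_id] += 1
        rows.append(
            {
                "drug_id": rec.drug_id,
                "pmid": rec.pmid,
                "text": rec.text,
                "judgment": j.value,
                "human_judgment": "",
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["drug_id", "pmid", "text", "judgment", "human_judgment"]
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=min(n, len(rows)), replace=False)
    return pd.DataFrame([rows[i] for i in sorted(idx)])


# ---------------------------------------------------------------------- #
# I/O


def write_corpus(records: Sequence[AbstractRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "drug": rec.drug_id,
                        "pmid": rec.pmid,
                        "year": rec.year,
                        "text": rec.text,
                    }
                )
                + "\n"
            )


def load_corpus(path) -> list[AbstractRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            records.append(
                AbstractRecord(
                    drug_id=obj["drug"],
                    pmid=str(obj["pmid"]),
                    year=int(obj["year"]),
                    text=obj["text"],
                )
            )
    return records


def write_profiles(profiles: Sequence[EvidenceProfile], path) -> None:
    rows = []
    for prof in profiles:
        p, u, n = prof.counts if prof.counts else ("", "", "")
        if prof.has_evidence:
            rp, ru, rn = prof.rounded_rates()
            c1, c2 = apply_criterion1(prof), apply_criterion2(prof)
        else:
            rp = ru = rn = ""
            c1 = c2 = INSUFFICIENT_KNOWLEDGE
        rows.append(
            {
                "drug_id": prof.drug_id,
                "T": prof.total,
                "P": p,
                "U": u,
                "N": n,
                "R_p": rp,
                "R_u": ru,
                "R_n": rn,
                "criterion1": c1,
                "criterion2": c2,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
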
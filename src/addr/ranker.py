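"""Elastic-net logistic regression over DWPC features (the "RLR" model).

The model scores drug-disease indication probability from metapath
topology: ``logit(y) = b0 + sum_lambda b_lambda * DWPC_lambda(s, t)`` with
an elastic-net penalty that shrinks and sparsifies the metapath
coefficients.  Labels follow the closed-world assumption: every
(drug, disease) pair without a recorded indication edge is a negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dwpc import DEFAULT_DAMPING, DEFAULT_MAX_LENGTH, build_feature_table
from .hetnet import Hetnet, HetnetError, SynthKGConfig, generate_synthetic_kg

#: FDA-approved Alzheimer's therapeutics masked from ranking when scoring
#: repurposing candidates for Alzheimer's disease.
DEFAULT_AD_MASK = (
    "epicriptine",
    "pramiracetam",
    "acetylcarnitine",
    "ipidacrine",
    "galantamine",
    "tacrine",
    "rivastigmine",
    "donepezil",
)


class FitError(ValueError):
    """Raised when a model cannot be fitted from the given labels/features."""


def label_pairs_closed_world(
    hetnet: Hetnet, edge_type: str = "indication"
) -> pd.Series:
    """Label every (drug, disease) pair: 1 if an indication edge exists, else 0.

    Returns an int Series indexed by a (drug_id, disease_id) MultiIndex over
    the full cartesian product, so the negative set is {all pairs} minus
    {known indications}.
    """
    drugs = hetnet.node_ids_of_type("drug")
    diseases = hetnet.node_ids_of_type("disease")
    if not drugs or not diseases:
        raise HetnetError("hetnet has no drug or no disease nodes")
    positives = hetnet.edge_pairs(edge_type)
    index = pd.MultiIndex.from_product(
        [drugs, diseases], names=["drug_id", "disease_id"]
    )
    labels = pd.Series(
        [1 if pair in positives else 0 for pair in index],
        index=index,
        name="label",
        dtype=int,
    )
    return labels


@dataclass
class RLRModel:
    """Fitted elastic-net logistic model on standardized DWPC features."""

    intercept: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)
    l1_ratio: float = 0.5
    C: float = 1.0
    feature_names: tuple[str, ...] = ()
    feature_means: np.ndarray = field(default_factory=lambda: np.zeros(0))
    feature_scales: np.ndarray = field(default_factory=lambda: np.ones(0))
    fitted: bool = False

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        """Indication probability for each feature row."""
        if not self.fitted:
            raise FitError("model is not fitted")
        x = features[list(self.feature_names)].to_numpy(dtype=float)
        z = (x - self.feature_means) / self.feature_scales
        beta = np.array([self.coefficients[c] for c in self.feature_names])
        logit = self.intercept + z @ beta
        return pd.Series(1.0 / (1.0 + np.exp(-logit)), index=features.index)

    @property
    def nonzero_features(self) -> list[str]:
        return [c for c, b in self.coefficients.items() if b != 0.0]


def fit_rlr(
    features: pd.DataFrame,
    labels: pd.Series,
    *,
    l1_ratio: float = 0.5,
    strength: Optional[float] = None,
    cv_folds: int = 5,
    seed: int = 0,
    max_iter: int = 5000,
) -> RLRModel:
    """Fit the elastic-net logistic regression.

    ``strength`` is the overall penalty weight (``1/C``); ``None`` selects
    it by ``cv_folds``-fold cross-validated log-loss over a logarithmic
    grid, and ``0`` fits without regularization.  Features are standardized
    to zero mean and unit variance internally; coefficients are reported on
    the standardized scale.
    """
    labels = labels.loc[features.index]
    x = features.to_numpy(dtype=float)
    y = labels.to_numpy(dtype=int)
    if not np.isfinite(x).all():
        raise FitError("non-finite feature values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise FitError("labels contain a single class; need >=1 of each")

    means = x.mean(axis=0)
    raw_scales = x.std(axis=0)
    varying = raw_scales > 0.0
    scales = np.where(varying, raw_scales, 1.0)
    z = ((x - means) / scales)[:, varying]

    if not varying.any():
        # constant features carry no information: intercept-only closed form
        prevalence = y.mean()
        return RLRModel(
            intercept=float(np.log(prevalence / (1.0 - prevalence))),
            coefficients={c: 0.0 for c in features.columns},
            l1_ratio=l1_ratio,
            C=np.inf,
            feature_names=tuple(features.columns),
            feature_means=means,
            feature_scales=scales,
            fitted=True,
        )

    if strength == 0.0:
        est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter)
        est.fit(z, y)
        C = np.inf
    elif strength is not None:
        C = 1.0 / strength
        est = LogisticRegression(
            solver="saga",
            l1_ratio=l1_ratio,
            C=C,
            max_iter=max_iter,
            random_state=seed,
        )
        est.fit(z, y)
    else:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        est = LogisticRegressionCV(
            Cs=np.logspace(-2, 2, 9),
            solver="saga",
            l1_ratios=[l1_ratio],
            cv=cv,
            scoring="neg_log_loss",
            max_iter=max_iter,
            random_state=seed,
            use_legacy_attributes=False,
        )
        est.fit(z, y)
        C = float(np.atleast_1d(est.C_)[0])

    beta = np.zeros(len(features.columns))
    beta[varying] = est.coef_.ravel()
    coefs = dict(zip(features.columns, beta.tolist()))
    return RLRModel(
        intercept=float(est.intercept_[0]),
        coefficients=coefs,
        l1_ratio=l1_ratio,
        C=C,
        feature_names=tuple(features.columns),
        feature_means=means,
        feature_scales=scales,
        fitted=True,
    )


@dataclass
class RankedList:
    """One model's ordered candidate drugs for the target disease."""

    model_name: str
    entries: list[tuple[str, float, int]]  # (drug_id, score, rank)
    masked_drugs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        masked = set(self.masked_drugs)
        last = None
        for i, (drug, score, rank) in enumerate(self.entries):
            if rank != i + 1:
                raise ValueError(f"ranks must be 1..n without gaps, got {rank}")
            if drug in masked:
                raise ValueError(f"masked drug {drug!r} present in ranking")
            if last is not None and score > last + 1e-12:
                raise ValueError("scores must be non-increasing with rank")
            last = score

    @property
    def drugs(self) -> list[str]:
        return [d for d, _, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["drug_id", "score", "rank"])


def rank_candidates(
    model: RLRModel,
    features: pd.DataFrame,
    target_disease: str,
    mask: Sequence[str] = (),
    top_k: int = 30,
) -> RankedList:
    """Score all drugs against ``target_disease`` and keep the top ``top_k``.

    Masked drugs are removed before ranking.  Ties are broken by drug id
    (lexicographic), making the output deterministic.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    diseases = features.index.get_level_values("disease_id")
    if target_disease not in set(diseases):
        raise KeyError(f"disease {target_disease!r} absent from feature table")
    sub = features.xs(target_disease, level="disease_id")
    sub = sub.loc[~sub.index.isin(set(mask))]
    entries: list[tuple[str, float, int]] = []
    if len(sub):
        scores = model.predict_proba(sub)
        order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        entries = [(d, float(s), i + 1) for i, (d, s) in enumerate(order)]
    return RankedList(
        model_name="RLR", entries=entries, masked_drugs=tuple(mask)
    )


# ---------------------------------------------------------------------- #
# planted-indication recovery experiment


def remove_indication_edges(
    hetnet: Hetnet, pairs: Sequence[tuple[str, str]], edge_type: str = "indication"
) -> Hetnet:
    """Copy of ``hetnet`` without the indication edges joining ``pairs``."""
    drop = set(pairs)
    edges = [
        (s, e, t)
        for s, e, t in hetnet.edges
        if not (e == edge_type and (s, t) in drop)
    ]
    return Hetnet(nodes=dict(hetnet.nodes), edges=edges, names=dict(hetnet.names))


def evaluate_recovery(
    config: SynthKGConfig,
    *,
    holdout_fraction: float = 0.25,
    damping: float = DEFAULT_DAMPING,
    max_length: int = DEFAULT_MAX_LENGTH,
    seed: Optional[int] = None,
) -> dict:
    """Held-out recovery of planted indications on a synthetic hetnet.

    A fraction of the planted indication edges is removed from the graph;
    the model is fitted closed-world on the remainder and the held-out
    pairs are scored against all non-indicated pairs.  Returns the AUROC
    and the mean rank of held-out positives among the scored pairs.
    """
    hetnet, planted = generate_synthetic_kg(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_hold = max(1, round(holdout_fraction * len(planted)))
    hold_idx = rng.choice(len(planted), size=n_hold, replace=False)
    holdout = [planted[i] for i in sorted(hold_idx)]
    trimmed = remove_indication_edges(hetnet, holdout)

    features = build_feature_table(
        trimmed, damping=damping, max_length=max_length
    )
    labels = label_pairs_closed_world(trimmed)
    model = fit_rlr(features, labels, seed=config.seed)
    scores = model.predict_proba(features)

    eval_index = labels.index[labels == 0]  # holdout pairs are labeled 0
    y_true = np.array([pair in set(holdout) for pair in eval_index], dtype=int)
    y_score = scores.loc[eval_index].to_numpy()
    auroc = float(roc_auc_score(y_true, y_score))
    order = pd.Series(y_score, index=eval_index).rank(ascending=False)
    mean_rank = float(order[y_true == 1].mean())
    return {
        "auroc": auroc,
        "mean_holdout_rank": mean_rank,
        "n_holdout": n_hold,
        "n_eval_pairs": int(len(eval_index)),
        "model": model,
    }


def write_scores(ranked: RankedList, path) -> None:
    ranked.to_frame().to_csv(path, sep="\t", index=False)


def write_coefficients(model: RLRModel, path) -> None:
    pd.DataFrame(
        sorted(model.coefficients.items()), columns=["metapath", "beta"]
    ).to_csv(path, sep="\t", index=False)
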
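"""MSI status classification from unstable-locus counts.

Each sample is encoded by the number of unstable microsatellites in a
chosen genic-region stratum (optionally split by repeat class).  A tree
ensemble — random forest by default, gradient-boosted trees as an
alternative — is trained on a balanced resample: 80% of the MSI-H samples
and an equal number of MSS samples, drawn without replacement; everything
else forms the test set.  Evaluation repeats the resample/train/test cycle
(10 repetitions by default) and reports the AUC per repeat.  The predicted
MSI-H probability of a random forest is the fraction of trees voting
MSI-H.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .instability import SampleInstabilitySummary
from .catalog import REPEAT_CLASSES

MSI_H = "MSI-H"
MSS = "MSS"


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    """Balanced-resampling and ensemble settings.

    ``train_fraction`` is the fraction of MSI-H samples drawn per repeat
    (an equal number of MSS samples joins them); ``region`` selects the
    locus stratum whose unstable count is the feature.
    """

    train_fraction: float = 0.8
    n_repeats: int = 10
    n_trees: int = 100
    model_type: str = "random_forest"
    region: Optional[str] = "UTR3"
    stratify_features: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1 or self.n_trees < 1:
            raise ValueError("n_repeats and n_trees must be >= 1")
        if self.model_type not in ("random_forest", "gradient_boosted"):
            raise ValueError(f"unknown model_type {self.model_type!r}")


@dataclass
class MSIModel:
    estimator: object
    config: TrainingConfig
    feature_names: list[str]


@dataclass(frozen=True)
class MSIPrediction:
    sample_id: str
    probability: float
    label: str


def encode_features(
    summaries: Sequence[SampleInstabilitySummary],
    cfg: TrainingConfig = TrainingConfig(),
    labels: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, Optional[np.ndarray]]:
    """Build the feature table (samples x features) and label vector.

    Default: one column, the unstable-locus count in ``cfg.region`` (all
    regions when ``cfg.region`` is None).  With ``stratify_features``, one
    count per repeat class within the region plus the total.  A sample
    with zero tested loci in the stratum is an error, not a zero feature.
    """
    region = cfg.region
    suffix = region if region is not None else "ALL"
    rows, index = [], []
    for s in summaries:
        if s.n_tested(region=region) == 0:
            raise ClassifyError(
                f"sample {s.sample_id}: no tested locus in region {suffix}"
            )
        if cfg.stratify_features:
            row = {
                f"n_unstable_{suffix}_{cls}": s.n_unstable(region=region, repeat_class=cls)
                for cls in REPEAT_CLASSES
            }
            row[f"n_unstable_{suffix}"] = s.n_unstable(region=region)
        else:
            row = {f"n_unstable_{suffix}": s.n_unstable(region=region)}
        rows.append(row)
        index.append(s.sample_id)
    X = pd.DataFrame(rows, index=index)
    y = None
    if labels is not None:
        missing = [sid for sid in index if sid not in labels]
        if missing:
            raise ClassifyError(f"samples without MSI label: {missing[:3]}")
        y = np.array([labels[sid] for sid in index])
    return X, y


def balanced_split(
    labels: Mapping[str, str],
    cfg: TrainingConfig = TrainingConfig(),
    seed: Optional[int] = None,
) -> tuple[list[str], list[str]]:
    """Balanced train/test split by MSI status.

    Training set: floor(train_fraction * n_MSI-H) MSI-H samples plus
    equally many MSS samples, sampled without replacement under ``seed``
    (defaults to ``cfg.seed``); all remaining samples are the test set.
    """
    pos = [sid for sid, lab in labels.items() if lab == MSI_H]
    neg = [sid for sid, lab in labels.items() if lab == MSS]
    if len(pos) < 2 or len(neg) < 2:
        raise ClassifyError("need at least 2 samples per class")
    n_train = math.floor(cfg.train_fraction * len(pos))
    if n_train < 1:
        raise ClassifyError("train_fraction leaves no MSI-H training sample")
    if len(neg) < n_train:
        raise ClassifyError(
            f"need {n_train} MSS training samples, have {len(neg)}"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    train_pos = list(rng.choice(pos, size=n_train, replace=False))
    train_neg = list(rng.choice(neg, size=n_train, replace=False))
    train = train_pos + train_neg
    train_set = set(train)
    test = [sid for sid in labels if sid not in train_set]
    return train, test


def _make_estimator(cfg: TrainingConfig, seed: int):
    if cfg.model_type == "random_forest":
        return RandomForestClassifier(n_estimators=cfg.n_trees, random_state=seed)
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=cfg.n_trees,
        random_state=seed,
        eval_metric="logloss",
    )


def train_classifier(
    X: pd.DataFrame,
    y: Sequence[str],
    cfg: TrainingConfig = TrainingConfig(),
    seed: Optional[int] = None,
) -> MSIModel:
    """Fit the tree ensemble; both classes must be present in ``y``."""
    y = np.asarray(y)
    if len(set(y)) < 2:
        raise ClassifyError("training labels contain a single class")
    est = _make_estimator(cfg, cfg.seed if seed is None else seed)
    est.fit(X.values, (y == MSI_H).astype(int))
    return MSIModel(estimator=est, config=cfg, feature_names=list(X.columns))


def predict_probability(
    model: MSIModel, X: pd.DataFrame, threshold: float = 0.5
) -> list[MSIPrediction]:
    """Per-sample MSI-H probability and thresholded label.

    For a random forest the probability is the fraction of trees whose
    individual prediction is MSI-H; gradient-boosted models report their
    native probability.
    """
    if list(X.columns) != model.feature_names:
        raise ClassifyError(
            f"feature mismatch: model expects {model.feature_names}, "
            f"got {list(X.columns)}"
        )
    est = model.estimator
    if isinstance(est, RandomForestClassifier):
        votes = np.stack(
            [tree.predict(X.values.astype(np.float32)) for tree in est.estimators_]
        )
        prob = votes.mean(axis=0)
    else:
        prob = est.predict_proba(X.values)[:, 1]
    return [
        MSIPrediction(
            sample_id=str(sid),
            probability=float(p),
            label=MSI_H if p >= threshold else MSS,
        )
        for sid, p in zip(X.index, prob)
    ]


def compute_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), via the rank formula."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ClassifyError("AUC needs both classes present")
    return float(roc_auc_score((labels == MSI_H).astype(int), np.asarray(scores)))


@dataclass
class CVResult:
    aucs: list[float]
    mean_auc: float
    sd_auc: float  # NaN when a single repeat


def cross_validate(
    X: pd.DataFrame,
    labels: Mapping[str, str],
    cfg: TrainingConfig = TrainingConfig(),
) -> CVResult:
    """Repeated balanced resampling: split, train, score the held-out set.

    Repeat seeds are derived from ``cfg.seed`` so the whole procedure is
    reproducible; each repeat's AUC is computed on its own test samples.
    """
    aucs = []
    for rep in range(cfg.n_repeats):
        rep_seed = (cfg.seed + 1000003 * (rep + 1)) % (2**31 - 1)
        train_ids, test_ids = balanced_split(labels, cfg, seed=rep_seed)
        model = train_classifier(
            X.loc[train_ids], [labels[s] for s in train_ids], cfg, seed=rep_seed
        )
        preds = predict_probability(model, X.loc[test_ids])
        aucs.append(
            compute_auc([p.probability for p in preds], [labels[s] for s in test_ids])
        )
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else float("nan")
    return CVResult(aucs=aucs, mean_auc=mean, sd_auc=sd)


def write_predictions(preds: Sequence[MSIPrediction], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tprobability\tlabel\n")
        for p in preds:
            fh.write(f"{p.sample_id}\t{p.probability:.4f}\t{p.label}\n")
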
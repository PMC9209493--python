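"""Two-stage LASSO classification producing ApV scores.

Stage 1 separates subjects without Alzheimer-related pathology (nADrp:
healthy controls, Parkinson's, frontotemporal dementia) from those with it
(ADrp: MCI due to AD, plus AD); stage 2 separates prodromal (MCI_AD) from
late (AD) disease among stage-1 positives.  Each stage is a pipeline:

    standardize (training stats) -> FDR < 5% univariate screen ->
    [optionally append standardized clinical scores and age] ->
    L1-penalized fit with 10-fold cross-validated lambda ->
    Youden-optimal operating threshold on the training ROC.

The ApV score of a subject is the linear predictor: intercept plus the
weighted sum of the selected standardized features.  Clinical-score variants
are conventionally tagged ApV1s / ApV2s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from .diagnostics import (
    DiagnosticReport,
    evaluate_scores,
    roc_curve,
    youden_threshold,
)
from .screening import (
    FeatureMatrix,
    SchemaError,
    ScreeningResult,
    StandardizationParams,
    screen_features,
    standardize_apply,
    standardize_fit,
)

#: published CSF biomarker cut-offs (pg/ml), kept as reference constants
CSF_CUTOFFS_PG_ML = {"tau": 93.0, "abeta": 192.0, "ptau": 23.0}

STAGE1_CONTRAST = (frozenset({"CN", "PD", "FTD"}), frozenset({"MCI_AD", "AD"}))
STAGE2_CONTRAST = (frozenset({"MCI_AD"}), frozenset({"AD"}))


class LabelError(ValueError):
    pass


class FoldError(ValueError):
    pass


class EmptyModelError(ValueError):
    """Screening kept no features and no clinical scores were offered."""


@dataclass
class StageConfig:
    """Tunables of one LASSO stage."""

    screening_test: str = "mann_whitney"
    fdr_level: float = 0.05
    family: str = "binomial"          # binomial (CV deviance) | gaussian (CV MSE)
    folds: int = 10
    seed: int = 0
    n_lambda: int = 40
    lambda_decades: float = 3.0


@dataclass
class LassoCVResult:
    lambda_grid: np.ndarray
    cv_loss: np.ndarray
    lambda_chosen: float
    coef: pd.Series
    intercept: float


def _fit_at_lambda(X: np.ndarray, y: np.ndarray, lam: float, family: str):
    """Fit an L1 model parameterized so lambda matches the penalized
    objective (1/n) * loss + lambda * ||w||_1."""
    n = len(y)
    if family == "binomial":
        model = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
            max_iter=2000, tol=1e-8, random_state=0,
        )
        model.fit(X, y)
        return model.coef_.ravel().copy(), float(model.intercept_[0]), model
    model = Lasso(alpha=lam, max_iter=50000, tol=1e-10)
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_), model


def _cv_loss(model, X: np.ndarray, y: np.ndarray, family: str) -> float:
    if family == "binomial":
        p = np.clip(model.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
        return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return float(np.mean((model.predict(X) - y) ** 2))


def lasso_cv_fit(
    X,
    y,
    family: str = "binomial",
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 40,
    lambda_decades: float = 3.0,
) -> LassoCVResult:
    """L1 path over a geometric lambda grid with stratified K-fold CV.

    The grid runs from lambda_max (the smallest lambda at which every
    coefficient is zero) down ``lambda_decades`` decades; the chosen lambda
    minimizes the cross-validated loss (deviance for binomial, MSE for
    gaussian), with ties resolved toward the sparser (larger) lambda.
    """
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unknown family {family!r}")
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64).ravel()
    classes = np.unique(ya)
    if len(classes) < 2:
        raise LabelError("both classes must be present")
    counts = [int((ya == c).sum()) for c in classes]
    if min(counts) < folds:
        raise FoldError(
            f"need >= {folds} subjects per class for {folds}-fold CV, got {counts}"
        )
    n = len(ya)
    lam_max = float(np.max(np.abs(Xa.T @ (ya - ya.mean()))) / n)
    if lam_max <= 0:
        lam_max = 1e-3
    grid = np.geomspace(lam_max, lam_max * 10.0 ** (-lambda_decades), n_lambda)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xa, ya))
    cv_loss = np.zeros(n_lambda)
    for i, lam in enumerate(grid):
        losses = []
        for train_idx, val_idx in splits:
            _, _, model = _fit_at_lambda(Xa[train_idx], ya[train_idx], lam, family)
            losses.append(_cv_loss(model, Xa[val_idx], ya[val_idx], family))
        cv_loss[i] = np.mean(losses)
    best = int(np.argmin(cv_loss))  # grid is descending: ties favour sparser fits
    lam_chosen = float(grid[best])
    coef, intercept, _ = _fit_at_lambda(Xa, ya, lam_chosen, family)
    return LassoCVResult(
        lambda_grid=grid,
        cv_loss=cv_loss,
        lambda_chosen=lam_chosen,
        coef=pd.Series(coef, index=columns),
        intercept=intercept,
    )


@dataclass
class LassoStageModel:
    """One fitted stage: selected features, weights, lambda, threshold.

    ``columns`` is the full LASSO input (screened features plus any clinical
    scores); ``coef`` is aligned to it and mostly zero.  Standardization
    statistics cover every input column so the model can score raw data.
    """

    tag: str                                 # ApV1 | ApV1s | ApV2 | ApV2s
    columns: list[str]
    coef: pd.Series
    intercept: float
    lambda_grid: np.ndarray
    cv_loss: np.ndarray
    lambda_chosen: float
    threshold: float
    mean: pd.Series
    sd: pd.Series
    negative_groups: frozenset
    positive_groups: frozenset
    family: str
    folds: int
    seed: int
    screening: ScreeningResult | None = None
    score_columns: list[str] = field(default_factory=list)

    @property
    def selected(self) -> pd.Index:
        return self.coef.index[self.coef != 0.0]

    def _input_matrix(self, m: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
        if isinstance(m, FeatureMatrix):
            parts = [m.data]
            if self.score_columns:
                if m.scores is None:
                    raise SchemaError(
                        f"model expects clinical scores {self.score_columns}"
                    )
                parts.append(m.scores)
            raw = pd.concat(parts, axis=1)
        else:
            raw = m
        missing = [c for c in self.selected if c not in raw.columns]
        if missing:
            raise SchemaError(f"missing selected features: {missing[:5]}")
        cols = [c for c in self.columns if c in raw.columns]
        return raw[cols]

    def score(self, m: FeatureMatrix | pd.DataFrame) -> pd.Series:
        """ApV = intercept + sum of weight_i * standardized feature_i."""
        raw = self._input_matrix(m)
        mean = self.mean.reindex(raw.columns)
        sd = self.sd.reindex(raw.columns).replace(0.0, 1.0)
        z = ((raw - mean) / sd).fillna(0.0)
        w = self.coef.reindex(raw.columns).fillna(0.0)
        return (z @ w) + self.intercept

    def evaluate(self, m: FeatureMatrix | pd.DataFrame, labels) -> DiagnosticReport:
        scores = self.score(m)
        return evaluate_scores(scores.to_numpy(), np.asarray(labels), self.threshold)

    def to_dict(self) -> dict:
        return {
            "tag": self.tag,
            "columns": list(self.columns),
            "coef": {c: float(v) for c, v in self.coef.items() if v != 0.0},
            "intercept": self.intercept,
            "lambda_grid": [float(v) for v in self.lambda_grid],
            "cv_loss": [float(v) for v in self.cv_loss],
            "lambda_chosen": self.lambda_chosen,
            "threshold": self.threshold,
            "mean": {c: float(v) for c, v in self.mean.items()},
            "sd": {c: float(v) for c, v in self.sd.items()},
            "negative_groups": sorted(self.negative_groups),
            "positive_groups": sorted(self.positive_groups),
            "family": self.family,
            "folds": self.folds,
            "seed": self.seed,
            "score_columns": list(self.score_columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LassoStageModel":
        columns = list(d["columns"])
        coef = pd.Series(0.0, index=columns)
        for c, v in d["coef"].items():
            coef[c] = v
        return cls(
            tag=d["tag"],
            columns=columns,
            coef=coef,
            intercept=float(d["intercept"]),
            lambda_grid=np.asarray(d["lambda_grid"]),
            cv_loss=np.asarray(d["cv_loss"]),
            lambda_chosen=float(d["lambda_chosen"]),
            threshold=float(d["threshold"]),
            mean=pd.Series(d["mean"]).reindex(columns),
            sd=pd.Series(d["sd"]).reindex(columns),
            negative_groups=frozenset(d["negative_groups"]),
            positive_groups=frozenset(d["positive_groups"]),
            family=d["family"],
            folds=int(d["folds"]),
            seed=int(d["seed"]),
            score_columns=list(d["score_columns"]),
        )


def fit_stage(
    m: FeatureMatrix,
    contrast: tuple[frozenset, frozenset] = STAGE1_CONTRAST,
    include_scores: bool = False,
    config: StageConfig | None = None,
    tag: str | None = None,
) -> LassoStageModel:
    """Fit one cascade stage on the subjects belonging to the contrast groups.

    Clinical scores and age, when included, bypass the FDR screen and enter
    the LASSO as candidates directly; the fitted orientation is fixed so the
    positive (disease) class has the higher mean training score.
    """
    config = config or StageConfig()
    negative, positive = frozenset(contrast[0]), frozenset(contrast[1])
    labels = m.binary_labels(set(negative), set(positive))
    if (labels == 0).sum() == 0 or (labels == 1).sum() == 0:
        raise LabelError(f"both contrast groups must be present ({negative} vs {positive})")
    sub = m.select_subjects(labels.index)
    y = labels.to_numpy()

    params = standardize_fit(sub.data)
    z = standardize_apply(sub.data, params)
    screening = screen_features(
        z, y, test=config.screening_test, level=config.fdr_level
    )
    X = z.loc[:, screening.kept_features]

    score_columns: list[str] = []
    score_params: StandardizationParams | None = None
    if include_scores:
        if sub.scores is None or sub.scores.shape[1] == 0:
            raise SchemaError("include_scores=True but the matrix has no clinical scores")
        sc = sub.scores.astype(np.float64)
        score_params = standardize_fit(sc)
        zs = standardize_apply(sc, score_params)
        score_columns = list(zs.columns)
        X = pd.concat([X, zs], axis=1)

    if X.shape[1] == 0:
        raise EmptyModelError("screening kept 0 features and no scores were included")

    cv = lasso_cv_fit(
        X, y, family=config.family, folds=config.folds, seed=config.seed,
        n_lambda=config.n_lambda, lambda_decades=config.lambda_decades,
    )
    coef = cv.coef
    intercept = cv.intercept
    scores_train = (X @ coef) + intercept
    # orientation: the disease class must sit above the threshold
    if scores_train[y == 1].mean() < scores_train[y == 0].mean():
        coef = -coef
        intercept = -intercept
        scores_train = -scores_train
    threshold = youden_threshold(roc_curve(scores_train.to_numpy(), y))

    mean = pd.concat([params.mean, score_params.mean]) if score_params else params.mean
    sd = pd.concat([params.sd, score_params.sd]) if score_params else params.sd
    columns = list(X.columns)
    if tag is None:
        tag = ("ApV1" if positive == frozenset({"MCI_AD", "AD"}) else "ApV2") + (
            "s" if include_scores else ""
        )
    return LassoStageModel(
        tag=tag,
        columns=columns,
        coef=coef,
        intercept=float(intercept),
        lambda_grid=cv.lambda_grid,
        cv_loss=cv.cv_loss,
        lambda_chosen=cv.lambda_chosen,
        threshold=float(threshold),
        mean=mean.reindex(columns),
        sd=sd.reindex(columns),
        negative_groups=negative,
        positive_groups=positive,
        family=config.family,
        folds=config.folds,
        seed=config.seed,
        screening=screening,
        score_columns=score_columns,
    )


def apv_score(model: LassoStageModel, row: pd.Series | pd.DataFrame) -> pd.Series:
    """Score one or more feature rows with a fitted stage model."""
    if isinstance(row, pd.Series):
        row = row.to_frame().T
    return model.score(row)


@dataclass
class CascadeModel:
    """The chained two-stage classifier with label semantics
    nADrp -> MCI_AD -> AD."""

    stage1: LassoStageModel
    stage2: LassoStageModel
    region_set: str = "ALL115"
    catalogue_hash: str = ""

    def predict(self, m: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
        """Per subject: both stage scores, the cascade label, and whether the
        stage-2 score was actually used (stage-1 positives only)."""
        s1 = self.stage1.score(m)
        s2 = self.stage2.score(m)
        gate = s1 >= self.stage1.threshold
        label = np.where(
            ~gate, "nADrp", np.where(s2 >= self.stage2.threshold, "AD", "MCI_AD")
        )
        return pd.DataFrame(
            {
                "apv1": s1,
                "apv2": s2,
                "label": label,
                "stage2_used": gate,
            },
            index=s1.index,
        )

    def to_json(self, path) -> None:
        d = {
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
            "region_set": self.region_set,
            "catalogue_hash": self.catalogue_hash,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "CascadeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            stage1=LassoStageModel.from_dict(d["stage1"]),
            stage2=LassoStageModel.from_dict(d["stage2"]),
            region_set=d["region_set"],
            catalogue_hash=d["catalogue_hash"],
        )


def cascade_predict(model: CascadeModel, m: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    return model.predict(m)


def fit_cascade(
    train: FeatureMatrix,
    include_scores: bool = False,
    config: StageConfig | None = None,
    region_set: str = "ALL115",
    catalogue_hash: str = "",
) -> CascadeModel:
    """Fit both stages on their own training contrasts.

    Stage 2 trains on the true MCI_AD / AD labels; at deployment only
    stage-1 positives are routed to it.
    """
    stage1 = fit_stage(train, STAGE1_CONTRAST, include_scores, config)
    stage2 = fit_stage(train, STAGE2_CONTRAST, include_scores, config)
    return CascadeModel(
        stage1=stage1, stage2=stage2, region_set=region_set, catalogue_hash=catalogue_hash
    )


def train_validation_split(
    m: FeatureMatrix, fraction: float = 0.7, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified train/validation split of subjects (default 70/30)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    train_idx, val_idx = train_test_split(
        m.subjects.to_numpy(),
        train_size=fraction,
        stratify=m.groups.to_numpy(),
        random_state=seed,
    )
    return m.select_subjects(train_idx), m.select_subjects(val_idx)


def _top_k_features(model: LassoStageModel, k: int) -> list[str]:
    """Top-k selected features by |weight|; ties broken by feature name."""
    w = model.coef[model.coef != 0.0]
    order = sorted(w.index, key=lambda c: (-abs(w[c]), c))
    return order[:k]


def subset_robustness(
    model: LassoStageModel,
    eval_m: FeatureMatrix | pd.DataFrame,
    labels,
    k: int = 4,
) -> pd.DataFrame:
    """Diagnostic panel of ApV restricted to feature subsets.

    Rows: Ftot (all selected features), Ftest{k} (top-k by |weight|), every
    size-(k-1) subset (Ftest3-p1..p4 for k = 4) and every size-(k-2) subset
    (Ftest2-p5..p10).  Weights stay at their fitted values; each subset's
    threshold is re-derived by the Youden rule on the evaluation split.
    """
    selected = list(model.selected)
    if len(selected) < k:
        raise ValueError(f"model has {len(selected)} selected features; need >= {k}")
    y = np.asarray(labels).astype(int)
    raw = model._input_matrix(eval_m)
    mean = model.mean.reindex(raw.columns)
    sd = model.sd.reindex(raw.columns).replace(0.0, 1.0)
    z = ((raw - mean) / sd).fillna(0.0)

    top = _top_k_features(model, k)
    subsets: list[tuple[str, list[str]]] = [("Ftot", selected), (f"Ftest{k}", top)]
    counter = 1
    for size in (k - 1, k - 2):
        for combo in combinations(top, size):
            subsets.append((f"Ftest{size}-p{counter}", list(combo)))
            counter += 1

    rows = {}
    feats = {}
    for name, cols in subsets:
        w = model.coef.reindex(z.columns).fillna(0.0).copy()
        w[~w.index.isin(cols)] = 0.0
        scores = ((z @ w) + model.intercept).to_numpy()
        curve = roc_curve(scores, y)
        thr = youden_threshold(curve)
        report = evaluate_scores(scores, y, thr, auc=curve.auc)
        rows[name] = report.to_series()
        feats[name] = ";".join(cols)
    out = pd.DataFrame(rows).T
    out["features"] = pd.Series(feats)
    out.index.name = "subset"
    return out
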
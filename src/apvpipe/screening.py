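"""Feature standardization and FDR-controlled univariate screening.

Features are z-scored on training-split statistics, compared between the two
contrast groups with a rank-sum (Mann-Whitney) or Welch t test, and the
subset with Benjamini-Hochberg false discovery rate below 5% is passed to
the LASSO.  The same two-group test doubles as the generic per-region scalar
comparison (e.g. fractional anisotropy tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class SampleSizeError(ValueError):
    pass


class SchemaError(ValueError):
    pass


#: group vocabulary: raw study groups and the binary supergroups
RAW_GROUPS = ("CN", "PD", "FTD", "MCI_AD", "AD")
NADRP_GROUPS = frozenset({"CN", "PD", "FTD"})
ADRP_GROUPS = frozenset({"MCI_AD", "AD"})

CLINICAL_SCORE_COLUMNS = ("MMSE", "LDELTOTAL", "abeta", "tau", "ptau", "age")


def to_supergroup(label: str) -> str:
    """Collapse a raw group label to nADrp / ADrp."""
    if label in NADRP_GROUPS or label == "nADrp":
        return "nADrp"
    if label in ADRP_GROUPS or label == "ADrp":
        return "ADrp"
    raise ValueError(f"unknown group label {label!r}")


@dataclass
class FeatureMatrix:
    """Subjects x features table with group labels and optional clinical scores."""

    data: pd.DataFrame                      # index: subject_id, columns: feature names
    groups: pd.Series                       # index: subject_id
    scores: pd.DataFrame | None = None      # optional clinical-score columns

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise SchemaError(f"duplicate subject ids: {dup}")
        self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise SchemaError(f"subjects without group label: {missing}")
        if self.scores is not None:
            self.scores = self.scores.reindex(self.data.index)

    @property
    def subjects(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> pd.Index:
        return self.data.columns

    def select_subjects(self, subjects) -> "FeatureMatrix":
        return FeatureMatrix(
            data=self.data.loc[subjects],
            groups=self.groups.loc[subjects],
            scores=None if self.scores is None else self.scores.loc[subjects],
        )

    def binary_labels(self, negative: set[str], positive: set[str]) -> pd.Series:
        """0/1 labels for a contrast; subjects outside both sets are dropped."""
        g = self.groups
        keep = g.isin(negative | positive)
        return g[keep].isin(positive).astype(int)


@dataclass
class StandardizationParams:
    """Per-feature training mean and (sample) standard deviation."""

    mean: pd.Series
    sd: pd.Series
    flagged: pd.Index = field(default_factory=lambda: pd.Index([]))  # zero-variance features

    def feature_names(self) -> pd.Index:
        return self.mean.index


def standardize_fit(train: pd.DataFrame | FeatureMatrix) -> StandardizationParams:
    """Estimate per-feature mean/sd on the training split only.

    Masked (NaN) entries are ignored in the estimates; zero-variance features
    are flagged and later standardized to 0.
    """
    df = train.data if isinstance(train, FeatureMatrix) else train
    if len(df) < 2:
        raise SampleSizeError(f"need >= 2 subjects to standardize, got {len(df)}")
    mean = df.mean(axis=0, skipna=True)
    sd = df.std(axis=0, ddof=1, skipna=True)
    sd = sd.fillna(0.0)
    mean = mean.fillna(0.0)
    flagged = sd.index[sd == 0.0]
    return StandardizationParams(mean=mean, sd=sd, flagged=flagged)


def standardize_apply(
    m: pd.DataFrame | FeatureMatrix, params: StandardizationParams
) -> pd.DataFrame:
    """(x - mean) / sd per feature; flagged features and masked values map to 0.

    A 0 after z-scoring is the training mean: the neutral value under a
    linear model on standardized inputs.
    """
    df = m.data if isinstance(m, FeatureMatrix) else m
    if not df.columns.equals(params.feature_names()):
        raise SchemaError("feature names do not match standardization parameters")
    sd = params.sd.replace(0.0, 1.0)
    z = (df - params.mean) / sd
    z.loc[:, params.flagged] = 0.0
    return z.fillna(0.0)


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact null for n1, n2 <= 8 without ties,
    normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise SampleSizeError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= 8 and len(y) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def groupwise_test(
    m: pd.DataFrame | FeatureMatrix,
    labels: pd.Series | np.ndarray,
    test: str = "mann_whitney",
) -> pd.Series:
    """Per-feature two-sided p-values for a binary contrast.

    Constant features (identical in every subject) get p = 1.  NaN entries
    are dropped per feature.
    """
    df = m.data if isinstance(m, FeatureMatrix) else m
    y = np.asarray(labels).astype(int)
    if len(y) != len(df):
        raise SchemaError("labels length does not match subject count")
    if (y == 0).sum() == 0 or (y == 1).sum() == 0:
        raise SampleSizeError("both contrast groups must be non-empty")
    if test not in ("mann_whitney", "welch_t"):
        raise ValueError(f"unknown test {test!r}")

    values = df.to_numpy(dtype=np.float64)
    pvals = np.ones(values.shape[1])
    mask0 = y == 0
    mask1 = y == 1

    if test == "welch_t":
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(
                values[mask1], values[mask0], equal_var=False, nan_policy="omit", axis=0
            )
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        return pd.Series(pvals, index=df.columns, name="p")

    clean = ~np.isnan(values)
    all_clean = clean.all()
    n0, n1 = int(mask0.sum()), int(mask1.sum())
    exact_ok = n0 <= 8 and n1 <= 8
    if all_clean and not exact_ok:
        # vectorized tie-corrected normal approximation over all features
        const = np.all(values == values[0], axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(
                values[mask1], values[mask0], alternative="two-sided",
                method="asymptotic", axis=0,
            )
        pvals = np.where(const, 1.0, res.pvalue)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
    else:
        for j in range(values.shape[1]):
            col = values[:, j]
            ok = ~np.isnan(col)
            xj = col[ok & mask1]
            yj = col[ok & mask0]
            if len(xj) == 0 or len(yj) == 0:
                pvals[j] = 1.0
                continue
            pvals[j] = mann_whitney_p(xj, yj)
    return pd.Series(pvals, index=df.columns, name="p")


def bh_fdr(p, level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (kept mask, q-values).

    q-values are the monotone adjusted p-values; the kept set is
    ``q < level`` (strict, matching an "FDR < 5%" selection rule).
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q < level, q


@dataclass
class ScreeningResult:
    """Outcome of the univariate FDR screen."""

    p: pd.Series
    q: pd.Series
    kept: pd.Series          # boolean mask over features
    test: str
    level: float = 0.05

    @property
    def kept_features(self) -> pd.Index:
        return self.kept.index[self.kept]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.p, "q": self.q, "kept": self.kept.astype(bool)}
        ).rename_axis("feature")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def screen_features(
    m: pd.DataFrame | FeatureMatrix,
    labels,
    test: str = "mann_whitney",
    level: float = 0.05,
) -> ScreeningResult:
    """Univariate two-group test per feature, then BH-FDR selection."""
    df = m.data if isinstance(m, FeatureMatrix) else m
    p = groupwise_test(df, labels, test=test)
    kept, q = bh_fdr(p.to_numpy(), level=level)
    return ScreeningResult(
        p=p,
        q=pd.Series(q, index=df.columns, name="q"),
        kept=pd.Series(kept, index=df.columns, name="kept"),
        test=test,
        level=level,
    )
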
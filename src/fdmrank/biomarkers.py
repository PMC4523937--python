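"""Biomarker utility of top-ranked DMR-coupled genes.

Two downstream procedures: (1) an expression risk score for survival —
univariable Cox screening of candidate genes at a loose significance
cutoff, a multivariable Cox fit of the survivors, a linear risk score
weighted by the fitted coefficients, a median split into high/low-risk
groups and a two-sided log-rank test; (2) stratified k-fold
cross-validated classification of case vs control samples restricted to
a gene set, summarized by the area under the pooled out-of-fold ROC
curve.

Proportional-hazards fitting and the log-rank statistic are delegated to
lifelines; the classifier and cross-validation to scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core_genomics import logger
from .feature_ranks import ExpressionMatrix


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int
    stage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.sample_id}: negative survival time")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event flag must be 0 or 1")


@dataclass
class RiskModel:
    """Linear risk score: sum of coefficient * expression over genes."""

    genes: list[str]
    coefficients: list[float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.coefficients):
            raise ValueError("genes and coefficients differ in length")
        if not all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficient")


def _survival_frame(
    genes: Sequence[str], expr: ExpressionMatrix, surv: Sequence[SurvivalRecord]
) -> pd.DataFrame:
    samples = [s.sample_id for s in surv if s.sample_id in expr.values.columns]
    if len(samples) < len(surv):
        logger.warning(
            "%d survival records lack expression; dropped",
            len(surv) - len(samples),
        )
    df = expr.values.loc[list(genes), samples].T.astype(float)
    meta = {s.sample_id: s for s in surv}
    df["time"] = [meta[s].time for s in samples]
    df["event"] = [meta[s].event for s in samples]
    return df


def select_prognostic_genes(
    candidates: Sequence[str],
    expr: ExpressionMatrix,
    surv: Sequence[SurvivalRecord],
    alpha: float = 0.1,
) -> list[str]:
    """Univariable Cox screen: keep genes with Wald p < alpha.

    Non-convergent fits are skipped with a warning.
    """
    if sum(s.event for s in surv) < 2:
        raise ValueError("need >=2 events for Cox screening")
    selected: list[str] = []
    for g in candidates:
        if g not in expr.values.index:
            raise KeyError(f"candidate gene {g!r} absent from expression matrix")
        df = _survival_frame([g], expr, surv)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, ValueError) as exc:
            logger.warning("univariable Cox fit failed for %s: %s", g, exc)
            continue
        if float(cph.summary.loc[g, "p"]) < alpha:  # Wald p
            selected.append(g)
    return selected


def fit_risk_model(
    genes: Sequence[str],
    expr: ExpressionMatrix,
    surv: Sequence[SurvivalRecord],
) -> RiskModel:
    """Multivariable Cox fit of the selected genes."""
    if not genes:
        raise ValueError("no genes to fit")
    sub = expr.values.loc[list(genes)]
    const = sub.index[sub.nunique(axis=1) <= 1]
    if len(const):
        raise ValueError(f"constant gene(s) across samples: {list(const)}")
    if len(genes) > 1:
        corr = np.corrcoef(sub.to_numpy())
        iu = np.triu_indices(len(genes), k=1)
        collinear = np.argwhere(np.abs(corr[iu]) > 0.9999)
        if len(collinear):
            i = int(collinear[0][0])
            raise ValueError(
                f"collinear genes: {genes[iu[0][i]]!r} and {genes[iu[1][i]]!r}"
            )
    df = _survival_frame(genes, expr, surv)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    coefs = [float(cph.params_[g]) for g in genes]
    return RiskModel(
        genes=list(genes),
        coefficients=coefs,
        provenance=f"multivariable Cox on {df.shape[0]} samples (Wald p available)",
    )


def risk_score(model: RiskModel, expression: Mapping[str, float]) -> float:
    """Linear risk score of one sample: sum(coef_g * expr_g)."""
    missing = [g for g in model.genes if g not in expression]
    if missing:
        raise KeyError(f"expression missing for model genes: {missing}")
    return float(
        sum(c * expression[g] for g, c in zip(model.genes, model.coefficients))
    )


def risk_scores(model: RiskModel, expr: ExpressionMatrix) -> pd.Series:
    sub = expr.values.loc[model.genes]
    return pd.Series(
        np.asarray(model.coefficients) @ sub.to_numpy(),
        index=sub.columns,
        name="risk_score",
    )


def stratify_and_logrank(
    scores: Mapping[str, float],
    surv: Sequence[SurvivalRecord],
    split: str = "median",
) -> tuple[dict[str, str], float]:
    """Median split into high/low-risk groups + two-sided log-rank p."""
    if split != "median":
        raise ValueError(f"unknown split rule {split!r}")
    samples = [s for s in surv if s.sample_id in scores]
    vals = np.array([scores[s.sample_id] for s in samples])
    if np.ptp(vals) == 0:
        raise ValueError("all risk scores identical; cannot stratify")
    # strictly-above-median is high risk; ties at the median go low so
    # group sizes differ by at most the tie count
    med = float(np.median(vals))
    labels = {
        s.sample_id: ("high" if scores[s.sample_id] > med else "low")
        for s in samples
    }
    hi = [s for s in samples if labels[s.sample_id] == "high"]
    lo = [s for s in samples if labels[s.sample_id] == "low"]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need >=2 samples per risk group")
    res = logrank_test(
        [s.time for s in hi], [s.time for s in lo],
        event_observed_A=[s.event for s in hi],
        event_observed_B=[s.event for s in lo],
    )
    return labels, float(res.p_value)


def cross_validated_roc(
    expr: ExpressionMatrix,
    gene_set: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    classifier=None,
) -> float:
    """Pooled out-of-fold area under the ROC curve.

    Stratified k-fold cross-validation of a regularized logistic
    regression (standardized features) restricted to the gene set; every
    sample is scored exactly once out-of-fold.
    """
    missing = [g for g in gene_set if g not in expr.values.index]
    if missing:
        raise KeyError(f"gene set members absent from expression: {missing}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    # canonical sample order makes the result invariant to column order
    samples = sorted(expr.values.columns)
    X = expr.values.loc[list(gene_set), samples].T.to_numpy(dtype=float)
    y = (expr.labels.loc[samples] == "case").to_numpy(dtype=int)
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise ValueError("each class needs >= folds members")
    model = classifier or make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=1000)
    )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = np.empty(len(y))
    seen = np.zeros(len(y), dtype=int)
    for train, test in cv.split(X, y):
        model.fit(X[train], y[train])
        pooled[test] = model.predict_proba(X[test])[:, 1]
        seen[test] += 1
    assert np.all(seen == 1)
    return float(roc_auc_score(y, pooled))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_survival(path: str) -> list[SurvivalRecord]:
    """Survival TSV: sample, time, event[, stage]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        stage = str(row["stage"]) if "stage" in df.columns and pd.notna(row.get("stage")) else None
        out.append(
            SurvivalRecord(str(row["sample"]), float(row["time"]), int(row["event"]), stage)
        )
    return out


def write_survival(records: Sequence[SurvivalRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttime\tevent\tstage\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.time:.6g}\t{r.event}\t{r.stage or 'NA'}\n")


def write_risk_model(model: RiskModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcoefficient\n")
        for g, c in zip(model.genes, model.coefficients):
            fh.write(f"{g}\t{c:.6g}\n")
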
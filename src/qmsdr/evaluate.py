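"""Nested cross-validation, performance statistics and clinical transfer.

Model quality is assessed by repeated Monte-Carlo 70%/15%/15%
(train/validation/test) splits: per repeat, a model is fitted on the
training partition, early stopping is tuned on the validation partition,
and held-out predictions are made exactly once on the test partition.
Test predictions are pooled across repeats (samples tested more than
once are averaged) and scored by Pearson correlation; two correlations
are compared with Fisher's r-to-z test.

Clinical transfer uses the trained cell-line ensemble: patients are
labelled responders when their ensemble-mean predicted AUDRC falls at or
below the 20th percentile of the measured cell-line AUDRC distribution,
and the labels are scored against RECIST classes (F1, precision-recall)
or against overall survival (concordance index, Cox hazard ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigError,
    DimensionError,
    EvaluationError,
    IntegrityError,
    ValidationError,
)
from .features import FeatureMatrix
from .io import MutationRecord, ScoreTable
from .network import ModelConfig, ResponseNetwork, TrainHistory, init_model, train

RECIST_POSITIVE = "PR"
RECIST_CLASSES = ("PR", "SD", "PD")


# ---------------------------------------------------------------------------
# split plans
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Repeated random train/validation/test partitions of a sample set."""

    repeats: list[dict[str, tuple[str, ...]]]
    fractions: tuple[float, float, float]
    seed: int

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


def make_split_plan(
    sample_ids: Sequence[str],
    n_repeats: int = 5,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitPlan:
    """Draw ``n_repeats`` independent random 70/15/15 partitions.

    Validation and test sizes are rounded to the nearest integer and the
    training partition absorbs the remainder, so each repeat's three
    partitions are disjoint and exhaustive.  A sample may appear in the
    test sets of several repeats; pooling accounts for that.
    """
    ids = [str(s) for s in sample_ids]
    n = len(ids)
    if n < 10:
        raise ValidationError(f"need at least 10 samples to split, got {n}")
    if len(set(ids)) != n:
        raise ValidationError("sample ids must be unique")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"split fractions {fractions} do not sum to 1")
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    if n_val == 0 or n_test == 0 or n_val + n_test >= n:
        raise ConfigError("fractions leave an empty partition")
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        test = tuple(ids[i] for i in perm[:n_test])
        val = tuple(ids[i] for i in perm[n_test : n_test + n_val])
        trn = tuple(ids[i] for i in perm[n_test + n_val :])
        repeats.append({"train": trn, "val": val, "test": test})
    return SplitPlan(repeats=repeats, fractions=tuple(fractions), seed=seed)


def _check_partitions(repeat: Mapping[str, tuple[str, ...]]) -> None:
    trn, val, tst = set(repeat["train"]), set(repeat["val"]), set(repeat["test"])
    if trn & val or trn & tst or val & tst:
        raise IntegrityError("train/validation/test partitions overlap")


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Trained models and held-out predictions from a nested CV run."""

    models: list[ResponseNetwork]
    histories: list[TrainHistory]
    test_ids: list[tuple[str, ...]]
    test_predictions: list[np.ndarray]
    pooled: pd.Series  # sample -> mean held-out prediction

    @property
    def n_repeats(self) -> int:
        return len(self.models)


def run_nested_cv(
    features: FeatureMatrix,
    responses: pd.Series,
    model_config: ModelConfig,
    plan: SplitPlan,
) -> CVResult:
    """Fit one model per repeat and collect pooled held-out predictions.

    Within each repeat, fitting uses only the training partition and
    stopping decisions only the validation partition; the test partition
    is predicted once, after training.  Per-repeat model seeds are
    derived from the config seed so repeats are independent but the
    whole run is reproducible.
    """
    resp = responses.astype(float)
    missing = [s for s in features.sample_ids if s not in resp.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} feature samples lack responses (e.g. {missing[0]!r})"
        )
    models, histories, test_ids, test_preds = [], [], [], []
    pooled_sum: dict[str, float] = {}
    pooled_n: dict[str, int] = {}
    for r, repeat in enumerate(plan.repeats):
        _check_partitions(repeat)
        cfg_dict = {**model_config.__dict__}
        cfg_dict["seed"] = int(model_config.seed + 1000 * r)
        cfg = ModelConfig(**cfg_dict)
        model = init_model(cfg)
        X = {part: features.subset(repeat[part]).flat() for part in repeat}
        y = {part: resp.loc[list(repeat[part])].to_numpy() for part in repeat}
        model, history = train(model, X["train"], y["train"], X["val"], y["val"])
        preds = model.predict(X["test"])
        models.append(model)
        histories.append(history)
        test_ids.append(repeat["test"])
        test_preds.append(preds)
        for s, p in zip(repeat["test"], preds):
            pooled_sum[s] = pooled_sum.get(s, 0.0) + float(p)
            pooled_n[s] = pooled_n.get(s, 0) + 1
    pooled = pd.Series(
        {s: pooled_sum[s] / pooled_n[s] for s in pooled_sum}
    ).sort_index()
    return CVResult(models, histories, test_ids, test_preds, pooled)


def shuffle_control(
    features: FeatureMatrix,
    responses: pd.Series,
    model_config: ModelConfig,
    plan: SplitPlan,
    seed: int = 0,
) -> tuple[float, CVResult]:
    """Re-run the CV with responses permuted across samples.

    Destroying the genotype-response pairing while preserving the
    response distribution should break performance almost entirely;
    returns the pooled Pearson r under the permutation.
    """
    rng = np.random.default_rng(seed)
    resp = responses.astype(float)
    shuffled = pd.Series(
        rng.permutation(resp.to_numpy()), index=resp.index, name=resp.name
    )
    result = run_nested_cv(features, shuffled, model_config, plan)
    observed = shuffled.loc[result.pooled.index].to_numpy()
    r = pearson_eval(result.pooled.to_numpy(), observed)
    return r, result


def ensemble_predict(
    models: Sequence[ResponseNetwork], features: FeatureMatrix
) -> pd.Series:
    """Arithmetic-mean inference-mode prediction across CV models."""
    if not models:
        raise EvaluationError("ensemble is empty")
    X = features.flat()
    preds = np.mean([m.predict(X) for m in models], axis=0)
    return pd.Series(preds, index=list(features.sample_ids))


# ---------------------------------------------------------------------------
# correlation statistics
# ---------------------------------------------------------------------------


def pearson_eval(predictions: np.ndarray, observed: np.ndarray) -> float:
    """Sample Pearson correlation of pooled predictions vs measurements."""
    x = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    if x.size != y.size:
        raise DimensionError("prediction/observation lengths differ")
    if x.size < 3:
        raise EvaluationError("Pearson correlation needs >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EvaluationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def fisher_r_to_z_test(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Compare two independent Pearson correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided p-value from the standard normal.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise EvaluationError(f"|r| must be < 1, got {r}")
        if n <= 3:
            raise EvaluationError(f"need n > 3 per group, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# responder labelling and precision-recall
# ---------------------------------------------------------------------------


def label_response_classes(audrc: pd.Series, pct: float = 20.0) -> pd.Series:
    """Split samples into sensitive / resistant / excluded tails.

    Sensitive samples have AUDRC at or below the ``pct``-th percentile,
    resistant at or above the ``100-pct``-th; the middle is excluded.
    Percentiles use inclusive linear interpolation.
    """
    if not 0.0 < pct < 50.0:
        raise ConfigError(f"pct must be in (0, 50), got {pct}")
    vals = audrc.astype(float)
    if len(vals) < 10:
        raise ValidationError("need >= 10 samples to label response classes")
    if np.ptp(vals.to_numpy()) == 0:
        raise EvaluationError("degenerate response distribution (all equal)")
    lo = float(np.percentile(vals, pct))
    hi = float(np.percentile(vals, 100.0 - pct))
    labels = pd.Series("excluded", index=vals.index, dtype=object)
    labels[vals <= lo] = "sensitive"
    labels[vals >= hi] = "resistant"
    return labels


@dataclass
class PRCurve:
    """A precision-recall curve with its step-wise area."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    area: float


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> PRCurve:
    """Precision-recall of a continuous sensitivity score.

    ``labels`` are booleans (True = sensitive); ``scores`` are oriented
    so that larger means more likely sensitive (negate predicted AUDRC
    before calling).  The area is the step-wise sum
    sum((R_i - R_{i-1}) * P_i), not a trapezoid.
    """
    from sklearn.metrics import average_precision_score, precision_recall_curve

    y = np.asarray(labels, dtype=bool).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.all() or not y.any():
        raise EvaluationError("need both positive and negative labels")
    precision, recall, thresholds = precision_recall_curve(y, s)
    area = float(average_precision_score(y, s))
    return PRCurve(precision=precision, recall=recall, thresholds=thresholds, area=area)


def marker_point(marker: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Precision and recall of a binary biomarker as a classifier."""
    m = np.asarray(marker, dtype=bool).ravel()
    y = np.asarray(labels, dtype=bool).ravel()
    tp = int((m & y).sum())
    fp = int((m & ~y).sum())
    fn = int((~m & y).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def recall_at_precision(curve: PRCurve, precision_floor: float) -> float:
    """Maximum recall among thresholds with precision >= the floor (0 if none)."""
    ok = curve.precision >= precision_floor
    if not ok.any():
        return 0.0
    return float(curve.recall[ok].max())


# ---------------------------------------------------------------------------
# clinical transfer
# ---------------------------------------------------------------------------


@dataclass
class ClinicalCohort:
    """Patient mutations plus exactly one outcome type.

    ``recist`` maps patient -> RECIST class (PR/SD/PD); ``survival`` is a
    frame with columns ``months`` and ``event`` indexed by patient.
    """

    mutations: list[MutationRecord]
    recist: pd.Series | None = None
    survival: pd.DataFrame | None = None
    score_table: "ScoreTable | None" = None

    def __post_init__(self) -> None:
        if (self.recist is None) == (self.survival is None):
            raise ValidationError("cohort must carry exactly one outcome type")

    @property
    def patient_ids(self) -> tuple[str, ...]:
        outcome = self.recist if self.recist is not None else self.survival
        return tuple(outcome.index)


def predict_patient_labels(
    models: Sequence[ResponseNetwork],
    patient_features: FeatureMatrix,
    reference_audrc: Sequence[float],
    pct: float = 20.0,
) -> tuple[pd.Series, pd.Series]:
    """Responder flags from ensemble predictions vs a cell-line reference.

    A patient is flagged a responder when the ensemble-mean predicted
    AUDRC is at or below the ``pct``-th percentile of the measured
    cell-line AUDRC distribution for the drug.  Returns (flags,
    predictions).
    """
    ref = np.asarray(list(reference_audrc), dtype=float)
    if ref.size == 0:
        raise EvaluationError("reference AUDRC distribution is empty")
    preds = ensemble_predict(models, patient_features)
    threshold = float(np.percentile(ref, pct))
    flags = (preds <= threshold).astype(int)
    return flags, preds


def f1_eval(responder_flags: pd.Series, recist: pd.Series) -> float:
    """F1 of predicted responder flags against RECIST outcomes.

    PR counts as the positive (sensitive) class; SD and PD as negative.
    Returns 0 when precision + recall is 0.
    """
    from sklearn.metrics import f1_score

    bad = set(recist.unique()) - set(RECIST_CLASSES)
    if bad:
        raise ValidationError(f"unknown RECIST classes {sorted(bad)}")
    truth = (recist.loc[responder_flags.index] == RECIST_POSITIVE).astype(int)
    return float(f1_score(truth, responder_flags.astype(int), zero_division=0))


def concordance(
    risk_scores: np.ndarray, months: np.ndarray, events: np.ndarray
) -> float:
    """C-index of a risk score against censored survival times.

    ``risk_scores`` are oriented so that larger predicts *shorter*
    survival (predicted AUDRC works directly for drugs whose responders
    live longer).  Pairs are comparable only when the shorter time ends
    in an event.  Delegates to lifelines.
    """
    from lifelines.utils import concordance_index

    events = np.asarray(events, dtype=bool)
    if not events.any():
        raise EvaluationError("C-index undefined on fully censored data")
    return float(
        concordance_index(
            np.asarray(months, dtype=float),
            -np.asarray(risk_scores, dtype=float),
            events,
        )
    )


def survival_stratify(
    predicted_scores: pd.Series,
    months: pd.Series,
    events: pd.Series,
    responder_flags: pd.Series | None = None,
) -> dict:
    """Score survival stratification by C-index and Cox hazard ratio.

    ``predicted_scores`` are predicted AUDRC values (higher = more
    resistant = expected shorter survival under an effective drug).  If
    responder flags are given, a univariate Cox proportional-hazards fit
    on the flag yields the hazard ratio and per-group medians.
    """
    idx = predicted_scores.index
    t = months.loc[idx].to_numpy(dtype=float)
    e = events.loc[idx].to_numpy(dtype=bool)
    out: dict = {"c_index": concordance(predicted_scores.to_numpy(), t, e)}
    if responder_flags is not None:
        from lifelines import CoxPHFitter

        flags = responder_flags.loc[idx].astype(int)
        for grp in (0, 1):
            if (flags == grp).sum() < 2:
                raise ValidationError("need >= 2 patients per group")
        df = pd.DataFrame({"responder": flags.to_numpy(), "months": t, "event": e})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="months", event_col="event")
        out["hazard_ratio"] = float(np.exp(cph.params_["responder"]))
        out["hazard_ratio_p"] = float(cph.summary.loc["responder", "p"])
        med = df.groupby("responder")["months"].median()
        out["median_months"] = {int(k): float(v) for k, v in med.items()}
        out["group_sizes"] = {
            int(k): int(v) for k, v in flags.value_counts().items()
        }
    return out
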
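"""Session-level group classification from manifold descriptors, with shuffle controls.

The discriminative question is: can a session's group (e.g. wild-type vs.
transgenic) be read off a scalar manifold descriptor such as the
intracluster distance, or a per-behavior ellipse descriptor pair?  The
encoder is deliberately simple — with one feature, a decision threshold
chosen on training data; with several, a Fisher linear discriminant — and is
evaluated over independent stratified train/test resplits.  Rerunning the
whole chain on temporally shuffled recordings provides the negative control:
if the descriptors encode genuine cross-neuron temporal coordination,
shuffling must drive accuracy to chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .manifold import embed, flatten_windows, intracluster_distance, temporal_shuffle
from .synthetic import CalciumRecording

log = logging.getLogger(__name__)

METRICS = ("accuracy", "precision", "recall", "f1")


@dataclass
class FeatureTable:
    """Per-session feature matrix with group and mouse labels.

    ``data`` must contain a ``group`` column, a ``mouse_id`` column and the
    named feature columns; rows are sessions.
    """

    data: pd.DataFrame
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        missing = [c for c in ("group", "mouse_id", *self.feature_names)
                   if c not in self.data.columns]
        if missing:
            raise InputError(f"feature table is missing columns: {missing}")
        if self.data["group"].isna().any():
            raise InputError("feature table has missing group labels")


@dataclass
class ClassifierReport:
    """Test-split metrics across independent repeats, with mean ± SEM."""

    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    n_repeats: int
    seed: int
    condition: str = "original"  # or "shuffled"
    group_a: str = ""
    group_b: str = ""
    feature_names: tuple[str, ...] = ()

    def mean(self, metric: str) -> float:
        return float(np.mean(getattr(self, metric)))

    def sem(self, metric: str) -> float:
        v = getattr(self, metric)
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        rows = [
            {"metric": m, "mean": self.mean(m), "sem": self.sem(m)} for m in METRICS
        ]
        return pd.DataFrame(rows)


def _threshold_classifier(train_x: np.ndarray, train_y: np.ndarray):
    """Best training-accuracy threshold on a single feature.

    Candidate cuts are midpoints between consecutive sorted unique training
    values (plus open ends); both decision directions are tried.  Returns a
    ``predict(x) -> bool array`` marking membership of the positive class.
    Ties in training accuracy keep the first (lowest-threshold, 'below'
    direction first) candidate, which makes the fit deterministic.
    """
    values = np.unique(train_x)
    if len(values) == 1:
        cuts = np.array([values[0]])
    else:
        cuts = np.concatenate(
            ([values[0] - 1.0], (values[:-1] + values[1:]) / 2.0, [values[-1] + 1.0])
        )
    best = (-1.0, None, None)
    for cut in cuts:
        for below in (True, False):
            pred = train_x <= cut if below else train_x > cut
            acc = float(np.mean(pred == train_y))
            if acc > best[0]:
                best = (acc, cut, below)
    _, cut, below = best
    return lambda x: (x <= cut if below else x > cut)


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Accuracy / precision / recall / F1 with the positive class = True."""
    tp = float(np.sum(y_true & y_pred))
    fp = float(np.sum(~y_true & y_pred))
    fn = float(np.sum(y_true & ~y_pred))
    acc = float(np.mean(y_true == y_pred))
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def encode_classify(
    features: FeatureTable,
    group_a: str,
    group_b: str,
    n_repeats: int = 10,
    test_fraction: float = 0.3,
    seed: int = 0,
    condition: str = "original",
) -> ClassifierReport:
    """Train/evaluate the encoder over independent stratified resplits.

    Each repeat draws a fresh stratified split (``test_fraction`` of each
    group's sessions held out); a single feature is classified by the
    training-optimal threshold, two or more by a Fisher linear discriminant.
    Metrics are computed on the test split only, with ``group_a`` as the
    positive class.  Deterministic given ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ConfigurationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    if n_repeats < 1:
        raise ConfigurationError(f"n_repeats must be >= 1, got {n_repeats}")
    df = features.data
    for g in (group_a, group_b):
        if not (df["group"] == g).any():
            raise InputError(f"group {g!r} absent from feature table")
    sub = df[df["group"].isin([group_a, group_b])].reset_index(drop=True)
    x = sub[list(features.feature_names)].to_numpy(dtype=float)
    y = (sub["group"] == group_a).to_numpy()  # positive class = first-named group
    # splits are drawn per group in label-sorted order, so swapping the
    # first/second-named groups reproduces the identical splits
    split_groups = sorted(
        [(group_a, np.nonzero(y)[0]), (group_b, np.nonzero(~y)[0])],
        key=lambda kv: kv[0],
    )
    per_group_test = {}
    for name, idx in split_groups:
        n_test = max(1, int(round(test_fraction * len(idx))))
        if len(idx) - n_test < 2:
            raise InputError(
                f"group {name!r} leaves fewer than 2 training sessions; "
                "add sessions or lower test_fraction"
            )
        per_group_test[name] = n_test

    def draw_split(rng: np.random.Generator) -> np.ndarray:
        mask = np.zeros(len(y), dtype=bool)
        for name, idx in split_groups:
            perm = rng.permutation(idx)
            mask[perm[: per_group_test[name]]] = True
        return mask

    rng = np.random.default_rng(seed)
    rows: list[dict[str, float]] = []
    for _ in range(n_repeats):
        test_mask = draw_split(rng)
        train_mask = ~test_mask
        for attempt in range(100):
            if y[train_mask].any() and (~y[train_mask]).any():
                break
            log.warning("degenerate split (one group empty in training); resampling")
            test_mask = draw_split(rng)
            train_mask = ~test_mask
        else:
            raise InputError("could not draw a non-degenerate split in 100 attempts")

        if x.shape[1] == 1:
            predict = _threshold_classifier(x[train_mask, 0], y[train_mask])
            y_pred = predict(x[test_mask, 0])
        else:
            from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

            lda = LinearDiscriminantAnalysis()
            lda.fit(x[train_mask], y[train_mask])
            y_pred = lda.predict(x[test_mask]).astype(bool)
        rows.append(_binary_metrics(y[test_mask], y_pred))

    return ClassifierReport(
        accuracy=np.array([r["accuracy"] for r in rows]),
        precision=np.array([r["precision"] for r in rows]),
        recall=np.array([r["recall"] for r in rows]),
        f1=np.array([r["f1"] for r in rows]),
        n_repeats=n_repeats,
        seed=seed,
        condition=condition,
        group_a=group_a,
        group_b=group_b,
        feature_names=features.feature_names,
    )


@dataclass(frozen=True)
class ChainConfig:
    """Settings for the flatten → embed → metric → classify chain."""

    window_len: int = 30
    method: str = "tsne"
    dim: int = 2
    embed_seed: int = 0
    standardize: bool = False
    embed_params: dict[str, Any] = field(default_factory=dict)
    n_repeats: int = 10
    test_fraction: float = 0.3
    shuffle_mode: str = "permute_frames"


def icd_feature_table(
    cohort: Sequence[CalciumRecording], config: ChainConfig = ChainConfig()
) -> FeatureTable:
    """Per-session intracluster distance of the embedded manifold, as features."""
    rows = []
    for rec in cohort:
        windows = flatten_windows(rec, config.window_len, standardize=config.standardize)
        emb = embed(
            windows, method=config.method, dim=config.dim,
            seed=config.embed_seed, params=dict(config.embed_params),
        )
        metric = intracluster_distance(
            emb.points, session_id=rec.session_id, group_tag=rec.group_tag
        )
        rows.append(
            {
                "session_id": rec.session_id,
                "mouse_id": rec.mouse_id,
                "group": rec.group_tag,
                "intracluster_distance": metric.intracluster_distance,
            }
        )
    return FeatureTable(
        data=pd.DataFrame(rows), feature_names=("intracluster_distance",)
    )


def shuffled_control_run(
    cohort: Sequence[CalciumRecording],
    config: ChainConfig = ChainConfig(),
    seed: int = 0,
) -> tuple[ClassifierReport, ClassifierReport]:
    """Run the full chain on original and temporally shuffled recordings.

    Both passes share the same downstream seeds (embedding, splits), so the
    only difference is the shuffle.  Groups are the first two distinct group
    tags in cohort order.  Returns ``(original_report, shuffled_report)``.
    """
    groups = list(dict.fromkeys(rec.group_tag for rec in cohort))
    if len(groups) < 2:
        raise InputError(f"cohort has {len(groups)} group(s); need at least 2")
    group_a, group_b = groups[0], groups[1]

    shuffle_seeds = np.random.SeedSequence(seed).generate_state(len(cohort)) % (2**31)
    shuffled = [
        temporal_shuffle(rec, mode=config.shuffle_mode, seed=int(s))
        for rec, s in zip(cohort, shuffle_seeds)
    ]
    reports = []
    for condition, recs in (("original", cohort), ("shuffled", shuffled)):
        table = icd_feature_table(recs, config)
        reports.append(
            encode_classify(
                table, group_a, group_b,
                n_repeats=config.n_repeats, test_fraction=config.test_fraction,
                seed=seed, condition=condition,
            )
        )
    return reports[0], reports[1]


def compare_reports(
    a: ClassifierReport, b: ClassifierReport, test: str = "mann_whitney"
) -> pd.DataFrame:
    """Two-sided per-metric comparison of two reports.

    Returns a frame with columns metric, p_value, direction (sign of
    ``mean(a) - mean(b)``).  Identical metric vectors give p = 1.0.
    """
    if test not in ("t", "mann_whitney"):
        raise ConfigurationError(f"unknown test {test!r}; use 't' or 'mann_whitney'")
    if a.n_repeats != b.n_repeats:
        raise InputError(
            f"repeat counts differ: {a.n_repeats} vs {b.n_repeats}"
        )
    rows = []
    for m in METRICS:
        va, vb = getattr(a, m), getattr(b, m)
        if np.array_equal(va, vb):
            p = 1.0
        elif test == "t":
            p = float(stats.ttest_ind(va, vb).pvalue)
        else:
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        diff = float(np.mean(va) - np.mean(vb))
        rows.append({"metric": m, "p_value": p, "direction": float(np.sign(diff))})
    return pd.DataFrame(rows)
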
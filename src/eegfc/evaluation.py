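"""Split orchestration, the metric suite, and the experiment grid.

Samples (epochs) are split into training (70%), validation (15%) and
test (15%) parts, stratified by class; ten such triples are drawn and
the median of each test-set metric over the ten repeats is reported.
Epoch-level splitting reproduces the reference protocol but lets epochs
of one subject appear in different parts; a subject-level mode is
provided to rule out that leakage and is the recommended setting for any
claim about generalization to new subjects.

Metrics follow the one-vs-rest convention: for each class, TP/TN/FP/FN
are counted on the test set and accuracy, sensitivity (recall),
specificity, precision and F1 are derived; aggregate values are
unweighted (macro) class means, and overall accuracy is also reported as
the plain fraction of correct predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BandSpec, BROADBAND, get_band
from .classifiers import CLASS_LABELS, build_cnn, train_cnn
from .cnn import CnnConfig
from .connectivity import connectivity_matrix
from .network import ThresholdSpec, apply_threshold, zscore_normalize
from .preprocessing import conventional_features, epoch_recording
from .synth import SyntheticDataset

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass(frozen=True)
class SplitPlan:
    """Stratified 70/15/15 splitting, repeated with independent seeds."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    n_repeats: int = 10
    unit: str = "epoch"
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.unit not in ("epoch", "subject"):
            raise ValueError("unit must be 'epoch' or 'subject'")
        if not self.seeds:
            object.__setattr__(self, "seeds", tuple(range(self.n_repeats)))
        if len(self.seeds) != self.n_repeats:
            raise ValueError("need one seed per repeat")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for one class on a test set."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("all-zero confusion counts")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    F1 is defined as 0 when precision + sensitivity is 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    accuracy = (tp + tn) / counts.total
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    denom = precision + sensitivity
    f1 = 2 * precision * sensitivity / denom if denom else 0.0
    return {
        "accuracy": accuracy, "sensitivity": sensitivity,
        "specificity": specificity, "precision": precision, "f1": f1,
    }


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int = 3) -> list[ConfusionCounts]:
    """Per-class one-vs-rest confusion counts."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = []
    for c in range(n_classes):
        t = y_true == c
        p = y_pred == c
        out.append(ConfusionCounts(
            tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)),
        ))
    return out


def classification_report(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Per-class and macro-averaged metrics plus overall accuracy."""
    counts = confusion_counts(y_true, y_pred, len(CLASS_LABELS))
    per_class = {
        CLASS_LABELS[c]: compute_metrics(counts[c]) for c in range(len(counts))
    }
    macro = {
        m: float(np.mean([per_class[lab][m] for lab in CLASS_LABELS]))
        for m in METRIC_NAMES
    }
    overall = float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    # cross-check: one-vs-rest accuracies are consistent with the plain
    # fraction correct (sum of per-class TP equals total correct)
    assert abs(sum(counts[c].tp for c in range(len(counts))) / counts[0].total
               - overall) < 1e-12
    return {"per_class": per_class, "macro": macro, "overall_accuracy": overall}


# ---------------------------------------------------------------------------
# splitting

def make_splits(table: pd.DataFrame, plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Stratified train/val/test index triples, one per repeat.

    ``table`` is an epoch-level table with columns ``group`` and
    ``subject_id``.  In epoch mode, epochs are allocated per class with
    rounded 70/15/15 counts; in subject mode, whole subjects are
    allocated per class and their epochs follow, so no subject appears in
    two parts.
    """
    for col in ("group", "subject_id"):
        if col not in table.columns:
            raise ValueError(f"table must have a {col!r} column")
    f_tr, f_va, _ = plan.fractions
    splits = []
    for seed in plan.seeds:
        rng = np.random.default_rng(seed)
        tr, va, te = [], [], []
        for group, sub in table.groupby("group", sort=True):
            if plan.unit == "epoch":
                units = sub.index.to_numpy()
            else:
                units = np.sort(sub["subject_id"].unique())
            n = len(units)
            n_tr = int(round(f_tr * n))
            n_va = int(round(f_va * n))
            n_te = n - n_tr - n_va
            if min(n_tr, n_va, n_te) < 1:
                raise ValueError(
                    f"class {group!r} too small ({n} {plan.unit}s) to appear "
                    "in all three parts"
                )
            perm = rng.permutation(units)
            u_tr, u_va, u_te = (perm[:n_tr], perm[n_tr:n_tr + n_va],
                                perm[n_tr + n_va:])
            if plan.unit == "epoch":
                tr.extend(u_tr); va.extend(u_va); te.extend(u_te)
            else:
                sid = sub["subject_id"]
                tr.extend(sub.index[sid.isin(u_tr)])
                va.extend(sub.index[sid.isin(u_va)])
                te.extend(sub.index[sid.isin(u_te)])
        splits.append((np.sort(tr), np.sort(va), np.sort(te)))
    return splits


# ---------------------------------------------------------------------------
# dataset-level feature assembly

def epoch_table(dataset: SyntheticDataset) -> pd.DataFrame:
    """One row per epoch: subject_id, group, epoch index."""
    rows = []
    for rec in dataset.recordings:
        n = int(rec.duration_s // dataset.epoch_duration_s)
        for k in range(n):
            rows.append({"subject_id": rec.subject_id, "group": rec.group_label,
                         "epoch": k})
    return pd.DataFrame(rows)


def connectivity_tensor(
    dataset: SyntheticDataset,
    method: str,
    band: BandSpec = BROADBAND,
    threshold: ThresholdSpec | None = None,
    zscore: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-epoch connectivity matrices for a whole dataset.

    Returns (X, table) with X of shape (n_epochs_total, n_ch, n_ch); the
    table matches :func:`epoch_table`.  Thresholding (if any) and z-score
    normalization are applied per matrix, mirroring classifier input
    preparation.
    """
    mats, rows = [], []
    for rec in dataset.recordings:
        for ep in epoch_recording(rec, dataset.epoch_duration_s):
            m = connectivity_matrix(ep, method, band)
            if threshold is not None:
                m = apply_threshold(m, threshold)
            if zscore:
                try:
                    m = zscore_normalize(m)
                except ValueError:
                    # thresholding can empty a matrix entirely; feed it
                    # through unnormalized (typically all zeros)
                    logger.debug("degenerate matrix for %s; z-score skipped",
                                 m.epoch_ref)
            mats.append(m.values.astype(np.float32))
            rows.append({"subject_id": rec.subject_id,
                         "group": rec.group_label, "epoch": ep.index})
    return np.stack(mats), pd.DataFrame(rows)


def conventional_feature_table(
    dataset: SyntheticDataset,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flattened conventional features for every epoch of a dataset."""
    feats, rows = [], []
    for rec in dataset.recordings:
        for ep in epoch_recording(rec, dataset.epoch_duration_s):
            feats.append(conventional_features(ep))
            rows.append({"subject_id": rec.subject_id,
                         "group": rec.group_label, "epoch": ep.index})
    return np.stack(feats), pd.DataFrame(rows)


def labels_to_ints(groups) -> np.ndarray:
    return np.array([CLASS_LABELS.index(g) for g in groups])


# ---------------------------------------------------------------------------
# repeated training and the experiment grid

def evaluate_cnn_over_splits(
    x: np.ndarray,
    table: pd.DataFrame,
    plan: SplitPlan,
    cnn_config: CnnConfig | None = None,
) -> pd.DataFrame:
    """Train/evaluate the CNN once per split; tidy per-repeat results."""
    y = labels_to_ints(table["group"])
    base_cfg = cnn_config or CnnConfig(input_shape=x.shape[1:3])
    rows = []
    for r, (tr, va, te) in enumerate(make_splits(table, plan)):
        cfg = CnnConfig(**{**base_cfg.__dict__, "seed": plan.seeds[r]})
        model = build_cnn(cfg)
        trained = train_cnn(model, x[tr], y[tr], x[va], y[va])
        y_pred = trained.predict(x[te])
        report = classification_report(y[te], y_pred)
        rows.append(_report_rows(report, repeat=r, model="cnn"))
    return pd.concat(rows, ignore_index=True)


def evaluate_baseline_over_splits(
    kind: str,
    features: np.ndarray,
    table: pd.DataFrame,
    plan: SplitPlan,
) -> pd.DataFrame:
    """Fit a baseline on train+val and evaluate on test, per split.

    (The baselines' own 10-fold CV estimate is available through
    :func:`eegfc.classifiers.train_baseline`; here they are scored on
    the same held-out test sets as the CNN for a like-for-like
    comparison.)
    """
    y = labels_to_ints(table["group"])
    rows = []
    for r, (tr, va, te) in enumerate(make_splits(table, plan)):
        fit_idx = np.concatenate([tr, va])
        from .classifiers import _make_baseline
        pipe = _make_baseline(kind, seed=int(plan.seeds[r]))
        pipe.fit(features[fit_idx], y[fit_idx])
        y_pred = pipe.predict(features[te])
        report = classification_report(y[te], y_pred)
        rows.append(_report_rows(report, repeat=r, model=kind))
    return pd.concat(rows, ignore_index=True)


def _report_rows(report: dict, **provenance) -> pd.DataFrame:
    rows = []
    for lab, metrics in report["per_class"].items():
        for m, v in metrics.items():
            rows.append({**provenance, "class": lab, "metric": m, "value": v})
    for m, v in report["macro"].items():
        rows.append({**provenance, "class": "macro", "metric": m, "value": v})
    rows.append({**provenance, "class": "overall", "metric": "accuracy",
                 "value": report["overall_accuracy"]})
    return pd.DataFrame(rows)


def median_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Median over repeats for every (cell, class, metric)."""
    keys = [c for c in results.columns if c not in ("repeat", "value")]
    return (results.groupby(keys, sort=False, dropna=False)["value"]
            .median().reset_index())


def run_experiment(
    dataset: SyntheticDataset,
    methods: tuple[str, ...] = ("psi", "imcoh", "corr", "aec"),
    bands: tuple[str, ...] = ("broadband",),
    thresholds: tuple[ThresholdSpec, ...] = (ThresholdSpec(mode="none"),),
    models: tuple[str, ...] = ("cnn",),
    plan: SplitPlan | None = None,
    cnn_config: CnnConfig | None = None,
) -> pd.DataFrame:
    """Run a {method x band x threshold x model} grid on a dataset.

    CNN cells consume connectivity matrices; baseline cells consume the
    conventional feature vectors (their cells are labelled method
    'conventional').  Cell failures are recorded and the grid continues.
    """
    plan = plan or SplitPlan()
    all_rows = []
    baseline_models = [m for m in models if m != "cnn"]
    if baseline_models:
        feats, table = conventional_feature_table(dataset)
        for kind in baseline_models:
            res = evaluate_baseline_over_splits(kind, feats, table, plan)
            res.insert(0, "threshold", "none")
            res.insert(0, "band", "broadband")
            res.insert(0, "method", "conventional")
            all_rows.append(res)
    if "cnn" in models:
        for method in methods:
            for band_name in bands:
                band = get_band(band_name)
                for spec in thresholds:
                    cell = f"{method}/{band_name}/{spec.mode}:{spec.value}"
                    try:
                        x, table = connectivity_tensor(
                            dataset, method, band, threshold=spec)
                        res = evaluate_cnn_over_splits(x, table, plan, cnn_config)
                    except Exception as exc:  # cell failure, grid continues
                        logger.warning("cell %s failed: %s", cell, exc)
                        continue
                    thr = ("none" if spec.mode == "none"
                           else f"{spec.mode}:{spec.value:g}")
                    res.insert(0, "threshold", thr)
                    res.insert(0, "band", band_name)
                    res.insert(0, "method", method)
                    all_rows.append(res)
    if not all_rows:
        raise ValueError("every grid cell failed")
    return pd.concat(all_rows, ignore_index=True)


def best_proportional_threshold(summary: pd.DataFrame) -> float:
    """Argmax of median overall accuracy over proportional-threshold cells."""
    s = summary[(summary["class"] == "overall")
                & (summary["metric"] == "accuracy")
                & summary["threshold"].str.startswith("proportional")]
    if s.empty:
        raise ValueError("no proportional-threshold cells in summary")
    best = s.loc[s["value"].idxmax(), "threshold"]
    return float(best.split(":")[1])


def probability_severity_report(
    proba: np.ndarray,
    table: pd.DataFrame,
    manifest: pd.DataFrame,
) -> pd.DataFrame | None:
    """Per-group correlation between own-class probability and severity.

    ``proba`` holds per-epoch class probabilities aligned with ``table``;
    severity comes from the dataset manifest.  Returns None (with a
    notice) when the severity covariate is absent or degenerate.
    """
    if "severity" not in manifest.columns or manifest["severity"].isna().all():
        logger.info("severity covariate absent; report skipped")
        return None
    sev = table["subject_id"].map(
        manifest.set_index("subject_id")["severity"])
    rows = []
    for c, lab in enumerate(CLASS_LABELS):
        mask = (table["group"] == lab).to_numpy()
        s = sev[mask].to_numpy(dtype=float)
        p = proba[mask, c]
        if np.std(s) == 0 or np.isnan(s).any() or np.std(p) == 0:
            logger.info("group %s: severity degenerate, skipped", lab)
            continue
        rows.append({"group": lab, "n": int(mask.sum()),
                     "correlation": float(np.corrcoef(s, p)[0, 1])})
    if not rows:
        logger.info("no group had usable severity variance; report skipped")
        return None
    return pd.DataFrame(rows)
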
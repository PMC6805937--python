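"""Evaluation protocol: six-fold cross-validation with a validation
holdout, ROC/AUROC with bootstrap confidence intervals, hours-before-onset
(HBO) lead-time statistics, and the pre-onset sliding AUROC curve.

Admission-level score = the maximum per-hour probability over the
(onset-truncated) stay, matching first-alarm semantics.  The AUROC is the
rank (Mann-Whitney) formulation — the probability that a random positive
outscores a random negative, ties counted half — which equals the
trapezoidal area under the empirical ROC.  Confidence intervals are
percentile bootstraps over the six fold-level results.  HBO is the gap in
hours between septic-shock onset and the first alarm at an operating
threshold chosen on validation data at a target sensitivity; admissions
never alarmed at or before onset are excluded (only correctly predicted
positives contribute).

The pre-onset curve reports, for each offset h = 1..48, the AUROC of the
probabilities the model emitted exactly h hours before onset (positives)
against the negatives' admission scores: it shows how reliability changes
as onset approaches.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence as Seq

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .config import ClinicalRangeTable, EvalConfig, default_ranges, derive_seed
from .features import (HourlyGrid, build_grids, compute_population_stats,
                       impute, standardize)
from .labeling import AdmissionMeta, SepsisStateSeries, label_admission
from .lstm import (LSTMClassifier, ModelConfig, PredictionSeries, Sequence)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    validation: list[str]
    folds: list[list[str]]

    def training_ids(self, fold_index: int) -> list[str]:
        return [a for j, f in enumerate(self.folds) if j != fold_index
                for a in f]

    def all_ids(self) -> list[str]:
        return self.validation + [a for f in self.folds for a in f]


def make_folds(
    admission_ids: Seq[str],
    labels: Seq[bool],
    k: int = 6,
    val_frac: float = 0.05,
    seed: int = 0,
    stratify_tolerance: float = 0.05,
) -> FoldAssignment:
    """Set aside a stratified validation holdout, then split the remainder
    into ``k`` stratified folds.  Deterministic given the seed; raises if
    the cohort is too small for a stratified split or if any fold's class
    proportion strays more than ``stratify_tolerance`` from the global one.
    """
    ids = np.asarray(admission_ids)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("cohort must contain both classes")
    rest_ids, val_ids, rest_y, _ = train_test_split(
        ids, y, test_size=val_frac, stratify=y, random_state=seed % (2**32))
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=(seed + 1) % (2**32))
    folds = [list(rest_ids[test]) for _, test in skf.split(rest_ids, rest_y)]
    global_frac = y.mean()
    y_by_id = dict(zip(ids.tolist(), y.tolist()))
    for j, f in enumerate(folds):
        frac = np.mean([y_by_id[a] for a in f])
        if abs(frac - global_frac) > stratify_tolerance:
            raise ValueError(
                f"fold {j} positive fraction {frac:.3f} deviates more than "
                f"{stratify_tolerance:.0%} from global {global_frac:.3f}")
    return FoldAssignment(list(val_ids), folds)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_and_auroc(
    scores: Seq[float], labels: Seq[bool]
) -> tuple[np.ndarray, float]:
    """Empirical ROC points and tie-aware rank-formulation AUROC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes")
    ranks = rankdata(s)  # midranks handle ties as half-wins
    auroc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, s)
    return np.column_stack([fpr, tpr]), float(auroc)


def bootstrap_ci(
    values: Seq[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of fold-level metrics."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two fold values")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable intervals", stacklevel=2)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(v), size=(n_boot, len(v)))
    means = v[draws].mean(axis=1)
    alpha = (1 - level) / 2
    return (float(np.quantile(means, alpha)),
            float(np.quantile(means, 1 - alpha)))


def compute_hbo(
    pred: PredictionSeries, onset_hour: int, threshold: float
) -> Optional[int]:
    """Hours before onset of the first alarm at or before onset; None when
    the admission is never (correctly) alarmed."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    upto = pred.probs[: onset_hour + 1]
    idx = np.nonzero(upto >= threshold)[0]
    if len(idx) == 0:
        return None
    return int(onset_hour - idx[0])


def choose_threshold(
    scores: Seq[float], labels: Seq[bool], target_sensitivity: float = 0.85
) -> float:
    """Largest threshold whose sensitivity on the given (validation)
    admissions is at least the target."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = np.sort(s[y])
    if len(pos) == 0:
        return 0.5  # no positives to calibrate on; neutral default
    # keep at least ceil(target * n_pos) positives at/above the threshold
    k = int(np.ceil(target_sensitivity * len(pos)))
    return float(pos[len(pos) - k])


def preonset_auroc_curve(
    preds: dict[str, PredictionSeries],
    onsets: dict[str, int],
    labels: dict[str, bool],
    window: int = 48,
) -> pd.DataFrame:
    """AUROC at each offset h = 1..window hours before septic-shock onset.

    The positive class score at offset h is the probability the model
    emitted at hour ``onset − h``; positives whose onset precedes h are
    skipped (and counted in ``n_pos``).  Negatives contribute their
    admission-level (max) score at every offset.  Offsets with no eligible
    positive yield NaN.
    """
    neg_scores = [preds[a].admission_score
                  for a, lab in labels.items() if not lab]
    rows = []
    for h in range(1, window + 1):
        pos_scores = []
        for a, lab in labels.items():
            if not lab:
                continue
            onset = onsets[a]
            if onset < h:
                continue
            pos_scores.append(float(preds[a].probs[onset - h]))
        if pos_scores and neg_scores:
            scores = np.array(pos_scores + neg_scores)
            y = np.array([True] * len(pos_scores) + [False] * len(neg_scores))
            _, auroc = roc_and_auroc(scores, y)
        else:
            auroc = np.nan
        rows.append({"hours_before_onset": h, "auroc": auroc,
                     "n_pos": len(pos_scores)})
    skipped = sum(1 for a, lab in labels.items() if lab and onsets[a] < window)
    if skipped:
        logger.info("preonset curve: %d positive(s) lack the full %d h of "
                    "pre-onset history at the largest offsets", skipped, window)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    roc_points: np.ndarray
    auroc: float
    auroc_ci: tuple[float, float]
    fold_aurocs: list[float]
    operating_thresholds: list[float]
    hbo_values: list[int]
    hbo_median: float
    hbo_iqr: tuple[float, float]
    preonset: pd.DataFrame  # hours_before_onset, auroc, ci_lo, ci_hi, n_pos
    n_admissions: int
    n_positive: int
    predictions: dict[str, PredictionSeries] = field(default_factory=dict)
    onsets: dict[str, int] = field(default_factory=dict)
    labels: dict[str, bool] = field(default_factory=dict)
    fold_of: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_admissions": self.n_admissions,
            "n_positive": self.n_positive,
            "auroc": self.auroc,
            "auroc_ci_95": list(self.auroc_ci),
            "fold_aurocs": self.fold_aurocs,
            "hbo_median_hours": self.hbo_median,
            "hbo_iqr_hours": list(self.hbo_iqr),
            "n_hbo": len(self.hbo_values),
            "operating_thresholds": self.operating_thresholds,
        }

    def to_json(self, path: str | Path) -> None:
        doc = self.summary()
        doc["roc_points"] = self.roc_points.tolist()
        doc["preonset_auroc"] = self.preonset.to_dict(orient="records")
        Path(path).write_text(json.dumps(doc, indent=2, allow_nan=True))

    def write_csvs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(
            outdir / "roc.csv", index=False)
        pd.DataFrame({"hbo_hours": self.hbo_values}).to_csv(
            outdir / "hbo.csv", index=False)
        self.preonset.to_csv(outdir / "preonset_auroc.csv", index=False)

    def plot(self, outdir: str | Path, fmt: str = "svg") -> list[Path]:
        """Optional ROC and pre-onset AUROC figures."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(self.roc_points[:, 0], self.roc_points[:, 1],
                label=f"AUROC {self.auroc:.3f}")
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        p = outdir / f"roc.{fmt}"
        fig.savefig(p, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
        fig, ax = plt.subplots(figsize=(6, 4))
        pre = self.preonset
        ax.errorbar(pre["hours_before_onset"], pre["auroc"],
                    yerr=[pre["auroc"] - pre["ci_lo"],
                          pre["ci_hi"] - pre["auroc"]]
                    if "ci_lo" in pre else None, fmt="o-", ms=3, lw=1)
        ax.invert_xaxis()
        ax.set_xlabel("hours before septic-shock onset")
        ax.set_ylabel("AUROC")
        p = outdir / f"preonset_auroc.{fmt}"
        fig.savefig(p, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
        return paths


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------

def make_sequences(
    grids: Seq[HourlyGrid],
    series_by_id: dict[str, SepsisStateSeries],
    stats,
    ranges: ClinicalRangeTable,
) -> list[Sequence]:
    """Impute + standardize grids and wrap them as model sequences.
    Positives are truncated at shock onset (inclusive) so post-onset hours
    never leak the outcome into the input."""
    seqs = []
    for g in grids:
        series = series_by_id[g.admission_id]
        dense = standardize(impute(g, stats), stats, ranges)
        X = dense.values.to_numpy(dtype=float)
        onset = series.onset_hour
        if onset is not None:
            X = X[: onset + 1]
        seqs.append(Sequence(g.admission_id, X, series.ever_shock))
    return seqs


def run_cross_validation(
    events: pd.DataFrame,
    metas: Seq[AdmissionMeta],
    model_config: Optional[ModelConfig] = None,
    eval_config: Optional[EvalConfig] = None,
    ranges: Optional[ClinicalRangeTable] = None,
    seed: int = 0,
    progress: bool = False,
) -> EvalReport:
    """Label, featurize, train k model instances on rotating fold unions,
    predict each held-out fold with the one model that never saw it, and
    pool the fold-level metrics into an :class:`EvalReport`.

    Population statistics (imputation fallback and standardization) are
    recomputed on each rotation's training admissions only.
    """
    model_config = model_config or ModelConfig()
    eval_config = eval_config or EvalConfig()
    ranges = ranges or default_ranges()

    grids, metas = build_grids(events, metas, ranges)
    grid_by_id = {g.admission_id: g for g in grids}

    # ground-truth labeling on physical units (full-cohort imputation
    # statistics: the rule verdicts are ground truth, not model output)
    stats_all = compute_population_stats(grids)
    series_by_id = {
        g.admission_id: label_admission(impute(g, stats_all),
                                        m)
        for g, m in zip(grids, metas)
    }
    labels = {a: s.ever_shock for a, s in series_by_id.items()}
    onsets = {a: s.onset_hour for a, s in series_by_id.items()
              if s.onset_hour is not None}

    assignment = make_folds(
        list(labels), list(labels.values()), k=eval_config.k_folds,
        val_frac=eval_config.val_frac, seed=derive_seed(seed, "folds"),
        stratify_tolerance=eval_config.stratify_tolerance)
    for j, fold in enumerate(assignment.folds):
        fold_labels = [labels[a] for a in fold]
        if all(fold_labels) or not any(fold_labels):
            raise ValueError(f"fold {j} contains a single class")

    fold_aurocs, thresholds = [], []
    predictions: dict[str, PredictionSeries] = {}
    fold_of: dict[str, int] = {}
    fold_curves = []
    for j, test_ids in enumerate(assignment.folds):
        train_ids = assignment.training_ids(j)
        stats = compute_population_stats(grids, scope=train_ids)
        seqs = {
            name: make_sequences([grid_by_id[a] for a in ids],
                                 series_by_id, stats, ranges)
            for name, ids in (("train", train_ids),
                              ("val", assignment.validation),
                              ("test", test_ids))
        }
        cfg_j = ModelConfig(**{**model_config.__dict__,
                               "seed": derive_seed(seed, f"train-{j}")})
        model = LSTMClassifier(
            n_features=len(seqs["train"][0].X[0]), config=cfg_j,
            feature_names=grids[0].features)
        model.fit(seqs["train"], seqs["val"], progress=progress)

        val_preds = model.predict(seqs["val"])
        thr = choose_threshold(
            [p.admission_score for p in val_preds],
            [s.label for s in seqs["val"]],
            eval_config.target_sensitivity)
        thresholds.append(thr)

        test_preds = model.predict(seqs["test"])
        for p in test_preds:
            predictions[p.admission_id] = p
            fold_of[p.admission_id] = j
        _, auroc_j = roc_and_auroc(
            [p.admission_score for p in test_preds],
            [s.label for s in seqs["test"]])
        fold_aurocs.append(auroc_j)
        fold_curves.append(preonset_auroc_curve(
            {p.admission_id: p for p in test_preds},
            onsets, {a: labels[a] for a in test_ids},
            eval_config.preonset_window))
        if progress:
            print(f"fold {j}: test AUROC {auroc_j:.3f}, threshold {thr:.3f}")

    return assemble_report(predictions, labels, onsets, fold_of,
                           fold_aurocs, thresholds, fold_curves, eval_config,
                           seed)


def assemble_report(
    predictions: dict[str, PredictionSeries],
    labels: dict[str, bool],
    onsets: dict[str, int],
    fold_of: dict[str, int],
    fold_aurocs: list[float],
    thresholds: list[float],
    fold_curves: list[pd.DataFrame],
    eval_config: EvalConfig,
    seed: int = 0,
) -> EvalReport:
    """Pool per-fold predictions into the final report.  Pure given its
    inputs, so reports can be regenerated from persisted predictions."""
    tested = list(predictions)
    scores = [predictions[a].admission_score for a in tested]
    y = [labels[a] for a in tested]
    roc_points, auroc = roc_and_auroc(scores, y)
    ci = bootstrap_ci(fold_aurocs, eval_config.n_boot, eval_config.ci_level,
                      seed=derive_seed(seed, "bootstrap"))

    hbo_values = []
    for a in tested:
        if labels[a]:
            h = compute_hbo(predictions[a], onsets[a],
                            thresholds[fold_of[a]])
            if h is not None:
                hbo_values.append(h)
    if hbo_values:
        hbo_median = float(np.median(hbo_values))
        hbo_iqr = (float(np.percentile(hbo_values, 25)),
                   float(np.percentile(hbo_values, 75)))
    else:
        hbo_median, hbo_iqr = float("nan"), (float("nan"), float("nan"))

    pooled = preonset_auroc_curve(predictions, onsets,
                                  {a: labels[a] for a in tested},
                                  eval_config.preonset_window)
    ci_lo, ci_hi = [], []
    boot_seed = derive_seed(seed, "bootstrap-preonset")
    for h_idx in range(len(pooled)):
        per_fold = [c["auroc"].iloc[h_idx] for c in fold_curves
                    if np.isfinite(c["auroc"].iloc[h_idx])]
        if len(per_fold) >= 2:
            lo, hi = bootstrap_ci(per_fold, eval_config.n_boot,
                                  eval_config.ci_level, seed=boot_seed)
        else:
            lo = hi = float("nan")
        ci_lo.append(lo)
        ci_hi.append(hi)
    pooled = pooled.assign(ci_lo=ci_lo, ci_hi=ci_hi)

    return EvalReport(
        roc_points=roc_points, auroc=auroc, auroc_ci=ci,
        fold_aurocs=fold_aurocs, operating_thresholds=thresholds,
        hbo_values=hbo_values, hbo_median=hbo_median, hbo_iqr=hbo_iqr,
        preonset=pooled, n_admissions=len(tested),
        n_positive=int(sum(y)), predictions=predictions, onsets=onsets,
        labels=labels, fold_of=fold_of,
    )
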
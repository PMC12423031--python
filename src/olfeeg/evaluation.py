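"""Leave-one-subject-out evaluation with per-subject majority voting.

Protocol: one fold per subject - all of that subject's trials form the test
set, everything else trains the pipeline.  Within each fold the supervised
and data-dependent stages (CSP, tangent-space reference, feature
standardization) are fitted on training trials only; the classifier then
predicts every test trial and the subject receives the modal predicted
label, with any tie resolved toward AD.  The whole fold structure is
repeated with fresh model seeds and metrics are reported as mean +/- s.d.
over repetitions.

Metrics follow the binary confusion-matrix definitions (accuracy =
(TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP), recall = TP/(TP+FN), F1 =
harmonic mean), applied per class one-vs-rest and macro-averaged across the
three classes; accuracy is the global correct fraction.  Subject-level
(voted) metrics are the primary report; trial-level accuracy is logged
secondarily.

Every fitted extractor records the trial indices it saw, and the runner
audits that no test-subject trial was ever seen during fitting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import EEGTrialSet, Label
from .errors import ProtocolError
from .model import (
    FeatureStandardizer,
    FusionConfig,
    FusionModel,
    TrainParams,
    train_fusion_model,
)
from .spatial import fit_csp, fit_tangent, tangent_map, transform_csp, trial_covariances
from .tqwcm import build_tqwcm
from .tqwt import TQWTParams

__all__ = [
    "FoldPlan",
    "MetricReport",
    "PipelineConfig",
    "loso_folds",
    "subject_vote",
    "compute_metrics",
    "prepare_images",
    "permute_subject_labels",
    "run_experiment",
]


@dataclass(frozen=True)
class FoldPlan:
    """One (train_subjects, test_subject) pair per subject, ordered by id."""

    folds: tuple[tuple[tuple[str, ...], str], ...]

    def __len__(self) -> int:
        return len(self.folds)


def loso_folds(ts: EEGTrialSet) -> FoldPlan:
    """Deterministic leave-one-subject-out plan (subjects sorted by id)."""
    subjects = sorted(ts.subject_ids)
    if len(subjects) < 2:
        raise ProtocolError("leave-one-subject-out needs at least two subjects")
    folds = tuple(
        (tuple(s for s in subjects if s != test), test) for test in subjects
    )
    return FoldPlan(folds=folds)


def subject_vote(preds) -> Label:
    """Modal predicted label of one subject's trials; any tie -> AD."""
    if len(preds) == 0:
        raise ProtocolError("cannot vote on an empty prediction list")
    counts = Counter(int(p) for p in preds)
    top = max(counts.values())
    modal = [lab for lab, c in counts.items() if c == top]
    return Label.AD if len(modal) > 1 else Label(modal[0])


@dataclass
class SingleRunMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict[str, dict[str, float]]
    confusion: np.ndarray


def compute_metrics(true_labels, predicted_labels, average: str = "macro") -> SingleRunMetrics:
    """Confusion-matrix metrics, one-vs-rest per class then averaged.

    ``average`` is 'macro' (unweighted class mean, the default) or
    'weighted' (by class support).
    """
    t = np.array([int(x) for x in true_labels])
    p = np.array([int(x) for x in predicted_labels])
    if t.shape != p.shape:
        raise ProtocolError(f"length mismatch: {t.shape} vs {p.shape}")
    k = len(Label)
    conf = np.zeros((k, k), dtype=int)
    for ti, pi in zip(t, p):
        conf[ti, pi] += 1
    per_class: dict[str, dict[str, float]] = {}
    precs, recs, f1s, support = [], [], [], []
    for c in range(k):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        rec = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        per_class[Label(c).name] = {"precision": prec, "recall": rec, "f1": f1}
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
        support.append(conf[c, :].sum())
    if average == "weighted":
        w = np.array(support) / max(sum(support), 1)
    elif average == "macro":
        w = np.full(k, 1.0 / k)
    else:
        raise ProtocolError(f"unknown averaging {average!r}")
    return SingleRunMetrics(
        accuracy=float((t == p).mean()),
        precision=float(np.dot(w, precs)),
        recall=float(np.dot(w, recs)),
        f1=float(np.dot(w, f1s)),
        per_class=per_class,
        confusion=conf,
    )


@dataclass
class MetricReport:
    """Subject-level scores: mean +/- s.d. over repetitions, plus the
    consensus confusion matrix (modal vote per subject across repetitions,
    ties toward AD; row sums equal the per-class subject counts)."""

    accuracy: tuple[float, float]
    precision: tuple[float, float]
    recall: tuple[float, float]
    f1: tuple[float, float]
    per_class: dict[str, dict[str, float]]
    confusion: np.ndarray
    n_repetitions: int
    repetition_metrics: list[SingleRunMetrics] = field(default_factory=list)
    leakage_violations: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": {"mean": self.accuracy[0], "std": self.accuracy[1]},
            "precision": {"mean": self.precision[0], "std": self.precision[1]},
            "recall": {"mean": self.recall[0], "std": self.recall[1]},
            "f1": {"mean": self.f1[0], "std": self.f1[1]},
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "n_repetitions": self.n_repetitions,
            "leakage_violations": self.leakage_violations,
        }


@dataclass
class PipelineConfig:
    """Everything the experiment runner needs besides the data."""

    tqwt: TQWTParams = field(default_factory=TQWTParams)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    train: TrainParams = field(default_factory=TrainParams)
    n_csp_components: int = 4
    cov_method: str = "oas"
    standardize: bool = True
    magnitude_images: bool = False
    selection: str = "last"  # or 'best': optimistic highest-test-score epoch


def prepare_images(ts: EEGTrialSet, params: TQWTParams,
                   magnitude: bool = False) -> np.ndarray:
    """TQWCM image tensor (n_trials, channels, J+1, N) for a whole set."""
    return np.stack(
        [build_tqwcm(t, params, magnitude=magnitude).pixels for t in ts]
    ).astype(np.float32)


def permute_subject_labels(ts: EEGTrialSet, rng: np.random.Generator) -> EEGTrialSet:
    """Shuffle the subject -> label assignment (a permutation null model).

    Each subject keeps its trials but receives another subject's label, so
    any genuine class signal is destroyed while the subject-block structure
    that LOSO relies on is preserved.
    """
    subjects = ts.subject_ids
    labels = [ts.subject_label(s) for s in subjects]
    perm = rng.permutation(len(subjects))
    mapping = {s: labels[perm[i]] for i, s in enumerate(subjects)}
    new_trials = [replace(t, label=mapping[t.subject_id]) for t in ts.trials]
    return EEGTrialSet(new_trials, list(ts.channel_names))


def _fold_features(ts, images, covs, tr_idx, te_idx, cfg: PipelineConfig):
    """Fit CSP / tangent space / scaler on the training indices only and
    return standardized (image, csp, cmts) tensors for both partitions."""
    train_set = ts.subset(tr_idx)
    csp_model = fit_csp(train_set, n_components=cfg.n_csp_components,
                        trial_ids=list(tr_idx))
    tan_model = fit_tangent([covs[i] for i in tr_idx], trial_ids=list(tr_idx))

    def spatial_feats(idx):
        csp_f = np.stack([transform_csp(csp_model, ts[i]) for i in idx])
        cmts_f = np.stack([tangent_map(tan_model, covs[i]) for i in idx])
        return csp_f.astype(np.float32), cmts_f.astype(np.float32)

    csp_tr, cmts_tr = spatial_feats(tr_idx)
    csp_te, cmts_te = spatial_feats(te_idx)
    scaler = FeatureStandardizer(standardize_images=cfg.standardize)
    scaler.fit(images[tr_idx], csp_tr, cmts_tr, trial_ids=list(tr_idx))
    train_feats = scaler.transform(images[tr_idx], csp_tr, cmts_tr)
    test_feats = scaler.transform(images[te_idx], csp_te, cmts_te)
    fitted = (csp_model, tan_model, scaler)
    return train_feats, test_feats, fitted


def run_experiment(
    ts: EEGTrialSet,
    pipeline: PipelineConfig | None = None,
    n_repetitions: int = 5,
    seed: int = 0,
    verbose: bool = False,
) -> tuple[MetricReport, list[dict]]:
    """Full LOSO x repetitions evaluation of the fusion pipeline.

    Returns the aggregated :class:`MetricReport` and a per-fold log (one
    dict per repetition x fold with the voted and true labels, the trial
    vote histogram, trial-level accuracy and the leakage audit).
    TQWCM images and per-trial covariances are unsupervised per-trial
    transforms, so they are computed once up front; everything label- or
    population-dependent is refitted inside each fold.
    """
    cfg = pipeline or PipelineConfig()
    plan = loso_folds(ts)
    images = prepare_images(ts, cfg.tqwt, magnitude=cfg.magnitude_images)
    covs = trial_covariances(ts, method=cfg.cov_method)
    subj_arr = np.array([t.subject_id for t in ts.trials])
    labels = ts.labels()
    fold_log: list[dict] = []
    rep_metrics: list[SingleRunMetrics] = []
    votes_by_subject: dict[str, list[int]] = {test: [] for _, test in plan.folds}
    leakage = 0
    for rep in range(n_repetitions):
        rep_seed = seed + rep
        subj_true: list[int] = []
        subj_pred: list[int] = []
        for fold_i, (train_subjects, test_subject) in enumerate(plan.folds):
            tr_idx = np.flatnonzero(subj_arr != test_subject)
            te_idx = np.flatnonzero(subj_arr == test_subject)
            train_feats, test_feats, fitted = _fold_features(
                ts, images, covs, tr_idx, te_idx, cfg
            )
            te_set = set(te_idx.tolist())
            for est in (*fitted[:2], fitted[2]):
                seen = getattr(est, "fit_trial_ids", None) or []
                leakage += len(te_set.intersection(seen))
            model = FusionModel(replace(cfg.fusion, seed=rep_seed))
            tp = replace(cfg.train, seed=rep_seed)
            eval_fn = None
            if cfg.selection == "best":
                def eval_fn(m, _tf=test_feats, _y=labels[te_idx]):
                    return float((m.predict(*_tf) == _y).mean())
            result = train_fusion_model(model, *train_feats, labels[tr_idx], tp,
                                        eval_fn=eval_fn)
            preds = model.predict(*test_feats)
            vote = subject_vote(preds)
            true_lab = int(labels[te_idx][0])
            subj_true.append(true_lab)
            subj_pred.append(int(vote))
            votes_by_subject[test_subject].append(int(vote))
            fold_log.append(
                {
                    "repetition": rep,
                    "fold": fold_i,
                    "subject_id": test_subject,
                    "true": Label(true_lab).name,
                    "voted": vote.name,
                    "vote_histogram": {
                        Label(k).name: int(v) for k, v in Counter(preds.tolist()).items()
                    },
                    "trial_accuracy": float((preds == labels[te_idx]).mean()),
                    "loss_history": [float(x) for x in result.loss_history],
                    "final_train_loss": result.loss_history[-1],
                    "best_epoch_accuracy": (max(result.eval_history)
                                            if result.eval_history else None),
                    "leakage_violations": leakage,
                }
            )
            if verbose:
                print(
                    f"rep {rep} fold {fold_i:2d} subject {test_subject}: "
                    f"true {Label(true_lab).name:7s} voted {vote.name:7s} "
                    f"(trial acc {fold_log[-1]['trial_accuracy']:.2f})"
                )
        rep_metrics.append(compute_metrics(subj_true, subj_pred))
    # consensus prediction per subject across repetitions (ties toward AD)
    cons_true = [int(ts.subject_label(s)) for _, s in plan.folds]
    cons_pred = [int(subject_vote(votes_by_subject[s])) for _, s in plan.folds]
    consensus = compute_metrics(cons_true, cons_pred)

    def agg(attr):
        vals = np.array([getattr(m, attr) for m in rep_metrics])
        return float(vals.mean()), float(vals.std())

    per_class: dict[str, dict[str, float]] = {}
    for lab in Label:
        per_class[lab.name] = {
            k: float(np.mean([m.per_class[lab.name][k] for m in rep_metrics]))
            for k in ("precision", "recall", "f1")
        }
    report = MetricReport(
        accuracy=agg("accuracy"),
        precision=agg("precision"),
        recall=agg("recall"),
        f1=agg("f1"),
        per_class=per_class,
        confusion=consensus.confusion,
        n_repetitions=n_repetitions,
        repetition_metrics=rep_metrics,
        leakage_violations=leakage,
    )
    return report, fold_log
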
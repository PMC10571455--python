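"""End-to-end orchestration: phantoms -> patches -> features -> labels ->
correlation ranking -> cross-validated grading models -> report.

The experiment unit is the nodule: its three slices, patches and
features always travel together through fold assignment, so no nodule
straddles a train/test boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import correlation, dbn, mbcnn, metrics, patches, ratings, synthetic
from .features import feature_vector

GRADABLE_SCS = ratings.GRADABLE_SCS


@dataclass
class ExperimentConfig:
    n_nodules: int = 100
    sc_list: tuple = tuple(GRADABLE_SCS)
    model: str = "mbcnn"
    seed: int = 0
    out_dir: str | None = None
    n_folds: int = 5
    image_size: int = 64
    base_radius: float = 12.0
    n_readers: int = 4
    # scaled-down training schedules for the experiment driver
    dbn_hp: dbn.DBNHyperParams = field(default_factory=lambda: dbn.DBNHyperParams(
        pretrain_epochs=10, finetune_epochs=100))
    mbcnn_epochs: int = 8

    def __post_init__(self):
        unknown = [sc for sc in self.sc_list if sc not in GRADABLE_SCS]
        if unknown:
            raise ValueError(f"not gradable: {unknown}; choose from {GRADABLE_SCS}")
        if self.model not in ("dbn1", "dbn2", "mbcnn"):
            raise ValueError(f"unknown model {self.model!r}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {**{k: v for k, v in asdict(self).items() if k != "out_dir"}},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class CaseData:
    """Per-nodule intermediates used by every model regime."""

    case_id: str
    triplet: np.ndarray        # (3, 64, 64) grayscale patches in [0, 1]
    patch0: patches.NodulePatch
    features: np.ndarray       # 72-vector of the first slice's patch
    labels: dict               # sc -> 0/1


def prepare_cases(config: ExperimentConfig):
    """Generate the cohort and run patch extraction + feature stages.

    Returns (cases_data, stage_log, ratings_table).
    """
    cohort, table = synthetic.generate_cohort(
        config.n_nodules, seed=config.seed, image_size=config.image_size,
        base_radius=config.base_radius, n_readers=config.n_readers,
    )
    label_df = ratings.labels_table(table).set_index("case_id")
    log = {"nodules_in": len(cohort), "discarded_consensus": 0, "discarded_no_region": 0}
    out = []
    for case in cohort:
        if case.case_id not in label_df.index:
            log["discarded_consensus"] += 1
            continue
        try:
            case_patches = patches.patches_from_case(case)
        except patches.NoConsensusRegion:
            log["discarded_no_region"] += 1
            continue
        triplet = np.stack([p.G for p in case_patches]).astype(np.float32)
        fv = feature_vector(case_patches[0])
        out.append(CaseData(
            case_id=case.case_id,
            triplet=np.clip(triplet, 0.0, 1.0),
            patch0=case_patches[0],
            features=fv.values,
            labels=label_df.loc[case.case_id].to_dict(),
        ))
    log["patches_out"] = len(out)
    return out, log, table


def _dbn_fold_fn(cases, regime, hp):
    feats = np.stack([c.features for c in cases])
    g_flat = np.stack([np.clip(c.patch0.G, 0, 1).ravel() for c in cases])
    b_flat = np.stack([c.patch0.B.astype(float).ravel() for c in cases])

    def fn(labels):
        def train_eval(train_idx, test_idx, fold_seed):
            if regime == "dbn1":
                X = np.concatenate([g_flat, b_flat], axis=1)
                scaler = None
            else:
                scaler = dbn.FeatureScaler().fit(feats[train_idx])
                X = np.concatenate([g_flat, scaler.transform(feats)], axis=1)
            model = dbn.train_dbn(X[train_idx], labels[train_idx], seed=fold_seed,
                                  regime=regime, hp=hp, scaler=scaler)
            return dbn.dbn_predict(model, X[train_idx]), dbn.dbn_predict(model, X[test_idx])
        return train_eval
    return fn


def _mbcnn_fold_fn(cases, config):
    x = np.stack([c.triplet for c in cases])

    def fn(labels):
        def train_eval(train_idx, test_idx, fold_seed):
            model = mbcnn.train_mbcnn(
                x[train_idx], labels[train_idx],
                config=mbcnn.MBCNNConfig(max_epochs=config.mbcnn_epochs, seed=fold_seed),
            )
            return model.predict_proba(x[train_idx]), model.predict_proba(x[test_idx])
        return train_eval
    return fn


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute every stage and assemble the experiment report."""
    cases, log, table = prepare_cases(config)

    consensus_norm = ratings.consensus_table(table, normalize=True)
    corr_report = correlation.rank_sc_correlations(consensus_norm)

    if config.model in ("dbn1", "dbn2"):
        fold_factory = _dbn_fold_fn(cases, config.model, config.dbn_hp)
    else:
        fold_factory = _mbcnn_fold_fn(cases, config)

    per_sc = {}
    for sc in config.sc_list:
        labels = np.array([c.labels[sc] for c in cases])
        if len(np.unique(labels)) < 2:
            per_sc[sc] = {"error": "single-class labels in cohort"}
            continue
        cv = metrics.fivefold_cv(labels, fold_factory(labels), seed=config.seed,
                                 n_splits=config.n_folds, sc=sc)
        per_sc[sc] = cv
    accs = {sc: r["mean_test_acc"] for sc, r in per_sc.items() if "mean_test_acc" in r}
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "model": config.model,
        "registry_version": "1.0",
        "stage_log": log,
        "correlation": corr_report,
        "per_sc": per_sc,
        "ave": metrics.average_accuracy(accs) if accs else float("nan"),
    }
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def report_frame(report: dict) -> pd.DataFrame:
    """Flatten the per-SC, per-fold metrics into a tidy table."""
    rows = []
    for sc, cv in report["per_sc"].items():
        if "error" in cv:
            continue
        for split in ("train", "test"):
            for r in cv[split]:
                rows.append({
                    "sc": sc, "fold": r.fold, "split": split,
                    "acc": r.acc, "rec": r.rec, "auc": r.auc, "dsc": r.dsc,
                    "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
                })
    return pd.DataFrame(rows)


def write_report(report: dict, out_dir: str):
    import os

    os.makedirs(out_dir, exist_ok=True)
    report_frame(report).to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
    report["correlation"].to_frame().to_csv(os.path.join(out_dir, "correlation.csv"), index=False)
    summary = {
        "config_hash": report["config_hash"],
        "seed": report["seed"],
        "model": report["model"],
        "registry_version": report["registry_version"],
        "stage_log": report["stage_log"],
        "ave": report["ave"],
        "mean_test_acc": {sc: cv.get("mean_test_acc") for sc, cv in report["per_sc"].items()},
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def rating_distribution_report(ratings_table: pd.DataFrame, plot_path: str | None = None) -> pd.DataFrame:
    """Per-SC histogram of rating levels (columns rating_1 .. rating_6).

    Accepts a table with SC-named columns on their native scales; counts
    use rounded integer levels. Levels beyond an SC's scale are zero.
    """
    if len(ratings_table) == 0:
        raise ValueError("empty ratings table")
    sc_cols = [c for c in ratings_table.columns if c in ratings.SC_SCALE_MAX]
    rows = []
    for sc in sc_cols:
        t = ratings.SC_SCALE_MAX[sc]
        vals = np.rint(ratings_table[sc].to_numpy(dtype=float)).astype(int)
        counts = [int(np.sum(vals == level)) for level in range(1, 7)]
        rows.append({"sc": sc, "scale_max": t,
                     **{f"rating_{level}": counts[level - 1] for level in range(1, 7)}})
    df = pd.DataFrame(rows)
    if plot_path:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(sc_cols), figsize=(3 * len(sc_cols), 3), squeeze=False)
        for ax, (_, row) in zip(axes[0], df.iterrows()):
            levels = range(1, int(row["scale_max"]) + 1)
            ax.bar(list(levels), [row[f"rating_{level}"] for level in levels])
            ax.set_title(row["sc"])
            ax.set_xlabel("rating")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=100)
        plt.close(fig)
    return df


def audit_fold_leakage(case_ids: list, folds: np.ndarray) -> bool:
    """True iff every nodule maps to exactly one fold."""
    assignment = {}
    for cid, fold in zip(case_ids, folds):
        if cid in assignment and assignment[cid] != fold:
            return False
        assignment[cid] = fold
    return True
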
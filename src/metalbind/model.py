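"""Gradient-boosting classifier, cross-validation protocol and metrics.

The classifier is an additive stagewise ensemble of regression trees
(gradient boosting); its four tuned hyperparameters are the number of
trees, tree interaction depth, shrinkage (learning rate) and the minimum
number of observations in a terminal node. Evaluation follows a stratified
5-fold cross-validation at the fragment level in which every fitted
artifact (pair screens, propensity table, PWMs) is refitted on each
training fold; confusion counts are pooled over folds and sensitivity,
specificity, accuracy, Matthews correlation and AUROC are computed from
the pooled counts/scores. Class imbalance is left untouched (no resampling
or reweighting); the decision threshold on the predicted binding
probability is 0.5.

The user-facing surface is `MetalBindingModel` (built from annotated
chains) whose ``fit`` / ``cross_validate`` return a `MetalBindingResults`
with a ``summary()`` table, mirroring the Model/Results convention of
statistical modelling packages.
"""

from __future__ import annotations

import math
import pickle
import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .features import (
    FEATURE_MASKS,
    LigandProfile,
    feature_matrix,
    feature_names,
    fit_profile,
)
from .correlation import correlation_table, select_orders
from .io import AnnotatedChain, Fragment, make_fragments

__all__ = [
    "GBMConfig",
    "EvalReport",
    "metrics",
    "cv_run",
    "ablation_run",
    "grid_search",
    "window_sweep",
    "rf_baseline",
    "MetalBindingModel",
    "MetalBindingResults",
]

#: tuning grids for the four gradient-boosting hyperparameters
GBM_GRIDS: dict[str, tuple] = {
    "n_trees": tuple(range(100, 501, 50)),
    "interaction_depth": (3, 5, 7, 9),
    "shrinkage": (0.01, 0.1),
    "min_node": (10, 20, 30, 40, 50),
}

DEFAULT_WINDOWS = (5, 7, 9, 11, 13, 15, 17)


@dataclass(frozen=True)
class GBMConfig:
    """Gradient-boosting hyperparameters (names follow the R gbm package)."""

    n_trees: int = 100
    interaction_depth: int = 3
    shrinkage: float = 0.1
    min_node: int = 10
    seed: int = 0

    def estimator(self) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            n_estimators=self.n_trees,
            max_depth=self.interaction_depth,
            learning_rate=self.shrinkage,
            min_samples_leaf=self.min_node,
            random_state=self.seed,
        )


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and derived metrics, per fold and pooled.

    Sn = TP/(TP+FN)*100, Sp = TN/(TN+FP)*100, Acc = (TP+TN)/total*100,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero
    factor in the MCC denominator yields MCC = 0. AUROC is computed on the
    pooled out-of-fold scores when available.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    auroc: float = float("nan")
    fold_counts: tuple = ()  # ((tp, fn, tn, fp), ...) per fold
    fold_aurocs: tuple = ()
    scores: np.ndarray | None = field(default=None, repr=False, compare=False)
    labels: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def sn(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def sp(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def acc(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return 100.0 * (self.tp + self.tn) / total if total else 0.0

    @property
    def mcc(self) -> float:
        factors = [
            self.tp + self.fp,
            self.tp + self.fn,
            self.tn + self.fp,
            self.tn + self.fn,
        ]
        if any(f == 0 for f in factors):
            warnings.warn("zero factor in MCC denominator; MCC defined as 0")
            return 0.0
        num = self.tp * self.tn - self.fp * self.fn
        return num / math.sqrt(math.prod(float(f) for f in factors))

    def per_fold(self) -> pd.DataFrame:
        rows = []
        for k, counts in enumerate(self.fold_counts, start=1):
            rep = metrics(*counts)
            rows.append(
                {
                    "fold": k,
                    "TP": counts[0],
                    "FN": counts[1],
                    "TN": counts[2],
                    "FP": counts[3],
                    "Sn": rep.sn,
                    "Sp": rep.sp,
                    "Acc": rep.acc,
                    "MCC": rep.mcc,
                    "AUROC": self.fold_aurocs[k - 1] if self.fold_aurocs else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FN": self.fn,
            "TN": self.tn,
            "FP": self.fp,
            "Sn": self.sn,
            "Sp": self.sp,
            "Acc": self.acc,
            "MCC": self.mcc,
            "AUROC": self.auroc,
        }

    def roc_points(self) -> pd.DataFrame:
        """Pooled ROC curve points (fpr, tpr, threshold)."""
        if self.scores is None or self.labels is None:
            raise ValueError("no pooled scores stored in this report")
        fpr, tpr, thr = roc_curve(self.labels, self.scores)
        return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def metrics(tp: int, fn: int, tn: int, fp: int) -> EvalReport:
    """Build an EvalReport from confusion counts alone."""
    for v in (tp, fn, tn, fp):
        if v < 0 or int(v) != v:
            raise ValueError("confusion counts must be non-negative integers")
    return EvalReport(tp=int(tp), fn=int(fn), tn=int(tn), fp=int(fp))


def _chains_to_fragments(chains: Iterable[AnnotatedChain], L: int) -> list[Fragment]:
    return [f for chain in chains for f in make_fragments(chain, L)]


def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    """Stratified fold indices; re-draw with the next seed if a fold lacks positives."""
    for attempt in range(10):
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = list(splitter.split(np.zeros(len(labels)), labels))
        if all(labels[test].sum() > 0 and labels[train].sum() > 0 for train, test in folds):
            if attempt:
                warnings.warn(f"fold without positives; re-drew split with seed {seed + attempt}")
            return folds
    raise ValueError("could not build stratified folds with positives in every fold")


def _cv_masked(
    fragments: Sequence[Fragment],
    orders: Sequence[int],
    masks: Sequence[str],
    config: GBMConfig,
    seed: int,
    n_folds: int,
    estimator_factory=None,
    ligand: str = "ION",
    threshold: float = 0.5,
) -> dict[str, EvalReport]:
    """Shared CV engine: features are assembled once per fold, then column-
    masked per ablation mask, so ablations see identical folds and artifacts."""
    labels = np.array([f.label for f in fragments], dtype=bool)
    folds = _stratified_folds(labels, n_folds, seed)

    per_mask_counts: dict[str, list[tuple]] = {m: [] for m in masks}
    per_mask_aurocs: dict[str, list[float]] = {m: [] for m in masks}
    per_mask_scores: dict[str, np.ndarray] = {
        m: np.zeros(len(fragments)) for m in masks
    }

    for train_idx, test_idx in folds:
        train = [fragments[i] for i in train_idx]
        test = [fragments[i] for i in test_idx]
        profile = fit_profile(train, orders, ligand=ligand)
        x_train_full = feature_matrix(train, profile, "d")
        x_test_full = feature_matrix(test, profile, "d")
        full_names = feature_names(profile, "d")
        y_train = labels[train_idx]
        y_test = labels[test_idx]
        for mask in masks:
            keep = _mask_columns(full_names, profile, mask)
            est = (
                estimator_factory(config)
                if estimator_factory is not None
                else config.estimator()
            )
            est.fit(x_train_full[:, keep], y_train)
            prob = est.predict_proba(x_test_full[:, keep])[:, 1]
            pred = prob >= threshold
            tp = int(np.sum(pred & y_test))
            fn = int(np.sum(~pred & y_test))
            tn = int(np.sum(~pred & ~y_test))
            fp = int(np.sum(pred & ~y_test))
            per_mask_counts[mask].append((tp, fn, tn, fp))
            per_mask_aurocs[mask].append(float(roc_auc_score(y_test, prob)))
            per_mask_scores[mask][test_idx] = prob

    reports = {}
    for mask in masks:
        counts = np.array(per_mask_counts[mask]).sum(axis=0)
        reports[mask] = EvalReport(
            tp=int(counts[0]),
            fn=int(counts[1]),
            tn=int(counts[2]),
            fp=int(counts[3]),
            auroc=float(roc_auc_score(labels, per_mask_scores[mask])),
            fold_counts=tuple(map(tuple, per_mask_counts[mask])),
            fold_aurocs=tuple(per_mask_aurocs[mask]),
            scores=per_mask_scores[mask],
            labels=labels.astype(int),
        )
    return reports


def _mask_columns(full_names: Sequence[str], profile: LigandProfile, mask: str) -> np.ndarray:
    wanted = set(feature_names(profile, mask))
    return np.array([name in wanted for name in full_names])


def cv_run(
    chains: Sequence[AnnotatedChain],
    L: int,
    feature_mask: str = "d",
    config: GBMConfig | None = None,
    seed: int = 0,
    n_folds: int = 5,
    orders: Sequence[int] | None = None,
    ligand: str = "ION",
) -> EvalReport:
    """Stratified fragment-level cross-validation of the boosted classifier.

    Gap orders are selected from the full chain set (a ligand-level
    statistic); screens, propensity table and PWMs are refitted inside each
    training fold. Counts are pooled across folds.
    """
    if feature_mask not in FEATURE_MASKS:
        raise ValueError(f"unknown feature mask {feature_mask!r}")
    config = config or GBMConfig(seed=seed)
    if orders is None:
        orders = select_orders(correlation_table(chains))
    fragments = _chains_to_fragments(chains, L)
    return _cv_masked(fragments, orders, [feature_mask], config, seed, n_folds, ligand=ligand)[
        feature_mask
    ]


def ablation_run(
    chains: Sequence[AnnotatedChain],
    L: int,
    masks: Sequence[str] = ("a", "b", "c", "d"),
    config: GBMConfig | None = None,
    seed: int = 0,
    n_folds: int = 5,
    orders: Sequence[int] | None = None,
) -> dict[str, EvalReport]:
    """Run the CV protocol for several ablation masks on shared folds."""
    config = config or GBMConfig(seed=seed)
    if orders is None:
        orders = select_orders(correlation_table(chains))
    fragments = _chains_to_fragments(chains, L)
    return _cv_masked(fragments, orders, list(masks), config, seed, n_folds)


def grid_search(
    chains: Sequence[AnnotatedChain],
    L: int,
    grids: Mapping[str, Sequence] | None = None,
    feature_mask: str = "d",
    seed: int = 0,
    n_folds: int = 5,
) -> tuple[GBMConfig, float]:
    """Exhaustive hyperparameter search selected by mean CV AUROC.

    Ties are broken toward fewer trees, then shallower depth.
    """
    grids = dict(grids or GBM_GRIDS)
    for key, domain in GBM_GRIDS.items():
        values = grids.setdefault(key, domain)
        if not set(values) <= set(domain):
            raise ValueError(f"grid values for {key} outside the allowed domain")
    best: tuple | None = None
    for n_trees, depth, shrink, min_node in product(
        grids["n_trees"], grids["interaction_depth"], grids["shrinkage"], grids["min_node"]
    ):
        config = GBMConfig(n_trees, depth, shrink, min_node, seed=seed)
        report = cv_run(chains, L, feature_mask, config, seed=seed, n_folds=n_folds)
        mean_auroc = float(np.mean(report.fold_aurocs))
        key = (-mean_auroc, n_trees, depth)
        if best is None or key < best[0]:
            best = (key, config, mean_auroc)
    assert best is not None
    return best[1], best[2]


def window_sweep(
    chains: Sequence[AnnotatedChain],
    windows: Sequence[int] = DEFAULT_WINDOWS,
    feature_mask: str = "d",
    config: GBMConfig | None = None,
    seed: int = 0,
    n_folds: int = 5,
) -> tuple[int, dict[int, EvalReport]]:
    """Evaluate every window length; pick max MCC, ties to Sn then smaller L."""
    reports = {
        L: cv_run(chains, L, feature_mask, config, seed=seed, n_folds=n_folds)
        for L in windows
    }
    best = min(reports, key=lambda L: (-reports[L].mcc, -reports[L].sn, L))
    return best, reports


def rf_baseline(
    chains: Sequence[AnnotatedChain],
    L: int,
    feature_mask: str = "d",
    n_trees: int = 500,
    seed: int = 0,
    n_folds: int = 5,
    orders: Sequence[int] | None = None,
) -> EvalReport:
    """Random-forest baseline (500 trees) under the identical CV protocol."""
    if orders is None:
        orders = select_orders(correlation_table(chains))
    fragments = _chains_to_fragments(chains, L)
    factory = lambda cfg: RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    return _cv_masked(
        fragments, orders, [feature_mask], GBMConfig(seed=seed), seed, n_folds,
        estimator_factory=factory,
    )[feature_mask]


# ---------------------------------------------------------------------------
# Model / Results objects


class MetalBindingModel:
    """Predictor of metal-ion ligand-binding residues for one ligand.

    Parameters
    ----------
    chains : sequence of AnnotatedChain
        Training chains with binding annotations.
    ligand : str
        Ligand identifier (e.g. "ZN", "MN"); informational.
    window : int
        Odd sliding-window length L.
    feature_mask : str
        "a" basic blocks only, "b" +correlation, "c" +propensity, "d" all.
    config : GBMConfig, optional
        Boosting hyperparameters (defaults to 100 trees, depth 3,
        shrinkage 0.1, min node 10).
    orders : sequence of int, optional
        Gap orders for the correlation block; selected from the chains'
        gap-probability table (p > 0.10) when omitted.
    """

    def __init__(
        self,
        chains: Sequence[AnnotatedChain],
        ligand: str = "ION",
        window: int = 11,
        feature_mask: str = "d",
        config: GBMConfig | None = None,
        orders: Sequence[int] | None = None,
    ):
        if feature_mask not in FEATURE_MASKS:
            raise ValueError(f"unknown feature mask {feature_mask!r}")
        self.chains = list(chains)
        self.ligand = ligand
        self.window = int(window)
        self.feature_mask = feature_mask
        self.config = config or GBMConfig()
        self._orders = list(orders) if orders is not None else None

    @classmethod
    def from_files(
        cls, fasta_path, annotation_path, structure_path=None, ligand=None, **kwargs
    ) -> "MetalBindingModel":
        from .io import read_chains

        chains = read_chains(fasta_path, annotation_path, structure_path, ligand=ligand)
        return cls(chains, ligand=ligand or "ION", **kwargs)

    @property
    def orders(self) -> list[int]:
        if self._orders is None:
            self._orders = select_orders(correlation_table(self.chains))
        return self._orders

    def fit(self, seed: int | None = None) -> "MetalBindingResults":
        """Fit the profile and classifier on all chains (no held-out report)."""
        config = self.config if seed is None else replace(self.config, seed=seed)
        fragments = _chains_to_fragments(self.chains, self.window)
        profile = fit_profile(fragments, self.orders, ligand=self.ligand)
        x = feature_matrix(fragments, profile, self.feature_mask)
        y = np.array([f.label for f in fragments])
        est = config.estimator()
        est.fit(x, y)
        return MetalBindingResults(self, profile, est, report=None, config=config)

    def cross_validate(self, seed: int = 0, n_folds: int = 5) -> "MetalBindingResults":
        """5-fold CV report plus a final fit on all chains."""
        report = cv_run(
            self.chains,
            self.window,
            self.feature_mask,
            replace(self.config, seed=seed),
            seed=seed,
            n_folds=n_folds,
            orders=self.orders,
            ligand=self.ligand,
        )
        results = self.fit(seed=seed)
        return MetalBindingResults(
            self, results.profile, results.estimator, report=report, config=results.config
        )


class MetalBindingResults:
    """Fitted artifacts, classifier and evaluation report of one model."""

    def __init__(self, model, profile, estimator, report, config):
        self.model = model
        self.profile: LigandProfile = profile
        self.estimator = estimator
        self.report: EvalReport | None = report
        self.config: GBMConfig = config

    def predict(self, chains: Sequence[AnnotatedChain], threshold: float = 0.5) -> pd.DataFrame:
        """Per-residue predictions: chain, position, residue, score, 0/1 call."""
        rows = []
        for chain in chains:
            fragments = make_fragments(chain, self.model.window)
            x = feature_matrix(fragments, self.profile, self.model.feature_mask)
            prob = self.estimator.predict_proba(x)[:, 1]
            for frag, p in zip(fragments, prob):
                rows.append(
                    {
                        "chain_id": chain.chain_id,
                        "position": frag.center_position,
                        "residue": frag.center,
                        "score": float(p),
                        "call": int(p >= threshold),
                    }
                )
        return pd.DataFrame(rows)

    def evaluate(self, chains: Sequence[AnnotatedChain], threshold: float = 0.5) -> EvalReport:
        """Score chains against their own binding annotations."""
        pred = self.predict(chains, threshold)
        truth = {
            (c.chain_id, p): True for c in chains for p in c.binding_positions
        }
        y = np.array(
            [truth.get((r.chain_id, r.position), False) for r in pred.itertuples()]
        )
        calls = pred["call"].to_numpy().astype(bool)
        rep = metrics(
            int(np.sum(calls & y)),
            int(np.sum(~calls & y)),
            int(np.sum(~calls & ~y)),
            int(np.sum(calls & ~y)),
        )
        auroc = float(roc_auc_score(y, pred["score"])) if 0 < y.sum() < len(y) else float("nan")
        return replace(rep, auroc=auroc, scores=pred["score"].to_numpy(), labels=y.astype(int))

    def summary(self) -> str:
        """Human-readable summary of the model, profile and CV metrics."""
        lines = [
            "Metal-ion binding-residue model",
            "=" * 47,
            f"ligand:           {self.model.ligand}",
            f"window length L:  {self.model.window}",
            f"feature mask:     {self.model.feature_mask}",
            f"gap orders:       {list(self.profile.orders)}",
            f"features:         {self.profile.n_features if self.model.feature_mask == 'd' else 'masked'}",
            f"chains:           {len(self.model.chains)}",
            (
                "gbm:              trees={0.n_trees} depth={0.interaction_depth} "
                "shrinkage={0.shrinkage} min_node={0.min_node} seed={0.seed}"
            ).format(self.config),
        ]
        if self.report is not None:
            r = self.report
            lines += [
                "-" * 47,
                "5-fold cross-validation (pooled counts)",
                f"TP={r.tp}  FN={r.fn}  TN={r.tn}  FP={r.fp}",
                f"Sn:    {r.sn:7.2f} %",
                f"Sp:    {r.sp:7.2f} %",
                f"Acc:   {r.acc:7.2f} %",
                f"MCC:   {r.mcc:7.4f}",
                f"AUROC: {r.auroc:7.4f}",
            ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Pickle the results (profile + classifier + config) to a file."""
        payload = {
            "ligand": self.model.ligand,
            "window": self.model.window,
            "feature_mask": self.model.feature_mask,
            "profile": self.profile,
            "estimator": self.estimator,
            "report": self.report,
            "config": self.config,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "MetalBindingResults":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        model = MetalBindingModel(
            [],
            ligand=payload["ligand"],
            window=payload["window"],
            feature_mask=payload["feature_mask"],
            config=payload["config"],
            orders=list(payload["profile"].orders),
        )
        return cls(
            model, payload["profile"], payload["estimator"], payload["report"], payload["config"]
        )
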
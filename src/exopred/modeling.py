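"""Random-forest training, repeated stratified cross-validation, grid
selection, and scoring of new sequences.

The classifier is a random forest over one of the five sequence encodings;
the tunable that matters is the number of trees (sometimes called the
"interaction value" in this context), swept over a grid from 100 to 10,000.
Model quality is estimated by stratified tenfold cross-validation repeated
ten times, with mean ± sd of ACC/AUC/MCC taken over the fold-level values.

Two surfaces are offered: plain functions (:func:`train_forest`,
:func:`cross_validate`, :func:`grid_select`, :func:`predict_scores`) and a
model/results pair (:class:`ExosomeSecretionModel` /
:class:`ExosomeSecretionResults`) for the common fit-inspect-predict flow.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from . import io_formats
from .features import (
    SCHEMES,
    ScaleSet,
    default_scale_set,
    encode_dataset,
)
from .io_formats import ProteinRecord
from .metrics import evaluate_predictions

#: the reference tree-count sweep: 100..1000 by 50, 1500..6000 by 500,
#: then 8000 and 10000 (31 values)
def default_tree_grid() -> list[int]:
    return list(range(100, 1001, 50)) + list(range(1500, 6001, 500)) + [8000, 10000]


_METRIC_COLUMNS = ("acc", "auc", "mcc", "se", "sp")


class ModelingError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    scheme: str = "DP"
    tree_grid: tuple[int, ...] = tuple(default_tree_grid())
    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ModelingError(f"unknown scheme {self.scheme!r}")
        grid = tuple(int(t) for t in self.tree_grid)
        if not grid or any(t <= 0 for t in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ModelingError("tree_grid must be positive and strictly increasing")
        if self.n_folds < 2:
            raise ModelingError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ModelingError("n_repeats must be >= 1")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ModelingError("decision_threshold must be in (0, 1)")


@dataclasses.dataclass
class ModelBundle:
    """A trained forest plus everything needed to reproduce and apply it."""

    forest: RandomForestClassifier
    scheme: str
    n_trees: int
    seed: int
    scale_set_version: str
    feature_names: tuple[str, ...]
    decision_threshold: float = 0.5
    training_summary: Optional[pd.DataFrame] = None

    def predict_matrix(self, features: pd.DataFrame) -> np.ndarray:
        """Positive-class probability for each row of a feature matrix."""
        if list(features.columns) != list(self.feature_names):
            raise ModelingError(
                "feature matrix columns do not match the bundle's feature scheme"
            )
        pos_col = int(np.flatnonzero(self.forest.classes_ == 1)[0])
        return self.forest.predict_proba(features.to_numpy())[:, pos_col]


def _seed_for(base_seed: int, *keys) -> int:
    """Stable sub-seed derived from the base seed and structural keys."""
    digest = hashlib.blake2b(
        repr((base_seed,) + keys).encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "little") % (2**31 - 1)


def train_forest(
    features: pd.DataFrame,
    labels: Sequence[int],
    n_trees: int,
    seed: int,
    scheme: str = "DP",
    scale_set_version: str = "bundled-1",
    decision_threshold: float = 0.5,
) -> ModelBundle:
    """Fit one random forest (sqrt features per split, unlimited depth).

    Deterministic for fixed inputs and seed: the bundle's scores on any probe
    set are reproducible bit for bit.
    """
    y = np.asarray(labels, dtype=int)
    if len(features) != len(y):
        raise ModelingError("feature rows and labels differ in length")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ModelingError("training labels contain a single class")
    if counts.min() < 2:
        raise ModelingError("need at least 2 examples of each class")
    forest = RandomForestClassifier(
        n_estimators=int(n_trees),
        max_features="sqrt",
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(features.to_numpy(), y)
    return ModelBundle(
        forest=forest,
        scheme=scheme,
        n_trees=int(n_trees),
        seed=int(seed),
        scale_set_version=scale_set_version,
        feature_names=tuple(features.columns),
        decision_threshold=decision_threshold,
    )


@dataclasses.dataclass
class CVResult:
    """Fold-level metrics for every (scheme, n_trees, repeat, fold) cell."""

    cells: pd.DataFrame  # columns: scheme, n_trees, repeat, fold, n_test, + metrics
    n_folds: int
    n_repeats: int
    seed: int

    def aggregate(self) -> pd.DataFrame:
        """Mean ± sd of each metric over the repeat × fold cells."""
        if self.cells.empty:
            raise ModelingError("empty cross-validation result")
        grouped = self.cells.groupby(["scheme", "n_trees"])
        out = {}
        for metric in _METRIC_COLUMNS:
            out[f"{metric}_mean"] = grouped[metric].mean()
            out[f"{metric}_sd"] = grouped[metric].std(ddof=1)
        out["n_cells"] = grouped.size()
        return pd.DataFrame(out)

    def merge(self, other: "CVResult") -> "CVResult":
        if (self.n_folds, self.n_repeats, self.seed) != (
            other.n_folds,
            other.n_repeats,
            other.seed,
        ):
            raise ModelingError("cannot merge CV results with different designs")
        return CVResult(
            cells=pd.concat([self.cells, other.cells], ignore_index=True),
            n_folds=self.n_folds,
            n_repeats=self.n_repeats,
            seed=self.seed,
        )

    def to_long_tsv(self, path) -> None:
        long = self.cells.melt(
            id_vars=["scheme", "n_trees", "repeat", "fold"],
            value_vars=list(_METRIC_COLUMNS),
            var_name="metric",
            value_name="value",
        )
        long.to_csv(path, sep="\t", index=False)


def cross_validate(
    records: Sequence[ProteinRecord],
    config: TrainConfig,
    scale_set: Optional[ScaleSet] = None,
    tree_grid: Optional[Sequence[int]] = None,
) -> CVResult:
    """Repeated stratified k-fold CV of the config's scheme over a tree grid.

    Encoding is per-sequence and precedes the fold split, so no information
    can leak between folds. Each repeat reshuffles the stratified folds with
    its own derived seed; each (n_trees, repeat, fold) forest gets a derived
    seed of its own.
    """
    scale_set = scale_set or default_scale_set()
    grid = [int(t) for t in (tree_grid if tree_grid is not None else config.tree_grid)]
    features, labels = encode_dataset(
        records, config.scheme, scale_set, require_labels=True
    )
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ModelingError("cross-validation needs both classes")
    if counts.min() < config.n_folds:
        raise ModelingError(
            f"class with {counts.min()} members cannot fill {config.n_folds} folds"
        )
    X = features.to_numpy()
    rows = []
    for repeat in range(config.n_repeats):
        splitter = StratifiedKFold(
            n_splits=config.n_folds,
            shuffle=True,
            random_state=_seed_for(config.seed, "fold-shuffle", repeat),
        )
        for fold, (train_idx, test_idx) in enumerate(splitter.split(X, labels)):
            for n_trees in grid:
                forest = RandomForestClassifier(
                    n_estimators=n_trees,
                    max_features="sqrt",
                    random_state=_seed_for(
                        config.seed, "rf", config.scheme, n_trees, repeat, fold
                    ),
                    n_jobs=1,
                )
                forest.fit(X[train_idx], labels[train_idx])
                pos_col = int(np.flatnonzero(forest.classes_ == 1)[0])
                scores = forest.predict_proba(X[test_idx])[:, pos_col]
                report = evaluate_predictions(
                    labels[test_idx], scores, threshold=config.decision_threshold
                )
                rows.append(
                    {
                        "scheme": config.scheme,
                        "n_trees": n_trees,
                        "repeat": repeat,
                        "fold": fold,
                        "n_test": len(test_idx),
                        "acc": report.acc_percent,
                        "auc": report.auc,
                        "mcc": report.mcc,
                        "se": report.se,
                        "sp": report.sp,
                    }
                )
    return CVResult(
        cells=pd.DataFrame(rows),
        n_folds=config.n_folds,
        n_repeats=config.n_repeats,
        seed=config.seed,
    )


def sweep(
    records: Sequence[ProteinRecord],
    schemes: Sequence[str],
    config: TrainConfig,
    scale_set: Optional[ScaleSet] = None,
    tree_grid: Optional[Sequence[int]] = None,
) -> CVResult:
    """Cross-validate several feature schemes under one CV design."""
    result: Optional[CVResult] = None
    for scheme in schemes:
        cfg = dataclasses.replace(config, scheme=scheme)
        part = cross_validate(records, cfg, scale_set, tree_grid)
        result = part if result is None else result.merge(part)
    if result is None:
        raise ModelingError("no schemes requested")
    return result


def grid_select(cv: CVResult, criterion: str = "ACC") -> tuple[str, int]:
    """Best (scheme, n_trees) by mean criterion over the CV cells.

    Ties break toward fewer trees, then toward the earlier scheme in
    PCP < AA < PCP_AA < DP < PCP_AA_DP order.
    """
    criterion = criterion.lower()
    if criterion not in _METRIC_COLUMNS:
        raise ModelingError(f"unknown selection criterion {criterion!r}")
    agg = cv.aggregate()
    if agg.empty:
        raise ModelingError("empty cross-validation result")
    scheme_rank = {s: i for i, s in enumerate(SCHEMES)}
    best = None
    for (scheme, n_trees), row in agg.iterrows():
        key = (-row[f"{criterion}_mean"], n_trees, scheme_rank[scheme])
        if best is None or key < best[0]:
            best = (key, (scheme, int(n_trees)))
    return best[1]


def predict_scores(
    bundle: ModelBundle,
    records: Sequence[ProteinRecord],
    scale_set: Optional[ScaleSet] = None,
    threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Score records with a trained bundle.

    Returns a frame indexed by record id with columns ``score`` (positive-
    class probability) and ``call`` (Y iff score ≥ threshold).
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ModelingError("duplicate record ids in prediction batch")
    threshold = bundle.decision_threshold if threshold is None else threshold
    features, _ = encode_dataset(records, bundle.scheme, scale_set)
    scores = bundle.predict_matrix(features)
    return pd.DataFrame(
        {"score": scores, "call": np.where(scores >= threshold, "Y", "N")},
        index=pd.Index(ids, name="id"),
    )


class ExosomeSecretionModel:
    """Random-forest model of exosome-mediated secretion, built from labeled
    protein records.

    Parameters
    ----------
    records : labeled ProteinRecords (label 1 = exosome cargo, 0 = not)
    scheme : feature encoding, default the dipeptide composition that the
        underlying study selected
    scale_set : physico-chemical scales for PCP-containing schemes
    """

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        scheme: str = "DP",
        scale_set: Optional[ScaleSet] = None,
    ):
        if not records:
            raise ModelingError("no training records")
        if any(r.label is None for r in records):
            raise ModelingError("all training records must be labeled")
        self.records = list(records)
        self.scheme = scheme
        self.scale_set = scale_set or default_scale_set()
        self.n_pos = sum(r.label == 1 for r in self.records)
        self.n_neg = sum(r.label == 0 for r in self.records)

    @classmethod
    def from_fasta(
        cls,
        positives_path,
        negatives_path,
        scheme: str = "DP",
        scale_set: Optional[ScaleSet] = None,
        sanitize_policy: io_formats.SanitizePolicy = "drop_ambiguous",
    ) -> "ExosomeSecretionModel":
        pos = io_formats.read_fasta(positives_path, sanitize_policy, label=1)
        neg = io_formats.read_fasta(negatives_path, sanitize_policy, label=0)
        return cls(pos + neg, scheme=scheme, scale_set=scale_set)

    @classmethod
    def from_manifest(
        cls, manifest_path, scheme: str = "DP", scale_set: Optional[ScaleSet] = None
    ) -> "ExosomeSecretionModel":
        manifest = io_formats.read_manifest(manifest_path)
        records, _ = io_formats.load_dataset(manifest)
        return cls(records, scheme=scheme, scale_set=scale_set)

    def fit(
        self,
        n_trees: int = 3000,
        seed: int = 0,
        cross_validate_first: bool = True,
        n_folds: int = 10,
        n_repeats: int = 10,
        decision_threshold: float = 0.5,
    ) -> "ExosomeSecretionResults":
        """Train the final forest on all records, optionally preceded by a
        repeated stratified CV at the same tree count for uncertainty
        estimates."""
        config = TrainConfig(
            scheme=self.scheme,
            tree_grid=(n_trees,),
            n_folds=n_folds,
            n_repeats=n_repeats,
            seed=seed,
            decision_threshold=decision_threshold,
        )
        cv = (
            cross_validate(self.records, config, self.scale_set)
            if cross_validate_first
            else None
        )
        features, labels = encode_dataset(
            self.records, self.scheme, self.scale_set, require_labels=True
        )
        bundle = train_forest(
            features,
            labels,
            n_trees=n_trees,
            seed=_seed_for(seed, "final-fit", self.scheme, n_trees),
            scheme=self.scheme,
            scale_set_version=self.scale_set.version,
            decision_threshold=decision_threshold,
        )
        if cv is not None:
            bundle.training_summary = cv.aggregate()
        return ExosomeSecretionResults(model=self, bundle=bundle, cv_result=cv)


class ExosomeSecretionResults:
    """Fitted-model results: the trained bundle, CV-based uncertainty
    estimates, prediction and persistence."""

    def __init__(
        self,
        model: ExosomeSecretionModel,
        bundle: ModelBundle,
        cv_result: Optional[CVResult] = None,
    ):
        self.model = model
        self.bundle = bundle
        self.cv_result = cv_result

    @property
    def estimates(self) -> Optional[pd.Series]:
        """CV mean ± sd row for the fitted (scheme, n_trees), if CV was run."""
        if self.cv_result is None:
            return None
        return self.cv_result.aggregate().loc[(self.bundle.scheme, self.bundle.n_trees)]

    def predict(self, records: Sequence[ProteinRecord]) -> pd.DataFrame:
        return predict_scores(self.bundle, records, self.model.scale_set)

    def save(self, path) -> None:
        io_formats.save_model(self.bundle, path)

    def summary(self) -> str:
        lines = [
            "Exosome secretion random-forest model",
            "=" * 46,
            f"feature scheme       {self.bundle.scheme}",
            f"trees                {self.bundle.n_trees}",
            f"training proteins    {self.model.n_pos} exosome / "
            f"{self.model.n_neg} non-exosome",
            f"decision threshold   {self.bundle.decision_threshold}",
            f"scale set            {self.bundle.scale_set_version}",
        ]
        est = self.estimates
        if est is not None:
            lines += [
                "-" * 46,
                f"cross-validation     {self.cv_result.n_folds}-fold x "
                f"{self.cv_result.n_repeats} repeats",
                f"ACC (%)              {est['acc_mean']:.2f} ± {est['acc_sd']:.2f}",
                f"AUC                  {est['auc_mean']:.3f} ± {est['auc_sd']:.3f}",
                f"MCC                  {est['mcc_mean']:.3f} ± {est['mcc_sd']:.3f}",
                f"SE                   {est['se_mean']:.3f} ± {est['se_sd']:.3f}",
                f"SP                   {est['sp_mean']:.3f} ± {est['sp_sd']:.3f}",
            ]
        return "\n".join(lines)
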
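"""Downstream-classification evaluation of imputation quality.

Imputation quality is scored indirectly: ampute a complete dataset, impute
it back, and measure how well a classifier trained on the imputed table
predicts the class column under repeated stratified 10-fold cross-
validation.  The benchmark grid crosses datasets x mechanisms x rates x
imputers x classifiers; each (dataset, mechanism, rate) cell shares one
amputation mask across all imputers, so method comparisons are paired.
An un-amputed "origin" control row per (dataset, classifier) gives the
clean-data reference accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed
from .amputate import AmputationConfig, ampute
from .data import DiscreteTable, OneHotLayout, encode_one_hot
from .errors import ConfigError, MissingCellError

#: imputer signature: (table, mechanism, seed) -> complete table
ImputerFn = Callable[[DiscreteTable, str, int], DiscreteTable]
#: classifier factory: (seed) -> object with fit/predict
ClassifierFactory = Callable[[int], object]


def repeated_kfold_accuracy(
    table: DiscreteTable,
    classifier_factory: ClassifierFactory,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and std of k-fold accuracy over seeded repeats.

    Folds are stratified on the class column (a 9:1 train:test split at
    k=10); features are the one-hot encoded feature attributes.  Per repeat
    the accuracy is the mean over folds; the returned std is the population
    std over the repeat means.
    """
    if not table.is_complete:
        raise MissingCellError("evaluation requires a complete (imputed) table")
    ci = table.schema.class_index
    if ci is None:
        raise ConfigError("evaluation requires a class column")
    if k < 2:
        raise ConfigError("k must be >= 2")
    layout = OneHotLayout.from_table(table, table.schema.feature_indices)
    X = encode_one_hot(table, layout)
    y = table.columns[ci]
    repeat_accs = []
    for rep in range(repeats):
        rep_seed = derive_seed(seed, "cv-repeat", rep)
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        fold_accs = []
        with warnings.catch_warnings():
            # classes rarer than k trip sklearn's stratification warning;
            # the fold is kept per the evaluation contract
            warnings.simplefilter("ignore")
            for fold, (tr, te) in enumerate(splitter.split(X, y)):
                clf = classifier_factory(derive_seed(rep_seed, "fold", fold))
                clf.fit(X[tr], y[tr])
                pred = np.asarray(clf.predict(X[te]))
                fold_accs.append(float((pred == y[te]).mean()))
        repeat_accs.append(float(np.mean(fold_accs)))
    return float(np.mean(repeat_accs)), float(np.std(repeat_accs))


@dataclass
class BenchmarkRecord:
    """One grid cell: accuracy mean +- std for a full pipeline combination."""

    dataset: str
    mechanism: str
    rate: float
    imputer: str
    classifier: str
    mean_accuracy: float
    std_accuracy: float
    error: str | None = None


class BenchmarkResult:
    """Tidy record collection with CSV-friendly views."""

    def __init__(self, records: list[BenchmarkRecord], seed: int):
        self.records = records
        self.seed = seed

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.records])
        return df.sort_values(
            ["dataset", "mechanism", "rate", "imputer", "classifier"]
        ).reset_index(drop=True)

    def aggregate(self) -> pd.DataFrame:
        """Mean accuracy over rates per (dataset, mechanism, imputer, classifier)."""
        df = self.to_frame()
        df = df[df["error"].isna() & (df["mechanism"] != "origin")]
        return (
            df.groupby(["dataset", "mechanism", "imputer", "classifier"], as_index=False)
            .agg(mean_accuracy=("mean_accuracy", "mean"), n_rates=("rate", "nunique"))
            .sort_values(["dataset", "mechanism", "imputer", "classifier"])
            .reset_index(drop=True)
        )


def run_benchmark(
    datasets: Mapping[str, DiscreteTable],
    mechanisms: Sequence[str],
    rates: Sequence[float],
    imputers: Mapping[str, ImputerFn],
    classifiers: Mapping[str, ClassifierFactory],
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    dependence_odds: float = 9.0,
) -> BenchmarkResult:
    """Run the full (dataset x mechanism x rate x imputer x classifier) grid.

    Per-cell seeds derive from the master seed and the cell's names, so the
    result is independent of grid iteration order.  Failures in any stage
    are recorded in the cell's ``error`` field and the grid continues.
    """
    if not datasets or not mechanisms or not rates or not imputers or not classifiers:
        raise ConfigError("benchmark grids must be non-empty")
    records: list[BenchmarkRecord] = []
    for ds_name, table in datasets.items():
        if not table.is_complete:
            raise MissingCellError(f"benchmark dataset {ds_name!r} must be complete")
        # origin control: the clean dataset through the same evaluation
        for clf_name, factory in classifiers.items():
            mean, std = repeated_kfold_accuracy(
                table, factory, k=k, repeats=repeats,
                seed=derive_seed(seed, ds_name, "origin", clf_name),
            )
            records.append(
                BenchmarkRecord(ds_name, "origin", 0.0, "origin", clf_name, mean, std)
            )
        for mech in mechanisms:
            for rate in rates:
                rate_key = f"{rate:.6g}"
                amp_seed = derive_seed(seed, ds_name, mech, rate_key, "ampute")
                amputed = ampute(
                    table,
                    AmputationConfig(
                        mechanism=mech, rate=rate,
                        dependence_odds=dependence_odds, seed=amp_seed,
                    ),
                )
                for imp_name, imputer in imputers.items():
                    imp_seed = derive_seed(seed, ds_name, mech, rate_key, "impute", imp_name)
                    try:
                        imputed = imputer(amputed, mech, imp_seed)
                    except Exception as exc:
                        for clf_name in classifiers:
                            records.append(
                                BenchmarkRecord(
                                    ds_name, mech, rate, imp_name, clf_name,
                                    float("nan"), float("nan"), error=str(exc),
                                )
                            )
                        continue
                    for clf_name, factory in classifiers.items():
                        cv_seed = derive_seed(seed, ds_name, mech, rate_key, "cv", clf_name)
                        try:
                            mean, std = repeated_kfold_accuracy(
                                imputed, factory, k=k, repeats=repeats, seed=cv_seed
                            )
                            records.append(
                                BenchmarkRecord(
                                    ds_name, mech, rate, imp_name, clf_name, mean, std
                                )
                            )
                        except Exception as exc:
                            records.append(
                                BenchmarkRecord(
                                    ds_name, mech, rate, imp_name, clf_name,
                                    float("nan"), float("nan"), error=str(exc),
                                )
                            )
    return BenchmarkResult(records, seed)


# ---------------------------------------------------------------------------
# registries
# ---------------------------------------------------------------------------

def default_imputers(
    epochs: int = 1000,
    k: int = 5,
    hidden: tuple[int, ...] = (32, 32, 32),
    learning_rate: float = 0.001,
    batch_size: int = 256,
) -> dict[str, ImputerFn]:
    """Name -> imputer callables for the nine methods of the comparison."""
    from .baselines import (
        impute_autoencoder,
        impute_forest,
        impute_hotdeck,
        impute_knn,
        impute_mlp,
        impute_mode,
        impute_random,
        impute_tree,
    )
    from .imlp import impute_isb_imlp
    from .mlp import TrainConfig

    def cfg(seed: int) -> TrainConfig:
        return TrainConfig(
            learning_rate=learning_rate, batch_size=batch_size,
            epochs=epochs, hidden=hidden, seed=seed,
        )

    return {
        "mode": lambda t, mech, seed: impute_mode(t),
        "random": lambda t, mech, seed: impute_random(t, seed=seed),
        "hotdeck": lambda t, mech, seed: impute_hotdeck(t),
        "knn": lambda t, mech, seed: impute_knn(t, k=k),
        "tree": lambda t, mech, seed: impute_tree(t, seed=seed),
        "forest": lambda t, mech, seed: impute_forest(t, seed=seed),
        "autoencoder": lambda t, mech, seed: impute_autoencoder(t, cfg(seed)),
        "mlp": lambda t, mech, seed: impute_mlp(t, cfg(seed)),
        "imlp": lambda t, mech, seed: impute_isb_imlp(t, mech, cfg(seed)),
    }


def default_classifiers() -> dict[str, ClassifierFactory]:
    """The SVM / naive-Bayes / decision-tree / k-NN evaluation panel
    (scikit-learn defaults, seeded where the learner is stochastic)."""
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "svm": lambda seed: SVC(),
        "nb": lambda seed: GaussianNB(),
        "dt": lambda seed: DecisionTreeClassifier(random_state=seed),
        "knn": lambda seed: KNeighborsClassifier(),
    }


class MajorityClassifier:
    """Stub learner predicting the most frequent training label."""

    def fit(self, X, y):
        vals, counts = np.unique(np.asarray(y), return_counts=True)
        self.label_ = vals[int(counts.argmax())]
        return self

    def predict(self, X):
        return np.full(len(X), self.label_)


class NearestRowClassifier:
    """Stub learner predicting the label of the closest training row (L1)."""

    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        out = []
        for row in X:
            d = np.abs(self.X_ - row).sum(axis=1)
            out.append(self.y_[int(d.argmin())])
        return np.asarray(out)


def stub_classifiers() -> dict[str, ClassifierFactory]:
    """Cheap deterministic learners for smoke tests and dry runs."""
    return {
        "majority": lambda seed: MajorityClassifier(),
        "nearest": lambda seed: NearestRowClassifier(),
    }
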
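"""Baseline imputers: mode, random, hot-deck, k-NN, learner-backed, autoencoder, plain MLP.

All imputers share three contracts: the returned table has zero MISSING
cells, observed cells are never modified, and every fill is a member of the
attribute's domain.  Donor methods (hot-deck, k-NN) measure similarity with
the Hamming distance over the one-hot encoding of the categorical
attributes the incomplete row actually observes; numeric attributes are
excluded from the metric.

Classification-style imputation (decision tree, random forest) treats each
missing attribute as a label to predict from the attributes its missing
type leaves observed; the learners themselves are delegated to
scikit-learn through a minimal fit/predict interface.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .data import (
    DiscreteTable,
    OneHotLayout,
    _decode_codes,
    detect_missing_types,
    encode_one_hot,
    split_by_completeness,
)
from .errors import (
    NoDonorError,
    ShapeError,
    UnimputableAttributeError,
    UnimputableTypeError,
)
from .mlp import TrainConfig, forward, train


@runtime_checkable
class LearnerInterface(Protocol):
    """Duck-typed classifier contract for delegated learners."""

    def fit(self, X, y): ...

    def predict(self, X): ...


LearnerFactory = Callable[[], LearnerInterface]


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Number of differing positions between two equal-length 0/1 vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError(f"hamming_distance needs equal-length vectors, got {a.shape} and {b.shape}")
    return int(np.count_nonzero(a != b))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _check_imputable(table: DiscreteTable) -> None:
    """Reject numeric missing cells (out of scope: targets are discrete)."""
    for j, attr in enumerate(table.schema.attributes):
        if attr.kind == "numeric" and np.isnan(table.columns[j]).any():
            raise UnimputableAttributeError(
                f"numeric attribute {attr.name!r} has missing cells; "
                "only discrete attributes are imputation targets"
            )


def _mode_code(codes: np.ndarray, domain_size: int, name: str) -> int:
    observed = codes[codes >= 0]
    if observed.size == 0:
        raise UnimputableAttributeError(f"attribute {name!r} has no observed values")
    counts = np.bincount(observed, minlength=domain_size)
    return int(counts.argmax())  # first maximum = domain order tie-break


def _codes_matrix(table: DiscreteTable, attrs: Sequence[int]) -> np.ndarray:
    return np.column_stack([table.columns[j] for j in attrs])


def _donor_distances(
    dcom_codes: np.ndarray, row_codes: np.ndarray, observed: np.ndarray
) -> np.ndarray:
    """Hamming distances (over one-hot encoding) from a row to all donors.

    Two different categories differ in exactly two one-hot positions, so the
    encoded Hamming distance is twice the number of mismatching attributes.
    """
    return 2 * (dcom_codes[:, observed] != row_codes[observed]).sum(axis=1)


# ---------------------------------------------------------------------------
# statistical imputers
# ---------------------------------------------------------------------------

def impute_mode(table: DiscreteTable) -> DiscreteTable:
    """Fill each missing cell with its attribute's most frequent observed value.

    Frequency ties break to the earlier category in domain order.
    """
    _check_imputable(table)
    out = table.copy()
    for j in table.schema.categorical_indices:
        codes = out.columns[j]
        miss = codes < 0
        if miss.any():
            fill = _mode_code(codes, len(table.schema.domain(j)), table.schema.names[j])
            codes[miss] = fill
    return out


def impute_random(table: DiscreteTable, seed: int = 0) -> DiscreteTable:
    """Fill each missing cell with a draw from the attribute's observed
    empirical distribution, so more frequent values are more likely chosen."""
    _check_imputable(table)
    out = table.copy()
    rng = np.random.default_rng(seed)
    for j in table.schema.categorical_indices:
        codes = out.columns[j]
        miss = codes < 0
        if not miss.any():
            continue
        observed = codes[~miss]
        if observed.size == 0:
            raise UnimputableAttributeError(
                f"attribute {table.schema.names[j]!r} has no observed values"
            )
        dom_size = len(table.schema.domain(j))
        counts = np.bincount(observed, minlength=dom_size)
        probs = counts / counts.sum()
        codes[miss] = rng.choice(dom_size, size=int(miss.sum()), p=probs).astype(np.int32)
    return out


# ---------------------------------------------------------------------------
# donor imputers
# ---------------------------------------------------------------------------

def impute_hotdeck(table: DiscreteTable) -> DiscreteTable:
    """Copy all missing cells of each incomplete row from its nearest
    complete donor row (Hamming distance over the row's observed categorical
    attributes); distance ties go to the lowest donor row index."""
    _check_imputable(table)
    out = table.copy()
    mask = table.missing_mask
    incomplete = np.nonzero(mask.any(axis=1))[0]
    if incomplete.size == 0:
        return out
    complete = np.nonzero(~mask.any(axis=1))[0]
    if complete.size == 0:
        raise NoDonorError("hot-deck needs at least one complete row as donor")
    cat = np.array(table.schema.categorical_indices)
    dcom_codes = _codes_matrix(table, cat)[complete]
    for r in incomplete:
        row_codes = np.array([table.columns[j][r] for j in cat])
        observed = row_codes >= 0
        d = _donor_distances(dcom_codes, row_codes, observed)
        donor = complete[int(d.argmin())]  # argmin = lowest index on ties
        for j in np.nonzero(mask[r])[0]:
            out.columns[j][r] = table.columns[j][donor]
    return out


def impute_knn(table: DiscreteTable, k: int = 5) -> DiscreteTable:
    """Distance-weighted vote among the k nearest complete donors.

    Donor weight is 1/(1+distance); per missing cell the category with the
    highest aggregate weight wins, ties broken by higher donor frequency,
    then domain order.  ``k`` is capped at the donor-pool size; ``k = 1``
    coincides with hot-deck.
    """
    if k < 1:
        raise ShapeError(f"k must be >= 1, got {k}")
    _check_imputable(table)
    out = table.copy()
    mask = table.missing_mask
    incomplete = np.nonzero(mask.any(axis=1))[0]
    if incomplete.size == 0:
        return out
    complete = np.nonzero(~mask.any(axis=1))[0]
    if complete.size == 0:
        raise NoDonorError("k-NN imputation needs at least one complete row as donor")
    k_eff = min(k, complete.size)
    cat = np.array(table.schema.categorical_indices)
    dcom_codes = _codes_matrix(table, cat)[complete]
    for r in incomplete:
        row_codes = np.array([table.columns[j][r] for j in cat])
        observed = row_codes >= 0
        d = _donor_distances(dcom_codes, row_codes, observed)
        nn = np.argsort(d, kind="stable")[:k_eff]  # stable: index tie-break
        w = 1.0 / (1.0 + d[nn])
        for j in np.nonzero(mask[r])[0]:
            donor_codes = np.array([table.columns[j][complete[i]] for i in nn])
            dom_size = len(table.schema.domain(j))
            weight = np.bincount(donor_codes, weights=w, minlength=dom_size)
            count = np.bincount(donor_codes, minlength=dom_size)
            best = max(
                range(dom_size), key=lambda c: (weight[c], count[c], -c)
            )
            out.columns[j][r] = best
    return out


# ---------------------------------------------------------------------------
# learner-backed imputation
# ---------------------------------------------------------------------------

def impute_learner(
    table: DiscreteTable, learner_factory: LearnerFactory
) -> DiscreteTable:
    """Per (missing type, attribute): train a classifier on complete rows with
    the type's observed attributes as features and the target attribute as
    label, then predict fills for the type's rows."""
    _check_imputable(table)
    out = table.copy()
    types = detect_missing_types(table)
    if not types:
        return out
    mask = table.missing_mask
    complete_rows = np.nonzero(~mask.any(axis=1))[0]
    if complete_rows.size == 0:
        raise NoDonorError("learner imputation needs complete rows to train on")
    for mt in types:
        input_attrs = [j for j in range(table.schema.n_attrs) if j not in mt.missing_attrs]
        layout = OneHotLayout.from_table(table, input_attrs)
        X_train = encode_one_hot(table, layout, complete_rows)
        X_pred = encode_one_hot(table, layout, list(mt.rows))
        for j in mt.missing_attrs:
            labels = table.columns[j][complete_rows]
            try:
                learner = learner_factory()
                learner.fit(X_train, labels)
                pred = np.asarray(learner.predict(X_pred))
            except Exception as exc:  # add context, propagate
                raise UnimputableTypeError(
                    f"learner failed for missing type {mt.missing_attrs} on "
                    f"attribute {table.schema.names[j]!r}: {exc}"
                ) from exc
            out.columns[j][list(mt.rows)] = pred.astype(np.int32)
    return out


def tree_learner_factory(seed: int = 0) -> LearnerFactory:
    """CART decision tree (Gini split criterion, scikit-learn defaults)."""
    from sklearn.tree import DecisionTreeClassifier

    return lambda: DecisionTreeClassifier(random_state=seed)


def forest_learner_factory(seed: int = 0) -> LearnerFactory:
    """Random forest with scikit-learn defaults."""
    from sklearn.ensemble import RandomForestClassifier

    return lambda: RandomForestClassifier(random_state=seed)


def impute_tree(table: DiscreteTable, seed: int = 0) -> DiscreteTable:
    return impute_learner(table, tree_learner_factory(seed))


def impute_forest(table: DiscreteTable, seed: int = 0) -> DiscreteTable:
    return impute_learner(table, forest_learner_factory(seed))


# ---------------------------------------------------------------------------
# neural imputers
# ---------------------------------------------------------------------------

def impute_autoencoder(table: DiscreteTable, config: TrainConfig) -> DiscreteTable:
    """Autoencoder imputation: equal input/output width over the full one-hot
    encoding, trained to reproduce the complete rows; incomplete rows are
    mode-prefilled, passed forward, and only their originally-missing blocks
    are replaced by the decoded reconstruction."""
    _check_imputable(table)
    out = table.copy()
    mask = table.missing_mask
    incomplete = np.nonzero(mask.any(axis=1))[0]
    if incomplete.size == 0:
        return out
    complete = np.nonzero(~mask.any(axis=1))[0]
    if complete.size == 0:
        raise NoDonorError("autoencoder imputation needs complete rows to train on")
    attrs = list(range(table.schema.n_attrs))
    layout = OneHotLayout.from_table(table, attrs)
    X_com = encode_one_hot(table, layout, complete)
    model, _ = train(X_com, X_com, config)
    prefilled = impute_mode(table)
    X_miss = encode_one_hot(prefilled, layout, incomplete)
    recon = forward(model, X_miss)[-1]
    for i, r in enumerate(incomplete):
        miss_attrs = [int(j) for j in np.nonzero(mask[r])[0]]
        cols = np.concatenate(
            [
                np.arange(layout.block_for(j).offset, layout.block_for(j).offset + layout.block_for(j).width)
                for j in miss_attrs
            ]
        )
        sub_layout_scores = recon[i:i + 1, cols]
        codes = _decode_codes(sub_layout_scores, layout, miss_attrs)
        for j, arr in codes.items():
            out.columns[j][r] = arr[0]
    return out


def impute_mlp(table: DiscreteTable, config: TrainConfig) -> DiscreteTable:
    """Plain-MLP imputation: the per-missing-type scheme with momentum forced
    to 0 (vanilla SGD) and no prefilling — each type's model trains on the
    complete rows only."""
    from .imlp import _impute_per_type

    cfg = replace(config, momentum=0.0)
    return _impute_per_type(table, mechanism=None, config=cfg, use_prefill=False)
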
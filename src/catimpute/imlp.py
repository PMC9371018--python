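"""Per-missing-type MLP imputation with momentum training and prefilling.

The scheme decomposes the incomplete rows of a table by *missing type* (the
exact set of simultaneously-missing attributes), then trains one network
per type: the type's observed attributes, one-hot encoded, are the inputs
and its missing attributes are the multi-label outputs.  Before training,
the whole table is *prefilled* — mode fills under MAR/NMAR, frequency-
weighted random fills under MCAR — so that rows of *other* missing types
can also serve as training rows for a type, enlarging the training set
beyond the complete rows.  A row is eligible to train a type's model only
if its originally-missing attributes are disjoint from the type's targets
(the targets must be genuinely observed; the inputs may be prefilled).

Prediction runs each incomplete row through its own type's trained network
and decodes the output blocks by per-block argmax; observed cells are never
altered, and the complete and imputed parts merge back in original row
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import derive_seed
from .data import (
    DiscreteTable,
    MissingType,
    OneHotLayout,
    _decode_codes,
    detect_missing_types,
    encode_one_hot,
)
from .errors import ConfigError, NoDonorError, ReconstructionError, UnimputableTypeError
from .mlp import MLPModel, TrainConfig, forward, train

_PREFILL_MECHANISMS = ("MCAR", "MAR", "NMAR")


def prefill(
    table: DiscreteTable, mechanism: str, seed: int = 0
) -> tuple[DiscreteTable, np.ndarray]:
    """Mechanism-specific provisional fill; returns (complete table, mask).

    Random (frequency-weighted) fills for MCAR, mode fills for MAR and
    NMAR.  The returned mask is the original missing mask, kept for target
    bookkeeping downstream.
    """
    from .baselines import impute_mode, impute_random

    mechanism = mechanism.upper()
    mask = table.missing_mask.copy()
    if mechanism == "MCAR":
        return impute_random(table, seed=seed), mask
    if mechanism in ("MAR", "NMAR"):
        return impute_mode(table), mask
    raise ConfigError(
        f"unknown mechanism {mechanism!r}; expected one of {_PREFILL_MECHANISMS}"
    )


@dataclass
class TypeModel:
    """Trained network for one missing type plus its encoding bookkeeping."""

    missing_type: MissingType
    model: MLPModel
    input_attrs: tuple[int, ...]
    output_attrs: tuple[int, ...]
    input_layout: OneHotLayout
    output_layout: OneHotLayout
    n_training_rows: int


class TypeModelSet:
    """One :class:`TypeModel` per detected missing type, keyed by pattern."""

    def __init__(self, models: dict[tuple[int, ...], TypeModel], mechanism: str | None,
                 config: TrainConfig):
        self.models = models
        self.mechanism = mechanism
        self.config = config

    def __getitem__(self, missing_attrs: tuple[int, ...]) -> TypeModel:
        return self.models[missing_attrs]

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models.values())


def _fit_type_models(
    table: DiscreteTable,
    mechanism: str | None,
    config: TrainConfig,
    use_prefill: bool = True,
) -> tuple[TypeModelSet, DiscreteTable, np.ndarray]:
    """Internal fit; returns (models, prefilled table, original mask).

    ``use_prefill=False`` restricts each type's training rows to the
    complete rows and still prefills for *prediction-time* inputs only
    (an incomplete row's non-target missing slots must hold something).
    """
    mask = table.missing_mask
    types = detect_missing_types(table)
    if not types:
        raise UnimputableTypeError("table has no missing types to fit")
    if not (~mask.any(axis=1)).any():
        raise NoDonorError("fitting needs at least one complete row")
    if use_prefill:
        if mechanism is None:
            raise ConfigError("mechanism tag required when prefilling")
        prefilled, _ = prefill(table, mechanism, seed=derive_seed(config.seed, "prefill"))
    else:
        # Mode prefill only feeds prediction inputs, never training rows.
        from .baselines import impute_mode

        prefilled = impute_mode(table)

    n_attrs = table.schema.n_attrs
    models: dict[tuple[int, ...], TypeModel] = {}
    for t_idx, mt in enumerate(types):
        for j in mt.missing_attrs:
            if table.schema.attributes[j].kind != "categorical":
                raise UnimputableTypeError(
                    f"missing type {mt.missing_attrs} targets non-categorical "
                    f"attribute {table.schema.names[j]!r}"
                )
        input_attrs = tuple(j for j in range(n_attrs) if j not in mt.missing_attrs)
        output_attrs = tuple(mt.missing_attrs)
        input_layout = OneHotLayout.from_table(table, input_attrs)
        output_layout = OneHotLayout.from_table(table, output_attrs)
        target_observed = ~mask[:, list(mt.missing_attrs)].any(axis=1)
        if use_prefill:
            train_rows = np.nonzero(target_observed)[0]
        else:
            train_rows = np.nonzero(~mask.any(axis=1))[0]
        if train_rows.size == 0:
            raise UnimputableTypeError(
                f"missing type {mt.missing_attrs} has no eligible training rows"
            )
        X = encode_one_hot(prefilled, input_layout, train_rows)
        Y = encode_one_hot(prefilled, output_layout, train_rows)
        cfg = TrainConfig(
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            batch_size=config.batch_size,
            epochs=config.epochs,
            hidden=config.hidden,
            seed=derive_seed(config.seed, "type", t_idx),
        )
        model, _ = train(X, Y, cfg)
        assert model.layer_dims[0] == input_layout.total_width
        assert model.layer_dims[-1] == output_layout.total_width
        models[mt.missing_attrs] = TypeModel(
            missing_type=mt,
            model=model,
            input_attrs=input_attrs,
            output_attrs=output_attrs,
            input_layout=input_layout,
            output_layout=output_layout,
            n_training_rows=int(train_rows.size),
        )
    return TypeModelSet(models, mechanism, config), prefilled, mask


def fit_type_models(
    table: DiscreteTable, mechanism: str, config: TrainConfig
) -> TypeModelSet:
    """Detect missing types, prefill, and train one network per type."""
    models, _, _ = _fit_type_models(table, mechanism, config, use_prefill=True)
    return models


def _impute_per_type(
    table: DiscreteTable,
    mechanism: str | None,
    config: TrainConfig,
    use_prefill: bool = True,
) -> DiscreteTable:
    from .baselines import _check_imputable

    _check_imputable(table)
    if table.is_complete:
        return table.copy()
    models, prefilled, mask = _fit_type_models(table, mechanism, config, use_prefill)
    out = table.copy()
    for tm in models:
        rows = list(tm.missing_type.rows)
        X = encode_one_hot(prefilled, tm.input_layout, rows)
        scores = forward(tm.model, X)[-1]
        codes = _decode_codes(scores, tm.output_layout, tm.output_attrs)
        for j, arr in codes.items():
            out.columns[j][rows] = arr
    return out


def impute_isb_imlp(
    table: DiscreteTable, mechanism: str, config: TrainConfig
) -> DiscreteTable:
    """Full scheme: type decomposition, mechanism-specific prefill,
    per-type momentum-trained networks, prediction and reconstruction.

    Deterministic given (table, mechanism, config.seed); observed cells are
    returned untouched.
    """
    return _impute_per_type(table, mechanism, config, use_prefill=True)


def reconstruct(dcom: DiscreteTable, dmiss_imputed: DiscreteTable) -> DiscreteTable:
    """Merge the complete part and the imputed part back into one table in
    the original row order (row identities must be disjoint)."""
    if dcom.schema != dmiss_imputed.schema:
        raise ReconstructionError("parts have different schemas")
    ids = np.concatenate([dcom.row_ids, dmiss_imputed.row_ids])
    if len(np.unique(ids)) != len(ids):
        raise ReconstructionError("row identities of the parts overlap")
    order = np.argsort(ids, kind="stable")
    cols = [
        np.concatenate([a, b])[order]
        for a, b in zip(dcom.columns, dmiss_imputed.columns)
    ]
    return DiscreteTable(dcom.schema, cols, row_ids=ids[order])
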
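"""Synthetic complete categorical datasets with known dependence structure.

Two generators stand in for small UCI-style classification tables (a few
hundred to a couple of thousand rows, a handful of mostly categorical
attributes, 2-5 classes) so that amputation, the imputers, and the full
benchmark run without any download:

* :func:`gen_latent_class` — a latent-class mixture: each row draws a
  latent class, each attribute equals the class's modal category with
  probability ``1 - noise`` (else uniform over the *other* categories), and
  the class column is the latent class itself.  Attributes are therefore
  mutually dependent through the class, which is exactly what gives
  model-based imputation an edge over the per-column mode.
* :func:`gen_functional` — a two-attribute table where A2 is a fixed
  mapping of A1, optionally corrupted uniformly at rate ``noise``; the
  noise-free case makes imputation accuracy exactly measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import Attribute, CategoricalSchema, DiscreteTable
from .errors import ConfigError


@dataclass
class LatentClassSpec:
    """Parameters of the latent-class generator.

    ``modal`` maps (class, attribute) to the class's modal category code;
    by default class ``c`` gets modal category ``(c + a) % domain_size`` in
    attribute ``a``, which keeps class profiles distinct whenever the
    domain is at least as large as the class count.
    """

    n_rows: int = 1000
    n_attrs: int = 6
    domain_sizes: int | Sequence[int] = 4
    n_classes: int = 4
    weights: Sequence[float] | None = None
    modal: np.ndarray | None = None  # (n_classes, n_attrs) category codes
    noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_attrs < 1 or self.n_classes < 1:
            raise ConfigError("n_rows, n_attrs and n_classes must be >= 1")
        if not 0.0 <= self.noise < 1.0:
            raise ConfigError(f"noise must lie in [0, 1), got {self.noise}")
        if isinstance(self.domain_sizes, int):
            self.domain_sizes = (self.domain_sizes,) * self.n_attrs
        else:
            self.domain_sizes = tuple(int(d) for d in self.domain_sizes)
        if len(self.domain_sizes) != self.n_attrs or any(d < 2 for d in self.domain_sizes):
            raise ConfigError("need one domain size >= 2 per attribute")
        if self.weights is None:
            self.weights = (1.0 / self.n_classes,) * self.n_classes
        w = np.asarray(self.weights, dtype=float)
        if len(w) != self.n_classes or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("mixture weights must be non-negative and sum to 1")
        if self.modal is None:
            self.modal = np.array(
                [
                    [(c + a) % d for a, d in enumerate(self.domain_sizes)]
                    for c in range(self.n_classes)
                ],
                dtype=np.int32,
            )
        else:
            self.modal = np.asarray(self.modal, dtype=np.int32)
            if self.modal.shape != (self.n_classes, self.n_attrs):
                raise ConfigError("modal must have shape (n_classes, n_attrs)")
            for a, d in enumerate(self.domain_sizes):
                if (self.modal[:, a] < 0).any() or (self.modal[:, a] >= d).any():
                    raise ConfigError("modal categories must lie within domains")


def _latent_schema(spec: LatentClassSpec) -> CategoricalSchema:
    attrs = [
        Attribute(
            name=f"A{a + 1}",
            domain=tuple(f"c{v}" for v in range(spec.domain_sizes[a])),
        )
        for a in range(spec.n_attrs)
    ]
    attrs.append(
        Attribute(
            name="class",
            domain=tuple(f"k{c}" for c in range(spec.n_classes)),
            role="class",
        )
    )
    return CategoricalSchema(attrs)


def gen_latent_class(spec: LatentClassSpec) -> DiscreteTable:
    """Draw a complete latent-class table; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    z = rng.choice(spec.n_classes, size=spec.n_rows, p=np.asarray(spec.weights))
    cols: list[np.ndarray] = []
    for a, d in enumerate(spec.domain_sizes):
        col = spec.modal[z, a].astype(np.int32).copy()
        corrupt = rng.random(spec.n_rows) < spec.noise
        if corrupt.any():
            # uniform over the d-1 categories other than the modal one
            alt = rng.integers(0, d - 1, size=int(corrupt.sum())).astype(np.int32)
            modal_here = col[corrupt]
            alt = np.where(alt >= modal_here, alt + 1, alt)
            col[corrupt] = alt
        cols.append(col)
    cols.append(z.astype(np.int32))
    return DiscreteTable(_latent_schema(spec), cols)


def gen_functional(
    n_rows: int,
    domain_size: int = 4,
    mapping: Mapping[int, int] | Sequence[int] | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> DiscreteTable:
    """Two dependent attributes: A1 uniform, A2 = mapping(A1) up to noise.

    ``mapping`` must be total on the driver domain (default: identity).
    Corruption replaces A2 with a uniform draw over the *whole* domain with
    probability ``noise``, so the expected agreement with the mapping is
    ``1 - noise + noise / domain_size``.  The binary class column is the
    fixed rule "A1 in the upper half of its domain".
    """
    if n_rows < 1 or domain_size < 2:
        raise ConfigError("need n_rows >= 1 and domain_size >= 2")
    if not 0.0 <= noise < 1.0:
        raise ConfigError(f"noise must lie in [0, 1), got {noise}")
    if mapping is None:
        map_arr = np.arange(domain_size, dtype=np.int32)
    else:
        if isinstance(mapping, Mapping):
            try:
                map_arr = np.array([mapping[v] for v in range(domain_size)], dtype=np.int32)
            except KeyError as exc:
                raise ConfigError(f"mapping is not total on the driver domain: {exc}") from None
        else:
            map_arr = np.asarray(list(mapping), dtype=np.int32)
            if len(map_arr) != domain_size:
                raise ConfigError("mapping is not total on the driver domain")
    if (map_arr < 0).any() or (map_arr >= domain_size).any():
        raise ConfigError("mapping values must lie within the domain")
    rng = np.random.default_rng(seed)
    a1 = rng.integers(0, domain_size, size=n_rows).astype(np.int32)
    a2 = map_arr[a1].copy()
    corrupt = rng.random(n_rows) < noise
    if corrupt.any():
        a2[corrupt] = rng.integers(0, domain_size, size=int(corrupt.sum())).astype(np.int32)
    label = (a1 >= domain_size // 2).astype(np.int32)
    dom = tuple(f"c{v}" for v in range(domain_size))
    schema = CategoricalSchema(
        [
            Attribute(name="A1", domain=dom),
            Attribute(name="A2", domain=dom),
            Attribute(name="class", domain=("neg", "pos"), role="class"),
        ]
    )
    return DiscreteTable(schema, [a1, a2, label])
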
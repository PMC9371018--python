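"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops over cells, independent of the
package's vectorized implementations, so oracle agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

from catimpute.data import MISSING, DiscreteTable


def brute_missing_groups(table: DiscreteTable) -> dict[tuple[int, ...], list[int]]:
    """Group rows by their frozen set of missing attribute indices."""
    groups: dict[tuple[int, ...], list[int]] = {}
    for r in range(table.n_rows):
        missing = tuple(
            j for j in range(table.schema.n_attrs) if table.cell(r, j) is MISSING
        )
        if missing:
            groups.setdefault(missing, []).append(r)
    return groups


def brute_mode_fill(table: DiscreteTable) -> dict[tuple[int, int], str]:
    """Expected mode fills: frequency count per attribute, domain-order ties."""
    fills = {}
    for j in table.schema.categorical_indices:
        dom = table.schema.domain(j)
        counts = {lab: 0 for lab in dom}
        for r in range(table.n_rows):
            v = table.cell(r, j)
            if v is not MISSING:
                counts[v] += 1
        best = max(dom, key=lambda lab: (counts[lab], -dom.index(lab)))
        for r in range(table.n_rows):
            if table.cell(r, j) is MISSING:
                fills[(r, j)] = best
    return fills


def brute_hamming(a, b) -> int:
    total = 0
    for x, y in zip(a, b):
        total += 1 if x != y else 0
    return total


def _row_distance(table: DiscreteTable, r: int, donor: int) -> int:
    """Hamming distance over the one-hot coding of r's observed categorical attrs."""
    d = 0
    for j in table.schema.categorical_indices:
        v = table.cell(r, j)
        if v is MISSING:
            continue
        dom = table.schema.domain(j)
        a = [1 if lab == v else 0 for lab in dom]
        b = [1 if lab == table.cell(donor, j) else 0 for lab in dom]
        d += brute_hamming(a, b)
    return d


def brute_hotdeck_fill(table: DiscreteTable) -> dict[tuple[int, int], str]:
    complete = [
        r for r in range(table.n_rows)
        if all(table.cell(r, j) is not MISSING for j in range(table.schema.n_attrs))
    ]
    fills = {}
    for r in range(table.n_rows):
        missing = [
            j for j in range(table.schema.n_attrs) if table.cell(r, j) is MISSING
        ]
        if not missing:
            continue
        best, best_d = None, None
        for donor in complete:  # ascending index: ties keep the first
            d = _row_distance(table, r, donor)
            if best_d is None or d < best_d:
                best, best_d = donor, d
        for j in missing:
            fills[(r, j)] = table.cell(best, j)
    return fills


def brute_knn_fill(table: DiscreteTable, k: int) -> dict[tuple[int, int], str]:
    complete = [
        r for r in range(table.n_rows)
        if all(table.cell(r, j) is not MISSING for j in range(table.schema.n_attrs))
    ]
    fills = {}
    for r in range(table.n_rows):
        missing = [
            j for j in range(table.schema.n_attrs) if table.cell(r, j) is MISSING
        ]
        if not missing:
            continue
        dists = [(_row_distance(table, r, donor), donor) for donor in complete]
        dists.sort(key=lambda t: (t[0], t[1]))
        nn = dists[: min(k, len(dists))]
        for j in missing:
            dom = table.schema.domain(j)
            weight = {lab: 0.0 for lab in dom}
            count = {lab: 0 for lab in dom}
            for d, donor in nn:
                lab = table.cell(donor, j)
                weight[lab] += 1.0 / (1.0 + d)
                count[lab] += 1
            fills[(r, j)] = max(
                dom, key=lambda lab: (weight[lab], count[lab], -dom.index(lab))
            )
    return fills


def random_table(
    rng: np.random.Generator,
    n_rows: int,
    n_attrs: int,
    max_domain: int = 4,
    missing_frac: float = 0.0,
    with_class: bool = True,
) -> DiscreteTable:
    """A random schema-conformant table, optionally with MCAR-style holes."""
    from catimpute.data import Attribute, CategoricalSchema

    attrs = []
    for j in range(n_attrs):
        d = int(rng.integers(2, max_domain + 1))
        attrs.append(Attribute(name=f"A{j + 1}", domain=tuple(f"v{i}" for i in range(d))))
    if with_class:
        attrs.append(Attribute(name="class", domain=("y0", "y1"), role="class"))
    schema = CategoricalSchema(attrs)
    cols = []
    for j, a in enumerate(schema.attributes):
        codes = rng.integers(0, len(a.domain), size=n_rows).astype(np.int32)
        if missing_frac > 0 and a.role == "feature":
            holes = rng.random(n_rows) < missing_frac
            codes[holes] = -1
        cols.append(codes)
    if missing_frac > 0:
        # keep at least one complete row so donor methods stay defined
        for j in range(len(cols)):
            if cols[j][0] == -1:
                cols[j][0] = 0
    return DiscreteTable(schema, cols)


def fill_accuracy(
    imputed: DiscreteTable, truth: DiscreteTable, mask: np.ndarray
) -> float:
    """Fraction of originally-missing cells imputed to their true category."""
    total, correct = 0, 0
    for j in truth.schema.categorical_indices:
        m = mask[:, j]
        total += int(m.sum())
        correct += int((imputed.columns[j][m] == truth.columns[j][m]).sum())
    return correct / total if total else float("nan")
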
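"""Amputation: simulate MCAR, MAR and NMAR missingness on a complete table.

The three mechanisms follow the standard taxonomy: MCAR deletes cells
independently of all data; MAR deletes with probability tied to an
*observed* conditioning attribute; NMAR ties deletion to the deleted cell's
own value.  Since the taxonomy defines the mechanisms but not a generator,
the generator here is a design choice: per eligible attribute exactly
``round(rate * n_rows)`` cells are deleted by weighted sampling without
replacement, where rows whose driver value falls in the driver attribute's
high-frequency half carry ``dependence_odds`` times the weight of the rest.
Exact per-attribute budgets (rather than Bernoulli draws) make the realized
rate deterministic and testable.

A row-protection rule guarantees every row keeps at least one observed
eligible attribute, so no row becomes fully unobservable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import DiscreteTable
from .errors import ConfigError, MissingCellError

MECHANISMS = ("MCAR", "MAR", "NMAR")

#: Standard experimental grid of missing rates: 10% to 30% in steps of 5%.
RATE_GRID = (0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass
class AmputationConfig:
    """Settings for one amputation run.

    ``rate`` is the fraction of cells deleted *per eligible attribute*
    (categorical, non-class).  ``dependence_odds`` is the weight ratio
    between high-frequency-half rows and the rest for MAR/NMAR (1 would
    degenerate to MCAR).  ``conditioning`` optionally maps each target
    attribute index to the attribute that drives its MAR missingness; by
    default each eligible attribute conditions on the next one cyclically.
    """

    mechanism: str
    rate: float
    dependence_odds: float = 9.0
    conditioning: dict[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.mechanism = self.mechanism.upper()
        if self.mechanism not in MECHANISMS:
            raise ConfigError(f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}")
        if not 0.0 <= self.rate <= 0.5:
            raise ConfigError(f"rate must lie in [0, 0.5], got {self.rate}")
        if self.dependence_odds < 1.0:
            raise ConfigError(f"dependence_odds must be >= 1, got {self.dependence_odds}")
        if self.conditioning is not None:
            for tgt, cond in self.conditioning.items():
                if tgt == cond:
                    raise ConfigError(
                        f"MAR conditioning attribute must differ from the target "
                        f"(attribute {tgt + 1} conditions on itself)"
                    )


def _budget(rate: float, n: int) -> int:
    """Half-up rounding of the per-attribute deletion count."""
    return int(np.floor(rate * n + 0.5))


def _conditioning_map(eligible: tuple[int, ...], config: AmputationConfig) -> dict[int, int]:
    mapping = {}
    for i, j in enumerate(eligible):
        mapping[j] = eligible[(i + 1) % len(eligible)]
    if config.conditioning:
        mapping.update(config.conditioning)
    for tgt, cond in mapping.items():
        if tgt == cond:
            raise ConfigError("conditioning attribute equals target attribute")
    return mapping


def _high_frequency_half(codes: np.ndarray, domain_size: int) -> np.ndarray:
    """Boolean membership of each category in the high-frequency half.

    Categories are taken most frequent first (ties by domain order) until
    they accumulate at least 50% of the mass.
    """
    counts = np.bincount(codes[codes >= 0], minlength=domain_size)
    order = np.lexsort((np.arange(domain_size), -counts))
    member = np.zeros(domain_size, dtype=bool)
    total = counts.sum()
    acc = 0
    for c in order:
        member[c] = True
        acc += counts[c]
        if acc * 2 >= total:
            break
    return member


def ampute(table: DiscreteTable, config: AmputationConfig) -> DiscreteTable:
    """Delete cells from a complete table to plant the configured mechanism.

    For each eligible attribute exactly ``round(rate * n_rows)`` cells are
    set MISSING; the class column and numeric attributes are never touched.
    Deterministic given ``config.seed``.
    """
    if not table.is_complete:
        raise MissingCellError("ampute requires a complete table")
    eligible = table.schema.eligible_indices
    if len(eligible) < 2:
        raise ConfigError(
            f"amputation needs at least 2 eligible attributes, found {len(eligible)}"
        )
    n = table.n_rows
    k = _budget(config.rate, n)
    out = table.copy()
    if k == 0:
        return out
    rng = np.random.default_rng(config.seed)
    cond_map = _conditioning_map(eligible, config)
    n_elig = len(eligible)
    masked_count = np.zeros(n, dtype=np.int64)

    for j in eligible:
        if config.mechanism == "MCAR":
            weights = np.ones(n)
        else:
            driver = cond_map[j] if config.mechanism == "MAR" else j
            codes = table.columns[driver]
            member = _high_frequency_half(codes, len(table.schema.domain(driver)))
            weights = np.where(member[codes], config.dependence_odds, 1.0)
        # Weighted sampling without replacement via exponential keys; rows
        # that would lose their last observed eligible cell are skipped
        # (the bounded re-draw realized as a scan in key order).
        keys = rng.exponential(size=n) / weights
        order = np.argsort(keys, kind="stable")
        chosen: list[int] = []
        for r in order:
            if masked_count[r] >= n_elig - 1:
                continue
            chosen.append(int(r))
            if len(chosen) == k:
                break
        if len(chosen) < k:
            raise ConfigError(
                f"row protection exhausted candidates for attribute "
                f"{table.schema.names[j]!r}: cannot delete {k} cells"
            )
        idx = np.array(chosen, dtype=np.int64)
        out.columns[j][idx] = -1
        masked_count[idx] += 1
    return out


def realized_missingness(table: DiscreteTable) -> tuple[dict[str, float], float]:
    """Exact missing fractions per eligible attribute and overall."""
    eligible = table.schema.eligible_indices
    n = table.n_rows
    per_attr: dict[str, float] = {}
    total_missing = 0
    for j in eligible:
        m = int((table.columns[j] < 0).sum())
        per_attr[table.schema.names[j]] = m / n if n else 0.0
        total_missing += m
    overall = total_missing / (n * len(eligible)) if n and eligible else 0.0
    return per_attr, overall


@dataclass(frozen=True)
class DiagnosticResult:
    """Chi-squared independence test between a mask and its driver values."""

    statistic: float
    pvalue: float
    dof: int


def mechanism_diagnostic(
    original: DiscreteTable, amputed: DiscreteTable, config: AmputationConfig
) -> dict[str, DiagnosticResult | None]:
    """Test, per eligible attribute, whether the mask depends on its driver.

    The driver is the conditioning attribute's pre-amputation value for MAR
    (and, as an arbitrary observed probe, for MCAR) and the cell's own
    pre-amputation value for NMAR.  Degenerate contingency tables (a zero
    margin, e.g. at rate 0) yield ``None`` rather than an error.
    """
    if not original.is_complete:
        raise MissingCellError("diagnostic requires the complete original table")
    eligible = original.schema.eligible_indices
    cond_map = _conditioning_map(eligible, config)
    results: dict[str, DiagnosticResult | None] = {}
    for j in eligible:
        mask = (amputed.columns[j] < 0).astype(np.int64)
        driver_attr = j if config.mechanism == "NMAR" else cond_map[j]
        driver = original.columns[driver_attr]
        dom = len(original.schema.domain(driver_attr))
        contingency = np.zeros((2, dom), dtype=np.int64)
        np.add.at(contingency, (mask, driver), 1)
        contingency = contingency[:, contingency.sum(axis=0) > 0]
        if contingency.shape[1] < 2 or (contingency.sum(axis=1) == 0).any():
            results[original.schema.names[j]] = None
            continue
        chi2 = stats.chi2_contingency(contingency)
        results[original.schema.names[j]] = DiagnosticResult(
            statistic=float(chi2.statistic), pvalue=float(chi2.pvalue), dof=int(chi2.dof)
        )
    return results
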
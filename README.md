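# catimpute

Imputation of **discrete (categorical) missing data** with per-missing-type
multilayer perceptrons, plus the full experimental apparatus around it:
MCAR/MAR/NMAR amputation simulators, eight classical baseline imputers, and
a repeated cross-validation benchmark that scores imputation by downstream
classification accuracy.

It is aimed at practitioners and methods researchers working with small
UCI-style tabular classification data (a few hundred to a few thousand
rows, mostly categorical attributes), where most imputation tooling
assumes continuous variables.

## The method

A table with missing cells splits into its complete rows `Dcom` and
incomplete rows `Dmiss`. Each distinct pattern of simultaneously-missing
attributes among the incomplete rows is a *missing type*
`mt_i`, collected in `MT = {mt_1, ..., mt_n}`.

For each missing type, one dense network is trained: the one-hot encoding
of the attributes *outside* the type is the input, the one-hot blocks of
the attributes *inside* it are the multi-label output (rectifier hidden
layers, sigmoid outputs, binary cross-entropy). Training uses momentum
gradient descent,

    v ← β·v + (1−β)·∇        (velocity, zero at the start)
    ω ← ω − α·v

with α = 0.001, β = 0.9, batch 256 and three hidden layers of 32 units by
default. Before training, the table is *prefilled* — frequency-weighted
random fills when the data are MCAR, per-column mode fills under MAR/NMAR —
so that rows of other missing types can also serve as training rows for a
type (their targets are genuinely observed; only their inputs contain
prefilled values). Each incomplete row is then predicted by its own type's
network, the output blocks are decoded by per-block argmax, and only the
originally missing cells are written back.

Baselines: mode, frequency-weighted random, hot-deck and k-NN over the
Hamming distance `HD = Σ_i (A_i ⊕ B_i)` on one-hot encodings, CART and
random-forest classification imputers (delegated to scikit-learn), a
reconstruction autoencoder, and a plain MLP (no momentum, no prefill) that
isolates exactly what the full scheme adds.

## Worked example

```python
import numpy as np
from catimpute import (
    AmputationConfig, LatentClassSpec, TrainConfig,
    ampute, gen_latent_class, impute_isb_imlp, impute_mode, realized_missingness,
)

table = gen_latent_class(LatentClassSpec(n_rows=500, n_attrs=6, noise=0.1, seed=7))
holed = ampute(table, AmputationConfig(mechanism="MAR", rate=0.2, seed=8))
per_attr, overall = realized_missingness(holed)
print(f"overall missing fraction: {overall:.3f}")

mask = holed.missing_mask
filled = impute_isb_imlp(holed, "MAR", TrainConfig(epochs=2000, seed=9))
mode_filled = impute_mode(holed)

def fill_acc(imputed):
    tot = cor = 0
    for j in table.schema.eligible_indices:
        m = mask[:, j]
        tot += m.sum()
        cor += (imputed.columns[j][m] == table.columns[j][m]).sum()
    return cor / tot

print(f"IMLP fill accuracy: {fill_acc(filled):.3f}")
print(f"mode fill accuracy: {fill_acc(mode_filled):.3f}")
```

Output:

```
overall missing fraction: 0.200
IMLP fill accuracy: 0.313
mode fill accuracy: 0.112
```

The generator plants a latent-class dependence between attributes (each
attribute is the class's modal category up to 10% noise), and the MAR
amputation preferentially deletes cells in rows whose neighbouring
attribute takes a frequent value. Exactly 20% of each eligible attribute
is deleted. The per-type networks exploit the inter-attribute dependence
and recover 31% of the deleted cells at this short 2000-epoch budget,
against 11% for the per-column mode (chance is 25% for balanced
4-category attributes, but the MAR mask concentrates deletions on rows
where the mode is *wrong*, which is why mode falls below chance while the
model-based fills stay above it).

## Command line

```bash
catimpute synth --n-rows 1000 --out data.csv --schema-out schema.json
catimpute ampute --mechanism mar --rate 0.2 --seed 1 \
    --in data.csv --schema schema.json --out holed.csv
catimpute impute --method imlp --mechanism mar --seed 2 \
    --in holed.csv --schema schema.json --out filled.csv
catimpute benchmark --config bench.yaml --seed 3 --out results.csv
```

Input is RFC-4180 CSV with a header row and a configurable missing
sentinel (default `?`); the schema is a JSON list of attributes with
ordered category domains and an optional class column. See
`docs/methods.md` for the model details, parameter meanings and the
design decisions.

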
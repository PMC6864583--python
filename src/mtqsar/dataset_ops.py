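"""Curation, k-means modelling/validation division, random splits, pre-treatment.

The modelling/external-validation division follows the chemometric k-MCA
recipe: k-means on the z-standardised descriptors with the class label
appended as one extra standardised coordinate, then a fixed fraction of every
cluster is sampled into the external validation set, so both sets span the
same chemobiological space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .boxjenkins import DataRecord
from .chem_core import write_smiles


class SplitError(ValueError):
    pass


@dataclass
class SplitResult:
    """Modelling / validation division plus the sub-training / test sub-split.

    Invariants: validation ∩ modelling = ∅; sub_training ∪ test = modelling;
    modelling ∪ validation covers every record.
    """

    modelling: list[str]
    validation: list[str]
    sub_training: list[str] = field(default_factory=list)
    test: list[str] = field(default_factory=list)
    seed: int | None = None
    cluster_assignments: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.modelling) & set(self.validation):
            raise SplitError("modelling and validation sets overlap")
        if self.sub_training or self.test:
            if set(self.sub_training) | set(self.test) != set(self.modelling):
                raise SplitError("sub_training ∪ test must equal modelling")
            if set(self.sub_training) & set(self.test):
                raise SplitError("sub_training and test overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitResult":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


# -- curation ------------------------------------------------------------------


def deduplicate(records: Sequence[DataRecord]) -> tuple[list[DataRecord], pd.DataFrame]:
    """One record per (canonical structure, bt, me); ties resolved by potency.

    When the same structure was assayed more than once under the same
    condition the most potent (lowest nM) measurement is kept.  Returns the
    curated records and a removal report.
    """
    best: dict[tuple[str, str, str], DataRecord] = {}
    removed = []
    for r in records:
        structure = write_smiles(r.graph) if r.graph is not None else r.compound_id
        key = (structure, r.condition.bt, r.condition.me)
        cur = best.get(key)
        if cur is None:
            best[key] = r
        else:
            keep, drop = (r, cur) if (r.activity_nM or np.inf) < (cur.activity_nM or np.inf) else (cur, r)
            best[key] = keep
            removed.append(
                {"compound_id": drop.compound_id, "bt": key[1], "me": key[2], "activity_nM": drop.activity_nM}
            )
    return list(best.values()), pd.DataFrame(removed, columns=["compound_id", "bt", "me", "activity_nM"])


# -- k-MCA division ------------------------------------------------------------


def _standardise(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def kmca_split(
    D: pd.DataFrame,
    labels: Sequence[int],
    k: int = 10,
    max_iter: int = 500,
    validation_fraction: float = 0.30,
    seed: int | None = None,
) -> SplitResult:
    """k-means cluster analysis division into modelling and validation sets.

    Features are the z-standardised descriptors with the standardised class
    label appended; Euclidean k-means with ``k`` clusters and up to
    ``max_iter`` iterations.  From each cluster, round(fraction × size)
    records are sampled without replacement into the validation set.
    """
    if len(D) < k:
        raise SplitError(f"need at least k={k} rows, got {len(D)}")
    y = np.asarray(labels, dtype=float)
    if y.shape[0] != len(D):
        raise SplitError("labels length mismatch")
    X = _standardise(np.column_stack([D.values, y]))
    rng = np.random.default_rng(seed)
    km = KMeans(n_clusters=k, max_iter=max_iter, n_init=10, random_state=int(rng.integers(2**31)))
    assign = km.fit_predict(X)
    ids = np.array(D.index.astype(str))
    validation: list[str] = []
    for c in range(k):
        members = ids[assign == c]
        n_val = int(round(validation_fraction * len(members)))
        if n_val > 0:
            validation.extend(rng.choice(members, size=n_val, replace=False))
    vset = set(validation)
    modelling = [i for i in ids if i not in vset]
    res = SplitResult(
        modelling=modelling,
        validation=sorted(validation),
        seed=seed,
        cluster_assignments={i: int(c) for i, c in zip(ids, assign)},
        parameters={"k": k, "max_iter": max_iter, "validation_fraction": validation_fraction},
    )
    res.validate()
    return res


def sub_split(
    modelling: Sequence[str],
    train_fraction: float = 0.8,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """Random division of the modelling set into sub-training and test ids."""
    if len(modelling) < 5:
        raise SplitError("modelling set too small to sub-split")
    rng = np.random.default_rng(seed)
    ids = np.array(modelling)
    rng.shuffle(ids)
    n_train = int(round(train_fraction * len(ids)))
    return list(ids[:n_train]), list(ids[n_train:])


# -- descriptor pre-treatment --------------------------------------------------


def pretreat(
    D: pd.DataFrame,
    var_min: float = 0.001,
    r2_max: float = 0.85,
) -> tuple[pd.DataFrame, dict]:
    """Drop near-constant then pairwise-collinear descriptor columns.

    First pass removes columns with variance below ``var_min``; second pass
    scans the surviving column pairs in canonical order and drops the later
    member of any pair with squared Pearson correlation above ``r2_max``
    (keep-earlier is the deterministic tie-break).  Idempotent.
    """
    if D.shape[1] < 2:
        raise SplitError("pre-treatment needs at least two columns")
    variances = D.var(axis=0, ddof=1)
    low_var = [c for c in D.columns if variances[c] < var_min]
    kept = [c for c in D.columns if c not in set(low_var)]
    if not kept:
        raise SplitError("all columns removed by variance filter")
    sub = D[kept]
    corr2 = np.square(np.corrcoef(sub.values, rowvar=False))
    dropped_corr: list[str] = []
    alive = np.ones(len(kept), dtype=bool)
    for i in range(len(kept)):
        if not alive[i]:
            continue
        for j in range(i + 1, len(kept)):
            if alive[j] and corr2[i, j] > r2_max:
                alive[j] = False
                dropped_corr.append(kept[j])
    survivors = [c for c, a in zip(kept, alive) if a]
    if not survivors:
        raise SplitError("all columns removed by correlation filter")
    report = {
        "n_input": int(D.shape[1]),
        "n_output": len(survivors),
        "dropped_low_variance": low_var,
        "dropped_correlated": dropped_corr,
        "var_min": var_min,
        "r2_max": r2_max,
    }
    return D[survivors], report
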
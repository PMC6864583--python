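"""Experimental-condition ontology and Box–Jenkins condition-deviation descriptors.

A multi-target dataset annotates every assay record with an experimental
condition c_j → (bt, me): the biological target (here ERK-1 or ERK-2) and the
measure of effectiveness (IC50 or Ki, in nM).  A raw molecular descriptor D_i
says nothing about the condition; the Box–Jenkins moving-average device makes
it condition-aware by replacing it with its deviation from the mean of the
*active* training compounds sharing one condition element:

    Δ(D_i)_e(r) = D_i(r) − mean{ D_i(r') : r' active in training,
                                  element_e(r') = element_e(r) }

applied once per element (bt and me), doubling the column count.  The means
are frozen at training time; asking for a condition value never seen in
training is a hard error rather than a silent zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_core import MolecularGraph

ACTIVE, INACTIVE = 1, -1
DEFAULT_CUTOFF_NM = 500.0

ELEMENTS = ("bt", "me")


class ConditionError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentalCondition:
    """One assay context: biological target and measure of effectiveness."""

    bt: str
    me: str

    def __post_init__(self):
        if not self.bt or not self.me:
            raise ConditionError("condition elements must be non-empty")

    def element(self, name: str) -> str:
        if name not in ELEMENTS:
            raise ConditionError(f"unknown condition element {name!r}")
        return getattr(self, name)


#: the four assay conditions of the ERK-1/2 study design
DEFAULT_CONDITIONS: dict[str, ExperimentalCondition] = {
    "c1": ExperimentalCondition("ERK-1", "IC50"),
    "c2": ExperimentalCondition("ERK-1", "Ki"),
    "c3": ExperimentalCondition("ERK-2", "IC50"),
    "c4": ExperimentalCondition("ERK-2", "Ki"),
}


@dataclass
class DataRecord:
    """One compound–condition assay record."""

    compound_id: str
    condition: ExperimentalCondition
    activity_nM: float | None = None
    label: int | None = None
    graph: MolecularGraph | None = None

    @property
    def record_id(self) -> str:
        return f"{self.compound_id}|{self.condition.bt}|{self.condition.me}"

    def with_label(self, cutoff_nM: float = DEFAULT_CUTOFF_NM) -> "DataRecord":
        return DataRecord(
            self.compound_id,
            self.condition,
            self.activity_nM,
            label_activity(self.activity_nM, cutoff_nM),
            self.graph,
        )


def label_activity(activity_nM: float | None, cutoff_nM: float = DEFAULT_CUTOFF_NM) -> int:
    """+1 (active) iff activity ≤ cutoff; the 500 nM boundary is inclusive."""
    if activity_nM is None or not np.isfinite(activity_nM) or activity_nM <= 0:
        raise ConditionError(f"activity must be a positive concentration, got {activity_nM!r}")
    return ACTIVE if activity_nM <= cutoff_nM else INACTIVE


# -- condition averages --------------------------------------------------------


@dataclass
class ConditionAverages:
    """Per-descriptor means over ACTIVE training records, by element value."""

    element: str
    means: dict[str, pd.Series]
    counts: dict[str, int]

    def mean_for(self, value: str) -> pd.Series:
        if value not in self.means:
            raise ConditionError(
                f"element {self.element}={value!r} was never seen among training actives"
            )
        return self.means[value]

    def probability(self, value: str) -> float:
        total = sum(self.counts.values())
        return self.counts[value] / total if total else 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "element": self.element,
            "counts": self.counts,
            "means": {v: s.to_dict() for v, s in self.means.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConditionAverages":
        payload = json.loads(Path(path).read_text())
        return cls(
            element=payload["element"],
            means={v: pd.Series(d) for v, d in payload["means"].items()},
            counts={v: int(c) for v, c in payload["counts"].items()},
        )


def build_condition_averages(
    D: pd.DataFrame,
    records: Sequence[DataRecord],
    element: str,
) -> ConditionAverages:
    """Arithmetic descriptor means over training actives, per element value.

    ``D`` is indexed by record id and must cover every record.  An element
    value with zero actives is an error naming the value — the deviation for
    that condition would be undefined.
    """
    if element not in ELEMENTS:
        raise ConditionError(f"unknown condition element {element!r}")
    groups: dict[str, list[str]] = {}
    for r in records:
        groups.setdefault(r.condition.element(element), [])
        if r.label == ACTIVE:
            groups[r.condition.element(element)].append(r.record_id)
    means, counts = {}, {}
    for value, rids in groups.items():
        if not rids:
            raise ConditionError(f"no active training records for {element}={value!r}")
        means[value] = D.loc[rids].mean(axis=0)
        counts[value] = len(rids)
    return ConditionAverages(element, means, counts)


def deviation_column(raw_name: str, element: str) -> str:
    return f"D[{raw_name}]_{element}"


def raw_column(deviation_name: str) -> tuple[str, str]:
    """Inverse of :func:`deviation_column` → (raw descriptor name, element)."""
    element = deviation_name[-2:]
    if not (
        deviation_name.startswith("D[")
        and element in ELEMENTS
        and deviation_name.endswith(f"]_{element}")
    ):
        raise ConditionError(f"not a deviation column name: {deviation_name!r}")
    return deviation_name[2:-4], element


def deviation_descriptors(
    D: pd.DataFrame,
    averages: Mapping[str, ConditionAverages],
    records: Sequence[DataRecord],
    probability_weighted: bool = False,
) -> pd.DataFrame:
    """Box–Jenkins deviation matrix: one Δ column per element per raw column.

    ``averages`` must have been built on the training partition only; this
    function never recomputes means.  With ``probability_weighted`` the
    deviation is additionally multiplied by the training-active prevalence
    p(element value), a sensitivity-analysis variant.
    """
    rids = [r.record_id for r in records]
    sub = D.loc[rids]
    blocks = []
    for element in ELEMENTS:
        if element not in averages:
            raise ConditionError(f"no averages for element {element!r}")
        avg = averages[element]
        mu = np.empty_like(sub.values)
        weight = np.ones(len(records))
        for i, r in enumerate(records):
            value = r.condition.element(element)
            mu[i, :] = avg.mean_for(value).loc[sub.columns].values
            if probability_weighted:
                weight[i] = avg.probability(value)
        block = (sub.values - mu) * weight[:, None]
        blocks.append(
            pd.DataFrame(
                block,
                index=rids,
                columns=[deviation_column(c, element) for c in sub.columns],
            )
        )
    return pd.concat(blocks, axis=1)


# -- dataset table IO ----------------------------------------------------------


def records_to_frame(records: Sequence[DataRecord]) -> pd.DataFrame:
    from .chem_core import write_smiles

    return pd.DataFrame(
        {
            "id": [r.compound_id for r in records],
            "smiles": [write_smiles(r.graph) if r.graph else "" for r in records],
            "bt": [r.condition.bt for r in records],
            "me": [r.condition.me for r in records],
            "activity_nM": [r.activity_nM for r in records],
            "label": [r.label for r in records],
        }
    )


def read_dataset_csv(path: str | Path, cutoff_nM: float = DEFAULT_CUTOFF_NM) -> list[DataRecord]:
    """Read the standard dataset table (id, smiles, bt, me, activity_nM[, label])."""
    from .chem_core import parse_smiles

    df = pd.read_csv(path)
    required = {"id", "smiles", "bt", "me", "activity_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ConditionError(f"dataset table missing columns: {sorted(missing)}")
    graphs: dict[str, MolecularGraph] = {}
    records = []
    for _, row in df.iterrows():
        cid = str(row["id"])
        if cid not in graphs:
            graphs[cid] = parse_smiles(str(row["smiles"]), id=cid, keep_largest_fragment=True)
        activity = float(row["activity_nM"])
        label = int(row["label"]) if "label" in df.columns and pd.notna(row.get("label")) else label_activity(activity, cutoff_nM)
        records.append(
            DataRecord(
                cid,
                ExperimentalCondition(str(row["bt"]), str(row["me"])),
                activity,
                label,
                graphs[cid],
            )
        )
    return records
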
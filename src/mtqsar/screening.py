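"""Multi-condition virtual screening, consensus hits and drug-likeness.

Every library compound is screened once per experimental condition: its raw
descriptors are computed, each condition's frozen Box–Jenkins deviations are
applied, and the classifier (linear discriminant or random forest) votes
active/inactive.  A *consensus hit* is a compound predicted active under
every screened condition — the stringent multi-condition criterion that cuts
a kinase library down to a shortlist.  Predictions falling outside the
applicability domain are flagged but not removed.

Drug-likeness follows the rule of five: MW < 500 Da, H-bond donors ≤ 5,
H-bond acceptors ≤ 10 (classical N/O counting), logP < 5 (Ghose–Crippen
atomic contributions, i.e. the sum of the HYD property over atoms).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import Descriptors, Lipinski

from .boxjenkins import (
    ACTIVE,
    ConditionAverages,
    ExperimentalCondition,
    deviation_column,
    raw_column,
)
from .chem_core import MolecularGraph, write_smiles
from .descriptors import QuadraticIndexConfig, compute_descriptor_matrix
from .modeling import LinearDiscriminantModel, RandomForestModel
from .validation import applicability_domain


class ScreeningError(ValueError):
    pass


@dataclass
class LipinskiProfile:
    mw: float
    n_hdon: int
    n_hacc: int
    alogp: float
    passes: bool


def lipinski_properties(g: MolecularGraph) -> LipinskiProfile:
    """Rule-of-five profile; MW includes implicit hydrogens."""
    mol = g.to_rdkit()
    mw = float(Descriptors.MolWt(mol))
    n_hdon = int(Lipinski.NumHDonors(mol))  # N/O with >= 1 attached H
    n_hacc = int(Lipinski.NOCount(mol))  # N + O count
    alogp = float(Descriptors.MolLogP(mol))  # sum of Ghose-Crippen atomic contributions
    passes = mw < 500 and n_hdon <= 5 and n_hacc <= 10 and alogp < 5
    return LipinskiProfile(mw, n_hdon, n_hacc, alogp, passes)


@dataclass
class ScreeningResult:
    table: pd.DataFrame  # one row per compound
    conditions: list[str]
    n_cases: int
    n_positive_cases: int

    @property
    def consensus_hits(self) -> list[str]:
        return list(self.table.index[self.table["consensus_hit"]])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="id")


def _deviation_frame_for_condition(
    D_raw: pd.DataFrame,
    cond: ExperimentalCondition,
    averages: Mapping[str, ConditionAverages],
    needed_dev: Sequence[str],
) -> pd.DataFrame:
    cols = {}
    for dev_name in needed_dev:
        rname, element = raw_column(dev_name)
        mean = averages[element].mean_for(cond.element(element))
        if rname not in D_raw.columns or rname not in mean.index:
            raise ScreeningError(f"descriptor {rname!r} unavailable for screening")
        cols[dev_name] = D_raw[rname] - float(mean[rname])
    return pd.DataFrame(cols, index=D_raw.index)


def screen_library(
    library: Sequence[MolecularGraph],
    model: LinearDiscriminantModel | RandomForestModel,
    conditions: Mapping[str, ExperimentalCondition],
    averages: Mapping[str, ConditionAverages],
    descriptor_config: QuadraticIndexConfig | None = None,
    D_raw: pd.DataFrame | None = None,
    ad_train: pd.DataFrame | None = None,
) -> ScreeningResult:
    """Predict every (compound, condition) case and collect consensus hits.

    ``D_raw`` may carry precomputed raw descriptors (indexed by compound id);
    otherwise they are computed here with ``descriptor_config``.  When
    ``ad_train`` (the model's training deviation frame) is given, each
    prediction also receives an applicability-domain flag.
    """
    if isinstance(model, RandomForestModel):
        needed_dev = model.feature_names
    else:
        needed_dev = model.descriptor_names
    if D_raw is None:
        raw_names = sorted({raw_column(n)[0] for n in needed_dev})
        cfg = descriptor_config or QuadraticIndexConfig()
        D_full = compute_descriptor_matrix(library, cfg)
        missing = [n for n in raw_names if n not in D_full.columns]
        if missing:
            raise ScreeningError(f"descriptor config does not produce: {missing[:5]}")
        D_raw = D_full
    ids = list(D_raw.index.astype(str))

    table = pd.DataFrame(index=ids)
    n_positive = 0
    for cname, cond in conditions.items():
        Xdev = _deviation_frame_for_condition(D_raw, cond, averages, needed_dev)
        pred = model.predict(Xdev)
        table[f"pred_{cname}"] = pred
        n_positive += int(np.sum(pred == ACTIVE))
        if ad_train is not None:
            flags = applicability_domain(ad_train[needed_dev], Xdev)
            table[f"in_ad_{cname}"] = [f.inside for f in flags]
    pred_cols = [f"pred_{c}" for c in conditions]
    table["consensus_hit"] = (table[pred_cols] == ACTIVE).all(axis=1)

    profile_by_id = {}
    for pos, g in enumerate(library):
        gid = g.id or f"mol{pos}"
        if gid in table.index and gid not in profile_by_id:
            profile_by_id[gid] = (lipinski_properties(g), write_smiles(g))
    for col in ("smiles", "mw", "n_hdon", "n_hacc", "alogp", "ro5_pass"):
        table[col] = None
    for gid, (prof, smi) in profile_by_id.items():
        table.loc[gid, ["smiles", "mw", "n_hdon", "n_hacc", "alogp", "ro5_pass"]] = [
            smi, prof.mw, prof.n_hdon, prof.n_hacc, prof.alogp, prof.passes,
        ]
    return ScreeningResult(
        table=table,
        conditions=list(conditions),
        n_cases=len(ids) * len(conditions),
        n_positive_cases=n_positive,
    )
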
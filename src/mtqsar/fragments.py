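"""Bemis–Murcko scaffolds, ring-fragment enumeration and fragment contribution scores.

A linear condition-aware discriminant can be read fragment-wise: compute its
raw descriptors on a bare ring fragment, apply the frozen Box–Jenkins
condition deviations, and evaluate the linear score once per experimental
condition.  Standardising all fragment × condition scores jointly (z over all
cells) gives *confidence scores*; averaging a fragment's confidence scores
over the conditions gives its *average confidence score* (ACS).  Positive ACS
marks activity-favouring ring systems.

Fragments are scored as standalone molecules with implicit hydrogens —
attachment-point context is deliberately out of scope, so scores are relative
indications, not additive free energies.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .boxjenkins import ConditionAverages, ExperimentalCondition, deviation_column
from .chem_core import MolecularGraph
from .descriptors import compute_named_descriptors
from .modeling import LinearDiscriminantModel


class FragmentError(ValueError):
    pass


def murcko_scaffold(g: MolecularGraph) -> MolecularGraph | None:
    """Ring systems plus linkers after pruning acyclic side chains.

    Acyclic molecules have no scaffold and yield ``None``.  Idempotent.
    """
    mol = g.to_rdkit()
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return None
    return MolecularGraph.from_rdkit(scaffold, id=g.id)


def _single_ring_smiles(mol: Chem.Mol) -> set[str]:
    """Canonical SMILES of each SSSR ring of ``mol`` taken as a standalone
    molecule; fused systems are split into their constituent single rings."""
    out = set()
    ri = mol.GetRingInfo()
    for ring_atoms, ring_bonds in zip(ri.AtomRings(), ri.BondRings()):
        try:
            smi = Chem.MolFragmentToSmiles(
                mol, atomsToUse=list(ring_atoms), bondsToUse=list(ring_bonds), canonical=True
            )
            frag = Chem.MolFromSmiles(smi)
            if frag is None:  # aromatic subring not valid standalone: kekulised fallback
                smi = Chem.MolFragmentToSmiles(
                    mol,
                    atomsToUse=list(ring_atoms),
                    bondsToUse=list(ring_bonds),
                    canonical=True,
                    kekuleSmiles=True,
                )
                frag = Chem.MolFromSmiles(smi)
            if frag is not None:
                out.add(Chem.MolToSmiles(frag))
        except Exception:
            continue
    return out


@dataclass
class RingFragment:
    smiles: str
    compound_count: int
    compound_ids: list[str]

    def graph(self) -> MolecularGraph:
        from .chem_core import parse_smiles

        return parse_smiles(self.smiles, id=self.smiles)


def enumerate_ring_fragments(
    dataset: Sequence[MolecularGraph],
    min_compounds: int = 15,
) -> list[RingFragment]:
    """Single-ring fragments present in strictly more than ``min_compounds``
    compounds; a compound counts once per fragment however often the ring recurs."""
    containing: dict[str, list[str]] = defaultdict(list)
    for pos, g in enumerate(dataset):
        scaffold = murcko_scaffold(g)
        if scaffold is None:
            continue
        cid = g.id or f"mol{pos}"
        for smi in _single_ring_smiles(scaffold.to_rdkit()):
            containing[smi].append(cid)
    frags = [
        RingFragment(smi, len(cids), sorted(cids))
        for smi, cids in containing.items()
        if len(cids) > min_compounds
    ]
    frags.sort(key=lambda f: (-f.compound_count, f.smiles))
    return frags


# -- contribution scoring ------------------------------------------------------


def fragment_scores(
    fragments: Sequence[RingFragment | MolecularGraph],
    model: LinearDiscriminantModel,
    conditions: Mapping[str, ExperimentalCondition],
    averages: Mapping[str, ConditionAverages],
) -> pd.DataFrame:
    """Raw linear scores, fragments × conditions.

    For each fragment the model's raw descriptors are computed on the bare
    ring; each condition's stored active means then yield the deviation
    descriptors the model is evaluated on.
    """
    from .boxjenkins import raw_column

    needed = [raw_column(n) for n in model.descriptor_names]
    raw_names = sorted({rn for rn, _ in needed})
    rows = {}
    for frag in fragments:
        g = frag.graph() if isinstance(frag, RingFragment) else frag
        fid = g.id or f"fragment{len(rows)}"
        raw = compute_named_descriptors(g, raw_names)
        scores = {}
        for cname, cond in conditions.items():
            x = {}
            for dev_name, (rname, element) in zip(model.descriptor_names, needed):
                mean = averages[element].mean_for(cond.element(element))
                if rname not in mean.index:
                    raise FragmentError(f"no stored mean for descriptor {rname!r}")
                x[dev_name] = raw[rname] - float(mean[rname])
            scores[cname] = float(model.score(x)[0])
        rows[fid] = scores
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class FragmentScoreTable:
    raw: pd.DataFrame  # fragments × conditions
    z: pd.DataFrame  # standardised confidence scores
    acs: pd.Series  # per-fragment mean of z, ranked descending

    def to_csv(self, path: str | Path) -> None:
        out = self.z.copy()
        out.columns = [f"z_{c}" for c in out.columns]
        out["ACS"] = self.acs
        out.sort_values("ACS", ascending=False).to_csv(path, index_label="fragment")

    def summary(self, top: int = 10) -> str:
        ranked = self.acs.sort_values(ascending=False)
        lines = ["fragment contribution ranking (ACS):"]
        for smi, val in ranked.head(top).items():
            lines.append(f"  {val:+7.3f}  {smi}")
        return "\n".join(lines)


def standardize_scores(raw: pd.DataFrame, per_condition: bool = False, ddof: int = 1) -> FragmentScoreTable:
    """Confidence scores: z-standardise the raw scores, then ACS per fragment.

    By default all fragment × condition cells are standardised jointly with
    the sample SD (ddof=1); ``per_condition`` standardises each condition
    column separately instead.
    """
    if raw.size < 2:
        raise FragmentError("need at least two scores to standardise")
    if per_condition:
        mu, sd = raw.mean(axis=0), raw.std(axis=0, ddof=ddof)
        if (sd == 0).any():
            raise FragmentError("zero score SD in a condition column")
        z = (raw - mu) / sd
    else:
        vals = raw.values.ravel()
        sd = float(np.std(vals, ddof=ddof))
        if sd == 0:
            raise FragmentError("zero score SD: all raw scores equal")
        z = (raw - float(vals.mean())) / sd
    acs = z.mean(axis=1).sort_values(ascending=False)
    return FragmentScoreTable(raw, z, acs)
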
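"""Molecular complexity and drug-likeness descriptors by structural class.

Six descriptors per molecule: molecular weight (Da), heavy-atom count,
ring count (SSSR), number of specified tetrahedral stereocentres, Fsp3
(fraction of carbons sp3-hybridized; undefined without carbon) and QED,
the weighted-desirability drug-likeness score in [0, 1].

Summaries aggregate the descriptor table over the structural classes of
the network decomposition (core, periphery, island) plus the hub class,
which overlaps the others — a hub molecule also belongs to a component.
Distribution views cropped at mean +/- 2 SD are provided for plotting;
means and standard deviations are always computed on uncropped data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, QED, rdMolDescriptors

from .components import ComponentLabeling
from .graphs import ReactionNetwork
from .topology import HubSet

logger = logging.getLogger(__name__)

__all__ = [
    "DESCRIPTOR_COLUMNS",
    "MoleculeDescriptors",
    "ClassSummary",
    "compute_descriptors",
    "descriptor_table",
    "summarize_by_class",
]

DESCRIPTOR_COLUMNS = ("mw", "heavy_atoms", "rings", "chiral_atoms", "fsp3", "qed")


class DescriptorError(ValueError):
    """The structure could not be parsed or scored."""


@dataclass(frozen=True)
class MoleculeDescriptors:
    molecular_weight: float
    n_heavy_atoms: int
    n_rings: int
    n_chiral_atoms: int
    fsp3: float | None  # None when the molecule has no carbon
    qed: float

    def as_row(self) -> dict:
        return {
            "mw": self.molecular_weight,
            "heavy_atoms": self.n_heavy_atoms,
            "rings": self.n_rings,
            "chiral_atoms": self.n_chiral_atoms,
            "fsp3": self.fsp3 if self.fsp3 is not None else np.nan,
            "qed": self.qed,
        }


def compute_descriptors(mol: Chem.Mol | str) -> MoleculeDescriptors:
    """Descriptors of one molecule (SMILES or RDKit mol).

    Chiral atoms are atoms with *specified* tetrahedral stereochemistry;
    potential but unassigned stereocentres are not counted.
    """
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise DescriptorError(f"unparsable structure: {mol!r}")
        mol = parsed
    n_carbon = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    chiral = Chem.FindMolChiralCenters(mol, includeUnassigned=False, useLegacyImplementation=False)
    return MoleculeDescriptors(
        molecular_weight=float(Descriptors.MolWt(mol)),
        n_heavy_atoms=mol.GetNumHeavyAtoms(),
        n_rings=rdMolDescriptors.CalcNumRings(mol),
        n_chiral_atoms=len(chiral),
        fsp3=float(rdMolDescriptors.CalcFractionCSP3(mol)) if n_carbon else None,
        qed=float(QED.qed(mol)),
    )


def descriptor_table(molecules) -> pd.DataFrame:
    """Descriptor table for ``(molecule_id, smiles)`` pairs (or a mapping).

    Unparsable structures are excluded with a logged count.
    """
    if isinstance(molecules, dict):
        molecules = [(mid, smi) for smi, mid in molecules.items()]
    rows, index, failed = [], [], 0
    for mid, smi in molecules:
        try:
            desc = compute_descriptors(smi)
        except DescriptorError:
            failed += 1
            continue
        rows.append({"smiles": smi, **desc.as_row()})
        index.append(mid)
    if failed:
        logger.warning("descriptor computation skipped %d unparsable structures", failed)
    return pd.DataFrame(rows, index=pd.Index(index, name="molecule_id"))


@dataclass
class ClassSummary:
    name: str  # {'core', 'periphery', 'island', 'hub'}
    n: int
    means: dict[str, float]
    sds: dict[str, float]
    cropped: dict[str, np.ndarray]  # distribution views within mean +/- 2 SD

    def as_dict(self) -> dict:
        return {"class": self.name, "n": self.n, "means": dict(self.means), "sds": dict(self.sds)}


def _summarize_one(name: str, sub: pd.DataFrame) -> ClassSummary:
    means, sds, cropped = {}, {}, {}
    for col in DESCRIPTOR_COLUMNS:
        vals = sub[col].dropna().to_numpy(dtype=np.float64) if len(sub) else np.empty(0)
        if vals.size == 0:
            means[col] = float("nan")
            sds[col] = float("nan")
            cropped[col] = vals
            continue
        m, s = float(vals.mean()), float(vals.std())
        means[col], sds[col] = m, s
        cropped[col] = vals[np.abs(vals - m) <= 2.0 * s]
    return ClassSummary(name=name, n=int(len(sub)), means=means, sds=sds, cropped=cropped)


def summarize_by_class(
    labels: ComponentLabeling,
    hubs: HubSet | None,
    table: pd.DataFrame,
    net: ReactionNetwork | None = None,
    smiles_to_id=None,
) -> dict[str, ClassSummary]:
    """Per-class descriptor summaries.

    ``labels`` is the bipartite decomposition (molecule rows are matched
    through ``net``/``smiles_to_id``); ``hubs`` adds the overlapping hub
    class.  Classes without molecules yield an ``n = 0`` summary with
    missing statistics.
    """
    mol_labels = labels.molecule_labels(net) if net is not None else labels.label
    if smiles_to_id is None:
        smiles_to_id = {}
        if "smiles" in table.columns:
            smiles_to_id = {smi: mid for mid, smi in table["smiles"].items()}

    def rows_for(node_ids) -> pd.DataFrame:
        ids = [smiles_to_id.get(n, n) for n in node_ids]
        ids = [i for i in ids if i in table.index]
        return table.loc[ids]

    out: dict[str, ClassSummary] = {}
    for cls, want in (("core", "core"), ("periphery", "periphery"), ("island", "island")):
        node_ids = [n for n, lab in mol_labels.items() if lab == want]
        out[cls] = _summarize_one(cls, rows_for(node_ids))
    if hubs is not None:
        out["hub"] = _summarize_one("hub", rows_for([m for m, _ in hubs.members]))
    return out
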
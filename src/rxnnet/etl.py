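"""Cleaning of atom-mapped reaction SMILES into deduplicated reactions.

A raw record is one line in the three-slot ``reactants>agents>products``
dialect with optional tab-separated metadata (record id, yield percent).
Cleaning proceeds in four stages:

1. **Parsing** — the line is split into its three component slots and every
   component is parsed with RDKit; malformed lines become ``parse_error``
   rejections, multi-arrow strings ``not_single_step``.
2. **Role assignment** — any left-slot or above-arrow component sharing at
   least one atom-map number with the product is a *reactant*; everything
   else is a *reagent*.  Role assignment is purely map-number based, never
   chemical.
3. **Neutralization** — reactants and products pass through the RDKit
   uncharger, cancelling every formal charge that can be fixed by adding or
   removing hydrogens (quaternary nitrogens and the like are retained).
   Reagents are left untouched.
4. **Filtering** — a record is kept only if it has exactly one product, at
   least one reactant, a product canonically different from every reactant,
   and no dummy atoms; an optional yield threshold mirrors sources curated
   by minimum yield.

Accepted reactions are keyed by their reagent-blind canonical form
(sorted canonical reactants ``>>`` canonical product); records differing
only in reagents collapse onto one key.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "REJECTION_REASONS",
    "ReactionRecord",
    "CleanReaction",
    "RejectionReport",
    "ETLResult",
    "parse_reaction_line",
    "assign_roles",
    "neutralize",
    "canonical_smiles",
    "apply_filters",
    "run_etl",
]

REJECTION_REASONS = (
    "not_single_step",
    "multi_product",
    "no_reactant",
    "product_equals_reactant",
    "dummy_atom",
    "parse_error",
    "yield_below_threshold",
)

_UNCHARGER = rdMolStandardize.Uncharger()


@dataclass
class ReactionRecord:
    """One parsed reaction with role-annotated components."""

    record_id: str
    components_left: list[Chem.Mol]
    components_agent: list[Chem.Mol]
    components_right: list[Chem.Mol]
    yield_percent: float | None = None
    roles_assigned: bool = False


@dataclass(frozen=True)
class CleanReaction:
    """A reaction that survived all filters, in canonical form."""

    reactants: tuple[str, ...]  # canonical SMILES, input order
    product: str
    reagents: tuple[str, ...]
    reaction_key: str
    record_id: str
    yield_percent: float | None = None
    n_grouped: int = 1  # records collapsed onto this key


@dataclass(frozen=True)
class RejectionReport:
    record_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


@dataclass
class ETLResult:
    """Accepted (deduplicated) reactions plus the rejection ledger."""

    accepted: list[CleanReaction]
    rejections: list[RejectionReport]
    n_input: int
    n_accepted_records: int
    molecules: dict[str, int] = field(default_factory=dict)  # canonical SMILES -> id
    rejection_counts: Counter = field(default_factory=Counter)


def _mol_maps(mol: Chem.Mol) -> set[int]:
    return {a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0}


def _has_dummy(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 0 for a in mol.GetAtoms())


def parse_reaction_line(line: str, line_no: int = 0) -> ReactionRecord | RejectionReport:
    """Parse one raw line into a :class:`ReactionRecord`.

    Malformed input is returned as a :class:`RejectionReport`, never raised:
    the ETL is total over arbitrary text.
    """
    parts = line.rstrip("\n").split("\t")
    rxn_smiles = parts[0].strip()
    record_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"line{line_no}"

    n_arrows = rxn_smiles.count(">")
    if n_arrows > 2:
        return RejectionReport(record_id, "not_single_step")
    if n_arrows < 2:
        return RejectionReport(record_id, "parse_error")

    yield_percent: float | None = None
    if len(parts) > 2 and parts[2].strip():
        try:
            yield_percent = float(parts[2])
        except ValueError:
            return RejectionReport(record_id, "parse_error")

    slots: list[list[Chem.Mol]] = []
    for slot in rxn_smiles.split(">"):
        mols: list[Chem.Mol] = []
        if slot:
            for smi in slot.split("."):
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    return RejectionReport(record_id, "parse_error")
                mols.append(mol)
        slots.append(mols)

    if not slots[2]:
        return RejectionReport(record_id, "parse_error")

    return ReactionRecord(
        record_id=record_id,
        components_left=slots[0],
        components_agent=slots[1],
        components_right=slots[2],
        yield_percent=yield_percent,
    )


def assign_roles(record: ReactionRecord) -> ReactionRecord:
    """Split left and above-arrow components into reactants and reagents.

    A component is a reactant iff it shares at least one atom-map number
    with any product component; reactants end up in ``components_left``,
    everything else above the arrow.  Structures are not modified.
    """
    product_maps: set[int] = set()
    for mol in record.components_right:
        product_maps |= _mol_maps(mol)

    reactants: list[Chem.Mol] = []
    reagents: list[Chem.Mol] = []
    for mol in record.components_left + record.components_agent:
        if _mol_maps(mol) & product_maps:
            reactants.append(mol)
        else:
            reagents.append(mol)

    return ReactionRecord(
        record_id=record.record_id,
        components_left=reactants,
        components_agent=reagents,
        components_right=list(record.components_right),
        yield_percent=record.yield_percent,
        roles_assigned=True,
    )


def neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Cancel hydrogen-adjustable formal charges (RDKit uncharger).

    Charges that cannot be fixed by (de)protonation — e.g. quaternary
    ammonium — are retained.  Idempotent.
    """
    return _UNCHARGER.uncharge(mol)


def canonical_smiles(mol: Chem.Mol) -> str:
    """Molecule identity: canonical SMILES, atom maps dropped, stereo kept."""
    copy = Chem.Mol(mol)
    for atom in copy.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(copy)


def apply_filters(
    record: ReactionRecord,
    yield_threshold: float | None = None,
) -> CleanReaction | RejectionReport:
    """Keep the record only if every cleaning criterion holds.

    Expects roles already assigned.  Neutralizes reactants and product
    before the canonical-equality test so that charged/neutral pairs
    collapse onto one molecule.  Criteria, in order of precedence:
    exactly one product; at least one reactant; product canonically
    different from each reactant; no dummy atoms anywhere; and, when a
    threshold is set, a recorded yield at or above it.
    """
    if not record.roles_assigned:
        record = assign_roles(record)

    if len(record.components_right) != 1:
        return RejectionReport(record.record_id, "multi_product")
    if not record.components_left:
        return RejectionReport(record.record_id, "no_reactant")

    reactants = [neutralize(m) for m in record.components_left]
    product = neutralize(record.components_right[0])

    reactant_smiles = tuple(canonical_smiles(m) for m in reactants)
    product_smiles = canonical_smiles(product)
    if product_smiles in reactant_smiles:
        return RejectionReport(record.record_id, "product_equals_reactant")

    if any(_has_dummy(m) for m in reactants + [product] + record.components_agent):
        return RejectionReport(record.record_id, "dummy_atom")

    if yield_threshold is not None and record.yield_percent is not None:
        if record.yield_percent < yield_threshold:
            return RejectionReport(record.record_id, "yield_below_threshold")

    key = ".".join(sorted(reactant_smiles)) + ">>" + product_smiles
    return CleanReaction(
        reactants=reactant_smiles,
        product=product_smiles,
        reagents=tuple(canonical_smiles(m) for m in record.components_agent),
        reaction_key=key,
        record_id=record.record_id,
        yield_percent=record.yield_percent,
    )


def run_etl(lines: Iterable[str], yield_threshold: float | None = None) -> ETLResult:
    """Clean a raw reaction file end to end.

    Returns deduplicated accepted reactions (one per reaction key, with
    ``n_grouped`` recording how many records collapsed onto it), the full
    rejection ledger, and the molecule table of canonical reactant/product
    structures (reagents excluded).  ``|accepted records| + |rejections| =
    |input|`` always holds.
    """
    by_key: dict[str, CleanReaction] = {}
    rejections: list[RejectionReport] = []
    n_input = 0
    n_accepted = 0

    for line_no, line in enumerate(lines):
        if not line.strip():
            continue
        n_input += 1
        parsed = parse_reaction_line(line, line_no)
        if isinstance(parsed, RejectionReport):
            rejections.append(parsed)
            continue
        outcome = apply_filters(assign_roles(parsed), yield_threshold)
        if isinstance(outcome, RejectionReport):
            rejections.append(outcome)
            continue
        n_accepted += 1
        prev = by_key.get(outcome.reaction_key)
        if prev is None:
            by_key[outcome.reaction_key] = outcome
        else:
            by_key[outcome.reaction_key] = CleanReaction(
                reactants=prev.reactants,
                product=prev.product,
                reagents=prev.reagents,
                reaction_key=prev.reaction_key,
                record_id=prev.record_id,
                yield_percent=prev.yield_percent,
                n_grouped=prev.n_grouped + 1,
            )

    accepted = list(by_key.values())
    molecules: dict[str, int] = {}
    for rxn in accepted:
        for smi in (*rxn.reactants, rxn.product):
            if smi not in molecules:
                molecules[smi] = len(molecules)

    return ETLResult(
        accepted=accepted,
        rejections=rejections,
        n_input=n_input,
        n_accepted_records=n_accepted,
        molecules=molecules,
        rejection_counts=Counter(r.reason for r in rejections),
    )
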
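"""Synthetic atom-mapped reaction corpora with controllable network structure.

Real reaction corpora (patent extractions, commercial databases, electronic
lab notebooks) are proprietary or too large to redistribute.  This module
produces text files in the same three-slot ``reactants>agents>products``
reaction-SMILES dialect that reproduce the *statistical* structure such
corpora exhibit:

* heavy-tailed molecule reuse driven by preferential attachment
  (a molecule is drawn as a reactant with probability proportional to its
  current use count plus an offset),
* single-product reactions whose product atoms carry atom-map numbers
  copied from the reactant atoms,
* above-arrow reagents that share no atom maps with the product,
* a configurable fraction of records violating each downstream cleaning
  rule (multiple products, no mapped reactant, product identical to a
  reactant, dummy atoms, chargeable species),
* duplicate reactions that differ only in their reagents, and
* optional directed cycles so that a strongly connected core can exist
  or not by configuration.

No chemical plausibility is attempted or implied: products are syntactic
concatenations of their reactants' atoms.  Only syntactic validity and
correct atom-map bookkeeping are guaranteed.

The module also provides an exact sampler for the discrete (zeta) power
law, used to validate the tail-fitting machinery against known ground
truth.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.special import zeta

__all__ = [
    "DIRT_KINDS",
    "GeneratorConfig",
    "BuildingBlockPool",
    "ReactionEvent",
    "GrowthTrace",
    "simulate_growth",
    "skeleton_molecule_graph",
    "generate_dataset",
    "generate_trend_dataset",
    "sample_discrete_powerlaw",
    "write_dataset",
]

#: Violation kinds the generator can inject.  The first four are rejected by
#: the cleaning filters with a reason of the same name; ``charged_atom``
#: exercises the neutralizer (charged records are repaired, not rejected) and
#: ``duplicate_reagent_variant`` exercises reagent-blind deduplication.
DIRT_KINDS = (
    "multi_product",
    "no_reactant",
    "product_equals_reactant",
    "dummy_atom",
    "charged_atom",
    "duplicate_reagent_variant",
)

#: Unmapped above-arrow species (common solvents / additives).
REAGENT_VOCAB = (
    "O",
    "CCO",
    "CC(C)=O",
    "ClCCl",
    "C1CCOC1",
    "CC(=O)O",
    "CN(C)C=O",
    "CCOCC",
)

#: Second product components used for ``multi_product`` dirt.
_EXTRA_PRODUCTS = ("OCC(O)CO", "CC#N", "O=C=O")


class ConfigError(ValueError):
    """A generator configuration field is invalid."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic reaction corpus.

    Parameters
    ----------
    n_reactions:
        Number of reaction lines to emit.
    reactant_count_weights:
        Probability of a reaction having 1, 2 or 3 reactants.  Bimolecular
        reactions dominate real corpora, hence the default mode at 2.
    attach_strength:
        Additive offset ``a`` of the preferential-attachment rule: an
        existing molecule is selected with probability proportional to
        ``use_count + a``.  Larger values flatten the reuse distribution.
    reuse_prob:
        Probability that a reactant slot is filled from the existing
        molecule population rather than a fresh building block.
    closure_prob:
        Probability that a reactant slot after the first is filled from the
        first reactant's current reaction neighborhood (a molecule that
        already shares a reaction with it) instead of the global population.
        This triadic-closure step models the tendency to combine molecules
        from related prior chemistry; it is what gives the molecule graph
        its hierarchical ``1/k`` decay of degree-dependent clustering.  The
        default is strong enough to produce that decay while weak enough to
        leave hub formation (the 100 x average-degree rule) intact.
    cycle_prob:
        Probability that a reaction's product is an already-existing
        molecule, which can close directed cycles (the mechanism that lets
        a strongly connected core emerge).
    reagent_rate:
        Mean (Poisson) number of unmapped reagent components per reaction.
    dirt_rates:
        Per-kind injection fractions; see :data:`DIRT_KINDS`.
    yield_range:
        Bounds of the uniformly drawn yield metadata column, in percent.
    seed:
        Seed for all randomness; identical configs generate identical files.
    planted_scc_molecules:
        If set, append a directed reaction cycle over this many dedicated
        molecules (``M_i + hub -> M_(i+1 mod c)``), producing one strongly
        connected component of exactly ``2 * planted_scc_molecules``
        bipartite nodes attached to the main component through the hub
        co-reactant.
    min_block_chain:
        Minimum carbon-chain length of fresh building blocks; raises the
        molecular weight floor of new molecules.
    max_product_atoms:
        Cap on product heavy-atom count.  Reactants that would push a
        product past the cap do not contribute atoms (and are therefore
        demoted to reagents downstream); this keeps molecule sizes bounded
        over long preferential-attachment runs.
    """

    n_reactions: int
    reactant_count_weights: tuple[float, float, float] = (0.2, 0.6, 0.2)
    attach_strength: float = 1.0
    reuse_prob: float = 0.9
    closure_prob: float = 0.08
    cycle_prob: float = 0.0
    reagent_rate: float = 0.8
    dirt_rates: Mapping[str, float] = field(default_factory=dict)
    yield_range: tuple[float, float] = (5.0, 100.0)
    seed: int = 0
    planted_scc_molecules: int | None = None
    min_block_chain: int = 1
    max_product_atoms: int = 120

    def __post_init__(self) -> None:
        if not isinstance(self.n_reactions, (int, np.integer)) or self.n_reactions < 1:
            raise ConfigError("n_reactions must be a positive integer")
        w = tuple(self.reactant_count_weights)
        if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ConfigError("reactant_count_weights must be 3 non-negative values summing to 1")
        if self.attach_strength < 0:
            raise ConfigError("attach_strength must be non-negative")
        for name in ("reuse_prob", "cycle_prob", "closure_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.reagent_rate < 0:
            raise ConfigError("reagent_rate must be non-negative")
        for kind, rate in dict(self.dirt_rates).items():
            if kind not in DIRT_KINDS:
                raise ConfigError(f"dirt_rates contains unknown kind {kind!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"dirt_rates[{kind!r}] must be in [0, 1]")
        lo, hi = self.yield_range
        if not (0.0 <= lo <= hi <= 100.0):
            raise ConfigError("yield_range must satisfy 0 <= low <= high <= 100")
        if self.planted_scc_molecules is not None and self.planted_scc_molecules < 2:
            raise ConfigError("planted_scc_molecules must be at least 2")
        if self.min_block_chain < 1:
            raise ConfigError("min_block_chain must be at least 1")
        if self.max_product_atoms < 8:
            raise ConfigError("max_product_atoms must be at least 8")


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

_CHAIN_ALPHABET = ("C", "O", "N")


def _encode_tail(i: int) -> str:
    """Base-3 encoding of ``i`` as a C/O/N chain; grows like log3(i)."""
    if i == 0:
        return ""
    digits = []
    while i:
        i, d = divmod(i, 3)
        digits.append(_CHAIN_ALPHABET[d])
    return "".join(digits)


class BuildingBlockPool:
    """Inexhaustible supply of small, distinct, uncharged molecules.

    Blocks are linear C/O/N chains of slowly growing length: the ``i``-th
    candidate is ``'C' * min_chain`` followed by the base-3 C/O/N encoding
    of ``i``, so ~3^k distinct blocks exist below ``min_chain + k`` heavy
    atoms.  Candidates whose canonical structure was already issued are
    skipped, so every returned block is canonically unique.
    """

    def __init__(self, min_chain: int = 1) -> None:
        if min_chain < 1:
            raise ConfigError("min_chain must be at least 1")
        self._prefix = "C" * min_chain
        self._seen: set[str] = set()
        self._i = 0

    @property
    def next_id(self) -> int:
        return self._i

    def fresh(self) -> Chem.Mol:
        """Return the next unique building block as an RDKit molecule."""
        while True:
            smi = self._prefix + _encode_tail(self._i)
            self._i += 1
            mol = Chem.MolFromSmiles(smi)
            if mol is None:  # pragma: no cover - all candidates are valid chains
                continue
            canon = Chem.MolToSmiles(mol)
            if canon not in self._seen:
                self._seen.add(canon)
                return mol


# ---------------------------------------------------------------------------
# Growth skeleton (pure-integer bookkeeping, no SMILES)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionEvent:
    """One reaction of the growth process, in molecule-index space."""

    reactants: tuple[int, ...]
    product: int
    product_is_new: bool
    dirt: tuple[str, ...]
    n_reagents: int
    yield_percent: float
    duplicate_of: int | None = None
    planted: bool = False


@dataclass
class GrowthTrace:
    """Outcome of :func:`simulate_growth`."""

    events: list[ReactionEvent]
    n_molecules: int
    reactant_uses: np.ndarray
    planted_molecules: tuple[int, ...] = ()
    planted_hub: int | None = None


def simulate_growth(config: GeneratorConfig) -> GrowthTrace:
    """Run the preferential-attachment growth process without emitting SMILES.

    The trace is the ground truth for the structural properties of the
    corpus (reuse counts, cycle events, dirt assignment) and is consumed by
    :func:`generate_dataset` for emission.  Separating the two lets the
    network structure be audited independently of the chemistry layer.
    """
    rng = np.random.default_rng(config.seed)
    rates = dict(config.dirt_rates)
    uses: list[int] = []
    ball: list[int] = []  # one entry per reuse event; uniform draw == preferential
    nbrs: list[list[int]] = []  # molecule-graph neighborhoods for triadic closure
    edges: set[tuple[int, int]] = set()
    events: list[ReactionEvent] = []
    last_clean: int | None = None

    def new_mol() -> int:
        uses.append(0)
        nbrs.append([])
        return len(uses) - 1

    for _ in range(config.n_reactions):
        dirt = tuple(k for k in DIRT_KINDS if rates.get(k, 0.0) > 0.0 and rng.random() < rates[k])
        yld = rng.uniform(*config.yield_range)

        if "duplicate_reagent_variant" in dirt and last_clean is not None:
            base = events[last_clean]
            events.append(
                dataclasses.replace(
                    base,
                    dirt=("duplicate_reagent_variant",),
                    n_reagents=base.n_reagents + 1,
                    yield_percent=yld,
                    duplicate_of=last_clean,
                )
            )
            continue
        dirt = tuple(k for k in dirt if k != "duplicate_reagent_variant")

        n_r = int(rng.choice((1, 2, 3), p=config.reactant_count_weights))
        chosen: list[int] = []
        for slot in range(n_r):
            m: int
            if (
                slot > 0
                and chosen
                and nbrs[chosen[0]]
                and rng.random() < config.closure_prob
            ):
                cand = nbrs[chosen[0]]
                m = cand[int(rng.integers(len(cand)))]
            elif uses and rng.random() < config.reuse_prob:
                total_uses = len(ball)
                uniform_w = config.attach_strength * len(uses)
                if total_uses and rng.random() < total_uses / (total_uses + uniform_w):
                    m = ball[int(rng.integers(total_uses))]
                else:
                    m = int(rng.integers(len(uses)))
            else:
                m = new_mol()
            if m in chosen:  # keep reactant lists duplicate-free
                m = new_mol()
            chosen.append(m)

        n_existing = len(uses)
        if rng.random() < config.cycle_prob and n_existing > len(chosen):
            # close a potential directed cycle: product is an older molecule
            product = int(rng.integers(n_existing))
            for _try in range(8):
                if product not in chosen:
                    break
                product = int(rng.integers(n_existing))
            if product in chosen:
                product = new_mol()
                is_new = True
            else:
                is_new = False
        else:
            product = new_mol()
            is_new = True

        for m in chosen:
            uses[m] += 1
            ball.append(m)
            if m != product and (m, product) not in edges:
                edges.add((m, product))
                nbrs[m].append(product)
                nbrs[product].append(m)

        events.append(
            ReactionEvent(
                reactants=tuple(chosen),
                product=product,
                product_is_new=is_new,
                dirt=dirt,
                n_reagents=int(rng.poisson(config.reagent_rate)),
                yield_percent=yld,
            )
        )
        if not dirt:
            last_clean = len(events) - 1

    planted: tuple[int, ...] = ()
    hub: int | None = None
    if config.planted_scc_molecules:
        c = config.planted_scc_molecules
        hub = int(np.argmax(uses)) if uses else new_mol()
        planted = tuple(new_mol() for _ in range(c))
        for j in range(c):
            events.append(
                ReactionEvent(
                    reactants=(planted[j], hub),
                    product=planted[(j + 1) % c],
                    product_is_new=False,
                    dirt=(),
                    n_reagents=0,
                    yield_percent=float(np.mean(config.yield_range)),
                    planted=True,
                )
            )
            uses[planted[j]] += 1
            uses[hub] += 1

    return GrowthTrace(
        events=events,
        n_molecules=len(uses),
        reactant_uses=np.asarray(uses, dtype=np.int64),
        planted_molecules=planted,
        planted_hub=hub,
    )


def skeleton_molecule_graph(trace: GrowthTrace):
    """Directed reactant->product molecule graph of the clean trace events.

    Index-space counterpart of the post-ETL molecule projection; useful for
    testing graph statistics at scale without any SMILES round trip.
    """
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(trace.n_molecules))
    for ev in trace.events:
        if ev.dirt or ev.duplicate_of is not None:
            continue
        for r in ev.reactants:
            if r != ev.product:
                g.add_edge(r, ev.product)
    return g


# ---------------------------------------------------------------------------
# SMILES emission
# ---------------------------------------------------------------------------


def _free_valence_idx(mol: Chem.Mol, offset: int = 0, lo: int = 0, hi: int | None = None) -> int | None:
    hi = mol.GetNumAtoms() if hi is None else hi
    for idx in range(lo, hi):
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetAtomicNum() > 1 and atom.GetTotalNumHs() > 0:
            return idx + offset
    return None


def _bond_pair(a: Chem.Mol, b: Chem.Mol) -> Chem.Mol:
    """Join two fragments with one single bond between H-bearing atoms."""
    na = a.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(a, b))
    i = _free_valence_idx(combo, hi=na)
    j = _free_valence_idx(combo, lo=na)
    if i is not None and j is not None:
        combo.AddBond(i, j, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _append_atom(mol: Chem.Mol, atomic_num: int) -> Chem.Mol:
    """Bond one extra atom (carbon or dummy) onto the first H-bearing atom."""
    combo = Chem.RWMol(mol)
    new_idx = combo.AddAtom(Chem.Atom(atomic_num))
    anchor = _free_valence_idx(combo, hi=new_idx)
    if anchor is not None:
        combo.AddBond(anchor, new_idx, Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _combine_product(mapped_reactants: Sequence[Chem.Mol], max_atoms: int) -> Chem.Mol:
    """Bonded concatenation of the reactants' atoms (map numbers retained).

    Reactants beyond the atom cap contribute no atoms; with a single
    contributing reactant an extra unmapped carbon is appended so the
    product is never structurally identical to a reactant.
    """
    contributors = [mapped_reactants[0]]
    total = mapped_reactants[0].GetNumAtoms()
    for m in mapped_reactants[1:]:
        if total + m.GetNumAtoms() <= max_atoms:
            contributors.append(m)
            total += m.GetNumAtoms()
    product = contributors[0]
    for nxt in contributors[1:]:
        product = _bond_pair(product, nxt)
    if len(contributors) == 1:
        product = _append_atom(product, 6)
    return product


def _strip_maps(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out


def _charge_one_atom(mol: Chem.Mol) -> Chem.Mol:
    """Introduce one H-cancellable formal charge (deprotonated O / protonated N)."""
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 8 and atom.GetTotalNumHs() > 0:
            atom.SetFormalCharge(-1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
            atom.SetNoImplicit(True)
            Chem.SanitizeMol(out)
            return out
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 7:
            atom.SetFormalCharge(1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
            atom.SetNoImplicit(True)
            Chem.SanitizeMol(out)
            return out
    return out  # no chargeable site; emit unchanged


def _planted_structures(count: int) -> list[Chem.Mol]:
    """``count`` canonically distinct linear molecules of (near-)equal size."""
    mols: list[Chem.Mol] = []
    seen: set[str] = set()
    for length in itertools.count(6):
        for het in ("O", "N"):
            for pos in range(1, length - 1):
                smi = "C" * pos + het + "C" * (length - 1 - pos)
                mol = Chem.MolFromSmiles(smi)
                canon = Chem.MolToSmiles(mol)
                if canon in seen:
                    continue
                seen.add(canon)
                mols.append(mol)
                if len(mols) == count:
                    return mols


def _emit_lines(
    events: Sequence[ReactionEvent],
    *,
    seed: int,
    pool: BuildingBlockPool,
    preset_structures: Mapping[int, Chem.Mol] | None = None,
    max_product_atoms: int = 120,
    id_prefix: str = "R",
) -> list[str]:
    """Turn growth events into tab-separated mapped reaction lines."""
    rng = np.random.default_rng([seed, 0x5EED])
    structures: dict[int, Chem.Mol] = dict(preset_structures or {})
    emitted: dict[int, tuple[str, str]] = {}  # event idx -> (left slot, product slot)
    lines: list[str] = []

    for idx, ev in enumerate(events):
        rec_id = f"{id_prefix}{idx:06d}"

        if ev.duplicate_of is not None and ev.duplicate_of in emitted:
            left_slot, product_slot = emitted[ev.duplicate_of]
            reagents = [REAGENT_VOCAB[(i + idx) % len(REAGENT_VOCAB)] for i in range(max(1, ev.n_reagents))]
            lines.append(f"{left_slot}>{'.'.join(reagents)}>{product_slot}\t{rec_id}\t{ev.yield_percent:.1f}")
            continue

        for m in ev.reactants:
            if m not in structures:
                structures[m] = pool.fresh()

        mapped: list[Chem.Mol] = []
        counter = 1
        for m in ev.reactants:
            copy = Chem.Mol(structures[m])
            for atom in copy.GetAtoms():
                atom.SetAtomMapNum(counter)
                counter += 1
            mapped.append(copy)
        n_reactant_atoms = counter - 1

        if ev.product_is_new:
            product = _combine_product(mapped, max_product_atoms)
            structures[ev.product] = _strip_maps(product)
        else:
            if ev.product not in structures:  # cycle target not yet materialized
                structures[ev.product] = pool.fresh()
            product = Chem.Mol(structures[ev.product])
            for j, atom in enumerate(product.GetAtoms()):
                atom.SetAtomMapNum(j + 1 if j + 1 <= n_reactant_atoms else 0)

        # --- dirt mutations (after product construction, so stored structures
        #     used for future reuse stay clean) -------------------------------
        if "charged_atom" in ev.dirt and mapped:
            mapped[0] = _charge_one_atom(mapped[0])
        if "dummy_atom" in ev.dirt:
            product = _append_atom(product, 0)
        if "no_reactant" in ev.dirt:
            product = _strip_maps(product)

        product_slot = Chem.MolToSmiles(product)
        if "product_equals_reactant" in ev.dirt and mapped:
            product_slot = Chem.MolToSmiles(mapped[0])
        if "multi_product" in ev.dirt:
            product_slot += "." + _EXTRA_PRODUCTS[idx % len(_EXTRA_PRODUCTS)]

        left_slot = ".".join(Chem.MolToSmiles(m) for m in mapped)
        n_reag = min(ev.n_reagents, len(REAGENT_VOCAB))
        agent_slot = ""
        if n_reag:
            picks = rng.choice(len(REAGENT_VOCAB), size=n_reag, replace=False)
            agent_slot = ".".join(REAGENT_VOCAB[int(p)] for p in picks)

        if not ev.dirt:
            emitted[idx] = (left_slot, product_slot)
        lines.append(f"{left_slot}>{agent_slot}>{product_slot}\t{rec_id}\t{ev.yield_percent:.1f}")

    return lines


def generate_dataset(config: GeneratorConfig) -> list[str]:
    """Generate ``config.n_reactions`` raw reaction lines.

    Each line is ``<reaction_smiles>\\t<record_id>\\t<yield_percent>``.
    Deterministic for a fixed config (including seed).
    """
    trace = simulate_growth(config)
    pool = BuildingBlockPool(config.min_block_chain)
    preset: dict[int, Chem.Mol] = {}
    if trace.planted_molecules:
        for mid, mol in zip(trace.planted_molecules, _planted_structures(len(trace.planted_molecules))):
            preset[mid] = mol
    return _emit_lines(
        trace.events,
        seed=config.seed,
        pool=pool,
        preset_structures=preset,
        max_product_atoms=config.max_product_atoms,
    )


def write_dataset(lines: Sequence[str], path, header: bool = False) -> None:
    """Write generated lines to ``path`` (UTF-8, one reaction per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("reaction_smiles\trecord_id\tyield_percent\n")
        for line in lines:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Designed descriptor-trend corpus
# ---------------------------------------------------------------------------


def generate_trend_dataset(
    seed: int = 0,
    n_periphery: int = 600,
    n_islands: int = 120,
    cycle_len: int = 20,
) -> list[str]:
    """Corpus designed so molecular weight rises from hubs to islands.

    Construction (molecule classes in parentheses):

    * one tiny universal co-reactant, methane-like ``C`` (the hub),
    * ``n_periphery`` reactions ``hub + fresh small block -> product``
      forming one large connected component (the periphery),
    * a planted ``cycle_len``-molecule directed reaction cycle of
      mid-weight isomers, each consuming the hub (the core, attached to
      the central component through the hub),
    * ``n_islands`` disconnected reactions of three large fresh blocks
      (the islands).

    Block sizes are chosen so mean molecular weight orders
    hubs < core < periphery < islands, the gradient the descriptor
    summaries are meant to resolve.
    """
    rng = np.random.default_rng(seed)
    events: list[ReactionEvent] = []
    preset: dict[int, Chem.Mol] = {}

    hub = 0
    preset[hub] = Chem.MolFromSmiles("C")
    next_id = 1

    def take() -> int:
        nonlocal next_id
        next_id += 1
        return next_id - 1

    small_pool = BuildingBlockPool(min_chain=6)
    big_pool = BuildingBlockPool(min_chain=14)

    for _ in range(n_periphery):
        block = take()
        preset[block] = small_pool.fresh()
        events.append(
            ReactionEvent(
                reactants=(hub, block),
                product=take(),
                product_is_new=True,
                dirt=(),
                n_reagents=int(rng.poisson(0.5)),
                yield_percent=float(rng.uniform(5.0, 100.0)),
            )
        )

    core_ids = [take() for _ in range(cycle_len)]
    for mid, mol in zip(core_ids, _planted_structures(cycle_len)):
        preset[mid] = mol
    for j in range(cycle_len):
        events.append(
            ReactionEvent(
                reactants=(core_ids[j], hub),
                product=core_ids[(j + 1) % cycle_len],
                product_is_new=False,
                dirt=(),
                n_reagents=0,
                yield_percent=float(rng.uniform(5.0, 100.0)),
                planted=True,
            )
        )

    for _ in range(n_islands):
        blocks = [take() for _ in range(3)]
        for b in blocks:
            preset[b] = big_pool.fresh()
        events.append(
            ReactionEvent(
                reactants=tuple(blocks),
                product=take(),
                product_is_new=True,
                dirt=(),
                n_reagents=int(rng.poisson(0.5)),
                yield_percent=float(rng.uniform(5.0, 100.0)),
            )
        )

    return _emit_lines(
        events,
        seed=seed,
        pool=BuildingBlockPool(min_chain=6),
        preset_structures=preset,
        max_product_atoms=400,
        id_prefix="T",
    )


# ---------------------------------------------------------------------------
# Discrete power-law sampling
# ---------------------------------------------------------------------------

_TABLE_CAP = 2_000_000


def sample_discrete_powerlaw(
    gamma: float,
    kmin: int = 1,
    n: int = 1,
    seed: int | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. integers from ``P(k) = k^-gamma / zeta(gamma, kmin)``.

    Inverse-CDF lookup against a cumulative table truncated where the
    remaining tail mass falls below 1e-9 (capped at 2e6 entries); the rare
    draws falling beyond the table are resolved exactly by bisection on the
    Hurwitz-zeta CCDF, so the sampler is exact over the full support.

    Parameters
    ----------
    gamma:
        Power-law exponent; must exceed 1 for normalizability.
    kmin:
        Lower support bound (inclusive).
    n:
        Sample size.
    seed:
        Seed of the dedicated random stream.
    """
    if gamma <= 1:
        raise ValueError("gamma must be > 1 for a normalizable discrete power law")
    if kmin < 1:
        raise ValueError("kmin must be a positive integer")
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    z = zeta(gamma, kmin)

    # table size so that zeta(gamma, K) / z < 1e-9, using zeta(g, K) ~ K^(1-g)/(g-1)
    k_cut = int(np.ceil(((gamma - 1.0) * z * 1e-9) ** (1.0 / (1.0 - gamma)))) + 1
    k_cut = min(max(k_cut, kmin + 1), kmin + _TABLE_CAP)

    ks = np.arange(kmin, k_cut + 1, dtype=np.float64)
    cdf = np.cumsum(ks ** (-gamma) / z)
    u = rng.random(n)
    out = kmin + np.searchsorted(cdf, u, side="left")

    overflow = np.nonzero(out > k_cut)[0]
    for i in overflow:
        out[i] = _ppf_bisect(u[i], gamma, kmin, z, lo=k_cut)
    return out.astype(np.int64)


def _ppf_bisect(u: float, gamma: float, kmin: int, z: float, lo: int) -> int:
    """Smallest k with CDF(k) >= u, via doubling + bisection on exact zeta."""

    def cdf(k: int) -> float:
        return 1.0 - zeta(gamma, k + 1) / z

    hi = lo
    while cdf(hi) < u:
        hi *= 2
    lo = max(kmin, lo)
    while lo < hi:
        mid = (lo + hi) // 2
        if cdf(mid) >= u:
            hi = mid
        else:
            lo = mid + 1
    return lo
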
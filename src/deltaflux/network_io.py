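"""Stoichiometric network representation and SBML input.

A metabolic network is held as an explicit list of metabolites and
reactions together with the m x n stoichiometric matrix S (rows =
metabolites, columns = reactions; negative entries for consumption,
positive for production).  Reversible reactions are split into a
forward/backward pair of irreversible reactions before any optimisation,
so that the moles-passed variables are all non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "SplitNetwork",
    "NetworkError",
    "SBMLFormatError",
    "load_sbml",
    "write_sbml",
    "split_reversible",
    "find_boundary_reactions",
    "block_boundary",
    "write_split_tsv",
]

#: default upper bound on moles passed when the model supplies none
DEFAULT_UPPER_BOUND = 1000.0

REVERSE_SUFFIX = "_R"


class NetworkError(ValueError):
    """Invalid network structure."""


class SBMLFormatError(NetworkError):
    """The SBML document could not be parsed into a network."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A directed reaction: substrates -> products.

    ``upper_bound`` caps the moles passed in the written direction;
    ``reverse_upper_bound`` (reversible reactions only) caps the backward
    direction and feeds the split.  Both are non-negative.
    """

    id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    reversible: bool = False
    upper_bound: float = DEFAULT_UPPER_BOUND
    reverse_upper_bound: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("reaction id must be non-empty")
        subs = {m for m, _ in self.substrates}
        prods = {m for m, _ in self.products}
        if subs & prods:
            raise NetworkError(
                f"reaction {self.id}: substrates and products must be disjoint "
                f"(shared: {sorted(subs & prods)})"
            )
        for mid, coeff in (*self.substrates, *self.products):
            if not coeff > 0:
                raise NetworkError(
                    f"reaction {self.id}: coefficient for {mid} must be > 0, got {coeff}"
                )
        if self.upper_bound < 0:
            raise NetworkError(f"reaction {self.id}: upper bound must be >= 0")
        if self.reverse_upper_bound is not None and self.reverse_upper_bound < 0:
            raise NetworkError(f"reaction {self.id}: reverse upper bound must be >= 0")


class MetabolicNetwork:
    """Ordered metabolite/reaction lists plus the stoichiometric matrix."""

    def __init__(self, metabolites: list[Metabolite], reactions: list[Reaction]):
        met_ids = [m.id for m in metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise NetworkError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise NetworkError(f"duplicate reaction ids: {dup}")
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.met_index: dict[str, int] = {m.id: i for i, m in enumerate(metabolites)}
        self.rxn_index: dict[str, int] = {r.id: j for j, r in enumerate(reactions)}
        self.S = self._build_matrix()

    def _build_matrix(self) -> sparse.csc_array:
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for mid, coeff in rxn.substrates:
                if mid not in self.met_index:
                    raise NetworkError(f"reaction {rxn.id} references unknown metabolite {mid}")
                rows.append(self.met_index[mid])
                cols.append(j)
                vals.append(-coeff)
            for mid, coeff in rxn.products:
                if mid not in self.met_index:
                    raise NetworkError(f"reaction {rxn.id} references unknown metabolite {mid}")
                rows.append(self.met_index[mid])
                cols.append(j)
                vals.append(coeff)
        m, n = len(self.metabolites), len(self.reactions)
        return sparse.csc_array(
            sparse.coo_array((vals, (rows, cols)), shape=(m, n), dtype=float)
        )

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MetabolicNetwork({self.n_metabolites} metabolites, "
            f"{self.n_reactions} reactions)"
        )


@dataclass
class SplitNetwork:
    """An all-irreversible network plus the forward/backward pairing.

    ``pair_map`` holds unordered index pairs (j_forward, j_backward) into
    ``base.reactions``; ``origin_map`` maps every split reaction id back to
    (original id, direction) with direction in {"forward", "reverse"}.
    """

    base: MetabolicNetwork
    pair_map: list[tuple[int, int]] = field(default_factory=list)
    origin_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    # convenience pass-throughs so the split network reads like a network
    @property
    def S(self) -> sparse.csc_array:
        return self.base.S

    @property
    def metabolites(self) -> list[Metabolite]:
        return self.base.metabolites

    @property
    def reactions(self) -> list[Reaction]:
        return self.base.reactions

    @property
    def met_index(self) -> dict[str, int]:
        return self.base.met_index

    @property
    def rxn_index(self) -> dict[str, int]:
        return self.base.rxn_index

    @property
    def n_metabolites(self) -> int:
        return self.base.n_metabolites

    @property
    def n_reactions(self) -> int:
        return self.base.n_reactions

    def upper_bounds(self) -> np.ndarray:
        return np.array([r.upper_bound for r in self.base.reactions], dtype=float)

    def origin(self, rxn_id: str) -> tuple[str, str]:
        return self.origin_map.get(rxn_id, (rxn_id, "forward"))


# ---------------------------------------------------------------------------
# SBML input / output (via python-libsbml)

def _sbml_bounds(reaction, model, default: float) -> tuple[float, float]:
    """Extract (lb, ub) from fbc attributes or legacy kinetic-law parameters."""
    lb = ub = None
    fbc = reaction.getPlugin("fbc")
    if fbc is not None:
        for getter, slot in ((fbc.getLowerFluxBound, 0), (fbc.getUpperFluxBound, 1)):
            pid = getter()
            if pid:
                param = model.getParameter(pid)
                if param is not None and param.isSetValue():
                    if slot == 0:
                        lb = param.getValue()
                    else:
                        ub = param.getValue()
    if lb is None and ub is None and reaction.isSetKineticLaw():
        kl = reaction.getKineticLaw()
        for i in range(kl.getNumParameters()):
            p = kl.getParameter(i)
            if p.getId() == "LOWER_BOUND" and p.isSetValue():
                lb = p.getValue()
            elif p.getId() == "UPPER_BOUND" and p.isSetValue():
                ub = p.getValue()
    if lb is None:
        lb = -default if reaction.getReversible() else 0.0
    if ub is None:
        ub = default
    return lb, ub


def load_sbml(
    path: str,
    *,
    u_default: float = DEFAULT_UPPER_BOUND,
    boundary_suffix: str | None = "_b",
    use_boundary_condition: bool = True,
) -> MetabolicNetwork:
    """Read an SBML (L2/L3) document into a :class:`MetabolicNetwork`.

    Species flagged ``boundaryCondition`` (when ``use_boundary_condition``)
    or whose id ends in ``boundary_suffix`` are marked as outside the
    modelled system.  Reaction flux bounds come from the fbc package or
    legacy kinetic-law LOWER_BOUND/UPPER_BOUND parameters; absent or
    infinite bounds fall back to ``u_default``.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise SBMLFormatError(
                    f"SBML parse failure in {path}: {err.getMessage().strip()} "
                    f"(line {err.getLine()})"
                )
    model = doc.getModel()
    if model is None:
        raise SBMLFormatError(f"{path}: document contains no model")
    if model.getNumReactions() == 0:
        raise NetworkError(f"{path}: model has zero reactions")

    metabolites = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        is_boundary = bool(use_boundary_condition and sp.getBoundaryCondition())
        if boundary_suffix and sp.getId().endswith(boundary_suffix):
            is_boundary = True
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=sp.getCompartment() or "",
                is_boundary=is_boundary,
            )
        )

    reactions = []
    for j in range(model.getNumReactions()):
        rxn = model.getReaction(j)
        # net duplicate listings; a species on both sides is netted to one side
        coeffs: dict[str, float] = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            coeffs[ref.getSpecies()] = coeffs.get(ref.getSpecies(), 0.0) - (
                ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0
            )
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            coeffs[ref.getSpecies()] = coeffs.get(ref.getSpecies(), 0.0) + (
                ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0
            )
        subs = tuple((m, -c) for m, c in coeffs.items() if c < 0)
        prods = tuple((m, c) for m, c in coeffs.items() if c > 0)
        reversible = bool(rxn.getReversible())
        lb, ub = _sbml_bounds(rxn, model, u_default)
        fwd_u = abs(ub) if math.isfinite(ub) and ub != 0 else u_default
        if ub == 0:
            fwd_u = 0.0
        rev_u = None
        if reversible:
            rev_u = abs(lb) if math.isfinite(lb) and lb != 0 else u_default
            if lb == 0:
                rev_u = 0.0
        reactions.append(
            Reaction(
                id=rxn.getId(),
                substrates=subs,
                products=prods,
                reversible=reversible,
                upper_bound=fwd_u,
                reverse_upper_bound=rev_u,
            )
        )
    return MetabolicNetwork(metabolites, reactions)


def write_sbml(net: MetabolicNetwork, path: str) -> None:
    """Write a network as SBML L3v1 (structure, reversibility, no kinetics)."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("model")
    comps = sorted({m.compartment or "c" for m in net.metabolites})
    for cid in comps:
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
    for met in net.metabolites:
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment or "c")
        sp.setBoundaryCondition(met.is_boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
    for rxn in net.reactions:
        r = model.createReaction()
        r.setId(rxn.id)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for mid, coeff in rxn.substrates:
            ref = r.createReactant()
            ref.setSpecies(mid)
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
        for mid, coeff in rxn.products:
            ref = r.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# reversible splitting and boundary handling

def split_reversible(
    net: MetabolicNetwork, *, u_default: float = DEFAULT_UPPER_BOUND
) -> SplitNetwork:
    """Split every reversible reaction into an irreversible forward/backward pair.

    The forward member keeps the original id; the backward member gets the
    ``_R`` suffix with substrates and products swapped.  Upper bounds follow
    the SBML flux bounds when present (|ub| forward, |lb| backward) and fall
    back to ``u_default``.
    """
    existing = {r.id for r in net.reactions}
    reactions: list[Reaction] = []
    origin_map: dict[str, tuple[str, str]] = {}
    pair_ids: list[tuple[str, str]] = []
    for rxn in net.reactions:
        if not rxn.reversible:
            reactions.append(rxn)
            origin_map[rxn.id] = (rxn.id, "forward")
            continue
        back_id = rxn.id + REVERSE_SUFFIX
        if back_id in existing:
            raise NetworkError(
                f"cannot split {rxn.id}: backward id {back_id} collides with an "
                f"existing reaction"
            )
        fwd = replace(rxn, reversible=False, reverse_upper_bound=None)
        rev_u = rxn.reverse_upper_bound if rxn.reverse_upper_bound is not None else u_default
        back = Reaction(
            id=back_id,
            substrates=rxn.products,
            products=rxn.substrates,
            reversible=False,
            upper_bound=rev_u,
        )
        reactions.extend([fwd, back])
        origin_map[fwd.id] = (rxn.id, "forward")
        origin_map[back.id] = (rxn.id, "reverse")
        pair_ids.append((fwd.id, back.id))
    base = MetabolicNetwork(net.metabolites, reactions)
    pair_map = [(base.rxn_index[a], base.rxn_index[b]) for a, b in pair_ids]
    return SplitNetwork(base=base, pair_map=pair_map, origin_map=origin_map)


def find_boundary_reactions(net: SplitNetwork) -> list[str]:
    """Reaction ids acting as sources/sinks.

    A reaction qualifies if its substrate or product set is empty, or if
    every substrate (or every product) is a boundary-flagged species.
    """
    boundary_mets = {m.id for m in net.metabolites if m.is_boundary}
    out = []
    for rxn in net.reactions:
        subs = {m for m, _ in rxn.substrates}
        prods = {m for m, _ in rxn.products}
        if not subs or not prods:
            out.append(rxn.id)
        elif subs <= boundary_mets or prods <= boundary_mets:
            out.append(rxn.id)
    return out


def block_boundary(
    net: SplitNetwork, exempt: list[str] | None = None
) -> tuple[SplitNetwork, list[str]]:
    """Set upper_bound = 0 on all boundary reactions not in ``exempt``.

    Blocking keeps the column in place (indices stay stable) but removes the
    reaction from any solution, so concentration changes cannot leak outside
    the modelled system.  Returns the modified network and the blocked ids.
    """
    exempt = list(exempt or [])
    known = set(net.rxn_index)
    unknown = [e for e in exempt if e not in known]
    if unknown:
        raise NetworkError(f"exempt reaction(s) not in network: {unknown}")
    exempt_set = set(exempt)
    to_block = [rid for rid in find_boundary_reactions(net) if rid not in exempt_set]
    block_set = set(to_block)
    reactions = [
        replace(r, upper_bound=0.0) if r.id in block_set else r
        for r in net.reactions
    ]
    base = MetabolicNetwork(net.metabolites, reactions)
    return (
        SplitNetwork(base=base, pair_map=list(net.pair_map), origin_map=dict(net.origin_map)),
        to_block,
    )


def write_split_tsv(net: SplitNetwork, path: str) -> None:
    """Debug dump: one row per split reaction with origin and bound."""
    with open(path, "w") as fh:
        fh.write("reaction_id\torigin_id\tdirection\tupper_bound\n")
        for r in net.reactions:
            orig, direction = net.origin(r.id)
            fh.write(f"{r.id}\t{orig}\t{direction}\t{r.upper_bound:g}\n")
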
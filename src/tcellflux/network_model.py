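"""Compartmentalized metabolic network model: types, parser, stoichiometry.

A model is defined in a plain-text dialect with a metabolite declaration
block and one reaction per line::

    [metabolites]
    GLC.x  carbons=6  balanced=no
    G6P.c  carbons=6  balanced=yes

    [reactions]
    hk:  GLC.x (abcdef) -> G6P.c (abcdef)
    pgi: G6P.c (abcdef) -> F6P.c (abcdef)  reversible

Compartment tags are mandatory suffixes on metabolite ids: ``.x``
(extracellular), ``.c`` (cytosol), ``.m`` (mitochondrion), ``.u``
(unlabeled external source) and ``.obs`` (measurement pool for
dual-compartment metabolites). Atom strings are lowercase letters,
left-to-right = carbon 1..n. A reaction id may appear on several lines
with identical stoichiometry but different atom maps; these are merged
into equally weighted atom-map *variants* (used for the rotational
symmetry of succinate/fumarate). Reactions may be tagged ``reversible``,
``kind=mixing`` or ``kind=dilution``.

Flux units are nmol per 1e6 cells per hour throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Metabolite",
    "ReactionTerm",
    "Reaction",
    "NetworkModel",
    "FluxState",
    "ModelSyntaxError",
    "ModelValidationError",
    "parse_model",
    "serialize_model",
    "stoichiometric_matrix",
    "free_flux_basis",
    "load_builtin_model",
]

COMPARTMENTS = {
    "x": "extracellular",
    "c": "cytosol",
    "m": "mitochondrion",
    "u": "unlabeled-source",
    "obs": "measurement-pool",
}


class ModelSyntaxError(ValueError):
    """Raised for malformed model text; carries line number context."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class ModelValidationError(ValueError):
    """Raised when a syntactically valid model violates an invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    n_carbons: int
    balanced: bool

    def __post_init__(self):
        if self.n_carbons < 0:
            raise ModelValidationError(f"{self.id}: n_carbons must be >= 0")
        if self.compartment not in COMPARTMENTS.values():
            raise ModelValidationError(
                f"{self.id}: unknown compartment {self.compartment!r}"
            )


@dataclass(frozen=True)
class ReactionTerm:
    """One molecule instance on one side of a reaction.

    ``atoms`` is the carbon label string for this instance; empty for
    zero-carbon species.
    """

    metabolite: str
    atoms: str

    @property
    def n_carbons(self) -> int:
        return len(self.atoms)


@dataclass
class Reaction:
    id: str
    reactants: List[ReactionTerm]
    products: List[ReactionTerm]
    reversible: bool = False
    kind: str = "chemical"  # chemical | transport | mixing | dilution
    # Additional equally weighted atom-map variants: each entry is a
    # (reactants, products) pair with the same species in the same order
    # but permuted atom letters.
    variants: List[Tuple[List[ReactionTerm], List[ReactionTerm]]] = field(
        default_factory=list
    )

    @property
    def all_variants(self) -> List[Tuple[List[ReactionTerm], List[ReactionTerm]]]:
        return [(self.reactants, self.products)] + self.variants

    def stoich(self) -> Dict[str, int]:
        """Net stoichiometric coefficient per metabolite id."""
        s: Dict[str, int] = {}
        for t in self.reactants:
            s[t.metabolite] = s.get(t.metabolite, 0) - 1
        for t in self.products:
            s[t.metabolite] = s.get(t.metabolite, 0) + 1
        return {k: v for k, v in s.items() if v != 0}


@dataclass
class NetworkModel:
    metabolites: Dict[str, Metabolite]
    reactions: List[Reaction]
    tracer_species: str = "GLC.x"

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def flux_reactions(self) -> List[Reaction]:
        """Reactions that carry a net flux (mixing reactions are virtual)."""
        return [r for r in self.reactions if r.kind != "mixing"]

    @property
    def reversible_ids(self) -> List[str]:
        return [r.id for r in self.flux_reactions if r.reversible]

    @property
    def mixing_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.kind == "mixing"]

    @property
    def balanced_ids(self) -> List[str]:
        return sorted(m.id for m in self.metabolites.values() if m.balanced)


@dataclass
class FluxState:
    """Net/exchange fluxes plus mixing fractions.

    ``net`` maps every flux-carrying reaction id to its net flux;
    ``exchange`` maps reversible reaction ids to a nonnegative exchange
    flux; ``mixing`` maps the measurement-pool metabolite id (e.g.
    ``PYR.obs``) to the cytosolic mixing fraction f in [0, 1]. Dilution
    parameters (unlabeled CO2 inflow, extracellular pyruvate exchange)
    live in ``net``/``exchange`` under their reaction ids.
    """

    net: Dict[str, float]
    exchange: Dict[str, float] = field(default_factory=dict)
    mixing: Dict[str, float] = field(default_factory=dict)

    def forward(self, rid: str) -> float:
        v = self.net[rid]
        return self.exchange.get(rid, 0.0) + max(v, 0.0)

    def backward(self, rid: str) -> float:
        v = self.net[rid]
        return self.exchange.get(rid, 0.0) + max(-v, 0.0)

    def validate(self, model: NetworkModel, tol: float = 1e-6) -> None:
        S, met_ids, rxn_ids = stoichiometric_matrix(model)
        v = np.array([self.net[r] for r in rxn_ids])
        resid = np.abs(S @ v)
        if resid.size and resid.max() > tol:
            i = int(np.argmax(resid))
            raise ModelValidationError(
                f"flux state violates balance at {met_ids[i]} "
                f"(|S v| = {resid.max():.3e})"
            )
        for rid, x in self.exchange.items():
            if x < 0:
                raise ModelValidationError(f"exchange flux {rid} < 0")
        for mid, f in self.mixing.items():
            if not 0.0 <= f <= 1.0:
                raise ModelValidationError(f"mixing fraction {mid} not in [0,1]")

    def copy(self) -> "FluxState":
        return FluxState(dict(self.net), dict(self.exchange), dict(self.mixing))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_MET_LINE = re.compile(
    r"^(?P<id>[A-Za-z][\w.]*)\s+carbons=(?P<nc>\d+)\s+balanced=(?P<bal>yes|no)$"
)
_TERM = re.compile(r"^(?P<met>[A-Za-z][\w.]*)(?:\s*\((?P<atoms>[a-z]*)\))?$")


def _split_compartment(met_id: str, line: Optional[int] = None) -> str:
    if "." not in met_id:
        raise ModelSyntaxError(
            f"metabolite id {met_id!r} lacks a compartment suffix", line
        )
    suffix = met_id.rsplit(".", 1)[1]
    if suffix not in COMPARTMENTS:
        raise ModelSyntaxError(
            f"metabolite id {met_id!r} has unknown compartment suffix "
            f"{suffix!r} (expected one of {sorted(COMPARTMENTS)})",
            line,
        )
    return COMPARTMENTS[suffix]


def _parse_side(text: str, lineno: int) -> List[ReactionTerm]:
    terms: List[ReactionTerm] = []
    for chunk in text.split("+"):
        chunk = chunk.strip()
        if not chunk:
            raise ModelSyntaxError("empty reaction term", lineno)
        m = _TERM.match(chunk)
        if not m:
            raise ModelSyntaxError(f"cannot parse term {chunk!r}", lineno)
        terms.append(ReactionTerm(m.group("met"), m.group("atoms") or ""))
    return terms


def parse_model(model_text: str, tracer_species: str = "GLC.x") -> NetworkModel:
    """Parse model text in the reaction-list dialect into a validated model."""
    metabolites: Dict[str, Metabolite] = {}
    reactions: List[Reaction] = []
    by_id: Dict[str, Reaction] = {}
    section = None
    for lineno, raw in enumerate(model_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if line not in ("[metabolites]", "[reactions]"):
                raise ModelSyntaxError(f"unknown section {line!r}", lineno)
            section = line.strip("[]")
            continue
        if section == "metabolites":
            m = _MET_LINE.match(line)
            if not m:
                raise ModelSyntaxError(f"cannot parse metabolite line {line!r}", lineno)
            mid = m.group("id")
            if mid in metabolites:
                raise ModelSyntaxError(f"duplicate metabolite {mid!r}", lineno)
            metabolites[mid] = Metabolite(
                id=mid,
                compartment=_split_compartment(mid, lineno),
                n_carbons=int(m.group("nc")),
                balanced=m.group("bal") == "yes",
            )
        elif section == "reactions":
            if ":" not in line:
                raise ModelSyntaxError("reaction line lacks 'id:'", lineno)
            rid, rest = line.split(":", 1)
            rid = rid.strip()
            reversible = False
            kind = "chemical"
            tokens = rest.split()
            flags = []
            while tokens and (tokens[-1] == "reversible" or tokens[-1].startswith("kind=")):
                flags.append(tokens.pop())
            rest = " ".join(tokens)
            for f in flags:
                if f == "reversible":
                    reversible = True
                else:
                    kind = f.split("=", 1)[1]
                    if kind not in ("chemical", "transport", "mixing", "dilution"):
                        raise ModelSyntaxError(f"unknown kind {kind!r}", lineno)
            if "->" not in rest:
                raise ModelSyntaxError("reaction line lacks '->'", lineno)
            left, right = rest.split("->", 1)
            reactants = _parse_side(left, lineno)
            products = _parse_side(right, lineno)
            if rid in by_id:
                base = by_id[rid]
                same = [t.metabolite for t in base.reactants] == [
                    t.metabolite for t in reactants
                ] and [t.metabolite for t in base.products] == [
                    t.metabolite for t in products
                ]
                if not same or base.reversible != reversible or base.kind != kind:
                    raise ModelSyntaxError(
                        f"duplicate reaction id {rid!r} with differing "
                        "stoichiometry or flags (variants must match)",
                        lineno,
                    )
                base.variants.append((reactants, products))
            else:
                rxn = Reaction(rid, reactants, products, reversible, kind)
                by_id[rid] = rxn
                reactions.append(rxn)
        else:
            raise ModelSyntaxError("content outside of a section", lineno)

    model = NetworkModel(metabolites, reactions, tracer_species)
    validate_model(model)
    return model


def validate_model(model: NetworkModel) -> None:
    """Check all structural invariants; raise ModelValidationError on failure."""
    for rxn in model.reactions:
        for rl, pl in rxn.all_variants:
            _check_atom_maps(model, rxn, rl, pl)
        if rxn.kind == "mixing":
            _check_mixing(model, rxn)
    _check_participation(model)
    if model.tracer_species not in model.metabolites:
        raise ModelValidationError(
            f"tracer species {model.tracer_species!r} not declared"
        )
    unreachable = _unreachable_measureables(model)
    if unreachable:
        raise ModelValidationError(
            "metabolites unreachable from tracer via atom maps: "
            + ", ".join(sorted(unreachable))
        )


def _check_atom_maps(
    model: NetworkModel, rxn: Reaction, reactants: Sequence[ReactionTerm],
    products: Sequence[ReactionTerm],
) -> None:
    for t in list(reactants) + list(products):
        if t.metabolite not in model.metabolites:
            raise ModelValidationError(f"{rxn.id}: undeclared metabolite {t.metabolite}")
        met = model.metabolites[t.metabolite]
        if len(t.atoms) != met.n_carbons:
            raise ModelValidationError(
                f"{rxn.id}: {t.metabolite} has {met.n_carbons} carbons but atom "
                f"string {t.atoms!r} has {len(t.atoms)}"
            )
    if rxn.kind == "mixing":
        return  # mixing reactions are virtual; exempt from conservation
    r_labels = "".join(t.atoms for t in reactants)
    p_labels = "".join(t.atoms for t in products)
    if sorted(r_labels) != sorted(p_labels):
        raise ModelValidationError(
            f"{rxn.id}: carbon-count mismatch — reactant atoms {r_labels!r} vs "
            f"product atoms {p_labels!r} (each label must appear exactly once "
            "per side; CO2 carbons must map to a CO2 species)"
        )
    if len(set(r_labels)) != len(r_labels):
        raise ModelValidationError(f"{rxn.id}: repeated atom label on reactant side")
    if len(set(p_labels)) != len(p_labels):
        raise ModelValidationError(f"{rxn.id}: repeated atom label on product side")


def _check_mixing(model: NetworkModel, rxn: Reaction) -> None:
    if len(rxn.reactants) != 2 or len(rxn.products) != 1:
        raise ModelValidationError(
            f"{rxn.id}: mixing reactions take exactly two pools to one "
            "measurement pool"
        )
    obs = rxn.products[0]
    if not obs.metabolite.endswith(".obs"):
        raise ModelValidationError(
            f"{rxn.id}: mixing product must be a .obs measurement pool"
        )
    ncs = {len(t.atoms) for t in rxn.reactants} | {len(obs.atoms)}
    if len(ncs) != 1:
        raise ModelValidationError(f"{rxn.id}: mixing pools differ in carbon count")
    for t in rxn.reactants:
        if t.atoms != obs.atoms:
            raise ModelValidationError(
                f"{rxn.id}: mixing atom maps must be identities"
            )


def _check_participation(model: NetworkModel) -> None:
    produced, consumed = set(), set()
    for rxn in model.reactions:
        if rxn.kind == "mixing":
            continue
        for t in rxn.reactants:
            consumed.add(t.metabolite)
            if rxn.reversible:
                produced.add(t.metabolite)
        for t in rxn.products:
            produced.add(t.metabolite)
            if rxn.reversible:
                consumed.add(t.metabolite)
    for m in model.metabolites.values():
        if m.balanced and (m.id not in produced or m.id not in consumed):
            raise ModelValidationError(
                f"balanced metabolite {m.id} lacks a producing or consuming reaction"
            )


def _unreachable_measureables(model: NetworkModel) -> List[str]:
    """Balanced/.obs metabolites with no atom-map path from the tracer."""
    reachable = {model.tracer_species}
    changed = True
    while changed:
        changed = False
        for rxn in model.reactions:
            for rl, pl in rxn.all_variants:
                pairs = [(rl, pl)]
                if rxn.reversible:
                    pairs.append((pl, rl))
                for src_side, dst_side in pairs:
                    if any(t.metabolite in reachable for t in src_side):
                        for t in dst_side:
                            if t.metabolite not in reachable and t.n_carbons > 0:
                                reachable.add(t.metabolite)
                                changed = True
    out = []
    for m in model.metabolites.values():
        if m.n_carbons == 0:
            continue
        if (m.balanced or m.compartment == "measurement-pool") and m.id not in reachable:
            out.append(m.id)
    return out


def serialize_model(model: NetworkModel) -> str:
    """Serialize to the same dialect in canonical (sorted) order."""
    lines = ["[metabolites]"]
    for mid in sorted(model.metabolites):
        m = model.metabolites[mid]
        lines.append(
            f"{m.id}  carbons={m.n_carbons}  balanced={'yes' if m.balanced else 'no'}"
        )
    lines.append("")
    lines.append("[reactions]")

    def fmt_side(terms: Sequence[ReactionTerm]) -> str:
        return " + ".join(
            f"{t.metabolite} ({t.atoms})" if t.atoms else t.metabolite for t in terms
        )

    for rxn in sorted(model.reactions, key=lambda r: r.id):
        for rl, pl in rxn.all_variants:
            flags = ""
            if rxn.reversible:
                flags += "  reversible"
            if rxn.kind != "chemical":
                flags += f"  kind={rxn.kind}"
            lines.append(f"{rxn.id}: {fmt_side(rl)} -> {fmt_side(pl)}{flags}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Stoichiometry
# ---------------------------------------------------------------------------


def stoichiometric_matrix(
    model: NetworkModel,
) -> Tuple[np.ndarray, List[str], List[str]]:
    """Net stoichiometric matrix over (balanced metabolites x flux reactions).

    Rows and columns are sorted by id. Mixing reactions are virtual
    (extraction artifacts) and excluded.
    """
    met_ids = model.balanced_ids
    rxn_ids = sorted(r.id for r in model.flux_reactions)
    row = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reaction(rid).stoich().items():
            if mid in row:
                S[row[mid], j] = coeff
    return S, met_ids, rxn_ids


def free_flux_basis(model: NetworkModel):
    """Free-flux parameterization of the null space of S.

    Uses exact rational RREF (sympy) so the pivot choice — and hence the
    identity of the free fluxes — is deterministic. Free fluxes are the
    non-pivot reaction columns; the returned map is linear:
    ``v_full = N @ v_free`` with ``S @ N == 0`` exactly.

    Returns ``(free_ids, rxn_ids, N)`` where ``N`` is
    (n_reactions x n_free) and ``rxn_ids`` gives the row order of the
    full flux vector.
    """
    import sympy

    S, _, rxn_ids = stoichiometric_matrix(model)
    Sr = sympy.Matrix([[Fraction(x).limit_denominator() for x in row] for row in S])
    rref, pivots = Sr.rref()
    n = len(rxn_ids)
    free_cols = [j for j in range(n) if j not in pivots]
    if not free_cols:
        raise ModelValidationError("no degrees of freedom (null space is empty)")
    N = np.zeros((n, len(free_cols)))
    for k, j in enumerate(free_cols):
        N[j, k] = 1.0
        for pi, pj in enumerate(pivots):
            N[pj, k] = -float(rref[pi, j])
    free_ids = [rxn_ids[j] for j in free_cols]
    return free_ids, rxn_ids, N


def load_builtin_model() -> NetworkModel:
    """Parse and return the bundled T-cell central-carbon network."""
    from importlib import resources

    text = resources.files("tcellflux.data").joinpath("tcell_model.txt").read_text()
    return parse_model(text)
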
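"""Steady-state mass-isotopomer simulation.

Two independent routes are provided:

* :func:`emu_decompose` / :func:`simulate_mids` — decomposition of the
  network into elementary metabolite units (EMUs) and a cascade of small
  dense linear solves, one per EMU size level. This is the fast path used
  by the fitting code.
* :func:`brute_force_isotopomer_mids` — direct fixed-point solution of
  the full isotopomer balance equations, feasible only for small total
  carbon counts. It shares no machinery with the EMU path beyond the
  model itself and serves as a verification oracle.

Simulation happens in *tracer-atom space*: natural isotope abundance is
not modelled here (it is applied/removed by :mod:`tcellflux.ms_processing`),
so unlabeled inputs are exactly M0 = 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import comb

from .network_model import FluxState, NetworkModel, ReactionTerm

__all__ = [
    "EMU",
    "EMUSystem",
    "TracerSpec",
    "EMUSimulationError",
    "emu_decompose",
    "simulate_mids",
    "brute_force_isotopomer_mids",
    "system_to_dot",
]

#: floor applied to reversible exchange fluxes when assembling systems
EXCHANGE_FLOOR = 1e-9
#: floor applied to every directional flux (keeps level systems nonsingular)
FLUX_FLOOR = 1e-12


class EMUSimulationError(RuntimeError):
    pass


@dataclass(frozen=True, order=True)
class EMU:
    """A subset of one metabolite's carbon atoms (1-based, sorted)."""

    metabolite: str
    atoms: Tuple[int, ...]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("EMU atom subset must be non-empty")
        if tuple(sorted(set(self.atoms))) != self.atoms:
            raise ValueError(f"EMU atoms must be sorted and unique: {self.atoms}")
        if self.atoms[0] < 1:
            raise ValueError("EMU atoms are 1-based")

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:  # e.g. PYR.c[1,2,3]
        return f"{self.metabolite}[{','.join(map(str, self.atoms))}]"


@dataclass(frozen=True)
class TracerSpec:
    """Isotopic composition of the tracer substrate.

    ``components`` maps labeling patterns (strings of '0'/'1', one char
    per carbon) to mole fractions; ``purity`` is the per-atom isotopic
    purity of labeled positions. Default: 75% [U-13C]glucose (15 mM
    tracer added into 5 mM unlabeled medium glucose).
    """

    metabolite: str = "GLC.x"
    components: Tuple[Tuple[str, float], ...] = (("111111", 0.75), ("000000", 0.25))
    purity: float = 0.99

    def __post_init__(self):
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tracer mole fractions sum to {total}, not 1")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        ncs = {len(p) for p, _ in self.components}
        if len(ncs) != 1:
            raise ValueError("tracer patterns must have equal length")

    @property
    def n_carbons(self) -> int:
        return len(self.components[0][0])

    def emu_mid(self, atoms: Sequence[int]) -> np.ndarray:
        """MID of a tracer EMU over the given (1-based) atom subset."""
        n = len(atoms)
        mid = np.zeros(n + 1)
        for pattern, frac in self.components:
            n_lab = sum(1 for a in atoms if pattern[a - 1] == "1")
            # each labeled atom is 13C with probability = purity
            for k in range(n_lab + 1):
                mid[k] += frac * comb(n_lab, k, exact=True) * (
                    self.purity ** k
                ) * ((1 - self.purity) ** (n_lab - k))
        return mid

    def isotopomer_distribution(self) -> np.ndarray:
        """Full isotopomer distribution tensor, shape (2,)*n_carbons."""
        n = self.n_carbons
        dist = np.zeros((2,) * n)
        for pattern, frac in self.components:
            t = np.array(frac)
            for ch in pattern:
                p1 = self.purity if ch == "1" else 0.0
                t = np.multiply.outer(t, np.array([1 - p1, p1]))
            dist += t
        return dist


# ---------------------------------------------------------------------------
# Structural transitions (shared by both simulation routes)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Transition:
    """One directional, single-variant realization of a reaction."""

    reaction: str
    direction: int  # +1 forward, -1 backward
    weight: float  # 1 / number of atom-map variants
    reactants: Tuple[ReactionTerm, ...]
    products: Tuple[ReactionTerm, ...]


def _structural_transitions(model: NetworkModel) -> List[_Transition]:
    out: List[_Transition] = []
    for rxn in model.flux_reactions:
        variants = rxn.all_variants
        w = 1.0 / len(variants)
        for rl, pl in variants:
            out.append(_Transition(rxn.id, +1, w, tuple(rl), tuple(pl)))
            if rxn.reversible:
                out.append(_Transition(rxn.id, -1, w, tuple(pl), tuple(rl)))
    return out


def _direction_fluxes(model: NetworkModel, flux: FluxState) -> Dict[Tuple[str, int], float]:
    """Directional flux per (reaction id, direction), with floors applied."""
    d: Dict[Tuple[str, int], float] = {}
    for rxn in model.flux_reactions:
        net = flux.net[rxn.id]
        if rxn.reversible:
            exch = max(flux.exchange.get(rxn.id, 0.0), EXCHANGE_FLOOR)
            d[(rxn.id, +1)] = max(exch + max(net, 0.0), FLUX_FLOOR)
            d[(rxn.id, -1)] = max(exch + max(-net, 0.0), FLUX_FLOOR)
        else:
            d[(rxn.id, +1)] = max(net, FLUX_FLOOR)
    return d


# ---------------------------------------------------------------------------
# EMU decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _EMUReaction:
    reaction: str
    direction: int
    weight: float
    sources: Tuple[EMU, ...]  # condensation if len > 1
    target: EMU


@dataclass
class EMUSystem:
    """Levelled EMU balance systems for a fixed set of target EMUs."""

    model: NetworkModel
    targets: Tuple[EMU, ...]
    producers: Dict[EMU, List[_EMUReaction]]
    input_emus: List[EMU]
    levels: List[List[EMU]]  # unknown EMUs grouped by size, ascending
    #: measurement-pool EMU -> (cytosolic EMU, mitochondrial EMU, obs metabolite)
    obs_specs: Dict[EMU, Tuple[EMU, EMU, str]] = field(default_factory=dict)
    _compiled: Optional["_CompiledSystem"] = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_unknowns(self) -> int:
        return sum(len(lv) for lv in self.levels)

    def compiled(self) -> "_CompiledSystem":
        if self._compiled is None:
            self._compiled = _CompiledSystem(self)
        return self._compiled


class _CompiledLevel:
    """Integer-indexed assembly structure for one EMU size level."""

    __slots__ = ("n", "size", "slots", "diag_i", "diag_dp", "diag_w",
                 "off_i", "off_j", "off_dp", "off_w", "b_entries")

    def __init__(self, system: "EMUSystem", level: List[EMU], slot_of, dp_of):
        self.n = len(level)
        self.size = level[0].size
        self.slots = np.array([slot_of[e] for e in level])
        idx = {e: i for i, e in enumerate(level)}
        diag_i, diag_dp, diag_w = [], [], []
        off_i, off_j, off_dp, off_w = [], [], [], []
        b_entries: List[Tuple[int, int, float, Tuple[int, ...]]] = []
        for i, emu in enumerate(level):
            for er in system.producers[emu]:
                dp = dp_of[(er.reaction, er.direction)]
                diag_i.append(i)
                diag_dp.append(dp)
                diag_w.append(er.weight)
                if len(er.sources) == 1 and er.sources[0] in idx:
                    off_i.append(i)
                    off_j.append(idx[er.sources[0]])
                    off_dp.append(dp)
                    off_w.append(er.weight)
                else:
                    b_entries.append(
                        (i, dp, er.weight, tuple(slot_of[s] for s in er.sources))
                    )
        self.diag_i = np.array(diag_i)
        self.diag_dp = np.array(diag_dp)
        self.diag_w = np.array(diag_w)
        self.off_i = np.array(off_i, dtype=int)
        self.off_j = np.array(off_j, dtype=int)
        self.off_dp = np.array(off_dp, dtype=int)
        self.off_w = np.array(off_w)
        self.b_entries = b_entries


class _CompiledSystem:
    """Flux-independent index structure for fast repeated simulation."""

    def __init__(self, system: "EMUSystem"):
        self.system = system
        all_emus = list(system.input_emus)
        for lv in system.levels:
            all_emus.extend(lv)
        self.slot_of: Dict[EMU, int] = {e: i for i, e in enumerate(all_emus)}
        self.emus = all_emus
        # directional flux slots
        self.dirpairs: List[Tuple[str, int]] = []
        for rxn in system.model.flux_reactions:
            self.dirpairs.append((rxn.id, +1))
            if rxn.reversible:
                self.dirpairs.append((rxn.id, -1))
        dp_of = {p: i for i, p in enumerate(self.dirpairs)}
        self.levels = [
            _CompiledLevel(system, lv, self.slot_of, dp_of) for lv in system.levels
        ]
        self.input_slots = [self.slot_of[e] for e in system.input_emus]
        self._input_cache: Dict[TracerSpec, List[np.ndarray]] = {}

    def direction_flux_vector(self, flux: FluxState) -> np.ndarray:
        d = _direction_fluxes(self.system.model, flux)
        return np.array([d[p] for p in self.dirpairs])

    def input_mids(self, tracer: TracerSpec) -> List[np.ndarray]:
        cached = self._input_cache.get(tracer)
        if cached is None:
            cached = [
                _input_mid(e, self.system.model, tracer)
                for e in self.system.input_emus
            ]
            self._input_cache[tracer] = cached
        return cached


def _producing_emu_reactions(
    model: NetworkModel, transitions: List[_Transition], emu: EMU
) -> List[_EMUReaction]:
    """All EMU reactions producing ``emu`` across transitions."""
    out = []
    for t in transitions:
        for p in t.products:
            if p.metabolite != emu.metabolite:
                continue
            letters = [p.atoms[a - 1] for a in emu.atoms]
            # locate each letter among the reactant instances
            per_reactant: Dict[int, List[int]] = {}
            for letter in letters:
                found = False
                for ri, rterm in enumerate(t.reactants):
                    j = rterm.atoms.find(letter)
                    if j >= 0:
                        per_reactant.setdefault(ri, []).append(j + 1)
                        found = True
                        break
                if not found:  # pragma: no cover - blocked by model validation
                    raise EMUSimulationError(
                        f"atom {letter!r} of {emu} untraceable in reaction "
                        f"{t.reaction}"
                    )
            sources = tuple(
                sorted(
                    EMU(t.reactants[ri].metabolite, tuple(sorted(pos)))
                    for ri, pos in per_reactant.items()
                )
            )
            out.append(_EMUReaction(t.reaction, t.direction, t.weight, sources, emu))
    return out


def emu_decompose(model: NetworkModel, targets: Sequence[EMU]) -> EMUSystem:
    """Minimal EMU network reaching ``targets`` from source metabolites.

    Source metabolites (unbalanced pools, e.g. the tracer and unlabeled
    dilution species) terminate the traversal; measurement pools (.obs)
    are expanded through their mixing reaction into the two contributing
    compartment pools.
    """
    for e in targets:
        met = model.metabolites.get(e.metabolite)
        if met is None:
            raise EMUSimulationError(f"unknown metabolite in target {e}")
        if e.atoms[-1] > met.n_carbons:
            raise EMUSimulationError(f"target {e} exceeds {met.n_carbons} carbons")

    transitions = _structural_transitions(model)
    producers: Dict[EMU, List[_EMUReaction]] = {}
    obs_specs: Dict[EMU, Tuple[EMU, EMU, str]] = {}
    input_emus: List[EMU] = []
    seen: set = set()
    queue: List[EMU] = list(targets)
    while queue:
        emu = queue.pop()
        if emu in seen:
            continue
        seen.add(emu)
        met = model.metabolites[emu.metabolite]
        if met.compartment == "measurement-pool":
            mix = next(
                (
                    r
                    for r in model.mixing_reactions
                    if r.products[0].metabolite == emu.metabolite
                ),
                None,
            )
            if mix is None:
                raise EMUSimulationError(f"no mixing reaction produces {emu.metabolite}")
            parents = tuple(EMU(t.metabolite, emu.atoms) for t in mix.reactants)
            obs_specs[emu] = (parents[0], parents[1], emu.metabolite)
            queue.extend(parents)
            continue
        if not met.balanced:
            input_emus.append(emu)
            continue
        prods = _producing_emu_reactions(model, transitions, emu)
        if not prods:
            raise EMUSimulationError(
                f"EMU {emu} has no producing reaction (untraceable to tracer)"
            )
        producers[emu] = prods
        for er in prods:
            queue.extend(er.sources)

    unknowns = sorted(producers, key=lambda e: (e.size, e))
    levels: List[List[EMU]] = []
    for size, group in itertools.groupby(unknowns, key=lambda e: e.size):
        levels.append(list(group))
    return EMUSystem(
        model=model,
        targets=tuple(targets),
        producers=producers,
        input_emus=sorted(set(input_emus)),
        levels=levels,
        obs_specs=obs_specs,
    )


def _input_mid(emu: EMU, model: NetworkModel, tracer: TracerSpec) -> np.ndarray:
    if emu.metabolite == tracer.metabolite:
        return tracer.emu_mid(emu.atoms)
    mid = np.zeros(emu.size + 1)
    mid[0] = 1.0  # unlabeled in tracer-atom space
    return mid


def simulate_mids(
    system: EMUSystem, flux: FluxState, tracer: TracerSpec
) -> Dict[EMU, np.ndarray]:
    """Solve the levelled EMU systems and return MIDs for all system EMUs.

    Measurement-pool EMUs are returned as the mixing-fraction-weighted
    combination f * MID_first_pool + (1 - f) * MID_second_pool, with f
    taken from ``flux.mixing`` keyed by the .obs metabolite id.
    """
    comp = system.compiled()
    mids = _simulate_slots(comp, flux, tracer)
    known: Dict[EMU, np.ndarray] = {e: mids[i] for e, i in comp.slot_of.items()}
    for obs_emu, (emu_a, emu_b, obs_met) in system.obs_specs.items():
        f = flux.mixing.get(obs_met)
        if f is None:
            raise EMUSimulationError(f"no mixing fraction provided for {obs_met}")
        known[obs_emu] = f * known[emu_a] + (1 - f) * known[emu_b]
    return known


def _simulate_slots(
    comp: "_CompiledSystem", flux: FluxState, tracer: TracerSpec
) -> List[np.ndarray]:
    """Solve the level cascade, returning MIDs indexed by compiled slot."""
    system = comp.system
    dv = comp.direction_flux_vector(flux)
    mids: List[Optional[np.ndarray]] = [None] * len(comp.emus)
    for slot, mid in zip(comp.input_slots, comp.input_mids(tracer)):
        mids[slot] = mid
    for lv in comp.levels:
        A = np.zeros((lv.n, lv.n))
        np.add.at(A, (lv.diag_i, lv.diag_i), lv.diag_w * dv[lv.diag_dp])
        if lv.off_i.size:
            np.add.at(A, (lv.off_i, lv.off_j), -(lv.off_w * dv[lv.off_dp]))
        b = np.zeros((lv.n, lv.size + 1))
        for i, dp, w, src_slots in lv.b_entries:
            mid = mids[src_slots[0]]
            for s in src_slots[1:]:
                mid = np.convolve(mid, mids[s])
            b[i] += (w * dv[dp]) * mid
        try:
            X = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise EMUSimulationError(
                f"singular EMU system at level {lv.size} (metabolites: "
                f"{sorted({e.metabolite for e in system.levels[comp.levels.index(lv)]})})"
            ) from exc
        for slot, row in zip(lv.slots, X):
            mids[slot] = row
    return mids


# ---------------------------------------------------------------------------
# Brute-force full-isotopomer oracle
# ---------------------------------------------------------------------------


def brute_force_isotopomer_mids(
    model: NetworkModel,
    flux: FluxState,
    tracer: TracerSpec,
    tol: float = 1e-14,
    max_iter: int = 200_000,
    size_guard: int = 2 ** 20,
) -> Dict[str, np.ndarray]:
    """Solve the full isotopomer balances by damped fixed-point iteration.

    Returns the mass-isotopomer distribution of every balanced metabolite
    and every measurement pool. Independent of the EMU machinery; used to
    verify :func:`simulate_mids`.
    """
    balanced = [
        m for m in model.metabolites.values() if m.balanced and m.n_carbons > 0
    ]
    total = sum(2 ** m.n_carbons for m in balanced)
    if total > size_guard:
        raise EMUSimulationError(
            f"isotopomer space too large for brute force ({total} > {size_guard})"
        )
    transitions = _structural_transitions(model)
    dirflux = _direction_fluxes(model, flux)

    # fixed distributions for source (unbalanced) pools, as (2,)*n tensors
    fixed: Dict[str, np.ndarray] = {}
    for m in model.metabolites.values():
        if m.balanced or m.n_carbons == 0 or m.compartment == "measurement-pool":
            continue
        if m.id == tracer.metabolite:
            fixed[m.id] = tracer.isotopomer_distribution()
        else:
            t = np.zeros((2,) * m.n_carbons)
            t[(0,) * m.n_carbons] = 1.0
            fixed[m.id] = t

    x: Dict[str, np.ndarray] = {}
    for m in balanced:
        t = np.zeros((2,) * m.n_carbons)
        t[(0,) * m.n_carbons] = 1.0
        x[m.id] = t

    # pre-index inflow routes per balanced metabolite
    inflows: Dict[str, List[Tuple[float, List[Tuple[str, List[int], List[int]]]]]] = {
        m.id: [] for m in balanced
    }
    for t in transitions:
        v = t.weight * dirflux[(t.reaction, t.direction)]
        for p in t.products:
            if p.metabolite not in inflows or not p.atoms:
                continue
            # route: per reactant instance, (metabolite, source axes, product axes)
            route: List[Tuple[str, List[int], List[int]]] = []
            for rterm in t.reactants:
                src_axes, dst_axes = [], []
                for j, letter in enumerate(rterm.atoms):
                    k = p.atoms.find(letter)
                    if k >= 0:
                        src_axes.append(j)
                        dst_axes.append(k)
                if src_axes:
                    route.append((rterm.metabolite, src_axes, dst_axes))
            inflows[p.metabolite].append((v, route))

    for it in range(max_iter):
        delta = 0.0
        new_x: Dict[str, np.ndarray] = {}
        for m in balanced:
            total_in = 0.0
            acc = np.zeros((2,) * m.n_carbons)
            for v, route in inflows[m.id]:
                total_in += v
                tensor = np.array(1.0)
                dst_order: List[int] = []
                for met, src_axes, dst_axes in route:
                    src = fixed[met] if met in fixed else x[met]
                    # marginal over src_axes, in listed order
                    drop = tuple(a for a in range(src.ndim) if a not in src_axes)
                    marg = src.sum(axis=drop) if drop else src
                    kept_sorted = sorted(src_axes)
                    perm = [kept_sorted.index(a) for a in src_axes]
                    if marg.ndim > 1:
                        marg = np.transpose(marg, perm)
                    tensor = np.multiply.outer(tensor, marg)
                    dst_order.extend(dst_axes)
                # tensor axes follow dst_order; rearrange to product order
                perm = [dst_order.index(k) for k in range(m.n_carbons)]
                acc += v * np.transpose(tensor, perm)
            nx = acc / total_in
            delta = max(delta, float(np.abs(nx - x[m.id]).max()))
            new_x[m.id] = nx
        x = new_x
        if delta < tol:
            break
    else:  # pragma: no cover
        raise EMUSimulationError(
            f"isotopomer fixed point did not converge (last delta {delta:.2e})"
        )

    def to_mid(tensor: np.ndarray) -> np.ndarray:
        n = tensor.ndim
        mid = np.zeros(n + 1)
        flat = tensor.reshape(-1)
        for i, val in enumerate(flat):
            mid[bin(i).count("1")] += val
        return mid

    mids = {mid_id: to_mid(t) for mid_id, t in x.items()}
    # measurement pools: mixing-fraction-weighted combination
    for rxn in model.mixing_reactions:
        obs = rxn.products[0].metabolite
        f = flux.mixing.get(obs)
        if f is None:
            continue
        a, b_ = (t.metabolite for t in rxn.reactants)
        src_a = mids.get(a, to_mid(fixed[a]) if a in fixed else None)
        src_b = mids.get(b_, to_mid(fixed[b_]) if b_ in fixed else None)
        mids[obs] = f * src_a + (1 - f) * src_b
    return mids


def system_to_dot(system: EMUSystem) -> str:
    """DOT-format dump of the EMU graph for debugging/inspection."""
    lines = ["digraph emu {", '  rankdir="LR";']
    for emu, prods in system.producers.items():
        for er in prods:
            src = " + ".join(str(s) for s in er.sources)
            arrow = f'  "{src}" -> "{emu}" [label="{er.reaction}"];'
            lines.append(arrow)
    for obs, (a, b, _) in system.obs_specs.items():
        lines.append(f'  "{a}" -> "{obs}" [style=dashed, label="mix f"];')
        lines.append(f'  "{b}" -> "{obs}" [style=dashed, label="mix 1-f"];')
    lines.append("}")
    return "\n".join(lines)
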
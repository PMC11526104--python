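"""Flux estimation by variance-weighted least squares.

The residual vector stacks, for every measured fragment, the corrected
mass fractions M0..M(n-1) (the last fraction of each normalized MID is
redundant and dropped) and, for every measured exchange rate, the signed
net flux of its transport reaction — each standardized by its SD.

Net fluxes are parameterized on the null space of the stoichiometric
matrix (free fluxes), exchange fluxes in the compactified coordinate
u = v/(v+c) with c = 100, and mixing fractions directly in [0, 1].
Multi-start bounded trust-region least squares provides the global
search; goodness of fit is a two-sided chi-square test on the SSR, and
per-flux confidence intervals are found by profiling the SSR against a
chi-square threshold (3.841 at 95%, 1 dof).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2

from .emu_engine import (
    EMU,
    EMUSystem,
    TracerSpec,
    _simulate_slots,
    emu_decompose,
)
from .exchange_rates import ExchangeRate
from .ms_processing import FragmentDef
from .network_model import FluxState, NetworkModel, free_flux_basis

__all__ = [
    "MeasurementSet",
    "FitConfig",
    "FitResult",
    "FluxComparison",
    "FluxProblem",
    "DEFAULT_RATE_MAP",
    "DEFAULT_FIXED_EXCHANGES",
    "objective",
    "fit",
    "confidence_interval",
    "profile_ssr_at",
    "compare_conditions",
    "result_to_json",
    "fluxes_to_dot",
]

#: measured metabolite -> (transport reaction, sign) such that
#: measured rate (uptake positive) = sign * net flux, for the bundled model
DEFAULT_RATE_MAP: Dict[str, Tuple[str, float]] = {
    "GLC": ("hk", 1.0),
    "GLN": ("gln_upt", 1.0),
    "PYR": ("pyrx", 1.0),
    "LAC": ("lac_out", -1.0),
}

#: exchange fluxes of the bundled model with no effect on any measured
#: labeling (single-source pools); held fixed so the chi-square dof count
#: reflects only effective parameters
DEFAULT_FIXED_EXCHANGES: Dict[str, float] = {
    "g3pdh": 25.0,
    "ldh": 100.0,
    "alt": 30.0,
    "sdh": 30.0,
    "got": 50.0,
}

EXCHANGE_C = 100.0  # compactification constant for u = v/(v+c)
PENALTY_WEIGHT = 1e3  # soft penalty on negative irreversible net fluxes


@dataclass
class MeasurementSet:
    """Corrected MIDs + exchange rates for one condition."""

    mids: Dict[str, Tuple[np.ndarray, np.ndarray]]  # fragment -> (mid, sd)
    rates: Dict[str, ExchangeRate]
    condition: str = ""
    rate_map: Mapping[str, Tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATE_MAP)
    )


@dataclass
class FitConfig:
    n_starts: int = 50
    seed: int = 20241030
    net_bounds: Tuple[float, float] = (-500.0, 500.0)
    exchange_ub: float = 1e4
    exchange_init: Tuple[float, float] = (1e-3, 1e3)  # log-uniform start range
    ftol: float = 1e-9
    xtol: float = 1e-8
    max_nfev: int = 500
    #: iteration budget for the coarse multi-start pass; the best
    #: ``refine_top`` starts are then polished at full budget
    coarse_nfev: int = 40
    refine_top: int = 3
    gof_alpha: float = 0.05
    gof_two_sided: bool = True
    ci_level: float = 0.95
    fixed_exchanges: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EXCHANGES)
    )

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not 0 < self.gof_alpha < 1 or not 0 < self.ci_level < 1:
            raise ValueError("significance/confidence levels must be in (0,1)")


class FluxProblem:
    """Parameterization + residual machinery for one (model, data) pair."""

    def __init__(
        self,
        model: NetworkModel,
        measurements: MeasurementSet,
        tracer: TracerSpec,
        fragments: Mapping[str, FragmentDef],
        config: FitConfig,
    ):
        self.model = model
        self.measurements = measurements
        self.tracer = tracer
        self.config = config
        self.free_ids, self.rxn_ids, self.N = free_flux_basis(model)
        self._rxn_index = {r: i for i, r in enumerate(self.rxn_ids)}
        self.fragments = {
            fid: fragments[fid] for fid in sorted(measurements.mids)
        }
        self.frag_emus: Dict[str, EMU] = {
            fid: EMU(f.metabolite, f.atoms) for fid, f in self.fragments.items()
        }
        self.system: EMUSystem = emu_decompose(
            model, sorted(set(self.frag_emus.values()))
        )
        fixed = set(config.fixed_exchanges)
        self.fit_exchange_ids = [
            r for r in model.reversible_ids if r not in fixed
        ]
        self.fit_exchange_ids.sort()
        self.mixing_ids = sorted(
            r.products[0].metabolite for r in model.mixing_reactions
        )
        self.irreversible_ids = [
            r.id for r in model.flux_reactions if not r.reversible
        ]
        # parameter layout
        self.n_free = len(self.free_ids)
        self.n_exch = len(self.fit_exchange_ids)
        self.n_mix = len(self.mixing_ids)
        self.n_params = self.n_free + self.n_exch + self.n_mix
        for met in measurements.rates:
            if met not in measurements.rate_map:
                raise ValueError(f"no rate-to-reaction mapping for {met!r}")
        for fid in measurements.mids:
            if fid not in fragments:
                raise ValueError(f"unknown fragment id {fid!r}")
        self.n_residuals = sum(
            f.n_skeleton for f in self.fragments.values()
        ) + len(measurements.rates)
        self.dof = self.n_residuals - self.n_params
        # slot-indexed fragment lookups into the compiled EMU cascade
        comp = self.system.compiled()
        self._frag_slots: Dict[str, Tuple] = {}
        for fid, emu in self.frag_emus.items():
            if emu in self.system.obs_specs:
                a, b, obs_met = self.system.obs_specs[emu]
                self._frag_slots[fid] = (comp.slot_of[a], comp.slot_of[b], obs_met)
            else:
                self._frag_slots[fid] = (comp.slot_of[emu], None, None)

    # -- parameter packing ------------------------------------------------

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lb_net, ub_net = self.config.net_bounds
        u_max = self.config.exchange_ub / (self.config.exchange_ub + EXCHANGE_C)
        lo = np.concatenate(
            [np.full(self.n_free, lb_net), np.zeros(self.n_exch), np.zeros(self.n_mix)]
        )
        hi = np.concatenate(
            [np.full(self.n_free, ub_net), np.full(self.n_exch, u_max),
             np.ones(self.n_mix)]
        )
        return lo, hi

    def param_names(self) -> List[str]:
        return (
            [f"net:{r}" for r in self.free_ids]
            + [f"exch:{r}" for r in self.fit_exchange_ids]
            + [f"mix:{m}" for m in self.mixing_ids]
        )

    def sample_start(self, rng: np.random.Generator) -> np.ndarray:
        lb, ub = self.config.net_bounds
        free = rng.uniform(lb, ub, self.n_free)
        lo_e, hi_e = self.config.exchange_init
        v = np.exp(rng.uniform(np.log(lo_e), np.log(hi_e), self.n_exch))
        u = v / (v + EXCHANGE_C)
        mix = rng.uniform(0.0, 1.0, self.n_mix)
        return np.concatenate([free, u, mix])

    def rate_informed_start(self) -> np.ndarray:
        """Deterministic start: least-norm free fluxes reproducing the
        measured rates, mid-range exchange fluxes and mixing fractions."""
        rows, vals = [], []
        for met in sorted(self.measurements.rates):
            rid, sign = self.measurements.rate_map[met]
            rows.append(sign * self.net_flux_row(rid))
            vals.append(self.measurements.rates[met].rate)
        if rows:
            A = np.vstack(rows)
            free, *_ = np.linalg.lstsq(A, np.array(vals), rcond=None)
        else:
            free = np.zeros(self.n_free)
        lb, ub = self.config.net_bounds
        free = np.clip(free, lb, ub)
        u0 = 10.0 / (10.0 + EXCHANGE_C)
        return np.concatenate(
            [free, np.full(self.n_exch, u0), np.full(self.n_mix, 0.5)]
        )

    def flux_state(self, params: np.ndarray) -> FluxState:
        x = params[: self.n_free]
        v = self.N @ x
        net = {r: float(v[i]) for i, r in enumerate(self.rxn_ids)}
        exchange = {k: float(val) for k, val in self.config.fixed_exchanges.items()}
        for k, u in zip(self.fit_exchange_ids,
                        params[self.n_free : self.n_free + self.n_exch]):
            u = min(float(u), 1.0 - 1e-12)
            exchange[k] = EXCHANGE_C * u / (1.0 - u)
        mixing = {
            m: float(f)
            for m, f in zip(self.mixing_ids, params[self.n_free + self.n_exch :])
        }
        return FluxState(net, exchange, mixing)

    def pack_state(self, state: FluxState) -> np.ndarray:
        """Parameter vector reproducing ``state`` (inverse of flux_state)."""
        free = np.array([state.net[r] for r in self.free_ids])
        u = np.array(
            [
                state.exchange.get(r, 0.0)
                / (state.exchange.get(r, 0.0) + EXCHANGE_C)
                for r in self.fit_exchange_ids
            ]
        )
        mix = np.array([state.mixing[m] for m in self.mixing_ids])
        return np.concatenate([free, u, mix])

    def net_flux_row(self, reaction_id: str) -> np.ndarray:
        """Linear map from free fluxes to one reaction's net flux."""
        return self.N[self._rxn_index[reaction_id]]

    # -- residuals --------------------------------------------------------

    def residuals(
        self, params: np.ndarray, with_table: bool = False
    ) -> Tuple[np.ndarray, List[dict]]:
        """Measurement residuals (sim - meas)/sd; optionally a table."""
        state = self.flux_state(params)
        slots = _simulate_slots(self.system.compiled(), state, self.tracer)
        res: List[float] = []
        table: List[dict] = []
        for fid, frag in self.fragments.items():
            meas, sd = self.measurements.mids[fid]
            slot_a, slot_b, obs_met = self._frag_slots[fid]
            if slot_b is None:
                mid = slots[slot_a]
            else:
                f = state.mixing[obs_met]
                mid = f * slots[slot_a] + (1 - f) * slots[slot_b]
            n = frag.n_skeleton  # drop redundant last fraction
            block = (mid[:n] - meas[:n]) / sd[:n]
            res.extend(block)
            if with_table:
                for k, r in enumerate(block):
                    table.append(
                        {
                            "kind": "mid",
                            "name": f"{fid}:M{k}",
                            "measured": float(meas[k]),
                            "simulated": float(mid[k]),
                            "sd": float(sd[k]),
                            "residual": float(r),
                        }
                    )
        for met in sorted(self.measurements.rates):
            rate = self.measurements.rates[met]
            rid, sign = self.measurements.rate_map[met]
            simulated = sign * state.net[rid]
            r = (simulated - rate.rate) / rate.sd
            res.append(r)
            if with_table:
                table.append(
                    {
                        "kind": "rate",
                        "name": f"rate:{met}",
                        "measured": float(rate.rate),
                        "simulated": float(simulated),
                        "sd": float(rate.sd),
                        "residual": float(r),
                    }
                )
        return np.asarray(res), table

    def solver_residuals(self, params: np.ndarray) -> np.ndarray:
        """Residuals + soft penalties keeping irreversible nets >= 0."""
        res, _ = self.residuals(params)
        state = self.flux_state(params)
        pen = np.array(
            [PENALTY_WEIGHT * max(0.0, -state.net[r]) for r in self.irreversible_ids]
        )
        return np.concatenate([res, pen])

    def ssr(self, params: np.ndarray) -> float:
        res, _ = self.residuals(params)
        return float(res @ res)


def objective(
    params: np.ndarray,
    problem: FluxProblem,
) -> Tuple[float, np.ndarray]:
    """SSR and measurement residual vector at ``params``."""
    res, _ = problem.residuals(params)
    return float(res @ res), res


@dataclass
class FitResult:
    problem: FluxProblem
    params: np.ndarray
    state: FluxState
    ssr: float
    dof: int
    chi2_lo: float
    chi2_hi: float
    passed: bool
    start_ssrs: List[float]
    residual_table: List[dict]
    seed: int
    n_starts: int
    ci: Dict[str, Tuple[float, float, str]] = field(default_factory=dict)


def _local_fit(problem: FluxProblem, x0: np.ndarray,
               extra: Optional[Callable[[np.ndarray], np.ndarray]] = None,
               max_nfev: Optional[int] = None):
    cfg = problem.config
    lo, hi = problem.bounds()
    x_scale = np.concatenate(
        [
            np.full(problem.n_free, 50.0),
            np.full(problem.n_exch, 0.1),
            np.full(problem.n_mix, 0.2),
        ]
    )

    def fun(p):
        base = problem.solver_residuals(p)
        if extra is not None:
            return np.concatenate([base, np.atleast_1d(extra(p))])
        return base

    return least_squares(
        fun,
        np.clip(x0, lo, hi),
        bounds=(lo, hi),
        method="trf",
        x_scale=x_scale,
        ftol=cfg.ftol,
        xtol=cfg.xtol,
        gtol=1e-10,
        max_nfev=max_nfev or cfg.max_nfev,
    )


def fit(
    model: NetworkModel,
    measurements: MeasurementSet,
    tracer: TracerSpec,
    fragments: Mapping[str, FragmentDef],
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Multi-start weighted least-squares flux estimation.

    Runs ``config.n_starts`` bounded trust-region optimizations from
    seeded random initial points and keeps the lowest-SSR solution
    (earliest start wins ties within 1e-9). Deterministic given the seed.
    """
    config = config or FitConfig()
    problem = FluxProblem(model, measurements, tracer, fragments, config)
    if problem.dof <= 0:
        raise ValueError(
            f"model not identifiable from measurements "
            f"(residuals {problem.n_residuals} <= parameters {problem.n_params})"
        )
    logger = logging.getLogger(__name__)
    t_start = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    coarse: List[Tuple[float, int, np.ndarray]] = []
    start_ssrs: List[float] = []
    failures: List[str] = []
    for k in range(config.n_starts):
        # start 0 is deterministic and rate-informed; the rest are random
        x0 = problem.rate_informed_start() if k == 0 else problem.sample_start(rng)
        try:
            sol = _local_fit(problem, x0, max_nfev=config.coarse_nfev)
            ssr = problem.ssr(sol.x)
        except Exception as exc:  # singular simulation etc.
            start_ssrs.append(float("nan"))
            failures.append(f"start {k}: {exc}")
            logger.info("start %d: failed (%s)", k, exc)
            continue
        start_ssrs.append(ssr)
        logger.info("start %d: ssr=%.6g (%s)", k, ssr, sol.message)
        coarse.append((ssr, k, sol.x))
    if not coarse:
        raise RuntimeError(
            "all optimization starts failed:\n" + "\n".join(failures)
        )
    coarse.sort(key=lambda t: (t[0], t[1]))
    best = None
    for ssr_c, k, x_c in coarse[: max(1, config.refine_top)]:
        try:
            sol = _local_fit(problem, x_c)
            ssr = problem.ssr(sol.x)
        except Exception as exc:  # pragma: no cover
            failures.append(f"refine of start {k}: {exc}")
            continue
        start_ssrs[k] = ssr
        if best is None or ssr < best[0] - 1e-9:
            best = (ssr, sol.x)
    if best is None:
        raise RuntimeError(
            "all refinement passes failed:\n" + "\n".join(failures)
        )
    ssr, params = best
    logger.info(
        "best ssr=%.6g after %d starts, %.2f s wall",
        ssr, config.n_starts, time.perf_counter() - t_start,
    )
    res, table = problem.residuals(params, with_table=True)
    alpha = config.gof_alpha
    if config.gof_two_sided:
        lo_q = chi2.ppf(alpha / 2, problem.dof)
        hi_q = chi2.ppf(1 - alpha / 2, problem.dof)
    else:
        lo_q, hi_q = 0.0, chi2.ppf(1 - alpha, problem.dof)
    return FitResult(
        problem=problem,
        params=params,
        state=problem.flux_state(params),
        ssr=ssr,
        dof=problem.dof,
        chi2_lo=float(lo_q),
        chi2_hi=float(hi_q),
        passed=bool(lo_q <= ssr <= hi_q),
        start_ssrs=start_ssrs,
        residual_table=table,
        seed=config.seed,
        n_starts=config.n_starts,
    )


# ---------------------------------------------------------------------------
# Profile (SSR-sensitivity) confidence intervals
# ---------------------------------------------------------------------------


def _flux_value_fn(problem: FluxProblem, flux_id: str) -> Callable[[np.ndarray], float]:
    if flux_id.startswith("exch:"):
        rid = flux_id.split(":", 1)[1]
        j = problem.n_free + problem.fit_exchange_ids.index(rid)

        def val(p):
            u = min(float(p[j]), 1 - 1e-12)
            return EXCHANGE_C * u / (1 - u)

        return val
    if flux_id.startswith("mix:"):
        mid = flux_id.split(":", 1)[1]
        j = problem.n_free + problem.n_exch + problem.mixing_ids.index(mid)
        return lambda p: float(p[j])
    row = problem.net_flux_row(flux_id)
    return lambda p: float(row @ p[: problem.n_free])


def profile_ssr_at(fit_result: FitResult, flux_id: str, value: float,
                   x_warm: Optional[np.ndarray] = None) -> Tuple[float, np.ndarray]:
    """Minimum SSR with the named flux constrained to ``value``.

    Used both by the CI search and directly by coverage checks (the flux
    lies inside the CI iff this SSR is below SSR_min + threshold).
    """
    problem = fit_result.problem
    val = _flux_value_fn(problem, flux_id)
    scale = max(abs(val(fit_result.params)), 1.0)
    eps = 1e-4 * scale

    def constraint(p):
        return (val(p) - value) / eps

    x0 = fit_result.params if x_warm is None else x_warm
    sol = _local_fit(problem, x0, extra=constraint)
    return problem.ssr(sol.x), sol.x


def confidence_interval(
    fit_result: FitResult,
    flux_id: str,
    level: Optional[float] = None,
) -> Tuple[float, float, str]:
    """SSR-profile confidence interval for one flux.

    Steps the flux away from its optimum (re-optimizing all other
    parameters) until the SSR exceeds SSR_min + chi2 quantile (3.841 at
    95%), then bisects to 0.5% of the flux magnitude (floor 0.01).
    Returns (lower, upper, flags); directions that fail to bracket
    within the search range are reported at the range limit with a flag.
    """
    problem = fit_result.problem
    level = level if level is not None else problem.config.ci_level
    threshold = fit_result.ssr + float(chi2.ppf(level, 1))
    val = _flux_value_fn(problem, flux_id)
    v0 = val(fit_result.params)
    tol = max(0.005 * abs(v0), 0.01)
    step0 = max(0.05 * abs(v0), 10 * tol)
    flags = []
    out = {}
    for direction in (-1.0, +1.0):
        inside_t, inside_x = v0, fit_result.params
        outside_t = None
        step = step0
        for _ in range(40):
            t = inside_t + direction * step
            ssr, x = profile_ssr_at(fit_result, flux_id, t, x_warm=inside_x)
            if ssr > threshold:
                outside_t = t
                break
            inside_t, inside_x = t, x
            step *= 2.0
        if outside_t is None:
            flags.append(f"{'lower' if direction < 0 else 'upper'}:unbounded")
            out[direction] = inside_t
            continue
        lo_t, hi_t = inside_t, outside_t
        while abs(hi_t - lo_t) > tol:
            mid = 0.5 * (lo_t + hi_t)
            ssr, x = profile_ssr_at(fit_result, flux_id, mid, x_warm=inside_x)
            if ssr > threshold:
                hi_t = mid
            else:
                lo_t, inside_x = mid, x
        out[direction] = 0.5 * (lo_t + hi_t)
    lower, upper = out[-1.0], out[1.0]
    flag = ";".join(flags)
    fit_result.ci[flux_id] = (float(lower), float(upper), flag)
    return float(lower), float(upper), flag


# ---------------------------------------------------------------------------
# Condition comparison and serialization
# ---------------------------------------------------------------------------


@dataclass
class FluxComparison:
    condition_a: str
    condition_b: str
    table: List[dict]

    def distinguishable(self, reaction_id: str) -> Optional[bool]:
        for row in self.table:
            if row["reaction"] == reaction_id:
                return row["distinguishable"]
        raise KeyError(reaction_id)


def compare_conditions(fit_a: FitResult, fit_b: FitResult) -> FluxComparison:
    """Per-reaction net-flux differences with CI-overlap verdicts."""
    if fit_a.problem.rxn_ids != fit_b.problem.rxn_ids:
        raise ValueError("fits use different models")
    table = []
    for rid in fit_a.problem.rxn_ids:
        a, b = fit_a.state.net[rid], fit_b.state.net[rid]
        ci_a = fit_a.ci.get(rid)
        ci_b = fit_b.ci.get(rid)
        disjoint = None
        if ci_a is not None and ci_b is not None:
            disjoint = bool(ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0])
        table.append(
            {
                "reaction": rid,
                "net_a": a,
                "net_b": b,
                "difference": b - a,
                "ci_a": list(ci_a[:2]) if ci_a else None,
                "ci_b": list(ci_b[:2]) if ci_b else None,
                "distinguishable": disjoint,
            }
        )
    return FluxComparison(
        fit_a.problem.measurements.condition,
        fit_b.problem.measurements.condition,
        table,
    )


def result_to_json(result: FitResult) -> str:
    """Deterministic JSON serialization of a fit result."""
    fluxes = {}
    for rid in result.problem.rxn_ids:
        entry = {"net": result.state.net[rid]}
        if rid in result.state.exchange:
            entry["exchange"] = result.state.exchange[rid]
        if rid in result.ci:
            lo, hi, flag = result.ci[rid]
            entry["ci_lo"], entry["ci_hi"] = lo, hi
            if flag:
                entry["ci_flag"] = flag
        fluxes[rid] = entry
    payload = {
        "condition": result.problem.measurements.condition,
        "fluxes": fluxes,
        "mixing": result.state.mixing,
        "ssr": result.ssr,
        "dof": result.dof,
        "chi2_lo": result.chi2_lo,
        "chi2_hi": result.chi2_hi,
        "passed": result.passed,
        "n_starts": result.n_starts,
        "seed": result.seed,
        "start_ssrs": result.start_ssrs,
        "residuals": result.residual_table,
        "free_fluxes": {
            name: float(v)
            for name, v in zip(result.problem.param_names(), result.params)
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def fluxes_to_dot(result: FitResult) -> str:
    """Flux-map export: reaction graph with net-flux edge labels."""
    lines = ["digraph fluxmap {", '  rankdir="LR";']
    for rxn in result.problem.model.flux_reactions:
        v = result.state.net[rxn.id]
        width = max(0.3, min(6.0, 6.0 * abs(v) / 300.0))
        for t_r in rxn.reactants:
            for t_p in rxn.products:
                lines.append(
                    f'  "{t_r.metabolite}" -> "{t_p.metabolite}" '
                    f'[label="{rxn.id}: {v:.1f}", penwidth={width:.2f}];'
                )
    lines.append("}")
    return "\n".join(lines)
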
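"""Synthetic tracer experiments with known ground truth.

Generates complete experiment bundles (MID tables with natural-abundance
contributions re-applied, spent-media time courses, growth curves) from a
ground-truth flux state, so the whole pipeline — correction, rate
estimation, fitting, confidence intervals — is testable without any
external data. Two presets mirror the qualitative contrast of the study:
``WT-like`` (glycolysis/lactate high) and ``KO-like`` (OxPhos/TCA high
with elevated glutamine and pyruvate uptake).

The design emulates the source experiment: 75% [U-13C]glucose (15 mM
tracer into 5 mM unlabeled glucose), three biological replicates,
sampling at 0/6/24 h, isotopic steady state at the fitted timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .emu_engine import EMU, TracerSpec, emu_decompose, simulate_mids
from .exchange_rates import ExchangeRate, GrowthCurve, integrate_cell_density
from .flux_fitting import DEFAULT_RATE_MAP, MeasurementSet
from .ms_processing import (
    FragmentDef,
    MIDMeasurement,
    correction_matrix,
    load_fragment_library,
    write_mid_table,
)
from .network_model import FluxState, NetworkModel, load_builtin_model

__all__ = [
    "ScenarioSpec",
    "SyntheticExperiment",
    "PRESETS",
    "make_scenario",
    "generate",
    "true_fragment_mids",
    "make_fit_measurements",
]

_FIXED_EXCH = {"g3pdh": 25.0, "ldh": 100.0, "alt": 30.0, "sdh": 30.0, "got": 50.0}

#: ground-truth flux regimes (order-of-magnitude choices, labelled
#: "-like": the study's flux values are not machine-readable)
PRESETS: Dict[str, dict] = {
    "WT-like": {
        "net": {
            "hk": 150.0, "pgi": 150.0, "pfk": 150.0, "ald": 150.0, "tpi": 150.0,
            "gapdh": 300.0, "eno": 300.0, "pk": 300.0, "g3pdh": 0.0,
            "ldh": 250.0, "lac_out": 250.0, "alt": 0.0, "pyrx": 10.0,
            "mpc": 60.0, "pdh": 50.0, "cs": 50.0, "idh": 50.0, "akgdh": 75.0,
            "sdh": 75.0, "fh": 75.0, "mdh": 70.0, "pc": 15.0, "me": 5.0,
            "got": 35.0, "asp_out": 35.0, "gdh": -25.0, "gls": 35.0, "gs": 5.0,
            "glu_out": 5.0, "gln_upt": 30.0, "co2d": 20.0, "co2_out": 185.0,
        },
        "exchange": {"pyrx": 20.0, "gdh": 150.0, "fh": 80.0, "mdh": 60.0,
                     **_FIXED_EXCH},
        "mixing": {"PYR.obs": 0.6},
    },
    "KO-like": {
        "net": {
            "hk": 50.0, "pgi": 50.0, "pfk": 50.0, "ald": 50.0, "tpi": 50.0,
            "gapdh": 100.0, "eno": 100.0, "pk": 100.0, "g3pdh": 0.0,
            "ldh": 25.0, "lac_out": 25.0, "alt": 0.0, "pyrx": 35.0,
            "mpc": 110.0, "pdh": 100.0, "cs": 100.0, "idh": 100.0,
            "akgdh": 145.0, "sdh": 145.0, "fh": 145.0, "mdh": 135.0,
            "pc": 20.0, "me": 10.0, "got": 55.0, "asp_out": 55.0,
            "gdh": -45.0, "gls": 65.0, "gs": 5.0, "glu_out": 15.0,
            "gln_upt": 60.0, "co2d": 20.0, "co2_out": 355.0,
        },
        "exchange": {"pyrx": 30.0, "gdh": 180.0, "fh": 90.0, "mdh": 70.0,
                     **_FIXED_EXCH},
        "mixing": {"PYR.obs": 0.55},
    },
}

#: initial medium concentrations, mM (tracer experiment: 5 mM medium
#: glucose + 15 mM added [U-13C]glucose)
DEFAULT_MEDIA_C0 = {"GLC": 20.0, "GLN": 4.0, "PYR": 1.0, "LAC": 0.0}


@dataclass
class ScenarioSpec:
    name: str
    model: NetworkModel
    truth: FluxState
    tracer: TracerSpec = field(default_factory=TracerSpec)
    mid_sd: float = 0.003  # mol fraction, per raw mass fraction
    rate_cv: float = 0.05
    conc_cv: float = 0.02
    replicates: int = 3
    timepoints: Tuple[float, ...] = (0.0, 6.0, 24.0)
    n0_e6: float = 0.5
    doubling_h: float = 18.0
    volume_ml: float = 1.0
    media_c0: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MEDIA_C0))
    extra_masses: int = 2
    seed: int = 20241030

    def __post_init__(self):
        if self.mid_sd <= 0 or self.rate_cv < 0 or self.conc_cv < 0:
            raise ValueError("noise settings must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        self.truth.validate(self.model)

    def growth_curve(self) -> GrowthCurve:
        mu = np.log(2.0) / self.doubling_h
        ts = np.asarray(self.timepoints)
        return GrowthCurve(ts, self.n0_e6 * np.exp(mu * ts))

    def true_rates(self) -> Dict[str, float]:
        """Signed uptake(+)/secretion(-) rates implied by the truth."""
        return {
            met: sign * self.truth.net[rid]
            for met, (rid, sign) in DEFAULT_RATE_MAP.items()
        }


@dataclass
class SyntheticExperiment:
    mids_csv: str
    media_csv: str
    growth_csv: str
    truth: dict


def make_scenario(preset: str, seed: int = 20241030, **overrides) -> ScenarioSpec:
    """Build a ScenarioSpec for a named preset ('WT-like' or 'KO-like')."""
    if preset not in PRESETS:
        raise KeyError(
            f"unknown preset {preset!r} (available: {sorted(PRESETS)})"
        )
    model = overrides.pop("model", None) or load_builtin_model()
    p = PRESETS[preset]
    truth = FluxState(dict(p["net"]), dict(p["exchange"]), dict(p["mixing"]))
    spec = ScenarioSpec(name=preset, model=model, truth=truth, seed=seed)
    if overrides:
        spec = replace(spec, **overrides)
    return spec


def true_fragment_mids(
    spec: ScenarioSpec, fragments: Optional[Mapping[str, FragmentDef]] = None
) -> Dict[str, np.ndarray]:
    """Noise-free skeleton MIDs (tracer-atom space) per fragment."""
    fragments = fragments or load_fragment_library()
    emus = {fid: EMU(f.metabolite, f.atoms) for fid, f in sorted(fragments.items())}
    system = emu_decompose(spec.model, sorted(set(emus.values())))
    sim = simulate_mids(system, spec.truth, spec.tracer)
    return {fid: sim[e] for fid, e in emus.items()}


def generate(
    spec: ScenarioSpec, fragments: Optional[Mapping[str, FragmentDef]] = None
) -> SyntheticExperiment:
    """Full synthetic experiment: raw MID CSV (natural abundance applied,
    Gaussian noise, truncated at 0 and renormalized), media and growth
    CSVs, and the ground-truth sidecar record. Deterministic per seed."""
    fragments = fragments or load_fragment_library()
    rng = np.random.default_rng(spec.seed)
    skeleton = true_fragment_mids(spec, fragments)

    measurements: List[MIDMeasurement] = []
    for fid in sorted(fragments):
        frag = fragments[fid]
        C = correction_matrix(frag)
        raw = C @ skeleton[fid]
        n_keep = frag.n_skeleton + 1 + spec.extra_masses
        raw = raw[: min(n_keep, len(raw))]
        for rep in range(1, spec.replicates + 1):
            for t in spec.timepoints[1:]:
                noisy = raw + rng.normal(0.0, spec.mid_sd, raw.shape)
                noisy = np.clip(noisy, 0.0, None)
                noisy /= noisy.sum()
                measurements.append(
                    MIDMeasurement(
                        fragment_id=fid,
                        fractions=noisy,
                        sd=np.full(raw.shape, spec.mid_sd),
                        replicate=f"r{rep}",
                        time_h=t,
                    )
                )
    mids_csv = write_mid_table(measurements)

    growth = spec.growth_curve()
    rates = spec.true_rates()
    media_rows = []
    for met in sorted(spec.media_c0):
        c0 = spec.media_c0[met]
        rate = rates.get(met, 0.0)
        for rep in range(1, spec.replicates + 1):
            for t in spec.timepoints:
                if t == 0:
                    c = c0
                else:
                    consumed = rate * integrate_cell_density(growth, 0.0, t)
                    c = c0 - consumed / (1000.0 * spec.volume_ml)
                noisy = max(c * (1.0 + rng.normal(0.0, spec.conc_cv)), 0.0) if c > 0 else 0.0
                media_rows.append(
                    {
                        "metabolite": met,
                        "replicate": f"r{rep}",
                        "time_h": t,
                        "conc_mM": noisy,
                        "volume_ml": spec.volume_ml,
                    }
                )
    media_df = pd.DataFrame(
        media_rows, columns=["metabolite", "replicate", "time_h", "conc_mM", "volume_ml"]
    )
    growth_df = pd.DataFrame(
        {"time_h": growth.times_h, "cells_e6": growth.cells_e6}
    )

    truth = {
        "preset": spec.name,
        "seed": spec.seed,
        "net": {k: spec.truth.net[k] for k in sorted(spec.truth.net)},
        "exchange": {k: spec.truth.exchange[k] for k in sorted(spec.truth.exchange)},
        "mixing": dict(sorted(spec.truth.mixing.items())),
        "rates": {k: rates[k] for k in sorted(rates)},
        "noise": {
            "mid_sd": spec.mid_sd,
            "rate_cv": spec.rate_cv,
            "conc_cv": spec.conc_cv,
        },
        "tracer": {
            "metabolite": spec.tracer.metabolite,
            "components": [[p, f] for p, f in spec.tracer.components],
            "purity": spec.tracer.purity,
        },
    }
    import io

    media_buf, growth_buf = io.StringIO(), io.StringIO()
    media_df.to_csv(media_buf, index=False, float_format="%.12g")
    growth_df.to_csv(growth_buf, index=False, float_format="%.12g")
    return SyntheticExperiment(
        mids_csv=mids_csv,
        media_csv=media_buf.getvalue(),
        growth_csv=growth_buf.getvalue(),
        truth=truth,
    )


def make_fit_measurements(
    spec: ScenarioSpec,
    fragments: Optional[Mapping[str, FragmentDef]] = None,
    noise: bool = True,
    rate_sd_floor: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> MeasurementSet:
    """Calibration-grade measurement set built directly in skeleton space.

    Adds independent Gaussian noise (SD = ``spec.mid_sd``) to the
    independent mass fractions M0..M(n-1) of each fragment (the last
    fraction absorbs the normalization constraint) and Gaussian noise of
    SD ``rate_cv * |rate|`` to each rate, with exactly those SDs recorded
    for weighting — so the fitted SSR is chi-square distributed to
    first order. Bypasses the natural-abundance/file round-trip, which is
    exercised separately by :func:`generate`.
    """
    fragments = fragments or load_fragment_library()
    rng = rng or np.random.default_rng(spec.seed)
    skeleton = true_fragment_mids(spec, fragments)
    mids: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for fid in sorted(skeleton):
        x = skeleton[fid].copy()
        n = len(x) - 1
        if noise:
            x[:n] += rng.normal(0.0, spec.mid_sd, n)
            x[n] = 1.0 - x[:n].sum()
        mids[fid] = (x, np.full(n + 1, spec.mid_sd))
    rates: Dict[str, ExchangeRate] = {}
    for met, r in sorted(spec.true_rates().items()):
        sd = max(spec.rate_cv * abs(r), rate_sd_floor)
        value = r + (rng.normal(0.0, sd) if noise else 0.0)
        rates[met] = ExchangeRate(met, value, sd, n=spec.replicates)
    return MeasurementSet(mids=mids, rates=rates, condition=spec.name)
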
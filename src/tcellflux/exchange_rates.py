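"""Cell-normalized uptake/secretion rates from spent-media time courses.

Rates are obtained by through-origin least-squares regression of
cumulative consumption (nmol) against integrated viable-cell density
(1e6 cell·h), pooling biological replicates. Sign convention: uptake
positive, secretion negative. Units: nmol / (1e6 cells) / h.

Evaporation and spontaneous degradation (relevant for glutamine) are not
modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MediaTimeCourse",
    "GrowthCurve",
    "ExchangeRate",
    "integrate_cell_density",
    "estimate_rate",
    "read_media_table",
    "read_growth_table",
    "rates_to_json",
    "rates_from_json",
]


@dataclass
class MediaTimeCourse:
    metabolite: str
    times_h: np.ndarray
    conc_mM: np.ndarray
    volume_ml: float = 1.0
    replicate: str = "r1"

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_mM = np.asarray(self.conc_mM, dtype=float)
        if self.times_h[0] != 0 or (np.diff(self.times_h) <= 0).any():
            raise ValueError(
                f"{self.metabolite}/{self.replicate}: times must strictly "
                "increase from 0"
            )
        if (self.conc_mM < 0).any():
            raise ValueError(f"{self.metabolite}: negative concentration")


@dataclass
class GrowthCurve:
    times_h: np.ndarray
    cells_e6: np.ndarray  # viable cells x 1e6 per culture

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.cells_e6 = np.asarray(self.cells_e6, dtype=float)
        if (self.cells_e6 <= 0).any():
            raise ValueError("cell counts must be > 0")
        if (np.diff(self.times_h) <= 0).any():
            raise ValueError("growth times must strictly increase")


@dataclass
class ExchangeRate:
    metabolite: str
    rate: float  # nmol/(1e6 cells)/h; + uptake, - secretion
    sd: float
    n: int = 0


def integrate_cell_density(growth: GrowthCurve, t0: float, t1: float) -> float:
    """Integral of N(t) dt over [t0, t1] in 1e6 cell·hours.

    Exponential interpolation between consecutive samples, with the exact
    closed form N0 (e^{mu dt} - 1)/mu per segment (linear fallback for
    |mu| < 1e-9).
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    ts, ns = growth.times_h, growth.cells_e6
    if t0 < ts[0] or t1 > ts[-1]:
        raise ValueError("integration interval outside growth curve range")
    total = 0.0
    for i in range(len(ts) - 1):
        a, b = max(ts[i], t0), min(ts[i + 1], t1)
        if b <= a:
            continue
        dt_seg = ts[i + 1] - ts[i]
        mu = np.log(ns[i + 1] / ns[i]) / dt_seg
        n_a = ns[i] * np.exp(mu * (a - ts[i]))
        if abs(mu) < 1e-9:
            total += n_a * (b - a)
        else:
            total += n_a * (np.exp(mu * (b - a)) - 1.0) / mu
    return total


def estimate_rate(
    media: Sequence[MediaTimeCourse], growth: GrowthCurve
) -> ExchangeRate:
    """Rate from through-origin regression of consumption vs cell-hours.

    ``media`` holds the replicate time courses of one metabolite.
    Consumption at time t is (C(0) - C(t)) * V in nmol (mM * mL = umol;
    x1000). The slope SD comes from the regression residuals.
    """
    if isinstance(media, MediaTimeCourse):
        media = [media]
    mets = {m.metabolite for m in media}
    if len(mets) != 1:
        raise ValueError(f"mixed metabolites in rate estimate: {sorted(mets)}")
    xs, ys = [], []
    for tc in media:
        for t, c in zip(tc.times_h[1:], tc.conc_mM[1:]):
            xs.append(integrate_cell_density(growth, 0.0, t))
            ys.append((tc.conc_mM[0] - c) * tc.volume_ml * 1000.0)
    x = np.asarray(xs)
    y = np.asarray(ys)
    sxx = float(x @ x)
    if sxx <= 0:
        raise ValueError("zero integrated cell density (singular regressor)")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    dof = len(x) - 1
    var = float(resid @ resid) / dof / sxx if dof > 0 else 0.0
    return ExchangeRate(
        metabolite=mets.pop(), rate=slope, sd=float(np.sqrt(var)), n=len(x)
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_media_table(path_or_buf) -> Dict[str, List[MediaTimeCourse]]:
    """Media CSV (metabolite, replicate, time_h, conc_mM, volume_ml) ->
    time courses grouped per metabolite."""
    df = pd.read_csv(path_or_buf)
    required = ["metabolite", "replicate", "time_h", "conc_mM", "volume_ml"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"media table missing columns: {missing}")
    out: Dict[str, List[MediaTimeCourse]] = {}
    for (met, rep), grp in df.groupby(["metabolite", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        out.setdefault(met, []).append(
            MediaTimeCourse(
                metabolite=met,
                times_h=grp["time_h"].to_numpy(),
                conc_mM=grp["conc_mM"].to_numpy(),
                volume_ml=float(grp["volume_ml"].iloc[0]),
                replicate=str(rep),
            )
        )
    return out


def read_growth_table(path_or_buf) -> GrowthCurve:
    """Growth CSV (time_h, cells_e6) -> GrowthCurve."""
    df = pd.read_csv(path_or_buf).sort_values("time_h")
    return GrowthCurve(df["time_h"].to_numpy(), df["cells_e6"].to_numpy())


def rates_to_json(rates: Mapping[str, ExchangeRate]) -> str:
    payload = {
        met: {"rate": r.rate, "sd": r.sd, "n": r.n}
        for met, r in sorted(rates.items())
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def rates_from_json(text: str) -> Dict[str, ExchangeRate]:
    payload = json.loads(text)
    return {
        met: ExchangeRate(met, d["rate"], d["sd"], d.get("n", 0))
        for met, d in payload.items()
    }
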
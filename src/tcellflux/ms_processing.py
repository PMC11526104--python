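"""GC-MS fragment handling and natural-abundance correction.

Measured MIDs of MOX-TBDMS-derivatized fragments contain mass shifts
contributed by the natural isotopes of every atom in the detected ion
that is not a tracer-attributable skeleton carbon (derivatization
carbons, H, N, O, Si, S, P). :func:`correction_matrix` builds the
convolution matrix ``C`` with ``raw = C @ skeleton_mid``;
:func:`correct_mid` inverts it by non-negative least squares.

The bundled fragment library (full-skeleton ions for the eleven fitted
metabolites) is a plausible reconstruction — the monitored SIM ions of
the source study are unpublished.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "FragmentDef",
    "MIDMeasurement",
    "DEFAULT_ABUNDANCES",
    "parse_formula",
    "correction_matrix",
    "natural_mid",
    "correct_mid",
    "read_mid_table",
    "write_mid_table",
    "average_replicates",
    "load_fragment_library",
]

#: natural isotope mass-shift distributions (IUPAC), per element
DEFAULT_ABUNDANCES: Dict[str, Tuple[float, ...]] = {
    "C": (1 - 0.0107, 0.0107),
    "H": (1 - 0.000115, 0.000115),
    "N": (1 - 0.00364, 0.00364),
    "O": (1 - 0.00038 - 0.00205, 0.00038, 0.00205),
    "Si": (1 - 0.04685 - 0.03092, 0.04685, 0.03092),
    "S": (1 - 0.0075 - 0.0425, 0.0075, 0.0425),
    "P": (1.0,),
}

#: conventional GC-MS accuracy floor on mol fractions
SD_FLOOR = 0.003

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Dict[str, int]:
    """Parse an elemental formula such as ``C11H26NO2Si2``."""
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {pos}")
        pos = m.end()
        if not m.group(1):
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r}")
    return counts


@dataclass(frozen=True)
class FragmentDef:
    """A monitored GC-MS ion: skeleton atoms plus derivatization formula."""

    id: str
    metabolite: str
    atoms: Tuple[int, ...]  # 1-based parent carbons included in the ion
    formula: Mapping[str, int]  # element counts of the whole detected ion

    def __post_init__(self):
        n_c = self.formula.get("C", 0)
        if n_c < self.n_skeleton:
            raise ValueError(
                f"{self.id}: formula has {n_c} carbons but {self.n_skeleton} "
                "skeleton carbons claimed"
            )
        if any(v < 0 for v in self.formula.values()):
            raise ValueError(f"{self.id}: negative element count")

    @property
    def n_skeleton(self) -> int:
        return len(self.atoms)


@dataclass
class MIDMeasurement:
    fragment_id: str
    fractions: np.ndarray  # raw mass fractions M0..M(n+k)
    sd: np.ndarray
    replicate: str = "r1"
    time_h: float = 24.0

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if (self.fractions < 0).any():
            raise ValueError(f"{self.fragment_id}: negative mass fraction")
        if self.fractions.shape != self.sd.shape:
            raise ValueError(f"{self.fragment_id}: fraction/sd length mismatch")

    def normalized(self) -> np.ndarray:
        s = self.fractions.sum()
        if s <= 0:
            raise ValueError(f"{self.fragment_id}: all-zero measurement")
        return self.fractions / s


def _element_distribution(counts: Mapping[str, int],
                          abundances: Mapping[str, Sequence[float]]) -> np.ndarray:
    """Mass-shift pmf of a set of atoms at natural abundance."""
    dist = np.array([1.0])
    for element, n in sorted(counts.items()):
        if n == 0:
            continue
        if element not in abundances:
            raise ValueError(f"no abundance distribution for element {element!r}")
        pmf = np.asarray(abundances[element], dtype=float)
        if (pmf < 0).any():
            raise ValueError(f"negative abundance for element {element!r}")
        if abs(pmf.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances for {element!r} do not sum to 1")
        for _ in range(n):
            dist = np.convolve(dist, pmf)
    return dist


def natural_mid(fragment: FragmentDef,
                abundances: Mapping[str, Sequence[float]] = DEFAULT_ABUNDANCES,
                ) -> np.ndarray:
    """Theoretical natural mass-shift distribution of all non-skeleton atoms."""
    counts = dict(fragment.formula)
    counts["C"] = counts.get("C", 0) - fragment.n_skeleton
    return _element_distribution(counts, abundances)


def correction_matrix(fragment: FragmentDef,
                      abundances: Mapping[str, Sequence[float]] = DEFAULT_ABUNDANCES,
                      ) -> np.ndarray:
    """Convolution matrix C with ``raw = C @ skeleton_mid``.

    Rows cover mass shifts 0..n_skeleton + len(natural pmf) - 1; column j
    is the natural pmf shifted down by j. Column sums equal 1.
    """
    if fragment.n_skeleton == 0:
        raise ValueError(f"{fragment.id}: fragment has zero skeleton carbons")
    d = natural_mid(fragment, abundances)
    n = fragment.n_skeleton
    rows = n + len(d)
    C = np.zeros((rows, n + 1))
    for j in range(n + 1):
        C[j : j + len(d), j] = d
    return C


def correct_mid(
    measurement: MIDMeasurement,
    fragment: FragmentDef,
    abundances: Mapping[str, Sequence[float]] = DEFAULT_ABUNDANCES,
) -> Tuple[np.ndarray, np.ndarray]:
    """Remove natural-abundance contributions from a raw measurement.

    Solves ``C x = raw`` by non-negative least squares, renormalizes x to
    sum 1, and propagates the measurement SDs linearly through the
    pseudo-inverse. Returns ``(corrected, sd)`` of length
    ``n_skeleton + 1``.
    """
    raw = measurement.normalized()
    m = len(raw)
    n = fragment.n_skeleton
    if m < n + 1:
        raise ValueError(
            f"{fragment.id}: measurement has {m} masses, needs >= {n + 1}"
        )
    C = correction_matrix(fragment, abundances)[:m, :]
    cond = np.linalg.cond(C)
    if cond > 1e8:
        raise ValueError(
            f"{fragment.id}: correction matrix ill-conditioned (cond {cond:.2e})"
        )
    x, _ = nnls(C, raw)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{fragment.id}: correction produced an all-zero MID")
    P = np.linalg.pinv(C)
    scale = raw.sum() / max(measurement.fractions.sum(), 1e-300)
    sd_raw = measurement.sd * scale
    sd = np.sqrt((P ** 2) @ (sd_raw ** 2)) / total
    return x / total, sd


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

MID_COLUMNS = ["fragment_id", "replicate", "time_h", "mass_shift", "fraction", "sd"]


def read_mid_table(path_or_buf, fragments: Optional[Mapping[str, FragmentDef]] = None,
                   ) -> List[MIDMeasurement]:
    """Read a MID CSV (columns fragment_id, replicate, time_h, mass_shift,
    fraction, sd) into grouped, validated measurements."""
    df = pd.read_csv(path_or_buf)
    missing = [c for c in MID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MID table missing columns: {missing}")
    if (df["fraction"] < 0).any():
        bad = df.index[df["fraction"] < 0][0]
        raise ValueError(f"negative fraction at row {bad}")
    keys = ["fragment_id", "replicate", "time_h", "mass_shift"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise ValueError(f"duplicate measurement rows at index {df.index[dup][0]}")
    if fragments is not None:
        unknown = set(df["fragment_id"]) - set(fragments)
        if unknown:
            raise ValueError(f"unknown fragment ids: {sorted(unknown)}")
    out: List[MIDMeasurement] = []
    for (fid, rep, t), grp in df.groupby(
        ["fragment_id", "replicate", "time_h"], sort=True
    ):
        grp = grp.sort_values("mass_shift")
        shifts = grp["mass_shift"].to_numpy()
        if not np.array_equal(shifts, np.arange(len(shifts))):
            raise ValueError(
                f"{fid}/{rep}/t={t}: mass shifts must be contiguous from 0"
            )
        out.append(
            MIDMeasurement(
                fragment_id=fid,
                fractions=grp["fraction"].to_numpy(),
                sd=grp["sd"].to_numpy(),
                replicate=str(rep),
                time_h=float(t),
            )
        )
    return out


def write_mid_table(measurements: Sequence[MIDMeasurement]) -> str:
    """Serialize measurements to CSV text (inverse of read_mid_table)."""
    rows = []
    for m in sorted(measurements, key=lambda m: (m.fragment_id, m.replicate, m.time_h)):
        for k, (f, s) in enumerate(zip(m.fractions, m.sd)):
            rows.append(
                {
                    "fragment_id": m.fragment_id,
                    "replicate": m.replicate,
                    "time_h": m.time_h,
                    "mass_shift": k,
                    "fraction": f,
                    "sd": s,
                }
            )
    df = pd.DataFrame(rows, columns=MID_COLUMNS)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.12g")
    return buf.getvalue()


def average_replicates(
    measurements: Sequence[MIDMeasurement],
    time_h: Optional[float] = None,
    sd_floor: float = SD_FLOOR,
) -> Dict[str, MIDMeasurement]:
    """Average biological replicates per fragment.

    SD of the mean = max(sample SD / sqrt(n), sd_floor). If ``time_h`` is
    given, only that timepoint is used (default: the latest timepoint,
    treated as isotopic steady state).
    """
    if time_h is None:
        time_h = max(m.time_h for m in measurements)
    by_frag: Dict[str, List[MIDMeasurement]] = {}
    for m in measurements:
        if m.time_h == time_h:
            by_frag.setdefault(m.fragment_id, []).append(m)
    out: Dict[str, MIDMeasurement] = {}
    for fid, group in sorted(by_frag.items()):
        stack = np.vstack([m.normalized() for m in group])
        mean = stack.mean(axis=0)
        n = len(group)
        if n > 1:
            se = stack.std(axis=0, ddof=1) / np.sqrt(n)
        else:
            se = np.zeros_like(mean)
        sd = np.maximum(se, sd_floor)
        out[fid] = MIDMeasurement(fid, mean, sd, replicate="mean", time_h=time_h)
    return out


def load_fragment_library() -> Dict[str, FragmentDef]:
    """Load the bundled TBDMS fragment library (documented reconstruction)."""
    from importlib import resources

    text = resources.files("tcellflux.data").joinpath("fragments.tsv").read_text()
    frags: Dict[str, FragmentDef] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line or line.startswith("fragment_id"):
            continue
        fid, met, atoms, formula = line.split("\t")
        frags[fid] = FragmentDef(
            id=fid,
            metabolite=met,
            atoms=tuple(int(a) for a in atoms.split(",")),
            formula=parse_formula(formula),
        )
    return frags
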
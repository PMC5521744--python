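"""Quantitative outputs: volumetric fractions, streamwise profiles,
conditional phase-overlap probabilities, and the worked hydraulic /
stoichiometric / wall-shear numbers of the emulated experiment.

Probabilities are computed on exact voxel counts (no partial-volume
weighting); per-conditioning-phase conditionals sum to one by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BIOFILM, LIQUID, OUTSIDE, PHASE_NAMES, SOLID, LabelVolume

__all__ = [
    "FractionProfile",
    "OverlapTable",
    "HydraulicsParams",
    "RheologyParams",
    "mean_fractions",
    "fraction_profile",
    "conditional_overlap",
    "hydraulic_summary",
    "speciation",
    "wall_shear_powerlaw",
    "wall_shear_ratio",
    "MOLAR_MASS",
]

#: atomic / formula masses (g/mol) used by the speciation arithmetic
MOLAR_MASS = {
    "Fe": 55.845,
    "S": 32.065,
    "O": 15.999,
}
MOLAR_MASS["SO4"] = MOLAR_MASS["S"] + 4 * MOLAR_MASS["O"]
MOLAR_MASS["FeSO4"] = MOLAR_MASS["Fe"] + MOLAR_MASS["SO4"]


# ---------------------------------------------------------------------------
# volumetric fractions
# ---------------------------------------------------------------------------

def mean_fractions(labels: LabelVolume) -> dict[str, float]:
    """Voxel-count phase fractions over the in-column domain."""
    codes = labels.codes
    mask = codes != OUTSIDE
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no in-column voxels")
    counts = np.bincount(codes[mask].ravel(), minlength=5)
    return {PHASE_NAMES[c]: counts[c] / n for c in sorted(PHASE_NAMES)
            if c != OUTSIDE}


@dataclass
class FractionProfile:
    """Per-slice phase fractions along the streamwise (z) axis, with an
    optional biofilm sensitivity band from the low/high thresholds."""

    z_positions_um: np.ndarray
    fractions: pd.DataFrame          # columns: solid, liquid, biofilm, air
    band_low: np.ndarray | None = None   # biofilm fraction, low threshold
    band_high: np.ndarray | None = None  # biofilm fraction, high threshold
    empty_slices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def to_csv(self, path) -> None:
        df = self.fractions.copy()
        df.insert(0, "z_um", self.z_positions_um)
        if self.band_low is not None:
            df["biofilm_band_low"] = self.band_low
        if self.band_high is not None:
            df["biofilm_band_high"] = self.band_high
        df.to_csv(path, index=False)


def fraction_profile(labels: LabelVolume,
                     band_labels: tuple[LabelVolume, LabelVolume] | None = None
                     ) -> FractionProfile:
    """Streamwise profile of per-slice phase fractions inside the column.

    ``band_labels`` = (low-threshold labels, high-threshold labels) adds the
    biofilm sensitivity band (lower threshold -> more biofilm).  Slices with
    no in-column voxels are flagged, not dropped.
    """
    codes = labels.codes
    nz = codes.shape[0]
    dz = labels.spacing_um[0]
    rows = np.zeros((nz, 4))
    empty = []
    for iz in range(nz):
        sl = codes[iz]
        m = sl != OUTSIDE
        n = int(m.sum())
        if n == 0:
            empty.append(iz)
            rows[iz] = np.nan
            continue
        counts = np.bincount(sl[m].ravel(), minlength=5)
        rows[iz] = counts[[SOLID, LIQUID, BIOFILM, 4]] / n
    df = pd.DataFrame(rows, columns=["solid", "liquid", "biofilm", "air"])
    band_low = band_high = None
    if band_labels is not None:
        lo_labels, hi_labels = band_labels
        if lo_labels.shape != labels.shape or hi_labels.shape != labels.shape:
            raise ValueError("band labels must share the grid")
        band_low = _biofilm_per_slice(lo_labels)
        band_high = _biofilm_per_slice(hi_labels)
    return FractionProfile(np.arange(nz) * dz, df, band_low, band_high,
                           np.asarray(empty, dtype=int))


def _biofilm_per_slice(labels: LabelVolume) -> np.ndarray:
    codes = labels.codes
    out = np.full(codes.shape[0], np.nan)
    for iz in range(codes.shape[0]):
        m = codes[iz] != OUTSIDE
        n = int(m.sum())
        if n:
            out[iz] = np.count_nonzero(codes[iz][m] == BIOFILM) / n
    return out


def dominant_period_um(profile: np.ndarray, dz_um: float) -> float:
    """Dominant oscillation period of a streamwise profile (DFT peak of the
    detrended signal) — used to recover the grain-size periodicity of an
    ordered packing."""
    y = np.asarray(profile, dtype=float)
    y = y[np.isfinite(y)]
    y = y - y.mean()
    spec = np.abs(np.fft.rfft(y))
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if k == 0:
        return math.inf
    return len(y) * dz_um / k


# ---------------------------------------------------------------------------
# conditional overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapTable:
    """Conditional probabilities P(phase_a in A | phase_b in B) over the
    common registered in-column domain, with the joint counts retained."""

    joint_counts: pd.DataFrame       # index: phase in A, columns: phase in B
    conditional: dict[tuple[str, str], float]
    undefined: list[str] = field(default_factory=list)

    def p(self, phase_a: str, phase_b: str) -> float:
        """P(phase_a in A | phase_b in B)."""
        key = (phase_a, phase_b)
        if key not in self.conditional:
            raise KeyError(f"P({phase_a}|{phase_b}) undefined: conditioning "
                           "phase absent")
        return self.conditional[key]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), p in sorted(self.conditional.items()):
            rows.append({"phase_a": a, "phase_b": b,
                         "count": int(self.joint_counts.loc[a, b]),
                         "probability": p})
        return pd.DataFrame(rows)


def conditional_overlap(a: LabelVolume, b: LabelVolume) -> OverlapTable:
    """All pairwise conditionals P(phase_A | phase_B) from joint voxel counts
    over the intersection of both in-column domains.

    Conditioning phases absent from B are flagged undefined, not reported as
    zero.
    """
    if a.shape != b.shape:
        raise ValueError("label volumes must be registered onto one grid")
    common = (a.codes != OUTSIDE) & (b.codes != OUTSIDE)
    if not common.any():
        raise ValueError("common in-column domain is empty")
    ca = a.codes[common].astype(np.intp)
    cb = b.codes[common].astype(np.intp)
    joint = np.zeros((5, 5), dtype=np.int64)
    np.add.at(joint, (ca, cb), 1)
    phases = [PHASE_NAMES[c] for c in range(5)]
    jc = pd.DataFrame(joint, index=phases, columns=phases)
    conditional: dict[tuple[str, str], float] = {}
    undefined: list[str] = []
    col_tot = joint.sum(axis=0)
    for cb_i in range(5):
        if cb_i == OUTSIDE:
            continue
        if col_tot[cb_i] == 0:
            undefined.append(PHASE_NAMES[cb_i])
            continue
        for ca_i in range(5):
            if ca_i == OUTSIDE:
                continue
            conditional[(PHASE_NAMES[ca_i], PHASE_NAMES[cb_i])] = (
                joint[ca_i, cb_i] / col_tot[cb_i])
    return OverlapTable(jc, conditional, undefined)


# ---------------------------------------------------------------------------
# hydraulics, stoichiometry, wall shear
# ---------------------------------------------------------------------------

@dataclass
class HydraulicsParams:
    """Column hydraulics of the emulated growth experiment.

    Defaults: 5 mL/min through a 10 mm ID column of 2.5 mm grains at 40 %
    porosity; kinematic viscosity of water 1e-6 m^2/s; molecular diffusivity
    2.65e-9 m^2/s (an inferred default consistent with a Peclet number of
    1000 at these conditions, not an independently measured value).
    """

    Q_mL_min: float = 5.0
    column_id_mm: float = 10.0
    phi: float = 0.40
    grain_d_mm: float = 2.5
    nu_m2s: float = 1.0e-6
    D_h2o_m2s: float = 2.65e-9

    def __post_init__(self) -> None:
        if min(self.Q_mL_min, 0.0) < 0 or self.column_id_mm <= 0 \
                or not 0 < self.phi < 1 or self.grain_d_mm <= 0 \
                or self.nu_m2s <= 0 or self.D_h2o_m2s <= 0:
            raise ValueError("invalid hydraulic parameters")


def hydraulic_summary(p: HydraulicsParams) -> dict[str, float]:
    """Darcy velocity q = Q/A, pore velocity v_p = q/phi, Re = q d / nu,
    Pe = q d / D.  Values are reported at full precision (no rounding)."""
    area_m2 = math.pi * (p.column_id_mm * 1e-3 / 2.0) ** 2
    q_m_s = (p.Q_mL_min * 1e-6 / 60.0) / area_m2
    v_p = q_m_s / p.phi
    d_m = p.grain_d_mm * 1e-3
    return {
        "q_mm_s": q_m_s * 1e3,
        "v_p_mm_s": v_p * 1e3,
        "Re": q_m_s * d_m / p.nu_m2s,
        "Pe": q_m_s * d_m / p.D_h2o_m2s,
    }


def speciation(feso4_mg_L: float) -> dict[str, float]:
    """Iron sulfate speciation: mg/L FeSO4 -> mmol/L plus Fe and SO4 mass
    concentrations."""
    if feso4_mg_L < 0:
        raise ValueError("concentration must be non-negative")
    mmol_L = feso4_mg_L / MOLAR_MASS["FeSO4"]
    return {
        "mmol_L": mmol_L,
        "fe_mg_L": mmol_L * MOLAR_MASS["Fe"],
        "so4_mg_L": mmol_L * MOLAR_MASS["SO4"],
    }


@dataclass
class RheologyParams:
    """Power-law fluid in an idealized cylindrical pore."""

    K: float               # consistency index, Pa s^n
    n: float               # flow-behaviour index (1 = Newtonian)
    pore_diameter_m: float
    Q_m3s: float

    def __post_init__(self) -> None:
        if self.K <= 0 or self.n <= 0 or self.pore_diameter_m <= 0:
            raise ValueError("K, n and pore diameter must be positive")


def wall_shear_powerlaw(r: RheologyParams) -> float:
    """Rabinowitsch-Mooney wall shear stress of a power-law fluid in a
    circular conduit: tau_w = K * ((3n+1)/(4n) * 8 u / d)^n with
    u = Q / (pi d^2 / 4).  Reduces to tau_w = 8 mu u / d for n = 1."""
    d = r.pore_diameter_m
    u = r.Q_m3s / (math.pi * (d / 2.0) ** 2)
    gamma_w = (3.0 * r.n + 1.0) / (4.0 * r.n) * 8.0 * u / d
    return r.K * gamma_w ** r.n


def wall_shear_ratio(suspension: RheologyParams,
                     water: RheologyParams) -> float:
    """tau_w(suspension) / tau_w(water) — e.g. a shear-thinning contrast
    suspension injected at a tenth of the growth flow rate against water at
    the growth flow rate."""
    return wall_shear_powerlaw(suspension) / wall_shear_powerlaw(water)
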
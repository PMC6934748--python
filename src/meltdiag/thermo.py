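"""Nearest-neighbor duplex thermodynamics and two-state melting.

ΔH and ΔS of a B-DNA duplex are computed with the unified nearest-neighbor
parameter set (ten Watson–Crick doublet terms plus terminal A·T / G·C
initiation). The melting temperature of a non-self-complementary duplex at
total single-strand concentration :math:`C_T` is

.. math:: T_m = \\frac{\\Delta H \\times 1000}{\\Delta S' + R \\ln(C_T/4)}

with :math:`\\Delta S'` the entropy after monovalent-salt correction
(0.368 cal/(mol·K) per internal base pair times ln[Na+]); divalent magnesium
is folded into a sodium equivalent (120·sqrt(Mg mM)). Conversion to the
instrument scale — dye, ramp-rate and optics effects the model does not
capture — is a single additive calibration offset anchored on an observed
melting peak.

The two-state (all-or-none) assumption is adequate for the short amplicons
this toolkit targets (≲110 bp, single melting domain); multi-domain melting
is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError, NumericError

#: Gas constant, cal/(mol·K).
R_CAL = 1.9872

# Unified nearest-neighbor parameters, 1 M NaCl: 5'XY3' doublet ->
# (dH kcal/mol, dS cal/(mol*K)). The ten unique stacks; the other six dimers
# are their reverse complements.
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# fill reverse complements (TT<-AA, TG<-CA, AC<-GT, AG<-CT, TC<-GA, CC<-GG)
_RC = str.maketrans("ACGT", "TGCA")
for _dimer in list(NN_PARAMS):
    _rc = _dimer.translate(_RC)[::-1]
    NN_PARAMS.setdefault(_rc, NN_PARAMS[_dimer])

#: Duplex initiation terms: (dH, dS) for a terminal G·C or A·T pair.
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)

#: Entropic monovalent-salt correction, cal/(mol·K) per internal base pair.
SALT_DS_PER_BP = 0.368

#: Derivative-peak position of the bimolecular two-state transition:
#: -dθ/dT is maximal where the association constant satisfies K·CT = 1+sqrt(2)
#: (θ = 0.5 corresponds to K·CT = 4).
A_PEAK = 1.0 + math.sqrt(2.0)


@dataclass(frozen=True)
class ThermoConditions:
    """Ionic/strand conditions plus instrument calibration.

    monovalent_mM
        Na+-equivalent monovalent cations, mM.
    free_mg_mM
        Free Mg2+, mM, folded into the monovalent equivalent.
    strand_conc_M
        Total single-strand concentration C_T (mol/L); PCR products are
        treated as non-self-complementary duplexes with equal strands (C_T/4).
    calibration_offset_C
        Additive °C applied to every predicted Tm; absorbs dye (LCGreen) and
        instrument effects.
    """

    monovalent_mM: float = 50.0
    free_mg_mM: float = 2.0
    strand_conc_M: float = 0.25e-6
    calibration_offset_C: float = 0.0

    def __post_init__(self):
        if self.monovalent_mM <= 0 or self.strand_conc_M <= 0:
            raise InputError("concentrations must be > 0")
        if self.free_mg_mM < 0:
            raise InputError("free_mg_mM must be >= 0")
        if not math.isfinite(self.calibration_offset_C):
            raise InputError("calibration offset must be finite")

    @property
    def sodium_equivalent_M(self) -> float:
        """Monovalent equivalent: [mono] + 120·sqrt([Mg]) (mM scale) / 1000."""
        return (self.monovalent_mM + 120.0 * math.sqrt(self.free_mg_mM)) / 1000.0

    def with_offset(self, offset_C: float) -> "ThermoConditions":
        return replace(self, calibration_offset_C=offset_C)


@dataclass(frozen=True)
class ThermoResult:
    dH_kcal_mol: float
    dS_cal_molK: float
    tm_C: float


def nn_sum(duplex_seq: str) -> tuple[float, float]:
    """Sum nearest-neighbor doublet and initiation terms for one duplex.

    Returns (ΔH kcal/mol, ΔS cal/(mol·K)) at the 1 M NaCl reference state.
    The sequence is one strand 5'→3'; A/C/G/T only, length ≥ 2.
    """
    seq = duplex_seq.upper()
    if len(seq) < 2:
        raise InputError("duplex must be at least 2 nt")
    if not set(seq) <= set("ACGT"):
        raise InputError(
            "ambiguity codes not supported; expand haplotypes to A/C/G/T first"
        )
    dh, ds = 0.0, 0.0
    for terminal in (seq[0], seq[-1]):
        ih, is_ = INIT_GC if terminal in "GC" else INIT_AT
        dh += ih
        ds += is_
    for i in range(len(seq) - 1):
        ph, ps = NN_PARAMS[seq[i : i + 2]]
        dh += ph
        ds += ps
    return dh, ds


def salt_corrected_ds(ds_cal: float, n_bp: int, cond: ThermoConditions) -> float:
    """Entropy after the monovalent correction over the n-1 internal stacks."""
    return ds_cal + SALT_DS_PER_BP * (n_bp - 1) * math.log(cond.sodium_equivalent_M)


def melting_temperature(
    dh_kcal: float, ds_cal: float, n_bp: int, cond: ThermoConditions
) -> float:
    """Two-state Tm (°C) of a non-self-complementary duplex, plus calibration.

    ``ds_cal`` is the 1 M reference entropy from :func:`nn_sum`; the salt
    correction is applied here.
    """
    if not (dh_kcal < 0 and ds_cal < 0):
        raise InputError("expected dH < 0 and dS < 0 for a stable duplex")
    ds_salt = salt_corrected_ds(ds_cal, n_bp, cond)
    denom = ds_salt + R_CAL * math.log(cond.strand_conc_M / 4.0)
    if abs(denom) < 1e-9:
        raise NumericError("entropy term ~0; Tm undefined for this input")
    tm_K = dh_kcal * 1000.0 / denom
    if tm_K <= 0:
        raise NumericError("non-physical Tm for this input")
    return tm_K - 273.15 + cond.calibration_offset_C


def duplex_thermo(seq: str, cond: ThermoConditions) -> ThermoResult:
    """Convenience: NN summation + Tm for a duplex sequence."""
    dh, ds = nn_sum(seq)
    return ThermoResult(dh, ds, melting_temperature(dh, ds, len(seq), cond))


def duplex_tm(seq: str, cond: ThermoConditions) -> float:
    return duplex_thermo(seq, cond).tm_C


def _theta_from_log_a(log_a: np.ndarray) -> np.ndarray:
    """Duplex fraction θ from ln(K·C_T), numerically safe at both extremes.

    For A + B ⇌ AB with equal strands, θ solves a(1-θ)² = 2θ with a = K·C_T;
    the cancellation-free root is θ = a / (1 + a + sqrt(1 + 2a)).
    """
    theta = np.empty_like(log_a, dtype=float)
    high = log_a > 40.0
    mid = ~high
    a = np.exp(log_a[mid])
    theta[mid] = a / (1.0 + a + np.sqrt(1.0 + 2.0 * a))
    # avoid exp overflow: θ → 1 - sqrt(2/a)
    theta[high] = 1.0 - np.sqrt(2.0) * np.exp(-log_a[high] / 2.0)
    return np.clip(theta, 0.0, 1.0)


def helicity_curve(
    dh_kcal: float,
    tm_C: float,
    cond: ThermoConditions,
    t_grid_C: np.ndarray,
) -> np.ndarray:
    """Equilibrium duplex fraction θ(T) on an ascending temperature grid.

    Parametrized by the duplex ΔH and its (already calibrated) Tm: the
    effective entropy is chosen so that θ(Tm) = 0.5 exactly under the
    bimolecular equilibrium at ``cond.strand_conc_M``. θ is strictly
    decreasing in T.
    """
    t = np.asarray(t_grid_C, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise InputError("temperature grid must be 1-D and strictly ascending")
    if dh_kcal >= 0:
        raise InputError("expected dH < 0")
    tm_K = tm_C + 273.15
    ct = cond.strand_conc_M
    # ΔS' such that ΔG(Tm) = -R·Tm·ln(CT/4)
    ds_eff = dh_kcal * 1000.0 / tm_K - R_CAL * math.log(ct / 4.0)
    t_K = t + 273.15
    # ln a = ln(K·CT) = ln CT - ΔG/(R·T)
    log_a = np.log(ct) - (dh_kcal * 1000.0 - t_K * ds_eff) / (R_CAL * t_K)
    return _theta_from_log_a(log_a)


def derivative_peak_offset(
    dh_kcal: float, tm_C: float, cond: ThermoConditions
) -> float:
    """Offset (°C) of the -dθ/dT maximum above the θ=0.5 Tm.

    The bimolecular two-state transition is asymmetric: the derivative peak
    sits where K·C_T = 1+sqrt(2) rather than 4, i.e. slightly above Tm. First
    order in 1/ΔH: ΔT = ln(4/(1+sqrt 2))·R·Tm_K²/(-ΔH·1000).
    """
    tm_K = tm_C + 273.15
    return math.log(4.0 / A_PEAK) * R_CAL * tm_K**2 / (-dh_kcal * 1000.0)


def calibrate_offset(predicted_tm_C: float, observed_peak_C: float) -> float:
    """Additive instrument calibration: observed − predicted."""
    if not (math.isfinite(predicted_tm_C) and math.isfinite(observed_peak_C)):
        raise InputError("temperatures must be finite")
    return observed_peak_C - predicted_tm_C
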
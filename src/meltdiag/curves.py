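"""Melt-curve simulation, processing, species calling and reporting.

The forward model of the instrument signal is

    F(T) = amplitude · θ(T + δ − jitter) · (1 + pre_slope·(T − T0))
           + post_level + post_slope·(T − T0) + ε,

where θ is the two-state duplex fraction of :mod:`meltdiag.thermo`, jitter is
a per-specimen Normal(0, sd_tm) temperature shift emulating well-to-well
variation, and ε is Gaussian fluorescence noise. δ is a fixed model shift that
places the noiseless −dF/dT maximum exactly at the duplex's calibrated Tm
(peak-position convention — melters report peak temperatures, and the
asymmetric bimolecular transition would otherwise peak ~0.2–0.3 °C above the
θ=0.5 point for a short amplicon).

Processing mirrors instrument software: linear pre-/post-melt baseline
normalization, Savitzky–Golay smoothed −dF/dT, peak calling with sub-grid
parabolic interpolation, nearest-reference species assignment with a
tolerance and margin rule, and a throughput report of failed / ambiguous /
assigned / morphology-discordant counts with half-up rounded percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .errors import ConfigError, InputError, NormalizationError
from .thermo import ThermoConditions, helicity_curve

#: Default acquisition grid: 65–85 °C, 20 acquisitions/°C (0.05 °C step).
def default_grid(start_C: float = 65.0, end_C: float = 85.0, step_C: float = 0.05) -> np.ndarray:
    n = int(round((end_C - start_C) / step_C)) + 1
    return np.round(np.linspace(start_C, end_C, n), 6)


@dataclass
class MeltCurve:
    specimen_id: str
    temps_C: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        self.temps_C = np.asarray(self.temps_C, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temps_C.shape != self.fluorescence.shape or self.temps_C.ndim != 1:
            raise InputError("temperature and fluorescence grids must match")
        if np.any(np.diff(self.temps_C) <= 0):
            raise InputError("temperature grid must be strictly ascending")
        if not np.all(np.isfinite(self.fluorescence)):
            raise InputError("fluorescence must be finite")


@dataclass
class DerivativeCurve:
    specimen_id: str
    temps_C: np.ndarray
    neg_dF_dT: np.ndarray
    peak_tm_C: float | None
    peak_height: float
    secondary_peaks: list[tuple[float, float]] = field(default_factory=list)
    flagged_low_signal: bool = False


@dataclass(frozen=True)
class SpeciesCall:
    specimen_id: str
    call: str  # species label | "ambiguous" | "failed"
    peak_tm_C: float | None
    margin_C: float | None


@dataclass(frozen=True)
class MeltSimParams:
    """Noise and baseline parameters of the simulated signal."""

    sd_fluor: float = 0.01
    sd_tm_shift_C: float = 0.15
    pre_slope: float = -0.004  # relative helix-baseline slope, 1/°C
    post_slope: float = -0.0005  # absolute post-melt drift, units/°C
    amplitude: float = 1.0
    post_level: float = 0.05


def simulate_melt_curve(
    dh_kcal: float,
    tm_C: float,
    cond: ThermoConditions,
    params: MeltSimParams = MeltSimParams(),
    rng: np.random.Generator | None = None,
    t_grid_C: np.ndarray | None = None,
    specimen_id: str = "sim",
) -> MeltCurve:
    """Simulate one specimen's melt curve for a duplex with the given ΔH/Tm.

    ``tm_C`` is the calibrated melting temperature; the noiseless −dF/dT peak
    of the returned curve sits at ``tm_C`` (within one grid step). Reproducible
    for a fixed ``rng`` state.
    """
    if params.amplitude < 0:
        raise InputError("amplitude must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    t = default_grid() if t_grid_C is None else np.asarray(t_grid_C, dtype=float)
    jitter = rng.normal(0.0, params.sd_tm_shift_C) if params.sd_tm_shift_C > 0 else 0.0
    if params.amplitude > 0:
        delta = _peak_alignment_shift(dh_kcal, tm_C, cond, params)
        theta = helicity_curve(dh_kcal, tm_C, cond, t + delta - jitter)
    else:
        theta = np.zeros_like(t)
    t0 = t[0]
    signal = (
        params.amplitude * theta * (1.0 + params.pre_slope * (t - t0))
        + params.post_level
        + params.post_slope * (t - t0)
    )
    if params.sd_fluor > 0:
        signal = signal + rng.normal(0.0, params.sd_fluor, size=t.shape)
    return MeltCurve(specimen_id, t, signal)


def _peak_alignment_shift(
    dh_kcal: float, tm_C: float, cond: ThermoConditions, params: MeltSimParams
) -> float:
    """Shift δ so the noiseless −dF/dT maximum lands exactly at ``tm_C``.

    Located numerically on a fine grid of the noiseless signal (baselines
    included), so the asymmetry of the bimolecular transition and the helix
    baseline slope are both accounted for.
    """
    fine = np.arange(tm_C - 4.0, tm_C + 4.0, 0.005)
    theta = helicity_curve(dh_kcal, tm_C, cond, fine)
    signal = params.amplitude * theta * (1.0 + params.pre_slope * (fine - fine[0]))
    deriv = -np.gradient(signal, fine)
    k = int(np.argmax(deriv))
    peak = _parabolic_refine(fine, deriv, k)
    return peak - tm_C


def _fit_peak(t: np.ndarray, y: np.ndarray, k: int, half_width_C: float = 0.5) -> float:
    """Peak position from a least-squares parabola over ±half_width_C around
    the argmax. Averaging over the whole peak top makes the estimate robust to
    point-level noise that a 3-point interpolation would amplify."""
    mask = np.abs(t - t[k]) <= half_width_C
    if mask.sum() < 5:
        return _parabolic_refine(t, y, k)
    a, b, _ = np.polyfit(t[mask], y[mask], 2)
    if a >= 0:
        return _parabolic_refine(t, y, k)
    vertex = -b / (2.0 * a)
    lo, hi = t[mask][0], t[mask][-1]
    return float(np.clip(vertex, lo, hi))


def _parabolic_refine(t: np.ndarray, y: np.ndarray, k: int) -> float:
    """Sub-grid peak position by a parabola through (k-1, k, k+1)."""
    if k <= 0 or k >= len(t) - 1:
        return float(t[k])
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[k])
    shift = 0.5 * (y0 - y2) / denom
    step = t[k + 1] - t[k]
    return float(t[k] + np.clip(shift, -1.0, 1.0) * step)


def normalize_curve(
    curve: MeltCurve,
    pre_window: tuple[float, float] = (66.0, 68.0),
    post_window: tuple[float, float] = (83.0, 85.0),
) -> MeltCurve:
    """Two-baseline normalization to the [0, 1] helicity scale.

    Linear baselines are fitted on the pre-melt and post-melt temperature
    windows; the output is (F − lower)/(upper − lower) clipped to
    [−0.05, 1.05]. Invariant under affine transforms of the input signal.
    """
    t, f = curve.temps_C, curve.fluorescence
    fits = []
    for lo, hi in (pre_window, post_window):
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 5:
            raise NormalizationError(
                f"baseline window {(lo, hi)} has fewer than 5 grid points"
            )
        if np.ptp(t[mask]) == 0:
            raise NormalizationError(f"degenerate baseline window {(lo, hi)}")
        fits.append(np.polyfit(t[mask], f[mask], 1))
    upper = np.polyval(fits[0], t)
    lower = np.polyval(fits[1], t)
    span = upper - lower
    # guard against a melted-out/flat curve where the baselines cross
    span = np.where(np.abs(span) < 1e-12, 1e-12, span)
    norm = np.clip((f - lower) / span, -0.05, 1.05)
    return MeltCurve(curve.specimen_id, t.copy(), norm)


def derivative_and_peak(
    curve: MeltCurve,
    smooth: tuple[int, int] = (31, 3),
    min_prominence_frac: float = 0.2,
    flat_height: float = 1e-3,
) -> DerivativeCurve:
    """Savitzky–Golay smoothed −dF/dT with sub-grid peak calling.

    The global maximum is the melting peak, refined to sub-grid resolution by
    a least-squares parabola over the peak top (±0.5 °C); other
    local maxima with at least ``min_prominence_frac`` of the main peak height
    are recorded as secondary peaks. A derivative that never rises above
    ``flat_height`` is flagged as low-signal (failed amplification pathway).
    """
    window_pts, poly_order = smooth
    if window_pts % 2 == 0 or window_pts < poly_order + 2:
        raise InputError("smoothing window must be odd and >= poly_order + 2")
    t, f = curve.temps_C, curve.fluorescence
    step = float(np.median(np.diff(t)))
    neg = -savgol_filter(f, window_pts, poly_order, deriv=1, delta=step)
    k = int(np.argmax(neg))
    height = float(neg[k])
    if height <= flat_height:
        return DerivativeCurve(
            curve.specimen_id, t, neg, None, 0.0, flagged_low_signal=True
        )
    peak_tm = _fit_peak(t, neg, k)
    idx, props = find_peaks(neg, height=min_prominence_frac * height)
    secondary = [
        (_parabolic_refine(t, neg, int(i)), float(neg[i]))
        for i in idx
        if int(i) != k
    ]
    return DerivativeCurve(curve.specimen_id, t, neg, peak_tm, height, secondary)


def call_species(
    dcurve: DerivativeCurve,
    refs: Mapping[str, float],
    tau_C: float = 0.75,
    min_margin_C: float = 0.5,
    min_height: float = 0.05,
) -> SpeciesCall:
    """Assign a species from the melting-peak position.

    failed if the peak is absent or below ``min_height``; otherwise the
    nearest reference within ``tau_C`` wins, provided the gap to the next
    reference is at least ``min_margin_C``; otherwise ambiguous. References
    closer together than 2·tau make the assay non-diagnostic at these
    thresholds and raise :class:`ConfigError`.
    """
    if len(refs) < 2:
        raise InputError("need at least two species references")
    ref_items = sorted(refs.items(), key=lambda kv: kv[1])
    for (_, a), (_, b) in zip(ref_items, ref_items[1:]):
        if b - a < 2 * tau_C:
            raise ConfigError(
                f"references {a} and {b} closer than 2*tau ({2 * tau_C}); "
                "assay not diagnostic at these thresholds"
            )
    if dcurve.flagged_low_signal or dcurve.peak_height < min_height or dcurve.peak_tm_C is None:
        return SpeciesCall(dcurve.specimen_id, "failed", None, None)
    dists = sorted(
        ((abs(dcurve.peak_tm_C - tm), sp) for sp, tm in refs.items()),
        key=lambda x: x[0],
    )
    d1, best = dists[0]
    margin = dists[1][0] - d1
    if d1 <= tau_C and margin >= min_margin_C:
        return SpeciesCall(dcurve.specimen_id, best, dcurve.peak_tm_C, margin)
    return SpeciesCall(dcurve.specimen_id, "ambiguous", dcurve.peak_tm_C, margin)


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the peak-Tm classifier and failure detection."""

    tau_C: float = 0.75
    min_margin_C: float = 0.5
    min_height: float = 0.05
    min_amplitude: float = 0.1
    pre_window: tuple[float, float] = (66.0, 68.0)
    post_window: tuple[float, float] = (83.0, 85.0)
    smooth: tuple[int, int] = (31, 3)


def classify_curves(
    curves: Iterable[MeltCurve],
    refs: Mapping[str, float],
    params: ClassifierParams = ClassifierParams(),
) -> list[SpeciesCall]:
    """Full per-specimen pipeline: amplitude check, normalize, derivative,
    peak call, species assignment.

    A curve whose raw pre-melt minus post-melt signal difference is below
    ``min_amplitude`` is called failed before normalization (flat curves blow
    up the baseline rescaling).
    """
    calls = []
    for curve in curves:
        t, f = curve.temps_C, curve.fluorescence
        pre = f[(t >= params.pre_window[0]) & (t <= params.pre_window[1])]
        post = f[(t >= params.post_window[0]) & (t <= params.post_window[1])]
        if pre.size and post.size and (pre.mean() - post.mean()) < params.min_amplitude:
            calls.append(SpeciesCall(curve.specimen_id, "failed", None, None))
            continue
        norm = normalize_curve(curve, params.pre_window, params.post_window)
        dcurve = derivative_and_peak(norm, params.smooth)
        calls.append(
            call_species(
                dcurve, refs, params.tau_C, params.min_margin_C, params.min_height
            )
        )
    return calls


def _pct(count: int, denom: int, decimals: int) -> float:
    """Half-up rounded percentage; 0.0 when the denominator is zero."""
    if denom == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) * 100 / Decimal(denom)).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass
class AssayReport:
    """Throughput summary shaped like a high-throughput HRMA results table.

    One row per group (total / male / female) with counts of samples, failed
    and ambiguous curves, per-species assignments, and — where prior
    morphology labels exist — calls discordant with those labels. Percentages
    are emitted half-up at one and two decimals; the discordance denominator
    is every specimen in the group carrying a prior label.
    """

    table: pd.DataFrame

    def group(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def to_text(self) -> str:
        lines = ["High-throughput HRMA report", "=" * 27]
        for name, row in self.table.iterrows():
            lines.append(f"[{name}]")
            lines.append(f"  samples            {int(row['n_samples'])}")
            lines.append(
                f"  failed             {int(row['n_failed'])} ({row['pct_failed_1dp']}%)"
            )
            lines.append(
                f"  ambiguous          {int(row['n_ambiguous'])} ({row['pct_ambiguous_1dp']}%)"
            )
            for col in row.index:
                if col.startswith("n_assigned_"):
                    lines.append(
                        f"  {col[len('n_assigned_'):]:<18} {int(row[col])}"
                    )
            if row["n_with_prior"] > 0:
                lines.append(
                    f"  discordant w/prior {int(row['n_discordant'])} "
                    f"({row['pct_discordant_1dp']}% / {row['pct_discordant_2dp']}%)"
                )
        return "\n".join(lines)


def summarize_assay(
    calls: Sequence[SpeciesCall], metadata: pd.DataFrame
) -> AssayReport:
    """Join species calls with specimen metadata into an :class:`AssayReport`.

    ``metadata`` needs columns ``specimen_id``, ``sex`` ("male"/"female"; other
    values are counted only in the total row) and ``prior_label`` (nullable).
    Discordance is counted over specimens with a non-null prior label *and* a
    successful, unambiguous call; its percentage uses all prior-labelled
    specimens of the group as denominator.
    """
    required = {"specimen_id", "sex", "prior_label"}
    if not required <= set(metadata.columns):
        raise InputError(f"metadata must have columns {sorted(required)}")
    by_id = {c.specimen_id: c for c in calls}
    missing = [sid for sid in metadata["specimen_id"] if sid not in by_id]
    if missing:
        raise InputError(f"no call for specimens {missing[:5]}...")
    species = sorted(
        {c.call for c in calls if c.call not in ("failed", "ambiguous")}
    )

    def _summarize(df: pd.DataFrame) -> dict:
        n = len(df)
        its_calls = [by_id[sid] for sid in df["specimen_id"]]
        n_failed = sum(c.call == "failed" for c in its_calls)
        n_ambig = sum(c.call == "ambiguous" for c in its_calls)
        prior = df["prior_label"]
        has_prior = prior.notna()
        n_prior = int(has_prior.sum())
        n_disc = sum(
            1
            for sid, p in zip(df["specimen_id"], prior)
            if pd.notna(p)
            and by_id[sid].call not in ("failed", "ambiguous")
            and by_id[sid].call != p
        )
        row = {
            "n_samples": n,
            "n_failed": n_failed,
            "n_ambiguous": n_ambig,
            "n_with_prior": n_prior,
            "n_discordant": n_disc,
            "pct_failed_1dp": _pct(n_failed, n, 1),
            "pct_failed_2dp": _pct(n_failed, n, 2),
            "pct_ambiguous_1dp": _pct(n_ambig, n, 1),
            "pct_discordant_1dp": _pct(n_disc, n_prior, 1),
            "pct_discordant_2dp": _pct(n_disc, n_prior, 2),
        }
        for sp in species:
            row[f"n_assigned_{sp}"] = sum(c.call == sp for c in its_calls)
        return row

    rows = {
        "total": _summarize(metadata),
        "male": _summarize(metadata[metadata["sex"] == "male"]),
        "female": _summarize(metadata[metadata["sex"] == "female"]),
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return AssayReport(table)


def curves_to_frame(curves: Iterable[MeltCurve]) -> pd.DataFrame:
    """Long-format melt-curve table (specimen_id, temp_C, fluorescence)."""
    frames = [
        pd.DataFrame(
            {
                "specimen_id": c.specimen_id,
                "temp_C": c.temps_C,
                "fluorescence": c.fluorescence,
            }
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)


def frame_to_curves(df: pd.DataFrame) -> list[MeltCurve]:
    required = {"specimen_id", "temp_C", "fluorescence"}
    if not required <= set(df.columns):
        raise InputError(f"curve table must have columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("temp_C")
        out.append(
            MeltCurve(str(sid), grp["temp_C"].to_numpy(), grp["fluorescence"].to_numpy())
        )
    return out
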
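"""NMR-detected hydrogen/deuterium exchange in the EX2 limit.

The observed per-residue signal decay S/N(t) = A exp(-k_obs t) is fitted by
least squares.  In the EX2 regime the opening equilibrium constant is
K_ex = k_obs / k_int with k_int the sequence-dependent intrinsic exchange
rate (supplied as an external table, e.g. from the Sphere server); the
protection factor is P = K_ex^-1 and the open/closed free-energy
difference is

    dG_op/cl = -R T ln K_ex      (positive when the closed state is favoured)

Residues that exchange within the measurement dead time cannot be fitted
and are classified "fast" (half-life reported as "<15 min"); residues
without appreciable decay over the experiment horizon are "stable"
(">4000 min").  Chemical shift perturbations combine 1H and 15N shifts as
sqrt(ddH^2 + (w * ddN)^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import DEFAULT_TEMPERATURE_K, R_KJ_PER_MOL_K

FAST_HALF_LIFE_LABEL = "<15"
STABLE_HALF_LIFE_LABEL = ">4000"


@dataclass
class DecaySeries:
    residue: str
    time_min: np.ndarray
    sn: np.ndarray
    noise_sigma: float
    dead_time_min: float = 35.0
    horizon_min: float = 3600.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        s = np.asarray(self.sn, dtype=float)
        if len(t) < 1 or len(t) != len(s):
            raise ValueError("need equally many times and observations")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.noise_sigma <= 0:
            raise ValueError("noise level must be positive")
        self.time_min, self.sn = t, s


@dataclass
class HDXRecord:
    residue: str
    klass: str                       # fast | fitted | stable | excluded
    k_obs_per_min: float | None = None
    amplitude: float | None = None
    t_half_min: float | None = None
    t_half_label: str | None = None
    k_int_per_min: float | None = None
    K_ex: float | None = None
    protection: float | None = None
    dg_kj: float | None = None
    unprotected: bool = False
    reason: str | None = None


def fit_decay(series: DecaySeries, outlier_sigma: float = 6.0) -> HDXRecord:
    """Classify and, where possible, fit a first-order exponential decay.

    Classification precedes fitting: a residue whose signal never rises
    above 3x the noise level is "fast" (exchanged within the dead time); a
    residue whose total decay over the horizon is below 5% is "stable".
    Otherwise A exp(-k t) is fitted (A > 0, k > 0, no baseline: the fully
    exchanged signal falls into the noise).  Gross non-monotone outliers
    (> ``outlier_sigma`` x noise from the fit) mark the series "excluded",
    as overlapping peaks would in a real spectrum.
    """
    t, s = series.time_min, series.sn
    sig = series.noise_sigma
    if np.max(s) <= 3.0 * sig:
        return HDXRecord(series.residue, "fast",
                         t_half_min=None, t_half_label=FAST_HALF_LIFE_LABEL)
    head = s[: max(1, min(3, len(s)))].mean()
    tail = s[-max(1, min(3, len(s))):].mean()
    if head > 0 and (head - tail) / head < 0.05:
        return HDXRecord(series.residue, "stable",
                         t_half_min=None, t_half_label=STABLE_HALF_LIFE_LABEL)
    # initial guess from a log-linear fit on the clearly positive points
    pos = s > max(3.0 * sig, 1e-12)
    if pos.sum() >= 2:
        slope, icept = np.polyfit(t[pos], np.log(s[pos]), 1)
        p0 = (float(np.exp(icept)), float(max(-slope, 1e-6)))
    else:
        p0 = (float(s[0]), 1e-3)
    try:
        popt, _ = curve_fit(
            lambda tt, a, k: a * np.exp(-k * tt), t, s, p0=p0,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000)
    except RuntimeError:
        return HDXRecord(series.residue, "excluded", reason="fit failed")
    a, k = float(popt[0]), float(popt[1])
    resid = s - a * np.exp(-k * t)
    if np.max(np.abs(resid)) > outlier_sigma * sig:
        return HDXRecord(series.residue, "excluded",
                         reason="gross outlier beyond robustness window")
    t_half = np.log(2.0) / k
    return HDXRecord(series.residue, "fitted", k_obs_per_min=k, amplitude=a,
                     t_half_min=t_half, t_half_label=f"{t_half:.1f}")


def intrinsic_rate(table: dict[int, float] | pd.Series, position: int) -> float:
    """Intrinsic exchange rate at a position, averaged over the i-1, i, i+1
    entries present in the table (arithmetic mean)."""
    if isinstance(table, pd.Series):
        table = table.to_dict()
    vals = [table[p] for p in (position - 1, position, position + 1) if p in table]
    if not vals:
        raise KeyError(f"no intrinsic rate near position {position}")
    return float(np.mean(vals))


def protection(k_obs_per_min: float, k_int_per_min: float) -> tuple[float, float, bool]:
    """(K_ex, P, unprotected flag).  K_ex = k_obs/k_int, P = k_int/k_obs;
    P < 1 means exchange faster than the intrinsic rate."""
    if k_obs_per_min <= 0 or k_int_per_min <= 0:
        raise ValueError("rates must be positive")
    K_ex = k_obs_per_min / k_int_per_min
    P = 1.0 / K_ex
    return K_ex, P, P < 1.0


def open_close_energy(K_ex: float,
                      temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """dG_op/cl = -R T ln(K_ex) in kJ/mol; positive for protected amides."""
    if K_ex <= 0:
        raise ValueError("K_ex must be positive")
    return -R_KJ_PER_MOL_K * temperature_K * np.log(K_ex)


def classify_dataset(records: list[HDXRecord]) -> dict[str, int]:
    counts = {"fast": 0, "fitted": 0, "stable": 0, "excluded": 0}
    for r in records:
        counts[r.klass] += 1
    return counts


def csp(dd_h_ppm, dd_n_ppm, nitrogen_weight: float = 0.14) -> np.ndarray | float:
    """Combined chemical shift perturbation sqrt(ddH^2 + (w ddN)^2), ppm."""
    if nitrogen_weight <= 0:
        raise ValueError("nitrogen weight must be positive")
    h = np.asarray(dd_h_ppm, dtype=float)
    n = np.asarray(dd_n_ppm, dtype=float)
    out = np.sqrt(h ** 2 + (nitrogen_weight * n) ** 2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# dataset-level driver and TSV I/O
# ---------------------------------------------------------------------------

def read_decay_table(path: str | Path) -> pd.DataFrame:
    """Long-form TSV with columns residue, time_min, sn."""
    df = pd.read_csv(path, sep="\t")
    missing = {"residue", "time_min", "sn"} - set(df.columns)
    if missing:
        raise ValueError(f"decay table lacks columns {sorted(missing)}")
    return df


def read_intrinsic_rates(path: str | Path) -> dict[int, float]:
    """TSV with columns position, k_int_per_min."""
    df = pd.read_csv(path, sep="\t")
    missing = {"position", "k_int_per_min"} - set(df.columns)
    if missing:
        raise ValueError(f"intrinsic rate table lacks columns {sorted(missing)}")
    return dict(zip(df["position"].astype(int), df["k_int_per_min"].astype(float)))


def analyze_decay_table(
    table: pd.DataFrame,
    noise_sigma: float,
    intrinsic: dict[int, float] | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> list[HDXRecord]:
    """Fit every residue of a long-form decay table; when an intrinsic-rate
    table is given, derive K_ex, protection factor and dG for the fitted
    residues (residue ids must then be integer sequence positions)."""
    records = []
    for residue, grp in table.groupby("residue", sort=False):
        grp = grp.sort_values("time_min")
        series = DecaySeries(residue=str(residue),
                             time_min=grp["time_min"].to_numpy(),
                             sn=grp["sn"].to_numpy(),
                             noise_sigma=noise_sigma)
        rec = fit_decay(series)
        if rec.klass == "fitted" and intrinsic is not None:
            try:
                pos = int(residue)
            except (TypeError, ValueError):
                pos = None
            if pos is not None:
                rec.k_int_per_min = intrinsic_rate(intrinsic, pos)
                rec.K_ex, rec.protection, rec.unprotected = protection(
                    rec.k_obs_per_min, rec.k_int_per_min)
                rec.dg_kj = open_close_energy(rec.K_ex, temperature_K)
        records.append(rec)
    return records


def records_to_frame(records: list[HDXRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
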
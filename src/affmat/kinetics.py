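"""1:1 Langmuir SPR kinetics: forward model, global fitting, table arithmetic.

The single-site reversible binding model

    association  (0 <= t <= t_assoc):
        R(t) = Req * (1 - exp(-(ka*C + kd) * t)),
        Req  = ka * C * Rmax / (ka * C + kd)
    dissociation (t > t_assoc):
        R(t) = R(t_assoc) * exp(-kd * (t - t_assoc))

with ka in M^-1 s^-1, kd in s^-1, C the analyte concentration in M and
responses in resonance units (RU).  K_D = kd/ka.  Fitting is a global
nonlinear least squares sharing (ka, kd, Rmax) across curves of
different concentrations (per-curve local fits available behind a
flag), with reproducible initial guesses: kd from a log-linear fit of
the dissociation tail and ka from the linearized observed rate
k_obs = ka*C + kd.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import lmfit

__all__ = [
    "Sensorgram", "KineticFit", "AffinityRow", "KineticsError",
    "IdentifiabilityWarning", "langmuir_response", "simulate_sensorgram",
    "fit_langmuir", "kd_from_rates", "fold_increase",
    "summarize_affinity_table", "affinity_rows_to_frame",
]


class KineticsError(ValueError):
    """Invalid kinetic parameters or unfittable data."""


class IdentifiabilityWarning(UserWarning):
    """The data constrain the kinetic parameters only weakly."""


@dataclass
class Sensorgram:
    """An SPR response trace for one analyte concentration."""

    times: np.ndarray            # s, strictly increasing
    response: np.ndarray         # RU
    analyte_concentration: float  # M
    t_assoc_end: float           # s
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise KineticsError("a sensorgram needs >= 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise KineticsError("times must be strictly increasing")
        if self.response.shape != self.times.shape:
            raise KineticsError("times and response must align")
        if not (self.times[0] <= self.t_assoc_end <= self.times[-1]):
            raise KineticsError("t_assoc_end outside the time range")
        if self.analyte_concentration <= 0:
            raise KineticsError("analyte concentration must be positive")


@dataclass
class KineticFit:
    """Fitted 1:1 Langmuir parameters; KD = kd/ka by construction."""

    ka: float                    # M^-1 s^-1
    kd: float                    # s^-1
    Rmax: float                  # RU
    stderr: Dict[str, Optional[float]] = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.Rmax <= 0:
            raise KineticsError("ka, kd and Rmax must be positive")

    @property
    def KD(self) -> float:
        return self.kd / self.ka


def langmuir_response(t: np.ndarray, ka: float, kd: float, Rmax: float,
                      conc: float, t_assoc: float) -> np.ndarray:
    """Closed-form 1:1 Langmuir response over association + dissociation."""
    t = np.asarray(t, dtype=float)
    kobs = ka * conc + kd
    req = ka * conc * Rmax / kobs
    r_assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - math.exp(-kobs * t_assoc))
    r_dissoc = r_end * np.exp(-kd * np.maximum(t - t_assoc, 0.0))
    return np.where(t <= t_assoc, r_assoc, r_dissoc)


def simulate_sensorgram(ka: float, kd: float, Rmax: float, conc: float,
                        t_assoc: float = 90.0, t_dissoc: float = 1800.0,
                        dt: float = 1.0, noise_sd: float = 0.0,
                        seed: Optional[int] = None,
                        label: str = "") -> Sensorgram:
    """Simulate a sensorgram from the closed-form model plus Gaussian noise."""
    for name, v in (("ka", ka), ("kd", kd), ("Rmax", Rmax), ("conc", conc),
                    ("t_assoc", t_assoc), ("t_dissoc", t_dissoc), ("dt", dt)):
        if v <= 0:
            raise KineticsError(f"{name} must be positive, got {v}")
    if noise_sd < 0:
        raise KineticsError("noise_sd must be >= 0")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    response = langmuir_response(times, ka, kd, Rmax, conc, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, size=times.shape)
    return Sensorgram(times=times, response=response,
                      analyte_concentration=conc, t_assoc_end=t_assoc,
                      label=label or f"C={conc:.3g} M")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _initial_guesses(curves: Sequence[Sensorgram]) -> Dict[str, float]:
    """Reproducible starting values for the global fit.

    kd: log-linear regression of the dissociation tail of the curve with
    the largest response.  ka: linear regression of per-curve observed
    association rates k_obs against concentration (slope = ka), with
    k_obs from a coarse exponential fit of the association phase.
    """
    by_resp = max(curves, key=lambda c: float(np.nanmax(np.abs(c.response))))
    mask = by_resp.times > by_resp.t_assoc_end
    t_d = by_resp.times[mask]
    r_d = by_resp.response[mask]
    pos = r_d > max(1e-3, 0.01 * np.nanmax(np.abs(r_d), initial=1e-3))
    kd0 = 1e-3
    if pos.sum() >= 3:
        slope = np.polyfit(t_d[pos], np.log(r_d[pos]), 1)[0]
        if slope < 0:
            kd0 = float(-slope)

    kobs, concs = [], []
    for c in curves:
        mask = c.times <= c.t_assoc_end
        t_a, r_a = c.times[mask], c.response[mask]
        plateau = float(np.nanmax(r_a))
        if plateau <= 0:
            continue
        # time to reach ~63% of plateau approximates 1/kobs
        reached = t_a[r_a >= 0.6321 * plateau]
        if reached.size and reached[0] > 0:
            kobs.append(1.0 / float(reached[0]))
            concs.append(c.analyte_concentration)
    if len(kobs) >= 2:
        slope = np.polyfit(concs, kobs, 1)[0]
        ka0 = float(slope) if slope > 0 else 1e4
    elif len(kobs) == 1:
        ka0 = max((kobs[0] - kd0) / concs[0], 1e2)
    else:
        ka0 = 1e4
    rmax0 = float(max(np.nanmax(np.abs(c.response)) for c in curves)) * 1.5
    return {"ka": ka0, "kd": kd0, "Rmax": max(rmax0, 1.0)}


def fit_langmuir(curves: Sequence[Sensorgram],
                 global_fit: bool = True) -> KineticFit:
    """Global 1:1 Langmuir fit sharing (ka, kd, Rmax) across curves.

    With ``global_fit=False`` each curve is fitted separately and the
    parameter medians are returned (Biacore-style local fitting).
    Raises on non-convergence (carrying the final residual) and on
    unidentifiable input such as a single flat curve; warns when the
    Fisher information is ill-conditioned (weak identifiability).
    """
    curves = list(curves)
    if not curves:
        raise KineticsError("no sensorgrams to fit")
    spans = [float(np.nanmax(c.response) - np.nanmin(c.response))
             for c in curves]
    if max(spans) < 1e-9:
        raise KineticsError("flat sensorgram(s): kinetics unidentifiable")

    if not global_fit and len(curves) > 1:
        fits = [fit_langmuir([c], global_fit=True) for c in curves]
        ka = float(np.median([f.ka for f in fits]))
        kd = float(np.median([f.kd for f in fits]))
        rmax = float(np.median([f.Rmax for f in fits]))
        rss = float(sum(f.rss for f in fits))
        return KineticFit(ka=ka, kd=kd, Rmax=rmax, rss=rss,
                          n_points=sum(f.n_points for f in fits))

    guesses = _initial_guesses(curves)
    params = lmfit.Parameters()
    # log-scale parametrization keeps rates positive and well-scaled
    params.add("log_ka", value=math.log10(guesses["ka"]), min=-2, max=12)
    params.add("log_kd", value=math.log10(guesses["kd"]), min=-12, max=3)
    params.add("Rmax", value=guesses["Rmax"], min=1e-6)

    def residual(p):
        ka = 10.0 ** p["log_ka"].value
        kd = 10.0 ** p["log_kd"].value
        rmax = p["Rmax"].value
        res = [c.response - langmuir_response(c.times, ka, kd, rmax,
                                              c.analyte_concentration,
                                              c.t_assoc_end)
               for c in curves]
        return np.concatenate(res)

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise KineticsError(
            f"Langmuir fit did not converge (final residual sum of squares "
            f"{float(np.sum(result.residual**2)):.4g}): {result.message}")

    ka = 10.0 ** result.params["log_ka"].value
    kd = 10.0 ** result.params["log_kd"].value
    rmax = float(result.params["Rmax"].value)
    rss = float(np.sum(result.residual ** 2))

    # Fisher-information conditioning as an identifiability check
    ill_conditioned = False
    if result.covar is None:
        ill_conditioned = True
    else:
        eig = np.linalg.eigvalsh(result.covar)
        if eig.min() <= 0 or eig.max() / eig.min() > 1e14:
            ill_conditioned = True
    if ill_conditioned or len(curves) == 1:
        warnings.warn(
            "kinetic parameters are weakly identified (single concentration "
            "or ill-conditioned fit); use >= 2 concentrations spanning KD",
            IdentifiabilityWarning, stacklevel=2)

    stderr: Dict[str, Optional[float]] = {"ka": None, "kd": None, "Rmax": None}
    lka, lkd = result.params["log_ka"], result.params["log_kd"]
    ln10 = math.log(10.0)
    if lka.stderr is not None:
        stderr["ka"] = ka * ln10 * lka.stderr
    if lkd.stderr is not None:
        stderr["kd"] = kd * ln10 * lkd.stderr
    if result.params["Rmax"].stderr is not None:
        stderr["Rmax"] = float(result.params["Rmax"].stderr)

    return KineticFit(ka=ka, kd=kd, Rmax=rmax, stderr=stderr, rss=rss,
                      n_points=int(sum(c.times.size for c in curves)))


# ---------------------------------------------------------------------------
# Affinity-table arithmetic
# ---------------------------------------------------------------------------

def kd_from_rates(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant K_D = kd/ka (M)."""
    if ka <= 0 or kd <= 0:
        raise KineticsError("rate constants must be positive")
    return kd / ka


def fold_increase(kd_wt: float, kd_mut: float) -> float:
    """Affinity fold-increase of a mutant: K_D(wild-type) / K_D(mutant)."""
    if kd_wt <= 0 or kd_mut <= 0:
        raise KineticsError("K_D values must be positive")
    return kd_wt / kd_mut


@dataclass
class AffinityRow:
    """One row of an affinity table (rates, K_D, fold-increase)."""

    mutant: str
    ka: float
    kd: float
    KD: float
    fold_increase: Optional[float] = None


_WT_NAMES = {"wild-type", "wildtype", "wt", "wild type"}


def summarize_affinity_table(rows: Sequence[AffinityRow],
                             threshold: float = 10.0) -> Dict[str, int]:
    """Count improved / worsened / strongly-improved mutants vs wild type.

    Returns ``n_improved`` (fold > 1), ``n_decreased`` (fold < 1) and
    ``n_ge_threshold`` (fold >= threshold), excluding the wild-type row.
    The fold is taken from the row when present, else recomputed from the
    wild-type K_D.
    """
    wt = next((r for r in rows if r.mutant.strip().lower() in _WT_NAMES), None)
    if wt is None:
        raise KineticsError("affinity table lacks a wild-type row")
    n_improved = n_decreased = n_ge = 0
    for r in rows:
        if r is wt:
            continue
        fold = r.fold_increase if r.fold_increase is not None \
            else fold_increase(wt.KD, r.KD)
        if fold > 1:
            n_improved += 1
        elif fold < 1:
            n_decreased += 1
        if fold >= threshold:
            n_ge += 1
    return {"n_improved": n_improved, "n_decreased": n_decreased,
            "n_ge_threshold": n_ge}


def affinity_rows_to_frame(rows: Sequence[AffinityRow]):
    import pandas as pd

    return pd.DataFrame([
        {"mutant": r.mutant, "ka_per_M_s": r.ka, "kd_per_s": r.kd,
         "KD_M": r.KD, "fold_increase": r.fold_increase}
        for r in rows
    ])


# ---------------------------------------------------------------------------
# Sensorgram CSV layout: time_s,response_RU,conc_M,phase
# ---------------------------------------------------------------------------

def sensorgrams_to_frame(curves: Sequence[Sensorgram]):
    import pandas as pd

    frames = []
    for c in curves:
        phase = np.where(c.times <= c.t_assoc_end, "assoc", "dissoc")
        frames.append(pd.DataFrame({
            "time_s": c.times, "response_RU": c.response,
            "conc_M": c.analyte_concentration, "phase": phase}))
    return pd.concat(frames, ignore_index=True)


def sensorgrams_from_frame(frame) -> List[Sensorgram]:
    curves = []
    for conc, grp in frame.groupby("conc_M", sort=True):
        grp = grp.sort_values("time_s")
        assoc = grp[grp["phase"] == "assoc"]
        if assoc.empty:
            raise KineticsError(f"curve at {conc} M has no association phase")
        curves.append(Sensorgram(
            times=grp["time_s"].to_numpy(),
            response=grp["response_RU"].to_numpy(),
            analyte_concentration=float(conc),
            t_assoc_end=float(assoc["time_s"].max())))
    return curves
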
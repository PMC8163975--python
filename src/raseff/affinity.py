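"""Quadratic (ligand-depletion) binding model for fluorescence-polarization titrations.

A labeled GTPase is held at a fixed total concentration ``R`` (typically
1 uM of the mGppNHp-loaded protein) while the effector domain is titrated
over a wide range ``L`` (typically 0.002-300 uM).  Because ``R`` is
comparable to the dissociation constants of interest, the free-ligand
approximation (simple hyperbola) is biased and the exact 1:1 isotherm is
required.  The fraction of receptor bound is the physical root of

    R*fb^2 - (R + L + Kd)*fb + L = 0

i.e. ``fb = ((R + L + Kd) - sqrt((R + L + Kd)^2 - 4*R*L)) / (2*R)``,
and the observed polarization is the linear readout
``P = P_free + (P_bound - P_free) * fb``.

Fitted Kd values are classified into the affinity bands used throughout
this package: high (0.1-5 uM), intermediate (6-30 uM), low (31-90 uM),
very low (91-510 uM) and no binding (> 500 uM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TitrationDataset",
    "BindingFit",
    "FitComparison",
    "fraction_bound",
    "titration_signal",
    "fit_titration",
    "classify_affinity",
    "compare_fits",
    "read_titration_csv",
    "write_titration_csv",
]

#: Kd above which a pair is reported as non-binding (uM).
NO_BINDING_KD = 500.0

#: Band edges in uM.  The printed band ranges (0.1-5, 6-30, 31-90, 91-510)
#: leave gaps between bands; half-open intervals split each gap at its
#: midpoint so that every positive Kd classifies deterministically.
_BAND_EDGES = (5.5, 30.5, 90.5)
_BAND_NAMES = ("high", "intermediate", "low", "very_low")

MIN_POINTS = 6


def fraction_bound(receptor_total: float, effector_total, kd) -> np.ndarray | float:
    """Exact 1:1 bound fraction of the receptor under ligand depletion.

    Parameters
    ----------
    receptor_total : float
        Total labeled-receptor concentration R (uM), > 0.
    effector_total : float or array
        Total titrant concentration(s) L (uM), >= 0.
    kd : float or array
        Dissociation constant (uM), >= 0.

    Returns
    -------
    Bound fraction in [0, 1], with the shape broadcast from the inputs.

    Notes
    -----
    Computed as ``2L / (S + sqrt(S^2 - 4RL))`` with ``S = R + L + Kd``,
    which is algebraically equal to ``(S - sqrt(S^2 - 4RL)) / (2R)`` but
    avoids catastrophic cancellation when ``L << Kd``.
    """
    R = float(receptor_total)
    L = np.asarray(effector_total, dtype=float)
    K = np.asarray(kd, dtype=float)
    if R <= 0:
        raise ValueError(f"receptor_total must be > 0, got {R}")
    if np.any(L < 0):
        raise ValueError("effector concentrations must be >= 0")
    if np.any(K < 0):
        raise ValueError("kd must be >= 0")
    s = R + L + K
    disc = s * s - 4.0 * R * L
    # disc >= 0 analytically; clip round-off
    root = np.sqrt(np.maximum(disc, 0.0))
    denom = s + root
    fb = np.where(denom > 0, 2.0 * L / np.where(denom > 0, denom, 1.0), 0.0)
    fb = np.clip(fb, 0.0, 1.0)
    if np.ndim(effector_total) == 0 and np.ndim(kd) == 0:
        return float(fb)
    return fb


def titration_signal(effector_total, receptor_total: float, kd, p_free, p_bound):
    """Polarization signal of the quadratic binding model."""
    fb = fraction_bound(receptor_total, effector_total, kd)
    return p_free + (p_bound - p_free) * fb


@dataclass(frozen=True)
class TitrationDataset:
    """One titration series: effector concentration vs polarization signal."""

    receptor_total: float
    concentrations: tuple[float, ...]
    signals: tuple[float, ...]
    label: str = ""

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if len(conc) != len(self.signals):
            raise ValueError("concentrations and signals differ in length")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.receptor_total <= 0:
            raise ValueError("receptor_total must be > 0")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class BindingFit:
    """Result of fitting one titration with the quadratic model."""

    kd: float
    p_free: float
    p_bound: float
    kd_se: float
    p_free_se: float
    p_bound_se: float
    rss: float
    affinity_band: str
    converged: bool
    label: str = ""


@dataclass(frozen=True)
class FitComparison:
    """Fold change and significance for a pair of binding fits."""

    fold_change: float
    z: float
    p_value: float


def classify_affinity(kd: float) -> str:
    """Assign an affinity band to a dissociation constant (uM).

    high [0, 5.5) < intermediate [5.5, 30.5) < low [30.5, 90.5)
    < very_low [90.5, 500] < no_binding (> 500).
    """
    if not kd > 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if kd > NO_BINDING_KD:
        return "no_binding"
    for edge, name in zip(_BAND_EDGES, _BAND_NAMES):
        if kd < edge:
            return name
    return _BAND_NAMES[-1]


def _initial_guesses(data: TitrationDataset) -> tuple[float, float, float]:
    conc = np.asarray(data.concentrations)
    sig = np.asarray(data.signals)
    k = max(1, len(sig) // 10)
    p_free0 = float(np.mean(sig[:k]))
    p_bound0 = float(np.mean(sig[-k:]))
    half = p_free0 + 0.5 * (p_bound0 - p_free0)
    idx = int(np.argmin(np.abs(sig - half)))
    kd0 = float(conc[idx])
    return max(kd0, 1e-3), p_free0, p_bound0


def fit_titration(
    data: TitrationDataset,
    initial: tuple[float, float, float] | None = None,
    multistart: int = 5,
) -> BindingFit:
    """Nonlinear least-squares fit of (Kd, P_free, P_bound).

    Uses trust-region-reflective least squares with Kd bounded positive.
    The starting Kd is the concentration nearest half dynamic range;
    P_free/P_bound start at the first/last deciles of the signal.  On
    non-convergence the fit is restarted from ``multistart`` log-spaced
    Kd values spanning the concentration range.

    Degenerate series (no measurable dynamic range) and fits with
    Kd above 500 uM are reported with band ``no_binding``.
    """
    if len(data) < MIN_POINTS:
        raise ValueError(
            f"need >= {MIN_POINTS} points to fit, got {len(data)}"
        )
    conc = np.asarray(data.concentrations)
    sig = np.asarray(data.signals)
    R = data.receptor_total

    span = float(np.ptp(sig))
    if span == 0.0:
        warnings.warn(
            f"titration {data.label!r}: zero dynamic range, reporting no_binding",
            stacklevel=2,
        )
        return BindingFit(
            kd=math.inf, p_free=float(np.mean(sig)), p_bound=float(np.mean(sig)),
            kd_se=math.nan, p_free_se=math.nan, p_bound_se=math.nan,
            rss=float(np.sum((sig - sig.mean()) ** 2)),
            affinity_band="no_binding", converged=False, label=data.label,
        )

    def model(L, kd, p_free, p_bound):
        return titration_signal(L, R, kd, p_free, p_bound)

    kd0, pf0, pb0 = initial if initial is not None else _initial_guesses(data)
    starts = [(kd0, pf0, pb0)]
    for kd_alt in np.geomspace(conc[0], conc[-1], multistart):
        starts.append((float(kd_alt), pf0, pb0))

    lo = [1e-9, -np.inf, -np.inf]
    hi = [np.inf, np.inf, np.inf]
    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                model, conc, sig, p0=p0, bounds=(lo, hi),
                method="trf", maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(conc, *popt) - sig) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
        if rss <= 1e-12 * max(1.0, float(np.sum(sig**2))):
            break
    if best is None:
        return BindingFit(
            kd=math.inf, p_free=pf0, p_bound=pb0,
            kd_se=math.nan, p_free_se=math.nan, p_bound_se=math.nan,
            rss=math.inf, affinity_band="no_binding", converged=False,
            label=data.label,
        )
    popt, pcov, rss = best
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    kd = float(popt[0])
    converged = bool(np.all(np.isfinite(popt)))
    band = "no_binding" if (not converged or kd > NO_BINDING_KD) else classify_affinity(kd)
    return BindingFit(
        kd=kd, p_free=float(popt[1]), p_bound=float(popt[2]),
        kd_se=float(se[0]), p_free_se=float(se[1]), p_bound_se=float(se[2]),
        rss=rss, affinity_band=band, converged=converged, label=data.label,
    )


def compare_fits(fit_a: BindingFit, fit_b: BindingFit) -> FitComparison:
    """Fold change Kd_A / Kd_B with a z-test on the log-Kd difference.

    Standard errors of log Kd are propagated from the fitting standard
    errors by the delta method (se_log = se_kd / kd).  This mirrors error
    bars "derived from the fitting errors" when no replicates exist; it
    is an error-propagation approximation, not a replicate-based test.
    """
    for f in (fit_a, fit_b):
        if not f.converged:
            raise ValueError(f"cannot compare non-converged fit {f.label!r}")
    fold = fit_a.kd / fit_b.kd
    se_log = math.sqrt(
        (fit_a.kd_se / fit_a.kd) ** 2 + (fit_b.kd_se / fit_b.kd) ** 2
    )
    if se_log == 0:
        z = 0.0 if fold == 1.0 else math.inf
    else:
        z = (math.log(fit_a.kd) - math.log(fit_b.kd)) / se_log
    p = 2.0 * stats.norm.sf(abs(z))
    return FitComparison(fold_change=fold, z=z, p_value=float(p))


def read_titration_csv(path, receptor_total: float = 1.0,
                       label: str | None = None) -> TitrationDataset:
    """Read a titration CSV with columns concentration_uM, polarization."""
    df = pd.read_csv(path)
    missing = {"concentration_uM", "polarization"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("concentration_uM")
    return TitrationDataset(
        receptor_total=receptor_total,
        concentrations=tuple(df["concentration_uM"].astype(float)),
        signals=tuple(df["polarization"].astype(float)),
        label=label if label is not None else Path(str(path)).stem,
    )


def write_titration_csv(data: TitrationDataset, path) -> None:
    pd.DataFrame(
        {"concentration_uM": data.concentrations, "polarization": data.signals}
    ).to_csv(path, index=False)
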
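"""Fitness-effect statistics and enzyme characterization fits.

Distribution of fitness effects (DFE): per-variant activities relative to
wild type are binned as strongly deleterious (ratio < 0.1), mildly
deleterious (0.1 <= r < 1/1.5), neutral (1/1.5 <= r <= 1.5) or beneficial
(r > 1.5); cohort averages use the geometric mean, with below-detection
("censored") measurements floored at a configurable detection limit.
The specificity ratio — fold improvement of the promiscuous activity
divided by fold retention of the native one — separates strong trade-off
variants (> 100) from weak-trade-off generalists.

Kinetics: Michaelis-Menten parameters are obtained by nonlinear least
squares on initial rates, v0 = Vmax * S / (KM + S), with kcat = Vmax/[E]
and efficiency kcat/KM in M^-1 s^-1 (substrate concentrations in µM).
Melt temperatures are read off thermal-denaturation curves as the
temperature of the first-derivative maximum after light smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: Default detection floor for below-detection relative activities.
CENSOR_FLOOR = 0.01

#: Fitness-bin boundaries on the wild-type-relative activity ratio.
STRONG_DELETERIOUS_MAX = 0.1
NEUTRAL_MIN = 1 / 1.5
NEUTRAL_MAX = 1.5

FITNESS_BINS = ("strongly_deleterious", "mildly_deleterious", "neutral", "beneficial")


@dataclass
class ActivityRecord:
    """Per-variant activity for one substrate, relative to wild type."""

    variant_id: str
    substrate: str
    rel_activity: float
    v0_replicates: tuple[float, ...] = ()
    censored: bool = False

    def __post_init__(self) -> None:
        if self.rel_activity < 0:
            raise ValueError("rel_activity must be >= 0")


def classify_fitness(rel_activity: float) -> str:
    """Bin a wild-type-relative activity ratio.

    Boundary convention: exactly 0.1 is mildly deleterious, exactly 1.5 is
    neutral.
    """
    if rel_activity < 0:
        raise ValueError("rel_activity must be >= 0")
    if rel_activity < STRONG_DELETERIOUS_MAX:
        return "strongly_deleterious"
    if rel_activity < NEUTRAL_MIN:
        return "mildly_deleterious"
    if rel_activity <= NEUTRAL_MAX:
        return "neutral"
    return "beneficial"


def dfe_summary(records: Sequence[ActivityRecord],
                censor_floor: float = CENSOR_FLOOR,
                include_censored: bool = True) -> dict:
    """Bin fractions and geometric mean of relative activities.

    Censored records enter at ``censor_floor``; ``include_censored=False``
    drops them from the geometric mean (but never from the bin counts).
    """
    if not records:
        raise ValueError("need at least one activity record")
    values = []
    counts = {b: 0 for b in FITNESS_BINS}
    gm_values = []
    for r in records:
        v = max(r.rel_activity, censor_floor) if r.censored else r.rel_activity
        counts[classify_fitness(v)] += 1
        values.append(v)
        if include_censored or not r.censored:
            gm_values.append(max(v, censor_floor) if v == 0 else v)
    n = len(records)
    gm_arr = np.maximum(np.array(gm_values if gm_values else values), censor_floor)
    return {
        "n": n,
        "bin_counts": counts,
        "bin_fractions": {b: c / n for b, c in counts.items()},
        "geometric_mean": float(np.exp(np.mean(np.log(gm_arr)))),
    }


def specificity_ratio(rel_ae: float, rel_pte: float,
                      censor_floor: float = CENSOR_FLOOR,
                      strong_threshold: float = 100.0) -> tuple[float, str]:
    """Promiscuous-over-native activity ratio and its trade-off class.

    ``rel_ae`` is the fold change of the evolved (arylesterase) activity,
    ``rel_pte`` the fold retention of the native (phosphotriesterase)
    activity; the latter is floored at the detection limit.  Ratios above
    ``strong_threshold`` mark a strong negative trade-off, the rest are
    weak-trade-off generalists.
    """
    if rel_ae < 0 or rel_pte < 0:
        raise ValueError("relative activities must be >= 0")
    if rel_ae == 0 and rel_pte == 0:
        return float("nan"), "undefined"
    denom = max(rel_pte, censor_floor)
    ratio = rel_ae / denom
    return ratio, ("strong" if ratio > strong_threshold else "weak")


# -- Michaelis-Menten kinetics ----------------------------------------------


@dataclass
class KineticsFit:
    """Michaelis-Menten fit result.

    kcat in s^-1, KM in µM, efficiency kcat/KM in M^-1 s^-1.  Standard
    errors come from the parameter covariance of the least-squares fit.
    ``km_identifiable`` is False when the data do not span KM (relative
    SE of KM above 50%), in which case KM is reported but unreliable.
    """

    kcat: float
    km: float
    kcat_se: float
    km_se: float
    enzyme_conc: float  # same concentration units as the rates' enzyme basis
    km_identifiable: bool = True

    @property
    def efficiency(self) -> float:
        """kcat/KM in M^-1 s^-1 (KM given in µM)."""
        return self.kcat / (self.km * 1e-6)

    @property
    def efficiency_se(self) -> float:
        rel = np.hypot(self.kcat_se / self.kcat, self.km_se / self.km)
        return self.efficiency * rel


class FitError(RuntimeError):
    pass


def michaelis_menten(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def fit_michaelis_menten(concentrations_uM: Sequence[float], v0: Sequence[float],
                         enzyme_conc: float = 1.0) -> KineticsFit:
    """Nonlinear least-squares Michaelis-Menten fit of initial rates.

    ``v0`` must be in units of (enzyme_conc x s^-1) so that
    kcat = Vmax / enzyme_conc; substrate concentrations in µM.
    Initialized at Vmax = max(v0) and KM = S at half-maximal rate.
    """
    s = np.asarray(concentrations_uM, dtype=float)
    v = np.asarray(v0, dtype=float)
    if len(np.unique(s[s > 0])) < 4:
        raise FitError("need at least 4 distinct non-zero substrate concentrations")
    if np.any(v < 0):
        raise FitError("negative initial rates")
    vmax0 = float(v.max())
    half = vmax0 / 2
    km0 = float(s[np.argmin(np.abs(v - half))]) or float(np.median(s[s > 0]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(michaelis_menten, s, v, p0=[vmax0, km0],
                                   bounds=([0, 0], [np.inf, np.inf]), maxfev=10000)
    except Exception as e:  # pragma: no cover - scipy failure paths
        raise FitError(f"Michaelis-Menten fit failed: {e}") from e
    vmax, km = popt
    if not np.all(np.isfinite(popt)) or vmax <= 0 or km <= 0:
        raise FitError(f"non-physical fit: Vmax={vmax}, KM={km}")
    perr = np.sqrt(np.diag(pcov))
    kcat = vmax / enzyme_conc
    kcat_se = perr[0] / enzyme_conc
    km_se = perr[1]
    identifiable = np.isfinite(km_se) and km_se / km <= 0.5
    return KineticsFit(kcat=float(kcat), km=float(km), kcat_se=float(kcat_se),
                       km_se=float(km_se), enzyme_conc=enzyme_conc,
                       km_identifiable=bool(identifiable))


def catalytic_efficiency(kcat: float, km_uM: float) -> float:
    """kcat/KM in M^-1 s^-1 from kcat in s^-1 and KM in µM."""
    return kcat / (km_uM * 1e-6)


# -- thermal denaturation ----------------------------------------------------


@dataclass
class MeltResult:
    tm: float
    reliable: bool
    derivative: np.ndarray
    temperatures: np.ndarray


def tm_from_melt(temperatures: Sequence[float], fluorescence: Sequence[float],
                 smooth_window: int = 5) -> MeltResult:
    """Melt temperature as the first-derivative maximum of the melt curve.

    The fluorescence trace is smoothed with a centered moving average
    (default 5 points), differentiated by central differences, and Tm is
    the temperature at the derivative maximum.  A maximum on the grid
    boundary (flat or monotone-derivative curves) is flagged unreliable.
    """
    t = np.asarray(temperatures, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        fp = np.pad(f, pad, mode="edge")
        f = np.convolve(fp, kernel, mode="valid")
    df = np.gradient(f, t)
    i = int(np.argmax(df))
    # a trustworthy Tm needs an interior maximum that stands out from the
    # baseline derivative (flat or linearly ramping curves have none)
    margin = max(1, smooth_window // 2)
    interior = margin <= i < len(t) - margin
    baseline = float(np.median(df))
    prominent = df[i] > 0 and df[i] > 2 * max(baseline, 0)
    reliable = interior and prominent
    return MeltResult(tm=float(t[i]), reliable=bool(reliable), derivative=df,
                      temperatures=t)


# -- tabular I/O -------------------------------------------------------------


def read_activity_tsv(path) -> list[ActivityRecord]:
    """Read activity records from TSV (variant_id, substrate, rel_activity[, censored])."""
    df = pd.read_csv(path, sep="\t")
    recs = []
    for _, row in df.iterrows():
        recs.append(ActivityRecord(
            variant_id=str(row["variant_id"]),
            substrate=str(row["substrate"]),
            rel_activity=float(row["rel_activity"]),
            censored=bool(row.get("censored", False)),
        ))
    return recs
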
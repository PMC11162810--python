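"""Steady-state flavoenzyme kinetics and relative modification content.

The dihydrouridine synthases are FMN flavoenzymes whose reductive half
reaction consumes NAD(P)H; under air the NAD(P)H oxidase activity follows
Michaelis-Menten behaviour,

    v = kcat * [E] * [S] / (KM + [S]),

monitored at 340 nm.  Fits report kcat (s^-1), KM (uM) and the catalytic
efficiency kcat/KM (uM^-1 s^-1), with asymptotic standard errors.  Substrate
preference (NADH vs NADPH) is decided on the efficiency fold ratio with a
1.5-fold indifference band: below it the enzyme is reported as not
discriminating.

tRNA binding monitored through FMN fluorescence is cooperative and fitted
with a Hill isotherm, dF = A * S^n / (K_half^n + S^n).

Relative dihydrouridine content across strains is bookkept as the D ion
signal normalized to the adenosine UV signal of the same run, expressed as a
percentage of the same ratio in the reference (wild-type) sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RateSeries", "KineticFit", "BindingFit", "DContentReport",
    "EfficiencyComparison", "KineticsError", "fit_michaelis_menten",
    "compare_efficiencies", "fit_hill", "relative_d_content",
    "read_rate_table", "rate_from_a340_slope", "NADPH_EXTINCTION_340",
]

#: Molar extinction coefficient of NAD(P)H at 340 nm (M^-1 cm^-1), 1 cm path;
#: used to convert A340 slopes to rates when raw absorbance traces are supplied.
NADPH_EXTINCTION_340 = 6220.0

INDIFFERENCE_FOLD = 1.5


class KineticsError(ValueError):
    """Fit failure or degenerate kinetic design."""


@dataclass
class RateSeries:
    substrate_conc: np.ndarray    # uM
    initial_rate: np.ndarray      # uM s^-1
    enzyme_conc: float            # uM
    substrate_name: str = ""

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.initial_rate = np.asarray(self.initial_rate, dtype=float)
        if self.substrate_conc.shape != self.initial_rate.shape:
            raise KineticsError("concentration and rate lists differ in length")
        if (self.substrate_conc <= 0).any():
            raise KineticsError("substrate concentrations must be positive")
        if len(np.unique(self.substrate_conc)) != len(self.substrate_conc):
            raise KineticsError("substrate concentrations must be distinct")
        if self.enzyme_conc <= 0:
            raise KineticsError("enzyme concentration must be positive")


@dataclass(frozen=True)
class KineticFit:
    kcat: float          # s^-1
    KM: float            # uM
    kcat_se: float
    KM_se: float
    substrate_name: str = ""

    @property
    def efficiency(self) -> float:
        """kcat/KM in uM^-1 s^-1."""
        return self.kcat / self.KM

    @property
    def efficiency_se(self) -> float:
        # first-order error propagation for the quotient
        rel = np.hypot(self.kcat_se / self.kcat, self.KM_se / self.KM)
        return self.efficiency * float(rel)


@dataclass(frozen=True)
class BindingFit:
    K_half: float        # uM
    hill_n: float
    amplitude: float
    K_half_se: float
    hill_n_se: float
    amplitude_se: float


@dataclass(frozen=True)
class DContentReport:
    strain: str
    relative_D: float    # percent of the reference strain
    normalization: str = "adenosine_UV"


def michaelis_menten(s, kcat, km, enzyme_conc):
    return kcat * enzyme_conc * s / (km + s)


def fit_michaelis_menten(series: RateSeries) -> KineticFit:
    """Bounded nonlinear least squares of the Michaelis-Menten rate law.

    Initial guesses are deterministic: Vmax0 = max rate, KM0 = median [S].
    Raises when fewer than 5 distinct concentrations are given or when KM is
    unidentifiable (a saturating-plateau design leaves the curvature
    unconstrained, detected through the asymptotic relative error of KM).
    """
    s = series.substrate_conc
    v = series.initial_rate
    if len(s) < 5:
        raise KineticsError("need >= 5 distinct substrate concentrations")
    e = series.enzyme_conc
    vmax0 = float(np.max(v))
    km0 = float(np.median(s))
    p0 = (max(vmax0 / e, 1e-12), km0)
    # normalize residuals to the observed rate scale so the optimizer's
    # gradient test is insensitive to the absolute magnitude of the rates
    sigma = np.full(len(v), max(float(np.max(np.abs(v))), 1e-30))
    try:
        popt, pcov = curve_fit(
            lambda x, kcat, km: michaelis_menten(x, kcat, km, e),
            s, v, p0=p0, sigma=sigma,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            x_scale=list(p0), maxfev=20000)
    except RuntimeError as exc:
        raise KineticsError(
            f"Michaelis-Menten fit did not converge (initial guesses "
            f"kcat0={p0[0]:.4g}, KM0={p0[1]:.4g})") from exc
    kcat, km = popt
    perr = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(perr)):
        raise KineticsError("KM unidentifiable: singular fit covariance "
                            "(concentration grid does not constrain KM)")
    if km <= 0 or kcat <= 0:
        raise KineticsError("fit collapsed to a non-positive parameter")
    if km <= float(np.min(s)) / 2.0 or perr[1] / km > 1.0:
        # all sampled concentrations sit far above KM: saturating-plateau
        # design, the hyperbola's curvature is unconstrained
        raise KineticsError(
            f"KM unidentifiable from this design (KM={km:.3g} +/- {perr[1]:.3g} uM); "
            f"include concentrations below and above KM")
    return KineticFit(float(kcat), float(km), float(perr[0]), float(perr[1]),
                      substrate_name=series.substrate_name)


@dataclass(frozen=True)
class EfficiencyComparison:
    efficiency_fold: float       # >= 1
    kcat_fold: float             # >= 1, fold of the efficiency-preferred substrate
    preferred: str | None        # None inside the indifference band
    numerator: str


def compare_efficiencies(fit_a: KineticFit, fit_b: KineticFit,
                         indifference_fold: float = INDIFFERENCE_FOLD,
                         ) -> EfficiencyComparison:
    """Fold ratio of catalytic efficiencies, >= 1, with preference label."""
    ea, eb = fit_a.efficiency, fit_b.efficiency
    if ea >= eb:
        hi, lo = fit_a, fit_b
    else:
        hi, lo = fit_b, fit_a
    fold = hi.efficiency / lo.efficiency
    kcat_fold = hi.kcat / lo.kcat if hi.kcat >= lo.kcat else lo.kcat / hi.kcat
    preferred = hi.substrate_name if fold >= indifference_fold else None
    return EfficiencyComparison(float(fold), float(kcat_fold), preferred,
                                numerator=hi.substrate_name)


def hill(s, amplitude, k_half, n):
    s = np.asarray(s, dtype=float)
    return amplitude * s ** n / (k_half ** n + s ** n)


def fit_hill(conc, delta_f) -> BindingFit:
    """Fit the cooperative binding isotherm dF = A*S^n/(K^n + S^n)."""
    s = np.asarray(conc, dtype=float)
    f = np.asarray(delta_f, dtype=float)
    if s.shape != f.shape:
        raise KineticsError("concentration and signal lists differ in length")
    if len(s) < 6:
        raise KineticsError("need >= 6 titration points")
    if (s <= 0).any():
        raise KineticsError("titration concentrations must be positive")
    a0 = float(np.max(np.abs(f)))
    half = a0 / 2.0
    k0 = float(s[np.argmin(np.abs(f - half))])
    try:
        popt, pcov = curve_fit(hill, s, f, p0=(a0, max(k0, 1e-6), 1.0),
                               bounds=([0, 0, 0.05], [np.inf, np.inf, 10.0]),
                               maxfev=20000)
    except RuntimeError as exc:
        raise KineticsError("Hill fit did not converge") from exc
    perr = np.sqrt(np.diag(pcov))
    return BindingFit(K_half=float(popt[1]), hill_n=float(popt[2]),
                      amplitude=float(popt[0]), K_half_se=float(perr[1]),
                      hill_n_se=float(perr[2]), amplitude_se=float(perr[0]))


def relative_d_content(sample: tuple[float, float],
                       reference: tuple[float, float],
                       strain: str = "") -> DContentReport:
    """Percent D content: (D/A)_sample / (D/A)_reference x 100.

    ``sample`` and ``reference`` are (D ion signal, adenosine UV signal)
    pairs; the adenosine normalization cancels loading differences, the
    reference division expresses the result relative to wild type.
    """
    d_s, a_s = sample
    d_r, a_r = reference
    if a_s <= 0 or a_r <= 0:
        raise KineticsError("adenosine UV signal must be positive")
    if d_r <= 0:
        raise KineticsError("reference D signal must be positive")
    ratio = (d_s / a_s) / (d_r / a_r)
    return DContentReport(strain, 100.0 * ratio)


def rate_from_a340_slope(slope_per_s: float,
                         extinction: float = NADPH_EXTINCTION_340,
                         path_cm: float = 1.0) -> float:
    """Convert an absorbance slope at 340 nm (A/s) to a rate in uM/s.

    Beer-Lambert: d[NAD(P)H]/dt = (dA/dt) / (epsilon * l), reported positive
    for consumption (a negative absorbance slope).
    """
    if extinction <= 0 or path_cm <= 0:
        raise KineticsError("extinction coefficient and path must be positive")
    return abs(slope_per_s) / (extinction * path_cm) * 1e6


def read_rate_table(source, enzyme_conc: float) -> dict[str, RateSeries]:
    """Kinetics TSV (substrate, conc_uM, rate) -> one RateSeries per substrate."""
    df = pd.read_csv(source, sep="\t")
    needed = {"substrate", "conc_uM", "rate"}
    if not needed <= set(df.columns):
        raise KineticsError(f"kinetics table needs columns {sorted(needed)}")
    out = {}
    for name, grp in df.groupby("substrate", sort=False):
        out[str(name)] = RateSeries(grp["conc_uM"].to_numpy(),
                                    grp["rate"].to_numpy(),
                                    enzyme_conc=enzyme_conc,
                                    substrate_name=str(name))
    return out
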
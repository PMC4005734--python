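"""Cascade-impactor data reduction for radiolabeled aerosols.

Reduces per-stage radioactivity deposits from a low-pressure cascade impactor
into a cumulative activity size distribution and its summary metrics: the
activity median aerodynamic diameter (AMAD), the geometric standard deviation
(GSD), the one-sigma diameters d16/d84, sub-cutoff activity fractions (fine
particles < 2.5 um, ultrafine < 0.1 um, ...), and the emitted nebulizer
fraction.

Conventions
-----------
* Interpolation is linear in (ln diameter, cumulative fraction) space, the
  standard treatment for aerodynamic size distributions.
* d16 and d84 are the one-sigma points of the cumulative distribution,
  i.e. the diameters at cumulative fractions Phi(-1) = 15.87% and
  Phi(+1) = 84.13%.  For a lognormal aerosol this makes
  sqrt(d84/d16) equal the geometric standard deviation exactly.
* The throat-model deposit sits upstream of aerodynamic classification: it
  counts toward the emitted fraction but never toward the size distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StageDeposit",
    "ImpactorRun",
    "CumulativeActivityDistribution",
    "SizeDistributionSummary",
    "default_stage_bounds",
    "build_cumulative",
    "percentile_diameter",
    "fraction_below",
    "fit_lognormal",
    "summarize",
    "emitted_fraction",
    "P16",
    "P84",
    "DEFAULT_CUTOFFS_UM",
]

# one-sigma cumulative fractions defining d16/d84
P16: float = float(stats.norm.cdf(-1.0))
P84: float = float(stats.norm.cdf(1.0))

#: sub-cutoff diameters reported by summarize(): FP (<2.5 um), <1 um,
#: <0.5 um, UFP (<0.1 um)
DEFAULT_CUTOFFS_UM: tuple[float, ...] = (2.5, 1.0, 0.5, 0.1)


def default_stage_bounds(
    n_stages: int = 12, d_min_um: float = 0.007, d_max_um: float = 10.0
) -> np.ndarray:
    """Geometric ladder of ``n_stages + 1`` cut-point diameters (um).

    The default spans 7 nm to 10 um in 12 stages with a constant ratio in
    log space — a generic stand-in for a commercial 12-stage low-pressure
    impactor whose exact cut-point table must otherwise be supplied.
    """
    if n_stages < 1 or d_min_um <= 0 or d_max_um <= d_min_um:
        raise ValueError("need n_stages >= 1 and 0 < d_min < d_max")
    return np.exp(np.linspace(np.log(d_min_um), np.log(d_max_um), n_stages + 1))


@dataclass(frozen=True)
class StageDeposit:
    """Radioactivity collected on one impactor stage.

    Parameters
    ----------
    stage_index : int
        1-based stage number (0 is reserved for the throat model in CSV I/O).
    d_lower, d_upper : float
        Aerodynamic cut-point bounds of the stage, um.
    activity : float
        Collected activity in counts (arbitrary activity units), >= 0.
    """

    stage_index: int
    d_lower: float
    d_upper: float
    activity: float

    def __post_init__(self) -> None:
        if not self.d_lower < self.d_upper:
            raise ValueError(
                f"stage {self.stage_index}: d_lower {self.d_lower} must be "
                f"< d_upper {self.d_upper}"
            )
        if self.d_lower <= 0:
            raise ValueError(f"stage {self.stage_index}: diameters must be > 0")
        if self.activity < 0:
            raise ValueError(f"stage {self.stage_index}: activity must be >= 0")


@dataclass
class ImpactorRun:
    """One impactor acquisition: ordered stage deposits plus run metadata.

    ``stages`` must form a contiguous, strictly increasing diameter ladder.
    ``throat_activity`` is the deposit in the throat model upstream of stage 1.
    ``charge_before``/``charge_after`` are the syringe gamma-counter readings
    (MBq) before and after charging the nebulizer; their difference is the
    nebulizer charge.
    """

    stages: list[StageDeposit]
    throat_activity: float = 0.0
    charge_before: float | None = None
    charge_after: float | None = None
    flow_lpm: float | None = None

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("run needs at least one stage")
        if self.throat_activity < 0:
            raise ValueError("throat_activity must be >= 0")
        for a, b in zip(self.stages, self.stages[1:]):
            if not np.isclose(a.d_upper, b.d_lower, rtol=1e-9):
                raise ValueError(
                    f"stage ladder not contiguous between stages "
                    f"{a.stage_index} and {b.stage_index} "
                    f"({a.d_upper} vs {b.d_lower})"
                )

    @property
    def stage_total(self) -> float:
        """Total activity on the sizing stages (throat excluded)."""
        return float(sum(s.activity for s in self.stages))

    @property
    def collected_total(self) -> float:
        """Throat plus stage activity — everything the impactor caught."""
        return self.stage_total + self.throat_activity

    def bounds(self) -> np.ndarray:
        """The n+1 cut-point diameters of the ladder, ascending, um."""
        return np.array(
            [self.stages[0].d_lower] + [s.d_upper for s in self.stages]
        )


@dataclass
class CumulativeActivityDistribution:
    """Cumulative activity fraction vs aerodynamic diameter, as knots.

    ``diameters`` are the stage cut-points (strictly increasing, um);
    ``fractions`` the cumulative activity fraction at each, nondecreasing
    from 0 at the smallest bound to 1 at the largest.
    """

    diameters: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if d.shape != f.shape or d.ndim != 1 or d.size < 2:
            raise ValueError("need matching 1-D knot arrays with >= 2 knots")
        if not np.all(np.diff(d) > 0):
            raise ValueError("diameters must be strictly increasing")
        if np.any(np.diff(f) < 0):
            raise ValueError("cumulative fractions must be nondecreasing")
        if not (np.isclose(f[0], 0.0) and np.isclose(f[-1], 1.0)):
            raise ValueError("fractions must run from 0 to 1")
        self.diameters = d
        self.fractions = f


@dataclass
class SizeDistributionSummary:
    """Summary metrics of one activity size distribution.

    ``gsd`` is the percentile estimator sqrt(d84/d16); ``amad_fit``/``gsd_fit``
    come from a lognormal probit least-squares fit to the knots and are the
    better estimators when stage resolution is coarse.
    """

    amad: float
    gsd: float
    d16: float
    d84: float
    frac_below: dict[float, float] = field(default_factory=dict)
    emitted_fraction: float | None = None
    amad_fit: float | None = None
    gsd_fit: float | None = None


def build_cumulative(run: ImpactorRun) -> CumulativeActivityDistribution:
    """Cumulative activity distribution from per-stage deposits.

    The cumulative fraction at each stage's upper bound is the activity
    collected at or below that bound divided by the total stage activity.
    The throat deposit is excluded: it is collected before aerodynamic
    classification and carries no size information.

    Raises
    ------
    ValueError
        If fewer than 2 stages or zero total stage activity.
    """
    if len(run.stages) < 2:
        raise ValueError("need at least 2 stages to build a distribution")
    activities = np.array([s.activity for s in run.stages], dtype=float)
    total = activities.sum()
    if total <= 0:
        raise ValueError("zero total stage activity: no distribution")
    fractions = np.concatenate([[0.0], np.cumsum(activities) / total])
    # guard against cumsum round-off at the top knot
    fractions[-1] = 1.0
    return CumulativeActivityDistribution(run.bounds(), fractions)


def percentile_diameter(dist: CumulativeActivityDistribution, p: float) -> float:
    """Diameter at cumulative activity fraction ``p``.

    Interpolates linearly in (ln diameter, cumulative fraction) between the
    bracketing knots; ``p = 0.5`` defines the AMAD.  Never extrapolates
    beyond the outermost knots.
    """
    f = dist.fractions
    if not (f[0] <= p <= f[-1]):
        raise ValueError(f"p={p} outside the span [{f[0]}, {f[-1]}] of the knots")
    idx = int(np.searchsorted(f, p, side="left"))
    if f[idx] == p:  # exact knot: return its diameter exactly
        return float(dist.diameters[idx])
    lnd = np.log(dist.diameters)
    w = (p - f[idx - 1]) / (f[idx] - f[idx - 1])
    return float(np.exp(lnd[idx - 1] + w * (lnd[idx] - lnd[idx - 1])))


def fraction_below(dist: CumulativeActivityDistribution, cutoff_um: float) -> float:
    """Cumulative activity fraction below ``cutoff_um``.

    Log-linear interpolation between knots; clamps to 0 below the smallest
    bound and 1 above the largest.
    """
    if cutoff_um <= 0:
        raise ValueError("cutoff must be > 0")
    return float(
        np.interp(np.log(cutoff_um), np.log(dist.diameters), dist.fractions)
    )


def fit_lognormal(dist: CumulativeActivityDistribution) -> tuple[float, float]:
    """Least-squares lognormal fit (AMAD, GSD) in probit space.

    Regresses the normal quantile of the cumulative fraction on ln diameter
    over the interior knots (0 < fraction < 1).  For a run sampled from a
    lognormal without noise this recovers (AMAD, GSD) exactly at any stage
    count, unlike the percentile estimator which carries interpolation bias
    on coarse ladders.
    """
    f = dist.fractions
    interior = (f > 1e-9) & (f < 1 - 1e-9)
    if interior.sum() < 2:
        return float("nan"), float("nan")
    z = stats.norm.ppf(f[interior])
    x = np.log(dist.diameters[interior])
    slope, intercept = np.polyfit(x, z, 1)
    if slope <= 0:
        return float("nan"), float("nan")
    return float(np.exp(-intercept / slope)), float(np.exp(1.0 / slope))


def summarize(
    run: ImpactorRun,
    cutoffs_um: tuple[float, ...] = DEFAULT_CUTOFFS_UM,
    counts_per_mbq: float | None = None,
) -> SizeDistributionSummary:
    """Full size-distribution summary of one impactor run.

    AMAD is the median diameter, d16/d84 the one-sigma points, GSD the
    percentile estimator sqrt(d84/d16); a lognormal fit is reported
    alongside.  The emitted fraction is included when the run carries
    nebulizer charge readings (``counts_per_mbq`` bridges impactor counting
    units to MBq; defaults to 1, i.e. activities already in MBq).
    """
    dist = build_cumulative(run)
    d16 = percentile_diameter(dist, P16)
    d50 = percentile_diameter(dist, 0.5)
    d84 = percentile_diameter(dist, P84)
    amad_fit, gsd_fit = fit_lognormal(dist)
    ef = None
    if run.charge_before is not None and run.charge_after is not None:
        ef = emitted_fraction(run, counts_per_mbq=counts_per_mbq or 1.0)
    return SizeDistributionSummary(
        amad=d50,
        gsd=float(np.sqrt(d84 / d16)),
        d16=d16,
        d84=d84,
        frac_below={c: fraction_below(dist, c) for c in cutoffs_um},
        emitted_fraction=ef,
        amad_fit=amad_fit,
        gsd_fit=gsd_fit,
    )


def emitted_fraction(run: ImpactorRun, counts_per_mbq: float = 1.0) -> float:
    """Fraction of the nebulizer charge released as aerosol.

    The numerator is everything the impactor caught — the 12 stage deposits
    plus the throat-model deposit — converted from counting units to MBq via
    ``counts_per_mbq``.  The denominator is the nebulizer charge: the syringe
    activity before charging minus the residue left in the syringe after.
    """
    if run.charge_before is None or run.charge_after is None:
        raise ValueError("run carries no nebulizer charge readings")
    if run.charge_after < 0 or run.charge_before <= run.charge_after:
        raise ValueError(
            f"invalid charge readings: before={run.charge_before}, "
            f"after={run.charge_after}"
        )
    if counts_per_mbq <= 0:
        raise ValueError("counts_per_mbq must be > 0")
    charge = run.charge_before - run.charge_after
    ef = (run.collected_total / counts_per_mbq) / charge
    if ef > 1:
        warnings.warn(
            f"collected activity exceeds nebulizer charge (fraction {ef:.3f}); "
            "check the counts_per_mbq calibration",
            stacklevel=2,
        )
    return float(ef)
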
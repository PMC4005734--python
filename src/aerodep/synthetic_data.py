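"""Ground-truth synthetic inputs for the deposition pipeline.

Two generators stand in for the laboratory acquisitions:

* :func:`gen_impactor_run` — impactor runs sampled from a lognormal
  activity-weighted aerodynamic size distribution (AMAD, GSD), with optional
  Poisson counting noise, a throat-model deposit and nebulizer charge
  readings so the emitted fraction is recoverable.
* :func:`gen_phantom` — planar count phantoms with two ground-truth regions
  (extrathoracic ET above, thoracic TH below), region-specific attenuation,
  Gaussian point-spread blur, uniform background and Poisson counting
  statistics.

:func:`gen_study` assembles a full synthetic study — three subjects, each
inhaling each of three aerosols twice (six inhalations per nebulizer) — and
returns a truth ledger for parameter-recovery tests.  All generators are
pure functions of (spec, seed).

The three default aerosols mirror the study conditions: AMAD/GSD of
2.8 um/3.2, 550 nm/2.1 and 230 nm/1.6, with emitted fractions of 44.5%,
9.3% and 4.2% of a 74 MBq nebulizer charge and regional percent-of-emitted
truths of ET/TH = 3.7/1.3, 3.45/3.3 and 0.75/3.5.  The default count scale
(camera sensitivity 600 cps/MBq over 120 s) puts the smallest ROI near
1100 net counts, i.e. a Poisson relative accuracy of about 3%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .dosimetry import BreathingParameters, ExposureConfig
from .impactor_reduction import ImpactorRun, StageDeposit, default_stage_bounds
from .scintigraphy_quant import TC99M_HALF_LIFE_S, CorrectionSet, PlanarImage, ROIMask

__all__ = [
    "AerosolSpec",
    "PhantomTruth",
    "StudySet",
    "DEFAULT_AEROSOLS",
    "phantom_geometry",
    "gen_impactor_run",
    "gen_phantom",
    "corrections_for",
    "gen_study",
]


@dataclass(frozen=True)
class AerosolSpec:
    """Lognormal activity-weighted aerosol to sample onto impactor stages."""

    amad_um: float
    gsd: float
    total_activity: float = 1e5
    noise_model: str = "none"  # "none" | "poisson"
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.amad_um <= 0:
            raise ValueError("amad must be > 0")
        if self.gsd < 1:
            raise ValueError("gsd must be >= 1")
        if self.total_activity < 0:
            raise ValueError("total_activity must be >= 0")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class PhantomTruth:
    """Ground truth behind one planar phantom."""

    activities_mbq: dict[str, float]
    attenuation: dict[str, float] = field(
        default_factory=lambda: {"ET": 1.4, "TH": 2.0}
    )
    background_rate: float = 0.002  # counts/pixel/s
    psf_sigma: float = 1.5  # pixels
    acquisition_seconds: float = 120.0
    acquisition_start: float = 0.0
    sensitivity_cps_per_mbq: float = 600.0
    half_life_seconds: float = TC99M_HALF_LIFE_S
    noise_model: str = "poisson"  # "poisson" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for label, a in self.activities_mbq.items():
            if a < 0:
                raise ValueError(f"negative activity for {label}")
        for label, f in self.attenuation.items():
            if f < 1:
                raise ValueError(f"attenuation factor for {label} must be >= 1")
        if self.psf_sigma < 0:
            raise ValueError("psf sigma must be >= 0")


#: The three study aerosols: size distribution, emitted fraction of the
#: 74 MBq nebulizer charge, and true regional deposition as percent of the
#: emitted fraction.
DEFAULT_AEROSOLS: dict[str, dict] = {
    "1um-9um": dict(
        amad_um=2.8, gsd=3.2, emitted_fraction=0.445,
        pct_of_emitted={"ET": 3.7, "TH": 1.3},
    ),
    "0.25um-1um": dict(
        amad_um=0.55, gsd=2.1, emitted_fraction=0.093,
        pct_of_emitted={"ET": 3.45, "TH": 3.3},
    ),
    "0.15um-0.5um": dict(
        amad_um=0.23, gsd=1.6, emitted_fraction=0.042,
        pct_of_emitted={"ET": 0.75, "TH": 3.5},
    ),
}

DEFAULT_CHARGE_MBQ = 74.0


def gen_impactor_run(
    spec: AerosolSpec,
    stage_bounds: np.ndarray | None = None,
    emitted_fraction: float | None = None,
    throat_fraction: float = 0.15,
    charge_before: float = DEFAULT_CHARGE_MBQ,
    charge_after: float = 0.0,
    counts_per_mbq: float = 1000.0,
    flow_lpm: float = 10.0,
) -> ImpactorRun:
    """Sample a lognormal aerosol onto an impactor stage ladder.

    Expected activity on each stage is ``total x [CDF(d_upper) - CDF(d_lower)]``
    of the lognormal; mass outside the ladder is clamped into the end stages
    (with a warning when the ladder misses the central +/-3 ln-GSD span).
    With ``noise_model="poisson"`` each stage receives an independent Poisson
    draw; generation is deterministic given ``spec.seed``.

    When ``emitted_fraction`` is given the run is scaled so that
    (throat + stages) / (charge_before - charge_after) equals it, with
    ``throat_fraction`` of the emitted activity in the throat model; the
    charge readings are attached to the run.  Otherwise ``spec.total_activity``
    lands on the sizing stages and the charges are left unset.
    """
    bounds = (
        default_stage_bounds() if stage_bounds is None else np.asarray(stage_bounds)
    )
    if bounds.ndim != 1 or bounds.size < 3 or np.any(np.diff(bounds) <= 0):
        raise ValueError("stage_bounds must be an increasing ladder of >= 3 cuts")
    sigma = max(np.log(spec.gsd), 1e-12)
    lo_needed = spec.amad_um * np.exp(-3 * sigma)
    hi_needed = spec.amad_um * np.exp(3 * sigma)
    if bounds[0] > lo_needed or bounds[-1] < hi_needed:
        warnings.warn(
            f"stage ladder [{bounds[0]:.3g}, {bounds[-1]:.3g}] um does not "
            f"cover +/-3 ln-GSD of the aerosol "
            f"([{lo_needed:.3g}, {hi_needed:.3g}] um); tail mass clamped "
            "into the end stages",
            stacklevel=2,
        )
    cdf = stats.norm.cdf((np.log(bounds) - np.log(spec.amad_um)) / sigma)
    mass = np.diff(cdf)
    mass[0] += cdf[0]
    mass[-1] += 1.0 - cdf[-1]
    mass /= mass.sum()

    if emitted_fraction is not None:
        if not 0 < emitted_fraction <= 1:
            raise ValueError("emitted_fraction must be in (0, 1]")
        if not 0 <= throat_fraction < 1:
            raise ValueError("throat_fraction must be in [0, 1)")
        charge = charge_before - charge_after
        if charge <= 0:
            raise ValueError("charge_before must exceed charge_after")
        emitted_counts = emitted_fraction * charge * counts_per_mbq
        throat_expected = throat_fraction * emitted_counts
        stage_total = (1.0 - throat_fraction) * emitted_counts
    else:
        throat_expected = 0.0
        stage_total = spec.total_activity

    expected = stage_total * mass
    if spec.noise_model == "poisson":
        rng = np.random.default_rng(spec.seed)
        activities = rng.poisson(expected).astype(float)
        throat = float(rng.poisson(throat_expected)) if throat_expected else 0.0
    else:
        activities = expected
        throat = throat_expected

    stages = [
        StageDeposit(i + 1, float(bounds[i]), float(bounds[i + 1]), float(a))
        for i, a in enumerate(activities)
    ]
    if emitted_fraction is not None:
        return ImpactorRun(
            stages,
            throat_activity=throat,
            charge_before=charge_before,
            charge_after=charge_after,
            flow_lpm=flow_lpm,
        )
    return ImpactorRun(stages, throat_activity=throat, flow_lpm=flow_lpm)


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             radii: tuple[float, float]) -> np.ndarray:
    yy, xx = np.indices(shape)
    return ((yy - center[0]) / radii[0]) ** 2 + (
        (xx - center[1]) / radii[1]
    ) ** 2 <= 1.0


def phantom_geometry(shape: tuple[int, int] = (128, 128)) -> dict[str, np.ndarray]:
    """Fixed phantom geometry: source regions, ROI masks, background ROI.

    Two elliptical sources — head/ET in the upper field, thorax/TH below —
    with ROI masks dilated 7 pixels beyond the sources so that point-spread
    and smoothing spill stays inside the ROI, and a rectangular background
    ROI clear of both.  Keys: ``ET_source``, ``TH_source``, ``ET``, ``TH``,
    ``BACKGROUND``.
    """
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError("phantom geometry needs at least a 64x64 field")
    sy, sx = shape[0] / 128.0, shape[1] / 128.0
    et_src = _ellipse(shape, (24 * sy, 64 * sx), (11 * sy, 8 * sx))
    th_src = _ellipse(shape, (78 * sy, 64 * sx), (20 * sy, 16 * sx))
    geom = {
        "ET_source": et_src,
        "TH_source": th_src,
        "ET": ndimage.binary_dilation(et_src, iterations=7),
        "TH": ndimage.binary_dilation(th_src, iterations=7),
    }
    bg = np.zeros(shape, dtype=bool)
    bg[int(108 * sy): int(126 * sy), int(6 * sx): int(48 * sx)] = True
    geom["BACKGROUND"] = bg
    if np.any(geom["ET"] & geom["TH"]) or np.any(bg & (geom["ET"] | geom["TH"])):
        raise ValueError("phantom ROIs overlap at this image size")
    return geom


def gen_phantom(
    truth: PhantomTruth,
    shape: tuple[int, int] = (128, 128),
    geometry: dict[str, np.ndarray] | None = None,
) -> tuple[PlanarImage, list[ROIMask]]:
    """Simulate one planar acquisition from ground truth.

    Each region's activity is spread uniformly over its source ellipse at
    ``activity x sensitivity / attenuation`` counts/s, decayed to the
    acquisition start, blurred by a Gaussian point-spread function, summed
    with a uniform background rate, scaled by the acquisition duration and
    Poisson-sampled per pixel.  Deterministic given ``truth.seed``.
    """
    geom = phantom_geometry(shape) if geometry is None else geometry
    rate = np.zeros(shape, dtype=float)
    decay = 2.0 ** (-truth.acquisition_start / truth.half_life_seconds)
    for label, activity in truth.activities_mbq.items():
        src = geom.get(f"{label}_source")
        if src is None:
            raise ValueError(f"geometry has no source region for {label!r}")
        factor = truth.attenuation.get(label, 1.0)
        rate[src] += (
            activity * truth.sensitivity_cps_per_mbq * decay / factor / src.sum()
        )
    if truth.psf_sigma > 0:
        rate = ndimage.gaussian_filter(rate, truth.psf_sigma)
    rate += truth.background_rate
    if truth.noise_model == "poisson":
        rng = np.random.default_rng(truth.seed)
        counts = rng.poisson(rate * truth.acquisition_seconds)
    else:
        counts = rate * truth.acquisition_seconds
    img = PlanarImage(
        counts=counts,
        acquisition_seconds=truth.acquisition_seconds,
        acquisition_start=truth.acquisition_start,
    )
    masks = [
        ROIMask(label, geom[label]) for label in ("ET", "TH", "BACKGROUND")
    ]
    return img, masks


def corrections_for(truth: PhantomTruth) -> CorrectionSet:
    """The correction set matching a phantom's ground-truth parameters."""
    return CorrectionSet(
        half_life_seconds=truth.half_life_seconds,
        reference_time=0.0,
        attenuation_factor=dict(truth.attenuation),
    )


@dataclass
class StudySet:
    """A full synthetic study with its ground-truth ledger.

    ``phantoms`` rows are (subject, replicate, aerosol label, image, masks);
    ``truth`` is a tidy ledger with one row per phantom carrying the true
    regional activities, shares and percent-of-emitted values.
    """

    impactor_runs: dict[str, ImpactorRun]
    phantoms: list[tuple[str, int, str, PlanarImage, list[ROIMask]]]
    truth: pd.DataFrame
    exposures: dict[str, ExposureConfig]
    breathing: BreathingParameters
    corrections: CorrectionSet
    sensitivity_cps_per_mbq: float
    charge_mbq: float


def gen_study(
    seed: int = 0,
    n_subjects: int = 3,
    n_replicates: int = 2,
    aerosols: dict[str, dict] | None = None,
    between_inhalation_cv: float = 0.15,
    noise_model: str = "poisson",
    shape: tuple[int, int] = (128, 128),
) -> StudySet:
    """Generate the full synthetic study.

    Defaults mirror the study design: 3 subjects x 2 replicates x 3 aerosols
    (six inhalations per nebulizer -> 18 phantoms) plus one impactor run per
    aerosol.  Per-inhalation regional activities jitter lognormally around
    the aerosol's truth with coefficient of variation
    ``between_inhalation_cv``; the jittered values are what the truth ledger
    records, so recovery tests compare against per-inhalation truth.
    """
    aerosols = DEFAULT_AEROSOLS if aerosols is None else aerosols
    master = np.random.default_rng(seed)
    geom = phantom_geometry(shape)
    bp = BreathingParameters.baboon()

    runs: dict[str, ImpactorRun] = {}
    exposures: dict[str, ExposureConfig] = {}
    phantoms = []
    truth_rows = []
    corr = None
    sens = PhantomTruth(activities_mbq={}).sensitivity_cps_per_mbq
    sigma_j = np.sqrt(np.log1p(between_inhalation_cv**2))

    for label, cfg in aerosols.items():
        spec = AerosolSpec(
            amad_um=cfg["amad_um"],
            gsd=cfg["gsd"],
            noise_model=noise_model,
            seed=int(master.integers(0, 2**31 - 1)),
            label=label,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # broad aerosols exceed the ladder
            runs[label] = gen_impactor_run(
                spec, emitted_fraction=cfg["emitted_fraction"]
            )
        exposures[label] = ExposureConfig(
            emitted_fraction=cfg["emitted_fraction"], aerosol_label=label
        )
        emitted_mbq = cfg["emitted_fraction"] * DEFAULT_CHARGE_MBQ
        for subject in [f"S{i + 1}" for i in range(n_subjects)]:
            for repl in range(1, n_replicates + 1):
                jitter = {
                    r: float(np.exp(master.normal(-0.5 * sigma_j**2, sigma_j)))
                    for r in cfg["pct_of_emitted"]
                }
                acts = {
                    r: emitted_mbq * p / 100.0 * jitter[r]
                    for r, p in cfg["pct_of_emitted"].items()
                }
                truth = PhantomTruth(
                    activities_mbq=acts,
                    seed=int(master.integers(0, 2**31 - 1)),
                )
                if corr is None:
                    corr = corrections_for(truth)
                img, masks = gen_phantom(truth, shape=shape, geometry=geom)
                phantoms.append((subject, repl, label, img, masks))
                total = sum(acts.values())
                truth_rows.append(
                    {
                        "subject": subject,
                        "replicate": repl,
                        "aerosol": label,
                        "et_mbq": acts["ET"],
                        "th_mbq": acts["TH"],
                        "et_share": acts["ET"] / total,
                        "th_share": acts["TH"] / total,
                        "et_pct_of_emitted": 100 * acts["ET"] / emitted_mbq,
                        "th_pct_of_emitted": 100 * acts["TH"] / emitted_mbq,
                        "emitted_fraction": cfg["emitted_fraction"],
                        "phantom_seed": truth.seed,
                    }
                )

    return StudySet(
        impactor_runs=runs,
        phantoms=phantoms,
        truth=pd.DataFrame(truth_rows),
        exposures=exposures,
        breathing=bp,
        corrections=corr,
        sensitivity_cps_per_mbq=sens,
        charge_mbq=DEFAULT_CHARGE_MBQ,
    )
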
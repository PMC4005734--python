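"""Regional deposited-dose fraction accounting.

Converts corrected regional activities (extrathoracic ET, thoracic TH) into
the three standard normalizations of an inhalation exposure:

* share of the total deposited activity (ET + TH sum to 1),
* percent of the emitted nebulizer fraction,
* percent of the inhaled fraction, where the inhaled fraction is minute
  ventilation divided by nebulizer flow (inhalability losses neglected).

All internal quantities are fractions in [0, 1]; percent appears only in the
explicitly ``pct_``-named report fields and at rendering time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BreathingParameters",
    "ExposureConfig",
    "RegionDose",
    "DepositionReport",
    "inhaled_fraction",
    "et_th_balance",
    "pct_of_inhaled",
    "fold_ratio",
    "build_report",
    "aggregate_reports",
    "cross_species_compare",
]


@dataclass
class BreathingParameters:
    """Ventilation parameters of the exposed subject.

    ``minute_ventilation_lpm`` should agree with breathing_rate x
    tidal_volume within ``tolerance`` (relative); the measured value is
    authoritative.
    """

    breathing_rate_bpm: float
    tidal_volume_ml: float
    minute_ventilation_lpm: float
    ie_ratio: tuple[float, float] = (0.41, 0.59)
    tolerance: float = 0.15

    def __post_init__(self) -> None:
        if min(
            self.breathing_rate_bpm, self.tidal_volume_ml, self.minute_ventilation_lpm
        ) <= 0:
            raise ValueError("breathing parameters must be positive")
        if not np.isclose(sum(self.ie_ratio), 1.0, atol=1e-6):
            raise ValueError("I:E ratio fractions must sum to 1")
        derived = self.breathing_rate_bpm * self.tidal_volume_ml / 1000.0
        if abs(derived - self.minute_ventilation_lpm) > self.tolerance * derived:
            raise ValueError(
                f"minute ventilation {self.minute_ventilation_lpm} L/min "
                f"inconsistent with rate x tidal volume = {derived:.2f} L/min"
            )

    @classmethod
    def baboon(cls) -> "BreathingParameters":
        """Resting ventilation of the juvenile baboon subjects
        (35 breaths/min, 54 mL tidal volume, 1.8 L/min inspired air)."""
        return cls(35.0, 54.0, 1.8)

    @classmethod
    def adult_human(cls) -> "BreathingParameters":
        """Reference resting adult: ~9 L/min minute ventilation."""
        return cls(12.0, 750.0, 9.0)


@dataclass
class ExposureConfig:
    """Aerosol exposure conditions for one nebulizer/aerosol."""

    nebulizer_flow_lpm: float = 8.0
    emitted_fraction: float | None = None
    species_label: str = "baboon"
    aerosol_label: str = ""

    def __post_init__(self) -> None:
        if self.nebulizer_flow_lpm <= 0:
            raise ValueError("nebulizer flow must be > 0")
        if self.emitted_fraction is not None and not 0 <= self.emitted_fraction <= 1:
            raise ValueError("emitted_fraction must be in [0, 1]")


@dataclass
class RegionDose:
    share_of_total_deposited: float
    pct_of_emitted: float
    pct_of_inhaled: float


@dataclass
class DepositionReport:
    """Per-region deposition in all three normalizations for one inhalation."""

    regions: dict[str, RegionDose]
    total_deposited_pct_of_inhaled: float
    aerosol_label: str = ""
    species_label: str = "baboon"
    nebulizer_flow_lpm: float = 8.0
    minute_ventilation_lpm: float = 1.8


def inhaled_fraction(bp: BreathingParameters, ec: ExposureConfig) -> float:
    """Share of the emitted aerosol available for inhalation.

    Minute ventilation divided by nebulizer flow, neglecting inhalability
    losses.  Capped at 1 (with a warning) if ventilation exceeds flow.
    """
    frac = bp.minute_ventilation_lpm / ec.nebulizer_flow_lpm
    if frac > 1:
        warnings.warn(
            f"minute ventilation ({bp.minute_ventilation_lpm} L/min) exceeds "
            f"nebulizer flow ({ec.nebulizer_flow_lpm} L/min); capping inhaled "
            "fraction at 1",
            stacklevel=2,
        )
        return 1.0
    return float(frac)


def et_th_balance(et_activity: float, th_activity: float) -> tuple[float, float]:
    """(ET, TH) shares of the total deposited activity; sums to exactly 1."""
    if et_activity < 0 or th_activity < 0:
        raise ValueError("activities must be nonnegative")
    total = et_activity + th_activity
    if total == 0:
        raise ValueError("no deposited activity in either region")
    et = et_activity / total
    return float(et), float(1.0 - et)


def pct_of_inhaled(
    pct_of_emitted: float, ec: ExposureConfig, bp: BreathingParameters
) -> float:
    """Rescale a percent-of-emitted deposition to percent-of-inhaled.

    Division by the inhaled fraction (minute ventilation / nebulizer flow):
    pct_emitted x flow / MV.
    """
    if bp.minute_ventilation_lpm <= 0:
        raise ValueError("minute ventilation must be > 0")
    if pct_of_emitted < 0:
        raise ValueError("pct_of_emitted must be >= 0")
    return float(
        pct_of_emitted * ec.nebulizer_flow_lpm / bp.minute_ventilation_lpm
    )


def fold_ratio(a: float, b: float, ndigits: int | None = None) -> float:
    """Ratio a/b, optionally rounded to the displayed number of digits."""
    if b <= 0:
        raise ValueError("fold_ratio denominator must be > 0")
    r = a / b
    return float(round(r, ndigits)) if ndigits is not None else float(r)


def build_report(
    et_activity_mbq: float,
    th_activity_mbq: float,
    emitted_activity_mbq: float,
    ec: ExposureConfig,
    bp: BreathingParameters,
) -> DepositionReport:
    """Assemble the three normalizations for one inhalation.

    Activities are in consistent units (MBq-equivalent after the
    scintigraphic correction chain); ``emitted_activity_mbq`` is the emitted
    nebulizer fraction times the nebulizer charge.
    """
    if emitted_activity_mbq <= 0:
        raise ValueError("emitted activity must be > 0")
    et_share, th_share = et_th_balance(et_activity_mbq, th_activity_mbq)
    regions = {}
    for label, act, share in (
        ("ET", et_activity_mbq, et_share),
        ("TH", th_activity_mbq, th_share),
    ):
        p_em = 100.0 * act / emitted_activity_mbq
        regions[label] = RegionDose(
            share_of_total_deposited=share,
            pct_of_emitted=p_em,
            pct_of_inhaled=pct_of_inhaled(p_em, ec, bp),
        )
    return DepositionReport(
        regions=regions,
        total_deposited_pct_of_inhaled=sum(
            r.pct_of_inhaled for r in regions.values()
        ),
        aerosol_label=ec.aerosol_label,
        species_label=ec.species_label,
        nebulizer_flow_lpm=ec.nebulizer_flow_lpm,
        minute_ventilation_lpm=bp.minute_ventilation_lpm,
    )


def aggregate_reports(
    reports: list[DepositionReport], convention: str = "mean_of_shares"
) -> pd.DataFrame:
    """Aggregate per-inhalation reports across a group.

    Two labeled conventions, which differ whenever deposition varies across
    inhalations:

    * ``"mean_of_shares"`` — average each inhalation's ET/TH share of total
      deposited (per-subject shares averaged, the usual figure convention);
    * ``"ratio_of_means"`` — compute shares from the mean per-region
      percent-of-emitted values (the table convention).

    Returns a tidy frame indexed by region with mean/sd of each
    normalization plus the share under the requested convention.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    if convention not in ("mean_of_shares", "ratio_of_means"):
        raise ValueError(f"unknown aggregation convention {convention!r}")
    rows = []
    for rep in reports:
        for label, r in rep.regions.items():
            rows.append(
                {
                    "region": label,
                    "share": r.share_of_total_deposited,
                    "pct_of_emitted": r.pct_of_emitted,
                    "pct_of_inhaled": r.pct_of_inhaled,
                }
            )
    df = pd.DataFrame(rows)
    agg = df.groupby("region").agg(["mean", "std"])
    agg.columns = [f"{a}_{b}" for a, b in agg.columns]
    if convention == "mean_of_shares":
        agg["share_of_total"] = agg["share_mean"]
    else:
        mean_em = agg["pct_of_emitted_mean"]
        agg["share_of_total"] = mean_em / mean_em.sum()
    agg["convention"] = convention
    return agg


def cross_species_compare(
    report_a: DepositionReport, report_b: DepositionReport
) -> pd.DataFrame:
    """Species comparison table for the same aerosol.

    Rows per region: ratio of percent-of-emitted (a/b), difference of
    shares of total deposited; plus a summary row with the ventilation
    ratio.  Warns if the aerosol labels differ.
    """
    if report_a.aerosol_label != report_b.aerosol_label:
        warnings.warn(
            f"comparing different aerosols: {report_a.aerosol_label!r} vs "
            f"{report_b.aerosol_label!r}",
            stacklevel=2,
        )
    rows = []
    for label in report_a.regions:
        if label not in report_b.regions:
            continue
        ra, rb = report_a.regions[label], report_b.regions[label]
        rows.append(
            {
                "region": label,
                "pct_of_emitted_ratio": fold_ratio(
                    ra.pct_of_emitted, rb.pct_of_emitted
                ),
                "share_difference": ra.share_of_total_deposited
                - rb.share_of_total_deposited,
            }
        )
    out = pd.DataFrame(rows).set_index("region")
    out.attrs["ventilation_ratio"] = fold_ratio(
        report_a.minute_ventilation_lpm, report_b.minute_ventilation_lpm
    )
    out.attrs["species"] = (report_a.species_label, report_b.species_label)
    return out
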
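"""File formats, study loading and report rendering.

On-disk study layout (as produced by ``aerodep simulate``)::

    study/
      study.yaml           study configuration (paths below, aggregation, seed)
      stages.csv           stage ladder: stage_index, d_lower_um, d_upper_um
      runs/<aerosol>.csv   impactor runs: stage_index, d_lower_um, d_upper_um,
                           activity  (stage_index 0 = throat-model row)
      exposure/<aerosol>.json   nebulizer flow, charges, emitted fraction
      breathing.json       ventilation parameters
      corrections.json     half-life, attenuation factors, camera sensitivity
      masks/<LABEL>.csv    0/1 matrices congruent with the images
      images/<subject>_<replicate>_<aerosol>.csv   count matrices
      truth.csv            generator ground-truth ledger (synthetic studies)

Images and masks are plain CSV matrices by default; 16-bit grayscale TIFF is
read when the optional ``tifffile`` dependency is present.  All internal
quantities are fractions; percent appears only in rendered tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dosimetry import (
    BreathingParameters,
    DepositionReport,
    ExposureConfig,
    aggregate_reports,
    build_report,
)
from .group_stats import bonferroni_pairwise
from .impactor_reduction import (
    ImpactorRun,
    StageDeposit,
    SizeDistributionSummary,
    summarize,
)
from .scintigraphy_quant import (
    TC99M_HALF_LIFE_S,
    CorrectionSet,
    PlanarImage,
    ROIMask,
    quantify_regions,
)
from .synthetic_data import StudySet

logger = logging.getLogger("aerodep")

__all__ = [
    "StudyConfig",
    "Study",
    "read_impactor_run",
    "write_impactor_run",
    "read_stage_bounds",
    "write_stage_bounds",
    "read_image",
    "write_image",
    "read_masks",
    "read_corrections",
    "write_corrections",
    "read_exposure",
    "write_exposure",
    "read_breathing",
    "write_breathing",
    "write_study",
    "load_study",
    "process_study",
    "render_report",
    "write_report",
]


# ---------------------------------------------------------------- impactor

def write_impactor_run(run: ImpactorRun, path: str | Path) -> None:
    """Write a run as CSV; the throat deposit becomes a stage_index-0 row."""
    rows = []
    if run.throat_activity > 0:
        rows.append(
            {"stage_index": 0, "d_lower_um": np.nan, "d_upper_um": np.nan,
             "activity": run.throat_activity}
        )
    for s in run.stages:
        rows.append(
            {"stage_index": s.stage_index, "d_lower_um": s.d_lower,
             "d_upper_um": s.d_upper, "activity": s.activity}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_impactor_run(
    path: str | Path,
    charge_before: float | None = None,
    charge_after: float | None = None,
    flow_lpm: float | None = None,
) -> ImpactorRun:
    """Read a run CSV.  Nebulizer charge readings are not part of the CSV
    format and are attached from the exposure configuration."""
    df = pd.read_csv(path)
    required = {"stage_index", "d_lower_um", "d_upper_um", "activity"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    throat = float(df.loc[df.stage_index == 0, "activity"].sum())
    body = df[df.stage_index > 0].sort_values("stage_index")
    stages = [
        StageDeposit(int(r.stage_index), float(r.d_lower_um),
                     float(r.d_upper_um), float(r.activity))
        for r in body.itertuples()
    ]
    return ImpactorRun(
        stages, throat_activity=throat, charge_before=charge_before,
        charge_after=charge_after, flow_lpm=flow_lpm,
    )


def write_stage_bounds(bounds: np.ndarray, path: str | Path) -> None:
    b = np.asarray(bounds)
    pd.DataFrame(
        {
            "stage_index": np.arange(1, b.size),
            "d_lower_um": b[:-1],
            "d_upper_um": b[1:],
        }
    ).to_csv(path, index=False)


def read_stage_bounds(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("stage_index")
    bounds = np.concatenate([df.d_lower_um.values[:1], df.d_upper_um.values])
    if np.any(np.diff(bounds) <= 0):
        raise ValueError(f"{path}: stage bounds not strictly increasing")
    return bounds.astype(float)


# ------------------------------------------------------------------ images

def read_image(path: str | Path) -> np.ndarray:
    """Read a count matrix from CSV, TIFF or PGM."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return np.loadtxt(path, delimiter=",")
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    if suffix == ".pgm":
        from PIL import Image

        return np.asarray(Image.open(path))
    raise ValueError(f"unsupported image format {suffix!r} ({path})")


def write_image(arr: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    a = np.asarray(arr)
    if suffix == ".csv":
        fmt = "%d" if np.issubdtype(a.dtype, np.integer) else "%.6g"
        np.savetxt(path, a, delimiter=",", fmt=fmt)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, a.astype(np.uint16))
    else:
        raise ValueError(f"unsupported image format {suffix!r} ({path})")


def read_masks(mask_dir: str | Path) -> list[ROIMask]:
    """Read every ``<LABEL>.<ext>`` mask file in a directory."""
    mask_dir = Path(mask_dir)
    masks = []
    for p in sorted(mask_dir.iterdir()):
        if p.suffix.lower() not in (".csv", ".tif", ".tiff", ".pgm"):
            continue
        masks.append(ROIMask(p.stem.upper(), read_image(p) > 0))
    if not masks:
        raise ValueError(f"no mask files found in {mask_dir}")
    return masks


# ------------------------------------------------------------------ configs

def write_corrections(corr: CorrectionSet, path: str | Path,
                      sensitivity_cps_per_mbq: float | None = None) -> None:
    payload = {
        "half_life_seconds": corr.half_life_seconds,
        "reference_time": corr.reference_time,
        "attenuation_factor": corr.attenuation_factor,
        "background_rate": corr.background_rate,
        "attenuation_rel_unc": corr.attenuation_rel_unc,
    }
    if sensitivity_cps_per_mbq is not None:
        payload["sensitivity_cps_per_mbq"] = sensitivity_cps_per_mbq
    Path(path).write_text(json.dumps(payload, indent=2))


def read_corrections(path: str | Path) -> tuple[CorrectionSet, float | None]:
    """Returns the correction set and the camera sensitivity (cps/MBq)."""
    payload = json.loads(Path(path).read_text())
    sens = payload.pop("sensitivity_cps_per_mbq", None)
    corr = CorrectionSet(
        half_life_seconds=payload.get("half_life_seconds", TC99M_HALF_LIFE_S),
        reference_time=payload.get("reference_time", 0.0),
        attenuation_factor=payload.get("attenuation_factor", {}),
        background_rate=payload.get("background_rate"),
        attenuation_rel_unc=payload.get("attenuation_rel_unc", 0.0),
    )
    return corr, sens


def write_exposure(ec: ExposureConfig, path: str | Path,
                   charge_before_mbq: float | None = None,
                   charge_after_mbq: float | None = None,
                   counts_per_mbq: float = 1.0) -> None:
    Path(path).write_text(json.dumps(
        {
            "nebulizer_flow_lpm": ec.nebulizer_flow_lpm,
            "emitted_fraction": ec.emitted_fraction,
            "species_label": ec.species_label,
            "aerosol_label": ec.aerosol_label,
            "charge_before_mbq": charge_before_mbq,
            "charge_after_mbq": charge_after_mbq,
            "counts_per_mbq": counts_per_mbq,
        },
        indent=2,
    ))


def read_exposure(path: str | Path) -> tuple[ExposureConfig, dict]:
    """Returns the exposure config plus the charge/calibration extras."""
    payload = json.loads(Path(path).read_text())
    ec = ExposureConfig(
        nebulizer_flow_lpm=payload.get("nebulizer_flow_lpm", 8.0),
        emitted_fraction=payload.get("emitted_fraction"),
        species_label=payload.get("species_label", "baboon"),
        aerosol_label=payload.get("aerosol_label", ""),
    )
    extras = {
        "charge_before_mbq": payload.get("charge_before_mbq"),
        "charge_after_mbq": payload.get("charge_after_mbq"),
        "counts_per_mbq": payload.get("counts_per_mbq", 1.0),
    }
    return ec, extras


def write_breathing(bp: BreathingParameters, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {
            "breathing_rate_bpm": bp.breathing_rate_bpm,
            "tidal_volume_ml": bp.tidal_volume_ml,
            "minute_ventilation_lpm": bp.minute_ventilation_lpm,
            "ie_ratio": list(bp.ie_ratio),
        },
        indent=2,
    ))


def read_breathing(path: str | Path) -> BreathingParameters:
    payload = json.loads(Path(path).read_text())
    return BreathingParameters(
        breathing_rate_bpm=payload["breathing_rate_bpm"],
        tidal_volume_ml=payload["tidal_volume_ml"],
        minute_ventilation_lpm=payload["minute_ventilation_lpm"],
        ie_ratio=tuple(payload.get("ie_ratio", (0.41, 0.59))),
    )


# ------------------------------------------------------------ study config

_CONFIG_KEYS = {
    "stage_table", "runs", "images", "masks", "corrections", "exposure",
    "breathing", "aggregation", "seed",
}


@dataclass
class StudyConfig:
    """Validated study configuration; all paths resolved against its root."""

    root: Path
    stage_table: Path
    runs: Path
    images: Path
    masks: Path
    corrections: Path
    exposure: Path
    breathing: Path
    aggregation: str = "both"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        payload = yaml.safe_load(path.read_text())
        unknown = set(payload) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        root = path.parent
        kwargs = {"root": root}
        for key in ("stage_table", "runs", "images", "masks", "corrections",
                    "exposure", "breathing"):
            if key not in payload:
                raise ValueError(f"{path}: missing required key {key!r}")
            p = root / payload[key]
            if not p.exists():
                raise ValueError(f"{path}: {key} path {p} does not exist")
            kwargs[key] = p
        agg = payload.get("aggregation", "both")
        if agg not in ("mean_of_shares", "ratio_of_means", "both"):
            raise ValueError(f"{path}: unknown aggregation {agg!r}")
        kwargs["aggregation"] = agg
        kwargs["seed"] = int(payload.get("seed", 0))
        return cls(**kwargs)


@dataclass
class Study:
    """A fully loaded, cross-validated study."""

    config: StudyConfig
    stage_bounds: np.ndarray
    runs: dict[str, ImpactorRun]
    exposures: dict[str, ExposureConfig]
    exposure_extras: dict[str, dict]
    images: list[tuple[str, int, str, PlanarImage]]  # subject, repl, aerosol
    masks: list[ROIMask]
    corrections: CorrectionSet
    sensitivity_cps_per_mbq: float
    breathing: BreathingParameters
    truth: pd.DataFrame | None = None


def load_study(config: StudyConfig | str | Path) -> Study:
    """Load and cross-validate every file a study config points at.

    Failures name the offending file and field.  Mask shapes are checked
    against every image; each impactor run must have a matching exposure
    file (the charges live there).
    """
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    stage_bounds = read_stage_bounds(config.stage_table)

    exposures, extras = {}, {}
    for p in sorted(Path(config.exposure).glob("*.json")):
        ec, extra = read_exposure(p)
        label = ec.aerosol_label or p.stem
        exposures[label] = ec
        extras[label] = extra

    runs = {}
    for p in sorted(Path(config.runs).glob("*.csv")):
        label = p.stem
        if label not in exposures:
            raise ValueError(
                f"{p}: no exposure file for aerosol {label!r} "
                f"in {config.exposure}"
            )
        extra = extras[label]
        runs[label] = read_impactor_run(
            p,
            charge_before=extra["charge_before_mbq"],
            charge_after=extra["charge_after_mbq"],
        )

    corr, sens = read_corrections(config.corrections)
    if sens is None:
        raise ValueError(
            f"{config.corrections}: missing sensitivity_cps_per_mbq"
        )
    breathing = read_breathing(config.breathing)
    masks = read_masks(config.masks)

    images = []
    for p in sorted(Path(config.images).glob("*.*")):
        subject, repl, aerosol = p.stem.split("_", 2)
        if aerosol not in exposures:
            raise ValueError(f"{p}: unknown aerosol label {aerosol!r}")
        counts = read_image(p)
        for m in masks:
            if m.mask.shape != counts.shape:
                raise ValueError(
                    f"{p}: image shape {counts.shape} does not match "
                    f"{m.label} mask shape {m.mask.shape}"
                )
        images.append(
            (subject, int(repl), aerosol,
             PlanarImage(counts=counts, acquisition_seconds=120.0))
        )
    if not images:
        raise ValueError(f"no images found in {config.images}")

    truth = None
    truth_path = config.root / "truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)

    return Study(
        config=config, stage_bounds=stage_bounds, runs=runs,
        exposures=exposures, exposure_extras=extras, images=images,
        masks=masks, corrections=corr, sensitivity_cps_per_mbq=sens,
        breathing=breathing, truth=truth,
    )


def write_study(study: StudySet, outdir: str | Path) -> Path:
    """Write a generated study to disk in the documented layout."""
    out = Path(outdir)
    for sub in ("runs", "images", "masks", "exposure"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    first_run = next(iter(study.impactor_runs.values()))
    write_stage_bounds(first_run.bounds(), out / "stages.csv")
    for label, run in study.impactor_runs.items():
        write_impactor_run(run, out / "runs" / f"{label}.csv")
        write_exposure(
            study.exposures[label], out / "exposure" / f"{label}.json",
            charge_before_mbq=run.charge_before,
            charge_after_mbq=run.charge_after,
            counts_per_mbq=1000.0,
        )
    for subject, repl, aerosol, img, _ in study.phantoms:
        write_image(img.counts, out / "images" / f"{subject}_{repl}_{aerosol}.csv")
    for mask in study.phantoms[0][4]:
        write_image(
            mask.mask.astype(np.uint8), out / "masks" / f"{mask.label}.csv"
        )
    write_corrections(
        study.corrections, out / "corrections.json",
        sensitivity_cps_per_mbq=study.sensitivity_cps_per_mbq,
    )
    write_breathing(study.breathing, out / "breathing.json")
    study.truth.to_csv(out / "truth.csv", index=False)
    (out / "study.yaml").write_text(yaml.safe_dump(
        {
            "stage_table": "stages.csv",
            "runs": "runs",
            "images": "images",
            "masks": "masks",
            "corrections": "corrections.json",
            "exposure": "exposure",
            "breathing": "breathing.json",
            "aggregation": "both",
            "seed": 0,
        },
        sort_keys=False,
    ))
    return out / "study.yaml"


# ------------------------------------------------------------------ pipeline

def process_study(study: Study) -> dict:
    """Run the full quantification chain over a loaded study.

    Returns a results dict with per-aerosol size-distribution summaries,
    per-inhalation deposition reports, group aggregates under both
    aggregation conventions, and the Bonferroni pairwise statistics for
    regional shares and percent-of-inhaled values.
    """
    summaries: dict[str, SizeDistributionSummary] = {}
    for label, run in study.runs.items():
        cpm = study.exposure_extras[label]["counts_per_mbq"]
        summaries[label] = summarize(run, counts_per_mbq=cpm)
        logger.info("aerosol %s: AMAD %.3g um, GSD %.2f, emitted %.1f%%",
                    label, summaries[label].amad, summaries[label].gsd,
                    100 * (summaries[label].emitted_fraction or np.nan))

    reports: list[tuple[str, int, str, DepositionReport]] = []
    duration_sens = study.sensitivity_cps_per_mbq
    for subject, repl, aerosol, img in study.images:
        regions = quantify_regions(img, study.masks, study.corrections)
        acts = {
            r.region: r.corrected / (duration_sens * img.acquisition_seconds)
            for r in regions
        }
        ec = study.exposures[aerosol]
        extra = study.exposure_extras[aerosol]
        ef = ec.emitted_fraction
        if ef is None:
            ef = summaries[aerosol].emitted_fraction
        charge = (extra["charge_before_mbq"] or 0) - (extra["charge_after_mbq"] or 0)
        emitted_mbq = ef * charge
        rep = build_report(
            acts.get("ET", 0.0), acts.get("TH", 0.0), emitted_mbq,
            ec, study.breathing,
        )
        logger.info(
            "%s r%d %s: ET %.3f / TH %.3f MBq, shares %.1f/%.1f%%",
            subject, repl, aerosol, acts.get("ET", 0), acts.get("TH", 0),
            100 * rep.regions["ET"].share_of_total_deposited,
            100 * rep.regions["TH"].share_of_total_deposited,
        )
        reports.append((subject, repl, aerosol, rep))

    rows = []
    for subject, repl, aerosol, rep in reports:
        for region, r in rep.regions.items():
            rows.append(
                {
                    "subject": subject, "replicate": repl, "aerosol": aerosol,
                    "region": region,
                    "share_of_total": r.share_of_total_deposited,
                    "pct_of_emitted": r.pct_of_emitted,
                    "pct_of_inhaled": r.pct_of_inhaled,
                }
            )
    per_inhalation = pd.DataFrame(rows)

    aggregates = {}
    conventions = (
        ("mean_of_shares", "ratio_of_means")
        if study.config.aggregation == "both"
        else (study.config.aggregation,)
    )
    for conv in conventions:
        aggregates[conv] = {
            label: aggregate_reports(
                [rep for _, _, lab, rep in reports if lab == label], conv
            )
            for label in study.runs
        }

    stats_tables = {}
    for metric in ("share_of_total", "pct_of_inhaled"):
        for region in ("ET", "TH"):
            sub = per_inhalation[per_inhalation.region == region]
            grouped = {
                label: sub[sub.aerosol == label]
                .sort_values(["subject", "replicate"])[metric]
                .to_numpy()
                for label in study.runs
            }
            stats_tables[f"{region}_{metric}"] = bonferroni_pairwise(grouped)

    return {
        "summaries": summaries,
        "per_inhalation": per_inhalation,
        "aggregates": aggregates,
        "stats": stats_tables,
        "truth": study.truth,
    }


# ------------------------------------------------------------------- report

def render_report(results: dict, ndigits: int = 1) -> dict[str, pd.DataFrame]:
    """Render results as the study's standard tables.

    ``size_distributions`` mirrors the aerosol-characterization table
    (AMAD, GSD, d16-d84, sub-cutoff fractions, emitted %);
    ``regional_deposition`` the percent-of-emitted table;
    ``shares`` the ET/TH balance; ``pct_of_inhaled`` the percent-of-inhaled
    figures; ``stats_*`` the Bonferroni tables.  Deterministic column order,
    values rounded to ``ndigits`` decimals.
    """
    tables: dict[str, pd.DataFrame] = {}

    rows = []
    for label, s in results["summaries"].items():
        rows.append(
            {
                "aerosol": label,
                "amad_um": s.amad,
                "gsd": s.gsd,
                "d16_um": s.d16,
                "d84_um": s.d84,
                "pct_below_2.5um": 100 * s.frac_below.get(2.5, np.nan),
                "pct_below_1um": 100 * s.frac_below.get(1.0, np.nan),
                "pct_below_0.5um": 100 * s.frac_below.get(0.5, np.nan),
                "pct_below_0.1um": 100 * s.frac_below.get(0.1, np.nan),
                "emitted_pct": 100 * s.emitted_fraction
                if s.emitted_fraction is not None else np.nan,
            }
        )
    tables["size_distributions"] = pd.DataFrame(rows).round(ndigits)

    per = results["per_inhalation"]
    if len(per):
        dep = (
            per.pivot_table(
                index="aerosol", columns="region",
                values=["pct_of_emitted", "pct_of_inhaled"],
                aggfunc=["mean", "std"], sort=False,
            )
        )
        dep.columns = [f"{r}_{v}_{a}" for a, v, r in dep.columns]
        tables["regional_deposition"] = dep[
            sorted(dep.columns)
        ].round(ndigits).reset_index()

        share = per.assign(share_pct=100 * per.share_of_total).pivot_table(
            index="aerosol", columns="region", values="share_pct",
            aggfunc=["mean", "std"], sort=False,
        )
        share.columns = [f"{r}_share_pct_{a}" for a, r in share.columns]
        tables["shares"] = share[sorted(share.columns)].round(
            ndigits
        ).reset_index()
    else:
        tables["regional_deposition"] = pd.DataFrame()
        tables["shares"] = pd.DataFrame()

    for name, df in results.get("stats", {}).items():
        tables[f"stats_{name}"] = df.round(
            {"mean_a": ndigits, "mean_b": ndigits}
        )
    return tables


def write_report(tables: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    """Write each table as CSV plus a combined Markdown report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    md = []
    for name in sorted(tables):
        tables[name].to_csv(out / f"{name}.csv", index=False)
        md.append(f"## {name}\n\n{tables[name].to_markdown(index=False)}\n")
    (out / "report.md").write_text("\n".join(md))
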
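"""End-to-end pipeline: simulate -> normalize -> quantify -> compare ->
call -> report, as one configured, logged, seeded run.

The manifest's ``group`` column drives the comparisons: one label (by
default ``control``, the scrambled-RNP cohort) is the shared control
group, and every other label is treated as a knocked-out gene compared
against that same control — mirroring a screen in which one scrambled
cohort serves all gene comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from . import quantify as rq
from . import stats as rs

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "load_config",
    "reduce_cohort",
]

logger = logging.getLogger("rpescreen")


@dataclass(frozen=True)
class PipelineConfig:
    """Fully-resolved pipeline parameters; defaults are the screen's values."""

    manifest: str
    out_dir: str
    control_group: str = "control"
    normalization_target: str | float = "auto"  # "auto" = dataset mean
    bin_sizes: tuple[int, ...] = (1, 5)
    omit_ranges: tuple[tuple[float, float], ...] = rs.DEFAULT_OMIT_RANGES
    alpha: float = 0.05
    min_span_deg: float = 20.0
    n_permutations: int = 20_000
    min_per_group: int = 3
    seed: int = 0
    write_plots: bool = False


@dataclass(frozen=True)
class PipelineResult:
    comparison_csv: dict[str, Path]
    calls_csv: Path
    report_csv: Path
    profiles_csv: Path
    normalization_csv: Path
    report: pd.DataFrame
    calls: dict[str, rs.PhenotypeCall] = field(repr=False, default_factory=dict)


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Parse a plain-text ``key = value`` config file (# comments allowed)."""
    values: dict[str, object] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        values[key] = _parse_value(key, val)
    values.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig(**values)  # type: ignore[arg-type]
    except TypeError as exc:
        raise ValueError(f"bad config key: {exc}") from exc


def _parse_value(key: str, val: str):
    if key == "bin_sizes":
        return tuple(int(x) for x in val.split(","))
    if key == "omit_ranges":
        parts = [p for p in val.split(";") if p.strip()]
        return tuple(tuple(float(x) for x in p.split("-")) for p in parts)
    if key in ("alpha", "min_span_deg"):
        return float(val)
    if key in ("n_permutations", "min_per_group", "seed"):
        return int(val)
    if key == "write_plots":
        return val.lower() in ("1", "true", "yes")
    if key == "normalization_target":
        return val if val == "auto" else float(val)
    return val


def reduce_cohort(records, target: str | float = "auto", bin_size: int = 1):
    """Normalize and profile an in-memory cohort of eye records.

    ``records`` is an iterable with ``image`` (uint8 raster), ``roi``
    (polygon vertices), ``group`` and ``larva_id`` attributes, e.g. the
    output of :func:`rpescreen.simulate.generate_cohort`.  Images are
    normalized to ``target`` ("auto" = dataset mean of per-image means),
    the eye center is fitted per larva, and per-larva angular profiles
    are returned.
    """
    records = list(records)
    masks = [rio.rasterize(rec.roi, rec.image.shape) for rec in records]
    if target == "auto":
        target = rq.dataset_mean([rec.image for rec in records])
    profiles = []
    for rec, mask in zip(records, masks):
        norm = rq.normalize_image(rec.image, float(target))
        center, _ = rq.estimate_center(mask)
        profiles.append(
            rq.angular_profile(
                norm.image, mask, center, bin_size=bin_size,
                larva_id=rec.larva_id, group=rec.group,
            )
        )
    return profiles


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute normalize -> quantify -> compare -> call -> report.

    Deterministic for a fixed config (per-gene permutation seeds derive
    from ``config.seed``); all artifacts plus the resolved config and a
    log land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    except Exception:
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> PipelineResult:
    (out / "config_resolved.json").write_text(json.dumps(asdict(config), indent=2))

    manifest = rio.read_manifest(config.manifest)
    stage = "load"
    images: dict[str, np.ndarray] = {}
    masks: dict[str, rio.RoiMask] = {}
    for row in manifest.itertuples(index=False):
        try:
            images[row.larva_id] = rio.read_image(row.image)
            masks[row.larva_id] = rio.rasterize(
                rio.read_roi(row.roi), images[row.larva_id].shape
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage}: larva {row.larva_id}: {exc}") from exc

    stage = "normalize"
    if config.normalization_target == "auto":
        target = rq.dataset_mean(images.values())
        logger.info("normalization target (dataset mean): %.3f", target)
    else:
        target = float(config.normalization_target)
    norm_rows = []
    for larva_id, img in images.items():
        res = rq.normalize_image(img, target)
        images[larva_id] = res.image
        norm_rows.append({"larva_id": larva_id, **res.report_row()})
        logger.info(
            "normalized %s: offset %+.2f, post-mean %.2f, clipped %.4f",
            larva_id, res.offset_applied, res.post_mean, res.clipped_fraction,
        )
    normalization_csv = out / "normalization.csv"
    pd.DataFrame(norm_rows).to_csv(normalization_csv, index=False)

    stage = "quantify"
    profiles_by_bin: dict[int, list[rq.AngularProfile]] = {b: [] for b in config.bin_sizes}
    if 1 not in profiles_by_bin:
        profiles_by_bin[1] = []
    for row in manifest.itertuples(index=False):
        try:
            center, _ = rq.estimate_center(masks[row.larva_id])
            for b in profiles_by_bin:
                profiles_by_bin[b].append(
                    rq.angular_profile(
                        images[row.larva_id], masks[row.larva_id], center,
                        bin_size=b, larva_id=row.larva_id, group=row.group,
                    )
                )
        except Exception as exc:
            raise RuntimeError(f"stage {stage}: larva {row.larva_id}: {exc}") from exc
    profiles_csv = out / "profiles_bin1.csv"
    rq.profiles_to_frame(profiles_by_bin[1]).to_csv(profiles_csv, index=False)

    stage = "compare"
    controls = [p for p in profiles_by_bin[1] if p.group == config.control_group]
    genes = sorted({p.group for p in profiles_by_bin[1]} - {config.control_group})
    if not controls or not genes:
        raise RuntimeError(
            f"stage {stage}: need control group {config.control_group!r} plus >= 1 other group"
        )
    comparison_csv: dict[str, Path] = {}
    calls: dict[str, rs.PhenotypeCall] = {}
    for gi, gene in enumerate(genes):
        ko = [p for p in profiles_by_bin[1] if p.group == gene]
        gene_seed = int(
            np.random.SeedSequence(config.seed, spawn_key=(gi,)).generate_state(1)[0]
        )
        try:
            result = rs.compare_groups(
                controls, ko,
                n_permutations=config.n_permutations,
                omit=config.omit_ranges,
                min_per_group=config.min_per_group,
                seed=gene_seed,
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage}: gene {gene}: {exc}") from exc
        logger.info(
            "compared %s vs %s: %s mode, %d assignments/draws",
            gene, config.control_group, result.mode, result.n_permutations,
        )
        path = out / f"comparison_{gene}.csv"
        result.to_csv(path)
        comparison_csv[gene] = path
        calls[gene] = rs.call_phenotype(
            result, alpha=config.alpha, min_span_deg=config.min_span_deg
        )
        if config.write_plots:
            _plot_comparison(result, gene, out / f"comparison_{gene}.png")

    stage = "report"
    report = rs.screen_report(calls)
    calls_rows = [
        {
            "gene": gene,
            "classification": call.classification,
            "block_start": b.start_deg,
            "block_end": b.end_deg,
            "direction": b.direction,
            "span_deg": b.span_deg,
            "min_p": b.min_p,
        }
        for gene, call in calls.items()
        for b in (call.blocks or [None])
        if b is not None
    ] or [
        {"gene": gene, "classification": call.classification}
        for gene, call in calls.items()
    ]
    calls_csv = out / "calls.csv"
    pd.DataFrame(calls_rows).to_csv(calls_csv, index=False)
    report_csv = out / "report.csv"
    report.to_csv(report_csv, index=False)
    return PipelineResult(
        comparison_csv=comparison_csv,
        calls_csv=calls_csv,
        report_csv=report_csv,
        profiles_csv=profiles_csv,
        normalization_csv=normalization_csv,
        report=report,
        calls=calls,
    )


def _plot_comparison(result: rs.GroupComparisonResult, gene: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.frame
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    ax1.plot(df["bin_start"], df["delta"], color="k", lw=1)
    ax1.plot(df["bin_start"], df["ci_low"], "k--", lw=0.8)
    ax1.plot(df["bin_start"], df["ci_high"], "k--", lw=0.8)
    ax1.axhline(0, color="gray", lw=0.5)
    ax1.set_ylabel("median intensity difference")
    ax2.plot(df["bin_start"], df["p"], color="tab:blue", lw=1)
    ax2.axhline(0.05, color="r", lw=0.6, ls=":")
    ax2.set_yscale("log")
    ax2.set_xlabel("angular degrees (dorsal to ventral)")
    ax2.set_ylabel("permutation p")
    fig.suptitle(f"{gene} vs control")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
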
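"""Benchmark harness: distort × normalize × metric sensitivity grids.

Workflow per grid cell: a reference image is distorted at one of five
strengths, then the distorted image and the untouched reference are
*individually* normalized, reference metrics are evaluated on the pair
(with the pair data range of the normalized images) and non-reference
metrics on the normalized distorted image.  Non-reference metrics are also
evaluated on the normalized reference (recorded at strength 0) so quality
deltas against the reference are reportable.

Aggregation mirrors the sensitivity tables: the *median table* takes, per
(metric, distortion), the median over all images and all strengths pooled;
the *relative table* divides each such cell by the median of the metric's
values pooled over every distortion, exposing which distortions a metric is
unusually sensitive to.

A metric failing on a particular cell (e.g. a constant image after
distortion) is recorded as a missing value with a reason instead of
aborting the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import data_range, write_table
from .distort import DEFAULT_SCHEDULE, DistortionSpec, ParameterSchedule, apply, spec_seed
from .nonref_metrics import NONREF_METRICS
from .normalize import normalize
from .phantom import PhantomSpec, generate_dataset
from .ref_metrics import REFERENCE_METRICS

__all__ = [
    "BenchmarkRecord",
    "BenchmarkConfig",
    "run_benchmark",
    "records_to_frame",
    "aggregate_medians",
    "relative_scores",
    "load_config",
]


@dataclass(frozen=True)
class BenchmarkRecord:
    """One metric value for one benchmark grid cell (long format).

    ``distortion = "reference"`` with ``strength = 0`` marks non-reference
    scores of the undistorted reference.  ``value`` is NaN with a ``note``
    when the metric failed on that cell.
    """

    image_id: str
    distortion: str
    strength: int
    normalization: str
    metric: str
    value: float
    note: str = ""


@dataclass
class BenchmarkConfig:
    """Validated benchmark configuration.

    ``distortions`` maps name → strengths; ``ref_metrics``/``nonref_metrics``
    are metric name lists; phantom images are generated when no paths are
    given.  ``schedules`` overrides individual strength parameters.
    """

    n_images: int = 4
    image_size: tuple[int, int] = (240, 240)
    image_paths: list[str] = field(default_factory=list)
    distortions: dict[str, list[int]] = field(
        default_factory=lambda: {name: [1, 2, 3, 4, 5] for name in DEFAULT_SCHEDULE}
    )
    normalizations: list[str] = field(default_factory=lambda: ["none"])
    ref_metrics: list[str] = field(default_factory=lambda: ["ssim", "psnr", "mse", "nmi"])
    nonref_metrics: list[str] = field(default_factory=list)
    seed: int = 0
    schedules: dict = field(default_factory=dict)

    def validate(self) -> "BenchmarkConfig":
        for name in self.distortions:
            if name not in DEFAULT_SCHEDULE:
                raise ValueError(f"unknown distortion {name!r}")
        for m in self.ref_metrics:
            if m not in REFERENCE_METRICS:
                raise ValueError(f"unknown reference metric {m!r}")
        for m in self.nonref_metrics:
            if m not in NONREF_METRICS:
                raise ValueError(f"unknown non-reference metric {m!r}")
        for norm in self.normalizations:
            if norm not in ("none", "minmax", "cminmax", "zscore", "quantile", "binning"):
                raise ValueError(f"unknown normalization {norm!r}")
        return self


def load_config(path: str | Path) -> BenchmarkConfig:
    """Load a YAML/JSON benchmark config file."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    cfg = BenchmarkConfig(
        n_images=raw.get("n_images", 4),
        image_size=tuple(raw.get("image_size", (240, 240))),
        image_paths=list(raw.get("images", []) or []),
        distortions={
            k: list(v) for k, v in raw.get(
                "distortions", {n: [1, 2, 3, 4, 5] for n in DEFAULT_SCHEDULE}
            ).items()
        },
        normalizations=list(raw.get("normalizations", ["none"])),
        ref_metrics=list(raw.get("ref_metrics", ["ssim", "psnr", "mse", "nmi"])),
        nonref_metrics=list(raw.get("nonref_metrics", [])),
        seed=int(raw.get("seed", 0)),
        schedules=dict(raw.get("schedules", {})),
    )
    return cfg.validate()


def _load_images(cfg: BenchmarkConfig):
    if cfg.image_paths:
        from .core import read_image

        return [(Path(p).stem, read_image(p)) for p in cfg.image_paths]
    template = PhantomSpec(size=cfg.image_size)
    items = generate_dataset(cfg.n_images, base_seed=cfg.seed, template=template)
    return [(f"phantom_{i:03d}", img) for i, (img, _mask) in enumerate(items)]


def _eval_ref(metric: str, distorted, reference) -> float:
    L = data_range(distorted, reference)
    return REFERENCE_METRICS[metric](distorted, reference, L)


def _eval_nonref(metric: str, image) -> float:
    return NONREF_METRICS[metric](image)


def run_benchmark(config: BenchmarkConfig) -> list[BenchmarkRecord]:
    """Run the full distort × normalize × metric grid; fully seeded."""
    cfg = config.validate()
    schedule = ParameterSchedule(cfg.schedules)
    images = _load_images(cfg)
    records: list[BenchmarkRecord] = []

    for image_id, reference in images:
        # baseline records (strength 0): reference metrics at their identity
        # value, non-reference metrics scored on the reference itself
        for norm in cfg.normalizations:
            ref_n, _ = normalize(reference, norm)
            for metric in cfg.ref_metrics:
                records.append(
                    _safe_record(image_id, "reference", 0, norm, metric,
                                 _eval_ref, metric, ref_n, ref_n)
                )
            for metric in cfg.nonref_metrics:
                records.append(
                    _safe_record(image_id, "reference", 0, norm, metric,
                                 _eval_nonref, metric, ref_n)
                )
        for name, strengths in cfg.distortions.items():
            for strength in strengths:
                seed = spec_seed(cfg.seed, image_id, name, strength)
                spec = DistortionSpec(name, strength, seed=seed)
                distorted = apply(spec, reference, schedule)
                for norm in cfg.normalizations:
                    try:
                        dist_n, _ = normalize(distorted, norm)
                        ref_n, _ = normalize(reference, norm)
                    except ValueError as exc:
                        for metric in cfg.ref_metrics + cfg.nonref_metrics:
                            records.append(BenchmarkRecord(
                                image_id, name, strength, norm, metric,
                                math.nan, f"normalization failed: {exc}"))
                        continue
                    for metric in cfg.ref_metrics:
                        records.append(
                            _safe_record(image_id, name, strength, norm, metric,
                                         _eval_ref, metric, dist_n, ref_n)
                        )
                    for metric in cfg.nonref_metrics:
                        records.append(
                            _safe_record(image_id, name, strength, norm, metric,
                                         _eval_nonref, metric, dist_n)
                        )
    return records


def _safe_record(image_id, distortion, strength, norm, metric, fn, *args) -> BenchmarkRecord:
    try:
        value = float(fn(*args))
        return BenchmarkRecord(image_id, distortion, strength, norm, metric, value)
    except (ValueError, ArithmeticError) as exc:
        return BenchmarkRecord(
            image_id, distortion, strength, norm, metric, math.nan, str(exc)
        )


def records_to_frame(records: Sequence[BenchmarkRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def write_records(records: Sequence[BenchmarkRecord], path: str | Path) -> Path:
    return write_table(records, path)


def aggregate_medians(
    records: Sequence[BenchmarkRecord] | pd.DataFrame,
    normalization: str | None = None,
) -> pd.DataFrame:
    """Median metric value per (metric, distortion) over images and strengths.

    Strength-0 reference records are excluded.  Missing values are excluded
    from each cell's median; a cell with no valid record at all is NaN, and
    the count of dropped records is available via the ``attrs['n_missing']``
    table on the result.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no benchmark records to aggregate")
    df = df[df["distortion"] != "reference"]
    if normalization is not None:
        df = df[df["normalization"] == normalization]
    if df.empty:
        raise ValueError("no benchmark records to aggregate")
    table = df.pivot_table(
        index="metric", columns="distortion", values="value", aggfunc="median"
    )
    missing = (
        df[df["value"].isna()]
        .groupby(["metric", "distortion"])
        .size()
        .unstack(fill_value=0)
    )
    table.attrs["n_missing"] = missing
    return table


def relative_scores(
    records: Sequence[BenchmarkRecord] | pd.DataFrame,
    normalization: str | None = None,
) -> pd.DataFrame:
    """Relative sensitivity: per-distortion median / pooled all-distortion median.

    The denominator pools the metric's raw per-cell values over every
    distortion (not the median of medians).  Cells whose denominator is 0
    are flagged as NaN.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[df["distortion"] != "reference"]
    if normalization is not None:
        df = df[df["normalization"] == normalization]
    table = aggregate_medians(df)
    pooled = df.groupby("metric")["value"].median()
    out = table.copy()
    for metric in out.index:
        denom = pooled.get(metric, math.nan)
        if denom == 0 or math.isnan(denom):
            out.loc[metric] = math.nan
        else:
            out.loc[metric] = table.loc[metric] / denom
    return out
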
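"""Study orchestration and summary analyses of per-feature repeatability.

This module runs the whole study — simulate (or ingest) a test-retest
cohort, extract the feature grid, estimate per-feature ICC(1,1), and
summarize — and implements the summary analyses the per-feature ICC
table feeds:

* the *Volume reference*: since absolute ICC thresholds are not
  comparable across populations, every feature's ICC is compared to the
  ICC of the tumor/gland volume within the same study;
* the ICC range and rank histogram across discretization bin widths;
* the top-k most repeatable features per feature class at their best
  pre-filter configuration;
* how often each pre-filter appears among features beating the
  reference (one feature may count under several filters);
* paired ICC deltas between two normalization modes.

CSV artifacts are the contract; the whole run is deterministic given the
config seed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .feature_engine import (DEFAULT_ROSTER, ExtractionConfig, FeatureRecord,
                             FeatureTable, extract_from_filtered)
from .filter_bank import FilterSpec, apply_filter, enumerate_filters, parse_filter_spec
from .preprocessing import NormalizationSpec, apply_normalization
from .repeatability_stats import ICC_KEY, icc_table
from .synthetic_data import PhantomSpec, generate_cohort, write_cohort
from .texture_core import DiscretizationSpec, STUDY_BIN_WIDTHS

logger = logging.getLogger("radstab")

#: the study's default reporting bin width
DEFAULT_REPORT_BIN_WIDTH = 15.0


class ConfigurationError(ValueError):
    """A report was asked for a key the ICC table cannot supply."""


# ---------------------------------------------------------------------------
# Summary analyses over an ICC results table
# ---------------------------------------------------------------------------

def volume_reference(icc_results: pd.DataFrame, roi: str, image_type: str) -> float:
    """The Volume ICC for one (roi, image_type) — the in-study threshold.

    Volume is a shape feature, invariant to normalization, filtering and
    discretization, so all its rows for a key agree; the single value is
    returned.  Missing or NaN Volume raises :class:`ConfigurationError`.
    """
    sel = icc_results[(icc_results["feature"] == "Volume")
                      & (icc_results["feature_class"] == "shape")
                      & (icc_results["roi"] == roi)
                      & (icc_results["image_type"] == image_type)]
    values = sel["icc"].dropna().unique()
    if len(values) == 0:
        raise ConfigurationError(f"no Volume ICC for roi={roi!r}, image_type={image_type!r}")
    if len(values) > 1 and not np.allclose(values, values[0]):
        raise ConfigurationError("Volume ICC differs across configurations")
    return float(values[0])


_BINWIDTH_GROUP = [c for c in ICC_KEY if c != "bin_width"]


def icc_range_over_binwidths(icc_results: pd.DataFrame) -> pd.DataFrame:
    """Per (feature, filter, ...) key: max - min ICC across bin widths.

    Keys observed at fewer than two bin widths are skipped with a
    warning.  Output columns: the key, ``n_widths``, ``icc_range``.
    """
    rows = []
    skipped = 0
    for key, grp in icc_results.dropna(subset=["icc"]).groupby(_BINWIDTH_GROUP, sort=True):
        if grp["bin_width"].nunique() < 2:
            skipped += 1
            continue
        rows.append(dict(zip(_BINWIDTH_GROUP, key), n_widths=grp["bin_width"].nunique(),
                         icc_range=float(grp["icc"].max() - grp["icc"].min())))
    if skipped:
        warnings.warn(f"{skipped} keys had a single bin width and were skipped")
    return pd.DataFrame(rows, columns=_BINWIDTH_GROUP + ["n_widths", "icc_range"])


def rank_histogram_over_binwidths(icc_results: pd.DataFrame) -> pd.DataFrame:
    """Histogram of per-key ICC ranks of each bin width.

    For every key with all bin widths present, widths are ranked by ICC
    descending (rank 1 = best); ties share the better rank.  Returns a
    DataFrame indexed by rank with one column per bin width; each
    column sums to the number of keys.
    """
    df = icc_results.dropna(subset=["icc"])
    widths = sorted(df["bin_width"].unique())
    hist = pd.DataFrame(0, index=pd.Index(range(1, len(widths) + 1), name="rank"),
                        columns=pd.Index(widths, name="bin_width"))
    for _, grp in df.groupby(_BINWIDTH_GROUP, sort=True):
        if sorted(grp["bin_width"].unique()) != widths or len(grp) != len(widths):
            continue
        grp = grp.sort_values("bin_width")
        ranks = rankdata(-grp["icc"].to_numpy(), method="min").astype(int)
        for w, r in zip(grp["bin_width"], ranks):
            hist.loc[r, w] += 1
    return hist


def top_k_per_class(icc_results: pd.DataFrame, k: int = 3,
                    bin_width: float = DEFAULT_REPORT_BIN_WIDTH) -> pd.DataFrame:
    """Top-k features per class by best-over-filters ICC at one bin width.

    "Best configuration" is the maximum ICC over the pre-filter grid at
    the reporting bin width.  Ties are broken lexicographically by
    feature name.  Output also carries the ICC spread (min/max) across
    filters for each selected feature.
    """
    df = icc_results[(icc_results["bin_width"] == bin_width)].dropna(subset=["icc"])
    if df.empty:
        # shape features carry the bin-width tag but do not depend on it;
        # an empty selection means the table lacks that bin width entirely
        raise ConfigurationError(f"no ICC rows at bin width {bin_width}")
    per_feature = df.groupby(["feature_class", "feature"])["icc"].agg(
        best_icc="max", icc_min="min", icc_max="max").reset_index()
    rows = []
    for cls, grp in per_feature.groupby("feature_class", sort=True):
        grp = grp.sort_values(["best_icc", "feature"], ascending=[False, True],
                              kind="mergesort")
        rows.append(grp.head(k))
    return pd.concat(rows, ignore_index=True)


def filter_frequency_above_reference(icc_results: pd.DataFrame,
                                     reference: float) -> tuple[pd.Series, int]:
    """Per-filter count of features whose ICC beats the reference.

    A feature contributes to *every* filter under which it exceeds the
    reference.  Returns the per-filter counts (indexed by filter
    fingerprint, including zero-count filters) and the number of
    distinct features above the reference under at least one filter.
    """
    df = icc_results.dropna(subset=["icc"])
    above = df[df["icc"] > reference]
    feat_key = above["feature_class"] + "/" + above["feature"]
    counts = above.assign(feat=feat_key).groupby("filter")["feat"].nunique()
    counts = counts.reindex(sorted(df["filter"].unique()), fill_value=0).astype(int)
    counts.name = "n_features_above_reference"
    return counts, int(feat_key.nunique())


_DELTA_KEY = [c for c in ICC_KEY if c != "normalization"]


def normalization_delta(icc_results_a: pd.DataFrame, icc_results_b: pd.DataFrame,
                        k: int = 3, bin_width: float = DEFAULT_REPORT_BIN_WIDTH
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature ICC change between two normalization modes.

    Tables are matched on every key column except ``normalization``;
    unmatched keys are dropped with a warning.  Returns the paired table
    with ``delta = icc_b - icc_a`` plus the union of the two modes'
    top-k sets per feature class (up to 2k features per class).
    """
    a = icc_results_a.rename(columns={"icc": "icc_a"})
    b = icc_results_b.rename(columns={"icc": "icc_b"})
    merged = a.merge(b[_DELTA_KEY + ["icc_b"]], on=_DELTA_KEY, how="inner")
    dropped = max(len(a), len(b)) - len(merged)
    if dropped > 0:
        warnings.warn(f"{dropped} unmatched keys dropped from normalization delta")
    deltas = merged[_DELTA_KEY + ["icc_a", "icc_b"]].copy()
    deltas["delta"] = deltas["icc_b"] - deltas["icc_a"]

    tops = pd.concat([top_k_per_class(icc_results_a, k=k, bin_width=bin_width),
                      top_k_per_class(icc_results_b, k=k, bin_width=bin_width)])
    union = (tops.sort_values(["feature_class", "feature"])
             .drop_duplicates(["feature_class", "feature"])
             .loc[:, ["feature_class", "feature"]].reset_index(drop=True))
    return deltas, union


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "image_type": "synthetic",
    "cohort": {},
    "normalization": ["none", "whole_image"],
    "filters": {},            # kwargs of enumerate_filters, or {"specs": [...fingerprints]}
    "bin_widths": list(STUDY_BIN_WIDTHS),
    "dim": ["2D"],
    "rois": ["tumor"],
    "roster": list(DEFAULT_ROSTER),
    "alpha": 0.1,
    "write_images": False,
}


def demo_config(n_subjects: int = 5, seed: int = 0) -> dict:
    """Reduced end-to-end grid: 5 subjects, 4 filters, 2 bin widths."""
    return load_config({
        "seed": seed,
        "cohort": {"n_subjects": n_subjects, "shape": [12, 32, 32]},
        "filters": {"specs": ["original", "log:sigma=2.0", "wavelet:HLL", "square"]},
        "bin_widths": [10.0, 15.0],
        "rois": ["tumor", "peripheral_zone"],
    })


def load_config(source: str | Path | Mapping | None = None) -> dict:
    """Merge a YAML file or mapping over the defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, list) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        import yaml

        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    unknown = set(source) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
    cfg.update(source)
    return cfg


def _filters_from_config(cfg: Mapping) -> list[FilterSpec]:
    fcfg = dict(cfg.get("filters") or {})
    if "specs" in fcfg:
        return [parse_filter_spec(s) for s in fcfg["specs"]]
    return enumerate_filters(**fcfg)


def build_configs(cfg: Mapping) -> list[ExtractionConfig]:
    """The full extraction grid of one run config."""
    roster = {cls: DEFAULT_ROSTER[cls] for cls in cfg["roster"]}
    dims = [cfg["dim"]] if isinstance(cfg["dim"], str) else list(cfg["dim"])
    configs = []
    for roi in cfg["rois"]:
        for mode in cfg["normalization"]:
            for filt in _filters_from_config(cfg):
                for w in cfg["bin_widths"]:
                    for dim in dims:
                        configs.append(ExtractionConfig(
                            image_type=cfg["image_type"], roi=roi,
                            normalization=NormalizationSpec(mode=mode),
                            filter=filt,
                            discretization=DiscretizationSpec(bin_width=float(w)),
                            dim=dim, roster=roster))
    return configs


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def extract_table(records, configs: Sequence[ExtractionConfig],
                  provenance: Mapping | None = None) -> FeatureTable:
    """Extract the full grid for a cohort, caching shared pipeline stages.

    Normalized and filtered images are computed once per scan per
    (roi, normalization, filter) and reused across bin widths and
    dimensionalities; results are identical to calling
    :func:`radstab.feature_engine.extract` per config.
    """
    out: list[FeatureRecord] = []
    for rec in records:
        logger.info("extracting %s/%s", rec.subject_id, rec.timepoint)
        norm_cache: dict[str, object] = {}
        for (roi, norm_fp, filt_fp), group in _grouped(configs):
            cache_key = norm_fp
            if cache_key not in norm_cache:
                norm_cache[cache_key] = apply_normalization(
                    rec.image, rec.mask, group[0].normalization)
            filtered = apply_filter(norm_cache[cache_key], group[0].filter)
            for config in group:
                out.extend(extract_from_filtered(filtered, rec.mask, config,
                                                 rec.subject_id, rec.timepoint))
    return FeatureTable.from_records(out, provenance=provenance)


def _grouped(configs: Sequence[ExtractionConfig]):
    groups: dict[tuple, list[ExtractionConfig]] = {}
    for c in configs:
        groups.setdefault((c.roi, c.normalization.fingerprint, c.filter.fingerprint),
                          []).append(c)
    return groups.items()


@dataclasses.dataclass
class StudyReport:
    """All summary artifacts of one study run."""

    icc: pd.DataFrame
    references: dict[tuple[str, str], float]       # (roi, image_type) -> Volume ICC
    icc_ranges: pd.DataFrame
    rank_histogram: pd.DataFrame
    top3: pd.DataFrame
    filter_frequency: dict[tuple[str, str], pd.Series]
    features_above_reference: dict[tuple[str, str], int]


def build_report(icc: pd.DataFrame, top_k: int = 3,
                 report_bin_width: float = DEFAULT_REPORT_BIN_WIDTH) -> StudyReport:
    """Assemble every summary from a persisted ICC table (idempotent)."""
    references: dict[tuple[str, str], float] = {}
    freq: dict[tuple[str, str], pd.Series] = {}
    above: dict[tuple[str, str], int] = {}
    for (roi, itype), grp in icc.groupby(["roi", "image_type"], sort=True):
        ref = volume_reference(icc, roi, itype)
        references[(roi, itype)] = ref
        at_width = grp[grp["bin_width"] == report_bin_width]
        counts, total = filter_frequency_above_reference(at_width, ref)
        freq[(roi, itype)] = counts
        above[(roi, itype)] = total
    tops = []
    for (roi, itype), grp in icc.groupby(["roi", "image_type"], sort=True):
        t = top_k_per_class(grp, k=top_k, bin_width=report_bin_width)
        t.insert(0, "roi", roi)
        t.insert(1, "image_type", itype)
        tops.append(t)
    return StudyReport(icc=icc, references=references,
                       icc_ranges=icc_range_over_binwidths(icc),
                       rank_histogram=rank_histogram_over_binwidths(icc),
                       top3=pd.concat(tops, ignore_index=True),
                       filter_frequency=freq, features_above_reference=above)


def write_report(report: StudyReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.icc.to_csv(outdir / "icc.csv", index=False)
    ref = pd.DataFrame([{"roi": r, "image_type": t, "volume_icc": v}
                        for (r, t), v in sorted(report.references.items())])
    ref.to_csv(outdir / "volume_reference.csv", index=False)
    report.icc_ranges.to_csv(outdir / "icc_ranges.csv", index=False)
    report.rank_histogram.to_csv(outdir / "rank_histogram.csv")
    report.top3.to_csv(outdir / "top3_per_class.csv", index=False)
    rows = []
    for (roi, itype), counts in sorted(report.filter_frequency.items()):
        for filt, n in counts.items():
            rows.append({"roi": roi, "image_type": itype, "filter": filt,
                         "n_features_above_reference": n,
                         "total_features_above_reference":
                             report.features_above_reference[(roi, itype)]})
    pd.DataFrame(rows).to_csv(outdir / "filter_frequency.csv", index=False)


def run_study(config: str | Path | Mapping | None, outdir: str | Path) -> StudyReport:
    """simulate -> extract -> ICC -> report, deterministic given the seed.

    All intermediates (cohort manifest if requested, feature table, ICC
    table, report CSVs) are persisted under ``outdir``.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("simulating cohort (seed=%s)", cfg["seed"])
    spec = PhantomSpec(seed=int(cfg["seed"]),
                       **{k: tuple(v) if isinstance(v, list) else v
                          for k, v in cfg["cohort"].items()})
    records = generate_cohort(spec)
    if cfg.get("write_images"):
        write_cohort(records, outdir / "cohort")

    configs = build_configs(cfg)
    logger.info("extracting %d records x %d configs", len(records), len(configs))
    table = extract_table(records, configs,
                          provenance={"seed": cfg["seed"], "n_configs": len(configs)})
    table.to_csv(outdir / "features.csv")

    logger.info("estimating ICC (alpha=%s)", cfg["alpha"])
    icc = icc_table(table, alpha=float(cfg["alpha"]))
    icc.to_csv(outdir / "icc.csv", index=False)

    report = build_report(icc)
    write_report(report, outdir / "report")
    logger.info("report written to %s", outdir / "report")
    return report
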
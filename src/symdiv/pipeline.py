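"""End-to-end orchestration of the assemblage-diversity analysis.

The pipeline filters association records, computes per-species raw and
rarefied diversity metrics, and runs two families of lambda-gated
comparative regressions:

* the depth series -- rarefied richness at each standard depth (15, 20,
  30, 40, 50, 60 records) against the bleaching response index, on the
  shrinking taxon set eligible at each depth;
* trait regressions -- a configurable pair list covering richness,
  evenness and bleaching response against bathymetric/geographic ranges
  and sampling effort, including the debiasing diagnostics (raw metrics
  vs effort should correlate; rarefied metrics vs effort should not).

Outputs are plain TSV tables plus a JSON run manifest recording versions,
seed and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import diversity, phylo, records

log = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "DEFAULT_DEPTHS",
    "DEFAULT_PAIRS",
    "load_config",
    "metrics_table",
    "curves_table",
    "depth_series",
    "trait_regressions",
    "run_all",
]

DEFAULT_DEPTHS: tuple[int, ...] = (15, 20, 30, 40, 50, 60)

#: Default regression pair list: (metric y, covariate x). The first nine
#: pairs relate richness metrics and bleaching response to species range
#: sizes; the effort pairs are the sampling-bias diagnostics; the final
#: pairs relate evenness metrics to each other and to bleaching response.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("raw_R", "delta_depth"),
    ("raw_R", "delta_lat"),
    ("raw_R", "delta_long"),
    ("rarefied_R_15", "delta_depth"),
    ("rarefied_R_15", "delta_lat"),
    ("rarefied_R_15", "delta_long"),
    ("taxon_bri", "delta_depth"),
    ("taxon_bri", "delta_lat"),
    ("taxon_bri", "delta_long"),
    ("raw_R", "n_records"),
    ("raw_E", "n_records"),
    ("rarefied_R_15", "n_records"),
    ("pie", "n_records"),
    ("pie", "raw_E"),
    ("pie", "taxon_bri"),
    ("rarefied_R_15", "raw_R"),
)


@dataclass
class AnalysisConfig:
    """Flat configuration for a pipeline run; every key can come from a
    YAML config file or be overridden on the command line."""

    records: str = ""
    traits: str = ""
    tree: str = ""
    out_dir: str = "results"
    dialect: str = "tsv"
    depths: tuple[int, ...] = DEFAULT_DEPTHS
    min_records: int = 15
    alpha: float = 0.05
    exclude_pigv: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.depths = tuple(int(d) for d in self.depths)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_records < 1:
            raise ValueError("min_records must be >= 1")
        if self.depths and min(self.depths) < self.min_records:
            log.warning(
                "smallest rarefaction depth %d is below min_records %d; "
                "species are normally filtered at the smallest depth",
                min(self.depths), self.min_records,
            )


def load_config(path: str | Path, **overrides) -> AnalysisConfig:
    """Read an AnalysisConfig from a flat YAML key-value file, applying
    keyword overrides (used for CLI flags)."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    unknown = set(data) - set(AnalysisConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return AnalysisConfig(**data)


# ---------------------------------------------------------------------------
# metric tables


def metrics_table(
    rs: records.RecordSet,
    depths: Iterable[int] = DEFAULT_DEPTHS,
    traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-species metric table: sampling effort, raw richness/evenness,
    PIE, rarefied richness at each depth, end-slope, observed ranges, and
    (when supplied) joined trait columns such as taxon_bri.

    Ranges computed from the records take precedence; missing values are
    filled from the trait table's optional range columns.
    """
    depths = sorted({int(d) for d in depths})
    assemblages = records.tabulate_assemblages(rs)
    ranges = records.species_ranges(rs)
    rows = []
    for species in sorted(assemblages):
        a = assemblages[species]
        m = diversity.species_metrics(a, depths)
        curve = diversity.rarefaction_curve(a, label=species)
        row = {
            "host_species": species,
            "n_records": m.n_records,
            "raw_R": m.raw_richness,
            "raw_E": m.raw_evenness,
            "pie": m.pie,
            "slope_at_end": curve.slope_at_end,
        }
        for d in depths:
            v = m.rarefied_richness[d]
            row[f"rarefied_R_{d}"] = np.nan if v is None else v
        rows.append(row)
    out = pd.DataFrame(rows).set_index("host_species")
    out = out.join(ranges)
    if traits is not None:
        for col in traits.columns:
            if col in ("delta_depth", "delta_lat", "delta_long"):
                out[col] = out[col].fillna(traits[col])
            else:
                out = out.join(traits[[col]], how="left")
        missing = out.index[~out.index.isin(traits.index)]
        if len(missing):
            log.warning("%d species missing from trait table", len(missing))
    return out


def curves_table(rs: records.RecordSet) -> pd.DataFrame:
    """Long-format rarefaction curves (species, n, expected_richness)."""
    assemblages = records.tabulate_assemblages(rs)
    frames = []
    for species in sorted(assemblages):
        curve = diversity.rarefaction_curve(assemblages[species], label=species)
        frames.append(pd.DataFrame({
            "host_species": species,
            "n": curve.sizes,
            "expected_richness": curve.expected,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# gated regressions


def _gated_row(
    tree: dendropy.Tree,
    sub: pd.DataFrame,
    ycol: str,
    xcol: str,
    alpha: float,
    seed: int,
) -> dict:
    x = {s: float(v) for s, v in sub[xcol].items()}
    y = {s: float(v) for s, v in sub[ycol].items()}
    gated = phylo.lambda_gated_regression(tree, x, y, alpha=alpha, seed=seed)
    acc = gated.accepted_result
    return {
        "n": gated.ols.n,
        "linear_r": gated.ols.r,
        "linear_p": gated.ols.p_value,
        "lambda_hat": gated.lambda_test.lambda_hat,
        "lambda_p": gated.lambda_test.p_value,
        "phylo_r": gated.pic.r,
        "phylo_p": gated.pic.p_value,
        "accepted": gated.accepted,
        "accepted_r": acc.r,
        "accepted_p": acc.p_value,
    }


def depth_series(
    metrics: pd.DataFrame,
    tree: dendropy.Tree,
    depths: Iterable[int] = DEFAULT_DEPTHS,
    response: str = "taxon_bri",
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Gated regression of the bleaching response on rarefied richness at
    each standard depth, over the taxon set eligible (N >= depth) there.

    Depths with fewer than 3 eligible species are skipped with a warning.
    """
    rows = []
    for d in sorted({int(d) for d in depths}):
        col = f"rarefied_R_{d}"
        if col not in metrics.columns:
            raise ValueError(f"metrics table lacks column {col}")
        sub = metrics[[col, response]].dropna()
        sub = sub[sub.index.isin(phylo.tip_labels(tree))]
        if len(sub) < 3:
            log.warning("depth %d: only %d eligible species; skipped", d, len(sub))
            continue
        row = {"depth": d, "n_species": len(sub)}
        row.update(_gated_row(tree, sub, response, col, alpha, seed))
        rows.append(row)
    return pd.DataFrame(rows)


def trait_regressions(
    metrics: pd.DataFrame,
    tree: dendropy.Tree,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Gated regression for each configured (metric, covariate) pair.

    Pairs whose covariate is constant (or with < 3 complete cases) are
    skipped with a warning; one output row per completed pair.
    """
    rows = []
    for ycol, xcol in pairs:
        if ycol not in metrics.columns or xcol not in metrics.columns:
            log.warning("pair (%s, %s): column missing; skipped", ycol, xcol)
            continue
        sub = metrics[[ycol, xcol]].dropna()
        sub = sub[sub.index.isin(phylo.tip_labels(tree))]
        if len(sub) < 3:
            log.warning("pair (%s, %s): < 3 complete cases; skipped", ycol, xcol)
            continue
        if np.ptp(sub[xcol].to_numpy()) == 0 or np.ptp(sub[ycol].to_numpy()) == 0:
            log.warning("pair (%s, %s): constant values; skipped", ycol, xcol)
            continue
        row = {"metric": ycol, "parameter": xcol}
        row.update(_gated_row(tree, sub, ycol, xcol, alpha, seed))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(config: AnalysisConfig) -> dict:
    """Execute the whole analysis from the configured input files and
    write all result tables under ``config.out_dir``.

    Returns a dict with the in-memory tables (``metrics``, ``curves``,
    ``depth_series``, ``trait_regressions``, ``manifest``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rs = records.read_records(config.records, dialect=config.dialect)
    n_raw = len(rs)
    if config.exclude_pigv:
        rs = records.exclude_pigv(rs)
    rs = records.filter_min_records(rs, min_n=config.min_records)
    traits = records.read_traits(config.traits, dialect=config.dialect) \
        if config.traits else None
    tree = phylo.parse_newick(config.tree) if config.tree else None

    metrics = metrics_table(rs, depths=config.depths, traits=traits)
    curves = curves_table(rs)
    metrics.to_csv(out_dir / "species_metrics.tsv", sep="\t")
    curves.to_csv(out_dir / "rarefaction_curves.tsv", sep="\t", index=False)

    ds = pd.DataFrame()
    tr = pd.DataFrame()
    if tree is not None:
        if "taxon_bri" in metrics.columns:
            ds = depth_series(metrics, tree, depths=config.depths,
                              alpha=config.alpha, seed=config.seed)
        tr = trait_regressions(metrics, tree, alpha=config.alpha,
                               seed=config.seed)
        ds.to_csv(out_dir / "depth_series.tsv", sep="\t", index=False)
        tr.to_csv(out_dir / "trait_regressions.tsv", sep="\t", index=False)

    manifest = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {
            name: _sha256(path)
            for name, path in (("records", config.records),
                               ("traits", config.traits),
                               ("tree", config.tree))
            if path
        },
        "n_records_read": n_raw,
        "summary": records.summarize(rs),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "metrics": metrics,
        "curves": curves,
        "depth_series": ds,
        "trait_regressions": tr,
        "manifest": manifest,
    }
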
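"""End-to-end orchestration: simulate/ingest -> segment -> quantify -> stats.

``run_pipeline`` chains the stage modules behind one seeded, structured
config and writes the standard report bundle::

    cases.csv            one row per case (CaseSummary)
    objects.csv          one row per segmented object
    folds.csv            GBM:control fold change + Mann-Whitney U per measure
    correlations.csv     per-group Spearman matrix of OATP vs cell markers
    regions.csv          per-case niche-resolved OATP intensity (simulate mode)
    degs.csv             CT-vs-niche differential expression (optional stage)
    overlap.json         shared/unique DEGs between PPN and PNZ
    gene_correlations.csv OATP genes vs top DEGs, cluster-ordered
    run_manifest.json    config echo, versions, seed, per-stage row counts

Identical config and seed produce byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, niche, quantify, segment, simgen, stats
from .types import CHANNELS, CaseImage

logger = logging.getLogger("oatpquant")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "config_from_yaml"]

DEFAULT_FOLD_MEASURES = (
    "tissue_mean_integrated_intensity",
    "tissue_integrated_intensity",
    "percent_area_coverage",
    "myeloid_mean_oatp",
    "vessel_mean_oatp",
)

MARKER_VARIABLES = (
    "tissue_mean_integrated_intensity",
    "iba1_tissue_mean",
    "gfap_tissue_mean",
    "pdgfrb_tissue_mean",
    "lectin_tissue_mean",
)


@dataclass
class RunConfig:
    """Structured configuration of one pipeline run.

    Exactly one input mode: ``simulate`` draws the cohort from
    ``generator``; ``ingest`` reads TIFFs + ``cases_manifest.csv`` from
    ``input_dir``.  ``seed`` (if given) overrides the generator and
    expression seeds so one integer reproduces the whole run.
    """

    mode: str = "simulate"
    generator: simgen.GeneratorConfig = field(default_factory=simgen.GeneratorConfig)
    segmentation: segment.SegmentationParams = field(default_factory=segment.SegmentationParams)
    expression: simgen.ExpressionConfig | None = None
    input_dir: str | None = None
    outdir: str = "results"
    seed: int | None = None
    log_level: str = "INFO"
    fold_measures: tuple[str, ...] = DEFAULT_FOLD_MEASURES
    positivity_percentile: float = 0.99  # of control single-cell OATP means
    top_deg_count: int = 40
    save_images: bool = False

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest" and not self.input_dir:
            raise ValueError("ingest mode requires input_dir")


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    objects: pd.DataFrame
    folds: pd.DataFrame
    correlations: pd.DataFrame
    regions: pd.DataFrame
    degs: pd.DataFrame | None
    overlap: dict | None
    gene_correlations: pd.DataFrame | None
    manifest: dict
    outdir: Path
    positivity_thresholds: dict[str, float]


def _objects_frame(objects: list[quantify.ObjectMeasurement]) -> pd.DataFrame:
    rows = []
    for m in objects:
        row = {
            "case_id": m.case_id,
            "object_id": m.object_id,
            "type": m.type,
            "row": m.centroid[0],
            "col": m.centroid[1],
            "area_px": m.area_px,
        }
        for ch in CHANNELS:
            if ch in m.mean_intensity:
                row[f"mean_{ch}"] = m.mean_intensity[ch]
        rows.append(row)
    cols = ["case_id", "object_id", "type", "row", "col", "area_px"] + [
        f"mean_{ch}" for ch in CHANNELS
    ]
    return pd.DataFrame(rows, columns=cols)


def _iter_input_cases(config: RunConfig):
    """Yield (list-of-CaseImage, GroundTruth-or-None) per case."""
    if config.mode == "simulate":
        for case, truth in simgen.iter_cohort(config.generator):
            yield [case], truth
    else:
        indir = Path(config.input_dir)
        manifest = io.read_manifest(indir)
        for case_id, rows in manifest.groupby("case_id", sort=True):
            images = []
            for _, row in rows.iterrows():
                mp = indir / f"{case_id}.tif"
                src = mp if mp.exists() else indir
                images.append(
                    io.load_case(
                        src, case_id=case_id, group=row["group"], isoform=row.get("isoform")
                    )
                )
            yield images, None


def positivity_thresholds_from_objects(
    objects: pd.DataFrame, percentile: float
) -> dict[str, float]:
    """Per-type OATP positivity cutoffs: percentile of control object means."""
    out = {}
    ctrl = objects[objects["group"] == "control"]
    for cell_type in ("myeloid", "vessel"):
        vals = ctrl.loc[ctrl["type"] == cell_type, "mean_oatp"].dropna()
        if len(vals):
            out[cell_type] = float(np.quantile(vals, percentile))
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    generator = config.generator
    expr_cfg = config.expression
    if config.seed is not None:
        generator = generator.copy(seed=int(config.seed))
        if expr_cfg is not None:
            import copy as _copy

            expr_cfg = _copy.deepcopy(expr_cfg)
            expr_cfg.seed = int(config.seed) + 1

    t0 = time.time()
    summaries: list[quantify.CaseSummary] = []
    object_rows: list[pd.DataFrame] = []
    region_rows: list[dict] = []
    stage = "simulate" if config.mode == "simulate" else "ingest"
    try:
        for images, truth in _iter_input_cases(
            RunConfig(**{**asdict_shallow(config), "generator": generator})
        ):
            stage = "segment"
            segs = [segment.segment_case(img, config.segmentation) for img in images]
            stage = "quantify"
            summary, objects = quantify.summarize_case(images, segs)
            summaries.append(summary)
            df = _objects_frame(objects)
            df.insert(1, "group", summary.group)
            object_rows.append(df)
            if truth is not None:
                means = quantify.regional_quantify(images[0].channels["oatp"], truth.regions)
                for region, value in means.items():
                    region_rows.append(
                        {
                            "case_id": summary.case_id,
                            "group": summary.group,
                            "region": region,
                            "mean_oatp": value,
                        }
                    )
            if config.save_images:
                io.save_case(images[0], outdir / "images")
                if truth is not None:
                    io.save_ground_truth(truth, outdir / "truth", summary.case_id)
            logger.info(
                "case %s: %d objects, %.2fs elapsed",
                summary.case_id,
                len(objects),
                time.time() - t0,
            )
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        raise

    objects_df = (
        pd.concat(object_rows, ignore_index=True)
        if object_rows
        else _objects_frame([]).assign(group=pd.Series(dtype=str))
    )
    thresholds = positivity_thresholds_from_objects(objects_df, config.positivity_percentile)
    for s in summaries:
        sub = objects_df[objects_df["case_id"] == s.case_id]
        for cell_type, attr in (("myeloid", "myeloid_positive_fraction"), ("vessel", "vessel_positive_fraction")):
            thr = thresholds.get(cell_type)
            vals = sub.loc[sub["type"] == cell_type, "mean_oatp"]
            if thr is not None and len(vals):
                setattr(s, attr, float((vals > thr).mean()))
    cohort = quantify.cohort_table(summaries)

    stage = "stats"
    fold_rows = []
    have_both = {"gbm", "control"} <= set(cohort["group"])
    if have_both:
        for measure in config.fold_measures:
            try:
                fc = quantify.group_fold_change(cohort, measure)
            except (ValueError, ZeroDivisionError) as exc:
                logger.warning("skipping fold for %r: %s", measure, exc)
                continue
            fold_rows.append(
                {
                    "measure": measure,
                    "fold": fc.fold,
                    "gbm_mean": fc.group_means["gbm"],
                    "control_mean": fc.group_means["control"],
                    "U": fc.test.statistic,
                    "p": fc.test.p_two_sided,
                    "n_gbm": fc.test.n1,
                    "n_control": fc.test.n2,
                    "method": fc.test.method,
                }
            )
    folds = pd.DataFrame(
        fold_rows,
        columns=["measure", "fold", "gbm_mean", "control_mean", "U", "p", "n_gbm", "n_control", "method"],
    )

    corr_rows = []
    for group in ("gbm", "control"):
        sub = cohort[cohort["group"] == group]
        if len(sub) >= 3:
            mat = stats.correlation_matrix(sub, list(MARKER_VARIABLES))
            long = mat.to_long()
            long.insert(0, "group", group)
            corr_rows.append(long)
    correlations = (
        pd.concat(corr_rows, ignore_index=True)
        if corr_rows
        else pd.DataFrame(columns=["group", "var_a", "var_b", "rho", "p", "p_bh", "n"])
    )

    regions = pd.DataFrame(region_rows, columns=["case_id", "group", "region", "mean_oatp"])

    degs_df = overlap = gene_corr_df = None
    if expr_cfg is not None:
        stage = "niche"
        table = simgen.generate_expression_table(expr_cfg)
        deg_frames = []
        deg_lists = {}
        for region in ("PPN", "PNZ"):
            degs = niche.differential_expression(table, region)
            deg_lists[region] = degs
            deg_frames.append(pd.DataFrame([vars(d) for d in degs]))
        degs_df = pd.concat(deg_frames, ignore_index=True)
        overlap = niche.region_overlap(deg_lists["PPN"], deg_lists["PNZ"]).to_dict()
        top = sorted(
            set(niche.top_genes(deg_lists["PPN"], config.top_deg_count))
            | set(niche.top_genes(deg_lists["PNZ"], config.top_deg_count))
        )
        oatp_genes = [g for g in simgen.SLCO_GENES if g in table.values.index]
        gene_set = [g for g in top if g not in oatp_genes]
        if len(gene_set) >= 1:
            gene_corr_df = niche.oatp_gene_correlation(table, oatp_genes, gene_set).to_long()

    # report bundle
    cohort.to_csv(outdir / "cases.csv", index=False)
    objects_df.to_csv(outdir / "objects.csv", index=False)
    folds.to_csv(outdir / "folds.csv", index=False)
    correlations.to_csv(outdir / "correlations.csv", index=False)
    regions.to_csv(outdir / "regions.csv", index=False)
    if degs_df is not None:
        degs_df.to_csv(outdir / "degs.csv", index=False)
        with open(outdir / "overlap.json", "w") as fh:
            json.dump(overlap, fh, indent=1, sort_keys=True)
    if gene_corr_df is not None:
        gene_corr_df.to_csv(outdir / "gene_correlations.csv", index=False)

    manifest = {
        "package_version": __version__,
        "mode": config.mode,
        "seed": config.seed if config.seed is not None else generator.seed,
        "isoform": generator.isoform,
        "positivity_thresholds": thresholds,
        "row_counts": {
            "cases": len(cohort),
            "objects": len(objects_df),
            "folds": len(folds),
            "correlations": len(correlations),
            "regions": len(regions),
            "degs": 0 if degs_df is None else len(degs_df),
        },
        "elapsed_s": round(time.time() - t0, 3),
    }
    io.config_to_json(
        {
            "run": {k: v for k, v in asdict_shallow(config).items() if not hasattr(v, "__dataclass_fields__")},
            "generator": asdict(generator),
            "segmentation": asdict(config.segmentation),
            "expression": None if expr_cfg is None else asdict(expr_cfg),
            **manifest,
        },
        outdir / "run_manifest.json",
    )
    return PipelineResult(
        cohort=cohort,
        objects=objects_df,
        folds=folds,
        correlations=correlations,
        regions=regions,
        degs=degs_df,
        overlap=overlap,
        gene_correlations=gene_corr_df,
        manifest=manifest,
        outdir=outdir,
        positivity_thresholds=thresholds,
    )


def asdict_shallow(config) -> dict:
    return {k: getattr(config, k) for k in config.__dataclass_fields__}


def _apply(dc, payload: dict):
    for key, value in payload.items():
        if not hasattr(dc, key):
            raise KeyError(f"unknown config key {key!r} for {type(dc).__name__}")
        current = getattr(dc, key)
        if isinstance(current, tuple) and isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        if isinstance(current, dict) and isinstance(value, dict):
            merged = dict(current)
            for k, v in value.items():
                merged[k] = tuple(v) if isinstance(v, list) else v
            value = merged
        setattr(dc, key, value)
    return dc


def config_from_yaml(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file with optional nested sections
    ``generator``, ``segmentation`` and ``expression``."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    gen = payload.pop("generator", None)
    seg = payload.pop("segmentation", None)
    expr = payload.pop("expression", None)
    _apply(cfg, payload)
    if gen:
        _apply(cfg.generator, gen)
    if seg:
        _apply(cfg.segmentation, seg)
    if expr is not None:
        cfg.expression = _apply(simgen.ExpressionConfig(), expr or {})
    return cfg
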
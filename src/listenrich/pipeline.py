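"""End-to-end pipeline: load universes, compile lists, run the battery,
classify immune genes, rank cell types, and write a reproducible report."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__
from .de_table import call_directions, load_de_table
from .enrichment import celltype_enrich
from .immune import ClassificationResource, calls_to_tsv, classify_immune, load_curation
from .marker_lists import IdMap, compile_from_config, finalize_against
from .model import MarkerOverlapModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    File paths may be None where a stage is optional (protein universe,
    immune resources, cell-type database).  All thresholds are echoed into
    the run log so the record carries every cutoff the conclusions hinge on.
    """

    de_table: str
    lists_config: str
    out_dir: str
    protein_table: str | None = None
    idmap_gene_protein: str | None = None
    idmap_transcript_gene: str | None = None
    curated_immune: str | None = None
    go_immune: str | None = None
    curation: str | None = None
    celltype_db: str | None = None
    alpha: float = 0.05
    min_abs_log2fc: float = 0.0
    direction_mode: str = "call"  # call | as-given
    sidedness: str = "greater"
    background: float | None = None
    protein_background: float | None = None
    top_n: int = 20
    seed: int = 0
    de_schema: dict = field(default_factory=dict)

    def required_paths(self):
        paths = {"de_table": self.de_table, "lists_config": self.lists_config}
        for name in ("protein_table", "idmap_gene_protein", "idmap_transcript_gene",
                     "curated_immune", "go_immune", "curation", "celltype_db"):
            value = getattr(self, name)
            if value is not None:
                paths[name] = value
        return paths


def load_celltype_db(path) -> dict[str, frozenset[str]]:
    """Two-column TSV (term, gene), one marker per row, with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    db: dict[str, set[str]] = {}
    for term, gene in zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()):
        db.setdefault(term, set()).add(gene)
    return {t: frozenset(g) for t, g in db.items()}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every configured stage; returns a dict of output paths.

    Fails fast — every referenced input file is checked before any
    computation — and each stage error is surfaced with its stage name.
    """
    missing = [f"{name}: {path}" for name, path in cfg.required_paths().items()
               if not Path(path).exists()]
    if missing:
        raise FileNotFoundError("missing input file(s): " + "; ".join(missing))

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("listenrich")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict = {"log": log_path}
    try:
        logger.info(
            "listenrich %s | python %s | numpy %s scipy %s pandas %s statsmodels %s",
            __version__, sys.version.split()[0], np.__version__,
            scipy.__version__, pd.__version__, statsmodels.__version__,
        )
        logger.info(
            "thresholds: alpha=%s min_abs_log2fc=%s direction_mode=%s sidedness=%s "
            "background=%s protein_background=%s top_n=%s seed=%s",
            cfg.alpha, cfg.min_abs_log2fc, cfg.direction_mode, cfg.sidedness,
            cfg.background, cfg.protein_background, cfg.top_n, cfg.seed,
        )

        stage = "load DE universe"
        universe = load_de_table(cfg.de_table, schema=cfg.de_schema, modality="transcript")
        if cfg.direction_mode == "call":
            universe = call_directions(universe, alpha=cfg.alpha, min_abs_log2fc=cfg.min_abs_log2fc)
        logger.info(
            "universe: %d detected, %d increased, %d decreased",
            universe.n_detected, universe.n_increased, universe.n_decreased,
        )

        protein_universe = idmap = None
        if cfg.protein_table is not None:
            stage = "load protein universe"
            protein_universe = load_de_table(cfg.protein_table, schema=cfg.de_schema, modality="protein")
            if cfg.direction_mode == "call":
                protein_universe = call_directions(
                    protein_universe, alpha=cfg.alpha, min_abs_log2fc=cfg.min_abs_log2fc
                )
            stage = "load id map"
            idmap = IdMap.from_tsv(cfg.idmap_gene_protein, cfg.idmap_transcript_gene)

        stage = "compile marker lists"
        compiled = compile_from_config(cfg.lists_config)
        lists = [
            finalize_against(raw, universe, name=name, combination=combination)
            for name, (combination, raw) in compiled.items()
        ]
        membership_path = out_dir / "list_members.tsv"
        with open(membership_path, "w") as fh:
            fh.write("list\tgene_id\tdetected\n")
            for lst in lists:
                for gene in sorted(lst.raw_members):
                    fh.write(f"{lst.name}\t{gene}\t{str(gene in lst.detected_members).lower()}\n")
        outputs["list_members"] = membership_path

        stage = "overlap enrichment"
        results = MarkerOverlapModel(
            lists, universe,
            protein_universe=protein_universe, idmap=idmap,
            background=cfg.background, protein_background=cfg.protein_background,
            sidedness=cfg.sidedness,
        ).fit()
        summary_path = out_dir / "enrichment_summary.tsv"
        results.to_tsv(summary_path)
        results.to_json(out_dir / "enrichment_results.json")
        outputs["summary"] = summary_path
        outputs["results_json"] = out_dir / "enrichment_results.json"
        logger.info("battery:\n%s", results.summary())

        if cfg.curated_immune or cfg.go_immune:
            stage = "immune classification"
            res = ClassificationResource.from_files(
                curated=cfg.curated_immune, go=cfg.go_immune
            )
            challenge = frozenset().union(*(l.raw_members for l in lists)) if lists else frozenset()
            res.immune_challenge_members = challenge
            curation = load_curation(cfg.curation) if cfg.curation else None
            increased = sorted(universe.gene_ids("increased"))
            calls = classify_immune(increased, res, curation=curation)
            immune_path = out_dir / "immune_calls.tsv"
            calls_to_tsv(calls, immune_path)
            outputs["immune_calls"] = immune_path
            logger.info("immune: %d of %d increased genes flagged",
                        sum(c.is_immune for c in calls), len(calls))

        if cfg.celltype_db is not None:
            stage = "cell-type enrichment"
            db = load_celltype_db(cfg.celltype_db)
            ranked = celltype_enrich(
                universe.gene_ids("increased"), db, universe.gene_ids(),
                alpha=cfg.alpha, top_n=cfg.top_n, sidedness=cfg.sidedness,
            )
            ct_path = out_dir / "celltype_ranking.tsv"
            with open(ct_path, "w") as fh:
                fh.write("rank\tterm\tn_markers_detected\tn_overlap\tfold_enrichment\tp_raw\tp_adjusted\n")
                for r in ranked:
                    fh.write(
                        f"{r.rank}\t{r.term}\t{r.n_markers_detected}\t{r.n_overlap}\t"
                        f"{r.fold_enrichment:.6g}\t{r.p_raw:.6g}\t{r.p_adjusted:.6g}\n"
                    )
            outputs["celltype_ranking"] = ct_path
            logger.info("cell types: %d significant terms reported", len(ranked))
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    outputs["config"] = out_dir / "run_config.json"
    with open(outputs["config"], "w") as fh:
        json.dump({k: str(v) if isinstance(v, Path) else v
                   for k, v in vars(cfg).items()}, fh, indent=2, default=str)
    return outputs
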
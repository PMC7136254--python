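"""Config-driven orchestration of the full screen.

Stages run in method order: mutation loads -> expression z-scores ->
per-cancer Spearman screen (top-K lists) -> cross-cancer aggregation
(recurrence, tripartition) -> enrichment (hypergeometric over-representation
and, when a pathway with complexes is configured, the complex-level
chi-square). Every intermediate table is written under
``outdir/<cancer>/...`` or ``outdir/cross_cancer/...`` and a JSON manifest
records config, seed, per-stage row counts, output checksums and wall time;
rerunning with the same config reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .correlation import TopKLists, screen_cancer, top_k, write_results
from .cross_cancer import classify_genes, recurrence, recurrent_genes
from .enrichment import (CATEGORY_LABELS, complex_chi_square,
                         complex_tests_table, hypergeom_enrich)
from .expression import read_matrix, zscore_transform
from .gmt import read_gmt
from .mutation_load import (MAF_DIALECT, SIMPLE_DIALECT, compute_loads,
                            read_maf_like, write_loads)

logger = logging.getLogger(__name__)

STAGES = ("mutation_load", "expression_zscore", "correlation_screen",
          "cross_cancer", "enrichment")


class PipelineError(RuntimeError):
    """Stage failure, annotated with the stage and cancer type."""


@dataclass
class CancerInputs:
    mutations: str
    expression: str
    expression_is_zscore: bool = True


@dataclass
class RunConfig:
    """Parameters of one screen run.

    ``k`` is the top-list size (400 by default; 200 is the usual
    sensitivity check), ``min_cancers`` the recurrence threshold,
    ``mutation_class`` one of all/missense/sense. ``gene_sets`` is an
    optional GMT whose ``pathway`` set (with ``complexes``, other GMT sets
    nested in the pathway) drives the complex chi-square stage.
    """

    cancers: dict[str, CancerInputs]
    outdir: str
    mutation_class: str = "all"
    k: int = 400
    min_cancers: int = 6
    min_samples: int = 20
    zscore_reference: str = "all"
    maf_dialect: str = "simple"
    gene_sets: str | None = None
    pathway: str | None = None
    complexes: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.min_cancers < 1:
            raise ValueError("min_cancers must be >= 1")
        if self.mutation_class not in ("all", "missense", "sense"):
            raise ValueError(f"unknown mutation_class {self.mutation_class!r}")
        if self.maf_dialect not in ("simple", "maf"):
            raise ValueError(f"unknown maf_dialect {self.maf_dialect!r}")
        if not self.cancers:
            raise ValueError("no cancer types configured")
        for name, ci in self.cancers.items():
            for p in (ci.mutations, ci.expression):
                if not Path(p).exists():
                    raise ValueError(f"{name}: input path does not exist: {p}")
        if self.gene_sets is not None and not Path(self.gene_sets).exists():
            raise ValueError(f"gene_sets path does not exist: {self.gene_sets}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cancers = {name: CancerInputs(**ci) for name, ci in raw.pop("cancers").items()}
        zscore = raw.pop("zscore", {})
        return cls(cancers=cancers,
                   zscore_reference=zscore.get("reference", "all"), **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def setup_logging(outdir: str | Path | None = None,
                  level: int = logging.INFO) -> None:
    """INFO logging to stderr plus, when an output directory is given, a
    run-local ``run.log``."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(outdir) / "run.log", mode="a"))
    logging.basicConfig(
        level=level, handlers=handlers, force=True,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s")


def run_screen(config: RunConfig) -> dict:
    """Execute the full screen and return the run manifest (also written to
    ``outdir/manifest.json``)."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dialect = SIMPLE_DIALECT if config.maf_dialect == "simple" else MAF_DIALECT
    manifest: dict = {
        "package": "mutcorr", "version": __version__, "seed": config.seed,
        "config": {
            "mutation_class": config.mutation_class, "k": config.k,
            "min_cancers": config.min_cancers,
            "min_samples": config.min_samples,
            "zscore_reference": config.zscore_reference,
            "maf_dialect": config.maf_dialect,
            "cancers": {n: vars(ci) for n, ci in config.cancers.items()},
            "gene_sets": config.gene_sets, "pathway": config.pathway,
            "complexes": config.complexes,
        },
        "stages": {}, "outputs": {},
    }

    def record(stage: str, **counts: int) -> None:
        manifest["stages"].setdefault(stage, {}).update(counts)

    loads_by_cancer: dict[str, pd.DataFrame] = {}
    expr_by_cancer = {}
    stage = cancer = ""
    try:
        for cancer, inputs in config.cancers.items():
            cdir = outdir / cancer
            cdir.mkdir(exist_ok=True)

            stage = "expression_zscore"
            matrix = read_matrix(inputs.expression)
            if inputs.expression_is_zscore:
                matrix.is_zscore = True
                matrix.reference = "precomputed (input flagged as z-scores)"
            else:
                ref = ("all" if config.zscore_reference == "all"
                       else config.zscore_reference)
                matrix = zscore_transform(matrix, ref)
            expr_by_cancer[cancer] = matrix
            record(stage, **{f"{cancer}_genes": int(matrix.values.shape[0]),
                             f"{cancer}_samples": int(matrix.values.shape[1])})

            stage = "mutation_load"
            records = read_maf_like(inputs.mutations, dialect)
            loads = compute_loads(records, cancer,
                                  roster=list(matrix.samples))
            write_loads(loads, cdir / "loads.tsv")
            loads_by_cancer[cancer] = loads
            record(stage, **{f"{cancer}_records": len(records),
                             f"{cancer}_samples": len(loads)})

        stage = "correlation_screen"
        lists: list[TopKLists] = []
        screened_genes: set[str] = set()
        for cancer in config.cancers:
            results = screen_cancer(expr_by_cancer[cancer],
                                    loads_by_cancer[cancer],
                                    load_class=config.mutation_class,
                                    min_samples=config.min_samples)
            write_results(results, outdir / cancer / "correlations.tsv")
            tk = top_k(results, config.k)
            with open(outdir / cancer / "top_k.json", "w") as fh:
                json.dump(tk.to_json_dict(), fh, indent=1, sort_keys=True)
            lists.append(tk)
            screened_genes.update(results["gene"])
            record(stage, **{f"{cancer}_genes_tested": len(results)})

        stage = "cross_cancer"
        cancer = ""
        xdir = outdir / "cross_cancer"
        xdir.mkdir(exist_ok=True)
        rec = recurrence(lists)
        rec.to_csv(xdir / "recurrence.tsv", sep="\t")
        for direction in ("positive", "negative"):
            genes = recurrent_genes(rec, direction, config.min_cancers)
            pd.Series(genes, name="gene").to_csv(
                xdir / f"recurrent_{direction}.tsv", sep="\t", index=False)
            record(stage, **{f"recurrent_{direction}": len(genes)})
        classification = classify_genes(sorted(screened_genes), rec)
        classification.to_csv(xdir / "classification.tsv", sep="\t")
        record(stage, genes_classified=len(classification))

        stage = "enrichment"
        edir = outdir / "enrichment"
        edir.mkdir(exist_ok=True)
        if config.gene_sets is not None:
            sets = read_gmt(config.gene_sets)
            background = sorted(screened_genes)
            for direction in ("positive", "negative"):
                genes = recurrent_genes(rec, direction, config.min_cancers)
                enr = hypergeom_enrich(genes, sets, background)
                enr.to_csv(edir / f"hypergeom_{direction}.tsv", sep="\t",
                           index=False)
                record(stage, **{f"hypergeom_{direction}_sets": len(enr)})
            if config.pathway is not None:
                if config.pathway not in sets:
                    raise ValueError(f"pathway set {config.pathway!r} not in "
                                     f"{config.gene_sets}")
                pathway = sets[config.pathway]
                labels = classify_genes(pathway, rec)["label"].to_dict()
                complexes = config.complexes or [s for s in sets
                                                 if s != config.pathway]
                tests = [complex_chi_square(sets[cx], pathway, labels,
                                            category=cat, complex_name=cx)
                         for cx in complexes for cat in CATEGORY_LABELS]
                table = complex_tests_table(tests)
                table.to_csv(edir / "complex_chi_square.tsv", sep="\t",
                             index=False, float_format="%.10g")
                record(stage, complex_tests=len(table))
        else:
            record(stage, skipped=1)
    except Exception as exc:
        where = f"stage {stage!r}" + (f", cancer type {cancer!r}" if cancer else "")
        raise PipelineError(f"{where}: {exc}") from exc

    for path in sorted(outdir.rglob("*.tsv")) + sorted(outdir.rglob("*.json")):
        if path.name == "manifest.json":
            continue
        manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    manifest["wall_time_s"] = round(time.time() - t0, 3)
    manifest["n_stages"] = len(manifest["stages"])
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("screen finished in %.1fs; %d outputs",
                manifest["wall_time_s"], len(manifest["outputs"]))
    return manifest
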
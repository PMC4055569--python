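"""End-to-end pipeline orchestration.

``run_pipeline`` chains the stages — predication filtering, network assembly,
expression normalization, GA weight training and (optionally) leave-one-out
evaluation — writing each stage's artifact plus a JSON manifest recording
inputs, parameters, seed and library versions so a run can be reproduced
exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import compare_models, loo_by_timepoint
from .expression import normalize_expression, read_expression
from .ga import GAConfig, topology_from_network, evolve_network
from .netbuild import build_network, restrict_to_genes
from .predications import (SymbolMap, read_predications, run_filter_pipeline)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All file paths and parameters of a pipeline run."""

    predications: str
    symbols: str
    expression: str
    outdir: str
    reference: str | None = None
    max_distance: int = 1
    min_docs: int = 2
    distance_filter: bool = True
    frequency_filter: bool = True
    per_gene_normalization: bool = True
    ga: GAConfig = field(default_factory=GAConfig)
    evaluate: bool = False
    baseline_k: int = 10

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ga = GAConfig(**raw.pop("ga", {}))
        return cls(ga=ga, **raw)


def write_weights(path: Union[str, Path], W: np.ndarray, topology) -> None:
    """Trained weights as TSV: target, regulator, weight, literature_sign."""
    rows = []
    hints = topology.sign_hint
    for i, target in enumerate(topology.genes):
        for j, regulator in enumerate(topology.genes):
            if topology.allowed[i, j]:
                rows.append({
                    "target": target, "regulator": regulator,
                    "weight": W[i, j],
                    "literature_sign":
                        int(hints[i, j]) if hints is not None else 0,
                })
    pd.DataFrame(rows, columns=["target", "regulator", "weight",
                                "literature_sign"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run filtering -> network -> weights (-> evaluation); return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    try:
        preds = read_predications(config.predications)
        symbol_map = SymbolMap.from_tsv(config.symbols)
        upreds, report = run_filter_pipeline(
            preds, symbol_map, max_distance=config.max_distance,
            min_docs=config.min_docs,
            distance_filter=config.distance_filter,
            frequency_filter=config.frequency_filter)
        report_path = outdir / "filter_report.tsv"
        report.write(report_path)
        filtered_path = outdir / "filtered_predications.tsv"
        pd.DataFrame([{
            "subject": u.subject_symbol, "predicate": u.predicate,
            "object": u.object_symbol, "doc_frequency": u.doc_frequency,
            "pmids": ",".join(sorted(u.pmids)),
        } for u in upreds]).to_csv(filtered_path, sep="\t", index=False)
        outputs["filter_report"] = str(report_path)
        outputs["filtered_predications"] = str(filtered_path)
    except Exception as exc:
        raise PipelineError("filter", exc) from exc

    try:
        net = build_network(upreds)
        net_path = outdir / "network.tsv"
        net.write_tsv(net_path)
        outputs["network"] = str(net_path)
    except Exception as exc:
        raise PipelineError("network", exc) from exc

    try:
        ds = read_expression(config.expression)
        ds = normalize_expression(ds, per_gene=config.per_gene_normalization)
        net = restrict_to_genes(net, ds.genes)
        topology = topology_from_network(net)
    except Exception as exc:
        raise PipelineError("expression", exc) from exc

    try:
        keep = [g for g in ds.genes if g in set(topology.genes)]
        ds_sub = _subset_dataset(ds, keep) if keep != ds.genes else ds
        W = evolve_network(ds_sub, topology, config.ga)
        weights_path = outdir / "weights.tsv"
        write_weights(weights_path, W, topology)
        outputs["weights"] = str(weights_path)
    except Exception as exc:
        raise PipelineError("infer", exc) from exc

    if config.evaluate:
        try:
            lit = loo_by_timepoint(ds_sub, topology, config.ga, "literature")
            base = loo_by_timepoint(ds_sub, topology, config.ga,
                                    "random_baseline", k=config.baseline_k)
            cmpres = compare_models(lit, base)
            eval_path = outdir / "evaluation.tsv"
            rows = []
            for rep in (lit, base):
                for t, r in zip(rep.held_out_times, rep.fold_rmse):
                    rows.append({"fold": t + 1, "model": rep.model, "rmse": r})
            pd.DataFrame(rows).to_csv(eval_path, sep="\t", index=False)
            summary_path = outdir / "evaluation_summary.json"
            summary_path.write_text(json.dumps({
                "mean_rmse": {"literature": lit.mean_rmse,
                              "random_baseline": base.mean_rmse},
                "overall_t": cmpres.overall.t,
                "overall_df": cmpres.overall.df,
                "overall_p": cmpres.overall.p,
            }, indent=2))
            outputs["evaluation"] = str(eval_path)
            outputs["evaluation_summary"] = str(summary_path)
        except Exception as exc:
            raise PipelineError("evaluate", exc) from exc

    manifest = {
        "litgrn_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "inputs": {"predications": config.predications,
                   "symbols": config.symbols,
                   "expression": config.expression,
                   "reference": config.reference},
        "parameters": {
            "max_distance": config.max_distance,
            "min_docs": config.min_docs,
            "distance_filter": config.distance_filter,
            "frequency_filter": config.frequency_filter,
            "per_gene_normalization": config.per_gene_normalization,
            "ga": dataclasses.asdict(config.ga),
        },
        "seed": config.ga.rng_seed,
        "outputs": outputs,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _subset_dataset(ds, genes):
    from .expression import ExpressionDataset
    idx = [ds.genes.index(g) for g in genes]
    return ExpressionDataset(genes=list(genes), values=ds.values[idx],
                             present=ds.present.copy())
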
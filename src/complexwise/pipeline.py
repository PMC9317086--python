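"""End-to-end workflow: weight -> detect -> classify -> evaluate -> enrich.

One config object drives the whole run; every stage draws its randomness
from the single global seed through a stage-salted fan-out, and the
written manifest (config + seed + package version) makes a run
reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from . import embedding as emb_mod
from . import evaluation as eval_mod
from . import io as cwio
from . import svcc as svcc_mod
from . import weighting
from .core import ComplexSet, ValidationError, fanout_seed

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    network: str = ""
    gaf: Optional[str] = None
    reference: str = ""
    out_dir: str = "complexwise-out"
    min_weight: float = 0.0
    log_base: float = 10.0
    svcc: svcc_mod.SvccConfig = field(default_factory=svcc_mod.SvccConfig)
    walks: emb_mod.WalkConfig = field(default_factory=emb_mod.WalkConfig)
    cv: eval_mod.CvConfig = field(default_factory=eval_mod.CvConfig)
    rf_estimators: int = 1000
    threshold: float = 0.5
    with_baseline: bool = False
    enrich_bonferroni: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        nested = {
            "svcc": svcc_mod.SvccConfig,
            "walks": emb_mod.WalkConfig,
            "cv": eval_mod.CvConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested:
                kwargs[key] = nested[key](**(value or {}))
            else:
                kwargs[key] = value
        kwargs.update(overrides)
        return cls(**kwargs)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full five-fold protocol and write all artifacts.

    Writes weighted.tsv, final.txt (predictions with probabilities),
    eval.tsv, enrichment.tsv and manifest.json under ``cfg.out_dir`` and
    returns a summary dict.  A missing GAF degrades gracefully to
    topology-only (HOCN) edge weights with a logged warning.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = cwio.read_edge_list(cfg.network)
    ann = None
    if cfg.gaf:
        ann = cwio.read_gaf(cfg.gaf)
    else:
        logger.warning(
            "no GAF given: edge weights fall back to topology only (HOCN)"
        )
    reference = cwio.read_complexes(cfg.reference, restrict_to=net)
    if len(reference) == 0:
        raise ValidationError("no usable reference complexes after filtering")

    wnet = weighting.weight_network(
        net, ann, min_weight=cfg.min_weight, log_base=cfg.log_base
    )
    cwio.write_edge_list(wnet, out / "weighted.tsv")

    walk_cfg = dataclasses.replace(
        cfg.walks, seed=fanout_seed(cfg.seed, "walks")
    )
    result = eval_mod.cross_validate(
        wnet,
        net,
        wnet,
        reference,
        seed=cfg.seed,
        cfg=cfg.cv,
        svcc_cfg=cfg.svcc,
        walk_cfg=walk_cfg,
        with_baseline=cfg.with_baseline,
        rf_estimators=cfg.rf_estimators,
        threshold=cfg.threshold,
    )
    cwio.write_complexes(result.complexes, out / "final.txt")

    with open(out / "eval.tsv", "w", encoding="utf-8") as fh:
        items = result.evaluation.as_dict()
        fh.write("\t".join(items) + "\n")
        fh.write("\t".join(_fmt(v) for v in items.values()) + "\n")

    universe = net.number_of_nodes()
    with open(out / "enrichment.tsv", "w", encoding="utf-8") as fh:
        fh.write("complex\taspect\tterm\tp_value\n")
        if ann is not None:
            for cx in result.complexes:
                enr = eval_mod.best_enrichment(
                    cx, ann, universe, bonferroni=cfg.enrich_bonferroni
                )
                for aspect, (term, p) in sorted(enr.best.items()):
                    fh.write(
                        f"{' '.join(cx.canonical)}\t{aspect}\t"
                        f"{term or '-'}\t{p:.6g}\n"
                    )

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "network_summary": cwio.network_summary(net),
        "evaluation": result.evaluation.as_dict(),
    }
    if result.svcc_only_evaluation is not None:
        manifest["svcc_only_evaluation"] = result.svcc_only_evaluation.as_dict()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _fmt(v) -> str:
    return f"{v:.4f}" if isinstance(v, float) else str(v)


def _config_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)
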
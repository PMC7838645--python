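"""End-to-end orchestration of the signature-detection workflow.

For each requested data layer (methylation, expression, combined) the
pipeline runs Monte Carlo feature selection to rank all features, sweeps
nested top-k prefixes with each configured classifier under
cross-validation, records the optimum (k, ACC, MCC) per algorithm, and —
for the rule learner — re-induces an ordered decision list on the
optimum feature subset and serialises it in the rule grammar.  Every
stage is seeded from the single pipeline seed and all outputs (ranking
TSV, curve TSVs + JSON sidecars, optimum summary, rule files, manifest)
land in the output directory.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifiers import ClassifierSpec, cross_validate
from .datasets import LAYERS, LabeledDataset, read_dataset
from .ifs import IFSCurve, default_k_grid, ifs_sweep, write_curve
from .mcfs import McfsParams, run_mcfs, write_ranking
from .rules import induce_rules, write_rules
from .synthetic import SyntheticConfig, generate

log = logging.getLogger("asmsig.pipeline")

DEFAULT_CLASSIFIERS = ("rf", "svm", "knn", "ripper")


@dataclass
class PipelineConfig:
    """Everything one run needs; serialisable to/from YAML."""

    outdir: str | Path = "asmsig_out"
    layers: Sequence[str] = ("expression",)
    #: either a synthetic config ...
    synthetic: SyntheticConfig | None = None
    #: ... or a mapping layer -> dataset directory (matrix/labels/meta files)
    inputs: dict[str, str] | None = None
    mcfs: McfsParams = field(default_factory=McfsParams)
    k_grid: Sequence[int] | None = None
    classifiers: Sequence[ClassifierSpec] = field(
        default_factory=lambda: [ClassifierSpec(a) for a in DEFAULT_CLASSIFIERS]
    )
    folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not self.layers:
            raise ValueError("at least one layer must be requested")
        bad = [l for l in self.layers if l not in LAYERS]
        if bad:
            raise ValueError(f"unknown layer {bad[0]!r}; expected one of {LAYERS}")
        if not self.classifiers:
            raise ValueError("at least one classifier spec is required")
        if self.synthetic is None and not self.inputs:
            raise ValueError("either a synthetic config or input paths are required")
        if self.inputs is not None:
            missing = [l for l in self.layers if l not in self.inputs]
            if self.synthetic is None and missing:
                raise ValueError(f"no input path for layer {missing[0]!r}")

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        cfg = cls(
            outdir=d.get("outdir", "asmsig_out"),
            layers=tuple(d.get("layers", ("expression",))),
            synthetic=(
                SyntheticConfig(**d["synthetic"]) if "synthetic" in d else None
            ),
            inputs=d.get("inputs"),
            mcfs=McfsParams(**d.get("mcfs", {})),
            k_grid=d.get("k_grid"),
            classifiers=[
                ClassifierSpec.from_dict(c)
                for c in d.get(
                    "classifiers",
                    [{"algorithm": a} for a in DEFAULT_CLASSIFIERS],
                )
            ],
            folds=int(d.get("folds", 10)),
            seed=int(d.get("seed", 0)),
        )
        return cfg

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "layers": list(self.layers),
            "synthetic": vars(self.synthetic).copy() if self.synthetic else None,
            "inputs": self.inputs,
            "mcfs": vars(self.mcfs).copy(),
            "k_grid": list(self.k_grid) if self.k_grid is not None else None,
            "classifiers": [c.to_dict() for c in self.classifiers],
            "folds": self.folds,
            "seed": self.seed,
        }


def _derived_seed(base: int, *tags: str) -> int:
    """Stable per-stage seed below 2**31 (process-independent)."""
    h = np.random.SeedSequence(
        [base] + [zlib.crc32(t.encode()) for t in tags]
    )
    return int(h.generate_state(1)[0] % (2**31))


def _load_layers(cfg: PipelineConfig) -> dict[str, LabeledDataset]:
    out: dict[str, LabeledDataset] = {}
    if cfg.inputs:
        for layer in cfg.layers:
            if layer in cfg.inputs:
                out[layer] = read_dataset(cfg.inputs[layer])
    missing = [l for l in cfg.layers if l not in out]
    if missing:
        if cfg.synthetic is None:
            raise ValueError(f"no data source for layer {missing[0]!r}")
        meth, expr, combined = generate(cfg.synthetic)
        gen = {"methylation": meth, "expression": expr, "combined": combined}
        for layer in missing:
            out[layer] = gen[layer]
    return out


def run_pipeline(cfg: PipelineConfig) -> pd.DataFrame:
    """Run the full workflow; returns the optimum summary table.

    The summary has one row per (layer, algorithm): the optimum subset
    size with its ACC and MCC — the shape of a headline results table.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    datasets = _load_layers(cfg)

    summary_rows = []
    for layer in cfg.layers:
        ds = datasets[layer]
        log.info("layer %s: %d samples x %d features", layer, ds.n_samples, ds.n_features)
        mcfs_params = McfsParams(
            m=cfg.mcfs.m, s=cfg.mcfs.s, t=cfg.mcfs.t,
            train_fraction=cfg.mcfs.train_fraction,
            u=cfg.mcfs.u, v=cfg.mcfs.v,
            seed=_derived_seed(cfg.seed, "mcfs", layer),
        )
        t0 = time.time()
        ranking = run_mcfs(ds, mcfs_params)
        log.info("layer %s: MCFS done in %.1fs", layer, time.time() - t0)
        write_ranking(ranking, outdir / f"ranking_{layer}.tsv")

        k_grid = (
            list(cfg.k_grid)
            if cfg.k_grid is not None
            else default_k_grid(ds.n_features)
        )
        k_grid = [k for k in k_grid if k <= ds.n_features]
        for spec in cfg.classifiers:
            t0 = time.time()
            curve = ifs_sweep(
                ds, ranking, spec, k_grid=k_grid, folds=cfg.folds,
                seed=_derived_seed(cfg.seed, "ifs", layer),
            )
            log.info(
                "layer %s: IFS with %s done in %.1fs (optimum k=%d, MCC=%.3f)",
                layer, spec.algorithm, time.time() - t0,
                curve.optimum_k, curve.optimum_record.mcc,
            )
            write_curve(curve, outdir / f"curve_{layer}_{spec.algorithm}.tsv")
            summary_rows.append(
                {
                    "layer": layer,
                    "algorithm": spec.algorithm,
                    "k": curve.optimum_k,
                    "acc": curve.optimum_record.acc,
                    "mcc": curve.optimum_record.mcc,
                }
            )
            if spec.algorithm == "ripper":
                sub = ds.subset(ranking.top(curve.optimum_k))
                rl = induce_rules(sub, seed=spec.seed)
                write_rules(rl, outdir / f"rules_{layer}.rules")

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "optimum_summary.tsv", sep="\t", index=False,
                   float_format="%.10g")
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "version": __version__,
        "runtime_s": round(time.time() - t_start, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return summary
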
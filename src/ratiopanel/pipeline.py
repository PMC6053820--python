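"""End-to-end orchestration: config, pipeline run, and report writing.

A run executes, per contrast: abundance filter -> pair enumeration ->
dCT features -> differential screen -> ROC marker selection -> SVM-RFE ->
panel assembly with stratified CV -> application to the validation cohort
-> tabular reports. Inputs come either from files or from the bundled
synthetic-study generator; every stage's parameters and the seed are
recorded in a provenance file, and report files are byte-deterministic
for a fixed config + seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError
from .io import (
    CountMatrix,
    CtMatrix,
    read_annotations,
    read_count_matrix,
    read_ct_matrix,
    read_metadata,
)
from .model import CONTRASTS, RatioPanelModel, resolve_contrast
from .simulate import SimulationConfig, simulate_study
from .svmpanel import save_panel

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = list(CONTRASTS)


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML."""

    # file inputs (ignored when ``simulate`` is set)
    counts: str | None = None
    ct_training: str | None = None
    ct_validation: str | None = None
    ct_replicates: int = 1
    metadata: str | None = None
    annotations: str | None = None
    # or: simulate a study in-process
    simulate: SimulationConfig | None = None

    contrasts: list = field(default_factory=lambda: list(DEFAULT_CONTRASTS))
    min_copies: int = 50
    fc_min: float = 2.0
    q_max: float = 0.05
    sen_min: float = 0.80
    spe_min: float = 0.80
    auc_min: float = 0.800
    correction: str = "benjamini_hochberg"
    t_variant: str = "student"
    panel_size: int | str = "auto"
    max_panel_size: int = 10
    max_rfe_features: int = 50
    cv_folds: int = 10
    svm_C: float = 1.0
    seed: int = 0
    write_full_stats: bool = False

    def __post_init__(self):
        if not self.contrasts:
            raise ConfigError("at least one contrast is required")
        for c in self.contrasts:
            resolve_contrast(c)
        if self.simulate is None and (self.ct_training is None or self.metadata is None):
            raise ConfigError(
                "either 'simulate' or file inputs (ct_training, metadata) are required"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if doc.get("simulate") is not None:
            sim = doc["simulate"]
            doc["simulate"] = (
                SimulationConfig.from_dict(sim) if isinstance(sim, dict) else sim
            )
        return cls(**doc)


def _slug(name: str) -> str:
    return (
        name.lower().replace("+", "_").replace(".", "").replace(" ", "_").replace("__", "_")
    )


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = config.simulate.with_seed(
            config.simulate.seed if config.simulate.seed else config.seed
        )
        study = simulate_study(sim)
        return {
            "counts": study.counts,
            "ct_training": study.training.ct,
            "ct_validation": study.validation.ct,
            "metadata": study.metadata,
            "annotations": study.annotations,
            "truth": study.truth,
        }
    out = {
        "counts": read_count_matrix(config.counts) if config.counts else None,
        "ct_training": read_ct_matrix(config.ct_training, config.ct_replicates),
        "ct_validation": (
            read_ct_matrix(config.ct_validation, config.ct_replicates)
            if config.ct_validation
            else None
        ),
        "metadata": read_metadata(config.metadata),
        "annotations": read_annotations(config.annotations)
        if config.annotations
        else None,
        "truth": None,
    }
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every contrast end to end and write reports under ``out_dir``.

    Returns ``{"results": {contrast: RatioPanelResults},
    "validation": {contrast: ConfusionMetrics}, "inputs": ...}``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = _load_inputs(config)
    meta = inputs["metadata"]
    train_meta = meta.loc[meta["cohort"] == "training"]
    val_meta = meta.loc[meta["cohort"] == "validation"]

    results, validation = {}, {}
    for cname in config.contrasts:
        contrast = resolve_contrast(cname)
        logger.info("contrast %s: assembling features", contrast.name)
        model = RatioPanelModel.from_matrices(
            inputs["ct_training"],
            train_meta,
            contrast=contrast,
            annotations=inputs["annotations"],
            counts=inputs["counts"],
            min_copies=config.min_copies,
        )
        logger.info(
            "contrast %s: %d pairs, fitting", contrast.name, model.features.shape[1]
        )
        res = model.fit(
            fc_min=config.fc_min,
            q_max=config.q_max,
            sen_min=config.sen_min,
            spe_min=config.spe_min,
            auc_min=config.auc_min,
            correction=config.correction,
            t_variant=config.t_variant,
            panel_size=config.panel_size,
            max_panel_size=config.max_panel_size,
            max_rfe_features=config.max_rfe_features,
            k=config.cv_folds,
            C=config.svm_C,
            seed=config.seed,
        )
        results[contrast.name] = res
        if inputs["ct_validation"] is not None and res.panel is not None and len(val_meta):
            validation[contrast.name] = res.evaluate(inputs["ct_validation"], val_meta)

    report_tables(results, validation, out, config)
    return {"results": results, "validation": validation, "inputs": inputs,
            "report_dir": out}


_PAIR_COLS = [
    "pair_id", "p_value", "p_adjusted", "ratio", "fold_change",
    "auc", "sensitivity", "specificity", "threshold",
]


def _metrics_row(panel_name, contrast, stage, n_pos, n_neg, m) -> dict:
    return {
        "panel": panel_name, "contrast": contrast, "stage": stage,
        "sample_size": f"{n_pos} vs. {n_neg}",
        "sen": m.sen, "spe": m.spe,
        "ppv": m.ppv if m.ppv is not None else "undefined",
        "npv": m.npv if m.npv is not None else "undefined",
        "fpr": m.fpr, "fnr": m.fnr, "auc": m.auc,
        "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
    }


def report_tables(results: dict, validation: dict, out_dir, config: PipelineConfig) -> list[str]:
    """Write candidate/marker tables, panel files, metrics, and a summary.

    Data files carry full float precision; the human-readable summary uses
    2-3 decimals. Regenerating from identical inputs yields byte-identical
    files (no timestamps inside reports).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    metric_rows = []
    summary_parts = []
    for cname, res in results.items():
        slug = _slug(cname)
        cand = res.candidates.reindex(columns=_PAIR_COLS)
        cand.to_csv(out / f"candidates_{slug}.tsv", sep="\t", index=False)
        written.append(f"candidates_{slug}.tsv")
        res.markers.reindex(columns=_PAIR_COLS).to_csv(
            out / f"markers_{slug}.tsv", sep="\t", index=False
        )
        written.append(f"markers_{slug}.tsv")
        if config.write_full_stats:
            res.pair_stats.to_csv(out / f"pair_stats_{slug}.tsv", sep="\t", index=False)
            written.append(f"pair_stats_{slug}.tsv")
        if res.panel is not None:
            save_panel(res.panel, out / f"panel_{slug}.yaml")
            written.append(f"panel_{slug}.yaml")
            n_pos = int(res.model.labels.sum())
            n_neg = int((~res.model.labels).sum())
            metric_rows.append(
                _metrics_row(f"panel_{slug}", cname, "training_cv",
                             n_pos, n_neg, res.panel.cv_metrics)
            )
            if cname in validation:
                vm = validation[cname]
                metric_rows.append(
                    _metrics_row(f"panel_{slug}", cname, "validation",
                                 vm.tp + vm.fn, vm.tn + vm.fp, vm)
                )
        summary_parts.append(res.summary())
        if cname in validation:
            vm = validation[cname]
            summary_parts.append(
                f"Validation ({cname}): SEN {vm.sen:.3f}  SPE {vm.spe:.3f}  "
                f"AUC {vm.auc:.3f}"
            )
        summary_parts.append("")
    pd.DataFrame(metric_rows).to_csv(out / "panel_metrics.tsv", sep="\t", index=False)
    written.append("panel_metrics.tsv")
    (out / "summary.txt").write_text("\n".join(summary_parts))
    written.append("summary.txt")

    params = {k: v for k, v in asdict(config).items() if k != "simulate"}
    params["contrasts"] = [resolve_contrast(c).name for c in config.contrasts]
    prov = {
        "ratiopanel_version": __version__,
        "seed": config.seed,
        "parameters": params,
        "simulated": config.simulate is not None,
    }
    if config.simulate is not None:
        sim = asdict(config.simulate)
        sim["planted_pairs"] = [
            {**p, "affected_groups": list(p["affected_groups"])}
            for p in sim["planted_pairs"]
        ]
        prov["simulation"] = sim
    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)
    written.append("provenance.yaml")
    return written
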
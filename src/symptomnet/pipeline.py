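"""End-to-end analysis: descriptives -> pooled network + shared layout ->
stratified networks -> centrality -> stability, with a JSON report index.

Stability is computed on the pooled (all-subjects) network by default —
stratum samples are usually too small for a meaningful case-drop curve —
and per-stratum stability can be switched on in the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .data_model import (
    DEFAULT_LEVELS,
    SymptomCodebook,
    read_dataset,
    stratify,
)
from .descriptives import symptom_frequencies
from .ising_elasso import ElassoConfig, fit_ising_elasso
from .network_metrics import (
    centrality_table,
    plot_centrality_profiles,
    plot_network,
    shared_layout,
)
from .stability import DEFAULT_DROP_PROPORTIONS, case_drop_bootstrap
from .synthetic_data import emulate_study, write_truth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Fully serializable configuration of one analysis run."""

    input_csv: str | None = None
    synthetic_seed: int | None = None
    codebook_path: str | None = None
    strata_variables: tuple[str, ...] = ("gender", "age_group")
    elasso: ElassoConfig = field(default_factory=ElassoConfig)
    stability_B: int = 1000
    stability_drop_proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS
    stability_enabled: bool = True
    stability_per_stratum: bool = False
    layout_seed: int = 0
    seed: int = 0
    out_dir: str = "symptomnet_output"
    plots: bool = True

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic_seed is None):
            raise ValueError(
                "exactly one of input_csv and synthetic_seed must be set"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        elasso = ElassoConfig(**raw.pop("elasso", {}))
        for key in ("strata_variables", "stability_drop_proportions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(elasso=elasso, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["elasso"] = dataclasses.asdict(self.elasso)
        return d


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Execute the full workflow; returns (and writes) the report index."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "outputs": {},
        "log": [],
        "complete": False,
    }

    def stage(name: str):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                report["log"].append({"stage": name, "error": str(exc)})
                _write_report(report, out)
                raise StageError(name, exc) from exc
            report["log"].append(
                {"stage": name, "seconds": round(time.perf_counter() - t0, 3)}
            )
            return result

        return deco

    codebook = (
        SymptomCodebook.from_file(cfg.codebook_path)
        if cfg.codebook_path
        else SymptomCodebook.default()
    )

    @stage("load_data")
    def ds():
        if cfg.synthetic_seed is not None:
            dataset, truth = emulate_study(
                cfg.synthetic_seed, codebook, return_truth=True
            )
            dataset.to_csv(out / "dataset.csv")
            write_truth(truth, out / "ground_truth.json")
            report["outputs"]["dataset"] = "dataset.csv"
            report["outputs"]["ground_truth"] = "ground_truth.json"
            return dataset
        return read_dataset(cfg.input_csv, codebook)

    logger.info("loaded dataset: n=%d, p=%d", ds.n, ds.p)

    strata = {}
    for var in cfg.strata_variables:
        @stage(f"frequencies[{var}]")
        def freq(var=var):
            parts = stratify(ds, var)
            strata[var] = parts
            table = symptom_frequencies(ds, parts)
            fname = f"frequencies_{var}.csv"
            table.to_csv(out / fname)
            report["outputs"][f"frequencies_{var}"] = fname
            return table

    @stage("pooled_network")
    def pooled():
        net = fit_ising_elasso(ds, cfg.elasso)
        _export_network(net, out, "pooled", report)
        return net

    @stage("layout")
    def layout():
        lay = shared_layout(pooled, seed=cfg.layout_seed)
        lay.to_csv(out / "layout.csv")
        report["outputs"]["layout"] = "layout.csv"
        return lay

    nets = {"pooled": pooled}
    tables = {}

    @stage("pooled_centrality")
    def _():
        tables["pooled"] = _export_centrality(pooled, out, "pooled", report)

    for var, parts in strata.items():
        for spec, sub in parts:
            name = spec.level

            @stage(f"network[{name}]")
            def _(sub=sub, name=name):
                net = fit_ising_elasso(sub, cfg.elasso)
                nets[name] = net
                _export_network(net, out, name, report)
                tables[name] = _export_centrality(net, out, name, report)

    if cfg.plots:
        @stage("plots")
        def _():
            for name, net in nets.items():
                fname = f"network_{name}.svg"
                plot_network(net, layout, out / fname, title=name)
                report["outputs"][f"plot_{name}"] = fname
            for var in cfg.strata_variables:
                group = {
                    spec.level: tables[spec.level] for spec, _ in strata[var]
                }
                fname = f"centrality_{var}.svg"
                plot_centrality_profiles(group, out / fname)
                report["outputs"][f"plot_centrality_{var}"] = fname

    if cfg.stability_enabled:
        targets = {"pooled": ds}
        if cfg.stability_per_stratum:
            for var, parts in strata.items():
                targets.update({spec.level: sub for spec, sub in parts})
        for name, data in targets.items():
            @stage(f"stability[{name}]")
            def _(data=data, name=name):
                res = case_drop_bootstrap(
                    data,
                    cfg.elasso,
                    drop_proportions=cfg.stability_drop_proportions,
                    B=cfg.stability_B,
                    seed=cfg.seed,
                )
                res.to_long_frame().to_csv(
                    out / f"stability_{name}.csv", index=False
                )
                res.to_json(out / f"stability_{name}.json")
                report["outputs"][f"stability_{name}"] = f"stability_{name}.json"
                report["outputs"][f"stability_{name}_long"] = f"stability_{name}.csv"

    report["complete"] = True
    _write_report(report, out)
    return report


def _export_network(net, out: Path, name: str, report: dict) -> None:
    net.adjacency_frame().to_csv(out / f"network_{name}_adjacency.csv",
                                 index_label="symptom")
    net.edge_list().to_csv(out / f"network_{name}_edges.csv", index=False)
    net.thresholds_frame().to_csv(out / f"network_{name}_thresholds.csv",
                                  index=False)
    net.to_graphml(out / f"network_{name}.graphml")
    for kind in ("adjacency", "edges", "thresholds"):
        report["outputs"][f"network_{name}_{kind}"] = f"network_{name}_{kind}.csv"
    report["outputs"][f"network_{name}_graphml"] = f"network_{name}.graphml"


def _export_centrality(net, out: Path, name: str, report: dict):
    table = centrality_table(net)
    table.to_csv(out / f"centrality_{name}.csv")
    table.standardized_long().to_csv(out / f"centrality_{name}_z.csv",
                                     index=False)
    report["outputs"][f"centrality_{name}"] = f"centrality_{name}.csv"
    report["outputs"][f"centrality_{name}_z"] = f"centrality_{name}_z.csv"
    return table


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2))
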
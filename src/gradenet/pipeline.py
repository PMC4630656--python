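"""End-to-end pipeline: build -> topology -> motifs -> hierarchy -> ffl ->
survival screen, per grade, with a run manifest.

The pipeline consumes file paths (a prior edge list, per-dataset per-grade
expression TSVs, per-dataset survival TSVs for the final grade) or, for
synthetic studies, an in-memory :class:`~gradenet.synth.SimulationBundle`.
All per-stage outputs are TSV/JSON under one output directory; the manifest
records parameters and seeds so a run can be reproduced bit-identically
(modulo timestamps).
"""
from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ffl as ffl_mod
from . import hierarchy as hier_mod
from . import io as io_mod
from . import motifs as motifs_mod
from . import netbuild, topology
from . import survival as surv_mod
from .errors import ConfigurationError, UndefinedProfileError
from .network import DirectedNetwork

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for one pipeline run."""

    prior: str
    #: {dataset: {grade: expression TSV path}}
    expression: dict[str, dict[str, str]]
    #: {dataset: survival TSV path} for the final grade (screen stage)
    survival: dict[str, str] = field(default_factory=dict)
    out_dir: str = "results/pipeline"
    grades: list[str] = field(default_factory=list)  # inferred if empty
    r_threshold: float = 0.5
    p_threshold: float = 0.01
    min_datasets: int = 2
    require_sign_consistency: bool = True
    correlation_method: str = "spearman"
    hub_fraction: float = 0.10
    hierarchy_upper: float = 1.0 / 3.0
    hierarchy_lower: float = -1.0 / 3.0
    n_random: int = 1000
    swaps_per_edge: int = 100
    preserve_mutual: bool = True
    induced_ffls: bool = True
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.prior).exists():
            raise ConfigurationError(f"prior file not found: {self.prior}")
        for dataset, by_grade in self.expression.items():
            for grade, p in by_grade.items():
                if not Path(p).exists():
                    raise ConfigurationError(
                        f"expression file not found ({dataset}, {grade}): {p}")
        for dataset, p in self.survival.items():
            if not Path(p).exists():
                raise ConfigurationError(
                    f"survival file not found ({dataset}): {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write per-stage outputs plus a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    prior = io_mod.read_edge_list(config.prior)
    grades = config.grades or sorted({g for by_grade in config.expression.values()
                                      for g in by_grade})

    # build
    nets: dict[str, DirectedNetwork] = {}
    summaries = {}
    for grade in grades:
        expr_by_dataset = {
            ds: io_mod.read_expression(by_grade[grade])
            for ds, by_grade in config.expression.items() if grade in by_grade}
        net, _ = netbuild.build_grade_network(
            prior, expr_by_dataset, grade=grade,
            r_threshold=config.r_threshold, p_threshold=config.p_threshold,
            min_datasets=config.min_datasets,
            require_sign_consistency=config.require_sign_consistency,
            method=config.correlation_method)
        nets[grade] = net
        io_mod.write_edge_list(net, out / f"net_grade{grade}.tsv")
        summaries[grade] = netbuild.network_summary(net, prior)
    report["stages"]["build"] = summaries

    # topology
    topo = {}
    for grade, net in nets.items():
        if net.n_edges == 0:
            topo[grade] = {"empty": True}
            continue
        frac_tgt, frac_reg = topology.multiplicity_fractions(net)
        size, frac = topology.largest_weak_component(net)
        topo[grade] = {
            "hubs": sorted(topology.hubs(net, config.hub_fraction)),
            "multi_target_fraction": frac_tgt,
            "multi_regulator_fraction": frac_reg,
            "largest_component_size": size,
            "largest_component_fraction": frac,
        }
        topology.degree_frame(net).to_csv(
            out / f"degrees_grade{grade}.tsv", sep="\t", index=False)
    if len(nets) >= 2:
        overlap = topology.edge_overlap(list(nets.values()))
        topo["edge_overlap"] = {k: overlap[k] for k in
                                ("union_edges", "shared_fraction",
                                 "grade_specific_fraction")}
    report["stages"]["topology"] = topo

    # motifs
    motif_report = {}
    for grade, net in nets.items():
        if net.n_edges < 2:
            motif_report[grade] = {"empty": True}
            continue
        profile = motifs_mod.motif_zscores(
            net, n_random=config.n_random, seed=config.seed,
            swaps_per_edge=config.swaps_per_edge,
            preserve_mutual=config.preserve_mutual)
        motif_report[grade] = profile.to_dict()
        io_mod.write_json(profile.to_dict(), out / f"motifs_grade{grade}.json")
    report["stages"]["motifs"] = motif_report

    # hierarchy
    assignments = {g: hier_mod.classify_levels(net, config.hierarchy_upper,
                                               config.hierarchy_lower)
                   for g, net in nets.items() if net.n_edges}
    hier_report = {g: hier_mod.level_proportions(a)
                   for g, a in assignments.items() if a}
    for g, a in assignments.items():
        hier_mod.assignment_frame(a).to_csv(
            out / f"hierarchy_grade{g}.tsv", sep="\t", index=False)
    report["stages"]["hierarchy"] = hier_report

    # ffl
    ffls_by_grade = {g: ffl_mod.find_ffls(net, induced=config.induced_ffls)
                     for g, net in nets.items()}
    ffl_report = {g: {"n_ffls": len(f)} for g, f in ffls_by_grade.items()}
    for g, f in ffls_by_grade.items():
        io_mod.write_ffl_list(f, out / f"ffls_grade{g}.tsv")
        freqs = ffl_mod.position_frequencies(f, grade=g)
        ffl_mod.position_frequency_frame(freqs).to_csv(
            out / f"ffl_positions_grade{g}.tsv", sep="\t", index=False)
    report["stages"]["ffl"] = ffl_report

    # screen (final grade)
    if config.survival:
        last = grades[-1]
        candidates = ffls_by_grade[last]
        screen_report = {}
        for dataset, surv_path in sorted(config.survival.items()):
            expr = io_mod.read_expression(config.expression[dataset][last])
            surv = io_mod.read_survival(surv_path)
            results = surv_mod.screen_ffls(candidates, expr, surv,
                                           seed=config.seed, alpha=config.alpha)
            screen_report[dataset] = [{
                "ffl": list(r.ffl.tfs),
                "betas": list(r.model.betas),
                "threshold": r.model.threshold,
                "cox_pvalues": list(r.model.cox_pvalues or ()),
                "p_train": r.p_train,
                "p_test": r.p_test,
                "retained": r.retained,
            } for r in results]
        report["stages"]["screen"] = screen_report
        io_mod.write_json(screen_report, out / "prognostic_ffls.json")

    manifest = {
        "parameters": dataclasses.asdict(config),
        "grades": grades,
        "timestamp": datetime.datetime.now().isoformat(),
    }
    io_mod.write_json(manifest, out / "manifest.json")
    io_mod.write_json(report, out / "report.json")
    return report
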
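"""End-to-end orchestration: filter, eligibility, node-splitting, verdicts.

``analyze_network`` runs the full chain for one dataset — event-risk
filter, eligibility check, node-splitting for every split node, the KLD
index and both classification frameworks — and returns a serialisable
report.  ``summarize_prevalence`` tabulates split nodes and networks over
the {acceptably_low, material} x {conclusive, inconclusive} cells, and
``export_plot_data`` writes the tidy tables behind the standard diagnostic
plots (posterior spread by node size, index vs IF, directed-divergence
difference vs index, index vs tau).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .data import (
    EligibilityReport,
    EligibilityRules,
    FilterReport,
    NMADataset,
    check_eligibility,
    filter_event_risk,
    write_results_table,
)
from .kld import (
    NetworkVerdict,
    NodeVerdict,
    classify_network,
    classify_node,
    heterogeneity_band,
    low_inconsistency_threshold,
)
from .model import MCMCSettings, NodeSplitResult, PriorSpec, run_all_nodes

logger = logging.getLogger("nmasplit")

__all__ = [
    "PipelineConfig",
    "NetworkReport",
    "PrevalenceSummary",
    "analyze_network",
    "summarize_prevalence",
    "export_plot_data",
    "network_seed",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one analysis run needs; loadable from YAML/JSON."""

    risk_lo: float = 0.15
    risk_hi: float = 0.85
    eligibility: EligibilityRules = field(default_factory=EligibilityRules)
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    threshold: float | None = None  # None -> low_inconsistency_threshold()
    rhat_method: str = "classic"

    @property
    def threshold_value(self) -> float:
        return (
            low_inconsistency_threshold() if self.threshold is None else self.threshold
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("risk_lo", "risk_hi", "threshold", "rhat_method"):
            if key in d:
                kwargs[key] = d[key]
        if "eligibility" in d:
            kwargs["eligibility"] = EligibilityRules(**d["eligibility"])
        if "prior" in d:
            p = dict(d["prior"])
            if "tau2_params" in p:
                p["tau2_params"] = tuple(p["tau2_params"])
            kwargs["prior"] = PriorSpec(**p)
        if "mcmc" in d:
            kwargs["mcmc"] = MCMCSettings(**d["mcmc"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass(frozen=True)
class NetworkReport:
    """Full audit trail of one network analysis."""

    name: str
    filter_report: FilterReport
    eligibility: EligibilityReport | None
    results: tuple[NodeSplitResult, ...]
    node_verdicts: tuple[NodeVerdict, ...]
    network_verdict: NetworkVerdict | None
    threshold: float
    converged: bool
    reason: str | None = None  # why no model was fitted, if applicable

    @property
    def analyzed(self) -> bool:
        return len(self.results) > 0

    @property
    def max_rhat(self) -> float | None:
        if not self.results:
            return None
        return max(r.max_rhat for r in self.results)

    def to_json(self) -> str:
        payload: dict = {
            "name": self.name,
            "filter": json.loads(self.filter_report.to_json()),
            "eligibility": (
                json.loads(self.eligibility.to_json()) if self.eligibility else None
            ),
            "threshold": self.threshold,
            "converged": self.converged,
            "max_rhat": self.max_rhat,
            "reason": self.reason,
            "network_verdict": (
                {
                    "index_based": self.network_verdict.index_based,
                    "cri_based": self.network_verdict.cri_based,
                }
                if self.network_verdict
                else None
            ),
            "split_nodes": [
                {
                    "comparison": r.node.label,
                    "n_direct_studies": r.node.n_direct_studies,
                    "single_study": r.node.single_study,
                    "if_mean": r.inconsistency_factor.mean,
                    "if_q025": r.inconsistency_factor.q025,
                    "if_q975": r.inconsistency_factor.q975,
                    "index": r.kld.index,
                    "d_di": r.kld.d_di,
                    "d_id": r.kld.d_id,
                    "tau_median": r.tau.median,
                    "tau_band": heterogeneity_band(r.tau.median),
                    "extent": v.extent.value,
                    "conclusiveness": v.conclusiveness.value,
                    "max_rhat": r.max_rhat,
                }
                for r, v in zip(self.results, self.node_verdicts)
            ],
        }
        return json.dumps(payload, indent=2)


def network_seed(master_seed: int, name: str) -> int:
    """Deterministic per-network seed: hash of the network id and master seed.

    Kept below 2**31 so it is portable as an RNG seed anywhere.
    """
    return (zlib.crc32(name.encode()) ^ (master_seed * 2654435761)) % (2**31)


def analyze_network(
    ds: NMADataset,
    config: PipelineConfig | None = None,
    master_seed: int | None = None,
) -> NetworkReport:
    """Run the full pipeline on one dataset.

    When ``master_seed`` is given, the MCMC seed is derived from it and the
    network's name, so batch runs are reproducible network by network.
    Ineligible networks get a report with the reason and no model fit.
    """
    config = config or PipelineConfig()
    name = ds.name or "network"
    threshold = config.threshold_value
    frep = filter_event_risk(ds, config.risk_lo, config.risk_hi)
    if frep.all_removed:
        return NetworkReport(
            name, frep, None, (), (), None, threshold, False,
            reason="all studies outside the event-risk band",
        )
    retained = frep.retained
    erep = check_eligibility(retained, config.eligibility)
    if not erep.overall_eligible:
        return NetworkReport(
            name, frep, erep, (), (), None, threshold, False,
            reason="network ineligible",
        )
    mcmc = config.mcmc
    if master_seed is not None:
        mcmc = replace(mcmc, seed=network_seed(master_seed, name))
    results = run_all_nodes(
        retained, config.prior, mcmc, rhat_method=config.rhat_method
    )
    if not results:
        return NetworkReport(
            name, frep, erep, (), (), None, threshold, False,
            reason="no split nodes",
        )
    verdicts = tuple(classify_node(r, threshold) for r in results)
    net_verdict = classify_network(verdicts)
    converged = all(r.converged for r in results)
    logger.info(
        "analyze_network %s: %d split nodes, verdict %s/%s, converged=%s "
        "(threshold %.4f)",
        name, len(results), net_verdict.index_based, net_verdict.cri_based,
        converged, threshold,
    )
    return NetworkReport(
        name=name,
        filter_report=frep,
        eligibility=erep,
        results=tuple(results),
        node_verdicts=verdicts,
        network_verdict=net_verdict,
        threshold=threshold,
        converged=converged,
    )


@dataclass(frozen=True)
class PrevalenceSummary:
    """Counts over the extent x conclusiveness cells; percentages derived.

    ``node_cells`` / ``network_cells`` map (extent, conclusiveness) resp.
    (index_based, cri_based) labels to counts.  Node counts are also split
    by the single-study flag.
    """

    node_cells: dict[tuple[str, str], int]
    network_cells: dict[tuple[str, str], int]
    single_study_nodes: dict[tuple[str, str], int]
    multi_study_nodes: dict[tuple[str, str], int]
    n_nodes: int
    n_networks: int

    def node_percentages(self) -> dict[tuple[str, str], float]:
        if self.n_nodes == 0:
            return {k: 0.0 for k in self.node_cells}
        return {
            k: 100.0 * v / self.n_nodes for k, v in self.node_cells.items()
        }

    def network_percentages(self) -> dict[tuple[str, str], float]:
        if self.n_networks == 0:
            return {k: 0.0 for k in self.network_cells}
        return {
            k: 100.0 * v / self.n_networks for k, v in self.network_cells.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level, cells, total in (
            ("split_node", self.node_cells, self.n_nodes),
            ("network", self.network_cells, self.n_networks),
        ):
            for (a, b), count in sorted(cells.items()):
                rows.append(
                    {
                        "level": level,
                        "extent": a,
                        "conclusiveness": b,
                        "count": count,
                        "percent": 100.0 * count / total if total else 0.0,
                    }
                )
        return pd.DataFrame(
            rows, columns=["level", "extent", "conclusiveness", "count", "percent"]
        )


def summarize_prevalence(reports: Sequence[NetworkReport]) -> PrevalenceSummary:
    """Tabulate node- and network-level verdicts over analyzed networks."""
    analyzed = [r for r in reports if r.analyzed]
    node_cells: dict[tuple[str, str], int] = {}
    single: dict[tuple[str, str], int] = {}
    multi: dict[tuple[str, str], int] = {}
    net_cells: dict[tuple[str, str], int] = {}
    n_nodes = 0
    for rep in analyzed:
        for res, v in zip(rep.results, rep.node_verdicts):
            key = (v.extent.value, v.conclusiveness.value)
            node_cells[key] = node_cells.get(key, 0) + 1
            bucket = single if res.node.single_study else multi
            bucket[key] = bucket.get(key, 0) + 1
            n_nodes += 1
        nv = rep.network_verdict
        nkey = (nv.index_based, nv.cri_based)
        net_cells[nkey] = net_cells.get(nkey, 0) + 1
    return PrevalenceSummary(
        node_cells=node_cells,
        network_cells=net_cells,
        single_study_nodes=single,
        multi_study_nodes=multi,
        n_nodes=n_nodes,
        n_networks=len(analyzed),
    )


def export_plot_data(
    reports: Sequence[NetworkReport], out_dir: str | Path
) -> dict[str, Path]:
    """Write the tidy tables behind the four standard diagnostic plots.

    ``posterior_by_node_size.csv``  mean/sd of IF and (in)direct effects per
        node, with the single-study flag (box-plot backing data);
    ``index_vs_if.csv``             D^j against IF posterior mean and sd;
    ``kld_difference.csv``          D_DI - D_ID against D^j;
    ``index_vs_tau.csv``            D^j against the tau posterior median and
        its heterogeneity band.
    Counts always accompany derived quantities; empty report lists yield
    empty tables with headers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    node_rows = []
    for rep in reports:
        for res, v in zip(rep.results, rep.node_verdicts):
            node_rows.append(
                {
                    "network": rep.name,
                    "comparison": res.node.label,
                    "n_direct_studies": res.node.n_direct_studies,
                    "single_study": res.node.single_study,
                    "direct_mean": res.direct.mean,
                    "direct_sd": res.direct.sd,
                    "indirect_mean": res.indirect.mean,
                    "indirect_sd": res.indirect.sd,
                    "if_mean": res.inconsistency_factor.mean,
                    "if_sd": res.inconsistency_factor.sd,
                    "d_di": res.kld.d_di,
                    "d_id": res.kld.d_id,
                    "index": res.kld.index,
                    "tau_median": res.tau.median,
                    "tau_band": heterogeneity_band(res.tau.median),
                    "extent": v.extent.value,
                    "conclusiveness": v.conclusiveness.value,
                }
            )
    nodes = pd.DataFrame(
        node_rows,
        columns=[
            "network", "comparison", "n_direct_studies", "single_study",
            "direct_mean", "direct_sd", "indirect_mean", "indirect_sd",
            "if_mean", "if_sd", "d_di", "d_id", "index", "tau_median",
            "tau_band", "extent", "conclusiveness",
        ],
    )
    tables = {
        "posterior_by_node_size": nodes[
            ["network", "comparison", "n_direct_studies", "single_study",
             "direct_mean", "direct_sd", "indirect_mean", "indirect_sd",
             "if_mean", "if_sd"]
        ],
        "index_vs_if": nodes[
            ["network", "comparison", "single_study", "index",
             "if_mean", "if_sd", "extent", "conclusiveness"]
        ],
        "kld_difference": nodes.assign(
            kld_diff=nodes["d_di"] - nodes["d_id"]
        )[
            ["network", "comparison", "single_study", "d_di", "d_id",
             "kld_diff", "index"]
        ],
        "index_vs_tau": nodes[
            ["network", "comparison", "single_study", "index",
             "tau_median", "tau_band", "extent"]
        ],
    }
    paths = {}
    for stem, table in tables.items():
        path = out_dir / f"{stem}.csv"
        table.to_csv(path, index=False, float_format="%.6g")
        paths[stem] = path
    return paths


def write_report_outputs(
    report: NetworkReport, out_dir: str | Path
) -> dict[str, Path]:
    """Serialise one network report: JSON report + results CSV (if any)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    jpath = out_dir / f"{report.name}_report.json"
    jpath.write_text(report.to_json())
    paths["report"] = jpath
    if report.analyzed:
        cpath = out_dir / f"{report.name}_results.csv"
        write_results_table(list(report.results), cpath, report.threshold)
        paths["results"] = cpath
    return paths
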
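"""End-to-end orchestration: read -> filter -> impute -> split -> differential
correlation -> permutation -> correction -> network -> hubs -> export.

Each sex stratum is processed independently; a failure in one stratum aborts
that stratum with a structured message and the others continue. Every output
is deterministic given the configuration (including the seed): re-running
reproduces all files byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .diffcorr import (
    DiffCorrResult,
    adjust_significance,
    diffcorr_all_pairs,
    permutation_pvalues,
    write_diffcorr_table,
)
from .network import (
    build_network,
    centralities,
    export_network,
    hub_list,
    identify_hubs,
    mean_degree,
    node_table,
)
from .panel_io import (
    CohortDesign,
    ConcentrationTable,
    PanelValidationError,
    preprocess_stratum,
    read_cohort_design,
    read_concentration_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of a full pipeline run.

    Defaults follow the analysis conventions of targeted-panel differential
    correlation studies: strictly-more-than-80% detection filter, alpha 0.05,
    1000 permutations, Bonferroni correction over all metabolite pairs, and a
    pooled permutation null.
    """

    concentrations: str | Path = ""
    metadata: str | Path = ""
    classes: str | Path | None = None
    outdir: str | Path = "dcmnet_out"
    stratify_by: str = "stratum"
    min_detection: float = 0.8
    filter_scope: str = "pooled"
    zero_as_missing: bool = False
    alpha: float = 0.05
    permutations: int = 1000
    correction: str = "bonferroni"
    scheme: str = "pooled"
    weighted: bool = True
    degree_quantile: float = 0.9
    centrality_quantile: float = 0.9
    hub_combine: str = "or"
    hub_ties: str = "include"
    export_formats: tuple[str, ...] = ("graphml", "sif", "edge-table")
    seed: int = 0

    def validate(self) -> None:
        if self.permutations < 1:
            raise ValueError(
                f"permutations must be >= 1, got {self.permutations}"
            )
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.min_detection <= 1:
            raise ValueError(
                f"min_detection must be in (0, 1], got {self.min_detection}"
            )
        if not 0 < self.degree_quantile <= 1 or not 0 < self.centrality_quantile <= 1:
            raise ValueError("hub quantiles must be in (0, 1]")


@dataclass
class StratumResult:
    """Everything the pipeline produced for one stratum."""

    stratum: str
    diffcorr: DiffCorrResult
    network_nominal: nx.Graph
    network_adjusted: nx.Graph
    hubs: list[str]
    summary: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _stratum_seed(seed: int, index: int) -> int:
    """Stable per-stratum child seed below 2**31."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def _drop_zero_variance(paired) -> None:
    """Drop metabolites constant in either compartment (warned, not fatal)."""
    const = [
        mid
        for mid in paired.metabolite_ids
        if paired.plasma[mid].std() == 0 or paired.jf[mid].std() == 0
    ]
    if const:
        logger.warning(
            "dropping %d zero-variance metabolites in stratum %s: %s",
            len(const), paired.stratum, const,
        )
        paired.plasma = paired.plasma.drop(columns=const)
        paired.jf = paired.jf.drop(columns=const)


def run_stratum(
    table: ConcentrationTable,
    design: CohortDesign,
    stratum: str,
    config: RunConfig,
    seed: int,
    outdir: Path | None = None,
) -> StratumResult:
    """The full analysis for one stratum; optionally writes all outputs."""
    paired = preprocess_stratum(
        table, design, stratum,
        min_fraction=config.min_detection, filter_scope=config.filter_scope,
    )
    _drop_zero_variance(paired)
    result = permutation_pvalues(
        paired,
        B=config.permutations,
        scheme=config.scheme,
        seed=seed,
        alpha=config.alpha,
        weighted=config.weighted,
    )
    result = adjust_significance(result, alpha=config.alpha, method=config.correction)

    net_nom = build_network(result, tier="nominal")
    net_adj = build_network(result, tier="adjusted")
    hubs: list[str] = []
    if net_nom.number_of_nodes():
        centralities(net_nom)
        identify_hubs(
            net_nom,
            degree_quantile=config.degree_quantile,
            centrality_quantile=config.centrality_quantile,
            combine=config.hub_combine,
            ties=config.hub_ties,
        )
        hubs = hub_list(net_nom)

    sig = result.significant("nominal")
    n_pos = int((sig["r_diff"] >= 0).sum())
    n_neg = int((sig["r_diff"] < 0).sum())
    summary = {
        "stratum": stratum,
        "n_plasma": result.n_plasma,
        "n_jf": result.n_jf,
        "n_metabolites": len(paired.metabolite_ids),
        "n_pairs": result.n_pairs,
        "n_significant_nominal": int(len(sig)),
        "n_significant_positive": n_pos,
        "n_significant_negative": n_neg,
        "n_significant_adjusted": int(result.table["sig_adjusted"].sum()),
        "adjusted_threshold": result.adjusted_threshold,
        "network_nodes": net_nom.number_of_nodes(),
        "network_edges": net_nom.number_of_edges(),
        "mean_degree": round(mean_degree(net_nom), 4),
        "adjusted_network_nodes": net_adj.number_of_nodes(),
        "adjusted_network_edges": net_adj.number_of_edges(),
        "hubs": hubs,
        "seed": seed,
    }
    assert n_pos + n_neg == len(sig)

    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        paths["diffcorr"] = outdir / "diffcorr.tsv"
        write_diffcorr_table(result, paths["diffcorr"])
        for tier, net in (("nominal", net_nom), ("adjusted", net_adj)):
            for fmt in config.export_formats:
                ext = {"graphml": "graphml", "sif": "sif", "edge-table": "edges.tsv"}[fmt]
                p = outdir / f"network_{tier}.{ext}"
                export_network(net, p, fmt)
                paths[f"network_{tier}_{fmt}"] = p
        paths["nodes"] = outdir / "node_centralities.tsv"
        node_table(net_nom).to_csv(paths["nodes"], sep="\t", index=False)
        paths["hubs"] = outdir / "hubs.txt"
        paths["hubs"].write_text("".join(f"{h}\n" for h in hubs))
        paths["summary"] = outdir / "summary.json"
        paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return StratumResult(
        stratum=stratum,
        diffcorr=result,
        network_nominal=net_nom,
        network_adjusted=net_adj,
        hubs=hubs,
        summary=summary,
        paths=paths,
    )


def run(config: RunConfig) -> dict[str, StratumResult]:
    """Run the whole pipeline for every stratum of the design.

    Writes, per stratum, the differential correlation table, nominal- and
    adjusted-tier network exports, the node centrality table, the hub list
    and a JSON summary; plus one run manifest at the top level. Returns the
    in-memory results keyed by stratum.
    """
    config.validate()
    table = read_concentration_table(
        config.concentrations,
        zero_as_missing=config.zero_as_missing,
        class_path=config.classes,
    )
    design = read_cohort_design(config.metadata)
    if config.stratify_by != "stratum":
        design.table["stratum"] = design.table[config.stratify_by]

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "dcmnet_version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )

    results: dict[str, StratumResult] = {}
    for idx, stratum in enumerate(design.strata):
        seed = _stratum_seed(config.seed, idx)
        try:
            res = run_stratum(
                table, design, stratum, config, seed, outdir / str(stratum)
            )
        except (PanelValidationError, ValueError) as exc:
            logger.error("stratum %r failed: %s", stratum, exc)
            (outdir / f"{stratum}.error.json").write_text(
                json.dumps({"stratum": stratum, "error": str(exc)}, sort_keys=True)
                + "\n"
            )
            continue
        logger.info(
            "stratum %s: %d pairs, %d significant (%d+/%d-), network %d nodes / "
            "%d edges, mean degree %.2f, hubs: %s",
            stratum,
            res.summary["n_pairs"],
            res.summary["n_significant_nominal"],
            res.summary["n_significant_positive"],
            res.summary["n_significant_negative"],
            res.summary["network_nodes"],
            res.summary["network_edges"],
            res.summary["mean_degree"],
            ", ".join(res.hubs) or "none",
        )
        results[stratum] = res
    return results
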
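"""End-to-end orchestration: gene merge -> network -> proximity ->
signature enrichment -> DEG/target intersection, from one config.

Stages run in the order the analysis demands: the merged disease gene
set and confidence-filtered interactome feed the proximity screen; only
drugs passing the distance threshold enter the enrichment screen (a
flag screens all drugs instead); the final intersection uses targets of
the strictest FDR tier.  Every stage writes a TSV under the output
directory and contributes counts to the run report; a fixed seed makes
reruns byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import diffexp, enrichment, genesets, network, proximity
from .errors import PipelineStageError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_all"]


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    Threshold defaults are the analysis's published operating points:
    combined score >= 0.9, distance < 1.0, DEG p < 0.05, FDR tiers
    0.25 / 0.1, ORA FDR < 0.05, 10,000 proximity randomizations and
    1,000 enrichment permutations.
    """

    # input paths
    disease_sources: list[str] = field(default_factory=list)
    alias_map: str | None = None
    drop_list: str | None = None
    ppi_edges: list[str] = field(default_factory=list)
    drug_targets: str = ""
    profiles: str = ""
    expression: str = ""
    labels: str = ""
    # thresholds
    string_min_score: float = 0.9
    distance_threshold: float = 1.0
    deg_alpha: float = 0.05
    fdr_tiers: tuple[float, float] = (0.25, 0.1)
    ora_fdr: float = 0.05
    # iteration counts
    proximity_n_iter: int = 10_000
    igsea_n_perm: int = 1000
    # behaviour
    screen_all_drugs: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML or flat ``key = value`` text (both accepted)."""
        import yaml

        raw = Path(path).read_text()
        try:
            data = yaml.safe_load(raw)
        except yaml.YAMLError:
            data = None
        if not isinstance(data, dict):
            data = {}
            for line in raw.splitlines():
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = yaml.safe_load(value.strip())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for key in ("disease_sources", "ppi_edges"):
            v = kwargs.get(key)
            if isinstance(v, str):
                kwargs[key] = [s.strip() for s in v.split(",") if s.strip()]
        if "fdr_tiers" in kwargs and isinstance(kwargs["fdr_tiers"], (list, str)):
            v = kwargs["fdr_tiers"]
            if isinstance(v, str):
                v = [float(s) for s in v.split(",")]
            kwargs["fdr_tiers"] = tuple(float(x) for x in v)
        known = set(cls.__dataclass_fields__)
        unknown = set(kwargs) - known
        if unknown:
            raise PipelineStageError(
                "config", f"unknown config key(s): {sorted(unknown)}"
            )
        return cls(**kwargs)


@dataclass
class RunReport:
    """Per-stage record counts, seeds, config echo and wall-clock."""

    counts: dict = field(default_factory=dict)
    seed: int = 0
    config: dict = field(default_factory=dict)
    wall_clock: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
            fh.write("\n")

    def to_text(self) -> str:
        lines = ["Pipeline run report", "=" * 40, f"seed: {self.seed}"]
        for stage, n in self.counts.items():
            lines.append(f"{stage}: {n}")
        for stage, t in self.wall_clock.items():
            lines.append(f"[time] {stage}: {t:.2f}s")
        if self.failed_stage:
            lines.append(f"FAILED at stage: {self.failed_stage}")
        return "\n".join(lines)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every violation (ranges, file existence, seed); [] means ok."""
    errs: list[str] = []

    def _range(name: str, value: float, lo: float, hi: float) -> None:
        if not lo <= value <= hi:
            errs.append(f"{name}={value} outside [{lo}, {hi}]")

    _range("string_min_score", config.string_min_score, 0.0, 1.0)
    _range("deg_alpha", config.deg_alpha, 0.0, 1.0)
    _range("ora_fdr", config.ora_fdr, 0.0, 1.0)
    for t in config.fdr_tiers:
        _range("fdr_tiers", t, 0.0, 1.0)
    if config.proximity_n_iter < 100:
        errs.append(f"proximity_n_iter={config.proximity_n_iter} below 100")
    if config.igsea_n_perm < 100:
        errs.append(f"igsea_n_perm={config.igsea_n_perm} below 100")
    if not isinstance(config.seed, int):
        errs.append("seed must be an integer")
    if not config.disease_sources:
        errs.append("disease_sources is empty")
    if not config.ppi_edges:
        errs.append("ppi_edges is empty")
    for label, p in [
        *[("disease_sources", p) for p in config.disease_sources],
        *[("ppi_edges", p) for p in config.ppi_edges],
        ("drug_targets", config.drug_targets),
        ("profiles", config.profiles),
        ("expression", config.expression),
        ("labels", config.labels),
        ("alias_map", config.alias_map),
        ("drop_list", config.drop_list),
    ]:
        if p and not Path(p).exists():
            errs.append(f"{label}: file not found: {p}")
    return errs


def _banner(stage: str) -> None:
    print(f"=== [{stage}] ===", file=sys.stderr)


def run_all(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute the full analysis; outputs and report land under ``out_dir``.

    Any stage failure aborts with :class:`PipelineStageError` naming the
    stage, after writing the partial report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, config=asdict(config))
    stage = "validate"
    t0 = time.perf_counter()
    try:
        errors = validate_config(config)
        if errors:
            raise PipelineStageError(stage, "; ".join(errors))
        report.wall_clock[stage] = time.perf_counter() - t0

        # -- gene-set integration ------------------------------------
        stage = "geneset_integration"
        _banner(stage)
        t0 = time.perf_counter()
        named_lists: dict[str, list[str]] = {}
        for path in config.disease_sources:
            p = Path(path)
            if p.suffix.lower() == ".gmt":
                named_lists.update(genesets.read_gmt(p))
            else:
                named_lists[p.stem] = genesets.read_gene_list(p)
        alias = genesets.read_alias_map(config.alias_map) if config.alias_map else {}
        drops = genesets.read_gene_list(config.drop_list) if config.drop_list else []
        disease = genesets.merge_gene_sources(named_lists, alias, drops,
                                              name="disease")
        genesets.write_provenance_table(disease, out / "disease_genes.tsv")
        report.counts["genes_merged"] = len(disease)
        report.wall_clock[stage] = time.perf_counter() - t0

        # -- network construction ------------------------------------
        stage = "ppi_network"
        _banner(stage)
        t0 = time.perf_counter()
        edge_lists = {}
        n_retained = 0
        for path in config.ppi_edges:
            p = Path(path)
            table = network.read_edge_table(p)
            scored = "combined_score" in pd.read_csv(p, sep="\t", nrows=0).columns
            cutoff = config.string_min_score if scored else 0.0
            edges = network.filter_scored_edges(table, cutoff)
            n_retained += len(edges)
            edge_lists[p.stem] = edges
        net = network.merge_networks(edge_lists)
        network.write_edge_table(net, out / "merged_network.tsv")
        report.counts["edges_retained"] = n_retained
        report.counts["network_nodes"] = net.number_of_nodes()
        report.counts["network_edges"] = net.number_of_edges()
        report.wall_clock[stage] = time.perf_counter() - t0

        # -- proximity screen ----------------------------------------
        stage = "proximity"
        _banner(stage)
        t0 = time.perf_counter()
        dtm = proximity.read_drug_targets(config.drug_targets)
        if len(dtm) == 0:
            raise PipelineStageError(
                stage, f"empty drug-target file: {config.drug_targets}"
            )
        prox_model = proximity.NetworkProximity(net, disease.genes, dtm)
        prox = prox_model.fit(
            n_iter=config.proximity_n_iter,
            seed=config.seed,
            threshold=config.distance_threshold,
        )
        prox.to_tsv(out / "proximity.tsv")
        screened = prox.screen()
        report.counts["drugs_scored"] = len(prox.results)
        report.counts["drugs_pass_screen"] = len(screened)
        report.wall_clock[stage] = time.perf_counter() - t0

        # -- signature enrichment ------------------------------------
        stage = "enrichment"
        _banner(stage)
        t0 = time.perf_counter()
        profiles = pd.read_csv(config.profiles, sep="\t", index_col=0)
        wanted = (
            list(profiles.columns) if config.screen_all_drugs else
            [d for d in profiles.columns if d in set(screened)]
        )
        loose, strict = max(config.fdr_tiers), min(config.fdr_tiers)
        if wanted:
            enr_model = enrichment.SignatureEnrichment(
                profiles[wanted], disease.genes
            )
            enr = enr_model.fit(n_perm=config.igsea_n_perm, seed=config.seed)
            enr.select(config.fdr_tiers).to_csv(
                out / "igsea.tsv", sep="\t", index=False, float_format="%.6g"
            )
            tier_loose = enr.candidates(loose)
            tier_strict = enr.candidates(strict)
        else:
            pd.DataFrame(
                columns=["drug_id", "es", "p_nominal", "fdr", "n_perm", "tier"]
            ).to_csv(out / "igsea.tsv", sep="\t", index=False)
            tier_loose, tier_strict = [], []
        report.counts[f"drugs_fdr_lt_{loose}"] = len(tier_loose)
        report.counts[f"drugs_fdr_lt_{strict}"] = len(tier_strict)
        report.wall_clock[stage] = time.perf_counter() - t0

        # -- differential expression & intersection ------------------
        stage = "deg_intersection"
        _banner(stage)
        t0 = time.perf_counter()
        expr = diffexp.read_expression(config.expression)
        labels = diffexp.read_labels(config.labels)
        de_model = diffexp.GroupDifferentialExpression(expr, labels)
        de = de_model.fit(alpha=config.deg_alpha)
        de.to_tsv(out / "deg.tsv")
        inter = de.intersect_targets(dtm, drug_ids=tier_strict)
        inter.to_csv(out / "intersection.tsv", sep="\t", index=False,
                     float_format="%.6g")
        report.counts["degs"] = len(de.degs)
        report.counts["intersection_genes"] = len(inter)
        if len(inter) >= 1:
            de.group_summary(list(inter["gene"])).to_csv(
                out / "intersection_summary.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
        if len(inter) >= 2:
            labels_map, order = de.cluster(list(inter["gene"]), n_clusters=2)
            with open(out / "intersection_clusters.tsv", "w") as fh:
                fh.write("gene\tcluster\tleaf_order\n")
                rank = {g: i for i, g in enumerate(order)}
                for g in sorted(labels_map):
                    fh.write(f"{g}\t{labels_map[g]}\t{rank[g]}\n")
        report.wall_clock[stage] = time.perf_counter() - t0

    except PipelineStageError:
        report.failed_stage = stage
        report.to_json(out / "report.json")
        raise
    except Exception as exc:
        report.failed_stage = stage
        report.to_json(out / "report.json")
        raise PipelineStageError(stage, str(exc)) from exc

    report.to_json(out / "report.json")
    (out / "report.txt").write_text(report.to_text() + "\n")
    return report
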
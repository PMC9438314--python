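"""End-to-end orchestration: mfa -> clustering -> differential -> pathway ->
decomposition -> taxonomy -> survival.

A run consumes a directory of plain-text inputs (contig-annotation TSV,
clinical CSV, total-reads TSV, optional KO->pathway and KO->CAZy maps),
writes each stage's tables under the output directory and records a JSON
manifest (parameters, package/library versions, per-stage row counts and
timings).  Re-running with the same config reproduces identical outputs;
the only randomness in the package lives in the synthetic generator and is
fully determined by its seed.

Stages whose documented preconditions are not met by the data at hand
(e.g. the decomposition on a two-sample toy) are recorded in the manifest
as skipped with the reason and the run continues; any unexpected failure
aborts with the stage name.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import clustering as clus
from . import decomposition as decomp
from . import differential as diff_mod
from . import io
from . import mfa as mfa_mod
from . import pathway as pw
from . import survival as surv
from . import taxonomy as tax
from .errors import MucometaError

logger = logging.getLogger(__name__)

STAGE_ORDER = ["mfa", "clustering", "differential", "pathway",
               "decomposition", "taxonomy", "survival"]


@dataclass
class RunConfig:
    """All inputs and tunables of a pipeline run (one serialisable record)."""

    contigs: str
    clinical: str
    total_reads: str
    out_dir: str
    pathway_map: str | None = None
    cazy_map: str | None = None
    k: int = 14                    # group size for the supervised split
    alpha: float = 0.05            # unadjusted per-test cutoff
    min_samples: int = 30          # prevalence filter ahead of clustering
    pseudocount: float = 1.0       # for every log2 transform
    min_lt: int = 9                # pathway overlap floors (LT / ST favouring)
    min_st: int = 4
    grid_n: int = 512              # decomposition KDE grid
    bandwidth: str = "silverman"
    rank: str = "order"            # taxonomy rank
    n_sample_clusters: int = 2
    n_ko_clusters: int = 2
    n_subclusters: int = 4
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))

    def validate(self) -> None:
        for name in ("k", "min_samples", "min_lt", "min_st", "grid_n"):
            if getattr(self, name) < 1:
                raise MucometaError(f"config.{name} must be positive")
        if not 0 < self.alpha < 1:
            raise MucometaError("config.alpha must be in (0, 1)")
        if self.pseudocount < 0:
            raise MucometaError("config.pseudocount must be >= 0")
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise MucometaError(f"unknown stages: {sorted(unknown)}")


@dataclass
class Manifest:
    config: dict
    versions: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, seconds: float, **counts):
        self.stages[stage] = {"status": status,
                              "seconds": round(seconds, 3), **counts}


def run_all(config: RunConfig) -> Manifest:
    """Execute all configured stages in order and write a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import numpy, scipy, lifelines  # versions for the manifest

    manifest = Manifest(
        config=asdict(config),
        versions={"mucometa": __version__, "numpy": numpy.__version__,
                  "scipy": scipy.__version__, "pandas": pd.__version__,
                  "lifelines": lifelines.__version__},
    )

    contigs = io.read_contig_table(config.contigs)
    clinical = io.read_clinical(config.clinical)
    totals = io.read_total_reads(config.total_reads)
    pmap = pw.load_pathway_map(config.pathway_map) if config.pathway_map else None
    cazy = pw.load_cazy_map(config.cazy_map) if config.cazy_map else None

    state: dict = {}
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            counts = _STAGE_FUNCS[stage](config, out, contigs, clinical,
                                         totals, pmap, cazy, state)
        except MucometaError as exc:
            logger.warning("stage %s skipped: %s", stage, exc)
            manifest.record(stage, f"skipped: {exc}", time.perf_counter() - t0)
            continue
        except Exception:
            manifest.record(stage, "failed", time.perf_counter() - t0)
            _write_manifest(manifest, out)
            logger.error("stage %s failed", stage)
            raise
        manifest.record(stage, "ok", time.perf_counter() - t0, **counts)
        logger.info("stage %s done in %.2fs", stage,
                    manifest.stages[stage]["seconds"])
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: Manifest, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": manifest.config, "versions": manifest.versions,
                   "stages": manifest.stages}, fh, indent=2, default=str)


def _stage_mfa(config, out, contigs, clinical, totals, pmap, cazy, state):
    raw = mfa_mod.build_mfa(contigs, totals)
    norm = mfa_mod.normalize(raw)
    io.write_matrix_tsv(raw.values, out / "mfa_raw.tsv")
    io.write_matrix_tsv(norm.values, out / "mfa_normalized.tsv")
    io.write_total_reads(raw.total_reads, out / "total_reads.tsv")
    state["raw"], state["norm"] = raw, norm
    return {"n_kos": len(raw.kos), "n_samples": len(raw.samples)}


def _stage_clustering(config, out, contigs, clinical, totals, pmap, cazy, state):
    prevalent = mfa_mod.filter_prevalent(state["norm"], config.min_samples)
    centered = mfa_mod.log2_center(prevalent, config.pseudocount)
    assignment = clus.hierarchical_cluster(
        centered, config.n_sample_clusters, config.n_ko_clusters)
    frame = assignment.sample_labels.to_frame()
    frame[f"sample_subcluster_k{config.n_subclusters}"] = (
        assignment.cut_samples(config.n_subclusters))
    frame.to_csv(out / "sample_clusters.tsv", sep="\t")
    assignment.ko_labels.to_frame().to_csv(out / "ko_clusters.tsv", sep="\t")
    for name, link, labels in (
        ("samples", assignment.sample_linkage, assignment.sample_labels.index),
        ("kos", assignment.ko_linkage, assignment.ko_labels.index),
    ):
        (out / f"tree_{name}.nwk").write_text(
            clus.linkage_to_newick(link, labels) + "\n")
    assoc = clus.cluster_clinical_association(assignment, clinical)
    assoc.to_csv(out / "cluster_clinical_association.tsv", sep="\t")
    counts = {"n_clustered_kos": len(assignment.ko_labels)}
    if pmap is not None:
        overlap = clus.ko_cluster_pathway_overlap(assignment, pmap)
        overlap.to_csv(out / "ko_cluster_pathway_overlap.tsv", sep="\t",
                       index=False)
        counts["n_overlap_rows"] = len(overlap)
    state["assignment"] = assignment
    return counts


def _stage_differential(config, out, contigs, clinical, totals, pmap, cazy, state):
    groups = diff_mod.assign_size_groups(clinical, config.k)
    groups.to_frame().to_csv(out / "size_groups.tsv", sep="\t")
    diff = diff_mod.differential_kos(state["norm"], groups, config.alpha)
    diff.to_csv(out / "differential_kos.tsv", sep="\t")
    richness = diff_mod.functional_richness(state["raw"], clinical)
    richness.richness.to_frame().assign(
        tumor_size_cm=clinical["tumor_size_cm"]).to_csv(
            out / "functional_richness.tsv", sep="\t")
    (out / "functional_richness_summary.txt").write_text(
        richness.summary() + "\n")
    state["groups"], state["diff"], state["richness"] = groups, diff, richness
    return {"n_selected": int(diff["selected"].sum()),
            "n_LT": int((diff["direction"] == "LT").sum()),
            "n_ST": int((diff["direction"] == "ST").sum())}


def _stage_pathway(config, out, contigs, clinical, totals, pmap, cazy, state):
    if pmap is None:
        raise MucometaError("no pathway map supplied")
    if "diff" not in state:
        raise MucometaError("differential stage did not run")
    diff = state["diff"]
    scores = pw.enrichment_scores(diff, pmap, config.min_lt, config.min_st)
    scores.to_csv(out / "pathway_enrichment.tsv", sep="\t")
    activities = {}
    for pid in pmap:
        try:
            activities[pid] = pw.activity_score(
                state["norm"], pmap[pid], config.pseudocount, pid)
        except MucometaError:
            continue
    act = pd.DataFrame(activities)
    act.rename_axis("sample_id").to_csv(out / "pathway_activity.tsv", sep="\t")
    counts = {"n_scored": len(scores), "n_activities": act.shape[1]}
    if cazy is not None:
        summary = pw.cazy_summary(diff, cazy)
        summary.to_csv(out / "cazy_summary.tsv", sep="\t")
    state["enrichment"], state["activity"] = scores, act
    return counts


def _stage_decomposition(config, out, contigs, clinical, totals, pmap, cazy, state):
    if "diff" not in state:
        raise MucometaError("differential stage did not run")
    report = decomp.dominance_report(
        state["groups"], state["norm"], state["diff"],
        pseudocount=config.pseudocount, grid_n=config.grid_n,
        bandwidth=config.bandwidth)
    report.to_frame().to_csv(out / "decomposition.tsv", sep="\t")
    (out / "decomposition_summary.txt").write_text(report.summary() + "\n")
    state["dominance"] = report
    return {"ratio_lt": round(report.ratio_lt, 4),
            "ratio_st": round(report.ratio_st, 4)}


def _stage_taxonomy(config, out, contigs, clinical, totals, pmap, cazy, state):
    otu = tax.taxa_abundance(contigs, config.rank)
    io.write_matrix_tsv(otu.values, out / f"otu_{config.rank}.tsv")
    counts = {"n_taxa": len(otu.values)}
    if "groups" in state:
        dtaxa = tax.differential_taxa(otu, state["groups"], config.alpha)
        dtaxa.to_csv(out / "differential_taxa.tsv", sep="\t")
        counts["n_taxa_selected"] = int(dtaxa["selected"].sum())
    if pmap is not None and "enrichment" in state and len(state["enrichment"]):
        top = state["enrichment"]["score"].abs().idxmax()
        profile = tax.pathway_taxa_profile(contigs, pmap[top], config.rank)
        io.write_matrix_tsv(profile.values, out / f"pathway_taxa_{top}.tsv")
        if "activity" in state and top in state["activity"]:
            corr = tax.correlate_pathway_taxa(state["activity"][top], profile)
            corr.to_csv(out / f"pathway_taxa_correlation_{top}.tsv", sep="\t")
        counts["profiled_pathway"] = top
    return counts


def _stage_survival(config, out, contigs, clinical, totals, pmap, cazy, state):
    survdata = clinical[["rfs_months", "rfs_event"]]
    results = []
    cats = surv.categorize_clinical(clinical)
    for var in cats.columns:
        labels = cats[var]
        if labels.nunique() != 2:
            continue
        km = surv.km_logrank(labels, survdata)
        results.append((var, km.statistic, km.p_value))
    if "activity" in state:
        for pid in state["activity"].columns:
            try:
                labels = surv.categorize_score(state["activity"][pid])
                km = surv.km_logrank(labels, survdata)
            except MucometaError:
                continue
            results.append((f"activity_{pid}", km.statistic, km.p_value))
    frame = pd.DataFrame(results, columns=["variable", "logrank_statistic",
                                           "logrank_p"]).set_index("variable")
    frame.to_csv(out / "survival_logrank.tsv", sep="\t")
    covs = pd.DataFrame({
        "tumor_size_cm": clinical["tumor_size_cm"].astype(float),
        "node_positive": clinical["node_positive"].astype(bool).astype(int),
    })
    if "activity" in state and state["activity"].shape[1]:
        first = state["activity"].columns[0]
        covs[f"activity_{first}"] = state["activity"][first]
    try:
        cox = surv.cox_ph(covs, survdata)
        cox.table.to_csv(out / "survival_cox.tsv", sep="\t")
        (out / "survival_cox_summary.txt").write_text(cox.summary() + "\n")
    except MucometaError as exc:
        logger.warning("Cox model skipped: %s", exc)
    return {"n_logrank": len(frame)}


_STAGE_FUNCS = {
    "mfa": _stage_mfa,
    "clustering": _stage_clustering,
    "differential": _stage_differential,
    "pathway": _stage_pathway,
    "decomposition": _stage_decomposition,
    "taxonomy": _stage_taxonomy,
    "survival": _stage_survival,
}
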
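"""End-to-end analyses: karyotype, CGH and trisomy-index pipelines.

Each run takes a :class:`RunConfig`, executes the stages in order and
writes its artifacts (TSVs, GraphML/SIF, Newick, a JSON manifest with
the serialized configuration, seed and config hash) into the output
directory.  All randomness flows from ``config.seed``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import cgh as cgh_mod
from .bands import CytobandModel, default_cytoband_model
from .class_similarity import ClassSimilarity, build_correlative_matrix
from .cohort import apply_filter_cascade, load_records, parse_records, report_frame
from .cooccurrence import PairCooccurrence, write_graphml, write_sif
from .matrix import build_matrix
from .reconstruction import classify_token, reconstruct
from .stats import enrichment_table
from . import trisomy

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and schedule for one pipeline run (defaults = published values)."""

    seed: int = 0
    t: float = 0.05
    min_row_support: int = 10
    prefilter_p_max: float = 0.001
    fdr_level: float = 0.05
    bonferroni_alpha: float = 0.05
    min_class_size: int = 50
    n_perm_pairs: int = 10**6
    n_perm_classes: int = 10**7
    swaps_per_sample: int | None = None
    burn_in: int | None = None
    include_selected: bool = False

    def __post_init__(self) -> None:
        for name in ("t", "prefilter_p_max", "fdr_level", "bonferroni_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_perm_pairs <= 0 or self.n_perm_classes <= 0:
            raise ValueError("permutation counts must be positive")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class KaryotypeRun:
    """Artifacts of one karyotype analysis."""

    records: pd.DataFrame
    classes: pd.DataFrame
    filter_reports: list
    aberration_table: pd.DataFrame
    n_ambiguous: int
    enrichment: pd.DataFrame
    pair_results: object
    class_results: object
    clustering: object | None


def reconstruct_cohort(records: pd.DataFrame) -> tuple[pd.DataFrame, set]:
    """Reconstruct events for every surviving record.

    Returns the aberration occurrence table (record_id, canonical_id,
    kind) and the set of ambiguous record ids, which are excluded from
    all downstream statistics.
    """
    rows = []
    ambiguous: set = set()
    for row in records.itertuples(index=False):
        rec = reconstruct(row.parsed)
        if rec.ambiguous:
            ambiguous.add(row.record_id)
            continue
        for event in rec.events:
            rows.append((row.record_id, event.canonical_id, classify_token(event)))
    table = pd.DataFrame(rows, columns=["record_id", "canonical_id", "kind"])
    return table, ambiguous


def run_karyotype_analysis(
    records: pd.DataFrame | str,
    config: RunConfig,
    out_dir: str | None = None,
) -> KaryotypeRun:
    """Filter -> reconstruct -> enrichment -> pair test -> class similarity."""
    if isinstance(records, str):
        records = load_records(records)
    records = parse_records(records)
    filtered, classes, reports = apply_filter_cascade(
        records,
        min_class_size=config.min_class_size,
        include_selected=config.include_selected,
    )
    ab_table, ambiguous_ids = reconstruct_cohort(filtered)
    analysed = filtered[~filtered["record_id"].isin(ambiguous_ids)].reset_index(
        drop=True
    )
    enrich = enrichment_table(ab_table, analysed, fdr_level=config.fdr_level)
    matrix = build_matrix(ab_table, analysed, min_row_support=config.min_row_support)
    pair_model = PairCooccurrence(
        matrix, prefilter_p_max=config.prefilter_p_max, correction="bonferroni"
    )
    pair_results = pair_model.fit(
        n_permutations=config.n_perm_pairs,
        seed=config.seed,
        swaps_per_sample=config.swaps_per_sample,
        burn_in=config.burn_in,
        alpha=config.bonferroni_alpha,
    )
    mt = build_correlative_matrix(enrich, t=config.t)
    class_results = ClassSimilarity(mt).fit(
        n_permutations=config.n_perm_classes,
        seed=config.seed + 1,
        swaps_per_sample=config.swaps_per_sample,
        burn_in=config.burn_in,
        fdr_level=config.fdr_level,
    )
    try:
        clustering = class_results.cluster()
    except ValueError:
        logger.info("class clustering skipped: fewer than two similar classes")
        clustering = None
    run = KaryotypeRun(
        analysed,
        classes,
        reports,
        ab_table,
        len(ambiguous_ids),
        enrich,
        pair_results,
        class_results,
        clustering,
    )
    if out_dir is not None:
        _write_karyotype_artifacts(run, config, out_dir)
    return run


def _write_karyotype_artifacts(run: KaryotypeRun, config: RunConfig, out_dir: str):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_frame(run.filter_reports).to_csv(
        out / "filter_report.tsv", sep="\t", index=False
    )
    run.aberration_table.to_csv(out / "aberrations.tsv", sep="\t", index=False)
    run.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    run.pair_results.write_tsv(out / "pairs.tsv")
    g = run.pair_results.to_network()
    write_graphml(g, str(out / "network.graphml"))
    write_sif(g, str(out / "network.sif"))
    run.class_results.write_tsv(out / "class_pairs.tsv")
    run.class_results.similarity_matrix().to_csv(out / "similarity.tsv", sep="\t")
    if run.clustering is not None:
        (out / "dendrogram.nwk").write_text(run.clustering.newick + "\n")
    _write_manifest(out, config, analysis="karyotype")


def run_cgh_analysis(
    segments: pd.DataFrame | str,
    config: RunConfig,
    band_model: CytobandModel | None = None,
    out_dir: str | None = None,
):
    """CGH calling plus the unstratified, unfiltered pair test (FDR 5%)."""
    if isinstance(segments, str):
        segments = cgh_mod.load_segments(segments)
    model = band_model or default_cytoband_model()
    samples = cgh_mod.call_samples(segments, model)
    results = cgh_mod.cgh_cooccurrence(
        samples,
        n_permutations=config.n_perm_pairs,
        seed=config.seed,
        fdr_level=config.fdr_level,
        swaps_per_sample=config.swaps_per_sample,
        burn_in=config.burn_in,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cgh_mod.calls_frame(samples).to_csv(out / "calls.tsv", sep="\t", index=False)
        results.write_tsv(out / "pairs.tsv")
        g = results.to_network()
        write_graphml(g, str(out / "network.graphml"))
        write_sif(g, str(out / "network.sif"))
        _write_manifest(out, config, analysis="cgh")
    return samples, results


def run_tit_analysis(
    records: pd.DataFrame | str,
    config: RunConfig,
    candidate_pool=trisomy.DEFAULT_POOL,
    set_size: int = 3,
    k_range=(1, 2, 3),
    out_dir: str | None = None,
):
    """Trisomy-index search on an MM cohort given as karyotype records."""
    if isinstance(records, str):
        records = load_records(records)
    records = parse_records(records)
    ab_table, _ = reconstruct_cohort(records[records["valid"] & records["well_defined"]])
    gains = ab_table.groupby("record_id")["canonical_id"].apply(set)
    cohort = records[["record_id", "modal_count"]].copy()
    cohort["aberrations"] = [
        gains.get(rid, set()) for rid in cohort["record_id"]
    ]
    cohort = trisomy.prepare_cohort(cohort)
    evaluations = trisomy.search_best(
        cohort, candidate_pool=candidate_pool, set_size=set_size, k_range=k_range
    )
    report = trisomy.report_frame(evaluations)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "tit_report.tsv", sep="\t", index=False)
        _write_manifest(out, config, analysis="tit")
    return cohort, evaluations, report


def _write_manifest(out: Path, config: RunConfig, analysis: str) -> None:
    manifest = {
        "analysis": analysis,
        "config": asdict(config),
        "config_hash": config.hash(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
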
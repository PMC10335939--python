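"""End-to-end orchestration: simulate/load -> RSS classify -> junction calls
-> cohort summaries -> JSON report.

All tunables live in :class:`RunConfig`; the serialized config is embedded in
the report for provenance, and identical config + seed reproduces an
identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    count_rag_per_sample,
    fit_negbin,
    summarize_by_category,
)
from .junctions import JunctionKind, call_junction, summarize_nts
from .rss import RSSConfig, RSSStatus, classify_cohort, distance_to_nearest_rss
from .simulate import GeneratorConfig, SVCohort, simulate_sv_cohort
from .sv_catalog import Category, fetch_flanks, read_sv_table

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    seed: int = 0
    outdir: Optional[str] = None
    # input mode: either simulate (default) or load from files
    simulate: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    sv_table: Optional[str] = None
    reference: Optional[str] = None
    allowlist: Optional[str] = None
    group_table: Optional[str] = None
    rss: RSSConfig = field(default_factory=RSSConfig)
    min_anchor: int = 5
    junction_retained_len: int = 50
    max_rss_search: int = 200


def _load_inputs(cfg: RunConfig):
    if cfg.simulate:
        gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
        cohort = simulate_sv_cohort(gen)
        return cohort.svs, cohort.ref, cohort.allowlist, cohort.sample_groups, cohort
    import pyfaidx

    svs = read_sv_table(cfg.sv_table)
    ref = pyfaidx.Fasta(cfg.reference)
    allowlist = None
    if cfg.allowlist:
        df = pd.read_csv(cfg.allowlist, sep="\t")
        allowlist = list(df.itertuples(index=False, name=None))
    groups = None
    if cfg.group_table:
        gdf = pd.read_csv(cfg.group_table, sep="\t")
        groups = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
    return svs, ref, allowlist, groups, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and return (and optionally write) the report."""
    svs, ref, allowlist, groups, cohort = _load_inputs(cfg)
    logger.info("pipeline: %d SVs loaded", len(svs))

    classifications, clusters = classify_cohort(svs, ref, cfg.rss, allowlist=allowlist)
    status = {c.sv_id: c for c in classifications}

    junction_calls = []
    for sv in svs:
        flanks = fetch_flanks(sv, ref, retained_len=cfg.junction_retained_len)
        junction_calls.append(call_junction(sv, flanks, min_anchor=cfg.min_anchor))

    summaries, assoc = summarize_by_category(classifications, junction_calls, svs)

    # breakpoint-to-RSS distances for RSS+ cooperating SVs (both breakends)
    distances = []
    for sv in svs:
        cl = status[sv.sv_id]
        if sv.category is Category.COOPERATING and cl.status is RSSStatus.PLUS:
            for hit in (cl.best_hit_bnd1, cl.best_hit_bnd2):
                if hit is not None:
                    distances.append(hit.distance_bp)
    nb_fit = fit_negbin(distances) if len(distances) >= 10 else None

    per_sample, comparison = count_rag_per_sample(classifications, svs, group_map=groups)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "version": __version__,
        "seed": cfg.seed,
        "n_svs": len(svs),
        "n_clusters": len(clusters),
        "config": _jsonable(asdict(cfg)),
        "categories": [
            {
                "category": s.category.value,
                "n_total": s.n_total,
                "n_rss_plus": s.n_rss_plus,
                "frac_rss_plus": s.frac_rss_plus,
                "nts": {
                    st: {
                        "n_with_nts": n.n_with_nts,
                        "n_total": n.n_total,
                        "mean_len": n.mean_len,
                        "gc_fraction": n.gc_fraction,
                    }
                    for st, n in s.nts_by_status.items()
                },
            }
            for s in summaries
        ],
        "association": {
            "table": assoc.table.tolist(),
            "odds_ratio": _jsonable(assoc.odds_ratio),
            "p_value": assoc.p_value,
        },
        "negbin_fit": None
        if nb_fit is None
        else {
            "size_r": _jsonable(nb_fit.size_r),
            "prob_p": nb_fit.prob_p,
            "mean": nb_fit.mean,
            "loglik": nb_fit.loglik,
            "n": nb_fit.n,
            "poisson_fallback": nb_fit.poisson_fallback,
        },
        "per_sample_rag": [
            {"sample_id": c.sample_id, "n_rag_svs": c.n_rag_svs, "group": c.group_label}
            for c in per_sample
        ],
        "group_comparison": None
        if comparison is None
        else {
            "statistic": comparison.statistic,
            "p_value": comparison.p_value,
            "group_means": comparison.group_means,
        },
    }

    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_stage_tables(outdir, svs, classifications, junction_calls, per_sample)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        if cohort is not None:
            cohort.write(outdir / "simulated")
    return report


def _write_stage_tables(outdir, svs, classifications, junction_calls, per_sample):
    rows = []
    for cl in classifications:
        row = {
            "sv_id": cl.sv_id,
            "status": cl.status.value,
            "rule_applied": cl.rule_applied.value,
            "motifs_counted": cl.motifs_counted,
            "rescued_breakend": cl.rescued_breakend or "",
        }
        for side, hit in (("bnd1", cl.best_hit_bnd1), ("bnd2", cl.best_hit_bnd2)):
            row[f"{side}_motif"] = hit.motif_seq if hit else ""
            row[f"{side}_pos"] = hit.ref_pos if hit else ""
            row[f"{side}_deviations"] = hit.n_deviations if hit else ""
            row[f"{side}_distance"] = hit.distance_bp if hit else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "rss_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sv_id": c.sv_id,
                "kind": c.kind.value,
                "nts_seq": c.nts_seq,
                "nts_len": c.nts_len,
                "mh_len": c.mh_len,
                "gc_count": c.gc_count,
            }
            for c in junction_calls
        ]
    ).to_csv(outdir / "junctions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"sample_id": c.sample_id, "n_rag_svs": c.n_rag_svs, "group": c.group_label}
            for c in per_sample
        ]
    ).to_csv(outdir / "per_sample_rag.tsv", sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
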
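"""Cohort-level footprint statistics.

Aggregates per-SV RSS classifications and junction calls into the summaries
reported for a cohort: RSS+ fractions by SV category with an exact test of
association, NTS prevalence stratified by RSS status, a maximum-likelihood
negative-binomial fit of breakpoint-to-RSS distances, per-sample RAG-mediated
SV counts with a rank-sum group comparison, and generic nearest-interval
annotation (H3K4me3 peaks, chromatin states).

"RAG-mediated SV" is operationalized as category == cooperating AND
status == RSS+.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .junctions import JunctionCall, JunctionKind, NTSSummary, summarize_nts
from .rss import RSSClassification, RSSStatus
from .sv_catalog import Breakend, Category, SVRecord


@dataclass
class CategorySummary:
    category: Category
    n_total: int
    n_rss_plus: int
    frac_rss_plus: float
    nts_by_status: dict  # {"RSS_plus": NTSSummary, "RSS_minus": NTSSummary}


@dataclass
class AssociationTest:
    table: np.ndarray      # 2x2 [[coop RSS+, coop RSS-], [other RSS+, other RSS-]]
    odds_ratio: float      # sample (cross-product) odds ratio
    p_value: float         # two-sided Fisher exact


@dataclass
class NegBinFit:
    size_r: float
    prob_p: float
    mean: float
    loglik: float
    n: int
    poisson_fallback: bool = False

    def expected_counts(self, bin_edges: Sequence[int]) -> np.ndarray:
        """Expected counts per [edge_k, edge_{k+1}) bin for histogram overlay."""
        edges = np.asarray(bin_edges)
        if self.poisson_fallback:
            cdf = stats.poisson.cdf(edges - 1, self.mean)
        else:
            cdf = stats.nbinom.cdf(edges - 1, self.size_r, self.prob_p)
        return self.n * np.diff(cdf)


@dataclass
class SampleRAGCount:
    sample_id: str
    n_rag_svs: int
    group_label: Optional[str] = None


@dataclass
class GroupComparison:
    statistic: float   # Mann-Whitney U (group A vs B)
    p_value: float
    group_means: dict


def summarize_by_category(
    classifications: Sequence[RSSClassification],
    junction_calls: Sequence[JunctionCall],
    sv_records: Sequence[SVRecord],
) -> tuple[list[CategorySummary], AssociationTest]:
    """Per-category RSS+ fractions and NTS summaries, plus the 2x2 exact test
    of RSS status x category association."""
    status = {c.sv_id: c.status for c in classifications}
    calls = {c.sv_id: c for c in junction_calls}
    sv_ids = {sv.sv_id for sv in sv_records}
    orphans = (set(status) | set(calls)) - sv_ids
    missing = sv_ids - set(status)
    if orphans or missing:
        raise ValueError(
            f"sv_id mismatch: {len(orphans)} orphan classification/call id(s), "
            f"{len(missing)} SV(s) without classification: "
            f"{sorted(orphans | missing)[:5]}"
        )

    summaries = []
    for cat in Category:
        members = [sv for sv in sv_records if sv.category is cat]
        if not members:
            continue
        plus = [sv for sv in members if status[sv.sv_id] is RSSStatus.PLUS]
        nts_by_status = {}
        for st in RSSStatus:
            ids = {sv.sv_id for sv in members if status[sv.sv_id] is st}
            nts_by_status[st.value] = summarize_nts(
                [calls[i] for i in ids if i in calls]
            )
        summaries.append(
            CategorySummary(
                category=cat,
                n_total=len(members),
                n_rss_plus=len(plus),
                frac_rss_plus=len(plus) / len(members),
                nts_by_status=nts_by_status,
            )
        )

    coop = [sv for sv in sv_records if sv.category is Category.COOPERATING]
    other = [sv for sv in sv_records if sv.category is not Category.COOPERATING]
    a = sum(status[sv.sv_id] is RSSStatus.PLUS for sv in coop)
    b = len(coop) - a
    c = sum(status[sv.sv_id] is RSSStatus.PLUS for sv in other)
    d = len(other) - c
    table = np.array([[a, b], [c, d]])
    if min(b, c) == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return summaries, AssociationTest(table=table, odds_ratio=odds, p_value=p)


def _nb_loglik(distances: np.ndarray, r: float) -> float:
    p = r / (r + distances.mean())
    return float(stats.nbinom.logpmf(distances, r, p).sum())


def fit_negbin(distances: Sequence[int]) -> NegBinFit:
    """Maximum-likelihood negative-binomial fit of non-negative counts.

    For fixed size r the MLE of p matches the sample mean (p = r/(r+m)), so
    the fit profiles the likelihood over r only, started at the
    method-of-moments estimate.  Under-dispersed input (variance <= mean)
    falls back to the Poisson limit with a flag.
    """
    x = np.asarray(list(distances), dtype=float)
    if x.size < 10:
        raise ValueError("fit_negbin requires at least 10 observations")
    if np.unique(x).size < 2:
        m = float(x.mean())
        ll = float(stats.poisson.logpmf(x, m).sum())
        return NegBinFit(size_r=math.inf, prob_p=1.0, mean=m, loglik=ll,
                         n=x.size, poisson_fallback=True)
    m, v = float(x.mean()), float(x.var(ddof=1))
    if v <= m:
        ll = float(stats.poisson.logpmf(x, m).sum())
        return NegBinFit(size_r=math.inf, prob_p=1.0, mean=m, loglik=ll,
                         n=x.size, poisson_fallback=True)
    r_mom = m * m / (v - m)
    res = optimize.minimize_scalar(
        lambda log_r: -_nb_loglik(x, math.exp(log_r)),
        bracket=(math.log(r_mom) - 1.0, math.log(r_mom), math.log(r_mom) + 1.0),
        method="brent",
        options={"xtol": 1e-8},
    )
    r_hat = math.exp(res.x)
    p_hat = r_hat / (r_hat + m)
    ll = _nb_loglik(x, r_hat)
    # Profile likelihood can only improve on the method-of-moments start.
    assert ll >= _nb_loglik(x, r_mom) - 1e-6
    return NegBinFit(size_r=r_hat, prob_p=p_hat, mean=r_hat * (1 - p_hat) / p_hat,
                     loglik=ll, n=x.size)


def count_rag_per_sample(
    classifications: Sequence[RSSClassification],
    sv_records: Sequence[SVRecord],
    group_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[SampleRAGCount], Optional[GroupComparison]]:
    """Per-sample RAG-mediated SV counts (cooperating AND RSS+), with an
    optional two-group Wilcoxon rank-sum comparison when a group map with
    exactly two labels is supplied.  Samples absent from the map are counted
    with group_label None and excluded from the comparison."""
    status = {c.sv_id: c.status for c in classifications}
    counts: dict[str, int] = {}
    for sv in sv_records:
        counts.setdefault(sv.sample_id, 0)
        if sv.category is Category.COOPERATING and status[sv.sv_id] is RSSStatus.PLUS:
            counts[sv.sample_id] += 1
    out = [
        SampleRAGCount(
            sample_id=s, n_rag_svs=n,
            group_label=None if group_map is None else group_map.get(s),
        )
        for s, n in sorted(counts.items())
    ]
    comparison = None
    if group_map is not None:
        labels = sorted({c.group_label for c in out if c.group_label is not None})
        if len(labels) == 2:
            ga = [c.n_rag_svs for c in out if c.group_label == labels[0]]
            gb = [c.n_rag_svs for c in out if c.group_label == labels[1]]
            if ga and gb:
                u, p = stats.mannwhitneyu(ga, gb, alternative="two-sided")
                comparison = GroupComparison(
                    statistic=float(u), p_value=float(p),
                    group_means={labels[0]: float(np.mean(ga)),
                                 labels[1]: float(np.mean(gb))},
                )
    return out, comparison


def read_bed(path) -> pd.DataFrame:
    """Read a BED track (chrom, start, end[, name/state])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = cols
    if df.shape[1] > 3:
        df = df.rename(columns={"col3": "state"})
    return df


def annotate_with_intervals(
    breakends: Sequence[Breakend],
    bed: Union[pd.DataFrame, str],
) -> pd.DataFrame:
    """Nearest-feature distance and containing-interval label per breakend.

    Distance is 0 inside an interval (half-open [start, end)), otherwise the
    gap to the nearest edge; None when the contig is absent from the track.
    """
    if not isinstance(bed, pd.DataFrame):
        bed = read_bed(bed)
    has_state = "state" in bed.columns
    per_chrom = {}
    for chrom, grp in bed.groupby("chrom"):
        grp = grp.sort_values("start")
        per_chrom[chrom] = (
            grp["start"].to_numpy(), grp["end"].to_numpy(),
            grp["state"].to_numpy() if has_state else None,
        )
    rows = []
    for bnd in breakends:
        rec = {"chrom": bnd.chrom, "pos": bnd.pos, "distance": None, "state": None}
        if bnd.chrom in per_chrom:
            starts, ends, states = per_chrom[bnd.chrom]
            idx = np.searchsorted(starts, bnd.pos, side="right") - 1
            dist = math.inf
            if idx >= 0:
                if bnd.pos < ends[idx]:
                    dist = 0
                    if states is not None:
                        rec["state"] = states[idx]
                else:
                    dist = int(bnd.pos - ends[idx])
            if dist > 0 and idx + 1 < len(starts):
                dist = min(dist, int(starts[idx + 1] - bnd.pos))
            rec["distance"] = int(dist) if math.isfinite(dist) else None
        rows.append(rec)
    return pd.DataFrame(rows)
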
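"""Cryptic recombination-signal-sequence (RSS) detection at SV breakpoints.

The RAG1/2 endonuclease cleaves next to a conserved heptamer (canonical
``CACAGTG``).  Off-target RAG activity leaves RSS-like motifs immediately
*inside* both breakpoints of a structural variant, i.e. in the sequence lost
from the derivative allele.  This module scans the inside windows of each
breakend for heptamer matches at configurable tolerance, groups recurrent
breakpoints into clusters, and classifies every SV as RSS+ or RSS- using a
base rule (qualifying motif inside both breakpoints within 30 bp) plus four
ordered exception rules for less-conserved or more-distant motifs near
breakpoint clusters.

Orientation convention: the heptamer reads ``CACAGTG`` going away from the
breakpoint into the lost segment.  For a breakend whose inside direction runs
leftward, the motif therefore appears as ``CACTGTG`` on the forward strand and
is reported reverse-complemented (as read in scan orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .sv_catalog import (
    Breakend,
    FlankPair,
    RetainedSide,
    SVRecord,
    fetch_flanks,
    revcomp,
)

CANONICAL_HEPTAMER = "CACAGTG"


class Tolerance(str, Enum):
    STRICT = "strict_canonical"
    BASE = "base"
    RELAXED = "relaxed"


class RSSStatus(str, Enum):
    PLUS = "RSS_plus"
    MINUS = "RSS_minus"


class RuleApplied(str, Enum):
    BASE = "base"
    EXCEPTION1 = "exception1"
    EXCEPTION2 = "exception2"
    EXCEPTION3 = "exception3"
    EXCEPTION4 = "exception4"
    CLUSTER_RESCUE = "cluster_rescue"
    NONE = "none"


@dataclass
class RSSConfig:
    """Tunable scanning parameters (defaults documented in the methods note)."""

    base_window: int = 30          # bp searched inside each breakpoint
    extended_window: int = 100     # bp allowed under exceptions 2/3 (and 4)
    max_tail_mismatches: int = 2   # base tolerance: CACA + <=2 deviations in pos 5-7
    max_relaxed_mismatches: int = 3  # relaxed: CAC + <=3 deviations in pos 4-7
    scan_both_orientations: bool = False
    cluster_window: int = 300
    min_cluster_size: int = 3
    cluster_rss_fraction: float = 0.5  # member fraction with own motif => RSS+ cluster
    cluster_pad: int = 300         # "near a cluster" = within this of the span
    retained_len: int = 50


@dataclass(frozen=True)
class RSSHit:
    motif_seq: str        # 7-mer as read in scan orientation
    ref_pos: int          # forward-strand genomic start of the motif
    side: str             # "bnd1" | "bnd2"
    orientation: str      # "plus" | "minus"
    n_deviations: int     # bases differing from CACAGTG (in scan orientation)
    distance_bp: int      # breakpoint boundary -> proximal motif edge


@dataclass
class BreakpointCluster:
    chrom: str
    start: int
    end: int
    member_breakends: list  # (sample_id, pos) tuples
    allowlist_motif: Optional[str] = None
    rss_positive: Optional[bool] = None

    def near(self, bnd: Breakend, pad: int) -> bool:
        return (
            bnd.chrom == self.chrom
            and self.start - pad <= bnd.pos <= self.end + pad
        )


@dataclass
class RSSClassification:
    sv_id: str
    status: RSSStatus
    best_hit_bnd1: Optional[RSSHit]
    best_hit_bnd2: Optional[RSSHit]
    rule_applied: RuleApplied
    motifs_counted: int
    rescued_breakend: Optional[str] = None  # "bnd1"/"bnd2" qualifying without a motif
    flags: list = field(default_factory=list)


def match_heptamer(seq7: str, tolerance: Tolerance | str = Tolerance.BASE,
                   cfg: Optional[RSSConfig] = None) -> tuple[bool, int]:
    """Score a 7-mer against the canonical heptamer under a tolerance level.

    Returns ``(is_match, n_deviations)`` where deviations count all positions
    differing from ``CACAGTG`` (N always deviates).  ``strict_canonical``
    accepts only the exact heptamer; ``base`` requires the ``CACA`` prefix and
    at most ``max_tail_mismatches`` deviations among positions 5-7; ``relaxed``
    requires the ``CAC`` prefix and at most ``max_relaxed_mismatches``
    deviations among positions 4-7.
    """
    cfg = cfg or RSSConfig()
    tolerance = Tolerance(tolerance)
    if len(seq7) != 7:
        raise ValueError(f"heptamer must have length 7, got {len(seq7)}")
    seq7 = seq7.upper()
    devs = [a != b for a, b in zip(seq7, CANONICAL_HEPTAMER)]
    n_dev = sum(devs)
    if tolerance is Tolerance.STRICT:
        return n_dev == 0, n_dev
    if tolerance is Tolerance.BASE:
        ok = not any(devs[:4]) and sum(devs[4:]) <= cfg.max_tail_mismatches
        return ok, n_dev
    ok = not any(devs[:3]) and sum(devs[3:]) <= cfg.max_relaxed_mismatches
    return ok, n_dev


def scan_inside_window(
    window_seq: str,
    orientation: str,
    tolerance: Tolerance | str = Tolerance.BASE,
    cfg: Optional[RSSConfig] = None,
    ref_start: int = 0,
    side: str = "bnd1",
    max_distance: Optional[int] = None,
    exact_motif: Optional[str] = None,
) -> list[RSSHit]:
    """Scan one inside window for heptamer hits, nearest-first.

    ``orientation`` "minus" reverse-complements the window before scanning so
    offsets always measure distance from the breakpoint boundary.  The motif
    must lie entirely within ``max_distance`` of the breakpoint when given.
    ``exact_motif`` switches the match to a literal 7-mer (cluster allowlist).
    """
    cfg = cfg or RSSConfig()
    window_seq = window_seq.upper()
    length = len(window_seq)
    oriented = revcomp(window_seq) if orientation == "minus" else window_seq
    hits: list[RSSHit] = []
    for offset in range(0, length - 6):
        if max_distance is not None and offset + 7 > max_distance:
            break
        mer = oriented[offset : offset + 7]
        if "N" in mer:
            continue
        if exact_motif is not None:
            if mer != exact_motif:
                continue
            n_dev = sum(a != b for a, b in zip(mer, CANONICAL_HEPTAMER))
        else:
            ok, n_dev = match_heptamer(mer, tolerance, cfg)
            if not ok:
                continue
        if orientation == "minus":
            ref_pos = ref_start + length - offset - 7
        else:
            ref_pos = ref_start + offset
        hits.append(
            RSSHit(
                motif_seq=mer,
                ref_pos=ref_pos,
                side=side,
                orientation=orientation,
                n_deviations=n_dev,
                distance_bp=offset,
            )
        )
    hits.sort(key=lambda h: (h.distance_bp, h.n_deviations, h.ref_pos))
    return hits


def detect_breakpoint_clusters(
    svs: Sequence[SVRecord],
    cluster_window: int = 300,
    min_cluster_size: int = 3,
    allowlist: Optional[Sequence[tuple[str, int, int, str]]] = None,
) -> list[BreakpointCluster]:
    """Group recurrent breakends (pooled across samples) into clusters.

    Single-linkage on positions per contig: consecutive breakends closer than
    ``cluster_window`` join a cluster; clusters with fewer than
    ``min_cluster_size`` members are dropped.  ``allowlist`` entries
    ``(chrom, start, end, motif)`` attach a special heptamer to any
    overlapping cluster (e.g. CATACTG near a LEMD3-like cluster).
    """
    per_chrom: dict[str, list[tuple[int, str]]] = {}
    for sv in svs:
        for bnd in (sv.bnd1, sv.bnd2):
            per_chrom.setdefault(bnd.chrom, []).append((bnd.pos, sv.sample_id))
    clusters: list[BreakpointCluster] = []
    for chrom, items in per_chrom.items():
        items.sort()
        group: list[tuple[int, str]] = []
        for pos, sample in items:
            if group and pos - group[-1][0] > cluster_window:
                if len(group) >= min_cluster_size:
                    clusters.append(_make_cluster(chrom, group))
                group = []
            group.append((pos, sample))
        if len(group) >= min_cluster_size:
            clusters.append(_make_cluster(chrom, group))
    if allowlist:
        for chrom, start, end, motif in allowlist:
            for cl in clusters:
                if cl.chrom == chrom and cl.start <= end and start <= cl.end:
                    cl.allowlist_motif = motif.upper()
    return clusters


def _make_cluster(chrom: str, group: list[tuple[int, str]]) -> BreakpointCluster:
    return BreakpointCluster(
        chrom=chrom,
        start=min(p for p, _ in group),
        end=max(p for p, _ in group),
        member_breakends=[(s, p) for p, s in group],
    )


def _inside_windows(sv: SVRecord, ref, cfg: RSSConfig) -> FlankPair:
    return fetch_flanks(sv, ref, retained_len=cfg.retained_len, inside_len=cfg.extended_window)


def _scan_bnd(
    flanks: FlankPair,
    side: str,
    tolerance: Tolerance,
    cfg: RSSConfig,
    max_distance: int,
    exact_motif: Optional[str] = None,
) -> list[RSSHit]:
    seq = flanks.inside1_seq if side == "bnd1" else flanks.inside2_seq
    orient = flanks.inside1_orient if side == "bnd1" else flanks.inside2_orient
    start = flanks.inside1_ref_start if side == "bnd1" else flanks.inside2_ref_start
    hits = scan_inside_window(
        seq, orient, tolerance, cfg, ref_start=start, side=side,
        max_distance=max_distance, exact_motif=exact_motif,
    )
    if cfg.scan_both_orientations and exact_motif is None:
        other = "minus" if orient == "plus" else "plus"
        hits = hits + scan_inside_window(
            seq, other, tolerance, cfg, ref_start=start, side=side,
            max_distance=max_distance, exact_motif=exact_motif,
        )
        hits.sort(key=lambda h: (h.distance_bp, h.n_deviations, h.ref_pos))
    return hits


def _best(hits: list[RSSHit]) -> Optional[RSSHit]:
    return hits[0] if hits else None


def annotate_clusters_rss(
    clusters: Sequence[BreakpointCluster],
    svs: Sequence[SVRecord],
    ref,
    cfg: Optional[RSSConfig] = None,
) -> None:
    """Mark each cluster RSS+ when enough member breakends carry their own
    base-tolerance motif within the base window (fraction >=
    ``cfg.cluster_rss_fraction``)."""
    cfg = cfg or RSSConfig()
    bnd_hit: dict[tuple[str, int], bool] = {}
    for sv in svs:
        flanks = _inside_windows(sv, ref, cfg)
        for side, bnd in (("bnd1", sv.bnd1), ("bnd2", sv.bnd2)):
            key = (bnd.chrom, bnd.pos)
            if key in bnd_hit:
                continue
            hits = _scan_bnd(flanks, side, Tolerance.BASE, cfg, cfg.base_window)
            bnd_hit[key] = bool(hits)
    for cl in clusters:
        flags = [
            bnd_hit.get((cl.chrom, pos), False) for _, pos in cl.member_breakends
        ]
        cl.rss_positive = (sum(flags) / len(flags)) >= cfg.cluster_rss_fraction


def classify_rss_status(
    sv: SVRecord,
    ref,
    clusters: Sequence[BreakpointCluster] = (),
    cfg: Optional[RSSConfig] = None,
) -> RSSClassification:
    """Classify one SV as RSS+ or RSS- under the base rule and exceptions.

    Base rule: a base-tolerance heptamer entirely within the first
    ``base_window`` bp inside both breakpoints.  Exceptions, tried in order,
    first match wins:

    1. one breakpoint has a base-window motif; the other may carry a relaxed
       (``CAC``-prefix) variant within the base window;
    2. one breakpoint has a base-window motif; the other motif may lie
       further away, up to ``extended_window``;
    3. a breakpoint near a breakpoint cluster may have its motif up to
       ``extended_window`` away (both sides searched extended);
    4. a breakpoint near a cluster with an allowlisted less-conserved motif
       accepts that exact motif within ``extended_window``.

    Additionally, when one breakend carries a base-window motif *and* lies in
    an RSS+ cluster, the partner breakend may lack a motif entirely
    (``cluster_rescue``; motifs_counted is then 1).
    """
    cfg = cfg or RSSConfig()
    flanks = _inside_windows(sv, ref, cfg)
    if flanks.unscannable1 and flanks.unscannable2:
        return RSSClassification(
            sv_id=sv.sv_id, status=RSSStatus.MINUS, best_hit_bnd1=None,
            best_hit_bnd2=None, rule_applied=RuleApplied.NONE, motifs_counted=0,
            flags=["unscannable"],
        )

    base30 = {
        side: _scan_bnd(flanks, side, Tolerance.BASE, cfg, cfg.base_window)
        for side in ("bnd1", "bnd2")
    }
    if base30["bnd1"] and base30["bnd2"]:
        return _plus(sv, RuleApplied.BASE, _best(base30["bnd1"]), _best(base30["bnd2"]))

    relaxed30 = {
        side: _scan_bnd(flanks, side, Tolerance.RELAXED, cfg, cfg.base_window)
        for side in ("bnd1", "bnd2")
    }
    for anchor, other in (("bnd1", "bnd2"), ("bnd2", "bnd1")):
        if base30[anchor] and relaxed30[other]:
            hits = {anchor: _best(base30[anchor]), other: _best(relaxed30[other])}
            return _plus(sv, RuleApplied.EXCEPTION1, hits["bnd1"], hits["bnd2"])

    base_ext = {
        side: _scan_bnd(flanks, side, Tolerance.BASE, cfg, cfg.extended_window)
        for side in ("bnd1", "bnd2")
    }
    for anchor, other in (("bnd1", "bnd2"), ("bnd2", "bnd1")):
        if base30[anchor] and base_ext[other]:
            hits = {anchor: _best(base30[anchor]), other: _best(base_ext[other])}
            return _plus(sv, RuleApplied.EXCEPTION2, hits["bnd1"], hits["bnd2"])

    near = {
        side: [cl for cl in clusters if cl.near(bnd, cfg.cluster_pad)]
        for side, bnd in (("bnd1", sv.bnd1), ("bnd2", sv.bnd2))
    }
    if (near["bnd1"] or near["bnd2"]) and base_ext["bnd1"] and base_ext["bnd2"]:
        return _plus(sv, RuleApplied.EXCEPTION3, _best(base_ext["bnd1"]), _best(base_ext["bnd2"]))

    for side, other in (("bnd1", "bnd2"), ("bnd2", "bnd1")):
        motifs = [cl.allowlist_motif for cl in near[side] if cl.allowlist_motif]
        for motif in motifs:
            allow_hits = _scan_bnd(
                flanks, side, Tolerance.BASE, cfg, cfg.extended_window, exact_motif=motif
            )
            if allow_hits and base_ext[other]:
                hits = {side: _best(allow_hits), other: _best(base_ext[other])}
                return _plus(sv, RuleApplied.EXCEPTION4, hits["bnd1"], hits["bnd2"])

    # Cluster rescue: reaching this point with a base-window motif at the
    # anchor means the partner breakend has no qualifying hit under any rule
    # (exceptions 1/2 would have fired otherwise).
    for anchor, other in (("bnd1", "bnd2"), ("bnd2", "bnd1")):
        if not base30[anchor]:
            continue
        in_plus_cluster = any(cl.rss_positive for cl in near[anchor])
        if in_plus_cluster:
            hit = _best(base30[anchor])
            return RSSClassification(
                sv_id=sv.sv_id,
                status=RSSStatus.PLUS,
                best_hit_bnd1=hit if anchor == "bnd1" else None,
                best_hit_bnd2=hit if anchor == "bnd2" else None,
                rule_applied=RuleApplied.CLUSTER_RESCUE,
                motifs_counted=1,
                rescued_breakend=other,
            )

    return RSSClassification(
        sv_id=sv.sv_id, status=RSSStatus.MINUS, best_hit_bnd1=_best(base_ext["bnd1"]),
        best_hit_bnd2=_best(base_ext["bnd2"]), rule_applied=RuleApplied.NONE,
        motifs_counted=0,
    )


def _plus(sv: SVRecord, rule: RuleApplied, hit1: Optional[RSSHit],
          hit2: Optional[RSSHit]) -> RSSClassification:
    return RSSClassification(
        sv_id=sv.sv_id,
        status=RSSStatus.PLUS,
        best_hit_bnd1=hit1,
        best_hit_bnd2=hit2,
        rule_applied=rule,
        motifs_counted=int(hit1 is not None) + int(hit2 is not None),
    )


def classify_cohort(
    svs: Sequence[SVRecord],
    ref,
    cfg: Optional[RSSConfig] = None,
    allowlist: Optional[Sequence[tuple[str, int, int, str]]] = None,
) -> tuple[list[RSSClassification], list[BreakpointCluster]]:
    """Cluster detection + RSS+ annotation + per-SV classification."""
    cfg = cfg or RSSConfig()
    clusters = detect_breakpoint_clusters(
        svs, cfg.cluster_window, cfg.min_cluster_size, allowlist=allowlist
    )
    annotate_clusters_rss(clusters, svs, ref, cfg)
    return [classify_rss_status(sv, ref, clusters, cfg) for sv in svs], clusters


def distance_to_nearest_rss(
    bnd: Breakend, ref, max_search: int = 200, cfg: Optional[RSSConfig] = None
) -> Optional[int]:
    """Distance (bp) from a breakend to the nearest inside base-tolerance
    heptamer, or None if none lies within ``max_search``."""
    cfg = cfg or RSSConfig()
    from .sv_catalog import _fetch_window

    if bnd.inside_is_right:
        seq, _ = _fetch_window(ref, bnd.chrom, bnd.pos, bnd.pos + max_search)
        orient, start = "plus", bnd.pos
    else:
        seq, _ = _fetch_window(ref, bnd.chrom, bnd.pos - max_search, bnd.pos)
        orient, start = "minus", max(bnd.pos - max_search, 0)
    hits = scan_inside_window(seq, orient, Tolerance.BASE, cfg, ref_start=start)
    return hits[0].distance_bp if hits else None


def heptamer_pfm(classifications: Iterable[RSSClassification]):
    """Position-frequency matrix (7 x ACGT) over counted best-hit motifs.

    Motifs are already orientation-normalized (as read in scan orientation),
    so canonical right-side RSS contribute ``CACAGTG`` columns.
    """
    import numpy as np

    order = "ACGT"
    pfm = np.zeros((7, 4), dtype=int)
    n = 0
    for cl in classifications:
        for hit in (cl.best_hit_bnd1, cl.best_hit_bnd2):
            if hit is None:
                continue
            for i, b in enumerate(hit.motif_seq):
                if b in order:
                    pfm[i, order.index(b)] += 1
            n += 1
    if n == 0:
        raise ValueError("heptamer_pfm requires at least one counted motif")
    return pfm


def pfm_to_transfac(pfm, name: str = "cryptic_RSS") -> str:
    lines = [f"ID {name}", "BF synthetic", "P0      A      C      G      T"]
    for i, row in enumerate(pfm, start=1):
        lines.append(f"{i:02d} {row[0]:6d} {row[1]:6d} {row[2]:6d} {row[3]:6d}")
    lines.append("XX\n//")
    return "\n".join(lines)
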
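"""Seeded generators for synthetic cohorts with planted truth.

The SV generator emulates the mutational footprints the analyses assume:

* RAG-mediated SVs (category ``cooperating``): breakpoints placed so that a
  planted heptamer lies inside each breakpoint at a negative-binomially
  distributed offset (defaults r=1, p=0.1, putting ~96% of motifs within
  30 bp), with TdT-style non-template insertions in 94.2% of junctions
  (length 1+Poisson(mean-1), G:C-biased bases);
* non-RAG cooperating SVs: breakpoints away from planted motifs, NTS in
  65.5% of junctions (mean 5.93), microhomology otherwise;
* translocation-like SVs (category ``bcr_abl1_associated``): inter-contig
  breakend pairs, clean junctions in 91.8%, short NTS (mean 2.55) otherwise,
  and planted RSS pairs in 8.2% of events.

Breakpoint clusters (shared hotspots across samples) are planted, including
one cluster whose motif is the less-conserved allowlisted ``CATACTG`` and two
SVs whose partner breakpoint carries no motif at all (cluster rescue).  The
single-cell and response generators plant per-cell phase/lineage labels and
per-patient log-reduction trajectories.  Every entity has exactly one truth
entry; identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .response import Measurement, ResponseSeries
from .rss import CANONICAL_HEPTAMER, RSSConfig, Tolerance, match_heptamer
from .sc_metrics import CellMatrix
from .sv_catalog import (
    Breakend,
    Category,
    RetainedSide,
    SVRecord,
    SVType,
    revcomp,
    write_sv_table,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------
@dataclass
class GeneratorConfig:
    seed: int = 0
    ref_length: int = 3_000_000        # main contig (chrA); chrB is 1/5 of it
    gc_content: float = 0.41
    n_rag_svs: int = 390
    n_nonrag_svs: int = 110
    n_translocation_svs: int = 150
    rss_offset_nb: tuple = (1.0, 0.1)  # (r, p); mean 9 bp, ~96% within 30 bp
    rss_offset_cap: int = 90
    p_nts_rag: float = 0.942
    nts_len_mean_rag: float = 5.58
    p_gc_nts: float = 2.0 / 3.0
    p_nts_nonrag: float = 0.655
    nts_len_mean_nonrag: float = 5.93
    p_clean_translocation: float = 0.918
    nts_len_mean_translocation: float = 2.55
    p_rss_translocation: float = 0.082
    background_rss_density: float = 0.05  # planted decoy motifs per kb
    p_variant_motif: float = 0.25      # planted motifs with one tail deviation
    p_relaxed_motif2: float = 0.10     # second motif only CAC-conserved
    junction_arm: int = 25
    slot_width: int = 2400
    n_samples_group_a: int = 25        # e.g. SLX4IP-deleted samples
    n_samples_group_b: int = 25
    rag_enrichment_a: float = 2.0      # RAG-SV weight ratio group A : group B
    n_cluster_svs: tuple = (5, 4, 4)   # two plain clusters + one allowlist cluster
    n_rescued: int = 2                 # motif-less partner breakpoints planted
    # --- single-cell ------------------------------------------------------
    sc_samples: tuple = (
        ("early1", "Early-Pro"), ("early2", "Early-Pro"),
        ("early3", "Early-Pro"), ("early4", "Early-Pro"),
        ("inter1", "Inter-Pro"),
        ("late1", "Late-Pro"), ("late2", "Late-Pro"),
        ("late3", "Late-Pro"), ("late4", "Late-Pro"),
    )
    sc_cells_per_sample: int = 220
    sc_phase_fractions: dict = field(default_factory=lambda: {
        "Early-Pro": (0.05, 0.03),    # (G1S, G2M) -> cycling 8%
        "Inter-Pro": (0.013, 0.007),  # cycling 2%
        "Late-Pro": (0.15, 0.08),     # cycling 23%
    })
    sc_lineage_profiles: dict = field(default_factory=lambda: {
        "Early-Pro": {"early-pro-B": 0.42, "GMP": 0.26, "pro-B": 0.10,
                      "pre-B-I": 0.12, "LMPP": 0.05, "MLP": 0.05},
        "Inter-Pro": {"early-pro-B": 0.214, "pro-B": 0.366, "pre-B-I": 0.405,
                      "LMPP": 0.015},
        "Late-Pro": {"pro-B": 0.68, "pre-B-I": 0.27, "early-pro-B": 0.05},
    })
    sc_qc_fail_fraction: float = 0.10
    sc_contaminant_per_sample: int = 12
    sc_n_background_genes: int = 1600
    # --- residual disease -------------------------------------------------
    response_profiles: dict = field(default_factory=lambda: {
        # subtype: (n_patients, median_first_lr, mmr_rate, top_lr)
        "Early-Pro": (20, 1.4, 0.10, 3.9),
        "Inter-Pro": (12, 2.2, 0.17, 3.9),
        "Late-Pro": (25, 3.5, 0.56, 5.0),
    })
    detection_limit_lr: float = 5.0


# --------------------------------------------------------------------------
# Truth registry
# --------------------------------------------------------------------------
@dataclass
class SVTruth:
    sv_id: str
    sample_id: str
    category: str
    is_rag: bool
    rss_planted: bool
    motif1: Optional[str] = None
    motif2: Optional[str] = None
    d1: Optional[int] = None
    d2: Optional[int] = None
    junction_kind: str = "clean"
    nts_seq: str = ""
    mh_len: int = 0
    rescue_planted: bool = False
    cluster_id: Optional[str] = None
    allowlist_cluster: bool = False


@dataclass
class SVCohort:
    ref: dict                 # contig -> sequence string
    svs: list                 # SVRecord
    truth: dict               # sv_id -> SVTruth
    allowlist: list           # (chrom, start, end, motif)
    sample_groups: dict       # sample_id -> group label
    background_motifs: list   # (chrom, pos, strand, motif)
    config: GeneratorConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.ref, outdir / "reference.fa")
        write_sv_table(self.svs, outdir / "svs.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({k: asdict(v) for k, v in self.truth.items()}, fh, indent=1)
        pd.DataFrame(self.allowlist, columns=["chrom", "start", "end", "motif"]).to_csv(
            outdir / "allowlist.tsv", sep="\t", index=False
        )
        pd.Series(self.sample_groups).rename("group").rename_axis("sample_id").to_csv(
            outdir / "sample_groups.tsv", sep="\t"
        )


def write_fasta(ref: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ref.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# --------------------------------------------------------------------------
# Reference builder
# --------------------------------------------------------------------------
class RefBuilder:
    """Mutable random reference; motifs/homologies are planted by overwrite."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        gc = cfg.gc_content
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        self.contigs = {
            "chrA": rng.choice(BASES, size=cfg.ref_length, p=p),
            "chrB": rng.choice(BASES, size=max(cfg.ref_length // 5, 50_000), p=p),
        }

    def plant(self, chrom: str, pos: int, seq: str) -> None:
        arr = np.frombuffer(seq.encode(), dtype="S1")
        self.contigs[chrom][pos : pos + len(seq)] = arr

    def get(self, chrom: str, start: int, end: int) -> str:
        return self.contigs[chrom][max(start, 0) : end].tobytes().decode()

    def set_base(self, chrom: str, pos: int, base: str) -> None:
        self.contigs[chrom][pos] = base.encode()

    def finalize(self) -> dict:
        return {c: a.tobytes().decode() for c, a in self.contigs.items()}


def _random_seq(rng: np.random.Generator, n: int, p_gc: float = 0.5) -> str:
    p = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def _draw_motif(rng: np.random.Generator, cfg: GeneratorConfig,
                allow_relaxed: bool = False) -> str:
    """Canonical heptamer, a 1-tail-deviation variant, or (second motifs
    only) a relaxed CAC-conserved variant."""
    u = rng.random()
    motif = list(CANONICAL_HEPTAMER)
    if allow_relaxed and u < cfg.p_relaxed_motif2:
        pos = 3
        motif[pos] = rng.choice([b for b in "CGT"])
        return "".join(motif)
    if u < cfg.p_relaxed_motif2 * allow_relaxed + cfg.p_variant_motif:
        pos = int(rng.integers(4, 7))
        motif[pos] = rng.choice([b for b in "ACGT" if b != motif[pos]])
    return "".join(motif)


def _draw_offset(rng: np.random.Generator, cfg: GeneratorConfig,
                 cap: Optional[int] = None) -> int:
    r, p = cfg.rss_offset_nb
    d = int(rng.negative_binomial(r, p))
    cap = cfg.rss_offset_cap if cap is None else cap
    return min(d, cap)


def _draw_nts(rng: np.random.Generator, mean_len: float, p_gc: float) -> str:
    n = 1 + int(rng.poisson(max(mean_len - 1.0, 0.0)))
    return _random_seq(rng, n, p_gc=p_gc)


def _plant_inside_motif(builder: RefBuilder, chrom: str, pos: int,
                        inside_right: bool, d: int, motif: str) -> None:
    """Plant a heptamer reading breakpoint-outward at offset d inside."""
    if inside_right:
        builder.plant(chrom, pos + d, motif)
    else:
        builder.plant(chrom, pos - d - 7, revcomp(motif))


def _scrub_inside(builder: RefBuilder, chrom: str, pos: int, inside_right: bool,
                  window: int, rng: np.random.Generator) -> None:
    """Remove relaxed-tolerance heptamer matches from an inside window so a
    planted motif-less breakpoint stays motif-less."""
    cfg = RSSConfig()
    for _ in range(20):
        if inside_right:
            w = builder.get(chrom, pos, pos + window)
            oriented = w
        else:
            w = builder.get(chrom, pos - window, pos)
            oriented = revcomp(w)
        dirty = False
        for off in range(len(oriented) - 6):
            mer = oriented[off : off + 7]
            ok, _ = match_heptamer(mer, Tolerance.RELAXED, cfg)
            if not ok:
                continue
            dirty = True
            # break the CAC prefix: oriented index 1 ('A') -> 'T'
            if inside_right:
                builder.set_base(chrom, pos + off + 1, "T")
            else:
                builder.set_base(chrom, pos - off - 2, "A")  # complements to 'T'
        if not dirty:
            return


# --------------------------------------------------------------------------
# SV cohort generation
# --------------------------------------------------------------------------
class _SlotAllocator:
    """Disjoint SV placement slots; optional contiguous regions reserved at
    the contig start (for planted breakpoint clusters)."""

    def __init__(self, contig_len: int, width: int, margin: int,
                 rng: np.random.Generator, n_regions: int = 0,
                 region_width: int = 12_000):
        self.regions = [margin + i * (region_width + 500) for i in range(n_regions)]
        first_slot = margin + n_regions * (region_width + 500)
        starts = np.arange(first_slot, contig_len - margin - width, width)
        rng.shuffle(starts)
        self._starts = list(starts)
        self.width = width

    def take(self) -> int:
        return int(self._starts.pop())

    def take_region(self) -> int:
        return int(self.regions.pop(0))


def _assemble_junction(builder: RefBuilder, sv_chroms: tuple, p: int, q: int,
                       middle: str, arm: int, right_skip: int = 0) -> str:
    left = builder.get(sv_chroms[0], p - arm, p)
    right = builder.get(sv_chroms[1], q + right_skip, q + right_skip + arm)
    return left + middle + right


def simulate_sv_cohort(cfg: GeneratorConfig,
                       rng: Optional[np.random.Generator] = None) -> SVCohort:
    """Generate the full SV cohort: reference, RAG / non-RAG / translocation
    SVs, planted clusters (incl. allowlist + rescue cases), and truth."""
    rng = rng or np.random.default_rng(cfg.seed)
    builder = RefBuilder(cfg, rng)
    samples_a = [f"PhA{i:02d}" for i in range(cfg.n_samples_group_a)]
    samples_b = [f"PhB{i:02d}" for i in range(cfg.n_samples_group_b)]
    sample_groups = {s: "group_a" for s in samples_a}
    sample_groups.update({s: "group_b" for s in samples_b})
    all_samples = samples_a + samples_b
    rag_weights = np.array(
        [cfg.rag_enrichment_a] * len(samples_a) + [1.0] * len(samples_b)
    )
    rag_weights = rag_weights / rag_weights.sum()
    uniform_weights = np.full(len(all_samples), 1.0 / len(all_samples))

    margin = 300
    alloc_a = _SlotAllocator(len(builder.contigs["chrA"]), cfg.slot_width, margin,
                             rng, n_regions=3)
    alloc_b = _SlotAllocator(len(builder.contigs["chrB"]), cfg.slot_width, margin, rng)

    # background decoy motifs (outside SV inside-windows, enforced by
    # rejection during SV placement below)
    background: list = []
    for chrom, arr in builder.contigs.items():
        n_bg = rng.poisson(cfg.background_rss_density * len(arr) / 1000.0)
        for pos in sorted(rng.integers(100, len(arr) - 100, size=n_bg).tolist()):
            motif = _draw_motif(rng, cfg)
            strand = "+" if rng.random() < 0.5 else "-"
            builder.plant(chrom, pos, motif if strand == "+" else revcomp(motif))
            background.append((chrom, int(pos), strand, motif))
    bg_positions = {}
    for chrom, pos, _, _ in background:
        bg_positions.setdefault(chrom, []).append(pos)
    bg_positions = {c: np.array(sorted(v)) for c, v in bg_positions.items()}

    def _bg_clear(chrom: str, pos: int, inside_right: bool, window: int = 110) -> bool:
        if chrom not in bg_positions:
            return True
        lo, hi = (pos - 8, pos + window) if inside_right else (pos - window - 8, pos + 8)
        arr = bg_positions[chrom]
        i = np.searchsorted(arr, lo)
        return not (i < arr.size and arr[i] <= hi)

    svs: list[SVRecord] = []
    truth: dict[str, SVTruth] = {}
    sv_counter = [0]

    def _new_id(prefix: str) -> str:
        sv_counter[0] += 1
        return f"{prefix}{sv_counter[0]:04d}"

    def _rag_junction(p: int, q: int, sample: str, sv_id: str,
                      chroms=("chrA", "chrA")) -> tuple[str, str, str]:
        if rng.random() < cfg.p_nts_rag:
            nts = _draw_nts(rng, cfg.nts_len_mean_rag, cfg.p_gc_nts)
            return _assemble_junction(builder, chroms, p, q, nts, cfg.junction_arm), "NTS", nts
        return _assemble_junction(builder, chroms, p, q, "", cfg.junction_arm), "clean", ""

    def _add_rag_sv(p: int, q: int, sample: str, d1: int, d2: int,
                    motif1: Optional[str], motif2: Optional[str],
                    cluster_id: Optional[str] = None,
                    allowlist_cluster: bool = False,
                    rescue: bool = False) -> None:
        sv_id = _new_id("RAG")
        if motif1 is not None:
            _plant_inside_motif(builder, "chrA", p, True, d1, motif1)
        if motif2 is not None:
            _plant_inside_motif(builder, "chrA", q, False, d2, motif2)
        if rescue:
            _scrub_inside(builder, "chrA", q, False, 110, rng)
        junction, kind, nts = _rag_junction(p, q, sample, sv_id)
        svs.append(
            SVRecord(
                sv_id=sv_id, sample_id=sample, sv_type=SVType.DEL,
                bnd1=Breakend("chrA", p, RetainedSide.LEFT),
                bnd2=Breakend("chrA", q, RetainedSide.RIGHT),
                category=Category.COOPERATING, junction_seq=junction,
            )
        )
        truth[sv_id] = SVTruth(
            sv_id=sv_id, sample_id=sample, category=Category.COOPERATING.value,
            is_rag=True, rss_planted=True, motif1=motif1, motif2=motif2,
            d1=d1 if motif1 else None, d2=d2 if motif2 else None,
            junction_kind=kind, nts_seq=nts, rescue_planted=rescue,
            cluster_id=cluster_id, allowlist_cluster=allowlist_cluster,
        )

    # ---- planted breakpoint clusters ------------------------------------
    allowlist: list = []
    n_cl_a, n_cl_b, n_cl_allow = cfg.n_cluster_svs
    if cfg.n_rag_svs < n_cl_a + n_cl_b + n_cl_allow:
        n_cl_a = n_cl_b = n_cl_allow = 0  # too few RAG SVs to plant hotspots
    cluster_samples = rng.choice(all_samples, size=n_cl_a + n_cl_b + n_cl_allow,
                                 p=rag_weights).tolist()
    csi = 0
    rescued_left = cfg.n_rescued

    for cname, n_members in (("clusterA", n_cl_a), ("clusterB", n_cl_b)):
        region = alloc_a.take_region()
        c0 = region + 600
        for i in range(n_members):
            p = c0 + i * 55
            q = p + 1500 + i * 1700
            d1 = min(_draw_offset(rng, cfg), 20)
            d2 = _draw_offset(rng, cfg)
            motif1 = _draw_motif(rng, cfg)
            rescue = rescued_left > 0 and i == 0
            if rescue:
                rescued_left -= 1
                motif2 = None
            else:
                motif2 = _draw_motif(rng, cfg, allow_relaxed=True)
            _add_rag_sv(p, q, cluster_samples[csi], d1, d2, motif1, motif2,
                        cluster_id=cname, rescue=rescue)
            csi += 1

    # allowlist cluster: recurrent bnd2 hotspot carrying CATACTG
    region = alloc_a.take_region()
    c2 = region + 9000
    allow_motif = "CATACTG"
    # plant everything first: the bnd2 hotspots sit 60 bp apart, so a later
    # member's scrub/plant would otherwise mutate an earlier member's
    # already-assembled junction arm
    allow_geom = []
    for i in range(n_cl_allow):
        q = c2 + i * 60
        p = q - (1500 + i * 1700)
        d1 = min(_draw_offset(rng, cfg), 20)
        d2 = min(_draw_offset(rng, cfg), 50)
        motif1 = _draw_motif(rng, cfg)
        _scrub_inside(builder, "chrA", q, False, 110, rng)
        _plant_inside_motif(builder, "chrA", q, False, d2, allow_motif)
        _plant_inside_motif(builder, "chrA", p, True, d1, motif1)
        allow_geom.append((p, q, d1, d2, motif1))
    for p, q, d1, d2, motif1 in allow_geom:
        sv_id = _new_id("RAG")
        junction, kind, nts = _rag_junction(p, q, cluster_samples[csi], sv_id)
        svs.append(
            SVRecord(
                sv_id=sv_id, sample_id=cluster_samples[csi], sv_type=SVType.DEL,
                bnd1=Breakend("chrA", p, RetainedSide.LEFT),
                bnd2=Breakend("chrA", q, RetainedSide.RIGHT),
                category=Category.COOPERATING, junction_seq=junction,
            )
        )
        truth[sv_id] = SVTruth(
            sv_id=sv_id, sample_id=cluster_samples[csi],
            category=Category.COOPERATING.value, is_rag=True, rss_planted=True,
            motif1=motif1, motif2=allow_motif, d1=d1, d2=d2,
            junction_kind=kind, nts_seq=nts, cluster_id="clusterAllow",
            allowlist_cluster=True,
        )
        csi += 1
    if n_cl_allow:
        allowlist.append(("chrA", int(c2 - 150), int(c2 + n_cl_allow * 60 + 150), allow_motif))

    # ---- independent RAG SVs --------------------------------------------
    n_free_rag = cfg.n_rag_svs - (n_cl_a + n_cl_b + n_cl_allow)
    rag_samples = rng.choice(all_samples, size=n_free_rag, p=rag_weights).tolist()
    for sample in rag_samples:
        slot = alloc_a.take()
        for _ in range(20):
            p = slot + 700 + int(rng.integers(0, 200))
            q = p + int(rng.integers(800, 1400))
            if _bg_clear("chrA", p, True) and _bg_clear("chrA", q, False):
                break
        d1 = _draw_offset(rng, cfg)
        d2 = _draw_offset(rng, cfg)
        motif1 = _draw_motif(rng, cfg)
        motif2 = _draw_motif(rng, cfg, allow_relaxed=True)
        _add_rag_sv(p, q, sample, d1, d2, motif1, motif2)

    # ---- non-RAG cooperating SVs ----------------------------------------
    nonrag_samples = rng.choice(all_samples, size=cfg.n_nonrag_svs,
                                p=uniform_weights).tolist()
    for sample in nonrag_samples:
        slot = alloc_a.take()
        for _ in range(20):
            p = slot + 700 + int(rng.integers(0, 400))
            q = p + int(rng.integers(800, 1400))
            if _bg_clear("chrA", p, True) and _bg_clear("chrA", q, False):
                break
        sv_id = _new_id("NRG")
        if rng.random() < cfg.p_nts_nonrag:
            nts = _draw_nts(rng, cfg.nts_len_mean_nonrag, cfg.p_gc_nts)
            junction = _assemble_junction(builder, ("chrA", "chrA"), p, q, nts,
                                          cfg.junction_arm)
            kind, mh = "NTS", 0
        else:
            mh = 1 + int(rng.poisson(1.5))
            mh = min(mh, 8)
            builder.plant("chrA", q, builder.get("chrA", p - mh, p))
            junction = _assemble_junction(builder, ("chrA", "chrA"), p, q, "",
                                          cfg.junction_arm, right_skip=mh)
            kind, nts = "microhomology", ""
        svs.append(
            SVRecord(
                sv_id=sv_id, sample_id=sample, sv_type=SVType.DEL,
                bnd1=Breakend("chrA", p, RetainedSide.LEFT),
                bnd2=Breakend("chrA", q, RetainedSide.RIGHT),
                category=Category.COOPERATING, junction_seq=junction,
            )
        )
        truth[sv_id] = SVTruth(
            sv_id=sv_id, sample_id=sample, category=Category.COOPERATING.value,
            is_rag=False, rss_planted=False, junction_kind=kind,
            nts_seq=nts, mh_len=mh,
        )

    # ---- translocation-like SVs -----------------------------------------
    tx_samples = rng.choice(all_samples, size=cfg.n_translocation_svs,
                            p=uniform_weights).tolist()
    for sample in tx_samples:
        slot_a = alloc_a.take()
        slot_b = alloc_b.take()
        for _ in range(20):
            p = slot_a + 700 + int(rng.integers(0, 400))
            q = slot_b + 700 + int(rng.integers(0, 400))
            if _bg_clear("chrA", p, True) and _bg_clear("chrB", q, False):
                break
        sv_id = _new_id("CTX")
        rss_planted = rng.random() < cfg.p_rss_translocation
        d1 = d2 = motif1 = motif2 = None
        if rss_planted:
            d1 = min(_draw_offset(rng, cfg), 20)
            d2 = min(_draw_offset(rng, cfg), 20)
            motif1 = _draw_motif(rng, cfg)
            motif2 = _draw_motif(rng, cfg)
            _plant_inside_motif(builder, "chrA", p, True, d1, motif1)
            _plant_inside_motif(builder, "chrB", q, False, d2, motif2)
        if rng.random() < cfg.p_clean_translocation:
            kind, nts = "clean", ""
        else:
            kind = "NTS"
            nts = _draw_nts(rng, cfg.nts_len_mean_translocation, cfg.p_gc_nts)
        junction = _assemble_junction(builder, ("chrA", "chrB"), p, q, nts,
                                      cfg.junction_arm)
        svs.append(
            SVRecord(
                sv_id=sv_id, sample_id=sample, sv_type=SVType.CTX,
                bnd1=Breakend("chrA", p, RetainedSide.LEFT),
                bnd2=Breakend("chrB", q, RetainedSide.RIGHT),
                category=Category.BCR_ABL1, junction_seq=junction,
            )
        )
        truth[sv_id] = SVTruth(
            sv_id=sv_id, sample_id=sample, category=Category.BCR_ABL1.value,
            is_rag=False, rss_planted=rss_planted, motif1=motif1, motif2=motif2,
            d1=d1, d2=d2, junction_kind=kind, nts_seq=nts,
        )

    return SVCohort(
        ref=builder.finalize(), svs=svs, truth=truth, allowlist=allowlist,
        sample_groups=sample_groups, background_motifs=background, config=cfg,
    )


# --------------------------------------------------------------------------
# Single-cell generation
# --------------------------------------------------------------------------
MITO_GENES = [f"MT-G{i}" for i in range(1, 14)]
RIBO_GENES = [f"RPL{i}" for i in range(1, 11)] + [f"RPS{i}" for i in range(1, 11)]
MARKER_GENES = ["DNTT", "LYZ", "GZMH", "IL32", "CD3E", "CD3G", "CD8A"]
G1S_GENES = [f"G1S-{i:02d}" for i in range(1, 21)]
G2M_GENES = [f"G2M-{i:02d}" for i in range(1, 21)]


def _nb_counts(rng, mean, r, size):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    p = r / (r + np.maximum(mean, 1e-9))
    return rng.negative_binomial(r, p, size=size)


def gen_sc_matrix(cfg: GeneratorConfig,
                  rng: Optional[np.random.Generator] = None):
    """Synthetic UMI matrix with planted QC failures, non-leukemic
    contaminants, cell-cycle phases and lineage labels.

    Returns ``(matrix, truth, gene_sets, cluster_labels)`` where truth is a
    per-cell DataFrame (sample, phase, lineage, qc_fail, non_leukemic).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    genes = (
        [f"BG{i:04d}" for i in range(cfg.sc_n_background_genes)]
        + MITO_GENES + RIBO_GENES + MARKER_GENES + G1S_GENES + G2M_GENES
    )
    gi = {g: j for j, g in enumerate(genes)}
    rows, cells, records, cluster_labels = [], [], [], {}

    for sample, subtype in cfg.sc_samples:
        n_leuk = cfg.sc_cells_per_sample
        n_cont = cfg.sc_contaminant_per_sample
        f_g1s, f_g2m = cfg.sc_phase_fractions[subtype]
        lineages = list(cfg.sc_lineage_profiles[subtype].items())
        lineage_names = [k for k, _ in lineages]
        lineage_p = np.array([v for _, v in lineages])
        lineage_p = lineage_p / lineage_p.sum()
        n_qc = int(round(cfg.sc_qc_fail_fraction * n_leuk))
        qc_reasons = [("mito", "ribo", "lowcomplexity")[i % 3] for i in range(n_qc)]

        # exact planted phase counts among QC-passing leukemic cells
        n_pass = n_leuk - n_qc
        n_g1s = int(round(f_g1s * n_pass))
        n_g2m = int(round(f_g2m * n_pass))
        phases = (["G1S"] * n_g1s + ["G2M"] * n_g2m + ["G0"] * (n_pass - n_g1s - n_g2m))
        rng.shuffle(phases)

        specs = []
        for i in range(n_pass):
            specs.append(dict(phase=phases[i], qc_fail="", non_leukemic=False))
        for reason in qc_reasons:
            specs.append(dict(phase="G0", qc_fail=reason, non_leukemic=False))
        for i in range(n_cont):
            specs.append(dict(phase="G0", qc_fail="", non_leukemic=True))
        rng.shuffle(specs)

        for k, spec in enumerate(specs):
            cell = f"{sample}_c{k:04d}"
            lineage = str(rng.choice(lineage_names, p=lineage_p))
            row = np.zeros(len(genes), dtype=int)
            scale = 0.12 if spec["qc_fail"] == "lowcomplexity" else 1.0
            row[: cfg.sc_n_background_genes] = _nb_counts(
                rng, 2.2 * scale, 2.0, cfg.sc_n_background_genes
            )
            mito_mean = 17.0 * (25.0 if spec["qc_fail"] == "mito" else 1.0) * scale
            ribo_mean = 35.0 * (12.0 if spec["qc_fail"] == "ribo" else 1.0) * scale
            row[[gi[g] for g in MITO_GENES]] = _nb_counts(rng, mito_mean, 2.0, len(MITO_GENES))
            row[[gi[g] for g in RIBO_GENES]] = _nb_counts(rng, ribo_mean, 2.0, len(RIBO_GENES))
            # leukemic marker pattern
            if spec["non_leukemic"]:
                row[gi["DNTT"]] = 0
                bad = str(rng.choice(["LYZ", "GZMH", "IL32", "CD3E"]))
                row[gi[bad]] = 2 + int(rng.poisson(3))
            else:
                row[gi["DNTT"]] = 1 + int(rng.poisson(2))
            g1s_mean = 18.0 if spec["phase"] == "G1S" else 1.0
            g2m_mean = 18.0 if spec["phase"] == "G2M" else 1.0
            row[[gi[g] for g in G1S_GENES]] = _nb_counts(rng, g1s_mean * scale, 2.0, len(G1S_GENES))
            row[[gi[g] for g in G2M_GENES]] = _nb_counts(rng, g2m_mean * scale, 2.0, len(G2M_GENES))
            rows.append(row)
            cells.append(cell)
            cluster_labels[cell] = f"{sample}_main"
            records.append(
                dict(cell=cell, sample_id=sample, subtype=subtype,
                     phase=spec["phase"], lineage=lineage,
                     qc_fail=spec["qc_fail"], non_leukemic=spec["non_leukemic"])
            )

        # one contaminated cluster (mostly non-leukemic) in the first sample
        if sample == cfg.sc_samples[0][0]:
            for k in range(20):
                cell = f"{sample}_t{k:04d}"
                row = np.zeros(len(genes), dtype=int)
                row[: cfg.sc_n_background_genes] = _nb_counts(rng, 2.2, 2.0, cfg.sc_n_background_genes)
                row[[gi[g] for g in MITO_GENES]] = _nb_counts(rng, 17.0, 2.0, len(MITO_GENES))
                row[[gi[g] for g in RIBO_GENES]] = _nb_counts(rng, 35.0, 2.0, len(RIBO_GENES))
                flagged = k < 14  # 70% of the cluster -> whole cluster removed
                if flagged:
                    row[gi["DNTT"]] = 0
                    row[gi["CD3E"]] = 2 + int(rng.poisson(3))
                else:
                    row[gi["DNTT"]] = 1 + int(rng.poisson(2))
                row[[gi[g] for g in G1S_GENES]] = _nb_counts(rng, 1.0, 2.0, len(G1S_GENES))
                row[[gi[g] for g in G2M_GENES]] = _nb_counts(rng, 1.0, 2.0, len(G2M_GENES))
                rows.append(row)
                cells.append(cell)
                cluster_labels[cell] = f"{sample}_contam"
                records.append(
                    dict(cell=cell, sample_id=sample, subtype=subtype, phase="G0",
                         lineage="T", qc_fail="", non_leukemic=True)
                )

    matrix = CellMatrix(genes=genes, cells=cells, counts=np.vstack(rows))
    truth = pd.DataFrame(records).set_index("cell")
    gene_sets = {"G1S": list(G1S_GENES), "G2M": list(G2M_GENES),
                 "MITO": list(MITO_GENES), "RIBO": list(RIBO_GENES)}
    return matrix, truth, gene_sets, cluster_labels


# --------------------------------------------------------------------------
# Residual-disease generation
# --------------------------------------------------------------------------
def _quantile_lr(u: float, median: float, mmr_rate: float, top: float) -> float:
    """Piecewise-linear quantile function through (0, 0.3), the planted
    median, the MMR boundary at quantile 1-mmr_rate, and (1, top)."""
    knots_u, knots_q = [0.0], [0.3]
    anchors = sorted([(0.5, median), (1.0 - mmr_rate, 3.0)])
    for ku, kq in anchors:
        knots_u.append(ku)
        knots_q.append(kq)
    knots_u.append(1.0)
    knots_q.append(top)
    return float(np.interp(u, knots_u, knots_q))


def gen_response_series(cfg: GeneratorConfig,
                        rng: Optional[np.random.Generator] = None):
    """Per-patient transcript trajectories with known first post-induction
    log reductions.

    First-measurement log reductions are drawn from a stratified grid mapped
    through a subtype quantile function, so the planted per-subtype median
    and MMR rate are recovered exactly.  Returns (series list, truth frame).
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    series, records = [], []
    for subtype, (n, median, mmr_rate, top) in cfg.response_profiles.items():
        grid = (np.arange(n) + 0.5) / n
        order = rng.permutation(n)
        for i in range(n):
            u = float(grid[order[i]])
            lr1 = _quantile_lr(u, median, mmr_rate, top)
            pid = f"{subtype.split('-')[0].lower()}P{i:02d}"
            baseline = float(np.round(rng.uniform(50.0, 150.0), 1))
            day1 = int(rng.integers(25, 45))
            measurements = [Measurement(day=0, value=baseline, detected=True)]
            v1 = baseline * 10 ** (-lr1)
            measurements.append(Measurement(day=day1, value=v1, detected=True))
            for t, day in enumerate((90, 180), start=1):
                lr_t = lr1 + 0.8 * t * rng.uniform(0.5, 1.0)
                if lr_t >= cfg.detection_limit_lr:
                    measurements.append(Measurement(day=day, value=0.0, detected=False))
                else:
                    measurements.append(
                        Measurement(day=day, value=baseline * 10 ** (-lr_t), detected=True)
                    )
            series.append(
                ResponseSeries(patient_id=pid, baseline=baseline,
                               measurements=measurements,
                               detection_limit_lr=cfg.detection_limit_lr)
            )
            records.append(dict(patient_id=pid, subtype=subtype, planted_first_lr=lr1,
                                planted_mmr=lr1 >= 3.0, planted_dmr=lr1 >= 4.0))
    truth = pd.DataFrame(records).set_index("patient_id")
    return series, truth


def write_response_table(series: Sequence[ResponseSeries], path) -> None:
    rows = []
    for s in series:
        for m in s.measurements:
            rows.append(dict(patient_id=s.patient_id, day=m.day,
                             percent_transcript=m.value, detected=m.detected))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
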
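"""Structural-variant data model, table/VCF readers, and reference flank access.

Coordinates are 0-based half-open internally.  A breakend is a position plus a
``retained_side``: the flank of ``pos`` that survives in the derivative allele.
For a deletion, bnd1 retains its left flank and bnd2 its right flank, so the
"inside" (lost, partner-facing) direction of bnd1 runs rightward from ``pos``
and the inside of bnd2 runs leftward.  The two breakpoints split the genome
into segments 1A/1B and 2A/2B with 1A joined to 2B; the inside windows are the
first bases of 1B and the last bases of 2A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REQUIRED_COLUMNS = (
    "sv_id",
    "sample_id",
    "chrom1",
    "pos1",
    "orient1",
    "chrom2",
    "pos2",
    "orient2",
    "sv_type",
    "category",
)
OPTIONAL_COLUMNS = ("junction_seq", "ins_seq", "hom_len")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SVType(str, Enum):
    DEL = "DEL"
    INS = "INS"
    INV = "INV"
    ITX = "ITX"
    CTX = "CTX"


class Category(str, Enum):
    """Which event class an SV belongs to.

    ``bcr_abl1_associated`` marks breakpoints of the initiating translocation;
    ``cooperating`` marks transformation-related secondary events (e.g. IKZF1,
    PAX5, CDKN2A/B deletions).
    """

    BCR_ABL1 = "bcr_abl1_associated"
    COOPERATING = "cooperating"


class RetainedSide(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    retained_side: RetainedSide

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"breakend position must be >= 0, got {self.pos}")

    @property
    def inside_is_right(self) -> bool:
        """True when the lost/partner-facing direction runs rightward."""
        return self.retained_side is RetainedSide.LEFT


@dataclass
class SVRecord:
    sv_id: str
    sample_id: str
    sv_type: SVType
    bnd1: Breakend
    bnd2: Breakend
    category: Category
    junction_seq: Optional[str] = None
    caller_ins_seq: Optional[str] = None
    caller_hom_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sv_type in (SVType.DEL, SVType.INV, SVType.ITX):
            if self.bnd1.chrom != self.bnd2.chrom:
                raise ValueError(
                    f"{self.sv_id}: {self.sv_type.value} breakends must share a contig"
                )
            if self.bnd1.pos > self.bnd2.pos:
                raise ValueError(f"{self.sv_id}: bnd1.pos must be <= bnd2.pos")

    @property
    def has_junction_evidence(self) -> bool:
        return (
            self.junction_seq is not None
            or self.caller_ins_seq is not None
            or self.caller_hom_len is not None
        )


@dataclass
class FlankPair:
    """Retained and inside sequence windows around the two breakends.

    All sequences are uppercase forward-strand reference text.  ``left_seq``
    is the retained sequence ending at bnd1 (reverse-complemented when bnd1
    retains its right flank, so it always reads *into* the junction);
    ``right_seq`` is the retained sequence starting at bnd2, reading *out of*
    the junction.  ``inside1_seq``/``inside2_seq`` are the lost-side windows
    as forward-strand text; ``inside1_orient``/``inside2_orient`` record the
    scan orientation needed so each window is read breakpoint-outward
    ("plus" = forward, "minus" = reverse complement first).
    """

    left_seq: str
    right_seq: str
    inside1_seq: str
    inside2_seq: str
    inside1_orient: str = "plus"
    inside2_orient: str = "minus"
    inside1_ref_start: int = 0
    inside2_ref_start: int = 0
    truncated: bool = False
    unscannable1: bool = False
    unscannable2: bool = False


class SVTableFormatError(ValueError):
    pass


def _parse_enum(enum_cls, token: str, row: int, colname: str):
    try:
        return enum_cls(token)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise ValueError(
            f"row {row}: unknown {colname} {token!r} (expected one of: {valid})"
        ) from None


def _orient_to_side(token: str, row: int) -> RetainedSide:
    tok = str(token).strip().lower()
    if tok in ("left", "l", "+"):
        return RetainedSide.LEFT
    if tok in ("right", "r", "-"):
        return RetainedSide.RIGHT
    raise ValueError(f"row {row}: unknown orientation {token!r} (expected left/right)")


def read_sv_table(path: Union[str, Path]) -> list[SVRecord]:
    """Read SVs from a tab-separated table (one row per SV, header required).

    Required columns: sv_id, sample_id, chrom1, pos1, orient1, chrom2, pos2,
    orient2, sv_type, category.  Optional: junction_seq, ins_seq, hom_len.
    ``#``-prefixed lines are ignored.  Positions are 0-based breakpoint
    boundaries.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SVTableFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    records: list[SVRecord] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based file line, counting the header
        sv_type = _parse_enum(SVType, str(row["sv_type"]).strip(), rownum, "sv_type")
        category = _parse_enum(Category, str(row["category"]).strip(), rownum, "category")
        hom_len = row.get("hom_len")
        hom_len = (
            int(hom_len) if hom_len is not None and not pd.isna(hom_len) and str(hom_len) != "" else None
        )
        ins_seq = row.get("ins_seq")
        ins_seq = None if ins_seq is None or pd.isna(ins_seq) or ins_seq == "" else str(ins_seq).upper()
        junction = row.get("junction_seq")
        junction = (
            None if junction is None or pd.isna(junction) or junction == "" else str(junction).upper()
        )
        records.append(
            SVRecord(
                sv_id=str(row["sv_id"]),
                sample_id=str(row["sample_id"]),
                sv_type=sv_type,
                bnd1=Breakend(str(row["chrom1"]), int(row["pos1"]), _orient_to_side(row["orient1"], rownum)),
                bnd2=Breakend(str(row["chrom2"]), int(row["pos2"]), _orient_to_side(row["orient2"], rownum)),
                category=category,
                junction_seq=junction,
                caller_ins_seq=ins_seq,
                caller_hom_len=hom_len,
            )
        )
    return records


def write_sv_table(records: Sequence[SVRecord], path: Union[str, Path]) -> None:
    rows = []
    for sv in records:
        rows.append(
            {
                "sv_id": sv.sv_id,
                "sample_id": sv.sample_id,
                "chrom1": sv.bnd1.chrom,
                "pos1": sv.bnd1.pos,
                "orient1": sv.bnd1.retained_side.value,
                "chrom2": sv.bnd2.chrom,
                "pos2": sv.bnd2.pos,
                "orient2": sv.bnd2.retained_side.value,
                "sv_type": sv.sv_type.value,
                "category": sv.category.value,
                "junction_seq": sv.junction_seq or "",
                "ins_seq": sv.caller_ins_seq or "",
                "hom_len": "" if sv.caller_hom_len is None else sv.caller_hom_len,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf_breakends(
    path: Union[str, Path],
    category_tag: str = "CATEGORY",
    category_map: Optional[Mapping[str, str]] = None,
    default_category: Category = Category.COOPERATING,
) -> list[SVRecord]:
    """Read SVs from VCF 4.2: symbolic DEL/INV with END, or BND mate pairs.

    VCF POS is 1-based; symbolic DEL ``POS=p, END=e`` converts to 0-based
    breakpoint boundaries (p, e).  HOMLEN populates ``caller_hom_len`` and
    INSERTION/INSSEQ/SVINSSEQ populate ``caller_ins_seq``.  The per-record
    category is read from INFO tag ``category_tag`` or looked up by record id
    in ``category_map``; unpaired BNDs are skipped with a logged count.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    records: list[SVRecord] = []
    bnd_buffer: dict[str, "pysam.VariantRecord"] = {}
    n_skipped = 0

    def _info(rec, tag, default=None):
        # pysam raises for tags absent from the header, not just the record
        try:
            val = rec.info.get(tag, default)
        except (KeyError, ValueError):
            return default
        return default if val is None else val

    def _category_for(rec) -> Category:
        if category_map is not None and rec.id in category_map:
            return Category(category_map[rec.id])
        val = _info(rec, category_tag)
        if val is not None:
            if isinstance(val, tuple):
                val = val[0]
            return Category(str(val))
        return default_category

    def _ins_seq(rec) -> Optional[str]:
        for tag in ("INSERTION", "INSSEQ", "SVINSSEQ", "CONSENSUS_INS"):
            val = _info(rec, tag)
            if val:
                if isinstance(val, tuple):
                    val = val[0]
                return str(val).upper()
        return None

    def _hom_len(rec) -> Optional[int]:
        val = _info(rec, "HOMLEN")
        if val is None:
            return None
        if isinstance(val, tuple):
            val = val[0]
        return int(val)

    def _bracket_side(alt: str) -> RetainedSide:
        # t[p[ / t]p] : sequence before the bracket -> left flank retained
        return RetainedSide.LEFT if alt[0] not in "[]" else RetainedSide.RIGHT

    for rec in vf:
        svtype = _info(rec, "SVTYPE")
        if svtype in ("DEL", "INV"):
            end = rec.stop  # pysam: 0-based exclusive end from END
            records.append(
                SVRecord(
                    sv_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    sample_id=str(_info(rec, "SAMPLE", "unknown")),
                    sv_type=SVType(svtype),
                    bnd1=Breakend(rec.chrom, rec.start, RetainedSide.LEFT),
                    bnd2=Breakend(rec.chrom, end, RetainedSide.RIGHT),
                    category=_category_for(rec),
                    caller_ins_seq=_ins_seq(rec),
                    caller_hom_len=_hom_len(rec),
                )
            )
        elif svtype == "BND":
            mate = _info(rec, "MATEID")
            if isinstance(mate, tuple):
                mate = mate[0]
            if mate is None:
                n_skipped += 1
                continue
            if mate in bnd_buffer:
                first = bnd_buffer.pop(mate)
                alt1 = first.alts[0]
                alt2 = rec.alts[0]
                records.append(
                    SVRecord(
                        sv_id=first.id or mate,
                        sample_id=str(_info(first, "SAMPLE", "unknown")),
                        sv_type=SVType.CTX if first.chrom != rec.chrom else SVType.ITX,
                        bnd1=Breakend(first.chrom, first.start, _bracket_side(alt1)),
                        bnd2=Breakend(rec.chrom, rec.start, _bracket_side(alt2)),
                        category=_category_for(first),
                        caller_ins_seq=_ins_seq(first),
                        caller_hom_len=_hom_len(first),
                    )
                )
            else:
                bnd_buffer[rec.id] = rec
    n_skipped += len(bnd_buffer)
    if n_skipped:
        logger.warning("read_vcf_breakends: skipped %d unpaired BND record(s)", n_skipped)
    return records


def _fetch_window(ref, chrom: str, start: int, end: int) -> tuple[str, bool]:
    """Fetch ref[start:end) clipped to the contig; returns (seq, truncated)."""
    contig_len = len(ref[chrom])
    cstart, cend = max(start, 0), min(end, contig_len)
    if cstart >= cend:
        return "", True
    seq = str(ref[chrom][cstart:cend]).upper()
    return seq, (cstart != start or cend != end)


def fetch_flanks(sv: SVRecord, ref, retained_len: int, inside_len: int = 30) -> FlankPair:
    """Extract retained flanks and inside (lost-side) windows for an SV.

    ``ref`` is any indexed FASTA-like mapping (pyfaidx.Fasta or a plain
    ``{chrom: str}`` dict).  For a deletion with boundaries (p, q):
    ``left_seq = ref[p-retained_len, p)``, ``right_seq = ref[q, q+retained_len)``,
    ``inside1_seq = ref[p, p+inside_len)``, ``inside2_seq = ref[q-inside_len, q)``.
    Other orientations follow each breakend's retained side; the recorded
    orientation flags keep every inside window readable breakpoint-outward.
    """
    if inside_len < 7:
        raise ValueError("inside_len must be >= 7 (heptamer length)")
    truncated = False

    def _retained(bnd: Breakend, toward_junction_end: bool) -> str:
        nonlocal truncated
        if bnd.retained_side is RetainedSide.LEFT:
            seq, t = _fetch_window(ref, bnd.chrom, bnd.pos - retained_len, bnd.pos)
            if not toward_junction_end:
                seq = revcomp(seq)
        else:
            seq, t = _fetch_window(ref, bnd.chrom, bnd.pos, bnd.pos + retained_len)
            if toward_junction_end:
                seq = revcomp(seq)
        truncated = truncated or t
        return seq

    def _inside(bnd: Breakend) -> tuple[str, str, int]:
        nonlocal truncated
        if bnd.inside_is_right:
            seq, t = _fetch_window(ref, bnd.chrom, bnd.pos, bnd.pos + inside_len)
            orient, start = "plus", bnd.pos
        else:
            seq, t = _fetch_window(ref, bnd.chrom, bnd.pos - inside_len, bnd.pos)
            orient, start = "minus", max(bnd.pos - inside_len, 0)
        truncated = truncated or t
        return seq, orient, start

    left_seq = _retained(sv.bnd1, toward_junction_end=True)
    right_seq = _retained(sv.bnd2, toward_junction_end=False)
    in1, o1, s1 = _inside(sv.bnd1)
    in2, o2, s2 = _inside(sv.bnd2)
    return FlankPair(
        left_seq=left_seq,
        right_seq=right_seq,
        inside1_seq=in1,
        inside2_seq=in2,
        inside1_orient=o1,
        inside2_orient=o2,
        inside1_ref_start=s1,
        inside2_ref_start=s2,
        truncated=truncated,
        unscannable1=(set(in1) <= {"N"} if in1 else True),
        unscannable2=(set(in2) <= {"N"} if in2 else True),
    )


def expand_inversion(sv: SVRecord) -> list[SVRecord]:
    """Expand an INV record into its two junction orientations.

    Each inversion produces two novel junctions; each expanded record has a
    well-defined inside direction at both breakends and is scanned
    independently.
    """
    if sv.sv_type is not SVType.INV:
        return [sv]
    a = replace(
        sv,
        sv_id=f"{sv.sv_id}_j1",
        bnd1=Breakend(sv.bnd1.chrom, sv.bnd1.pos, RetainedSide.LEFT),
        bnd2=Breakend(sv.bnd2.chrom, sv.bnd2.pos, RetainedSide.LEFT),
    )
    b = replace(
        sv,
        sv_id=f"{sv.sv_id}_j2",
        bnd1=Breakend(sv.bnd1.chrom, sv.bnd1.pos, RetainedSide.RIGHT),
        bnd2=Breakend(sv.bnd2.chrom, sv.bnd2.pos, RetainedSide.RIGHT),
    )
    return [a, b]
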
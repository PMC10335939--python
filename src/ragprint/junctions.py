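"""Junction decomposition: non-template sequence, microhomology, or clean.

A resolved junction contig spans the novel adjacency.  Writing the retained
flank ending at bnd1 as L and the retained flank starting at bnd2 as R, the
junction J is explained by a split ``J = J[:i] + J[i:j] + J[j:]`` where
``J[:i]`` equals the length-i suffix of L (the left part ends exactly at the
breakpoint), ``J[j:]`` equals the length-(n-j) prefix of R, and the middle
``J[i:j]`` is non-template sequence (NTS) added by TdT.  If valid left and
right attributions overlap (max valid i > min valid j), the doubly-attributed
bases are microhomology.  The caller maximizes flank attribution (minimal
NTS / maximal microhomology); NTS and microhomology are mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Optional, Sequence

from .sv_catalog import FlankPair, SVRecord


class JunctionKind(str, Enum):
    NTS = "NTS"
    MICROHOMOLOGY = "microhomology"
    CLEAN = "clean"
    UNRESOLVED = "unresolved"


@dataclass
class JunctionCall:
    sv_id: str
    kind: JunctionKind
    nts_seq: str = ""
    nts_len: int = 0
    mh_seq: str = ""
    mh_len: int = 0
    gc_count: int = 0
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind is JunctionKind.NTS and (self.nts_len < 1 or self.mh_len != 0):
            raise ValueError("NTS call requires nts_len >= 1 and mh_len == 0")
        if self.kind is JunctionKind.MICROHOMOLOGY and (self.mh_len < 1 or self.nts_len != 0):
            raise ValueError("microhomology call requires mh_len >= 1 and nts_len == 0")
        if self.kind is JunctionKind.CLEAN and (self.nts_len or self.mh_len):
            raise ValueError("clean call requires nts_len == mh_len == 0")


@dataclass
class NTSSummary:
    n_with_nts: int
    n_total: int
    mean_len: Optional[float]
    gc_fraction: Optional[float]


def _gc(seq: str) -> int:
    return sum(1 for b in seq if b in "GC")


def _valid_left(junction: str, left: str, min_anchor: int) -> list[int]:
    """All i with junction[:i] == suffix of ``left`` of length i (i >= anchor)."""
    out = []
    for i in range(min_anchor, min(len(junction), len(left)) + 1):
        if "N" in junction[:i]:
            break
        if junction[:i] == left[len(left) - i :]:
            out.append(i)
    return out


def _valid_right(junction: str, right: str, min_anchor: int) -> list[int]:
    """All j with junction[j:] == prefix of ``right`` of length n-j."""
    n = len(junction)
    out = []
    for j in range(max(0, n - len(right)), n - min_anchor + 1):
        if "N" in junction[j:]:
            continue
        if junction[j:] == right[: n - j]:
            out.append(j)
    return out


def call_junction(
    sv: SVRecord,
    flanks: Optional[FlankPair] = None,
    min_anchor: int = 5,
) -> JunctionCall:
    """Decompose one SV junction into NTS / microhomology / clean.

    Prefers an assembled ``junction_seq`` (split search against the retained
    flanks); falls back to caller-reported insertion/homology fields.  When a
    caller reports both, the insertion wins and the call is flagged.
    """
    if sv.junction_seq is not None and flanks is not None:
        return _call_from_contig(sv, flanks, min_anchor)
    if sv.caller_ins_seq is not None or sv.caller_hom_len is not None:
        return _call_from_caller_fields(sv)
    if sv.junction_seq is not None:
        raise ValueError(f"{sv.sv_id}: junction_seq given but no flanks supplied")
    raise ValueError(f"{sv.sv_id}: no junction evidence (contig or caller fields)")


def _call_from_contig(sv: SVRecord, flanks: FlankPair, min_anchor: int) -> JunctionCall:
    junction = sv.junction_seq.upper()
    left, right = flanks.left_seq, flanks.right_seq
    if len(junction) <= 2 * min_anchor:
        return JunctionCall(sv.sv_id, JunctionKind.UNRESOLVED, flags=["too_short"])
    lefts = _valid_left(junction, left, min_anchor)
    rights = _valid_right(junction, right, min_anchor)
    if not lefts or not rights:
        return JunctionCall(sv.sv_id, JunctionKind.UNRESOLVED, flags=["no_anchor"])
    i_star = max(lefts)   # maximal flank attribution; ties toward left flank
    j_star = min(rights)
    if i_star >= j_star:
        h = i_star - j_star
        if h == 0:
            return JunctionCall(sv.sv_id, JunctionKind.CLEAN)
        return JunctionCall(
            sv.sv_id, JunctionKind.MICROHOMOLOGY, mh_seq=junction[j_star:i_star], mh_len=h
        )
    nts = junction[i_star:j_star]
    return JunctionCall(
        sv.sv_id, JunctionKind.NTS, nts_seq=nts, nts_len=len(nts), gc_count=_gc(nts)
    )


def _call_from_caller_fields(sv: SVRecord) -> JunctionCall:
    ins = sv.caller_ins_seq or ""
    hom = sv.caller_hom_len or 0
    flags = []
    if ins and hom:
        flags.append("caller_reported_both")
        hom = 0
    if ins:
        return JunctionCall(
            sv.sv_id, JunctionKind.NTS, nts_seq=ins.upper(), nts_len=len(ins),
            gc_count=_gc(ins.upper()), flags=flags,
        )
    if hom:
        return JunctionCall(sv.sv_id, JunctionKind.MICROHOMOLOGY, mh_len=hom, flags=flags)
    return JunctionCall(sv.sv_id, JunctionKind.CLEAN, flags=flags)


def summarize_nts(
    calls: Iterable[JunctionCall],
    subset: Optional[Callable[[JunctionCall], bool]] = None,
) -> NTSSummary:
    """NTS prevalence, mean length and G:C fraction over a subset of calls.

    ``gc_fraction`` pools inserted bases (sum gc / sum nts length) and is
    None — not 0 — when no NTS bases exist.
    """
    selected = [c for c in calls if subset is None or subset(c)]
    with_nts = [c for c in selected if c.kind is JunctionKind.NTS]
    total_len = sum(c.nts_len for c in with_nts)
    total_gc = sum(c.gc_count for c in with_nts)
    return NTSSummary(
        n_with_nts=len(with_nts),
        n_total=len(selected),
        mean_len=(total_len / len(with_nts)) if with_nts else None,
        gc_fraction=(total_gc / total_len) if total_len else None,
    )
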
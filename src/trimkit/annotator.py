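"""Copy classification, LTR substructure and family grouping.

An LTR is partitioned into U3 (promoter region, carrying the TATA box), R
(repeated RNA, canonically starting with G about 11 bp after the TATA
hexamer and ending with CA) and U5.  Families follow the 80/80 similarity
rule: two copies belong to one family when they share at least 80% identity
over at least 80% of their internal domain or of their LTR; families are the
connected components of that link relation (single linkage).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import Align

from .core_io import FormatError, GenomicInterval, TrimElement, ValidationError


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# LTR substructure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstructureParams:
    tata_search_bp: int = 70        # TATAAA must start within this prefix
    r_offset: int = 11              # R starts ~11 bp after the TATA hexamer
    r_offset_slack: int = 3
    r_length_range: tuple[int, int] = (60, 80)
    default_u3: int = 62            # fallback partition when no TATA box
    default_r: int = 69


@dataclass(frozen=True)
class LtrSubstructure:
    """U3 / R / U5 partition of one LTR (coordinates relative to the LTR)."""

    u3: tuple[int, int]
    r: tuple[int, int]
    u5: tuple[int, int]
    tata_pos: Optional[int] = None      # start of the TATAAA hexamer
    r_offset_used: Optional[int] = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not (self.u3[0] == 0 and self.u3[1] == self.r[0]
                and self.r[1] == self.u5[0]):
            raise ValidationError("U3, R, U5 must partition the LTR in order")


def annotate_ltr_substructure(ltr_seq: str,
                              params: SubstructureParams | None = None
                              ) -> LtrSubstructure:
    """Partition one LTR into U3, R and U5.

    The first exact TATAAA in the U3 search prefix anchors the partition:
    R starts at the G nearest to 11 bp after the hexamer (within the slack),
    and ends at the last CA that keeps |R| inside the configured range.
    Without a TATA box the configured default lengths are used and the
    result is flagged low-confidence.
    """
    p = params or SubstructureParams()
    seq = ltr_seq.upper()
    n = len(seq)
    if n < 100:
        raise AnnotationError(f"LTR of {n} bp is too short to partition")
    if n < p.default_u3 + p.default_r + 1:
        raise AnnotationError("LTR shorter than the combined minimum region lengths")

    tata = seq.find("TATAAA", 0, p.tata_search_bp)
    if tata == -1:
        u3_end = p.default_u3
        r_end = u3_end + p.default_r
        if r_end >= n:
            raise AnnotationError("default partition exceeds the LTR length")
        return LtrSubstructure(
            u3=(0, u3_end), r=(u3_end, r_end), u5=(r_end, n),
            tata_pos=None, low_confidence=True,
        )
    tata_end = tata + 6
    # R start: the G nearest to tata_end + r_offset, within the slack
    target = tata_end + p.r_offset
    r_start = None
    for delta in sorted(range(-p.r_offset_slack, p.r_offset_slack + 1),
                        key=lambda d: (abs(d), d)):
        pos = target + delta
        if 0 <= pos < n and seq[pos] == "G":
            r_start = pos
            break
    if r_start is None:
        return LtrSubstructure(
            u3=(0, p.default_u3), r=(p.default_u3, p.default_u3 + p.default_r),
            u5=(p.default_u3 + p.default_r, n),
            tata_pos=tata, low_confidence=True,
        )
    # R end: the last CA whose implied |R| falls in the configured range
    lo, hi = p.r_length_range
    r_end = None
    for end in range(min(n - 1, r_start + hi), r_start + lo - 1, -1):
        if seq[end - 2 : end] == "CA":
            r_end = end
            break
    if r_end is None:
        r_end = min(n - 1, r_start + (lo + hi) // 2)
        low = True
    else:
        low = False
    return LtrSubstructure(
        u3=(0, r_start), r=(r_start, r_end), u5=(r_end, n),
        tata_pos=tata, r_offset_used=r_start - tata_end, low_confidence=low,
    )


# ---------------------------------------------------------------------------
# Family grouping (80/80 rule, single linkage)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyParams:
    min_identity: float = 0.80
    min_coverage: float = 0.80


def _semiglobal_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    try:
        aligner.open_end_gap_score = 0
        aligner.extend_end_gap_score = 0
    except AttributeError:  # older Biopython naming
        aligner.target_end_open_gap_score = 0
        aligner.target_end_extend_gap_score = 0
        aligner.query_end_open_gap_score = 0
        aligner.query_end_extend_gap_score = 0
    return aligner


def domain_similarity(a: str, b: str,
                      aligner: Align.PairwiseAligner | None = None
                      ) -> tuple[float, float]:
    """(identity, coverage) of a semi-global alignment of two domains.

    Identity is matches over aligned (non-end-gap) columns; coverage is
    aligned columns over the longer domain length.
    """
    if not a or not b:
        return 0.0, 0.0
    aligner = aligner or _semiglobal_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    ra, rb = str(aln[0]), str(aln[1])
    # strip end gaps; highly dissimilar pairs may leave no aligned core
    start, end = 0, len(ra)
    while start < end and (ra[start] == "-" or rb[start] == "-"):
        start += 1
    while end > start and (ra[end - 1] == "-" or rb[end - 1] == "-"):
        end -= 1
    if start >= end:
        return 0.0, 0.0
    core_a, core_b = ra[start:end], rb[start:end]
    columns = len(core_a)
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    identity = matches / columns if columns else 0.0
    coverage = columns / max(len(a), len(b))
    return identity, coverage


def group_families(
    ids: Sequence[str],
    ltr_seqs: dict[str, str],
    internal_seqs: Optional[dict[str, str]] = None,
    params: FamilyParams | None = None,
) -> dict[str, str]:
    """Single-linkage families under the 80/80 rule.

    Two copies are linked iff either their LTRs or their internal domains
    align at >= ``min_identity`` over >= ``min_coverage`` of the domain.
    Family labels are ``F_<smallest member id>``; the result is invariant to
    input order and idempotent.
    """
    p = params or FamilyParams()
    ids = sorted(ids)
    internal_seqs = internal_seqs or {}
    aligner = _semiglobal_aligner()
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            linked = False
            if a in ltr_seqs and b in ltr_seqs:
                ident, cov = domain_similarity(ltr_seqs[a], ltr_seqs[b], aligner)
                linked = ident >= p.min_identity and cov >= p.min_coverage
            if not linked and a in internal_seqs and b in internal_seqs:
                ident, cov = domain_similarity(internal_seqs[a], internal_seqs[b], aligner)
                linked = ident >= p.min_identity and cov >= p.min_coverage
            if linked:
                union(a, b)
    return {i: f"F_{find(i)}" for i in ids}


# ---------------------------------------------------------------------------
# Gene association
# ---------------------------------------------------------------------------

def _read_gene_models(path: str | Path):
    """Parse a user-supplied GFF3 into gene spans with exon lists."""
    genes: dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
        scaf, _src, ftype, start, end, _score, strand, _frame, attrs_s = cols
        try:
            iv = GenomicInterval(scaf, int(start) - 1, int(end), strand if strand in "+-" else "+")
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        attrs = dict(kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv)
        if ftype == "gene":
            gid = attrs.get("ID", f"gene{lineno}")
            genes[gid] = {"span": iv, "exons": []}
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent in genes:
                genes[parent]["exons"].append(iv)
    return list(genes.values())


def overlap_with_genes(elements: Sequence[TrimElement],
                       gene_models: str | Path,
                       window_bp: int = 1000) -> tuple[pd.DataFrame, float]:
    """Classify each copy against user-supplied gene models.

    Per element the status is the highest-priority match among
    ``overlaps_exon`` > ``overlaps_intron`` > ``within_window`` > ``none``
    (the window applies to distance from the gene span).  Returns the
    per-element table and the fraction of associated (non-``none``) copies.
    """
    genes = _read_gene_models(gene_models)
    rows = []
    for el in elements:
        iv = el.element_interval
        status = "none"
        for gene in genes:
            span = gene["span"]
            if span.scaffold_id != iv.scaffold_id:
                continue
            exons = gene["exons"] or [span]  # exon-less models count as one exon
            if any(iv.overlaps(ex) for ex in exons):
                status = "overlaps_exon"
                break
            if iv.overlaps(span):
                status = "overlaps_intron"
                continue
            dist = max(span.start - iv.end, iv.start - span.end, 0)
            if dist <= window_bp and status == "none":
                status = "within_window"
        rows.append({"element_id": el.id, "category": el.category, "status": status})
    table = pd.DataFrame(rows, columns=["element_id", "category", "status"])
    if len(table):
        fraction = float((table["status"] != "none").mean())
    else:
        fraction = 0.0
    return table, fraction
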
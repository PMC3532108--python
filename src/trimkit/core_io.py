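"""Shared domain types, file formats and run configuration.

All coordinates held in memory are 0-based, half-open ``[start, end)``.
GFF3 output converts to the format's 1-based inclusive convention; the two
conversions compose to the identity.  FASTA is read through Biopython and
canonicalised to uppercase; Newick trees are read and written through
``Bio.Phylo`` and converted to :class:`trimkit.phylo.TreeNode`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml
from Bio import SeqIO

log = logging.getLogger("trimkit")

VALID_BASES = set("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file (names the offending record)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a pipeline precondition."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaffold:
    """A named DNA sequence (uppercase, alphabet {A,C,G,T,N})."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GenomeAssembly:
    """An ordered collection of scaffolds with unique ids."""

    scaffolds: list[Scaffold]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.scaffolds]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate scaffold ids in assembly")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.scaffolds)

    def __iter__(self):
        return iter(self.scaffolds)

    def __len__(self) -> int:
        return len(self.scaffolds)

    def get(self, scaffold_id: str) -> Scaffold:
        for s in self.scaffolds:
            if s.id == scaffold_id:
                return s
        raise KeyError(scaffold_id)

    def digest(self) -> str:
        h = hashlib.sha256()
        for s in self.scaffolds:
            h.update(s.id.encode())
            h.update(b"\0")
            h.update(s.seq.encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named scaffold."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold_id}"
            )
        if self.strand not in "+-":
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold_id == other.scaffold_id
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.scaffold_id, self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class MotifHit:
    """A PBS or PPT hit inside the internal region of an element."""

    kind: str                       # "PBS" | "PPT"
    interval: GenomicInterval
    matched_trna: Optional[str] = None
    score: int = 0                  # matched bases (PBS) / purine count (PPT)


@dataclass
class TrimElement:
    """One annotated TRIM copy: complete, truncated or a solo-LTR."""

    id: str
    category: str                   # "complete" | "truncated" | "solo_ltr"
    element_interval: GenomicInterval
    ltr5: Optional[GenomicInterval] = None
    ltr3: Optional[GenomicInterval] = None
    tsd: Optional[str] = None
    pbs: Optional[MotifHit] = None
    ppt: Optional[MotifHit] = None
    family: Optional[str] = None
    subfamily: Optional[str] = None
    ltr_identity: Optional[float] = None
    termini_ok: Optional[tuple[bool, bool]] = None
    subtype: Optional[str] = None   # e.g. "truncated_solo" vs "truncated_element"

    CATEGORIES = ("complete", "truncated", "solo_ltr")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValidationError(f"unknown element category {self.category!r}")
        if self.category == "complete" and (self.ltr5 is None or self.ltr3 is None):
            raise ValidationError(f"complete element {self.id} lacks LTR intervals")
        if self.tsd is not None and len(self.tsd) != 4:
            raise ValidationError(f"TSD of element {self.id} is not 4 bp: {self.tsd!r}")

    @property
    def scaffold_id(self) -> str:
        return self.element_interval.scaffold_id


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

# Average synonymous substitution rate for ants (substitutions/site/year),
# estimated from orthologous nuclear protein-coding genes; the denominator of
# the insertion-age formula T = K / (2 r).
DEFAULT_SUBSTITUTION_RATE = 0.54e-8


@dataclass
class RunConfig:
    """All tunable parameters of a run; serialisable, hashable, complete.

    A serialised RunConfig plus the input digests fully determines a run:
    every stochastic stage draws its generator from :attr:`seed`.
    """

    seed: int = 0
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE
    n_randomization_reps: int = 5000
    bootstrap_reps: int = 1000
    # detector
    seed_k: int = 15
    min_ltr: int = 100
    max_ltr: int = 350
    min_internal: int = 50
    max_internal: int = 700
    max_element: int = 1000
    min_ltr_identity: float = 0.80
    # generator
    background_gc: float = 0.37
    hotspot_gc: float = 0.19
    strict_alphabet: bool = True
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = {k: v for k, v in data.items() if k not in known}
        kwargs = {k: v for k, v in data.items() if k in known}
        cfg = cls(**kwargs)
        cfg.extra.update(unknown)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def log_provenance(self, **input_digests: str) -> None:
        log.info("run config %s; inputs: %s", self.digest(),
                 ", ".join(f"{k}={v}" for k, v in sorted(input_digests.items())) or "none")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, strict: bool = True) -> GenomeAssembly:
    """Read a multi-FASTA into an assembly.

    Sequences are uppercased.  Characters outside {A,C,G,T,N} raise a
    :class:`FormatError` naming the record under ``strict`` mode and are
    mapped to ``N`` otherwise.
    """
    scaffolds = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise FormatError(f"{path}: record with empty header")
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                if strict:
                    raise FormatError(
                        f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
                    )
                seq = "".join(c if c in VALID_BASES else "N" for c in seq)
            scaffolds.append(Scaffold(rec.id, seq))
    if not scaffolds:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeAssembly(scaffolds)


def write_fasta(assembly_or_seqs, path: str | Path, width: int = 70) -> None:
    """Write an assembly, or a mapping label -> sequence, as FASTA."""
    if isinstance(assembly_or_seqs, GenomeAssembly):
        items = [(s.id, s.seq) for s in assembly_or_seqs]
    else:
        items = list(assembly_or_seqs.items())
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_aligned_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA (rows over {A,C,G,T,N,-}) -> (labels, rows)."""
    labels, rows = [], []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
    if len(set(map(len, rows))) > 1:
        raise FormatError(f"{path}: aligned rows have unequal lengths")
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate sequence labels")
    return labels, rows


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_SOURCE = "trimkit"
_PARENT_TYPE = "repeat_region"
_CHILD_TYPES = {"ltr5": "long_terminal_repeat", "ltr3": "long_terminal_repeat",
                "pbs": "primer_binding_site", "ppt": "RNA_polymerase_promoter"}


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v is not None)


def write_gff3(elements: Iterable[TrimElement], path: str | Path,
               assembly: Optional[GenomeAssembly] = None) -> None:
    """Write elements as GFF3 (1-based inclusive coordinates).

    One ``repeat_region`` feature per element with child features for each
    LTR, PBS and PPT; category, TSD and family labels go in column 9.
    Intervals are validated against ``assembly`` when it is given.
    """
    lines = ["##gff-version 3"]
    for el in elements:
        iv = el.element_interval
        if assembly is not None:
            scaf = assembly.get(iv.scaffold_id)
            if iv.end > scaf.length:
                raise ValidationError(
                    f"element {el.id} interval [{iv.start},{iv.end}) exceeds "
                    f"scaffold {scaf.id} length {scaf.length}"
                )
        attrs = {
            "ID": el.id,
            "category": el.category,
            "tsd": el.tsd,
            "family": el.family,
            "subfamily": el.subfamily,
            "subtype": el.subtype,
            "ltr_identity": None if el.ltr_identity is None else f"{el.ltr_identity:.4f}",
            "termini_ok": None if el.termini_ok is None
            else f"{int(el.termini_ok[0])}-{int(el.termini_ok[1])}",
        }
        lines.append("\t".join([
            iv.scaffold_id, _GFF_SOURCE, _PARENT_TYPE,
            str(iv.start + 1), str(iv.end), ".", iv.strand, ".", _fmt_attrs(attrs),
        ]))
        children = [("ltr5", el.ltr5, None), ("ltr3", el.ltr3, None)]
        if el.pbs is not None:
            children.append(("pbs", el.pbs.interval, el.pbs))
        if el.ppt is not None:
            children.append(("ppt", el.ppt.interval, el.ppt))
        for tag, civ, motif in children:
            if civ is None:
                continue
            cattrs = {"ID": f"{el.id}.{tag}", "Parent": el.id, "part": tag}
            if motif is not None:
                cattrs["score_bases"] = str(motif.score)
                if motif.matched_trna:
                    cattrs["trna"] = motif.matched_trna
            lines.append("\t".join([
                civ.scaffold_id, _GFF_SOURCE, _CHILD_TYPES[tag],
                str(civ.start + 1), str(civ.end), ".", civ.strand, ".", _fmt_attrs(cattrs),
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(col9: str) -> dict[str, str]:
    out = {}
    for part in col9.split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list[TrimElement]:
    """Read a trimkit-dialect GFF3 back into elements (round-trip partner)."""
    parents: dict[str, TrimElement] = {}
    children: list[tuple[str, str, GenomicInterval, dict]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
        scaf, _src, ftype, start, end, _score, strand, _frame, attrs_s = cols
        attrs = _parse_attrs(attrs_s)
        iv = GenomicInterval(scaf, int(start) - 1, int(end), strand)
        if ftype == _PARENT_TYPE:
            tok = attrs.get("termini_ok")
            el = TrimElement(
                id=attrs["ID"], category=attrs.get("category", "complete"),
                element_interval=iv, tsd=attrs.get("tsd"),
                family=attrs.get("family"), subfamily=attrs.get("subfamily"),
                subtype=attrs.get("subtype"),
                ltr_identity=float(attrs["ltr_identity"]) if "ltr_identity" in attrs else None,
                termini_ok=tuple(bool(int(x)) for x in tok.split("-")) if tok else None,
                # complete elements are patched with LTR children below
                ltr5=iv if attrs.get("category") == "complete" else None,
                ltr3=iv if attrs.get("category") == "complete" else None,
            )
            parents[el.id] = el
        else:
            children.append((attrs.get("Parent", ""), attrs.get("part", ""), iv, attrs))
    for parent_id, part, iv, attrs in children:
        el = parents.get(parent_id)
        if el is None:
            raise FormatError(f"{path}: child feature references unknown parent {parent_id!r}")
        if part == "ltr5":
            el.ltr5 = iv
        elif part == "ltr3":
            el.ltr3 = iv
        elif part == "pbs":
            el.pbs = MotifHit("PBS", iv, attrs.get("trna"), int(attrs.get("score_bases", 0)))
        elif part == "ppt":
            el.ppt = MotifHit("PPT", iv, None, int(attrs.get("score_bases", 0)))
    return list(parents.values())


# ---------------------------------------------------------------------------
# Newick (delegates parsing/serialisation to Bio.Phylo)
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> "trimkit.phylo.TreeNode":  # noqa: F821
    """Read a Newick tree (path or literal string) into the package tree type.

    Numeric internal-node labels are interpreted as bootstrap/support values,
    the convention used by the distance-tree programs this package mirrors.
    """
    from Bio import Phylo
    from .phylo import TreeNode

    text = None
    p = Path(str(source))
    if isinstance(source, Path) or (p.suffix in {".nwk", ".tree", ".newick"} and p.exists()):
        text = p.read_text()
    else:
        text = str(source)
    if text.count("(") != text.count(")"):
        raise FormatError("unbalanced parentheses in Newick input")
    btree = Phylo.read(io.StringIO(text), "newick")

    def convert(clade) -> TreeNode:
        node = TreeNode(name=clade.name, length=clade.branch_length,
                        support=clade.confidence)
        # Bio.Phylo may leave a numeric support in .name for internal nodes
        if node.name is not None and clade.clades:
            try:
                node.support = float(node.name)
                node.name = None
            except ValueError:
                pass
        for child in clade.clades:
            node.children.append(convert(child))
        return node

    root = convert(btree.root)
    labels = [leaf.name for leaf in root.leaves()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in Newick input")
    return root


def write_newick(tree, path: str | Path | None = None) -> str:
    """Serialise a tree; returns the Newick string (and writes it if asked)."""
    text = tree.to_newick() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
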
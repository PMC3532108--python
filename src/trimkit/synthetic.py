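"""Synthetic genomes with planted TRIM copies and a ground-truth registry.

The generator emulates the features of the study system that the analysis
stages depend on: scaffolds with a configurable length law and background GC
(default 0.37, the host genome's composition), AT-rich insertion hotspots
(default GC 0.19, matching the composition of observed insertion flanks),
planted complete elements (two co-oriented LTRs of 100-350 bp flanking a
non-coding internal region, total < 1000 bp, TG...CA termini, PBS/PPT
motifs, 4-bp TSD), solo-LTRs and truncated copies, LTR-pair divergence
calibrated so the expected Kimura-2-parameter distance equals 2*r*age, and
spatial clustering of insertions.

Insertion follows integrase biology: the 4-mer already present at the target
site is duplicated on both sides of the new copy, so planted TSDs are
host-derived and the scaffold grows by (element length + 4) bp.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .core_io import (
    DEFAULT_SUBSTITUTION_RATE,
    GenomeAssembly,
    GenomicInterval,
    Scaffold,
    ValidationError,
    revcomp,
)
from .dating import k2p_distance

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_IDX = {b: i for i, b in enumerate("ACGT")}

# Maximum plantable expected divergence: beyond this the K2P estimator sits
# too close to its singularity to be meaningful for two short LTRs.
MAX_EXPECTED_K = 0.7


class ParameterError(ValueError):
    pass


class PlacementError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Background scaffolds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HotspotModel:
    """Fixed-length AT-rich blocks dropped into background scaffolds."""

    fraction: float = 0.0          # fraction of scaffold length inside hotspots
    gc: float = 0.19
    block_length: int = 2000


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def generate_background(
    n_scaffolds: int,
    length_law: int | Callable[[np.random.Generator], int],
    gc: float = 0.37,
    hotspot_model: Optional[HotspotModel] = None,
    seed: int = 0,
) -> tuple[GenomeAssembly, list[GenomicInterval]]:
    """Generate i.i.d. background scaffolds, optionally with AT-rich hotspots.

    ``length_law`` is either a constant length or a callable drawing one
    length from the supplied generator.  Returns the assembly together with
    the realised hotspot intervals (the ground truth for insertion-preference
    tests); the list is empty when no hotspot model is given.
    """
    if not (0 < gc < 1):
        raise ParameterError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    scaffolds: list[Scaffold] = []
    hotspots: list[GenomicInterval] = []
    for i in range(n_scaffolds):
        length = length_law if isinstance(length_law, int) else int(length_law(rng))
        if length <= 0:
            raise ParameterError(f"length law produced non-positive length {length}")
        name = f"scaffold_{i + 1}"
        seq = _random_seq(rng, length, gc)
        if hotspot_model is not None and hotspot_model.fraction > 0:
            if not (0 < hotspot_model.gc < 1):
                raise ParameterError("hotspot gc must be in (0, 1)")
            block = min(hotspot_model.block_length, length)
            n_blocks = int(round(hotspot_model.fraction * length / block))
            starts: list[int] = []
            for _ in range(n_blocks):
                for _attempt in range(100):
                    s = int(rng.integers(0, max(length - block, 1)))
                    if all(abs(s - t) >= block for t in starts):
                        starts.append(s)
                        break
            chars = list(seq)
            for s in sorted(starts):
                chars[s : s + block] = _random_seq(rng, block, hotspot_model.gc)
                hotspots.append(GenomicInterval(name, s, s + block))
            seq = "".join(chars)
        scaffolds.append(Scaffold(name, seq))
    return GenomeAssembly(scaffolds), hotspots


# ---------------------------------------------------------------------------
# LTR templates and element payloads
# ---------------------------------------------------------------------------

def make_ltr_template(rng: np.random.Generator, length: int = 160,
                      gc: float = 0.37) -> str:
    """A random LTR template with TG...CA termini and a TATAAA promoter box.

    The substructure follows the canonical U3-R-U5 layout: the TATA hexamer
    sits inside U3 and the repeated-RNA region starts 11 bp after it with a
    G and ends with CA.
    """
    if length < 100:
        raise ParameterError("LTR templates must be at least 100 bp")
    seq = list(_random_seq(rng, length, gc))
    seq[0:2] = "TG"
    seq[-2:] = "CA"
    tata_start = 40
    seq[tata_start : tata_start + 6] = "TATAAA"
    r_start = tata_start + 6 + 11
    seq[r_start] = "G"
    r_end = r_start + 69          # R-region length within the observed range
    if r_end + 2 < length:
        seq[r_end - 2 : r_end] = "CA"
    return "".join(seq)


def make_internal_template(rng: np.random.Generator, length: int = 300,
                           pbs: str = "TGGGGATTCGAACCG",
                           ppt: str = "AAGGGAGGGAAGGAG",
                           gc: float = 0.37) -> str:
    """A non-coding internal template carrying a PBS at its 5' end and a PPT
    just before its 3' end.

    The default PBS is the exact reverse complement of the 3'-terminal 15 nt
    of the packaged leucine-like synthetic tRNA, so planted elements carry a
    detectable primer binding site.
    """
    if length < len(pbs) + len(ppt) + 10:
        raise ParameterError("internal template too short for PBS + PPT")
    seq = list(_random_seq(rng, length, gc))
    seq[2 : 2 + len(pbs)] = pbs
    seq[length - len(ppt) - 2 : length - 2] = ppt
    return "".join(seq)


@dataclass(frozen=True)
class PlantSpec:
    """One copy to plant: templates, target site, age and category."""

    ltr_template: str
    internal_template: str
    target_interval: GenomicInterval
    age_years: float = 0.0
    category: str = "complete"
    tsd: Optional[str] = None              # None -> host-derived from the site
    truncation_fraction: float = 0.6       # kept fraction for truncated copies
    truncation_side: str = "5p"            # which side is missing

    def __post_init__(self) -> None:
        ltr = self.ltr_template
        if not (100 <= len(ltr) <= 350):
            raise ParameterError(f"LTR template length {len(ltr)} outside 100-350 bp")
        if not (ltr.startswith("TG") and ltr.endswith("CA")):
            raise ParameterError("LTR template must begin TG and end CA")
        if self.category == "complete" and 2 * len(ltr) + len(self.internal_template) >= 1000:
            raise ParameterError("complete element would reach 1000 bp")
        if self.category not in ("complete", "truncated", "solo_ltr"):
            raise ParameterError(f"unknown category {self.category!r}")
        if self.tsd is not None and len(self.tsd) != 4:
            raise ParameterError("TSD must be 4 bp")
        if self.age_years < 0:
            raise ParameterError("age must be non-negative")


@dataclass
class TruthRecord:
    element_id: str
    spec: PlantSpec
    interval: GenomicInterval              # element span, TSDs excluded
    ltr5: Optional[GenomicInterval]
    ltr3: Optional[GenomicInterval]
    realized_k: float
    tsd: Optional[str]
    sequence: str


@dataclass
class TruthRegistry:
    records: list[TruthRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_category(self, category: str) -> list[TruthRecord]:
        return [r for r in self.records if r.spec.category == category]

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "element_id": [r.element_id for r in self.records],
                "scaffold": [r.interval.scaffold_id for r in self.records],
                "start": [r.interval.start for r in self.records],
                "end": [r.interval.end for r in self.records],
                "category": [r.spec.category for r in self.records],
                "age_years": [r.spec.age_years for r in self.records],
                "realized_k": [r.realized_k for r in self.records],
                "tsd": [r.tsd for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# LTR divergence calibrated to age
# ---------------------------------------------------------------------------

def _k2p_probs(d: float, ts_tv_ratio: float) -> tuple[float, float]:
    """(transition prob, per-target transversion prob) after expected
    divergence ``d`` under a Kimura-2 process with instantaneous ts:tv ratio
    ``R = alpha/(2 beta)`` and total rate normalised to 1."""
    R = ts_tv_ratio
    alpha = R / (R + 1.0)
    beta = 1.0 / (2.0 * (R + 1.0))
    t = d
    p_ts = 0.25 + 0.25 * np.exp(-4 * beta * t) - 0.5 * np.exp(-2 * (alpha + beta) * t)
    p_tv_each = 0.25 - 0.25 * np.exp(-4 * beta * t)
    return float(p_ts), float(p_tv_each)


_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _evolve(seq: str, d: float, ts_tv_ratio: float,
            rng: np.random.Generator) -> str:
    """Evolve one copy for expected ``d`` substitutions/site (K2P process)."""
    p_ts, p_tv = _k2p_probs(d, ts_tv_ratio)
    u = rng.random(len(seq))
    v = rng.random(len(seq))
    out = list(seq)
    for i, b in enumerate(seq):
        if b not in _TS_PARTNER:
            continue
        if u[i] < p_ts:
            out[i] = _TS_PARTNER[b]
        elif u[i] < p_ts + 2 * p_tv:
            out[i] = _TV_PARTNERS[b][0] if v[i] < 0.5 else _TV_PARTNERS[b][1]
    return "".join(out)


def diverge_ltr_pair(
    ltr_template: str,
    age_years: float,
    r: float = DEFAULT_SUBSTITUTION_RATE,
    ts_tv_ratio: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str, float]:
    """Independently mutate two copies of an LTR so the expected K2P distance
    between them is ``2 * r * age_years``; returns (ltr5, ltr3, realized_K).

    The two copies were identical at integration time and each accumulates
    point substitutions for ``r * age_years`` expected substitutions/site.
    """
    expected = 2.0 * r * age_years
    if expected >= MAX_EXPECTED_K:
        raise ParameterError(
            f"expected divergence {expected:.3f} >= {MAX_EXPECTED_K}: "
            "K2P dating is undefined this close to saturation"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = expected / 2.0
    ltr5 = _evolve(ltr_template, half, ts_tv_ratio, rng)
    ltr3 = _evolve(ltr_template, half, ts_tv_ratio, rng)
    est = k2p_distance(ltr5, ltr3)
    return ltr5, ltr3, est.K


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def _build_payload(spec: PlantSpec, r: float, ts_tv_ratio: float,
                   rng: np.random.Generator) -> tuple[str, float, Optional[tuple[int, int]]]:
    """(payload sequence, realized_K, (ltr5_off, ltr3_off) within payload)."""
    if spec.category == "solo_ltr":
        solo = _evolve(spec.ltr_template, r * spec.age_years, ts_tv_ratio, rng)
        return solo, 0.0, None
    ltr5, ltr3, realized_k = diverge_ltr_pair(
        spec.ltr_template, spec.age_years, r, ts_tv_ratio, rng)
    internal = _evolve(spec.internal_template, r * spec.age_years, ts_tv_ratio, rng)
    full = ltr5 + internal + ltr3
    if spec.category == "complete":
        return full, realized_k, (0, len(ltr5) + len(internal))
    keep = max(1, int(round(spec.truncation_fraction * len(full))))
    frag = full[-keep:] if spec.truncation_side == "5p" else full[:keep]
    return frag, realized_k, None


def plant_elements(
    assembly: GenomeAssembly,
    specs: Sequence[PlantSpec],
    seed: int = 0,
    r: float = DEFAULT_SUBSTITUTION_RATE,
    ts_tv_ratio: float = 2.0,
) -> tuple[GenomeAssembly, TruthRegistry]:
    """Insert copies into an assembly and return exact realised coordinates.

    Complete and solo copies duplicate the 4-mer at the insertion site on
    both sides of the payload (or the spec's ``tsd``, which then replaces the
    site 4-mer); truncated copies are inserted bare, as a real truncated copy
    has lost at least one TSD flank.  Target intervals must be in bounds and
    non-overlapping per scaffold; collisions raise :class:`PlacementError`
    naming the offending specs.
    """
    rng = np.random.default_rng(seed)
    by_scaffold: dict[str, list[tuple[int, PlantSpec]]] = {}
    for i, spec in enumerate(specs):
        by_scaffold.setdefault(spec.target_interval.scaffold_id, []).append((i, spec))

    registry = TruthRegistry()
    new_scaffolds: list[Scaffold] = []
    ordered_records: list[tuple[int, TruthRecord]] = []
    for scaf in assembly:
        todo = sorted(by_scaffold.pop(scaf.id, []), key=lambda t: t[1].target_interval.start)
        for (ia, sa), (ib, sb) in itertools.pairwise(todo):
            if sb.target_interval.start < sa.target_interval.start + 4:
                raise PlacementError(
                    f"specs {ia} and {ib} collide on {scaf.id} "
                    f"(sites {sa.target_interval.start}, {sb.target_interval.start})"
                )
        pieces: list[str] = []
        cursor = 0
        offset = 0
        for i, spec in todo:
            s = spec.target_interval.start
            if s + 4 > scaf.length:
                raise PlacementError(
                    f"spec {i}: site {s} too close to the end of {scaf.id}"
                )
            payload, realized_k, ltr_offs = _build_payload(spec, r, ts_tv_ratio, rng)
            uses_tsd = spec.category in ("complete", "solo_ltr")
            site_4mer = spec.tsd if spec.tsd is not None else scaf.seq[s : s + 4]
            pieces.append(scaf.seq[cursor:s])
            if uses_tsd:
                pieces.append(site_4mer + payload + site_4mer)
                elem_start = s + offset + 4
                consumed = 4
                growth = len(payload) + 4
                tsd = site_4mer
            else:
                pieces.append(payload)
                elem_start = s + offset
                consumed = 0
                growth = len(payload)
                tsd = None
            cursor = s + consumed
            offset += growth
            iv = GenomicInterval(scaf.id, elem_start, elem_start + len(payload))
            ltr5 = ltr3 = None
            if ltr_offs is not None:
                L = len(spec.ltr_template)
                ltr5 = GenomicInterval(scaf.id, elem_start + ltr_offs[0],
                                       elem_start + ltr_offs[0] + L)
                ltr3 = GenomicInterval(scaf.id, elem_start + ltr_offs[1],
                                       elem_start + ltr_offs[1] + L)
            ordered_records.append((i, TruthRecord(
                element_id=f"planted_{i + 1}", spec=spec, interval=iv,
                ltr5=ltr5, ltr3=ltr3, realized_k=realized_k, tsd=tsd,
                sequence=payload,
            )))
        pieces.append(scaf.seq[cursor:])
        new_scaffolds.append(Scaffold(scaf.id, "".join(pieces)))
    if by_scaffold:
        raise PlacementError(f"specs target unknown scaffolds: {sorted(by_scaffold)}")
    registry.records = [rec for _, rec in sorted(ordered_records, key=lambda t: t[0])]
    return GenomeAssembly(new_scaffolds), registry


# ---------------------------------------------------------------------------
# Homolog sets along a species tree (horizontal-transfer scenarios)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HtEvent:
    """Copy a near-identical element across lineages (donor -> recipient)."""

    donor: str
    recipient: str
    residual_divergence: float = 0.01


def simulate_homolog_set(
    subfamily_consensus: str,
    species_tree: "trimkit.phylo.TreeNode",  # noqa: F821
    ht_events: Sequence[HtEvent] = (),
    seed: int = 0,
    rate: float = 1.0,
    ts_tv_ratio: float = 2.0,
    copies_per_species: int = 1,
) -> dict[str, str]:
    """Evolve an element family along a species tree, with optional
    horizontal transfer.

    Branch lengths of ``species_tree`` are multiplied by ``rate`` to give
    expected substitutions/site per branch.  Each HT event replaces the
    recipient species' sequence with the donor's, re-diverged by
    ``residual_divergence`` — the signature of a recent cross-species jump.
    Output labels are ``species`` or ``species.copyN``; substitution-only
    evolution keeps the set alignment-free (equal lengths).
    """
    rng = np.random.default_rng(seed)
    species = species_tree.leaf_names()
    seqs: dict[str, str] = {}

    def walk(node, seq: str) -> None:
        branch = (node.length or 0.0) * rate
        seq = _evolve(seq, branch, ts_tv_ratio, rng) if branch > 0 else seq
        if node.is_leaf():
            seqs[node.name] = seq
        else:
            for child in node.children:
                walk(child, seq)

    walk(species_tree, subfamily_consensus)
    for ev in ht_events:
        if ev.donor not in seqs or ev.recipient not in seqs:
            unknown = {ev.donor, ev.recipient} - set(seqs)
            raise ParameterError(f"HT event names unknown species: {sorted(unknown)}")
        seqs[ev.recipient] = _evolve(seqs[ev.donor], ev.residual_divergence,
                                     ts_tv_ratio, rng)
    if copies_per_species == 1:
        return seqs
    out: dict[str, str] = {}
    for sp in species:
        for c in range(copies_per_species):
            out[f"{sp}.copy{c + 1}"] = _evolve(seqs[sp], 0.002, ts_tv_ratio, rng)
    return out
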
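"""Spatial statistics and insertion-site profiling.

Two questions from the biology drive this module.  First, are copies spread
evenly across scaffolds?  A randomization test re-assigns the observed
number of copies to positions drawn uniformly over the concatenated genome
(scaffolds weighted by length) and compares the observed number of occupied
scaffolds with the null distribution of that count.  Second, what does the
integration site look like?  The 4-bp target site duplication and 5 bp of
flank on each side (a 14-mer context) are tabulated into a position
frequency table, from which GC content, modal nucleotides and sequence-logo
information content are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GenomeAssembly, GenomicInterval, TrimElement, ValidationError

POSITIONS = ["-5", "-4", "-3", "-2", "-1",
             "T1", "T2", "T3", "T4",
             "+1", "+2", "+3", "+4", "+5"]
TSD_POSITIONS = ["T1", "T2", "T3", "T4"]
UP_POSITIONS = POSITIONS[:5]
DOWN_POSITIONS = POSITIONS[9:]
_BASES = "ACGT"


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Randomization test of scaffold occupancy
# ---------------------------------------------------------------------------

@dataclass
class RandomizationResult:
    observed_scaffolds: int
    n_elements: int
    n_reps: int
    null_counts: np.ndarray
    p_value: float
    seed: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "observed_scaffolds": [self.observed_scaffolds],
            "n_elements": [self.n_elements],
            "n_reps": [self.n_reps],
            "null_mean": [float(np.mean(self.null_counts))],
            "null_q05": [float(np.quantile(self.null_counts, 0.05))],
            "p_value": [self.p_value],
        })


def randomization_test(
    scaffold_lengths: Sequence[int],
    n_elements: int,
    observed_scaffolds: int,
    n_reps: int = 5000,
    seed: int = 0,
) -> RandomizationResult:
    """Permutation test for clustering of copies onto few scaffolds.

    Each replicate drops ``n_elements`` positions uniformly over the
    concatenated assembly (so a scaffold is hit with probability
    proportional to its length) and records the number of distinct scaffolds
    hit.  The one-sided p-value for the observed count being small uses the
    +1 finite-sample correction:
    p = (1 + #{null <= observed}) / (n_reps + 1).
    """
    lengths = np.asarray(list(scaffold_lengths), dtype=np.int64)
    if len(lengths) == 0 or (lengths <= 0).any():
        raise ParameterError("scaffold lengths must be positive")
    if n_elements < 1:
        raise ParameterError("need at least one element")
    upper = min(n_elements, len(lengths))
    if not (1 <= observed_scaffolds <= upper):
        raise ParameterError(
            f"observed_scaffolds={observed_scaffolds} outside [1, {upper}]"
        )
    cum = np.cumsum(lengths)
    total = int(cum[-1])
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_reps, dtype=np.int64)
    # vectorised in blocks to bound memory for large replicate counts
    block = max(1, min(n_reps, int(2e6) // max(n_elements, 1)))
    done = 0
    while done < n_reps:
        b = min(block, n_reps - done)
        pos = rng.integers(0, total, size=(b, n_elements))
        scaf = np.searchsorted(cum, pos, side="right")
        scaf.sort(axis=1)
        distinct = 1 + (np.diff(scaf, axis=1) != 0).sum(axis=1)
        null_counts[done : done + b] = distinct
        done += b
    p = (1 + int((null_counts <= observed_scaffolds).sum())) / (n_reps + 1)
    return RandomizationResult(
        observed_scaffolds=observed_scaffolds, n_elements=n_elements,
        n_reps=n_reps, null_counts=null_counts, p_value=p, seed=seed,
    )


# ---------------------------------------------------------------------------
# Regional density and clusters
# ---------------------------------------------------------------------------

def region_density(elements: Sequence[TrimElement],
                   region: GenomicInterval) -> float:
    """Copies per Mb: elements whose interval midpoint lies in the region,
    divided by the region length in Mb (round to one decimal to report)."""
    count = sum(
        1 for el in elements
        if el.element_interval.scaffold_id == region.scaffold_id
        and region.start <= el.element_interval.midpoint < region.end
    )
    return count / (region.length / 1e6)


def find_clusters(elements: Sequence[TrimElement], max_gap_bp: int
                  ) -> list[tuple[GenomicInterval, list[str]]]:
    """Single-linkage clusters of copies on the same scaffold.

    Two copies join when the gap between their intervals is at most
    ``max_gap_bp``; a cluster's region is the span of its members.
    Singletons are returned as clusters of one.
    """
    by_scaffold: dict[str, list[TrimElement]] = {}
    for el in elements:
        by_scaffold.setdefault(el.scaffold_id, []).append(el)
    clusters: list[tuple[GenomicInterval, list[str]]] = []
    for scaf_id in sorted(by_scaffold):
        els = sorted(by_scaffold[scaf_id], key=lambda e: e.element_interval.start)
        current = [els[0]]
        for el in els[1:]:
            gap = el.element_interval.start - current[-1].element_interval.end
            if gap <= max_gap_bp:
                current.append(el)
            else:
                clusters.append(_close_cluster(scaf_id, current))
                current = [el]
        clusters.append(_close_cluster(scaf_id, current))
    return clusters


def _close_cluster(scaf_id: str, members: list[TrimElement]
                   ) -> tuple[GenomicInterval, list[str]]:
    start = min(e.element_interval.start for e in members)
    end = max(e.element_interval.end for e in members)
    return GenomicInterval(scaf_id, start, end), [e.id for e in members]


# ---------------------------------------------------------------------------
# TSD context profiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TsdContext:
    """A 4-bp TSD with 5 bp of flank on each side (the 14-mer unit)."""

    up_flank: str
    tsd: str
    down_flank: str

    def __post_init__(self) -> None:
        if len(self.up_flank) != 5 or len(self.tsd) != 4 or len(self.down_flank) != 5:
            raise ValidationError("TSD context must be 5 + 4 + 5 bp")

    @property
    def sequence(self) -> str:
        return self.up_flank + self.tsd + self.down_flank


@dataclass
class PositionFrequencyTable:
    """Counts of A, C, G, T at each of the 14 context positions."""

    counts: np.ndarray                      # shape (14, 4), order ACGT
    n: int
    positions: list[str] = field(default_factory=lambda: list(POSITIONS))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.positions), 4):
            raise ValidationError("count matrix must be positions x 4")
        sums = self.counts.sum(axis=1)
        if not (sums == self.n).all():
            raise ValidationError(
                f"per-position counts must sum to n={self.n}; got {sums.tolist()}"
            )

    @classmethod
    def from_contexts(cls, contexts: Sequence[TsdContext]) -> "PositionFrequencyTable":
        counts = np.zeros((len(POSITIONS), 4), dtype=np.int64)
        for ctx in contexts:
            for i, base in enumerate(ctx.sequence):
                counts[i, _BASES.index(base)] += 1
        return cls(counts=counts, n=len(contexts))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PositionFrequencyTable":
        df = df.set_index("position") if "position" in df.columns else df
        counts = df.loc[POSITIONS, list(_BASES)].to_numpy(dtype=np.int64)
        return cls(counts=counts, n=int(counts.sum(axis=1)[0]))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.counts, columns=list(_BASES))
        out.insert(0, "position", self.positions)
        return out

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n


def load_published_tsd_counts() -> PositionFrequencyTable:
    """The published nucleotide-frequency table for 171 TSD contexts of the
    ant TRIM family (59 complete elements + 112 solo-LTRs)."""
    from importlib import resources

    path = resources.files("trimkit") / "data" / "pbtrim_tsd_counts.tsv"
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return PositionFrequencyTable.from_frame(df)


def extract_tsd_contexts(elements: Sequence[TrimElement],
                         assembly: GenomeAssembly) -> list[TsdContext]:
    """Contexts for every element with a called TSD and full 5-bp flanks."""
    contexts = []
    for el in elements:
        if el.tsd is None:
            continue
        scaf = assembly.get(el.scaffold_id)
        iv = el.element_interval
        up_start = iv.start - 9       # 5 bp flank + 4 bp TSD upstream copy
        down_end = iv.end + 9
        if up_start < 0 or down_end > scaf.length:
            continue
        up = scaf.seq[iv.start - 9 : iv.start - 4]
        down = scaf.seq[iv.end + 4 : iv.end + 9]
        if set(up + el.tsd + down) - set(_BASES):
            continue
        contexts.append(TsdContext(up_flank=up, tsd=el.tsd, down_flank=down))
    return contexts


def tsd_context_table(elements: Sequence[TrimElement],
                      assembly: GenomeAssembly) -> PositionFrequencyTable:
    """Position frequency table over all qualifying TSD contexts."""
    return PositionFrequencyTable.from_contexts(extract_tsd_contexts(elements, assembly))


def composition_stats(table: PositionFrequencyTable,
                      position_subset: Sequence[str]) -> dict:
    """GC fraction and per-position modal nucleotide over a position subset.

    GC is summed C+G counts over the subset divided by n * |subset|; modal
    frequencies are percentages of n.  GC + AT = 1 by construction.
    """
    idx = [table.positions.index(p) for p in position_subset]
    if not idx:
        raise ParameterError("empty position subset")
    sub = table.counts[idx]
    gc = float(sub[:, [1, 2]].sum() / (table.n * len(idx)))
    modal = []
    for row, pos in zip(sub, position_subset):
        b = int(np.argmax(row))
        modal.append((pos, _BASES[b], 100.0 * row[b] / table.n))
    return {"gc": gc, "at": 1.0 - gc, "modal": modal}


def logo_information(table: PositionFrequencyTable,
                     small_sample_correction: bool = False) -> np.ndarray:
    """Per-position information content in bits, R = 2 - H (- e_n).

    H is the Shannon entropy of the column's base frequencies; the optional
    small-sample correction subtracts e_n = 3 / (2 ln2 n).  Values are
    floored at zero.  Letter heights for rendering are p * R (see
    :func:`logo_letter_heights`).
    """
    p = table.frequencies()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    h = -terms.sum(axis=1)
    r = 2.0 - h
    if small_sample_correction:
        r = r - 3.0 / (2.0 * np.log(2) * table.n)
    return np.maximum(r, 0.0)


def logo_letter_heights(table: PositionFrequencyTable,
                        small_sample_correction: bool = False) -> pd.DataFrame:
    r = logo_information(table, small_sample_correction)
    heights = table.frequencies() * r[:, None]
    out = pd.DataFrame(heights, columns=list(_BASES))
    out.insert(0, "position", table.positions)
    return out


def render_logo(table: PositionFrequencyTable, path: str,
                small_sample_correction: bool = False) -> None:
    """Render a simple stacked-bar sequence logo with matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heights = logo_letter_heights(table, small_sample_correction)
    fig, ax = plt.subplots(figsize=(8, 2.5))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    x = np.arange(len(table.positions))
    for i in x:
        bottom = 0.0
        order = sorted(_BASES, key=lambda b: heights.loc[i, b])
        for b in order:
            h = heights.loc[i, b]
            if h <= 0:
                continue
            ax.bar(i, h, bottom=bottom, color=colors[b], width=0.8)
            if h > 0.08:
                ax.text(i, bottom + h / 2, b, ha="center", va="center",
                        fontsize=7, color="white", fontweight="bold")
            bottom += h
    ax.set_xticks(x, table.positions)
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
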
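"""Insertion-age estimation from LTR-pair divergence.

At integration time the two LTRs of a retroelement are identical copies;
they then accumulate point substitutions independently, so their divergence
clocks the insertion.  The pipeline is: global alignment of the two LTRs,
Kimura-2-parameter distance K from transition (P) and transversion (Q)
proportions over comparable (gap- and N-free) columns, and

    T = K / (2 r)

with r the host synonymous substitution rate in substitutions/site/year
(default 0.54e-8, an average for ant nuclear genes).  Saturated pairs raise
an error rather than producing a clamped age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import DEFAULT_SUBSTITUTION_RATE, ValidationError

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = set("ACGT")


class SaturationError(ValueError):
    """K2P distance undefined: 1-2P-Q <= 0 or 1-2Q <= 0."""


@dataclass(frozen=True)
class K2PResult:
    aligned_sites: int
    P: float
    Q: float
    K: float


@dataclass(frozen=True)
class AgeEstimate:
    """Dated complete element: K2P quantities plus T = K/(2 r)."""

    element_id: str
    aligned_sites: int
    P: float
    Q: float
    K: float
    r: float
    T: float

    @property
    def T_my(self) -> float:
        return self.T / 1e6


# ---------------------------------------------------------------------------
# Global alignment (match +1, mismatch -1, gap -2, end gaps penalised)
# ---------------------------------------------------------------------------

MATCH, MISMATCH, GAP = 1, -1, -2


def align_ltr_pair(a: str, b: str) -> tuple[str, str]:
    """Needleman–Wunsch global alignment of two LTR sequences.

    End gaps are penalised like internal ones.  Traceback ties are broken
    deterministically: diagonal first, then up (gap in the second sequence),
    then left.
    """
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = GAP * np.arange(n + 1)
    score[0, :] = GAP * np.arange(m + 1)
    sub = np.where(
        (np.frombuffer(a.encode(), dtype="S1")[:, None]
         == np.frombuffer(b.encode(), dtype="S1")[None, :]),
        MATCH, MISMATCH,
    )
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + GAP
        row = score[i]
        prev = row[0]
        best = np.maximum(diag, up)
        for j in range(1, m + 1):
            prev = max(best[j - 1], prev + GAP)
            row[j] = prev
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        s = score[i, j]
        if i > 0 and j > 0 and s == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and s == score[i - 1, j] + GAP:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def alignment_score(a_row: str, b_row: str) -> int:
    """Score of an alignment under the module's scoring scheme."""
    s = 0
    for x, y in zip(a_row, b_row):
        if x == "-" or y == "-":
            s += GAP
        else:
            s += MATCH if x == y else MISMATCH
    return s


# ---------------------------------------------------------------------------
# Kimura 2-parameter distance
# ---------------------------------------------------------------------------

def k2p_distance(a_row: str, b_row: str) -> K2PResult:
    """K2P distance over the comparable columns of an aligned pair.

    Columns containing a gap or an ambiguous base in either row are excluded
    from the site count.  K = -1/2 ln((1-2P-Q) sqrt(1-2Q)).
    """
    if len(a_row) != len(b_row):
        raise ValidationError("aligned rows differ in length; align first")
    n = ts = tv = 0
    for x, y in zip(a_row.upper(), b_row.upper()):
        if x not in _BASES or y not in _BASES:
            continue
        n += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValidationError("no comparable sites between the two rows")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P distance undefined (P={P:.4f}, Q={Q:.4f}): divergence saturated"
        )
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(aligned_sites=n, P=P, Q=Q, K=max(K, 0.0))


def insertion_age(K: float, r: float = DEFAULT_SUBSTITUTION_RATE) -> float:
    """T = K / (2 r), in years."""
    if K < 0:
        raise ValidationError(f"negative distance K={K}")
    if r <= 0:
        raise ValidationError(f"substitution rate must be positive, got {r}")
    return K / (2.0 * r)


def date_ltr_pair(element_id: str, ltr5: str, ltr3: str,
                  r: float = DEFAULT_SUBSTITUTION_RATE,
                  pre_aligned: bool = False) -> AgeEstimate:
    """Align (unless ``pre_aligned``), compute K2P and date one element."""
    rows = (ltr5, ltr3) if pre_aligned else align_ltr_pair(ltr5, ltr3)
    res = k2p_distance(*rows)
    return AgeEstimate(
        element_id=element_id, aligned_sites=res.aligned_sites,
        P=res.P, Q=res.Q, K=res.K, r=r, T=insertion_age(res.K, r),
    )


def age_distribution(estimates: Sequence[AgeEstimate], bin_width_my: float = 1.0,
                     subfamilies: Optional[dict[str, str]] = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram of ages (My) plus per-subfamily mean ages.

    Returns (histogram table, summary table).  The histogram uses left-closed
    bins of ``bin_width_my``; the summary reports n and mean age per
    subfamily label (single "all" row when no labels are given).
    """
    if bin_width_my <= 0:
        raise ValidationError("bin width must be positive")
    ages = np.array([e.T_my for e in estimates])
    if len(ages) == 0:
        hist = pd.DataFrame({"bin_left_my": [], "bin_right_my": [], "count": []})
        return hist, pd.DataFrame({"subfamily": [], "n": [], "mean_age_my": []})
    n_bins = max(1, int(np.floor(ages.max() / bin_width_my)) + 1)
    edges = np.arange(n_bins + 1) * bin_width_my
    counts, _ = np.histogram(ages, bins=edges)
    hist = pd.DataFrame({
        "bin_left_my": edges[:-1], "bin_right_my": edges[1:], "count": counts,
    })
    labels = [
        (subfamilies or {}).get(e.element_id, "all") for e in estimates
    ]
    summary = (
        pd.DataFrame({"subfamily": labels, "age_my": ages})
        .groupby("subfamily", as_index=False)
        .agg(n=("age_my", "size"), mean_age_my=("age_my", "mean"))
    )
    return hist, summary
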
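"""Sequential correlation of binding residues and amino-acid-pair screening.

Binding residues of one metal-ion site cluster along the sequence: the gap
``d`` between two consecutive binding residues (number of residues strictly
between them, so d = 0 means adjacent) has a heavy mass at small d. The
pipeline here (i) estimates the gap distribution p(d) over a chain set,
(ii) selects the gap orders with p(d) above a probability threshold,
(iii) for each selected order screens the 400 ordered amino-acid pairs by
the difference of their occurrence probabilities between positive and
negative fragment sets (D-values), and (iv) turns the top-100 pairs, split
into 10 rank groups of 10, into per-fragment group-occupancy features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabets import PAIR_INDEX, PAIRS400, X
from .io import AnnotatedChain, Fragment

__all__ = [
    "CorrelationTable",
    "PairScreen",
    "consecutive_distances",
    "correlation_table",
    "select_orders",
    "pair_frequencies",
    "screen_pairs",
    "correlation_features",
]

#: gap orders with probability strictly above this are kept as features
ORDER_THRESHOLD = 0.10


@dataclass(frozen=True)
class CorrelationTable:
    """Empirical distribution of gaps between consecutive binding residues."""

    counts: Mapping[int, int]
    total_pairs: int

    def p(self, d: int) -> float:
        if self.total_pairs == 0:
            return 0.0
        return self.counts.get(d, 0) / self.total_pairs

    @property
    def probabilities(self) -> dict[int, float]:
        return {d: c / self.total_pairs for d, c in sorted(self.counts.items())}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"d": d, "count": c, "p": c / self.total_pairs if self.total_pairs else 0.0}
            for d, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["d", "count", "p"])


@dataclass(frozen=True)
class PairScreen:
    """Top-100 D-value screen of the 400 ordered pairs at one gap order.

    ``dvalues`` is positive-set frequency minus negative-set frequency in
    the fixed row-major pair order (AA, AC, ..., YY); ``top100`` holds pair
    strings ranked by |D| descending (ties broken by that fixed order), and
    ``groups`` maps each top-100 pair to its rank group 0..9 (10 consecutive
    ranks per group).
    """

    order: int
    pos_freq: np.ndarray
    neg_freq: np.ndarray
    dvalues: np.ndarray
    top100: tuple
    groups: Mapping[str, int] = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": r + 1,
                "pair": p,
                "D": float(self.dvalues[PAIR_INDEX[p]]),
                "group": self.groups[p] + 1,
            }
            for r, p in enumerate(self.top100)
        ]
        return pd.DataFrame(rows, columns=["rank", "pair", "D", "group"])


def consecutive_distances(chain: AnnotatedChain) -> list[int]:
    """Gaps between consecutive binding residues, scanned left to right.

    For consecutive binding positions a < b the gap is b - a - 1 (residues
    strictly between), so adjacent binders give d = 0. Chains with fewer
    than two binding residues yield an empty list.
    """
    pos = sorted(chain.binding_positions)
    return [b - a - 1 for a, b in zip(pos, pos[1:])]


def correlation_table(chains: Iterable[AnnotatedChain]) -> CorrelationTable:
    """Pool gap counts over chains into an empirical gap distribution."""
    counts: dict[int, int] = {}
    total = 0
    for chain in chains:
        for d in consecutive_distances(chain):
            counts[d] = counts.get(d, 0) + 1
            total += 1
    if total == 0:
        warnings.warn("no consecutive binding-residue pairs; correlation table is empty")
    return CorrelationTable(counts=counts, total_pairs=total)


def select_orders(table: CorrelationTable, threshold: float = ORDER_THRESHOLD) -> list[int]:
    """Gap orders whose probability strictly exceeds ``threshold``, ascending.

    If no order clears the threshold, the single most probable order is
    returned (with a warning) so downstream features stay well-defined.
    """
    if table.total_pairs == 0:
        raise ValueError("cannot select orders from an empty correlation table")
    selected = sorted(d for d in table.counts if table.p(d) > threshold)
    if not selected:
        best = max(sorted(table.counts), key=table.p)
        warnings.warn(
            f"no gap order has probability > {threshold}; falling back to d={best}"
        )
        return [best]
    return selected


def pair_frequencies(fragments: Sequence[Fragment], d: int) -> np.ndarray:
    """Occurrence frequencies of the 400 ordered pairs at window offset d+1.

    For each fragment, every slot (i, i+d+1) inside the window contributes
    one pair; slots touching the pseudo-residue X are skipped, but still
    count in the denominator (total scanned slots), so the vector sums to 1
    only when no X is present.
    """
    if d < 0:
        raise ValueError("gap order d must be >= 0")
    offset = d + 1
    counts = np.zeros(len(PAIRS400), dtype=np.int64)
    slots = 0
    for frag in fragments:
        s = frag.residues
        if len(s) <= offset:
            continue
        slots += len(s) - offset
        for i in range(len(s) - offset):
            a, b = s[i], s[i + offset]
            if a == X or b == X:
                continue
            counts[PAIR_INDEX[a + b]] += 1
    if slots == 0:
        return np.zeros(len(PAIRS400))
    return counts / slots


def screen_pairs(pos_freq: np.ndarray, neg_freq: np.ndarray, order: int = 0) -> PairScreen:
    """Rank the 400 pairs by |positive - negative| frequency difference.

    Ranking is by absolute D-value descending; ties are broken by the fixed
    row-major pair order. The top 100 pairs are split into 10 consecutive
    rank groups of 10.
    """
    pos_freq = np.asarray(pos_freq, dtype=float)
    neg_freq = np.asarray(neg_freq, dtype=float)
    if pos_freq.shape != (400,) or neg_freq.shape != (400,):
        raise ValueError("pair frequency vectors must have length 400")
    dvalues = pos_freq - neg_freq
    # stable sort on -|D| keeps the fixed pair order among ties
    ranking = np.argsort(-np.abs(dvalues), kind="stable")
    top100 = tuple(PAIRS400[i] for i in ranking[:100])
    groups = {p: r // 10 for r, p in enumerate(top100)}
    return PairScreen(
        order=order,
        pos_freq=pos_freq,
        neg_freq=neg_freq,
        dvalues=dvalues,
        top100=top100,
        groups=groups,
    )


def correlation_features(fragment: Fragment, screens: Sequence[PairScreen]) -> np.ndarray:
    """Group-occupancy features of one fragment, 10 per screened gap order.

    For each screen (order d), entry g is the number of X-free window pairs
    at offset d+1 that fall in rank group g, divided by the number of slots
    L - d - 1. Screens are concatenated in ascending order of d.
    """
    blocks = []
    for screen in sorted(screens, key=lambda s: s.order):
        offset = screen.order + 1
        s = fragment.residues
        vec = np.zeros(10)
        n_slots = len(s) - offset
        if n_slots <= 0:
            warnings.warn(
                f"fragment shorter than offset {offset + 1}; zero correlation block"
            )
            blocks.append(vec)
            continue
        for i in range(n_slots):
            a, b = s[i], s[i + offset]
            if a == X or b == X:
                continue
            g = screen.groups.get(a + b)
            if g is not None:
                vec[g] += 1
        blocks.append(vec / n_slots)
    return np.concatenate(blocks) if blocks else np.zeros(0)
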
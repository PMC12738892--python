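"""Comparison of consensus signal sets between two drug cohorts.

Supports the standard presentation of a two-drug pharmacovigilance
comparison: shared vs drug-exclusive significant terms, the per-method
Venn partition (which of the four detection methods flagged each term),
and top-N rankings by report count or ROR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import pandas as pd

from .signals import SignalScore

METHODS = ("ror", "mhra", "bcpnn", "mgps")


@dataclass
class SignalComparison:
    drug_a: str
    drug_b: str
    shared: list[tuple[SignalScore, SignalScore]]
    exclusive_a: list[SignalScore]
    exclusive_b: list[SignalScore]

    @property
    def shared_terms(self) -> set[str]:
        return {sa.term for sa, _ in self.shared}


def compare(
    signals_a: Sequence[SignalScore],
    signals_b: Sequence[SignalScore],
    drug_a: str = "A",
    drug_b: str = "B",
) -> SignalComparison:
    """Set algebra on the consensus-significant terms of two score lists.

    Both lists must be computed at the same level (PT or SOC) and with the
    same background convention; a level mismatch is a hard error.
    """
    levels = {s.level for s in signals_a} | {s.level for s in signals_b}
    if len(levels) > 1:
        raise ValueError(f"signal lists mix levels: {sorted(levels)}")
    sig_a = {s.term: s for s in signals_a if s.consensus}
    sig_b = {s.term: s for s in signals_b if s.consensus}
    shared_terms = sorted(sig_a.keys() & sig_b.keys())
    return SignalComparison(
        drug_a,
        drug_b,
        shared=[(sig_a[t], sig_b[t]) for t in shared_terms],
        exclusive_a=[sig_a[t] for t in sorted(sig_a.keys() - sig_b.keys())],
        exclusive_b=[sig_b[t] for t in sorted(sig_b.keys() - sig_a.keys())],
    )


def top_n(
    signals: Sequence[SignalScore],
    key: Literal["count", "ror"] = "count",
    n: int = 15,
) -> list[SignalScore]:
    """Top-n signals by report count (the a cell) or ROR, descending.

    Ties break on the other key (also descending), then on the term
    lexicographically; an undefined (NaN) ROR sorts after any finite one.
    """
    if n < 1:
        raise ValueError("n must be >= 1")

    def _ror(s: SignalScore) -> float:
        return -math.inf if math.isnan(s.ror) else s.ror

    if key == "count":
        sort_key = lambda s: (-s.table.a, -_ror(s), s.term)
    elif key == "ror":
        sort_key = lambda s: (-_ror(s), -s.table.a, s.term)
    else:
        raise ValueError(f"unknown ranking key {key!r}")
    return sorted(signals, key=sort_key)[:n]


def venn_regions(signals: Sequence[SignalScore]) -> pd.DataFrame:
    """Membership table of the 15 non-empty regions of the four-method Venn
    partition: one row per region (subset of methods) with its term count
    and the terms flagged by exactly that subset of methods."""
    flag_of = {
        "ror": lambda s: s.flag_ror,
        "mhra": lambda s: s.flag_mhra,
        "bcpnn": lambda s: s.flag_bcpnn,
        "mgps": lambda s: s.flag_mgps,
    }
    rows = []
    for r in range(1, len(METHODS) + 1):
        for subset in combinations(METHODS, r):
            terms = sorted(
                s.term
                for s in signals
                if all(flag_of[m](s) for m in subset)
                and not any(flag_of[m](s) for m in METHODS if m not in subset)
            )
            rows.append(
                {
                    "region": "+".join(subset),
                    "n_methods": r,
                    "n_terms": len(terms),
                    "terms": ";".join(terms),
                }
            )
    return pd.DataFrame(rows)


def comparison_frames(cmp: SignalComparison) -> dict[str, pd.DataFrame]:
    """shared / exclusive tables ready to be written as TSV."""
    from .signals import scores_to_frame

    shared = scores_to_frame([sa for sa, _ in cmp.shared])
    if not shared.empty:
        other = scores_to_frame([sb for _, sb in cmp.shared]).set_index("term")
        for colname in ("a", "ROR", "IC025", "EBGM05"):
            shared[f"{colname}_{cmp.drug_b}"] = shared["term"].map(other[colname])
    return {
        "shared": shared,
        "exclusive_a": scores_to_frame(cmp.exclusive_a),
        "exclusive_b": scores_to_frame(cmp.exclusive_b),
    }
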
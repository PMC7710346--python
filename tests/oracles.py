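"""Independent brute-force oracles the implementation is checked against."""

from __future__ import annotations

from itertools import chain
from typing import Iterable, Mapping


def bh_oracle(p_values: list[float]) -> list[float]:
    """Literal double-loop Benjamini-Hochberg step-up.

    Sort ascending; q at sorted position i is min over j >= i of m*p_(j)/(j+1)
    (0-based), clipped to 1; return in the input order.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    sorted_p = [p_values[i] for i in order]
    q_sorted = []
    for i in range(m):
        best = min(m * sorted_p[j] / (j + 1) for j in range(i, m))
        q_sorted.append(min(best, 1.0))
    q = [0.0] * m
    for pos, idx in enumerate(order):
        q[idx] = q_sorted[pos]
    return q


def venn_regions_oracle(named_sets: Mapping[str, Iterable[str]]) -> dict[int, int]:
    """Exhaustive per-gene classification into membership bitmasks."""
    names = list(named_sets)
    sets = {n: set(named_sets[n]) for n in names}
    counts: dict[int, int] = {}
    for gene in set(chain.from_iterable(sets.values())):
        mask = 0
        for bit, name in enumerate(names):
            if gene in sets[name]:
                mask |= 1 << bit
        counts[mask] = counts.get(mask, 0) + 1
    return counts
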
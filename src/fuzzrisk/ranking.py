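"""Shared rank assignment.

Every ranking in the package uses competition ("1224") ranking: tied scores
share the minimum rank of their group and the next distinct score resumes at
1 + number of already-ranked items.  Within a tie group the input order
(failure-mode id order) is preserved, so output order is deterministic.
"""

from __future__ import annotations

from typing import Sequence

__all__ = ["competition_ranks"]


def competition_ranks(values: Sequence[float], descending: bool = True) -> list[int]:
    """Competition ranks of ``values`` (rank 1 = best).

    Ties are detected by exact equality: tied groups arise here from
    genuinely identical inputs, which produce bit-identical floats.
    """
    order = sorted(range(len(values)), key=lambda i: values[i], reverse=descending)
    ranks = [0] * len(values)
    prev_val: float | None = None
    prev_rank = 0
    for pos, idx in enumerate(order, start=1):
        v = values[idx]
        if prev_val is not None and v == prev_val:
            ranks[idx] = prev_rank
        else:
            ranks[idx] = pos
            prev_rank = pos
            prev_val = v
    return ranks
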
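"""Independent oracles used only by the test suite.

These deliberately re-derive results through a different route than the
package (plain dynamic programming, exact enumeration) so that agreement is
evidence, not tautology.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def sw_gotoh_score(
    query: str,
    reference: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -1.0,
    gap_extend: float = -0.5,
) -> float:
    """Smith-Waterman local alignment score with Gotoh affine gaps.

    A length-g gap costs gap_open + (g-1)*gap_extend.  N is a mismatch
    against everything, including N.  Score-only, exhaustive over all cells.
    """

    def s(a: str, b: str) -> float:
        return match if (a == b and a != "N") else mismatch

    n, m = len(reference), len(query)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in reference (insertion)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in query (deletion)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            H[i, j] = max(
                0.0,
                H[i - 1, j - 1] + s(reference[i - 1], query[j - 1]),
                E[i, j],
                F[i, j],
            )
            best = max(best, H[i, j])
    return best


@lru_cache(maxsize=None)
def _signed_rank_counts(n: int) -> tuple[int, ...]:
    """Distribution of the signed-rank statistic W+ = sum of positive ranks
    under the null, by exact enumeration over the 2^n sign assignments
    (counts[w] = number of assignments with W+ == w)."""
    total = n * (n + 1) // 2
    counts = [0] * (total + 1)
    counts[0] = 1
    for rank in range(1, n + 1):
        new = counts[:]
        for w in range(total - rank + 1):
            if counts[w]:
                new[w + rank] += counts[w]
        counts = new
    return tuple(counts)


def exact_wilcoxon_pvalue(diffs: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p-value (no ties, no zeros)."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
    w_plus = int(ranks[diffs > 0].sum())
    counts = _signed_rank_counts(n)
    total = n * (n + 1) // 2
    w_min = min(w_plus, total - w_plus)
    lower = sum(counts[: w_min + 1])
    p = 2.0 * lower / 2**n
    return min(p, 1.0)


def replay_errors(true_seq: str, error_log: str) -> str:
    """Rebuild a mutated read region from its true sequence and the
    truth-table error entries (``pos:type:from:to`` in true coordinates)."""
    events: dict[int, list[tuple[str, str, str]]] = {}
    if error_log:
        for entry in error_log.split(";"):
            pos, etype, frm, to = entry.split(":")
            events.setdefault(int(pos), []).append((etype, frm, to))
    out = []
    for i, base in enumerate(true_seq, start=1):
        here = events.get(i, [])
        deleted = any(e[0] == "del" for e in here)
        subs = [e for e in here if e[0] == "sub"]
        if deleted:
            pass
        elif subs:
            assert subs[0][1] == base
            out.append(subs[0][2])
        else:
            out.append(base)
        for etype, _frm, to in here:
            if etype == "ins":
                out.append(to)
    return "".join(out)
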
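"""Independent reference implementations used only by the tests."""

from __future__ import annotations

import sys
from functools import lru_cache


def oracle_identity(a: str, b: str) -> float:
    """Top-down memoized global alignment under match=+1, mismatch=-1,
    gap=-1, preferring the fewest matches among score-optimal
    alignments (the most compact one); identity = matches / length."""
    sys.setrecursionlimit(10000)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> tuple[int, int]:
        """(score, -matches) of the best alignment of suffixes."""
        if i == len(a) and j == len(b):
            return (0, 0)
        cands = []
        if i < len(a) and j < len(b):
            s, neg_m = best(i + 1, j + 1)
            if a[i] == b[j]:
                cands.append((s + 1, neg_m - 1))
            else:
                cands.append((s - 1, neg_m))
        if i < len(a):
            s, neg_m = best(i + 1, j)
            cands.append((s - 1, neg_m))
        if j < len(b):
            s, neg_m = best(i, j + 1)
            cands.append((s - 1, neg_m))
        return max(cands)

    score, neg_matches = best(0, 0)
    best.cache_clear()
    matches = -neg_matches
    return matches / (2 * matches - score)


def brute_force_summary(abundance, samples, threshold, cosmopolitan_min):
    """Full-scan recomputation of the per-sOTU ecology summary (plain
    loops over the matrix, no pandas reductions)."""
    from amplidiv.ecology import CATEGORY_ORDER, EXCLUDED

    active = [s for s in samples if s.category != EXCLUDED and s.sample_id in abundance.index]
    out = {}
    for sotu in abundance.columns:
        n_pos = n_ge = 0
        counts: dict[str, int] = {}
        sums: dict[str, float] = {}
        max_val, max_cat = 0.0, ""
        for s in active:
            val = float(abundance.at[s.sample_id, sotu])
            if val > 0:
                n_pos += 1
                counts[s.category] = counts.get(s.category, 0) + 1
                sums[s.category] = sums.get(s.category, 0.0) + val
                if val > max_val:
                    max_val, max_cat = val, s.category
            if val >= threshold:
                n_ge += 1
        dominant = ""
        if counts:
            dominant = min(counts, key=lambda c: (-counts[c], -sums[c], CATEGORY_ORDER.index(c)))
        out[sotu] = {
            "n_positive": n_pos,
            "n_positive_ge_threshold": n_ge,
            "dominant_environment": dominant,
            "max_abundance": max_val,
            "max_abundance_environment": max_cat,
            "cosmopolitan": n_pos >= cosmopolitan_min,
        }
    return out
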
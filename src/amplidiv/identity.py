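"""Global-alignment percent identity between ungapped sequences.

Identity is defined over an end-to-end (Needleman-Wunsch) alignment with
match = +1, mismatch = -1, gap = -1 and equals matches / alignment
length.  Among score-optimal alignments the most compact one (fewest
gap columns, equivalently fewest matches) is used, which makes the
value deterministic and symmetric; for equal-length sequences this is
the gap-free alignment whenever it is optimal, so identity reduces to
1 - hamming/length there.  With this scoring the alignment length need
not be traced back: every alignment satisfies
``length = 2 * matches - score``, so the lexicographic DP on
(score, -matches) determines identity exactly.

The inner loop is JIT-compiled with numba; a pure-Python fallback keeps
the module importable without it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pairwise_identity", "alignment_stats"]

_ENCODE = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate(b"ACGTN-", start=1):
    _ENCODE[_c] = _i


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def _nw_kernel_py(a, b):
    n, m = len(a), len(b)
    prev_s = np.arange(0, -(m + 1), -1, dtype=np.int64)
    prev_m = np.zeros(m + 1, dtype=np.int64)
    cur_s = np.empty(m + 1, dtype=np.int64)
    cur_m = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        cur_s[0] = -i
        cur_m[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            match = ai == b[j - 1]
            s = prev_s[j - 1] + (1 if match else -1)
            mm = prev_m[j - 1] + (1 if match else 0)
            s2 = prev_s[j] - 1
            if s2 > s or (s2 == s and prev_m[j] < mm):
                s, mm = s2, prev_m[j]
            s3 = cur_s[j - 1] - 1
            if s3 > s or (s3 == s and cur_m[j - 1] < mm):
                s, mm = s3, cur_m[j - 1]
            cur_s[j] = s
            cur_m[j] = mm
        prev_s, cur_s = cur_s, prev_s
        prev_m, cur_m = cur_m, prev_m
    return prev_s[m], prev_m[m]


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _nw_kernel = njit(cache=True, nogil=True)(_nw_kernel_py)
except ImportError:  # pragma: no cover
    _nw_kernel = _nw_kernel_py


def alignment_stats(a: str, b: str) -> tuple[int, int, int]:
    """Return (score, matches, alignment_length) of the optimal global
    alignment, minimising gap columns among score-optimal alignments."""
    if not a or not b:
        raise ValueError("pairwise identity requires two nonempty sequences")
    score, matches = _nw_kernel(_encode(a), _encode(b))
    return int(score), int(matches), int(2 * matches - score)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching columns in the optimal global alignment of
    *a* and *b*; symmetric, in [0, 1]."""
    _, matches, length = alignment_stats(a, b)
    return matches / length
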
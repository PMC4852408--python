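"""Independent reference implementations used only to check the library.

These deliberately avoid the library's own algorithms: interval overlap by
literal base enumeration, and HMM decoding by scoring every possible state
path.
"""

from __future__ import annotations

import numpy as np


def overlap_by_enumeration(a, b) -> int:
    """Shared bases counted one position at a time (small intervals only)."""
    if a.chrom != b.chrom:
        return 0
    bases_a = set(range(a.start, a.end + 1))
    return sum(1 for p in range(b.start, b.end + 1) if p in bases_a)


def exhaustive_best_path(log_em: np.ndarray, log_prior: np.ndarray, log_trans: np.ndarray):
    """Score all S^n state sequences; return (best path, best log joint).

    Path index i encodes states most-significant-digit-first in base S, so
    decoding i recovers the chronological state sequence.
    """
    n, n_states = log_em.shape
    scores = log_prior + log_em[0]
    for t in range(1, n):
        last = np.arange(scores.size) % n_states
        scores = (scores[:, None] + log_trans[last, :] + log_em[t][None, :]).ravel()
    best_idx = int(scores.argmax())
    path = np.empty(n, dtype=int)
    for t in range(n - 1, -1, -1):
        path[t] = best_idx % n_states
        best_idx //= n_states
    return path, float(scores.max())
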
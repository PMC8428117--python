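"""Exhaustive reference scanner: brute-force maximal-window enumeration.

Independent correctness oracle for :mod:`pirnascan.scan`. Enumerates every
(query offset, target offset, length) window directly from the full
query-vs-target mismatch matrix and applies the maximality definition
literally: a window is a hit iff its length is within [min_len, max_len],
its mismatch count is within budget, and any 1-nt extension on either side
would exceed the budget, the length cap, or a sequence boundary.

Shares no search logic with the seeded scanner; only the parameter object
and the hit container are reused.
"""

from __future__ import annotations

import numpy as np

from .scan import HomologyHit, ScanParams
from .sequence import SeqRecord, reverse_complement


def _seq_array(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _maximal_hits_matrix(q: str, t: str, params: ScanParams) -> list[tuple[int, int, int, int]]:
    """All maximal (q_start, t_start, length, mismatches), q read forward."""
    nq, nt = len(q), len(t)
    if nq < params.min_len or nt < params.min_len:
        return []
    k = params.max_mismatch
    BIG = k + 1  # out-of-bounds cells block any window or extension crossing them
    qa, ta = _seq_array(q), _seq_array(t)
    n_code = ord("N")
    M = (qa[:, None] != ta[None, :]) | (qa[:, None] == n_code) | (ta[None, :] == n_code)
    M = M.astype(np.int32)
    # Shear rows so each column is one diagonal, padded with blocking cells.
    D = np.full((nq, nq + nt - 1), BIG, dtype=np.int32)
    for i in range(nq):
        D[i, nq - 1 - i : nq - 1 - i + nt] = M[i]
    # Virtual blocking rows above and below for boundary extensions.
    De = np.vstack(
        [np.full((1, D.shape[1]), BIG, np.int32), D, np.full((1, D.shape[1]), BIG, np.int32)]
    )
    P = np.vstack([np.zeros((1, D.shape[1]), np.int32), np.cumsum(D, axis=0)])
    out: list[tuple[int, int, int, int]] = []
    for L in range(params.min_len, params.max_len + 1):
        if L > nq:
            break
        mm = P[L:] - P[:-L]  # shape (nq - L + 1, ndiag); row s = window start
        ok = mm <= k
        if L < params.max_len:
            ns = mm.shape[0]
            left = De[0:ns]        # cell just before each window start
            right = De[L + 1 : L + 1 + ns]  # cell just after each window end
            ok &= (mm + left > k) & (mm + right > k)
        for s, d in zip(*np.nonzero(ok)):
            ts = int(s) + int(d) - (nq - 1)
            out.append((int(s), ts, L, int(mm[s, d])))
    return out


def scan_bruteforce(
    queries: list[SeqRecord], targets: list[SeqRecord], params: ScanParams
) -> list[HomologyHit]:
    """Oracle equivalent of :func:`pirnascan.scan.scan`."""
    hits: list[HomologyHit] = []
    for q in queries:
        oriented = {}
        if "+/+" in params.orientations:
            oriented["+/+"] = q.seq
        if "+/-" in params.orientations:
            oriented["+/-"] = reverse_complement(q.seq)
        for t in targets:
            for orient, qseq in oriented.items():
                for qs, ts, length, mm in _maximal_hits_matrix(qseq, t.seq, params):
                    if orient == "+/-":
                        fwd_start = len(qseq) - (qs + length)
                        fwd_end = len(qseq) - qs
                    else:
                        fwd_start, fwd_end = qs, qs + length
                    hits.append(
                        HomologyHit(
                            query_id=q.id,
                            query_start=fwd_start,
                            query_end=fwd_end,
                            target_id=t.id,
                            target_start=ts,
                            target_end=ts + length,
                            orientation=orient,
                            mismatches=mm,
                        )
                    )
    hits.sort(key=HomologyHit.sort_key)
    return hits
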
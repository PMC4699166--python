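"""Compare-and-exchange networks for oblivious merging of sorted records.

Two data owners each hold a locally sorted list of keyed records; the
computational parties must combine them into one sorted list without
learning anything from the control flow.  Both networks here are built from
the compare-and-exchange primitive

    [c]   = LT([a], [b], ell)
    [min] = [c]([a] - [b]) + [b]
    [max] = [c]([b] - [a]) + [a]

which costs a single multiplication for both outputs (compute
m = [c]([a]-[b]) once; min = m + [b], max = [a] - m).  The comparison is on
the key; the full record (key plus payload) swaps with the same [c].

``batcher_merge`` is the odd-even merge of Batcher's mergesort: the two
sorted inputs are concatenated with the second reversed, forming a sequence
that rises then falls, and a fixed schedule of strides halving from
(m+n)/2 to 1 sorts it.  It requires the combined size to be a power of two.

``new_merge`` removes that requirement: at every iteration each sublist of
odd length is extended with a copy of its own last record before the
stride's exchanges, so inputs of arbitrary sizes merge correctly; the output
may contain duplicated records (never more than the next power of two in
total).  Downstream distance computations neutralise the duplicates via a
location transform that separates genuine equal-location pairs from copies.

Every compare-and-exchange within one stride executes in the same batched
rounds, independent of the list length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

from .primitives import Backend


@dataclass(frozen=True, slots=True)
class KeyedRecord:
    """A merge element: comparison key plus payload swapped along with it."""

    key: Any
    payload: tuple = ()


def _check_arity(records: Sequence[KeyedRecord]) -> int:
    arity = len(records[0].payload)
    for r in records:
        if len(r.payload) != arity:
            raise ValueError("payload arity differs within one merge")
    return arity


def compare_exchange_vec(backend: Backend, pairs: list[tuple[KeyedRecord, KeyedRecord]],
                         ell: int) -> list[tuple[KeyedRecord, KeyedRecord]]:
    """Batched compare-and-exchange on record pairs (min first).

    Equal keys leave the pair unchanged (strict LT gives c = 0), so the
    network is stable on ties.  One LT plus one multiplication round for the
    whole batch regardless of its size.
    """
    if not pairs:
        return []
    arity = _check_arity([r for ab in pairs for r in ab])
    a_keys = [a.key for a, _ in pairs]
    b_keys = [b.key for _, b in pairs]
    c = backend.lt_vec(a_keys, b_keys, ell)
    # diffs for key and every payload slot, all multiplied by c in one round
    cols_a = [a_keys] + [[a.payload[i] for a, _ in pairs] for i in range(arity)]
    cols_b = [b_keys] + [[b.payload[i] for _, b in pairs] for i in range(arity)]
    diffs = []
    c_rep = []
    for ca, cb in zip(cols_a, cols_b):
        diffs.extend(backend.sub_vec(ca, cb))
        c_rep.extend(c)
    m = backend.mult_vec(c_rep, diffs)
    n = len(pairs)
    out = []
    mins, maxs = [], []
    for k in range(arity + 1):
        mk = m[k * n:(k + 1) * n]
        mins.append(backend.add_vec(mk, cols_b[k]))
        maxs.append(backend.sub_vec(cols_a[k], mk))
    for i in range(n):
        lo = KeyedRecord(mins[0][i], tuple(mins[k + 1][i] for k in range(arity)))
        hi = KeyedRecord(maxs[0][i], tuple(maxs[k + 1][i] for k in range(arity)))
        out.append((lo, hi))
    return out


def _apply_stride(backend: Backend, L: list[KeyedRecord], lo: int, size: int,
                  r: int, ell: int) -> None:
    """Run all exchanges (k, k+r) of one stride over L[lo:lo+size] in place."""
    idx = []
    for j in range(0, size, 2 * r):
        for k in range(j, j + r):
            idx.append((lo + k, lo + k + r))
    pairs = [(L[i], L[j]) for i, j in idx]
    res = compare_exchange_vec(backend, pairs, ell)
    for (i, j), (mn, mx) in zip(idx, res):
        L[i] = mn
        L[j] = mx


def batcher_merge(backend: Backend, L1: Sequence[KeyedRecord],
                  L2: Sequence[KeyedRecord], ell: int,
                  trace: list | None = None) -> list[KeyedRecord]:
    """Batcher odd-even merge of two sorted lists (combined size 2**q).

    The working list starts as (a_1..a_m, b_n..b_1); strides halve from
    (m+n)/2 down to 1.  ``trace``, if given, receives a snapshot of the
    working list after every outer iteration.
    """
    m, n = len(L1), len(L2)
    total = m + n
    if total == 0 or total & (total - 1):
        raise ValueError(f"combined size {total} is not a power of 2")
    L = list(L1) + list(reversed(list(L2)))
    _check_arity(L)
    r = total // 2
    while r > 0:
        _apply_stride(backend, L, 0, total, r, ell)
        if trace is not None:
            trace.append(list(L))
        r //= 2
    return L


def new_merge(backend: Backend, L1: Sequence[KeyedRecord],
              L2: Sequence[KeyedRecord], ell: int,
              trace: list | None = None) -> list[KeyedRecord]:
    """Generalised odd-even merge for arbitrary input sizes.

    Works on the rise-then-fall concatenation like ``batcher_merge`` but,
    at each iteration, any sublist of odd length is first extended with a
    copy of its last record; the copies are full records indistinguishable
    from originals downstream.  Output is sorted, contains every input
    record, and its surplus consists only of such copies; its length never
    exceeds the next power of two of ``len(L1)+len(L2)``.

    ``trace`` receives ``{"padded_sublists": [...], "after": [...]}`` per
    iteration.
    """
    if not L1 or not L2:
        raise ValueError("new_merge requires two non-empty sorted lists")
    L = list(L1) + list(reversed(list(L2)))
    _check_arity(L)
    sublists = [L]
    while max(len(s) for s in sublists) > 1:
        padded = []
        for s in sublists:
            s = list(s)
            if len(s) > 1 and len(s) % 2:
                s.append(s[-1])  # copy of the entire last record
            padded.append(s)
        if trace is not None:
            trace.append({"padded_sublists": [list(s) for s in padded],
                          "after": None})
        flat: list[KeyedRecord] = []
        bounds = []
        for s in padded:
            bounds.append((len(flat), len(s)))
            flat.extend(s)
        idx = []
        for lo, size in bounds:
            if size > 1:
                r = size // 2
                for j in range(0, size, 2 * r):
                    for k in range(j, j + r):
                        idx.append((lo + k, lo + k + r))
        pairs = [(flat[i], flat[j]) for i, j in idx]
        res = compare_exchange_vec(backend, pairs, ell)
        for (i, j), (mn, mx) in zip(idx, res):
            flat[i] = mn
            flat[j] = mx
        if trace is not None:
            trace[-1]["after"] = list(flat)
        nxt = []
        for lo, size in bounds:
            if size > 1:
                r = size // 2
                nxt.append(flat[lo:lo + r])
                nxt.append(flat[lo + r:lo + size])
            else:
                nxt.append(flat[lo:lo + size])
        sublists = nxt
    return [s[0] for s in sublists]
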
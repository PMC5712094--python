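"""Self-contained RNA secondary-structure engine.

Model: pseudoknot-free structures, minimum hairpin loop of 3 unpaired bases,
Watson-Crick plus G:U pairs.  The energy of a structure is the sum over
stacked pairs: whenever (i, j) and (i+1, j-1) are both paired, the stack
contributes -2 if (i, j) is a G:C pair and -1 otherwise (A:U or G:U).
An isolated pair contributes nothing, so every score is <= 0.

The same stack weights are reused for ungapped duplexes in the target
predictor, keeping the "MFE" internally comparable across the package.

The fill stage runs per anti-diagonal on numpy matrices, which keeps windows
of a few hundred bases well under a second; the traceback is plain Python.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import normalize, validate_alphabet

MIN_LOOP = 3
_INF = np.int64(10**9)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# pairable[a, b] and weight[a, b] indexed by base codes
_PAIRABLE = np.zeros((4, 4), dtype=bool)
_WEIGHT = np.zeros((4, 4), dtype=np.int64)
for _a, _b, _w in [("A", "T", -1), ("G", "C", -2), ("G", "T", -1)]:
    for _x, _y in [(_a, _b), (_b, _a)]:
        _PAIRABLE[_CODE[_x], _CODE[_y]] = True
        _WEIGHT[_CODE[_x], _CODE[_y]] = _w


@dataclass(frozen=True)
class FoldResult:
    """Optimal structure of a single sequence under the stacked-pair model."""

    sequence: str
    dotbracket: str
    energy: int
    pairs: tuple[tuple[int, int], ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in seq), dtype=np.int64, count=len(seq))


def fold(sequence: str) -> FoldResult:
    """Return the minimum-energy pseudoknot-free structure of ``sequence``.

    Raises ``ValueError`` on alphabet violations (position is reported).
    """
    seq = normalize(sequence)
    validate_alphabet(seq, context="fold input")
    n = len(seq)
    if n < 2 + MIN_LOOP:
        return FoldResult(seq, "." * n, 0, ())

    code = _encode(seq)
    pairable = _PAIRABLE[code[:, None], code[None, :]]
    weight = _WEIGHT[code[:, None], code[None, :]]

    # V[i, j]: best energy on [i, j] with (i, j) paired; W[i, j]: best on [i, j]
    V = np.full((n, n), _INF, dtype=np.int64)
    W = np.zeros((n, n), dtype=np.int64)

    for d in range(MIN_LOOP + 1, n):
        m = n - d
        idx = np.arange(m)
        jdx = idx + d
        # V: either the inner pair (i+1, j-1) stacks under (i, j), or anything
        # inside without the stack bonus.
        inner = W.diagonal(d - 2)[1 : m + 1].copy()
        stacked = V.diagonal(d - 2)[1 : m + 1] + weight.diagonal(d)
        v = np.minimum(inner, stacked)
        v = np.where(pairable.diagonal(d), v, _INF)
        V[idx, jdx] = v
        # W: leave j unpaired, or pair some k with j.
        best = W.diagonal(d - 1)[:m].copy()
        for t in range(0, d - MIN_LOOP):
            vterm = V.diagonal(d - t)[t : t + m]
            if t == 0:
                term = vterm
            else:
                term = W.diagonal(t - 1)[:m] + vterm
            np.minimum(best, term, out=best)
        W[idx, jdx] = best

    pairs: list[tuple[int, int]] = []
    _trace_w(0, n - 1, V, W, weight, pairable, pairs)
    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return FoldResult(seq, "".join(db), int(W[0, n - 1]), tuple(pairs))


def _trace_w(i: int, j: int, V, W, weight, pairable, out: list) -> None:
    stack = [("W", i, j)]
    while stack:
        kind, i, j = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if kind == "W":
            target = W[i, j]
            if target == W[i, j - 1]:
                stack.append(("W", i, j - 1))
                continue
            for k in range(i, j - MIN_LOOP):
                left = W[i, k - 1] if k > i else 0
                if pairable[k, j] and left + V[k, j] == target:
                    if k > i:
                        stack.append(("W", i, k - 1))
                    stack.append(("V", k, j))
                    break
            else:  # pragma: no cover - fill/traceback mismatch would be a bug
                raise AssertionError("traceback failed in W")
        else:
            out.append((i, j))
            target = V[i, j]
            if (
                j - i - 2 > MIN_LOOP
                and pairable[i + 1, j - 1]
                and V[i + 1, j - 1] + weight[i, j] == target
            ):
                stack.append(("V", i + 1, j - 1))
            else:
                stack.append(("W", i + 1, j - 1))


def pairs_energy(sequence: str, pairs) -> int:
    """Energy of an explicit pair set under the package's stacking model."""
    seq = normalize(sequence)
    pairset = {tuple(p) for p in pairs}
    total = 0
    for i, j in pairset:
        if (i + 1, j - 1) in pairset:
            total += int(_WEIGHT[_CODE[seq[i]], _CODE[seq[j]]])
    return total
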
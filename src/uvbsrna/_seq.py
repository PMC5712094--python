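"""Low-level nucleotide helpers shared across the package.

All sequences are handled internally in DNA alphabet (A/C/G/T, plus N in raw
reads); U is normalized to T at every file boundary.  Pairing predicates treat
T as U.
"""

from __future__ import annotations

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: canonical Watson-Crick pairs plus the G:U (here G:T) wobble
_PAIRABLE = frozenset(
    [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
)
_WC = frozenset([("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")])
_GU = frozenset([("G", "T"), ("T", "G")])


def normalize(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def is_wc(a: str, b: str) -> bool:
    return (a, b) in _WC


def is_gu(a: str, b: str) -> bool:
    return (a, b) in _GU


def pair_weight(a: str, b: str) -> int:
    """Stacking weight contributed by a pair: G:C stacks -2, A:U / G:U -1."""
    if not can_pair(a, b):
        raise ValueError(f"{a}:{b} is not a valid base pair")
    return -2 if {a, b} == {"G", "C"} else -1


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def validate_alphabet(seq: str, allowed: str = "ACGT", context: str = "sequence") -> None:
    allowed_set = set(allowed)
    for pos, base in enumerate(seq):
        if base not in allowed_set:
            raise ValueError(
                f"invalid character {base!r} at position {pos} in {context}"
            )
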
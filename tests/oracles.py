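"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (hand-rolled
codon table, naive quadratic ORF scan, direct-summation Pearson) so that it
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import math

_BASES = "TCAG"
# amino acids in TTT, TTC, TTA, TTG, TCT, ... TCAG-nested codon order
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def translate(seq: str) -> str:
    """Translate complete codons; '*' marks stops, translation keeps going."""
    return "".join(
        CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def translate_to_stop(seq: str) -> str:
    prot = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            break
        prot.append(aa)
    return "".join(prot)


def longest_orf(seq: str) -> tuple[int, int] | None:
    """Naive scan: every ATG, walk codon by codon to the first in-frame stop.

    Returns 1-based inclusive (start, end) of the longest hit, ties to the
    smallest start.
    """
    best = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            if CODON_TABLE[seq[j : j + 3]] == "*":
                cand = (i + 1, j + 3)
                if best is None or (cand[1] - cand[0]) > (best[1] - best[0]):
                    best = cand
                break
            j += 3
    return best


def apply_variant_oracle(seq: str, pos: int, ref: str, alt: str) -> str:
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def classify_oracle(seq: str, pos: int, ref: str, alt: str) -> str:
    """Classify a variant by mutating the full sequence and comparing whole
    protein translations of the original reading frame."""
    orf = longest_orf(seq)
    is_snp = len(ref) == 1 == len(alt)
    if orf is None:
        return "not_in_orf"
    start, end = orf
    if is_snp:
        inside = start <= pos <= end
    elif len(ref) == 1 < len(alt):  # insertion after pos
        inside = start <= pos < end
    else:  # deletion/complex alters pos+1 .. pos+len(ref)-1
        lo, hi = pos + 1, pos + len(ref) - 1
        inside = not (hi < start or lo > end)
    if not inside:
        return "not_in_orf"
    if is_snp:
        mutated = apply_variant_oracle(seq, pos, ref, alt)
        before = translate_to_stop(seq[start - 1 :])
        after = translate_to_stop(mutated[start - 1 :])
        return "synonymous" if before == after else "non_synonymous"
    shift = len(alt) - len(ref)
    return "orf_shift" if shift % 3 != 0 else "in_frame_indel"


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
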
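"""Open-reading-frame detection and mutation-effect classification.

Transcripts are oriented, mRNA-like assemblies, so the ORF search covers the
three forward frames only (a flag enables the reverse strand for unoriented
input).  The longest ATG→stop ORF wins; ties go to the smallest start.
Coordinates are 1-based and inclusive throughout, matching the anchored
``pos_REF_ALT`` variant notation.

A variant is classified by its consequence on the transcript's ORF:

========================  ====================================================
category                  rule
========================  ====================================================
``not_in_orf``            variant lies entirely outside the ORF
``synonymous``            SNP in the ORF; affected codon translates unchanged
``non_synonymous``        SNP in the ORF; amino acid changes
``orf_shift``             indel in the ORF; length change not a multiple of 3
``in_frame_indel``        indel in the ORF; length change a multiple of 3
========================  ====================================================

Reports can collapse ``in_frame_indel`` into ``orf_shift`` for a four-way
labeling (S / NS / ORF shift / Not in ORF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .association import VariantRecord
from .core import ValidationError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

CATEGORIES = (
    "synonymous",
    "non_synonymous",
    "orf_shift",
    "in_frame_indel",
    "not_in_orf",
)

#: Four-way compatibility labels (in-frame indels folded into "ORF shift").
SHORT_LABELS = {
    "synonymous": "S",
    "non_synonymous": "NS",
    "orf_shift": "ORF shift",
    "in_frame_indel": "ORF shift",
    "not_in_orf": "Not in ORF",
}


@dataclass
class TranscriptSequence:
    """A transcript nucleotide sequence with optional ORF coordinates."""

    id: str
    seq: str
    orf: Optional[tuple[int, int]] = None  # 1-based inclusive (start, end)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not set(self.seq) <= set("ACGT"):
            bad = sorted(set(self.seq) - set("ACGT"))
            raise ValidationError(f"non-ACGT characters in {self.id!r}: {bad}")
        if self.orf is not None:
            start, end = self.orf
            sub = self.seq[start - 1 : end]
            if (
                len(sub) % 3 != 0
                or not sub.startswith("ATG")
                or sub[-3:] not in STOP_CODONS
            ):
                raise ValidationError(
                    f"declared ORF ({start}, {end}) of {self.id!r} is not a "
                    "valid ATG..stop frame"
                )
            internal = {sub[i : i + 3] for i in range(3, len(sub) - 3, 3)}
            if internal & STOP_CODONS:
                raise ValidationError(
                    f"declared ORF of {self.id!r} contains an internal stop"
                )


def find_orf(
    seq: str | TranscriptSequence, include_reverse: bool = False
) -> Optional[tuple[int, int]]:
    """Longest forward-frame ATG→stop ORF as 1-based inclusive coordinates.

    Ties are broken by the smallest start; returns ``None`` when no complete
    ORF exists.  With ``include_reverse`` the reverse complement is also
    searched and coordinates are reported on the forward strand of whichever
    orientation won (reverse hits are returned on the reverse complement and
    are only meaningful for unoriented input).
    """
    s = seq.seq if isinstance(seq, TranscriptSequence) else seq.upper()
    if not set(s) <= set("ACGT"):
        raise ValidationError("sequence contains non-ACGT characters")
    if len(s) < 6:
        raise ValidationError("sequence shorter than one codon pair")

    def _scan(t: str) -> Optional[tuple[int, int]]:
        # index stop codons per frame once, then pair each ATG with the next
        # in-frame stop by bisection
        from bisect import bisect_left

        stops_by_frame: tuple[list[int], list[int], list[int]] = ([], [], [])
        for j in range(len(t) - 2):
            if t[j : j + 3] in STOP_CODONS:
                stops_by_frame[j % 3].append(j)
        best: Optional[tuple[int, int]] = None
        pos = t.find("ATG")
        while pos != -1:
            stops = stops_by_frame[pos % 3]
            k = bisect_left(stops, pos)
            if k < len(stops):
                start, end = pos + 1, stops[k] + 3
                if best is None or (end - start) > (best[1] - best[0]):
                    best = (start, end)
            pos = t.find("ATG", pos + 1)
        return best

    best = _scan(s)
    if include_reverse:
        rc = str(Seq(s).reverse_complement())
        rbest = _scan(rc)
        if rbest is not None and (
            best is None or (rbest[1] - rbest[0]) > (best[1] - best[0])
        ):
            best = rbest
    return best


@dataclass(frozen=True)
class MutationEffect:
    """A variant's consequence on its transcript's reading frame."""

    variant: VariantRecord
    category: str
    detail: str = ""

    @property
    def short_label(self) -> str:
        return SHORT_LABELS[self.category]


def apply_variant(seq: str, v: VariantRecord) -> str:
    """Apply an anchored variant to a sequence, checking REF consistency."""
    start = v.position - 1
    observed = seq[start : start + len(v.ref)]
    if observed != v.ref:
        raise ValidationError(
            f"REF mismatch for {v.id_string}: sequence has {observed!r}"
        )
    return seq[:start] + v.alt + seq[start + len(v.ref):]


def _overlaps_orf(v: VariantRecord, orf: tuple[int, int]) -> bool:
    start, end = orf
    if v.is_snp:
        return start <= v.position <= end
    if len(v.alt) > len(v.ref) == 1:
        # pure insertion between position p and p+1: inside iff strictly
        # before the ORF's last base
        return start <= v.position < end
    # deletion / complex: the altered bases are positions p+1 .. p+len(ref)-1
    lo, hi = v.position + 1, v.position + len(v.ref) - 1
    return not (hi < start or lo > end)


def classify_effect(t: TranscriptSequence, v: VariantRecord) -> MutationEffect:
    """Classify a variant by its ORF consequence (see module docstring)."""
    if v.position + len(v.ref) - 1 > len(t.seq):
        raise ValidationError(
            f"variant {v.id_string} runs past the end of {t.id!r} "
            f"(length {len(t.seq)})"
        )
    apply_variant(t.seq, v)  # REF consistency check
    orf = t.orf if t.orf is not None else find_orf(t.seq)
    if orf is None or not _overlaps_orf(v, orf):
        return MutationEffect(v, "not_in_orf")
    start, end = orf
    if v.is_snp:
        codon_index = (v.position - start) // 3  # 0-based within ORF
        cstart = start - 1 + 3 * codon_index
        before = t.seq[cstart : cstart + 3]
        offset = v.position - 1 - cstart
        after = before[:offset] + v.alt + before[offset + 1:]
        aa_before = str(Seq(before).translate())
        aa_after = str(Seq(after).translate())
        detail = f"codon {codon_index + 1}: {before}({aa_before})->{after}({aa_after})"
        if aa_before == aa_after:
            return MutationEffect(v, "synonymous", detail)
        return MutationEffect(v, "non_synonymous", detail)
    shift = v.length_change
    detail = f"length change {shift:+d} nt in ORF"
    if shift % 3 != 0:
        return MutationEffect(v, "orf_shift", detail)
    return MutationEffect(v, "in_frame_indel", detail)


def effect_tally(effects: list[MutationEffect], collapse: bool = False) -> dict[str, int]:
    """Count effects per category; with ``collapse`` use the four-way labels."""
    tally: dict[str, int] = {}
    for e in effects:
        key = e.short_label if collapse else e.category
        tally[key] = tally.get(key, 0) + 1
    return tally
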
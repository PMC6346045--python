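"""Genic variant filtering and single-marker trait association.

Variants live in transcript coordinates and use the anchored ``pos_REF_ALT``
notation (VCF convention: 1-based position, indels share their first base
with the reference).  Genotypes are binary carrier / non-carrier per cultivar,
as resolved from pooled RNA-seq calls.

The association test is a two-sample t-test of the trait values of carriers
against non-carriers.  With a binary marker the single-marker regression of
QTL mapping (trait ~ genotype) is algebraically identical to the
pooled-variance Student t-test, so that is the default; a Welch (unequal
variance) variant is available for panels where carrier and non-carrier
spreads differ.  The per-variant effect size ("effect %") is the percent
difference of the carrier-group mean from the non-carrier-group mean;
variance explained (point-biserial r² × 100) is available as an alternative
definition.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import TraitTable, ValidationError, bonferroni_threshold

logger = logging.getLogger(__name__)

_MUTATION_ID_RE = re.compile(r"^(\d+)_([ACGT]+)_([ACGT]+)$")


@dataclass
class VariantRecord:
    """An anchored transcript-space variant (``pos_REF_ALT``)."""

    gene_id: str
    transcript_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.position}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= set("ACGT"):
                raise ValidationError(
                    f"alleles must be non-empty uppercase ACGT, got {allele!r}"
                )
        if self.ref == self.alt:
            raise ValidationError("REF and ALT must differ")

    @property
    def id_string(self) -> str:
        return f"{self.position}_{self.ref}_{self.alt}"

    @property
    def key(self) -> str:
        return f"{self.transcript_id}:{self.id_string}"

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snp

    @property
    def variant_class(self) -> str:
        """``SNP``, ``insertion``, ``deletion`` or ``complex``."""
        if self.is_snp:
            return "SNP"
        if len(self.alt) > len(self.ref):
            return "insertion"
        if len(self.alt) < len(self.ref):
            return "deletion"
        return "complex"

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


def parse_mutation_id(
    id_string: str, gene_id: str = "", transcript_id: str = ""
) -> VariantRecord:
    """Parse an anchored ``pos_REF_ALT`` label (e.g. ``667_A_G``,
    ``1214_A_AAT``, ``70_CT_C``) into a :class:`VariantRecord`.

    Internal whitespace (line-wrapped labels) is stripped before matching.
    """
    cleaned = re.sub(r"\s+", "", id_string)
    m = _MUTATION_ID_RE.match(cleaned)
    if not m:
        raise ValidationError(f"malformed mutation id: {id_string!r}")
    pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
    return VariantRecord(gene_id, transcript_id, pos, ref, alt)


@dataclass
class GenotypeMatrix:
    """Variants × samples binary carrier matrix."""

    variants: list[VariantRecord]
    samples: list[str]
    carrier: np.ndarray  # bool, shape (n_variants, n_samples)

    def __post_init__(self) -> None:
        self.carrier = np.asarray(self.carrier, dtype=bool)
        if self.carrier.shape != (len(self.variants), len(self.samples)):
            raise ValidationError(
                f"carrier matrix shape {self.carrier.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )

    @property
    def carrier_counts(self) -> np.ndarray:
        return self.carrier.sum(axis=1)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.gene_id, None)
        return list(seen)

    def subset_genes(self, genes: Iterable[str]) -> "GenotypeMatrix":
        keep = set(genes)
        idx = [i for i, v in enumerate(self.variants) if v.gene_id in keep]
        return GenotypeMatrix(
            [self.variants[i] for i in idx], list(self.samples), self.carrier[idx]
        )

    def reorder_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        if set(samples) != set(self.samples):
            diff = sorted(set(samples) ^ set(self.samples))
            raise ValidationError(f"sample sets differ: {diff}")
        order = [self.samples.index(s) for s in samples]
        return GenotypeMatrix(list(self.variants), list(samples), self.carrier[:, order])

    # -- IO ------------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        """Columns: gene_id, transcript_id, mutation_id, then one 0/1 column
        per sample."""
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str})
        fixed = ["gene_id", "transcript_id", "mutation_id"]
        for col in fixed:
            if col not in df.columns:
                raise ValidationError(f"variant table lacks required column {col!r}")
        samples = [c for c in df.columns if c not in fixed]
        variants = [
            parse_mutation_id(row.mutation_id, row.gene_id, row.transcript_id)
            for row in df.itertuples()
        ]
        carrier = df[samples].to_numpy().astype(bool)
        return cls(variants, samples, carrier)

    def to_tsv(self, path: str | Path) -> None:
        rows = {
            "gene_id": [v.gene_id for v in self.variants],
            "transcript_id": [v.transcript_id for v in self.variants],
            "mutation_id": [v.id_string for v in self.variants],
        }
        df = pd.DataFrame(rows)
        for j, s in enumerate(self.samples):
            df[s] = self.carrier[:, j].astype(int)
        df.to_csv(path, sep="\t", index=False)


def presence_filter(gm: GenotypeMatrix, min_carriers: int = 4) -> GenotypeMatrix:
    """Keep variants carried by at least ``min_carriers`` samples.

    Requiring presence in several cultivars screens out spurious calls from
    sequencing or assembly error, whose chance of recurring independently is
    vanishingly small (see :func:`chance_probability`).  Idempotent.
    """
    if min_carriers < 1:
        raise ValidationError("min_carriers must be >= 1")
    keep = np.flatnonzero(gm.carrier_counts >= min_carriers)
    return GenotypeMatrix(
        [gm.variants[i] for i in keep], list(gm.samples), gm.carrier[keep]
    )


def chance_probability(transcript_len: int, k_samples: int) -> float:
    """Probability that ``k_samples`` samples show the same erroneous call at
    one position of a transcript of ``transcript_len`` bases by chance:
    ``(1 / transcript_len) ** k_samples``."""
    if transcript_len < 1 or k_samples < 1:
        raise ValidationError("transcript_len and k_samples must be >= 1")
    return (1.0 / transcript_len) ** k_samples


@dataclass(frozen=True)
class AssociationRecord:
    """One variant × trait single-marker test result."""

    variant: VariantRecord
    trait: str
    carrier_mean: float
    noncarrier_mean: float
    effect_pct: float  # nan when the non-carrier mean is zero
    p: float
    passes_bonferroni: bool
    passes_strict: bool
    effect_defined: bool = True


def associate(
    gm: GenotypeMatrix,
    traits: TraitTable,
    bonferroni_m: int,
    strict_alpha: float = 1.0e-4,
    alpha: float = 0.05,
    effect_mode: str = "percent_diff",
    min_group: int = 2,
    test: str = "student",
) -> list[AssociationRecord]:
    """Two-sample t-test of carrier vs non-carrier trait values for every
    variant × trait pair, with effect % and significance flags.

    ``test="student"`` (default) is the pooled-variance t, equivalent to the
    single-marker regression of QTL mapping for a binary marker;
    ``test="welch"`` drops the equal-variance assumption.
    ``passes_bonferroni`` compares p against ``bonferroni_threshold(alpha,
    bonferroni_m)``; ``passes_strict`` against ``strict_alpha``.  Variants
    with fewer than ``min_group`` carriers or non-carriers are skipped with a
    logged reason.
    """
    if effect_mode not in ("percent_diff", "variance_explained"):
        raise ValidationError(f"unknown effect_mode {effect_mode!r}")
    if test not in ("student", "welch"):
        raise ValidationError(f"unknown test {test!r}")
    gm = gm.reorder_samples(traits.samples)
    bonf = bonferroni_threshold(alpha, bonferroni_m)
    values = traits.values  # samples x traits
    out: list[AssociationRecord] = []
    for i, v in enumerate(gm.variants):
        mask = gm.carrier[i]
        k = int(mask.sum())
        if k < min_group or (len(mask) - k) < min_group:
            logger.info(
                "skipping %s: %d carriers / %d non-carriers (< %d per group)",
                v.key, k, len(mask) - k, min_group,
            )
            continue
        a = values[mask]      # carriers x traits
        b = values[~mask]     # non-carriers x traits
        res = stats.ttest_ind(a, b, axis=0, equal_var=(test == "student"))
        pvals = np.atleast_1d(res.pvalue)
        am = a.mean(axis=0)
        bm = b.mean(axis=0)
        for j, trait in enumerate(traits.traits):
            p = float(pvals[j])
            if math.isnan(p):  # zero within-group variance in both groups
                p = 1.0
            if effect_mode == "percent_diff":
                defined = bm[j] > 0
                eff = 100.0 * abs(am[j] - bm[j]) / bm[j] if defined else float("nan")
            else:
                r = stats.pointbiserialr(mask.astype(float), values[:, j])[0]
                defined = not math.isnan(r)
                eff = 100.0 * r * r if defined else float("nan")
            out.append(
                AssociationRecord(
                    variant=v,
                    trait=trait,
                    carrier_mean=float(am[j]),
                    noncarrier_mean=float(bm[j]),
                    effect_pct=float(eff),
                    p=p,
                    passes_bonferroni=p <= bonf,
                    passes_strict=p <= strict_alpha,
                    effect_defined=bool(defined),
                )
            )
    return out


def associations_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Flatten association records into a tidy DataFrame."""
    return pd.DataFrame(
        {
            "gene_id": [r.variant.gene_id for r in records],
            "transcript_id": [r.variant.transcript_id for r in records],
            "mutation_id": [r.variant.id_string for r in records],
            "trait": [r.trait for r in records],
            "carrier_mean": [r.carrier_mean for r in records],
            "noncarrier_mean": [r.noncarrier_mean for r in records],
            "effect_pct": [r.effect_pct for r in records],
            "p": [r.p for r in records],
            "passes_bonferroni": [r.passes_bonferroni for r in records],
            "passes_strict": [r.passes_strict for r in records],
        }
    )
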
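"""Synthetic cultivar-panel data with planted, recoverable structure.

The generator emulates a germplasm panel of 42 ginseng cultivars profiled for
(i) transcript-level expression (TPM) of a cytochrome-P450-like gene family,
(ii) nine mono-ginsenoside root contents plus their total, (iii) genic
SNP/InDel genotypes in transcript coordinates, and (iv) the transcript
nucleotide sequences themselves.  Three kinds of signal can be planted:

* **expression–trait correlation** — a transcript's expression is built from
  the standardized realized trait vector z as ``rho * z + sqrt(1 - rho**2) * eps``,
  so its sample Pearson correlation with the trait targets ``rho`` in
  expectation;
* **variant–trait association** — carriers of a variant have one trait
  shifted by a stated multiple of that trait's standard deviation;
* **a co-expressed module** — a set of transcripts shares a latent factor
  with a stated loading.

Everything else is independent noise.  A truth ledger records the planted
entities so every downstream stage can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MONO_TRAITS,
    TOTAL_TRAIT,
    ExpressionMatrix,
    TraitTable,
    ValidationError,
)
from .association import GenotypeMatrix, VariantRecord
from .orf import TranscriptSequence, find_orf

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedCorrelation:
    """A transcript whose expression tracks a trait at target Pearson rho."""

    transcript_index: int
    trait: str
    rho: float


@dataclass(frozen=True)
class PlantedVariant:
    """A variant whose carriers have ``trait`` shifted by ``effect_sd`` SDs."""

    transcript_index: int
    trait: str
    n_carriers: int
    effect_sd: float
    kind: str = "snp"  # "snp" | "insertion" | "deletion"


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cultivar panel.

    Defaults mirror the study design the package targets: 42 cultivars,
    440 transcripts from 414 genes, nine mono-ginsenoside traits plus total.
    """

    n_samples: int = 42
    n_transcripts: int = 440
    n_genes: int = 414
    trait_names: tuple[str, ...] = MONO_TRAITS
    planted_correlated: list[PlantedCorrelation] = field(default_factory=list)
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    planted_module: list[int] = field(default_factory=list)
    module_loading: float = 0.9
    n_background_variants: int = 60
    transcript_length_mean: int = 1306
    # expression scale: TPM ~ max(0, expr_base + expr_scale * standard score)
    expr_base: float = 50.0
    expr_scale: float = 10.0
    # trait marginals: lognormal(mu, sigma) per mono trait
    trait_log_mu: float = 0.8
    trait_log_sigma: float = 0.35
    noise_sd: float = 1.0
    #: skip nucleotide-sequence generation (variants then carry random
    #: alleles not anchored to a realized sequence) — useful for large
    #: statistics-only replicate studies
    generate_sequences: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ValidationError("need at least 3 samples")
        if not 1 <= self.n_genes <= self.n_transcripts:
            raise ValidationError("n_genes must lie in [1, n_transcripts]")
        traits = set(self.trait_names) | {TOTAL_TRAIT}
        for pc in self.planted_correlated:
            if not 0 <= pc.transcript_index < self.n_transcripts:
                raise ValidationError(f"planted transcript index {pc.transcript_index} out of range")
            if abs(pc.rho) >= 1:
                raise ValidationError("target |rho| must be < 1")
            if pc.trait not in traits:
                raise ValidationError(f"unknown trait {pc.trait!r}")
        for pv in self.planted_variants:
            if not 0 <= pv.transcript_index < self.n_transcripts:
                raise ValidationError(f"planted variant transcript {pv.transcript_index} out of range")
            if pv.trait not in traits or pv.trait == TOTAL_TRAIT:
                raise ValidationError("variant effects must target a mono trait")
            if not 0 <= pv.n_carriers <= self.n_samples:
                raise ValidationError("carrier count must lie in [0, n_samples]")
            if pv.n_carriers == 0 and pv.effect_sd != 0:
                raise ValidationError("cannot plant an effect with zero carriers")
        for i in self.planted_module:
            if not 0 <= i < self.n_transcripts:
                raise ValidationError(f"module transcript index {i} out of range")


@dataclass
class SimulatedTruth:
    """A realized synthetic panel plus the ledger of planted signal."""

    expression: ExpressionMatrix
    traits: TraitTable
    genotypes: GenotypeMatrix
    sequences: dict[str, TranscriptSequence]
    ledger: dict

    def write(self, outdir: str | Path) -> None:
        """Emit the TSV/FASTA/JSON files the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.to_tsv(outdir / "expression.tsv")
        self.traits.to_tsv(outdir / "traits.tsv")
        self.genotypes.to_tsv(outdir / "variants.tsv")
        with open(outdir / "transcripts.fasta", "w") as fh:
            for seq in self.sequences.values():
                fh.write(f">{seq.id}\n{seq.seq}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.ledger, fh, indent=2, sort_keys=True)


def _transcript_names(n_transcripts: int, n_genes: int) -> tuple[list[str], dict[str, str]]:
    """Gene names PgSIM001..PgSIM<n_genes>; the first (n_transcripts - n_genes)
    genes carry two alternative transcripts (suffix -1/-2)."""
    n_multi = n_transcripts - n_genes
    names: list[str] = []
    gene_of: dict[str, str] = {}
    for g in range(n_genes):
        gene = f"PgSIM{g + 1:03d}"
        if g < n_multi:
            for k in (1, 2):
                t = f"{gene}-{k}"
                names.append(t)
                gene_of[t] = gene
        else:
            names.append(gene)
            gene_of[gene] = gene
    return names, gene_of


def simulate_dataset(config: SimulationConfig) -> SimulatedTruth:
    """Draw one panel according to ``config``; deterministic given its seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"cv{i + 1:02d}" for i in range(n)]
    transcript_ids, gene_of = _transcript_names(config.n_transcripts, config.n_genes)

    # --- traits: lognormal mono contents, then planted carrier shifts -------
    n_mono = len(config.trait_names)
    mono = rng.lognormal(
        mean=config.trait_log_mu, sigma=config.trait_log_sigma, size=(n, n_mono)
    )
    trait_df = pd.DataFrame(mono, index=samples, columns=list(config.trait_names))

    # --- sequences and variants --------------------------------------------
    lengths = {
        t: int(max(300, rng.normal(config.transcript_length_mean, 150)))
        for t in transcript_ids
    }
    sequences: dict[str, TranscriptSequence] = {}

    def _sequence_for(tid: str) -> TranscriptSequence:
        if tid not in sequences:
            L = lengths[tid]
            orf_codons = max(20, int(L * 0.6) // 3)
            seq = simulate_transcript_with_orf(
                length=L,
                orf_start=int(rng.integers(1, max(2, L - 3 * orf_codons - 3))),
                orf_len_codons=orf_codons,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sequences[tid] = TranscriptSequence(tid, seq.seq, seq.orf)
        return sequences[tid]

    def _draw_variant(tid: str, kind: str) -> VariantRecord:
        if config.generate_sequences:
            s = _sequence_for(tid).seq
        else:
            # statistics-only mode: alleles are synthetic, not anchored to a
            # realized sequence
            s = "".join(rng.choice(_BASES, size=lengths[tid]))
        pos = int(rng.integers(1, len(s) - 10))
        anchor = s[pos - 1]
        if kind == "snp":
            ref = anchor
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        elif kind == "insertion":
            ref = anchor
            alt = ref + "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        elif kind == "deletion":
            dlen = int(rng.integers(1, 4))
            ref = s[pos - 1 : pos + dlen]
            alt = anchor
        else:
            raise ValidationError(f"unknown variant kind {kind!r}")
        return VariantRecord(
            gene_id=gene_of[tid], transcript_id=tid, position=pos, ref=ref, alt=alt
        )

    variant_rows: list[VariantRecord] = []
    carrier_rows: list[np.ndarray] = []
    planted_variant_ids: list[str] = []

    for pv in config.planted_variants:
        tid = transcript_ids[pv.transcript_index]
        rec = _draw_variant(tid, pv.kind)
        carriers = np.zeros(n, dtype=bool)
        carriers[rng.choice(n, size=pv.n_carriers, replace=False)] = True
        sd = float(trait_df[pv.trait].std(ddof=1))
        trait_df.loc[carriers, pv.trait] += pv.effect_sd * sd
        variant_rows.append(rec)
        carrier_rows.append(carriers)
        planted_variant_ids.append(rec.key)

    for _ in range(config.n_background_variants):
        tid = transcript_ids[int(rng.integers(0, config.n_transcripts))]
        kind = str(rng.choice(["snp", "snp", "snp", "insertion", "deletion"]))
        rec = _draw_variant(tid, kind)
        carriers = np.zeros(n, dtype=bool)
        k = int(rng.integers(1, max(2, n // 3)))
        carriers[rng.choice(n, size=k, replace=False)] = True
        variant_rows.append(rec)
        carrier_rows.append(carriers)

    trait_table = TraitTable(trait_df).with_total()

    # --- expression ---------------------------------------------------------
    # standard scores first, then an affine map onto the TPM scale
    scores = rng.normal(0.0, config.noise_sd, size=(config.n_transcripts, n))
    z_traits = {
        name: (trait_table.data[name] - trait_table.data[name].mean())
        / trait_table.data[name].std(ddof=1)
        for name in trait_table.traits
    }
    for pc in config.planted_correlated:
        z = z_traits[pc.trait].to_numpy()
        eps = rng.normal(0.0, 1.0, size=n)
        scores[pc.transcript_index] = pc.rho * z + np.sqrt(1 - pc.rho**2) * eps
    if config.planted_module:
        factor = rng.normal(0.0, 1.0, size=n)
        lam = config.module_loading
        for i in config.planted_module:
            eps = rng.normal(0.0, 1.0, size=n)
            scores[i] = lam * factor + np.sqrt(1 - lam**2) * eps
    tpm = np.maximum(0.0, config.expr_base + config.expr_scale * scores)
    expr = ExpressionMatrix(
        pd.DataFrame(tpm, index=transcript_ids, columns=samples), dict(gene_of)
    )

    genotypes = GenotypeMatrix(
        variants=variant_rows,
        samples=samples,
        carrier=np.vstack(carrier_rows) if carrier_rows else np.zeros((0, n), bool),
    )

    ledger = {
        "seed": config.seed,
        "planted_correlated": [
            {
                "transcript_id": transcript_ids[pc.transcript_index],
                "gene_id": gene_of[transcript_ids[pc.transcript_index]],
                "trait": pc.trait,
                "rho": pc.rho,
            }
            for pc in config.planted_correlated
        ],
        "planted_variants": [
            {
                "key": key,
                "trait": pv.trait,
                "n_carriers": pv.n_carriers,
                "effect_sd": pv.effect_sd,
            }
            for key, pv in zip(planted_variant_ids, config.planted_variants)
        ],
        "planted_module": [transcript_ids[i] for i in config.planted_module],
    }
    return SimulatedTruth(expr, trait_table, genotypes, sequences, ledger)


def simulate_transcript_with_orf(
    length: int, orf_start: int, orf_len_codons: int, seed: int
) -> TranscriptSequence:
    """Random transcript whose longest ORF sits exactly at the requested
    coordinates (1-based start, ``orf_len_codons`` codons incl. ATG and stop).

    Rejection-samples until no equal-or-longer ORF occurs elsewhere.
    """
    if orf_len_codons < 2:
        raise ValidationError("an ORF needs at least a start and a stop codon")
    orf_nt = 3 * orf_len_codons
    end = orf_start + orf_nt - 1
    if orf_start < 1 or end > length:
        raise ValidationError(
            f"ORF ({orf_start}..{end}) does not fit in a transcript of length {length}"
        )
    rng = np.random.default_rng(seed)
    non_stop = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in STOP_CODONS and a + b + c != "ATG"
    ]
    for _ in range(10_000):
        seq = rng.choice(_BASES, size=length)
        body = rng.choice(non_stop, size=orf_len_codons - 2)
        orf = "ATG" + "".join(body) + str(rng.choice(STOP_CODONS))
        seq[orf_start - 1 : end] = list(orf)
        s = "".join(seq)
        found = find_orf(s)
        if found == (orf_start, end):
            return TranscriptSequence("sim", s, found)
    raise ValidationError(
        "could not realize the requested ORF geometry after 10000 attempts"
    )
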
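"""Stage 1: expression–trait correlation screening at two significance tiers.

Every transcript is correlated (Pearson, two-tailed) with every trait across
the sample panel.  A transcript–trait pair passes a tier iff ``p <= alpha``
(inclusive); a gene passes iff at least one of its transcripts passes for at
least one trait.  No multiple-testing correction is applied at this stage —
the raw tiers (conventionally 0.05 and 0.01) are the screen, and correction
enters only in the downstream association stage.

Zero-variance transcripts carry no correlation signal and are skipped with a
logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CorrelationResult,
    ExpressionMatrix,
    TraitTable,
    ValidationError,
    check_matched_samples,
    pairwise_correlations,
)

logger = logging.getLogger(__name__)

DEFAULT_TIERS: tuple[float, ...] = (0.05, 0.01)


@dataclass
class ScreenReport:
    """All transcript–trait correlations plus per-tier summaries.

    ``results`` holds one row per (transcript, trait) pair that passed the
    loosest tier, sorted by transcript then trait for order-invariance.
    """

    tiers: tuple[float, ...]
    n_samples: int
    results: pd.DataFrame  # transcript_id, gene_id, trait, r, p
    skipped_transcripts: list[str] = field(default_factory=list)

    def hits_at(self, alpha: float) -> pd.DataFrame:
        return self.results[self.results["p"] <= alpha].reset_index(drop=True)

    def transcripts_at(self, alpha: float) -> list[str]:
        return sorted(self.hits_at(alpha)["transcript_id"].unique())

    def genes_at(self, alpha: float) -> list[str]:
        return sorted(self.hits_at(alpha)["gene_id"].unique())

    def per_trait_transcript_counts(self, alpha: float) -> dict[str, int]:
        hits = self.hits_at(alpha)
        return hits.groupby("trait")["transcript_id"].nunique().to_dict()

    def gene_trait_table(self, alpha: float) -> pd.DataFrame:
        """Gene × trait membership (1 if any transcript of the gene passes
        for the trait), with a final ``n_genes`` row of per-trait gene counts."""
        hits = self.hits_at(alpha)
        if hits.empty:
            return pd.DataFrame()
        tab = (
            hits.assign(hit=1)
            .pivot_table(index="gene_id", columns="trait", values="hit",
                         aggfunc="max", fill_value=0)
            .astype(int)
            .sort_index()
        )
        tab.loc["n_genes"] = tab.sum(axis=0)
        return tab

    def summary(self) -> dict:
        out: dict = {"tiers": {}, "n_samples": self.n_samples,
                     "skipped_transcripts": len(self.skipped_transcripts)}
        for alpha in self.tiers:
            out["tiers"][str(alpha)] = {
                "n_pairs": int(len(self.hits_at(alpha))),
                "n_transcripts": len(self.transcripts_at(alpha)),
                "n_genes": len(self.genes_at(alpha)),
                "per_trait_transcripts": self.per_trait_transcript_counts(alpha),
            }
        return out

    def correlation_results(self, alpha: float) -> list[CorrelationResult]:
        return [
            CorrelationResult(
                row.transcript_id, row.gene_id, row.trait,
                float(row.r), self.n_samples, float(row.p),
            )
            for row in self.hits_at(alpha).itertuples()
        ]


def screen(
    expr: ExpressionMatrix,
    traits: TraitTable,
    tiers: Sequence[float] = DEFAULT_TIERS,
) -> ScreenReport:
    """Correlate every transcript with every trait and report tiered hits."""
    if not tiers:
        raise ValidationError("at least one significance tier is required")
    for a in tiers:
        if not 0.0 < a < 1.0:
            raise ValidationError(f"tier alpha {a} outside (0, 1)")
    tiers = tuple(sorted(set(tiers), reverse=True))
    samples = check_matched_samples(expr, traits)
    if len(samples) < 3:
        raise ValidationError("screening requires at least 3 samples")

    X = expr.data.to_numpy()  # transcripts x samples
    Y = traits.data.loc[samples].to_numpy().T  # traits x samples
    r, p = pairwise_correlations(X, Y)

    zero_var = np.flatnonzero(np.isnan(r).all(axis=1))
    skipped = [expr.transcript_ids[i] for i in zero_var]
    for t in skipped:
        logger.warning("transcript %s has zero variance; skipped in screen", t)

    loosest = max(tiers)
    ti, tj = np.nonzero(p <= loosest)
    transcript_ids = np.asarray(expr.transcript_ids, dtype=object)
    trait_names = np.asarray(traits.traits, dtype=object)
    results = pd.DataFrame(
        {
            "transcript_id": transcript_ids[ti],
            "gene_id": [expr.gene_of[t] for t in transcript_ids[ti]],
            "trait": trait_names[tj],
            "r": r[ti, tj],
            "p": p[ti, tj],
        }
    ).sort_values(["transcript_id", "trait"], kind="mergesort").reset_index(drop=True)
    return ScreenReport(tiers, len(samples), results, skipped)


def write_screen_report(report: ScreenReport, outdir: str | Path) -> None:
    """Write the hits table and one gene × trait membership table per tier."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hits = report.results.copy()
    for alpha in report.tiers:
        hits[f"tier_{alpha}"] = (hits["p"] <= alpha).astype(int)
    hits["p"] = hits["p"].map(lambda v: f"{v:.2E}")
    hits.to_csv(outdir / "correlation_hits.tsv", sep="\t", index=False)
    for alpha in report.tiers:
        tab = report.gene_trait_table(alpha)
        tab.to_csv(outdir / f"gene_trait_membership_p{alpha}.tsv", sep="\t")
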
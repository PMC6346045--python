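"""End-to-end orchestration: screen → filter → associate → classify → network.

All stages run on one shared sample universe.  The output directory layout is
fixed::

    <out>/
      screen/      correlation hits and gene x trait membership tables
      variants/    filtered genotype table, association results, Table-2-style report
      orf/         mutation-effect classifications
      network/     edge lists, GraphML, tendency-test JSON
      report.json  per-stage counts plus provenance (config hash, seed, version)

A stage failure writes a ``FAILED`` marker naming the stage and re-raises;
artifacts from completed stages are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .association import (
    AssociationRecord,
    GenotypeMatrix,
    associate,
    associations_to_frame,
    presence_filter,
)
from .core import ExpressionMatrix, TraitTable, ValidationError, bonferroni_threshold
from .network import build_network, tendency_test
from .orf import MutationEffect, TranscriptSequence, classify_effect, effect_tally
from .screen import DEFAULT_TIERS, screen, write_screen_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one full pipeline run."""

    expression: str
    traits: str
    variants: str
    sequences: Optional[str] = None  # FASTA; ORF stage skipped when absent
    gene_map: Optional[str] = None
    out: str = "cypscreen_out"
    tiers: tuple[float, ...] = DEFAULT_TIERS
    min_carriers: int = 4
    bonferroni_m: int | str = "auto"  # "auto" = genes entering association
    bonferroni_alpha: float = 0.05
    strict_alpha: float = 1.0e-4
    network_alpha: float = 0.05
    tendency_R: int = 20
    seed: int = 0
    effect_mode: str = "percent_diff"
    association_test: str = "student"

    def __post_init__(self) -> None:
        for a in (*self.tiers, self.bonferroni_alpha, self.strict_alpha):
            if not 0.0 < a < 1.0:
                raise ValidationError(f"alpha {a} outside (0, 1)")
        if self.strict_alpha > 0.05:
            logger.warning(
                "strict_alpha %.3g is weaker than the raw 0.05 tier; the final "
                "cut will not tighten the funnel", self.strict_alpha,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tiers" in raw:
            raw["tiers"] = tuple(raw["tiers"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage counts plus provenance for one pipeline run."""

    counts: dict
    provenance: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"counts": self.counts, "provenance": self.provenance},
                      fh, indent=2, sort_keys=True)


def read_fasta(path: str | Path) -> dict[str, TranscriptSequence]:
    from Bio import SeqIO

    out: dict[str, TranscriptSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = TranscriptSequence(rec.id, str(rec.seq))
    return out


def table2_report(
    assocs: Sequence[AssociationRecord],
    effects: Sequence[MutationEffect],
    out: str | Path | None = None,
) -> "pd.DataFrame":
    """Publication-style summary: one row per variant, one effect%(p) cell
    per trait for which the variant passed the strict cut, plus the four-way
    mutation-type label."""
    import pandas as pd

    by_variant: dict[str, list[AssociationRecord]] = {}
    for a in assocs:
        by_variant.setdefault(a.variant.key, []).append(a)
    rows = []
    traits_seen: list[str] = []
    for e in effects:
        key = e.variant.key
        if key not in by_variant:
            raise ValidationError(
                f"mutation effect for {key} has no matching association record"
            )
        sig = [a for a in by_variant[key] if a.passes_strict]
        row: dict[str, str] = {
            "gene": e.variant.gene_id,
            "mutation": e.variant.id_string,
            "mutation_type": e.short_label,
        }
        for a in sig:
            eff = "NA" if not a.effect_defined else f"{a.effect_pct:.1f}"
            row[a.trait] = f"{eff} ({a.p:.2E})"
            if a.trait not in traits_seen:
                traits_seen.append(a.trait)
        rows.append(row)
    cols = ["gene", "mutation", "mutation_type"] + traits_seen
    df = pd.DataFrame(rows, columns=cols).fillna("")
    df = df.sort_values(["gene", "mutation"]).reset_index(drop=True)
    if out is not None:
        df.to_csv(out, sep="\t", index=False)
    return df


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full chain from files on disk (see :class:`PipelineConfig`)."""
    expr = ExpressionMatrix.from_tsv(config.expression, config.gene_map)
    traits = TraitTable.from_tsv(config.traits)
    gm = GenotypeMatrix.from_tsv(config.variants)
    sequences = read_fasta(config.sequences) if config.sequences else None
    return run_from_objects(expr, traits, gm, sequences, config)


def run_from_objects(
    expr: ExpressionMatrix,
    traits: TraitTable,
    gm: GenotypeMatrix,
    sequences: Optional[dict[str, TranscriptSequence]],
    config: PipelineConfig,
) -> RunReport:
    """Run the full chain on in-memory objects; writes all artifacts."""
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {
        "n_transcripts": len(expr.transcript_ids),
        "n_genes": len(expr.genes),
        "n_samples": len(expr.samples),
        "n_variants_input": len(gm.variants),
    }
    stage = "screen"
    try:
        report = screen(expr, traits, config.tiers)
        write_screen_report(report, outdir / "screen")
        counts["screen"] = report.summary()["tiers"]
        loosest = max(config.tiers)
        screened_genes = report.genes_at(loosest)
        logger.info("screen: %d genes pass the %.3g tier", len(screened_genes), loosest)

        stage = "variant_association"
        gm_screened = gm.subset_genes(screened_genes)
        counts["n_variants_in_screened_genes"] = len(gm_screened.variants)
        gm_f = presence_filter(gm_screened, config.min_carriers)
        counts["n_variants_filtered"] = len(gm_f.variants)
        m = (
            len(screened_genes) or 1
            if config.bonferroni_m == "auto"
            else int(config.bonferroni_m)
        )
        counts["bonferroni_m"] = m
        counts["bonferroni_threshold"] = bonferroni_threshold(config.bonferroni_alpha, m)
        assocs = associate(
            gm_f, traits, m, config.strict_alpha,
            config.bonferroni_alpha, config.effect_mode,
            test=config.association_test,
        )
        (outdir / "variants").mkdir(exist_ok=True)
        gm_f.to_tsv(outdir / "variants" / "filtered_variants.tsv")
        adf = associations_to_frame(assocs)
        adf_out = adf.copy()
        adf_out["p"] = adf_out["p"].map(lambda v: f"{v:.2E}")
        adf_out.to_csv(outdir / "variants" / "associations.tsv", sep="\t", index=False)

        def _variants_at(flag: str) -> list[str]:
            if adf.empty:
                return []
            return sorted(adf.loc[adf[flag], "mutation_id"].unique())

        raw_hits = sorted(adf.loc[adf["p"] <= 0.05, "mutation_id"].unique()) if not adf.empty else []
        counts["n_variants_raw05"] = len(raw_hits)
        counts["n_variants_bonferroni"] = len(_variants_at("passes_bonferroni"))
        counts["n_variants_strict"] = len(_variants_at("passes_strict"))
        strict_records = [a for a in assocs if a.passes_strict]
        strict_variants = {a.variant.key: a.variant for a in strict_records}
        strict_genes = sorted({v.gene_id for v in strict_variants.values()})
        counts["n_genes_strict"] = len(strict_genes)
        logger.info(
            "association: %d/%d variants pass the strict cut (%d genes)",
            len(strict_variants), len(gm_f.variants), len(strict_genes),
        )

        stage = "orf_effects"
        effects: list[MutationEffect] = []
        if sequences is not None and strict_variants:
            (outdir / "orf").mkdir(exist_ok=True)
            rows = []
            for v in strict_variants.values():
                if v.transcript_id not in sequences:
                    logger.warning("no sequence for %s; ORF effect skipped", v.key)
                    continue
                eff = classify_effect(sequences[v.transcript_id], v)
                effects.append(eff)
                rows.append((v.gene_id, v.transcript_id, v.id_string,
                             eff.category, eff.short_label, eff.detail))
            import pandas as pd

            pd.DataFrame(
                rows,
                columns=["gene_id", "transcript_id", "mutation_id",
                         "category", "label", "detail"],
            ).to_csv(outdir / "orf" / "mutation_effects.tsv", sep="\t", index=False)
            counts["mutation_type_tally"] = effect_tally(effects, collapse=True)
            table2_report(strict_records, effects, outdir / "variants" / "table2.tsv")

        stage = "network"
        candidate_transcripts = sorted(
            t for t in expr.transcript_ids if expr.gene_of[t] in set(strict_genes)
        )
        screened_set = set(screened_genes)
        background_pool = sorted(
            t for t in expr.transcript_ids if expr.gene_of[t] not in screened_set
        )
        counts["network"] = None
        if candidate_transcripts:
            net = build_network(expr, traits, candidate_transcripts, config.network_alpha)
            (outdir / "network").mkdir(exist_ok=True)
            net.write(outdir / "network")
            counts["network"] = {
                "n_nodes": len(net.nodes),
                "n_connected_nodes": net.n_connected_nodes,
                "n_edges": net.n_edges,
                "n_clusters": len(net.clusters),
                "edge_classes": net.edge_class_counts(),
            }
            if len(background_pool) >= len(candidate_transcripts):
                tr = tendency_test(
                    expr, traits, candidate_transcripts, background_pool,
                    R=config.tendency_R, alpha_edge=config.network_alpha,
                    seed=config.seed,
                )
                with open(outdir / "network" / "tendency.json", "w") as fh:
                    json.dump(tr.to_dict(), fh, indent=2, sort_keys=True)
                counts["tendency"] = {
                    "p_nodes": tr.p_nodes, "p_edges": tr.p_edges,
                    "p_nodes_empirical": tr.p_nodes_empirical,
                    "p_edges_empirical": tr.p_edges_empirical,
                }
            else:
                logger.warning("background pool too small; tendency test skipped")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_out = RunReport(
        counts=counts,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    report_out.to_json(outdir / "report.json")
    return report_out
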
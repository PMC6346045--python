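"""Replicate studies quantifying calibration and power of the pipeline
stages on synthetic cultivar panels.

Each study repeatedly draws a panel from :func:`~cypscreen.simulate.
simulate_dataset` under fixed study conditions (42 cultivars, nine
mono-ginsenoside traits plus total), runs one pipeline stage, and aggregates
a rate across replicates:

* **null calibration** — with no planted signal, the fraction of tests at or
  below a nominal threshold should approximate that threshold;
* **power / sensitivity** — with planted signal of stated size, the fraction
  of planted effects the stage recovers;
* **tendency behaviour** — how often a planted co-expressed module (or a
  null gene set) is declared to form a network more readily than random
  background sets.

Replicate seeds are derived deterministically from a single base seed.
"""

from __future__ import annotations

import numpy as np

from .association import associate, associations_to_frame, presence_filter
from .network import tendency_test
from .screen import screen
from .simulate import (
    PlantedCorrelation,
    PlantedVariant,
    SimulationConfig,
    simulate_dataset,
)

_MONOS = SimulationConfig().trait_names


def _sub_seed(base: int, study: int, rep: int) -> int:
    """Deterministic per-replicate seed, kept below 2**31."""
    return int(
        np.random.default_rng([base, study, rep]).integers(0, 2**31 - 1)
    )


def screen_null_calibration(
    n_seeds: int = 200, n_transcripts: int = 400, base_seed: int = 0
) -> dict:
    """Hit rates of the correlation screen on all-null panels.

    Every transcript is independent noise, so the fraction of transcript ×
    trait pairs at or below each tier estimates the tier itself.
    """
    tested = hits05 = hits01 = 0
    for rep in range(n_seeds):
        config = SimulationConfig(
            seed=_sub_seed(base_seed, 1, rep),
            n_transcripts=n_transcripts, n_genes=n_transcripts,
            n_background_variants=0, generate_sequences=False,
        )
        truth = simulate_dataset(config)
        report = screen(truth.expression, truth.traits, (0.05, 0.01))
        tested += n_transcripts * len(truth.traits.traits)
        hits05 += len(report.hits_at(0.05))
        hits01 += len(report.hits_at(0.01))
    return {
        "rate_p05": hits05 / tested,
        "rate_p01": hits01 / tested,
        "n_tests": tested,
    }


def association_null_calibration(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """Fraction of null variant × trait tests with p <= 0.05 after the
    presence filter (carrier groups of realistic, small sizes)."""
    tested = hits = 0
    for rep in range(n_seeds):
        config = SimulationConfig(
            seed=_sub_seed(base_seed, 2, rep),
            n_transcripts=5, n_genes=5, n_background_variants=40,
            generate_sequences=False,
        )
        truth = simulate_dataset(config)
        gm = presence_filter(truth.genotypes, 4)
        df = associations_to_frame(associate(gm, truth.traits, bonferroni_m=100))
        tested += len(df)
        hits += int((df["p"] <= 0.05).sum())
    return {"rate_p05": hits / tested, "n_tests": tested}


def screen_recovery(
    n_seeds: int = 100, rho: float = 0.6, tier: float = 0.01,
    n_planted: int = 10, n_null: int = 400, base_seed: int = 0,
) -> dict:
    """Sensitivity of the screen for transcripts planted at Pearson ``rho``:
    the fraction of planted (transcript, trait) pairs passing ``tier``."""
    planted = recovered = 0
    for rep in range(n_seeds):
        config = SimulationConfig(
            seed=_sub_seed(base_seed, 3, rep),
            n_transcripts=n_planted + n_null, n_genes=n_planted + n_null,
            n_background_variants=0, generate_sequences=False,
            planted_correlated=[
                PlantedCorrelation(i, "Rg1", rho) for i in range(n_planted)
            ],
        )
        truth = simulate_dataset(config)
        report = screen(truth.expression, truth.traits, (0.05, tier))
        hitset = set(
            zip(report.hits_at(tier)["transcript_id"], report.hits_at(tier)["trait"])
        )
        for d in truth.ledger["planted_correlated"]:
            planted += 1
            recovered += (d["transcript_id"], d["trait"]) in hitset
    return {"sensitivity": recovered / planted, "n_planted": planted}


def variant_detection(
    n_seeds: int = 200, effect_sd: float = 2.0, n_carriers: int = 12,
    strict_alpha: float = 1.0e-4, base_seed: int = 0,
) -> dict:
    """Sensitivity of the single-marker test for planted carrier-group
    effects of ``effect_sd`` trait SDs at the strict threshold."""
    planted = detected = 0
    for rep in range(n_seeds):
        config = SimulationConfig(
            seed=_sub_seed(base_seed, 4, rep),
            n_transcripts=20, n_genes=20, n_background_variants=0,
            generate_sequences=False,
            planted_variants=[
                PlantedVariant(i, _MONOS[i], n_carriers, effect_sd)
                for i in range(len(_MONOS))
            ],
        )
        truth = simulate_dataset(config)
        gm = presence_filter(truth.genotypes, 4)
        df = associations_to_frame(
            associate(gm, truth.traits, bonferroni_m=100, strict_alpha=strict_alpha)
        )
        for d in truth.ledger["planted_variants"]:
            tid, mid = d["key"].split(":")
            sub = df[
                (df["transcript_id"] == tid)
                & (df["mutation_id"] == mid)
                & (df["trait"] == d["trait"])
            ]
            planted += 1
            detected += bool(len(sub) and sub["passes_strict"].any())
    return {"sensitivity": detected / planted, "n_planted": planted}


def tendency_study(
    n_seeds: int = 50, module_size: int = 10, loading: float = 0.9,
    pool_size: int = 200, R: int = 20, planted: bool = True,
    base_seed: int = 0,
) -> dict:
    """Fraction of replicates in which the tendency test calls the candidate
    set significant at p <= 0.01.

    With ``planted`` the candidates share a latent factor at ``loading``;
    otherwise they are drawn from the same null as the background pool, and
    the fraction estimates the test's false-positive rate.
    """
    study = 5 if planted else 6
    significant = 0
    for rep in range(n_seeds):
        config = SimulationConfig(
            seed=_sub_seed(base_seed, study, rep),
            n_transcripts=module_size + pool_size,
            n_genes=module_size + pool_size,
            n_background_variants=0, generate_sequences=False,
            planted_module=list(range(module_size)) if planted else [],
            module_loading=loading,
        )
        truth = simulate_dataset(config)
        ids = truth.expression.transcript_ids
        cand, pool = ids[:module_size], ids[module_size:]
        res = tendency_test(
            truth.expression, truth.traits, cand, pool,
            R=R, seed=_sub_seed(base_seed, study + 10, rep),
        )
        significant += res.p_edges <= 0.01
    return {"fraction_significant_p01": significant / n_seeds, "n_seeds": n_seeds}
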
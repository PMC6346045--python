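import numpy as np
import pandas as pd
import pytest

from cypscreen import (
    GenotypeMatrix,
    TraitTable,
    ValidationError,
    VariantRecord,
    associate,
    chance_probability,
    parse_mutation_id,
    presence_filter,
)
from cypscreen.association import associations_to_frame


class TestParseMutationId:
    @pytest.mark.parametrize(
        "raw,pos,ref,alt,cls",
        [
            ("667_A_G", 667, "A", "G", "SNP"),
            ("1214_A_AAT", 1214, "A", "AAT", "insertion"),
            ("70_CT_C", 70, "CT", "C", "deletion"),
        ],
    )
    def test_anchored_notation(self, raw, pos, ref, alt, cls):
        v = parse_mutation_id(raw)
        assert (v.position, v.ref, v.alt) == (pos, ref, alt)
        assert v.variant_class == cls
        assert v.id_string == raw

    def test_line_wrapped_label_is_cleaned(self):
        v = parse_mutation_id("73_C_CGTGTGA AAATAAAAGAA ACCCAGAACCCA TTAAAGCACCAG")
        assert v.position == 73
        assert v.variant_class == "insertion"
        assert v.ref == "C" and v.alt.startswith("CGTGTGA")
        assert len(v.alt) == 42

    @pytest.mark.parametrize("bad", ["x_A_G", "12_A_", "12_AU_G", "_A_G", "12-A-G"])
    def test_malformed_label_echoes_input(self, bad):
        with pytest.raises(ValidationError, match="malformed"):
            parse_mutation_id(bad)

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValidationError):
            parse_mutation_id("10_A_A")


def _toy_genotypes(counts, n_samples=42):
    rng = np.random.default_rng(1)
    variants, rows = [], []
    for i, k in enumerate(counts):
        variants.append(VariantRecord("g", "t", 10 + i, "A", "G"))
        row = np.zeros(n_samples, bool)
        row[rng.choice(n_samples, size=k, replace=False)] = True
        rows.append(row)
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(variants, samples, np.vstack(rows))


class TestPresenceFilter:
    def test_keeps_variants_with_enough_carriers(self):
        gm = _toy_genotypes([1, 3, 4, 5, 42])
        kept = presence_filter(gm, 4)
        assert len(kept.variants) == 3
        assert (kept.carrier_counts >= 4).all()

    def test_threshold_one_is_weakest(self):
        gm = _toy_genotypes([1, 3, 4])
        assert len(presence_filter(gm, 1).variants) == 3

    def test_idempotent(self):
        gm = _toy_genotypes([1, 3, 4, 5, 42])
        once = presence_filter(gm, 4)
        twice = presence_filter(once, 4)
        assert [v.id_string for v in once.variants] == [v.id_string for v in twice.variants]
        np.testing.assert_array_equal(once.carrier, twice.carrier)


class TestChanceProbability:
    def test_recurrent_call_probability(self):
        # four cultivars sharing one erroneous call on an average-length
        # transcript: (1/1306)^4, i.e. 3.4e-13 at two significant digits
        p = chance_probability(1306, 4)
        assert p == pytest.approx(3.4e-13, rel=0.02)

    @pytest.mark.parametrize("L,k,expected", [(1, 5, 1.0), (10, 2, 0.01)])
    def test_arithmetic(self, L, k, expected):
        assert chance_probability(L, k) == pytest.approx(expected, rel=1e-12)


def _traits_for(samples, **cols):
    df = pd.DataFrame(cols, index=samples)
    return TraitTable(df)


class TestAssociate:
    def test_effect_percent_is_carrier_mean_difference(self):
        samples = [f"s{i}" for i in range(10)]
        carrier = np.array([True] * 5 + [False] * 5)
        gm = GenotypeMatrix([VariantRecord("g", "t", 5, "A", "G")], samples,
                            carrier[None, :])
        vals = np.where(carrier, 15.0, 10.0) + np.tile([0.0, 0.1], 5)
        tt = _traits_for(samples, Rg1=vals)
        rec = associate(gm, tt, bonferroni_m=1)[0]
        expected = 100 * abs(vals[carrier].mean() - vals[~carrier].mean()) / vals[~carrier].mean()
        assert rec.effect_pct == pytest.approx(expected)
        assert rec.effect_pct == pytest.approx(50.0, abs=1.0)

    def test_zero_noncarrier_mean_flags_effect_undefined(self):
        samples = [f"s{i}" for i in range(8)]
        carrier = np.array([True] * 4 + [False] * 4)
        gm = GenotypeMatrix([VariantRecord("g", "t", 5, "A", "G")], samples,
                            carrier[None, :])
        vals = np.array([1.0, 2.0, 1.5, 2.5, 0.0, 0.0, 0.0, 0.0])
        rec = associate(gm, _traits_for(samples, Rg1=vals), bonferroni_m=1)[0]
        assert not rec.effect_defined
        assert np.isnan(rec.effect_pct)
        assert 0 < rec.p <= 1

    def test_variant_without_two_per_group_is_skipped(self, caplog):
        samples = [f"s{i}" for i in range(6)]
        carrier = np.array([True] + [False] * 5)
        gm = GenotypeMatrix([VariantRecord("g", "t", 5, "A", "G")], samples,
                            carrier[None, :])
        with caplog.at_level("INFO"):
            recs = associate(gm, _traits_for(samples, Rg1=np.arange(6.0)), 1)
        assert recs == []

    def test_p_invariant_to_sample_order(self, planted_panel):
        gm = presence_filter(planted_panel.genotypes, 4)
        base = associations_to_frame(associate(gm, planted_panel.traits, 100))
        order = list(reversed(planted_panel.traits.samples))
        shuffled_traits = TraitTable(planted_panel.traits.data.loc[order])
        other = associations_to_frame(associate(gm, shuffled_traits, 100))
        merged = base.merge(other, on=["mutation_id", "transcript_id", "trait"],
                            suffixes=("_a", "_b"))
        assert len(merged) == len(base)
        np.testing.assert_allclose(merged["p_a"], merged["p_b"], rtol=1e-9)

    def test_funnel_monotone_in_thresholds(self, planted_panel):
        gm = presence_filter(planted_panel.genotypes, 4)
        df = associations_to_frame(
            associate(gm, planted_panel.traits, bonferroni_m=100, strict_alpha=1e-4)
        )
        strict = set(df.loc[df.passes_strict, "mutation_id"])
        bonf = set(df.loc[df.passes_bonferroni, "mutation_id"])
        raw = set(df.loc[df.p <= 0.05, "mutation_id"])
        assert strict <= bonf <= raw

    def test_planted_effects_detected_at_strict_threshold(self, planted_panel):
        gm = presence_filter(planted_panel.genotypes, 4)
        df = associations_to_frame(associate(gm, planted_panel.traits, 100))
        detected = 0
        planted = planted_panel.ledger["planted_variants"]
        for d in planted:
            tid, mid = d["key"].split(":")
            sub = df[(df.transcript_id == tid) & (df.mutation_id == mid)
                     & (df.trait == d["trait"])]
            detected += bool(len(sub) and sub.passes_strict.any())
        assert detected >= len(planted) - 1

    def test_welch_variant_available(self, planted_panel):
        gm = presence_filter(planted_panel.genotypes, 4)
        student = associations_to_frame(associate(gm, planted_panel.traits, 100))
        welch = associations_to_frame(
            associate(gm, planted_panel.traits, 100, test="welch")
        )
        assert len(student) == len(welch)
        assert not np.allclose(student["p"], welch["p"])
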
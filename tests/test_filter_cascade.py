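"""Prioritization cascade rules, failure attribution, and set invariants."""

import csv

import pandas as pd
import pytest

from pmfvar import filter_cascade as fc
from pmfvar.io_formats import (
    Consequence,
    FrequencyPanel,
    MutationTaster,
    PolyPhen2,
    PredictionProfile,
    Sift,
    VariantRecord,
)


def make_variant(vid="v1", gene="GENE1", consequence=Consequence.MISSENSE,
                 n_carriers=3, protein_change="p.Arg153Cys"):
    if consequence is Consequence.NONSENSE:
        protein_change = "p.Arg432Ter"
    return VariantRecord(
        variant_id=vid, gene=gene, chrom="1", pos=100, ref="C", alt="T",
        rsid=None, consequence=consequence, cdna_change="c.457C>T",
        protein_change=protein_change,
        carrier_cases=frozenset(f"case{i:03d}" for i in range(1, n_carriers + 1)),
    )


def panel_of(vid="v1", finrisk=None, gnomad=None):
    return FrequencyPanel(vid, {"finrisk": (finrisk, 2654), "gnomad_fin": (gnomad, 25000)})


class TestResolveFrequency:
    def test_regional_missing_falls_back_to_national(self):
        freq, an, src = fc.resolve_frequency(panel_of(finrisk=None, gnomad=0.0008),
                                             ["finrisk", "gnomad_fin"])
        assert (freq, an, src) == (0.0008, 25000, "gnomad_fin")

    def test_regional_present_takes_precedence(self):
        freq, an, src = fc.resolve_frequency(panel_of(finrisk=0.0026, gnomad=0.0045),
                                             ["finrisk", "gnomad_fin"])
        assert (freq, an, src) == (0.0026, 2654, "finrisk")

    def test_all_missing_raises(self):
        with pytest.raises(fc.UnresolvedFrequencyError):
            fc.resolve_frequency(panel_of(), ["finrisk", "gnomad_fin"])


class TestRarityRule:
    @pytest.mark.parametrize("finrisk,gnomad,expected", [
        (None, 0.0049, True),    # just under the bar
        (None, 0.005, False),    # strict inequality boundary
        (0.004, 0.006, False),   # AND across sources: one common source kills it
        (0.004, 0.004, True),
        (0.004, None, True),     # missing source does not veto
        (None, None, False),     # nothing known -> cannot claim rare
    ])
    def test_two_source_truth_table(self, finrisk, gnomad, expected):
        assert fc.rarity_rule(panel_of(finrisk=finrisk, gnomad=gnomad)) is expected


class TestRecurrenceRule:
    @pytest.mark.parametrize("n,expected", [(3, True), (2, False), (5, True)])
    def test_carrier_threshold(self, n, expected):
        assert fc.recurrence_rule(make_variant(n_carriers=n)) is expected


class TestPredictionRule:
    def damaging(self, **kw):
        base = dict(sift=Sift.DELETERIOUS, polyphen2=PolyPhen2.POSSIBLY_DAMAGING,
                    cadd=23.9, mutation_taster=MutationTaster.MISSING)
        base.update(kw)
        return PredictionProfile(**base)

    def test_missense_conjunction_passes(self):
        assert fc.prediction_rule(Consequence.MISSENSE, self.damaging())

    def test_nonsense_keys_on_mutation_taster(self):
        prof = PredictionProfile(cadd=44.0, mutation_taster=MutationTaster.DISEASE_CAUSING)
        assert fc.prediction_rule(Consequence.NONSENSE, prof)
        assert not fc.prediction_rule(
            Consequence.NONSENSE, PredictionProfile(cadd=44.0))

    def test_benign_polyphen_fails_conjunction(self):
        assert not fc.prediction_rule(
            Consequence.MISSENSE, self.damaging(polyphen2=PolyPhen2.BENIGN, cadd=30))

    def test_cadd_threshold_is_strict(self):
        assert not fc.prediction_rule(Consequence.MISSENSE, self.damaging(cadd=20.0))

    def test_missing_required_field_never_passes(self):
        assert not fc.prediction_rule(Consequence.MISSENSE, self.damaging(cadd=None))
        assert not fc.prediction_rule(Consequence.MISSENSE, self.damaging(sift=Sift.MISSING))

    def test_other_consequence_always_fails(self):
        assert not fc.prediction_rule(Consequence.OTHER, self.damaging())


class TestFlaggedGeneAndTier:
    def test_case_insensitive_flag_match(self):
        flagged = frozenset({"TTN"})
        cfg = fc.FilterConfig(flagged_genes=frozenset({"Ttn "}))
        assert cfg.flagged_genes == flagged
        assert not fc.flagged_gene_rule("Ttn", flagged)
        assert fc.flagged_gene_rule("CAPN1", flagged)
        assert fc.flagged_gene_rule("ANY", frozenset())

    @pytest.mark.parametrize("vr,ms,expected", [
        (0.386, 0.764, True),    # one score above suffices
        (None, None, False),     # missing contributes false
        (0.7, 0.7, False),       # strict inequality
        (0.941, 0.922, True),
    ])
    def test_tier_rule(self, vr, ms, expected):
        prof = PredictionProfile(varity_r=vr, mutscore=ms)
        assert fc.assign_tier(prof) is expected


class TestClinvarSideTable:
    def test_no_table_gives_empty_side_table(self):
        assert fc.flag_clinvar([make_variant()], None).empty

    def test_pathogenic_match_reported_outside_cascade(self):
        table = pd.DataFrame([{"gene": "GENE1", "chrom": "1", "pos": 100,
                               "ref": "C", "alt": "T",
                               "clinical_significance": "pathogenic"}])
        side = fc.flag_clinvar([make_variant(n_carriers=1)], table)
        assert len(side) == 1

    def test_rsid_match_with_position_mismatch_is_not_joined(self, caplog):
        import logging
        v = VariantRecord(
            variant_id="v9", gene="G", chrom="1", pos=100, ref="C", alt="T",
            rsid="rs1", consequence=Consequence.MISSENSE, cdna_change="c.1C>T",
            protein_change="p.Arg1Cys", carrier_cases=frozenset({"case001"}))
        table = pd.DataFrame([{"gene": "G", "chrom": "1", "pos": 999, "ref": "C",
                               "alt": "T", "rsid": "rs1",
                               "clinical_significance": "pathogenic"}])
        with caplog.at_level(logging.WARNING, logger="pmfvar"):
            side = fc.flag_clinvar([v], table)
        assert side.empty
        assert any("coordinates differ" in r.message for r in caplog.records)


def independent_rule_evaluation(variants_path, frequencies_path, cfg, source_order):
    """Brute-force re-evaluation of all cascade rules straight off the TSVs,
    sharing no code with the cascade."""
    with open(frequencies_path) as fh:
        freq_rows = {r["variant_id"]: r for r in csv.DictReader(fh, delimiter="\t")}
    statuses = {}
    with open(variants_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            vid = row["variant_id"]
            f = freq_rows[vid]
            afs = []
            for src in source_order:
                cell = f[f"{src}_af"]
                if cell not in ("", "NA"):
                    afs.append(float(cell))
            carriers = [c for c in row["carriers"].split(",") if c]
            is_nonsense = row["protein_change"].endswith("Ter")
            if is_nonsense:
                pred_ok = row["mutation_taster"] == "DC"
            else:
                pred_ok = (
                    row["sift"] == "D" and row["polyphen2"] in ("PD", "PoD")
                    and row["cadd"] not in ("", "NA") and float(row["cadd"]) > cfg.cadd_threshold)
            ok = (
                bool(afs)
                and all(a < cfg.maf_threshold for a in afs)
                and len(carriers) >= cfg.min_carrier_cases
                and pred_ok
                and row["gene"].strip().upper() not in cfg.flagged_genes
            )
            if not ok:
                statuses[vid] = "excluded"
            else:
                tiered = any(
                    row[k] not in ("", "NA") and float(row[k]) > cfg.tier_threshold
                    for k in ("varity_r", "mutscore"))
                statuses[vid] = "candidate_tiered" if tiered else "candidate"
    return statuses


class TestCascade:
    def test_statuses_match_brute_force_on_synthetic_bundle(self, tmp_path):
        """Cascade outcome equals an independent rule-by-rule evaluation on
        1000 random synthetic variants."""
        from pmfvar import io_formats
        from pmfvar.synthetic_data import SimulationConfig, generate_cohort

        cfg = SimulationConfig(n_variants=1000, seed=20240901)
        paths, _ = generate_cohort(cfg, tmp_path)
        fcfg = fc.FilterConfig(flagged_genes=frozenset({"GENE0000", "GENE0007"}))
        order = ["finrisk", "gnomad_fin"]
        records = io_formats.read_variant_table(paths["variants"])
        panels = io_formats.read_frequency_panel(paths["frequencies"], order)
        outcome = fc.run_cascade(records, panels, fcfg, order)
        expected = independent_rule_evaluation(
            paths["variants"], paths["frequencies"], fcfg, order)
        assert outcome.status == expected
        # telescoping counts
        for prev, nxt in zip(outcome.stage_counts, outcome.stage_counts[1:]):
            assert prev["passed"] == nxt["entered"]
            assert prev["entered"] == prev["passed"] + prev["failed"]
        assert outcome.stage_counts[0]["entered"] == 1000

    def test_all_common_cohort_has_zero_candidates(self):
        variants = [(make_variant(vid=f"v{i}"), PredictionProfile()) for i in range(5)]
        panels = {f"v{i}": panel_of(f"v{i}", finrisk=0.1) for i in range(5)}
        outcome = fc.run_cascade(variants, panels, source_order=["finrisk", "gnomad_fin"])
        assert outcome.n_candidates == 0
        assert all(r == "rarity" for r in outcome.failing_rule.values())

    def test_reference_rows_give_22_candidates_10_tiered(self, reference_inputs):
        from pmfvar.datasets import SOURCE_ORDER
        outcome = fc.run_cascade(reference_inputs["records"], reference_inputs["panels"],
                                 source_order=SOURCE_ORDER)
        assert outcome.n_candidates == 22
        assert outcome.n_tiered == 10

    def test_excluded_variants_blame_exactly_one_rule(self, tmp_path):
        from pmfvar import io_formats
        from pmfvar.synthetic_data import SimulationConfig, generate_cohort

        paths, _ = generate_cohort(SimulationConfig(n_variants=200, seed=5), tmp_path)
        records = io_formats.read_variant_table(paths["variants"])
        panels = io_formats.read_frequency_panel(paths["frequencies"], ["finrisk", "gnomad_fin"])
        outcome = fc.run_cascade(records, panels, source_order=["finrisk", "gnomad_fin"])
        excluded = {vid for vid, s in outcome.status.items() if s == "excluded"}
        assert excluded == set(outcome.failing_rule)
        assert set(outcome.failing_rule.values()) <= {
            "no_population_frequency", "rarity", "recurrence",
            "prediction", "insufficient_annotation", "flagged_gene"}

    def test_monotonicity_in_thresholds(self, reference_inputs):
        """Loosening MAF or CADD thresholds never removes a survivor."""
        from pmfvar.datasets import SOURCE_ORDER
        strict = fc.run_cascade(reference_inputs["records"], reference_inputs["panels"],
                                fc.FilterConfig(maf_threshold=0.003, cadd_threshold=25),
                                SOURCE_ORDER)
        loose = fc.run_cascade(reference_inputs["records"], reference_inputs["panels"],
                               fc.FilterConfig(maf_threshold=0.005, cadd_threshold=20),
                               SOURCE_ORDER)
        strict_ids = {c.variant.variant_id for c in strict.candidates}
        loose_ids = {c.variant.variant_id for c in loose.candidates}
        assert strict_ids <= loose_ids
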
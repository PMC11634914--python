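"""Ordered rare-variant prioritization cascade with full failure logging.

Stage order: frequency resolution -> rarity -> recurrence -> in-silico
prediction -> flagged-gene exclusion.  All rules are conjunctive, so the
surviving set is order-invariant; the order only decides which rule is
blamed for an exclusion.  Survivors are additionally tiered by the
Varity_R / MutScore > 0.7 rule (the "likely functional" subset).

Thresholds are strict inequalities throughout: MAF < 0.005, CADD > 20,
score > 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import (
    Consequence,
    FrequencyPanel,
    MutationTaster,
    PolyPhen2,
    PredictionProfile,
    Sift,
    VariantRecord,
)

STAGES = ("frequency_resolution", "rarity", "recurrence", "prediction", "flagged_gene")


@dataclass(frozen=True)
class FilterConfig:
    maf_threshold: float = 0.005
    min_carrier_cases: int = 3
    cadd_threshold: float = 20.0
    tier_threshold: float = 0.7
    flagged_genes: frozenset[str] = frozenset()
    significance_alpha: float = 0.05

    def __post_init__(self):
        if min(self.maf_threshold, self.cadd_threshold, self.tier_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        object.__setattr__(
            self, "flagged_genes",
            frozenset(normalize_symbol(g) for g in self.flagged_genes))


def normalize_symbol(gene: str) -> str:
    """Case-insensitive gene symbol matching after whitespace stripping."""
    return gene.strip().upper()


class UnresolvedFrequencyError(ValueError):
    """No population source carries a frequency for this variant."""


def resolve_frequency(panel: FrequencyPanel,
                      source_order: list[str] | None = None) -> tuple[float, int | None, str]:
    """Return (frequency, allele_number, source) from the first non-missing
    source in precedence order (regional panel first, national second)."""
    order = source_order if source_order is not None else list(panel.sources)
    for source in order:
        af, an = panel.sources.get(source, (None, None))
        if af is not None:
            return af, an, source
    raise UnresolvedFrequencyError(
        f"{panel.variant_id}: no population frequency in any source")


def rarity_rule(panel: FrequencyPanel, maf_threshold: float = 0.005) -> bool:
    """Rare means strictly below threshold in EVERY non-missing source."""
    known = panel.non_missing()
    if not known:
        return False
    return all(af < maf_threshold for af, _an in known.values())


def recurrence_rule(variant: VariantRecord, min_carrier_cases: int = 3) -> bool:
    return variant.n_carriers >= min_carrier_cases


def prediction_rule(consequence: Consequence, profile: PredictionProfile,
                    cadd_threshold: float = 20.0) -> bool:
    """Consequence-specific deleteriousness requirement.

    Missense requires SIFT deleterious AND PolyPhen-2 possibly/probably
    damaging AND CADD strictly above threshold.  Indels require
    MutationTaster disease-causing.  Stop gains likewise key on
    MutationTaster (their CADD is recorded but not gating, since truncation
    is damaging by mechanism).  A missing required annotation fails its
    clause — never a silent pass.
    """
    if consequence is Consequence.MISSENSE:
        return (
            profile.sift is Sift.DELETERIOUS
            and profile.polyphen2 in (PolyPhen2.POSSIBLY_DAMAGING, PolyPhen2.PROBABLY_DAMAGING)
            and profile.cadd is not None
            and profile.cadd > cadd_threshold
        )
    if consequence in (Consequence.INDEL, Consequence.NONSENSE):
        return profile.mutation_taster is MutationTaster.DISEASE_CAUSING
    return False


def flagged_gene_rule(gene: str, flagged_genes: frozenset[str]) -> bool:
    """True (pass) iff the gene is NOT on the recurrent-false-positive list."""
    return normalize_symbol(gene) not in flagged_genes


def assign_tier(profile: PredictionProfile, tier_threshold: float = 0.7) -> bool:
    """Likely-functional tier: Varity_R > 0.7 OR MutScore > 0.7 (strict);
    a missing score contributes False."""
    return any(
        score is not None and score > tier_threshold
        for score in (profile.varity_r, profile.mutscore)
    )


def flag_clinvar(variants: list[VariantRecord], clinvar_table: pd.DataFrame | None) -> pd.DataFrame:
    """Match cohort variants against a ClinVar-like pathogenicity table.

    Matches on (chrom, pos, ref, alt); pathogenic hits are reported in a
    side table and bypass the cascade (they are carried by single
    individuals, below the recurrence bar, but remain clinically
    reportable).  An rsid agreeing while the position differs is NOT a
    match and raises a warning.
    """
    columns = ["variant_id", "gene", "chrom", "pos", "ref", "alt", "clinical_significance"]
    if clinvar_table is None or clinvar_table.empty:
        return pd.DataFrame(columns=columns)
    import logging
    log = logging.getLogger("pmfvar")
    keyed = {
        (str(r["chrom"]), int(r["pos"]), r["ref"], r["alt"]): r
        for _, r in clinvar_table.iterrows()
    }
    by_rsid = {
        r["rsid"]: (str(r["chrom"]), int(r["pos"]), r["ref"], r["alt"])
        for _, r in clinvar_table.iterrows()
        if "rsid" in clinvar_table.columns and str(r.get("rsid", "")).startswith("rs")
    }
    rows = []
    for v in variants:
        key = (str(v.chrom), v.pos, v.ref, v.alt)
        hit = keyed.get(key)
        if hit is not None and str(hit["clinical_significance"]).lower() == "pathogenic":
            rows.append({
                "variant_id": v.variant_id, "gene": v.gene, "chrom": v.chrom,
                "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "clinical_significance": hit["clinical_significance"],
            })
        elif v.rsid in by_rsid and by_rsid[v.rsid] != key:
            log.warning("%s: rsid %s matches ClinVar but coordinates differ; not joined",
                        v.variant_id, v.rsid)
    return pd.DataFrame(rows, columns=columns)


@dataclass
class Candidate:
    """A cascade survivor with its resolved frequency, ready for association."""

    variant: VariantRecord
    profile: PredictionProfile
    frequency: float
    allele_number: int | None
    source_used: str
    tier: bool


@dataclass
class FilterOutcome:
    """Per-variant statuses plus telescoping per-stage counts."""

    candidates: list[Candidate]
    status: dict[str, str]              # variant_id -> excluded|candidate|candidate_tiered
    failing_rule: dict[str, str]        # variant_id -> first failing rule (excluded only)
    stage_counts: list[dict]            # per stage: entered / passed / failed

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_tiered(self) -> int:
        return sum(c.tier for c in self.candidates)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_counts, columns=["stage", "entered", "passed", "failed"])


def run_cascade(variants: list[tuple[VariantRecord, PredictionProfile]],
                panels: dict[str, FrequencyPanel],
                config: FilterConfig = FilterConfig(),
                source_order: list[str] | None = None) -> FilterOutcome:
    """Apply all rules in stage order, recording the first failure per variant.

    Counts telescope: each stage's ``entered`` equals the previous stage's
    ``passed``, and ``entered = passed + failed`` at every stage.
    """
    alive: list[tuple[VariantRecord, PredictionProfile, tuple]] = []
    status: dict[str, str] = {}
    failing: dict[str, str] = {}
    stage_counts: list[dict] = []

    def record_stage(name, entered, passed):
        stage_counts.append({"stage": name, "entered": len(entered),
                             "passed": len(passed), "failed": len(entered) - len(passed)})

    current = list(variants)

    # Stage 1: frequency resolution
    passed = []
    for v, prof in current:
        panel = panels.get(v.variant_id)
        try:
            if panel is None:
                raise UnresolvedFrequencyError(v.variant_id)
            freq, an, src = resolve_frequency(panel, source_order)
            passed.append((v, prof, (panel, freq, an, src)))
        except UnresolvedFrequencyError:
            status[v.variant_id] = "excluded"
            failing[v.variant_id] = "no_population_frequency"
    record_stage("frequency_resolution", current, passed)
    alive = passed

    # Stage 2: rarity (conservative AND over all non-missing sources)
    passed = [t for t in alive if rarity_rule(t[2][0], config.maf_threshold)]
    for v, _p, _x in alive:
        if all(v is not t[0] for t in passed):
            status[v.variant_id] = "excluded"
            failing[v.variant_id] = "rarity"
    record_stage("rarity", alive, passed)
    alive = passed

    # Stage 3: recurrence
    passed = [t for t in alive if recurrence_rule(t[0], config.min_carrier_cases)]
    for v, _p, _x in alive:
        if all(v is not t[0] for t in passed):
            status[v.variant_id] = "excluded"
            failing[v.variant_id] = "recurrence"
    record_stage("recurrence", alive, passed)
    alive = passed

    # Stage 4: in-silico prediction
    passed = []
    for v, prof, extra in alive:
        if prediction_rule(v.consequence, prof, config.cadd_threshold):
            passed.append((v, prof, extra))
        else:
            status[v.variant_id] = "excluded"
            required_missing = (
                v.consequence is Consequence.MISSENSE
                and (prof.sift is Sift.MISSING or prof.polyphen2 is PolyPhen2.MISSING
                     or prof.cadd is None)
            ) or (
                v.consequence in (Consequence.INDEL, Consequence.NONSENSE)
                and prof.mutation_taster is MutationTaster.MISSING
            )
            failing[v.variant_id] = "insufficient_annotation" if required_missing else "prediction"
    record_stage("prediction", alive, passed)
    alive = passed

    # Stage 5: flagged-gene exclusion
    passed = [t for t in alive if flagged_gene_rule(t[0].gene, config.flagged_genes)]
    for v, _p, _x in alive:
        if all(v is not t[0] for t in passed):
            status[v.variant_id] = "excluded"
            failing[v.variant_id] = "flagged_gene"
    record_stage("flagged_gene", alive, passed)

    candidates = []
    for v, prof, (panel, freq, an, src) in passed:
        tier = assign_tier(prof, config.tier_threshold)
        status[v.variant_id] = "candidate_tiered" if tier else "candidate"
        candidates.append(Candidate(v, prof, freq, an, src, tier))
    return FilterOutcome(candidates, status, failing, stage_counts)
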
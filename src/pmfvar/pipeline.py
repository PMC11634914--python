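"""End-to-end orchestration: filter -> associate -> profile -> enrich.

One config, one seed, structured stage logging, and a summary that mirrors
the published report: per-stage cascade counts, candidate/tiered/
significant tallies, the tiered-and-significant gene list, and carrier
coverage (cases carrying at least one candidate variant).

Every number in the summary is re-derivable from the stage output files;
the summary does no computation of its own beyond counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, biochem_profile, filter_cascade, interactome_matrisome, io_formats
from .association import ALPHA, DEFAULT_ALLELE_NUMBERS
from .datasets import SOURCE_ORDER
from .filter_cascade import FilterConfig

logger = logging.getLogger("pmfvar")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class PipelineConfig:
    variants: str
    frequencies: str
    out_dir: str
    n_cases: int = 127
    source_order: list[str] = field(default_factory=lambda: list(SOURCE_ORDER))
    allele_numbers: dict = field(default_factory=lambda: dict(DEFAULT_ALLELE_NUMBERS))
    alpha: float = ALPHA
    filter: FilterConfig = field(default_factory=FilterConfig)
    clinvar: str | None = None
    ptm: str | None = None
    domains: str | None = None
    biogrid: str | None = None
    pairs: str | None = None
    staining: str | None = None
    matrisome: str | None = None
    continuity: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fdict = dict(raw.pop("filter", {}))
        fdict["flagged_genes"] = frozenset(fdict.get("flagged_genes", []))
        return cls(filter=FilterConfig(**fdict), **raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "filter"}
        f = self.filter
        d["filter"] = {
            "maf_threshold": f.maf_threshold, "min_carrier_cases": f.min_carrier_cases,
            "cadd_threshold": f.cadd_threshold, "tier_threshold": f.tier_threshold,
            "flagged_genes": sorted(f.flagged_genes),
            "significance_alpha": f.significance_alpha,
        }
        return d


def round_half_up_1dp(x: float) -> float:
    import math
    return math.floor(x * 10 + 0.5) / 10


def summarize_carriers(candidates, n_cases: int) -> tuple[int, float, int]:
    """Distinct cases carrying >= 1 candidate variant.

    Returns (count, percent to one decimal, reported integer percent).
    The integer percent is the nearest integer of the one-decimal value,
    half-up — 54/127 -> 42.5% -> reported 43 — matching how such coverage
    figures are conventionally printed.
    """
    carriers: set[str] = set()
    for c in candidates:
        carriers |= c.variant.carrier_cases
    if n_cases == 0 or not carriers:
        return 0, 0.0, 0
    pct = round_half_up_1dp(100.0 * len(carriers) / n_cases)
    import math
    return len(carriers), pct, math.floor(pct + 0.5)


def _resolve_allele_numbers(candidates, allele_numbers: dict):
    """Fill allele numbers missing from the frequency file from config."""
    for c in candidates:
        if c.allele_number is None:
            an = allele_numbers.get(c.source_used)
            if an is None:
                raise PipelineStageError(
                    "associate", "missing_allele_number",
                    f"{c.variant.variant_id}: no allele number for source {c.source_used!r}")
            c.allele_number = an


def run_all(config: PipelineConfig) -> dict:
    """Run every stage, write the output bundle, return the summary dict.

    On stage failure the outputs written so far are retained and a FAILED
    marker file records the stage and error code.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    try:
        return _run_all_inner(config, out)
    except PipelineStageError as err:
        (out / "FAILED").write_text(f"{err.stage}\t{err.code}\n{err}\n")
        raise


def _stage(name: str, code: str, fn, *args, **kwargs):
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(name, code, str(exc)) from exc
    logger.info("stage=%s event=done", name)
    return result


def _run_all_inner(config: PipelineConfig, out: Path) -> dict:
    variants = _stage("load", "variant_table", io_formats.read_variant_table, config.variants)
    panels = _stage("load", "frequency_panel", io_formats.read_frequency_panel,
                    config.frequencies, config.source_order)

    # --- filter cascade ---
    outcome = _stage("filter", "cascade", filter_cascade.run_cascade,
                     variants, panels, config.filter, config.source_order)
    outcome.counts_frame().to_csv(out / "cascade_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"variant_id": vid, "failing_rule": rule}
         for vid, rule in sorted(outcome.failing_rule.items())]
    ).to_csv(out / "exclusions.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "variant_id": c.variant.variant_id, "gene": c.variant.gene,
        "protein_change": c.variant.protein_change,
        "n_carriers": c.variant.n_carriers,
        "frequency": c.frequency, "frequency_source": c.source_used,
        "tier": int(c.tier),
    } for c in outcome.candidates]).to_csv(out / "candidates.tsv", sep="\t", index=False)

    clinvar_table = None
    if config.clinvar:
        clinvar_table = _stage("filter", "clinvar", io_formats.read_clinvar_table, config.clinvar)
    side = filter_cascade.flag_clinvar([v for v, _p in variants], clinvar_table)
    side.to_csv(out / "clinvar_side_table.tsv", sep="\t", index=False)

    # --- association ---
    _resolve_allele_numbers(outcome.candidates, config.allele_numbers)
    results = _stage("associate", "allelic_or", association.associate,
                     outcome.candidates, config.n_cases, config.alpha,
                     config.continuity)
    io_formats.write_results_table(results, out / "associations.tsv")

    # --- biochemical profile ---
    ptm = io_formats.read_ptm_table(config.ptm) if config.ptm else []
    domains = io_formats.read_domain_table(config.domains) if config.domains else []
    profiles = _stage("profile", "substitution", biochem_profile.profile_variants,
                      outcome.candidates, ptm, domains)
    biochem_profile.profiles_frame(profiles).to_csv(out / "profiles.tsv", sep="\t", index=False)

    # --- interactome / matrisome enrichment ---
    enrichment_rows = []
    if config.biogrid and config.pairs and config.staining and config.matrisome:
        edges = _stage("enrich", "interactions", io_formats.read_interaction_files,
                       config.biogrid, config.pairs)
        annotations = _stage("enrich", "annotations", io_formats.read_gene_annotations,
                             config.matrisome, config.staining)
        query = [c.variant.gene for c in outcome.candidates]
        comp = interactome_matrisome.build_compendium(edges, query, annotations)
        comp_rows = []
        for q in sorted(comp.interactors):
            for sym, it in sorted(comp.partners(q).items()):
                comp_rows.append({
                    "query": q, "interactor": sym, "source": it.source.value,
                    "n_supporting_publications": it.n_supporting_publications,
                    "staining": it.staining.value,
                    "matrisome_division": it.matrisome_division.value,
                })
        pd.DataFrame(comp_rows, columns=["query", "interactor", "source",
                                         "n_supporting_publications", "staining",
                                         "matrisome_division"]).to_csv(
            out / "compendium.tsv", sep="\t", index=False)
        mat_genes = {g: a for g, a in annotations.items()
                     if a.matrisome_division is not io_formats.MatrisomeDivision.NON_MATRISOME}
        observed = {g: a.matrisome_division.value for g, a in mat_genes.items()
                    if g in {q.upper() for q in query}}
        background_div = {g: a.matrisome_division.value for g, a in mat_genes.items()}
        background_fam = {g: a.matrisome_category for g, a in mat_genes.items()}
        observed_fam = {g: a.matrisome_category for g, a in mat_genes.items()
                        if g in {q.upper() for q in query}}
        for res in (
            interactome_matrisome.chisq_category_test(observed, background_div, "division"),
            interactome_matrisome.chisq_category_test(observed_fam, background_fam, "family"),
            interactome_matrisome.heart_enrichment_test(comp, annotations),
        ):
            enrichment_rows.append({
                "test": res.test,
                "statistic": "NA" if res.statistic is None else f"{res.statistic:.6g}",
                "p_value": f"{res.p_value:.6g}",
                "observed": str(res.observed), "expected": str(res.expected),
            })
        pd.DataFrame(enrichment_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # --- summary ---
    significant = association.significant_set(results, config.alpha)
    tiered_significant = [r for r in significant if r.tier]
    n_carriers, pct_1dp, pct_int = summarize_carriers(outcome.candidates, config.n_cases)
    summary = {
        "n_variants_in": len(variants),
        "stage_counts": outcome.stage_counts,
        "n_candidates": outcome.n_candidates,
        "n_tiered": outcome.n_tiered,
        "n_significant": len(significant),
        "n_tiered_significant": len(tiered_significant),
        "tiered_significant_genes": sorted(r.gene for r in tiered_significant),
        "n_clinvar_pathogenic": int(len(side)),
        "carrier_cases": n_carriers,
        "carrier_percent_1dp": pct_1dp,
        "carrier_percent": pct_int,
        "seed": config.seed,
    }
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return summary
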
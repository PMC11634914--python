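"""Synthetic case-cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
cohort of rare, (by default) heterozygous variants whose case carrier
counts are drawn under planted allelic odds ratios against reference-
population frequencies, predictor scores drawn from class-conditional
distributions that differ between planted-causal and benign variants, and
an interaction network with a planted heart-enhanced connection bias.

The carrier model multiplies odds: odds_case = OR x odds(pop_af), and the
carrier count is Binomial(2*n_cases, f_case) with f_case the implied case
allele frequency — so the estimand of the downstream odds-ratio estimator
equals the planted OR exactly, making parameter-recovery tests unbiased by
construction.  Draws exceeding n_cases are rejected and resampled to keep
every carrier heterozygous (a config switch admits homozygotes for stress
tests).

One global seed feeds named substreams (variants, carriers, scores,
network) through ``numpy.random.SeedSequence``, so adding a stream never
perturbs another, and identical (config, seed) yields byte-identical
output bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biochem_profile import _ONE_TO_THREE

BASES = ("A", "C", "G", "T")
_AA20 = [a for a in _ONE_TO_THREE if a != "Ter"]


class ConfigError(ValueError):
    """The simulation config is infeasible; raised before any file is written."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults mirror the real analysis setting: 127 sequenced cases, rare
    variants (population MAF in (0.0005, 0.0045), safely under the 0.005
    rarity bar even after per-source count rounding), a regional frequency
    panel of 2654 alleles and a national one of 25000, and planted allelic
    odds ratios drawn log-uniformly from (2, 20) for the causal fraction.
    """

    n_cases: int = 127
    n_variants: int = 100
    causal_fraction: float = 0.2
    or_range: tuple[float, float] = (2.0, 20.0)
    pop_af_range: tuple[float, float] = (0.0005, 0.0045)
    source_an: dict = field(default_factory=lambda: {"finrisk": 2654, "gnomad_fin": 25000})
    source_missingness: dict = field(default_factory=lambda: {"finrisk": 0.1, "gnomad_fin": 0.0})
    nonsense_fraction: float = 0.05
    allow_homozygotes: bool = False
    network_size: int = 300
    heart_fraction: float = 0.3
    edge_prob: float = 0.05
    heart_enhanced_bias: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_variants < 0:
            raise ConfigError("n_cases must be positive, n_variants non-negative")
        if not (0.0 <= self.causal_fraction <= 1.0):
            raise ConfigError("causal_fraction must lie in [0, 1]")
        lo, hi = self.or_range
        if lo <= 1.0 or hi < lo:
            raise ConfigError("or_range must satisfy 1 < low <= high")
        alo, ahi = self.pop_af_range
        if not (0.0 < alo <= ahi < 0.005):
            raise ConfigError("pop_af_range must lie within (0, 0.005)")
        if any(an < 2 for an in self.source_an.values()):
            raise ConfigError("source allele numbers must be >= 2")
        if not (0.0 <= self.edge_prob <= 1.0) or self.heart_enhanced_bias < 0:
            raise ConfigError("edge_prob in [0,1]; heart_enhanced_bias >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["or_range"] = list(d["or_range"])
        d["pop_af_range"] = list(d["pop_af_range"])
        return d

    def content_hash(self) -> str:
        raw = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(raw).hexdigest()[:16]


@dataclass
class TruthManifest:
    """Ground truth for every generated entity, keyed by id."""

    variants: pd.DataFrame     # variant_id, gene, is_causal, true_or, true_pop_af
    genes: pd.DataFrame        # gene, heart_enhanced, matrisome_division
    seed: int
    config_hash: str

    def write(self, path) -> None:
        self.variants.to_csv(path, sep="\t", index=False)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ("variants", "carriers", "scores", "network")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def case_allele_frequency(true_or: float, pop_af: float) -> float:
    """Invert the odds-multiplication model: f_case from OR and pop AF."""
    odds = true_or * pop_af / (1.0 - pop_af)
    return odds / (1.0 + odds)


def _draw_carrier_count(rng: np.random.Generator, n_chromosomes: int,
                        f_case: float, n_cases: int, allow_hom: bool) -> int:
    count = int(rng.binomial(n_chromosomes, f_case))
    if allow_hom:
        return count
    while count > n_cases:  # reject multi-allele draws: heterozygous-only cohort
        count = int(rng.binomial(n_chromosomes, f_case))
    return count


def _draw_predictions(rng: np.random.Generator, causal: bool, nonsense: bool) -> dict:
    """Class-conditional predictor scores.

    Causal variants look deleterious (SIFT D, PolyPhen-2 damaging, CADD
    ~N(28,3), Varity/MutScore ~Beta(8,2)); benign ones are diffuse (mixed
    calls, CADD ~N(14,5) clipped at 0, scores ~Beta(2,8)).
    """
    if causal:
        sift = "D" if rng.random() < 0.95 else "T"
        pp2 = rng.choice(["PD", "PoD", "B"], p=[0.80, 0.15, 0.05])
        cadd = max(0.0, rng.normal(28.0, 3.0))
        mt = "DC" if rng.random() < 0.95 else "P"
        vr, ms = rng.beta(8, 2), rng.beta(8, 2)
    else:
        sift = "T" if rng.random() < 0.70 else "D"
        pp2 = rng.choice(["B", "PoD", "PD"], p=[0.60, 0.25, 0.15])
        cadd = max(0.0, rng.normal(14.0, 5.0))
        mt = "P" if rng.random() < 0.85 else "DC"
        vr, ms = rng.beta(2, 8), rng.beta(2, 8)
    if nonsense:
        # stop gains carry no missense-predictor scores
        return {"sift": "NA", "polyphen2": "NA", "cadd": round(cadd + 10.0, 1),
                "mutation_taster": mt, "varity_r": "NA", "mutscore": "NA"}
    return {"sift": sift, "polyphen2": pp2, "cadd": round(cadd, 1),
            "mutation_taster": mt,
            "varity_r": round(float(vr), 3), "mutscore": round(float(ms), 3)}


def generate_cohort(config: SimulationConfig, outdir) -> tuple[dict, TruthManifest]:
    """Write variants.tsv / frequencies.tsv / truth_manifest.tsv / config.yaml.

    Returns (paths, manifest).  Every generated file passes the io_formats
    readers' validation; every variant appears in the manifest exactly once.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rngs = _substreams(config.seed)
    rv, rc, rs = rngs["variants"], rngs["carriers"], rngs["scores"]
    case_ids = [f"case{i:03d}" for i in range(1, config.n_cases + 1)]
    sources = list(config.source_an)

    variant_rows, freq_rows, truth_rows = [], [], []
    for i in range(config.n_variants):
        vid = f"var{i:04d}"
        gene = f"GENE{i:04d}"
        causal = bool(rv.random() < config.causal_fraction)
        lo, hi = config.or_range
        true_or = float(np.exp(rv.uniform(np.log(lo), np.log(hi)))) if causal else 1.0
        true_af = float(rv.uniform(*config.pop_af_range))
        nonsense = bool(rv.random() < config.nonsense_fraction)

        chrom = str(rv.integers(1, 23))
        pos = int(rv.integers(1, 50_000_000))
        ref = str(rv.choice(BASES))
        alt = str(rv.choice([b for b in BASES if b != ref]))
        aa_pos = int(rv.integers(2, 800))
        ref_aa = str(rv.choice(_AA20))
        if nonsense:
            alt_aa3 = "Ter"
        else:
            alt_aa3 = _ONE_TO_THREE[str(rv.choice([a for a in _AA20 if a != ref_aa]))]
        protein_change = f"p.{_ONE_TO_THREE[ref_aa]}{aa_pos}{alt_aa3}"

        f_case = case_allele_frequency(true_or, true_af)
        count = _draw_carrier_count(rc, 2 * config.n_cases, f_case,
                                    config.n_cases, config.allow_homozygotes)
        n_hom = max(0, count - config.n_cases)
        n_het = count - 2 * n_hom
        chosen = list(rc.choice(case_ids, size=n_het + n_hom, replace=False)) if count else []
        carriers = ",".join(
            sorted([f"{c}:hom" for c in chosen[:n_hom]] + chosen[n_hom:]))

        preds = _draw_predictions(rs, causal, nonsense)
        variant_rows.append({
            "variant_id": vid, "gene": gene, "chrom": chrom, "pos": pos,
            "ref": ref, "alt": alt, "rsid": "NA",
            "consequence": "nonsense" if nonsense else "missense",
            "cdna_change": f"c.{3 * aa_pos}{ref}>{alt}",
            "protein_change": protein_change, "carriers": carriers, **preds,
        })
        frow = {"variant_id": vid}
        for s in sources:
            an = config.source_an[s]
            if rs.random() < config.source_missingness.get(s, 0.0):
                frow[f"{s}_af"], frow[f"{s}_an"] = "NA", an
            else:
                frow[f"{s}_af"] = repr(round(true_af * an) / an)
                frow[f"{s}_an"] = an
        freq_rows.append(frow)
        truth_rows.append({"variant_id": vid, "gene": gene, "is_causal": int(causal),
                           "true_or": round(true_or, 6), "true_pop_af": round(true_af, 8),
                           "n_carriers": (n_het + n_hom)})

    paths = {
        "variants": outdir / "variants.tsv",
        "frequencies": outdir / "frequencies.tsv",
        "truth": outdir / "truth_manifest.tsv",
        "config": outdir / "config.yaml",
    }
    freq_cols = ["variant_id"] + [c for s in sources for c in (f"{s}_af", f"{s}_an")]
    pd.DataFrame(variant_rows).to_csv(paths["variants"], sep="\t", index=False)
    pd.DataFrame(freq_rows, columns=freq_cols).to_csv(paths["frequencies"], sep="\t", index=False)
    manifest = TruthManifest(
        variants=pd.DataFrame(truth_rows),
        genes=pd.DataFrame(columns=["gene", "heart_enhanced", "matrisome_division"]),
        seed=config.seed, config_hash=config.content_hash(),
    )
    manifest.write(paths["truth"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump({"config": config.to_dict(), "hash": config.content_hash()},
                       fh, sort_keys=True)
    return paths, manifest


def generate_network(config: SimulationConfig, query_genes: list[str], outdir) -> tuple[dict, pd.DataFrame]:
    """Write biogrid.tsv / pairs.tsv / staining.tsv / matrisome.tsv.

    Background proteins are flagged heart-enhanced with probability
    ``heart_fraction``; each (background, query) pair becomes an edge with
    probability ``edge_prob``, multiplied by ``heart_enhanced_bias`` for
    heart-enhanced backgrounds (capped at 1).  BioGRID edges are written as
    two rows with distinct publication ids so they qualify as
    multi-validated downstream.  Returns (paths, gene-truth frame).
    """
    queries = [q.strip().upper() for q in query_genes]
    if config.network_size < len(queries):
        raise ConfigError("network_size smaller than the query set")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _substreams(config.seed)["network"]
    n_bg = config.network_size
    background = [f"PROT{i:04d}" for i in range(1, n_bg + 1)]
    heart = rng.random(n_bg) < config.heart_fraction
    p_edge_heart = min(1.0, config.edge_prob * config.heart_enhanced_bias)

    bg_rows = []
    for j, prot in enumerate(background):
        p = p_edge_heart if heart[j] else config.edge_prob
        for q in queries:
            if rng.random() < p:
                for pub in ("PUB1", "PUB2"):
                    bg_rows.append({"symbol_a": q, "symbol_b": prot,
                                    "experimental_system_type": "physical",
                                    "publication": f"{pub}_{q}_{prot}"})
    divisions = ["core_matrisome", "matrisome_associated", "non_matrisome"]
    categories = {"core_matrisome": ["collagens", "ecm_glycoproteins", "basement_membrane"],
                  "matrisome_associated": ["ecm_regulators", "secreted_factors", "ecm_affiliated"]}
    gene_rows, stain_rows, mat_rows = [], [], []
    for j, prot in enumerate(background):
        division = str(rng.choice(divisions, p=[0.15, 0.25, 0.60]))
        category = str(rng.choice(categories[division])) if division in categories else "none"
        staining = (str(rng.choice(["high", "medium"])) if heart[j]
                    else str(rng.choice(["low", "not_detected"])))
        stain_rows.append({"gene": prot, "cardiomyocyte_staining": staining})
        if division != "non_matrisome":
            mat_rows.append({"gene": prot, "division": division, "category": category})
        gene_rows.append({"gene": prot, "heart_enhanced": int(heart[j]),
                          "matrisome_division": division})
    paths = {
        "biogrid": outdir / "biogrid.tsv",
        "pairs": outdir / "pairs.tsv",
        "staining": outdir / "staining.tsv",
        "matrisome": outdir / "matrisome.tsv",
    }
    pd.DataFrame(bg_rows, columns=["symbol_a", "symbol_b", "experimental_system_type",
                                   "publication"]).to_csv(paths["biogrid"], sep="\t", index=False)
    pd.DataFrame(columns=[0, 1]).to_csv(paths["pairs"], sep="\t", index=False, header=False)
    pd.DataFrame(stain_rows).to_csv(paths["staining"], sep="\t", index=False)
    pd.DataFrame(mat_rows, columns=["gene", "division", "category"]).to_csv(
        paths["matrisome"], sep="\t", index=False)
    return paths, pd.DataFrame(gene_rows)
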
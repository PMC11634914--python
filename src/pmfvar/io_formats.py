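"""Typed records and TSV readers/writers for every file the pipeline touches.

All external files are flat, tab-separated UTF-8 tables with documented
headers (see README).  Parsing is total: every input row is either converted
into a typed record or produces a counted, logged diagnostic — never a
silent drop.  Missingness is always the literal ``NA`` or an empty cell, and
is carried through as an explicit state, never as 0.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("pmfvar")

NA_STRINGS = {"", "NA", "na", "NaN", "nan", "."}

# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    INDEL = "indel"
    OTHER = "other"


class Sift(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    MISSING = "missing"


class PolyPhen2(str, enum.Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    MISSING = "missing"


class MutationTaster(str, enum.Enum):
    DISEASE_CAUSING = "disease_causing"
    POLYMORPHISM = "polymorphism"
    MISSING = "missing"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"


class MatrisomeDivision(str, enum.Enum):
    CORE = "core_matrisome"
    ASSOCIATED = "matrisome_associated"
    NON_MATRISOME = "non_matrisome"


class Staining(str, enum.Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"
    NOT_DETECTED = "not_detected"
    MISSING = "missing"


class InteractionSource(str, enum.Enum):
    BIOGRID = "biogrid"
    HURI = "huri"
    OTHER = "other"


# Accepted spellings in input files (wANNOVAR-style one-letter codes and
# full words); anything else maps to MISSING with a warning.
_SIFT_ALIASES = {
    "D": Sift.DELETERIOUS, "deleterious": Sift.DELETERIOUS,
    "T": Sift.TOLERATED, "tolerated": Sift.TOLERATED,
}
_PP2_ALIASES = {
    "PD": PolyPhen2.PROBABLY_DAMAGING, "probably_damaging": PolyPhen2.PROBABLY_DAMAGING,
    "PoD": PolyPhen2.POSSIBLY_DAMAGING, "possibly_damaging": PolyPhen2.POSSIBLY_DAMAGING,
    "B": PolyPhen2.BENIGN, "benign": PolyPhen2.BENIGN,
}
_MT_ALIASES = {
    "DC": MutationTaster.DISEASE_CAUSING, "disease_causing": MutationTaster.DISEASE_CAUSING,
    "P": MutationTaster.POLYMORPHISM, "polymorphism": MutationTaster.POLYMORPHISM,
}


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


class SchemaError(ValueError):
    """A file does not match its declared schema."""


class RowParseError(ValueError):
    """A single data row could not be converted; carries the row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant: where it is, what it changes, who carries it."""

    variant_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None
    consequence: Consequence
    cdna_change: str
    protein_change: str
    carrier_cases: frozenset[str]
    zygosity: dict[str, Zygosity] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref == alt")
        if self.protein_change.endswith("Ter") and self.consequence is not Consequence.NONSENSE:
            raise ValueError(
                f"{self.variant_id}: protein change {self.protein_change!r} "
                f"implies a stop gain but consequence is {self.consequence.value}"
            )

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_cases)

    @property
    def alt_allele_count(self) -> int:
        """Alternate alleles carried in the cohort (het = 1, hom = 2)."""
        return sum(
            2 if self.zygosity.get(c, Zygosity.HET) is Zygosity.HOM else 1
            for c in self.carrier_cases
        )


@dataclass(frozen=True)
class PredictionProfile:
    """In-silico deleteriousness annotations for one variant.

    Missing is an explicit state: a predictor the annotator did not run is
    never conflated with a benign call.
    """

    sift: Sift = Sift.MISSING
    polyphen2: PolyPhen2 = PolyPhen2.MISSING
    cadd: float | None = None
    mutation_taster: MutationTaster = MutationTaster.MISSING
    varity_r: float | None = None
    mutscore: float | None = None

    def __post_init__(self):
        if self.cadd is not None and self.cadd < 0:
            raise ValueError("CADD is PHRED-scaled and non-negative")
        for name in ("varity_r", "mutscore"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class FrequencyPanel:
    """Per-variant allele frequencies from ordered population sources.

    ``sources`` maps source name -> (allele_frequency | None, allele_number
    | None); insertion order is the precedence order used downstream.
    """

    variant_id: str
    sources: dict[str, tuple[float | None, int | None]]

    def __post_init__(self):
        for src, (af, an) in self.sources.items():
            if af is not None and not (0.0 <= af < 1.0):
                raise ValueError(f"{self.variant_id}/{src}: frequency {af} outside [0, 1)")
            if an is not None and an <= 0:
                raise ValueError(f"{self.variant_id}/{src}: allele number must be positive")

    def non_missing(self) -> dict[str, tuple[float, int | None]]:
        return {s: (af, an) for s, (af, an) in self.sources.items() if af is not None}


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    matrisome_division: MatrisomeDivision = MatrisomeDivision.NON_MATRISOME
    matrisome_category: str = "none"
    cardiomyocyte_staining: Staining = Staining.MISSING
    functional_class: str = ""

    def __post_init__(self):
        in_matrisome = self.matrisome_division is not MatrisomeDivision.NON_MATRISOME
        if in_matrisome == (self.matrisome_category == "none"):
            raise ValueError(
                f"{self.gene}: matrisome_category 'none' iff division is non_matrisome"
            )


@dataclass(frozen=True)
class InteractionEdge:
    """One undirected protein-protein interaction, canonically ordered."""

    protein_a: str
    protein_b: str
    source: InteractionSource
    experimental_system_type: str  # "physical" | "genetic" | "missing"
    n_supporting_publications: int = 0

    @staticmethod
    def make(a: str, b: str, source: InteractionSource,
             system_type: str = "missing", n_pubs: int = 0) -> "InteractionEdge":
        a, b = a.strip().upper(), b.strip().upper()
        if a > b:
            a, b = b, a
        return InteractionEdge(a, b, source, system_type, n_pubs)

    @property
    def is_self_loop(self) -> bool:
        return self.protein_a == self.protein_b


@dataclass(frozen=True)
class PtmSite:
    protein: str
    position: int
    ptm_type: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("PTM residue position is 1-based")


@dataclass(frozen=True)
class DomainInterval:
    protein: str
    domain_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.domain_id}: need 1 <= start <= end")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------


def _is_na(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return True
    return str(value).strip() in NA_STRINGS


def _opt_float(value, what: str, row_index: int) -> float | None:
    if _is_na(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowParseError(row_index, f"non-numeric {what}: {value!r}") from None


def _enum_or_missing(value, aliases: dict, missing, what: str):
    if _is_na(value):
        return missing
    token = str(value).strip()
    if token in aliases:
        return aliases[token]
    logger.warning("unknown %s string %r mapped to missing", what, token)
    return missing


def infer_consequence(raw: str | None, protein_change: str) -> Consequence:
    """Resolve the consequence class, trusting the protein-level notation.

    A ``Ter`` suffix always wins (stop gain), matching the HGVS convention.
    """
    if protein_change.endswith("Ter"):
        return Consequence.NONSENSE
    if raw is None or _is_na(raw):
        return Consequence.OTHER
    token = str(raw).strip().lower()
    aliases = {
        "missense": Consequence.MISSENSE, "missense_variant": Consequence.MISSENSE,
        "nonsense": Consequence.NONSENSE, "stop_gained": Consequence.NONSENSE,
        "indel": Consequence.INDEL, "frameshift": Consequence.INDEL,
        "inframe_indel": Consequence.INDEL,
    }
    return aliases.get(token, Consequence.OTHER)


def parse_carriers(cell: str, row_index: int = -1) -> tuple[frozenset[str], dict[str, Zygosity]]:
    """Parse a ``id[,id...]`` carrier list; a ``:hom`` suffix marks homozygotes."""
    if _is_na(cell):
        return frozenset(), {}
    carriers: set[str] = set()
    zygosity: dict[str, Zygosity] = {}
    for token in str(cell).split(","):
        token = token.strip()
        if not token:
            continue
        if ":" in token:
            case_id, zyg = token.split(":", 1)
            case_id = case_id.strip()
            try:
                zygosity[case_id] = Zygosity(zyg.strip().lower())
            except ValueError:
                raise RowParseError(row_index, f"unknown zygosity {zyg!r}") from None
        else:
            case_id = token
            zygosity[case_id] = Zygosity.HET
        carriers.add(case_id)
    return frozenset(carriers), zygosity


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "variant_id", "gene", "chrom", "pos", "ref", "alt", "rsid", "consequence",
    "cdna_change", "protein_change", "carriers", "sift", "polyphen2", "cadd",
    "mutation_taster", "varity_r", "mutscore",
]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return df


def read_variant_table(path, schema_version: str = "1") -> list[tuple[VariantRecord, PredictionProfile]]:
    """Read an annotated variant table into typed records.

    One row per variant; row count is preserved (every row converts or the
    reader raises naming the offending row).
    """
    if schema_version != "1":
        raise SchemaError(f"unknown variant-table schema version {schema_version!r}")
    df = _read_tsv(path, VARIANT_COLUMNS)
    out: list[tuple[VariantRecord, PredictionProfile]] = []
    for i, row in df.iterrows():
        carriers, zyg = parse_carriers(row["carriers"], i)
        cadd = _opt_float(row["cadd"], "CADD", i)
        profile = PredictionProfile(
            sift=_enum_or_missing(row["sift"], _SIFT_ALIASES, Sift.MISSING, "SIFT"),
            polyphen2=_enum_or_missing(row["polyphen2"], _PP2_ALIASES, PolyPhen2.MISSING, "PolyPhen-2"),
            cadd=cadd,
            mutation_taster=_enum_or_missing(
                row["mutation_taster"], _MT_ALIASES, MutationTaster.MISSING, "MutationTaster"),
            varity_r=_opt_float(row["varity_r"], "Varity_R", i),
            mutscore=_opt_float(row["mutscore"], "MutScore", i),
        )
        try:
            pos = int(row["pos"])
        except ValueError:
            raise RowParseError(i, f"non-integer position {row['pos']!r}") from None
        record = VariantRecord(
            variant_id=row["variant_id"],
            gene=row["gene"].strip(),
            chrom=str(row["chrom"]),
            pos=pos,
            ref=row["ref"],
            alt=row["alt"],
            rsid=None if _is_na(row["rsid"]) else row["rsid"],
            consequence=infer_consequence(row["consequence"], row["protein_change"]),
            cdna_change=row["cdna_change"],
            protein_change=row["protein_change"],
            carrier_cases=carriers,
            zygosity=zyg,
        )
        out.append((record, profile))
    return out


def read_frequency_panel(path, source_order: list[str]) -> dict[str, FrequencyPanel]:
    """Read per-source allele frequencies; missingness stays explicit.

    Expects columns ``variant_id`` then ``<source>_af`` / ``<source>_an``
    pairs for every source in ``source_order`` (precedence order).
    """
    required = ["variant_id"] + [f"{s}_af" for s in source_order]
    df = _read_tsv(path, required)
    dupes = df["variant_id"][df["variant_id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"{path}: duplicate variant_id(s) {sorted(set(dupes))}")
    panels: dict[str, FrequencyPanel] = {}
    for i, row in df.iterrows():
        sources: dict[str, tuple[float | None, int | None]] = {}
        for s in source_order:
            af = _opt_float(row[f"{s}_af"], f"{s} frequency", i)
            an_cell = row.get(f"{s}_an")
            an = None
            if an_cell is not None and not _is_na(an_cell):
                an = int(float(an_cell))
            sources[s] = (af, an)
        panels[row["variant_id"]] = FrequencyPanel(row["variant_id"], sources)
    return panels


def read_interaction_files(biogrid_path, pairlist_path) -> list[InteractionEdge]:
    """Read a BioGRID-TAB3-like table and a two-column pair list.

    BioGRID rows for the same (unordered) pair are aggregated, counting
    distinct publication identifiers; pair-list edges are tagged as
    reference-interactome (physical by construction, single-publication).
    Self-pairs are retained here and flagged downstream.
    """
    bg = _read_tsv(biogrid_path, ["symbol_a", "symbol_b", "experimental_system_type", "publication"])
    skipped = 0
    pubs: dict[tuple[str, str, str], set[str]] = {}
    for _, row in bg.iterrows():
        a, b = str(row["symbol_a"]).strip(), str(row["symbol_b"]).strip()
        if not a or not b or _is_na(a) or _is_na(b):
            skipped += 1
            continue
        system = str(row["experimental_system_type"]).strip().lower()
        if system not in ("physical", "genetic"):
            system = "missing"
        a, b = a.upper(), b.upper()
        key = (min(a, b), max(a, b), system)
        pubs.setdefault(key, set()).add(str(row["publication"]).strip())
    if skipped:
        logger.warning("skipped %d malformed interaction row(s)", skipped)
    edges = [
        InteractionEdge(a, b, InteractionSource.BIOGRID, system, len(ids))
        for (a, b, system), ids in pubs.items()
    ]
    try:
        pl = pd.read_csv(pairlist_path, sep="\t", dtype=str, keep_default_na=False, header=None)
    except pd.errors.EmptyDataError:
        return edges
    if pl.shape[1] < 2:
        raise SchemaError(f"{pairlist_path}: pair list needs two columns")
    for _, row in pl.iterrows():
        a, b = str(row[0]).strip(), str(row[1]).strip()
        if not a or not b:
            skipped += 1
            continue
        edges.append(InteractionEdge.make(a, b, InteractionSource.HURI, "physical", 1))
    return edges


def read_gene_annotations(matrisome_path, staining_path, genes_path=None) -> dict[str, GeneAnnotation]:
    """Join matrisome membership, staining and (optional) literature class tables."""
    mat = _read_tsv(matrisome_path, ["gene", "division", "category"])
    stain = _read_tsv(staining_path, ["gene", "cardiomyocyte_staining"])
    classes: dict[str, str] = {}
    if genes_path is not None:
        g = _read_tsv(genes_path, ["gene", "functional_class"])
        classes = dict(zip(g["gene"].str.upper(), g["functional_class"]))
    division = {
        r["gene"].upper(): (MatrisomeDivision(r["division"]), r["category"])
        for _, r in mat.iterrows()
    }
    staining = {}
    for _, r in stain.iterrows():
        cell = r["cardiomyocyte_staining"].strip().lower()
        staining[r["gene"].upper()] = Staining(cell) if cell in Staining._value2member_map_ else Staining.MISSING
    out: dict[str, GeneAnnotation] = {}
    for gene in set(division) | set(staining) | set(classes):
        div, cat = division.get(gene, (MatrisomeDivision.NON_MATRISOME, "none"))
        out[gene] = GeneAnnotation(
            gene=gene,
            matrisome_division=div,
            matrisome_category=cat,
            cardiomyocyte_staining=staining.get(gene, Staining.MISSING),
            functional_class=classes.get(gene, ""),
        )
    return out


def read_ptm_table(path) -> list[PtmSite]:
    df = _read_tsv(path, ["protein", "position", "ptm_type"])
    return [
        PtmSite(r["protein"].upper(), int(r["position"]), r["ptm_type"])
        for _, r in df.iterrows()
    ]


def read_domain_table(path) -> list[DomainInterval]:
    df = _read_tsv(path, ["protein", "domain_id", "start", "end"])
    return [
        DomainInterval(r["protein"].upper(), r["domain_id"], int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    ]


def read_clinvar_table(path) -> pd.DataFrame:
    """Optional ClinVar-like pathogenicity table (variant_id, rsid, gene,
    chrom, pos, ref, alt, clinical_significance)."""
    return _read_tsv(path, ["gene", "chrom", "pos", "ref", "alt", "clinical_significance"])


# ---------------------------------------------------------------------------
# Results formatting (mirrors the published summary-table layout)
# ---------------------------------------------------------------------------


def format_p(p: float) -> str:
    """P to 3 decimals, 4 when below 0.001 (scientific below 1e-4)."""
    if p < 1e-4:
        return f"{p:.1e}"
    if p < 0.001:
        return f"{p:.4f}"
    return f"{p:.3f}"


RESULTS_COLUMNS = [
    "variant_id", "gene", "protein_change", "rsid", "or", "ci_low", "ci_high",
    "p", "p_adjusted", "significant", "tier", "frequency_source_used",
]


def write_results_table(results, path) -> None:
    """Write association results as TSV, OR/CI to 2 decimals, P to 3 (4 if
    < 0.001); empty input yields a header-only file. Tier flag is the
    underline marker (Varity_R or MutScore > 0.7)."""
    rows = []
    for r in results:
        rows.append({
            "variant_id": r.variant_id,
            "gene": r.gene,
            "protein_change": r.protein_change,
            "rsid": r.rsid or "NA",
            "or": f"{r.or_estimate:.2f}",
            "ci_low": f"{r.ci_low:.2f}",
            "ci_high": f"{r.ci_high:.2f}",
            "p": format_p(r.p_value),
            "p_adjusted": format_p(r.p_adjusted),
            "significant": int(r.significant),
            "tier": int(r.tier),
            "frequency_source_used": r.frequency_source_used,
        })
    pd.DataFrame(rows, columns=RESULTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    df = _read_tsv(path, RESULTS_COLUMNS)
    for col in ("or", "ci_low", "ci_high", "p", "p_adjusted"):
        df[col] = df[col].astype(float)
    for col in ("significant", "tier"):
        df[col] = df[col].astype(int)
    return df
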
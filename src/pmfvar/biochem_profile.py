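"""Nucleotide- and protein-level characterization of candidate variants.

Each candidate is profiled on four axes: transition/transversion class of
the nucleotide substitution; amino-acid class change along chemical
(aliphatic / aromatic / neutral / acidic / basic / unique), electrical
dipole, and residue-size axes; overlap with known post-translational
modification sites; and the Pfam-style domain containing the mutated
residue, if any.

The residue class assignments ship as an editable, versioned data table
(``data/aa_classes.tsv``) rather than code: the class vocabulary is
standard but the exact partition of the 20 residues is a curation choice,
so it is kept swappable.  Defaults: unique = {C, G, P} (disulfide bonds,
backbone flexibility, ring constraint), acidic = {D, E}, basic = {H, K, R},
aromatic = {F, W, Y}, aliphatic = {A, I, L, V, M}, neutral = {S, T, N, Q};
size classes cut residue van-der-Waals volume (A^3) at <120 (small),
120-170 (medium), >170 (large); dipole classes are ordinal
low/moderate/high (nonpolar, polar-uncharged, charged).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io_formats import DomainInterval, PtmSite

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "Ter",
}

_PROTEIN_CHANGE_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


@dataclass(frozen=True)
class AminoAcidClasses:
    chemical: str
    dipole: str
    volume: float
    size: str


class AminoAcidClassTable:
    """Per-residue chemical/dipole/size classes, loaded from the shipped TSV."""

    def __init__(self, frame: pd.DataFrame):
        expected = sorted(a for a in THREE_TO_ONE.values() if a != "Ter")
        if sorted(frame["aa"]) != expected:
            raise ValueError("amino-acid class table must cover exactly the 20 residues")
        self._table = {
            r["aa"]: AminoAcidClasses(r["chemical_class"], r["dipole_class"],
                                      float(r["volume"]), r["size_class"])
            for _, r in frame.iterrows()
        }

    def __getitem__(self, aa: str) -> AminoAcidClasses:
        return self._table[aa]

    def __contains__(self, aa: str) -> bool:
        return aa in self._table


def load_aa_class_table() -> AminoAcidClassTable:
    with resources.files("pmfvar.data").joinpath("aa_classes.tsv").open() as fh:
        return AminoAcidClassTable(pd.read_csv(fh, sep="\t"))


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs
    transversion; multi-base alleles are not_applicable."""
    ref, alt = ref_base.upper(), alt_base.upper()
    valid = PURINES | PYRIMIDINES
    if len(ref) != 1 or len(alt) != 1 or ref not in valid or alt not in valid:
        return "not_applicable"
    pair = {ref, alt}
    if pair <= PURINES or pair <= PYRIMIDINES:
        return "transition"
    return "transversion"


def parse_protein_change(protein_change: str) -> tuple[str, int, str]:
    """Parse ``p.Arg153Cys``-style notation to (one-letter ref, position,
    one-letter alt); ``Ter`` is preserved as-is."""
    m = _PROTEIN_CHANGE_RE.match(protein_change.strip())
    if not m:
        raise ValueError(f"unparseable protein change: {protein_change!r}")
    ref3, pos, alt3 = m.groups()
    for token in (ref3, alt3):
        if token not in THREE_TO_ONE:
            raise ValueError(f"unknown residue token {token!r} in {protein_change!r}")
    return THREE_TO_ONE[ref3], int(pos), THREE_TO_ONE[alt3]


_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def format_protein_change(ref_aa: str, position: int, alt_aa: str) -> str:
    return f"p.{_ONE_TO_THREE[ref_aa]}{position}{_ONE_TO_THREE[alt_aa]}"


@dataclass(frozen=True)
class ClassChange:
    axis: str
    from_class: str
    to_class: str

    @property
    def changed(self) -> bool:
        return self.from_class != self.to_class


def profile_aa_change(ref_aa: str, alt_aa: str,
                      class_table: AminoAcidClassTable) -> tuple[ClassChange, ClassChange, ClassChange]:
    """(chemical, dipole, size) class-change triple for a missense swap.

    Stop gains carry no residue classes and are rejected here; callers mark
    those axes unavailable instead.
    """
    for aa in (ref_aa, alt_aa):
        if aa not in class_table:
            raise ValueError(f"no amino-acid classes for {aa!r} (stop gain?)")
    r, a = class_table[ref_aa], class_table[alt_aa]
    return (
        ClassChange("chemical", r.chemical, a.chemical),
        ClassChange("dipole", r.dipole, a.dipole),
        ClassChange("size", r.size, a.size),
    )


def scan_ptm(protein: str, position: int, ptm_table: list[PtmSite],
             window: int = 0) -> list[PtmSite]:
    """Known PTM sites at the mutated residue (exact position by default;
    a window admits sites within +-window residues for sensitivity runs)."""
    protein = protein.upper()
    return [
        s for s in ptm_table
        if s.protein == protein and abs(s.position - position) <= window
    ]


def map_domain(protein: str, position: int,
               domain_table: list[DomainInterval]) -> DomainInterval | None:
    """Pfam-style domain of origin: the interval containing the residue
    (1-based inclusive); overlaps resolve deterministically to the smallest
    start, with a log note."""
    protein = protein.upper()
    hits = sorted(
        (d for d in domain_table if d.protein == protein and d.contains(position)),
        key=lambda d: (d.start, d.end, d.domain_id),
    )
    if not hits:
        return None
    if len(hits) > 1:
        import logging
        logging.getLogger("pmfvar").info(
            "%s position %d in %d overlapping domains; keeping %s",
            protein, position, len(hits), hits[0].domain_id)
    return hits[0]


@dataclass
class SubstitutionProfile:
    variant_id: str
    gene: str
    nt_class: str
    ref_aa: str | None
    alt_aa: str | None
    chem_change: ClassChange | None
    dipole_change: ClassChange | None
    size_change: ClassChange | None
    ptm_hits: list[PtmSite]
    domain: DomainInterval | None


def profile_variants(candidates, ptm_table: list[PtmSite],
                     domain_table: list[DomainInterval],
                     class_table: AminoAcidClassTable | None = None,
                     ptm_window: int = 0) -> list[SubstitutionProfile]:
    """Full per-candidate profile; nonsense variants get explicit
    unavailable markers on the amino-acid axes."""
    if class_table is None:
        class_table = load_aa_class_table()
    profiles = []
    for cand in candidates:
        v = cand.variant
        nt = classify_substitution(v.ref, v.alt)
        ref_aa = alt_aa = None
        chem = dip = size = None
        try:
            ref_aa, pos, alt_aa = parse_protein_change(v.protein_change)
        except ValueError:
            pos = None
        if ref_aa is not None and alt_aa in class_table and ref_aa in class_table:
            chem, dip, size = profile_aa_change(ref_aa, alt_aa, class_table)
        ptm_hits = scan_ptm(v.gene, pos, ptm_table, window=ptm_window) if pos else []
        domain = map_domain(v.gene, pos, domain_table) if pos else None
        profiles.append(SubstitutionProfile(
            variant_id=v.variant_id, gene=v.gene, nt_class=nt,
            ref_aa=ref_aa, alt_aa=alt_aa,
            chem_change=chem, dipole_change=dip, size_change=size,
            ptm_hits=ptm_hits, domain=domain,
        ))
    return profiles


def profiles_frame(profiles: list[SubstitutionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({
            "variant_id": p.variant_id,
            "gene": p.gene,
            "nt_class": p.nt_class,
            "ref_aa": p.ref_aa or "NA",
            "alt_aa": p.alt_aa or "NA",
            "chem_from": p.chem_change.from_class if p.chem_change else "NA",
            "chem_to": p.chem_change.to_class if p.chem_change else "NA",
            "dipole_from": p.dipole_change.from_class if p.dipole_change else "NA",
            "dipole_to": p.dipole_change.to_class if p.dipole_change else "NA",
            "size_from": p.size_change.from_class if p.size_change else "NA",
            "size_to": p.size_change.to_class if p.size_change else "NA",
            "n_ptm_hits": len(p.ptm_hits),
            "domain": p.domain.domain_id if p.domain else "NA",
        })
    return pd.DataFrame(rows)
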
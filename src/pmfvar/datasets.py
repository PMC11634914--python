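"""Bundled reference dataset: the published 22-variant PMF cohort summary.

``data/pmf_reference_table.tsv`` re-encodes the published summary table of
rare variants found by exome sequencing in 127 sudden-cardiac-death victims
with primary myocardial fibrosis: per variant, the gene, cDNA/protein
change, dbSNP id, allele frequencies in the national (gnomAD Finnish) and
regional (FINRISK, Northern Ostrobothnia) panels, carrier count among the
127 cases, predictor annotations (SIFT, PolyPhen-2, CADD, MutationTaster,
Varity_R, MutScore) and the published OR (95% CI), P and BH-adjusted P.

The loader can also re-express the table as pipeline input files.  Carrier
case IDs are not public, so the input view synthesizes deterministic
placeholder IDs (the counts are faithful, the identities are not); genomic
coordinates are likewise stand-ins parsed from the cDNA notation, carried
opaquely by the pipeline.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import pandas as pd

#: Precedence order of the population frequency sources: regional panel
#: first, national gnomAD-FIN as fallback.
SOURCE_ORDER = ["finrisk", "gnomad_fin"]

#: Cohort size of the reference study.
N_CASES = 127

_CDNA_RE = re.compile(r"^c\.(\d+)([ACGT]+)>([ACGT]+)$")


def load_reference_table() -> pd.DataFrame:
    """The 22-variant reference summary as a DataFrame (NA preserved)."""
    with resources.files("pmfvar.data").joinpath("pmf_reference_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def reference_input_files(outdir) -> dict[str, Path]:
    """Re-express the reference table as variants.tsv + frequencies.tsv.

    Carrier IDs are synthetic placeholders assigned round-robin over
    ``case001..case127`` so that per-variant carrier counts match the
    published table; cross-variant carrier overlap is NOT meaningful.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = load_reference_table()
    variant_rows, freq_rows = [], []
    cursor = 0
    for i, row in table.iterrows():
        m = _CDNA_RE.match(row["cdna_change"])
        if not m:
            raise ValueError(f"unparseable cDNA change {row['cdna_change']!r}")
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        n = int(row["n_carriers"])
        carriers = []
        for _ in range(n):
            carriers.append(f"case{(cursor % N_CASES) + 1:03d}")
            cursor += 1
        variant_rows.append({
            "variant_id": f"ref_{row['gene']}",
            "gene": row["gene"], "chrom": "un", "pos": pos,
            "ref": ref, "alt": alt, "rsid": row["rsid"],
            "consequence": "nonsense" if row["protein_change"].endswith("Ter") else "missense",
            "cdna_change": row["cdna_change"],
            "protein_change": row["protein_change"],
            "carriers": ",".join(carriers),
            "sift": row["sift"], "polyphen2": row["polyphen2"],
            "cadd": row["cadd"], "mutation_taster": row["mutation_taster"],
            "varity_r": row["varity_r"], "mutscore": row["mutscore"],
        })
        freq_rows.append({
            "variant_id": f"ref_{row['gene']}",
            "finrisk_af": row["finrisk_af"], "finrisk_an": 2654,
            "gnomad_fin_af": row["gnomad_fin_af"], "gnomad_fin_an": 25000,
        })
    paths = {"variants": outdir / "variants.tsv", "frequencies": outdir / "frequencies.tsv"}
    pd.DataFrame(variant_rows).to_csv(paths["variants"], sep="\t", index=False)
    pd.DataFrame(freq_rows).to_csv(paths["frequencies"], sep="\t", index=False)
    return paths
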
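"""Tab-separated readers and writers for the pipeline's on-disk formats.

Everything is plain TSV: count matrices (features x samples, first column =
feature id), gene metadata (gene, gc, length), fusion-call tables, MAF-like
variant tables, sample label files and two-column maps. VCF input is
supported through cyvcf2 with a user-provided INFO-key mapping.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import FUSION_COLUMNS, VARIANT_COLUMNS


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_fusion_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FUSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fusion table missing column(s): {', '.join(missing)}")
    return df


def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=True)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing column(s): {', '.join(missing)}")
    return df


#: default mapping from variant-table column to VCF INFO key
DEFAULT_VCF_INFO_MAP = {
    "alt_reads": "ALT_READS",
    "tumor_af": "TUMOR_AF",
    "pop_af_max": "POP_AF_MAX",
    "cadd_phred": "CADD_PHRED",
    "consequence": "CSQ_TERM",
    "variant_class": "VARIANT_CLASS",
    "impact": "IMPACT",
    "polyphen": "POLYPHEN",
    "sift": "SIFT",
    "condel": "CONDEL",
    "gene": "GENE",
    "protein_change": "HGVSP",
}


def read_variants_vcf(path, sample_id: str | None = None,
                      info_map: dict | None = None) -> pd.DataFrame:
    """Read an annotated single-sample VCF into the MAF-like table layout."""
    from cyvcf2 import VCF

    info_map = info_map or DEFAULT_VCF_INFO_MAP
    vcf = VCF(str(path))
    sid = sample_id or (vcf.samples[0] if vcf.samples else Path(str(path)).stem)
    rows = []
    for rec in vcf:
        row = {"sample_id": sid, "chrom": rec.CHROM, "pos": rec.POS,
               "ref": rec.REF, "alt": rec.ALT[0] if rec.ALT else ""}
        for col, key in info_map.items():
            row[col] = rec.INFO.get(key)
        rows.append(row)
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def read_labels(path) -> pd.Series:
    """Sample label file: sample_id <tab> subtype; 'unknown' or empty means
    unlabeled (NaN)."""
    df = pd.read_csv(path, sep="\t", header=0, names=["sample_id", "subtype"])
    labels = df.set_index("sample_id")["subtype"]
    return labels.mask(labels.str.lower() == "unknown")


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_gene_pairs(path) -> set[frozenset]:
    pairs = set()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 2:
                pairs.add(frozenset(parts[:2]))
    return pairs


def read_subtype_map(path) -> dict:
    """Subtype map config: either 'GENE<tab>label' (single partner) or
    'GENE5<tab>GENE3<tab>label' (ordered pair)."""
    mapping: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 2:
                mapping[parts[0]] = parts[1]
            elif len(parts) == 3:
                mapping[(parts[0], parts[1])] = parts[2]
    return mapping


def read_decay_constants(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=0, names=["gene", "decay_constant"])
    return df.set_index("gene")["decay_constant"]
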
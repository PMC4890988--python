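"""Readers and writers for the pipeline's plain-text formats.

Dialects: PLINK text .ped/.map genotypes, phased VCF or haplotype-TSV LD
panel, BED gene annotation (0-based half-open on disk, 1-based inclusive in
memory), genes x samples expression TSV with a separate groups TSV, GMT
pathway sets, and YAML configs. Writers and readers round-trip exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    GenotypeDataset,
    GeneAnnotation,
    GroundTruth,
    Pathway,
    PathwayCollection,
    ExpressionDataset,
    ReferencePanel,
)
from .errors import ParseError

MISSING_ALLELE = "0"

# ---------------------------------------------------------------------------
# PLINK text

def write_genotypes_plink_text(
    dataset: GenotypeDataset, ped_path: str, map_path: str
) -> None:
    snps = dataset.snps
    with open(map_path, "w") as fh:
        for _, row in snps.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}\n")
    minor = snps["allele_minor"].to_numpy()
    major = snps["allele_major"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(dataset.sample_ids):
            pheno = 2 if dataset.phenotypes[i] == 1 else 1
            fields = [sid, sid, "0", "0", "0", str(pheno)]
            row = dataset.calls[i]
            for j, code in enumerate(row):
                if code < 0:
                    fields.append(f"{MISSING_ALLELE} {MISSING_ALLELE}")
                elif code == 0:
                    fields.append(f"{major[j]} {major[j]}")
                elif code == 1:
                    fields.append(f"{minor[j]} {major[j]}")
                else:
                    fields.append(f"{minor[j]} {minor[j]}")
            fh.write("\t".join(fields) + "\n")


def read_genotypes_plink_text(ped_path: str, map_path: str) -> GenotypeDataset:
    """Parse .ped/.map; the minor allele is determined per SNP from the data.

    Phenotype column 6: 1 = control, 2 = case; anything else is an error with
    the offending line number. "0 0" is the missing genotype.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if len(parts) != 4:
                raise ParseError("expected 4 columns in .map", map_path, ln)
            map_rows.append((parts[0], parts[1], int(parts[3])))
    n_snps = len(map_rows)

    sample_ids: list[str] = []
    phenotypes: list[int] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            # tolerate space-separated .ped too
            if len(parts) < 6 + n_snps:
                parts = line.split()
                if len(parts) == 6 + 2 * n_snps:
                    parts = parts[:6] + [
                        f"{parts[6 + 2 * k]} {parts[7 + 2 * k]}" for k in range(n_snps)
                    ]
            if len(parts) != 6 + n_snps:
                raise ParseError(
                    f"ragged .ped row: {len(parts)} fields, expected {6 + n_snps}",
                    ped_path,
                    ln,
                )
            pheno = parts[5]
            if pheno not in ("1", "2"):
                raise ParseError(f"unknown phenotype code {pheno!r}", ped_path, ln)
            sample_ids.append(parts[1])
            phenotypes.append(1 if pheno == "2" else 0)
            row = []
            for k in range(n_snps):
                ab = parts[6 + k].split()
                if len(ab) != 2:
                    raise ParseError(
                        f"malformed genotype field {parts[6 + k]!r}", ped_path, ln
                    )
                row.append((ab[0], ab[1]))
            allele_rows.append(row)

    n_samples = len(sample_ids)
    calls = np.full((n_samples, n_snps), -1, dtype=np.int8)
    minor_alleles, major_alleles = [], []
    for j in range(n_snps):
        counts: dict[str, int] = {}
        for i in range(n_samples):
            for a in allele_rows[i][j]:
                if a != MISSING_ALLELE:
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ParseError(
                f"SNP {map_rows[j][1]} has >2 alleles: {sorted(counts)}", ped_path
            )
        if not counts:
            minor, major = "A", "G"
        elif len(counts) == 1:
            major = next(iter(counts))
            minor = "A" if major != "A" else "G"
        else:
            # rarer allele is minor; lexicographic tie-break for determinism
            (a1, c1), (a2, c2) = sorted(counts.items())
            minor, major = (a1, a2) if (c1, a1) <= (c2, a2) else (a2, a1)
        minor_alleles.append(minor)
        major_alleles.append(major)
        for i in range(n_samples):
            a, b = allele_rows[i][j]
            if a == MISSING_ALLELE or b == MISSING_ALLELE:
                calls[i, j] = -1
            else:
                calls[i, j] = (a == minor) + (b == minor)
    snps = pd.DataFrame(
        {
            "snp_id": [r[1] for r in map_rows],
            "chrom": [r[0] for r in map_rows],
            "pos": [r[2] for r in map_rows],
            "allele_minor": minor_alleles,
            "allele_major": major_alleles,
        }
    )
    return GenotypeDataset(
        sample_ids=sample_ids,
        phenotypes=np.array(phenotypes, dtype=np.int8),
        snps=snps,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Reference panel: phased VCF or haplotype TSV

def write_panel_vcf(panel: ReferencePanel, snps: pd.DataFrame, path: str) -> None:
    """Phased single-sample-per-individual VCF; ALT is the minor allele."""
    if not panel.phased:
        raise ValueError("VCF writer expects a phased panel")
    n_ind = panel.haplotypes.shape[0] // 2
    meta = snps.set_index("snp_id")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"P{i + 1:04d}" for i in range(n_ind))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, sid in enumerate(panel.snp_ids):
            row = meta.loc[sid]
            h = panel.haplotypes[:, j]
            gts = "\t".join(f"{h[2 * i]}|{h[2 * i + 1]}" for i in range(n_ind))
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{sid}\t{row['allele_major']}\t"
                f"{row['allele_minor']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_panel(path: str, study_snp_ids: list[str] | None = None) -> ReferencePanel:
    """Read a panel from phased VCF (via pysam) or from a haplotype TSV.

    Multi-allelic VCF records are skipped with a warning. When
    ``study_snp_ids`` is given and no panel SNP overlaps it, an error is
    raised (the panel would be useless for tagging).
    """
    panel = (
        _read_panel_vcf(path) if path.endswith((".vcf", ".vcf.gz")) else _read_panel_tsv(path)
    )
    if study_snp_ids is not None and not (set(panel.snp_ids) & set(study_snp_ids)):
        raise ParseError("panel shares no SNP id with the study data", path)
    return panel


def _read_panel_vcf(path: str) -> ReferencePanel:
    import pysam

    snp_ids: list[str] = []
    hap_cols: list[np.ndarray] = []
    phased = True
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot open VCF: {exc}", path) from exc
    with vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(
                    f"skipping multi-allelic record {rec.id or rec.pos} in {path}"
                )
                continue
            col = []
            for sample in rec.samples.values():
                gt = sample["GT"]
                if gt is None or any(a is None for a in gt) or len(gt) != 2:
                    raise ParseError(
                        f"malformed GT for record {rec.id or rec.pos}", path
                    )
                if not sample.phased:
                    phased = False
                col.extend(int(a) for a in gt)
            snp_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            hap_cols.append(np.array(col, dtype=np.int8))
    if not snp_ids:
        raise ParseError("VCF panel contains no usable biallelic record", path)
    hap = np.stack(hap_cols, axis=1)
    if not phased:  # collapse haplotype pairs to dosages
        hap = hap[0::2] + hap[1::2]
    return ReferencePanel(snp_ids=snp_ids, haplotypes=hap, phased=phased)


def write_panel_tsv(panel: ReferencePanel, path: str) -> None:
    """Haplotype TSV: snp_id column then one 0/1 column per haplotype."""
    cols = [f"H{i + 1:04d}" for i in range(panel.haplotypes.shape[0])]
    df = pd.DataFrame(panel.haplotypes.T, index=panel.snp_ids, columns=cols)
    df.index.name = "snp_id"
    df.to_csv(path, sep="\t")


def _read_panel_tsv(path: str) -> ReferencePanel:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message is adequate
        raise ParseError(f"cannot parse haplotype TSV: {exc}", path) from exc
    hap = df.to_numpy(dtype=np.int8).T
    return ReferencePanel(snp_ids=df.index.astype(str).tolist(), haplotypes=hap, phased=True)


# ---------------------------------------------------------------------------
# BED annotation (0-based half-open on disk -> 1-based inclusive in memory)

def write_annotation_bed(annotation: GeneAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        for _, row in annotation.table.iterrows():
            fh.write(f"{row['chrom']}\t{row['start'] - 1}\t{row['end']}\t{row['gene_id']}\n")


def read_annotation_bed(path: str) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError("BED needs chrom, start, end, name", path, ln)
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if end <= start:
                raise ParseError(f"empty BED interval for {name}", path, ln)
            rows.append(
                {"gene_id": name, "chrom": chrom, "start": start + 1, "end": end}
            )
    return GeneAnnotation(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Expression matrix + groups

def write_expression(dataset: ExpressionDataset, expr_path: str, groups_path: str) -> None:
    dataset.values.to_csv(expr_path, sep="\t", float_format="%.6f")
    dataset.groups.rename("group").to_frame().to_csv(
        groups_path, sep="\t", index_label="sample_id"
    )


def read_expression(expr_path: str, groups_path: str, level: str = "gene") -> ExpressionDataset:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t", index_col=0)
    if "group" not in groups_df.columns:
        raise ParseError("groups TSV needs a 'group' column", groups_path)
    groups = groups_df["group"].astype(str)
    unknown = [s for s in groups.index if s not in values.columns]
    if unknown:
        raise ParseError(f"groups file names unknown samples: {unknown[:3]}", groups_path)
    missing = [s for s in values.columns if s not in groups.index]
    if missing:
        raise ParseError(f"samples without group labels: {missing[:3]}", groups_path)
    return ExpressionDataset(values=values, groups=groups, level=level)


# ---------------------------------------------------------------------------
# GMT pathway sets

def write_gmt(collection: PathwayCollection, path: str) -> None:
    with open(path, "w") as fh:
        for pw in collection:
            desc = pw.function_class or pw.name
            fh.write("\t".join([pw.pathway_id, desc, *pw.genes]) + "\n")


def read_gmt(path: str) -> PathwayCollection:
    items: list[Pathway] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError("GMT line needs id, description, >=1 gene", path, ln)
            pid, desc, genes = parts[0], parts[1], tuple(g for g in parts[2:] if g)
            if pid in seen:
                raise ParseError(f"duplicate pathway id {pid}", path, ln)
            if not genes:
                raise ParseError(f"pathway {pid} has an empty member list", path, ln)
            seen.add(pid)
            items.append(
                Pathway(pathway_id=pid, name=pid, genes=genes, function_class=desc)
            )
    return PathwayCollection.from_list(items)


# ---------------------------------------------------------------------------
# Ground truth, results, config

def write_truth(truth: GroundTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("category\tid\n")
        for cat, ids in (
            ("causal_snp", truth.causal_snp_ids),
            ("causal_gene", truth.causal_gene_ids),
            ("de_gene", truth.de_gene_ids),
            ("enriched_pathway", truth.enriched_pathway_ids),
        ):
            for i in sorted(ids):
                fh.write(f"{cat}\t{i}\n")


def read_truth(path: str) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    def grab(cat: str) -> set[str]:
        return set(df.loc[df["category"] == cat, "id"].astype(str))
    return GroundTruth(
        causal_snp_ids=grab("causal_snp"),
        causal_gene_ids=grab("causal_gene"),
        de_gene_ids=grab("de_gene"),
        enriched_pathway_ids=grab("enriched_pathway"),
    )


RESULT_HEADERS = {
    "pathway_id": "pathway_id",
    "name": "name",
    "n_members": "n_members",
    "n_scored": "n_scored",
    "s_true": "S_true",
    "p_perm": "p_perm",
    "q": "q",
    "significant": "significant",
}


def write_results(results: pd.DataFrame, path: str) -> None:
    out = results[list(RESULT_HEADERS)].rename(columns=RESULT_HEADERS)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str) -> pd.DataFrame:
    inv = {v: k for k, v in RESULT_HEADERS.items()}
    return pd.read_csv(path, sep="\t").rename(columns=inv)


def write_gene_scores(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_yaml(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
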
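"""On-disk formats: expression/metadata/P-A/probe-map TSV, VCF, BED, profiles.

Conventions: expression TSV has probeset ids in the first column and sample
ids as remaining columns, tab-separated log2 values.  Genotypes travel as
VCF v4.2 with a GT-only FORMAT (diploid, ``./.`` missing), read back through
cyvcf2.  Regions come as BED (0-based half-open, converted on read) or as a
1-based inclusive TSV.  All tables round-trip exactly enough for the
pipeline to re-consume its own outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from admeta.compounds import ProfileSet
from admeta.expression import ExpressionStudy
from admeta.genetics import GeneRegion, GenotypeStudy, STRICT_WINDOW
from admeta.scan import CompendiumDataset, SampleCompendium


# ------------------------------------------------------------- expression

def write_expression_study(study: ExpressionStudy, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.matrix.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6g")
    study.samples.to_csv(outdir / "samples.tsv", sep="\t")
    study.probe_map.rename("gene_symbol").to_csv(outdir / "probe_map.tsv", sep="\t")
    if study.pa_calls is not None:
        study.pa_calls.to_csv(outdir / "pa_calls.tsv", sep="\t")


def _axis_names(frame: pd.DataFrame, index: str, columns: str) -> pd.DataFrame:
    frame.index.name = index
    frame.columns.name = columns
    return frame


def read_expression_study(indir: Path, name: str | None = None) -> ExpressionStudy:
    indir = Path(indir)
    matrix = _axis_names(pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0),
                         "probeset", "sample_id")
    samples = pd.read_csv(indir / "samples.tsv", sep="\t", index_col=0)
    probe_map = pd.read_csv(indir / "probe_map.tsv", sep="\t", index_col=0)["gene_symbol"]
    pa_path = indir / "pa_calls.tsv"
    pa = (
        _axis_names(pd.read_csv(pa_path, sep="\t", index_col=0), "probeset", "sample_id")
        if pa_path.exists()
        else None
    )
    return ExpressionStudy(
        name=name or indir.name, matrix=matrix, samples=samples,
        probe_map=probe_map, pa_calls=pa,
    )


# ------------------------------------------------------------- compendium

def write_compendium(compendium: SampleCompendium, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for ds in compendium.datasets:
        ds_dir = outdir / ds.name
        ds_dir.mkdir(exist_ok=True)
        ds.matrix.to_csv(ds_dir / "expression.tsv", sep="\t", float_format="%.6g")
        ds.attributes.to_csv(ds_dir / "attributes.tsv", sep="\t")
        ds.probe_map.rename("gene_symbol").to_csv(ds_dir / "probe_map.tsv", sep="\t")
        manifest.append({"dataset_id": ds.name, "path": ds.name})
    pd.DataFrame(manifest).to_csv(outdir / "manifest.tsv", sep="\t", index=False)


def read_compendium(indir: Path) -> SampleCompendium:
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.tsv", sep="\t")
    datasets = []
    for _, row in manifest.iterrows():
        ds_dir = indir / row["path"]
        datasets.append(
            CompendiumDataset(
                name=row["dataset_id"],
                matrix=_axis_names(
                    pd.read_csv(ds_dir / "expression.tsv", sep="\t", index_col=0),
                    "probeset", "sample_id"),
                attributes=pd.read_csv(ds_dir / "attributes.tsv", sep="\t", index_col=0),
                probe_map=pd.read_csv(ds_dir / "probe_map.tsv", sep="\t", index_col=0)["gene_symbol"],
            )
        )
    return SampleCompendium(datasets=datasets)


# -------------------------------------------------------------------- VCF

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotype_study(study: GenotypeStudy, outdir: Path) -> None:
    """Write genotypes as VCF v4.2 (GT-only FORMAT) plus a subjects TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.subjects.to_csv(outdir / "subjects.tsv", sep="\t")
    subject_ids = list(study.subjects.index)
    contigs = {}
    for chrom, grp in study.snps.groupby("chrom", sort=False):
        contigs[chrom] = int(grp["pos"].max()) + 1_000_000
    lines = ["##fileformat=VCFv4.2", "##source=admeta"]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subject_ids))
    geno = study.genotypes.to_numpy(dtype=float)
    for i, (snp_id, row) in enumerate(study.snps.iterrows()):
        calls = "\t".join(
            "./." if np.isnan(g) else _GT[g] for g in geno[i]
        )
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\t{row['ref']}\t{row['alt']}"
            f"\t.\tPASS\t.\tGT\t{calls}"
        )
    (outdir / "genotypes.vcf").write_text("\n".join(lines) + "\n")


def read_genotype_study(indir: Path, name: str | None = None) -> GenotypeStudy:
    """Read a cohort back from VCF + subjects TSV (via cyvcf2)."""
    from cyvcf2 import VCF

    indir = Path(indir)
    subjects = pd.read_csv(indir / "subjects.tsv", sep="\t", index_col=0)
    vcf = VCF(str(indir / "genotypes.vcf"))
    sample_order = list(vcf.samples)
    snp_rows, geno_rows = [], []
    for variant in vcf:
        snp_rows.append(
            {"snp_id": variant.ID, "chrom": variant.CHROM, "pos": variant.POS,
             "ref": variant.REF, "alt": variant.ALT[0]}
        )
        # gt_types: 0 hom-ref, 1 het, 2 unknown-in-some-builds/3 unknown, 3 hom-alt
        counts = np.array([sum(g[:2]) if g[0] >= 0 else np.nan
                           for g in variant.genotypes], dtype=float)
        geno_rows.append(counts)
    vcf.close()
    snps = pd.DataFrame(snp_rows).set_index("snp_id")
    genotypes = pd.DataFrame(np.vstack(geno_rows), index=snps.index, columns=sample_order)
    genotypes = genotypes[subjects.index]  # align to subject table order
    genotypes.columns.name = "subject_id"
    return GenotypeStudy(name=name or indir.name, subjects=subjects, snps=snps,
                         genotypes=genotypes)


# ------------------------------------------------------------------ regions

def write_regions_bed(regions: list[GeneRegion], path: Path) -> None:
    """BED: 0-based half-open, so start-1 / end of the 1-based inclusive body."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene}\n")


def read_regions_bed(path: Path, window: int = STRICT_WINDOW) -> list[GeneRegion]:
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end, gene = line.split("\t")[:4]
        regions.append(GeneRegion(gene=gene, chrom=chrom, start=int(start) + 1,
                                  end=int(end), window=window))
    return regions


def write_regions_tsv(regions: list[GeneRegion], path: Path) -> None:
    pd.DataFrame(
        [{"gene": r.gene, "chrom": r.chrom, "start": r.start, "end": r.end}
         for r in regions]
    ).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path: Path, window: int = STRICT_WINDOW) -> list[GeneRegion]:
    frame = pd.read_csv(path, sep="\t")
    return [GeneRegion(gene=r.gene, chrom=str(r.chrom), start=int(r.start),
                       end=int(r.end), window=window)
            for r in frame.itertuples()]


# ----------------------------------------------------------------- profiles

def write_profiles(profiles: ProfileSet, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles.values.to_csv(outdir / "profiles.tsv", sep="\t", float_format="%.6g")
    profiles.meta.to_csv(outdir / "profile_meta.tsv", sep="\t")
    profiles.probe_map.rename("gene_symbol").to_csv(outdir / "probe_map.tsv", sep="\t")


def read_profiles(indir: Path) -> ProfileSet:
    indir = Path(indir)
    return ProfileSet(
        values=_axis_names(pd.read_csv(indir / "profiles.tsv", sep="\t", index_col=0),
                           "probeset", "profile_id"),
        meta=pd.read_csv(indir / "profile_meta.tsv", sep="\t", index_col=0),
        probe_map=pd.read_csv(indir / "probe_map.tsv", sep="\t", index_col=0)["gene_symbol"],
    )


# ------------------------------------------------------------------- tissue

def write_tissue_matrix(matrix: pd.DataFrame, flags: pd.Series, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(outdir / "tissue_expression.tsv", sep="\t", float_format="%.6g")
    flags.astype(int).rename("is_brain").to_csv(outdir / "tissue_flags.tsv", sep="\t")


def read_tissue_matrix(indir: Path) -> tuple[pd.DataFrame, pd.Series]:
    indir = Path(indir)
    matrix = pd.read_csv(indir / "tissue_expression.tsv", sep="\t", index_col=0)
    flags = pd.read_csv(indir / "tissue_flags.tsv", sep="\t", index_col=0)["is_brain"].astype(bool)
    return matrix, flags


# ----------------------------------------------------------------- manifest

def file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
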
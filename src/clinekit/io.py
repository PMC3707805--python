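"""Readers and writers for the external formats the toolkit consumes.

Supported genotype sources: VCF 4.x (GT field only, via cyvcf2), PLINK
PED/MAP text, and a simple TSV dialect (``<prefix>.geno.tsv`` +
``<prefix>.map.tsv``). Only biallelic autosomal SNPs are retained; dropped
records are counted and logged.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    GenotypeMatrix,
    IBDSegmentTable,
    PairMatrix,
    SiteTable,
    ValidationError,
)

log = logging.getLogger(__name__)

_NON_AUTOSOMES = {"X", "Y", "MT", "M", "XY", "chrX", "chrY", "chrM", "chrMT"}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Load a :class:`GenotypeMatrix` from ``path``.

    ``format`` is one of ``vcf``, ``plink_pedmap`` (pass the ``.ped`` path;
    the ``.map`` is found next to it) or ``tsv`` (pass the prefix). The
    genotype code counts copies of the alternate allele as declared in the
    source; for PED/MAP the in-file minor allele is the alternate (ties
    broken lexicographically).
    """
    path = Path(path)
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "plink_pedmap":
        gm = _read_pedmap(path)
    elif format == "tsv":
        gm = _read_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return gm.sort_markers().validate()


def _read_vcf(path: Path) -> GenotypeMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    from cyvcf2 import VCF

    with open(path) as fh:  # htslib collapses duplicate samples; check first
        for ln, line in enumerate(fh, 1):
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                if len(set(samples)) != len(samples):
                    dupes = sorted({s for s in samples if samples.count(s) > 1})
                    raise ValidationError(f"duplicate individual ids: {dupes}")
                break
            if not line.startswith("#"):
                raise ParseError(f"{path}:{ln}: header line #CHROM not found")
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    ids = list(vcf.samples)
    rows, chroms, poss, mids = [], [], [], []
    dropped = 0
    for v in vcf:
        if str(v.CHROM).lstrip("chr") in {"X", "Y", "MT", "M", "XY"} or str(
            v.CHROM
        ) in _NON_AUTOSOMES:
            dropped += 1
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            dropped += 1
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0/1/2 alt dosage, 3 unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
        mids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    if dropped:
        log.info("read_genotypes: dropped %d non-biallelic/non-autosomal records", dropped)
    calls = (
        np.vstack(rows).T if rows else np.empty((len(ids), 0), dtype=np.int8)
    )
    mm = pd.DataFrame({"id": mids, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(ids, mm, calls)


def _read_pedmap(ped_path: Path) -> GenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    if not ped_path.exists():
        raise FileNotFoundError(ped_path)
    if not map_path.exists():
        raise FileNotFoundError(map_path)
    mm_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{ln}: expected 4 MAP columns")
            mm_rows.append((parts[1], parts[0], int(parts[3])))
    n_snps = len(mm_rows)
    ids: list[str] = []
    allele_rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            ids.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype="U8").reshape(len(ids), n_snps, 2)
    calls = np.full((len(ids), n_snps), MISSING, dtype=np.int8)
    keep = np.ones(n_snps, dtype=bool)
    dropped = 0
    for s in range(n_snps):
        col = alleles[:, s, :]
        observed = col[col != "0"]
        uniq = sorted(set(observed.tolist()))
        if len(uniq) > 2 or any(len(a) != 1 for a in uniq):
            keep[s] = False
            dropped += 1
            continue
        typed = (col != "0").all(axis=1)
        if not uniq:  # all missing: calls stay MISSING
            continue
        if len(uniq) == 1:
            # monomorphic: the unobserved second allele is the minor one,
            # hence the alternate; its dosage is 0 everywhere typed
            calls[typed, s] = 0
            continue
        counts = {a: (observed == a).sum() for a in uniq}
        # minor allele in-file is alternate; ties lexicographic
        alt = min(uniq, key=lambda a: (counts[a], a))
        calls[typed, s] = (col[typed] == alt).sum(axis=1)
    if dropped:
        log.info("read_genotypes: dropped %d non-biallelic PED sites", dropped)
    mm = pd.DataFrame(
        [r for r, k in zip(mm_rows, keep) if k], columns=["id", "chrom", "pos"]
    )
    return GenotypeMatrix(ids, mm, calls[:, keep])


def _read_tsv(prefix: Path) -> GenotypeMatrix:
    geno = Path(str(prefix) + ".geno.tsv")
    mapf = Path(str(prefix) + ".map.tsv")
    gdf = pd.read_csv(geno, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    mm = pd.read_csv(mapf, sep="\t", dtype={"id": str, "chrom": str, "pos": int})
    calls = gdf.replace("NA", str(MISSING)).to_numpy(dtype=np.int8)
    if list(gdf.columns) != list(mm["id"]):
        raise ParseError(f"{geno}: marker columns do not match {mapf}")
    return GenotypeMatrix(list(gdf.index), mm, calls)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write genotypes as a minimal uncompressed VCF 4.2 (GT field only).

    The alternate allele is written as ``A``→``G`` placeholders; dosage
    coding round-trips exactly.
    """
    gm = gm.sort_markers()
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.marker_map["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids)
            + "\n"
        )
        for s in range(gm.n_snps):
            row = gm.marker_map.iloc[s]
            gts = "\t".join(code_to_gt[int(g)] for g in gm.calls[:, s])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_pedmap(gm: GenotypeMatrix, ped_path) -> None:
    """Write genotypes as PLINK PED/MAP text (alleles A=ref, G=alt)."""
    ped_path = Path(ped_path)
    map_path = ped_path.with_suffix(".map")
    gm = gm.sort_markers()
    with open(map_path, "w") as fh:
        for s in range(gm.n_snps):
            row = gm.marker_map.iloc[s]
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
    code_to_alleles = {0: "A A", 1: "A G", 2: "G G", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(gm.individual_ids):
            geno = " ".join(code_to_alleles[int(g)] for g in gm.calls[i])
            fh.write(f"FAM {ind} 0 0 1 -9 {geno}\n")


def read_sites(sites_path, assignment_path=None) -> SiteTable:
    """Read a site TSV (header ``site``, ``lat``, ``lon``; extra columns kept)
    and an optional assignment TSV (header ``individual``, ``site``)."""
    df = pd.read_csv(sites_path, sep="\t", dtype={"site": str})
    for col in ("site", "lat", "lon"):
        if col not in df.columns:
            raise ParseError(f"{sites_path}: missing column {col!r}")
    assignment: dict[str, str] = {}
    if assignment_path is not None:
        adf = pd.read_csv(assignment_path, sep="\t", dtype=str)
        for col in ("individual", "site"):
            if col not in adf.columns:
                raise ParseError(f"{assignment_path}: missing column {col!r}")
        assignment = dict(zip(adf["individual"], adf["site"]))
    return SiteTable(df, assignment).validate()


def write_sites(st: SiteTable, sites_path, assignment_path=None) -> None:
    st.sites.to_csv(sites_path, sep="\t", index=False)
    if assignment_path is not None:
        pd.DataFrame(
            {"individual": list(st.assignment), "site": list(st.assignment.values())}
        ).to_csv(assignment_path, sep="\t", index=False)


def write_matrix(m: PairMatrix, path) -> None:
    """Write a PairMatrix as TSV: first row/column are labels (csv-quoted)."""
    if not m.labels:
        raise ValidationError("cannot write matrix with empty labels")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_MINIMAL)
        w.writerow([f"#kind={m.kind}"] + list(m.labels))
        for lab, row in zip(m.labels, m.values):
            w.writerow([lab] + [repr(float(x)) for x in row])


def read_matrix(path) -> PairMatrix:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        kind = header[0].removeprefix("#kind=") if header[0].startswith("#kind=") else "distance"
        labels = header[1:]
        rows, row_labels = [], []
        for ln, row in enumerate(r, 2):
            row_labels.append(row[0])
            vals = [float(x) for x in row[1:]]
            if any(np.isnan(v) for v in vals):
                raise ParseError(f"{path}:{ln}: NaN cell in matrix")
            rows.append(vals)
    if row_labels != labels:
        raise ValidationError(f"{path}: row labels do not match column labels")
    m = PairMatrix(labels, np.array(rows), kind)
    if np.max(np.abs(m.values - m.values.T)) > 1e-9:
        raise ValidationError(f"{path}: matrix is not symmetric")
    return m


def read_ibd_segments(path) -> IBDSegmentTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"id_a": str, "id_b": str, "chrom": str, "start_bp": int, "end_bp": int},
    )
    return IBDSegmentTable(df).validate()


def write_ibd_segments(tbl: IBDSegmentTable, path) -> None:
    tbl.records.to_csv(path, sep="\t", index=False)


def write_genotypes_tsv(gm: GenotypeMatrix, prefix) -> None:
    gm = gm.sort_markers()
    df = pd.DataFrame(
        gm.calls, index=gm.individual_ids, columns=list(gm.marker_map["id"])
    ).replace(MISSING, "NA")
    df.to_csv(str(prefix) + ".geno.tsv", sep="\t", index_label="id")
    gm.marker_map.to_csv(str(prefix) + ".map.tsv", sep="\t", index=False)
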
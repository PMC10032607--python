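"""Readers and writers for the standard formats the pipeline touches.

VCF parsing goes through :mod:`cyvcf2`; BED/BedGraph/sample sheets through
pandas; Newick through dendropy. VCF writing emits plain uncompressed text
so synthetic fixtures round-trip without binary artefacts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    DepthTrack,
    GenotypeMatrix,
    Morph,
    PhenotypeCounts,
    Region,
    SampleInfo,
    SampleSheet,
    SVTable,
    SVType,
    WindowMode,
    WindowSpec,
)
from .tree import SpeciesTree

logger = logging.getLogger(__name__)

SHEET_COLUMNS = ["sample_id", "species", "region", "morph", "population"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample_filter: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and indel records are skipped (a count is logged) since
    every downstream pattern/frequency statistic is defined on biallelic
    SNPs. VCF 1-based positions are converted to 0-based.
    """
    vcf = VCF(str(path))
    all_samples = list(vcf.samples)
    if sample_filter is not None:
        absent = [s for s in sample_filter if s not in all_samples]
        if absent:
            raise KeyError(f"samples not present in VCF: {absent}")
        keep = [all_samples.index(s) for s in sample_filter]
        samples = list(sample_filter)
    else:
        keep = list(range(len(all_samples)))
        samples = all_samples

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        gt = np.asarray(variant.genotype.array())[:, :2]
        dose = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        chroms.append(variant.CHROM)
        pos.append(variant.POS - 1)
        ref.append(variant.REF)
        alt.append(variant.ALT[0])
        rows.append(dose[keep].astype(np.int8))
    vcf.close()
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNP records", path, n_skipped)
    geno = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        genotypes=geno,
        samples=samples,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in geno.chroms():
            sel = geno.chrom == c
            length = int(geno.pos[sel].max()) + 2 if sel.any() else 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for i in range(geno.n_sites):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in geno.genotypes[i])
            fh.write(
                f"{geno.chrom[i]}\t{geno.pos[i] + 1}\t.\t{geno.ref[i]}\t"
                f"{geno.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_sv_vcf(path: str | Path, min_gq_tag: str = "GQ") -> SVTable:
    """Read a DELLY-style SV VCF (SVTYPE INFO tag) into an :class:`SVTable`.

    Only INS/DEL records are kept; others are skipped with a logged count.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom: list[str] = []
    pos: list[int] = []
    svtype: list[SVType] = []
    length: list[int] = []
    filt: list[bool] = []
    gts: list[np.ndarray] = []
    gqs: list[np.ndarray] = []
    n_skipped = 0
    for v in vcf:
        st = v.INFO.get("SVTYPE")
        if st not in ("INS", "DEL"):
            n_skipped += 1
            continue
        end = v.INFO.get("END")
        svlen = v.INFO.get("SVLEN")
        if svlen is not None:
            ln = abs(int(svlen if np.isscalar(svlen) else svlen[0]))
        elif end is not None:
            ln = int(end) - v.POS
        else:
            ln = abs(len(v.ALT[0]) - len(v.REF)) if v.ALT else 0
        gt = np.asarray(v.genotype.array())[:, :2]
        dose = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        try:
            gq = np.asarray(v.format(min_gq_tag), dtype=float).reshape(-1)
        except (KeyError, TypeError):
            gq = np.full(len(samples), np.nan)
        chrom.append(v.CHROM)
        pos.append(v.POS)
        svtype.append(SVType(st))
        length.append(ln)
        filt.append(v.FILTER is None)  # cyvcf2: None means PASS
        gts.append(dose.astype(np.int8))
        gqs.append(gq)
    vcf.close()
    if n_skipped:
        logger.info("read_sv_vcf(%s): skipped %d non-INS/DEL records", path, n_skipped)
    n = len(pos)
    return SVTable(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        sv_type=np.asarray(svtype, dtype=object),
        length=np.asarray(length, dtype=np.int64),
        filter_pass=np.asarray(filt, dtype=bool),
        genotypes=np.vstack(gts) if n else np.empty((0, len(samples)), dtype=np.int8),
        gq=np.vstack(gqs) if n else np.empty((0, len(samples))),
        samples=samples,
    )


def write_sv_vcf(table: SVTable, path: str | Path) -> None:
    """Write an SVTable as an uncompressed SV VCF with SVTYPE/SVLEN tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(table.chrom.tolist()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in range(table.n_records):
            sv = table.sv_type[i].value
            alt = f"<{sv}>"
            flt = "PASS" if table.filter_pass[i] else "LowQual"
            fields = []
            for j in range(table.n_samples):
                g = _GT_STRINGS[int(table.genotypes[i, j])]
                q = table.gq[i, j]
                fields.append(f"{g}:{int(q) if np.isfinite(q) else '.'}")
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\tsv{i}\tN\t{alt}\t.\t{flt}\t"
                f"SVTYPE={sv};SVLEN={table.length[i]}\tGT:GQ\t" + "\t".join(fields) + "\n"
            )


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a delimited sample sheet (CSV or TSV, sniffed from the header)."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing_cols = [c for c in SHEET_COLUMNS[:4] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"sample sheet missing columns: {missing_cols}")
    samples = []
    for _, row in df.iterrows():
        try:
            region = Region(row.get("region") or "unknown")
        except ValueError:
            raise ValueError(f"unknown region token: {row.get('region')!r}") from None
        try:
            morph = Morph(row.get("morph") or "unknown")
        except ValueError:
            raise ValueError(f"unknown morph token: {row.get('morph')!r}") from None
        samples.append(
            SampleInfo(
                sample_id=row["sample_id"],
                species=row["species"],
                region=region,
                morph=morph,
                population=row.get("population") or None,
            )
        )
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "species": s.species,
                "region": s.region.value,
                "morph": s.morph.value,
                "population": s.population or "",
            }
            for s in sheet.samples
        ],
        columns=SHEET_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_windows(
    genome_layout: Mapping[str, int] | None,
    mode: WindowMode | str,
    size: int,
    sites: GenotypeMatrix | None = None,
) -> list[WindowSpec]:
    """Tile the genome into non-overlapping windows.

    ``bp`` mode tiles [0, L) per chromosome in fixed steps, truncating the
    last window at L. ``snp_count`` mode emits consecutive blocks of exactly
    ``size`` SNPs per chromosome (trailing partial block dropped); each
    window spans [first_snp_pos, last_snp_pos + 1).
    """
    mode = WindowMode(mode)
    if size <= 0:
        raise ValueError("window size must be > 0")
    windows: list[WindowSpec] = []
    if mode is WindowMode.bp:
        if genome_layout is None:
            raise ValueError("bp mode requires chromosome lengths")
        for chrom, length in genome_layout.items():
            start = 0
            while start < length:
                windows.append(
                    WindowSpec(chrom, start, min(start + size, length), WindowMode.bp)
                )
                start += size
    else:
        if sites is None:
            raise ValueError("snp_count mode requires site positions")
        for chrom in sites.chroms():
            p = sites.pos[sites.chrom == chrom]
            n_full = len(p) // size
            for k in range(n_full):
                block = p[k * size : (k + 1) * size]
                windows.append(
                    WindowSpec(chrom, int(block[0]), int(block[-1]) + 1, WindowMode.snp_count)
                )
    return windows


# ---------------------------------------------------------------------------
# BED / BedGraph / Newick / TSV
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based half-open), ignoring track/comment lines."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed_intervals(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_depth_bedgraph(path: str | Path, sample_id: str | None = None) -> DepthTrack:
    """Read a BedGraph depth track; intervals must be sorted, non-overlapping."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": float},
    )
    if sample_id is None:
        sample_id = Path(path).stem
    for c, sub in df.groupby("chrom", sort=False):
        if not sub["start"].is_monotonic_increasing:
            raise ValueError(f"BedGraph intervals not sorted on {c} in {path}")
    return DepthTrack(
        sample_id=sample_id,
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(),
        end=df["end"].to_numpy(),
        depth=df["depth"].to_numpy(),
    )


def write_depth_bedgraph(track: DepthTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e, d in zip(track.chrom, track.start, track.end, track.depth):
            d_str = f"{d:g}"
            fh.write(f"{c}\t{s}\t{e}\t{d_str}\n")


def read_newick(path: str | Path) -> SpeciesTree:
    with open(path) as fh:
        return SpeciesTree.from_newick(fh.read())


def write_results_tsv(records: Iterable[Mapping[str, object]], path: str | Path,
                      columns: Sequence[str] | None = None) -> None:
    """Write records as a TSV with one header row and deterministic columns."""
    records = list(records)
    if columns is None:
        columns = list(records[0].keys()) if records else []
    df = pd.DataFrame(records, columns=list(columns))
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotype_counts(path: str | Path) -> list[PhenotypeCounts]:
    """Read a phenotype-count TSV: population, n_alba, n_colored."""
    df = pd.read_csv(path, sep="\t")
    need = {"population", "n_alba", "n_colored"}
    if not need.issubset(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(need)}")
    return [
        PhenotypeCounts(str(r["population"]), int(r["n_alba"]), int(r["n_colored"]))
        for _, r in df.iterrows()
    ]
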
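"""Standard-format I/O: fragment tables, VCF mutation lists, BED tracks.

Internal coordinates are 0-based half-open everywhere; VCF (1-based) is
the only conversion boundary and is crossed exactly once on read/write.
All readers accept gzip-compressed input transparently.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeModel
from .simulate import FRAGMENT_COLUMNS

__all__ = [
    "read_fragments",
    "write_fragments",
    "MutationList",
    "read_vcf_mutations",
    "write_vcf_mutations",
    "read_bed_track",
    "ResultRecordIO",
    "write_results",
]


# ---------------------------------------------------------------------------
# fragment tables
# ---------------------------------------------------------------------------


def write_fragments(records: pd.DataFrame, path: str) -> None:
    """Write a fragment table as TSV (gzip if the path ends in .gz).

    Empty umi / locus_alleles fields are stored as ``.``.
    """
    out = records[FRAGMENT_COLUMNS].copy()
    for col in ("umi", "locus_alleles"):
        vals = out[col].astype(str)
        vals[vals == ""] = "."
        out[col] = vals
    out.to_csv(path, sep="\t", index=False)


def read_fragments(path: str) -> pd.DataFrame:
    """Read a fragment table written by :func:`write_fragments`.

    Raises a parse error naming the offending line for malformed rows,
    and a validation error when ``end <= start``.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "chrom": str,
                "start": np.int64,
                "end": np.int64,
                "length": np.int64,
                "source": str,
                "umi": str,
                "locus_alleles": str,
            },
            keep_default_na=False,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed fragment table {path}: {exc}") from exc
    missing = set(FRAGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fragment table missing columns: {sorted(missing)}")
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        # +2: one for the header, one for 0- vs 1-based line numbers
        raise ValueError(f"end <= start at line {int(bad[0]) + 2} of {path}")
    for col in ("umi", "locus_alleles"):
        df[col] = df[col].replace(".", "")
    return df[FRAGMENT_COLUMNS]


# ---------------------------------------------------------------------------
# VCF mutation lists
# ---------------------------------------------------------------------------

_SNV_BASES = {"A", "C", "G", "T"}


@dataclass
class MutationList:
    """Patient-specific SNVs: positions are 1-based at this surface.

    INFO keys written/read: TNC (trinucleotide context, middle base =
    ref), TMAF (tissue mutant allele fraction), RGN (comma-separated
    region labels).
    """

    records: pd.DataFrame  # chrom, pos (1-based), ref, alt, context, tissue_maf, regions
    n_skipped_indels: int = 0

    def __len__(self) -> int:
        return len(self.records)


def read_vcf_mutations(path: str) -> MutationList:
    """Read SNVs from a VCF 4.x file; indels are skipped with a warning
    counter and multi-allelic records are split into one row per alt."""
    rows, skipped = [], 0
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in _SNV_BASES:
                    skipped += 1
                    continue
                def _info(key):
                    try:
                        return rec.info[key]
                    except KeyError:
                        return None

                tmaf = _info("TMAF")
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,  # pysam exposes the 1-based POS
                        "ref": rec.ref,
                        "alt": alt,
                        "context": _info("TNC"),
                        "tissue_maf": float(tmaf) if tmaf is not None else np.nan,
                        "regions": _info("RGN"),
                    }
                )
    if skipped:
        warnings.warn(f"skipped {skipped} non-SNV records in {path}")
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "context", "tissue_maf", "regions"]
    )
    return MutationList(records=df, n_skipped_indels=skipped)


def write_vcf_mutations(
    mutations: MutationList, path: str, genome: GenomeModel | None = None
) -> None:
    """Write a MutationList as VCF 4.2 with documented INFO keys."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=TNC,Number=1,Type=String,Description="Trinucleotide context">')
    header.add_line('##INFO=<ID=TMAF,Number=1,Type=Float,Description="Tissue mutant allele fraction">')
    header.add_line('##INFO=<ID=RGN,Number=1,Type=String,Description="Region labels">')
    recs = mutations.records
    if genome is not None:
        contigs = genome.chromosomes
    else:
        contigs = [(c, 2**29) for c in pd.unique(recs["chrom"])]
    for name, size in contigs:
        header.add_line(f"##contig=<ID={name},length={size}>")
    with pysam.VariantFile(path, "w", header=header) as out:
        for _, r in recs.iterrows():
            rec = out.new_record(
                contig=r["chrom"],
                start=int(r["pos"]) - 1,  # pysam takes 0-based start
                alleles=(r["ref"], r["alt"]),
            )
            if pd.notna(r.get("context")) and r.get("context"):
                rec.info["TNC"] = str(r["context"])
            if pd.notna(r.get("tissue_maf")):
                rec.info["TMAF"] = float(r["tissue_maf"])
            if pd.notna(r.get("regions")) and r.get("regions"):
                rec.info["RGN"] = str(r["regions"])
            out.write(rec)


# ---------------------------------------------------------------------------
# BED interval tracks
# ---------------------------------------------------------------------------


def read_bed_track(
    path: str, merge: bool = True, genome: GenomeModel | None = None
) -> list[tuple[str, int, int]]:
    """Read a BED3+ file as sorted (chrom, start, end) intervals.

    Unsorted input is sorted internally; overlapping intervals are
    merged when ``merge`` is set.  Negative coordinates raise; when a
    genome is given, intervals beyond the chromosome end raise too.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    intervals = []
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {ln}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or end < 0:
                raise ValueError(f"BED line {ln}: negative coordinate")
            if end <= start:
                raise ValueError(f"BED line {ln}: end <= start")
            intervals.append((chrom, start, end))
    if genome is not None:
        sizes = dict(genome.chromosomes)
        for chrom, start, end in intervals:
            if chrom not in sizes or end > sizes[chrom]:
                raise ValueError(f"interval {(chrom, start, end)} beyond chromosome end")
    intervals.sort()
    if not merge:
        return intervals
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in intervals:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged.pop()
            merged.append((chrom, prev[1], max(prev[2], end)))
        else:
            merged.append((chrom, start, end))
    return merged


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------


@dataclass
class ResultRecordIO:
    schema_version: str = "1"


def write_results(records: list, tsv_path: str, json_path: str | None = None) -> None:
    """Write ResultRecords as one TSV row per (sample, assay) plus an
    optional JSON report (schema versioned)."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows)
    if "ancillary" in df.columns:
        df["ancillary"] = df["ancillary"].map(lambda a: json.dumps(a) if a else "")
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump({"schema_version": "1", "results": rows}, fh, indent=2, default=str)
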
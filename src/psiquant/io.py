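"""Readers and writers shared by all stages.

Conventions: TSV tables carry a header naming their columns and use 1-based
inclusive coordinates; BED6/bedGraph exports are 0-based half-open.  Readers
validate headers and report malformed lines by line number.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import REGION_ORDER, TranscriptModel
from .psicall import PILEUP_COLUMNS, SITE_COLUMNS


class FormatError(ValueError):
    """A file does not follow the documented dialect."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# pileup TSV
# ---------------------------------------------------------------------------

def write_pileup(pileup: pd.DataFrame, path: str | Path) -> None:
    pileup[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Read a pileup TSV (ref_id, pos, strand, total_reads, deletion_reads;
    1-based positions), validating per line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != PILEUP_COLUMNS:
        raise FormatError(
            f"{path}: expected header {PILEUP_COLUMNS}, got {list(df.columns)}"
        )
    if len(df) == 0:
        return pd.DataFrame(columns=PILEUP_COLUMNS)
    out = df.copy()
    for col in ("pos", "total_reads", "deletion_reads"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise FormatError(f"{path}: line {line}: non-numeric {col!r}")
        out[col] = converted.astype(int)
    bad_strand = ~out["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 2
        raise FormatError(f"{path}: line {line}: strand must be + or -")
    bad_pos = out["pos"] < 1
    if bad_pos.any():
        line = int(bad_pos.idxmax()) + 2
        raise FormatError(f"{path}: line {line}: positions are 1-based (pos >= 1)")
    over = out["deletion_reads"] > out["total_reads"]
    if over.any():
        line = int(over.idxmax()) + 2
        raise FormatError(
            f"{path}: line {line}: deletion_reads exceeds total_reads"
        )
    if (out["deletion_reads"] < 0).any():
        line = int((out["deletion_reads"] < 0).idxmax()) + 2
        raise FormatError(f"{path}: line {line}: negative deletion_reads")
    return out[PILEUP_COLUMNS]


# ---------------------------------------------------------------------------
# site tables and BED
# ---------------------------------------------------------------------------

def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    sites[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing site columns {missing}")
    df["tissue"] = df["tissue"].fillna("")
    return df


def write_bed(sites: pd.DataFrame, path: str | Path) -> None:
    """BED6 export: 0-based half-open, score = round(1000 * fraction)."""
    bed = pd.DataFrame(
        {
            "chrom": sites["ref_id"],
            "start": sites["pos"].astype(int) - 1,
            "end": sites["pos"].astype(int),
            "name": [
                f"psi|{t}|{m}" if t else f"psi|{m}"
                for t, m in zip(sites.get("tissue", ""), sites.get("motif3", ""))
            ],
            "score": np.clip(
                np.round(1000 * sites["fraction"].to_numpy()), 0, 1000
            ).astype(int),
            "strand": sites["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 back to 1-based site coordinates with fraction =
    score / 1000 (the inverse of :func:`write_bed`)."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "ref_id": bed["chrom"],
            "pos": bed["start"].astype(int) + 1,
            "strand": bed["strand"],
            "fraction": bed["score"] / 1000.0,
        }
    )


def write_bedgraph(values: np.ndarray, ref_id: str, path: str | Path) -> None:
    """Per-position track as bedGraph (0-based half-open)."""
    df = pd.DataFrame(
        {
            "chrom": ref_id,
            "start": np.arange(len(values)),
            "end": np.arange(1, len(values) + 1),
            "value": values,
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# transcript annotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["transcript_id", "region", "start", "end"]


def write_annotation(models: Mapping[str, TranscriptModel], path: str | Path) -> None:
    """Simple TSV dialect: transcript_id, region, start, end (1-based
    inclusive); intron intervals get region label 'intron'."""
    rows = []
    for tid in sorted(models):
        model = models[tid]
        for label, start, end in model.regions:
            rows.append((tid, label, start, end))
        for start, end in model.introns:
            rows.append((tid, "intron", start, end))
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> dict[str, TranscriptModel]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise FormatError(
            f"{path}: expected header {ANNOTATION_COLUMNS}, got {list(df.columns)}"
        )
    models = {}
    for tid, group in df.groupby("transcript_id", sort=True):
        regions = tuple(
            (row.region, int(row.start), int(row.end))
            for row in group.itertuples()
            if row.region in REGION_ORDER
        )
        introns = tuple(
            (int(row.start), int(row.end))
            for row in group.itertuples()
            if row.region == "intron"
        )
        models[str(tid)] = TranscriptModel(
            transcript_id=str(tid), gene_id=str(tid),
            regions=regions, introns=introns,
        )
    return models


_GFF_REGION = {
    "five_prime_UTR": "5UTR",
    "CDS": "CDS",
    "three_prime_UTR": "3UTR",
}


def read_gff3(path: str | Path) -> dict[str, TranscriptModel]:
    """Minimal GFF3 reader for five_prime_UTR / CDS / three_prime_UTR / exon
    features keyed by their Parent transcript.

    Coordinates are used as written; site tables must share the same
    coordinate space as the annotation.  Gaps between consecutive exons of a
    transcript become introns.
    """
    feats: dict[str, dict[str, list[tuple[int, int]]]] = {}
    strands: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            ftype, start, end, strand, attrs = (
                fields[2], int(fields[3]), int(fields[4]), fields[6], fields[8]
            )
            if ftype not in _GFF_REGION and ftype != "exon":
                continue
            parent = None
            for item in attrs.split(";"):
                key, _, value = item.strip().partition("=")
                if key in ("Parent", "transcript_id"):
                    parent = value.split(",")[0]
                    break
            if parent is None:
                continue
            feats.setdefault(parent, {}).setdefault(ftype, []).append((start, end))
            strands[parent] = strand
    models = {}
    for tid, groups in feats.items():
        regions = []
        for ftype, label in _GFF_REGION.items():
            for start, end in sorted(groups.get(ftype, [])):
                regions.append((label, start, end))
        regions.sort(key=lambda r: r[1])
        # merge contiguous CDS pieces is unnecessary for labelling; introns
        # come from exon gaps
        introns = []
        exons = sorted(groups.get("exon", []))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1 + 1:
                introns.append((e1 + 1, s2 - 1))
        models[tid] = TranscriptModel(
            transcript_id=tid, gene_id=tid, strand=strands.get(tid, "+"),
            regions=tuple(regions), introns=tuple(introns),
        )
    return models


# ---------------------------------------------------------------------------
# generic tables, config, hashing
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(data: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=True)


def config_hash(data: Mapping) -> str:
    """Stable short hash of a configuration mapping (for run manifests)."""
    canon = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
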
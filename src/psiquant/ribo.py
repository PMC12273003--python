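"""Translation efficiency from ribosome footprints and RNA abundance.

Transcript-level efficiency (E_transcript) is the ratio of ribosome-bound
TPM to whole-cell RNA TPM.  Codon-level efficiency (E_codon) is the
reciprocal of the codon dwell time: per gene, P-site counts are summed over
each codon and divided by the gene's mean codon coverage (so relative
coverages average 1 per gene); per codon type, dwell is the
expression-weighted mean of those relative coverages across genes.  A slow
codon dwells longer under the ribosome, accumulates more footprints, and
hence has low E_codon.

Footprint reads are length-filtered to 29-35 nt and assigned to their
P-site by a fixed offset (default 12 nt from the 5' end).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotate import TranscriptModel

logger = logging.getLogger(__name__)

FOOTPRINT_LENGTH_RANGE = (29, 35)
DEFAULT_PSITE_OFFSET = 12


def filter_footprints(
    reads: pd.DataFrame,
    min_len: int = FOOTPRINT_LENGTH_RANGE[0],
    max_len: int = FOOTPRINT_LENGTH_RANGE[1],
) -> pd.DataFrame:
    """Retain reads with min_len <= length <= max_len (bounds inclusive)."""
    keep = (reads["length"] >= min_len) & (reads["length"] <= max_len)
    removed = int((~keep).sum())
    if removed:
        logger.info("filtered %d footprint reads outside %d-%d nt",
                    removed, min_len, max_len)
    return reads.loc[keep].reset_index(drop=True)


def psite_coverage(
    reads: pd.DataFrame,
    transcript_lengths: Mapping[str, int],
    offset: int = DEFAULT_PSITE_OFFSET,
) -> dict[str, np.ndarray]:
    """Per-nucleotide P-site coverage: each read adds one count at
    ``start + offset`` (1-based).  Reads whose P-site falls beyond the
    transcript end are dropped (logged)."""
    coverage = {
        tid: np.zeros(int(L)) for tid, L in transcript_lengths.items()
    }
    dropped = 0
    for tid, group in reads.groupby("transcript_id"):
        if tid not in coverage:
            dropped += len(group)
            continue
        psite = group["start"].to_numpy(dtype=int) - 1 + offset
        valid = (psite >= 0) & (psite < len(coverage[tid]))
        dropped += int((~valid).sum())
        np.add.at(coverage[tid], psite[valid], 1)
    if dropped:
        logger.info("dropped %d reads with P-site outside the transcript", dropped)
    return coverage


def compute_tpm(counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """Transcripts per kilobase million.

    TPM_i = 1e6 * (counts_i / length_i) / sum_j (counts_j / length_j);
    the result sums to 1e6.  All-zero counts are undefined and raise.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every transcript needs a positive length")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("TPM undefined: zero counts everywhere")
    out = 1e6 * rate / total
    out.name = "tpm"
    return out


def transcript_te(
    ribo_tpm: pd.Series, rna_tpm: pd.Series, min_tpm: float = 1.0
) -> pd.Series:
    """E_transcript = ribosome-bound TPM / whole-cell TPM, restricted to
    transcripts with both values >= min_tpm."""
    shared = ribo_tpm.index.intersection(rna_tpm.index)
    r, m = ribo_tpm[shared], rna_tpm[shared]
    keep = (r >= min_tpm) & (m >= min_tpm)
    out = r[keep] / m[keep]
    out.name = "e_transcript"
    return out


def codon_dwell(
    coverage: Mapping[str, np.ndarray],
    models: Mapping[str, TranscriptModel],
    sequences: Mapping[str, str],
    rna_tpm: pd.Series | None = None,
    *,
    trim_codons: int = 5,
    min_mean_codon_coverage: float = 0.5,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-codon dwell time over the 61 sense codons.

    Per gene: codon coverage = sum of P-site counts over the codon's three
    nucleotides; relative coverage = codon coverage / gene mean (mean 1 per
    gene by construction).  ``trim_codons`` codons at each CDS end (which
    always removes the start and stop codons) are excluded, as are genes
    whose mean codon coverage falls below ``min_mean_codon_coverage``.
    Aggregation across genes weights each codon occurrence by the gene's
    RNA TPM unless ``weighted=False``.
    """
    acc_num: dict[str, float] = {}
    acc_den: dict[str, float] = {}
    acc_n: dict[str, int] = {}
    genes_used = 0
    for tid, cov in coverage.items():
        model = models.get(tid)
        if model is None or model.cds_len == 0:
            continue
        cds_start, cds_end = model.region_interval("CDS")
        cds_cov = np.asarray(cov[cds_start - 1 : cds_end], dtype=float)
        codon_cov = cds_cov.reshape(-1, 3).sum(axis=1)
        n_codons = len(codon_cov)
        lo, hi = trim_codons, n_codons - trim_codons
        if hi - lo < 5:
            continue
        kept = codon_cov[lo:hi]
        mean_cov = kept.mean()
        if mean_cov < min_mean_codon_coverage or mean_cov == 0:
            continue
        rel = kept / mean_cov
        seq = sequences[tid]
        codons = [
            seq[cds_start - 1 + 3 * k : cds_start + 2 + 3 * k]
            for k in range(lo, hi)
        ]
        if weighted:
            if rna_tpm is None:
                raise ValueError("weighted aggregation requires rna_tpm")
            w = float(rna_tpm.get(tid, 0.0))
            if w <= 0:
                continue
        else:
            w = 1.0
        genes_used += 1
        for codon, r in zip(codons, rel):
            acc_num[codon] = acc_num.get(codon, 0.0) + w * r
            acc_den[codon] = acc_den.get(codon, 0.0) + w
            acc_n[codon] = acc_n.get(codon, 0) + 1
    if genes_used == 0:
        raise ValueError("no gene passed the coverage floor")
    logger.info("codon dwell aggregated over %d genes", genes_used)
    rows = []
    for codon in sorted(acc_num):
        if codon in ("TAA", "TAG", "TGA"):
            continue
        rows.append(
            {
                "codon": codon,
                "amino_acid": str(Seq(codon).translate()),
                "dwell": acc_num[codon] / acc_den[codon],
                "n_occurrences": acc_n[codon],
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def codon_te(dwell: pd.Series | pd.DataFrame) -> pd.Series:
    """E_codon = 1 / dwell time (elementwise)."""
    if isinstance(dwell, pd.DataFrame):
        dwell = dwell["dwell"]
    if (dwell <= 0).any():
        raise ValueError("dwell times must be positive")
    out = 1.0 / dwell
    out.name = "e_codon"
    return out
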
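"""Psi site calling from BID-seq pileups.

BID-seq converts pseudouridine into a reverse-transcription deletion, so the
per-site "gap ratio" (deletion-bearing reads over total reads) reports the
modification level.  The calling procedure implemented here:

1. sum replicate pileups per tissue (:func:`combine_replicates`);
2. gap ratio per site (:func:`compute_gap_ratio`);
3. one-sided binomial test of each uridine site against the background
   deletion rate, estimated from non-uridine positions, with
   Benjamini-Hochberg adjustment (:func:`site_pvalue`, :func:`call_sites`);
4. calibration of the gap ratio to stoichiometry through a monotone
   piecewise-linear spike-in curve (:class:`CalibrationCurve`);
5. sequence-motif annotation of retained sites (:func:`extract_motif`).

Positions are 1-based inclusive; only reference T (= U in RNA) positions are
candidate sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

PILEUP_COLUMNS = ["ref_id", "pos", "strand", "total_reads", "deletion_reads"]
SITE_COLUMNS = [
    "ref_id", "pos", "strand", "depth", "del", "gap_ratio",
    "fraction", "p", "q", "motif3", "motif5", "tissue",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone piecewise-linear map from observed gap ratio to Psi fraction.

    Control points are (gap_ratio, fraction) pairs, strictly increasing in
    both coordinates, starting at (0, 0) and ending at fraction 1.0 (a
    spike-in style calibration).  Gap ratios beyond the last control point
    clamp to 1.0.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = self.points
        if len(pts) < 2:
            raise ValueError("calibration curve needs at least 2 control points")
        gaps = np.array([p[0] for p in pts], dtype=float)
        fracs = np.array([p[1] for p in pts], dtype=float)
        if gaps[0] != 0.0 or fracs[0] != 0.0:
            raise ValueError("calibration curve must start at (0, 0)")
        if fracs[-1] != 1.0:
            raise ValueError("calibration curve must end at fraction 1.0")
        if np.any(np.diff(gaps) <= 0) or np.any(np.diff(fracs) <= 0):
            raise ValueError("control points must be strictly increasing")
        if gaps.min() < 0 or gaps.max() > 1 or fracs.min() < 0 or fracs.max() > 1:
            raise ValueError("control points must lie in [0, 1]")

    @classmethod
    def identity(cls) -> "CalibrationCurve":
        return cls(((0.0, 0.0), (1.0, 1.0)))

    def fraction_for_gap(self, gap_ratio):
        """Calibrated fraction(s); accepts scalars or arrays."""
        gaps = np.array([p[0] for p in self.points])
        fracs = np.array([p[1] for p in self.points])
        out = np.interp(gap_ratio, gaps, fracs)
        return float(out) if np.isscalar(gap_ratio) else out

    def gap_for_fraction(self, fraction):
        """Inverse map (used when simulating the deletion signal)."""
        gaps = np.array([p[0] for p in self.points])
        fracs = np.array([p[1] for p in self.points])
        out = np.interp(fraction, fracs, gaps)
        return float(out) if np.isscalar(fraction) else out


def combine_replicates(pileups: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum replicate pileups per (ref_id, pos, strand).

    Positions absent from a replicate contribute zero counts; a single
    replicate passes through unchanged (up to row order).
    """
    if len(pileups) == 0:
        raise ValueError("no pileups to combine")
    merged = pd.concat([p[PILEUP_COLUMNS] for p in pileups], ignore_index=True)
    out = (
        merged.groupby(["ref_id", "pos", "strand"], as_index=False, sort=True)[
            ["total_reads", "deletion_reads"]
        ].sum()
    )
    return out[PILEUP_COLUMNS]


def compute_gap_ratio(deletion_reads, total_reads):
    """deletion_reads / total_reads; vectorised, requires total_reads > 0."""
    total = np.asarray(total_reads, dtype=float)
    dele = np.asarray(deletion_reads, dtype=float)
    if np.any(total <= 0):
        raise ValueError("gap ratio undefined for total_reads == 0")
    out = dele / total
    return float(out) if out.ndim == 0 else out


def calibrate_fraction(gap_ratio, curve: CalibrationCurve):
    """Gap ratio -> Psi stoichiometry through the calibration curve."""
    return curve.fraction_for_gap(gap_ratio)


def site_pvalue(deletion_reads, total_reads, background_rate: float):
    """One-sided upper-tail binomial probability P(X >= deletion_reads) with
    X ~ Binomial(total_reads, background_rate)."""
    if not 0 <= background_rate < 1:
        raise ValueError("background_rate must be in [0, 1)")
    k = np.asarray(deletion_reads)
    n = np.asarray(total_reads)
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("deletion_reads must be in [0, total_reads]")
    out = sps.binom.sf(k - 1, n, background_rate)
    return float(out) if out.ndim == 0 else out


def ref_base_at(sequences: Mapping[str, str], ref_id: str, pos: int, strand: str) -> str:
    """Reference base read on the given strand at a 1-based position."""
    base = sequences[ref_id][pos - 1].upper()
    return base.translate(_COMPLEMENT) if strand == "-" else base


def extract_motif(sequence: str, position: int, k: int = 3, strand: str = "+") -> str:
    """k-mer (k in {3, 5}) centred on a 1-based position; reverse-complemented
    for minus-strand sites.  Returns "" when the window leaves the sequence."""
    if k not in (3, 5):
        raise ValueError("k must be 3 or 5")
    half = (k - 1) // 2
    lo, hi = position - half, position + half
    if lo < 1 or hi > len(sequence):
        return ""
    window = sequence[lo - 1 : hi].upper()
    return reverse_complement(window) if strand == "-" else window


def estimate_background_rate(
    pileup: pd.DataFrame,
    sequences: Mapping[str, str],
    min_depth: int = 20,
    floor: float = 1e-4,
) -> float:
    """Median gap ratio over non-T reference positions with adequate depth.

    The floor keeps the downstream binomial test defined when the dataset is
    essentially deletion-free.
    """
    bases = np.array(
        [
            ref_base_at(sequences, r, int(p), s)
            for r, p, s in zip(pileup["ref_id"], pileup["pos"], pileup["strand"])
        ]
    )
    mask = (bases != "T") & (pileup["total_reads"].to_numpy() >= min_depth)
    if not mask.any():
        logger.warning("no non-T positions for background estimation; using floor")
        return floor
    sub = pileup.loc[mask]
    ratios = sub["deletion_reads"].to_numpy() / sub["total_reads"].to_numpy()
    return max(float(np.median(ratios)), floor)


def call_sites(
    pileup: pd.DataFrame,
    sequences: Mapping[str, str],
    curve: CalibrationCurve | None = None,
    *,
    min_depth: int = 20,
    min_deletion_reads: int = 5,
    min_gap_ratio: float = 0.02,
    q_cutoff: float = 0.05,
    background_rate: float | None = None,
    tissue: str = "",
) -> pd.DataFrame:
    """Call Psi sites with stoichiometry from a (replicate-combined) pileup.

    Only reference T/U positions are candidates.  Candidates with depth >=
    ``min_depth`` are tested against the background deletion rate
    (estimated from non-T positions when not supplied); Benjamini-Hochberg
    adjustment is applied across all tested candidates and sites are
    retained when q <= ``q_cutoff``, deletion reads >= ``min_deletion_reads``
    and gap ratio >= ``min_gap_ratio`` (ties at thresholds pass).
    """
    if curve is None:
        curve = CalibrationCurve.identity()
    missing = set(pileup["ref_id"]) - set(sequences)
    if missing:
        raise KeyError(f"missing reference sequences: {sorted(missing)[:5]}")

    zero_depth = int((pileup["total_reads"] == 0).sum())
    if zero_depth:
        logger.info("skipping %d zero-depth positions (gap ratio undefined)", zero_depth)
    pileup = pileup[pileup["total_reads"] > 0]

    if background_rate is None:
        background_rate = estimate_background_rate(pileup, sequences, min_depth)
    logger.info("background deletion rate: %.5f", background_rate)

    bases = np.array(
        [
            ref_base_at(sequences, r, int(p), s)
            for r, p, s in zip(pileup["ref_id"], pileup["pos"], pileup["strand"])
        ]
    )
    cand = pileup.loc[(bases == "T") & (pileup["total_reads"] >= min_depth)].copy()
    logger.info("%d candidate T positions at depth >= %d", len(cand), min_depth)
    if len(cand) == 0:
        return pd.DataFrame(columns=SITE_COLUMNS)

    depth = cand["total_reads"].to_numpy()
    dele = cand["deletion_reads"].to_numpy()
    gap = compute_gap_ratio(dele, depth)
    pvals = site_pvalue(dele, depth, background_rate)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    keep = (
        (qvals <= q_cutoff)
        & (dele >= min_deletion_reads)
        & (gap >= min_gap_ratio)
    )
    cand = cand.loc[keep]
    logger.info("%d sites pass q<=%.3g, del>=%d, gap>=%.3g", len(cand),
                q_cutoff, min_deletion_reads, min_gap_ratio)

    gap_kept = gap[keep]
    out = pd.DataFrame(
        {
            "ref_id": cand["ref_id"].to_numpy(),
            "pos": cand["pos"].astype(int).to_numpy(),
            "strand": cand["strand"].to_numpy(),
            "depth": depth[keep].astype(int),
            "del": dele[keep].astype(int),
            "gap_ratio": gap_kept,
            "fraction": calibrate_fraction(gap_kept, curve),
            "p": pvals[keep],
            "q": qvals[keep],
        }
    )
    out["motif3"] = [
        extract_motif(sequences[r], int(p), 3, s)
        for r, p, s in zip(out["ref_id"], out["pos"], out["strand"])
    ]
    out["motif5"] = [
        extract_motif(sequences[r], int(p), 5, s)
        for r, p, s in zip(out["ref_id"], out["pos"], out["strand"])
    ]
    out["tissue"] = tissue
    return out.reset_index(drop=True)[SITE_COLUMNS]


def motif_summary(
    sites: pd.DataFrame,
    k: int = 3,
    min_mean_fraction: float | None = None,
) -> pd.DataFrame:
    """Per-motif site counts, site percentages and mean Psi fraction.

    ``min_mean_fraction`` (e.g. 0.2) optionally retains only motifs whose
    mean fraction exceeds the cutoff, the convention used when plotting
    enriched motifs.
    """
    col = f"motif{k}"
    if col not in sites.columns:
        raise KeyError(f"sites table lacks {col}")
    table = sites[sites[col] != ""]
    if len(table) == 0:
        return pd.DataFrame(columns=["motif", "n", "percent", "mean_fraction"])
    grouped = table.groupby(col)["fraction"].agg(["size", "mean"])
    out = pd.DataFrame(
        {
            "motif": grouped.index,
            "n": grouped["size"].to_numpy(),
            "percent": 100.0 * grouped["size"].to_numpy() / len(table),
            "mean_fraction": grouped["mean"].to_numpy(),
        }
    ).reset_index(drop=True)
    if min_mean_fraction is not None:
        out = out[out["mean_fraction"] > min_mean_fraction].reset_index(drop=True)
    return out.sort_values("n", ascending=False, ignore_index=True)
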
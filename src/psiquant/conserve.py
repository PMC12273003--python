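"""Cross-species conservation of Psi sites.

Orthologous gene pairs are aligned with a linear-gap Smith-Waterman local
aligner; each Psi (uridine) position in species A is mapped through the
alignment to its homologous column in species B and assigned one of four
conservation classes:

    1  non-homologous (no aligned base in any partner)
    2  homologous but not U in any partner
    3  one aligned partner carries U (one-to-one conserved)
    4  two or more partners carry an aligned U (one-to-many conserved)

Classes 3 and 4 count as conserved.  The module also computes per-column
conservation scores over a multiple sequence alignment (mean pairwise
identity, smoothed and min-max scaled) and the Pearson correlation between
windowed Psi density and conservation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

_ALPHABET = set("ACGTN")
GAP = "-"


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0  # linear gap penalty per gapped column

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch penalty must be <= 0")
        if self.gap >= 0:
            raise ValueError("gap penalty must be negative")


@dataclass
class LocalAlignment:
    """Best local alignment: score plus aligned column pairs.

    ``columns`` lists (i, j) with 1-based positions; a gap is None on the
    corresponding side.  Empty columns mean the best alignment is empty
    (score 0).
    """

    score: float
    columns: list[tuple[int | None, int | None]]

    @property
    def a_span(self) -> tuple[int, int] | None:
        idx = [i for i, _ in self.columns if i is not None]
        return (min(idx), max(idx)) if idx else None


def smith_waterman(
    seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None
) -> LocalAlignment:
    """Optimal local alignment under linear gap scoring.

    Ties in the cell recurrence prefer diagonal, then up (gap in B), then
    left; the reported optimum is the first maximal cell in row-major order.
    Both choices make the traceback deterministic.
    """
    if scoring is None:
        scoring = AlignmentScoring()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = seq_a.upper(), seq_b.upper()
    if (set(a) | set(b)) - _ALPHABET:
        raise ValueError("sequences must be over {A,C,G,T,N}")

    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    # pointers: 0 stop, 1 diagonal, 2 up, 3 left
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (scoring.match if ai == b[j - 1] else scoring.mismatch)
            up = prev[j] + scoring.gap
            left = row[j - 1] + scoring.gap
            score, p = diag, 1
            if up > score:
                score, p = up, 2
            if left > score:
                score, p = left, 3
            if score <= 0:
                score, p = 0.0, 0
            row[j] = score
            ptr[i, j] = p
            if score > best:
                best, best_ij = score, (i, j)
    if best == 0:
        return LocalAlignment(0.0, [])

    columns: list[tuple[int | None, int | None]] = []
    i, j = best_ij
    while ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            columns.append((i, j))
            i, j = i - 1, j - 1
        elif p == 2:
            columns.append((i, None))
            i -= 1
        else:
            columns.append((None, j))
            j -= 1
    columns.reverse()
    return LocalAlignment(float(best), columns)


def map_homologous_sites(
    alignment: LocalAlignment,
    psi_positions: Sequence[int],
    seq_b: str,
) -> pd.DataFrame:
    """Map 1-based Psi positions in A through a local alignment.

    Returns one row per queried position with the aligned position and base
    in B: ``aligned_base`` is the base letter, ``'gap'`` when the column has
    a gap in B, or ``'none'`` when the position lies outside the local
    alignment window.
    """
    col_by_a = {i: j for i, j in alignment.columns if i is not None}
    rows = []
    for pos in psi_positions:
        if pos < 1:
            raise ValueError(f"position {pos} out of range")
        if pos not in col_by_a:
            rows.append((pos, pd.NA, "none"))
        else:
            j = col_by_a[pos]
            if j is None:
                rows.append((pos, pd.NA, "gap"))
            else:
                rows.append((pos, j, seq_b[j - 1].upper()))
    return pd.DataFrame(rows, columns=["pos_a", "pos_b", "aligned_base"])


def classify_site_pair(aligned_bases: Sequence[str]) -> int:
    """Class 1-4 from the aligned bases across all orthologous partners.

    A 'gap' or 'none' partner contributes no homologous site.  Class is 1
    when no partner aligns a base, 2 when bases align but none is U, 3 when
    exactly one partner carries an aligned U, 4 when several do.
    """
    if len(aligned_bases) == 0:
        raise ValueError("need at least one partner")
    aligned = [b for b in aligned_bases if b in _ALPHABET]
    if not aligned:
        return 1
    n_u = sum(1 for b in aligned if b == "T")
    if n_u == 0:
        return 2
    return 3 if n_u == 1 else 4


def classify_conservation(
    seq_a: str,
    partner_seqs: Mapping[str, str],
    psi_positions: Sequence[int],
    scoring: AlignmentScoring | None = None,
) -> pd.DataFrame:
    """Align A against every orthologous partner and classify each Psi site.

    Returns (pos, class, conserved) with conserved = class in {3, 4}.
    """
    mapped = {}
    for name, seq_b in partner_seqs.items():
        aln = smith_waterman(seq_a, seq_b, scoring)
        mapped[name] = map_homologous_sites(aln, psi_positions, seq_b)
    rows = []
    for k, pos in enumerate(psi_positions):
        bases = [mapped[name]["aligned_base"].iat[k] for name in mapped]
        cls = classify_site_pair(bases)
        rows.append((pos, cls, cls in (3, 4)))
    return pd.DataFrame(rows, columns=["pos", "class", "conserved"])


# ---------------------------------------------------------------------------
# conservation score over an MSA
# ---------------------------------------------------------------------------

@dataclass
class ConservationProfile:
    raw: np.ndarray      # per-column mean pairwise identity in [0, 1]
    scaled: np.ndarray   # smoothed then min-max scaled to [0, 1]
    window: int


def conservation_score(
    msa: Sequence[str], window: int = 50
) -> ConservationProfile:
    """Per-column conservation of a multiple sequence alignment.

    The raw score of a column is the fraction of identical pairs among all
    sequence pairs in which both members have a base there (all-gap or
    single-base columns score 0).  The track is smoothed with a centred
    moving average of the given width and min-max scaled; a constant track
    scales to all zeros with a warning.
    """
    if len(msa) < 2:
        raise ValueError("MSA needs at least 2 sequences")
    lengths = {len(s) for s in msa}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    arr = np.array([list(s.upper()) for s in msa])
    n_seq, L = arr.shape
    raw = np.zeros(L)
    for col in range(L):
        bases = arr[:, col]
        keep = bases != GAP
        k = int(keep.sum())
        if k < 2:
            continue
        total_pairs = k * (k - 1) // 2
        _, counts = np.unique(bases[keep], return_counts=True)
        same = int((counts * (counts - 1) // 2).sum())
        raw[col] = same / total_pairs
    smoothed = (
        pd.Series(raw).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    lo, hi = smoothed.min(), smoothed.max()
    if hi > lo:
        scaled = (smoothed - lo) / (hi - lo)
    else:
        warnings.warn("constant conservation track; scaled score set to zero")
        scaled = np.zeros_like(smoothed)
    return ConservationProfile(raw=raw, scaled=scaled, window=window)


def density_conservation_correlation(
    profile: ConservationProfile,
    site_positions: Sequence[int],
    window: int = 50,
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between windowed Psi density and
    windowed conservation score along one molecule."""
    L = len(profile.scaled)
    n_windows = L // window
    if n_windows < 3:
        raise ValueError("fewer than 3 windows; correlation undefined")
    density = np.zeros(n_windows)
    for pos in site_positions:
        w = min((pos - 1) // window, n_windows - 1)
        density[w] += 1
    cons = np.array([
        profile.scaled[w * window : (w + 1) * window].mean()
        for w in range(n_windows)
    ])
    if density.std() == 0 or cons.std() == 0:
        raise ValueError("zero variance in density or conservation")
    r, p = sps.pearsonr(density, cons)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# naive global alignment / center-star MSA for synthetic fixtures only
# ---------------------------------------------------------------------------

def global_align(
    seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None
) -> list[tuple[int | None, int | None]]:
    """Needleman-Wunsch with the same scoring and tie-breaking conventions."""
    if scoring is None:
        scoring = AlignmentScoring()
    a, b = seq_a.upper(), seq_b.upper()
    n, m = len(a), len(b)
    F = np.zeros((n + 1, m + 1))
    F[:, 0] = scoring.gap * np.arange(n + 1)
    F[0, :] = scoring.gap * np.arange(m + 1)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr[1:, 0], ptr[0, 1:] = 2, 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = F[i - 1, j - 1] + (
                scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            )
            up = F[i - 1, j] + scoring.gap
            left = F[i, j - 1] + scoring.gap
            score, p = diag, 1
            if up > score:
                score, p = up, 2
            if left > score:
                score, p = left, 3
            F[i, j], ptr[i, j] = score, p
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 1:
            cols.append((i, j))
            i, j = i - 1, j - 1
        elif p == 2:
            cols.append((i, None))
            i -= 1
        else:
            cols.append((None, j))
            j -= 1
    cols.reverse()
    return cols


def center_star_msa(seqs: Sequence[str], scoring: AlignmentScoring | None = None) -> list[str]:
    """Tiny center-star MSA for synthetic fixtures (the first sequence is the
    star centre).  Not intended for real data."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    center = seqs[0]
    rows = [list(center)]
    for other in seqs[1:]:
        cols = global_align(center, other, scoring)
        merged: list[list[str]] = [[] for _ in rows]
        other_row: list[str] = []
        pos_in_rows = 0
        # existing column index for each centre residue
        residue_cols = [k for k, ch in enumerate(rows[0]) if ch != GAP]
        for ci, oj in cols:
            if ci is not None:
                target = residue_cols[ci - 1]
                while pos_in_rows <= target:
                    for r, mr in zip(rows, merged):
                        mr.append(r[pos_in_rows])
                    other_row.append(GAP)
                    pos_in_rows += 1
                other_row[-1] = other[oj - 1] if oj is not None else GAP
            else:
                for mr in merged:
                    mr.append(GAP)
                other_row.append(other[oj - 1])
        while pos_in_rows < len(rows[0]):
            for r, mr in zip(rows, merged):
                mr.append(r[pos_in_rows])
            other_row.append(GAP)
            pos_in_rows += 1
        rows = merged + [other_row]
    return ["".join(r) for r in rows]
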
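"""Correlation and group-comparison statistics for Psi stoichiometry.

This layer links per-tissue Psi stoichiometry to translation efficiency and
mRNA stability:

* per-(site, transcript) Pearson correlations across tissues, summarised by
  the median r per site and a positive/negative sign tally;
* per-(tRNA site, codon) correlations pooled by cloverleaf region with a
  sign odds ratio (positives over negatives) tested one-tailed against a
  fair-coin null;
* quantile-group analyses of mRNA lifetime and translation efficiency
  against the per-transcript summed Psi fraction, compared with one-tailed
  Wilcoxon rank-sum tests (exact by enumeration for small samples).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def percent_share(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` in ``total`` rounded to ``ndigits`` decimals
    (e.g. a species' share of uridines that are pseudouridylated)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _pvals_from_r(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return 2.0 * sps.t.sf(np.abs(t), n - 2)


# ---------------------------------------------------------------------------
# site x transcript correlations over tissues
# ---------------------------------------------------------------------------

@dataclass
class SiteTECorrelation:
    records: pd.DataFrame        # site, transcript, r, p, n_tissues
    site_median: pd.Series       # median r per site over transcripts
    n_positive: int              # sites with positive median r
    n_negative: int
    skipped_sites: list[str] = field(default_factory=list)

    @property
    def positive_share(self) -> float:
        total = self.n_positive + self.n_negative
        return self.n_positive / total if total else float("nan")


def site_te_correlation(
    site_matrix: pd.DataFrame,
    te_matrix: pd.DataFrame,
    min_tissues: int = 3,
) -> SiteTECorrelation:
    """Correlate each site's stoichiometry with each transcript's TE across
    tissues.

    ``site_matrix`` is sites x tissues (NaN = not called), ``te_matrix`` is
    transcripts x tissues.  A site measured in fewer than ``min_tissues``
    tissues, or with zero variance, is skipped; so is any (site, transcript)
    pair whose TE has zero variance over the shared tissues.  The summary is
    the median r per site and the tally of positive/negative medians.
    """
    shared = site_matrix.columns.intersection(te_matrix.columns)
    te = te_matrix[shared]
    rec_frames = []
    medians = {}
    skipped = []
    for site, row in site_matrix[shared].iterrows():
        mask = row.notna().to_numpy()
        n = int(mask.sum())
        if n < min_tissues:
            skipped.append(site)
            continue
        x = row.to_numpy(dtype=float)[mask]
        if x.std() == 0:
            skipped.append(site)
            continue
        sub = te.to_numpy(dtype=float)[:, mask]
        sd = sub.std(axis=1)
        ok = sd > 0
        if not ok.any():
            skipped.append(site)
            continue
        xz = (x - x.mean()) / x.std()
        sz = (sub[ok] - sub[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
        r = sz @ xz / n
        p = _pvals_from_r(r, n)
        rec_frames.append(pd.DataFrame({
            "site": site,
            "transcript": te.index[ok],
            "r": r,
            "p": p,
            "n_tissues": n,
        }))
        medians[site] = float(np.median(r))
    records = (
        pd.concat(rec_frames, ignore_index=True)
        if rec_frames
        else pd.DataFrame(columns=["site", "transcript", "r", "p", "n_tissues"])
    )
    med = pd.Series(medians, name="median_r")
    return SiteTECorrelation(
        records=records,
        site_median=med,
        n_positive=int((med > 0).sum()),
        n_negative=int((med < 0).sum()),
        skipped_sites=skipped,
    )


def binomial_band(n: int, level: float = 0.99) -> tuple[int, int]:
    """Central binomial(n, 1/2) acceptance band on the count scale."""
    alpha = (1 - level) / 2
    return int(sps.binom.ppf(alpha, n, 0.5)), int(sps.binom.ppf(1 - alpha, n, 0.5))


# ---------------------------------------------------------------------------
# gene grouping by structural features
# ---------------------------------------------------------------------------

def relative_utr5_length(utr5_len: pd.Series, cds_len: pd.Series) -> pd.Series:
    """5'-UTR length relative to CDS length; zero-CDS transcripts excluded."""
    keep = cds_len > 0
    out = utr5_len[keep] / cds_len[keep]
    out.name = "relative_utr5_length"
    return out


def group_by_feature(feature: pd.Series, k: int = 5) -> pd.Series:
    """Split into k quantile groups of equal size (+-1).

    Ties are broken by a stable sort on (feature value, index label), so
    group assignment is reproducible.  Groups are labelled 0 (lowest) to
    k-1 (highest).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    feature = feature.dropna()
    if len(feature) < k:
        raise ValueError("fewer observations than groups")
    order = feature.reset_index()
    order.columns = ["_id", "_value"]
    order = order.sort_values(["_value", "_id"], kind="mergesort")
    chunks = np.array_split(np.arange(len(order)), k)
    labels = np.empty(len(order), dtype=int)
    for g, chunk in enumerate(chunks):
        labels[chunk] = g
    out = pd.Series(labels, index=order["_id"].to_numpy(), name="group")
    return out.reindex(feature.index)


# ---------------------------------------------------------------------------
# tRNA region correlations and sign odds ratio
# ---------------------------------------------------------------------------

def trna_region_te_correlation(
    trna_sites: pd.DataFrame,
    decode: pd.DataFrame,
    e_codon: pd.DataFrame,
    min_tissues: int = 3,
) -> pd.DataFrame:
    """Correlate each tRNA site's stoichiometry with the E_codon of every
    codon its tRNA decodes, across tissues.

    ``trna_sites`` is long format (trna_id, position, region, tissue,
    fraction); ``decode`` maps trna_id -> codon (one row per decoded codon);
    ``e_codon`` is codons x tissues.  Returns one record per (site, codon)
    with its region label, for pooling by region.
    """
    if trna_sites["region"].isna().any():
        raise ValueError("every tRNA site needs a region label")
    frac = trna_sites.pivot_table(
        index=["trna_id", "position", "region"], columns="tissue",
        values="fraction", aggfunc="first",
    )
    shared = frac.columns.intersection(e_codon.columns)
    rows = []
    for (trna_id, position, region), row in frac.iterrows():
        x = row[shared].dropna()
        if len(x) < min_tissues or x.std() == 0:
            continue
        for codon in decode.loc[decode["trna_id"] == trna_id, "codon"]:
            if codon not in e_codon.index:
                continue
            y = e_codon.loc[codon, x.index]
            if y.std() == 0:
                continue
            r, p = pearson_r(x.to_numpy(), y.to_numpy())
            rows.append((trna_id, position, region, codon, r, p, len(x)))
    return pd.DataFrame(
        rows,
        columns=["trna_id", "position", "region", "codon", "r", "p", "n_tissues"],
    )


@dataclass
class SignOddsRatio:
    n_positive: int
    n_negative: int
    odds_ratio: float      # inf when n_negative == 0
    p_value: float         # one-tailed binomial, null probability 0.5

    @property
    def n(self) -> int:
        return self.n_positive + self.n_negative


def sign_odds_ratio(correlations: Sequence[float]) -> SignOddsRatio:
    """Positives over negatives among correlation signs, with a one-tailed
    binomial test of P(positive) = 0.5.  Exact zeros are excluded."""
    r = np.asarray(list(correlations), dtype=float)
    if len(r) == 0:
        raise ValueError("need at least one correlation")
    n_pos = int((r > 0).sum())
    n_neg = int((r < 0).sum())
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("all correlations are exactly zero")
    odds = float("inf") if n_neg == 0 else n_pos / n_neg
    p = float(sps.binom.sf(n_pos - 1, n, 0.5))
    return SignOddsRatio(n_pos, n_neg, odds, p)


# ---------------------------------------------------------------------------
# one-tailed Wilcoxon rank-sum
# ---------------------------------------------------------------------------

EXACT_ENUMERATION_MAX_N = 12


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values)


def wilcoxon_one_tailed(
    a: Sequence[float], b: Sequence[float], alternative: str = "less"
) -> float:
    """One-tailed Wilcoxon rank-sum p-value.

    ``alternative='less'`` tests whether ``a`` tends to take smaller values
    than ``b``.  For combined sample sizes up to 12 the p-value is exact,
    by enumerating every assignment of the (mid)ranks to group a; larger
    samples use the normal approximation with tie correction and a
    continuity correction.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    w_obs = ranks[:na].sum()
    n = na + nb
    if n <= EXACT_ENUMERATION_MAX_N:
        total = math.comb(n, na)
        count = 0
        for idx in itertools.combinations(range(n), na):
            w = ranks[list(idx)].sum()
            if alternative == "less":
                count += w <= w_obs + 1e-9
            else:
                count += w >= w_obs - 1e-9
        return count / total
    mu = na * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    sd = math.sqrt(var)
    if sd == 0:
        return 1.0
    if alternative == "less":
        z = (w_obs - mu + 0.5) / sd
        return float(sps.norm.cdf(z))
    z = (w_obs - mu - 0.5) / sd
    return float(sps.norm.sf(z))


# ---------------------------------------------------------------------------
# quantile-group analyses of lifetime and TE
# ---------------------------------------------------------------------------

@dataclass
class GroupAnalysis:
    """Quantile groups of transcripts by summed Psi fraction, with the
    distribution of an outcome (lifetime or TE) per group."""

    groups: pd.DataFrame      # group, n, feature_median, value_median, value_iqr
    contrasts: pd.DataFrame   # group_low, group_high, p, q (BH)
    assignments: pd.Series    # transcript -> group
    alternative: str

    @property
    def medians_monotone_decreasing(self) -> bool:
        med = self.groups["value_median"].to_numpy()
        return bool(np.all(np.diff(med) < 0))

    @property
    def medians_monotone_increasing(self) -> bool:
        med = self.groups["value_median"].to_numpy()
        return bool(np.all(np.diff(med) > 0))

    @property
    def bottom_vs_top_p(self) -> float:
        lo, hi = self.groups["group"].min(), self.groups["group"].max()
        row = self.contrasts[
            (self.contrasts["group_low"] == lo) & (self.contrasts["group_high"] == hi)
        ]
        return float(row["p"].iloc[0])


def _grouped_outcome(
    summed_fraction: pd.Series,
    outcome: pd.Series,
    k: int,
    alternative: str,
) -> GroupAnalysis:
    shared = summed_fraction.index.intersection(outcome.index)
    if len(shared) < 2 * k:
        raise ValueError("too few matched transcripts for grouping")
    s, y = summed_fraction[shared], outcome[shared]
    groups = group_by_feature(s, k=k)
    nonempty = sorted(groups.unique())
    if len(nonempty) < 2:
        raise ValueError("fewer than 2 non-empty groups")
    rows = []
    for g in nonempty:
        members = groups.index[groups == g]
        vals = y[members]
        rows.append({
            "group": g,
            "n": len(members),
            "feature_median": float(s[members].median()),
            "value_median": float(vals.median()),
            "value_iqr": float(vals.quantile(0.75) - vals.quantile(0.25)),
        })
    table = pd.DataFrame(rows)
    contrasts = []
    for lo, hi in itertools.combinations(nonempty, 2):
        a = y[groups.index[groups == hi]]  # higher-Psi group
        b = y[groups.index[groups == lo]]
        p = wilcoxon_one_tailed(a, b, alternative=alternative)
        contrasts.append({"group_low": lo, "group_high": hi, "p": p})
    contrasts = pd.DataFrame(contrasts)
    _, q, _, _ = multipletests(contrasts["p"], method="fdr_bh")
    contrasts["q"] = q
    return GroupAnalysis(
        groups=table, contrasts=contrasts, assignments=groups,
        alternative=alternative,
    )


def lifetime_group_analysis(
    summed_fraction: pd.Series, lifetimes: pd.Series, k: int = 4
) -> GroupAnalysis:
    """Quantile groups on the summed Psi fraction versus mRNA lifetime.

    Contrasts test one-tailed whether the higher-Psi group has *shorter*
    lifetimes (the inverse stability association).
    """
    return _grouped_outcome(summed_fraction, lifetimes, k, alternative="less")


def te_group_analysis(
    summed_fraction: pd.Series,
    e_transcript: pd.Series,
    k: int = 3,
    strata: pd.Series | None = None,
) -> GroupAnalysis | dict[str, GroupAnalysis]:
    """Tertile groups (low/medium/high summed Psi fraction) versus
    E_transcript; contrasts test one-tailed whether the higher-Psi group has
    *higher* TE.  With ``strata`` (transcript -> label, e.g. 5UTR vs
    non-5UTR site location) the analysis runs per stratum.
    """
    if strata is None:
        return _grouped_outcome(summed_fraction, e_transcript, k,
                                alternative="greater")
    out = {}
    for label in sorted(strata.dropna().unique()):
        members = strata.index[strata == label]
        out[str(label)] = _grouped_outcome(
            summed_fraction[summed_fraction.index.intersection(members)],
            e_transcript, k, alternative="greater",
        )
    return out
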
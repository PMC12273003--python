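"""Gene-structure annotation of Psi sites.

Transcripts are segmented into 5'-UTR, CDS and 3'-UTR (and, when an
annotation provides them, exon/intron intervals).  This module assigns
called sites to regions, builds metagene and per-region density profiles,
classifies how sites are shared across tissues, and sums per-site
stoichiometries into a per-transcript modification load.

Coordinates are 1-based inclusive throughout, matching the site tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UTR5, CDS, UTR3 = "5UTR", "CDS", "3UTR"
REGION_ORDER = (UTR5, CDS, UTR3)


@dataclass
class TranscriptModel:
    """A transcript segmented into 5'-UTR | CDS | 3'-UTR.

    Regions are stored as 1-based inclusive intervals in transcript
    coordinates, ordered 5'->3'.  ``introns`` is optional and used only by
    the exon/intron labelling scheme (e.g. sites mapped on unspliced
    coordinates); when empty the whole transcript is exonic.
    """

    transcript_id: str
    gene_id: str
    strand: str = "+"
    regions: tuple[tuple[str, int, int], ...] = ()
    introns: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        last_end = 0
        for label, start, end in self.regions:
            if label not in REGION_ORDER:
                raise ValueError(f"unknown region label {label!r}")
            if start < 1 or end < start - 1:  # end == start-1 encodes empty
                raise ValueError(f"bad interval {label} {start}-{end}")
            if start <= last_end:
                raise ValueError("regions overlap or are unordered")
            last_end = max(last_end, end)
        if self.cds_len % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_len} not a multiple of 3"
            )

    @classmethod
    def from_lengths(
        cls,
        transcript_id: str,
        utr5_len: int,
        cds_len: int,
        utr3_len: int,
        gene_id: str | None = None,
        strand: str = "+",
    ) -> "TranscriptModel":
        regions = []
        pos = 1
        for label, length in zip(REGION_ORDER, (utr5_len, cds_len, utr3_len)):
            if length > 0:
                regions.append((label, pos, pos + length - 1))
                pos += length
        return cls(
            transcript_id=transcript_id,
            gene_id=gene_id or transcript_id,
            strand=strand,
            regions=tuple(regions),
        )

    def region_interval(self, label: str) -> tuple[int, int] | None:
        for lab, start, end in self.regions:
            if lab == label:
                return start, end
        return None

    def region_length(self, label: str) -> int:
        iv = self.region_interval(label)
        return 0 if iv is None else iv[1] - iv[0] + 1

    @property
    def utr5_len(self) -> int:
        return self.region_length(UTR5)

    @property
    def cds_len(self) -> int:
        return self.region_length(CDS)

    @property
    def utr3_len(self) -> int:
        return self.region_length(UTR3)

    @property
    def length(self) -> int:
        return max((end for _, _, end in self.regions), default=0)


def assign_region(
    position: int, model: TranscriptModel | None, scheme: str = "utr_cds"
) -> str:
    """Label a 1-based site position within a transcript model.

    ``scheme='utr_cds'`` returns one of {5UTR, CDS, 3UTR, intergenic};
    ``scheme='exon_intron'`` returns one of {exon, intron, intergenic}.
    A missing model, or a position outside it, is intergenic.
    """
    if model is None or position < 1 or position > model.length:
        return "intergenic"
    if scheme == "exon_intron":
        for start, end in model.introns:
            if start <= position <= end:
                return "intron"
        return "exon"
    if scheme != "utr_cds":
        raise ValueError(f"unknown scheme {scheme!r}")
    for label, start, end in model.regions:
        if start <= position <= end:
            return label
    return "intergenic"


def assign_regions(
    sites: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    scheme: str = "utr_cds",
    ref_col: str = "ref_id",
    pos_col: str = "pos",
) -> pd.Series:
    """Vector version of :func:`assign_region` over a site table."""
    labels = [
        assign_region(int(pos), models.get(ref), scheme)
        for ref, pos in zip(sites[ref_col], sites[pos_col])
    ]
    return pd.Series(labels, index=sites.index, name=f"region_{scheme}")


def metagene_profile(
    sites: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    bins_per_region: int = 30,
    ref_col: str = "ref_id",
    pos_col: str = "pos",
) -> pd.DataFrame:
    """Site density over the concatenated 5UTR | CDS | 3UTR metagene axis.

    Each site is placed at its relative position within its own region and
    binned into ``bins_per_region`` bins per region (regions drawn at equal
    width regardless of their nucleotide lengths).  Densities sum to 1 over
    all occupied-able bins; an empty site list yields an all-zero profile.
    """
    counts = np.zeros(3 * bins_per_region)
    for ref, pos in zip(sites[ref_col], sites[pos_col]):
        model = models.get(ref)
        if model is None:
            continue
        label = assign_region(int(pos), model)
        if label not in REGION_ORDER:
            continue
        start, end = model.region_interval(label)
        span = end - start + 1
        rel = (int(pos) - start) / span  # in [0, 1)
        b = min(int(rel * bins_per_region), bins_per_region - 1)
        counts[REGION_ORDER.index(label) * bins_per_region + b] += 1
    total = counts.sum()
    density = counts / total if total > 0 else counts
    return pd.DataFrame(
        {
            "region": np.repeat(REGION_ORDER, bins_per_region),
            "bin": np.tile(np.arange(bins_per_region), 3),
            "count": counts.astype(int),
            "density": density,
        }
    )


def region_density(
    sites: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    ref_col: str = "ref_id",
    pos_col: str = "pos",
) -> pd.DataFrame:
    """Sites per nucleotide per region, normalised by the total region length
    across the supplied (i.e. expressed) transcript models."""
    total_nt = {label: 0 for label in REGION_ORDER}
    for model in models.values():
        for label in REGION_ORDER:
            total_nt[label] += model.region_length(label)
    n_sites = {label: 0 for label in REGION_ORDER}
    for ref, pos in zip(sites[ref_col], sites[pos_col]):
        label = assign_region(int(pos), models.get(ref))
        if label in n_sites:
            n_sites[label] += 1
    rows = []
    for label in REGION_ORDER:
        if total_nt[label] == 0:
            import warnings

            warnings.warn(f"region {label} has zero total length; omitted")
            continue
        rows.append(
            {
                "region": label,
                "n_sites": n_sites[label],
                "total_nt": total_nt[label],
                "density": n_sites[label] / total_nt[label],
            }
        )
    return pd.DataFrame(rows)


def build_site_matrix(
    site_tables: Mapping[str, pd.DataFrame],
    value_col: str = "fraction",
) -> pd.DataFrame:
    """Assemble per-tissue site tables into a sites x tissues fraction matrix.

    Rows are keyed ``ref_id:pos:strand``; a missing entry (NaN) means the
    site was not called in that tissue.
    """
    columns = {}
    for tissue, table in site_tables.items():
        if len(table) == 0:
            columns[tissue] = pd.Series(dtype=float)
            continue
        keys = (
            table["ref_id"].astype(str)
            + ":"
            + table["pos"].astype(int).astype(str)
            + ":"
            + table["strand"].astype(str)
        )
        columns[tissue] = pd.Series(table[value_col].to_numpy(), index=keys)
    matrix = pd.DataFrame(columns)
    matrix.index.name = "site"
    return matrix


def classify_tissue_sharing(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Label each site row of a sites x tissues matrix.

    ``shared_all`` -- called (non-NaN) in every tissue; ``unique:<tissue>`` --
    called in exactly one; ``partial`` otherwise.  Returns (labels, counts)
    where counts aggregates all unique:* labels under ``unique``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("tissue sharing needs at least 2 tissues")
    present = matrix.notna()
    n_present = present.sum(axis=1)
    labels = []
    for site, n in n_present.items():
        if n == matrix.shape[1]:
            labels.append("shared_all")
        elif n == 1:
            tissue = present.columns[present.loc[site].to_numpy().argmax()]
            labels.append(f"unique:{tissue}")
        else:
            labels.append("partial")
    labels = pd.Series(labels, index=matrix.index, name="sharing")
    simplified = labels.str.replace(r"unique:.*", "unique", regex=True)
    counts = simplified.value_counts().reindex(
        ["shared_all", "unique", "partial"], fill_value=0
    )
    return labels, counts


def summed_fraction_per_transcript(
    sites: pd.DataFrame,
    ref_col: str = "ref_id",
    fraction_col: str = "fraction",
) -> pd.Series:
    """Sum of Psi fractions per transcript; transcripts without sites are
    simply absent from the result."""
    if len(sites) == 0:
        return pd.Series(dtype=float, name="summed_fraction")
    out = sites.groupby(ref_col)[fraction_col].sum()
    out.name = "summed_fraction"
    return out
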
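"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a multi-tissue BID-seq /
polysome-profiling study: a transcriptome of UTR|CDS|UTR transcripts, Psi
sites planted at uridine positions with tissue-resolved stoichiometries, a
binomial deletion signal on top of a background deletion rate, ribosome
footprint coverage shaped by per-codon dwell times, RNA abundance, and mRNA
lifetimes with a planted (negative) dependence on the summed Psi load.

Everything is deterministic under ``SimConfig.seed``: each tissue/replicate
consumes its own child stream spawned from the global seed, so adding a
replicate never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotate import TranscriptModel
from .psicall import CalibrationCurve, reverse_complement

BASES = np.array(list("ACGT"))
STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]

#: Tissue panel mirroring a nine-organ dicot survey (used when n_tissues <= 9).
TISSUE_PANEL = (
    "seedling", "shoot", "root", "rosette_leaf", "cauline_leaf",
    "stem", "flower", "silique", "seed",
)

TRNA_LENGTH = 76
#: Cloverleaf region labels for positions 1..76.  Linker positions 8, 9 and
#: 26 are folded into the adjacent stems so the eight labels cover every
#: position.
_TRNA_REGION_SPANS = (
    ("acceptor-stem", 1, 7),
    ("D-arm-stem", 8, 13),
    ("D-arm-loop", 14, 21),
    ("D-arm-stem", 22, 25),
    ("anticodon-arm-stem", 26, 31),
    ("anticodon-arm-loop", 32, 38),
    ("anticodon-arm-stem", 39, 43),
    ("variable", 44, 48),
    ("T-arm-stem", 49, 53),
    ("T-arm-loop", 54, 60),
    ("T-arm-stem", 61, 65),
    ("acceptor-stem", 66, 76),
)
#: One planted Psi site per structural region (position -> region).
TRNA_SITE_POSITIONS = {
    4: "acceptor-stem",
    11: "D-arm-stem",
    17: "D-arm-loop",
    30: "anticodon-arm-stem",
    38: "anticodon-arm-loop",
    50: "T-arm-stem",
    55: "T-arm-loop",
}
#: Relative coupling strength of each loop to its codon's dwell time.
TRNA_LOOP_WEIGHTS = {
    "T-arm-loop": 1.0,
    "anticodon-arm-loop": 0.5,
    "D-arm-loop": 0.5,
}


def trna_region_of(position: int) -> str:
    for label, lo, hi in _TRNA_REGION_SPANS:
        if lo <= position <= hi:
            return label
    raise ValueError(f"position {position} outside tRNA model")


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe the simulated survey: ~200 planted mRNA Psi sites over
    60 transcripts, sequencing depth ~1000x (negative binomial), background
    deletion rate 1%, nine tissues with two BID-seq replicates each, planted
    codon dwell times spanning [0.5, 2], and negative/positive planted slopes
    of log-lifetime / log-TE on the summed Psi fraction.
    """

    n_genes: int = 60
    utr5_len_range: tuple[int, int] = (30, 150)
    cds_len_range: tuple[int, int] = (300, 900)
    utr3_len_range: tuple[int, int] = (60, 240)
    n_tissues: int = 9
    n_replicates: int = 2
    # -- planted Psi sites -------------------------------------------------
    psi_site_rate: float = 0.017
    share_all_tissues: float = 0.30
    share_unique: float = 0.30
    fraction_low_weight: float = 0.78
    fraction_low_beta: tuple[float, float] = (1.2, 12.0)
    fraction_high_beta: tuple[float, float] = (5.0, 2.0)
    tissue_fraction_sd: float = 0.08
    # -- BID-seq signal ----------------------------------------------------
    background_deletion_rate: float = 0.01
    depth_mean: float = 1000.0
    depth_dispersion: float = 10.0
    calibration: CalibrationCurve | None = None  # None -> identity curve
    # -- ribosome footprints ----------------------------------------------
    footprint_reads_per_codon: float = 20.0
    dwell_noise_sd: float = 0.15
    dwell_range: tuple[float, float] = (0.5, 2.0)
    # -- tRNA layer --------------------------------------------------------
    trna_fraction_sd: float = 0.12
    trna_loop_coupling: float = 1.0
    codon_dwell_tissue_sd: float = 0.03
    # -- transcript-level effects -----------------------------------------
    te_effect: float = 0.5
    te_noise_sd: float = 0.3
    lifetime_effect: float = -0.5
    lifetime_noise_sd: float = 0.3
    lifetime_baseline_hours: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("psi_site_rate", "share_all_tissues", "share_unique",
                     "fraction_low_weight", "background_deletion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.share_all_tissues + self.share_unique > 1.0:
            raise ValueError("tissue-sharing shares exceed 1")
        for name in ("utr5_len_range", "cds_len_range", "utr3_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name}=({lo},{hi}) is empty or negative")
        if self.cds_len_range[1] < 3:
            raise ValueError("CDS range admits no codons")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_genes < 1 or self.n_tissues < 1:
            raise ValueError("n_genes and n_tissues must be >= 1")
        if self.dwell_noise_sd < 0:
            raise ValueError("dwell_noise_sd must be non-negative")

    @property
    def curve(self) -> CalibrationCurve:
        return self.calibration or CalibrationCurve.identity()

    def tissue_names(self) -> list[str]:
        if self.n_tissues <= len(TISSUE_PANEL):
            return list(TISSUE_PANEL[: self.n_tissues])
        return [f"tissue{i:02d}" for i in range(self.n_tissues)]


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    """Hierarchical stream: same seed + same key -> same stream, always."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def make_transcriptome(
    config: SimConfig,
) -> tuple[dict[str, TranscriptModel], dict[str, str]]:
    """Random transcripts with 5'-UTR | CDS (ATG..stop) | 3'-UTR structure."""
    rng = _rng(config, 0)
    models: dict[str, TranscriptModel] = {}
    sequences: dict[str, str] = {}
    for g in range(config.n_genes):
        tid = f"gene{g:04d}"
        u5 = int(rng.integers(config.utr5_len_range[0], config.utr5_len_range[1] + 1))
        u3 = int(rng.integers(config.utr3_len_range[0], config.utr3_len_range[1] + 1))
        lo = max(config.cds_len_range[0] // 3, 3)  # >= ATG + codon + stop
        hi = config.cds_len_range[1] // 3
        n_codons = int(rng.integers(lo, hi + 1))
        internal = rng.choice(SENSE_CODONS, size=n_codons - 2)
        cds = "ATG" + "".join(internal) + str(rng.choice(STOP_CODONS))
        seq = (
            "".join(rng.choice(BASES, size=u5))
            + cds
            + "".join(rng.choice(BASES, size=u3))
        )
        models[tid] = TranscriptModel.from_lengths(tid, u5, len(cds), u3)
        sequences[tid] = seq
    return models, sequences


# ---------------------------------------------------------------------------
# planted Psi sites
# ---------------------------------------------------------------------------

def sample_fractions(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Planted stoichiometries: a two-component Beta mixture with most mass
    below 0.2 and a minority component above 0.5."""
    low = rng.random(n) < config.fraction_low_weight
    out = np.where(
        low,
        rng.beta(*config.fraction_low_beta, size=n),
        rng.beta(*config.fraction_high_beta, size=n),
    )
    return np.clip(out, 0.005, 0.995)


def plant_psi_sites(
    models: Mapping[str, TranscriptModel],
    sequences: Mapping[str, str],
    config: SimConfig,
) -> pd.DataFrame:
    """Plant Psi sites at uridine positions; returns the long truth table
    (transcript_id, pos, strand, tissue, true_fraction, base_fraction).

    A ``share_all_tissues`` share of sites is present in every tissue, a
    ``share_unique`` share in exactly one, the rest in a random subset.
    """
    rng = _rng(config, 1)
    tissues = config.tissue_names()
    rows: list[tuple] = []
    for tid in sorted(models):
        seq = sequences[tid]
        t_pos = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) == ord("T")) + 1
        planted = t_pos[rng.random(len(t_pos)) < config.psi_site_rate]
        if len(planted) == 0:
            continue
        bases = sample_fractions(config, rng, len(planted))
        for pos, base in zip(planted, bases):
            u = rng.random()
            if config.n_tissues == 1 or u < config.share_all_tissues:
                chosen = tissues
            elif u < config.share_all_tissues + config.share_unique:
                chosen = [tissues[int(rng.integers(config.n_tissues))]]
            else:
                k = int(rng.integers(2, config.n_tissues)) if config.n_tissues > 2 else 2
                chosen = [tissues[i] for i in sorted(
                    rng.choice(config.n_tissues, size=min(k, config.n_tissues), replace=False)
                )]
            for tissue in chosen:
                f = float(np.clip(
                    base + rng.normal(0.0, config.tissue_fraction_sd), 0.01, 0.99
                ))
                rows.append((tid, int(pos), "+", tissue, f, float(base)))
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "pos", "strand", "tissue",
                 "true_fraction", "base_fraction"],
    )


def truth_site_matrix(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Pivot the truth table to a sites x tissues fraction matrix."""
    if len(truth) == 0:
        return pd.DataFrame(columns=config.tissue_names())
    keyed = truth.assign(
        site=truth["transcript_id"] + ":" + truth["pos"].astype(str) + ":" + truth["strand"]
    )
    matrix = keyed.pivot_table(
        index="site", columns="tissue", values="true_fraction", aggfunc="first"
    )
    return matrix.reindex(columns=config.tissue_names())


def summed_truth_fraction(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-transcript sum of planted fractions, per tissue (0 where no site)."""
    if len(truth) == 0:
        return pd.DataFrame(columns=config.tissue_names())
    out = truth.pivot_table(
        index="transcript_id", columns="tissue", values="true_fraction", aggfunc="sum"
    )
    return out.reindex(columns=config.tissue_names()).fillna(0.0)


# ---------------------------------------------------------------------------
# BID-seq pileups
# ---------------------------------------------------------------------------

def simulate_bidseq_pileup(
    truth: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    config: SimConfig,
    tissues: Sequence[str] | None = None,
) -> dict[tuple[str, int], pd.DataFrame]:
    """Per (tissue, replicate) pileups over every transcript position.

    Depth is negative binomial (mean ``depth_mean``, dispersion
    ``depth_dispersion``).  At a planted site with fraction f the deletion
    count is Binomial(depth, g(f) + bg) where g inverts the configured
    calibration curve; elsewhere it is Binomial(depth, bg).
    """
    tissue_list = config.tissue_names()
    wanted = tissue_list if tissues is None else list(tissues)
    tids = sorted(models)
    lengths = np.array([models[t].length for t in tids])
    offsets = dict(zip(tids, np.concatenate([[0], np.cumsum(lengths)[:-1]])))
    n_pos = int(lengths.sum())
    ref_col = np.repeat(tids, lengths)
    pos_col = np.concatenate([np.arange(1, L + 1) for L in lengths])

    bg = config.background_deletion_rate
    curve = config.curve
    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.depth_mean)

    out: dict[tuple[str, int], pd.DataFrame] = {}
    for tissue in wanted:
        t_idx = tissue_list.index(tissue)
        p_del = np.full(n_pos, bg)
        sub = truth[truth["tissue"] == tissue]
        if len(sub):
            idx = np.array([
                offsets[t] + p - 1 for t, p in zip(sub["transcript_id"], sub["pos"])
            ])
            p_del[idx] = np.clip(
                curve.gap_for_fraction(sub["true_fraction"].to_numpy()) + bg, 0.0, 1.0
            )
        for rep in range(config.n_replicates):
            rng = _rng(config, 2, t_idx, rep)
            depth = rng.negative_binomial(nb_n, nb_p, size=n_pos)
            dele = rng.binomial(depth, p_del)
            out[(tissue, rep)] = pd.DataFrame(
                {
                    "ref_id": ref_col,
                    "pos": pos_col,
                    "strand": "+",
                    "total_reads": depth,
                    "deletion_reads": dele,
                }
            )
    return out


# ---------------------------------------------------------------------------
# tRNA layer
# ---------------------------------------------------------------------------

@dataclass
class TRNASet:
    """Synthetic tRNA complement: per-position models, anticodon->codon
    decoding map, and the planted per-tissue site stoichiometries."""

    table: pd.DataFrame      # trna_id, position, base, region, anticodon
    decode: pd.DataFrame     # trna_id, codon
    sites: pd.DataFrame      # trna_id, position, region, tissue, fraction


def _trna_inventory() -> list[tuple[str, str, list[str]]]:
    """(trna_id, anticodon, decoded codons); G34 anticodons wobble-decode the
    third-base C and T codons, everything else is read one-to-one."""
    inventory = []
    for codon in SENSE_CODONS:
        third = codon[2]
        if third == "T" and (codon[:2] + "C") in SENSE_CODONS:
            continue  # covered by the G34 wobble tRNA of the C-ending codon
        anticodon = reverse_complement(codon)
        decoded = [codon]
        if third == "C":
            sibling = codon[:2] + "T"
            if sibling in SENSE_CODONS:
                decoded.append(sibling)
        aa = str(Seq(codon).translate())
        inventory.append((f"tRNA-{aa}-{anticodon}", anticodon, decoded))
    return inventory


def make_trna_set(config: SimConfig) -> TRNASet:
    """Build the tRNA models and plant per-region Psi sites with per-tissue
    stoichiometries (one site per structural region per tRNA)."""
    rng = _rng(config, 5)
    tissues = config.tissue_names()
    table_rows, decode_rows, site_rows = [], [], []
    for trna_id, anticodon, decoded in _trna_inventory():
        seq = rng.choice(BASES, size=TRNA_LENGTH)
        seq[33:36] = list(anticodon)  # positions 34-36
        for pos in TRNA_SITE_POSITIONS:
            seq[pos - 1] = "T"
        for pos in range(1, TRNA_LENGTH + 1):
            table_rows.append(
                (trna_id, pos, seq[pos - 1], trna_region_of(pos), anticodon)
            )
        for codon in decoded:
            decode_rows.append((trna_id, codon))
        for pos, region in TRNA_SITE_POSITIONS.items():
            base = rng.uniform(0.2, 0.9)
            for tissue in tissues:
                f = float(np.clip(
                    base + rng.normal(0.0, config.trna_fraction_sd), 0.02, 0.98
                ))
                site_rows.append((trna_id, pos, region, tissue, f))
    return TRNASet(
        table=pd.DataFrame(
            table_rows, columns=["trna_id", "position", "base", "region", "anticodon"]
        ),
        decode=pd.DataFrame(decode_rows, columns=["trna_id", "codon"]),
        sites=pd.DataFrame(
            site_rows, columns=["trna_id", "position", "region", "tissue", "fraction"]
        ),
    )


def plant_codon_dwell(trna_set: TRNASet, config: SimConfig) -> pd.DataFrame:
    """True per-codon dwell times per tissue (codons x tissues).

    Baseline dwell is log-uniform over ``dwell_range``.  Loop-region Psi
    stoichiometry lowers the dwell of the decoded codons (faster decoding,
    hence higher codon translation efficiency): T-arm loop at full
    ``trna_loop_coupling``, anticodon-arm and D-arm loops at half strength.
    Stem sites are uncoupled by construction.
    """
    rng = _rng(config, 6)
    tissues = config.tissue_names()
    lo, hi = np.log(config.dwell_range[0]), np.log(config.dwell_range[1])
    base = pd.Series(
        np.exp(rng.uniform(lo, hi, size=len(SENSE_CODONS))), index=SENSE_CODONS
    )
    # site fraction deviations from their own cross-tissue mean
    sites = trna_set.sites
    dev = sites.assign(
        dev=sites["fraction"]
        - sites.groupby(["trna_id", "position"])["fraction"].transform("mean")
    )
    loop_dev = dev[dev["region"].isin(TRNA_LOOP_WEIGHTS)]
    coupled = loop_dev.merge(trna_set.decode, on="trna_id")
    coupled = coupled.assign(
        shift=-config.trna_loop_coupling
        * coupled["region"].map(TRNA_LOOP_WEIGHTS)
        * coupled["dev"]
    )
    shift = coupled.pivot_table(
        index="codon", columns="tissue", values="shift", aggfunc="sum"
    ).reindex(index=SENSE_CODONS, columns=tissues).fillna(0.0)
    noise = rng.normal(0.0, config.codon_dwell_tissue_sd,
                       size=(len(SENSE_CODONS), len(tissues)))
    dwell = np.exp(
        np.log(base.to_numpy())[:, None] + shift.to_numpy() + noise
    )
    return pd.DataFrame(dwell, index=SENSE_CODONS, columns=tissues)


# ---------------------------------------------------------------------------
# expression, footprints, lifetimes
# ---------------------------------------------------------------------------

def simulate_expression(
    models: Mapping[str, TranscriptModel],
    summed_truth: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RNA abundance and true translation efficiency per transcript x tissue.

    log TE = te_effect * (summed Psi fraction) + noise, so a positive
    ``te_effect`` plants the positive Psi-TE association.
    """
    rng = _rng(config, 3)
    tids = sorted(models)
    tissues = config.tissue_names()
    s = summed_truth.reindex(index=tids, columns=tissues).fillna(0.0).to_numpy()
    log_ab = rng.normal(np.log(50.0), 1.0, size=len(tids))[:, None] + rng.normal(
        0.0, 0.2, size=(len(tids), len(tissues))
    )
    abundance = pd.DataFrame(np.exp(log_ab), index=tids, columns=tissues)
    log_te = config.te_effect * s + rng.normal(
        0.0, config.te_noise_sd, size=s.shape
    )
    te = pd.DataFrame(np.exp(log_te), index=tids, columns=tissues)
    return abundance, te


def simulate_footprints(
    models: Mapping[str, TranscriptModel],
    sequences: Mapping[str, str],
    codon_dwell: pd.Series,
    te: pd.Series,
    abundance: pd.Series,
    config: SimConfig,
    rng: np.random.Generator,
    poisson: bool = True,
) -> tuple[dict[str, np.ndarray], pd.Series]:
    """One tissue's ribosome P-site coverage and RNA-seq counts.

    Expected counts at a codon are proportional to
    dwell(codon) * TE(gene) * abundance(gene), scaled so the average codon
    receives ``footprint_reads_per_codon`` reads; multiplicative lognormal
    noise of sd ``dwell_noise_sd`` is applied per codon occurrence.  Counts
    are Poisson unless ``poisson=False`` (then the expectation is returned,
    useful for noise-free checks).  Coverage is placed on the first
    nucleotide of each codon; UTRs receive none.
    """
    tids = sorted(models)
    load = np.array([te[t] * abundance[t] for t in tids])
    mean_load = load.mean() if load.size else 1.0
    coverage: dict[str, np.ndarray] = {}
    rna_counts = {}
    for tid, w in zip(tids, load):
        model, seq = models[tid], sequences[tid]
        cds_start, cds_end = model.region_interval("CDS")
        codons = [seq[i : i + 3] for i in range(cds_start - 1, cds_end, 3)]
        dwell = np.array([codon_dwell.get(c, 1.0) for c in codons])
        lam = config.footprint_reads_per_codon * dwell * (w / mean_load)
        if config.dwell_noise_sd > 0:
            lam = lam * np.exp(
                rng.normal(0.0, config.dwell_noise_sd, size=len(lam))
            )
        counts = rng.poisson(lam) if poisson else lam
        cov = np.zeros(model.length)
        cov[cds_start - 1 : cds_end : 3] = counts
        coverage[tid] = cov
        rna_lam = abundance[tid] * model.length / 100.0
        rna_counts[tid] = rng.poisson(rna_lam) if poisson else rna_lam
    return coverage, pd.Series(rna_counts, name="rna_counts")


def simulate_lifetimes(
    summed_fraction: pd.Series,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """mRNA lifetimes (hours): log-lifetime = baseline + lifetime_effect *
    summed Psi fraction + Gaussian noise.  A negative effect plants the
    inverse Psi-stability association."""
    if rng is None:
        rng = _rng(config, 4)
    s = summed_fraction.to_numpy(dtype=float)
    log_lt = (
        np.log(config.lifetime_baseline_hours)
        + config.lifetime_effect * s
        + (rng.normal(0.0, config.lifetime_noise_sd, size=len(s))
           if config.lifetime_noise_sd > 0 else 0.0)
    )
    return pd.Series(np.exp(log_lt), index=summed_fraction.index, name="lifetime_h")


# ---------------------------------------------------------------------------
# orthologue fixture with planted conservation classes
# ---------------------------------------------------------------------------

@dataclass
class OrthologueFixture:
    """Cross-species gene pairs with known conservation classes.

    ``truth`` columns: gene_a, pos (1-based Psi position in gene_a),
    true_class in {1,2,3,4}.  ``partners`` maps each gene_a to its partner
    sequences in the other species (two partners for class-4 genes).
    """

    seqs_a: dict[str, str]
    partners: dict[str, dict[str, str]]
    truth: pd.DataFrame


def _mutate(seq: str, rng: np.random.Generator, rate: float,
            protect: set[int]) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protect:
            continue
        if rng.random() < rate:
            out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def make_orthologue_fixture(
    seed: int = 0,
    n_per_class: int = 10,
    seq_len: int = 200,
    sub_rate: float = 0.05,
) -> OrthologueFixture:
    """Plant one Psi site per gene with a known class:

    class 1 -- the partner covers only the first half of the gene, the site
    sits in the final quarter (outside any local alignment);
    class 2 -- the partner carries C at the homologous position;
    class 3 -- one partner with U conserved;
    class 4 -- two paralogous partners, both with U conserved.
    """
    rng = np.random.default_rng(seed)
    seqs_a, partners, rows = {}, {}, []
    for cls in (1, 2, 3, 4):
        for i in range(n_per_class):
            gid = f"c{cls}_{i:02d}"
            seq = "".join(rng.choice(BASES, size=seq_len))
            if cls == 1:
                pos = int(rng.integers(int(seq_len * 0.8), seq_len - 2)) + 1
            else:
                pos = int(rng.integers(int(seq_len * 0.3), int(seq_len * 0.7))) + 1
            seq = seq[: pos - 1] + "T" + seq[pos:]
            protect = {pos - 1 + d for d in (-2, -1, 0, 1, 2)}
            if cls == 1:
                partner = _mutate(seq[: seq_len // 2], rng, sub_rate, set())
                partners[gid] = {f"{gid}_b0": partner}
            elif cls == 2:
                p = _mutate(seq, rng, sub_rate, protect)
                p = p[: pos - 1] + "C" + p[pos:]
                partners[gid] = {f"{gid}_b0": p}
            elif cls == 3:
                partners[gid] = {f"{gid}_b0": _mutate(seq, rng, sub_rate, protect)}
            else:
                partners[gid] = {
                    f"{gid}_b0": _mutate(seq, rng, sub_rate, protect),
                    f"{gid}_b1": _mutate(seq, rng, sub_rate, protect),
                }
            seqs_a[gid] = seq
            rows.append((gid, pos, cls))
    return OrthologueFixture(
        seqs_a=seqs_a,
        partners=partners,
        truth=pd.DataFrame(rows, columns=["gene_a", "pos", "true_class"]),
    )


@dataclass
class ConservationFixture:
    """A synthetic rRNA-like MSA with alternating conserved/variable blocks.

    Divergence is substitution-only, so the unaligned sequences are already
    columnwise homologous (the MSA is known by construction).  Psi sites are
    planted preferentially in conserved blocks, the pattern whose recovery
    the density-conservation correlation measures.
    """

    msa: list[str]
    site_positions: list[int]
    block_size: int
    conserved_blocks: list[int]


def make_conservation_fixture(
    seed: int = 0,
    length: int = 1200,
    n_species: int = 4,
    block_size: int = 150,
    conserved_rate: float = 0.02,
    variable_rate: float = 0.30,
    n_sites: int = 40,
) -> ConservationFixture:
    """Alternating conserved (low substitution rate) and variable blocks;
    planted sites fall in conserved blocks with probability 0.9."""
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(BASES, size=length)
    n_blocks = (length + block_size - 1) // block_size
    conserved = [b for b in range(n_blocks) if b % 2 == 0]
    rate = np.where(
        (np.arange(length) // block_size) % 2 == 0, conserved_rate, variable_rate
    )
    msa = []
    for _ in range(n_species):
        seq = ancestor.copy()
        mutate = rng.random(length) < rate
        for i in np.flatnonzero(mutate):
            seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
        msa.append("".join(seq))
    positions = []
    for _ in range(n_sites):
        if rng.random() < 0.9:
            block = int(rng.choice(conserved))
        else:
            block = int(rng.choice([b for b in range(n_blocks) if b % 2 == 1]))
        lo = block * block_size
        hi = min(lo + block_size, length)
        positions.append(int(rng.integers(lo, hi)) + 1)
    return ConservationFixture(
        msa=msa,
        site_positions=sorted(positions),
        block_size=block_size,
        conserved_blocks=conserved,
    )


# ---------------------------------------------------------------------------
# tissue-coupled site/TE matrices (correlation-layer fixture)
# ---------------------------------------------------------------------------

def simulate_tissue_coupling(
    n_sites: int,
    n_transcripts: int,
    n_tissues: int,
    coupling: float,
    seed: int = 0,
    fraction_sd: float = 0.1,
    te_sd: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site-fraction and TE matrices sharing a latent per-tissue factor.

    With ``coupling > 0`` every site's stoichiometry and every transcript's
    TE co-vary through the tissue factor (positive cross-correlations);
    ``coupling = 0`` gives fully independent matrices (the null).
    """
    rng = np.random.default_rng(seed)
    g = rng.normal(size=n_tissues)
    tissues = [f"t{i:02d}" for i in range(n_tissues)]
    base = rng.uniform(0.1, 0.9, size=n_sites)
    frac = np.clip(
        base[:, None]
        + fraction_sd * (coupling * g[None, :]
                         + rng.normal(size=(n_sites, n_tissues))),
        0.01, 0.99,
    )
    log_te = te_sd * (
        coupling * g[None, :] + rng.normal(size=(n_transcripts, n_tissues))
    )
    site_matrix = pd.DataFrame(
        frac, index=[f"site{i:03d}" for i in range(n_sites)], columns=tissues
    )
    te_matrix = pd.DataFrame(
        np.exp(log_te),
        index=[f"tx{i:03d}" for i in range(n_transcripts)],
        columns=tissues,
    )
    return site_matrix, te_matrix


# ---------------------------------------------------------------------------
# one-call orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    """Everything a full synthetic run needs, with ground truth attached."""

    config: SimConfig
    models: dict[str, TranscriptModel]
    sequences: dict[str, str]
    truth: pd.DataFrame
    site_matrix_truth: pd.DataFrame
    summed_truth: pd.DataFrame
    trna_set: TRNASet
    codon_dwell: pd.DataFrame
    abundance: pd.DataFrame
    te: pd.DataFrame
    lifetimes: pd.Series
    pileups: dict[tuple[str, int], pd.DataFrame] = field(default_factory=dict)
    coverage: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    rna_counts: dict[str, pd.Series] = field(default_factory=dict)


def simulate_all(
    config: SimConfig,
    with_pileups: bool = True,
    with_footprints: bool = True,
    tissues: Sequence[str] | None = None,
) -> SimBundle:
    """Run every generator stage under one seed and return the bundle."""
    models, sequences = make_transcriptome(config)
    truth = plant_psi_sites(models, sequences, config)
    summed = summed_truth_fraction(truth, config)
    trna_set = make_trna_set(config)
    dwell = plant_codon_dwell(trna_set, config)
    abundance, te = simulate_expression(models, summed, config)
    seedling = config.tissue_names()[0]
    s0 = summed[seedling] if seedling in summed.columns else pd.Series(
        0.0, index=sorted(models)
    )
    lifetimes = simulate_lifetimes(s0.reindex(sorted(models)).fillna(0.0), config)
    bundle = SimBundle(
        config=config,
        models=models,
        sequences=sequences,
        truth=truth,
        site_matrix_truth=truth_site_matrix(truth, config),
        summed_truth=summed,
        trna_set=trna_set,
        codon_dwell=dwell,
        abundance=abundance,
        te=te,
        lifetimes=lifetimes,
    )
    wanted = config.tissue_names() if tissues is None else list(tissues)
    if with_pileups:
        bundle.pileups = simulate_bidseq_pileup(truth, models, config, wanted)
    if with_footprints:
        for t_idx, tissue in enumerate(config.tissue_names()):
            if tissue not in wanted:
                continue
            rng = _rng(config, 7, t_idx)
            cov, rna = simulate_footprints(
                models, sequences, dwell[tissue], te[tissue],
                abundance[tissue], config, rng,
            )
            bundle.coverage[tissue] = cov
            bundle.rna_counts[tissue] = rna
    return bundle
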
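"""Synthetic genomes, gene annotations and expression studies with planted truth.

Every generator is a pure function of its config and seed, so any run is
reproducible bit for bit. The genome simulator plants motif words at known
Hamming distances from a consensus and then *rejection-samples* the
background until no unplanned window comes within the mismatch budget of
the consensus (on either strand), which makes the recorded truth
exhaustive: a scanner's recall and false-positive count against it are
exact, not approximate.

The expression simulator emulates a two-color-free intensity array design:
each gene carries 1-3 unique probes, each probe synthesized in triplicate
(so 3-9 measurements per gene per sample); each sex has a set of unique
biological replicates plus repeat hybridizations that share their parent's
systematic signal but draw fresh measurement noise. Probe intensities are
log-normal on the raw scale:

    intensity = 2 ** (mu_g + a_p + b_g * x_j + e)

with gene baseline mu_g, probe offset a_p, male indicator x_j, planted
per-gene sex effect b_g (log2 units, positive = male-up) and i.i.d. noise e.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gff_genes
from .expression import ExpressionStudy
from .motif import MotifSpec, hamming, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named deterministic sub-stream of a single global seed."""
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode())])


@dataclass(frozen=True)
class PlantedSiteSpec:
    """Request for `count` sites at exactly `distance` mismatches, on `strand`."""

    distance: int
    count: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.distance < 0 or self.count < 0:
            raise ValueError("distance and count must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class PlantedSite:
    scaffold: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str
    distance: int  # Hamming distance to consensus on the planted strand


@dataclass(frozen=True)
class GenomeSimConfig:
    n_scaffolds: int = 2
    scaffold_length: int = 10_000
    gc_content: float = 0.45
    planted_sites: tuple[PlantedSiteSpec, ...] = ()
    seed: int = 0
    site_min_gap: int = 1  # minimum bp between planted sites (>= 1)

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        if self.scaffold_length < 13:
            raise ValueError("scaffold_length must be >= 13")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if self.site_min_gap < 1:
            raise ValueError("site_min_gap must be >= 1")
        object.__setattr__(
            self,
            "planted_sites",
            tuple(
                s if isinstance(s, PlantedSiteSpec) else PlantedSiteSpec(*s)
                for s in self.planted_sites
            ),
        )


@dataclass(frozen=True)
class ExprSimConfig:
    n_genes: int = 500
    probes_per_gene: tuple[int, int] = (1, 3)
    tech_reps_per_probe: int = 3
    n_unique_per_sex: int = 4
    n_repeat_per_sex: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    probe_offset_sd: float = 0.25
    noise_sd: float = 0.5
    de_fraction: float = 0.1
    effect_size: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.probes_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("probes_per_gene must be an increasing range from >=1")
        if min(self.n_genes, self.tech_reps_per_probe, self.n_unique_per_sex) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_repeat_per_sex < 0:
            raise ValueError("n_repeat_per_sex must be >= 0")
        if self.n_repeat_per_sex > 0 and self.n_repeat_per_sex > self.n_unique_per_sex:
            raise ValueError("cannot have more repeats than unique samples per sex")
        for name in ("baseline_sd", "probe_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")


@dataclass
class Truth:
    """Planted ground truth for a simulated dataset."""

    planted_sites: list[PlantedSite] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)

    def sites_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scaffold": s.scaffold,
                    "start": s.start,
                    "end": s.end,
                    "strand": s.strand,
                    "distance": s.distance,
                }
                for s in self.planted_sites
            ],
            columns=["scaffold", "start", "end", "strand", "distance"],
        )

    def de_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.de_genes.items()), columns=["gene_id", "effect_log2"]
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _mutate_word(consensus: str, distance: int, rng: np.random.Generator) -> str:
    """A word at exactly `distance` mismatches from the consensus."""
    word = list(consensus)
    positions = rng.choice(len(consensus), size=distance, replace=False)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != consensus[p]]
        word[p] = alternatives[rng.integers(3)]
    return "".join(word)


def _place_intervals(
    lengths_by_scaffold: Mapping[str, int],
    n_intervals: int,
    interval_len: int,
    rng: np.random.Generator,
    min_gap: int = 1,
    max_tries: int = 200,
) -> list[tuple[str, int]]:
    """Random non-overlapping (scaffold, start) placements with a minimum gap.

    Raises ValueError when the request cannot be placed (sizing error).
    """
    names = list(lengths_by_scaffold)
    capacity = sum(
        max(0, (lengths_by_scaffold[n] + min_gap) // (interval_len + min_gap))
        for n in names
    )
    if n_intervals > capacity:
        raise ValueError(
            f"cannot place {n_intervals} non-overlapping intervals of "
            f"{interval_len} bp (capacity {capacity})"
        )
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    placements: list[tuple[str, int]] = []
    for _ in range(n_intervals):
        for attempt in range(max_tries):
            scaf = names[rng.integers(len(names))]
            limit = lengths_by_scaffold[scaf] - interval_len
            if limit < 0:
                continue
            start = int(rng.integers(limit + 1))
            lo, hi = start - min_gap, start + interval_len + min_gap
            if all(e <= lo or s >= hi for s, e in occupied[scaf]):
                occupied[scaf].append((start, start + interval_len))
                placements.append((scaf, start))
                break
        else:
            raise ValueError(
                f"failed to place interval {len(placements) + 1}/{n_intervals} "
                f"after {max_tries} tries; genome too crowded"
            )
    return placements


def _window_distances(codes: np.ndarray, motif_codes: np.ndarray) -> np.ndarray:
    """Hamming distance of every window to the motif (vectorized)."""
    k = len(motif_codes)
    if len(codes) < k:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return (windows != motif_codes).sum(axis=1)


def simulate_genome(
    cfg: GenomeSimConfig, motif: MotifSpec = MotifSpec()
) -> tuple[dict[str, str], Truth]:
    """Multi-scaffold genome with planted sites and a clean background.

    Background bases are i.i.d. at the configured GC content. Each planted
    site is written at exactly its requested distance (on its requested
    strand) at a recorded non-overlapping position. Background windows
    that accidentally fall within ``motif.max_mismatches`` of the
    consensus, on either strand, are re-sampled until none survive, so the
    returned :class:`Truth` lists *every* matching location.
    """
    k = len(motif.consensus)
    if k > cfg.scaffold_length:
        raise ValueError("motif longer than scaffold")
    rng = stage_rng(cfg.seed, "genome")
    p_at = (1.0 - cfg.gc_content) / 2.0
    p_gc = cfg.gc_content / 2.0
    base_probs = np.array([p_at, p_gc, p_gc, p_at])

    names = [f"scaffold_{i + 1}" for i in range(cfg.n_scaffolds)]
    scaffolds = {
        n: _BASES[rng.choice(4, size=cfg.scaffold_length, p=base_probs)].copy()
        for n in names
    }

    site_requests = [
        (spec.distance, spec.strand)
        for spec in cfg.planted_sites
        for _ in range(spec.count)
    ]
    if any(d >= k for d, _ in site_requests):
        raise ValueError("planted distance must be < motif length")
    placements = _place_intervals(
        {n: cfg.scaffold_length for n in names},
        len(site_requests),
        k,
        rng,
        min_gap=cfg.site_min_gap,
    )
    planted: list[PlantedSite] = []
    protected = {n: np.zeros(cfg.scaffold_length, dtype=bool) for n in names}
    for (distance, strand), (scaf, start) in zip(site_requests, placements):
        word = _mutate_word(motif.consensus, distance, rng)
        genomic = word if strand == "+" else reverse_complement(word)
        scaffolds[scaf][start : start + k] = np.frombuffer(
            genomic.encode(), dtype=np.uint8
        )
        protected[scaf][start : start + k] = True
        planted.append(PlantedSite(scaf, start, start + k, strand, distance))

    _scrub_background(scaffolds, protected, planted, motif, base_probs, rng)

    genome = {n: scaffolds[n].tobytes().decode() for n in names}
    truth = Truth(planted_sites=sorted(planted, key=lambda s: (s.scaffold, s.start)))
    for site in truth.planted_sites:
        seq = genome[site.scaffold][site.start : site.end]
        strand_word = seq if site.strand == "+" else reverse_complement(seq)
        assert hamming(strand_word, motif.consensus) == site.distance
    return genome, truth


def _scrub_background(
    scaffolds: dict[str, np.ndarray],
    protected: dict[str, np.ndarray],
    planted: list[PlantedSite],
    motif: MotifSpec,
    base_probs: np.ndarray,
    rng: np.random.Generator,
    max_rounds: int = 100,
) -> None:
    """Re-sample background until no unplanned near-consensus window remains."""
    k = len(motif.consensus)
    fwd = np.frombuffer(motif.consensus.encode(), dtype=np.uint8)
    rev = np.frombuffer(reverse_complement(motif.consensus).encode(), dtype=np.uint8)
    planted_starts = {(s.scaffold, s.start) for s in planted}
    for _ in range(max_rounds):
        dirty = False
        for name, codes in scaffolds.items():
            d_fwd = _window_distances(codes, fwd)
            d_rev = _window_distances(codes, rev)
            matching = np.minimum(d_fwd, d_rev) <= motif.max_mismatches
            for i in np.nonzero(matching)[0]:
                if (name, int(i)) in planted_starts:
                    continue
                free = np.nonzero(~protected[name][i : i + k])[0]
                if free.size == 0:
                    raise ValueError(
                        "planted sites too densely packed to scrub an "
                        "accidental match between them"
                    )
                codes[i + free] = _BASES[
                    rng.choice(4, size=free.size, p=base_probs)
                ]
                dirty = True
        if not dirty:
            return
    raise RuntimeError("background scrubbing did not converge")


def write_genome_fasta(
    genome: Mapping[str, str], path: Union[str, PathLike]
) -> None:
    """Write scaffolds as FASTA wrapped at 60 columns."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def simulate_annotation(
    genome: Mapping[str, str],
    n_genes: int,
    seed: int,
    min_len: int = 300,
    max_len: int = 2_000,
    contain_intervals: Optional[Sequence[tuple[str, int, int]]] = None,
) -> list[GeneModel]:
    """Non-overlapping gene intervals with random strands.

    ``contain_intervals`` optionally forces the first genes to each contain
    one of the given (scaffold, start, end) intervals, e.g. planted motif
    sites, which makes those sites intragenic by construction.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    contain_intervals = list(contain_intervals or [])
    if len(contain_intervals) > n_genes:
        raise ValueError("more contain_intervals than genes")
    rng = stage_rng(seed, "annotation")
    lengths = {name: len(seq) for name, seq in genome.items()}

    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in lengths}

    def _fits(scaf: str, start: int, end: int) -> bool:
        return 0 <= start and end <= lengths[scaf] and all(
            e <= start or s >= end for s, e in occupied[scaf]
        )

    for idx, (scaf, s_start, s_end) in enumerate(contain_intervals):
        if s_end - s_start > max_len:
            raise ValueError(f"interval {idx} longer than max_len")
        placed = None
        # random lengths first, then shuffled exhaustive left offsets, so a
        # feasible containing placement is always found if one exists
        trial_lengths = list(
            rng.integers(min_len, max_len + 1, size=5)
        ) + [max_len, min_len]
        for length in trial_lengths:
            length = max(int(length), s_end - s_start)
            max_left = min(length - (s_end - s_start), s_start)
            lefts = rng.permutation(max_left + 1)
            for left in lefts:
                start = s_start - int(left)
                end = start + length
                if end >= s_end and end <= lengths[scaf] and _fits(scaf, start, end):
                    placed = (start, end)
                    break
            if placed:
                break
        if placed is None:
            raise ValueError(f"cannot place a gene containing interval {idx}")
        start, end = placed
        strand = "+" if rng.integers(2) == 0 else "-"
        occupied[scaf].append((start, end))
        genes.append(GeneModel(f"g{idx + 1:04d}", scaf, start, end, strand))

    remaining = n_genes - len(genes)
    names = list(lengths)
    for j in range(remaining):
        length = int(rng.integers(min_len, max_len + 1))
        for _ in range(400):
            scaf = names[int(rng.integers(len(names)))]
            limit = lengths[scaf] - length
            if limit < 0:
                continue
            start = int(rng.integers(limit + 1))
            if _fits(scaf, start, start + length):
                break
        else:
            raise ValueError(
                f"cannot fit gene {len(genes) + 1}/{n_genes} without overlap"
            )
        strand = "+" if rng.integers(2) == 0 else "-"
        gid = f"g{len(contain_intervals) + j + 1:04d}"
        occupied[scaf].append((start, start + length))
        genes.append(GeneModel(gid, scaf, start, start + length, strand))
    genes.sort(key=lambda g: (g.scaffold, g.start))
    return genes


def simulate_expression(
    cfg: ExprSimConfig,
    gene_ids: Optional[Sequence[str]] = None,
    de_gene_ids: Optional[Sequence[str]] = None,
) -> tuple[ExpressionStudy, Truth]:
    """Probe-level log-normal intensity study with planted sex effects.

    The number of differentially expressed genes is exactly
    round(n_genes * de_fraction) (half up), with signs balanced half up in
    favor of male-biased effects. ``de_gene_ids`` pins the affected genes;
    otherwise they are drawn uniformly. Repeat samples reuse their
    parent's systematic signal and draw fresh noise only.
    """
    rng = stage_rng(cfg.seed, "expression")
    if gene_ids is None:
        gene_ids = [f"g{i + 1:04d}" for i in range(cfg.n_genes)]
    else:
        gene_ids = list(gene_ids)
        if len(gene_ids) != cfg.n_genes:
            raise ValueError("gene_ids length must equal n_genes")

    n_de = _round_half_up(cfg.n_genes * cfg.de_fraction)
    if de_gene_ids is None:
        de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
        de_gene_ids = [gene_ids[i] for i in sorted(de_idx)]
    else:
        de_gene_ids = list(de_gene_ids)
        if len(de_gene_ids) != n_de:
            raise ValueError(
                f"de_gene_ids must list exactly {n_de} genes for this config"
            )
        missing = set(de_gene_ids) - set(gene_ids)
        if missing:
            raise ValueError(f"de_gene_ids not in gene_ids: {sorted(missing)}")
    n_male_up = _round_half_up(n_de / 2.0)
    effects = {g: 0.0 for g in gene_ids}
    for rank, g in enumerate(de_gene_ids):
        sign = 1.0 if rank < n_male_up else -1.0
        effects[g] = sign * cfg.effect_size

    # sample sheet: unique samples then repeat hybridizations (cyclic parents)
    rows = []
    for sex in ("male", "female"):
        for i in range(cfg.n_unique_per_sex):
            rows.append({"sample_id": f"{sex}_{i + 1}", "sex": sex, "repeat_of": ""})
        for j in range(cfg.n_repeat_per_sex):
            parent = f"{sex}_{(j % cfg.n_unique_per_sex) + 1}"
            rows.append(
                {
                    "sample_id": f"{sex}_{cfg.n_unique_per_sex + j + 1}",
                    "sex": sex,
                    "repeat_of": parent,
                }
            )
    samples = pd.DataFrame(rows, columns=["sample_id", "sex", "repeat_of"])
    is_male = (samples["sex"] == "male").to_numpy(dtype=float)

    lo, hi = cfg.probes_per_gene
    n_probes_per_gene = rng.integers(lo, hi + 1, size=cfg.n_genes)
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    probe_ids: list[str] = []
    probe_gene: list[str] = []
    signal_rows: list[np.ndarray] = []
    for gi, gene in enumerate(gene_ids):
        b = effects[gene]
        gene_signal = mu[gi] + b * is_male  # per-sample systematic part
        for p in range(n_probes_per_gene[gi]):
            a_p = rng.normal(0.0, cfg.probe_offset_sd)
            for r in range(cfg.tech_reps_per_probe):
                probe_ids.append(f"{gene}_p{p + 1}_r{r + 1}")
                probe_gene.append(gene)
                signal_rows.append(gene_signal + a_p)
    signal = np.vstack(signal_rows)
    noise = rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    intensities = pd.DataFrame(
        np.exp2(signal + noise),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=samples["sample_id"].tolist(),
    )
    study = ExpressionStudy(
        intensities=intensities,
        probe_to_gene=pd.Series(probe_gene, index=intensities.index, name="gene_id"),
        samples=samples,
    )
    truth = Truth(de_genes={g: e for g, e in effects.items() if e != 0.0})
    return study, truth
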
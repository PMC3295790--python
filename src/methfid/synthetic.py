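"""Synthetic differential-methylation-hybridization study generator.

Emulates the study design the downstream pipeline analyzes: CpG-rich
60-mer promoter probes from multi-probe genes, per-probe methylation
trajectories planted in the five propagation categories (plus an
uncategorized pool), two-color array scans of generations 1/3/5 against
the parental line with intensity-dependent dye bias and pixel-level
noise, a dye-swap replicate of generation 3, motif planting in the
non-random categories, and GC/length-matched random background
sequences.

The generative intensity model: each probe has a log-normal baseline
efficiency, and a sample's log2 net fluorescence on its channel is

    x = baseline_log2 + intensity_range_log2 * level (+ noise),

so the true log-ratio of progeny over parental is
``intensity_range_log2 * (level_t - level_parental)`` and absolute
fluorescence tracks absolute methylation, as in a methylation-dependent
enrichment assay. A smooth additive dye bias b(A) of configurable
amplitude is applied to the red/green log-ratio (so it cancels in a
dye-swap average), and pixel statistics are generated so that
SD/sqrt(n_pixels) is exactly the standard error of each reported
channel mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .categories import HYPER_PATTERNS, HYPO_PATTERNS, RANDOM_PATTERNS
from .normalize import TwoColorArray
from .tfbs import WeightMatrix, consensus, gc_fraction, reverse_complement

__all__ = [
    "SimulationConfig",
    "GroundTruthProbe",
    "ConfigError",
    "TIMEPOINTS",
    "GENERATIONS",
    "TRUTH_LABELS",
    "generate_probe_set",
    "simulate_array_scan",
    "plant_motifs",
    "generate_matched_background",
    "probes_to_annotation",
    "probe_sequences",
    "write_fasta",
    "read_fasta",
]

TIMEPOINTS = ("parental", "g1", "g3", "g5")
GENERATIONS = ("g1", "g3", "g5")
TRUTH_LABELS = (
    "heritable_high",
    "heritable_low",
    "stochastic_hyper",
    "stochastic_hypo",
    "random",
    "uncategorized",
)
PROBE_LENGTH = 60
_NONRANDOM = ("heritable_high", "heritable_low", "stochastic_hyper", "stochastic_hypo")


class ConfigError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic experiment.

    ``effect_size`` is the log2-ratio shift a single stochastic step
    produces (the generation-5 step is 1.5x); internally it is mapped
    to a methylation-level increment of
    ``effect_size / intensity_range_log2``. ``bio_sd`` is the
    between-hybridization (inter-sample) log-ratio noise that the
    empirical-Bayes null variance captures; pixel-level (intra-sample)
    noise is controlled by ``pixel_sd_scale`` and ``n_pixels``.
    """

    n_probes_per_category: int = 400
    seed: int = 0
    gc_mean: float = 0.65
    gc_sd: float = 0.05
    dye_bias_amplitude: float = 0.3
    pixel_sd_scale: float = 0.08
    n_pixels: int = 25
    effect_size: float = 1.0
    motif_plant_rate: float = 0.3
    bio_sd: float = 0.1
    intensity_range_log2: float = 8.0
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 0.25
    background_mean: float = 64.0
    uncategorized_multiplier: int = 4

    def __post_init__(self) -> None:
        if self.n_probes_per_category < 0:
            raise ConfigError("n_probes_per_category must be >= 0")
        for name in ("gc_mean", "gc_sd", "motif_plant_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_pixels < 2:
            raise ConfigError("n_pixels must be >= 2")
        for name in (
            "dye_bias_amplitude", "pixel_sd_scale", "effect_size", "bio_sd",
            "baseline_log2_sd", "background_mean",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.intensity_range_log2 <= 0:
            raise ConfigError("intensity_range_log2 must be > 0")
        if self.uncategorized_multiplier < 0:
            raise ConfigError("uncategorized_multiplier must be >= 0")


@dataclass
class GroundTruthProbe:
    """One synthetic 60-mer probe with its planted truth."""

    probe_id: str
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    sequence: str
    true_category: str
    true_level: tuple[float, float, float, float]  # parental, g1, g3, g5
    baseline_log2: float

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LENGTH:
            raise ConfigError(f"{self.probe_id}: sequence must be {PROBE_LENGTH}-mer")
        if self.true_category not in TRUTH_LABELS:
            raise ConfigError(f"{self.probe_id}: bad category {self.true_category}")
        if not all(0 <= v <= 1 for v in self.true_level):
            raise ConfigError(f"{self.probe_id}: levels must be in [0, 1]")


def _random_sequence(rng: np.random.Generator, gc: float, length: int = PROBE_LENGTH) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


# Parental starting-level bands per planted category. The heritable
# bands sit well inside the >0.85 / <0.15 category floors so the
# planted label is recoverable by construction under the default
# probe-baseline spread. The differential bands are wide (hyper starts
# low, hypo starts high, as in the shared-starting-level overlap
# structure) and leave room for the largest trajectory excursion
# (1.5 level steps); together with the broad uncategorized null pool
# this keeps non-differential probes the local majority at every
# intensity, which loess normalization assumes.
_PARENTAL_BANDS = {
    "heritable_high": (0.92, 0.98),
    "heritable_low": (0.02, 0.08),
    "stochastic_hyper": (0.10, 0.45),
    "stochastic_hypo": (0.55, 0.90),
    "random": (0.35, 0.65),
    "uncategorized": (0.16, 0.84),
}


def _trajectory(category: str, p0: float, d: float, rng: np.random.Generator):
    """Per-timepoint true levels for one probe; d is the level step."""
    if category in ("heritable_high", "heritable_low", "uncategorized"):
        return (p0, p0, p0, p0)
    if category == "stochastic_hyper":
        pattern = sorted(HYPER_PATTERNS)[rng.integers(3)]
    elif category == "stochastic_hypo":
        pattern = sorted(HYPO_PATTERNS)[rng.integers(3)]
    else:
        pattern = sorted(RANDOM_PATTERNS)[rng.integers(len(RANDOM_PATTERNS))]
    steps = []
    for gen, direction in zip(GENERATIONS, pattern):
        mag = d * (1.5 if gen == "g5" else 1.0)
        steps.append({"up": mag, "down": -mag, "even": 0.0}[direction])
    levels = (p0, p0 + steps[0], p0 + steps[1], p0 + steps[2])
    return tuple(float(np.clip(v, 0.0, 1.0)) for v in levels)


def generate_probe_set(config: SimulationConfig) -> list[GroundTruthProbe]:
    """Generate the full probe set: five planted categories plus the
    uncategorized pool, grouped into genes of 1-3 probes so that some
    genes carry >= 2 probes within 1500 bp (exercising cluster
    analysis). Deterministic given ``config.seed``."""
    rng = np.random.default_rng([config.seed, 0])
    d = config.effect_size / config.intensity_range_log2
    probes: list[GroundTruthProbe] = []
    probe_idx = 0
    gene_idx = 0
    for category in TRUTH_LABELS:
        n = config.n_probes_per_category
        if category == "uncategorized":
            n *= config.uncategorized_multiplier
        remaining = n
        while remaining > 0:
            gene_size = int(min(rng.integers(1, 4), remaining))
            gene_id = f"g{gene_idx:05d}"
            gene_start = gene_idx * 10_000
            gene_idx += 1
            offset = 0
            for j in range(gene_size):
                if j > 0:
                    # mostly adjacent (<1500 bp), occasionally beyond
                    gap = int(rng.choice([500, 900, 1300, 1700], p=[0.35, 0.3, 0.2, 0.15]))
                    offset += gap
                lo, hi = _PARENTAL_BANDS[category]
                p0 = float(rng.uniform(lo, hi))
                gc = float(np.clip(rng.normal(config.gc_mean, config.gc_sd), 0.2, 0.9))
                probes.append(
                    GroundTruthProbe(
                        probe_id=f"p{probe_idx:06d}",
                        gene_id=gene_id,
                        chrom="chr1",
                        start=gene_start + offset,
                        end=gene_start + offset + PROBE_LENGTH,
                        sequence=_random_sequence(rng, gc),
                        true_category=category,
                        true_level=_trajectory(category, p0, d, rng),
                        baseline_log2=float(
                            rng.normal(config.baseline_log2_mean, config.baseline_log2_sd)
                        ),
                    )
                )
                probe_idx += 1
            remaining -= gene_size
    return probes


def _dye_bias(A: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth intensity-dependent bias on the red/green log-ratio."""
    if amplitude == 0 or len(A) == 0:
        return np.zeros_like(A)
    span = float(A.max() - A.min())
    if span == 0:
        return np.zeros_like(A)
    return amplitude * np.sin(2 * np.pi * (A - A.min()) / span)


def simulate_array_scan(
    probes: list[GroundTruthProbe],
    timepoint: str,
    swap_dyes: bool = False,
    config: SimulationConfig = SimulationConfig(),
) -> TwoColorArray:
    """Simulate one two-color hybridization of ``timepoint`` against the
    parental sample.

    The progeny sample is on the red channel (green when
    ``swap_dyes``); the dye bias attaches to the red/green ratio, so it
    enters the progeny-over-parental log-ratio with opposite sign on
    swap arrays and cancels in a dye-swap average. With
    ``pixel_sd_scale=0``, ``bio_sd=0`` and ``dye_bias_amplitude=0`` the
    true log-ratio is recovered exactly from the written values.
    """
    if timepoint not in GENERATIONS:
        raise ConfigError(f"timepoint must be one of {GENERATIONS}, got {timepoint!r}")
    gen_index = GENERATIONS.index(timepoint)
    rng = np.random.default_rng([config.seed, 1000 + gen_index, int(swap_dyes)])
    n = len(probes)
    baseline = np.array([p.baseline_log2 for p in probes])
    lvl_par = np.array([p.true_level[0] for p in probes])
    lvl_t = np.array([p.true_level[1 + gen_index] for p in probes])
    c = config.intensity_range_log2

    x_par = baseline + c * lvl_par
    x_pro = baseline + c * lvl_t + rng.normal(0.0, config.bio_sd, n) if n else np.array([])
    A0 = 0.5 * (x_par + x_pro)
    bias = _dye_bias(A0, config.dye_bias_amplitude)
    if swap_dyes:
        x_red, x_green = x_par + bias / 2, x_pro - bias / 2
    else:
        x_red, x_green = x_pro + bias / 2, x_par - bias / 2

    bg = config.background_mean
    data = {"probe_id": [p.probe_id for p in probes]}
    for channel, x in (("red", x_red), ("green", x_green)):
        net = np.power(2.0, x)
        f_true = net + bg
        f_sd = config.pixel_sd_scale * f_true
        b_sd = config.pixel_sd_scale * bg
        se = np.sqrt(config.n_pixels)
        f_mean = f_true + rng.normal(0.0, 1.0, n) * f_sd / se
        b_mean = bg + rng.normal(0.0, 1.0, n) * b_sd / se
        data[f"f_{channel}_mean"] = f_mean
        data[f"f_{channel}_sd"] = f_sd
        data[f"b_{channel}_mean"] = b_mean
        data[f"b_{channel}_sd"] = np.full(n, b_sd)
    data["n_pixels"] = np.full(n, config.n_pixels, dtype=int)
    # column order per the scan-table contract
    cols = ["probe_id",
            "f_red_mean", "f_red_sd", "b_red_mean", "b_red_sd",
            "f_green_mean", "f_green_sd", "b_green_mean", "b_green_sd", "n_pixels"]
    array_id = f"{timepoint}_swap" if swap_dyes else timepoint
    return TwoColorArray(
        array_id=array_id,
        channel_of_progeny="green" if swap_dyes else "red",
        data=pd.DataFrame(data)[cols],
    )


def plant_motifs(
    probes: list[GroundTruthProbe],
    matrices: list[WeightMatrix],
    config: SimulationConfig,
    category_matrices: dict[str, list[str]] | None = None,
) -> tuple[list[GroundTruthProbe], pd.DataFrame]:
    """Embed motif consensus sequences in non-random-category probes.

    A fraction ``motif_plant_rate`` of probes in the four non-random
    categories receives the per-position argmax consensus of one
    eligible matrix at a random offset on a random strand; random and
    uncategorized probes receive none. By default the matrix library is
    split in half, the first half eligible in stochastic_hypo +
    heritable_high (high parental methylation) and the second half in
    stochastic_hyper + heritable_low, mirroring the shared-starting-
    level overlap structure; ``category_matrices`` overrides this.
    Returns new probes and the planting manifest.
    """
    if not matrices:
        raise ConfigError("matrices must be nonempty")
    by_id = {m.matrix_id: m for m in matrices}
    for m in matrices:
        if m.length > PROBE_LENGTH:
            raise ConfigError(
                f"motif {m.matrix_id} (length {m.length}) longer than probe length"
            )
    if category_matrices is None:
        ids = [m.matrix_id for m in matrices]
        half = max(1, len(ids) // 2)
        group_x, group_y = ids[:half], ids[half:] or ids[:half]
        category_matrices = {
            "stochastic_hypo": group_x,
            "heritable_high": group_x,
            "stochastic_hyper": group_y,
            "heritable_low": group_y,
        }
    rng = np.random.default_rng([config.seed, 2])
    out: list[GroundTruthProbe] = []
    manifest_rows = []
    for probe in probes:
        eligible = category_matrices.get(probe.true_category, [])
        if (
            probe.true_category in _NONRANDOM
            and eligible
            and rng.random() < config.motif_plant_rate
        ):
            mid = eligible[rng.integers(len(eligible))]
            matrix = by_id[mid]
            motif = consensus(matrix)
            strand = "+" if rng.random() < 0.5 else "-"
            insert = motif if strand == "+" else reverse_complement(motif)
            offset = int(rng.integers(0, PROBE_LENGTH - matrix.length + 1))
            seq = probe.sequence[:offset] + insert + probe.sequence[offset + matrix.length:]
            out.append(replace(probe, sequence=seq))
            manifest_rows.append((probe.probe_id, mid, offset, strand))
        else:
            out.append(probe)
    manifest = pd.DataFrame(
        manifest_rows, columns=["probe_id", "matrix_id", "offset", "strand"]
    )
    return out, manifest


def generate_matched_background(
    sequences: dict[str, str], k_per_sequence: int, seed: int = 0
) -> dict[str, str]:
    """Random sequences matched per template for exact length and
    expected GC: for a template of GC fraction g, bases are drawn
    independently with P(G) = P(C) = g/2 and P(A) = P(T) = (1-g)/2."""
    if k_per_sequence < 1:
        raise ConfigError("k_per_sequence must be >= 1")
    rng = np.random.default_rng([seed, 3])
    out: dict[str, str] = {}
    for sid in sorted(sequences):
        seq = sequences[sid]
        g = gc_fraction(seq)
        for i in range(k_per_sequence):
            out[f"{sid}|bg{i}"] = _random_sequence(rng, g, length=len(seq))
    return out


def probes_to_annotation(probes: list[GroundTruthProbe]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.probe_id, p.gene_id, p.chrom, p.start, p.end, p.true_category)
            for p in probes
        ],
        columns=["probe_id", "gene_id", "chrom", "start", "end", "true_category"],
    )


def probe_sequences(probes: list[GroundTruthProbe]) -> dict[str, str]:
    return {p.probe_id: p.sequence for p in probes}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
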
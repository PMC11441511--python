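"""Synthetic-data generators for serial-passage clonal evolution.

The simulator embodies the experimental design: barcoded founder
populations grow exponentially on a substrate for ~7 days, then a fixed
bottleneck of 2 x 10^4 cells is re-seeded onto fresh substrate.  Growth
within a passage is deterministic exponential per clone (each clone i
multiplies by ``2**(eta_i * passage_days)``); genetic drift enters only at
the bottleneck, as a multinomial draw of the bottleneck size from the
end-of-passage abundances.  A deterministic mode replaces the draw by
largest-remainder proportional rounding for bit-reproducible trajectories.

Downstream generators emit every input format the analysis pipeline
consumes: replicate growth-rate trajectories, paired-end barcode-amplicon
FASTQ with substitution sequencing error, Bismark-style CpG coverage files
with region-level condition effects, and nucleus/cytoplasm intensity
images — each with a machine-readable ground-truth record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .barcodes import BARCODE_LEN, FLANK3, FLANK5, reverse_complement
from .selection import GrowthTrajectory, SelectionParams, predicted_growth_rate

__all__ = [
    "CloneSpec",
    "ExperimentConfig",
    "SimOutput",
    "simulate_passage",
    "simulate_experiment",
    "random_barcodes",
    "uniform_founder",
    "sweep_config",
    "generate_reads",
    "generate_methylation_dataset",
    "generate_cell_image",
    "make_growth_trajectory",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CloneSpec:
    """One barcoded founder lineage and its per-condition growth rates."""

    barcode: str
    n0: int
    fitness: Mapping[str, float]  # condition -> eta, doublings/day

    def __post_init__(self):
        if len(self.barcode) != BARCODE_LEN or set(self.barcode) - set("ACGT"):
            raise ValueError(f"barcode must be a {BARCODE_LEN}-mer over ACGT")
        if self.n0 < 0:
            raise ValueError("initial cell count must be >= 0")
        if not self.fitness:
            raise ValueError("at least one condition must be defined")


@dataclass
class ExperimentConfig:
    """Serial-passage experiment: clones, schedule, replication and seeding."""

    clones: Sequence[CloneSpec]
    n_passages: int
    bottleneck: int = 20_000
    passage_days: float = 7.0
    conditions: Sequence[str] = ("soft", "stiff")
    replicates: int = 5
    seed: Optional[int] = None
    mode: str = "stochastic"
    #: clone index whose eta converts days to generations; None = fastest clone
    reference_clone: Optional[int] = None

    def __post_init__(self):
        if self.bottleneck < 1:
            raise ValueError("bottleneck must be >= 1")
        if self.passage_days <= 0:
            raise ValueError("passage_days must be positive")
        if self.mode not in ("stochastic", "deterministic"):
            raise ValueError("mode must be 'stochastic' or 'deterministic'")
        if self.mode == "stochastic" and self.seed is None:
            raise ValueError("stochastic mode requires a seed")
        for cond in self.conditions:
            for c in self.clones:
                if cond not in c.fitness:
                    raise ValueError(f"clone {c.barcode} lacks fitness for {cond!r}")

    def etas(self, condition: str) -> np.ndarray:
        return np.array([c.fitness[condition] for c in self.clones], float)

    def generations_per_passage(self, condition: str) -> float:
        etas = self.etas(condition)
        eta_ref = etas[self.reference_clone] if self.reference_clone is not None \
            else etas.max()
        return float(eta_ref * self.passage_days)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Round proportional shares to integers summing exactly to ``total``."""
    shares = weights / weights.sum() * total
    base = np.floor(shares).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(shares - base), kind="stable")
        base[order[:short]] += 1
    return base


class ExtinctionError(RuntimeError):
    """All clones reached zero cells; the culture is extinct."""


def simulate_passage(counts: np.ndarray, etas: np.ndarray, passage_days: float,
                     bottleneck: int, rng: Optional[np.random.Generator] = None,
                     mode: str = "stochastic"):
    """One growth-plus-bottleneck cycle.

    Each clone grows ``N_i <- N_i * 2**(eta_i * passage_days)`` (real-valued
    during growth); the realized population growth rate is
    ``log2(N_end/N_start)/passage_days``.  The bottleneck is a multinomial
    draw of ``bottleneck`` cells with probabilities proportional to the
    end-of-passage abundances (stochastic) or largest-remainder proportional
    rounding (deterministic).  Returns ``(new_counts, realized_gr)``.
    """
    counts = np.asarray(counts, float)
    total_start = counts.sum()
    if total_start <= 0:
        raise ExtinctionError("no cells at the start of the passage")
    grown = counts * np.exp2(np.asarray(etas, float) * passage_days)
    total_end = grown.sum()
    realized_gr = float(np.log2(total_end / total_start) / passage_days)
    if mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        new_counts = rng.multinomial(bottleneck, grown / total_end)
    elif mode == "deterministic":
        new_counts = _largest_remainder(grown, bottleneck)
    else:
        raise ValueError("mode must be 'stochastic' or 'deterministic'")
    return new_counts.astype(np.int64), realized_gr


@dataclass
class SimOutput:
    """Simulator observables: trajectories, true frequencies, abundances."""

    #: replicate-level rows: condition, replicate, generation, growth_rate_per_day
    trajectories: pd.DataFrame
    #: (condition, replicate) -> (n_passages + 1) x n_clones frequency array
    frequencies: dict
    #: barcode x sample cell-count table; 'ancestral' column is the founder
    abundance: pd.DataFrame
    config: ExperimentConfig = field(repr=False, default=None)

    def growth_trajectory(self, condition: str) -> GrowthTrajectory:
        """Replicate-averaged trajectory for one condition."""
        df = self.trajectories[self.trajectories["condition"] == condition]
        return GrowthTrajectory.from_replicates(df)

    def write_trajectory_tsv(self, path, condition: str) -> None:
        df = self.trajectories[self.trajectories["condition"] == condition]
        df[["replicate", "generation", "growth_rate_per_day"]].to_csv(
            path, sep="\t", index=False)


def simulate_experiment(config: ExperimentConfig) -> SimOutput:
    """Run every condition x replicate stream from a single master seed.

    Replicate streams are independent ``spawn``s of the master seed, so the
    deterministic mode is bit-reproducible and the stochastic mode is
    reproducible given the config seed.
    """
    n0 = np.array([c.n0 for c in config.clones], dtype=np.int64)
    barcodes = [c.barcode for c in config.clones]
    seeds = np.random.SeedSequence(config.seed if config.seed is not None else 0)
    streams = seeds.spawn(len(config.conditions) * config.replicates)

    rows = []
    freqs: dict = {}
    abundance = {"ancestral": pd.Series(n0, index=barcodes)}
    k = 0
    for condition in config.conditions:
        etas = config.etas(condition)
        gen_per_passage = config.generations_per_passage(condition)
        for rep in range(1, config.replicates + 1):
            rng = np.random.default_rng(streams[k])
            k += 1
            counts = n0.copy()
            traj_f = [counts / counts.sum()]
            t = 0.0
            for _ in range(config.n_passages):
                counts, gr = simulate_passage(counts, etas, config.passage_days,
                                              config.bottleneck, rng, config.mode)
                rows.append((condition, rep, t, gr))
                traj_f.append(counts / counts.sum())
                t += gen_per_passage
            freqs[(condition, rep)] = np.array(traj_f)
            abundance[f"{condition}_rep{rep}"] = pd.Series(counts, index=barcodes)

    traj = pd.DataFrame(rows, columns=["condition", "replicate", "generation",
                                       "growth_rate_per_day"])
    ab = pd.DataFrame(abundance)
    ab.index.name = "barcode"
    return SimOutput(traj, freqs, ab, config)


# ---------------------------------------------------------------------------
# founder-population helpers


def random_barcodes(n: int, rng: np.random.Generator,
                    min_dist: int = 0) -> list:
    """Distinct random 20-mers; ``min_dist`` enforces a minimum pairwise
    Levenshtein distance by rejection (keep n modest when min_dist > 0)."""
    import edlib

    out: list = []
    while len(out) < n:
        bc = "".join(rng.choice(BASES, size=BARCODE_LEN))
        if min_dist <= 0:
            if bc not in out:
                out.append(bc)
        elif all(edlib.align(bc, other, task="distance", k=min_dist - 1)
                 ["editDistance"] == -1 for other in out):
            out.append(bc)
    return out


def uniform_founder(n_lineages: int, total_cells: int,
                    barcodes: Optional[Sequence[str]] = None,
                    fitness: Optional[Sequence[Mapping[str, float]]] = None,
                    rng: Optional[np.random.Generator] = None) -> list:
    """Founder population with lineages at (near-)uniform abundance."""
    if barcodes is None:
        if rng is None:
            raise ValueError("need an rng to draw barcodes")
        barcodes = random_barcodes(n_lineages, rng)
    counts = _largest_remainder(np.ones(n_lineages), total_cells)
    if fitness is None:
        fitness = [{"soft": 0.5, "stiff": 0.5}] * n_lineages
    return [CloneSpec(b, int(c), f) for b, c, f in zip(barcodes, counts, fitness)]


def sweep_config(n_lineages: int = 220, bottleneck: int = 20_000,
                 focal_w: float = 2.23, generations_per_passage: float = 4.0,
                 n_passages: int = 10, replicates: int = 5,
                 passage_days: float = 7.0, condition: str = "soft",
                 eta_anc: Optional[float] = None, seed: int = 0,
                 mode: str = "stochastic") -> ExperimentConfig:
    """Selective-sweep experiment: uniform founder lineages, one focal clone
    with per-generation relative fitness ``focal_w``, all others neutral.

    Neutral clones double once per generation (``eta_anc`` defaults to
    generations_per_passage / passage_days); the focal clone's growth rate
    is offset so its per-generation multiplication factor is ``focal_w``
    times the neutral one.  The focal clone is the first lineage.
    """
    rng = np.random.default_rng(seed)
    if eta_anc is None:
        eta_anc = generations_per_passage / passage_days
    eta_focal = eta_anc + generations_per_passage * np.log2(focal_w) / passage_days
    fitness = [{condition: eta_focal}] + [{condition: eta_anc}] * (n_lineages - 1)
    clones = uniform_founder(n_lineages, bottleneck, fitness=fitness, rng=rng)
    return ExperimentConfig(clones, n_passages=n_passages, bottleneck=bottleneck,
                            passage_days=passage_days, conditions=(condition,),
                            replicates=replicates, seed=seed, mode=mode,
                            reference_clone=0)


# ---------------------------------------------------------------------------
# barcode-amplicon reads


def _mutate(seq: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-base substitution errors on a base array (in place on a copy)."""
    seq = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        choices = BASES[BASES != seq[i]]
        seq[i] = rng.choice(choices)
    return seq


def generate_reads(frequencies: Mapping[str, float], n_reads: int,
                   error_rate: float, rng: np.random.Generator,
                   fastq1, fastq2, *, read_len: int = 60,
                   pad_len: int = 6, low_quality_frac: float = 0.0,
                   phred_high: int = 37, phred_low: int = 20) -> dict:
    """Write paired-end amplicon FASTQ for a sample and return the truth.

    Reads are drawn multinomially from the lineage frequencies.  Each
    template is pad + flank5 + barcode + flank3 + pad with per-base
    substitution errors at ``error_rate`` applied independently per mate;
    mate 2 is the reverse complement of the template's 3' window, leaving a
    long mate overlap for merging.  A ``low_quality_frac`` share of reads is
    given mean Phred ~``phred_low`` (< 30) to exercise the quality filter.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must lie in [0, 0.1]")
    barcodes = list(frequencies)
    p = np.array([frequencies[b] for b in barcodes], float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    template_len = 2 * pad_len + len(FLANK5) + BARCODE_LEN + len(FLANK3)
    if read_len > template_len or 2 * read_len - template_len < 10:
        raise ValueError("read_len incompatible with template layout")

    draws = rng.multinomial(n_reads, p)
    truth = {b: int(c) for b, c in zip(barcodes, draws) if c > 0}
    order = rng.permutation(np.repeat(np.arange(len(barcodes)), draws))

    n_low = 0
    with open(fastq1, "w") as h1, open(fastq2, "w") as h2:
        for i, bi in enumerate(order):
            pads = rng.choice(BASES, size=2 * pad_len)
            template = np.concatenate([
                pads[:pad_len], np.array(list(FLANK5)),
                np.array(list(barcodes[bi])), np.array(list(FLANK3)),
                pads[pad_len:]])
            mate1 = _mutate(template[:read_len], error_rate, rng)
            mate2_f = _mutate(template[template_len - read_len:], error_rate, rng)
            mate2 = reverse_complement("".join(mate2_f))
            low = rng.random() < low_quality_frac
            n_low += low
            base_q = phred_low if low else phred_high
            q1 = rng.integers(base_q - 2, base_q + 3, size=read_len)
            q2 = rng.integers(base_q - 2, base_q + 3, size=read_len)
            name = f"read{i}"
            h1.write(f"@{name}/1\n{''.join(mate1)}\n+\n"
                     f"{''.join(chr(q + 33) for q in q1)}\n")
            h2.write(f"@{name}/2\n{mate2}\n+\n"
                     f"{''.join(chr(q + 33) for q in q2)}\n")
    return {"reads_per_barcode": truth, "n_reads": n_reads, "n_low_quality": int(n_low)}


# ---------------------------------------------------------------------------
# RRBS methylation counts


def generate_methylation_dataset(outdir, rng: np.random.Generator, *,
                                 n_regions: int = 60, loci_per_region: int = 5,
                                 locus_spacing: int = 50, region_spacing: int = 2000,
                                 coverage: Union[int, Callable] = 50,
                                 effect: float = 2.0, frac_affected: float = 0.25,
                                 replicates: Sequence[int] = (4, 4),
                                 labels: Sequence[str] = ("ancestral", "selected"),
                                 effect_sign: int = -1) -> dict:
    """Write per-sample Bismark-style coverage files with region effects.

    Each region draws a true methylation level pi_A ~ Uniform(0.55, 0.9)
    (high enough to survive the >= 50%-methylation region filter); a random
    ``frac_affected`` subset of regions shifts condition B by ``effect``
    log-odds (sign per ``effect_sign``).  Per-locus methylated counts are
    binomial(T, pi) at the region's pi.  Returns sample paths, condition
    labels and the truth table; also writes sample_sheet.tsv + truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cov_fn = coverage if callable(coverage) else (
        lambda rng_, size: np.full(size, int(coverage)))

    pi_a = rng.uniform(0.55, 0.9, size=n_regions)
    affected = rng.random(n_regions) < frac_affected
    logit = np.log(pi_a / (1 - pi_a))
    pi_b = np.where(affected,
                    1.0 / (1.0 + np.exp(-(logit + effect_sign * effect))), pi_a)

    samples, conditions, paths = [], {}, {}
    truth_rows = []
    region_span = (loci_per_region - 1) * locus_spacing
    starts = 1000 + np.arange(n_regions) * (region_span + region_spacing)

    per_sample_rows: dict = {}
    for ci, (label, n_rep) in enumerate(zip(labels, replicates)):
        pis = pi_a if ci == 0 else pi_b
        for r in range(1, n_rep + 1):
            sample = f"{label}_rep{r}"
            samples.append(sample)
            conditions[sample] = label
            per_sample_rows[sample] = []
            for g in range(n_regions):
                t = cov_fn(rng, loci_per_region)
                m = rng.binomial(t, pis[g])
                for j in range(loci_per_region):
                    pos = int(starts[g] + j * locus_spacing)
                    per_sample_rows[sample].append(
                        ("chr1", pos, m[j], t[j] - m[j]))

    for sample in samples:
        path = outdir / f"{sample}.cov"
        paths[sample] = str(path)
        with open(path, "w") as fh:
            for chrom, pos, m, u in per_sample_rows[sample]:
                pct = 100.0 * m / (m + u)
                fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:.6f}\t{m}\t{u}\n")

    for g in range(n_regions):
        truth_rows.append({"region": g, "chrom": "chr1", "start": int(starts[g]),
                           "end": int(starts[g] + region_span),
                           "pi_a": float(pi_a[g]), "pi_b": float(pi_b[g]),
                           "affected": bool(affected[g])})
    truth = pd.DataFrame(truth_rows)

    sheet = pd.DataFrame({"sample": samples,
                          "condition": [conditions[s] for s in samples],
                          "path": [paths[s] for s in samples]})
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_rows, fh, indent=1)
    return {"paths": paths, "conditions": conditions, "truth": truth,
            "sample_sheet": str(outdir / "sample_sheet.tsv")}


# ---------------------------------------------------------------------------
# phenotype images


def generate_cell_image(shape=(192, 192), cell_radius: float = 60.0,
                        nucleus_radius: float = 25.0,
                        nuclear_intensity: float = 1000.0,
                        cytoplasmic_intensity: float = 500.0,
                        background_intensity: float = 100.0,
                        noise_sd: float = 0.0,
                        rng: Optional[np.random.Generator] = None,
                        pixel_size: float = 1.0) -> dict:
    """Synthetic cell: disk nucleus inside a disk cell over flat background.

    Returns the image, the nuclear/cell masks and the analytic truth
    (configured N/C ratio and the exact disk areas in um^2).
    """
    if nucleus_radius >= cell_radius:
        raise ValueError("nucleus radius must be smaller than cell radius")
    if noise_sd > 0 and rng is None:
        raise ValueError("noise requires an rng")
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    nuclear_mask = r2 <= nucleus_radius**2
    cell_mask = r2 <= cell_radius**2
    image = np.full(shape, background_intensity, float)
    image[cell_mask] = cytoplasmic_intensity
    image[nuclear_mask] = nuclear_intensity
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=shape)
    truth = {
        "nc_ratio": (nuclear_intensity - background_intensity)
        / (cytoplasmic_intensity - background_intensity),
        "cell_area_um2": np.pi * (cell_radius * pixel_size) ** 2,
        "nucleus_area_um2": np.pi * (nucleus_radius * pixel_size) ** 2,
    }
    return {"image": image, "nuclear_mask": nuclear_mask, "cell_mask": cell_mask,
            "truth": truth, "pixel_size": pixel_size}


# ---------------------------------------------------------------------------
# growth-rate trajectories


def make_growth_trajectory(params: SelectionParams, generations,
                           noise_sd: float = 0.0, replicates: int = 1,
                           rng: Optional[np.random.Generator] = None):
    """Model growth-rate curve plus i.i.d. Gaussian replicate noise.

    Returns ``(GrowthTrajectory, replicate_df)`` where the DataFrame holds
    replicate-level rows (replicate, generation, growth_rate_per_day) in the
    trajectory TSV layout.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0 and rng is None:
        raise ValueError("noise requires an rng")
    t = np.asarray(generations, float)
    curve = predicted_growth_rate(params, t)
    rows = []
    for rep in range(1, replicates + 1):
        gr = curve if noise_sd == 0 else curve + rng.normal(0.0, noise_sd, size=len(t))
        rows.extend(zip([rep] * len(t), t, gr))
    df = pd.DataFrame(rows, columns=["replicate", "generation", "growth_rate_per_day"])
    return GrowthTrajectory.from_replicates(df), df
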
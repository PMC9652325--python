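"""Synthetic multi-condition Hi-C maps with planted compartment truth.

The generator emulates the features of real cis Hi-C data that the pipeline
relies on: power-law distance decay, a plaid (checkerboard) modulation from
a blockwise A/B compartment track, Poisson counting noise at a target
sequencing depth, replicates, and — between conditions — planted sign flips
and within-compartment strength shifts with known truth labels. GC content
and gene density covariates are generated as noisy monotone functions of the
compartment track so that PC selection and orientation are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, NumericError
from .genome import BinSet, ContactMap, CovariateTrack, GenomeBins, write_contact_map, write_scores_bedgraph

__all__ = [
    "SimulationSpec",
    "SimulatedTracks",
    "simulate_tracks",
    "simulate_map",
    "intensity_matrix",
    "thin_map",
    "simulate_experiment",
    "write_fixture",
]


@dataclass
class SimulationSpec:
    """Study-design parameters of one simulated chromosome.

    depth is the total expected read count of one replicate map;
    compartment_affinity (delta) scales the plaid modulation
    1 + delta * a_i * a_j; decay_exponent (alpha) gives the |i-j|^-alpha
    distance decay. Differential truth: flip_fraction of bins change
    compartment sign in the non-reference conditions, shift_fraction change
    |score| by shift_factor without changing sign.
    """

    n_bins: int = 2000
    resolution: int = 100_000
    chrom: str = "chrS"
    decay_exponent: float = 1.0
    compartment_affinity: float = 1.0
    depth: float = 5e6
    n_conditions: int = 2
    n_replicates: int = 2
    flip_fraction: float = 0.0
    shift_fraction: float = 0.0
    shift_factor: float = 0.4
    block_min: int = 10
    block_max: int = 40
    diff_block_size: int = 20
    magnitude_range: tuple[float, float] = (0.5, 0.9)
    track_jitter: float = 0.1
    boundary_smooth: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ConfigError("decay_exponent must be > 0")
        if self.compartment_affinity < 0:
            raise ConfigError("compartment_affinity must be >= 0")
        if self.flip_fraction + self.shift_fraction > 0.5:
            raise ConfigError("differential fraction > 50%: null model swamped")
        if self.diff_block_size < 5 or self.block_min < 5:
            raise ConfigError("track blocks must span >= 5 bins")

    def bins(self) -> GenomeBins:
        starts = np.arange(self.n_bins, dtype=np.int64) * self.resolution
        return GenomeBins(self.chrom, starts, starts + self.resolution, self.resolution)


@dataclass
class SimulatedTracks:
    """Per-condition compartment tracks plus the planted truth."""

    spec: SimulationSpec
    condition_tracks: list[np.ndarray]
    truth: pd.DataFrame  # bin, label in {null, flip, shift}
    gc: CovariateTrack
    gene_density: CovariateTrack

    @property
    def differential(self) -> np.ndarray:
        return (self.truth.label != "null").to_numpy()


def _block_track(n: int, spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Alternating-sign blocks with per-bin magnitude variability.

    Real compartment scores vary smoothly within a block; a piecewise-
    constant track would give a plateaued score distribution whose quantile
    mapping is unstable, which no real chromosome shows.
    """
    track = np.empty(n)
    sign = rng.choice([-1.0, 1.0])
    pos = 0
    while pos < n:
        size = min(int(rng.integers(spec.block_min, spec.block_max + 1)), n - pos)
        mag = rng.uniform(*spec.magnitude_range)
        jitter = rng.normal(0.0, spec.track_jitter, size)
        track[pos : pos + size] = sign * np.clip(mag + jitter, 0.05, 0.97)
        sign = -sign
        pos += size
    # taper block boundaries: bins straddling a compartment boundary show
    # intermediate scores in real data, populating the near-zero range
    for _ in range(spec.boundary_smooth):
        track = np.convolve(track, [0.25, 0.5, 0.25], mode="same")
    return np.clip(track, -0.97, 0.97)


def _disjoint_intervals(
    n: int,
    total: int,
    size: int,
    rng: np.random.Generator,
    base: np.ndarray | None = None,
    taken: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Disjoint intervals covering exactly ``total`` bins, each >= 5 bins.

    When ``base`` is given, placements alternate between predominantly
    positive and predominantly negative stretches of it, so that planted
    sign flips are balanced between the A->B and B->A directions and the
    marginal score composition — which quantile normalization equalizes by
    construction — stays comparable across conditions.
    """
    sizes = [size] * (total // size)
    rem = total % size
    if rem:
        if sizes and rem < 5:
            sizes[-1] += rem
        else:
            sizes.append(rem)
    if taken is None:
        taken = np.zeros(n, dtype=bool)
    out: list[tuple[int, int]] = []
    for k, s in enumerate(sizes):
        target = 1.0 if k % 2 == 0 else -1.0
        for attempt in range(20_000):
            start = int(rng.integers(0, n - s + 1))
            lo, hi = max(0, start - 1), min(n, start + s + 1)
            if taken[lo:hi].any():
                continue
            if base is not None and attempt < 15_000:
                frac = (np.sign(base[start : start + s]) == target).mean()
                if frac < 0.8:
                    continue
            taken[start : start + s] = True
            out.append((start, start + s))
            break
        else:
            raise ConfigError("could not place differential blocks; fraction too high")
    return out


def simulate_tracks(spec: SimulationSpec) -> SimulatedTracks:
    """Blockwise compartment tracks per condition, with truth labels.

    The reference condition carries the base track; every other condition
    carries the planted flips (sign change) and strength shifts (|a| scaled
    by ``shift_factor``). The GC covariate is a noisy increasing function of
    the condition-average track; gene density is Poisson with a
    track-dependent rate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 101]))
    n = spec.n_bins
    base = _block_track(n, spec, rng)
    labels = np.array(["null"] * n, dtype=object)
    n_flip = int(round(spec.flip_fraction * n))
    n_shift = int(round(spec.shift_fraction * n))
    alt = base.copy()
    taken = np.zeros(n, dtype=bool)
    if n_flip:
        for a, b in _disjoint_intervals(n, n_flip, spec.diff_block_size, rng, base, taken):
            alt[a:b] *= -1.0
            labels[a:b] = "flip"
    if n_shift:
        for a, b in _disjoint_intervals(n, n_shift, spec.diff_block_size, rng, base, taken):
            alt[a:b] *= spec.shift_factor
            labels[a:b] = "shift"
    tracks = [base] + [alt.copy() for _ in range(spec.n_conditions - 1)]
    mean_track = np.mean(tracks, axis=0)
    gc = np.clip(0.41 + 0.05 * mean_track + rng.normal(0, 0.01, n), 0.2, 0.8)
    gd = rng.poisson(np.exp(0.7 + 0.8 * mean_track)).astype(float)
    truth = pd.DataFrame({"bin": np.arange(n), "label": labels})
    return SimulatedTracks(
        spec,
        tracks,
        truth,
        CovariateTrack(gc, mask=np.zeros(n, dtype=bool)),
        CovariateTrack(gd, mask=np.zeros(n, dtype=bool)),
    )


def intensity_matrix(track: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """Expected (noiseless) contact intensities, scaled to the target depth.

    lambda_ij proportional to |i-j|^-alpha * (1 + delta a_i a_j); the
    diagonal uses the offset-1 decay intensity.
    """
    track = np.asarray(track, dtype=float)
    n = len(track)
    offsets = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    decay = np.maximum(offsets, 1).astype(float) ** (-spec.decay_exponent)
    plaid = 1.0 + spec.compartment_affinity * np.outer(track, track)
    if plaid.min() <= 0:
        raise NumericError(
            "1 + delta*a_i*a_j <= 0: compartment affinity too strong for the track"
        )
    lam = decay * plaid
    scale = spec.depth / np.triu(lam).sum()
    return lam * scale


def simulate_map(
    track: np.ndarray,
    spec: SimulationSpec,
    replicate_seed: int,
    sample: str = "",
    replicate: str = "",
) -> ContactMap:
    """One replicate contact map: independent Poisson draws per bin pair."""
    lam = intensity_matrix(track, spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 211, int(replicate_seed)]))
    n = lam.shape[0]
    iu, ju = np.triu_indices(n)
    counts = np.zeros((n, n))
    draws = rng.poisson(lam[iu, ju]).astype(float)
    counts[iu, ju] = draws
    counts = counts + counts.T - np.diag(np.diag(counts))
    return ContactMap(spec.chrom, counts, sample=sample, replicate=replicate)


def thin_map(cmap: ContactMap, fraction: float, seed: int) -> ContactMap:
    """Binomially down-sample a map to ``fraction`` of its depth."""
    if not 0 < fraction <= 1:
        raise ConfigError("thinning fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = cmap.n_bins
    iu, ju = np.triu_indices(n)
    thin = rng.binomial(cmap.counts[iu, ju].astype(np.int64), fraction).astype(float)
    counts = np.zeros((n, n))
    counts[iu, ju] = thin
    counts = counts + counts.T - np.diag(np.diag(counts))
    return ContactMap(cmap.chrom, counts, sample=cmap.sample, replicate=cmap.replicate)


def simulate_experiment(
    spec: SimulationSpec,
) -> tuple[SimulatedTracks, dict[tuple[str, str], ContactMap]]:
    """Full design: one map per (condition, replicate), fully deterministic.

    Conditions are named ``cond1..condC``, replicates ``r1..rR``.
    """
    tracks = simulate_tracks(spec)
    maps: dict[tuple[str, str], ContactMap] = {}
    k = 0
    for c, track in enumerate(tracks.condition_tracks):
        for r in range(spec.n_replicates):
            name = (f"cond{c + 1}", f"r{r + 1}")
            maps[name] = simulate_map(track, spec, k, sample=name[0], replicate=name[1])
            k += 1
    return tracks, maps


def write_fixture(
    tracks: SimulatedTracks,
    maps: dict[tuple[str, str], ContactMap],
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit the exact on-disk formats the pipeline consumes.

    Writes bins BED, per-replicate triplet matrices, a design TSV, GC and
    gene-density bedGraph covariates, and the truth BED; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gb = tracks.spec.bins()
    binset = BinSet({gb.chrom: gb}, None)
    bins_path = outdir / "bins.bed"
    with open(bins_path, "w") as fh:
        for i in range(gb.n_bins):
            fh.write(f"{gb.chrom}\t{gb.starts[i]}\t{gb.ends[i]}\t{i + 1}\n")
    design_rows = []
    for (sample, replicate), cmap in maps.items():
        mat = outdir / f"{sample}_{replicate}.matrix"
        write_contact_map(cmap, binset, mat)
        design_rows.append((str(mat), sample, replicate))
    design_path = outdir / "design.tsv"
    pd.DataFrame(design_rows, columns=["file", "sample", "replicate"]).to_csv(
        design_path, sep="\t", index=False
    )
    gc_path = outdir / "gc.bedgraph"
    gd_path = outdir / "gene_density.bedgraph"
    write_scores_bedgraph(gb, tracks.gc.values, gc_path)
    write_scores_bedgraph(gb, tracks.gene_density.values, gd_path)
    truth_path = outdir / "truth.bed"
    with open(truth_path, "w") as fh:
        for i, label in enumerate(tracks.truth.label):
            fh.write(f"{gb.chrom}\t{gb.starts[i]}\t{gb.ends[i]}\t{label}\n")
    return {
        "bins": bins_path,
        "design": design_path,
        "gc": gc_path,
        "gene_density": gd_path,
        "truth": truth_path,
    }
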
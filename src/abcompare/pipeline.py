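"""End-to-end orchestration: maps -> scores -> normalization -> testing.

Thin glue over the estimator classes, shared by the CLI and by scripted
analyses. All stages are deterministic for a fixed configuration.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .compartment import CompartmentScorer
from .differential import differential_compartments
from .errors import DegenerateChromosomeError
from .genome import ContactMap, CovariateTrack, GenomeBins
from .normalize import ScoreMatrix, average_replicates, quantile_normalize

__all__ = ["score_replicates", "run_differential_pipeline"]


def score_replicates(
    maps: Mapping[str, Mapping[str, ContactMap]],
    gc: Mapping[str, CovariateTrack],
    gene_density: Mapping[str, CovariateTrack],
    bins: Mapping[str, GenomeBins],
    samples: Mapping[str, str],
    **scorer_params,
) -> ScoreMatrix:
    """Raw compartment scores for every replicate column.

    ``maps`` maps column label -> {chrom: ContactMap}; ``samples`` maps
    column label -> sample name. Chromosomes that are degenerate for any
    column are skipped (scores NaN) with a warning.
    """
    chroms = list(bins)
    columns = list(maps)
    frames = [bins[c].frame() for c in chroms]
    bin_frame = pd.concat(frames, ignore_index=True)
    offsets = np.cumsum([0] + [bins[c].n_bins for c in chroms])
    values = np.full((len(bin_frame), len(columns)), np.nan)
    for k, chrom in enumerate(chroms):
        for j, col in enumerate(columns):
            scorer = CompartmentScorer(**scorer_params)
            try:
                s = scorer.fit_transform(
                    maps[col][chrom], gc=gc[chrom], gene_density=gene_density[chrom]
                )
            except DegenerateChromosomeError as exc:
                warnings.warn(f"skipping {chrom} for {col}: {exc}")
                continue
            values[offsets[k] : offsets[k + 1], j] = s
    return ScoreMatrix(bin_frame, values, columns, [samples[c] for c in columns])


def run_differential_pipeline(
    maps: Mapping[str, Mapping[str, ContactMap]],
    gc: Mapping[str, CovariateTrack],
    gene_density: Mapping[str, CovariateTrack],
    bins: Mapping[str, GenomeBins],
    samples: Mapping[str, str],
    scorer_params: dict | None = None,
    **diff_params,
) -> dict:
    """Score, quantile-normalize, average replicates, and test.

    Returns the intermediate matrices and the per-bin result table under
    keys ``raw``, ``normalized``, ``sample_scores`` and ``table``.
    """
    raw = score_replicates(
        maps, gc, gene_density, bins, samples, **(scorer_params or {})
    )
    normalized = quantile_normalize(raw)
    design: dict[str, list[str]] = {}
    for col, sample in zip(normalized.columns, normalized.samples):
        design.setdefault(sample, []).append(col)
    sample_scores = average_replicates(normalized, design)
    with_replicates = all(len(v) >= 2 for v in design.values())
    table = differential_compartments(
        sample_scores,
        replicate_scores=normalized if with_replicates else None,
        **diff_params,
    )
    return {
        "raw": raw,
        "normalized": normalized,
        "sample_scores": sample_scores,
        "table": table,
    }
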
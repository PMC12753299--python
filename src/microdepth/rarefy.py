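"""Rarefaction: subsampling read sets and quantifying depth-induced bias.

Read sets are subsampled on a fraction grid or down to fixed target depths,
metrics are recomputed per subsample, and two bias statistics are formed
against the full data set: the diversity ratio (subsample metric divided by
full-data metric; 1 means no depth-induced bias) and the average absolute
relative error in percent.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .profile import ProfileParams, compute_anir, coverage_stats, genome_pi
from .recruit import RecruitedRead, apply_filters, build_pileup
from .synthgen import Genome

__all__ = [
    "DEPTH_BIN_EDGES",
    "DEPTH_BIN_LABELS",
    "RarefactionPoint",
    "depth_category",
    "subsample_fraction",
    "rarefy_to_depth",
    "diversity_ratio",
    "average_absolute_error",
    "rarefaction_series",
]

# depth bins used for tabular error summaries
DEPTH_BIN_EDGES = (10.0, 50.0, 200.0)
DEPTH_BIN_LABELS = ("<10X", "10-50X", "50-200X", ">200X")


class InsufficientDepthError(ValueError):
    """Raised when a rarefaction target exceeds the achieved depth."""


@dataclass(frozen=True)
class RarefactionPoint:
    """Metrics at one subsample fraction, relative to the full data set."""

    fraction: float
    replicate: int
    seed: int
    n_reads: int
    mean_depth: float
    pi: float
    anir: float
    ratio_pi: float
    ratio_anir: float


def depth_category(mean_depth: float,
                   edges: Sequence[float] = DEPTH_BIN_EDGES,
                   labels: Sequence[str] = DEPTH_BIN_LABELS) -> str:
    """Assign a mean depth to its reporting bin."""
    for edge, label in zip(edges, labels):
        if mean_depth < edge:
            return label
    return labels[len(edges)]


def _sampling_units(reads: Sequence[RecruitedRead]) -> list[list[int]]:
    """Group read indices into sampling units; mates form one unit."""
    units: dict[str, list[int]] = {}
    order: list[list[int]] = []
    for i, r in enumerate(reads):
        if r.is_paired:
            if r.read_id in units:
                units[r.read_id].append(i)
                continue
            unit: list[int] = [i]
            units[r.read_id] = unit
            order.append(unit)
        else:
            order.append([i])
    return order


def subsample_fraction(reads: Sequence[RecruitedRead], fraction: float,
                       seed: int = 0, mode: str = "exact"
                       ) -> list[RecruitedRead]:
    """Randomly subsample a read set, seeded.

    In "exact" mode (default, without replacement) exactly
    ``floor(fraction * N)`` units are kept; in "expected" mode each unit is
    kept independently with probability ``fraction``. Mates are kept or
    dropped together when pairing information exists. Input order is
    preserved.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if len(reads) == 0:
        raise ValueError("cannot subsample an empty read set")
    if mode not in ("exact", "expected"):
        raise ValueError("mode must be 'exact' or 'expected'")
    if fraction == 1.0 and mode == "exact":
        return list(reads)
    units = _sampling_units(reads)
    rng = np.random.default_rng(seed)
    n = len(units)
    if mode == "exact":
        k = int(math.floor(fraction * n))
        chosen = rng.choice(n, size=k, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[chosen] = True
    else:
        mask = rng.random(n) < fraction
    out: list[RecruitedRead] = []
    for keep, unit in zip(mask, units):
        if keep:
            out.extend(reads[i] for i in unit)
    return out


def _mean_depth(reads: Sequence[RecruitedRead], ref_length: int) -> float:
    cols = sum(r.n_match + r.n_mismatch for r in reads)
    return cols / ref_length


def rarefy_to_depth(reads: Sequence[RecruitedRead], target_depth: float,
                    ref_length: int, seed: int = 0, mode: str = "exact"
                    ) -> tuple[list[RecruitedRead], float]:
    """Subsample down to a fixed target mean depth (X).

    Returns ``(subsampled_reads, achieved_depth)``. Raises
    :class:`InsufficientDepthError` when the achieved depth is below the
    target rather than silently keeping everything.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be > 0")
    current = _mean_depth(reads, ref_length)
    if current < target_depth:
        raise InsufficientDepthError(
            f"achieved mean depth {current:.2f}X is below target "
            f"{target_depth:.2f}X; rarefaction is infeasible"
        )
    if current == target_depth:
        return list(reads), current
    sub = subsample_fraction(reads, target_depth / current, seed=seed, mode=mode)
    return sub, _mean_depth(sub, ref_length)


def diversity_ratio(sub_value: float, full_value: float) -> float:
    """Subsample metric divided by full-data metric; NaN when undefined.

    A full-data value of zero (e.g. pi of a clonal error-free metagenome)
    leaves the ratio undefined; such points are excluded from summaries.
    """
    if not np.isfinite(full_value) or full_value <= 0:
        return float("nan")
    return sub_value / full_value


def average_absolute_error(points: Sequence[tuple[float, float]],
                           depths: Sequence[float],
                           edges: Sequence[float] = DEPTH_BIN_EDGES,
                           labels: Sequence[str] = DEPTH_BIN_LABELS
                           ) -> pd.DataFrame:
    """Mean and sd of the absolute relative error (%) per depth bin.

    Each point is ``(sub_value, full_value)`` with its subsample mean depth;
    per point the error is ``100 * |sub - full| / full``. Points with a
    zero/undefined full value are excluded (their count is reported in
    ``df.attrs['n_excluded']`` and via a warning). sd is the population
    standard deviation (0 for a single-point bin).
    """
    if len(points) != len(depths):
        raise ValueError("points and depths must have equal length")
    rows = []
    n_excluded = 0
    for (sub, full), depth in zip(points, depths):
        if not np.isfinite(full) or full <= 0:
            n_excluded += 1
            continue
        rows.append((depth_category(depth, edges, labels),
                     100.0 * abs(sub - full) / full))
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} point(s) with zero/undefined "
                      "full-data value", stacklevel=2)
    df = pd.DataFrame(rows, columns=["depth_bin", "error_pct"])
    out = (df.groupby("depth_bin", sort=False)["error_pct"]
             .agg(mean_abs_error_pct="mean",
                  sd_error_pct=lambda s: float(np.std(s)),
                  n="size")
             .reset_index())
    order = {lab: i for i, lab in enumerate(labels)}
    out = out.sort_values("depth_bin", key=lambda s: s.map(order),
                          ignore_index=True)
    out.attrs["n_excluded"] = n_excluded
    return out


def _child_seed(seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rarefaction_series(reads: Sequence[RecruitedRead], ref: Genome,
                       fractions: Sequence[float], replicates: int = 1,
                       params: ProfileParams | None = None, seed: int = 0,
                       mode: str = "exact") -> list[RarefactionPoint]:
    """Profile every (fraction x replicate) subsample against the full set.

    The full-data metrics are computed once and serve as the fixed
    denominators for every replicate. Reads are filtered once up front, so
    subsampling operates on the recruited read set.
    """
    params = params or ProfileParams()
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    kept = apply_filters(reads, min_identity=params.min_identity,
                         pairing=params.pairing, best_match=params.best_match)
    if not kept:
        raise ValueError("no reads pass the recruitment filters")
    full_pileup = build_pileup(kept, ref)
    full_pi, _ = genome_pi(full_pileup, params)
    full_anir = compute_anir(kept, weight=params.anir_weight)

    points: list[RarefactionPoint] = []
    for fi, fraction in enumerate(fractions):
        for rep in range(replicates):
            child = _child_seed(seed, fi, rep)
            sub = subsample_fraction(kept, fraction, seed=child, mode=mode)
            pileup = build_pileup(sub, ref)
            pi, _ = genome_pi(pileup, params)
            anir = compute_anir(sub, weight=params.anir_weight) if sub else math.nan
            mean_depth, _ = coverage_stats(pileup)
            points.append(RarefactionPoint(
                fraction=fraction, replicate=rep, seed=child,
                n_reads=len(sub), mean_depth=mean_depth, pi=pi, anir=anir,
                ratio_pi=diversity_ratio(pi, full_pi),
                ratio_anir=diversity_ratio(anir, full_anir),
            ))
    return points
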
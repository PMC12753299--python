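"""Microdiversity metrics from recruited reads: pi, ANIr, depth, breadth.

Nucleotide diversity is the plugin per-site heterozygosity
``pi = 1 - (f_A^2 + f_C^2 + f_G^2 + f_T^2)`` averaged over reference sites
with depth >= ``min_cov``; the estimator deliberately carries no ``n/(n-1)``
finite-sample correction, so its depth-dependent downward bias
(E[pi_hat] = (n-1)/n * pi at depth n) is part of the phenomenon under study.
ANIr is the mean alignment identity of recruited reads, in percent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .recruit import (PileupMatrix, RecruitedRead, apply_filters,
                      build_pileup, load_alignments)
from .synthgen import Genome

__all__ = [
    "ProfileParams",
    "ProfileResult",
    "site_pi",
    "genome_pi",
    "compute_anir",
    "coverage_stats",
    "profile_genome",
]


@dataclass(frozen=True)
class ProfileParams:
    """Profiling thresholds (defaults mirror common microdiversity practice).

    ``min_cov``: minimum depth for a site to enter the genome-wide pi mean.
    ``min_identity``: recruitment identity cutoff (inclusive).
    ``pi_denominator``: "min_cov" (default) averages pi over qualifying sites
    only; "covered" divides the same pi sum by the number of sites with
    depth >= 1.
    ``anir_weight``: "reads" (one vote per read) or "bases" (weighted by
    aligned columns).
    """

    min_cov: int = 5
    min_identity: float = 0.95
    pi_denominator: str = "min_cov"
    anir_weight: str = "reads"
    pairing: str = "non_discordant"
    best_match: bool = True

    def __post_init__(self) -> None:
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in [0, 1]")
        if self.pi_denominator not in ("min_cov", "covered"):
            raise ValueError("pi_denominator must be 'min_cov' or 'covered'")
        if self.anir_weight not in ("reads", "bases"):
            raise ValueError("anir_weight must be 'reads' or 'bases'")


@dataclass(frozen=True)
class ProfileResult:
    """Genome-wide microdiversity metrics for one reference."""

    ref_id: str
    pi: float  # NaN when no site reaches min_cov
    anir: float  # percent
    mean_depth: float  # X
    breadth: float  # percent
    n_reads: int
    n_sites_pi: int


def site_pi(counts: Sequence[int] | np.ndarray) -> float:
    """Per-site nucleotide diversity from a 4-vector of A/C/G/T counts.

    A monomorphic column returns 0; an equal quartet returns the maximum,
    0.75.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (4,) or np.any(c < 0):
        raise ValueError("counts must be a non-negative 4-vector")
    depth = c.sum()
    if depth < 1:
        raise ValueError("site has zero depth")
    f = c / depth
    return float(1.0 - np.dot(f, f))


def genome_pi(pileup: PileupMatrix, params: ProfileParams | None = None
              ) -> tuple[float, int]:
    """Genome-wide pi: mean of site pi over sites with depth >= min_cov.

    Returns ``(pi, n_sites_pi)``; ``pi`` is NaN when no site qualifies
    (undefined, deliberately distinct from zero).
    """
    params = params or ProfileParams()
    counts = pileup.counts.astype(float)
    depth = counts.sum(axis=1)
    qual = depth >= params.min_cov
    n_sites = int(np.count_nonzero(qual))
    if n_sites == 0:
        return float("nan"), 0
    f = counts[qual] / depth[qual, None]
    pi_sites = 1.0 - np.einsum("ij,ij->i", f, f)
    if params.pi_denominator == "covered":
        denom = int(np.count_nonzero(depth >= 1))
        return float(pi_sites.sum() / denom), n_sites
    return float(pi_sites.mean()), n_sites


def compute_anir(reads: Sequence[RecruitedRead], weight: str = "reads") -> float:
    """ANIr: average nucleotide identity of recruited reads, in percent."""
    if len(reads) == 0:
        raise ValueError("ANIr is undefined for an empty recruitment")
    ident = np.fromiter((r.identity for r in reads), dtype=float, count=len(reads))
    if weight == "reads":
        return float(100.0 * ident.mean())
    if weight == "bases":
        cols = np.fromiter(
            (r.n_match + r.n_mismatch + r.n_ins + r.n_del for r in reads),
            dtype=float, count=len(reads))
        return float(100.0 * np.average(ident, weights=cols))
    raise ValueError("weight must be 'reads' or 'bases'")


def coverage_stats(pileup: PileupMatrix) -> tuple[float, float]:
    """Mean sequencing depth (X) and breadth (%) over the whole reference.

    Depth counts only match/mismatch columns (consistent with the pileup);
    positions with zero depth are included in the denominator.
    """
    depth = pileup.depths
    L = pileup.ref_length
    if L < 1:
        raise ValueError("reference length must be >= 1")
    mean_depth = float(depth.sum(dtype=np.int64) / L)
    breadth = float(100.0 * np.count_nonzero(depth) / L)
    return mean_depth, breadth


def profile_genome(alignments: str | Path | Sequence[RecruitedRead],
                   ref: Genome,
                   params: ProfileParams | None = None) -> ProfileResult:
    """Filter -> pileup -> pi / ANIr / coverage, in one deterministic pass.

    ``alignments`` may be a SAM/BAM path or an already-loaded read list.
    """
    params = params or ProfileParams()
    if isinstance(alignments, (str, Path)):
        reads: Sequence[RecruitedRead] = load_alignments(alignments, ref)
    else:
        reads = alignments
    kept = apply_filters(reads, min_identity=params.min_identity,
                         pairing=params.pairing, best_match=params.best_match)
    pileup = build_pileup(kept, ref)
    pi, n_sites = genome_pi(pileup, params)
    anir = compute_anir(kept, weight=params.anir_weight) if kept else math.nan
    mean_depth, breadth = coverage_stats(pileup)
    return ProfileResult(ref_id=ref.id, pi=pi, anir=anir,
                         mean_depth=mean_depth, breadth=breadth,
                         n_reads=len(kept), n_sites_pi=n_sites)
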
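"""Orchestration of the in silico design and result reporting.

Drives the full simulation grid (strain counts x error profiles), profiles
each synthetic metagenome, runs the rarefaction series, and writes long-form
tables plus a run manifest. Everything is deterministic under a single master
seed: per-metagenome and per-subsample seeds are derived by a stable
splitting rule, so the paper-scale design is a parameter change only.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import tempfile
import time
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .profile import ProfileParams, profile_genome
from .rarefy import (average_absolute_error, depth_category,
                     rarefaction_series)
from .recruit import load_alignments, load_reference
from .synthgen import (ErrorProfile, derive_strain_set, generate_ancestor,
                       sample_lognormal_abundances, simulate_metagenome)

__all__ = [
    "ExperimentConfig",
    "run_insilico_design",
    "compare_environments",
    "write_report",
]

logger = logging.getLogger(__name__)

# the full study grid; the default config below scales the strain counts down
FULL_STRAIN_COUNTS = (1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
PAPER_FRACTIONS = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the scaled-down in silico design.

    Defaults keep a full run on one core in the minutes range while
    preserving every qualitative regime of the study (clonal vs 100-strain,
    three error profiles, the 1-90% subsampling grid); the paper-scale
    design is reachable purely by changing parameters.
    """

    genome_length: int = 200_000
    strain_counts: tuple[int, ...] = (1, 5, 20, 100)
    error_profiles: tuple[str, ...] = ("none", "q20", "q30")
    n_reads: int = 400_000  # ~300X at the default genome/read length
    read_length: int = 150
    fractions: tuple[float, ...] = PAPER_FRACTIONS
    replicates: int = 3
    divergence_range: tuple[float, float] = (0.0, 0.0249)
    sigma: float = 1.0
    gc_fraction: float = 0.5
    seed: int = 0
    min_cov: int = 5
    min_identity: float = 0.95
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.strain_counts:
            raise ValueError("strain_counts must be non-empty")
        if any(c < 1 or c > 100 for c in self.strain_counts):
            raise ValueError("strain counts must lie in [1, 100]")
        if any(not 0.0 < f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        for name in self.error_profiles:
            ErrorProfile.from_name(name)  # validates

    @classmethod
    def from_mapping(cls, data: Mapping) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(data)
        for key in ("strain_counts", "error_profiles", "fractions",
                    "divergence_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def params(self) -> ProfileParams:
        return ProfileParams(min_cov=self.min_cov,
                             min_identity=self.min_identity)


def _child_seed(master: int, *keys) -> int:
    """Stable seed splitting: strings are hashed with crc32."""
    ints = [zlib.crc32(k.encode()) if isinstance(k, str) else int(k)
            for k in keys]
    ss = np.random.SeedSequence([int(master), *ints])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_insilico_design(config: ExperimentConfig,
                        workdir: str | Path | None = None
                        ) -> dict[str, pd.DataFrame]:
    """Run the simulate -> profile -> rarefy grid and collect result tables.

    One strain set per strain count (shared across error profiles, so error
    effects are compared on identical communities). Returns
    ``{"rarefaction_points": ..., "error_summary": ...}``. Metagenomes whose
    full data set yields no pi-qualifying site are flagged, not fatal.

    ``workdir`` holds the bulky per-metagenome FASTQ/SAM intermediates; by
    default a temporary directory is used and discarded.
    """
    tmp = None
    if workdir is None:
        tmp = tempfile.TemporaryDirectory(prefix="microdepth_sim_")
        workdir = Path(tmp.name)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    rows = []
    for sc in config.strain_counts:
        ancestor = generate_ancestor(config.genome_length, config.gc_fraction,
                                     seed=_child_seed(config.seed, "ancestor"))
        sset = derive_strain_set(ancestor, sc, config.divergence_range,
                                 seed=_child_seed(config.seed, "strains", sc))
        ab = sample_lognormal_abundances(
            sc, config.sigma, seed=_child_seed(config.seed, "abund", sc))
        for profile_name in config.error_profiles:
            t0 = time.perf_counter()
            sim_seed = _child_seed(config.seed, "sim", sc, profile_name)
            sim = simulate_metagenome(
                sset, ab, config.n_reads, config.read_length,
                ErrorProfile.from_name(profile_name), seed=sim_seed,
                out_prefix=workdir / f"sc{sc}_{profile_name}")
            reads = load_alignments(sim.sam, ancestor)
            full = profile_genome(reads, ancestor, params)
            flagged = full.n_sites_pi == 0
            if flagged:
                warnings.warn(
                    f"metagenome sc={sc} profile={profile_name}: no site "
                    f"reaches min_cov={params.min_cov}; rows flagged")
            points = rarefaction_series(
                reads, ancestor, config.fractions, config.replicates, params,
                seed=_child_seed(config.seed, "rarefy", sc, profile_name))
            for p in points:
                rows.append({
                    "strain_count": sc, "error_profile": profile_name,
                    "fraction": p.fraction, "replicate": p.replicate,
                    "seed": p.seed, "n_reads": p.n_reads,
                    "mean_depth": p.mean_depth, "pi": p.pi, "anir": p.anir,
                    "ratio_pi": p.ratio_pi, "ratio_anir": p.ratio_anir,
                    "full_pi": full.pi, "full_anir": full.anir,
                    "full_mean_depth": full.mean_depth, "flagged": flagged,
                })
            logger.info("sc=%d profile=%s done in %.1fs (full depth %.1fX)",
                        sc, profile_name, time.perf_counter() - t0,
                        full.mean_depth)
    points_df = pd.DataFrame(rows)
    summaries = []
    for metric in ("pi", "anir"):
        ok = points_df[~points_df["flagged"]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ = average_absolute_error(
                list(zip(ok[metric], ok[f"full_{metric}"])),
                list(ok["mean_depth"]))
        summ.insert(0, "metric", metric)
        if not summ.empty:
            summaries.append(summ)
    if summaries:
        summary_df = pd.concat(summaries, ignore_index=True)
    else:
        summary_df = pd.DataFrame(columns=["metric", "depth_bin",
                                           "mean_abs_error_pct",
                                           "sd_error_pct", "n"])
    if tmp is not None:
        tmp.cleanup()
    return {"rarefaction_points": points_df, "error_summary": summary_df}


def compare_environments(inputs: Iterable[Mapping],
                         params: ProfileParams | None = None) -> pd.DataFrame:
    """Profile externally produced alignments into an observed-pi table.

    ``inputs`` is an iterable of mappings with keys ``sample``, ``species``,
    ``alignments`` (SAM/BAM path) and ``reference`` (FASTA path). Missing or
    unreadable inputs are reported per sample via warnings, not fatal. The
    output table (sample, species, mean_depth, depth_category, pi, anir) is
    formatted for direct use by external PERMANOVA software.
    """
    params = params or ProfileParams()
    rows = []
    for item in inputs:
        sample, species = item["sample"], item["species"]
        try:
            ref = load_reference(item["reference"])
            res = profile_genome(item["alignments"], ref, params)
        except (OSError, ValueError) as exc:
            warnings.warn(f"sample {sample!r} / species {species!r} skipped: "
                          f"{exc}")
            continue
        rows.append({
            "sample": sample, "species": species,
            "mean_depth": res.mean_depth,
            "depth_category": depth_category(res.mean_depth),
            "pi": res.pi, "anir": res.anir,
        })
    return pd.DataFrame(
        rows, columns=["sample", "species", "mean_depth", "depth_category",
                       "pi", "anir"])


def write_report(tables: Mapping[str, pd.DataFrame], output_dir: str | Path,
                 config: ExperimentConfig | None = None,
                 wall_clock_s: float | None = None) -> list[Path]:
    """Write result tables as TSV plus a JSON run manifest.

    Overwrites idempotently, logging each file. Returns the written paths.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        logger.info("wrote %s (%d rows)", path, len(df))
        written.append(path)
    manifest = {
        "package": "microdepth",
        "version": __version__,
        "config": dataclasses.asdict(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
        "tables": {name: len(df) for name, df in tables.items()},
        "wall_clock_s": wall_clock_s,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("wrote %s", mpath)
    written.append(mpath)
    return written
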
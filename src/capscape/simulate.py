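"""Synthetic genome, small-RNA libraries, mass observations and TLC plates.

Generates every input the pipeline consumes, with per-record ground truth,
emulating the experimental design the pipeline targets: four library types
(a plain small-RNA library with the expected miRNA prominence at 20-24 nt, a
pyrophosphatase-selected capped library, a cap-trapped CAGE library whose
tags are cleaved to a fixed 27 nt, and a methylguanosine-cap
immunoprecipitation enriched for snRNA fragments plus its no-antibody
control), 100-nt single-end reads carrying a 17-nt 3' adapter, rRNA
contamination, [M-H]- cap masses with ppm-scale Gaussian noise, and
triplicate TLC plates.

All randomness derives from the single configured seed; the same seed gives
byte-identical outputs.  The rDNA "reference" is a designated segment of
the synthetic genome, so no external sequence is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annot import AnnotationFeature, write_features_bed
from .chem import CapStructure
from .match import FRACTIONS, enumerate_caps
from .reads import DEFAULT_ADAPTER, _revcomp
from .tlc import TLC_FRACTIONS

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "SimRead",
    "gen_genome_and_annotation",
    "gen_library",
    "gen_mass_observations",
    "gen_spot_tables",
    "write_fastq",
    "simulate_all",
    "DEFAULT_LIBRARY_PROFILES",
    "DEFAULT_SPOT_PROFILES",
]

_BASES = np.array(list("ACGT"))

# Genomic footprint of each planted feature class (lo, hi nt).
DEFAULT_FEATURE_LENGTH_RANGES: Mapping[str, tuple[int, int]] = {
    "intron": (200, 600),
    "exon": (100, 300),
    "miRNA": (60, 90),
    "snRNA": (100, 200),
    "snoRNA": (60, 150),
    "tRNA": (70, 90),
}

DEFAULT_FEATURES_PER_BIOTYPE: Mapping[str, int] = {b: 20 for b in DEFAULT_FEATURE_LENGTH_RANGES}

# Per-library biotype mixture weights and truncated-normal insert-length
# parameters (mean, sd, lo, hi).  "unknown" draws from intergenic sequence.
DEFAULT_LIBRARY_PROFILES: Mapping[str, Mapping] = {
    "sRNA": {
        "weights": {
            "miRNA": 0.55, "exon": 0.12, "tRNA": 0.08, "snoRNA": 0.07,
            "snRNA": 0.05, "intron": 0.05, "unknown": 0.08,
        },
        "lengths": {
            "miRNA": (22, 1.5, 19, 26), "exon": (40, 20, 15, 95),
            "tRNA": (72, 8, 55, 90), "snoRNA": (70, 15, 45, 95),
            "snRNA": (120, 25, 80, 180), "intron": (45, 20, 15, 95),
            "unknown": (40, 20, 15, 95),
        },
    },
    "capped_sRNA": {
        "weights": {
            "snoRNA": 0.28, "tRNA": 0.15, "miRNA": 0.15, "exon": 0.15,
            "snRNA": 0.07, "intron": 0.05, "unknown": 0.15,
        },
        "lengths": {
            "snoRNA": (40, 8, 20, 60), "tRNA": (38, 6, 25, 50),
            "miRNA": (22, 1.5, 19, 26), "exon": (30, 15, 12, 90),
            "snRNA": (130, 25, 80, 180), "intron": (40, 20, 15, 95),
            "unknown": (30, 15, 12, 90),
        },
    },
    "sRNA_CAGE": {
        "weights": {
            "snRNA": 0.35, "exon": 0.15, "snoRNA": 0.10, "tRNA": 0.05,
            "miRNA": 0.05, "intron": 0.10, "unknown": 0.20,
        },
        "lengths": {
            "snRNA": (120, 25, 60, 180), "exon": (60, 20, 30, 95),
            "snoRNA": (80, 20, 40, 150), "tRNA": (72, 8, 55, 90),
            "miRNA": (22, 1.5, 19, 26), "intron": (60, 25, 30, 95),
            "unknown": (60, 25, 30, 95),
        },
    },
    "IP_K121": {
        "weights": {
            "snRNA": 0.50, "snoRNA": 0.20, "exon": 0.10, "unknown": 0.10,
            "intron": 0.05, "tRNA": 0.05,
        },
        "lengths": {
            "snRNA": (40, 6, 30, 55), "snoRNA": (45, 10, 25, 80),
            "exon": (15, 4, 8, 18), "tRNA": (38, 6, 25, 50),
            "intron": (40, 20, 15, 95), "unknown": (40, 20, 15, 95),
        },
    },
    "IP_control": {
        "weights": {
            "miRNA": 0.30, "exon": 0.20, "unknown": 0.20, "intron": 0.10,
            "tRNA": 0.10, "snoRNA": 0.05, "snRNA": 0.05,
        },
        "lengths": {
            "miRNA": (22, 1.5, 19, 26), "exon": (40, 20, 15, 95),
            "tRNA": (72, 8, 55, 90), "snoRNA": (70, 15, 45, 95),
            "snRNA": (120, 25, 80, 180), "intron": (45, 20, 15, 95),
            "unknown": (40, 20, 15, 95),
        },
    },
}

# True spot percentage profiles per gel fraction (sum to 100 within each).
DEFAULT_SPOT_PROFILES: Mapping[str, Mapping[str, float]] = {
    "<50": {
        "Gp": 28, "2,2,7mGp": 20, "2,2mGp": 17, "7mGp": 8, "2,7mGp": 6,
        "2mGp": 5, "1mGp": 5, "Cmp": 4, "Ap": 3, "Cp": 2, "Up": 2,
    },
    "50-100": {
        "2,2mGp": 30, "Gp": 22, "2,2,7mGp": 15, "2mGp": 8, "1mGp": 6,
        "7mGp": 5, "Cmp": 5, "Ap": 4, "Cp": 3, "Up": 2,
    },
    "100-200": {
        "2,2,7mGp": 25, "Gp": 24, "2,2mGp": 14, "2,7mGp": 8, "7mGp": 7,
        "2mGp": 6, "1mGp": 5, "Cmp": 4, "Cp": 3, "Ap": 2, "Up": 2,
    },
}

# rng stream indices: one independent stream per generator stage.
_STREAMS = {
    "genome": 0,
    "sRNA": 1,
    "capped_sRNA": 2,
    "sRNA_CAGE": 3,
    "IP_K121": 4,
    "IP_control": 5,
    "mass": 6,
    "tlc": 7,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 100_000
    chrom_name: str = "chrS"
    features_per_biotype: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURES_PER_BIOTYPE)
    )
    feature_length_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_LENGTH_RANGES)
    )
    rrna_length: int = 2_000
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 100
    cage_tag_length: int = 27
    rrna_contamination: float = 0.05
    reads_per_library: int = 2_000
    library_profiles: Mapping[str, Mapping] = field(
        default_factory=lambda: {k: {kk: dict(vv) for kk, vv in v.items()}
                                 for k, v in DEFAULT_LIBRARY_PROFILES.items()}
    )
    mass_noise_sd_ppm: float = 1.5
    n_mass_observations: int = 200
    tlc_replicates: int = 3
    tlc_noise_sd: float = 0.01  # intensity noise as a fraction of plate scale
    spot_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SPOT_PROFILES.items()}
    )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class SimulatedGenome:
    genome: dict[str, str]
    features: list[AnnotationFeature]
    rrna: str
    rrna_interval: tuple[int, int]
    truth: pd.DataFrame


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def gen_genome_and_annotation(config: SimulationConfig) -> SimulatedGenome:
    """Random genome with non-overlapping planted features and an rDNA segment.

    Every feature's sequence is verified to occur exactly once in the genome
    (either strand), so exact-substring alignment of feature-derived tags is
    unambiguous; clashing intervals are re-randomised.
    """
    rng = config.rng("genome")
    n = config.genome_length
    seq = list(_random_seq(rng, n))
    rrna_start = n - config.rrna_length
    if rrna_start <= 0:
        raise ValueError("genome too small for the rDNA segment")
    occupied: list[tuple[int, int]] = [(rrna_start, n)]
    features: list[AnnotationFeature] = []
    for biotype in sorted(config.features_per_biotype):
        count = config.features_per_biotype[biotype]
        lo, hi = config.feature_length_ranges[biotype]
        for k in range(count):
            length = int(rng.integers(lo, hi + 1))
            for _attempt in range(2000):
                start = int(rng.integers(0, rrna_start - length))
                if all(start >= e + 5 or start + length <= s - 5 for s, e in occupied):
                    break
            else:
                raise ValueError("genome too small for requested features")
            occupied.append((start, start + length))
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                AnnotationFeature(
                    config.chrom_name, start, start + length, strand,
                    biotype, f"{biotype}-{k + 1}",
                )
            )
    genome_str = "".join(seq)
    # uniqueness check: re-randomise any feature whose sequence repeats
    for f in sorted(features, key=lambda f: f.start):
        for _ in range(10):
            sub = genome_str[f.start:f.end]
            fwd = genome_str.count(sub)
            rev = genome_str.count(_revcomp(sub))
            if fwd == 1 and rev == 0:
                break
            genome_str = (
                genome_str[: f.start] + _random_seq(rng, f.end - f.start) + genome_str[f.end:]
            )
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not plant a unique sequence for {f.name}")
    truth = pd.DataFrame(
        {
            "name": f.name, "biotype": f.biotype, "chrom": f.chrom,
            "start": f.start, "end": f.end, "strand": f.strand,
        }
        for f in sorted(features, key=lambda f: (f.start, f.name))
    )
    return SimulatedGenome(
        genome={config.chrom_name: genome_str},
        features=sorted(features, key=lambda f: f.start),
        rrna=genome_str[rrna_start:],
        rrna_interval=(rrna_start, n),
        truth=truth,
    )


def _trunc_normal_int(rng: np.random.Generator, mean, sd, lo, hi) -> int:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return int(round(x))
    return int(np.clip(round(mean), lo, hi))


def gen_library(
    config: SimulationConfig,
    library_type: str,
    sim: SimulatedGenome,
    library_id: str | None = None,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Simulate one sequencing library: reads plus a per-read truth table.

    Each read is an insert (drawn 5'-anchored from a planted feature
    according to the library's biotype mixture, or from intergenic sequence
    for "unknown", or from the rDNA segment for contaminants) followed by
    the 3' adapter and random fill to the read length.  CAGE inserts are
    cleaved to the fixed tag length before adapter ligation.
    """
    if library_type not in config.library_profiles:
        raise ValueError(f"unknown library type {library_type!r}")
    library_id = library_id or library_type
    rng = config.rng(library_type)
    profile = config.library_profiles[library_type]
    weights = profile["weights"]
    lengths = profile["lengths"]
    biotypes = sorted(weights)
    p = np.array([weights[b] for b in biotypes], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{library_type}: mixture weights sum to {p.sum()}, not 1")
    chrom = config.chrom_name
    genome_seq = sim.genome[chrom]
    by_biotype: dict[str, list[AnnotationFeature]] = {}
    for f in sim.features:
        by_biotype.setdefault(f.biotype, []).append(f)
    blocked = [(f.start, f.end) for f in sim.features] + [sim.rrna_interval]

    reads, truth_rows = [], []
    for i in range(config.reads_per_library):
        read_id = f"{library_id}_r{i:05d}"
        if rng.random() < config.rrna_contamination:
            biotype, feature_name, strand = "rRNA", "rDNA", "+"
            L = _trunc_normal_int(rng, *lengths["unknown"])
            off = int(rng.integers(0, len(sim.rrna) - L))
            insert = sim.rrna[off : off + L]
            start = sim.rrna_interval[0] + off
        else:
            biotype = str(rng.choice(biotypes, p=p))
            L = _trunc_normal_int(rng, *lengths[biotype])
            if biotype == "unknown":
                feature_name = "intergenic"
                strand = "+" if rng.random() < 0.5 else "-"
                for _ in range(1000):
                    start = int(rng.integers(0, config.genome_length - L))
                    if all(start >= e or start + L <= s for s, e in blocked):
                        break
                sub = genome_seq[start : start + L]
                insert = sub if strand == "+" else _revcomp(sub)
            else:
                pool = by_biotype.get(biotype)
                if not pool:
                    raise ValueError(
                        f"{library_type}: mixture requires {biotype!r} but no such "
                        "features were planted in the genome"
                    )
                f = pool[int(rng.integers(0, len(pool)))]
                feature_name, strand = f.name, f.strand
                L = min(L, f.end - f.start)
                if strand == "+":
                    start = f.start
                    insert = genome_seq[f.start : f.start + L]
                else:
                    start = f.end - L
                    insert = _revcomp(genome_seq[f.end - L : f.end])
        if library_type == "sRNA_CAGE":
            insert = insert[: config.cage_tag_length]
            L = len(insert)
        read = insert + config.adapter
        if len(read) < config.read_length:
            read += _random_seq(rng, config.read_length - len(read))
        reads.append(SimRead(read_id, read[: config.read_length]))
        truth_rows.append(
            {
                "read_id": read_id, "library_id": library_id,
                "library_type": library_type, "biotype": biotype,
                "feature_name": feature_name, "insert_length": len(insert),
                "strand": strand, "insert_start": start,
            }
        )
    return reads, pd.DataFrame(truth_rows)


def gen_mass_observations(
    config: SimulationConfig,
    true_caps: Sequence[CapStructure] | None = None,
    n: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed [M-H]- masses from randomly drawn true cap structures.

    observed = true anion mass x (1 + eps), eps ~ N(0, sd_ppm x 1e-6).
    Returns (observations, truth); truth records the generating structure
    and its composition, the key under which isobar recovery is judged.
    """
    rng = config.rng("mass")
    caps = list(true_caps) if true_caps is not None else enumerate_caps()
    n = n if n is not None else config.n_mass_observations
    idx = rng.integers(0, len(caps), n)
    eps = rng.normal(0.0, config.mass_noise_sd_ppm * 1e-6, n)
    obs_rows, truth_rows = [], []
    for i in range(n):
        cap = caps[idx[i]]
        ident = f"obs{i:04d}"
        obs_rows.append(
            {
                "identifier": ident,
                "observed_mass": cap.anion_mass * (1.0 + eps[i]),
                "fraction": FRACTIONS[int(rng.integers(0, len(FRACTIONS)))],
            }
        )
        truth_rows.append(
            {
                "identifier": ident,
                "true_label": cap.canonical_label,
                "composition": cap.neutral_formula.composition(),
            }
        )
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


def gen_spot_tables(
    config: SimulationConfig,
    true_profiles: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw TLC spot intensities from true percentage profiles.

    raw = truth/100 x plate scale + background + Gaussian noise, one plate
    per (fraction, replicate); each plate also carries a saturated origin
    spot that normalisation must exclude.
    """
    rng = config.rng("tlc")
    profiles = true_profiles if true_profiles is not None else config.spot_profiles
    rows = []
    for fraction in TLC_FRACTIONS:
        if fraction not in profiles:
            continue
        profile = profiles[fraction]
        for rep in range(1, config.tlc_replicates + 1):
            plate_id = f"{fraction}_rep{rep}"
            scale = float(rng.uniform(5_000, 20_000))
            background = float(rng.uniform(50, 150))
            for spot, pct in sorted(profile.items()):
                noise = float(rng.normal(0.0, config.tlc_noise_sd * scale)) if config.tlc_noise_sd > 0 else 0.0
                signal = max(pct / 100.0 * scale + noise, 0.0)
                rows.append(
                    {
                        "plate_id": plate_id, "replicate_id": f"rep{rep}",
                        "fraction": fraction, "spot_label": spot,
                        "raw_intensity": signal + background,
                        "background": background, "saturated": False,
                    }
                )
            rows.append(
                {
                    "plate_id": plate_id, "replicate_id": f"rep{rep}",
                    "fraction": fraction, "spot_label": "origin",
                    "raw_intensity": 65_535.0, "background": background,
                    "saturated": True,
                }
            )
    truth = pd.DataFrame(
        {"fraction": fr, "spot_label": spot, "true_pct": pct}
        for fr, profile in profiles.items()
        for spot, pct in sorted(profile.items())
    )
    return pd.DataFrame(rows), truth


def write_fastq(reads: Sequence[SimRead], path) -> int:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    return len(reads)


def simulate_all(config: SimulationConfig, outdir) -> dict:
    """Generate and write every pipeline input; returns paths and counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = gen_genome_and_annotation(config)
    chrom = config.chrom_name
    with open(outdir / "genome.fasta", "w") as fh:
        fh.write(f">{chrom}\n{sim.genome[chrom]}\n")
    with open(outdir / "rrna.fasta", "w") as fh:
        fh.write(f">rDNA_synthetic\n{sim.rrna}\n")
    write_features_bed(sim.features, outdir / "features.bed")
    sim.truth.to_csv(outdir / "features_truth.csv", index=False)
    manifest = {
        "genome": str(outdir / "genome.fasta"),
        "rrna": str(outdir / "rrna.fasta"),
        "features": str(outdir / "features.bed"),
        "n_features": len(sim.features),
        "libraries": {},
    }
    for lib_type in config.library_profiles:
        reads, truth = gen_library(config, lib_type, sim)
        fq = outdir / f"{lib_type}.fastq"
        write_fastq(reads, fq)
        truth.to_csv(outdir / f"{lib_type}_truth.csv", index=False)
        manifest["libraries"][lib_type] = {"fastq": str(fq), "n_reads": len(reads)}
    obs, mass_truth = gen_mass_observations(config)
    obs.to_csv(outdir / "mass_observations.csv", index=False)
    mass_truth.to_csv(outdir / "mass_truth.csv", index=False)
    manifest["mass_observations"] = str(outdir / "mass_observations.csv")
    manifest["n_mass_observations"] = len(obs)
    spots, spot_truth = gen_spot_tables(config)
    spots.to_csv(outdir / "tlc_spots.csv", index=False)
    spot_truth.to_csv(outdir / "tlc_truth.csv", index=False)
    manifest["tlc_spots"] = str(outdir / "tlc_spots.csv")
    manifest["n_tlc_spots"] = len(spots)
    return manifest
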
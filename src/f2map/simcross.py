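"""Synthetic F2 intercross data generator.

Simulates two fully homozygous founders that differ at parent-unique SNP
loci laid out on multi-scaffold contigs, F2 progeny genotypes formed from
two independently recombined gametes, per-site Poisson read depth with
per-read error, missing calls, a fully penetrant recessive trait locus
(3:1 F2 segregation) and an optional hemizygous deletion that silences
read coverage over an interval.

The generator is the ground-truth source for all downstream tests: the
returned :class:`TruthTrack` records latent genotype states, crossover
positions and phenotypes, while :func:`observe` degrades the truth into
per-sample VCF-style calls the rest of the pipeline consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATE_AA",
    "STATE_H",
    "STATE_BB",
    "Scaffold",
    "SimConfig",
    "ConfigError",
    "TruthTrack",
    "simulate_founders",
    "simulate_f2",
    "observe",
    "simulate_coverage",
    "write_vcf",
    "write_phenotype_table",
]

# Latent genotype states: dosage of the P2 haplotype.
STATE_AA, STATE_H, STATE_BB = 0, 1, 2
STATE_LABELS = ("AA", "H", "BB")

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised when a :class:`SimConfig` violates its invariants."""


@dataclass(frozen=True)
class Scaffold:
    """A simulated contig with a physical and a genetic length."""

    name: str
    length_bp: int
    length_cm: float


@dataclass
class SimConfig:
    """Parameters of the simulated cross and sequencing experiment.

    Attributes
    ----------
    n_progeny:
        Number of F2 individuals.
    scaffolds:
        Contigs carrying the simulated loci.
    snp_density:
        Expected parent-unique SNP loci per bp.
    mean_depth:
        Poisson mean of per-site read depth.
    per_read_error:
        Probability that a single read reports the wrong allele.
    missing_rate:
        Probability that a covered site still yields no call.
    trait_locus:
        ``(scaffold, position)`` of the fully penetrant recessive locus;
        a locus is inserted there if none exists.
    trait_parent:
        Which founder carries the recessive (trait-causing) allele.
    deletion:
        Optional ``(scaffold, start, end)`` interval (1-based inclusive)
        with zero read coverage in deletion carriers.
    deletion_carriers:
        Sample names affected by the deletion.
    """

    scaffolds: Sequence[Scaffold]
    n_progeny: int = 120
    snp_density: float = 5e-4
    mean_depth: float = 10.0
    per_read_error: float = 0.005
    missing_rate: float = 0.0
    trait_locus: Optional[tuple[str, int]] = None
    trait_parent: str = "P1"
    deletion: Optional[tuple[str, int, int]] = None
    deletion_carriers: tuple[str, ...] = ()
    seed: int = 0

    def validation_errors(self) -> list[str]:
        errors: list[str] = []
        if not self.scaffolds:
            errors.append("scaffolds: at least one scaffold is required")
        if self.n_progeny < 1:
            errors.append("n_progeny: must be >= 1")
        for name, value in (
            ("per_read_error", self.per_read_error),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= value <= 1.0:
                errors.append(f"{name}: must lie in [0, 1]")
        if self.snp_density <= 0:
            errors.append("snp_density: must be > 0")
        if self.mean_depth < 0:
            errors.append("mean_depth: must be >= 0")
        if self.trait_parent not in ("P1", "P2"):
            errors.append("trait_parent: must be 'P1' or 'P2'")
        by_name = {s.name: s for s in self.scaffolds}
        for s in self.scaffolds:
            if s.length_bp < 1:
                errors.append(f"scaffolds[{s.name}]: length_bp must be >= 1")
            if s.length_cm <= 0:
                errors.append(f"scaffolds[{s.name}]: length_cm must be > 0")
        if self.deletion is not None:
            name, start, end = self.deletion
            if name not in by_name:
                errors.append("deletion: scaffold not among config scaffolds")
            elif not 1 <= start <= end <= by_name[name].length_bp:
                errors.append("deletion: interval must lie within its scaffold")
        if self.trait_locus is not None and self.trait_locus[0] not in by_name:
            errors.append("trait_locus: scaffold not among config scaffolds")
        return errors

    def validate(self) -> "SimConfig":
        errors = self.validation_errors()
        if errors:
            raise ConfigError("; ".join(errors))
        return self


@dataclass
class TruthTrack:
    """Latent ground truth of a simulated F2 population.

    ``states`` is a loci x progeny matrix of {AA, H, BB} codes (dosage of
    the P2 haplotype); crossovers are recorded per progeny as
    ``(scaffold, bp position, gamete index)``; phenotypes are 1 for the
    recessive (determinate-analog) class and 0 otherwise.
    """

    loci: pd.DataFrame
    progeny: list[str]
    states: np.ndarray
    crossovers: dict[str, list[tuple[str, float, int]]]
    phenotypes: np.ndarray
    trait_index: int
    #: starting parental haplotype (0=P1, 1=P2) per (progeny, scaffold, gamete)
    gamete_starts: dict[tuple[str, str, int], int] | None = None

    def state_labels(self) -> np.ndarray:
        return np.array(STATE_LABELS)[self.states]


def _progeny_names(n: int) -> list[str]:
    return [f"F{i + 1:03d}" for i in range(n)]


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the founder locus table.

    Every locus is homozygous REF in one parent and homozygous ALT in the
    other; the ``origin`` column records which parent carries the ALT
    allele (P1-unique or P2-unique).  Positions are strictly increasing
    within each scaffold.  The trait locus, if configured, is guaranteed
    to be present.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    frames = []
    for scaf in config.scaffolds:
        n_loci = min(int(rng.poisson(config.snp_density * scaf.length_bp)), scaf.length_bp)
        pos = np.sort(rng.choice(scaf.length_bp, size=n_loci, replace=False)) + 1
        if (
            config.trait_locus is not None
            and config.trait_locus[0] == scaf.name
            and config.trait_locus[1] not in pos
        ):
            pos = np.sort(np.append(pos, config.trait_locus[1]))
        ref_idx = rng.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaf.name,
                    "pos": pos.astype(np.int64),
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "origin": np.where(rng.random(len(pos)) < 0.5, "P1", "P2"),
                }
            )
        )
    founders = pd.concat(frames, ignore_index=True)
    return founders


def _gamete_haplotypes(
    gpos_cm: np.ndarray, length_cm: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """One recombinant gamete along a scaffold.

    Crossover count is Poisson with mean ``length_cm / 100`` (genetic
    length in Morgans) and crossover positions are uniform on the genetic
    map — no interference, so the Kosambi scale used downstream is an
    approximation the simulator deliberately ignores.

    Returns (haplotype per locus in {0=P1, 1=P2}, crossover cM positions,
    starting haplotype).
    """
    n_xo = rng.poisson(length_cm / 100.0)
    xo = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    start = int(rng.integers(0, 2))
    hap = (start + np.searchsorted(xo, gpos_cm)) % 2
    return hap, xo, start


def simulate_f2(founders: pd.DataFrame, config: SimConfig) -> TruthTrack:
    """Simulate F2 progeny as the union of two independent recombinant gametes.

    Phenotypes are assigned with complete penetrance at the trait locus:
    the recessive class is homozygosity for the ``trait_parent`` haplotype.

    Raises ``ValueError`` if the founder table is empty or the configured
    trait locus is not among the simulated loci.
    """
    if founders.empty:
        raise ValueError("founder table is empty")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF2]))
    progeny = _progeny_names(config.n_progeny)
    n_loci = len(founders)
    states = np.zeros((n_loci, config.n_progeny), dtype=np.int8)
    crossovers: dict[str, list[tuple[str, float, int]]] = {p: [] for p in progeny}
    gamete_starts: dict[tuple[str, str, int], int] = {}

    scaf_by_name = {s.name: s for s in config.scaffolds}
    for scaf_name, idx in founders.groupby("scaffold", sort=False).indices.items():
        scaf = scaf_by_name[str(scaf_name)]
        pos = founders["pos"].to_numpy()[idx]
        gpos = pos / scaf.length_bp * scaf.length_cm
        for j, name in enumerate(progeny):
            for gamete in (0, 1):
                hap, xo, start = _gamete_haplotypes(gpos, scaf.length_cm, rng)
                states[idx, j] += hap.astype(np.int8)
                bp = xo / scaf.length_cm * scaf.length_bp
                crossovers[name].extend((scaf.name, float(b), gamete) for b in bp)
                gamete_starts[(name, scaf.name, gamete)] = start

    if config.trait_locus is not None:
        match = (founders["scaffold"] == config.trait_locus[0]) & (
            founders["pos"] == config.trait_locus[1]
        )
        if not match.any():
            raise ValueError(f"trait locus {config.trait_locus} not among simulated loci")
        trait_index = int(np.flatnonzero(match.to_numpy())[0])
        recessive_state = STATE_AA if config.trait_parent == "P1" else STATE_BB
        phenotypes = (states[trait_index] == recessive_state).astype(np.int8)
    else:
        trait_index = -1
        phenotypes = np.zeros(config.n_progeny, dtype=np.int8)

    return TruthTrack(
        loci=founders[["scaffold", "pos"]].copy(),
        progeny=progeny,
        states=states,
        crossovers=crossovers,
        phenotypes=phenotypes,
        trait_index=trait_index,
        gamete_starts=gamete_starts,
    )


# Observation layer ---------------------------------------------------------

# call codes in the observation table
CALL_NONE, CALL_HOM_P1, CALL_HET, CALL_HOM_P2 = 0, 1, 2, 3
CALL_LABELS = ("none", "hom_p1", "het", "hom_p2")


def _sample_calls(
    states_col: np.ndarray,
    depth: np.ndarray,
    missing: np.ndarray,
    per_read_error: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Reads and calls for one sample. Returns (call code, P2-allele read count)."""
    # probability a read shows the P2 allele, by latent state
    p_read = np.array([per_read_error, 0.5, 1.0 - per_read_error])[states_col]
    n_p2 = rng.binomial(depth, p_read)
    call = np.full(states_col.shape, CALL_HET, dtype=np.int8)
    call[n_p2 == 0] = CALL_HOM_P1
    call[n_p2 == depth] = CALL_HOM_P2
    call[(depth == 0) | missing] = CALL_NONE
    return call, n_p2


def observe(
    truth: TruthTrack,
    founders: pd.DataFrame,
    config: SimConfig,
    out_dir: str | os.PathLike | None = None,
) -> tuple[pd.DataFrame, dict[str, Path]]:
    """Degrade latent truth into sequencing observations and per-sample VCFs.

    Depth is Poisson(``mean_depth``); each read from a heterozygote shows
    either allele with probability 1/2 before error; per-read error flips
    the allele with probability ``per_read_error``.  Sites where both
    alleles are seen are called heterozygous, a single seen allele gives a
    homozygous call, and depth 0 or a missing draw gives no call.
    Deletion carriers have depth 0 across the deleted interval.

    Parents are observed through the same read model as progeny.

    Returns the long observation table and, when ``out_dir`` is given,
    a mapping sample -> written VCF path (one file per sample).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0B5]))
    samples = ["P1", "P2"] + truth.progeny
    n_loci = len(founders)
    scaffolds = founders["scaffold"].to_numpy()
    positions = founders["pos"].to_numpy()

    # parental latent states are homozygous for their own haplotype
    parent_states = {
        "P1": np.full(n_loci, STATE_AA, dtype=np.int8),
        "P2": np.full(n_loci, STATE_BB, dtype=np.int8),
    }

    deletion_mask = np.zeros(n_loci, dtype=bool)
    if config.deletion is not None:
        name, start, end = config.deletion
        deletion_mask = (scaffolds == name) & (positions >= start) & (positions <= end)

    records = []
    vcf_paths: dict[str, Path] = {}
    for j, sample in enumerate(samples):
        col = parent_states[sample] if sample in parent_states else truth.states[:, j - 2]
        depth = rng.poisson(config.mean_depth, size=n_loci)
        if sample in config.deletion_carriers:
            depth = np.where(deletion_mask, 0, depth)
        missing = rng.random(n_loci) < config.missing_rate
        call, n_p2 = _sample_calls(col, depth, missing, config.per_read_error, rng)
        records.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "scaffold": scaffolds,
                    "pos": positions,
                    "depth": depth,
                    "n_p1": depth - n_p2,
                    "n_p2": n_p2,
                    "call": np.array(CALL_LABELS)[call],
                }
            )
        )
        if out_dir is not None:
            gt = _call_to_gt(call, founders["origin"].to_numpy())
            path = Path(out_dir) / f"{sample}.vcf"
            write_vcf(path, sample, founders, gt, depth, config.scaffolds)
            vcf_paths[sample] = path

    observations = pd.concat(records, ignore_index=True)
    return observations, vcf_paths


def _call_to_gt(call: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Map parent-oriented calls to VCF GT strings given each locus's ALT parent."""
    p1_is_alt = origin == "P1"
    gt = np.full(call.shape, "./.", dtype=object)
    gt[call == CALL_HET] = "0/1"
    hom_p1 = call == CALL_HOM_P1
    hom_p2 = call == CALL_HOM_P2
    gt[hom_p1 & p1_is_alt] = "1/1"
    gt[hom_p1 & ~p1_is_alt] = "0/0"
    gt[hom_p2 & p1_is_alt] = "0/0"
    gt[hom_p2 & ~p1_is_alt] = "1/1"
    return gt


def write_vcf(
    path: str | os.PathLike,
    sample: str,
    loci: pd.DataFrame,
    gt: np.ndarray,
    depth: np.ndarray,
    scaffolds: Sequence[Scaffold],
) -> Path:
    """Write a minimal single-sample VCF (CHROM, POS, REF, ALT, GT, DP)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for scaf in scaffolds:
            fh.write(f"##contig=<ID={scaf.name},length={scaf.length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for i, row in enumerate(loci.itertuples(index=False)):
            fh.write(
                f"{row.scaffold}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\t"
                f"GT:DP\t{gt[i]}:{int(depth[i])}\n"
            )
    return path


def write_phenotype_table(path: str | os.PathLike, truth: TruthTrack) -> Path:
    """Write the progeny phenotype table (sample, phenotype) as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = np.where(truth.phenotypes == 1, "determinate", "indeterminate")
    pd.DataFrame({"sample": truth.progeny, "phenotype": labels}).to_csv(
        path, sep="\t", index=False
    )
    return path


def simulate_coverage(
    length_bp: int,
    mean_depth: float = 10.0,
    deletion: Optional[tuple[int, int]] = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-base Poisson coverage with an optional zeroed 1-based inclusive interval."""
    rng = np.random.default_rng(seed)
    depth = rng.poisson(mean_depth, size=length_bp)
    if deletion is not None:
        start, end = deletion
        if not 1 <= start <= end <= length_bp:
            raise ValueError("deletion interval must lie within the scaffold")
        depth[start - 1 : end] = 0
    return depth
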
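"""Seeded generators for bioassay datasets and toy genomes.

Everything downstream — efficacy tables, ANOVAs, cluster screens, ANI — is
exercised on data from this module, so the generators encode the study
conditions explicitly:

* :func:`generate_bioassay` emulates a 5-group (control + 1e5..1e8
  conidia/mL) x 4-replicate x 10-tick adult immersion test.  The per-group
  default probabilities and means are calibrated to the published group
  summaries of such a bioassay (mortality 5/10/15/50/50%, morbidity
  2.5/90/100/100/100%, EPI ~53/51/53/40/49%, hatching ~86/76/71/68/56%);
  they are calibration targets of the stochastic model, not fitted
  estimates.  Hatching is beta-binomial (replicate-level hatch-rate spread
  in real assays is far above binomial noise).
* :func:`generate_cluster_genome` plants an ordered, optionally mutated /
  deleted / permuted gene cluster into a random background genome and emits
  the ground truth (coordinates, realized identity) for parameter-recovery
  tests.
* :func:`generate_genome_pair` produces a genome and a diverged copy with
  i.i.d. substitutions for ANI recovery tests.

One global seed feeds a hierarchy of per-unit streams (``SeedSequence``
spawn keys), so enlarging the design does not perturb the records already
generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .bioassay_model import CONTROL_LABEL, TickRecord
from .genome_screen import Sequence

__all__ = [
    "SyntheticBioassayConfig",
    "ClusterPlantSpec",
    "PlantedCluster",
    "GenomePair",
    "generate_bioassay",
    "generate_cluster_genome",
    "generate_genome_pair",
    "AFLATOXIN_CLUSTER_GENES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Reference gene order of the ~29-gene aflatoxin biosynthesis cluster
#: (aflF .. sugR plus the hypB1 hypothetical member).
AFLATOXIN_CLUSTER_GENES = (
    "aflF", "aflU", "aflT", "aflC", "aflD", "aflA", "aflB", "aflR", "aflS",
    "aflH", "aflJ", "aflE", "aflM", "aflN", "aflG", "aflL", "aflI", "aflO",
    "aflP", "aflQ", "aflK", "aflV", "aflW", "aflX", "nadA", "hypB1", "htxtA",
    "glcA", "sugR",
)


@dataclass(frozen=True)
class SyntheticBioassayConfig:
    """Generative parameters of the synthetic adult immersion test.

    Per-group vectors run parallel to ``groups``.  ``epi_mean`` is the group
    mean egg-mass / body-mass fraction; ``epi_cv`` the per-tick coefficient
    of variation of that fraction; ``hatch_rho`` the beta-binomial
    intraclass correlation of hatching; ``dead_no_ovi_fraction`` the chance
    a dead tick laid nothing at all.
    """

    groups: tuple[str, ...] = (CONTROL_LABEL, "1e5", "1e6", "1e7", "1e8")
    replicates: int = 4
    ticks_per_replicate: int = 10
    p_dead: tuple[float, ...] = (0.05, 0.10, 0.15, 0.50, 0.50)
    p_morbid: tuple[float, ...] = (0.025, 0.90, 1.0, 1.0, 1.0)
    epi_mean: tuple[float, ...] = (0.534, 0.507, 0.534, 0.398, 0.486)
    p_hatch: tuple[float, ...] = (0.856, 0.757, 0.706, 0.675, 0.563)
    epi_cv: float = 0.30
    hatch_rho: float = 0.10
    mass_median_mg: float = 250.0
    mass_log_sd: float = 0.15
    eggs_per_mg: float = 20.0
    dead_no_ovi_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.groups)
        for name in ("p_dead", "p_morbid", "epi_mean", "p_hatch"):
            vec = getattr(self, name)
            if len(vec) != k:
                raise ValueError(f"{name} must have one entry per group")
            if any(not 0 <= v <= 1 for v in vec) and name != "epi_mean":
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if any(v < 0 for v in self.epi_mean):
            raise ValueError("epi_mean entries must be >= 0")
        if not 0 <= self.dead_no_ovi_fraction <= 1:
            raise ValueError("dead_no_ovi_fraction must lie in [0, 1]")
        if not 0 <= self.hatch_rho < 1:
            raise ValueError("hatch_rho must lie in [0, 1)")
        if self.replicates < 1 or self.ticks_per_replicate < 1:
            raise ValueError("replicates and ticks_per_replicate must be >= 1")
        if self.epi_cv < 0 or self.eggs_per_mg <= 0:
            raise ValueError("epi_cv must be >= 0 and eggs_per_mg > 0")


def generate_bioassay(config: SyntheticBioassayConfig) -> list[TickRecord]:
    """Simulate one adult immersion test under ``config`` (reproducibly).

    Per tick: initial mass ~ log-normal; death and morbidity ~ independent
    Bernoullis; the egg-mass fraction ~ gamma around the group EPI mean
    (zeroed for a configurable fraction of dead ticks); total eggs ~
    Poisson(egg mass x eggs/mg); hatched ~ beta-binomial.
    """
    records: list[TickRecord] = []
    for gi, group in enumerate(config.groups):
        for rep in range(1, config.replicates + 1):
            ss = np.random.SeedSequence(config.seed, spawn_key=(gi, rep))
            rng = np.random.default_rng(ss)
            for t in range(1, config.ticks_per_replicate + 1):
                mass = float(
                    rng.lognormal(math.log(config.mass_median_mg), config.mass_log_sd)
                )
                dead = bool(rng.random() < config.p_dead[gi])
                morbid = bool(rng.random() < config.p_morbid[gi])
                # epi_mean is the observed group target; dead-tick zeroing
                # shrinks the realized mean, so the gamma mean compensates.
                zero_frac = config.p_dead[gi] * config.dead_no_ovi_fraction
                gamma_mean = config.epi_mean[gi] / max(1.0 - zero_frac, 1e-9)
                if config.epi_cv > 0:
                    shape = 1.0 / config.epi_cv**2
                    frac = float(rng.gamma(shape, gamma_mean / shape))
                else:
                    frac = gamma_mean
                if dead and rng.random() < config.dead_no_ovi_fraction:
                    frac = 0.0
                egg_mass = mass * frac
                eggs = (
                    int(rng.poisson(egg_mass * config.eggs_per_mg))
                    if egg_mass > 0
                    else 0
                )
                if eggs == 0:
                    egg_mass = 0.0  # no eggs laid at all
                    hatched = unhatched = 0
                else:
                    if config.hatch_rho > 0:
                        ab = (1.0 - config.hatch_rho) / config.hatch_rho
                        p = float(
                            rng.beta(
                                config.p_hatch[gi] * ab,
                                (1.0 - config.p_hatch[gi]) * ab,
                            )
                        )
                    else:
                        p = config.p_hatch[gi]
                    hatched = int(rng.binomial(eggs, p))
                    unhatched = eggs - hatched
                records.append(
                    TickRecord(
                        tick_id=f"{group}-r{rep}-t{t}",
                        group=group,
                        replicate=rep,
                        initial_mass=mass,
                        dead=dead,
                        morbid=morbid,
                        egg_mass=egg_mass,
                        hatched=hatched,
                        unhatched=unhatched,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Toy genomes
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, residues: str, mu: float) -> tuple[str, int]:
    """Substitute each base independently with probability ``mu``.

    Substituted bases are guaranteed different from the original.  Returns
    (mutated sequence, realized substitution count).
    """
    codes = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    idx = np.empty_like(codes)
    for i, b in enumerate(_BASES):
        idx[codes == b] = i
    hit = rng.random(len(codes)) < mu
    shift = rng.integers(1, 4, size=len(codes))
    new_idx = np.where(hit, (idx + shift) % 4, idx)
    return _BASES[new_idx].tobytes().decode("ascii"), int(hit.sum())


@dataclass(frozen=True)
class ClusterPlantSpec:
    """Recipe for planting a mutated gene cluster into a toy genome.

    ``deletions`` maps a gene name to 1-based inclusive spans removed from
    its planted copy.  ``order`` permutes the planting order (indices into
    the reference order); ``strands`` gives each planted copy's strand.
    """

    gene_names: tuple[str, ...] = AFLATOXIN_CLUSTER_GENES
    gene_lengths: tuple[int, ...] | None = None
    spacer_range: tuple[int, int] = (1000, 2000)
    mu: float = 0.0
    deletions: Mapping[str, tuple[tuple[int, int], ...]] = field(
        default_factory=dict
    )
    order: tuple[int, ...] | None = None
    strands: tuple[int, ...] | None = None
    background_length: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mu <= 0.3:
            raise ValueError("mu must lie in [0, 0.3]")
        if self.gene_lengths is not None and len(self.gene_lengths) != len(
            self.gene_names
        ):
            raise ValueError("gene_lengths must match gene_names")
        if self.order is not None and sorted(self.order) != list(
            range(len(self.gene_names))
        ):
            raise ValueError("order must be a permutation of gene indices")
        unknown = set(self.deletions) - set(self.gene_names)
        if unknown:
            raise ValueError(f"deletions for unknown genes: {sorted(unknown)}")


@dataclass(frozen=True)
class PlantedCluster:
    """A toy genome with its reference gene set and planting ground truth.

    ``truth`` columns: gene, start, end (1-based genome coordinates of the
    planted, possibly deletion-shortened copy), strand, planted_length,
    realized_identity (percent of surviving planted bases identical to the
    reference gene).
    """

    genome: Sequence
    genes: tuple[Sequence, ...]
    truth: pd.DataFrame


def generate_cluster_genome(spec: ClusterPlantSpec) -> PlantedCluster:
    """Generate a background genome with the cluster planted per ``spec``."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    n_genes = len(spec.gene_names)
    if spec.gene_lengths is not None:
        lengths = list(spec.gene_lengths)
    else:
        lengths = [int(rng.integers(900, 2401)) for _ in range(n_genes)]
    genes = tuple(
        Sequence(name, _random_dna(rng, ln))
        for name, ln in zip(spec.gene_names, lengths)
    )
    if max(lengths) > spec.background_length:
        raise ValueError("genes longer than background")

    order = list(spec.order) if spec.order is not None else list(range(n_genes))
    strands = list(spec.strands) if spec.strands is not None else [1] * n_genes

    mut_rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(1,))
    )
    planted: dict[str, tuple[str, float]] = {}
    for gene in genes:
        mutated, n_sub = _mutate(mut_rng, gene.residues, spec.mu)
        kept = np.ones(len(mutated), dtype=bool)
        for s, e in spec.deletions.get(gene.id, ()):
            if not 1 <= s <= e <= len(mutated):
                raise ValueError(
                    f"{gene.id}: deletion span ({s}, {e}) outside gene bounds"
                )
            kept[s - 1 : e] = False
        ref = np.frombuffer(gene.residues.encode(), dtype=np.uint8)
        mut = np.frombuffer(mutated.encode(), dtype=np.uint8)
        surviving = int(kept.sum())
        if surviving == 0:
            raise ValueError(f"{gene.id}: deletions removed the whole gene")
        ident = 100.0 * float((ref[kept] == mut[kept]).sum()) / surviving
        planted[gene.id] = (
            mut[kept].tobytes().decode("ascii"),
            ident,
        )

    # assemble: left flank + [gene spacer]* + right flank
    left = spec.background_length // 2
    right = spec.background_length - left
    parts = [_random_dna(rng, left)]
    pos = left
    rows = []
    for slot, gi in enumerate(order):
        gene = genes[gi]
        copy, ident = planted[gene.id]
        strand = strands[gi]
        if strand == -1:
            copy = Sequence("tmp", copy).reverse_complement().residues
        start = pos + 1
        parts.append(copy)
        pos += len(copy)
        rows.append(
            {
                "gene": gene.id,
                "start": start,
                "end": pos,
                "strand": "+" if strand == 1 else "-",
                "planted_length": len(copy),
                "realized_identity": ident,
            }
        )
        if slot < n_genes - 1:
            spacer = int(rng.integers(spec.spacer_range[0], spec.spacer_range[1] + 1))
            parts.append(_random_dna(rng, spacer))
            pos += spacer
    parts.append(_random_dna(rng, right))
    genome = Sequence("synthetic_genome", "".join(parts))
    return PlantedCluster(
        genome=genome, genes=genes, truth=pd.DataFrame(rows)
    )


@dataclass(frozen=True)
class GenomePair:
    """A genome, a diverged copy, and the realized substitution count."""

    a: Sequence
    b: Sequence
    n_substitutions: int

    @property
    def realized_identity(self) -> float:
        return 100.0 * (1.0 - self.n_substitutions / len(self.a))


def generate_genome_pair(length: int, mu: float, seed: int = 0) -> GenomePair:
    """Random genome plus a copy with i.i.d. substitutions at rate ``mu``."""
    if not 0 <= mu <= 0.3:
        raise ValueError("mu must lie in [0, 0.3]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    base = _random_dna(rng, length)
    mutated, n_sub = _mutate(rng, base, mu)
    return GenomePair(
        a=Sequence("genome_a", base),
        b=Sequence("genome_b", mutated),
        n_substitutions=n_sub,
    )
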
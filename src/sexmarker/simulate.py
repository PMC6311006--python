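"""Synthetic genotype, haplotype and offspring-count generators.

The generators emulate the statistical structure the scan assumes in a
reduced-representation (RAD-style) genotype matrix:

* autosomal biallelic loci in Hardy-Weinberg proportions, allele
  frequency independent of sex;
* fully penetrant sex-linked divergent sites — under ZW every female is
  heterozygous (one W-specific plus one Z allele) and every male is
  homozygous for the Z allele; XY mirrors the sexes.  Full penetrance
  models suppressed recombination between the nascent sex chromosomes;
* uniform genotyping error (a corrupted call is replaced by a uniform
  draw over the three genotypes at that locus) and random missingness.

Defaults mirror the study design this pipeline targets: 10 females and
10 males, a few thousand autosomal loci, a small set of W-linked sites,
and a W/Z haplotype pair whose 10 divergent sites cluster in a 285 bp
window of a 2315 bp sequence.  Error (0.02) and missingness (0.05) rates
are illustrative desk-scale values, not estimates from any dataset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .genotypes import Genotype, GenotypeMatrix, LocusRecord, MISSING, SampleInfo, Sex
from .primers import HaplotypePair
from .scan import HeterogametySystem


class TrueLocusClass(enum.Enum):
    AUTOSOMAL = "AUTOSOMAL"
    SEX_LINKED = "SEX_LINKED"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the genotype-matrix simulator (see module docstring)."""

    n_female: int = 10
    n_male: int = 10
    n_autosomal: int = 2000
    n_sexlinked: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    genotyping_error_rate: float = 0.02
    missing_rate: float = 0.05
    system: HeterogametySystem = HeterogametySystem.ZW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ValidationError("sample counts must be >= 0")
        if self.n_autosomal < 0 or self.n_sexlinked < 0:
            raise ValidationError("locus counts must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        for name in ("genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.system not in (HeterogametySystem.ZW, HeterogametySystem.XY):
            raise ValidationError("system must be ZW or XY")


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, list[TrueLocusClass]]:
    """Simulate a sexed genotype matrix plus its per-locus truth table.

    Sex-linked and autosomal loci are interleaved in a seeded random
    order; the returned truth list is aligned with ``matrix.loci``.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_f, n_m = config.n_female, config.n_male
    n_samples = n_f + n_m
    n_loci = config.n_autosomal + config.n_sexlinked

    samples = [
        SampleInfo(f"F{i + 1:03d}", Sex.FEMALE, "simulated") for i in range(n_f)
    ] + [SampleInfo(f"M{i + 1:03d}", Sex.MALE, "simulated") for i in range(n_m)]

    classes = [TrueLocusClass.AUTOSOMAL] * config.n_autosomal + [
        TrueLocusClass.SEX_LINKED
    ] * config.n_sexlinked
    order = rng.permutation(n_loci)
    classes = [classes[i] for i in order]

    het_sex, hom_sex = (
        (Sex.FEMALE, Sex.MALE)
        if config.system is HeterogametySystem.ZW
        else (Sex.MALE, Sex.FEMALE)
    )

    loci: list[LocusRecord] = []
    rows: list[list[Genotype]] = []
    bases = "ACGT"
    for i, cls in enumerate(classes):
        ref, alt = rng.choice(4, size=2, replace=False)
        ref_b, alt_b = bases[ref], bases[alt]
        prefix = "sl" if cls is TrueLocusClass.SEX_LINKED else "auto"
        loci.append(
            LocusRecord(f"{prefix}_{i + 1:05d}", "SIM", i + 1, ref_b, alt_b)
        )
        genotype_set = (
            Genotype((ref_b, ref_b)),
            Genotype((ref_b, alt_b)),
            Genotype((alt_b, alt_b)),
        )
        if cls is TrueLocusClass.AUTOSOMAL:
            q = rng.uniform(*config.maf_range)  # alt (minor) allele frequency
            alt_doses = rng.binomial(2, q, size=n_samples)
            row = [genotype_set[d] for d in alt_doses]
        else:
            het = Genotype((ref_b, alt_b))  # ref = shared allele, alt = W (or Y)
            hom = Genotype((ref_b, ref_b))
            row = [
                het if s.sex is het_sex else hom if s.sex is hom_sex else MISSING
                for s in samples
            ]
        if config.genotyping_error_rate > 0:
            err = rng.random(n_samples) < config.genotyping_error_rate
            draws = rng.integers(0, 3, size=n_samples)
            row = [
                genotype_set[draws[j]] if err[j] else row[j]
                for j in range(n_samples)
            ]
        if config.missing_rate > 0:
            miss = rng.random(n_samples) < config.missing_rate
            row = [MISSING if miss[j] else row[j] for j in range(n_samples)]
        rows.append(row)

    return GenotypeMatrix(loci, samples, rows), classes


def simulate_haplotype_pair(
    length: int = 2315,
    n_divergent: int = 10,
    region: tuple[int, int] | None = None,
    seed: int = 0,
) -> HaplotypePair:
    """Simulate a W/Z haplotype pair with planted divergent sites.

    A random base sequence of ``length`` is the Z haplotype; the W copy
    differs at ``n_divergent`` distinct positions drawn within ``region``
    (1-based inclusive; default: a 285 bp window starting at position
    1001, mirroring a short divergent cluster inside a longer cloned
    sequence).  Each substitution is to a different base.
    """
    if region is None:
        region = (min(1001, max(1, length - 284)), min(1285, length))
    lo, hi = region
    if not (1 <= lo <= hi <= length):
        raise ValidationError("region must lie within [1, length]")
    width = hi - lo + 1
    if n_divergent > width:
        raise ValidationError(
            f"cannot place {n_divergent} divergent sites in a {width} bp region"
        )
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    z = "".join(bases[i] for i in rng.integers(0, 4, size=length))
    sites = sorted(rng.choice(np.arange(lo, hi + 1), size=n_divergent, replace=False))
    w = list(z)
    for pos in sites:
        current = w[pos - 1]
        alternatives = [b for b in bases if b != current]
        w[pos - 1] = alternatives[rng.integers(0, 3)]
    return HaplotypePair("".join(w), z)


def simulate_offspring_sexes(
    n: int, p_female: float = 0.5, seed: int = 0
) -> tuple[int, int]:
    """Binomial offspring sexing: returns (n_female, n_male) summing to n."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    if not (0.0 <= p_female <= 1.0):
        raise ValidationError("p_female must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_f = int(rng.binomial(n, p_female))
    return n_f, n - n_f
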
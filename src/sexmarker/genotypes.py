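"""Core domain types: genotypes, samples, loci and the genotype matrix.

A :class:`Genotype` is an unordered diploid base-call pair, stored in
canonical (alphabetical) order, or missing.  Heterozygosity — not allele
identity — is what the downstream sex-association scan inspects, so the
type deliberately exposes ``is_het``/``is_hom`` as its main predicates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .errors import GenotypeParseError, ValidationError

VALID_BASES = frozenset("ACGT")
MISSING_TOKENS = frozenset({".", "./.", "-"})


class Sex(enum.Enum):
    """Phenotypic/recorded sex label of a sample."""

    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"

    @classmethod
    def from_token(cls, token: str) -> "Sex":
        t = token.strip().lower()
        if t in ("f", "female"):
            return cls.FEMALE
        if t in ("m", "male"):
            return cls.MALE
        if t in ("u", "unknown"):
            return cls.UNKNOWN
        raise GenotypeParseError(f"unrecognised sex token: {token!r}")


@dataclass(frozen=True)
class Genotype:
    """Unordered diploid genotype at one site; ``alleles is None`` == missing.

    The allele pair is canonicalised alphabetically, so ``("T", "C")`` and
    ``("C", "T")`` construct equal objects.
    """

    alleles: tuple[str, str] | None

    def __post_init__(self) -> None:
        if self.alleles is None:
            return
        a, b = self.alleles
        a, b = a.upper(), b.upper()
        if a not in VALID_BASES or b not in VALID_BASES:
            raise GenotypeParseError(f"invalid base in genotype: {self.alleles!r}")
        if (a, b) != tuple(sorted((a, b))):
            a, b = sorted((a, b))
        object.__setattr__(self, "alleles", (a, b))

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    def to_token(self) -> str:
        """Serialise in the compact genotype-table dialect.

        Homozygotes are a single base, heterozygotes ``X/Y``, missing ``.``.
        """
        if self.alleles is None:
            return "."
        a, b = self.alleles
        return a if a == b else f"{a}/{b}"


MISSING = Genotype(None)


def normalize_genotype(token: str, where: str = "") -> Genotype:
    """Parse a genotype-table token into a canonical :class:`Genotype`.

    Accepted forms (case-insensitive): a single base ``X`` (homozygote
    ``X/X``), a pair ``X/Y``, or a missing token (``.``, ``./.``, ``-``).

    Parameters
    ----------
    token
        The text token.
    where
        Optional location hint (file/row/column) used in error messages.

    Raises
    ------
    GenotypeParseError
        For any other token, naming the token and its location.
    """
    t = token.strip()
    if t in MISSING_TOKENS:
        return MISSING
    loc = f" at {where}" if where else ""
    up = t.upper()
    if len(up) == 1:
        if up not in VALID_BASES:
            raise GenotypeParseError(f"unparseable genotype token {token!r}{loc}")
        return Genotype((up, up))
    parts = up.split("/")
    if len(parts) == 2 and all(p in VALID_BASES for p in parts):
        return Genotype((parts[0], parts[1]))
    raise GenotypeParseError(f"unparseable genotype token {token!r}{loc}")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    sex: Sex
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")


@dataclass(frozen=True)
class LocusRecord:
    """One SNP locus: a named site on a contig with its two alleles.

    ``position`` is 1-based and inclusive within the contig, matching the
    usual marker-table convention; BED export converts to 0-based half-open.
    """

    marker_name: str
    contig_id: str
    position: int
    reference_base: str = "N"
    alternative_base: str = "N"
    sequence_length: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"locus {self.marker_name}: position must be >= 1, got {self.position}"
            )
        if self.sequence_length is not None and self.position > self.sequence_length:
            raise ValidationError(
                f"locus {self.marker_name}: position {self.position} exceeds "
                f"sequence length {self.sequence_length}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig_id, self.position)


class GenotypeMatrix:
    """Loci x samples genotype grid with per-sample sex labels.

    Rows are loci, columns are samples.  Dimensions are validated on
    construction; ``(contig_id, position)`` must be unique across loci and
    sample ids unique across samples.
    """

    def __init__(
        self,
        loci: Sequence[LocusRecord],
        samples: Sequence[SampleInfo],
        genotypes: Sequence[Sequence[Genotype]],
    ) -> None:
        self.loci = list(loci)
        self.samples = list(samples)
        self.genotypes = [list(row) for row in genotypes]
        if len(self.genotypes) != len(self.loci):
            raise ValidationError(
                f"genotype grid has {len(self.genotypes)} rows for {len(self.loci)} loci"
            )
        for i, row in enumerate(self.genotypes):
            if len(row) != len(self.samples):
                raise ValidationError(
                    f"genotype row {i} has {len(row)} entries for "
                    f"{len(self.samples)} samples"
                )
        keys = [loc.key for loc in self.loci]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (contig, position) among loci")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dups = sorted({x for x in ids if ids.count(x) > 1})
            raise ValidationError(f"duplicate sample ids: {', '.join(dups)}")

    # -- shape ---------------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    # -- access --------------------------------------------------------
    def row(self, locus_index: int) -> list[Genotype]:
        return self.genotypes[locus_index]

    def locus_by_name(self, marker_name: str) -> int:
        for i, loc in enumerate(self.loci):
            if loc.marker_name == marker_name:
                return i
        raise KeyError(marker_name)

    def sex_indices(self, sex: Sex) -> list[int]:
        return [j for j, s in enumerate(self.samples) if s.sex is sex]

    def genotypes_by_sex(self, locus_index: int, sex: Sex) -> list[Genotype]:
        row = self.genotypes[locus_index]
        return [row[j] for j in self.sex_indices(sex)]

    # -- transforms ----------------------------------------------------
    def subset_samples(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = list(indices)
        samples = [self.samples[j] for j in idx]
        rows = [[row[j] for j in idx] for row in self.genotypes]
        return GenotypeMatrix(self.loci, samples, rows)

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = sorted(range(self.n_loci), key=lambda i: self.loci[i].key)
        return GenotypeMatrix(
            [self.loci[i] for i in order],
            self.samples,
            [self.genotypes[i] for i in order],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.samples == other.samples
            and self.genotypes == other.genotypes
        )

    def __iter__(self) -> Iterator[tuple[LocusRecord, list[Genotype]]]:
        return iter(zip(self.loci, self.genotypes))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<GenotypeMatrix {self.n_loci} loci x {self.n_samples} samples>"


def replicate_samples(matrix: GenotypeMatrix, n_per_sample: int) -> GenotypeMatrix:
    """Expand each sample into ``n_per_sample`` identical copies.

    Used to turn a per-sex *pattern* row (one printed genotype row standing
    for every individual of that sex) into an explicit cohort.  Copies are
    suffixed ``_r1 .. _rN``; the expansion is always explicit, never applied
    silently by any reader.
    """
    if n_per_sample < 1:
        raise ValidationError("n_per_sample must be >= 1")
    samples: list[SampleInfo] = []
    for s in matrix.samples:
        for r in range(1, n_per_sample + 1):
            samples.append(
                SampleInfo(f"{s.sample_id}_r{r}", s.sex, s.species)
            )
    rows = [
        [g for g in row for _ in range(n_per_sample)] for row in matrix.genotypes
    ]
    return GenotypeMatrix(matrix.loci, samples, rows)
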
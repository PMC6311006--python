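"""Cross-species conservation of female-heterozygous (W-linked) markers.

A reference species' sex-specific markers are tested in another species'
genotype table: a marker is conserved when its locus shows the *same*
direction of sex linkage (heterozygous females, homozygous males) in that
species.  Direction matters — the claim being tested is homologous
W-linkage — but allele identity does not, since orthologous sites may
segregate different base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .genotypes import GenotypeMatrix, Sex
from .scan import LocusSexPattern, classify_locus, summarize_locus


@dataclass(frozen=True)
class ConservationResult:
    species: str
    conserved_marker_names: tuple[str, ...]
    n_conserved: int

    def __post_init__(self) -> None:
        if self.n_conserved != len(self.conserved_marker_names):
            raise ValidationError("n_conserved must equal the list length")


def conserved_sex_markers(
    reference_markers: list[str],
    species_matrix: GenotypeMatrix,
    tolerance: int = 0,
    min_called_per_sex: int = 3,
    species: str | None = None,
) -> ConservationResult:
    """Count reference markers conserved (female-het) in another species.

    A reference marker is conserved iff its locus classifies
    ``FEMALE_HET_MALE_HOM`` in ``species_matrix`` at the given tolerance.
    Markers are reported in reference order.

    Raises
    ------
    ValidationError
        If a reference marker is absent from the species matrix, naming it.
    """
    if not species_matrix.sex_indices(Sex.FEMALE) or not species_matrix.sex_indices(
        Sex.MALE
    ):
        raise ValidationError("species matrix needs at least one sample per sex")
    label = species if species is not None else (
        species_matrix.samples[0].species or "unknown"
    )
    conserved: list[str] = []
    for name in reference_markers:
        try:
            i = species_matrix.locus_by_name(name)
        except KeyError:
            raise ValidationError(
                f"reference marker {name!r} absent from species matrix"
            ) from None
        counts = summarize_locus(
            species_matrix.genotypes_by_sex(i, Sex.FEMALE),
            species_matrix.genotypes_by_sex(i, Sex.MALE),
        )
        if (
            classify_locus(counts, tolerance, min_called_per_sex)
            is LocusSexPattern.FEMALE_HET_MALE_HOM
        ):
            conserved.append(name)
    return ConservationResult(label, tuple(conserved), len(conserved))


def conservation_table(
    reference_markers: list[str],
    species_matrices: dict[str, GenotypeMatrix],
    tolerance: int = 0,
    min_called_per_sex: int = 3,
) -> list[ConservationResult]:
    """Run :func:`conserved_sex_markers` over several species."""
    return [
        conserved_sex_markers(
            reference_markers, m, tolerance, min_called_per_sex, species=sp
        )
        for sp, m in species_matrices.items()
    ]
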
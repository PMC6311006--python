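"""Packaged reference datasets for the mud-crab (genus Scylla) sexing system.

Three small published tables ship with the package:

* the ten-marker genotype table of the four Scylla species (SNP1..SNP10,
  per-individual genotypes with sex labels).  The S. paramamosain entry
  prints one genotype *pattern* row per sex — every verified female shared
  the fully heterozygous pattern and every male the homozygous one — so
  its matrix has one sample per sex; use
  :func:`sexmarker.genotypes.replicate_samples` to expand it into an
  explicit cohort when a per-individual analysis needs one.
* the 20 candidate sex-linked marker loci (marker name, contig, contig
  length, SNP position, reference/alternative base);
* the primer panel: the female-specific pair (SPFS, four designed
  mismatches at primer offsets 1/17/25/29 of the forward 29-mer), the
  control pair (SPC) and the ten validation pairs, with annealing
  temperatures.
"""

from __future__ import annotations

from .genotypes import (
    GenotypeMatrix,
    LocusRecord,
    SampleInfo,
    Sex,
    normalize_genotype,
)
from .primers import PrimerPairSpec, PrimerRole, PrimerSpec, Strand

MARKER_NAMES = tuple(f"SNP{i}" for i in range(1, 11))

# species -> list of (sample_id, sex, ten genotype tokens)
_TABLE5: dict[str, list[tuple[str, str, str]]] = {
    "S. paramamosain": [
        ("F", "F", "C/T C/T C/T T/C G/A C/T A/T T/G A/T A/T"),
        ("M", "M", "C C C T G C A T A A"),
    ],
    "S. tranquebarica": [
        ("F1", "F", "C C/T C/T T/C G/A C/T A/T T/G A/T A/T"),
        ("F2", "F", "C C/T C/T T/C G/A C/T A/T T/G A/T A/T"),
        ("F3", "F", "C C/T C/T T/C G/A C/T A/T T/G A/T A/T"),
        ("M1", "M", "C C C T G C A T A A"),
        ("M2", "M", "C C C T G C A T A A"),
        ("M3", "M", "C C C T G C A T A A"),
    ],
    "S. serrata": [
        ("F1", "F", "C C/T C/T T G C A/C T A/T A/T"),
        ("F2", "F", "C C/T C/T T G C A/C T A/T A/T"),
        ("F3", "F", "C C/T C/T T G/A C A T/G A/T A/T"),
        ("M1", "M", "C C C T G C A T A A"),
        ("M2", "M", "C C C T G C A T A A"),
        ("M3", "M", "C C C T G C A T A A"),
    ],
    "S. olivacea": [
        ("F1", "F", "C C C T G C A/T T A A/T"),
        ("F2", "F", "C C C T G C A T A A/T"),
        ("F3", "F", "C C/T C T/C G/A C/T A/T T/G A A/T"),
        ("M1", "M", "C C C T G C A T A A/T"),
        ("M2", "M", "C C C T G C A T/G A A/T"),
        ("M3", "M", "C C C T G C A/T T/G A A/T"),
    ],
}

# marker name, contig, contig length, SNP position (1-based), ref, alt
_CANDIDATE_LOCI: list[tuple[str, str, int, int, str, str]] = [
    ("SNP-4307", "Cluster_121142", 306, 140, "T", "A"),
    ("SNP-8966-1", "Cluster_136335", 294, 242, "T", "C"),
    ("SNP-8966-2", "Cluster_136335", 294, 265, "G", "A"),
    ("SNP-6579-1", "Cluster_164559", 299, 205, "C", "T"),
    ("SNP-6579-2", "Cluster_164559", 299, 236, "T", "C"),
    ("SNP-9673-1", "Cluster_22418", 246, 128, "C", "T"),
    ("SNP-9673-2", "Cluster_22418", 246, 133, "A", "T"),
    ("SNP-9673-3", "Cluster_22418", 246, 231, "T", "A"),
    ("SNP-8171", "Cluster_31265", 290, 214, "C", "G"),
    ("SNP-11508", "Cluster_384014", 285, 70, "T", "C"),
    ("SNP-1888", "Cluster_39896", 319, 294, "T", "C"),
    ("SNP-572", "Cluster_40991", 297, 285, "T", "A"),
    ("SNP-4225-1", "Cluster_4545", 317, 98, "A", "G"),
    ("SNP-4225-2", "Cluster_4545", 317, 143, "T", "C"),
    ("SNP-4225-3", "Cluster_4545", 317, 285, "T", "A"),
    ("SNP-9132-1", "Cluster_4856", 320, 198, "C", "T"),
    ("SNP-9132-2", "Cluster_4856", 320, 226, "T", "C"),
    ("SNP-5476-1", "Cluster_71436", 243, 13, "T", "C"),
    ("SNP-5476-2", "Cluster_71436", 243, 133, "G", "C"),
    ("SNP-5476-3", "Cluster_71436", 243, 148, "T", "A"),
]

# name, reference, forward, reverse, annealing deg C
_VALIDATION_PRIMERS: list[tuple[str, str, str, str, int]] = [
    ("4307", "Cluster_121142", "TTTGCTTTTTTTGTCTTATGGTTC", "AAACAAATTTACTGAAAACGTGTCT", 52),
    ("8966", "Cluster_136335", "TATAGAGTGCTTTGCATCAATT", "TTCAAAACAAAATTACTGAAAAC", 51),
    ("6579", "Cluster_164559", "CCTTGTGGTTCTTTTGAAC", "AACGAAATTACTGAAAACTTG", 50),
    ("9673", "Cluster_22418", "TCATAGGTACCAAGATGCC", "GGTTTCTCGTAATGTCGTT", 55),
    ("8171", "Cluster_31265", "GAAAACGTGTCTTCCCAGTG", "ATATACACGAAGGTTTGCGTT", 54),
    ("11508", "Cluster_384014", "GCTTATCATAGTTATTGCCTTGT", "TGCACTCATGCTGGATTTT", 53),
    ("1888", "Cluster_39896", "GATTTCATCATCACCGACG", "GCAATTCTTGTCTGAGCATG", 57),
    ("4225", "Cluster_4545", "CAGCCCCGACATTAAGGC", "ATATACTGCAATTCTAATGCCAGG", 56),
    ("9132", "Cluster_4856", "ATTATTCTGGTGACTAACA", "GCTAAAACTTCTTTATAGAG", 55),
    ("5476", "Cluster_71436", "CTATATTGTTAATTGTTTTGGTGAC", "TCATCTTCATAGGTACCAATATCA", 53),
]

SPFS_FORWARD = "CTTAGTATATCACAACTACATCAGGATGT"
SPFS_REVERSE = "AAGATGCTTGCTGTCTCATTGGT"
SPFS_MISMATCH_OFFSETS = (1, 17, 25, 29)
SPC_FORWARD = "GTTCTGCTTATCATAGTTATTGCCTTG"
SPC_REVERSE = "CTGCCAGTGATTCAGTGACTTAGC"
SEXING_PRODUCT_BP = 320  # female-specific band
CONTROL_PRODUCT_BP = 282  # control band


def load_fixture_table5() -> dict[str, GenotypeMatrix]:
    """The four-species, ten-marker genotype matrices (SNP1..SNP10)."""
    out: dict[str, GenotypeMatrix] = {}
    for species, rows in _TABLE5.items():
        loci = [
            LocusRecord(name, "TABLE", k + 1)
            for k, name in enumerate(MARKER_NAMES)
        ]
        samples = [
            SampleInfo(sample_id, Sex.from_token(sex), species)
            for sample_id, sex, _ in rows
        ]
        grid = [
            [
                normalize_genotype(tok, where=f"{species}/{rows[j][0]}/SNP{i + 1}")
                for j, (_, _, tokens) in enumerate(rows)
                for tok in [tokens.split()[i]]
            ]
            for i in range(len(MARKER_NAMES))
        ]
        out[species] = GenotypeMatrix(loci, samples, grid)
    return out


def load_fixture_candidate_loci() -> list[LocusRecord]:
    """The 20 candidate sex-linked marker loci on their 11 contigs."""
    return [
        LocusRecord(name, contig, pos, ref, alt, sequence_length=length)
        for name, contig, length, pos, ref, alt in _CANDIDATE_LOCI
    ]


def load_fixture_primers() -> dict[str, PrimerPairSpec]:
    """The sexing primer panel keyed by pair name (SPFS, SPC, validation)."""
    pairs: dict[str, PrimerPairSpec] = {
        "SPFS": PrimerPairSpec(
            PrimerSpec(
                SPFS_FORWARD,
                Strand.PLUS,
                designed_mismatch_offsets=SPFS_MISMATCH_OFFSETS,
                annealing_celsius=65.0,
                name="SPFS-F",
            ),
            PrimerSpec(
                SPFS_REVERSE, Strand.MINUS, annealing_celsius=65.0, name="SPFS-R"
            ),
            PrimerRole.SEX_SPECIFIC,
            expected_product_bp=SEXING_PRODUCT_BP,
            name="SPFS",
        ),
        "SPC": PrimerPairSpec(
            PrimerSpec(SPC_FORWARD, Strand.PLUS, annealing_celsius=65.0, name="SPC-F"),
            PrimerSpec(SPC_REVERSE, Strand.MINUS, annealing_celsius=65.0, name="SPC-R"),
            PrimerRole.CONTROL,
            expected_product_bp=CONTROL_PRODUCT_BP,
            name="SPC",
        ),
    }
    for name, _ref, fwd, rev, anneal in _VALIDATION_PRIMERS:
        pairs[name] = PrimerPairSpec(
            PrimerSpec(fwd, Strand.PLUS, annealing_celsius=float(anneal), name=f"{name}-F"),
            PrimerSpec(rev, Strand.MINUS, annealing_celsius=float(anneal), name=f"{name}-R"),
            PrimerRole.VALIDATION,
            name=name,
        )
    return pairs


# offspring cohorts of the full-sib family at three early stages
STAGE_SEX_COUNTS: list[tuple[str, int, int]] = [
    ("Megalopa stage (M)", 30, 30),
    ("First crablet stage (C1)", 24, 36),
    ("Second crablet stage (C2)", 25, 35),
]
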
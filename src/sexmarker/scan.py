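"""Per-locus sex-association scan and heterogamety-system inference.

The scan classifies each locus by the joint heterozygosity pattern of the
two sexes.  A locus where every called female is heterozygous and every
called male is homozygous is the signature of a W-linked divergent site in
a ZW (female-heterogametic) system; the mirrored pattern indicates XY.
``tolerance`` relaxes the all-or-nothing rule to absorb genotyping error;
at tolerance 0 the rule is exact.

Each locus also receives a two-sided Fisher exact p-value on the
het/hom x female/male table and a Benjamini-Hochberg q-value across the
scan.  Significance is reported but does not gate candidacy by default:
with three individuals per sex a perfect pattern only reaches p = 0.1, so
an alpha gate would throw away exactly the kind of small validation cohort
this analysis is typically run on.  Gating is opt-in via ``alpha``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .genotypes import Genotype, GenotypeMatrix, LocusRecord, Sex


class LocusSexPattern(enum.Enum):
    FEMALE_HET_MALE_HOM = "FEMALE_HET_MALE_HOM"
    MALE_HET_FEMALE_HOM = "MALE_HET_FEMALE_HOM"
    NOT_SEX_LINKED = "NOT_SEX_LINKED"
    MONOMORPHIC = "MONOMORPHIC"
    INSUFFICIENT_DATA = "INSUFFICIENT_DATA"


CANDIDATE_PATTERNS = frozenset(
    {LocusSexPattern.FEMALE_HET_MALE_HOM, LocusSexPattern.MALE_HET_FEMALE_HOM}
)


class HeterogametySystem(enum.Enum):
    ZW = "ZW"
    XY = "XY"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class SexCountSummary:
    """Het/hom/missing genotype counts split by sex at one locus."""

    n_f_het: int = 0
    n_f_hom: int = 0
    n_f_missing: int = 0
    n_m_het: int = 0
    n_m_hom: int = 0
    n_m_missing: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_f_het",
            "n_f_hom",
            "n_f_missing",
            "n_m_het",
            "n_m_hom",
            "n_m_missing",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def n_f_called(self) -> int:
        return self.n_f_het + self.n_f_hom

    @property
    def n_m_called(self) -> int:
        return self.n_m_het + self.n_m_hom

    def swapped(self) -> "SexCountSummary":
        """The summary with female and male labels exchanged."""
        return SexCountSummary(
            n_f_het=self.n_m_het,
            n_f_hom=self.n_m_hom,
            n_f_missing=self.n_m_missing,
            n_m_het=self.n_f_het,
            n_m_hom=self.n_f_hom,
            n_m_missing=self.n_f_missing,
        )


@dataclass(frozen=True)
class AssociationStat:
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.q_value <= 1.0):
            raise ValidationError("p and q must lie in [0, 1]")


@dataclass(frozen=True)
class MarkerReport:
    """One scanned locus: its counts, pattern class and significance."""

    locus: LocusRecord
    counts: SexCountSummary
    pattern: LocusSexPattern
    stat: AssociationStat

    @property
    def is_candidate(self) -> bool:
        return self.pattern in CANDIDATE_PATTERNS


@dataclass(frozen=True)
class HeterogametyCall:
    system: HeterogametySystem
    n_female_het_markers: int
    n_male_het_markers: int


def summarize_locus(
    female_genotypes: list[Genotype], male_genotypes: list[Genotype]
) -> SexCountSummary:
    """Count het / hom / missing genotypes per sex at one locus."""
    return SexCountSummary(
        n_f_het=sum(g.is_het for g in female_genotypes),
        n_f_hom=sum(g.is_hom for g in female_genotypes),
        n_f_missing=sum(g.is_missing for g in female_genotypes),
        n_m_het=sum(g.is_het for g in male_genotypes),
        n_m_hom=sum(g.is_hom for g in male_genotypes),
        n_m_missing=sum(g.is_missing for g in male_genotypes),
    )


def classify_locus(
    counts: SexCountSummary,
    tolerance: int = 0,
    min_called_per_sex: int = 3,
) -> LocusSexPattern:
    """Classify the sex pattern of a locus from its count summary.

    Rules, applied in order on called genotypes only:

    * ``INSUFFICIENT_DATA`` — either sex has fewer than
      ``min_called_per_sex`` called genotypes.
    * ``MONOMORPHIC`` — no heterozygote in either sex (all called
      genotypes homozygous; allele identity is not part of the summary).
    * ``FEMALE_HET_MALE_HOM`` — at most ``tolerance`` homozygous females
      and at most ``tolerance`` heterozygous males, with at least one
      heterozygous female and one homozygous male.  At tolerance 0 this is
      exactly "every called female het, every called male hom".
    * ``MALE_HET_FEMALE_HOM`` — the mirror image.
    * ``NOT_SEX_LINKED`` otherwise, and also in the degenerate case where
      both directions qualify simultaneously (only possible at
      tolerance > 0), which keeps the classification symmetric under a
      label swap.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be non-negative")
    if min_called_per_sex < 1:
        raise ValidationError("min_called_per_sex must be >= 1")

    if counts.n_f_called < min_called_per_sex or counts.n_m_called < min_called_per_sex:
        return LocusSexPattern.INSUFFICIENT_DATA
    if counts.n_f_het == 0 and counts.n_m_het == 0:
        return LocusSexPattern.MONOMORPHIC

    female_het = (
        counts.n_f_hom <= tolerance
        and counts.n_m_het <= tolerance
        and counts.n_f_het >= 1
        and counts.n_m_hom >= 1
    )
    male_het = (
        counts.n_m_hom <= tolerance
        and counts.n_f_het <= tolerance
        and counts.n_m_het >= 1
        and counts.n_f_hom >= 1
    )
    if female_het and not male_het:
        return LocusSexPattern.FEMALE_HET_MALE_HOM
    if male_het and not female_het:
        return LocusSexPattern.MALE_HET_FEMALE_HOM
    return LocusSexPattern.NOT_SEX_LINKED


@lru_cache(maxsize=65536)
def _fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def fisher_het_by_sex(counts: SexCountSummary) -> float:
    """Two-sided Fisher exact p for the het/hom x female/male 2x2 table.

    Probability, under fixed margins, of tables at least as extreme as the
    observed one.  An all-zero table carries no evidence and returns 1.0.
    Results are cached: a genome-scale scan hits few distinct tables.
    """
    a, b = counts.n_f_het, counts.n_f_hom
    c, d = counts.n_m_het, counts.n_m_hom
    if a + b + c + d == 0:
        return 1.0
    return _fisher_2x2(a, b, c, d)


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """Step-up FDR adjustment, order-aligned with the input.

    q_i = min over ranks j >= rank(i) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    # guard the q >= p guarantee against float round-off in p*m/j
    return np.maximum(q, p).tolist()


def scan_markers(
    matrix: GenotypeMatrix,
    tolerance: int = 0,
    min_called_per_sex: int = 3,
    alpha: float | None = None,
) -> list[MarkerReport]:
    """Scan every locus of a sexed genotype matrix for sex linkage.

    Returns one :class:`MarkerReport` per locus ordered by
    (contig, position).  q-values are computed across all loci of the scan.
    ``alpha``, when given, additionally demotes candidates whose q-value
    exceeds it to ``NOT_SEX_LINKED`` (significance gating is opt-in; see
    module docstring).
    """
    f_idx = matrix.sex_indices(Sex.FEMALE)
    m_idx = matrix.sex_indices(Sex.MALE)
    if not f_idx or not m_idx:
        raise ValidationError(
            "scan requires at least one female and one male sample"
        )
    ordered = matrix.sorted_by_position()
    summaries = []
    for i in range(ordered.n_loci):
        summaries.append(
            summarize_locus(
                ordered.genotypes_by_sex(i, Sex.FEMALE),
                ordered.genotypes_by_sex(i, Sex.MALE),
            )
        )
    p_values = [fisher_het_by_sex(c) for c in summaries]
    q_values = benjamini_hochberg(p_values)
    reports = []
    for locus, counts, p, q in zip(ordered.loci, summaries, p_values, q_values):
        pattern = classify_locus(counts, tolerance, min_called_per_sex)
        if (
            alpha is not None
            and pattern in CANDIDATE_PATTERNS
            and q > alpha
        ):
            pattern = LocusSexPattern.NOT_SEX_LINKED
        reports.append(
            MarkerReport(locus, counts, pattern, AssociationStat(p, q))
        )
    return reports


def candidate_reports(reports: list[MarkerReport]) -> list[MarkerReport]:
    return [r for r in reports if r.is_candidate]


def infer_heterogamety(reports: list[MarkerReport]) -> HeterogametyCall:
    """Call the heterogamety system from a scan's candidate markers.

    A surplus of female-het candidates indicates ZW (heterogametic
    females); a surplus of male-het candidates indicates XY.  Ties —
    including zero candidates — are UNDETERMINED: no conclusion without
    directional evidence.
    """
    n_f = sum(r.pattern is LocusSexPattern.FEMALE_HET_MALE_HOM for r in reports)
    n_m = sum(r.pattern is LocusSexPattern.MALE_HET_FEMALE_HOM for r in reports)
    if n_f > n_m:
        system = HeterogametySystem.ZW
    elif n_m > n_f:
        system = HeterogametySystem.XY
    else:
        system = HeterogametySystem.UNDETERMINED
    return HeterogametyCall(system, n_f, n_m)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class SexLinkageScan:
    """Sex-linkage scan model over a sexed genotype matrix.

    Parameters
    ----------
    matrix
        Loci x samples genotypes with per-sample sex labels.
    tolerance
        Number of out-of-pattern individuals tolerated per sex (default 0,
        the exact all-females-het / all-males-hom rule).
    min_called_per_sex
        Minimum called genotypes per sex below which a locus is
        INSUFFICIENT_DATA (default 3).
    alpha
        Optional FDR gate on candidates (off by default).

    Examples
    --------
    >>> res = SexLinkageScan(matrix).fit()
    >>> res.heterogamety.system
    <HeterogametySystem.ZW: 'ZW'>
    """

    def __init__(
        self,
        matrix: GenotypeMatrix,
        tolerance: int = 0,
        min_called_per_sex: int = 3,
        alpha: float | None = None,
    ) -> None:
        self.matrix = matrix
        self.tolerance = tolerance
        self.min_called_per_sex = min_called_per_sex
        self.alpha = alpha

    def fit(self) -> "SexLinkageScanResults":
        reports = scan_markers(
            self.matrix, self.tolerance, self.min_called_per_sex, self.alpha
        )
        return SexLinkageScanResults(self, reports)


class SexLinkageScanResults:
    """Fitted scan: per-locus reports, candidates and the system call."""

    def __init__(self, model: SexLinkageScan, reports: list[MarkerReport]) -> None:
        self.model = model
        self.reports = reports
        self.heterogamety = infer_heterogamety(reports)

    @property
    def candidates(self) -> list[MarkerReport]:
        return candidate_reports(self.reports)

    @property
    def candidate_names(self) -> list[str]:
        return [r.locus.marker_name for r in self.candidates]

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {p.value: 0 for p in LocusSexPattern}
        for r in self.reports:
            out[r.pattern.value] += 1
        return out

    def summary(self) -> pd.DataFrame:
        """Per-locus summary table (one row per locus, scan order)."""
        rows = []
        for r in self.reports:
            rows.append(
                {
                    "marker": r.locus.marker_name,
                    "contig": r.locus.contig_id,
                    "position": r.locus.position,
                    "pattern": r.pattern.value,
                    "n_f_het": r.counts.n_f_het,
                    "n_f_hom": r.counts.n_f_hom,
                    "n_f_missing": r.counts.n_f_missing,
                    "n_m_het": r.counts.n_m_het,
                    "n_m_hom": r.counts.n_m_hom,
                    "n_m_missing": r.counts.n_m_missing,
                    "p_value": r.stat.p_value,
                    "q_value": r.stat.q_value,
                }
            )
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        h = self.heterogamety
        return (
            f"<SexLinkageScanResults {len(self.reports)} loci, "
            f"{len(self.candidates)} candidates, system={h.system.value}>"
        )
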
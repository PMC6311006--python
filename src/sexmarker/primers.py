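"""Allele-specific sexing-primer design and in-silico PCR.

The molecular-sexing assay rests on two primer pairs run in one reaction:

* a *sex-specific* pair whose forward primer's 3'-terminal base sits on a
  W-linked divergent site and carries the W (female-specific) allele, so
  polymerase extension starts only on the W haplotype; extra deliberate
  mismatches at nearby divergent sites (and optionally an artificial one
  at the 5' end) sharpen the discrimination;
* a *control* pair placed entirely outside the divergent region, which
  amplifies both haplotypes and guards against false negatives.

In-silico PCR here is a binary band/no-band model: a primer anneals when
its 3'-terminal base matches the template, its 3'-terminal window carries
at most a small number of mismatches, and its total mismatch count stays
within budget.  Product length follows the inclusive-span convention:
from the forward primer's 5' plus-strand position to the reverse primer's
5' plus-strand position, inclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import PrimerDesignError, ValidationError
from .genotypes import VALID_BASES

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_bases(seq: str, what: str = "sequence") -> str:
    s = seq.upper()
    if not s or any(c not in VALID_BASES for c in s):
        raise ValidationError(f"{what} must be non-empty A/C/G/T text")
    return s


class Strand(enum.Enum):
    PLUS = "+"
    MINUS = "-"


class PrimerRole(enum.Enum):
    SEX_SPECIFIC = "sex_specific"
    CONTROL = "control"
    VALIDATION = "validation"


class BandSexCall(enum.Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"
    INVALID = "INVALID"


@dataclass(frozen=True)
class HaplotypePair:
    """Aligned W and Z haplotype sequences with their divergent sites.

    ``divergent_sites`` (1-based offsets where the two sequences differ)
    is derived on construction and validated if supplied.
    """

    w_seq: str
    z_seq: str
    divergent_sites: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        w = _check_bases(self.w_seq, "w_seq")
        z = _check_bases(self.z_seq, "z_seq")
        if len(w) != len(z):
            raise ValidationError(
                f"haplotype lengths differ: {len(w)} vs {len(z)}"
            )
        sites = tuple(call_divergent_sites(w, z))
        if self.divergent_sites and tuple(self.divergent_sites) != sites:
            raise ValidationError(
                "divergent_sites do not match the sequence disagreement positions"
            )
        object.__setattr__(self, "w_seq", w)
        object.__setattr__(self, "z_seq", z)
        object.__setattr__(self, "divergent_sites", sites)

    @property
    def length(self) -> int:
        return len(self.w_seq)


def call_divergent_sites(w_seq: str, z_seq: str) -> list[int]:
    """Sorted 1-based positions where two equal-length sequences differ."""
    if len(w_seq) != len(z_seq):
        raise ValidationError(
            f"sequence lengths differ: {len(w_seq)} vs {len(z_seq)}"
        )
    w, z = w_seq.upper(), z_seq.upper()
    return [i + 1 for i, (a, b) in enumerate(zip(w, z)) if a != b]


@dataclass(frozen=True)
class PrimerSpec:
    """A primer written 5'->3' with its template placement.

    ``bind_start`` is the 1-based plus-strand position of the primer's
    5'-most template-aligned base: for a plus-strand primer that is its
    leftmost covered position, for a minus-strand primer its rightmost.
    ``designed_mismatch_offsets`` are 1-based offsets *within the primer*
    of deliberately non-template bases.
    """

    sequence: str
    strand: Strand = Strand.PLUS
    bind_start: int | None = None
    designed_mismatch_offsets: tuple[int, ...] = ()
    tm_celsius: float | None = None
    annealing_celsius: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        seq = _check_bases(self.sequence, "primer sequence")
        if len(seq) < 15:
            raise ValidationError(f"primer shorter than 15 nt: {seq}")
        offs = tuple(sorted(set(self.designed_mismatch_offsets)))
        if offs and (offs[0] < 1 or offs[-1] > len(seq)):
            raise ValidationError("designed mismatch offsets outside primer")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "designed_mismatch_offsets", offs)
        if self.tm_celsius is None:
            object.__setattr__(self, "tm_celsius", melting_temperature(seq))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPairSpec:
    forward: PrimerSpec
    reverse: PrimerSpec
    role: PrimerRole
    expected_product_bp: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.forward.strand is not Strand.PLUS:
            raise ValidationError("forward primer must be plus-strand")
        if self.reverse.strand is not Strand.MINUS:
            raise ValidationError("reverse primer must be minus-strand")
        f, r = self.forward.bind_start, self.reverse.bind_start
        if f is not None and r is not None:
            if not f < r:
                raise ValidationError("forward 5' must lie left of reverse 5'")
            span = r - f + 1
            if self.expected_product_bp is None:
                object.__setattr__(self, "expected_product_bp", span)
            elif self.expected_product_bp != span:
                raise ValidationError(
                    f"expected_product_bp {self.expected_product_bp} != "
                    f"primer span {span}"
                )


@dataclass(frozen=True)
class AmplificationResult:
    amplifies: bool
    product_bp: int | None
    n_mismatches_forward: int
    n_mismatches_reverse: int
    three_prime_mismatch: bool
    note: str = ""

    def __post_init__(self) -> None:
        if self.amplifies != (self.product_bp is not None):
            raise ValidationError("product_bp present iff amplifies")


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------


def melting_temperature(sequence: str) -> float:
    """Deterministic primer Tm in deg C.

    Wallace rule ``2*(A+T) + 4*(G+C)`` for length <= 14 nt; for longer
    primers the GC-fraction formula ``64.9 + 41*(n_GC - 16.4)/N`` with
    ``n_GC`` the G+C count and ``N`` the length.  Nearest-neighbour
    thermodynamics are deliberately out of scope.
    """
    s = _check_bases(sequence, "sequence")
    n_gc = s.count("G") + s.count("C")
    n = len(s)
    if n <= 14:
        return float(2 * (n - n_gc) + 4 * n_gc)
    return 64.9 + 41.0 * (n_gc - 16.4) / n


# ---------------------------------------------------------------------------
# Primer placement / in-silico PCR
# ---------------------------------------------------------------------------


def _site_on_template(primer: PrimerSpec, template: str) -> tuple[int, str] | None:
    """Plus-strand window covered by the primer at its bind position.

    Returns ``(start_1based, window)`` or None when the placement falls off
    the template.
    """
    L = len(primer)
    if primer.bind_start is None:
        return None
    if primer.strand is Strand.PLUS:
        start = primer.bind_start
        end = start + L - 1
    else:
        end = primer.bind_start
        start = end - L + 1
    if start < 1 or end > len(template):
        return None
    return start, template[start - 1 : end]


def _compare(primer: PrimerSpec, window: str) -> tuple[int, list[int], bool]:
    """(total mismatches, 0-based mismatch offsets, 3'-terminal base ok).

    The primer is compared 5'->3' against the annealing strand: the
    plus-strand window itself for a plus primer, its reverse complement
    for a minus primer.
    """
    target = window if primer.strand is Strand.PLUS else reverse_complement(window)
    mism = [i for i, (p, t) in enumerate(zip(primer.sequence, target)) if p != t]
    three_prime_ok = (len(primer) - 1) not in mism
    return len(mism), mism, three_prime_ok


def locate_primer(
    primer: PrimerSpec, template: str, max_mismatch_fraction: float = 0.5
) -> tuple[int, int] | None:
    """Best ungapped placement of a primer on a template.

    Returns ``(bind_start, n_mismatches)`` under the 5'-most-base
    convention of :class:`PrimerSpec`, or None when even the best window
    exceeds ``max_mismatch_fraction`` mismatches.  Ties go to the leftmost
    window.
    """
    t = _check_bases(template, "template")
    L = len(primer)
    if L > len(t):
        return None
    probe = (
        primer.sequence if primer.strand is Strand.PLUS else reverse_complement(primer.sequence)
    )
    best: tuple[int, int] | None = None
    for a in range(len(t) - L + 1):
        window = t[a : a + L]
        n = sum(p != w for p, w in zip(probe, window))
        if best is None or n < best[1]:
            if primer.strand is Strand.PLUS:
                pos = a + 1
            else:
                pos = a + L
            best = (pos, n)
            if n == 0:
                break
    if best is None or best[1] > max_mismatch_fraction * L:
        return None
    return best


def in_silico_pcr(
    pair: PrimerPairSpec,
    template: str,
    max_internal_mismatches: int = 3,
    three_prime_window: int = 5,
    max_window_mismatches: int = 1,
    use_bind_positions: bool = True,
) -> AmplificationResult:
    """Predict whether a primer pair amplifies a template, and the band size.

    Each primer anneals iff its 3'-terminal base matches the template,
    mismatches within its 3'-terminal window (default 5 nt) do not exceed
    ``max_window_mismatches`` (default 1), and its total mismatch count
    does not exceed ``max_internal_mismatches`` (default 3).  The product
    spans, inclusively, the plus-strand positions of the two primers' 5'
    ends.  A primer that cannot be mapped at all yields a non-amplifying
    result with a diagnostic note, not an error.
    """
    t = _check_bases(template, "template")

    placements: list[tuple[int, int, bool, bool] | None] = []
    for primer in (pair.forward, pair.reverse):
        placed = _site_on_template(primer, t) if use_bind_positions else None
        if placed is not None:
            start, window = placed
            pos5 = primer.bind_start
        else:
            loc = locate_primer(primer, t)
            if loc is None:
                placements.append(None)
                continue
            pos5 = loc[0]
            L = len(primer)
            if primer.strand is Strand.PLUS:
                window = t[pos5 - 1 : pos5 - 1 + L]
            else:
                window = t[pos5 - L : pos5]
        n_mm, mism, ok3 = _compare(primer, window)
        window_mm = sum(m >= len(primer) - three_prime_window for m in mism)
        anneals = (
            ok3
            and window_mm <= max_window_mismatches
            and n_mm <= max_internal_mismatches
        )
        placements.append((pos5, n_mm, anneals, ok3))

    fwd, rev = placements
    if fwd is None or rev is None:
        missing = "forward" if fwd is None else "reverse"
        return AmplificationResult(
            False,
            None,
            len(pair.forward) if fwd is None else fwd[1],
            len(pair.reverse) if rev is None else rev[1],
            False,
            note=f"{missing} primer does not map to template",
        )
    f5, f_mm, f_ok, f3 = fwd
    r5, r_mm, r_ok, r3 = rev
    three_prime_mismatch = not (f3 and r3)
    if f_ok and r_ok and f5 < r5:
        return AmplificationResult(True, r5 - f5 + 1, f_mm, r_mm, three_prime_mismatch)
    note = "" if f5 < r5 else "primers not in amplifying orientation"
    return AmplificationResult(False, None, f_mm, r_mm, three_prime_mismatch, note)


# ---------------------------------------------------------------------------
# Primer design
# ---------------------------------------------------------------------------


def design_allele_specific_primer(
    pair: HaplotypePair,
    anchor_site: int,
    length_range: tuple[int, int] = (18, 30),
    n_extra_snp_mismatches: int = 0,
    add_five_prime_mismatch: bool = False,
) -> PrimerSpec:
    """Design the W-specific (plus-strand) primer anchored on a divergent site.

    The primer's 3'-terminal base aligns to ``anchor_site`` and carries the
    W allele there, so it mismatches the Z haplotype at the 3' terminus —
    the veto position of allele-specific PCR.  Up to
    ``n_extra_snp_mismatches`` additional spanned divergent sites (those
    nearest the 3' end first) also carry the W allele; all other spanned
    divergent sites keep the Z allele so the primer still anneals to Z-like
    templates away from the designed mismatches.  With
    ``add_five_prime_mismatch`` the 5'-terminal base is substituted to a
    base matching neither haplotype.

    Length is chosen within ``length_range`` to maximise the number of
    usable divergent sites spanned (capped at ``1 + n_extra``); ties go to
    the shortest primer, which also minimises spanned-but-unused sites.
    """
    lo, hi = length_range
    if not (15 <= lo <= hi <= 35):
        raise ValidationError("length_range must lie within [15, 35]")
    if n_extra_snp_mismatches < 0:
        raise ValidationError("n_extra_snp_mismatches must be >= 0")
    if anchor_site not in pair.divergent_sites:
        raise PrimerDesignError(
            f"anchor position {anchor_site} is not a divergent site"
        )

    sites = set(pair.divergent_sites)
    best: tuple[int, int] | None = None  # (score, length)
    for L in range(lo, hi + 1):
        start = anchor_site - L + 1
        if start < 1:
            break
        spanned = sum(1 for p in range(start, anchor_site + 1) if p in sites)
        score = min(spanned, 1 + n_extra_snp_mismatches)
        if best is None or score > best[0]:
            best = (score, L)
    if best is None:
        raise PrimerDesignError(
            f"no primer length in {length_range} fits 5' of position {anchor_site}"
        )
    score, L = best
    if score < 1 + n_extra_snp_mismatches:
        raise PrimerDesignError(
            "cannot satisfy mismatch design: only "
            f"{score - 1} extra divergent site(s) spannable, "
            f"{n_extra_snp_mismatches} requested"
        )

    start = anchor_site - L + 1
    spanned_others = sorted(
        (p for p in sites if start <= p < anchor_site), reverse=True
    )
    chosen = set(spanned_others[:n_extra_snp_mismatches])

    bases = list(pair.z_seq[start - 1 : anchor_site])
    offsets = {L}
    bases[L - 1] = pair.w_seq[anchor_site - 1]
    for p in chosen:
        bases[p - start] = pair.w_seq[p - 1]
        offsets.add(p - start + 1)
    if add_five_prime_mismatch:
        w0, z0 = pair.w_seq[start - 1], pair.z_seq[start - 1]
        bases[0] = next(b for b in "ACGT" if b not in (w0, z0))
        offsets.add(1)
    return PrimerSpec(
        "".join(bases),
        Strand.PLUS,
        bind_start=start,
        designed_mismatch_offsets=tuple(sorted(offsets)),
    )


def choose_anchor_site(
    pair: HaplotypePair,
    length_range: tuple[int, int] = (18, 30),
    n_extra_snp_mismatches: int = 0,
    add_five_prime_mismatch: bool = False,
    max_internal_mismatches: int = 3,
    three_prime_window: int = 5,
    max_window_mismatches: int = 1,
) -> int:
    """Pick a divergent site on which an allele-specific primer is feasible.

    A dense divergent cluster can make some anchors unusable: spanned
    sites beyond the designed ones keep the Z allele and therefore
    mismatch the W template, and too many of them (or one in the
    3'-terminal window) would stop the primer amplifying even its own
    haplotype under the default annealing model.  Candidate anchors are
    tried from the 3'-most site leftwards and the first one whose design
    stays within the mismatch budget is returned.
    """
    for anchor in sorted(pair.divergent_sites, reverse=True):
        if anchor < length_range[0]:
            continue
        try:
            primer = design_allele_specific_primer(
                pair, anchor, length_range, n_extra_snp_mismatches,
                add_five_prime_mismatch,
            )
        except PrimerDesignError:
            continue
        start = primer.bind_start
        assert start is not None
        window = pair.w_seq[start - 1 : start - 1 + len(primer)]
        n_mm, mism, ok3 = _compare(primer, window)
        window_mm = sum(m >= len(primer) - three_prime_window for m in mism)
        if (
            ok3
            and n_mm <= max_internal_mismatches
            and window_mm <= max_window_mismatches
        ):
            return anchor
    raise PrimerDesignError(
        "no divergent site admits an allele-specific primer within the "
        "mismatch budget"
    )


def design_sex_specific_pair(
    pair: HaplotypePair,
    anchor_site: int | None = None,
    length_range: tuple[int, int] = (18, 30),
    n_extra_snp_mismatches: int = 0,
    add_five_prime_mismatch: bool = False,
    target_product_range: tuple[int, int] = (200, 400),
    tm_target: float = 60.0,
) -> PrimerPairSpec:
    """Complete the allele-specific forward primer into an amplifying pair.

    The forward primer comes from :func:`design_allele_specific_primer`
    (anchored on :func:`choose_anchor_site`'s pick when ``anchor_site`` is
    None); the reverse primer is a perfect-match primer placed downstream
    of the anchor, avoiding divergent sites so it anneals to both
    haplotypes, with the product length inside ``target_product_range``.
    """
    if anchor_site is None:
        anchor_site = choose_anchor_site(
            pair, length_range, n_extra_snp_mismatches, add_five_prime_mismatch
        )
    forward = design_allele_specific_primer(
        pair, anchor_site, length_range, n_extra_snp_mismatches,
        add_five_prime_mismatch,
    )
    template = pair.w_seq
    sites = set(pair.divergent_sites)
    lo, hi = length_range
    pmin, pmax = target_product_range
    best = None  # (tm distance, product, length)
    for product in range(pmin, pmax + 1):
        e = forward.bind_start + product - 1  # type: ignore[operator]
        if e <= anchor_site:
            continue
        if e > len(template):
            break
        for L in range(lo, hi + 1):
            a = e - L + 1
            if a <= anchor_site:
                continue
            if any(p in sites for p in range(a, e + 1)):
                continue
            d = abs(melting_temperature(template[a - 1 : e]) - tm_target)
            if best is None or (d, product, L) < best:
                best = (d, product, L)
    if best is None:
        raise PrimerDesignError(
            "no reverse-primer placement downstream of the anchor avoids "
            "the divergent sites within the product range"
        )
    _, product, L = best
    e = forward.bind_start + product - 1  # type: ignore[operator]
    reverse = PrimerSpec(
        reverse_complement(template[e - L : e]), Strand.MINUS, bind_start=e
    )
    return PrimerPairSpec(forward, reverse, PrimerRole.SEX_SPECIFIC, product)


def design_control_pair(
    pair: HaplotypePair | str,
    target_product_range: tuple[int, int] = (250, 300),
    tm_target: float = 60.0,
    primer_length_range: tuple[int, int] = (18, 26),
) -> PrimerPairSpec:
    """Design a control pair avoiding every divergent site.

    Both primers match W and Z perfectly (their windows contain no
    divergent site), so the pair amplifies the same-size fragment from
    both haplotypes.  Among feasible placements the pair whose primer Tm
    values are jointly closest to ``tm_target`` is chosen; ties go to the
    leftmost, then shortest, product.
    """
    if isinstance(pair, HaplotypePair):
        template = pair.w_seq
        forbidden = set(pair.divergent_sites)
    else:
        template = _check_bases(pair, "template")
        forbidden = set()
    n = len(template)
    pmin, pmax = target_product_range
    if pmin > pmax or pmin < 2 * primer_length_range[0]:
        raise ValidationError("invalid target_product_range")
    if n < pmin:
        raise PrimerDesignError("template shorter than the minimum product")

    # prefix sums: forbidden-site count and GC count, for O(1) window queries
    bad = [0] * (n + 1)
    gc = [0] * (n + 1)
    for i, b in enumerate(template, start=1):
        bad[i] = bad[i - 1] + (i in forbidden)
        gc[i] = gc[i - 1] + (b in "GC")

    def clean(a: int, b: int) -> bool:  # 1-based inclusive window
        return bad[b] - bad[a - 1] == 0

    def tm(a: int, b: int) -> float:
        L = b - a + 1
        n_gc = gc[b] - gc[a - 1]
        if L <= 14:
            return float(2 * (L - n_gc) + 4 * n_gc)
        return 64.9 + 41.0 * (n_gc - 16.4) / L

    lmin, lmax = primer_length_range

    def best_forward_len(s: int) -> tuple[float, int] | None:
        out = None
        for L in range(lmin, lmax + 1):
            e = s + L - 1
            if e > n or not clean(s, e):
                continue
            d = abs(tm(s, e) - tm_target)
            if out is None or d < out[0]:
                out = (d, L)
        return out

    def best_reverse_len(e: int) -> tuple[float, int] | None:
        out = None
        for L in range(lmin, lmax + 1):
            a = e - L + 1
            if a < 1 or not clean(a, e):
                continue
            d = abs(tm(a, e) - tm_target)
            if out is None or d < out[0]:
                out = (d, L)
        return out

    best = None  # (score, s, product, Lf, Lr)
    rev_cache: dict[int, tuple[float, int] | None] = {}
    for s in range(1, n - pmin + 2):
        f = best_forward_len(s)
        if f is None:
            continue
        for product in range(pmin, pmax + 1):
            e = s + product - 1
            if e > n:
                break
            if e not in rev_cache:
                rev_cache[e] = best_reverse_len(e)
            r = rev_cache[e]
            if r is None:
                continue
            score = f[0] + r[0]
            cand = (score, s, product, f[1], r[1])
            if best is None or score < best[0] - 1e-12:
                best = cand
            elif abs(score - best[0]) <= 1e-12 and (s, product) < (best[1], best[2]):
                best = cand
    if best is None:
        raise PrimerDesignError(
            "no control-primer placement avoids the divergent sites "
            "within the requested product range"
        )
    _, s, product, Lf, Lr = best
    e = s + product - 1
    forward = PrimerSpec(template[s - 1 : s - 1 + Lf], Strand.PLUS, bind_start=s)
    reverse = PrimerSpec(
        reverse_complement(template[e - Lr : e]), Strand.MINUS, bind_start=e
    )
    return PrimerPairSpec(forward, reverse, PrimerRole.CONTROL, product)


def predict_band_pattern(
    sex_pair: PrimerPairSpec,
    control_pair: PrimerPairSpec,
    individual_haplotypes: str | list[str],
    **pcr_kwargs,
) -> BandSexCall:
    """Call an individual's sex from in-silico band presence.

    Each primer pair is run against every haplotype the individual
    carries; a band is present when any haplotype amplifies.  FEMALE =
    control band + sex-specific band; MALE = control band only; INVALID =
    no control band (the reaction cannot be trusted).
    """
    if isinstance(individual_haplotypes, str):
        haplotypes = [individual_haplotypes]
    else:
        haplotypes = list(individual_haplotypes)
    if not haplotypes:
        raise ValidationError("at least one haplotype required")

    def band(pair: PrimerPairSpec) -> bool:
        return any(in_silico_pcr(pair, h, **pcr_kwargs).amplifies for h in haplotypes)

    if not band(control_pair):
        return BandSexCall.INVALID
    return BandSexCall.FEMALE if band(sex_pair) else BandSexCall.MALE
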
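"""Design of 3Cs mutagenic oligonucleotides.

A 3Cs oligo carries the insert (a 20-nt protospacer, a partially randomized
IUPAC pattern, or a sense-loop-antisense shRNA cassette) flanked by two
homology arms that anneal it to circular ssDNA template: the 5' arm matches
the 3' end of the U6 promoter, the 3' arm the 5' start of the gRNA
scaffold. Arms must be long enough (>= 15 nt by default) and stable enough
(Wallace Tm >= 50 degC by default), and the finished oligo must not contain
the template clean-up restriction site (I-SceI for the gRNA vectors, Bsu36I
for the shRNA vector) on either strand — otherwise the clean-up digest
would destroy correct products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .degenerate import DegeneratePattern
from .seqcore import IUPAC_EXPANSION, clean_sequence, reverse_complement, tm_wallace

ISCEI_SITE = "TAGGGATAACAGGGTAAT"
BSU36I_SITE = "CCTNAGG"


class DesignError(ValueError):
    """A design constraint cannot be satisfied."""


def _site_occurrences(sequence: str, site: str) -> list[int]:
    """Start positions where the (possibly degenerate) ``site`` pattern has a
    concrete realization inside ``sequence``; naive scan, both inputs IUPAC.

    A window counts as an occurrence if every position's base sets intersect,
    i.e. the window *could* realize the site (conservative for degenerate
    sequence windows such as randomized N-blocks that have been constrained
    elsewhere).
    """
    hits = []
    m = len(site)
    for i in range(len(sequence) - m + 1):
        if all(
            IUPAC_EXPANSION[a] & IUPAC_EXPANSION[b]
            for a, b in zip(sequence[i : i + m], site)
        ):
            hits.append(i)
    return hits


def find_forbidden_site(sequence: str, site: str) -> list[tuple[int, str]]:
    """All occurrences of ``site`` in ``sequence`` on either strand, as
    ``(start_on_forward, strand)``."""
    fwd = [(i, "+") for i in _site_occurrences(sequence, site)]
    rc = reverse_complement(site)
    rev = [(i, "-") for i in _site_occurrences(sequence, rc)]
    return sorted(fwd + rev)


@dataclass(frozen=True)
class TemplateContext:
    """Invariant vector sequences flanking the insert site of a 3Cs template.

    ``placeholder`` is the non-targeting stuffer between U6 tail and scaffold
    head in the unreacted template; it must contain ``cleanup_site`` (either
    orientation) so the clean-up digest can destroy template remnants.
    """

    u6_tail: str
    scaffold_head: str
    placeholder: str
    cleanup_site: str = ISCEI_SITE

    def __post_init__(self) -> None:
        object.__setattr__(self, "u6_tail", clean_sequence(self.u6_tail))
        object.__setattr__(self, "scaffold_head", clean_sequence(self.scaffold_head))
        for name in ("placeholder", "cleanup_site"):
            val = getattr(self, name).upper()
            bad = set(val) - set(IUPAC_EXPANSION)
            if bad:
                raise DesignError(f"{name}: invalid character(s) {sorted(bad)}")
            object.__setattr__(self, name, val)
        if not find_forbidden_site(self.placeholder, self.cleanup_site):
            raise DesignError(
                "placeholder does not contain the clean-up site in either "
                "orientation; template remnants could not be digested away"
            )


@dataclass(frozen=True)
class ThreeCsOligo:
    """A designed mutagenic oligonucleotide: 5' arm + insert + 3' arm."""

    name: str
    arm5: str
    insert: str
    arm3: str
    arm5_tm: float = field(init=False)
    arm3_tm: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm5_tm", tm_wallace(self.arm5) if self.arm5 else 0.0)
        object.__setattr__(self, "arm3_tm", tm_wallace(self.arm3) if self.arm3 else 0.0)

    @property
    def full(self) -> str:
        return self.arm5 + self.insert + self.arm3


def _select_arm(
    context: str, min_homology: int, tm_threshold: float, end: str
) -> str:
    """Shortest suffix (end='5') or prefix (end='3') of ``context`` with
    length >= min_homology and Wallace Tm >= tm_threshold."""
    for k in range(min_homology, len(context) + 1):
        arm = context[-k:] if end == "5" else context[:k]
        if tm_wallace(arm) >= tm_threshold:
            return arm
    raise DesignError(
        f"no {'suffix' if end == '5' else 'prefix'} of the "
        f"{len(context)}-nt context reaches Tm {tm_threshold} degC "
        f"at length >= {min_homology}"
    )


def design_grna_oligo(
    guide: str,
    ctx: TemplateContext,
    name: str = "",
    min_homology: int = 15,
    tm_threshold: float = 50.0,
) -> ThreeCsOligo:
    """Design a single-guide 3Cs oligo: shortest arms satisfying both the
    length and the Tm constraint, clean-up site excluded from the product.

    Raises :class:`DesignError` if the guide or the assembled oligo contains
    the clean-up site on either strand, or no arm satisfies the constraints.
    """
    guide = clean_sequence(guide, frozenset("ACGT"))
    if not 17 <= len(guide) <= 20:
        raise DesignError(f"guide length {len(guide)} outside 17-20 nt")
    hits = find_forbidden_site(guide, ctx.cleanup_site)
    if hits:
        raise DesignError(f"guide contains the clean-up site at {hits}")
    arm5 = _select_arm(ctx.u6_tail, min_homology, tm_threshold, "5")
    arm3 = _select_arm(ctx.scaffold_head, min_homology, tm_threshold, "3")
    oligo = ThreeCsOligo(name or guide, arm5, guide, arm3)
    hits = find_forbidden_site(oligo.full, ctx.cleanup_site)
    if hits:
        raise DesignError(f"assembled oligo contains the clean-up site at {hits}")
    return oligo


def randomized_block_span(
    n_random: int, start_position: int = 30, extend_order: str = "left_first"
) -> tuple[int, int]:
    """1-based inclusive (start, end) of the randomized block.

    Four consecutive Ns begin at ``start_position``; each increment beyond 4
    extends the block alternately one position left and one right
    (``extend_order`` decides which comes first).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if extend_order not in ("left_first", "right_first"):
        raise ValueError(f"unknown extend_order {extend_order!r}")
    left, right = start_position, start_position + min(n_random, 4) - 1
    for step in range(max(0, n_random - 4)):
        first_move = step % 2 == 0
        go_left = first_move == (extend_order == "left_first")
        if go_left:
            left -= 1
        else:
            right += 1
    return left, right


def design_randomized_oligo(
    n_random: int,
    backbone: str,
    name: str = "",
    start_position: int = 30,
    extend_order: str = "left_first",
    cleanup_site: str = ISCEI_SITE,
    arm_length: int = 0,
) -> ThreeCsOligo:
    """Replace a block of ``backbone`` with N's per the alternating-extension
    rule, producing a partially randomized 3Cs oligo.

    ``backbone`` is the full concrete oligo (arms plus non-targeting insert).
    If ``backbone`` contains ``cleanup_site`` (either strand), every
    occurrence must overlap the randomized block so the concrete site is
    destroyed in correct products. ``arm_length``, if given, splits ``full``
    into arm5/insert/arm3 for reporting; otherwise the N-block's flanks are
    treated as the arms.
    """
    backbone = clean_sequence(backbone, frozenset("ACGT"))
    left, right = randomized_block_span(n_random, start_position, extend_order)
    if left < 1 or right > len(backbone):
        raise DesignError(
            f"randomized block {left}-{right} falls outside the "
            f"{len(backbone)}-nt backbone"
        )
    site_hits = find_forbidden_site(backbone, cleanup_site)
    m = len(cleanup_site)
    for pos0, _strand in site_hits:
        # pos0 is 0-based; block coords are 1-based inclusive.
        if not (pos0 + 1 <= right and pos0 + m >= left):
            raise DesignError(
                "clean-up site occurrence at 0-based position "
                f"{pos0} is not covered by the randomized block {left}-{right}"
            )
    full = backbone[: left - 1] + "N" * n_random + backbone[right:]
    if arm_length:
        arm5, insert, arm3 = (
            full[:arm_length],
            full[arm_length:-arm_length],
            full[-arm_length:],
        )
    else:
        arm5, insert, arm3 = full[: left - 1], "N" * n_random, full[right:]
    return ThreeCsOligo(name or f"{n_random}N", arm5, insert, arm3)


def design_shrna_oligo(
    target: str,
    loop: str,
    ctx: TemplateContext,
    name: str = "",
    min_homology: int = 15,
    tm_threshold: float = 50.0,
) -> ThreeCsOligo:
    """Design a 3Cs shRNA oligo: sense target + 6-nt loop + antisense target,
    flanked by homology arms against the shRNA vector context.

    The hairpin cassette is ``target + loop + reverse_complement(target)``.
    A palindromic target (sense == antisense) yields an unusually stable
    hairpin and triggers a warning. The vector clean-up site (Bsu36I for
    pLKO.1-style templates) must not occur outside the intended region.
    """
    target = clean_sequence(target, frozenset("ACGT"))
    if not 19 <= len(target) <= 22:
        raise DesignError(f"shRNA target length {len(target)} outside 19-22 nt")
    loop = clean_sequence(loop, frozenset("ACGT"))
    if len(loop) != 6:
        raise ValueError(f"hairpin loop must be exactly 6 nt, got {len(loop)}")
    antisense = reverse_complement(target)
    if target == antisense:
        warnings.warn(
            "palindromic shRNA target: sense equals antisense, hairpin "
            "will be unusually stable",
            stacklevel=2,
        )
    insert = target + loop + antisense
    arm5 = _select_arm(ctx.u6_tail, min_homology, tm_threshold, "5")
    arm3 = _select_arm(ctx.scaffold_head, min_homology, tm_threshold, "3")
    oligo = ThreeCsOligo(name or f"sh_{target[:8]}", arm5, insert, arm3)
    for pos0, strand in find_forbidden_site(oligo.full, ctx.cleanup_site):
        inside = len(arm5) <= pos0 and pos0 + len(ctx.cleanup_site) <= len(arm5) + len(insert)
        if not inside:
            raise DesignError(
                f"clean-up site on strand {strand} at position {pos0} lies "
                "outside the hairpin cassette"
            )
    return oligo


@dataclass(frozen=True)
class PoolManifest:
    """Equimolar pooling manifest for a set of designed oligos."""

    name: str
    oligos: tuple[ThreeCsOligo, ...]

    @property
    def count(self) -> int:
        return len(self.oligos)

    @property
    def fraction(self) -> float:
        """Equimolar fraction per oligo."""
        return 1.0 / self.count


def pool_oligos(oligos: list[ThreeCsOligo], name: str = "pool") -> PoolManifest:
    """Hand-pool oligos in equimolar ratios; duplicate inserts are rejected."""
    if not oligos:
        raise ValueError("cannot pool zero oligos")
    seen: dict[str, str] = {}
    for o in oligos:
        if o.insert in seen:
            raise DesignError(
                f"duplicate insert shared by {seen[o.insert]!r} and {o.name!r}"
            )
        seen[o.insert] = o.name
    return PoolManifest(name, tuple(oligos))
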
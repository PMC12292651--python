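"""The SFZE grammar: rule evaluation and compliance-tier classification.

A compliant arrangement places Su(H) (S), Foxh1 (F, one or two sites), Zic
(Z) and Ets (E) sites in the linear order 5'-S-F-F-Z-E-3' (or the whole
arrangement mirrored), with the Zic and Ets sites facing each other, the
Foxh1 site adjacent to Zic on the same strand as Zic, and the F/Z/E core
confined to at most one nucleosome length (~147 bp).  The position of the
Su(H) site is flexible; it may sit on either flank of the core.

Candidate site combinations are enumerated from a deduplicated
:class:`~sfze.site_scanner.SiteSet`, each combination is scored against the
individual rules, and the resulting flag vector is mapped to a compliance
tier:

``SFZE_FULL``
    every rule passes (order may be mirrored);
``SFZE_LIKE_INVERTED``
    orientation and span rules pass but the linear order deviates (e.g. the
    partially inverted S-E-Z-F arrangement), or the order is intact but no
    Su(H) site is present;
``SFZE_LIKE_ORIENT``
    the orientation rules are violated (Zic and Ets in the same direction,
    or the Zic-adjacent Foxh1 on the opposite strand);
``SFZE_LIKE_SPAN``
    orientation passes but the F/Z/E core spans more than one nucleosome;
``INCOMPLETE``
    the F/Z/E core is not complete.

Orientation violations outrank span violations in the precedence because
they disrupt the grammar more fundamentally; the tier is a pure function of
the flag vector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .motif_models import TFClass
from .site_scanner import Site, SiteSet

NUCLEOSOME_BP = 147

CORE_CLASSES = (TFClass.F, TFClass.Z, TFClass.E)
S_CLASSES = (TFClass.S, TFClass.S_LIKE)

FLAG_NAMES = (
    "complete_core",
    "s_present",
    "order_ok",
    "mirror_used",
    "ze_face_to_face",
    "fz_same_dir",
    "span_ok",
)


class GrammarError(ValueError):
    """Raised for invalid grammar configuration or candidate input."""


class Tier(str, Enum):
    SFZE_FULL = "SFZE_FULL"
    SFZE_LIKE_INVERTED = "SFZE_LIKE_INVERTED"
    SFZE_LIKE_ORIENT = "SFZE_LIKE_ORIENT"
    SFZE_LIKE_SPAN = "SFZE_LIKE_SPAN"
    INCOMPLETE = "INCOMPLETE"


#: Ranking used by :func:`best_instance`; higher is better.  Partial
#: inversions retain more of the grammar (and, in reporter assays, more
#: activity) than span or orientation violations.
TIER_RANK = {
    Tier.SFZE_FULL: 4,
    Tier.SFZE_LIKE_INVERTED: 3,
    Tier.SFZE_LIKE_SPAN: 2,
    Tier.SFZE_LIKE_ORIENT: 1,
    Tier.INCOMPLETE: 0,
}


@dataclass(frozen=True)
class SyntaxGrammar:
    """The SFZE rule set.

    ``max_core_span`` is the nucleosome-length bound on the F/Z/E core (bp,
    inclusive).  ``s_max_distance`` limits how far an S/S_LIKE site may sit
    from the core bounding interval; ``None`` accepts an S anywhere in the
    scanned region.  ``max_f`` is the number of Foxh1 slots in the order
    template (one or two sites are expected).  ``allow_mirror`` accepts the
    whole arrangement read in the opposite genomic direction.
    """

    max_f: int = 2
    allow_mirror: bool = True
    max_core_span: int = NUCLEOSOME_BP
    s_max_distance: int | None = None
    require_ze_face_to_face: bool = True
    require_fz_same_dir: bool = True
    enumeration_budget: int = 10_000

    def __post_init__(self):
        if self.max_core_span <= 0:
            raise GrammarError("max_core_span must be positive")
        if self.max_f < 1:
            raise GrammarError("max_f must be >= 1")
        if self.enumeration_budget < 1:
            raise GrammarError("enumeration_budget must be >= 1")


@dataclass(frozen=True)
class SyntaxFlags:
    complete_core: bool
    s_present: bool
    order_ok: bool
    mirror_used: bool
    ze_face_to_face: bool
    fz_same_dir: bool
    span_ok: bool

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FLAG_NAMES}

    def n_passing(self) -> int:
        return sum(self.as_dict().values())


@dataclass(frozen=True)
class SyntaxInstance:
    """One candidate site combination with its rule flags and tier."""

    member_sites: tuple
    flags: SyntaxFlags
    tier: Tier
    core_span: int

    @property
    def arrangement(self) -> str:
        return arrangement_string(self)

    @property
    def start(self) -> int:
        return min(s.start for s in self.member_sites) if self.member_sites else 0

    def member_score_sum(self) -> float:
        return sum(s.score for s in self.member_sites)


def _core_members(sites: Sequence[Site]) -> list:
    return [s for s in sites if s.tf_class in CORE_CLASSES]


def _core_span(sites: Sequence[Site]) -> int:
    core = _core_members(sites)
    if not core:
        return 0
    return max(s.end for s in core) - min(s.start for s in core)


def _interval_distance(a: Site, b: Site) -> int:
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def evaluate_rules(members: Sequence[Site], g: SyntaxGrammar) -> SyntaxFlags:
    """Score one candidate site combination against every grammar rule.

    ``members`` is the combination's site list (any order); all sites must
    come from one sequence.  Flags are independent where the rules are:
    orientation and span are evaluated even when the order deviates, which
    is what distinguishes the partially inverted arrangements from outright
    grammar violations.
    """
    members = sorted(members, key=lambda s: (s.start, s.end))
    if len({s.seq_id for s in members}) > 1:
        raise GrammarError("candidate members span multiple sequences")

    z_sites = [s for s in members if s.tf_class is TFClass.Z]
    e_sites = [s for s in members if s.tf_class is TFClass.E]
    f_sites = [s for s in members if s.tf_class is TFClass.F]
    s_sites = [s for s in members if s.tf_class in S_CLASSES]

    complete_core = bool(z_sites) and bool(e_sites) and bool(f_sites)
    span = _core_span(members)
    span_ok = complete_core and span <= g.max_core_span

    # Zic and Ets face each other: the upstream one on +, the downstream on -.
    ze_face_to_face = False
    if z_sites and e_sites:
        z, e = z_sites[0], e_sites[0]
        up, down = (z, e) if z.start <= e.start else (e, z)
        ze_face_to_face = up.strand == "+" and down.strand == "-"
        if not g.require_ze_face_to_face:
            ze_face_to_face = True

    # The Foxh1 site adjacent to Zic (nearest by interval distance, ties to
    # the upstream one) runs in the same direction as Zic.
    fz_same_dir = False
    if z_sites and f_sites:
        z = z_sites[0]
        nearest = min(f_sites, key=lambda f: (_interval_distance(f, z), f.start))
        fz_same_dir = nearest.strand == z.strand
        if not g.require_fz_same_dir:
            fz_same_dir = True

    # Linear class order against the 5'-S-F..F-Z-E-3' template (restricted
    # to the classes present) or, if mirroring is allowed, its reversal.
    order_ok = False
    mirror_used = False
    if complete_core and len(f_sites) <= g.max_f:
        observed = [
            TFClass.S if s.tf_class in S_CLASSES else s.tf_class for s in members
        ]
        template = ([TFClass.S] if s_sites else []) + [TFClass.F] * len(f_sites) + [
            TFClass.Z,
            TFClass.E,
        ]
        if observed == template:
            order_ok = True
        elif g.allow_mirror and observed == template[::-1]:
            order_ok = True
            mirror_used = True

    # Su(H) may flank the core on either side; only its distance from the
    # core bounding interval is (optionally) constrained.
    s_present = False
    if s_sites:
        if g.s_max_distance is None or not complete_core:
            s_present = True
        else:
            core = _core_members(members)
            lo = min(c.start for c in core)
            hi = max(c.end for c in core)
            for s in s_sites:
                gap = max(lo - s.end, s.start - hi, 0)
                if gap <= g.s_max_distance:
                    s_present = True
                    break

    return SyntaxFlags(
        complete_core=complete_core,
        s_present=s_present,
        order_ok=order_ok,
        mirror_used=mirror_used,
        ze_face_to_face=ze_face_to_face,
        fz_same_dir=fz_same_dir,
        span_ok=span_ok,
    )


def classify(flags: SyntaxFlags) -> Tier:
    """Map a flag vector to its compliance tier (total and deterministic)."""
    if not flags.complete_core:
        return Tier.INCOMPLETE
    if not (flags.ze_face_to_face and flags.fz_same_dir):
        return Tier.SFZE_LIKE_ORIENT
    if not flags.span_ok:
        return Tier.SFZE_LIKE_SPAN
    if flags.order_ok and flags.s_present:
        return Tier.SFZE_FULL
    return Tier.SFZE_LIKE_INVERTED


def make_instance(members: Sequence[Site], g: SyntaxGrammar) -> SyntaxInstance:
    """Evaluate and classify one candidate combination."""
    members = tuple(sorted(members, key=lambda s: (s.start, s.end)))
    flags = evaluate_rules(members, g)
    return SyntaxInstance(
        member_sites=members,
        flags=flags,
        tier=classify(flags),
        core_span=_core_span(members),
    )


def enumerate_candidates(s: SiteSet, g: SyntaxGrammar) -> list:
    """All candidate combinations from a deduplicated site set.

    A combination takes exactly one Zic and one Ets site (when any exist —
    a missing core class yields incomplete candidates rather than none),
    1..max_f Foxh1 sites, and at most one S/S_LIKE site.  The combination
    count is bounded by ``g.enumeration_budget``; exceeding the budget is an
    error (never silent truncation) so the caller can tighten thresholds.
    """
    if len(s) == 0:
        return []
    z_sites = s.by_class(TFClass.Z) or [None]
    e_sites = s.by_class(TFClass.E) or [None]
    f_sites = [s_ for s_ in s if s_.tf_class is TFClass.F]
    s_sites = [s_ for s_ in s if s_.tf_class in S_CLASSES]

    f_choices: list = []
    for k in range(1, g.max_f + 1):
        f_choices.extend(itertools.combinations(f_sites, k))
    if not f_choices:
        f_choices = [()]
    s_choices: list = [None] + s_sites

    n = len(z_sites) * len(e_sites) * len(f_choices) * len(s_choices)
    if n > g.enumeration_budget:
        raise GrammarError(
            f"{n} candidate combinations exceed the enumeration budget of "
            f"{g.enumeration_budget}; tighten scanning thresholds or raise the budget"
        )

    instances = []
    for z, e, fs, su in itertools.product(z_sites, e_sites, f_choices, s_choices):
        members = [m for m in (z, e, *fs, su) if m is not None]
        if not members:
            continue
        instances.append(make_instance(members, g))
    return instances


_CLASS_LETTER = {
    TFClass.S: "S",
    TFClass.S_LIKE: "s",
    TFClass.F: "F",
    TFClass.Z: "Z",
    TFClass.E: "E",
    TFClass.PROMOTER_ELEMENT: "P",
}
_LETTER_CLASS = {v: k for k, v in _CLASS_LETTER.items()}


def arrangement_string(i: SyntaxInstance) -> str:
    """Text rendering of an instance, e.g. ``"S> F> F> Z> <E"``.

    Members appear left to right in genomic order; ``X>`` is a plus-strand
    site of class X and ``<X`` a minus-strand one.  A lower-case ``s``
    marks a suboptimal Su(H)-like site.
    """
    parts = []
    for site in sorted(i.member_sites, key=lambda s: (s.start, s.end)):
        letter = _CLASS_LETTER[site.tf_class]
        parts.append(f"{letter}>" if site.strand == "+" else f"<{letter}")
    return " ".join(parts)


def parse_arrangement(text: str) -> list:
    """Inverse of :func:`arrangement_string`: [(TFClass, strand), ...]."""
    out = []
    for token in text.split():
        if token.endswith(">") and len(token) == 2:
            out.append((_LETTER_CLASS[token[0]], "+"))
        elif token.startswith("<") and len(token) == 2:
            out.append((_LETTER_CLASS[token[1]], "-"))
        else:
            raise GrammarError(f"bad arrangement token {token!r}")
    return out


def best_instance(instances: Iterable[SyntaxInstance]):
    """The maximal instance, or None for an empty collection.

    Ordering: tier rank, then number of passing flags, then smaller core
    span, then larger member score sum; deterministic tie-break by leftmost
    start.
    """
    instances = list(instances)
    if not instances:
        return None
    return max(
        instances,
        key=lambda i: (
            TIER_RANK[i.tier],
            i.flags.n_passing(),
            -i.core_span,
            i.member_score_sum(),
            -i.start,
        ),
    )
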
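"""Both-strand scanning of DNA sequences for matrix and consensus motifs.

Coordinates are 0-based half-open on the plus strand throughout; a minus
strand site is one whose reverse complement satisfies the motif.  Windows
containing non-ACGT bases are skipped rather than wildcarded, so ambiguity
runs in draft assemblies cannot produce spurious matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .motif_models import (
    ModelKind,
    MotifModel,
    ScoringParams,
    TFClass,
    WeightMatrix,
    build_weight_matrix,
    iupac_set,
    reverse_complement_consensus,
)


class ScanError(ValueError):
    """Raised for invalid scanner input."""


@dataclass(frozen=True, order=True)
class Site:
    """One binding-site occurrence on a scanned sequence.

    ``score`` is the relative log-odds score in [0, 1] for matrix motifs and
    1.0 for consensus matches; ``matched_seq`` is always the plus-strand
    substring of [start, end).
    """

    seq_id: str = field(compare=False)
    start: int
    end: int
    strand: str
    tf_class: TFClass
    motif_id: str = field(compare=False)
    score: float = field(compare=False)
    matched_seq: str = field(compare=False)

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ScanError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ScanError(f"invalid strand {self.strand!r}")
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ScanError(f"score {self.score} outside [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_fraction(self, other: "Site") -> float:
        """Overlap as a fraction of the shorter site."""
        inter = min(self.end, other.end) - max(self.start, other.start)
        if inter <= 0:
            return 0.0
        return inter / min(len(self), len(other))


@dataclass(frozen=True)
class SiteSet:
    """Deduplicated, sorted site calls for one sequence."""

    seq_id: str
    sites: tuple = ()

    def __post_init__(self):
        object.__setattr__(
            self,
            "sites",
            tuple(sorted(self.sites, key=lambda s: (s.start, s.end, s.strand, s.tf_class.value))),
        )

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def by_class(self, tf_class: TFClass) -> list:
        return [s for s in self.sites if s.tf_class is tf_class]


_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> "np.ndarray":
    """Sequence -> int codes (A,C,G,T = 0..3; anything else = -1)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(codes: "np.ndarray", width: int):
    """(n_windows x width) view of codes plus the all-ACGT window mask."""
    if codes.size < width:
        return None, None
    win = np.lib.stride_tricks.sliding_window_view(codes, width)
    return win, (win >= 0).all(axis=1)


def scan_consensus(
    seq: str,
    m: MotifModel,
    both_strands: bool = True,
    seq_id: str = "",
) -> list:
    """Exact IUPAC-consensus matches on one or both strands.

    Minus-strand hits are found by matching the reverse-complement consensus
    against the plus strand and are reported in plus-strand coordinates with
    strand '-'.  Windows containing non-ACGT bases never match.
    """
    if m.model_kind is not ModelKind.CONSENSUS:
        raise ScanError(f"{m.motif_id}: scan_consensus requires a CONSENSUS model")
    seq = seq.upper()
    codes = _encode(seq)
    win, valid = _window_codes(codes, len(m))
    if win is None:
        return []

    def match_table(consensus: str) -> "np.ndarray":
        table = np.zeros((4, len(consensus)), dtype=bool)
        for j, code in enumerate(consensus):
            for base in iupac_set(code):
                table["ACGT".index(base), j] = True
        return table

    hits = {}
    safe = np.where(win >= 0, win, 0)
    cols = np.arange(len(m))
    fwd = match_table(m.consensus)
    hits["+"] = np.flatnonzero(fwd[safe, cols].all(axis=1) & valid)
    if both_strands:
        rev = match_table(reverse_complement_consensus(m.consensus))
        hits["-"] = np.flatnonzero(rev[safe, cols].all(axis=1) & valid)
    sites = []
    for strand, idx in hits.items():
        for i in idx:
            i = int(i)
            sites.append(
                Site(seq_id, i, i + len(m), strand, m.tf_class, m.motif_id,
                     1.0, seq[i : i + len(m)])
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def relative_score(window: str, wm: WeightMatrix) -> float:
    """Min-max normalised log-odds score of a window, in [0, 1]."""
    rng = wm.max_score - wm.min_score
    if rng <= 0:
        raise ScanError(f"{wm.motif_id}: degenerate matrix (max_score == min_score)")
    return (wm.score(window) - wm.min_score) / rng


def scan_matrix(
    seq: str,
    m: MotifModel,
    p: ScoringParams,
    both_strands: bool = True,
    seq_id: str = "",
) -> list:
    """Matrix scan reporting every window at or above the class threshold.

    A minus-strand call means the reverse complement of the window reaches
    the threshold; this is computed with the reverse-complemented weight
    matrix so both strands come out of one pass over the sequence.
    """
    if m.model_kind is not ModelKind.MATRIX:
        raise ScanError(f"{m.motif_id}: scan_matrix requires a MATRIX model")
    wm = build_weight_matrix(m, p)
    rng = wm.max_score - wm.min_score
    if rng <= 0:
        raise ScanError(f"{m.motif_id}: degenerate matrix (max_score == min_score)")
    threshold = p.threshold_for(m.tf_class)
    seq = seq.upper()
    codes = _encode(seq)
    win, valid = _window_codes(codes, len(m))
    if win is None:
        return []
    safe = np.where(win >= 0, win, 0)
    cols = np.arange(len(m))
    strand_values = {"+": wm.values}
    if both_strands:
        # reverse complement of the matrix: flip positions, swap A<->T, C<->G
        strand_values["-"] = wm.values[::-1, ::-1]
    sites = []
    for strand, values in strand_values.items():
        raw = values[safe, cols].sum(axis=1)
        rel = (raw - wm.min_score) / rng
        for i in np.flatnonzero((rel >= threshold) & valid):
            i = int(i)
            sites.append(
                Site(seq_id, i, i + len(m), strand, m.tf_class, m.motif_id,
                     float(min(rel[i], 1.0)), seq[i : i + len(m)])
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _dedup_same_class(sites: list, max_overlap: float) -> list:
    """Within one class, keep the best of any group overlapping above the cap.

    Preference: higher score, then smaller start, then plus strand.  Greedy
    over the preference order; a retained site suppresses all worse sites
    overlapping it by more than ``max_overlap``.
    """
    order = sorted(sites, key=lambda s: (-s.score, s.start, 0 if s.strand == "+" else 1))
    kept: list = []
    for cand in order:
        if all(cand.overlap_fraction(k) <= max_overlap for k in kept):
            kept.append(cand)
    return kept


def detect_sites(
    seq_id: str,
    seq: str,
    motifs: Iterable[MotifModel],
    p: ScoringParams | None = None,
    both_strands: bool = True,
) -> SiteSet:
    """Scan with every motif and deduplicate same-class overlaps.

    Sites of different classes may overlap freely; within a class, among
    sites overlapping by more than ``p.same_class_overlap`` only the best
    scoring one is retained (ties: smaller start, then plus strand).
    """
    motifs = list(motifs)
    if not motifs:
        raise ScanError("empty motif list")
    ids = [m.motif_id for m in motifs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ScanError(f"duplicate motif_id(s): {', '.join(dup)}")
    p = p or ScoringParams()
    calls: list = []
    for m in motifs:
        if m.model_kind is ModelKind.CONSENSUS:
            calls.extend(scan_consensus(seq, m, both_strands, seq_id=seq_id))
        else:
            calls.extend(scan_matrix(seq, m, p, both_strands, seq_id=seq_id))
    kept: list = []
    for cls in TFClass:
        group = [s for s in calls if s.tf_class is cls]
        if group:
            kept.extend(_dedup_same_class(group, p.same_class_overlap))
    return SiteSet(seq_id=seq_id, sites=tuple(kept))


def mirror_site(site: Site, seq_len: int) -> Site:
    """The same site in the coordinates of the reverse-complemented sequence."""
    return replace(
        site,
        start=seq_len - site.end,
        end=seq_len - site.start,
        strand="-" if site.strand == "+" else "+",
        matched_seq=str(Seq(site.matched_seq).reverse_complement()),
    )
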
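"""Synthetic CRM-scale sequences with planted SFZE arrangements.

The generator is the package's no-download test bed: it emits background
sequences of CRM scale (several hundred bp, configurable GC content) with
binding-site arrangements of a requested compliance tier written in at
sampled gaps, together with machine-readable truth labels.  Every planted
geometry is re-derived through the grammar evaluator at generation time —
the intended tier is never asserted, always recomputed — so the simulator
and the classifier cannot drift apart.

Chance background matches to the scanned motifs are removed by point
mutation after planting (planted sites and decoys are protected), making
the truth unambiguous: with ``decoy_density`` 0 the scanner's output on a
clean synthetic sequence is exactly the planted truth.  Decoy sites are
genuine consensus matches planted outside the truth set; they exercise
precision, and their density is the knob for false-positive pressure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .motif_models import (
    BASES,
    ModelKind,
    MotifModel,
    ScoringParams,
    TFClass,
    build_weight_matrix,
    default_motif_set,
    iupac_set,
)
from .site_scanner import (
    Site,
    SiteSet,
    relative_score,
    scan_consensus,
    scan_matrix,
)
from .syntax_grammar import (
    SyntaxGrammar,
    Tier,
    best_instance,
    enumerate_candidates,
)


class SimulationError(RuntimeError):
    pass


class Arrangement(str, Enum):
    """Planted geometry, named for the compliance tier it realises."""

    FULL_DIRECT = "FULL_DIRECT"            # 5'-S-F(-F)-Z-E-3', all rules pass
    FULL_MIRROR = "FULL_MIRROR"            # the same syntax read 3'->5'
    PARTIAL_INVERTED = "PARTIAL_INVERTED"  # S-E-Z-F order, orientations intact
    ORIENT_VIOLATION = "ORIENT_VIOLATION"  # Zic and Ets in the same direction
    SPAN_VIOLATION = "SPAN_VIOLATION"      # core spread beyond one nucleosome
    INCOMPLETE = "INCOMPLETE"              # core class missing (no Zic)
    BACKGROUND_ONLY = "BACKGROUND_ONLY"    # nothing planted


#: Tier each arrangement realises (verified, not assumed, at generation).
ARRANGEMENT_TIER = {
    Arrangement.FULL_DIRECT: Tier.SFZE_FULL,
    Arrangement.FULL_MIRROR: Tier.SFZE_FULL,
    Arrangement.PARTIAL_INVERTED: Tier.SFZE_LIKE_INVERTED,
    Arrangement.ORIENT_VIOLATION: Tier.SFZE_LIKE_ORIENT,
    Arrangement.SPAN_VIOLATION: Tier.SFZE_LIKE_SPAN,
    Arrangement.INCOMPLETE: Tier.INCOMPLETE,
    Arrangement.BACKGROUND_ONLY: Tier.INCOMPLETE,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic batch.

    Defaults mirror the scale of the real candidate CRMs: ~700 bp regions
    (the hemichordate CRM the grammar was traced through spans 717 bp),
    AT-rich background (GC 0.40), one or two Foxh1 sites, inter-site gaps
    drawn uniformly within a span budget of one nucleosome length for the
    compliant tiers and beyond it for span violations.
    """

    seed: int = 0
    n_sequences: int = 1
    length: int = 700
    gc_content: float = 0.40
    arrangement: Arrangement | Sequence[Arrangement] | None = None
    n_f_sites: int = 2
    decoy_density: float = 0.0      # expected decoy consensus matches per kb
    plant_score_floor: float = 0.9  # min relative score of matrix-sampled plants
    core_gap_range: tuple = (2, 30)
    s_gap_range: tuple = (5, 40)
    violation_span_range: tuple = (160, 260)
    max_attempts: int = 50

    def __post_init__(self):
        if not 0.0 < self.gc_content <= 1.0:
            raise SimulationError("gc_content must be in (0, 1]")
        if self.n_f_sites not in (1, 2):
            raise SimulationError("n_f_sites must be 1 or 2")
        if not 0.0 <= self.plant_score_floor <= 1.0:
            raise SimulationError("plant_score_floor must be in [0, 1]")
        if self.decoy_density < 0:
            raise SimulationError("decoy_density must be nonnegative")
        if self.length < 300:
            raise SimulationError("length must be >= 300 to fit arrangements")

    def arrangement_for(self, index: int) -> Arrangement:
        """Arrangement of the index-th sequence (cycled for mixed batches)."""
        if self.arrangement is None:
            cycle = list(Arrangement)
        elif isinstance(self.arrangement, Arrangement):
            cycle = [self.arrangement]
        else:
            cycle = [Arrangement(a) for a in self.arrangement]
        return cycle[index % len(cycle)]


@dataclass(frozen=True)
class TruthRecord:
    """Planted sites and the tier the geometry realises for one sequence."""

    seq_id: str
    arrangement: Arrangement
    sites: tuple           # planted Site objects (truth)
    decoys: tuple = ()     # planted decoy Sites, excluded from the truth set
    intended_tier: Tier = Tier.INCOMPLETE
    intended_flags: Mapping | None = None


@dataclass(frozen=True)
class SyntheticDataset:
    sequences: tuple   # of (seq_id, sequence)
    truths: tuple      # of TruthRecord, parallel to sequences
    config: SimulationConfig

    def write_fasta(self, path) -> None:
        lines = []
        for seq_id, seq in self.sequences:
            lines.append(f">{seq_id}")
            lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
        Path(path).write_text("\n".join(lines) + "\n")

    def write_truth_json(self, path) -> None:
        data = []
        for rec in self.truths:
            data.append(
                {
                    "seq_id": rec.seq_id,
                    "arrangement": rec.arrangement.value,
                    "intended_tier": rec.intended_tier.value,
                    "intended_flags": dict(rec.intended_flags or {}),
                    "sites": [
                        {
                            "start": s.start, "end": s.end, "strand": s.strand,
                            "tf_class": s.tf_class.value, "motif_id": s.motif_id,
                        }
                        for s in rec.sites
                    ],
                    "decoys": [
                        {
                            "start": s.start, "end": s.end, "strand": s.strand,
                            "tf_class": s.tf_class.value, "motif_id": s.motif_id,
                        }
                        for s in rec.decoys
                    ],
                }
            )
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    def write_truth_bed(self, path) -> None:
        lines = []
        for rec in self.truths:
            for s in rec.sites:
                lines.append(
                    "\t".join(
                        [rec.seq_id, str(s.start), str(s.end),
                         f"{s.tf_class.value}|{s.motif_id}", "1000", s.strand]
                    )
                )
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Primitive samplers
# ---------------------------------------------------------------------------

def sequence_rng(seed: int, index: int) -> np.random.Generator:
    """Independent substream for one sequence of a batch.

    Mixing the sequence index into the seed material makes each record
    reproducible on its own, independent of batch size or order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def sample_background(cfg: SimulationConfig, rng: np.random.Generator,
                      length: int | None = None) -> str:
    """i.i.d. background with P(G)+P(C) = gc_content, split equally."""
    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A,C,G,T
    n = cfg.length if length is None else length
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=probs)])


def sample_site_sequence(
    m: MotifModel,
    rng: np.random.Generator,
    floor: float = 0.9,
    params: ScoringParams | None = None,
    max_attempts: int = 1000,
) -> str:
    """Draw one concrete site sequence from a motif model.

    Consensus models: uniform draw over the consensus expansion.  Matrix
    models: per-position draw from the normalised count frequencies,
    rejection-sampled until the relative log-odds score reaches ``floor``.
    """
    if m.model_kind is ModelKind.CONSENSUS:
        return "".join(rng.choice(sorted(iupac_set(c))) for c in m.consensus)
    params = params or ScoringParams()
    wm = build_weight_matrix(m, params)
    freqs = m.matrix / m.matrix.sum(axis=0)
    for _ in range(max_attempts):
        word = "".join(
            BASES[rng.choice(4, p=freqs[:, j])] for j in range(m.matrix.shape[1])
        )
        if relative_score(word, wm) >= floor:
            return word
    raise SimulationError(
        f"{m.motif_id}: no draw reached relative score {floor} in {max_attempts} attempts"
    )


def _reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# Arrangement geometry
# ---------------------------------------------------------------------------

def _layout(arrangement: Arrangement, n_f: int) -> list:
    """Left-to-right (tf_class, strand) plan; 's' marks a free-strand S."""
    S, F, Z, E = TFClass.S, TFClass.F, TFClass.Z, TFClass.E
    if arrangement in (Arrangement.FULL_DIRECT, Arrangement.SPAN_VIOLATION):
        return [(S, None)] + [(F, "+")] * n_f + [(Z, "+"), (E, "-")]
    if arrangement is Arrangement.FULL_MIRROR:
        return [(E, "+"), (Z, "-")] + [(F, "-")] * n_f + [(S, None)]
    if arrangement is Arrangement.PARTIAL_INVERTED:
        return [(S, None), (E, "+"), (Z, "-")] + [(F, "-")] * n_f
    if arrangement is Arrangement.ORIENT_VIOLATION:
        return [(S, None)] + [(F, "+")] * n_f + [(Z, "+"), (E, "+")]
    if arrangement is Arrangement.INCOMPLETE:
        return [(S, None)] + [(F, "+")] * n_f + [(E, "-")]
    return []


def _split_slack(total: int, parts: int, rng: np.random.Generator) -> list:
    """Split a nonnegative integer into ``parts`` nonnegative summands."""
    if parts == 0:
        return []
    cuts = sorted(rng.integers(0, total + 1, size=parts - 1).tolist())
    bounds = [0] + cuts + [total]
    return [bounds[i + 1] - bounds[i] for i in range(parts)]


def _pick_motif(motifs: Sequence[MotifModel], tf_class: TFClass,
                rng: np.random.Generator) -> MotifModel:
    pool = [m for m in motifs if m.tf_class is tf_class]
    if tf_class is TFClass.S and not pool:  # fall back to Su(H)-like
        pool = [m for m in motifs if m.tf_class is TFClass.S_LIKE]
    if not pool:
        raise SimulationError(f"no motif of class {tf_class.value} to plant")
    return pool[int(rng.integers(len(pool)))]


def plant_arrangement(
    seq: str,
    cfg: SimulationConfig,
    grammar: SyntaxGrammar,
    rng: np.random.Generator,
    motifs: Sequence[MotifModel] | None = None,
    arrangement: Arrangement | None = None,
    seq_id: str = "synthetic",
) -> tuple:
    """Write one arrangement into a background sequence.

    Returns ``(sequence, TruthRecord)``.  Gaps between consecutive core
    sites are drawn uniformly within a span budget (at most one nucleosome
    length for compliant geometries, beyond it for span violations); the
    Su(H) site sits at a sampled gap on the 5' flank (3' for the mirrored
    form).  The intended tier is recomputed from the planted geometry with
    the grammar evaluator and the geometry is rejected if it does not
    realise the requested tier.
    """
    arrangement = arrangement or cfg.arrangement_for(0)
    motifs = list(motifs) if motifs is not None else default_motif_set()
    layout = _layout(arrangement, cfg.n_f_sites)
    if not layout:
        return seq, TruthRecord(
            seq_id=seq_id, arrangement=arrangement, sites=(),
            intended_tier=Tier.INCOMPLETE, intended_flags={},
        )

    chosen = []
    for tf_class, strand in layout:
        motif = _pick_motif(motifs, tf_class, rng)
        word = sample_site_sequence(motif, rng, cfg.plant_score_floor)
        if strand is None:
            strand = "+" if rng.random() < 0.5 else "-"
        chosen.append((motif, strand, word))
    widths = [len(w) for _, _, w in chosen]

    # Gap plan: core sites packed within the span budget; S offset separately.
    core_idx = [i for i, (m, _, _) in enumerate(chosen) if m.tf_class in
                (TFClass.F, TFClass.Z, TFClass.E)]
    n_core_gaps = max(len(core_idx) - 1, 0)
    core_width = sum(widths[i] for i in core_idx)
    if arrangement is Arrangement.SPAN_VIOLATION:
        lo, hi = cfg.violation_span_range
        span = int(rng.integers(max(lo, core_width + n_core_gaps), hi + 1))
    else:
        gmin, gmax = cfg.core_gap_range
        lo = core_width + n_core_gaps * gmin
        hi = min(core_width + n_core_gaps * gmax, grammar.max_core_span)
        if lo > hi:
            raise SimulationError("core gap range inconsistent with span budget")
        span = int(rng.integers(lo, hi + 1))
    gaps = _split_slack(span - core_width - n_core_gaps, n_core_gaps, rng)
    core_gaps = [g + 1 for g in gaps]  # at least 1 bp between plants
    if arrangement is Arrangement.SPAN_VIOLATION and n_core_gaps:
        # Put the violation entirely into the gap between the Zic-adjacent
        # Foxh1 and Zic: even the tightest Foxh1 subset (that F, Z, E) must
        # span more than the nucleosome bound.
        z_pos = next(
            k for k, i in enumerate(core_idx) if chosen[i][0].tf_class is TFClass.Z
        )
        tail = sum(widths[i] for i in core_idx[z_pos - 1 :]) + sum(
            core_gaps[z_pos:]
        )
        core_gaps[z_pos - 1] = max(
            core_gaps[z_pos - 1], grammar.max_core_span + 1 - tail
        )

    s_gap = int(rng.integers(*cfg.s_gap_range))
    all_gaps = []
    for k in range(len(chosen) - 1):
        left_is_core = k in core_idx and (k + 1) in core_idx
        all_gaps.append(core_gaps.pop(0) if left_is_core else s_gap)
    total = sum(widths) + sum(all_gaps)
    if total >= len(seq) - 2:
        raise SimulationError(
            f"arrangement of {total} bp does not fit in a {len(seq)} bp sequence"
        )
    offset = int(rng.integers(1, len(seq) - total - 1))

    out = list(seq)
    sites = []
    pos = offset
    for k, (motif, strand, word) in enumerate(chosen):
        plus_word = word if strand == "+" else _reverse_complement(word)
        out[pos : pos + len(word)] = plus_word
        sites.append(
            Site(seq_id, pos, pos + len(word), strand, motif.tf_class,
                 motif.motif_id, 1.0, plus_word)
        )
        pos += len(word)
        if k < len(all_gaps):
            pos += all_gaps[k]

    truth_sites = tuple(sorted(sites, key=lambda s: s.start))
    tier, flags = _derive_tier(truth_sites, grammar)
    expected = ARRANGEMENT_TIER[arrangement]
    if tier is not expected:
        raise SimulationError(
            f"planted {arrangement.value} geometry classifies as {tier.value}, "
            f"expected {expected.value}"
        )
    return "".join(out), TruthRecord(
        seq_id=seq_id, arrangement=arrangement, sites=truth_sites,
        intended_tier=tier, intended_flags=flags,
    )


def _derive_tier(sites: Sequence[Site], grammar: SyntaxGrammar):
    """Tier and flags the grammar assigns to a planted geometry."""
    if not sites:
        return Tier.INCOMPLETE, {}
    seq_id = sites[0].seq_id
    best = best_instance(enumerate_candidates(SiteSet(seq_id, tuple(sites)), grammar))
    if best is None:
        return Tier.INCOMPLETE, {}
    return best.tier, best.flags.as_dict()


# ---------------------------------------------------------------------------
# Decoys and background scrubbing
# ---------------------------------------------------------------------------

def _plant_decoys(
    out: list,
    truth_sites: Sequence[Site],
    cfg: SimulationConfig,
    motifs: Sequence[MotifModel],
    rng: np.random.Generator,
    seq_id: str,
) -> list:
    """Plant Poisson-distributed decoy consensus matches in free positions."""
    consensus_pool = [m for m in motifs if m.model_kind is ModelKind.CONSENSUS]
    if not consensus_pool or cfg.decoy_density == 0:
        return []
    n = int(rng.poisson(cfg.decoy_density * len(out) / 1000.0))
    occupied = [(s.start, s.end) for s in truth_sites]
    decoys = []
    for _ in range(n):
        motif = consensus_pool[int(rng.integers(len(consensus_pool)))]
        word = sample_site_sequence(motif, rng, cfg.plant_score_floor)
        strand = "+" if rng.random() < 0.5 else "-"
        plus_word = word if strand == "+" else _reverse_complement(word)
        for _attempt in range(50):
            start = int(rng.integers(0, len(out) - len(word)))
            span = (start, start + len(word))
            if all(span[1] <= a or span[0] >= b for a, b in occupied):
                out[span[0] : span[1]] = plus_word
                occupied.append(span)
                decoys.append(
                    Site(seq_id, span[0], span[1], strand, motif.tf_class,
                         motif.motif_id, 1.0, plus_word)
                )
                break
    return decoys


def _matches_any(site: Site, allowed: Sequence[Site]) -> bool:
    # exact coordinates and strand: a same-class call merely overlapping a
    # plant is a chance match and could displace the plant in deduplication
    return any(
        site.tf_class is a.tf_class
        and (site.start, site.end, site.strand) == (a.start, a.end, a.strand)
        for a in allowed
    )


def _scrub(
    out: list,
    allowed: Sequence[Site],
    motifs: Sequence[MotifModel],
    params: ScoringParams,
    rng: np.random.Generator,
    seq_id: str,
    max_rounds: int = 60,
) -> bool:
    """Mutate background bases until no spurious motif match remains.

    Works on the raw per-motif calls, before same-class deduplication: a
    chance match shadowed by a planted site under deduplication would
    otherwise survive and resurface under coordinate mirroring.  Only
    positions outside planted intervals may be touched; a spurious match
    lying entirely inside planted sites is unfixable and reported as
    failure so the caller can resample the sequence.
    """
    protected = [(a.start, a.end) for a in allowed]

    def mutable(i: int) -> bool:
        return all(not (a <= i < b) for a, b in protected)

    def raw_calls(seq: str) -> list:
        calls = []
        for m in motifs:
            if m.model_kind is ModelKind.CONSENSUS:
                calls.extend(scan_consensus(seq, m, seq_id=seq_id))
            else:
                calls.extend(scan_matrix(seq, m, params, seq_id=seq_id))
        return calls

    for _ in range(max_rounds):
        spurious = [c for c in raw_calls("".join(out)) if not _matches_any(c, allowed)]
        if not spurious:
            return True
        for call in spurious:
            positions = [i for i in range(call.start, call.end) if mutable(i)]
            if not positions:
                return False
            i = positions[int(rng.integers(len(positions)))]
            out[i] = rng.choice([b for b in BASES if b != out[i]])
    return False


# ---------------------------------------------------------------------------
# Dataset generation and recovery scoring
# ---------------------------------------------------------------------------

def generate_sequence(
    cfg: SimulationConfig,
    index: int,
    grammar: SyntaxGrammar | None = None,
    motifs: Sequence[MotifModel] | None = None,
    params: ScoringParams | None = None,
) -> tuple:
    """One synthetic record: ``(seq_id, sequence, TruthRecord)``."""
    grammar = grammar or SyntaxGrammar()
    motifs = list(motifs) if motifs is not None else default_motif_set()
    params = params or ScoringParams()
    rng = sequence_rng(cfg.seed, index)
    arrangement = cfg.arrangement_for(index)
    seq_id = f"synth_{index:04d}_{arrangement.value.lower()}"
    for _attempt in range(cfg.max_attempts):
        background = sample_background(cfg, rng)
        try:
            seq, truth = plant_arrangement(
                background, cfg, grammar, rng, motifs, arrangement, seq_id
            )
        except SimulationError:
            continue
        out = list(seq)
        decoys = _plant_decoys(out, truth.sites, cfg, motifs, rng, seq_id)
        allowed = list(truth.sites) + decoys
        if _scrub(out, allowed, motifs, params, rng, seq_id):
            return seq_id, "".join(out), replace(truth, decoys=tuple(decoys))
    raise SimulationError(
        f"could not realise {arrangement.value} for sequence {index} "
        f"in {cfg.max_attempts} attempts"
    )


def generate_dataset(
    cfg: SimulationConfig,
    grammar: SyntaxGrammar | None = None,
    motifs: Sequence[MotifModel] | None = None,
    params: ScoringParams | None = None,
) -> SyntheticDataset:
    """A reproducible batch of synthetic CRMs with truth labels."""
    sequences, truths = [], []
    for index in range(cfg.n_sequences):
        seq_id, seq, truth = generate_sequence(cfg, index, grammar, motifs, params)
        sequences.append((seq_id, seq))
        truths.append(truth)
    return SyntheticDataset(tuple(sequences), tuple(truths), cfg)


@dataclass(frozen=True)
class RecoveryMetrics:
    site_precision: float
    site_recall: float
    n_truth_sites: int
    n_called_sites: int
    tier_confusion: Mapping  # {(intended, reported): count}
    tier_accuracy: float

    def confusion_diagonal(self) -> bool:
        return all(a == b for (a, b), n in self.tier_confusion.items() if n)


def evaluate_recovery(
    truths: Sequence[TruthRecord],
    report,
    overlap_fraction: float = 0.5,
) -> RecoveryMetrics:
    """Site-level precision/recall and the tier confusion matrix.

    A call matches a planted site when it has the same class and their
    reciprocal overlap reaches ``overlap_fraction``; matching is one-to-one
    and greedy in call order.  Decoys are genuine motif matches outside the
    truth set: calls hitting them count against precision.
    """
    truth_by_id = {t.seq_id: t for t in truths}
    report_ids = {res.crm.name for res in report.results}
    missing = set(truth_by_id) ^ report_ids
    if missing:
        raise SimulationError(f"truth/report seq_id mismatch: {sorted(missing)[:5]}")

    n_truth = n_called = n_call_matched = n_truth_matched = 0
    confusion: dict = {}
    n_tier_correct = 0
    for res in report.results:
        truth = truth_by_id[res.crm.name]
        remaining = list(truth.sites)
        n_truth += len(truth.sites)
        n_called += len(res.sites)
        for call in res.sites:
            hit = next(
                (
                    t for t in remaining
                    if call.tf_class is t.tf_class
                    and call.overlap_fraction(t) >= overlap_fraction
                ),
                None,
            )
            if hit is not None:
                remaining.remove(hit)
                n_call_matched += 1
        n_truth_matched += len(truth.sites) - len(remaining)
        key = (truth.intended_tier.value, res.tier.value)
        confusion[key] = confusion.get(key, 0) + 1
        n_tier_correct += key[0] == key[1]

    return RecoveryMetrics(
        site_precision=n_call_matched / n_called if n_called else 1.0,
        site_recall=n_truth_matched / n_truth if n_truth else 1.0,
        n_truth_sites=n_truth,
        n_called_sites=n_called,
        tier_confusion=confusion,
        tier_accuracy=n_tier_correct / len(report.results) if report.results else 1.0,
    )
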
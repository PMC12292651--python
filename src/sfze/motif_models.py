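"""Binding-site models for the SFZE regulatory syntax.

The syntax involves four transcription-factor classes — Su(H) (S), Foxh1
(F), Zic (Z) and Ets (E) — whose sites are recognised either by position
frequency matrices (Zic, Foxh1; JASPAR format) or by short degenerate
consensus cores (Ets: MGGAW; Su(H): GTGTRGAR; suboptimal "Su(H)-like":
NTGRGAR or GTGRGAN).  This module defines the motif containers, the JASPAR
reader/writer, IUPAC helpers and the log-odds scoring machinery used by the
scanner.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
from Bio import motifs as _bio_motifs
from Bio.Data.IUPACData import ambiguous_dna_values as _IUPAC_VALUES
from Bio.Seq import Seq

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC degenerate code -> frozenset of concrete bases (A/C/G/T).
IUPAC_SETS: Mapping[str, frozenset] = {
    code: frozenset(expansion)
    for code, expansion in _IUPAC_VALUES.items()
    if code in "ACGTRYSWKMBDHVN"
}


class TFClass(str, Enum):
    """Transcription-factor class of a motif within the SFZE grammar."""

    S = "S"              # Su(H), canonical consensus
    S_LIKE = "S_LIKE"    # suboptimal Su(H)-like consensus
    F = "F"              # Foxh1
    Z = "Z"              # Zic
    E = "E"              # Ets
    PROMOTER_ELEMENT = "PROMOTER_ELEMENT"


class ModelKind(str, Enum):
    MATRIX = "MATRIX"
    CONSENSUS = "CONSENSUS"


class MotifError(ValueError):
    """Raised for malformed motif definitions or motif-format input."""


def iupac_set(code: str) -> frozenset:
    """Return the set of concrete bases an IUPAC nucleotide code stands for.

    >>> sorted(iupac_set("M"))
    ['A', 'C']
    """
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise MotifError(f"invalid IUPAC nucleotide code: {code!r}") from None


def validate_iupac(consensus: str) -> str:
    """Validate and upper-case an IUPAC consensus string."""
    consensus = consensus.upper()
    if not consensus:
        raise MotifError("empty consensus string")
    for ch in consensus:
        if ch not in IUPAC_SETS:
            raise MotifError(f"invalid IUPAC nucleotide code: {ch!r}")
    return consensus


def reverse_complement_consensus(consensus: str) -> str:
    """Reverse complement of an IUPAC consensus (M<->K, R<->Y, W/S/N fixed)."""
    return str(Seq(validate_iupac(consensus)).reverse_complement())


@dataclass(frozen=True)
class MotifModel:
    """One named binding-site model: a count matrix or an IUPAC consensus.

    ``matrix`` is a 4 x L array of nonnegative counts with rows in A,C,G,T
    order; ``consensus`` an IUPAC string.  Exactly one of the two is set,
    matching ``model_kind``.
    """

    motif_id: str
    tf_class: TFClass
    model_kind: ModelKind
    matrix: np.ndarray | None = None
    consensus: str | None = None
    source: str = ""

    def __post_init__(self):
        if self.model_kind is ModelKind.MATRIX:
            if self.matrix is None or self.consensus is not None:
                raise MotifError(f"{self.motif_id}: MATRIX model must set matrix only")
            mat = np.asarray(self.matrix, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != 4:
                raise MotifError(f"{self.motif_id}: matrix must be 4 x L")
            if (mat < 0).any():
                raise MotifError(f"{self.motif_id}: negative matrix counts")
            if (mat.sum(axis=0) == 0).any():
                raise MotifError(f"{self.motif_id}: all-zero matrix column")
            object.__setattr__(self, "matrix", mat)
            mat.setflags(write=False)
        elif self.model_kind is ModelKind.CONSENSUS:
            if self.consensus is None or self.matrix is not None:
                raise MotifError(f"{self.motif_id}: CONSENSUS model must set consensus only")
            object.__setattr__(self, "consensus", validate_iupac(self.consensus))
        else:  # pragma: no cover - enum exhausts kinds
            raise MotifError(f"{self.motif_id}: unknown model kind")
        if len(self) < 4:
            raise MotifError(f"{self.motif_id}: motif length must be >= 4")

    def __len__(self) -> int:
        if self.model_kind is ModelKind.MATRIX:
            return self.matrix.shape[1]
        return len(self.consensus)

    @property
    def matrix_consensus(self) -> str:
        """Per-position argmax word of a matrix model (ties -> A,C,G,T order)."""
        if self.model_kind is not ModelKind.MATRIX:
            raise MotifError("matrix_consensus is defined for MATRIX models only")
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class ScoringParams:
    """Scanning parameters: pseudocount, background composition, thresholds.

    ``rel_threshold`` maps a :class:`TFClass` to the minimum relative
    log-odds score (0..1) a matrix window must reach to be reported.
    Consensus motifs are exact-match and ignore thresholds.
    """

    pseudocount: float = 0.8
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    rel_threshold: Mapping[TFClass, float] = field(
        default_factory=lambda: {cls: 0.80 for cls in TFClass}
    )
    same_class_overlap: float = 0.5

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise MotifError("pseudocount must be positive")
        bg = tuple(float(x) for x in self.background)
        if len(bg) != 4 or any(x <= 0 for x in bg):
            raise MotifError("background must be 4 positive probabilities")
        if abs(sum(bg) - 1.0) > 1e-9:
            raise MotifError("background probabilities must sum to 1")
        object.__setattr__(self, "background", bg)
        for cls, v in self.rel_threshold.items():
            if not 0.0 <= v <= 1.0:
                raise MotifError(f"rel_threshold[{cls}] outside [0, 1]")
        if not 0.0 <= self.same_class_overlap <= 1.0:
            raise MotifError("same_class_overlap outside [0, 1]")

    def threshold_for(self, tf_class: TFClass) -> float:
        return self.rel_threshold.get(tf_class, 0.80)


@dataclass(frozen=True)
class WeightMatrix:
    """Log-odds matrix (4 x L, rows A,C,G,T) with its score range."""

    motif_id: str
    values: np.ndarray
    min_score: float
    max_score: float

    def score(self, window: str) -> float:
        """Raw log-odds score of an ACGT window of matching length."""
        if len(window) != self.values.shape[1]:
            raise MotifError(
                f"window length {len(window)} != matrix length {self.values.shape[1]}"
            )
        try:
            idx = [BASE_INDEX[b] for b in window.upper()]
        except KeyError as exc:
            raise MotifError(f"non-ACGT base in window: {exc.args[0]!r}") from None
        return float(self.values[idx, range(len(idx))].sum())


def build_weight_matrix(m: MotifModel, p: ScoringParams) -> WeightMatrix:
    """Log-odds weight matrix from a count matrix.

    Each cell is ``log2(((n_bi + a*q_b) / (N_i + a)) / q_b)`` with
    pseudocount ``a`` distributed by the background ``q``; the score range
    is the sum of per-position extrema.
    """
    if m.model_kind is not ModelKind.MATRIX:
        raise MotifError(f"{m.motif_id}: cannot build weight matrix from consensus")
    counts = m.matrix
    colsums = counts.sum(axis=0)
    if (colsums == 0).any():
        raise MotifError(f"{m.motif_id}: zero column sum")
    bg = np.asarray(p.background)[:, None]
    probs = (counts + p.pseudocount * bg) / (colsums + p.pseudocount)
    values = np.log2(probs / bg)
    return WeightMatrix(
        motif_id=m.motif_id,
        values=values,
        min_score=float(values.min(axis=0).sum()),
        max_score=float(values.max(axis=0).sum()),
    )


# ---------------------------------------------------------------------------
# JASPAR format I/O (Bio.motifs behind the surface; per-record so that
# errors can name the record)
# ---------------------------------------------------------------------------

def _split_jaspar_records(text: str) -> list[str]:
    records, current = [], []
    for line in text.splitlines():
        if line.startswith(">"):
            if current:
                records.append("\n".join(current))
            current = [line]
        elif line.strip():
            if not current:
                raise MotifError("JASPAR input does not start with a '>' header")
            current.append(line)
    if current:
        records.append("\n".join(current))
    return records


def parse_jaspar(
    text: str,
    tf_class: TFClass | Mapping[str, TFClass] = TFClass.PROMOTER_ELEMENT,
    source: str = "jaspar",
) -> list[MotifModel]:
    """Parse JASPAR-format matrix text into MATRIX motif models.

    ``tf_class`` is either a single class for all records or a mapping from
    motif id to class.  Row order is normalised to A,C,G,T regardless of the
    order the rows appear in.
    """
    records = _split_jaspar_records(text)
    if not records:
        raise MotifError("no JASPAR records found")
    models = []
    for rec in records:
        header = rec.splitlines()[0][1:].strip()
        rec_id = header.split()[0] if header else "<unnamed>"
        try:
            parsed = _bio_motifs.parse(io.StringIO(rec + "\n"), "jaspar")
        except Exception as exc:
            raise MotifError(f"malformed JASPAR record {rec_id!r}: {exc}") from exc
        if len(parsed) != 1:
            raise MotifError(f"malformed JASPAR record {rec_id!r}")
        bm = parsed[0]
        motif_id = bm.matrix_id or rec_id
        mat = np.array([bm.counts[b] for b in BASES], dtype=float)
        cls = tf_class.get(motif_id, TFClass.PROMOTER_ELEMENT) if isinstance(
            tf_class, Mapping
        ) else tf_class
        try:
            models.append(
                MotifModel(
                    motif_id=motif_id,
                    tf_class=cls,
                    model_kind=ModelKind.MATRIX,
                    matrix=mat,
                    source=source,
                )
            )
        except MotifError as exc:
            raise MotifError(f"invalid JASPAR record {rec_id!r}: {exc}") from exc
    return models


def format_jaspar(models: Iterable[MotifModel]) -> str:
    """Serialise MATRIX motif models back to JASPAR text."""
    bio = []
    for m in models:
        if m.model_kind is not ModelKind.MATRIX:
            raise MotifError(f"{m.motif_id}: only MATRIX models serialise to JASPAR")
        counts = {b: [float(x) for x in m.matrix[i]] for i, b in enumerate(BASES)}
        bm = _bio_motifs.Motif(alphabet="GATC", counts=counts)
        bm.matrix_id = m.motif_id
        bm.name = m.motif_id
        bio.append(bm)
    return _bio_motifs.write(bio, "jaspar")


# ---------------------------------------------------------------------------
# Built-in consensus motifs
# ---------------------------------------------------------------------------

def builtin_consensus_motifs() -> list[MotifModel]:
    """The Ets and Su(H)/Su(H)-like consensus-core models.

    Ets sites use the core MGGAW; canonical Su(H) sites GTGTRGAR; the
    suboptimal Su(H)-like sites are NTGRGAR or GTGRGAN.
    """
    mk = ModelKind.CONSENSUS
    return [
        MotifModel("ETS_core", TFClass.E, mk, consensus="MGGAW", source="builtin"),
        MotifModel("SUH_core", TFClass.S, mk, consensus="GTGTRGAR", source="builtin"),
        MotifModel("SUH_like_1", TFClass.S_LIKE, mk, consensus="NTGRGAR", source="builtin"),
        MotifModel("SUH_like_2", TFClass.S_LIKE, mk, consensus="GTGRGAN", source="builtin"),
    ]


def synthetic_test_matrices() -> list[MotifModel]:
    """Small sharp synthetic count matrices standing in for Zic and Foxh1.

    These are synthetic stand-ins for user-supplied JASPAR matrices, built
    for tests and simulations: their consensus words (and reverse
    complements) contain no Ets or Su(H) core so that planted sites of
    different classes cannot shadow one another.
    """

    def sharp(word: str) -> np.ndarray:
        mat = np.full((4, len(word)), 1.0)
        for i, b in enumerate(word):
            mat[BASE_INDEX[b], i] = 97.0
        return mat

    mk = ModelKind.MATRIX
    return [
        MotifModel("ZIC_synth", TFClass.Z, mk, matrix=sharp("CAGCTGTG"),
                   source="synthetic"),
        MotifModel("FOXH1_synth", TFClass.F, mk, matrix=sharp("AATCCACA"),
                   source="synthetic"),
    ]


def default_motif_set() -> list[MotifModel]:
    """Built-in consensi plus the synthetic Zic/Foxh1 matrices."""
    return builtin_consensus_motifs() + synthetic_test_matrices()


#: Core-promoter and promoter-proximal element consensi with their
#: positional windows relative to the TSS (start offsets, inclusive).
#: These are standard literature definitions shipped as defaults, all
#: overridable in configuration.
PROMOTER_ELEMENTS: Mapping[str, dict] = {
    "TATA": {"consensus": "TATAWAWR", "window": (-40, -20)},
    "Inr": {"consensus": "YYANWYY", "window": "spanning"},
    "BREd": {"consensus": "RTDKKKK", "window": "after_tata"},
    "DPE": {"consensus": "RGWYV", "window": (25, 35)},
    "CCAAT": {"consensus": "CCAAT", "window": (-250, -1)},
    "GC_box": {"consensus": "GGGCGG", "window": (-250, -1)},
}
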
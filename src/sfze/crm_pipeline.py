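"""End-to-end CRM scanning pipeline and report writers.

Reads candidate cis-regulatory modules (a CRM multi-FASTA, or a genome
FASTA plus a BED of intervals), scans each CRM for SFZE binding sites,
enumerates and classifies syntax instances, annotates core-promoter
elements, and writes GFF3/BED/TSV/JSON reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml
from Bio import SeqIO
from pyfaidx import Fasta

from . import __version__
from .motif_models import (
    PROMOTER_ELEMENTS,
    ModelKind,
    MotifModel,
    ScoringParams,
    TFClass,
    builtin_consensus_motifs,
    parse_jaspar,
)
from .site_scanner import ScanError, Site, SiteSet, detect_sites, scan_consensus
from .syntax_grammar import (
    SyntaxGrammar,
    SyntaxInstance,
    Tier,
    arrangement_string,
    best_instance,
    enumerate_candidates,
    make_instance,
)

logger = logging.getLogger("sfze")


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class CRMRecord:
    """One candidate CRM: a named plus-strand sequence, optionally anchored
    to genome coordinates (0-based half-open) when extracted from a BED."""

    name: str
    seq_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if self.end - self.start != len(self.sequence):
            raise PipelineError(
                f"CRM {self.name}: interval length {self.end - self.start} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class CRMResult:
    crm: CRMRecord
    sites: SiteSet
    instances: tuple
    best: SyntaxInstance | None
    tier: Tier

    @property
    def arrangement(self) -> str:
        return arrangement_string(self.best) if self.best else ""


@dataclass(frozen=True)
class ScanReport:
    results: tuple
    config_hash: str
    seed: int | None = None
    version: str = __version__


@dataclass(frozen=True)
class ElementCall:
    element: str
    start: int
    end: int
    strand: str
    matched_seq: str
    in_window: bool


@dataclass(frozen=True)
class PromoterAnnotation:
    seq_id: str
    tss_index: int
    calls: tuple


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a (multi-)FASTA into an ordered {id: sequence} mapping."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise PipelineError(f"duplicate FASTA record id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_bed(path) -> list:
    """Read BED3+ intervals as (chrom, start, end, name) tuples.

    The BED strand column, when present, is ignored with a warning: CRMs are
    scanned on the plus strand and mirrored arrangements are handled by the
    grammar itself.
    """
    intervals = []
    strand_seen = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PipelineError(f"{path}:{ln}: BED record has fewer than 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or end <= start:
                raise PipelineError(f"{path}:{ln}: invalid interval {start}-{end}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"{chrom}:{start}-{end}"
            if len(fields) > 5 and fields[5] in "+-":
                strand_seen = True
            intervals.append((chrom, start, end, name))
    if strand_seen:
        logger.warning("BED strand column ignored; CRMs are scanned on the plus strand")
    return intervals


def extract_crms(genome_path, bed_path) -> list:
    """Extract plus-strand CRM sequences for BED intervals from a genome."""
    genome = Fasta(str(genome_path), sequence_always_upper=True)
    crms = []
    names = set()
    for chrom, start, end, name in read_bed(bed_path):
        if chrom not in genome:
            raise PipelineError(f"BED record {name!r}: sequence {chrom!r} not in genome")
        if end > len(genome[chrom]):
            raise PipelineError(
                f"BED record {name!r}: end {end} beyond {chrom!r} length {len(genome[chrom])}"
            )
        if name in names:
            raise PipelineError(f"duplicate CRM name {name!r}")
        names.add(name)
        crms.append(CRMRecord(name, chrom, start, end, str(genome[chrom][start:end])))
    return crms


def crms_from_fasta(path) -> list:
    """Treat each record of a multi-FASTA as one CRM (coordinates 0..len)."""
    return [
        CRMRecord(name, name, 0, len(seq), seq)
        for name, seq in read_fasta(path).items()
    ]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "pseudocount": 0.8,
    "background": [0.25, 0.25, 0.25, 0.25],
    "rel_threshold": {"Z": 0.80, "F": 0.80},
    "same_class_overlap": 0.5,
    "grammar": {},
    # JASPAR matrix files for the matrix-scanned classes; the suggested
    # entries are a vertebrate Zic-family and the FOXH1 matrix from JASPAR.
    "matrices": {},  # e.g. {"Z": "jaspar/zic.jaspar", "F": "jaspar/foxh1.jaspar"}
    "promoter_elements": {},
}


def load_config(path=None) -> dict:
    """Load a YAML/JSON config and merge it over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def params_from_config(cfg: Mapping) -> ScoringParams:
    thresholds = {TFClass(k): float(v) for k, v in cfg.get("rel_threshold", {}).items()}
    base = {cls: 0.80 for cls in TFClass}
    base.update(thresholds)
    return ScoringParams(
        pseudocount=float(cfg.get("pseudocount", 0.8)),
        background=tuple(cfg.get("background", (0.25,) * 4)),
        rel_threshold=base,
        same_class_overlap=float(cfg.get("same_class_overlap", 0.5)),
    )


def grammar_from_config(cfg: Mapping) -> SyntaxGrammar:
    return SyntaxGrammar(**cfg.get("grammar", {}))


def motifs_from_config(cfg: Mapping, base_dir=None) -> list:
    """Built-in consensi plus any configured JASPAR matrices."""
    motifs = builtin_consensus_motifs()
    for cls_name, path in cfg.get("matrices", {}).items():
        cls = TFClass(cls_name)
        p = Path(path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        motifs.extend(parse_jaspar(p.read_text(), tf_class=cls, source=str(p)))
    return motifs


# ---------------------------------------------------------------------------
# Scan runner
# ---------------------------------------------------------------------------

def run_scan(
    crms: Sequence[CRMRecord],
    motifs: Sequence[MotifModel],
    grammar: SyntaxGrammar | None = None,
    params: ScoringParams | None = None,
    cfg: Mapping | None = None,
    seed: int | None = None,
) -> ScanReport:
    """Scan every CRM, classify its syntax instances, and assemble a report.

    Deterministic: identical inputs and configuration give identical
    reports.  Errors from any stage carry the CRM name.
    """
    grammar = grammar or SyntaxGrammar()
    params = params or ScoringParams()
    names = [c.name for c in crms]
    if len(set(names)) != len(names):
        raise PipelineError("CRM names are not unique")
    results = []
    for crm in crms:
        try:
            sites = detect_sites(crm.name, crm.sequence, motifs, params)
            instances = tuple(enumerate_candidates(sites, grammar))
            best = best_instance(instances)
        except (ScanError, ValueError) as exc:
            raise PipelineError(f"CRM {crm.name}: {exc}") from exc
        tier = best.tier if best is not None else Tier.INCOMPLETE
        logger.info(
            "scan crm=%s sites=%d instances=%d tier=%s",
            crm.name, len(sites), len(instances), tier.value,
        )
        results.append(CRMResult(crm, sites, instances, best, tier))
    return ScanReport(
        results=tuple(results),
        config_hash=config_hash(dict(cfg) if cfg else DEFAULT_CONFIG),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Promoter annotation
# ---------------------------------------------------------------------------

#: Elements that are strand-specific relative to the transcript: scanned on
#: the plus (sense) strand only.  CCAAT and GC boxes act in either
#: orientation and are scanned on both strands.
_SENSE_ONLY = {"TATA", "Inr", "BREd", "DPE"}


def annotate_promoter(
    seq: str,
    tss_index: int,
    seq_id: str = "",
    elements: Mapping[str, dict] | None = None,
) -> PromoterAnnotation:
    """Locate core-promoter and promoter-proximal elements around a TSS.

    Calls everywhere in the sequence are reported; ``in_window`` marks the
    calls whose position relative to the TSS falls inside the element's
    canonical window (TATA at -40..-20, Inr spanning the TSS, DPE at
    +25..+35, BREd immediately downstream of an in-window TATA, CCAAT and
    GC boxes within 250 bp upstream).
    """
    if not 0 <= tss_index < len(seq):
        raise PipelineError(f"TSS index {tss_index} outside sequence of length {len(seq)}")
    elements = elements or PROMOTER_ELEMENTS
    calls = []
    tata_ends = []
    for name, spec_ in elements.items():
        motif = MotifModel(
            f"promoter_{name}", TFClass.PROMOTER_ELEMENT, ModelKind.CONSENSUS,
            consensus=spec_["consensus"], source="promoter-element default",
        )
        both = name not in _SENSE_ONLY
        hits = scan_consensus(seq, motif, both_strands=both, seq_id=seq_id)
        if not both:
            hits = [h for h in hits if h.strand == "+"]
        for h in sorted(hits, key=lambda s: (s.start, s.strand)):
            window = spec_["window"]
            if window == "spanning":
                in_window = h.start <= tss_index < h.end
            elif window == "after_tata":
                in_window = False  # resolved after TATA calls are known
            else:
                lo, hi = window
                in_window = lo <= h.start - tss_index <= hi
            calls.append(ElementCall(name, h.start, h.end, h.strand, h.matched_seq, in_window))
            if name == "TATA" and in_window:
                tata_ends.append(h.end)
    resolved = []
    for c in calls:
        if c.element == "BREd":
            c = dataclasses.replace(c, in_window=c.start in tata_ends)
        resolved.append(c)
    resolved.sort(key=lambda c: (c.start, c.end, c.element))
    return PromoterAnnotation(seq_id=seq_id, tss_index=tss_index, calls=tuple(resolved))


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def _site_rows(report: ScanReport):
    for res in report.results:
        for site in res.sites:
            yield res, site


def write_sites_gff3(report: ScanReport, path) -> None:
    """GFF3 (1-based inclusive): one region line per CRM, one line per site."""
    lines = ["##gff-version 3"]
    for res in report.results:
        crm = res.crm
        attrs = f"ID={crm.name};tier={res.tier.value}"
        if res.arrangement:
            attrs += f";arrangement={res.arrangement.replace(' ', '_')}"
        lines.append(
            "\t".join(
                [crm.seq_id, "sfze", "region", str(crm.start + 1), str(crm.end),
                 ".", ".", ".", attrs]
            )
        )
        for site in res.sites:
            lines.append(
                "\t".join(
                    [
                        crm.seq_id,
                        "sfze",
                        "TF_binding_site",
                        str(crm.start + site.start + 1),
                        str(crm.start + site.end),
                        f"{site.score:.4f}",
                        site.strand,
                        ".",
                        f"Parent={crm.name};tf_class={site.tf_class.value};"
                        f"motif_id={site.motif_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_sites_bed(report: ScanReport, path) -> None:
    """BED6 (0-based half-open) with scores scaled to 0-1000."""
    lines = []
    for res, site in _site_rows(report):
        crm = res.crm
        lines.append(
            "\t".join(
                [
                    crm.seq_id,
                    str(crm.start + site.start),
                    str(crm.start + site.end),
                    f"{crm.name}|{site.tf_class.value}|{site.motif_id}",
                    str(round(site.score * 1000)),
                    site.strand,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


SUMMARY_COLUMNS = [
    "crm", "n_S", "n_S_LIKE", "n_F", "n_Z", "n_E", "tier", "core_span", "arrangement",
]


def write_summary_tsv(report: ScanReport, path) -> None:
    """One row per CRM: per-class site counts, tier, core span, arrangement."""
    lines = ["\t".join(SUMMARY_COLUMNS)]
    for res in report.results:
        counts = {cls: len(res.sites.by_class(cls)) for cls in TFClass}
        lines.append(
            "\t".join(
                [
                    res.crm.name,
                    str(counts[TFClass.S]),
                    str(counts[TFClass.S_LIKE]),
                    str(counts[TFClass.F]),
                    str(counts[TFClass.Z]),
                    str(counts[TFClass.E]),
                    res.tier.value,
                    str(res.best.core_span if res.best else 0),
                    res.arrangement,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _site_to_dict(site: Site) -> dict:
    return {
        "seq_id": site.seq_id,
        "start": site.start,
        "end": site.end,
        "strand": site.strand,
        "tf_class": site.tf_class.value,
        "motif_id": site.motif_id,
        "score": site.score,
        "matched_seq": site.matched_seq,
    }


def _site_from_dict(d: dict) -> Site:
    return Site(
        d["seq_id"], d["start"], d["end"], d["strand"],
        TFClass(d["tf_class"]), d["motif_id"], d["score"], d["matched_seq"],
    )


def _instance_to_dict(inst: SyntaxInstance) -> dict:
    return {
        "member_sites": [_site_to_dict(s) for s in inst.member_sites],
        "flags": inst.flags.as_dict(),
        "tier": inst.tier.value,
        "core_span": inst.core_span,
        "arrangement": arrangement_string(inst),
    }


def report_to_dict(report: ScanReport) -> dict:
    return {
        "version": report.version,
        "config_hash": report.config_hash,
        "seed": report.seed,
        "crms": [
            {
                "name": res.crm.name,
                "seq_id": res.crm.seq_id,
                "start": res.crm.start,
                "end": res.crm.end,
                "sequence": res.crm.sequence,
                "tier": res.tier.value,
                "arrangement": res.arrangement,
                "sites": [_site_to_dict(s) for s in res.sites],
                "instances": [_instance_to_dict(i) for i in res.instances],
                "best_instance": (
                    _instance_to_dict(res.best) if res.best is not None else None
                ),
            }
            for res in report.results
        ],
    }


def write_report_json(report: ScanReport, path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2) + "\n")


def read_report_json(path, grammar: SyntaxGrammar | None = None) -> ScanReport:
    """Rebuild a ScanReport from its JSON serialisation (lossless for sites,
    instances and tiers; instances are re-evaluated under the grammar)."""
    grammar = grammar or SyntaxGrammar()
    data = json.loads(Path(path).read_text())
    results = []
    for c in data["crms"]:
        crm = CRMRecord(c["name"], c["seq_id"], c["start"], c["end"], c["sequence"])
        sites = SiteSet(c["name"], tuple(_site_from_dict(d) for d in c["sites"]))
        instances = tuple(
            make_instance([_site_from_dict(d) for d in i["member_sites"]], grammar)
            for i in c["instances"]
        )
        best = best_instance(instances)
        results.append(CRMResult(crm, sites, instances, best, Tier(c["tier"])))
    return ScanReport(
        results=tuple(results),
        config_hash=data["config_hash"],
        seed=data["seed"],
        version=data["version"],
    )
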
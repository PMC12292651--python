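# Methods

## Site models and scanning

Four transcription-factor classes participate in the grammar. Ets and
Su(H) sites are matched by degenerate consensus cores — `MGGAW` for Ets,
`GTGTRGAR` for canonical Su(H), and the suboptimal Su(H)-like 7-mers
`NTGRGAR` / `GTGRGAN` — as exact IUPAC matches with no mismatch allowance.
Zic and Foxh1 sites are matched by position frequency matrices (JASPAR
format). A count matrix is converted to log-odds with

    w(b, i) = log2( ((n_bi + a·q_b) / (N_i + a)) / q_b )

where `a` is the pseudocount (default 0.8, distributed across bases by the
background) and `q` the background composition (default uniform, 0.25 per
base, because the scanner is applied across genomes of widely differing
composition). A window is reported when its min–max-normalised score
`(s − s_min)/(s_max − s_min)` reaches the class threshold (default 0.80
for all matrix classes, configurable per class).

Both strands are scanned in plus-strand coordinates: a minus-strand call
means the window's reverse complement satisfies the motif. Windows with
non-ACGT bases are skipped rather than wildcarded, so ambiguity runs in
draft assemblies cannot match. Within one class, calls overlapping by more
than half the shorter site are deduplicated to the best-scoring one (ties:
smaller start, then plus strand); calls of different classes may overlap
freely, since composite words can legitimately carry two classes.

The distribution ships small, deliberately sharp synthetic matrices for
Zic and Foxh1 (`synthetic_test_matrices`) for tests and simulations; real
analyses should supply JASPAR matrices (vertebrate Zic-family and FOXH1
entries are the natural choices) through the configuration, which is why
no real matrix is hard-coded.

## Grammar evaluation

Candidate instances are enumerated from the deduplicated site set: exactly
one Zic and one Ets site (when present), one to `max_f` Foxh1 sites
(default 2), and at most one S/S-like site. When a core class has no sites
at all, enumeration still emits candidates so those regions surface as
`INCOMPLETE` rather than vanishing. The combination count is capped
(default 10,000); exceeding the cap raises an error instead of silently
truncating, pointing at threshold tightening.

Per-candidate rules:

* `ze_face_to_face` — the upstream of {Z, E} on `+` and the downstream on
  `-`. The definition is symmetric, so it holds identically under
  coordinate mirroring.
* `fz_same_dir` — the Foxh1 site nearest Zic by interval distance (ties:
  the upstream one) shares Zic's strand. "Adjacent" is not defined
  numerically in the source material, so nearest-by-distance is the
  package's operationalisation.
* `order_ok` / `mirror_used` — the positional class order equals
  `S?,F{1..max_f},Z,E` restricted to the classes present, or its reversal
  when mirroring is allowed.
* `span_ok` — the bounding interval of the F/Z/E members (Su(H) excluded,
  since only the core is spacing-constrained) spans at most
  `max_core_span` bp, default 147, the DNA length of one nucleosome.
* `s_present` — an S/S-like member exists; optionally within
  `s_max_distance` of the core bounding interval (default unconstrained:
  the S position is flexible and may flank either core end, with no
  orientation requirement).

Tier precedence: incomplete core → `INCOMPLETE`; any orientation failure →
`SFZE_LIKE_ORIENT`; span failure → `SFZE_LIKE_SPAN`; order and S intact →
`SFZE_FULL`; otherwise `SFZE_LIKE_INVERTED` (covering both deviant order
with intact orientations, and intact order with no S site — the flags
record which). Orientation precedes span in the precedence because it
disrupts the grammar more fundamentally. The tier is a pure function of
the seven flags; all 128 flag combinations map to exactly one tier.

A region's reported tier is its best instance's tier, ranked by tier
(`FULL > LIKE_INVERTED > LIKE_SPAN > LIKE_ORIENT > INCOMPLETE`, mirroring
the relative enhancer activities observed for those configurations), then
by number of passing rules, smaller core span, larger member score sum,
and finally leftmost start for determinism.

## Promoter elements

Core-promoter annotation uses standard literature consensi as defaults —
TATA `TATAWAWR` at −40..−20 from the TSS, initiator `YYANWYY` spanning the
TSS, DPE `RGWYV` at +25..+35, BREd `RTDKKKK` immediately downstream of an
in-window TATA, CCAAT and GC box (`CCAAT`, `GGGCGG`) within 250 bp
upstream. These are package defaults, all config-overridable, not values
taken from any one study. TATA/Inr/BREd/DPE are directional and scanned on
the sense strand only; CCAAT and GC boxes act in either orientation and
are scanned on both strands. All matches are reported; `in_window` flags
the positionally plausible ones.

## Synthetic data

The generator emulates the study conditions the detector targets: 700 bp
regions (real candidate CRMs run to roughly this scale, e.g. a 717 bp
hemichordate CRM), i.i.d. background at GC 0.40 (AT-rich, typical of the
invertebrate regulatory regions involved), one or two Foxh1 sites, and
inter-core gaps drawn uniformly within a span budget — at most 147 bp for
compliant geometries, 160–260 bp for span violations, where the excess is
placed in the Foxh1→Zic gap so that no Foxh1 subset brings the core back
under the bound. Matrix-derived plants are rejection-sampled from the
matrix frequencies until their relative score reaches the plant floor
(default 0.9, above the 0.80 detection threshold, so planted sites are
always detectable). Each sequence draws from an independent substream
(sequence index mixed into the seed material), making records reproducible
independently of batch size.

Two integrity mechanisms keep truth labels unambiguous. First, the
intended tier of every planted geometry is recomputed by running the
grammar evaluator on the planted sites; a geometry that does not realise
its requested tier is resampled, never relabelled. Second, chance
background matches to any scanned motif are removed by point mutations in
background positions (pre-deduplication, so a chance match shadowed by a
planted site cannot resurface under mirroring); planted sites and decoys
are never touched, and a sequence whose spurious match cannot be fixed is
regenerated. Consequently, with no decoys the scan of a synthetic sequence
returns exactly the planted truth, which is what makes recall 1.0 and a
diagonal tier confusion matrix a meaningful end-to-end check rather than a
statistical accident. Decoy sites — genuine consensus words planted
outside the truth set at a Poisson rate per kb — are the controlled source
of false positives; site precision is non-increasing in their density.

What the simulator does **not** emulate: dinucleotide or repeat structure
of real genomes, binding-site degeneracy beyond the plant floor,
overlapping true arrangements, chromatin context, and real inter-species
matrix differences. Passing the recovery benchmark therefore demonstrates
the internal consistency of scanner + grammar + reporting on unambiguous
inputs, not detection power on real genomes, where thresholds and matrix
choice dominate.

## Problem sizes and numerics

The shipped benchmarks use exhaustive enumeration where feasible (all
1,024 pentamers / 65,536 octamers; all 128 flag vectors; all site subsets
for ≤ 15 sites) and simulation elsewhere: 50 × 300 bp sequences for the
matrix-scanner oracle, 100 regions for strand-flip invariance, and a
200-sequence mixed-tier batch for recovery — sizes at which every check is
exact and the whole suite runs in seconds. Scores are compared at full
float precision except where rounded to 9 decimals for cross-oracle
comparison; the span rule is inclusive at exactly 147 bp and fails at
148 bp. Relative scores are clipped to 1.0 against floating-point
overshoot. Ties throughout (deduplication, nearest-Foxh1, best instance)
are broken deterministically, so reports are byte-identical across runs.
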
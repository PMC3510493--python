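"""Expression-guided candidate screening.

The screening procedure, per gene:

1. Candidate selection: genes whose transcript level changes at least
   ``fold_threshold``-fold (either direction) in the mutant/wild-type
   contrast; for genes inside an operon, the operon's first ORF is screened
   as well.
2. Search-region construction: the full 5'-UTR plus the first
   ``cds_extension`` nt of CDS when the TSS is known, otherwise
   ``utr_fallback`` nt upstream of the translation start plus the CDS
   extension.
3. Seed-constrained interaction prediction with accessibility-corrected
   energies (:mod:`srnascreen.interact`); only sites with favourable total
   energy (E_total < 0) count as evidence.
4. Direction-conditional classification:
   * down-regulated -> repression candidate if a site overlaps the
     ribosome-covered region (default -39..+19 around the start codon);
   * up-regulated -> activation candidate if the best site strictly
     upstream of the RBS raises the RBS unpaired probability by more than
     ``dPu_threshold`` (default 0.001) when the site is forced single-
     stranded ("after the interaction" is modelled as constrained folding).

Also here: cis-antisense overlap classification and qRT-PCR 2^-ddCt fold
changes, both small coordinate/arithmetic operations the screen's evidence
table uses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .energy import EnergyModel
from .interact import InteractionSite, SeedSpec, scan_region
from .rbs import (DEFAULT_ANTI_SD, DEFAULT_RBS_THRESHOLD, DEFAULT_SCAN_WINDOW,
                  RBSLocation, locate_rbs)
from .seqio import ExpressionRecord, GeneAnnotation, TranscriptModel
from .thermo import AccessibilityCalculator, FoldConstraint

__all__ = ["ScreenConfig", "SearchRegion", "TargetCall", "OverlapRecord",
           "select_candidates", "build_search_region", "repression_filter",
           "rbs_accessibility_change", "classify_candidate", "run_screen",
           "antisense_overlap", "fold_change_from_ct", "REPORT_COLUMNS"]


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds of the screening procedure (defaults as published)."""

    fold_threshold: float = 3.0
    ribosome_window: tuple[int, int] = (-39, 19)
    dPu_threshold: float = 0.001
    utr_fallback: int = 200
    cds_extension: int = 100
    seed: SeedSpec = field(default_factory=SeedSpec)
    window: int = 100
    max_span: int = 50
    #: windows grid used when averaging accessibility for ED/dPu terms;
    #: 1 = every window (slowest, exact plfold-style average)
    window_step: int = 5
    #: "single" folds one window centered on the queried interval (keeps the
    #: interval's potential pairing partners in view; sliding-window
    #: averaging systematically overestimates the accessibility of long-
    #: range stems whose partner falls outside some windows)
    window_mode: str = "single"
    #: repression filter semantics: any overlap with the ribosome window
    #: (False) or full containment (True)
    contained: bool = False
    max_sites: int = 3
    anti_sd: str = DEFAULT_ANTI_SD
    rbs_scan_window: tuple[int, int] = DEFAULT_SCAN_WINDOW
    rbs_threshold: float = DEFAULT_RBS_THRESHOLD
    #: extend the RBS probe this many nt 3' (toward the codon) for dPu
    rbs_probe_extension: int = 0

    def __post_init__(self):
        if not self.fold_threshold > 1:
            raise ValueError("fold_threshold must be > 1")
        lo, hi = self.ribosome_window
        if not (lo <= -1 and hi >= 1):
            raise ValueError("ribosome window must span the start codon")
        if not self.dPu_threshold > 0:
            raise ValueError("dPu_threshold must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "seed" in d:
            d["seed"] = SeedSpec(**d["seed"]) if isinstance(d["seed"], dict) \
                else SeedSpec(int(d["seed"]))
        for key in ("ribosome_window", "rbs_scan_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SearchRegion:
    """Prepared interaction search region of one transcript."""

    gene_id: str
    sequence: str
    #: region-local (1-based) position of the first start-codon nt
    codon_offset: int
    utr_known: bool

    def to_codon_relative(self, pos: int) -> int:
        return pos - self.codon_offset + 1 if pos >= self.codon_offset \
            else pos - self.codon_offset

    def from_codon_relative(self, rel: int) -> int:
        if rel == 0:
            raise ValueError("there is no start-codon-relative position 0")
        return self.codon_offset + rel - 1 if rel > 0 else self.codon_offset + rel


@dataclass
class TargetCall:
    """Per-gene screening verdict with the evidence that produced it."""

    gene_id: str
    verdict: str                      # repression_candidate|activation_candidate|none
    fold_change: float
    direction: str
    best_site: InteractionSite | None = None
    rbs: RBSLocation | None = None
    dPu: float | None = None
    rationale: str = ""


def select_candidates(expression: list[ExpressionRecord],
                      annotations: list[GeneAnnotation],
                      config: ScreenConfig) -> tuple[list[str], list[str]]:
    """Genes changing >= fold_threshold (either direction) plus the first
    ORF of any operon containing a selected gene.

    Returns (selected gene ids, skipped-genes report lines).  Input order is
    preserved; operon heads are appended after the directly selected genes.
    """
    ann_by_gene = {a.gene_id: a for a in annotations}
    heads: dict[str, str] = {}   # operon_id -> rank-1 gene
    for a in annotations:
        if a.operon_id is not None and a.operon_rank == 1:
            heads[a.operon_id] = a.gene_id
    selected: list[str] = []
    skipped: list[str] = []
    seen: set[str] = set()
    pulled: list[str] = []
    for rec in expression:
        ratio = max(rec.fold_change, 1.0 / rec.fold_change)
        if ratio < config.fold_threshold:
            continue
        ann = ann_by_gene.get(rec.gene_id)
        if ann is None:
            skipped.append(f"{rec.gene_id}: selected ({rec.fold_change:.3g}-fold)"
                           " but missing annotation")
            continue
        if rec.gene_id not in seen:
            selected.append(rec.gene_id)
            seen.add(rec.gene_id)
        if ann.operon_id is not None:
            head = heads.get(ann.operon_id)
            if head is None:
                skipped.append(f"{rec.gene_id}: operon {ann.operon_id} has no"
                               " rank-1 ORF annotated")
            elif head not in seen:
                pulled.append(head)
                seen.add(head)
    return selected + pulled, skipped


def build_search_region(transcript: TranscriptModel,
                        config: ScreenConfig) -> SearchRegion:
    """[TSS .. start+cds_extension-1] (UTR known) or the fallback window."""
    codon = transcript.start_codon_offset
    end = codon + config.cds_extension - 1
    n = len(transcript.sequence)
    if end > n:
        warnings.warn(f"{transcript.gene_id}: CDS shorter than "
                      f"{config.cds_extension} nt; search region truncated")
        end = n
    return SearchRegion(
        gene_id=transcript.gene_id,
        sequence=transcript.sequence.residues[:end],
        codon_offset=codon,
        utr_known=transcript.utr_length is not None)


def repression_filter(site: InteractionSite, config: ScreenConfig) -> bool:
    """True iff the site's target interval intersects (or, with
    ``config.contained``, lies within) the ribosome-covered window."""
    if site.mrna_interval_codon is None:
        raise ValueError("site lacks start-codon-relative coordinates")
    a, b = site.mrna_interval_codon
    lo, hi = config.ribosome_window
    if config.contained:
        return lo <= a and b <= hi
    return a <= hi and b >= lo


def _rbs_local_interval(region: SearchRegion, rbs_loc: RBSLocation,
                        config: ScreenConfig) -> tuple[int, int]:
    a = region.from_codon_relative(rbs_loc.interval[0])
    b = region.from_codon_relative(rbs_loc.interval[1]) + config.rbs_probe_extension
    return a, min(b, len(region.sequence))


def rbs_accessibility_change(region: SearchRegion, site: InteractionSite,
                             rbs_loc: RBSLocation,
                             model: EnergyModel | None = None,
                             config: ScreenConfig | None = None,
                             calc: AccessibilityCalculator | None = None) -> float:
    """dPu = Pu(RBS | site forced unpaired) - Pu(RBS), both window-averaged.

    The site must lie strictly upstream of the RBS (a site overlapping the
    RBS belongs to the repression branch).
    """
    config = config or ScreenConfig()
    model = model or EnergyModel.default()
    if site.mrna_interval_codon is None:
        site = replace(site, mrna_interval_codon=(
            region.to_codon_relative(site.mrna_interval[0]),
            region.to_codon_relative(site.mrna_interval[1])))
    rbs_a, rbs_b = _rbs_local_interval(region, rbs_loc, config)
    if site.mrna_interval[1] >= rbs_a:
        raise ValueError("site is not strictly upstream of the RBS; use the"
                         " repression branch")
    if calc is None:
        calc = AccessibilityCalculator(region.sequence, model,
                                       window=config.window,
                                       max_span=config.max_span,
                                       step=config.window_step,
                                       mode=config.window_mode)
    before = calc.pu((rbs_a, rbs_b))
    after = calc.pu((rbs_a, rbs_b),
                    constraint=FoldConstraint.from_intervals(site.mrna_interval))
    return after - before


def _usable(site: InteractionSite) -> bool:
    return site.usable and site.E_total < 0


def classify_candidate(gene_id: str, sites: list[InteractionSite],
                       rbs_loc: RBSLocation | None, direction: str,
                       dPu: float | None, fold_change: float,
                       config: ScreenConfig) -> TargetCall:
    """Direction-conditional verdict from ranked sites and RBS evidence.

    For the up branch, ``dPu`` must correspond to the best usable site
    strictly upstream of the RBS (as computed by :func:`run_screen`).
    """
    call = TargetCall(gene_id=gene_id, verdict="none", fold_change=fold_change,
                      direction=direction, rbs=rbs_loc, dPu=dPu)
    usable = [s for s in sites if _usable(s)]
    if not usable:
        call.rationale = "no_favorable_site"
        call.best_site = sites[0] if sites else None
        return call
    if direction == "down":
        passing = [s for s in usable if repression_filter(s, config)]
        if passing:
            call.verdict = "repression_candidate"
            call.best_site = min(passing, key=lambda s: s.E_total)
            call.rationale = "site_in_ribosome_window"
        else:
            call.best_site = usable[0]
            call.rationale = "site_outside_ribosome_window"
        return call
    # up-regulated branch
    if rbs_loc is None:
        call.best_site = usable[0]
        call.rationale = "no_rbs_call"
        return call
    upstream = [s for s in usable
                if s.mrna_interval_codon is not None
                and s.mrna_interval_codon[1] < rbs_loc.interval[0]]
    if not upstream:
        call.best_site = usable[0]
        call.rationale = "no_site_upstream_of_rbs"
        return call
    call.best_site = min(upstream, key=lambda s: s.E_total)
    if dPu is None:
        call.rationale = "dPu_not_computed"
    elif dPu > config.dPu_threshold:
        call.verdict = "activation_candidate"
        call.rationale = "rbs_accessibility_increase"
    else:
        call.rationale = "dPu_below_threshold"
    return call


_VERDICT_ORDER = {"repression_candidate": 0, "activation_candidate": 1, "none": 2}

REPORT_COLUMNS = [
    "gene_id", "fold_change", "direction", "verdict", "rationale",
    "srna_start", "srna_end", "mrna_start", "mrna_end",
    "start_rel_start_codon", "E_hybrid", "ED_srna", "ED_mrna", "E_total",
    "pairing", "rbs_start", "rbs_end", "rbs_energy", "rbs_significant", "dPu",
]


@dataclass
class ScreenReport:
    """run_screen output: per-gene calls, the evidence table, warnings."""

    calls: list[TargetCall]
    table: pd.DataFrame
    skipped: list[str]


def run_screen(srna: str, transcripts: dict[str, TranscriptModel] | list[TranscriptModel],
               expression: list[ExpressionRecord],
               annotations: list[GeneAnnotation],
               config: ScreenConfig | None = None,
               model: EnergyModel | None = None) -> ScreenReport:
    """Run the full screen; one report row per candidate gene, ranked by
    verdict class then E_total.  Per-gene problems are aggregated in
    ``skipped``, never silently dropped."""
    config = config or ScreenConfig()
    model = model or EnergyModel.default()
    if not isinstance(transcripts, dict):
        transcripts = {t.gene_id: t for t in transcripts}
    expr_by_gene = {r.gene_id: r for r in expression}
    candidates, skipped = select_candidates(expression, annotations, config)

    srna_calc = AccessibilityCalculator(srna, model, window=config.window,
                                        max_span=config.max_span,
                                        step=config.window_step,
                                        mode=config.window_mode)
    calls: list[TargetCall] = []
    for gene in candidates:
        tr = transcripts.get(gene)
        if tr is None:
            skipped.append(f"{gene}: no transcript provided")
            continue
        rec = expr_by_gene.get(gene)
        fold = rec.fold_change if rec else 1.0
        direction = rec.direction if rec else "up"
        region = build_search_region(tr, config)
        mrna_calc = AccessibilityCalculator(region.sequence, model,
                                            window=config.window,
                                            max_span=config.max_span,
                                            step=config.window_step,
                                            mode=config.window_mode)
        sites = scan_region(srna, region.sequence, model, config.seed,
                            codon_offset=region.codon_offset,
                            max_sites=config.max_sites,
                            srna_acc=srna_calc, mrna_acc=mrna_calc)
        rbs_loc = locate_rbs(tr, config.anti_sd, model,
                             config.rbs_scan_window, config.rbs_threshold)
        dPu = None
        if direction == "up" and rbs_loc is not None:
            rbs_a, _ = _rbs_local_interval(region, rbs_loc, config)
            upstream = [s for s in sites
                        if _usable(s) and s.mrna_interval[1] < rbs_a]
            if upstream:
                best_up = min(upstream, key=lambda s: s.E_total)
                dPu = rbs_accessibility_change(region, best_up, rbs_loc,
                                               model, config, calc=mrna_calc)
        calls.append(classify_candidate(gene, sites, rbs_loc, direction,
                                        dPu, fold, config))

    calls.sort(key=lambda c: (_VERDICT_ORDER.get(c.verdict, 3),
                              c.best_site.E_total if c.best_site else math.inf,
                              c.gene_id))
    return ScreenReport(calls=calls, table=_report_table(calls), skipped=skipped)


def _report_table(calls: list[TargetCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        s = c.best_site
        rel = None
        if s is not None and s.mrna_interval_codon is not None:
            rel = f"{s.mrna_interval_codon[0]}..{s.mrna_interval_codon[1]}"
        rows.append({
            "gene_id": c.gene_id, "fold_change": c.fold_change,
            "direction": c.direction, "verdict": c.verdict,
            "rationale": c.rationale,
            "srna_start": s.srna_interval[0] if s else None,
            "srna_end": s.srna_interval[1] if s else None,
            "mrna_start": s.mrna_interval[0] if s else None,
            "mrna_end": s.mrna_interval[1] if s else None,
            "start_rel_start_codon": rel,
            "E_hybrid": s.E_hybrid if s else None,
            "ED_srna": s.ED_srna if s else None,
            "ED_mrna": s.ED_mrna if s else None,
            "E_total": s.E_total if s else None,
            "pairing": s.pairing_string() if s else None,
            "rbs_start": c.rbs.interval[0] if c.rbs else None,
            "rbs_end": c.rbs.interval[1] if c.rbs else None,
            "rbs_energy": c.rbs.duplex_energy if c.rbs else None,
            "rbs_significant": c.rbs.significant if c.rbs else None,
            "dPu": c.dPu,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


# ---------------------------------------------------------------------------
# cis-antisense overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapRecord:
    overlap: int
    classification: str   # 5'-5' | 3'-3' | internal | none | not_antisense


def antisense_overlap(a: GeneAnnotation, b: GeneAnnotation) -> OverlapRecord:
    """Overlap length and end-class of two opposite-strand features.

    The class records which ends meet in each feature's own orientation:
    divergent 5' ends -> ``5'-5'`` (the cis-antisense arrangement studied
    here), convergent 3' ends -> ``3'-3'``, anything else with a nonzero
    overlap -> ``internal``.
    """
    if a.contig_id != b.contig_id:
        raise ValueError("features on different contigs")
    if a.strand == b.strand:
        return OverlapRecord(0, "not_antisense")
    lo = max(a.span[0], b.span[0])
    hi = min(a.span[1], b.span[1])
    if lo > hi:
        return OverlapRecord(0, "none")
    ov = hi - lo + 1

    def ends_in(span, strand):
        five = span[0] if strand == "+" else span[1]
        three = span[1] if strand == "+" else span[0]
        out = set()
        if lo <= five <= hi:
            out.add(5)
        if lo <= three <= hi:
            out.add(3)
        return out

    ea = ends_in(a.span, a.strand)
    eb = ends_in(b.span, b.strand)
    if ea == {5} and eb == {5}:
        cls = "5'-5'"
    elif ea == {3} and eb == {3}:
        cls = "3'-3'"
    else:
        cls = "internal"
    return OverlapRecord(ov, cls)


# ---------------------------------------------------------------------------
# qRT-PCR fold change
# ---------------------------------------------------------------------------

def fold_change_from_ct(ct: pd.DataFrame, reference_genes: list[str],
                        conditions: tuple[str, str] = ("wt", "mut")) -> dict[str, float]:
    """2^-ddCt fold changes from a threshold-cycle table.

    ``ct`` needs columns gene_id, condition, ct (replicates are averaged).
    Per condition dCt = Ct_target - mean(Ct_references); ddCt = dCt_mut -
    dCt_wt; fold change = 2^-ddCt.  Requires every reference gene in both
    conditions.
    """
    wt, mut = conditions
    need = {"gene_id", "condition", "ct"}
    if not need <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(need)}")
    if not np.isfinite(ct["ct"]).all():
        raise ValueError("Ct values must be finite")
    mean_ct = ct.groupby(["gene_id", "condition"])["ct"].mean()

    def ref_mean(cond):
        vals = []
        for g in reference_genes:
            if (g, cond) not in mean_ct.index:
                raise ValueError(f"reference gene {g} missing in condition {cond}")
            vals.append(mean_ct[(g, cond)])
        return float(np.mean(vals))

    ref = {c: ref_mean(c) for c in (wt, mut)}
    out = {}
    targets = [g for g in mean_ct.index.get_level_values(0).unique()
               if g not in reference_genes]
    for g in targets:
        for c in (wt, mut):
            if (g, c) not in mean_ct.index:
                raise ValueError(f"target {g} missing in condition {c}")
        d_wt = mean_ct[(g, wt)] - ref[wt]
        d_mut = mean_ct[(g, mut)] - ref[mut]
        out[g] = float(2.0 ** -(d_mut - d_wt))
    return out
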
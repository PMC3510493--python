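"""Seeded synthetic datasets with the structural and statistical properties
the screen assumes.

The generated sRNA emulates a 191-nt regulator with three stem-loops and a
39-nt single-stranded linker (SLR) between SL2 and SL3 — the trans-targeting
domain — plus an unstructured 3' tail.  Design choices that make the
generator verifiable rather than merely labelled:

* The linker is drawn from the purine alphabet {A, G} (no canonical pair is
  possible within a purine tract, so the linker cannot fold on itself) and
  carries a fixed AGGAGG "activation word".  Planted target sites are exact
  pyrimidine reverse complements of linker subsequences.
* Stems are GC-biased complementary arms; the generator *verifies* its own
  structural contract with the package's folding engine (mean linker
  Pu >= 0.9, mean stem Pu <= 0.3 under the default model, base-pair span
  capped at 50) and resamples deterministically until it holds.
* Activation targets physically realize the RBS-release mechanism: the
  planted site is the reverse complement of the linker window starting at
  the activation word, so the mRNA tract ends in CCUCCU, which sequesters a
  downstream AGGAGG RBS in a hairpin; forcing the site single-stranded
  frees the RBS.
* The negative-control linker mode replaces the SLR by poly(U)
  (``linker_mode="polyU"``), mirroring a linker-to-poly(T) replacement
  mutant: a poly-U tract can pair with none of the pyrimidine target sites.
  A compositional shuffle (``"shuffled"``) is also available, but note that
  a shuffled purine tract retains pairing capacity against pyrimidine sites
  and is therefore not a zero-interaction control.

Benchmarks are pure functions of (spec, seed): a contig carrying all genes,
annotations in the package TSV dialect, an expression table with planted
fold changes under multiplicative lognormal noise, and a truth table
sufficient to score any screen run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import EnergyModel
from .screen import ScreenConfig, ScreenReport
from .seqio import (ExpressionRecord, GeneAnnotation, NucleotideSequence,
                    TranscriptModel, reverse_complement, write_annotations,
                    write_expression, write_fasta, write_table)
from .thermo import partition_function

__all__ = ["SrnaArchitecture", "BenchmarkSpec", "Benchmark", "make_srna",
           "plant_trans_target", "make_cis_pair", "simulate_expression",
           "make_benchmark", "score_report"]

# planted in the linker; its first 6 nt are the SD word AGGAGG, the AAG
# extension deepens the RBS-sequestration hairpin of activation targets
# without introducing sticky G runs
ACTIVATION_WORD = "AGGAGGAAG"
RBS_WORD = "AGGAGG"


@dataclass(frozen=True)
class SrnaArchitecture:
    """Stem-loop/linker layout of the synthetic sRNA (defaults: 191 nt,
    SL1-SL2-SLR(39)-SL3-tail, processing cut sites 65/60/55)."""

    total_length: int = 191
    stems: tuple[tuple[int, int], ...] = ((12, 4), (13, 5), (22, 5))
    linker_length: int = 39
    tail_length: int = 44
    fragment_cut_sites: tuple[int, ...] = (65, 60, 55)
    stem_gc: float = 0.75
    linker_g_fraction: float = 0.30
    #: 1-based offset of the AGGAGG activation word within the linker
    activation_word_offset: int = 18

    def __post_init__(self):
        segs = sum(2 * s + l for s, l in self.stems) \
            + self.linker_length + self.tail_length
        if segs != self.total_length:
            raise ValueError(f"segment lengths sum to {segs}, expected"
                             f" {self.total_length}")
        if self.activation_word_offset + len(ACTIVATION_WORD) - 1 > self.linker_length:
            raise ValueError("activation word does not fit in the linker")

    @property
    def segment_intervals(self) -> dict[str, tuple[int, int]]:
        out = {}
        pos = 1
        for idx, (s, l) in enumerate(self.stems, 1):
            if idx == 3:
                out["linker"] = (pos, pos + self.linker_length - 1)
                pos += self.linker_length
            out[f"SL{idx}"] = (pos, pos + 2 * s + l - 1)
            pos += 2 * s + l
        out["tail"] = (pos, pos + self.tail_length - 1)
        return out


def _random_seq(rng, n, letters="ACGU", p=None):
    return "".join(rng.choice(list(letters), size=n, p=p))


def _structure_check(seq: str, features: dict, arch: SrnaArchitecture,
                     model: EnergyModel) -> tuple[float, float]:
    """(mean linker Pu, mean stem Pu) under the default span-capped fold."""
    es = partition_function(seq, model, max_span=50)
    a, b = features["linker"]
    linker_pu = float(np.mean([es.unpaired_probability((p, p))
                               for p in range(a, b + 1)]))
    stem_pos = []
    for idx, (s, l) in enumerate(arch.stems, 1):
        sa, sb = features[f"SL{idx}"]
        stem_pos.extend(range(sa, sa + s))            # 5' arm
        stem_pos.extend(range(sb - s + 1, sb + 1))    # 3' arm
    stem_pu = float(np.mean([es.unpaired_probability((p, p))
                             for p in stem_pos]))
    return linker_pu, stem_pu


def make_srna(arch: SrnaArchitecture | None = None, rng_seed: int = 0,
              linker_mode: str = "wt", model: EnergyModel | None = None,
              check: bool = True, max_attempts: int = 20):
    """Generate the synthetic sRNA and its ground-truth feature map.

    Returns ``(NucleotideSequence, features)`` where features maps segment
    names (SL1..SL3, linker, tail, activation_word) to 1-based intervals and
    records the fragment cut sites.  With ``check=True`` the structural
    contract (linker Pu >= 0.9, stem Pu <= 0.3) is verified with the folding
    engine and stems are resampled (deterministically) until it holds.
    """
    arch = arch or SrnaArchitecture()
    if linker_mode not in ("wt", "polyU", "shuffled"):
        raise ValueError("linker_mode must be wt, polyU or shuffled")
    model = model or EnergyModel.default()
    gc = arch.stem_gc
    probs = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "U": (1 - gc) / 2}

    for attempt in range(max_attempts):
        rng = np.random.default_rng(rng_seed + 100_003 * attempt)
        # linker: purines with the activation word planted
        pg = arch.linker_g_fraction
        linker = list(_random_seq(rng, arch.linker_length, "AG", [1 - pg, pg]))
        w0 = arch.activation_word_offset - 1
        linker[w0:w0 + len(ACTIVATION_WORD)] = list(ACTIVATION_WORD)
        linker = "".join(linker)
        if linker_mode == "polyU":
            linker = "U" * arch.linker_length
        elif linker_mode == "shuffled":
            linker = "".join(rng.permutation(list(linker)))
        parts = []
        for idx, (s, l) in enumerate(arch.stems, 1):
            if idx == 3:
                parts.append(linker)
                # SL3 5' arm from {G, U}: its 3' arm is then G-free {C, A},
                # so the adjacent poly-C tail cannot pair with it
                arm = _random_seq(rng, s, "GU", [gc, 1 - gc])
            else:
                arm = _random_seq(rng, s, "ACGU", [probs[b] for b in "ACGU"])
            parts.append(arm + "A" * l + reverse_complement(arm))
        # tail: poly-C — pairs only G runs, which neither the pyrimidine
        # target sites nor a neutralized linker provide
        parts.append("C" * arch.tail_length)
        seq = "".join(parts)
        features = dict(arch.segment_intervals)
        la = features["linker"][0]
        features["activation_word"] = (la + w0, la + w0 + len(ACTIVATION_WORD) - 1)
        features["fragment_cut_sites"] = arch.fragment_cut_sites
        features["linker_mode"] = linker_mode
        if not check or linker_mode == "polyU":
            break
        linker_pu, stem_pu = _structure_check(seq, features, arch, model)
        if linker_pu >= 0.9 and stem_pu <= 0.3:
            break
    else:
        raise RuntimeError("could not satisfy the sRNA structural contract")
    return NucleotideSequence("sRNA_synth", seq), features


# ---------------------------------------------------------------------------
# trans-target construction
# ---------------------------------------------------------------------------

def _rel_positions(a: int, b: int) -> list[int]:
    """Start-codon-relative positions a..b, skipping the nonexistent 0."""
    return [p for p in range(a, b + 1) if p != 0]


def plant_trans_target(srna_residues: str, features: dict,
                       placement: tuple[int, int], utr_length: int,
                       rng_seed: int = 0, gene_id: str = "target",
                       linker_window_start: int = 1, cds_len: int = 150,
                       scramble: bool = False, plant_rbs: bool = False):
    """Build a transcript carrying the reverse complement of a linker
    subsequence at a start-codon-relative placement.

    The start codon AUG is always preserved; a placement straddling it plants
    the complementary tract in blocks around +1..+3.  The truth record stores
    each planted block and its linker source so exact reverse
    complementarity is checkable.  ``scramble=True`` shuffles the planted
    letters (same composition, complementarity destroyed).  ``plant_rbs``
    writes AGGAGG at -13..-8 (refused if the site overlaps it).
    """
    rng = np.random.default_rng(rng_seed)
    a, b = placement
    if a > b or a == 0 or b == 0:
        raise ValueError("placement must be a nonempty interval without 0")
    if a < -utr_length:
        raise ValueError(f"placement {placement} not representable with a"
                         f" {utr_length}-nt UTR")
    if b > cds_len:
        raise ValueError("placement extends beyond the CDS")
    rel = [p for p in _rel_positions(a, b) if p not in (1, 2, 3)]
    lw0, lw1 = linker_window_start, linker_window_start + len(rel) - 1
    la, lb_ = features["linker"]
    if lw1 > lb_ - la + 1:
        raise ValueError("linker window exceeds the linker")
    window = srna_residues[la - 1 + lw0 - 1: la - 1 + lw1]
    site = reverse_complement(window)
    if scramble:
        site = "".join(rng.permutation(list(site)))

    n = utr_length + cds_len
    seq = list(_random_seq(rng, n))
    codon = utr_length + 1
    seq[codon - 1:codon + 2] = list("AUG")

    def local(p):  # codon-relative -> transcript-local (1-based)
        return codon + p - 1 if p > 0 else codon + p

    for s_char, p in zip(site, rel):
        seq[local(p) - 1] = s_char
    if plant_rbs:
        # RBS word = the first 6+ext nt of the linker window (AGGAGG plus
        # following purines), so the site tract's 3' end sequesters the RBS
        # in a 6+ext bp hairpin that the interaction releases
        ext = 3
        word = window[:6 + ext]
        if not word.startswith(RBS_WORD):
            raise ValueError("plant_rbs requires a linker window starting at"
                             " the activation word")
        rbs_pos = [local(p) for p in range(-13, -13 + len(word))]
        planted = {local(p) for p in rel}
        if planted & set(rbs_pos):
            raise ValueError("site overlaps the RBS; cannot plant both")
        for c, lp in zip(word, rbs_pos):
            seq[lp - 1] = c

    # truth blocks: maximal runs of consecutive local positions
    blocks = []
    run = [local(rel[0])]
    for prev, cur in zip(rel, rel[1:]):
        lp = local(cur)
        if lp == run[-1] + 1:
            run.append(lp)
        else:
            blocks.append((run[0], run[-1]))
            run = [lp]
    blocks.append((run[0], run[-1]))
    # matching linker sub-blocks (site laid 5'->3' on the mRNA corresponds
    # to the linker window read 3'->5')
    linker_blocks = []
    consumed = 0
    for (ba, bb) in blocks:
        blen = bb - ba + 1
        hi = (la + lw1 - 1) - consumed
        linker_blocks.append((hi - blen + 1, hi))
        consumed += blen
    truth = {
        "gene_id": gene_id,
        "placement": placement,
        "utr_length": utr_length,
        "site_blocks_local": blocks,
        "linker_blocks": linker_blocks,
        "scrambled": scramble,
    }
    tr = TranscriptModel(gene_id=gene_id,
                         sequence=NucleotideSequence(gene_id, "".join(seq)),
                         utr_length=utr_length, start_codon_offset=codon)
    return tr, truth


# ---------------------------------------------------------------------------
# cis-antisense pair
# ---------------------------------------------------------------------------

def make_cis_pair(overlap_len: int = 65, rng_seed: int = 0,
                  srna_len: int = 191, antisense_utr: int = 184,
                  antisense_cds: int = 300):
    """Opposite-strand gene pair whose 5' ends overlap by ``overlap_len``.

    The sRNA-like feature sits on the plus strand; the antisense gene runs
    minus-strand with its TSS inside the sRNA's 5' end and a 5'-UTR of
    ``antisense_utr`` nt (so with the defaults the arrangement reproduces a
    65-nt 5'-5' antisense overlap with a TSS 184 nt upstream of the
    translation start).  Returns (srna annotation, antisense annotation,
    contig).
    """
    if overlap_len >= min(srna_len, antisense_utr + antisense_cds):
        raise ValueError("overlap must be shorter than both features")
    rng = np.random.default_rng(rng_seed)
    pad = 30
    s0 = pad + antisense_utr + antisense_cds  # leave room leftward
    srna_span = (s0, s0 + srna_len - 1)
    if overlap_len > 0:
        b_tss = s0 + overlap_len - 1
    else:
        b_tss = s0 - 10  # disjoint, gap of 9 nt
    b_codon = b_tss - antisense_utr
    b_span = (b_codon - antisense_cds + 1, b_tss)
    contig_len = srna_span[1] + pad
    contig = NucleotideSequence("cis_contig", _random_seq(rng, contig_len))
    a = GeneAnnotation("sRNA_locus", "cis_contig", srna_span, "+",
                       start_codon_pos=srna_span[0], tss_pos=srna_span[0])
    b = GeneAnnotation("asgene", "cis_contig", b_span, "-",
                       start_codon_pos=b_codon, tss_pos=b_tss)
    return a, b, contig


# ---------------------------------------------------------------------------
# expression simulation and full benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkSpec:
    """Size and effect structure of a synthetic screening benchmark."""

    n_genes: int = 50
    n_repression_targets: int = 5
    n_activation_targets: int = 3
    n_decoys_with_offwindow_sites: int = 10
    effect_fold: float = 5.0
    noise_sigma: float = 0.2
    rng_seed: int = 0
    cds_len: int = 150
    utr_repression: int = 36
    utr_activation: int = 60
    include_operon: bool = True
    n_unknown_tss: int = 2

    def __post_init__(self):
        reserved = (self.n_repression_targets + self.n_activation_targets
                    + self.n_decoys_with_offwindow_sites
                    + (1 if self.include_operon else 0) + self.n_unknown_tss)
        if reserved > self.n_genes:
            raise ValueError("target counts exceed n_genes")


# placements cycled over the planted repression targets / off-window decoys
_REPRESSION_PLACEMENTS = [(-18, -3), (-30, -15), (-12, 6), (-20, -5), (-10, 8)]
_OFFWINDOW_PLACEMENTS = [(20, 35), (22, 37), (30, 45), (50, 65), (40, 55)]
_ACTIVATION_PLACEMENT = (-48, -33)


def simulate_expression(truth: pd.DataFrame, spec: BenchmarkSpec) -> list[ExpressionRecord]:
    """Planted repression targets ~ 1/effect, activation ~ effect, everything
    else ~ 1, times lognormal(0, noise_sigma) noise; fully seeded."""
    rng = np.random.default_rng(spec.rng_seed + 777)
    out = []
    for row in truth.itertuples(index=False):
        if row.kind == "repression":
            base = 1.0 / spec.effect_fold
        elif row.kind == "activation":
            base = spec.effect_fold
        else:
            base = 1.0
        noise = float(np.exp(rng.normal(0.0, spec.noise_sigma))) \
            if spec.noise_sigma > 0 else 1.0
        out.append(ExpressionRecord(row.gene_id, base * noise))
    return out


@dataclass
class Benchmark:
    """A self-contained synthetic dataset plus the screen config it assumes."""

    srna: NucleotideSequence
    srna_features: dict
    genome: NucleotideSequence
    annotations: list[GeneAnnotation]
    transcripts: dict[str, TranscriptModel]
    expression: list[ExpressionRecord]
    truth: pd.DataFrame
    config: ScreenConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prov = ["generated by srnascreen.synth.make_benchmark"]
        write_fasta([self.srna], out / "srna.fasta")
        write_fasta([self.genome], out / "genome.fasta")
        write_annotations(self.annotations, out / "annotations.tsv", prov)
        write_expression(self.expression, out / "expression.tsv", prov)
        write_table(self.truth, out / "truth.tsv", prov)


def make_benchmark(spec: BenchmarkSpec | None = None,
                   arch: SrnaArchitecture | None = None,
                   linker_mode: str = "wt",
                   out_dir=None) -> Benchmark:
    """Generate the full benchmark (deterministic in (spec, arch, seed))."""
    spec = spec or BenchmarkSpec()
    arch = arch or SrnaArchitecture()
    srna, features = make_srna(arch, spec.rng_seed, linker_mode=linker_mode)
    # plant against the wild-type linker so negative modes measure loss
    wt_srna, wt_features = (srna, features) if linker_mode == "wt" else \
        make_srna(arch, spec.rng_seed, linker_mode="wt")

    rng = np.random.default_rng(spec.rng_seed + 31)
    transcripts: dict[str, TranscriptModel] = {}
    rows = []
    gid = 0

    def next_id(prefix):
        nonlocal gid
        gid += 1
        return f"{prefix}{gid:03d}"

    linker_len = arch.linker_length
    for k in range(spec.n_repression_targets):
        g = next_id("rep")
        placement = _REPRESSION_PLACEMENTS[k % len(_REPRESSION_PLACEMENTS)]
        npos = len([p for p in _rel_positions(*placement) if p not in (1, 2, 3)])
        lw = 1 + (3 * k) % max(1, linker_len - npos + 1)
        tr, t = plant_trans_target(
            wt_srna.residues, wt_features, placement, spec.utr_repression,
            rng_seed=spec.rng_seed + 1000 + k, gene_id=g,
            linker_window_start=lw, cds_len=spec.cds_len)
        transcripts[g] = tr
        rows.append({"gene_id": g, "kind": "repression", "direction": "down",
                     "placement": f"{placement[0]}..{placement[1]}",
                     "expected_verdict": "repression_candidate", **_truth_cols(t)})

    word_rel = (wt_features["activation_word"][0] - wt_features["linker"][0]) + 1
    for k in range(spec.n_activation_targets):
        g = next_id("act")
        tr, t = plant_trans_target(
            wt_srna.residues, wt_features, _ACTIVATION_PLACEMENT,
            spec.utr_activation, rng_seed=spec.rng_seed + 2000 + k, gene_id=g,
            linker_window_start=word_rel, cds_len=spec.cds_len, plant_rbs=True)
        transcripts[g] = tr
        rows.append({"gene_id": g, "kind": "activation", "direction": "up",
                     "placement": f"{_ACTIVATION_PLACEMENT[0]}..{_ACTIVATION_PLACEMENT[1]}",
                     "expected_verdict": "activation_candidate", **_truth_cols(t)})

    for k in range(spec.n_decoys_with_offwindow_sites):
        g = next_id("dec")
        placement = _OFFWINDOW_PLACEMENTS[k % len(_OFFWINDOW_PLACEMENTS)]
        npos = len(_rel_positions(*placement))
        lw = 1 + (5 * k) % max(1, linker_len - npos + 1)
        tr, t = plant_trans_target(
            wt_srna.residues, wt_features, placement, spec.utr_repression,
            rng_seed=spec.rng_seed + 3000 + k, gene_id=g,
            linker_window_start=lw, cds_len=spec.cds_len)
        transcripts[g] = tr
        rows.append({"gene_id": g, "kind": "offwindow_decoy", "direction": "flat",
                     "placement": f"{placement[0]}..{placement[1]}",
                     "expected_verdict": "none", **_truth_cols(t)})

    operon_genes: dict[str, tuple[str, int]] = {}
    if spec.include_operon:
        # the first repression target becomes rank 2 of an operon whose
        # rank-1 head is a plain background gene
        head = next_id("oph")
        tr = _background_transcript(head, spec, rng)
        transcripts[head] = tr
        rows.append({"gene_id": head, "kind": "operon_head", "direction": "flat",
                     "placement": "", "expected_verdict": "none",
                     **_truth_cols(None)})
        operon_genes[head] = ("opA", 1)
        operon_genes["rep001"] = ("opA", 2)

    n_background = spec.n_genes - len(transcripts)
    for k in range(n_background):
        g = next_id("bkg")
        unknown_tss = k < spec.n_unknown_tss
        tr = _background_transcript(g, spec, rng, unknown_tss=unknown_tss)
        transcripts[g] = tr
        rows.append({"gene_id": g, "kind": "background", "direction": "flat",
                     "placement": "", "expected_verdict": "none",
                     **_truth_cols(None)})

    truth = pd.DataFrame(rows)
    expression = simulate_expression(truth, spec)
    genome, annotations = _assemble_contig(transcripts, operon_genes, rng)
    bench = Benchmark(srna=srna, srna_features=features, genome=genome,
                      annotations=annotations, transcripts=transcripts,
                      expression=expression, truth=truth,
                      config=ScreenConfig())
    if out_dir is not None:
        bench.write(out_dir)
    return bench


def _truth_cols(t: dict | None) -> dict:
    if t is None:
        return {"site_blocks_local": "", "linker_blocks": ""}
    fmt = lambda bs: ";".join(f"{a}-{b}" for a, b in bs)
    return {"site_blocks_local": fmt(t["site_blocks_local"]),
            "linker_blocks": fmt(t["linker_blocks"])}


def _background_transcript(gene_id: str, spec: BenchmarkSpec, rng,
                           unknown_tss: bool = False) -> TranscriptModel:
    utr = 200 if unknown_tss else spec.utr_repression
    seq = list(_random_seq(rng, utr + spec.cds_len))
    seq[utr:utr + 3] = list("AUG")
    return TranscriptModel(gene_id=gene_id,
                           sequence=NucleotideSequence(gene_id, "".join(seq)),
                           utr_length=None if unknown_tss else utr,
                           start_codon_offset=utr + 1)


def _assemble_contig(transcripts: dict[str, TranscriptModel],
                     operon_genes: dict[str, tuple[str, int]], rng):
    """Concatenate all transcripts (plus strand, 250-nt spacers) into one
    contig with matching annotations, so seqio.build_transcript reproduces
    every transcript exactly (including the unknown-TSS fallback)."""
    spacer_len = 250
    parts = []
    annotations = []
    pos = 1
    for g, tr in transcripts.items():
        parts.append(_random_seq(rng, spacer_len))
        pos += spacer_len
        start = pos
        seq = tr.sequence.residues
        parts.append(seq)
        codon = start + tr.start_codon_offset - 1
        end = start + len(seq) - 1
        op = operon_genes.get(g)
        annotations.append(GeneAnnotation(
            gene_id=g, contig_id="bench_contig", span=(codon, end), strand="+",
            start_codon_pos=codon,
            tss_pos=start if tr.utr_length is not None else None,
            operon_id=op[0] if op else None,
            operon_rank=op[1] if op else None))
        pos = end + 1
    genome = NucleotideSequence("bench_contig", "".join(parts))
    return genome, annotations


def score_report(report: ScreenReport, truth: pd.DataFrame) -> dict[str, float]:
    """Precision/recall of repression and activation calls against truth,
    plus the count of calls on genes that are not planted targets."""
    verdicts = {c.gene_id: c.verdict for c in report.calls}
    kind = dict(zip(truth["gene_id"], truth["kind"]))
    out = {}
    for label, verdict in (("repression", "repression_candidate"),
                           ("activation", "activation_candidate")):
        truth_pos = {g for g, k in kind.items() if k == label}
        called = {g for g, v in verdicts.items() if v == verdict}
        tp = len(called & truth_pos)
        out[f"{label}_precision"] = tp / len(called) if called else 1.0
        out[f"{label}_recall"] = tp / len(truth_pos) if truth_pos else 1.0
    decoys = {g for g, k in kind.items()
              if k in ("offwindow_decoy", "background", "operon_head")}
    out["decoy_false_positives"] = float(sum(
        1 for g, v in verdicts.items() if g in decoys and v != "none"))
    return out
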
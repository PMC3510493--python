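"""Ribosome-binding-site location by anti-SD hybridization scanning.

The Shine-Dalgarno (SD) element of an mRNA pairs with the anti-SD tail of
16S rRNA; here the RBS of a transcript is located by hybridizing a short
anti-SD probe (default ``CCUCCU``, the complement of AGGAGG) against the
region upstream of the start codon (default -20..-4, start-codon-relative)
and taking the minimum duplex energy, with a relaxed seed of 4 consecutive
pairs.  A call is significant when its energy is at or below a configurable
free-energy threshold (default -3.5 kcal/mol).

Whether the original genome-wide prediction this stage stands in for used a
hybridization energy or a position-weight model is not publicly described;
the anti-SD free-energy scan is the transparent, declared choice here (see
docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .energy import EnergyModel
from .interact import SeedSpec, hybridize
from .seqio import TranscriptModel

__all__ = ["RBSLocation", "DEFAULT_ANTI_SD", "DEFAULT_SCAN_WINDOW",
           "DEFAULT_RBS_THRESHOLD", "locate_rbs"]

DEFAULT_ANTI_SD = "CCUCCU"
DEFAULT_SCAN_WINDOW = (-20, -4)
DEFAULT_RBS_THRESHOLD = -3.5  # kcal/mol


@dataclass(frozen=True)
class RBSLocation:
    """An RBS call in start-codon-relative coordinates (all upstream of +1)."""

    interval: tuple[int, int]
    duplex_energy: float
    significant: bool

    def __post_init__(self):
        if self.interval[1] >= 1:
            raise ValueError("RBS interval must lie entirely upstream of +1")


def locate_rbs(transcript: TranscriptModel, anti_sd: str = DEFAULT_ANTI_SD,
               model: EnergyModel | None = None,
               scan_window: tuple[int, int] = DEFAULT_SCAN_WINDOW,
               threshold: float = DEFAULT_RBS_THRESHOLD) -> RBSLocation | None:
    """Best anti-SD duplex within the upstream scan window, or None.

    A transcript whose 5' end does not cover the window is scanned over the
    available truncated window, with a warning.
    """
    model = model or EnergyModel.default()
    lo, hi = scan_window
    if not (lo <= hi < 0):
        raise ValueError("scan window must lie upstream of the start codon")
    codon = transcript.start_codon_offset
    # start-codon-relative -k  <->  transcript-local codon - k  (no 0)
    a = codon + lo
    b = codon + hi
    if b < 1:
        return None
    if a < 1:
        warnings.warn(f"{transcript.gene_id}: upstream sequence shorter than"
                      " the RBS scan window; scanning truncated window")
        a = 1
    region = transcript.sequence.residues[a - 1:b]
    if len(region) < 4:
        return None
    site = hybridize(anti_sd, region, model, SeedSpec(4))
    if site is None:
        return None
    m0, m1 = site.mrna_interval
    interval = (m0 + a - 1 - codon, m1 + a - 1 - codon)
    return RBSLocation(interval=interval, duplex_energy=site.E_hybrid,
                       significant=site.E_hybrid <= threshold)
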
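"""Simulated Sanger colony screening against an expected shRNAmir cassette.

A colony read is classified by anchoring on the invariant 19-nt terminal
loop — the cheapest reliable landmark, since it is identical in every
correctly assembled construct — and then comparing the two flanking 22-mers
against the expected sense and guide strands. Both read orientations are
searched. The error model is substitution-only with a uniform per-base rate;
indels, quality trimming and chromatogram handling are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .oligo_design import ShRNAmirCassette
from .seqcore import DnaSeq, revcomp_str

__all__ = ["SangerRead", "VerifyReport", "simulate_read", "verify_read", "screen_summary"]

_OTHER_BASES = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


@dataclass(frozen=True)
class SangerRead:
    bases: str
    origin: str = ""
    primer_offset: int = 0
    error_positions: tuple[int, ...] = ()


@dataclass
class VerifyReport:
    positive: bool
    orientation: str  # "forward" | "reverse" | "not_found"
    loop_found: bool
    sense_match: int | None  # mismatch count, None when window not covered
    guide_match: int | None
    notes: str = ""


def simulate_read(
    construct: DnaSeq,
    primer_offset: int,
    read_len: int = 700,
    sub_rate: float = 0.0,
    seed: int | None = None,
    origin: str = "",
) -> SangerRead:
    """Draw one read starting at ``primer_offset``, deterministic given seed.

    Circular constructs wrap past the origin; linear templates truncate the
    read at the template end. Substitution errors hit each base
    independently with probability ``sub_rate``; positions are recorded.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    if not 0 <= primer_offset < len(construct):
        raise ValueError("primer_offset out of range")
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError("sub_rate must be a probability")
    n = len(construct)
    if construct.is_circular:
        doubled = construct.bases * (read_len // n + 2)
        bases = doubled[primer_offset : primer_offset + read_len]
    else:
        bases = construct.bases[primer_offset : primer_offset + read_len]
    errors: list[int] = []
    if sub_rate > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(len(bases)) < sub_rate
        out = list(bases)
        for i in np.flatnonzero(mask):
            out[i] = rng.choice(_OTHER_BASES[out[i]])
            errors.append(int(i))
        bases = "".join(out)
    return SangerRead(
        bases=bases,
        origin=origin,
        primer_offset=primer_offset,
        error_positions=tuple(errors),
    )


def _anchor_positions(text: str, anchor: str, max_mismatch: int) -> list[int]:
    if max_mismatch == 0:
        hits, start = [], text.find(anchor)
        while start != -1:
            hits.append(start)
            start = text.find(anchor, start + 1)
        return hits
    return [
        i
        for i in range(len(text) - len(anchor) + 1)
        if sum(a != b for a, b in zip(text[i : i + len(anchor)], anchor))
        <= max_mismatch
    ]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def verify_read(
    read: SangerRead,
    expected: ShRNAmirCassette,
    mismatch_budget: int = 0,
    anchor_mismatch: int = 0,
) -> VerifyReport:
    """Classify a read positive/negative for the expected cassette.

    The loop is located (exact by default; ``anchor_mismatch`` relaxes the
    anchor for noisy reads) in the forward read, then in its reverse
    complement. The 22-mers flanking the anchor are scored against the
    expected sense and guide; the read is positive iff the loop was found,
    both windows are covered, and each carries at most ``mismatch_budget``
    mismatches. Garbage input never raises — it is reported not_found.
    """
    loop = expected.loop
    best: VerifyReport | None = None
    for orientation, text in (
        ("forward", read.bases),
        ("reverse", revcomp_str(read.bases)),
    ):
        for pos in _anchor_positions(text, loop, anchor_mismatch):
            covered = pos >= 22 and pos + len(loop) + 22 <= len(text)
            if not covered:
                candidate = VerifyReport(
                    positive=False,
                    orientation=orientation,
                    loop_found=True,
                    sense_match=None,
                    guide_match=None,
                    notes="loop found but flanking 22-mers not covered by read",
                )
            else:
                sm = _hamming(text[pos - 22 : pos], expected.sense)
                gm = _hamming(
                    text[pos + len(loop) : pos + len(loop) + 22], expected.guide
                )
                candidate = VerifyReport(
                    positive=sm <= mismatch_budget and gm <= mismatch_budget,
                    orientation=orientation,
                    loop_found=True,
                    sense_match=sm,
                    guide_match=gm,
                )
            if candidate.positive:
                return candidate
            if best is None or (
                candidate.sense_match is not None and best.sense_match is None
            ):
                best = candidate
    if best is not None:
        return best
    return VerifyReport(
        positive=False,
        orientation="not_found",
        loop_found=False,
        sense_match=None,
        guide_match=None,
        notes="loop anchor not found in either orientation",
    )


def screen_summary(reports: list[VerifyReport]) -> dict:
    """Positivity summary over a batch of colony reads."""
    if not reports:
        raise ValueError("no reports to summarize")
    n = len(reports)
    n_pos = sum(r.positive for r in reports)
    return {"n": n, "n_positive": n_pos, "percent_positive": 100.0 * n_pos / n}
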
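"""Synonymous codon recoding to remove forbidden restriction sites.

Fluorescent-reporter and selection-marker coding sequences often contain
recognition sites for the enzymes a vector system relies on; such sites are
eliminated here by swapping codons for synonyms, leaving the protein
unchanged. The goal — not the algorithm — is fixed by the application, so we
use a deterministic greedy rule (see :func:`recode`): determinism and
verifiability over optimality. Codon-usage optimization is deliberately out
of scope; only site removal is performed. Standard genetic code only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .seqcore import DnaSeq, revcomp_str

__all__ = ["RecodeEntry", "UnresolvableSiteError", "translate", "recode", "SYNONYMS"]

# aa -> codons in lexicographic order (stop codons under "*")
SYNONYMS: dict[str, list[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    SYNONYMS.setdefault(aa, []).append(codon)
SYNONYMS["*"] = sorted(standard_dna_table.stop_codons)

_CODON_TO_AA = {c: aa for aa, cods in SYNONYMS.items() for c in cods}


@dataclass(frozen=True)
class RecodeEntry:
    codon_index: int
    old_codon: str
    new_codon: str
    removed_site: str
    site_offset: int


class UnresolvableSiteError(ValueError):
    """A forbidden site overlaps only codons without synonyms (Met/Trp)."""


def translate(cds: DnaSeq | str) -> str:
    """Standard-code translation; terminal stop rendered as ``*``.

    Warns (does not raise) on an internal stop codon.
    """
    bases = cds.bases if isinstance(cds, DnaSeq) else str(DnaSeq(cds))
    if len(bases) % 3:
        raise ValueError(f"CDS length {len(bases)} is not a multiple of 3")
    if not bases:
        return ""
    protein = str(Seq(bases).translate())
    if "*" in protein[:-1]:
        warnings.warn("internal stop codon in CDS")
    return protein


def _motif_set(forbidden: list[str]) -> list[str]:
    """Forbidden motifs plus reverse complements (scan the forward strand only)."""
    out = []
    for m in forbidden:
        m = str(DnaSeq(m))
        for v in (m, revcomp_str(m)):
            if v not in out:
                out.append(v)
    return out


def _find_hits(bases: str, motifs: list[str]) -> list[tuple[int, str]]:
    hits = []
    for m in motifs:
        start = bases.find(m)
        while start != -1:
            hits.append((start, m))
            start = bases.find(m, start + 1)
    return sorted(hits)


def recode(
    cds: DnaSeq | str, forbidden: list[str]
) -> tuple[DnaSeq, list[RecodeEntry]]:
    """Remove every forbidden motif (both strands) by synonymous substitution.

    Greedy left-to-right rule: for the leftmost remaining hit, try each
    overlapping codon left to right; within a codon, try synonymous codons
    in lexicographic order; accept the first substitution that removes the
    hit and introduces no new forbidden hit within +/-6 codons of it; then
    re-scan the whole sequence until no hit remains (new junction-created
    hits are caught by the re-scan). Deterministic; translation is
    preserved exactly.

    Raises :class:`UnresolvableSiteError` if some hit admits no admissible
    substitution (e.g. a site spanning only Met/Trp codons).
    """
    bases = cds.bases if isinstance(cds, DnaSeq) else str(DnaSeq(cds))
    if len(bases) % 3:
        raise ValueError(f"CDS length {len(bases)} is not a multiple of 3")
    motifs = _motif_set(forbidden)
    log: list[RecodeEntry] = []
    max_rounds = 10 * (len(bases) + 1)
    for _ in range(max_rounds):
        hits = _find_hits(bases, motifs)
        if not hits:
            return DnaSeq(bases), log
        off, motif = hits[0]
        window_lo = max(0, off - 18)
        window_hi = min(len(bases), off + len(motif) + 18)
        before = {
            (p, m)
            for p, m in _find_hits(bases[window_lo:window_hi], motifs)
        }
        first_codon = off // 3
        last_codon = (off + len(motif) - 1) // 3
        replaced = False
        for ci in range(first_codon, last_codon + 1):
            old = bases[3 * ci : 3 * ci + 3]
            aa = _CODON_TO_AA.get(old)
            if aa is None:
                continue
            for new in SYNONYMS[aa]:
                if new == old:
                    continue
                candidate = bases[: 3 * ci] + new + bases[3 * ci + 3 :]
                window = candidate[window_lo:window_hi]
                after = set(_find_hits(window, motifs))
                if (off - window_lo, motif) in after:
                    continue  # hit not removed
                if after - before:
                    continue  # created a new nearby hit
                log.append(RecodeEntry(ci, old, new, motif, off))
                bases = candidate
                replaced = True
                break
            if replaced:
                break
        if not replaced:
            raise UnresolvableSiteError(
                f"forbidden site {motif} at offset {off} cannot be removed by "
                f"synonymous substitution"
            )
    raise RuntimeError("recode did not converge")  # pragma: no cover
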
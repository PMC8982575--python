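"""Restriction digest, duplex annealing, and sticky-end ligation simulator.

The model covers type IIP enzymes cutting inside palindromic recognition
sites. A cut is described by two offsets within the site: where the top
strand is cut and where the bottom strand is cut. Unequal offsets leave a
single-stranded overhang; ``cut_top < cut_bottom`` protrudes the 5' strand
(e.g. BamHI G^GATCC -> 5' GATC), ``cut_top > cut_bottom`` protrudes the 3'
strand (e.g. ApaI GGGCC^C -> 3' GGCC), equal offsets cut blunt.

A linear :class:`Fragment` is represented by its full top strand plus typed
sticky ends. Top-strand protrusions (a 5' overhang on the left end, a 3'
overhang on the right end) are part of ``top``; bottom-strand protrusions
(3' left / 5' right) live only in the end descriptor. With this convention
joining two compatible ends is always plain concatenation of top strands,
which makes ligation round-trips exact.

Two ends join iff they have the same polarity and one overhang is the
reverse complement of the other. Star activity, methylation sensitivity and
enzyme kinetics are not modeled; ligation enumerates only circular products
using each fragment at most once (no concatemers, no partial digests).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .seqcore import DnaSeq, find_motif, revcomp_str

logger = logging.getLogger(__name__)

__all__ = [
    "Enzyme",
    "StickyEnd",
    "Fragment",
    "ENZYMES",
    "AnnealingError",
    "digest",
    "anneal",
    "ligate",
    "screen_sites",
    "make_mock_vector",
    "assemble_construct",
    "canonical_rotation",
    "circular_equal",
]


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if revcomp_str(self.recognition) != self.recognition:
            raise ValueError(
                f"{self.name}: only palindromic type IIP sites are supported"
            )

    @property
    def overhang(self) -> str:
        lo, hi = sorted((self.cut_top, self.cut_bottom))
        return self.recognition[lo:hi]

    @property
    def polarity(self) -> str:
        if self.cut_top < self.cut_bottom:
            return "five_prime"
        if self.cut_top > self.cut_bottom:
            return "three_prime"
        return "blunt"


#: Enzymes used by the vector system: the two cloning enzymes (BamHI/ApaI)
#: plus the backbone/screening enzymes. Offsets follow the standard cut-site
#: definitions and are validated in-repo against the oligo-layout arithmetic
#: (designed top oligos begin GATCC and end with an unpaired GGCC tail).
ENZYMES: dict[str, Enzyme] = {
    e.name: e
    for e in [
        Enzyme("BamHI", "GGATCC", 1, 5),
        Enzyme("ApaI", "GGGCCC", 5, 1),
        Enzyme("XhoI", "CTCGAG", 1, 5),
        Enzyme("EcoRI", "GAATTC", 1, 5),
        Enzyme("AfeI", "AGCGCT", 3, 3),
        Enzyme("ClaI", "ATCGAT", 2, 4),
        Enzyme("KpnI", "GGTACC", 5, 1),
        Enzyme("PacI", "TTAATTAA", 5, 3),
        Enzyme("PmeI", "GTTTAAAC", 4, 4),
        Enzyme("BglII", "AGATCT", 1, 5),
    ]
}


@dataclass(frozen=True)
class StickyEnd:
    polarity: str  # "five_prime" | "three_prime" | "blunt"
    overhang: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("five_prime", "three_prime", "blunt"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.polarity == "blunt" and self.overhang:
            raise ValueError("blunt ends carry no overhang")

    def compatible(self, other: "StickyEnd") -> bool:
        """Symmetric: ends join iff same polarity and complementary overhangs."""
        return self.polarity == other.polarity and self.overhang == revcomp_str(
            other.overhang
        )


BLUNT = StickyEnd("blunt")


@dataclass(frozen=True)
class Fragment:
    """A double-stranded DNA segment with typed ends.

    ``top`` is the full top strand 5'->3'. Circular fragments have no ends
    (``left_end`` and ``right_end`` are None).
    """

    top: str
    left_end: StickyEnd | None = BLUNT
    right_end: StickyEnd | None = BLUNT
    topology: str = "linear"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.topology == "circular" and (self.left_end or self.right_end):
            raise ValueError("circular fragments have no ends")

    def __len__(self) -> int:
        return len(self.top)

    @property
    def core(self) -> str:
        """Double-stranded core: top minus top-strand protrusions."""
        if self.topology == "circular":
            return self.top
        a = len(self.left_end.overhang) if self.left_end.polarity == "five_prime" else 0
        b = len(self.right_end.overhang) if self.right_end.polarity == "three_prime" else 0
        return self.top[a : len(self.top) - b]

    @property
    def bottom(self) -> str:
        """Full bottom strand 5'->3' (bottom protrusions included)."""
        if self.topology == "circular":
            return revcomp_str(self.top)
        right = self.right_end.overhang if self.right_end.polarity == "five_prime" else ""
        left = self.left_end.overhang if self.left_end.polarity == "three_prime" else ""
        return right + revcomp_str(self.core) + left

    def flipped(self) -> "Fragment":
        """The same molecule read from the other strand."""
        if self.topology == "circular":
            return replace(self, top=revcomp_str(self.top))
        return Fragment(
            top=self.bottom,
            left_end=self.right_end,
            right_end=self.left_end,
            topology="linear",
            provenance=self.provenance,
        )

    def as_dnaseq(self) -> DnaSeq:
        return DnaSeq(self.top, topology=self.topology)


class AnnealingError(ValueError):
    """Two oligos admit no ungapped perfect-complement alignment."""


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------


def _cut_positions(seq: DnaSeq, enzymes: list[Enzyme]) -> list[tuple[int, Enzyme, int]]:
    """(top_cut_position, enzyme, site_offset) for every site, sorted."""
    cuts = []
    for enz in enzymes:
        for hit in find_motif(seq, enz.recognition):
            site = hit.offset
            top_cut = (site + enz.cut_top) % len(seq) if seq.is_circular else site + enz.cut_top
            cuts.append((top_cut, enz, site))
    cuts.sort()
    return cuts


def digest(seq: DnaSeq, enzymes: list[Enzyme | str]) -> list[Fragment]:
    """Cut at every recognition site of every enzyme.

    A circular input with k total sites yields k fragments; a linear input
    yields k + 1 (original linear ends are blunt). With zero sites the input
    is returned uncut with a logged notice.
    """
    enzymes = [ENZYMES[e] if isinstance(e, str) else e for e in enzymes]
    cuts = _cut_positions(seq, enzymes)
    n = len(seq)
    if not cuts:
        logger.info("no recognition sites found; input returned uncut")
        if seq.is_circular:
            return [Fragment(seq.bases, None, None, "circular", provenance="uncut")]
        return [Fragment(seq.bases, BLUNT, BLUNT, provenance="uncut")]

    def ends_at_cut(enz: Enzyme, site: int) -> tuple[StickyEnd, StickyEnd]:
        """(right end of upstream fragment, left end of downstream fragment)."""
        lo, hi = sorted((enz.cut_top, enz.cut_bottom))
        ov = "".join(seq.bases[(site + j) % n] for j in range(lo, hi))
        if enz.polarity == "five_prime":
            return StickyEnd("five_prime", revcomp_str(ov)), StickyEnd("five_prime", ov)
        if enz.polarity == "three_prime":
            return StickyEnd("three_prime", ov), StickyEnd("three_prime", revcomp_str(ov))
        return BLUNT, BLUNT

    ends = [ends_at_cut(enz, site) for _, enz, site in cuts]
    positions = [c[0] for c in cuts]
    frags = []
    if seq.is_circular:
        doubled = seq.bases + seq.bases
        for i in range(len(cuts)):
            j = (i + 1) % len(cuts)
            start = positions[i]
            stop = positions[j] if positions[j] > start else positions[j] + n
            frags.append(
                Fragment(
                    top=doubled[start:stop],
                    left_end=ends[i][1],
                    right_end=ends[j][0],
                    provenance=f"digest[{i}]",
                )
            )
    else:
        bounds = [0] + positions + [n]
        left_ends = [BLUNT] + [e[1] for e in ends]
        right_ends = [e[0] for e in ends] + [BLUNT]
        for i in range(len(bounds) - 1):
            frags.append(
                Fragment(
                    top=seq.bases[bounds[i] : bounds[i + 1]],
                    left_end=left_ends[i],
                    right_end=right_ends[i],
                    provenance=f"digest[{i}]",
                )
            )
    return frags


# ---------------------------------------------------------------------------
# Annealing
# ---------------------------------------------------------------------------


def anneal(top: DnaSeq | str, bottom: DnaSeq | str, name: str = "") -> Fragment:
    """Anneal two oligos into a duplex with typed sticky ends.

    The bottom oligo must be the exact reverse complement of a contiguous
    window of the top oligo (the thermodynamics of slow cooling are modeled
    as exact alignment). An unpaired top-strand prefix becomes a 5' overhang
    on the left end; an unpaired suffix becomes a 3' overhang on the right.
    """
    t = top.bases if isinstance(top, DnaSeq) else str(DnaSeq(top))
    b = bottom.bases if isinstance(bottom, DnaSeq) else str(DnaSeq(bottom))
    window = revcomp_str(b)
    p = t.find(window)
    if p == -1 or len(b) > len(t):
        raise AnnealingError(
            "bottom oligo is not the reverse complement of any contiguous "
            "window of the top oligo"
        )
    left = StickyEnd("five_prime", t[:p]) if p else BLUNT
    tail = t[p + len(window):]
    right = StickyEnd("three_prime", tail) if tail else BLUNT
    return Fragment(top=t, left_end=left, right_end=right, provenance=name or "anneal")


# ---------------------------------------------------------------------------
# Ligation
# ---------------------------------------------------------------------------


def canonical_rotation(s: str) -> str:
    """Lexicographically minimal rotation (circular canonical form)."""
    if not s:
        return s
    doubled = s + s
    return min(doubled[i : i + len(s)] for i in range(len(s)))


def circular_equal(a: str, b: str) -> bool:
    """Circular identity: equality up to rotation (either strand)."""
    return canonical_rotation(a) in (
        canonical_rotation(b),
        canonical_rotation(revcomp_str(b)),
    )


def ligate(fragments: list[Fragment]) -> list[Fragment]:
    """Enumerate distinct circular ligation products.

    Fragments are treated as oriented molecules, each used at most once;
    products closing into a circle (including self-circularization of a
    single fragment whose two ends are mutually compatible) are reported,
    deduplicated up to rotation and strand flip. Reverse-orientation joins
    (head-to-head dimers through palindromic overhangs) are outside the
    model, which targets the intended single-insert product.
    """
    linear = [f for f in fragments if f.topology == "linear"]
    if not linear:
        raise ValueError("ligation needs at least one linear fragment")
    products: list[Fragment] = []
    seen: set[str] = set()
    n = len(linear)
    for size in range(1, n + 1):
        for combo in itertools.permutations(range(n), size):
            if combo[0] != min(combo):  # fix rotation of the fragment order
                continue
            chain = [linear[i] for i in combo]
            ok = all(
                chain[k].right_end.compatible(chain[(k + 1) % size].left_end)
                for k in range(size)
            )
            if not ok:
                continue
            top = "".join(f.top for f in chain)
            key = min(
                canonical_rotation(top),
                canonical_rotation(revcomp_str(top)),
            )
            if key in seen:
                continue
            seen.add(key)
            products.append(
                Fragment(
                    top=top,
                    left_end=None,
                    right_end=None,
                    topology="circular",
                    provenance="+".join(f.provenance or "frag" for f in chain),
                )
            )
    if not products:
        logger.warning(
            "ligation produced no circular product: no mutually compatible ends"
        )
    return products


# ---------------------------------------------------------------------------
# Site screening and the mock vector
# ---------------------------------------------------------------------------


def screen_sites(seq: DnaSeq, enzymes: list[Enzyme | str]) -> pd.DataFrame:
    """Per-enzyme recognition-site hits (both strands; palindromic sites).

    Returns a table with columns enzyme, recognition, offset, strand.
    """
    enzymes = [ENZYMES[e] if isinstance(e, str) else e for e in enzymes]
    rows = []
    for enz in enzymes:
        for hit in find_motif(seq, enz.recognition, both_strands=True):
            rows.append(
                {
                    "enzyme": enz.name,
                    "recognition": enz.recognition,
                    "offset": hit.offset,
                    "strand": hit.strand,
                }
            )
    return pd.DataFrame(rows, columns=["enzyme", "recognition", "offset", "strand"])


def _random_clean_dna(rng: np.random.Generator, length: int, forbidden: list[str]) -> str:
    """Random DNA of given length containing no forbidden motif (rejection)."""
    bases = np.array(list("ACGT"))
    while True:
        s = "".join(rng.choice(bases, size=length))
        if not any(m in s or revcomp_str(m) in s for m in forbidden):
            return s


def make_mock_vector(
    seed: int, stuffer_len: int = 800, backbone_len: int = 2400
) -> tuple[DnaSeq, pd.DataFrame]:
    """A seeded, reproducible circular test plasmid.

    Layout: backbone | GGATCC | stuffer | GGGCCC, circularized. The backbone
    and stuffer are rejection-sampled to be free of BamHI and ApaI sites, so
    the plasmid carries exactly one site per cloning enzyme flanking the
    stuffer. Double digestion releases a stuffer fragment whose top strand
    is ``GATCC + stuffer + GGGCC`` (stuffer_len + 10 nt, of which 4 + 4 nt
    are the unpaired overhangs).

    Returns the circular sequence and an annotation table (feature, start,
    end, strand; 0-based half-open).
    """
    if stuffer_len < 20:
        raise ValueError("stuffer_len must be >= 20")
    rng = np.random.default_rng(seed)
    forbidden = ["GGATCC", "GGGCCC"]
    while True:
        backbone = _random_clean_dna(rng, backbone_len, forbidden)
        stuffer = _random_clean_dna(rng, stuffer_len, forbidden)
        full = backbone + "GGATCC" + stuffer + "GGGCCC"
        vec = DnaSeq(full, topology="circular")
        table = screen_sites(vec, ["BamHI", "ApaI"])
        # junction-spanning sites can sneak in; resample if so
        if len(table) == 2:
            break
    b = backbone_len
    ann = pd.DataFrame(
        [
            ("backbone", 0, b, "+"),
            ("BamHI_site", b, b + 6, "+"),
            ("stuffer", b + 6, b + 6 + stuffer_len, "+"),
            ("ApaI_site", b + 6 + stuffer_len, b + 12 + stuffer_len, "+"),
        ],
        columns=["feature", "start", "end", "strand"],
    )
    return vec, ann


def assemble_construct(
    vector: DnaSeq, top: str, bottom: str, name: str = ""
) -> Fragment:
    """Digest the vector with BamHI + ApaI and ligate in the annealed duplex.

    Returns the single circular construct containing the insert; raises if
    the expected product is not formed.
    """
    frags = digest(vector, ["BamHI", "ApaI"])
    if len(frags) != 2:
        raise ValueError(
            f"vector must have exactly one BamHI and one ApaI site "
            f"(digest gave {len(frags)} fragments)"
        )
    backbone = max(frags, key=len)
    duplex = anneal(top, bottom, name=name)
    products = [
        p for p in ligate([backbone, duplex]) if duplex.core in (p.top + p.top)
        or revcomp_str(duplex.core) in (p.top + p.top)
    ]
    if not products:
        raise ValueError("ligation produced no insert-bearing circular product")
    return products[0]
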
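"""97-nt shRNAmir cassette validation and two-oligo conversion.

A gene-specific shRNAmir produced by the SplashRNA or shERWOOD predictors is
a 97-nt DNA string laid out as::

    flank5 (18 nt) | sense (22 nt) | loop (19 nt) | guide (22 nt) | flank3 (16 nt)
    [0, 18)          [18, 40)        [40, 59)       [59, 81)        [81, 97)

Only the sense-loop-guide core is gene specific; the flanks and the 19-nt
terminal loop are invariant across designs. Cloning into the miR-AB backbone
therefore needs only the core, delivered as an annealed pair of synthetic
oligos: a 75-nt top strand ``GATCC + G + sense + loop + guide + T + GGGCC``
and a 67-nt bottom strand that is the reverse complement of ``top[4:71]``.
Annealing leaves a 4-nt 5' GATC overhang (BamHI-compatible) at the top
strand's 5' end and a 4-nt 3' GGCC overhang (ApaI-compatible) at its 3' end,
so the duplex drops directly into a BamHI/ApaI-cut vector.

The layout constants below were derived by parsing every bundled oligo pair
and confirming a single consensus; the bundled table is the ground truth and
the regeneration test enforces character-for-character agreement.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .seqcore import AlphabetError, DnaSeq, RecordError, revcomp_str, _normalize

__all__ = [
    "CANONICAL_LOOP",
    "CANONICAL_FLANK5",
    "CANONICAL_FLANK3",
    "TOP_PREFIX",
    "TOP_SUFFIX",
    "ShRNAmirCassette",
    "OligoPair",
    "Issue",
    "ValidationReport",
    "LayoutError",
    "validate_97",
    "design_oligos",
    "parse_oligos",
    "reconstruct_97",
    "batch_design",
    "load_bundled_oligos",
    "read_oligo_table",
    "write_oligo_table",
]

# Invariant constants of the miR-AB layout (consensus of all bundled pairs).
CANONICAL_LOOP = "TAGTGAAGCCACAGATGTA"
CANONICAL_FLANK5 = "TGCTGTTGACAGTGAGCG"
CANONICAL_FLANK3 = "TGCCTACTGCCTCGGA"
TOP_PREFIX = "GATCCG"
TOP_SUFFIX = "TGGGCC"

# 0-based half-open regions of the 97-mer.
FLANK5_SLICE = slice(0, 18)
SENSE_SLICE = slice(18, 40)
LOOP_SLICE = slice(40, 59)
GUIDE_SLICE = slice(59, 81)
FLANK3_SLICE = slice(81, 97)

# Regions of the 75-nt top oligo.
TOP_SENSE = slice(6, 28)
TOP_LOOP = slice(28, 47)
TOP_GUIDE = slice(47, 69)
BOTTOM_WINDOW = slice(4, 71)  # bottom == revcomp(top[4:71])


class LayoutError(ValueError):
    """An oligo pair violates the fixed miR-AB layout."""


@dataclass(frozen=True)
class ShRNAmirCassette:
    """A parsed 97-nt shRNAmir record."""

    flank5: str
    sense: str
    loop: str
    guide: str
    flank3: str
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for attr, want in (("sense", 22), ("guide", 22), ("loop", 19)):
            got = len(getattr(self, attr))
            if got != want:
                raise ValueError(f"{attr} must be {want} nt, got {got}")
        if len(self.flank5) + len(self.flank3) != 34:
            raise ValueError("flanks must total 34 nt for a 97-nt cassette")

    @property
    def core(self) -> str:
        """The gene-specific sense-loop-guide core (63 nt)."""
        return self.sense + self.loop + self.guide


@dataclass(frozen=True)
class OligoPair:
    """The 75-nt top and 67-nt bottom synthesis oligos for one cassette."""

    top: str
    bottom: str
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(self.top) != 75:
            raise ValueError(f"top oligo must be 75 nt, got {len(self.top)}")
        if len(self.bottom) != 67:
            raise ValueError(f"bottom oligo must be 67 nt, got {len(self.bottom)}")


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    position: int | None = None


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def add(self, severity: str, code: str, message: str, position: int | None = None):
        self.issues.append(Issue(severity, code, message, position))


def validate_97(
    seq: DnaSeq | str, mode: str = "strict", name: str = ""
) -> tuple[ValidationReport, ShRNAmirCassette | None]:
    """Validate a candidate 97-nt shRNAmir input and parse it.

    Lenient mode errors only on length != 97 or a bad alphabet (the
    documented behaviour of the original converter). Strict mode (default)
    additionally requires the canonical 19-nt loop at positions [40, 59) and
    warns if the region [18, 81) contains an internal GGATCC or GGGCCC,
    which would be cut during cloning.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    report = ValidationReport()
    try:
        bases = seq.bases if isinstance(seq, DnaSeq) else _normalize(seq)
    except AlphabetError as exc:
        report.add("error", "alphabet", str(exc))
        return report, None
    if len(bases) != 97:
        report.add("error", "length", f"expected 97 nt, got {len(bases)}")
        return report, None
    if mode == "strict":
        loop = bases[LOOP_SLICE]
        if loop != CANONICAL_LOOP:
            report.add(
                "error",
                "loop",
                f"loop region [40,59) is {loop}, expected {CANONICAL_LOOP}",
                position=40,
            )
        core_region = bases[18:81]
        for site in ("GGATCC", "GGGCCC"):
            pos = core_region.find(site)
            if pos != -1:
                report.add(
                    "warning",
                    "internal_site",
                    f"internal {site} at position {18 + pos} conflicts with cloning",
                    position=18 + pos,
                )
    if not report.ok:
        return report, None
    cassette = ShRNAmirCassette(
        flank5=bases[FLANK5_SLICE],
        sense=bases[SENSE_SLICE],
        loop=bases[LOOP_SLICE],
        guide=bases[GUIDE_SLICE],
        flank3=bases[FLANK3_SLICE],
        name=name,
    )
    return report, cassette


def design_oligos(cassette: ShRNAmirCassette) -> OligoPair:
    """Convert a cassette into its 75/67-nt synthesis oligo pair."""
    top = "GATCC" + "G" + cassette.sense + cassette.loop + cassette.guide + "T" + "GGGCC"
    bottom = revcomp_str(top[BOTTOM_WINDOW])
    return OligoPair(top=top, bottom=bottom, name=cassette.name)


def parse_oligos(pair: OligoPair) -> ShRNAmirCassette:
    """Invert the oligo conversion, recovering the cassette.

    The flanks are filled with the canonical constants: the oligos do not
    encode them, so this is canonical-flank reconstruction, not recovery of
    the user's original flanks. Raises :class:`LayoutError` on a layout or
    strand-consistency violation.
    """
    top, bottom = pair.top, pair.bottom
    if not top.startswith("GATCC") or top[:6] != TOP_PREFIX:
        raise LayoutError(f"top oligo must start with {TOP_PREFIX!r}, got {top[:6]!r}")
    if not top.endswith("GGGCC") or top[69:] != TOP_SUFFIX:
        raise LayoutError(f"top oligo must end with {TOP_SUFFIX!r}, got {top[69:]!r}")
    expected_bottom = revcomp_str(top[BOTTOM_WINDOW])
    if bottom != expected_bottom:
        mismatch = next(
            i for i, (a, b) in enumerate(zip(bottom, expected_bottom)) if a != b
        )
        raise LayoutError(
            f"bottom oligo is not revcomp(top[4:71]); first mismatch at "
            f"bottom position {mismatch}"
        )
    return ShRNAmirCassette(
        flank5=CANONICAL_FLANK5,
        sense=top[TOP_SENSE],
        loop=top[TOP_LOOP],
        guide=top[TOP_GUIDE],
        flank3=CANONICAL_FLANK3,
        name=pair.name,
    )


def reconstruct_97(cassette: ShRNAmirCassette) -> DnaSeq:
    """Rebuild the 97-nt input sequence from a cassette."""
    return DnaSeq(
        cassette.flank5 + cassette.sense + cassette.loop + cassette.guide + cassette.flank3
    )


def batch_design(
    records: list[tuple[str, DnaSeq]], mode: str = "strict"
) -> list[dict]:
    """Convert many 97-nt inputs; one output row per input.

    Failures carry a status and message instead of raising, so a single bad
    record does not abort a batch (the original tool converts up to 1,000
    sequences per sheet; there is no such cap here).
    """
    rows = []
    for name, seq in records:
        report, cassette = validate_97(seq, mode=mode, name=name)
        if cassette is None:
            msg = "; ".join(i.message for i in report.issues if i.severity == "error")
            rows.append(
                {"name": name, "top": "", "bottom": "", "status": "error", "message": msg}
            )
            continue
        pair = design_oligos(cassette)
        msg = "; ".join(i.message for i in report.issues)
        rows.append(
            {
                "name": name,
                "top": pair.top,
                "bottom": pair.bottom,
                "status": "ok",
                "message": msg,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Oligo-pair TSV I/O (columns: name, top, bottom; extra columns preserved on
# read, ignored otherwise) and the bundled ground-truth table.
# ---------------------------------------------------------------------------


def read_oligo_table(path: str | Path) -> list[OligoPair]:
    """Read oligo pairs from a TSV with columns name/top/bottom."""
    with open(path, newline="") as fh:
        rows = [
            r
            for r in csv.reader(fh, delimiter="\t")
            if r and any(r) and not r[0].startswith("#")
        ]
    if not rows:
        raise RecordError(f"no rows in {path}")
    header = [h.strip().lower() for h in rows[0]]
    if "top" in header and "name" in header:
        idx = {k: header.index(k) for k in ("name", "top", "bottom")}
        rows = rows[1:]
    else:
        idx = {"name": 0, "top": 1, "bottom": 2}
    pairs = []
    for row in rows:
        pairs.append(
            OligoPair(
                top=_normalize(row[idx["top"]]),
                bottom=_normalize(row[idx["bottom"]]),
                name=row[idx["name"]].strip(),
            )
        )
    return pairs


def write_oligo_table(
    path: str | Path, rows: list[dict], header: str | None = None
) -> None:
    """Write batch_design output rows as TSV."""
    with open(path, "w", newline="") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        w = csv.DictWriter(
            fh,
            fieldnames=["name", "top", "bottom", "status", "message"],
            delimiter="\t",
            lineterminator="\n",
        )
        w.writeheader()
        w.writerows(rows)


def load_bundled_oligos() -> list[OligoPair]:
    """The bundled ground-truth oligo table (one pair per published shRNAmir)."""
    ref = resources.files("mirab").joinpath("data/table2_oligos.tsv")
    with resources.as_file(ref) as path:
        return read_oligo_table(path)
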
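"""Fluorescent-label panel planning by channel-exclusive assignment.

The distinguishability model is channel exclusivity: a detection channel is
one (laser, band-pass filter) slot, and two labels conflict iff they would
be forced into the same channel on the given instrument. A panel is
feasible iff a perfect matching exists in the bipartite graph between
labels and the instrument's channels, restricted to each label's usable
channels. When infeasible, a minimal Hall-violator witness is returned: a
smallest label subset whose joint usable channels number fewer than the
subset. Spectral overlap and spillover are out of scope — the guidance this
reproduces is channel-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import yaml

__all__ = [
    "Channel",
    "LabelSpec",
    "Instrument",
    "ChannelAssignment",
    "INSTRUMENT_PRESETS",
    "load_channel_table",
    "get_label",
    "feasible_assignment",
    "enumerate_populations",
    "population_label",
]


@dataclass(frozen=True)
class Channel:
    laser_nm: int
    filter: str

    def __str__(self) -> str:
        return f"{self.laser_nm}nm/{self.filter}"


@dataclass(frozen=True)
class LabelSpec:
    name: str
    usable_channels: tuple[Channel, ...]
    kind: str = "reporter"  # "reporter" | "antibody_fluorophore"

    def __post_init__(self) -> None:
        if not self.usable_channels:
            raise ValueError(f"label {self.name!r} has no usable channels")


@dataclass(frozen=True)
class Instrument:
    name: str
    lasers: tuple[int, ...]
    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        bad = [c for c in self.channels if c.laser_nm not in self.lasers]
        if bad:
            raise ValueError(f"channels on uninstalled lasers: {bad}")


@dataclass
class ChannelAssignment:
    mapping: dict[str, Channel]
    feasible: bool
    conflict_set: list[str] = field(default_factory=list)


def _load_fixture() -> dict:
    ref = resources.files("mirab").joinpath("data/channel_map.yaml")
    with resources.as_file(ref) as path:
        with open(path) as fh:
            return yaml.safe_load(fh)


_ALIASES: dict[str, str] = {}


def load_channel_table() -> list[LabelSpec]:
    """All labels (8 reporters + equivalent antibody fluorophores)."""
    data = _load_fixture()
    labels: list[LabelSpec] = []
    by_name: dict[str, LabelSpec] = {}
    for rep in data["reporters"]:
        chans = tuple(Channel(c["laser_nm"], c["filter"]) for c in rep["channels"])
        spec = LabelSpec(rep["name"], chans, kind="reporter")
        labels.append(spec)
        by_name[spec.name] = spec
        for alias in rep.get("aliases", []):
            _ALIASES[alias] = rep["name"]
    for fl in data["fluorophores"]:
        like = by_name[fl["like"]]
        chans = like.usable_channels
        if "lasers" in fl:
            chans = tuple(c for c in chans if c.laser_nm in fl["lasers"])
        labels.append(LabelSpec(fl["name"], chans, kind="antibody_fluorophore"))
    return labels


def get_label(name: str) -> LabelSpec:
    """Look up a label by name (aliases such as GFP -> EGFP resolve)."""
    table = load_channel_table()
    target = _ALIASES.get(name, name)
    for spec in table:
        if spec.name == target:
            return spec
    raise KeyError(f"unknown label {name!r}")


def _all_channels() -> tuple[Channel, ...]:
    chans: list[Channel] = []
    for spec in load_channel_table():
        for c in spec.usable_channels:
            if c not in chans:
                chans.append(c)
    return tuple(chans)


def _make_instrument(name: str, lasers: tuple[int, ...]) -> Instrument:
    chans = tuple(c for c in _all_channels() if c.laser_nm in lasers)
    return Instrument(name, lasers, chans)


#: "4laser" is the standard four-laser configuration (405/488/561/633 nm);
#: "5laser" adds the 355 nm UV line. Both descriptions appear in the source
#: documentation of the instrument; neither is canonical, so both ship.
INSTRUMENT_PRESETS: dict[str, Instrument] = {}


def get_instrument(preset: str) -> Instrument:
    if not INSTRUMENT_PRESETS:
        INSTRUMENT_PRESETS["4laser"] = _make_instrument("4laser", (405, 488, 561, 633))
        INSTRUMENT_PRESETS["5laser"] = _make_instrument(
            "5laser", (355, 405, 488, 561, 633)
        )
    try:
        return INSTRUMENT_PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown instrument preset {preset!r}; "
            f"available: {sorted(INSTRUMENT_PRESETS)}"
        ) from None


def feasible_assignment(
    labels: list[LabelSpec], instrument: Instrument
) -> ChannelAssignment:
    """Injective label -> channel assignment via maximum bipartite matching.

    Feasible iff a perfect matching over the labels exists. When infeasible,
    ``conflict_set`` is a minimal Hall violator: a smallest label subset S
    with fewer joint usable channels than |S| (a label with no channel on
    the instrument is a singleton violator).
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    names = [l.name for l in labels]
    if len(set(names)) != len(names):
        raise ValueError("duplicate label names")
    usable = {
        l.name: [c for c in l.usable_channels if c in instrument.channels]
        for l in labels
    }
    g = nx.Graph()
    g.add_nodes_from(names, bipartite=0)
    chan_nodes = {c: ("chan", c) for cs in usable.values() for c in cs}
    g.add_nodes_from(chan_nodes.values(), bipartite=1)
    for name, cs in usable.items():
        for c in cs:
            g.add_edge(name, chan_nodes[c])
    matching = nx.algorithms.bipartite.maximum_matching(g, top_nodes=set(names))
    mapping = {n: matching[n][1] for n in names if n in matching}
    if len(mapping) == len(names):
        return ChannelAssignment(mapping=mapping, feasible=True)
    # minimal Hall violator by exhaustive subset search (few labels)
    for size in range(1, len(names) + 1):
        for subset in itertools.combinations(names, size):
            joint = set().union(*(usable[n] for n in subset))
            if len(joint) < size:
                return ChannelAssignment(
                    mapping={}, feasible=False, conflict_set=list(subset)
                )
    raise AssertionError("imperfect matching implies a Hall violator")


def population_label(reporters: list[str], present: tuple[bool, ...] | list[bool]) -> str:
    names = [r for r, p in zip(reporters, present) if p]
    return "+".join(names) + "+" if names else "none"


def enumerate_populations(reporters: list[str]) -> list[str]:
    """All 2^n presence/absence barcode populations in canonical order.

    Ordered by number of positive reporters (none first, all-positive
    last); within a stratum, combinations follow the input reporter order.
    """
    n = len(reporters)
    if not 1 <= n <= 8:
        raise ValueError("between 1 and 8 reporters supported")
    if len(set(reporters)) != n:
        raise ValueError("duplicate reporter names")
    out = []
    for k in range(n + 1):
        for combo in itertools.combinations(range(n), k):
            present = tuple(i in combo for i in range(n))
            out.append(population_label(reporters, present))
    return out
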
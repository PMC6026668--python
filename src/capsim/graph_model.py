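"""Neurite-network data model, validation, synthetic generators and file I/O.

A network is a directed multigraph of membrane *segments* joining typed
*nodes*.  Segment direction fixes the forward propagation sense at
junctions, but pulses may traverse a segment in either direction (a
stimulus applied at a segment's target end launches an antidromic pulse,
which is what head-on collision experiments rely on).

Units follow neurophysiology convention: lengths and channel spacings in
micrometres, conduction velocities in metres per second, times in seconds
(the native file format stores refractory durations in milliseconds for
readability).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "NodeRole",
    "StimulusLabel",
    "MembraneDynamics",
    "Node",
    "Segment",
    "NeuriteGraph",
    "Stimulus",
    "StimulusSchedule",
    "GraphFormatError",
    "GraphValidationError",
    "generate_ladder",
    "generate_binary_tree",
    "generate_collision_edge",
    "validate_graph",
    "read_graph",
    "write_graph",
    "read_stimuli",
    "write_stimuli",
]

UM_PER_M = 1e6


class GraphFormatError(ValueError):
    """Raised when a graph or stimulus file cannot be parsed."""


class GraphValidationError(ValueError):
    """Raised when a graph violates structural invariants."""


class NodeRole(str, Enum):
    ENTRY = "ENTRY"
    BRANCH = "BRANCH"
    CONVERGE = "CONVERGE"
    TERMINAL = "TERMINAL"
    PASS = "PASS"


class StimulusLabel(str, Enum):
    SIGNAL = "SIGNAL"
    NOISE = "NOISE"


@dataclass(frozen=True)
class MembraneDynamics:
    """Local transmission dynamics of a membrane segment.

    velocity_m_per_s
        Conduction speed of the threshold front.  The default 1.0 m/s is
        the canonical unmyelinated maximum.
    refractory_s
        Length of the analog refractory tail trailing the front.
    channel_spacing_um
        Distance between adjacent ion channels; spacing / velocity sets the
        temporal accuracy of phase comparisons (about 1 us at defaults).
    dissipation_per_um
        Soliton energy lost per micrometre travelled (arbitrary energy
        units).  Zero by default, making energy bookkeeping inert.
    activation_threshold
        Minimum residual energy needed to trigger the next channel on
        entering a segment; a pulse below it fails to propagate.
    """

    velocity_m_per_s: float = 1.0
    refractory_s: float = 2e-3
    channel_spacing_um: float = 1.5
    dissipation_per_um: float = 0.0
    activation_threshold: float = 0.0
    myelinated: bool = False

    def __post_init__(self) -> None:
        if self.velocity_m_per_s <= 0:
            raise GraphValidationError("velocity must be > 0")
        if self.refractory_s < 0:
            raise GraphValidationError("refractory duration must be >= 0")
        if self.channel_spacing_um <= 0:
            raise GraphValidationError("channel spacing must be > 0")
        if self.dissipation_per_um < 0:
            raise GraphValidationError("dissipation rate must be >= 0")
        if self.activation_threshold < 0:
            raise GraphValidationError("activation threshold must be >= 0")

    @property
    def velocity_um_per_s(self) -> float:
        return self.velocity_m_per_s * UM_PER_M

    @property
    def temporal_accuracy_s(self) -> float:
        """Channel spacing divided by velocity: the phase-comparison grain."""
        return self.channel_spacing_um * 1e-6 / self.velocity_m_per_s


@dataclass(frozen=True)
class Node:
    id: str
    role: NodeRole = NodeRole.PASS


@dataclass(frozen=True)
class Segment:
    id: str
    source: str
    target: str
    length_um: float
    dynamics: MembraneDynamics = field(default_factory=MembraneDynamics)

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise GraphValidationError(
                f"segment {self.id!r}: length must be > 0, got {self.length_um}"
            )

    @property
    def transit_time_s(self) -> float:
        return self.length_um / self.dynamics.velocity_um_per_s

    def other_end(self, node_id: str) -> str:
        if node_id == self.source:
            return self.target
        if node_id == self.target:
            return self.source
        raise KeyError(f"node {node_id!r} is not an endpoint of segment {self.id!r}")


class NeuriteGraph:
    """Directed multigraph of membrane segments between typed nodes."""

    def __init__(
        self,
        nodes: Iterable[Node] = (),
        segments: Iterable[Segment] = (),
        meta: dict | None = None,
    ) -> None:
        self.nodes: dict[str, Node] = {}
        self.segments: dict[str, Segment] = {}
        self.meta: dict = dict(meta or {})
        for n in nodes:
            self.add_node(n)
        for s in segments:
            self.add_segment(s)

    def add_node(self, node: Node) -> None:
        if node.id in self.nodes:
            raise GraphValidationError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node

    def add_segment(self, seg: Segment) -> None:
        if seg.id in self.segments:
            raise GraphValidationError(f"duplicate segment id {seg.id!r}")
        self.segments[seg.id] = seg

    # -- topology helpers -------------------------------------------------

    def incident(self, node_id: str) -> list[Segment]:
        return [
            s for s in self.segments.values() if node_id in (s.source, s.target)
        ]

    def out_segments(self, node_id: str) -> list[Segment]:
        """Segments directed away from the node (forward continuations)."""
        return [s for s in self.segments.values() if s.source == node_id]

    def in_segments(self, node_id: str) -> list[Segment]:
        return [s for s in self.segments.values() if s.target == node_id]

    def entry_nodes(self) -> list[str]:
        return sorted(
            n.id for n in self.nodes.values() if n.role is NodeRole.ENTRY
        )

    def terminal_nodes(self) -> list[str]:
        return sorted(
            n.id for n in self.nodes.values() if n.role is NodeRole.TERMINAL
        )

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, role=n.role.value)
        for s in self.segments.values():
            g.add_edge(s.source, s.target, key=s.id, length_um=s.length_um)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NeuriteGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.segments == other.segments

    def __repr__(self) -> str:
        return (
            f"NeuriteGraph({len(self.nodes)} nodes, {len(self.segments)} segments)"
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "neurite-graph",
            "version": 1,
            "meta": self.meta,
            "nodes": [
                {"id": n.id, "role": n.role.value}
                for n in sorted(self.nodes.values(), key=lambda n: n.id)
            ],
            "segments": [
                {
                    "id": s.id,
                    "source": s.source,
                    "target": s.target,
                    "length_um": s.length_um,
                    "velocity_m_per_s": s.dynamics.velocity_m_per_s,
                    "refractory_ms": s.dynamics.refractory_s * 1e3,
                    "channel_spacing_um": s.dynamics.channel_spacing_um,
                    "dissipation_per_um": s.dynamics.dissipation_per_um,
                    "activation_threshold": s.dynamics.activation_threshold,
                    "myelinated": s.dynamics.myelinated,
                }
                for s in sorted(self.segments.values(), key=lambda s: s.id)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuriteGraph":
        try:
            nodes = [Node(str(n["id"]), NodeRole(n["role"])) for n in d["nodes"]]
            segments = [
                Segment(
                    id=str(s["id"]),
                    source=str(s["source"]),
                    target=str(s["target"]),
                    length_um=float(s["length_um"]),
                    dynamics=MembraneDynamics(
                        velocity_m_per_s=float(s.get("velocity_m_per_s", 1.0)),
                        refractory_s=float(s.get("refractory_ms", 2.0)) * 1e-3,
                        channel_spacing_um=float(s.get("channel_spacing_um", 1.5)),
                        dissipation_per_um=float(s.get("dissipation_per_um", 0.0)),
                        activation_threshold=float(s.get("activation_threshold", 0.0)),
                        myelinated=bool(s.get("myelinated", False)),
                    ),
                )
                for s in d["segments"]
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise GraphFormatError(f"malformed graph document: {exc}") from exc
        return cls(nodes, segments, meta=d.get("meta"))


# -- validation ------------------------------------------------------------


def validate_graph(g: NeuriteGraph, include_warnings: bool = True) -> list[str]:
    """Return one diagnostic string per invariant violation (empty = valid).

    Errors (prefixed ``error:``) are invariant violations; warnings
    (prefixed ``warning:``) flag role annotations that disagree with the
    local topology, since roles are annotations rather than constraints.
    """
    diags: list[str] = []
    for s in g.segments.values():
        for end in (s.source, s.target):
            if end not in g.nodes:
                diags.append(
                    f"error: segment {s.id!r} references missing node {end!r}"
                )
    if g.nodes:
        undirected = nx.Graph()
        undirected.add_nodes_from(g.nodes)
        for s in g.segments.values():
            if s.source in g.nodes and s.target in g.nodes:
                undirected.add_edge(s.source, s.target)
        if not nx.is_connected(undirected):
            n_comp = nx.number_connected_components(undirected)
            diags.append(
                f"error: graph is disconnected ({n_comp} components)"
            )
    for n in g.nodes.values():
        deg = len(g.incident(n.id))
        n_out = len(g.out_segments(n.id))
        n_in = len(g.in_segments(n.id))
        if n.role is NodeRole.ENTRY and deg < 1:
            diags.append(f"error: ENTRY node {n.id!r} has no incident segment")
        if n.role is NodeRole.TERMINAL and deg < 1:
            diags.append(f"error: TERMINAL node {n.id!r} has no incident segment")
        if include_warnings:
            if n.role is NodeRole.BRANCH and n_out < 2:
                diags.append(
                    f"warning: BRANCH node {n.id!r} has out-degree {n_out} < 2"
                )
            if n.role is NodeRole.CONVERGE and n_in < 2:
                diags.append(
                    f"warning: CONVERGE node {n.id!r} has in-degree {n_in} < 2"
                )
    return diags


def require_valid(g: NeuriteGraph) -> None:
    errors = [d for d in validate_graph(g) if d.startswith("error:")]
    if errors:
        raise GraphValidationError("; ".join(errors))


# -- synthetic generators --------------------------------------------------


def generate_ladder(
    n_layers: int,
    n_parallel: int,
    segment_length_um: float = 100.0,
    dynamics: MembraneDynamics | None = None,
    jitter_sd_um: float = 0.0,
    seed: int | None = None,
) -> NeuriteGraph:
    """Parallel-ladder motif: one ENTRY fanning into ``n_parallel`` equal
    paths that re-converge at each of ``n_layers`` CONVERGE nodes, then a
    single connector to one TERMINAL.

    Node count is ``n_layers + 2``; segment count is
    ``n_layers * n_parallel + 1`` (the final connector).  With
    ``jitter_sd_um > 0`` each parallel segment length is perturbed by
    seeded Gaussian noise, clamped positive.
    """
    if n_layers < 1:
        raise GraphValidationError("n_layers must be >= 1")
    if n_parallel < 1:
        raise GraphValidationError("n_parallel must be >= 1")
    if segment_length_um <= 0:
        raise GraphValidationError("segment_length_um must be > 0")
    if jitter_sd_um < 0:
        raise GraphValidationError("jitter_sd_um must be >= 0")
    dyn = dynamics or MembraneDynamics()
    rng = np.random.default_rng(seed)

    nodes = [Node("entry", NodeRole.ENTRY)]
    nodes += [Node(f"conv{i}", NodeRole.CONVERGE) for i in range(1, n_layers + 1)]
    nodes.append(Node("term", NodeRole.TERMINAL))

    def jittered() -> float:
        if jitter_sd_um == 0:
            return segment_length_um
        length = segment_length_um + rng.normal(0.0, jitter_sd_um)
        return max(length, 1e-3)

    segments = []
    prev = "entry"
    for layer in range(1, n_layers + 1):
        nxt = f"conv{layer}"
        for j in range(1, n_parallel + 1):
            segments.append(
                Segment(f"L{layer}P{j}", prev, nxt, jittered(), dyn)
            )
        prev = nxt
    segments.append(Segment("out", prev, "term", segment_length_um, dyn))

    meta = {
        "generator": "ladder",
        "n_layers": n_layers,
        "n_parallel": n_parallel,
        "segment_length_um": segment_length_um,
        "jitter_sd_um": jitter_sd_um,
        "seed": seed,
    }
    return NeuriteGraph(nodes, segments, meta=meta)


def generate_binary_tree(
    depth: int,
    segment_length_um: float = 100.0,
    dynamics: MembraneDynamics | None = None,
    branching: int = 2,
) -> NeuriteGraph:
    """Rooted fan-out tree: ENTRY root, BRANCH interior nodes, TERMINAL leaves."""
    if depth < 1:
        raise GraphValidationError("depth must be >= 1")
    if branching < 2:
        raise GraphValidationError("branching must be >= 2")
    if segment_length_um <= 0:
        raise GraphValidationError("segment_length_um must be > 0")
    dyn = dynamics or MembraneDynamics()
    nodes = [Node("root", NodeRole.ENTRY)]
    segments = []
    frontier = ["root"]
    for level in range(1, depth + 1):
        role = NodeRole.TERMINAL if level == depth else NodeRole.BRANCH
        nxt_frontier = []
        for parent in frontier:
            for b in range(branching):
                child = f"{parent}.{b}" if parent != "root" else f"n{b}"
                nodes.append(Node(child, role))
                segments.append(
                    Segment(f"s:{parent}->{child}", parent, child,
                            segment_length_um, dyn)
                )
                nxt_frontier.append(child)
        frontier = nxt_frontier
    meta = {"generator": "tree", "depth": depth, "branching": branching,
            "segment_length_um": segment_length_um}
    return NeuriteGraph(nodes, segments, meta=meta)


def generate_collision_edge(
    length_um: float = 100.0,
    dynamics: MembraneDynamics | None = None,
) -> NeuriteGraph:
    """Single segment with an ENTRY node at each end, for head-on collisions."""
    if length_um <= 0:
        raise GraphValidationError("length_um must be > 0")
    dyn = dynamics or MembraneDynamics()
    nodes = [Node("A", NodeRole.ENTRY), Node("B", NodeRole.ENTRY)]
    segments = [Segment("edge", "A", "B", length_um, dyn)]
    return NeuriteGraph(nodes, segments,
                        meta={"generator": "collision-edge",
                              "length_um": length_um})


# -- native JSON + SWC I/O -------------------------------------------------


def write_graph(g: NeuriteGraph, path: str | Path) -> None:
    """Write the canonical native-JSON form (sorted keys, stable floats)."""
    text = json.dumps(g.to_dict(), sort_keys=True, indent=2)
    Path(path).write_text(text + "\n")


def read_graph(g_path: str | Path, fmt: str | None = None) -> NeuriteGraph:
    path = Path(g_path)
    if fmt is None:
        fmt = "swc" if path.suffix.lower() == ".swc" else "native-json"
    if fmt == "swc":
        return _read_swc(path)
    if fmt == "native-json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise GraphFormatError(
                f"{path}: JSON parse error at line {exc.lineno}: {exc.msg}"
            ) from exc
        return NeuriteGraph.from_dict(doc)
    raise ValueError(f"unknown graph format {fmt!r}")


def _read_swc(path: Path) -> NeuriteGraph:
    """Import a 7-column SWC morphology (id type x y z radius parent).

    Coordinates are micrometres; each parent link becomes one segment whose
    length is the Euclidean distance between the two sample points.  Radius
    is ignored — conduction velocity is a segment parameter here, not a
    function of calibre.  Default membrane dynamics are assigned.
    """
    samples: dict[int, tuple[float, float, float, int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 7:
            raise GraphFormatError(
                f"{path}: line {lineno}: expected 7 SWC columns, got {len(cols)}"
            )
        try:
            sid = int(cols[0])
            x, y, z = float(cols[2]), float(cols[3]), float(cols[4])
            parent = int(cols[6])
        except ValueError as exc:
            raise GraphFormatError(
                f"{path}: line {lineno}: {exc}"
            ) from exc
        if sid in samples:
            raise GraphFormatError(f"{path}: line {lineno}: duplicate id {sid}")
        samples[sid] = (x, y, z, parent)

    if not samples:
        raise GraphFormatError(f"{path}: empty SWC file")
    for sid, (_, _, _, parent) in samples.items():
        if parent != -1 and parent not in samples:
            raise GraphValidationError(
                f"SWC sample {sid} has orphan parent {parent}"
            )
    # cycle check: walk parent chains
    for sid in samples:
        seen = set()
        cur = sid
        while cur != -1:
            if cur in seen:
                raise GraphValidationError(f"SWC parent cycle involving {sid}")
            seen.add(cur)
            cur = samples[cur][3]

    children: dict[int, int] = {sid: 0 for sid in samples}
    for sid, (_, _, _, parent) in samples.items():
        if parent != -1:
            children[parent] += 1

    nodes = []
    for sid, (_, _, _, parent) in sorted(samples.items()):
        if parent == -1:
            role = NodeRole.ENTRY
        elif children[sid] == 0:
            role = NodeRole.TERMINAL
        elif children[sid] >= 2:
            role = NodeRole.BRANCH
        else:
            role = NodeRole.PASS
        nodes.append(Node(str(sid), role))

    segments = []
    for sid, (x, y, z, parent) in sorted(samples.items()):
        if parent == -1:
            continue
        px, py, pz, _ = samples[parent]
        length = math.dist((px, py, pz), (x, y, z))
        if length <= 0:
            raise GraphValidationError(
                f"SWC samples {parent} and {sid} are coincident"
            )
        segments.append(Segment(f"swc:{parent}-{sid}", str(parent), str(sid), length))
    return NeuriteGraph(nodes, segments, meta={"source": "swc"})


# -- stimulus schedules ----------------------------------------------------


@dataclass(frozen=True, order=True)
class Stimulus:
    time_s: float
    node_id: str
    label: StimulusLabel = StimulusLabel.SIGNAL

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise GraphValidationError("stimulus time must be >= 0")


@dataclass
class StimulusSchedule:
    stimuli: list[Stimulus] = field(default_factory=list)

    def sorted(self) -> "StimulusSchedule":
        return StimulusSchedule(sorted(self.stimuli))

    def validate_against(self, g: NeuriteGraph) -> None:
        for st in self.stimuli:
            node = g.nodes.get(st.node_id)
            if node is None:
                raise GraphValidationError(
                    f"stimulus targets unknown node {st.node_id!r}"
                )
            if node.role is not NodeRole.ENTRY:
                raise GraphValidationError(
                    f"stimulus targets non-ENTRY node {st.node_id!r}"
                )

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)


def write_stimuli(schedule: StimulusSchedule, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "time_s", "label"])
        for st in schedule.sorted():
            writer.writerow([st.node_id, repr(st.time_s), st.label.value])


def read_stimuli(path: str | Path) -> StimulusSchedule:
    stimuli = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["node_id", "time_s", "label"]:
            raise GraphFormatError(
                f"{path}: line 1: expected header node_id,time_s,label"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise GraphFormatError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(row)}"
                )
            try:
                stimuli.append(
                    Stimulus(float(row[1]), row[0].strip(),
                             StimulusLabel(row[2].strip()))
                )
            except ValueError as exc:
                raise GraphFormatError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    return StimulusSchedule(stimuli)
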
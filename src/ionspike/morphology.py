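"""Neuron morphologies: SWC I/O, validation, synthesis, and synapse-site sampling.

A morphology is a tree of 3D points with radii; consecutive points define
cylindrical *segments*.  Synapse sites are sampled on dendritic segments
either uniformly across the whole tree ("distributed" input) or within a
spherical neighbourhood of a random centre segment ("localized" input,
mimicking in-vivo synaptic clustering on a dendritic branch).

SWC conventions: 7 whitespace-separated columns
``id type x y z radius parent``, ``#`` comments, type codes
1=soma, 2=axon, 3=basal dendrite, 4=apical dendrite, other codes map to
``other``.  Multiple soma contour rows are collapsed into a single root
node (centroid position, mean radius), a common dialect decision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: SWC integer type code -> tag
SWC_TYPE_TAGS = {1: "soma", 2: "axon", 3: "basal_dendrite", 4: "apical_dendrite"}
TAG_SWC_TYPES = {v: k for k, v in SWC_TYPE_TAGS.items()}
TAG_SWC_TYPES["other"] = 5

DENDRITE_TAGS = frozenset({"basal_dendrite", "apical_dendrite"})


class MorphologyFormatError(ValueError):
    """Malformed SWC content (bad columns, orphan parent, duplicate id)."""


class MorphologyStructureError(ValueError):
    """Structurally invalid tree (cycle, disconnection, bad geometry)."""


@dataclass(frozen=True)
class Node:
    id: int
    type_tag: str
    x: float
    y: float
    z: float
    radius: float
    parent_id: int | None

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class Segment:
    """Cylinder between a proximal and a distal node (ids into the node table)."""

    segment_id: int
    proximal: int
    distal: int


@dataclass(frozen=True)
class SynapseSite:
    segment_id: int
    arc_fraction: float  # 0 at proximal node, 1 at distal node
    position: tuple[float, float, float]


class Morphology:
    """Validated tree of typed nodes; segments join each non-root node to its parent."""

    def __init__(self, nodes: list[Node]):
        self.nodes: dict[int, Node] = {n.id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise MorphologyFormatError("duplicate node ids")
        self._validate()
        self.segments: list[Segment] = []
        for n in nodes:
            if n.parent_id is None:
                continue
            self.segments.append(
                Segment(segment_id=len(self.segments), proximal=n.parent_id, distal=n.id)
            )
        for seg in self.segments:
            if self.segment_length(seg.segment_id) <= 0.0:
                raise MorphologyStructureError(
                    f"segment {seg.segment_id} has non-positive length"
                )

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise MorphologyStructureError(f"expected exactly one root, found {len(roots)}")
        for n in self.nodes.values():
            if n.radius <= 0.0:
                raise ValueError(f"node {n.id}: non-positive radius {n.radius}")
            if n.parent_id is not None:
                if n.parent_id not in self.nodes:
                    raise MorphologyFormatError(
                        f"node {n.id}: parent {n.parent_id} does not exist"
                    )
                if n.parent_id >= n.id:
                    raise MorphologyStructureError(
                        f"node {n.id}: parent id {n.parent_id} not smaller than child id"
                    )
        # parent_id < id on every edge rules out cycles; connectivity check:
        seen = set()
        for n in sorted(self.nodes.values(), key=lambda n: n.id):
            if n.parent_id is None or n.parent_id in seen:
                seen.add(n.id)
        if len(seen) != len(self.nodes):
            raise MorphologyStructureError("tree is not connected")

    # -- geometry -----------------------------------------------------------
    @property
    def root(self) -> Node:
        return next(n for n in self.nodes.values() if n.parent_id is None)

    def segment_tag(self, segment_id: int) -> str:
        return self.nodes[self.segments[segment_id].distal].type_tag

    def segment_length(self, segment_id: int) -> float:
        s = self.segments[segment_id]
        a, b = self.nodes[s.proximal], self.nodes[s.distal]
        return float(np.linalg.norm(a.xyz - b.xyz))

    def segment_midpoint(self, segment_id: int) -> np.ndarray:
        s = self.segments[segment_id]
        return 0.5 * (self.nodes[s.proximal].xyz + self.nodes[s.distal].xyz)

    def point_on_segment(self, segment_id: int, arc_fraction: float) -> np.ndarray:
        s = self.segments[segment_id]
        a, b = self.nodes[s.proximal].xyz, self.nodes[s.distal].xyz
        return a + arc_fraction * (b - a)

    def segment_ids(self, region: str | set[str] | None = None) -> list[int]:
        """Segment ids filtered by type tag.

        ``region`` may be a tag, a set of tags, the shorthand ``"dendrite"``
        (both dendrite types), or None for all segments.
        """
        if region is None:
            return [s.segment_id for s in self.segments]
        if region == "dendrite":
            tags = DENDRITE_TAGS
        elif isinstance(region, str):
            tags = {region}
        else:
            tags = set(region)
        return [s.segment_id for s in self.segments if self.segment_tag(s.segment_id) in tags]

    def total_length(self, region: str | set[str] | None = None) -> float:
        return sum(self.segment_length(i) for i in self.segment_ids(region))


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> Morphology:
    """Read a 7-column SWC file into a validated :class:`Morphology`.

    Soma rows are merged into one root node at their centroid with their
    mean radius; children of any soma row are re-parented onto the root.
    """
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise MorphologyFormatError(f"line {lineno}: expected 7 columns, got {len(cols)}")
            try:
                nid, typ = int(cols[0]), int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                parent = int(cols[6])
            except ValueError as exc:
                raise MorphologyFormatError(f"line {lineno}: {exc}") from exc
            raw.append((nid, typ, x, y, z, r, parent))
    if not raw:
        raise MorphologyFormatError("empty SWC file")

    ids = {r[0] for r in raw}
    soma_rows = [r for r in raw if r[1] == 1]
    if not soma_rows:
        raise MorphologyFormatError("no soma row in SWC file")
    soma_ids = {r[0] for r in soma_rows}
    centroid = np.mean([[r[2], r[3], r[4]] for r in soma_rows], axis=0)
    soma_radius = float(np.mean([r[5] for r in soma_rows]))

    for r in raw:
        if r[6] != -1 and r[6] not in ids:
            raise MorphologyFormatError(f"node {r[0]}: parent {r[6]} does not exist")
        if r[5] <= 0:
            raise ValueError(f"node {r[0]}: non-positive radius {r[5]}")

    # renumber: root = 1, remaining non-soma nodes densely in original order
    new_id = {}
    nodes = [Node(1, "soma", *centroid, soma_radius, None)]
    next_id = 2
    for r in sorted(raw, key=lambda r: r[0]):
        if r[0] in soma_ids:
            new_id[r[0]] = 1
            continue
        new_id[r[0]] = next_id
        next_id += 1
    for r in sorted(raw, key=lambda r: r[0]):
        if r[0] in soma_ids:
            continue
        parent = 1 if (r[6] == -1 or r[6] in soma_ids) else new_id[r[6]]
        nodes.append(
            Node(new_id[r[0]], SWC_TYPE_TAGS.get(r[1], "other"),
                 r[2], r[3], r[4], r[5], parent)
        )
    return Morphology(nodes)


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as 7-column SWC (inverse of :func:`read_swc`)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in sorted(m.nodes.values(), key=lambda n: n.id):
            parent = -1 if n.parent_id is None else n.parent_id
            fh.write(
                f"{n.id} {TAG_SWC_TYPES[n.type_tag]} {n.x:.9g} {n.y:.9g} {n.z:.9g} "
                f"{n.radius:.9g} {parent}\n"
            )


# ---------------------------------------------------------------------------
# Synapse-site sampling
# ---------------------------------------------------------------------------

def _make_site(m: Morphology, seg_id: int, frac: float) -> SynapseSite:
    pos = m.point_on_segment(seg_id, frac)
    return SynapseSite(segment_id=seg_id, arc_fraction=float(frac), position=tuple(pos))


def sample_distributed(
    m: Morphology, n: int, region: str | set[str] | None = "dendrite",
    rng_seed: int | np.random.Generator = 0,
) -> list[SynapseSite]:
    """Draw ``n`` sites uniformly over dendritic segments (then uniform arc fraction).

    The measure is uniform over *segment count*, not length-weighted; pass a
    region filter to restrict to e.g. ``"apical_dendrite"``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    seg_ids = m.segment_ids(region if region is not None else "dendrite")
    if not seg_ids:
        raise ValueError(f"morphology has no segment in region {region!r}")
    choices = rng.integers(0, len(seg_ids), size=n)
    fracs = rng.uniform(size=n)
    return [_make_site(m, seg_ids[c], f) for c, f in zip(choices, fracs)]


def sample_localized(
    m: Morphology, n: int, radius: float = 50.0,
    region: str | set[str] | None = "dendrite",
    rng_seed: int | np.random.Generator = 0,
) -> list[SynapseSite]:
    """Draw ``n`` clustered sites within a sphere of ``radius`` μm.

    A random dendritic centre segment is chosen; candidates are dendritic
    segments whose *midpoints* lie within ``radius`` of the centre midpoint.
    Sites are sampled without replacement, falling back to replacement (with
    a log message) when fewer than ``n`` candidates exist.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    seg_ids = m.segment_ids(region if region is not None else "dendrite")
    if not seg_ids:
        raise ValueError(f"morphology has no segment in region {region!r}")
    centre_seg = seg_ids[rng.integers(0, len(seg_ids))]
    centre = m.segment_midpoint(centre_seg)
    candidates = [
        s for s in seg_ids
        if np.linalg.norm(m.segment_midpoint(s) - centre) <= radius
    ]
    replace = len(candidates) < n
    if replace:
        logger.info(
            "localized sampling: only %d candidate segments within %g um; "
            "sampling with replacement", len(candidates), radius,
        )
    chosen = rng.choice(len(candidates), size=n, replace=replace)
    fracs = rng.uniform(size=n)
    return [_make_site(m, candidates[c], f) for c, f in zip(chosen, fracs)]


# ---------------------------------------------------------------------------
# Synthetic morphologies
# ---------------------------------------------------------------------------

SOMA_HEIGHT_UM = 20.0  # default soma height


def generate_synthetic_morphology(
    kind: str = "ball_and_stick",
    *,
    length: float = 600.0,
    depth: int = 5,
    mean_segment_length: float = 40.0,
    soma_radius: float = SOMA_HEIGHT_UM / 2,
    dendrite_radius: float = 1.0,
    taper: float = 0.7,
    dendrite_tag: str = "apical_dendrite",
    rng_seed: int | np.random.Generator = 0,
) -> Morphology:
    """Build a synthetic morphology fixture.

    ``ball_and_stick``: a soma plus one straight dendrite of total ``length``
    split into pieces of ``mean_segment_length``.  ``random_binary_tree``: a
    trunk that bifurcates recursively ``depth`` times with randomly tilted
    branch directions and tapering radii — a stand-in with the gross scale of
    a pyramidal cell (apical tree several hundred μm tall).
    """
    rng = np.random.default_rng(rng_seed)
    nodes = [Node(1, "soma", 0.0, 0.0, 0.0, soma_radius, None)]

    def add_node(tag, xyz, radius, parent) -> int:
        nid = len(nodes) + 1
        nodes.append(Node(nid, tag, *xyz, radius, parent))
        return nid

    if kind == "ball_and_stick":
        if length <= 0 or mean_segment_length <= 0:
            raise ValueError("length and mean_segment_length must be positive")
        n_pieces = max(1, int(round(length / mean_segment_length)))
        step = length / n_pieces
        parent = 1
        for i in range(1, n_pieces + 1):
            # chain anchored at the soma centre so the cable length sums to `length`
            parent = add_node(dendrite_tag, (0.0, i * step, 0.0),
                              dendrite_radius, parent)
    elif kind == "random_binary_tree":
        if depth < 1 or mean_segment_length <= 0:
            raise ValueError("depth >= 1 and positive segment length required")

        def grow(parent_id, origin, direction, level, radius):
            seg_len = mean_segment_length * rng.uniform(0.7, 1.3)
            tip = origin + direction * seg_len
            nid = add_node(dendrite_tag, tuple(tip), radius, parent_id)
            if level >= depth:
                return
            for sign in (-1.0, 1.0):
                angle = rng.uniform(0.25, 0.6) * sign
                azim = rng.uniform(0, 2 * math.pi)
                # rotate direction by `angle` towards a random azimuth
                perp = np.array([math.cos(azim), 0.0, math.sin(azim)])
                perp -= perp.dot(direction) * direction
                nrm = np.linalg.norm(perp)
                perp = perp / nrm if nrm > 1e-12 else np.array([1.0, 0.0, 0.0])
                newdir = math.cos(angle) * direction + math.sin(angle) * perp
                newdir /= np.linalg.norm(newdir)
                grow(nid, tip, newdir, level + 1, max(radius * taper, 0.1))

        grow(1, np.array([0.0, soma_radius, 0.0]), np.array([0.0, 1.0, 0.0]),
             1, dendrite_radius)
    else:
        raise ValueError(f"unknown morphology kind {kind!r}")
    return Morphology(nodes)
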
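"""Idealized regionalized airway geometry.

The delivery path is modelled as a chain of extrathoracic ducts (inhaler
mouthpiece, mouth, pharynx, larynx) feeding a symmetric bifurcating
tracheobronchial tree from the trachea (G0) down to a configurable terminal
generation (default G9, i.e. 512 outlets).  Generation dimensions follow the
classical symmetric morphometric table; the five lung lobes partition the
eight G3 subtrees.

Coordinate conventions: gravity acts along -z; angles are stored in degrees;
lengths and diameters are stored in cm externally and converted to metres by
consumers.  The trachea is inclined 15 degrees from the vertical (upright
posture) and child gravity angles alternate about the parent's by half the
branching angle -- a documented, deterministic convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "Region",
    "AirwaySegment",
    "AirwayTree",
    "GeometryConfig",
    "build_tree",
    "assign_lobes",
    "path_to_outlet",
    "DEFAULT_LOBE_RULE",
    "WEIBEL_TABLE_CM",
]

REGIONS = ("MDI_MOUTHPIECE", "MOUTH", "PHARYNX", "LARYNX", "TB")
LOBES = ("LU", "LL", "RU", "RM", "RL")

#: Default partition of the eight G3 subtrees into five lobes (left lung gets
#: the first four subtrees under G1's left branch).  5 lobes cannot evenly
#: split 4 G2 branches, hence the asymmetric counts.
DEFAULT_LOBE_RULE = ("LU", "LU", "LL", "LL", "RU", "RM", "RL", "RL")

#: Symmetric morphometric scaling table: generation -> (length_cm, diameter_cm).
WEIBEL_TABLE_CM = {
    0: (12.0, 1.80),
    1: (4.76, 1.22),
    2: (1.90, 0.83),
    3: (0.76, 0.56),
    4: (1.27, 0.45),
    5: (1.07, 0.35),
    6: (0.90, 0.28),
    7: (0.76, 0.23),
    8: (0.64, 0.186),
    9: (0.54, 0.154),
}

SEGMENT_COLUMNS = [
    "id",
    "parent_id",
    "region",
    "generation",
    "lobe",
    "length_cm",
    "diameter_cm",
    "branch_angle_deg",
    "gravity_angle_deg",
]


class Region:
    """Region label vocabulary (string constants)."""

    MDI_MOUTHPIECE = "MDI_MOUTHPIECE"
    MOUTH = "MOUTH"
    PHARYNX = "PHARYNX"
    LARYNX = "LARYNX"
    TB = "TB"


@dataclass
class AirwaySegment:
    """One duct of the airway model."""

    id: int
    parent_id: int | None
    region: str
    generation: int | None  # trachea = 0 ... depth; None for extrathoracic
    lobe: str | None
    length_cm: float
    diameter_cm: float
    branch_angle_deg: float = 0.0
    gravity_angle_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.length_cm <= 0.0 or self.diameter_cm <= 0.0:
            raise ValueError("segment length and diameter must be positive")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.lobe is not None and self.lobe not in LOBES:
            raise ValueError(f"unknown lobe {self.lobe!r}")

    @property
    def area_cm2(self) -> float:
        return math.pi * self.diameter_cm**2 / 4.0

    @property
    def area_m2(self) -> float:
        return self.area_cm2 * 1e-4

    @property
    def length_m(self) -> float:
        return self.length_cm * 1e-2

    @property
    def diameter_m(self) -> float:
        return self.diameter_cm * 1e-2


@dataclass(frozen=True)
class GeometryConfig:
    """Configuration of the idealized airway geometry."""

    tree_depth: int = 9
    scaling_table_cm: dict = field(default_factory=lambda: dict(WEIBEL_TABLE_CM))
    mouthpiece_length_cm: float = 3.0
    mouthpiece_area_cm2: float = 1.28
    mouth_length_cm: float = 9.0
    mouth_diameter_cm: float = 2.5
    pharynx_length_cm: float = 5.0
    pharynx_diameter_cm: float = 1.4
    larynx_length_cm: float = 4.0
    larynx_diameter_cm: float = 0.9  # glottis constriction
    pharynx_bend_deg: float = 70.0
    larynx_bend_deg: float = 20.0
    branch_angle_deg: float = 35.0
    tracheal_inclination_deg: float = 15.0
    lobe_rule: tuple = DEFAULT_LOBE_RULE

    def __post_init__(self) -> None:
        if self.tree_depth < 0:
            raise ValueError("tree depth must be non-negative")
        if not (0.0 <= self.tracheal_inclination_deg < 90.0):
            raise ValueError("tracheal inclination must be in [0, 90)")
        missing = [g for g in range(self.tree_depth + 1) if g not in self.scaling_table_cm]
        if missing:
            raise ValueError(f"scaling table missing generations {missing}")

    @property
    def mouthpiece_diameter_cm(self) -> float:
        return math.sqrt(4.0 * self.mouthpiece_area_cm2 / math.pi)


@dataclass
class AirwayTree:
    """Segment graph: extrathoracic chain plus a rooted binary TB tree."""

    segments: dict[int, AirwaySegment]
    children: dict[int, list[int]]
    outlet_ids: list[int]
    config: GeometryConfig

    @property
    def mouthpiece_area_cm2(self) -> float:
        return self.config.mouthpiece_area_cm2

    def parent(self, seg_id: int) -> int | None:
        return self.segments[seg_id].parent_id

    def segments_at_generation(self, g: int) -> list[AirwaySegment]:
        return [s for s in self.segments.values() if s.generation == g]

    def extrathoracic_ids(self) -> list[int]:
        order = {r: i for i, r in enumerate(REGIONS[:4])}
        ext = [s for s in self.segments.values() if s.generation is None]
        return [s.id for s in sorted(ext, key=lambda s: order[s.region])]

    def trachea_id(self) -> int:
        (trachea,) = [s.id for s in self.segments.values() if s.generation == 0]
        return trachea

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": s.id,
                "parent_id": -1 if s.parent_id is None else s.parent_id,
                "region": s.region,
                "generation": -1 if s.generation is None else s.generation,
                "lobe": "" if s.lobe is None else s.lobe,
                "length_cm": s.length_cm,
                "diameter_cm": s.diameter_cm,
                "branch_angle_deg": s.branch_angle_deg,
                "gravity_angle_deg": s.gravity_angle_deg,
            }
            for s in sorted(self.segments.values(), key=lambda s: s.id)
        ]
        return pd.DataFrame(rows)[SEGMENT_COLUMNS]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_tree(config: GeometryConfig | None = None) -> AirwayTree:
    """Construct the airway model: extrathoracic chain plus symmetric tree.

    Segments are created in order mouthpiece -> mouth -> pharynx -> larynx ->
    trachea, then breadth-first down the bifurcating tree.  Lobes are assigned
    afterwards for trees of depth >= 3 (see :func:`assign_lobes`).
    """
    cfg = config if config is not None else GeometryConfig()
    segments: dict[int, AirwaySegment] = {}
    children: dict[int, list[int]] = {}

    def add(seg: AirwaySegment) -> int:
        segments[seg.id] = seg
        children[seg.id] = []
        if seg.parent_id is not None:
            children[seg.parent_id].append(seg.id)
        return seg.id

    mp = add(
        AirwaySegment(
            id=0, parent_id=None, region=Region.MDI_MOUTHPIECE, generation=None,
            lobe=None, length_cm=cfg.mouthpiece_length_cm,
            diameter_cm=cfg.mouthpiece_diameter_cm, branch_angle_deg=0.0,
            gravity_angle_deg=90.0,
        )
    )
    mouth = add(
        AirwaySegment(
            id=1, parent_id=mp, region=Region.MOUTH, generation=None, lobe=None,
            length_cm=cfg.mouth_length_cm, diameter_cm=cfg.mouth_diameter_cm,
            branch_angle_deg=0.0, gravity_angle_deg=90.0,
        )
    )
    pharynx = add(
        AirwaySegment(
            id=2, parent_id=mouth, region=Region.PHARYNX, generation=None,
            lobe=None, length_cm=cfg.pharynx_length_cm,
            diameter_cm=cfg.pharynx_diameter_cm,
            branch_angle_deg=cfg.pharynx_bend_deg, gravity_angle_deg=10.0,
        )
    )
    larynx = add(
        AirwaySegment(
            id=3, parent_id=pharynx, region=Region.LARYNX, generation=None,
            lobe=None, length_cm=cfg.larynx_length_cm,
            diameter_cm=cfg.larynx_diameter_cm,
            branch_angle_deg=cfg.larynx_bend_deg, gravity_angle_deg=10.0,
        )
    )

    length0, diameter0 = cfg.scaling_table_cm[0]
    trachea = add(
        AirwaySegment(
            id=4, parent_id=larynx, region=Region.TB, generation=0, lobe=None,
            length_cm=length0, diameter_cm=diameter0, branch_angle_deg=0.0,
            gravity_angle_deg=cfg.tracheal_inclination_deg,
        )
    )

    next_id = 5
    frontier = [trachea]
    for g in range(1, cfg.tree_depth + 1):
        length, diameter = cfg.scaling_table_cm[g]
        new_frontier = []
        for parent in frontier:
            parent_gravity = segments[parent].gravity_angle_deg
            for child_idx in range(2):
                sign = 1.0 if child_idx == 0 else -1.0
                gravity = min(88.0, max(2.0, parent_gravity + sign * cfg.branch_angle_deg / 2.0))
                seg_id = add(
                    AirwaySegment(
                        id=next_id, parent_id=parent, region=Region.TB,
                        generation=g, lobe=None, length_cm=length,
                        diameter_cm=diameter, branch_angle_deg=cfg.branch_angle_deg,
                        gravity_angle_deg=gravity,
                    )
                )
                next_id += 1
                new_frontier.append(seg_id)
        frontier = new_frontier

    tree = AirwayTree(
        segments=segments,
        children=children,
        outlet_ids=list(frontier),
        config=cfg,
    )
    if cfg.tree_depth >= 3:
        assign_lobes(tree, cfg.lobe_rule)
    return tree


def assign_lobes(tree: AirwayTree, rule=DEFAULT_LOBE_RULE) -> AirwayTree:
    """Label every G3 subtree (and its descendants) with one lobe, in place.

    ``rule`` lists the lobe of each of the eight G3 subtrees in tree order.
    The partition is complete and disjoint: every outlet inherits exactly one
    lobe.
    """
    depth = tree.config.tree_depth
    if depth < 3:
        raise ValueError("lobe assignment requires a tree of depth >= 3")
    rule = tuple(rule)
    if len(rule) != 8:
        raise ValueError("lobe rule must name exactly 8 G3 subtrees")
    unknown = [lobe for lobe in rule if lobe not in LOBES]
    if unknown:
        raise ValueError(f"unknown lobe labels: {unknown}")

    g3_roots = sorted(s.id for s in tree.segments_at_generation(3))
    for root, lobe in zip(g3_roots, rule):
        stack = [root]
        while stack:
            seg_id = stack.pop()
            tree.segments[seg_id].lobe = lobe
            stack.extend(tree.children[seg_id])
    return tree


def path_to_outlet(tree: AirwayTree, outlet_id: int) -> list[AirwaySegment]:
    """Ordered mouthpiece-to-outlet segment chain for one terminal outlet."""
    if outlet_id not in set(tree.outlet_ids):
        raise KeyError(f"unknown outlet id {outlet_id}")
    chain: list[AirwaySegment] = []
    seg_id: int | None = outlet_id
    while seg_id is not None:
        seg = tree.segments[seg_id]
        chain.append(seg)
        seg_id = seg.parent_id
    chain.reverse()
    return chain
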
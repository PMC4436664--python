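"""Assembly of coarse-grain 3D models from sampled placement parameters.

A model is built by walking the skeleton graph's traversal order: the
first stem is placed at the origin, every further stem is positioned
relative to its already-placed neighbour through the six inter-helical
parameters of the connecting element, and hairpins/5'/3' regions become
straight segments (anchors) hanging off stem ends.  Junction break
segments receive no parameters; whether they can bridge their two stems
is judged afterwards by the junction-closure rule.

Resampling an element replaces only its stored parameters and re-runs
the deterministic realization, so upstream geometry is reproduced
bit-for-bit while the downstream subtree moves rigidly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .helix_geometry import (
    AFormTemplate,
    DEFAULT_TEMPLATE,
    StemCylinder,
    corner_atom,
    rotation_about_axis,
    virtual_residues,
)
from .proposal_stats import (
    InterhelixParams,
    LoopPlacement,
    StatsTable,
    _reference_twist,
    sample_interhelix,
    sample_loop,
    sample_stem,
)
from .ss_graph import SkeletonGraph

__all__ = [
    "CoarseGrainModel",
    "place_stem",
    "build_model",
    "resample_element",
    "junction_gap",
    "closure_limit",
    "is_feasible",
]

_KIND_TO_STATS = {"interior_loop": "i", "multiloop_segment": "m"}
_LOOP_TO_STATS = {"hairpin": "h", "five_prime": "f", "three_prime": "t"}


def place_stem(
    prev: StemCylinder,
    connection: tuple[int, int],
    params: InterhelixParams,
    stem_params: tuple[float, float],
    n_bp: int,
    template: AFormTemplate | None = None,
) -> StemCylinder:
    """Place a new stem relative to ``prev``; inverse of extract_interhelix.

    ``connection`` is the corner pattern (corner of prev, corner of the
    new stem) of the connecting element; ``stem_params`` is the new
    stem's (rise, per-bp twist).
    """
    from .helix_geometry import CORNER_END, CORNER_SIGN

    ca, cb = connection
    template = template or prev.template
    o, F = prev.corner_frame(ca)
    e1, e2, e3 = F
    rise, twist = stem_params
    eb = CORNER_END[cb]

    def from_spherical(polar, azim):
        return np.cos(polar) * e1 + np.sin(polar) * (
            np.cos(azim) * e2 + np.sin(azim) * e3
        )

    pos = o + params.r * from_spherical(params.u, params.v)
    inward = from_spherical(params.u_p, params.v_p)
    w_ref = _reference_twist(e2, e3, inward)
    w_conn = CORNER_SIGN[cb] * (
        rotation_about_axis(inward, params.t) @ w_ref
    )
    L = (n_bp - 1) * rise
    total = (n_bp - 1) * twist
    if eb == 0:
        a_s, a_e = pos, pos + L * inward
        t_s = w_conn
        t_e = rotation_about_axis(inward, total) @ t_s
    else:
        a_e, a_s = pos, pos + L * inward
        t_e = w_conn
        t_s = rotation_about_axis(-inward, -total) @ t_e
    return StemCylinder(a_s, a_e, t_s, t_e, n_bp, template)


def _body_frame(cyl: StemCylinder):
    e = cyl.axis
    w = cyl.t_s
    return cyl.a_s, np.vstack([e, w, np.cross(e, w)])


def _place_inverse(
    placed_b: StemCylinder,
    connection: tuple[int, int],
    params: InterhelixParams,
    a_stem_params: tuple[float, float],
    a_n_bp: int,
    b_stem_params: tuple[float, float],
    template: AFormTemplate,
) -> StemCylinder:
    """Recover stem a when the traversal reaches a connector from side b.

    Placement statistics are always expressed as "b relative to a"; the
    inverse pose is obtained by realizing the pair at a canonical
    origin and rigidly transporting it onto the placed b cylinder.
    """
    rise_a, twist_a = a_stem_params
    L = (a_n_bp - 1) * rise_a
    axis = np.array([0.0, 0.0, 1.0])
    t_s = np.array([1.0, 0.0, 0.0])
    t_e = rotation_about_axis(axis, (a_n_bp - 1) * twist_a) @ t_s
    a0 = StemCylinder(np.zeros(3), L * axis, t_s, t_e, a_n_bp, template)
    b0 = place_stem(
        a0, connection, params, b_stem_params, placed_b.n_bp, template
    )
    o0, F0 = _body_frame(b0)
    oa, Fa = _body_frame(placed_b)
    M = Fa.T @ F0

    def pt(p):
        return M @ (p - o0) + oa

    return StemCylinder(
        pt(a0.a_s), pt(a0.a_e), M @ a0.t_s, M @ a0.t_e, a_n_bp, template
    )


@dataclass
class CoarseGrainModel:
    """Skeleton graph plus realized 3D geometry and its parameters."""

    graph: SkeletonGraph
    params: dict[str, object] = field(default_factory=dict)
    stems: dict[str, StemCylinder] = field(default_factory=dict)
    loop_anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    template: AFormTemplate = field(default=DEFAULT_TEMPLATE)
    provenance: list[tuple[str, int]] = field(default_factory=list)
    rng_seed: int | None = None

    _vr_cache: dict | None = field(default=None, repr=False, compare=False)

    def realize(self) -> "CoarseGrainModel":
        """Recompute all geometry from the stored parameters (in place)."""
        g = self.graph
        self.stems = {}
        self.loop_anchors = {}
        self._vr_cache = None
        for name in g.traversal:
            elem = g.elements[name]
            if elem.kind == "stem":
                if name in self.stems:
                    continue
                # only the traversal root reaches here un-placed
                rise, twist = self.params[name]
                L = (elem.n_bp - 1) * rise
                axis = np.array([0.0, 0.0, 1.0])
                t_s = np.array([1.0, 0.0, 0.0])
                t_e = (
                    rotation_about_axis(axis, (elem.n_bp - 1) * twist) @ t_s
                )
                self.stems[name] = StemCylinder(
                    np.zeros(3), L * axis, t_s, t_e, elem.n_bp, self.template
                )
            elif elem.kind in _KIND_TO_STATS:
                conn = g.connections[name]
                sa, sb = conn.a[0], conn.b[0]
                if sa in self.stems and sb not in self.stems:
                    self.stems[sb] = place_stem(
                        self.stems[sa],
                        conn.corners,
                        self.params[name],
                        self.params[sb],
                        g.elements[sb].n_bp,
                        self.template,
                    )
                elif sb in self.stems and sa not in self.stems:
                    self.stems[sa] = _place_inverse(
                        self.stems[sb],
                        conn.corners,
                        self.params[name],
                        self.params[sa],
                        g.elements[sa].n_bp,
                        self.params[sb],
                        self.template,
                    )
                else:  # pragma: no cover - traversal places each stem once
                    continue
            else:
                conn = g.connections.get(name)
                if conn is None:
                    continue
                stem, _end = conn.a
                lp: LoopPlacement = self.params[name]
                o, F = self.stems[stem].corner_frame(conn.corner_a)
                direction = F.T @ np.asarray(lp.direction)
                self.loop_anchors[name] = (o, o + lp.length * direction)
        return self

    # -- geometry queries ---------------------------------------------------

    def stem_virtual_residues(self) -> dict[str, list]:
        if self._vr_cache is None:
            self._vr_cache = {
                name: virtual_residues(cyl) for name, cyl in self.stems.items()
            }
        return self._vr_cache

    def stem_positions(self) -> np.ndarray:
        """Stacked virtual-residue axis positions of all stems."""
        vrs = self.stem_virtual_residues()
        return np.array(
            [vr.position for name in sorted(vrs) for vr in vrs[name]]
        )

    def virtual_atoms(self) -> tuple[np.ndarray, list[str]]:
        """(positions, element name per atom) over all stem virtual atoms."""
        vrs = self.stem_virtual_residues()
        pts, owner = [], []
        for name in sorted(vrs):
            for vr in vrs[name]:
                for p in vr.atoms.values():
                    pts.append(p)
                    owner.append(name)
        return np.array(pts), owner

    def copy(self) -> "CoarseGrainModel":
        dup = CoarseGrainModel(
            graph=self.graph,
            params=dict(self.params),
            stems=dict(self.stems),
            loop_anchors=dict(self.loop_anchors),
            template=self.template,
            provenance=list(self.provenance),
            rng_seed=self.rng_seed,
        )
        dup._vr_cache = self._vr_cache
        return dup


def _sampleable_elements(g: SkeletonGraph) -> list[str]:
    return [n for n in g.traversal if n not in g.break_names]


def build_model(
    g: SkeletonGraph,
    table: StatsTable,
    rng: np.random.Generator,
) -> CoarseGrainModel:
    """Sample parameters for every placeable element and realize the model."""
    model = CoarseGrainModel(graph=g, template=table.template)
    for name in g.traversal:
        elem = g.elements[name]
        if elem.kind == "stem":
            model.params[name] = sample_stem(table, elem.n_bp, rng)
        elif elem.kind in _KIND_TO_STATS:
            model.params[name] = sample_interhelix(
                table, _KIND_TO_STATS[elem.kind], elem.size_signature, rng
            )
        elif elem.kind in _LOOP_TO_STATS and name in g.connections:
            model.params[name] = sample_loop(
                table, _LOOP_TO_STATS[elem.kind], max(elem.size, 1), rng
            )
        model.provenance.append((name, 0))
    return model.realize()


def resample_element(
    model: CoarseGrainModel,
    name: str,
    table: StatsTable,
    rng: np.random.Generator,
    iteration: int = 0,
) -> CoarseGrainModel:
    """New model with one element's parameters redrawn.

    The original model is untouched; geometry upstream of the element in
    traversal order is recomputed identically, downstream placements move
    rigidly with their parent frames.
    """
    g = model.graph
    if name not in g.elements:
        raise KeyError(f"unknown element {name!r}")
    if name in g.break_names or name not in model.params:
        raise KeyError(f"element {name!r} carries no sampled parameters")
    elem = g.elements[name]
    new = model.copy()
    if elem.kind == "stem":
        new.params[name] = sample_stem(table, elem.n_bp, rng)
    elif elem.kind in _KIND_TO_STATS:
        new.params[name] = sample_interhelix(
            table, _KIND_TO_STATS[elem.kind], elem.size_signature, rng
        )
    else:
        new.params[name] = sample_loop(
            table, _LOOP_TO_STATS[elem.kind], max(elem.size, 1), rng
        )
    new.provenance.append((name, iteration))
    return new.realize()


def junction_gap(model: CoarseGrainModel, segment: str) -> float:
    """Backbone gap a multiloop segment must bridge.

    Distance between the virtual O3' of the exiting corner nucleotide of
    one adjacent stem and the virtual P of the entering corner nucleotide
    of the other.
    """
    conn = model.graph.connections[segment]
    if conn.exit_corner is None or conn.entry_corner is None:
        raise ValueError(f"{segment!r} has no junction corner annotation")
    (s_exit, c_exit), (s_entry, c_entry) = conn.exit_corner, conn.entry_corner
    o3 = corner_atom(model.stems[s_exit], c_exit, "O3'")
    p = corner_atom(model.stems[s_entry], c_entry, "P")
    return float(np.linalg.norm(o3 - p))


def closure_limit(n_nt: int, g0: float = 3.0, g1: float = 6.5) -> float:
    """Maximum bridgeable O3'-P gap for a segment of ``n_nt`` nucleotides.

    One phosphodiester linkage with slack plus a near-maximal backbone
    extension per nucleotide; the rule is a configurable stand-in for the
    allowed-distance function.
    """
    return g0 + g1 * n_nt


def is_feasible(
    model: CoarseGrainModel, g0: float = 3.0, g1: float = 6.5
) -> bool:
    """No clash and every break segment's gap within the closure limit."""
    from .energy import clash_energy  # deferred: energy imports this module

    if clash_energy(model) > 0:
        return False
    for name in model.graph.break_names:
        n = model.graph.elements[name].size
        if junction_gap(model, name) > closure_limit(n, g0, g1):
            return False
    return True
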
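"""Constraint and adaptive reference-ratio energies.

Two constraint terms exclude physically impossible structures: a clash
penalty over stem virtual atoms and a junction-closure penalty on break
segments whose backbone gap cannot be bridged.  Three knowledge-based
terms (radius of gyration, expected A-minor interactions per loop,
hairpin nearest-neighbour distance) score a structure by

    E(x) = -c * log( p_target(x) / p_reference(x) )

where both densities are Gaussian kernel density estimates with Scott's
bandwidth.  The target distribution comes from native-like measures of
comparable sequence length; the reference distribution starts from
decoy/proposal measures and absorbs the simulation's own samples every
tenth step, so that the sampled ensemble is steered toward the target
distribution rather than toward a single optimum.

Penalty constants are 10,000 per violation -- far above the knowledge
terms' range, guaranteeing Metropolis rejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .helix_geometry import rotation_about_axis
from .model_builder import (
    CoarseGrainModel,
    closure_limit,
    junction_gap,
)

__all__ = [
    "PENALTY",
    "CLASH_DISTANCE",
    "scott_bandwidth",
    "GaussianKDE",
    "MeasureDistribution",
    "refratio_energy",
    "update_reference",
    "build_target_distribution",
    "clash_energy",
    "junction_energy",
    "radius_of_gyration",
    "loop_loop_distance",
    "AminorGeometry",
    "AminorModel",
    "aminor_geometry",
    "aminor_probability",
    "expected_aminor",
    "loop_segment",
    "EnergyTerm",
    "EnergyFunction",
]

#: per-violation constraint penalty; any value far above the knowledge
#: terms' range guarantees Metropolis rejection
PENALTY = 10_000.0
CLASH_DISTANCE = 1.8
AMINOR_CUTOFF = 30.0

_DENSITY_FLOOR_FRACTION = 1e-12
_BANDWIDTH_FLOOR = 1e-3


def scott_bandwidth(samples, dims: int = 1, floor: float = _BANDWIDTH_FLOOR):
    """Per-dimension Scott's-rule bandwidth: std * n^(-1/(dims+4)).

    ``samples`` is (n,) for 1D or (n, dims); sample standard deviation
    (ddof=1) per dimension.  Zero-variance dimensions fall back to the
    configured floor with a warning.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for a bandwidth")
    sd = x.std(axis=0, ddof=1)
    h = sd * n ** (-1.0 / (dims + 4))
    if np.any(h <= 0):
        warnings.warn(
            "zero-variance samples: using floor bandwidth", stacklevel=2
        )
        h = np.where(h <= 0, floor, h)
    return h if dims > 1 else float(h[0])


class GaussianKDE:
    """Product-kernel Gaussian KDE with fixed per-dimension bandwidths."""

    def __init__(self, samples, bandwidths=None):
        x = np.asarray(samples, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        self.samples = x
        self.dims = x.shape[1]
        if bandwidths is None:
            bandwidths = scott_bandwidth(x, self.dims)
        self.bandwidths = np.atleast_1d(np.asarray(bandwidths, dtype=float))

    def evaluate(self, points) -> np.ndarray:
        """Density at one or more points; always returns a 1D array."""
        p = np.asarray(points, dtype=float)
        if p.ndim == 0:
            p = p[None, None]
        elif p.ndim == 1:
            p = p[:, None] if self.dims == 1 else p[None, :]
        h = self.bandwidths
        z = (p[:, None, :] - self.samples[None, :, :]) / h
        log_norm = -0.5 * self.dims * np.log(2 * np.pi) - np.log(h).sum()
        return np.exp(-0.5 * (z**2).sum(-1) + log_norm).mean(axis=1)

    __call__ = evaluate

    def max_density(self) -> float:
        """Approximate mode height: max density over the sample points."""
        if not hasattr(self, "_max_density"):
            self._max_density = float(self.evaluate(self.samples).max())
        return self._max_density


@dataclass
class MeasureDistribution:
    """Target and reference sample stores of one coarse-grain measure."""

    measure_name: str
    target_samples: np.ndarray
    reference_samples: np.ndarray
    c: float = 1.0

    _kde_t: GaussianKDE | None = field(default=None, repr=False)
    _kde_r: GaussianKDE | None = field(default=None, repr=False)

    def __post_init__(self):
        self.target_samples = np.asarray(self.target_samples, dtype=float)
        self.reference_samples = np.asarray(
            self.reference_samples, dtype=float
        )

    def _kdes(self):
        if self._kde_t is None:
            self._kde_t = GaussianKDE(self.target_samples)
        if self._kde_r is None:
            self._kde_r = GaussianKDE(self.reference_samples)
        return self._kde_t, self._kde_r

    def energy(self, x: float) -> float:
        kt, kr = self._kdes()
        floor_t = max(kt.max_density() * _DENSITY_FLOOR_FRACTION, 1e-300)
        floor_r = max(kr.max_density() * _DENSITY_FLOOR_FRACTION, 1e-300)
        pt = max(float(kt.evaluate([x])[0]), floor_t)
        pr = max(float(kr.evaluate([x])[0]), floor_r)
        return -self.c * float(np.log(pt / pr))


def refratio_energy(x: float, dist: MeasureDistribution) -> float:
    """-c log(p_target(x) / p_reference(x)), densities floored."""
    return dist.energy(x)


def update_reference(
    dist: MeasureDistribution, new_samples
) -> MeasureDistribution:
    """Append samples to the reference store; KDE recomputed lazily."""
    new = np.atleast_1d(np.asarray(new_samples, dtype=float))
    if new.size:
        dist.reference_samples = np.concatenate(
            [dist.reference_samples, new]
        )
        dist._kde_r = None
    return dist


def build_target_distribution(
    corpus,
    target_length: int,
    min_count: int = 500,
    window: float = 0.01,
) -> np.ndarray:
    """Length-windowed measure collection with symmetric widening.

    ``corpus`` holds (length, value) records.  Measures within
    ``window * target_length`` of the target length are collected; the
    window widens symmetrically until at least ``min_count`` measures are
    available or the corpus is exhausted (then all are used, with a
    warning).
    """
    arr = np.asarray(corpus, dtype=float)
    if arr.size == 0:
        raise ValueError("empty measure corpus")
    lengths, values = arr[:, 0], arr[:, 1]
    w = max(window * target_length, 0.5)
    max_span = np.abs(lengths - target_length).max()
    while True:
        mask = np.abs(lengths - target_length) <= w
        if mask.sum() >= min_count:
            return values[mask]
        if w >= max_span:
            warnings.warn(
                f"corpus exhausted with {mask.sum()} < {min_count} measures; "
                "using all records",
                stacklevel=2,
            )
            return values[mask]
        w *= 1.5


# ---------------------------------------------------------------------------
# constraint terms


def _excluded_stem_pairs(model: CoarseGrainModel) -> set[frozenset]:
    """Stem pairs sharing a connector element are not clash-checked."""
    g = model.graph
    out: set[frozenset] = set()
    for conn in g.connections.values():
        if conn.b is not None:
            out.add(frozenset((conn.a[0], conn.b[0])))
    return out


def clash_count(model: CoarseGrainModel, use_grid: bool = True) -> int:
    """Number of clashing virtual-atom pairs between non-adjacent stems."""
    pts, owner = model.virtual_atoms()
    if len(pts) == 0:
        return 0
    excluded = _excluded_stem_pairs(model)

    def pair_ok(i, j):
        a, b = owner[i], owner[j]
        return a != b and frozenset((a, b)) not in excluded

    count = 0
    if use_grid:
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(CLASH_DISTANCE):
            if pair_ok(i, j) and np.linalg.norm(pts[i] - pts[j]) < CLASH_DISTANCE:
                count += 1
    else:
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if pair_ok(i, j) and np.linalg.norm(
                    pts[i] - pts[j]
                ) < CLASH_DISTANCE:
                    count += 1
    return count


def clash_energy(model: CoarseGrainModel, use_grid: bool = True) -> float:
    """PENALTY per clashing atom pair; 0 for clash-free models."""
    return PENALTY * clash_count(model, use_grid)


def junction_energy(
    model: CoarseGrainModel, g0: float = 3.0, g1: float = 6.5
) -> float:
    """PENALTY per break segment whose gap exceeds the closure limit."""
    total = 0.0
    for name in model.graph.break_names:
        n = model.graph.elements[name].size
        if junction_gap(model, name) > closure_limit(n, g0, g1):
            total += PENALTY
    return total


# ---------------------------------------------------------------------------
# knowledge-based measures


def radius_of_gyration(model: CoarseGrainModel) -> float:
    """Root mean squared distance of stem virtual residues from their
    centroid; loops are excluded."""
    pts = model.stem_positions()
    if len(pts) == 0:
        raise ValueError("model has no stems")
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt((centred**2).sum(axis=1).mean()))


def loop_loop_distance(model: CoarseGrainModel, hairpin: str) -> float:
    """Distance from one hairpin's anchor to its nearest other hairpin."""
    g = model.graph
    if g.elements[hairpin].kind != "hairpin":
        raise ValueError(f"{hairpin!r} is not a hairpin")
    others = [
        n
        for n, e in g.elements.items()
        if e.kind == "hairpin" and n != hairpin
    ]
    if not others:
        raise ValueError("loop-loop distance needs at least two hairpins")
    mine = model.loop_anchors[hairpin][1]
    return min(
        float(np.linalg.norm(mine - model.loop_anchors[o][1])) for o in others
    )


# ---------------------------------------------------------------------------
# A-minor


@dataclass(frozen=True)
class AminorGeometry:
    """(d, phi, psi) of a candidate loop-stem interaction.

    d: closest distance between the loop segment and the stem axis; phi:
    angle between the element direction vectors; psi: angle between the
    interaction vector and the stem's minor-groove direction at the
    closest axis point.
    """

    d: float
    phi: float
    psi: float

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("d must be non-negative")
        for name in ("phi", "psi"):
            if not -1e-9 <= getattr(self, name) <= np.pi + 1e-9:
                raise ValueError(f"{name} must lie in [0, pi]")

    def as_array(self):
        return np.array([self.d, self.phi, self.psi])


def _closest_points_segments(p0, p1, q0, q1):
    """Closest points of segments [p0,p1] and [q0,q1].

    Returns (distance, point on P, point on Q, parameter t on Q in [0,1]).
    """
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = np.dot(d1, d1)
    e = np.dot(d2, d2)
    f = np.dot(d2, r)
    EPS = 1e-14
    if a <= EPS and e <= EPS:
        s = t = 0.0
    elif a <= EPS:
        s = 0.0
        t = np.clip(f / e, 0.0, 1.0)
    else:
        c = np.dot(d1, r)
        if e <= EPS:
            t = 0.0
            s = np.clip(-c / a, 0.0, 1.0)
        else:
            b = np.dot(d1, d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > EPS else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t = 1.0
                s = np.clip((b - c) / a, 0.0, 1.0)
    cp = p0 + s * d1
    cq = q0 + t * d2
    return float(np.linalg.norm(cp - cq)), cp, cq, float(t)


def aminor_geometry(
    loop_points: tuple[np.ndarray, np.ndarray],
    stem,
    groove_offset: float = np.pi,
) -> AminorGeometry:
    """Geometric parameters of a loop-stem pair.

    ``loop_points`` are the two endpoints of the loop's segment
    representation; ``stem`` is a StemCylinder.  The minor-groove
    direction is the interpolated twist at the closest axis point rotated
    about the axis by ``groove_offset`` (default half a turn, i.e.
    opposite the C1' direction; an explicit approximation).
    """
    p0, p1 = (np.asarray(p, dtype=float) for p in loop_points)
    d, cp, cq, t_axis = _closest_points_segments(p0, p1, stem.a_s, stem.a_e)

    loop_dir = p1 - p0
    if np.linalg.norm(loop_dir) < 1e-12:
        phi = 0.0
    else:
        cosphi = np.dot(loop_dir / np.linalg.norm(loop_dir), stem.axis)
        phi = float(np.arccos(np.clip(cosphi, -1.0, 1.0)))

    if d < 1e-12:
        psi = 0.0
    else:
        w = rotation_about_axis(
            stem.axis, t_axis * stem.total_twist() + groove_offset
        ) @ stem.t_s
        inter = (cq - cp) / d
        psi = float(np.arccos(np.clip(np.dot(inter, w), -1.0, 1.0)))
    return AminorGeometry(d, phi, psi)


@dataclass
class AminorModel:
    """Bayes model of A-minor interaction probability for one loop kind.

    P(I | d, phi, psi) = P(I) * p(d, phi, psi | I) / p(d, phi, psi),
    with both densities 3D product-kernel Gaussian KDEs.
    """

    density_interacting: GaussianKDE
    density_all: GaussianKDE
    prior: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.prior <= 1.0:
            raise ValueError("prior must lie in [0, 1]")

    @classmethod
    def fit(cls, interacting_samples, all_samples, prior: float = 0.2):
        return cls(
            GaussianKDE(interacting_samples),
            GaussianKDE(all_samples),
            prior,
        )


def aminor_probability(geom: AminorGeometry, model: AminorModel) -> float:
    """P(I) p(d,phi,psi | I) / p(d,phi,psi), clamped to [0, 1]."""
    x = geom.as_array()[None, :]
    p_i = float(model.density_interacting.evaluate(x)[0])
    p_all = float(model.density_all.evaluate(x)[0])
    if p_i <= 0.0:
        return 0.0
    if p_all <= 0.0:
        return 1.0
    return float(np.clip(model.prior * p_i / p_all, 0.0, 1.0))


def loop_segment(model: CoarseGrainModel, name: str):
    """Segment representation of a loop element.

    Hairpins and 5'/3' regions span attachment to anchor; an interior
    loop spans the two connected stem-end axis points.
    """
    g = model.graph
    elem = g.elements[name]
    if elem.kind == "interior_loop":
        conn = g.connections[name]
        (sa, ea), (sb, eb) = conn.a, conn.b
        return (
            model.stems[sa].end_point(ea),
            model.stems[sb].end_point(eb),
        )
    return model.loop_anchors[name]


def expected_aminor(
    model: CoarseGrainModel,
    loop: str,
    amodel: AminorModel,
    cutoff: float = AMINOR_CUTOFF,
    groove_offset: float = np.pi,
) -> float:
    """Expected number of A-minor interactions of one donor loop.

    Sums the interaction probability over every stem that is not
    directly connected to the loop and lies within ``cutoff`` (default
    30 A, beyond which the probability is negligible).
    """
    g = model.graph
    kind = g.elements[loop].kind
    if kind not in ("hairpin", "interior_loop"):
        raise ValueError("A-minor donors are hairpins or interior loops")
    adjacent = set(g.neighbours(loop))
    seg = loop_segment(model, loop)
    total = 0.0
    for stem_name, cyl in model.stems.items():
        if stem_name in adjacent:
            continue
        geom = aminor_geometry(seg, cyl, groove_offset)
        if geom.d > cutoff:
            continue
        total += aminor_probability(geom, amodel)
    return total


def aminor_candidates(graph, sequence: str | None = None) -> list[str]:
    """Hairpins and interior loops qualifying as A-minor donors.

    With a sequence, loops must contain at least one adenine; without
    one, every hairpin/interior loop qualifies.
    """
    out = []
    for name, elem in graph.elements.items():
        if elem.kind not in ("hairpin", "interior_loop"):
            continue
        if sequence is not None and not any(
            sequence[i - 1].upper() == "A" for i in elem.nucleotides
        ):
            continue
        out.append(name)
    return sorted(out, key=lambda n: (n[0], int(n[1:])))


# ---------------------------------------------------------------------------
# assembled energy function


@dataclass
class EnergyTerm:
    """One knowledge-based term: a measure plus its distributions."""

    name: str
    measure: object  # callable CoarseGrainModel -> float
    dist: MeasureDistribution

    def __call__(self, model) -> float:
        return self.dist.energy(self.measure(model))


@dataclass
class EnergyFunction:
    """Sum of constraint penalties and reference-ratio terms.

    One radius-of-gyration term, one loop-loop term per hairpin (when
    the model has at least two), and one A-minor term per qualifying
    hairpin and interior loop -- a separate term instance per element.
    ``use_constraints=False`` with no terms gives the constant-zero
    energy (every proposal accepted; direct sampling of the proposal
    distribution).
    """

    terms: list[EnergyTerm] = field(default_factory=list)
    use_constraints: bool = True
    closure_g0: float = 3.0
    closure_g1: float = 6.5

    def constraint_energy(self, model) -> float:
        return clash_energy(model) + junction_energy(
            model, self.closure_g0, self.closure_g1
        )

    def evaluate(self, model) -> float:
        total = self.constraint_energy(model) if self.use_constraints else 0.0
        for term in self.terms:
            total += term(model)
        return float(total)

    __call__ = evaluate

    def evaluate_with_measures(self, model):
        """(total energy, measure values) in one pass over the terms."""
        measures: dict[str, float] = {}
        total = self.constraint_energy(model) if self.use_constraints else 0.0
        for term in self.terms:
            x = float(term.measure(model))
            measures[term.name] = x
            total += term.dist.energy(x)
        return float(total), measures

    def measures(self, model) -> dict[str, float]:
        return {t.name: float(t.measure(model)) for t in self.terms}

    def update_references(self, measures: dict[str, float]) -> None:
        for t in self.terms:
            if t.name in measures:
                update_reference(t.dist, [measures[t.name]])

    @classmethod
    def zero(cls) -> "EnergyFunction":
        return cls(terms=[], use_constraints=False)

    @classmethod
    def constraints_only(cls) -> "EnergyFunction":
        return cls(terms=[], use_constraints=True)


def load_measure_corpus(path) -> dict[str, np.ndarray]:
    """Measure corpus file -> measure name -> (length, value) records.

    Lines are ``structure_id length measure_name value``; '#' comments.
    """
    out: dict[str, list] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'id length measure value'"
                )
            _, length, measure, value = parts
            out.setdefault(measure, []).append(
                (float(length), float(value))
            )
    return {k: np.array(v, dtype=float) for k, v in out.items()}


def save_measure_corpus(records: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        fh.write("# helixcg-measures 1\n")
        for measure in sorted(records):
            for length, value in records[measure]:
                fh.write(f"x {length!r} {measure} {value!r}\n")


def assemble_energy(
    graph,
    target_corpora: dict[str, np.ndarray],
    reference_models,
    aminor_models: dict[str, AminorModel] | None = None,
    c: float = 1.0,
    min_count: int = 500,
    window: float = 0.01,
) -> EnergyFunction:
    """Build the full energy function for one structure.

    ``target_corpora`` maps measure names ('rog', 'loop_loop',
    'aminor_hairpin', 'aminor_interior_loop') to (length, value)
    records; targets are length-windowed around the structure's size.
    ``reference_models`` (proposal-only builds) seed the reference
    distributions.  One term instance is created per applicable element.
    """
    n = graph.length
    hairpins = sorted(
        (nm for nm, e in graph.elements.items() if e.kind == "hairpin"),
        key=lambda s: int(s[1:]),
    )
    terms: list[EnergyTerm] = []

    def make_term(name, measure_fn, corpus_key):
        target = build_target_distribution(
            target_corpora[corpus_key], n, min_count, window
        )
        reference = np.array([measure_fn(m) for m in reference_models])
        terms.append(
            EnergyTerm(
                name,
                measure_fn,
                MeasureDistribution(name, target, reference, c=c),
            )
        )

    if "rog" in target_corpora:
        make_term("rog", radius_of_gyration, "rog")
    if "loop_loop" in target_corpora and len(hairpins) >= 2:
        for h in hairpins:
            make_term(
                f"loop_loop_{h}",
                lambda m, h=h: loop_loop_distance(m, h),
                "loop_loop",
            )
    if aminor_models:
        for loop in aminor_candidates(graph, graph.sequence):
            kind = graph.elements[loop].kind
            amodel = aminor_models.get(kind)
            key = f"aminor_{'hairpin' if kind == 'hairpin' else 'interior_loop'}"
            if amodel is None or key not in target_corpora:
                continue
            make_term(
                f"aminor_{loop}",
                lambda m, loop=loop, amodel=amodel: expected_aminor(
                    m, loop, amodel
                ),
                key,
            )
    return EnergyFunction(terms=terms)
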
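"""Inter-helical and loop-placement statistics: the proposal distribution.

The placement of one stem relative to its predecessor is encoded by six
parameters: the separation ``r`` of the two connecting axis endpoints,
polar/azimuthal angles ``(u, v)`` of the separation vector in the
predecessor's end frame (outward axis, end twist, their cross product),
polar/azimuthal angles ``(u_p, v_p)`` of the new stem's inward axis in
the same frame, and ``t``, the rotation of the new stem's connecting
twist about its own axis relative to a reference twist transported from
the predecessor.  Drawing a stored tuple is the coarse-grain analogue of
inserting a fragment.

Statistics are bucketed by element kind and size (ordered strand-length
pair for interior loops, nucleotide count for multiloop segments and
loops) and may be mined from threaded structures or synthesised.  The
synthetic generator perturbs coaxial/ideal arrangements with configured
angular dispersion and size-scaled separations, and rejects tuples whose
canonical two-stem placement clashes or leaves an unbridgeable backbone
gap, emulating the pruning of sterically impossible fragments.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .helix_geometry import (
    AFormTemplate,
    DEFAULT_TEMPLATE,
    StemCylinder,
    corner_atom,
    signed_angle,
)

__all__ = [
    "InterhelixParams",
    "LoopPlacement",
    "StatsTable",
    "SynthConfig",
    "extract_interhelix",
    "sample_interhelix",
    "sample_loop",
    "sample_stem",
    "synthesize_stats",
    "load_stats",
    "save_stats",
    "extract_stats_from_model",
]

_TWO_PI = 2.0 * np.pi


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + np.pi) % _TWO_PI - np.pi
    return np.pi if a <= -np.pi else float(a)


@dataclass(frozen=True)
class InterhelixParams:
    """Six-parameter relative placement of a stem w.r.t. its predecessor."""

    r: float
    u: float
    v: float
    u_p: float
    v_p: float
    t: float

    def __post_init__(self):
        if self.r < 0:
            raise ValueError("separation r must be non-negative")
        for name in ("u", "u_p"):
            if not 0 <= getattr(self, name) <= np.pi + 1e-12:
                raise ValueError(f"{name} must lie in [0, pi]")
        for name in ("v", "v_p", "t"):
            val = getattr(self, name)
            if not -np.pi - 1e-12 < val <= np.pi + 1e-12:
                raise ValueError(f"{name} must lie in (-pi, pi]")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.u, self.v, self.u_p, self.v_p, self.t])

    @classmethod
    def from_array(cls, a) -> "InterhelixParams":
        return cls(*map(float, a))


@dataclass(frozen=True)
class LoopPlacement:
    """Direction (unit vector in the attached stem's end frame) + length."""

    direction: tuple[float, float, float]
    length: float

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("loop direction must be a unit vector")
        if self.length < 0:
            raise ValueError("loop length must be non-negative")
        object.__setattr__(self, "direction", tuple(map(float, d)))

    def as_array(self) -> np.ndarray:
        return np.array([*self.direction, self.length])


@dataclass
class StatsTable:
    """Bucketed placement statistics plus model constants.

    ``interhelix`` maps ('i', (la, lb)) or ('m', n) to arrays of six
    parameters per row; ``loops`` maps ('h'|'f'|'t', n) to rows of
    (dx, dy, dz, length); ``stems`` maps a base-pair count to rows of
    (rise A, twist rad).
    """

    interhelix: dict[tuple, np.ndarray] = field(default_factory=dict)
    loops: dict[tuple, np.ndarray] = field(default_factory=dict)
    stems: dict[int, np.ndarray] = field(default_factory=dict)
    provenance: str = "unspecified"
    template: AFormTemplate = field(default=DEFAULT_TEMPLATE)
    aminor_prior: dict[str, float] = field(
        default_factory=lambda: {"hairpin": 0.2, "interior_loop": 0.2}
    )


def _frame(cyl: StemCylinder, end: int):
    return cyl.end_frame(end)


def _spherical(F: np.ndarray, vec: np.ndarray) -> tuple[float, float]:
    """(polar, azimuth) of a unit vector in frame F (rows e1, e2, e3)."""
    local = F @ vec
    polar = float(np.arccos(np.clip(local[0], -1.0, 1.0)))
    azim = float(np.arctan2(local[2], local[1]))
    if np.hypot(local[1], local[2]) < 1e-12:
        azim = 0.0
    return polar, _wrap_angle(azim)


def _reference_twist(e2: np.ndarray, e3: np.ndarray, axis: np.ndarray):
    """End twist of the predecessor transported perpendicular to ``axis``."""
    w = e2 - np.dot(e2, axis) * axis
    if np.linalg.norm(w) < 1e-9:
        w = e3 - np.dot(e3, axis) * axis
    return w / np.linalg.norm(w)


def extract_interhelix(
    cyl1: StemCylinder,
    cyl2: StemCylinder,
    connection: tuple[int, int],
) -> InterhelixParams:
    """Parameters of cyl2 relative to cyl1; exact inverse of place_stem.

    ``connection`` is the corner pattern (corner of cyl1, corner of
    cyl2) the linking element attaches to; corners select the end and
    the strand-adjusted twist of the placement frames.
    """
    from .helix_geometry import CORNER_END, CORNER_SIGN

    ca, cb = connection
    o, F = cyl1.corner_frame(ca)
    e1, e2, e3 = F
    eb = CORNER_END[cb]
    pos = cyl2.end_point(eb)
    sep = pos - o
    r = float(np.linalg.norm(sep))
    if r > 1e-12:
        u, v = _spherical(F, sep / r)
    else:
        u = v = 0.0
    inward = -cyl2.outward_axis(eb)
    u_p, v_p = _spherical(F, inward)
    w_ref = _reference_twist(e2, e3, inward)
    w_actual = CORNER_SIGN[cb] * cyl2.end_twist(eb)
    t = _wrap_angle(signed_angle(w_ref, w_actual, inward))
    return InterhelixParams(r, u, v, u_p, v_p, t)


def _resolve_bucket(table: dict, kind: str, size, what: str):
    exact = (kind, size)
    if exact in table and len(table[exact]):
        return table[exact]
    candidates = [k for k in table if k[0] == kind and len(table[k])]
    if not candidates:
        raise KeyError(
            f"no {what} statistics for element kind {kind!r} "
            f"(requested size {size!r})"
        )

    if kind == "i":
        want = tuple(size)

        def dist_key(key):
            got = key[1]
            d = abs(got[0] - want[0]) + abs(got[1] - want[1])
            return (d, got[0] + got[1], got)

    else:
        want = int(size)

        def dist_key(key):
            return (abs(key[1] - want), key[1])

    best = min(candidates, key=dist_key)
    return table[best]


def sample_interhelix(
    table: StatsTable, kind: str, size, rng: np.random.Generator
) -> InterhelixParams:
    """Uniform draw from the best-matching size bucket (ties to smaller)."""
    rows = _resolve_bucket(table.interhelix, kind, size, "interhelix")
    row = rows[rng.integers(len(rows))]
    return InterhelixParams.from_array(row)


def sample_loop(
    table: StatsTable, kind: str, size: int, rng: np.random.Generator
) -> LoopPlacement:
    rows = _resolve_bucket(table.loops, kind, size, "loop")
    row = rows[rng.integers(len(rows))]
    return LoopPlacement(tuple(row[:3]), float(row[3]))


def sample_stem(
    table: StatsTable, n_bp: int, rng: np.random.Generator
) -> tuple[float, float]:
    """(rise, twist) draw for a stem of ``n_bp`` base pairs."""
    if not table.stems:
        tpl = table.template
        return tpl.rise, tpl.twist
    sizes = sorted(table.stems)
    best = min(sizes, key=lambda s: (abs(s - n_bp), s))
    rows = table.stems[best]
    row = rows[rng.integers(len(rows))]
    return float(row[0]), float(row[1])


# ---------------------------------------------------------------------------
# synthetic statistics generator


@dataclass(frozen=True)
class SynthConfig:
    """Settings of the synthetic-statistics generator.

    ``angular_dispersion`` (rad) scales the spread of the placed stem's
    axis orientation away from coaxial; separations grow linearly with
    the connecting element's nucleotide count.
    """

    count: int = 40
    angular_dispersion: float = 0.35
    interior_strand_max: int = 6
    multiloop_max_nt: int = 8
    hairpin_min: int = 3
    hairpin_max: int = 10
    end_region_max: int = 8
    stem_min_bp: int = 2
    stem_max_bp: int = 12
    rise_sd: float = 0.03
    twist_sd: float = np.deg2rad(0.6)
    # junction-closure limit used when pruning multiloop fragments
    closure_g0: float = 3.0
    closure_g1: float = 6.5


def _fold_polar(x: float) -> float:
    """Fold a real draw into [0, pi]."""
    x = abs(x) % _TWO_PI
    return float(x if x <= np.pi else _TWO_PI - x)


def _make_stem(template: AFormTemplate, n_bp: int = 8) -> StemCylinder:
    from .helix_geometry import rotation_about_axis

    axis = np.array([0.0, 0.0, 1.0])
    t_s = np.array([1.0, 0.0, 0.0])
    t_e = rotation_about_axis(axis, (n_bp - 1) * template.twist) @ t_s
    return StemCylinder(
        np.zeros(3),
        (n_bp - 1) * template.rise * axis,
        t_s,
        t_e,
        n_bp,
        template,
    )


#: the three multiloop corner patterns: c2->c1 (inner-to-child), c4->c1
#: (sibling-to-sibling), c4->c3 (last child to the closing stem)
MULTILOOP_PATTERNS = ((2, 1), (4, 1), (4, 3))


def _pattern_gap(prev, new, pattern) -> float:
    """Junction O3'->P gap of one placed pattern (exit on prev)."""
    c_exit, c_entry = pattern
    o3 = corner_atom(prev, c_exit, "O3'")
    p = corner_atom(new, c_entry, "P")
    return float(np.linalg.norm(o3 - p))


def _stems_clash(prev: StemCylinder, new: StemCylinder, threshold: float):
    """Any virtual-atom contact below threshold, ignoring the two
    interface base pairs at the connected ends."""
    from .helix_geometry import virtual_residues

    def atoms(cyl, skip_bp):
        pts = []
        for k, vr in enumerate(virtual_residues(cyl)):
            if k == skip_bp:
                continue
            pts.extend(vr.atoms.values())
        return np.array(pts)

    a = atoms(prev, prev.n_bp - 1)
    b = atoms(new, 0)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return bool((d2 < threshold * threshold).any())


def _draw_interhelix(
    rng, template, cfg, kind: str, n_total: int
) -> InterhelixParams:
    disp = cfg.angular_dispersion
    if kind == "i":
        r_mean = template.rise + 0.35 * n_total
        r = max(0.0, rng.normal(r_mean, 0.15 + 0.03 * n_total))
        u = _fold_polar(rng.normal(0.0, 0.15 + 0.04 * n_total))
        u_p = _fold_polar(rng.normal(0.0, disp * (1.0 + 0.1 * n_total)))
        t = _wrap_angle(template.twist + rng.normal(0.0, 0.3 + 0.05 * n_total))
    else:
        r_mean = template.rise + 0.9 * n_total
        r = max(0.0, rng.normal(r_mean, 0.3 + 0.12 * n_total))
        u = _fold_polar(rng.normal(0.0, 0.3 + 0.12 * n_total))
        u_p = _fold_polar(rng.normal(0.0, disp * (1.2 + 0.3 * n_total)))
        t = _wrap_angle(template.twist + rng.normal(0.0, 0.3 + 0.1 * n_total))
    v = _wrap_angle(rng.uniform(-np.pi, np.pi))
    v_p = _wrap_angle(rng.uniform(-np.pi, np.pi))
    return InterhelixParams(r, u, v, u_p, v_p, t)


def synthesize_stats(
    config: SynthConfig | None = None,
    rng: np.random.Generator | None = None,
    template: AFormTemplate = DEFAULT_TEMPLATE,
) -> StatsTable:
    """Generate a synthetic StatsTable emulating mined fragment statistics.

    Interior-loop and multiloop tuples perturb a coaxial-stack baseline;
    multiloop tuples are additionally rejected unless the implied
    junction backbone gap is comfortably bridgeable for every connection
    pattern, and interior-loop tuples unless a canonical two-stem
    placement is clash-free.
    """
    from .model_builder import place_stem  # deferred: avoids import cycle

    cfg = config or SynthConfig()
    rng = rng or np.random.default_rng(0)
    table = StatsTable(provenance="synthetic", template=template)
    prev = _make_stem(template)

    def accept(kind, params, n_total):
        stem_p = (template.rise, template.twist)
        if kind == "m":
            # the same tuple may realize any of the three corner
            # patterns, so its gap must be bridgeable for each
            limit = cfg.closure_g0 + cfg.closure_g1 * n_total
            for pattern in MULTILOOP_PATTERNS:
                new = place_stem(prev, pattern, params, stem_p, 8)
                if _pattern_gap(prev, new, pattern) > 0.85 * limit:
                    return False
                if _stems_clash(prev, new, 2.0):
                    return False
            return True
        new = place_stem(prev, (2, 1), params, stem_p, 8)
        return not _stems_clash(prev, new, 2.0)

    def fill(kind, size, n_total):
        rows = []
        tries = 0
        while len(rows) < cfg.count and tries < 200 * cfg.count:
            tries += 1
            p = _draw_interhelix(rng, template, cfg, kind, n_total)
            if accept(kind, p, n_total):
                rows.append(p.as_array())
        if not rows:  # pragma: no cover - generator defaults always fill
            raise RuntimeError(f"could not fill bucket ({kind}, {size})")
        table.interhelix[(kind, size)] = np.array(rows)

    for la in range(cfg.interior_strand_max + 1):
        for lb in range(cfg.interior_strand_max + 1):
            if la == 0 and lb == 0:
                continue
            fill("i", (la, lb), la + lb)
    for n in range(cfg.multiloop_max_nt + 1):
        fill("m", n, n)

    def loop_rows(n, base, per_nt, spread):
        rows = []
        for _ in range(cfg.count):
            polar = _fold_polar(rng.normal(0.0, spread))
            azim = rng.uniform(-np.pi, np.pi)
            d = np.array(
                [
                    np.cos(polar),
                    np.sin(polar) * np.cos(azim),
                    np.sin(polar) * np.sin(azim),
                ]
            )
            length = max(0.5, rng.normal(base + per_nt * n, 0.4))
            rows.append([*d, length])
        return np.array(rows)

    for n in range(cfg.hairpin_min, cfg.hairpin_max + 1):
        table.loops[("h", n)] = loop_rows(n, 1.0, 0.6, 0.45)
    for n in range(1, cfg.end_region_max + 1):
        table.loops[("f", n)] = loop_rows(n, 2.0, 1.0, 0.8)
        table.loops[("t", n)] = loop_rows(n, 2.0, 1.0, 0.8)

    for n_bp in range(cfg.stem_min_bp, cfg.stem_max_bp + 1):
        rises = rng.normal(template.rise, cfg.rise_sd, cfg.count)
        twists = rng.normal(template.twist, cfg.twist_sd, cfg.count)
        table.stems[n_bp] = np.column_stack([rises, twists])
    return table


# ---------------------------------------------------------------------------
# stats file I/O (line-oriented text; sections [config]/[interhelix]/
# [loops]/[stems]; '#' comments)

_MAGIC = "# helixcg-stats 1"


def save_stats(table: StatsTable, path) -> None:
    buf = io.StringIO()
    buf.write(_MAGIC + "\n")
    buf.write(f"# provenance: {table.provenance}\n")
    tpl = table.template
    buf.write("[config]\n")
    buf.write(f"rise {tpl.rise!r}\n")
    buf.write(f"twist_deg {float(np.rad2deg(tpl.twist))!r}\n")
    buf.write(f"c1_radius {tpl.c1_radius!r}\n")
    buf.write(f"linkage {tpl.linkage!r}\n")
    buf.write(f"template_version {tpl.version}\n")
    for kind, prior in sorted(table.aminor_prior.items()):
        buf.write(f"aminor_prior_{kind} {prior!r}\n")
    buf.write("[interhelix]\n")
    for key in sorted(table.interhelix, key=_key_sort):
        kind, size = key
        sizes = " ".join(map(str, size)) if kind == "i" else str(size)
        for row in table.interhelix[key]:
            buf.write(f"{kind} {sizes} " + " ".join(repr(float(x)) for x in row) + "\n")
    buf.write("[loops]\n")
    for key in sorted(table.loops, key=_key_sort):
        kind, size = key
        for row in table.loops[key]:
            buf.write(f"{kind} {size} " + " ".join(repr(float(x)) for x in row) + "\n")
    buf.write("[stems]\n")
    for n_bp in sorted(table.stems):
        for row in table.stems[n_bp]:
            buf.write(f"{n_bp} " + " ".join(repr(float(x)) for x in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _key_sort(key):
    kind, size = key
    return (kind, size if isinstance(size, tuple) else (size,))


class StatsFormatError(ValueError):
    pass


def load_stats(path) -> StatsTable:
    """Parse a stats file; malformed lines raise with their line number."""
    table = StatsTable()
    config: dict[str, str] = {}
    section = None
    saw_stems_section = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[]")
                if section not in ("config", "interhelix", "loops", "stems"):
                    raise StatsFormatError(
                        f"line {lineno}: unknown section [{section}]"
                    )
                if section == "stems":
                    saw_stems_section = True
                continue
            parts = line.split()
            try:
                if section == "config":
                    config[parts[0]] = parts[1]
                elif section == "interhelix":
                    kind = parts[0]
                    if kind == "i":
                        size = (int(parts[1]), int(parts[2]))
                        vals = list(map(float, parts[3:9]))
                    elif kind == "m":
                        size = int(parts[1])
                        vals = list(map(float, parts[2:8]))
                    else:
                        raise StatsFormatError(
                            f"line {lineno}: unknown interhelix kind {kind!r}"
                        )
                    if len(vals) != 6:
                        raise ValueError("expected 6 parameters")
                    table.interhelix.setdefault((kind, size), []).append(vals)
                elif section == "loops":
                    kind = parts[0]
                    if kind not in ("h", "f", "t"):
                        raise StatsFormatError(
                            f"line {lineno}: unknown loop kind {kind!r}"
                        )
                    size = int(parts[1])
                    vals = list(map(float, parts[2:6]))
                    if len(vals) != 4:
                        raise ValueError("expected 4 values")
                    table.loops.setdefault((kind, size), []).append(vals)
                elif section == "stems":
                    n_bp = int(parts[0])
                    vals = list(map(float, parts[1:3]))
                    if len(vals) != 2:
                        raise ValueError("expected 2 values")
                    table.stems.setdefault(n_bp, []).append(vals)
                else:
                    raise StatsFormatError(
                        f"line {lineno}: data outside any section"
                    )
            except StatsFormatError:
                raise
            except Exception as exc:
                raise StatsFormatError(f"line {lineno}: {exc}") from exc

    for key in list(table.interhelix):
        table.interhelix[key] = np.array(table.interhelix[key], dtype=float)
    for key in list(table.loops):
        table.loops[key] = np.array(table.loops[key], dtype=float)
    for key in list(table.stems):
        table.stems[key] = np.array(table.stems[key], dtype=float)

    tpl_kwargs = {}
    if "rise" in config:
        tpl_kwargs["rise"] = float(config["rise"])
    if "twist_deg" in config:
        tpl_kwargs["twist"] = float(np.deg2rad(float(config["twist_deg"])))
    if "c1_radius" in config:
        tpl_kwargs["c1_radius"] = float(config["c1_radius"])
    if "linkage" in config:
        tpl_kwargs["linkage"] = float(config["linkage"])
    if "template_version" in config:
        tpl_kwargs["version"] = config["template_version"]
    table.template = replace(DEFAULT_TEMPLATE, **tpl_kwargs)
    for kind in ("hairpin", "interior_loop"):
        key = f"aminor_prior_{kind}"
        if key in config:
            table.aminor_prior[kind] = float(config[key])
    if "provenance" in config:
        table.provenance = config["provenance"]

    if not saw_stems_section:
        warnings.warn(
            "stats file has no [stems] section; substituting template "
            "rise/twist defaults",
            stacklevel=2,
        )
        tpl = table.template
        table.stems[2] = np.array([[tpl.rise, tpl.twist]])
    return table


# ---------------------------------------------------------------------------
# mining statistics from coarse-grain models (the threaded-structure path)


def extract_stats_from_model(model, table: StatsTable | None = None) -> StatsTable:
    """Append one model's placement parameters to a StatsTable.

    Walks every interior-loop/multiloop connector joining two stems with
    coordinates, every loop anchor, and every stem's rise/twist.
    """
    g = model.graph
    if table is None:
        table = StatsTable(provenance="extracted", template=model.template)
    for name, conn in g.connections.items():
        elem = g.elements[name]
        if elem.kind not in ("interior_loop", "multiloop_segment"):
            continue
        if conn.b is None:
            continue
        sa, sb = conn.a[0], conn.b[0]
        if sa not in model.stems or sb not in model.stems:
            continue
        params = extract_interhelix(
            model.stems[sa], model.stems[sb], conn.corners
        )
        kind = "i" if elem.kind == "interior_loop" else "m"
        key = (kind, elem.size_signature)
        rows = table.interhelix.get(key)
        row = params.as_array()[None, :]
        table.interhelix[key] = (
            row if rows is None or not len(rows) else np.vstack([rows, row])
        )
    for name, (attach, far) in model.loop_anchors.items():
        elem = g.elements[name]
        kind = {"hairpin": "h", "five_prime": "f", "three_prime": "t"}.get(
            elem.kind
        )
        if kind is None:
            continue
        conn = g.connections[name]
        stem, _end = conn.a
        if stem not in model.stems:
            continue
        _, F = model.stems[stem].corner_frame(conn.corner_a)
        vec = np.asarray(far) - np.asarray(attach)
        length = float(np.linalg.norm(vec))
        if length < 1e-9:
            continue
        local = F @ (vec / length)
        row = np.array([[*local, length]])
        key = (kind, elem.size)
        rows = table.loops.get(key)
        table.loops[key] = (
            row if rows is None or not len(rows) else np.vstack([rows, row])
        )
    for name, cyl in model.stems.items():
        rise = cyl.length / (cyl.n_bp - 1)
        twist = cyl.total_twist() / (cyl.n_bp - 1)
        row = np.array([[rise, twist]])
        rows = table.stems.get(cyl.n_bp)
        table.stems[cyl.n_bp] = (
            row if rows is None or not len(rows) else np.vstack([rows, row])
        )
    return table
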
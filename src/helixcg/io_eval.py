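"""File formats, PDB threading and coarse-grain RMSD.

The coarse-grain text format stores the dot-bracket, the element
defines, per-stem axis/twist coordinates and per-loop anchors; reading
rebuilds the skeleton graph from the dot-bracket and checks the defines
against it.  Threading fits stem cylinders onto an all-atom PDB
structure given a canonical base-pair list (two whitespace-separated
1-based residue indices per line).
"""

from __future__ import annotations

import warnings

import numpy as np

from .helix_geometry import BasePairFrame, StemCylinder, fit_cylinder
from .model_builder import CoarseGrainModel
from .ss_graph import (
    PairTable,
    SkeletonGraph,
    build_skeleton_graph,
    parse_dotbracket,
    remove_pseudoknots,
)

__all__ = [
    "CoarseGrainRecord",
    "read_cg",
    "write_cg",
    "model_to_record",
    "record_to_model",
    "thread_pdb",
    "cg_rmsd",
    "superpose",
    "read_pair_list",
    "detect_canonical_pairs",
    "parse_structure_input",
    "write_c1_pdb",
]

_MAGIC = "# helixcg-cg 1"


class CoarseGrainRecord:
    """Serializable coarse-grain model: graph defines plus coordinates."""

    def __init__(
        self,
        name: str,
        length: int,
        dotbracket: str,
        sequence: str | None = None,
        defines: dict[str, tuple[int, ...]] | None = None,
        coords: dict[str, tuple] | None = None,
        twists: dict[str, tuple] | None = None,
        anchors: dict[str, tuple] | None = None,
    ):
        self.name = name
        self.length = length
        self.dotbracket = dotbracket
        self.sequence = sequence
        self.defines = defines or {}
        self.coords = coords or {}
        self.twists = twists or {}
        self.anchors = anchors or {}


def _runs(nts: tuple[int, ...]) -> tuple[int, ...]:
    """Contiguous inclusive runs of an ordered index tuple, flattened."""
    if not nts:
        return ()
    out = [nts[0]]
    for prev, cur in zip(nts, nts[1:]):
        if cur != prev + 1:
            out.extend([prev, cur])
    out.append(nts[-1])
    return tuple(out)


def _graph_dotbracket(g: SkeletonGraph) -> str:
    chars = ["."] * g.length
    for e in g.elements.values():
        if e.kind == "stem":
            c1, c2, c3, c4 = e.corners
            for k in range(c2 - c1 + 1):
                chars[c1 - 1 + k] = "("
                chars[c4 - 1 - k] = ")"
    return "".join(chars)


def model_to_record(
    model: CoarseGrainModel, name: str = "model"
) -> CoarseGrainRecord:
    g = model.graph
    rec = CoarseGrainRecord(
        name=name,
        length=g.length,
        dotbracket=_graph_dotbracket(g),
        sequence=g.sequence,
    )
    for ename, elem in g.elements.items():
        rec.defines[ename] = _runs(elem.nucleotides)
    for sname, cyl in model.stems.items():
        rec.coords[sname] = (tuple(cyl.a_s), tuple(cyl.a_e))
        rec.twists[sname] = (tuple(cyl.t_s), tuple(cyl.t_e))
    for lname, (attach, far) in model.loop_anchors.items():
        rec.anchors[lname] = (tuple(attach), tuple(far))
    return rec


def record_to_model(
    rec: CoarseGrainRecord, require_coords: bool = True
) -> CoarseGrainModel:
    """Rebuild a model; graph-only records allowed with require_coords=False."""
    g = build_skeleton_graph(parse_dotbracket(rec.dotbracket), rec.sequence)
    for ename, elem in g.elements.items():
        want = rec.defines.get(ename)
        if want is not None and want != _runs(elem.nucleotides):
            raise ValueError(
                f"define mismatch for {ename}: file says {want}, "
                f"structure implies {_runs(elem.nucleotides)}"
            )
    model = CoarseGrainModel(graph=g)
    for sname in g.stems():
        if sname not in rec.coords:
            if require_coords:
                raise ValueError(f"missing coordinates for stem {sname}")
            continue
        (a_s, a_e) = rec.coords[sname]
        (t_s, t_e) = rec.twists[sname]
        model.stems[sname] = StemCylinder(
            np.array(a_s),
            np.array(a_e),
            np.array(t_s),
            np.array(t_e),
            g.elements[sname].n_bp,
        )
    for lname, (attach, far) in rec.anchors.items():
        model.loop_anchors[lname] = (np.array(attach), np.array(far))
    return model


def write_cg(record: CoarseGrainRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"name {record.name}\n")
        fh.write(f"length {record.length}\n")
        if record.sequence:
            fh.write(f"seq {record.sequence}\n")
        fh.write(f"sstruct {record.dotbracket}\n")
        for ename in sorted(record.defines):
            nums = " ".join(map(str, record.defines[ename]))
            fh.write(f"define {ename} {nums}".rstrip() + "\n")
        for sname in sorted(record.coords):
            (a_s, a_e) = record.coords[sname]
            fh.write(
                f"coord {sname} "
                + " ".join(repr(float(x)) for x in (*a_s, *a_e))
                + "\n"
            )
            (t_s, t_e) = record.twists[sname]
            fh.write(
                f"twist {sname} "
                + " ".join(repr(float(x)) for x in (*t_s, *t_e))
                + "\n"
            )
        for lname in sorted(record.anchors):
            (attach, far) = record.anchors[lname]
            fh.write(
                f"anchor {lname} "
                + " ".join(repr(float(x)) for x in (*attach, *far))
                + "\n"
            )


def read_cg(path) -> CoarseGrainRecord:
    """Parse a coarse-grain file; malformed lines raise with line number."""
    rec = CoarseGrainRecord(name="", length=0, dotbracket="")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            try:
                if tag == "name":
                    rec.name = parts[1] if len(parts) > 1 else ""
                elif tag == "length":
                    rec.length = int(parts[1])
                elif tag == "seq":
                    rec.sequence = parts[1]
                elif tag == "sstruct":
                    rec.dotbracket = parts[1]
                elif tag == "define":
                    rec.defines[parts[1]] = tuple(map(int, parts[2:]))
                elif tag == "coord":
                    vals = list(map(float, parts[2:8]))
                    if len(vals) != 6:
                        raise ValueError("expected 6 coordinates")
                    rec.coords[parts[1]] = (tuple(vals[:3]), tuple(vals[3:]))
                elif tag == "twist":
                    vals = list(map(float, parts[2:8]))
                    if len(vals) != 6:
                        raise ValueError("expected 6 components")
                    rec.twists[parts[1]] = (tuple(vals[:3]), tuple(vals[3:]))
                elif tag == "anchor":
                    vals = list(map(float, parts[2:8]))
                    if len(vals) != 6:
                        raise ValueError("expected 6 coordinates")
                    rec.anchors[parts[1]] = (tuple(vals[:3]), tuple(vals[3:]))
                else:
                    raise ValueError(f"unknown line tag {tag!r}")
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not rec.dotbracket:
        raise ValueError(f"{path}: missing sstruct line")
    if not rec.length:
        rec.length = len(rec.dotbracket)
    return rec


# ---------------------------------------------------------------------------
# PDB threading


def _pdb_residues(path):
    """Ordered standard residues of model 1 (first-come altloc)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", path)
    model = next(iter(structure))
    residues = []
    for chain in model:
        for res in chain:
            if res.id[0] != " ":
                continue
            residues.append((chain.id, res))
    return residues


def read_pair_list(path) -> list[tuple[int, int]]:
    pairs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two indices")
            pairs.append((int(parts[0]), int(parts[1])))
    return pairs


def thread_pdb(pdb_path, pairs: list[tuple[int, int]]) -> CoarseGrainModel:
    """Thread the coarse-grain model onto a known all-atom structure.

    ``pairs`` are 1-based sequential residue indices of canonical base
    pairs; pseudoknotted pairs are removed first (with a warning naming
    them).  Stems are fitted with fit_cylinder over the C1' positions of
    their base pairs; loop anchors run from the nearest stem-end axis
    point to the centroid of the loop's C1' atoms.
    """
    residues = _pdb_residues(pdb_path)
    n = len(residues)
    if not pairs:
        raise ValueError("empty base-pair list: no stems to thread")
    missing = [
        i + 1
        for i, (_, res) in enumerate(residues)
        if "C1'" not in res
    ]
    if missing:
        raise ValueError(
            f"residues without C1' atoms: {missing} (cannot coarse-grain)"
        )
    c1 = np.array([res["C1'"].coord for _, res in residues], dtype=float)
    chains = [cid for cid, _ in residues]
    seq = "".join(
        (res.get_resname().strip() or "N")[-1] for _, res in residues
    )

    pt = PairTable.from_pairs(n, pairs)
    nested = remove_pseudoknots(pt)
    removed = sorted(set(pt.pairs()) - set(nested.pairs()))
    if removed:
        warnings.warn(
            f"removed pseudoknotted pairs: {removed}", stacklevel=2
        )
    g = build_skeleton_graph(nested, sequence=seq)

    model = CoarseGrainModel(graph=g)
    for sname in g.stems():
        c1_, c2_, c3_, c4_ = g.elements[sname].corners
        for strand in (range(c1_, c2_ + 1), range(c3_, c4_ + 1)):
            ids = list(strand)
            if len({chains[i - 1] for i in ids}) > 1:
                raise ValueError(f"chain break inside stem {sname}")
        frames = [
            BasePairFrame(c1p_a=c1[c1_ + k - 1], c1p_b=c1[c4_ - k - 1])
            for k in range(c2_ - c1_ + 1)
        ]
        model.stems[sname] = fit_cylinder(frames)
    for lname, conn in g.connections.items():
        elem = g.elements[lname]
        if elem.kind not in ("hairpin", "five_prime", "three_prime"):
            continue
        if not elem.nucleotides:
            continue
        stem, end = conn.a
        attach = model.stems[stem].end_point(end)
        centroid = c1[[i - 1 for i in elem.nucleotides]].mean(axis=0)
        model.loop_anchors[lname] = (attach, centroid)
    return model


def detect_canonical_pairs(
    pdb_path,
    c1_window: tuple[float, float] = (8.8, 11.6),
    n_distance_max: float = 3.6,
) -> list[tuple[int, int]]:
    """Heuristic canonical-pair detector (geometric convenience only).

    Flags residue pairs whose C1'-C1' distance falls in the Watson-Crick
    window and whose glycosidic-face nitrogens (purine N1 / pyrimidine
    N3) approach within hydrogen-bonding range; greedy one-partner
    assignment by N-N distance.  Intended as a convenience when no
    curated pair list is available -- not a replacement for proper
    annotation.
    """
    residues = _pdb_residues(pdb_path)
    feats = []
    for idx, (_, res) in enumerate(residues, start=1):
        if "C1'" not in res:
            continue
        name = res.get_resname().strip().upper()
        natom = None
        if name.endswith(("A", "G")) and "N1" in res:
            natom = res["N1"].coord
        elif name.endswith(("C", "U", "T")) and "N3" in res:
            natom = res["N3"].coord
        if natom is None:
            continue
        feats.append((idx, np.asarray(res["C1'"].coord), np.asarray(natom)))
    candidates = []
    for a in range(len(feats)):
        for b in range(a + 1, len(feats)):
            i, c1a, na = feats[a]
            j, c1b, nb = feats[b]
            if abs(i - j) < 3:
                continue
            dc1 = np.linalg.norm(c1a - c1b)
            dn = np.linalg.norm(na - nb)
            if c1_window[0] <= dc1 <= c1_window[1] and dn <= n_distance_max:
                candidates.append((dn, i, j))
    used: set[int] = set()
    pairs = []
    for dn, i, j in sorted(candidates):
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append((i, j))
    return sorted(pairs)


def _coord_field(v: float) -> str:
    """An 8-character PDB coordinate field with maximal precision."""
    for dec in range(6, -1, -1):
        s = f"{v:8.{dec}f}"
        if len(s) == 8:
            return s
    raise ValueError(f"coordinate out of range: {v}")


def write_c1_pdb(coords: np.ndarray, path, resnames=None) -> None:
    """Write C1'-only ATOM records, one residue per coordinate.

    Coordinates are written with as many decimals as the fixed 8-column
    field allows, so near-origin fixtures round-trip tightly.
    """
    with open(path, "w") as fh:
        for i, xyz in enumerate(np.asarray(coords, dtype=float), start=1):
            resname = (resnames[i - 1] if resnames else "G").rjust(3)
            fields = "".join(_coord_field(v) for v in xyz)
            fh.write(
                f"ATOM  {i:5d}  C1' {resname} A{i:4d}    "
                f"{fields}  1.00  0.00           C\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# coarse RMSD


def superpose(P: np.ndarray, Q: np.ndarray):
    """Least-squares rigid superposition of Q onto P (Kabsch, SVD with
    determinant correction; reflection-free).

    Returns (rmsd, R, t) with R @ q + t aligning Q to P.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("point sets differ in shape")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    aligned = (R @ Q.T).T + t
    rmsd = float(np.sqrt(((aligned - P) ** 2).sum(axis=1).mean()))
    return rmsd, R, t


def _graphs_match(g1: SkeletonGraph, g2: SkeletonGraph) -> bool:
    if set(g1.elements) != set(g2.elements):
        return False
    for name, e1 in g1.elements.items():
        e2 = g2.elements[name]
        if e1.kind != e2.kind:
            return False
        if e1.kind == "stem" and e1.n_bp != e2.n_bp:
            return False
    return True


def cg_rmsd(m1: CoarseGrainModel, m2: CoarseGrainModel) -> float:
    """Coarse RMSD: optimal superposition of pooled stem virtual residues."""
    if not _graphs_match(m1.graph, m2.graph):
        raise ValueError(
            "models have different skeleton graphs; coarse RMSD undefined"
        )
    rmsd, _, _ = superpose(m1.stem_positions(), m2.stem_positions())
    return rmsd


# ---------------------------------------------------------------------------
# structure input


def parse_structure_input(text: str):
    """(name, sequence, dotbracket) from dot-bracket text with optional
    FASTA-style header and sequence line."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    name = "structure"
    if lines and lines[0].startswith(">"):
        name = lines[0][1:].strip() or name
        lines = lines[1:]
    if not lines:
        raise ValueError("no structure line found")
    structure_chars = set(".()[]{}<>")
    seq = None
    if len(lines) >= 2 and not set(lines[0]) <= structure_chars:
        seq = lines[0].upper()
        db = lines[1]
    else:
        db = lines[0]
    if seq is not None and len(seq) != len(db):
        raise ValueError("sequence and structure lengths differ")
    return name, seq, db
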
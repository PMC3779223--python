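"""Synthetic PASS2-like superfamilies with planted perturbations.

Real superfamily data (structures + a structure-based alignment) cannot be
bundled, so every recovery test runs on generated ensembles that emulate
the statistical shape of a superfamily: *n* members share a conserved Cα
core, each member gets small isotropic coordinate noise and an arbitrary
rigid frame, and selected members carry large planted perturbations —
multi-hinge rotations, insertions/deletions, circular permutation or
segment swaps — the same structural events that make real members deviate.
Every generated ensemble carries a complete ground-truth record, so tests
can ask "was the planted member recovered?" rather than eyeballing.

All randomness flows from one integer seed per spec through a single
`numpy` generator with a fixed draw order (core trace, then per member in
index order: per-atom noise, then the random rigid frame), so regenerating
with the same spec is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .go_semantics import GOOntology
from .structure_io import (
    GAP,
    DomainStructure,
    MultipleAlignment,
    write_alignment_fasta,
    write_calpha_pdb,
    write_family_labels,
)

#: Ideal consecutive Cα spacing in Å.
CA_SPACING = 3.8
#: Perturbation kinds that make a member a planted outlier.
BIG_KINDS = frozenset({"hinge", "circular_permutation", "segment_swap"})


# ---------------------------------------------------------------------------
# Core backbone tracer
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5
_HELIX_TURN = math.radians(100.0)
# radius chosen so consecutive points sit exactly CA_SPACING apart
_HELIX_RADIUS = math.sqrt(CA_SPACING**2 - _HELIX_RISE**2) \
    / (2.0 * math.sin(_HELIX_TURN / 2.0))
_STRAND_OFFSET = 0.95
_STRAND_RISE = math.sqrt(CA_SPACING**2 - (2.0 * _STRAND_OFFSET) ** 2)


def _helix_points(n: int) -> np.ndarray:
    i = np.arange(n)
    pts = np.stack([_HELIX_RADIUS * np.cos(_HELIX_TURN * i),
                    _HELIX_RADIUS * np.sin(_HELIX_TURN * i),
                    _HELIX_RISE * i], axis=1)
    return pts - pts[0]


def _strand_points(n: int) -> np.ndarray:
    i = np.arange(n)
    pts = np.stack([np.zeros(n),
                    _STRAND_OFFSET * np.where(i % 2 == 0, 1.0, -1.0),
                    _STRAND_RISE * i], axis=1)
    return pts - pts[0]


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +z onto *direction* (unit vector)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, direction))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, direction)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * math.acos(c)).as_matrix()


def _perp(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to v."""
    e = np.eye(3)[int(np.argmin(np.abs(v)))]
    p = np.cross(v, e)
    return p / np.linalg.norm(p)


def generate_core_backbone(length: int, seed: int) -> np.ndarray:
    """Self-avoiding smooth Cα trace of alternating helix/strand segments.

    Consecutive points are CA_SPACING (3.8 Å) apart to within 0.01 Å;
    non-consecutive points stay > ~2.4 Å apart (segment placements that
    would clash are redrawn).  Deterministic per (length, seed).
    """
    if length < 30:
        raise ValueError("core backbone needs length >= 30")
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    direction = np.array([0.0, 0.0, 1.0])
    helix = True
    while len(pts) < length:
        n_seg = int(rng.integers(8, 15) if helix else rng.integers(4, 8))
        n_seg = min(n_seg, length - len(pts))
        local = _helix_points(n_seg) if helix else _strand_points(n_seg)
        if not pts:
            pts.extend(local)
            helix = not helix
            continue
        old = np.asarray(pts)
        best_pts, best_sep = None, -np.inf
        for _ in range(200):
            bend = math.radians(float(rng.uniform(20.0, 70.0)))
            raw = rng.normal(size=3)
            perp = raw - np.dot(raw, direction) * direction
            if np.linalg.norm(perp) < 1e-9:
                perp = _perp(direction)
            perp /= np.linalg.norm(perp)
            new_dir = Rotation.from_rotvec(perp * bend).apply(direction)
            spin = Rotation.from_rotvec(
                new_dir * float(rng.uniform(0.0, 2.0 * math.pi)))
            cand = spin.apply(local @ _rotation_to(new_dir).T) \
                + old[-1] + CA_SPACING * new_dir
            # min separation from all previous points, ignoring the
            # chain-consecutive pair (cand[0], old[-1])
            d = np.linalg.norm(cand[:, None, :] - old[None, :, :], axis=2)
            d[0, -1] = np.inf
            sep = float(d.min())
            if sep > best_sep:
                best_pts, best_sep = cand, sep
                best_dir = new_dir
            if sep > 2.4:
                break
        pts.extend(best_pts)
        direction = best_dir
        helix = not helix
    return np.asarray(pts[:length])


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Perturbation:
    """One planted structural event; build via the classmethod factories."""

    kind: str
    params: tuple  # sorted (key, value) pairs, hashable

    def param(self, key: str):
        return dict(self.params)[key]

    @classmethod
    def noise(cls, sd: float) -> "Perturbation":
        if sd <= 0:
            raise ValueError("noise sd must be positive")
        return cls("noise", (("sd", float(sd)),))

    @classmethod
    def hinge(cls, start: int, stop: int, angle_deg: float,
              axis=None) -> "Perturbation":
        """Rotate residues [start, stop) about an axis through residue
        *start*.  axis: None (auto, perpendicular to the block span),
        'ortho' (perpendicular to the previous hinge's axis), or a
        3-vector."""
        if not 0.0 < angle_deg <= 180.0:
            raise ValueError("hinge angle must be in (0, 180] degrees")
        if stop <= start or start < 0:
            raise ValueError("invalid hinge range")
        if axis is not None and axis != "ortho":
            axis = tuple(float(x) for x in axis)
        return cls("hinge", (("angle_deg", float(angle_deg)),
                             ("axis", axis), ("start", int(start)),
                             ("stop", int(stop))))

    @classmethod
    def insertion(cls, position: int, length: int) -> "Perturbation":
        if length < 1 or position < 0:
            raise ValueError("invalid insertion")
        return cls("insertion", (("length", int(length)),
                                 ("position", int(position))))

    @classmethod
    def deletion(cls, position: int, length: int) -> "Perturbation":
        if length < 1 or position < 0:
            raise ValueError("invalid deletion")
        return cls("deletion", (("length", int(length)),
                                ("position", int(position))))

    @classmethod
    def circular_permutation(cls, shift: int) -> "Perturbation":
        if shift <= 0:
            raise ValueError("shift must be positive")
        return cls("circular_permutation", (("shift", int(shift)),))

    @classmethod
    def segment_swap(cls, range_a: tuple[int, int],
                     range_b: tuple[int, int]) -> "Perturbation":
        (a0, a1), (b0, b1) = range_a, range_b
        if a1 - a0 != b1 - b0 or a1 - a0 < 1:
            raise ValueError("segment swap ranges must be equal, non-empty")
        if not (a1 <= b0 or b1 <= a0):
            raise ValueError("segment swap ranges overlap")
        return cls("segment_swap", (("range_a", (int(a0), int(a1))),
                                    ("range_b", (int(b0), int(b1)))))

    def validate(self, core_length: int) -> None:
        p = dict(self.params)
        if self.kind == "hinge" and p["stop"] > core_length:
            raise ValueError("hinge range exceeds member length")
        if self.kind in ("insertion", "deletion") \
                and p["position"] > core_length:
            raise ValueError(f"{self.kind} position exceeds member length")
        if self.kind == "deletion" \
                and p["position"] + p["length"] > core_length:
            raise ValueError("deletion runs past member end")
        if self.kind == "circular_permutation" \
                and p["shift"] >= core_length:
            raise ValueError("shift must be smaller than member length")
        if self.kind == "segment_swap" \
                and max(p["range_a"][1], p["range_b"][1]) > core_length:
            raise ValueError("segment swap range exceeds member length")


def plant_two_hinge_outlier(core_length: int = 120) -> tuple[Perturbation, ...]:
    """Canonical heavy perturbation: two hinge rotations about orthogonal
    axes — residues [L/3, 2L/3) by 120° and [2L/3, L) by 150° — leaving a
    largest rigid block of L/3 so no single superposition fits well."""
    if core_length < 90:
        raise ValueError("two-hinge plan needs core_length >= 90")
    a = core_length // 3
    b = 2 * core_length // 3
    return (Perturbation.hinge(a, b, 120.0),
            Perturbation.hinge(b, core_length, 150.0, axis="ortho"))


# ---------------------------------------------------------------------------
# Superfamily generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic superfamily."""

    n_members: int
    core_length: int = 120
    noise_sd: float = 0.3
    outlier_plan: tuple = ()  # ((member_index, (Perturbation, ...)), ...)
    seed: int = 0
    family_plan: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("need >= 2 members")
        if self.core_length < 30:
            raise ValueError("core_length must be >= 30")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        plan = tuple((int(i), tuple(ps)) for i, ps in self.outlier_plan)
        for i, ps in plan:
            if not 0 <= i < self.n_members:
                raise ValueError(f"outlier index {i} out of range")
            for p in ps:
                p.validate(self.core_length)
        object.__setattr__(self, "outlier_plan", plan)

    def member_id(self, i: int) -> str:
        return f"mem{i:02d}"


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a generated superfamily."""

    planted_outliers: frozenset
    perturbations: Mapping[str, tuple]
    column_tags: tuple  # per column: ("core", pos) or ("ins", member, pos, j)
    family_branches: Mapping[str, int] | None = None


def _hinge_axis(axis_spec, block_vec: np.ndarray,
                prev_axis: np.ndarray | None) -> np.ndarray:
    v = block_vec / max(np.linalg.norm(block_vec), 1e-9)
    if axis_spec == "ortho" and prev_axis is not None:
        ax = np.cross(prev_axis, v)
        if np.linalg.norm(ax) > 1e-9:
            return ax / np.linalg.norm(ax)
    if isinstance(axis_spec, tuple):
        ax = np.asarray(axis_spec, dtype=float)
        return ax / np.linalg.norm(ax)
    return _perp(v)


def _insertion_loop(base: np.ndarray, direction: np.ndarray,
                    length: int) -> np.ndarray:
    """A semicircular excursion of *length* points leaving from *base*."""
    w = _perp(direction)
    radius = (CA_SPACING / 2.0) / math.sin(math.pi / (2 * (length + 1)))
    theta = math.pi * (np.arange(1, length + 1)) / (length + 1)
    return (base[None, :]
            + radius * np.sin(theta)[:, None] * direction[None, :]
            + radius * (1.0 - np.cos(theta))[:, None] * w[None, :])


def _apply_perturbations(coords: np.ndarray, perts: Sequence[Perturbation],
                         rng: np.random.Generator
                         ) -> tuple[np.ndarray, set, dict]:
    """Returns (perturbed core coords, deleted positions, insertions).

    *insertions* maps a core position p to the coordinates inserted
    *before* residue p (p == len(coords) appends at the C terminus).
    """
    coords = coords.copy()
    deleted: set[int] = set()
    insertions: dict[int, np.ndarray] = {}
    prev_axis: np.ndarray | None = None
    centroid = coords.mean(axis=0)
    for p in perts:
        d = dict(p.params)
        if p.kind == "noise":
            coords += rng.normal(0.0, d["sd"], coords.shape)
        elif p.kind == "hinge":
            start, stop = d["start"], d["stop"]
            block = coords[start:stop]
            axis = _hinge_axis(d["axis"], block[-1] - block[0], prev_axis)
            R = Rotation.from_rotvec(
                axis * math.radians(d["angle_deg"])).as_matrix()
            pivot = coords[start]
            coords[start:stop] = (block - pivot) @ R.T + pivot
            prev_axis = axis
        elif p.kind == "circular_permutation":
            coords = np.roll(coords, -d["shift"], axis=0)
        elif p.kind == "segment_swap":
            (a0, a1), (b0, b1) = d["range_a"], d["range_b"]
            block_a = coords[a0:a1].copy()
            coords[a0:a1] = coords[b0:b1]
            coords[b0:b1] = block_a
        elif p.kind == "deletion":
            deleted.update(range(d["position"],
                                 d["position"] + d["length"]))
        elif p.kind == "insertion":
            pos = d["position"]
            base = coords[pos - 1] if pos > 0 else coords[0]
            direction = base - centroid
            if np.linalg.norm(direction) < 1e-9:
                direction = np.array([0.0, 0.0, 1.0])
            direction = direction / np.linalg.norm(direction)
            insertions[pos] = _insertion_loop(base, direction, d["length"])
        else:  # pragma: no cover - factories prevent this
            raise ValueError(f"unknown perturbation kind {p.kind!r}")
    return coords, deleted, insertions


def make_superfamily(spec: SyntheticSpec) -> tuple[
        list[DomainStructure], MultipleAlignment, dict[str, str],
        SyntheticTruth]:
    """Generate structures, the true alignment, family labels and truth.

    Each member is the shared core plus isotropic Gaussian noise plus its
    planted perturbations, placed in a random rigid frame.  The alignment
    maps surviving core residues across members; insertion columns are
    gapped in every non-carrier, deletions are gapped in the carrier.
    Circular permutation and segment swap keep a *positionally naive*
    alignment (column i ↔ residue i), mirroring how a permuted member
    defeats a linear structure alignment and shows up as an outlier.
    """
    rng = np.random.default_rng(spec.seed)
    core = generate_core_backbone(spec.core_length, seed=spec.seed)
    plan = dict(spec.outlier_plan)
    L = spec.core_length

    per_member = []
    for i in range(spec.n_members):
        coords, deleted, ins = _apply_perturbations(
            core, plan.get(i, ()), rng)
        per_member.append((coords, deleted, ins))

    # column layout: insertion columns precede the core residue they sit at
    insert_at: dict[int, list[tuple[int, int]]] = {}
    for i, (_, _, ins) in enumerate(per_member):
        for pos, arr in ins.items():
            insert_at.setdefault(pos, []).append((i, len(arr)))
    column_tags: list[tuple] = []
    for p in range(L + 1):
        for mi, ln in insert_at.get(p, []):
            column_tags.extend(("ins", mi, p, j) for j in range(ln))
        if p < L:
            column_tags.append(("core", p))

    if sum(1 for t in column_tags if t[0] == "core") < 3:
        raise ValueError("perturbations would empty the common core")

    planted = frozenset(
        spec.member_id(i) for i, ps in plan.items()
        if any(p.kind in BIG_KINDS for p in ps))
    if spec.family_plan is not None:
        families = {spec.member_id(i): spec.family_plan[i]
                    for i in range(spec.n_members)}
    else:
        families = {spec.member_id(i): ("fam.dev" if spec.member_id(i)
                                        in planted else "fam.core")
                    for i in range(spec.n_members)}

    structures: list[DomainStructure] = []
    rows: dict[str, np.ndarray] = {}
    for i in range(spec.n_members):
        mid = spec.member_id(i)
        coords_core, deleted, ins = per_member[i]
        row = np.full(len(column_tags), GAP, dtype=int)
        member_xyz: list[np.ndarray] = []
        for c, tag in enumerate(column_tags):
            if tag[0] == "core":
                p = tag[1]
                if p in deleted:
                    continue
                row[c] = len(member_xyz)
                member_xyz.append(coords_core[p])
            else:
                _, mi, p, j = tag
                if mi == i:
                    row[c] = len(member_xyz)
                    member_xyz.append(ins[p][j])
        xyz = np.asarray(member_xyz)
        xyz = xyz + rng.normal(0.0, spec.noise_sd, xyz.shape)
        frame = Rotation.random(random_state=rng)
        xyz = frame.apply(xyz) + rng.uniform(-30.0, 30.0, 3)
        labels = tuple(f"A/ALA{k + 1}" for k in range(len(xyz)))
        structures.append(DomainStructure(mid, families[mid], labels, xyz))
        rows[mid] = row

    member_ids = tuple(spec.member_id(i) for i in range(spec.n_members))
    aln = MultipleAlignment(member_ids, rows)

    truth = SyntheticTruth(
        planted_outliers=planted,
        perturbations={spec.member_id(i): tuple(ps)
                       for i, ps in plan.items()},
        column_tags=tuple(column_tags))
    return structures, aln, families, truth


# ---------------------------------------------------------------------------
# Toy ontology with planted annotation structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationPlan:
    """Which DAG branch each family draws its terms from."""

    branch_terms: tuple  # per branch, the chain of term ids (shallow->deep)
    outlier_branch: int = 0

    def terms_for_branch(self, b: int, k: int = 2) -> frozenset:
        chain = self.branch_terms[b]
        return frozenset(chain[-k:])


ROOT_TERM = "GO:0000000"


def generate_toy_ontology(n_branches: int, depth: int, seed: int
                          ) -> tuple[GOOntology, AnnotationPlan]:
    """A single-root DAG of disjoint is_a chains, one per branch.

    Branches only meet at the root, so terms from different branches share
    no ancestry below it — annotating one family from a reserved branch
    makes it semantically remote from everyone else (the planted contrast
    used for outlier-vs-non-outlier comparisons; the reserved branch is
    ``outlier_branch``).  Non-reserved branches occasionally gain a
    ``part_of`` shortcut to a grandparent, exercising the second edge type.
    """
    if n_branches < 2 or depth < 2:
        raise ValueError("need n_branches >= 2 and depth >= 2")
    rng = np.random.default_rng(seed)
    terms = {ROOT_TERM: "root"}
    edges: list[tuple[str, str, str]] = []
    branch_terms = []
    for b in range(n_branches):
        chain = []
        prev = ROOT_TERM
        for d in range(1, depth + 1):
            t = f"GO:{(b + 1) * 10000 + d:07d}"
            terms[t] = f"branch{b} level{d}"
            edges.append((t, prev, "is_a"))
            chain.append(t)
            prev = t
        branch_terms.append(tuple(chain))
    for b in range(n_branches):
        if b == 0:
            continue  # keep the reserved branch a pure chain
        for d in range(3, depth + 1):
            if rng.random() < 0.3:
                edges.append((branch_terms[b][d - 1],
                              branch_terms[b][d - 3], "part_of"))
    onto = GOOntology.from_edges(terms, edges)
    return onto, AnnotationPlan(branch_terms=tuple(branch_terms))


def assign_annotations(families: Mapping[str, str],
                       outlier_families: frozenset | set,
                       plan: AnnotationPlan,
                       terms_per_member: int = 2) -> dict[str, frozenset]:
    """Give every member terms from its family's branch.

    Outlier families draw from the reserved branch; the remaining families
    cycle (in sorted order) over the other branches.
    """
    other_branches = [b for b in range(len(plan.branch_terms))
                      if b != plan.outlier_branch]
    fams = sorted(set(families.values()) - set(outlier_families))
    branch_of = {f: other_branches[i % len(other_branches)]
                 for i, f in enumerate(fams)}
    for f in outlier_families:
        branch_of[f] = plan.outlier_branch
    return {m: plan.terms_for_branch(branch_of[fam], terms_per_member)
            for m, fam in families.items()}


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def write_superfamily(out_dir, structures: Sequence[DomainStructure],
                      aln: MultipleAlignment, families: Mapping[str, str],
                      truth: SyntheticTruth | None = None) -> dict[str, Path]:
    """Write PDBs, the gapped FASTA alignment, family labels and truth."""
    out_dir = Path(out_dir)
    (out_dir / "pdb").mkdir(parents=True, exist_ok=True)
    paths = {}
    for s in structures:
        p = out_dir / "pdb" / f"{s.member_id}.pdb"
        write_calpha_pdb(p, s)
        paths[s.member_id] = p
    write_alignment_fasta(out_dir / "alignment.fasta", aln)
    paths["alignment"] = out_dir / "alignment.fasta"
    write_family_labels(out_dir / "families.tsv", families)
    paths["families"] = out_dir / "families.tsv"
    if truth is not None:
        p = out_dir / "truth.tsv"
        with open(p, "w") as fh:
            fh.write("member_id\tplanted_outlier\tperturbations\n")
            for s in structures:
                perts = truth.perturbations.get(s.member_id, ())
                desc = ";".join(
                    f"{q.kind}({','.join(f'{k}={v}' for k, v in q.params)})"
                    for q in perts)
                fh.write(f"{s.member_id}\t"
                         f"{int(s.member_id in truth.planted_outliers)}\t"
                         f"{desc}\n")
        paths["truth"] = p
    return paths
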
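"""Structural deviation statistics and outlier calling.

The deviation protocol mirrors the PASS2-style analysis of superfamily
divergence: after multiple superposition, every pair of members is
compared over its matched (pairwise ungapped) alignment columns to give a
symmetric RMSD matrix; each member's *mean RMSD* is the arithmetic mean of
its one-against-all row.  A member is called a structural outlier when its
mean RMSD exceeds 5.5 Å **and** its TM-score against the other members
(median over pairs) falls below 0.5 — high RMSD flags the deviation,
TM-score confirms that the member genuinely adopts a different fold rather
than, say, a long flexible tail inflating the RMSD.

Two screening heuristics annotate *why* a member deviates: gap-run
summaries (insertions / deletions / terminal extensions read off the
alignment) and a cyclic-shift scan that flags possible circular
permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import TooFewPointsError
from .structure_io import GAP, DomainStructure, MultipleAlignment
from .superposition import SuperposedEnsemble, kabsch, pair_columns

logger = logging.getLogger(__name__)

#: Mean one-against-all RMSD above which a member is an outlier candidate.
DEFAULT_RMSD_CUT = 5.5
#: TM-score below which an outlier candidate is confirmed.
DEFAULT_TM_CUT = 0.5


@dataclass(frozen=True)
class TMScoreParams:
    """TM-score constants.

    ``d0 = max(d0_floor, c1 * (L_N - c2)^(1/3) - c3)`` with coefficients
    ``(c1, c2, c3) = (1.24, 15, 1.8)``; the cube-root formula goes negative
    for targets shorter than ~21 residues, hence the floor.
    ``normalization_rule`` selects the target length L_N.
    """

    d0_coefficients: tuple[float, float, float] = (1.24, 15.0, 1.8)
    d0_floor: float = 0.5
    normalization_rule: str = "shorter"  # shorter | longer | first | second

    def d0(self, target_length: int) -> float:
        c1, c2, c3 = self.d0_coefficients
        return max(self.d0_floor, c1 * np.cbrt(target_length - c2) - c3)

    def target_length(self, len_a: int, len_b: int) -> int:
        rule = self.normalization_rule
        if rule == "shorter":
            return min(len_a, len_b)
        if rule == "longer":
            return max(len_a, len_b)
        if rule == "first":
            return len_a
        if rule == "second":
            return len_b
        raise ValueError(f"unknown normalization rule {rule!r}")


def tm_terms(distances: np.ndarray, d0: float, target_length: int) -> float:
    """TM-score of a fixed superposition: ``(1/L_N) sum 1/(1+(d_i/d0)^2)``."""
    d = np.asarray(distances, dtype=float)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / target_length)


def _refine_tm(Xa: np.ndarray, Xb: np.ndarray, seed_idx: np.ndarray,
               d0: float, target_length: int,
               max_rounds: int = 20, tol: float = 1e-6) -> float:
    """Seed-and-extend refinement: best TM reached from one seed fragment."""
    tr, _ = kabsch(Xa[seed_idx], Xb[seed_idx], allow_degenerate=True)
    best = -np.inf
    prev = -np.inf
    for _ in range(max_rounds):
        d = np.linalg.norm(tr.apply(Xb) - Xa, axis=1)
        score = tm_terms(d, d0, target_length)
        best = max(best, score)
        if score - prev < tol:
            break
        prev = score
        sel = np.flatnonzero(d < d0 + 1.0)
        if sel.size < 4:
            sel = np.argsort(d)[:4]
        tr, _ = kabsch(Xa[sel], Xb[sel], allow_degenerate=True)
    # score the final transform too (loop may exit right after re-fitting)
    d = np.linalg.norm(tr.apply(Xb) - Xa, axis=1)
    return max(best, tm_terms(d, d0, target_length))


#: Below this many matched columns every contiguous fragment is tried;
#: above it, the strided subset.  Exhaustive seeding costs O(n^2) seeds
#: and is only affordable for short alignments.
EXHAUSTIVE_SEED_LIMIT = 48


def seed_fragments(n: int) -> list[np.ndarray]:
    """Deterministic seed fragments for the TM-score search.

    For n <= EXHAUSTIVE_SEED_LIMIT: every contiguous run of length >= 4
    (the search is then exhaustive over seeds).  For larger n: runs of
    lengths {n, n/2, n/4, 4} at stride max(1, n // 10) — the score
    landscape at realistic domain sizes is dominated by large rigid
    blocks that these seeds always intersect, while exhaustive seeding
    would be quadratically more expensive.
    """
    seeds = []
    if n <= EXHAUSTIVE_SEED_LIMIT:
        for ln in range(4, n + 1):
            for start in range(0, n - ln + 1):
                seeds.append(np.arange(start, start + ln))
        return seeds
    stride = max(1, n // 10)
    lengths = sorted({n, max(4, n // 2), max(4, n // 4), 4}, reverse=True)
    for ln in lengths:
        for start in range(0, n - ln + 1, stride):
            seeds.append(np.arange(start, start + ln))
    return seeds


def tm_score(aln: MultipleAlignment, a: DomainStructure, b: DomainStructure,
             params: TMScoreParams | None = None) -> float:
    """TM-score between two members over their matched alignment columns.

    The score ``(1/L_N) sum_i 1/(1 + (d_i/d0)^2)`` is maximized over
    superpositions with a deterministic seed-and-extend search: every seed
    fragment (see :func:`seed_fragments`) is Kabsch-fitted, then iteratively
    re-fitted on the residue pairs closer than ``d0 + 1`` Å (never fewer
    than 4) until the score converges; the maximum over seeds is returned.
    Identical inputs score exactly 1 under the default (shorter-length)
    normalization.
    """
    params = params or TMScoreParams()
    cols = pair_columns(aln, a.member_id, b.member_id, min_count=3)
    Xa = a.coords[aln.rows[a.member_id][cols]]
    Xb = b.coords[aln.rows[b.member_id][cols]]
    L_N = params.target_length(len(a), len(b))
    d0 = params.d0(L_N)
    best = -np.inf
    for seed in seed_fragments(len(cols)):
        best = max(best, _refine_tm(Xa, Xb, seed, d0, L_N))
    return float(min(best, 1.0))


# ---------------------------------------------------------------------------
# RMSD matrix and mean RMSD
# ---------------------------------------------------------------------------

def rmsd_matrix(aln: MultipleAlignment,
                structures: Sequence[DomainStructure],
                ensemble: SuperposedEnsemble | None = None,
                mode: str = "common-frame") -> np.ndarray:
    """Pairwise RMSD matrix over matched Cα columns.

    In the default ``common-frame`` mode each entry is the RMSD between the
    two members' coordinates *as placed by the multiple superposition* —
    no per-pair re-fitting, matching the MNYFIT-then-MeanRMSD protocol
    order.  ``repair`` mode instead re-superposes every pair optimally
    (clearly non-default).  When *ensemble* is None the raw input frames
    are used.  Pairs sharing fewer than 3 columns are NaN and excluded
    from means.
    """
    if mode not in ("common-frame", "repair"):
        raise ValueError(f"unknown pairwise mode {mode!r}")
    by_id = {s.member_id: s for s in structures}
    ids = aln.member_ids
    n = len(ids)
    placed = {}
    for m in ids:
        s = by_id[m]
        placed[m] = (ensemble.superposed_coords(s) if ensemble is not None
                     else np.asarray(s.coords, dtype=float))
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                cols = pair_columns(aln, ids[i], ids[j], min_count=3)
            except TooFewPointsError:
                logger.warning("pair (%s, %s) has < 3 matched columns; "
                               "excluded from means", ids[i], ids[j])
                M[i, j] = M[j, i] = np.nan
                continue
            Xi = placed[ids[i]][aln.rows[ids[i]][cols]]
            Xj = placed[ids[j]][aln.rows[ids[j]][cols]]
            if mode == "repair":
                _, r = kabsch(Xi, Xj, allow_degenerate=True)
            else:
                r = float(np.sqrt(np.mean(np.sum((Xi - Xj) ** 2, axis=1))))
            M[i, j] = M[j, i] = r
    return M


def mean_rmsd(matrix: np.ndarray, index: int) -> float:
    """Mean of the off-diagonal, non-missing entries of one member's row."""
    row = np.delete(np.asarray(matrix, dtype=float)[index], index)
    row = row[~np.isnan(row)]
    if row.size == 0:
        raise ValueError("all pairwise entries missing for this member")
    return float(np.mean(row))


def mean_rmsd_all(matrix: np.ndarray,
                  member_ids: Sequence[str]) -> dict[str, float]:
    return {m: mean_rmsd(matrix, i) for i, m in enumerate(member_ids)}


# ---------------------------------------------------------------------------
# Outlier classification
# ---------------------------------------------------------------------------

@dataclass
class DeviationReport:
    """Deviation statistics and outlier calls for one superfamily."""

    member_ids: tuple[str, ...]
    rmsd_matrix: np.ndarray
    mean_rmsd: dict[str, float]
    tm_matrix: np.ndarray
    tm_median: dict[str, float]
    outliers: frozenset
    category: str
    rmsd_cut: float
    tm_cut: float
    family_specific: bool = False
    family_label: str | None = None
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        M = np.asarray(self.rmsd_matrix, dtype=float)
        ok = ~(np.isnan(M) | np.isnan(M.T))
        if not np.allclose(M[ok], M.T[ok]):
            raise ValueError("RMSD matrix not symmetric")
        if not np.allclose(np.diag(M), 0.0):
            raise ValueError("RMSD matrix diagonal not zero")
        if not self.outliers <= set(self.member_ids):
            raise ValueError("outliers not a subset of members")


def call_outliers(means: Mapping[str, float],
                  tm_medians: Mapping[str, float],
                  rmsd_cut: float = DEFAULT_RMSD_CUT,
                  tm_cut: float = DEFAULT_TM_CUT,
                  rule: str = "and") -> frozenset:
    """The outlier decision rule, isolated.

    ``and`` (default): mean RMSD strictly above *rmsd_cut* AND median TM
    strictly below *tm_cut*; a member sitting exactly on either cut is not
    an outlier.  A NaN TM median never satisfies the TM condition.
    """
    if rule not in ("and", "or"):
        raise ValueError(f"unknown outlier rule {rule!r}")
    out = set()
    for m, mu in means.items():
        tm = tm_medians.get(m, np.nan)
        high_rmsd = mu > rmsd_cut
        low_tm = (not np.isnan(tm)) and tm < tm_cut
        if (high_rmsd and low_tm) if rule == "and" else (high_rmsd or low_tm):
            out.add(m)
    return frozenset(out)


def categorize(n_outliers: int) -> str:
    if n_outliers == 0:
        return "no-outlier"
    if n_outliers == 1:
        return "single-outlier"
    if n_outliers == 2:
        return "two-outlier"
    return "multiple-outlier"


def classify_outliers(aln: MultipleAlignment,
                      structures: Sequence[DomainStructure],
                      ensemble: SuperposedEnsemble | None = None,
                      rmsd_cut: float = DEFAULT_RMSD_CUT,
                      tm_cut: float = DEFAULT_TM_CUT,
                      tm_params: TMScoreParams | None = None,
                      rule: str = "and",
                      pairwise_mode: str = "common-frame",
                      full_tm: bool = False) -> DeviationReport:
    """Call structural outliers from mean RMSD and TM-score.

    A member is an outlier iff ``mean_rmsd > rmsd_cut`` AND its median
    TM-score against the other members is ``< tm_cut`` (strict
    inequalities at both cuts: a member at exactly 5.5 Å is not an
    outlier).  With ``rule="or"`` either condition suffices.

    TM-scores are expensive, and under the default AND rule they only
    matter for members already over the RMSD cut, so the TM matrix is
    computed lazily for candidate rows unless ``full_tm=True`` (the OR
    rule always computes all rows).  Uncomputed entries are NaN.
    """
    if rule not in ("and", "or"):
        raise ValueError(f"unknown outlier rule {rule!r}")
    tm_params = tm_params or TMScoreParams()
    by_id = {s.member_id: s for s in structures}
    ids = aln.member_ids
    n = len(ids)

    M = rmsd_matrix(aln, structures, ensemble, mode=pairwise_mode)
    means = mean_rmsd_all(M, ids)

    candidates = set(ids) if (full_tm or rule == "or") else {
        m for m in ids if means[m] > rmsd_cut}
    T = np.full((n, n), np.nan)
    np.fill_diagonal(T, 1.0)
    want_rows = {i for i, m in enumerate(ids) if m in candidates}
    for i in range(n):
        for j in range(i + 1, n):
            if i in want_rows or j in want_rows:
                try:
                    T[i, j] = T[j, i] = tm_score(
                        aln, by_id[ids[i]], by_id[ids[j]], tm_params)
                except TooFewPointsError:
                    pass

    tm_median: dict[str, float] = {}
    for i, m in enumerate(ids):
        row = np.delete(T[i], i)
        row = row[~np.isnan(row)]
        tm_median[m] = float(np.median(row)) if row.size else np.nan

    outliers = call_outliers(means, tm_median, rmsd_cut, tm_cut, rule)

    report = DeviationReport(
        member_ids=tuple(ids), rmsd_matrix=M, mean_rmsd=means,
        tm_matrix=T, tm_median=tm_median, outliers=frozenset(outliers),
        category=categorize(len(outliers)), rmsd_cut=rmsd_cut,
        tm_cut=tm_cut,
        families={s.member_id: s.family_id for s in structures})
    return report


def family_specificity(report: DeviationReport,
                       families: Mapping[str, str] | None = None
                       ) -> tuple[bool, str | None]:
    """Whether all outliers come from one family absent among non-outliers.

    Returns ``(True, family_id)`` when the outlier set is non-empty, every
    outlier shares one family label and no non-outlier carries it;
    ``(False, None)`` otherwise.
    """
    families = dict(families) if families is not None else report.families
    if not report.outliers:
        return False, None
    fams = {families[m] for m in report.outliers}
    if len(fams) != 1:
        return False, None
    fam = next(iter(fams))
    for m in report.member_ids:
        if m not in report.outliers and families.get(m) == fam:
            return False, None
    return True, fam


# ---------------------------------------------------------------------------
# Reason heuristics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapRun:
    kind: str  # insertion | deletion | N-terminal-extension | C-terminal-extension
    start: int  # first alignment column of the run
    length: int  # run length in columns


def gap_run_summary(aln: MultipleAlignment, member: str,
                    majority: float = 0.5) -> list[GapRun]:
    """Indel / terminal-extension hints for one member.

    An *insertion* is a maximal run of columns where the member is ungapped
    but more than half of the other members are gapped; a *deletion* is the
    converse.  Runs touching an alignment end are relabeled as terminal
    extensions (of the member for insertions; runs of missing residues at
    the ends are reported as deletions still, since the member is short
    there).
    """
    others = [m for m in aln.member_ids if m != member]
    if not others:
        return []
    row = aln.rows[member]
    others_gapped = np.mean(
        np.stack([aln.rows[m] == GAP for m in others]), axis=0)
    state = np.zeros(aln.n_columns, dtype=int)  # 0 none, 1 ins, 2 del
    state[(row != GAP) & (others_gapped > majority)] = 1
    state[(row == GAP) & (1.0 - others_gapped > majority)] = 2

    runs: list[GapRun] = []
    c = 0
    n = aln.n_columns
    while c < n:
        if state[c] == 0:
            c += 1
            continue
        start = c
        while c < n and state[c] == state[start]:
            c += 1
        kind = "insertion" if state[start] == 1 else "deletion"
        if state[start] == 1:
            if start == 0:
                kind = "N-terminal-extension"
            elif c == n:
                kind = "C-terminal-extension"
        runs.append(GapRun(kind, start, c - start))
    return runs


@dataclass(frozen=True)
class CPResult:
    best_shift: int
    improvement: float
    rmsd_unshifted: float
    rmsd_best: float
    has_signal: bool


def circular_permutation_score(a: DomainStructure, b: DomainStructure,
                               aln: MultipleAlignment | None = None,
                               grid: int = 5,
                               min_improvement: float = 1.0,
                               min_fraction: float = 0.5) -> CPResult:
    """Screen a pair for circular permutation by cyclic-shift superposition.

    For cyclic shifts *k* of member *b*'s residue order (every *grid*
    residues, then ±(grid-1) refinement around the best), residues are
    matched positionally over the min-length overlap and Kabsch-fitted;
    the shift minimizing RMSD is reported.  A CP signal requires the
    improvement over the unshifted fit to exceed both *min_improvement* Å
    and ``min_fraction *`` the unshifted RMSD — unrelated structures show
    small relative improvements, a genuine CP pair collapses to near-zero
    RMSD at the true shift.  The alignment argument is accepted for
    interface symmetry but unused: the scan deliberately rebuilds naive
    positional correspondences, which is what exposes a permutation.
    """
    del aln
    la, lb = len(a), len(b)
    if la < 20 or lb < 20:
        raise TooFewPointsError("circular permutation scan needs >= 20 "
                                "residues in both members")
    m = min(la, lb)
    Xa = a.coords[:m]

    def rmsd_at(k: int) -> float:
        Xb = np.roll(b.coords, -k, axis=0)[:m]
        _, r = kabsch(Xa, Xb, allow_degenerate=True)
        return r

    coarse = {k: rmsd_at(k) for k in range(0, lb, grid)}
    k0 = min(coarse, key=lambda k: (coarse[k], k))
    fine = dict(coarse)
    for k in range(k0 - (grid - 1), k0 + grid):
        kk = k % lb
        if kk not in fine:
            fine[kk] = rmsd_at(kk)
    best = min(fine, key=lambda k: (fine[k], k))
    r0 = fine.get(0, rmsd_at(0))
    improvement = r0 - fine[best]
    signal = improvement > max(min_improvement, min_fraction * r0)
    return CPResult(best_shift=best, improvement=float(improvement),
                    rmsd_unshifted=float(r0), rmsd_best=float(fine[best]),
                    has_signal=bool(signal))
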
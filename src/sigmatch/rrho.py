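"""Rank-rank hypergeometric overlap statistics.

Two signatures are compared by asking whether their top-ranked gene lists
overlap more (or less) than expected by chance when both draw from the same
gene universe of size ``N``.  The overlap count ``k`` between a list of size
``s1`` and a list of size ``s2`` follows a Hypergeometric(N, s1, s2)
distribution under independence, and evidence is reported as ``-log10`` of a
tail probability.

Two views are provided:

* :func:`quadrant_score` — four fixed-cutoff tests at the top-``n`` up/down
  sets (quadrants A: up-up, B: up-down, C: down-up, D: down-down) combined
  into the congruence score ``A + D - B - C``.  A large positive score means
  the two signatures move the same genes in the same direction; a large
  negative score means they oppose each other.
* :func:`rrho_matrix` — the stepped heatmap: both signatures are ranked over
  the shared universe by signed significance and the signed overlap evidence
  of every pair of top-list prefixes is laid out on a grid.

All tail probabilities are computed in log space.  When the requested tail
holds most of the probability mass, it is evaluated through the complement
via ``log1p``/``expm1`` so that ``-log10 p`` stays accurate even for p close
to 1 — the regime where naive summation loses all relative precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp

from .exceptions import ContractError, InvalidInputError, NoOverlapError
from .signatures import SIGNIFICANCE_CAP, GeneSignature, RankedSets

__all__ = [
    "QuadrantScore",
    "RRHOMatrix",
    "hypergeom_tail_neglog",
    "hypergeom_tail_neglog_all_k",
    "quadrant_score",
    "rrho_matrix",
    "write_rrho",
    "load_rrho",
]

_LN10 = float(np.log(10.0))


def _log_factorials(n: int) -> np.ndarray:
    """Table t with t[i] = log(i!) for i = 0..n."""
    return gammaln(np.arange(n + 1, dtype=float) + 1.0)


def _log_pmf(i: np.ndarray, s1: int, s2: int, N: int, lgf: np.ndarray) -> np.ndarray:
    """log P(X = i) for X ~ Hypergeometric(N, s1, s2) on the support array i."""
    return (
        lgf[s1] - lgf[i] - lgf[s1 - i]
        + lgf[N - s1] - lgf[s2 - i] - lgf[N - s1 - s2 + i]
        - (lgf[N] - lgf[s2] - lgf[N - s2])
    )


def _tail_neglog(
    k: int, s1: int, s2: int, N: int, lgf: np.ndarray, upper: bool, cap: float
) -> float:
    """-log10 of P(X >= k) (upper) or P(X <= k) (lower), accurate for p near 1."""
    if s1 > s2:
        s1, s2 = s2, s1  # tail is symmetric in the list sizes; fix the float path
    lo = max(0, s1 + s2 - N)
    hi = min(s1, s2)
    if upper:
        if k <= lo:
            return 0.0
        direct = np.arange(k, hi + 1)
        complement = np.arange(lo, k)
    else:
        if k >= hi:
            return 0.0
        direct = np.arange(lo, k + 1)
        complement = np.arange(k + 1, hi + 1)
    log_direct = logsumexp(_log_pmf(direct, s1, s2, N, lgf)) if direct.size else -np.inf
    if log_direct < float(np.log(0.5)):
        neglog = -log_direct / _LN10
    else:
        # p is close to 1: evaluate via the (small) complementary tail
        log_comp = logsumexp(_log_pmf(complement, s1, s2, N, lgf))
        neglog = -float(np.log1p(-np.exp(log_comp))) / _LN10
    return float(min(max(neglog, 0.0), cap))


def hypergeom_tail_neglog(
    k: int, s1: int, s2: int, N: int, cap: float = SIGNIFICANCE_CAP
) -> float:
    """Upper-tail overlap evidence ``-log10 P(X >= k)``, X ~ Hypergeometric(N, s1, s2).

    ``s1`` and ``s2`` are the two list sizes drawn from a universe of ``N``
    genes and ``k`` the observed overlap.  Returns 0 for ``k = 0`` (an
    overlap of at least zero is certain) and is capped at ``cap``.
    """
    k, s1, s2, N = int(k), int(s1), int(s2), int(N)
    if N < 0 or s1 < 0 or s2 < 0 or s1 > N or s2 > N:
        raise InvalidInputError(f"need 0 <= s1,s2 <= N; got s1={s1}, s2={s2}, N={N}")
    if not (0 <= k <= min(s1, s2)):
        raise InvalidInputError(f"need 0 <= k <= min(s1,s2); got k={k}, s1={s1}, s2={s2}")
    return _tail_neglog(k, s1, s2, N, _log_factorials(N), upper=True, cap=cap)


def hypergeom_tail_neglog_all_k(
    s1: int, s2: int, N: int, cap: float = SIGNIFICANCE_CAP
) -> np.ndarray:
    """Upper-tail evidence ``-log10 P(X >= k)`` for every k = 0..min(s1, s2).

    Vectorised companion of :func:`hypergeom_tail_neglog` (same probability
    model and the same near-p=1 complement handling), useful when a whole
    profile of overlap thresholds is needed at fixed list sizes.
    """
    s1, s2, N = int(s1), int(s2), int(N)
    if N < 0 or s1 < 0 or s2 < 0 or s1 > N or s2 > N:
        raise InvalidInputError(f"need 0 <= s1,s2 <= N; got s1={s1}, s2={s2}, N={N}")
    if s1 > s2:
        s1, s2 = s2, s1
    lo, hi = max(0, s1 + s2 - N), min(s1, s2)
    lgf = _log_factorials(N)
    lp = _log_pmf(np.arange(lo, hi + 1), s1, s2, N, lgf)
    log_upper = np.logaddexp.accumulate(lp[::-1])[::-1]  # log P(X >= i), i = lo..hi
    log_lower = np.logaddexp.accumulate(lp)              # log P(X <= i)
    out = np.zeros(hi + 1)
    ks = np.arange(lo + 1, hi + 1)
    if ks.size:
        direct = log_upper[ks - lo]
        comp = log_lower[ks - 1 - lo]  # log P(X <= k-1), small where direct ~ 0
        vals = np.empty(ks.size)
        use_direct = direct < np.log(0.5)
        vals[use_direct] = -direct[use_direct] / _LN10
        vals[~use_direct] = -np.log1p(-np.exp(comp[~use_direct])) / _LN10
        out[ks] = np.clip(vals, 0.0, cap)
    return out


@dataclass(frozen=True)
class QuadrantScore:
    """Fixed-cutoff quadrant evidence and the combined congruence score.

    ``A``/``B``/``C``/``D`` hold ``-log10`` upper-tail hypergeometric p-values
    of the four directional overlaps (A up-up, B up-down, C down-up,
    D down-down); ``kA``..``kD`` the corresponding overlap counts.  The final
    score is ``A + D - B - C``: same-direction evidence rewarded,
    opposite-direction evidence penalised.
    """

    A: float
    B: float
    C: float
    D: float
    kA: int
    kB: int
    kC: int
    kD: int
    universe_size: int

    @property
    def score(self) -> float:
        return self.A + self.D - self.B - self.C


def quadrant_score(a: RankedSets, b: RankedSets, cap: float = SIGNIFICANCE_CAP) -> QuadrantScore:
    """Score the directional overlap of two ranked-set pairs on one universe.

    ``a`` is conventionally the model, ``b`` the reference (human depression
    portrait), but the score construction is symmetric in the two arguments.
    """
    if a.universe != b.universe:
        raise ContractError("ranked sets built on different universes cannot be scored")
    N = len(a.universe)
    lgf = _log_factorials(N)
    a_up, a_dn = set(a.up), set(a.down)
    b_up, b_dn = set(b.up), set(b.down)

    def tail(k: int, s1: int, s2: int) -> float:
        return _tail_neglog(k, s1, s2, N, lgf, upper=True, cap=cap)

    kA = len(a_up & b_up)
    kB = len(a_up & b_dn)
    kC = len(a_dn & b_up)
    kD = len(a_dn & b_dn)
    return QuadrantScore(
        A=tail(kA, len(a_up), len(b_up)),
        B=tail(kB, len(a_up), len(b_dn)),
        C=tail(kC, len(a_dn), len(b_up)),
        D=tail(kD, len(a_dn), len(b_dn)),
        kA=kA, kB=kB, kC=kC, kD=kD,
        universe_size=N,
    )


@dataclass
class RRHOMatrix:
    """Stepped rank-rank overlap grid between two signatures.

    ``cells[i, j]`` is the signed overlap evidence between the top
    ``steps_y[i]`` genes of the Y dataset and the top ``steps_x[j]`` genes of
    the X dataset (both ranked by signed significance, most up-regulated
    first): positive values are ``-log10`` upper-tail p (over-enrichment),
    negative values ``-log10`` lower-tail p (depletion).  By convention the
    reference/portrait is plotted on X.
    """

    steps_x: np.ndarray
    steps_y: np.ndarray
    cells: np.ndarray
    counts: np.ndarray
    x_id: str
    y_id: str
    universe_size: int
    orientation: str = "reference on X"

    def __post_init__(self) -> None:
        if self.cells.shape != (len(self.steps_y), len(self.steps_x)):
            raise ContractError("RRHO grid shape does not match threshold lists")
        if not np.all(np.isfinite(self.cells)):
            raise ContractError("RRHO grid contains non-finite cells")


def rrho_matrix(
    a: GeneSignature,
    b: GeneSignature,
    step: int | None = None,
    cap: float = SIGNIFICANCE_CAP,
) -> RRHOMatrix:
    """Compute the stepped RRHO heatmap of ``a`` (Y axis) against ``b`` (X axis).

    Both signatures are ranked over their shared universe by descending
    signed significance (ties broken by symbol).  ``step`` defaults to
    ``max(1, N // 100)``, which yields roughly a 100 x 100 grid.
    """
    universe = sorted(a.genes & b.genes)
    N = len(universe)
    if N == 0:
        raise NoOverlapError(
            f"signatures {a.dataset_id!r} and {b.dataset_id!r} share no genes"
        )
    if N < 10:
        raise InvalidInputError(f"shared universe must have >= 10 genes; got {N}")
    if step is None:
        step = max(1, N // 100)
    if step < 1:
        raise InvalidInputError(f"step must be >= 1; got {step}")

    order_a = sorted(universe, key=lambda g: (-a.values[g], g))
    order_b = sorted(universe, key=lambda g: (-b.values[g], g))
    pos_a = {g: i for i, g in enumerate(order_a)}
    pos_b = {g: i for i, g in enumerate(order_b)}

    thresholds = np.arange(step, N + 1, step)
    n_steps = len(thresholds)
    # joint rank histogram -> cumulative overlap counts at every threshold pair
    hist = np.zeros((n_steps, n_steps), dtype=np.int64)
    for g in universe:
        ia, ib = pos_a[g] // step, pos_b[g] // step
        if ia < n_steps and ib < n_steps:
            hist[ia, ib] += 1
    counts = hist.cumsum(axis=0).cumsum(axis=1)

    lgf = _log_factorials(N)
    cells = np.zeros_like(counts, dtype=float)
    for i, ti in enumerate(thresholds):
        for j, tj in enumerate(thresholds):
            k = int(counts[i, j])
            expected = ti * tj / N
            if k > expected:
                cells[i, j] = _tail_neglog(k, int(ti), int(tj), N, lgf, upper=True, cap=cap)
            else:
                cells[i, j] = -_tail_neglog(k, int(ti), int(tj), N, lgf, upper=False, cap=cap)
    return RRHOMatrix(
        steps_x=thresholds.copy(),
        steps_y=thresholds.copy(),
        cells=cells,
        counts=counts,
        x_id=b.dataset_id,
        y_id=a.dataset_id,
        universe_size=N,
    )


def write_rrho(matrix: RRHOMatrix, path) -> Path:
    """Write an RRHO grid as TSV with ``#`` header lines carrying the thresholds."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# y_id={matrix.y_id}\tx_id={matrix.x_id}\tN={matrix.universe_size}\n")
        fh.write("# steps_x\t" + "\t".join(str(int(t)) for t in matrix.steps_x) + "\n")
        fh.write("# steps_y\t" + "\t".join(str(int(t)) for t in matrix.steps_y) + "\n")
        for row in matrix.cells:
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
    return path


def load_rrho(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back a grid written by :func:`write_rrho` -> (steps_x, steps_y, cells)."""
    steps_x = steps_y = None
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# steps_x"):
                steps_x = np.array([int(t) for t in line.split("\t")[1:]])
            elif line.startswith("# steps_y"):
                steps_y = np.array([int(t) for t in line.split("\t")[1:]])
            elif not line.startswith("#"):
                rows.append([float(v) for v in line.split("\t")])
    return steps_x, steps_y, np.array(rows)
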
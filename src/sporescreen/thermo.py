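"""Thermodynamic core: folding, partition function, z-scores, consensus.

Two energy backends are provided.

``simple``
    A self-contained base-pair scoring model (GC -3, AU -2, GU -1 in
    arbitrary units, minimum hairpin of 3 unpaired bases).  Minimum-energy
    structures come from a Nussinov-style dynamic program, base-pair
    probabilities from a McCaskill-style inside/outside recursion over the
    *identical* structure space, so every quantity can be cross-checked
    against exhaustive enumeration on short sequences.

``full``
    The complete nearest-neighbour (Turner) parameter set at 37 deg C,
    delegated to the ViennaRNA bindings.  Needed only when physically
    calibrated energies (kcal/mol) or loop probabilities are required.

All structures are pseudoknot-free; only canonical pairs
{AU, UA, GC, CG, GU, UG} may form and N never pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ._util import rng_from

__all__ = [
    "EnergyModel",
    "FoldResult",
    "PairProbMatrix",
    "LoopProfile",
    "fold_mfe",
    "brute_force_fold",
    "enumerate_structures",
    "partition_probs",
    "loop_probability",
    "shuffle_zscore",
    "consensus_fold",
    "sci",
]

_ALPHABET = "ACGUN"
_INDEX = {c: i for i, c in enumerate(_ALPHABET)}

# canonical pair energies of the simple model, arbitrary units
_SIMPLE_PAIRS: Dict[str, float] = {
    "GC": -3.0, "CG": -3.0,
    "AU": -2.0, "UA": -2.0,
    "GU": -1.0, "UG": -1.0,
}

CANONICAL_PAIRS = frozenset(_SIMPLE_PAIRS)


@dataclass(frozen=True)
class EnergyModel:
    """Scoring model shared by every folding routine.

    mode : 'simple' or 'full'
    pair_scores : canonical pair -> energy (simple mode)
    min_hairpin : minimum number of unpaired bases enclosed by a pair
    temperature : kelvin (full mode; 310.15 K = 37 deg C)
    """

    mode: str = "simple"
    pair_scores: Dict[str, float] = field(default_factory=lambda: dict(_SIMPLE_PAIRS))
    min_hairpin: int = 3
    temperature: float = 310.15

    def __post_init__(self):
        if self.mode not in ("simple", "full"):
            raise ValueError(f"unknown energy model mode {self.mode!r}")
        if self.min_hairpin < 0:
            raise ValueError("min_hairpin must be >= 0")
        for pair in self.pair_scores:
            if pair not in CANONICAL_PAIRS:
                raise ValueError(f"non-canonical pair {pair!r} in pair_scores")

    def pair_energy(self, a: str, b: str) -> float:
        return self.pair_scores.get(a + b, 0.0)

    def can_pair(self, a: str, b: str) -> bool:
        return (a + b) in self.pair_scores


SIMPLE_MODEL = EnergyModel()
FULL_MODEL = EnergyModel(mode="full")


@dataclass(frozen=True)
class FoldResult:
    structure: str
    energy: float


@dataclass(frozen=True)
class PairProbMatrix:
    """Base-pair probabilities p[i,j] and per-base unpaired probabilities q."""

    p: np.ndarray          # (L, L) symmetric
    q: np.ndarray          # (L,)
    ensemble_energy: float


@dataclass(frozen=True)
class LoopProfile:
    per_base: np.ndarray
    mean_loop_prob: float


def _validate(seq: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in _INDEX:
            raise ValueError(
                f"invalid RNA character {ch!r} at position {pos} "
                f"(alphabet is {_ALPHABET})"
            )
    return seq


def _score_matrix(seq: str, model: EnergyModel) -> Tuple[np.ndarray, np.ndarray]:
    """Pair score matrix and allowed-pair mask (min_hairpin enforced)."""
    n = len(seq)
    score = np.zeros((n, n))
    allowed = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + model.min_hairpin + 1, n):
            pair = seq[i] + seq[j]
            if pair in model.pair_scores:
                score[i, j] = model.pair_scores[pair]
                allowed[i, j] = True
    return score, allowed


# ---------------------------------------------------------------------------
# Nussinov fill (numba-accelerated; pure-python fallback keeps the package
# importable if jit compilation is unavailable)
# ---------------------------------------------------------------------------

def _fill_py(score, allowed, min_hairpin):
    n = score.shape[0]
    E = np.zeros((n, n))
    for d in range(min_hairpin + 1, n):
        for i in range(n - d):
            j = i + d
            best = E[i + 1, j]
            for k in range(i + min_hairpin + 1, j + 1):
                if allowed[i, k]:
                    v = score[i, k]
                    if k - 1 >= i + 1:
                        v += E[i + 1, k - 1]
                    if k + 1 <= j:
                        v += E[k + 1, j]
                    if v < best:
                        best = v
            E[i, j] = best
    return E


try:  # pragma: no cover - exercised implicitly by every fold call
    from numba import njit

    _fill = njit(cache=True)(_fill_py)
except Exception:  # pragma: no cover
    _fill = _fill_py


def _energy_matrix(seq: str, model: EnergyModel) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    score, allowed = _score_matrix(seq, model)
    E = _fill(score, allowed, model.min_hairpin) if len(seq) else np.zeros((0, 0))
    return E, score, allowed


def _traceback(E, score, allowed, min_hairpin) -> List[Tuple[int, int]]:
    """Deterministic traceback: at each interval prefer pairing the left end
    with its smallest admissible partner over leaving it unpaired."""
    n = E.shape[0]
    pairs: List[Tuple[int, int]] = []
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if j - i < min_hairpin + 1:
            continue
        target = E[i, j]
        chosen = False
        for k in range(i + min_hairpin + 1, j + 1):
            if allowed[i, k]:
                v = score[i, k]
                if k - 1 >= i + 1:
                    v += E[i + 1, k - 1]
                if k + 1 <= j:
                    v += E[k + 1, j]
                if abs(v - target) < 1e-9:
                    pairs.append((i, k))
                    stack.append((k + 1, j))
                    stack.append((i + 1, k - 1))
                    chosen = True
                    break
        if not chosen:
            stack.append((i + 1, j))
    return pairs


def pairs_to_dotbracket(pairs: Sequence[Tuple[int, int]], length: int) -> str:
    db = ["."] * length
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def dotbracket_to_pairs(db: str) -> List[Tuple[int, int]]:
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def fold_mfe(seq: str, model: EnergyModel = SIMPLE_MODEL) -> FoldResult:
    """Minimum-energy pseudoknot-free structure under the model."""
    seq = _validate(seq)
    if not seq:
        return FoldResult("", 0.0)
    if model.mode == "full":
        import RNA

        structure, energy = RNA.fold(seq)
        return FoldResult(structure, float(energy))
    E, score, allowed = _energy_matrix(seq, model)
    pairs = _traceback(E, score, allowed, model.min_hairpin)
    return FoldResult(pairs_to_dotbracket(pairs, len(seq)), float(E[0, -1]))


# ---------------------------------------------------------------------------
# Exhaustive enumeration (test oracle)
# ---------------------------------------------------------------------------

MAX_BRUTE_LEN = 16


def enumerate_structures(seq: str, model: EnergyModel = SIMPLE_MODEL):
    """Yield (pairs, energy) for every pseudoknot-free structure of ``seq``.

    Enumeration order matches the fold_mfe traceback preference (left end
    paired with ascending partners before left end unpaired), so the first
    minimum-energy structure encountered is the fold_mfe structure.
    Simple-model energies only; full-model callers re-evaluate each
    structure themselves.
    """
    seq = _validate(seq)
    if len(seq) > MAX_BRUTE_LEN:
        raise ValueError(f"enumeration refused for length {len(seq)} > {MAX_BRUTE_LEN}")
    score, allowed = _score_matrix(seq, model)
    n = len(seq)

    def rec(i, j):
        if i > j:
            yield [], 0.0
            return
        # left end paired first, ascending partner
        for k in range(i + model.min_hairpin + 1, j + 1):
            if allowed[i, k]:
                for inner, e_in in rec(i + 1, k - 1):
                    for outer, e_out in rec(k + 1, j):
                        yield [(i, k)] + inner + outer, score[i, k] + e_in + e_out
        for rest, e in rec(i + 1, j):
            yield rest, e

    yield from rec(0, n - 1)


def brute_force_fold(seq: str, model: EnergyModel = SIMPLE_MODEL) -> FoldResult:
    """Exhaustive minimum-energy search; independent oracle for fold_mfe."""
    seq = _validate(seq)
    if len(seq) > MAX_BRUTE_LEN:
        raise ValueError(f"brute force refused for length {len(seq)} > {MAX_BRUTE_LEN}")
    if not seq:
        return FoldResult("", 0.0)
    if model.mode == "full":
        import RNA

        fc = RNA.fold_compound(seq)
        best_pairs, best_e = [], fc.eval_structure("." * len(seq))
        for pairs, _ in enumerate_structures(seq, EnergyModel(min_hairpin=model.min_hairpin)):
            e = fc.eval_structure(pairs_to_dotbracket(pairs, len(seq)))
            if e < best_e - 1e-6:
                best_pairs, best_e = pairs, e
        return FoldResult(pairs_to_dotbracket(best_pairs, len(seq)), float(best_e))
    best_pairs: List[Tuple[int, int]] = []
    best_e = math.inf
    for pairs, e in enumerate_structures(seq, model):
        if e < best_e - 1e-9:
            best_pairs, best_e = pairs, e
    return FoldResult(pairs_to_dotbracket(best_pairs, len(seq)), float(best_e))


# ---------------------------------------------------------------------------
# Partition function (McCaskill-style inside/outside)
# ---------------------------------------------------------------------------

def partition_probs(seq: str, model: EnergyModel = SIMPLE_MODEL) -> PairProbMatrix:
    """Boltzmann pair probabilities over the fold_mfe structure space.

    Simple mode uses unit inverse temperature (weights exp(-E)); the
    ensemble energy is -log Z on the same arbitrary scale.  Full mode
    delegates to the ViennaRNA partition function (kcal/mol).
    """
    seq = _validate(seq)
    n = len(seq)
    if n == 0:
        return PairProbMatrix(np.zeros((0, 0)), np.zeros(0), 0.0)
    if model.mode == "full":
        import RNA

        fc = RNA.fold_compound(seq)
        _, ensemble = fc.pf()
        raw = np.array(fc.bpp())  # (n+1, n+1), 1-indexed upper triangle
        p = np.zeros((n, n))
        p[np.triu_indices(n, 1)] = raw[1:, 1:][np.triu_indices(n, 1)]
        p = p + p.T
        q = 1.0 - p.sum(axis=1)
        return PairProbMatrix(p, q, float(ensemble))

    score, allowed = _score_matrix(seq, model)
    w = np.where(allowed, np.exp(-score), 0.0)

    # inside: Z[i,j] over closed intervals, Z = 1 for empty intervals
    Z = np.ones((n + 1, n + 1))   # padded: Zg(i,j) = Z[i, j+1] valid for j >= i-1
    Zb = np.zeros((n, n))

    def Zg(i, j):
        if i > j:
            return 1.0
        return Z[i, j + 1]

    for j in range(n):
        for i in range(j, -1, -1):
            total = Zg(i, j - 1)  # j unpaired
            for k in range(i, j - model.min_hairpin):
                if allowed[k, j]:
                    Zb[k, j] = w[k, j] * Zg(k + 1, j - 1)
                    total += Zg(i, k - 1) * Zb[k, j]
            Z[i, j + 1] = total
    Ztot = Zg(0, n - 1)

    # outside: process spans descending; D[k, jp] accumulates
    # sum_{l > jp} w(k,l) * Zout(k,l) * Zg(jp+1, l-1)
    P = np.zeros((n, n))
    D = np.zeros((n, n))
    for d in range(n - 1, model.min_hairpin, -1):
        span_pairs = [(i, i + d) for i in range(n - d) if allowed[i, i + d]]
        for i, j in span_pairs:
            ext = Zg(0, i - 1) * Zg(j + 1, n - 1)
            inner = 0.0
            for k in range(i):
                if D[k, j]:
                    inner += D[k, j] * Zg(k + 1, i - 1)
            zout = ext + inner
            P[i, j] = Zb[i, j] * zout / Ztot
        for i, j in span_pairs:
            if P[i, j] == 0.0:
                continue
            C = w[i, j] * (P[i, j] * Ztot / Zb[i, j])
            for jp in range(j):
                D[i, jp] += C * Zg(jp + 1, j - 1)
    P = P + P.T
    q = 1.0 - P.sum(axis=1)
    return PairProbMatrix(P, q, float(-math.log(Ztot)))


def loop_probability(seq: str, model: EnergyModel = SIMPLE_MODEL) -> LoopProfile:
    """Mean per-base unpaired ("loop-forming") probability."""
    if not seq:
        raise ValueError("loop probability undefined for an empty sequence")
    probs = partition_probs(seq, model)
    return LoopProfile(probs.q, float(probs.q.mean()))


# ---------------------------------------------------------------------------
# Thermodynamic z-score
# ---------------------------------------------------------------------------

def _mfe_energy(seq: str, model: EnergyModel) -> float:
    if model.mode == "full":
        import RNA

        return float(RNA.fold(seq)[1])
    E, _, _ = _energy_matrix(seq, model)
    return float(E[0, -1]) if len(seq) else 0.0


def shuffle_zscore(
    seq: str,
    model: EnergyModel = SIMPLE_MODEL,
    n_shuffles: int = 100,
    seed: int = 0,
) -> float:
    """Standardized MFE against mononucleotide shuffles.

    z = (E_seq - mu) / sigma over ``n_shuffles`` composition-preserving
    shuffles from the seeded stream (sample sd, ddof=1); sigma = 0 yields
    z = 0 by convention.  Negative z marks unusually stable sequences.
    """
    seq = _validate(seq)
    if len(seq) < 2:
        raise ValueError("z-score needs a sequence of length >= 2")
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    rng = rng_from(seed)
    letters = np.array(list(seq))
    energies = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuf = "".join(rng.permutation(letters))
        energies[s] = _mfe_energy(shuf, model)
    mu = energies.mean()
    sigma = energies.std(ddof=1)
    if sigma == 0.0:
        return 0.0
    return float((_mfe_energy(seq, model) - mu) / sigma)


# ---------------------------------------------------------------------------
# Consensus folding over an alignment and the structure conservation index
# ---------------------------------------------------------------------------

def _rows_of(alignment) -> List[str]:
    if hasattr(alignment, "texts"):
        rows = list(alignment.texts)
    elif hasattr(alignment, "rows"):
        rows = [t for _, t in alignment.rows]
    else:
        rows = list(alignment)
    if len(rows) < 2:
        raise ValueError("consensus folding needs >= 2 rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment rows")
    return [r.upper() for r in rows]


def consensus_column_score(
    bases: Sequence[str],
    model: EnergyModel,
    covariance_bonus: float,
    inconsistency_penalty: float,
) -> Tuple[float, bool]:
    """Score one column pair from its per-row base pairs.

    score = mean pair energy over all rows (non-pairing rows contribute 0)
            - bonus * (distinct canonical pair types - 1)
            + penalty * (fraction of rows that cannot pair; gaps count)

    The covariance bonus lowers (stabilizes) the energy of column pairs
    supported by compensatory substitutions.  Only columns where >= 1 row
    forms a canonical pair and the combined score is stabilizing (< 0) are
    admitted into the structure space.
    """
    n_rows = len(bases)
    types = set()
    total = 0.0
    bad = 0
    for pair in bases:
        if "-" in pair or pair not in model.pair_scores:
            bad += 1
        else:
            types.add(pair)
            total += model.pair_scores[pair]
    if not types:
        return 0.0, False
    score = (
        total / n_rows
        - covariance_bonus * (len(types) - 1)
        + inconsistency_penalty * (bad / n_rows)
    )
    return score, score < 0.0


def consensus_fold(
    alignment,
    model: EnergyModel = SIMPLE_MODEL,
    covariance_bonus: float = 1.0,
    inconsistency_penalty: float = 1.0,
) -> FoldResult:
    """Covariance-aware consensus structure over alignment columns.

    A Nussinov-style minimisation where each column pair is scored by the
    mean pair energy across rows, stabilised by a bonus for every distinct
    compensatory pair type beyond the first and destabilised in proportion
    to rows (or gaps) that cannot pair.  On identical rows this reduces
    exactly to single-sequence fold_mfe.

    Full-model consensus delegates to ViennaRNA's alifold.
    """
    rows = _rows_of(alignment)
    if model.mode == "full":
        import RNA

        structure, energy = RNA.alifold(rows)
        return FoldResult(structure, float(energy))
    n = len(rows[0])
    score = np.zeros((n, n))
    allowed = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + model.min_hairpin + 1, n):
            bases = [r[i] + r[j] for r in rows]
            s, ok = consensus_column_score(
                bases, model, covariance_bonus, inconsistency_penalty
            )
            score[i, j] = s
            allowed[i, j] = ok
    E = _fill(score, allowed, model.min_hairpin) if n else np.zeros((0, 0))
    pairs = _traceback(E, score, allowed, model.min_hairpin)
    return FoldResult(pairs_to_dotbracket(pairs, n), float(E[0, -1]) if n else 0.0)


def sci(
    alignment,
    model: EnergyModel = SIMPLE_MODEL,
    covariance_bonus: float = 1.0,
    inconsistency_penalty: float = 1.0,
) -> float:
    """Structure conservation index: E_consensus / mean individual MFE.

    ~1 when every row folds into the consensus structure as stably as it
    folds on its own; 0 by convention when no row is structurable.
    """
    rows = _rows_of(alignment)
    cons = consensus_fold(alignment, model, covariance_bonus, inconsistency_penalty)
    singles = [_mfe_energy(r.replace("-", ""), model) for r in rows]
    mean_single = float(np.mean(singles))
    if mean_single == 0.0:
        return 0.0
    return float(cons.energy / mean_single)
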
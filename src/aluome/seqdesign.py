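"""Design of structure-matched, sequence-divergent UTR analogs.

To ask whether a fold-back RNA structure alone (rather than the Alu sequence
itself) represses expression, the inverted-repeat portion of a 3' UTR is
replaced by artificial sequence designed to reproduce the original UTR's
secondary-structure thermodynamics: the same minimum-free-energy (MFE)
structure, the same MFE, and the same ensemble free energy (EFE, -kT ln Z),
while the spacer regions between/around the repeats are kept byte-identical.
Among candidates meeting those constraints, ones with similar GC content and
base-pair probability (bpp) matrix and low sequence identity to the replaced
repeat are preferred.

Folding is delegated to a pluggable engine satisfying the
:class:`FoldResult` contract:

* :class:`ViennaRNAEngine` — the Turner-parameter thermodynamic model via the
  ViennaRNA bindings (production use);
* :class:`NussinovEngine` — a base-pair-maximization toy model (energy -1
  per pair, kT = 1, minimum hairpin loop 3) whose MFE comes from the Nussinov
  recursion and whose partition function / pair probabilities come from an
  exact inside-outside computation on the same model.  Every number the toy
  engine emits can be re-derived by exhaustively enumerating structures, so
  design runs against it are oracle-checkable.

The search itself is seeded stochastic hill-climbing with random restarts:
designable segments are filled uniformly at random and single-nucleotide
mutations are accepted when they do not worsen (base-pair distance to the
target structure, energy mismatch), lexicographically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Protocol, Sequence

import numpy as np
from Bio import Align

log = logging.getLogger(__name__)

RNA_BASES = "ACGU"
_CAN_PAIR = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)
MIN_LOOP = 3  # minimum unpaired bases in a hairpin loop


def _clean(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set(RNA_BASES)
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)}; expected A/C/G/U (or T)")
    if not seq:
        raise ValueError("empty sequence")
    return seq


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CAN_PAIR


def pairs_of_structure(db: str) -> set[tuple[int, int]]:
    """Base pairs (i, j), i < j, of a dot-bracket string; raises if unbalanced."""
    stack: list[int] = []
    pairs = set()
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            pairs.add((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unclosed '('")
    return pairs


def structure_bp_distance(a: str, b: str) -> int:
    """Symmetric-difference base-pair distance between two dot-brackets."""
    if len(a) != len(b):
        raise ValueError("structures must have equal length")
    return len(pairs_of_structure(a) ^ pairs_of_structure(b))


@dataclass(frozen=True)
class FoldResult:
    """Thermodynamic summary of one sequence under one engine.

    ``mfe_structure`` is the MFE dot-bracket, ``mfe`` its energy, ``efe`` the
    ensemble free energy (-kT ln Z <= mfe), and ``bpp`` the symmetric
    base-pair probability matrix (row sums <= 1).
    """

    mfe_structure: str
    mfe: float
    efe: float
    bpp: np.ndarray

    def __post_init__(self) -> None:
        pairs_of_structure(self.mfe_structure)  # validates balance
        n = len(self.mfe_structure)
        if self.bpp.shape != (n, n):
            raise ValueError("bpp matrix shape must match structure length")


class FoldingEngine(Protocol):  # pragma: no cover - structural type only
    def fold(self, sequence: str) -> FoldResult: ...
    def mfe(self, sequence: str) -> tuple[str, float]: ...


class NussinovEngine:
    """Base-pair maximization model: -1 per canonical pair (incl. GU), kT = 1.

    MFE by the Nussinov recursion with deterministic traceback (ties prefer
    leaving the 3' base unpaired, then the 5'-most partner).  Z, EFE and the
    bpp matrix by exact inside-outside sums over all structures with hairpin
    loops >= MIN_LOOP.
    """

    kT = 1.0
    pair_energy = -1.0

    # -- MFE -------------------------------------------------------------
    def mfe(self, sequence: str) -> tuple[str, float]:
        seq = _clean(sequence)
        n = len(seq)
        best = [[0] * n for _ in range(n)]
        for span in range(MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                v = best[i][j - 1]  # j unpaired
                for k in range(i, j - MIN_LOOP):
                    if can_pair(seq[k], seq[j]):
                        left = best[i][k - 1] if k > i else 0
                        inner = best[k + 1][j - 1] if k + 1 <= j - 1 else 0
                        v = max(v, left + inner + 1)
                best[i][j] = v

        struct = ["."] * n

        def trace(i: int, j: int) -> None:
            while j - i > MIN_LOOP:
                if best[i][j] == best[i][j - 1]:
                    j -= 1
                    continue
                for k in range(i, j - MIN_LOOP):
                    if can_pair(seq[k], seq[j]):
                        left = best[i][k - 1] if k > i else 0
                        inner = best[k + 1][j - 1] if k + 1 <= j - 1 else 0
                        if left + inner + 1 == best[i][j]:
                            struct[k] = "("
                            struct[j] = ")"
                            trace(k + 1, j - 1)
                            j = k - 1
                            break
                else:  # pragma: no cover - DP/traceback mismatch cannot happen
                    raise AssertionError("traceback failed")

        if n > MIN_LOOP:
            trace(0, n - 1)
        return "".join(struct), self.pair_energy * best[0][n - 1]

    # -- partition function ----------------------------------------------
    def _inside(self, seq: str) -> list[list[float]]:
        n = len(seq)
        w = math.exp(-self.pair_energy / self.kT)
        Q = [[1.0] * n for _ in range(n)]  # Q[i][j] over seq[i..j]; empty -> 1

        def get(i: int, j: int) -> float:  # inclusive coords, 1 if empty
            return Q[i][j] if i <= j else 1.0

        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                total = get(i, j - 1)  # j unpaired
                for k in range(i, j - MIN_LOOP):
                    if can_pair(seq[k], seq[j]):
                        total += get(i, k - 1) * w * get(k + 1, j - 1)
                Q[i][j] = total
        return Q

    def partition(self, sequence: str) -> tuple[float, float]:
        """(Z, EFE) over all structures of the sequence."""
        seq = _clean(sequence)
        Q = self._inside(seq)
        z = Q[0][len(seq) - 1] if len(seq) > 1 else 1.0
        return z, -self.kT * math.log(z)

    def base_pair_probabilities(self, sequence: str) -> np.ndarray:
        seq = _clean(sequence)
        n = len(seq)
        Q = self._inside(seq)
        w = math.exp(-self.pair_energy / self.kT)

        def q(i: int, j: int) -> float:
            return Q[i][j] if 0 <= i <= j < n else 1.0

        pairable = [
            (i, j)
            for i in range(n)
            for j in range(i + MIN_LOOP + 1, n)
            if can_pair(seq[i], seq[j])
        ]

        @lru_cache(maxsize=None)
        def outside(i: int, j: int) -> float:
            # partition function over configurations of positions outside
            # [i, j] given that (i, j) is paired; the sum enumerates the
            # innermost pair (p, q) enclosing (i, j), if any.
            total = q(0, i - 1) * q(j + 1, n - 1)
            for p, qq in pairable:
                if p < i and qq > j:
                    total += w * outside(p, qq) * q(p + 1, i - 1) * q(j + 1, qq - 1)
            return total

        z = q(0, n - 1)
        bpp = np.zeros((n, n))
        for i, j in pairable:
            p = w * q(i + 1, j - 1) * outside(i, j) / z
            bpp[i, j] = bpp[j, i] = p
        outside.cache_clear()
        return bpp

    def fold(self, sequence: str) -> FoldResult:
        struct, energy = self.mfe(sequence)
        _, efe = self.partition(sequence)
        bpp = self.base_pair_probabilities(sequence)
        return FoldResult(mfe_structure=struct, mfe=energy, efe=efe, bpp=bpp)


class ViennaRNAEngine:
    """Turner-model folding via the ViennaRNA bindings (kcal/mol)."""

    def __init__(self) -> None:
        import RNA  # deferred so the toy engine works without the bindings

        self._rna = RNA

    def _compound(self, sequence: str):
        return self._rna.fold_compound(_clean(sequence))

    def mfe(self, sequence: str) -> tuple[str, float]:
        struct, energy = self._compound(sequence).mfe()
        return struct, float(energy)

    def fold(self, sequence: str) -> FoldResult:
        fc = self._compound(sequence)
        struct, energy = fc.mfe()
        fc.exp_params_rescale(energy)
        _, efe = fc.pf()
        n = len(_clean(sequence))
        raw = np.asarray(fc.bpp())  # (n+1, n+1), 1-based upper triangle
        bpp = raw[1:, 1:]
        bpp = bpp + bpp.T
        return FoldResult(
            mfe_structure=struct, mfe=float(energy), efe=float(efe), bpp=bpp
        )


_default_engine: FoldingEngine | None = None


def default_engine() -> FoldingEngine:
    """ViennaRNA if its bindings import, else the toy engine (logged)."""
    global _default_engine
    if _default_engine is None:
        try:
            _default_engine = ViennaRNAEngine()
        except ImportError:  # pragma: no cover - bindings present in CI image
            log.warning("ViennaRNA bindings unavailable; using NussinovEngine")
            _default_engine = NussinovEngine()
    return _default_engine


def fold(sequence: str, engine: FoldingEngine | None = None) -> FoldResult:
    """Fold a sequence with the given (default: thermodynamic) engine."""
    return (engine or default_engine()).fold(sequence)


# ---------------------------------------------------------------------------
# similarity measures
# ---------------------------------------------------------------------------

def bpp_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Frobenius norm of the upper-triangular bpp difference over length."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("bpp matrices must be square and of equal shape")
    n = p.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.linalg.norm(p[iu] - q[iu])) / n


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-1,
    extend_gap_score=-1,
)


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns (unit scores)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    aln = _aligner.align(a, b)[0]
    return aln.counts().identities / aln.length


# ---------------------------------------------------------------------------
# templates, criteria, candidates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignTemplate:
    """A UTR sequence split into fixed spacer and replaceable designable segments."""

    full_sequence: str
    segments: tuple[tuple[str, int, int], ...]  # (kind, start, end), tiling

    def __post_init__(self) -> None:
        seq = _clean(self.full_sequence)
        object.__setattr__(self, "full_sequence", seq)
        pos = 0
        kinds = set()
        for kind, s, e in self.segments:
            if kind not in ("spacer", "designable"):
                raise ValueError(f"unknown segment kind {kind!r}")
            if s != pos or e < s:
                raise ValueError("segments must tile the sequence without overlap")
            pos = e
            kinds.add(kind)
        if pos != len(seq):
            raise ValueError("segments must cover the full sequence")
        if "designable" not in kinds:
            raise ValueError("need at least one designable segment")

    @property
    def designable_positions(self) -> tuple[int, ...]:
        return tuple(
            i
            for kind, s, e in self.segments
            if kind == "designable"
            for i in range(s, e)
        )

    def designable_subsequence(self, sequence: str | None = None) -> str:
        seq = sequence if sequence is not None else self.full_sequence
        return "".join(seq[i] for i in self.designable_positions)

    def spacer_subsequence(self, sequence: str | None = None) -> str:
        seq = sequence if sequence is not None else self.full_sequence
        spacer = set(range(len(seq))) - set(self.designable_positions)
        return "".join(seq[i] for i in sorted(spacer))


@dataclass(frozen=True)
class DesignCriteria:
    """Acceptance bounds and search budget for analog design.

    Energies are in the engine's units (kcal/mol for ViennaRNA); the default
    +-0.5 tolerance is one thermodynamic-parameter quantum.  Identity is
    measured over the designable segments against the template's original
    content there.
    """

    mfe_tolerance: float = 0.5
    efe_tolerance: float = 0.5
    gc_weight: float = 1.0
    bpp_weight: float = 1.0
    max_identity_to_original: float = 0.6
    max_steps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mfe_tolerance < 0 or self.efe_tolerance < 0:
            raise ValueError("tolerances must be >= 0")
        if not (0 < self.max_identity_to_original <= 1):
            raise ValueError("max_identity_to_original must be in (0, 1]")
        if self.max_steps < 0:
            raise ValueError("max_steps must be >= 0")


@dataclass(frozen=True)
class DesignCandidate:
    """One designed sequence scored against the template's fold."""

    sequence: str
    fold: FoldResult
    gc_diff: float
    bpp_distance: float
    identity_to_original: float
    accepted: bool

    def score(self, criteria: DesignCriteria) -> float:
        return criteria.gc_weight * self.gc_diff + criteria.bpp_weight * self.bpp_distance


def gc_fraction(sequence: str) -> float:
    seq = _clean(sequence)
    return sum(1 for b in seq if b in "GC") / len(seq)


# ---------------------------------------------------------------------------
# the design loop
# ---------------------------------------------------------------------------

_PLATEAU_RESTART = 150  # steps without improvement before a random restart


def design_analog(
    template: DesignTemplate,
    criteria: DesignCriteria = DesignCriteria(),
    engine: FoldingEngine | None = None,
) -> list[DesignCandidate]:
    """Search for analogs reproducing the template's fold with divergent sequence.

    Seeded stochastic hill-climb: designable positions are initialized
    uniformly at random and mutated one nucleotide at a time; a mutation is
    kept when the objective (base-pair distance of the current MFE structure
    to the target structure, then |MFE mismatch|) does not get lexicographically
    worse.  Whenever the current sequence reproduces the target MFE structure,
    it is evaluated in full (EFE, bpp, GC, identity) and recorded; the search
    then restarts from a fresh random fill, as it does on a plateau.  Spacer
    positions are never touched.  Returns the accepted candidates (possibly
    none — then a diagnostic is logged, not raised), ranked by
    ``gc_weight * gc_diff + bpp_weight * bpp_distance`` ascending.
    """
    eng = engine or default_engine()
    target = eng.fold(template.full_sequence)
    target_pairs = pairs_of_structure(target.mfe_structure)
    original_designable = template.designable_subsequence()
    positions = template.designable_positions

    if not positions:
        cand = DesignCandidate(
            sequence=template.full_sequence,
            fold=target,
            gc_diff=0.0,
            bpp_distance=0.0,
            identity_to_original=0.0,
            accepted=True,
        )
        return [cand]

    rng = np.random.default_rng(criteria.seed)
    template_gc = gc_fraction(template.full_sequence)

    def random_fill(seq: list[str]) -> None:
        for i in positions:
            seq[i] = RNA_BASES[rng.integers(4)]

    def objective(seq_str: str) -> tuple[int, float, str]:
        struct, energy = eng.mfe(seq_str)
        dist = len(pairs_of_structure(struct) ^ target_pairs)
        return dist, abs(energy - target.mfe), struct

    candidates: dict[str, DesignCandidate] = {}
    current = list(template.full_sequence)
    random_fill(current)
    cur_dist, cur_emis, cur_struct = objective("".join(current))
    since_improvement = 0

    def evaluate(seq_str: str, mfe_struct: str, energy_gap: float) -> None:
        if seq_str in candidates:
            return
        full = eng.fold(seq_str)
        identity = sequence_identity(
            template.designable_subsequence(seq_str), original_designable
        )
        accepted = (
            full.mfe_structure == target.mfe_structure
            and energy_gap <= criteria.mfe_tolerance
            and abs(full.efe - target.efe) <= criteria.efe_tolerance
            and identity <= criteria.max_identity_to_original
        )
        candidates[seq_str] = DesignCandidate(
            sequence=seq_str,
            fold=full,
            gc_diff=abs(gc_fraction(seq_str) - template_gc),
            bpp_distance=bpp_distance(full.bpp, target.bpp),
            identity_to_original=identity,
            accepted=accepted,
        )

    for _ in range(criteria.max_steps):
        if cur_dist == 0:
            evaluate("".join(current), cur_struct, cur_emis)
            random_fill(current)
            cur_dist, cur_emis, cur_struct = objective("".join(current))
            since_improvement = 0
            continue
        if since_improvement >= _PLATEAU_RESTART:
            random_fill(current)
            cur_dist, cur_emis, cur_struct = objective("".join(current))
            since_improvement = 0
            continue
        i = positions[rng.integers(len(positions))]
        old = current[i]
        new = RNA_BASES[rng.integers(4)]
        if new == old:
            since_improvement += 1
            continue
        current[i] = new
        dist, emis, struct = objective("".join(current))
        if (dist, emis) <= (cur_dist, cur_emis):
            if (dist, emis) < (cur_dist, cur_emis):
                since_improvement = 0
            else:
                since_improvement += 1
            cur_dist, cur_emis, cur_struct = dist, emis, struct
        else:
            current[i] = old
            since_improvement += 1
    if cur_dist == 0:
        evaluate("".join(current), cur_struct, cur_emis)

    accepted = [c for c in candidates.values() if c.accepted]
    if not accepted:
        log.warning(
            "design search exhausted %d steps without an accepted candidate "
            "(%d structure matches rejected on energy/identity bounds)",
            criteria.max_steps,
            len(candidates),
        )
    accepted.sort(key=lambda c: (c.score(criteria), c.sequence))
    return accepted
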
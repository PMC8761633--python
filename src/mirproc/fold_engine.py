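"""Minimum-free-energy folding of nested RNA secondary structures.

A self-contained nearest-neighbor energy model (Watson-Crick + GU stacking,
Jacobson-Stockmayer-style loop size penalties, affine multiloops) drives a
Zuker-style dynamic program. The model is deliberately desk-scale: no
pseudoknots, no dangling ends or coaxial stacking, minimum hairpin loop of
three unpaired nucleotides — small enough that exhaustive enumeration can
verify optimality on short sequences, while preserving the relative ΔG
ordering that downstream hairpin-domain analyses depend on.

Energies are handled internally as integer centi-kcal/mol so that
co-optimality is exact; the public API reports kcal/mol floats.

Tie-breaking among co-optimal structures: maximal pair count first, then the
lexicographically smallest dot-bracket string (with ``'(' < ')' < '.'``,
which is plain ASCII order).
"""
from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from ._fold_kernel import INF, fill_tables

_RT37 = 0.616  # kcal/mol at 37 degrees C
_JS = 1.75 * _RT37  # Jacobson-Stockmayer extrapolation slope

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIRS = ["AU", "UA", "GC", "CG", "GU", "UG"]

_PAIR_IDX = np.full((4, 4), -1, dtype=np.int8)
for _k, _pq in enumerate(_PAIRS):
    _PAIR_IDX[_CODE[_pq[0]], _CODE[_pq[1]]] = _k


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an RNA string to integer codes; reject anything outside ACGU."""
    try:
        return np.array([_CODE[c] for c in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(
            f"invalid RNA character {exc.args[0]!r} in sequence"
        ) from None


class EnergyModel:
    """Nearest-neighbor parameter set.

    Parameters are loaded from two packaged TSV tables: pairwise stacking
    free energies (symmetric under strand flip) and loop-size penalties with
    logarithmic extrapolation beyond the tabulated sizes.
    """

    def __init__(self, stack_energies: dict, hairpin_loop_penalty: dict,
                 bulge_penalty: dict, internal_loop_penalty: dict,
                 multiloop_affine: tuple[float, float, float],
                 min_hairpin_unpaired: int = 3, max_interior_span: int = 30):
        self.stack_energies = dict(stack_energies)
        self.hairpin_loop_penalty = dict(hairpin_loop_penalty)
        self.bulge_penalty = dict(bulge_penalty)
        self.internal_loop_penalty = dict(internal_loop_penalty)
        self.multiloop_affine = tuple(multiloop_affine)
        self.min_hairpin_unpaired = int(min_hairpin_unpaired)
        self.max_interior_span = int(max_interior_span)
        self.allowed_pairs = frozenset(_PAIRS)
        self._check_flip_symmetry()
        # integer (centi-kcal) stacking matrix in canonical pair order
        self._stack_ci = np.zeros((6, 6), dtype=np.int32)
        for a, p1 in enumerate(_PAIRS):
            for b, p2 in enumerate(_PAIRS):
                self._stack_ci[a, b] = round(100 * self.stack_energies[(p1, p2)])
        self._ml_ci = tuple(round(100 * x) for x in self.multiloop_affine)

    @staticmethod
    def _flip(p: str) -> str:
        return p[1] + p[0]

    def _check_flip_symmetry(self) -> None:
        for (p1, p2), e in self.stack_energies.items():
            mirror = self.stack_energies[(self._flip(p2), self._flip(p1))]
            if abs(e - mirror) > 1e-9:
                raise ValueError(f"stack table not flip-symmetric at {(p1, p2)}")

    @classmethod
    def default(cls) -> "EnergyModel":
        data = resources.files("mirproc").joinpath("data")
        stacks = {}
        with data.joinpath("stack_energies.tsv").open() as fh:
            next(fh)
            for line in fh:
                p1, p2, e = line.split("\t")
                stacks[(p1, p2)] = float(e)
        hp, bu, il = {}, {}, {}
        ml = {}
        with data.joinpath("loop_penalties.tsv").open() as fh:
            next(fh)
            for line in fh:
                kind, size, e = line.split("\t")
                if kind == "hairpin":
                    hp[int(size)] = float(e)
                elif kind == "bulge":
                    bu[int(size)] = float(e)
                elif kind == "internal":
                    il[int(size)] = float(e)
                else:
                    ml[kind] = float(e)
        affine = (ml["multiloop_offset"], ml["multiloop_branch"],
                  ml["multiloop_unpaired"])
        return cls(stacks, hp, bu, il, affine)

    # ---- size-penalty evaluation (centi-kcal ints) ----

    def _pen_ci(self, table: dict, size: int) -> int:
        if size in table:
            return round(100 * table[size])
        mx = max(table)
        return round(100 * (table[mx] + _JS * math.log(size / mx)))

    def hairpin_ci(self, size: int) -> int:
        if size < self.min_hairpin_unpaired:
            raise ValueError(f"hairpin loop of {size} < minimum "
                             f"{self.min_hairpin_unpaired} unpaired")
        return self._pen_ci(self.hairpin_loop_penalty, size)

    def bulge_ci(self, size: int) -> int:
        return self._pen_ci(self.bulge_penalty, size)

    def internal_ci(self, size: int) -> int:
        return self._pen_ci(self.internal_loop_penalty, size)

    def penalty_arrays(self, n: int):
        """Penalty vectors indexed by loop size, long enough for length n."""
        hp = np.zeros(max(n, self.min_hairpin_unpaired + 1), dtype=np.int32)
        for s in range(self.min_hairpin_unpaired, hp.shape[0]):
            hp[s] = self.hairpin_ci(s)
        m = self.max_interior_span
        bu = np.zeros(m + 1, dtype=np.int32)
        il = np.zeros(m + 1, dtype=np.int32)
        for s in range(1, m + 1):
            bu[s] = self.bulge_ci(s)
        for s in range(2, m + 1):
            il[s] = self.internal_ci(s)
        return hp, bu, il


_DEFAULT_MODEL: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = EnergyModel.default()
    return _DEFAULT_MODEL


@dataclass
class FoldResult:
    """A single nested secondary structure with its free energy."""
    sequence: str
    dotbracket: str
    pair_table: np.ndarray  # 1-based partner per position, 0 = unpaired
    delta_g: float  # kcal/mol
    _dg_ci: int = field(default=0, repr=False)

    def partner(self, pos: int) -> int:
        """1-based pairing partner of 1-based position ``pos`` (0 if unpaired)."""
        return int(self.pair_table[pos - 1])


def pair_table_from_dotbracket(dotbracket: str) -> np.ndarray:
    """1-based partner array (0 = unpaired). Raises on unbalanced input."""
    pt = np.zeros(len(dotbracket), dtype=np.int64)
    stack = []
    for idx, c in enumerate(dotbracket):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket: unmatched ')'")
            i = stack.pop()
            pt[i] = idx + 1
            pt[idx] = i + 1
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unmatched '('")
    return pt


# --------------------------------------------------------------------------
# loop decomposition and structure evaluation
# --------------------------------------------------------------------------

@dataclass
class LoopTerm:
    """One additive term of the loop decomposition.

    ``participants`` is the frozen set of 0-based positions the term touches:
    both closing pairs for stacks and two-sided loops, the whole enclosed
    region for hairpin loops, and the loop-facing positions for multiloops.
    """
    kind: str  # 'stack' | 'hairpin' | 'bulge' | 'internal' | 'multiloop'
    energy_ci: int
    participants: frozenset


def loop_decomposition(sequence: str, dotbracket: str,
                       model: EnergyModel | None = None) -> list[LoopTerm]:
    """Decompose a structure into its additive nearest-neighbor terms."""
    model = model or default_model()
    seq = encode_sequence(sequence)
    if len(dotbracket) != len(seq):
        raise ValueError("sequence/structure length mismatch")
    pt = pair_table_from_dotbracket(dotbracket)
    terms: list[LoopTerm] = []
    ml_a, ml_b, ml_c = model._ml_ci
    for i0 in range(len(seq)):
        j1 = pt[i0]
        if j1 == 0 or j1 - 1 < i0:
            continue
        i, j = i0, int(j1) - 1
        pi = _PAIR_IDX[seq[i], seq[j]]
        if pi < 0:
            raise ValueError(
                f"disallowed pair {sequence[i]}{sequence[j]} at "
                f"({i + 1},{j + 1})")
        # walk the loop closed by (i, j)
        children = []
        unpaired = []
        p = i + 1
        while p < j:
            q = pt[p]
            if q == 0:
                unpaired.append(p)
                p += 1
            else:
                children.append((p, int(q) - 1))
                p = int(q)
        if not children:
            size = j - i - 1
            if size < model.min_hairpin_unpaired:
                raise ValueError(f"hairpin loop of {size} unpaired at "
                                 f"({i + 1},{j + 1}) below minimum")
            terms.append(LoopTerm("hairpin", model.hairpin_ci(size),
                                  frozenset(range(i, j + 1))))
        elif len(children) == 1:
            k, l = children[0]
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 and s2 == 0:
                pk = _PAIR_IDX[seq[k], seq[l]]
                terms.append(LoopTerm("stack", int(model._stack_ci[pi, pk]),
                                      frozenset((i, k, l, j))))
            else:
                part = frozenset(range(i, k + 1)) | frozenset(range(l, j + 1))
                if s1 == 0 or s2 == 0:
                    terms.append(LoopTerm("bulge", model.bulge_ci(s1 + s2), part))
                else:
                    terms.append(
                        LoopTerm("internal", model.internal_ci(s1 + s2), part))
        else:
            part = {i, j} | set(unpaired)
            for k, l in children:
                part |= {k, l}
            e = ml_a + ml_b * (len(children) + 1) + ml_c * len(unpaired)
            terms.append(LoopTerm("multiloop", e, frozenset(part)))
    return terms


def evaluate_structure_energy(sequence: str, dotbracket: str,
                              model: EnergyModel | None = None) -> float:
    """Free energy (kcal/mol) of a fixed structure by loop decomposition."""
    return _evaluate_ci(sequence, dotbracket, model) / 100.0


def _evaluate_ci(sequence: str, dotbracket: str,
                 model: EnergyModel | None = None) -> int:
    return sum(t.energy_ci for t in loop_decomposition(sequence, dotbracket, model))


def _normalize_region(region) -> frozenset:
    """Accept a set/iterable of 1-based positions or a list of (start, end)
    1-based inclusive spans."""
    pos = set()
    for item in region:
        if isinstance(item, tuple):
            a, b = item
            pos.update(range(int(a), int(b) + 1))
        else:
            pos.add(int(item))
    return frozenset(p - 1 for p in pos)  # 0-based


def region_energy(sequence: str, dotbracket: str, region,
                  model: EnergyModel | None = None,
                  return_boundary: bool = False):
    """ΔG attributed to a coordinate region (kcal/mol).

    A decomposition term is attributed to the region only when every
    participating nucleotide lies inside it; terms straddling the region
    boundary are excluded (and optionally reported separately). Consequently
    ``region_energy`` over the full sequence equals the total ΔG, and regions
    that tile the molecule along decomposition boundaries sum exactly to it.
    """
    model = model or default_model()
    region0 = _normalize_region(region)
    n = len(sequence)
    if region0 and (min(region0) < 0 or max(region0) >= n):
        raise ValueError("region outside sequence bounds")
    inside = 0
    boundary = 0
    for t in loop_decomposition(sequence, dotbracket, model):
        if t.participants <= region0:
            inside += t.energy_ci
        elif t.participants & region0:
            boundary += t.energy_ci
    if return_boundary:
        return inside / 100.0, boundary / 100.0
    return inside / 100.0


# --------------------------------------------------------------------------
# MFE folding
# --------------------------------------------------------------------------

def fold_mfe(sequence: str, model: EnergyModel | None = None) -> FoldResult:
    """Most stable nested structure under the nearest-neighbor model.

    Deterministic: among co-optimal structures the one with the most pairs
    is chosen, then the lexicographically smallest dot-bracket.
    """
    model = model or default_model()
    seq = encode_sequence(sequence)
    n = seq.shape[0]
    if n == 0:
        raise ValueError("empty sequence")
    if n <= model.min_hairpin_unpaired + 1:
        return FoldResult(sequence, "." * n, np.zeros(n, dtype=np.int64), 0.0, 0)
    hp, bu, il = model.penalty_arrays(n)
    ml_a, ml_b, ml_c = model._ml_ci
    V, Vp, WM, WMp, Wsuf, Wp = fill_tables(
        seq, _PAIR_IDX, model._stack_ci, hp, bu, il,
        np.int32(ml_a), np.int32(ml_b), np.int32(ml_c),
        model.min_hairpin_unpaired, model.max_interior_span)
    db = _traceback(seq, model, hp, bu, il, V, Vp, WM, WMp, Wsuf, Wp)
    dg_ci = int(Wsuf[0])
    return FoldResult(sequence, db, pair_table_from_dotbracket(db),
                      dg_ci / 100.0, dg_ci)


def _traceback(seq, model, hp, bu, il, V, Vp, WM, WMp, Wsuf, Wp) -> str:
    """Lex-min dot-bracket among (energy, -pairs)-optimal structures."""
    n = seq.shape[0]
    min_hp = model.min_hairpin_unpaired
    maxloop = model.max_interior_span
    ml_a, ml_b, ml_c = model._ml_ci
    memo: dict = {}
    limit = max(sys.getrecursionlimit(), 6 * n + 200)
    sys.setrecursionlimit(limit)
    # precomputed interior-loop cost template: entry (s1, s2) is the cost of
    # an interior/bulge extension with those unpaired sizes; (0, 0) is patched
    # per closing pair with the actual stack term
    M = maxloop + 1
    cost_grid = np.zeros((M, M), dtype=np.int64)
    for s1 in range(M):
        for s2 in range(M):
            if s1 + s2 == 0 or s1 + s2 > maxloop:
                continue
            if s1 == 0 or s2 == 0:
                cost_grid[s1, s2] = bu[s1 + s2]
            else:
                cost_grid[s1, s2] = il[s1 + s2]
    tri_grid = np.add.outer(np.arange(M), np.arange(M))

    def ext(i: int) -> str:
        if i == n:
            return ""
        key = ("E", i)
        if key in memo:
            return memo[key]
        E, P = int(Wsuf[i]), int(Wp[i])
        cands = []
        if int(Wsuf[i + 1]) == E and int(Wp[i + 1]) == P:
            cands.append(("u", 0))
        ks = np.arange(i + min_hp + 1, n)
        if ks.size:
            ok = (V[i, ks].astype(np.int64) + Wsuf[ks + 1] == E) & \
                 (Vp[i, ks] + Wp[ks + 1] == P) & (V[i, ks] < INF)
            for k in ks[ok]:
                cands.append(("p", int(k)))
        out = _pick(cands, lambda c: "." + ext(i + 1) if c[0] == "u"
                    else vtrace(i, c[1]) + ext(c[1] + 1))
        memo[key] = out
        return out

    def vtrace(i: int, j: int) -> str:
        key = ("V", i, j)
        if key in memo:
            return memo[key]
        E, P = int(V[i, j]), int(Vp[i, j])
        d = j - i
        cands = []
        if P == 1 and int(hp[d - 1]) == E:
            cands.append(("h", 0, 0))
        # interior/bulge/stack candidates scanned as one (s1, s2) grid
        cap = min(maxloop, d - min_hp - 3)
        if cap >= 0:
            S = cap + 1
            sub = V[i + 1:i + 1 + S, j - S:j][:, ::-1].astype(np.int64)
            subp = Vp[i + 1:i + 1 + S, j - S:j][:, ::-1]
            costs = cost_grid[:S, :S].copy()
            if V[i + 1, j - 1] < INF:
                pi = _PAIR_IDX[seq[i], seq[j]]
                pin = _PAIR_IDX[seq[i + 1], seq[j - 1]]
                costs[0, 0] = model._stack_ci[pi, pin]
            ok = (sub < INF) & (subp + 1 == P) & (tri_grid[:S, :S] <= cap) \
                & (sub + costs == E)
            for s1, s2 in np.argwhere(ok):
                cands.append(("i", i + 1 + int(s1), j - 1 - int(s2)))
        ks = np.arange(i + 1, j - 1)
        if ks.size:
            a = WM[i + 1, ks].astype(np.int64)
            b = WM[ks + 1, j - 1].astype(np.int64)
            ok = (a < INF) & (b < INF) & (ml_a + ml_b + a + b == E) & \
                 (1 + WMp[i + 1, ks] + WMp[ks + 1, j - 1] == P)
            for k in ks[ok]:
                cands.append(("m", int(k), 0))

        def build(c):
            kind, k, l = c
            if kind == "h":
                return "(" + "." * (j - i - 1) + ")"
            if kind == "i":
                return ("(" + "." * (k - i - 1) + vtrace(k, l)
                        + "." * (j - l - 1) + ")")
            return "(" + wmtrace(i + 1, k) + wmtrace(k + 1, j - 1) + ")"

        out = _pick(cands, build)
        memo[key] = out
        return out

    def wmtrace(i: int, j: int) -> str:
        key = ("M", i, j)
        if key in memo:
            return memo[key]
        E, P = int(WM[i, j]), int(WMp[i, j])
        cands = []
        if V[i, j] < INF and int(V[i, j]) + ml_b == E and int(Vp[i, j]) == P:
            cands.append(("v", 0))
        if i < j and WM[i + 1, j] < INF and int(WM[i + 1, j]) + ml_c == E \
                and int(WMp[i + 1, j]) == P:
            cands.append(("l", 0))
        if i < j and WM[i, j - 1] < INF and int(WM[i, j - 1]) + ml_c == E \
                and int(WMp[i, j - 1]) == P:
            cands.append(("r", 0))
        ks = np.arange(i + 1, j)
        if ks.size:
            a = WM[i, ks].astype(np.int64)
            b = WM[ks + 1, j].astype(np.int64)
            ok = (a < INF) & (b < INF) & (a + b == E) & \
                 (WMp[i, ks] + WMp[ks + 1, j] == P)
            for k in ks[ok]:
                cands.append(("s", int(k)))

        def build(c):
            kind, k = c
            if kind == "v":
                return vtrace(i, j)
            if kind == "l":
                return "." + wmtrace(i + 1, j)
            if kind == "r":
                return wmtrace(i, j - 1) + "."
            return wmtrace(i, k) + wmtrace(k + 1, j)

        out = _pick(cands, build)
        memo[key] = out
        return out

    def _pick(cands, build):
        if not cands:
            raise AssertionError("traceback found no optimal case")
        if len(cands) == 1:
            return build(cands[0])
        return min(build(c) for c in cands)

    return ext(0)


# --------------------------------------------------------------------------
# dot-bracket record I/O
# --------------------------------------------------------------------------

def write_fold(path, record_id: str, fold: FoldResult) -> None:
    """Write a single ``>id / sequence / structure (ΔG)`` dot-bracket record."""
    with open(path, "a") as fh:
        fh.write(f">{record_id}\n{fold.sequence}\n"
                 f"{fold.dotbracket} ({fold.delta_g:.2f})\n")


def read_folds(path) -> dict[str, FoldResult]:
    """Read dot-bracket records written by :func:`write_fold`."""
    out: dict[str, FoldResult] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for a in range(0, len(lines), 3):
        rid = lines[a].lstrip(">")
        seq = lines[a + 1]
        struct_line = lines[a + 2]
        db, dg = struct_line.rsplit(" ", 1)
        out[rid] = FoldResult(seq, db, pair_table_from_dotbracket(db),
                              float(dg.strip("()")),
                              round(100 * float(dg.strip("()"))))
    return out
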
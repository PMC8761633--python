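"""Shared fixtures and independent oracles for the test suite."""
from functools import lru_cache

import numpy as np
import pytest

from mirproc.fold_engine import (_PAIR_IDX, _evaluate_ci, default_model,
                                 encode_sequence)
from mirproc.synthetic_data import GeneratorConfig, generate_cohort

MIN_HP = 3


def enumerate_structures(seq: str) -> list[str]:
    """Every admissible nested structure of ``seq`` (allowed pairs only,
    hairpin loops of at least three unpaired bases)."""
    codes = encode_sequence(seq)
    n = len(seq)

    @lru_cache(maxsize=None)
    def enum(i, j):
        if j - i <= 0:
            return ("",)
        out = ["." + s for s in enum(i + 1, j)]
        for k in range(i + MIN_HP + 1, j):
            if _PAIR_IDX[codes[i], codes[k]] >= 0:
                for inner in enum(i + 1, k):
                    for rest in enum(k + 1, j):
                        out.append("(" + inner + ")" + rest)
        return tuple(out)

    return list(enum(0, n))


def brute_force_mfe(seq: str, model=None) -> tuple[int, str]:
    """Exhaustive-enumeration optimum under the same tie-break rule as the
    folding engine: minimal energy, then maximal pair count, then the
    lexicographically smallest dot-bracket. Returns (energy_ci, dotbracket)."""
    model = model or default_model()
    best = None
    for db in enumerate_structures(seq):
        e = _evaluate_ci(seq, db, model)
        key = (e, -db.count("("), db)
        if best is None or key < best:
            best = key
    return best[0], best[2]


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort reused by structural tests (kept small: every
    hairpin is folded by several tests)."""
    return generate_cohort(GeneratorConfig(n_mirnas=40, seed=11))
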
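"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from crispramp.align import ScoringScheme
from crispramp.simulate import generate_locus


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def cas9_locus():
    return generate_locus(11, 300, "EcoRI", "cas9")


@pytest.fixture(scope="session")
def nickase_locus():
    return generate_locus(12, 300, "SacI", "nickase")


def enumerate_best_score(read: str, ref: str, scheme: ScoringScheme) -> float:
    """Exhaustive recursive enumeration of every monotone alignment path of a
    semi-global (read-global, reference end-gap-free) affine-gap alignment.

    Exponential; only usable for tiny inputs. Serves as the ground truth
    that validates the scalar reference scorer, which in turn validates the
    vectorized aligner.
    """
    m, n = len(read), len(ref)
    go_pen, ge = scheme.gap_open, scheme.gap_extend
    best = -np.inf

    def walk(i: int, j: int, prev: str | None, acc: float) -> None:
        nonlocal best
        if i == m:  # unaligned reference suffix is free
            best = max(best, acc)
            return
        if j < n:
            s = scheme.match if read[i] == ref[j] else scheme.mismatch
            walk(i + 1, j + 1, "M", acc + s)
            walk(i, j + 1, "D", acc + ge + (go_pen if prev != "D" else 0))
        walk(i + 1, j, "I", acc + ge + (go_pen if prev != "I" else 0))

    for start in range(n + 1):  # unaligned reference prefix is free
        walk(0, start, None, 0.0)
    return best


def all_sequences(alphabet: str, max_len: int):
    """Every non-empty sequence over ``alphabet`` up to ``max_len``."""
    for ln in range(1, max_len + 1):
        for tup in itertools.product(alphabet, repeat=ln):
            yield "".join(tup)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
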
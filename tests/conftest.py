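"""Shared fixtures and the independent brute-force scoring oracle.

The oracle deliberately re-derives everything from the sequence with plain
Python string operations — per window, per site, per dinucleotide step — so
it shares no code path with the vectorized kernel it checks.
"""

import numpy as np
import pytest

from wsnuc import build_template

_WW = {"AA", "TT", "AT", "TA"}
_SS = {"GG", "CC", "GC", "CG"}


def oracle_window_score(window: str, template) -> int:
    """Brute-force gain/penalty sum over every site of one window."""
    window = window.upper()
    total = 0
    for site in template.sites:
        tet = window[site.start - 1 : site.end]
        c_ww = sum(tet[i : i + 2] in _WW for i in range(3))
        c_ss = sum(tet[i : i + 2] in _SS for i in range(3))
        if site.groove == "minor":
            total += c_ww - c_ss
        else:
            total += c_ss - c_ww
    return total


def oracle_profile(seq: str, t147, t146) -> list[int]:
    """Max-of-three frame score at every valid dyad, rescanning each window."""
    out = []
    for n in range(73, len(seq) - 73):
        out.append(
            max(
                oracle_window_score(seq[n - 73 : n + 74], t147),
                oracle_window_score(seq[n - 73 : n + 73], t146),
                oracle_window_score(seq[n - 72 : n + 74], t146),
            )
        )
    return out


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


@pytest.fixture(scope="session")
def t147():
    return build_template(147)


@pytest.fixture(scope="session")
def t146():
    return build_template(146)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230913)
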
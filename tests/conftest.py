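"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive pure-Python enumeration (substring
recounts, full IUPAC expansion, per-position scans) so they share no
code path with the implementations they check.
"""

from __future__ import annotations

import itertools

import pytest

from methclone.seq_core import IUPAC_EXPANSION, ReferenceLocus


@pytest.fixture
def toy_locus() -> ReferenceLocus:
    return ReferenceLocus(id="toy", sequence="AACGACTGACTTA")


def expand_iupac(pattern: str) -> set[str]:
    """All concrete words a degenerate IUPAC pattern stands for."""
    return {
        "".join(word)
        for word in itertools.product(
            *(sorted(IUPAC_EXPANSION[c]) for c in pattern.upper())
        )
    }


def oracle_islands(
    seq: str,
    window: int = 100,
    min_length: int = 100,
    min_gc: float = 0.50,
    min_obs_exp: float = 0.60,
) -> list[tuple[int, int]]:
    """Maximal runs of passing windows, recounted per window from scratch."""

    def window_passes(sub: str) -> bool:
        n_valid = len(sub) - sub.count("N")
        if n_valid == 0:
            return False
        gc = (sub.count("G") + sub.count("C")) / n_valid
        n_c, n_g = sub.count("C"), sub.count("G")
        oe = 0.0 if n_c * n_g == 0 else sub.count("CG") * len(sub) / (n_c * n_g)
        return gc >= min_gc and oe >= min_obs_exp

    starts = [
        i for i in range(len(seq) - window + 1) if window_passes(seq[i : i + window])
    ]
    regions = []
    run: list[int] = []
    for s in starts + [None]:
        # windows overlap or abut while successive starts differ by <= window
        if run and (s is None or s - run[-1] > window):
            if (run[-1] + window) - run[0] >= min_length:
                regions.append((run[0], run[-1] + window))
            run = []
        if s is not None:
            run.append(s)
    return regions


def oracle_context(seq: str, pos: int) -> str | None:
    """Direct trinucleotide classification of the C at ``pos``."""
    assert seq[pos] == "C"
    tri = seq[pos : pos + 3]
    if len(tri) >= 2 and tri[1] == "G":
        return "CpG"
    if len(tri) < 3 or "N" in tri[1:]:
        return None
    if tri[1] in "ACT" and tri[2] == "G":
        return "CpHpG"
    if tri[1] in "ACT" and tri[2] in "ACT":
        return "CpHpH"
    return None


def oracle_scan(seq: str, pattern: str) -> list[tuple[int, int, str]]:
    """Motif scan by full expansion + substring search, both strands."""
    comp = str.maketrans("ACGT", "TGCA")
    hits = []
    words = expand_iupac(pattern)
    rc_words = {w.translate(comp)[::-1] for w in words}
    L = len(pattern)
    for i in range(len(seq) - L + 1):
        sub = seq[i : i + L]
        if sub in words:
            hits.append((i, i + L, "+"))
        if sub in rc_words:
            hits.append((i, i + L, "-"))
    return hits
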
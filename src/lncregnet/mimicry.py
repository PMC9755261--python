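"""miRNA target-mimicry screening by penalty-scored duplex alignment.

A lncRNA acts as a target mimic when a stretch of it is near-complementary
to a mature miRNA.  Candidate sites are scored by a banded antiparallel
alignment with an expectation penalty: Watson-Crick pair 0, G:U wobble 0.5,
mismatch 1.0, gap 2.0, all doubled within the miRNA seed (positions 2-13).
Sites pass with expectation <= 5 and fewer than four mismatches.  The
unpairing-energy (UPE) filter of structure-aware screens is not evaluated
here (it needs RNA secondary-structure prediction); the field is reported
as None.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["MiRNADuplex", "duplex_score", "screen"]

PAIR_WC = 0.0
PAIR_GU = 0.5
PAIR_MISMATCH = 1.0
GAP_PENALTY = 2.0
SEED_START, SEED_END = 2, 13  # miRNA positions (1-based, inclusive)
SEED_MULTIPLIER = 2.0
MAX_BULGE = 2  # site length may differ from miRNA length by at most this

DEFAULT_MAX_EXPECTATION = 5.0
DEFAULT_MAX_MISMATCHES = 3

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# pair penalty matrix indexed [mirna_base, site_base]; T stands for U.
_PAIR_PENALTY = np.full((4, 4), PAIR_MISMATCH)
for _m, _t in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _PAIR_PENALTY[_BASE_INDEX[_m], _BASE_INDEX[_t]] = PAIR_WC
for _m, _t in (("G", "T"), ("T", "G")):
    _PAIR_PENALTY[_BASE_INDEX[_m], _BASE_INDEX[_t]] = PAIR_GU
_IS_MISMATCH = (_PAIR_PENALTY == PAIR_MISMATCH).astype(np.int64)


@dataclass(frozen=True)
class MiRNADuplex:
    mirna_id: str
    lncrna_id: str
    offset: int  # site start within the lncRNA (0-based)
    site: str  # lncRNA subsequence, 5'->3'
    alignment: str  # per miRNA-side column: | WC, o G:U, x mismatch, - gap
    expectation: float
    n_mismatches: int
    upe: float | None = None  # not evaluated (structure term out of scope)


def _normalize(seq: str, label: str) -> str:
    seq = seq.upper().replace("U", "T")
    if any(b not in _BASE_INDEX for b in seq):
        raise ValueError(f"{label} contains non-nucleotide characters: {seq!r}")
    return seq


def _seed_mult(position: int) -> float:
    return SEED_MULTIPLIER if SEED_START <= position <= SEED_END else 1.0


def duplex_score(mirna: str, site: str, mirna_id: str = "", lncrna_id: str = "",
                 offset: int = 0) -> MiRNADuplex:
    """Best banded antiparallel pairing of a miRNA against a candidate site.

    The miRNA (5'->3') pairs the site read 3'->5'; at most ``MAX_BULGE``
    unpaired bases are allowed on either strand.  Ties in expectation are
    broken toward fewer mismatches.
    """
    m = _normalize(mirna, "miRNA")
    s = _normalize(site, "site")
    M, S = len(m), len(s)
    if not (M - MAX_BULGE <= S <= M + MAX_BULGE):
        raise ValueError(
            f"site length {S} outside [{M - MAX_BULGE}, {M + MAX_BULGE}]"
        )
    rt = s[::-1]  # site 3'->5'
    INF = float("inf")
    # dp[i][j]: (cost, mismatches) aligning first i miRNA bases with first j
    # bases of the reversed site, band |i-j| <= MAX_BULGE.
    cost = [[INF] * (S + 1) for _ in range(M + 1)]
    mism = [[0] * (S + 1) for _ in range(M + 1)]
    back: dict[tuple[int, int], tuple[int, int, str]] = {}
    cost[0][0] = 0.0
    for j in range(1, MAX_BULGE + 1):
        if j > S:
            break
        cost[0][j] = cost[0][j - 1] + GAP_PENALTY * _seed_mult(1)
        back[(0, j)] = (0, j - 1, "-")
    for i in range(1, M + 1):
        for j in range(max(0, i - MAX_BULGE), min(S, i + MAX_BULGE) + 1):
            best = (INF, 0, None)
            if j >= 1 and cost[i - 1][j - 1] < INF:
                mi, ti = _BASE_INDEX[m[i - 1]], _BASE_INDEX[rt[j - 1]]
                pen = _PAIR_PENALTY[mi, ti] * _seed_mult(i)
                sym = "|" if _PAIR_PENALTY[mi, ti] == PAIR_WC else (
                    "o" if _PAIR_PENALTY[mi, ti] == PAIR_GU else "x"
                )
                cand = (
                    cost[i - 1][j - 1] + pen,
                    mism[i - 1][j - 1] + int(sym == "x"),
                    (i - 1, j - 1, sym),
                )
                if (cand[0], cand[1]) < (best[0], best[1]):
                    best = cand
            if cost[i - 1][j] < INF:  # miRNA base unpaired (gap in site)
                cand = (
                    cost[i - 1][j] + GAP_PENALTY * _seed_mult(i),
                    mism[i - 1][j],
                    (i - 1, j, "-"),
                )
                if (cand[0], cand[1]) < (best[0], best[1]):
                    best = cand
            if j >= 1 and cost[i][j - 1] < INF:  # site base unpaired
                cand = (
                    cost[i][j - 1] + GAP_PENALTY * _seed_mult(min(i + 1, M)),
                    mism[i][j - 1],
                    (i, j - 1, "-"),
                )
                if (cand[0], cand[1]) < (best[0], best[1]):
                    best = cand
            if best[2] is not None:
                cost[i][j], mism[i][j] = best[0], best[1]
                back[(i, j)] = best[2]
    # traceback
    symbols = []
    node = (M, S)
    while node != (0, 0):
        pi, pj, sym = back[node]
        symbols.append(sym)
        node = (pi, pj)
    return MiRNADuplex(
        mirna_id=mirna_id,
        lncrna_id=lncrna_id,
        offset=offset,
        site=s,
        alignment="".join(reversed(symbols)),
        expectation=float(cost[M][S]),
        n_mismatches=int(mism[M][S]),
    )


def _vector_costs(
    m_enc: np.ndarray, lnc_enc: np.ndarray, site_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Banded DP vectorized over all site start offsets for one site length.

    Returns (expectation, n_mismatches) arrays over starts 0..len-site_len.
    """
    M = m_enc.size
    n = lnc_enc.size - site_len + 1
    if n <= 0:
        return np.zeros(0), np.zeros(0, dtype=np.int64)
    INF = 1e18
    cost: dict[tuple[int, int], np.ndarray] = {(0, 0): np.zeros(n)}
    mism: dict[tuple[int, int], np.ndarray] = {(0, 0): np.zeros(n, dtype=np.int64)}
    for j in range(1, MAX_BULGE + 1):
        if j > site_len:
            break
        cost[(0, j)] = cost[(0, j - 1)] + GAP_PENALTY * _seed_mult(1)
        mism[(0, j)] = mism[(0, j - 1)]
    for i in range(1, M + 1):
        for j in range(max(0, i - MAX_BULGE), min(site_len, i + MAX_BULGE) + 1):
            c_best = np.full(n, INF)
            m_best = np.zeros(n, dtype=np.int64)
            if j >= 1 and (i - 1, j - 1) in cost:
                # reversed-site base j pairs lnc position start + site_len - j
                sb = lnc_enc[site_len - j : site_len - j + n]
                pen = _PAIR_PENALTY[m_enc[i - 1], sb] * _seed_mult(i)
                c_new = cost[(i - 1, j - 1)] + pen
                m_new = mism[(i - 1, j - 1)] + _IS_MISMATCH[m_enc[i - 1], sb]
                better = (c_new < c_best) | ((c_new == c_best) & (m_new < m_best))
                c_best = np.where(better, c_new, c_best)
                m_best = np.where(better, m_new, m_best)
            if (i - 1, j) in cost:
                c_new = cost[(i - 1, j)] + GAP_PENALTY * _seed_mult(i)
                m_new = mism[(i - 1, j)]
                better = (c_new < c_best) | ((c_new == c_best) & (m_new < m_best))
                c_best = np.where(better, c_new, c_best)
                m_best = np.where(better, m_new, m_best)
            if j >= 1 and (i, j - 1) in cost:
                c_new = cost[(i, j - 1)] + GAP_PENALTY * _seed_mult(min(i + 1, M))
                m_new = mism[(i, j - 1)]
                better = (c_new < c_best) | ((c_new == c_best) & (m_new < m_best))
                c_best = np.where(better, c_new, c_best)
                m_best = np.where(better, m_new, m_best)
            cost[(i, j)] = c_best
            mism[(i, j)] = m_best
    return cost[(M, site_len)], mism[(M, site_len)]


def screen(
    mirnas: Mapping[str, str],
    lncrnas: Mapping[str, str],
    max_expectation: float = DEFAULT_MAX_EXPECTATION,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[MiRNADuplex]:
    """All passing miRNA/lncRNA duplex sites, sorted deterministically.

    Every site start is evaluated at site lengths within +-MAX_BULGE of the
    miRNA length (best length kept per start); a site passes with
    expectation <= ``max_expectation`` and n_mismatches <= ``max_mismatches``.
    Output order is independent of input ordering.
    """
    results: list[MiRNADuplex] = []
    for mirna_id in sorted(mirnas):
        m = _normalize(mirnas[mirna_id], "miRNA")
        m_enc = np.array([_BASE_INDEX[b] for b in m], dtype=np.int64)
        M = m_enc.size
        for lncrna_id in sorted(lncrnas):
            lnc = _normalize(lncrnas[lncrna_id], "lncRNA")
            lnc_enc = np.array([_BASE_INDEX[b] for b in lnc], dtype=np.int64)
            best_at_start: dict[int, tuple[float, int, int]] = {}
            for site_len in range(M - MAX_BULGE, M + MAX_BULGE + 1):
                costs, mms = _vector_costs(m_enc, lnc_enc, site_len)
                ok = np.flatnonzero(
                    (costs <= max_expectation) & (mms <= max_mismatches)
                )
                for start in ok:
                    key = int(start)
                    cand = (float(costs[start]), int(mms[start]), site_len)
                    if key not in best_at_start or cand < best_at_start[key]:
                        best_at_start[key] = cand
            for start, (exp, _mm, site_len) in sorted(best_at_start.items()):
                site = lnc[start : start + site_len]
                results.append(
                    duplex_score(m, site, mirna_id, lncrna_id, offset=start)
                )
    results.sort(key=lambda d: (d.mirna_id, d.lncrna_id, d.offset))
    return results
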
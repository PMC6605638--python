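"""Numba dynamic-programming kernels.

Three exact DP cores back the whole package:

* ``sw_protein`` — Smith–Waterman local alignment of two encoded proteins
  with affine gaps (first gapped residue costs ``gap_open``, each further
  one ``gap_extend``).
* ``profile_scan`` — the same local DP with a position-specific score
  matrix (log-odds bits) on the query axis.
* ``spliced_dp`` — protein-to-genomic-DNA local alignment in codon space
  with GT..AG intron jumps between codons, 1-nt frameshift slips inside
  codons, and traversable in-frame stop codons.

Tracebacks are reconstructed in Python from the pointer matrices; the
alignments themselves are short, so only the fill is performance-critical.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**8))
FNEG = np.float32(-1e8)


@njit(cache=True)
def sw_protein(q, s, sub, gap_open, gap_extend):
    """Affine-gap local alignment fill. Returns (best, bi, bj, pH, pE, pF).

    pH codes: 0 stop, 1 diagonal, 2 from E (gap in subject), 3 from F
    (gap in query). pE/pF: 1 = the gap was opened from H at that cell.
    """
    m = q.shape[0]
    n = s.shape[0]
    E = np.full(n + 1, NEG, np.int32)
    Hrow = np.zeros(n + 1, np.int32)
    Hprev = np.zeros(n + 1, np.int32)
    pH = np.zeros((m + 1, n + 1), np.uint8)
    pE = np.zeros((m + 1, n + 1), np.uint8)
    pF = np.zeros((m + 1, n + 1), np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        F = NEG
        Hrow, Hprev = Hprev, Hrow
        Hrow[0] = 0
        for j in range(1, n + 1):
            eo = Hprev[j] + gap_open
            ee = E[j] + gap_extend
            if eo >= ee:
                E[j] = eo
                pE[i, j] = 1
            else:
                E[j] = ee
            fo = Hrow[j - 1] + gap_open
            fe = F + gap_extend
            if fo >= fe:
                F = fo
                pF[i, j] = 1
            else:
                F = fe
            d = Hprev[j - 1] + sub[qi, s[j - 1]]
            h = np.int32(0)
            p = 0
            if d > h:
                h = d
                p = 1
            if E[j] > h:
                h = E[j]
                p = 2
            if F > h:
                h = F
                p = 3
            Hrow[j] = h
            pH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, pH, pE, pF


def sw_traceback(pH, pE, pF, bi, bj):
    """Walk the pointer matrices from (bi, bj) back to the local start.

    Returns (qs, qe, ss, se, matches, columns) with 1-based inclusive
    endpoints on query and subject, plus the aligned index pairs.
    """
    i, j = bi, bj
    state = "H"
    pairs = []  # (qi or None, sj or None), 1-based
    while True:
        if state == "H":
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                pairs.append((i, j))
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            opened = pE[i, j] == 1
            pairs.append((i, None))
            i -= 1
            if opened:
                state = "H"
        else:
            opened = pF[i, j] == 1
            pairs.append((None, j))
            j -= 1
            if opened:
                state = "H"
    pairs.reverse()
    qs = i + 1
    ss = j + 1
    return qs, bi, ss, bj, pairs


@njit(cache=True)
def profile_scan_kernel(prof, s, gap_open, gap_extend):
    """Local DP of a position-specific bit-score profile vs a protein."""
    m = prof.shape[0]
    n = s.shape[0]
    E = np.full(n + 1, FNEG, np.float32)
    Hrow = np.zeros(n + 1, np.float32)
    Hprev = np.zeros(n + 1, np.float32)
    pH = np.zeros((m + 1, n + 1), np.uint8)
    pE = np.zeros((m + 1, n + 1), np.uint8)
    pF = np.zeros((m + 1, n + 1), np.uint8)
    best = np.float32(0.0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        F = FNEG
        Hrow, Hprev = Hprev, Hrow
        Hrow[0] = 0.0
        for j in range(1, n + 1):
            eo = Hprev[j] + gap_open
            ee = E[j] + gap_extend
            if eo >= ee:
                E[j] = eo
                pE[i, j] = 1
            else:
                E[j] = ee
            fo = Hrow[j - 1] + gap_open
            fe = F + gap_extend
            if fo >= fe:
                F = fo
                pF[i, j] = 1
            else:
                F = fe
            d = Hprev[j - 1] + prof[i - 1, s[j - 1]]
            h = np.float32(0.0)
            p = 0
            if d > h:
                h = d
                p = 1
            if E[j] > h:
                h = E[j]
                p = 2
            if F > h:
                h = F
                p = 3
            Hrow[j] = h
            pH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, pH, pE, pF


@njit(cache=True)
def spliced_dp(dna, tpl, sub, codon_aa, gap_open, gap_extend, fs_pen,
               stop_pen, intron_open, ilen_pen, min_intron, allow_intron,
               allow_fs, stop_aa):
    """Fill for spliced protein-to-DNA local alignment.

    States per (template residue i, last consumed nt j):
      H  — alignment ends with a consumed codon/slip or a gap state;
      Ep — run of unmatched template residues (no DNA consumed);
      Eq — run of inserted genomic codons (no template consumed).
    Intron bookkeeping: a donor GT opening at genomic position p becomes
    eligible for an acceptor AG ending at column j once j - p + 1 >=
    min_intron; ``aval[i, j]`` holds the best resume score at such an
    acceptor and ``adonor`` the donor position that achieved it. Intron
    cost is ``intron_open`` plus ``ilen_pen`` per started 100 nt of
    length (a coarse geometric length model that keeps long-range jumps
    between distinct homologous loci unprofitable); the linear form folds
    into the running donor maximum.

    Pointer codes in pH: 0 stop, 1 codon (3 nt), 2 slip (2 nt), 3 slip
    (4 nt), 4 from Ep, 5 from Eq. ``res`` holds the intron donor when the
    codon transition resumed from aval, else 0.
    """
    m = tpl.shape[0]
    n = dna.shape[0]
    H = np.full((m + 1, n + 1), np.int32(0), np.int32)
    Ep = np.full((m + 1, n + 1), NEG, np.int32)
    Eq = np.full((m + 1, n + 1), NEG, np.int32)
    aval = np.full((m + 1, n + 1), NEG, np.int32)
    adonor = np.zeros((m + 1, n + 1), np.int32)
    pH = np.zeros((m + 1, n + 1), np.uint8)
    pEp = np.zeros((m + 1, n + 1), np.uint8)
    pEq = np.zeros((m + 1, n + 1), np.uint8)
    res = np.zeros((m + 1, n + 1), np.int32)
    donorbest = np.full(m + 1, NEG, np.int32)
    donorpos = np.zeros(m + 1, np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for j in range(1, n + 1):
        if allow_intron:
            # donor p0 becomes eligible: intron [p0..j] has length min_intron
            p0 = j - min_intron + 1
            if p0 >= 1 and p0 + 1 <= n and dna[p0 - 1] == 2 and dna[p0] == 3:
                for i in range(m + 1):
                    v = H[i, p0 - 1] - ilen_pen * (p0 // 100)
                    if v > donorbest[i]:
                        donorbest[i] = v
                        donorpos[i] = p0
            # acceptor AG ending exactly at j
            if j >= 2 and dna[j - 2] == 0 and dna[j - 1] == 2:
                for i in range(m + 1):
                    if donorbest[i] > NEG // 2:
                        aval[i, j] = (donorbest[i] + intron_open
                                      + ilen_pen * (j // 100))
                        adonor[i, j] = donorpos[i]
        for i in range(1, m + 1):
            ti = tpl[i - 1]
            # Ep: skip a template residue, consume nothing
            eo = H[i - 1, j] + gap_open
            ee = Ep[i - 1, j] + gap_extend
            if eo >= ee:
                Ep[i, j] = eo
                pEp[i, j] = 1
            else:
                Ep[i, j] = ee
            # Eq: insert a genomic codon, consume 3 nt
            if j >= 3:
                qo = H[i, j - 3] + gap_open
                qe = Eq[i, j - 3] + gap_extend
                if qo >= qe:
                    Eq[i, j] = qo
                    pEq[i, j] = 1
                else:
                    Eq[i, j] = qe
            h = np.int32(0)
            p = 0
            rdon = 0
            # codon match: consume dna[j-3..j-1] (0-based), i.e. 3 nt
            if j >= 3:
                c0 = dna[j - 3]
                c1 = dna[j - 2]
                c2 = dna[j - 1]
                if c0 < 4 and c1 < 4 and c2 < 4:
                    aa = codon_aa[25 * c0 + 5 * c1 + c2]
                else:
                    aa = codon_aa[124]  # X
                if aa == stop_aa:
                    sc = stop_pen
                else:
                    sc = sub[ti, aa]
                pred = H[i - 1, j - 3]
                pdon = 0
                if aval[i - 1, j - 3] > pred:
                    pred = aval[i - 1, j - 3]
                    pdon = adonor[i - 1, j - 3]
                d = pred + sc
                if d > h:
                    h = d
                    p = 1
                    rdon = pdon
            if allow_fs:
                if j >= 2:
                    pred = H[i - 1, j - 2]
                    pdon = 0
                    if aval[i - 1, j - 2] > pred:
                        pred = aval[i - 1, j - 2]
                        pdon = adonor[i - 1, j - 2]
                    d = pred + fs_pen
                    if d > h:
                        h = d
                        p = 2
                        rdon = pdon
                if j >= 4:
                    pred = H[i - 1, j - 4]
                    pdon = 0
                    if aval[i - 1, j - 4] > pred:
                        pred = aval[i - 1, j - 4]
                        pdon = adonor[i - 1, j - 4]
                    d = pred + fs_pen
                    if d > h:
                        h = d
                        p = 3
                        rdon = pdon
            if Ep[i, j] > h:
                h = Ep[i, j]
                p = 4
                rdon = 0
            if Eq[i, j] > h:
                h = Eq[i, j]
                p = 5
                rdon = 0
            H[i, j] = h
            pH[i, j] = p
            res[i, j] = rdon
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, pH, pEp, pEq, res, aval, adonor
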
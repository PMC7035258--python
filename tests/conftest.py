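"""Shared fixtures: quick row constructors and independent oracles.

The oracles deliberately re-derive each quantity from first principles
(exhaustive enumeration, closed forms) without touching the implementation
paths they check.
"""

from __future__ import annotations

import itertools

import pytest

from polyretain.io import SimilarityRow


@pytest.fixture(scope="session")
def sim_row():
    """Compact SimilarityRow constructor with sensible defaults."""

    def make(q, s, identity=80.0, evalue=1e-20, bitscore=100.0, aln_len=450):
        return SimilarityRow(
            query_id=q,
            subject_id=s,
            pct_identity=identity,
            aln_len=aln_len,
            mismatches=0,
            gapopens=0,
            qstart=1,
            qend=aln_len,
            sstart=1,
            send=aln_len,
            evalue=evalue,
            bitscore=bitscore,
        )

    return make


# --- chaining oracle ---------------------------------------------------------


def _valid_chain_key(subset, max_gap):
    """Chain-order key of an anchor subset, or None if it is not a valid chain."""
    seq = sorted((a.rank_a, a.rank_b) for a in subset)
    for (a1, _), (a2, _) in zip(seq, seq[1:]):
        if a2 <= a1:
            return None
    bs = [b for _, b in seq]
    if len(seq) > 1:
        inc = all(b2 > b1 for b1, b2 in zip(bs, bs[1:]))
        dec = all(b2 < b1 for b1, b2 in zip(bs, bs[1:]))
        if not (inc or dec):
            return None
    gap = 0
    for (a1, b1), (a2, b2) in zip(seq, seq[1:]):
        da, db = a2 - a1, abs(b2 - b1)
        if db == 0 or da > max_gap + 1 or db > max_gap + 1:
            return None
        gap += (da - 1) + (db - 1)
    return (-len(seq), gap, tuple(seq))


def brute_force_blocks(anchors, max_gap, min_anchors):
    """Greedy best-chain extraction by exhaustive subset enumeration."""
    remaining = list(anchors)
    blocks = []
    while remaining:
        n = len(remaining)
        best = None
        for mask in range(1, 1 << n):
            subset = [remaining[i] for i in range(n) if (mask >> i) & 1]
            key = _valid_chain_key(subset, max_gap)
            if key is not None and (best is None or key < best[0]):
                best = (key, subset)
        if best is None or len(best[1]) < min_anchors:
            break
        blocks.append(sorted(best[1], key=lambda a: a.rank_a))
        used = set(best[1])
        remaining = [a for a in remaining if a not in used]
    return blocks


@pytest.fixture(scope="session")
def chain_oracle():
    return brute_force_blocks


# --- NG86 oracle -------------------------------------------------------------


def _oracle_translate(codon):
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate())
    return None if aa == "*" else aa


def oracle_codon_sites(codon):
    aa = _oracle_translate(codon)
    s = 0.0
    for pos, nt in enumerate(codon):
        for alt in "ACGT":
            if alt == nt:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            maa = _oracle_translate(mutant)
            if maa is not None and maa == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


def oracle_differences(ca, cb):
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    all_paths = []
    for order in itertools.permutations(positions):
        cur, steps, blocked = ca, [], False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _oracle_translate(nxt) is None and nxt != cb:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        all_paths.append((blocked, steps))
    open_paths = [s for blocked, s in all_paths if not blocked] or [
        s for _, s in all_paths
    ]
    sd = nd = 0.0
    for steps in open_paths:
        for c1, c2 in steps:
            a1, a2 = _oracle_translate(c1), _oracle_translate(c2)
            if a1 is not None and a1 == a2:
                sd += 1
            else:
                nd += 1
    return sd / len(open_paths), nd / len(open_paths)


def oracle_kaks(seq_a, seq_b):
    import math

    codons = [(seq_a[i : i + 3], seq_b[i : i + 3]) for i in range(0, len(seq_a), 3)]
    sa = na = sb = nb = sd = nd = 0.0
    for ca, cb in codons:
        s1, n1 = oracle_codon_sites(ca)
        s2, n2 = oracle_codon_sites(cb)
        sa, na, sb, nb = sa + s1, na + n1, sb + s2, nb + n2
        ds, dn = oracle_differences(ca, cb)
        sd, nd = sd + ds, nd + dn
    s_sites, n_sites = (sa + sb) / 2, (na + nb) / 2
    ps, pn = sd / s_sites, nd / n_sites
    ks = -0.75 * math.log(1 - 4 * ps / 3)
    ka = -0.75 * math.log(1 - 4 * pn / 3)
    return {
        "s_sites": s_sites,
        "n_sites": n_sites,
        "sd": sd,
        "nd": nd,
        "ps": ps,
        "pn": pn,
        "ks": ks,
        "ka": ka,
    }


@pytest.fixture(scope="session")
def ng86_oracle():
    return oracle_kaks


# --- robustness oracle -------------------------------------------------------


def exact_mean_r_two_removed(g):
    """Exact E[R] for Nr = 2 by enumerating every unordered node pair."""
    import itertools as it

    import networkx as nx

    nodes = sorted(g.nodes)
    n = len(nodes)
    values = []
    for u, v in it.combinations(nodes, 2):
        sub = g.subgraph(set(nodes) - {u, v})
        c = max((len(cc) for cc in nx.connected_components(sub)), default=0)
        values.append(c / (n - 2))
    return values


@pytest.fixture(scope="session")
def robustness_oracle():
    return exact_mean_r_two_removed
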
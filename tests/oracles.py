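"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reference to the package
implementation: plain loops, exhaustive enumeration, and small
finite-model semantics.  The tests compare package output against these.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Finite-interpretation semantics for the EL normalization soundness check
# ---------------------------------------------------------------------------
# Subsets of a domain {0..d-1} are bitmasks; a relation is a tuple of d
# successor bitmasks.  exists(R, E) = {x : succ(x) ∩ E ≠ ∅}.

def _exists(succ: tuple[int, ...], e_mask: int) -> int:
    out = 0
    for x, s in enumerate(succ):
        if s & e_mask:
            out |= 1 << x
    return out


def _all_relations(d: int):
    return itertools.product(range(1 << d), repeat=d)


def equivalence_rewrite_agrees(max_domain: int = 3) -> bool:
    """Check both entailment directions of the definition rewrite.

    The rewrite of C ≡ D ⊓ ∃R.E is NF1 ``C ⊑ D``, NF3 ``C ⊑ ∃R.E``,
    NF4 ``∃R.E ⊑ X`` and NF2 ``D ⊓ X ⊑ C`` with fresh X.  Over every
    interpretation on domains of size 1..max_domain:

    * (models of the equivalence, with X read as ∃R.E) satisfy every
      normalized axiom, and
    * models of the normalized axioms (any X) satisfy the equivalence.

    Returns True when no disagreement exists.
    """
    for d in range(1, max_domain + 1):
        n_sets = 1 << d
        subsets = np.arange(n_sets, dtype=np.int64)
        for succ in _all_relations(d):
            x0 = np.array([_exists(succ, e) for e in range(n_sets)],
                          dtype=np.int64)  # ∃R.E per E
            # direction 1: equivalence models -> normalized satisfied
            for e in range(n_sets):
                for dd in range(n_sets):
                    c = dd & int(x0[e])
                    xx = int(x0[e])
                    if c & ~dd or c & ~xx or xx & ~xx or (dd & xx) & ~c:
                        return False
            # direction 2: normalized models -> equivalence holds
            E = subsets[:, None, None, None]
            D = subsets[None, :, None, None]
            X = subsets[None, None, :, None]
            C = subsets[None, None, None, :]
            X0E = x0[:, None, None, None]
            valid = ((C & ~D) == 0) & ((C & ~X0E) == 0) \
                & ((X0E & ~X) == 0) & (((D & X) & ~C) == 0)
            equiv = C == (D & X0E)
            if np.any(valid & ~equiv):
                return False
    return True


def check_normalized_equivalence(nf1, nf2, nf3, nf4, equivalence,
                                 max_domain: int = 3) -> bool:
    """Same check but driven by an actual normalized axiom set.

    ``equivalence`` is the raw tuple (C, D, R, E); the nf lists are the
    package's rewrite restricted to ids touching the equivalence.  The
    structural shape is verified (exactly the four expected entries, one
    fresh class) and then the semantic agreement above applies.
    """
    c, d, r, e = equivalence
    nf1_hit = [(a, b) for a, b in nf1 if a == c and b == d]
    nf3_hit = [(a, rr, b) for a, rr, b in nf3 if a == c and rr == r and b == e]
    nf4_hit = [(rr, a, x) for rr, a, x in nf4 if rr == r and a == e]
    if not (nf1_hit and nf3_hit and nf4_hit):
        return False
    fresh = {x for _, _, x in nf4_hit}
    nf2_hit = [(a, x, b) for a, x, b in nf2
               if a == d and b == c and x in fresh]
    if not nf2_hit:
        return False
    return equivalence_rewrite_agrees(max_domain)


# ---------------------------------------------------------------------------
# Hierarchy oracles
# ---------------------------------------------------------------------------

def ancestors_by_path_enumeration(edges: list[tuple[str, str]],
                                  node: str) -> set[str]:
    """All nodes reachable by repeatedly following child->parent edges."""
    out = {node}
    frontier = [node]
    while frontier:
        cur = frontier.pop()
        for child, parent in edges:
            if child == cur and parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def union_find_components(nodes, edges):
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set] = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted(frozenset(g) for g in groups.values())


# ---------------------------------------------------------------------------
# Geometric loss oracles: one pair/triple at a time, plain scalar math
# ---------------------------------------------------------------------------

def nf1_term(fc, fd, rc, rd, gamma):
    dist = math.sqrt(sum((a - b) ** 2 for a, b in zip(fc, fd)))
    return max(0.0, dist + rc - rd - gamma)


def nf2_term(fc, fd, fe, rc, rd, re, gamma):
    def dist(u, v):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(u, v)))
    return (max(0.0, dist(fc, fd) - rc - rd - gamma)
            + max(0.0, dist(fc, fe) - rc - gamma)
            + max(0.0, dist(fd, fe) - rc - gamma)
            + max(0.0, min(rc, rd) - re - gamma))


def nf3_term(fc, fr, fd, rc, rd, gamma):
    dist = math.sqrt(sum((a - b - c) ** 2 for a, b, c in zip(fc, fr, fd)))
    return max(0.0, dist - rc - rd - gamma)


def nf4_term(fc, fr, fd, rc, rd, gamma):
    dist = math.sqrt(sum((a + b - c) ** 2 for a, b, c in zip(fc, fr, fd)))
    return max(0.0, dist + rc - rd - gamma)


def score_term(fp, hf, fc, rc):
    z = sum(p * (h + c) for p, h, c in zip(fp, hf, fc)) + rc
    return 1.0 / (1.0 + math.exp(-z))


# ---------------------------------------------------------------------------
# Metric oracles: exhaustive loops over proteins, classes and thresholds
# ---------------------------------------------------------------------------

def fmax_brute(scores, labels, thresholds):
    best = (0.0, float(thresholds[0]))
    n, k = scores.shape
    for t in thresholds:
        precs, recs = [], []
        for i in range(n):
            pred = {j for j in range(k) if scores[i, j] >= t}
            true = {j for j in range(k) if labels[i, j]}
            if not true:
                continue
            tp = len(pred & true)
            if pred:
                precs.append(tp / len(pred))
            recs.append(tp / len(true))
        if not precs or not recs:
            continue
        p, r = sum(precs) / len(precs), sum(recs) / len(recs)
        if p + r > 0:
            f = 2 * p * r / (p + r)
            if f > best[0]:
                best = (f, float(t))
    return best


def smin_brute(scores, labels, ic_vec, thresholds):
    n, k = scores.shape
    best = math.inf
    for t in thresholds:
        ru = mi = 0.0
        for i in range(n):
            for j in range(k):
                pred = scores[i, j] >= t
                if labels[i, j] and not pred:
                    ru += ic_vec[j]
                if pred and not labels[i, j]:
                    mi += ic_vec[j]
        best = min(best, math.sqrt((ru / n) ** 2 + (mi / n) ** 2))
    return best


def aupr_brute(scores, labels):
    """Step-wise AP: sum of precision * recall-increment over thresholds."""
    s = scores.ravel()
    y = labels.ravel().astype(bool)
    npos = int(y.sum())
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(s), reverse=True):
        pred = s >= t
        tp = int((pred & y).sum())
        prec = tp / int(pred.sum())
        rec = tp / npos
        ap += (rec - prev_recall) * prec
        prev_recall = rec
    return ap


def auc_brute(scores, labels):
    """Pairwise comparison with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                wins += 1
            elif p == q:
                wins += 0.5
    return wins / total


def diamond_brute(hits, train_annotations, query, class_id, evalue_max=0.001):
    """hits: list of (query, subject, bitscore, evalue)."""
    num = den = 0.0
    for q, s, bs, ev in hits:
        if q != query or s == query or ev > evalue_max:
            continue
        den += bs
        if class_id in train_annotations.get(s, ()):
            num += bs
    return (num / den if den else 0.0), den > 0


def conditional_ic_brute(annotations, parents, base=2.0):
    """Counting-script IC: -log(P(c | all direct parents))."""
    n = len(annotations)
    out = {}
    for c, par in parents.items():
        cnt_c = sum(1 for terms in annotations.values() if c in terms)
        if par:
            cnt_p = sum(1 for terms in annotations.values()
                        if all(p in terms for p in par))
        else:
            cnt_p = n
        if cnt_c > 0 and cnt_p > 0:
            out[c] = max(0.0, -math.log(cnt_c / cnt_p) / math.log(base))
        else:
            out[c] = max(0.0, -math.log(1.0 / (cnt_p + 1.0)) / math.log(base))
    return out
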
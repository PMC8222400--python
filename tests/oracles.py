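"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a statistic from first principles (explicit
loops, all-pairs BFS, closed forms) without calling the package's own
code paths, so agreement is evidence of correctness rather than
self-consistency.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def brute_force_weighted_distance(
    graph: nx.Graph, disease_set: set[str], targets: set[str]
) -> tuple[float, int, int]:
    """Direct evaluation of the closest weighted distance.

    All-pairs BFS distances, then for each target the explicit minimum
    over disease genes of d(g, t) plus the target's weight
    -ln(degree + 1) when the target is a disease gene.  Unmapped or
    unreachable targets are dropped.
    """
    dist = dict(nx.all_pairs_shortest_path_length(graph))
    values = []
    dropped = 0
    for t in targets:
        if t not in graph:
            dropped += 1
            continue
        best = math.inf
        for g in disease_set:
            if g in graph and t in dist[g]:
                best = min(best, dist[g][t])
        if best is math.inf or best == math.inf:
            dropped += 1
            continue
        w = -math.log(graph.degree(t) + 1) if t in disease_set else 0.0
        values.append(best + w)
    if not values:
        raise ValueError("no contributing target")
    return sum(values) / len(values), len(values), dropped


def brute_force_es(
    ranked_genes: list[str],
    stats: np.ndarray,
    gene_set: set[str],
    weight_exponent: float = 1.0,
) -> float:
    """Sequential running-sum walk, pure Python accumulation."""
    n = len(ranked_genes)
    hits = [g in gene_set for g in ranked_genes]
    n_hit = sum(hits)
    if n_hit == 0:
        raise ValueError("no overlap")
    w = np.abs(stats) ** weight_exponent
    norm = float(np.sum(w[np.asarray(hits)]))
    running = 0.0
    best_pos, best_neg = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            running += (w[i] / norm) if norm > 0 else 1.0 / n_hit
        elif n > n_hit:
            running -= 1.0 / (n - n_hit)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    return best_pos if best_pos >= -best_neg else best_neg


def bh_step_up(p_values: list[float]) -> list[float]:
    """Closed-form Benjamini-Hochberg step-up, returned in input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        q = p_values[i] * m / rank_from_top
        running_min = min(running_min, q)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def welch_t(case: np.ndarray, ctrl: np.ndarray) -> tuple[float, float]:
    """Textbook Welch t statistic, Welch-Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist

    n1, n2 = len(case), len(ctrl)
    v1 = np.var(case, ddof=1)
    v2 = np.var(ctrl, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t_stat = (np.mean(case) - np.mean(ctrl)) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * tdist.sf(abs(t_stat), df)
    return t_stat, p


def rank_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Probability a positive outranks (scores lower than) a negative.

    Computed by exhaustive pairwise comparison; ties count one half.
    """
    wins = 0.0
    for a in scores_pos:
        for b in scores_neg:
            if a < b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))
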
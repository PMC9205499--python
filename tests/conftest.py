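"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import poisson

from netdnv import GeneNetwork, GeneTable, MrfParams


@pytest.fixture
def star_net():
    """Star network: center C with leaves L1..L4 (w_C = 2, w_leaf = 1)."""
    edges = [("C", f"L{i}") for i in range(1, 5)]
    return GeneNetwork.from_edges(["C", "L1", "L2", "L3", "L4"], edges)


@pytest.fixture
def path3_net():
    """Path A - B - C."""
    return GeneNetwork.from_edges(["A", "B", "C"], [("A", "B"), ("B", "C")])


def random_network(rng, n_min=2, n_max=12, p_edge=0.4):
    """Small Erdos-Renyi network on named genes."""
    n = int(rng.integers(n_min, n_max + 1))
    names = [f"g{i:02d}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p_edge
    ]
    return GeneNetwork.from_edges(names, edges)


def joint_log_weight(S, net, params, table=None, gamma=None):
    """Independent term-by-term evaluation of the unnormalized log joint.

    Prior energy summed edge by edge with explicit indicator products, plus
    (optionally) the Poisson log likelihood of the counts.
    """
    S = np.asarray(S)
    total = params.h * sum(1 for s in S if s == 1)
    index = net.node_index
    seen = set()
    for a in net.nodes:
        for b in net.neighbors(a):
            key = (a, b) if a < b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            i, j = index[key[0]], index[key[1]]
            wsum = net.weights[i] + net.weights[j]
            if S[i] == -1 and S[j] == -1:
                total += params.tau0 * wsum
            if S[i] == 1 and S[j] == 1:
                total += params.tau1 * wsum
    if table is not None:
        rate = 2.0 * table.n_trios * table.mutability * np.where(S == 1, gamma, 1.0)
        total += poisson.logpmf(table.counts, rate).sum()
    return total


def enumerate_conditional(i, S, net, params):
    """P(S_i = +1 | others) from exhaustive evaluation of the joint prior."""
    S_plus = np.array(S)
    S_plus[i] = 1
    S_minus = np.array(S)
    S_minus[i] = -1
    lw = np.array(
        [joint_log_weight(S_plus, net, params), joint_log_weight(S_minus, net, params)]
    )
    return float(np.exp(lw[0] - logsumexp(lw)))


def enumerate_posterior_marginals(net, params, table, gamma):
    """Exact q_i = P(S_i = -1 | Y) by summing over all 2^n label states."""
    n = net.n_nodes
    states = list(itertools.product([-1, 1], repeat=n))
    logw = np.array(
        [joint_log_weight(np.array(s), net, params, table, gamma) for s in states]
    )
    post = np.exp(logw - logsumexp(logw))
    q = np.zeros(n)
    for s, p in zip(states, post):
        for i in range(n):
            if s[i] == -1:
                q[i] += p
    return q


def make_table(net_or_genes, counts, mu, n_trios):
    genes = net_or_genes.nodes if isinstance(net_or_genes, GeneNetwork) else net_or_genes
    return GeneTable.from_arrays(genes, counts, mu, n_trios)


def random_mrf_params(rng, h_range=(-3.0, 1.0), tau_range=(0.0, 1.0)):
    return MrfParams(
        h=float(rng.uniform(*h_range)),
        tau0=float(rng.uniform(*tau_range)),
        tau1=float(rng.uniform(*tau_range)),
    )
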
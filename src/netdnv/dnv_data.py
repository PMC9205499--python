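"""Per-gene de novo variant counts, mutabilities, and the Poisson emission model.

The count model: in a cohort of N parent-offspring trios, the number of
damaging de novo variants in gene i is Poisson with mean ``2*N*mu_i`` when
the gene is not a risk gene and ``2*N*mu_i*gamma`` when it is, where ``mu_i``
is the per-gene mutability (per haploid genome per generation, for the
damaging class) and ``gamma >= 1`` is the relative risk in risk genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_io import ParseError, _open_text

__all__ = [
    "GeneTable",
    "CountParams",
    "read_gene_table",
    "log_emission",
    "poisson_upper_tail_test",
    "bh_adjust",
]


@dataclass(frozen=True)
class CountParams:
    """Relative risk of de novo variants in risk genes (>= 1)."""

    gamma: float

    def __post_init__(self):
        if not np.isfinite(self.gamma) or self.gamma < 1.0:
            raise ValueError(f"relative risk gamma must be finite and >= 1, got {self.gamma}")


@dataclass(frozen=True)
class GeneTable:
    """Per-gene DNV counts and mutabilities for a trio cohort.

    Genes are stored in lexicographic order; ``counts`` and ``mutability``
    follow that order.  ``n_trios`` is the cohort size N.
    """

    genes: tuple
    counts: np.ndarray
    mutability: np.ndarray
    n_trios: int

    @staticmethod
    def from_arrays(genes, counts, mutability, n_trios) -> "GeneTable":
        genes = list(genes)
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene identifiers in gene table")
        counts = np.asarray(counts, dtype=np.int64)
        mutability = np.asarray(mutability, dtype=float)
        if counts.shape != (len(genes),) or mutability.shape != (len(genes),):
            raise ValueError("genes, counts and mutability must have equal length")
        if np.any(counts < 0):
            raise ValueError("DNV counts must be nonnegative")
        if np.any(~(mutability > 0)):
            raise ValueError("mutabilities must be strictly positive")
        if int(n_trios) < 1:
            raise ValueError("cohort size N must be >= 1")
        order = np.argsort(np.array(genes))
        return GeneTable(
            genes=tuple(genes[i] for i in order),
            counts=counts[order],
            mutability=mutability[order],
            n_trios=int(n_trios),
        )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def null_rates(self) -> np.ndarray:
        """Expected counts 2*N*mu_i under the non-risk state."""
        return 2.0 * self.n_trios * self.mutability

    def restrict(self, genes) -> "GeneTable":
        """Subset the table to ``genes`` (all must be present)."""
        idx = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"{len(missing)} gene(s) absent from the table, e.g. {missing[0]!r}")
        sel = np.array([idx[g] for g in sorted(set(genes))], dtype=np.int64)
        return GeneTable(
            genes=tuple(self.genes[i] for i in sel),
            counts=self.counts[sel],
            mutability=self.mutability[sel],
            n_trios=self.n_trios,
        )


def read_gene_table(path, n_trios: int) -> GeneTable:
    """Read a TSV gene table with header columns gene, count, mutability."""
    genes, counts, mus = [], [], []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = [c.strip().lower() for c in header]
        for name in ("gene", "count", "mutability"):
            if name not in cols:
                raise ParseError(f"missing required column {name!r} in header", 1)
        gi, ci, mi = cols.index("gene"), cols.index("count"), cols.index("mutability")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) <= max(gi, ci, mi):
                raise ParseError(
                    f"expected >= {max(gi, ci, mi) + 1} columns, got {len(parts)}", lineno
                )
            gene = parts[gi].strip()
            try:
                count = int(parts[ci])
            except ValueError:
                raise ParseError(f"non-integer count {parts[ci]!r}", lineno) from None
            try:
                mu = float(parts[mi])
            except ValueError:
                raise ParseError(f"non-numeric mutability {parts[mi]!r}", lineno) from None
            if count < 0:
                raise ParseError(f"negative count {count}", lineno)
            if not mu > 0:
                raise ParseError(f"mutability must be > 0, got {mu}", lineno)
            if gene in set(genes):
                raise ParseError(f"duplicate gene {gene!r}", lineno)
            genes.append(gene)
            counts.append(count)
            mus.append(mu)
    return GeneTable.from_arrays(genes, counts, mus, n_trios)


def write_gene_table(table: GeneTable, path) -> None:
    with open(path, "wt") as fh:
        fh.write("gene\tcount\tmutability\n")
        for g, y, mu in zip(table.genes, table.counts, table.mutability):
            fh.write(f"{g}\t{int(y)}\t{mu:.10g}\n")


def log_emission(y, mu, n_trios, state, gamma):
    """Log Poisson pmf of count(s) y under latent state(s) +/-1.

    Rate is ``2*N*mu`` for state -1 and ``2*N*mu*gamma`` for state +1.
    Vectorized over y/mu/state.
    """
    if gamma < 1.0:
        raise ValueError("gamma must be >= 1")
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    state = np.asarray(state)
    rate = 2.0 * n_trios * mu * np.where(state == 1, gamma, 1.0)
    out = stats.poisson.logpmf(y, rate)
    if out.ndim == 0:
        return float(out)
    return out


def log_emission_pair(table: GeneTable, gamma: float):
    """(log pmf under state -1, log pmf under state +1) for every gene."""
    rate0 = table.null_rates()
    le_minus = stats.poisson.logpmf(table.counts, rate0)
    le_plus = stats.poisson.logpmf(table.counts, rate0 * gamma)
    return le_minus, le_plus


def poisson_upper_tail_test(table: GeneTable) -> np.ndarray:
    """One-sided exact Poisson burden p-values p_i = P(Pois(2*N*mu_i) >= Y_i).

    A count of zero gives p = 1.  This is the single-gene baseline test that
    ignores the network.
    """
    rate = table.null_rates()
    return stats.poisson.sf(table.counts - 1, rate)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def pvalue_init_states(table: GeneTable, p_cut: float = 0.01) -> np.ndarray:
    """Initial labels: +1 where the baseline Poisson p-value < p_cut, else -1."""
    p = poisson_upper_tail_test(table)
    s = np.where(p < p_cut, 1, -1).astype(np.int64)
    if not np.any(s == 1):
        warnings.warn("no gene passes the initialization p-value cutoff", stacklevel=2)
    return s
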
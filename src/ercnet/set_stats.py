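"""Gene-group ERC statistics: permutation nulls, q-values and group scans.

A disease gene grouping (DGG) is tested for elevated mean ERC by comparing
the observed mean over its defined within-group pairs to the means of random
gene sets of the same size drawn from all genes in the ERC matrix. The
permutation p-value is the fraction of null means greater than or equal to
the observed mean; a zero tally is reported censored as "< 1/n_perm" and
imputed at 1/(2 n_perm) when fed into the false-discovery analysis.

Across many groups, q-values and the null proportion eta0 are estimated with
Storey's smoother; Benjamini-Hochberg is available as a conservative
fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._sampling import null_group_means
from .erc_core import ERCMatrix
from .errors import InsufficientDataError

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 100_000
DEFAULT_MIN_GROUP = 3


@dataclass(frozen=True)
class GeneGroup:
    """A named disease gene grouping (DGG)."""

    name: str
    genes: tuple
    mims: tuple | None = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("group name must be nonempty")
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"group {self.name!r} has duplicate gene ids")

    def __len__(self):
        return len(self.genes)


@dataclass(frozen=True)
class PermutationP:
    """Tally-based permutation p-value with the censored-zero convention.

    ``value`` is the plain tally fraction (0.0 possible); ``fdr_value``
    imputes a zero tally at 1/(2 n) so the p can enter FDR estimation;
    ``text`` renders "<1/n" for a zero tally.
    """

    tally: int
    n: int

    @property
    def censored(self) -> bool:
        return self.tally == 0

    @property
    def value(self) -> float:
        return self.tally / self.n

    @property
    def fdr_value(self) -> float:
        return self.tally / self.n if self.tally else 1.0 / (2 * self.n)

    @property
    def text(self) -> str:
        return f"<{1.0 / self.n:g}" if self.censored else f"{self.value:g}"

    def __float__(self) -> float:
        return self.fdr_value

    def __str__(self) -> str:
        return self.text


@dataclass
class GroupTestResult:
    """Permutation-test outcome for one gene group."""

    name: str
    n_genes: int
    n_pairs: int
    mean_erc: float
    positive_fraction: float
    p: PermutationP
    n_perm: int
    q: float | None = None
    eta0: float | None = None


def _present_indices(matrix: ERCMatrix, group: GeneGroup) -> list:
    return matrix.gene_indices(group.genes)


def _group_pair_values(matrix: ERCMatrix, group: GeneGroup) -> np.ndarray:
    idx = _present_indices(matrix, group)
    if len(idx) < 2:
        raise InsufficientDataError(
            f"group {group.name!r}: fewer than 2 member genes in the matrix")
    sub = matrix.values[np.ix_(idx, idx)]
    vals = sub[np.triu_indices(len(idx), 1)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InsufficientDataError(
            f"group {group.name!r}: no defined ERC pairs")
    return vals


def group_mean_erc(matrix: ERCMatrix, group: GeneGroup):
    """Mean ERC over all defined unordered member pairs -> (mean, n_pairs)."""
    vals = _group_pair_values(matrix, group)
    return float(vals.mean()), int(vals.size)


def positive_fraction(matrix: ERCMatrix, group: GeneGroup) -> float:
    """Fraction of defined within-group ERC values that are positive."""
    vals = _group_pair_values(matrix, group)
    return float((vals > 0).mean())


def permutation_test_group(matrix: ERCMatrix, group: GeneGroup,
                           n_perm: int = DEFAULT_N_PERM,
                           seed=None, rng: np.random.Generator | None = None
                           ) -> GroupTestResult:
    """Test a group for elevated mean ERC against size-matched random sets.

    The null universe is every gene in the ERC matrix; each of the ``n_perm``
    null sets matches the count of the group's matrix-present genes and is
    drawn without replacement within the set. Ties count in favour of the
    null (p uses >=).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = _present_indices(matrix, group)
    k = len(idx)
    if matrix.n_genes < k + 1:
        raise InsufficientDataError(
            f"group {group.name!r}: universe of {matrix.n_genes} genes admits "
            f"no size-{k} null set other than the group itself")
    if matrix.n_genes < 2 * k:
        log.warning("group %r: universe (%d genes) is under twice the group "
                    "size; the permutation null is heavily constrained",
                    group.name, matrix.n_genes)
    observed, n_pairs = group_mean_erc(matrix, group)
    pos = positive_fraction(matrix, group)
    null = null_group_means(matrix.values, k, n_perm, rng)
    tally = int(np.count_nonzero(null >= observed))
    return GroupTestResult(name=group.name, n_genes=k, n_pairs=n_pairs,
                           mean_erc=observed, positive_fraction=pos,
                           p=PermutationP(tally, n_perm), n_perm=n_perm)


# ---------------------------------------------------------------------------
# q-values / eta0
# ---------------------------------------------------------------------------

#: Storey tail-estimate grid; eta0 averages the mid-range, where the
#: estimates are both nearly unbiased (signal p-values rarely reach it) and
#: far less variable than the lambda -> 1 extrapolation.
ETA0_LAMBDA_GRID = np.arange(0.0, 0.901, 0.05)
ETA0_AVERAGING_RANGE = (0.3, 0.75)


def estimate_qvalues(pvals, method: str = "storey"):
    """Storey-style q-values and the null proportion eta0.

    eta0 is estimated from the flat tail of the p-value distribution: the
    tail estimates #{p > lambda} / (m (1 - lambda)) are computed on the grid
    lambda = 0.00, 0.05, ..., 0.90, clipped at 1, and averaged over the
    mid-range lambda in [0.3, 0.75]. (Averaging replaces the classical
    smoother-extrapolation to the last grid point, whose sampling noise is
    unusable at the few-hundred-test scale this package targets.) q-values
    are the monotone step-up transform scaled by eta0. ``method="bh"``
    returns Benjamini-Hochberg adjusted p-values with eta0 fixed at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size

    if method == "bh":
        q = multipletests(p, method="fdr_bh")[1]
        return q, 1.0

    if method != "storey":
        raise ValueError(f"unknown method {method!r}")

    lam = ETA0_LAMBDA_GRID
    pi0 = np.minimum(np.array([(p > l).mean() / (1.0 - l) for l in lam]), 1.0)
    lo, hi = ETA0_AVERAGING_RANGE
    mid = (lam >= lo) & (lam <= hi)
    eta0 = float(np.clip(pi0[mid].mean(), 1.0 / m, 1.0))

    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = eta0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, eta0


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

@dataclass
class GroupScan:
    """Result of testing many groups: per-group results plus scan summary."""

    results: list
    skipped: list
    eta0: float
    n_perm: int

    @property
    def table(self) -> pd.DataFrame:
        rows = [{
            "disease": r.name,
            "mean_erc": r.mean_erc,
            "p": r.p.text,
            "p_numeric": r.p.fdr_value,
            "q": r.q,
            "n_genes": r.n_genes,
            "n_pairs": r.n_pairs,
            "positive_fraction": r.positive_fraction,
        } for r in self.results]
        return pd.DataFrame(rows)

    @property
    def summary(self) -> dict:
        means = np.array([r.mean_erc for r in self.results])
        pnum = np.array([r.p.fdr_value for r in self.results])
        return {
            "n_tested": len(self.results),
            "n_skipped": len(self.skipped),
            "n_positive_mean": int((means > 0).sum()),
            "frac_positive_mean": float((means > 0).mean()) if means.size else float("nan"),
            "n_p_below_0.05": int((pnum < 0.05).sum()),
            "n_p_below_0.01": int((pnum < 0.01).sum()),
            "eta0": self.eta0,
            "n_perm": self.n_perm,
        }


def scan_groups(matrix: ERCMatrix, groups, n_perm: int = DEFAULT_N_PERM,
                seed=None, min_size: int = DEFAULT_MIN_GROUP,
                qvalue_method: str = "storey") -> GroupScan:
    """Permutation-test every admissible group and attach scan-wide q-values.

    Groups with fewer than ``min_size`` matrix-present genes are skipped with
    a logged reason. Results are sorted by p-value then name; null draws are
    seeded independently per group from ``seed``, so a rerun with the same
    seed reproduces the table exactly.
    """
    admissible, skipped = [], []
    for g in groups:
        k = len(_present_indices(matrix, g))
        if k < min_size:
            reason = (f"below minimum group size: {k} present genes "
                      f"(minimum {min_size})")
            skipped.append((g.name, reason))
            log.info("skipping %s: %s", g.name, reason)
        else:
            admissible.append(g)
    if not admissible:
        raise InsufficientDataError("no admissible groups to scan")

    streams = np.random.SeedSequence(seed).spawn(len(admissible))
    results = []
    for g, ss in zip(admissible, streams):
        results.append(permutation_test_group(
            matrix, g, n_perm=n_perm, rng=np.random.default_rng(ss)))
    results.sort(key=lambda r: (r.p.fdr_value, r.name))

    q, eta0 = estimate_qvalues([r.p.fdr_value for r in results],
                               method=qvalue_method)
    for r, qi in zip(results, q):
        r.q = float(qi)
        r.eta0 = eta0
    return GroupScan(results=results, skipped=skipped, eta0=eta0,
                     n_perm=n_perm)
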
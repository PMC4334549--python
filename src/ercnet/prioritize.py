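"""Guilt-by-association candidate gene prioritization.

Candidates are scored by their ERC with a training set of genes already
known for the disease: GROUP scoring averages the candidate's defined ERC
values with the training genes (the default, and the strategy applied in the
benchmarks); BEST scoring takes the maximum. Candidates are ranked by
descending score and reported with a percentile — the fraction of candidates
scoring strictly lower, so the top gene among n candidates sits at
(n-1)/n. Candidate lists come either from a chromosomal window around the
target gene or from random genes scattered across the matrix universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .erc_core import ERCMatrix
from .errors import InsufficientDataError, LabelError
from .set_stats import GeneGroup, PermutationP, permutation_test_group

log = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_000_000


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _score_matrix(matrix: ERCMatrix, training, candidates) -> np.ndarray:
    """Candidate x training block of ERC values (NaN rows for absent genes)."""
    training = list(training)
    candidates = list(candidates)
    overlap = set(training) & set(candidates)
    if overlap:
        raise ValueError(f"training and candidate sets overlap: {sorted(overlap)}")
    index = {g: i for i, g in enumerate(matrix.genes)}
    tr_idx = [index[g] for g in training if g in index]
    if not tr_idx:
        raise InsufficientDataError("no training gene present in the ERC matrix")
    block = np.full((len(candidates), len(tr_idx)), np.nan)
    for row, cand in enumerate(candidates):
        ci = index.get(cand)
        if ci is not None:
            block[row] = matrix.values[ci, tr_idx]
    return block


def group_erc_scores(matrix: ERCMatrix, training, candidates) -> pd.Series:
    """GROUP score: mean of a candidate's defined ERC values with the training set.

    Candidates with no defined entry (or absent from the matrix) score NaN.
    """
    block = _score_matrix(matrix, training, candidates)
    finite = np.isfinite(block)
    count = finite.sum(axis=1)
    total = np.where(finite, block, 0.0).sum(axis=1)
    scores = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return pd.Series(scores, index=list(candidates), name="group_erc")


def best_erc_scores(matrix: ERCMatrix, training, candidates) -> pd.Series:
    """BEST score: maximum defined ERC between the candidate and any training gene."""
    block = _score_matrix(matrix, training, candidates)
    finite = np.isfinite(block)
    filled = np.where(finite, block, -np.inf)
    best = filled.max(axis=1)
    scores = np.where(finite.any(axis=1), best, np.nan)
    return pd.Series(scores, index=list(candidates), name="best_erc")


def rank_and_percentile(scores: pd.Series) -> pd.DataFrame:
    """Rank candidates by descending score with mean ranks at ties.

    ``percentile`` is the fraction of candidates scoring strictly lower;
    undefined (NaN) scores rank below every defined score and share
    percentile 0 among themselves.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 candidates to rank")
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).any():
        raise InsufficientDataError("all candidate scores are undefined")
    keys = np.where(np.isfinite(vals), vals, -np.inf)
    ranks = stats.rankdata(-keys, method="average")
    n = len(vals)
    lower = (keys[None, :] < keys[:, None]).sum(axis=1)
    out = pd.DataFrame({
        "gene": scores.index,
        "score": vals,
        "rank": ranks,
        "percentile": lower / n,
    })
    return out.sort_values(["rank", "gene"], kind="stable").reset_index(drop=True)


def empirical_candidate_p(matrix: ERCMatrix, training, candidate: str,
                          n_rand: int = 1000, seed=None,
                          rng: np.random.Generator | None = None) -> PermutationP:
    """Empirical p-value of a candidate's GROUP score.

    Compares the candidate against ``n_rand`` genes drawn uniformly (with
    replacement) from the matrix, excluding the training genes and the
    candidate itself; the p-value is the fraction whose GROUP score is
    greater than or equal to the candidate's, censored as "<1/n_rand" at a
    zero tally.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    score = group_erc_scores(matrix, training, [candidate]).iloc[0]
    if not np.isfinite(score):
        raise InsufficientDataError(
            f"candidate {candidate!r} has no defined GROUP score")
    index = {g: i for i, g in enumerate(matrix.genes)}
    tr_idx = [index[g] for g in training if g in index]
    excluded = set(tr_idx) | ({index[candidate]} if candidate in index else set())
    eligible = np.array([i for i in range(matrix.n_genes) if i not in excluded])
    if eligible.size == 0:
        raise InsufficientDataError("no eligible comparison genes")
    draws = rng.choice(eligible, size=n_rand, replace=True)
    block = matrix.values[draws][:, tr_idx]
    finite = np.isfinite(block)
    count = finite.sum(axis=1)
    total = np.where(finite, block, 0.0).sum(axis=1)
    null = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    tally = int(np.count_nonzero(null >= score))
    return PermutationP(tally, n_rand)


# ---------------------------------------------------------------------------
# chromosomal windows
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a 4+-column BED (0-based, half-open; column 4 = gene id)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "gene"],
                     dtype={"chrom": str, "gene": str})
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: BED interval with start >= end")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"{path}: duplicate gene record {dup!r}")
    return df.set_index("gene")


def window_candidates(annotation: pd.DataFrame, target: str,
                      window_bp: int = DEFAULT_WINDOW_BP) -> list:
    """Genes overlapping a window of total width ``window_bp`` centred on the
    target gene's midpoint (same chromosome, target included)."""
    if target not in annotation.index:
        raise LabelError(f"target gene {target!r} not in the annotation")
    row = annotation.loc[target]
    mid = (float(row["start"]) + float(row["end"])) / 2.0
    left = max(mid - window_bp / 2.0, 0.0)
    right = mid + window_bp / 2.0
    same = annotation[annotation["chrom"] == row["chrom"]]
    hit = same[(same["start"] < right) & (same["end"] > left)]
    return list(hit.sort_values(["start", "end"]).index)


# ---------------------------------------------------------------------------
# leave-one-out benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkRow:
    group: str
    target: str
    n_candidates: int
    rank: float
    percentile: float
    training_p: PermutationP | None


def loo_benchmark(matrix: ERCMatrix, groups, mode: str = "window",
                  annotation: pd.DataFrame | None = None,
                  window_bp: int = DEFAULT_WINDOW_BP,
                  n_scattered: int = 90,
                  n_perm: int = 1000, min_group: int = 3, seed=None,
                  training_pvals: bool = True) -> pd.DataFrame:
    """Leave-one-out prioritization benchmark over gene groups.

    Each matrix-present member of each group is treated in turn as the
    target; the remaining members form the training set. Candidates are the
    target's chromosomal neighbours (``mode="window"``) or the target plus
    ``n_scattered`` random matrix genes (``mode="scattered"``). Rows record
    the GROUP-score rank and percentile of the target and, optionally, the
    training set's own permutation p-value.
    """
    if mode not in {"window", "scattered"}:
        raise ValueError(f"unknown benchmark mode {mode!r}")
    if mode == "window" and annotation is None:
        raise ValueError("window mode needs a gene annotation")
    rng = np.random.default_rng(seed)
    present = set(matrix.genes)
    rows = []
    for group in groups:
        members = [g for g in group.genes if g in present]
        if len(members) < min_group:
            log.info("skipping %s: %d present genes (< %d)",
                     group.name, len(members), min_group)
            continue
        for target in members:
            training = [g for g in members if g != target]
            if mode == "window":
                cands = [c for c in window_candidates(annotation, target, window_bp)
                         if c not in training]
            else:
                pool = [g for g in matrix.genes
                        if g != target and g not in training]
                n_draw = min(n_scattered, len(pool))
                picked = rng.choice(len(pool), size=n_draw, replace=False)
                cands = [target] + [pool[i] for i in picked]
            if len(cands) < 2:
                continue
            scores = group_erc_scores(matrix, training, cands)
            ranked = rank_and_percentile(scores).set_index("gene")
            tp = None
            if training_pvals:
                tp = permutation_test_group(
                    matrix, GeneGroup(name=f"{group.name}-minus-{target}",
                                      genes=tuple(training)),
                    n_perm=n_perm, rng=rng).p
            rows.append(BenchmarkRow(
                group=group.name, target=target, n_candidates=len(cands),
                rank=float(ranked.loc[target, "rank"]),
                percentile=float(ranked.loc[target, "percentile"]),
                training_p=tp))
    df = pd.DataFrame([{
        "group": r.group, "target": r.target, "n_candidates": r.n_candidates,
        "rank": r.rank, "percentile": r.percentile,
        "training_p": r.training_p.fdr_value if r.training_p else np.nan,
        "training_p_text": r.training_p.text if r.training_p else "",
    } for r in rows])
    return df


TRAINING_P_BANDS = ((0.0, 1e-4), (1e-4, 1e-3), (1e-3, 1e-2), (1e-2, 5e-2),
                    (5e-2, 1.0001))


def benchmark_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median target percentile binned by training-set p-value band."""
    rows = [{"band": "all", "n": len(table),
             "median_percentile": float(table["percentile"].median())}]
    if table["training_p"].notna().any():
        for lo, hi in TRAINING_P_BANDS:
            sel = table[(table["training_p"] >= lo) & (table["training_p"] < hi)]
            if len(sel):
                rows.append({"band": f"[{lo:g}, {hi:g})", "n": len(sel),
                             "median_percentile": float(sel["percentile"].median())})
    return pd.DataFrame(rows)
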
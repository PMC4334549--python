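"""Pairwise evolutionary rate covariation (ERC) values.

The ERC value of a gene pair is the correlation coefficient of their
relative evolutionary rates over the branches both genes have data for
(their shared branches). Pearson correlation on the projection residuals is
the default; Spearman is available as an option. A pair's ERC is undefined
(NaN) when the shared-branch count falls below ``min_shared`` or either
restricted vector is constant — undefined entries propagate as missing, never
as zero, into every downstream statistic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, IntegrityError
from .phylo_rates import RelativeRateMatrix

DEFAULT_MIN_SHARED = 10


def erc_pair(r1: np.ndarray, r2: np.ndarray,
             min_shared: int = DEFAULT_MIN_SHARED,
             method: str = "pearson") -> float:
    """ERC value between two relative-rate rows (NaN = missing branch).

    Returns NaN when fewer than ``min_shared`` branches are shared or either
    restricted vector has zero variance.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("rows are on different branch coordinate systems")
    shared = np.isfinite(r1) & np.isfinite(r2)
    n = int(shared.sum())
    if n < max(min_shared, 2):
        return float("nan")
    x = r1[shared]
    y = r2[shared]
    if method == "spearman":
        res = stats.spearmanr(x, y)
        return float(res.statistic)
    if method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if den == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


@dataclass
class ERCMatrix:
    """Symmetric gene x gene matrix of ERC values.

    ``values`` is exactly symmetric with NaN on the diagonal and wherever a
    pair is undefined; ``counts`` holds the shared-branch count behind each
    entry. ``meta`` records provenance (min_shared, method, source hash).
    """

    genes: tuple
    values: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        g = len(self.genes)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int32)
        if self.values.shape != (g, g) or self.counts.shape != (g, g):
            raise ValueError("ERC matrix must be square over the gene list")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_indices(self, genes) -> list:
        index = {g: i for i, g in enumerate(self.genes)}
        return [index[g] for g in genes if g in index]

    def value(self, g1: str, g2: str) -> float:
        i = self.genes.index(g1)
        j = self.genes.index(g2)
        return float(self.values[i, j])

    def values_hash(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.values).tobytes()).hexdigest()


def erc_matrix(rates: RelativeRateMatrix,
               min_shared: int = DEFAULT_MIN_SHARED,
               method: str = "pearson") -> ERCMatrix:
    """All-pairs ERC over a relative-rate matrix.

    Pearson is computed with masked matrix products (one pass over G x G
    pairs); Spearman falls back to a pairwise loop because ranks must be
    recomputed on each pair's shared-branch subset.
    """
    if rates.n_genes < 2:
        raise ValueError("need at least 2 genes")
    X = rates.values
    M = np.isfinite(X)
    G = rates.n_genes
    n = (M.astype(float) @ M.T.astype(float))

    if method == "pearson":
        Xz = np.where(M, X, 0.0)
        Mf = M.astype(float)
        Sx = Xz @ Mf.T          # sum of x_i over the pair's shared mask
        Sxx = (Xz ** 2) @ Mf.T
        Sxy = Xz @ Xz.T
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = Sxy - Sx * Sx.T / n
            varx = Sxx - Sx ** 2 / n
            corr = cov / np.sqrt(varx * varx.T)
        bad = (n < max(min_shared, 2)) | (varx <= 0) | (varx.T <= 0)
        corr = np.where(bad, np.nan, np.clip(corr, -1.0, 1.0))
    elif method == "spearman":
        corr = np.full((G, G), np.nan)
        for i in range(G):
            for j in range(i + 1, G):
                corr[i, j] = corr[j, i] = erc_pair(
                    X[i], X[j], min_shared=min_shared, method="spearman")
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(corr, np.nan)
    counts = n.astype(np.int32)
    meta = {
        "min_shared": int(min_shared),
        "method": method,
        "source_hash": hashlib.sha256(
            np.ascontiguousarray(rates.values).tobytes()).hexdigest(),
    }
    return ERCMatrix(genes=rates.genes, values=corr, counts=counts, meta=meta)


# ---------------------------------------------------------------------------
# Persistence: TSV (human-readable) and npz (binary container)
# ---------------------------------------------------------------------------

def save_matrix(matrix: ERCMatrix, path) -> Path:
    """Save an ERC matrix; format chosen by suffix (.npz or .tsv).

    The TSV form writes the square value table at ``path`` plus sidecar
    ``<base>.counts.tsv`` and ``<base>.meta.json`` files; npz is one file.
    Both record a checksum of the value array for strict-mode verification.
    """
    path = Path(path)
    meta = dict(matrix.meta)
    meta["values_sha256"] = matrix.values_hash()
    if path.suffix == ".npz":
        np.savez(path, values=matrix.values, counts=matrix.counts,
                 genes=np.array(matrix.genes), meta=json.dumps(meta))
    elif path.suffix == ".tsv":
        genes = list(matrix.genes)
        pd.DataFrame(matrix.values, index=genes, columns=genes).to_csv(
            path, sep="\t", index_label="gene", float_format="%.17g", na_rep="")
        base = path.with_suffix("")
        pd.DataFrame(matrix.counts, index=genes, columns=genes).to_csv(
            base.with_suffix(".counts.tsv"), sep="\t", index_label="gene")
        with open(base.with_suffix(".meta.json"), "w") as fh:
            json.dump(meta, fh, indent=1)
    else:
        raise ValueError(f"unknown matrix format {path.suffix!r} (use .tsv or .npz)")
    return path


def load_matrix(path, strict: bool = False) -> ERCMatrix:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as zf:
            values = zf["values"]
            counts = zf["counts"]
            genes = tuple(str(g) for g in zf["genes"])
            meta = json.loads(str(zf["meta"]))
    elif path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="gene",
                         float_precision="round_trip")
        genes = tuple(df.index)
        values = df.to_numpy(dtype=float)
        base = path.with_suffix("")
        cdf = pd.read_csv(base.with_suffix(".counts.tsv"), sep="\t",
                          index_col="gene")
        counts = cdf.to_numpy(dtype=np.int32)
        meta_path = base.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    else:
        raise FormatError(f"unknown matrix format {path.suffix!r}")
    out = ERCMatrix(genes=genes, values=values, counts=counts, meta=meta)
    expected = meta.get("values_sha256")
    if strict and expected is not None and out.values_hash() != expected:
        raise IntegrityError(f"{path}: value checksum mismatch")
    return out
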
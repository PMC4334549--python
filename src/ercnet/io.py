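"""Small shared readers/writers: GMT group files, gene lists, result tables.

Every result table written by the CLI starts with ``#``-prefixed metadata
lines (package version, seed, input hashes) so a run can be audited and
reproduced; readers skip them.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .errors import FormatError
from .set_stats import GeneGroup


def read_gmt(path) -> list:
    """Read GMT: one group per line — name, description, then gene ids.

    Duplicate genes within a line are collapsed (first occurrence kept).
    """
    groups = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, "
                              "description and at least one gene")
        name = parts[0].strip()
        genes = list(dict.fromkeys(g.strip() for g in parts[2:] if g.strip()))
        if not name or not genes:
            raise FormatError(f"{path}:{lineno}: empty group name or gene list")
        groups.append(GeneGroup(name=name, genes=tuple(genes)))
    if not groups:
        raise FormatError(f"{path}: no groups found")
    return groups


def write_gmt(groups, path):
    with open(path, "w") as fh:
        for g in groups:
            fh.write("\t".join([g.name, "na", *g.genes]) + "\n")


def read_gene_list(path) -> list:
    """One gene id per line; blanks and #-comments ignored; order kept."""
    genes = []
    for line in Path(path).read_text().splitlines():
        token = line.split("#")[0].strip()
        if token:
            genes.append(token)
    if not genes:
        raise FormatError(f"{path}: no gene ids found")
    return list(dict.fromkeys(genes))


def sha256_file(path, prefix: int = 12) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:prefix]


def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                index: bool = False):
    """TSV with ``# key: value`` metadata header lines."""
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
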
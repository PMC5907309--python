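"""Paired gene co-expression networks from expression matrices.

Two expression matrices (genes x samples) — a *primary* and a *secondary*
condition — are turned into one co-expression network on the primary's
gene set.  An edge joins genes u and v iff either

1. their Pearson correlation within the primary dataset exceeds the
   *stringent* cutoff (default 0.95), or
2. their correlation within the secondary dataset exceeds the stringent
   cutoff while that within the primary dataset exceeds the *relaxed*
   cutoff (default 0.75).

Comparisons are strict (">"), applied by default to the signed
correlation (an ``absolute`` flag applies them to |r| instead).  Genes
absent from one matrix, and zero-variance genes (undefined correlation),
are excluded by default; a flag lets primary-only genes participate via
condition (1).

A network *pathway* (start network -> final network) is compiled into an
edit script by randomly ordering the edge differences: one deletion per
edge only in the start network, one insertion per edge only in the final.

The module also ships a synthetic expression generator (a latent-module
model) so the whole workflow is testable without any external dataset.
"""

from __future__ import annotations

import random

import numpy as np
import pandas as pd

from .graph_core import DELETE, INSERT, EditOp, EditScript, Graph, edge_key


def read_expression(path) -> pd.DataFrame:
    """Read a genes-x-samples TSV (header = sample ids, first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def validate_expression(df: pd.DataFrame) -> None:
    if df.shape[1] < 3:
        raise ValueError("expression matrix needs >= 3 samples for Pearson correlation")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r}")


def pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson correlation of the rows (genes).

    Zero-variance genes yield NaN rows/columns; the diagonal is 1 for
    well-defined genes.  Values are clipped to [-1, 1] against rounding.
    """
    validate_expression(expr)
    values = expr.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def build_coexpression(primary: pd.DataFrame, secondary: pd.DataFrame,
                       stringent: float = 0.95, relaxed: float = 0.75,
                       absolute: bool = False,
                       unshared_genes: str = "exclude") -> Graph:
    """Build the two-condition co-expression network (see module docstring).

    Parameters
    ----------
    unshared_genes : {"exclude", "stringent-only"}
        Policy for genes present in the primary matrix but not the
        secondary: drop them entirely (default) or admit edges among them
        via condition (1) only.
    """
    for name, t in (("stringent", stringent), ("relaxed", relaxed)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} cutoff {t} outside [0, 1]")
    if relaxed > stringent:
        raise ValueError(f"relaxed cutoff {relaxed} > stringent cutoff {stringent}")
    if unshared_genes not in ("exclude", "stringent-only"):
        raise ValueError(f"unknown unshared_genes policy {unshared_genes!r}")

    def usable(df: pd.DataFrame) -> pd.Index:
        return df.index[df.std(axis=1, ddof=0) > 0]

    p_genes = usable(primary)
    s_genes = usable(secondary)
    shared = p_genes.intersection(s_genes)
    genes = p_genes if unshared_genes == "stringent-only" else shared
    genes = list(genes)
    if not genes:
        return Graph()

    rp = pearson_matrix(primary.loc[genes]).to_numpy()
    if absolute:
        rp = np.abs(rp)
    in_secondary = np.array([g in set(shared) for g in genes])
    rs = np.full_like(rp, -np.inf)
    if in_secondary.any():
        sec_genes = [g for g, ok in zip(genes, in_secondary) if ok]
        rs_block = pearson_matrix(secondary.loc[sec_genes]).to_numpy()
        if absolute:
            rs_block = np.abs(rs_block)
        ix = np.flatnonzero(in_secondary)
        rs[np.ix_(ix, ix)] = rs_block

    with np.errstate(invalid="ignore"):
        mask = (rp > stringent) | ((rs > stringent) & (rp > relaxed))
    mask &= ~np.isnan(rp)

    net = Graph(nodes=genes)
    for i, j in zip(*np.triu_indices(len(genes), k=1)):
        if mask[i, j]:
            net.add_edge(genes[int(i)], genes[int(j)])
    return net


def diff_to_script(start: Graph, final: Graph, seed: int) -> EditScript:
    """Edit script turning ``start`` into ``final``, edge diffs in random order."""
    e0, e1 = start.edge_set(), final.edge_set()
    ops = [EditOp(DELETE, *e) for e in sorted(e0 - e1, key=str)]
    ops += [EditOp(INSERT, *e) for e in sorted(e1 - e0, key=str)]
    random.Random(seed).shuffle(ops)
    return EditScript(ops)


def synthetic_expression(n_genes: int = 60, n_samples: int = 19,
                         n_modules: int = 6, noise_sd: float = 0.15,
                         seed: int = 0,
                         gene_prefix: str = "g") -> pd.DataFrame:
    """Latent-module synthetic expression matrix.

    Genes are split evenly into modules; each module has one latent
    standard-normal profile across samples, and each gene is that profile
    plus independent Gaussian noise of standard deviation ``noise_sd``.
    Within-module correlations concentrate around 1 / (1 + noise_sd^2), so
    the cutoff structure of the co-expression rule is directly exercisable.
    The default sample count mirrors a typical multi-cell-line
    developmental expression panel.
    """
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_modules, n_samples))
    rows = []
    names = []
    width = len(str(n_genes))
    for i in range(n_genes):
        m = i % n_modules
        rows.append(latent[m] + noise_sd * rng.standard_normal(n_samples))
        names.append(f"{gene_prefix}{i:0{width}d}")
    return pd.DataFrame(rows, index=names,
                        columns=[f"s{j:02d}" for j in range(n_samples)])
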
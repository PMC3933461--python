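"""Module validation against an independent dataset, and gene-set enrichment.

Directional concordance compares the signed statistics of a module's genes
between a discovery and a validation dataset.  The 2x2 sign-agreement
table crosses sign(t_discovery) with sign(t_validation) over all shared
module genes and is tested with a two-sided Fisher exact test; in
addition, the counts of genes that are nominally significant in the
validation set with matching ("same") or opposing ("opposite") sign are
reported, since replication claims are usually phrased in those terms.

Enrichment is the standard upper-tail hypergeometric test of a module
against named gene sets, with Benjamini-Hochberg FDR across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConcordanceResult",
    "directional_concordance",
    "fisher_exact_2x2",
    "hypergeometric_enrichment",
    "read_gmt",
]


@dataclass
class ConcordanceResult:
    table: np.ndarray          # rows: sign(t_d) +/-, cols: sign(t_v) +/-
    n_same: int                # validation-significant, matching sign
    n_opposite: int            # validation-significant, opposing sign
    fisher_p: float
    per_gene: pd.DataFrame     # t_discovery, t_validation, class

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=int)
        if self.table.shape != (2, 2) or (self.table < 0).any():
            raise ValueError("table must be a nonnegative 2x2 count matrix")


def _as_stats_frame(stats_like) -> pd.DataFrame:
    """Accept a DEStats DataFrame (columns t, p) or a Series of t (p assumed 0)."""
    if isinstance(stats_like, pd.DataFrame):
        if "t" not in stats_like.columns:
            raise ValueError("statistics table needs a 't' column")
        out = stats_like[["t"]].copy()
        out["p"] = stats_like["p"] if "p" in stats_like.columns else 0.0
        return out
    s = pd.Series(stats_like)
    return pd.DataFrame({"t": s, "p": 0.0})


def directional_concordance(
    module, stats_d, stats_v, alpha: float = 0.05
) -> ConcordanceResult:
    """Sign agreement of a module's statistics across two datasets.

    Genes are classified as ``same`` / ``opposite`` when their validation
    p-value is below ``alpha`` and their validation sign matches / opposes
    the discovery sign; everything else is ``nonsignificant``.  The Fisher
    test is applied to the sign(t_d) x sign(t_v) table over all shared
    module genes (zero statistics count as positive sign).
    """
    d = _as_stats_frame(stats_d)
    v = _as_stats_frame(stats_v)
    shared = [g for g in module if g in d.index and g in v.index]
    if not shared:
        raise ValueError("module has no genes shared between discovery and validation")

    td = d.loc[shared, "t"].to_numpy(dtype=float)
    tv = v.loc[shared, "t"].to_numpy(dtype=float)
    pv = v.loc[shared, "p"].to_numpy(dtype=float)
    sd = td >= 0
    sv = tv >= 0

    signif = pv < alpha
    same = signif & (sd == sv)
    opposite = signif & (sd != sv)
    cls = np.where(same, "same", np.where(opposite, "opposite", "nonsignificant"))

    table = np.array(
        [
            [int((sd & sv).sum()), int((sd & ~sv).sum())],
            [int((~sd & sv).sum()), int((~sd & ~sv).sum())],
        ]
    )
    per_gene = pd.DataFrame(
        {"t_discovery": td, "t_validation": tv, "p_validation": pv, "class": cls},
        index=pd.Index(shared, name="gene_id"),
    )
    return ConcordanceResult(
        table=table,
        n_same=int(same.sum()),
        n_opposite=int(opposite.sum()),
        fisher_p=fisher_exact_2x2(table),
        per_gene=per_gene,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric point masses <= observed)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (table < 0).any():
        raise ValueError("table entries must be nonnegative")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def hypergeometric_enrichment(module, gene_sets: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``module`` in each gene set.

    ``universe`` is the background gene collection (the module must be a
    subset); each set is intersected with the universe first.  Returns a
    DataFrame (one row per set) with overlap counts, p and BH FDR, sorted
    by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module)
    if not module <= universe:
        raise ValueError("module must be contained in the universe")
    rows = []
    for name, genes in gene_sets.items():
        in_universe = set(genes) & universe
        overlap = module & in_universe
        # P(X >= k) for X ~ Hypergeom(N=|U|, K=|set|, n=|module|)
        p = float(stats.hypergeom.sf(len(overlap) - 1, len(universe),
                                     len(in_universe), len(module)))
        rows.append(
            {
                "gene_set": name,
                "set_size": len(in_universe),
                "overlap": len(overlap),
                "p": min(p, 1.0),
                "overlap_genes": ",".join(sorted(map(str, overlap))),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["p", "gene_set"], kind="stable").reset_index(drop=True)
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
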
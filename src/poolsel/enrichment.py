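"""Gene-level enrichment of diverged variants by SNP resampling.

Gene-set testing on SNP statistics is biased by gene length: long genes
collect more SNPs and hence smaller minimum p-values.  The resampling test
used here corrects for that the way GOWINDA does in its gene mode: each
gene is scored by the smallest per-SNP model p-value within the gene body
plus a flank; the observed statistic is how many genes of the query set
fall in the top tail of that gene-score distribution; and the null is built
by repeatedly drawing random SNP sets of the same size as the observed
tail-defining SNP set, mapping them to genes (a gene counts once no matter
how many of its SNPs are drawn), and counting query-set hits.

Also here: the fly-to-human ortholog-table join (union over sources,
conflict and fan-out pruning) and shared-gene intersection reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ResamplingConfig:
    n_sims: int = 100_000
    flank: int = 500
    tail: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be positive")
        if not 0.0 < self.tail < 1.0:
            raise ValueError("tail must lie in (0, 1)")
        if self.flank < 0:
            raise ValueError("flank must be non-negative")


def assign_snps_to_genes(results: pd.DataFrame, genes: pd.DataFrame,
                         flank: int = 500) -> pd.DataFrame:
    """Interval assignment of SNPs to genes within gene body +/- flank.

    A SNP may land in several overlapping genes and is assigned to all of
    them.  The flank edge is half-open: a SNP exactly ``flank`` bp outside
    the gene body is excluded.  Returns rows (snp_idx, gene).
    """
    pos0 = results["pos"].to_numpy() - 1
    arms = results["arm"].to_numpy()
    rows = []
    for _, g in genes.iterrows():
        lo, hi = g["start"] - flank, g["end"] + flank
        hit = (arms == g["arm"]) & (pos0 >= lo) & (pos0 < hi)
        for idx in np.where(hit)[0]:
            rows.append((int(idx), g["gene"]))
    return pd.DataFrame(rows, columns=["snp_idx", "gene"])


def gene_min_p(results: pd.DataFrame, genes: pd.DataFrame,
               flank: int = 500):
    """Per-gene minimum model p-value over assigned SNPs.

    Returns ``(GeneScores frame with gene/min_p/n_snps, snp-to-gene map with
    each SNP's own p attached)``; genes with no SNP are absent.
    """
    snp_map = assign_snps_to_genes(results, genes, flank)
    if not len(snp_map):
        return (pd.DataFrame(columns=["gene", "min_p", "n_snps"]),
                snp_map.assign(p=[]))
    p = results["p"].to_numpy()
    snp_map = snp_map.assign(p=p[snp_map["snp_idx"].to_numpy()])
    scores = (snp_map.groupby("gene")
              .agg(min_p=("p", "min"), n_snps=("p", "size"))
              .reset_index())
    return scores, snp_map


def geneset_resampling_test(gene_sets: dict[str, set[str]],
                            gene_scores: pd.DataFrame,
                            snp_map: pd.DataFrame,
                            config: ResamplingConfig | None = None,
                            rng: np.random.Generator | None = None
                            ) -> pd.DataFrame:
    """SNP-resampling enrichment of each gene set in the top score tail.

    The tail threshold is the lower ``tail`` quantile of the gene min-p
    distribution; the observed statistic counts query-set genes in that
    tail, and the tail-defining SNP set is every mapped SNP whose own
    p-value is at or below the threshold.  Null draws resample that many
    SNPs uniformly without replacement from all mapped SNPs and count
    query-set genes hit at least once (a gene counts once however many of
    its SNPs are drawn, which removes the gene-length bias).  Empirical
    p-values use the add-one estimator (1 + #{null >= observed}) /
    (1 + n_sims), bounded below by 1/(1 + n_sims); Bonferroni across sets.
    Query genes without any SNP are dropped from scoring.
    """
    if config is None:
        config = ResamplingConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    for name, members in gene_sets.items():
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
    if "p" not in snp_map.columns:
        raise ValueError("snp_map must carry a 'p' column; use the map "
                         "returned by gene_min_p")

    scores = gene_scores.sort_values("min_p", kind="stable")
    k_tail = max(int(np.ceil(config.tail * len(scores))), 1)
    thr = scores["min_p"].to_numpy()[k_tail - 1]
    tail_genes = set(scores["gene"].head(k_tail))
    scored_genes = set(gene_scores["gene"])

    snp_p = snp_map.groupby("snp_idx")["p"].first()
    universe = snp_p.index.to_numpy()
    m = int((snp_p.to_numpy() <= thr).sum())
    gene_lists = (snp_map.groupby("snp_idx")["gene"].apply(list)
                  .reindex(universe).tolist())

    rows = []
    n_sets = len(gene_sets)
    draws = rng.random((config.n_sims, len(universe))).argsort(axis=1)[:, :m] \
        if config.n_sims * len(universe) <= 5_000_000 else None
    for name, members in gene_sets.items():
        members_scored = set(members) & scored_genes
        observed = len(members_scored & tail_genes)
        count_ge = 0
        for i in range(config.n_sims):
            draw = draws[i] if draws is not None else \
                rng.choice(len(universe), size=m, replace=False)
            hit = set()
            for d in draw:
                hit.update(gene_lists[d])
            if len(hit & members_scored) >= observed:
                count_ge += 1
        p_emp = (1.0 + count_ge) / (1.0 + config.n_sims)
        rows.append({
            "set": name, "n_members_scored": len(members_scored),
            "observed_tail_genes": observed, "p_empirical": p_emp,
            "p_bonferroni": min(1.0, p_emp * n_sets),
            "n_dropped_unscored": len(set(members) - scored_genes),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ortholog mapping and shared-gene reports


def ortholog_join(mapping: pd.DataFrame, fly_genes: set[str] | None = None,
                  max_fanout: int = 1) -> pd.DataFrame:
    """Union of per-source ortholog calls with conflict and fan-out pruning.

    ``mapping`` needs columns fly_gene, human_gene, source.  Within each
    source, fly genes mapping to more than ``max_fanout`` human genes are
    dropped from that source's contribution.  After the union, a pair is
    conflicted - and removed - when another source maps the same fly gene
    but never to that human gene (silence about the fly gene is not
    conflict).  ``fly_genes`` optionally restricts the output.
    """
    required = {"fly_gene", "human_gene", "source"}
    if not required <= set(mapping.columns):
        raise ValueError(f"mapping table needs columns {sorted(required)}")
    pruned = []
    for source, sub in mapping.groupby("source"):
        sub = sub.drop_duplicates(["fly_gene", "human_gene"])
        fanout = sub.groupby("fly_gene")["human_gene"].transform("size")
        pruned.append(sub[fanout <= max_fanout])
    union = pd.concat(pruned, ignore_index=True)

    by_source = {
        (src, fly): set(sub["human_gene"])
        for (src, fly), sub in union.groupby(["source", "fly_gene"])
    }
    sources = union["source"].unique()
    keep = []
    for _, row in union.iterrows():
        ok = True
        for other in sources:
            if other == row["source"]:
                continue
            humans = by_source.get((other, row["fly_gene"]))
            if humans is not None and row["human_gene"] not in humans:
                ok = False
                break
        keep.append(ok)
    out = (union[np.array(keep, dtype=bool)]
           .drop_duplicates(["fly_gene", "human_gene"])
           .reset_index(drop=True)[["fly_gene", "human_gene"]])
    if fly_genes is not None:
        out = out[out["fly_gene"].isin(fly_genes)].reset_index(drop=True)
    return out


def shared_gene_report(hits: dict[str, set[str]]) -> pd.DataFrame:
    """Venn-style intersection counts and gene lists across populations."""
    if len(hits) < 2:
        raise ValueError("need hit sets from at least two populations")
    rows = []
    names = sorted(hits)
    for name in names:
        rows.append({"populations": name, "k": 1,
                     "n_genes": len(hits[name]),
                     "genes": ",".join(sorted(hits[name]))})
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            inter = set.intersection(*(hits[n] for n in combo))
            rows.append({"populations": "&".join(combo), "k": k,
                         "n_genes": len(inter),
                         "genes": ",".join(sorted(inter))})
    return pd.DataFrame(rows)
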
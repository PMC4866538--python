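"""Population branch statistic (PBS) and candidate-gene tail enrichment.

For three populations - a focal (e.g. high-altitude, H), a related lowland
control (L) and an outgroup (O) - pairwise FST values are turned into
branch lengths T = -log(1 - FST), and

    PBS = (T_HL + T_HO - T_LO) / 2

is the focal population's branch length since its divergence from the
control: large PBS marks loci whose allele frequency moved specifically on
the focal lineage, the signature of lineage-specific positive selection.
FST uses the Reynolds (1983) two-population ANOVA estimator with the n_c
small-sample correction (sample sizes in chromosomes), negative estimates
clipped to zero.

Enrichment of a candidate-gene SNP set in the top PBS tail is scored by an
exact two-sided binomial test of the candidate tail count against the
genome-wide tail fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def reynolds_fst(p1, p2, n1, n2):
    """Reynolds (1983) per-site FST between two populations.

    ``p1``/``p2`` are alt-allele frequencies and ``n1``/``n2`` sample sizes
    in chromosomes (>= 2 each).  Uses the ANOVA mean-square form

        MSP = n1 (p1 - pbar)^2 + n2 (p2 - pbar)^2
        MSG = [n1 p1 (1-p1) + n2 p2 (1-p2)] / (n1 - 1 + n2 - 1)
        FST = (MSP - MSG) / (MSP + (n_c - 1) MSG),
        n_c = n1 + n2 - (n1^2 + n2^2) / (n1 + n2).

    Returns ``(clipped, raw)``: estimates clipped to [0, 1] and pre-clip
    values.  Sites monomorphic in both populations get FST 0.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 < 2).any() or (n2 < 2).any():
        raise ValueError("need at least 2 chromosomes per population")
    n = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n - 2)
    nc = n - (n1 * n1 + n2 * n2) / n
    denom = msp + (nc - 1.0) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(denom > 0, (msp - msg) / denom, 0.0)
    clipped = np.clip(raw, 0.0, 1.0)
    return clipped, raw


def compute_pbs(fst_hl, fst_ho, fst_lo):
    """PBS from the three pairwise FST values (H focal, L control, O out).

    T = -log(1 - FST), natural log; FST of 1 would give an infinite branch
    and is rejected.  Returns a frame with the branch lengths and pbs.
    """
    hl = np.atleast_1d(np.asarray(fst_hl, dtype=float))
    ho = np.atleast_1d(np.asarray(fst_ho, dtype=float))
    lo = np.atleast_1d(np.asarray(fst_lo, dtype=float))
    for name, v in (("fst_hl", hl), ("fst_ho", ho), ("fst_lo", lo)):
        if ((v < 0) | (v >= 1)).any():
            raise ValueError(f"{name} must lie in [0, 1); an FST of 1 "
                             "implies an infinite branch length")
    t_hl, t_ho, t_lo = (-np.log1p(-v) for v in (hl, ho, lo))
    pbs = (t_hl + t_ho - t_lo) / 2.0
    return pd.DataFrame({"t_hl": t_hl, "t_ho": t_ho, "t_lo": t_lo,
                         "pbs": pbs})


def pbs_from_frequencies(freqs: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP PBS from a three-population allele-frequency table.

    Expects columns freq_h, n_h, freq_l, n_l, freq_o, n_o (frequencies and
    chromosome counts); any additional columns (chrom, pos, gene) pass
    through.
    """
    hl, _ = reynolds_fst(freqs["freq_h"], freqs["freq_l"],
                         freqs["n_h"], freqs["n_l"])
    ho, _ = reynolds_fst(freqs["freq_h"], freqs["freq_o"],
                         freqs["n_h"], freqs["n_o"])
    lo, _ = reynolds_fst(freqs["freq_l"], freqs["freq_o"],
                         freqs["n_l"], freqs["n_o"])
    eps = 1e-12
    clip = lambda v: np.minimum(v, 1.0 - eps)
    out = compute_pbs(clip(hl), clip(ho), clip(lo))
    keep = [c for c in freqs.columns
            if c not in {"freq_h", "n_h", "freq_l", "n_l", "freq_o", "n_o"}]
    return pd.concat([freqs[keep].reset_index(drop=True),
                      pd.DataFrame({"fst_hl": hl, "fst_ho": ho,
                                    "fst_lo": lo}), out], axis=1)


def binom_two_sided(k: int, n: int, p0: float,
                    convention: str = "minlike") -> float:
    """Exact two-sided binomial p-value.

    ``minlike`` sums the probabilities of all outcomes no more likely than
    the observed one (the common exact-test default); ``double`` doubles the
    smaller one-sided tail (capped at 1).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    if convention == "minlike":
        return float(stats.binomtest(k, n, p0).pvalue)
    if convention == "double":
        lo = stats.binom.cdf(k, n, p0)
        hi = stats.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class EnrichmentResult:
    set_id: str
    k: int                   # candidate SNPs in the tail
    n: int                   # candidate SNPs total
    p0: float                # background tail proportion
    p_two_sided: float
    direction: str
    threshold: float


def pbs_tail_enrichment(pbs: np.ndarray, candidate: np.ndarray,
                        tail: float = 0.05, set_id: str = "candidates",
                        convention: str = "minlike",
                        exclude_candidates_from_background: bool = False
                        ) -> EnrichmentResult:
    """Two-sided binomial enrichment of candidate SNPs in the top PBS tail.

    ``candidate`` is a boolean mask over the PBS table.  The tail threshold
    is the (1 - tail) empirical quantile of all PBS values; the background
    proportion p0 is the realized tail fraction (optionally computed with
    candidates excluded).
    """
    pbs = np.asarray(pbs, dtype=float)
    candidate = np.asarray(candidate, dtype=bool)
    if not 0.0 < tail < 1.0:
        raise ValueError("tail must lie in (0, 1)")
    n = int(candidate.sum())
    if n == 0:
        raise ValueError("no candidate SNPs")
    thr = float(np.quantile(pbs, 1.0 - tail))
    in_tail = pbs >= thr
    k = int((in_tail & candidate).sum())
    if exclude_candidates_from_background:
        bg = ~candidate
        p0 = float(in_tail[bg].mean())
    else:
        p0 = float(in_tail.mean())
    p = binom_two_sided(k, n, p0, convention)
    direction = "enriched" if k >= n * p0 else "depleted"
    return EnrichmentResult(set_id=set_id, k=k, n=n, p0=p0, p_two_sided=p,
                            direction=direction, threshold=thr)


def tail_gene_hits(pbs_table: pd.DataFrame, tail: float = 0.05) -> set[str]:
    """Genes with at least one SNP at or above the top-tail PBS threshold."""
    pbs = pbs_table["pbs"].to_numpy(dtype=float)
    thr = np.quantile(pbs, 1.0 - tail)
    hit = pbs_table.loc[(pbs >= thr) & pbs_table["gene"].notna(), "gene"]
    return set(hit)


def windowed_pbs(pbs_table: pd.DataFrame, window: int = 50_000,
                 step: int = 2_000) -> pd.DataFrame:
    """Mean PBS in sliding windows (the windowed variant of the statistic)."""
    rows = []
    for chrom, sub in pbs_table.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy() - 1
        order = np.argsort(pos)
        pos = pos[order]
        vals = sub["pbs"].to_numpy()[order]
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        starts = np.arange(0, pos.max() + 1, step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        keep = hi > lo
        mean = (csum[hi[keep]] - csum[lo[keep]]) / (hi[keep] - lo[keep])
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts[keep],
            "end": starts[keep] + window, "n_snps": hi[keep] - lo[keep],
            "mean_pbs": mean,
        }))
    return pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "mean_pbs"])
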
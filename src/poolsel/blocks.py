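"""Hypergeometric sliding-window scan for clusters of diverged variants.

Because pooled sequencing carries no haplotype information, linked selection
is detected spatially: each chromosome arm is tiled with overlapping
windows, and a window holding n variants of which s are significantly
diverged (SDV) is scored by the upper tail P(X >= s) of a
Hypergeometric(N, S, n) law, with N and S the arm-wide totals.  After
genome-wide multiple-testing adjustment, significant windows that overlap
or abut are consolidated into maximal nonoverlapping blocks - each read as
one selected region plus its hitchhikers - and each block nominates the SDV
with the smallest model p-value and the gene(s) hosting it.

Coordinates are 0-based half-open internally (variant positions arrive
1-based and are shifted); BED output is native, TSV output 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_WINDOW = 50_000
DEFAULT_STEP = 10_000


def scan_windows(variants: pd.DataFrame, window: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP,
                 arm_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Tile each arm and score every non-empty window.

    ``variants`` needs columns arm, pos (1-based) and sdv (bool).  Windows
    with no variants are skipped; per-arm totals feed the hypergeometric
    upper tail.
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    rows = []
    for arm, sub in variants.groupby("arm", sort=False):
        pos = np.sort(sub["pos"].to_numpy() - 1)
        sdv_pos = np.sort(sub.loc[sub["sdv"], "pos"].to_numpy() - 1)
        N, S = len(pos), len(sdv_pos)
        length = (arm_lengths or {}).get(arm, int(pos.max()) + 1)
        starts = np.arange(0, length, step)
        n = (np.searchsorted(pos, starts + window, side="left")
             - np.searchsorted(pos, starts, side="left"))
        s = (np.searchsorted(sdv_pos, starts + window, side="left")
             - np.searchsorted(sdv_pos, starts, side="left"))
        keep = n > 0
        p = stats.hypergeom.sf(s[keep] - 1, N, S, n[keep])
        rows.append(pd.DataFrame({
            "arm": arm, "start": starts[keep],
            "end": np.minimum(starts[keep] + window, length),
            "n": n[keep], "s": s[keep], "p": np.minimum(p, 1.0),
        }))
    if not rows:
        return pd.DataFrame(columns=["arm", "start", "end", "n", "s", "p"])
    return pd.concat(rows, ignore_index=True)


def storey_qvalues(p: np.ndarray,
                   lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with pi0 from a lambda grid (smoother-free median)."""
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    pi0s = [(p > lam).mean() / (1 - lam) for lam in lambdas]
    pi0 = min(1.0, float(np.median(pi0s)))
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.minimum(q, 1.0)


def adjust_windows(windows: pd.DataFrame, alpha: float = 0.05,
                   method: str = "bh") -> pd.DataFrame:
    """Genome-wide multiple-testing adjustment; flags q < alpha."""
    out = windows.copy()
    if len(out) == 0:
        out["q"] = []
        out["significant"] = []
        return out
    if method == "bh":
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    elif method == "storey":
        out["q"] = storey_qvalues(out["p"].to_numpy())
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    out["significant"] = out["q"] < alpha
    return out


@dataclass
class Block:
    arm: str
    start: int
    end: int
    windows: pd.DataFrame

    @property
    def length(self) -> int:
        return self.end - self.start


def consolidate_blocks(windows: pd.DataFrame) -> list[Block]:
    """Merge significant windows that overlap or abut into maximal blocks."""
    sig = windows[windows["significant"]] if "significant" in windows \
        else windows
    blocks: list[Block] = []
    for arm, sub in sig.groupby("arm", sort=False):
        sub = sub.sort_values("start")
        start = end = None
        members = []
        for _, w in sub.iterrows():
            if start is None:
                start, end = int(w["start"]), int(w["end"])
                members = [w]
            elif w["start"] <= end:             # overlap or abut
                end = max(end, int(w["end"]))
                members.append(w)
            else:
                blocks.append(Block(arm, start, end, pd.DataFrame(members)))
                start, end = int(w["start"]), int(w["end"])
                members = [w]
        if start is not None:
            blocks.append(Block(arm, start, end, pd.DataFrame(members)))
    return blocks


def block_summary(blocks: list[Block]) -> dict:
    """Median block length and median edge-to-edge gap between neighbours."""
    if not blocks:
        raise ValueError("no blocks")
    lengths = [b.length for b in blocks]
    gaps = []
    frame = pd.DataFrame([(b.arm, b.start, b.end) for b in blocks],
                         columns=["arm", "start", "end"])
    for _, sub in frame.groupby("arm"):
        sub = sub.sort_values("start")
        gaps.extend((sub["start"].to_numpy()[1:]
                     - sub["end"].to_numpy()[:-1]).tolist())
    return {
        "n_blocks": len(blocks),
        "median_length": float(np.median(lengths)),
        "median_gap": float(np.median(gaps)) if gaps else float("nan"),
    }


def _flanking_genes(genes: pd.DataFrame, arm: str, pos0: int) -> list[str]:
    sub = genes[genes["arm"] == arm]
    host = sub[(sub["start"] <= pos0) & (pos0 < sub["end"])]
    if len(host):
        return sorted(host["gene"].tolist())
    out = []
    up = sub[sub["end"] <= pos0]
    if len(up):
        out.append(up.loc[up["end"].idxmax(), "gene"])
    down = sub[sub["start"] > pos0]
    if len(down):
        out.append(down.loc[down["start"].idxmin(), "gene"])
    return out


def nominate_candidates(blocks: list[Block], results: pd.DataFrame,
                        genes: pd.DataFrame) -> pd.DataFrame:
    """Top variant (smallest model p among SDV; ties all kept) and its genes.

    An intragenic top variant nominates its host gene(s); an intergenic one
    nominates the nearest gene on each flank.
    """
    rows = []
    for b in blocks:
        pos0 = results["pos"].to_numpy() - 1
        inside = ((results["arm"] == b.arm).to_numpy()
                  & (pos0 >= b.start) & (pos0 < b.end)
                  & results["sdv"].to_numpy())
        sub = results[inside]
        if not len(sub):
            raise ValueError(f"block {b.arm}:{b.start}-{b.end} contains no "
                             "SDV; blocks must be built from SDV windows")
        best = sub[sub["p"] == sub["p"].min()]
        for _, v in best.iterrows():
            hosts = _flanking_genes(genes, b.arm, int(v["pos"]) - 1)
            rows.append({
                "arm": b.arm, "block_start": b.start, "block_end": b.end,
                "top_pos": int(v["pos"]), "top_p": float(v["p"]),
                "candidate_genes": ",".join(hosts),
            })
    return pd.DataFrame(rows)


def blocks_to_bed(blocks: list[Block]) -> pd.DataFrame:
    return pd.DataFrame([(b.arm, b.start, b.end) for b in blocks],
                        columns=["arm", "start", "end"])


DEFAULT_SCALES = ((50_000, 10_000), (100_000, 25_000), (250_000, 50_000))


def multiscale_scan(variants: pd.DataFrame,
                    scales=DEFAULT_SCALES, alpha: float = 0.05,
                    arm_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Regions significant at every window/step scale.

    Runs the scan-adjust-consolidate chain at each scale and intersects the
    resulting block intervals across scales; a region surviving all scales
    is robust to the window-size choice.  Returns BED-style intervals.
    """
    if not scales:
        raise ValueError("need at least one (window, step) scale")
    per_scale = []
    for window, step in scales:
        wins = adjust_windows(scan_windows(variants, window, step,
                                           arm_lengths), alpha=alpha)
        per_scale.append(consolidate_blocks(wins))
    regions = [(b.arm, b.start, b.end) for b in per_scale[0]]
    for blocks in per_scale[1:]:
        others = [(b.arm, b.start, b.end) for b in blocks]
        merged = []
        for arm, s1, e1 in regions:
            for arm2, s2, e2 in others:
                if arm == arm2 and s1 < e2 and s2 < e1:
                    merged.append((arm, max(s1, s2), min(e1, e2)))
        regions = merged
    return pd.DataFrame(regions, columns=["arm", "start", "end"])
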
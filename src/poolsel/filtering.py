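"""Count-level QC that defines the analyzable biallelic variant set.

The filters operate on raw Pool-seq nucleotide counts merged across all
samples (the variant reference, "VarRef"):

1. a sequencing-error threshold taken as an empirical quantile of the
   third-largest allele count over sites; sites whose third allele exceeds
   it are dropped as unresolvable, and sites whose minor allele does not
   exceed it are dropped as likely errors;
2. coverage filters: a global minimum depth, removal of the upper tail of
   the merged-depth distribution (repeat/CNV suspects), and removal of
   sites under-covered in every sample of a generation cohort;
3. a binomial confidence-interval filter: a site is high-confidence when
   the lower bound of the minor-allele CI clears zero in at least one
   sample.

Counts on alleles other than the retained ref/alt pair are excluded from
depth, and allele frequencies are estimated as alt count over depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ALLELE_CLASS_IDX, ALLELE_COLS, PooledCountsTable


@dataclass(frozen=True)
class FilterConfig:
    third_allele_quantile: float = 0.75
    min_global_depth: int = 10
    high_cov_quantile: float = 0.95
    per_sample_min_depth: int = 10
    ci_level: float = 0.9973
    ci_method: str = "clopper-pearson"   # or "wilson", "wald"
    min_minor_reads: int | None = None   # None -> use third-allele threshold
    triallelic_per_sample: bool = False

    def __post_init__(self) -> None:
        for q in (self.third_allele_quantile, self.high_cov_quantile):
            if not 0.0 < q < 1.0:
                raise ValueError("quantiles must lie in (0, 1)")
        if not 0.5 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0.5, 1)")


@dataclass
class BiallelicVariantTable:
    """Retained biallelic sites with per-sample alt counts and depths.

    ``depths`` count only reads on the retained ref/alt pair.
    """

    sites: pd.DataFrame          # arm, pos, ref, alt
    alt_counts: np.ndarray       # (n_samples, n_sites)
    depths: np.ndarray           # (n_samples, n_sites)
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.sites["ref"] == self.sites["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        if (self.alt_counts > self.depths).any():
            raise ValueError("alt counts cannot exceed depth")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset(self, mask: np.ndarray) -> "BiallelicVariantTable":
        return BiallelicVariantTable(
            sites=self.sites.loc[mask].reset_index(drop=True),
            alt_counts=self.alt_counts[:, mask],
            depths=self.depths[:, mask], samples=list(self.samples))

    def write_tsv(self, path: str | Path) -> None:
        df = self.sites.copy()
        for j, s in enumerate(self.samples):
            df[s] = [f"{a}:{d}" for a, d in
                     zip(self.alt_counts[j], self.depths[j])]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BiallelicVariantTable":
        df = pd.read_csv(path, sep="\t")
        samples = [c for c in df.columns
                   if c not in ("arm", "pos", "ref", "alt")]
        alt = np.zeros((len(samples), len(df)), dtype=np.int64)
        dep = np.zeros_like(alt)
        for j, s in enumerate(samples):
            parts = df[s].str.split(":", expand=True).astype(int)
            alt[j] = parts[0].to_numpy()
            dep[j] = parts[1].to_numpy()
        return cls(sites=df[["arm", "pos", "ref", "alt"]].copy(),
                   alt_counts=alt, depths=dep, samples=samples)


def lower_quantile(values: np.ndarray, q: float) -> float:
    """Lower (type-1) empirical quantile: an order statistic of the data."""
    values = np.sort(np.asarray(values))
    if len(values) == 0:
        raise ValueError("empty sample")
    idx = max(int(np.ceil(q * len(values))) - 1, 0)
    return values[idx]


def merge_varref(table: PooledCountsTable | list[PooledCountsTable]):
    """Element-wise per-nucleotide sum of counts across all samples.

    Returns ``(merged counts (n_sites, 6), median merged depth)``.  When
    given several tables, their site sets must agree exactly.
    """
    if isinstance(table, PooledCountsTable):
        tables = [table]
    else:
        tables = list(table)
        if not tables:
            raise ValueError("need at least one sample table")
        ref_keys = tables[0].site_keys()
        for other in tables[1:]:
            keys = other.site_keys()
            if not ref_keys.equals(keys):
                diff = ref_keys.symmetric_difference(keys)
                raise ValueError(
                    "site sets differ between samples; offending sites: "
                    + ", ".join(f"{a}:{p}" for a, p in list(diff)[:10]))
    merged = sum(t.counts.sum(axis=0) for t in tables)
    depth = merged[:, ALLELE_CLASS_IDX].sum(axis=1)
    return merged, float(np.median(depth))


def third_allele_threshold(varref: np.ndarray, q: float = 0.75) -> int:
    """Empirical error threshold from the third-largest allele count.

    Per site the allele-class counts are sorted descending and the
    third-largest collected; the threshold is the lower empirical q-quantile
    of that distribution, as an integer.
    """
    classes = np.sort(varref[:, ALLELE_CLASS_IDX], axis=1)[:, ::-1]
    third = classes[:, 2]
    return int(lower_quantile(third, q))


def call_biallelic(table: PooledCountsTable, varref: np.ndarray,
                   threshold: int,
                   per_sample: bool = False) -> BiallelicVariantTable:
    """Resolve candidate biallelic sites against the error threshold.

    Drops sites whose third allele exceeds ``threshold`` (merged counts by
    default; with ``per_sample`` the rule applies in any single sample) and
    sites whose merged minor-allele count does not exceed it.  Ref/alt are
    the two most frequent merged alleles, with the reference base claiming
    the ref slot when it is one of them; reads on other alleles are excluded
    from depth.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    classes = varref[:, ALLELE_CLASS_IDX]
    order = np.argsort(classes, axis=1, kind="stable")[:, ::-1]
    ranked = np.take_along_axis(classes, order, axis=1)
    if per_sample:
        sc = table.counts[:, :, ALLELE_CLASS_IDX]
        # third allele in each sample, judged by the merged allele ranking
        third_any = np.take_along_axis(
            sc, np.broadcast_to(order[None], sc.shape), axis=2)[:, :, 2:]
        ok_third = (third_any.sum(axis=2).max(axis=0) <= threshold)
    else:
        ok_third = ranked[:, 2:].sum(axis=1) <= threshold
    ok_minor = ranked[:, 1] > threshold
    keep = ok_third & ok_minor

    top_idx = ALLELE_CLASS_IDX[order[:, :2]]         # indices into 6 columns
    names = np.array(ALLELE_COLS)
    first, second = names[top_idx[:, 0]], names[top_idx[:, 1]]
    ref_base = table.sites["ref"].to_numpy()
    ref_is_second = second == ref_base
    ref_allele = np.where(ref_is_second, second, first)
    alt_allele = np.where(ref_is_second, first, second)
    ref_col = np.where(ref_is_second, top_idx[:, 1], top_idx[:, 0])
    alt_col = np.where(ref_is_second, top_idx[:, 0], top_idx[:, 1])

    nsite = np.arange(table.n_sites)
    alt = table.counts[:, nsite, alt_col]
    dep = alt + table.counts[:, nsite, ref_col]
    sites = pd.DataFrame({
        "arm": table.sites["arm"].to_numpy(), "pos":
        table.sites["pos"].to_numpy(),
        "ref": ref_allele, "alt": alt_allele,
    })
    out = BiallelicVariantTable(sites=sites, alt_counts=alt, depths=dep,
                                samples=list(table.samples))
    return out.subset(keep)


def coverage_filters(table: BiallelicVariantTable, design: pd.DataFrame,
                     config: FilterConfig,
                     high_cov_cutoff: float | None = None):
    """Global-depth, high-coverage-quantile and cohort low-coverage filters.

    A site survives when its merged depth strictly exceeds
    ``min_global_depth``, does not exceed the lower ``high_cov_quantile`` of
    the merged-depth distribution at biallelic sites (or an explicit
    ``high_cov_cutoff``), and in every generation cohort at least one sample
    covers it at ``per_sample_min_depth`` or better.

    Returns ``(filtered table, realized high-coverage cutoff)``.
    """
    merged = table.depths.sum(axis=0)
    keep = merged > config.min_global_depth
    hi = (lower_quantile(merged, config.high_cov_quantile)
          if high_cov_cutoff is None else high_cov_cutoff)
    keep &= merged <= hi
    sample_pos = {s: j for j, s in enumerate(table.samples)}
    for _, cohort in design.groupby("generation"):
        idx = [sample_pos[s] for s in cohort["sample"] if s in sample_pos]
        if not idx:
            continue
        all_low = (table.depths[idx] < config.per_sample_min_depth).all(axis=0)
        keep &= ~all_low
    return table.subset(keep), float(hi)


def binomial_ci_lower(minor, depth, level: float = 0.9973,
                      method: str = "clopper-pearson"):
    """Lower bound of a two-sided binomial CI for the minor-allele fraction.

    Clopper-Pearson (exact) by default, in which case zero minor reads give
    a bound of exactly 0; Wilson and Wald (normal-approximation) bounds are
    available as options.
    """
    minor = np.asarray(minor, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if (depth <= 0).any():
        raise ValueError("depth must be positive")
    if ((minor < 0) | (minor > depth)).any():
        raise ValueError("minor count must lie in [0, depth]")
    alpha = 1.0 - level
    if method == "clopper-pearson":
        with np.errstate(invalid="ignore"):
            lo = stats.beta.ppf(alpha / 2.0, minor, depth - minor + 1.0)
        return np.where(minor == 0, 0.0, lo)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    phat = minor / depth
    if method == "wilson":
        denom = 1.0 + z * z / depth
        centre = phat + z * z / (2.0 * depth)
        rad = z * np.sqrt(phat * (1 - phat) / depth
                          + z * z / (4.0 * depth * depth))
        return np.maximum((centre - rad) / denom, 0.0)
    if method == "wald":
        return np.maximum(phat - z * np.sqrt(phat * (1 - phat) / depth), 0.0)
    raise ValueError(f"unknown CI method {method!r}")


def high_confidence_filter(table: BiallelicVariantTable,
                           level: float = 0.9973,
                           method: str = "clopper-pearson"
                           ) -> BiallelicVariantTable:
    """Keep sites whose minor-allele CI lower bound clears zero somewhere.

    The minor allele is the globally less frequent member of the ref/alt
    pair; the rule needs to fire in only one sample ("any one" semantics).
    """
    merged_alt = table.alt_counts.sum(axis=0)
    merged_dep = table.depths.sum(axis=0)
    alt_is_minor = merged_alt * 2 <= merged_dep
    minor = np.where(alt_is_minor, table.alt_counts,
                     table.depths - table.alt_counts)
    ok = np.zeros(table.n_sites, dtype=bool)
    pos_depth = table.depths > 0
    lo = np.zeros_like(minor, dtype=float)
    if pos_depth.any():
        lo[pos_depth] = binomial_ci_lower(minor[pos_depth],
                                          table.depths[pos_depth],
                                          level, method)
    ok = (pos_depth & (lo > 0)).any(axis=0)
    return table.subset(ok)


def allele_frequencies(table: BiallelicVariantTable) -> np.ndarray:
    """Per-sample alt-allele fraction, NaN where a sample has zero depth."""
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = table.alt_counts / table.depths
    return np.where(table.depths > 0, freq, np.nan)


def frequencies_frame(table: BiallelicVariantTable) -> pd.DataFrame:
    freq = allele_frequencies(table)
    df = table.sites.copy()
    for j, s in enumerate(table.samples):
        df[s] = freq[j]
    return df


@dataclass
class FilterReport:
    n_input: int
    median_merged_depth: float
    third_allele_threshold: int
    high_cov_cutoff: float
    n_biallelic: int
    n_after_coverage: int
    n_high_confidence: int


def filter_pipeline(table: PooledCountsTable, design: pd.DataFrame,
                    config: FilterConfig | None = None,
                    frozen: FilterReport | None = None):
    """Run the full QC chain; returns (BiallelicVariantTable, FilterReport).

    Data-derived thresholds (the third-allele error threshold and the
    high-coverage depth cutoff) are recorded in the report; passing a
    previous report as ``frozen`` re-applies those realized thresholds
    instead of re-estimating them, which makes the pipeline idempotent on
    its own output.
    """
    if config is None:
        config = FilterConfig()
    varref, median_depth = merge_varref(table)
    if frozen is not None:
        thr = frozen.third_allele_threshold
        hi_cut = frozen.high_cov_cutoff
    else:
        thr = third_allele_threshold(varref, config.third_allele_quantile)
        if config.min_minor_reads is not None:
            thr = config.min_minor_reads
        hi_cut = None
    bial = call_biallelic(table, varref, thr,
                          per_sample=config.triallelic_per_sample)
    n_bial = bial.n_sites
    covered, hi_cut = coverage_filters(bial, design, config,
                                       high_cov_cutoff=hi_cut)
    n_cov = covered.n_sites
    final = high_confidence_filter(covered, config.ci_level, config.ci_method)
    report = FilterReport(
        n_input=table.n_sites, median_merged_depth=median_depth,
        third_allele_threshold=thr, high_cov_cutoff=hi_cut,
        n_biallelic=n_bial, n_after_coverage=n_cov,
        n_high_confidence=final.n_sites)
    return final, report
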
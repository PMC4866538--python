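"""Core data containers and text-format I/O.

The pipeline's universal currency is a table of per-site, per-sample
nucleotide read counts from pooled sequencing (Pool-seq).  Counts travel
in PoPoolation2 "sync" format: one row per site with columns

    arm  pos(1-based)  refbase  A:T:C:G:N:del  [one column per sample]

Sample metadata (treatment, replicate, generation, pool size) travels as a
plain TSV, and gene models as BED or minimal GFF3.  All coordinates are
1-based in files and 0-based half-open internally for intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Column order of a sync count field.
ALLELE_COLS = ("A", "T", "C", "G", "N", "del")
#: Indices of true allele classes (N is an ambiguity code, not an allele).
ALLELE_CLASS_IDX = np.array([0, 1, 2, 3, 5])

REQUIRED_DESIGN_COLS = ("sample", "treatment", "replicate", "generation",
                        "pool_chromosomes")
TREATMENTS = ("selected", "control")


@dataclass
class PooledCountsTable:
    """Per-site nucleotide read counts for a set of pooled samples.

    Attributes
    ----------
    sites : pandas.DataFrame with columns ``arm``, ``pos`` (1-based), ``ref``.
    counts : int array of shape (n_samples, n_sites, 6) in ALLELE_COLS order.
    samples : list of sample identifiers matching axis 0 of ``counts``.
    """

    sites: pd.DataFrame
    counts: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != len(ALLELE_COLS):
            raise ValueError("counts must have shape (n_samples, n_sites, 6)")
        if self.counts.shape[1] != len(self.sites):
            raise ValueError("counts/sites length mismatch")
        if self.counts.shape[0] != len(self.samples):
            raise ValueError("counts/samples length mismatch")
        if (self.counts < 0).any():
            raise ValueError("read counts must be non-negative")
        dup = self.sites.duplicated(subset=["arm", "pos"])
        if dup.any():
            raise ValueError("duplicate sites: "
                             + str(self.sites[dup].head().to_dict("records")))

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.sites[["arm", "pos"]])

    def write_sync(self, path: str | Path) -> None:
        cols = {}
        for j, sample in enumerate(self.samples):
            c = self.counts[j]
            cols[sample] = [":".join(map(str, row)) for row in c]
        df = self.sites[["arm", "pos", "ref"]].copy()
        for sample in self.samples:
            df[sample] = cols[sample]
        df.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def read_sync(cls, path: str | Path,
                  samples: list[str] | None = None) -> "PooledCountsTable":
        rows = pd.read_csv(path, sep="\t", header=None, dtype=str,
                           comment="#")
        n_samp = rows.shape[1] - 3
        if samples is None:
            samples = [f"sample{i + 1}" for i in range(n_samp)]
        if len(samples) != n_samp:
            raise ValueError(f"expected {n_samp} sample names, "
                             f"got {len(samples)}")
        sites = pd.DataFrame({
            "arm": rows[0].to_numpy(),
            "pos": rows[1].astype(int).to_numpy(),
            "ref": rows[2].to_numpy(),
        })
        counts = np.zeros((n_samp, len(rows), 6), dtype=np.int64)
        for j in range(n_samp):
            parts = rows[3 + j].str.split(":", expand=True).astype(int)
            counts[j] = parts.to_numpy()
        return cls(sites=sites, counts=counts, samples=list(samples))


def make_design(samples: list[str], treatments: list[str],
                replicates: list[int], generations: list[int],
                pool_chromosomes: int | list[int] = 200) -> pd.DataFrame:
    if np.isscalar(pool_chromosomes):
        pool_chromosomes = [int(pool_chromosomes)] * len(samples)
    df = pd.DataFrame({
        "sample": samples, "treatment": treatments,
        "replicate": replicates, "generation": generations,
        "pool_chromosomes": pool_chromosomes,
    })
    validate_design(df)
    return df


def validate_design(design: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_DESIGN_COLS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    bad = set(design["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValueError(f"unknown treatment labels: {sorted(bad)}; "
                         f"expected {TREATMENTS}")


def design_is_balanced(design: pd.DataFrame) -> bool:
    """Equal replicate counts per treatment within every generation."""
    for _, sub in design.groupby("generation"):
        sizes = sub.groupby("treatment").size()
        if len(sizes) != 2 or sizes.iloc[0] != sizes.iloc[1]:
            return False
    return True


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_design(df)
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open, native)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = pd.DataFrame({
        "gene": df[3] if df.shape[1] > 3 else
        [f"iv{i}" for i in range(len(df))],
        "arm": df[0], "start": df[1].astype(int), "end": df[2].astype(int),
    })
    return _check_genes(genes)


def read_gff(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Read gene features from minimal GFF3 (1-based closed -> half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["seqid", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"])
    df = df[df["type"] == feature]
    ids = []
    for attr in df["attributes"]:
        fields = dict(kv.split("=", 1) for kv in str(attr).split(";") if "=" in kv)
        ids.append(fields.get("ID") or fields.get("Name") or attr)
    genes = pd.DataFrame({
        "gene": ids, "arm": df["seqid"].to_numpy(),
        "start": df["start"].astype(int).to_numpy() - 1,
        "end": df["end"].astype(int).to_numpy(),
    })
    return _check_genes(genes)


def _check_genes(genes: pd.DataFrame) -> pd.DataFrame:
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("gene intervals must satisfy start < end")
    if genes["gene"].duplicated().any():
        raise ValueError("gene ids must be unique")
    return genes.reset_index(drop=True)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return read_gff(path)
    return read_bed(path)
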
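"""Replicate-consistency descriptive statistics.

diffStat scores a variant by the smallest absolute allele-frequency
difference over the nine treatment-by-control replicate pairs, and is
nonzero only when all nine differences share one sign - a variant must have
moved the same way in every cross-replicate comparison to score at all.

Between-generation consistency asks, within one treatment, whether the
allele frequency moved in the same direction in every replicate between the
early and late sampled generations, and bins the minimum magnitude of that
movement for the treated/control ratio histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DiffStatRecord:
    diffs: np.ndarray          # the nine signed differences d_ij
    consistent: bool
    diffstat: float


def diffstat(treat_freqs, control_freqs) -> DiffStatRecord:
    """diffStat for one variant from its 3+3 replicate frequencies.

    All nine pairwise differences treat_i - control_j are formed; if they
    share one strict sign the score is min |d|, otherwise 0 (a zero
    difference has no direction and breaks consistency).
    """
    t = np.asarray(treat_freqs, dtype=float)
    c = np.asarray(control_freqs, dtype=float)
    if ((t < 0) | (t > 1)).any() or ((c < 0) | (c > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    d = (t[:, None] - c[None, :]).ravel()
    consistent = bool((d > 0).all() or (d < 0).all())
    return DiffStatRecord(diffs=d, consistent=consistent,
                          diffstat=float(np.abs(d).min()) if consistent
                          else 0.0)


def diffstat_table(treat_freqs: np.ndarray,
                   control_freqs: np.ndarray) -> pd.DataFrame:
    """Vectorized diffStat over variants: arrays of shape (n_sites, k)."""
    t = np.asarray(treat_freqs, dtype=float)
    c = np.asarray(control_freqs, dtype=float)
    d = t[:, :, None] - c[:, None, :]
    d = d.reshape(len(t), -1)
    consistent = (d > 0).all(axis=1) | (d < 0).all(axis=1)
    score = np.where(consistent, np.abs(d).min(axis=1), 0.0)
    return pd.DataFrame({"consistent": consistent, "diffstat": score})


def generation_consistency(freq_late: np.ndarray, freq_early: np.ndarray,
                           bin_width: float = 0.05):
    """Directional consistency of per-replicate changes between generations.

    ``freq_late``/``freq_early`` are (n_sites, n_replicates) for one
    treatment.  Returns a per-variant frame (deltas, consistency, minimum
    magnitude and its bin) plus the summary fraction of consistent variants.
    A zero change in any replicate breaks consistency.
    """
    late = np.asarray(freq_late, dtype=float)
    early = np.asarray(freq_early, dtype=float)
    if late.shape != early.shape:
        raise ValueError("generation frequency tables must align")
    delta = late - early
    consistent = (delta > 0).all(axis=1) | (delta < 0).all(axis=1)
    mag = np.abs(delta).min(axis=1)
    bin_idx = np.floor(mag / bin_width).astype(int)
    records = pd.DataFrame({
        "consistent": consistent, "min_abs_change": mag,
        "magnitude_bin": np.where(consistent, bin_idx, -1),
    })
    return records, float(consistent.mean())


def change_ratio_histogram(treat_records: pd.DataFrame,
                           control_records: pd.DataFrame,
                           bin_width: float = 0.05) -> pd.DataFrame:
    """Per-magnitude-bin ratio of consistent variant counts, treated/control.

    Bins partition (0, 1] in ``bin_width`` steps; a bin with no consistent
    control variants reports a missing ratio rather than infinity.
    """
    n_bins = int(np.ceil(1.0 / bin_width))
    rows = []
    for b in range(n_bins):
        n_t = int(((treat_records["consistent"])
                   & (treat_records["magnitude_bin"] == b)).sum())
        n_c = int(((control_records["consistent"])
                   & (control_records["magnitude_bin"] == b)).sum())
        rows.append((b * bin_width, (b + 1) * bin_width, n_t, n_c,
                     n_t / n_c if n_c > 0 else np.nan))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n_treat",
                                       "n_control", "ratio"])


def two_proportion_chisq(k1: int, n1: int, k2: int, n2: int):
    """Textbook 2x2 chi-square (no continuity correction) and its p-value.

    Compares consistent-variant counts k out of n between two treatments.
    """
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    from scipy import stats
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
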
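"""Rarefaction, richness estimation and technical-replicate correlation.

Rarefaction here is bootstrap resampling *with replacement*: at each depth
d the observed relative abundances are resampled d reads at a time, and the
mean number of distinct features over the resamples traces the curve. With
replacement, the curve approaches the observed richness only when the
sample is deep enough to have captured essentially all features — so the
ratio of the curve's limit to the observed richness ("limit rarefaction")
is a saturation diagnostic, flagged below 0.97.

Chao1 and ACE estimate the unseen-feature count from the rare tail
(singletons/doubletons for Chao1, counts up to 10 for ACE); S_obs divided
by the estimate is the fraction of the estimated richness actually
observed.

The N-1 tag synthesis error is exploited for technical replication: reads
carrying the truncated variant of a tag are an independent draw from the
same PCR tube, and the per-OTU count correlation between the full-length
and N-1 pseudo-samples measures within-sample reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio.diversity.alpha import ace as _skbio_ace, chao1 as _skbio_chao1

__all__ = [
    "RarefactionCurve",
    "RichnessEstimate",
    "ReplicateReport",
    "rarefy",
    "rarefaction_closed_form",
    "richness",
    "saturation_report",
    "replicate_correlation",
]


@dataclass
class RarefactionCurve:
    sample_id: str
    feature_level: str  # "ISU" | "OTU"
    min_count: int
    depths: np.ndarray
    mean_richness: np.ndarray
    ci95: np.ndarray  # (n_depths, 2)
    ci99: np.ndarray
    n_resamples: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depths,
                "mean_richness": self.mean_richness,
                "ci95_lo": self.ci95[:, 0],
                "ci95_hi": self.ci95[:, 1],
                "ci99_lo": self.ci99[:, 0],
                "ci99_hi": self.ci99[:, 1],
            }
        )


def rarefy(
    counts: Sequence[int],
    depths: Sequence[int] | None = None,
    n_resamples: int = 10000,
    min_count: int = 1,
    seed: int = 0,
    sample_id: str = "",
    feature_level: str = "OTU",
) -> RarefactionCurve:
    """Bootstrap rarefaction of one sample's feature count vector.

    ``min_count`` filters the source vector *before* resampling (a filter of
    3 keeps features seen more than twice). Default depth grid: 20 evenly
    spaced points up to the sample total.
    """
    counts = np.asarray([c for c in counts if c >= min_count], dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("no features left after min_count filter")
    total = int(counts.sum())
    if depths is None:
        depths = np.unique(np.linspace(1, total, 20).astype(int))
    depths = np.asarray(depths, dtype=int)
    if (depths <= 0).any():
        raise ValueError("rarefaction depths must be positive")

    rng = np.random.default_rng(seed)
    p = counts / counts.sum()
    means = np.empty(len(depths))
    ci95 = np.empty((len(depths), 2))
    ci99 = np.empty((len(depths), 2))
    for i, d in enumerate(depths):
        draws = rng.multinomial(int(d), p, size=n_resamples)
        rich = (draws > 0).sum(axis=1)
        means[i] = rich.mean()
        ci95[i] = np.percentile(rich, [2.5, 97.5])
        ci99[i] = np.percentile(rich, [0.5, 99.5])
    return RarefactionCurve(
        sample_id=sample_id,
        feature_level=feature_level,
        min_count=min_count,
        depths=depths,
        mean_richness=means,
        ci95=ci95,
        ci99=ci99,
        n_resamples=n_resamples,
        seed=seed,
    )


def rarefaction_closed_form(counts: Sequence[int], depth: int) -> float:
    """Expected distinct-feature count at a given bootstrap depth:
    sum_i 1 - (1 - p_i)^d. Used as the analytic check on the Monte-Carlo
    curve."""
    p = np.asarray(counts, dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    return float((1.0 - (1.0 - p) ** depth).sum())


@dataclass
class RichnessEstimate:
    s_obs: int
    f1: int
    f2: int
    chao1: float
    chao1_bias_corrected: float
    ace: float
    saturation_chao1: float
    saturation_ace: float
    #: mean bootstrap-rarefied richness at full depth / S_obs; filled by
    #: saturation_report, which owns the resampling
    limit_rarefaction: float | None = None


def richness(counts: Sequence[int]) -> RichnessEstimate:
    """Chao1 (classic and bias-corrected) and ACE richness for one sample.

    Classic Chao1 is S_obs + F1^2/(2 F2); with no doubletons it degrades to
    S_obs + F1(F1-1)/2. ACE uses the standard rare-class cutoff of 10; in
    the degenerate case where every rare feature is a singleton (ACE
    undefined) the bias-corrected Chao1 is substituted, and with no rare
    class at all ACE equals S_obs.
    """
    arr = np.asarray([c for c in counts if c > 0], dtype=int)
    if arr.size == 0:
        raise ValueError("empty count vector")
    s_obs = int(arr.size)
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    chao1 = float(_skbio_chao1(arr, bias_corrected=False))
    chao1_bc = float(_skbio_chao1(arr, bias_corrected=True))
    rare = arr[arr <= 10]
    if rare.size == 0:
        ace_val = float(s_obs)
    else:
        try:
            ace_val = float(_skbio_ace(arr, rare_threshold=10))
        except ValueError:
            # all rare features are singletons; ACE is undefined there
            ace_val = chao1_bc
    return RichnessEstimate(
        s_obs=s_obs,
        f1=f1,
        f2=f2,
        chao1=chao1,
        chao1_bias_corrected=chao1_bc,
        ace=ace_val,
        saturation_chao1=s_obs / chao1 if chao1 > 0 else 1.0,
        saturation_ace=s_obs / ace_val if ace_val > 0 else 1.0,
    )


def saturation_report(
    sample_counts: Mapping[str, Sequence[int]],
    limit_threshold: float = 0.97,
    n_resamples: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample richness estimates, limit-rarefaction values and
    saturation flags.

    A sample is flagged when the mean bootstrap-rarefied richness at full
    depth falls below ``limit_threshold`` of the observed richness — the
    sample was too shallow to capture its own diversity.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample, counts in sample_counts.items():
        est = richness(counts)
        arr = np.asarray([c for c in counts if c > 0], dtype=float)
        p = arr / arr.sum()
        depth = int(arr.sum())
        draws = rng.multinomial(depth, p, size=n_resamples)
        limit = float((draws > 0).sum(axis=1).mean()) / est.s_obs
        est.limit_rarefaction = limit
        rows.append(
            {
                "sample_id": sample,
                "s_obs": est.s_obs,
                "f1": est.f1,
                "f2": est.f2,
                "chao1": est.chao1,
                "chao1_bias_corrected": est.chao1_bias_corrected,
                "ace": est.ace,
                "saturation_chao1": est.saturation_chao1,
                "saturation_ace": est.saturation_ace,
                "limit_rarefaction": limit,
                "flagged": limit < limit_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class ReplicateReport:
    #: (full sample, N-1 sample) -> Pearson r on log10 counts, or None when
    #: fewer than 3 OTUs pass the filters
    correlations: dict[tuple[str, str], float | None] = field(default_factory=dict)
    n_otus_used: dict[tuple[str, str], int] = field(default_factory=dict)


def replicate_correlation(
    count_table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    min_full: int = 30,
    min_n1: int = 10,
) -> ReplicateReport:
    """Pearson correlation of log10 OTU counts between full-length-tag and
    N-1-tag pseudo-samples.

    Only OTUs with at least ``min_full`` reads in the full sample and
    ``min_n1`` in the N-1 sample enter; below 3 such OTUs the correlation
    is reported as undefined (None) rather than a number.
    """
    report = ReplicateReport()
    for full, n1 in pairs:
        a = count_table.loc[full].to_numpy(dtype=float)
        b = count_table.loc[n1].to_numpy(dtype=float)
        mask = (a >= min_full) & (b >= min_n1)
        n = int(mask.sum())
        report.n_otus_used[(full, n1)] = n
        if n < 3:
            report.correlations[(full, n1)] = None
            continue
        r, _ = sps.pearsonr(np.log10(a[mask]), np.log10(b[mask]))
        report.correlations[(full, n1)] = float(r)
    return report
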
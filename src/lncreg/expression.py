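"""Count normalization, expression filtering and differential expression.

Counts are normalized between samples by trimmed mean of M-values (TMM,
the edgeR formulation: M-ratios trimmed 30%, A-abundances trimmed 5%,
precision weights from the asymptotic binomial variance). Transcripts
are retained per tissue when they reach 1 CPM in at least half of that
tissue's samples. Differential expression between the high and low
feed-efficiency groups uses a per-transcript Welch t-test on
log2(CPM + 0.5) with a raw p < 0.01 cutoff — a deliberately permissive
prioritization rule rather than a multiplicity-corrected discovery rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GROUPS = ("highFE", "lowFE")


@dataclass
class CountMatrix:
    """Transcripts x samples integer counts with sample metadata.

    ``sample_meta`` is indexed by sample ID with columns ``tissue`` and
    ``group`` (highFE/lowFE).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("transcript IDs must be unique")
        if list(self.values.columns) != list(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        if (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.lib_size <= 0).any():
            bad = self.lib_size[self.lib_size <= 0].index.tolist()
            raise ValueError(f"samples with zero library size: {bad}")

    @property
    def lib_size(self) -> pd.Series:
        return self.values.sum(axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.values[list(samples)], self.sample_meta.loc[list(samples)])

    def subset_tissue(self, tissue: str) -> "CountMatrix":
        keep = self.sample_meta.index[self.sample_meta["tissue"] == tissue]
        return self.subset_samples(list(keep))

    def to_tsv(self, counts_path: Union[str, Path], meta_path: Union[str, Path]) -> None:
        self.values.to_csv(counts_path, sep="\t", index_label="transcript")
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(
        cls, counts_path: Union[str, Path], meta_path: Union[str, Path]
    ) -> "CountMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values, meta)


def cpm(
    m: CountMatrix, factors: Optional[pd.Series] = None, log2: bool = False,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Counts per million over effective library sizes (lib_size * factor)."""
    if factors is None:
        factors = pd.Series(1.0, index=m.values.columns)
    factors = factors.reindex(m.values.columns)
    if (factors <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = m.lib_size * factors
    out = m.values / eff * 1e6
    if log2:
        out = np.log2(out + prior)
    return out


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (before rescaling)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # asymptotic binomial precision weights
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[finite], a[finite], v[finite]
    n = m.size
    if n == 0 or float(np.max(np.abs(m))) < 1e-6:
        return 1.0
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or np.sum(1.0 / v[keep]) == 0:
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    m: CountMatrix,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    The reference sample is the one whose upper-quartile CPM is closest
    to the mean upper-quartile.
    """
    if m.values.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = m.values.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    uq = np.array(
        [np.quantile(x[:, j][x[:, j] > 0] / lib[j], 0.75) if (x[:, j] > 0).any() else 0.0
         for j in range(x.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            factors[j] = _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
                                   logratio_trim, sum_trim)
            continue
        shared = (x[:, j] > 0) & (x[:, ref_idx] > 0)
        if not shared.any():
            logger.warning(
                "sample %s shares no expressed transcript with the reference; factor 1",
                m.values.columns[j],
            )
            factors[j] = 1.0
            continue
        factors[j] = _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
                               logratio_trim, sum_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.values.columns)


def expressed_filter(
    m: CountMatrix,
    factors: Optional[pd.Series] = None,
    min_cpm: float = 1.0,
    min_fraction: float = 0.5,
) -> dict[str, set[str]]:
    """Per-tissue sets of transcripts with CPM >= min_cpm in >= half the samples."""
    c = cpm(m, factors)
    out: dict[str, set[str]] = {}
    for tissue in sorted(m.sample_meta["tissue"].unique()):
        cols = m.sample_meta.index[m.sample_meta["tissue"] == tissue]
        need = int(np.ceil(len(cols) * min_fraction))
        ok = (c[cols] >= min_cpm).sum(axis=1) >= need
        out[tissue] = set(m.values.index[ok])
    return out


@dataclass(frozen=True)
class DEResult:
    transcript: str
    mean_high: float
    mean_low: float
    t_stat: float
    p: float
    de_flag: bool


def de_ttest(
    m: CountMatrix,
    factors: Optional[pd.Series] = None,
    transcripts: Optional[Sequence[str]] = None,
    alpha: float = 0.01,
    group_col: str = "group",
) -> pd.DataFrame:
    """Welch t-test per transcript on log2(CPM + 0.5), highFE vs lowFE.

    Expected to be applied within one tissue after the expression filter.
    Returns columns (transcript, mean_high, mean_low, t, p, de_flag);
    no multiple-testing correction by design.
    """
    groups = m.sample_meta[group_col]
    high = groups.index[groups == GROUPS[0]]
    low = groups.index[groups == GROUPS[1]]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("both groups need at least two samples")
    logc = cpm(m, factors, log2=True)
    if transcripts is not None:
        logc = logc.loc[list(transcripts)]
    a = logc[high].to_numpy()
    b = logc[low].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    equal_means = np.isclose(mean_a, mean_b)
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    t = np.where(np.isfinite(t), t, 0.0)
    return pd.DataFrame(
        {
            "transcript": logc.index,
            "mean_high": mean_a,
            "mean_low": mean_b,
            "t": t,
            "p": p,
            "de_flag": p < alpha,
        }
    ).reset_index(drop=True)
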
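"""Two-condition TMT quantification of site-modification abundance.

Reporter-ion intensities from two channels (condition 1: +Nro1, condition 2:
-Nro1) are compared per peptide-spectrum match. Non-site PSMs give a
protein-loading correction factor f = sum(ch1)/sum(ch2); site-covering PSMs
are grouped by modification state and summarized as normalized log2 ratios
log2((ch1/ch2)/f), tested against zero with the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .silac import STATES, NOT_APPLICABLE

logger = logging.getLogger(__name__)


@dataclass
class TMTStateResult:
    n_psms: int
    log2_ratios: list = field(default_factory=list)
    fold_change: float = None          # arithmetic mean of 2**log2 ratios
    fold_change_geometric: float = None  # 2**mean(log2 ratios)
    p_value: float = None
    n_excluded_zero_channel: int = 0
    absent: bool = False


@dataclass
class TMTResult:
    """Correction factor and per-state normalized ratio summaries."""

    correction_factor: float
    n_background_psms: int
    n_duplicates_dropped: int
    states: dict  # state name -> TMTStateResult

    def to_dict(self) -> dict:
        d = asdict(self)
        d["states"] = {k: asdict(v) for k, v in self.states.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TMTResult":
        return cls(
            correction_factor=d["correction_factor"],
            n_background_psms=d["n_background_psms"],
            n_duplicates_dropped=d["n_duplicates_dropped"],
            states={k: TMTStateResult(**v) for k, v in d["states"].items()},
        )


def deduplicate(psms: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep one row per quan_result_id (highest summed reporter intensity)."""
    if psms.empty or "quan_result_id" not in psms.columns:
        return psms.copy(), 0
    df = psms.copy()
    total = df["intensity_ch1"].fillna(0) + df["intensity_ch2"].fillna(0)
    order = total.sort_values(ascending=False, kind="stable").index
    df = df.loc[order].drop_duplicates(subset="quan_result_id", keep="first")
    n_dropped = len(psms) - len(df)
    if n_dropped:
        logger.info("dropped %d duplicate QuanResultID row(s)", n_dropped)
    return df.sort_index(), n_dropped


def correction_factor(non_site_psms: pd.DataFrame) -> float:
    """Protein-loading correction f = sum(channel 1) / sum(channel 2).

    The input must already be deduplicated by quan_result_id.
    """
    if non_site_psms.empty:
        raise ValueError("correction factor requires at least one non-site PSM")
    s1 = float(pd.to_numeric(non_site_psms["intensity_ch1"], errors="coerce").sum())
    s2 = float(pd.to_numeric(non_site_psms["intensity_ch2"], errors="coerce").sum())
    if s2 == 0:
        raise ValueError("channel-2 intensity sum is zero; cannot form ratio")
    return s1 / s2


def normalized_log_ratios(
    psms_by_state: Mapping[str, pd.DataFrame], f: float
) -> dict[str, tuple[np.ndarray, int]]:
    """Per-PSM log2((ch1/ch2)/f) by state; zero-channel PSMs are excluded.

    Returns ``state -> (log2 ratios, n_excluded)``.
    """
    if f <= 0:
        raise ValueError(f"correction factor must be positive, got {f}")
    out = {}
    for state, df in psms_by_state.items():
        ch1 = pd.to_numeric(df["intensity_ch1"], errors="coerce").to_numpy(float)
        ch2 = pd.to_numeric(df["intensity_ch2"], errors="coerce").to_numpy(float)
        ok = np.nan_to_num(ch1) > 0
        ok &= np.nan_to_num(ch2) > 0
        n_excluded = int(len(df) - ok.sum())
        if n_excluded:
            logger.info(
                "state %r: excluded %d PSM(s) with zero/missing reporter channel",
                state, n_excluded,
            )
        out[state] = (np.log2((ch1[ok] / ch2[ok]) / f), n_excluded)
    return out


def wilcoxon_vs_zero(log_ratios: Sequence[float]) -> float:
    """Two-sided signed-rank p-value for median log-ratio equal to zero.

    Exact for n <= 25 without ties among nonzero values, otherwise the normal
    approximation with continuity correction. Zeros are dropped (their count
    logged); an all-zero input warns and returns p = 1.
    """
    x = np.asarray(list(log_ratios), dtype=float)
    if x.size == 0:
        raise ValueError("signed-rank test requires at least one value")
    nonzero = x[x != 0]
    n_zeros = x.size - nonzero.size
    if n_zeros:
        logger.info("dropped %d zero log-ratio(s) before signed-rank test", n_zeros)
    if nonzero.size == 0:
        warnings.warn("all log-ratios are zero; signed-rank p-value set to 1")
        return 1.0
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    return float(
        stats.wilcoxon(
            nonzero, alternative="two-sided", method=method, correction=True
        ).pvalue
    )


def fold_change(log_ratios: Sequence[float]) -> float:
    """Mean fold change: arithmetic mean of 2**log2-ratio values."""
    x = np.asarray(list(log_ratios), dtype=float)
    if x.size == 0:
        raise ValueError("fold change requires at least one log ratio")
    return float(np.mean(2.0 ** x))


def geometric_fold_change(log_ratios: Sequence[float]) -> float:
    """Geometric-mean fold change: 2**mean(log2 ratios)."""
    x = np.asarray(list(log_ratios), dtype=float)
    if x.size == 0:
        raise ValueError("fold change requires at least one log ratio")
    return float(2.0 ** np.mean(x))


class TmtStoichiometry(BaseEstimator):
    """Two-channel TMT relative-abundance estimator per modification state.

    Attributes (after :meth:`fit`)
    ------------------------------
    correction_factor_ : float
        Protein-loading factor from non-site PSMs.
    result_ : TMTResult
        Full audit trail.
    fold_changes_ : dict
        ``state -> mean fold change`` (channel 1 / channel 2).
    p_values_ : dict
        ``state -> Wilcoxon signed-rank p-value`` against zero.
    """

    def __init__(self, states: tuple = STATES):
        self.states = states

    def fit(self, psm_table: pd.DataFrame):
        """Quantify a two-channel TMT experiment.

        ``psm_table`` columns: ``sequence``, ``p62_state``,
        ``intensity_ch1``, ``intensity_ch2``, ``quan_result_id``.
        """
        df, n_dropped = deduplicate(psm_table)

        background = df[df["p62_state"] == NOT_APPLICABLE]
        if background.empty:
            raise ValueError("missing non-site PSMs (protein correction factor)")
        f = correction_factor(background)

        site = df[df["p62_state"].isin(self.states)]
        if site.empty:
            raise ValueError("missing site-covering PSMs (no P62 peptide groups)")

        by_state = {s: site[site["p62_state"] == s] for s in self.states}
        ratios = normalized_log_ratios(by_state, f)

        states_out: dict[str, TMTStateResult] = {}
        for state in self.states:
            log2r, n_excluded = ratios[state]
            if log2r.size == 0:
                states_out[state] = TMTStateResult(
                    n_psms=0, n_excluded_zero_channel=n_excluded, absent=True
                )
                continue
            states_out[state] = TMTStateResult(
                n_psms=int(log2r.size),
                log2_ratios=log2r.tolist(),
                fold_change=fold_change(log2r),
                fold_change_geometric=geometric_fold_change(log2r),
                p_value=wilcoxon_vs_zero(log2r),
                n_excluded_zero_channel=n_excluded,
            )

        self.correction_factor_ = f
        self.result_ = TMTResult(
            correction_factor=f,
            n_background_psms=int(len(background)),
            n_duplicates_dropped=n_dropped,
            states=states_out,
        )
        self.fold_changes_ = {
            s: r.fold_change for s, r in states_out.items() if not r.absent
        }
        self.p_values_ = {
            s: r.p_value for s, r in states_out.items() if not r.absent
        }
        return self


def run_tmt(psm_table: pd.DataFrame) -> TMTResult:
    """One-call TMT quantification; see :class:`TmtStoichiometry`."""
    return TmtStoichiometry().fit(psm_table).result_
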
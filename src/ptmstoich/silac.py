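"""SILAC stoichiometry quantification of the Rps23 P62 hydroxylation states.

The workflow: filter peptide-spectrum matches (PSMs), estimate the heavy-label
incorporation efficiency e from a heavy-only reference sample, correct H/L
ratios for e, normalize hydroxylation-site peptide ratios to total protein
level, convert to fractional-heavy stoichiometries, and test each modification
state's log-ratios against a theoretical H = L null with a Mann-Whitney U test.

Core transforms, with r an H/L intensity ratio:

    e        = s~ / (1 + s~)                    (s~: median heavy-only ratio)
    ra       = |x / (1 - x)|,  x = (1/e) r/(1+r)   (efficiency correction)
    pn       = p / median(ra)                   (protein-level normalization)
    H        = (1/e) pn/(1+pn), clamped to [0,1]   (fractional heavy)
    sn       = (y/2) / (1 - y/2),  y = sa/(1+sa)   (H = L theoretical null)

%H is the median H times 100 and %L = 100 - %H.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

#: Modification states of the target proline, lightest first.
STATES = ("unmodified", "mono", "di")

#: Sentinel state value for PSMs whose peptide does not cover the target site.
NOT_APPLICABLE = "na"


# --- domain types -----------------------------------------------------------


@dataclass(frozen=True)
class LabelingModel:
    """Heavy-label incorporation efficiency and its provenance."""

    e: float
    n_reference_psms: int
    reference_median_ratio: float

    def __post_init__(self):
        if not 0 < self.e <= 1:
            raise ValueError(f"labeling efficiency must be in (0, 1], got {self.e}")


@dataclass(frozen=True)
class StateComposition:
    """Percent of the site in each modification state; sums to 100."""

    percent_unmodified: float
    percent_mono: float
    percent_di: float


@dataclass
class StateResult:
    """Per-modification-state intermediates and summaries."""

    n_psms: int
    pn: list = field(default_factory=list)
    pa: list = field(default_factory=list)
    log2_pa: list = field(default_factory=list)
    h_values: list = field(default_factory=list)
    percent_heavy: float = None
    percent_light: float = None
    p_value: float = None
    n_saturated: int = 0
    n_clamped: int = 0
    absent: bool = False


@dataclass
class SilacStoichiometryResult:
    """Full audit trail of one SILAC pair quantification."""

    labeling: LabelingModel
    normalizer: float
    n_normalizer_psms: int
    n_normalizer_saturated: int
    null_sn: list
    null_log2_sn: list
    states: dict  # state name -> StateResult
    null_assumes_eq2_correction: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["labeling"] = asdict(self.labeling)
        d["states"] = {k: asdict(v) for k, v in self.states.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SilacStoichiometryResult":
        return cls(
            labeling=LabelingModel(**d["labeling"]),
            normalizer=d["normalizer"],
            n_normalizer_psms=d["n_normalizer_psms"],
            n_normalizer_saturated=d["n_normalizer_saturated"],
            null_sn=list(d["null_sn"]),
            null_log2_sn=list(d["null_log2_sn"]),
            states={k: StateResult(**v) for k, v in d["states"].items()},
            null_assumes_eq2_correction=d.get("null_assumes_eq2_correction", True),
        )


# --- PSM filtering ----------------------------------------------------------


def filter_psms(records: pd.DataFrame) -> pd.DataFrame:
    """Retain unique, high-confidence PSMs and impute single-missing channels.

    Rows failing either flag are dropped. For retained rows missing exactly
    one intensity channel, the missing value is replaced by the minimum
    observed intensity of that channel across the retained table (single-peak
    quan channels are kept, flagged via the ``imputed`` column). Rows missing
    both channels are dropped unless they carry a precomputed ratio. H/L
    ratios are recomputed from intensities after imputation.
    """
    if records.empty:
        return records.copy()
    df = records.copy()
    df = df[df["confidence"].astype(bool) & df["unique"].astype(bool)]
    if df.empty:
        return df

    for col in ("intensity_h", "intensity_l"):
        if col not in df.columns:
            df[col] = np.nan
        vals = pd.to_numeric(df[col], errors="coerce")
        df[col] = vals.where(vals > 0)  # non-positive counts as missing

    if "ratio_hl" not in df.columns:
        df["ratio_hl"] = np.nan
    df["ratio_hl"] = pd.to_numeric(df["ratio_hl"], errors="coerce")

    h_missing = df["intensity_h"].isna()
    l_missing = df["intensity_l"].isna()
    has_ratio = df["ratio_hl"] > 0
    df = df[~(h_missing & l_missing & ~has_ratio)]
    h_missing, l_missing = df["intensity_h"].isna(), df["intensity_l"].isna()

    min_h = df["intensity_h"].min()
    min_l = df["intensity_l"].min()
    df["imputed"] = False
    one_missing = h_missing ^ l_missing
    if one_missing.any():
        df.loc[one_missing & h_missing, "intensity_h"] = min_h
        df.loc[one_missing & l_missing, "intensity_l"] = min_l
        df.loc[one_missing, "imputed"] = True
        n = int(one_missing.sum())
        logger.info("imputed %d single-missing quan channel(s)", n)

    both = df["intensity_h"].notna() & df["intensity_l"].notna()
    df.loc[both, "ratio_hl"] = df.loc[both, "intensity_h"] / df.loc[both, "intensity_l"]
    return df


# --- closed-form transforms -------------------------------------------------


def labeling_efficiency(heavy_only_ratios: Sequence[float]) -> LabelingModel:
    """Estimate incorporation efficiency from heavy-only reference H/L ratios.

    e = s~/(1+s~) with s~ the (interpolated) median reference ratio.
    """
    ratios = np.asarray(list(heavy_only_ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError(
            "labeling efficiency requires at least one heavy-only reference PSM"
        )
    if np.any(ratios <= 0):
        raise ValueError("heavy-only reference ratios must be positive")
    med = float(np.median(ratios))
    return LabelingModel(
        e=med / (1.0 + med),
        n_reference_psms=int(ratios.size),
        reference_median_ratio=med,
    )


def _check_e(e: float) -> None:
    if not 0 < e <= 1:
        raise ValueError(f"labeling efficiency must be in (0, 1], got {e}")


def correct_ratio(r: float, e: float, on_saturation: str = "raise") -> float:
    """Efficiency-correct a single H/L ratio: |x/(1-x)| with x = (1/e) r/(1+r).

    x >= 1 means the implied heavy fraction exceeds the labeling ceiling
    (saturation); depending on ``on_saturation`` this raises or returns NaN.
    """
    _check_e(e)
    if r <= 0:
        raise ValueError(f"ratio must be positive, got {r}")
    x = (1.0 / e) * r / (1.0 + r)
    if x >= 1.0:
        if on_saturation == "nan":
            return math.nan
        raise ValueError(
            f"ratio {r} saturates the labeling model (x = {x:.6f} >= 1)"
        )
    return abs(x / (1.0 - x))


def correct_ratios(ratios: Sequence[float], e: float) -> tuple[np.ndarray, int]:
    """Vectorized :func:`correct_ratio`; saturated entries become NaN.

    Returns the corrected array and the count of saturated (excluded) entries.
    """
    _check_e(e)
    r = np.asarray(list(ratios), dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    x = (1.0 / e) * r / (1.0 + r)
    saturated = x >= 1.0
    out = np.full_like(x, np.nan)
    ok = ~saturated
    out[ok] = np.abs(x[ok] / (1.0 - x[ok]))
    n_sat = int(saturated.sum())
    if n_sat:
        logger.warning("%d ratio(s) saturated the labeling model (x >= 1)", n_sat)
    return out, n_sat


def protein_normalizer(
    non_site_ratios: Sequence[float], e: float
) -> tuple[float, int]:
    """Median efficiency-corrected H/L over non-site protein PSMs.

    Returns ``(normalizer, n_saturated)``; saturated PSMs are excluded from
    the median.
    """
    ratios = np.asarray(list(non_site_ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError("protein normalizer requires at least one non-site PSM")
    corrected, n_sat = correct_ratios(ratios, e)
    valid = corrected[~np.isnan(corrected)]
    if valid.size == 0:
        raise ValueError("all normalizer PSMs saturated the labeling model")
    return float(np.median(valid)), n_sat


def normalize_p62_ratios(
    ratios_by_state: Mapping[str, Sequence[float]], normalizer: float
) -> dict[str, np.ndarray]:
    """Divide each state group's site-peptide ratios by the protein normalizer."""
    if normalizer <= 0:
        raise ValueError(f"normalizer must be positive, got {normalizer}")
    out = {}
    for state, ratios in ratios_by_state.items():
        arr = np.asarray(list(ratios), dtype=float)
        if arr.size == 0:
            logger.info("state %r has no PSMs; flagged absent", state)
        out[state] = arr / normalizer
    return out


def fractional_heavy(pn, e: float) -> np.ndarray | float:
    """Fractional heavy H = (1/e) pn/(1+pn), clamped into [0, 1].

    Accepts a scalar or array; clamping (raw value > 1) is logged.
    """
    _check_e(e)
    arr = np.asarray(pn, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("normalized ratios must be positive")
    h = (1.0 / e) * arr / (1.0 + arr)
    n_clamped = int(np.sum(h > 1.0))
    if n_clamped:
        logger.info("clamped %d fractional-heavy value(s) above 1", n_clamped)
    h = np.clip(h, 0.0, 1.0)
    return float(h) if np.isscalar(pn) else h


def percent_heavy(h_values: Sequence[float]) -> tuple[float, float]:
    """(%H, %L) = (median(H) x 100, 100 - %H)."""
    h = np.asarray(list(h_values), dtype=float)
    if h.size == 0:
        raise ValueError("percent_heavy requires at least one H value")
    ph = float(np.median(h) * 100.0)
    return ph, 100.0 - ph


def theoretical_null(
    reference_ratios: Sequence[float], e: float
) -> tuple[np.ndarray, np.ndarray]:
    """Build the H = L null ratio set from reference H/L ratios.

    Each ratio is efficiency-corrected (same transform as for measured
    ratios), then mapped to the ratio it would have if heavy and light truly
    contributed equally: sn = (y/2)/(1 - y/2) with y = sa/(1+sa). The map is
    bounded (sn -> 1 as sa -> infinity), so ratios that saturate the
    efficiency correction - which the reference median itself always does,
    since e is estimated from it - take the limit value sn = 1.
    """
    corrected, _ = correct_ratios(reference_ratios, e)
    sa = corrected[np.isfinite(corrected)]
    sn = np.ones(len(corrected))
    y = sa / (1.0 + sa)
    sn[np.isfinite(corrected)] = (y * 0.5) / (1.0 - y * 0.5)
    return sn, np.log2(sn)


def mw_test(log2_pa_values: Sequence[float], log2_null_values: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value of measured vs null log2 ratios.

    Exact when both samples have fewer than 20 observations and no ties;
    otherwise the normal approximation with midranks and tie correction.
    """
    x = np.asarray(list(log2_pa_values), dtype=float)
    y = np.asarray(list(log2_null_values), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size < 20 and y.size < 20 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


# --- modification-state inference by mass conservation ----------------------


def infer_unmodified_percent(median_hl_unmod_pair: float) -> float:
    """Percent unmodified site in the light genotype, from a reference pair.

    The heavy partner is a genotype whose site is assumed 100% unmodified, so
    the light genotype's unmodified share is 100 / (H/L), capped at 100.
    """
    if median_hl_unmod_pair <= 0:
        raise ValueError("H/L ratio must be positive")
    return min(100.0 / median_hl_unmod_pair, 100.0)


def infer_state_composition(
    percent_unmod: float, percent_di: float
) -> StateComposition:
    """Remaining mono-hydroxylated share by conservation: 100 - unmod - di."""
    for name, v in (("percent_unmod", percent_unmod), ("percent_di", percent_di)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    if percent_unmod + percent_di > 100:
        raise ValueError(
            "inconsistent pair estimates: percent_unmod + percent_di = "
            f"{percent_unmod + percent_di} > 100"
        )
    return StateComposition(
        percent_unmodified=percent_unmod,
        percent_mono=100.0 - percent_unmod - percent_di,
        percent_di=percent_di,
    )


# --- estimator --------------------------------------------------------------


class SilacStoichiometry(BaseEstimator):
    """Per-modification-state SILAC stoichiometry estimator.

    Parameters
    ----------
    target_protein : str
        Accession of the protein carrying the quantified site; its non-site
        PSMs provide the protein-level normalizer.
    apply_filter : bool
        Run :func:`filter_psms` (confidence/uniqueness flags, single-channel
        imputation) before quantification.
    states : tuple of str
        Modification-state labels analyzed independently.

    Attributes
    ----------
    labeling_ : LabelingModel
        Estimated incorporation efficiency e.
    normalizer_ : float
        Median efficiency-corrected non-site H/L ratio.
    result_ : SilacStoichiometryResult
        Full audit trail including every intermediate.
    percent_heavy_ : dict
        ``state -> %H`` for each non-absent state.
    p_values_ : dict
        ``state -> Mann-Whitney p-value`` vs the theoretical H = L null.
    """

    def __init__(
        self,
        target_protein: str = "RPS23",
        apply_filter: bool = True,
        states: tuple = STATES,
    ):
        self.target_protein = target_protein
        self.apply_filter = apply_filter
        self.states = states

    def fit(self, psm_table: pd.DataFrame, reference_ratios: Sequence[float]):
        """Quantify a SILAC pair.

        Parameters
        ----------
        psm_table : DataFrame
            PSMs of the mixed H:L pair; columns ``sequence``, ``protein``,
            ``p62_state``, ``intensity_h``, ``intensity_l``, ``ratio_hl``,
            ``quan_result_id``, ``confidence``, ``unique``.
        reference_ratios : sequence of float
            H/L ratios of small-subunit protein PSMs from the heavy-only
            reference sample (labeling-efficiency estimation).
        """
        df = filter_psms(psm_table) if self.apply_filter else psm_table.copy()

        ref = np.asarray(list(reference_ratios), dtype=float)
        if ref.size == 0:
            raise ValueError("missing heavy-only reference PSMs (labeling efficiency)")
        self.labeling_ = labeling_efficiency(ref)
        e = self.labeling_.e

        is_target = df["protein"].astype(str) == self.target_protein
        non_site = df[is_target & (df["p62_state"] == NOT_APPLICABLE)]
        if non_site.empty:
            raise ValueError(
                f"missing non-site {self.target_protein} PSMs (protein normalizer)"
            )
        norm_ratios = pd.to_numeric(non_site["ratio_hl"], errors="coerce").dropna()
        self.normalizer_, n_norm_sat = protein_normalizer(norm_ratios, e)

        site = df[df["p62_state"].isin(self.states)]
        if site.empty:
            raise ValueError("missing site-covering PSMs (no P62 peptides)")

        ratios_by_state = {
            s: pd.to_numeric(
                site.loc[site["p62_state"] == s, "ratio_hl"], errors="coerce"
            ).dropna().to_numpy()
            for s in self.states
        }
        pn_by_state = normalize_p62_ratios(ratios_by_state, self.normalizer_)

        sn, log2_sn = theoretical_null(ref, e)

        states_out: dict[str, StateResult] = {}
        for state in self.states:
            pn = pn_by_state[state]
            if pn.size == 0:
                states_out[state] = StateResult(n_psms=0, absent=True)
                continue
            pa, n_sat = correct_ratios(pn, e)
            pa_valid = pa[~np.isnan(pa)]
            log2_pa = np.log2(pa_valid)
            h_raw = (1.0 / e) * pn / (1.0 + pn)
            n_clamped = int(np.sum(h_raw > 1.0))
            h = np.clip(h_raw, 0.0, 1.0)
            ph, pl = percent_heavy(h)
            pval = mw_test(log2_pa, log2_sn) if pa_valid.size else None
            states_out[state] = StateResult(
                n_psms=int(pn.size),
                pn=pn.tolist(),
                pa=pa_valid.tolist(),
                log2_pa=log2_pa.tolist(),
                h_values=h.tolist(),
                percent_heavy=ph,
                percent_light=pl,
                p_value=pval,
                n_saturated=n_sat,
                n_clamped=n_clamped,
            )

        self.result_ = SilacStoichiometryResult(
            labeling=self.labeling_,
            normalizer=self.normalizer_,
            n_normalizer_psms=int(len(norm_ratios)),
            n_normalizer_saturated=n_norm_sat,
            null_sn=sn.tolist(),
            null_log2_sn=log2_sn.tolist(),
            states=states_out,
        )
        self.percent_heavy_ = {
            s: r.percent_heavy for s, r in states_out.items() if not r.absent
        }
        self.p_values_ = {
            s: r.p_value for s, r in states_out.items() if not r.absent
        }
        return self


def run_silac(
    psm_table: pd.DataFrame,
    reference_ratios: Sequence[float],
    target_protein: str = "RPS23",
    apply_filter: bool = True,
) -> SilacStoichiometryResult:
    """One-call SILAC quantification; see :class:`SilacStoichiometry`."""
    est = SilacStoichiometry(target_protein=target_protein, apply_filter=apply_filter)
    est.fit(psm_table, reference_ratios)
    return est.result_
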
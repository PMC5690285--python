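"""Synthetic SILAC and TMT PSM tables with embedded ground truth.

The SILAC generator emulates a mixed heavy:light lysate pair in which the
heavy and light genotypes carry known fractions of the three modification
states at the quantified proline, plus a heavy-only reference sample for
labeling-efficiency estimation. Incomplete label incorporation is modeled as
a fraction (1 - e) of genuinely heavy-genotype molecules being counted in
the light channel. Ratio noise is multiplicative lognormal.

The TMT generator emulates a two-condition reporter-ion experiment with a
global protein-loading offset between channels and state-specific true fold
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .silac import STATES, NOT_APPLICABLE

#: Ratio emitted for a heavy-only reference at perfect incorporation (e = 1),
#: where the model ratio e/(1-e) diverges.
PERFECT_LABEL_RATIO_CAP = 1e6

_DEFAULT_TARGET = "RPS23"
# Arbitrary site-covering / non-site tryptic-scale sequences for the table.
_SITE_PEPTIDE = "QPNSAIRK"
_NONSITE_PEPTIDE = "AVGDEVLK"


def _validate_fractions(name: str, fractions) -> np.ndarray:
    arr = np.asarray(fractions, dtype=float)
    if arr.shape != (3,) or np.any(arr < 0) or not np.isclose(arr.sum(), 1.0):
        raise ValueError(
            f"{name} must be three non-negative fractions summing to 1, got {fractions}"
        )
    return arr


@dataclass
class SilacSimConfig:
    """Design of a simulated SILAC pair.

    Defaults emulate a wild-type (heavy, fully dihydroxylated) against a
    partially modified light genotype at 1:1 mixing with 95% incorporation.
    """

    e_true: float = 0.95
    state_fractions_heavy: tuple = (0.0, 0.0, 1.0)   # (unmod, mono, di)
    state_fractions_light: tuple = (0.32, 0.60, 0.08)
    n_psms_per_state: int = 200
    n_reference_psms: int = 100
    n_normalizer_psms: int = 50
    n_background_psms: int = 300
    noise_sigma: float = 0.25
    mix_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.e_true <= 1:
            raise ValueError(f"e_true must be in (0, 1], got {self.e_true}")
        _validate_fractions("state_fractions_heavy", self.state_fractions_heavy)
        _validate_fractions("state_fractions_light", self.state_fractions_light)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.mix_ratio <= 0:
            raise ValueError("mix_ratio must be positive")
        for name in ("n_psms_per_state", "n_reference_psms", "n_normalizer_psms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_background_psms < 0:
            raise ValueError("n_background_psms must be >= 0")


@dataclass
class TMTSimConfig:
    """Design of a simulated two-channel TMT experiment.

    Defaults: a loading offset of 3 between channels and a 1.6-fold
    condition-1 enrichment of the dihydroxylated state.
    """

    state_fold_changes: tuple = (1.0, 1.0, 1.6)  # (unmod, mono, di), ch1/ch2
    loading_offset: float = 3.0
    n_psms_per_state: int = 50
    n_background_psms: int = 200
    noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        fc = np.asarray(self.state_fold_changes, dtype=float)
        if fc.shape != (3,) or np.any(fc <= 0):
            raise ValueError("state_fold_changes must be three positive ratios")
        if self.loading_offset <= 0:
            raise ValueError("loading_offset must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("n_psms_per_state", "n_background_psms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _base_intensities(
    rng: np.random.Generator, n: int, sigma_ln: float = 2.0
) -> np.ndarray:
    # Whole-lysate peak areas span 3-4 decades (lognormal, sigma 2 on the
    # natural-log scale), so the observed per-channel minimum sits near a
    # detection floor well below typical abundances; single-protein digests
    # use a narrower spread (see simulate_tmt).
    return np.exp(rng.normal(np.log(1e6), sigma_ln, size=n))


def _noise(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.ones(n)


def simulate_heavy_only_reference(
    e_true: float, n: int, noise_sigma: float, seed: int
) -> np.ndarray:
    """H/L ratios of a heavy-labeled-only sample.

    The expected ratio is e/(1-e); at e = 1 a large capped ratio
    (:data:`PERFECT_LABEL_RATIO_CAP`) is emitted instead of infinity.
    """
    if not 0 < e_true <= 1:
        raise ValueError(f"e_true must be in (0, 1], got {e_true}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    expected = PERFECT_LABEL_RATIO_CAP if e_true == 1 else e_true / (1 - e_true)
    return expected * _noise(rng, noise_sigma, n)


def simulate_silac_pair(config: SilacSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the mixed-pair PSM table of a SILAC experiment.

    Per modification state, the expected H/L ratio follows from the genotype
    state fractions, the mixing ratio and the incorporation model: heavy
    channel e * mix * f_heavy, light channel f_light + (1-e) * mix * f_heavy.
    A state with zero signal in one channel yields single-channel PSMs
    (missing intensity). Returns the table and a ground-truth dict.
    """
    rng = np.random.default_rng(config.seed)
    e = config.e_true
    mix = config.mix_ratio
    f_h = _validate_fractions("state_fractions_heavy", config.state_fractions_heavy)
    f_l = _validate_fractions("state_fractions_light", config.state_fractions_light)

    rows = []
    truth_percent_heavy = {}
    for state, fh, fl in zip(STATES, f_h, f_l):
        h_signal = e * mix * fh
        l_signal = fl + (1 - e) * mix * fh
        if fh == 0 and fl == 0:
            truth_percent_heavy[state] = None
            continue
        n = config.n_psms_per_state
        base = _base_intensities(rng, n)
        noise = _noise(rng, config.noise_sigma, n)
        if l_signal == 0:
            ih, il = base, np.full(n, np.nan)
        elif h_signal == 0:
            ih, il = np.full(n, np.nan), base
        else:
            il = base
            ih = base * (h_signal / l_signal) * noise
        total = mix * fh + fl
        truth_percent_heavy[state] = 100.0 * mix * fh / total
        for i in range(n):
            rows.append(
                dict(
                    sequence=_SITE_PEPTIDE,
                    protein=_DEFAULT_TARGET,
                    p62_state=state,
                    intensity_h=ih[i],
                    intensity_l=il[i],
                    ratio_hl=(ih[i] / il[i]) if np.isfinite(ih[i]) and np.isfinite(il[i]) else np.nan,
                    quan_result_id=f"{state}_{i}",
                    confidence=True,
                    unique=True,
                    sample="pair",
                )
            )

    # Non-site PSMs of the target protein: total protein loading.
    norm_expected = e * mix / (1 + (1 - e) * mix)
    n = config.n_normalizer_psms
    base = _base_intensities(rng, n)
    noise = _noise(rng, config.noise_sigma, n)
    ih = base * norm_expected * noise
    for i in range(n):
        rows.append(
            dict(
                sequence=_NONSITE_PEPTIDE,
                protein=_DEFAULT_TARGET,
                p62_state=NOT_APPLICABLE,
                intensity_h=ih[i],
                intensity_l=base[i],
                ratio_hl=ih[i] / base[i],
                quan_result_id=f"norm_{i}",
                confidence=True,
                unique=True,
                sample="pair",
            )
        )

    # Other 40S-protein PSMs co-enriched with the target: same protein-level
    # loading ratio, not used for quantification but part of the table (they
    # set the realistic per-channel minimum used for missing-value imputation).
    n = config.n_background_psms
    if n:
        base = _base_intensities(rng, n)
        noise = _noise(rng, config.noise_sigma, n)
        ih = base * norm_expected * noise
        for i in range(n):
            rows.append(
                dict(
                    sequence=_NONSITE_PEPTIDE,
                    protein=f"RPS{3 + (i % 20)}",
                    p62_state=NOT_APPLICABLE,
                    intensity_h=ih[i],
                    intensity_l=base[i],
                    ratio_hl=ih[i] / base[i],
                    quan_result_id=f"bg_{i}",
                    confidence=True,
                    unique=True,
                    sample="pair",
                )
            )

    truth = dict(
        e_true=e,
        mix_ratio=mix,
        state_fractions_heavy=tuple(f_h),
        state_fractions_light=tuple(f_l),
        percent_heavy=truth_percent_heavy,
        noise_sigma=config.noise_sigma,
        seed=config.seed,
    )
    return pd.DataFrame(rows), truth


def simulate_tmt(config: TMTSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a two-channel TMT PSM table.

    Background (non-site) PSMs carry expected ch1/ch2 equal to the loading
    offset; site PSMs of state k carry offset * fold_change_k, with
    multiplicative lognormal noise on the ratio.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    # A purified single-protein digest spans a far narrower abundance range
    # than a whole lysate; the summed-intensity correction factor would
    # otherwise be dominated by a handful of extreme PSMs.
    sigma_ln = 0.5
    n = config.n_background_psms
    base = _base_intensities(rng, n, sigma_ln)
    noise = _noise(rng, config.noise_sigma, n)
    for i in range(n):
        rows.append(
            dict(
                sequence=_NONSITE_PEPTIDE,
                p62_state=NOT_APPLICABLE,
                intensity_ch1=base[i] * config.loading_offset * noise[i],
                intensity_ch2=base[i],
                quan_result_id=f"bg_{i}",
            )
        )
    for state, fc in zip(STATES, config.state_fold_changes):
        m = config.n_psms_per_state
        base = _base_intensities(rng, m, sigma_ln)
        noise = _noise(rng, config.noise_sigma, m)
        for i in range(m):
            rows.append(
                dict(
                    sequence=_SITE_PEPTIDE,
                    p62_state=state,
                    intensity_ch1=base[i] * config.loading_offset * fc * noise[i],
                    intensity_ch2=base[i],
                    quan_result_id=f"{state}_{i}",
                )
            )
    truth = dict(
        loading_offset=config.loading_offset,
        state_fold_changes=dict(zip(STATES, config.state_fold_changes)),
        noise_sigma=config.noise_sigma,
        seed=config.seed,
    )
    return pd.DataFrame(rows), truth
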
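"""Monoisotopic peptide mass arithmetic.

Residue masses, modification deltas, in-silico digestion, m/z computation,
targeted inclusion-list generation and ppm-windowed SILAC feature pairing.
All masses are monoisotopic and in daltons; residue coordinates are 1-based.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pyteomics import mass as _pyt_mass

#: Mass of a proton (Da), used for protonated m/z.
PROTON_MASS = 1.00727646
#: Mass of one water molecule (Da), added once per peptide chain.
WATER_MASS = 18.010565
#: Monoisotopic mass shift of one added oxygen (hydroxylation).
OXYGEN_ADDITION = 15.994915

# Isotope mass differences used for the heavy-lysine (K8: 13C6, 15N2) delta.
_C13_MINUS_C12 = 13.00335484 - 12.0
_N15_MINUS_N14 = 15.00010890 - 14.00307401

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pyt_mass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

N_TERM = "N-term"
C_TERM = "C-term"


class UnknownResidueError(ValueError):
    """A sequence contains a character outside the residue mass table."""


@dataclass(frozen=True)
class ModificationDelta:
    """A named monoisotopic mass shift restricted to certain targets.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"dioxidation"``.
    targets : frozenset of str
        One-letter residue codes and/or the terminus markers ``"N-term"`` /
        ``"C-term"`` the modification may attach to.
    delta : float
        Monoisotopic mass shift in Da.
    """

    name: str
    targets: frozenset
    delta: float

    def allows(self, residue_or_terminus: str) -> bool:
        return residue_or_terminus in self.targets


def _mod(name: str, targets: Iterable[str], delta: float) -> ModificationDelta:
    return ModificationDelta(name, frozenset(targets), delta)


#: Registry of the variable modifications this workflow quantifies.
MODIFICATIONS: dict[str, ModificationDelta] = {
    m.name: m
    for m in (
        _mod("oxidation", ("P", "M"), OXYGEN_ADDITION),
        _mod("dioxidation", ("P",), 2 * OXYGEN_ADDITION),
        _mod("deamidation", ("N", "Q"), 0.984016),
        _mod("k8_heavy", ("K",), 6 * _C13_MINUS_C12 + 2 * _N15_MINUS_N14),
        # TMT 10/6-plex reagent; labels free amines (K side chains, N-terminus).
        _mod("tmt", ("K", N_TERM), 229.162932),
    )
}


def heavy_lysine_delta() -> float:
    """Mass shift of a 13C6,15N2 (K8) heavy lysine over light lysine, in Da.

    Computed from standard isotope masses: six 13C-for-12C substitutions plus
    two 15N-for-14N substitutions, 8.014199 Da (8.014 at three decimals).
    """
    return 6 * _C13_MINUS_C12 + 2 * _N15_MINUS_N14


def _resolve_mod(mod) -> ModificationDelta:
    if isinstance(mod, ModificationDelta):
        return mod
    try:
        return MODIFICATIONS[mod]
    except KeyError:
        raise KeyError(
            f"unknown modification {mod!r}; registered: {sorted(MODIFICATIONS)}"
        ) from None


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for i, aa in enumerate(sequence, start=1):
        if aa not in RESIDUE_MASSES:
            raise UnknownResidueError(
                f"unknown residue code {aa!r} at position {i} of {sequence!r}"
            )


def peptide_mass(sequence: str, modifications: Sequence = ()) -> float:
    """Neutral monoisotopic mass of a (possibly modified) peptide, in Da.

    ``modifications`` is an iterable of ``(position, mod)`` pairs where
    ``position`` is a 1-based residue index or a terminus marker
    (``"N-term"`` / ``"C-term"``) and ``mod`` is a :class:`ModificationDelta`
    or a registered name. The mass is the residue-mass sum plus one water
    plus the sum of modification deltas.
    """
    _validate_sequence(sequence)
    total = sum(RESIDUE_MASSES[aa] for aa in sequence) + WATER_MASS
    for position, mod in modifications:
        mod = _resolve_mod(mod)
        if position in (N_TERM, C_TERM):
            target = position
        else:
            if not 1 <= int(position) <= len(sequence):
                raise ValueError(
                    f"modification position {position} outside 1..{len(sequence)}"
                )
            target = sequence[int(position) - 1]
        if not mod.allows(target):
            raise ValueError(
                f"modification {mod.name!r} does not target {target!r}"
            )
        total += mod.delta
    return total


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of a positively protonated species: (M + z·proton) / z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def neutral_mass_from_mz(mz_value: float, charge: int) -> float:
    """Inverse of :func:`mz`: neutral mass from observed m/z and charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz_value * charge - charge * PROTON_MASS


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide sequence with positioned modifications and a charge state."""

    sequence: str
    modifications: tuple = ()
    charge: int = 1

    def __post_init__(self):
        _validate_sequence(self.sequence)
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")

    @property
    def neutral_mass(self) -> float:
        return peptide_mass(self.sequence, self.modifications)

    @property
    def mz(self) -> float:
        return mz(self.neutral_mass, self.charge)


# --- in-silico digestion ----------------------------------------------------

_CLEAVAGE_RULES = {
    # LysC cleaves C-terminal to lysine.
    "lysc": re.compile(r"(?<=K)"),
    # Trypsin cleaves C-terminal to K/R but not when followed by proline.
    "trypsin": re.compile(r"(?<=[KR])(?!P)"),
}


def digest(
    protein_sequence: str, enzyme: str = "trypsin", missed_cleavages: int = 0
) -> list[tuple[str, int, int]]:
    """In-silico proteolytic digestion.

    Returns ``(peptide, start, end)`` tuples with 1-based inclusive
    coordinates, ordered along the protein. With ``missed_cleavages`` > 0 the
    list additionally contains every run of up to that many skipped sites.
    At zero missed cleavages the peptides tile the protein exactly.
    """
    enzyme_key = enzyme.lower().replace("-", "")
    if enzyme_key not in _CLEAVAGE_RULES:
        raise ValueError(
            f"unsupported enzyme {enzyme!r}; supported: {sorted(_CLEAVAGE_RULES)}"
        )
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if not protein_sequence:
        return []

    rule = _CLEAVAGE_RULES[enzyme_key]
    cut_points = [0]
    cut_points += [m.start() for m in rule.finditer(protein_sequence)
                   if 0 < m.start() < len(protein_sequence)]
    cut_points.append(len(protein_sequence))

    base = [
        (protein_sequence[a:b], a + 1, b)
        for a, b in zip(cut_points, cut_points[1:])
    ]
    peptides = list(base)
    for n_missed in range(1, missed_cleavages + 1):
        for i in range(len(base) - n_missed):
            seq = "".join(p for p, _, _ in base[i : i + n_missed + 1])
            peptides.append((seq, base[i][1], base[i + n_missed][2]))
    peptides.sort(key=lambda t: (t[1], t[2]))
    return peptides


# --- inclusion lists --------------------------------------------------------

#: Hydroxylation states of the target proline, in increasing mass order.
P62_STATES = ("unmodified", "mono", "di")

_STATE_MODS = {"unmodified": None, "mono": "oxidation", "di": "dioxidation"}


def build_inclusion_list(
    sequence: str,
    label_scheme: str = "tmt",
    charge: int = 3,
    states: Sequence[str] = P62_STATES,
    deamidation: Sequence[bool] = (False, True),
) -> list[tuple[str, float]]:
    """Targeted precursor m/z list for each hydroxylation/deamidation state.

    For the TMT scheme one label is placed on the N-terminus and one on each
    lysine. Hydroxylations go on the first proline, deamidation on the first
    asparagine (falling back to glutamine). Returns ``(description, m/z)``
    pairs sorted by m/z ascending.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    scheme = label_scheme.lower()
    if scheme not in ("tmt", "none"):
        raise ValueError(f"unsupported label scheme {label_scheme!r}")
    _validate_sequence(sequence)

    base_mods: list[tuple] = []
    if scheme == "tmt":
        base_mods.append((N_TERM, "tmt"))
        base_mods += [(i, "tmt") for i, aa in enumerate(sequence, 1) if aa == "K"]

    p_pos = sequence.find("P") + 1
    nq_pos = sequence.find("N") + 1 or sequence.find("Q") + 1

    entries = []
    for state, deam in itertools.product(states, deamidation):
        mods = list(base_mods)
        if _STATE_MODS[state] is not None:
            if p_pos == 0:
                raise ValueError(f"no proline in {sequence!r} to hydroxylate")
            mods.append((p_pos, _STATE_MODS[state]))
        if deam:
            if nq_pos == 0:
                raise ValueError(f"no N/Q in {sequence!r} to deamidate")
            mods.append((nq_pos, "deamidation"))
        label = state + ("+deamidated" if deam else "")
        entries.append((label, mz(peptide_mass(sequence, mods), charge)))
    entries.sort(key=lambda t: t[1])
    return entries


# --- SILAC feature pairing --------------------------------------------------


@dataclass(frozen=True)
class MSFeature:
    """An observed MS1 feature with its assigned peptide's lysine count."""

    identifier: str
    neutral_mass: float = None
    mz: float = None
    charge: int = None
    n_lysines: int = 0
    mass: float = field(init=False)

    def __post_init__(self):
        if self.neutral_mass is not None:
            m = float(self.neutral_mass)
        elif self.mz is not None and self.charge is not None:
            m = neutral_mass_from_mz(self.mz, self.charge)
        else:
            raise ValueError("provide neutral_mass, or mz together with charge")
        if m <= 0:
            raise ValueError(f"feature mass must be positive, got {m}")
        if self.n_lysines < 0:
            raise ValueError("lysine count must be >= 0")
        object.__setattr__(self, "mass", m)


def match_silac_pairs(
    features: Sequence[MSFeature],
    ppm_tolerance: float = 4.0,
    heavy_delta_per_k: float = None,
) -> list[tuple[MSFeature, MSFeature]]:
    """Pair light/heavy SILAC partner features within a ppm mass window.

    A light feature i pairs with a heavy feature j when
    ``|mass_j - (mass_i + nK * delta)| / mass_j * 1e6 <= ppm_tolerance``,
    with nK the light feature's assigned lysine count (ppm is taken relative
    to the heavier member). Each feature joins at most one pair; candidate
    pairs are accepted closest-mass first, ties broken by lower identifier,
    so the result is independent of input order.
    """
    if ppm_tolerance < 0:
        raise ValueError("ppm tolerance must be non-negative")
    if heavy_delta_per_k is None:
        heavy_delta_per_k = heavy_lysine_delta()

    candidates = []
    for light, heavy in itertools.permutations(features, 2):
        if light.n_lysines < 1:
            continue
        expected = light.mass + light.n_lysines * heavy_delta_per_k
        ppm = abs(heavy.mass - expected) / heavy.mass * 1e6
        if ppm <= ppm_tolerance:
            candidates.append(
                (ppm, str(light.identifier), str(heavy.identifier), light, heavy)
            )
    candidates.sort(key=lambda t: t[:3])

    used: set[str] = set()
    pairs = []
    for ppm, lid, hid, light, heavy in candidates:
        if lid in used or hid in used:
            continue
        used.update((lid, hid))
        pairs.append((light, heavy))
    return pairs
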
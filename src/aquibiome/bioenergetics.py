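"""Available-energy (∆G_A) calculations for anaerobic groundwater metabolisms.

The energy a microbial functional group can harvest from its respiratory
reaction under in situ conditions is

    ∆G_r = ∆G°_T + R·T·ln Q,      ∆G_A = −∆G_r

where ∆G°_T is the standard-state free energy change at the groundwater
temperature, and the reaction quotient Q is built from molal concentrations
and extended Debye-Hückel activity coefficients.  A reaction is considered
exploitable when ∆G_A meets a minimum energy quantum ∆G_min (default
10 kJ per mole of reaction).

The catalog covers the H2-fueled metabolisms relevant to sulfate-zoned
aquifers — sulfate reduction, hydrogenotrophic methanogenesis, anaerobic
oxidation of methane (AOM) as reverse methanogenesis, direct
sulfate-coupled AOM, and ferrihydrite reduction — written as 8-electron
forms per mole of terminal acceptor (or CH4), except iron reduction which
is written per mole of H2 (2 electrons).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geochem import (
    Measurement,
    SulfateClass,
    WellChemistry,
    classify_sulfate,
    estimate_ionic_strength,
)

__all__ = [
    "Phase",
    "ThermoSpecies",
    "REGISTRY",
    "RedoxReaction",
    "reaction_catalog",
    "SolutionState",
    "EnergyConfig",
    "EnergyResult",
    "standard_free_energy_at_T",
    "activity_coefficient",
    "reaction_quotient",
    "solution_state_from_chemistry",
    "available_energy",
    "h2_threshold_aom",
    "h2_threshold_closed_form",
    "assumption_sensitivity",
    "sulfide_shift_per_decade",
]

R_GAS = 8.314462618e-3  # kJ mol⁻¹ K⁻¹
T_REF = 298.15  # K


class Phase(str, enum.Enum):
    AQUEOUS = "aqueous"
    GAS = "gas"
    MINERAL = "mineral"
    WATER = "water"


@dataclass(frozen=True)
class ThermoSpecies:
    """A thermodynamic species: formation properties plus ion parameters.

    ``dGf0``/``dHf0`` are standard Gibbs free energy / enthalpy of formation
    at 25 °C in kJ/mol; ``ion_size`` is the Debye-Hückel å parameter in Å
    (ignored for neutral species); ``elements`` maps element symbol to
    count, used for reaction balance checks.
    """

    name: str
    charge: int
    dGf0: float
    dHf0: float
    elements: Mapping[str, int]
    ion_size: float = 0.0
    phase: Phase = Phase.AQUEOUS

    @property
    def unit_activity(self) -> bool:
        return self.phase in (Phase.WATER, Phase.MINERAL)


def _sp(name, charge, dGf0, dHf0, elements, ion_size=0.0, phase=Phase.AQUEOUS):
    return ThermoSpecies(name, charge, dGf0, dHf0, dict(elements), ion_size, phase)


# Formation constants in kJ/mol at 25 °C, from the SUPCRT92 / CODATA
# lineage of standard compilations (converted from kcal where needed).
# Ion sizes å (Å) follow the Kielland tabulation.
REGISTRY: dict[str, ThermoSpecies] = {
    s.name: s
    for s in [
        _sp("H2O", 0, -237.183, -285.838, {"H": 2, "O": 1}, phase=Phase.WATER),
        _sp("H+", +1, 0.0, 0.0, {"H": 1}, ion_size=9.0),
        _sp("SO4--", -2, -744.459, -909.602, {"S": 1, "O": 4}, ion_size=4.0),
        _sp("HS-", -1, 11.966, -16.108, {"H": 1, "S": 1}, ion_size=3.5),
        _sp("H2(aq)", 0, 17.723, -4.184, {"H": 2}),
        _sp("CH4(aq)", 0, -34.451, -87.906, {"C": 1, "H": 4}),
        _sp("HCO3-", -1, -586.940, -689.933, {"H": 1, "C": 1, "O": 3}, ion_size=4.0),
        _sp("CO2(aq)", 0, -385.974, -413.798, {"C": 1, "O": 2}),
        _sp("Fe++", +2, -78.870, -89.100, {"Fe": 1}, ion_size=6.0),
        # 2-line ferrihydrite, unit activity solid
        _sp("Fe(OH)3", 0, -708.5, -823.0, {"Fe": 1, "O": 3, "H": 3},
            phase=Phase.MINERAL),
    ]
}


class ReactionName(str, enum.Enum):
    SULFATE_REDUCTION_H2 = "sulfate_reduction_h2"
    METHANOGENESIS_H2 = "methanogenesis_h2"
    AOM_REVERSE = "aom_reverse"
    AOM_SULFATE_COUPLED = "aom_sulfate_coupled"
    IRON_REDUCTION_H2 = "iron_reduction_h2"


@dataclass(frozen=True)
class RedoxReaction:
    """A full (electron-balanced) redox reaction over registry species.

    ``stoichiometry`` maps species name to its signed coefficient v_i
    (products positive).  ``electrons`` is the number of electrons
    transferred between the underlying half-reactions.
    """

    name: str
    stoichiometry: Mapping[str, float]
    electrons: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    def check_balance(self, registry: Mapping[str, ThermoSpecies] = REGISTRY) -> None:
        """Raise ValueError unless element- and charge-balanced."""
        elements: dict[str, float] = {}
        charge = 0.0
        for name, v in self.stoichiometry.items():
            if name not in registry:
                raise KeyError(f"species {name!r} not in registry")
            sp = registry[name]
            charge += v * sp.charge
            for el, n in sp.elements.items():
                elements[el] = elements.get(el, 0.0) + v * n
        bad = {el: n for el, n in elements.items() if abs(n) > 1e-9}
        if bad:
            raise ValueError(f"{self.name}: element imbalance {bad}")
        if abs(charge) > 1e-9:
            raise ValueError(f"{self.name}: charge imbalance {charge}")

    def reversed(self, name: str) -> "RedoxReaction":
        return RedoxReaction(
            name, {s: -v for s, v in self.stoichiometry.items()}, self.electrons
        )


def reaction_catalog() -> list[RedoxReaction]:
    """The five balanced metabolic reactions, products positive.

    Sulfate reduction, methanogenesis, both AOM variants are 8-electron
    forms per mole of SO4²⁻/HCO3⁻/CH4; iron reduction is per mole of H2.
    """
    sr = RedoxReaction(
        ReactionName.SULFATE_REDUCTION_H2.value,
        {"SO4--": -1, "H2(aq)": -4, "H+": -1, "HS-": +1, "H2O": +4},
        electrons=8,
    )
    mg = RedoxReaction(
        ReactionName.METHANOGENESIS_H2.value,
        {"HCO3-": -1, "H2(aq)": -4, "H+": -1, "CH4(aq)": +1, "H2O": +3},
        electrons=8,
    )
    aom = mg.reversed(ReactionName.AOM_REVERSE.value)
    aom_sr = RedoxReaction(
        ReactionName.AOM_SULFATE_COUPLED.value,
        {"CH4(aq)": -1, "SO4--": -1, "HCO3-": +1, "HS-": +1, "H2O": +1},
        electrons=8,
    )
    fe = RedoxReaction(
        ReactionName.IRON_REDUCTION_H2.value,
        {"Fe(OH)3": -2, "H2(aq)": -1, "H+": -4, "Fe++": +2, "H2O": +6},
        electrons=2,
    )
    catalog = [sr, mg, aom, aom_sr, fe]
    for rxn in catalog:
        rxn.check_balance()
    return catalog


def get_reaction(name: str) -> RedoxReaction:
    for rxn in reaction_catalog():
        if rxn.name == name:
            return rxn
    raise KeyError(f"unknown reaction {name!r}")


def standard_free_energy_at_T(
    rxn: RedoxReaction,
    T: float,
    registry: Mapping[str, ThermoSpecies] = REGISTRY,
) -> float:
    """∆G°_T (kJ/mol) via the Gibbs-Helmholtz relation with constant ∆H°.

    ∆G°_T = ∆G°_298 · (T/T_ref) + ∆H°_298 · (1 − T/T_ref).  Adequate for
    the small departure of aquifer temperatures (12-16 °C) from 25 °C.
    """
    if not (273.0 < T < 323.0):
        raise ValueError(f"temperature {T} K outside supported range (273, 323)")
    dG298 = 0.0
    dH298 = 0.0
    for name, v in rxn.stoichiometry.items():
        if name not in registry:
            raise KeyError(f"species {name!r} not in registry")
        sp = registry[name]
        dG298 += v * sp.dGf0
        dH298 += v * sp.dHf0
    ratio = T / T_REF
    return dG298 * ratio + dH298 * (1.0 - ratio)


# Debye-Hückel A (kg½ mol⁻½) and B (kg½ mol⁻½ Å⁻¹, ×10⁻⁸ absorbed) for
# water at 1 bar, 0-50 °C (standard water-property tables).
_DH_TEMPS_C = np.array([0.0, 10.0, 20.0, 25.0, 30.0, 40.0, 50.0])
_DH_A = np.array([0.4913, 0.4976, 0.5050, 0.5092, 0.5141, 0.5241, 0.5351])
_DH_B = np.array([0.3247, 0.3261, 0.3276, 0.3283, 0.3291, 0.3307, 0.3325])


def debye_huckel_params(T: float) -> tuple[float, float]:
    """Interpolated extended Debye-Hückel A and B at temperature T (K)."""
    t_c = T - 273.15
    if not (_DH_TEMPS_C[0] <= t_c <= _DH_TEMPS_C[-1]):
        raise ValueError(f"temperature {t_c} °C outside Debye-Hückel table (0-50)")
    return (
        float(np.interp(t_c, _DH_TEMPS_C, _DH_A)),
        float(np.interp(t_c, _DH_TEMPS_C, _DH_B)),
    )


def activity_coefficient(z: int, a_ring: float, I: float, T: float) -> float:
    """Extended Debye-Hückel single-ion activity coefficient.

    log10 y = −A(T)·z²·√I / (1 + B(T)·å·√I); neutral species return 1.
    """
    if I < 0:
        raise ValueError(f"negative ionic strength {I}")
    if z == 0 or I == 0:
        return 1.0
    A, B = debye_huckel_params(T)
    sqrt_i = math.sqrt(I)
    log10_y = -A * z * z * sqrt_i / (1.0 + B * a_ring * sqrt_i)
    return 10.0 ** log10_y


@dataclass(frozen=True)
class SolutionState:
    """In situ solution composition for quotient evaluation.

    ``molalities`` in mol/kg; ``activity_overrides`` supplies activities
    directly (used for H+, whose activity is 10^−pH by definition of the
    measurement).  Activity coefficients not overridden are computed from
    the extended Debye-Hückel model at (I, T).
    """

    temperature: float  # K
    ionic_strength: float  # mol/kg
    molalities: Mapping[str, float]
    activity_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be ≥ 0")
        for name, m in self.molalities.items():
            if m < 0:
                raise ValueError(f"negative molality for {name}")
        object.__setattr__(self, "molalities", dict(self.molalities))
        object.__setattr__(self, "activity_overrides", dict(self.activity_overrides))

    def activity(self, name: str, registry: Mapping[str, ThermoSpecies] = REGISTRY) -> float:
        sp = registry[name]
        if sp.unit_activity:
            return 1.0
        if name in self.activity_overrides:
            return self.activity_overrides[name]
        if name not in self.molalities:
            raise KeyError(f"no molality for species {name!r}")
        m = self.molalities[name]
        if m <= 0:
            raise ValueError(
                f"zero molality for {name!r}; supply a floor value or exclude the well"
            )
        y = activity_coefficient(
            sp.charge, sp.ion_size, self.ionic_strength, self.temperature
        )
        return y * m

    def with_molality(self, name: str, m: float) -> "SolutionState":
        new = dict(self.molalities)
        new[name] = m
        return replace(self, molalities=new)


def reaction_quotient(
    rxn: RedoxReaction,
    state: SolutionState,
    registry: Mapping[str, ThermoSpecies] = REGISTRY,
) -> float:
    """ln Q = Σ v_i ln(y_i·m_i) over aqueous species (water/minerals drop out)."""
    ln_q = 0.0
    for name, v in rxn.stoichiometry.items():
        sp = registry[name]
        if sp.unit_activity:
            continue
        ln_q += v * math.log(state.activity(name, registry))
    return ln_q


@dataclass(frozen=True)
class EnergyConfig:
    """Assumptions and policies for per-well energy calculations.

    ``dG_min``: minimum exploitable energy, kJ per mole of reaction.
    ``sulfide_molal`` / ``fe2_molal``: assumed molalities of analytes the
    survey did not report (dissolved sulfide, ferrous iron).
    ``censoring``: how below-detection analytes enter the quotient
    ("limit" | "half" | "exclude").
    ``conductivity_k``: ionic-strength-per-conductance proxy constant.
    """

    dG_min: float = 10.0
    sulfide_molal: float = 1.0e-5
    fe2_molal: float = 1.0e-5
    censoring: str = "limit"
    conductivity_k: float = 1.6e-5
    registry: Mapping[str, ThermoSpecies] = field(default_factory=lambda: REGISTRY)


#: registry species fed from measured analytes (with scale to mol/kg)
_MEASURED_SPECIES = {
    "SO4--": ("so4", 1e-3),
    "CH4(aq)": ("ch4_aq", 1e-6),
    "H2(aq)": ("h2_aq", 1e-9),
    "HCO3-": ("dic", 1e-3),
}
#: registry species filled from declared assumptions
_ASSUMED_SPECIES = ("HS-", "Fe++")


@dataclass(frozen=True)
class EnergyResult:
    """Per-well, per-reaction available energy."""

    well_id: str
    reaction: str
    dG0_T: float = math.nan
    ln_q: float = math.nan
    dG_r: float = math.nan
    dG_A: float = math.nan
    per_electron: float = math.nan
    viable: bool = False
    ok: bool = True
    missing: tuple[str, ...] = ()
    assumptions: tuple[str, ...] = ()


def solution_state_from_chemistry(
    chem: WellChemistry,
    config: EnergyConfig = EnergyConfig(),
) -> tuple[SolutionState, tuple[str, ...], tuple[str, ...]]:
    """Build a SolutionState from a well record.

    Returns (state, missing_analytes, assumption_flags).  DIC is treated
    entirely as bicarbonate (valid in the survey's pH window 7.1-7.9);
    sulfide and ferrous iron take their configured assumed molalities; the
    H+ activity is 10^−pH directly.
    """
    missing: list[str] = []
    molal: dict[str, float] = {}
    for species, (attr, scale) in _MEASURED_SPECIES.items():
        meas: Measurement = getattr(chem, attr)
        value = meas.resolve(config.censoring)
        if value is None:
            missing.append(species)
        else:
            molal[species] = value * scale
    assumptions = []
    molal["HS-"] = config.sulfide_molal
    assumptions.append(f"HS-={config.sulfide_molal:g}")
    molal["Fe++"] = config.fe2_molal
    assumptions.append(f"Fe++={config.fe2_molal:g}")
    try:
        ionic = estimate_ionic_strength(chem, config.conductivity_k)
    except ValueError:
        ionic = 0.0
        assumptions.append("I=0 (no conductance)")
    state = SolutionState(
        temperature=chem.temperature_k,
        ionic_strength=ionic,
        molalities=molal,
        activity_overrides={"H+": 10.0 ** (-chem.ph)},
    )
    return state, tuple(missing), tuple(assumptions)


def available_energy(
    rxn: RedoxReaction,
    chem: WellChemistry,
    config: EnergyConfig = EnergyConfig(),
) -> EnergyResult:
    """∆G_A of one reaction in one well: ∆G_r = ∆G°_T + RT ln Q, ∆G_A = −∆G_r.

    Wells lacking a required measured analyte yield ``ok=False`` with the
    missing species named, rather than an imputed number.
    """
    state, missing_all, assumptions = solution_state_from_chemistry(chem, config)
    needed = [
        s for s in rxn.stoichiometry
        if s in _MEASURED_SPECIES and s in missing_all
    ]
    if needed:
        return EnergyResult(
            chem.well_id, rxn.name, ok=False, missing=tuple(needed),
            assumptions=assumptions,
        )
    registry = config.registry
    dG0_T = standard_free_energy_at_T(rxn, chem.temperature_k, registry)
    ln_q = reaction_quotient(rxn, state, registry)
    dG_r = dG0_T + R_GAS * chem.temperature_k * ln_q
    dG_A = -dG_r
    used_assumptions = tuple(
        a for a in assumptions
        if a.split("=")[0] in rxn.stoichiometry or a.startswith("I=")
    )
    return EnergyResult(
        well_id=chem.well_id,
        reaction=rxn.name,
        dG0_T=dG0_T,
        ln_q=ln_q,
        dG_r=dG_r,
        dG_A=dG_A,
        per_electron=dG_A / rxn.electrons,
        viable=dG_A >= config.dG_min,
        ok=True,
        assumptions=used_assumptions,
    )


def _aom_dga_at_h2(
    chem: WellChemistry, m_h2: float, config: EnergyConfig
) -> float:
    rxn = get_reaction(ReactionName.AOM_REVERSE.value)
    state, missing, _ = solution_state_from_chemistry(chem, config)
    state = state.with_molality("H2(aq)", m_h2)
    needed = [s for s in rxn.stoichiometry if s in _MEASURED_SPECIES
              and s != "H2(aq)" and s in missing]
    if needed:
        raise ValueError(f"{chem.well_id}: missing analytes {needed} for AOM threshold")
    dG0_T = standard_free_energy_at_T(rxn, chem.temperature_k, config.registry)
    ln_q = reaction_quotient(rxn, state, config.registry)
    return -(dG0_T + R_GAS * chem.temperature_k * ln_q)


def h2_threshold_aom(
    chem: WellChemistry,
    config: EnergyConfig = EnergyConfig(),
    bracket: tuple[float, float] = (1e-15, 1e-3),
    tol: float = 1e-9,
    max_iter: int = 200,
) -> float:
    """Dissolved H2 (nM) at which AOM (reverse methanogenesis) breaks even.

    AOM produces H2 (coefficient +4), so its ∆G_A falls as H2 rises; the
    root of ∆G_A = 0 is found by bisection on log10 m(H2) within
    ``bracket`` (mol/kg) to |∆G_A| < ``tol`` kJ/mol.
    """
    lo, hi = (math.log10(bracket[0]), math.log10(bracket[1]))
    f_lo = _aom_dga_at_h2(chem, 10.0 ** lo, config)
    f_hi = _aom_dga_at_h2(chem, 10.0 ** hi, config)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"{chem.well_id}: no ∆G_A sign change in H2 bracket {bracket}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _aom_dga_at_h2(chem, 10.0 ** mid, config)
        if abs(f_mid) < tol:
            return 10.0 ** mid * 1e9
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 10.0 ** (0.5 * (lo + hi)) * 1e9


def h2_threshold_closed_form(
    chem: WellChemistry, config: EnergyConfig = EnergyConfig()
) -> float:
    """Algebraic break-even H2 (nM): ln a_H2 = (ln K − ln Q_rest) / 4.

    Because H2 is neutral (a = m) and enters the AOM quotient with
    coefficient +4, the root is available in closed form; serves as the
    independent check on the bisection solver.
    """
    rxn = get_reaction(ReactionName.AOM_REVERSE.value)
    state, missing, _ = solution_state_from_chemistry(chem, config)
    needed = [s for s in rxn.stoichiometry if s in _MEASURED_SPECIES
              and s != "H2(aq)" and s in missing]
    if needed:
        raise ValueError(f"{chem.well_id}: missing analytes {needed} for AOM threshold")
    dG0_T = standard_free_energy_at_T(rxn, chem.temperature_k, config.registry)
    rt = R_GAS * chem.temperature_k
    ln_k = -dG0_T / rt
    partial = RedoxReaction(
        "aom_without_h2",
        {s: v for s, v in rxn.stoichiometry.items() if s != "H2(aq)"},
        rxn.electrons,
    )
    ln_q_rest = reaction_quotient(partial, state, config.registry)
    ln_a_h2 = (ln_k - ln_q_rest) / 4.0
    return math.exp(ln_a_h2) * 1e9


def assumption_sensitivity(
    rxn: RedoxReaction,
    chem: WellChemistry,
    species_attr: str,
    molalities: Sequence[float],
    config: EnergyConfig = EnergyConfig(),
) -> list[tuple[float, float]]:
    """Sweep an assumed molality (``sulfide_molal`` or ``fe2_molal``).

    Returns (molality, ∆G_A) pairs, exposing how strongly a declared
    assumption moves the result (logarithmic: RT·ln10 per decade per unit
    stoichiometric coefficient).
    """
    if species_attr not in ("sulfide_molal", "fe2_molal"):
        raise ValueError(f"not an assumed species field: {species_attr!r}")
    out = []
    for m in molalities:
        cfg = replace(config, **{species_attr: m})
        res = available_energy(rxn, chem, cfg)
        if not res.ok:
            raise ValueError(f"{chem.well_id}: {res.missing} missing")
        out.append((m, res.dG_A))
    return out


def sulfide_shift_per_decade(
    chem: WellChemistry, config: EnergyConfig = EnergyConfig()
) -> float:
    """kJ/mol change of sulfate-reduction ∆G_A per decade of assumed sulfide."""
    rxn = get_reaction(ReactionName.SULFATE_REDUCTION_H2.value)
    pairs = assumption_sensitivity(
        rxn, chem, "sulfide_molal",
        [config.sulfide_molal, config.sulfide_molal / 10.0], config,
    )
    return pairs[1][1] - pairs[0][1]
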